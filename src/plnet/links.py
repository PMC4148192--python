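"""Deriving scored gene-pair link sets from raw evidence.

Every evidence source — co-expression matrices, protein-interaction tables,
annotation vocabularies, or pre-scored pair lists — is reduced to a
:class:`LinkSet`: a set of unordered gene pairs with one real-valued score
each.  Raw link sets are later calibrated against the phenotype benchmark
and only then integrated into the combined network.
"""

from __future__ import annotations

import itertools
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import FormatError, PlnetError, logger, pair_key
from .ontology import AnnotationSet, Ontology
from .semsim import (
    SemanticSimilarity,
    as_benchmark,
    gene_similarity_flat,
    information_content,
)

RAW = "raw"
RESCORED = "rescored"


@dataclass
class LinkSet:
    """One evidence source's scored, unordered gene pairs."""

    source: str
    pairs: dict = field(default_factory=dict)  # (a, b) sorted -> float
    score_kind: str = RAW
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.score_kind not in (RAW, RESCORED):
            raise ValueError(f"score_kind must be raw/rescored, got {self.score_kind!r}")
        clean = {}
        for (a, b), v in self.pairs.items():
            clean[pair_key(a, b)] = float(v)
        self.pairs = clean

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        return pair_key(*pair) in self.pairs

    def items(self):
        return self.pairs.items()

    def genes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.pairs:
            out.add(a)
            out.add(b)
        return out

    def score(self, g1: str, g2: str) -> float:
        return self.pairs[pair_key(g1, g2)]


# ---------------------------------------------------------------------------
# Co-expression
# ---------------------------------------------------------------------------


def coexpression_links(
    expr: pd.DataFrame,
    min_shared: int = 10,
    floor: float = 0.0,
    source: str = "coexpression",
) -> LinkSet:
    """Pearson correlation of expression profiles over shared tissues.

    A gene counts as expressed in a sample when its value is non-missing and
    above ``floor``.  A pair is scored only when both genes are expressed in
    at least ``min_shared`` common samples, and the correlation uses exactly
    those shared samples.  Pairs whose shared profile has zero variance are
    skipped (the correlation is undefined) and counted in a log summary.
    """
    if min_shared < 2:
        raise ValueError("min_shared must be >= 2")
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene ids in expression matrix: {dups[:5]}")
    if expr.shape[1] < 2:
        raise FormatError("expression matrix needs at least 2 samples")
    genes = list(expr.index)
    x = expr.to_numpy(dtype=float)
    expressed = np.isfinite(x) & (x > floor)

    pairs: dict[tuple[str, str], float] = {}
    n_zero_var = 0
    for i, j in itertools.combinations(range(len(genes)), 2):
        mask = expressed[i] & expressed[j]
        if int(mask.sum()) < min_shared:
            continue
        xi = x[i, mask]
        xj = x[j, mask]
        xi = xi - xi.mean()
        xj = xj - xj.mean()
        denom = np.sqrt((xi * xi).sum() * (xj * xj).sum())
        if denom == 0.0:
            n_zero_var += 1
            continue
        r = float((xi * xj).sum() / denom)
        pairs[pair_key(genes[i], genes[j])] = max(-1.0, min(1.0, r))
    if n_zero_var:
        logger.info(
            "%s: skipped %d pair(s) with zero-variance shared profiles",
            source,
            n_zero_var,
        )
    return LinkSet(source=source, pairs=pairs, score_kind=RAW)


def read_expression_tsv(path: str) -> pd.DataFrame:
    """Genes x samples TSV with a header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return df.astype(float)


# ---------------------------------------------------------------------------
# Physical interactions
# ---------------------------------------------------------------------------


def _clean_interactions(tab: pd.DataFrame) -> pd.DataFrame:
    required = {"gene_a", "gene_b", "assay"}
    if not required.issubset(tab.columns):
        raise FormatError(f"interaction table needs columns {sorted(required)}")
    tab = tab[tab["gene_a"] != tab["gene_b"]].copy()
    a = tab[["gene_a", "gene_b"]].min(axis=1)
    b = tab[["gene_a", "gene_b"]].max(axis=1)
    tab["gene_a"], tab["gene_b"] = a, b
    return tab.drop_duplicates(["gene_a", "gene_b", "assay"])


def ppi_direct_links(
    tab: pd.DataFrame,
    benchmark,
    min_benchmarked: int = 100,
    source: str = "ppi",
) -> list[LinkSet]:
    """Score binary interactions by per-assay benchmark medians.

    Physical interactions carry no intrinsic score, so every pair reported
    by a given assay type receives the same weight: the median phenotype
    similarity of that assay's benchmarked pairs.  This median is already on
    the benchmark scale, so the returned link sets are marked rescored.
    Assay types with fewer than ``min_benchmarked`` benchmarked pairs are
    dropped with a warning.  One link set is returned per assay, so a pair
    observed in two assays keeps both candidate scores until integration.
    """
    bench = as_benchmark(benchmark)
    tab = _clean_interactions(tab)
    out: list[LinkSet] = []
    for assay, grp in tab.groupby("assay", sort=True):
        pairs = {pair_key(a, b) for a, b in zip(grp["gene_a"], grp["gene_b"])}
        sims = []
        for a, b in pairs:
            s = bench.pair_similarity(a, b)
            if s is not None:
                sims.append(s)
        if len(sims) < min_benchmarked:
            logger.warning(
                "%s assay %r dropped: only %d benchmarked pair(s) (< %d)",
                source,
                assay,
                len(sims),
                min_benchmarked,
            )
            continue
        med = float(np.median(sims))
        out.append(
            LinkSet(
                source=f"{source}:{assay}",
                pairs={p: med for p in pairs},
                score_kind=RESCORED,
                meta={"assay": assay, "median_similarity": med, "n_benchmarked": len(sims)},
            )
        )
    return out


def ppi_indirect_links(
    tab: pd.DataFrame,
    min_shared_partners: int = 1,
    source: str = "ppi_indirect",
) -> LinkSet:
    """Indirect association of non-interacting genes via shared partners.

    The raw score is the Jaccard index of the two genes' interaction-partner
    sets; any monotone shared-partner statistic would do, since the score is
    recalibrated against the benchmark downstream, and Jaccard is bounded in
    [0, 1].  Directly interacting pairs are excluded — they are covered by
    the direct link sets.
    """
    tab = _clean_interactions(tab)
    neighbors: dict[str, set[str]] = {}
    direct: set[tuple[str, str]] = set()
    for a, b in zip(tab["gene_a"], tab["gene_b"]):
        neighbors.setdefault(a, set()).add(b)
        neighbors.setdefault(b, set()).add(a)
        direct.add(pair_key(a, b))

    shared_count: dict[tuple[str, str], int] = {}
    for hub in neighbors:
        for a, b in itertools.combinations(sorted(neighbors[hub]), 2):
            key = pair_key(a, b)
            shared_count[key] = shared_count.get(key, 0) + 1

    pairs: dict[tuple[str, str], float] = {}
    for key, n_shared in shared_count.items():
        if key in direct or n_shared < min_shared_partners:
            continue
        a, b = key
        na, nb = neighbors[a], neighbors[b]
        pairs[key] = len(na & nb) / len(na | nb)
    return LinkSet(source=source, pairs=pairs, score_kind=RAW)


def read_interaction_tsv(path: str) -> pd.DataFrame:
    """``gene_a<TAB>gene_b<TAB>assay`` records."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["gene_a", "gene_b", "assay"],
        dtype=str,
    )
    if df.isna().any().any():
        raise FormatError(f"{path}: malformed interaction rows (expected 3 columns)")
    return df


# ---------------------------------------------------------------------------
# Annotation vocabularies as evidence
# ---------------------------------------------------------------------------


def annotation_links(
    ann: AnnotationSet,
    ont: Ontology,
    method: str = "bma",
    ic: Mapping[str, float] | None = None,
    benchmark_source: str | None = None,
    allow_benchmark: bool = False,
    min_score: float = 0.0,
    source: str | None = None,
) -> LinkSet:
    """Pairwise semantic similarity of an annotation vocabulary as evidence.

    ``method`` is ``max``/``bma`` for hierarchical ontologies or ``flat``
    for direct-match-only vocabularies.  Scores at or below ``min_score``
    (default 0) are omitted to keep the link set sparse.  Using the
    benchmark annotation source itself as evidence is refused unless
    explicitly overridden, to avoid self-benchmarking.
    """
    if benchmark_source is not None and ann.source == benchmark_source and not allow_benchmark:
        raise PlnetError(
            f"annotation source {ann.source!r} is the benchmark; "
            "pass allow_benchmark=True to override"
        )
    if ic is None:
        ic = information_content(ann, ont)
    genes = sorted(ann.universe)
    semsim = SemanticSimilarity(ont, ic)
    pairs: dict[tuple[str, str], float] = {}
    for i, g1 in enumerate(genes):
        t1 = ann.annotations(g1)
        for g2 in genes[i + 1 :]:
            if method == "flat":
                val = gene_similarity_flat(g1, g2, ann, ic)
            else:
                val = semsim.termset_similarity(t1, ann.annotations(g2), method)
            if val is not None and val > min_score:
                pairs[(g1, g2)] = val
    return LinkSet(source=source or ann.source, pairs=pairs, score_kind=RAW)


# ---------------------------------------------------------------------------
# Pre-scored pair lists and ortholog mapping
# ---------------------------------------------------------------------------


def read_scored_pairs(path: str, source: str | None = None) -> LinkSet:
    """Edge-list TSV ``gene_a<TAB>gene_b<TAB>score``.

    Duplicate unordered pairs collapse to their maximum score (the most
    confident record within a source); self-pairs are dropped with a logged
    count; a malformed line is an error naming the line number.  An empty
    file yields an empty link set.
    """
    pairs: dict[tuple[str, str], float] = {}
    n_self = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(fields)}"
                )
            a, b, raw_score = fields
            try:
                score = float(raw_score)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: score {raw_score!r} is not a number"
                ) from None
            if a == b:
                n_self += 1
                continue
            key = pair_key(a, b)
            if key not in pairs or score > pairs[key]:
                pairs[key] = score
    if n_self:
        logger.info("%s: dropped %d self-pair(s)", path, n_self)
    return LinkSet(source=source or path, pairs=pairs, score_kind=RAW)


def map_genes(ls: LinkSet, mapping: Mapping[str, str]) -> LinkSet:
    """Apply an ortholog (or any id) map to a link set.

    Pairs with an unmapped gene are dropped with a logged count; pairs that
    collapse onto the same mapped pair keep the maximum score.
    """
    pairs: dict[tuple[str, str], float] = {}
    n_dropped = 0
    for (a, b), v in ls.pairs.items():
        ma, mb = mapping.get(a), mapping.get(b)
        if ma is None or mb is None or ma == mb:
            n_dropped += 1
            continue
        key = pair_key(ma, mb)
        if key not in pairs or v > pairs[key]:
            pairs[key] = v
    if n_dropped:
        logger.info("%s: dropped %d pair(s) without ortholog mapping", ls.source, n_dropped)
    return LinkSet(source=ls.source, pairs=pairs, score_kind=ls.score_kind, meta=dict(ls.meta))


# ---------------------------------------------------------------------------
# LinkSet I/O
# ---------------------------------------------------------------------------


def write_linkset(ls: LinkSet, path: str, extra_header: Mapping[str, object] | None = None):
    """Write as edge-list TSV with an audit comment header."""
    with open(path, "w") as fh:
        fh.write(f"# source={ls.source}\n# score_kind={ls.score_kind}\n")
        for k in sorted(ls.meta):
            fh.write(f"# {k}={ls.meta[k]}\n")
        for k, v in (extra_header or {}).items():
            fh.write(f"# {k}={v}\n")
        for (a, b), v in sorted(ls.pairs.items()):
            fh.write(f"{a}\t{b}\t{v:.10g}\n")


def read_linkset(path: str) -> LinkSet:
    """Read a link set written by :func:`write_linkset`."""
    header: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            if not raw.startswith("#"):
                break
            body = raw[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                header[k.strip()] = v.strip()
    ls = read_scored_pairs(path, source=header.get("source", path))
    ls.score_kind = header.get("score_kind", RAW)
    ls.meta = {k: v for k, v in header.items() if k not in ("source", "score_kind")}
    return ls


def shuffled_equal(ls1: LinkSet, ls2: LinkSet) -> bool:
    """True when two link sets carry identical pairs and scores."""
    return ls1.pairs == ls2.pairs and ls1.score_kind == ls2.score_kind
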