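"""Permutation tests for gene-set connectivity with matched nulls.

The clustering statistic of a gene set is the sum of integrated link
weights over all pairs inside the set.  Its significance is assessed
against random gene sets drawn either uniformly, or matched gene-by-gene to
a confounder of the study set: coding-sequence (CDS) length — long genes
both accumulate more chance de-novo variants and tend to be interlinked —
or network node degree.  For the matched nulls each study gene gets an
ordered candidate list (the k nearest genes by CDS length, or the genes in
the same degree shell) and every null set draws one gene per list.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from ._util import FormatError, PlnetError, logger
from .integrate import PhenotypicLinkageNetwork

NULL_KINDS = ("cds", "degree", "uniform")

GeneLengthTable = dict  # gene -> longest CDS length in base pairs (> 0)


def read_gene_lengths(path: str) -> GeneLengthTable:
    """``gene<TAB>length`` TSV; lengths must be positive integers."""
    lengths: GeneLengthTable = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'gene<TAB>length'")
            gene, raw_len = fields
            try:
                length = int(raw_len)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: length {raw_len!r} not an integer") from None
            if length <= 0:
                raise FormatError(f"{path}:{lineno}: length must be > 0")
            if gene in lengths:
                raise FormatError(f"{path}:{lineno}: duplicate gene {gene!r}")
            lengths[gene] = length
    return lengths


def write_gene_lengths(lengths: GeneLengthTable, path: str, header: dict | None = None):
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}={v}\n")
        for gene in sorted(lengths):
            fh.write(f"{gene}\t{int(lengths[gene])}\n")


def link_weight_sum(net: PhenotypicLinkageNetwork, genes: Iterable[str]) -> float:
    """Sum of link weights over all pairs within the set.

    Genes absent from the network contribute nothing.  The set must contain
    at least two distinct genes.
    """
    gene_set = set(genes)
    if len(gene_set) < 2:
        raise PlnetError(f"gene set must contain >= 2 distinct genes, got {len(gene_set)}")
    total = 0.0
    adj = net.graph.adj
    for g in gene_set:
        if g not in adj:
            continue
        for nbr, data in adj[g].items():
            if nbr in gene_set and g < nbr:
                total += data["weight"]
    return total


def cds_matched_candidates(
    lengths: GeneLengthTable,
    gene: str,
    k: int = 100,
) -> list[str]:
    """The k genes nearest the query in CDS length.

    The query itself is excluded; ties in length distance break
    lexicographically by gene id, so the list is deterministic.
    """
    if gene not in lengths:
        raise KeyError(f"gene absent from length table: {gene!r}")
    if len(lengths) - 1 < k:
        raise PlnetError(
            f"need at least {k} other genes for CDS matching, have {len(lengths) - 1}"
        )
    target = lengths[gene]
    others = sorted(
        ((abs(length - target), g) for g, length in lengths.items() if g != gene),
    )
    return [g for _, g in others[:k]]


def degree_matched_candidates(
    net: PhenotypicLinkageNetwork,
    gene: str,
    tolerance: int = 0,
) -> list[str]:
    """Genes whose node degree is within ``tolerance`` of the query's.

    When the shell is empty the tolerance widens to the nearest non-empty
    shell (logged).  A gene absent from the network is treated as degree 0.
    """
    degrees = net.degree()
    target = degrees.get(gene, 0)
    if gene not in net:
        logger.warning("gene %r absent from network; degree-matching at degree 0", gene)
    pool = sorted(g for g in degrees if g != gene)
    tol = tolerance
    while True:
        shell = [g for g in pool if abs(degrees[g] - target) <= tol]
        if shell:
            if tol > tolerance:
                logger.warning(
                    "degree shell for %r widened from %d to %d", gene, tolerance, tol
                )
            return shell
        tol += 1
        if tol > max((degrees[g] for g in pool), default=0) + target:
            return pool  # degenerate: no other genes at all


def sample_null_set(
    candidate_lists: Sequence[Sequence[str]],
    rng: np.random.Generator,
    max_retries: int = 100,
) -> set[str]:
    """One random gene per candidate list, redrawing collisions.

    When the drawn set contains duplicates, the colliding positions (all but
    the first occurrence) are redrawn, up to ``max_retries`` rounds; after
    that the draw is accepted with a warning and de-duplicated.
    """
    draw = [lst[rng.integers(len(lst))] for lst in candidate_lists]
    for _ in range(max_retries):
        seen: set[str] = set()
        dup_pos = []
        for pos, g in enumerate(draw):
            if g in seen:
                dup_pos.append(pos)
            else:
                seen.add(g)
        if not dup_pos:
            return set(draw)
        for pos in dup_pos:
            lst = candidate_lists[pos]
            draw[pos] = lst[rng.integers(len(lst))]
    logger.warning("null set kept %d duplicate position(s) after retries", len(dup_pos))
    return set(draw)


@dataclass
class ClusterTestResult:
    """Observed statistic, null summary, empirical p-value and fold change."""

    statistic: float
    n_genes: int
    null_kind: str
    n_rand: int
    p_value: float
    fold_change: float
    null_median: float
    null_quantiles: dict
    seed: object = None
    n_missing_from_network: int = 0
    null: np.ndarray | None = None
    notes: list = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Gene-set connectivity permutation test",
            "--------------------------------------",
            f"genes in set         : {self.n_genes}"
            + (f" ({self.n_missing_from_network} absent from network)"
               if self.n_missing_from_network else ""),
            f"null model           : {self.null_kind} ({self.n_rand} randomizations)",
            f"sum of link weights  : {self.statistic:.4f}",
            f"null median          : {self.null_median:.4f}",
            f"fold change vs null  : {self.fold_change:.3f}",
            f"empirical p-value    : {self.p_value:.6g}",
        ]
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)

    def to_row(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "fold_change": self.fold_change,
            "null_median": self.null_median,
            "null_kind": self.null_kind,
            "n_rand": self.n_rand,
            "seed": self.seed,
        }


class ClusterTester:
    """Reusable permutation tester bound to one network (and length table).

    Caches the node index and weight matrix so repeated tests against the
    same network (for example hundreds of replicate study sets) do not
    rebuild them.
    """

    def __init__(
        self,
        net: PhenotypicLinkageNetwork,
        lengths: GeneLengthTable | None = None,
        k: int = 100,
        degree_tolerance: int = 0,
        max_retries: int = 100,
        dense_limit: int = 6000,
    ):
        self.net = net
        self.lengths = lengths
        self.k = k
        self.degree_tolerance = degree_tolerance
        self.max_retries = max_retries
        self.dense_limit = dense_limit
        self._matrix_cache: dict[str, tuple[dict, object]] = {}
        self._length_order: np.ndarray | None = None

    # -- internals ---------------------------------------------------------

    def _universe(self, null_kind: str) -> list[str]:
        if null_kind == "cds":
            if self.lengths is None:
                raise PlnetError("cds null requires a gene length table")
            return sorted(self.lengths)
        return sorted(self.net.graph.nodes)

    def _index_and_matrix(self, null_kind: str, genes: Sequence[str]):
        cache_key = null_kind if null_kind != "degree" else "uniform"
        cached = self._matrix_cache.get(cache_key)
        if cached is not None:
            index, w = cached
            if all(g in index for g in genes):
                return index, w
        nodes = sorted(set(self._universe(null_kind)) | set(genes))
        index = {g: i for i, g in enumerate(nodes)}
        n = len(nodes)
        if n <= self.dense_limit:
            w = np.zeros((n, n))
            for a, b, weight in self.net.edges():
                ia, ib = index.get(a), index.get(b)
                if ia is not None and ib is not None:
                    w[ia, ib] = w[ib, ia] = weight
        else:
            from scipy import sparse

            rows, cols, vals = [], [], []
            for a, b, weight in self.net.edges():
                ia, ib = index.get(a), index.get(b)
                if ia is not None and ib is not None:
                    rows += [ia, ib]
                    cols += [ib, ia]
                    vals += [weight, weight]
            w = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
        self._matrix_cache[cache_key] = (index, w)
        return index, w

    def _candidate_lists(self, null_kind: str, genes: Sequence[str]) -> list[list[str]]:
        if null_kind == "cds":
            missing = sorted(g for g in genes if g not in self.lengths)
            if missing:
                raise PlnetError(
                    "genes missing from length table: " + ", ".join(missing)
                )
            return [cds_matched_candidates(self.lengths, g, self.k) for g in genes]
        return [
            degree_matched_candidates(self.net, g, self.degree_tolerance) for g in genes
        ]

    def _draw_matrix(
        self,
        null_kind: str,
        genes: Sequence[str],
        index: Mapping[str, int],
        n_rand: int,
        rng: np.random.Generator,
    ) -> np.ndarray:
        s = len(genes)
        if null_kind == "uniform":
            universe_idx = np.array([index[g] for g in self._universe(null_kind)])
            if len(universe_idx) < s:
                raise PlnetError("uniform null: universe smaller than the gene set")
            # random-key top-k: a without-replacement sample per row,
            # generated in chunks to bound memory
            n_univ = len(universe_idx)
            draws = np.empty((n_rand, s), dtype=np.int64)
            chunk = max(1, 20_000_000 // max(n_univ, 1))
            for start in range(0, n_rand, chunk):
                stop = min(start + chunk, n_rand)
                keys = rng.random((stop - start, n_univ))
                picks = np.argpartition(keys, s - 1, axis=1)[:, :s]
                draws[start:stop] = universe_idx[picks]
            return draws

        lists = self._candidate_lists(null_kind, genes)
        cand = [np.array([index[g] for g in lst]) for lst in lists]
        draws = np.empty((n_rand, s), dtype=np.int64)
        for j, cj in enumerate(cand):
            draws[:, j] = cj[rng.integers(len(cj), size=n_rand)]
        # redraw colliding positions, row by row, bounded rounds
        for _ in range(self.max_retries):
            srt = np.sort(draws, axis=1)
            dup_rows = np.flatnonzero((srt[:, 1:] == srt[:, :-1]).any(axis=1))
            if dup_rows.size == 0:
                break
            for r in dup_rows:
                row = draws[r]
                seen: set[int] = set()
                for pos in range(s):
                    v = int(row[pos])
                    if v in seen:
                        cj = cand[pos]
                        row[pos] = cj[rng.integers(len(cj))]
                    else:
                        seen.add(v)
        return draws

    @staticmethod
    def _set_sums(w, draws: np.ndarray, chunk: int = 2000) -> np.ndarray:
        """Within-set weight sums for each row of index draws.

        Rows still containing duplicate indices (possible after bounded
        collision retries) are recomputed on their unique indices so a
        repeated gene never double-counts.
        """
        n_rand = draws.shape[0]
        out = np.empty(n_rand)
        dense = isinstance(w, np.ndarray)
        for start in range(0, n_rand, chunk):
            block = draws[start : start + chunk]
            if dense:
                sub = w[block[:, :, None], block[:, None, :]]
                out[start : start + chunk] = sub.sum(axis=(1, 2)) / 2.0
            else:
                for i, row in enumerate(block):
                    sub = w[row][:, row]
                    out[start + i] = sub.sum() / 2.0
        srt = np.sort(draws, axis=1)
        dup_rows = np.flatnonzero((srt[:, 1:] == srt[:, :-1]).any(axis=1))
        for r in dup_rows:
            uniq = np.unique(draws[r])
            sub = w[uniq[:, None], uniq[None, :]] if dense else w[uniq][:, uniq]
            out[r] = float(np.asarray(sub).sum()) / 2.0
        return out

    # -- public ------------------------------------------------------------

    def test(
        self,
        genes: Iterable[str],
        null_kind: str = "cds",
        n_rand: int = 100_000,
        seed=None,
        keep_null: bool = False,
    ) -> ClusterTestResult:
        if null_kind not in NULL_KINDS:
            raise PlnetError(f"unknown null kind {null_kind!r}; choose from {NULL_KINDS}")
        study = sorted(set(genes))
        if len(study) < 2:
            raise PlnetError("gene set must contain >= 2 distinct genes")
        statistic = link_weight_sum(self.net, study)
        rng = np.random.default_rng(seed)

        index, w = self._index_and_matrix(null_kind, study)
        draws = self._draw_matrix(null_kind, study, index, n_rand, rng)
        null = self._set_sums(w, draws)

        n_ge = int((null >= statistic).sum())
        p = (1 + n_ge) / (1 + n_rand)
        med = float(np.median(null))
        if med > 0:
            fold = statistic / med
        else:
            fold = float("inf") if statistic > 0 else float("nan")
        qs = np.quantile(null, [0.05, 0.25, 0.5, 0.75, 0.95])
        return ClusterTestResult(
            statistic=statistic,
            n_genes=len(study),
            null_kind=null_kind,
            n_rand=n_rand,
            p_value=p,
            fold_change=fold,
            null_median=med,
            null_quantiles=dict(zip(("q05", "q25", "median", "q75", "q95"), map(float, qs))),
            seed=seed,
            n_missing_from_network=sum(1 for g in study if g not in self.net),
            null=null if keep_null else None,
        )


def cluster_test(
    net: PhenotypicLinkageNetwork,
    genes: Iterable[str],
    null_kind: str = "cds",
    n_rand: int = 100_000,
    lengths: GeneLengthTable | None = None,
    seed=None,
    k: int = 100,
    degree_tolerance: int = 0,
    keep_null: bool = False,
) -> ClusterTestResult:
    """One-shot permutation test; see :class:`ClusterTester` for batches."""
    tester = ClusterTester(net, lengths=lengths, k=k, degree_tolerance=degree_tolerance)
    return tester.test(genes, null_kind=null_kind, n_rand=n_rand, seed=seed, keep_null=keep_null)
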