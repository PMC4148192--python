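"""Information content and semantic similarity.

Terms of an annotation vocabulary carry an information content

    IC(a) = -log p(a)

where ``p(a)`` is the proportion, among all genes with at least one
annotation, of genes annotated with term ``a`` or any of its descendant
terms.  Term-to-term similarity follows Resnik's measure combined with
disjunctive common ancestors: the similarity of two terms is the average IC
of their disjunct common ancestor set rather than the IC of the single most
informative ancestor, which rewards term pairs that share several
independent interpretations.

Gene-to-gene similarity aggregates term similarities over the two genes'
annotation sets with either the ``max`` or the best-match-average (``bma``)
rule; hierarchy-less vocabularies use exact term matches only.
"""

from __future__ import annotations

import math
from collections import Counter
from collections.abc import Iterable, Mapping

from ._util import pair_key
from .ontology import AnnotationSet, Ontology

ICTable = dict  # term -> information content (non-negative real)


def information_content(
    ann: AnnotationSet,
    ont: Ontology,
    base: float = math.e,
) -> ICTable:
    """IC for every term annotating at least one gene, directly or below.

    Direct annotations are propagated to all ancestors before counting, so a
    parent's gene count is at least each child's and IC is monotone
    non-increasing towards the roots.  Terms covering zero genes get no
    entry.  ``base`` selects the logarithm base (natural log by default; all
    downstream similarity scales inherit it).
    """
    n = len(ann.universe)
    if n == 0:
        raise ValueError("annotation universe is empty")
    unknown = ann.terms - ont.terms
    if unknown:
        some = ", ".join(sorted(unknown)[:5])
        raise KeyError(f"annotated term(s) missing from ontology: {some}")
    counts: Counter[str] = Counter()
    for terms in ann.direct.values():
        covered: set[str] = set()
        for t in terms:
            covered |= ont.ancestors(t, include_self=True)
        counts.update(covered)
    logb = math.log(base)
    return {t: -math.log(c / n) / logb for t, c in counts.items()}


def _reaches_avoiding(ont: Ontology, start: str, target: str, blocked: set) -> bool:
    """Is there a directed child->parent path start..target avoiding ``blocked``?

    The path includes its start node, so a blocked start means no path.
    """
    if start in blocked:
        return False
    if start == target:
        return True
    stack = [start]
    seen = {start}
    while stack:
        node = stack.pop()
        for p in ont.parents(node):
            if p == target:
                return True
            if p in blocked or p in seen:
                continue
            seen.add(p)
            stack.append(p)
    return False


def disjunctive_common_ancestors(
    t1: str,
    t2: str,
    ont: Ontology,
    ic: Mapping[str, float],
) -> set[str]:
    """Greedy disjunct-common-ancestor selection.

    Common ancestors (a term counts as its own ancestor) are visited in
    decreasing IC order, ties broken by term id.  An ancestor is accepted iff
    for each of ``t1`` and ``t2`` some directed path from the term to that
    ancestor avoids every already-accepted ancestor; the most informative
    common ancestor is always accepted.  Returns the empty set when the terms
    share no ancestor.
    """
    common = ont.ancestors(t1, include_self=True) & ont.ancestors(t2, include_self=True)
    if not common:
        return set()
    order = sorted(common, key=lambda t: (-ic.get(t, float("-inf")), t))
    accepted: list[str] = [order[0]]
    blocked = set(accepted)
    for cand in order[1:]:
        if _reaches_avoiding(ont, t1, cand, blocked) and _reaches_avoiding(
            ont, t2, cand, blocked
        ):
            accepted.append(cand)
            blocked.add(cand)
    return set(accepted)


def resnik_grasm(
    t1: str,
    t2: str,
    ont: Ontology,
    ic: Mapping[str, float],
) -> float:
    """Average IC of the disjunct common ancestors of two terms.

    Ancestors without an IC entry (they annotate no gene) are dropped from
    the average; the similarity is 0 when nothing remains.
    """
    dca = disjunctive_common_ancestors(t1, t2, ont, ic)
    vals = [ic[t] for t in sorted(dca) if t in ic]
    if not vals:
        return 0.0
    return sum(vals) / len(vals)


class SemanticSimilarity:
    """Cached term- and gene-level similarity over one ontology + IC table."""

    def __init__(self, ont: Ontology, ic: Mapping[str, float]):
        self.ont = ont
        self.ic = ic
        self._cache: dict[tuple[str, str], float] = {}

    def term_similarity(self, t1: str, t2: str) -> float:
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        val = self._cache.get(key)
        if val is None:
            val = resnik_grasm(t1, t2, self.ont, self.ic)
            self._cache[key] = val
        return val

    def termset_similarity(
        self, terms1: Iterable[str], terms2: Iterable[str], method: str = "bma"
    ) -> float:
        """Aggregate term-pair similarities between two annotation sets.

        ``max``: the single largest term-pair similarity.  ``bma``: for every
        term of each set take its best match in the other set, then average
        all best matches with equal weight per term (the two directions are
        pooled, so sets of unequal size weigh by their term counts).
        """
        ts1, ts2 = sorted(set(terms1)), sorted(set(terms2))
        if not ts1 or not ts2:
            raise ValueError("termset_similarity requires non-empty term sets")
        sim = self.term_similarity
        if method == "max":
            return max(sim(a, b) for a in ts1 for b in ts2)
        if method == "bma":
            best1 = [max(sim(a, b) for b in ts2) for a in ts1]
            best2 = [max(sim(a, b) for a in ts1) for b in ts2]
            pooled = best1 + best2
            return sum(pooled) / len(pooled)
        raise ValueError(f"unknown method {method!r} (use 'max' or 'bma')")


def gene_similarity(
    g1: str,
    g2: str,
    ann: AnnotationSet,
    ont: Ontology,
    ic: Mapping[str, float] | None = None,
    method: str = "bma",
    semsim: SemanticSimilarity | None = None,
):
    """Similarity of two genes' annotation profiles, or None if undefined.

    A gene without any annotation has no defined similarity to anything;
    the distinguished ``None`` (rather than 0) keeps unannotated genes out
    of benchmark statistics instead of deflating them.
    """
    if g1 not in ann or g2 not in ann:
        return None
    if semsim is None:
        if ic is None:
            ic = information_content(ann, ont)
        semsim = SemanticSimilarity(ont, ic)
    return semsim.termset_similarity(ann.annotations(g1), ann.annotations(g2), method)


def gene_similarity_flat(
    g1: str,
    g2: str,
    ann: AnnotationSet,
    ic: Mapping[str, float],
):
    """Direct-match similarity for flat vocabularies.

    The maximum IC over terms shared exactly by both genes; 0 when no term is
    shared; None when either gene is unannotated.
    """
    if g1 not in ann or g2 not in ann:
        return None
    shared = ann.annotations(g1) & ann.annotations(g2)
    vals = [ic[t] for t in shared if t in ic]
    return max(vals) if vals else 0.0


# ---------------------------------------------------------------------------
# Benchmark providers: a uniform "pair -> similarity or None" interface
# ---------------------------------------------------------------------------


class PhenotypeBenchmark:
    """Gene-pair similarity provider backed by a phenotype annotation set.

    This is the yardstick every evidence source is measured against: the
    similarity of the phenotype annotations of the two linked genes.
    """

    def __init__(
        self,
        ann: AnnotationSet,
        ont: Ontology,
        method: str = "bma",
        ic: Mapping[str, float] | None = None,
        base: float = math.e,
    ):
        if method not in ("bma", "max", "flat"):
            raise ValueError(f"unknown benchmark method {method!r}")
        self.ann = ann
        self.ont = ont
        self.method = method
        self.ic = dict(ic) if ic is not None else information_content(ann, ont, base)
        self._semsim = SemanticSimilarity(ont, self.ic)
        self._pairs: dict[tuple[str, str], float] = {}

    def covers(self, gene: str) -> bool:
        return gene in self.ann

    def pair_similarity(self, g1: str, g2: str):
        if g1 not in self.ann or g2 not in self.ann:
            return None
        key = pair_key(g1, g2)
        val = self._pairs.get(key)
        if val is None:
            if self.method == "flat":
                val = gene_similarity_flat(g1, g2, self.ann, self.ic)
            else:
                val = self._semsim.termset_similarity(
                    self.ann.annotations(g1), self.ann.annotations(g2), self.method
                )
            self._pairs[key] = val
        return val


class DictBenchmark:
    """Benchmark provider backed by a plain pair -> similarity mapping."""

    def __init__(self, pairs: Mapping[tuple[str, str], float]):
        self._pairs = {pair_key(a, b): float(v) for (a, b), v in pairs.items()}
        genes: set[str] = set()
        for a, b in self._pairs:
            genes.add(a)
            genes.add(b)
        self._genes = genes

    def covers(self, gene: str) -> bool:
        return gene in self._genes

    def pair_similarity(self, g1: str, g2: str):
        if g1 == g2:
            return None
        return self._pairs.get(pair_key(g1, g2))


def as_benchmark(obj):
    """Normalize a mapping or provider into the benchmark interface."""
    if hasattr(obj, "pair_similarity"):
        return obj
    if isinstance(obj, Mapping):
        return DictBenchmark(obj)
    raise TypeError(f"cannot interpret {type(obj).__name__} as a benchmark")


def pairwise_gene_similarity(
    ann: AnnotationSet,
    ont: Ontology,
    ic: Mapping[str, float] | None = None,
    method: str = "bma",
    genes: Iterable[str] | None = None,
) -> dict[tuple[str, str], float]:
    """All-pairs gene similarity over ``genes`` (default: the whole universe)."""
    if ic is None:
        ic = information_content(ann, ont)
    gs = sorted(set(genes) if genes is not None else ann.universe)
    semsim = SemanticSimilarity(ont, ic)
    out: dict[tuple[str, str], float] = {}
    for i, g1 in enumerate(gs):
        t1 = ann.annotations(g1)
        if not t1:
            continue
        for g2 in gs[i + 1 :]:
            t2 = ann.annotations(g2)
            if not t2:
                continue
            if method == "flat":
                val = gene_similarity_flat(g1, g2, ann, ic)
            else:
                val = semsim.termset_similarity(t1, t2, method)
            out[(g1, g2)] = val
    return out
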