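"""Synthetic data with the statistical structure the method assumes.

The generators build a miniature, fully controlled counterpart of each real
input: a layered random ontology with module-structured gene annotations; a
random-DAG ontology for similarity stress tests; noisy monotone evidence
scores over a coverage subset of the true pairwise similarities; log-normal
CDS lengths optionally coupled to network connectivity; and "study" gene
sets that are either length-biased without any functional signal (the
confound to be cured) or drawn from one planted functional module (the
signal to be detected).

Everything is deterministic under a fixed seed and emitted in exactly the
file dialects the rest of the package reads.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._util import PlnetError
from .cluster import GeneLengthTable, write_gene_lengths
from .integrate import PhenotypicLinkageNetwork
from .links import RAW, LinkSet, write_linkset
from .ontology import (
    AnnotationSet,
    Ontology,
    write_annotation_tsv,
    write_obo,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for every generator; defaults define the reference conditions.

    ``n_genes`` genes are partitioned into ``n_modules`` equal functional
    modules.  The ontology is a layered DAG of the given depth and
    branching.  Evidence sources report ``evidence_scale * similarity +
    noise`` on a random ``coverage`` fraction of pairs.  CDS lengths are
    log-normal (location/scale on the natural-log scale); ``beta``
    couples connectivity to length (0 = no coupling).  ``effect_size``
    multiplies within-module link weights.
    """

    n_genes: int = 2000
    n_modules: int = 20
    depth: int = 4
    branching: int = 3
    extra_annotations: int = 2
    second_module_prob: float = 0.1
    rare_annotation_prob: float = 0.02
    evidence_scale: float = 1.0
    noise_sd: float = 0.3
    coverage: float = 0.5
    length_meanlog: float = 7.5
    length_sdlog: float = 0.8
    beta: float = 0.0
    baseline_density: float = 0.01
    module_density: float = 0.2
    effect_size: float = 2.0
    set_size: int = 50
    seed: int = 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    def module_of(self, i: int) -> int:
        """Module of gene index i: contiguous, near-equal blocks."""
        return i * self.n_modules // self.n_genes

    def module_genes(self, module: int) -> list[str]:
        return [
            g
            for i, g in enumerate(self.gene_ids())
            if self.module_of(i) == module
        ]


# ---------------------------------------------------------------------------
# Ontologies and annotations
# ---------------------------------------------------------------------------


def simulate_ontology(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[Ontology, AnnotationSet]:
    """Layered DAG ontology plus module-structured annotations.

    Layer ``l`` holds ``branching**l`` terms; each term below the root draws
    one or two parents from the layer above, so some terms have multiple
    inheritance.  Every module owns one distinct leaf (deepest-layer) term;
    genes are annotated with their module's leaf, a few random mid-layer
    terms, occasionally a second module's leaf, and (rarely) a random leaf,
    mimicking the sparsely annotated deep terms of real phenotype
    vocabularies.  With the default geometry the IC spectrum runs from 0 at
    the root through ~log(n_modules) nats at module leaves up to
    -log(1/n_genes) at the rarest terms.
    """
    if cfg.depth < 2:
        raise PlnetError("ontology depth must be >= 2")
    rng = rng if rng is not None else cfg.rng()

    layers: list[list[str]] = []
    parents: dict[str, list[str]] = {}
    for level in range(cfg.depth):
        width = cfg.branching**level
        layer = [f"T{level}_{j:04d}" for j in range(width)]
        for term in layer:
            if level == 0:
                parents[term] = []
            else:
                n_par = 1 + int(rng.random() < 0.5)
                n_par = min(n_par, len(layers[level - 1]))
                idx = rng.choice(len(layers[level - 1]), size=n_par, replace=False)
                parents[term] = [layers[level - 1][i] for i in sorted(idx)]
        layers.append(layer)
    ont = Ontology.from_term_parents(parents)

    leaves = layers[-1]
    if cfg.n_modules > len(leaves):
        raise PlnetError(
            f"{cfg.n_modules} modules need >= {cfg.n_modules} leaf terms, "
            f"have {len(leaves)} (increase depth or branching)"
        )
    leaf_of_module = [leaves[i] for i in rng.permutation(len(leaves))[: cfg.n_modules]]
    mid_terms = [t for layer in layers[1:-1] for t in layer]

    direct: dict[str, set[str]] = {}
    for i, gene in enumerate(cfg.gene_ids()):
        terms = {leaf_of_module[cfg.module_of(i)]}
        if mid_terms and cfg.extra_annotations > 0:
            n_extra = min(cfg.extra_annotations, len(mid_terms))
            idx = rng.choice(len(mid_terms), size=n_extra, replace=False)
            terms.update(mid_terms[j] for j in sorted(idx))
        if cfg.n_modules > 1 and rng.random() < cfg.second_module_prob:
            terms.add(leaf_of_module[int(rng.integers(cfg.n_modules))])
        # occasional rare deep terms: real phenotype vocabularies carry many
        # sparsely annotated leaves, which stretches the IC spectrum
        if rng.random() < cfg.rare_annotation_prob:
            terms.add(leaves[int(rng.integers(len(leaves)))])
        direct[gene] = terms
    ann = AnnotationSet(direct, source="simulated_phenotypes", ontology=ont)
    return ont, ann


def random_dag_ontology(
    rng: np.random.Generator,
    n_terms: int,
    n_genes: int,
    max_parents: int = 3,
    max_terms_per_gene: int = 3,
) -> tuple[Ontology, AnnotationSet]:
    """Arbitrary random DAG for stress-testing similarity computations.

    Terms are created in topological order and each draws 1..max_parents
    parents among the earlier terms; genes annotate random term subsets.
    Small instances of these are compared against the brute-force oracle.
    """
    terms = [f"t{j:03d}" for j in range(n_terms)]
    parents: dict[str, list[str]] = {terms[0]: []}
    for j in range(1, n_terms):
        n_par = int(rng.integers(1, min(j, max_parents) + 1))
        idx = rng.choice(j, size=n_par, replace=False)
        parents[terms[j]] = [terms[i] for i in sorted(idx)]
    ont = Ontology.from_term_parents(parents)

    direct: dict[str, set[str]] = {}
    for g in range(n_genes):
        n_ann = int(rng.integers(1, max_terms_per_gene + 1))
        idx = rng.choice(n_terms, size=n_ann, replace=False)
        direct[f"g{g:03d}"] = {terms[i] for i in idx}
    return ont, AnnotationSet(direct, source="random_dag", ontology=ont)


# ---------------------------------------------------------------------------
# Evidence
# ---------------------------------------------------------------------------


def simulate_evidence(
    truth: dict,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    signal: bool = True,
    source: str = "evidence",
    noise_sd: float | None = None,
    coverage: float | None = None,
    scale: float | None = None,
) -> LinkSet:
    """Noisy monotone evidence over a random coverage subset of the truth.

    ``truth`` maps unordered gene pairs to their true functional similarity.
    With ``signal`` the raw score is ``scale * similarity + N(0, noise_sd)``
    (the per-source scale is hidden from downstream consumers, which must
    recover the calibration by benchmarking); without it the score is pure
    noise.
    """
    rng = rng if rng is not None else cfg.rng()
    noise_sd = cfg.noise_sd if noise_sd is None else noise_sd
    coverage = cfg.coverage if coverage is None else coverage
    scale = cfg.evidence_scale if scale is None else scale

    keys = sorted(truth)
    keep = rng.random(len(keys)) < coverage
    sims = np.array([truth[k] for k in keys])
    noise = rng.normal(0.0, noise_sd, size=len(keys))
    scores = (scale * sims if signal else np.zeros(len(keys))) + noise
    pairs = {k: float(s) for k, s, m in zip(keys, scores, keep) if m}
    return LinkSet(source=source, pairs=pairs, score_kind=RAW)


# ---------------------------------------------------------------------------
# Lengths and networks
# ---------------------------------------------------------------------------


def simulate_lengths_and_network(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GeneLengthTable, PhenotypicLinkageNetwork]:
    """Log-normal CDS lengths and a network whose wiring can track length.

    With ``z`` the standardized log CDS length, winsorized at |z| <= 2, a
    pair's edge probability is

        p_ij = clip( d0 * exp(beta/2 * (z_i + z_j) + beta/2 * z_i * z_j), 0, 1 )

    — the additive term makes long genes better connected (degree-length
    coupling) and the interaction term makes long genes prefer other long
    genes (length assortativity of a gene's connections); both vanish at
    ``beta = 0``.  The winsorizing and the half-strength exponents keep the
    default ``beta = 0.5`` coupling in the regime observed in real exome
    networks (length assortativity around 0.3-0.5 rather than near 1),
    where the confound is strong but not degenerate.  Same-module pairs additionally connect with probability
    ``module_density`` and their edge weights are multiplied by
    ``effect_size``, planting detectable functional modules.  Edge weights
    are otherwise log-normal on the benchmark (IC-like) scale and
    independent of length.
    """
    rng = rng if rng is not None else cfg.rng()
    genes = cfg.gene_ids()
    n = cfg.n_genes

    log_len = rng.normal(cfg.length_meanlog, cfg.length_sdlog, size=n)
    lengths = {g: max(30, int(round(math.exp(v)))) for g, v in zip(genes, log_len)}
    z = (log_len - log_len.mean()) / log_len.std()
    z = np.clip(z, -2.0, 2.0)

    iu, ju = np.triu_indices(n, k=1)
    half = cfg.beta / 2.0
    logit = half * (z[iu] + z[ju]) + half * z[iu] * z[ju]
    p = np.clip(cfg.baseline_density * np.exp(logit), 0.0, 1.0)
    modules = np.array([cfg.module_of(i) for i in range(n)])
    same_module = modules[iu] == modules[ju]
    p = np.where(same_module, 1.0 - (1.0 - p) * (1.0 - cfg.module_density), p)

    keep = rng.random(len(p)) < p
    ei, ej, emod = iu[keep], ju[keep], same_module[keep]
    weights = rng.lognormal(mean=-0.35, sigma=0.6, size=len(ei))
    weights = np.where(emod, weights * cfg.effect_size, weights)

    net = PhenotypicLinkageNetwork()
    for a, b, w in zip(ei, ej, weights):
        net.add_edge(genes[a], genes[b], float(w), [("simulated", float(w))])
    return lengths, net


# ---------------------------------------------------------------------------
# Study gene sets
# ---------------------------------------------------------------------------


def simulate_study_genes(
    lengths: GeneLengthTable,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    mode: str = "length_biased_null",
    set_size: int | None = None,
    module: int = 0,
) -> set[str]:
    """Draw a study gene set.

    ``length_biased_null``: genes sampled without replacement with
    probability proportional to CDS length and no functional structure —
    the chance profile of de-novo hits under a uniform per-base mutation
    rate.  ``planted_module``: a uniform sample from one functional module,
    whose internal links were boosted by the network generator.
    """
    rng = rng if rng is not None else cfg.rng()
    size = cfg.set_size if set_size is None else set_size
    if mode == "length_biased_null":
        genes = sorted(lengths)
        w = np.array([lengths[g] for g in genes], dtype=float)
        picks = rng.choice(len(genes), size=size, replace=False, p=w / w.sum())
        return {genes[i] for i in picks}
    if mode == "planted_module":
        pool = cfg.module_genes(module)
        if size > len(pool):
            raise PlnetError(
                f"module {module} has {len(pool)} genes, cannot draw {size}"
            )
        picks = rng.choice(len(pool), size=size, replace=False)
        return {pool[i] for i in picks}
    raise PlnetError(f"unknown study-set mode {mode!r}")


# ---------------------------------------------------------------------------
# Expression (minimal: just enough correlation structure for co-expression)
# ---------------------------------------------------------------------------


def simulate_expression(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_samples: int = 24,
    missing_rate: float = 0.05,
) -> pd.DataFrame:
    """Module-correlated positive expression with some missing entries."""
    rng = rng if rng is not None else cfg.rng()
    factors = rng.normal(size=(cfg.n_modules, n_samples))
    rows = []
    genes = cfg.gene_ids()
    for i in range(cfg.n_genes):
        latent = factors[cfg.module_of(i)] + rng.normal(scale=0.7, size=n_samples)
        rows.append(np.exp(1.0 + 0.8 * latent))
    x = np.array(rows)
    mask = rng.random(x.shape) < missing_rate
    x[mask] = np.nan
    return pd.DataFrame(x, index=genes, columns=[f"S{j:02d}" for j in range(n_samples)])


# ---------------------------------------------------------------------------
# Demo workspace
# ---------------------------------------------------------------------------

FIXTURE_CONFIG = SimulationConfig(
    n_genes=150,
    n_modules=8,
    depth=3,
    branching=3,
    beta=0.5,
    baseline_density=0.03,
    module_density=0.35,
    set_size=12,
    coverage=0.8,
    noise_sd=0.25,
)


def write_fixtures(outdir: str, cfg: SimulationConfig | None = None, seed: int | None = None):
    """Materialize a small, self-consistent demo workspace.

    Writes an OBO ontology, phenotype annotations, CDS lengths, an
    expression matrix, an interaction table, a pre-scored pair list and a
    planted study gene set, all derived from one configuration.
    """
    cfg = cfg if cfg is not None else FIXTURE_CONFIG
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = cfg.rng()
    os.makedirs(outdir, exist_ok=True)

    ont, ann = simulate_ontology(cfg, rng)
    write_obo(ont, os.path.join(outdir, "ontology.obo"))
    write_annotation_tsv(ann, os.path.join(outdir, "annotations.tsv"),
                         header=f"# source={ann.source}\n")

    from .semsim import pairwise_gene_similarity

    truth = pairwise_gene_similarity(ann, ont)
    lengths, net = simulate_lengths_and_network(cfg, rng)
    write_gene_lengths(lengths, os.path.join(outdir, "lengths.tsv"))

    expr = simulate_expression(cfg, rng)
    expr.to_csv(os.path.join(outdir, "expression.tsv"), sep="\t")

    # interactions: prefer truly similar pairs, two assay flavours
    keys = sorted(truth)
    sims = np.array([truth[k] for k in keys])
    prob = 0.02 + 0.2 * (sims > np.quantile(sims, 0.9))
    rows = []
    for (a, b), p in zip(keys, prob):
        for assay in ("Y2H", "AP-MS"):
            if rng.random() < p:
                rows.append((a, b, assay))
    with open(os.path.join(outdir, "interactions.tsv"), "w") as fh:
        fh.write("# gene_a\tgene_b\tassay\n")
        for a, b, assay in rows:
            fh.write(f"{a}\t{b}\t{assay}\n")

    evid = simulate_evidence(truth, cfg, rng, source="scored_evidence")
    write_linkset(evid, os.path.join(outdir, "scored_pairs.tsv"))

    study = simulate_study_genes(lengths, cfg, rng, mode="planted_module", module=0)
    with open(os.path.join(outdir, "study_genes.txt"), "w") as fh:
        for g in sorted(study):
            fh.write(g + "\n")
    return cfg
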