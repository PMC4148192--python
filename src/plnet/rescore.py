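"""Benchmark evaluation and rescoring of evidence sources.

A raw evidence source is judged by whether its strongest links connect genes
with similar phenotype annotations.  The benchmarked pairs are sorted by raw
score, cut into consecutive bins, and the per-bin median raw score is
related to the per-bin median phenotype similarity.  Sources whose binned
curve shows a significant positive rank correlation are accepted and their
raw scores are mapped onto the phenotype-similarity scale by ordinary least
squares on the bin medians; everything else is excluded from integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import InsufficientBenchmarkOverlap, PlnetError, logger
from .links import RESCORED, LinkSet
from .semsim import as_benchmark


@dataclass
class LinearMap:
    """y = slope * x + intercept"""

    slope: float
    intercept: float

    def __call__(self, x: float) -> float:
        return self.slope * x + self.intercept


@dataclass
class BinTable:
    """Per-bin medians of raw score and benchmark similarity.

    ``table`` columns: bin, score_median, sim_median, n_pairs, full.  Bins
    partition the benchmarked pairs in descending raw-score order; all bins
    except possibly the last hold exactly ``bin_size`` pairs, and the last,
    partial bin is kept but flagged not-full.
    """

    table: pd.DataFrame
    bin_size: int
    source: str = ""

    @property
    def full(self) -> pd.DataFrame:
        return self.table[self.table["full"]]

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path: str, header: dict | None = None) -> None:
        with open(path, "w") as fh:
            fh.write(f"# source={self.source}\n# bin_size={self.bin_size}\n")
            for k, v in (header or {}).items():
                fh.write(f"# {k}={v}\n")
            self.table.to_csv(fh, sep="\t", index=False)


@dataclass
class EvaluationReport:
    """Outcome of benchmarking one evidence source."""

    source: str
    n_pairs: int
    n_benchmarked: int
    n_bins: int
    n_full_bins: int
    bin_size: int
    rho: float
    pvalue: float
    alpha: float
    include: bool
    slope: float
    intercept: float
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "n_pairs": self.n_pairs,
            "n_benchmarked": self.n_benchmarked,
            "n_bins": self.n_bins,
            "n_full_bins": self.n_full_bins,
            "bin_size": self.bin_size,
            "rho": self.rho,
            "pvalue": self.pvalue,
            "alpha": self.alpha,
            "include": self.include,
            "slope": self.slope,
            "intercept": self.intercept,
        }


def evaluate(
    ls: LinkSet,
    benchmark,
    bin_size: int = 1000,
    alpha: float = 0.05,
) -> tuple[BinTable, EvaluationReport]:
    """Binned benchmark curve and inclusion decision for one source.

    Pairs are restricted to those where both genes carry benchmark
    annotations, sorted by raw score from largest to smallest (ties broken
    by pair id for determinism) and cut into consecutive bins of
    ``bin_size``.  The inclusion rule is a positive Spearman correlation
    between the full bins' score and similarity medians, one-sided p <
    ``alpha``.  Requires at least two full bins of benchmarked pairs.
    """
    bench = as_benchmark(benchmark)
    rows = []
    for (a, b), score in ls.pairs.items():
        sim = bench.pair_similarity(a, b)
        if sim is not None:
            rows.append((score, a, b, sim))
    if len(rows) < 2 * bin_size:
        raise InsufficientBenchmarkOverlap(
            f"insufficient benchmark overlap for {ls.source!r}: "
            f"{len(rows)} benchmarked pair(s) < 2 full bins of {bin_size}"
        )
    rows.sort(key=lambda r: (-r[0], r[1], r[2]))
    scores = np.array([r[0] for r in rows])
    sims = np.array([r[3] for r in rows])

    recs = []
    for start in range(0, len(rows), bin_size):
        stop = min(start + bin_size, len(rows))
        recs.append(
            {
                "bin": start // bin_size,
                "score_median": float(np.median(scores[start:stop])),
                "sim_median": float(np.median(sims[start:stop])),
                "n_pairs": stop - start,
                "full": (stop - start) == bin_size,
            }
        )
    bt = BinTable(table=pd.DataFrame(recs), bin_size=bin_size, source=ls.source)

    full = bt.full
    notes: list[str] = []
    x = full["score_median"].to_numpy()
    y = full["sim_median"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        rho, pval = float("nan"), float("nan")
        notes.append("degenerate bins: constant medians, correlation undefined")
    else:
        res = stats.spearmanr(x, y, alternative="greater")
        rho, pval = float(res.statistic), float(res.pvalue)
    include = bool(rho > 0 and pval < alpha) if np.isfinite(rho) else False

    try:
        lin = fit_rescoring(bt)
        slope, intercept = lin.slope, lin.intercept
    except PlnetError as exc:
        slope = intercept = float("nan")
        notes.append(str(exc))

    report = EvaluationReport(
        source=ls.source,
        n_pairs=len(ls),
        n_benchmarked=len(rows),
        n_bins=len(bt),
        n_full_bins=len(full),
        bin_size=bin_size,
        rho=rho,
        pvalue=pval,
        alpha=alpha,
        include=include,
        slope=slope,
        intercept=intercept,
        notes=notes,
    )
    return bt, report


def fit_rescoring(bt: BinTable) -> LinearMap:
    """OLS of bin-median similarity on bin-median raw score (full bins only)."""
    full = bt.full
    if len(full) < 2:
        raise InsufficientBenchmarkOverlap(
            f"need >= 2 full bins to fit a rescoring map, have {len(full)}"
        )
    x = full["score_median"].to_numpy()
    y = full["sim_median"].to_numpy()
    if np.ptp(x) == 0:
        raise PlnetError("bin score medians have zero variance; cannot fit rescoring")
    res = stats.linregress(x, y)
    return LinearMap(slope=float(res.slope), intercept=float(res.intercept))


def rescore(ls: LinkSet, lin: LinearMap) -> LinkSet:
    """Map every pair's raw score onto the benchmark scale.

    All pairs are rescored, whether or not their genes carry phenotype
    annotations.  Fitted values are clamped at zero and pairs rescored to
    zero are dropped — a link with no benchmark-scale weight carries no
    evidence.
    """
    pairs = {}
    n_dropped = 0
    for key, raw in ls.pairs.items():
        val = lin(raw)
        if val > 0:
            pairs[key] = val
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("%s: %d pair(s) rescored to <= 0 and dropped", ls.source, n_dropped)
    meta = dict(ls.meta)
    meta.update({"slope": lin.slope, "intercept": lin.intercept})
    return LinkSet(source=ls.source, pairs=pairs, score_kind=RESCORED, meta=meta)


def rescore_source(
    ls: LinkSet,
    benchmark,
    bin_size: int = 1000,
    alpha: float = 0.05,
    force: bool = False,
) -> tuple[LinkSet, BinTable, EvaluationReport]:
    """Evaluate, fit, and rescore one source in a single step.

    Sources failing the inclusion rule are refused (they must never reach
    integration) unless ``force`` is set.
    """
    bt, report = evaluate(ls, benchmark, bin_size=bin_size, alpha=alpha)
    if not report.include and not force:
        raise PlnetError(
            f"source {ls.source!r} failed the benchmark inclusion rule "
            f"(rho={report.rho:.3f}, one-sided p={report.pvalue:.3g}); "
            "excluded from integration"
        )
    lin = fit_rescoring(bt)
    return rescore(ls, lin), bt, report


def write_report_tsv(reports, path: str, header: dict | None = None) -> None:
    rows = [r.to_dict() for r in (reports if isinstance(reports, list) else [reports])]
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}={v}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
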