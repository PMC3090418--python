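"""Probe-level expression normalization and differential-expression calling.

The processing chain mirrors classic oligonucleotide-array practice:
quantile normalization across arrays, log2 transform, Tukey median
polish to summarize each gene's probe block into one value per array,
then a two-sample t-test between treatments.  Differential expression
uses a fold-change rule with two granularities: a single gene needs a
>= 2-fold change, a putative operon (consecutive same-strand genes with
minimal intergenic space) needs a geometric-mean change >= 1.7-fold
across its members, in both cases with p <= 0.05.

Background correction of raw scanner files is out of scope; the
pipeline starts from a probe-level intensity table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GeneAnnotation

__all__ = [
    "ExpressionExperiment",
    "OperonGroup",
    "DECall",
    "quantile_normalize",
    "median_polish",
    "median_polish_summarize",
    "two_sample_t",
    "group_operons",
    "summarize_genes",
    "call_differential",
]


@dataclass
class ExpressionExperiment:
    """Probe-level intensities plus the sample/treatment design.

    ``intensities``: probes x samples DataFrame of positive linear-scale
    values, indexed by probe_id.  ``probe_to_gene`` maps each probe to
    exactly one gene.  ``samples`` has columns sample_id, treatment,
    replicate; sample_id values match the intensity columns.
    """

    intensities: pd.DataFrame
    probe_to_gene: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.isfinite(self.intensities.to_numpy()).all():
            raise ValueError("intensities must be finite")
        if (self.intensities.to_numpy() <= 0).any():
            raise ValueError("intensities must be strictly positive (linear scale)")
        missing = set(self.intensities.index) - set(self.probe_to_gene.index)
        if missing:
            raise ValueError(f"{len(missing)} probes lack a gene mapping")
        if list(self.samples["sample_id"]) != list(self.intensities.columns):
            raise ValueError("sample sheet order must match intensity columns")
        counts = self.samples.groupby("treatment")["sample_id"].count()
        if (counts < 2).any():
            raise ValueError("every treatment needs >= 2 replicates")

    @classmethod
    def from_tsv(cls, intensities_path: str | Path, samples_path: str | Path) -> "ExpressionExperiment":
        """Load from a probe table (probe_id, gene_id, one column per sample)
        and a sample sheet (sample_id, treatment, replicate)."""
        tab = pd.read_csv(intensities_path, sep="\t")
        samples = pd.read_csv(samples_path, sep="\t")
        tab = tab.set_index("probe_id")
        probe_to_gene = tab["gene_id"]
        intensities = tab.drop(columns=["gene_id"])
        return cls(intensities, probe_to_gene, samples)


@dataclass(frozen=True)
class OperonGroup:
    """Consecutive same-strand genes with small intergenic gaps."""

    gene_ids: tuple[str, ...]
    strand: str
    max_gap: int


@dataclass(frozen=True)
class DECall:
    """One differential-expression call (single gene or operon)."""

    unit: tuple[str, ...]
    direction: str          # 'up_in_A' or 'up_in_B'
    rule_used: str          # 'single_2fold' or 'operon_1.7fold'
    fold: float             # >= 1, oriented by `direction`
    p_values: tuple[float, ...]


def quantile_normalize(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Force every column onto the mean empirical distribution.

    After normalization each column's sorted values equal the
    across-column mean of sorted values; within-column ranks are
    preserved and ties receive the mean of the reference quantiles they
    span.  Idempotent.
    """
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 columns")
    if not np.isfinite(arr).all():
        raise ValueError("matrix contains non-finite values")
    reference = np.sort(arr, axis=0).mean(axis=1)
    n = arr.shape[0]
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = reference
        # ties: mean of the reference quantiles the tied group spans
        out[:, j] = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


@dataclass
class MedianPolishResult:
    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray

    def fitted(self) -> np.ndarray:
        return (
            self.overall
            + self.row_effects[:, None]
            + self.col_effects[None, :]
        )


def median_polish(block: np.ndarray, tol: float = 0.01, max_iter: int = 10) -> MedianPolishResult:
    """Tukey median polish of a probes x samples block.

    Alternately sweeps row and column medians into effect vectors until
    the reduction in total absolute residual falls below ``tol`` (or
    ``max_iter`` sweeps).  The decomposition identity
    ``block = overall + row + col + residual`` holds exactly.
    """
    resid = np.array(block, dtype=float)
    if resid.ndim != 2 or resid.size == 0:
        raise ValueError("block must be a non-empty 2-D array")
    if not np.isfinite(resid).all():
        raise ValueError("block contains non-finite values")
    nr, nc = resid.shape
    overall = 0.0
    row_eff = np.zeros(nr)
    col_eff = np.zeros(nc)
    prev_sum = np.abs(resid).sum()
    for _ in range(max_iter):
        rmed = np.median(resid, axis=1)
        resid -= rmed[:, None]
        row_eff += rmed
        delta = np.median(col_eff)
        col_eff -= delta
        overall += delta

        cmed = np.median(resid, axis=0)
        resid -= cmed[None, :]
        col_eff += cmed
        delta = np.median(row_eff)
        row_eff -= delta
        overall += delta

        cur_sum = np.abs(resid).sum()
        if prev_sum - cur_sum < tol:
            break
        prev_sum = cur_sum
    return MedianPolishResult(overall, row_eff, col_eff, resid)


def median_polish_summarize(
    log2_block: np.ndarray, tol: float = 0.01, max_iter: int = 10
) -> np.ndarray:
    """Per-sample expression summary: overall effect + column effect."""
    fit = median_polish(log2_block, tol=tol, max_iter=max_iter)
    return fit.overall + fit.col_effects


def two_sample_t(
    a: Sequence[float], b: Sequence[float], equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided two-sample t-test (pooled variance by default).

    Degenerate convention: when both groups have zero variance, p = 1 if
    the means agree and p = 0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def group_operons(
    genes: Sequence[GeneAnnotation], gap_threshold: int = 25
) -> list[OperonGroup]:
    """Group consecutive same-strand genes with small intergenic gaps.

    Genes must be sorted by start on a single replicon.  The intergenic
    gap between adjacent genes is ``next.start - prev.end - 1``; runs
    whose every gap is <= ``gap_threshold`` and whose members share a
    strand become operons.  Singletons are not reported.
    """
    starts = [g.start for g in genes]
    if starts != sorted(starts):
        raise ValueError("genes must be sorted by start position")
    operons: list[OperonGroup] = []
    run: list[GeneAnnotation] = []
    run_max_gap = 0

    def flush() -> None:
        nonlocal run, run_max_gap
        if len(run) >= 2:
            operons.append(
                OperonGroup(tuple(g.gene_id for g in run), run[0].strand, run_max_gap)
            )
        run = []
        run_max_gap = 0

    for g in genes:
        if run:
            gap = g.start - run[-1].end - 1
            if g.strand == run[-1].strand and gap <= gap_threshold:
                run.append(g)
                run_max_gap = max(run_max_gap, gap)
                continue
            flush()
        run = [g]
        run_max_gap = 0
    flush()
    return operons


def summarize_genes(
    experiment: ExpressionExperiment,
    treatment_a: str = "light",
    treatment_b: str = "dark",
    tol: float = 0.01,
    max_iter: int = 10,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Quantile-normalize, log2, median-polish per gene and test A vs B.

    Returns a DataFrame indexed by gene_id with the per-sample log2
    summaries, per-treatment means, the linear fold change oriented as
    A over B (``fold = 2 ** (mean_A - mean_B)``) and the t-test p-value.
    """
    cols = list(experiment.intensities.columns)
    a_cols = [
        s for s, t in zip(experiment.samples["sample_id"], experiment.samples["treatment"])
        if t == treatment_a
    ]
    b_cols = [
        s for s, t in zip(experiment.samples["sample_id"], experiment.samples["treatment"])
        if t == treatment_b
    ]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError(f"need >= 2 replicates in both {treatment_a!r} and {treatment_b!r}")
    normalized = quantile_normalize(experiment.intensities)
    log2_mat = np.log2(normalized.to_numpy())
    gene_of = experiment.probe_to_gene.reindex(normalized.index)

    rows = []
    a_idx = [cols.index(c) for c in a_cols]
    b_idx = [cols.index(c) for c in b_cols]
    # group probe row indices by gene, preserving table order
    probe_rows: dict[str, list[int]] = {}
    for i, g in enumerate(gene_of.to_numpy()):
        probe_rows.setdefault(g, []).append(i)
    for gene_id, idx in probe_rows.items():
        summary = median_polish_summarize(log2_mat[idx, :], tol=tol, max_iter=max_iter)
        a_vals = summary[a_idx]
        b_vals = summary[b_idx]
        t, p = two_sample_t(a_vals, b_vals, equal_var=equal_var)
        mean_a, mean_b = float(a_vals.mean()), float(b_vals.mean())
        rows.append(
            {
                "gene_id": gene_id,
                **{f"log2_{c}": float(v) for c, v in zip(cols, summary)},
                "mean_log2_a": mean_a,
                "mean_log2_b": mean_b,
                "log2_fold": mean_a - mean_b,
                "fold_change": float(2.0 ** (mean_a - mean_b)),
                "t_stat": t,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def call_differential(
    summaries: pd.DataFrame,
    operons: Iterable[OperonGroup] = (),
    fc_single: float = 2.0,
    fc_operon: float = 1.7,
    alpha: float = 0.05,
) -> list[DECall]:
    """Apply the fold-change significance rules.

    A single gene is called when ``max(fold, 1/fold) >= fc_single`` and
    ``p <= alpha``.  An operon is called when all members change in the
    same direction with ``p <= alpha`` each and the geometric-mean fold
    across members is >= ``fc_operon``.  Genes inside a called operon
    are reported once, within the operon call.
    """
    if fc_single <= 1 or fc_operon <= 1:
        raise ValueError("fold-change thresholds must exceed 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    calls: list[DECall] = []
    covered: set[str] = set()

    for op in operons:
        members = [g for g in op.gene_ids if g in summaries.index]
        if len(members) != len(op.gene_ids) or not members:
            continue
        sub = summaries.loc[list(members)]
        lf = sub["log2_fold"].to_numpy()
        pv = sub["p_value"].to_numpy()
        same_dir = (lf > 0).all() or (lf < 0).all()
        if not same_dir or (pv > alpha).any():
            continue
        gm_fold = float(2.0 ** np.abs(lf.mean()))
        if gm_fold >= fc_operon:
            direction = "up_in_A" if lf.mean() > 0 else "up_in_B"
            calls.append(
                DECall(tuple(members), direction, "operon_1.7fold", gm_fold, tuple(map(float, pv)))
            )
            covered.update(members)

    for gene_id, row in summaries.iterrows():
        if gene_id in covered:
            continue
        fold = float(row["fold_change"])
        stat = max(fold, 1.0 / fold) if fold > 0 else float("inf")
        if stat >= fc_single and row["p_value"] <= alpha:
            direction = "up_in_A" if row["log2_fold"] > 0 else "up_in_B"
            calls.append(
                DECall((str(gene_id),), direction, "single_2fold", stat, (float(row["p_value"]),))
            )
    return calls


def calls_to_frame(calls: Sequence[DECall]) -> pd.DataFrame:
    """Tabular view of DE calls (one row per call, members comma-joined)."""
    return pd.DataFrame(
        [
            {
                "unit": ",".join(c.unit),
                "n_members": len(c.unit),
                "direction": c.direction,
                "rule_used": c.rule_used,
                "fold": c.fold,
                "min_p": min(c.p_values),
                "max_p": max(c.p_values),
            }
            for c in calls
        ]
    )
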