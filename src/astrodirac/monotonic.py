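"""Genes whose expression changes monotonically with tumor grade.

Candidates are genes differentially expressed (Wilcoxon rank-sum, Bonferroni
over all tested genes) in *every* adjacent grade comparison — Normal vs G2,
G2 vs G3, G3 vs pGBM, and G3 vs sGBM (both grade-4 subtypes must continue the
trend past G3).  Within that intersection, a gene is *increasing* when its
per-phenotype mean within-array rank rises strictly along
Normal < G2 < G3 < pGBM and Normal < G2 < G3 < sGBM (the two GBM subtypes are
unordered relative to each other), and *decreasing* in the mirror case.

Two resampling procedures qualify the gene lists: a subsampling robustness
check (draw 80% of each phenotype, rerun, count same-direction recurrence;
genes recurring in at least half the replicates are high-confidence) and a
directionality permutation test (shuffle all labels, count monotone genes per
direction, compare the observed counts to that null).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ADJACENT_PAIRS,
    LAYER_RANK,
    PHENOTYPES,
    ExpressionMatrix,
    PhenotypeLabels,
    logger,
    substream,
)

INCREASING = "increasing"
DECREASING = "decreasing"


def wilcoxon_rank_sum(group_a, group_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when the smaller group has <=8 values and there are no
    ties; otherwise the normal approximation with tie and continuity
    correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def _wilcoxon_battery(values_a: np.ndarray, values_b: np.ndarray) -> np.ndarray:
    """Row-wise two-sided p-values for genes x samples blocks (vectorized)."""
    n_min = min(values_a.shape[1], values_b.shape[1])
    method = "exact" if n_min <= 8 else "asymptotic"
    if method == "exact":
        pooled = np.concatenate([values_a, values_b], axis=1)
        has_ties = any(np.unique(row).size < row.size for row in pooled)
        if has_ties:
            method = "asymptotic"
    res = stats.mannwhitneyu(values_a, values_b, alternative="two-sided", method=method, axis=1)
    return np.asarray(res.pvalue, dtype=float)


@dataclass
class DEGSet:
    """Differential-expression result for one adjacent phenotype pair."""

    pair: tuple[str, str]
    pvalues: pd.Series  # per gene, two-sided
    alpha: float
    family_size: int

    @property
    def significant(self) -> pd.Index:
        """Genes passing Bonferroni: p < alpha / family_size."""
        return self.pvalues.index[self.pvalues < self.alpha / self.family_size]


def adjacent_degs(
    matrix: ExpressionMatrix, labels: PhenotypeLabels, alpha: float = 0.05
) -> dict[tuple[str, str], DEGSet]:
    """Wilcoxon DEG sets for the four adjacent-grade comparisons.

    Runs on the rank layer; the Bonferroni family size is the number of genes
    tested (all matrix genes), applied identically in every comparison.
    """
    labels.check_cover(matrix.sample_ids)
    present = set(labels.phenotypes_present())
    missing = [p for p in PHENOTYPES if p not in present]
    if missing:
        raise ValueError(f"adjacent-grade DEGs need all five phenotypes; missing {missing}")
    values = matrix.values
    out: dict[tuple[str, str], DEGSet] = {}
    for pair in ADJACENT_PAIRS:
        a, b = pair
        va = values[list(labels.samples_of(a))].to_numpy()
        vb = values[list(labels.samples_of(b))].to_numpy()
        p = _wilcoxon_battery(va, vb)
        out[pair] = DEGSet(
            pair=pair,
            pvalues=pd.Series(p, index=matrix.gene_ids),
            alpha=alpha,
            family_size=matrix.n_genes,
        )
    return out


@dataclass
class MonotonicGeneReport:
    """Monotone-trend candidates with per-phenotype mean ranks.

    ``table`` has one row per gene in the intersection of all four DEG sets:
    mean within-array rank per phenotype, direction (increasing / decreasing /
    none for non-monotone intersection genes), and — after the robustness
    step — subsample support counts and the high-confidence flag.
    """

    table: pd.DataFrame
    alpha: float
    n_rep: int = 0
    min_support: int = 0
    directionality_p: dict[str, float] = field(default_factory=dict)

    def genes(self, direction: str) -> list[str]:
        return list(self.table.index[self.table["direction"] == direction])


def _mean_ranks(matrix: ExpressionMatrix, labels: PhenotypeLabels) -> pd.DataFrame:
    cols = {}
    for phen in labels.phenotypes_present():
        cols[phen] = matrix.values[list(labels.samples_of(phen))].mean(axis=1)
    return pd.DataFrame(cols)


def _direction_of(means: pd.Series) -> str | None:
    lower = [means["Normal"], means["G2"], means["G3"]]
    inc_low = all(lower[i] < lower[i + 1] for i in range(2))
    dec_low = all(lower[i] > lower[i + 1] for i in range(2))
    if inc_low and means["G3"] < means["pGBM"] and means["G3"] < means["sGBM"]:
        return INCREASING
    if dec_low and means["G3"] > means["pGBM"] and means["G3"] > means["sGBM"]:
        return DECREASING
    return None


def find_monotonic(
    deg_sets: dict[tuple[str, str], DEGSet],
    matrix: ExpressionMatrix,
    labels: PhenotypeLabels,
) -> MonotonicGeneReport:
    """Intersect the four DEG sets and classify candidates by trend direction.

    Direction uses strict inequalities on per-phenotype mean within-array
    ranks; intersection genes that are not monotone stay in the table with
    direction "none".
    """
    if set(deg_sets) != set(ADJACENT_PAIRS):
        raise ValueError("deg_sets must cover exactly the four adjacent-grade pairs")
    candidate = None
    for pair in ADJACENT_PAIRS:
        sig = set(deg_sets[pair].significant)
        candidate = sig if candidate is None else candidate & sig
    candidates = [g for g in matrix.gene_ids if g in candidate]  # matrix order
    means = _mean_ranks(matrix, labels).loc[candidates]
    directions = [(_direction_of(means.loc[g]) or "none") for g in candidates]
    table = means.copy()
    table["direction"] = directions
    table.index.name = "gene"
    alpha = deg_sets[ADJACENT_PAIRS[0]].alpha
    return MonotonicGeneReport(table=table, alpha=alpha)


def _monotone_directions(
    matrix: ExpressionMatrix, labels: PhenotypeLabels, alpha: float
) -> pd.Series:
    """One pipeline pass: direction per monotone gene (helper for resampling)."""
    degs = adjacent_degs(matrix, labels, alpha=alpha)
    report = find_monotonic(degs, matrix, labels)
    tab = report.table
    keep = tab["direction"].isin([INCREASING, DECREASING])
    return tab.loc[keep, "direction"]


def subsample_robustness(
    matrix: ExpressionMatrix,
    labels: PhenotypeLabels,
    report: MonotonicGeneReport,
    n_rep: int = 1000,
    frac: float = 0.8,
    min_support: int | None = None,
    alpha: float = 0.05,
    seed: int = 0,
) -> MonotonicGeneReport:
    """Subsampling support for the full-data monotone genes.

    Each replicate draws ``frac`` of every phenotype's samples without
    replacement, reruns the DEG + monotonicity pipeline, and records whether
    each full-data gene recurs *with the same direction*.  Genes recurring in
    at least ``min_support`` replicates (default: half of ``n_rep``) are
    flagged high-confidence.  Returns a new report with support columns.
    """
    if min_support is None:
        min_support = n_rep // 2
    rng = substream(seed, "subsample")
    phenos = labels.phenotypes_present()
    groups = {p: np.asarray(labels.samples_of(p)) for p in phenos}
    for p, g in groups.items():
        if int(np.ceil(frac * g.size)) < 2:
            raise ValueError(f"subsampling fraction {frac} leaves <2 samples for {p}")

    flagged = report.table["direction"].isin([INCREASING, DECREASING])
    target = report.table.loc[flagged, "direction"]
    support = pd.Series(0, index=target.index, dtype=int)
    for _ in range(n_rep):
        chosen: list[str] = []
        for p in phenos:
            g = groups[p]
            k = int(np.ceil(frac * g.size))
            chosen.extend(g[rng.permutation(g.size)[:k]])
        sub_matrix = ExpressionMatrix(matrix.values[chosen], layer=matrix.layer)
        sub_labels = PhenotypeLabels(labels.labels.loc[chosen], universe=labels.universe)
        sub_dir = _monotone_directions(sub_matrix, sub_labels, alpha)
        recur = target.index[(target.index.isin(sub_dir.index))
                             & (sub_dir.reindex(target.index) == target)]
        support.loc[recur] += 1

    table = report.table.copy()
    table["support"] = support.reindex(table.index).fillna(0).astype(int)
    table.loc[~flagged, "support"] = 0
    table["high_confidence"] = flagged & (table["support"] >= min_support) & (n_rep > 0)
    return MonotonicGeneReport(
        table=table, alpha=report.alpha, n_rep=n_rep, min_support=min_support,
        directionality_p=dict(report.directionality_p),
    )


def directionality_test(
    matrix: ExpressionMatrix,
    labels: PhenotypeLabels,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float, pd.DataFrame]:
    """Permutation test of the monotone-gene counts, per direction.

    Permutes all phenotype labels jointly, reruns the DEG + monotonicity
    pipeline (no robustness step), and compares the observed increasing and
    decreasing counts against the null counts:
    p = (1 + #{null count >= observed}) / (n_perm + 1).
    Returns (p_increasing, p_decreasing, null-count table).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    obs = _monotone_directions(matrix, labels, alpha)
    obs_inc = int((obs == INCREASING).sum())
    obs_dec = int((obs == DECREASING).sum())

    rng = substream(seed, "directionality")
    sample_ids = np.asarray(labels.labels.index)
    label_values = labels.labels.to_numpy()
    null_inc = np.zeros(n_perm, dtype=int)
    null_dec = np.zeros(n_perm, dtype=int)
    for k in range(n_perm):
        shuffled = label_values[rng.permutation(label_values.size)]
        perm_labels = PhenotypeLabels(pd.Series(shuffled, index=sample_ids), universe=labels.universe)
        d = _monotone_directions(matrix, perm_labels, alpha)
        null_inc[k] = int((d == INCREASING).sum())
        null_dec[k] = int((d == DECREASING).sum())

    p_inc = (1.0 + (null_inc >= obs_inc).sum()) / (n_perm + 1.0)
    p_dec = (1.0 + (null_dec >= obs_dec).sum()) / (n_perm + 1.0)
    null = pd.DataFrame({"increasing": null_inc, "decreasing": null_dec})
    logger.info("directionality: observed %d increasing (p=%.4g), %d decreasing (p=%.4g)",
                obs_inc, p_inc, obs_dec, p_dec)
    return float(p_inc), float(p_dec), null


def monotonic_pipeline(
    matrix: ExpressionMatrix,
    labels: PhenotypeLabels,
    alpha: float = 0.05,
    n_rep: int = 1000,
    frac: float = 0.8,
    min_support: int | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> MonotonicGeneReport:
    """Full monotone-gene analysis: DEGs, trend calls, robustness, direction p.

    Expects the rank layer (the trend statistic is the mean within-array rank).
    """
    if matrix.layer != LAYER_RANK:
        raise ValueError("monotonic analysis runs on the rank layer; apply rank_transform first")
    degs = adjacent_degs(matrix, labels, alpha=alpha)
    report = find_monotonic(degs, matrix, labels)
    if n_rep > 0:
        report = subsample_robustness(
            matrix, labels, report, n_rep=n_rep, frac=frac,
            min_support=min_support, alpha=alpha, seed=seed,
        )
    else:
        table = report.table.copy()
        table["support"] = 0
        table["high_confidence"] = False
        report = MonotonicGeneReport(table=table, alpha=alpha, n_rep=0,
                                     min_support=min_support or 0)
    if n_perm > 0:
        p_inc, p_dec, _ = directionality_test(matrix, labels, n_perm=n_perm, alpha=alpha, seed=seed)
        report.directionality_p = {INCREASING: p_inc, DECREASING: p_dec}
    return report
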