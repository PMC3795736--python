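"""Post-normalization consensus preprocessing.

Four steps, applied in order after upstream normalization of the raw arrays:

1. present-call filter — drop probes with zero present calls in any phenotype;
2. probe-to-gene collapse — drop ambiguous multi-gene probes, then take the
   per-sample maximum over a gene's remaining probes;
3. within-array rank transform — replace intensities by their relative ranks
   within each array (midranks for ties), making everything downstream
   invariant to monotone per-array distortions;
4. a correlation QC statistic — the mean sample-to-sample Pearson correlation,
   which rises as lab effects are suppressed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import (
    LAYER_INTENSITY,
    LAYER_RANK,
    ExpressionMatrix,
    PhenotypeLabels,
    ProbeLayer,
    logger,
)


def filter_probes_by_present_call(probes: ProbeLayer, labels: PhenotypeLabels) -> ProbeLayer:
    """Keep probes with at least one present call in *every* phenotype.

    A probe silent (0% present) across all samples of any single phenotype is
    removed: such a probe cannot inform comparisons involving that phenotype.
    """
    labels.check_cover(probes.intensities.columns)
    calls = probes.present_calls
    keep = pd.Series(True, index=probes.probe_ids)
    for phen in labels.phenotypes_present():
        cols = labels.samples_of(phen)
        keep &= calls[cols].any(axis=1)
    kept = probes.subset(list(keep.index[keep]))
    n_removed = int((~keep).sum())
    logger.info("present-call filter: removed %d of %d probes", n_removed, len(keep))
    return kept


def collapse_probes_to_genes(probes: ProbeLayer) -> ExpressionMatrix:
    """Collapse the probe layer to one row per gene.

    Probes mapping to multiple genes are eliminated as ambiguous.  When a gene
    retains several probes, each cell takes the maximum intensity over those
    probes, computed per sample (so different probes may win in different
    samples).
    """
    single = [p for p, genes in probes.probe_to_genes.items() if len(genes) == 1]
    n_multi = len(probes.probe_to_genes) - len(single)
    if n_multi:
        logger.info("collapse: eliminated %d multi-gene probes", n_multi)
    if not single:
        raise ValueError("no single-gene probes remain; cannot build a gene matrix")
    intens = probes.intensities.loc[single]
    gene_of = pd.Series({p: probes.probe_to_genes[p][0] for p in single})
    collapsed = intens.groupby(gene_of, sort=True).max()
    collapsed.index.name = None
    return ExpressionMatrix(collapsed, layer=LAYER_INTENSITY)


def rank_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Replace intensities by their relative ranks within each array.

    Each column is ranked ascending (1 = lowest intensity); ties receive
    average (mid) ranks, so every column sums to n(n+1)/2.
    """
    if matrix.layer != LAYER_INTENSITY:
        raise ValueError("rank_transform expects the intensity layer")
    values = matrix.values.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or not np.isfinite(values).all():
        raise ValueError("non-numeric or non-finite intensities")
    ranks = rankdata(values, method="average", axis=0)
    return ExpressionMatrix(
        pd.DataFrame(ranks, index=matrix.gene_ids, columns=matrix.sample_ids),
        layer=LAYER_RANK,
    )


def mean_sample_correlation(matrix: ExpressionMatrix) -> float:
    """Mean off-diagonal Pearson correlation over all unordered sample pairs.

    Zero-variance samples cannot be correlated; pairs involving them are
    excluded with a warning.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    values = matrix.values.to_numpy()
    sd = values.std(axis=0)
    ok = sd > 0
    if not ok.all():
        bad = list(matrix.sample_ids[~ok])
        logger.warning("mean_sample_correlation: excluding zero-variance samples %s", bad[:5])
    values = values[:, ok]
    if values.shape[1] < 2:
        raise ValueError("fewer than 2 samples with nonzero variance")
    corr = np.corrcoef(values, rowvar=False)
    iu = np.triu_indices_from(corr, k=1)
    return float(corr[iu].mean())


def preprocess_probe_layer(probes: ProbeLayer, labels: PhenotypeLabels) -> ExpressionMatrix:
    """Full consensus chain: present-call filter -> collapse -> rank transform."""
    filtered = filter_probes_by_present_call(probes, labels)
    collapsed = collapse_probes_to_genes(filtered)
    return rank_transform(collapsed)
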