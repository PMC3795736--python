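"""Template-based two-class classification from network rank orderings.

Each network yields a classifier: build one rank template per phenotype, then
assign every sample to the phenotype whose template it matches more closely
(higher rank matching score).  Apparent accuracy scores the training samples
themselves; leave-one-out cross-validation rebuilds both templates without the
held-out sample before predicting it.  Significance comes from a pooled
permutation null of apparent accuracies over all networks, with a
permutation-based false discovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GeneSetCollection, PhenotypeLabels, logger, substream
from .dirac import pair_order_matrix, resolve_networks


@dataclass
class ClassificationResult:
    """Two-template classification of one network, apparent or cross-validated.

    Phenotype A plays the positive class: sensitivity is the fraction of A
    samples predicted A, specificity the fraction of B predicted B.  Ties in
    matching score are assigned to the larger class (equal sizes: the
    lexicographically smaller phenotype name) and counted in ``n_ties``.
    """

    network: str
    pheno_a: str
    pheno_b: str
    n_a: int
    n_b: int
    accuracy: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    predictions: pd.Series
    n_ties: int
    kind: str = "apparent"  # or "loocv"


def _prepare(matrix, labels, pheno_a, pheno_b, min_samples):
    labels.check_cover(matrix.sample_ids)
    samples_a = list(labels.samples_of(pheno_a))
    samples_b = list(labels.samples_of(pheno_b))
    if len(samples_a) < min_samples or len(samples_b) < min_samples:
        raise ValueError(
            f"need >={min_samples} samples per phenotype "
            f"(got {len(samples_a)} {pheno_a}, {len(samples_b)} {pheno_b})"
        )
    values = matrix.values[samples_a + samples_b].to_numpy()
    return samples_a, samples_b, values


def _tie_label_is_a(n_a: int, n_b: int, pheno_a: str, pheno_b: str) -> bool:
    """Ties go to the larger class; equal sizes fall back to the
    lexicographically smaller phenotype name, which keeps the rule symmetric
    under swapping the two class arguments."""
    if n_a != n_b:
        return n_a > n_b
    return pheno_a < pheno_b


def _metrics(correct_a: np.ndarray, correct_b: np.ndarray) -> tuple[float, float, float, float]:
    sens = float(correct_a.mean())
    spec = float(correct_b.mean())
    acc = float((correct_a.sum() + correct_b.sum()) / (correct_a.size + correct_b.size))
    return acc, sens, spec, (sens + spec) / 2.0


def classify_samples(
    matrix: ExpressionMatrix,
    labels: PhenotypeLabels,
    network: str,
    networks: GeneSetCollection,
    pheno_a: str,
    pheno_b: str,
    min_genes: int = 2,
) -> ClassificationResult:
    """Apparent (training-set) classification of one network.

    Templates are built from *all* samples of each phenotype; every sample is
    then assigned to the template with the higher matching score.
    """
    samples_a, samples_b, values = _prepare(matrix, labels, pheno_a, pheno_b, min_samples=2)
    resolved = resolve_networks(matrix, networks, min_genes=min_genes)
    if network not in resolved:
        raise ValueError(f"network {network!r} has <{min_genes} usable genes; skipped")
    bits = pair_order_matrix(values[resolved[network], :])
    n_a, n_b = len(samples_a), len(samples_b)

    tie_to_a = _tie_label_is_a(n_a, n_b, pheno_a, pheno_b)
    pred_a, n_ties = _predict_two_template(bits, n_a, n_b, tie_to_a)
    correct_a, correct_b = pred_a[:n_a], ~pred_a[n_a:]
    acc, sens, spec, bal = _metrics(correct_a, correct_b)
    preds = pd.Series(np.where(pred_a, pheno_a, pheno_b), index=samples_a + samples_b)
    return ClassificationResult(network, pheno_a, pheno_b, n_a, n_b,
                                acc, sens, spec, bal, preds, n_ties, kind="apparent")


def _predict_two_template(bits: np.ndarray, n_a: int, n_b: int, tie_to_a: bool) -> tuple[np.ndarray, int]:
    """Predict every pooled sample (A block first) from the two full templates."""
    counts_a = bits[:, :n_a].sum(axis=1)
    counts_b = bits[:, n_a:].sum(axis=1)
    t_a = counts_a * 2 > n_a
    t_b = counts_b * 2 > n_b
    s_a = (bits == t_a[:, None]).mean(axis=0)
    s_b = (bits == t_b[:, None]).mean(axis=0)
    ties = s_a == s_b
    pred_a = s_a > s_b
    if ties.any() and tie_to_a:
        pred_a = pred_a | ties
    return pred_a, int(ties.sum())


def loocv(
    matrix: ExpressionMatrix,
    labels: PhenotypeLabels,
    network: str,
    networks: GeneSetCollection,
    pheno_a: str,
    pheno_b: str,
    min_genes: int = 2,
    min_samples: int = 3,
) -> ClassificationResult:
    """Leave-one-out cross-validation of one network's two-template classifier.

    For every sample, both templates are rebuilt without it (so each phenotype
    needs >=3 samples for the template to survive removal), the held-out
    sample is predicted, and metrics are tallied over all folds.  Fully
    deterministic.
    """
    samples_a, samples_b, values = _prepare(matrix, labels, pheno_a, pheno_b, min_samples=min_samples)
    resolved = resolve_networks(matrix, networks, min_genes=min_genes)
    if network not in resolved:
        raise ValueError(f"network {network!r} has <{min_genes} usable genes; skipped")
    bits = pair_order_matrix(values[resolved[network], :])
    n_a, n_b = len(samples_a), len(samples_b)
    counts_a = bits[:, :n_a].sum(axis=1)
    counts_b = bits[:, n_a:].sum(axis=1)

    pred_a = np.zeros(n_a + n_b, dtype=bool)
    n_ties = 0
    # score ties break on the full-cohort class prior, not the fold's training
    # sizes: the fold sizes always disfavor the held-out sample's own class
    tie_to_a = _tie_label_is_a(n_a, n_b, pheno_a, pheno_b)
    for s in range(n_a + n_b):
        held = bits[:, s]
        in_a = s < n_a
        ca = counts_a - (held if in_a else 0)
        cb = counts_b - (0 if in_a else held)
        na_s, nb_s = n_a - in_a, n_b - (not in_a)
        t_a = ca * 2 > na_s
        t_b = cb * 2 > nb_s
        s_a = float((held == t_a).mean())
        s_b = float((held == t_b).mean())
        if s_a == s_b:
            n_ties += 1
            pred_a[s] = tie_to_a
        else:
            pred_a[s] = s_a > s_b
    correct_a, correct_b = pred_a[:n_a], ~pred_a[n_a:]
    acc, sens, spec, bal = _metrics(correct_a, correct_b)
    preds = pd.Series(np.where(pred_a, pheno_a, pheno_b), index=samples_a + samples_b)
    return ClassificationResult(network, pheno_a, pheno_b, n_a, n_b,
                                acc, sens, spec, bal, preds, n_ties, kind="loocv")


def classification_significance(
    matrix: ExpressionMatrix,
    labels: PhenotypeLabels,
    networks: GeneSetCollection,
    pheno_a: str,
    pheno_b: str,
    n_perm: int = 1000,
    seed: int = 0,
    min_genes: int = 2,
    fdr_method: str = "permutation",
) -> pd.DataFrame:
    """Permutation p-values and FDR for every network's apparent accuracy.

    The null pools apparent accuracies of *all* networks under each label
    permutation; p(network) = (1 + #{null >= observed}) / (1 + pooled size).
    ``fdr_method="permutation"`` estimates FDR at each observed accuracy t as
    (expected null networks >= t per permutation) / (observed networks >= t),
    clipped to [0, 1]; ``"bh"`` applies Benjamini-Hochberg to the p-values.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    samples_a, samples_b, values = _prepare(matrix, labels, pheno_a, pheno_b, min_samples=2)
    resolved = resolve_networks(matrix, networks, min_genes=min_genes)
    if not resolved:
        raise ValueError("no usable networks")
    n_a, n_b = len(samples_a), len(samples_b)
    n = n_a + n_b

    rng = substream(seed, f"classify:{pheno_a}:{pheno_b}")
    member = np.zeros((n, n_perm))
    for k in range(n_perm):
        member[rng.permutation(n)[:n_a], k] = 1.0

    names = list(resolved)
    observed = np.empty(len(names))
    null_acc = np.empty((len(names), n_perm))
    tie_to_a = _tie_label_is_a(n_a, n_b, pheno_a, pheno_b)
    for r, name in enumerate(names):
        bits = pair_order_matrix(values[resolved[name], :]).astype(float)
        pred_a, _ = _predict_two_template(bits.astype(bool), n_a, n_b, tie_to_a)
        truth = np.zeros(n, dtype=bool)
        truth[:n_a] = True
        observed[r] = float((pred_a == truth).mean())
        null_acc[r] = _permuted_accuracies(bits, member, n_a, n_b, tie_to_a)

    pool = np.sort(null_acc.ravel())
    ge = pool.size - np.searchsorted(pool, observed, side="left")
    p = (1.0 + ge) / (1.0 + pool.size)

    if fdr_method == "bh":
        fdr = stats.false_discovery_control(p)
    elif fdr_method == "permutation":
        obs_sorted = np.sort(observed)
        fdr = np.empty_like(observed)
        for r, t in enumerate(observed):
            expected_fp = (pool.size - np.searchsorted(pool, t, side="left")) / n_perm
            n_pos = observed.size - np.searchsorted(obs_sorted, t, side="left")
            fdr[r] = min(1.0, expected_fp / n_pos) if n_pos else 1.0
    else:
        raise ValueError(f"unknown fdr_method {fdr_method!r}")

    return pd.DataFrame(
        {"accuracy": observed, "p": p, "fdr": fdr},
        index=pd.Index(names, name="network"),
    ).sort_values(["accuracy", "network"], ascending=[False, True])


def _permuted_accuracies(bits: np.ndarray, member: np.ndarray, n_a: int, n_b: int,
                         tie_to_a: bool) -> np.ndarray:
    """Apparent accuracy of one network under each label permutation.

    ``bits`` is pairs x samples (float 0/1), ``member`` samples x n_perm with
    1 marking permuted-A membership.  Matching scores against the per-
    permutation majority templates are computed by matrix products.
    """
    n_pairs = bits.shape[0]
    counts_a = bits @ member  # pairs x n_perm
    row_tot = bits.sum(axis=1)[:, None]
    t_a = (counts_a * 2 > n_a).astype(float)
    t_b = ((row_tot - counts_a) * 2 > n_b).astype(float)
    # score(sample, perm) = fraction of pairs agreeing with the template
    s_a = (t_a.T @ bits + (1.0 - t_a).T @ (1.0 - bits)) / n_pairs  # n_perm x n
    s_b = (t_b.T @ bits + (1.0 - t_b).T @ (1.0 - bits)) / n_pairs
    pred_a = s_a > s_b
    ties = s_a == s_b
    if tie_to_a:
        pred_a = pred_a | ties
    truth_a = member.T.astype(bool)  # n_perm x n
    return (pred_a == truth_a).mean(axis=1)


@dataclass
class OneVsRestSummary:
    """One phenotype against the pooled rest: per-network metrics and top-k."""

    phenotype: str
    per_network: pd.DataFrame  # apparent acc/sens/spec (+ loocv, p, fdr when computed)
    top: pd.DataFrame
    n_target: int
    n_rest: int


def one_vs_rest(
    matrix: ExpressionMatrix,
    labels: PhenotypeLabels,
    networks: GeneSetCollection,
    phenotype: str,
    top_k: int = 10,
    n_perm: int = 0,
    seed: int = 0,
    do_loocv: bool = True,
    min_genes: int = 2,
) -> OneVsRestSummary:
    """Classify one phenotype against all other phenotypes pooled as "rest".

    Emits per-network apparent metrics (and LOOCV when requested), the pooled
    permutation p/FDR when ``n_perm > 0``, and a top-k table sorted by
    apparent accuracy descending with ties broken by network name.
    """
    rest = "rest"
    binary = pd.Series(
        np.where(labels.labels == phenotype, phenotype, rest), index=labels.labels.index
    )
    bin_labels = PhenotypeLabels(binary, universe=(phenotype, rest))
    resolved = resolve_networks(matrix, networks, min_genes=min_genes)
    rows = []
    for name in resolved:
        res = classify_samples(matrix, bin_labels, name, networks, phenotype, rest, min_genes)
        row = {
            "network": name,
            "accuracy": res.accuracy,
            "sensitivity": res.sensitivity,
            "specificity": res.specificity,
            "balanced_accuracy": res.balanced_accuracy,
        }
        if do_loocv:
            cv = loocv(matrix, bin_labels, name, networks, phenotype, rest, min_genes)
            row["loocv_accuracy"] = cv.accuracy
            row["loocv_sensitivity"] = cv.sensitivity
            row["loocv_specificity"] = cv.specificity
        rows.append(row)
    per_network = pd.DataFrame(rows).set_index("network")
    if n_perm > 0:
        sig = classification_significance(
            matrix, bin_labels, networks, phenotype, rest, n_perm=n_perm, seed=seed, min_genes=min_genes
        )
        per_network = per_network.join(sig[["p", "fdr"]])
    # accuracy descending, ties broken by network name ascending (stable sort)
    per_network = per_network.sort_index().sort_values("accuracy", ascending=False, kind="stable")
    top = per_network.head(top_k)
    n_target = int((binary == phenotype).sum())
    return OneVsRestSummary(phenotype, per_network, top, n_target, len(binary) - n_target)
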