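"""Independent brute-force oracles for the test suite.

Deliberately naive: explicit Python loops over gene pairs, samples and rank
assignments, sharing no code with the package's vectorized implementations.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


# --- DIRAC by explicit pair enumeration ------------------------------------

def brute_pair_bits(sample: list[float]) -> list[int]:
    """Pair-order bits of one sample: 1 iff expr[i] < expr[j], ties 0."""
    m = len(sample)
    bits = []
    for i in range(m):
        for j in range(i + 1, m):
            bits.append(1 if sample[i] < sample[j] else 0)
    return bits


def brute_template(samples: list[list[float]]) -> tuple[list[int], list[int]]:
    """Strict-majority template and tie mask over a list of samples."""
    all_bits = [brute_pair_bits(s) for s in samples]
    n = len(samples)
    template, ties = [], []
    for p in range(len(all_bits[0])):
        ones = sum(bits[p] for bits in all_bits)
        if 2 * ones > n:
            template.append(1)
            ties.append(0)
        elif 2 * ones == n:
            template.append(0)
            ties.append(1)
        else:
            template.append(0)
            ties.append(0)
    return template, ties


def brute_matching_score(sample: list[float], template: list[int]) -> float:
    bits = brute_pair_bits(sample)
    agree = sum(1 for b, t in zip(bits, template) if b == t)
    return agree / len(template)


def brute_conservation_index(samples: list[list[float]]) -> float:
    template, _ = brute_template(samples)
    agree = 0
    for s in samples:
        bits = brute_pair_bits(s)
        agree += sum(1 for b, t in zip(bits, template) if b == t)
    # one division of exact integer counts
    return agree / (len(template) * len(samples))


def brute_two_template_predictions(
    samples_a: list[list[float]], samples_b: list[list[float]]
) -> list[str]:
    """Apparent two-template classification; tie -> larger class (A if equal)."""
    t_a, _ = brute_template(samples_a)
    t_b, _ = brute_template(samples_b)
    tie_label = "A" if len(samples_a) >= len(samples_b) else "B"
    preds = []
    for s in samples_a + samples_b:
        sa = brute_matching_score(s, t_a)
        sb = brute_matching_score(s, t_b)
        preds.append("A" if sa > sb else "B" if sb > sa else tie_label)
    return preds


def brute_loocv_predictions(
    samples_a: list[list[float]], samples_b: list[list[float]]
) -> list[str]:
    """Leave-one-out predictions; ties break on the full class sizes."""
    tie_label = "A" if len(samples_a) >= len(samples_b) else "B"
    preds = []
    for k in range(len(samples_a)):
        rest = samples_a[:k] + samples_a[k + 1:]
        t_a, _ = brute_template(rest)
        t_b, _ = brute_template(samples_b)
        sa = brute_matching_score(samples_a[k], t_a)
        sb = brute_matching_score(samples_a[k], t_b)
        preds.append("A" if sa > sb else "B" if sb > sa else tie_label)
    for k in range(len(samples_b)):
        rest = samples_b[:k] + samples_b[k + 1:]
        t_a, _ = brute_template(samples_a)
        t_b, _ = brute_template(rest)
        sa = brute_matching_score(samples_b[k], t_a)
        sb = brute_matching_score(samples_b[k], t_b)
        preds.append("A" if sa > sb else "B" if sb > sa else tie_label)
    return preds


# --- Wilcoxon rank-sum by full enumeration ----------------------------------

def brute_wilcoxon_two_sided(a: list[float], b: list[float]) -> float:
    """Exact two-sided rank-sum p by enumerating every C(n, nA) assignment.

    Requires untied pooled values.  Uses the symmetric |U - E[U]| convention,
    which for an untied (hence symmetric) null equals doubling the smaller
    tail.
    """
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires untied values"
    n_a = len(a)
    ranks = {v: r + 1 for r, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in a)
    mean_w = n_a * (len(pooled) + 1) / 2
    count = total = 0
    for combo in combinations(range(1, len(pooled) + 1), n_a):
        w = sum(combo)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total


# --- misc --------------------------------------------------------------------

def random_monotone_map(rng: np.random.Generator):
    """A random strictly increasing map R -> R."""
    a = float(rng.uniform(0.5, 3.0))
    b = float(rng.uniform(-5.0, 5.0))
    kind = int(rng.integers(0, 3))
    if kind == 0:
        return lambda x: a * x + b
    if kind == 1:
        return lambda x: np.exp(a * (x - np.mean(x)) / (np.std(x) + 1e-9)) + b
    return lambda x: a * (x + np.abs(x).max() + 1.0) ** 1.5 + b
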