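"""Synthetic multi-study astrocytoma cohorts with known ground truth.

The generator emulates the post-normalization output of a multi-lab microarray
compendium over the ordered phenotypes Normal < G2 < G3 < {pGBM, sGBM}:

    expr(g, s) = mu_g
               + grade_step(s) * delta * dir_g        (planted monotone genes)
               + batch_effect(batch(s), g)            (additive lab effect)
               + Normal(0, sigma_phen(s) [+ extra])   (per-phenotype noise)

where ``grade_step`` is 0,1,2,3,3 for Normal,G2,G3,pGBM,sGBM (the two GBM
subtypes are parallel grade-4 endpoints), ``dir_g`` is +1/-1 for planted
increasing/decreasing genes, and ``extra`` widens the noise of genes belonging
to a network planted as dysregulated in a sample's phenotype.  Per-phenotype
noise scales control within-phenotype ordering consistency: larger sigma means
more sample-to-sample reshuffling of gene order, i.e. lower downstream rank
conservation.

A probe layer (multi-probe genes, ambiguous multi-gene probes, Bernoulli
present calls, optionally phenotype-silent probes) exercises the preprocessing
filters.  Everything is determined by ``SimConfig.seed`` via named substreams.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    GRADE_STEP,
    LAYER_INTENSITY,
    PHENOTYPES,
    ExpressionMatrix,
    GeneSetCollection,
    PhenotypeLabels,
    ProbeLayer,
    logger,
    substream,
)

#: Per-phenotype sample counts of the emulated compendium (multi-study totals).
DEFAULT_SAMPLES: dict[str, int] = {"Normal": 30, "G2": 31, "G3": 57, "pGBM": 174, "sGBM": 44}

#: Per-phenotype noise scales: a ladder increasing with grade, so that network
#: ordering grows more heterogeneous in more aggressive phenotypes.  The two
#: GBM subtypes share one scale (same WHO grade).
DEFAULT_SIGMA: dict[str, float] = {"Normal": 10.0, "G2": 14.0, "G3": 18.0, "pGBM": 22.0, "sGBM": 22.0}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    ``planted_dysreg`` is a list of ``(network_name, phenotype, extra_sigma)``
    triples; ``planted_increasing``/``planted_decreasing`` are gene ids whose
    mean shifts by ``monotone_delta`` per grade step (up or down).
    """

    n_genes: int = 2000
    samples_per_phenotype: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SAMPLES))
    n_networks: int = 248
    network_size_range: tuple[int, int] = (5, 50)
    sigma_by_phenotype: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SIGMA))
    planted_dysreg: list[tuple[str, str, float]] = field(default_factory=list)
    planted_increasing: list[str] = field(default_factory=list)
    planted_decreasing: list[str] = field(default_factory=list)
    monotone_delta: float = 45.0
    n_batches: int = 3
    batch_sigma: float = 5.0
    mu_range: tuple[float, float] = (0.0, 1000.0)
    # probe layer
    multi_probe_gene_fraction: float = 0.10  # genes measured by 2 probes
    triple_probe_gene_fraction: float = 0.02  # genes measured by 3 probes
    n_multi_gene_probes: int = 20  # ambiguous probes mapping to 2 genes
    present_call_rate: float = 0.95
    n_silent_probes: int = 10  # probes forced all-absent in one random phenotype
    probe_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        for phen, n in self.samples_per_phenotype.items():
            if phen not in PHENOTYPES:
                raise ValueError(f"unknown phenotype {phen!r}")
            if n <= 0:
                raise ValueError(f"sample count for {phen} must be > 0")
        lo, hi = self.network_size_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid network size range")
        if hi > self.n_genes:
            raise ValueError(f"network size range {self.network_size_range} exceeds gene universe {self.n_genes}")
        for phen, s in self.sigma_by_phenotype.items():
            if s < 0:
                raise ValueError(f"sigma for {phen} must be >= 0")
        universe = set(self.gene_ids())
        planted = set(self.planted_increasing) | set(self.planted_decreasing)
        if not planted <= universe:
            raise ValueError("planted monotone gene ids outside gene universe")
        if set(self.planted_increasing) & set(self.planted_decreasing):
            raise ValueError("a gene cannot be planted both increasing and decreasing")
        for _net, phen, extra in self.planted_dysreg:
            if phen not in PHENOTYPES:
                raise ValueError(f"planted dysregulation in unknown phenotype {phen!r}")
            if extra < 0:
                raise ValueError("extra_sigma must be >= 0")

    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["network_size_range"] = list(self.network_size_range)
        d["mu_range"] = list(self.mu_range)
        d["planted_dysreg"] = [list(t) for t in self.planted_dysreg]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "network_size_range" in d:
            d["network_size_range"] = tuple(d["network_size_range"])
        if "mu_range" in d:
            d["mu_range"] = tuple(d["mu_range"])
        if "planted_dysreg" in d:
            d["planted_dysreg"] = [tuple(t) for t in d["planted_dysreg"]]
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth of a generated cohort; fully determined by the seed."""

    mu: dict[str, float]
    planted_increasing: list[str]
    planted_decreasing: list[str]
    planted_dysreg: list[tuple[str, str, float]]
    batch_of_sample: dict[str, int]
    silent_probes: list[tuple[str, str]]  # (probe_id, phenotype) forced absent

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["planted_dysreg"] = [list(t) for t in self.planted_dysreg]
        d["silent_probes"] = [list(t) for t in self.silent_probes]
        with open(path, "w") as fh:
            json.dump(d, fh, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["planted_dysreg"] = [tuple(t) for t in d["planted_dysreg"]]
        d["silent_probes"] = [tuple(t) for t in d["silent_probes"]]
        return cls(**d)


def generate_networks(config: SimConfig) -> GeneSetCollection:
    """Draw the named gene-set collection (networks) for a config.

    Each network samples its genes without replacement from the gene universe;
    sizes are uniform over the configured range.  Deterministic under seed.
    """
    lo, hi = config.network_size_range
    rng = substream(config.seed, "networks")
    genes = np.asarray(config.gene_ids())
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for k in range(config.n_networks):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        name = f"NET_{k:03d}"
        sets[name] = [str(g) for g in members]
        descriptions[name] = f"synthetic network of {size} genes"
    return GeneSetCollection(sets, descriptions)


def _sample_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    for phen in PHENOTYPES:
        n = config.samples_per_phenotype.get(phen, 0)
        for j in range(n):
            rows.append((f"{phen}_{j:03d}", phen))
    return pd.DataFrame(rows, columns=["sample_id", "phenotype"])


def generate_cohort(
    config: SimConfig, networks: GeneSetCollection | None = None
) -> tuple[ExpressionMatrix, PhenotypeLabels, ProbeLayer, SimTruth]:
    """Generate expression, labels, probe layer and ground truth for a config.

    ``networks`` is needed only when ``config.planted_dysreg`` names networks;
    if omitted it is drawn from the same seed via :func:`generate_networks`.
    """
    if networks is None and config.planted_dysreg:
        networks = generate_networks(config)

    gene_ids = config.gene_ids()
    samples = _sample_table(config)
    n_genes, n_samples = len(gene_ids), len(samples)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    rng_mu = substream(config.seed, "mu")
    mu = rng_mu.uniform(*config.mu_range, size=n_genes)

    # per-grade-step shift for planted monotone genes
    direction = np.zeros(n_genes)
    for g in config.planted_increasing:
        direction[gene_pos[g]] = 1.0
    for g in config.planted_decreasing:
        direction[gene_pos[g]] = -1.0
    steps = np.array([GRADE_STEP[p] for p in samples["phenotype"]], dtype=float)
    trend = np.outer(direction * config.monotone_delta, steps)

    rng_batch = substream(config.seed, "batch")
    batch_of_sample = rng_batch.integers(0, config.n_batches, size=n_samples)
    batch_shift = rng_batch.normal(0.0, config.batch_sigma, size=(config.n_batches, n_genes))
    batch_term = batch_shift[batch_of_sample, :].T  # genes x samples

    # per-cell noise scale: phenotype sigma, widened for planted (network, phenotype)
    sigma = np.empty((n_genes, n_samples))
    sigma[:] = np.array([config.sigma_by_phenotype.get(p, 0.0) for p in samples["phenotype"]])[None, :]
    for net_name, phen, extra in config.planted_dysreg:
        if net_name not in networks.sets:
            raise ValueError(f"planted dysregulation names unknown network {net_name!r}")
        rows = [gene_pos[g] for g in networks[net_name]]
        cols = np.flatnonzero((samples["phenotype"] == phen).values)
        # overlapping plantings: the widest extra_sigma wins
        block = sigma[np.ix_(rows, cols)]
        sigma[np.ix_(rows, cols)] = np.maximum(
            block, np.array([config.sigma_by_phenotype.get(phen, 0.0) + extra])
        )

    rng_noise = substream(config.seed, "noise")
    noise = rng_noise.standard_normal((n_genes, n_samples)) * sigma

    values = mu[:, None] + trend + batch_term + noise
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=samples["sample_id"].values),
        layer=LAYER_INTENSITY,
    )
    labels = PhenotypeLabels(pd.Series(samples["phenotype"].values, index=samples["sample_id"].values))

    probe_layer, silent = _generate_probe_layer(config, matrix, labels)

    truth = SimTruth(
        mu={g: float(m) for g, m in zip(gene_ids, mu)},
        planted_increasing=list(config.planted_increasing),
        planted_decreasing=list(config.planted_decreasing),
        planted_dysreg=list(config.planted_dysreg),
        batch_of_sample={s: int(b) for s, b in zip(samples["sample_id"], batch_of_sample)},
        silent_probes=silent,
    )
    return matrix, labels, probe_layer, truth


def _generate_probe_layer(
    config: SimConfig, matrix: ExpressionMatrix, labels: PhenotypeLabels
) -> tuple[ProbeLayer, list[tuple[str, str]]]:
    """Probe-level view: multi-probe genes, ambiguous probes, present calls."""
    rng = substream(config.seed, "probes")
    gene_ids = list(matrix.gene_ids)
    n_genes = len(gene_ids)

    probe_to_genes: dict[str, tuple[str, ...]] = {}
    probe_rows: list[np.ndarray] = []  # per-probe mean expression over mapped genes
    values = matrix.values.to_numpy()

    def add_probe(genes: tuple[str, ...]) -> None:
        pid = f"P{len(probe_to_genes):05d}"
        probe_to_genes[pid] = genes
        rows = values[[matrix.gene_ids.get_loc(g) for g in genes], :]
        probe_rows.append(rows.mean(axis=0))

    for g in gene_ids:  # every gene has at least one probe
        add_probe((g,))
    n_double = int(round(config.multi_probe_gene_fraction * n_genes))
    n_triple = int(round(config.triple_probe_gene_fraction * n_genes))
    extra = rng.choice(n_genes, size=min(n_double + n_triple, n_genes), replace=False)
    for i in extra[:n_double]:
        add_probe((gene_ids[i],))
    for i in extra[n_double:]:
        add_probe((gene_ids[i],))
        add_probe((gene_ids[i],))
    for _ in range(config.n_multi_gene_probes):
        i, j = rng.choice(n_genes, size=2, replace=False)
        add_probe((gene_ids[i], gene_ids[j]))

    probe_ids = list(probe_to_genes)
    intens = np.vstack(probe_rows)
    # probe-specific constant offset + measurement noise
    intens = intens + rng.normal(0.0, config.probe_sigma, size=(len(probe_ids), 1))
    intens = intens + rng.normal(0.0, config.probe_sigma, size=intens.shape)

    rng_calls = substream(config.seed, "calls")
    calls = rng_calls.random(intens.shape) < config.present_call_rate

    silent: list[tuple[str, str]] = []
    phenos = labels.phenotypes_present()
    if config.n_silent_probes > 0 and phenos:
        chosen = rng_calls.choice(len(probe_ids), size=min(config.n_silent_probes, len(probe_ids)), replace=False)
        for pi in chosen:
            phen = phenos[int(rng_calls.integers(0, len(phenos)))]
            cols = [labels.labels.index.get_loc(s) for s in labels.samples_of(phen)]
            calls[pi, cols] = False
            silent.append((probe_ids[pi], phen))

    layer = ProbeLayer(
        intensities=pd.DataFrame(intens, index=probe_ids, columns=matrix.sample_ids),
        present_calls=pd.DataFrame(calls, index=probe_ids, columns=matrix.sample_ids),
        probe_to_genes=probe_to_genes,
    )
    logger.info(
        "generated probe layer: %d probes over %d genes (%d ambiguous, %d phenotype-silent)",
        len(probe_ids), n_genes, config.n_multi_gene_probes, len(silent),
    )
    return layer, silent
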