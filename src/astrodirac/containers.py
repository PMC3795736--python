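"""Shared in-memory containers for the astrocytoma rank-conservation pipeline.

The pipeline works on three kinds of objects: a genes x samples expression
matrix (either raw intensities or within-array ranks), per-sample phenotype
labels drawn from the ordered grade ladder Normal < G2 < G3 < {pGBM, sGBM},
and a named collection of gene sets ("networks", GMT-backed).  A probe-level
layer carries the pre-collapse view of the data (probe intensities, a
probe->gene multimap, and Affymetrix-style present-call flags).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("astrodirac")

#: Ordered phenotype universe.  pGBM and sGBM are parallel grade-4 endpoints:
#: primary glioblastoma arises de novo, secondary progresses from a lower grade.
PHENOTYPES: tuple[str, ...] = ("Normal", "G2", "G3", "pGBM", "sGBM")

#: Position of each phenotype along the grade ladder.  Both GBM subtypes share
#: step 3, so monotone trends treat them as parallel endpoints past G3.
GRADE_STEP: dict[str, int] = {"Normal": 0, "G2": 1, "G3": 2, "pGBM": 3, "sGBM": 3}

#: Adjacent-grade comparisons used for differential expression.  The two
#: grade-4 subtypes are each compared against G3.
ADJACENT_PAIRS: tuple[tuple[str, str], ...] = (
    ("Normal", "G2"),
    ("G2", "G3"),
    ("G3", "pGBM"),
    ("G3", "sGBM"),
)

LAYER_INTENSITY = "intensity"
LAYER_RANK = "rank"


def substream(seed: int, name: str) -> np.random.Generator:
    """Named random substream derived from a single top-level seed.

    Every stochastic stage draws from ``substream(seed, "<stage>")`` so that
    changing one stage's parameters never perturbs another stage's draws, and
    the whole pipeline is reproducible from one integer.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())]))


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix tagged with its layer.

    ``layer`` is ``"intensity"`` for post-normalization intensities or
    ``"rank"`` for within-array midranks (each column a permutation of the
    average ranks of 1..n_genes).
    """

    values: pd.DataFrame
    layer: str = LAYER_INTENSITY

    def __post_init__(self) -> None:
        if self.layer not in (LAYER_INTENSITY, LAYER_RANK):
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class PhenotypeLabels:
    """Mapping sample -> phenotype with an ordered phenotype universe."""

    labels: pd.Series
    universe: tuple[str, ...] = PHENOTYPES

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels)
        unknown = set(self.labels.unique()) - set(self.universe)
        if unknown:
            raise ValueError(f"labels outside phenotype universe: {sorted(unknown)}")

    def samples_of(self, phenotype: str) -> pd.Index:
        return self.labels.index[self.labels == phenotype]

    def phenotypes_present(self) -> list[str]:
        present = set(self.labels.unique())
        return [p for p in self.universe if p in present]

    def check_cover(self, sample_ids: Sequence[str]) -> None:
        """Raise (naming the sample) if any matrix sample lacks a label."""
        missing = [s for s in sample_ids if s not in self.labels.index]
        if missing:
            raise ValueError(f"samples without phenotype label: {missing[:5]}")

    def merged_gbm(self) -> "PhenotypeLabels":
        """Collapse pGBM and sGBM into one 'GBM' class (global-trend view)."""
        merged = self.labels.replace({"pGBM": "GBM", "sGBM": "GBM"})
        return PhenotypeLabels(merged, universe=("Normal", "G2", "G3", "GBM"))


@dataclass
class GeneSetCollection:
    """Ordered, named gene sets (networks); GMT-backed.

    ``sets`` maps network name -> member gene list in file order;
    ``descriptions`` carries the GMT description column.
    """

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclass
class ProbeLayer:
    """Probe-level view: intensities, present calls, and a probe->gene multimap.

    Some probes map to two genes (dropped during collapse, as ambiguous), and
    some genes are measured by several probes (collapsed by per-sample max).
    """

    intensities: pd.DataFrame  # probes x samples
    present_calls: pd.DataFrame  # probes x samples, bool
    probe_to_genes: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if self.intensities.shape != self.present_calls.shape:
            raise ValueError("present-call matrix shape differs from intensity matrix")
        if not self.intensities.index.equals(self.present_calls.index):
            raise ValueError("present-call probe ids differ from intensity probe ids")
        for probe, genes in self.probe_to_genes.items():
            if len(genes) == 0:
                raise ValueError(f"probe {probe} maps to no gene")
        unmapped = set(self.intensities.index) - set(self.probe_to_genes)
        if unmapped:
            raise ValueError(f"probes without gene mapping: {sorted(unmapped)[:5]}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.intensities.index

    def subset(self, probes: Sequence[str]) -> "ProbeLayer":
        probes = list(probes)
        return ProbeLayer(
            intensities=self.intensities.loc[probes],
            present_calls=self.present_calls.loc[probes],
            probe_to_genes={p: self.probe_to_genes[p] for p in probes},
        )
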