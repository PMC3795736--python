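"""Readers and writers for the pipeline's plain-text formats.

Expression TSV: genes as rows, samples as columns, header row of sample ids,
first column the gene id.  Labels TSV: ``sample_id<TAB>phenotype``.  GMT:
``name<TAB>description<TAB>gene...`` per line (MSigDB/BioCarta dialect).
Probe map TSV: ``probe_id<TAB>gene_id``, one row per mapping.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import (
    LAYER_INTENSITY,
    PHENOTYPES,
    ExpressionMatrix,
    GeneSetCollection,
    PhenotypeLabels,
    ProbeLayer,
)


def read_expression_tsv(path: str | Path, layer: str = LAYER_INTENSITY) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return ExpressionMatrix(df, layer=layer)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


def read_labels_tsv(path: str | Path, universe: tuple[str, ...] = PHENOTYPES) -> PhenotypeLabels:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "phenotype"])
    return PhenotypeLabels(pd.Series(df["phenotype"].values, index=df["sample_id"].values), universe=universe)


def write_labels_tsv(labels: PhenotypeLabels, path: str | Path) -> None:
    labels.labels.to_csv(path, sep="\t", header=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line[:80]!r}")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_probe_layer(
    intensities_path: str | Path, calls_path: str | Path, map_path: str | Path
) -> ProbeLayer:
    intens = pd.read_csv(intensities_path, sep="\t", index_col=0)
    calls = pd.read_csv(calls_path, sep="\t", index_col=0).astype(bool)
    intens.index.name = calls.index.name = None
    pmap = pd.read_csv(map_path, sep="\t", header=None, names=["probe_id", "gene_id"])
    probe_to_genes: dict[str, tuple[str, ...]] = {}
    for probe, group in pmap.groupby("probe_id", sort=False):
        probe_to_genes[str(probe)] = tuple(group["gene_id"])
    return ProbeLayer(intens, calls, probe_to_genes)


def write_probe_layer(layer: ProbeLayer, out_dir: str | Path, prefix: str = "probes") -> dict[str, Path]:
    out_dir = Path(out_dir)
    paths = {
        "intensities": out_dir / f"{prefix}_intensities.tsv",
        "calls": out_dir / f"{prefix}_calls.tsv",
        "map": out_dir / f"{prefix}_map.tsv",
    }
    layer.intensities.to_csv(paths["intensities"], sep="\t", index_label="probe_id")
    layer.present_calls.astype(int).to_csv(paths["calls"], sep="\t", index_label="probe_id")
    with open(paths["map"], "w") as fh:
        for probe, genes in layer.probe_to_genes.items():
            for gene in genes:
                fh.write(f"{probe}\t{gene}\n")
    return paths


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
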