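"""End-to-end orchestration: simulate -> preprocess -> conserve -> diffreg ->
classify -> monotonic -> report, from a single config and seed.

Every stochastic stage draws a named substream of the one top-level seed, so
a rerun with the same config reproduces bit-identical outputs, recorded in a
manifest of per-file checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classify as _classify
from . import dirac as _dirac
from . import io as _io
from . import monotonic as _monotonic
from . import preprocess as _preprocess
from .containers import GRADE_STEP, PHENOTYPES, PhenotypeLabels, logger
from .simulate import SimConfig, generate_cohort, generate_networks

__version__ = "0.1.0"

#: comparisons run by default: each adjacent grade pair (lower, higher)
DEFAULT_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("Normal", "G2"),
    ("G2", "G3"),
    ("G3", "pGBM"),
    ("G3", "sGBM"),
)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    simulate: SimConfig = field(default_factory=SimConfig)
    comparisons: list[tuple[str, str]] = field(default_factory=lambda: [list(c) for c in DEFAULT_COMPARISONS])
    one_vs_rest_targets: list[str] = field(default_factory=list)
    n_perm: int = 1000
    alpha: float = 0.05
    diffreg_alpha: float = 0.01
    n_rep: int = 1000
    subsample_frac: float = 0.8
    min_support: int | None = None
    top_k: int = 10
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "preprocess", "conserve", "diffreg", "classify", "monotonic", "report"]
    )
    seed: int = 0

    def validate(self) -> None:
        known = set(PHENOTYPES)
        for pair in self.comparisons:
            if len(pair) != 2:
                raise ValueError(f"comparison must be a pair: {pair}")
            for p in pair:
                if p not in known:
                    raise ValueError(f"comparison references unknown phenotype {p!r}")
            for p in pair:
                if self.simulate.samples_per_phenotype.get(p, 0) < 2:
                    raise ValueError(f"comparison phenotype {p!r} has <2 samples in the simulated cohort")
        for p in self.one_vs_rest_targets:
            if p not in known:
                raise ValueError(f"one-vs-rest target references unknown phenotype {p!r}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not (0 < self.subsample_frac <= 1):
            raise ValueError("subsample_frac must be in (0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulate"] = self.simulate.to_dict()
        d["comparisons"] = [list(c) for c in self.comparisons]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulate" in d:
            d["simulate"] = SimConfig.from_dict(d["simulate"])
        if "comparisons" in d:
            d["comparisons"] = [tuple(c) for c in d["comparisons"]]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunManifest:
    """Provenance of one pipeline run: config hash, checksums, timings."""

    config_hash: str
    seed: int
    version: str
    checksums: dict[str, str]
    timings_s: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()


def run_all(config: RunConfig, out_dir: str | Path) -> RunManifest:
    """Run every configured stage, writing outputs and a manifest to out_dir."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    stages = list(config.stages)
    seed = config.seed
    sim = dataclasses.replace(config.simulate, seed=seed)

    def timed(name):
        class _T:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)

            def __exit__(self_inner, *exc):
                timings[name] = time.perf_counter() - self_inner.t0
                logger.info("stage %s: done in %.1fs", name, timings[name])

        return _T()

    # --- simulate -----------------------------------------------------------
    with timed("simulate"):
        networks = generate_networks(sim)
        matrix, labels, probes, truth = generate_cohort(sim, networks)
        _io.write_expression_tsv(matrix, out / "expression_intensity.tsv")
        _io.write_labels_tsv(labels, out / "labels.tsv")
        _io.write_gmt(networks, out / "networks.gmt")
        truth.to_json(out / "truth.json")
        _io.write_probe_layer(probes, out)

    # --- preprocess ---------------------------------------------------------
    with timed("preprocess"):
        rank_matrix = _preprocess.preprocess_probe_layer(probes, labels)
        _io.write_expression_tsv(rank_matrix, out / "expression_rank.tsv")
        qc = {
            "mean_sample_correlation_intensity": _preprocess.mean_sample_correlation(matrix),
            "mean_sample_correlation_rank": _preprocess.mean_sample_correlation(rank_matrix),
            "n_genes": rank_matrix.n_genes,
            "n_samples": rank_matrix.n_samples,
        }
        _io.write_json(qc, out / "preprocess_qc.json")

    results: dict[str, object] = {}

    # --- conserve -----------------------------------------------------------
    if "conserve" in stages:
        with timed("conserve"):
            table = _dirac.conservation_table(rank_matrix, labels, networks)
            table.indices.to_csv(out / "conservation.tsv", sep="\t", index_label="network")
            merged = _dirac.conservation_table(rank_matrix, labels, networks, merge_gbm=True)
            merged.indices.to_csv(out / "conservation_merged_gbm.tsv", sep="\t", index_label="network")
            f, p = _dirac.anova_conservation(merged)
            tmat = _dirac.pairwise_t_tests(merged)
            tmat.to_csv(out / "pairwise_t.tsv", sep="\t")
            global_means = {ph: _dirac.global_dysregulation(merged, ph) for ph in merged.phenotypes}
            _io.write_json(
                {"global_mean_conservation": global_means, "anova_F": f, "anova_p": p},
                out / "global_conservation.json",
            )
            results["conserve"] = global_means

    # --- diffreg ------------------------------------------------------------
    if "diffreg" in stages:
        with timed("diffreg"):
            direction_tests = {}
            for a, b in config.comparisons:
                res = _dirac.differential_regulation(
                    rank_matrix, labels, networks, a, b,
                    n_perm=config.n_perm, seed=seed, alpha=config.diffreg_alpha,
                )
                res.table.to_csv(out / f"diffreg_{a}_vs_{b}.tsv", sep="\t")
                sig = res.significant()
                # dysregulated in the higher grade <=> more conserved in the lower
                higher_is_b = GRADE_STEP[b] >= GRADE_STEP[a]
                k = int((sig["delta"] > 0).sum()) if higher_is_b else int((sig["delta"] < 0).sum())
                entry = {"n_significant": int(len(sig)), "n_more_dysreg_in_higher": k}
                if len(sig) > 0:
                    entry["binomial_p"] = _dirac.binomial_direction_test(len(sig), k)
                direction_tests[f"{a}_vs_{b}"] = entry
            _io.write_json(direction_tests, out / "diffreg_direction_tests.json")

    # --- classify -----------------------------------------------------------
    if "classify" in stages:
        with timed("classify"):
            for a, b in config.comparisons:
                sig = _classify.classification_significance(
                    rank_matrix, labels, networks, a, b, n_perm=config.n_perm, seed=seed
                )
                rows = []
                for name in sig.head(config.top_k).index:
                    cv = _classify.loocv(rank_matrix, labels, name, networks, a, b)
                    rows.append({"network": name, "loocv_accuracy": cv.accuracy,
                                 "loocv_sensitivity": cv.sensitivity, "loocv_specificity": cv.specificity})
                sig = sig.join(pd.DataFrame(rows).set_index("network"))
                sig.to_csv(out / f"classify_{a}_vs_{b}.tsv", sep="\t")
            for target in config.one_vs_rest_targets:
                summary = _classify.one_vs_rest(
                    rank_matrix, labels, networks, target,
                    top_k=config.top_k, n_perm=config.n_perm, seed=seed,
                )
                summary.per_network.to_csv(out / f"classify_{target}_vs_rest.tsv", sep="\t")

    # --- monotonic ----------------------------------------------------------
    if "monotonic" in stages:
        with timed("monotonic"):
            report = _monotonic.monotonic_pipeline(
                rank_matrix, labels, alpha=config.alpha, n_rep=config.n_rep,
                frac=config.subsample_frac, min_support=config.min_support,
                n_perm=config.n_perm, seed=seed,
            )
            report.table.to_csv(out / "monotonic_genes.tsv", sep="\t")
            _io.write_json(
                {
                    "n_increasing": len(report.genes(_monotonic.INCREASING)),
                    "n_decreasing": len(report.genes(_monotonic.DECREASING)),
                    "directionality_p": report.directionality_p,
                    "n_rep": report.n_rep,
                    "min_support": report.min_support,
                },
                out / "monotonic_summary.json",
            )

    # --- report -------------------------------------------------------------
    if "report" in stages:
        with timed("report"):
            write_report(out)

    checksums = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config_hash=_config_hash(config), seed=seed, version=__version__,
        checksums=checksums, timings_s={k: round(v, 3) for k, v in timings.items()},
    )
    manifest.to_json(out / "manifest.json")
    return manifest


def write_report(out_dir: str | Path) -> Path:
    """Assemble one human-readable summary from whatever stage outputs exist.

    Missing stages are flagged explicitly rather than silently omitted.
    """
    out = Path(out_dir)
    lines: list[str] = ["# Astrocytoma rank-conservation analysis report", ""]

    def section(title: str) -> None:
        lines.extend([f"## {title}", ""])

    section("Global network conservation")
    gc = out / "global_conservation.json"
    if gc.exists():
        data = _io.read_json(gc)
        for ph, v in data["global_mean_conservation"].items():
            lines.append(f"- mean conservation index, {ph}: {v:.4f}")
        lines.append(f"- one-way ANOVA across phenotypes: F = {data['anova_F']:.3f}, p = {data['anova_p']:.3g}")
        tmat = out / "pairwise_t.tsv"
        if tmat.exists():
            lines.append("- pairwise paired-t p-values: see pairwise_t.tsv")
    else:
        lines.append("- SKIPPED (conserve stage not run)")
    lines.append("")

    section("Differentially regulated networks")
    dr = sorted(out.glob("diffreg_*_vs_*.tsv"))
    if dr:
        for path in dr:
            df = pd.read_csv(path, sep="\t", index_col=0)
            top = df.head(5)
            lines.append(f"- {path.stem.removeprefix('diffreg_')}: top |delta| networks:")
            for name, row in top.iterrows():
                lines.append(
                    f"    - {name}: delta = {row['delta']:+.3f} ({row['direction']}), p = {row['p']:.3g}"
                )
        dt = out / "diffreg_direction_tests.json"
        if dt.exists():
            for comp, entry in _io.read_json(dt).items():
                msg = (f"- {comp}: {entry['n_more_dysreg_in_higher']}/{entry['n_significant']} "
                       "significant networks more dysregulated in the higher grade")
                if "binomial_p" in entry:
                    msg += f" (binomial p = {entry['binomial_p']:.3g})"
                lines.append(msg)
    else:
        lines.append("- SKIPPED (diffreg stage not run)")
    lines.append("")

    section("Monotonically changing genes")
    ms = out / "monotonic_summary.json"
    if ms.exists():
        data = _io.read_json(ms)
        lines.append(f"- increasing genes: {data['n_increasing']}")
        lines.append(f"- decreasing genes: {data['n_decreasing']}")
        for direction, p in (data.get("directionality_p") or {}).items():
            lines.append(f"- directionality p ({direction}): {p:.3g}")
    else:
        lines.append("- SKIPPED (monotonic stage not run)")
    lines.append("")

    section("Classification")
    cl = sorted(out.glob("classify_*.tsv"))
    if cl:
        for path in cl:
            df = pd.read_csv(path, sep="\t", index_col=0)
            best = df.iloc[0]
            lines.append(
                f"- {path.stem.removeprefix('classify_')}: best network {df.index[0]} "
                f"(apparent accuracy {best['accuracy']:.3f}"
                + (f", p = {best['p']:.3g}" if "p" in df.columns else "")
                + ")"
            )
    else:
        lines.append("- SKIPPED (classify stage not run)")
    lines.append("")

    section("Preprocessing QC")
    qc = out / "preprocess_qc.json"
    if qc.exists():
        data = _io.read_json(qc)
        lines.append(f"- genes x samples after preprocessing: {data['n_genes']} x {data['n_samples']}")
        lines.append(f"- mean sample-to-sample correlation (intensity layer): "
                     f"{data['mean_sample_correlation_intensity']:.3f}")
        lines.append(f"- mean sample-to-sample correlation (rank layer): "
                     f"{data['mean_sample_correlation_rank']:.3f}")
    else:
        lines.append("- SKIPPED (preprocess stage not run)")
    lines.append("")

    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path
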