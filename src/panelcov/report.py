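"""Orchestration of the full panel-coverage audit.

This module wires the library stages together against the on-disk
input contract (two BED annotation databases, a genome FASTA, and a
manifest of per-sample depth tables grouped by capture kit) and writes
every result table as TSV with a JSON mirror.  The CLI in
:mod:`panelcov.cli` is a thin shell over these functions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import __version__
from .annotations import AnnotationDB, build_db, enforce_nesting, representation_table
from .coverage_stats import (
    capture_fraction,
    count_flags,
    coverage_curve,
    gene_summaries,
    intersample_variability,
)
from .depth import (
    DepthTrack,
    SampleDepthMatrix,
    build_matrix,
    mean_track,
    read_depth_table,
    read_manifest,
)
from .gc_regression import build_features, extremes_gc_test, fit_ols
from .intervals import IntervalSet, read_bed

logger = logging.getLogger(__name__)

TSV_FLOAT = "%.6g"
VARIABILITY_BOUNDS = (1.0, 2.0, 5.0, 10.0, 20.0)


class AuditConfigError(ValueError):
    """The audit configuration is invalid (missing path, bad threshold)."""


@dataclass
class AuditConfig:
    superset_bed: Path
    subset_bed: Path
    fasta: Path
    manifest: Path
    out_dir: Path
    min_depth: float = 3.0
    optimal_depth: float = 30.0
    ci_bound: float = 5.0
    extremes_k: int = 5
    max_curve_depth: int = 200
    iqr_rule: str = "box_above"

    @classmethod
    def from_yaml(cls, path: Union[str, Path], out_dir: Optional[Union[str, Path]] = None) -> "AuditConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        paths = raw.get("paths", {})
        thresholds = raw.get("thresholds", {})
        missing = {"superset_bed", "subset_bed", "fasta", "manifest"} - set(paths)
        if missing:
            raise AuditConfigError(f"{path}: missing paths {sorted(missing)}")
        base = path.parent
        cfg = cls(
            superset_bed=(base / paths["superset_bed"]).resolve(),
            subset_bed=(base / paths["subset_bed"]).resolve(),
            fasta=(base / paths["fasta"]).resolve(),
            manifest=(base / paths["manifest"]).resolve(),
            out_dir=Path(out_dir) if out_dir is not None else (base / raw.get("out_dir", "audit_out")),
            min_depth=float(thresholds.get("min_depth", 3)),
            optimal_depth=float(thresholds.get("optimal_depth", 30)),
            ci_bound=float(thresholds.get("ci_bound", 5)),
            extremes_k=int(thresholds.get("extremes_k", 5)),
            max_curve_depth=int(thresholds.get("max_curve_depth", 200)),
            iqr_rule=str(raw.get("iqr_rule", "box_above")),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.min_depth < self.optimal_depth:
            raise AuditConfigError("min_depth must be below optimal_depth")
        if self.max_curve_depth < self.optimal_depth:
            raise AuditConfigError("max_curve_depth must reach at least optimal_depth")
        if self.extremes_k < 1:
            raise AuditConfigError("extremes_k must be >= 1")
        if self.iqr_rule not in {"box_above", "span"}:
            raise AuditConfigError(f"unknown iqr_rule {self.iqr_rule!r}")
        for name in ("superset_bed", "subset_bed", "fasta", "manifest"):
            p = getattr(self, name)
            if not Path(p).is_file():
                raise AuditConfigError(f"{name} not readable: {p}")

    def digest(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in dataclasses.asdict(self).items()}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class AuditInputs:
    subset_db: AnnotationDB
    superset_db: AnnotationDB
    subset_targets: IntervalSet
    superset_targets: IntervalSet
    manifest: pd.DataFrame


def load_inputs(cfg: AuditConfig) -> AuditInputs:
    superset_db = build_db(read_bed(cfg.superset_bed), "superset")
    subset_db = enforce_nesting(build_db(read_bed(cfg.subset_bed), "subset"), superset_db)
    return AuditInputs(
        subset_db=subset_db,
        superset_db=superset_db,
        subset_targets=subset_db.pooled_regions(),
        superset_targets=superset_db.pooled_regions(),
        manifest=read_manifest(cfg.manifest),
    )


def _write_table(df: pd.DataFrame, stem: Path) -> None:
    df.to_csv(stem.with_suffix(".tsv"), sep="\t", index=False, float_format=TSV_FLOAT)
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump(json.loads(df.to_json(orient="records", double_precision=15)), fh, indent=1)


def run_represent(cfg: AuditConfig, inputs: Optional[AuditInputs] = None) -> pd.DataFrame:
    """Representation table of the subset inside the superset database."""
    inputs = inputs or load_inputs(cfg)
    table = representation_table(inputs.subset_db, inputs.superset_db, ensure_nested=False)
    table = table.assign(percent=(100.0 * table["fraction"]).round(2))
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    _write_table(table, cfg.out_dir / "representation")
    return table


@dataclass
class KitCoverage:
    kit: str
    n_samples: int
    track: DepthTrack
    matrix: SampleDepthMatrix
    observed_mean_depth: float
    capture: dict[str, dict[str, float]]  # db -> {"min": ..., "optimal": ...}
    curves: dict[str, pd.DataFrame]
    summaries: list
    flags: tuple[int, int]
    variability: pd.DataFrame


def _kit_coverage(cfg: AuditConfig, inputs: AuditInputs, kit: str, rows: pd.DataFrame) -> KitCoverage:
    frames = {r["sample"]: read_depth_table(r["file"]) for _, r in rows.iterrows()}
    matrix = build_matrix(frames, inputs.superset_targets, sample_ids=list(frames))
    track = mean_track(matrix)

    curves: dict[str, pd.DataFrame] = {}
    capture: dict[str, dict[str, float]] = {}
    for db_name, targets in (("subset", inputs.subset_targets), ("superset", inputs.superset_targets)):
        curve = coverage_curve(track, targets, max_depth=cfg.max_curve_depth)
        curves[db_name] = pd.DataFrame(
            {"threshold": curve.thresholds, "fraction_covered": curve.fraction_covered}
        )
        capture[db_name] = {
            "min": capture_fraction(track, targets, cfg.min_depth),
            "optimal": capture_fraction(track, targets, cfg.optimal_depth),
        }

    summaries = gene_summaries(
        track, inputs.subset_db, optimal_depth=cfg.optimal_depth, iqr_rule=cfg.iqr_rule
    )
    flags = count_flags(summaries)

    # "captured" bases for the variability profile and the observed mean
    # depth: subset bases any sample actually reported (mean > 0)
    sub_matrix = matrix.restrict(inputs.subset_targets)
    captured_rows = sub_matrix.depths.mean(axis=1) > 0
    observed = float(sub_matrix.depths[captured_rows].mean()) if captured_rows.any() else 0.0
    variability_rows = []
    if sub_matrix.n_samples >= 2 and captured_rows.any():
        profile = intersample_variability(
            SampleDepthMatrix(
                chroms=sub_matrix.chroms[captured_rows],
                positions=sub_matrix.positions[captured_rows],
                sample_ids=sub_matrix.sample_ids,
                depths=sub_matrix.depths[captured_rows],
            )
        )
        for k in sorted(set(VARIABILITY_BOUNDS) | {cfg.ci_bound}):
            frac = profile.fraction_within(k)
            variability_rows.append(
                {
                    "bound_k": k,
                    "n_bases_within": int(round(frac * profile.half_widths.size)),
                    "fraction_within": frac,
                }
            )
    return KitCoverage(
        kit=kit,
        n_samples=len(frames),
        track=track,
        matrix=matrix,
        observed_mean_depth=observed,
        capture=capture,
        curves=curves,
        summaries=summaries,
        flags=flags,
        variability=pd.DataFrame(
            variability_rows, columns=["bound_k", "n_bases_within", "fraction_within"]
        ),
    )


def run_coverage(cfg: AuditConfig, inputs: Optional[AuditInputs] = None) -> dict[str, KitCoverage]:
    """Per-kit curves, capture fractions, gene summaries and variability."""
    inputs = inputs or load_inputs(cfg)
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    results: dict[str, KitCoverage] = {}
    for kit, rows in inputs.manifest.groupby("kit", sort=True):
        logger.info("coverage: kit %s (%d samples)", kit, len(rows))
        kc = _kit_coverage(cfg, inputs, str(kit), rows)
        results[str(kit)] = kc
        # per-base mean track export (TSV only; too granular for a JSON mirror)
        pd.DataFrame(
            {
                "chrom": kc.track.chroms,
                "pos": kc.track.positions,
                "mean_depth": kc.track.mean_depth,
            }
        ).to_csv(
            cfg.out_dir / f"mean_track_{kit}.tsv", sep="\t", index=False, float_format=TSV_FLOAT
        )
        for db_name, curve_df in kc.curves.items():
            _write_table(curve_df, cfg.out_dir / f"curve_{kit}_{db_name}")
        summary_df = pd.DataFrame(
            [
                {
                    "gene": s.gene,
                    "n_bases": s.n_bases,
                    "q1": s.q1,
                    "median": s.median,
                    "q3": s.q3,
                    "median_below_optimal": s.median_below_optimal,
                    "iqr_above_optimal": s.iqr_above_optimal,
                }
                for s in kc.summaries
            ]
        )
        _write_table(summary_df, cfg.out_dir / f"gene_summary_{kit}")
        _write_table(kc.variability, cfg.out_dir / f"variability_{kit}")
    return results


def run_gc(
    cfg: AuditConfig,
    inputs: Optional[AuditInputs] = None,
    coverage: Optional[dict[str, KitCoverage]] = None,
) -> dict:
    """GC/size regressions on the kit with the highest observed depth.

    Mirrors the audited study's choice of analysing uniformity on the
    most deeply sequenced arm.
    """
    inputs = inputs or load_inputs(cfg)
    coverage = coverage or run_coverage(cfg, inputs)
    best_kit = max(coverage.values(), key=lambda kc: kc.observed_mean_depth)
    feats = build_features(inputs.subset_db, best_kit.summaries, cfg.fasta)
    if len(feats) < 3:
        raise AuditConfigError("too few genes with defined GC and coverage for regression")
    gc = [f.gc_fraction for f in feats]
    size = [float(f.size_bases) for f in feats]
    med = [f.median_coverage for f in feats]
    gc_fit = fit_ols(gc, med)
    size_fit = fit_ols(size, med)
    extremes = extremes_gc_test(feats, k=cfg.extremes_k)
    result = {
        "kit": best_kit.kit,
        "n_genes": len(feats),
        "gc_regression": dataclasses.asdict(gc_fit),
        "size_regression": dataclasses.asdict(size_fit),
        "extremes_gc": dataclasses.asdict(extremes),
    }
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    feat_df = pd.DataFrame(
        [
            {
                "gene": f.gene,
                "size_bases": f.size_bases,
                "gc_percent": 100.0 * f.gc_fraction,
                "median_coverage": f.median_coverage,
            }
            for f in feats
        ]
    )
    _write_table(feat_df, cfg.out_dir / "gene_features")
    with open(cfg.out_dir / "regressions.json", "w") as fh:
        json.dump(result, fh, indent=1)
    return result


def run_report(cfg: AuditConfig) -> dict:
    """Run every stage and write the combined machine-readable report."""
    logger.info("panelcov %s | config %s", __version__, cfg.digest())
    inputs = load_inputs(cfg)
    stage = "representation"
    try:
        rep = run_represent(cfg, inputs)
        stage = "coverage"
        coverage = run_coverage(cfg, inputs)
        stage = "gc"
        gc = run_gc(cfg, inputs, coverage)
    except Exception as exc:
        raise RuntimeError(f"audit stage {stage!r} failed: {exc}") from exc
    overall = rep[rep["gene"] == "ALL"].iloc[0]
    report = {
        "version": __version__,
        "config_digest": cfg.digest(),
        "thresholds": {
            "min_depth": cfg.min_depth,
            "optimal_depth": cfg.optimal_depth,
            "ci_bound": cfg.ci_bound,
        },
        "representation": {
            "n_genes": int((rep["gene"] != "ALL").sum()),
            "subset_bases": int(overall["subset_bases"]),
            "superset_bases": int(overall["superset_bases"]),
            "overall_percent": float(100.0 * overall["fraction"]),
            "table": "representation.tsv",
        },
        "kits": {
            kit: {
                "n_samples": kc.n_samples,
                "observed_mean_depth": kc.observed_mean_depth,
                "capture_min_subset": kc.capture["subset"]["min"],
                "capture_min_superset": kc.capture["superset"]["min"],
                "capture_optimal_subset": kc.capture["subset"]["optimal"],
                "capture_optimal_superset": kc.capture["superset"]["optimal"],
                "n_genes_median_below_optimal": kc.flags[0],
                "n_genes_iqr_above_optimal": kc.flags[1],
                "fraction_within_ci_bound": (
                    float(
                        kc.variability.loc[
                            kc.variability["bound_k"] == cfg.ci_bound, "fraction_within"
                        ].iloc[0]
                    )
                    if len(kc.variability)
                    else None
                ),
                "tables": [
                    f"curve_{kit}_subset.tsv",
                    f"curve_{kit}_superset.tsv",
                    f"gene_summary_{kit}.tsv",
                    f"variability_{kit}.tsv",
                ],
            }
            for kit, kc in coverage.items()
        },
        "gc": {**gc, "tables": ["gene_features.tsv", "regressions.json"]},
    }
    with open(cfg.out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    _write_text_report(report, cfg.out_dir / "report.txt")
    return report


def _write_text_report(report: dict, path: Path) -> None:
    lines = [
        f"panelcov {report['version']} coverage audit (config {report['config_digest']})",
        "",
        f"Representation: {report['representation']['subset_bases']} of "
        f"{report['representation']['superset_bases']} superset bases in subset "
        f"({report['representation']['overall_percent']:.1f}%)",
        "",
    ]
    for kit, kc in report["kits"].items():
        lines.append(
            f"{kit}: n={kc['n_samples']}, observed depth {kc['observed_mean_depth']:.1f}X; "
            f"capture at {report['thresholds']['min_depth']:g}X "
            f"subset {100 * kc['capture_min_subset']:.1f}% / "
            f"superset {100 * kc['capture_min_superset']:.1f}%; "
            f"{kc['n_genes_median_below_optimal']} genes median < "
            f"{report['thresholds']['optimal_depth']:g}X, "
            f"{kc['n_genes_iqr_above_optimal']} genes IQR flag"
        )
    gc = report["gc"]
    lines += [
        "",
        f"GC regression ({gc['kit']}, n={gc['n_genes']}): slope "
        f"{gc['gc_regression']['slope']:.4g}, r2 {gc['gc_regression']['r_squared']:.3f}, "
        f"p {gc['gc_regression']['p_value']:.3g}",
        f"Size regression: r2 {gc['size_regression']['r_squared']:.3f}, "
        f"p {gc['size_regression']['p_value']:.3g}",
        f"Top-{len(gc['extremes_gc']['top_genes'])} vs bottom GC: "
        f"{100 * gc['extremes_gc']['top_mean_gc']:.1f}% vs "
        f"{100 * gc['extremes_gc']['bottom_mean_gc']:.1f}% "
        f"(p {gc['extremes_gc']['p_value']:.3g})",
        "",
    ]
    path.write_text("\n".join(lines))
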