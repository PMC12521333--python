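"""Pipeline orchestration: simulate -> normalize -> measure -> summarize -> stats.

Each stage reads only the previous stage's declared outputs from the run
directory and writes its own, so stages can be run separately (CLI
subcommands) or end-to-end (:func:`run_pipeline`).  A manifest records the
configuration, the master seed, per-stage row counts and a content hash of
every output file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as cio
from .datatypes import measurements_to_frame
from .normalize import NormalizeConfig, normalize_radiograph
from .phantom import CohortSpec, generate_cohort
from .segments import measure_image
from .stats import standard_comparisons
from .summary import gradient_table, group_segment_means, summarize_cohort

log = logging.getLogger("cxraer")


@dataclass
class PipelineConfig:
    out_dir: Path
    cohort: CohortSpec = field(default_factory=CohortSpec)
    normalize: NormalizeConfig = field(default_factory=NormalizeConfig)
    seed: int = 0
    write_images: bool = True
    write_normalized: bool = False  # float TIFFs are large; opt-in

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        self.cohort.master_seed = self.seed


def simulate_stage(cfg: PipelineConfig):
    """Generate the cohort; write raw PNGs + annotation/truth JSON + tables."""
    result = generate_cohort(cfg.cohort, render_images=True)
    raw_dir = cfg.out_dir / "raw"
    if cfg.write_images:
        for b in result.bundles:
            cio.write_bundle(b, raw_dir)
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    result.clinical.to_csv(cfg.out_dir / "clinical.csv", index=False)
    result.patients.to_csv(cfg.out_dir / "patients.csv", index=False)
    log.info("simulate: %d patients, %d clinical rows", len(result.patients), len(result.clinical))
    return result


def normalize_and_measure(cfg: PipelineConfig, bundles) -> pd.DataFrame:
    """Normalize every bundle and measure its 12 segments.

    Returns the long-format measurement frame and writes measurements.csv
    plus provenance.csv (per-image reference level and size factor).
    """
    measurements = []
    provenance = []
    for b in bundles:
        norm = normalize_radiograph(b.image, b.annotations, cfg.normalize)
        if cfg.write_normalized:
            ndir = cfg.out_dir / "normalized"
            ndir.mkdir(parents=True, exist_ok=True)
            cio.write_normalized_tiff(norm.pixels, ndir / f"{norm.image_id}.tif")
        provenance.append(
            {
                "image_id": norm.image_id,
                "reference_level": norm.reference_level,
                "size_factor": norm.size_factor,
                "interpolation": norm.interpolation,
            }
        )
        measurements.extend(measure_image(norm))
    frame = measurements_to_frame(measurements)
    frame.to_csv(cfg.out_dir / "measurements.csv", index=False)
    pd.DataFrame(provenance).to_csv(cfg.out_dir / "provenance.csv", index=False)
    log.info("measure: %d segment records from %d images", len(frame), len(bundles))
    return frame


def summarize_stage(cfg: PipelineConfig, measurements: pd.DataFrame, patients: pd.DataFrame):
    summaries = summarize_cohort(measurements)
    summaries.to_csv(cfg.out_dir / "lung_summaries.csv", index=False)
    groups = patients.set_index("patient_id")["group"]
    cells = []
    for grp, sub in measurements.merge(
        patients[["patient_id", "group"]], left_on="image_id", right_on="patient_id"
    ).groupby("group"):
        for metric in ("mpi", "fhpi"):
            c = group_segment_means(sub, metric=metric)
            c.insert(0, "group", grp)
            c.insert(1, "metric", metric)
            cells.append(c)
    pd.concat(cells, ignore_index=True).to_csv(cfg.out_dir / "segment_means.csv", index=False)
    grads = pd.concat(
        [gradient_table(measurements, groups, metric=m) for m in ("mpi", "fhpi")],
        ignore_index=True,
    )
    grads.to_csv(cfg.out_dir / "gradients.csv", index=False)
    log.info("summarize: %d lung summaries, %d gradient fits", len(summaries), len(grads))
    return summaries, grads


def stats_stage(cfg: PipelineConfig, summaries, measurements, clinical, patients) -> pd.DataFrame:
    report = standard_comparisons(summaries, measurements, clinical, patients)
    report.to_csv(cfg.out_dir / "stats_report.csv", index=False)
    lines = ["Statistical report", "=" * 60]
    for _, r in report.iterrows():
        lines.append(
            f"{r['comparison']}: {r['method']} stat={r['statistic']:.4g} p={r['p']:.4g}"
        )
    (cfg.out_dir / "stats_report.txt").write_text("\n".join(lines) + "\n")
    log.info("stats: %d comparisons", len(report))
    return report


def write_manifest(cfg: PipelineConfig) -> None:
    files = sorted(p for p in cfg.out_dir.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "cxraer_version": __version__,
        "seed": cfg.seed,
        "config": {
            "target_level": cfg.normalize.target_level,
            "canvas": [cfg.normalize.canvas_w, cfg.normalize.canvas_h],
            "interpolation": cfg.normalize.interpolation,
            "n_patients": {k: g.n for k, g in cfg.cohort.groups.items()},
        },
        "outputs": {
            str(p.relative_to(cfg.out_dir)): cio.sha256_of(p) for p in files
        },
    }
    (cfg.out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run all stages; returns the run directory."""
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    result = simulate_stage(cfg)
    measurements = normalize_and_measure(cfg, result.bundles)
    summaries, _ = summarize_stage(cfg, measurements, result.patients)
    stats_stage(cfg, summaries, measurements, result.clinical, result.patients)
    write_manifest(cfg)
    return cfg.out_dir
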