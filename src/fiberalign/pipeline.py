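"""The four pipeline stages: simulate, orient, stats, compare.

Each stage is a plain function over a :class:`~fiberalign.config.RunConfig`
and directories, so the command-line interface and the analysis drivers
stay thin.  Every stage serializes the config it ran with into its output
directory and funnels all randomness through named seeds, making two runs
from one config byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import compare as cmp
from . import orientation as ori
from . import stats as st
from . import synthetic as syn
from .config import RunConfig

__all__ = ["run_simulate", "run_orient", "run_stats", "run_compare", "run_all"]

log = logging.getLogger("fiberalign")


def _template(cfg: RunConfig) -> syn.SyntheticSpec:
    s = cfg.simulate
    return syn.SyntheticSpec(
        width=s.width,
        height=s.height,
        layout="confluent",
        coverage_fraction=1.0,
        n_cells=s.n_cells,
        fibers_per_cell=s.fibers_per_cell,
        fiber_length_px=(s.fiber_length_mean_px, s.fiber_length_sd_px),
        fiber_width_px=s.fiber_width_px,
        fiber_intensity=s.fiber_intensity,
        background_level=s.background_level,
        noise_sd=s.noise_sd,
    )


def _sparse_template(cfg: RunConfig) -> syn.SyntheticSpec:
    # generate_experiment switches layout per condition; coverage for sparse
    # comes from the template's sparse_coverage via min(.., 0.10)
    return _template(cfg)


def run_simulate(cfg: RunConfig, out_dir: str | Path, base_seed: int | None = None) -> pd.DataFrame:
    """Render the full synthetic experiment and write images + manifest."""
    s = cfg.simulate
    seed = s.base_seed if base_seed is None else base_seed
    design = syn.default_design(
        cell_type=s.cell_type,
        durations=s.durations_h,
        n_replicates=s.n_replicates,
        shear_dyn_cm2=s.shear_dyn_cm2,
    )
    out_dir = Path(out_dir)
    manifest = syn.generate_experiment(
        design, _template(cfg), seed, out_dir, mu=s.mu, sparse_coverage=s.sparse_coverage
    )
    cfg.to_yaml(out_dir / "config.yaml")
    log.info("simulate: %d images -> %s (base_seed=%d)", len(manifest), out_dir, seed)
    return manifest


def run_orient(cfg: RunConfig, data_dir: str | Path, out_dir: str | Path) -> pd.DataFrame:
    """Estimate orientations for every manifest row; one CSV per image.

    Rows whose mask comes out empty are flagged in the log table and get a
    zero-length CSV; the run continues.
    """
    o = cfg.orient
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(data_dir / "manifest.csv")
    log_rows = []
    for _, row in manifest.iterrows():
        img = tifffile.imread(data_dir / row["file"]).astype(np.float64)
        mic = ori.Micrograph(img, flow_dir_deg=0.0, image_id=row["file"])
        fld = ori.structure_tensor_field(mic, o.sigma_grad, o.sigma_window)
        mask = ori.fiber_mask(mic, fld, o.intensity_quantile, o.coherence_min)
        csv_path = out_dir / (Path(row["file"]).stem + ".orient.csv")
        if mask.provenance["empty"]:
            pd.DataFrame(columns=["angle_deg", "weight"]).to_csv(csv_path, index=False)
            log_rows.append({"file": row["file"], "n_pixels": 0, "flagged_empty": True})
            continue
        sample = ori.extract_orientation_sample(
            fld, mask, weighting=o.weighting, flow_dir_deg=mic.flow_dir_deg,
            source=row["file"],
        )
        pd.DataFrame({"angle_deg": sample.angles, "weight": sample.weights}).to_csv(
            csv_path, index=False, float_format="%.6f"
        )
        log_rows.append(
            {"file": row["file"], "n_pixels": int(mask.provenance["n_pixels"]),
             "flagged_empty": False}
        )
    occupancy = pd.DataFrame(log_rows)
    occupancy.to_csv(out_dir / "orient_log.csv", index=False)
    cfg.to_yaml(out_dir / "config.yaml")
    return occupancy


def run_stats(cfg: RunConfig, data_dir: str | Path, orient_dir: str | Path,
              out_dir: str | Path) -> pd.DataFrame:
    """Rose histograms (JSON) and the tidy percent-aligned table (CSV)."""
    data_dir, orient_dir, out_dir = Path(data_dir), Path(orient_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(data_dir / "manifest.csv")
    tidy_rows = []
    for _, row in manifest.iterrows():
        stem = Path(row["file"]).stem
        df = pd.read_csv(orient_dir / f"{stem}.orient.csv")
        cond = syn.ConditionLabel(
            cell_type=row["cell_type"], density=row["density"],
            exposure=row["exposure"], duration_h=row["duration_h"],
            shear_dyn_cm2=row["shear_dyn_cm2"], replicate=int(row["replicate"]),
        )
        if df.empty:
            continue
        sample = ori.OrientationSample(
            df["angle_deg"].to_numpy(), df["weight"].to_numpy(),
            flow_dir_deg=0.0, source=row["file"],
        )
        rose = st.rose_histogram(sample, cfg.stats.bin_width_deg, condition=cond)
        (out_dir / f"{stem}.rose.json").write_text(json.dumps(rose.to_dict(), indent=1))
        res = st.percent_aligned(sample, cfg.stats.threshold_deg)
        tidy_rows.append(
            {
                "file": row["file"], "cell_type": cond.cell_type,
                "density": cond.density, "level": cond.level,
                "duration_h": cond.duration_h, "replicate": cond.replicate,
                "percent_aligned": res.percent_aligned,
                "n_effective": res.n_effective, "kish_ess": res.kish_ess,
            }
        )
    tidy = pd.DataFrame(tidy_rows)
    tidy.to_csv(out_dir / "percent_aligned.csv", index=False, float_format="%.6f")
    cfg.to_yaml(out_dir / "config.yaml")
    return tidy


def run_compare(cfg: RunConfig, tidy: pd.DataFrame | str | Path,
                out_dir: str | Path, make_plot: bool = True):
    """Two-way ANOVA + Sidak post-hoc on the tidy table; writes CSVs and a
    box-plot summary (25-75th percentile box, median line, min-max whiskers)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not isinstance(tidy, pd.DataFrame):
        tidy = pd.read_csv(tidy)
    anova = cmp.two_way_anova(tidy, anova_type=cfg.compare.anova_type)
    posthoc = cmp.compare_to_static(
        tidy, anova, star_thresholds=[tuple(t) for t in cfg.compare.star_thresholds],
        family=cfg.compare.family,
    )
    anova.table.to_csv(out_dir / "anova.csv")
    posthoc.contrasts.to_csv(out_dir / "posthoc.csv", index=False, float_format="%.6g")
    if make_plot:
        from .plots import alignment_boxplot

        alignment_boxplot(tidy, out_dir / "percent_aligned_box.png")
    cfg.to_yaml(out_dir / "config.yaml")
    return anova, posthoc


def run_all(cfg: RunConfig, work_dir: str | Path, base_seed: int | None = None):
    """Convenience end-to-end run: simulate -> orient -> stats -> compare."""
    work = Path(work_dir)
    run_simulate(cfg, work / "images", base_seed=base_seed)
    run_orient(cfg, work / "images", work / "orient")
    tidy = run_stats(cfg, work / "images", work / "orient", work / "stats")
    return run_compare(cfg, tidy, work / "compare")
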