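"""End-to-end orchestration: synthetic cohorts through analysis to genotype
effect tables.

The in-memory round-trip helpers here (render → segment → index-correct →
mixed model) are the library core behind the ``danioeye`` CLI and the
reproduction script; the CLI subcommands only add file I/O around them.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from danioeye import synthkit
from danioeye.config import PipelineConfig
from danioeye.iop import aggregate_iop_csv
from danioeye.oct_biometry import (
    RefractiveIndexSet,
    SegmentationError,
    compute_biometry,
)
from danioeye.okr_analysis import AngleTrace, analyze_okr
from danioeye.refraction import RefractionCalibration, measure_refraction
from danioeye.stats_mixed import fit_cs_mixed, p_to_stars
from danioeye.synthkit import CohortSpec, OctRenderConfig
from danioeye.volume import OctVolume

log = logging.getLogger(__name__)

BIOMETRY_METRICS = [
    "axial_length",
    "corneal_thickness",
    "acd",
    "lens_diameter",
    "vcd",
    "retinal_thickness",
    "rpe_thickness",
    "eye_volume",
]


def simulate_biometry_cohort(
    preset_names: list[str],
    n_fish_per_genotype: int = 10,
    seed: int | np.random.SeedSequence = 0,
    oct_cfg: OctRenderConfig | None = None,
    indices: RefractiveIndexSet | None = None,
    band: int = 10,
) -> pd.DataFrame:
    """Render and re-measure a full OCT cohort in memory.

    For every eye of every fish the ground-truth geometry is drawn,
    rendered as an OCT volume, segmented and index-corrected; the returned
    table holds one row per eye with the measured biometry alongside cohort
    metadata (and the ground-truth axial components prefixed ``true_``).
    """
    oct_cfg = oct_cfg or OctRenderConfig()
    indices = indices or RefractiveIndexSet()
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    cohort_seed, render_root = ss.spawn(2)
    spec = CohortSpec.from_presets(
        preset_names, n_fish_per_genotype=n_fish_per_genotype,
        seed=cohort_seed.generate_state(1)[0] % (2**31),
    )
    truth = synthkit.sample_cohort_geometries(spec)
    render_seeds = render_root.spawn(len(truth))
    rows = []
    for (_, row), rseed in zip(truth.iterrows(), render_seeds):
        geom = synthkit.geometry_from_row(row)
        vol = synthkit.render_oct_volume(geom, oct_cfg, indices, rseed)
        record = compute_biometry(vol, indices, band=band)
        rows.append(
            {
                "fish_id": row.fish_id,
                "eye": row.eye,
                "genotype": row.genotype,
                "age_label": row.age_label,
                "body_length": row.body_length,
                **{m: getattr(record, m) for m in BIOMETRY_METRICS},
                "qc_flags": ";".join(record.qc_flags),
                **{f"true_{c}": row[c] for c in synthkit.AXIAL_COMPONENTS},
            }
        )
    return pd.DataFrame(rows)


def simulate_refraction_cohort(
    preset_names: list[str],
    n_fish_per_genotype: int = 10,
    frames_per_eye: int = 100,
    seed: int | np.random.SeedSequence = 0,
    calibration: RefractionCalibration | None = None,
    between_fish_sd_d: float = 0.5,
    between_eye_sd_d: float = 0.25,
    frame_noise_sd: float = 0.02,
) -> pd.DataFrame:
    """Render pupil-frame cohorts and re-measure refraction per eye.

    Each eye's true refraction is its genotype preset plus fish- and
    eye-level noise; the diopter value is encoded as a brightness slope via
    the inverse calibration, rendered into ``frames_per_eye`` noisy frames,
    and recovered with :func:`danioeye.refraction.measure_refraction`.
    """
    calibration = calibration or RefractionCalibration(gain=60.0, offset=0.0)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    presets = {p.rsplit("_", 1)[0]: p for p in preset_names}
    rows = []
    geno_seeds = ss.spawn(len(presets))
    for (genotype, preset), gseed in zip(sorted(presets.items()), geno_seeds):
        mean_d = synthkit.refraction_preset(preset)
        rng = np.random.default_rng(gseed)
        frame_seeds = iter(gseed.spawn(n_fish_per_genotype * 2 * frames_per_eye))
        for i in range(n_fish_per_genotype):
            fish_offset = rng.normal(0.0, between_fish_sd_d)
            for eye in ("L", "R"):
                true_d = mean_d + fish_offset + rng.normal(0.0, between_eye_sd_d)
                slope = (true_d - calibration.offset) / calibration.gain
                frames = [
                    synthkit.render_pupil_frame(
                        slope, noise_sd=frame_noise_sd, rng_seed=next(frame_seeds)
                    )
                    for _ in range(frames_per_eye)
                ]
                result = measure_refraction(frames, calibration)
                rows.append(
                    {
                        "fish_id": f"{genotype}_f{i:02d}",
                        "eye": eye,
                        "genotype": genotype,
                        "mean_diopters": result.mean_diopters,
                        "sd_diopters": result.sd_diopters,
                        "n_measurements": result.n_measurements,
                        "true_diopters": true_d,
                    }
                )
    return pd.DataFrame(rows)


def effect_table(
    measurements: pd.DataFrame,
    metrics: list[str],
    reference: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit the compound-symmetry mixed model per metric and per mutant
    genotype; one row per (metric, genotype) with effect, SE, p and stars."""
    rows = []
    genotypes = [g for g in sorted(measurements["genotype"].unique()) if g != reference]
    for metric in metrics:
        for genotype in genotypes:
            sub = measurements[measurements["genotype"].isin([reference, genotype])]
            try:
                fit = fit_cs_mixed(sub, metric, reference, genotype=genotype)
            except (ValueError, KeyError) as exc:
                log.warning("skipping %s/%s: %s", metric, genotype, exc)
                continue
            rows.append(
                {
                    "metric": metric,
                    "genotype": genotype,
                    "reference": reference,
                    "effect_size": fit.effect_size,
                    "se": fit.se,
                    "p_value": fit.p_value,
                    "stars": p_to_stars(fit.p_value),
                    "significant": fit.p_value < alpha,
                    "sigma_fish_sq": fit.sigma_fish_sq,
                    "sigma_eye_sq": fit.sigma_eye_sq,
                    "icc": fit.icc,
                    "n_fish": fit.n_fish,
                    "n_eyes": fit.n_eyes,
                }
            )
    return pd.DataFrame(rows)


def process_cohort_dir(cohort_dir: str | Path, config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run every available assay on an on-disk cohort (as written by
    :func:`danioeye.synthkit.make_cohort`) and return the per-assay tables."""
    import json

    cohort_dir = Path(cohort_dir)
    manifest_path = cohort_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {cohort_dir}")
    manifest = json.loads(manifest_path.read_text())
    missing = [
        e[key]
        for e in manifest["eyes"]
        for key in ("oct", "iop")
        if key in e and not (cohort_dir / e[key]).exists()
    ]
    if missing:
        raise FileNotFoundError(f"cohort files missing: {missing[:5]}...")

    indices = config.indices()
    out: dict[str, pd.DataFrame] = {}

    bio_rows = []
    for entry in manifest["eyes"]:
        if "oct" not in entry:
            continue
        vol = OctVolume.load(cohort_dir / entry["oct"])
        try:
            record = compute_biometry(vol, indices, band=config.segmentation_band)
        except SegmentationError as exc:
            log.warning("segmentation failed for %s: %s", entry["eye_id"], exc)
            continue
        bio_rows.append(
            {
                "eye_id": entry["eye_id"],
                "fish_id": entry["fish_id"],
                "eye": entry["eye"],
                "genotype": entry["genotype"],
                **{m: getattr(record, m) for m in BIOMETRY_METRICS},
                "qc_flags": ";".join(record.qc_flags),
            }
        )
    if bio_rows:
        out["biometry"] = pd.DataFrame(bio_rows)

    calib = (
        RefractionCalibration.from_json(config.calibration_path)
        if config.calibration_path
        else RefractionCalibration(
            gain=manifest.get("refraction_calibration", {}).get("gain", config.calibration_gain),
            offset=manifest.get("refraction_calibration", {}).get("offset", config.calibration_offset),
        )
    )
    import imageio.v3 as iio

    refr_rows = []
    for entry in manifest["eyes"]:
        names = entry.get("pupil_frames")
        if not names:
            continue
        frames = [iio.imread(cohort_dir / name).astype(float) / 65535.0 for name in names]
        result = measure_refraction(frames, calib)
        refr_rows.append(
            {
                "eye_id": entry["eye_id"],
                "fish_id": entry["fish_id"],
                "eye": entry["eye"],
                "genotype": entry["genotype"],
                "mean_diopters": result.mean_diopters,
                "sd_diopters": result.sd_diopters,
                "n_measurements": result.n_measurements,
            }
        )
    if refr_rows:
        out["refraction"] = pd.DataFrame(refr_rows)

    iop_rows = []
    for entry in manifest["eyes"]:
        if "iop" not in entry:
            continue
        table = aggregate_iop_csv(cohort_dir / entry["iop"], config.iop_expected_readings)
        table["fish_id"] = entry["fish_id"]
        table["genotype"] = entry["genotype"]
        iop_rows.append(table)
    if iop_rows:
        out["iop"] = pd.concat(iop_rows, ignore_index=True)

    okr_rows = []
    for entry in manifest.get("fish", []):
        if "okr" not in entry:
            continue
        trace = AngleTrace.from_csv(
            cohort_dir / entry["okr"],
            stimulus={
                "drum_velocity": config.drum_velocity,
                "spatial_frequency": config.spatial_frequency,
                "direction": "cw",
            },
        )
        result = analyze_okr(
            trace,
            velocity_threshold=config.saccade_velocity_threshold,
            r2_min=config.slow_phase_r2_min,
            etm_window_s=config.etm_window_s,
        )
        okr_rows.append(
            {
                "fish_id": entry["fish_id"],
                "genotype": entry["genotype"],
                "gain_tn": result.gain_tn,
                "gain_nt": result.gain_nt,
                "mean_etm_per_15s": float(np.mean(result.etm_per_15s)),
                "n_segments": result.n_segments,
                "no_response": result.no_response,
            }
        )
    if okr_rows:
        out["okr"] = pd.DataFrame(okr_rows)

    return out


def run_pipeline(cohort_dir: str | Path, config: PipelineConfig, out_dir: str | Path) -> dict:
    """Process a cohort directory end to end and write the per-assay CSVs
    plus the genotype effect table.  Deterministic given the cohort."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = process_cohort_dir(cohort_dir, config)
    if not tables:
        raise FileNotFoundError(f"no assay data found in {cohort_dir}")
    for name, table in tables.items():
        table.to_csv(out_dir / f"{name}.csv", index=False)
    report: dict = {"assays": sorted(tables)}
    if "biometry" in tables:
        meta = pd.read_csv(Path(cohort_dir) / "metadata.csv")
        merged = tables["biometry"].merge(
            meta[["fish_id", "eye", "body_length"]], on=["fish_id", "eye"], how="left"
        )
        effects = effect_table(
            merged,
            [m for m in BIOMETRY_METRICS if m != "eye_volume"],
            config.reference_genotype,
            alpha=config.alpha,
        )
        effects.to_csv(out_dir / "effects_biometry.csv", index=False)
        report["effects_biometry"] = len(effects)
    if "refraction" in tables:
        effects = effect_table(
            tables["refraction"], ["mean_diopters"], config.reference_genotype,
            alpha=config.alpha,
        )
        effects.to_csv(out_dir / "effects_refraction.csv", index=False)
        report["effects_refraction"] = len(effects)
    return report
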