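"""Seeded synthetic raw data for all four ocular assays.

The generator is the ground-truth side of every round-trip test in this
package: it renders OCT volumes, infrared pupil frames, optokinetic
eye-angle traces and tonometer reading lists from known parameters, so the
analysis modules can be validated without animal data.

Genotype presets
----------------
Registered presets (``wt``, ``prss56``, ``fbn1`` at 2/4/6 months
post-fertilization, e.g. ``"prss56_6mpf"``) encode the wild-type baselines
and the per-component mutant effect sizes of the reference phenotyping
study.  Only the WT retinal thickness values (152/137/126 µm at 2/4/6 mpf)
and the mutant-minus-WT differences are anchored measurements; the remaining
WT absolute baselines are plausible adult-zebrafish constants and only
differences should be asserted against published numbers.

For the ``prss56`` presets the per-component differences do not sum exactly
to the published axial-length effects (−157/−260/−330 µm); the small
residuals (−3/+4/+1 µm) are absorbed into the VCD delta so the preset axial
difference equals the published axial effect, axial length being the
headline endpoint.

Noise model
-----------
Between-fish and between-eye variability are shared ocular-scale factors:
each fish draws one relative size factor (SD such that axial length varies
by ``between_fish_sd_um``, default 10 µm), each eye another (default 4 µm on
axial length), and every axial component of that eye is scaled by
``1 + fish + eye``.  This mimics overall eye-size variation in size-matched
cohorts and gives each component an SD proportional to its magnitude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from danioeye.oct_biometry import RefractiveIndexSet
from danioeye.okr_analysis import AngleTrace
from danioeye.volume import OctVolume

AXIAL_COMPONENTS = (
    "corneal_thickness",
    "acd",
    "lens_diameter",
    "vcd",
    "retinal_thickness",
    "rpe_thickness",
)


@dataclass(frozen=True)
class EyeGeometrySpec:
    """Ground-truth geometric eye dimensions in µm."""

    corneal_thickness: float
    acd: float
    lens_diameter: float
    vcd: float
    retinal_thickness: float
    rpe_thickness: float
    equatorial_diameter_x: float
    equatorial_diameter_y: float

    def __post_init__(self) -> None:
        if self.acd < 0:
            raise ValueError("acd must be >= 0")
        for name in (
            "corneal_thickness",
            "lens_diameter",
            "vcd",
            "retinal_thickness",
            "rpe_thickness",
            "equatorial_diameter_x",
            "equatorial_diameter_y",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def axial_length(self) -> float:
        """Implied axial length: sum of the six axial components."""
        return float(sum(getattr(self, c) for c in AXIAL_COMPONENTS))

    def axial_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in AXIAL_COMPONENTS}

    def scaled(self, factor: float) -> "EyeGeometrySpec":
        """All dimensions multiplied by ``factor`` (ocular-scale noise)."""
        return EyeGeometrySpec(
            **{k: v * factor for k, v in self.axial_dict().items()},
            equatorial_diameter_x=self.equatorial_diameter_x * factor,
            equatorial_diameter_y=self.equatorial_diameter_y * factor,
        )


# WT baselines per age (mpf).  Retinal thickness values are the published WT
# means; the rest are plausible adult-zebrafish constants (documented, not
# measurements).
_WT_BASE = {
    2: EyeGeometrySpec(25.0, 30.0, 550.0, 420.0, 152.0, 12.0, 1250.0, 1250.0),
    4: EyeGeometrySpec(28.0, 30.0, 650.0, 500.0, 137.0, 12.0, 1400.0, 1400.0),
    6: EyeGeometrySpec(30.0, 30.0, 720.0, 550.0, 126.0, 12.0, 1500.0, 1500.0),
}

# Mutant-minus-WT per-component effect sizes (µm) by age; components absent
# here were not significantly altered (delta 0).  prss56 VCD deltas carry the
# residual so the implied axial delta equals the published axial effect
# (−157/−260/−330 µm at 2/4/6 mpf).
_PRSS56_DELTAS = {
    2: {"lens_diameter": -32.0, "vcd": -135.0, "retinal_thickness": 7.0, "rpe_thickness": 3.0},
    4: {"acd": -7.0, "lens_diameter": -34.0, "vcd": -233.0, "retinal_thickness": 19.0, "rpe_thickness": -5.0},
    6: {"corneal_thickness": 5.0, "acd": -6.0, "lens_diameter": -73.0, "vcd": -288.0, "retinal_thickness": 32.0},
}
_FBN1_DELTAS = {
    2: {"acd": 3.0},
    4: {"acd": 11.0},
    6: {"acd": 27.0, "vcd": -51.0, "retinal_thickness": 10.0},
}

# Mean photorefraction (diopters).  WT baseline is a plausible positive value
# (small-eye artifact bias); fbn1 presets add the published hyperopic shifts
# (+8 D at 4 mpf, +12 D at 6 mpf).  prss56 eyes were not measurable by
# photorefraction and have no preset.
_REFRACTION_PRESETS = {
    "wt_2mpf": 5.0,
    "wt_4mpf": 5.0,
    "wt_6mpf": 5.0,
    "fbn1_2mpf": 5.0,
    "fbn1_4mpf": 13.0,
    "fbn1_6mpf": 17.0,
}

# OKR presets: slow-phase velocity (deg/s) under the standard 20 deg/s drum,
# saccade interval (s), and number of non-responding fish out of 10.
_OKR_PRESETS = {
    "wt_6mpf": {"slow_phase_velocity": 18.0, "saccade_interval": 1.5, "n_nonresponders": 0},
    "prss56_6mpf": {"slow_phase_velocity": 12.0, "saccade_interval": 3.0, "n_nonresponders": 3},
    "fbn1_6mpf": {"slow_phase_velocity": 18.0, "saccade_interval": 2.5, "n_nonresponders": 0},
}

# Mean IOP (mmHg): WT plausible baseline, mutants elevated.
_IOP_PRESETS = {"wt": 11.0, "prss56": 15.5, "fbn1": 15.0}

# Mean standard body length (mm) by age; genotypes are size-matched by
# design, so all genotypes share the same mean.
_BODY_LENGTH_MM = {2: 22.0, 4: 26.0, 6: 30.0}


def _build_presets() -> dict[str, EyeGeometrySpec]:
    presets: dict[str, EyeGeometrySpec] = {}
    for age, wt in _WT_BASE.items():
        presets[f"wt_{age}mpf"] = wt
        for genotype, table in (("prss56", _PRSS56_DELTAS), ("fbn1", _FBN1_DELTAS)):
            deltas = table[age]
            fields = {c: getattr(wt, c) + deltas.get(c, 0.0) for c in AXIAL_COMPONENTS}
            # equatorial size follows the axial change (cosmetic: only the
            # en-face volume estimate sees it)
            scale = sum(fields.values()) / wt.axial_length
            presets[f"{genotype}_{age}mpf"] = EyeGeometrySpec(
                **fields,
                equatorial_diameter_x=wt.equatorial_diameter_x * scale,
                equatorial_diameter_y=wt.equatorial_diameter_y * scale,
            )
    return presets


PRESETS: dict[str, EyeGeometrySpec] = _build_presets()


def make_eye_geometry(preset_name: str, rng_seed: int | None = None) -> EyeGeometrySpec:
    """Return the mean eye geometry of a registered genotype/age preset.

    ``rng_seed`` is accepted for API symmetry with the other generators but
    unused: presets are deterministic means.
    """
    del rng_seed
    try:
        return PRESETS[preset_name]
    except KeyError:
        known = ", ".join(sorted(PRESETS))
        raise KeyError(f"unknown preset {preset_name!r}; known presets: {known}") from None


def refraction_preset(preset_name: str) -> float:
    """Mean photorefraction (diopters) for a genotype/age preset."""
    try:
        return _REFRACTION_PRESETS[preset_name]
    except KeyError:
        known = ", ".join(sorted(_REFRACTION_PRESETS))
        raise KeyError(
            f"no refraction preset {preset_name!r} (prss56 eyes are not measurable "
            f"by photorefraction); known presets: {known}"
        ) from None


def okr_preset(preset_name: str) -> dict:
    try:
        return dict(_OKR_PRESETS[preset_name])
    except KeyError:
        known = ", ".join(sorted(_OKR_PRESETS))
        raise KeyError(f"unknown OKR preset {preset_name!r}; known presets: {known}") from None


def iop_preset(genotype: str) -> float:
    try:
        return _IOP_PRESETS[genotype]
    except KeyError:
        known = ", ".join(sorted(_IOP_PRESETS))
        raise KeyError(f"unknown IOP preset {genotype!r}; known presets: {known}") from None


# ---------------------------------------------------------------------------
# OCT rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OctRenderConfig:
    """Rendering parameters for synthetic OCT volumes.

    Defaults cover a 1.7 × 1.7 × 2.2 mm field of view at 2 µm optical-path
    pitch in z and 12 µm lateral pitch.  ``curvature_radius_um`` bends the
    interfaces into shallow concentric caps (a common axial sag for all
    interfaces, cosmetic only — thicknesses along any A-scan are preserved).
    """

    z_pitch: float = 2.0
    lateral_pitch: float = 12.0
    volume_shape: tuple[int, int, int] = (1100, 142, 142)  # (z, y, x)
    interface_brightness: float = 4000.0
    interior_brightness: float = 200.0
    background: float = 100.0
    speckle_sd: float = 150.0
    interface_sigma_um: float = 2.5
    curvature_radius_um: float = 4000.0
    z_offset_um: float = 60.0

    def __post_init__(self) -> None:
        if self.z_pitch <= 0 or self.lateral_pitch <= 0:
            raise ValueError("pixel pitches must be positive")


def render_oct_volume(
    geom: EyeGeometrySpec,
    cfg: OctRenderConfig | None = None,
    indices: RefractiveIndexSet | None = None,
    rng_seed: int | np.random.SeedSequence = 0,
) -> OctVolume:
    """Render a synthetic OCT volume of one eye.

    The volume is the forward model of the biometry analysis: along the
    central axis the optical-path position of interface *k* is the cumulative
    sum of geometric thickness × refractive index over the compartments
    anterior to *k* (plus a fixed anterior offset).  Interfaces are Gaussian
    bright bands with sub-pixel centres, the globe interior is a dim
    ellipsoid, and additive speckle-like noise with SD ``cfg.speckle_sd`` is
    applied when nonzero.
    """
    cfg = cfg or OctRenderConfig()
    indices = indices or RefractiveIndexSet()
    rng = np.random.default_rng(rng_seed)

    optical = np.array(list(geom.axial_dict().values())) * np.asarray(indices.compartment_order)
    z_bounds = cfg.z_offset_um + np.concatenate([[0.0], np.cumsum(optical)])  # 7 positions

    nz, ny, nx = cfg.volume_shape
    depth = nz * cfg.z_pitch
    sigma = cfg.interface_sigma_um
    if z_bounds[-1] + 4 * sigma > depth:
        raise ValueError(
            f"eye optical depth {z_bounds[-1]:.0f} µm exceeds volume depth {depth:.0f} µm"
        )

    yy = (np.arange(ny) - (ny - 1) / 2.0) * cfg.lateral_pitch
    xx = (np.arange(nx) - (nx - 1) / 2.0) * cfg.lateral_pitch
    r2 = yy[:, None] ** 2 + xx[None, :] ** 2  # geometric µm², lateral

    vol = np.full(cfg.volume_shape, cfg.background, dtype=np.float32)

    # dim globe interior: ellipsoid spanning the axial extent in optical space
    zc = 0.5 * (z_bounds[0] + z_bounds[-1])
    az = 0.5 * (z_bounds[-1] - z_bounds[0])
    ax_ = geom.equatorial_diameter_x / 2.0
    ay = geom.equatorial_diameter_y / 2.0
    z_centers = ((np.arange(nz) + 0.5) * cfg.z_pitch).astype(np.float32)
    lateral_frac = ((xx[None, :] / ax_) ** 2 + (yy[:, None] / ay) ** 2).astype(np.float32)
    z_frac = ((z_centers - zc) / az) ** 2
    inside = lateral_frac[None] <= (1.0 - z_frac)[:, None, None]
    vol[inside] = cfg.interior_brightness

    # curved interface bands, common sag for all interfaces
    sag = (r2 / (2.0 * cfg.curvature_radius_um)).astype(np.float32)
    lat_mask = r2 <= (0.8 * min(ax_, ay)) ** 2
    sag_masked = np.where(lat_mask, sag, np.inf).astype(np.float32)
    sag_max = float(sag[lat_mask].max()) if lat_mask.any() else 0.0
    inv_two_sigma_sq = np.float32(1.0 / (2.0 * sigma**2))
    for zb in z_bounds:
        k0 = max(0, int((zb - 5 * sigma) / cfg.z_pitch))
        k1 = min(nz, int(np.ceil((zb + sag_max + 5 * sigma) / cfg.z_pitch)) + 1)
        zwin = z_centers[k0:k1]
        dz = zwin[:, None, None] - (np.float32(zb) + sag_masked[None])
        vol[k0:k1] += cfg.interface_brightness * np.exp(-(dz * dz) * inv_two_sigma_sq)

    if cfg.speckle_sd > 0:
        noise = rng.standard_normal(vol.shape, dtype=np.float32)
        noise *= cfg.speckle_sd
        vol += noise
        np.clip(vol, 0.0, None, out=vol)

    return OctVolume(
        data=vol,
        z_pitch=cfg.z_pitch,
        lateral_pitch=cfg.lateral_pitch,
        meta={"ground_truth_axial_um": geom.axial_dict(), "z_offset_um": cfg.z_offset_um},
    )


# ---------------------------------------------------------------------------
# Pupil frames (eccentric photorefraction forward model)
# ---------------------------------------------------------------------------

def render_pupil_frame(
    slope: float,
    pupil_center: tuple[float, float] = (64.0, 64.0),
    pupil_radius: float = 24.0,
    noise_sd: float = 0.0,
    rng_seed: int | np.random.SeedSequence = 0,
    shape: tuple[int, int] = (128, 128),
    background: float = 0.08,
    mean_brightness: float = 0.5,
) -> np.ndarray:
    """Render an infrared pupil image with a linear vertical brightness ramp.

    Inside the pupil disk the intensity is
    ``mean_brightness + slope * (row - cy) / pupil_radius`` — a positive
    slope makes the bottom of the pupil brighter (image rows increase
    downward); a negative slope inverts the ramp (top brighter).  This is
    the forward model of the eccentric-photorefraction brightness gradient.
    """
    if pupil_radius < 5:
        raise ValueError("pupil_radius must be >= 5 pixels")
    cy, cx = pupil_center
    h, w = shape
    if not (pupil_radius <= cy <= h - pupil_radius and pupil_radius <= cx <= w - pupil_radius):
        raise ValueError("pupil must fit inside the frame")
    rng = np.random.default_rng(rng_seed)
    yy, xx = np.mgrid[0:h, 0:w]
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= pupil_radius**2
    img = np.full(shape, background, dtype=np.float64)
    img[disk] = mean_brightness + slope * (yy[disk] - cy) / pupil_radius
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=shape)
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# OKR traces and dorsal-view fish frames
# ---------------------------------------------------------------------------

def synth_okr_trace(
    slow_phase_velocity: float,
    saccade_interval: float = 1.0,
    saccade_amplitude: float | None = None,
    duration: float = 60.0,
    sample_rate: float = 50.0,
    noise_sd: float = 0.3,
    rng_seed: int | np.random.SeedSequence = 0,
    drum_velocity: float = 20.0,
    spatial_frequency: float = 0.15,
    direction: str = "cw",
) -> AngleTrace:
    """Synthesize a sawtooth optokinetic eye-angle trace.

    The eye drifts at ``slow_phase_velocity`` (deg/s, sign = stimulus
    direction) and is reset every ``saccade_interval`` seconds by an
    instantaneous saccade of ``saccade_amplitude`` degrees in the opposite
    direction (default: exactly the accumulated drift, giving a bounded
    sawtooth).  Independent Gaussian angle noise is added per eye.  A zero
    slow-phase velocity yields a flat trace with no saccades.
    """
    if sample_rate < 25:
        raise ValueError("sample_rate must be >= 25 Hz")
    if duration < 30:
        raise ValueError("duration must be >= 30 s")
    if saccade_interval <= 2.0 / sample_rate:
        raise ValueError("saccade_interval must exceed two sample periods")
    rng = np.random.default_rng(rng_seed)
    t = np.arange(int(round(duration * sample_rate))) / sample_rate
    if slow_phase_velocity == 0.0:
        clean = np.zeros_like(t)
    else:
        amp = (
            abs(slow_phase_velocity) * saccade_interval
            if saccade_amplitude is None
            else abs(saccade_amplitude)
        )
        n_resets = np.floor(t / saccade_interval)
        clean = slow_phase_velocity * t - np.sign(slow_phase_velocity) * amp * n_resets
    left = clean + rng.normal(0.0, noise_sd, size=t.shape) if noise_sd > 0 else clean.copy()
    right = clean + rng.normal(0.0, noise_sd, size=t.shape) if noise_sd > 0 else clean.copy()
    return AngleTrace(
        time=t,
        angle_left=left,
        angle_right=right,
        sample_rate=sample_rate,
        stimulus={
            "drum_velocity": drum_velocity,
            "spatial_frequency": spatial_frequency,
            "direction": direction,
        },
    )


def render_fish_frames(
    angles_deg: np.ndarray,
    shape: tuple[int, int] = (120, 160),
    centers: tuple[tuple[float, float], tuple[float, float]] = ((60.0, 55.0), (60.0, 105.0)),
    axes: tuple[float, float] = (16.0, 8.0),
    eye_level: float = 0.15,
    body_level: float = 0.85,
) -> np.ndarray:
    """Render dorsal-view frames with two dark elliptical eyes rotated by the
    given angles (deg, counter-clockwise with x right / y up; both eyes
    conjugate).  Returns an array of shape (n_frames, h, w)."""
    angles = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    frames = np.full((len(angles), h, w), body_level)
    a, b = axes
    for i, theta in enumerate(np.deg2rad(angles)):
        for cy, cx in centers:
            x = xx - cx
            y = cy - yy  # y up
            xr = x * np.cos(theta) + y * np.sin(theta)
            yr = -x * np.sin(theta) + y * np.cos(theta)
            mask = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
            frames[i][mask] = eye_level
    return frames


# ---------------------------------------------------------------------------
# IOP readings
# ---------------------------------------------------------------------------

def synth_iop_readings(
    true_iop: float,
    sd: float = 1.5,
    n: int = 6,
    rng_seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """``n`` noisy rebound-tonometer readings around ``true_iop`` (mmHg)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(rng_seed)
    return true_iop + rng.normal(0.0, sd, size=n) if sd > 0 else np.full(n, float(true_iop))


# ---------------------------------------------------------------------------
# Cohort sampling and on-disk cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Specification of a synthetic cohort: per-genotype mean geometries,
    two eyes per fish, shared-scale noise (see module docstring)."""

    n_fish_per_genotype: int = 10
    genotypes: dict[str, EyeGeometrySpec] = field(default_factory=dict)
    age_label: int = 6
    between_fish_sd_um: float = 10.0
    between_eye_sd_um: float = 4.0
    body_length_sd_mm: float = 0.2
    seed: int = 0

    @classmethod
    def from_presets(
        cls, preset_names: dict[str, str] | list[str], n_fish_per_genotype: int = 10,
        seed: int = 0, **kwargs,
    ) -> "CohortSpec":
        """Build a spec from registered preset names.  ``preset_names`` maps
        genotype label → preset name, or is a list of preset names whose
        genotype labels are the part before ``_<age>mpf``."""
        if isinstance(preset_names, list):
            preset_names = {p.rsplit("_", 1)[0]: p for p in preset_names}
        ages = {p.rsplit("_", 1)[1] for p in preset_names.values()}
        if len(ages) > 1:
            raise ValueError(f"presets span multiple ages: {sorted(ages)}")
        age = int(next(iter(ages)).removesuffix("mpf"))
        genos = {g: make_eye_geometry(p) for g, p in preset_names.items()}
        return cls(
            n_fish_per_genotype=n_fish_per_genotype,
            genotypes=genos,
            age_label=age,
            seed=seed,
            **kwargs,
        )


def sample_cohort_geometries(spec: CohortSpec) -> pd.DataFrame:
    """Draw per-eye ground-truth geometries for a cohort.

    Returns one row per eye with columns fish_id, eye (L/R), genotype,
    body_length_mm, scale_factor and the six axial components plus the two
    equatorial diameters.  Fully determined by ``spec.seed``.
    """
    if not spec.genotypes:
        raise ValueError("CohortSpec.genotypes is empty")
    rng = np.random.default_rng(spec.seed)
    base_bl = _BODY_LENGTH_MM.get(spec.age_label, 28.0)
    rows = []
    for genotype in sorted(spec.genotypes):
        mean = spec.genotypes[genotype]
        axial = mean.axial_length
        fish_rel_sd = spec.between_fish_sd_um / axial
        eye_rel_sd = spec.between_eye_sd_um / axial
        # body lengths are recentered on the common mean: cohorts are
        # size-matched by construction, as deliberate selection against the
        # reference group's mean length would produce
        body_lengths = rng.normal(base_bl, spec.body_length_sd_mm, spec.n_fish_per_genotype)
        body_lengths += base_bl - body_lengths.mean()
        for i in range(spec.n_fish_per_genotype):
            fish_id = f"{genotype}_f{i:02d}"
            fish_factor = rng.normal(0.0, fish_rel_sd)
            body_length = body_lengths[i]
            for eye in ("L", "R"):
                scale = 1.0 + fish_factor + rng.normal(0.0, eye_rel_sd)
                g = mean.scaled(scale)
                rows.append(
                    {
                        "fish_id": fish_id,
                        "eye": eye,
                        "genotype": genotype,
                        "age_label": spec.age_label,
                        "body_length": body_length,
                        "scale_factor": scale,
                        **g.axial_dict(),
                        "equatorial_diameter_x": g.equatorial_diameter_x,
                        "equatorial_diameter_y": g.equatorial_diameter_y,
                    }
                )
    return pd.DataFrame(rows)


def geometry_from_row(row: pd.Series | dict) -> EyeGeometrySpec:
    """Rebuild an :class:`EyeGeometrySpec` from a cohort-table row."""
    return EyeGeometrySpec(
        **{c: float(row[c]) for c in AXIAL_COMPONENTS},
        equatorial_diameter_x=float(row["equatorial_diameter_x"]),
        equatorial_diameter_y=float(row["equatorial_diameter_y"]),
    )


def make_cohort(
    spec: CohortSpec,
    out_dir: str | Path,
    oct_cfg: OctRenderConfig | None = None,
    indices: RefractiveIndexSet | None = None,
    write_oct: bool = True,
    write_pupil: bool = True,
    write_okr: bool = True,
    write_iop: bool = True,
    pupil_frames_per_eye: int = 10,
    refraction_calibration_gain: float = 60.0,
    refraction_calibration_offset: float = 0.0,
    okr_duration: float = 60.0,
) -> dict:
    """Write a full synthetic cohort to ``out_dir`` and return the manifest.

    Per eye: an OCT TIFF volume, pupil PNG frames and an IOP CSV; per fish an
    OKR trace CSV; plus ``metadata.csv`` (fish id, eye, genotype, body
    length) and ``manifest.json`` listing every file with its ground-truth
    parameters.  Byte-identical for identical ``spec.seed``.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"cohort directory {out_dir} is not writable: {exc}") from exc

    oct_cfg = oct_cfg or OctRenderConfig()
    indices = indices or RefractiveIndexSet()
    truth = sample_cohort_geometries(spec)
    ss = np.random.SeedSequence(spec.seed)

    def _seeds():
        while True:
            yield ss.spawn(1)[0]

    seed_iter = _seeds()

    age = spec.age_label
    manifest: dict = {
        "seed": spec.seed,
        "age_label": age,
        "genotypes": sorted(spec.genotypes),
        "n_fish_per_genotype": spec.n_fish_per_genotype,
        "refraction_calibration": {
            "gain": refraction_calibration_gain,
            "offset": refraction_calibration_offset,
        },
        "eyes": [],
        "fish": [],
    }

    for _, row in truth.iterrows():
        eye_id = f"{row.fish_id}_{row.eye}"
        entry: dict = {
            "eye_id": eye_id,
            "fish_id": row.fish_id,
            "eye": row.eye,
            "genotype": row.genotype,
            "truth": {c: float(row[c]) for c in AXIAL_COMPONENTS},
        }
        if write_oct:
            vol = render_oct_volume(geometry_from_row(row), oct_cfg, indices, next(seed_iter))
            tiff = out_dir / f"oct_{eye_id}.tiff"
            vol.save(tiff)
            entry["oct"] = tiff.name
        if write_pupil:
            preset = f"{row.genotype}_{age}mpf"
            if preset in _REFRACTION_PRESETS:
                rng = np.random.default_rng(next(seed_iter))
                true_d = (
                    _REFRACTION_PRESETS[preset]
                    + rng.normal(0.0, 0.5)  # between-fish, D
                    + rng.normal(0.0, 0.25)  # between-eye, D
                )
                slope = (true_d - refraction_calibration_offset) / refraction_calibration_gain
                names = []
                for j in range(pupil_frames_per_eye):
                    frame = render_pupil_frame(slope, noise_sd=0.02, rng_seed=next(seed_iter))
                    name = f"pupil_{eye_id}_{j:03d}.png"
                    iio.imwrite(
                        out_dir / name, (frame * 65535).astype(np.uint16)
                    )
                    names.append(name)
                entry["pupil_frames"] = names
                entry["true_diopters"] = float(true_d)
        if write_iop:
            rng = np.random.default_rng(next(seed_iter))
            true_iop = _IOP_PRESETS.get(row.genotype, 12.0) + rng.normal(0.0, 0.8)
            readings = synth_iop_readings(true_iop, sd=1.5, n=6, rng_seed=next(seed_iter))
            name = f"iop_{eye_id}.csv"
            pd.DataFrame({"eye_id": eye_id, "reading_mmhg": readings}).to_csv(
                out_dir / name, index=False
            )
            entry["iop"] = name
            entry["true_iop"] = float(true_iop)
        manifest["eyes"].append(entry)

    if write_okr:
        for genotype in sorted(spec.genotypes):
            preset_name = f"{genotype}_{age}mpf"
            okr = _OKR_PRESETS.get(preset_name, {"slow_phase_velocity": 18.0,
                                                 "saccade_interval": 1.5,
                                                 "n_nonresponders": 0})
            for i in range(spec.n_fish_per_genotype):
                fish_id = f"{genotype}_f{i:02d}"
                responder = i >= okr["n_nonresponders"]
                v = okr["slow_phase_velocity"] if responder else 0.0
                trace = synth_okr_trace(
                    v,
                    saccade_interval=okr["saccade_interval"],
                    duration=okr_duration,
                    rng_seed=next(seed_iter),
                )
                name = f"okr_{fish_id}.csv"
                trace.to_csv(out_dir / name)
                manifest["fish"].append(
                    {
                        "fish_id": fish_id,
                        "genotype": genotype,
                        "okr": name,
                        "true_slow_phase_velocity": v,
                        "true_saccade_interval": okr["saccade_interval"],
                        "responder": bool(responder),
                    }
                )

    meta_cols = ["fish_id", "eye", "genotype", "age_label", "body_length"]
    truth[meta_cols].to_csv(out_dir / "metadata.csv", index=False)
    truth.to_csv(out_dir / "ground_truth.csv", index=False)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
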