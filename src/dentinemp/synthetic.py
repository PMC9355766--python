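"""Synthetic dentine multiphoton image generator.

Longitudinal SHG/TPEF views of dentine show the peritubular sheaths as
quasi-parallel bright stripes.  This module renders that geometry together
with the intensity statistics the downstream analysis assumes:

* a stripe ("tubule") field with controllable period, orientation, duty
  cycle and smooth orientation jitter — :func:`generate_tubule_field`;
* co-registered TPEF/SHG channel pairs whose mean-intensity ratio is the
  dial that sets the INAG contrast — :func:`render_channel_pair`;
* three-polarization SHG stacks following the cylindrical-symmetry SHG
  response with a signed hyperpolarizability ratio ρ —
  :func:`render_polarimetric_stack`;
* whole cohorts whose per-specimen ground truths (peritubule width, INAG,
  ρ) lie on configurable age regression lines — :func:`generate_cohort`.

Ground truth is emitted alongside every render, so each analysis stage can
be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .images import MPImage, PolarimetricStack

#: Default per-region stripe orientations (degrees), cycled region by region.
#: Chosen away from the fiber angles (30°, 45°, 75° mod 90°) at which the
#: default three-polarization geometry becomes mirror-degenerate for ρ.
ORIENTATION_CYCLE = (0.0, 20.0, 60.0, 90.0, 150.0)

#: Age regression lines as printed for the real cohort: (slope, intercept).
WIDTH_LINE = (0.03, 3.47)    # µm/year, µm
INAG_LINE = (-0.003, -0.25)  # 1/year, dimensionless
RHO_LINE = (-0.02, -1.03)    # 1/year, dimensionless


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TubuleFieldParams:
    """Geometry of the synthetic peritubular stripe field.

    period_um
        Peak-to-peak stripe spacing — the "peritubule size" ground truth.
    orientation_deg
        Axial stripe direction, degrees CCW from the image row axis in
        [0, 180).
    jitter_deg
        Standard deviation of the smooth local-orientation perturbation.
    ridge_contrast
        1 − (valley floor / peak); 1 gives fully dark valleys.
    field_um, n_px
        Physical field width and pixels per side (180 µm, 512 px default).
    duty
        Fraction of each period occupied by the bright ridge.
    jitter_corr_um
        Correlation length of the jitter field.
    """

    period_um: float
    orientation_deg: float = 0.0
    jitter_deg: float = 0.0
    ridge_contrast: float = 0.9
    field_um: float = 180.0
    n_px: int = 512
    duty: float = 0.45
    jitter_corr_um: float = 7.0

    @property
    def pixel_size_um(self) -> float:
        return self.field_um / self.n_px

    def validate(self) -> None:
        nyquist = 2.0 * self.pixel_size_um
        if not self.period_um > nyquist:
            raise ValueError(
                f"period_um={self.period_um:g} µm is at/below the Nyquist limit "
                f"of {nyquist:g} µm for {self.n_px} px over {self.field_um:g} µm")
        if self.jitter_deg < 0:
            raise ValueError("jitter_deg must be >= 0")
        if not 0.0 < self.duty < 1.0:
            raise ValueError("duty must lie strictly between 0 and 1")
        if not 0.0 <= self.ridge_contrast <= 1.0:
            raise ValueError("ridge_contrast must lie in [0, 1]")
        if self.n_px < 8:
            raise ValueError("n_px too small")


@dataclass(frozen=True)
class ChannelRenderParams:
    """Detector model for one TPEF/SHG channel pair.

    The rendered SHG channel is the TPEF channel scaled by
    ``shg_tpef_ratio``, so the spatial mean-intensity ratio equals that
    parameter by construction (exactly when noiseless, in expectation
    otherwise).  Noise is Poisson photon noise at ``photon_gain`` counts
    per intensity unit plus Gaussian read noise, quantized to
    ``bit_depth`` bits; with ``photon_gain == 0`` and zero read noise the
    continuous intensities are returned unquantized.
    """

    tpef_mean: float = 2000.0
    shg_tpef_ratio: float = 0.57
    background: float = 0.10
    photon_gain: float = 0.0
    read_noise_sd: float = 0.0
    bit_depth: int = 16

    def validate(self) -> None:
        if not 0.0 < self.shg_tpef_ratio <= 1.0:
            raise ValueError("shg_tpef_ratio must lie in (0, 1]")
        if self.tpef_mean <= 0:
            raise ValueError("tpef_mean must be positive")
        if not 0.0 <= self.background < 1.0:
            raise ValueError("background must lie in [0, 1)")
        if self.photon_gain < 0 or self.read_noise_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError("bit_depth must be 8, 12 or 16")

    @property
    def noiseless(self) -> bool:
        return self.photon_gain == 0.0 and self.read_noise_sd == 0.0


@dataclass(frozen=True)
class PolarimetricRenderParams:
    """Forward model parameters for a three-polarization SHG stack.

    rho
        Signed hyperpolarizability ratio of the collagen response.
    angles_deg
        Incident linear polarization states; the default (0°, 90°, 60°)
        is two orthogonal states plus one oblique state.
    scale
        Overall intensity constant K.
    baseline
        Fraction of the stripe pattern replaced by a uniform floor, so
        inter-ridge pixels still carry signal (0 keeps the bare model).
    """

    rho: float
    angles_deg: tuple[float, float, float] = (0.0, 90.0, 60.0)
    scale: float = 1.0
    baseline: float = 0.0
    photon_gain: float = 0.0
    read_noise_sd: float = 0.0
    bit_depth: int = 16

    def validate(self) -> None:
        if not np.isfinite(self.rho):
            raise ValueError("rho must be finite")
        if len(self.angles_deg) != 3:
            raise ValueError("exactly three polarization states are required")
        a = np.mod(np.asarray(self.angles_deg, dtype=float), 180.0)
        if len({round(x, 6) for x in a}) != 3:
            raise ValueError("polarization states must be distinct")
        d = np.abs(a[:, None] - a[None, :])
        d = np.minimum(d, 180.0 - d)
        if not np.any(np.isclose(d, 90.0, atol=1e-6)):
            raise ValueError("the stack must contain two orthogonal states")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not 0.0 <= self.baseline < 1.0:
            raise ValueError("baseline must lie in [0, 1)")


# --------------------------------------------------------------------------
# forward models
# --------------------------------------------------------------------------

def shg_response(delta_deg: np.ndarray | float, rho: float) -> np.ndarray | float:
    """Polarization-resolved SHG response of a cylindrically symmetric fiber.

    For incident linear polarization at angle ``delta_deg`` from the fiber
    axis the emitted SHG intensity is proportional to

        sin²(2Δ) + [sin²Δ + ρ·cos²Δ]²

    which evaluates to ρ² along the fiber (Δ=0) and 1 across it (Δ=90°).
    """
    d = np.deg2rad(delta_deg)
    s2, c2 = np.sin(d) ** 2, np.cos(d) ** 2
    return np.sin(2.0 * d) ** 2 + (s2 + rho * c2) ** 2


def _stripe_profile(phase: np.ndarray, duty: float, ridge_contrast: float) -> np.ndarray:
    """Raised-cosine ridge train on unit-period phase; valleys at floor level."""
    floor = 1.0 - ridge_contrast
    t = np.mod(phase + 0.5, 1.0) - 0.5  # ridge centered at phase 0
    ridge = np.zeros_like(t)
    inside = np.abs(t) < duty / 2.0
    ridge[inside] = 0.5 * (1.0 + np.cos(2.0 * np.pi * t[inside] / duty))
    return floor + (1.0 - floor) * ridge


def generate_tubule_field(params: TubuleFieldParams, seed: int) -> np.ndarray:
    """Render a unit-amplitude stripe field in [0, 1].

    Orientation jitter is applied as a smooth random displacement of the
    stripe phase; its scale is calibrated so the pointwise tilt of the
    local stripe direction has standard deviation ``jitter_deg``.
    Deterministic for a fixed seed.
    """
    params.validate()
    n = params.n_px
    px = params.pixel_size_um
    theta = np.deg2rad(params.orientation_deg)
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    # coordinate along the stripe normal (µm); t̂=(cosθ, sinθ) in (col,row)
    u = (yy * np.cos(theta) - xx * np.sin(theta)) * px

    if params.jitter_deg > 0:
        rng = np.random.default_rng(seed)
        corr_px = max(params.jitter_corr_um / px, 1.0)
        g = gaussian_filter(rng.standard_normal((n, n)), corr_px, mode="wrap")
        # tilt angle ≈ d(displacement)/d(along-stripe coordinate); rescale the
        # smooth field so that derivative has the requested std
        gx = np.gradient(g, px, axis=1)
        gy = np.gradient(g, px, axis=0)
        d_along = gx * np.cos(theta) + gy * np.sin(theta)
        sd = float(np.std(d_along))
        if sd > 0:
            g *= np.deg2rad(params.jitter_deg) / sd
        u = u + g

    return _stripe_profile(u / params.period_um, params.duty, params.ridge_contrast)


def generate_patchwork_field(params: TubuleFieldParams, seed: int,
                             n_patches: int = 8) -> np.ndarray:
    """Tile stripe patches at independent uniform-random orientations.

    Emulates a structurally disorganized tissue: each of the
    ``n_patches × n_patches`` tiles is a stripe field at its own random
    orientation, so the pooled orientation distribution is uniform.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    n = params.n_px
    out = np.empty((n, n), dtype=float)
    edges = np.linspace(0, n, n_patches + 1).astype(int)
    sub_field_um = params.field_um / n_patches
    for i in range(n_patches):
        for j in range(n_patches):
            ori = rng.uniform(0.0, 180.0)
            h = edges[i + 1] - edges[i]
            w = edges[j + 1] - edges[j]
            sub = replace(params, orientation_deg=ori,
                          n_px=max(h, w), field_um=sub_field_um * max(h, w)
                          / (n / n_patches))
            tile = generate_tubule_field(sub, seed=int(rng.integers(2**31)))
            out[edges[i]:edges[i + 1], edges[j]:edges[j + 1]] = tile[:h, :w]
    return out


def _detect(intensity: np.ndarray, photon_gain: float, read_noise_sd: float,
            bit_depth: int, rng: np.random.Generator) -> np.ndarray:
    """Photon + read noise and quantization; identity when fully noiseless."""
    if photon_gain == 0.0 and read_noise_sd == 0.0:
        return intensity
    counts = intensity * photon_gain if photon_gain > 0 else intensity
    if photon_gain > 0:
        counts = rng.poisson(counts).astype(float)
    if read_noise_sd > 0:
        counts = counts + rng.normal(0.0, read_noise_sd, counts.shape)
    counts = np.clip(np.rint(counts), 0, 2**bit_depth - 1)
    return counts


def render_channel_pair(pattern: np.ndarray, params: ChannelRenderParams,
                        seed: int, pixel_size_um: float,
                        meta: dict | None = None) -> tuple[MPImage, MPImage]:
    """Render a co-registered (TPEF, SHG) pair from one stripe pattern.

    Both channels share the pattern's geometry; the SHG channel is the
    TPEF channel scaled by ``shg_tpef_ratio``, so the expected ratio of
    spatial means equals that parameter.
    """
    params.validate()
    pattern = np.asarray(pattern, dtype=float)
    if pattern.min() < 0 or pattern.max() > 1:
        raise ValueError("pattern must lie in [0, 1]")
    mean_p = pattern.mean()
    if mean_p == 0:
        structured = np.zeros_like(pattern)
    else:
        structured = pattern / mean_p
    tpef_i = params.tpef_mean * (params.background
                                 + (1.0 - params.background) * structured)
    shg_i = params.shg_tpef_ratio * tpef_i

    rng = np.random.default_rng(seed)
    tpef_d = _detect(tpef_i, params.photon_gain, params.read_noise_sd,
                     params.bit_depth, rng)
    shg_d = _detect(shg_i, params.photon_gain, params.read_noise_sd,
                    params.bit_depth, rng)
    meta = dict(meta or {})
    meta.setdefault("seed", seed)
    tpef = MPImage(tpef_d, "TPEF", pixel_size_um, meta=dict(meta))
    shg = MPImage(shg_d, "SHG", pixel_size_um, meta=dict(meta))
    return tpef, shg


def render_polarimetric_stack(pattern: np.ndarray,
                              pparams: PolarimetricRenderParams,
                              fiber_orientation_deg: float, seed: int,
                              pixel_size_um: float,
                              meta: dict | None = None) -> PolarimetricStack:
    """Render three co-registered polarimetric SHG frames.

    Per-pixel intensity at incident polarization α is
    ``K · pattern · shg_response(α − θ, ρ)`` with θ the fiber orientation,
    plus optional detector noise.
    """
    pparams.validate()
    if not 0.0 <= fiber_orientation_deg < 180.0:
        raise ValueError("fiber orientation must lie in [0°, 180°)")
    pattern = np.asarray(pattern, dtype=float)
    pat = pparams.baseline + (1.0 - pparams.baseline) * pattern
    rng = np.random.default_rng(seed)
    meta = dict(meta or {})
    meta.setdefault("seed", seed)
    meta.setdefault("fiber_orientation_deg", fiber_orientation_deg)
    frames = []
    for alpha in pparams.angles_deg:
        inten = pparams.scale * pat * shg_response(alpha - fiber_orientation_deg,
                                                   pparams.rho)
        data = _detect(inten, pparams.photon_gain, pparams.read_noise_sd,
                       pparams.bit_depth, rng)
        frames.append(MPImage(data, "SHG", pixel_size_um,
                              polarization_deg=float(alpha), meta=dict(meta)))
    return PolarimetricStack(frames)


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

def inag_to_ratio(inag: float) -> float:
    """Invert the INAG contrast to the SHG/TPEF mean-intensity ratio."""
    if not -1.0 < inag < 1.0:
        raise ValueError(f"INAG={inag:g} outside (−1, 1): ratio undefined")
    return (1.0 + inag) / (1.0 - inag)


@dataclass(frozen=True)
class CohortConfig:
    """Study design for a synthetic cohort.

    Per-specimen ground truths are drawn as ``line(age) + N(0, residual)``
    for the peritubule width (µm), the INAG index and the ρ ratio; the
    per-region SHG/TPEF intensity ratio is back-solved from the target
    INAG.  Defaults mirror the real study's design: 9 specimens aged
    19–82 years, 5 imaged regions each, and the printed regression lines.
    """

    ages_years: tuple[float, ...] = (19, 27, 35, 43, 51, 58, 66, 74, 82)
    sexes: tuple[str, ...] | None = None  # default: 4 M then F
    width_line: tuple[float, float] = WIDTH_LINE
    inag_line: tuple[float, float] = INAG_LINE
    rho_line: tuple[float, float] = RHO_LINE
    residual_sds: dict[str, float] = field(
        default_factory=lambda: {"width": 0.4, "inag": 0.04, "rho": 0.15})
    regions_per_specimen: int = 5
    n_px: int = 512
    field_um: float = 180.0
    jitter_deg: float = 3.0
    orientation_deg: float | None = None  # None → cycle ORIENTATION_CYCLE
    tpef_mean: float = 2000.0
    background: float = 0.10
    photon_gain: float = 1.0
    read_noise_sd: float = 2.0
    bit_depth: int = 16
    polar_scale: float = 2000.0
    polar_baseline: float = 0.15
    include_polarimetry: bool = True
    seed: int = 0

    def validate(self) -> None:
        if len(self.ages_years) == 0:
            raise ValueError("cohort must contain at least one specimen")
        if self.regions_per_specimen < 1:
            raise ValueError("regions_per_specimen must be >= 1")
        if self.sexes is not None and len(self.sexes) != len(self.ages_years):
            raise ValueError("sexes must match ages_years in length")
        for k in ("width", "inag", "rho"):
            if self.residual_sds.get(k, 0.0) < 0:
                raise ValueError("residual sds must be >= 0")

    def sex_labels(self) -> tuple[str, ...]:
        if self.sexes is not None:
            return tuple(self.sexes)
        n = len(self.ages_years)
        return tuple("M" if i < min(4, n) else "F" for i in range(n))

    @property
    def noiseless(self) -> bool:
        return self.photon_gain == 0.0 and self.read_noise_sd == 0.0


@dataclass
class RegionImages:
    """Rendered images plus ground truth for one imaged dentinal area."""

    region_id: int
    tpef: MPImage
    shg: MPImage
    stack: PolarimetricStack | None
    truth: dict


@dataclass
class SpecimenRecord:
    """One synthetic tooth: metadata plus its imaged regions."""

    specimen_id: str
    age_years: float
    sex: str
    regions: list[RegionImages]


def cohort_truth(config: CohortConfig) -> pd.DataFrame:
    """Draw the per-specimen ground-truth table (reproducible from seed)."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1001]))
    rows = []
    sexes = config.sex_labels()
    for i, age in enumerate(config.ages_years):
        width = (config.width_line[0] * age + config.width_line[1]
                 + rng.normal(0.0, config.residual_sds.get("width", 0.0)))
        inag = (config.inag_line[0] * age + config.inag_line[1]
                + rng.normal(0.0, config.residual_sds.get("inag", 0.0)))
        rho = (config.rho_line[0] * age + config.rho_line[1]
               + rng.normal(0.0, config.residual_sds.get("rho", 0.0)))
        rows.append({
            "specimen_id": f"S{i + 1:02d}",
            "age_years": float(age),
            "sex": sexes[i],
            "width_true_um": float(width),
            "inag_true": float(inag),
            "rho_true": float(rho),
            "ratio_true": inag_to_ratio(float(inag)),
        })
    return pd.DataFrame(rows)


def _render_specimen(config: CohortConfig, row: pd.Series,
                     index: int) -> SpecimenRecord:
    px = config.field_um / config.n_px
    regions: list[RegionImages] = []
    base_ss = np.random.SeedSequence([config.seed, 2000 + index])
    child = base_ss.generate_state(4 * config.regions_per_specimen) % (2**31)
    for r in range(config.regions_per_specimen):
        ori = (config.orientation_deg if config.orientation_deg is not None
               else ORIENTATION_CYCLE[r % len(ORIENTATION_CYCLE)])
        fparams = TubuleFieldParams(
            period_um=row["width_true_um"], orientation_deg=float(ori),
            jitter_deg=config.jitter_deg, field_um=config.field_um,
            n_px=config.n_px)
        pattern = generate_tubule_field(fparams, seed=int(child[4 * r]))
        meta = {"specimen_id": row["specimen_id"], "age_years": row["age_years"],
                "sex": row["sex"], "region_id": r}
        cparams = ChannelRenderParams(
            tpef_mean=config.tpef_mean, shg_tpef_ratio=row["ratio_true"],
            background=config.background, photon_gain=config.photon_gain,
            read_noise_sd=config.read_noise_sd, bit_depth=config.bit_depth)
        tpef, shg = render_channel_pair(pattern, cparams,
                                        seed=int(child[4 * r + 1]),
                                        pixel_size_um=px, meta=meta)
        stack = None
        if config.include_polarimetry:
            pparams = PolarimetricRenderParams(
                rho=row["rho_true"], scale=config.polar_scale,
                baseline=config.polar_baseline,
                photon_gain=config.photon_gain,
                read_noise_sd=config.read_noise_sd,
                bit_depth=config.bit_depth)
            stack = render_polarimetric_stack(
                pattern, pparams, fiber_orientation_deg=float(ori),
                seed=int(child[4 * r + 2]), pixel_size_um=px, meta=meta)
        regions.append(RegionImages(
            region_id=r, tpef=tpef, shg=shg, stack=stack,
            truth={"orientation_deg": float(ori),
                   "width_true_um": float(row["width_true_um"]),
                   "inag_true": float(row["inag_true"]),
                   "rho_true": float(row["rho_true"]),
                   "ratio_true": float(row["ratio_true"])}))
    return SpecimenRecord(specimen_id=row["specimen_id"],
                          age_years=float(row["age_years"]),
                          sex=row["sex"], regions=regions)


def iter_specimens(config: CohortConfig,
                   truth: pd.DataFrame | None = None) -> Iterator[SpecimenRecord]:
    """Stream rendered specimens one at a time (memory-friendly)."""
    if truth is None:
        truth = cohort_truth(config)
    for i, (_, row) in enumerate(truth.iterrows()):
        yield _render_specimen(config, row, i)


def generate_cohort(config: CohortConfig) -> tuple[list[SpecimenRecord], pd.DataFrame]:
    """Render the full cohort and return (specimens, ground-truth table)."""
    truth = cohort_truth(config)
    return list(iter_specimens(config, truth)), truth


def simulate_to_dir(config: CohortConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write a cohort to disk (TIFF + sidecars + ground_truth.csv)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = cohort_truth(config)
    for spec in iter_specimens(config, truth):
        sdir = out / spec.specimen_id
        sdir.mkdir(exist_ok=True)
        for reg in spec.regions:
            stem = f"region_{reg.region_id:02d}"
            reg.tpef.save(sdir / f"{stem}_tpef.tif")
            reg.shg.save(sdir / f"{stem}_shg.tif")
            if reg.stack is not None:
                for im in reg.stack.images:
                    ang = int(round(im.polarization_deg))
                    im.save(sdir / f"{stem}_shg_pol{ang:03d}.tif")
    truth.to_csv(out / "ground_truth.csv", index=False)
    return truth
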