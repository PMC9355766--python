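"""Parameter-recovery experiments on synthetic cohorts.

The real tooth images behind the published regression lines are not
redistributable, so the package validates itself by synthesis-recovery:
cohorts are generated with ground truth *on* the printed age-regression
lines, pushed through the full measurement pipeline (image → metric →
per-specimen mean → least squares), and the recovered slopes/intercepts
are compared with the configured truth.  Each function here encodes one
such experiment under the study's design (9 specimens aged 19–82, five
imaged regions each, 180 µm fields at 512 px).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .images import MPImage
from .inag import inag_summary
from .morphometry import estimate_orientation_hough, peritubule_width, \
    structure_tensor_sd
from .polarimetry import rho_map
from .stats import fit_age_regression, relative_change
from .synthetic import (INAG_LINE, ChannelRenderParams, CohortConfig,
                        TubuleFieldParams, cohort_truth, generate_patchwork_field,
                        generate_tubule_field, iter_specimens,
                        render_channel_pair)


def _noiseless_cohort(seed: int, n_px: int, include_polarimetry: bool,
                      **overrides) -> CohortConfig:
    """Zero-residual, noise-free cohort on the printed regression lines."""
    return CohortConfig(
        residual_sds={"width": 0.0, "inag": 0.0, "rho": 0.0},
        photon_gain=0.0, read_noise_sd=0.0,
        include_polarimetry=include_polarimetry,
        n_px=n_px, seed=seed, **overrides)


def width_recovery(seed: int = 0, n_px: int = 512) -> dict:
    """Recover the width–age line end-to-end.

    Images → Otsu+Hough orientation → perpendicular cross-sections →
    valley spacing → specimen means → least squares.
    """
    config = _noiseless_cohort(seed, n_px, include_polarimetry=False)
    ages, means = [], []
    for spec in iter_specimens(config):
        widths = []
        for region in spec.regions:
            ori = estimate_orientation_hough(region.shg)
            widths.append(peritubule_width(region.shg, ori).width_um)
        ages.append(spec.age_years)
        means.append(float(np.mean(widths)))
    reg = fit_age_regression(ages, means, "width_um")
    return {"slope": reg.slope, "intercept": reg.intercept, "r": reg.pearson_r,
            "n": reg.n, "ages": ages, "means": means}


def inag_recovery(seed: int = 0, n_px: int = 512) -> dict:
    """Recover the INAG–age line from rendered TPEF/SHG pairs."""
    config = _noiseless_cohort(seed, n_px, include_polarimetry=False)
    ages, means = [], []
    for spec in iter_specimens(config):
        vals = [inag_summary(r.shg, r.tpef) for r in spec.regions]
        ages.append(spec.age_years)
        means.append(float(np.mean(vals)))
    reg = fit_age_regression(ages, means, "inag")
    return {"slope": reg.slope, "intercept": reg.intercept, "r": reg.pearson_r,
            "n": reg.n, "ages": ages, "means": means}


def rho_recovery(seed: int = 0, n_px: int = 512) -> dict:
    """Recover the ρ–age line from three-polarization stacks (fibers at 0°)."""
    config = _noiseless_cohort(seed, n_px, include_polarimetry=True,
                               orientation_deg=0.0)
    ages, means = [], []
    for spec in iter_specimens(config):
        vals = []
        for region in spec.regions:
            rm = rho_map(region.stack)  # θ estimated from the stack itself
            vals.append(rm.summary_mean)
        ages.append(spec.age_years)
        means.append(float(np.mean(vals)))
    reg = fit_age_regression(ages, means, "rho")
    return {"slope": reg.slope, "intercept": reg.intercept, "r": reg.pearson_r,
            "n": reg.n, "ages": ages, "means": means}


def sd_aligned(seed: int = 0, n_fields: int = 10, n_px: int = 512,
               jitter_deg: float = 5.0, orientation_deg: float = 30.0) -> list[float]:
    """Structural dispersion of quasi-aligned fields (mild photon noise)."""
    out = []
    rng_seeds = seed + np.arange(1, n_fields + 1)
    for s in rng_seeds:
        params = TubuleFieldParams(period_um=5.0, orientation_deg=orientation_deg,
                                   jitter_deg=jitter_deg, n_px=n_px)
        pattern = generate_tubule_field(params, seed=int(s))
        _, shg = render_channel_pair(
            pattern, ChannelRenderParams(photon_gain=1.0), seed=int(s),
            pixel_size_um=params.pixel_size_um)
        out.append(structure_tensor_sd(shg).sd_deg)
    return out


def sd_disorganized(seed: int = 0, n_fields: int = 10, n_px: int = 512,
                    n_patches: int = 8) -> list[float]:
    """Structural dispersion of patchworks at uniform random orientations."""
    out = []
    for s in seed + np.arange(1, n_fields + 1):
        params = TubuleFieldParams(period_um=5.0, n_px=n_px)
        field = generate_patchwork_field(params, seed=int(s),
                                         n_patches=n_patches)
        img = MPImage(field, "SHG", params.pixel_size_um)
        out.append(structure_tensor_sd(img).sd_deg)
    return out


def inag_relative_change_20_80() -> float:
    """Magnitude growth (%) of the printed INAG line between ages 20 and 80."""
    line = fit_age_regression([20.0, 50.0, 80.0],
                              [INAG_LINE[0] * a + INAG_LINE[1]
                               for a in (20.0, 50.0, 80.0)], "inag")
    return relative_change(line, 20, 80)["percent"]
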