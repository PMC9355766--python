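"""End-to-end pipeline: simulate/load → per-region metrics → age regressions.

One call, :func:`run_pipeline`, drives the whole analysis: render (or
read) a cohort of multiphoton image sets, measure every region (INAG,
SHG/TPEF ratio, peritubule width, orientation, structural dispersion,
signed ρ), aggregate per specimen, and regress each metric against age.
Outputs are a per-region CSV, a per-specimen CSV, a JSON regression
report, and a log; the resolved configuration and seed are serialized
alongside so every number is reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .images import MPImage, PolarimetricStack
from .inag import inag_map, inag_summary, shg_tpef_ratio
from .morphometry import (NoDominantOrientationError, estimate_orientation_hough,
                          peritubule_width, structure_tensor_sd)
from .polarimetry import GeometryError, rho_map
from .stats import (AgeRegression, aggregate_specimen, fit_age_regression,
                    relative_change, sex_comparison)
from .synthetic import CohortConfig, RegionImages, SpecimenRecord, iter_specimens

log = logging.getLogger("dentinemp")

REQUIRED_SIDECAR_FIELDS = ("specimen_id", "age_years", "channel", "pixel_size_um")


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable parameters of every analysis stage (all lengths in µm)."""

    inag_smooth_um: float = 1.0
    inag_floor: float | None = None
    n_sections: int = 9
    valley_prominence: float = 0.10
    grad_sigma_um: float = 0.5
    tensor_sigma_um: float = 2.0
    rho_floor: float | None = None
    rho_method: str = "pixelwise"
    hough_angle_step_deg: float = 0.5


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run."""

    cohort: CohortConfig | None = None
    input_dir: str | None = None
    output_dir: str = "dentinemp_out"
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.cohort is None) == (self.input_dir is None):
            raise ValueError("exactly one of cohort / input_dir must be set")


@dataclass
class PipelineResult:
    regions: pd.DataFrame
    specimens: pd.DataFrame
    regressions: dict[str, AgeRegression]
    report: dict


# --------------------------------------------------------------------------
# per-region analysis
# --------------------------------------------------------------------------

def analyze_region(region: RegionImages, specimen: SpecimenRecord,
                   params: AnalysisParams = AnalysisParams()) -> dict:
    """Measure one imaged dentinal area; returns a flat metric record."""
    rec: dict = {"specimen_id": specimen.specimen_id,
                 "age_years": specimen.age_years,
                 "sex": specimen.sex,
                 "region_id": region.region_id}
    shg, tpef = region.shg, region.tpef
    rec["inag"] = inag_summary(shg, tpef)
    rec["ratio"] = shg_tpef_ratio(shg, tpef)
    m = inag_map(shg, tpef, smooth_um=params.inag_smooth_um,
                 floor=params.inag_floor)
    rec["inag_map_mean"] = m.summary_mean
    rec["inag_map_sd"] = m.summary_sd

    try:
        ori = estimate_orientation_hough(shg,
                                         angle_step_deg=params.hough_angle_step_deg)
        rec["orientation_deg"] = ori
        tm = peritubule_width(shg, ori, n_sections=params.n_sections,
                              prominence=params.valley_prominence)
        rec["width_um"] = tm.width_um
        rec["width_sd_um"] = tm.width_sd_um
        rec["n_valleys"] = tm.n_valleys
    except (NoDominantOrientationError, ValueError) as exc:
        log.warning("width skipped for %s region %s: %s",
                    specimen.specimen_id, region.region_id, exc)
        rec["orientation_deg"] = np.nan
        rec["width_um"] = np.nan
        ori = None

    om = structure_tensor_sd(shg, grad_sigma_um=params.grad_sigma_um,
                             tensor_sigma_um=params.tensor_sigma_um)
    rec["sd_deg"] = om.sd_deg
    rec["org_class"] = om.org_class
    rec["preferred_orientation_deg"] = om.preferred_orientation_deg

    if region.stack is not None:
        try:
            rm = rho_map(region.stack, theta_deg=ori, floor=params.rho_floor,
                         method=params.rho_method)
            rec["rho_mean"] = rm.summary_mean
            rec["rho_sd"] = rm.summary_sd
            rec["rho_masked_fraction"] = rm.masked_fraction
            rec["theta_deg"] = rm.fiber_orientation_deg
        except (GeometryError, ValueError, NoDominantOrientationError) as exc:
            log.warning("rho skipped for %s region %s: %s",
                        specimen.specimen_id, region.region_id, exc)
            rec["rho_mean"] = np.nan
    return rec


def analyze_cohort(specimens: Iterable[SpecimenRecord],
                   params: AnalysisParams = AnalysisParams()) -> pd.DataFrame:
    """Per-region metric table for a whole cohort (streams specimens)."""
    rows = []
    for spec in specimens:
        if not spec.regions:
            log.warning("specimen %s has no regions; skipped", spec.specimen_id)
            continue
        for region in spec.regions:
            rows.append(analyze_region(region, spec, params))
        log.info("analyzed specimen %s (%d regions)",
                 spec.specimen_id, len(spec.regions))
    if not rows:
        raise ValueError("empty cohort: nothing to analyze")
    return pd.DataFrame(rows)


METRIC_COLUMNS = ("width_um", "inag", "ratio", "sd_deg", "rho_mean")


def specimen_table(regions: pd.DataFrame) -> pd.DataFrame:
    """Aggregate region metrics to one row per specimen (unweighted means)."""
    out_rows = []
    for sid, grp in regions.groupby("specimen_id", sort=True):
        metrics = [c for c in METRIC_COLUMNS if c in grp.columns]
        agg = aggregate_specimen(grp[metrics])
        row = {"specimen_id": sid,
               "age_years": float(grp["age_years"].iloc[0]),
               "sex": grp["sex"].iloc[0]}
        row.update(agg.to_dict())
        out_rows.append(row)
    return pd.DataFrame(out_rows)


def cohort_regressions(specimens: pd.DataFrame) -> dict[str, AgeRegression]:
    """Fit each specimen-mean metric against age; skips unfittable metrics."""
    out: dict[str, AgeRegression] = {}
    for metric in ("width_um", "inag", "rho_mean", "sd_deg", "ratio"):
        col = f"{metric}_mean"
        if col not in specimens.columns:
            continue
        sub = specimens.dropna(subset=[col])
        try:
            out[metric] = fit_age_regression(sub["age_years"], sub[col],
                                             metric_name=metric)
        except ValueError as exc:
            log.warning("regression for %s refused: %s", metric, exc)
    return out


# --------------------------------------------------------------------------
# directory input
# --------------------------------------------------------------------------

def _load_region(sdir: Path, stem: str) -> RegionImages | None:
    tpef_p = sdir / f"{stem}_tpef.tif"
    shg_p = sdir / f"{stem}_shg.tif"
    if not (tpef_p.exists() and shg_p.exists()):
        log.warning("region %s in %s incomplete; skipped", stem, sdir.name)
        return None
    tpef = MPImage.load(tpef_p)
    shg = MPImage.load(shg_p)
    pol_paths = sorted(sdir.glob(f"{stem}_shg_pol*.tif"))
    stack = None
    if len(pol_paths) == 3:
        stack = PolarimetricStack([MPImage.load(p) for p in pol_paths])
    elif pol_paths:
        log.warning("region %s in %s has %d polarimetric frames (need 3); "
                    "polarimetry skipped", stem, sdir.name, len(pol_paths))
    rid = int(stem.split("_")[-1])
    return RegionImages(region_id=rid, tpef=tpef, shg=shg, stack=stack, truth={})


def load_cohort_dir(input_dir: str | Path) -> Iterator[SpecimenRecord]:
    """Stream specimens from a directory laid out by ``simulate_to_dir``."""
    root = Path(input_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"input directory {root} not found")
    sdirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not sdirs:
        raise ValueError(f"no specimen directories under {root}")
    for sdir in sdirs:
        stems = sorted({"_".join(p.stem.split("_")[:2])
                        for p in sdir.glob("region_*_tpef.tif")})
        regions = [r for s in stems if (r := _load_region(sdir, s)) is not None]
        if not regions:
            log.warning("specimen dir %s has no readable regions", sdir.name)
            continue
        meta = regions[0].tpef.meta
        yield SpecimenRecord(specimen_id=meta.get("specimen_id", sdir.name),
                             age_years=float(meta.get("age_years", np.nan)),
                             sex=meta.get("sex", "unknown"),
                             regions=regions)


def validate_inputs(input_dir: str | Path) -> dict:
    """Non-destructive audit of an input directory.

    Returns a manifest of specimens/regions found plus a list of
    diagnostics (missing sidecar fields, shape mismatches, incomplete
    polarimetric stacks); never raises on malformed content.
    """
    root = Path(input_dir)
    manifest: list[dict] = []
    diagnostics: list[str] = []
    if not root.is_dir():
        return {"manifest": [], "diagnostics": [f"{root} is not a directory"]}
    for sdir in sorted(p for p in root.iterdir() if p.is_dir()):
        tpefs = sorted(sdir.glob("region_*_tpef.tif"))
        entry = {"specimen": sdir.name, "n_regions": len(tpefs)}
        manifest.append(entry)
        for tp in tpefs:
            stem = "_".join(tp.stem.split("_")[:2])
            side_p = tp.with_suffix(".json")
            if not side_p.exists():
                diagnostics.append(f"{tp}: missing sidecar")
                continue
            side = json.loads(side_p.read_text())
            for fld in REQUIRED_SIDECAR_FIELDS:
                if fld not in side or side[fld] is None:
                    diagnostics.append(f"{side_p}: missing field '{fld}'")
            shg_p = sdir / f"{stem}_shg.tif"
            if not shg_p.exists():
                diagnostics.append(f"{sdir / stem}: SHG channel missing")
            else:
                a = MPImage.load(tp)
                b = MPImage.load(shg_p)
                if a.shape != b.shape:
                    diagnostics.append(
                        f"{tp} vs {shg_p}: shape mismatch {a.shape} != {b.shape}")
            n_pol = len(list(sdir.glob(f"{stem}_shg_pol*.tif")))
            if n_pol not in (0, 3):
                diagnostics.append(
                    f"{sdir / stem}: {n_pol} polarimetric frames (expected 0 or 3)")
    return {"manifest": manifest, "diagnostics": diagnostics}


# --------------------------------------------------------------------------
# top-level run
# --------------------------------------------------------------------------

def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        return dataclasses.asdict(o)
    raise TypeError(f"not serializable: {type(o)}")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run simulate/load → analyze → aggregate → regress; write the bundle."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    try:
        if config.cohort is not None:
            cohort = dataclasses.replace(config.cohort, seed=config.seed)
            specimens: Iterable[SpecimenRecord] = iter_specimens(cohort)
        else:
            specimens = load_cohort_dir(config.input_dir)  # type: ignore[arg-type]
        regions = analyze_cohort(specimens, config.analysis)
        spec_df = specimen_table(regions)

        regs = cohort_regressions(spec_df)
        report: dict = {"config": dataclasses.asdict(config),
                        "n_specimens": int(len(spec_df)),
                        "n_regions": int(len(regions)),
                        "regressions": {}, "refused": {}}
        for metric in ("width_um", "inag", "rho_mean", "sd_deg", "ratio"):
            if metric in regs:
                report["regressions"][metric] = regs[metric].to_dict()
            elif f"{metric}_mean" in spec_df.columns:
                report["refused"][metric] = ("fewer than 3 specimens or "
                                             "degenerate data")
        if "inag" in regs:
            report["inag_change_20_80"] = relative_change(regs["inag"], 20, 80)
        if "width_um" in regs:
            report["width_change_20_80"] = relative_change(regs["width_um"], 20, 80)
        by_sex = {s: g["age_years"].tolist()
                  for s, g in spec_df.groupby("sex")}
        if len(by_sex) == 2 and all(len(v) for v in by_sex.values()):
            report["sex_comparison"] = sex_comparison(by_sex)

        regions.to_csv(out / "regions.csv", index=False)
        spec_df.to_csv(out / "specimens.csv", index=False)
        (out / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True, default=_json_default))
        log.info("pipeline finished: %d specimens, %d regions",
                 len(spec_df), len(regions))
        return PipelineResult(regions=regions, specimens=spec_df,
                              regressions=regs, report=report)
    finally:
        log.removeHandler(fh)
        fh.close()
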