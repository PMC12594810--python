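"""End-to-end analysis pipeline: raw measurements → QC gate → fits and
reference viscosities → stability calls → JSON report.

The replicate protocol mirrors rheometry practice for LCP media: each
viscosity curve is preceded by a thixotropy trace; replicates whose
before/after low-shear viscosity changes by more than the QC tolerance
are excluded; the surviving replicates are fitted, evaluated at the two
reference shear rates and aggregated as mean ± s.d.; the aggregate
viscosity is classified into a jetting regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from . import io as rio
from .datatypes import FlowCurve, ThixoTrace
from .errors import ConfigError, PipelineError, RangeError
from .powerlaw import (
    GAMMA_JET,
    GAMMA_LVE,
    aggregate_replicates,
    evaluate_viscosity,
    fit_power_law,
)
from .qc import DEFAULT_QC_TOLERANCE, thixo_qc
from .stability import (
    JET_THRESHOLDS,
    LVE_THRESHOLDS,
    ThresholdSet,
    classify_absolute,
    classify_ratio,
)

__all__ = ["PipelineConfig", "run_pipeline"]

PathLike = Union[str, Path]


@dataclass(frozen=True)
class PipelineConfig:
    """Pipeline parameters; defaults are the published values
    (QC tolerance 0.20, thresholds 7e5/1e4 mPa·s at 0.3 s⁻¹ and
    2e4/3e3 at 75.4 s⁻¹, ratio cuts 0.02/0.001)."""

    qc_tolerance: float = DEFAULT_QC_TOLERANCE
    fit_range: Optional[tuple[float, float]] = None
    classify_method: str = "absolute_lve"
    lve_thresholds: ThresholdSet = LVE_THRESHOLDS
    jet_thresholds: ThresholdSet = JET_THRESHOLDS
    ratio_cuts: tuple[float, float] = (0.02, 0.001)
    reference_eta: Optional[float] = None
    report_path: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classify_method not in ("absolute_lve", "absolute_jet", "ratio"):
            raise ConfigError(f"unknown classify method {self.classify_method!r}")
        if self.classify_method == "ratio" and self.reference_eta is None:
            raise ConfigError("ratio classification requires reference_eta")

    @classmethod
    def from_yaml(cls, path: PathLike) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "qc" in raw and "tolerance" in raw["qc"]:
            kwargs["qc_tolerance"] = float(raw["qc"]["tolerance"])
        if "fit" in raw and raw["fit"].get("range"):
            lo, hi = raw["fit"]["range"]
            kwargs["fit_range"] = (float(lo), float(hi))
        cl = raw.get("classify", {})
        if "method" in cl:
            kwargs["classify_method"] = cl["method"]
        if "thresholds" in cl:
            th = cl["thresholds"]
            kwargs["lve_thresholds"] = ThresholdSet(
                gamma_ref=float(th.get("gamma_ref", GAMMA_LVE)),
                stable_min=float(th["stable_min"]),
                unstable_max=float(th["unstable_max"]),
            )
        ref = raw.get("reference", {})
        if "eta" in ref:
            kwargs["reference_eta"] = float(ref["eta"])
        if "report" in raw and "path" in raw["report"]:
            kwargs["report_path"] = raw["report"]["path"]
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        return cls(**kwargs)


def _classify_sample(eta_lve: float, eta_jet: float, cfg: PipelineConfig) -> dict:
    calls = {}
    calls["absolute_lve"] = classify_absolute(eta_lve, cfg.lve_thresholds)
    calls["absolute_jet"] = classify_absolute(eta_jet, cfg.jet_thresholds)
    if cfg.reference_eta is not None:
        calls["ratio"] = classify_ratio(eta_lve, cfg.reference_eta, *cfg.ratio_cuts)
    primary = calls[cfg.classify_method]
    out = {
        "label": primary.label.value,
        "method": primary.method,
        "eta_used": primary.eta_used,
        "all_methods": {k: v.label.value for k, v in calls.items()},
    }
    if cfg.reference_eta is not None:
        out["conflict"] = calls["ratio"].label is not calls["absolute_lve"].label
    return out


def run_pipeline(
    flowcurve_path: PathLike,
    cfg: PipelineConfig = PipelineConfig(),
    thixo_path: Optional[PathLike] = None,
) -> dict:
    """Run the full analysis over one flow-curve CSV (any number of
    samples and replicates) with an optional thixotropy CSV for the QC
    gate.

    Returns the report dict (also written to ``cfg.report_path`` when
    set).  Raises :class:`~rheojet.errors.PipelineError` if every
    replicate of a sample fails QC.
    """
    curves = rio.read_flowcurves(flowcurve_path)
    traces: dict[tuple[str, int], ThixoTrace] = {}
    warnings: list[str] = []
    if thixo_path is not None:
        for t in rio.read_thixotraces(thixo_path):
            traces[(t.sample_id, t.replicate_id)] = t
    else:
        warnings.append("no thixotropy traces supplied: QC gate skipped")

    samples: dict[str, list[FlowCurve]] = {}
    for c in curves:
        samples.setdefault(c.sample_id, []).append(c)

    report: dict = {"samples": {}, "warnings": warnings}
    for sample_id in sorted(samples):
        reps = samples[sample_id]
        qc_block = []
        passing: list[FlowCurve] = []
        excluded: list[int] = []
        for c in reps:
            key = (c.sample_id, c.replicate_id)
            if key in traces:
                res = thixo_qc(traces[key], tolerance=cfg.qc_tolerance)
                qc_block.append(
                    {
                        "replicate_id": c.replicate_id,
                        "eta_before": res.eta_before,
                        "eta_after": res.eta_after,
                        "rel_change": res.rel_change,
                        "passed": res.passed,
                    }
                )
                if res.passed:
                    passing.append(c)
                else:
                    excluded.append(c.replicate_id)
            else:
                passing.append(c)
        if not passing:
            raise PipelineError(f"no valid measurements for sample {sample_id!r}")

        sample_warnings: list[str] = []
        if len(passing) < 3:
            sample_warnings.append(
                f"only {len(passing)} passing replicate(s); at least 3 consecutive "
                "measurements are recommended for error estimation"
            )
        for c in passing:
            if not (19.0 <= c.temperature <= 21.0) or not (70.0 <= c.humidity <= 85.0):
                sample_warnings.append(
                    f"replicate {c.replicate_id}: measured at {c.temperature:g} degC / "
                    f"{c.humidity:g}% RH, outside the 20 degC / 75-85% RH conditions the "
                    "stability thresholds were calibrated under"
                )

        fits = [fit_power_law(c, cfg.fit_range) for c in passing]
        eta_at = {}
        for gamma_ref, tag in ((GAMMA_LVE, "lve"), (GAMMA_JET, "jet")):
            vals = []
            for c in passing:
                try:
                    vals.append(evaluate_viscosity(c, gamma_ref))
                except RangeError:
                    vals.append(evaluate_viscosity(c, gamma_ref, extrapolate=True))
                    sample_warnings.append(
                        f"replicate {c.replicate_id}: {gamma_ref:g} s^-1 outside the "
                        "measured span; power-law extrapolation used"
                    )
            eta_at[tag] = aggregate_replicates(vals, gamma_ref)

        classification = _classify_sample(
            eta_at["lve"].eta_mean, eta_at["jet"].eta_mean, cfg
        )
        if cfg.classify_method == "absolute_jet":
            sample_warnings.append(
                "absolute_jet thresholds have low concordance with observed jetting; "
                "treat this call with caution"
            )

        report["samples"][sample_id] = {
            "n_replicates_input": len(reps),
            "n_replicates_passing": len(passing),
            "excluded_replicates": sorted(excluded),
            "qc": qc_block,
            "power_law": {
                "eta0_mean": sum(f.eta0 for f in fits) / len(fits),
                "n_mean": sum(f.n for f in fits) / len(fits),
                "per_replicate": [
                    {"replicate_id": c.replicate_id, "eta0": f.eta0, "n": f.n,
                     "se_eta0": f.se_eta0, "se_n": f.se_n, "r2": f.r2}
                    for c, f in zip(passing, fits)
                ],
            },
            "reference_viscosity": {
                tag: {
                    "gamma_ref": rv.gamma_ref,
                    "eta_mean": rv.eta_mean,
                    "eta_sd": rv.eta_sd,
                    "n_replicates": rv.n_replicates,
                }
                for tag, rv in eta_at.items()
            },
            "stability": classification,
            "warnings": sample_warnings,
        }

    report["parameters"] = {
        "qc_tolerance": cfg.qc_tolerance,
        "fit_range": cfg.fit_range,
        "classify_method": cfg.classify_method,
        "lve_thresholds": {
            "gamma_ref": cfg.lve_thresholds.gamma_ref,
            "stable_min": cfg.lve_thresholds.stable_min,
            "unstable_max": cfg.lve_thresholds.unstable_max,
        },
        "jet_thresholds": {
            "gamma_ref": cfg.jet_thresholds.gamma_ref,
            "stable_min": cfg.jet_thresholds.stable_min,
            "unstable_max": cfg.jet_thresholds.unstable_max,
        },
        "ratio_cuts": list(cfg.ratio_cuts),
        "reference_eta": cfg.reference_eta,
        "seed": cfg.seed,
    }

    if cfg.report_path:
        inputs = [flowcurve_path] + ([thixo_path] if thixo_path else [])
        rio.write_report(report, cfg.report_path, parameters=report["parameters"],
                         inputs=inputs)
    return report
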