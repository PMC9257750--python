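"""Batch orchestration: per-arm simulations across clearance scaling
methods and disposition model variants, prediction-vs-observation tables,
stratified metric panels, and the full-vs-reduced concordance comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import pk_metrics
from .absorption_acat import FormulationSpec, simulate_po, simulate_reduced
from .compound_model import (
    CompoundRecord,
    StudyArm,
    classify_binding,
    classify_clearance,
    classify_eccs,
    classify_ionization,
)
from .disposition import compute_kp_set, compute_vss, simulate_iv, simulate_reduced_iv
from .ivive import (
    ClearanceInputs,
    FlowLimitExceededError,
    RatPhysiologyConstants,
    SCALING_METHODS,
    ScalingMethod,
    back_calculate_clint,
    compute_fu_inc,
    scale_to_whole_body,
    unbound_clint,
)
from .physiology import RatPhysiology, default_physiology

__all__ = ["RunConfig", "PredictionReport", "run_evaluation", "compare_full_vs_reduced"]

PARAMETERS = ("cl", "vss", "aucinf", "cmax", "foral")
MIN_STRATUM_N = 5


@dataclass(frozen=True)
class RunConfig:
    """Evaluation settings: which scaling methods, model variants and routes
    to run, plus solver/physiology overrides."""

    methods: Tuple[str, ...] = ("direct", "dilution")
    model: str = "full"  # full | reduced | both
    routes: Tuple[str, ...] = ("IV", "PO")
    seed: int = 0
    dilution_factor: float = 0.1
    flow_margin: float = 0.99
    t_end_h: float = 48.0
    max_t_end_h: float = 2000.0
    n_times: int = 241

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("at least one scaling method is required")
        if not self.routes:
            raise ValueError("at least one route is required")
        unknown = set(self.methods) - set(SCALING_METHODS)
        if unknown:
            raise ValueError(f"unknown scaling methods: {sorted(unknown)}")
        if self.model not in ("full", "reduced", "both"):
            raise ValueError(f"model must be full/reduced/both, got {self.model!r}")

    @property
    def model_variants(self) -> Tuple[str, ...]:
        return ("full", "reduced") if self.model == "both" else (self.model,)


@dataclass
class PredictionReport:
    """Long prediction table, stratified metric panels, and exclusions."""

    predictions: pd.DataFrame
    panels: pd.DataFrame
    exclusions: pd.DataFrame

    def panel(self, parameter: str, method: str, model: str = "full",
              stratum: str = "overall", level: str = "all"):
        sel = self.panels[
            (self.panels.parameter == parameter)
            & (self.panels.method == method)
            & (self.panels.model == model)
            & (self.panels.stratum == stratum)
            & (self.panels.level == level)
        ]
        if sel.empty:
            raise KeyError(
                f"no panel for parameter={parameter} method={method} "
                f"model={model} stratum={stratum} level={level}"
            )
        return sel.iloc[0]


def _classify_compound(compound: CompoundRecord) -> Dict[str, str]:
    ion = classify_ionization(compound.ionization)
    return {
        "ionization_category": ion,
        "eccs_class": classify_eccs(
            compound.in_vitro.papp_llcpk1, ion, compound.in_vitro.mw
        ),
        "binding_category": classify_binding(compound.in_vitro.fup),
    }


def _derive_clint_wb(
    method: str,
    compound: CompoundRecord,
    arm: StudyArm,
    iv_cl_ref: Optional[float],
    config: RunConfig,
    scaling_phys: RatPhysiologyConstants,
    external_clint: Optional[Dict[str, float]],
) -> float:
    """Whole-body unbound intrinsic clearance (mL/min/kg) for one arm under
    one scaling method. Raises ValueError subclasses on exclusions."""
    iv_data = compound.in_vitro
    if method == "back_calculated":
        cl_obs = arm.observed_cl if arm.route == "IV" else iv_cl_ref
        if cl_obs is None:
            raise ValueError("no observed IV clearance available for back-calculation")
        clint_cells = back_calculate_clint(
            cl_obs, arm.fe, iv_data.fup, iv_data.bp,
            scaling_phys, flow_margin=config.flow_margin,
        )
        return scale_to_whole_body(clint_cells, scaling_phys)
    if method == "external_predicted":
        if not external_clint or compound.compound_id not in external_clint:
            raise ValueError("no externally predicted intrinsic clearance supplied")
        return scale_to_whole_body(external_clint[compound.compound_id], scaling_phys)
    inputs = ClearanceInputs(
        clint_heps=iv_data.clint_heps, fup=iv_data.fup, bp=iv_data.bp,
        logd_or_logp=iv_data.logd74,
        ionization_category=classify_ionization(compound.ionization),
    )
    fu_inc = compute_fu_inc(ScalingMethod(method, df=config.dilution_factor), inputs)
    return scale_to_whole_body(unbound_clint(iv_data.clint_heps, fu_inc), scaling_phys)


def _sim_horizon(cl_plasma: float, vss: float, config: RunConfig) -> float:
    """Simulation horizon long enough to identify the terminal phase."""
    if cl_plasma <= 0:
        return config.max_t_end_h
    t_half_h = math.log(2.0) * vss * 1000.0 / cl_plasma / 60.0
    return float(min(max(config.t_end_h, 8.0 * t_half_h), config.max_t_end_h))


def _simulate_arm(
    variant: str,
    compound: CompoundRecord,
    arm: StudyArm,
    clint_u_wb: float,
    kps,
    vss_mech: float,
    phys: RatPhysiology,
    scaling_phys: RatPhysiologyConstants,
    config: RunConfig,
) -> Dict[str, Optional[float]]:
    """Run one arm through one model variant and return predicted parameters."""
    iv_data = compound.in_vitro
    fub = iv_data.fup / iv_data.bp
    qh = scaling_phys.qh
    cl_blood = qh * fub * clint_u_wb / (qh + fub * clint_u_wb)
    cl_plasma = cl_blood * iv_data.bp
    if cl_plasma <= 0:
        raise ValueError("zero intrinsic clearance: AUC divergent")
    t_end = _sim_horizon(cl_plasma, vss_mech, config)

    if arm.route == "IV":
        if variant == "full":
            res = simulate_iv(arm.dose, clint_u_wb, iv_data.fup, iv_data.bp,
                              kps, phys, t_end_h=t_end, n_times=config.n_times)
        else:
            res = simulate_reduced_iv(arm.dose, cl_plasma, vss_mech,
                                      t_end_h=t_end, n_times=config.n_times)
        params = pk_metrics.nca(res.time_h, res.plasma, arm.dose, "IV")
        return {"cl": params.cl, "vss": params.vss, "aucinf": params.aucinf,
                "cmax": params.cmax, "foral": None}

    formulation = FormulationSpec(kind=arm.formulation)
    if variant == "full":
        res = simulate_po(compound, arm.dose, clint_u_wb, kps, phys,
                          formulation=formulation, t_end_h=t_end,
                          n_times=config.n_times)
        iv_ref = simulate_iv(arm.dose, clint_u_wb, iv_data.fup, iv_data.bp,
                             kps, phys, t_end_h=t_end, n_times=config.n_times)
    else:
        res = simulate_reduced(compound, arm.dose, "PO", clint_u_wb, vss_mech,
                               phys, formulation=formulation, t_end_h=t_end,
                               n_times=config.n_times)
        iv_ref = simulate_reduced_iv(arm.dose, cl_plasma, vss_mech,
                                     t_end_h=t_end, n_times=config.n_times)
    iv_params = pk_metrics.nca(iv_ref.time_h, iv_ref.plasma, arm.dose, "IV")
    params = pk_metrics.nca(res.time_h, res.plasma, arm.dose, "PO",
                            auc_iv_ref=iv_params.aucinf, dose_iv_ref=arm.dose)
    return {"cl": None, "vss": None, "aucinf": params.aucinf,
            "cmax": params.cmax, "foral": params.foral}


def run_evaluation(
    compounds: Sequence[CompoundRecord],
    arms: Sequence[StudyArm],
    config: Optional[RunConfig] = None,
    phys: Optional[RatPhysiology] = None,
    scaling_phys: Optional[RatPhysiologyConstants] = None,
    external_clint: Optional[Dict[str, float]] = None,
) -> PredictionReport:
    """Evaluate every arm under every configured method and model variant.

    Every input arm appears in the prediction table or carries an explicit
    exclusion reason; stratified metric panels are computed overall and by
    binding, clearance, and ECCS categories (strata with n >= 5 only).
    """
    config = config or RunConfig()
    phys = phys or default_physiology()
    scaling_phys = scaling_phys or RatPhysiologyConstants()
    by_id = {c.compound_id: c for c in compounds}
    unknown = sorted({a.compound_id for a in arms} - set(by_id))
    if unknown:
        raise ValueError(f"arms reference unknown compounds: {unknown}")

    # per-compound precomputation
    kp_cache, vss_cache, class_cache, iv_cl_ref = {}, {}, {}, {}
    for c in compounds:
        kp_cache[c.compound_id] = compute_kp_set(c, c.in_vitro.fup, c.in_vitro.bp, phys)
        vss_cache[c.compound_id] = compute_vss(kp_cache[c.compound_id], phys, c.in_vitro.bp)
        class_cache[c.compound_id] = _classify_compound(c)
    for cid in by_id:
        cls = [a.observed_cl for a in arms
               if a.compound_id == cid and a.route == "IV" and a.observed_cl is not None]
        iv_cl_ref[cid] = float(np.mean(cls)) if cls else None

    observed_map = {
        "cl": "observed_cl", "vss": "observed_vss", "aucinf": "observed_aucinf",
        "cmax": "observed_cmax", "foral": "observed_foral",
    }
    rows, excl_rows = [], []
    for variant in config.model_variants:
        for method in config.methods:
            for arm_index, arm in enumerate(arms):
                if arm.route not in config.routes:
                    continue
                compound = by_id[arm.compound_id]
                base = {
                    "compound_id": arm.compound_id, "arm_index": arm_index,
                    "route": arm.route, "dose": arm.dose,
                    "formulation": arm.formulation,
                    "method": method, "model": variant,
                }
                try:
                    clint_u_wb = _derive_clint_wb(
                        method, compound, arm, iv_cl_ref[arm.compound_id],
                        config, scaling_phys, external_clint,
                    )
                    pred = _simulate_arm(
                        variant, compound, arm, clint_u_wb,
                        kp_cache[arm.compound_id], vss_cache[arm.compound_id],
                        phys, scaling_phys, config,
                    )
                except (ValueError, FlowLimitExceededError, RuntimeError) as exc:
                    excl_rows.append({**base, "reason": str(exc)})
                    continue
                cls = class_cache[arm.compound_id]
                cl_obs = arm.observed_cl
                clearance_cat = (
                    classify_clearance(min(cl_obs / compound.in_vitro.bp, 60.0))
                    if cl_obs is not None else None
                )
                for parameter in PARAMETERS:
                    predicted = pred[parameter]
                    observed = getattr(arm, observed_map[parameter])
                    if predicted is None:
                        continue
                    fold = (
                        max(predicted / observed, observed / predicted)
                        if observed and observed > 0 and predicted > 0 else None
                    )
                    rows.append({
                        **base, "parameter": parameter,
                        "predicted": predicted, "observed": observed,
                        "fold_error": fold, "clearance_category": clearance_cat,
                        **cls,
                    })

    predictions = pd.DataFrame(rows)
    exclusions = pd.DataFrame(
        excl_rows, columns=["compound_id", "arm_index", "route", "dose",
                            "formulation", "method", "model", "reason"]
    )
    panels = _build_panels(predictions)
    return PredictionReport(predictions=predictions, panels=panels,
                            exclusions=exclusions)


def _build_panels(predictions: pd.DataFrame) -> pd.DataFrame:
    if predictions.empty:
        return pd.DataFrame()
    panel_rows = []
    strata = [("overall", None), ("binding", "binding_category"),
              ("clearance", "clearance_category"), ("eccs", "eccs_class")]
    for (model, method, parameter), grp in predictions.groupby(
        ["model", "method", "parameter"], sort=True
    ):
        valid = grp.dropna(subset=["observed"])
        valid = valid[valid.observed > 0]
        for stratum, column in strata:
            if column is None:
                levels = [("all", valid)]
            else:
                levels = [(lvl, sub) for lvl, sub in valid.groupby(column, sort=True)]
            for level, sub in levels:
                if len(sub) < max(2, MIN_STRATUM_N if column else 2):
                    continue
                panel = pk_metrics.fold_error_panel(
                    sub.predicted.to_numpy(), sub.observed.to_numpy()
                )
                panel_rows.append({
                    "model": model, "method": method, "parameter": parameter,
                    "stratum": stratum, "level": str(level), **panel.as_dict(),
                })
    return pd.DataFrame(panel_rows)


def compare_full_vs_reduced(
    compounds: Sequence[CompoundRecord],
    arms: Sequence[StudyArm],
    config: Optional[RunConfig] = None,
    phys: Optional[RatPhysiology] = None,
    scaling_phys: Optional[RatPhysiologyConstants] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Paired full-vs-reduced predictions plus a per-parameter concordance
    summary (Spearman rank correlation and AAFE between the two variants)."""
    from scipy import stats

    config = config or RunConfig()
    config = RunConfig(
        methods=config.methods, model="both", routes=config.routes,
        seed=config.seed, dilution_factor=config.dilution_factor,
        flow_margin=config.flow_margin, t_end_h=config.t_end_h,
        max_t_end_h=config.max_t_end_h, n_times=config.n_times,
    )
    report = run_evaluation(compounds, arms, config, phys, scaling_phys)
    pred = report.predictions
    key = ["compound_id", "arm_index", "route", "dose", "method", "parameter"]
    full = pred[pred.model == "full"].set_index(key)["predicted"]
    reduced = pred[pred.model == "reduced"].set_index(key)["predicted"]
    paired = pd.DataFrame({"full": full, "reduced": reduced}).dropna().reset_index()

    summary_rows = []
    for (method, parameter), grp in paired.groupby(["method", "parameter"]):
        ok = (grp["full"] > 0) & (grp["reduced"] > 0)
        sub = grp[ok]
        if len(sub) < 2:
            continue
        rho = stats.spearmanr(sub["full"], sub["reduced"]).statistic
        log_ratio = np.log10(sub["reduced"] / sub["full"])
        summary_rows.append({
            "method": method, "parameter": parameter, "n": len(sub),
            "spearman_rho": float(rho),
            "aafe": float(10.0 ** np.mean(np.abs(log_ratio))),
            "afe": float(10.0 ** np.mean(log_ratio)),
        })
    return paired, pd.DataFrame(summary_rows)
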