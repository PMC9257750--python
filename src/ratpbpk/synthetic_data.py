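"""Synthetic compound libraries and pseudo-observed PK.

Generates compound records whose marginal property distributions emulate a
lead-optimization-style dataset (MW centred near 413 Da, logD near 2.48,
mean derived human effective permeability near 2.18e-4 cm/s, a mostly
basic/neutral ionization mix, and ~11-12% of compounds with fup < 2%), and
study arms whose "observed" PK comes from the package's own forward model
plus configurable multiplicative noise. Everything is deterministic under a
fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .compound_model import (
    CompoundRecord,
    InVitroInputs,
    IonizationProfile,
    StudyArm,
    classify_ionization,
)
from .disposition import compute_kp_set, compute_vss
from .ivive import (
    ClearanceInputs,
    RatPhysiologyConstants,
    ScalingMethod,
    predict_plasma_cl,
    scale_to_whole_body,
    unbound_clint,
)
from .absorption_acat import default_acat_config, _compartment_constants, build_solubility_model
from .physiology import RatPhysiology, default_physiology

__all__ = [
    "LibrarySpec",
    "NoiseModel",
    "generate_library",
    "generate_observations",
]


@dataclass(frozen=True)
class LibrarySpec:
    """Marginal distributions and structure of a synthetic compound library.

    Location parameters are means for (truncated) normal marginals and
    geometric medians for lognormal ones; ``sd`` values for lognormal
    marginals are in log10 units.
    """

    n_compounds: int = 267
    seed: int = 0
    mw_mean: float = 413.0
    mw_sd: float = 75.0
    mw_range: Tuple[float, float] = (250.0, 700.0)
    logd_mean: float = 2.48
    logd_sd: float = 1.2
    logd_range: Tuple[float, float] = (-1.5, 5.5)
    # log10(Papp/cm/s) marginal chosen so the derived human Peff has an
    # arithmetic mean of ~2.18 (in 1e-4 cm/s units)
    log_papp_mean: float = -2.846
    log_papp_sd: float = 0.35
    s_aq_median: float = 0.2  # ug/mL, geometric-scale location
    s_aq_log_sd: float = 1.0
    clint_median: float = 10.0  # uL/min/1e6 cells
    clint_log_sd: float = 0.6
    fup_tail_weight: float = 0.115  # fraction of highly bound compounds
    fup_main_median: float = 0.2
    fup_main_log_sd: float = 0.45
    fup_tail_median: float = 0.008
    fup_tail_log_sd: float = 0.25
    bp_median: float = 1.0
    bp_log_sd: float = 0.12
    bp_range: Tuple[float, float] = (0.7, 3.0)
    # basic : neutral : acidic : zwitterion, matching an ~88:170:6:3 split
    ionization_proportions: Dict[str, float] = field(
        default_factory=lambda: {
            "basic": 0.330, "neutral": 0.636, "acidic": 0.022, "zwitterion": 0.012,
        }
    )
    biorelevant_fraction: float = 0.5  # compounds with FaSSIF/FeSSIF data
    iv_dose_range: Tuple[float, float] = (0.03, 10.0)
    po_dose_range: Tuple[float, float] = (0.2, 34.0)
    extra_arm_prob: float = 0.6  # chance of a second arm per compound/route

    def __post_init__(self) -> None:
        if self.n_compounds < 0:
            raise ValueError("n_compounds must be >= 0")
        total = sum(self.ionization_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"ionization proportions sum to {total}, expected 1")
        if not (0.0 <= self.fup_tail_weight <= 1.0):
            raise ValueError("fup_tail_weight must be in [0, 1]")


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal observation error (geometric SDs >= 1).

    ``clint_gsd`` perturbs the in vitro intrinsic clearance relative to the
    'true' in vivo value, creating a realistic extrapolation disconnect.
    """

    gsd_cl: float = 1.3
    gsd_vss: float = 1.3
    gsd_auc: float = 1.3
    gsd_cmax: float = 1.4
    clint_gsd: float = 2.0

    def __post_init__(self) -> None:
        for name in ("gsd_cl", "gsd_vss", "gsd_auc", "gsd_cmax", "clint_gsd"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1")


def _trunc_normal(rng, mean, sd, lo, hi, size=None):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out = np.where(bad, rng.normal(mean, sd, size=size), out)
        bad = (out < lo) | (out > hi)
    return out


def _lognormal10(rng, median, log_sd):
    return float(median * 10.0 ** rng.normal(0.0, log_sd))


def _sample_ionization(rng, category: str) -> IonizationProfile:
    if category == "neutral":
        return IonizationProfile(0.0, 0.0, 1.0, 0.0, ())
    if category == "basic":
        pka = float(np.clip(7.4 + abs(rng.normal(1.2, 0.8)) + 0.2, 7.7, 10.5))
        f_cat = 1.0 / (1.0 + 10.0 ** (7.4 - pka))
        return IonizationProfile(0.0, f_cat, 1.0 - f_cat, 0.0, ((pka, "base"),))
    if category == "acidic":
        pka = float(np.clip(7.4 - abs(rng.normal(2.5, 1.0)) - 0.2, 3.0, 7.1))
        f_an = 1.0 / (1.0 + 10.0 ** (pka - 7.4))
        return IonizationProfile(f_an, 0.0, 1.0 - f_an, 0.0, ((pka, "acid"),))
    if category == "zwitterion":
        pka_b = float(np.clip(rng.normal(9.0, 0.5), 8.0, 10.5))
        pka_a = float(np.clip(rng.normal(3.5, 0.5), 2.5, 5.0))
        return IonizationProfile(
            0.1, 0.1, 0.1, 0.7, ((pka_a, "acid"), (pka_b, "base"))
        )
    raise ValueError(f"unknown ionization category {category!r}")


def generate_library(spec: LibrarySpec) -> List[CompoundRecord]:
    """Draw a reproducible synthetic compound library from the spec."""
    rng = np.random.default_rng(spec.seed)
    cats = list(spec.ionization_proportions)
    probs = np.array([spec.ionization_proportions[c] for c in cats])
    compounds: List[CompoundRecord] = []
    for i in range(spec.n_compounds):
        category = str(rng.choice(cats, p=probs))
        ion = _sample_ionization(rng, category)
        assert classify_ionization(ion) == category
        mw = float(_trunc_normal(rng, spec.mw_mean, spec.mw_sd, *spec.mw_range))
        logd = float(_trunc_normal(rng, spec.logd_mean, spec.logd_sd, *spec.logd_range))
        papp = 10.0 ** rng.normal(spec.log_papp_mean, spec.log_papp_sd)
        s_aq = max(_lognormal10(rng, spec.s_aq_median, spec.s_aq_log_sd), 1e-4)
        clint = _lognormal10(rng, spec.clint_median, spec.clint_log_sd)
        if rng.random() < spec.fup_tail_weight:
            fup = float(
                np.clip(_lognormal10(rng, spec.fup_tail_median, spec.fup_tail_log_sd),
                        1e-3, 0.0199)
            )
        else:
            fup = float(
                np.clip(_lognormal10(rng, spec.fup_main_median, spec.fup_main_log_sd),
                        0.02, 1.0)
            )
        bp = float(np.clip(_lognormal10(rng, spec.bp_median, spec.bp_log_sd),
                           *spec.bp_range))
        s_fassif = s_fessif = None
        if rng.random() < spec.biorelevant_fraction:
            sr_true = _lognormal10(rng, 0.5, 0.3)
            s_fassif = s_aq * (1.0 + sr_true * 3.0)
            s_fessif = s_aq * (1.0 + sr_true * 15.0) * 10.0 ** rng.normal(0.0, 0.05)
        compounds.append(
            CompoundRecord(
                compound_id=f"SYN{i:04d}",
                in_vitro=InVitroInputs(
                    logd74=logd, s_aq=s_aq, papp_llcpk1=float(papp),
                    clint_heps=clint, fup=fup, bp=bp, mw=mw,
                    s_fassif=s_fassif, s_fessif=s_fessif,
                ),
                ionization=ion,
            )
        )
    return compounds


def _analytic_fabs(compound: CompoundRecord, phys: RatPhysiology) -> float:
    """Closed-form fraction absorbed for a solution in a first-order transit
    chain: Fabs = 1 - prod_i (1 + ka_i/kt_i)^-1."""
    gut = default_acat_config()
    solubility = build_solubility_model(compound)
    kt, ka, _, _ = _compartment_constants(compound, gut, solubility)
    return 1.0 - float(np.prod(1.0 / (1.0 + ka / kt)))


def generate_observations(
    library: Sequence[CompoundRecord],
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
    phys: Optional[RatPhysiology] = None,
    scaling_phys: Optional[RatPhysiologyConstants] = None,
    spec: Optional[LibrarySpec] = None,
    routes: Sequence[str] = ("IV", "PO"),
) -> List[StudyArm]:
    """Pseudo-observed study arms from the package's own forward model.

    For each compound, a "true" in vivo intrinsic clearance is drawn by
    perturbing the in vitro value (direct-scaling incubation assumption),
    the reduced forward model supplies noise-free PK parameters, and
    multiplicative lognormal observation noise is applied. With all GSDs at
    1 the observations are exactly self-consistent with direct scaling.
    """
    noise = noise or NoiseModel()
    phys = phys or default_physiology()
    scaling_phys = scaling_phys or RatPhysiologyConstants()
    spec = spec or LibrarySpec()
    rng = np.random.default_rng(seed)
    arms: List[StudyArm] = []

    def factor(gsd: float) -> float:
        return float(math.exp(math.log(gsd) * rng.normal())) if gsd > 1 else 1.0

    for compound in library:
        iv_data = compound.in_vitro
        category = classify_ionization(compound.ionization)
        # 'true' in vivo unbound intrinsic clearance: in vitro value under the
        # direct-scaling assumption, perturbed multiplicatively
        clint_u = unbound_clint(iv_data.clint_heps, iv_data.fup)
        clint_true_wb = scale_to_whole_body(clint_u, scaling_phys) * factor(noise.clint_gsd)
        fub = iv_data.fup / iv_data.bp
        qh = scaling_phys.qh
        cl_blood = qh * fub * clint_true_wb / (qh + fub * clint_true_wb)
        cl_true = cl_blood * iv_data.bp
        kps = compute_kp_set(compound, iv_data.fup, iv_data.bp, phys)
        vss_true = compute_vss(kps, phys, iv_data.bp)
        fh = 1.0 - cl_blood / qh
        fabs = _analytic_fabs(compound, phys)
        foral_true = min(fabs * fh, 1.0)

        for route in routes:
            n_arms = 1 + int(rng.random() < spec.extra_arm_prob)
            lo, hi = spec.iv_dose_range if route == "IV" else spec.po_dose_range
            for _ in range(n_arms):
                dose = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                obs_cl = cl_true * factor(noise.gsd_cl)
                obs_vss = vss_true * factor(noise.gsd_vss)
                if route == "IV":
                    auc = dose * 1e6 / (obs_cl * 60.0)
                    cmax = dose / (vss_true * 1000.0) * 1e6 * factor(noise.gsd_cmax)
                    arms.append(
                        StudyArm(
                            compound_id=compound.compound_id, route="IV", dose=dose,
                            formulation="solution",
                            observed_cl=obs_cl, observed_vss=obs_vss,
                            observed_aucinf=auc * factor(noise.gsd_auc),
                            observed_cmax=cmax,
                        )
                    )
                else:
                    auc_po = foral_true * dose * 1e6 / (cl_true * 60.0)
                    ke = cl_true / (vss_true * 1000.0) * 60.0  # 1/h
                    cmax_po = (
                        foral_true * dose / (vss_true * 1000.0) * 1e6
                        * math.exp(-ke * 0.5)
                    )
                    arms.append(
                        StudyArm(
                            compound_id=compound.compound_id, route="PO", dose=dose,
                            formulation="solution" if rng.random() < 0.7 else "suspension",
                            observed_aucinf=auc_po * factor(noise.gsd_auc),
                            observed_cmax=cmax_po * factor(noise.gsd_cmax),
                            observed_foral=min(foral_true * factor(noise.gsd_auc), 1.4),
                        )
                    )
    return arms
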