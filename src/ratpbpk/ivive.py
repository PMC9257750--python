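"""In vitro to in vivo extrapolation of hepatic clearance.

Forward path: incubation-binding correction (``compute_fu_inc``), unbound
intrinsic clearance, whole-body scaling, and the well-stirred liver model.
Reverse path: back-calculation of the unbound hepatocyte intrinsic clearance
from an observed systemic plasma clearance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "RatPhysiologyConstants",
    "ScalingMethod",
    "ClearanceInputs",
    "FlowLimitExceededError",
    "SCALING_METHODS",
    "compute_fu_inc",
    "unbound_clint",
    "scale_to_whole_body",
    "well_stirred_cl",
    "back_calculate_clint",
    "predict_plasma_cl",
]

SCALING_METHODS = (
    "direct",
    "dilution",
    "unbound",
    "austin",
    "back_calculated",
    "external_predicted",
)

#: Austin-type nonspecific hepatocyte binding: log10((1-fu)/fu) = 0.4*L - 1.38
AUSTIN_SLOPE = 0.4
AUSTIN_INTERCEPT = 1.38


class FlowLimitExceededError(ValueError):
    """Observed hepatic blood clearance is at or above liver blood flow, so
    no finite intrinsic clearance can reproduce it."""


@dataclass(frozen=True)
class RatPhysiologyConstants:
    """Scalar physiological constants for clearance scaling.

    qh: hepatic blood flow (mL/min/kg); lw: liver weight (g/kg);
    hpgl: 1e6 hepatocytes per g liver; bw: body weight (kg).
    """

    qh: float = 60.0
    lw: float = 40.0
    hpgl: float = 120.0
    bw: float = 0.25

    def __post_init__(self) -> None:
        for name in ("qh", "lw", "hpgl", "bw"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def whole_body_factor(self) -> float:
        """uL/min/1e6 cells -> mL/min/kg conversion (4.8 at defaults)."""
        return self.hpgl * self.lw / 1000.0


@dataclass(frozen=True)
class ScalingMethod:
    """Named incubation-binding assumption; ``df`` is the protein dilution
    factor used by the dilution method only."""

    name: str
    df: float = 0.1

    def __post_init__(self) -> None:
        if self.name not in SCALING_METHODS:
            raise ValueError(f"unknown scaling method {self.name!r}")
        if not (0.0 < self.df <= 1.0):
            raise ValueError(f"df must be in (0, 1], got {self.df}")


@dataclass(frozen=True)
class ClearanceInputs:
    """Compound-side inputs for clearance scaling.

    ``logd_or_logp`` should be logP for basic compounds when available and
    logD(7.4) otherwise (only the Austin method consumes it).
    """

    clint_heps: float
    fup: float
    bp: float
    logd_or_logp: float = 0.0
    ionization_category: str = "neutral"
    is_logp: bool = False

    def __post_init__(self) -> None:
        if self.clint_heps < 0:
            raise ValueError("clint_heps must be >= 0")
        if not (0.0 < self.fup <= 1.0):
            raise ValueError(f"fup must be in (0, 1], got {self.fup}")
        if self.bp <= 0:
            raise ValueError(f"bp must be > 0, got {self.bp}")


def compute_fu_inc(method: ScalingMethod, inputs: ClearanceInputs) -> float:
    """Fraction unbound in the hepatocyte incubation under the given
    scaling assumption.

    direct:   fu_inc = fup
    dilution: fu_inc = 1 / (1 + df * (1/fup - 1))
    unbound:  fu_inc = 1
    austin:   fu_inc = 1 / (1 + 10**(0.4*L - 1.38)), L = logP (bases) or logD
    """
    name = method.name
    if name in ("unbound", "back_calculated", "external_predicted"):
        # back-calculated / external clearances are already unbound estimates
        return 1.0
    if name == "direct":
        return inputs.fup
    if name == "dilution":
        return 1.0 / (1.0 + method.df * (1.0 / inputs.fup - 1.0))
    if name == "austin":
        if inputs.ionization_category == "basic" and not inputs.is_logp:
            warnings.warn(
                "Austin fu_inc for a basic compound should use logP; "
                "falling back to the supplied logD7.4",
                stacklevel=2,
            )
        lipophilicity = inputs.logd_or_logp
        return 1.0 / (1.0 + 10.0 ** (AUSTIN_SLOPE * lipophilicity - AUSTIN_INTERCEPT))
    raise ValueError(f"unknown scaling method {name!r}")


def unbound_clint(clint_heps: float, fu_inc: float) -> float:
    """Binding-corrected intrinsic clearance (uL/min/1e6 cells)."""
    if not (0.0 < fu_inc <= 1.0):
        raise ValueError(f"fu_inc must be in (0, 1], got {fu_inc}")
    if clint_heps < 0:
        raise ValueError("clint_heps must be >= 0")
    return clint_heps / fu_inc


def scale_to_whole_body(
    clint_u: float, phys: Optional[RatPhysiologyConstants] = None
) -> float:
    """Scale a per-cell unbound intrinsic clearance (uL/min/1e6 cells) to a
    whole-body value (mL/min/kg) via hepatocellularity and liver weight."""
    if clint_u < 0:
        raise ValueError("clint_u must be >= 0")
    phys = phys or RatPhysiologyConstants()
    return clint_u * phys.whole_body_factor


def well_stirred_cl(
    clint_u_wb: float,
    fup: float,
    bp: float,
    phys: Optional[RatPhysiologyConstants] = None,
) -> float:
    """Forward well-stirred hepatic model: plasma clearance (mL/min/kg) from
    a whole-body unbound intrinsic clearance (mL/min/kg)."""
    if clint_u_wb < 0:
        raise ValueError("clint_u_wb must be >= 0")
    phys = phys or RatPhysiologyConstants()
    fub = fup / bp
    cl_blood = phys.qh * fub * clint_u_wb / (phys.qh + fub * clint_u_wb)
    return cl_blood * bp


def back_calculate_clint(
    cl_plasma_obs: float,
    fe: float,
    fup: float,
    bp: float,
    phys: Optional[RatPhysiologyConstants] = None,
    flow_margin: float = 0.99,
) -> float:
    """Invert the well-stirred model: unbound hepatocyte intrinsic clearance
    (uL/min/1e6 cells) from an observed plasma clearance (mL/min/kg).

    ``fe`` is the fraction excreted renally (removed before inversion).
    Raises :class:`FlowLimitExceededError` when the implied hepatic blood
    clearance reaches ``flow_margin * qh``; such arms are excluded upstream.
    """
    if cl_plasma_obs < 0:
        raise ValueError("cl_plasma_obs must be >= 0")
    if not (0.0 <= fe <= 1.0):
        raise ValueError(f"fe must be in [0, 1], got {fe}")
    phys = phys or RatPhysiologyConstants()
    cl_h = cl_plasma_obs * (1.0 - fe)
    cl_h_blood = cl_h / bp
    if cl_h_blood >= flow_margin * phys.qh:
        raise FlowLimitExceededError(
            f"hepatic blood clearance {cl_h_blood:.3g} mL/min/kg is at or above "
            f"{flow_margin:.2f} x Qh ({phys.qh} mL/min/kg)"
        )
    fub = fup / bp
    clint_u_wb = phys.qh * cl_h_blood / (fub * (phys.qh - cl_h_blood))
    return clint_u_wb / phys.whole_body_factor


def predict_plasma_cl(
    method: ScalingMethod,
    inputs: ClearanceInputs,
    phys: Optional[RatPhysiologyConstants] = None,
) -> float:
    """Convenience chain: fu_inc -> unbound CLint -> whole body -> plasma CL."""
    phys = phys or RatPhysiologyConstants()
    fu_inc = compute_fu_inc(method, inputs)
    clint_u = unbound_clint(inputs.clint_heps, fu_inc)
    clint_u_wb = scale_to_whole_body(clint_u, phys)
    return well_stirred_cl(clint_u_wb, inputs.fup, inputs.bp, phys)
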