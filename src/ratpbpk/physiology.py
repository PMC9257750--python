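"""Rat whole-body physiology: tissue volumes, blood flows, and tissue
composition data for mechanistic partition-coefficient prediction.

The numbers shipped here are a versioned config assembled from standard
literature compendia of rat physiology and tissue composition; everything is
overridable via YAML so alternative generations can be swapped in. The only
hard constraint honoured by the defaults is a total hepatic blood flow of
60 mL/min/kg (arterial + portal), matching the scalar constants used in
clearance scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Optional

import yaml

__all__ = [
    "TISSUES",
    "TissueComposition",
    "RatPhysiology",
    "default_physiology",
    "load_physiology",
    "save_physiology",
]

#: the 11 perfusion-limited tissue compartments
TISSUES = (
    "adipose",
    "bone",
    "brain",
    "gut",
    "heart",
    "kidney",
    "liver",
    "lung",
    "muscle",
    "skin",
    "spleen",
)

#: tissues whose venous outflow drains into the portal vein (-> liver)
PORTAL_TISSUES = ("gut", "spleen")


@dataclass(frozen=True)
class TissueComposition:
    """Volume, perfusion, and composition of one tissue.

    volume: mL/kg body weight; blood_flow: mL/min/kg (for liver this is the
    *arterial* flow only — portal inflow comes from gut and spleen outflow);
    f_ew/f_iw: extra-/intracellular water volume fractions; f_nl/f_np:
    neutral lipid and neutral phospholipid fractions; ap: acidic
    phospholipid content (mg/g); ra_albumin / ra_lipoprotein:
    tissue-to-plasma protein concentration ratios; ph_iw: intracellular pH.
    """

    name: str
    volume: float
    blood_flow: float
    f_ew: float
    f_iw: float
    f_nl: float
    f_np: float
    ap: float
    ra_albumin: float
    ra_lipoprotein: float
    ph_iw: float = 7.0

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.blood_flow <= 0:
            raise ValueError(f"{self.name}: volume and blood_flow must be > 0")
        for fname in ("f_ew", "f_iw", "f_nl", "f_np"):
            v = getattr(self, fname)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{self.name}.{fname} must be in [0, 1], got {v}")
        if self.ap < 0:
            raise ValueError(f"{self.name}.ap must be >= 0")


@dataclass(frozen=True)
class RatPhysiology:
    """Whole-body rat physiology for the disposition and absorption models."""

    tissues: Dict[str, TissueComposition]
    v_venous: float = 49.3  # mL/kg
    v_arterial: float = 24.7  # mL/kg
    hematocrit: float = 0.46
    bw: float = 0.25  # kg
    ph_plasma: float = 7.4
    ph_rbc: float = 7.22
    # erythrocyte composition (fractions; ap in mg/g)
    rbc_f_iw: float = 0.603
    rbc_f_nl: float = 0.0017
    rbc_f_np: float = 0.0029
    rbc_ap: float = 0.5
    # plasma lipid fractions
    plasma_f_nl: float = 0.0023
    plasma_f_np: float = 0.0013

    def __post_init__(self) -> None:
        missing = [t for t in TISSUES if t not in self.tissues]
        if missing:
            raise ValueError(f"physiology is missing tissues: {missing}")
        if not (0.0 < self.hematocrit < 1.0):
            raise ValueError("hematocrit must be in (0, 1)")
        if self.v_venous <= 0 or self.v_arterial <= 0:
            raise ValueError("blood volumes must be > 0")

    @property
    def qh(self) -> float:
        """Total hepatic blood flow (arterial + portal), mL/min/kg."""
        return (
            self.tissues["liver"].blood_flow
            + sum(self.tissues[t].blood_flow for t in PORTAL_TISSUES)
        )

    @property
    def cardiac_output(self) -> float:
        """Sum of all arterial tissue flows (lung is in series), mL/min/kg."""
        return sum(t.blood_flow for name, t in self.tissues.items() if name != "lung")

    @property
    def v_blood(self) -> float:
        return self.v_venous + self.v_arterial

    @property
    def v_plasma(self) -> float:
        return self.v_blood * (1.0 - self.hematocrit)


# volume (mL/kg), arterial flow (mL/min/kg), f_ew, f_iw, f_nl, f_np,
# ap (mg/g), ra_albumin, ra_lipoprotein
_DEFAULT_TISSUE_TABLE = {
    "adipose": (76.0, 19.0, 0.135, 0.017, 0.853, 0.0016, 0.40, 0.049, 0.068),
    "bone":    (41.0, 25.0, 0.100, 0.346, 0.017, 0.0017, 0.67, 0.100, 0.050),
    "brain":   (5.7, 6.5, 0.162, 0.620, 0.039, 0.0015, 0.40, 0.048, 0.041),
    "gut":     (27.0, 45.0, 0.282, 0.475, 0.038, 0.0125, 2.41, 0.158, 0.141),
    "heart":   (3.3, 16.0, 0.320, 0.456, 0.014, 0.0111, 2.25, 0.157, 0.160),
    "kidney":  (7.3, 37.0, 0.273, 0.483, 0.012, 0.0240, 5.03, 0.130, 0.137),
    "liver":   (36.6, 10.0, 0.161, 0.573, 0.014, 0.0240, 4.56, 0.086, 0.161),
    "lung":    (5.0, 282.5, 0.336, 0.446, 0.022, 0.0128, 3.91, 0.212, 0.168),
    "muscle":  (404.0, 90.0, 0.118, 0.630, 0.010, 0.0072, 1.53, 0.064, 0.059),
    "skin":    (190.0, 29.0, 0.382, 0.291, 0.060, 0.0044, 1.32, 0.277, 0.096),
    "spleen":  (2.0, 5.0, 0.207, 0.579, 0.0077, 0.0113, 3.18, 0.097, 0.207),
}


def default_physiology() -> RatPhysiology:
    """Default rat physiology (0.25 kg rat, Qh = 60 mL/min/kg)."""
    tissues = {
        name: TissueComposition(name, *row)
        for name, row in _DEFAULT_TISSUE_TABLE.items()
    }
    return RatPhysiology(tissues=tissues)


def save_physiology(phys: RatPhysiology, path: str) -> None:
    """Serialize a physiology to a YAML file."""
    payload = asdict(phys)
    payload["tissues"] = {k: asdict(v) for k, v in phys.tissues.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_physiology(path: str) -> RatPhysiology:
    """Load a physiology from a YAML file written by :func:`save_physiology`."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    tissues = {
        name: TissueComposition(**row) for name, row in payload.pop("tissues").items()
    }
    return RatPhysiology(tissues=tissues, **payload)
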