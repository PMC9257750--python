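"""Domain types for compounds and dosing experiments, compound classification
rules, and the permeability correlations used to derive effective intestinal
permeability from monolayer assay data.

Classification categories
-------------------------
ionization : ``{"acidic", "basic", "neutral", "zwitterion"}``
ECCS       : ``{"1a", "1b", "2", "3a", "3b", "4"}``
clearance  : ``{"very_low", "low", "moderate", "high"}``
binding    : ``{"high", "moderate"}``
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

__all__ = [
    "ClassificationError",
    "IonizationProfile",
    "InVitroInputs",
    "CompoundRecord",
    "StudyArm",
    "classify_ionization",
    "classify_eccs",
    "classify_clearance",
    "classify_binding",
    "papp_to_peff_human",
    "peff_human_to_rat",
]

#: permeability threshold separating "high" from "low" ECCS permeability, cm/s
ECCS_PAPP_THRESHOLD = 5e-6
#: molecular weight split for the ECCS acid/zwitterion branch, g/mol
ECCS_MW_THRESHOLD = 400.0
#: slope / intercept of the log-log monolayer-to-jejunal permeability fit;
#: output is expressed in 1e-4 cm/s when the input is in cm/s
PEFF_SLOPE = 0.607
PEFF_INTERCEPT = 2.014
#: species scaling factor applied to human effective permeability
PEFF_RAT_FACTOR = 1.14

CLEARANCE_BINS = ((6.0, "very_low"), (18.0, "low"), (42.0, "moderate"))
BINDING_FUP_THRESHOLD = 0.02


class ClassificationError(ValueError):
    """Raised when a compound cannot be assigned to a category."""


def _check_fraction(name: str, value: Optional[float]) -> None:
    if value is not None and not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value!r}")


@dataclass(frozen=True)
class IonizationProfile:
    """Species fractions at plasma pH 7.4 plus the underlying pKa values.

    ``pka_list`` holds ``(value, kind)`` pairs with ``kind in {"acid", "base"}``.
    """

    f_anion: Optional[float] = None
    f_cation: Optional[float] = None
    f_union: Optional[float] = None
    f_zwitter: Optional[float] = None
    pka_list: Tuple[Tuple[float, str], ...] = ()

    def __post_init__(self) -> None:
        for name in ("f_anion", "f_cation", "f_union", "f_zwitter"):
            _check_fraction(name, getattr(self, name))
        fracs = (self.f_anion, self.f_cation, self.f_union, self.f_zwitter)
        if all(f is not None for f in fracs):
            total = sum(fracs)  # type: ignore[arg-type]
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"ionization fractions sum to {total}, expected 1")
        for value, kind in self.pka_list:
            if kind not in ("acid", "base"):
                raise ValueError(f"pKa kind must be 'acid' or 'base', got {kind!r}")
        object.__setattr__(self, "pka_list", tuple(tuple(p) for p in self.pka_list))

    def acid_pkas(self) -> Tuple[float, ...]:
        return tuple(v for v, k in self.pka_list if k == "acid")

    def base_pkas(self) -> Tuple[float, ...]:
        return tuple(v for v, k in self.pka_list if k == "base")


@dataclass(frozen=True)
class InVitroInputs:
    """Minimal measured input set needed for a bottom-up simulation.

    Units: ``s_aq``/``s_fassif``/``s_fessif`` in ug/mL, ``papp_llcpk1`` in
    cm/s, ``clint_heps`` in uL/min/1e6 cells, ``mw`` in g/mol; ``fup`` and
    ``bp`` are dimensionless.
    """

    logd74: float
    s_aq: float
    papp_llcpk1: float
    clint_heps: float
    fup: float
    bp: float
    mw: float
    s_fassif: Optional[float] = None
    s_fessif: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.fup <= 1.0):
            raise ValueError(f"fup must be in (0, 1], got {self.fup}")
        if self.bp <= 0:
            raise ValueError(f"bp must be > 0, got {self.bp}")
        if self.mw <= 0:
            raise ValueError(f"mw must be > 0, got {self.mw}")
        for name in ("s_aq", "clint_heps", "papp_llcpk1"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("s_fassif", "s_fessif"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0 when present")


@dataclass(frozen=True)
class CompoundRecord:
    """One molecule: identifier, measured/predicted inputs, ionization."""

    compound_id: str
    in_vitro: InVitroInputs
    ionization: IonizationProfile
    smiles: Optional[str] = None


@dataclass(frozen=True)
class StudyArm:
    """One dosing experiment with its observed NCA parameters.

    ``dose`` is in mg/kg; observed values use mL/min/kg (CL), L/kg (Vss),
    ng*h/mL (AUCinf), ng/mL (Cmax) and fractions (Foral, fe).
    """

    compound_id: str
    route: str
    dose: float
    formulation: str = "solution"
    observed_cl: Optional[float] = None
    observed_vss: Optional[float] = None
    observed_aucinf: Optional[float] = None
    observed_cmax: Optional[float] = None
    observed_foral: Optional[float] = None
    fe: float = 0.0

    def __post_init__(self) -> None:
        if self.route not in ("IV", "PO"):
            raise ValueError(f"route must be 'IV' or 'PO', got {self.route!r}")
        if self.formulation not in ("solution", "suspension"):
            raise ValueError(f"unknown formulation {self.formulation!r}")
        if self.dose <= 0:
            raise ValueError(f"dose must be > 0, got {self.dose}")
        if not (0.0 <= self.fe <= 1.0):
            raise ValueError(f"fe must be in [0, 1], got {self.fe}")


# ---------------------------------------------------------------------------
# classification rules
# ---------------------------------------------------------------------------

def classify_ionization(profile: IonizationProfile) -> str:
    """Assign an ionization category from the species fractions at pH 7.4.

    The zwitterion rule (``f_zwitter >= 0.5``) is checked first; acids and
    bases use a strict ``> 0.5`` threshold on their respective fractions.
    When no fraction reaches the threshold the dominant species wins.
    """
    fracs = {
        "acidic": profile.f_anion,
        "basic": profile.f_cation,
        "neutral": profile.f_union,
        "zwitterion": profile.f_zwitter,
    }
    if all(v is None for v in fracs.values()):
        raise ClassificationError("all ionization fractions are missing")
    filled = {k: (0.0 if v is None else v) for k, v in fracs.items()}
    if filled["zwitterion"] >= 0.5:
        return "zwitterion"
    if filled["acidic"] > 0.5:
        return "acidic"
    if filled["basic"] > 0.5:
        return "basic"
    if filled["neutral"] > 0.5:
        return "neutral"
    return max(filled, key=filled.get)  # no majority species: dominant wins


def classify_eccs(papp: float, ionization_category: str, mw: float) -> str:
    """Extended clearance classification from permeability, charge and MW.

    High permeability is ``papp >= 5e-6 cm/s`` (boundary inclusive); the
    molecular-weight split at 400 g/mol is inclusive on the low side.
    """
    if papp < 0:
        raise ValueError("papp must be >= 0")
    if mw <= 0:
        raise ValueError("mw must be > 0")
    high_perm = papp >= ECCS_PAPP_THRESHOLD
    if ionization_category in ("acidic", "zwitterion"):
        if high_perm:
            return "1a" if mw <= ECCS_MW_THRESHOLD else "1b"
        return "3a" if mw <= ECCS_MW_THRESHOLD else "3b"
    if ionization_category in ("basic", "neutral"):
        return "2" if high_perm else "4"
    raise ClassificationError(f"unknown ionization category {ionization_category!r}")


def classify_clearance(cl_blood: float) -> str:
    """Bin a systemic blood clearance (mL/min/kg) into four categories.

    Values above the hepatic-flow ceiling (60 mL/min/kg) are clipped into
    ``"high"``.
    """
    if cl_blood < 0:
        raise ValueError(f"cl_blood must be >= 0, got {cl_blood}")
    for upper, label in CLEARANCE_BINS:
        if cl_blood < upper:
            return label
    return "high"


def classify_binding(fup: float) -> str:
    """``"high"`` binding when the plasma unbound fraction is below 2%."""
    if not (0.0 < fup <= 1.0):
        raise ValueError(f"fup must be in (0, 1], got {fup}")
    return "high" if fup < BINDING_FUP_THRESHOLD else "moderate"


# ---------------------------------------------------------------------------
# permeability correlations
# ---------------------------------------------------------------------------

def papp_to_peff_human(papp_llcpk1: float) -> float:
    """Translate LLC-PK1 apparent permeability (cm/s) to human jejunal
    effective permeability in units of 1e-4 cm/s.

    Log-log linear correlation: ``log10(Peff) = 0.607*log10(Papp) + 2.014``.
    The intercept fixes the output unit convention (1e-4 cm/s).
    """
    if papp_llcpk1 <= 0:
        raise ValueError(f"papp must be > 0, got {papp_llcpk1}")
    return 10.0 ** (PEFF_SLOPE * math.log10(papp_llcpk1) + PEFF_INTERCEPT)


def peff_human_to_rat(peff_human: float) -> float:
    """Scale human effective permeability to rat (same units in and out)."""
    if peff_human < 0:
        raise ValueError("peff_human must be >= 0")
    return PEFF_RAT_FACTOR * peff_human
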