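"""CSV schemas for compound and study-arm datasets.

One row per compound / per (compound, route, dose, experiment). Missing
optional values are empty fields. Synthetic and externally supplied
datasets share these schemas, so they are interchangeable in the pipeline.
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence

import pandas as pd

from .compound_model import CompoundRecord, InVitroInputs, IonizationProfile, StudyArm

__all__ = [
    "compounds_to_frame",
    "frame_to_compounds",
    "arms_to_frame",
    "frame_to_arms",
    "write_compounds",
    "read_compounds",
    "write_arms",
    "read_arms",
]

COMPOUND_COLUMNS = [
    "compound_id", "mw", "logd74", "s_aq", "s_fassif", "s_fessif",
    "papp_llcpk1", "clint_heps", "fup", "bp",
    "f_anion", "f_cation", "f_union", "f_zwitter", "pka_acid", "pka_base",
    "clint_predicted", "smiles",
]

ARM_COLUMNS = [
    "compound_id", "route", "dose", "formulation",
    "observed_cl", "observed_vss", "observed_aucinf", "observed_cmax",
    "observed_foral", "fe",
]


def _opt(value) -> Optional[float]:
    if value is None:
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(v) else v


def compounds_to_frame(compounds: Sequence[CompoundRecord]) -> pd.DataFrame:
    rows = []
    for c in compounds:
        iv = c.in_vitro
        ion = c.ionization
        acid = ion.acid_pkas()
        base = ion.base_pkas()
        rows.append(
            {
                "compound_id": c.compound_id, "mw": iv.mw, "logd74": iv.logd74,
                "s_aq": iv.s_aq, "s_fassif": iv.s_fassif, "s_fessif": iv.s_fessif,
                "papp_llcpk1": iv.papp_llcpk1, "clint_heps": iv.clint_heps,
                "fup": iv.fup, "bp": iv.bp,
                "f_anion": ion.f_anion, "f_cation": ion.f_cation,
                "f_union": ion.f_union, "f_zwitter": ion.f_zwitter,
                "pka_acid": acid[0] if acid else None,
                "pka_base": base[0] if base else None,
                "clint_predicted": None, "smiles": c.smiles,
            }
        )
    return pd.DataFrame(rows, columns=COMPOUND_COLUMNS)


def frame_to_compounds(df: pd.DataFrame) -> List[CompoundRecord]:
    required = {"compound_id", "mw", "logd74", "s_aq", "papp_llcpk1",
                "clint_heps", "fup", "bp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"compound table is missing columns: {sorted(missing)}")
    if df["compound_id"].duplicated().any():
        dups = df.loc[df["compound_id"].duplicated(), "compound_id"].tolist()
        raise ValueError(f"duplicate compound_id values: {dups}")
    out = []
    for row in df.to_dict("records"):
        pkas = []
        if _opt(row.get("pka_acid")) is not None:
            pkas.append((float(row["pka_acid"]), "acid"))
        if _opt(row.get("pka_base")) is not None:
            pkas.append((float(row["pka_base"]), "base"))
        out.append(
            CompoundRecord(
                compound_id=str(row["compound_id"]),
                in_vitro=InVitroInputs(
                    logd74=float(row["logd74"]), s_aq=float(row["s_aq"]),
                    papp_llcpk1=float(row["papp_llcpk1"]),
                    clint_heps=float(row["clint_heps"]),
                    fup=float(row["fup"]), bp=float(row["bp"]),
                    mw=float(row["mw"]),
                    s_fassif=_opt(row.get("s_fassif")),
                    s_fessif=_opt(row.get("s_fessif")),
                ),
                ionization=IonizationProfile(
                    f_anion=_opt(row.get("f_anion")),
                    f_cation=_opt(row.get("f_cation")),
                    f_union=_opt(row.get("f_union")),
                    f_zwitter=_opt(row.get("f_zwitter")),
                    pka_list=tuple(pkas),
                ),
                smiles=row.get("smiles") if isinstance(row.get("smiles"), str) else None,
            )
        )
    return out


def arms_to_frame(arms: Sequence[StudyArm]) -> pd.DataFrame:
    rows = [
        {
            "compound_id": a.compound_id, "route": a.route, "dose": a.dose,
            "formulation": a.formulation, "observed_cl": a.observed_cl,
            "observed_vss": a.observed_vss, "observed_aucinf": a.observed_aucinf,
            "observed_cmax": a.observed_cmax, "observed_foral": a.observed_foral,
            "fe": a.fe,
        }
        for a in arms
    ]
    return pd.DataFrame(rows, columns=ARM_COLUMNS)


def frame_to_arms(df: pd.DataFrame) -> List[StudyArm]:
    required = {"compound_id", "route", "dose"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"arm table is missing columns: {sorted(missing)}")
    out = []
    for row in df.to_dict("records"):
        fe = _opt(row.get("fe"))
        out.append(
            StudyArm(
                compound_id=str(row["compound_id"]),
                route=str(row["route"]),
                dose=float(row["dose"]),
                formulation=str(row.get("formulation", "solution") or "solution"),
                observed_cl=_opt(row.get("observed_cl")),
                observed_vss=_opt(row.get("observed_vss")),
                observed_aucinf=_opt(row.get("observed_aucinf")),
                observed_cmax=_opt(row.get("observed_cmax")),
                observed_foral=_opt(row.get("observed_foral")),
                fe=fe if fe is not None else 0.0,
            )
        )
    return out


def write_compounds(compounds: Sequence[CompoundRecord], path: str) -> None:
    compounds_to_frame(compounds).to_csv(path, index=False)


def read_compounds(path: str) -> List[CompoundRecord]:
    return frame_to_compounds(pd.read_csv(path))


def write_arms(arms: Sequence[StudyArm], path: str) -> None:
    arms_to_frame(arms).to_csv(path, index=False)


def read_arms(path: str) -> List[StudyArm]:
    return frame_to_arms(pd.read_csv(path))
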