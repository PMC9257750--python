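"""Noncompartmental analysis and the prediction-success metric panel.

NCA uses the linear-up/log-down trapezoid with terminal-slope extrapolation
(best adjusted-R^2 window of at least three points). The metric panel is
log10-based throughout: AFE (geometric-mean bias), AAFE (geometric-mean
absolute precision), RMSLE, %within-x-fold (boundary inclusive), Lin's
concordance on log10 and linear scales, Spearman rho, and Pearson R^2 on
linear and log10 scales.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "PKParameterSet",
    "MetricPanel",
    "NCAError",
    "nca",
    "fold_error_panel",
    "lambda_z",
    "auc_linear_up_log_down",
]


class NCAError(ValueError):
    """Profile is unusable for noncompartmental analysis."""


@dataclass
class PKParameterSet:
    """Derived PK parameters for one profile.

    cl mL/min/kg; vss L/kg; aucinf ng*h/mL; cmax ng/mL; foral fraction.
    ``warnings`` collects NCA quality flags (e.g. non-identifiable terminal
    slope); ``extras`` carries lambda_z, MRT, and extrapolated fractions.
    """

    route: str
    cl: Optional[float] = None
    vss: Optional[float] = None
    aucinf: Optional[float] = None
    cmax: Optional[float] = None
    foral: Optional[float] = None
    warnings: Tuple[str, ...] = ()
    extras: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("cl", "vss", "aucinf", "cmax"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.foral is not None and not (0.0 <= self.foral <= 1.4 + 1e-9):
            raise ValueError(f"foral outside the tolerated [0, 1.4]: {self.foral}")


@dataclass(frozen=True)
class MetricPanel:
    """Prediction-success metrics for one predicted-vs-observed vector pair."""

    n: int
    pct_2fe: float
    pct_3fe: float
    pct_10fe: float
    afe: float
    aafe: float
    rmsle: float
    ccc_log: float
    ccc_lin: float
    spearman_rho: float
    r2_linear: float
    r2_log: float
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.aafe < 1.0 - 1e-9:
            raise ValueError(f"AAFE must be >= 1, got {self.aafe}")
        if not (
            -1e-9 <= self.pct_2fe <= self.pct_3fe + 1e-9
            and self.pct_3fe <= self.pct_10fe + 1e-9
            and self.pct_10fe <= 100.0 + 1e-9
        ):
            raise ValueError("%xfe values must be nondecreasing in x and <= 100")

    def as_dict(self) -> Dict[str, float]:
        return {
            "n": self.n, "pct_2fe": self.pct_2fe, "pct_3fe": self.pct_3fe,
            "pct_10fe": self.pct_10fe, "afe": self.afe, "aafe": self.aafe,
            "rmsle": self.rmsle, "ccc_log": self.ccc_log, "ccc_lin": self.ccc_lin,
            "spearman_rho": self.spearman_rho, "r2_linear": self.r2_linear,
            "r2_log": self.r2_log, "n_excluded": self.n_excluded,
        }


# ---------------------------------------------------------------------------
# noncompartmental analysis
# ---------------------------------------------------------------------------

def auc_linear_up_log_down(t: np.ndarray, c: np.ndarray) -> Tuple[float, float]:
    """(AUC, AUMC) to the last time point: linear trapezoid on rising or
    zero-crossing segments, log trapezoid on strictly declining ones."""
    auc = 0.0
    aumc = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if dt <= 0:
            continue
        if c1 > 0 and c2 > 0 and c2 < c1:
            k = math.log(c1 / c2) / dt
            auc += (c1 - c2) / k
            aumc += (t[i] * c1 - t[i + 1] * c2) / k + (c1 - c2) / k ** 2
        else:
            auc += 0.5 * (c1 + c2) * dt
            aumc += 0.5 * (t[i] * c1 + t[i + 1] * c2) * dt
    return auc, aumc


def lambda_z(
    t: np.ndarray,
    c: np.ndarray,
    max_points: int = 12,
) -> Optional[Tuple[float, float, int]]:
    """Terminal elimination rate constant by log-linear regression.

    Tries windows of the last 3..max_points positive concentrations and
    keeps the best adjusted R^2. Returns (lambda_z, adjusted_r2, n_points)
    or None when no window gives a positive slope.
    """
    mask = c > 0
    t_pos, c_pos = t[mask], np.log(c[mask])
    n = len(t_pos)
    if n < 3:
        return None
    best = None
    for k in range(3, min(n, max_points) + 1):
        res = stats.linregress(t_pos[-k:], c_pos[-k:])
        lam = -res.slope
        if lam <= 0:
            continue
        r2 = res.rvalue ** 2
        adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2)
        if best is None or adj > best[1]:
            best = (lam, adj, k)
    return best


def nca(
    time_h: np.ndarray,
    conc: np.ndarray,
    dose: float,
    route: str,
    auc_iv_ref: Optional[float] = None,
    dose_iv_ref: Optional[float] = None,
) -> PKParameterSet:
    """Noncompartmental parameters from a concentration-time profile.

    time in h, conc in ng/mL, dose in mg/kg. For IV profiles CL = Dose/AUCinf
    and Vss = CL * MRT; for PO profiles Foral is the dose-normalized AUC
    ratio against the supplied IV reference.
    """
    t = np.asarray(time_h, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.shape != c.shape or t.ndim != 1:
        raise NCAError("time and concentration must be 1-D arrays of equal length")
    if np.count_nonzero(c > 0) < 3:
        raise NCAError("need at least 3 positive concentrations")

    flags = []
    auc_last, aumc_last = auc_linear_up_log_down(t, c)
    pos = np.nonzero(c > 0)[0]
    t_last, c_last = t[pos[-1]], c[pos[-1]]
    lam = lambda_z(t, c)
    if lam is None:
        flags.append("lambda_z_not_identifiable")
        aucinf, aumcinf = auc_last, aumc_last
        lam_val = math.nan
    else:
        lam_val, adj_r2, n_lam = lam
        aucinf = auc_last + c_last / lam_val
        aumcinf = aumc_last + c_last * t_last / lam_val + c_last / lam_val ** 2
        if (aucinf - auc_last) / aucinf > 0.5:
            flags.append("auc_extrapolation_above_50pct")

    cmax = float(np.max(c))
    extras = {
        "lambda_z_per_h": lam_val,
        "auc_last": auc_last,
        "auc_extrap_frac": (aucinf - auc_last) / aucinf if aucinf > 0 else math.nan,
    }
    cl = vss = foral = None
    if route == "IV":
        # dose mg/kg = 1e6 ng/kg; AUC ng*h/mL -> CL mL/h/kg -> mL/min/kg
        cl = dose * 1e6 / aucinf / 60.0
        mrt_h = aumcinf / aucinf
        vss = cl * mrt_h * 60.0 / 1000.0  # mL/kg -> L/kg
        extras["mrt_h"] = mrt_h
    elif route == "PO":
        if auc_iv_ref is not None and dose_iv_ref is not None and auc_iv_ref > 0:
            foral = (aucinf / dose) / (auc_iv_ref / dose_iv_ref)
            foral = min(foral, 1.4)
    else:
        raise NCAError(f"route must be 'IV' or 'PO', got {route!r}")
    return PKParameterSet(
        route=route, cl=cl, vss=vss, aucinf=aucinf, cmax=cmax, foral=foral,
        warnings=tuple(flags), extras=extras,
    )


# ---------------------------------------------------------------------------
# prediction-success metrics
# ---------------------------------------------------------------------------

def _ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    return float(2.0 * cov / denom) if denom > 0 else math.nan


def fold_error_panel(
    pred: Sequence[float],
    obs: Sequence[float],
    folds: Sequence[float] = (2.0, 3.0, 10.0),
) -> MetricPanel:
    """Full prediction-success panel for positive predicted/observed pairs.

    Non-positive or non-finite pairs are excluded pairwise; the excluded
    count is reported on the panel.
    """
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape:
        raise ValueError("pred and obs must have equal length")
    ok = np.isfinite(p) & np.isfinite(o) & (p > 0) & (o > 0)
    n_excluded = int(np.sum(~ok))
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded} non-positive/non-finite pairs from the panel",
            stacklevel=2,
        )
    p, o = p[ok], o[ok]
    if len(p) < 2:
        raise ValueError("need at least 2 valid pairs")

    log_ratio = np.log10(p / o)
    fe = np.maximum(p / o, o / p)
    pcts = {f: 100.0 * float(np.mean(fe <= f + 1e-12)) for f in folds}
    lp, lo = np.log10(p), np.log10(o)
    rho = stats.spearmanr(p, o).statistic if len(p) > 2 else (
        1.0 if np.all(np.sign(np.diff(p)) == np.sign(np.diff(o))) else -1.0
    )
    r_lin = stats.pearsonr(p, o).statistic if np.std(p) > 0 and np.std(o) > 0 else math.nan
    r_log = stats.pearsonr(lp, lo).statistic if np.std(lp) > 0 and np.std(lo) > 0 else math.nan
    return MetricPanel(
        n=len(p),
        pct_2fe=pcts.get(2.0, math.nan),
        pct_3fe=pcts.get(3.0, math.nan),
        pct_10fe=pcts.get(10.0, math.nan),
        afe=float(10.0 ** np.mean(log_ratio)),
        aafe=float(10.0 ** np.mean(np.abs(log_ratio))),
        rmsle=float(np.sqrt(np.mean(log_ratio ** 2))),
        ccc_log=_ccc(lp, lo),
        ccc_lin=_ccc(p, o),
        spearman_rho=float(rho),
        r2_linear=float(r_lin ** 2) if math.isfinite(r_lin) else math.nan,
        r2_log=float(r_log ** 2) if math.isfinite(r_log) else math.nan,
        n_excluded=n_excluded,
    )
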