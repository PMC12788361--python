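"""Standardized cubic coupling regression of plantar pressure on joint angle.

For each joint and side, the kinematic-kinetic coupling is modeled as an
ordinary-least-squares fit of the standardized ipsilateral plantar
pressure on the raw powers of the standardized joint angle:

    z_P = b0 + b1 * z_theta + b2 * z_theta^2 + b3 * z_theta^3 + eps

Both variables are z-scored over the analyzed cycle before the powers are
formed; the powers themselves are *not* re-standardized, so the
first-order unstandardized coefficient B(X1) equals its standardized
counterpart Beta(X1) identically, while higher orders differ (Beta_j =
B_j * SD(X_j) with the response already unit-SD). Inference is plain OLS:
two-sided t tests and 90% confidence intervals on n - 4 degrees of
freedom. Within-cycle samples are serially dependent; like the source
analysis, no autocorrelation-corrected estimator is substituted - the
lag-1 residual autocorrelation is reported as a diagnostic instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import DataError
from .segmentation import PhaseSegmentation
from .synthetic import ANGLE_CHANNELS, PRESSURE_CHANNEL

__all__ = [
    "TermStats",
    "CouplingFit",
    "ResidualDiagnostics",
    "fit_cubic",
    "residual_diagnostics",
    "fit_all",
    "fits_frame",
]

TERMS = ("X1", "X2", "X3")
N_PARAMS = 4  # intercept + 3 slopes


@dataclass
class TermStats:
    b: float  # unstandardized coefficient on the standardized-angle power
    beta: float  # standardized coefficient
    t: float
    p: float
    ci90: tuple[float, float]


@dataclass
class CouplingFit:
    joint_name: str
    side: str
    n: int
    r: float
    r2: float
    adj_r2: float
    intercept: float
    terms: dict[str, TermStats]
    std_residuals: np.ndarray
    residual_summary: dict[str, float]
    condition_number: float


@dataclass
class ResidualDiagnostics:
    shapiro_stat: float
    shapiro_p: float
    lag1_autocorr: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    degenerate: bool = False


def _zscore(x: np.ndarray, what: str) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise DataError(f"constant {what} series: standardization undefined")
    return (x - x.mean()) / sd


def fit_cubic(
    angle: np.ndarray, pressure: np.ndarray, joint_name: str = "", side: str = ""
) -> CouplingFit:
    """OLS fit of standardized pressure on the cubic standardized-angle basis."""
    a = np.asarray(angle, dtype=float)
    y = np.asarray(pressure, dtype=float)
    if a.shape != y.shape or a.ndim != 1:
        raise DataError("angle and pressure must be 1-D series of equal length")
    n = len(a)
    if n < 10:
        raise DataError(f"insufficient data for a cubic fit (n={n}, need >= 10)")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(y))):
        raise DataError("non-finite samples in regression inputs")

    z = _zscore(a, "angle")
    zy = _zscore(y, "pressure")
    X = np.column_stack([z, z**2, z**3])
    design = sm.add_constant(X)

    cond = float(np.linalg.cond(design))
    if cond > 1e6:
        warnings.warn(
            f"ill-conditioned cubic design (condition number {cond:.3g})", stacklevel=2
        )

    res = sm.OLS(zy, design).fit()
    ci = res.conf_int(alpha=0.10)
    term_sds = X.std(ddof=1, axis=0)  # SD(X1) == 1 by construction
    terms = {
        name: TermStats(
            b=float(res.params[j + 1]),
            beta=float(res.params[j + 1]) * float(term_sds[j]),
            t=float(res.tvalues[j + 1]),
            p=float(res.pvalues[j + 1]),
            ci90=(float(ci[j + 1][0]), float(ci[j + 1][1])),
        )
        for j, name in enumerate(TERMS)
    }

    resid = np.asarray(res.resid)
    rss = float(resid @ resid)
    # an exact fit leaves only rounding noise: keep raw (near-zero)
    # residuals rather than blowing them up by a ~0 scale
    exact = rss < 1e-12 * (n - 1)  # TSS of the standardized response is n-1
    s = np.sqrt(rss / (n - N_PARAMS)) if not exact else 0.0
    std_resid = resid / s if s > 0 else resid
    r2 = float(res.rsquared)
    return CouplingFit(
        joint_name=joint_name,
        side=side,
        n=n,
        r=float(np.sqrt(max(r2, 0.0))),
        r2=r2,
        adj_r2=float(res.rsquared_adj),
        intercept=float(res.params[0]),
        terms=terms,
        std_residuals=std_resid,
        residual_summary={
            "min": float(std_resid.min()),
            "max": float(std_resid.max()),
            "mean": float(std_resid.mean()),
            "sd": float(std_resid.std(ddof=0)),
        },
        condition_number=cond,
    )


def residual_diagnostics(fit: CouplingFit, bins: int = 20) -> ResidualDiagnostics:
    """Normality (Shapiro-Wilk), lag-1 autocorrelation and histogram counts
    of the standardized residuals."""
    r = np.asarray(fit.std_residuals, dtype=float)
    counts, edges = np.histogram(r, bins=bins)
    if np.allclose(r, 0.0):
        return ResidualDiagnostics(
            shapiro_stat=np.nan,
            shapiro_p=np.nan,
            lag1_autocorr=np.nan,
            hist_counts=counts,
            hist_edges=edges,
            degenerate=True,
        )
    stat, p = sps.shapiro(r)
    rc = r - r.mean()
    denom = float(rc @ rc)
    lag1 = float(rc[1:] @ rc[:-1]) / denom if denom > 0 else np.nan
    return ResidualDiagnostics(
        shapiro_stat=float(stat),
        shapiro_p=float(p),
        lag1_autocorr=lag1,
        hist_counts=counts,
        hist_edges=edges,
    )


def fit_all(
    recordings: Mapping[str, pd.DataFrame],
    segmentations: Mapping[str, PhaseSegmentation] | None = None,
) -> list[CouplingFit]:
    """Eight fits (4 joints x 2 sides) of pressure on each ipsilateral
    joint angle, over each side's detected cycle if segmentations are
    given, else over the full recording."""
    fits: list[CouplingFit] = []
    for side in ("left", "right"):
        if side not in recordings:
            raise DataError(f"missing {side} recording")
        df = recordings[side]
        if segmentations is not None:
            seg = segmentations[side]
            lo, hi = seg.cycle_start, seg.cycle_end
        else:
            lo, hi = 0, len(df)
        pressure = df[PRESSURE_CHANNEL].to_numpy()[lo:hi]
        for joint in ANGLE_CHANNELS:
            fits.append(
                fit_cubic(df[joint].to_numpy()[lo:hi], pressure, joint_name=joint, side=side)
            )
    return fits


def fits_frame(fits: list[CouplingFit]) -> pd.DataFrame:
    """Tidy per-term table shaped like the published regression summary."""
    rows = []
    for f in fits:
        for term in TERMS:
            t = f.terms[term]
            rows.append(
                {
                    "side": f.side,
                    "joint": f.joint_name,
                    "term": term,
                    "R": f.r,
                    "R2": f.r2,
                    "adj_R2": f.adj_r2,
                    "B": t.b,
                    "Beta": t.beta,
                    "t": t.t,
                    "p": t.p,
                    "ci90_low": t.ci90[0],
                    "ci90_high": t.ci90[1],
                    "n": f.n,
                }
            )
    return pd.DataFrame(rows)
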