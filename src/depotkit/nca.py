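"""Noncompartmental analysis: terminal slope, AUC, and the flip-flop check.

The terminal elimination rate constant ``lambda_z`` is the negated slope of the
least-squares line through ln C(t) over a terminal window.  Comparing
``lambda_z`` between the subcutaneous (implant) and IV routes diagnoses
flip-flop kinetics: when absorption from the depot is slower than systemic
elimination, the terminal slope of the implant profile reflects the input
process and falls far below the IV terminal slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pkdata_io import PKDataset

__all__ = [
    "NCAResult",
    "estimate_lambda_z",
    "auc_trapezoid",
    "flip_flop_check",
    "group_mean_profile",
    "nca_summary",
]


# slopes this close to zero (1/h) are numerical noise, not a terminal phase
_ZERO_SLOPE = 1e-12


@dataclass
class NCAResult:
    """Terminal-phase regression result for one profile."""

    lambda_z: float | None  # 1/h; None when the slope is non-negative
    n_points_terminal: int
    r2_adj: float
    intercept_ln: float  # ln(ng/mL) at t=0 of the terminal line
    flagged: bool = False  # True when no valid (negative) slope was found


def _regress_loglinear(t: np.ndarray, lnc: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, adjusted r^2 of lnc ~ t."""
    n = len(t)
    slope, intercept = np.polyfit(t, lnc, 1)
    pred = slope * t + intercept
    sst = float(np.sum((lnc - lnc.mean()) ** 2))
    ssr = float(np.sum((lnc - pred) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 1.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    return float(slope), float(intercept), r2_adj


def estimate_lambda_z(
    times,
    concentrations,
    selection: str = "auto",
    window: tuple[int, int] | None = None,
) -> NCAResult:
    """Estimate the terminal elimination rate constant from one profile.

    ``selection="auto"`` scans contiguous terminal windows (suffixes of the
    profile after the global maximum, minimum 3 points, Cmax excluded) and
    keeps the window maximizing adjusted r^2 -- the convention of standard NCA
    software.  ``selection="manual"`` uses ``window=(start_index, stop_index)``
    on the time-sorted profile.

    Concentrations must be positive (BLQ records imputed beforehand).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.shape != c.shape or t.ndim != 1:
        raise ValueError("times and concentrations must be matching 1-D arrays")
    order = np.argsort(t, kind="stable")
    t, c = t[order], c[order]
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0 (impute BLQ values first)")
    lnc = np.log(c)

    if selection == "manual":
        if window is None:
            raise ValueError("manual selection requires window=(start, stop)")
        lo, hi = window
        if hi - lo < 3:
            raise ValueError("terminal window must contain >= 3 points")
        slope, intercept, r2_adj = _regress_loglinear(t[lo:hi], lnc[lo:hi])
        if slope >= -_ZERO_SLOPE:
            return NCAResult(None, hi - lo, r2_adj, intercept, flagged=True)
        return NCAResult(-slope, hi - lo, r2_adj, intercept)

    if selection != "auto":
        raise ValueError(f"unknown selection {selection!r}")

    i_cmax = int(np.argmax(c))
    start_min = i_cmax + 1  # Cmax itself excluded from terminal fit
    n = len(t)
    if n - start_min < 3:
        raise ValueError("need >= 3 quantifiable points after Cmax for lambda_z")
    best: NCAResult | None = None
    for start in range(start_min, n - 2):
        slope, intercept, r2_adj = _regress_loglinear(t[start:], lnc[start:])
        if slope >= -_ZERO_SLOPE:
            continue
        cand = NCAResult(-slope, n - start, r2_adj, intercept)
        if best is None or cand.r2_adj > best.r2_adj + 1e-12:
            best = cand
    if best is None:
        # no window with a declining slope: flag, report widest window stats
        slope, intercept, r2_adj = _regress_loglinear(t[start_min:], lnc[start_min:])
        return NCAResult(None, n - start_min, r2_adj, intercept, flagged=True)
    return best


def auc_trapezoid(
    times,
    concentrations,
    method: str = "linear-up/log-down",
    lambda_z: float | None = None,
) -> dict:
    """AUC by trapezoid rules; extrapolation to infinity when lambda_z given.

    ``method="linear"`` applies the linear trapezoid everywhere;
    ``"linear-up/log-down"`` uses the log trapezoid on strictly declining
    positive segments (exact for exponential decline).  Returns a dict with
    ``auc_last`` and, when ``lambda_z`` is provided, ``auc_inf``.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if len(t) < 2:
        raise ValueError("need >= 2 points for AUC")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    auc = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if method == "linear" or not (c1 > c2 > 0):
            auc += 0.5 * (c1 + c2) * dt
        elif method == "linear-up/log-down":
            auc += (c1 - c2) / np.log(c1 / c2) * dt
        else:
            raise ValueError(f"unknown AUC method {method!r}")
    out = {"auc_last": float(auc)}
    if lambda_z is not None and lambda_z > 0:
        out["auc_inf"] = float(auc + c[-1] / lambda_z)
    return out


def flip_flop_check(lambda_z_sq: float, lambda_z_iv: float) -> dict:
    """Ratio of SQ to IV terminal slopes and the flip-flop verdict (ratio < 1)."""
    if not (lambda_z_sq > 0 and lambda_z_iv > 0):
        raise ValueError("both terminal slopes must be positive")
    ratio = lambda_z_sq / lambda_z_iv
    return {"ratio": float(ratio), "flip_flop": bool(ratio < 1.0)}


def group_mean_profile(dataset: PKDataset, analyte: str, route: str = "IV"):
    """Per-timepoint mean concentration across subjects (sparse-design pooling).

    Used for the IV arm, where each subject contributes few samples and the
    group profile is the NCA substrate.
    """
    sub = dataset.subset(analyte=analyte, route=route)
    by_time: dict[float, list[float]] = {}
    for s in sub.samples:
        if s.concentration is None:
            raise ValueError("impute BLQ values before NCA")
        by_time.setdefault(s.time, []).append(s.concentration)
    times = np.array(sorted(by_time), dtype=float)
    means = np.array([float(np.mean(by_time[t])) for t in times])
    return times, means


def nca_summary(dataset: PKDataset, analyte: str) -> dict:
    """Route-wise lambda_z for one analyte, with the flip-flop comparison.

    IV: mean group profile (sparse pooling).  SQ: median of per-subject
    lambda_z estimates.  The dataset must already have BLQ imputed.
    """
    out: dict = {"analyte": analyte}
    t_iv, c_iv = group_mean_profile(dataset, analyte, "IV")
    res_iv = estimate_lambda_z(t_iv, c_iv)
    out["lambda_z_iv"] = res_iv.lambda_z

    sq = dataset.subset(analyte=analyte, route="SQ")
    per_subject = []
    for sid in sq.subjects():
        prof = sq.subset(subject_id=sid)
        t = [s.time for s in prof.samples]
        c = [s.concentration for s in prof.samples]
        try:
            r = estimate_lambda_z(t, c)
        except ValueError:
            continue
        if r.lambda_z is not None:
            per_subject.append(r.lambda_z)
    out["lambda_z_sq"] = float(np.median(per_subject)) if per_subject else None
    if out["lambda_z_sq"] is not None and out["lambda_z_iv"] is not None:
        out.update(flip_flop_check(out["lambda_z_sq"], out["lambda_z_iv"]))
    return out
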