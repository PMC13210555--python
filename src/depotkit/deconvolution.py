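"""Unit impulse response, analytic convolution, and numerical deconvolution.

Linear-systems PK: with a unit impulse response u(t) (plasma concentration per
ng delivered instantaneously to circulation), an input rate r(t) (ng/h) gives

    C(t) = integral_0^t u(t - tau) r(tau) dtau.

Here u(t) = sum_i c_i exp(-l_i t) is the dose-normalized macro model from the
IV bolus fit.  The input is parameterized as a non-negative step function on a
uniform grid (default 72-h spacing after a day-1 node), for which the
convolution is analytic: a segment [s, e) at rate r contributes, for t >= s,

    r * sum_i (c_i / l_i) * (exp(-l_i * max(0, t - e)) - exp(-l_i * (t - s))).

Deconvolution inverts this linear map by non-negative least squares on the
concentration scale, optionally ridge-penalized by the second difference of
the rate (smoothness) with generalized cross-validation when the system is
under-determined.  Cumulative absorbed mass is the exact integral of the
recovered step function, and fraction input divides by the implant's loaded
drug mass -- the convention that makes "percent remaining" arithmetic exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .iv_model import MacroModel
from .pkdata_io import PKDataset

__all__ = [
    "UIRFunction",
    "AbsorptionProfile",
    "build_uir",
    "make_grid",
    "convolve",
    "deconvolve",
    "deconvolve_dataset",
    "summarize_absorption",
    "remaining_percent",
]

HOURS_PER_DAY = 24.0
DAYS_PER_MONTH = 30.4  # month snapshots map to the grid node nearest 30.4*m days


@dataclass
class UIRFunction:
    """Dose-normalized sum of exponentials, units (ng/mL)/ng."""

    coefficients: list[float]
    exponents: list[float]  # 1/h, strictly decreasing
    source_dose: float | None = None  # ng

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.exponents):
            raise ValueError("coefficients and exponents must have equal length")
        if any(c <= 0 for c in self.coefficients) or any(l <= 0 for l in self.exponents):
            raise ValueError("coefficients and exponents must be > 0")
        lams = list(self.exponents)
        if any(lams[i] <= lams[i + 1] for i in range(len(lams) - 1)):
            raise ValueError("exponents must be strictly decreasing")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        c = np.asarray(self.coefficients)
        lam = np.asarray(self.exponents)
        return (c[None, :] * np.exp(-np.outer(t, lam))).sum(axis=1)

    @property
    def plateau_per_unit_rate(self) -> float:
        """Steady-state concentration per unit constant input rate: sum c_i/l_i.

        Units (ng/mL)/(ng/h); a constant infusion k0 ng/h plateaus at
        k0 * sum(c_i/l_i) ng/mL.
        """
        return float(sum(c / l for c, l in zip(self.coefficients, self.exponents)))


def build_uir(model: MacroModel, dose: float) -> UIRFunction:
    """Dose-normalize a fitted macro model into a unit impulse response."""
    if not (dose > 0):
        raise ValueError("dose must be > 0 ng")
    return UIRFunction(
        coefficients=[a / dose for a in model.coefficients],
        exponents=list(model.exponents),
        source_dose=dose,
    )


def make_grid(t_end_h: float, spacing_h: float = 72.0, first_node_h: float = 24.0) -> np.ndarray:
    """Segment edges [0, first_node, first_node + spacing, ...] covering t_end.

    Default: a day-1 node then 72-h spacing, the study's reporting grid.
    """
    if t_end_h <= first_node_h:
        raise ValueError("t_end_h must exceed the first node")
    edges = [0.0, first_node_h]
    while edges[-1] < t_end_h - 1e-9:
        edges.append(edges[-1] + spacing_h)
    return np.array(edges)


def _segment_response(uir: UIRFunction, s: float, e: float, times: np.ndarray) -> np.ndarray:
    """Concentration at ``times`` from unit rate on [s, e): the analytic kernel."""
    c = np.asarray(uir.coefficients)
    lam = np.asarray(uir.exponents)
    t = np.asarray(times, dtype=float)
    out = np.zeros_like(t)
    mask = t >= s
    if not np.any(mask):
        return out
    tm = t[mask]
    upper = np.exp(-np.outer(np.maximum(0.0, tm - e), lam))
    lower = np.exp(-np.outer(tm - s, lam))
    out[mask] = ((upper - lower) * (c / lam)[None, :]).sum(axis=1)
    return out


def convolve(uir: UIRFunction, edges, rate, times) -> np.ndarray:
    """Exact concentrations for a piecewise-constant input rate.

    ``edges`` (h) has one more element than ``rate`` (ng/h per segment).
    Times beyond the last edge see zero further input (the step function ends).
    """
    edges = np.asarray(edges, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if len(edges) != len(rate) + 1:
        raise ValueError("edges must have len(rate) + 1 elements")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing")
    if np.any(rate < 0):
        raise ValueError("input rate must be non-negative")
    times = np.asarray(times, dtype=float)
    out = np.zeros_like(times)
    for k in range(len(rate)):
        if rate[k] != 0.0:
            out += rate[k] * _segment_response(uir, edges[k], edges[k + 1], times)
    return out


@dataclass
class AbsorptionProfile:
    """Deconvolved input on a uniform grid.

    ``rate`` (ng/h) is constant on each segment ``[edges[k], edges[k+1])``.
    Cumulative mass and fraction input are evaluated at the segment ends
    (``node_times``), exactly integrating the step function.
    """

    edges: np.ndarray  # h, len = n_segments + 1
    rate: np.ndarray  # ng/h per segment
    loaded_mass: float | None = None  # ng
    subject_id: str | None = None
    analyte: str | None = None

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if len(self.edges) != len(self.rate) + 1:
            raise ValueError("edges must have len(rate) + 1 elements")
        if np.any(self.rate < -1e-12):
            raise ValueError("rate must be non-negative")
        self.rate = np.maximum(self.rate, 0.0)

    @property
    def node_times(self) -> np.ndarray:
        """Segment end times, h."""
        return self.edges[1:]

    @property
    def node_days(self) -> np.ndarray:
        return self.node_times / HOURS_PER_DAY

    @property
    def cumulative(self) -> np.ndarray:
        """ng absorbed by each node: exact integral of the step function."""
        return np.cumsum(self.rate * np.diff(self.edges))

    @property
    def fraction_input(self) -> np.ndarray:
        if self.loaded_mass is None or self.loaded_mass <= 0:
            raise ValueError("fraction_input requires a positive loaded_mass")
        return self.cumulative / self.loaded_mass

    @property
    def rate_ug_day(self) -> np.ndarray:
        return self.rate * HOURS_PER_DAY / 1000.0

    @property
    def cumulative_mg(self) -> np.ndarray:
        return self.cumulative / 1e6

    def cumulative_at(self, t_h) -> np.ndarray:
        """Exact cumulative input at arbitrary times (piecewise linear)."""
        t = np.atleast_1d(np.asarray(t_h, dtype=float))
        cum_edges = np.concatenate([[0.0], self.cumulative])
        return np.interp(t, self.edges, cum_edges)

    def fraction_at(self, t_h) -> np.ndarray:
        if self.loaded_mass is None or self.loaded_mass <= 0:
            raise ValueError("fraction_at requires a positive loaded_mass")
        return self.cumulative_at(t_h) / self.loaded_mass


def _second_difference(n: int) -> np.ndarray:
    if n < 3:
        return np.zeros((0, n))
    D = np.zeros((n - 2, n))
    for i in range(n - 2):
        D[i, i : i + 3] = (1.0, -2.0, 1.0)
    return D


def _gcv_lambda(A: np.ndarray, y: np.ndarray, D: np.ndarray) -> float:
    """Generalized cross-validation over a log-spaced ridge path.

    Uses the unconstrained ridge solution for the effective degrees of
    freedom; the selected penalty is then applied inside the non-negative
    solve.
    """
    n = len(y)
    best_lam, best_score = 1e-6, np.inf
    scale = np.trace(A.T @ A) / max(1, A.shape[1])
    for lam in scale * np.logspace(-8, 2, 22):
        M = A.T @ A + lam * (D.T @ D)
        try:
            Minv = np.linalg.inv(M)
        except np.linalg.LinAlgError:
            continue
        H = A @ Minv @ A.T
        df = float(np.trace(H))
        if n - df <= 0:
            continue
        resid = y - H @ y
        score = n * float(resid @ resid) / (n - df) ** 2
        if score < best_score:
            best_score, best_lam = score, lam
    return best_lam


def deconvolve(
    uir: UIRFunction,
    times,
    concentrations,
    edges=None,
    grid_spacing_h: float = 72.0,
    regularization: float | str = 0.0,
    loaded_mass: float | None = None,
    subject_id: str | None = None,
    analyte: str | None = None,
) -> AbsorptionProfile:
    """Estimate the input rate behind one observed SQ profile.

    Solves min ||C_obs - convolve(rate)||^2 + lambda * ||D2 rate||^2 subject
    to rate >= 0, with the rate piecewise constant on ``edges`` (built from
    ``grid_spacing_h`` when omitted).  ``regularization`` is a fixed lambda or
    ``"gcv"``; with lambda = 0 the design must have at least as many
    observations as grid segments.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.ndim != 1 or t.shape != c.shape:
        raise ValueError("times and concentrations must be matching 1-D arrays")
    order = np.argsort(t, kind="stable")
    t, c = t[order], c[order]
    if edges is None:
        edges = make_grid(float(t[-1]), spacing_h=grid_spacing_h)
    edges = np.asarray(edges, dtype=float)
    n_seg = len(edges) - 1
    if edges[-1] < t[-1] - 1e-9:
        raise ValueError("grid does not span the observation window")
    A = np.column_stack(
        [_segment_response(uir, edges[k], edges[k + 1], t) for k in range(n_seg)]
    )
    D = _second_difference(n_seg)
    if regularization == "gcv":
        lam = _gcv_lambda(A, c, D) if n_seg >= 3 else 0.0
    else:
        lam = float(regularization)
        if lam < 0:
            raise ValueError("regularization must be >= 0")
    if lam == 0.0 and len(t) < n_seg:
        raise ValueError(
            f"{len(t)} observations for {n_seg} grid segments: an unregularized "
            "deconvolution is under-determined; pass regularization > 0 or 'gcv'"
        )
    if lam > 0 and D.shape[0] > 0:
        A_aug = np.vstack([A, np.sqrt(lam) * D])
        y_aug = np.concatenate([c, np.zeros(D.shape[0])])
    else:
        A_aug, y_aug = A, c
    rate, _ = nnls(A_aug, y_aug, maxiter=50 * n_seg)
    return AbsorptionProfile(
        edges=edges, rate=rate, loaded_mass=loaded_mass,
        subject_id=subject_id, analyte=analyte,
    )


def deconvolve_dataset(
    uir: UIRFunction,
    dataset: PKDataset,
    analyte: str,
    grid_spacing_h: float = 72.0,
    regularization: float | str = "gcv",
) -> list[AbsorptionProfile]:
    """Per-subject deconvolution of every SQ profile for one analyte.

    BLQ values must be imputed and all-BLQ subjects excluded beforehand; an
    all-BLQ profile here is an error.
    """
    sq = dataset.subset(analyte=analyte, route="SQ")
    profiles: list[AbsorptionProfile] = []
    for sid in sq.subjects():
        prof = sq.subset(subject_id=sid)
        if all(s.bql for s in prof.samples):
            raise ValueError(f"subject {sid}: all observations BLQ; exclude before deconvolution")
        for s in prof.samples:
            if s.concentration is None:
                raise ValueError(f"subject {sid}: impute BLQ values before deconvolution")
        t = np.array([s.time for s in prof.samples])
        c = np.array([s.concentration for s in prof.samples])
        dose = prof.dose_for(sid, analyte, "SQ")
        profiles.append(
            deconvolve(
                uir, t, c,
                grid_spacing_h=grid_spacing_h,
                regularization=regularization,
                loaded_mass=dose.loaded_mass,
                subject_id=sid,
                analyte=analyte,
            )
        )
    return profiles


def summarize_absorption(
    profiles: list[AbsorptionProfile],
    months: tuple = (1, 3, 6, 12),
):
    """Median (IQR) absorption snapshots across subjects.

    Node-wise medians are taken over the subjects still observed at each node
    (profiles may have different horizons, e.g. a truncated arm).  Burst is
    the grid node with the maximal median rate; month ``m`` maps to the node
    nearest ``30.4 * m`` days.  Rates are reported in µg/day, cumulative mass
    in mg.  Returns a pandas DataFrame.
    """
    import pandas as pd

    if not profiles:
        raise ValueError("need >= 1 profile")
    # union grid: profiles share spacing by construction; align on node time
    all_nodes = sorted({round(float(x), 6) for p in profiles for x in p.node_times})
    med_rate, q1_rate, q3_rate = {}, {}, {}
    med_cum, q1_cum, q3_cum, n_at = {}, {}, {}, {}
    for node in all_nodes:
        rates, cums = [], []
        for p in profiles:
            idx = np.where(np.isclose(p.node_times, node, atol=1e-6))[0]
            if len(idx):
                rates.append(p.rate_ug_day[idx[0]])
                cums.append(p.cumulative_mg[idx[0]])
        rates, cums = np.array(rates), np.array(cums)
        med_rate[node], q1_rate[node], q3_rate[node] = (
            float(np.median(rates)), float(np.percentile(rates, 25)), float(np.percentile(rates, 75)),
        )
        med_cum[node], q1_cum[node], q3_cum[node] = (
            float(np.median(cums)), float(np.percentile(cums, 25)), float(np.percentile(cums, 75)),
        )
        n_at[node] = int(len(rates))
    nodes = np.array(all_nodes)
    burst_node = float(nodes[int(np.argmax([med_rate[x] for x in all_nodes]))])
    rows = []

    def _row(label, node):
        return {
            "snapshot": label,
            "time_day": node / HOURS_PER_DAY,
            "n": n_at[node],
            "rate_ug_day_median": med_rate[node],
            "rate_ug_day_q1": q1_rate[node],
            "rate_ug_day_q3": q3_rate[node],
            "cumulative_mg_median": med_cum[node],
            "cumulative_mg_q1": q1_cum[node],
            "cumulative_mg_q3": q3_cum[node],
        }

    rows.append(_row("burst", burst_node))
    for m in months:
        target_h = m * DAYS_PER_MONTH * HOURS_PER_DAY
        node = float(nodes[int(np.argmin(np.abs(nodes - target_h)))])
        rows.append(_row(f"month_{m}", node))
    return pd.DataFrame(rows)


def remaining_percent(loaded_mass: float, cumulative: float) -> float:
    """Percent of the loaded drug mass still in the implant.

    May go negative when the deconvolved cumulative exceeds the loading (an
    estimation artifact); a warning is emitted rather than an error.
    """
    if not (loaded_mass > 0):
        raise ValueError("loaded_mass must be > 0")
    if cumulative < 0:
        raise ValueError("cumulative must be >= 0")
    pct = 100.0 * (loaded_mass - cumulative) / loaded_mass
    if pct < 0:
        import warnings

        warnings.warn("cumulative absorbed exceeds loaded mass; remaining percent negative")
    return pct
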