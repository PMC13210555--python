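"""In vitro release profiles, dissolution-kinetics models, and sink checks.

Six empirical release models describe the cumulative fraction F(t) dissolved
(or, in vivo, absorbed):

* zero order      F = b + m*t                     (linear regression)
* first order     ln(Fres) = b + m*t, Fres = 1-F  (linear on the log of the
  fraction remaining; residuals are minimized on that scale)
* Higuchi         F = b + m*sqrt(t)               (linear regression)
* Weibull         F = Fmax * (1 - exp(-((t - Tlag)^b) / A)), Tlag = 0 default
* double Weibull  F = Fmax * [f*(1 - exp(-t^b1/A1)) + (1-f)*(1 - exp(-t^b2/A2))]
* Makoid-Banakar  F = Fmax_MB * (t/Tmax)^n * exp(n * (1 - t/Tmax))

Model comparison uses r^2 on the fitted scale and AIC = n*ln(SSR/n) + 2k with
k counting the regression parameters plus the residual SD.  Nonlinear fits use
seeded multi-start least squares; Weibull with b = 1 and Fmax = 1 reduces to
first-order release 1 - exp(-t/A), and a double Weibull with f = 1 collapses
to the single Weibull -- identities used as consistency checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .pkdata_io import ReleaseSample

__all__ = [
    "DissolutionProfile",
    "DissolutionFit",
    "MODEL_NAMES",
    "model_function",
    "build_profile",
    "fit_dissolution",
    "select_dissolution",
    "minimum_sink_volume",
]

MODEL_NAMES = (
    "zero_order",
    "first_order",
    "higuchi",
    "weibull",
    "double_weibull",
    "makoid_banakar",
)

_AIC_SSR_FLOOR = 1e-20


# ------------------------------------------------------------- model forms


def weibull_cdf(t, fmax: float, A: float, b: float, tlag: float = 0.0):
    t = np.asarray(t, dtype=float)
    x = np.maximum(t - tlag, 0.0)
    with np.errstate(divide="ignore", over="ignore"):
        return fmax * (1.0 - np.exp(-(x**b) / max(A, 1e-300)))


def double_weibull_cdf(t, fmax: float, f: float, A1: float, b1: float, A2: float, b2: float):
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        return fmax * (
            f * (1.0 - np.exp(-(t**b1) / max(A1, 1e-300)))
            + (1.0 - f) * (1.0 - np.exp(-(t**b2) / max(A2, 1e-300)))
        )


def makoid_banakar(t, fmax_mb: float, tmax: float, n: float):
    t = np.asarray(t, dtype=float)
    x = t / tmax
    out = np.zeros_like(t)
    pos = x > 0
    out[pos] = fmax_mb * x[pos] ** n * np.exp(n * (1.0 - x[pos]))
    return out


def model_function(model: str, params: dict):
    """Callable F(t) for a named model with its parameter dict."""
    if model == "zero_order":
        return lambda t: params["b"] + params["m"] * np.asarray(t, dtype=float)
    if model == "first_order":
        return lambda t: 1.0 - np.exp(params["b"] + params["m"] * np.asarray(t, dtype=float))
    if model == "higuchi":
        return lambda t: params["b"] + params["m"] * np.sqrt(np.asarray(t, dtype=float))
    if model == "weibull":
        return lambda t: weibull_cdf(t, params["fmax"], params["A"], params["b"], params.get("tlag", 0.0))
    if model == "double_weibull":
        return lambda t: double_weibull_cdf(
            t, params["fmax"], params["f"], params["A1"], params["b1"], params["A2"], params["b2"]
        )
    if model == "makoid_banakar":
        return lambda t: makoid_banakar(t, params["fmax_mb"], params["tmax"], params["n"])
    raise ValueError(f"unknown dissolution model {model!r}")


# --------------------------------------------------------------- profiles


@dataclass
class DissolutionProfile:
    """Cumulative dissolution of one implant (or a mean over implants)."""

    times: np.ndarray  # days, interval end times
    cumulative_mass: np.ndarray  # µg
    loaded_mass: float  # µg
    implant_id: str | None = None
    analyte: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cumulative_mass = np.asarray(self.cumulative_mass, dtype=float)
        if np.any(np.diff(self.cumulative_mass) < -1e-9):
            raise ValueError("cumulative mass must be non-decreasing")

    @property
    def fraction(self) -> np.ndarray:
        return self.cumulative_mass / self.loaded_mass

    def fraction_at(self, t_day) -> np.ndarray:
        """Linear interpolation of the cumulative fraction (0 at t=0)."""
        t = np.atleast_1d(np.asarray(t_day, dtype=float))
        xp = np.concatenate([[0.0], self.times])
        fp = np.concatenate([[0.0], self.fraction])
        return np.interp(t, xp, fp)


def build_profile(
    release: list[ReleaseSample],
    loaded_mass: float,
    rate_window: tuple[float, float] | None = None,
) -> dict:
    """Cumulative profile and daily release rates from interval measurements.

    Intervals must be ordered and non-overlapping.  Returns a dict with the
    :class:`DissolutionProfile`, per-interval daily rates (µg/day), and -- when
    ``rate_window=(d0, d1)`` is given -- the mean daily rate over intervals
    falling entirely inside that day range.
    """
    if not release:
        raise ValueError("empty release collection")
    rel = sorted(release, key=lambda r: r.interval_start)
    for a, b in zip(rel, rel[1:]):
        if b.interval_start < a.interval_end - 1e-9:
            raise ValueError(
                f"overlapping intervals: [{a.interval_start}, {a.interval_end}] and "
                f"[{b.interval_start}, {b.interval_end}]"
            )
    times = np.array([r.interval_end for r in rel])
    masses = np.array([r.mass_released for r in rel])
    cumulative = np.cumsum(masses)
    widths = np.array([r.interval_end - r.interval_start for r in rel])
    rates = masses / widths
    out = {
        "profile": DissolutionProfile(
            times=times,
            cumulative_mass=cumulative,
            loaded_mass=loaded_mass,
            implant_id=rel[0].implant_id,
            analyte=rel[0].analyte,
        ),
        "rate_times": times,
        "daily_rate_ug": rates,
    }
    if rate_window is not None:
        d0, d1 = rate_window
        mask = np.array([(r.interval_start >= d0) and (r.interval_end <= d1) for r in rel])
        if not mask.any():
            raise ValueError(f"no complete intervals inside day window [{d0}, {d1}]")
        out["windowed_mean_rate_ug_day"] = float(np.mean(rates[mask]))
    return out


# -------------------------------------------------------------------- fits


@dataclass
class DissolutionFit:
    model: str
    parameters: dict
    r2: float  # on the fitted scale (log scale for first_order)
    aic: float
    ssr: float  # on the fitted scale
    n_obs: int
    n_params: int
    predict: object = field(repr=False, default=None)  # F(t) on the fraction scale


def _aic(n: int, ssr: float, k: int) -> float:
    return n * np.log(max(ssr, _AIC_SSR_FLOOR * n) / n) + 2 * k


def _r2(y: np.ndarray, pred: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    ssr = float(np.sum((y - pred) ** 2))
    return 1.0 - ssr / sst if sst > 0 else 1.0


def _linear_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    m, b = np.polyfit(x, y, 1)
    return float(b), float(m)


def _multistart(residual, starts):
    """Unconstrained multi-start Levenberg-Marquardt on transformed parameters."""
    best = None
    for x0 in starts:
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                sol = least_squares(
                    residual, x0, method="lm",
                    xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000,
                )
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("nonlinear dissolution fit failed from all starts")
    return best


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _logit(p):
    p = min(max(p, 1e-9), 1 - 1e-9)
    return float(np.log(p / (1 - p)))


def fit_dissolution(profile: DissolutionProfile, model: str, seed: int = 0) -> DissolutionFit:
    """Fit one named release model to a cumulative-fraction profile.

    The Weibull lag time is fixed at zero: these implants release from
    insertion, and a free Tlag is rarely identifiable from twice-weekly
    sampling.
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown dissolution model {model!r}")
    t = profile.times
    F = profile.fraction
    n = len(t)

    if model == "zero_order":
        b, m = _linear_fit(t, F)
        params = {"b": b, "m": m}
        k = 3
    elif model == "first_order":
        fres = 1.0 - F
        if np.any(fres <= 0):
            raise ValueError("first-order model requires F < 1 at all points")
        y = np.log(fres)
        b, m = _linear_fit(t, y)
        params = {"b": b, "m": m}
        k = 3
    elif model == "higuchi":
        b, m = _linear_fit(np.sqrt(t), F)
        params = {"b": b, "m": m}
        k = 3
    elif model == "weibull":
        # transformed parameters (ln fmax, ln t63, ln b) with A = t63^b
        fmax0 = min(max(F.max() * 1.05, 0.1), 1.5)
        t63 = float(t[int(np.clip(np.searchsorted(F, 0.63 * F.max()), 0, n - 1))])
        rng = np.random.default_rng(seed)
        base = np.log(np.array([fmax0, max(t63, 1e-3), 1.0]))
        starts = [base] + [base + rng.normal(0, 0.7, 3) for _ in range(9)]

        def resid_w(z):
            fm, t63_, b_ = np.exp(z)
            return weibull_cdf(t, fm, t63_**b_, b_) - F

        sol = _multistart(resid_w, starts)
        fm, t63_, b_ = np.exp(sol.x)
        params = {"fmax": float(fm), "A": float(t63_**b_), "b": float(b_), "tlag": 0.0}
        k = 4
    elif model == "double_weibull":
        rng = np.random.default_rng(seed)
        single = fit_dissolution(profile, "weibull", seed=seed)
        fm, A, b = single.parameters["fmax"], single.parameters["A"], single.parameters["b"]
        t63 = max(A ** (1.0 / b), 1e-3)
        base = np.array([np.log(fm), _logit(0.5), np.log(t63 / 2), np.log(b), np.log(t63 * 2), np.log(b)])
        starts = [base]
        for _ in range(11):
            jit = base + rng.normal(0, 0.7, 6)
            jit[1] = _logit(rng.uniform(0.05, 0.95))
            starts.append(jit)

        def resid_dw(z):
            fm_ = np.exp(z[0])
            f_ = _sigmoid(z[1])
            t1, b1, t2, b2 = np.exp(z[2]), np.exp(z[3]), np.exp(z[4]), np.exp(z[5])
            return double_weibull_cdf(t, fm_, f_, t1**b1, b1, t2**b2, b2) - F

        sol = _multistart(resid_dw, starts)
        z = sol.x
        b1, b2 = float(np.exp(z[3])), float(np.exp(z[5]))
        params = {
            "fmax": float(np.exp(z[0])),
            "f": float(_sigmoid(z[1])),
            "A1": float(np.exp(z[2]) ** b1),
            "b1": b1,
            "A2": float(np.exp(z[4]) ** b2),
            "b2": b2,
        }
        k = 7
    else:  # makoid_banakar
        rng = np.random.default_rng(seed)
        i_pk = int(np.argmax(F))
        base = np.log(np.array([max(F.max(), 1e-3), max(t[i_pk], 1e-3), 1.0]))
        starts = [base] + [base + rng.normal(0, 0.7, 3) for _ in range(9)]

        def resid_mb(z):
            return makoid_banakar(t, *np.exp(z)) - F

        sol = _multistart(resid_mb, starts)
        params = dict(zip(["fmax_mb", "tmax", "n"], map(float, np.exp(sol.x))))
        k = 4

    fn = model_function(model, params)
    if model == "first_order":
        fitted_y = np.log(1.0 - F)
        pred_y = params["b"] + params["m"] * t
    else:
        fitted_y = F
        pred_y = fn(t)
    ssr = float(np.sum((fitted_y - pred_y) ** 2))
    return DissolutionFit(
        model=model,
        parameters=params,
        r2=_r2(fitted_y, pred_y),
        aic=_aic(n, ssr, k),
        ssr=ssr,
        n_obs=n,
        n_params=k,
        predict=fn,
    )


def select_dissolution(fits: list[DissolutionFit]) -> list[DissolutionFit]:
    """Rank candidate fits by AIC (ascending); ties go to fewer parameters."""
    if not fits:
        raise ValueError("no fits to rank")
    return sorted(fits, key=lambda f: (round(f.aic, 9), f.n_params))


def minimum_sink_volume(
    rate_ug_day: float, interval_days: float, solubility_ug_ml: float, sink_multiplier: float = 1.0
) -> float:
    """Minimum medium volume (mL) keeping the interval's released drug in sink.

    volume = multiplier * rate * interval / solubility.  Verifies that the
    drug released over the longest transfer interval stays well below its
    solubility limit in the dissolution medium.
    """
    for name, v in (
        ("rate_ug_day", rate_ug_day),
        ("interval_days", interval_days),
        ("solubility_ug_ml", solubility_ug_ml),
        ("sink_multiplier", sink_multiplier),
    ):
        if not (v > 0):
            raise ValueError(f"{name} must be > 0")
    return sink_multiplier * rate_ug_day * interval_days / solubility_ug_ml
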