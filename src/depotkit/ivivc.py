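"""Level-A in vitro - in vivo correlation (IVIVC) regression.

Pairs the mean in vitro fraction dissolved with the mean in vivo fraction
absorbed at matched times (the in vitro sampling schedule), then fits
point-to-point candidate regressions of fraction absorbed (y) on fraction
dissolved (x):

* linear_2p:    y = y0 + a*x
* exp_rise_3p:  y = y0 + a*(1 - exp(-b*x))      (exponential rise to maximum)
* sigmoid_4p:   y = y0 + a / (1 + exp(-(x - x0)/b))
* power_2p:     y = a * x^b
* sigmoid_5p:   y = y0 + a / (1 + exp(-(x - x0)/b))^c  (asymmetric sigmoid)

Candidates are compared on adjusted r^2 and AIC; 95% prediction bands come
from the t quantile times s*sqrt(1 + leverage) with delta-method leverage
J (J'J)^{-1} J'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

__all__ = [
    "IVIVCPairs",
    "IVIVCFit",
    "IVIVC_MODELS",
    "pair_profiles",
    "fit_ivivc",
    "rank_ivivc",
    "predict_absorbed",
]

IVIVC_MODELS = ("linear_2p", "exp_rise_3p", "sigmoid_4p", "power_2p", "sigmoid_5p")

_N_PARAMS = {"linear_2p": 2, "exp_rise_3p": 3, "sigmoid_4p": 4, "power_2p": 2, "sigmoid_5p": 5}
_AIC_SSR_FLOOR = 1e-20


@dataclass
class IVIVCPairs:
    times: np.ndarray  # days
    f_dissolved: np.ndarray
    f_absorbed: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.f_dissolved = np.asarray(self.f_dissolved, dtype=float)
        self.f_absorbed = np.asarray(self.f_absorbed, dtype=float)
        if not (len(self.times) == len(self.f_dissolved) == len(self.f_absorbed)):
            raise ValueError("times, f_dissolved, f_absorbed must have equal lengths")
        tol = 1e-6
        for name, v in (("f_dissolved", self.f_dissolved), ("f_absorbed", self.f_absorbed)):
            if np.any(v < -tol) or np.any(v > 1.0 + 0.05):
                raise ValueError(f"{name} must lie within [0, 1] (small tolerance)")


def pair_profiles(dissolution, absorption, schedule) -> IVIVCPairs:
    """Time-match fraction dissolved and fraction absorbed on a schedule (days).

    ``dissolution`` and ``absorption`` are objects exposing ``fraction_at``
    taking days and hours respectively (a :class:`~depotkit.dissolution.
    DissolutionProfile` and a mean :class:`~depotkit.deconvolution.
    AbsorptionProfile`), or plain ``(times_day, fraction)`` tuples, which are
    linearly interpolated.  The schedule must fall inside both spans.
    """
    sched = np.asarray(schedule, dtype=float)

    def _eval(obj, t_day, in_hours):
        if hasattr(obj, "fraction_at"):
            return np.asarray(obj.fraction_at(t_day * 24.0 if in_hours else t_day))
        tt, ff = obj
        tt = np.asarray(tt, dtype=float)
        ff = np.asarray(ff, dtype=float)
        if t_day.max() > tt.max() + 1e-9 or t_day.min() < tt.min() - 1e-9:
            raise ValueError("schedule outside the series span")
        return np.interp(t_day, tt, ff)

    if hasattr(dissolution, "times") and sched.max() > np.max(dissolution.times) + 1e-9:
        raise ValueError("schedule extends past the dissolution series")
    if hasattr(absorption, "edges") and sched.max() * 24.0 > absorption.edges[-1] + 1e-9:
        raise ValueError("schedule extends past the absorption series")
    f_diss = _eval(dissolution, sched, in_hours=False)
    f_abs = _eval(absorption, sched, in_hours=True)
    return IVIVCPairs(times=sched, f_dissolved=f_diss, f_absorbed=f_abs)


def _model_fn(model: str):
    if model == "linear_2p":
        return lambda x, p: p[0] + p[1] * x
    if model == "exp_rise_3p":
        return lambda x, p: p[0] + p[1] * (1.0 - np.exp(-p[2] * x))
    if model == "sigmoid_4p":
        return lambda x, p: p[0] + p[1] / (1.0 + np.exp(np.clip(-(x - p[2]) / p[3], -500, 500)))
    if model == "power_2p":
        return lambda x, p: p[0] * np.maximum(x, 1e-12) ** p[1]
    if model == "sigmoid_5p":
        return lambda x, p: p[0] + p[1] * np.exp(
            -p[4] * np.log1p(np.exp(np.clip(-(x - p[2]) / p[3], -500, 500)))
        )
    raise ValueError(f"unknown IVIVC model {model!r}")


_PARAM_NAMES = {
    "linear_2p": ["y0", "a"],
    "exp_rise_3p": ["y0", "a", "b"],
    "sigmoid_4p": ["y0", "a", "x0", "b"],
    "power_2p": ["a", "b"],
    "sigmoid_5p": ["y0", "a", "x0", "b", "c"],
}


@dataclass
class IVIVCFit:
    model: str
    parameters: dict
    r2: float
    r2_adj: float
    aic: float
    ssr: float
    residual_sd: float
    n_obs: int
    n_params: int
    x_range: tuple
    _p: np.ndarray = field(repr=False, default=None)
    _jtj_inv: np.ndarray = field(repr=False, default=None)

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return _model_fn(self.model)(x, self._p)


def _starts(model: str, x: np.ndarray, y: np.ndarray, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    span = max(y.max() - y.min(), 1e-6)
    if model == "linear_2p":
        return [np.array(np.polyfit(x, y, 1)[::-1])]
    if model == "exp_rise_3p":
        base = np.array([y.min(), span, 3.0 / max(x.max(), 1e-6)])
    elif model == "sigmoid_4p":
        base = np.array([y.min(), span, float(np.median(x)), max(x.max() - x.min(), 1e-3) / 5.0])
    elif model == "power_2p":
        base = np.array([max(y.max(), 1e-3), 1.0])
    else:  # sigmoid_5p
        base = np.array([y.min(), span, float(np.median(x)), max(x.max() - x.min(), 1e-3) / 5.0, 1.0])
    out = [base]
    for _ in range(9):
        jit = base.copy()
        jit = jit + rng.normal(0.0, 0.5, size=base.shape) * np.maximum(np.abs(base), 0.1)
        out.append(jit)
    return out


def fit_ivivc(pairs: IVIVCPairs, model: str, seed: int = 0) -> IVIVCFit:
    """Least-squares fit of one candidate IVIVC regression."""
    if model not in IVIVC_MODELS:
        raise ValueError(f"unknown IVIVC model {model!r}; choose from {IVIVC_MODELS}")
    x, y = pairs.f_dissolved, pairs.f_absorbed
    n = len(x)
    p = _N_PARAMS[model]
    if n < p + 2:
        raise ValueError(f"{model} needs >= {p + 2} points, got {n}")
    fn = _model_fn(model)

    def resid(pp):
        return fn(x, pp) - y

    best = None
    for x0 in _starts(model, x, y, seed):
        try:
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                sol = least_squares(resid, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=1500)
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(f"IVIVC fit {model} failed from all starts")
    pp = best.x
    pred = fn(x, pp)
    ssr = float(np.sum((y - pred) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 1.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    dof = max(n - p, 1)
    s = np.sqrt(ssr / dof)
    J = best.jac
    try:
        jtj_inv = np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        jtj_inv = np.linalg.pinv(J.T @ J)
    aic = n * np.log(max(ssr, _AIC_SSR_FLOOR * n) / n) + 2 * (p + 1)
    return IVIVCFit(
        model=model,
        parameters=dict(zip(_PARAM_NAMES[model], map(float, pp))),
        r2=r2,
        r2_adj=float(r2_adj),
        aic=float(aic),
        ssr=ssr,
        residual_sd=float(s),
        n_obs=n,
        n_params=p,
        x_range=(float(x.min()), float(x.max())),
        _p=pp,
        _jtj_inv=jtj_inv,
    )


def rank_ivivc(fits: list[IVIVCFit]) -> list[IVIVCFit]:
    """Rank by AIC ascending; ties to fewer parameters."""
    if not fits:
        raise ValueError("no fits to rank")
    return sorted(fits, key=lambda f: (round(f.aic, 9), f.n_params))


def _leverage(fit: IVIVCFit, x: np.ndarray) -> np.ndarray:
    fn = _model_fn(fit.model)
    eps = 1e-7
    p = fit._p
    J = np.empty((len(x), len(p)))
    for j in range(len(p)):
        dp = np.zeros_like(p)
        dp[j] = eps * max(abs(p[j]), 1.0)
        J[:, j] = (fn(x, p + dp) - fn(x, p - dp)) / (2 * dp[j])
    return np.einsum("ij,jk,ik->i", J, fit._jtj_inv, J)


def predict_absorbed(fit: IVIVCFit, f_dissolved, level: float = 0.95) -> dict:
    """Point prediction with a 95% prediction interval; flags extrapolation."""
    x = np.atleast_1d(np.asarray(f_dissolved, dtype=float))
    pred = fit.predict(x)
    dof = max(fit.n_obs - fit.n_params, 1)
    tq = stats.t.ppf(0.5 + level / 2.0, dof)
    lev = np.clip(_leverage(fit, x), 0.0, np.inf)
    half = tq * fit.residual_sd * np.sqrt(1.0 + lev)
    lo, hi = pred - half, pred + half
    extrapolated = (x < fit.x_range[0] - 1e-12) | (x > fit.x_range[1] + 1e-12)
    return {
        "prediction": pred,
        "lower": lo,
        "upper": hi,
        "extrapolated": extrapolated,
    }
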