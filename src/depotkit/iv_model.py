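"""Macro-parameterized compartment-model fitting for IV bolus data.

A 1/2/3-compartment disposition model after an IV bolus is written in macro
form as a sum of exponentials,

    C(t) = sum_i A_i * exp(-lambda_i * t),    lambda_1 > lambda_2 > ... > 0,

and fit to pooled (naive-pooled) log concentrations with an additive error on
the natural-log scale.  Parameters are estimated on the log scale to enforce
positivity, with multi-start initials from curve stripping (log-linear
peeling) plus seeded jitter, because sums of exponentials are notoriously
ill-conditioned.  Uncertainty comes from a subject-level bootstrap: the
resampling unit is the subject, so a subject's sparse samples move together.

The fitted macro-parameters feed directly into the unit impulse response used
for deconvolution; see :mod:`depotkit.deconvolution`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .nca import estimate_lambda_z
from .pkdata_io import PKDataset

__all__ = [
    "MacroModel",
    "FitReport",
    "BootstrapReport",
    "fit_macro",
    "select_model",
    "bootstrap_fit",
]

# floor on SSR/n inside the AIC so that numerically perfect fits (SSR at
# floating-point noise) compare by parameter count, not rounding noise
_AIC_SSR_FLOOR = 1e-20


@dataclass
class MacroModel:
    """Sum-of-exponentials concentration model C(t) = sum A_i exp(-l_i t)."""

    coefficients: list[float]  # ng/mL, ordered with exponents
    exponents: list[float]  # 1/h, strictly decreasing
    dose: float | None = None  # ng
    error_model: str = "log-additive"
    pooling: str = "naive-pooled"

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.exponents):
            raise ValueError("coefficients and exponents must have equal length")
        if any(a <= 0 for a in self.coefficients):
            raise ValueError("coefficients must be > 0")
        lams = list(self.exponents)
        if any(l <= 0 for l in lams) or any(
            lams[i] <= lams[i + 1] for i in range(len(lams) - 1)
        ):
            raise ValueError("exponents must be strictly decreasing and positive")

    @property
    def n_exp(self) -> int:
        return len(self.coefficients)

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        A = np.asarray(self.coefficients)
        lam = np.asarray(self.exponents)
        return (A[None, :] * np.exp(-np.outer(t, lam))).sum(axis=1)

    @property
    def c0(self) -> float:
        return float(sum(self.coefficients))


@dataclass
class FitReport:
    """One candidate fit with its precision and information criteria."""

    model: MacroModel
    cv_percent: list[float]  # per parameter, order (A_1.., lambda_1..)
    objective: float  # n * ln(SSR/n) on the log-concentration scale
    aic: float
    residual_sd: float  # SD of log-scale residuals
    n_obs: int
    diagnostics: dict = field(default_factory=dict)  # observed/predicted arrays


@dataclass
class BootstrapReport:
    n_resamples: int
    n_failed: int
    point: dict  # parameter name -> point estimate (original fit)
    ci_lower: dict  # 2.5th percentile
    ci_upper: dict  # 97.5th percentile
    samples: dict  # parameter name -> np.ndarray of resample estimates


def _pooled_arrays(dataset: PKDataset, analyte: str | None) -> tuple[np.ndarray, np.ndarray, list[str]]:
    samples = [
        s
        for s in dataset.samples
        if s.route == "IV" and (analyte is None or s.analyte == analyte)
    ]
    if not samples:
        raise ValueError("no IV samples to fit")
    for s in samples:
        if s.concentration is None:
            raise ValueError("impute BLQ values before fitting")
        if s.concentration <= 0:
            raise ValueError("concentrations must be > 0 for log-scale fitting")
    t = np.array([s.time for s in samples])
    c = np.array([s.concentration for s in samples])
    sid = [s.subject_id for s in samples]
    return t, c, sid


def _strip_initials(t: np.ndarray, c: np.ndarray, n_exp: int) -> np.ndarray:
    """Curve-stripping (log-linear peeling) starting values.

    Peels phases from slowest to fastest: regress ln C on t over the tail,
    subtract the fitted exponential, repeat on the positive residual.
    Returns log-parameters [ln A_1..A_n, ln l_1..l_n] with l_1 fastest.
    """
    order = np.argsort(t)
    t, c = t[order], c[order]
    # collapse replicate timepoints to their mean for stable peeling
    ut = np.unique(t)
    uc = np.array([c[t == x].mean() for x in ut])
    coeffs: list[float] = []
    lams: list[float] = []
    resid = uc.copy()
    tt = ut.copy()
    for phase in range(n_exp):
        mask = resid > 0
        if mask.sum() < 2:
            break
        tp, cp = tt[mask], resid[mask]
        k = max(2, len(tp) // 2) if phase < n_exp - 1 else len(tp)
        tp_tail, cp_tail = tp[-k:], cp[-k:]
        slope, intercept = np.polyfit(tp_tail, np.log(cp_tail), 1)
        lam = max(-slope, 1e-6)
        A = max(np.exp(intercept), 1e-12)
        coeffs.append(A)
        lams.append(lam)
        resid = resid - A * np.exp(-lam * tt)
        # remaining phases live at earlier times
        keep = tt < (tp_tail[0] if len(tp_tail) else tt[-1])
        if keep.sum() >= 2:
            tt, resid = tt[keep], resid[keep]
    while len(coeffs) < n_exp:
        # fall back: split the fastest phase
        coeffs.append(coeffs[-1] if coeffs else float(uc.max()))
        lams.append((lams[-1] * 3.0) if lams else 1.0)
    coeffs_arr = np.array(coeffs[:n_exp])
    lams_arr = np.array(lams[:n_exp])
    idx = np.argsort(lams_arr)[::-1]  # fastest first
    return np.log(np.concatenate([coeffs_arr[idx], lams_arr[idx]]))


def _residuals(logp: np.ndarray, t: np.ndarray, lnc: np.ndarray, n_exp: int) -> np.ndarray:
    with np.errstate(over="ignore", invalid="ignore"):
        A = np.exp(np.clip(logp[:n_exp], -500, 500))
        lam = np.exp(np.clip(logp[n_exp:], -500, 500))
        pred = (A[None, :] * np.exp(-np.outer(t, lam))).sum(axis=1)
        return np.log(np.maximum(np.nan_to_num(pred), 1e-300)) - lnc


def fit_macro(
    dataset: PKDataset,
    n_exp: int,
    analyte: str | None = None,
    init: np.ndarray | None = None,
    n_starts: int = 10,
    seed: int = 0,
) -> FitReport:
    """Fit an ``n_exp``-exponential macro model to pooled IV data.

    ``init`` may supply explicit log-parameters ``[ln A_i..., ln lambda_i...]``
    (e.g. from NCA); otherwise curve-stripping initials are used.  ``n_starts``
    seeded jitters of the initial guard against local minima.
    """
    if n_exp not in (1, 2, 3):
        raise ValueError("n_exp must be 1, 2, or 3")
    t, c, sid = _pooled_arrays(dataset, analyte)
    k_params = 2 * n_exp + 1  # coefficients, exponents, residual SD
    if len(t) < 2 * n_exp + 1:
        raise ValueError(f"need >= {2 * n_exp + 1} observations for n_exp={n_exp}")
    lnc = np.log(c)
    # identifiability floor: a phase whose half-life exceeds 5x the sampled
    # span is indistinguishable from a constant baseline, which lies outside
    # the disposition-model family (an IV bolus concentration must decay)
    min_exponent = np.log(2.0) / (5.0 * float(t.max()))
    base = np.asarray(init, dtype=float) if init is not None else _strip_initials(t, c, n_exp)
    rng = np.random.default_rng(seed)
    starts = [base]
    for _ in range(max(0, n_starts - 1)):
        starts.append(base + rng.normal(0.0, 0.5, size=base.shape))

    best = None
    for x0 in starts:
        try:
            sol = least_squares(
                _residuals, x0, args=(t, lnc, n_exp),
                method="lm" if len(t) >= len(x0) else "trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000,
            )
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        if np.exp(np.clip(sol.x[n_exp:], -500, 500)).min() < min_exponent:
            continue  # collapsed to a non-decaying baseline phase
        ssr = float(2 * sol.cost)
        if best is None or ssr < best[0] - 1e-15:
            best = (ssr, sol)
    if best is None:
        # every start collapsed: refit with the floor as an explicit bound
        lb = np.full_like(base, -np.inf)
        lb[n_exp:] = np.log(min_exponent)
        try:
            sol = least_squares(
                _residuals, np.maximum(base, lb + 1e-6), args=(t, lnc, n_exp),
                bounds=(lb, np.full_like(base, np.inf)),
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000,
            )
        except Exception as err:
            raise RuntimeError(
                f"macro fit failed to converge from {len(starts)} starts (n_exp={n_exp})"
            ) from err
        best = (float(2 * sol.cost), sol)
    ssr, sol = best
    n = len(t)
    logp = sol.x
    # sort phases fastest-first
    A = np.exp(logp[:n_exp])
    lam = np.exp(logp[n_exp:])
    idx = np.argsort(lam)[::-1]
    A, lam = A[idx], lam[idx]
    dof = max(n - (2 * n_exp), 1)
    resid_sd = float(np.sqrt(ssr / dof))
    objective = n * np.log(max(ssr, _AIC_SSR_FLOOR * n) / n)
    aic = objective + 2 * k_params

    # delta-method CV% from the log-scale covariance: SE(ln p) ~ CV(p)
    J = sol.jac[:, np.concatenate([idx, n_exp + idx])]
    try:
        cov = np.linalg.inv(J.T @ J) * (ssr / dof)
        se_log = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        cv = [float(100.0 * s) for s in se_log]
    except np.linalg.LinAlgError:
        cv = [float("inf")] * (2 * n_exp)

    doses = {d.amount for d in dataset.doses if d.route == "IV" and (analyte is None or d.analyte == analyte)}
    dose = doses.pop() if len(doses) == 1 else None
    # nudge ties apart so the strictly-decreasing invariant holds
    for i in range(1, n_exp):
        if lam[i] >= lam[i - 1]:
            lam[i] = lam[i - 1] * (1 - 1e-9)
    model = MacroModel(coefficients=list(A), exponents=list(lam), dose=dose)
    pred = model.predict(t)
    return FitReport(
        model=model,
        cv_percent=cv,
        objective=float(objective),
        aic=float(aic),
        residual_sd=resid_sd,
        n_obs=n,
        diagnostics={"time": t, "observed": c, "predicted": pred, "subject_id": sid},
    )


def select_model(reports: list[FitReport]) -> FitReport:
    """Pick the lowest-AIC candidate; ties go to fewer exponentials."""
    if len(reports) < 1:
        raise ValueError("need at least one candidate fit")
    return min(reports, key=lambda r: (round(r.aic, 9), r.model.n_exp))


def model_comparison_table(reports: list[FitReport]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "n_exp": r.model.n_exp,
                "aic": r.aic,
                "objective": r.objective,
                "residual_sd": r.residual_sd,
                "n_obs": r.n_obs,
            }
            for r in reports
        ]
    ).sort_values("aic", ignore_index=True)


def _param_names(n_exp: int) -> list[str]:
    coef = ["A", "B", "C"][:n_exp]
    lam = ["alpha", "beta", "gamma"][:n_exp]
    return coef + lam


def bootstrap_fit(
    dataset: PKDataset,
    n_exp: int,
    n_resamples: int = 250,
    seed: int = 0,
    analyte: str | None = None,
    n_starts: int = 4,
) -> BootstrapReport:
    """Subject-level bootstrap of the macro fit (percentile 95% CIs).

    Subjects are resampled with replacement; all of a subject's samples move
    together.  Refits that fail are logged and skipped; more than 20% failures
    aborts.
    """
    base_fit = fit_macro(dataset, n_exp, analyte=analyte, seed=seed)
    iv_subjects = sorted(
        {s.subject_id for s in dataset.samples if s.route == "IV" and (analyte is None or s.analyte == analyte)}
    )
    if len(iv_subjects) < 2:
        raise ValueError("subject bootstrap requires >= 2 subjects")
    rng = np.random.default_rng(seed)
    names = _param_names(n_exp)
    draws: dict[str, list[float]] = {k: [] for k in names}
    n_failed = 0
    base_init = np.log(
        np.concatenate([base_fit.model.coefficients, base_fit.model.exponents])
    )
    for _ in range(n_resamples):
        chosen = rng.choice(iv_subjects, size=len(iv_subjects), replace=True)
        samples = []
        doses = []
        for j, sid in enumerate(chosen):
            tag = f"bs{j}"
            for s in dataset.samples:
                if s.subject_id == sid and s.route == "IV" and (analyte is None or s.analyte == analyte):
                    samples.append(
                        type(s)(
                            subject_id=tag, analyte=s.analyte, route=s.route,
                            time=s.time, concentration=s.concentration,
                            bql=s.bql, lloq=s.lloq,
                        )
                    )
            for d in dataset.doses:
                if d.subject_id == sid and d.route == "IV" and (analyte is None or d.analyte == analyte):
                    doses.append(
                        type(d)(
                            subject_id=tag, analyte=d.analyte, route=d.route,
                            amount=d.amount, time=d.time,
                            body_weight=d.body_weight, loaded_mass=d.loaded_mass,
                        )
                    )
        try:
            ds = PKDataset(samples=samples, doses=doses)
            rep = fit_macro(
                ds, n_exp, analyte=analyte, init=base_init,
                n_starts=n_starts, seed=int(rng.integers(0, 2**31 - 1)),
            )
        except Exception:
            n_failed += 1
            continue
        vals = list(rep.model.coefficients) + list(rep.model.exponents)
        for k, v in zip(names, vals):
            draws[k].append(v)
    if n_failed > 0.2 * n_resamples:
        raise RuntimeError(f"{n_failed}/{n_resamples} bootstrap refits failed (> 20%)")
    point_vals = list(base_fit.model.coefficients) + list(base_fit.model.exponents)
    point = dict(zip(names, point_vals))
    arr = {k: np.array(v) for k, v in draws.items()}
    return BootstrapReport(
        n_resamples=n_resamples,
        n_failed=n_failed,
        point=point,
        ci_lower={k: float(np.percentile(v, 2.5)) for k, v in arr.items()},
        ci_upper={k: float(np.percentile(v, 97.5)) for k, v in arr.items()},
        samples=arr,
    )
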