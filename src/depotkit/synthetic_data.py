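"""Synthetic IV bolus, SQ implant, and in vitro dissolution studies.

The generator emulates the preclinical study design the analysis assumes:

* **IV arm** -- a sparse-sampling rabbit bolus study: 8 timepoints over 30 h
  (0.5, 1, 3, 6, 12, 18, 24, 30), 16 rabbits per analyte each contributing 2
  samples, balanced so every timepoint carries 4 observations.  Truth is a
  biexponential macro model with log-normal between-subject variability on
  each macro-parameter and additive error on log concentrations.
* **SQ arm** -- a year-long implant study sampled on days 1, 7, 14 and then
  every 14 days, with concentrations given by the exact convolution of the
  unit impulse response with a configured depot input rate (zero-order or
  Weibull-shaped), and BLQ censoring at the assay LLOQ.
* **In vitro arm** -- twice-weekly (3.5-day) total-replacement dissolution
  sampling with multiplicative measurement noise on interval masses.

Default macro-parameters are the study estimates for bictegravir (BIC),
islatravir (ISL), and emtricitabine (FTC); depot inputs are Weibull shapes
chosen to mirror each implant's qualitative behavior (BIC: peak absorption on
day 1 then decline; ISL/FTC: burst near day 7; year-end cumulative input of
roughly 35/34/68 mg against 165/62/100 mg loads).  Residual log-SD 0.2 and
between-subject log-SD 0.3 are package choices (the source study does not
report error magnitudes), as is the 3.0 kg default rabbit weight used to
convert per-kg IV doses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .deconvolution import UIRFunction, build_uir, convolve
from .dissolution import model_function
from .iv_model import MacroModel
from .pkdata_io import DoseEvent, PKDataset, PKSample, ReleaseSample

__all__ = [
    "ZeroOrderInput",
    "WeibullInput",
    "DoubleWeibullInput",
    "IVSimConfig",
    "SQSimConfig",
    "DissolutionSimConfig",
    "simulate_iv_study",
    "simulate_implant_study",
    "simulate_dissolution",
    "STUDY_ANALYTES",
    "study_iv_config",
    "study_sq_config",
    "study_dissolution_config",
    "make_study_bundle",
]

IV_TIMEPOINTS_H = (0.5, 1.0, 3.0, 6.0, 12.0, 18.0, 24.0, 30.0)
SQ_SAMPLING_DAYS = tuple([1.0, 7.0, 14.0] + [float(d) for d in range(28, 365, 14)])
DEFAULT_RESIDUAL_SD = 0.2  # additive SD on natural-log concentrations
DEFAULT_IIV_SD = 0.3  # log-normal between-subject SD per macro-parameter
DEFAULT_BODY_WEIGHT_KG = 3.0  # typical adult New Zealand White rabbit


# ------------------------------------------------------------ input shapes


@dataclass(frozen=True)
class ZeroOrderInput:
    """Constant rate k0 (ng/h) from t=0 to ``duration_h``."""

    k0: float  # ng/h
    duration_h: float = math.inf

    def rate(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.where((t >= 0) & (t < self.duration_h), self.k0, 0.0)

    def cumulative(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.k0 * np.clip(t, 0.0, self.duration_h)


@dataclass(frozen=True)
class WeibullInput:
    """Weibull-shaped depot input: cumulative M(t) = total * (1 - exp(-t^b / A)).

    ``A`` carries units of h^b.  b < 1 gives a declining rate from insertion;
    b > 1 gives a rise to a burst peak at ((b-1)*A/b)^(1/b) hours, then decay.
    """

    total: float  # ng eventually delivered
    A: float  # h^b
    b: float

    def __post_init__(self) -> None:
        if self.total <= 0 or self.A <= 0 or self.b <= 0:
            raise ValueError("total, A, b must all be > 0")

    def rate(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        pos = t > 0
        tp = t[pos]
        out[pos] = self.total * (self.b * tp ** (self.b - 1.0) / self.A) * np.exp(
            -(tp**self.b) / self.A
        )
        return out

    def cumulative(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.total * (1.0 - np.exp(-(np.maximum(t, 0.0) ** self.b) / self.A))


@dataclass(frozen=True)
class DoubleWeibullInput:
    """Mixture of two Weibull branches with mixing fraction f."""

    total: float
    f: float
    A1: float
    b1: float
    A2: float
    b2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f <= 1.0):
            raise ValueError("mixing fraction f must be in [0, 1]")

    def _branches(self) -> tuple[WeibullInput, WeibullInput]:
        return (
            WeibullInput(self.total * self.f, self.A1, self.b1) if self.f > 0 else None,
            WeibullInput(self.total * (1 - self.f), self.A2, self.b2) if self.f < 1 else None,
        )

    def rate(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        w1, w2 = self._branches()
        if w1 is not None:
            out = out + w1.rate(t)
        if w2 is not None:
            out = out + w2.rate(t)
        return out

    def cumulative(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        w1, w2 = self._branches()
        if w1 is not None:
            out = out + w1.cumulative(t)
        if w2 is not None:
            out = out + w2.cumulative(t)
        return out


# ---------------------------------------------------------------- configs


@dataclass
class IVSimConfig:
    analyte: str
    coefficients: list[float]  # ng/mL, fastest phase first
    exponents: list[float]  # 1/h, strictly decreasing
    dose_ng: float
    n_subjects: int = 16
    samples_per_subject: int = 2
    timepoints: tuple = IV_TIMEPOINTS_H
    iiv_sd: float = DEFAULT_IIV_SD
    residual_sd: float = DEFAULT_RESIDUAL_SD
    lloq: float = 1.0
    body_weight_kg: float = DEFAULT_BODY_WEIGHT_KG
    seed: int = 0
    subject_prefix: str = "R"

    def __post_init__(self) -> None:
        total = self.n_subjects * self.samples_per_subject
        if total % len(self.timepoints) != 0:
            raise ValueError(
                "n_subjects * samples_per_subject must be divisible by the "
                "number of timepoints for a balanced design"
            )
        if self.samples_per_subject > len(self.timepoints):
            raise ValueError("cannot give a subject more samples than timepoints")
        MacroModel(coefficients=list(self.coefficients), exponents=list(self.exponents))


@dataclass
class SQSimConfig:
    analyte: str
    true_input: object  # ZeroOrderInput | WeibullInput | DoubleWeibullInput
    uir: UIRFunction
    loaded_mass_ng: float
    n_subjects: int = 8
    sampling_days: tuple = SQ_SAMPLING_DAYS
    iiv_sd: float = DEFAULT_IIV_SD
    residual_sd: float = DEFAULT_RESIDUAL_SD
    lloq: float = 1.0
    seed: int = 0
    subject_prefix: str = "S"
    step_h: float = 12.0  # fine grid for the piecewise-constant input projection

    def __post_init__(self) -> None:
        horizon = max(self.sampling_days) * 24.0
        tt = np.linspace(0, horizon, 400)
        if np.any(self.true_input.rate(tt) < -1e-12):
            raise ValueError("true input rate must be non-negative")
        if float(self.true_input.cumulative(horizon)) > self.loaded_mass_ng * (1 + 1e-9):
            raise ValueError("cumulative input exceeds loaded mass over the study horizon")


@dataclass
class DissolutionSimConfig:
    analyte: str
    model: str  # one of the six dissolution forms
    parameters: dict
    loaded_mass_ug: float
    n_implants: int = 8
    study_days: float = 182.0
    interval_days: float = 3.5  # twice-weekly total replacement
    noise_sd: float = 0.05  # relative (log-normal) on interval masses
    seed: int = 0
    implant_prefix: str = "I"

    def __post_init__(self) -> None:
        if self.model in ("weibull", "double_weibull", "makoid_banakar"):
            # shape/scale parameters of the nonlinear forms must be positive
            # (the linear models' intercept "b" may be zero or negative)
            for key in ("A", "A1", "A2", "tmax", "b", "b1", "b2", "n"):
                if key in self.parameters and self.parameters[key] <= 0:
                    raise ValueError(f"dissolution parameter {key} must be > 0")
        fn = model_function(self.model, self.parameters)
        tt = np.linspace(0.0, self.study_days, 200)
        F = fn(tt)
        if self.model != "makoid_banakar" and np.any(np.diff(F) < -1e-9):
            raise ValueError("simulated cumulative fraction must be non-decreasing")


# ------------------------------------------------------------- simulators


def _balanced_allocation(cfg: IVSimConfig, rng: np.random.Generator) -> list[list[float]]:
    """Assign timepoints to subjects: balanced per timepoint, distinct within subject.

    Seeded permutations of the slot list (each timepoint repeated equally) are
    drawn until every subject's hand is duplicate-free.
    """
    reps = cfg.n_subjects * cfg.samples_per_subject // len(cfg.timepoints)
    slots = np.repeat(np.arange(len(cfg.timepoints)), reps)
    for _ in range(10000):
        perm = rng.permutation(slots)
        hands = perm.reshape(cfg.n_subjects, cfg.samples_per_subject)
        if all(len(set(h)) == cfg.samples_per_subject for h in hands.tolist()):
            return [[cfg.timepoints[i] for i in sorted(h)] for h in hands.tolist()]
    raise RuntimeError("could not balance the sparse design; check the configuration")


def simulate_iv_study(config: IVSimConfig) -> PKDataset:
    """Simulate a sparse-sampling IV bolus study under a macro-model truth."""
    rng = np.random.default_rng(config.seed)
    hands = _balanced_allocation(config, rng)
    samples: list[PKSample] = []
    doses: list[DoseEvent] = []
    coef = np.asarray(config.coefficients, dtype=float)
    expo = np.asarray(config.exponents, dtype=float)
    for i, hand in enumerate(hands, start=1):
        sid = f"{config.subject_prefix}{config.analyte}{i:02d}"
        c_i = coef * np.exp(rng.normal(0.0, config.iiv_sd, size=coef.shape))
        l_i = expo * np.exp(rng.normal(0.0, config.iiv_sd, size=expo.shape))
        l_i = np.sort(l_i)[::-1]  # keep phases ordered under jitter
        doses.append(
            DoseEvent(
                subject_id=sid, analyte=config.analyte, route="IV",
                amount=config.dose_ng, body_weight=config.body_weight_kg,
            )
        )
        for t in hand:
            pred = float((c_i * np.exp(-l_i * t)).sum())
            conc = pred * float(np.exp(rng.normal(0.0, config.residual_sd)))
            if conc < config.lloq:
                samples.append(
                    PKSample(sid, config.analyte, "IV", t, None, True, config.lloq)
                )
            else:
                samples.append(
                    PKSample(sid, config.analyte, "IV", t, conc, False, config.lloq)
                )
    return PKDataset(samples=samples, doses=doses)


def _project_to_steps(input_fn, edges: np.ndarray) -> np.ndarray:
    """Mass-preserving piecewise-constant projection of a rate function."""
    cum = input_fn.cumulative(edges)
    return np.diff(cum) / np.diff(edges)


def simulate_implant_study(config: SQSimConfig) -> PKDataset:
    """Simulate a year-long SQ implant study by exact UIR convolution.

    The configured input rate is projected mass-preservingly onto a fine step
    grid (``step_h``) and convolved analytically with the UIR; between-subject
    variability scales each subject's input rate log-normally (capped so the
    cumulative input never exceeds the load).
    """
    rng = np.random.default_rng(config.seed)
    t_obs = np.asarray(config.sampling_days, dtype=float) * 24.0
    edges = np.arange(0.0, t_obs[-1] + config.step_h, config.step_h)
    base_rate = _project_to_steps(config.true_input, edges)
    if np.any(base_rate < -1e-12):
        raise ValueError("true input rate must be non-negative on the grid")
    base_rate = np.maximum(base_rate, 0.0)
    base_conc = convolve(config.uir, edges, base_rate, t_obs)
    base_total = float(config.true_input.cumulative(t_obs[-1]))
    scale_cap = config.loaded_mass_ng / base_total if base_total > 0 else np.inf
    samples: list[PKSample] = []
    doses: list[DoseEvent] = []
    for i in range(1, config.n_subjects + 1):
        sid = f"{config.subject_prefix}{config.analyte}{i:02d}"
        scale = min(float(np.exp(rng.normal(0.0, config.iiv_sd))), scale_cap)
        doses.append(
            DoseEvent(
                subject_id=sid, analyte=config.analyte, route="SQ",
                amount=config.loaded_mass_ng, loaded_mass=config.loaded_mass_ng,
            )
        )
        for t, c0 in zip(t_obs, base_conc):
            conc = scale * c0 * float(np.exp(rng.normal(0.0, config.residual_sd)))
            if conc < config.lloq:
                samples.append(
                    PKSample(sid, config.analyte, "SQ", float(t), None, True, config.lloq)
                )
            else:
                samples.append(
                    PKSample(sid, config.analyte, "SQ", float(t), conc, False, config.lloq)
                )
    return PKDataset(samples=samples, doses=doses)


def simulate_dissolution(config: DissolutionSimConfig) -> list[ReleaseSample]:
    """Simulate twice-weekly total-replacement dissolution sampling."""
    rng = np.random.default_rng(config.seed)
    fn = model_function(config.model, config.parameters)
    n_intervals = int(round(config.study_days / config.interval_days))
    bounds = np.arange(n_intervals + 1) * config.interval_days
    F = fn(bounds)
    out: list[ReleaseSample] = []
    for j in range(1, config.n_implants + 1):
        iid = f"{config.implant_prefix}{config.analyte}{j:02d}"
        for k in range(n_intervals):
            mass = config.loaded_mass_ug * max(float(F[k + 1] - F[k]), 0.0)
            noisy = mass * float(np.exp(rng.normal(0.0, config.noise_sd)))
            out.append(
                ReleaseSample(
                    implant_id=iid, analyte=config.analyte,
                    interval_start=float(bounds[k]), interval_end=float(bounds[k + 1]),
                    mass_released=noisy,
                )
            )
    return out


# ------------------------------------------------- study-condition presets

MG = 1e6  # ng per mg

# macro-model generating truth per analyte: (coefficients ng/mL, exponents 1/h)
STUDY_ANALYTES: dict[str, dict] = {
    "BIC": {
        "coefficients": [1115.6, 102.0],
        "exponents": [0.438, 0.170],
        "dose_mg_per_kg": 0.75,
        "loaded_mg": 165.0,
        "lloq": 1.00,
        "n_sq_subjects": 8,
        # declining input from insertion: burst at the first node
        "true_input": lambda: WeibullInput(total=0.35 * 165.0 * MG, A=2500.0, b=0.85),
        "dissolution": {
            "model": "zero_order",
            "parameters": {"b": 0.0, "m": 172.0 / 165_000.0},  # ~172 µg/day released
        },
    },
    "ISL": {
        "coefficients": [5275.9, 6.3],
        "exponents": [0.5, 0.1],
        "dose_mg_per_kg": 5.0,
        "loaded_mg": 62.0,
        "lloq": 0.100,
        "n_sq_subjects": 16,
        # burst branch peaking near day 7 atop a slow first-order branch that
        # sustains quantifiable input through the year
        "true_input": lambda: DoubleWeibullInput(
            total=0.55 * 62.0 * MG, f=0.25, A1=6534.0, b1=1.5, A2=3500.0, b2=1.0
        ),
        "dissolution": {
            "model": "weibull",
            "parameters": {"fmax": 0.65, "A": 350.0, "b": 1.1},  # A in day^b
        },
    },
    "FTC": {
        "coefficients": [25323.5, 810.5],
        "exponents": [0.6, 0.1],
        "dose_mg_per_kg": 30.0,
        "loaded_mg": 100.0,
        "lloq": 0.100,
        "n_sq_subjects": 16,
        "true_input": lambda: DoubleWeibullInput(
            total=0.68 * 100.0 * MG, f=0.30, A1=6534.0, b1=1.5, A2=3200.0, b2=1.0
        ),
        "dissolution": {
            "model": "weibull",
            "parameters": {"fmax": 0.85, "A": 150.0, "b": 1.0},
        },
    },
}


def _truth_model(analyte: str) -> MacroModel:
    spec = STUDY_ANALYTES[analyte]
    return MacroModel(
        coefficients=list(spec["coefficients"]), exponents=list(spec["exponents"])
    )


def study_iv_config(analyte: str, seed: int = 0, **overrides) -> IVSimConfig:
    spec = STUDY_ANALYTES[analyte]
    dose_ng = spec["dose_mg_per_kg"] * DEFAULT_BODY_WEIGHT_KG * MG
    kw = dict(
        analyte=analyte,
        coefficients=list(spec["coefficients"]),
        exponents=list(spec["exponents"]),
        dose_ng=dose_ng,
        lloq=spec["lloq"],
        seed=seed,
    )
    kw.update(overrides)
    return IVSimConfig(**kw)


def study_sq_config(analyte: str, seed: int = 0, **overrides) -> SQSimConfig:
    spec = STUDY_ANALYTES[analyte]
    dose_ng = spec["dose_mg_per_kg"] * DEFAULT_BODY_WEIGHT_KG * MG
    uir = build_uir(_truth_model(analyte), dose_ng)
    kw = dict(
        analyte=analyte,
        true_input=spec["true_input"](),
        uir=uir,
        loaded_mass_ng=spec["loaded_mg"] * MG,
        n_subjects=spec["n_sq_subjects"],
        lloq=spec["lloq"],
        seed=seed,
    )
    kw.update(overrides)
    return SQSimConfig(**kw)


def study_dissolution_config(analyte: str, seed: int = 0, **overrides) -> DissolutionSimConfig:
    spec = STUDY_ANALYTES[analyte]
    kw = dict(
        analyte=analyte,
        model=spec["dissolution"]["model"],
        parameters=dict(spec["dissolution"]["parameters"]),
        loaded_mass_ug=spec["loaded_mg"] * 1000.0,
        seed=seed,
    )
    kw.update(overrides)
    return DissolutionSimConfig(**kw)


def make_study_bundle(seed: int = 0, analytes: tuple = ("BIC", "ISL", "FTC")) -> dict:
    """One complete synthetic study: IV + SQ datasets and release records.

    Seeds for each arm and analyte are derived deterministically from ``seed``.
    Returns ``{"dataset": PKDataset, "release": {analyte: [ReleaseSample]},
    "truth": {analyte: {...}}}``.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(3 * len(analytes))
    samples, doses = [], []
    release: dict[str, list[ReleaseSample]] = {}
    truth: dict[str, dict] = {}
    for j, analyte in enumerate(analytes):
        s_iv, s_sq, s_dis = (int(c.generate_state(1)[0] % (2**31 - 1)) for c in children[3 * j : 3 * j + 3])
        iv = simulate_iv_study(study_iv_config(analyte, seed=s_iv))
        sq_cfg = study_sq_config(analyte, seed=s_sq)
        sq = simulate_implant_study(sq_cfg)
        samples.extend(iv.samples + sq.samples)
        doses.extend(iv.doses + sq.doses)
        release[analyte] = simulate_dissolution(study_dissolution_config(analyte, seed=s_dis))
        truth[analyte] = {
            "macro_model": _truth_model(analyte),
            "uir": sq_cfg.uir,
            "true_input": sq_cfg.true_input,
            "loaded_mass_ng": sq_cfg.loaded_mass_ng,
            "dose_ng": STUDY_ANALYTES[analyte]["dose_mg_per_kg"] * DEFAULT_BODY_WEIGHT_KG * MG,
        }
    return {
        "dataset": PKDataset(samples=samples, doses=doses),
        "release": release,
        "truth": truth,
    }
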