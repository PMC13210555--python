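"""Pediatric dose translation: absorption rate -> steady-state concentration.

The implant is treated as a continuous constant-rate infusion, so the
predicted steady-state plasma concentration is Css = k0 / Cl, with k0 the
deconvolved absorption rate and Cl the clinical clearance for the target
population.  Clearance comes from published pediatric exposure when available
(Cl = Dose * F / AUC24) or from adult apparent clearance scaled allometrically
(Cl_ped = Cl_adult * (W_ped / W_adult)^0.75, default 15 kg child / 70 kg
adult).

Units: dose mg, AUC µg·h/mL, clearance mL/h, k0 µg/day, Css ng/mL; the
µg/day -> ng/h conversion (x 1000/24) happens inside :func:`predict_css`.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "TranslationParams",
    "CssPrediction",
    "clearance_from_auc",
    "allometric_clearance",
    "predict_css",
    "round_half_up",
]

DEFAULT_PEDIATRIC_WEIGHT_KG = 15.0
DEFAULT_ADULT_WEIGHT_KG = 70.0
DEFAULT_ALLOMETRIC_EXPONENT = 0.75


def clearance_from_auc(dose_mg: float, bioavailability: float, auc24_ug_h_ml: float) -> float:
    """Clearance (mL/h) from a published daily exposure: Cl = Dose * F / AUC24."""
    for name, v in (
        ("dose_mg", dose_mg),
        ("bioavailability", bioavailability),
        ("auc24_ug_h_ml", auc24_ug_h_ml),
    ):
        if not (v > 0):
            raise ValueError(f"{name} must be > 0")
    if bioavailability > 1:
        raise ValueError("bioavailability is a fraction in (0, 1]")
    return dose_mg * 1000.0 * bioavailability / auc24_ug_h_ml  # mg -> µg; µg / (µg·h/mL) = mL/h


def allometric_clearance(
    cl_adult_ml_h: float,
    weight_pediatric_kg: float = DEFAULT_PEDIATRIC_WEIGHT_KG,
    weight_adult_kg: float = DEFAULT_ADULT_WEIGHT_KG,
    exponent: float = DEFAULT_ALLOMETRIC_EXPONENT,
) -> float:
    """Scale adult clearance to a pediatric weight: Cl * (W_ped/W_adult)^0.75."""
    for name, v in (
        ("cl_adult_ml_h", cl_adult_ml_h),
        ("weight_pediatric_kg", weight_pediatric_kg),
        ("weight_adult_kg", weight_adult_kg),
        ("exponent", exponent),
    ):
        if not (v > 0):
            raise ValueError(f"{name} must be > 0")
    return cl_adult_ml_h * (weight_pediatric_kg / weight_adult_kg) ** exponent


def predict_css(k0_ug_day: float, cl_ml_h: float) -> float:
    """Steady-state concentration (ng/mL) under a constant-rate input.

    Css = (k0 * 1000 / 24) / Cl: µg/day -> ng/h, divided by mL/h gives ng/mL.
    """
    if k0_ug_day < 0:
        raise ValueError("k0 must be >= 0")
    if not (cl_ml_h > 0):
        raise ValueError("clearance must be > 0")
    return (k0_ug_day * 1000.0 / 24.0) / cl_ml_h


def round_half_up(value: float, decimals: int) -> float:
    """Display rounding (half away from zero), as clinical tables print."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class TranslationParams:
    """Published clinical parameters from which a pediatric clearance derives.

    Exactly one of ``published_auc24`` (µg·h/mL, with ``published_dose`` mg and
    ``bioavailability``) or ``published_cl_over_f`` (mL/h, scaled
    allometrically) must be supplied.
    """

    analyte: str
    bioavailability: float = 1.0
    published_dose_mg: float | None = None
    published_auc24: float | None = None  # µg·h/mL
    published_cl_over_f: float | None = None  # mL/h (adult apparent clearance)
    weight_pediatric_kg: float = DEFAULT_PEDIATRIC_WEIGHT_KG
    weight_adult_kg: float = DEFAULT_ADULT_WEIGHT_KG
    allometric_exponent: float = DEFAULT_ALLOMETRIC_EXPONENT
    display_decimals: int = 1

    def __post_init__(self) -> None:
        if (self.published_auc24 is None) == (self.published_cl_over_f is None):
            raise ValueError("provide exactly one of published_auc24 / published_cl_over_f")
        if not (0 < self.bioavailability <= 1):
            raise ValueError("bioavailability must be in (0, 1]")
        if self.published_auc24 is not None and self.published_dose_mg is None:
            raise ValueError("published_auc24 requires published_dose_mg")

    def pediatric_cl(self) -> float:
        """Pediatric clearance (mL/h) by the route the published data allow."""
        if self.published_auc24 is not None:
            return clearance_from_auc(self.published_dose_mg, self.bioavailability, self.published_auc24)
        return allometric_clearance(
            self.published_cl_over_f,
            self.weight_pediatric_kg,
            self.weight_adult_kg,
            self.allometric_exponent,
        )


@dataclass
class CssPrediction:
    analyte: str
    k0_ug_day: float
    cl_ml_h: float
    css_ng_ml: float

    @classmethod
    def from_rate(
        cls, params: TranslationParams, k0_ug_day: float, cl_ml_h: float | None = None
    ) -> "CssPrediction":
        """Predict Css from an absorption rate.

        ``cl_ml_h`` overrides the computed clearance -- used to reproduce
        published tables that carried a rounded clearance through the
        arithmetic.
        """
        cl = params.pediatric_cl() if cl_ml_h is None else cl_ml_h
        return cls(
            analyte=params.analyte,
            k0_ug_day=k0_ug_day,
            cl_ml_h=cl,
            css_ng_ml=predict_css(k0_ug_day, cl),
        )

    def display(self, decimals: int | None = None) -> float:
        return round_half_up(self.css_ng_ml, 1 if decimals is None else decimals)


# Published clinical anchors used by the pipeline's translation stage:
# pediatric AUC-based clearance for BIC and FTC, allometric scaling of the
# adult CL/F for ISL (no pediatric estimate available).
CLINICAL_PARAMS: dict[str, TranslationParams] = {
    "BIC": TranslationParams(
        analyte="BIC", bioavailability=0.70, published_dose_mg=30.0,
        published_auc24=126.0, display_decimals=1,
    ),
    "FTC": TranslationParams(
        analyte="FTC", bioavailability=0.93, published_dose_mg=120.0,
        published_auc24=15.0, display_decimals=1,
    ),
    "ISL": TranslationParams(
        analyte="ISL", bioavailability=1.0, published_cl_over_f=35_860.0,
        display_decimals=2,
    ),
}
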