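"""Data model and CSV I/O for concentration-time, dosing, and release records.

The package works on three tidy tables:

* ``samples.csv``  -- subject_id, analyte, route, time_h, conc_ng_ml, bql, lloq_ng_ml
* ``doses.csv``    -- subject_id, analyte, route, amount_ng, time_h,
  body_weight_kg, loaded_mass_ng
* ``release.csv``  -- implant_id, analyte, t_start_day, t_end_day, mass_released_ug

Times are hours internally.  An optional ``time_unit`` column (``h`` or ``day``)
on the samples table is converted on read.  Concentrations below the assay's
lower limit of quantification (LLOQ) are carried as censored records
(``bql=True``, concentration missing or below LLOQ) and imputed to LLOQ/2 by
:func:`impute_blq` -- the convention used for all downstream analysis here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "PKSample",
    "DoseEvent",
    "PKDataset",
    "ReleaseSample",
    "SchemaError",
    "ValidationError",
    "read_pk_csv",
    "read_dataset",
    "write_samples_csv",
    "write_doses_csv",
    "write_release_csv",
    "impute_blq",
    "exclude_subjects",
]

ROUTES = ("IV", "SQ")

SAMPLE_COLUMNS = ["subject_id", "analyte", "route", "time_h", "conc_ng_ml", "bql", "lloq_ng_ml"]
DOSE_COLUMNS = ["subject_id", "analyte", "route", "amount_ng", "time_h", "body_weight_kg", "loaded_mass_ng"]
RELEASE_COLUMNS = ["implant_id", "analyte", "t_start_day", "t_end_day", "mass_released_ug"]


class SchemaError(ValueError):
    """A CSV is missing required columns or uses an unknown schema."""


class ValidationError(ValueError):
    """A record violates a domain invariant (named by row where possible)."""


@dataclass(frozen=True)
class PKSample:
    """One plasma concentration observation."""

    subject_id: str
    analyte: str
    route: str
    time: float  # hours since dose start
    concentration: float | None  # ng/mL; None only when bql
    bql: bool
    lloq: float  # ng/mL

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ValidationError(f"route must be one of {ROUTES}, got {self.route!r}")
        if self.time < 0:
            raise ValidationError(f"time must be >= 0 h, got {self.time}")
        if not (self.lloq > 0):
            raise ValidationError(f"lloq must be > 0, got {self.lloq}")
        if self.concentration is None:
            if not self.bql:
                raise ValidationError(
                    f"missing concentration with bql=False for subject {self.subject_id!r}"
                )
        else:
            if self.concentration < 0:
                raise ValidationError(f"concentration must be >= 0, got {self.concentration}")
            if self.bql and self.concentration >= self.lloq:
                raise ValidationError(
                    f"bql sample has concentration {self.concentration} >= lloq {self.lloq}"
                )


@dataclass(frozen=True)
class DoseEvent:
    """A single administration: IV bolus or SQ implant insertion."""

    subject_id: str
    analyte: str
    route: str
    amount: float  # ng
    time: float = 0.0  # hours
    body_weight: float | None = None  # kg
    loaded_mass: float | None = None  # ng, total drug loaded in the implant

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ValidationError(f"route must be one of {ROUTES}, got {self.route!r}")
        if not (self.amount > 0):
            raise ValidationError(f"dose amount must be > 0 ng, got {self.amount}")
        if self.route == "SQ" and not (self.loaded_mass and self.loaded_mass > 0):
            raise ValidationError("SQ dose requires loaded_mass > 0")


@dataclass(frozen=True)
class ReleaseSample:
    """Mass released into the dissolution medium over one transfer interval."""

    implant_id: str
    analyte: str
    interval_start: float  # days
    interval_end: float  # days
    mass_released: float  # µg

    def __post_init__(self) -> None:
        if self.interval_start < 0 or self.interval_end <= self.interval_start:
            raise ValidationError(
                f"need interval_end > interval_start >= 0, got "
                f"[{self.interval_start}, {self.interval_end}]"
            )
        if self.mass_released < 0:
            raise ValidationError(f"mass_released must be >= 0, got {self.mass_released}")


@dataclass
class PKDataset:
    """Concentration-time samples plus their dosing records.

    Invariants checked on construction: every sample's
    (subject_id, analyte, route) has a matching dose event, and
    (subject_id, analyte, route, time) keys are unique.
    """

    samples: list[PKSample] = field(default_factory=list)
    doses: list[DoseEvent] = field(default_factory=list)
    n_imputed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        dosed = {(d.subject_id, d.analyte, d.route) for d in self.doses}
        seen: set[tuple] = set()
        for s in self.samples:
            if (s.subject_id, s.analyte, s.route) not in dosed:
                raise ValidationError(
                    f"sample ({s.subject_id}, {s.analyte}, {s.route}) has no matching dose event"
                )
            key = (s.subject_id, s.analyte, s.route, s.time)
            if key in seen:
                raise ValidationError(f"duplicate sample key {key}")
            seen.add(key)

    # ------------------------------------------------------------------ views
    def to_samples_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject_id": s.subject_id,
                    "analyte": s.analyte,
                    "route": s.route,
                    "time_h": s.time,
                    "conc_ng_ml": s.concentration,
                    "bql": s.bql,
                    "lloq_ng_ml": s.lloq,
                }
                for s in self.samples
            ],
            columns=SAMPLE_COLUMNS,
        )

    def to_doses_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject_id": d.subject_id,
                    "analyte": d.analyte,
                    "route": d.route,
                    "amount_ng": d.amount,
                    "time_h": d.time,
                    "body_weight_kg": d.body_weight,
                    "loaded_mass_ng": d.loaded_mass,
                }
                for d in self.doses
            ],
            columns=DOSE_COLUMNS,
        )

    def subjects(self, analyte: str | None = None, route: str | None = None) -> list[str]:
        ids: list[str] = []
        for s in self.samples:
            if analyte is not None and s.analyte != analyte:
                continue
            if route is not None and s.route != route:
                continue
            if s.subject_id not in ids:
                ids.append(s.subject_id)
        return ids

    def analytes(self) -> list[str]:
        out: list[str] = []
        for s in self.samples:
            if s.analyte not in out:
                out.append(s.analyte)
        return out

    def subset(
        self, analyte: str | None = None, route: str | None = None, subject_id: str | None = None
    ) -> "PKDataset":
        keep = [
            s
            for s in self.samples
            if (analyte is None or s.analyte == analyte)
            and (route is None or s.route == route)
            and (subject_id is None or s.subject_id == subject_id)
        ]
        kept_keys = {(s.subject_id, s.analyte, s.route) for s in keep}
        doses = [d for d in self.doses if (d.subject_id, d.analyte, d.route) in kept_keys]
        return PKDataset(samples=keep, doses=doses, n_imputed=self.n_imputed)

    def dose_for(self, subject_id: str, analyte: str, route: str) -> DoseEvent:
        for d in self.doses:
            if (d.subject_id, d.analyte, d.route) == (subject_id, analyte, route):
                return d
        raise KeyError(f"no dose event for ({subject_id}, {analyte}, {route})")


# ---------------------------------------------------------------------- I/O


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _as_bool(value, row: int) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("true", "1", "t", "yes"):
        return True
    if text in ("false", "0", "f", "no"):
        return False
    raise ValidationError(f"row {row}: cannot interpret bql value {value!r} as boolean")


def _opt_float(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return float(value)


def read_pk_csv(path: str | Path, schema: str):
    """Read one of the package's CSV dialects.

    ``schema`` is one of ``"samples"``, ``"doses"``, ``"release"``.  Returns a
    list of :class:`PKSample`, :class:`DoseEvent`, or :class:`ReleaseSample`.
    Malformed rows raise :class:`ValidationError` naming the (1-based data) row.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if schema == "samples":
        _require_columns(df, SAMPLE_COLUMNS, str(path))
        unit_col = "time_unit" in df.columns
        out_s: list[PKSample] = []
        for i, row in enumerate(df.itertuples(index=False), start=1):
            rec = row._asdict()
            t = float(rec["time_h"])
            if unit_col and str(rec["time_unit"]).strip().lower() in ("day", "d", "days"):
                t *= 24.0
            try:
                out_s.append(
                    PKSample(
                        subject_id=str(rec["subject_id"]),
                        analyte=str(rec["analyte"]),
                        route=str(rec["route"]),
                        time=t,
                        concentration=_opt_float(rec["conc_ng_ml"]),
                        bql=_as_bool(rec["bql"], i),
                        lloq=float(rec["lloq_ng_ml"]),
                    )
                )
            except ValidationError as err:
                raise ValidationError(f"{path} row {i}: {err}") from err
        return out_s
    if schema == "doses":
        _require_columns(df, DOSE_COLUMNS[:5], str(path))
        out_d: list[DoseEvent] = []
        for i, row in enumerate(df.itertuples(index=False), start=1):
            rec = row._asdict()
            try:
                out_d.append(
                    DoseEvent(
                        subject_id=str(rec["subject_id"]),
                        analyte=str(rec["analyte"]),
                        route=str(rec["route"]),
                        amount=float(rec["amount_ng"]),
                        time=float(rec["time_h"]),
                        body_weight=_opt_float(rec.get("body_weight_kg")),
                        loaded_mass=_opt_float(rec.get("loaded_mass_ng")),
                    )
                )
            except ValidationError as err:
                raise ValidationError(f"{path} row {i}: {err}") from err
        return out_d
    if schema == "release":
        _require_columns(df, RELEASE_COLUMNS, str(path))
        out_r: list[ReleaseSample] = []
        for i, row in enumerate(df.itertuples(index=False), start=1):
            rec = row._asdict()
            try:
                out_r.append(
                    ReleaseSample(
                        implant_id=str(rec["implant_id"]),
                        analyte=str(rec["analyte"]),
                        interval_start=float(rec["t_start_day"]),
                        interval_end=float(rec["t_end_day"]),
                        mass_released=float(rec["mass_released_ug"]),
                    )
                )
            except ValidationError as err:
                raise ValidationError(f"{path} row {i}: {err}") from err
        return out_r
    raise SchemaError(f"unknown schema {schema!r}; expected samples|doses|release")


def read_dataset(samples_path: str | Path, doses_path: str | Path) -> PKDataset:
    """Read matched samples and doses CSVs into one validated :class:`PKDataset`."""
    return PKDataset(
        samples=read_pk_csv(samples_path, "samples"),
        doses=read_pk_csv(doses_path, "doses"),
    )


def write_samples_csv(samples: Iterable[PKSample] | PKDataset, path: str | Path) -> None:
    if isinstance(samples, PKDataset):
        frame = samples.to_samples_frame()
    else:
        frame = pd.DataFrame(
            [
                {
                    "subject_id": s.subject_id,
                    "analyte": s.analyte,
                    "route": s.route,
                    "time_h": s.time,
                    "conc_ng_ml": s.concentration,
                    "bql": s.bql,
                    "lloq_ng_ml": s.lloq,
                }
                for s in samples
            ],
            columns=SAMPLE_COLUMNS,
        )
    frame.to_csv(path, index=False)


def write_doses_csv(doses: Iterable[DoseEvent] | PKDataset, path: str | Path) -> None:
    if isinstance(doses, PKDataset):
        frame = doses.to_doses_frame()
    else:
        frame = pd.DataFrame(
            [
                {
                    "subject_id": d.subject_id,
                    "analyte": d.analyte,
                    "route": d.route,
                    "amount_ng": d.amount,
                    "time_h": d.time,
                    "body_weight_kg": d.body_weight,
                    "loaded_mass_ng": d.loaded_mass,
                }
                for d in doses
            ],
            columns=DOSE_COLUMNS,
        )
    frame.to_csv(path, index=False)


def write_release_csv(release: Iterable[ReleaseSample], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "implant_id": r.implant_id,
                "analyte": r.analyte,
                "t_start_day": r.interval_start,
                "t_end_day": r.interval_end,
                "mass_released_ug": r.mass_released,
            }
            for r in release
        ],
        columns=RELEASE_COLUMNS,
    ).to_csv(path, index=False)


# ---------------------------------------------------------------- operations


def impute_blq(dataset: PKDataset) -> PKDataset:
    """Impute censored (BLQ) concentrations as LLOQ/2.

    Non-BLQ samples are untouched; the number of imputed records is recorded on
    the returned dataset (``n_imputed``) for reporting.  Idempotent: a record
    already at LLOQ/2 is simply re-set to LLOQ/2.
    """
    out: list[PKSample] = []
    n = 0
    for s in dataset.samples:
        if s.bql:
            out.append(replace(s, concentration=s.lloq / 2.0))
            n += 1
        else:
            out.append(s)
    return PKDataset(samples=out, doses=list(dataset.doses), n_imputed=n)


def exclude_subjects(
    dataset: PKDataset, rule: str = "all_blq"
) -> tuple[PKDataset, list[dict]]:
    """Remove subject-analyte groups matching an explicit, documented predicate.

    ``rule="all_blq"`` removes groups in which every sample is BLQ -- the
    situation in which a profile carries no quantifiable information and cannot
    be fit or deconvolved.  Exclusion is never automatic elsewhere in the
    package; callers apply this operation deliberately and keep the log.

    Returns the filtered dataset and a log of ``{"subject_id", "analyte",
    "route", "reason"}`` entries.
    """
    if rule != "all_blq":
        raise ValueError(f"unknown exclusion rule {rule!r}")
    groups: dict[tuple, list[PKSample]] = {}
    for s in dataset.samples:
        groups.setdefault((s.subject_id, s.analyte, s.route), []).append(s)
    removed = {key for key, ss in groups.items() if all(x.bql for x in ss)}
    log = [
        {"subject_id": k[0], "analyte": k[1], "route": k[2], "reason": "all observations BLQ"}
        for k in sorted(removed)
    ]
    keep = [s for s in dataset.samples if (s.subject_id, s.analyte, s.route) not in removed]
    kept_keys = {(s.subject_id, s.analyte, s.route) for s in keep}
    doses = [d for d in dataset.doses if (d.subject_id, d.analyte, d.route) in kept_keys]
    return PKDataset(samples=keep, doses=doses, n_imputed=dataset.n_imputed), log
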