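"""Domain types, validation and tabular I/O for two-arm trial datasets.

The data model mirrors how economic-evaluation trial exports are shared:
one wide row per participant, with suffixed columns for the three clinical
assessment timepoints (T1 = randomization, T2 = post treatment, T3 =
6-month follow-up) and the two 3-month resource-use recall windows
(``_W1`` covering the 3 months before baseline, ``_W3`` the 3 months
before follow-up).

Missingness convention: an empty cell means *missing*, never zero — a cost
of 0 is a meaningful, common observation and must stay distinguishable
from "not assessed".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

logger = logging.getLogger("trialcea")

ARMS = ("ISMI", "WLC")

TIMEPOINT_LABELS = ("T1", "T2", "T3")
WINDOW_LABELS = ("W1", "W3")

PSS_MIN, PSS_MAX = 0, 40
INCLUSION_CUTOFF = 22
#: a 3-month recall window cannot contain more inpatient days than it has days
MAX_INPATIENT_DAYS = 92


@dataclass(frozen=True)
class Timepoints:
    """Assessment schedule in weeks since randomization.

    The 6-month horizon uses a 52-week year exactly, so week 26 = 0.5 years
    and a participant in full health (utility 1 throughout) accrues 0.5 QALY.
    """

    t1_week: float = 0.0
    t2_week: float = 7.0
    t3_week: float = 26.0
    weeks_per_year: float = 52.0

    def __post_init__(self) -> None:
        if not (self.t1_week < self.t2_week < self.t3_week):
            raise ValueError("timepoints must be strictly increasing")

    @property
    def horizon_years(self) -> float:
        return (self.t3_week - self.t1_week) / self.weeks_per_year


@dataclass
class ResourceWindow:
    """Self-reported resource use over one 3-month recall window.

    Contact/day counts follow the TiC-P categories; ``prescriptions`` is a
    list of (drug id, number of packages); ``travel`` a list of
    (mode, quantity) where quantity is round-trip km for ``car`` and the
    fare in EUR for ``bus``/``taxi``.
    """

    physician_contacts: float = 0.0
    specialist_contacts: float = 0.0
    psychological_contacts: float = 0.0
    allied_health_contacts: float = 0.0
    inpatient_days: float = 0.0
    semiresidential_days: float = 0.0
    rehabilitation_days: float = 0.0
    prescriptions: list[tuple[str, float]] = field(default_factory=list)
    otc_spend: float = 0.0
    travel: list[tuple[str, float]] = field(default_factory=list)
    waiting_and_treatment_hours: float = 0.0
    informal_care_hours: float = 0.0
    absence_days: float = 0.0
    impaired_days: float = 0.0
    inefficiency_score: float = 0.0

    _COUNT_FIELDS = (
        "physician_contacts",
        "specialist_contacts",
        "psychological_contacts",
        "allied_health_contacts",
        "inpatient_days",
        "semiresidential_days",
        "rehabilitation_days",
        "otc_spend",
        "waiting_and_treatment_hours",
        "informal_care_hours",
        "absence_days",
        "impaired_days",
    )

    def validate(self, where: str = "") -> None:
        for name in self._COUNT_FIELDS:
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(f"{where}: {name} must be >= 0, got {v}")
        if not 0.0 <= self.inefficiency_score <= 1.0:
            raise ValidationError(
                f"{where}: inefficiency_score must be in [0,1], "
                f"got {self.inefficiency_score}"
            )
        if self.inpatient_days > MAX_INPATIENT_DAYS:
            raise ValidationError(
                f"{where}: inpatient_days {self.inpatient_days} exceeds "
                f"window length {MAX_INPATIENT_DAYS}"
            )
        for drug, packs in self.prescriptions:
            if packs < 0:
                raise ValidationError(f"{where}: negative package count for {drug}")
        for mode, qty in self.travel:
            if mode not in ("car", "bus", "taxi"):
                raise ValidationError(f"{where}: unknown travel mode {mode!r}")
            if qty < 0:
                raise ValidationError(f"{where}: negative travel quantity ({mode})")


@dataclass
class ParticipantRecord:
    """One trial participant, wide format.

    ``pss``, ``utility_sf6d`` and ``utility_eq5d`` map timepoint label
    ("T1"/"T2"/"T3") to the observed score, or ``None`` when missing.
    ``resource_use`` maps window label ("W1"/"W3") to a
    :class:`ResourceWindow`, or ``None`` when the whole window is missing.
    """

    id: str
    arm: str
    pss: dict[str, Optional[int]]
    utility_sf6d: dict[str, Optional[float]]
    utility_eq5d: dict[str, Optional[float]]
    resource_use: dict[str, Optional[ResourceWindow]]
    gross_monthly_wage: float

    @property
    def dropout(self) -> bool:
        """True when the 6-month follow-up assessment is missing."""
        return self.pss.get("T3") is None

    def validate(self, strict: bool = True) -> None:
        """Range/consistency checks; ``strict`` additionally enforces the
        trial's inclusion rule (baseline PSS >= 22)."""
        if self.arm not in ARMS:
            raise ValidationError(f"{self.id}: arm must be one of {ARMS}, got {self.arm!r}")
        if self.gross_monthly_wage < 0:
            raise ValidationError(f"{self.id}: wage must be >= 0")
        for t, v in self.pss.items():
            if v is not None and not PSS_MIN <= v <= PSS_MAX:
                raise ValidationError(f"{self.id}: pss_{t} out of range [0,40]: {v}")
        for t, v in self.utility_sf6d.items():
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValidationError(f"{self.id}: sf6d_{t} out of range [0,1]: {v}")
        for t, v in self.utility_eq5d.items():
            # EQ-5D tariffs admit worse-than-death states (negative utility)
            if v is not None and not -0.6 <= v <= 1.0:
                raise ValidationError(f"{self.id}: eq5d_{t} out of range [-0.6,1]: {v}")
        for w, win in self.resource_use.items():
            if win is not None:
                win.validate(where=f"{self.id}/{w}")
        if strict:
            t1 = self.pss.get("T1")
            if t1 is None:
                raise ValidationError(f"{self.id}: baseline PSS missing")
            if t1 < INCLUSION_CUTOFF:
                raise ValidationError(
                    f"{self.id}: baseline PSS {t1} below inclusion cutoff "
                    f"{INCLUSION_CUTOFF}"
                )


class ValidationError(ValueError):
    """A record violated a range or consistency rule; message names row+field."""


class SchemaError(ValueError):
    """The input file lacks a mandatory column."""


@dataclass
class UnitCostTable:
    """Resource category -> unit price (2013 EUR) plus the costing constants.

    Default unit prices are plausible German 2013 tariffs; all constants
    default to the evaluation's published rates and can be overridden via
    :func:`read_unit_costs`.
    """

    prices: dict[str, tuple[float, str]] = field(default_factory=lambda: dict(DEFAULT_UNIT_PRICES))
    car_km_rate: float = 0.30          # EUR per km driven
    opportunity_rate: float = 23.10    # EUR per hour of leisure time forgone
    informal_care_rate: float = 18.33  # EUR per hour, substitution method
    intervention_price: float = 299.0  # flat tariff, intervention arm only
    price_index_factor: float = 1.04   # consumer-price indexation to 2013
    ppp_eur_to_usd: float = 1.29       # OECD purchasing power parity, 2013
    statutory_share: float = 0.888     # statutorily insured population share

    _CONSTANTS = (
        "car_km_rate",
        "opportunity_rate",
        "informal_care_rate",
        "intervention_price",
        "price_index_factor",
        "ppp_eur_to_usd",
        "statutory_share",
    )

    def unit_price(self, category: str) -> float:
        try:
            return self.prices[category][0]
        except KeyError:
            raise KeyError(f"no unit price for category {category!r}") from None

    def validate(self) -> None:
        for cat, (price, _unit) in self.prices.items():
            if price < 0:
                raise ValidationError(f"negative unit price for {cat!r}")
        for name in self._CONSTANTS:
            if getattr(self, name) < 0:
                raise ValidationError(f"negative constant {name}")


#: per-contact / per-day tariffs (EUR, 2013)
DEFAULT_UNIT_PRICES: dict[str, tuple[float, str]] = {
    "physician_contact": (20.0, "EUR/contact"),
    "specialist_contact": (28.0, "EUR/contact"),
    "psychological_contact": (85.0, "EUR/session"),
    "allied_health_contact": (25.0, "EUR/session"),
    "inpatient_day": (550.0, "EUR/day"),
    "semiresidential_day": (280.0, "EUR/day"),
    "rehabilitation_day": (120.0, "EUR/day"),
}


# --------------------------------------------------------------------------
# wide-CSV schema
# --------------------------------------------------------------------------

_SCORE_COLS = (
    [f"pss_{t}" for t in TIMEPOINT_LABELS]
    + [f"sf6d_{t}" for t in TIMEPOINT_LABELS]
    + [f"eq5d_{t}" for t in TIMEPOINT_LABELS]
)

_WINDOW_SCALAR_FIELDS = (
    "physician_contacts",
    "specialist_contacts",
    "psychological_contacts",
    "allied_health_contacts",
    "inpatient_days",
    "semiresidential_days",
    "rehabilitation_days",
    "otc_spend",
    "waiting_and_treatment_hours",
    "informal_care_hours",
    "absence_days",
    "impaired_days",
    "inefficiency_score",
)

_WINDOW_LIST_FIELDS = ("prescriptions", "travel")

TRIAL_COLUMNS: list[str] = (
    ["id", "arm", "gross_monthly_wage"]
    + _SCORE_COLS
    + [
        f"{f}_{w}"
        for w in WINDOW_LABELS
        for f in (*_WINDOW_SCALAR_FIELDS, *_WINDOW_LIST_FIELDS)
    ]
)

MANDATORY_COLUMNS = ("id", "arm", "pss_T1")


def _encode_pairs(pairs: list[tuple[str, float]]) -> str:
    return ";".join(f"{k}:{v!r}" for k, v in pairs)


def _decode_pairs(cell: str) -> list[tuple[str, float]]:
    out: list[tuple[str, float]] = []
    for item in cell.split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, val = item.partition(":")
        out.append((key.strip(), float(val)))
    return out


def _cell(value) -> Optional[str]:
    if value is None:
        return None
    if isinstance(value, float) and pd.isna(value):
        return None
    s = str(value).strip()
    return s if s else None


def record_to_row(rec: ParticipantRecord) -> dict:
    row: dict = {"id": rec.id, "arm": rec.arm, "gross_monthly_wage": rec.gross_monthly_wage}
    for t in TIMEPOINT_LABELS:
        row[f"pss_{t}"] = rec.pss.get(t)
        row[f"sf6d_{t}"] = rec.utility_sf6d.get(t)
        row[f"eq5d_{t}"] = rec.utility_eq5d.get(t)
    for w in WINDOW_LABELS:
        win = rec.resource_use.get(w)
        for f in _WINDOW_SCALAR_FIELDS:
            row[f"{f}_{w}"] = None if win is None else getattr(win, f)
        for f in _WINDOW_LIST_FIELDS:
            row[f"{f}_{w}"] = None if win is None else _encode_pairs(getattr(win, f))
    return row


def row_to_record(row: pd.Series) -> ParticipantRecord:
    def num(col, cast=float):
        c = _cell(row.get(col))
        return None if c is None else cast(float(c))

    pss = {t: num(f"pss_{t}", lambda x: int(round(x))) for t in TIMEPOINT_LABELS}
    sf6d = {t: num(f"sf6d_{t}") for t in TIMEPOINT_LABELS}
    eq5d = {t: num(f"eq5d_{t}") for t in TIMEPOINT_LABELS}

    resource_use: dict[str, Optional[ResourceWindow]] = {}
    for w in WINDOW_LABELS:
        scalar_cells = {f: _cell(row.get(f"{f}_{w}")) for f in _WINDOW_SCALAR_FIELDS}
        list_cells = {f: _cell(row.get(f"{f}_{w}")) for f in _WINDOW_LIST_FIELDS}
        if all(v is None for v in scalar_cells.values()) and all(
            v is None for v in list_cells.values()
        ):
            resource_use[w] = None
            continue
        kwargs = {f: float(v) if v is not None else 0.0 for f, v in scalar_cells.items()}
        for f, v in list_cells.items():
            kwargs[f] = _decode_pairs(v) if v is not None else []
        resource_use[w] = ResourceWindow(**kwargs)

    wage_cell = _cell(row.get("gross_monthly_wage"))
    return ParticipantRecord(
        id=str(row["id"]),
        arm=str(row["arm"]),
        pss=pss,
        utility_sf6d=sf6d,
        utility_eq5d=eq5d,
        resource_use=resource_use,
        gross_monthly_wage=float(wage_cell) if wage_cell is not None else 0.0,
    )


def read_trial(path, strict: bool = False) -> list[ParticipantRecord]:
    """Read a wide trial CSV into validated :class:`ParticipantRecord` objects.

    Empty cells become missing values (never zero). Unknown columns are
    ignored with a warning. ``strict=True`` additionally enforces the trial
    inclusion rule; leave it off for user data that may legitimately
    violate it.
    """
    df = pd.read_csv(path, dtype=str)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} missing from {path}")
    unknown = set(df.columns) - set(TRIAL_COLUMNS)
    if unknown:
        logger.warning("ignoring unknown columns: %s", sorted(unknown))
    records = []
    for _, row in df.iterrows():
        rec = row_to_record(row)
        rec.validate(strict=strict)
        records.append(rec)
    return records


def write_trial(records: list[ParticipantRecord], path) -> None:
    """Write records to wide CSV; missing values are written as empty cells.

    Round-trips with :func:`read_trial` field-for-field and is byte-stable
    across repeated writes of the same records.
    """
    rows = [record_to_row(r) for r in records]
    # default float formatting is the shortest exact (round-trippable) repr
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df.to_csv(path, index=False)


def read_unit_costs(path) -> UnitCostTable:
    """Read a unit-cost CSV (columns: category, unit_price_eur, unit).

    Rows whose category matches one of the costing constants
    (``car_km_rate``, ``opportunity_rate``, ``informal_care_rate``,
    ``intervention_price``, ``price_index_factor``, ``ppp_eur_to_usd``,
    ``statutory_share``) override that constant; all other rows set the
    per-category tariff. Constants not present keep their defaults.
    """
    df = pd.read_csv(path)
    for col in ("category", "unit_price_eur"):
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} missing from {path}")
    if df["category"].duplicated().any():
        dups = df.loc[df["category"].duplicated(), "category"].tolist()
        raise ValidationError(f"duplicate categories in unit-cost table: {dups}")
    table = UnitCostTable()
    for _, row in df.iterrows():
        cat = str(row["category"]).strip()
        price = float(row["unit_price_eur"])
        if price < 0:
            raise ValidationError(f"negative price for category {cat!r}")
        if cat in UnitCostTable._CONSTANTS:
            setattr(table, cat, price)
        else:
            unit = str(row.get("unit", "")) if "unit" in df.columns else ""
            table.prices[cat] = (price, unit)
    table.validate()
    return table


def write_unit_costs(table: UnitCostTable, path) -> None:
    rows = [
        {"category": cat, "unit_price_eur": price, "unit": unit}
        for cat, (price, unit) in table.prices.items()
    ]
    rows += [
        {"category": name, "unit_price_eur": getattr(table, name), "unit": ""}
        for name in UnitCostTable._CONSTANTS
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
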