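"""Societal costing: resource-use windows -> per-participant euros.

Categories follow the published cost-table structure:

* health care — intervention, physician (incl. medical specialist),
  psychological, inpatient, semiresidential, rehabilitation, nonphysician
  (allied health), prescription drugs
* patient & family — over-the-counter spend, opportunity cost of waiting/
  treatment time, travel, domestic help / informal care
* productivity — absenteeism (human capital approach) and presenteeism
  (lost-workday equivalents via an inefficiency score)

Each 3-month recall window is costed separately; the 6-month figure is the
trapezoidal area under the two window rates (:func:`cumulate_auc`). The
intervention tariff is a one-off added once to the 6-month total, never
interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional

from .trial_data import ParticipantRecord, ResourceWindow, UnitCostTable

#: recurring (window-level) cost categories, in report order
RECURRING_CATEGORIES = (
    "physician",
    "psychological",
    "inpatient",
    "semiresidential",
    "rehabilitation",
    "nonphysician",
    "prescription",
    "otc",
    "opportunity",
    "travel",
    "informal_care",
    "absenteeism",
    "presenteeism",
)

CATEGORY_GROUPS = {
    "health_care": (
        "intervention",
        "physician",
        "psychological",
        "inpatient",
        "semiresidential",
        "rehabilitation",
        "nonphysician",
        "prescription",
    ),
    "patient_family": ("otc", "opportunity", "travel", "informal_care"),
    "productivity": ("absenteeism", "presenteeism"),
}

#: full working year of 260 days spread over 12 months
WORKDAYS_PER_MONTH = 260 / 12


@dataclass
class CostingOptions:
    """Scenario switches for the sensitivity analyses.

    ``exclude_categories`` drops categories from every total (e.g.
    ``{"inpatient"}``); ``intervention_offset`` shifts the flat intervention
    tariff by the given amount (±100 EUR in the published scenarios);
    ``auc_mode`` selects how the two window rates are cumulated to 6 months.
    """

    exclude_categories: frozenset[str] = frozenset()
    intervention_offset: float = 0.0
    auc_mode: str = "trapezoid"  # or "double_followup"
    workdays_per_month: float = WORKDAYS_PER_MONTH


@dataclass
class CostBreakdown:
    """Per-participant costs (2013 EUR) by window and category, plus the
    cumulated 6-month figures. Group totals are exact sums of their members."""

    participant_id: str
    arm: str
    window_costs: dict[str, dict[str, float]]  # window label -> category -> EUR
    six_month: dict[str, float]                # category (incl. intervention) -> EUR
    group_totals: dict[str, float] = field(default_factory=dict)
    total: float = 0.0

    def finalize(self) -> "CostBreakdown":
        self.group_totals = {
            g: sum(self.six_month.get(c, 0.0) for c in cats)
            for g, cats in CATEGORY_GROUPS.items()
        }
        self.total = sum(self.group_totals.values())
        return self


# --------------------------------------------------------------------------
# drug price table (configurable stand-in for a national price register)
# --------------------------------------------------------------------------


@dataclass
class DrugPriceTable:
    """Drug id -> package price pairs.

    Each entry lists packages as (pack_size, statutory_price, private_price).
    A drug's unit price is the mean per-package price over its up-to-3
    largest packages, taken separately for statutory and private insurance
    and then weighted by the statutorily insured population share.
    """

    packages: dict[str, list[tuple[float, float, float]]]

    def weighted_price(self, drug: str, statutory_share: float) -> float:
        try:
            packs = self.packages[drug]
        except KeyError:
            raise KeyError(f"unknown drug id {drug!r}") from None
        largest = sorted(packs, key=lambda p: p[0], reverse=True)[:3]
        statutory = sum(p[1] for p in largest) / len(largest)
        private = sum(p[2] for p in largest) / len(largest)
        return statutory_share * statutory + (1.0 - statutory_share) * private


#: synthetic package prices (EUR, 2013) for the generator and the examples;
#: stands in for a national drug-price register, which is out of scope
DEFAULT_DRUG_PRICES = DrugPriceTable(
    packages={
        "sertraline": [(100, 24.0, 28.0), (50, 15.5, 18.0), (20, 9.0, 10.5)],
        "citalopram": [(100, 19.5, 23.0), (50, 13.0, 15.0), (20, 8.0, 9.5)],
        "mirtazapine": [(100, 27.0, 31.0), (48, 17.0, 19.5)],
        "zopiclone": [(20, 12.5, 14.5), (10, 8.5, 10.0)],
        "ibuprofen": [(50, 6.5, 7.5), (20, 4.0, 4.8)],
    }
)


def read_drug_prices(path) -> DrugPriceTable:
    """Read a drug-price CSV (drug, pack_size, statutory_price_eur,
    private_price_eur)."""
    import pandas as pd

    df = pd.read_csv(path)
    packages: dict[str, list[tuple[float, float, float]]] = {}
    for _, row in df.iterrows():
        packages.setdefault(str(row["drug"]), []).append(
            (
                float(row["pack_size"]),
                float(row["statutory_price_eur"]),
                float(row["private_price_eur"]),
            )
        )
    return DrugPriceTable(packages=packages)


# --------------------------------------------------------------------------
# category operations
# --------------------------------------------------------------------------


def service_costs(window: ResourceWindow, unit_costs: UnitCostTable) -> dict[str, float]:
    """Units x unit price for the contact/day-based health-care categories."""
    return {
        "physician": (
            window.physician_contacts * unit_costs.unit_price("physician_contact")
            + window.specialist_contacts * unit_costs.unit_price("specialist_contact")
        ),
        "psychological": window.psychological_contacts
        * unit_costs.unit_price("psychological_contact"),
        "inpatient": window.inpatient_days * unit_costs.unit_price("inpatient_day"),
        "semiresidential": window.semiresidential_days
        * unit_costs.unit_price("semiresidential_day"),
        "rehabilitation": window.rehabilitation_days
        * unit_costs.unit_price("rehabilitation_day"),
        "nonphysician": window.allied_health_contacts
        * unit_costs.unit_price("allied_health_contact"),
    }


def medication_costs(
    prescriptions: list[tuple[str, float]],
    price_table: DrugPriceTable,
    statutory_share: float = 0.888,
) -> float:
    """Prescription-drug cost: packages x insurance-share-weighted mean price
    of the drug's up-to-3 largest packages."""
    return sum(
        packs * price_table.weighted_price(drug, statutory_share)
        for drug, packs in prescriptions
    )


def travel_costs(trips: list[tuple[str, float]], unit_costs: UnitCostTable) -> float:
    """Car trips carry round-trip km (valued per km); bus/taxi carry fares."""
    total = 0.0
    for mode, qty in trips:
        if mode == "car":
            total += qty * unit_costs.car_km_rate
        elif mode in ("bus", "taxi"):
            total += qty
        else:
            raise ValueError(f"unknown travel mode {mode!r}")
    return total


def opportunity_costs(hours: float, unit_costs: UnitCostTable) -> float:
    """Leisure time spent waiting for / receiving treatment, valued at the
    opportunity rate. Time spent on the intervention itself is leisure time
    and is deliberately not costed."""
    return hours * unit_costs.opportunity_rate


def informal_care_costs(hours: float, unit_costs: UnitCostTable) -> float:
    """Domestic help and informal care valued by the substitution method
    (market wage of a professional substitute)."""
    return hours * unit_costs.informal_care_rate


def absenteeism_cost(
    absence_days: float,
    gross_monthly_wage: float,
    workdays_per_month: float = WORKDAYS_PER_MONTH,
) -> float:
    """Human capital approach: work-loss days x gross daily wage."""
    return absence_days * gross_monthly_wage / workdays_per_month


def presenteeism_cost(
    impaired_days: float,
    inefficiency_score: float,
    gross_monthly_wage: float,
    workdays_per_month: float = WORKDAYS_PER_MONTH,
) -> float:
    """Reduced-efficiency workdays x inefficiency score = lost-workday
    equivalents, valued at the gross daily wage."""
    equivalents = impaired_days * inefficiency_score
    return equivalents * gross_monthly_wage / workdays_per_month


def intervention_cost(arm: str, unit_costs: UnitCostTable, offset: float = 0.0) -> float:
    """Flat intervention tariff for the treatment arm; zero for control."""
    return unit_costs.intervention_price + offset if arm == "ISMI" else 0.0


def cumulate_auc(
    cost_w1: float, cost_w3: float, horizon_months: float = 6.0, mode: str = "trapezoid"
) -> float:
    """Cumulate two 3-month window costs to the follow-up horizon.

    ``trapezoid`` linearly interpolates between the two window rates —
    6-month cost = (w1 + w3)/2 x (horizon/3). ``double_followup`` instead
    extrapolates the follow-up window alone over the horizon.
    """
    if cost_w1 is None or cost_w3 is None:
        raise ValueError("both windows required; run cost imputation first")
    scale = horizon_months / 3.0
    if mode == "trapezoid":
        return (cost_w1 + cost_w3) / 2.0 * scale
    if mode == "double_followup":
        return cost_w3 * scale
    raise ValueError(f"unknown AUC mode {mode!r}")


def price_adjust(amount_eur: float, index_factor: float = 1.0, ppp: float = 1.29) -> tuple[float, float]:
    """Index an amount to the reference year and convert to US dollars at
    the purchasing power parity; returns (EUR, USD)."""
    eur = amount_eur * index_factor
    return eur, eur * ppp


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Reporting-grade rounding (half away from zero on .5 ties)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------------
# per-window and per-participant assembly
# --------------------------------------------------------------------------


def window_costs(
    window: ResourceWindow,
    unit_costs: UnitCostTable,
    gross_monthly_wage: float,
    drug_prices: DrugPriceTable = DEFAULT_DRUG_PRICES,
    workdays_per_month: float = WORKDAYS_PER_MONTH,
) -> dict[str, float]:
    """All recurring category costs (EUR) for one 3-month recall window."""
    costs = service_costs(window, unit_costs)
    costs["prescription"] = medication_costs(
        window.prescriptions, drug_prices, unit_costs.statutory_share
    )
    costs["otc"] = window.otc_spend
    costs["opportunity"] = opportunity_costs(
        window.waiting_and_treatment_hours, unit_costs
    )
    costs["travel"] = travel_costs(window.travel, unit_costs)
    costs["informal_care"] = informal_care_costs(window.informal_care_hours, unit_costs)
    costs["absenteeism"] = absenteeism_cost(
        window.absence_days, gross_monthly_wage, workdays_per_month
    )
    costs["presenteeism"] = presenteeism_cost(
        window.impaired_days,
        window.inefficiency_score,
        gross_monthly_wage,
        workdays_per_month,
    )
    return costs


def cost_breakdown(
    participant: ParticipantRecord,
    unit_costs: UnitCostTable,
    options: Optional[CostingOptions] = None,
    drug_prices: DrugPriceTable = DEFAULT_DRUG_PRICES,
) -> CostBreakdown:
    """Full per-participant breakdown: both windows costed, categories
    cumulated to 6 months via the AUC rule, intervention tariff added once.

    Requires both recall windows (impute first when the follow-up window is
    missing); scenario options may exclude categories or offset the
    intervention price.
    """
    opts = options or CostingOptions()
    per_window: dict[str, dict[str, float]] = {}
    for w in ("W1", "W3"):
        win = participant.resource_use.get(w)
        if win is None:
            raise ValueError(
                f"{participant.id}: resource window {w} missing; "
                "cost imputation must run first"
            )
        wc = window_costs(
            win,
            unit_costs,
            participant.gross_monthly_wage,
            drug_prices,
            opts.workdays_per_month,
        )
        for cat in opts.exclude_categories:
            wc[cat] = 0.0
        per_window[w] = wc

    six_month = {
        cat: cumulate_auc(per_window["W1"][cat], per_window["W3"][cat], mode=opts.auc_mode)
        for cat in RECURRING_CATEGORIES
    }
    six_month["intervention"] = (
        0.0
        if "intervention" in opts.exclude_categories
        else intervention_cost(participant.arm, unit_costs, opts.intervention_offset)
    )
    return CostBreakdown(
        participant_id=participant.id,
        arm=participant.arm,
        window_costs=per_window,
        six_month=six_month,
    ).finalize()
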