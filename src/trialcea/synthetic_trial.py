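"""Synthetic two-arm trial generator.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline is testable without any data download: N = 2 x 132
employees randomized 1:1 to a guided internet-based stress-management
intervention (ISMI) or waitlist control (WLC); baseline PSS-10 drawn from
N(25.52, 3.91) truncated below at the inclusion cutoff of 22; arm-specific
mean PSS improvement to follow-up (9.75 vs 3.0 units, common SD 6);
SF-6D utility around 0.65 at baseline (SD 0.11 ISMI / 0.08 WLC), coupled
negatively to the concurrent stress score through a Gaussian copula;
right-skewed zero-inflated resource use with rare (3.4%) inpatient
admissions; and differential dropout (12.8% vs 8.33%) that removes the
follow-up assessment and recall window.

The generator reproduces the stated marginals, not the real trial's joint
distribution. :func:`expected_summaries` gives the generator's closed-form
moments, which the parameter-recovery tests compare against sample moments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .costing import DEFAULT_DRUG_PRICES, DrugPriceTable, WORKDAYS_PER_MONTH
from .trial_data import ParticipantRecord, ResourceWindow, UnitCostTable


@dataclass(frozen=True)
class ZeroInflatedLognormal:
    """Zero with probability ``p_zero``; otherwise lognormal with positive-part
    mean ``mean_pos`` and log-scale ``sigma``."""

    p_zero: float
    mean_pos: float
    sigma: float = 0.6

    @property
    def mu(self) -> float:
        return math.log(self.mean_pos) - self.sigma**2 / 2.0

    @property
    def mean(self) -> float:
        return (1.0 - self.p_zero) * self.mean_pos

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        pos = rng.lognormal(self.mu, self.sigma, size=n)
        zero = rng.random(n) < self.p_zero
        return np.where(zero, 0.0, pos)


@dataclass(frozen=True)
class ArmEffects:
    """Mean PSS improvement T1->T3 and utility gains over baseline."""

    pss_improvement: float
    pss_t2_fraction: float       # share of the T3 improvement realized at T2
    sf6d_gain_t2: float
    sf6d_gain_t3: float
    eq5d_gain_t2: float
    eq5d_gain_t3: float
    dropout_prob: float


@dataclass(frozen=True)
class GeneratorConfig:
    n_per_arm: int = 132
    baseline_pss_mean: float = 25.52
    baseline_pss_sd: float = 3.91
    inclusion_cutoff: float = 22.0
    pss_change_sd: float = 6.0
    pss_t2_sd: float = 4.0

    baseline_sf6d_mean: float = 0.65
    sf6d_sd: dict[str, float] = field(
        default_factory=lambda: {"ISMI": 0.11, "WLC": 0.08}
    )
    baseline_eq5d_mean: float = 0.56
    eq5d_sd: float = 0.10
    utility_pss_correlation: float = -0.4

    effects: dict[str, ArmEffects] = field(
        default_factory=lambda: {
            "ISMI": ArmEffects(9.75, 0.8, 0.015, 0.025, 0.003, 0.006, 0.128),
            "WLC": ArmEffects(3.0, 0.3, 0.0, 0.0, 0.0, 0.0, 0.0833),
        }
    )

    # zero-inflated right-skewed resource use, in natural units per window
    cost_models: dict[str, ZeroInflatedLognormal] = field(
        default_factory=lambda: {
            "physician_contacts": ZeroInflatedLognormal(0.35, 4.0),
            "specialist_contacts": ZeroInflatedLognormal(0.70, 2.0),
            "psychological_contacts": ZeroInflatedLognormal(0.80, 5.0),
            "allied_health_contacts": ZeroInflatedLognormal(0.60, 8.0),
            "semiresidential_days": ZeroInflatedLognormal(0.985, 12.0),
            "rehabilitation_days": ZeroInflatedLognormal(0.99, 8.0),
            "otc_spend": ZeroInflatedLognormal(0.50, 45.0),
            "waiting_and_treatment_hours": ZeroInflatedLognormal(0.20, 14.0),
            "car_km": ZeroInflatedLognormal(0.45, 60.0),
            "informal_care_hours": ZeroInflatedLognormal(0.70, 50.0),
            "absence_days": ZeroInflatedLognormal(0.55, 11.0),
            "impaired_days": ZeroInflatedLognormal(0.35, 25.0),
        }
    )
    inpatient_admission_prob: float = 0.034
    inpatient_days_model: ZeroInflatedLognormal = ZeroInflatedLognormal(0.0, 7.0, 0.5)
    taxi_prob: float = 0.08
    taxi_fare_mean: float = 18.0
    prescription_prob: float = 0.45
    packages_extra_n: int = 2      # packages = 1 + Binomial(n, p)
    packages_extra_p: float = 0.5
    inefficiency_alpha: float = 2.0
    inefficiency_beta: float = 5.0

    #: multiplicative intervention effect on follow-up-window resource use
    #: (applied to the natural quantity, treatment arm only)
    ismi_w3_factors: dict[str, float] = field(
        default_factory=lambda: {
            "psychological_contacts": 0.40,
            "informal_care_hours": 0.50,
            "absence_days": 0.70,
            "impaired_days": 0.75,
            "waiting_and_treatment_hours": 0.85,
        }
    )

    wage_median: float = 3000.0
    wage_sigma: float = 0.4

    def validate(self) -> None:
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be >= 2")
        if self.baseline_pss_sd <= 0:
            raise ValueError("baseline PSS SD must be positive (truncation degenerate)")
        for name, p in (
            ("inpatient_admission_prob", self.inpatient_admission_prob),
            ("taxi_prob", self.taxi_prob),
            ("prescription_prob", self.prescription_prob),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        for arm, eff in self.effects.items():
            if not 0.0 <= eff.dropout_prob <= 1.0:
                raise ValueError(f"dropout_prob for {arm} must be in [0,1]")
        for sd in self.sf6d_sd.values():
            if sd <= 0:
                raise ValueError("utility SDs must be positive")


def _truncated_baseline(
    config: GeneratorConfig, rng: np.random.Generator, n: int
) -> np.ndarray:
    a = (config.inclusion_cutoff - config.baseline_pss_mean) / config.baseline_pss_sd
    draws = stats.truncnorm.rvs(
        a, np.inf,
        loc=config.baseline_pss_mean,
        scale=config.baseline_pss_sd,
        size=n,
        random_state=rng,
    )
    return np.clip(np.rint(draws), config.inclusion_cutoff, 40).astype(int)


def _coupled_utility(
    rng: np.random.Generator,
    pss: np.ndarray,
    mean: float,
    sd: float,
    rho: float,
    lo: float,
    hi: float,
) -> np.ndarray:
    """Utility draw sharing a Gaussian copula with the concurrent PSS score.

    The PSS score is standardized within the sample so the utility mean is
    ``mean`` regardless of the coupling strength.
    """
    z_pss = (pss - pss.mean()) / (pss.std() if pss.std() > 0 else 1.0)
    eps = rng.standard_normal(pss.size)
    z = rho * z_pss + math.sqrt(max(0.0, 1.0 - rho**2)) * eps
    return np.clip(mean + sd * z, lo, hi)


def generate_trial(
    config: GeneratorConfig = GeneratorConfig(),
    seed: int = 0,
    drug_prices: DrugPriceTable = DEFAULT_DRUG_PRICES,
) -> list[ParticipantRecord]:
    """Draw one synthetic trial dataset; identical (config, seed) pairs give
    identical datasets."""
    config.validate()
    rng = np.random.default_rng(seed)
    drug_ids = sorted(drug_prices.packages)
    records: list[ParticipantRecord] = []

    for arm in ("ISMI", "WLC"):
        eff = config.effects[arm]
        n = config.n_per_arm
        pss_t1 = _truncated_baseline(config, rng, n)
        imp_t3 = rng.normal(eff.pss_improvement, config.pss_change_sd, n)
        pss_t3 = np.clip(np.rint(pss_t1 - imp_t3), 0, 40).astype(int)
        imp_t2 = rng.normal(eff.pss_t2_fraction * eff.pss_improvement, config.pss_t2_sd, n)
        pss_t2 = np.clip(np.rint(pss_t1 - imp_t2), 0, 40).astype(int)
        pss = {"T1": pss_t1, "T2": pss_t2, "T3": pss_t3}

        rho = config.utility_pss_correlation
        sf_sd = config.sf6d_sd[arm]
        sf_means = {
            "T1": config.baseline_sf6d_mean,
            "T2": config.baseline_sf6d_mean + eff.sf6d_gain_t2,
            "T3": config.baseline_sf6d_mean + eff.sf6d_gain_t3,
        }
        eq_means = {
            "T1": config.baseline_eq5d_mean,
            "T2": config.baseline_eq5d_mean + eff.eq5d_gain_t2,
            "T3": config.baseline_eq5d_mean + eff.eq5d_gain_t3,
        }
        sf6d = {
            t: _coupled_utility(rng, pss[t], sf_means[t], sf_sd, rho, 0.0, 1.0)
            for t in ("T1", "T2", "T3")
        }
        eq5d = {
            t: _coupled_utility(rng, pss[t], eq_means[t], config.eq5d_sd, rho, -0.59, 1.0)
            for t in ("T1", "T2", "T3")
        }

        wage = rng.lognormal(math.log(config.wage_median), config.wage_sigma, n)

        # resource use per window; a single rare inpatient admission lands in
        # one of the two windows with equal probability
        admitted = rng.random(n) < config.inpatient_admission_prob
        adm_days = np.clip(config.inpatient_days_model.sample(rng, n), 0, 92)
        adm_window = rng.integers(0, 2, n)  # 0 -> W1, 1 -> W3

        windows: dict[str, list[ResourceWindow]] = {"W1": [], "W3": []}
        for wi, w in enumerate(("W1", "W3")):
            factors = (
                config.ismi_w3_factors if (arm == "ISMI" and w == "W3") else {}
            )
            qty = {
                name: model.sample(rng, n) * factors.get(name, 1.0)
                for name, model in config.cost_models.items()
            }
            ineff = rng.beta(config.inefficiency_alpha, config.inefficiency_beta, n)
            has_rx = rng.random(n) < config.prescription_prob
            rx_drug = rng.integers(0, len(drug_ids), n)
            rx_packs = 1 + rng.binomial(config.packages_extra_n, config.packages_extra_p, n)
            has_taxi = rng.random(n) < config.taxi_prob
            # fare lognormal parametrized by its mean (sigma = 0.5)
            taxi_fare = rng.lognormal(math.log(config.taxi_fare_mean) - 0.125, 0.5, n)
            inpat = np.where(admitted & (adm_window == wi), adm_days, 0.0)
            for i in range(n):
                travel = []
                if qty["car_km"][i] > 0:
                    travel.append(("car", float(qty["car_km"][i])))
                if has_taxi[i]:
                    travel.append(("taxi", float(taxi_fare[i])))
                prescriptions = (
                    [(drug_ids[rx_drug[i]], float(rx_packs[i]))] if has_rx[i] else []
                )
                windows[w].append(
                    ResourceWindow(
                        physician_contacts=float(qty["physician_contacts"][i]),
                        specialist_contacts=float(qty["specialist_contacts"][i]),
                        psychological_contacts=float(qty["psychological_contacts"][i]),
                        allied_health_contacts=float(qty["allied_health_contacts"][i]),
                        inpatient_days=float(inpat[i]),
                        semiresidential_days=float(qty["semiresidential_days"][i]),
                        rehabilitation_days=float(qty["rehabilitation_days"][i]),
                        prescriptions=prescriptions,
                        otc_spend=float(qty["otc_spend"][i]),
                        travel=travel,
                        waiting_and_treatment_hours=float(
                            qty["waiting_and_treatment_hours"][i]
                        ),
                        informal_care_hours=float(qty["informal_care_hours"][i]),
                        absence_days=float(qty["absence_days"][i]),
                        impaired_days=float(qty["impaired_days"][i]),
                        inefficiency_score=float(ineff[i]),
                    )
                )

        dropped = rng.random(n) < eff.dropout_prob
        for i in range(n):
            is_drop = bool(dropped[i])
            records.append(
                ParticipantRecord(
                    id=f"{arm}-{i + 1:04d}",
                    arm=arm,
                    pss={
                        "T1": int(pss_t1[i]),
                        "T2": None if is_drop else int(pss_t2[i]),
                        "T3": None if is_drop else int(pss_t3[i]),
                    },
                    utility_sf6d={
                        "T1": float(sf6d["T1"][i]),
                        "T2": None if is_drop else float(sf6d["T2"][i]),
                        "T3": None if is_drop else float(sf6d["T3"][i]),
                    },
                    utility_eq5d={
                        "T1": float(eq5d["T1"][i]),
                        "T2": None if is_drop else float(eq5d["T2"][i]),
                        "T3": None if is_drop else float(eq5d["T3"][i]),
                    },
                    resource_use={
                        "W1": windows["W1"][i],
                        "W3": None if is_drop else windows["W3"][i],
                    },
                    gross_monthly_wage=float(wage[i]),
                )
            )
    return records


def expected_summaries(
    config: GeneratorConfig = GeneratorConfig(),
    unit_costs: UnitCostTable | None = None,
    drug_prices: DrugPriceTable = DEFAULT_DRUG_PRICES,
) -> dict:
    """Closed-form generator moments: per-arm mean PSS improvement, mean
    QALYs and expected 6-month cost by category (trapezoidal cumulation of
    the two window means)."""
    uc = unit_costs or UnitCostTable()
    cm = config.cost_models
    drug_ids = sorted(drug_prices.packages)
    mean_price = sum(
        drug_prices.weighted_price(d, uc.statutory_share) for d in drug_ids
    ) / len(drug_ids)
    e_packs = 1 + config.packages_extra_n * config.packages_extra_p
    e_wage = config.wage_median * math.exp(config.wage_sigma**2 / 2.0)
    e_daily_wage = e_wage / WORKDAYS_PER_MONTH
    e_ineff = config.inefficiency_alpha / (
        config.inefficiency_alpha + config.inefficiency_beta
    )

    def window_means(factors: dict[str, float]) -> dict[str, float]:
        def q(name: str) -> float:
            return cm[name].mean * factors.get(name, 1.0)

        return {
            "physician": q("physician_contacts") * uc.unit_price("physician_contact")
            + q("specialist_contacts") * uc.unit_price("specialist_contact"),
            "psychological": q("psychological_contacts")
            * uc.unit_price("psychological_contact"),
            "inpatient": config.inpatient_admission_prob
            / 2.0
            * config.inpatient_days_model.mean_pos
            * uc.unit_price("inpatient_day"),
            "semiresidential": q("semiresidential_days")
            * uc.unit_price("semiresidential_day"),
            "rehabilitation": q("rehabilitation_days")
            * uc.unit_price("rehabilitation_day"),
            "nonphysician": q("allied_health_contacts")
            * uc.unit_price("allied_health_contact"),
            "prescription": config.prescription_prob * e_packs * mean_price,
            "otc": q("otc_spend"),
            "opportunity": q("waiting_and_treatment_hours") * uc.opportunity_rate,
            "travel": q("car_km") * uc.car_km_rate
            + config.taxi_prob * config.taxi_fare_mean,
            "informal_care": q("informal_care_hours") * uc.informal_care_rate,
            "absenteeism": q("absence_days") * e_daily_wage,
            "presenteeism": q("impaired_days") * e_ineff * e_daily_wage,
        }

    from .outcomes import qaly_auc  # local import avoids a cycle at module load

    out: dict = {"arms": {}}
    for arm in ("ISMI", "WLC"):
        eff = config.effects[arm]
        w1 = window_means({})
        w3 = window_means(config.ismi_w3_factors if arm == "ISMI" else {})
        six_month = {cat: w1[cat] + w3[cat] for cat in w1}
        six_month["intervention"] = uc.intervention_price if arm == "ISMI" else 0.0
        sf_traj = (
            config.baseline_sf6d_mean,
            config.baseline_sf6d_mean + eff.sf6d_gain_t2,
            config.baseline_sf6d_mean + eff.sf6d_gain_t3,
        )
        eq_traj = (
            config.baseline_eq5d_mean,
            config.baseline_eq5d_mean + eff.eq5d_gain_t2,
            config.baseline_eq5d_mean + eff.eq5d_gain_t3,
        )
        out["arms"][arm] = {
            "pss_improvement": eff.pss_improvement,
            "qaly_sf6d": qaly_auc(sf_traj),
            "qaly_eq5d": qaly_auc(eq_traj),
            "six_month_costs": six_month,
            "total_cost": sum(six_month.values()),
        }
    i, w = out["arms"]["ISMI"], out["arms"]["WLC"]
    out["delta"] = {
        "pss_improvement": i["pss_improvement"] - w["pss_improvement"],
        "qaly_sf6d": i["qaly_sf6d"] - w["qaly_sf6d"],
        "qaly_eq5d": i["qaly_eq5d"] - w["qaly_eq5d"],
        "total_cost": i["total_cost"] - w["total_cost"],
    }
    return out
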