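"""Seeded synthetic intraoperative cohorts for end-to-end pipeline testing.

The generator emulates the statistical structure the TVI pipeline assumes:
three latent physiologic regimes (elevated / mixed / depressed) with
regime-specific MAP/BIS/MAC means, multi-rate quasi-periodic recording
(MAP roughly every 3 minutes, BIS and inhaled agents roughly every 5, with
timestamp jitter so streams rarely coincide), negative BIS–MAC coupling
through a shared anesthetic-depth factor, artifact contamination, CPB
cases with a mid-case gap in agent charting, repeat-surgery patients, and
regime-linked postoperative mortality. Agent concentrations are back-solved
from target MAC values so the agent→MAC round trip is exact; there are no
physiologic dynamics — streams are noisy draws around latent case means.

Every draw flows from one seeded generator, so a given spec and seed
reproduce byte-identical CSV output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tvi_core import MacEquivalents

__all__ = [
    "RegimeSpec",
    "CohortSpec",
    "CohortData",
    "default_regimes",
    "generate_cohort",
    "generate_worked_micro_case",
    "MICRO_CASE_ID",
]

REGIME_NAMES = ("elevated", "mixed", "depressed")


@dataclass(frozen=True)
class RegimeSpec:
    """One latent physiologic regime.

    SDs are measurement-level (within-case) spreads; mortality fields are
    per-window death probabilities. Defaults for the three regimes come
    from :func:`default_regimes`.
    """

    name: str
    prevalence: float
    map_mean: float
    map_sd: float
    bis_mean: float
    bis_sd: float
    mac_mean: float
    mac_sd: float
    mortality_30d: float
    mortality_31_365: float = 0.0
    mortality_366_730: float = 0.0
    age_mean: float = 53.6
    age_sd: float = 16.8
    male_fraction: float = 0.538
    emergent_fraction: float = 0.104
    asa_probs: tuple[float, ...] = (0.045, 0.289, 0.481, 0.176, 0.009)

    def __post_init__(self) -> None:
        if not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must lie in [0, 1]")
        if min(self.map_sd, self.bis_sd, self.mac_sd) <= 0:
            raise ValueError("regime SDs must be positive")
        for p in (self.mortality_30d, self.mortality_31_365, self.mortality_366_730):
            if not 0 <= p <= 1:
                raise ValueError("mortality probabilities must lie in [0, 1]")


def default_regimes() -> tuple[RegimeSpec, RegimeSpec, RegimeSpec]:
    """The three regimes at the published cluster prevalences and means.

    Prevalences 891/2931/1474 of 5296 profiles; MAP means 86.5/82.3/76.6
    mmHg, BIS 45.3/41.8/38.0, MAC 0.98/0.817/0.666; mortality 0.8/2.7/5.6%
    (30 d), 4.9/6.7/7.4% (31–365 d), 3.3/3.8/4.3% (366–730 d). Within-case
    measurement SDs (MAP 10 mmHg, BIS 6.5, MAC 0.17) are set so that
    window-averaged noise stays below the separation between adjacent
    regime means — the regimes the generator plants are meant to be
    identifiable, since validating their recovery is the generator's
    purpose; the resulting pooled dispersion is somewhat tighter than
    real-world intraoperative variability.
    """
    return (
        RegimeSpec(
            name="elevated", prevalence=891 / 5296,
            map_mean=86.5, map_sd=10.0, bis_mean=45.3, bis_sd=6.5,
            mac_mean=0.98, mac_sd=0.17,
            mortality_30d=0.008, mortality_31_365=0.049, mortality_366_730=0.033,
            age_mean=52.0, male_fraction=0.569, emergent_fraction=0.058,
            asa_probs=(0.052, 0.368, 0.511, 0.067, 0.002),
        ),
        RegimeSpec(
            name="mixed", prevalence=2931 / 5296,
            map_mean=82.3, map_sd=10.0, bis_mean=41.8, bis_sd=6.5,
            mac_mean=0.817, mac_sd=0.17,
            mortality_30d=0.027, mortality_31_365=0.067, mortality_366_730=0.038,
            age_mean=53.7, male_fraction=0.534, emergent_fraction=0.105,
            asa_probs=(0.046, 0.296, 0.490, 0.161, 0.007),
        ),
        RegimeSpec(
            name="depressed", prevalence=1474 / 5296,
            map_mean=76.6, map_sd=10.0, bis_mean=38.0, bis_sd=6.5,
            mac_mean=0.666, mac_sd=0.17,
            mortality_30d=0.056, mortality_31_365=0.074, mortality_366_730=0.043,
            age_mean=54.5, male_fraction=0.527, emergent_fraction=0.128,
            asa_probs=(0.039, 0.227, 0.444, 0.273, 0.017),
        ),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Full cohort-generation specification.

    Recording intervals (minutes) and the log-normal duration distribution
    (median 1.8 h) follow the published cohort summaries; ``jitter_frac``
    perturbs each inter-measurement gap by up to ±20% so the MAP and
    BIS/agent streams rarely share timestamps. ``between_case_sd`` values
    spread the latent case means within a regime; they are kept small
    because the regime itself encodes the case-level mean. ``mortality_link``
    is ``"regime"`` (per-regime window probabilities) or ``"logistic_tvi"``
    (30-day death probability a logistic function of the case's
    standardized latent TVI; later windows still from regime rates).
    """

    n_cases: int
    regimes: tuple[RegimeSpec, ...] = field(default_factory=default_regimes)
    map_interval_min: float = 3.0
    bis_interval_min: float = 5.0
    mac_interval_min: float = 5.0
    duration_median_hr: float = 1.8
    duration_log_sd: float = 0.5
    min_duration_min: float = 20.0
    max_duration_min: float = 600.0
    artifact_rate: float = 0.005
    cpb_fraction: float = 0.04
    cpb_missing_fraction: float = 0.33
    repeat_patient_fraction: float = 0.15
    multi_agent_fraction: float = 0.1
    jitter_frac: float = 0.2
    bis_mac_coupling: bool = True
    coupling_rho: float = 0.45
    map_between_sd: float = 1.0
    bis_between_sd: float = 0.7
    mac_between_sd: float = 0.02
    mortality_link: str = "regime"
    logistic_intercept: float = -4.0
    logistic_slope: float = -2.0
    follow_up_days: int = 800
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if min(self.map_interval_min, self.bis_interval_min, self.mac_interval_min) <= 0:
            raise ValueError("recording intervals must be positive")
        if abs(sum(r.prevalence for r in self.regimes) - 1.0) > 1e-9:
            raise ValueError("regime prevalences must sum to 1")
        if not 0 <= self.artifact_rate <= 1:
            raise ValueError("artifact_rate must lie in [0, 1]")
        if self.mortality_link not in ("regime", "logistic_tvi"):
            raise ValueError(f"unknown mortality_link {self.mortality_link!r}")
        if not 0 <= self.jitter_frac < 1:
            raise ValueError("jitter_frac must lie in [0, 1)")


@dataclass
class CohortData:
    """Generated cohort tables, in the exact CSV dialects the readers ingest."""

    measurements: pd.DataFrame
    cases: pd.DataFrame
    medications: pd.DataFrame
    truth: pd.DataFrame

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.measurements.to_csv(out / "measurements.csv", index=False)
        self.cases.to_csv(out / "cases.csv", index=False)
        self.medications.to_csv(out / "medications.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)


# Per-regime medication administration probabilities (elevated, mixed,
# depressed) and a median total dose, mirroring the published pattern of
# use; doses are log-normal around the median.
_MEDICATIONS: dict[str, tuple[tuple[float, float, float], float]] = {
    "propofol": ((0.97, 0.97, 0.96), 185.0),
    "fentanyl": ((0.96, 0.96, 0.96), 250.0),
    "hydromorphone": ((0.476, 0.263, 0.252), 1.0),
    "etomidate": ((0.030, 0.073, 0.126), 14.0),
    "ketamine": ((0.112, 0.046, 0.030), 30.0),
    "dexmedetomidine": ((0.184, 0.166, 0.136), 40.0),
    "phenylephrine": ((0.740, 0.748, 0.830), 500.0),
    "epinephrine": ((0.020, 0.060, 0.180), 0.1),
    "norepinephrine": ((0.024, 0.075, 0.212), 0.5),
    "vasopressin": ((0.034, 0.076, 0.210), 2.0),
    "succinylcholine": ((0.740, 0.690, 0.619), 100.0),
    "remifentanil": ((0.020, 0.050, 0.085), 250.0),
}

_SPECIALTIES = ("General", "Orthopedic", "Thoracic", "Cardiac", "Other")
_SPECIALTY_PROBS = {
    "elevated": (0.35, 0.20, 0.11, 0.022, 0.318),
    "mixed": (0.32, 0.19, 0.10, 0.065, 0.325),
    "depressed": (0.29, 0.16, 0.10, 0.161, 0.289),
}
_PROCEDURES = (
    "Irrigation and Debridement of Wound",
    "Exploratory Laparotomy",
    "Anterior Cervical Discectomy and Fusion",
    "Aortic Valve Replacement",
    "Other Procedure",
)
_PROCEDURE_PROBS = (0.10, 0.05, 0.03, 0.02, 0.80)


def _schedule(rng: np.random.Generator, duration: float, interval: float, jitter: float) -> np.ndarray:
    """Quasi-periodic measurement times on [0, duration], jittered gaps."""
    n = int(duration / (interval * (1 - jitter) if jitter else interval)) + 2
    gaps = interval * (1 + rng.uniform(-jitter, jitter, n))
    t = np.concatenate(([0.0], np.cumsum(gaps)))
    return t[t <= duration]


def _latent_standardizer(spec: CohortSpec):
    """Mean/SD of the latent TVI (sum of standardized latent case means)."""
    prev = np.array([r.prevalence for r in spec.regimes])
    out = {}
    for var, between in (
        ("map", spec.map_between_sd),
        ("bis", spec.bis_between_sd),
        ("mac", spec.mac_between_sd),
    ):
        means = np.array([getattr(r, f"{var}_mean") for r in spec.regimes])
        mu = float(prev @ means)
        var_mix = float(prev @ ((means - mu) ** 2)) + between**2
        out[var] = (mu, math.sqrt(var_mix))
    # latent TVI = sum of per-variable standardized latent means; its SD
    # combines the perfectly regime-coupled part and independent
    # between-case parts
    zsums = []
    for r, p in zip(spec.regimes, prev):
        z = sum(
            (getattr(r, f"{v}_mean") - out[v][0]) / out[v][1] for v in ("map", "bis", "mac")
        )
        zsums.append((z, p))
    mean_z = sum(z * p for z, p in zsums)
    var_regime = sum(p * (z - mean_z) ** 2 for z, p in zsums)
    var_between = sum(
        (b / out[v][1]) ** 2
        for v, b in (
            ("map", spec.map_between_sd),
            ("bis", spec.bis_between_sd),
            ("mac", spec.mac_between_sd),
        )
    )
    sd_z = math.sqrt(var_regime + var_between)
    return out, mean_z, sd_z


def generate_cohort(spec: CohortSpec) -> CohortData:
    """Generate a full synthetic cohort from a validated spec.

    Returns measurement, case, medication, and latent-truth tables. The
    truth table records each case's planted regime, standardized latent
    TVI, and death day — the reference for cluster-recovery and
    mortality-model checks.
    """
    rng = np.random.default_rng(spec.seed)
    equivalents = MacEquivalents()
    prev = np.array([r.prevalence for r in spec.regimes])
    per_var_std, latent_mean, latent_sd = _latent_standardizer(spec)

    m_case, m_t, m_var, m_val, m_src = [], [], [], [], []
    case_rows, med_rows, truth_rows = [], [], []

    for i in range(spec.n_cases):
        case_id = f"C{i + 1:05d}"
        regime_idx = int(rng.choice(len(spec.regimes), p=prev))
        regime = spec.regimes[regime_idx]

        duration = float(
            np.clip(
                math.exp(rng.normal(math.log(spec.duration_median_hr * 60.0), spec.duration_log_sd)),
                spec.min_duration_min,
                spec.max_duration_min,
            )
        )
        map_mu = regime.map_mean + rng.normal(0.0, spec.map_between_sd)
        bis_mu = regime.bis_mean + rng.normal(0.0, spec.bis_between_sd)
        mac_mu = regime.mac_mean + rng.normal(0.0, spec.mac_between_sd)

        # --- MAP stream -------------------------------------------------
        t_map = _schedule(rng, duration, spec.map_interval_min, spec.jitter_frac)
        map_vals = np.clip(rng.normal(map_mu, regime.map_sd, t_map.size), 20.0, 240.0)
        if spec.artifact_rate > 0:
            mask = rng.random(t_map.size) < spec.artifact_rate
            if mask.any():
                side = rng.random(int(mask.sum())) < 0.5
                bad = np.where(
                    side,
                    rng.uniform(0.5, 9.5, side.size),
                    rng.uniform(250.5, 300.0, side.size),
                )
                map_vals[mask] = bad
        arterial = bool(rng.random() < 0.25)

        # --- shared depth schedule for BIS and agents --------------------
        t_depth = _schedule(rng, duration, spec.bis_interval_min, spec.jitter_frac)
        depth = rng.normal(0.0, 1.0, t_depth.size)
        # BIS and agent concentrations are charted at the same events (one
        # machine charting stream); MAP is charted separately, so MAP and
        # BIS/agent timestamps rarely coincide.
        t_bis = np.round(t_depth + rng.uniform(0.0, 0.4, t_depth.size), 2)
        t_agent = t_bis

        if spec.bis_mac_coupling:
            rho = spec.coupling_rho
            eps = rng.normal(0.0, 1.0, t_depth.size)
            bis_vals = bis_mu + regime.bis_sd * (-rho * depth + math.sqrt(1 - rho**2) * eps)
        else:
            bis_vals = rng.normal(bis_mu, regime.bis_sd, t_depth.size)
        bis_vals = np.clip(bis_vals, 2.0, 98.0)
        if spec.artifact_rate > 0:
            mask = rng.random(t_depth.size) < spec.artifact_rate
            bis_vals[mask] = 0.0

        mac_targets = np.clip(mac_mu + regime.mac_sd * depth, 0.05, 2.8)
        if spec.artifact_rate > 0:
            mask = rng.random(t_depth.size) < spec.artifact_rate
            if mask.any():
                mac_targets[mask] = rng.uniform(3.05, 4.0, int(mask.sum()))

        # --- CPB gap in agent charting -----------------------------------
        cpb = bool(rng.random() < spec.cpb_fraction)
        if cpb:
            f = spec.cpb_missing_fraction
            cpb_start = duration * (0.5 - f / 2)
            cpb_end = duration * (0.5 + f / 2)
            keep_agent = (t_agent < cpb_start) | (t_agent >= cpb_end)
        else:
            cpb_start = cpb_end = np.nan
            keep_agent = np.ones(t_agent.size, dtype=bool)

        multi_agent = bool(rng.random() < spec.multi_agent_fraction)

        # --- emit rows ----------------------------------------------------
        t_map_r = np.round(t_map, 2)
        m_case.append(np.repeat(case_id, t_map_r.size))
        m_t.append(t_map_r)
        m_var.append(np.repeat("MAP", t_map_r.size))
        m_val.append(np.round(map_vals, 2))
        m_src.append(np.repeat("ARTERIAL" if arterial else "NONINVASIVE", t_map_r.size))

        m_case.append(np.repeat(case_id, t_bis.size))
        m_t.append(t_bis)
        m_var.append(np.repeat("BIS", t_bis.size))
        m_val.append(np.round(bis_vals, 2))
        m_src.append(np.repeat("NA", t_bis.size))

        ta = t_agent[keep_agent]
        mac_kept = mac_targets[keep_agent]
        if multi_agent:
            iso = np.round(0.6 * mac_kept * equivalents.isoflurane, 4)
            n2o = np.round(0.4 * mac_kept * equivalents.nitrous_oxide, 3)
            for var_name, conc in (("ISOFLURANE", iso), ("NITROUS_OXIDE", n2o)):
                m_case.append(np.repeat(case_id, ta.size))
                m_t.append(ta)
                m_var.append(np.repeat(var_name, ta.size))
                m_val.append(conc)
                m_src.append(np.repeat("NA", ta.size))
        else:
            sevo = np.round(mac_kept * equivalents.sevoflurane, 4)
            m_case.append(np.repeat(case_id, ta.size))
            m_t.append(ta)
            m_var.append(np.repeat("SEVOFLURANE", ta.size))
            m_val.append(sevo)
            m_src.append(np.repeat("NA", ta.size))

        # --- outcome ------------------------------------------------------
        latent_tvi = sum(
            (mu - per_var_std[v][0]) / per_var_std[v][1]
            for v, mu in (("map", map_mu), ("bis", bis_mu), ("mac", mac_mu))
        )
        latent_z = (latent_tvi - latent_mean) / latent_sd
        if spec.mortality_link == "logistic_tvi":
            from scipy.special import expit

            p30 = float(expit(spec.logistic_intercept + spec.logistic_slope * latent_z))
        else:
            p30 = regime.mortality_30d
        u = rng.random()
        if u < p30:
            days = int(rng.integers(1, 31))
        elif u < p30 + regime.mortality_31_365:
            days = int(rng.integers(31, 366))
        elif u < p30 + regime.mortality_31_365 + regime.mortality_366_730:
            days = int(rng.integers(366, 731))
        else:
            days = None

        specialty = "Cardiac" if cpb else str(
            rng.choice(_SPECIALTIES, p=_SPECIALTY_PROBS[regime.name])
        )
        procedure = str(rng.choice(_PROCEDURES, p=_PROCEDURE_PROBS))
        asa_p = np.array(regime.asa_probs) / sum(regime.asa_probs)
        case_rows.append(
            {
                "case_id": case_id,
                "patient_id": f"P{i + 1:05d}",
                "age_years": round(float(np.clip(rng.normal(regime.age_mean, regime.age_sd), 18.0, 95.0)), 1),
                "sex": "M" if rng.random() < regime.male_fraction else "F",
                "asa_status": int(rng.choice(5, p=asa_p)) + 1,
                "emergent": bool(rng.random() < regime.emergent_fraction),
                "specialty": specialty,
                "procedure": procedure,
                "cpb_used": cpb,
                "cpb_start_min": round(cpb_start, 2) if cpb else np.nan,
                "cpb_end_min": round(cpb_end, 2) if cpb else np.nan,
                "repeat_surgery": False,
                "days_to_death": days if days is not None else pd.NA,
                "follow_up_days": spec.follow_up_days,
            }
        )
        truth_rows.append(
            {
                "case_id": case_id,
                "regime": regime.name,
                "latent_tvi_z": round(latent_z, 6),
                "days_to_death": days if days is not None else pd.NA,
            }
        )

        regime_col = REGIME_NAMES.index(regime.name)
        for drug, (probs, median_dose) in _MEDICATIONS.items():
            if rng.random() < probs[regime_col]:
                dose = median_dose * math.exp(rng.normal(0.0, 0.4))
                med_rows.append({"case_id": case_id, "drug": drug, "total_dose": round(dose, 3)})

    cases = pd.DataFrame(case_rows)
    cases["days_to_death"] = cases["days_to_death"].astype("Int64")

    # repeat-surgery patients: reassign a fraction of later cases to the
    # patient of a uniformly drawn earlier case
    n_repeat = int(round(spec.n_cases * spec.repeat_patient_fraction))
    if n_repeat > 0 and spec.n_cases > 1:
        candidates = rng.choice(np.arange(1, spec.n_cases), size=min(n_repeat, spec.n_cases - 1), replace=False)
        for idx in np.sort(candidates):
            donor = int(rng.integers(0, idx))
            cases.loc[idx, "patient_id"] = cases.loc[donor, "patient_id"]
    seen: set[str] = set()
    repeat_flags = []
    for pid in cases["patient_id"]:
        repeat_flags.append(pid in seen)
        seen.add(pid)
    cases["repeat_surgery"] = repeat_flags

    measurements = pd.DataFrame(
        {
            "case_id": np.concatenate(m_case),
            "t_min": np.concatenate(m_t),
            "variable": np.concatenate(m_var),
            "value": np.concatenate(m_val),
            "source": np.concatenate(m_src),
        }
    ).sort_values(["case_id", "t_min", "variable"], kind="mergesort").reset_index(drop=True)

    medications = pd.DataFrame(med_rows, columns=["case_id", "drug", "total_dose"])
    truth = pd.DataFrame(truth_rows)
    truth["days_to_death"] = truth["days_to_death"].astype("Int64")
    return CohortData(measurements=measurements, cases=cases, medications=medications, truth=truth)


MICRO_CASE_ID = "micro-1"

# Hand-checkable micro case: 12 timepoints at t = 0, 5, ..., 55 minutes,
# MAP/BIS/sevoflurane all recorded at every timepoint, so windowing yields
# exactly three windows of 5, 5, and 2 timepoints, each with a TVI value.
_MICRO_MAP = (80.0, 90.0, 100.0, 70.0, 60.0, 85.0, 75.0, 95.0, 65.0, 105.0, 88.0, 72.0)
_MICRO_BIS = (40.0, 50.0, 45.0, 35.0, 55.0, 42.0, 48.0, 38.0, 52.0, 46.0, 44.0, 41.0)
_MICRO_MAC = (1.0, 1.2, 0.8, 1.4, 0.6, 0.9, 1.1, 0.7, 1.3, 1.0, 0.95, 1.05)


def generate_worked_micro_case() -> pd.DataFrame:
    """A tiny deterministic case whose TVI values can be checked by hand.

    Twelve timepoints, five minutes apart, with MAP, BIS, and sevoflurane
    (end-tidal % = target MAC × 1.8) all present at every timepoint —
    producing windows of 5, 5, and 2 timepoints. Population statistics
    fitted on this case alone give window TVI values reproducible by direct
    arithmetic on the value tuples above.
    """
    sevo_equiv = MacEquivalents().sevoflurane
    rows = []
    for k in range(12):
        t = 5.0 * k
        rows.append((MICRO_CASE_ID, t, "MAP", _MICRO_MAP[k], "NONINVASIVE"))
        rows.append((MICRO_CASE_ID, t, "BIS", _MICRO_BIS[k], "NA"))
        rows.append((MICRO_CASE_ID, t, "SEVOFLURANE", _MICRO_MAC[k] * sevo_equiv, "NA"))
    return pd.DataFrame(
        rows, columns=["case_id", "t_min", "variable", "value", "source"]
    )
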