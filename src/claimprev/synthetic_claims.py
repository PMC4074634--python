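"""Synthetic national claims extracts with known ground truth.

No accession accompanies the source data — a national insurance billing
extract cannot be redistributed — so every estimator is exercised against
simulated extracts whose statistical structure mirrors the real one: a
cohort of coded patients with stratified demographics, a visit-pattern
group per patient, a latent true-disease flag drawn with the stratum's
(or group's) positive predictive value, one or more billing rows per
patient-year, and chart-review criteria consistent with the latent truth.

Defaults reproduce the study conditions: 13 652 coded patients over
2004–2006, female fraction 0.894, age peak at 30–39, hospital mix
university 0.654 / general 0.179 / private 0.158 / local 0.009, and
visit-pattern group sizes abc 7842, bc 1672, ac 260, c 3878 (groups a, b
and ab get zero mass by default: their national sizes are not published).

Two cohort-composition modes exist: ``"fixed"`` sets group/stratum counts
exactly (needed when worked examples must reproduce to the digit) and
``"weights"`` draws them multinomially (needed for honest coverage
simulations).  Randomness comes from a single seed; each generation stage
derives an independent child stream, so stages are reproducible in
isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .case_definition import CRITERIA, SLE_CRITERION_THRESHOLD
from .claims_core import (
    CLAIMS_COLUMNS,
    DEPARTMENTS,
    HOSPITAL_TYPES,
    REGIONS,
    SERVICE_TYPES,
    StudyWindow,
)
from .visit_patterns import PATTERN_LABELS

logger = logging.getLogger("claimprev")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


_DEFAULT_REGION_WEIGHTS = {
    "Seoul": 0.434,
    "Kyounggi": 0.135,
    "Pusan": 0.106,
    "Daegu": 0.063,
    "Jeju": 0.011,
    "other": 0.251,
}
_DEFAULT_HOSPITAL_WEIGHTS = {
    "university_hospital": 0.654,
    "general_hospital": 0.179,
    "private_clinic": 0.158,
    "local_hospital": 0.009,
}
_DEFAULT_DEPARTMENT_WEIGHTS = {
    "rheumatology": 0.91,
    "dermatology": 0.03,
    "pediatrics": 0.03,
    "other": 0.03,
}
_DEFAULT_AGE_DECADE_WEIGHTS = (0.01, 0.04, 0.19, 0.30, 0.22, 0.13, 0.07, 0.03, 0.01)
_DEFAULT_PATTERN_COUNTS = {"abc": 7842, "bc": 1672, "ac": 260, "c": 3878,
                           "a": 0, "b": 0, "ab": 0}
_DEFAULT_GROUP_PPV = {"abc": 0.90, "bc": 0.76, "ac": 0.36, "c": 0.57,
                      "a": 0.0, "b": 0.0, "ab": 0.0}
_DEFAULT_HOSPITAL_PPV = {"private_clinic": 0.65, "general_hospital": 0.70,
                         "university_hospital": 0.76, "local_hospital": 0.70}

# Per-criterion marginal rates for chart-review flag generation.  True
# cases show the classic pattern (near-universal FANA, frequent arthritis
# and immunologic/hematologic involvement); miscoded patients get sparse
# flags dominated by an isolated positive FANA or arthritis — the profile
# that attracts a tentative code in the first place.
_DEFAULT_CRITERIA_RATES_SLE = {
    "malar_rash": 0.55, "discoid_rash": 0.15, "photosensitivity": 0.45,
    "oral_ulcer": 0.35, "arthritis": 0.80, "serositis": 0.30,
    "renal_disorder": 0.45, "hematologic_disorder": 0.55,
    "neurologic_disorder": 0.10, "immunologic_disorder": 0.70,
    "fana_positive": 0.98,
}
_DEFAULT_CRITERIA_RATES_NON_SLE = {
    "malar_rash": 0.08, "discoid_rash": 0.05, "photosensitivity": 0.10,
    "oral_ulcer": 0.10, "arthritis": 0.35, "serositis": 0.05,
    "renal_disorder": 0.08, "hematologic_disorder": 0.15,
    "neurologic_disorder": 0.03, "immunologic_disorder": 0.15,
    "fana_positive": 0.60,
}


def _check_weights(name: str, weights: Mapping[str, float], vocabulary) -> dict[str, float]:
    unknown = set(weights) - set(vocabulary)
    if unknown:
        raise ConfigError(f"{name}: unknown categories {sorted(unknown)}")
    values = {k: float(weights.get(k, 0.0)) for k in vocabulary}
    if any(v < 0 for v in values.values()):
        raise ConfigError(f"{name}: negative weight")
    total = sum(values.values())
    if total <= 0:
        raise ConfigError(f"{name}: weights sum to zero, cannot normalize")
    return {k: v / total for k, v in values.items()}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic national extract."""

    n_patients: int = 13652
    window: StudyWindow = field(default_factory=StudyWindow)
    female_fraction: float = 0.894
    age_decade_weights: tuple = _DEFAULT_AGE_DECADE_WEIGHTS
    region_weights: dict = field(default_factory=lambda: dict(_DEFAULT_REGION_WEIGHTS))
    hospital_type_weights: dict = field(default_factory=lambda: dict(_DEFAULT_HOSPITAL_WEIGHTS))
    department_weights: dict = field(default_factory=lambda: dict(_DEFAULT_DEPARTMENT_WEIGHTS))
    admission_fraction: float = 0.08
    #: "fixed": pattern-group sizes set exactly to `pattern_counts`;
    #: "weights": drawn multinomially with probabilities ∝ `pattern_counts`.
    count_mode: str = "fixed"
    pattern_counts: dict = field(default_factory=lambda: dict(_DEFAULT_PATTERN_COUNTS))
    #: "group": PPV per visit-pattern group; "hospital": PPV per hospital
    #: type; "homogeneous": a single PPV.  The two published PPV maps come
    #: from different sub-studies with unknown joint distribution, so they
    #: are mutually exclusive modes, never combined.
    ppv_mode: str = "group"
    group_ppv: dict = field(default_factory=lambda: dict(_DEFAULT_GROUP_PPV))
    hospital_ppv: dict = field(default_factory=lambda: dict(_DEFAULT_HOSPITAL_PPV))
    homogeneous_ppv: float = 0.67
    #: probability of one extra duplicate billing row per patient-year
    #: (exercises deduplication; zero claims are never emitted).
    duplicate_claim_rate: float = 0.10
    criteria_rates_sle: dict = field(default_factory=lambda: dict(_DEFAULT_CRITERIA_RATES_SLE))
    criteria_rates_non_sle: dict = field(default_factory=lambda: dict(_DEFAULT_CRITERIA_RATES_NON_SLE))
    #: bounded rejection budget for enforcing the 4-of-11 constraint.
    max_resample: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError(f"n_patients must be >= 1, got {self.n_patients}")
        if not isinstance(self.window, StudyWindow):
            self.window = StudyWindow(*self.window)
        if self.count_mode not in ("fixed", "weights"):
            raise ConfigError(f"count_mode must be 'fixed' or 'weights', got {self.count_mode!r}")
        if self.ppv_mode not in ("group", "hospital", "homogeneous"):
            raise ConfigError(f"unknown ppv_mode {self.ppv_mode!r}")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigError("female_fraction outside [0, 1]")
        self.region_weights = _check_weights("region_weights", self.region_weights, REGIONS)
        self.hospital_type_weights = _check_weights(
            "hospital_type_weights", self.hospital_type_weights, HOSPITAL_TYPES)
        self.department_weights = _check_weights(
            "department_weights", self.department_weights, DEPARTMENTS)
        if len(self.age_decade_weights) != 9 or any(w < 0 for w in self.age_decade_weights):
            raise ConfigError("age_decade_weights must be 9 non-negative weights")
        total = sum(self.age_decade_weights)
        if total <= 0:
            raise ConfigError("age_decade_weights sum to zero")
        self.age_decade_weights = tuple(w / total for w in self.age_decade_weights)
        unknown = set(self.pattern_counts) - set(PATTERN_LABELS)
        if unknown:
            raise ConfigError(f"pattern_counts: unknown labels {sorted(unknown)}")
        self.pattern_counts = {k: int(self.pattern_counts.get(k, 0)) for k in PATTERN_LABELS}
        if self.count_mode == "fixed" and sum(self.pattern_counts.values()) != self.n_patients:
            raise ConfigError(
                f"fixed pattern counts sum to {sum(self.pattern_counts.values())}, "
                f"but n_patients={self.n_patients}"
            )
        for name, ppv_map in (("group_ppv", self.group_ppv), ("hospital_ppv", self.hospital_ppv)):
            for key, p in ppv_map.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"{name}[{key!r}] outside [0, 1]: {p}")
        if not 0.0 <= self.homogeneous_ppv <= 1.0:
            raise ConfigError("homogeneous_ppv outside [0, 1]")

    # -- (de)serialisation --------------------------------------------------

    def to_json(self) -> str:
        payload = asdict(self)
        payload["window"] = list(self.window.years)
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        payload = json.loads(text)
        if "window" in payload:
            payload["window"] = StudyWindow(*payload["window"])
        if "age_decade_weights" in payload:
            payload["age_decade_weights"] = tuple(payload["age_decade_weights"])
        try:
            return cls(**payload)
        except TypeError as exc:
            raise ConfigError(f"invalid simulation config: {exc}") from exc


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent child generators derived from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _draw_patterns(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    labels = np.array(PATTERN_LABELS, dtype=object)
    counts = np.array([config.pattern_counts[l] for l in PATTERN_LABELS], dtype=np.int64)
    if config.count_mode == "fixed":
        patterns = np.repeat(labels, counts)
        rng.shuffle(patterns)
        return patterns
    probs = counts / counts.sum()
    return rng.choice(labels, size=config.n_patients, p=probs)


def generate_claims(
    config: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a synthetic claims extract and its ground-truth table.

    Returns ``(claims, truth)``: a canonical claims frame with one or more
    rows per patient-year billed, and a truth frame with columns
    ``patient_id`` and ``true_sle`` (0/1).  The latent disease flag is
    Bernoulli with the probability the configured PPV map assigns to the
    patient's visit-pattern group / hospital type (or the homogeneous
    value).  Deterministic given the seed (``config.seed`` unless
    overridden).
    """
    seed = config.seed if seed is None else seed
    rng_pattern, rng_strata, rng_truth, rng_claims = _substreams(seed, 4)
    n = config.n_patients

    patterns = _draw_patterns(config, rng_pattern)
    patient_id = np.array([f"P{i:07d}" for i in range(1, n + 1)], dtype=object)

    region = rng_strata.choice(
        np.array(REGIONS, dtype=object), size=n,
        p=[config.region_weights[r] for r in REGIONS])
    hospital = rng_strata.choice(
        np.array(HOSPITAL_TYPES, dtype=object), size=n,
        p=[config.hospital_type_weights[h] for h in HOSPITAL_TYPES])
    department = rng_strata.choice(
        np.array(DEPARTMENTS, dtype=object), size=n,
        p=[config.department_weights[d] for d in DEPARTMENTS])
    sex = np.where(rng_strata.random(n) < config.female_fraction, "female", "male").astype(object)
    decade = rng_strata.choice(9, size=n, p=config.age_decade_weights)
    age = decade * 10 + rng_strata.integers(0, 10, size=n)

    if config.ppv_mode == "group":
        p_true = np.array([config.group_ppv.get(l, 0.0) for l in patterns])
    elif config.ppv_mode == "hospital":
        p_true = np.array([config.hospital_ppv[h] for h in hospital])
    else:
        p_true = np.full(n, config.homogeneous_ppv)
    true_sle = (rng_truth.random(n) < p_true).astype(np.int8)
    truth = pd.DataFrame({"patient_id": patient_id, "true_sle": true_sle})

    # One row per billed patient-year, plus occasional duplicate billings.
    letter_index = {"a": 0, "b": 1, "c": 2}
    year_lists = {
        label: [config.window.years[letter_index[ch]] for ch in label]
        for label in PATTERN_LABELS
    }
    n_years = np.array([len(label) for label in patterns], dtype=np.int64)
    patient_rows = np.repeat(np.arange(n), n_years)
    years = np.concatenate([year_lists[label] for label in patterns]).astype(np.int64)
    if config.duplicate_claim_rate > 0:
        dup = rng_claims.random(len(patient_rows)) < config.duplicate_claim_rate
        patient_rows = np.concatenate([patient_rows, patient_rows[dup]])
        years = np.concatenate([years, years[dup]])
        order = np.lexsort((years, patient_rows))
        patient_rows, years = patient_rows[order], years[order]
    service = np.where(
        rng_claims.random(len(patient_rows)) < config.admission_fraction,
        "admission", "outpatient").astype(object)

    claims = pd.DataFrame(
        {
            "patient_id": patient_id[patient_rows],
            "billing_year": years,
            "region": region[patient_rows],
            "hospital_type": hospital[patient_rows],
            "department": department[patient_rows],
            "service_type": service,
            "age_years": age[patient_rows],
            "sex": sex[patient_rows],
        },
        columns=list(CLAIMS_COLUMNS),
    )
    logger.info(
        "generate_claims: %d patients, %d claim rows, %d true cases (seed %d)",
        n, len(claims), int(true_sle.sum()), seed,
    )
    return claims, truth


def _constrained_flags(
    n: int,
    rates: np.ndarray,
    want_case: bool,
    rng: np.random.Generator,
    max_resample: int,
) -> np.ndarray:
    """Bernoulli criterion flags conditioned on the 4-of-11 classification.

    Rows violating the constraint (count < 4 for cases, count >= 4 for
    non-cases) are redrawn; generation aborts if any row survives the
    resampling budget, which indicates infeasible marginal rates.
    """
    flags = np.empty((n, len(rates)), dtype=np.int8)
    pending = np.arange(n)
    for _ in range(max_resample):
        if pending.size == 0:
            break
        draw = (rng.random((pending.size, len(rates))) < rates).astype(np.int8)
        counts = draw.sum(axis=1)
        ok = counts >= SLE_CRITERION_THRESHOLD if want_case else counts < SLE_CRITERION_THRESHOLD
        flags[pending[ok]] = draw[ok]
        pending = pending[~ok]
    if pending.size:
        raise ConfigError(
            f"criterion rates infeasible: {pending.size} record(s) failed the "
            f"{'>=' if want_case else '<'}{SLE_CRITERION_THRESHOLD}-criteria "
            f"constraint after {max_resample} resampling rounds"
        )
    return flags


def generate_verification(
    sample: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate chart review for a verification sample.

    Every sampled patient gets eleven 0/1 criterion flags drawn from the
    per-status marginal rates, conditioned so that classification exactly
    reproduces the latent truth (≥4 criteria for true cases, ≤3 for
    non-cases).  Returns a verification frame: ``patient_id`` + the
    criterion columns.
    """
    seed = config.seed if seed is None else seed
    (rng,) = _substreams(seed, 5)[4:]
    truth_map = truth.set_index("patient_id")["true_sle"]
    ids = sample["patient_id"] if "patient_id" in sample.columns else pd.Series(sample)
    status = truth_map.reindex(ids)
    if status.isna().any():
        missing = ids[status.isna().to_numpy()].iloc[0]
        raise ValueError(f"sampled patient {missing!r} absent from truth table")
    status = status.to_numpy(dtype=bool)

    flags = np.empty((len(ids), len(CRITERIA)), dtype=np.int8)
    sle_rates = np.array([config.criteria_rates_sle[c] for c in CRITERIA])
    non_rates = np.array([config.criteria_rates_non_sle[c] for c in CRITERIA])
    if status.any():
        flags[status] = _constrained_flags(
            int(status.sum()), sle_rates, True, rng, config.max_resample)
    if (~status).any():
        flags[~status] = _constrained_flags(
            int((~status).sum()), non_rates, False, rng, config.max_resample)

    out = pd.DataFrame(flags, columns=list(CRITERIA))
    out.insert(0, "patient_id", ids.to_numpy())
    return out


def true_case_count(truth: pd.DataFrame) -> int:
    """Number of patients whose latent disease flag is true."""
    if len(truth) == 0:
        return 0
    return int(truth["true_sle"].sum())


def expected_case_count(config: SimulationConfig) -> float:
    """Design expectation of the true-case count under the configuration.

    In fixed-count group-PPV mode this is exactly Σ_g count_g × ppv_g; in
    weight mode or other PPV modes it is the corresponding mixture mean.
    """
    if config.ppv_mode == "group":
        counts = config.pattern_counts
        if config.count_mode == "weights":
            total = sum(counts.values())
            return config.n_patients * sum(
                counts[g] / total * config.group_ppv.get(g, 0.0) for g in PATTERN_LABELS)
        return float(sum(counts[g] * config.group_ppv.get(g, 0.0) for g in PATTERN_LABELS))
    if config.ppv_mode == "hospital":
        return config.n_patients * sum(
            config.hospital_type_weights[h] * config.hospital_ppv[h] for h in HOSPITAL_TYPES)
    return config.n_patients * config.homogeneous_ppv


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write the ground-truth table (synthetic, test-only artifact)."""
    truth.to_csv(path, index=False, lineterminator="\n")


def read_truth(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"patient_id": str, "true_sle": np.int8})
    return frame[["patient_id", "true_sle"]]
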