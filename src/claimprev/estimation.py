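"""PPV estimation, prevalence estimators, and stratified verification sampling.

The prevalence machinery is misclassification adjustment by positive
predictive value: the coded case count N is deflated by the fraction p of
coded patients confirmed on chart review,

    cases = N · p,      p ± z·sqrt(p(1−p)/n)  (Wald 95% interval, z = 1.96),

where n is the verification sample size.  Three ascertainment routes share
this core:

* ``random_sampling`` — p estimated on a stratified random verification
  sample of coded patients;
* ``all_registered``  — p estimated on a census of registered coded
  patients;
* ``subgroup``        — per-visit-pattern-group PPVs from a reference
  institution applied to the national group counts,
  cases = Σ_g count_g · ppv_g (no interval: the group PPVs carry no
  reported variance).

Interval bounds are reported at 4 decimal places.  ``ci_digits_mode``
controls whether scaling to case counts uses the full-precision bounds
(``"round"``, the default) or bounds truncated to 4 decimals
(``"truncate"``); case counts round half away from zero.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from . import case_definition
from .claims_core import DataError
from .visit_patterns import DEFAULT_ESTIMATOR_GROUPS, PatternTable

logger = logging.getLogger("claimprev")

DEFAULT_Z = 1.96
CI_DIGITS = 4

METHOD_LABELS = ("random_sampling", "all_registered", "subgroup")


def _round_half_away(x: float) -> int:
    """Round half away from zero (the reporting convention for case counts)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def truncate(x: float, digits: int = CI_DIGITS) -> float:
    """Truncate (not round) toward zero at the given number of decimals."""
    scale = 10.0 ** digits
    return math.trunc(x * scale) / scale


# ---------------------------------------------------------------------------
# Wald interval and PPV estimation
# ---------------------------------------------------------------------------


def wald_ci(p: float, n: int, z: float = DEFAULT_Z) -> tuple[float, float]:
    """Normal-approximation (Wald) confidence interval for a proportion.

    Returns ``(max(0, p − z·se), min(1, p + z·se))`` with
    ``se = sqrt(p(1−p)/n)``.  z is fixed at 1.96 by default rather than
    recomputed from a normal quantile.
    """
    if n < 1:
        raise ValueError(f"n must be a positive integer, got {n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion p outside [0, 1]: {p}")
    half_width = z * math.sqrt(p * (1.0 - p) / n)
    return (max(0.0, p - half_width), min(1.0, p + half_width))


def exact_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Clopper–Pearson exact interval (optional alternative to Wald)."""
    return tuple(float(b) for b in proportion_confint(k, n, alpha=alpha, method="beta"))


@dataclass(frozen=True)
class PPVEstimate:
    """Positive predictive value of the diagnostic code, with Wald 95% CI."""

    verified_true: int
    n: int
    p: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not 0 <= self.verified_true <= self.n:
            raise ValueError(f"verified_true {self.verified_true} outside [0, n={self.n}]")
        if not self.ci_low <= self.p <= self.ci_high:
            raise ValueError("CI does not bracket the point estimate")

    @classmethod
    def from_counts(cls, verified_true: int, n: int, z: float = DEFAULT_Z) -> "PPVEstimate":
        p = verified_true / n
        low, high = wald_ci(p, n, z)
        return cls(verified_true=verified_true, n=n, p=p, ci_low=low, ci_high=high)

    @classmethod
    def from_proportion(cls, p: float, n: int, z: float = DEFAULT_Z) -> "PPVEstimate":
        """Build an estimate from a reported proportion (e.g. a published
        4-decimal PPV) when the underlying integer count is not available."""
        low, high = wald_ci(p, n, z)
        return cls(verified_true=_round_half_away(p * n), n=n, p=p, ci_low=low, ci_high=high)


def estimate_ppv(verified, z: float = DEFAULT_Z) -> PPVEstimate:
    """PPV from chart-review records: confirmed count / sample size.

    ``verified`` is a verification frame (criterion columns) or an
    iterable of :class:`~claimprev.case_definition.CriteriaRecord`.
    """
    if isinstance(verified, pd.DataFrame):
        n = len(verified)
        if n == 0:
            raise DataError("estimate_ppv: empty verification sample")
        confirmed = int(case_definition.classify_sle_frame(verified).sum())
    else:
        records = list(verified)
        n = len(records)
        if n == 0:
            raise DataError("estimate_ppv: empty verification sample")
        confirmed = sum(case_definition.classify_sle(r) for r in records)
    return PPVEstimate.from_counts(confirmed, n, z)


# ---------------------------------------------------------------------------
# Prevalence estimators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrevalenceEstimate:
    """An estimated national (or regional) case count, optionally as a rate."""

    method: str
    cases: int
    cases_ci: tuple[int, int] | None = None
    population: int | None = None
    per_100k: float | None = None
    per_100k_ci: tuple[float, float] | None = None
    ci_digits_mode: str = "round"

    def __post_init__(self) -> None:
        if self.cases_ci is not None and not self.cases_ci[0] <= self.cases <= self.cases_ci[1]:
            raise ValueError(f"cases CI {self.cases_ci} does not bracket cases={self.cases}")


def scale_estimate(
    total_m32: int,
    ppv: PPVEstimate,
    method: str = "random_sampling",
    ci_digits_mode: str = "round",
) -> PrevalenceEstimate:
    """Deflate the coded patient count by the PPV: cases = total × p.

    The CI on cases scales the PPV interval bounds.  With
    ``ci_digits_mode="truncate"`` the bounds are first truncated to 4
    decimals (the arithmetic that reproduces published tables computed
    from 4-decimal truncated bounds); the default ``"round"`` scales the
    full-precision bounds.
    """
    if total_m32 < 1:
        raise ValueError(f"total_m32 must be >= 1, got {total_m32}")
    if ci_digits_mode not in ("round", "truncate"):
        raise ValueError(f"ci_digits_mode must be 'round' or 'truncate', got {ci_digits_mode!r}")
    low, high = ppv.ci_low, ppv.ci_high
    if ci_digits_mode == "truncate":
        low, high = truncate(low), truncate(high)
    return PrevalenceEstimate(
        method=method,
        cases=_round_half_away(total_m32 * ppv.p),
        cases_ci=(_round_half_away(total_m32 * low), _round_half_away(total_m32 * high)),
        ci_digits_mode=ci_digits_mode,
    )


def subgroup_estimate(
    table: PatternTable,
    included_groups: Sequence[str] = DEFAULT_ESTIMATOR_GROUPS,
) -> PrevalenceEstimate:
    """Visit-pattern subgroup estimator: cases = Σ_g count_g × ppv_g.

    Only the included groups (default abc, bc, ac, c) contribute; each
    must carry a PPV.  No interval is produced — the per-group PPVs carry
    no reported variance.
    """
    missing = [g for g in included_groups if g not in table.ppv]
    if missing:
        raise ValueError(f"no PPV supplied for included group(s): {missing}")
    total = sum(table.counts[g] * table.ppv[g] for g in included_groups)
    return PrevalenceEstimate(method="subgroup", cases=_round_half_away(total), cases_ci=None)


def per_100k(cases: int, population: int) -> float:
    """Convert a case count to a rate per 100 000 people."""
    if population < 1:
        raise ValueError(f"population must be >= 1, got {population}")
    return cases / population * 1e5


def attach_population(estimate: PrevalenceEstimate, population: int) -> PrevalenceEstimate:
    """Add per-100k fields to an estimate given a population denominator."""
    rate_ci = (
        (per_100k(estimate.cases_ci[0], population), per_100k(estimate.cases_ci[1], population))
        if estimate.cases_ci is not None
        else None
    )
    return replace(
        estimate,
        population=population,
        per_100k=per_100k(estimate.cases, population),
        per_100k_ci=rate_ci,
    )


def population_range_for_rate(cases: int, rate: float, digits: int = 1) -> tuple[float, float]:
    """Populations under which ``cases`` yields a per-100k rate that rounds
    to ``rate`` at the given precision (open-low, closed-high interval).

    Back-solving tool for published rates whose denominator is not stated.
    """
    half = 0.5 * 10.0 ** (-digits)
    return (cases * 1e5 / (rate + half), cases * 1e5 / (rate - half))


def regional_prevalence(
    local_m32: int,
    local_ppv: PPVEstimate,
    local_population: int,
    ci_digits_mode: str = "round",
) -> PrevalenceEstimate:
    """Regional validation: scale the local coded count by the local PPV
    and express it per 100 000 of the local population."""
    if local_m32 == 0:
        estimate = PrevalenceEstimate(method="regional", cases=0, cases_ci=(0, 0))
    else:
        estimate = scale_estimate(local_m32, local_ppv, method="regional", ci_digits_mode=ci_digits_mode)
    return attach_population(estimate, local_population)


# ---------------------------------------------------------------------------
# Stratified verification sampling
# ---------------------------------------------------------------------------

#: Stratification variables for verification sampling.
SAMPLING_STRATA = ("region", "hospital_type")


@dataclass
class SamplingPlan:
    """Per-stratum verification targets (strata = region × hospital type)."""

    targets: dict[tuple[str, str], int]
    total: int
    fraction: float
    warnings: list[str]

    def __post_init__(self) -> None:
        if sum(self.targets.values()) != self.total:
            raise ValueError("per-stratum targets must sum to the plan total")


def _largest_remainder(sizes: np.ndarray, total: int) -> np.ndarray:
    """Proportional integer allocation by the largest-remainder rule.

    Quotas ``sizes * total / sizes.sum()`` are floored; the leftover units
    go to the largest fractional remainders (ties to the earlier stratum).
    Allocations are capped at stratum sizes, any displaced units moving to
    the next-largest remainders with spare capacity.
    """
    quotas = sizes * (total / sizes.sum())
    alloc = np.floor(quotas).astype(np.int64)
    remainder_order = np.lexsort((np.arange(len(sizes)), -(quotas - alloc)))
    leftover = total - int(alloc.sum())
    for i in remainder_order:
        if leftover == 0:
            break
        if alloc[i] < sizes[i]:
            alloc[i] += 1
            leftover -= 1
    # Cap overshoot (possible only via flooring artefacts on tiny strata).
    over = alloc > sizes
    if over.any():
        spill = int((alloc[over] - sizes[over]).sum())
        alloc[over] = sizes[over]
        for i in remainder_order:
            if spill == 0:
                break
            room = int(sizes[i] - alloc[i])
            if room > 0:
                take = min(room, spill)
                alloc[i] += take
                spill -= take
    return alloc


def make_sampling_plan(
    patients: pd.DataFrame,
    fraction: float = 0.15,
    total_override: int | None = None,
) -> SamplingPlan:
    """Allocate verification targets across region × hospital-type strata.

    Targets are proportional to stratum sizes with largest-remainder
    rounding.  ``fraction`` (default 15% of coded patients) sets the total
    unless ``total_override`` pins it exactly (e.g. a review budget of
    2000 charts).  Targets never exceed stratum sizes; capping emits a
    warning and redistributes.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"sampling fraction must be in (0, 1], got {fraction}")
    if len(patients) == 0:
        raise DataError("make_sampling_plan: empty cohort")
    sizes = patients.groupby(list(SAMPLING_STRATA), sort=True).size()
    total = total_override if total_override is not None else _round_half_away(fraction * len(patients))
    if total > len(patients):
        raise ValueError(f"requested total {total} exceeds cohort size {len(patients)}")

    size_array = sizes.to_numpy(dtype=np.int64)
    alloc = _largest_remainder(size_array, total)
    plan_warnings: list[str] = []
    naive = size_array * (total / size_array.sum())
    capped = np.ceil(naive).astype(np.int64) > size_array
    for stratum, flag in zip(sizes.index, capped):
        if flag:
            plan_warnings.append(f"stratum {stratum} target capped at its size")
    for message in plan_warnings:
        warnings.warn(message, stacklevel=2)
    targets = {stratum: int(a) for stratum, a in zip(sizes.index, alloc)}
    logger.info(
        "make_sampling_plan: total %d over %d strata (fraction %.3f)",
        total, len(targets), fraction,
    )
    return SamplingPlan(targets=targets, total=total, fraction=fraction, warnings=plan_warnings)


def draw_sample(
    patients: pd.DataFrame,
    plan: SamplingPlan,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Draw the stratified verification sample.

    Within each stratum the draw is uniform without replacement;
    reproducible given the seed (strata are visited in sorted order).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    groups = patients.groupby(list(SAMPLING_STRATA), sort=True).indices
    chosen: list[np.ndarray] = []
    for stratum in sorted(plan.targets):
        target = plan.targets[stratum]
        if target == 0:
            continue
        idx = groups.get(stratum)
        if idx is None or target > len(idx):
            raise ValueError(f"plan target {target} infeasible for stratum {stratum}")
        chosen.append(rng.choice(idx, size=target, replace=False))
    if not chosen:
        return patients.iloc[:0].copy()
    picked = np.sort(np.concatenate(chosen))
    return patients.iloc[picked].reset_index(drop=True)
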