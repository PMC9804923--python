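"""Developmental acclimation response ratios (dARR) from group summaries.

The effect size is the slope of heat tolerance against developmental
temperature between two acclimation groups:

    dARR = (HT2 - HT1) / (T2 - T1),  with T2 > T1 (deg C per deg C).

Its sampling variance depends on the reporting and design of the two
groups:

* independent groups with sd and n:
      v = (T2 - T1)^-2 * (sd1^2/n1 + sd2^2/n2)
* independent groups with se only:
      v = (T2 - T1)^-2 * (se1^2 + se2^2)
* same animals measured at both temperatures (shared cohort), with a
  conservative between-measure correlation r (default 0.5):
      v = (T2 - T1)^-2 * (sd1^2 + sd2^2 - 2 r sd1 sd2) / (n1 + n2)
      v = (T2 - T1)^-2 * (se1^2 + se2^2 - 2 r se1 se2)

Designs with more than two acclimation temperatures are expanded into
stepwise comparisons of adjacent temperatures (20-22, 22-25, 25-27 ...),
which makes interior groups appear in two effect sizes; those effects are
stamped with shared-group identifiers so that a sampling
variance-covariance matrix can later encode the dependence.

Missing standard deviations are imputed from the dataset-wide (per
metric) mean of the sd-to-mean ratio, assuming that coefficient of
variation is constant across studies.  Static thermal-death-time assays
are converted to a heat-tolerance temperature by regressing log10 time to
knockdown on test temperature and solving for the temperature tolerated
for one hour.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Metric", "Timing", "Habitat", "SourceType",
    "GroupStat", "EffectSize", "TDTSeries", "ImputationSummary",
    "DegenerateComparisonError", "MismatchError", "UnusableRowError",
    "ImputationError", "ImplausibleTDTError",
    "compute_darr", "darr_variance_independent",
    "darr_variance_shared_cohort", "stepwise_effects", "build_effects",
    "impute_missing_sd", "tdt_to_heat_tolerance",
    "temperature_shift_for_unit_gain",
]

#: Temperatures closer than this (deg C) are treated as identical; they
#: usually arise from digitization round-off and cannot support a slope.
MIN_TEMPERATURE_DIFFERENCE = 0.1

#: Conservative correlation between repeated measures on the same cohort.
DEFAULT_COHORT_R = 0.5


class Metric(str, enum.Enum):
    ctmax = "ctmax"
    lt50 = "lt50"
    tdt_derived = "tdt_derived"


class Timing(str, enum.Enum):
    initial = "initial"
    persistent = "persistent"


class Habitat(str, enum.Enum):
    aquatic = "aquatic"
    terrestrial = "terrestrial"


class SourceType(str, enum.Enum):
    article = "article"
    thesis = "thesis"


class DegenerateComparisonError(ValueError):
    """Two groups at (effectively) the same developmental temperature."""


class MismatchError(ValueError):
    """Groups from different studies/species/metrics were paired."""


class UnusableRowError(ValueError):
    """No route to a sampling variance (no sd+n and no se)."""


class ImputationError(ValueError):
    """No complete rows from which to pool a coefficient of variation."""


class ImplausibleTDTError(ValueError):
    """Thermal-death-time slope is non-negative (time should fall with T)."""


@dataclass
class GroupStat:
    """Summary statistics for one acclimation-temperature group."""

    study_id: str
    species: str
    temperature: float
    mean_ht: float
    sd: float | None = None
    se: float | None = None
    n: int | None = None
    metric: str = Metric.ctmax.value
    design: str = "A"
    timing: str = Timing.initial.value
    habitat: str = Habitat.aquatic.value
    taxon_group: str = ""
    population_id: str | None = None
    cohort_id: str | None = None
    heating_rate: float | None = None
    year: int | None = None
    source_type: str = SourceType.article.value
    sd_imputed: bool = False
    row_id: str | None = None
    risk_of_bias: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.temperature):
            raise ValueError("temperature must be finite")
        if not math.isfinite(self.mean_ht):
            raise ValueError("mean_ht must be finite")
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.se is not None and self.se < 0:
            raise ValueError("se must be >= 0")
        if self.n is not None and self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def has_sd_n(self) -> bool:
        return self.sd is not None and self.n is not None

    @property
    def has_se(self) -> bool:
        return self.se is not None

    @property
    def usable(self) -> bool:
        """A sampling variance can be derived for comparisons using this row."""
        return self.has_sd_n or self.has_se


@dataclass
class EffectSize:
    """One dARR with its sampling variance and dependence bookkeeping."""

    darr: float
    variance: float
    t1: float
    t2: float
    study_id: str
    species: str
    metric: str
    design: str
    timing: str
    habitat: str
    taxon_group: str = ""
    population_id: str | None = None
    cohort_pairing: bool = False
    shared_group_ids: tuple[str, ...] = ()
    variance_basis: str = "sd"
    heating_rate: float | None = None
    year: int | None = None
    source_type: str = SourceType.article.value
    sd_imputed: bool = False
    risk_of_bias: bool = False
    effect_id: str | None = None

    def __post_init__(self) -> None:
        if not (self.t2 > self.t1):
            raise ValueError("t2 must exceed t1")
        if not math.isfinite(self.darr):
            raise ValueError("darr must be finite")
        if not (self.variance > 0):
            raise ValueError("variance must be > 0")

    @property
    def se(self) -> float:
        return math.sqrt(self.variance)


@dataclass
class TDTSeries:
    """Static-assay knockdown times at several test temperatures."""

    points: Sequence[tuple[float, float]]  # (test temperature degC, hours)
    study_id: str = ""
    species: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise ValueError("need >= 3 knockdown measurements")
        temps = [t for t, _ in self.points]
        times = [h for _, h in self.points]
        if any(h <= 0 for h in times):
            raise ValueError("knockdown times must be > 0")
        if len(set(temps)) < 2:
            raise ValueError("need >= 2 distinct test temperatures")


@dataclass
class ImputationSummary:
    """Outcome of within-dataset sd imputation for one metric pool."""

    pooled_cv: float
    k_complete: int
    imputed_row_ids: list[str]
    excluded_row_ids: list[str] = field(default_factory=list)


def _check_pair(g1: GroupStat, g2: GroupStat) -> None:
    if (g1.study_id, g1.species, g1.metric) != (g2.study_id, g2.species, g2.metric):
        raise MismatchError(
            f"cannot pair {g1.study_id}/{g1.species}/{g1.metric} with "
            f"{g2.study_id}/{g2.species}/{g2.metric}"
        )
    if abs(g1.temperature - g2.temperature) < MIN_TEMPERATURE_DIFFERENCE:
        raise DegenerateComparisonError(
            f"temperatures {g1.temperature} and {g2.temperature} differ by "
            f"< {MIN_TEMPERATURE_DIFFERENCE} degC"
        )


def _order(g1: GroupStat, g2: GroupStat) -> tuple[GroupStat, GroupStat]:
    """Return (cooler, warmer) so that T2 > T1."""
    return (g1, g2) if g1.temperature < g2.temperature else (g2, g1)


def compute_darr(g1: GroupStat, g2: GroupStat) -> float:
    """dARR point value: (HT2 - HT1)/(T2 - T1), invariant to input order."""
    _check_pair(g1, g2)
    lo, hi = _order(g1, g2)
    return (hi.mean_ht - lo.mean_ht) / (hi.temperature - lo.temperature)


def darr_variance_independent(g1: GroupStat, g2: GroupStat) -> tuple[float, str]:
    """Sampling variance of dARR for independent groups.

    Uses the sd/n form when both groups report sd and n, the se form when
    both report se.  Mixed availability converts sd, n to se = sd/sqrt(n)
    so the pair is kept.  Returns (variance, basis) where basis is one of
    ``sd``, ``se`` or ``imputed_sd``.
    """
    _check_pair(g1, g2)
    lo, hi = _order(g1, g2)
    dt2 = (hi.temperature - lo.temperature) ** 2
    if lo.has_sd_n and hi.has_sd_n:
        v = (lo.sd**2 / lo.n + hi.sd**2 / hi.n) / dt2
        basis = "imputed_sd" if (lo.sd_imputed or hi.sd_imputed) else "sd"
        return v, basis
    if lo.has_se and hi.has_se:
        return (lo.se**2 + hi.se**2) / dt2, "se"
    # mixed: convert whichever group has sd,n to an se
    ses = []
    for g in (lo, hi):
        if g.has_se:
            ses.append(g.se)
        elif g.has_sd_n:
            ses.append(g.sd / math.sqrt(g.n))
        else:
            raise UnusableRowError(
                f"group {g.row_id or g.study_id} has neither sd+n nor se"
            )
    return (ses[0] ** 2 + ses[1] ** 2) / dt2, "se"


def darr_variance_shared_cohort(
    g1: GroupStat, g2: GroupStat, r: float = DEFAULT_COHORT_R
) -> tuple[float, str]:
    """Sampling variance when the same animals were measured at T1 and T2.

    The repeated-measures correlation r (default 0.5, a conservative
    choice) reduces the variance of the paired difference.
    """
    if not (0 <= r < 1):
        raise ValueError(f"cohort correlation r must be in [0, 1), got {r}")
    _check_pair(g1, g2)
    lo, hi = _order(g1, g2)
    dt2 = (hi.temperature - lo.temperature) ** 2
    if lo.has_sd_n and hi.has_sd_n:
        num = lo.sd**2 + hi.sd**2 - 2 * r * lo.sd * hi.sd
        v = num / (lo.n + hi.n) / dt2
        basis = "imputed_sd" if (lo.sd_imputed or hi.sd_imputed) else "sd"
        return v, basis
    if lo.has_se and hi.has_se:
        return (lo.se**2 + hi.se**2 - 2 * r * lo.se * hi.se) / dt2, "se"
    raise UnusableRowError(
        "shared-cohort variance needs sd+n on both groups or se on both"
    )


def _group_key(g: GroupStat) -> str:
    return f"{g.study_id}|{g.species}|{g.metric}|{g.timing}|{g.temperature:g}"


def stepwise_effects(
    groups: Sequence[GroupStat], r_cohort: float = DEFAULT_COHORT_R
) -> list[EffectSize]:
    """Expand one study/species/metric/timing series into adjacent-pair dARRs.

    Temperatures are sorted ascending and one effect size is produced per
    adjacent pair, so a series with m distinct temperatures yields m - 1
    effects.  Interior groups feed two comparisons; each such group stamps
    a shared-group identifier on both effects it joins, which later drives
    the off-diagonal structure of the sampling VCV.  Pairs whose two
    groups share a cohort_id use the repeated-measures variance.
    """
    groups = sorted(groups, key=lambda g: g.temperature)
    keys = {(g.study_id, g.species, g.metric, g.timing) for g in groups}
    if len(keys) > 1:
        raise MismatchError(f"stepwise expansion mixes series: {sorted(keys)}")
    distinct = []
    for g in groups:
        if distinct and abs(g.temperature - distinct[-1].temperature) < MIN_TEMPERATURE_DIFFERENCE:
            raise DegenerateComparisonError(
                f"temperatures {distinct[-1].temperature} and {g.temperature} "
                "are indistinguishable"
            )
        distinct.append(g)
    if len(distinct) < 2:
        raise DegenerateComparisonError("need >= 2 distinct temperatures")

    effects: list[EffectSize] = []
    n_pairs = len(distinct) - 1
    for i in range(n_pairs):
        lo, hi = distinct[i], distinct[i + 1]
        paired = (
            lo.cohort_id is not None
            and hi.cohort_id is not None
            and lo.cohort_id == hi.cohort_id
        )
        darr = compute_darr(lo, hi)
        if paired:
            v, basis = darr_variance_shared_cohort(lo, hi, r_cohort)
        else:
            v, basis = darr_variance_independent(lo, hi)
        shared = []
        if i > 0:  # lower group also used by the previous pair
            shared.append(_group_key(lo))
        if i < n_pairs - 1:  # upper group also used by the next pair
            shared.append(_group_key(hi))
        effects.append(
            EffectSize(
                darr=darr,
                variance=v,
                t1=lo.temperature,
                t2=hi.temperature,
                study_id=lo.study_id,
                species=lo.species,
                metric=lo.metric,
                design=lo.design,
                timing=lo.timing,
                habitat=lo.habitat,
                taxon_group=lo.taxon_group,
                population_id=lo.population_id,
                cohort_pairing=paired,
                shared_group_ids=tuple(shared),
                variance_basis=basis,
                heating_rate=lo.heating_rate,
                year=lo.year,
                source_type=lo.source_type,
                sd_imputed=lo.sd_imputed or hi.sd_imputed,
                risk_of_bias=lo.risk_of_bias or hi.risk_of_bias,
                effect_id=f"{_group_key(lo)}->{hi.temperature:g}",
            )
        )
    return effects


def build_effects(
    rows: Iterable[GroupStat], r_cohort: float = DEFAULT_COHORT_R
) -> tuple[list[EffectSize], list[tuple[GroupStat, str]]]:
    """Expand a whole dataset of group rows into effect sizes.

    Rows are partitioned into (study, species, metric, timing) series and
    each series is expanded stepwise.  Returns (effects, rejects) where
    rejects pairs each unusable row with a machine-readable reason; rows
    are never silently dropped.
    """
    series: dict[tuple, list[GroupStat]] = {}
    rejects: list[tuple[GroupStat, str]] = []
    for g in rows:
        if not g.usable:
            rejects.append((g, "no_variance_route: neither sd+n nor se"))
            continue
        series.setdefault((g.study_id, g.species, g.metric, g.timing), []).append(g)
    effects: list[EffectSize] = []
    for key, groups in series.items():
        temps = {round(g.temperature, 6) for g in groups}
        if len(temps) < 2:
            for g in groups:
                rejects.append((g, "single_temperature_series"))
            continue
        effects.extend(stepwise_effects(groups, r_cohort))
    return effects, rejects


def impute_missing_sd(
    rows: Sequence[GroupStat], per_metric: bool = True
) -> tuple[list[GroupStat], dict[str, ImputationSummary]]:
    """Fill missing standard deviations from the pooled sd-to-mean ratio.

    The coefficient of variation sd/|mean| is assumed constant across
    studies; the pool is the arithmetic mean of that ratio over all
    complete rows (separately per heat-tolerance metric by default, since
    CTmax and LT50 dispersions live on different scales).  Rows with a
    missing sd, a known n, and a nonzero mean receive
    sd = pooled_cv * |mean| and are flagged imputed.  Rows reporting only
    a standard error are left untouched (an se admits a variance directly
    and cannot be back-converted without n).  Rows with no route to a
    variance are flagged for the rejects file.  Idempotent: a second pass
    changes nothing.
    """
    def pool_key(g: GroupStat) -> str:
        return g.metric if per_metric else "all"

    complete: dict[str, list[float]] = {}
    for g in rows:
        if g.sd is not None and not g.sd_imputed and abs(g.mean_ht) > 0:
            complete.setdefault(pool_key(g), []).append(g.sd / abs(g.mean_ht))

    out: list[GroupStat] = []
    summaries: dict[str, ImputationSummary] = {
        k: ImputationSummary(pooled_cv=float(np.mean(v)), k_complete=len(v),
                             imputed_row_ids=[])
        for k, v in complete.items()
    }
    needs_pool = [g for g in rows if g.sd is None and not g.has_se]
    if needs_pool and not complete:
        raise ImputationError("no complete rows to pool a CV from")

    for g in rows:
        if g.sd is not None or g.has_se:
            out.append(g)
            continue
        key = pool_key(g)
        summ = summaries.get(key)
        if summ is None or g.n is None or g.mean_ht == 0:
            reason = (
                "no_cv_pool_for_metric" if summ is None
                else "missing_n" if g.n is None
                else "zero_mean"
            )
            summ_all = summaries.setdefault(
                key, ImputationSummary(pooled_cv=float("nan"), k_complete=0,
                                       imputed_row_ids=[])
            )
            summ_all.excluded_row_ids.append(g.row_id or _group_key(g))
            out.append(g)
            continue
        imputed = replace(g, sd=summ.pooled_cv * abs(g.mean_ht), sd_imputed=True)
        summ.imputed_row_ids.append(g.row_id or _group_key(g))
        out.append(imputed)
    return out, summaries


def tdt_to_heat_tolerance(series: TDTSeries) -> GroupStat:
    """Convert a thermal-death-time series to a 1-h tolerated temperature.

    Fits ordinary least squares of log10(time in hours) on test
    temperature; the returned temperature solves the fitted line at
    log10(time) = 0, i.e. the temperature the animals tolerate for one
    hour, a proxy for CTmax from static assays.  A standard error for
    that temperature is attached by the delta method applied to
    T* = -a/b using the OLS coefficient covariance.  A warning is issued
    when T* lies outside the tested range (extrapolation beyond the
    thermal-death-time curve is less reliable than interpolation).
    """
    temps = np.array([t for t, _ in series.points], dtype=float)
    logt = np.log10([h for _, h in series.points])
    if len(np.unique(temps)) < 2:
        raise ValueError("need >= 2 distinct temperatures for the regression")
    X = np.column_stack([np.ones_like(temps), temps])
    coef, *_ = np.linalg.lstsq(X, logt, rcond=None)
    a, b = coef
    if b >= 0:
        raise ImplausibleTDTError(
            f"knockdown time should fall with temperature (slope={b:.3g})"
        )
    t_star = -a / b
    resid = logt - X @ coef
    dof = len(temps) - 2
    if dof > 0:
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(X.T @ X)
        grad = np.array([-1.0 / b, a / b**2])
        se = float(np.sqrt(grad @ cov @ grad))
    else:
        se = 0.0
    if not (temps.min() <= t_star <= temps.max()):
        warnings.warn(
            f"1-h tolerated temperature {t_star:.2f} degC extrapolates beyond "
            f"the tested range [{temps.min():g}, {temps.max():g}]",
            stacklevel=2,
        )
    md = {
        k: v for k, v in series.metadata.items()
        if k in GroupStat.__dataclass_fields__
        and k not in ("study_id", "species", "mean_ht", "se", "metric")
    }
    md.setdefault("temperature", 0.0)
    return GroupStat(
        study_id=series.study_id,
        species=series.species,
        mean_ht=float(t_star),
        se=se if se > 0 else None,
        metric=Metric.tdt_derived.value,
        **md,
    )


def temperature_shift_for_unit_gain(darr: float) -> float:
    """Developmental-temperature shift (deg C) needed to raise heat
    tolerance by 1 deg C, i.e. the reciprocal of dARR."""
    if darr == 0:
        raise ZeroDivisionError("a zero dARR implies no finite shift")
    return 1.0 / darr
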