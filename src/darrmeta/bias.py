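"""Publication-bias diagnostics and robustness (sensitivity) analyses.

Every refit here goes through the same REML path as the main analysis --
the sampling VCV and design are rebuilt for each subset, never
approximated by a shortcut estimator.  The battery covers:

* small-study effects: meta-regression of dARR on its own standard error
  (Egger-style) or sampling variance;
* time-lag ("decline") effects: meta-regression on mean-centered
  publication year;
* thesis vs. peer-reviewed article comparison (cell means + contrast);
* leave-one-study-out and leave-one-species-out refits of the
  intercept-only model;
* subset and cutoff refits (initial/persistent only, dropping imputed
  variances or risk-of-bias rows, dropping effects below a dARR cutoff);
* funnel data export (GLS residual vs. standard error).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from darrmeta.effects import EffectSize
from darrmeta.model import FitResult, contrast, t_inference
from darrmeta.phylo import PhyloCorrelation
from darrmeta.pipeline import fit_effects

__all__ = [
    "LooResult", "SubsetSpec", "small_study_test", "time_lag_test",
    "source_comparison", "leave_one_out", "subset_refits", "funnel_export",
    "default_subset_specs",
]

logger = logging.getLogger(__name__)

MIN_SUBSET_EFFECTS = 10


@dataclass
class LooResult:
    """Leave-one-out refits of the intercept-only model."""

    unit: str                      # "study" or "species"
    table: pd.DataFrame            # one row per excluded unit
    beta0_full: float

    @property
    def beta0_range(self) -> tuple[float, float]:
        return float(self.table["beta0"].min()), float(self.table["beta0"].max())


@dataclass
class SubsetSpec:
    """A named filter over effect sizes for a sensitivity refit."""

    label: str
    predicate: Callable[[EffectSize], bool]


def default_subset_specs(cutoffs: Sequence[float] = (-0.15,)) -> list[SubsetSpec]:
    specs = [
        SubsetSpec("initial_only", lambda e: e.timing == "initial"),
        SubsetSpec("persistent_only", lambda e: e.timing == "persistent"),
        SubsetSpec("exclude_imputed", lambda e: not e.sd_imputed),
        SubsetSpec("exclude_risk_of_bias", lambda e: not e.risk_of_bias),
    ]
    for c in cutoffs:
        specs.append(
            SubsetSpec(f"darr_ge_{c:g}", lambda e, c=c: e.darr >= c)
        )
    return specs


def _slope_fit(
    effects: Sequence[EffectSize],
    A: PhyloCorrelation | None,
    values: np.ndarray,
    name: str,
    center: bool = False,
    **kwargs,
) -> FitResult:
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0:
        raise ValueError(f"moderator {name!r} is constant; no slope is identified")
    if center:
        values = values - values.mean()
    fit, _ = fit_effects(
        effects, A=A, fixed=[name], moderator_values={name: values}, **kwargs
    )
    return fit


def small_study_test(
    effects: Sequence[EffectSize],
    A: PhyloCorrelation | None = None,
    moderator: str = "se",
    **kwargs,
) -> FitResult:
    """Meta-regression of dARR on its standard error (or variance).

    A slope whose 95% CI excludes zero flags small-study asymmetry, the
    funnel-plot signature of publication bias.
    """
    if moderator not in ("se", "variance"):
        raise ValueError("moderator must be 'se' or 'variance'")
    vals = np.array(
        [math.sqrt(e.variance) if moderator == "se" else e.variance for e in effects]
    )
    return _slope_fit(effects, A, vals, moderator, **kwargs)


def time_lag_test(
    effects: Sequence[EffectSize], A: PhyloCorrelation | None = None, **kwargs
) -> FitResult:
    """Meta-regression on mean-centered publication year (decline effect)."""
    years = [e.year for e in effects]
    if any(y is None for y in years):
        raise ValueError("publication year missing on some effects")
    return _slope_fit(effects, A, np.array(years, float), "year", center=True, **kwargs)


def source_comparison(
    effects: Sequence[EffectSize], A: PhyloCorrelation | None = None, **kwargs
) -> tuple[FitResult, dict] | None:
    """Thesis vs. peer-reviewed estimates: cell-means fit plus contrast.

    Returns None (with a logged reason) when only one source type is
    present.
    """
    sources = sorted({e.source_type for e in effects})
    if len(sources) < 2:
        logger.warning(
            "source comparison skipped: only source type(s) %s present", sources
        )
        return None
    fit, _ = fit_effects(effects, A=A, fixed=["source_type"], cell_means=True, **kwargs)
    c = np.zeros(fit.p)
    c[fit.coef_names.index(f"source_type[{sources[0]}]")] = 1.0
    c[fit.coef_names.index(f"source_type[{sources[1]}]")] = -1.0
    return fit, contrast(fit, c)


def leave_one_out(
    effects: Sequence[EffectSize],
    A: PhyloCorrelation | None = None,
    unit: str = "study",
    **kwargs,
) -> LooResult:
    """Refit the intercept-only model excluding one study/species at a time.

    The shared-treatment VCV is rebuilt for every subset.  Refits that
    fail to converge are recorded with a flag, not raised.
    """
    if unit not in ("study", "species"):
        raise ValueError("unit must be 'study' or 'species'")
    attr = "study_id" if unit == "study" else "species"
    units = sorted({getattr(e, attr) for e in effects})
    if len(units) < 3:
        raise ValueError(f"need >= 3 distinct {unit}s for leave-one-out")
    full_fit, _ = fit_effects(effects, A=A, **kwargs)
    rows = []
    for u in units:
        subset = [e for e in effects if getattr(e, attr) != u]
        try:
            fit, _ = fit_effects(subset, A=A, **kwargs)
            inf = t_inference(fit)
            rows.append({
                "excluded": u, "k": fit.k, "beta0": float(fit.beta[0]),
                "ci_lower": float(inf["ci_lower"][0]),
                "ci_upper": float(inf["ci_upper"][0]),
                "converged": fit.converged,
            })
        except Exception as exc:  # refit failure is data, not fatal
            logger.warning("leave-one-out refit without %s failed: %s", u, exc)
            rows.append({
                "excluded": u, "k": len(subset), "beta0": np.nan,
                "ci_lower": np.nan, "ci_upper": np.nan, "converged": False,
            })
    return LooResult(
        unit=unit, table=pd.DataFrame(rows), beta0_full=float(full_fit.beta[0])
    )


def subset_refits(
    effects: Sequence[EffectSize],
    specs: Sequence[SubsetSpec],
    A: PhyloCorrelation | None = None,
    min_effects: int = MIN_SUBSET_EFFECTS,
    **kwargs,
) -> pd.DataFrame:
    """One intercept-only refit per subset specification.

    Subsets with fewer than ``min_effects`` effects are skipped with a
    logged reason and appear in the table with skipped=True.
    """
    rows = []
    for spec in specs:
        subset = [e for e in effects if spec.predicate(e)]
        if len(subset) < min_effects:
            logger.warning(
                "subset %s skipped: %d effect(s) < %d",
                spec.label, len(subset), min_effects,
            )
            rows.append({
                "subset": spec.label, "k": len(subset), "beta0": np.nan,
                "ci_lower": np.nan, "ci_upper": np.nan, "skipped": True,
            })
            continue
        fit, _ = fit_effects(subset, A=A, **kwargs)
        inf = t_inference(fit)
        rows.append({
            "subset": spec.label, "k": fit.k, "beta0": float(fit.beta[0]),
            "ci_lower": float(inf["ci_lower"][0]),
            "ci_upper": float(inf["ci_upper"][0]),
            "skipped": False,
        })
    return pd.DataFrame(rows)


def funnel_export(
    fit: FitResult, effects: Sequence[EffectSize], plot_path=None
) -> pd.DataFrame:
    """Per-effect GLS residual and standard error for funnel inspection."""
    resid = fit.y - fit.X @ fit.beta
    tab = pd.DataFrame({
        "effect_id": [e.effect_id for e in effects],
        "residual": resid,
        "se": [math.sqrt(e.variance) for e in effects],
    })
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(tab["residual"], tab["se"], s=12, alpha=0.6)
        ax.axvline(0.0, color="grey", lw=0.8)
        ax.invert_yaxis()
        ax.set_xlabel("residual dARR")
        ax.set_ylabel("standard error")
        fig.tight_layout()
        fig.savefig(plot_path)
        plt.close(fig)
    return tab
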