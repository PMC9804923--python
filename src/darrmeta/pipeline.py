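"""End-to-end orchestration: group rows -> effects -> matrices -> REML fit.

The canonical ordering is: impute missing standard deviations, convert
thermal-death-time assays (already done upstream when rows arrive as
group summaries), expand stepwise effects, build the shared-treatment
sampling VCV and the phylogenetic correlation, then fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from darrmeta.effects import (
    EffectSize, GroupStat, ImputationSummary, build_effects, impute_missing_sd,
)
from darrmeta.model import FitResult, design_matrix, fit_reml
from darrmeta.phylo import PhyloCorrelation, SamplingVCV, build_sampling_vcv

__all__ = ["AnalysisResult", "effects_to_frame", "fit_effects", "analyze_groups"]

_EFFECT_COLS = [
    "effect_id", "study_id", "species", "darr", "variance", "t1", "t2",
    "metric", "design", "timing", "habitat", "taxon_group", "population_id",
    "cohort_pairing", "shared_group_ids", "variance_basis", "heating_rate",
    "year", "source_type", "sd_imputed", "risk_of_bias",
]


def effects_to_frame(effects: Sequence[EffectSize]) -> pd.DataFrame:
    rows = []
    for e in effects:
        d = {c: getattr(e, c) for c in _EFFECT_COLS}
        d["shared_group_ids"] = ";".join(e.shared_group_ids)
        rows.append(d)
    return pd.DataFrame(rows, columns=_EFFECT_COLS)


@dataclass
class AnalysisResult:
    fit: FitResult
    effects: list[EffectSize]
    V: SamplingVCV
    rejects: list[tuple[GroupStat, str]] = field(default_factory=list)
    imputation: dict[str, ImputationSummary] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.effects)


def fit_effects(
    effects: Sequence[EffectSize],
    A: PhyloCorrelation | None = None,
    fixed: Sequence[str] | None = None,
    cell_means: bool = True,
    obs_level_moderator: str | None = None,
    random: Sequence[str] = ("phylo", "species", "observation"),
    r_shared: float = 0.5,
    moderator_values: dict | None = None,
    **fit_kwargs,
) -> tuple[FitResult, SamplingVCV]:
    """Fit the main multilevel model to a list of effect sizes.

    ``fixed`` names EffectSize attributes used as moderators; extra
    continuous moderators (e.g. the effect's own SE for small-study
    tests) can be supplied through ``moderator_values``.
    """
    effects = list(effects)
    frame = effects_to_frame(effects)
    if moderator_values:
        for name, vals in moderator_values.items():
            frame[name] = np.asarray(vals)
    V = build_sampling_vcv(effects, r_shared=r_shared)
    X, names = design_matrix(frame, fixed, cell_means=cell_means)
    obs_levels = (
        frame[obs_level_moderator].astype(str).tolist()
        if obs_level_moderator else None
    )
    use_random = [r for r in random if r != "phylo" or A is not None]
    fit = fit_reml(
        frame["darr"].to_numpy(),
        X=X,
        V=V,
        species=frame["species"].tolist() if ("species" in use_random or "phylo" in use_random) else None,
        A=A,
        random=use_random,
        obs_levels=obs_levels,
        coef_names=names,
        **fit_kwargs,
    )
    return fit, V


def analyze_groups(
    groups: Sequence[GroupStat],
    A: PhyloCorrelation | None = None,
    impute: bool = True,
    r_cohort: float = 0.5,
    r_shared: float = 0.5,
    **fit_kwargs,
) -> AnalysisResult:
    """Full pipeline from group summaries to a fitted intercept-only (or
    moderator) model."""
    summaries: dict[str, ImputationSummary] = {}
    rows = list(groups)
    if impute:
        rows, summaries = impute_missing_sd(rows)
    effects, rejects = build_effects(rows, r_cohort=r_cohort)
    fit, V = fit_effects(effects, A=A, r_shared=r_shared, **fit_kwargs)
    return AnalysisResult(
        fit=fit, effects=effects, V=V, rejects=rejects, imputation=summaries
    )
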