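"""Synthetic study systems with known truth for the dARR meta-analysis.

The generator mirrors the generative reading of the meta-analytic model:
species carry a true plasticity slope drawn around the grand mean with a
phylogenetically correlated component (covariance s2_phylo * A) plus an
independent species component (s2_species); every stepwise comparison
adds its own observation-level deviation (s2_obs, optionally per level
of a categorical moderator).  Group summaries are then produced the way
empirical studies report them: the observed group mean is the true mean
plus normal error sd/sqrt(n), and the observed sd follows the exact
chi-square sampling law sd * sqrt(chisq(n-1)/(n-1)) so that downstream
sampling variances are correctly calibrated.  Multi-temperature designs
create shared-treatment dependence, a configurable fraction of
two-temperature studies are paired cohorts (repeated measures), some
standard deviations go missing, and some studies report static
thermal-death-time assays instead of direct tolerance summaries.

For paired-cohort studies the two observed group means are drawn jointly
with correlation r = 0.5 and variance sd^2/(n1 + n2), the sampling law
under which the repeated-measures variance formula used downstream is
exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from darrmeta.effects import GroupStat, TDTSeries, tdt_to_heat_tolerance
from darrmeta.phylo import grafen_lengths, phylo_correlation, PhyloCorrelation

__all__ = ["SimTruth", "simulate_tree", "simulate_dataset", "simulate_tdt"]


@dataclass
class SimTruth:
    """Ground truth and design configuration for one synthetic dataset.

    Defaults are paper-scale: a weak overall effect (~0.19 deg C per
    deg C) with heterogeneity dwarfing sampling error, ~40 species, a
    mix of 2-4 temperature designs, mostly aquatic species, about a
    fifth of effects from persistent designs.
    """

    beta0: float = 0.19
    moderator_effects: dict = field(default_factory=dict)
    sigma2_phylo: float = 0.05
    sigma2_species: float = 0.05
    sigma2_obs: float | dict = 0.15
    obs_level_moderator: str | None = None
    n_species: int = 40
    studies_per_species: tuple[int, int] = (2, 5)
    temps_probs: dict = field(default_factory=lambda: {2: 0.6, 3: 0.3, 4: 0.1})
    frac_paired_cohort: float = 0.10
    frac_persistent: float = 0.20
    frac_tdt: float = 0.05
    frac_missing_sd: float = 0.10
    frac_aquatic: float = 0.857
    frac_thesis: float = 0.10
    frac_lt50: float = 0.20
    baseline_ht: tuple[float, float] = (38.0, 3.0)
    ind_sd_range: tuple[float, float] = (0.5, 2.0)
    n_range: tuple[int, int] = (8, 30)
    t_min_range: tuple[float, float] = (18.0, 26.0)
    t_step_range: tuple[float, float] = (2.0, 5.0)
    year_range: tuple[int, int] = (1960, 2021)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma2_phylo", "sigma2_species"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        s2o = self.sigma2_obs
        if isinstance(s2o, dict):
            if any(v < 0 for v in s2o.values()):
                raise ValueError("per-level sigma2_obs must be >= 0")
            if self.obs_level_moderator is None:
                raise ValueError("per-level sigma2_obs needs obs_level_moderator")
        elif s2o < 0:
            raise ValueError("sigma2_obs must be >= 0")
        for name in ("frac_paired_cohort", "frac_persistent", "frac_tdt",
                     "frac_missing_sd", "frac_aquatic", "frac_thesis",
                     "frac_lt50"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_range[0] < 2:
            raise ValueError("group sample sizes must be >= 2")
        if self.n_species < 2:
            raise ValueError("need >= 2 species")


def simulate_tree(n_species: int, seed: int) -> dendropy.Tree:
    """Random binary rooted topology by successive random joins.

    Tips are labelled sp_1 ... sp_n; deterministic per seed.
    """
    if n_species < 2:
        raise ValueError("need >= 2 species")
    rng = np.random.default_rng(seed)
    lineages = [f"sp_{i + 1}" for i in range(n_species)]
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        merged = f"({lineages[i]},{lineages[j]})"
        lineages = [x for idx, x in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
    tree = dendropy.Tree.get(data=lineages[0] + ";", schema="newick")
    tree.is_rooted = True
    return tree


def simulate_tdt(
    a: float, b: float, noise_sd: float, n_points: int, seed: int,
    t_range: tuple[float, float] | None = None,
) -> TDTSeries:
    """Thermal-death-time series around the line log10(hours) = a + b*T."""
    if b >= 0:
        raise ValueError("TDT slope must be negative")
    if n_points < 3:
        raise ValueError("need >= 3 points")
    rng = np.random.default_rng(seed)
    if t_range is None:
        # span where tolerated time runs from ~10 h down to ~0.1 h
        t_star = -a / b
        t_range = (t_star + 1.0 / b, t_star - 1.0 / b)
    temps = np.linspace(t_range[0], t_range[1], n_points)
    logt = a + b * temps + rng.normal(0.0, noise_sd, n_points)
    return TDTSeries(points=[(float(t), float(10.0**lt)) for t, lt in zip(temps, logt)])


def _habitat_effect(truth: SimTruth, habitat: str) -> float:
    return truth.moderator_effects.get(f"habitat[{habitat}]", 0.0)


def simulate_dataset(
    truth: SimTruth, tree: dendropy.Tree | None = None
) -> tuple[list[GroupStat], pd.DataFrame, PhyloCorrelation]:
    """Generate group-level rows plus a per-comparison truth table.

    Returns (groups, truth_table, A) where A is the Grafen correlation of
    the (binary) tree actually used.  The truth table has one row per
    adjacent-temperature comparison with every latent quantity: the
    species deviations, the observation-level deviation, and the true
    slope realised over that interval.
    """
    rng = np.random.default_rng(truth.seed)
    if tree is None:
        tree = simulate_tree(truth.n_species, int(rng.integers(2**31 - 1)))
    A = phylo_correlation(grafen_lengths(tree))
    species = A.species[: truth.n_species]
    if len(species) < truth.n_species:
        raise ValueError("tree has fewer tips than n_species")
    Asub = A.submatrix(sorted(species))
    order = Asub.species

    # species-level deviations
    L = np.linalg.cholesky(Asub.matrix + 1e-10 * np.eye(len(order)))
    u_phylo = math.sqrt(truth.sigma2_phylo) * (L @ rng.standard_normal(len(order)))
    u_species = math.sqrt(truth.sigma2_species) * rng.standard_normal(len(order))
    sp_info = {}
    for i, sp in enumerate(order):
        sp_info[sp] = {
            "u_phylo": float(u_phylo[i]),
            "u_species": float(u_species[i]),
            "habitat": "aquatic" if rng.random() < truth.frac_aquatic else "terrestrial",
        }

    year_mid = 0.5 * (truth.year_range[0] + truth.year_range[1])
    temps_k = np.array(sorted(truth.temps_probs))
    temps_p = np.array([truth.temps_probs[k] for k in temps_k], dtype=float)
    temps_p /= temps_p.sum()

    groups: list[GroupStat] = []
    truth_rows: list[dict] = []
    study_idx = 0
    for sp in order:
        info = sp_info[sp]
        n_studies = int(rng.integers(truth.studies_per_species[0],
                                     truth.studies_per_species[1] + 1))
        for _ in range(n_studies):
            study_idx += 1
            study_id = f"S{study_idx:04d}"
            year = int(rng.integers(truth.year_range[0], truth.year_range[1] + 1))
            source = "thesis" if rng.random() < truth.frac_thesis else "article"
            metric = "lt50" if rng.random() < truth.frac_lt50 else "ctmax"
            persistent = rng.random() < truth.frac_persistent
            timing = "persistent" if persistent else "initial"
            design = rng.choice(list("DEF" if persistent else "ABC"))
            n_temps = int(rng.choice(temps_k, p=temps_p))
            paired = n_temps == 2 and rng.random() < truth.frac_paired_cohort
            use_tdt = (
                metric == "ctmax" and not paired and rng.random() < truth.frac_tdt
            )
            t0 = rng.uniform(*truth.t_min_range)
            steps = rng.uniform(*truth.t_step_range, size=n_temps - 1)
            temps = t0 + np.concatenate([[0.0], np.cumsum(steps)])
            baseline = rng.normal(*truth.baseline_ht)

            # moderator level controlling the observation-level variance
            if isinstance(truth.sigma2_obs, dict):
                lev_col = truth.obs_level_moderator
                lev = {"habitat": info["habitat"], "timing": timing,
                       "metric": metric, "source_type": source}[lev_col]
                s2_obs = truth.sigma2_obs[lev]
            else:
                s2_obs = truth.sigma2_obs

            fixed_part = (
                truth.beta0
                + _habitat_effect(truth, info["habitat"])
                + truth.moderator_effects.get("year", 0.0) * (year - year_mid)
                + (truth.moderator_effects.get("source[thesis]", 0.0)
                   if source == "thesis" else 0.0)
            )
            mu = [baseline]
            for j in range(n_temps - 1):
                e_obs = rng.normal(0.0, math.sqrt(s2_obs))
                slope = fixed_part + info["u_phylo"] + info["u_species"] + e_obs
                mu.append(mu[-1] + slope * (temps[j + 1] - temps[j]))
                truth_rows.append({
                    "study_id": study_id, "species": sp,
                    "t1": float(temps[j]), "t2": float(temps[j + 1]),
                    "true_slope": float(slope), "fixed_part": float(fixed_part),
                    "u_phylo": info["u_phylo"], "u_species": info["u_species"],
                    "e_obs": float(e_obs), "habitat": info["habitat"],
                    "timing": timing, "metric": metric, "year": year,
                    "source_type": source, "paired": paired, "tdt": use_tdt,
                })

            sds = rng.uniform(*truth.ind_sd_range, size=n_temps)
            ns = rng.integers(truth.n_range[0], truth.n_range[1] + 1, size=n_temps)
            if paired:
                ntot = int(ns[0] + ns[1])
                r = 0.5
                cov = np.array([
                    [sds[0] ** 2, r * sds[0] * sds[1]],
                    [r * sds[0] * sds[1], sds[1] ** 2],
                ]) / ntot
                errs = rng.multivariate_normal(np.zeros(2), cov)
            else:
                errs = rng.normal(0.0, sds / np.sqrt(ns))
            obs_sd = sds * np.sqrt(rng.chisquare(ns - 1) / (ns - 1))

            cohort = f"{study_id}_c" if paired else None
            for j in range(n_temps):
                g = GroupStat(
                    study_id=study_id,
                    species=sp,
                    temperature=float(temps[j]),
                    mean_ht=float(mu[j] + errs[j]),
                    sd=float(obs_sd[j]),
                    n=int(ns[j]),
                    metric=metric,
                    design=str(design),
                    timing=timing,
                    habitat=info["habitat"],
                    taxon_group="fish" if info["habitat"] == "aquatic" else "reptile",
                    cohort_id=cohort,
                    year=year,
                    source_type=source,
                    row_id=f"{study_id}_g{j + 1}",
                )
                if use_tdt:
                    # the derived estimate's error comes entirely from the
                    # regression noise, matching its delta-method SE, so the
                    # line is centred on the true group mean
                    series = simulate_tdt(
                        a=0.5 * float(mu[j]), b=-0.5, noise_sd=0.05,
                        n_points=6, seed=int(rng.integers(2**31 - 1)),
                    )
                    series.study_id = study_id
                    series.species = sp
                    series.metadata = {
                        "temperature": g.temperature, "design": g.design,
                        "timing": g.timing, "habitat": g.habitat,
                        "taxon_group": g.taxon_group, "year": g.year,
                        "source_type": g.source_type, "row_id": g.row_id,
                    }
                    g = tdt_to_heat_tolerance(series)
                elif truth.frac_missing_sd > 0 and rng.random() < truth.frac_missing_sd:
                    g.sd = None
                groups.append(g)

    return groups, pd.DataFrame(truth_rows), Asub
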