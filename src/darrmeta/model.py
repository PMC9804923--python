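"""Multilevel random-effects meta-analysis by REML with a known sampling VCV.

The marginal model for the k x 1 vector of effect sizes y is

    y ~ N(X beta, Sigma(theta)),
    Sigma(theta) = s2_phylo * Zs A Zs' + s2_species * Zs Zs'
                   + D_obs(theta) + V,

where Zs maps effects to species, A is the phylogenetic correlation
matrix, D_obs is a diagonal observation-level heterogeneity matrix
(a single variance, or one variance per level of a categorical moderator
-- a heteroscedastic structure with zero covariance between levels), and
V is the known sampling variance-covariance matrix.  Variance components
are estimated by restricted maximum likelihood on the log scale with a
deterministic multistart; fixed effects come from generalized least
squares at the REML optimum.  Inference on coefficients and linear
combinations uses t distributions with k - p degrees of freedom, and a
95% confidence interval excluding zero is the significance convention.

Heterogeneity is summarised by a multilevel I^2: with weights w_i = 1/v_i
the "typical" sampling variance is

    s2_typ = (k - 1) sum(w) / ((sum w)^2 - sum(w^2)),

and each component's I^2 is its variance over the common denominator
(sum of all components + s2_typ), so component values add up to the
total exactly.  Prediction intervals widen the coefficient CI by the
summed heterogeneity variance and say where a new study's true effect is
expected to fall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg as sla
import scipy.optimize as opt
import scipy.stats as st

from darrmeta.phylo import PhyloCorrelation, SamplingVCV

__all__ = [
    "FitResult", "fit_reml", "t_inference", "prediction_interval",
    "i2_decomposition", "marginal_means", "contrast", "aic_compare",
    "design_matrix",
]

VAR_FLOOR = 1e-8          # components below this are reported as exactly 0
_LOG_BOUNDS = (-30.0, 10.0)  # bounds for log variance components
_CLIP = 1e-10             # eigenvalue clip used for factorization only


@dataclass
class FitResult:
    """REML fit: fixed effects with t inference plus variance components."""

    beta: np.ndarray
    se_beta: np.ndarray
    cov_beta: np.ndarray
    coef_names: list[str]
    variance_components: dict[str, float]
    restricted_loglik: float
    k: int
    p: int
    converged: bool
    obs_level_counts: dict[str, int] | None = None
    y: np.ndarray | None = None
    X: np.ndarray | None = None
    vi: np.ndarray | None = None
    n_var_params: int = 0

    @property
    def df(self) -> int:
        return self.k - self.p

    @property
    def aic(self) -> float:
        """REML AIC counting variance parameters; comparable only across
        fits sharing the same fixed-effect design."""
        return -2.0 * self.restricted_loglik + 2.0 * self.n_var_params

    @property
    def sigma2_total(self) -> float:
        """Summed heterogeneity variance; per-level observation variances
        enter as their effect-count-weighted mean."""
        total = sum(
            s2 for name, s2 in self.variance_components.items()
            if not name.startswith("obs")
        )
        return total + self.sigma2_obs_pooled

    @property
    def sigma2_obs_pooled(self) -> float:
        per_level = {
            name[4:]: s2
            for name, s2 in self.variance_components.items()
            if name.startswith("obs:")
        }
        if not per_level:
            return self.variance_components.get("obs", 0.0)
        counts = self.obs_level_counts or {}
        ntot = sum(counts.get(lv, 1) for lv in per_level)
        return sum(s2 * counts.get(lv, 1) for lv, s2 in per_level.items()) / ntot

    def summary(self) -> dict:
        inf = t_inference(self)
        return {
            "k": self.k,
            "coefficients": [
                {
                    "name": n,
                    "estimate": float(b),
                    "se": float(s),
                    "t": float(t),
                    "df": self.df,
                    "p": float(pv),
                    "ci_lower": float(lo),
                    "ci_upper": float(hi),
                }
                for n, b, s, t, pv, lo, hi in zip(
                    self.coef_names, self.beta, self.se_beta,
                    inf["t"], inf["p"], inf["ci_lower"], inf["ci_upper"],
                )
            ],
            "variance_components": {k: float(v) for k, v in self.variance_components.items()},
            "restricted_loglik": float(self.restricted_loglik),
            "aic": float(self.aic),
            "converged": bool(self.converged),
        }


def design_matrix(
    data, fixed: Sequence[str] | None, cell_means: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Build a fixed-effect design from a DataFrame-like mapping of columns.

    ``fixed`` lists moderator columns; categorical (object/str) columns
    are coded as cell means (no intercept, one column per level) when
    ``cell_means`` and there is a single categorical moderator, otherwise
    as treatment contrasts with an intercept.  Continuous moderators are
    mean-centered and an intercept is retained.
    """
    import pandas as pd

    if not fixed:
        return np.ones((len(data), 1)), ["intercept"]
    k = len(pd.Series(list(data[fixed[0]])))
    cols = []
    names = []
    categorical = []
    continuous = []
    for m in fixed:
        vals = pd.Series(list(data[m]))
        if vals.dtype == object or isinstance(vals.iloc[0], str):
            categorical.append((m, vals.astype(str)))
        else:
            continuous.append((m, vals.astype(float)))
    if categorical and cell_means and not continuous and len(categorical) == 1:
        m, vals = categorical[0]
        for lev in sorted(vals.unique()):
            cols.append((vals == lev).to_numpy(dtype=float))
            names.append(f"{m}[{lev}]")
    else:
        cols.append(np.ones(k))
        names.append("intercept")
        for m, vals in categorical:
            levels = sorted(vals.unique())
            for lev in levels[1:]:
                cols.append((vals == lev).to_numpy(dtype=float))
                names.append(f"{m}[{lev}]")
        for m, vals in continuous:
            cols.append((vals - vals.mean()).to_numpy())
            names.append(m)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient fixed-effect design")
    return X, names


def _component_matrices(
    k: int,
    species: Sequence[str] | None,
    A: PhyloCorrelation | np.ndarray | None,
    random: Sequence[str],
    obs_levels: Sequence[str] | None,
) -> tuple[list[tuple[str, np.ndarray]], dict[str, int] | None]:
    comps: list[tuple[str, np.ndarray]] = []
    level_counts: dict[str, int] | None = None
    wants_species = "species" in random or "phylo" in random
    if wants_species:
        if species is None:
            raise ValueError("species map required for phylo/species random effects")
        species = list(species)
        uniq = sorted(set(species))
        Z = np.zeros((k, len(uniq)))
        for i, s in enumerate(species):
            Z[i, uniq.index(s)] = 1.0
    if "phylo" in random:
        if A is None:
            raise ValueError("phylogenetic correlation required for phylo effect")
        if isinstance(A, PhyloCorrelation):
            Am = A.submatrix(uniq).matrix
        else:
            Am = np.asarray(A, dtype=float)
            if Am.shape != (len(uniq), len(uniq)):
                raise ValueError(
                    "correlation matrix shape does not match the species set; "
                    "pass a PhyloCorrelation to align by name"
                )
        comps.append(("phylo", Z @ Am @ Z.T))
    if "species" in random:
        comps.append(("species", Z @ Z.T))
    if "observation" in random:
        if obs_levels is None:
            comps.append(("obs", np.eye(k)))
        else:
            obs_levels = [str(x) for x in obs_levels]
            if len(obs_levels) != k:
                raise ValueError("obs_levels length must equal k")
            level_counts = {}
            for lev in sorted(set(obs_levels)):
                mask = np.array([x == lev for x in obs_levels], dtype=float)
                comps.append((f"obs:{lev}", np.diag(mask)))
                level_counts[lev] = int(mask.sum())
    return comps, level_counts


def _chol_logdet_solve(Sigma: np.ndarray, rhs: np.ndarray):
    """Cholesky factorization with eigenvalue clipping as a fallback.

    Clipping is used for factorization only; reported results always come
    from the unmodified parameter values.
    """
    try:
        c = sla.cho_factor(Sigma, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        ev, U = np.linalg.eigh(Sigma)
        ev = np.clip(ev, _CLIP, None)
        Sigma = (U * ev) @ U.T
        c = sla.cho_factor(Sigma, lower=True, check_finite=False)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    return logdet, sla.cho_solve(c, rhs, check_finite=False)


def restricted_loglik(
    sigma2: Sequence[float],
    y: np.ndarray,
    X: np.ndarray,
    V: np.ndarray,
    comps: Sequence[tuple[str, np.ndarray]],
) -> float:
    """Restricted log-likelihood at the given variance components.

    Uses the standard form including the +0.5 log|X'X| constant, so the
    value equals the density of any orthonormal set of error contrasts.
    """
    k, p = X.shape
    Sigma = V.copy()
    for s2, (_, M) in zip(sigma2, comps):
        if s2 > 0:
            Sigma += s2 * M
    rhs = np.column_stack([X, y])
    logdet, sol = _chol_logdet_solve(Sigma, rhs)
    SiX, Siy = sol[:, :p], sol[:, p]
    XtSiX = X.T @ SiX
    cf = sla.cho_factor(XtSiX, lower=True, check_finite=False)
    logdet_x = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    beta = sla.cho_solve(cf, X.T @ Siy, check_finite=False)
    resid = y - X @ beta
    _, Sir = _chol_logdet_solve(Sigma, resid)
    quad = float(resid @ Sir)
    sign, logdet_xx = np.linalg.slogdet(X.T @ X)
    return -0.5 * (
        (k - p) * math.log(2 * math.pi) - logdet_xx + logdet + logdet_x + quad
    )


def _gls(y, X, Sigma):
    p = X.shape[1]
    rhs = np.column_stack([X, y])
    _, sol = _chol_logdet_solve(Sigma, rhs)
    SiX, Siy = sol[:, :p], sol[:, p]
    XtSiX = X.T @ SiX
    cov = np.linalg.inv(XtSiX)
    beta = cov @ (X.T @ Siy)
    return beta, cov


def fit_reml(
    y,
    X: np.ndarray | None = None,
    V: SamplingVCV | np.ndarray | None = None,
    species: Sequence[str] | None = None,
    A: PhyloCorrelation | np.ndarray | None = None,
    random: Sequence[str] = ("phylo", "species", "observation"),
    obs_levels: Sequence[str] | None = None,
    coef_names: Sequence[str] | None = None,
    n_starts: int = 3,
    rtol: float = 1e-8,
) -> FitResult:
    """Fit the multilevel meta-analytic model by REML.

    Parameters
    ----------
    y : array of effect sizes (dARR scale).
    X : fixed-effect design matrix; defaults to an intercept-only column.
    V : known sampling VCV (``SamplingVCV``, full matrix, or a 1-D array
        of independent sampling variances).
    species : per-effect species labels (for phylo/species effects).
    A : phylogenetic correlation aligned to the species set.
    random : subset of {"phylo", "species", "observation"}.
    obs_levels : per-effect labels of a categorical moderator; when given,
        a separate observation-level variance is estimated per level
        (heteroscedastic, zero covariance between levels).
    n_starts : deterministic multistart count for the optimizer.

    Variance components are optimized on the log scale; components that
    finish below a small floor are reported as exactly 0.
    """
    y = np.asarray(y, dtype=float)
    k = len(y)
    if X is None:
        X = np.ones((k, 1))
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if k <= p:
        raise ValueError(f"need more effects (k={k}) than coefficients (p={p})")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient fixed-effect design")
    if V is None:
        raise ValueError("a sampling (co)variance structure V is required")
    if isinstance(V, SamplingVCV):
        Vm = V.matrix
    else:
        Vm = np.asarray(V, dtype=float)
        if Vm.ndim == 1:
            Vm = np.diag(Vm)
    if Vm.shape != (k, k):
        raise ValueError("V shape does not match y")

    comps, level_counts = _component_matrices(k, species, A, random, obs_levels)
    q = len(comps)
    if q == 0:
        beta, cov = _gls(y, X, Vm)
        se = np.sqrt(np.diag(cov))
        ll = restricted_loglik([], y, X, Vm, [])
        return FitResult(
            beta=beta, se_beta=se, cov_beta=cov,
            coef_names=list(coef_names or [f"b{i}" for i in range(p)]),
            variance_components={}, restricted_loglik=ll, k=k, p=p,
            converged=True, y=y, X=X, vi=np.diag(Vm).copy(), n_var_params=0,
        )

    # moment-based scale for starting values
    w = 1.0 / np.diag(Vm)
    beta_w = np.linalg.lstsq(X * np.sqrt(w)[:, None], y * np.sqrt(w), rcond=None)[0]
    resid = y - X @ beta_w
    tau0 = max(float(np.var(resid, ddof=p)) - float(np.mean(np.diag(Vm))), 1e-3)
    starts = []
    starts.append(np.full(q, tau0 / q))                       # even split
    heavy_obs = np.full(q, 0.1 * tau0 / max(q - 1, 1))
    for i, (name, _) in enumerate(comps):
        if name.startswith("obs"):
            heavy_obs[i] = 0.9 * tau0 / sum(n.startswith("obs") for n, _ in comps)
    starts.append(heavy_obs)
    starts.append(np.full(q, 10 * tau0 / q))                  # inflated
    while len(starts) < n_starts:
        starts.append(starts[len(starts) % 3] * (0.5 ** (len(starts) // 3)))

    def nll(log_s2):
        return -restricted_loglik(np.exp(log_s2), y, X, Vm, comps)

    best = None
    converged = False
    for s0 in starts[:max(n_starts, 1)]:
        x0 = np.log(np.clip(s0, 1e-8, None))
        res = opt.minimize(
            nll, x0, method="L-BFGS-B",
            bounds=[_LOG_BOUNDS] * q,
            options={"ftol": rtol * 1e-4, "gtol": 1e-9, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        converged = converged or res.success
    # derivative-free polish for tight optima (flat log-likelihoods)
    polish = opt.minimize(
        nll, best.x, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-13, "maxiter": 400},
    )
    if polish.fun < best.fun:
        best = polish
    s2 = np.exp(best.x)
    s2[s2 < VAR_FLOOR] = 0.0
    ll = restricted_loglik(s2, y, X, Vm, comps)

    Sigma = Vm.copy()
    for s, (_, M) in zip(s2, comps):
        if s > 0:
            Sigma += s * M
    beta, cov = _gls(y, X, Sigma)
    se = np.sqrt(np.diag(cov))
    return FitResult(
        beta=beta,
        se_beta=se,
        cov_beta=cov,
        coef_names=list(coef_names or [f"b{i}" for i in range(p)]),
        variance_components={name: float(s) for (name, _), s in zip(comps, s2)},
        restricted_loglik=float(ll),
        k=k,
        p=p,
        converged=bool(converged),
        obs_level_counts=level_counts,
        y=y,
        X=X,
        vi=np.diag(Vm).copy(),
        n_var_params=q,
    )


def t_inference(fit: FitResult, level: float = 0.95) -> dict[str, np.ndarray]:
    """t statistics, p values and CIs for each coefficient, df = k - p."""
    df = fit.df
    if df <= 0:
        raise ValueError(f"no residual degrees of freedom (k={fit.k}, p={fit.p})")
    t = np.zeros_like(fit.beta)
    nz = fit.se_beta > 0
    t[nz] = fit.beta[nz] / fit.se_beta[nz]
    t[~nz] = np.sign(fit.beta[~nz]) * np.inf
    t[np.isnan(t)] = 0.0
    pvals = 2.0 * st.t.sf(np.abs(t), df)
    tc = st.t.ppf(0.5 + level / 2, df)
    return {
        "t": t,
        "df": df,
        "p": pvals,
        "ci_lower": fit.beta - tc * fit.se_beta,
        "ci_upper": fit.beta + tc * fit.se_beta,
    }


def prediction_interval(
    fit: FitResult, level: float = 0.95, obs_level: str | None = None
) -> dict[str, np.ndarray]:
    """Prediction interval per coefficient: where a new study's true
    effect is expected to fall.

    Adds the summed heterogeneity variance to the coefficient's squared
    SE.  Under per-level observation variances the default uses the
    effect-count-weighted mean of the level variances; pass ``obs_level``
    to use a specific level's own variance instead.
    """
    if obs_level is not None:
        key = f"obs:{obs_level}"
        if key not in fit.variance_components:
            raise KeyError(f"no observation-level variance for level {obs_level!r}")
        s2_obs = fit.variance_components[key]
        s2_between = sum(
            v for n, v in fit.variance_components.items() if not n.startswith("obs")
        )
        s2_tot = s2_between + s2_obs
    else:
        s2_tot = fit.sigma2_total
    tc = st.t.ppf(0.5 + level / 2, fit.df)
    half = tc * np.sqrt(fit.se_beta**2 + s2_tot)
    return {"pi_lower": fit.beta - half, "pi_upper": fit.beta + half}


def typical_sampling_variance(v: np.ndarray) -> float:
    """The multilevel "typical" sampling variance s2_typ used by I^2."""
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("sampling variances must be > 0")
    w = 1.0 / v
    k = len(v)
    return float((k - 1) * w.sum() / (w.sum() ** 2 - (w**2).sum()))


def i2_decomposition(
    fit: FitResult, v: np.ndarray | None = None
) -> dict[str, float]:
    """Percent of total variance attributable to each heterogeneity source.

    Components share one denominator (all heterogeneity variances plus
    the typical sampling variance), so they sum to the total exactly.
    Per-level observation variances are pooled by effect count.
    """
    if v is None:
        v = fit.vi
    s2_typ = typical_sampling_variance(v)
    parts = {
        name: s2
        for name, s2 in fit.variance_components.items()
        if not name.startswith("obs:")
    }
    pooled_obs = fit.sigma2_obs_pooled
    if "obs" not in parts:
        parts["obs"] = pooled_obs
    denom = sum(parts.values()) + s2_typ
    out = {f"i2_{name}": 100.0 * s2 / denom for name, s2 in parts.items()}
    out["i2_total"] = 100.0 * sum(parts.values()) / denom
    return out


def contrast(fit: FitResult, c: Sequence[float], level: float = 0.95) -> dict:
    """Inference for the linear combination c' beta with df = k - p."""
    c = np.asarray(c, dtype=float)
    if c.shape != (fit.p,):
        raise ValueError(f"contrast length {c.shape} does not match p={fit.p}")
    est = float(c @ fit.beta)
    se = float(np.sqrt(max(c @ fit.cov_beta @ c, 0.0)))
    df = fit.df
    if se > 0:
        t = est / se
        pval = 2.0 * float(st.t.sf(abs(t), df))
    else:
        t = 0.0 if est == 0 else math.copysign(math.inf, est)
        pval = 1.0 if est == 0 else 0.0
    tc = float(st.t.ppf(0.5 + level / 2, df))
    return {
        "estimate": est, "se": se, "t": t, "df": df, "p": pval,
        "ci_lower": est - tc * se, "ci_upper": est + tc * se,
    }


def marginal_means(
    fit: FitResult,
    levels: Sequence[str] | None = None,
    weights: Sequence[float] | None = None,
    level: float = 0.95,
) -> dict:
    """Post-stratified marginal mean over the levels of a cell-means fit.

    By default every level receives equal weight 1/L, which corrects for
    unbalanced representation of categories (e.g., the overabundance of
    aquatic species) rather than weighting by data share.  Returns the
    estimate with SE, CI and a prediction interval using the fit's df.
    """
    names = levels if levels is not None else fit.coef_names
    idx = []
    for name in names:
        if name not in fit.coef_names:
            raise KeyError(f"level {name!r} not among fitted coefficients")
        idx.append(fit.coef_names.index(name))
    L = len(idx)
    w = np.full(L, 1.0 / L) if weights is None else np.asarray(weights, float)
    if len(w) != L or not math.isclose(w.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("weights must match levels and sum to 1")
    c = np.zeros(fit.p)
    for i, j in enumerate(idx):
        c[j] = w[i]
    out = contrast(fit, c, level=level)
    tc = float(st.t.ppf(0.5 + level / 2, fit.df))
    half = tc * math.sqrt(out["se"] ** 2 + fit.sigma2_total)
    out["pi_lower"] = out["estimate"] - half
    out["pi_upper"] = out["estimate"] + half
    return out


def aic_compare(fits: Mapping[str, FitResult]):
    """Compare REML fits sharing the same fixed-effect design by AIC.

    AIC counts variance parameters only (REML likelihoods are comparable
    only at a fixed design matrix); differing designs raise.
    """
    import pandas as pd

    items = list(fits.items())
    X0 = items[0][1].X
    for name, f in items[1:]:
        if f.X.shape != X0.shape or not np.allclose(f.X, X0):
            raise ValueError(
                f"fit {name!r} has a different fixed-effect design; "
                "REML AICs are not comparable"
            )
    rows = [
        {
            "model": name,
            "n_var_params": f.n_var_params,
            "restricted_loglik": f.restricted_loglik,
            "aic": f.aic,
        }
        for name, f in items
    ]
    tab = pd.DataFrame(rows).set_index("model")
    tab["delta_aic"] = tab["aic"] - tab["aic"].min()
    return tab.sort_values("aic")
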