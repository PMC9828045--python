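"""Per-module macroevolutionary model fitting, rate comparison and disparity.

High-dimensional trait matrices (q coordinates may exceed the N species)
are fitted under Brownian motion (BM), single-optimum Ornstein-Uhlenbeck
(OU) and early-burst (EB) models by penalized restricted likelihood: the
data are projected onto mean-orthogonal contrasts and whitened by the
model's species covariance, the trait covariance R is estimated by linear
shrinkage toward its diagonal, and the evolutionary parameter and
shrinkage intensity are tuned jointly by leave-one-out cross-validation
over the whitened contrast rows.  Models are compared by a generalized information
criterion (GIC) whose effective degrees of freedom interpolate between the
full and the diagonal covariance with the shrinkage intensity.

The OU "rate of adaptation" alpha is parameterized per unit tree height;
its phylogenetic half-life in absolute time is ``t_1/2 = (ln 2 / alpha) * height``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from morphomod.hypotheses import ModulePartition
from morphomod.phylo import Phylogeny, species_covariance
from morphomod.procrustes import AlignedShapes

MODEL_ORDER = ("BM", "EB", "OU")  # fixed tie-break order for model preference

_GAMMA_GRID = np.array([0.01, 0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 0.9, 1.0])
_ALPHA_GRID = np.concatenate([[1e-3], np.geomspace(0.05, 50.0, 14)])  # per unit height
_EB_GRID = np.concatenate([-np.geomspace(10.0, 0.05, 7), [0.0], np.geomspace(0.05, 10.0, 7)])


@dataclass
class TraitModelFit:
    """One evolutionary model's penalized-likelihood fit to a trait block."""

    model: str
    alpha: Optional[float]  # per unit tree height (OU)
    r: Optional[float]  # per unit tree height (EB)
    trait_cov: np.ndarray  # q x q shrunk evolutionary covariance R
    shrinkage: float  # gamma in [0, 1]
    log_lik: float
    cv_score: float
    n_species: int
    n_traits: int
    tree_height: float
    boundary: bool = False
    gic_value: Optional[float] = None

    @property
    def t_half(self) -> Optional[float]:
        """Phylogenetic half-life in the tree's time units (OU only)."""
        if self.model == "OU" and self.alpha and self.alpha > 0:
            return phylo_half_life(self.alpha, self.tree_height)
        return None


@dataclass
class ModelSupportSummary:
    """GIC support for each candidate model across a set of trees."""

    models: list[str]
    mean_gic: dict[str, float]
    sd2_gic: dict[str, float]  # 2 * SD of GIC
    percent_preferred: dict[str, float]
    n_trees: int
    mean_parameter: dict[str, float]
    failures: list[str]


@dataclass
class RateComparison:
    """Multivariate net rates of shape evolution per module, with a simulation test."""

    rates: dict[str, float]  # per-landmark-standardized sigma^2_mult per module
    observed_ratio: float
    p_value: float
    pairwise_p: "pd.DataFrame"
    n_sim: int


@dataclass
class DisparityResult:
    """Per-module Procrustes variance standardized by landmark count."""

    disparities: dict[str, float]
    pairwise_p: "pd.DataFrame"


# ---------------------------------------------------------------------------
# penalized-likelihood model fitting


def _helmert(n: int) -> np.ndarray:
    """(n-1) x n orthonormal contrast basis orthogonal to the ones vector."""
    m = np.zeros((n - 1, n))
    for i in range(1, n):
        m[i - 1, :i] = 1.0 / np.sqrt(i * (i + 1))
        m[i - 1, i] = -i / np.sqrt(i * (i + 1))
    return m


def _whiten(X: np.ndarray, C: np.ndarray, M: Optional[np.ndarray] = None) -> tuple[np.ndarray, float]:
    """Restricted (REML) whitening: project onto mean-orthogonal contrasts
    and whiten by the Cholesky factor of the projected species covariance.

    The restriction removes the root state from the likelihood, which
    avoids the upward small-sample bias in the evolutionary parameter that
    the profile (ML) likelihood carries.  Returns the (N-1) x q whitened
    rows (i.i.d. N(0, R) under the model) and log det of the projected C.
    """
    if M is None:
        M = _helmert(X.shape[0])
    Cc = M @ C @ M.T
    L = np.linalg.cholesky(Cc)
    Y = scipy.linalg.solve_triangular(L, M @ X, lower=True)
    logdet_c = 2.0 * float(np.log(np.diag(L)).sum())
    return Y, logdet_c


def _loo_cv_score(Y: np.ndarray, gamma: float, logdet_c: float) -> float:
    """Leave-one-row-out Gaussian predictive log-density under shrunk covariance."""
    n, q = Y.shape
    G = Y.T @ Y
    total = 0.0
    for i in range(n):
        yi = Y[i]
        S = (G - np.outer(yi, yi)) / (n - 1)
        R = (1.0 - gamma) * S + gamma * np.diag(np.diag(S))
        try:
            L = np.linalg.cholesky(R)
        except np.linalg.LinAlgError:
            return -np.inf
        u = scipy.linalg.solve_triangular(L, yi, lower=True)
        logdet_r = 2.0 * float(np.log(np.diag(L)).sum())
        total += -0.5 * (q * np.log(2 * np.pi) + logdet_r + float(u @ u))
    return total - 0.5 * q * logdet_c


def _penalized_loglik(Y: np.ndarray, gamma: float, logdet_c: float) -> tuple[float, np.ndarray]:
    n, q = Y.shape
    S = Y.T @ Y / n  # rows are zero-mean under the restricted likelihood
    R = (1.0 - gamma) * S + gamma * np.diag(np.diag(S))
    L = np.linalg.cholesky(R)
    logdet_r = 2.0 * float(np.log(np.diag(L)).sum())
    U = scipy.linalg.solve_triangular(L, Y.T, lower=True)
    quad = float((U ** 2).sum())
    ll = -0.5 * (n * q * np.log(2 * np.pi) + q * logdet_c + n * logdet_r + quad)
    return ll, R


def _parameter_grid(model: str, fixed: Optional[float]) -> np.ndarray:
    if fixed is not None:
        return np.array([float(fixed)])
    if model == "BM":
        return np.array([0.0])
    if model == "OU":
        return _ALPHA_GRID
    if model == "EB":
        return _EB_GRID
    raise ValueError(f"unknown model {model!r}")


def fit_trait_model(module_data: np.ndarray, tree: Phylogeny, model: str = "BM",
                    order: Optional[Sequence[str]] = None,
                    fixed_parameter: Optional[float] = None,
                    gamma_grid: Optional[np.ndarray] = None) -> TraitModelFit:
    """Fit one evolutionary model to an N x q trait block by penalized likelihood.

    For each candidate evolutionary parameter (alpha or r, per unit tree
    height) the data are projected onto mean-orthogonal contrasts
    (restricted likelihood, which removes the root state and its
    small-sample bias on the evolutionary parameter) and whitened by the
    model covariance; the trait covariance is shrunk linearly toward its
    diagonal and the pair (parameter, shrinkage) maximizing the
    leave-one-out cross-validated log-density over the whitened contrast
    rows is selected.  The reported ``log_lik`` is the penalized restricted
    maximum log-likelihood at the optimum.
    """
    model = model.upper()
    X = np.asarray(module_data, dtype=float)
    n, q = X.shape
    if n < 4:
        raise ValueError("need at least 4 species")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite trait values")
    if float(np.var(X, axis=0).max()) <= 0:
        raise ValueError("constant data: no trait variation to fit")
    order = list(order) if order is not None else tree.tip_labels
    tree.check_tips(order)
    if model == "OU" and not tree.is_ultrametric():
        raise ValueError("OU fitting requires an ultrametric tree")
    h = tree.height
    gammas = _GAMMA_GRID if gamma_grid is None else np.asarray(gamma_grid, dtype=float)
    thetas = _parameter_grid(model, fixed_parameter)

    M = _helmert(n)
    best = (-np.inf, None)  # (cv score, (theta, gamma, Y, logdet_c))
    for theta in thetas:
        C = species_covariance(tree, model, theta / h if model != "BM" else 0.0, order=order).matrix
        Y, logdet_c = _whiten(X, C, M)
        for gamma in gammas:
            score = _loo_cv_score(Y, gamma, logdet_c)
            if score > best[0]:
                best = (score, (theta, gamma, Y, logdet_c))
    if best[1] is None:
        raise RuntimeError("no admissible (parameter, shrinkage) combination")
    cv, (theta, gamma, Y, logdet_c) = best
    ll, R = _penalized_loglik(Y, gamma, logdet_c)
    boundary = bool(
        fixed_parameter is None and model != "BM" and thetas.size > 1
        and (theta == thetas[0] or theta == thetas[-1])
    )
    eig_min = float(np.linalg.eigvalsh(R).min())
    if eig_min < -1e-10 * np.trace(R):
        raise ValueError(f"shrunk trait covariance not PSD (min eigenvalue {eig_min:.3e})")
    return TraitModelFit(
        model=model,
        alpha=float(theta) if model == "OU" else None,
        r=float(theta) if model == "EB" else None,
        trait_cov=R, shrinkage=float(gamma), log_lik=ll, cv_score=cv,
        n_species=n, n_traits=q, tree_height=h, boundary=boundary,
    )


def gic(fit: TraitModelFit, n: Optional[int] = None) -> float:
    """Generalized information criterion: ``-2 log_lik + 2 df``.

    Effective degrees of freedom: evolutionary parameters (0 for BM, 1 for
    OU or EB) plus q root states plus the shrinkage-interpolated covariance
    count ``(1 - gamma) q(q+1)/2 + gamma q``.
    """
    q = fit.n_traits
    evo = 0 if fit.model == "BM" else 1
    df = evo + q + (1.0 - fit.shrinkage) * q * (q + 1) / 2 + fit.shrinkage * q
    val = -2.0 * fit.log_lik + 2.0 * df
    fit.gic_value = val
    return val


def phylo_half_life(alpha: float, height_myr: float) -> float:
    """Phylogenetic half-life ``t_1/2 = (ln 2 / alpha) * height`` in Myr.

    ``alpha`` is the OU rate of adaptation per unit tree height; the
    half-life is the expected time to evolve halfway from the ancestral
    state toward the optimum.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive (alpha = 0 collapses OU to BM)")
    if height_myr <= 0:
        raise ValueError("tree height must be positive")
    return np.log(2.0) / alpha * height_myr


def model_support_over_trees(module_data: np.ndarray, trees: Sequence[Phylogeny],
                             models: Sequence[str] = MODEL_ORDER,
                             order: Optional[Sequence[str]] = None) -> ModelSupportSummary:
    """Fit every model on every tree; summarize GIC and the preferred-model share.

    Ties in GIC resolve to the earlier model in the fixed order BM, EB, OU.
    A tree on which any fit fails is dropped with a recorded warning.
    """
    if not trees:
        raise ValueError("need at least one tree")
    models = [m.upper() for m in models]
    gics: dict[str, list[float]] = {m: [] for m in models}
    params: dict[str, list[float]] = {m: [] for m in models}
    prefer: dict[str, int] = {m: 0 for m in models}
    failures: list[str] = []
    used = 0
    for ti, tree in enumerate(trees):
        try:
            row = {}
            for m in models:
                fit = fit_trait_model(module_data, tree, m, order=order)
                row[m] = (gic(fit), fit)
        except (ValueError, RuntimeError, np.linalg.LinAlgError) as e:
            failures.append(f"tree {ti}: {e}")
            continue
        used += 1
        for m in models:
            gics[m].append(row[m][0])
            f = row[m][1]
            params[m].append(f.alpha if m == "OU" else (f.r if m == "EB" else 0.0))
        ordered = sorted(models, key=lambda m: MODEL_ORDER.index(m) if m in MODEL_ORDER else 99)
        winner = min(ordered, key=lambda m: (round(row[m][0], 9),))
        prefer[winner] += 1
    if used == 0:
        raise RuntimeError("all trees failed: " + "; ".join(failures))
    return ModelSupportSummary(
        models=models,
        mean_gic={m: float(np.mean(gics[m])) for m in models},
        sd2_gic={m: 2.0 * float(np.std(gics[m], ddof=1)) if used > 1 else 0.0 for m in models},
        percent_preferred={m: 100.0 * prefer[m] / used for m in models},
        n_trees=used,
        mean_parameter={m: float(np.mean(params[m])) for m in models},
        failures=failures,
    )


# ---------------------------------------------------------------------------
# rates and disparity


def _module_columns(partition: ModulePartition, landmark_labels: Sequence[str]) -> dict[str, np.ndarray]:
    idx = partition.module_indices(landmark_labels)
    return {
        m: np.concatenate([np.arange(3 * i, 3 * i + 3) for i in lms])
        for m, lms in idx.items()
    }


def _rates_from_whitened(Y: np.ndarray, cols: dict[str, np.ndarray],
                         n_lms: dict[str, int]) -> dict[str, float]:
    n = Y.shape[0]
    return {m: float((Y[:, c] ** 2).sum()) / (n * n_lms[m]) for m, c in cols.items()}


def multi_module_rates(shapes: AlignedShapes, partition: ModulePartition, tree: Phylogeny,
                       n_sim: int = 999, seed: int = 0) -> RateComparison:
    """Compare multivariate net rates of shape evolution (sigma^2_mult) among modules.

    Per module, the rate is the mean squared BM-whitened, root-centered
    deviation per landmark.  The observed max/min rate ratio is tested
    against ``n_sim`` BM simulations on the tree under a common-rate
    covariance: the observed evolutionary covariance rescaled so every
    module carries the pooled per-landmark rate.  Each simulated dataset
    is re-superimposed by GPA around the observed mean shape before rates
    are computed, so the null reproduces the Procrustes normalization the
    observed data went through (without it the test is anticonservative).
    Pairwise ratios are tested against the same simulations.  Observed
    statistics are included in their null sets.
    """
    tree.check_tips(shapes.specimen_labels)
    X = shapes.flat()
    order = list(shapes.specimen_labels)
    C = species_covariance(tree, "BM", order=order).matrix
    L = np.linalg.cholesky(C)
    cols = _module_columns(partition, shapes.landmark_labels)
    n_lms = {m: len(lms) for m, lms in partition.module_indices(shapes.landmark_labels).items()}
    mods = list(cols)
    n, tp = X.shape
    p_total = shapes.n_landmarks

    def whiten(Xd: np.ndarray) -> np.ndarray:
        ones = np.ones(n)
        Ci1 = scipy.linalg.cho_solve((L, True), ones)
        root = (Ci1 @ Xd) / (ones @ Ci1)
        return scipy.linalg.solve_triangular(L, Xd - root[None, :], lower=True)

    Y = whiten(X)
    rates = _rates_from_whitened(Y, cols, n_lms)
    vals = np.array([rates[m] for m in mods])
    obs_ratio = float(vals.max() / vals.min())

    # common-rate null covariance: observed R rescaled per module to the pooled rate
    pooled = float((Y ** 2).sum()) / (n * p_total)
    scale = np.ones(tp)
    for m in mods:
        scale[cols[m]] = np.sqrt(pooled / rates[m])
    R = (Y.T @ Y) / n
    R_null = scale[:, None] * R * scale[None, :]
    # tiny ridge keeps the factorization stable when q > n
    w, V = np.linalg.eigh(R_null)
    w = np.clip(w, 0.0, None)
    LR = V * np.sqrt(w)[None, :]

    rng = np.random.default_rng(seed)
    pair_list = list(combinations(mods, 2))
    obs_pair = {
        (a, b): max(rates[a], rates[b]) / min(rates[a], rates[b]) for a, b in pair_list
    }
    count = 1
    pair_count = {k: 1 for k in pair_list}
    from morphomod.procrustes import _gpa_arrays

    mean_config = shapes.symmetric.mean(axis=0)
    for _ in range(n_sim):
        Z = rng.standard_normal((n, tp))
        Xs = L @ (Z @ LR.T)
        # pass the simulated configurations through the same Procrustes
        # normalization as the observed data
        sim_configs = mean_config[None, :, :] + Xs.reshape(n, p_total, 3)
        aligned, _, _ = _gpa_arrays(sim_configs, 1e-8, 100)
        scale = np.sqrt((mean_config ** 2).sum())
        Xs = aligned.reshape(n, tp) * scale
        Ys = whiten(Xs)
        rs = _rates_from_whitened(Ys, cols, n_lms)
        v = np.array([rs[m] for m in mods])
        if v.max() / v.min() >= obs_ratio - 1e-12:
            count += 1
        for a, b in pair_list:
            rr = max(rs[a], rs[b]) / min(rs[a], rs[b])
            if rr >= obs_pair[(a, b)] - 1e-12:
                pair_count[(a, b)] += 1

    import pandas as pd

    pw = pd.DataFrame(np.nan, index=mods, columns=mods)
    for (a, b), c in pair_count.items():
        pw.loc[a, b] = pw.loc[b, a] = c / (n_sim + 1)
    return RateComparison(
        rates=rates, observed_ratio=obs_ratio, p_value=count / (n_sim + 1),
        pairwise_p=pw, n_sim=n_sim,
    )


def module_disparity(shapes: AlignedShapes, partition: ModulePartition) -> DisparityResult:
    """Per-module Procrustes variance standardized by landmark count.

    Disparity of module m is ``(sum_i ||x_im - mean_m||^2 / N) / p_m``.
    Per-species per-landmark-standardized squared deviations serve as
    replicate observations in a one-way comparison across modules with
    Tukey-HSD-adjusted pairwise p-values.
    """
    import pandas as pd
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if shapes.n_specimens < 3:
        raise ValueError("need at least 3 specimens")
    cols = _module_columns(partition, shapes.landmark_labels)
    n_lms = {m: len(lms) for m, lms in partition.module_indices(shapes.landmark_labels).items()}
    X = shapes.flat()
    dev = X - X.mean(axis=0, keepdims=True)
    n = X.shape[0]
    disparities = {}
    obs_values = []
    obs_groups = []
    for m, c in cols.items():
        per_spec = (dev[:, c] ** 2).sum(axis=1) / n_lms[m]
        disparities[m] = float(per_spec.sum() / n)
        obs_values.extend(per_spec.tolist())
        obs_groups.extend([m] * n)
    mods = list(cols)
    pw = pd.DataFrame(np.nan, index=mods, columns=mods)
    if float(np.ptp(obs_values)) > 0:
        tk = pairwise_tukeyhsd(np.array(obs_values), np.array(obs_groups))
        res = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        for _, row in res.iterrows():
            pw.loc[row["group1"], row["group2"]] = float(row["p-adj"])
            pw.loc[row["group2"], row["group1"]] = float(row["p-adj"])
    else:
        pw.loc[:, :] = 1.0
        np.fill_diagonal(pw.values, np.nan)
    return DisparityResult(disparities=disparities, pairwise_p=pw)
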