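"""Modularity statistics: covariance-ratio tests, landmark correlation
matrices, and maximum-likelihood correlation-model selection.

Two complementary routes are provided, each in a raw and a phylogenetically
corrected form:

* the covariance ratio (CR) — a ratio of between-module to within-module
  covariation, tested against a null of random landmark reassignment; CR
  significantly below the null supports modularity, and the effect size
  Z_CR (more negative = stronger modular signal) ranks hypotheses;
* likelihood model selection over correlation parameterization schemes:
  each scheme assigns one correlation coefficient rho per group of
  landmark pairs, is fitted by maximum likelihood in Fisher-z space, and
  schemes are compared by small-sample-corrected AIC with the number of
  landmark pairs as the sample size.

Phylogenetic correction replaces the specimen covariance with the
evolutionary covariance under Brownian motion (for CR) or builds the
correlation matrix from independent contrasts (for the likelihood route).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from morphomod.hypotheses import ModulePartition, ParameterizationScheme
from morphomod.phylo import Phylogeny, species_covariance, independent_contrasts, gls_root
from morphomod.procrustes import AlignedShapes


@dataclass
class CRResult:
    """Covariance-ratio permutation test for one modularity hypothesis."""

    hypothesis: str
    cr: float
    p_value: float
    z_cr: float
    null_distribution: np.ndarray
    corrected: bool
    n_perm: int
    warnings: list[str]


@dataclass
class LandmarkCorrelationMatrix:
    """P x P absolute vector-congruence correlations between landmarks."""

    matrix: np.ndarray
    landmark_labels: list[str]
    n_rows_used: int
    corrected: bool


@dataclass
class EMMLiModelFit:
    """One parameterization scheme's ML fit: rho estimates and AICc bookkeeping."""

    scheme_id: str
    rho_hat: dict[str, float]
    max_l: float
    k: int
    aicc: float
    delta_aicc: float
    weight: float
    n_eff: int


# ---------------------------------------------------------------------------
# covariance ratio


def _block_sums(cov: np.ndarray, n_landmarks: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-landmark-pair sums of squared covariances and per-landmark squared variances."""
    p = n_landmarks
    v2 = cov ** 2
    w = v2.reshape(p, 3, p, 3).sum(axis=(1, 3))
    dvec = np.diag(v2).reshape(p, 3).sum(axis=1)
    return w, dvec


def _cr_from_assignment(w: np.ndarray, dvec: np.ndarray, codes: np.ndarray, n_mod: int) -> float:
    """CR from landmark-block sums and an integer module assignment."""
    onehot = np.zeros((codes.size, n_mod))
    onehot[np.arange(codes.size), codes] = 1.0
    b = onehot.T @ w @ onehot  # (K, K) block sums of squared covariances
    d = onehot.T @ dvec  # per-module summed squared variances
    within = np.diag(b) - d
    crs = []
    for i, j in combinations(range(n_mod), 2):
        denom = within[i] * within[j]
        if denom <= 0:
            raise ValueError(
                "zero within-module off-diagonal covariance: CR denominator vanishes"
            )
        crs.append(np.sqrt(b[i, j] / np.sqrt(denom)))
    return float(np.mean(crs))


def covariance_ratio(cov: np.ndarray, partition: ModulePartition,
                     landmark_labels: Sequence[str]) -> float:
    """Covariance ratio of a 3P x 3P trait covariance under a module partition.

    For two modules ``CR = sqrt(||S12||_F^2 / sqrt(||S11*||_F^2 ||S22*||_F^2))``
    where S12 is the between-module covariance block and S11*, S22* are the
    within-module blocks with zeroed diagonals; for more than two modules
    the arithmetic mean of all pairwise CRs.
    """
    p = len(landmark_labels)
    if cov.shape != (3 * p, 3 * p):
        raise ValueError(f"covariance must be {3 * p}x{3 * p} for {p} landmarks")
    if partition.n_modules < 2:
        raise ValueError("CR requires at least 2 modules")
    assign = partition.assignment(landmark_labels)
    labels = partition.module_labels
    codes = np.array([labels.index(a) for a in assign])
    w, dvec = _block_sums(cov, p)
    return _cr_from_assignment(w, dvec, codes, partition.n_modules)


def evolutionary_covariance(X: np.ndarray, tree: Phylogeny, order: Sequence[str]) -> np.ndarray:
    """BM evolutionary covariance ``(X - 1 a')' C^-1 (X - 1 a') / (N - 1)``."""
    C = species_covariance(tree, "BM", order=order).matrix
    a = gls_root(tree, X, order=order, cov=C)
    R = X - a[None, :]
    Ci_R = np.linalg.solve(C, R)
    return R.T @ Ci_R / (X.shape[0] - 1)


def cr_permutation_test(shapes: AlignedShapes, partition: ModulePartition,
                        n_perm: int = 999, seed: int = 0,
                        tree: Optional[Phylogeny] = None) -> CRResult:
    """CR permutation test for one hypothesis, raw or phylogenetically corrected.

    The null reassigns whole landmarks (their three coordinates together) to
    modules at random, preserving module sizes.  The observed value is
    included in the null set: ``p = #(null CR <= observed) / (n_perm + 1)``.
    ``z_cr = (CR_obs - mean(null)) / sd(null)``.
    """
    warnings = []
    if n_perm < 99:
        warnings.append(f"n_perm={n_perm} is low; p-value resolution is {1 / (n_perm + 1):.3g}")
    X = shapes.flat()
    if X.shape[0] < 4:
        raise ValueError("need at least 4 specimens")
    if tree is not None:
        tree.check_tips(shapes.specimen_labels)
        cov = evolutionary_covariance(X, tree, shapes.specimen_labels)
    else:
        cov = np.cov(X, rowvar=False)

    p = shapes.n_landmarks
    assign = partition.assignment(shapes.landmark_labels)
    labels = partition.module_labels
    codes = np.array([labels.index(a) for a in assign])
    w, dvec = _block_sums(cov, p)
    obs = _cr_from_assignment(w, dvec, codes, partition.n_modules)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm + 1)
    null[0] = obs
    for b in range(n_perm):
        null[b + 1] = _cr_from_assignment(w, dvec, rng.permutation(codes), partition.n_modules)
    p_value = float(np.mean(null <= obs + 1e-12))
    sd = float(null.std(ddof=1))
    if sd <= 0:
        raise ValueError("degenerate permutation null (sd = 0): Z_CR undefined")
    z = (obs - float(null.mean())) / sd
    return CRResult(
        hypothesis=partition.name, cr=obs, p_value=p_value, z_cr=z,
        null_distribution=null, corrected=tree is not None, n_perm=n_perm,
        warnings=warnings,
    )


def compare_cr(results: Sequence[CRResult]) -> "pd.DataFrame":
    """Rank CR results by effect size and report pairwise Z differences.

    Hypotheses are ordered by Z_CR (most negative = strongest modular
    signal).  Pairwise differences ``z_i - z_j`` are compared by a
    two-sample normal approximation: each standardized null has unit
    spread, so ``p = 2 Phi(-|z_i - z_j| / sqrt(2))``.
    """
    import pandas as pd

    if len({r.corrected for r in results}) > 1:
        raise ValueError("cannot compare corrected with uncorrected CR results")
    if len({r.n_perm for r in results}) > 1:
        raise ValueError("cannot compare results with different n_perm")
    ordered = sorted(results, key=lambda r: r.z_cr)
    rows = []
    for i, ri in enumerate(ordered):
        for rj in ordered[i + 1:]:
            diff = ri.z_cr - rj.z_cr
            pval = 2 * norm.sf(abs(diff) / np.sqrt(2))
            rows.append((ri.hypothesis, rj.hypothesis, ri.z_cr, rj.z_cr, diff, pval))
    return pd.DataFrame(
        rows, columns=["hypothesis_1", "hypothesis_2", "z_1", "z_2", "z_diff", "p_value"]
    )


# ---------------------------------------------------------------------------
# landmark correlations and likelihood model selection


def landmark_correlations(shapes: AlignedShapes,
                          tree: Optional[Phylogeny] = None) -> LandmarkCorrelationMatrix:
    """Absolute vector-congruence correlation between every landmark pair.

    For landmarks l, m with per-specimen 3-vector deviations from the mean
    shape, ``r_lm = |sum_s d_ls . d_ms| / (||d_l|| ||d_m||)``.  With a tree,
    specimen deviations are replaced by independent contrasts of the 3P
    coordinate columns and the effective row count becomes N - 1.
    """
    if tree is None:
        if shapes.n_specimens < 5:
            raise ValueError("need at least 5 specimens")
        dev = shapes.symmetric - shapes.symmetric.mean(axis=0, keepdims=True)
        n_rows = shapes.n_specimens
    else:
        tree.check_tips(shapes.specimen_labels)
        contrasts = independent_contrasts(tree, shapes.flat(), order=shapes.specimen_labels)
        dev = contrasts.reshape(contrasts.shape[0], shapes.n_landmarks, 3)
        n_rows = shapes.n_specimens - 1
        if n_rows < 5:
            raise ValueError("need at least 6 specimens for corrected correlations")
    # G[l, m] = sum over rows and axes of d_l . d_m
    g = np.einsum("slk,smk->lm", dev, dev)
    diag = np.diag(g)
    zero = np.flatnonzero(diag <= 0)
    if zero.size:
        bad = [shapes.landmark_labels[i] for i in zero]
        raise ValueError(f"landmarks with zero total deviation: {bad}")
    r = np.abs(g) / np.sqrt(np.outer(diag, diag))
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, 0.0, 1.0)
    return LandmarkCorrelationMatrix(
        matrix=r, landmark_labels=list(shapes.landmark_labels),
        n_rows_used=n_rows, corrected=tree is not None,
    )


def aicc(max_l: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC: ``-2 MaxL + 2k + 2k(k+1)/(n-k-1)``."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n - k - 1 = {n - k - 1} <= 0")
    return -2.0 * max_l + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def emmli_fit(corr: LandmarkCorrelationMatrix, schemes: Sequence[ParameterizationScheme],
              n_eff: Optional[int] = None) -> list[EMMLiModelFit]:
    """Fit every parameterization scheme to a landmark correlation matrix by ML.

    Correlations are Fisher-z transformed; within each rho set the normal
    likelihood (sd ``1/sqrt(n_eff - 3)``) is maximized exactly by the
    z-space mean, so ``rho_hat = tanh(mean z)``.  Model size is one
    parameter per rho set plus one; AICc uses the number of unordered
    landmark pairs as the sample size.  Akaike weights are normalized over
    the scheme list passed in.
    """
    if n_eff is None:
        n_eff = corr.n_rows_used
    if n_eff < 5:
        raise ValueError("n_eff must be at least 5")
    labels = corr.landmark_labels
    pos = {lab: i for i, lab in enumerate(labels)}
    p = len(labels)
    n_pairs = p * (p - 1) // 2
    sd = 1.0 / np.sqrt(n_eff - 3)
    z = np.arctanh(np.clip(corr.matrix, 0.0, 1.0 - 1e-9))

    fits = []
    for scheme in schemes:
        scheme.check_covers_pairs(labels)
        max_l = 0.0
        rho_hat = {}
        for set_name, pairs in scheme.rho_sets.items():
            idx = np.array([(pos[a], pos[b]) for a, b in pairs])
            zs = z[idx[:, 0], idx[:, 1]]
            mu = float(zs.mean())
            rho_hat[set_name] = float(np.tanh(mu))
            max_l += float(norm.logpdf(zs, loc=mu, scale=sd).sum())
        k = scheme.k
        fits.append(EMMLiModelFit(
            scheme_id=scheme.scheme_id, rho_hat=rho_hat, max_l=max_l, k=k,
            aicc=aicc(max_l, k, n_pairs), delta_aicc=0.0, weight=0.0, n_eff=n_eff,
        ))

    best = min(f.aicc for f in fits)
    raw = []
    for f in fits:
        f.delta_aicc = f.aicc - best
        raw.append(np.exp(-0.5 * f.delta_aicc))
    total = sum(raw)
    for f, r in zip(fits, raw):
        f.weight = r / total
    return sorted(fits, key=lambda f: f.aicc)


def integration_report(best_fit: EMMLiModelFit,
                       corrected_fit: Optional[EMMLiModelFit] = None) -> "pd.DataFrame":
    """Tabulate within- and between-module rho estimates of the best model.

    If a phylogenetically corrected fit of the same scheme is supplied its
    estimates appear in a side-by-side column.
    """
    import pandas as pd

    def classify(name: str) -> tuple[str, str]:
        if name.startswith("within:"):
            return "within", name.split(":", 1)[1]
        if name.startswith("between:"):
            return "between", name.split(":", 1)[1].replace("|", " vs ")
        return ("within", name) if "within" in name else ("between", name)

    rows = []
    for set_name, rho in best_fit.rho_hat.items():
        kind, target = classify(set_name)
        row = {"type": kind, "modules": target, "rho": rho}
        if corrected_fit is not None:
            row["rho_corrected"] = corrected_fit.rho_hat.get(set_name, np.nan)
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(["type", "modules"], ascending=[False, True]).reset_index(drop=True)
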