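"""Generalized Procrustes superimposition, object-symmetry decomposition,
and the phylogenetic allometry check that gates any size correction.

Superimposition separates shape from position, size and orientation by
centering each configuration, scaling it to unit centroid size and rotating
it (proper rotations only) onto an iteratively re-estimated mean shape.
Object symmetry is removed by aligning each configuration jointly with its
mirrored, left/right-relabelled copy; the symmetric component (the average
of the two) is what all downstream modularity analyses consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from morphomod.io import LandmarkDataset, SymmetryPairing
from morphomod.phylo import Phylogeny, species_covariance
import scipy.linalg


@dataclass
class AlignedShapes:
    """Procrustes-aligned configurations split into symmetric and asymmetric parts.

    ``symmetric + asymmetric`` reconstructs each aligned configuration.  For
    output of :func:`gpa` before symmetry decomposition the asymmetric part
    is zero and ``symmetric`` holds the aligned coordinates.
    """

    specimen_labels: list[str]
    landmark_labels: list[str]
    symmetric: np.ndarray  # (S, P, 3)
    asymmetric: np.ndarray  # (S, P, 3)
    mean_shape: np.ndarray  # (P, 3)
    centroid_sizes: np.ndarray  # (S,)

    def __post_init__(self) -> None:
        cent = self.symmetric.mean(axis=1)
        if np.abs(cent).max() > 1e-6:
            raise ValueError("symmetric component must be centered at the origin")

    @property
    def n_specimens(self) -> int:
        return self.symmetric.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.symmetric.shape[1]

    def flat(self) -> np.ndarray:
        """Symmetric component as S x 3P with landmark-contiguous column blocks."""
        s, p, _ = self.symmetric.shape
        return self.symmetric.reshape(s, 3 * p)

    def to_dataset(self) -> LandmarkDataset:
        return LandmarkDataset(
            list(self.specimen_labels), list(self.landmark_labels),
            self.symmetric.copy(), aligned=True, centroid_sizes=self.centroid_sizes.copy(),
        )


@dataclass
class AllometryResult:
    """Phylogenetic regression of shape on log centroid size."""

    effect_fraction: float
    p_value: float
    n_permutations: int
    warnings: list[str]


def centroid_size(config: np.ndarray) -> float:
    """Square root of summed squared landmark distances from the centroid."""
    c = config - config.mean(axis=0)
    return float(np.sqrt((c ** 2).sum()))


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation (det +1) minimizing ||source R - target||_F (Kabsch)."""
    u, _, vt = np.linalg.svd(source.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def _gpa_arrays(coords: np.ndarray, tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Core GPA on an (S, P, 3) stack; returns aligned stack, mean shape, centroid sizes."""
    s = coords.shape[0]
    cs = np.empty(s)
    work = np.empty_like(coords, dtype=float)
    for i in range(s):
        c = coords[i] - coords[i].mean(axis=0)
        size = np.sqrt((c ** 2).sum())
        if size <= 0:
            raise ValueError(f"degenerate (all-coincident) configuration at index {i}")
        cs[i] = size
        work[i] = c / size
    for i in range(s):
        if np.linalg.matrix_rank(work[i]) < 2:
            raise ValueError(f"rank-deficient configuration at index {i}")

    if s == 1:
        return work, work[0].copy(), cs

    mean = work[0].copy()
    for _ in range(max_iter):
        for i in range(s):
            work[i] = work[i] @ _optimal_rotation(work[i], mean)
        new_mean = work.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        size = np.sqrt((new_mean ** 2).sum())
        if size <= 0:
            raise ValueError("degenerate mean shape")
        new_mean /= size
        # anchor orientation to the previous mean: without this the mean can
        # drift rotationally and the iteration never meets a tight tolerance
        new_mean = new_mean @ _optimal_rotation(new_mean, mean)
        delta = np.sqrt(((new_mean - mean) ** 2).sum())
        mean = new_mean
        if delta < tol:
            break
    else:
        raise RuntimeError(f"GPA did not converge in {max_iter} iterations (last delta {delta:.3e})")

    # canonical orientation: principal axes of the mean shape with a
    # deterministic sign rule, so the output does not depend on the input's
    # arbitrary orientation
    _, vecs = np.linalg.eigh(mean.T @ mean)
    rot = vecs[:, ::-1]  # descending variance
    for k in range(3):
        if rot[np.argmax(np.abs(rot[:, k])), k] < 0:
            rot[:, k] *= -1
    if np.linalg.det(rot) < 0:
        rot[:, 2] *= -1
    mean = mean @ rot
    work = work @ rot
    return work, mean, cs


def gpa(dataset: LandmarkDataset, tol: float = 1e-10, max_iter: int = 1000) -> AlignedShapes:
    """Generalized Procrustes superimposition of a landmark dataset.

    Each configuration is centered, scaled to unit centroid size, and
    rotated (reflections excluded) onto the running mean, which is itself
    re-centered and rescaled to unit size each iteration; iteration stops
    when the mean shape moves by less than ``tol``.
    """
    aligned, mean, cs = _gpa_arrays(dataset.coords, tol, max_iter)
    return AlignedShapes(
        specimen_labels=list(dataset.specimen_labels),
        landmark_labels=list(dataset.landmark_labels),
        symmetric=aligned,
        asymmetric=np.zeros_like(aligned),
        mean_shape=mean,
        centroid_sizes=cs,
    )


def symmetry_decompose(dataset: LandmarkDataset, pairing: SymmetryPairing,
                       mirror_axis: int = 1, tol: float = 1e-10, max_iter: int = 1000) -> AlignedShapes:
    """Object-symmetry decomposition of bilaterally symmetric configurations.

    For every specimen a mirrored copy is built by negating the
    ``mirror_axis`` coordinate and swapping each left landmark with its
    right partner (midline landmarks stay in place).  A joint GPA over the
    originals and their mirrored copies aligns all 2S configurations; the
    symmetric component of a specimen is the average of its two aligned
    copies and the asymmetric component the remainder.
    """
    pairing.validate(dataset.landmark_labels)
    perm = pairing.swap_indices(dataset.landmark_labels)
    s = dataset.n_specimens
    mirrored = dataset.coords[:, perm, :].copy()
    mirrored[:, :, mirror_axis] *= -1.0
    stack = np.concatenate([dataset.coords, mirrored], axis=0)
    aligned, mean, cs = _gpa_arrays(stack, tol, max_iter)
    orig, refl = aligned[:s], aligned[s:]
    symmetric = 0.5 * (orig + refl)
    # re-center: averaging preserves centering, this guards rounding only
    symmetric -= symmetric.mean(axis=1, keepdims=True)
    asymmetric = orig - symmetric
    return AlignedShapes(
        specimen_labels=list(dataset.specimen_labels),
        landmark_labels=list(dataset.landmark_labels),
        symmetric=symmetric,
        asymmetric=asymmetric,
        mean_shape=mean,
        centroid_sizes=cs[:s],
    )


def phylo_allometry_test(shapes: AlignedShapes, tree: Phylogeny, n_perm: int = 999,
                         seed: int = 0) -> AllometryResult:
    """Phylogenetic regression of shape on log centroid size with a permutation test.

    Shape (the 3P-column symmetric component) is regressed on log centroid
    size by generalized least squares under a Brownian-motion species
    covariance; significance uses randomized residual permutation of the
    reduced (intercept-only) model, with the observed statistic included in
    the null set, so the attainable minimum p is ``1/(n_perm + 1)``.
    """
    warnings = []
    if n_perm < 99:
        warnings.append(f"n_perm={n_perm} is low; p-value resolution is {1 / (n_perm + 1):.3g}")
    tree.check_tips(shapes.specimen_labels)
    order = list(shapes.specimen_labels)
    C = species_covariance(tree, "BM", order=order).matrix
    L = np.linalg.cholesky(C)
    # GLS via whitening: solve L U = data
    Y = scipy.linalg.solve_triangular(L, shapes.flat(), lower=True)
    x = np.log(shapes.centroid_sizes)
    Xf = scipy.linalg.solve_triangular(L, np.column_stack([np.ones_like(x), x]), lower=True)
    Xr = Xf[:, :1]

    def r2(Xd: np.ndarray, Yd: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        beta, *_ = np.linalg.lstsq(Xd, Yd, rcond=None)
        fitted = Xd @ beta
        resid = Yd - fitted
        return float((fitted ** 2).sum()), fitted, resid

    # reduced model: intercept only
    _, fit_r, resid_r = r2(Xr, Y)
    ss_tot = float(((Y - fit_r) ** 2).sum())
    beta_f, *_ = np.linalg.lstsq(Xf, Y, rcond=None)
    resid_f = Y - Xf @ beta_f
    ss_full = float((resid_f ** 2).sum())
    ss_effect = ss_tot - ss_full
    obs = ss_effect / ss_tot if ss_tot > 0 else 0.0

    rng = np.random.default_rng(seed)
    count = 1  # observed included
    n = Y.shape[0]
    for _ in range(n_perm):
        idx = rng.permutation(n)
        Yp = fit_r + resid_r[idx]
        ss_tot_p = float(((Yp - Xr @ np.linalg.lstsq(Xr, Yp, rcond=None)[0]) ** 2).sum())
        bf, *_ = np.linalg.lstsq(Xf, Yp, rcond=None)
        ss_full_p = float(((Yp - Xf @ bf) ** 2).sum())
        stat = (ss_tot_p - ss_full_p) / ss_tot_p if ss_tot_p > 0 else 0.0
        if stat >= obs - 1e-12:
            count += 1
    return AllometryResult(
        effect_fraction=obs,
        p_value=count / (n_perm + 1),
        n_permutations=n_perm,
        warnings=warnings,
    )
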