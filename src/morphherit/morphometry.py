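"""Geometric morphometrics: superimposition, symmetry, ordination, tests.

The phenotype pipeline implemented here takes raw 2-D landmark
configurations to symmetric shape variables:

1. :func:`gpa` — Generalized Procrustes Analysis (partial fitting: centering,
   unit centroid size, iterative optimal rotation to the consensus), with
   optional sliding of semilandmarks along their curve chords to minimize
   thin-plate-spline bending energy, and orthogonal tangent-space projection
   of the final coordinates.
2. :func:`symmetric_component` — object-symmetry averaging: each
   configuration is averaged with its reflected, pair-relabeled copy,
   removing all asymmetric variation.  The output shapes are exactly
   bilaterally symmetric about the second (y) coordinate axis.
3. :func:`shape_pca` — principal components of the aligned coordinates; the
   retained scores are the shape variables passed to the quantitative
   genetics stage.
4. :func:`procrustes_anova` — (M)ANOVA with significance from residual
   permutation, used for sexual-dimorphism checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import minimize_scalar

from .scheme import LandmarkScheme
from .tps import Configuration

__all__ = [
    "AlignedShapes",
    "ShapeSpace",
    "PermTestResult",
    "GPAConvergenceError",
    "centroid_size",
    "gpa",
    "symmetric_component",
    "shape_pca",
    "procrustes_anova",
    "bending_energy_matrix",
]

log = logging.getLogger(__name__)


class GPAConvergenceError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------
@dataclass
class AlignedShapes:
    """Procrustes-superimposed coordinates.

    ``shapes`` is ``(n, 2k)`` with rows flattened ``[x1, y1, x2, y2, ...]``;
    ``centroid_sizes`` keeps the original (pre-scaling) centroid sizes;
    ``consensus`` is the arithmetic mean of the aligned shapes.  When the
    shapes were tangent-projected (``projected=True``) the aligned centroid
    sizes deviate from 1 by O(shape variance); without projection they are
    exactly 1.
    """

    shapes: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    specimen_ids: list[str]
    projected: bool = True
    ss_history: list[float] = field(default_factory=list)

    @property
    def n_specimens(self) -> int:
        return self.shapes.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.shapes.shape[1] // 2

    def as_landmarks(self) -> np.ndarray:
        """Shapes as an ``(n, k, 2)`` array."""
        return self.shapes.reshape(self.n_specimens, -1, 2)

    def to_dataframe(self):
        import pandas as pd

        k = self.n_landmarks
        cols = [f"{ax}{i + 1}" for i in range(k) for ax in ("x", "y")]
        df = pd.DataFrame(self.shapes, columns=cols)
        df.insert(0, "specimen_id", self.specimen_ids)
        df["centroid_size"] = self.centroid_sizes
        return df


@dataclass
class ShapeSpace:
    """PCA of aligned shapes: eigenvalues, orthonormal loadings, scores."""

    eigenvalues: np.ndarray          # full descending nonnegative spectrum
    loadings: np.ndarray             # (2k, n_retained), orthonormal columns
    scores: np.ndarray               # (n, n_retained)
    consensus: np.ndarray            # (2k,)
    n_retained: int
    rank: int

    @property
    def variance_fractions(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total

    @property
    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.variance_fractions)

    def project(self, shapes: np.ndarray) -> np.ndarray:
        """Project (centered) shape rows onto the retained loadings."""
        shapes = np.atleast_2d(np.asarray(shapes, dtype=float))
        return (shapes - self.consensus) @ self.loadings

    def back_project(self, vector: np.ndarray) -> np.ndarray:
        """Map a score-space vector back to a landmark displacement field."""
        vector = np.asarray(vector, dtype=float)
        if vector.shape[-1] != self.n_retained:
            raise ValueError(
                f"vector length {vector.shape[-1]} != retained components "
                f"{self.n_retained}"
            )
        return vector @ self.loadings.T

    def to_dataframe(self):
        import pandas as pd

        frac = self.variance_fractions
        return pd.DataFrame(
            {
                "component": np.arange(1, len(self.eigenvalues) + 1),
                "eigenvalue": self.eigenvalues,
                "proportion": frac,
                "cumulative": np.cumsum(frac),
            }
        )


@dataclass
class PermTestResult:
    """Permutation (M)ANOVA outcome."""

    statistic: float      # observed F ratio
    effect_size: float    # Z score of F against its permutation distribution
    p_value: float
    n_permutations: int


# --------------------------------------------------------------------------
# basic geometry
# --------------------------------------------------------------------------
def centroid_size(config: Union[Configuration, np.ndarray]) -> float:
    """Centroid size: sqrt of summed squared landmark distances from centroid."""
    coords = config.coords if isinstance(config, Configuration) else np.asarray(config, float)
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs <= 0.0 or not np.isfinite(cs):
        raise ValueError("degenerate configuration: all landmarks coincide")
    return cs


def _optimal_rotations(X: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Batched 2-D proper rotations minimizing ||X_i R_i - ref||^2.

    X is (n, k, 2); returns rotated copies.  Closed form: with
    H = X_i^T ref, the optimal angle has cos ~ (H00+H11), sin ~ (H10-H01).
    """
    H = np.einsum("nkx,ky->nxy", X, ref)
    a = H[:, 0, 0] + H[:, 1, 1]
    b = H[:, 1, 0] - H[:, 0, 1]
    r = np.hypot(a, b)
    r = np.where(r == 0.0, 1.0, r)
    c, s = a / r, b / r
    R = np.empty((X.shape[0], 2, 2))
    R[:, 0, 0] = c
    R[:, 0, 1] = -s
    R[:, 1, 0] = s
    R[:, 1, 1] = c
    return np.einsum("nkx,nxy->nky", X, R)


def bending_energy_matrix(ref: np.ndarray) -> np.ndarray:
    """Thin-plate-spline bending-energy matrix of a reference configuration.

    Returns the k x k matrix B such that the bending energy of a target
    configuration T (relative to ``ref``) is ``sum_dim T_dim^T B T_dim``;
    affine displacements have zero energy.
    """
    ref = np.asarray(ref, dtype=float)
    k = ref.shape[0]
    d2 = ((ref[:, None, :] - ref[None, :, :]) ** 2).sum(-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(d2 > 0.0, d2 * np.log(d2), 0.0)
    Q = np.column_stack([np.ones(k), ref])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    Li = np.linalg.pinv(L)
    B = Li[:k, :k]
    return (B + B.T) / 2.0


def _slide_semilandmarks(
    X: np.ndarray, consensus: np.ndarray, scheme: LandmarkScheme
) -> np.ndarray:
    """Slide each specimen's semilandmarks along its neighbor chords.

    Minimizes the bending energy of the specimen relative to the consensus;
    displacement of semilandmark j is restricted to the unit chord between
    its two scheme neighbors (measured on the specimen itself).
    """
    sem = scheme.semilandmarks0
    s_idx, b_idx, a_idx = sem[:, 0], sem[:, 1], sem[:, 2]
    B = bending_energy_matrix(consensus)
    U = X[:, a_idx, :] - X[:, b_idx, :]
    norms = np.linalg.norm(U, axis=2, keepdims=True)
    norms = np.where(norms == 0.0, 1.0, norms)
    U = U / norms
    # H_n = B[sem, sem] o (U_n U_n^T); rhs_n = -sum_d U_n o (B X_n)[sem]
    Bss = B[np.ix_(s_idx, s_idx)]
    H = Bss[None, :, :] * np.einsum("nmd,npd->nmp", U, U)
    BX = np.einsum("kl,nld->nkd", B, X)
    rhs = -np.einsum("nmd,nmd->nm", U, BX[:, s_idx, :])
    m = len(s_idx)
    ridge = 1e-12 * np.trace(Bss) / m
    H = H + ridge * np.eye(m)[None, :, :]
    t = np.linalg.solve(H, rhs[..., None])[..., 0]
    Xs = X.copy()
    Xs[:, s_idx, :] += t[:, :, None] * U
    return Xs


# --------------------------------------------------------------------------
# Generalized Procrustes Analysis
# --------------------------------------------------------------------------
def _align_loop(X, tol, max_iter, ss_history):
    """Iterate rotation-to-consensus / consensus update until convergence.

    X (n, k, 2) must be centered with unit centroid size.  Returns
    (X_aligned, unit-norm consensus).
    """
    n = X.shape[0]
    consensus = X[0].copy()
    delta = np.inf
    for _ in range(max_iter):
        X = _optimal_rotations(X, consensus)
        mean = X.mean(axis=0)
        # residual sum of squares about the (unnormalized) mean
        ss_history.append(float(n * (1.0 - (mean**2).sum())))
        new_consensus = mean - mean.mean(axis=0)
        new_consensus /= np.linalg.norm(new_consensus)
        delta = float(np.sqrt(((new_consensus - consensus) ** 2).mean()))
        consensus = new_consensus
        if delta < tol:
            return X, consensus
    raise GPAConvergenceError(
        f"GPA did not converge in {max_iter} iterations (last consensus RMS "
        f"change {delta:.3e})"
    )


def _canonical_rotation(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation putting the consensus in a canonical orientation.

    The consensus' major principal axis is mapped to the y axis, and the
    half-turn ambiguity is resolved by requiring the landmark farthest
    from the centroid to have positive y (positive x as a tie-break).
    Makes GPA output invariant to arbitrary per-specimen input rotations.
    """
    M = consensus.T @ consensus
    _, V = np.linalg.eigh(M)  # ascending: columns = (minor, major) axes
    R = V.copy()
    if np.linalg.det(R) < 0:
        R[:, 0] = -R[:, 0]
    c2 = consensus @ R
    im = int(np.argmax((c2**2).sum(axis=1)))
    scale = np.linalg.norm(c2)
    if c2[im, 1] < -1e-8 * scale or (
        abs(c2[im, 1]) <= 1e-8 * scale and c2[im, 0] < 0
    ):
        R = -R  # rotate by pi
    return R


def _tangent_project(X: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Orthogonal projection onto the tangent plane at the unit consensus."""
    c = consensus.reshape(-1)
    flat = X.reshape(X.shape[0], -1)
    coef = 1.0 - flat @ c
    return (flat + coef[:, None] * c[None, :]).reshape(X.shape)


def gpa(
    configs: Sequence[Union[Configuration, np.ndarray]],
    scheme: Optional[LandmarkScheme] = None,
    slide: bool = False,
    project: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
    slide_cycles: int = 5,
    slide_tol: float = 1e-8,
) -> AlignedShapes:
    """Generalized Procrustes Analysis with optional semilandmark sliding.

    Each configuration is centered, scaled to unit centroid size and
    iteratively rotated to the running consensus (partial Procrustes
    fitting).  With ``slide=True`` and a scheme declaring semilandmarks,
    alignment alternates with bending-energy sliding against the consensus
    until the consensus stabilizes.  With ``project=True`` (default) the
    final coordinates are orthogonally projected onto the tangent plane at
    the consensus.
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    ids = []
    mats = []
    for i, cfg in enumerate(configs):
        if isinstance(cfg, Configuration):
            ids.append(cfg.specimen_id)
            mats.append(np.asarray(cfg.coords, dtype=float))
        else:
            ids.append(str(i + 1))
            mats.append(np.asarray(cfg, dtype=float))
    k = mats[0].shape[0]
    if any(m.shape != (k, 2) for m in mats):
        raise ValueError("all configurations must share the same landmark count")
    if scheme is not None and k != scheme.n_landmarks:
        raise ValueError(
            f"configurations have {k} landmarks, scheme expects {scheme.n_landmarks}"
        )
    X = np.stack(mats)
    X = X - X.mean(axis=1, keepdims=True)
    cs = np.sqrt((X**2).sum(axis=(1, 2)))
    if np.any(cs <= 0) or not np.all(np.isfinite(cs)):
        bad = ids[int(np.argmin(cs))]
        raise ValueError(f"degenerate configuration with zero centroid size: {bad!r}")
    X = X / cs[:, None, None]

    ss_history: list[float] = []
    X, consensus = _align_loop(X, tol, max_iter, ss_history)

    do_slide = slide and scheme is not None and len(scheme.semilandmarks) > 0
    if slide and (scheme is None or len(scheme.semilandmarks) == 0):
        log.warning("slide=True but no semilandmarks declared; skipping sliding")
    if do_slide:
        for _ in range(slide_cycles):
            prev = consensus
            X = _slide_semilandmarks(X, consensus, scheme)
            X = X - X.mean(axis=1, keepdims=True)
            X = X / np.sqrt((X**2).sum(axis=(1, 2)))[:, None, None]
            X, consensus = _align_loop(X, tol, max_iter, ss_history)
            change = float(np.sqrt(((consensus - prev) ** 2).mean()))
            if change < slide_tol:
                break

    R = _canonical_rotation(consensus)
    X = X @ R
    consensus = consensus @ R
    if project:
        X = _tangent_project(X, consensus)
    flat = X.reshape(len(mats), -1)
    return AlignedShapes(
        shapes=flat,
        centroid_sizes=cs,
        consensus=flat.mean(axis=0),
        specimen_ids=ids,
        projected=project,
        ss_history=ss_history,
    )


# --------------------------------------------------------------------------
# object symmetry
# --------------------------------------------------------------------------
def _reflect_relabel(X: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Mirror the first coordinate axis and swap left/right landmark labels."""
    XR = X[..., perm, :].copy()
    XR[..., 0] = -XR[..., 0]
    return XR


def _asymmetry(X: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Squared distance of configurations from the y-axis-symmetric subspace."""
    R = _reflect_relabel(X, perm)
    return 0.25 * ((X - R) ** 2).sum(axis=tuple(range(1, X.ndim)))


def _axis_align_rotation(consensus: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Rotation making the consensus midline coincide with the y axis.

    Chosen by least squares: the angle minimizing the distance of the
    rotated consensus from the exactly symmetric subspace.
    """

    def objective(theta: float) -> float:
        c, s = np.cos(theta), np.sin(theta)
        R = np.array([[c, -s], [s, c]])
        return float(_asymmetry((consensus @ R)[None], perm)[0])

    thetas = np.linspace(0.0, 2 * np.pi, 721)
    vals = [objective(t) for t in thetas]
    t0 = thetas[int(np.argmin(vals))]
    res = minimize_scalar(
        objective, bounds=(t0 - 0.02, t0 + 0.02), method="bounded",
        options={"xatol": 1e-14},
    )
    theta = float(res.x)
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def symmetric_component(
    aligned: AlignedShapes,
    scheme: LandmarkScheme,
    project: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedShapes:
    """Object-symmetry averaging of aligned shapes.

    Reflected, pair-relabeled copies are superimposed together with the
    originals; each specimen's symmetric shape is the average of its aligned
    original and aligned reflected copy, after rotating the joint consensus
    so that its midline lies on the y axis.  The averages are then projected
    exactly onto the symmetric subspace and re-superimposed, so every output
    shape is exactly bilaterally symmetric about the y axis.
    """
    if not scheme.pairs:
        raise ValueError("scheme declares no bilateral pairs; symmetry undefined")
    perm = scheme.reflection_permutation()
    X = aligned.as_landmarks()
    n = X.shape[0]
    both = np.concatenate([X, _reflect_relabel(X, perm)], axis=0)
    both = both - both.mean(axis=1, keepdims=True)
    both = both / np.sqrt((both**2).sum(axis=(1, 2)))[:, None, None]
    ss: list[float] = []
    both, consensus = _align_loop(both, tol, max_iter, ss)
    R = _axis_align_rotation(consensus, perm)
    cR = consensus @ R
    im = int(np.argmax((cR**2).sum(axis=1)))
    if cR[im, 1] < 0:  # resolve the half-turn ambiguity of the axis fit
        R = -R
    both = both @ R
    sym = 0.5 * (both[:n] + both[n:])
    # exact projection onto the symmetric subspace (idempotent average with
    # the reflected-relabeled copy about the now-aligned axis)
    sym = 0.5 * (sym + _reflect_relabel(sym, perm))
    sym = sym - sym.mean(axis=1, keepdims=True)
    sym = sym / np.sqrt((sym**2).sum(axis=(1, 2)))[:, None, None]
    sym, consensus = _align_loop(sym, tol, max_iter, ss)
    if project:
        sym = _tangent_project(sym, consensus)
    flat = sym.reshape(n, -1)
    return AlignedShapes(
        shapes=flat,
        centroid_sizes=aligned.centroid_sizes.copy(),
        consensus=flat.mean(axis=0),
        specimen_ids=list(aligned.specimen_ids),
        projected=project,
        ss_history=ss,
    )


# --------------------------------------------------------------------------
# principal components
# --------------------------------------------------------------------------
def shape_pca(aligned: AlignedShapes, n_retained: Optional[int] = None) -> ShapeSpace:
    """PCA of the variance-covariance matrix of aligned coordinates.

    Eigenvalues are those of the sample covariance (``n - 1`` denominator);
    eigenvector signs are fixed so the largest-magnitude element is
    positive.  ``n_retained`` defaults to the positive-eigenvalue rank and
    may not exceed it.
    """
    shapes = aligned.shapes if isinstance(aligned, AlignedShapes) else np.asarray(aligned)
    mean = shapes.mean(axis=0)
    Xc = shapes - mean
    n = Xc.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 specimens")
    cov = (Xc.T @ Xc) / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    rank = int(np.sum(evals > 1e-10 * max(evals[0], 0.0))) if evals[0] > 0 else 0
    if n_retained is None:
        n_retained = rank
    if n_retained < 1:
        raise ValueError("n_retained must be >= 1")
    if n_retained > rank:
        raise ValueError(
            f"n_retained={n_retained} exceeds the positive-eigenvalue rank {rank}"
        )
    evals = np.clip(evals, 0.0, None)
    load = evecs[:, :n_retained].copy()
    flip = load[np.abs(load).argmax(axis=0), np.arange(n_retained)] < 0
    load[:, flip] *= -1.0
    scores = Xc @ load
    return ShapeSpace(
        eigenvalues=evals,
        loadings=load,
        scores=scores,
        consensus=mean,
        n_retained=int(n_retained),
        rank=rank,
    )


# --------------------------------------------------------------------------
# permutation (M)ANOVA
# --------------------------------------------------------------------------
def procrustes_anova(
    response,
    groups,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermTestResult:
    """(M)ANOVA with residual-permutation significance.

    ``F = (SS_model/df_model) / (SS_resid/df_resid)`` where sums of squares
    are summed squared distances (multivariate response) or squared
    deviations (scalar).  The null distribution permutes the residuals of
    the intercept-only model (equivalently, response rows) ``n_perm`` times
    with the given seed; ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
    """
    if isinstance(response, ShapeSpace):
        Y = response.scores
    else:
        Y = np.asarray(response, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels, codes = np.unique(np.asarray(groups), return_inverse=True)
    g = len(labels)
    n = Y.shape[0]
    if codes.shape[0] != n:
        raise ValueError("groups length does not match response rows")
    counts = np.bincount(codes, minlength=g).astype(float)
    if g < 2:
        raise ValueError("need at least 2 groups")
    if np.any(counts < 2):
        small = labels[np.argmin(counts)]
        raise ValueError(f"group {small!r} has fewer than 2 members")
    Yc = Y - Y.mean(axis=0)
    sst = float((Yc**2).sum())
    if sst <= 0.0:
        raise ValueError("constant response: no variance to partition")
    onehot = np.zeros((n, g))
    onehot[np.arange(n), codes] = 1.0
    df_model = g - 1
    df_resid = n - g

    def f_stat(Ymat: np.ndarray) -> np.ndarray:
        # Ymat: (..., n, q), grand-centered
        sums = np.einsum("...nq,ng->...gq", Ymat, onehot)
        ssb = ((sums**2) / counts[:, None]).sum(axis=(-2, -1))
        ssw = sst - ssb
        with np.errstate(divide="ignore", invalid="ignore"):
            return (ssb / df_model) / (ssw / df_resid)

    f_obs = float(f_stat(Yc))
    rng = np.random.default_rng(seed)
    # permute in manageable blocks to bound memory
    f_perm = np.empty(n_perm)
    block = max(1, int(2_000_000 / (n * Y.shape[1] + 1)))
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        idx = np.argsort(rng.random((b, n)), axis=1)
        f_perm[done : done + b] = f_stat(Yc[idx])
        done += b
    n_ge = int(np.sum(f_perm >= f_obs))
    p = (1.0 + n_ge) / (1.0 + n_perm)
    sd = float(f_perm.std())
    z = (f_obs - float(f_perm.mean())) / sd if sd > 0 else np.inf
    return PermTestResult(
        statistic=f_obs, effect_size=z, p_value=p, n_permutations=n_perm
    )
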