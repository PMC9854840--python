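"""Independent oracles used by the test suite.

Each function re-derives a quantity by a route deliberately different from
the package implementation: dense grid search over rotations for the
Procrustes consensus, allele gene-dropping for the relationship matrix,
explicit Kronecker assembly for the restricted likelihood, and a
hand-coded SVD pseudoinverse.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from morphherit.pedigree import Pedigree, relationship_matrix


# --------------------------------------------------------------------------
# GPA oracle: brute-force rotation search
# --------------------------------------------------------------------------
def _rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def grid_gpa(shapes: list[np.ndarray], n_grid: int = 720):
    """Minimize sum_i ||x_i R_i - mean||^2 over rotations by dense grid +
    local refinement.

    Shapes are centered and scaled to unit centroid size; the first shape's
    rotation is fixed (rotation gauge).  Returns (aligned shapes, consensus,
    objective value).
    """
    X = []
    for m in shapes:
        m = np.asarray(m, float)
        m = m - m.mean(axis=0)
        X.append(m / np.sqrt((m**2).sum()))
    k = len(X)

    def apply(thetas):
        return [X[0]] + [X[i + 1] @ _rot(t) for i, t in enumerate(thetas)]

    def objective(thetas):
        rotated = apply(thetas)
        mean = sum(rotated) / k
        return float(sum(((r - mean) ** 2).sum() for r in rotated))

    grid = np.linspace(0.0, 2 * np.pi, n_grid, endpoint=False)
    best, best_val = None, np.inf
    if k == 2:
        for t1 in grid:
            v = objective([t1])
            if v < best_val:
                best, best_val = [t1], v
    elif k == 3:
        for t1 in grid:
            for t2 in grid:
                v = objective([t1, t2])
                if v < best_val:
                    best, best_val = [t1, t2], v
    else:
        raise ValueError("grid oracle supports 2 or 3 shapes")
    res = minimize(objective, best, method="Nelder-Mead",
                   options={"xatol": 1e-14, "fatol": 1e-16, "maxiter": 5000})
    best = list(res.x)
    # coordinate-wise grid zoom to refine the angles far beyond the
    # objective's rounding plateau (the objective is locally quadratic)
    for width in (1e-2, 1e-4, 1e-6, 1e-8, 1e-10):
        for _ in range(2):
            for i in range(len(best)):
                local = best[i] + np.linspace(-width, width, 81)
                vals = []
                for t in local:
                    trial = list(best)
                    trial[i] = t
                    vals.append(objective(trial))
                best[i] = local[int(np.argmin(vals))]
    rotated = apply(best)
    mean = sum(rotated) / k
    return rotated, mean, objective(best)


# --------------------------------------------------------------------------
# relationship-matrix oracle: gene dropping
# --------------------------------------------------------------------------
def gene_drop_A(ped: Pedigree, n_rep: int = 200_000, seed: int = 0):
    """Monte-Carlo estimate of A (= 2 x kinship) by dropping alleles.

    Each founder receives two unique alleles; every non-founder inherits
    one random allele from each known parent (a fresh unique allele when a
    parent is unknown).  Returns (A_hat, standard errors) computed from the
    per-replicate identity indicators.
    """
    rng = np.random.default_rng(seed)
    n = len(ped)
    alleles = np.empty((n_rep, n, 2), dtype=np.int32)
    rows = np.arange(n_rep)
    for i in range(n):
        d, s = ped.dam_idx[i], ped.sire_idx[i]
        if d >= 0:
            pick = rng.integers(0, 2, n_rep)
            alleles[:, i, 0] = alleles[rows, d, pick]
        else:
            alleles[:, i, 0] = 2 * i
        if s >= 0:
            pick = rng.integers(0, 2, n_rep)
            alleles[:, i, 1] = alleles[rows, s, pick]
        else:
            alleles[:, i, 1] = 2 * i + 1
    A_hat = np.zeros((n, n))
    A_se = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            eq = (
                (alleles[:, i, :, None] == alleles[:, j, None, :])
                .sum(axis=(1, 2))
                .astype(float)
            )
            stat = 0.5 * eq  # 2 * (mean identity over the 4 allele pairs)
            if i == j:
                # a_ii = 1 + P(the two alleles of i are IBD)
                stat = 1.0 + (alleles[:, i, 0] == alleles[:, i, 1]).astype(float)
            A_hat[i, j] = A_hat[j, i] = stat.mean()
            A_se[i, j] = A_se[j, i] = stat.std(ddof=1) / np.sqrt(n_rep)
    return A_hat, A_se


def random_pedigree(n: int, seed: int) -> Pedigree:
    """A random valid pedigree: each individual's parents drawn among the
    earlier individuals (or unknown)."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        dam = sire = None
        if i >= 2 and rng.random() < 0.7:
            dam, sire = rng.choice(i, size=2, replace=False)
            dam, sire = f"I{dam}", f"I{sire}"
        records.append((f"I{i}", dam, sire))
    return Pedigree.from_records(records)


# --------------------------------------------------------------------------
# restricted-likelihood oracle: explicit Kronecker GLS assembly
# --------------------------------------------------------------------------
def dense_reml_logl(Y, covariate, ped: Pedigree, ids, dam_ids, sire_ids, comps):
    """Restricted logL -(log|V| + log|X'V^-1 X| + y'Py)/2 assembled from
    scratch: explicit incidence matrices, the full-pedigree A, np.kron and
    np.linalg.inv."""
    Y = np.asarray(Y, float)
    n, t = Y.shape
    A_full = relationship_matrix(ped).A
    Za = np.zeros((n, len(ped)))
    for r, i in enumerate(ids):
        Za[r, ped.index[str(i)]] = 1.0

    def incidence(labels):
        known = sorted({l for l in labels if l not in (None, "")})
        Z = np.zeros((n, len(known)))
        for r, l in enumerate(labels):
            if l in known:
                Z[r, known.index(l)] = 1.0
        return Z

    Zm = incidence(list(dam_ids))
    Zp = incidence(list(sire_ids))
    V = (
        np.kron(comps["G"], Za @ A_full @ Za.T)
        + np.kron(comps["Mat"], Zm @ Zm.T)
        + np.kron(comps["Pat"], Zp @ Zp.T)
        + np.kron(comps["R"], np.eye(n))
    )
    if covariate is not None:
        c = np.asarray(covariate, float)
        X0 = np.column_stack([np.ones(n), c - c.mean()])
    else:
        X0 = np.ones((n, 1))
    X = np.kron(np.eye(t), X0)
    y = Y.T.ravel()
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    sign_v, logdet_v = np.linalg.slogdet(V)
    sign_x, logdet_x = np.linalg.slogdet(XtViX)
    assert sign_v > 0 and sign_x > 0
    return -0.5 * (logdet_v + logdet_x + float(y @ P @ y))


# --------------------------------------------------------------------------
# pseudoinverse oracle
# --------------------------------------------------------------------------
def svd_pinv_product(numerator: np.ndarray, P: np.ndarray, rtol: float = 1e-10):
    """numerator @ pinv(P) with a hand-coded SVD pseudoinverse."""
    from scipy.linalg import svd

    U, s, Vt = svd(np.asarray(P, float))
    cut = rtol * s.max() if s.size else 0.0
    s_inv = np.array([1.0 / x if x > cut else 0.0 for x in s])
    return np.asarray(numerator, float) @ (Vt.T * s_inv) @ U.T


# --------------------------------------------------------------------------
# balanced half-sib ANOVA estimator
# --------------------------------------------------------------------------
def halfsib_anova_sire_variance(y: np.ndarray, groups: np.ndarray):
    """Expectation-of-mean-squares estimator for a balanced 1-way random
    design: sigma_s^2 = (MSB - MSW) / k."""
    labels = np.unique(groups)
    k = len(y) // len(labels)
    means = np.array([y[groups == g].mean() for g in labels])
    grand = y.mean()
    msb = k * ((means - grand) ** 2).sum() / (len(labels) - 1)
    msw = sum(((y[groups == g] - m) ** 2).sum() for g, m in zip(labels, means)) / (
        len(y) - len(labels)
    )
    return (msb - msw) / k, msw
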