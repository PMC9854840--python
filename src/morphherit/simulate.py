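"""Synthetic landmark data under a known animal model.

The generator emulates a captive-breeding quantitative-genetics study of
2-D head shape: a pedigree of dams x sires families, breeding values
propagated through the pedigree with Mendelian sampling, maternal/paternal
identity effects, an allometric log-centroid-size covariate, and landmark
configurations produced by perturbing a bilaterally symmetric template
inside an orthonormal basis of its symmetric tangent space.  Nuisance
rotation/translation/scale and small asymmetric digitization noise are
added so the full superimposition pipeline is exercised.

Because true covariance components are expressed in the same symmetric
tangent basis the pipeline estimates in, every stage is verifiable by
parameter recovery without any deposited data.

Presets
-------
``viper_pedigree`` / ``viper_truth`` reproduce the study design this
package targets: 12 families from 8 dams x 6 sires with 221 offspring and
trace proportions dominated by additive-genetic and maternal variance.
``recovery_pedigree`` / ``recovery_truth`` give a larger design (40 dams,
30 sires, 800 offspring) used for parameter-recovery checks.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import linalg

from .pedigree import Pedigree, relationship_matrix
from .scheme import LandmarkScheme, viper_head_scheme
from .tps import Configuration, write_tps

__all__ = [
    "SimulationTruth",
    "simulate_pedigree",
    "simulate_breeding_values",
    "simulate_dataset",
    "symmetric_basis",
    "viper_template",
    "viper_pedigree",
    "viper_truth",
    "recovery_pedigree",
    "recovery_truth",
    "family_sizes",
    "write_dataset",
]

# fixed seed for *structural* choices (component eigenvectors); data seeds
# are supplied by the caller and only drive sampling
_STRUCTURE_SEED = 20230116


# --------------------------------------------------------------------------
# template and symmetric tangent basis
# --------------------------------------------------------------------------
def viper_template() -> np.ndarray:
    """Bilaterally symmetric 40-landmark dorsal-head template.

    Right-side landmarks at positive x, mirrored to the left; midline
    landmarks (1, 34, 35, 40) on the y axis.  Centered, centroid size 1.
    """
    right = {
        1: (0.00, 1.00),
        2: (0.12, 0.95), 4: (0.20, 0.82), 6: (0.26, 0.68), 8: (0.30, 0.55),
        10: (0.38, 0.35), 12: (0.34, 0.22), 14: (0.22, 0.24), 16: (0.45, -0.10),
        18: (0.35, 0.49), 20: (0.38, 0.42),
        22: (0.42, 0.25), 24: (0.45, 0.13), 26: (0.46, 0.02), 28: (0.46, -0.05),
        30: (0.10, 0.50), 32: (0.09, 0.25),
        34: (0.00, 0.18), 35: (0.00, 0.12),
        36: (0.14, 0.10), 38: (0.12, -0.15),
        40: (0.00, -0.22),
    }
    coords = np.zeros((40, 2))
    for idx, (x, y) in right.items():
        coords[idx - 1] = (x, y)
        if x != 0.0:
            coords[idx] = (-x, y)  # left partner is idx+1 (1-based idx+1)
    coords -= coords.mean(axis=0)
    coords /= np.sqrt((coords**2).sum())
    return coords


def symmetric_basis(template: np.ndarray, scheme: LandmarkScheme) -> np.ndarray:
    """Orthonormal basis of the symmetric shape tangent space at a template.

    Spans all perturbations that keep the configuration bilaterally
    symmetric about the y axis, with axial translation and the scale
    (radial) direction removed; for an 18-pair / 4-midline scheme the
    result has ``2*18 + 4 - 2 = 38`` columns.  Construction is
    deterministic: coordinate perturbations are symmetrized per
    pair/midline landmark, the translation and scale directions are
    projected out, and the rest is orthonormalized by pivoted QR.
    """
    k = scheme.n_landmarks
    raw = []
    for left, right_ in scheme.pairs0:
        v = np.zeros((k, 2))
        v[left, 0], v[right_, 0] = 1.0, -1.0
        raw.append(v.ravel())
        v = np.zeros((k, 2))
        v[left, 1] = v[right_, 1] = 1.0
        raw.append(v.ravel())
    for m in scheme.midline0:
        v = np.zeros((k, 2))
        v[m, 1] = 1.0
        raw.append(v.ravel())
    raw = np.array(raw).T  # (2k, 2*n_pairs + n_midline)
    # remove axial translation and the scale direction
    t_y = np.zeros(2 * k)
    t_y[1::2] = 1.0
    remove = np.stack([t_y / np.linalg.norm(t_y)])
    templ = template.ravel().copy()
    templ -= (templ @ remove[0]) * remove[0]
    templ /= np.linalg.norm(templ)
    remove = np.vstack([remove, templ])
    raw = raw - remove.T @ (remove @ raw)
    Q, R, _ = linalg.qr(raw, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > 1e-10 * diag[0]))
    return Q[:, :rank]


# --------------------------------------------------------------------------
# truth container
# --------------------------------------------------------------------------
@dataclass
class SimulationTruth:
    """True generating quantities for a synthetic dataset.

    Component matrices are expressed in the first ``t`` columns of the
    symmetric tangent basis at ``template``; ``beta`` is the allometric
    slope on centered log centroid size, ``cs_mean``/``cs_sd`` parameterize
    log centroid size, and ``asym_noise_sd`` is the i.i.d. per-coordinate
    digitization noise (template units, hence asymmetric).
    """

    G: np.ndarray
    Mat: np.ndarray
    Pat: np.ndarray
    R: np.ndarray
    beta: np.ndarray
    cs_mean: float
    cs_sd: float
    asym_noise_sd: float
    seed: int = 0
    scheme: LandmarkScheme = field(default_factory=viper_head_scheme)
    template: np.ndarray = field(default_factory=viper_template)

    def __post_init__(self) -> None:
        mats = []
        for name in ("G", "Mat", "Pat", "R"):
            M = np.asarray(getattr(self, name), float)
            setattr(self, name, M)
            mats.append(M)
            if np.max(np.abs(M - M.T)) > 1e-10:
                raise ValueError(f"{name} must be symmetric")
            w = np.linalg.eigvalsh(M)
            if w.min() < -1e-8 * max(1.0, abs(w).max()):
                raise ValueError(f"{name} must be positive semidefinite")
        t = mats[0].shape[0]
        if any(M.shape != (t, t) for M in mats):
            raise ValueError("component matrices must share dimensions")
        self.beta = np.asarray(self.beta, float).reshape(-1)
        if self.beta.shape[0] != t:
            raise ValueError("beta length must equal trait count")
        asym = _asymmetry_of(self.template, self.scheme)
        if asym > 1e-8:
            raise ValueError("template is not bilaterally symmetric under scheme")

    @property
    def n_traits(self) -> int:
        return self.G.shape[0]

    @property
    def P(self) -> np.ndarray:
        return self.G + self.Mat + self.Pat + self.R

    def proportions(self) -> dict[str, float]:
        from .heritability import variance_proportions

        return variance_proportions(
            {"G": self.G, "Mat": self.Mat, "Pat": self.Pat, "R": self.R}
        )


def _asymmetry_of(template: np.ndarray, scheme: LandmarkScheme) -> float:
    perm = scheme.reflection_permutation()
    refl = template[perm].copy()
    refl[:, 0] *= -1.0
    return float(np.abs(template - refl).max())


# --------------------------------------------------------------------------
# pedigree simulation
# --------------------------------------------------------------------------
def family_sizes(n_offspring: int, n_families: int) -> list[int]:
    """Near-equal integer family sizes summing to ``n_offspring``."""
    base, extra = divmod(n_offspring, n_families)
    return [base + (1 if f < extra else 0) for f in range(n_families)]


def simulate_pedigree(
    n_dams: int,
    n_sires: int,
    n_families: int,
    offspring_per_family: list[int],
    seed: int = 0,
) -> Pedigree:
    """Pedigree of distinct (dam, sire) families with given litter sizes.

    Dams and sires may be reused across families but each (dam, sire) pair
    occurs once.  When the family count allows it, every dam and sire is
    used at least once (dams are cycled; sparsely used sires preferred).
    Deterministic under ``seed``.
    """
    if len(offspring_per_family) != n_families:
        raise ValueError("offspring_per_family length must equal n_families")
    if any(o < 1 for o in offspring_per_family):
        raise ValueError("every family needs at least one offspring")
    if n_families > n_dams * n_sires:
        raise ValueError(
            f"cannot form {n_families} distinct pairs from "
            f"{n_dams} dams x {n_sires} sires"
        )
    rng = np.random.default_rng(seed)
    dam_order = rng.permutation(n_dams)
    used: set[tuple[int, int]] = set()
    sire_counts = np.zeros(n_sires, dtype=int)
    pairs: list[tuple[int, int]] = []
    for f in range(n_families):
        d = int(dam_order[f % n_dams])
        order = np.lexsort((rng.random(n_sires), sire_counts))
        for s in order:
            if (d, int(s)) not in used:
                used.add((d, int(s)))
                sire_counts[s] += 1
                pairs.append((d, int(s)))
                break
        else:  # pragma: no cover - excluded by the n_families bound
            raise RuntimeError("could not place a distinct (dam, sire) pair")
    wd = len(str(n_dams))
    ws = len(str(n_sires))
    wo = len(str(sum(offspring_per_family)))
    records = [(f"D{d + 1:0{wd}d}", None, None) for d in range(n_dams)]
    records += [(f"S{s + 1:0{ws}d}", None, None) for s in range(n_sires)]
    o = 0
    for (d, s), size in zip(pairs, offspring_per_family):
        for _ in range(size):
            o += 1
            records.append(
                (f"O{o:0{wo}d}", f"D{d + 1:0{wd}d}", f"S{s + 1:0{ws}d}")
            )
    return Pedigree.from_records(records)


# --------------------------------------------------------------------------
# phenotype simulation
# --------------------------------------------------------------------------
def simulate_breeding_values(
    ped: Pedigree,
    G: np.ndarray,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Breeding values a ~ N(0, G (x) A) by Mendelian-sampling recursion.

    Founders are drawn from N(0, G); a non-founder gets the parent average
    plus a Mendelian deviation with variance ``(1 - 0.25(1+F_d) -
    0.25(1+F_s)) G`` (terms dropped for unknown parents), F being pedigree
    inbreeding coefficients.  Rows follow pedigree (topological) order.
    """
    G = np.asarray(G, float)
    w, V = np.linalg.eigh((G + G.T) / 2.0)
    if w.min() < -1e-8 * max(1.0, abs(w).max()):
        raise ValueError("G must be positive semidefinite")
    Lg = V * np.sqrt(np.clip(w, 0.0, None))
    if rng is None:
        rng = np.random.default_rng(seed)
    n, t = len(ped), G.shape[0]
    F = ped.inbreeding()
    Z = rng.standard_normal((n, t))
    a = np.zeros((n, t))
    for i in range(n):
        d, s = ped.dam_idx[i], ped.sire_idx[i]
        mean = np.zeros(t)
        var_coef = 1.0
        if d >= 0:
            mean += 0.5 * a[d]
            var_coef -= 0.25 * (1.0 + F[d])
        if s >= 0:
            mean += 0.5 * a[s]
            var_coef -= 0.25 * (1.0 + F[s])
        a[i] = mean + np.sqrt(max(var_coef, 0.0)) * (Z[i] @ Lg.T)
    return a


def simulate_dataset(
    truth: SimulationTruth,
    ped: Pedigree,
    phenotype_parents: bool = True,
    seed: Optional[int] = None,
) -> tuple[list[Configuration], pd.DataFrame]:
    """Generate landmark configurations and the hidden truth table.

    Per phenotyped individual: log CS ~ N(cs_mean, cs_sd); the trait-space
    deviation is ``beta (logCS - cs_mean) + a_i + m_dam + p_sire + e_i``;
    the deviation is mapped to landmarks through the symmetric tangent
    basis at the template, i.i.d. asymmetric digitization noise is added
    per coordinate, and a random rotation, translation and scale
    ``exp(logCS) / CS(template)`` is applied.

    Returns TPS-writable configurations (pedigree order) and a DataFrame
    with ids, parents, sex, family, true log CS and the true effect draws.
    """
    t = truth.n_traits
    basis = symmetric_basis(truth.template, truth.scheme)
    if t > basis.shape[1]:
        raise ValueError(
            f"trait count {t} exceeds symmetric-subspace dimension {basis.shape[1]}"
        )
    Bt = basis[:, :t]
    if seed is None:
        seed = truth.seed
    rng = np.random.default_rng(seed)
    a = simulate_breeding_values(ped, truth.G, rng=rng)

    def factor_draw(cov, labels):
        w, V = np.linalg.eigh((cov + cov.T) / 2.0)
        L = V * np.sqrt(np.clip(w, 0.0, None))
        return {lab: rng.standard_normal(t) @ L.T for lab in labels}

    dam_labels = sorted(
        {ped.ids[i] for i in ped.dam_idx if i >= 0},
        key=lambda l: ped.index[l],
    )
    sire_labels = sorted(
        {ped.ids[i] for i in ped.sire_idx if i >= 0},
        key=lambda l: ped.index[l],
    )
    m_draws = factor_draw(truth.Mat, dam_labels)
    p_draws = factor_draw(truth.Pat, sire_labels)
    wr, Vr = np.linalg.eigh((truth.R + truth.R.T) / 2.0)
    Lr = Vr * np.sqrt(np.clip(wr, 0.0, None))

    fam_of: dict[str, int] = {}
    fam_index: dict[tuple[str, str], int] = {}
    roles = {}
    for i, ind in enumerate(ped.ids):
        d, s = ped.dam_idx[i], ped.sire_idx[i]
        if d >= 0 or s >= 0:
            roles[ind] = "offspring"
            key = (
                ped.ids[d] if d >= 0 else "",
                ped.ids[s] if s >= 0 else "",
            )
            fam_of[ind] = fam_index.setdefault(key, len(fam_index) + 1)
        else:
            roles[ind] = (
                "dam" if ind in m_draws else "sire" if ind in p_draws else "founder"
            )
    phenotyped = [
        ind
        for ind in ped.ids
        if roles[ind] == "offspring" or phenotype_parents
    ]
    k = truth.scheme.n_landmarks
    template_cs = float(np.sqrt(((truth.template - truth.template.mean(0)) ** 2).sum()))
    configs: list[Configuration] = []
    rows = []
    for ind in phenotyped:
        i = ped.index[ind]
        d, s = ped.dam_idx[i], ped.sire_idx[i]
        log_cs = truth.cs_mean + truth.cs_sd * rng.standard_normal()
        e = rng.standard_normal(t) @ Lr.T
        m = m_draws.get(ped.ids[d], np.zeros(t)) if d >= 0 else np.zeros(t)
        p = p_draws.get(ped.ids[s], np.zeros(t)) if s >= 0 else np.zeros(t)
        dev = truth.beta * (log_cs - truth.cs_mean) + a[i] + m + p + e
        shape = truth.template + (Bt @ dev).reshape(k, 2)
        shape = shape + truth.asym_noise_sd * rng.standard_normal((k, 2))
        theta = rng.uniform(0.0, 2.0 * np.pi)
        c, sn = np.cos(theta), np.sin(theta)
        R2 = np.array([[c, -sn], [sn, c]])
        size = np.exp(log_cs) / template_cs
        offset = rng.uniform(-2.0, 2.0, size=2) * np.exp(truth.cs_mean)
        coords = shape @ R2 * size + offset
        sex = "F" if roles[ind] == "dam" else "M" if roles[ind] == "sire" else (
            "F" if rng.random() < 0.5 else "M"
        )
        meta = {
            "sex": sex,
            "role": roles[ind],
            "family": fam_of.get(ind, 0),
        }
        configs.append(Configuration(specimen_id=ind, coords=coords, metadata=meta))
        row = {
            "id": ind,
            "dam": ped.ids[d] if d >= 0 else "",
            "sire": ped.ids[s] if s >= 0 else "",
            "sex": sex,
            "role": roles[ind],
            "family": fam_of.get(ind, 0),
            "log_cs": log_cs,
        }
        for j in range(t):
            row[f"s{j + 1}"] = dev[j]
            row[f"a{j + 1}"] = a[i][j]
            row[f"m{j + 1}"] = m[j]
            row[f"p{j + 1}"] = p[j]
            row[f"e{j + 1}"] = e[j]
        rows.append(row)
    return configs, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------
def _component_matrix(trace: float, eig_fracs, rng: np.random.Generator, t: int):
    if trace <= 0.0:
        return np.zeros((t, t))
    fr = np.asarray(eig_fracs, float)[:t]
    fr = fr / fr.sum()
    Q, _ = np.linalg.qr(rng.standard_normal((t, t)))
    return (Q * (trace * fr)) @ Q.T


def viper_pedigree(seed: int = 0) -> Pedigree:
    """12 families from 8 dams x 6 sires with 221 offspring (235 members)."""
    return simulate_pedigree(8, 6, 12, family_sizes(221, 12), seed=seed)


def viper_truth(t: int = 3, seed: int = 0) -> SimulationTruth:
    """Study-condition truth: additive-genetic and maternal dominated.

    Trace proportions follow the study outcome (G 49.13%, Mat 50.69%,
    Pat 8.85e-4%, residual the remainder); the leading eigenvalue of G
    (resp. Mat) concentrates ~91% (77%) of its trace.  Total shape
    variance 1e-3 squared Procrustes units.
    """
    srng = np.random.default_rng(_STRUCTURE_SEED)
    total = 1.0e-3
    pg, pm, pp = 0.4913, 0.5069, 8.85e-6
    pr = 1.0 - pg - pm - pp
    G = _component_matrix(pg * total, [0.91, 0.06, 0.03, 0.015][:t] + [0.01] * max(0, t - 4), srng, t)
    Mat = _component_matrix(pm * total, [0.77, 0.15, 0.08, 0.04][:t] + [0.02] * max(0, t - 4), srng, t)
    Pat = _component_matrix(pp * total, [1.0] + [0.5] * (t - 1), srng, t)
    R = _component_matrix(pr * total, [1.0] * t, srng, t)
    beta = 0.07 * np.array([(-1.0) ** j / (j + 1) for j in range(t)])
    return SimulationTruth(
        G=G, Mat=Mat, Pat=Pat, R=R, beta=beta,
        cs_mean=float(np.log(25.0)), cs_sd=0.15, asym_noise_sd=0.002, seed=seed,
    )


def recovery_pedigree(seed: int = 0) -> Pedigree:
    """40 dams x 30 sires, 120 families, 800 offspring (870 members).

    Cross-classified: each dam appears in ~3 families with different sires
    and each sire in ~4, so maternal, paternal and additive-genetic
    variance are separately identified (unlike a nested one-dam-one-family
    layout, where dam identity is confounded with the family mean).
    """
    return simulate_pedigree(40, 30, 120, family_sizes(800, 120), seed=seed)


def recovery_truth(t: int = 3, seed: int = 0) -> SimulationTruth:
    """Recovery-design truth: trace proportions G:Mat:Pat:R = .45:.45:0:.10."""
    srng = np.random.default_rng(_STRUCTURE_SEED + 1)
    total = 1.0e-3
    G = _component_matrix(0.45 * total, [0.6, 0.25, 0.15][:t] + [0.1] * max(0, t - 3), srng, t)
    Mat = _component_matrix(0.45 * total, [0.5, 0.3, 0.2][:t] + [0.1] * max(0, t - 3), srng, t)
    Pat = np.zeros((t, t))
    R = _component_matrix(0.10 * total, [1.0] * t, srng, t)
    beta = 0.07 * np.array([(-1.0) ** j / (j + 1) for j in range(t)])
    return SimulationTruth(
        G=G, Mat=Mat, Pat=Pat, R=R, beta=beta,
        cs_mean=float(np.log(25.0)), cs_sd=0.15, asym_noise_sd=0.002, seed=seed,
    )


# --------------------------------------------------------------------------
# writers
# --------------------------------------------------------------------------
def write_dataset(
    configs: list[Configuration],
    truth_table: pd.DataFrame,
    ped: Pedigree,
    outdir,
) -> dict[str, str]:
    """Write TPS landmarks, pedigree CSV and the truth table to a directory.

    The pedigree CSV carries id/dam/sire plus sex and family columns for
    phenotyped individuals.  Returns the written paths.
    """
    os.makedirs(outdir, exist_ok=True)
    tps_path = os.path.join(outdir, "landmarks.tps")
    ped_path = os.path.join(outdir, "pedigree.csv")
    truth_path = os.path.join(outdir, "traits_truth.csv")
    write_tps(configs, tps_path)
    ped_df = ped.to_dataframe()
    extra = truth_table.set_index("id")[["sex", "family"]]
    ped_df = ped_df.join(extra, on="id")
    ped_df["sex"] = ped_df["sex"].fillna("")
    ped_df["family"] = ped_df["family"].fillna(0).astype(int)
    ped_df.to_csv(ped_path, index=False)
    truth_table.to_csv(truth_path, index=False)
    return {"tps": tps_path, "pedigree": ped_path, "truth": truth_path}
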