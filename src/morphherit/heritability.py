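"""Multivariate heritability and effect-structure summaries.

Given fitted variance components G, Mat, Pat, R (P = G + Mat + Pat + R),
this module computes the multivariate heritability matrix ``GP-`` (G times
the Moore-Penrose generalized inverse of P), the analogous maternal matrix
``MatP-``, their eigen-spectra (the dominant eigenvalue of GP- is the
maximum additive heritability h2_max), trace-based variance proportions,
angles between leading eigenvectors, the multivariate breeders' equation
``delta_z = GP- S`` and back-projection of trait-space vectors to landmark
displacement fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "variance_proportions",
    "gp_minus",
    "eigen_summary",
    "vector_angle",
    "predict_response",
    "back_project",
    "summarize",
    "EigenSummary",
    "SelectionResponse",
    "HeritabilitySummary",
]


def _component_dict(vc) -> dict[str, np.ndarray]:
    if isinstance(vc, dict):
        return {k: np.asarray(v, float) for k, v in vc.items()}
    return {
        "G": np.asarray(vc.G, float),
        "Mat": np.asarray(vc.Mat, float),
        "Pat": np.asarray(vc.Pat, float),
        "R": np.asarray(vc.R, float),
    }


def variance_proportions(vc) -> dict[str, float]:
    """Trace of each component divided by trace(P); sums to 1 exactly."""
    comp = _component_dict(vc)
    traces = {k: float(np.trace(M)) for k, M in comp.items()}
    total = sum(traces.values())
    if total <= 0.0:
        raise ValueError("trace(P) must be positive")
    return {k: v / total for k, v in traces.items()}


def gp_minus(numerator: np.ndarray, P: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Component matrix times the SVD pseudoinverse of P.

    Singular values of P below ``rtol * max_sv`` are treated as zero.  Both
    inputs must be symmetric (checked to 1e-8); serves GP- and MatP- alike.
    """
    numerator = np.asarray(numerator, float)
    P = np.asarray(P, float)
    for name, M in (("numerator", numerator), ("P", P)):
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError(f"{name} must be square")
        if np.max(np.abs(M - M.T)) > 1e-8:
            raise ValueError(f"{name} is not symmetric within 1e-8")
    if numerator.shape != P.shape:
        raise ValueError("numerator and P dimensions differ")
    return numerator @ np.linalg.pinv(P, rcond=rtol, hermitian=True)


@dataclass
class EigenSummary:
    """Descending eigenvalues and sign-fixed unit eigenvectors."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns

    @property
    def fractions_positive(self) -> np.ndarray:
        """Each eigenvalue as a fraction of the positive spectrum."""
        pos = self.eigenvalues[self.eigenvalues > 0].sum()
        if pos <= 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / pos

    @property
    def fractions_trace(self) -> np.ndarray:
        """Each eigenvalue as a fraction of the full trace."""
        tot = self.eigenvalues.sum()
        if tot == 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / tot

    @property
    def cumulative_positive(self) -> np.ndarray:
        return np.cumsum(self.fractions_positive)


def eigen_summary(M: np.ndarray, imag_tol: float = 1e-8) -> EigenSummary:
    """Eigen-decomposition with descending real sort and sign fixing.

    Products like GP- are not symmetric, so complex pairs can arise from
    invalid inputs; an imaginary magnitude at or above ``imag_tol``
    (relative to the spectral scale) raises.
    """
    M = np.asarray(M, float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("M must be square")
    w, V = np.linalg.eig(M)
    scale = max(float(np.max(np.abs(w))), 1.0)
    if np.max(np.abs(w.imag)) >= imag_tol * scale or (
        np.max(np.abs(V.imag)) >= imag_tol
    ):
        raise ValueError(
            "eigenvalues have non-negligible imaginary parts; component "
            "matrices are likely invalid"
        )
    w = w.real
    V = V.real
    order = np.argsort(w)[::-1]
    w = w[order]
    V = V[:, order]
    V = V / np.linalg.norm(V, axis=0)
    flip = V[np.abs(V).argmax(axis=0), np.arange(V.shape[1])] < 0
    V[:, flip] *= -1.0
    return EigenSummary(eigenvalues=w, eigenvectors=V)


def vector_angle(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle between directions in degrees, in [0, 90] (sign ignored).

    Computed as atan2 of the rejection norm against the absolute dot
    product, which stays accurate for nearly (anti)parallel vectors where
    the arccos form loses half the significant digits.
    """
    v1 = np.asarray(v1, float).reshape(-1)
    v2 = np.asarray(v2, float).reshape(-1)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("zero vector has no direction")
    u1, u2 = v1 / n1, v2 / n2
    c = float(u1 @ u2)
    if c < 0.0:
        u2, c = -u2, -c
    perp = u2 - c * u1
    return float(np.degrees(np.arctan2(np.linalg.norm(perp), c)))


@dataclass
class SelectionResponse:
    """Selection differential S and predicted response delta_z = GP- S."""

    S: np.ndarray
    delta_z: np.ndarray


def predict_response(GPm: np.ndarray, S: np.ndarray) -> SelectionResponse:
    """Multivariate breeders' equation: delta_z = GP- S."""
    GPm = np.asarray(GPm, float)
    S = np.asarray(S, float).reshape(-1)
    if GPm.ndim != 2 or GPm.shape[1] != S.shape[0]:
        raise ValueError(
            f"dimension mismatch: GPm {GPm.shape} vs S length {S.shape[0]}"
        )
    return SelectionResponse(S=S, delta_z=GPm @ S)


def back_project(vector: np.ndarray, space) -> np.ndarray:
    """Map a retained-PC-space vector to a landmark displacement field.

    ``space`` is a :class:`~morphherit.morphometry.ShapeSpace`; the result
    is ``loadings @ vector`` about the consensus, with the norm preserved
    (orthonormal loadings).
    """
    return space.back_project(np.asarray(vector, float))


@dataclass
class HeritabilitySummary:
    """GP-/MatP- eigenstructure, h2_max, trace proportions and angles."""

    proportions: dict[str, float]
    GPm: np.ndarray
    MatPm: np.ndarray
    GPm_eigen: EigenSummary
    MatPm_eigen: EigenSummary
    h2_max: float
    mat_max: float
    angles_deg: dict[str, float]
    component_eigen: dict[str, EigenSummary]

    def to_dict(self) -> dict:
        def eig(e: EigenSummary) -> dict:
            return {
                "eigenvalues": e.eigenvalues.tolist(),
                "fractions_positive": e.fractions_positive.tolist(),
                "fractions_trace": e.fractions_trace.tolist(),
                "cumulative_positive": e.cumulative_positive.tolist(),
                "eigenvectors": e.eigenvectors.tolist(),
            }

        return {
            "proportions": self.proportions,
            "h2_max": self.h2_max,
            "mat_max": self.mat_max,
            "angles_deg": self.angles_deg,
            "GPm_eigen": eig(self.GPm_eigen),
            "MatPm_eigen": eig(self.MatPm_eigen),
            "component_eigen": {k: eig(v) for k, v in self.component_eigen.items()},
        }


def summarize(vc, pinv_rtol: float = 1e-10) -> HeritabilitySummary:
    """Full heritability summary from fitted (or true) variance components.

    Computes trace proportions, GP- and MatP- with their eigen-spectra
    (h2_max and the maximal maternal eigenvalue), the eigenstructure of
    each symmetric component matrix, and the angles between the leading
    eigenvectors of P, G and Mat.
    """
    comp = _component_dict(vc)
    P = comp["G"] + comp["Mat"] + comp["Pat"] + comp["R"]
    proportions = variance_proportions(comp)
    GPm = gp_minus(comp["G"], P, rtol=pinv_rtol)
    MatPm = gp_minus(comp["Mat"], P, rtol=pinv_rtol)
    gp_eig = eigen_summary(GPm)
    mat_eig = eigen_summary(MatPm)
    comp_eig = {}
    for label, M in {**comp, "P": P}.items():
        w, V = np.linalg.eigh(M)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        flip = V[np.abs(V).argmax(axis=0), np.arange(V.shape[1])] < 0
        V = V.copy()
        V[:, flip] *= -1.0
        comp_eig[label] = EigenSummary(eigenvalues=w, eigenvectors=V)

    def lead(label: str) -> np.ndarray:
        return comp_eig[label].eigenvectors[:, 0]

    angles = {}
    for a, b in (("G", "P"), ("Mat", "P"), ("Mat", "G")):
        try:
            angles[f"{a}1:{b}1"] = vector_angle(lead(a), lead(b))
        except ValueError:
            angles[f"{a}1:{b}1"] = float("nan")
    return HeritabilitySummary(
        proportions=proportions,
        GPm=GPm,
        MatPm=MatPm,
        GPm_eigen=gp_eig,
        MatPm_eigen=mat_eig,
        h2_max=float(gp_eig.eigenvalues[0]),
        mat_max=float(mat_eig.eigenvalues[0]),
        angles_deg=angles,
        component_eigen=comp_eig,
    )
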