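"""Multivariate animal model fitted by REML.

The model for a t-variate phenotype y (here: retained PC scores of shape)
observed on n individuals is

    y = X beta + a + m + p + e

with a fixed intercept and (optionally) a log-centroid-size covariate per
trait, an additive-genetic effect ``a ~ N(0, G (x) A)`` structured by the
pedigree relationship matrix A, maternal- and paternal-identity effects
``m ~ N(0, Mat (x) I_dams)``, ``p ~ N(0, Pat (x) I_sires)`` that are i.i.d.
across parents, and a residual ``e ~ N(0, R (x) I)``.  The four t x t
covariance blocks are estimated by restricted maximum likelihood.

Estimation uses EM-REML (expectation-conditional covariance updates, which
keep every block positive semidefinite and increase the restricted
log-likelihood monotonically), accelerated by an over-relaxed EM line
search and by damped average-information (AI) steps; every accelerated
candidate is accepted only when it does not decrease the restricted
log-likelihood, so the reported likelihood trajectory is monotone
regardless of the method.

Likelihood evaluations exploit the covariance structure
``V = G (x) A + R (x) I + low rank``: after a one-time rotation of the
observations into the eigenbasis of A, the genetic-plus-residual core is
block diagonal (one t x t block per eigenvalue of A) and the maternal and
paternal terms, whose kernels have rank equal to the number of dams and
sires, enter through the Woodbury identity.  A dense reference
implementation of the same likelihood is kept for cross-checking.

The public surface follows the Model/Results convention:
``AnimalModel(...).fit()`` returns an :class:`AnimalModelResults` carrying
G, Mat, Pat, R, P, the fixed effects, the likelihood path and summaries.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .pedigree import Pedigree, relationship_matrix

__all__ = ["AnimalModel", "AnimalModelResults", "reml_fit", "COMPONENTS"]

log = logging.getLogger(__name__)

COMPONENTS = ("G", "Mat", "Pat", "R")


def _as_labels(values, n, what):
    if values is None:
        return [None] * n
    out = []
    for v in values:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            out.append(None)
        else:
            s = str(v).strip()
            out.append(None if s.upper() in {"", "0", "NA", "NAN", "NONE"} else s)
    if len(out) != n:
        raise ValueError(f"{what} length {len(out)} != number of rows {n}")
    return out


def _psd_clip(M: np.ndarray, floor: float = 0.0) -> np.ndarray:
    M = (M + M.T) / 2.0
    w, V = np.linalg.eigh(M)
    w = np.clip(w, floor, None)
    return (V * w) @ V.T


class AnimalModel:
    """Animal model for a multivariate phenotype on a pedigreed sample.

    Parameters
    ----------
    traits : (n, t) array
        Trait values (no missing entries).
    individual_ids : sequence of str
        One id per row; every id must be present in the pedigree.
    pedigree : Pedigree
        Source of the numerator relationship matrix.
    covariate : (n,) array, optional
        Fixed covariate (log centroid size); centered internally.  When
        omitted the fixed part is an intercept per trait.
    dam_ids, sire_ids : sequences, optional
        Maternal / paternal identity labels per row (unknown as
        None/''/0/NA); required when the corresponding component is active.
    components : subset of ("G", "Mat", "Pat", "R")
        Active covariance components; "R" is always fitted.  Excluded
        components are fixed at zero.
    """

    def __init__(
        self,
        traits,
        individual_ids,
        pedigree: Pedigree,
        covariate=None,
        dam_ids=None,
        sire_ids=None,
        components: Sequence[str] = COMPONENTS,
    ) -> None:
        Y = np.asarray(traits, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if Y.ndim != 2 or Y.shape[1] < 1:
            raise ValueError("traits must be an (n, t) array with t >= 1")
        if not np.all(np.isfinite(Y)):
            raise ValueError("traits contain missing/non-finite values")
        n, t = Y.shape
        ids = [str(i).strip() for i in individual_ids]
        if len(ids) != n:
            raise ValueError("individual_ids length does not match traits")
        if len(set(ids)) != n:
            raise ValueError("duplicate individual ids among observation rows")
        missing = [i for i in ids if i not in pedigree.index]
        if missing:
            raise ValueError(f"ids not in pedigree: {missing[:5]}")
        comp = tuple(dict.fromkeys(list(components) + ["R"]))
        unknown = set(comp) - set(COMPONENTS)
        if unknown:
            raise ValueError(f"unknown components {sorted(unknown)}")
        self.traits = Y
        self.n_obs, self.n_traits = n, t
        self.individual_ids = ids
        self.pedigree = pedigree
        self.components = tuple(c for c in COMPONENTS if c in comp)
        self.dam_ids = _as_labels(dam_ids, n, "dam_ids")
        self.sire_ids = _as_labels(sire_ids, n, "sire_ids")

        if covariate is not None:
            cov = np.asarray(covariate, dtype=float).reshape(-1)
            if cov.shape[0] != n:
                raise ValueError("covariate length does not match traits")
            X0 = np.column_stack([np.ones(n), cov - cov.mean()])
        else:
            X0 = np.ones((n, 1))
        if np.linalg.matrix_rank(X0) < X0.shape[1]:
            raise ValueError("singular fixed-effect design (constant covariate?)")
        self.X0 = X0
        if n < X0.shape[1] + 1:
            raise ValueError("fewer rows than fixed effects + 1")

        # kernel matrices (observation basis) for the active components
        self._kernels: dict[str, np.ndarray] = {}
        self._levels: dict[str, int] = {}
        if "G" in self.components:
            A = relationship_matrix(pedigree)
            self._kernels["G"] = A.submatrix(ids)
            self._levels["G"] = n
        if "Mat" in self.components:
            Z, q = self._incidence(self.dam_ids, "dam")
            self._kernels["Mat"] = Z @ Z.T
            self._levels["Mat"] = q
            self._Zm = Z
        if "Pat" in self.components:
            Z, q = self._incidence(self.sire_ids, "sire")
            self._kernels["Pat"] = Z @ Z.T
            self._levels["Pat"] = q
            self._Zp = Z
        self._kernels["R"] = np.eye(n)
        self._levels["R"] = n
        self._fast = None  # lazy eigen-rotation workspace

    def _incidence(self, labels, what):
        known = sorted({l for l in labels if l is not None})
        if len(known) < 2:
            raise ValueError(f"need >= 2 distinct {what} identities among rows")
        Z = np.zeros((self.n_obs, len(known)))
        lut = {l: j for j, l in enumerate(known)}
        for i, l in enumerate(labels):
            if l is not None:
                Z[i, lut[l]] = 1.0
        return Z, len(known)

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        pedigree: Pedigree,
        trait_cols: Sequence[str],
        covariate_col: Optional[str] = "log_cs",
        id_col: str = "id",
        dam_col: Optional[str] = "dam",
        sire_col: Optional[str] = "sire",
        components: Sequence[str] = COMPONENTS,
    ) -> "AnimalModel":
        cov = None
        if covariate_col is not None and covariate_col in df.columns:
            cov = df[covariate_col].to_numpy(float)
        return cls(
            traits=df[list(trait_cols)].to_numpy(float),
            individual_ids=df[id_col],
            pedigree=pedigree,
            covariate=cov,
            dam_ids=df[dam_col] if dam_col in df.columns else None,
            sire_ids=df[sire_col] if sire_col in df.columns else None,
            components=components,
        )

    # ------------------------------------------------------------------
    # dense reference likelihood (trait-major stacking y = [y_1; ...; y_t])
    # ------------------------------------------------------------------
    def _assemble_v(self, sig: dict[str, np.ndarray]) -> np.ndarray:
        n, t = self.n_obs, self.n_traits
        V = np.zeros((n * t, n * t))
        for c, K in self._kernels.items():
            S = sig[c]
            for r in range(t):
                for s in range(r, t):
                    if S[r, s] != 0.0:
                        V[r * n : (r + 1) * n, s * n : (s + 1) * n] += S[r, s] * K
        iu = np.triu_indices(n * t, 1)
        V[(iu[1], iu[0])] = V[iu]
        return V

    @property
    def _y(self) -> np.ndarray:
        return self.traits.T.ravel()

    @property
    def _X(self) -> np.ndarray:
        return np.kron(np.eye(self.n_traits), self.X0)

    def _dense_logl(self, sig) -> float:
        """Restricted logL by direct dense factorization (reference path)."""
        V = self._assemble_v(sig)
        try:
            cho = linalg.cho_factor(V, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return -np.inf
        X, y = self._X, self._y
        logdet_v = 2.0 * np.sum(np.log(np.diag(cho[0])))
        ViX = linalg.cho_solve(cho, X, check_finite=False)
        Viy = linalg.cho_solve(cho, y, check_finite=False)
        XtViX = X.T @ ViX
        sgn, logdet_x = np.linalg.slogdet(XtViX)
        if sgn <= 0:
            return -np.inf
        Xty = X.T @ Viy
        ypy = float(y @ Viy - Xty @ np.linalg.solve(XtViX, Xty))
        return -0.5 * (logdet_v + logdet_x + ypy)

    # ------------------------------------------------------------------
    # fast likelihood: eigen-rotation of A plus Woodbury for parental terms
    # ------------------------------------------------------------------
    def _fast_prepare(self):
        if self._fast is not None:
            return self._fast
        n, t = self.n_obs, self.n_traits
        if "G" in self._kernels:
            lam, Q = np.linalg.eigh(self._kernels["G"])
            lam = np.clip(lam, 0.0, None)
        else:
            lam, Q = np.zeros(n), np.eye(n)
        Yt = (Q.T @ self.traits).T  # (t, n)
        X0r = Q.T @ self.X0
        lowrank = []  # (component, rotated incidence)
        for c, attr in (("Mat", "_Zm"), ("Pat", "_Zp")):
            if c in self._kernels:
                lowrank.append((c, Q.T @ getattr(self, attr)))
        self._fast = {
            "lam": lam, "Q": Q, "Yt": Yt, "X0r": X0r, "lowrank": lowrank,
        }
        return self._fast

    def _fast_core(self, sig, derivs: bool):
        """Evaluate the restricted likelihood (and, optionally, the trace and
        quadratic ingredients of EM/AI updates) in O(n t^3 + n L^2) time.

        Works in the rotated basis where A is diagonal.  Returns None when
        the core covariance is not positive definite.
        """
        fw = self._fast_prepare()
        n, t = self.n_obs, self.n_traits
        lam, Yt, X0r = fw["lam"], fw["Yt"], fw["X0r"]
        G = sig.get("G")
        R = sig["R"]
        Cs = np.broadcast_to(R, (n, t, t)).copy()
        if G is not None:
            Cs += lam[:, None, None] * G
        try:
            chol = np.linalg.cholesky(Cs)
        except np.linalg.LinAlgError:
            return None
        logdet_c = 2.0 * float(np.log(np.diagonal(chol, axis1=1, axis2=2)).sum())
        Cinv = np.linalg.inv(Cs)  # (n, t, t)

        low = [(c, Z) for c, Z in fw["lowrank"] if c in sig]
        if low:
            Zall = np.concatenate([Z for _, Z in low], axis=1)  # (n, L)
            L = Zall.shape[1]
            Sb = np.empty((L, t, t))  # per-level component covariance
            slices = {}
            off = 0
            for c, Z in low:
                q = Z.shape[1]
                Sb[off : off + q] = sig[c]
                slices[c] = slice(off, off + q)
                off += q
            # W[(r,a),(s,b)] = sum_i Z[i,a] Cinv[i,r,s] Z[i,b]
            W4 = np.einsum("ia,irs,ib->rasb", Zall, Cinv, Zall, optimize=True)
            WS = np.einsum("raqb,bqs->rasb", W4, Sb, optimize=True)
            tL = t * L
            M_inner = np.eye(tL) + WS.reshape(tL, tL)
            sgn, logdet_m = np.linalg.slogdet(M_inner)
            if sgn <= 0:
                return None
            Minv = np.linalg.inv(M_inner)
            # N = S Minv (symmetric): N[(r,a),(u,b)] = sum_s Sb[a,r,s] Minv[(s,a),(u,b)]
            Minv4 = Minv.reshape(t, L, t, L)
            N4 = np.einsum("ars,saub->raub", Sb, Minv4, optimize=True)
            N = N4.reshape(tL, tL)
            N = (N + N.T) / 2.0
        else:
            Zall = None
            N = None
            logdet_m = 0.0

        def cinv_apply(M):
            # M (t, n, k) -> C^{-1} M
            return np.einsum("nqr,rnk->qnk", Cinv, M, optimize=True)

        def vinv_apply(M):
            W1 = cinv_apply(M)
            if Zall is None:
                return W1
            g = np.einsum("ia,qik->qak", Zall, W1, optimize=True)
            k = M.shape[2]
            h = (N @ g.reshape(-1, k)).reshape(t, -1, k)
            Uh = np.einsum("ia,qak->qik", Zall, h, optimize=True)
            return W1 - cinv_apply(Uh)

        p0 = X0r.shape[1]
        # X columns (q, j): e_q (x) X0r[:, j]
        Xc = np.zeros((t, n, t * p0))
        for q in range(t):
            Xc[q, :, q * p0 : (q + 1) * p0] = X0r
        ViX = vinv_apply(Xc)  # (t, n, t*p0)
        XtViX = np.einsum("ij,qiA->qjA", X0r, ViX[:, :, :], optimize=True)
        # assemble (t*p0, t*p0): row (q, j)
        XtViX = np.concatenate(
            [XtViX[q].reshape(p0, t * p0) for q in range(t)], axis=0
        )
        XtViX = (XtViX + XtViX.T) / 2.0
        sgn, logdet_x = np.linalg.slogdet(XtViX)
        if sgn <= 0:
            return None
        Bx = np.linalg.inv(XtViX)
        Viy = vinv_apply(Yt[:, :, None])[:, :, 0]  # (t, n)
        Xty = np.einsum("ij,qi->qj", X0r, Viy).reshape(-1)
        beta = Bx @ Xty
        Py = Viy - np.einsum("qiA,A->qi", ViX, beta, optimize=True)
        ypy = float(np.sum(Yt * Py))
        logl = -0.5 * (logdet_c + logdet_m + logdet_x + ypy)
        if not derivs:
            return {"logl": logl}

        # --- derivative ingredients ----------------------------------
        # kernel descriptors in the rotated basis
        kdesc = {}
        for c in self._kernels:
            if c == "G":
                kdesc[c] = ("diag", lam)
            elif c == "R":
                kdesc[c] = ("diag", np.ones(n))
            else:
                kdesc[c] = ("low", slices[c])

        if Zall is not None:
            CU = np.einsum("iqr,ia->qira", Cinv, Zall, optimize=True)
            CU = CU.reshape(t, n, -1)  # (t, n, tL) columns (r, a)
            HN = np.stack([CU[q] @ N for q in range(t)])  # (t, n, tL)
            ZtCU = np.stack([Zall.T @ CU[q] for q in range(t)])  # (t, L, tL)
            ZtHN = np.stack([Zall.T @ HN[q] for q in range(t)])
            ZtRx = np.stack([Zall.T @ ViX[q] for q in range(t)])  # (t, L, tp0)
            ZtPy = Zall.T @ Py.T  # (L, t)

        T = {c: np.zeros((t, t)) for c in self._kernels}
        B = {c: np.zeros((t, t)) for c in self._kernels}
        for c, (kind, info) in kdesc.items():
            if kind == "diag":
                d = info
                # tr(C^{-1}(E_rs (x) K)) = sum_i d_i Cinv[i, s, r]
                t1 = np.einsum("i,isr->rs", d, Cinv, optimize=True)
                if Zall is not None:
                    t2 = np.einsum("i,ria,sia->rs", d, HN, CU, optimize=True)
                else:
                    t2 = 0.0
                t3 = np.einsum("i,riA,AB,siB->rs", d, ViX, Bx, ViX, optimize=True)
                T[c] = t1 - t2 - t3
                B[c] = (Py * d) @ Py.T
            else:
                sl = info
                Zc = Zall[:, sl]
                t1 = np.einsum("i,isr->rs", (Zc**2).sum(axis=1), Cinv, optimize=True)
                t2 = np.einsum("rdA,sdA->rs", ZtHN[:, sl, :], ZtCU[:, sl, :],
                               optimize=True)
                t3 = np.einsum("rdA,AB,sdB->rs", ZtRx[:, sl, :], Bx,
                               ZtRx[:, sl, :], optimize=True)
                T[c] = t1 - t2 - t3
                B[c] = ZtPy[sl].T @ ZtPy[sl]
            T[c] = (T[c] + T[c].T) / 2.0
            B[c] = (B[c] + B[c].T) / 2.0

        return {"logl": logl, "T": T, "B": B, "beta": beta}

    # ------------------------------------------------------------------
    def loglike(self, G=None, Mat=None, Pat=None, R=None) -> float:
        """Restricted log-likelihood at the given component matrices.

        Convention: ``-(log|V| + log|X'V^-1 X| + y'Py) / 2`` (no constant).
        Inactive components default to zero.
        """
        t = self.n_traits
        given = {"G": G, "Mat": Mat, "Pat": Pat, "R": R}
        sig = {}
        for c in self._kernels:
            M = given.get(c)
            sig[c] = np.zeros((t, t)) if M is None else np.asarray(M, float)
        return self._quick_logl(sig)

    def _quick_logl(self, sig) -> float:
        out = self._fast_core(sig, derivs=False)
        return -np.inf if out is None else out["logl"]

    def _full_eval(self, sig):
        scale = max(float(np.trace(sig["R"])) / self.n_traits, 0.0)
        jitter = 0.0
        for _ in range(8):
            trial = dict(sig)
            if jitter > 0.0:
                trial["R"] = sig["R"] + jitter * np.eye(self.n_traits)
            out = self._fast_core(trial, derivs=True)
            if out is not None:
                return out
            jitter = max(jitter * 10.0, 1e-10 * (scale + 1e-300))
        raise np.linalg.LinAlgError("covariance matrix not positive definite")

    # ------------------------------------------------------------------
    def _em_update(self, sig, ev, floor):
        new = {}
        for c in self._kernels:
            S = sig[c]
            q = self._levels[c]
            upd = S + (S @ (ev["B"][c] - ev["T"][c]) @ S) / q
            new[c] = _psd_clip(upd, floor if c == "R" else 0.0)
        return new

    def _overrelaxed_em(self, sig, ev, floor):
        """One EM move, extended by a doubling line search along the EM
        direction when that improves the restricted logL further.  Returns
        the best candidate; never decreases the likelihood."""
        em_sig = self._em_update(sig, ev, floor)
        best_sig, best_logl = em_sig, self._quick_logl(em_sig)
        if best_logl >= ev["logl"]:
            alpha = 2.0
            while alpha <= 1024.0:
                cand = {
                    c: _psd_clip(
                        sig[c] + alpha * (em_sig[c] - sig[c]),
                        floor if c == "R" else 0.0,
                    )
                    for c in sig
                }
                logl = self._quick_logl(cand)
                if np.isfinite(logl) and logl > best_logl + 1e-12:
                    best_sig, best_logl = cand, logl
                    alpha *= 2.0
                else:
                    break
        return best_sig

    def _lbfgs_polish(self, sig, scale, maxiter, path):
        """Quasi-Newton maximization over Cholesky factors of the components.

        L-BFGS with the analytic REML gradient (chain rule through
        Sigma_c = L_c L_c') handles the long flat ridges that arise when a
        component is weakly identified, where EM and average-information
        steps crawl.  ``path`` is extended with the best logL seen at each
        accepted iterate.  Returns (sig, n_evals).
        """
        from scipy.optimize import minimize

        t = self.n_traits
        comps = list(self._kernels)
        tril = [(i, j) for i in range(t) for j in range(i + 1)]
        m = len(tril)

        def unpack(x):
            ch = {}
            for k, c in enumerate(comps):
                Lc = np.zeros((t, t))
                for a, (i, j) in enumerate(tril):
                    Lc[i, j] = x[k * m + a]
                ch[c] = Lc
            return ch

        state = {"best": -np.inf}

        def obj(x):
            ch = unpack(x)
            sig_ = {c: ch[c] @ ch[c].T for c in comps}
            try:
                e = self._full_eval(sig_)
            except np.linalg.LinAlgError:
                return 1e12, np.zeros_like(x)
            g = np.zeros_like(x)
            for k, c in enumerate(comps):
                D = 0.5 * (e["B"][c] - e["T"][c])
                GL = 2.0 * D @ ch[c]
                for a, (i, j) in enumerate(tril):
                    g[k * m + a] = GL[i, j]
            state["best"] = max(state["best"], e["logl"])
            return -e["logl"], -g

        x0 = np.empty(len(comps) * m)
        for k, c in enumerate(comps):
            Lc = np.linalg.cholesky(sig[c] + 1e-14 * scale * np.eye(t))
            for a, (i, j) in enumerate(tril):
                x0[k * m + a] = Lc[i, j]
        res = minimize(
            obj, x0, jac=True, method="L-BFGS-B",
            callback=lambda xk: path.append(state["best"]),
            options={"maxiter": maxiter, "ftol": 1e-16, "gtol": 1e-12,
                     "maxcor": 30},
        )
        ch = unpack(res.x)
        out = {c: ch[c] @ ch[c].T for c in comps}
        return out, int(res.nfev)

    def fit(
        self,
        method: str = "hybrid",
        max_iter: int = 2000,
        tol_logl: float = 1e-8,
        tol_param: float = 1e-6,
        em_burnin: int = 10,
        start: Optional[dict] = None,
        verbose: bool = False,
    ) -> "AnimalModelResults":
        """Estimate the variance components by REML.

        ``method='hybrid'`` (default) runs over-relaxed EM burn-in followed
        by quasi-Newton (L-BFGS) refinement on Cholesky factors, repeating
        until stationary; ``method='em'`` uses pure EM updates, whose
        restricted logL trajectory is non-decreasing by construction.

        Convergence requires ``|dlogL| < tol_logl`` together with a
        negligible EM move (max relative parameter change of the EM update
        below ``tol_param``): the EM map's fixed points are exactly the
        REML stationary points, so a small EM move certifies stationarity.
        Non-convergence within ``max_iter`` likelihood evaluations yields
        ``converged=False``, not an exception.
        """
        if method not in ("hybrid", "em"):
            raise ValueError("method must be 'hybrid' or 'em'")
        t = self.n_traits
        S0 = np.cov(self.traits, rowvar=False).reshape(t, t)
        scale = float(np.trace(S0)) / t
        if scale < 1e-24:
            zero = np.zeros((t, t))
            log.info("zero-variance traits: returning null components")
            return AnimalModelResults(
                model=self, sig={c: zero.copy() for c in self._kernels},
                beta=np.zeros(self._X.shape[1]), loglike=np.nan, n_iter=0,
                converged=True, logl_path=[], method=method,
            )
        n_par = sum(t * (t + 1) // 2 for _ in self._kernels)
        if n_par > self.n_obs:
            log.warning(
                "%d covariance parameters exceed %d observation rows; "
                "fit proceeds but may be poorly identified", n_par, self.n_obs,
            )
        floor = 1e-12 * scale
        n_active = len(self._kernels)
        if start is None:
            sig = {c: _psd_clip(S0 / n_active, floor) for c in self._kernels}
        else:
            sig = {
                c: _psd_clip(np.asarray(start[c], float), floor)
                for c in self._kernels
            }
        ev = self._full_eval(sig)
        path = [ev["logl"]]
        converged = False
        n_iter = 0

        def check(dl, cur_sig, cur_ev):
            em_next = self._em_update(cur_sig, cur_ev, floor)
            dpar = max(
                float(np.max(np.abs(em_next[c] - cur_sig[c]))) / max(scale, 1e-300)
                for c in cur_sig
            )
            return (abs(dl) < tol_logl and dpar < tol_param), dpar

        while n_iter < max_iter and not converged:
            if method == "em":
                new_sig = self._em_update(sig, ev, floor)
                n_iter += 1
            elif n_iter < em_burnin:
                new_sig = self._overrelaxed_em(sig, ev, floor)
                n_iter += 1
            else:
                new_sig, nev = self._lbfgs_polish(
                    sig, scale, maxiter=min(500, max_iter - n_iter), path=path
                )
                n_iter += max(nev, 1)
            new_ev = self._full_eval(new_sig)
            dl = new_ev["logl"] - ev["logl"]
            sig, ev = new_sig, new_ev
            path.append(ev["logl"])
            converged, dpar = check(dl, sig, ev)
            if verbose:
                log.info(
                    "iter %d logL %.8f dlogL %.3e dpar %.3e",
                    n_iter, ev["logl"], dl, dpar,
                )
        full = {c: sig.get(c, np.zeros((t, t))) for c in COMPONENTS}
        return AnimalModelResults(
            model=self, sig=full, beta=ev["beta"], loglike=ev["logl"],
            n_iter=n_iter, converged=converged, logl_path=path, method=method,
        )


class AnimalModelResults:
    """REML estimates of the animal-model covariance components.

    Attributes ``G``, ``Mat``, ``Pat``, ``R`` are the t x t component
    matrices (zero where the component was excluded); ``P`` is their sum.
    ``logl_path`` records the restricted log-likelihood per iteration.
    """

    def __init__(self, model, sig, beta, loglike, n_iter, converged, logl_path, method):
        self.model = model
        self.G = sig["G"]
        self.Mat = sig["Mat"]
        self.Pat = sig["Pat"]
        self.R = sig["R"]
        self.beta = np.asarray(beta, float)
        self.loglike = loglike
        self.n_iter = int(n_iter)
        self.converged = bool(converged)
        self.logl_path = list(logl_path)
        self.method = method

    @property
    def P(self) -> np.ndarray:
        return self.G + self.Mat + self.Pat + self.R

    @property
    def components(self) -> dict[str, np.ndarray]:
        return {"G": self.G, "Mat": self.Mat, "Pat": self.Pat, "R": self.R}

    def variance_proportions(self) -> dict[str, float]:
        from .heritability import variance_proportions

        return variance_proportions(self)

    def heritability(self, pinv_rtol: float = 1e-10):
        """Multivariate heritability summary (GP-, MatP-, h2_max, angles)."""
        from .heritability import summarize

        return summarize(self, pinv_rtol=pinv_rtol)

    def summary(self) -> str:
        t = self.model.n_traits
        lines = [
            "Animal model REML results",
            "=" * 58,
            f"observations: {self.model.n_obs}   traits: {t}   "
            f"method: {self.method}",
            f"iterations: {self.n_iter}   converged: {self.converged}",
            f"restricted logL: {self.loglike:.6f}",
            "",
            "trace proportions of P:",
        ]
        props = self.variance_proportions()
        lines.append(
            "  " + "  ".join(f"{c}: {props[c]:.4f}" for c in COMPONENTS)
        )
        lines.append("")
        for c, M in self.components.items():
            lines.append(f"{c} (trace {np.trace(M):.6g}):")
            for row in M:
                lines.append("  " + "  ".join(f"{v: .5e}" for v in row))
        lines.append("")
        lines.append("fixed effects (per trait, columns = design):")
        p0 = self.model.X0.shape[1]
        for r in range(t):
            seg = self.beta[r * p0 : (r + 1) * p0]
            lines.append(f"  trait {r + 1}: " + "  ".join(f"{v: .5e}" for v in seg))
        return "\n".join(lines)

    def save_components(self, directory, prefix: str = "") -> None:
        """Write G, Mat, Pat, R and P as labeled delimited matrices."""
        import os

        t = self.model.n_traits
        names = [f"trait{i + 1}" for i in range(t)]
        for label, M in {**self.components, "P": self.P}.items():
            df = pd.DataFrame(M, index=names, columns=names)
            df.to_csv(os.path.join(directory, f"{prefix}{label}.csv"))


def reml_fit(
    traits,
    individual_ids,
    pedigree: Pedigree,
    covariate=None,
    dam_ids=None,
    sire_ids=None,
    components: Sequence[str] = COMPONENTS,
    **fit_kwargs,
) -> AnimalModelResults:
    """Convenience wrapper: build an :class:`AnimalModel` and fit it."""
    model = AnimalModel(
        traits=traits,
        individual_ids=individual_ids,
        pedigree=pedigree,
        covariate=covariate,
        dam_ids=dam_ids,
        sire_ids=sire_ids,
        components=components,
    )
    return model.fit(**fit_kwargs)
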