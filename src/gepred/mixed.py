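"""Pedigree-based animal model: relationship matrix, REML, BLUP, pre-adjustment.

The model is the standard animal model with a maternal permanent-environment
term,

    y = X theta + Z u + W c + e,

with u ~ N(0, A sigma2_u) for the additive genetic effect (A the numerator
relationship matrix from the pedigree), c ~ N(0, I sigma2_c) for the
dam-associated permanent environment, and e ~ N(0, I sigma2_e).  Variance
components are estimated by REML — EM iterations on Henderson's mixed-model
equations, optionally accelerated with average-information (AI) updates once
the EM warm-up has stabilised the estimates.  The fitted results provide
BLUP solutions and the pre-adjusted phenotype

    y* = y - X theta_hat - W c_hat,

which deliberately retains the additive genetic signal (u_hat is NOT
subtracted): y* is the response passed to the whole-genome regression and
neural-network predictors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "VarianceComponents", "MixedModelSpec", "AnimalModel", "AnimalModelResults",
    "build_relationship_matrix", "reml_variance_components", "blup_solve",
    "preadjust", "variance_ratios", "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the iteration trajectory."""

    def __init__(self, message, trajectory=None):
        super().__init__(message)
        self.trajectory = trajectory


@dataclass
class VarianceComponents:
    """Variance components of the animal model, in squared trait units."""

    sigma2_u: float
    sigma2_c: float
    sigma2_e: float

    def __post_init__(self):
        if min(self.sigma2_u, self.sigma2_c, self.sigma2_e) < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def phenotypic(self) -> float:
        return self.sigma2_u + self.sigma2_c + self.sigma2_e

    @property
    def h2(self) -> float:
        return variance_ratios(self)[1]

    @property
    def c2(self) -> float:
        return variance_ratios(self)[2]

    def as_tuple(self):
        return (self.sigma2_u, self.sigma2_c, self.sigma2_e)


def variance_ratios(vc: VarianceComponents):
    """Return (phenotypic variance, h2, c2) from the components."""
    total = vc.sigma2_u + vc.sigma2_c + vc.sigma2_e
    if total <= 0:
        raise ValueError("zero total variance: ratios undefined")
    return total, vc.sigma2_u / total, vc.sigma2_c / total


def build_relationship_matrix(pedigree: pd.DataFrame):
    """Numerator relationship matrix A by the tabular method.

    Parameters
    ----------
    pedigree : DataFrame with columns id, sire, dam
        Parent code "0" (or NaN) means unknown; unknown parents contribute
        as unrelated founders.  Rows may be in any order: a topological
        order (parents before offspring) is derived internally and a cyclic
        pedigree raises ValueError.

    Returns
    -------
    A : ndarray (q, q) in the topological order
    ids : list of str, the id corresponding to each row/column of A
    """
    ped = pedigree.copy()
    for col in ("id", "sire", "dam"):
        ped[col] = ped[col].fillna("0").astype(str)
    ids = list(ped["id"])
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in pedigree")
    parents = {r.id: (r.sire, r.dam) for r in ped.itertuples()}

    # Kahn-style topological ordering over the parent->offspring DAG
    order, state = [], {}

    def visit(node):
        stack = [(node, False)]
        while stack:
            cur, processed = stack.pop()
            if processed:
                state[cur] = 2
                order.append(cur)
                continue
            if state.get(cur) == 1:
                raise ValueError("cyclic pedigree")
            if state.get(cur) == 2 or cur == "0" or cur not in parents:
                continue
            state[cur] = 1
            stack.append((cur, True))
            for p in parents[cur]:
                if p != "0" and p in parents and state.get(p) != 2:
                    if state.get(p) == 1:
                        raise ValueError("cyclic pedigree")
                    stack.append((p, False))

    for i in ids:
        visit(i)

    idx = {iid: k for k, iid in enumerate(order)}
    q = len(order)
    A = np.zeros((q, q))
    for i, iid in enumerate(order):
        s, d = parents[iid]
        si = idx.get(s, -1) if s != "0" else -1
        di = idx.get(d, -1) if d != "0" else -1
        a_sd = A[si, di] if (si >= 0 and di >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        for j in range(i):
            aij = 0.0
            if si >= 0:
                aij += 0.5 * A[j, si]
            if di >= 0:
                aij += 0.5 * A[j, di]
            A[i, j] = A[j, i] = aij
    return A, order


@dataclass
class MixedModelSpec:
    """Design matrices and relationship matrix for one animal-model fit.

    W (maternal incidence) and A may be None: W=None drops the maternal
    term, A=None means unrelated genetic levels (identity).
    """

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    W: np.ndarray = None
    A: np.ndarray = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        n = len(self.y)
        if self.X.shape[0] != n or self.Z.shape[0] != n:
            raise ValueError("design matrix row counts disagree with y")
        if self.W is not None:
            self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
            if self.W.shape[0] != n:
                raise ValueError("W row count disagrees with y")
        if self.A is not None:
            self.A = np.asarray(self.A, dtype=float)
            if self.A.shape != (self.Z.shape[1],) * 2:
                raise ValueError("A dimension disagrees with Z columns")


class AnimalModel:
    """Animal model y = X theta + Z u + W c + e fitted by REML.

    Build directly from design matrices via a :class:`MixedModelSpec`, or
    from tidy phenotype + pedigree tables with :meth:`from_dataframe`.
    """

    def __init__(self, spec: MixedModelSpec):
        self.spec = spec
        s = spec
        self.n = len(s.y)
        self.p = s.X.shape[1]
        self.q = s.Z.shape[1]
        self.d = 0 if s.W is None else s.W.shape[1]
        if np.linalg.matrix_rank(s.X) < self.p:
            raise ValueError("X is rank-deficient: drop reference levels first")
        self._Ainv = None
        self._logdetA = 0.0
        if s.A is not None:
            sign, logdet = np.linalg.slogdet(s.A)
            if sign <= 0:
                raise ValueError("A is not positive definite")
            self._logdetA = logdet
            self._Ainv = np.linalg.inv(s.A)
        # constant cross-product blocks
        X, Z, W, y = s.X, s.Z, s.W, s.y
        self._XtX, self._XtZ, self._ZtZ = X.T @ X, X.T @ Z, Z.T @ Z
        self._Xty, self._Zty, self._yty = X.T @ y, Z.T @ y, y @ y
        if W is not None:
            self._XtW, self._ZtW, self._WtW = X.T @ W, Z.T @ W, W.T @ W
            self._Wty = W.T @ y

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, phenotypes: pd.DataFrame, pedigree: pd.DataFrame,
                       trait: str = "weight", fixed=("sex", "contemporary_group"),
                       dam_col: str = "dam", maternal: bool = True):
        """Assemble the model from tidy tables.

        Fixed factors are dummy-coded with one reference level dropped per
        factor plus a global intercept.  The maternal term indexes each
        record's dam; records with unknown dam get their own singleton
        maternal level.
        """
        phen = phenotypes.reset_index(drop=True)
        y = phen[trait].to_numpy(dtype=float)
        n = len(phen)
        X_parts = [np.ones((n, 1))]
        for f in fixed:
            dummies = pd.get_dummies(phen[f].astype(str), prefix=f, drop_first=True)
            if dummies.shape[1]:
                X_parts.append(dummies.to_numpy(dtype=float))
        X = np.hstack(X_parts)
        A, order = build_relationship_matrix(pedigree)
        idx = {iid: k for k, iid in enumerate(order)}
        Z = np.zeros((n, len(order)))
        for i, iid in enumerate(phen["id"].astype(str)):
            Z[i, idx[iid]] = 1.0
        W = None
        if maternal:
            dams = phen[dam_col].fillna("0").astype(str)
            levels = [d if d != "0" else f"self:{iid}"
                      for d, iid in zip(dams, phen["id"].astype(str))]
            uniq = sorted(set(levels))
            pos = {l: k for k, l in enumerate(uniq)}
            W = np.zeros((n, len(uniq)))
            for i, l in enumerate(levels):
                W[i, pos[l]] = 1.0
        model = cls(MixedModelSpec(y=y, X=X, Z=Z, W=W, A=A))
        model.animal_ids = order
        return model

    # ------------------------------------------------------------------
    def _mme(self, sigma2_u, sigma2_c, sigma2_e):
        """Coefficient matrix (lambda form) and right-hand side."""
        lam_u = sigma2_e / sigma2_u
        top = [np.hstack([self._XtX, self._XtZ]),
               np.hstack([self._XtZ.T, self._ZtZ + lam_u * (
                   self._Ainv if self._Ainv is not None else np.eye(self.q))])]
        rhs = [self._Xty, self._Zty]
        if self.d:
            lam_c = sigma2_e / sigma2_c
            top[0] = np.hstack([top[0], self._XtW])
            top[1] = np.hstack([top[1], self._ZtW])
            bottom = np.hstack([self._XtW.T, self._ZtW.T,
                                self._WtW + lam_c * np.eye(self.d)])
            C = np.vstack([np.vstack(top), bottom])
            rhs.append(self._Wty)
        else:
            C = np.vstack(top)
        return C, np.concatenate(rhs)

    def _solve_mme(self, sigma2_u, sigma2_c, sigma2_e, need_inverse=False):
        C, rhs = self._mme(sigma2_u, sigma2_c, sigma2_e)
        try:
            cf = cho_factor(C, lower=True)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular mixed-model equations: {exc}")
        s = cho_solve(cf, rhs)
        Cinv = cho_solve(cf, np.eye(C.shape[0])) if need_inverse else None
        logdetC = 2.0 * np.sum(np.log(np.diag(cf[0])))
        return s, cf, Cinv, logdetC, rhs

    def _unpack(self, s):
        theta = s[:self.p]
        u = s[self.p:self.p + self.q]
        c = s[self.p + self.q:] if self.d else np.zeros(0)
        return theta, u, c

    def reml_loglik(self, vc: VarianceComponents) -> float:
        """Restricted log-likelihood (up to an additive constant)."""
        s2u, s2c, s2e = vc.sigma2_u, max(vc.sigma2_c, 1e-300), vc.sigma2_e
        s, _, _, logdetC, rhs = self._solve_mme(s2u, s2c, s2e)
        ypy = (self._yty - s @ rhs) / s2e
        dim = self.p + self.q + self.d
        ll = -(logdetC + self._logdetA + self.q * np.log(s2u)
               + (self.d * np.log(s2c) if self.d else 0.0)
               + (self.n - dim) * np.log(s2e) + ypy)
        return 0.5 * ll

    # ------------------------------------------------------------------
    def fit(self, start=None, tol=1e-8, max_iter=500, method="em+ai",
            ai_warmup=3, floor_frac=1e-6) -> "AnimalModelResults":
        """Estimate variance components by REML and solve the MME.

        Parameters
        ----------
        start : VarianceComponents, optional
            Starting values; defaults to an even split of Var(y).
        tol : float
            Relative-change convergence threshold on every component.
        method : {"em", "em+ai"}
            Pure EM (monotone in the restricted likelihood) or EM warm-up
            followed by average-information steps with EM fallback.
        floor_frac : float
            Components are pinned at floor_frac * Var(y) if an update goes
            non-positive.
        """
        if self.n <= self.p:
            raise ValueError("need n > rank(X) for REML")
        vary = float(np.var(self.spec.y, ddof=1))
        floor = floor_frac * vary
        if start is None:
            share = vary / (3 if self.d else 2)
            start = VarianceComponents(share, share if self.d else floor, share)
        s2u, s2c, s2e = (max(start.sigma2_u, floor),
                         max(start.sigma2_c, floor) if self.d else 0.0,
                         max(start.sigma2_e, floor))
        traj = []
        converged = False
        pin_c = pin_u = False
        Ainv = self._Ainv if self._Ainv is not None else np.eye(self.q)
        for it in range(max_iter):
            sol, cf, Cinv, logdetC, rhs = self._solve_mme(
                s2u, s2c if self.d else 1.0, s2e, need_inverse=True)
            theta, u, c = self._unpack(sol)
            ypy = (self._yty - sol @ rhs) / s2e
            dim = self.p + self.q + self.d
            ll = 0.5 * -(logdetC + self._logdetA + self.q * np.log(s2u)
                         + (self.d * np.log(s2c) if self.d else 0.0)
                         + (self.n - dim) * np.log(s2e) + ypy)
            traj.append((s2u, s2c, s2e, ll))

            Cuu = Cinv[self.p:self.p + self.q, self.p:self.p + self.q]
            tr_u = float(np.sum(Ainv * Cuu))
            uAu = float(u @ Ainv @ u)
            if self.d:
                Ccc = Cinv[self.p + self.q:, self.p + self.q:]
                tr_c = float(np.trace(Ccc))
                cc = float(c @ c)
            # EM updates
            new_u = (uAu + s2e * tr_u) / self.q
            new_c = ((cc + s2e * tr_c) / self.d) if self.d else 0.0
            resid = self.spec.y - self.spec.X @ theta - self.spec.Z @ u
            if self.d:
                resid = resid - self.spec.W @ c
            new_e = float((self._yty - sol @ rhs) / (self.n - self.p))

            # a component driven to a negligible share of the total variance
            # is a boundary estimate: freeze it and drop it from the AI
            # update and the convergence criterion (EM stagnates there and
            # the likelihood is flat in that direction)
            total_now = s2u + s2c + s2e
            pin_c = pin_c or (self.d and s2c < 1e-3 * total_now
                              and abs(new_c - s2c) < 1e-3 * max(s2c, floor))
            pin_u = pin_u or (s2u < 1e-3 * total_now
                              and abs(new_u - s2u) < 1e-3 * max(s2u, floor))

            use_ai = method == "em+ai" and it >= ai_warmup
            if use_ai and not pin_u:
                stepped = self._ai_step(
                    s2u, s2c, s2e, resid, tr_u, uAu, u, c, cf, floor,
                    tr_c if self.d else None, cc if self.d else None,
                    include_c=self.d and not pin_c)
                if stepped is not None:
                    cand = stepped
                    # accept AI step only if it improves the restricted
                    # likelihood; otherwise keep the safe EM update
                    try:
                        ll_cand = self.reml_loglik(
                            VarianceComponents(cand[0], cand[1], cand[2]))
                    except Exception:
                        ll_cand = -np.inf
                    if ll_cand >= ll - 1e-8 * (1.0 + abs(ll)):
                        new_u, new_c, new_e = cand
            if pin_u:
                new_u = min(s2u, max(new_u, floor))
            new_u = max(new_u, floor)
            new_e = max(new_e, floor)
            if self.d:
                new_c = max(new_c, floor) if not pin_c else min(s2c, max(new_c, floor))
            rel = max((abs(new_u - s2u) / max(s2u, floor)) if not pin_u else 0.0,
                      abs(new_e - s2e) / max(s2e, floor),
                      (abs(new_c - s2c) / max(s2c, floor))
                      if (self.d and not pin_c) else 0.0)
            s2u, s2c, s2e = new_u, new_c, new_e
            if rel < tol:
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                f"REML did not converge in {max_iter} iterations", trajectory=traj)
        vc = VarianceComponents(s2u, s2c if self.d else 0.0, s2e)
        theta, u, c = blup_solve(self, vc)
        return AnimalModelResults(self, vc, theta, u, c, traj, converged=True)

    def _ai_step(self, s2u, s2c, s2e, resid, tr_u, uAu, u, c, cf, floor,
                 tr_c=None, cc=None, include_c=None):
        """One average-information Newton step; None if it fails.

        ``include_c=False`` holds a floored maternal component fixed and
        performs the Newton update on the remaining components only.
        """
        if include_c is None:
            include_c = bool(self.d)
        X, Z, W = self.spec.X, self.spec.Z, self.spec.W
        f_vecs = [Z @ u / s2u]
        if include_c:
            f_vecs.append(W @ c / s2c)
        f_vecs.append(resid / s2e)
        # P f via an MME solve with f as data vector
        Pf = []
        for f in f_vecs:
            rhs_f = [X.T @ f, Z.T @ f] + ([W.T @ f] if self.d else [])
            sol_f = cho_solve(cf, np.concatenate(rhs_f))
            th_f, u_f, c_f = self._unpack(sol_f)
            r_f = f - X @ th_f - Z @ u_f
            if self.d:
                r_f = r_f - W @ c_f
            Pf.append(r_f / s2e)
        k = len(f_vecs)
        AI = np.empty((k, k))
        for i in range(k):
            for j in range(i, k):
                AI[i, j] = AI[j, i] = 0.5 * float(f_vecs[i] @ Pf[j])
        # first derivatives from MME trace identities
        g = []
        tr_PH_u = self.q / s2u - s2e * tr_u / s2u ** 2
        g.append(-0.5 * (tr_PH_u - uAu / s2u ** 2))
        if self.d:
            tr_PH_c = self.d / s2c - s2e * tr_c / s2c ** 2
            if include_c:
                g.append(-0.5 * (tr_PH_c - cc / s2c ** 2))
        else:
            tr_PH_c = 0.0
        tr_P = (self.n - self.p - s2u * tr_PH_u - (s2c * tr_PH_c if self.d else 0.0)) / s2e
        g.append(-0.5 * (tr_P - float(resid @ resid) / s2e ** 2))
        try:
            delta = np.linalg.solve(AI, np.array(g))
        except np.linalg.LinAlgError:
            return None
        theta_now = np.array([s2u] + ([s2c] if include_c else []) + [s2e])
        # step-halve into the positive orthant
        for _ in range(8):
            cand = theta_now + delta
            if np.all(cand > floor / 2):
                if include_c:
                    return float(cand[0]), float(cand[1]), float(cand[2])
                return float(cand[0]), s2c, float(cand[1])
            delta = delta / 2
        return None


class AnimalModelResults:
    """REML/BLUP results: variance components, solutions, pre-adjustment."""

    def __init__(self, model, vc, theta, u, c, trajectory, converged):
        self.model = model
        self.vc = vc
        self.theta = theta
        self.u = u
        self.c = c
        self.trajectory = trajectory
        self.converged = converged
        self.n_iter = len(trajectory)

    @property
    def variance_ratios(self):
        return variance_ratios(self.vc)

    def preadjusted(self) -> np.ndarray:
        """y* = y - X theta_hat - W c_hat (breeding values retained)."""
        s = self.model.spec
        W = s.W
        c_hat = self.c if W is not None else None
        return preadjust(s.y, s.X, W, self.theta, c_hat)

    def summary(self) -> str:
        total, h2, c2 = self.variance_ratios
        lines = [
            "Animal model REML results",
            "=" * 44,
            f"records             {self.model.n:>12d}",
            f"fixed effects (p)   {self.model.p:>12d}",
            f"genetic levels (q)  {self.model.q:>12d}",
            f"maternal levels     {self.model.d:>12d}",
            f"iterations          {self.n_iter:>12d}",
            "-" * 44,
            f"sigma2_u (additive) {self.vc.sigma2_u:>12.2f}",
            f"sigma2_c (maternal) {self.vc.sigma2_c:>12.2f}",
            f"sigma2_e (residual) {self.vc.sigma2_e:>12.2f}",
            f"phenotypic variance {total:>12.2f}",
            f"h2                  {h2:>12.3f}",
            f"c2                  {c2:>12.3f}",
            "=" * 44,
        ]
        return "\n".join(lines)


# ----------------------------------------------------------------------
# functional surface


def reml_variance_components(spec: MixedModelSpec, tol=1e-8, max_iter=500,
                             method="em+ai") -> VarianceComponents:
    """REML point estimates for (sigma2_u, sigma2_c, sigma2_e)."""
    return AnimalModel(spec).fit(tol=tol, max_iter=max_iter, method=method).vc


def blup_solve(model_or_spec, vc: VarianceComponents):
    """Solve Henderson's MME at fixed variance components.

    Returns (theta_hat, u_hat, c_hat); c_hat is empty when no maternal term.
    """
    model = (model_or_spec if isinstance(model_or_spec, AnimalModel)
             else AnimalModel(model_or_spec))
    if vc.sigma2_u <= 0 or vc.sigma2_e <= 0:
        raise ValueError("variance components of included terms must be positive")
    if model.d and vc.sigma2_c <= 0:
        raise ValueError("sigma2_c must be positive when a maternal term is present")
    sol, _, _, _, _ = model._solve_mme(vc.sigma2_u,
                                       vc.sigma2_c if model.d else 1.0,
                                       vc.sigma2_e)
    return model._unpack(sol)


def preadjust(y, X, W, theta_hat, c_hat):
    """Pre-adjusted phenotype y* = y - X theta_hat - W c_hat."""
    y = np.asarray(y, dtype=float).ravel()
    out = y - np.asarray(X, dtype=float) @ np.asarray(theta_hat, dtype=float)
    if W is not None and c_hat is not None and len(np.atleast_1d(c_hat)):
        out = out - np.asarray(W, dtype=float) @ np.asarray(c_hat, dtype=float)
    return out
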