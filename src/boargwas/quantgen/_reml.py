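"""Average-information REML for the repeatability animal model.

Estimates (sigma_a2, sigma_p2, sigma_e2) for

    y = X beta + Z a + W p + e,
    Var(y) = Z A Z' sigma_a2 + W W' sigma_p2 + I sigma_e2

by Newton steps on the average-information matrix, computed through the
mixed-model equations so the cost per iteration is one Cholesky of the
coefficient matrix (order: fixed effects + pedigree animals + animals with
records). An AI step that would leave the parameter space is halved up to
10 times and then replaced by an EM step, which cannot leave the space.

Identities used (standard MME/REML algebra): with C the lambda-scaled MME
coefficient matrix and Cinv its inverse,

    tr(P Z A Z') = (q - lam_a * tr(Ainv Caa)) / sigma_a2
    tr(P W W')   = (r - lam_p * tr(Cpp)) / sigma_p2
    tr(P) = (n - p - sum of the two terms above * sigma_i2) / sigma_e2
    P t = (t - X b_t - Z a_t - W p_t) / sigma_e2   (MME solved with t as data)

and -2 logL_R = log|C| + (n-p-q-r) log sigma_e2 + q log sigma_a2
                + r log sigma_p2 + log|A| + y'Py  (additive constant dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from ..types import PhenotypeTable
from ._amatrix import RelationshipMatrix
from ._design import ModelFrame, build_model_frame

__all__ = ["VarianceComponents", "RemlError", "reml_repeatability"]

_FLOOR_FRAC = 1e-8  # components floored at this fraction of var(y)


class RemlError(RuntimeError):
    """REML failure; carries the iteration trajectory when available."""

    def __init__(self, message, trajectory=None):
        super().__init__(message)
        self.trajectory = trajectory or []


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_p2: float
    sigma_e2: float
    se: dict = field(default_factory=dict)
    log_likelihood: float = float("nan")
    converged: bool = False
    n_iterations: int = 0
    trait: str = ""

    @property
    def total(self) -> float:
        return self.sigma_a2 + self.sigma_p2 + self.sigma_e2

    @property
    def h2(self) -> float:
        return self.sigma_a2 / self.total

    @property
    def repeatability(self) -> float:
        return (self.sigma_a2 + self.sigma_p2) / self.total


class _MmeWorkspace:
    """Precomputed data-dependent MME blocks; G-inverse blocks vary per iter."""

    def __init__(self, frame: ModelFrame):
        x, y = frame.x, frame.y
        ra, rp = frame.record_animal, frame.record_pe
        self.n, self.p = x.shape
        self.q = len(frame.animals)
        self.r = len(frame.pe_animals)
        self.frame = frame
        self.xtx = x.T @ x
        za_x = np.zeros((self.q, self.p))
        np.add.at(za_x, ra, x)
        self.xtza = za_x.T
        wp_x = np.zeros((self.r, self.p))
        np.add.at(wp_x, rp, x)
        self.xtwp = wp_x.T
        self.counts_a = np.bincount(ra, minlength=self.q).astype(float)
        self.counts_p = np.bincount(rp, minlength=self.r).astype(float)
        # Za'Wp: records pair animal i with its own PE level only
        self.za_wp = np.zeros((self.q, self.r))
        np.add.at(self.za_wp, (ra, rp), 1.0)
        self.a_inv = np.linalg.inv(frame.a_matrix)
        sign, self.logdet_a = np.linalg.slogdet(frame.a_matrix)
        if sign <= 0:
            raise RemlError("relationship matrix is not positive definite")
        self.yty = float(y @ y)
        self.xty = x.T @ y
        self.zaty = np.bincount(ra, weights=y, minlength=self.q)
        self.wpty = np.bincount(rp, weights=y, minlength=self.r)
        self.sl_x = slice(0, self.p)
        self.sl_a = slice(self.p, self.p + self.q)
        self.sl_p = slice(self.p + self.q, self.p + self.q + self.r)

    def coefficient_matrix(self, lam_a: float, lam_p: float) -> np.ndarray:
        dim = self.p + self.q + self.r
        c = np.zeros((dim, dim))
        c[self.sl_x, self.sl_x] = self.xtx
        c[self.sl_x, self.sl_a] = self.xtza
        c[self.sl_a, self.sl_x] = self.xtza.T
        c[self.sl_x, self.sl_p] = self.xtwp
        c[self.sl_p, self.sl_x] = self.xtwp.T
        c[self.sl_a, self.sl_a] = np.diag(self.counts_a) + lam_a * self.a_inv
        c[self.sl_a, self.sl_p] = self.za_wp
        c[self.sl_p, self.sl_a] = self.za_wp.T
        c[self.sl_p, self.sl_p] = np.diag(self.counts_p + lam_p)
        return c

    def rhs_for(self, t: np.ndarray) -> np.ndarray:
        frame = self.frame
        return np.concatenate(
            [
                frame.x.T @ t,
                np.bincount(frame.record_animal, weights=t, minlength=self.q),
                np.bincount(frame.record_pe, weights=t, minlength=self.r),
            ]
        )

    def fitted(self, sol: np.ndarray) -> np.ndarray:
        frame = self.frame
        return (
            frame.x @ sol[self.sl_x]
            + sol[self.sl_a][frame.record_animal]
            + sol[self.sl_p][frame.record_pe]
        )


def _iterate(ws: _MmeWorkspace, theta: np.ndarray):
    """One evaluation at theta: solutions, traces, gradient, AI, logL."""
    sa2, sp2, se2 = theta
    lam_a, lam_p = se2 / sa2, se2 / sp2
    c = ws.coefficient_matrix(lam_a, lam_p)
    cho = cho_factor(c, lower=True)
    rhs = np.concatenate([ws.xty, ws.zaty, ws.wpty])
    sol = cho_solve(cho, rhs)
    c_inv = cho_solve(cho, np.eye(c.shape[0]))
    a_hat = sol[ws.sl_a]
    p_hat = sol[ws.sl_p]
    y = ws.frame.y
    e_hat = y - ws.fitted(sol)
    tr_a = float(np.sum(ws.a_inv * c_inv[ws.sl_a, ws.sl_a]))
    tr_p = float(np.trace(c_inv[ws.sl_p, ws.sl_p]))
    quad_a = float(a_hat @ ws.a_inv @ a_hat)
    quad_p = float(p_hat @ p_hat)

    tr_pza = (ws.q - lam_a * tr_a) / sa2
    tr_pwp = (ws.r - lam_p * tr_p) / sp2
    tr_pmat = (ws.n - ws.p - tr_pza * sa2 - tr_pwp * sp2) / se2
    grad = -0.5 * np.array(
        [
            tr_pza - quad_a / sa2**2,
            tr_pwp - quad_p / sp2**2,
            tr_pmat - float(e_hat @ e_hat) / se2**2,
        ]
    )

    # AI matrix: t_i' P t_j with P t via an MME solve per working vector
    ra, rp = ws.frame.record_animal, ws.frame.record_pe
    t_vecs = [a_hat[ra] / sa2, p_hat[rp] / sp2, e_hat / se2]
    p_times = []
    for t in t_vecs:
        sol_t = cho_solve(cho, ws.rhs_for(t))
        p_times.append((t - ws.fitted(sol_t)) / se2)
    ai = np.empty((3, 3))
    for i in range(3):
        for j in range(i, 3):
            ai[i, j] = ai[j, i] = 0.5 * float(t_vecs[i] @ p_times[j])

    logdet_c = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    y_py = (ws.yty - float(sol @ rhs)) / se2
    minus2l = (
        logdet_c
        + (ws.n - ws.p - ws.q - ws.r) * np.log(se2)
        + ws.q * np.log(sa2)
        + ws.r * np.log(sp2)
        + ws.logdet_a
        + y_py
    )
    em = np.array(
        [
            (quad_a + tr_a * se2) / ws.q,
            (quad_p + tr_p * se2) / ws.r,
            float(e_hat @ y) / (ws.n - ws.p),
        ]
    )
    return {
        "logl": -0.5 * minus2l,
        "grad": grad,
        "ai": ai,
        "em": em,
        "sol": sol,
        "c_inv": c_inv,
    }


def reml_repeatability(
    phenotypes: PhenotypeTable,
    a: RelationshipMatrix,
    trait: str,
    max_iter: int = 100,
    tol: float = 1e-8,
    start: tuple | None = None,
) -> VarianceComponents:
    """AI-REML variance components for one trait.

    Returns estimates, asymptotic standard errors from the inverse AI
    matrix (including delta-method SEs for h2 and repeatability), the
    restricted log-likelihood and a convergence flag. Raises
    :class:`RemlError` (with the trajectory attached) on non-convergence.
    """
    frame = build_model_frame(phenotypes, a, trait)
    if np.max(np.bincount(frame.record_pe)) < 2:
        raise RemlError(
            "no animal has repeated records; sigma_p2 is unidentifiable"
        )
    ws = _MmeWorkspace(frame)
    vy = float(np.var(frame.y, ddof=1))
    floor = _FLOOR_FRAC * vy
    theta = np.array(start) if start is not None else vy * np.array([0.3, 0.2, 0.5])
    state = _iterate(ws, theta)
    trajectory = [(theta.copy(), state["logl"])]
    converged = False
    n_done = 0
    for it in range(1, max_iter + 1):
        n_done = it
        try:
            step = np.linalg.solve(state["ai"], state["grad"])
        except np.linalg.LinAlgError:
            step = None
        new_theta = None
        new_state = None
        if step is not None:
            cand = theta + step
            for _ in range(10):
                if np.all(cand > floor):
                    cand_state = _iterate(ws, cand)
                    if cand_state["logl"] >= state["logl"] - 1e-10:
                        new_theta, new_state = cand, cand_state
                        break
                cand = theta + (cand - theta) / 2.0
        if new_theta is None:  # EM fallback: guaranteed inside the space
            cand = np.maximum(state["em"], floor)
            new_theta, new_state = cand, _iterate(ws, cand)
        delta_l = new_state["logl"] - state["logl"]
        theta, state = new_theta, new_state
        trajectory.append((theta.copy(), state["logl"]))
        if abs(delta_l) < tol:
            converged = True
            break
    if not converged:
        raise RemlError(
            f"REML did not converge in {max_iter} iterations for {trait!r}",
            trajectory=trajectory,
        )
    sa2, sp2, se2 = theta
    try:
        cov = np.linalg.inv(state["ai"])
        se_comp = np.sqrt(np.maximum(np.diag(cov), 0.0))
        total = theta.sum()
        g_h2 = np.array([total - sa2, -sa2, -sa2]) / total**2
        g_re = (
            np.array([total - sa2 - sp2, total - sa2 - sp2, -(sa2 + sp2)])
            / total**2
        )
        se = {
            "sigma_a2": float(se_comp[0]),
            "sigma_p2": float(se_comp[1]),
            "sigma_e2": float(se_comp[2]),
            "h2": float(np.sqrt(max(g_h2 @ cov @ g_h2, 0.0))),
            "repeatability": float(np.sqrt(max(g_re @ cov @ g_re, 0.0))),
        }
    except np.linalg.LinAlgError:
        se = {}
    return VarianceComponents(
        sigma_a2=float(sa2),
        sigma_p2=float(sp2),
        sigma_e2=float(se2),
        se=se,
        log_likelihood=float(state["logl"]),
        converged=True,
        n_iterations=n_done,
        trait=trait,
    )
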