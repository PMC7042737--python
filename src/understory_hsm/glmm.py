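"""Binomial (Bernoulli) mixed models with crossed random intercepts.

The breeding-success model is a logistic GLMM:

    logit P(success) = X beta + u_year + u_female + u_male,
    u_g ~ Normal(0, sigma_g^2), crossed (not nested).

Fitting maximizes the Laplace approximation to the marginal likelihood.
For fixed standard deviations ``sigma`` the fixed effects and random-effect
modes are found jointly by penalized iteratively reweighted least squares
(PIRLS); the profiled Laplace objective

    l(sigma) = sum_i [y_i eta_i - log(1 + e^{eta_i})] - b'b/2
               - log det(Lambda' Z' W Z Lambda + I) / 2

(with scaled effects u = sigma * b) locates good starting values; a joint
BFGS polish over (beta, log sigma) then maximizes the exact Laplace
objective, matching lme4's glmer.  Wald standard errors come from the
fixed-effect block of the
inverse joint penalized Hessian at the optimum, conditional on the
estimated variance components — the same convention as the standard mixed
model packages.

Also here: AICc, the latent-scale marginal/conditional R² for logit GLMMs
(distribution-specific variance pi²/3), variance inflation factors, and the
model-selection procedures built on repeated fits (understory transform
choice, settlement-distance breakpoint scan, breakpoint sensitivity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import linalg as sla
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

from .config import RunConfig

log = logging.getLogger(__name__)

__all__ = [
    "MixedLogitFit",
    "fit_mixed_logit",
    "laplace_loglik",
    "aicc",
    "r2_glmm",
    "vif",
    "build_design",
    "fit_breeding_model",
    "transform_selection",
    "breakpoint_scan",
    "breakpoint_sensitivity",
]

_LOG_SIGMA_BOUNDS = (-8.0, 2.5)
_SIGMA_FLOOR = 1e-3  # below this an estimated SD is reported as boundary zero


# ---------------------------------------------------------------------------
# containers


@dataclass
class MixedLogitFit:
    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    sigma2: dict[str, float]
    loglik: float
    n: int
    k: int
    converged: bool
    fixed_linpred: np.ndarray
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    group_names: list[str] = field(default_factory=list)
    ranef_modes: dict = field(default_factory=dict, repr=False)
    n_iter: int = 0
    opt_hinv: np.ndarray | None = field(default=None, repr=False)

    def warm_start(self) -> tuple:
        """(beta, sigma, inverse-Hessian) triple to seed a neighbouring fit."""
        sigma = np.sqrt(np.maximum(list(self.sigma2.values()), 1e-6))
        return (self.beta, sigma, self.opt_hinv)

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.se

    @property
    def p_values(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.z))

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k, self.n)

    def coef(self, term: str) -> tuple[float, float]:
        i = self.terms.index(term)
        return float(self.beta[i]), float(self.se[i])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.beta,
                "se": self.se,
                "z": self.z,
                "p": self.p_values,
            },
            index=self.terms,
        )


# ---------------------------------------------------------------------------
# linear-algebra helpers


def _make_codes(groups: dict[str, np.ndarray]) -> tuple[list[np.ndarray], list[str], list[int]]:
    """Integer level codes per grouping factor; factors with < 2 levels dropped."""
    codes_list, names, sizes = [], [], []
    for name, codes in groups.items():
        _, idx = np.unique(np.asarray(codes), return_inverse=True)
        q_g = int(idx.max()) + 1
        if q_g < 2:
            log.warning("random factor %s has < 2 levels; dropped", name)
            continue
        codes_list.append(idx.astype(np.intp))
        names.append(name)
        sizes.append(q_g)
    return codes_list, names, sizes


class _LaplaceProblem:
    """Shared state for repeated Laplace-objective evaluations at one dataset.

    All linear algebra exploits the crossed-intercept structure directly on
    the factor level codes: each factor's own block of the penalized
    Hessian is diagonal, the smallest factor is Schur-complemented out, and
    the remaining factors couple only through shared observations, which
    splits their block into many small connected components (e.g.
    breeding-pair lineages) factorized in size-batched dense operations.
    A factorization therefore costs O(n + q) rather than a sparse LU.
    """

    def __init__(self, y, X, codes: list[np.ndarray], sizes: list[int]):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        self.codes = codes
        self.sizes = sizes
        self.g = len(sizes)
        self.offsets = np.concatenate([[0], np.cumsum(sizes)]).astype(int)
        self.q = int(self.offsets[-1])
        self._prepare_structure()

    # -- structure precomputation (pattern only; reused by every factorization)

    def _prepare_structure(self):
        if self.g <= 1:
            self.outer_g = None
            return
        sizes = self.sizes
        self.outer_g = int(np.argmin(sizes))
        self.inner_gs = [g for g in range(self.g) if g != self.outer_g]
        in_sizes = [sizes[g] for g in self.inner_gs]
        in_off = np.concatenate([[0], np.cumsum(in_sizes)]).astype(int)
        self.b_dim = int(in_off[-1])
        self.a_dim = sizes[self.outer_g]
        # inner position of each observation per inner factor
        self.inner_pos = {
            g: self.codes[g] + in_off[k] for k, g in enumerate(self.inner_gs)
        }
        # global q-index -> inner position (for rhs reordering)
        inner_global = np.concatenate(
            [np.arange(self.offsets[g], self.offsets[g + 1]) for g in self.inner_gs]
        )
        outer_global = np.arange(
            self.offsets[self.outer_g], self.offsets[self.outer_g + 1]
        )
        self.inner_global = inner_global
        self.outer_global = outer_global

        # connected components of the inner co-occurrence graph
        rows, cols = [], []
        for i in range(len(self.inner_gs)):
            for j in range(i + 1, len(self.inner_gs)):
                pi = self.inner_pos[self.inner_gs[i]]
                pj = self.inner_pos[self.inner_gs[j]]
                rows.append(pi)
                cols.append(pj)
        if rows:
            r = np.concatenate(rows)
            c = np.concatenate(cols)
            pattern = sp.coo_matrix(
                (np.ones(r.size), (r, c)), shape=(self.b_dim, self.b_dim)
            ).tocsr()
            from scipy.sparse.csgraph import connected_components

            _, labels = connected_components(pattern, directed=False)
        else:
            labels = np.arange(self.b_dim)

        # order component members; group components by size for batching
        order = np.argsort(labels, kind="stable")
        lab_sorted = labels[order]
        comp_starts = np.flatnonzero(np.r_[True, lab_sorted[1:] != lab_sorted[:-1]])
        comp_ends = np.r_[comp_starts[1:], lab_sorted.size]
        comp_members = [order[s:e] for s, e in zip(comp_starts, comp_ends)]
        by_size: dict[int, list[np.ndarray]] = {}
        for members in comp_members:
            by_size.setdefault(members.size, []).append(members)
        self.size_groups = []  # (s, members (m, s) inner positions)
        grp_of = np.empty(self.b_dim, dtype=np.intp)  # size-group id per inner pos
        mem_of = np.empty(self.b_dim, dtype=np.intp)  # component row within group
        loc_of = np.empty(self.b_dim, dtype=np.intp)  # local index within component
        for k, (s, groups_) in enumerate(sorted(by_size.items())):
            members = np.vstack(groups_)
            self.size_groups.append((s, members))
            m_idx, l_idx = np.divmod(np.arange(members.size), s)
            grp_of[members.ravel()] = k
            mem_of[members.ravel()] = m_idx
            loc_of[members.ravel()] = l_idx
        self.grp_of, self.mem_of, self.loc_of = grp_of, mem_of, loc_of

        # flat scatter indices for the block diagonals (per size group)
        self.diag_scatter = []
        for k, (s, members) in enumerate(self.size_groups):
            pos = members.ravel()
            flat = mem_of[pos] * s * s + loc_of[pos] * s + loc_of[pos]
            self.diag_scatter.append((pos, flat))
        # flat scatter indices for the off-diagonal pair entries (per size
        # group, per inner-factor pair), both symmetric halves concatenated
        self.pair_scatter = []  # (gi, gj, group k, obs_idx, flat_indices)
        for i in range(len(self.inner_gs)):
            for j in range(i + 1, len(self.inner_gs)):
                gi, gj = self.inner_gs[i], self.inner_gs[j]
                pi, pj = self.inner_pos[gi], self.inner_pos[gj]
                k_obs = grp_of[pi]  # same component, hence same group
                for k, (s, members) in enumerate(self.size_groups):
                    obs_idx = np.flatnonzero(k_obs == k)
                    if obs_idx.size == 0:
                        continue
                    base = mem_of[pi[obs_idx]] * s * s
                    f1 = base + loc_of[pi[obs_idx]] * s + loc_of[pj[obs_idx]]
                    f2 = base + loc_of[pj[obs_idx]] * s + loc_of[pi[obs_idx]]
                    self.pair_scatter.append(
                        (gi, gj, k, obs_idx, np.concatenate([f1, f2]))
                    )
        # flat scatter for the outer-inner cross block C (a x b)
        self.c_scatter = {
            g: self.codes[self.outer_g] * self.b_dim + self.inner_pos[g]
            for g in self.inner_gs
        }

    # -- per-evaluation pieces

    def _zb(self, lam: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Z Lambda b as gathers: sum_g lam_g b_g[code_g]."""
        out = np.zeros(self.n)
        for g in range(self.g):
            out += lam[g] * b[self.offsets[g] : self.offsets[g + 1]][self.codes[g]]
        return out

    def _ztr(self, lam: np.ndarray, r: np.ndarray) -> np.ndarray:
        """Lambda Z' r as weighted bincounts."""
        if self.g == 0:
            return np.zeros(0)
        return np.concatenate(
            [
                lam[g] * np.bincount(self.codes[g], weights=r, minlength=self.sizes[g])
                for g in range(self.g)
            ]
        )

    def hxz(self, lam: np.ndarray, w: np.ndarray) -> np.ndarray:
        """Cross block X' W Z Lambda (p x q), dense."""
        out = np.empty((self.p, self.q))
        for g in range(self.g):
            for j in range(self.p):
                out[j, self.offsets[g] : self.offsets[g + 1]] = lam[g] * np.bincount(
                    self.codes[g], weights=w * self.X[:, j], minlength=self.sizes[g]
                )
        return out

    def factorize(self, lam: np.ndarray, w: np.ndarray):
        """Factor Hq = Lambda Z' W Z Lambda + I at the given weights."""
        cnt = [
            np.bincount(self.codes[g], weights=w, minlength=self.sizes[g])
            for g in range(self.g)
        ]
        if self.g == 0:
            return _EmptyFactor()
        if self.g == 1:
            return _DiagFactor(1.0 + lam[0] ** 2 * cnt[0])
        a_diag = 1.0 + lam[self.outer_g] ** 2 * cnt[self.outer_g]
        d_inner = np.concatenate(
            [1.0 + lam[g] ** 2 * cnt[g] for g in self.inner_gs]
        )
        blocks_flat = [np.zeros(members.size * s) for s, members in self.size_groups]
        for k, (pos, flat) in enumerate(self.diag_scatter):
            np.add.at(blocks_flat[k], flat, d_inner[pos])
        for gi, gj, k, obs_idx, flat in self.pair_scatter:
            wgt = lam[gi] * lam[gj] * w[obs_idx]
            s = self.size_groups[k][0]
            blocks_flat[k] += np.bincount(
                flat, weights=np.concatenate([wgt, wgt]), minlength=blocks_flat[k].size
            )
        blocks = [
            bf.reshape(members.shape[0], s, s)
            for bf, (s, members) in zip(blocks_flat, self.size_groups)
        ]
        lam_o = lam[self.outer_g]
        c_flat = np.zeros(self.a_dim * self.b_dim)
        for g in self.inner_gs:
            c_flat += lam_o * lam[g] * np.bincount(
                self.c_scatter[g], weights=w, minlength=self.a_dim * self.b_dim
            )
        C = c_flat.reshape(self.a_dim, self.b_dim)
        return _StructuredFactor(self, a_diag, C, blocks)


    def _cond_loglik(self, eta: np.ndarray) -> float:
        # sum y*eta - log(1 + exp(eta)), stable
        return float(self.y @ eta - np.logaddexp(0.0, eta).sum())

    def pirls(self, sigma, beta0=None, b0=None, fix_beta=None, tol=1e-9, max_iter=100):
        """Joint penalized Newton over (beta, b); returns the mode and factor.

        With ``fix_beta`` set only the random-effect modes are optimized
        (used when evaluating the Laplace likelihood at given parameters).
        The factorization is reused across iterations (chord steps) while
        full steps are accepted, refreshed when progress stalls, and rebuilt
        once at the mode for the log-determinant.
        """
        y, X = self.y, self.X
        lam = np.asarray(sigma, dtype=float)
        profile_beta = fix_beta is None
        beta = (
            np.zeros(self.p) if beta0 is None else beta0.copy()
        ) if profile_beta else np.asarray(fix_beta, dtype=float)
        b = np.zeros(self.q) if b0 is None else b0.copy()

        eta = X @ beta + self._zb(lam, b)
        obj = self._cond_loglik(eta) - 0.5 * (b @ b)
        cache = None
        refresh = True
        for _ in range(max_iter):
            mu = expit(eta)
            w = np.maximum(mu * (1.0 - mu), 1e-10)
            r = y - mu
            if refresh or cache is None:
                factor = self.factorize(lam, w)
                if profile_beta:
                    Hxz = self.hxz(lam, w)
                    Hxx = X.T @ (X * w[:, None])
                    S = Hxx - Hxz @ factor.solve(Hxz.T)
                    try:
                        S_chol, S_pinv = sla.cho_factor(S), None
                    except sla.LinAlgError:
                        S_chol, S_pinv = None, np.linalg.pinv(S)
                else:
                    Hxz, S_chol, S_pinv = None, None, None
                cache = (factor, Hxz, S_chol, S_pinv)
                refresh = False
            factor, Hxz, S_chol, S_pinv = cache

            g_b = self._ztr(lam, r) - b
            if profile_beta:
                g_x = X.T @ r
                rhs = g_x - Hxz @ factor.solve(g_b)
                d_beta = sla.cho_solve(S_chol, rhs) if S_chol is not None else S_pinv @ rhs
                d_b = factor.solve(g_b - Hxz.T @ d_beta)
            else:
                d_beta = np.zeros(self.p)
                d_b = factor.solve(g_b)

            step = 1.0
            for _ in range(25):
                beta_new = beta + step * d_beta
                b_new = b + step * d_b
                eta_new = X @ beta_new + self._zb(lam, b_new)
                obj_new = self._cond_loglik(eta_new) - 0.5 * (b_new @ b_new)
                if obj_new >= obj - 1e-12:
                    break
                step *= 0.5
            if step < 1.0:
                refresh = True  # stale Hessian no longer trustworthy
            delta = obj_new - obj
            beta, b, eta, obj = beta_new, b_new, eta_new, obj_new
            if abs(delta) < tol and step == 1.0:
                break
        # fresh factorization at the mode for the log-determinant
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        factor = self.factorize(lam, w)
        return beta, b, eta, obj, factor, w, lam

    def laplace(self, sigma, beta0=None, b0=None, fix_beta=None):
        beta, b, eta, obj, factor, w, lam = self.pirls(
            sigma, beta0=beta0, b0=b0, fix_beta=fix_beta
        )
        ll = obj - 0.5 * factor.logdet()
        return ll, beta, b, factor, w, lam


class _EmptyFactor:
    def solve(self, rhs):
        return np.zeros_like(rhs)

    def logdet(self):
        return 0.0


class _DiagFactor:
    """A single random factor gives a purely diagonal penalized Hessian."""

    def __init__(self, d: np.ndarray):
        self.d = d

    def solve(self, rhs):
        if rhs.ndim == 1:
            return rhs / self.d
        return rhs / self.d[:, None]

    def logdet(self):
        return float(np.sum(np.log(self.d)))


class _StructuredFactor:
    """Schur-complement factorization for two or more crossed factors.

    ``logdet Hq = logdet B + logdet(A - C B^-1 C')`` with A the (diagonal)
    outer-factor block, B the inner block held as batched dense component
    inverses, and C the dense outer-inner cross block.
    """

    def __init__(self, prob: "_LaplaceProblem", a_diag, C, blocks):
        self.prob = prob
        self.C = C
        logdet_b = 0.0
        self._inv = []
        for blk in blocks:
            sign, ld = np.linalg.slogdet(blk)
            logdet_b += float(ld.sum())
            self._inv.append(np.linalg.inv(blk))
        BinvCt = np.empty((prob.b_dim, a_diag.size))
        Ct = C.T
        for inv, (s, members) in zip(self._inv, prob.size_groups):
            BinvCt[members.ravel()] = np.einsum(
                "mij,mjk->mik", inv, Ct[members]
            ).reshape(-1, a_diag.size)
        self.BinvCt = BinvCt
        S = np.diag(a_diag) - C @ BinvCt
        self.S_chol = sla.cho_factor(S)
        self._logdet = logdet_b + 2.0 * float(
            np.sum(np.log(np.diag(self.S_chol[0])))
        )

    def _binv(self, r):
        out = np.empty_like(r)
        for inv, (s, members) in zip(self._inv, self.prob.size_groups):
            if r.ndim == 1:
                gathered = r[members]  # (m, s)
                out[members.ravel()] = np.einsum("mij,mj->mi", inv, gathered).ravel()
            else:
                gathered = r[members]  # (m, s, k)
                out[members.reshape(-1)] = np.einsum(
                    "mij,mjk->mik", inv, gathered
                ).reshape(-1, r.shape[1])
        return out

    def solve(self, rhs):
        rhs = np.asarray(rhs)
        prob = self.prob
        r_out = rhs[prob.outer_global]
        r_in = rhs[prob.inner_global]
        wv = self._binv(r_in)
        t = r_out - self.C @ wv
        ysol = sla.cho_solve(self.S_chol, t)
        fmsol = wv - self.BinvCt @ ysol
        out = np.empty_like(rhs, dtype=float)
        out[prob.outer_global] = ysol
        out[prob.inner_global] = fmsol
        return out

    def logdet(self):
        return self._logdet


# ---------------------------------------------------------------------------
# fitting


def laplace_loglik(y, X, groups, beta, sigma) -> float:
    """Laplace marginal log-likelihood at fixed (beta, sigma).

    Random-effect modes are optimized internally; used for cross-checking
    against numerical-integration oracles.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    codes, names, sizes = _make_codes(dict(groups))
    prob = _LaplaceProblem(y, X, codes, sizes)
    sigma = np.asarray(sigma, dtype=float)
    ll, *_ = prob.laplace(sigma, fix_beta=np.asarray(beta, dtype=float))
    return ll



def _bfgs_minimize(fun, x0, lower, upper, hinv0=None, gtol=0.01, eps=1e-5, maxiter=60):
    """Projected BFGS with forward-difference gradients.

    Small custom loop so a carried-over inverse-Hessian estimate (e.g. from
    the previous candidate of a model scan) keeps repeated nearby fits
    cheap.  Returns (x, f, hinv, converged, n_evals).
    """
    x = np.clip(np.asarray(x0, dtype=float), lower, upper)
    n = x.size
    nev = [0]

    def f(xx):
        nev[0] += 1
        return fun(xx)

    def grad(xx, f0):
        g = np.empty(n)
        for i in range(n):
            step = eps * max(1.0, abs(xx[i]))
            xi = xx.copy()
            xi[i] = min(xi[i] + step, upper[i]) if xi[i] + step > upper[i] else xi[i] + step
            if xi[i] == xx[i]:
                xi[i] = xx[i] - step
                g[i] = (f0 - f(xi)) / step
            else:
                g[i] = (f(xi) - f0) / (xi[i] - xx[i])
        return g

    hinv = np.eye(n) if hinv0 is None else hinv0.copy()
    f0 = f(x)
    g = grad(x, f0)
    converged = False
    for _ in range(maxiter):
        # at active bounds, drop components of the gradient pointing outward
        g_eff = g.copy()
        g_eff[(x <= lower + 1e-12) & (g_eff > 0)] = 0.0
        g_eff[(x >= upper - 1e-12) & (g_eff < 0)] = 0.0
        if np.max(np.abs(g_eff)) < gtol:
            converged = True
            break
        d = -hinv @ g_eff
        if d @ g_eff > -1e-14:  # not a descent direction: reset curvature
            hinv = np.eye(n)
            d = -g_eff
        t = 1.0
        fx = f0
        for _ in range(30):
            x_new = np.clip(x + t * d, lower, upper)
            fx = f(x_new)
            if fx <= f0 + 1e-4 * (g_eff @ (x_new - x)):
                break
            t *= 0.5
        s = x_new - x
        if np.max(np.abs(s)) < 1e-12:
            converged = np.max(np.abs(g_eff)) < 10 * gtol
            break
        g_new = grad(x_new, fx)
        yk = g_new - g
        sy = s @ yk
        if sy > 1e-12:  # standard BFGS inverse update
            rho = 1.0 / sy
            I = np.eye(n)
            hinv = (I - rho * np.outer(s, yk)) @ hinv @ (I - rho * np.outer(yk, s)) \
                + rho * np.outer(s, s)
        x, f0, g = x_new, fx, g_new
    return x, f0, hinv, converged, nev[0]


def fit_mixed_logit(
    y,
    X,
    terms: list[str],
    groups: dict[str, np.ndarray],
    start: tuple | None = None,
    gtol: float = 5e-3,
) -> MixedLogitFit:
    """Fit the logistic mixed model by Laplace maximum likelihood.

    ``groups`` maps factor name -> per-observation level codes.  Factors with
    fewer than two levels are dropped with a warning.  The fit is
    deterministic: the default start is the plain logistic fit for beta and
    sigma^2 = 0.1 for every variance component.  ``start`` may carry
    ``(beta, sigma)`` or a ``fit.warm_start()`` triple including the
    optimizer's inverse-Hessian estimate, for cheap refits of neighbouring
    models.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n != y.size:
        raise ValueError("y and X disagree on n")
    codes, names, sizes = _make_codes(dict(groups))
    prob = _LaplaceProblem(y, X, codes, sizes)
    g = len(names)

    hinv0 = None
    if start is not None:
        beta0, sigma0 = np.asarray(start[0], float), np.asarray(start[1], float)
        if len(start) > 2 and start[2] is not None and start[2].shape == (p + g, p + g):
            hinv0 = np.asarray(start[2], float)
        if beta0.size != p or sigma0.size != g:
            beta0, sigma0, hinv0 = _plain_logistic(y, X), np.full(g, np.sqrt(0.1)), None
            start = None
    else:
        beta0 = _plain_logistic(y, X)
        sigma0 = np.full(g, np.sqrt(0.1))

    state = {"beta": beta0.copy(), "b": np.zeros(prob.q), "neval": 0}

    def objective(log_sigma: np.ndarray) -> float:
        sigma = np.exp(log_sigma)
        ll, beta, b, *_ = prob.laplace(sigma, beta0=state["beta"], b0=state["b"])
        state["beta"], state["b"] = beta, b
        state["neval"] += 1
        return -ll

    def joint_objective(x: np.ndarray) -> float:
        beta, sigma = x[:p], np.exp(x[p:])
        ll, _, b, *_ = prob.laplace(sigma, fix_beta=beta, b0=state["b"])
        state["b"] = b
        state["neval"] += 1
        return -ll

    converged = True
    if g > 0:
        if start is None:
            # stage 1: profile beta through PIRLS while locating sigma (cheap)
            res = minimize(
                objective,
                np.log(np.maximum(sigma0, 1e-6)),
                method="L-BFGS-B",
                bounds=[_LOG_SIGMA_BOUNDS] * g,
                options={"ftol": 1e-8, "gtol": 5e-4, "eps": 1e-4, "maxiter": 100},
            )
            x0 = np.concatenate([state["beta"], res.x])
        else:
            # warm start from a neighbouring fit: go straight to the joint stage
            x0 = np.concatenate([beta0, np.log(np.maximum(sigma0, 1e-6))])
        # stage 2: joint Laplace maximum over (beta, log sigma), the same
        # objective mixed-model packages maximize; beta now sees the
        # log-determinant term
        lower = np.r_[np.full(p, -np.inf), np.full(g, _LOG_SIGMA_BOUNDS[0])]
        upper = np.r_[np.full(p, np.inf), np.full(g, _LOG_SIGMA_BOUNDS[1])]
        xh, fh, hinv, converged, nev = _bfgs_minimize(
            joint_objective, x0, lower, upper, hinv0=hinv0, gtol=gtol
        )
        if not converged:  # robust fallback on the same objective
            res2 = minimize(
                joint_objective,
                xh,
                method="L-BFGS-B",
                bounds=[(None, None)] * p + [list(_LOG_SIGMA_BOUNDS)] * g,
                options={"ftol": 1e-10, "gtol": 1e-4, "eps": 1e-5, "maxiter": 200},
            )
            xh, converged = res2.x, bool(res2.success) or res2.status == 1
            hinv = None
        beta_hat, sigma_hat = xh[:p], np.exp(xh[p:])
        ll, beta, b, Hq_factor, w, lam = prob.laplace(
            sigma_hat, fix_beta=beta_hat, b0=state["b"]
        )
        beta = beta_hat
    else:
        hinv = None
        sigma_hat = np.zeros(0)
        ll, beta, b, Hq_factor, w, lam = prob.laplace(
            sigma_hat, beta0=state["beta"], b0=state["b"]
        )
    # Wald covariance: Schur complement of the q-block in the joint Hessian
    Hxx = X.T @ (X * w[:, None])
    if prob.q:
        Hxz = prob.hxz(lam, w)
        S = Hxx - Hxz @ Hq_factor.solve(Hxz.T)
    else:
        S = Hxx
    cov = _safe_inv(S)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    sigma2 = {}
    modes = {}
    off = 0
    for name, size, s_hat in zip(names, sizes, sigma_hat):
        s2 = float(s_hat**2) if s_hat > _SIGMA_FLOOR else 0.0
        if s2 == 0.0:
            log.info("variance component %s estimated at the boundary (0)", name)
        sigma2[name] = s2
        modes[name] = s_hat * b[off : off + size]
        off += size

    return MixedLogitFit(
        terms=list(terms),
        beta=beta,
        se=se,
        sigma2=sigma2,
        loglik=float(ll),
        n=n,
        k=p + g,
        converged=converged,
        fixed_linpred=X @ beta,
        X=X,
        y=y,
        group_names=names,
        ranef_modes=modes,
        n_iter=state["neval"],
        opt_hinv=hinv,
    )


def _plain_logistic(y, X, max_iter=50) -> np.ndarray:
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-10)
        try:
            delta = np.linalg.solve((X * w[:, None]).T @ X, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            break
        beta = beta + delta
        if np.max(np.abs(delta)) < 1e-10:
            break
        if np.max(np.abs(beta)) > 50:  # separation guard
            break
    return beta


def _safe_inv(S: np.ndarray) -> np.ndarray:
    try:
        return sla.inv(S)
    except sla.LinAlgError:
        return np.linalg.pinv(S)


# ---------------------------------------------------------------------------
# closed-form summaries


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 loglik + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def r2_glmm(fit: MixedLogitFit) -> tuple[float, float]:
    """Latent-scale marginal and conditional R² for the logit mixed model.

    sigma²_f is the variance of the fixed-effect linear predictor over the
    observations; the logit distribution-specific variance is pi²/3.
    """
    var_f = float(np.var(fit.fixed_linpred))
    var_r = float(sum(fit.sigma2.values()))
    denom = var_f + var_r + np.pi**2 / 3.0
    return var_f / denom, (var_f + var_r) / denom


def vif(X: np.ndarray, terms: list[str]) -> dict[str, float]:
    """Variance inflation factors 1/(1-R²) for each non-intercept column."""
    X = np.asarray(X, dtype=float)
    is_intercept = [np.allclose(X[:, j], X[0, j]) for j in range(X.shape[1])]
    cols = [j for j in range(X.shape[1]) if not is_intercept[j]]
    if len(cols) < 2:
        raise ValueError("VIF needs at least 2 non-intercept columns")
    out = {}
    ones = np.ones((X.shape[0], 1))
    for j in cols:
        others = np.column_stack([ones] + [X[:, m : m + 1] for m in cols if m != j])
        yj = X[:, j]
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
        out[terms[j]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


# ---------------------------------------------------------------------------
# the breeding-success model and its selection procedures


def build_design(
    df: pd.DataFrame,
    breakpoint: float,
    config: RunConfig | None = None,
    ud_transform: str = "log",
    ud_col: str = "ud_nest",
    forest_cover_col: str | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str], dict[str, np.ndarray]]:
    """Assemble (y, X, terms, groups) for the breeding-success GLMM.

    Fixed effects: intercept, study area (unmanaged), proximity to
    settlements (close = distance < breakpoint), the understory term(s)
    under the requested transform, and close x understory interaction(s).
    Random intercepts: year and both breeder identities.
    """
    config = config or RunConfig()
    y = df["success"].to_numpy(dtype=float)
    close = (df["dist_settlement"].to_numpy(dtype=float) < breakpoint).astype(float)
    unmanaged = (df["area"].astype(str).str.lower() == "unmanaged").to_numpy(dtype=float)
    ud = df[ud_col].to_numpy(dtype=float)

    if ud_transform == "log":
        u = np.log(np.maximum(ud, config.ud_log_floor))
        ud_terms = [("log_ud", u)]
    elif ud_transform == "linear":
        ud_terms = [("ud", ud)]
    elif ud_transform == "quadratic":
        ud_terms = [("ud", ud), ("ud_sq", ud**2)]
    else:
        raise ValueError(f"unknown ud transform {ud_transform!r}")

    if config.center_covariates:
        ud_terms = [(nm, v - v.mean()) for nm, v in ud_terms]

    cols = [("intercept", np.ones_like(y)), ("area_unmanaged", unmanaged), ("close", close)]
    cols += ud_terms
    cols += [(f"close_x_{nm}", close * v) for nm, v in ud_terms]
    if forest_cover_col is not None:
        fc = df[forest_cover_col].to_numpy(dtype=float)
        if np.std(fc) < 1e-3:
            # (near-)constant cover, e.g. fully forested buffers, would
            # duplicate the intercept or act as a pure leverage column;
            # drop it rather than fit a (near-)singular design
            log.info("forest cover is (near-)constant; column dropped from the design")
        else:
            if config.center_covariates:
                fc = fc - fc.mean()
            cols.append(("forest_cover", fc))

    terms = [nm for nm, _ in cols]
    X = np.column_stack([v for _, v in cols])
    groups = {
        "year": df["year"].to_numpy(),
        "breeder_f": df["breeder_f"].to_numpy(),
        "breeder_m": df["breeder_m"].to_numpy(),
    }
    return y, X, terms, groups


def fit_breeding_model(
    df: pd.DataFrame,
    breakpoint: float,
    config: RunConfig | None = None,
    ud_transform: str = "log",
    ud_col: str = "ud_nest",
    forest_cover_col: str | None = None,
    start=None,
) -> MixedLogitFit:
    y, X, terms, groups = build_design(
        df, breakpoint, config, ud_transform, ud_col, forest_cover_col
    )
    return fit_mixed_logit(y, X, terms, groups, start=start)


def transform_selection(
    df: pd.DataFrame,
    breakpoint: float,
    config: RunConfig | None = None,
    ud_col: str = "ud_nest",
) -> pd.DataFrame:
    """AICc comparison of log vs linear vs quadratic understory terms."""
    rows = []
    for tf in ("log", "linear", "quadratic"):
        fit = fit_breeding_model(df, breakpoint, config, ud_transform=tf, ud_col=ud_col)
        rows.append(
            {
                "transform": tf,
                "aicc": fit.aicc,
                "loglik": fit.loglik,
                "k": fit.k,
                "n": fit.n,
                "converged": fit.converged,
            }
        )
    table = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    table["delta_aicc"] = table["aicc"] - table["aicc"].min()
    return table


def breakpoint_scan(
    df: pd.DataFrame,
    config: RunConfig | None = None,
    ud_transform: str = "log",
    ud_col: str = "ud_nest",
    min_class_size: int = 10,
) -> tuple[float, pd.DataFrame]:
    """AICc scan over candidate settlement-distance breakpoints.

    Candidates come from the configured grid (default 500-3,500 m by 50 m)
    clipped to the 10th-90th percentile of observed nest distances (rounded
    to the grid step).  Candidates leaving fewer than ``min_class_size``
    nests in either proximity class are skipped.  Ties break toward the
    smaller distance.
    """
    config = config or RunConfig()
    dist = df["dist_settlement"].to_numpy(dtype=float)
    step = config.breakpoint_grid[2]
    lo = np.round(np.percentile(dist, 10) / step) * step
    hi = np.round(np.percentile(dist, 90) / step) * step
    candidates = config.breakpoint_candidates()
    candidates = candidates[(candidates >= lo) & (candidates <= hi)]
    if candidates.size == 0:
        raise ValueError("no breakpoint candidates inside the distance percentiles")

    rows = []
    start = None
    for D in candidates:
        n_close = int((dist < D).sum())
        n_far = dist.size - n_close
        if min(n_close, n_far) < min_class_size:
            rows.append({"breakpoint": D, "aicc": np.nan, "n_close": n_close,
                         "n_far": n_far, "skipped": True})
            continue
        fit = fit_breeding_model(
            df, D, config, ud_transform=ud_transform, ud_col=ud_col, start=start
        )
        start = fit.warm_start()
        rows.append(
            {
                "breakpoint": D,
                "aicc": fit.aicc,
                "n_close": n_close,
                "n_far": n_far,
                "skipped": False,
            }
        )
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["aicc"])
    if valid.empty:
        raise ValueError("every breakpoint candidate was skipped")
    best = float(valid.loc[valid["aicc"].idxmin(), "breakpoint"])  # first min = smaller D
    return best, table


def breakpoint_sensitivity(
    df: pd.DataFrame,
    low: float,
    high: float,
    config: RunConfig | None = None,
    step: float = 50.0,
    ud_transform: str = "log",
    ud_col: str = "ud_nest",
) -> pd.DataFrame:
    """Interaction estimate ± SE across a range of breakpoints.

    A row is flagged when the estimate ± one SE interval crosses zero, i.e.
    the interaction loses its sign at that breakpoint choice.
    """
    config = config or RunConfig()
    rows = []
    start = None
    inter_term = "close_x_log_ud" if ud_transform == "log" else "close_x_ud"
    for D in np.arange(low, high + 0.5 * step, step):
        fit = fit_breeding_model(
            df, D, config, ud_transform=ud_transform, ud_col=ud_col, start=start
        )
        start = fit.warm_start()
        est, se = fit.coef(inter_term)
        rows.append(
            {
                "breakpoint": float(D),
                "estimate": est,
                "se": se,
                "crosses_zero": bool((est - se) <= 0.0 <= (est + se)),
            }
        )
    return pd.DataFrame(rows)
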