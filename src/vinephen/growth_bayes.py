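"""Hierarchical Bayesian fitting of a Richards growth curve with exponential decay.

Shoot biomass of a staked vine genotype ``g`` at time ``t`` (days after
transplanting, DAP) is modelled as a generalized-logistic (Richards) rise
multiplied by an exponential senescence term:

    f(t; theta_g) = A * (1 + nu * exp(-k (t - t_i)))^(-1/nu) * exp(-d (t - t_d))

with ``theta_g = (A, nu, k, t_i, d, t_d)``: asymptotic maximum biomass ``A``
(g/plant), curvature ``nu`` (dimensionless, controls asymmetry around the
inflection), intrinsic growth-rate constant ``k`` (1/day), inflection time
``t_i`` (DAP), decay-rate constant ``d`` (1/day) and decay onset ``t_d`` (DAP).

Two decay modes are provided. ``"as_printed"`` applies the decay factor at all
times (so the factor exceeds 1 before ``t_d``); ``"gated"`` replaces it by 1
for ``t < t_d`` so that ``t_d`` is literally the onset of decay.

Observations ``y ~ Normal(f(t; theta_g), sigma_obs)`` are pooled across
genotypes through a hierarchical prior ``phi_g ~ Normal(mu0, diag(tau^2))`` on
the transformed scale ``phi = (log A, log nu, log k, t_i, log d, t_d)``,
sampled with a No-U-Turn sampler (multinomial tree sampling, dual-averaging
step-size adaptation, diagonal mass matrix) over a non-centered
parameterization. Convergence is reported as split-chain Gelman-Rubin R-hat
and effective sample size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

logger = logging.getLogger("vinephen.growth_bayes")

PARAM_NAMES = ("A", "nu", "k", "t_i", "d", "t_d")
#: transformed-scale component names; log for positive-only parameters
TRANSFORMED_NAMES = ("log_A", "log_nu", "log_k", "t_i", "log_d", "t_d")
#: indices of phi components that live on the log scale
_LOG_IDX = np.array([0, 1, 2, 4])

DECAY_MODES = ("as_printed", "gated")


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthParams:
    """Genotype-level parameter vector of the Richards-with-decay curve."""

    A: float
    nu: float
    k: float
    t_i: float
    d: float
    t_d: float

    def __post_init__(self) -> None:
        if not (self.A > 0 and self.nu > 0 and self.k > 0):
            raise ValueError("A, nu and k must be strictly positive")
        if self.d < 0:
            raise ValueError("decay rate d must be non-negative")
        vals = [self.A, self.nu, self.k, self.t_i, self.d, self.t_d]
        if not all(np.isfinite(vals)):
            raise ValueError("growth parameters must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.nu, self.k, self.t_i, self.d, self.t_d])

    def transformed(self) -> np.ndarray:
        """phi = (log A, log nu, log k, t_i, log d, t_d)."""
        arr = self.as_array()
        phi = arr.copy()
        phi[_LOG_IDX] = np.log(arr[_LOG_IDX])
        return phi

    @classmethod
    def from_transformed(cls, phi: np.ndarray) -> "GrowthParams":
        arr = np.asarray(phi, dtype=float).copy()
        arr[_LOG_IDX] = np.exp(arr[_LOG_IDX])
        return cls(*arr)


@dataclass(frozen=True)
class PopulationHyper:
    """Population-level mean vector, covariance and observation SD.

    ``mu0`` and ``sigma0`` are on the transformed scale
    ``(log A, log nu, log k, t_i, log d, t_d)``; ``sigma_obs`` is in g/plant.
    """

    mu0: np.ndarray
    sigma0: np.ndarray
    sigma_obs: float

    def __post_init__(self) -> None:
        mu0 = np.asarray(self.mu0, dtype=float)
        sigma0 = np.asarray(self.sigma0, dtype=float)
        if mu0.shape != (6,):
            raise ValueError("mu0 must be a 6-vector")
        if sigma0.shape != (6, 6):
            raise ValueError("sigma0 must be 6x6")
        if not np.allclose(sigma0, sigma0.T):
            raise ValueError("sigma0 must be symmetric")
        if np.linalg.eigvalsh(sigma0).min() <= 0:
            raise ValueError("sigma0 must be positive-definite")
        if not self.sigma_obs > 0:
            raise ValueError("sigma_obs must be positive")
        object.__setattr__(self, "mu0", mu0)
        object.__setattr__(self, "sigma0", sigma0)


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler configuration. Defaults: 4 chains x 3,000 iterations with 500
    warm-up steps each, retaining 4 x 2,500 = 10,000 posterior draws."""

    n_chains: int = 4
    n_iterations: int = 3000
    n_warmup: int = 500
    seed: int = 0
    max_treedepth: int = 10
    target_accept: float = 0.8

    def __post_init__(self) -> None:
        if self.n_warmup >= self.n_iterations:
            raise ValueError("n_warmup must be smaller than n_iterations")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @property
    def n_retained(self) -> int:
        return self.n_chains * (self.n_iterations - self.n_warmup)


#: reduced-iteration profile for quick runs; the default profile matches the
#: headline configuration above
REDUCED_MCMC = MCMCConfig(n_chains=4, n_iterations=1000, n_warmup=500)


@dataclass(frozen=True)
class PriorConfig:
    """Weakly informative priors of the hierarchical model.

    ``m0``/``s0``: Normal prior mean and SD per component of mu0 (transformed
    scale). ``tau_scale``: Half-Normal scales for the between-genotype SDs.
    ``sigma_obs_scale``: Half-Normal scale for the observation SD (g/plant).
    """

    m0: np.ndarray
    s0: np.ndarray
    tau_scale: np.ndarray
    sigma_obs_scale: float

    @classmethod
    def from_series(cls, series: pd.DataFrame) -> "PriorConfig":
        """Data-driven prior centers: log of the maximum observed biomass for
        log A, the time of the steepest rise of the pooled mean trajectory for
        t_i, ten days before the last observation for t_d; broad scales."""
        y = series["y"].to_numpy(dtype=float)
        t = series["t"].to_numpy(dtype=float)
        mean_by_t = series.groupby("t")["y"].mean().sort_index()
        tv = mean_by_t.index.to_numpy(dtype=float)
        yv = mean_by_t.to_numpy(dtype=float)
        if len(tv) >= 2:
            rates = np.diff(yv) / np.diff(tv)
            j = int(np.argmax(rates))
            t_i0 = 0.5 * (tv[j] + tv[j + 1])
        else:
            t_i0 = float(np.mean(t))
        ymax = max(float(np.max(y)), 1e-6)
        m0 = np.array([np.log(ymax), 0.0, np.log(0.07), t_i0, np.log(0.01), float(np.max(t)) - 10.0])
        s0 = np.array([1.0, 1.0, 1.0, 30.0, 1.5, 20.0])
        tau_scale = np.array([0.5, 0.5, 0.5, 10.0, 0.5, 10.0])
        sd_y = float(np.std(y))
        return cls(m0=m0, s0=s0, tau_scale=tau_scale, sigma_obs_scale=max(sd_y, 1e-3))


@dataclass(frozen=True)
class PosteriorDraws:
    """Constrained posterior draws indexed (chain, draw, parameter).

    ``names`` registers the parameter order: per-genotype natural-scale
    entries ``A[<genotype>]`` ... ``t_d[<genotype>]``, hyper-means
    ``mu0[log_A]`` ... (transformed scale), between-genotype SDs
    ``tau[log_A]`` ..., and ``sigma_obs``.
    """

    array: np.ndarray  # (chain, draw, parameter)
    names: tuple
    genotypes: tuple
    decay_mode: str = "as_printed"

    def __post_init__(self) -> None:
        if self.array.ndim != 3 or self.array.shape[2] != len(self.names):
            raise ValueError("draw array inconsistent with the name registry")

    @property
    def n_retained(self) -> int:
        return self.array.shape[0] * self.array.shape[1]

    def get(self, name: str) -> np.ndarray:
        """(chain, draw) array for one registered parameter."""
        return self.array[:, :, self.names.index(name)]

    def genotype_params(self, genotype) -> np.ndarray:
        """(chain*draw, 6) natural-scale theta draws for one genotype."""
        cols = [self.names.index(f"{p}[{genotype}]") for p in PARAM_NAMES]
        return self.array[:, :, cols].reshape(-1, 6)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (chain, draw, parameter, value) table."""
        nc, nd, np_ = self.array.shape
        chain = np.repeat(np.arange(nc), nd * np_)
        draw = np.tile(np.repeat(np.arange(nd), np_), nc)
        param = np.tile(np.asarray(self.names, dtype=object), nc * nd)
        return pd.DataFrame(
            {"chain": chain, "draw": draw, "parameter": param, "value": self.array.ravel()}
        )


@dataclass(frozen=True)
class ConvergenceReport:
    """Split-chain Gelman-Rubin R-hat and effective sample size per parameter."""

    table: pd.DataFrame  # parameter, rhat, ess
    max_rhat: float
    undefined: tuple = ()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ConvergenceReport(max_rhat={self.max_rhat:.4f}, "
            f"n_params={len(self.table)}, undefined={len(self.undefined)})"
        )


# --------------------------------------------------------------------------
# growth curve and likelihood
# --------------------------------------------------------------------------


def _check_decay_mode(decay_mode: str) -> None:
    if decay_mode not in DECAY_MODES:
        raise ValueError(f"decay_mode must be one of {DECAY_MODES}, got {decay_mode!r}")


def growth_curve(t, theta: GrowthParams, decay_mode: str = "as_printed"):
    """Richards-with-decay biomass at time(s) ``t`` (DAP), in g/plant.

    Evaluated in log space, ``log f = log A - log1p(nu e^{-k(t-t_i)})/nu
    - d (t - t_d)``, so that large ``|k (t - t_i)|`` does not overflow. In
    ``"gated"`` mode the decay exponent is zeroed for ``t < t_d``.
    """
    _check_decay_mode(decay_mode)
    if not isinstance(theta, GrowthParams):
        theta = GrowthParams(*theta)
    t = np.asarray(t, dtype=float)
    u = -theta.k * (t - theta.t_i)
    # log(1 + nu e^u) computed as logaddexp(0, log nu + u)
    L = np.logaddexp(0.0, np.log(theta.nu) + u)
    log_f = np.log(theta.A) - L / theta.nu
    decay_exponent = -theta.d * (t - theta.t_d)
    if decay_mode == "gated":
        decay_exponent = np.where(t < theta.t_d, 0.0, decay_exponent)
    out = np.exp(log_f + decay_exponent)
    return out if out.ndim else float(out)


def log_likelihood(
    series: pd.DataFrame,
    theta_by_genotype: dict,
    sigma_obs: float,
    decay_mode: str = "as_printed",
) -> float:
    """Gaussian log-likelihood of a series table under per-genotype curves.

    ``series`` needs columns ``genotype_id``, ``t``, ``y``; every genotype in
    the table must have an entry in ``theta_by_genotype``.
    """
    if sigma_obs <= 0:
        raise ValueError("sigma_obs must be positive")
    _check_decay_mode(decay_mode)
    missing = set(series["genotype_id"]) - set(theta_by_genotype)
    if missing:
        raise KeyError(f"no growth parameters for genotypes: {sorted(missing)}")
    total = 0.0
    for g, sub in series.groupby("genotype_id", sort=False):
        mu = growth_curve(sub["t"].to_numpy(dtype=float), theta_by_genotype[g], decay_mode)
        r = sub["y"].to_numpy(dtype=float) - mu
        total += float(
            -0.5 * np.sum(r**2) / sigma_obs**2
            - len(r) * (math.log(sigma_obs) + 0.5 * math.log(2 * math.pi))
        )
    return total


# --------------------------------------------------------------------------
# log posterior with analytic gradient
# --------------------------------------------------------------------------


class _HierarchicalModel:
    """Unconstrained-space log posterior of the hierarchical growth model.

    Parameter vector layout: z (G*6 non-centered genotype offsets), mu0 (6),
    log tau (6), log sigma_obs (1); dimension 6G + 13.
    """

    def __init__(self, t, y, gidx, n_genotypes, priors: PriorConfig, decay_mode: str):
        self.t = np.asarray(t, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.gidx = np.asarray(gidx, dtype=int)
        if np.any(np.diff(self.gidx) < 0):
            raise ValueError("records must be sorted by genotype index")
        self.G = int(n_genotypes)
        self.priors = priors
        self.gated = decay_mode == "gated"
        self.n = len(self.y)
        self.dim = 6 * self.G + 13
        # the curve mean depends only on (genotype, time); collapse records
        # to those cells with sufficient statistics (count, sum y, sum y^2)
        # — exact, and much cheaper when plants share acquisition dates
        order = np.lexsort((self.t, self.gidx))
        g_sorted, t_sorted, y_sorted = self.gidx[order], self.t[order], self.y[order]
        change = np.ones(len(order), dtype=bool)
        change[1:] = (np.diff(g_sorted) != 0) | (np.diff(t_sorted) != 0)
        starts = np.flatnonzero(change)
        self._cell_g = g_sorted[starts]
        self._cell_t = t_sorted[starts]
        self._cell_n = np.diff(np.append(starts, len(order))).astype(float)
        self._cell_s1 = np.add.reduceat(y_sorted, starts)
        self._cell_s2 = np.add.reduceat(y_sorted**2, starts)
        # per-genotype boundaries over the (sorted) cells
        self._gstarts = np.searchsorted(self._cell_g, np.arange(self.G))

    def unpack(self, q):
        G = self.G
        z = q[: 6 * G].reshape(G, 6)
        mu = q[6 * G : 6 * G + 6]
        log_tau = q[6 * G + 6 : 6 * G + 12]
        log_sigma = q[6 * G + 12]
        return z, mu, log_tau, log_sigma

    def phi(self, q):
        z, mu, log_tau, _ = self.unpack(q)
        return mu[None, :] + np.exp(log_tau)[None, :] * z

    def logp_grad(self, q):
        """Return (log posterior, gradient) — one vectorized pass."""
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return self._logp_grad(q)

    def _logp_grad(self, q):
        pr = self.priors
        z, mu, log_tau, log_sigma = self.unpack(q)
        tau = np.exp(log_tau)
        sigma = np.exp(log_sigma)
        phi = mu[None, :] + tau[None, :] * z  # (G, 6)

        ph = phi[self._cell_g]  # (cells, 6) transformed params per (g, t) cell
        logA, lognu, logk = ph[:, 0], ph[:, 1], ph[:, 2]
        t_i, logd, t_d = ph[:, 3], ph[:, 4], ph[:, 5]
        nu, k, d = np.exp(lognu), np.exp(logk), np.exp(logd)

        tc = self._cell_t
        u = -k * (tc - t_i)
        w = lognu + u
        L = np.logaddexp(0.0, w)
        with np.errstate(over="ignore"):
            p = 1.0 / (1.0 + np.exp(-w))  # sigmoid(w); saturates cleanly
        gate = 1.0 if not self.gated else (tc >= t_d).astype(float)
        decay_exp = -d * (tc - t_d) * gate
        log_m = logA - L / nu + decay_exp
        # cap far outside any plausible biomass so extreme leapfrog states
        # yield finite (divergent) energies rather than NaN gradients
        m = np.exp(np.clip(log_m, -40.0, 40.0))

        # sum of squared residuals via per-cell sufficient statistics
        ssr = float(np.sum(self._cell_s2 - 2.0 * m * self._cell_s1 + self._cell_n * m**2))
        inv_s2 = 1.0 / sigma**2
        lp = -0.5 * ssr * inv_s2 - self.n * (log_sigma + 0.5 * math.log(2 * math.pi))
        # priors
        lp += -0.5 * np.sum(z**2)
        lp += -0.5 * np.sum(((mu - pr.m0) / pr.s0) ** 2)
        lp += np.sum(-0.5 * (tau / pr.tau_scale) ** 2 + log_tau)  # half-normal + Jacobian
        lp += -0.5 * (sigma / pr.sigma_obs_scale) ** 2 + log_sigma

        # d log m / d phi, per cell
        dlog = np.empty_like(ph)
        dlog[:, 0] = 1.0
        dlog[:, 1] = (L - p) / nu
        dlog[:, 2] = -p * u / nu
        dlog[:, 3] = -p * k / nu
        dlog[:, 4] = decay_exp  # == -d (t - t_d) gate, i.e. d(decay)/d log d
        dlog[:, 5] = d * gate
        # d lp / d phi accumulated per genotype (cells sorted by genotype)
        coeff = ((self._cell_s1 - self._cell_n * m) * inv_s2 * m)[:, None]
        g_phi = np.add.reduceat(coeff * dlog, self._gstarts, axis=0)

        grad = np.empty_like(q)
        grad[: 6 * self.G] = (tau[None, :] * g_phi - z).ravel()
        grad[6 * self.G : 6 * self.G + 6] = g_phi.sum(axis=0) - (mu - pr.m0) / pr.s0**2
        grad[6 * self.G + 6 : 6 * self.G + 12] = (
            np.sum(g_phi * tau[None, :] * z, axis=0) - (tau / pr.tau_scale) ** 2 + 1.0
        )
        grad[6 * self.G + 12] = (
            ssr * inv_s2 - self.n - (sigma / pr.sigma_obs_scale) ** 2 + 1.0
        )
        return lp, grad


# --------------------------------------------------------------------------
# No-U-Turn sampler
# --------------------------------------------------------------------------


class _NUTS:
    """Multinomial NUTS with dual-averaging step size and diagonal mass matrix."""

    def __init__(self, logp_grad, dim, rng, target_accept=0.8, max_treedepth=10):
        self.logp_grad = logp_grad
        self.dim = dim
        self.rng = rng
        self.delta = target_accept
        self.max_treedepth = max_treedepth
        self.inv_mass = np.ones(dim)
        self._divergences = 0

    # -- hamiltonian helpers -------------------------------------------------

    def _kinetic(self, p):
        with np.errstate(over="ignore"):
            return 0.5 * np.dot(p * self.inv_mass, p)

    def _leapfrog(self, q, p, grad, eps):
        p = p + 0.5 * eps * grad
        q = q + eps * self.inv_mass * p
        lp, grad = self.logp_grad(q)
        p = p + 0.5 * eps * grad
        return q, p, lp, grad

    def _find_initial_step(self, q):
        lp, grad = self.logp_grad(q)
        eps = 1.0
        p = self.rng.standard_normal(self.dim) / np.sqrt(self.inv_mass)
        h0 = lp - self._kinetic(p)
        q1, p1, lp1, _ = self._leapfrog(q, p, grad, eps)
        h1 = lp1 - self._kinetic(p1)
        dh = h1 - h0 if np.isfinite(h1) else -np.inf
        direction = 1 if dh > math.log(0.5) else -1
        while True:
            eps *= 2.0**direction
            q1, p1, lp1, _ = self._leapfrog(q, p, grad, eps)
            h1 = lp1 - self._kinetic(p1)
            dh = h1 - h0 if np.isfinite(h1) else -np.inf
            if (direction == 1 and dh <= math.log(0.5)) or (
                direction == -1 and dh >= math.log(0.5)
            ):
                return eps
            if eps > 1e7 or eps < 1e-10:  # pathological target; bail out
                return max(min(eps, 1.0), 1e-8)

    # -- tree building (multinomial sampling) --------------------------------

    def _build_tree(self, q, p, grad, logu_norm, direction, depth, eps, h0):
        """Recursively double; returns a dict subtree summary or None on stop."""
        if depth == 0:
            q1, p1, lp1, grad1 = self._leapfrog(q, p, grad, direction * eps)
            h1 = lp1 - self._kinetic(p1) if np.isfinite(lp1) else -np.inf
            dh = h1 - h0
            if dh < -1000.0 or not np.isfinite(dh):
                self._divergences += 1
                return None
            return {
                "q_minus": q1, "p_minus": p1, "grad_minus": grad1,
                "q_plus": q1, "p_plus": p1, "grad_plus": grad1,
                "q_prop": q1, "log_w": dh, "sum_p": p1.copy(),
                "alpha": min(1.0, math.exp(min(dh, 0.0))), "n_alpha": 1,
            }
        first = self._build_tree(q, p, grad, logu_norm, direction, depth - 1, eps, h0)
        if first is None:
            return None
        if direction == 1:
            second = self._build_tree(
                first["q_plus"], first["p_plus"], first["grad_plus"],
                logu_norm, direction, depth - 1, eps, h0,
            )
        else:
            second = self._build_tree(
                first["q_minus"], first["p_minus"], first["grad_minus"],
                logu_norm, direction, depth - 1, eps, h0,
            )
        if second is None:
            return None
        total_log_w = np.logaddexp(first["log_w"], second["log_w"])
        if math.log(self.rng.uniform()) < second["log_w"] - total_log_w:
            q_prop = second["q_prop"]
        else:
            q_prop = first["q_prop"]
        if direction == 1:
            first["q_plus"] = second["q_plus"]
            first["p_plus"] = second["p_plus"]
            first["grad_plus"] = second["grad_plus"]
        else:
            first["q_minus"] = second["q_minus"]
            first["p_minus"] = second["p_minus"]
            first["grad_minus"] = second["grad_minus"]
        sum_p = first["sum_p"] + second["sum_p"]
        turned = self._uturn(first["q_minus"], first["q_plus"], first["p_minus"], first["p_plus"])
        first.update(
            q_prop=q_prop, log_w=total_log_w, sum_p=sum_p,
            alpha=first["alpha"] + second["alpha"],
            n_alpha=first["n_alpha"] + second["n_alpha"],
        )
        return None if turned else first

    def _uturn(self, q_minus, q_plus, p_minus, p_plus):
        dq = q_plus - q_minus
        return (
            np.dot(dq, self.inv_mass * p_minus) < 0.0
            or np.dot(dq, self.inv_mass * p_plus) < 0.0
        )

    def _transition(self, q, eps):
        lp, grad = self.logp_grad(q)
        p = self.rng.standard_normal(self.dim) / np.sqrt(self.inv_mass)
        h0 = lp - self._kinetic(p)
        tree = {
            "q_minus": q, "p_minus": p, "grad_minus": grad,
            "q_plus": q, "p_plus": p, "grad_plus": grad,
            "q_prop": q, "log_w": 0.0, "sum_p": p.copy(),
        }
        alpha_sum, n_alpha = 0.0, 0
        for depth in range(self.max_treedepth):
            direction = 1 if self.rng.uniform() < 0.5 else -1
            if direction == 1:
                sub = self._build_tree(
                    tree["q_plus"], tree["p_plus"], tree["grad_plus"], None,
                    direction, depth, eps, h0,
                )
            else:
                sub = self._build_tree(
                    tree["q_minus"], tree["p_minus"], tree["grad_minus"], None,
                    direction, depth, eps, h0,
                )
            if sub is None:
                break
            alpha_sum += sub["alpha"]
            n_alpha += sub["n_alpha"]
            # biased progressive sampling toward the new subtree
            if math.log(self.rng.uniform()) < sub["log_w"] - tree["log_w"]:
                tree["q_prop"] = sub["q_prop"]
            tree["log_w"] = np.logaddexp(tree["log_w"], sub["log_w"])
            if direction == 1:
                tree["q_plus"], tree["p_plus"], tree["grad_plus"] = (
                    sub["q_plus"], sub["p_plus"], sub["grad_plus"],
                )
            else:
                tree["q_minus"], tree["p_minus"], tree["grad_minus"] = (
                    sub["q_minus"], sub["p_minus"], sub["grad_minus"],
                )
            tree["sum_p"] = tree["sum_p"] + sub["sum_p"]
            if self._uturn(tree["q_minus"], tree["q_plus"], tree["p_minus"], tree["p_plus"]):
                break
        accept_stat = alpha_sum / max(n_alpha, 1)
        return tree["q_prop"], accept_stat

    # -- adaptation ----------------------------------------------------------

    def run(self, q0, n_iterations, n_warmup):
        """Sample; returns (draws after warmup, acceptance statistics)."""
        q = np.asarray(q0, dtype=float).copy()
        eps = self._find_initial_step(q)
        mu_da = math.log(10.0 * eps)
        log_eps_bar, h_bar = 0.0, 0.0
        gamma, t0, kappa = 0.05, 10.0, 0.75

        # Stan-like warmup phases: step-size only, then mass-estimation
        # windows, then a final step-size phase.
        init_buf = min(75, max(1, int(0.15 * n_warmup)))
        term_buf = min(50, max(1, int(0.10 * n_warmup)))
        window_start = init_buf
        window_size = 25
        window_end = min(window_start + window_size, n_warmup - term_buf)
        welford_n, welford_mean, welford_m2 = 0, np.zeros(self.dim), np.zeros(self.dim)

        draws = np.empty((n_iterations - n_warmup, self.dim))
        accepts = []
        da_it = 0  # dual-averaging steps since the last adaptation restart
        for it in range(n_iterations):
            q, accept_stat = self._transition(q, eps)
            if it < n_warmup:
                da_it += 1
                h_bar = (1 - 1 / (da_it + t0)) * h_bar + (self.delta - accept_stat) / (
                    da_it + t0
                )
                log_eps = mu_da - math.sqrt(da_it) / gamma * h_bar
                eta = da_it**-kappa
                log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
                eps = math.exp(log_eps)
                if window_start <= it < n_warmup - term_buf:
                    welford_n += 1
                    delta_w = q - welford_mean
                    welford_mean += delta_w / welford_n
                    welford_m2 += delta_w * (q - welford_mean)
                    if it + 1 == window_end:
                        if welford_n >= 10:
                            var = welford_m2 / (welford_n - 1)
                            # regularize toward unit metric as Stan does
                            self.inv_mass = (
                                welford_n / (welford_n + 5.0) * var
                                + 1e-3 * (5.0 / (welford_n + 5.0))
                            )
                        welford_n, welford_mean = 0, np.zeros(self.dim)
                        welford_m2 = np.zeros(self.dim)
                        eps = self._find_initial_step(q)
                        mu_da = math.log(10.0 * eps)
                        log_eps_bar, h_bar, da_it = math.log(eps), 0.0, 0
                        window_size *= 2
                        window_start = it + 1
                        window_end = min(window_start + window_size, n_warmup - term_buf)
                        if n_warmup - term_buf - window_end < window_size:
                            window_end = n_warmup - term_buf
                if it + 1 == n_warmup:
                    eps = math.exp(log_eps_bar)
            else:
                draws[it - n_warmup] = q
                accepts.append(accept_stat)
        return draws, np.asarray(accepts)


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


def _prepare_series(series: pd.DataFrame):
    required = {"genotype_id", "t", "y"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"series table lacks columns: {sorted(missing)}")
    sort_cols = [c for c in ("genotype_id", "plant_id", "replicate_id", "t") if c in series]
    df = series.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    genotypes = tuple(sorted(df["genotype_id"].unique()))
    gmap = {g: i for i, g in enumerate(genotypes)}
    gidx = df["genotype_id"].map(gmap).to_numpy()
    return df, genotypes, gidx


def fit_hierarchical(
    series: pd.DataFrame,
    priors: PriorConfig | None = None,
    mcmc: MCMCConfig = MCMCConfig(),
    decay_mode: str = "as_printed",
) -> PosteriorDraws:
    """Sample the joint posterior over genotype parameters and hyperparameters.

    Records are sorted internally, so the result is invariant to row order.
    Requires at least two genotypes with at least four distinct time points
    each. Initialization is jittered; up to 4 retries on a non-finite start.
    """
    _check_decay_mode(decay_mode)
    df, genotypes, gidx = _prepare_series(series)
    counts = df.groupby("genotype_id")["t"].nunique()
    if len(genotypes) < 2 or counts.min() < 4:
        raise ValueError(
            "need >= 2 genotypes with >= 4 distinct time points each "
            f"(got {len(genotypes)} genotypes, min {int(counts.min())} time points)"
        )
    if priors is None:
        priors = PriorConfig.from_series(df)
    model = _HierarchicalModel(
        df["t"].to_numpy(), df["y"].to_numpy(), gidx, len(genotypes), priors, decay_mode
    )
    G = len(genotypes)
    n_keep = mcmc.n_iterations - mcmc.n_warmup
    all_draws = np.empty((mcmc.n_chains, n_keep, model.dim))
    seed_seq = np.random.SeedSequence(mcmc.seed)
    for chain, child in enumerate(seed_seq.spawn(mcmc.n_chains)):
        rng = np.random.default_rng(child)
        q0 = None
        for attempt in range(5):
            cand = np.zeros(model.dim)
            cand[: 6 * G] = 0.1 * rng.standard_normal(6 * G)
            cand[6 * G : 6 * G + 6] = priors.m0 + 0.1 * priors.s0 * rng.standard_normal(6)
            cand[6 * G + 6 : 6 * G + 12] = np.log(priors.tau_scale) - 1.0 + 0.2 * rng.standard_normal(6)
            cand[6 * G + 12] = math.log(priors.sigma_obs_scale) - 0.5 + 0.2 * rng.standard_normal()
            lp, grad = model.logp_grad(cand)
            if np.isfinite(lp) and np.all(np.isfinite(grad)):
                q0 = cand
                break
            logger.warning("chain %d: non-finite start, retry %d", chain, attempt + 1)
        if q0 is None:
            raise RuntimeError("could not find a finite initialization after 5 attempts")
        sampler = _NUTS(
            model.logp_grad, model.dim, rng,
            target_accept=mcmc.target_accept, max_treedepth=mcmc.max_treedepth,
        )
        chain_draws, accepts = sampler.run(q0, mcmc.n_iterations, mcmc.n_warmup)
        all_draws[chain] = chain_draws
        logger.info(
            "chain %d done: mean accept %.3f, divergent %d",
            chain, float(np.mean(accepts)), sampler._divergences,
        )

    # back-transform to the constrained registry
    names = [f"{p}[{g}]" for g in genotypes for p in PARAM_NAMES]
    names += [f"mu0[{n}]" for n in TRANSFORMED_NAMES]
    names += [f"tau[{n}]" for n in TRANSFORMED_NAMES]
    names += ["sigma_obs"]
    out = np.empty((mcmc.n_chains, n_keep, len(names)))
    for c in range(mcmc.n_chains):
        q = all_draws[c]  # (n_keep, dim)
        z = q[:, : 6 * G].reshape(n_keep, G, 6)
        mu = q[:, 6 * G : 6 * G + 6]
        tau = np.exp(q[:, 6 * G + 6 : 6 * G + 12])
        sigma = np.exp(q[:, 6 * G + 12])
        phi = mu[:, None, :] + tau[:, None, :] * z  # (n_keep, G, 6)
        theta = phi.copy()
        theta[:, :, _LOG_IDX] = np.exp(phi[:, :, _LOG_IDX])
        out[c, :, : 6 * G] = theta.reshape(n_keep, 6 * G)
        out[c, :, 6 * G : 6 * G + 6] = mu
        out[c, :, 6 * G + 6 : 6 * G + 12] = tau
        out[c, :, 6 * G + 12] = sigma
    return PosteriorDraws(
        array=out, names=tuple(names), genotypes=genotypes, decay_mode=decay_mode
    )


# --------------------------------------------------------------------------
# diagnostics and summaries
# --------------------------------------------------------------------------


def convergence(draws: PosteriorDraws) -> ConvergenceReport:
    """Split-chain Gelman-Rubin R-hat and bulk effective sample size.

    A single chain is split in half (with a warning); parameters with zero
    variance are flagged undefined and excluded from ``max_rhat``.
    """
    arr = draws.array
    if arr.shape[0] < 2:
        logger.warning("single chain: split-chain fallback in use")
        half = arr.shape[1] // 2
        arr = np.stack([arr[0, :half], arr[0, half : 2 * half]], axis=0)
    ds = az.convert_to_dataset(arr)
    rhats = np.asarray(az.rhat(ds, method="split").x.values, dtype=float)
    esss = np.asarray(az.ess(ds).x.values, dtype=float)
    constant = np.array([np.ptp(arr[:, :, j]) == 0.0 for j in range(arr.shape[2])])
    rhats[constant] = np.nan
    esss[constant] = np.nan
    undefined = [n for n, c in zip(draws.names, constant) if c]
    table = pd.DataFrame({"parameter": list(draws.names), "rhat": rhats, "ess": esss})
    finite = table["rhat"].dropna()
    max_rhat = float(finite.max()) if len(finite) else float("nan")
    return ConvergenceReport(table=table, max_rhat=max_rhat, undefined=tuple(undefined))


def posterior_summaries(
    draws: PosteriorDraws,
    dap_grid=None,
    interval_level: float = 0.99,
    band_level: float = 0.95,
):
    """Per-parameter posterior summaries and fitted-curve credible bands.

    Returns ``(params, curves)``. ``params`` has one row per registered
    parameter with the posterior median, interquartile range and a central
    ``interval_level`` interval. If ``dap_grid`` is given, ``curves`` holds,
    per genotype and grid time, the pointwise posterior mean biomass and a
    central ``band_level`` band obtained by pushing every draw through the
    growth curve; otherwise ``curves`` is None.
    """
    for level in (interval_level, band_level):
        if not 0.0 < level < 1.0:
            raise ValueError("summary levels must lie strictly between 0 and 1")
    flat = draws.array.reshape(-1, len(draws.names))
    lo, hi = 50 * (1 - interval_level), 50 * (1 + interval_level)
    qs = np.percentile(flat, [lo, 25, 50, 75, hi], axis=0)
    params = pd.DataFrame(
        {
            "parameter": list(draws.names),
            "median": qs[2],
            "q25": qs[1],
            "q75": qs[3],
            "lower": qs[0],
            "upper": qs[4],
            "mean": flat.mean(axis=0),
        }
    )
    curves = None
    if dap_grid is not None:
        dap_grid = np.asarray(dap_grid, dtype=float)
        blo, bhi = 50 * (1 - band_level), 50 * (1 + band_level)
        rows = []
        for g in draws.genotypes:
            th = draws.genotype_params(g)  # (ndraw, 6)
            fvals = np.empty((th.shape[0], len(dap_grid)))
            for i in range(th.shape[0]):
                fvals[i] = growth_curve(dap_grid, GrowthParams(*th[i]), draws.decay_mode)
            mean_curve = fvals.mean(axis=0)
            lo_curve = np.percentile(fvals, blo, axis=0)
            hi_curve = np.percentile(fvals, bhi, axis=0)
            for j, t in enumerate(dap_grid):
                rows.append(
                    {
                        "genotype_id": g, "t": t, "mean": mean_curve[j],
                        "lower": lo_curve[j], "upper": hi_curve[j],
                    }
                )
        curves = pd.DataFrame(rows)
    return params, curves


# --------------------------------------------------------------------------
# parameter-recovery harness
# --------------------------------------------------------------------------


def recovery_experiment(
    theta_by_genotype: dict,
    sigma_obs: float,
    design,
    mcmc: MCMCConfig = REDUCED_MCMC,
    seed: int = 0,
    decay_mode: str = "as_printed",
    interval_level: float = 0.95,
):
    """Simulate a series from known parameters, refit, and score recovery.

    Returns a dict with the simulated series, posterior draws, a per-genotype
    per-parameter table (truth, posterior mean, relative error, interval
    coverage), pooled coverage at ``interval_level``, and the convergence
    report of the fit.
    """
    from .synthcanopy import simulate_growth_series  # local import; avoids a cycle

    series = simulate_growth_series(
        theta_by_genotype, sigma_obs=sigma_obs, design=design,
        decay_mode=decay_mode, seed=seed,
    )
    draws = fit_hierarchical(series, mcmc=mcmc, decay_mode=decay_mode)
    conv = convergence(draws)
    lo, hi = 50 * (1 - interval_level), 50 * (1 + interval_level)
    rows = []
    for g in draws.genotypes:
        th_true = theta_by_genotype[g]
        if not isinstance(th_true, GrowthParams):
            th_true = GrowthParams(*th_true)
        truth = th_true.as_array()
        post = draws.genotype_params(g)
        mean = post.mean(axis=0)
        lower = np.percentile(post, lo, axis=0)
        upper = np.percentile(post, hi, axis=0)
        for j, pname in enumerate(PARAM_NAMES):
            denom = abs(truth[j]) if truth[j] != 0 else 1.0
            rows.append(
                {
                    "genotype_id": g, "parameter": pname, "truth": truth[j],
                    "posterior_mean": mean[j],
                    "rel_error": abs(mean[j] - truth[j]) / denom,
                    "covered": bool(lower[j] <= truth[j] <= upper[j]),
                }
            )
    table = pd.DataFrame(rows)
    return {
        "series": series,
        "draws": draws,
        "table": table,
        "pooled_coverage": float(table["covered"].mean()),
        "convergence": conv,
    }
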