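"""Bilinear effective-connectivity model of the 6-region oculomotor
control network (FEF, SEF, rIFC, thalamus, caudate, superior colliculus).

Neural model
------------
Region activity z (one scalar per region) evolves as

    dz/dt = J(u_redirect) z + C u_task

where the Jacobian J has off-diagonal entries a_ij + u_redirect * b_ij on
the 19 permitted directed connections (zero elsewhere) and diagonal
entries -0.5 * exp(theta_i + u_redirect * b_ii).  The exponential
self-connection parameterization keeps within-region decay strictly
negative for every finite theta: positive theta means *more*
self-inhibition than the -0.5 Hz default.  A (in Hz) is the average
effective connectivity over the task; B adds to it on redirect trials;
C gates the driving input (all trial events) into each region.

Observation model
-----------------
Neural activity drives a standard balloon/Windkessel hemodynamic cascade
per region (vasodilatory signal s, inflow f, venous volume v,
deoxyhemoglobin q) read out as a BOLD signal sampled at the TR.
Hemodynamic constants are fixed, not estimated.

Inversion
---------
`invert_dcm` maximizes a variational (Laplace) free energy under a
Gaussian posterior by damped Gauss-Newton updates with finite-difference
sensitivities; `peb_group` fits a hierarchical Bayesian linear model
(design [1, group_code]) over subject posteriors with EM-estimated
between-subject variance and greedy Bayesian model reduction, yielding
group commonalities and differences with posterior probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import InvalidInputError, StabilityError

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (a and callable(a[0])) else deco(a[0])


REGIONS = ("FEF", "SEF", "rIFC", "Thal", "CD", "SC")

#: The 19 permitted directed between-region connections (source, target).
EDGES = (
    ("FEF", "SEF"), ("FEF", "CD"), ("FEF", "Thal"), ("FEF", "SC"),
    ("SEF", "FEF"), ("SEF", "SC"), ("SEF", "CD"), ("SEF", "Thal"), ("SEF", "rIFC"),
    ("rIFC", "SEF"), ("rIFC", "CD"), ("rIFC", "Thal"),
    ("Thal", "FEF"), ("Thal", "SEF"), ("Thal", "rIFC"),
    ("CD", "Thal"), ("CD", "SC"),
    ("SC", "Thal"), ("SC", "CD"),
)


@dataclass(frozen=True)
class NetworkStructure:
    """Fixed network scaffold: which connections exist, which are modulated
    (all edges plus all self-connections) and which regions receive the
    driving input (all of them)."""

    regions: tuple[str, ...] = REGIONS
    edges: tuple[tuple[str, str], ...] = EDGES

    def __post_init__(self):
        for s, t in self.edges:
            if s == t:
                raise InvalidInputError(f"self-pair {s}->{t} not allowed in edges")
            if s not in self.regions or t not in self.regions:
                raise InvalidInputError(f"unknown region in edge {s}->{t}")

    @property
    def n(self) -> int:
        return len(self.regions)

    def index(self, region: str) -> int:
        return self.regions.index(region)

    def adjacency_mask(self) -> np.ndarray:
        """Boolean (target, source) mask of permitted between-region edges."""
        m = np.zeros((self.n, self.n), dtype=bool)
        for s, t in self.edges:
            m[self.index(t), self.index(s)] = True
        return m

    def adjacency_frame(self) -> pd.DataFrame:
        """Labeled target-by-source adjacency in the fixed region order."""
        return pd.DataFrame(
            self.adjacency_mask().astype(int), index=self.regions, columns=self.regions
        )


def build_structure() -> NetworkStructure:
    """The study network: 6 regions, 19 of the 30 possible between-region
    connections switched on, every self-connection modeled and modulated,
    driving input to all regions."""
    return NetworkStructure()


@dataclass
class DCMParameters:
    """Neural parameters on the structure's support.

    ``a``: (n, n) between-region couplings in Hz, nonzero only on permitted
    edges (target row, source column).  ``theta_self``: per-region
    log-scale of the self-connection (effective diagonal is
    -0.5 exp(theta)).  ``b``/``b_self``: redirect modulation of edges
    (additive, Hz) and selves (additive inside the exponent).  ``c``:
    driving-input gains.
    """

    a: np.ndarray
    theta_self: np.ndarray
    b: np.ndarray
    b_self: np.ndarray
    c: np.ndarray
    structure: NetworkStructure = field(default_factory=build_structure)

    def __post_init__(self):
        n = self.structure.n
        self.a = np.asarray(self.a, dtype=float).reshape(n, n)
        self.b = np.asarray(self.b, dtype=float).reshape(n, n)
        self.theta_self = np.asarray(self.theta_self, dtype=float).reshape(n)
        self.b_self = np.asarray(self.b_self, dtype=float).reshape(n)
        self.c = np.asarray(self.c, dtype=float).reshape(n)
        mask = self.structure.adjacency_mask()
        for name, m in (("a", self.a), ("b", self.b)):
            bad = (~mask) & (m != 0)
            if bad.any():
                t, s = np.argwhere(bad)[0]
                raise InvalidInputError(
                    f"{name} parameter on disallowed edge "
                    f"{self.structure.regions[s]}->{self.structure.regions[t]}"
                )

    @classmethod
    def zeros(cls, structure: Optional[NetworkStructure] = None) -> "DCMParameters":
        structure = structure or build_structure()
        n = structure.n
        return cls(np.zeros((n, n)), np.zeros(n), np.zeros((n, n)), np.zeros(n), np.zeros(n), structure)

    def jacobian(self, u_redirect: float = 0.0) -> np.ndarray:
        """Neural Jacobian J(u_redirect)."""
        j = self.a + u_redirect * self.b
        np.fill_diagonal(j, -0.5 * np.exp(self.theta_self + u_redirect * self.b_self))
        return j

    # --- flat-vector view used by the inversion --------------------------
    def labels(self) -> list[str]:
        regs = self.structure.regions
        lab = [f"a:{s}->{t}" for s, t in self.structure.edges]
        lab += [f"self:{r}" for r in regs]
        lab += [f"b:{s}->{t}" for s, t in self.structure.edges]
        lab += [f"bself:{r}" for r in regs]
        lab += [f"c:{r}" for r in regs]
        return lab

    def to_vector(self) -> np.ndarray:
        st = self.structure
        a_part = [self.a[st.index(t), st.index(s)] for s, t in st.edges]
        b_part = [self.b[st.index(t), st.index(s)] for s, t in st.edges]
        return np.concatenate([a_part, self.theta_self, b_part, self.b_self, self.c])

    @classmethod
    def from_vector(cls, vec: np.ndarray, structure: Optional[NetworkStructure] = None) -> "DCMParameters":
        st = structure or build_structure()
        n, ne = st.n, len(st.edges)
        vec = np.asarray(vec, dtype=float)
        if vec.size != 2 * ne + 3 * n:
            raise InvalidInputError(f"expected vector of length {2 * ne + 3 * n}, got {vec.size}")
        a = np.zeros((n, n))
        b = np.zeros((n, n))
        for k, (s, t) in enumerate(st.edges):
            a[st.index(t), st.index(s)] = vec[k]
            b[st.index(t), st.index(s)] = vec[ne + n + k]
        return cls(a, vec[ne: ne + n], b, vec[2 * ne + n: 2 * ne + 2 * n],
                   vec[2 * ne + 2 * n:], st)


@dataclass(frozen=True)
class HemodynamicParameters:
    """Fixed balloon/Windkessel constants (per region identical).

    kappa: vasodilatory signal decay (1/s); gamma: flow feedback (1/s);
    tau: venous transit time (s); alpha: vessel stiffness; e0: resting
    oxygen extraction; v0: resting venous volume fraction of the readout.
    """

    kappa: float = 0.65
    gamma: float = 0.41
    tau: float = 0.98
    alpha: float = 0.32
    e0: float = 0.34
    v0: float = 0.04

    def __post_init__(self):
        if min(self.kappa, self.gamma, self.tau, self.v0) <= 0:
            raise InvalidInputError("hemodynamic rate constants must be positive")
        if not (0 < self.alpha < 1 and 0 < self.e0 < 1):
            raise InvalidInputError("alpha and e0 must lie in (0, 1)")


@dataclass
class DesignInput:
    """Stimulus design on a common fine time grid.

    ``u_task`` carries all trial events (the driving input, mean-centered
    so A reads as average connectivity); ``u_redirect`` is the binary
    redirect-trial indicator modulating the connections.
    """

    u_task: np.ndarray
    u_redirect: np.ndarray
    dt: float
    tr: float
    n_volumes: int

    def __post_init__(self):
        self.u_task = np.asarray(self.u_task, dtype=float)
        self.u_redirect = np.asarray(self.u_redirect, dtype=float)
        if self.u_task.shape != self.u_redirect.shape:
            raise InvalidInputError("u_task and u_redirect must share the fine grid")
        if self.obs_every * (self.n_volumes - 1) > self.u_task.size - 1:
            raise InvalidInputError("input grid shorter than the volume grid")

    @property
    def obs_every(self) -> int:
        return int(round(self.tr / self.dt))


def make_design(
    n_volumes: int,
    tr: float = 2.0,
    dt: float = 0.025,
    trial_interval: float = 4.0,
    interval_jitter: float = 2.0,
    p_redirect: float = 0.40,
    event_duration: float = 0.5,
    gain: float = 1.0,
    seed: int = 0,
) -> DesignInput:
    """Event-related design emulating the search-step task timing: trials
    every ``trial_interval`` s on average (uniformly jittered by up to
    +/- ``interval_jitter``/2, which decorrelates the regressors and
    enriches the design's frequency content), a fraction ``p_redirect``
    of them redirect trials.  All events enter the (mean-centered)
    driving regressor; redirect events additionally enter the binary
    modulatory regressor and are by construction a subset of task
    events."""
    rng = np.random.default_rng(seed)
    n_steps = n_volumes * int(round(tr / dt))
    u_task = np.zeros(n_steps)
    u_red = np.zeros(n_steps)
    dur = max(1, int(round(event_duration / dt)))
    t_end = n_steps * dt
    onset = trial_interval / 2.0
    while onset < t_end - event_duration:
        i = int(round(onset / dt))
        u_task[i: i + dur] = gain
        if rng.random() < p_redirect:
            u_red[i: i + dur] = 1.0
        onset += trial_interval + interval_jitter * (rng.random() - 0.5)
    u_task = u_task - u_task.mean()
    return DesignInput(u_task=u_task, u_redirect=u_red, dt=dt, tr=tr, n_volumes=n_volumes)


def neural_derivative(
    z: np.ndarray, params: DCMParameters, u_task: float, u_redirect: float
) -> np.ndarray:
    """dz/dt of the bilinear neural model at one instant."""
    z = np.asarray(z, dtype=float)
    if z.shape != (params.structure.n,):
        raise InvalidInputError("z must have one entry per region")
    return params.jacobian(u_redirect) @ z + params.c * u_task


def check_stability(params: DCMParameters, u_levels: Sequence[float] = (0.0, 1.0)) -> float:
    """Largest real part over eigenvalues of J at the given modulation
    levels; raises StabilityError when >= 0."""
    worst = -np.inf
    for u in u_levels:
        worst = max(worst, float(np.linalg.eigvals(params.jacobian(u)).real.max()))
    if worst >= 0:
        raise StabilityError(worst)
    return worst


# ---------------------------------------------------------------------------
# fixed-step RK4 integration of the neural + balloon cascade
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _integrate_core(a, b, theta, bself, c, u_task, u_red, dt, obs_every, n_vol,
                    kappa, gamma, tau, alpha, e0, v0):  # pragma: no cover - jitted
    n = a.shape[0]
    n_steps = u_task.shape[0]
    k1 = 7.0 * e0
    k2 = 2.0
    k3 = 2.0 * e0 - 0.2
    ia = 1.0 / alpha

    z = np.zeros(n)
    s = np.zeros(n)
    f = np.ones(n)
    v = np.ones(n)
    q = np.ones(n)
    y = np.zeros((n_vol, n))

    j = np.zeros((n, n))
    u_prev = -1e30
    # state (z, s, f, v, q) stacked as rows of a (5, n) array
    state = np.zeros((5, n))
    state[2] = 1.0
    state[3] = 1.0
    state[4] = 1.0
    st0 = np.zeros((5, n))
    stg = np.zeros((5, n))
    k = np.zeros((4, 5, n))
    weights = np.array([0.0, 0.5, 0.5, 1.0])
    vol = 0
    for step in range(n_steps):
        if vol < n_vol and step == vol * obs_every:
            for r in range(n):
                y[vol, r] = v0 * (k1 * (1.0 - state[4, r]) + k2 * (1.0 - state[4, r] / state[3, r])
                                  + k3 * (1.0 - state[3, r]))
            vol += 1
        ur = u_red[step]
        ut = u_task[step]
        if ur != u_prev:
            for i in range(n):
                for jj in range(n):
                    j[i, jj] = a[i, jj] + ur * b[i, jj]
                j[i, i] = -0.5 * np.exp(theta[i] + ur * bself[i])
            u_prev = ur
        for i in range(5):
            for r in range(n):
                st0[i, r] = state[i, r]
        for stage in range(4):
            wdt = weights[stage] * dt
            if stage == 0:
                for i in range(5):
                    for r in range(n):
                        stg[i, r] = st0[i, r]
            else:
                for i in range(5):
                    for r in range(n):
                        stg[i, r] = st0[i, r] + wdt * k[stage - 1, i, r]
            for r in range(n):
                acc = c[r] * ut
                for jj in range(n):
                    acc += j[r, jj] * stg[0, jj]
                fr = stg[2, r]
                if fr < 1e-3:
                    fr = 1e-3
                vr = stg[3, r]
                if vr < 1e-3:
                    vr = 1e-3
                qr = stg[4, r]
                if qr < 1e-6:
                    qr = 1e-6
                vout = vr ** ia
                ex = (1.0 - (1.0 - e0) ** (1.0 / fr)) / e0
                k[stage, 0, r] = acc
                k[stage, 1, r] = stg[0, r] - kappa * stg[1, r] - gamma * (fr - 1.0)
                k[stage, 2, r] = stg[1, r]
                k[stage, 3, r] = (fr - vout) / tau
                k[stage, 4, r] = (fr * ex - vout * qr / vr) / tau
        for i in range(5):
            for r in range(n):
                state[i, r] = st0[i, r] + dt / 6.0 * (
                    k[0, i, r] + 2.0 * k[1, i, r] + 2.0 * k[2, i, r] + k[3, i, r]
                )
    return y


def _predict(params: DCMParameters, hemo: HemodynamicParameters, design: DesignInput) -> np.ndarray:
    """Noiseless BOLD prediction, shape (n_volumes, n_regions)."""
    return _integrate_core(
        np.ascontiguousarray(params.a * ~np.eye(params.structure.n, dtype=bool)),
        np.ascontiguousarray(params.b),
        params.theta_self, params.b_self, params.c,
        design.u_task, design.u_redirect, design.dt, design.obs_every, design.n_volumes,
        hemo.kappa, hemo.gamma, hemo.tau, hemo.alpha, hemo.e0, hemo.v0,
    )


def bold_forward(
    params: DCMParameters,
    hemo: HemodynamicParameters,
    design: DesignInput,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Simulate region BOLD time series (n_volumes x n_regions).

    The neural and hemodynamic states are integrated with fixed-step RK4
    on the design's fine grid, observed at the TR, with i.i.d. Gaussian
    noise of ``noise_sd`` added to every sample.  Raises StabilityError
    when the neural Jacobian is not strictly stable.
    """
    check_stability(params, u_levels=(0.0, float(design.u_redirect.max(initial=0.0))))
    y = _predict(params, hemo, design)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=y.shape)
    return y


# ---------------------------------------------------------------------------
# single-subject inversion (variational Laplace, damped Gauss-Newton)
# ---------------------------------------------------------------------------

@dataclass
class Priors:
    """Zero-mean Gaussian shrinkage priors on the flat parameter vector."""

    var_a: float = 1.0 / 16.0
    var_self: float = 1.0 / 64.0
    var_b: float = 1.0 / 16.0
    var_c: float = 1.0

    def variance_vector(self, structure: NetworkStructure) -> np.ndarray:
        n, ne = structure.n, len(structure.edges)
        return np.concatenate([
            np.full(ne, self.var_a), np.full(n, self.var_self),
            np.full(ne, self.var_b), np.full(n, self.var_self),
            np.full(n, self.var_c),
        ])


@dataclass
class InversionResult:
    """Posterior over the flat parameter vector plus diagnostics."""

    theta_mean: np.ndarray
    theta_cov: np.ndarray
    params: DCMParameters
    free_energy: float
    objective_history: list[float]
    explained_variance: np.ndarray
    noise_precision: np.ndarray
    converged: bool
    labels: list[str]


def _stack_predictions(theta, structure, hemo, designs):
    p = DCMParameters.from_vector(theta, structure)
    return np.concatenate([_predict(p, hemo, d) for d in designs], axis=0)


def _stable(theta, structure, u_max, margin=1e-3):
    p = DCMParameters.from_vector(theta, structure)
    try:
        return check_stability(p, u_levels=(0.0, u_max)) < -margin
    except StabilityError:
        return False


def invert_dcm(
    timeseries: np.ndarray | Sequence[np.ndarray],
    structure: NetworkStructure,
    design: DesignInput | Sequence[DesignInput],
    priors: Optional[Priors] = None,
    hemo: Optional[HemodynamicParameters] = None,
    max_iter: int = 32,
    tol: float = 0.05,
    fd_step: float = 1e-3,
    theta0: Optional[np.ndarray] = None,
    jacobian_refresh: int = 2,
) -> InversionResult:
    """Fit the bilinear model to observed region time series.

    Gauss-Newton / Levenberg-Marquardt ascent on a penalized Gaussian
    log-joint (likelihood with per-region noise precision, estimated
    between iterations, plus the shrinkage prior); sensitivities by
    forward finite differences.  After the first three iterations the
    sensitivity matrix is refreshed only every ``jacobian_refresh``
    iterations (step acceptance still evaluates the exact objective, so
    a stale matrix can only slow progress, never corrupt it).  Accepted
    iterations never decrease the objective; the full Laplace free
    energy (with the posterior-volume complexity term) is evaluated at
    the final iterate and is the model comparison score.
    Non-convergence returns the best iterate flagged.
    """
    designs = list(design) if isinstance(design, (list, tuple)) else [design]
    runs = list(timeseries) if isinstance(timeseries, (list, tuple)) else [timeseries]
    y = np.concatenate([np.asarray(r, dtype=float) for r in runs], axis=0)
    n_reg = structure.n
    if y.shape[1] != n_reg:
        raise InvalidInputError("time series must have one column per region")
    if y.shape[0] != sum(d.n_volumes for d in designs):
        raise InvalidInputError("time series length does not match the design volumes")
    hemo = hemo or HemodynamicParameters()
    priors = priors or Priors()
    u_max = float(max(d.u_redirect.max(initial=0.0) for d in designs))

    prior_var = priors.variance_vector(structure)
    free = prior_var > 0
    p0_diag = np.zeros_like(prior_var)
    p0_diag[free] = 1.0 / prior_var[free]
    n_par = int(free.sum())
    n_obs = y.shape[0]

    theta = np.zeros(prior_var.size) if theta0 is None else np.asarray(theta0, float).copy()
    g = _stack_predictions(theta, structure, hemo, designs)
    resid = y - g
    lam = np.clip(n_obs / np.maximum((resid**2).sum(axis=0), 1e-12), 1e-8, 1e8)

    def objective(resid, lam, theta):
        sse = (resid**2).sum(axis=0)
        like = float(np.sum(-0.5 * lam * sse + 0.5 * n_obs * np.log(lam)))
        pen = -0.5 * float(np.sum(p0_diag * theta**2))
        return like + pen

    obj = objective(resid, lam, theta)
    history = [obj]
    damping = 1.0
    converged = False
    jac = None
    jac_age = 10**9
    idx_free = np.flatnonzero(free)

    for it in range(max_iter):
        if it < 3 or jac_age >= jacobian_refresh:
            # forward-difference sensitivities over free parameters
            jac = np.zeros((n_obs, n_reg, n_par))
            for col, k in enumerate(idx_free):
                th = theta.copy()
                th[k] += fd_step
                if not _stable(th, structure, u_max):
                    th[k] -= 2 * fd_step
                gk = _stack_predictions(th, structure, hemo, designs)
                jac[:, :, col] = (gk - g) / (th[k] - theta[k])
            jac_age = 0
        else:
            jac_age += 1

        w = np.repeat(lam[None, :], n_obs, axis=0).reshape(-1)
        jf = jac.reshape(n_obs * n_reg, n_par)
        rf = resid.reshape(-1)
        h = jf.T @ (jf * w[:, None])
        grad = jf.T @ (rf * w) - p0_diag[idx_free] * theta[idx_free]
        h_reg = h + np.diag(p0_diag[idx_free])

        improved = False
        for _try in range(8):
            lhs = h_reg + damping * np.diag(np.maximum(np.diag(h_reg), 1e-8))
            try:
                step = np.linalg.solve(lhs, grad)
            except np.linalg.LinAlgError:
                damping *= 8.0
                continue
            cand = theta.copy()
            cand[idx_free] += step
            if not _stable(cand, structure, u_max):
                damping *= 8.0
                continue
            g_cand = _stack_predictions(cand, structure, hemo, designs)
            r_cand = y - g_cand
            obj_cand = objective(r_cand, lam, cand)
            if obj_cand > obj:
                theta, g, resid = cand, g_cand, r_cand
                obj = obj_cand
                damping = max(damping / 4.0, 1e-6)
                improved = True
                break
            damping *= 8.0
        # closed-form noise precision update; keep only if it helps
        lam_new = np.clip(n_obs / np.maximum((resid**2).sum(axis=0), 1e-12), 1e-8, 1e8)
        obj_new = objective(resid, lam_new, theta)
        if obj_new > obj:
            lam, obj = lam_new, obj_new
            improved = True
        history.append(obj)
        if history[-1] - history[-2] < tol:
            if jac_age == 0:  # genuine plateau, not a stale-matrix stall
                converged = True
                break
            jac_age = 10**9  # force a refresh before judging convergence

    # Laplace posterior covariance and full free energy at the final iterate
    w = np.repeat(lam[None, :], n_obs, axis=0).reshape(-1)
    jf = jac.reshape(n_obs * n_reg, n_par)
    h = jf.T @ (jf * w[:, None]) + np.diag(p0_diag[free])
    cov_free = np.linalg.inv(h)
    cov = np.zeros((free.size, free.size))
    cov[np.ix_(free, free)] = cov_free
    sign, logdet_post = np.linalg.slogdet(cov_free)
    logdet_prior = float(np.sum(np.log(prior_var[free])))
    # Laplace evidence: penalized log-joint + posterior-volume term,
    # normalized by the prior volume so models of different size compare.
    f_full = obj - 0.5 * n_obs * n_reg * np.log(2 * np.pi) + 0.5 * logdet_post - 0.5 * logdet_prior if sign > 0 else obj
    sse = (resid**2).sum(axis=0)
    sst = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
    ev = 1.0 - sse / np.maximum(sst, 1e-12)

    params = DCMParameters.from_vector(theta, structure)
    return InversionResult(
        theta_mean=theta,
        theta_cov=cov,
        params=params,
        free_energy=float(f_full),
        objective_history=history,
        explained_variance=ev,
        noise_precision=lam,
        converged=converged,
        labels=params.labels(),
    )


# ---------------------------------------------------------------------------
# group level: parametric empirical Bayes + Bayesian model reduction
# ---------------------------------------------------------------------------

@dataclass
class PEBResult:
    """Group posteriors per parameter: commonalities (design intercept) and
    group differences (the -1/+1 group-code regressor)."""

    table: pd.DataFrame  # index: parameter label
    threshold: float = 0.95

    @property
    def commonalities(self) -> pd.DataFrame:
        return self.table[["common_mean", "common_sd", "common_prob"]]

    @property
    def group_difference(self) -> pd.DataFrame:
        return self.table[["diff_mean", "diff_sd", "diff_prob"]]


def _log_evidence(m, total_var, x, prior_var):
    """Gaussian marginal likelihood of subject means under the two-column
    design with independent zero-mean coefficient priors."""
    cov = x @ np.diag(prior_var) @ x.T + np.diag(total_var)
    sign, logdet = np.linalg.slogdet(cov)
    sol = np.linalg.solve(cov, m)
    return float(-0.5 * (m @ sol) - 0.5 * logdet - 0.5 * m.size * np.log(2 * np.pi))


def peb_group(
    results: Sequence[InversionResult],
    group_codes: Sequence[int],
    prior_scale: float = 1.0,
    em_iter: int = 32,
    reduction: bool = True,
) -> PEBResult:
    """Hierarchical (parametric empirical Bayes) group model.

    Each parameter is modeled independently: subject posterior means m_i
    with within-subject variance s_i obey
    m_i = beta_0 + beta_1 x_i + b_i + e_i with x_i the -1/+1 group code,
    b_i ~ N(0, tau) a between-subject effect whose variance is estimated
    by EM, and e_i ~ N(0, s_i).  Coefficients carry zero-mean Gaussian
    priors inherited from the first level.  Greedy Bayesian model
    reduction turns each coefficient off (prior variance -> 0) when the
    model evidence is higher without it; switched-off coefficients report
    mean 0 and posterior probability 0.  The posterior probability of a
    retained coefficient is the probability that its sign matches the
    posterior mean's sign.
    """
    codes = np.asarray(group_codes, dtype=float)
    if not set(np.unique(codes)) <= {-1.0, 1.0}:
        raise InvalidInputError("group codes must be -1 or +1")
    if (codes == -1).sum() < 2 or (codes == 1).sum() < 2:
        raise InvalidInputError("need >= 2 subjects per group")
    labels = results[0].labels
    for r in results:
        if r.labels != labels:
            raise InvalidInputError("mismatched parameter sets across subjects")

    means = np.stack([r.theta_mean for r in results])          # (n_subj, n_par)
    wvars = np.stack([np.diag(r.theta_cov) for r in results])  # (n_subj, n_par)
    # prior variance per parameter from the first-level prior structure
    st = results[0].params.structure
    pvar = Priors().variance_vector(st) * prior_scale
    x = np.column_stack([np.ones_like(codes), codes])

    rows = []
    for j, label in enumerate(labels):
        m = means[:, j]
        s = np.maximum(wvars[:, j], 1e-10)
        vbeta = np.array([pvar[j], pvar[j]])
        tau = max(float(np.var(m)) / 2.0, 1e-8)
        mu = np.zeros(2)
        for _ in range(em_iter):
            w = 1.0 / (s + tau)
            sig = np.linalg.inv(x.T @ (x * w[:, None]) + np.diag(1.0 / vbeta))
            mu = sig @ (x.T @ (m * w))
            r_i = m - x @ mu
            shrink = tau / (tau + s)
            eb2 = (shrink * r_i) ** 2 + shrink * s
            tau_new = max(float(eb2.mean()), 1e-10)
            if abs(tau_new - tau) < 1e-12:
                tau = tau_new
                break
            tau = tau_new

        total = s + tau
        keep = [True, True]
        if reduction:
            off = 1e-12
            best = _log_evidence(m, total, x, vbeta)
            improved = True
            while improved:
                improved = False
                for c in (1, 0):
                    if not keep[c]:
                        continue
                    trial = vbeta.copy()
                    trial[c] = off
                    ev = _log_evidence(m, total, x, np.where(keep, trial, off))
                    if ev > best:
                        best, keep[c] = ev, False
                        improved = True
        v_used = np.where(keep, vbeta, 1e-12)
        w = 1.0 / total
        sig = np.linalg.inv(x.T @ (x * w[:, None]) + np.diag(1.0 / v_used))
        mu = sig @ (x.T @ (m * w))
        sd = np.sqrt(np.diag(sig))
        prob = norm.cdf(np.abs(mu) / np.maximum(sd, 1e-12))
        row = {"parameter": label, "tau": tau}
        for c, name in enumerate(("common", "diff")):
            if keep[c]:
                row[f"{name}_mean"] = mu[c]
                row[f"{name}_sd"] = sd[c]
                row[f"{name}_prob"] = float(prob[c])
            else:
                row[f"{name}_mean"] = 0.0
                row[f"{name}_sd"] = 0.0
                row[f"{name}_prob"] = 0.0
        rows.append(row)
    table = pd.DataFrame(rows).set_index("parameter")
    table["common_credible"] = table["common_prob"] > 0.95
    table["diff_credible"] = table["diff_prob"] > 0.95
    return PEBResult(table=table)


def credible_set(peb: PEBResult, threshold: float = 0.95, level: str = "diff") -> list[str]:
    """Parameters whose posterior probability strictly exceeds the
    threshold at the requested level ('common' or 'diff')."""
    if level not in ("common", "diff"):
        raise InvalidInputError("level must be 'common' or 'diff'")
    col = f"{level}_prob"
    return list(peb.table.index[peb.table[col] > threshold])
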