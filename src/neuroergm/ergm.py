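"""ERGM estimation: pseudolikelihood, Metropolis sampling, and MCMC-MLE.

The model is P(Y = y) = exp(theta' g(y)) / c(theta) over graphs with a fixed
node set. Estimation follows the standard two-stage scheme: a maximum
pseudolikelihood fit (a logistic regression of dyad states on change
statistics) provides the starting value, after which the intractable
normalizing-constant ratio c(theta)/c(theta_s) is replaced by the
importance-sampling average (1/M) sum_i exp((theta - theta_s)' g(y_i)) over
networks y_i drawn from the model at theta_s, and the resulting approximate
likelihood is maximized by Newton steps with step-halving, re-sampling at
the updated value until the simulated statistic means match the observed
statistics.

The same machinery serves conditional (dyad-constrained) fits, which is how
the separable temporal models in :mod:`neuroergm.stergm` are estimated: a
fit is internally a sum of independent likelihood components, each with its
own graph, free-dyad set, and observed statistic vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from .graph import Network
from .terms import BoundModel, GraphState, ModelSpec, all_dyads

__all__ = [
    "SamplerControl",
    "SampleResult",
    "FitResult",
    "MCMCDiagnostics",
    "EstimationError",
    "DegeneracyError",
    "fit_mple",
    "sample_networks",
    "fit_mcmc_mle",
    "approx_loglik_ratio",
    "mcmc_diagnostics",
    "select_gwesp_decay",
    "significance_stars",
]


class EstimationError(RuntimeError):
    """Estimation failed (rank deficiency, separation, no free dyads)."""


class DegeneracyError(EstimationError):
    """The sampler drifted to near-empty/near-full graphs far from the data."""


def significance_stars(p: float) -> str:
    """Conventional thresholds: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class SamplerControl:
    """Metropolis chain settings.

    ``burn_in`` and ``interval`` default to 10*D and D respectively, where D
    is the number of free dyads. ``proposal`` is one of ``"uniform"``
    (symmetric uniform dyad toggle), ``"tnt"`` (tie/no-tie, which proposes
    existing ties half the time and helps mixing on sparse graphs), or
    ``"mixture"`` (each step picks tie/no-tie with probability
    ``tnt_prob``, otherwise a uniform toggle). Identical control plus
    identical inputs yield identical draws.
    """

    burn_in: int | None = None
    interval: int | None = None
    samples: int = 1000
    proposal: str = "mixture"
    tnt_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("burn_in", "interval"):
            v = getattr(self, name)
            if v is not None and v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v}")
        if self.samples < 1:
            raise ValueError(f"samples must be >= 1, got {self.samples}")
        if self.proposal not in ("uniform", "tnt", "mixture"):
            raise ValueError(f"unknown proposal {self.proposal!r}")

    def resolved(self, n_free: int) -> "SamplerControl":
        return replace(
            self,
            burn_in=self.burn_in if self.burn_in is not None else 10 * n_free,
            interval=self.interval if self.interval is not None else n_free,
        )


# ---------------------------------------------------------------------------
# Metropolis chain over dyad toggles

_CHUNK = 8192


class _Chain:
    """Edge-toggle Metropolis chain restricted to a free-dyad set.

    Frozen dyads (those outside the free set) keep their initial state and
    still contribute to the statistics; this is what conditional
    formation/dissolution sampling needs.
    """

    def __init__(self, bound, theta, state, free_pairs, rng, proposal, tnt_prob):
        self.bound = bound
        self.state = state
        self.terms = bound.terms
        self.theta_split = bound.split_theta(theta)
        self.rng = rng
        if proposal == "uniform":
            self.p_tnt = 0.0
        elif proposal == "tnt":
            self.p_tnt = 1.0
        else:
            self.p_tnt = float(tnt_prob)
        self.fi = [int(i) for i, _ in free_pairs]
        self.fj = [int(j) for _, j in free_pairs]
        self.D = len(free_pairs)
        if self.D == 0:
            raise EstimationError("no free dyads to sample over")
        self.pair_idx = {(i, j): k for k, (i, j) in enumerate(zip(self.fi, self.fj))}
        self.edges: list[tuple[int, int]] = []
        self.pos: dict[tuple[int, int], int] = {}
        for i, j in zip(self.fi, self.fj):
            if state.has(i, j):
                self._edge_add(i, j)

    def _edge_add(self, i, j):
        self.pos[(i, j)] = len(self.edges)
        self.edges.append((i, j))

    def _edge_remove(self, i, j):
        k = self.pos.pop((i, j))
        last = self.edges.pop()
        if last != (i, j):
            self.edges[k] = last
            self.pos[last] = k

    def _score(self, i, j) -> float:
        s = 0.0
        for term, th in zip(self.terms, self.theta_split):
            s += term.score(self.state, i, j, th)
        return s

    def advance(self, nsteps: int) -> None:
        state, rng = self.state, self.rng
        fi, fj, D = self.fi, self.fj, self.D
        p_tnt = self.p_tnt
        log, exp = math.log, math.exp
        done = 0
        while done < nsteps:
            m = min(_CHUNK, nsteps - done)
            u_kern = rng.random(m)
            u_branch = rng.random(m)
            u_pick = rng.random(m)
            u_acc = rng.random(m)
            for t in range(m):
                E = len(self.edges)
                tnt = u_kern[t] < p_tnt
                if tnt and E > 0 and u_branch[t] < 0.5:
                    i, j = self.edges[int(u_pick[t] * E)]
                else:
                    k = int(u_pick[t] * D)
                    i, j = fi[k], fj[k]
                present = j in state.nbrs[i]
                if tnt:
                    # Hastings correction for the tie/no-tie kernel
                    if present:
                        q_f = (0.5 / E if E else 0.0) + 0.5 / D
                        Ep = E - 1
                        q_r = 0.5 / D if Ep > 0 else 1.0 / D
                    else:
                        q_f = 0.5 / D if E > 0 else 1.0 / D
                        Ep = E + 1
                        q_r = 0.5 / Ep + 0.5 / D
                    log_h = log(q_r) - log(q_f)
                else:
                    log_h = 0.0
                if present:
                    state.remove(i, j)
                    dlp = -self._score(i, j) + log_h
                    if dlp >= 0.0 or u_acc[t] < exp(dlp):
                        self._edge_remove(i, j)
                    else:
                        state.add(i, j)
                else:
                    dlp = self._score(i, j) + log_h
                    if dlp >= 0.0 or u_acc[t] < exp(dlp):
                        state.add(i, j)
                        self._edge_add(i, j)
            done += m

    def free_edge_indicator(self, out: np.ndarray) -> None:
        pair_idx = self.pair_idx
        for e in self.edges:
            out[pair_idx[e]] += 1.0


@dataclass
class SampleResult:
    """Draws from an ERGM at fixed coefficients."""

    stats: pd.DataFrame
    networks: list[Network] | None
    occupancy: np.ndarray | None  # per free dyad, mean edge indicator
    free_pairs: list[tuple[int, int]]
    control: SamplerControl

    @property
    def mean_occupancy(self) -> float:
        if self.occupancy is None:
            raise ValueError("sampling was run without track_occupancy=True")
        return float(self.occupancy.mean())


def _run_sampler(
    bound,
    theta,
    state,
    free_pairs,
    control: SamplerControl,
    rng,
    return_networks: bool,
    track_occupancy: bool,
    labels,
):
    control = control.resolved(len(free_pairs))
    chain = _Chain(bound, theta, state, free_pairs, rng, control.proposal, control.tnt_prob)
    chain.advance(control.burn_in)
    stats = np.empty((control.samples, bound.k))
    nets = [] if return_networks else None
    occ = np.zeros(len(free_pairs)) if track_occupancy else None
    for s in range(control.samples):
        chain.advance(control.interval)
        stats[s] = bound.stats(state)
        if nets is not None:
            nets.append(state.to_network(labels))
        if occ is not None:
            chain.free_edge_indicator(occ)
    if occ is not None:
        occ /= control.samples
    return stats, nets, occ, control


def sample_networks(
    spec: ModelSpec,
    theta,
    n_nodes: int | None = None,
    attrs=None,
    control: SamplerControl | None = None,
    start: Network | None = None,
    free_dyads: Sequence[tuple[int, int]] | None = None,
    return_networks: bool = True,
    track_occupancy: bool = False,
) -> SampleResult:
    """Draw networks from the model at fixed ``theta``.

    The chain starts at ``start`` (default: the empty graph on ``n_nodes``
    nodes), discards ``burn_in`` proposals, then retains one draw every
    ``interval`` proposals. ``free_dyads`` restricts toggles to a subset of
    index pairs; all other dyads are frozen at their starting state.
    """
    if start is None:
        if n_nodes is None:
            raise ValueError("give either n_nodes or a start network")
        start = Network.empty([f"n{i}" for i in range(n_nodes)])
    if control is None:
        control = SamplerControl()
    bound = BoundModel(spec, start, attrs)
    state = GraphState.from_network(start)
    free = list(free_dyads) if free_dyads is not None else all_dyads(start.n)
    rng = np.random.default_rng(control.seed)
    theta = np.asarray(theta, dtype=float)
    stats, nets, occ, control = _run_sampler(
        bound, theta, state, free, control, rng, return_networks, track_occupancy,
        start.node_labels,
    )
    return SampleResult(
        stats=pd.DataFrame(stats, columns=bound.names),
        networks=nets,
        occupancy=occ,
        free_pairs=free,
        control=control,
    )


# ---------------------------------------------------------------------------
# diagnostics


@dataclass
class MCMCDiagnostics:
    """Per-statistic comparison of a sampled chain with the observed values."""

    summary: pd.DataFrame  # mean, sd, deviation, z, lag1_autocorr, ess, ok
    sd_multiple: float

    @property
    def ok(self) -> bool:
        return bool(self.summary["ok"].all())


def _lag1_autocorr(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if len(x) < 3 or np.std(x) == 0:
        return 0.0
    a, b = x[:-1], x[1:]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def mcmc_diagnostics(stats, g_obs, sd_multiple: float = 4.0) -> MCMCDiagnostics:
    """Mean deviation, lag-1 autocorrelation, and effective sample size.

    A statistic fails when the simulated mean sits more than ``sd_multiple``
    simulated standard deviations from the observed value (the degeneracy
    guard used during estimation).
    """
    if isinstance(stats, pd.DataFrame):
        names = list(stats.columns)
        x = stats.to_numpy(dtype=float)
    else:
        x = np.asarray(stats, dtype=float)
        names = [f"stat{j}" for j in range(x.shape[1])]
    if x.shape[0] < 10:
        raise ValueError("need at least 10 sampled statistic vectors")
    g_obs = np.asarray(g_obs, dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    dev = mean - g_obs
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, dev / np.where(sd > 0, sd, 1.0), np.where(dev == 0, 0.0, np.inf))
    rho = np.array([_lag1_autocorr(x[:, j]) for j in range(x.shape[1])])
    ess = np.clip(len(x) * (1 - rho) / np.clip(1 + rho, 1e-9, None), 1.0, len(x))
    ok = np.abs(z) <= sd_multiple
    df = pd.DataFrame(
        {
            "observed": g_obs,
            "mean": mean,
            "sd": sd,
            "deviation": dev,
            "z": z,
            "lag1_autocorr": rho,
            "ess": ess,
            "ok": ok,
        },
        index=names,
    )
    return MCMCDiagnostics(summary=df, sd_multiple=sd_multiple)


# ---------------------------------------------------------------------------
# fit results


@dataclass
class FitResult:
    """Coefficients, Wald inference, and sampler bookkeeping for one fit."""

    names: list[str]
    theta: np.ndarray
    se: np.ndarray
    method: str
    converged: bool
    iterations: int = 0
    loglik_ratio: float | None = None
    control: SamplerControl | None = None
    diagnostics: MCMCDiagnostics | None = None

    @property
    def tvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.theta / self.se

    @property
    def pvalues(self) -> np.ndarray:
        # normal reference for t = theta / SE
        return 2.0 * norm.sf(np.abs(self.tvalues))

    def coef(self) -> dict[str, float]:
        return dict(zip(self.names, self.theta.tolist()))

    def summary(self) -> pd.DataFrame:
        p = self.pvalues
        return pd.DataFrame(
            {
                "estimate": self.theta,
                "se": self.se,
                "t": self.tvalues,
                "p": p,
                "signif": [significance_stars(v) for v in p],
            },
            index=self.names,
        )

    def __str__(self) -> str:
        head = f"{self.method.upper()} fit ({'converged' if self.converged else 'NOT converged'})"
        return head + "\n" + self.summary().to_string(float_format=lambda v: f"{v:.4f}")


# ---------------------------------------------------------------------------
# maximum pseudolikelihood


def _change_stat_matrix(bound, state: GraphState, free_pairs):
    """Design matrix of toggle-on change statistics and dyad states."""
    X = np.empty((len(free_pairs), bound.k))
    y = np.empty(len(free_pairs))
    for r, (i, j) in enumerate(free_pairs):
        present = state.has(i, j)
        if present:
            state.remove(i, j)
        X[r] = bound.delta(state, i, j)
        if present:
            state.add(i, j)
        y[r] = 1.0 if present else 0.0
    return X, y


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # walk columns, flag those that do not increase the rank
        bad, keep = [], np.empty((X.shape[0], 0))
        for c in range(X.shape[1]):
            cand = np.column_stack([keep, X[:, c]])
            if np.linalg.matrix_rank(cand) > keep.shape[1]:
                keep = cand
            else:
                bad.append(names[c])
        raise EstimationError(
            "change-statistic design matrix is rank deficient; "
            f"collinear terms: {bad}"
        )


def _mple_from_design(X, y, names) -> tuple[np.ndarray, np.ndarray, float]:
    import statsmodels.api as sm

    _check_rank(X, names)
    try:
        with np.errstate(divide="ignore", over="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as e:  # statsmodels PerfectSeparationError and kin
        raise EstimationError(
            f"pseudolikelihood fit failed ({e}); check for separation in "
            f"terms {names}"
        ) from None
    if not np.all(np.isfinite(res.bse)):
        raise EstimationError(
            "pseudolikelihood standard errors are not finite; the model "
            f"may be separated in terms {names}"
        )
    return np.asarray(res.params), np.asarray(res.bse), float(res.llr)


def fit_mple(spec: ModelSpec, net: Network, attrs=None) -> FitResult:
    """Maximum pseudolikelihood: logistic fit of dyad states on change stats.

    Exact MLE for dyad-independent models (edges/nodecov/nodemix only); a
    starting value and benchmark otherwise. Standard errors come from the
    inverse observed information of the logistic likelihood.
    """
    bound = BoundModel(spec, net, attrs)
    state = GraphState.from_network(net)
    X, y = _change_stat_matrix(bound, state, all_dyads(net.n))
    theta, se, llr = _mple_from_design(X, y, bound.names)
    return FitResult(
        names=bound.names, theta=theta, se=se, method="mple", converged=True,
        loglik_ratio=llr,
    )


# ---------------------------------------------------------------------------
# importance-sampled likelihood maximization


def approx_loglik_ratio(theta, theta_s, sampled_stats, g_obs) -> float:
    """log P_theta(y_obs) - log P_theta_s(y_obs), via the importance-sampling
    approximation of c(theta)/c(theta_s) over draws taken at ``theta_s``.

    Computed with a log-sum-exp shift, so the result is finite whenever the
    inputs are.
    """
    theta = np.asarray(theta, dtype=float)
    theta_s = np.asarray(theta_s, dtype=float)
    g = np.asarray(
        sampled_stats.to_numpy() if isinstance(sampled_stats, pd.DataFrame) else sampled_stats,
        dtype=float,
    )
    if g.ndim != 2 or g.shape[0] < 1:
        raise ValueError("need at least one sampled statistic vector")
    d = theta - theta_s
    return float(d @ np.asarray(g_obs, dtype=float) - (logsumexp(g @ d) - math.log(g.shape[0])))


def _is_objective(theta, theta_ref, g_obs_total, samples, base_logw):
    """Value/gradient/Hessian of the importance-sampled log-likelihood
    (relative to theta_ref's normalizing constants) plus the minimum
    effective sample size of the weights across components."""
    k = len(theta)
    val = float(theta @ g_obs_total)
    grad = np.array(g_obs_total, dtype=float)
    H = np.zeros((k, k))
    ess_min = math.inf
    for g, b in zip(samples, base_logw):
        a = g @ theta - b
        val -= logsumexp(a) - math.log(len(a))
        w = np.exp(a - a.max())
        w /= w.sum()
        mu = w @ g
        grad -= mu
        gc = g - mu
        H -= gc.T @ (gc * w[:, None])
        ess_min = min(ess_min, 1.0 / float(w @ w))
    return val, grad, H, ess_min


def _maximize_is(theta0, g_obs_total, samples, base_logw, scale, grad_tol=1e-3,
                 max_steps=100, ess_floor=5.0):
    """Newton ascent with step-halving on the importance-sampled likelihood."""
    theta = np.asarray(theta0, dtype=float).copy()
    val, grad, H, ess = _is_objective(theta, theta0, g_obs_total, samples, base_logw)
    for _ in range(max_steps):
        if np.max(np.abs(grad) / scale) < grad_tol:
            break
        ridge = 1e-8 * np.trace(-H) / len(theta) + 1e-12
        try:
            step = np.linalg.solve(-H + ridge * np.eye(len(theta)), grad)
        except np.linalg.LinAlgError:
            step = grad / np.maximum(scale**2, 1e-12)
        accepted = False
        for _h in range(40):
            cand = theta + step
            v2, g2, H2, e2 = _is_objective(cand, theta0, g_obs_total, samples, base_logw)
            if np.isfinite(v2) and v2 >= val - 1e-12 and e2 >= ess_floor:
                theta, val, grad, H, ess = cand, v2, g2, H2, e2
                accepted = True
                break
            step = step / 2.0
        if not accepted:
            break
    return theta, val, grad, H, ess


@dataclass
class _Component:
    """One independent likelihood factor of a (possibly conditional) fit."""

    bound: BoundModel
    start_nbrs: list[set]
    free_pairs: list[tuple[int, int]]
    g_obs: np.ndarray
    labels: tuple

    def fresh_state(self) -> GraphState:
        return GraphState(len(self.start_nbrs), [set(s) for s in self.start_nbrs])


def _component_from_network(spec, net, attrs, free_pairs=None) -> _Component:
    bound = BoundModel(spec, net, attrs)
    state = GraphState.from_network(net)
    free = list(free_pairs) if free_pairs is not None else all_dyads(net.n)
    if not free:
        raise EstimationError("no free dyads in component")
    return _Component(
        bound=bound,
        start_nbrs=[set(s) for s in state.nbrs],
        free_pairs=free,
        g_obs=bound.stats(state),
        labels=net.node_labels,
    )


def _pooled_mple(components) -> tuple[np.ndarray, np.ndarray]:
    Xs, ys = [], []
    for comp in components:
        X, y = _change_stat_matrix(comp.bound, comp.fresh_state(), comp.free_pairs)
        Xs.append(X)
        ys.append(y)
    X = np.vstack(Xs)
    y = np.concatenate(ys)
    theta, se, _ = _mple_from_design(X, y, components[0].bound.names)
    return theta, se


def _fit_components(
    components: list[_Component],
    control: SamplerControl,
    theta_init=None,
    max_iter: int = 20,
    outer_tol: float = 0.1,
    grad_tol: float = 1e-3,
    degeneracy_sd: float = 4.0,
    max_restarts: int = 2,
) -> FitResult:
    names = components[0].bound.names
    k = components[0].bound.k
    if theta_init is None:
        theta_s, _ = _pooled_mple(components)
    else:
        theta_s = np.asarray(theta_init, dtype=float).copy()
        if theta_s.shape != (k,):
            raise ValueError(f"theta_init has length {theta_s.size}, expected {k}")
    g_obs_total = np.sum([c.g_obs for c in components], axis=0)
    rng = np.random.default_rng(control.seed)
    burn_mult = 1
    restarts = 0
    converged = False
    theta_hat = theta_s
    last = None  # (samples, theta_s of that sample)
    it = 0
    while it < max_iter:
        it += 1
        samples = []
        for comp in components:
            ctl = control.resolved(len(comp.free_pairs))
            ctl = replace(ctl, burn_in=ctl.burn_in * burn_mult)
            stats, _, _, _ = _run_sampler(
                comp.bound, theta_s, comp.fresh_state(), comp.free_pairs, ctl,
                rng, False, False, comp.labels,
            )
            samples.append(stats)
        mean = np.sum([s.mean(axis=0) for s in samples], axis=0)
        sd = np.sqrt(np.sum([s.var(axis=0, ddof=1) for s in samples], axis=0))
        # degeneracy guard: simulated means far outside the simulated spread
        dev = np.abs(mean - g_obs_total)
        bad = dev > degeneracy_sd * np.where(sd > 0, sd, np.finfo(float).tiny)
        stuck = (sd == 0) & (dev > 0)
        if np.any(bad | stuck):
            if restarts < max_restarts:
                restarts += 1
                burn_mult *= 2
                it -= 1
                continue
            detail = pd.DataFrame(
                {"observed": g_obs_total, "sim_mean": mean, "sim_sd": sd},
                index=names,
            )
            raise DegeneracyError(
                "sampler drifted away from the observed statistics "
                f"(>{degeneracy_sd} simulated SDs):\n{detail}"
            )
        scale = np.where(sd > 0, sd, 1.0)
        base_logw = [s @ theta_s for s in samples]
        zmax = float(np.max(dev / scale))
        theta_hat, _val, _grad, H, _ess = _maximize_is(
            theta_s, g_obs_total, samples, base_logw, scale, grad_tol=grad_tol,
            ess_floor=max(5.0, 0.01 * control.samples),
        )
        last = (samples, theta_hat, H)
        if zmax <= outer_tol:
            converged = True
            break
        theta_s = theta_hat
    samples, theta_hat, H = last
    info = -H  # importance-weighted covariance of statistics = Fisher info
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    # approximate LR against the null (uniform) model via reverse importance
    # sampling on the final draws; noisy, used for model comparison only
    lr0 = float(theta_hat @ g_obs_total)
    for s in samples:
        lr0 += float(logsumexp(-(s @ theta_hat)) - math.log(len(s)))
    diag = None
    if len(components) == 1:
        diag = mcmc_diagnostics(
            pd.DataFrame(samples[0], columns=names), g_obs_total,
            sd_multiple=degeneracy_sd,
        )
    return FitResult(
        names=names,
        theta=theta_hat,
        se=se,
        method="mcmc-mle",
        converged=converged,
        iterations=it,
        loglik_ratio=lr0,
        control=control,
        diagnostics=diag,
    )


def fit_mcmc_mle(
    spec: ModelSpec,
    net: Network,
    attrs=None,
    control: SamplerControl | None = None,
    theta_init=None,
    max_iter: int = 20,
    outer_tol: float = 0.1,
    grad_tol: float = 1e-3,
    degeneracy_sd: float = 4.0,
) -> FitResult:
    """Monte Carlo maximum likelihood for a single observed network.

    Starts from the pseudolikelihood estimate (unless ``theta_init`` is
    given) and alternates sampling at the current value with maximization of
    the importance-sampled likelihood, stopping once the simulated statistic
    means match the observed vector to within ``outer_tol`` simulated SDs.
    Standard errors are the square roots of the diagonal of the inverse
    importance-weighted covariance of the sampled statistics; t = theta/SE
    is referred to the standard normal.
    """
    if net.edge_count == 0 or net.edge_count == net.dyad_count:
        raise EstimationError(
            "observed network is empty or complete; the MLE does not exist"
        )
    comp = _component_from_network(spec, net, attrs)
    control = control if control is not None else SamplerControl()
    return _fit_components(
        [comp], control, theta_init=theta_init, max_iter=max_iter,
        outer_tol=outer_tol, grad_tol=grad_tol, degeneracy_sd=degeneracy_sd,
    )


# ---------------------------------------------------------------------------
# GWESP decay grid


def default_decay_grid() -> np.ndarray:
    """The screening grid for the GWESP decay: 0.05 to 2.0 in steps of 0.05."""
    return np.round(np.arange(1, 41) * 0.05, 2)


def select_gwesp_decay(
    spec_template: ModelSpec,
    net: Network,
    attrs=None,
    grid=None,
    control: SamplerControl | None = None,
    **fit_kwargs,
) -> tuple[float, dict[float, FitResult]]:
    """Profile the fixed GWESP decay over a grid and pick the best fit.

    One MCMC-MLE fit is run at a pilot decay (the grid median); because
    every candidate GWESP statistic is a function of the same edgewise
    shared-partner histogram, a single reference sample (with per-network
    ESP histograms recorded) supports an importance-sampled maximum
    likelihood fit at every other decay. The winner is the converged fit
    with the highest approximated log-likelihood (equal up to one shared
    normalizing constant across candidates); ties break toward the smaller
    decay. Candidates whose importance weights degenerate (tiny effective
    sample size) are marked non-converged.
    """
    from .graph import esp_counts
    from .terms import Gwesp

    grid = default_decay_grid() if grid is None else np.asarray(list(grid), dtype=float)
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("decay grid must be nonempty with positive values")
    grid = np.sort(grid)
    gw_pos = [t for t, term in enumerate(spec_template.terms) if isinstance(term, Gwesp)]
    if len(gw_pos) != 1:
        raise ValueError("spec_template must contain exactly one gwesp term")
    control = control if control is not None else SamplerControl()
    if grid.size == 1:
        fr = fit_mcmc_mle(spec_template.with_gwesp_decay(grid[0]), net, attrs,
                          control=control, **fit_kwargs)
        return float(grid[0]), {float(grid[0]): fr}

    pilot = float(grid[len(grid) // 2])
    pilot_spec = spec_template.with_gwesp_decay(pilot)
    pilot_fit = fit_mcmc_mle(pilot_spec, net, attrs, control=control, **fit_kwargs)
    bound = BoundModel(pilot_spec, net, attrs)
    gw_col = int(bound.offsets[gw_pos[0]])
    draw = sample_networks(
        pilot_spec, pilot_fit.theta, attrs=attrs,
        control=replace(control, seed=control.seed + 1),
        start=net, return_networks=True,
    )
    g_ref = draw.stats.to_numpy()
    esp_hists = np.array([esp_counts(y).counts for y in draw.networks], dtype=float)
    esp_obs = esp_counts(net).counts.astype(float)
    g_obs_ref = bound.stats(GraphState.from_network(net))
    base_logw = g_ref @ pilot_fit.theta

    idx = np.arange(1, esp_hists.shape[1])
    results: dict[float, FitResult] = {}
    failures: dict[float, str] = {}
    M = g_ref.shape[0]
    for tau in grid:
        w = math.exp(tau) * (1.0 - (1.0 - math.exp(-tau)) ** idx)
        g_tau = g_ref.copy()
        g_tau[:, gw_col] = esp_hists[:, 1:] @ w
        g_obs_tau = g_obs_ref.copy()
        g_obs_tau[gw_col] = esp_obs[1:] @ w
        sd = g_tau.std(axis=0, ddof=1)
        scale = np.where(sd > 0, sd, 1.0)
        theta0 = pilot_fit.theta.copy()
        theta_hat, val, _grad, H, ess = _maximize_is(
            theta0, g_obs_tau, [g_tau], [base_logw], scale,
            ess_floor=max(10.0, 0.02 * M),
        )
        conv = ess >= max(20.0, 0.05 * M)
        try:
            se = np.sqrt(np.clip(np.diag(np.linalg.inv(-H)), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(bound.k, np.nan)
        names = list(bound.names)
        names[gw_col] = f"gwesp.fixed.{tau:g}"
        fr = FitResult(
            names=names, theta=theta_hat, se=se, method="mcmc-mle/is",
            converged=bool(conv), iterations=pilot_fit.iterations,
            loglik_ratio=val, control=control,
        )
        results[float(tau)] = fr
        if not conv:
            failures[float(tau)] = f"importance weights degenerate (ESS={ess:.1f})"
    ok = [(tau, fr) for tau, fr in results.items() if fr.converged]
    if not ok:
        raise DegeneracyError(
            "no decay candidate produced a usable fit: "
            + "; ".join(f"{t}: {m}" for t, m in failures.items())
        )
    best = min(ok, key=lambda item: (-item[1].loglik_ratio, item[0]))[0]
    return float(best), results
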