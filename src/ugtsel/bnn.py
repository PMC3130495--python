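"""Hierarchical Bayesian neural-network classifier trained by Gibbs + HMC.

A single-hidden-layer network (tanh hidden units, logistic output) is given
independent zero-mean Gaussian priors on its parameters.  Prior precisions
are shared within four parameter groups — input-to-hidden weights, hidden
biases, hidden-to-output weights, and the output bias — and each trainable
group's precision tau carries a Gamma hyperprior parameterized by shape
control alpha and scale control w:

    P(tau) = (alpha/2w)^(alpha/2) / Gamma(alpha/2)
             * tau^(alpha/2 - 1) * exp(-tau * alpha / 2w)

i.e. a Gamma with shape alpha/2 and rate alpha/(2w), whose mean is w; smaller
alpha spreads the hyperprior (variance 2 w^2 / alpha).  The Gaussian/Gamma
pair is conjugate, so precision updates are exact Gibbs draws, alternated
with Hamiltonian Monte Carlo (leapfrog + Metropolis) weight updates:

  phase 1  short sampling at fixed precisions to move near equilibrium;
  phase 2  alternating Gibbs precision draws and HMC weight trajectories,
           with thinned post-burn-in snapshots kept as the posterior sample.

Prediction averages the per-sample network outputs; sigma = tau^(-1/2)
relates a group's precision to its prior standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "Topology",
    "GroupPrior",
    "MCMCSchedule",
    "PosteriorSample",
    "param_count",
    "default_groups",
    "gamma_hyperprior_pdf",
    "sample_hyperprior",
    "gibbs_update_precision",
    "mcmc_train",
    "bnn_predict",
]

GROUP_NAMES = ("input_hidden", "hidden_bias", "hidden_output", "output_unit")


@dataclass(frozen=True)
class Topology:
    """One-hidden-layer network shape; the default working size is
    (602, 301, 1) for 86 concatenated window positions x 7 indices."""

    n_in: int
    n_hidden: int
    n_out: int = 1

    def __post_init__(self) -> None:
        if min(self.n_in, self.n_hidden, self.n_out) < 1:
            raise ValueError("all layer sizes must be >= 1")

    def slices(self) -> dict[str, slice]:
        """Flat-parameter-vector slices of the four parameter groups."""
        a = self.n_in * self.n_hidden
        b = a + self.n_hidden
        c = b + self.n_hidden * self.n_out
        d = c + self.n_out
        return {
            "input_hidden": slice(0, a),
            "hidden_bias": slice(a, b),
            "hidden_output": slice(b, c),
            "output_unit": slice(c, d),
        }


def param_count(t: Topology) -> int:
    """Total network parameters: weights plus hidden and output biases."""
    return t.n_in * t.n_hidden + t.n_hidden + t.n_hidden * t.n_out + t.n_out


@dataclass(frozen=True)
class GroupPrior:
    """Precision state and hyperprior of one parameter group.

    ``fixed`` groups keep tau constant; trainable groups draw tau from the
    conjugate posterior each Gibbs pass.  The output bias is always fixed.
    """

    alpha: float = 1.0
    w: float = 1.0
    fixed: bool = False
    tau: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.w <= 0 or self.tau <= 0:
            raise ValueError("alpha, w and tau must be > 0")


def default_groups() -> dict[str, GroupPrior]:
    """Gamma(alpha=1, w=1) hyperpriors on the trainable groups; output bias
    fixed at precision 1 (sigma = 1)."""
    return {
        "input_hidden": GroupPrior(),
        "hidden_bias": GroupPrior(),
        "hidden_output": GroupPrior(),
        "output_unit": GroupPrior(fixed=True, tau=1.0),
    }


def gamma_hyperprior_pdf(tau, alpha: float, w: float):
    """Density of the precision hyperprior: Gamma(shape alpha/2, rate alpha/2w)."""
    if alpha <= 0 or w <= 0:
        raise ValueError("alpha and w must be > 0")
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau must be > 0")
    return stats.gamma.pdf(tau, a=alpha / 2.0, scale=2.0 * w / alpha)


def sample_hyperprior(alpha: float, w: float, rng: np.random.Generator, size=None):
    """Draw precisions from the Gamma hyperprior."""
    return rng.gamma(shape=alpha / 2.0, scale=2.0 * w / alpha, size=size)


def gibbs_update_precision(
    group_weights: np.ndarray, alpha: float, w: float, rng: np.random.Generator
) -> float:
    """Exact conjugate draw of a group precision given its current weights.

    Posterior is Gamma(shape alpha/2 + k/2, rate alpha/(2w) + sum(w_i^2)/2);
    an empty group returns a prior draw.
    """
    gw = np.asarray(group_weights, dtype=float)
    shape = alpha / 2.0 + gw.size / 2.0
    rate = alpha / (2.0 * w) + 0.5 * float(np.dot(gw, gw))
    return float(rng.gamma(shape=shape, scale=1.0 / rate))


# ---------------------------------------------------------------------------
# network evaluation and posterior geometry
# ---------------------------------------------------------------------------

def _unpack(params: np.ndarray, t: Topology):
    s = t.slices()
    w1 = params[s["input_hidden"]].reshape(t.n_in, t.n_hidden)
    b1 = params[s["hidden_bias"]]
    w2 = params[s["hidden_output"]].reshape(t.n_hidden, t.n_out)
    b2 = params[s["output_unit"]]
    return w1, b1, w2, b2


def _forward(params: np.ndarray, t: Topology, x: np.ndarray):
    w1, b1, w2, b2 = _unpack(params, t)
    h = np.tanh(x @ w1 + b1)
    f = (h @ w2 + b2).ravel()
    return h, f


def _sigmoid(f: np.ndarray) -> np.ndarray:
    out = np.empty_like(f)
    pos = f >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-f[pos]))
    ef = np.exp(f[~pos])
    out[~pos] = ef / (1.0 + ef)
    return out


def _potential_and_grad(
    params: np.ndarray, t: Topology, x: np.ndarray, y: np.ndarray, taus: np.ndarray
):
    """U = -log posterior (up to a constant) and its gradient.

    taus is the per-parameter precision vector; with no data the potential is
    the Gaussian prior energy alone.
    """
    grad = taus * params
    u = 0.5 * float(np.dot(params, taus * params))
    if len(y):
        h, f = _forward(params, t, x)
        p = _sigmoid(f)
        eps = 1e-12
        u -= float(np.dot(y, np.log(p + eps)) + np.dot(1 - y, np.log(1 - p + eps)))
        w1, b1, w2, b2 = _unpack(params, t)
        df = (p - y)[:, None]  # n x 1
        gw2 = h.T @ df
        gb2 = df.sum(axis=0)
        dh = (df @ w2.T) * (1 - h * h)
        gw1 = x.T @ dh
        gb1 = dh.sum(axis=0)
        s = t.slices()
        grad[s["input_hidden"]] += gw1.ravel()
        grad[s["hidden_bias"]] += gb1
        grad[s["hidden_output"]] += gw2.ravel()
        grad[s["output_unit"]] += gb2
    return u, grad


def _leapfrog(params, momentum, grad_fn, step: float, n_steps: int):
    p = params.copy()
    m = momentum.copy()
    u, g = grad_fn(p)
    for _ in range(n_steps):
        m = m - 0.5 * step * g
        p = p + step * m
        u, g = grad_fn(p)
        m = m - 0.5 * step * g
    return p, m, u


@dataclass(frozen=True)
class MCMCSchedule:
    """Two-phase sampling plan with HMC trajectory settings."""

    phase1: int = 100
    phase2: int = 1000
    leapfrog_steps: int = 20
    step_size: float = 0.05
    thin: int = 5

    def __post_init__(self) -> None:
        if self.phase1 < 0 or self.phase2 < 0:
            raise ValueError("phase lengths must be >= 0")
        if self.leapfrog_steps < 1 or self.step_size <= 0 or self.thin < 1:
            raise ValueError("invalid trajectory settings")


@dataclass
class PosteriorSample:
    """One thinned posterior snapshot: weights, group precisions, iteration."""

    weights: np.ndarray
    taus: dict[str, float]
    iteration: int


@dataclass
class TrainResult:
    samples: list[PosteriorSample]
    diagnostics: dict = field(default_factory=dict)


def _tau_vector(t: Topology, groups: dict[str, GroupPrior]) -> np.ndarray:
    taus = np.empty(param_count(t))
    for name, sl in t.slices().items():
        taus[sl] = groups[name].tau
    return taus


def mcmc_train(
    x: np.ndarray,
    y: np.ndarray,
    topology: Topology,
    groups: dict[str, GroupPrior] | None = None,
    schedule: MCMCSchedule | None = None,
    rng: np.random.Generator | int | None = None,
) -> TrainResult:
    """Train the hierarchical BNN; returns thinned post-burn-in samples.

    Weights start at zero.  Phase 1 runs HMC at the groups' fixed initial
    precisions; phase 2 alternates conjugate Gibbs precision draws with HMC
    weight trajectories, keeping every ``thin``-th state after the first half.
    Divergent trajectories (non-finite or exploding Hamiltonian) halve the
    step size with a warning.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if len(y) and not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if len(y) and x.shape[0] != len(y):
        raise ValueError("x and y disagree on the number of records")
    groups = dict(groups or default_groups())
    schedule = schedule or MCMCSchedule()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    t = topology
    params = np.zeros(param_count(t))
    step = schedule.step_size
    slices = t.slices()
    n_accept = n_total = 0

    def hmc_update(params, step):
        nonlocal n_accept, n_total
        taus = _tau_vector(t, groups)
        grad_fn = lambda p: _potential_and_grad(p, t, x, y, taus)
        m0 = rng.standard_normal(params.size)
        u0, _ = grad_fn(params)
        h0 = u0 + 0.5 * float(np.dot(m0, m0))
        p1, m1, u1 = _leapfrog(params, m0, grad_fn, step, schedule.leapfrog_steps)
        h1 = u1 + 0.5 * float(np.dot(m1, m1))
        n_total += 1
        if not np.isfinite(h1) or (h1 - h0) > 1e3:
            warnings.warn(f"divergent HMC trajectory (dH={h1 - h0:.3g}); halving step size")
            return params, step / 2.0
        if np.log(rng.uniform()) < h0 - h1:
            n_accept += 1
            return p1, step
        return params, step

    for _ in range(schedule.phase1):
        params, step = hmc_update(params, step)

    samples: list[PosteriorSample] = []
    burn = schedule.phase2 // 2
    if schedule.phase1 == 0 and schedule.phase2 == 0:
        samples.append(
            PosteriorSample(
                weights=params.copy(),
                taus={g: gp.tau for g, gp in groups.items()},
                iteration=0,
            )
        )
    for it in range(schedule.phase2):
        for name in GROUP_NAMES:
            gp = groups[name]
            if gp.fixed:
                continue
            tau = gibbs_update_precision(params[slices[name]], gp.alpha, gp.w, rng)
            groups[name] = replace(gp, tau=tau)
        params, step = hmc_update(params, step)
        if it >= burn and (it - burn) % schedule.thin == 0:
            samples.append(
                PosteriorSample(
                    weights=params.copy(),
                    taus={g: gp.tau for g, gp in groups.items()},
                    iteration=it,
                )
            )

    diagnostics: dict = {"acceptance_rate": (n_accept / n_total) if n_total else 1.0,
                         "final_step_size": step}
    if samples and len(y):
        sq_err = [
            float(np.mean((_sigmoid(_forward(s.weights, t, x)[1]) - y) ** 2))
            for s in samples
        ]
        diagnostics["mean_squared_error"] = float(np.mean(sq_err))
    if samples:
        w_all = np.stack([s.weights for s in samples])
        diagnostics["weight_range"] = float(np.ptp(w_all))
        for name in GROUP_NAMES:
            taus = [s.taus[name] for s in samples]
            diagnostics[f"tau_range_{name}"] = float(np.ptp(taus))
    return TrainResult(samples=samples, diagnostics=diagnostics)


def bnn_predict(
    samples: list[PosteriorSample], x: np.ndarray, topology: Topology
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-mean class probability and thresholded binary label."""
    if not samples:
        raise ValueError("empty posterior sample list")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    probs = np.mean(
        [_sigmoid(_forward(s.weights, topology, x)[1]) for s in samples], axis=0
    )
    return probs, (probs >= 0.5).astype(int)
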