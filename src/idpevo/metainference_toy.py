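"""Desk-scale Gaussian metainference with parallel-bias well-tempered
metadynamics, on analytic toy systems.

The total energy over ``N`` replicas is

    E = sum_r { E_ff(X_r)
                + kT * sum_i [ (fbar_i - d_i)^2 / (2 sigma_{r,i}^2)
                               + 0.5 log(2 pi sigma_{r,i})
                               + 0.5 log sigma_{r,i} ] }

where ``fbar_i`` is the forward-model prediction averaged over the
replicas and ``sigma_{r,i}`` are per-replica error parameters sampled on
the fly.  Sampling is Metropolis Monte Carlo; each replica is enhanced
by a shared parallel-bias well-tempered metadynamics potential over the
system's collective variables, with the bias held constant outside a
configured interval per CV.  Final-bias reweighting uses
``w ∝ exp(+B(X)/kT)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ToySystem:
    """Analytic stand-in for a molecular system.

    ``energy`` maps a configuration vector (shape ``(dim,)``) to kJ/mol;
    ``cvs`` and ``forward_models`` are scalar functions of the
    configuration.
    """

    name: str
    dim: int
    energy: callable
    cvs: list = field(default_factory=list)
    forward_models: list = field(default_factory=list)
    bounds: tuple = (-3.0, 3.0)  # configuration-space box (per dimension)

    def cv_values(self, x: np.ndarray) -> np.ndarray:
        return np.array([cv(x) for cv in self.cvs], dtype=float)

    def observables(self, x: np.ndarray) -> np.ndarray:
        return np.array([f(x) for f in self.forward_models], dtype=float)


@dataclass
class Dataset:
    """Reference observable values the forward models are restrained to."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("reference observables must be finite")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class ReplicaState:
    """Replica configurations and per-replica, per-datum error parameters."""

    X: np.ndarray  # (n_replicas, dim)
    sigma: np.ndarray  # (n_replicas, n_data)
    kt: float
    sigma_bounds: tuple = (0.01, 10.0)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        lo, hi = self.sigma_bounds
        if not lo < hi:
            raise ValueError("sigma bounds must satisfy lo < hi")
        if self.sigma.size and (
            np.any(self.sigma < lo) or np.any(self.sigma > hi)
        ):
            raise ValueError("sigma values must lie within bounds")
        if self.kt <= 0:
            raise ValueError("kT must be positive")

    @property
    def n_replicas(self) -> int:
        return self.X.shape[0]


def _replica_average(system: ToySystem, X: np.ndarray) -> np.ndarray:
    obs = np.array([system.observables(x) for x in X])
    return obs.mean(axis=0)


def metainference_energy(
    state: ReplicaState, data: Dataset | None, system: ToySystem
) -> float:
    """Total metainference energy (kJ/mol) of the replica ensemble."""
    if np.any(state.sigma <= 0):
        raise ValueError("sigma must be positive")
    E = float(sum(system.energy(x) for x in state.X))
    if data is None or data.n == 0:
        return E
    fbar = _replica_average(system, state.X)
    resid2 = (fbar - data.values) ** 2  # (n_data,)
    sig = state.sigma
    per_replica = (
        resid2[None, :] / (2.0 * sig**2)
        + 0.5 * np.log(2.0 * np.pi * sig)
        + 0.5 * np.log(sig)
    )
    return E + state.kt * float(per_replica.sum())


def _sigma_energy(resid2: np.ndarray, sigma: np.ndarray, kt: float) -> np.ndarray:
    """Energy terms involving sigma only (same shape as sigma)."""
    return kt * (
        resid2 / (2.0 * sigma**2) + 0.5 * np.log(2.0 * np.pi * sigma) + 0.5 * np.log(sigma)
    )


def sample_sigma(
    state: ReplicaState,
    data: Dataset,
    system: ToySystem,
    rng: np.random.Generator,
    proposal_width: float = 0.1,
) -> int:
    """One Metropolis sweep over every ``sigma_{r,i}`` (log-scale proposals).

    Detailed balance with respect to the Boltzmann density of the
    metainference energy in sigma: the acceptance ratio includes the
    ``sigma'/sigma`` Jacobian of the log-scale move.  Returns the number
    of accepted updates.
    """
    if data is None or data.n == 0:
        return 0
    fbar = _replica_average(system, state.X)
    resid2 = np.broadcast_to((fbar - data.values) ** 2, state.sigma.shape)
    lo, hi = state.sigma_bounds
    accepted = 0
    for r in range(state.sigma.shape[0]):
        for i in range(state.sigma.shape[1]):
            old = state.sigma[r, i]
            new = old * np.exp(proposal_width * rng.standard_normal())
            if not lo <= new <= hi:
                continue
            dE = float(
                _sigma_energy(resid2[r, i], np.array(new), state.kt)
                - _sigma_energy(resid2[r, i], np.array(old), state.kt)
            )
            log_acc = -dE / state.kt + np.log(new / old)
            if log_acc >= 0 or rng.random() < np.exp(log_acc):
                state.sigma[r, i] = new
                accepted += 1
    return accepted


@dataclass
class PBMetaDBias:
    """Per-CV bias grids for parallel-bias well-tempered metadynamics.

    Each CV ``j`` owns a one-dimensional grid over its interval
    ``[lo_j, hi_j]``; evaluation clamps the CV into the interval, which
    makes the bias constant outside it.  The combined (acting) bias is
    ``B(s) = -kT ln sum_j exp(-V_j(s_j)/kT)``.
    """

    intervals: list  # [(lo, hi)] per CV
    sigmas: np.ndarray  # Gaussian widths per CV
    h0: float  # initial Gaussian height, kJ/mol
    gamma: float  # well-tempered bias factor
    kt: float
    n_points: int = 512
    grids: list = field(default_factory=list)
    values: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sigmas = np.atleast_1d(np.asarray(self.sigmas, dtype=float))
        if len(self.sigmas) != len(self.intervals):
            raise ValueError("one Gaussian width per CV required")
        if self.gamma <= 1:
            raise ValueError("well-tempered bias factor must exceed 1")
        if not self.grids:
            self.grids = [
                np.linspace(lo, hi, self.n_points) for lo, hi in self.intervals
            ]
            self.values = [np.zeros(self.n_points) for _ in self.intervals]

    @property
    def n_cvs(self) -> int:
        return len(self.intervals)

    def cv_bias(self, j: int, s: float) -> float:
        lo, hi = self.intervals[j]
        return float(np.interp(np.clip(s, lo, hi), self.grids[j], self.values[j]))

    def potential(self, cv_values) -> float:
        """Acting parallel-bias potential at the given CV values (kJ/mol)."""
        v = np.array([self.cv_bias(j, s) for j, s in enumerate(cv_values)])
        m = (-v / self.kt).max()
        return float(-self.kt * (m + np.log(np.exp(-v / self.kt - m).sum())))

    def deposit(self, cv_values) -> np.ndarray:
        """Add one Gaussian per CV with well-tempered + parallel-bias heights.

        CV values outside a grid are deposited at the nearest interval
        edge.  Returns the per-CV heights actually deposited.
        """
        cv_values = np.asarray(cv_values, dtype=float)
        v_here = np.array(
            [self.cv_bias(j, s) for j, s in enumerate(cv_values)]
        )
        log_w = -v_here / self.kt
        log_w -= log_w.max()
        w = np.exp(log_w)
        w /= w.sum()
        heights = self.h0 * np.exp(-v_here / ((self.gamma - 1.0) * self.kt)) * w
        for j, (s, h) in enumerate(zip(cv_values, heights)):
            lo, hi = self.intervals[j]
            centre = float(np.clip(s, lo, hi))
            self.values[j] += h * np.exp(
                -((self.grids[j] - centre) ** 2) / (2.0 * self.sigmas[j] ** 2)
            )
        return heights

    def free_energy_estimate(self, j: int = 0) -> np.ndarray:
        """Instantaneous free-energy estimate ``-V_j / (1 - 1/gamma)``,
        min-shifted to zero, over CV ``j``'s grid."""
        F = -self.values[j] / (1.0 - 1.0 / self.gamma)
        return F - F.min()


@dataclass
class SamplerConfig:
    steps: int
    seed: int
    n_replicas: int = 1
    kt: float = 2.48
    step_size: float = 0.25
    stride: int = 50  # Gaussian deposition stride (0 = no bias)
    sigma_stride: int = 25  # sigma Metropolis sweep stride (0 = never)
    record_stride: int = 10
    sigma_bounds: tuple = (0.01, 10.0)
    sigma_proposal: float = 0.1
    checkpoint_steps: tuple = ()  # steps at which bias snapshots are stored


@dataclass
class SamplerResult:
    trajectory: dict  # arrays: step, replica, x, cvs, energy
    bias: PBMetaDBias | None
    state: ReplicaState
    acceptance: float
    checkpoints: dict  # step -> list of per-CV bias-value snapshots

    def cv_series(self, j: int = 0) -> np.ndarray:
        return self.trajectory["cvs"][:, j]


def run_sampler(
    system: ToySystem,
    data: Dataset | None,
    config: SamplerConfig,
    bias: PBMetaDBias | None = None,
) -> SamplerResult:
    """Metropolis sampling of the metainference energy plus PB bias.

    All replicas share (feel and deposit into) one set of bias grids.
    Deterministic under a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n, dim = config.n_replicas, system.dim
    lo, hi = system.bounds
    X = rng.uniform(lo, hi, size=(n, dim))
    n_data = data.n if data is not None else 0
    sigma = np.full((n, n_data), np.sqrt(np.prod(config.sigma_bounds)))
    state = ReplicaState(X, sigma, config.kt, config.sigma_bounds)

    eff = np.array([system.energy(x) for x in state.X])
    cvs = np.array([system.cv_values(x) for x in state.X])
    vbias = np.array(
        [bias.potential(c) for c in cvs] if bias is not None else np.zeros(n)
    )

    def data_term(Xmat: np.ndarray) -> float:
        if n_data == 0:
            return 0.0
        fbar = _replica_average(system, Xmat)
        resid2 = (fbar - data.values) ** 2
        return config.kt * float((resid2[None, :] / (2.0 * state.sigma**2)).sum())

    dterm = data_term(state.X)
    rec_steps, rec_rep, rec_x, rec_cv, rec_e = [], [], [], [], []
    checkpoints: dict[int, list[np.ndarray]] = {}
    accepted = moves = 0
    checkpoint_set = set(config.checkpoint_steps)

    for step in range(1, config.steps + 1):
        for r in range(n):
            prop = state.X[r] + config.step_size * rng.standard_normal(dim)
            e_new = float(system.energy(prop))
            if not np.isfinite(e_new):
                raise FloatingPointError("divergent energy during sampling")
            X_new = state.X.copy()
            X_new[r] = prop
            d_new = data_term(X_new)
            cv_new = system.cv_values(prop)
            vb_new = bias.potential(cv_new) if bias is not None else 0.0
            delta = (e_new - eff[r]) + (d_new - dterm) + (vb_new - vbias[r])
            moves += 1
            if delta <= 0 or rng.random() < np.exp(-delta / config.kt):
                state.X[r] = prop
                eff[r] = e_new
                cvs[r] = cv_new
                vbias[r] = vb_new
                dterm = d_new
                accepted += 1
        if n_data and config.sigma_stride and step % config.sigma_stride == 0:
            sample_sigma(state, data, system, rng, config.sigma_proposal)
            dterm = data_term(state.X)
        if bias is not None and config.stride and step % config.stride == 0:
            for r in range(n):
                bias.deposit(cvs[r])
            vbias = np.array([bias.potential(c) for c in cvs])
        if step % config.record_stride == 0:
            for r in range(n):
                rec_steps.append(step)
                rec_rep.append(r)
                rec_x.append(state.X[r].copy())
                rec_cv.append(cvs[r].copy())
                rec_e.append(eff[r])
        if step in checkpoint_set and bias is not None:
            checkpoints[step] = [v.copy() for v in bias.values]

    trajectory = {
        "step": np.array(rec_steps),
        "replica": np.array(rec_rep),
        "x": np.array(rec_x),
        "cvs": np.array(rec_cv),
        "energy": np.array(rec_e),
    }
    return SamplerResult(
        trajectory, bias, state, accepted / max(moves, 1), checkpoints
    )


def final_weights(bias: PBMetaDBias | None, cv_trajectory, kt: float) -> np.ndarray:
    """Per-frame weights ``w ∝ exp(+B(X)/kT)`` from the final bias."""
    cv_trajectory = np.atleast_2d(np.asarray(cv_trajectory, dtype=float))
    if bias is None:
        return np.full(len(cv_trajectory), 1.0 / len(cv_trajectory))
    b = np.array([bias.potential(c) for c in cv_trajectory])
    z = (b - b.max()) / kt
    w = np.exp(z)
    return w / w.sum()


def convergence_check(estimates, align: str = "mean") -> float:
    """Maximum drift (kJ/mol) of free-energy estimates from their average.

    ``estimates`` is a sequence of free-energy arrays on a common grid
    (e.g. instantaneous estimates over the second half of a run).  Each
    estimate is aligned (free energies are defined up to a constant) by
    its mean — or its minimum with ``align="min"`` — before computing
    the maximum absolute deviation from the point-wise average.
    """
    arrs = [np.asarray(f, dtype=float) for f in estimates]
    if len(arrs) < 2:
        raise ValueError("need at least two estimates to measure drift")
    if align == "mean":
        arrs = [a - a.mean() for a in arrs]
    elif align == "min":
        arrs = [a - a.min() for a in arrs]
    else:
        raise ValueError("align must be 'mean' or 'min'")
    avg = np.mean(arrs, axis=0)
    return float(max(np.abs(a - avg).max() for a in arrs))
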