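"""Two-state analysis of chemically induced CD transitions at 222 nm.

Supports urea denaturation (thermodynamic m-value, kcal/mol/M, with
``dG = m * midpoint``) and TFE-induced helix formation (dimensionless
exponent coefficient per % TFE, no free energy reported).  Linear
baselines on both sides of the transition; single and global shared-m
fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

R_KCAL = 1.987204259e-3  # kcal / mol / K

#: Default temperatures: urea scans run at 10 C (in 1 M TMAO), TFE at 25 C.
DEFAULT_TEMPERATURE = {"urea": 283.15, "tfe": 298.15}


@dataclass
class DenaturationData:
    """A single CD-monitored titration curve."""

    x: np.ndarray  # denaturant concentration (M) or TFE (% v/v)
    y: np.ndarray  # CD signal at 222 nm (arbitrary units)
    mode: str  # "urea" or "tfe"
    temperature: float | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.mode not in ("urea", "tfe"):
            raise ValueError("mode must be 'urea' or 'tfe'")
        if self.temperature is None:
            self.temperature = DEFAULT_TEMPERATURE[self.mode]
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same shape")
        if len(self.x) < 8:
            raise ValueError("need at least 8 titration points")
        if np.any(self.x < 0) or np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be nonnegative and strictly increasing")

    @property
    def rt(self) -> float:
        """Effective RT: kcal/mol for urea, 1 (dimensionless) for TFE."""
        return R_KCAL * self.temperature if self.mode == "urea" else 1.0


@dataclass
class TwoStateParams:
    """Midpoint, cooperativity and linear baselines of a two-state transition."""

    midpoint: float
    m: float
    a_n: float  # pre-transition (native / coil) baseline intercept
    b_n: float
    a_d: float  # post-transition (denatured / helical) baseline intercept
    b_d: float
    se: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.midpoint, self.m, self.a_n, self.b_n, self.a_d, self.b_d]
        )


@dataclass
class StabilityResult:
    """Free energy of denaturation from the linear-extrapolation model."""

    delta_g: float  # kcal/mol
    se: float


def transition_population(midpoint: float, m: float, x: np.ndarray, rt: float):
    """Population of the post-transition state at each ``x``.

    ``f = exp(m (x - midpoint) / RT) / (1 + exp(...))``; exactly 0.5 at
    the midpoint.
    """
    z = m * (np.asarray(x, dtype=float) - midpoint) / rt
    return 1.0 / (1.0 + np.exp(-z))


def two_state_curve(params: TwoStateParams, x, mode: str, temperature=None):
    """Predicted CD signal of a two-state transition with linear baselines.

    For urea the post-transition state is the denatured one; for TFE it
    is the helical (TFE-induced) state.  The functional form is the same.
    """
    data_rt = _rt_for(mode, temperature)
    x = np.asarray(x, dtype=float)
    f = transition_population(params.midpoint, params.m, x, data_rt)
    native = params.a_n + params.b_n * x
    other = params.a_d + params.b_d * x
    return native * (1.0 - f) + other * f


def _rt_for(mode: str, temperature) -> float:
    if mode not in ("urea", "tfe"):
        raise ValueError("mode must be 'urea' or 'tfe'")
    if mode == "tfe":
        return 1.0
    t = DEFAULT_TEMPERATURE["urea"] if temperature is None else temperature
    return R_KCAL * t


def _initial_guess(data: DenaturationData) -> np.ndarray:
    x, y = data.x, data.y
    a_n, a_d = y[0], y[-1]
    mid = x[np.argmin(np.abs(y - (a_n + a_d) / 2.0))]
    if mid <= x[0] or mid >= x[-1]:
        mid = 0.5 * (x[0] + x[-1])
    span = x[-1] - x[0]
    m0 = 4.0 * data.rt / max(span / 4.0, 1e-9)
    return np.array([mid, m0, a_n, 0.0, a_d, 0.0])


def _check_flags(params: TwoStateParams, data: DenaturationData) -> list[str]:
    flags = []
    lo, hi = data.x[0], data.x[-1]
    span = max(hi - lo, 1e-12)
    if not (lo - span) <= params.midpoint <= (hi + span):
        flags.append("midpoint_outside_scan")
    # a baseline supported by < 3 points is poorly determined
    f = transition_population(params.midpoint, params.m, data.x, data.rt)
    if np.sum(f < 0.2) < 3:
        flags.append("short_pre_transition_baseline")
    if np.sum(f > 0.8) < 3:
        flags.append("short_post_transition_baseline")
    # a transition amplitude buried in the signal range is no transition
    amplitude = abs(
        (params.a_d + params.b_d * params.midpoint)
        - (params.a_n + params.b_n * params.midpoint)
    )
    y_range = max(data.y.max() - data.y.min(), 1e-12)
    if amplitude < 0.1 * y_range:
        flags.append("no_transition_detected")
    return flags


def fit_single(data: DenaturationData) -> tuple[TwoStateParams, StabilityResult | None]:
    """Least-squares fit of the six two-state parameters to one curve.

    Returns the parameters and, in urea mode, the derived stability
    ``dG = m * midpoint`` with errors propagated in quadrature.
    """
    rt = data.rt

    def residuals(p: np.ndarray) -> np.ndarray:
        f = transition_population(p[0], p[1], data.x, rt)
        y = (p[2] + p[3] * data.x) * (1.0 - f) + (p[4] + p[5] * data.x) * f
        return y - data.y

    res = least_squares(residuals, _initial_guess(data), method="lm", xtol=1e-14)
    if not res.success:
        raise RuntimeError(f"two-state fit did not converge: {res.message}")
    se = _standard_errors(res, n_obs=len(data.x))
    params = TwoStateParams(
        *res.x,
        se={
            k: v
            for k, v in zip(["midpoint", "m", "a_n", "b_n", "a_d", "b_d"], se)
        },
    )
    params.flags = _check_flags(params, data)
    stability = None
    if data.mode == "urea":
        stability = delta_g(
            params.midpoint,
            params.m,
            params.se.get("midpoint", 0.0),
            params.se.get("m", 0.0),
        )
    return params, stability


def fit_global_shared_m(
    datasets: list[DenaturationData],
) -> tuple[float, float, list[TwoStateParams]]:
    """Joint fit of several curves sharing a single m-value.

    Each dataset keeps its own midpoint and baselines.  Returns
    ``(m, m_standard_error, per_dataset_params)``.
    """
    if len(datasets) < 1:
        raise ValueError("need at least one dataset")
    modes = {d.mode for d in datasets}
    if len(modes) != 1:
        raise ValueError("cannot mix urea and TFE datasets in a shared-m fit")
    guesses = [_initial_guess(d) for d in datasets]
    m0 = float(np.mean([g[1] for g in guesses]))
    # parameter vector: [m, (midpoint, a_n, b_n, a_d, b_d) per dataset]
    p0 = np.concatenate([[m0]] + [np.delete(g, 1) for g in guesses])

    def residuals(p: np.ndarray) -> np.ndarray:
        m = p[0]
        out = []
        for i, d in enumerate(datasets):
            mid, a_n, b_n, a_d, b_d = p[1 + 5 * i : 6 + 5 * i]
            f = transition_population(mid, m, d.x, d.rt)
            y = (a_n + b_n * d.x) * (1.0 - f) + (a_d + b_d * d.x) * f
            out.append(y - d.y)
        return np.concatenate(out)

    res = least_squares(residuals, p0, method="lm", xtol=1e-14)
    if not res.success:
        raise RuntimeError(f"global two-state fit did not converge: {res.message}")
    n_obs = sum(len(d.x) for d in datasets)
    se = _standard_errors(res, n_obs=n_obs)
    m, m_se = float(res.x[0]), float(se[0])
    all_params = []
    for i, d in enumerate(datasets):
        block = res.x[1 + 5 * i : 6 + 5 * i]
        block_se = se[1 + 5 * i : 6 + 5 * i]
        params = TwoStateParams(
            block[0],
            m,
            *block[1:],
            se={
                "midpoint": block_se[0],
                "m": m_se,
                "a_n": block_se[1],
                "b_n": block_se[2],
                "a_d": block_se[3],
                "b_d": block_se[4],
            },
        )
        params.flags = _check_flags(params, d)
        all_params.append(params)
    return m, m_se, all_params


def _standard_errors(res, n_obs: int) -> np.ndarray:
    dof = max(n_obs - len(res.x), 1)
    chi2 = 2.0 * res.cost
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * chi2 / dof
        return np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        return np.full(len(res.x), np.nan)


def delta_g(
    midpoint: float, m: float, se_midpoint: float = 0.0, se_m: float = 0.0
) -> StabilityResult:
    """Linear-extrapolation stability ``dG = m * midpoint`` (kcal/mol).

    The standard error combines the two contributions in quadrature.
    """
    dg = m * midpoint
    se = float(np.hypot(midpoint * se_m, m * se_midpoint))
    return StabilityResult(delta_g=float(dg), se=se)
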