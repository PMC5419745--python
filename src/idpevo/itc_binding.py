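"""Single-site (1:1) isothermal titration calorimetry: forward model and fits.

The forward model is the standard single-site binding isotherm for a
perfusion-cell instrument: titrant and cell concentrations are updated
per injection with the displaced-volume convention

    M_t(v) = M_0 * (1 - v/2V0) / (1 + v/2V0)
    X_t(v) = X_0 * (v/V0) / (1 + v/2V0)

with ``v`` the cumulative injected volume and ``V0`` the cell volume.
Heats are tracked in calories internally; the I/O layer uses ucal and uM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

R_CAL = 1.987204259e-3  # kcal / mol / K


@dataclass
class TitrationSchedule:
    """Instrument schedule: volumes in litres, concentrations in mol/L."""

    cell_volume: float
    cell_concentration: float
    syringe_concentration: float
    injection_volumes: np.ndarray
    temperature: float = 298.15

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if (
            self.cell_volume <= 0
            or self.cell_concentration <= 0
            or self.syringe_concentration <= 0
            or self.temperature <= 0
        ):
            raise ValueError("volumes, concentrations and temperature must be > 0")
        if np.any(self.injection_volumes <= 0):
            raise ValueError("injection volumes must be positive")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)

    @classmethod
    def itc200_default(
        cls,
        n_injections: int = 20,
        injection_volume_uL: float = 2.0,
        cell_volume_uL: float = 200.0,
        cell_uM: float = 20.0,
        syringe_uM: float = 200.0,
        temperature_C: float = 25.0,
    ) -> "TitrationSchedule":
        """Typical iTC200-style design used for simulations."""
        return cls(
            cell_volume=cell_volume_uL * 1e-6,
            cell_concentration=cell_uM * 1e-6,
            syringe_concentration=syringe_uM * 1e-6,
            injection_volumes=np.full(n_injections, injection_volume_uL * 1e-6),
            temperature=temperature_C + 273.15,
        )


@dataclass
class ITCData:
    """Observed per-injection heats (cal) plus the schedule that produced them."""

    heats: np.ndarray
    schedule: TitrationSchedule

    def __post_init__(self) -> None:
        self.heats = np.asarray(self.heats, dtype=float)
        if len(self.heats) != self.schedule.n_injections:
            raise ValueError("need exactly one heat per injection")


@dataclass
class BindingFit:
    """Fitted 1:1 binding parameters.

    ``kd`` in mol/L, ``dh`` in cal/mol, ``offset`` in cal/injection.
    ``c_value = n * cell_concentration / kd`` gauges how well the
    titration determines the parameters; fits with ``c`` outside
    [0.1, 1e4] are flagged low-confidence.
    """

    n: float
    kd: float
    dh: float
    offset: float
    se: dict = field(default_factory=dict)
    chi2: float = np.nan
    c_value: float = np.nan
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("Kd must be positive")

    @property
    def kd_uM(self) -> float:
        return self.kd * 1e6

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "Kd_uM": self.kd_uM,
            "dH_kcal_mol": self.dh / 1000.0,
            "offset_ucal": self.offset * 1e6,
            "se": {k: v for k, v in self.se.items()},
            "chi2": self.chi2,
            "c_value": self.c_value,
            "flags": list(self.flags),
        }


def _concentrations(schedule: TitrationSchedule) -> tuple[np.ndarray, np.ndarray]:
    """Total cell-macromolecule and titrant concentrations after each injection."""
    v = np.cumsum(schedule.injection_volumes)
    v0 = schedule.cell_volume
    dil = 1.0 + v / (2.0 * v0)
    M = schedule.cell_concentration * (1.0 - v / (2.0 * v0)) / dil
    X = schedule.syringe_concentration * (v / v0) / dil
    return M, X


def bound_fraction(n: float, kd: float, M: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Fraction of binding sites occupied, from the single-site quadratic.

    Solves ``Theta^2 - Theta (1 + X/nM + Kd/nM) + X/nM = 0`` taking the
    physical (smaller) root.
    """
    if kd <= 0:
        raise ValueError("Kd must be positive")
    xr = X / (n * M)
    kr = kd / (n * M)
    b = 1.0 + xr + kr
    disc = np.maximum(b * b - 4.0 * xr, 0.0)
    return (b - np.sqrt(disc)) / 2.0


def predict_heats(
    n: float,
    kd: float,
    dh: float,
    offset: float,
    schedule: TitrationSchedule,
) -> np.ndarray:
    """Per-injection heats (cal) for a 1:1 binding isotherm.

    The cumulative bound heat is ``Q_i = n Theta_i M_i dH V0``; the
    observed heat of injection ``i`` corrects for the displaced volume:
    ``dQ_i = Q_i - Q_{i-1} + (dV_i/V0) (Q_i + Q_{i-1})/2 + offset``.
    """
    M, X = _concentrations(schedule)
    theta = bound_fraction(n, kd, M, X)
    Q = n * theta * M * dh * schedule.cell_volume
    Qprev = np.concatenate([[0.0], Q[:-1]])
    dV = schedule.injection_volumes
    return Q - Qprev + (dV / schedule.cell_volume) * (Q + Qprev) / 2.0 + offset


def fit_binding(
    data: ITCData,
    fix_n: float | None = None,
    c_bounds: tuple[float, float] = (0.1, 1e4),
) -> BindingFit:
    """Nonlinear least-squares fit of ``(n, Kd, dH, offset)``.

    Kd is fitted on a log scale for positivity; three log-spaced Kd
    starting values are tried and the best-chi2 solution kept.  Standard
    errors come from the Jacobian at the optimum (delta method for Kd).
    Weak-binding fits (c-value outside ``c_bounds``) are flagged rather
    than rejected, mirroring how low-affinity titrations leave the
    stoichiometry poorly determined.
    """
    if data.schedule.n_injections < 6:
        raise ValueError("need at least 6 injections to fit a binding isotherm")
    heats = data.heats
    schedule = data.schedule
    M0 = schedule.cell_concentration

    dh0 = heats[0] - heats[-1]
    if dh0 == 0:
        dh0 = 1.0
    scale = max(np.max(np.abs(heats)), 1e-12)

    def unpack(p: np.ndarray) -> tuple[float, float, float, float]:
        if fix_n is None:
            n, log_kd, dh, off = p
        else:
            n = fix_n
            log_kd, dh, off = p
        return n, float(np.exp(log_kd)), dh, off

    def residuals(p: np.ndarray) -> np.ndarray:
        n, kd, dh, off = unpack(p)
        return (predict_heats(n, kd, dh, off, schedule) - heats) / scale

    best = None
    for kd0 in M0 * np.array([0.05, 1.0, 20.0]):
        p0 = [np.log(kd0), dh0 / (M0 * schedule.cell_volume), heats[-1]]
        lower = [np.log(M0 * 1e-6), -np.inf, -np.inf]
        upper = [np.log(M0 * 1e6), np.inf, np.inf]
        if fix_n is None:
            p0 = [1.0] + p0
            lower = [0.05] + lower
            upper = [20.0] + upper
        try:
            res = least_squares(
                residuals, p0, bounds=(lower, upper), method="trf", xtol=1e-14
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("ITC fit failed to converge from all starting points")

    n, kd, dh, off = unpack(best.x)
    resid = best.fun * scale
    chi2 = float(np.sum(resid**2))
    dof = max(len(heats) - len(best.x), 1)
    se: dict[str, float] = {}
    try:
        J = best.jac * scale
        cov = np.linalg.inv(J.T @ J) * chi2 / dof
        errs = np.sqrt(np.maximum(np.diag(cov), 0.0))
        if fix_n is None:
            se = {"n": errs[0], "kd": errs[1] * kd, "dh": errs[2], "offset": errs[3]}
        else:
            se = {"kd": errs[0] * kd, "dh": errs[1], "offset": errs[2]}
    except np.linalg.LinAlgError:
        se = {}

    c_value = n * M0 / kd
    flags = []
    if not c_bounds[0] <= c_value <= c_bounds[1]:
        flags.append("low_confidence_c_value")
    if se.get("kd", 0.0) > 0.5 * kd:
        flags.append("low_confidence_kd")
    return BindingFit(n, kd, dh, off, se=se, chi2=chi2, c_value=c_value, flags=flags)


def summarize_kd(values) -> tuple[float, float]:
    """Arithmetic mean and standard error of the mean of Kd values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("SEM requires at least two values")
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(arr.size))


def relative_affinity(kd: float, reference_kd: float) -> float:
    """Kd expressed relative to a reference interaction (ratio >= 0)."""
    if kd <= 0 or reference_kd <= 0:
        raise ValueError("dissociation constants must be positive")
    return kd / reference_kd
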