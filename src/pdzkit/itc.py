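"""One-set-of-identical-sites ITC model, fitting and thermodynamic decomposition.

Units: volumes in µL, concentrations in mol/L, heats in µcal, molar energies
in kcal/mol, temperatures in K.  ΔG uses the 1 M reference state,
ΔG = R·T·ln(K_d).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import FitConvergenceError, ValidationError

__all__ = [
    "R_KCAL",
    "InjectionSchedule",
    "Isotherm",
    "OneSiteParams",
    "ThermoTable",
    "FitDiagnostics",
    "ConditionComparison",
    "model_heats",
    "dilution_correct",
    "fit_one_site",
    "free_energy",
    "entropy_term",
    "compare_conditions",
]

#: Gas constant, kcal·mol⁻¹·K⁻¹.
R_KCAL = 1.9872e-3


@dataclass(frozen=True)
class InjectionSchedule:
    """Titration design: cell/syringe concentrations and injection volumes."""

    injection_volumes: tuple[float, ...]  # µL per injection
    syringe_conc: float  # ligand molarity in the syringe
    cell_conc_initial: float  # macromolecule molarity in the cell
    cell_volume: float = 200.0  # µL (nominal active volume, configurable)
    temperature: float = 298.15  # K

    def __post_init__(self):
        object.__setattr__(
            self, "injection_volumes", tuple(float(v) for v in self.injection_volumes)
        )
        if not self.injection_volumes:
            raise ValidationError("at least one injection is required")
        if any(v <= 0 for v in self.injection_volumes):
            raise ValidationError("injection volumes must be > 0")
        for name in ("syringe_conc", "cell_conc_initial", "cell_volume", "temperature"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")

    @classmethod
    def uniform(
        cls,
        n_injections: int,
        injection_volume: float = 2.0,
        syringe_conc: float = 900e-6,
        cell_conc_initial: float = 70e-6,
        **kw,
    ) -> "InjectionSchedule":
        return cls((injection_volume,) * n_injections, syringe_conc, cell_conc_initial, **kw)

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)


@dataclass
class Isotherm:
    """Observed per-injection heats, optionally with a blank dilution run."""

    heats: np.ndarray  # µcal
    schedule: InjectionSchedule
    blank_heats: np.ndarray | None = None

    def __post_init__(self):
        self.heats = np.asarray(self.heats, dtype=float)
        if len(self.heats) != self.schedule.n_injections:
            raise ValidationError(
                f"{len(self.heats)} heats for {self.schedule.n_injections} injections"
            )
        if self.blank_heats is not None:
            self.blank_heats = np.asarray(self.blank_heats, dtype=float)
            if len(self.blank_heats) != len(self.heats):
                raise ValidationError("blank length does not match heats")


@dataclass(frozen=True)
class OneSiteParams:
    n: float  # sites per macromolecule
    Kd: float  # molarity
    dH: float  # kcal/mol

    def __post_init__(self):
        if not self.n > 0:
            raise ValidationError("n must be > 0")
        if not self.Kd > 0:
            raise ValidationError("Kd must be > 0")


def _cell_concentrations(schedule: InjectionSchedule):
    """Macromolecule/ligand cell concentrations after each injection.

    Perfusion-cell accounting with the mean-concentration convention for the
    displaced liquid; with cumulative injected volume v and cell volume V0:

        [M]_i = [M]_0 (1 - v/2V0) / (1 + v/2V0)
        [X]_i = [X]_syr (v/V0) / (1 + v/2V0)
    """
    v = np.cumsum(schedule.injection_volumes)
    V0 = schedule.cell_volume
    M = schedule.cell_conc_initial * (1 - v / (2 * V0)) / (1 + v / (2 * V0))
    X = schedule.syringe_conc * (v / V0) / (1 + v / (2 * V0))
    if np.any(M < 0) or np.any(X < 0):
        raise ValidationError(
            "volume accounting drove a concentration negative "
            "(total injected volume exceeds 2x cell volume)"
        )
    return M, X


def _bound_concentration(n: float, Kd: float, M: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Complex concentration from the exact single-site quadratic."""
    b = X + n * M + Kd
    disc = b * b - 4 * n * M * X
    return 0.5 * (b - np.sqrt(np.maximum(disc, 0.0)))


def model_heats(params: OneSiteParams, schedule: InjectionSchedule) -> np.ndarray:
    """Per-injection heats (µcal) for a single set of identical sites.

    The cumulative cell heat content is Q_i = [MX]_i · V0 · ΔH; the observed
    injection heat adds back the mean heat carried out by the displaced
    volume: q_i = Q_i - Q_{i-1} + (dV_i/V0)(Q_i + Q_{i-1})/2.
    """
    M, X = _cell_concentrations(schedule)
    B = _bound_concentration(params.n, params.Kd, M, X)
    # mol/L * µL * kcal/mol -> µcal requires a factor 1e-6 L/µL * 1e9 µcal/kcal
    Q = B * schedule.cell_volume * params.dH * 1.0e3
    Qprev = np.concatenate([[0.0], Q[:-1]])
    dV = np.asarray(schedule.injection_volumes)
    return Q - Qprev + (dV / schedule.cell_volume) * (Q + Qprev) / 2.0


def dilution_correct(isotherm: Isotherm, constant_offset: float | None = None) -> np.ndarray:
    """Subtract the blank (dilution) heats, or a constant offset, element-wise."""
    if isotherm.blank_heats is not None:
        return isotherm.heats - isotherm.blank_heats
    if constant_offset is not None:
        return isotherm.heats - constant_offset
    raise ValidationError("no blank heats and no constant offset supplied")


@dataclass
class FitDiagnostics:
    converged: bool
    cost: float
    residual_norm: float
    message: str
    n_restarts: int = 0
    wiseman_c: float | None = None


def _initial_guess(heats: np.ndarray, schedule: InjectionSchedule) -> OneSiteParams:
    dV = np.asarray(schedule.injection_volumes)
    moles = schedule.syringe_conc * dV * 1e-6  # mol per injection
    dH0 = float(heats[0] / (moles[0] * 1e9))  # kcal/mol from first injection
    if not np.isfinite(dH0) or dH0 == 0:
        dH0 = -5.0
    # n: molar ratio at the half-heat point of the cumulative curve
    M, X = _cell_concentrations(schedule)
    ratio = X / M
    cum = np.cumsum(np.abs(heats))
    half_idx = int(np.searchsorted(cum, cum[-1] / 2.0))
    n0 = float(np.clip(ratio[min(half_idx, len(ratio) - 1)], 0.1, 10.0))
    Kd0 = schedule.cell_conc_initial / 10.0
    return OneSiteParams(n=n0, Kd=Kd0, dH=dH0)


def fit_one_site(
    isotherm: Isotherm,
    initial_guess: OneSiteParams | None = None,
    max_restarts: int = 3,
) -> tuple[OneSiteParams, FitDiagnostics]:
    """Least-squares fit of (n, K_d, ΔH) to dilution-corrected heats.

    K_d is fitted on a log scale to keep it positive.  On non-convergence the
    fit is restarted from up to ``max_restarts`` perturbed guesses before
    raising :class:`FitConvergenceError` with the last iterate attached.
    """
    if isotherm.schedule.n_injections < 6:
        raise ValidationError("at least 6 injections are required for a fit")
    heats = (
        dilution_correct(isotherm)
        if isotherm.blank_heats is not None
        else isotherm.heats
    )
    guess = initial_guess or _initial_guess(heats, isotherm.schedule)

    def residuals(x):
        n, log_kd, dH = x
        return model_heats(
            OneSiteParams(n=n, Kd=float(np.exp(log_kd)), dH=dH), isotherm.schedule
        ) - heats

    rng = np.random.default_rng(0)
    x0 = np.array([guess.n, np.log(guess.Kd), guess.dH])
    last = None
    for attempt in range(1 + max_restarts):
        start = x0 if attempt == 0 else x0 * rng.uniform(0.7, 1.4, size=3)
        result = least_squares(
            residuals,
            start,
            bounds=([1e-3, np.log(1e-15), -np.inf], [1e3, np.log(1.0), np.inf]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        last = result
        if result.success:
            n, log_kd, dH = result.x
            params = OneSiteParams(n=float(n), Kd=float(np.exp(log_kd)), dH=float(dH))
            c = params.n * isotherm.schedule.cell_conc_initial / params.Kd
            if not 1.0 <= c <= 1000.0:
                warnings.warn(
                    f"Wiseman c = {c:.3g} outside the well-conditioned range 1-1000",
                    stacklevel=2,
                )
            diag = FitDiagnostics(
                converged=True,
                cost=float(result.cost),
                residual_norm=float(np.linalg.norm(result.fun)),
                message=result.message,
                n_restarts=attempt,
                wiseman_c=float(c),
            )
            return params, diag
    raise FitConvergenceError(
        f"one-site fit failed to converge: {last.message}", last_iterate=last.x
    )


def free_energy(Kd: float, T: float = 298.15) -> float:
    """Standard-state binding free energy ΔG = R·T·ln(K_d), kcal/mol."""
    if not Kd > 0:
        raise ValidationError("Kd must be > 0")
    return R_KCAL * T * float(np.log(Kd))


def entropy_term(dG: float, dH: float) -> float:
    """Entropic term −TΔS = ΔG − ΔH, kcal/mol."""
    return dG - dH


@dataclass(frozen=True)
class ThermoTable:
    """One row of a binding-thermodynamics table (energies in kcal/mol)."""

    Kd_uM: float
    dH: float
    minus_TdS: float
    dG: float
    T: float = 298.15
    label: str = ""

    def __post_init__(self):
        if abs(self.dG - (self.dH + self.minus_TdS)) > 0.05:
            raise ValidationError(
                f"{self.label or 'row'}: ΔG != ΔH + (−TΔS) beyond rounding"
            )
        if abs(self.dG - free_energy(self.Kd_uM * 1e-6, self.T)) > 0.1:
            raise ValidationError(
                f"{self.label or 'row'}: ΔG inconsistent with R·T·ln(Kd)"
            )

    @classmethod
    def from_fit(cls, params: OneSiteParams, T: float = 298.15, label: str = "") -> "ThermoTable":
        dG = free_energy(params.Kd, T)
        return cls(
            Kd_uM=params.Kd * 1e6,
            dH=params.dH,
            minus_TdS=entropy_term(dG, params.dH),
            dG=dG,
            T=T,
            label=label,
        )


@dataclass(frozen=True)
class ConditionComparison:
    ddH: float  # ΔΔH = ΔH_b − ΔH_a (b is the comparison condition)
    minus_TddS: float  # (−TΔS)_b − (−TΔS)_a
    kd_fold: float  # Kd_a / Kd_b (>1 means b binds tighter)


def compare_conditions(a: ThermoTable, b: ThermoTable) -> ConditionComparison:
    """Differences b − a of the enthalpic/entropic terms plus the Kd fold-change."""
    if abs(a.T - b.T) > 1e-9:
        raise ValidationError("cannot compare conditions at different temperatures")
    return ConditionComparison(
        ddH=b.dH - a.dH,
        minus_TddS=b.minus_TdS - a.minus_TdS,
        kd_fold=a.Kd_uM / b.Kd_uM,
    )
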