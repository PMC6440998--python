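"""Thermodynamic and kinetic post-processing of fitted models.

Converts a fitted kinetic model into the derived quantities of interest:
stationary state populations, the active/inactive population ratio
(state 1 over state 2 in the canonical descending-efficiency order), and
an approximate free-energy profile in kBT using the Arrhenius relation
``dG_barrier = ln(A / k)`` with a pre-exponential factor A (default
1e5 s^-1, a conservative choice for large-scale conformational motion).
Also houses the small closed-form fits used around the single-molecule
work: the binomial statistics of labeled protomers per hexamer, Hill
fits of ATPase saturation curves, and simple binding isotherms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import binom

from .kinetics import KineticModel, stationary_distribution

__all__ = [
    "stationary_distribution",
    "active_inactive_ratio",
    "FreeEnergyProfile",
    "free_energy_profile",
    "LabelingMix",
    "labeling_distribution",
    "HillFit",
    "fit_hill",
    "BindingFit",
    "fit_binding_isotherm",
]


def active_inactive_ratio(model: KineticModel,
                          pi_std: np.ndarray | None = None) -> tuple[float, float]:
    """Occupancy ratio of state 1 (active) to state 2 (inactive).

    For a sequential chain this equals k21 / k12 exactly.  Returns
    (ratio, standard error); the error is propagated from per-state
    occupancy uncertainties when supplied, else NaN.
    """
    if model.K < 2:
        raise ValueError("need at least two states")
    pi = model.pi
    ratio = float(pi[0] / pi[1])
    if pi_std is None:
        return ratio, float("nan")
    err = ratio * np.hypot(pi_std[0] / pi[0], pi_std[1] / pi[1])
    return ratio, float(err)


@dataclass
class FreeEnergyProfile:
    """State free energies and transition barriers, in kBT.

    ``state_energy[i] - state_energy[j] = ln(pi[j] / pi[i])`` and
    ``barrier[(i, j)] = ln(A / k_ij)`` (1-based transition keys).
    Negative barriers (rate exceeding the pre-exponential factor) are
    listed in ``flagged``.
    """

    state_energy: np.ndarray
    barriers: dict
    pre_exponential: float
    reference_state: int
    flagged: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "state_energy_kBT": self.state_energy.tolist(),
            "barriers_kBT": {f"{i}->{j}": v for (i, j), v in self.barriers.items()},
            "pre_exponential_s-1": self.pre_exponential,
            "reference_state": self.reference_state,
            "flagged_transitions": [f"{i}->{j}" for i, j in self.flagged],
        }


def free_energy_profile(model: KineticModel, A: float = 1e5,
                        reference_state: int = 1) -> FreeEnergyProfile:
    """Arrhenius free-energy profile of a kinetic model.

    Barrier heights are ``ln(A / k_ij)`` for every allowed transition with
    k_ij > 0; state free energies follow from log occupancy ratios
    relative to ``reference_state`` (1-based).  All energies are in kBT.
    """
    if A <= 0:
        raise ValueError("pre-exponential factor must be positive")
    pi = model.pi
    ref = reference_state - 1
    energies = np.log(pi[ref] / pi)
    barriers = {}
    flagged = []
    for i in range(model.K):
        for j in range(model.K):
            if i != j and model.connectivity[i, j] and model.Q[i, j] > 0:
                dg = float(np.log(A / model.Q[i, j]))
                barriers[(i + 1, j + 1)] = dg
                if dg < 0:
                    flagged.append((i + 1, j + 1))
    return FreeEnergyProfile(state_energy=energies, barriers=barriers,
                             pre_exponential=A, reference_state=reference_state,
                             flagged=flagged)


def rates_from_profile(profile: FreeEnergyProfile) -> dict:
    """Invert the profile back to rates: k_ij = A * exp(-dG_barrier)."""
    return {key: profile.pre_exponential * np.exp(-dg)
            for key, dg in profile.barriers.items()}


@dataclass
class LabelingMix:
    """Binomial distribution of labeled protomers per n-mer complex."""

    n: int
    p: float
    P: np.ndarray

    @property
    def p_single(self) -> float:
        """Probability of exactly one labeled protomer."""
        return float(self.P[1])

    @property
    def p_multi(self) -> float:
        """Probability of two or more labeled protomers."""
        return float(self.P[2:].sum())


def labeling_distribution(n: int = 6, labeled_conc: float = 1.0,
                          unlabeled_conc: float = 100.0) -> LabelingMix:
    """P(k labeled protomers) for complexes assembled from a subunit mix.

    ``p = labeled / (labeled + unlabeled)`` and P(k) = C(n, k) p^k (1-p)^(n-k).
    At the standard 1:100 labeled:unlabeled mixing ratio of a hexamer,
    P(1) = 5.7% (two significant figures) and P(2) = 0.14%.
    """
    if labeled_conc < 0 or unlabeled_conc < 0:
        raise ValueError("concentrations must be non-negative")
    if labeled_conc + unlabeled_conc == 0:
        raise ValueError("at least one concentration must be positive")
    p = labeled_conc / (labeled_conc + unlabeled_conc)
    P = binom.pmf(np.arange(n + 1), n, p)
    return LabelingMix(n=n, p=float(p), P=P)


def _hill_model(s, vmax, k_half, n):
    s = np.asarray(s, dtype=float)
    return vmax * s ** n / (s ** n + k_half ** n)


def _hill_jac(s, vmax, k_half, n):
    s = np.asarray(s, dtype=float)
    sn = s ** n
    kn = k_half ** n
    den = sn + kn
    d_vmax = sn / den
    d_khalf = -vmax * sn * n * kn / k_half / den ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(s > 0, np.log(s), 0.0)
    d_n = vmax * (sn * logs * den - sn * (sn * logs + kn * np.log(k_half))) / den ** 2
    return np.column_stack([d_vmax, d_khalf, d_n])


@dataclass
class HillFit:
    vmax: float
    k_half: float
    n_hill: float
    covariance: np.ndarray
    residuals: np.ndarray
    converged: bool = True

    @property
    def errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def predict(self, s):
        return _hill_model(s, self.vmax, self.k_half, self.n_hill)


def fit_hill(S, v, fix_n: float | None = None) -> HillFit:
    """Constrained least-squares Hill fit v = Vmax S^n / (S^n + K_half^n).

    Start values come from the data (Vmax from the top quantile, K_half
    from the half-maximum crossing); ``fix_n=1`` reduces the model to the
    rectangular hyperbola.  All parameters are constrained positive.
    """
    S = np.asarray(S, dtype=float)
    v = np.asarray(v, dtype=float)
    n_free = 2 if fix_n is not None else 3
    if len(S) < n_free + 1:
        raise ValueError("need more points than free parameters")
    vmax0 = float(np.quantile(v, 0.95))
    k0 = float(np.interp(vmax0 / 2, np.sort(v), S[np.argsort(v)]))
    k0 = k0 if k0 > 0 else float(np.median(S))
    try:
        if fix_n is None:
            popt, pcov = curve_fit(_hill_model, S, v, p0=[vmax0, k0, 2.0],
                                   jac=_hill_jac, bounds=(1e-12, np.inf), maxfev=20000)
            vmax, k_half, n = popt
        else:
            def fixed(s, vmax, k_half):
                return _hill_model(s, vmax, k_half, fix_n)

            popt, pcov2 = curve_fit(fixed, S, v, p0=[vmax0, k0],
                                    bounds=(1e-12, np.inf), maxfev=20000)
            vmax, k_half, n = popt[0], popt[1], fix_n
            pcov = np.zeros((3, 3))
            pcov[:2, :2] = pcov2
        converged = True
    except RuntimeError:
        vmax, k_half, n = vmax0, k0, 2.0
        pcov = np.full((3, 3), np.nan)
        converged = False
    res = v - _hill_model(S, vmax, k_half, n)
    return HillFit(vmax=float(vmax), k_half=float(k_half), n_hill=float(n),
                   covariance=pcov, residuals=res, converged=converged)


def _isotherm_model(c, r0, amplitude, kd):
    c = np.asarray(c, dtype=float)
    return r0 + amplitude * c / (c + kd)


def _isotherm_jac(c, r0, amplitude, kd):
    c = np.asarray(c, dtype=float)
    den = c + kd
    return np.column_stack([np.ones_like(c), c / den, -amplitude * c / den ** 2])


@dataclass
class BindingFit:
    r0: float
    amplitude: float
    kd: float
    covariance: np.ndarray
    residuals: np.ndarray
    converged: bool = True

    @property
    def errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def predict(self, c):
        return _isotherm_model(c, self.r0, self.amplitude, self.kd)


def fit_binding_isotherm(conc, ratio) -> BindingFit:
    """Fit ratio(c) = r0 + amplitude * c / (c + Kd) (single-site binding).

    Used for titrations such as the DnaK dependence of the active/inactive
    population ratio, where the half-saturation concentration is the
    apparent dissociation constant.
    """
    conc = np.asarray(conc, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    if len(conc) < 4:
        raise ValueError("need at least 4 points")
    r00 = float(np.min(ratio))
    amp0 = float(np.max(ratio) - r00)
    kd0 = float(np.median(conc[conc > 0])) if np.any(conc > 0) else 1.0
    try:
        popt, pcov = curve_fit(_isotherm_model, conc, ratio, p0=[r00, max(amp0, 1e-6), kd0],
                               jac=_isotherm_jac,
                               bounds=([-np.inf, 1e-12, 1e-12], np.inf), maxfev=20000)
        converged = True
    except RuntimeError:
        popt = [r00, amp0, kd0]
        pcov = np.full((3, 3), np.nan)
        converged = False
    res = ratio - _isotherm_model(conc, *popt)
    return BindingFit(r0=float(popt[0]), amplitude=float(popt[1]), kd=float(popt[2]),
                      covariance=pcov, residuals=res, converged=converged)
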