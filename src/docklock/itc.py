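"""Single-site isothermal titration calorimetry: forward model and fitting.

The forward model reproduces the standard perfusion-cell protocol: each
injection of volume dV displaces mixed cell content (every total
concentration is scaled by V₀/(V₀+dV), and the injected ligand enters as
L_syr·dV/(V₀+dV)), the bound concentration follows the 1:1 ligand-depletion
quadratic on n·P binding sites, and the differential heat of injection i is

    ΔQᵢ = Qᵢ − Qᵢ₋₁ + (dVᵢ/V₀)·(Qᵢ + Qᵢ₋₁)/2,   Q = n·ΔH·[bound]·V₀

(the trapezoidal term compensates heat carried out with the displaced
volume). The cell working volume is fixed at 200 µL, the instrument-class
constant for a MicroCal ITC200. The Wiseman parameter c = n·P_cell/K_D
governs identifiability: fits outside c ∈ [1, 1000] carry a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .thermo import bound_fraction_two_state, delta_g_from_kd, entropy_term, T_STANDARD

__all__ = [
    "CELL_VOLUME_UL",
    "ItcExperiment",
    "ItcFitResult",
    "simulate_itc",
    "fit_itc",
    "wiseman_c",
]

CELL_VOLUME_UL = 200.0


@dataclass
class ItcExperiment:
    """One calorimetric titration: schedule, concentrations and heats (µJ)."""

    cell_concentration: float  # µM protein (per-monomer)
    syringe_concentration: float  # µM peptide
    injection_volumes: np.ndarray  # µL
    heats: np.ndarray | None = None  # µJ per injection
    cell_volume: float = CELL_VOLUME_UL
    temperature: float = T_STANDARD
    replicate_id: int = 0

    def __post_init__(self):
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if self.cell_concentration <= 0 or self.syringe_concentration <= 0:
            raise ValueError("concentrations must be positive")
        if len(self.injection_volumes) < 1:
            raise ValueError("at least one injection required")
        if self.heats is not None:
            self.heats = np.asarray(self.heats, dtype=float)
            if len(self.heats) != len(self.injection_volumes):
                raise ValueError("heats and injection schedule differ in length")

    @classmethod
    def standard(cls, cell_um=30.0, syringe_um=400.0, n_injections=25, volume_ul=1.5, **kw):
        """The 25 x 1.5 µL protocol used throughout this package."""
        return cls(cell_um, syringe_um, np.full(n_injections, volume_ul), **kw)


def wiseman_c(n: float, cell_um: float, kd_um: float) -> float:
    """Wiseman c-value n·[cell]/K_D (sigmoid steepness of the isotherm)."""
    return n * cell_um / kd_um


def _injection_heats(exp: ItcExperiment, kd: float, dh: float, n: float) -> np.ndarray:
    """Noise-free differential heats (µJ) for the perfusion displacement model."""
    v0 = exp.cell_volume
    p, l = exp.cell_concentration, 0.0
    q_prev = 0.0
    out = np.empty(len(exp.injection_volumes))
    for i, dv in enumerate(exp.injection_volumes):
        f = v0 / (v0 + dv)
        p *= f
        l = l * f + exp.syringe_concentration * dv / (v0 + dv)
        sites = n * p
        bound = bound_fraction_two_state(sites, l, kd) * sites  # µM of bound ligand
        # Q in µJ: [µM]*1e-6 mol/L * V0*1e-6 L * dH kJ/mol *1e9 µJ/kJ
        q = dh * bound * v0 * 1e-3
        out[i] = q - q_prev + (dv / v0) * (q + q_prev) / 2.0
        q_prev = q
    return out


def simulate_itc(
    exp: ItcExperiment,
    kd: float,
    dh: float,
    n: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Simulated per-injection heats (µJ) with seeded Gaussian noise.

    ``kd`` in µM, ``dh`` in kJ/mol, ``n`` the per-monomer stoichiometry.
    """
    if not kd > 0:
        raise ValueError("kd must be positive")
    heats = _injection_heats(exp, kd, dh, n)
    if noise_sd > 0:
        heats = heats + np.random.default_rng(seed).normal(0, noise_sd, len(heats))
    return heats


@dataclass
class ItcFitResult:
    kd: float
    kd_err: float
    dh: float
    dh_err: float
    n: float
    n_err: float
    dg: float
    neg_tds: float
    q_dilution: float
    c_value: float
    warnings: list = field(default_factory=list)
    replicates: list = field(default_factory=list)


def _fit_single(
    exp: ItcExperiment, fit_baseline: bool, discard_first: bool
) -> ItcFitResult:
    heats = exp.heats
    idx = np.arange(len(heats))
    use = idx >= (1 if discard_first else 0)
    if use.sum() < 10:
        raise ValueError("need >= 10 informative injections")

    total_q = float(heats[use].sum())
    dh0 = total_q / (
        exp.syringe_concentration * exp.injection_volumes.sum() * 1e-3
    )  # rough molar heat, kJ/mol
    if abs(total_q) < 1e-9 or abs(dh0) < 1e-9:
        warnings.warn("all-zero heats: dH ~ 0 and K_D unidentifiable")
        return ItcFitResult(
            kd=float("nan"), kd_err=float("nan"), dh=0.0, dh_err=0.0,
            n=float("nan"), n_err=float("nan"), dg=float("nan"),
            neg_tds=float("nan"), q_dilution=0.0, c_value=float("nan"),
            warnings=["unidentifiable: no heat signal"],
        )
    dh0 = np.clip(dh0, -200.0, 200.0)
    if dh0 == 0:
        dh0 = -10.0

    def residual(x):
        kd, dh, n = 10 ** x[0], x[1], x[2]
        offset = x[3] if fit_baseline else 0.0
        model = _injection_heats(exp, kd, dh, n) + offset
        return (model - heats)[use]

    x0 = [math.log10(exp.cell_concentration / 10.0), dh0, 1.0]
    if fit_baseline:
        x0.append(0.0)
    sol = least_squares(residual, x0, method="lm", max_nfev=2000)
    kd, dh, n = 10 ** sol.x[0], sol.x[1], sol.x[2]
    offset = sol.x[3] if fit_baseline else 0.0

    J = sol.jac
    dof = max(len(sol.fun) - len(sol.x), 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = np.linalg.inv(J.T @ J) * s2
        kd_err = kd * math.log(10) * math.sqrt(max(cov[0, 0], 0))
        dh_err = math.sqrt(max(cov[1, 1], 0))
        n_err = math.sqrt(max(cov[2, 2], 0))
    except np.linalg.LinAlgError:
        kd_err = dh_err = n_err = float("nan")

    c = wiseman_c(n, exp.cell_concentration, kd)
    warns = []
    if not 1.0 <= c <= 1000.0:
        warns.append(
            f"Wiseman c = {c:.3g} outside [1, 1000]: K_D poorly determined"
        )
        warnings.warn(warns[-1])
    dg = delta_g_from_kd(kd, exp.temperature)
    return ItcFitResult(
        kd=kd, kd_err=kd_err, dh=dh, dh_err=dh_err, n=n, n_err=n_err,
        dg=dg, neg_tds=entropy_term(dg, dh), q_dilution=offset,
        c_value=c, warnings=warns,
    )


def fit_itc(
    experiments: "ItcExperiment | list[ItcExperiment]",
    fit_baseline: bool = True,
    discard_first: bool = True,
) -> ItcFitResult:
    """Least-squares single-site fit of (K_D, ΔH, N) plus derived ΔG and −TΔS.

    A list of experiments is treated as technical replicates: each is
    fitted independently and the mean ± SD across replicates is reported.
    ΔG and −TΔS are derived through the thermodynamic identities rather
    than fitted.
    """
    if isinstance(experiments, ItcExperiment):
        return _fit_single(experiments, fit_baseline, discard_first)
    fits = [_fit_single(e, fit_baseline, discard_first) for e in experiments]
    kds = np.array([f.kd for f in fits])
    dhs = np.array([f.dh for f in fits])
    ns = np.array([f.n for f in fits])
    kd, dh, n = float(kds.mean()), float(dhs.mean()), float(ns.mean())
    dg = delta_g_from_kd(kd, experiments[0].temperature)
    return ItcFitResult(
        kd=kd, kd_err=float(kds.std(ddof=1)) if len(fits) > 1 else fits[0].kd_err,
        dh=dh, dh_err=float(dhs.std(ddof=1)) if len(fits) > 1 else fits[0].dh_err,
        n=n, n_err=float(ns.std(ddof=1)) if len(fits) > 1 else fits[0].n_err,
        dg=dg, neg_tds=entropy_term(dg, dh),
        q_dilution=float(np.mean([f.q_dilution for f in fits])),
        c_value=wiseman_c(n, experiments[0].cell_concentration, kd),
        warnings=sum((f.warnings for f in fits), []),
        replicates=fits,
    )
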