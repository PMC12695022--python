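"""Two-step 'dock-and-lock' binding model and its inversion.

The model: a ligand first *docks* into a partially formed pocket
(dissociation constant K_D^D, off-rate k_off^D), after which the receptor
folds around it (*lock* step) with a dimensionless lock dissociation
constant K_D^L defined here as [dock]/[lock] at equilibrium. When the
dock⇌lock exchange is fast on the chemical-shift timescale, the two bound
states average and binding looks two-state with effective constants

    K'_D    = K_D^D · K_D^L / (K_D^L + 1)
    k'_off  = k_off^D · K_D^L / (K_D^L + 1)

i.e. both are scaled by the fraction of bound protein in the dock state.
Measuring the dock step alone on a truncated construct (no lock step) and
the effective constants on the full-length construct lets one invert these
relations for K_D^L and the hidden intermediate-state population, and check
the on-rate inequality k'_on ≤ k_on^D.

Uncertainty propagation is seeded Monte Carlo with Gaussian draws truncated
to the physical domain — the r/(1−r) inversion is strongly non-linear when
the effective and dock constants approach each other, where a first-order
Taylor expansion would misbehave.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .thermo import ThermoRecord, kon_from_kd_koff

__all__ = [
    "DockLockDissection",
    "EnergyLedger",
    "LedgerEntry",
    "effective_from_dock_lock",
    "infer_lock_constant",
    "dock_state_population",
    "lock_exchange_lower_bound",
    "check_kon_inequality",
    "build_energy_ledger",
    "propagate_errors",
    "dissect_pair",
]


@dataclass
class DockLockDissection:
    """Dock-step, lock-step and effective parameters for one construct pair.

    Rates s⁻¹, on-rates µM⁻¹ s⁻¹, concentrations µM; ``kl`` is the
    dimensionless lock dissociation constant [dock]/[lock]. ``errors`` maps
    field name to the 1σ uncertainty where one is available.
    """

    label: str
    kd_dock: float
    koff_dock: float | None
    kon_dock: float | None
    kd_eff: float
    koff_eff: float | None
    kon_eff: float | None
    kl: float
    kl_small_limit: float
    kl_rate_route: float | None
    dock_fraction: float
    kex_lock_lower_bound: float | None = None
    errors: dict = field(default_factory=dict)
    kon_verdict: str | None = None

    def __post_init__(self):
        if self.kl < 0:
            raise ValueError("kl must be >= 0")
        if not 0 <= self.dock_fraction < 1 + 1e-12:
            raise ValueError("dock_fraction must lie in [0, 1)")
        if self.kd_eff > self.kd_dock * (1 + 1e-12):
            raise ValueError("effective K_D cannot exceed the dock K_D")


@dataclass
class LedgerEntry:
    label: str
    pair: tuple[str, str]
    ddg: float
    ddg_err: float | None
    provenance: str


@dataclass
class EnergyLedger:
    """Ordered ΔΔG decomposition built from pairs of ThermoRecord ΔG values."""

    entries: list[LedgerEntry]

    def as_dict(self) -> dict[str, float]:
        return {e.label: e.ddg for e in self.entries}


def effective_from_dock_lock(
    kd_dock: float, koff_dock: float, kl: float
) -> tuple[float, float]:
    """Effective (K'_D, k'_off) of the two-step scheme under fast lock exchange.

    Both constants scale by kl/(kl+1), the dock fraction of the bound pool;
    kl → ∞ recovers the pure dock step.
    """
    if not kd_dock > 0:
        raise ValueError("kd_dock must be positive")
    if koff_dock < 0 or kl < 0:
        raise ValueError("koff_dock and kl must be >= 0")
    if math.isinf(kl):
        return kd_dock, koff_dock
    scale = kl / (kl + 1.0)
    return kd_dock * scale, koff_dock * scale


def infer_lock_constant(
    kd_eff: float,
    kd_dock: float,
    mode: Literal["exact", "small_kl_limit"] = "exact",
) -> float:
    """Lock dissociation constant K_D^L from effective and dock K_D values.

    ``exact`` inverts K'_D = K_D^D·K_L/(K_L+1): K_L = r/(1−r) with
    r = K'_D/K_D^D. ``small_kl_limit`` returns r itself, the approximation
    valid when most bound protein is locked (K_L ≪ 1).
    """
    if not 0 < kd_eff <= kd_dock:
        if kd_eff > kd_dock:
            raise ValueError(
                "kd_eff > kd_dock: inconsistent construct pair (the lock step "
                "can only deepen binding)"
            )
        raise ValueError("kd values must be positive")
    r = kd_eff / kd_dock
    if mode == "small_kl_limit":
        return r
    if mode == "exact":
        if r >= 1.0:
            raise ValueError("kd_eff == kd_dock: no measurable lock contribution")
        return r / (1.0 - r)
    raise ValueError(f"unknown mode {mode!r}")


def dock_state_population(kd_eff: float, kd_dock: float) -> float:
    """Equilibrium fraction of *bound* protein in the dock state.

    Equals K'_D/K_D^D = K_D^L/(1+K_D^L).
    """
    if not 0 < kd_eff <= kd_dock:
        raise ValueError("require 0 < kd_eff <= kd_dock")
    return kd_eff / kd_dock


def lock_exchange_lower_bound(max_shift_difference_hz: float) -> float:
    """Fast-exchange threshold on the lock step, k_ex^L ≫ Δν.

    The absence of exchange broadening in a saturated complex requires the
    dock⇌lock exchange rate to greatly exceed the largest free/bound shift
    difference; the returned number is that 'must greatly exceed' threshold
    in s⁻¹ (numerically equal to the Hz input).
    """
    if max_shift_difference_hz < 0:
        raise ValueError("shift difference must be non-negative")
    return float(max_shift_difference_hz)


def check_kon_inequality(
    dissection: "DockLockDissection | None" = None,
    *,
    kon_eff: float | None = None,
    kon_eff_err: float | None = None,
    kon_dock: float | None = None,
    kon_dock_err: float | None = None,
    tolerance_sigma: float = 1.0,
    allow_zero_uncertainty: bool = False,
) -> str:
    """Verdict on the two-step on-rate inequality k'_on ≤ k_on^D.

    Returns ``"consistent"``, ``"boundary"`` or ``"violated"``, comparing
    the difference to ``tolerance_sigma`` propagated standard deviations.
    A violation (effective on-rate apparently above the dock on-rate) is
    the signature of an unreliable slow-exchange lineshape rate rather
    than of the model itself.
    """
    if dissection is not None:
        kon_eff = dissection.kon_eff
        kon_dock = dissection.kon_dock
        kon_eff_err = dissection.errors.get("kon_eff")
        kon_dock_err = dissection.errors.get("kon_dock")
    if kon_eff is None or kon_dock is None:
        raise ValueError("both on-rates are required")
    if (kon_eff_err is None or kon_dock_err is None) and not allow_zero_uncertainty:
        raise ValueError(
            "on-rate uncertainties are required; pass allow_zero_uncertainty=True "
            "to compare point values"
        )
    s = math.hypot(kon_eff_err or 0.0, kon_dock_err or 0.0)
    diff = kon_eff - kon_dock
    if diff <= 0:
        return "consistent"
    if diff <= tolerance_sigma * s:
        return "boundary"
    return "violated"


def build_energy_ledger(
    records: Sequence[ThermoRecord],
    comparisons: Sequence[tuple[str, str, str]],
) -> EnergyLedger:
    """ΔΔG ledger from labelled (a, b) record pairs: ΔΔG = ΔG(a) − ΔG(b).

    ``comparisons`` entries are (label, complex_a, complex_b); each cited
    complex must exist and carry a ΔG.
    """
    by_label = {r.complex_label: r for r in records}
    entries = []
    for label, a, b in comparisons:
        for name in (a, b):
            if name not in by_label:
                raise KeyError(f"record {name!r} not found")
            if by_label[name].dg is None:
                raise ValueError(f"record {name!r} has no ΔG")
        ra, rb = by_label[a], by_label[b]
        err = None
        if ra.dg_err is not None and rb.dg_err is not None:
            err = math.hypot(ra.dg_err, rb.dg_err)
        entries.append(
            LedgerEntry(
                label=label,
                pair=(a, b),
                ddg=ra.dg - rb.dg,
                ddg_err=err,
                provenance=f"dG({a}) - dG({b})",
            )
        )
    return EnergyLedger(entries)


def propagate_errors(
    func: Callable[..., float],
    inputs: Sequence[tuple[float, float]],
    n_draws: int = 10000,
    seed: int = 0,
    lower_bounds: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Monte-Carlo propagation of independent Gaussian input uncertainties.

    ``inputs`` is a sequence of (value, sigma). Draws are truncated to the
    physical domain via ``lower_bounds`` (default 0 for every input —
    concentrations and rates are non-negative) by rejection resampling.
    Returns (median, half-width of the central 68% interval); deterministic
    for a given seed. With all sigmas zero the exact value with zero
    spread is returned.
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000")
    values = np.array([v for v, _ in inputs], dtype=float)
    sigmas = np.array([s for _, s in inputs], dtype=float)
    if np.any(sigmas < 0):
        raise ValueError("sigmas must be >= 0")
    if lower_bounds is None:
        lower_bounds = np.zeros_like(values)
    else:
        lower_bounds = np.asarray(lower_bounds, dtype=float)
    if np.all(sigmas == 0):
        return float(func(*values)), 0.0
    rng = np.random.default_rng(seed)
    draws = np.empty((n_draws, len(values)))
    for j, (v, s, lo) in enumerate(zip(values, sigmas, lower_bounds)):
        if s == 0:
            draws[:, j] = v
            continue
        col = rng.normal(v, s, size=n_draws)
        bad = col <= lo
        while np.any(bad):  # rejection resampling keeps the draws Gaussian above lo
            col[bad] = rng.normal(v, s, size=int(bad.sum()))
            bad = col <= lo
        draws[:, j] = col
    out = np.array([func(*row) for row in draws])
    lo_q, med, hi_q = np.percentile(out, [15.865, 50.0, 84.135])
    return float(med), float((hi_q - lo_q) / 2.0)


def dissect_pair(
    full: ThermoRecord,
    truncated: ThermoRecord,
    max_shift_difference_hz: float | None = None,
    n_draws: int = 20000,
    seed: int = 0,
) -> DockLockDissection:
    """Full two-step dissection from a paired full-length/truncated measurement.

    ``truncated`` supplies the dock-step parameters (its construct cannot
    lock), ``full`` the effective two-state parameters. Computes K_D^L by
    the exact inversion plus the small-K_L limit and, where off-rates are
    available, the independent rate-route estimate k'_off/k_off^D; derives
    on-rates as k_off/K_D with Monte-Carlo uncertainties.
    """
    kd_dock, kd_eff = truncated.kd, full.kd
    kl_exact = infer_lock_constant(kd_eff, kd_dock, "exact")
    kl_small = infer_lock_constant(kd_eff, kd_dock, "small_kl_limit")
    kl_rate = None
    if full.koff is not None and truncated.koff is not None and truncated.koff > 0:
        kl_rate = full.koff / truncated.koff

    errors: dict[str, float] = {}
    kon_dock = kon_eff = None
    if truncated.koff is not None:
        kon_dock, err = propagate_errors(
            kon_from_kd_koff,
            [(kd_dock, truncated.kd_err or 0.0), (truncated.koff, truncated.koff_err or 0.0)],
            n_draws=n_draws,
            seed=seed,
        )
        errors["kon_dock"] = err
    if full.koff is not None:
        kon_eff, err = propagate_errors(
            kon_from_kd_koff,
            [(kd_eff, full.kd_err or 0.0), (full.koff, full.koff_err or 0.0)],
            n_draws=n_draws,
            seed=seed + 1,
        )
        errors["kon_eff"] = err

    _, kl_err = propagate_errors(
        lambda a, b: infer_lock_constant(min(a, b * (1 - 1e-12)), b, "exact"),
        [(kd_eff, full.kd_err or 0.0), (kd_dock, truncated.kd_err or 0.0)],
        n_draws=n_draws,
        seed=seed + 2,
    )
    errors["kl"] = kl_err

    diss = DockLockDissection(
        label=f"{full.complex_label} vs {truncated.complex_label}",
        kd_dock=kd_dock,
        koff_dock=truncated.koff,
        kon_dock=kon_dock,
        kd_eff=kd_eff,
        koff_eff=full.koff,
        kon_eff=kon_eff,
        kl=kl_exact,
        kl_small_limit=kl_small,
        kl_rate_route=kl_rate,
        dock_fraction=dock_state_population(kd_eff, kd_dock),
        kex_lock_lower_bound=(
            lock_exchange_lower_bound(max_shift_difference_hz)
            if max_shift_difference_hz is not None
            else None
        ),
        errors=errors,
    )
    if kon_eff is not None and kon_dock is not None:
        diss.kon_verdict = check_kon_inequality(diss)
    return diss
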