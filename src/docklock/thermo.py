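"""Closed-form binding equilibria and thermodynamic conversions.

Conventions used throughout the package:

* concentrations are in µM at every interface (converted to molar
  internally where a molar quantity such as ΔG is needed);
* energies are in kJ/mol; rates in s⁻¹; on-rates in µM⁻¹ s⁻¹;
* the standard state temperature is 298.15 K (25 °C), matching the
  calorimetry and NMR conditions these models describe.

The two equilibrium solvers are the 1:1 ligand-depletion quadratic and the
sequential two-site dimer scheme D + L ⇌ DL ⇌ DL₂ with statistical factors
K₁ = K_micro/2 and K₂ = 2·α·K_micro (α > 1 ⇒ negative cooperativity).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "R_GAS_KJ",
    "T_STANDARD",
    "ThermoRecord",
    "MixtureComposition",
    "bound_fraction_two_state",
    "dimer_site_fractions",
    "delta_g_from_kd",
    "kd_from_delta_g",
    "entropy_term",
    "kon_from_kd_koff",
    "read_thermo_table",
    "write_thermo_table",
]

#: gas constant in kJ mol^-1 K^-1
R_GAS_KJ = 8.314e-3
#: 25 C; both 298 K and 298.15 K reproduce printed DG values within rounding
T_STANDARD = 298.15

_UM_TO_M = 1e-6


@dataclass
class ThermoRecord:
    """One complex's thermodynamic/kinetic parameter set (one results-table row).

    Concentrations in µM, energies in kJ/mol, rates in s⁻¹, on-rate in
    µM⁻¹ s⁻¹. Missing values are ``None``. ``method_tags`` records which
    experiment determined which field (e.g. ``{"kd": "ITC"}``).
    """

    complex_label: str
    kd: float
    kd_err: float | None = None
    dg: float | None = None
    dg_err: float | None = None
    dh: float | None = None
    dh_err: float | None = None
    neg_tds: float | None = None
    neg_tds_err: float | None = None
    n_sites: float | None = None
    n_err: float | None = None
    koff: float | None = None
    koff_err: float | None = None
    kon: float | None = None
    kon_err: float | None = None
    method_tags: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kd is not None and not self.kd > 0:
            raise ValueError(f"{self.complex_label}: kd must be positive")
        for name in ("koff", "kon"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{self.complex_label}: {name} must be >= 0")

    def validate_consistency(self, dg_tol: float = 0.25, kon_sigma: float = 3.0) -> None:
        """Check ΔG = ΔH + (−TΔS) and k_on = k_off/K_D where all terms are set."""
        if None not in (self.dg, self.dh, self.neg_tds):
            if abs(self.dg - (self.dh + self.neg_tds)) > dg_tol:
                raise ValueError(
                    f"{self.complex_label}: dG != dH + (-TdS) beyond {dg_tol} kJ/mol"
                )
        if None not in (self.kon, self.koff, self.kd):
            pred = self.koff / self.kd
            sigma = self.kon_err or 0.0
            if abs(self.kon - pred) > max(kon_sigma * sigma, 1e-9 * pred):
                raise ValueError(
                    f"{self.complex_label}: kon inconsistent with koff/kd "
                    f"({self.kon} vs {pred:.3g})"
                )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class MixtureComposition:
    """Equilibrium species make-up of a protein/ligand mixture.

    ``species_fractions`` is keyed by species label and holds the fraction
    of total protein (monomer-equivalent) in that species environment; the
    fractions sum to 1.
    """

    p_total: float
    l_total: float
    species_fractions: dict[str, float]
    l_free: float | None = None

    def __post_init__(self):
        vals = np.array(list(self.species_fractions.values()), dtype=float)
        if np.any(vals < -1e-12) or np.any(vals > 1 + 1e-12):
            raise ValueError("species fractions must lie in [0, 1]")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("species fractions must sum to 1")


def bound_fraction_two_state(p_total: float, l_total: float, kd: float) -> float:
    """Fraction of protein bound in a 1:1 equilibrium with ligand depletion.

    Solves the mass-balance quadratic exactly:
    f_b = ((P+L+K_D) − sqrt((P+L+K_D)² − 4PL)) / (2P).

    Parameters are total protein, total ligand and K_D, all in µM.
    ``p_total == 0`` is a degenerate input and returns 0.
    """
    if p_total < 0 or l_total < 0:
        raise ValueError("concentrations must be non-negative")
    if not kd > 0:
        raise ValueError("kd must be positive")
    if p_total == 0 or l_total == 0:
        return 0.0
    b = p_total + l_total + kd
    disc = b * b - 4.0 * p_total * l_total
    bound = (b - math.sqrt(max(disc, 0.0))) / 2.0
    return min(bound / p_total, 1.0)


def _dimer_free_ligand(d_total: float, l_total: float, k1: float, k2: float) -> float:
    """Free-ligand root of the sequential dimer mass balance (brentq)."""

    def residual(x):
        denom = 1.0 + x / k1 + x * x / (k1 * k2)
        d_free = d_total / denom
        return x + d_free * (x / k1 + 2.0 * x * x / (k1 * k2)) - l_total

    if l_total == 0:
        return 0.0
    lo, hi = 0.0, l_total
    if residual(hi) < 0:  # cannot happen with exact mass balance
        raise ValueError("no positive real root of the dimer mass balance")
    return brentq(residual, lo, hi, xtol=1e-14, rtol=1e-14)


def dimer_site_fractions(
    p_dimer_total: float, l_total: float, kd_micro: float, alpha: float = 1.0
) -> MixtureComposition:
    """Equilibrium composition of a symmetric dimer binding up to two ligands.

    Sequential scheme D + L ⇌ DL ⇌ DL₂ with macroscopic dissociation
    constants K₁ = kd_micro/2 and K₂ = 2·α·kd_micro (statistical factors;
    α = 1 ⇒ independent sites, α > 1 ⇒ negative cooperativity).

    Returns a :class:`MixtureComposition` whose ``species_fractions``
    contains both the dimer-state fractions ``DD``/``DL``/``DL2`` (fraction
    of dimers) and the four subunit environments ``F`` (free subunit of the
    free dimer), ``F'``/``B'`` (free and bound subunits of the asymmetric
    singly-bound dimer) and ``B`` (bound subunit of the saturated dimer),
    expressed as fractions of protein monomers. Only the subunit fractions
    sum to 1.
    """
    if p_dimer_total <= 0 or l_total < 0 or kd_micro <= 0 or alpha <= 0:
        raise ValueError("inputs must be positive (l_total may be zero)")
    k1 = kd_micro / 2.0
    k2 = 2.0 * alpha * kd_micro
    x = _dimer_free_ligand(p_dimer_total, l_total, k1, k2)
    denom = 1.0 + x / k1 + x * x / (k1 * k2)
    d = p_dimer_total / denom
    dl = d * x / k1
    dl2 = d * x * x / (k1 * k2)
    frac = {
        "DD": d / p_dimer_total,
        "DL": dl / p_dimer_total,
        "DL2": dl2 / p_dimer_total,
    }
    sub = {
        "F": d / p_dimer_total,
        "F'": dl / (2.0 * p_dimer_total),
        "B'": dl / (2.0 * p_dimer_total),
        "B": dl2 / p_dimer_total,
    }
    comp = MixtureComposition(
        p_total=2.0 * p_dimer_total,
        l_total=l_total,
        species_fractions=sub,
        l_free=x,
    )
    # attach the dimer-state view without breaking the sum-to-1 invariant
    comp.dimer_fractions = frac
    return comp


def delta_g_from_kd(kd: float, temperature: float = T_STANDARD) -> float:
    """Standard binding free energy ΔG = RT·ln(K_D[M]) in kJ/mol (K_D in µM)."""
    if not kd > 0:
        raise ValueError("kd must be positive")
    return R_GAS_KJ * temperature * math.log(kd * _UM_TO_M)


def kd_from_delta_g(dg: float, temperature: float = T_STANDARD) -> float:
    """Inverse of :func:`delta_g_from_kd`; returns K_D in µM."""
    return math.exp(dg / (R_GAS_KJ * temperature)) / _UM_TO_M


def entropy_term(dg: float, dh: float) -> float:
    """Entropic component −TΔS = ΔG − ΔH (kJ/mol)."""
    return dg - dh


def kon_from_kd_koff(kd: float, koff: float) -> float:
    """Association rate k_on = k_off / K_D in µM⁻¹ s⁻¹."""
    if not kd > 0:
        raise ValueError("kd must be positive")
    if koff < 0:
        raise ValueError("koff must be >= 0")
    return koff / kd


# ---------------------------------------------------------------------------
# tabular I/O

_CSV_COLUMNS = [
    "complex", "kd_um", "kd_err", "dg", "dg_err", "dh", "dh_err",
    "neg_tds", "neg_tds_err", "n", "n_err", "koff", "koff_err",
    "kon", "kon_err", "kd_method",
]


def read_thermo_table(path) -> list[ThermoRecord]:
    """Read a ThermoRecord table from CSV (see data/table1.csv for the dialect)."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        get = lambda c: None if c not in row or pd.isna(row[c]) else float(row[c])
        records.append(
            ThermoRecord(
                complex_label=str(row["complex"]),
                kd=get("kd_um"),
                kd_err=get("kd_err"),
                dg=get("dg"),
                dg_err=get("dg_err"),
                dh=get("dh"),
                dh_err=get("dh_err"),
                neg_tds=get("neg_tds"),
                neg_tds_err=get("neg_tds_err"),
                n_sites=get("n"),
                n_err=get("n_err"),
                koff=get("koff"),
                koff_err=get("koff_err"),
                kon=get("kon"),
                kon_err=get("kon_err"),
                method_tags={"kd": row.get("kd_method", "")}
                if "kd_method" in row and not pd.isna(row.get("kd_method"))
                else {},
            )
        )
    return records


def write_thermo_table(records: list[ThermoRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "complex": r.complex_label,
                "kd_um": r.kd, "kd_err": r.kd_err,
                "dg": r.dg, "dg_err": r.dg_err,
                "dh": r.dh, "dh_err": r.dh_err,
                "neg_tds": r.neg_tds, "neg_tds_err": r.neg_tds_err,
                "n": r.n_sites, "n_err": r.n_err,
                "koff": r.koff, "koff_err": r.koff_err,
                "kon": r.kon, "kon_err": r.kon_err,
                "kd_method": r.method_tags.get("kd", ""),
            }
        )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False, float_format="%.6g")
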