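"""Seeded generators for every input type the fitters consume.

A :class:`GroundTruthFixture` bundles a binding model with its constants,
a per-residue shift/relaxation panel, the experimental design and a noise
model; :func:`generate` forward-simulates it through the corresponding
module's simulator into the package's CSV dialects. Shipped presets mirror
the reference results table's parameter sets (e.g. ``EBH_11MACF``) with
the experimental designs used there: ¹H,¹⁵N titrations at 600/800 MHz,
CEST at B1 = 12.5/25/50 Hz with 400 ms irradiation and ~2.5% bound
population, and ITC with 25 × 1.5 µL injections from a 20–40 µM cell /
200–600 µM syringe at 25 °C.

Noise is independent Gaussian: 1% of the maximum signal for the NMR
observables and 2% of the largest |heat| for ITC — large enough to make
recovery non-trivial, small enough to match careful desk-scale data.
Regeneration from an identical fixture and seed is bit-identical, and
every dataset carries a manifest recording the fixture hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cest as cest_mod
from . import itc as itc_mod
from .csp import PeakTrajectory
from .lineshape import (
    TitrationSeries,
    nucleus_frequency,
    titration_networks,
    spectrum_1d,
)

__all__ = [
    "GroundTruthFixture",
    "make_residue_panel",
    "generate",
    "fixture_preset",
    "PRESETS",
]

#: |Δω| ceiling (Hz at the stated field) for the bound-state shift changes
MAX_DELTA_OMEGA_HZ = 2000.0

NMR_NOISE_FRACTION = 0.01
ITC_NOISE_FRACTION = 0.02


def make_residue_panel(
    n_residues: int, seed: int = 0, spectrometer_h_freq: float = 800.0
) -> pd.DataFrame:
    """Random but realistic amide shift/relaxation panel.

    Free shifts are drawn from the amide envelope (¹H 7.0–9.5 ppm,
    ¹⁵N 105–130 ppm); bound-state changes are capped so that |Δω| stays
    below 2000 Hz in either dimension at the stated field; R2 ∈ [10, 30]
    and R1 ∈ [1, 2] s⁻¹.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    rng = np.random.default_rng(seed)
    mhz_h = nucleus_frequency(spectrometer_h_freq, "H")
    mhz_n = nucleus_frequency(spectrometer_h_freq, "N")
    free_h = rng.uniform(7.0, 9.5, n_residues)
    free_n = rng.uniform(105.0, 130.0, n_residues)
    max_dh = MAX_DELTA_OMEGA_HZ / mhz_h
    max_dn = MAX_DELTA_OMEGA_HZ / mhz_n
    # triangular-ish spread: most residues perturb modestly, a few strongly
    dh = rng.uniform(-1.0, 1.0, n_residues) * rng.uniform(0.1, 1.0, n_residues) * max_dh
    dn = rng.uniform(-1.0, 1.0, n_residues) * rng.uniform(0.1, 1.0, n_residues) * max_dn
    return pd.DataFrame(
        {
            "residue": [f"R{i + 1}" for i in range(n_residues)],
            "free_h": free_h,
            "free_n": free_n,
            "bound_h": free_h + dh,
            "bound_n": free_n + dn,
            "r2": rng.uniform(10.0, 30.0, n_residues),
            "r1": rng.uniform(1.0, 2.0, n_residues),
        }
    )


@dataclass
class GroundTruthFixture:
    """Ground truth + experimental design for one synthetic study condition."""

    label: str
    model: str  # two_state | dimer | dock_lock
    kd: float  # µM (micro/site constant for the dimer model)
    koff: float  # s^-1
    kd_itc: float | None = None  # method-specific K_D for the ITC design
    alpha: float = 1.0
    kl: float | None = None  # dock_lock only
    kex_lock: float | None = None  # dock_lock only
    dh: float = -30.0  # kJ/mol (ITC)
    n_sites: float = 1.0
    spectrometer_h_freq: float = 800.0
    n_residues: int = 4
    # titration design (µM)
    p_total: tuple = (50.0,) * 8
    l_total: tuple = (0.0, 10.0, 25.0, 50.0, 80.0, 120.0, 180.0, 250.0)
    # CEST design
    cest_b1_hz: tuple = (12.5, 25.0, 50.0)
    cest_t_ex: float = 0.4
    cest_p_bound: float = 0.025
    cest_offsets_n: int = 60
    cest_span_ppm: float = 6.0
    # ITC design
    itc_cell_um: float = 30.0
    itc_syringe_um: float = 400.0
    itc_n_injections: int = 25
    itc_injection_ul: float = 1.5
    noise_nmr: float = NMR_NOISE_FRACTION
    noise_itc: float = ITC_NOISE_FRACTION
    seed: int = 0
    panel: pd.DataFrame | None = None

    def __post_init__(self):
        if self.kd <= 0 or self.koff < 0:
            raise ValueError("kd must be positive, koff non-negative")
        if self.model not in ("two_state", "dimer", "dock_lock"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "dock_lock" and (self.kl is None or self.kex_lock is None):
            raise ValueError("dock_lock fixtures need kl and kex_lock")
        if self.panel is None:
            self.panel = make_residue_panel(
                self.n_residues, seed=self.seed, spectrometer_h_freq=self.spectrometer_h_freq
            )

    def content_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["panel"] = self.panel.round(10).to_csv(index=False)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# -- presets keyed to the reference table's NMR-lineshape parameter sets ----
PRESETS = {
    "EBH_11MACF": dict(
        model="two_state", kd=4.91, kd_itc=3.5, koff=130.2, dh=-39.6, n_sites=1.13,
        itc_cell_um=30.0, itc_syringe_um=400.0,
    ),
    "EBHdC_11MACF": dict(
        model="two_state", kd=26.6, kd_itc=41.5, koff=1900.0, dh=-29.1, n_sites=1.08,
        itc_cell_um=40.0, itc_syringe_um=600.0,
        l_total=(0.0, 25.0, 60.0, 120.0, 220.0, 350.0, 500.0, 700.0),
    ),
    "EBH_11MACF_VLL": dict(
        model="dimer", kd=0.32, kd_itc=0.081, koff=15.63, alpha=2.0, dh=-40.2, n_sites=0.906,
        itc_cell_um=20.0, itc_syringe_um=200.0,
        l_total=(0.0, 5.0, 12.0, 25.0, 40.0, 55.0, 70.0, 100.0),
    ),
    "EBH_4MACF": dict(
        model="two_state", kd=10400.0, koff=5e5, dh=-5.0,
        l_total=(0.0, 250.0, 500.0, 1000.0, 1750.0, 2750.0, 4000.0, 5000.0),
    ),
    "EBH_6MACF": dict(
        model="two_state", kd=1730.0, koff=2e5, dh=-8.0,
        l_total=(0.0, 250.0, 500.0, 1000.0, 1750.0, 2750.0, 4000.0, 5000.0),
    ),
    "EBHdC_11MACF_VLL": dict(
        model="two_state", kd=25.62, kd_itc=18.7, koff=1541.0, dh=-24.9, n_sites=0.99,
        itc_cell_um=40.0, itc_syringe_um=600.0,
        l_total=(0.0, 25.0, 60.0, 120.0, 220.0, 350.0, 500.0, 700.0),
    ),
}


def fixture_preset(label: str, seed: int = 0, **overrides) -> GroundTruthFixture:
    """Instantiate a shipped preset by label (see ``PRESETS``)."""
    if label not in PRESETS:
        raise KeyError(f"unknown preset {label!r}; available: {sorted(PRESETS)}")
    kw = dict(PRESETS[label])
    kw.update(overrides)
    return GroundTruthFixture(label=label, seed=seed, **kw)


# ---------------------------------------------------------------------------


def _simulate_lineshape_series(fix: GroundTruthFixture, rng) -> TitrationSeries:
    panel = fix.panel
    residues = list(panel["residue"])
    free = {r.residue: (r.free_h, r.free_n) for r in panel.itertuples()}
    bound = {r.residue: (r.bound_h, r.bound_n) for r in panel.itertuples()}
    series = TitrationSeries(
        p_total=np.array(fix.p_total),
        l_total=np.array(fix.l_total),
        residues=residues,
        spectrometer_h_freq=fix.spectrometer_h_freq,
    )
    model = "dimer" if fix.model == "dimer" else "two_state"
    r2 = {row.residue: row.r2 for row in panel.itertuples()}
    for res in residues:
        one = TitrationSeries(
            p_total=series.p_total, l_total=series.l_total, residues=[res],
            spectrometer_h_freq=fix.spectrometer_h_freq,
        )
        nets = titration_networks(
            fix.kd, fix.koff, one, model,
            {res: free[res]}, {res: bound[res]},
            alpha=fix.alpha, r2_h=r2[res], r2_n=r2[res] * 0.6,
        )
        for i in range(series.n_points):
            # a common grid per residue/dim spanning the whole titration
            for dim in ("H", "N"):
                mhz = nucleus_frequency(fix.spectrometer_h_freq, dim)
                lo = min(free[res][0 if dim == "H" else 1], bound[res][0 if dim == "H" else 1])
                hi = max(free[res][0 if dim == "H" else 1], bound[res][0 if dim == "H" else 1])
                pad = 5 * r2[res] / np.pi + 0.1 * max((hi - lo) * mhz, 1.0) + 20.0
                grid = np.linspace(lo * mhz - pad, hi * mhz + pad, 140)
                sig = spectrum_1d(nets[(res, i)], dim, grid)
                noise = rng.normal(0, fix.noise_nmr * sig.max(), len(grid)) if fix.noise_nmr else 0
                series.cross_sections[(res, i, dim)] = (grid, sig + noise)
    return series


def _simulate_peaks(fix: GroundTruthFixture, rng) -> list[PeakTrajectory]:
    from .thermo import bound_fraction_two_state

    trajs = []
    fb = np.array(
        [
            bound_fraction_two_state(p, l, fix.kd)
            for p, l in zip(fix.p_total, fix.l_total)
        ]
    )
    for row in fix.panel.itertuples():
        sh = row.free_h + fb * (row.bound_h - row.free_h)
        sn = row.free_n + fb * (row.bound_n - row.free_n)
        if fix.noise_nmr:
            sh = sh + rng.normal(0, fix.noise_nmr * 0.05, len(fb))
            sn = sn + rng.normal(0, fix.noise_nmr * 0.5, len(fb))
        inten = np.full(len(fb), 1.0) + (rng.normal(0, fix.noise_nmr, len(fb)) if fix.noise_nmr else 0)
        trajs.append(
            PeakTrajectory(residue=row.residue, shift_h=sh, shift_n=sn, intensity=inten)
        )
    return trajs


def _simulate_cest(fix: GroundTruthFixture, rng) -> list[cest_mod.CestProfile]:
    mhz_n = nucleus_frequency(fix.spectrometer_h_freq, "N")
    # the offset sweep must cover every bound-state dip with margin
    dw_max = float(np.abs(fix.panel["bound_n"] - fix.panel["free_n"]).max()) * mhz_n
    base_half = fix.cest_span_ppm * mhz_n
    half = max(base_half, dw_max + 150.0)
    # widening the sweep keeps the per-Hz sampling density of the base design
    n_off = int(round(fix.cest_offsets_n * half / base_half))
    offsets = np.linspace(-half, half, n_off)
    profiles = []
    for row in fix.panel.itertuples():
        nu_free = 0.0  # carrier placed on the free resonance per residue
        dw = (row.bound_n - row.free_n) * mhz_n
        for b1 in fix.cest_b1_hz:
            prof = cest_mod.simulate_cest(
                row.residue, offsets, b1, fix.cest_t_ex,
                p_bound=fix.cest_p_bound, koff=fix.koff,
                nu_free_hz=nu_free, delta_omega_hz=dw,
                r1=row.r1, r2_free=row.r2 * 0.6, r2_bound=row.r2,
                spectrometer_h_freq=fix.spectrometer_h_freq,
            )
            if fix.noise_nmr:
                prof.intensities = np.clip(
                    prof.intensities + rng.normal(0, fix.noise_nmr, len(offsets)),
                    -0.05, 1.05,
                )
            profiles.append(prof)
    return profiles


def _simulate_itc(fix: GroundTruthFixture, rng, n_replicates: int = 3):
    exps = []
    for rep in range(n_replicates):
        exp = itc_mod.ItcExperiment.standard(
            cell_um=fix.itc_cell_um, syringe_um=fix.itc_syringe_um,
            n_injections=fix.itc_n_injections, volume_ul=fix.itc_injection_ul,
            replicate_id=rep,
        )
        clean = itc_mod.simulate_itc(exp, fix.kd_itc or fix.kd, fix.dh, fix.n_sites)
        sd = fix.noise_itc * np.abs(clean).max()
        exp.heats = clean + (rng.normal(0, sd, len(clean)) if sd else 0)
        exps.append(exp)
    return exps


def generate(fixture: GroundTruthFixture, kind: str, outdir: str | Path | None = None):
    """Forward-simulate a dataset of the requested kind from a fixture.

    ``kind`` is one of ``titration_peaks``, ``titration_lineshapes``,
    ``cest`` or ``itc``. Returns the native in-memory objects; when
    ``outdir`` is given also writes the module's CSV dialect plus a
    ``manifest.json`` recording the fixture hash, seed and ground truth.
    """
    kind_tag = int.from_bytes(hashlib.sha256(kind.encode()).digest()[:4], "big")
    rng = np.random.default_rng([fixture.seed, kind_tag % 2**31])
    if kind == "titration_lineshapes":
        data = _simulate_lineshape_series(fixture, rng)
    elif kind == "titration_peaks":
        data = _simulate_peaks(fixture, rng)
    elif kind == "cest":
        if fixture.panel is None or "r1" not in fixture.panel:
            raise ValueError("CEST generation needs a panel with R1 rates")
        data = _simulate_cest(fixture, rng)
    elif kind == "itc":
        data = _simulate_itc(fixture, rng)
    else:
        raise ValueError(f"unknown dataset kind {kind!r}")

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from . import io as io_mod

        io_mod.write_dataset(data, kind, outdir)
        manifest = {
            "fixture_label": fixture.label,
            "fixture_hash": fixture.content_hash(),
            "seed": fixture.seed,
            "kind": kind,
            "ground_truth": {
                "model": fixture.model, "kd_um": fixture.kd,
                "kd_itc_um": fixture.kd_itc, "koff": fixture.koff,
                "alpha": fixture.alpha, "kl": fixture.kl, "dh": fixture.dh,
                "n_sites": fixture.n_sites, "cest_p_bound": fixture.cest_p_bound,
            },
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return data
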