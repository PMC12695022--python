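"""CSV/JSON/YAML dialects for every dataset the package consumes or emits.

All numbers are serialized in plain ASCII at 6 significant figures and
round-trip losslessly at that precision. Dialects:

* peak lists: ``point_id,residue,shift_h_ppm,shift_n_ppm,intensity``
* 1D cross-sections: ``point_id,residue,dim,freq_hz,intensity``
* CEST: ``residue,b1_hz,offset_hz,intensity_ratio``
* ITC: ``replicate,injection_index,volume_ul,heat_uj``
* concentrations and acquisition settings travel in a sidecar YAML config.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cest import CestProfile
from .csp import PeakTrajectory
from .itc import ItcExperiment
from .lineshape import TitrationSeries

__all__ = [
    "load_reference_table",
    "read_config",
    "write_config",
    "write_dataset",
    "read_lineshape_series",
    "read_peak_trajectories",
    "read_cest_profiles",
    "read_itc_experiments",
]

FLOAT_FMT = "%.6g"


def load_reference_table() -> pd.DataFrame:
    """The packaged thermodynamic/kinetic results table (µM, kJ/mol, s⁻¹).

    Columns carry the ITC values with the NMR-determined alternatives in
    ``kd_nmr_um``/``koff_cest`` where both were measured.
    """
    with importlib.resources.files("docklock.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# dataset writers (used by synthetic.generate)


def write_dataset(data, kind: str, outdir: Path) -> None:
    outdir = Path(outdir)
    if kind == "titration_lineshapes":
        rows = []
        for (res, i, dim), (grid, inten) in data.cross_sections.items():
            for f, y in zip(grid, inten):
                rows.append((i, res, dim, f, y))
        pd.DataFrame(
            rows, columns=["point_id", "residue", "dim", "freq_hz", "intensity"]
        ).to_csv(outdir / "cross_sections.csv", index=False, float_format=FLOAT_FMT)
        write_config(
            {
                "p_total_um": [float(x) for x in data.p_total],
                "l_total_um": [float(x) for x in data.l_total],
                "spectrometer_h_freq": float(data.spectrometer_h_freq),
            },
            outdir / "config.yaml",
        )
    elif kind == "titration_peaks":
        rows = []
        for t in data:
            for i in range(len(t.shift_h)):
                rows.append(
                    (i, t.residue, t.shift_h[i], t.shift_n[i],
                     t.intensity[i] if t.intensity is not None else 1.0)
                )
        pd.DataFrame(
            rows,
            columns=["point_id", "residue", "shift_h_ppm", "shift_n_ppm", "intensity"],
        ).to_csv(outdir / "peaks.csv", index=False, float_format=FLOAT_FMT)
    elif kind == "cest":
        rows = []
        t_ex = None
        mhz = None
        for prof in data:
            t_ex, mhz = prof.t_ex, prof.spectrometer_h_freq
            for off, y in zip(prof.offsets_hz, prof.intensities):
                rows.append((prof.residue, prof.b1_hz, off, y))
        pd.DataFrame(
            rows, columns=["residue", "b1_hz", "offset_hz", "intensity_ratio"]
        ).to_csv(outdir / "cest.csv", index=False, float_format=FLOAT_FMT)
        write_config(
            {"t_ex_s": float(t_ex), "spectrometer_h_freq": float(mhz)},
            outdir / "config.yaml",
        )
    elif kind == "itc":
        rows = []
        for exp in data:
            for i, (v, q) in enumerate(zip(exp.injection_volumes, exp.heats)):
                rows.append((exp.replicate_id, i, v, q))
        pd.DataFrame(
            rows, columns=["replicate", "injection_index", "volume_ul", "heat_uj"]
        ).to_csv(outdir / "itc.csv", index=False, float_format=FLOAT_FMT)
        write_config(
            {
                "cell_um": float(data[0].cell_concentration),
                "syringe_um": float(data[0].syringe_concentration),
                "cell_volume_ul": float(data[0].cell_volume),
            },
            outdir / "config.yaml",
        )
    else:
        raise ValueError(f"unknown dataset kind {kind!r}")


# ---------------------------------------------------------------------------
# dataset readers


def read_lineshape_series(directory) -> TitrationSeries:
    directory = Path(directory)
    cfg = read_config(directory / "config.yaml")
    df = pd.read_csv(directory / "cross_sections.csv")
    series = TitrationSeries(
        p_total=np.array(cfg["p_total_um"], dtype=float),
        l_total=np.array(cfg["l_total_um"], dtype=float),
        residues=sorted(df["residue"].unique()),
        spectrometer_h_freq=float(cfg["spectrometer_h_freq"]),
    )
    for (res, i, dim), g in df.groupby(["residue", "point_id", "dim"]):
        g = g.sort_values("freq_hz")
        series.cross_sections[(res, int(i), dim)] = (
            g["freq_hz"].to_numpy(),
            g["intensity"].to_numpy(),
        )
    return series


def read_peak_trajectories(path) -> list[PeakTrajectory]:
    df = pd.read_csv(path)
    out = []
    for res, g in df.groupby("residue"):
        g = g.sort_values("point_id")
        out.append(
            PeakTrajectory(
                residue=str(res),
                shift_h=g["shift_h_ppm"].to_numpy(),
                shift_n=g["shift_n_ppm"].to_numpy(),
                intensity=g["intensity"].to_numpy() if "intensity" in g else None,
            )
        )
    return out


def read_cest_profiles(directory) -> list[CestProfile]:
    directory = Path(directory)
    cfg = read_config(directory / "config.yaml")
    df = pd.read_csv(directory / "cest.csv")
    out = []
    for (res, b1), g in df.groupby(["residue", "b1_hz"]):
        g = g.sort_values("offset_hz")
        out.append(
            CestProfile(
                residue=str(res),
                offsets_hz=g["offset_hz"].to_numpy(),
                intensities=np.clip(g["intensity_ratio"].to_numpy(), -0.05, 1.05),
                b1_hz=float(b1),
                t_ex=float(cfg["t_ex_s"]),
                spectrometer_h_freq=float(cfg["spectrometer_h_freq"]),
            )
        )
    return out


def read_itc_experiments(directory) -> list[ItcExperiment]:
    directory = Path(directory)
    cfg = read_config(directory / "config.yaml")
    df = pd.read_csv(directory / "itc.csv")
    out = []
    for rep, g in df.groupby("replicate"):
        g = g.sort_values("injection_index")
        out.append(
            ItcExperiment(
                cell_concentration=float(cfg["cell_um"]),
                syringe_concentration=float(cfg["syringe_um"]),
                injection_volumes=g["volume_ul"].to_numpy(),
                heats=g["heat_uj"].to_numpy(),
                cell_volume=float(cfg.get("cell_volume_ul", 200.0)),
                replicate_id=int(rep),
            )
        )
    return out
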