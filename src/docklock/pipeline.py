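"""End-to-end orchestration: fits → ThermoRecords → dissection → energy ledger.

`run_pipeline` consumes a RunConfig (usually a YAML file) naming datasets
per complex and the construct pairs to dissect, runs every requested fit
in dependency order, and writes machine-readable JSON plus a plain-text
report with the two-step kinetic scheme numbers and the ΔΔG ledger.

`table1_derivations` re-derives every derivable column of a results table
(ΔG from K_D, −TΔS from ΔG and ΔH, k_on from k_off and K_D) and the
two-step constants implied by the full-length/truncated pairs, tabulating
computed-vs-printed deltas — the package's internal-consistency audit of a
published parameter table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as io_mod
from .thermo import (
    ThermoRecord,
    delta_g_from_kd,
    entropy_term,
    kon_from_kd_koff,
)
from .twostep import build_energy_ledger, dissect_pair, infer_lock_constant

__all__ = ["RunConfig", "run_pipeline", "table1_derivations", "HEADLINE_CONTRASTS"]

#: the four headline free-energy contrasts of the dissection
HEADLINE_CONTRASTS = [
    ("full_vs_SxIP_only", "EBH/11MACF", "EBH/4MACF"),
    ("C_terminal_folding", "EBH/11MACF", "EBH-dC/11MACF"),
    ("VLL_vs_WT", "EBH/11MACF-VLL", "EBH/11MACF"),
    ("VLLRK_vs_VLL", "EBH/11MACF-VLLRK", "EBH/11MACF-VLL"),
]


@dataclass
class RunConfig:
    datasets: dict  # complex label -> {kind: directory}
    pairs: list = field(default_factory=list)  # {label, full, truncated}
    ledger: list = field(default_factory=list)  # {label, a, b}
    output_dir: str = "out"
    seed: int = 0
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        cfg = io_mod.read_config(path)
        rc = cls(
            datasets=cfg.get("datasets", {}),
            pairs=cfg.get("pairs", []),
            ledger=cfg.get("ledger", []),
            output_dir=cfg.get("output_dir", "out"),
            seed=int(cfg.get("seed", 0)),
        )
        rc.validate()
        return rc

    def validate(self):
        if not self.datasets:
            raise ValueError("config names no datasets (empty stage list)")
        for label, kinds in self.datasets.items():
            for kind, path in kinds.items():
                if not Path(path).exists():
                    raise FileNotFoundError(f"{label}/{kind}: {path} does not exist")


def _fit_complex(label: str, kinds: dict, seed: int) -> tuple[ThermoRecord, dict]:
    """Fit every dataset available for one complex and merge into a record."""
    from . import cest as cest_mod
    from . import itc as itc_mod
    from . import lineshape as ls_mod

    detail: dict = {}
    kd = kd_err = dh = dh_err = n = n_err = koff = koff_err = None
    tags = {}
    if "itc" in kinds:
        fit = itc_mod.fit_itc(io_mod.read_itc_experiments(kinds["itc"]))
        kd, kd_err, dh, dh_err, n, n_err = fit.kd, fit.kd_err, fit.dh, fit.dh_err, fit.n, fit.n_err
        tags["kd"] = "ITC"
        detail["itc"] = dict(kd=fit.kd, dh=fit.dh, n=fit.n, c=fit.c_value,
                             warnings=fit.warnings)
    if "lineshapes" in kinds:
        series = io_mod.read_lineshape_series(kinds["lineshapes"])
        fit = ls_mod.fit_titration(series, seed=seed)
        koff, koff_err = fit.koff, fit.koff_err
        detail["lineshape"] = dict(kd=fit.kd, koff=fit.koff, regime=fit.regime)
        if kd is None:
            kd, kd_err = fit.kd, fit.kd_err
            tags["kd"] = "NMR_lineshape"
        tags["koff"] = "NMR_lineshape"
    if "cest" in kinds:
        profiles = io_mod.read_cest_profiles(kinds["cest"])
        free_pos = {p.residue: 0.0 for p in profiles}
        fit = cest_mod.fit_cest(profiles, free_pos, seed=seed)
        detail["cest"] = dict(
            koff=fit.koff, p_bound=fit.p_bound, flag=fit.flag_slow_exchange
        )
        if koff is None:
            koff, koff_err = fit.koff, fit.koff_err
            tags["koff"] = "CEST"
    if "peaks" in kinds:
        from . import csp as csp_mod

        cfg = io_mod.read_config(Path(kinds["peaks"]).parent / "config.yaml")
        trajs = io_mod.read_peak_trajectories(kinds["peaks"])
        fit = csp_mod.fit_csp_titration(
            trajs, cfg["p_total_um"], cfg["l_total_um"]
        )
        detail["csp"] = dict(kd=fit.kd, warnings=fit.warnings)
        if kd is None:
            kd, kd_err = fit.kd, fit.kd_err
            tags["kd"] = "CSP"
    if kd is None:
        raise ValueError(f"{label}: no dataset yields a K_D")
    dg = delta_g_from_kd(kd)
    rec = ThermoRecord(
        complex_label=label, kd=kd, kd_err=kd_err, dg=dg,
        dh=dh, dh_err=dh_err,
        neg_tds=None if dh is None else entropy_term(dg, dh),
        n_sites=n, n_err=n_err, koff=koff, koff_err=koff_err,
        kon=None if koff is None else kon_from_kd_koff(kd, koff),
        method_tags=tags,
    )
    return rec, detail


def run_pipeline(config: RunConfig) -> dict:
    """Execute all requested stages; returns (and writes) the report bundle.

    Stage failures do not abort the run: they are recorded per stage in the
    bundle's ``failures`` map, and the CLI maps a non-empty map to a
    non-zero exit status.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"seed": config.seed, "records": {}, "details": {},
                    "dissections": {}, "ledger": [], "failures": {}}

    records = []
    for label, kinds in config.datasets.items():
        try:
            rec, detail = _fit_complex(label, kinds, config.seed)
            records.append(rec)
            bundle["records"][label] = {
                "kd_um": rec.kd, "kd_err": rec.kd_err, "dg": rec.dg,
                "dh": rec.dh, "neg_tds": rec.neg_tds, "n": rec.n_sites,
                "koff": rec.koff, "kon": rec.kon, "tags": rec.method_tags,
            }
            bundle["details"][label] = detail
        except Exception as exc:  # recorded, not fatal
            bundle["failures"][label] = repr(exc)

    by_label = {r.complex_label: r for r in records}
    for pair in config.pairs:
        try:
            diss = dissect_pair(
                by_label[pair["full"]], by_label[pair["truncated"]],
                seed=config.seed,
            )
            bundle["dissections"][pair["label"]] = {
                "kd_dock_um": diss.kd_dock, "koff_dock": diss.koff_dock,
                "kon_dock": diss.kon_dock, "kd_eff_um": diss.kd_eff,
                "koff_eff": diss.koff_eff, "kon_eff": diss.kon_eff,
                "kl_exact": diss.kl, "kl_small_limit": diss.kl_small_limit,
                "kl_rate_route": diss.kl_rate_route,
                "dock_fraction": diss.dock_fraction,
                "kon_verdict": diss.kon_verdict,
                "errors": diss.errors,
            }
        except Exception as exc:
            bundle["failures"][f"pair:{pair.get('label')}"] = repr(exc)

    if config.ledger:
        try:
            ledger = build_energy_ledger(
                records, [(c["label"], c["a"], c["b"]) for c in config.ledger]
            )
            bundle["ledger"] = [
                {"label": e.label, "pair": list(e.pair), "ddg": e.ddg,
                 "ddg_err": e.ddg_err}
                for e in ledger.entries
            ]
        except Exception as exc:
            bundle["failures"]["ledger"] = repr(exc)

    (out / "results.json").write_text(json.dumps(bundle, indent=2, default=float))
    (out / "report.txt").write_text(_format_report(bundle))
    return bundle


def _format_report(bundle: dict) -> str:
    lines = [f"docklock pipeline report (seed {bundle['seed']})", ""]
    for label, rec in bundle["records"].items():
        lines.append(f"[{label}]")
        lines.append(
            f"  K_D = {rec['kd_um']:.4g} uM   dG = {rec['dg']:.4g} kJ/mol"
            + (f"   k_off = {rec['koff']:.4g} s-1" if rec["koff"] else "")
        )
    for label, d in bundle["dissections"].items():
        lines += [
            "",
            f"[two-step dissection: {label}]",
            f"  dock:      K_D^D = {d['kd_dock_um']:.4g} uM, "
            f"k_off^D = {d['koff_dock']:.4g} s-1, k_on^D = {d['kon_dock']:.4g} uM-1 s-1"
            if d["koff_dock"] else f"  dock: K_D^D = {d['kd_dock_um']:.4g} uM",
            f"  effective: K'_D = {d['kd_eff_um']:.4g} uM",
            f"  lock:      K_D^L = {d['kl_small_limit']:.3g} (small-K_L) / "
            f"{d['kl_exact']:.3g} (exact)"
            + (f" / {d['kl_rate_route']:.3g} (rate route)" if d["kl_rate_route"] else ""),
            f"  dock-state population of the bound pool: "
            f"{100 * d['dock_fraction']:.2g}%",
            f"  on-rate inequality (k'_on <= k_on^D): {d['kon_verdict']}",
        ]
    if bundle["ledger"]:
        lines += ["", "[free-energy ledger]"]
        for e in bundle["ledger"]:
            lines.append(f"  {e['label']}: ddG = {e['ddg']:+.3g} kJ/mol")
    if bundle["failures"]:
        lines += ["", "[failures]"] + [
            f"  {k}: {v}" for k, v in bundle["failures"].items()
        ]
    return "\n".join(lines) + "\n"


def table1_derivations(records: pd.DataFrame | str | Path) -> dict:
    """Recompute every derivable quantity of a results table.

    Accepts the packaged reference-table dialect (or a path to one) and
    returns a dict with a per-row DataFrame of computed-vs-printed deltas
    plus the derived two-step constants and headline ΔΔG contrasts. An
    empty table yields an empty report.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.read_csv(records)
    if records.empty:
        return {"rows": pd.DataFrame(), "derived": {}, "ledger": {}}
    need = {"complex", "kd_um", "dg"}
    if not need.issubset(records.columns):
        raise ValueError(f"missing required columns: {sorted(need - set(records.columns))}")

    rows = []
    for _, r in records.iterrows():
        dg_calc = delta_g_from_kd(r["kd_um"]) if r["kd_um"] > 0 else math.nan
        row = {
            "complex": r["complex"],
            "dg_printed": r["dg"],
            "dg_calc": dg_calc,
            "dg_delta": dg_calc - r["dg"],
        }
        if not pd.isna(r.get("dh")):
            row["neg_tds_printed"] = r["neg_tds"]
            row["neg_tds_calc"] = entropy_term(r["dg"], r["dh"])
            row["neg_tds_delta"] = row["neg_tds_calc"] - r["neg_tds"]
        if not pd.isna(r.get("koff")) and not pd.isna(r.get("kon")):
            row["kon_printed"] = r["kon"]
            row["kon_calc"] = kon_from_kd_koff(r["kd_um"], r["koff"])
            row["kon_delta"] = row["kon_calc"] - r["kon"]
        rows.append(row)
    df = pd.DataFrame(rows)

    by = records.set_index("complex")
    derived = {}
    for tag, full, trunc in [
        ("11MACF", "EBH/11MACF", "EBH-dC/11MACF"),
        ("11MACF-VLL", "EBH/11MACF-VLL", "EBH-dC/11MACF-VLL"),
    ]:
        if full in by.index and trunc in by.index:
            kd_eff, kd_dock = by.loc[full, "kd_um"], by.loc[trunc, "kd_um"]
            d = {
                "kl_kd_route": infer_lock_constant(kd_eff, kd_dock, "small_kl_limit"),
                "kl_exact": infer_lock_constant(kd_eff, kd_dock, "exact"),
                "dock_fraction": kd_eff / kd_dock,
            }
            if not pd.isna(by.loc[full].get("koff")) and not pd.isna(
                by.loc[trunc].get("koff")
            ):
                d["kl_rate_route"] = by.loc[full, "koff"] / by.loc[trunc, "koff"]
            derived[tag] = d

    ledger = {}
    for label, a, b in HEADLINE_CONTRASTS:
        if a in by.index and b in by.index:
            ledger[label] = float(by.loc[a, "dg"] - by.loc[b, "dg"])
    return {"rows": df, "derived": derived, "ledger": ledger}
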