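"""End-to-end pipeline: simulate -> analyze -> fit -> AP-compare -> report.

Chains the synthetic recordings, the voltage-clamp analysis, the IKs
parameter fit and the ventricular-AP comparison into one reproducible
run, with all intermediate tables written to disk:

* sweeps as long-format CSV (cell_id, group, step_mv, t_ms, i_pa) with a
  JSON sidecar (per-cell capacitance, generator config);
* tail I-V and per-cell Boltzmann fits as CSV;
* per-group IKs fit results, AP biomarkers and a manifest as JSON.

The fitted conductances from heterologous recordings carry an arbitrary
expression-level scale, so before AP simulation every group's fitted
g_ks is multiplied by the single factor that maps the WT fit onto the
published epicardial conductance (0.392 mS/uF); relative reductions
between groups are preserved.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ap_model import G_KS_DEFAULT, IKsParams, PacingConfig, compare_variants
from .ephys_analysis import (
    SweepSet,
    TailIV,
    VoltageProtocol,
    build_tail_iv,
    fit_boltzmann,
)
from .iks_fitting import FitProblem, FitResult, fit_iks_params, fit_report
from .synthetic_data import DEFAULT_N_CELLS, DNMixture, generate_cell_population

__all__ = [
    "RunConfig",
    "ResultsBundle",
    "run_pipeline",
    "read_sweeps",
    "write_sweeps",
    "write_bundle",
]

log = logging.getLogger("ikslab")

SWEEP_COLUMNS = ["cell_id", "group", "step_mv", "t_ms", "i_pa"]


@dataclass
class RunConfig:
    """One-file configuration of the whole pipeline."""

    seed: int = 2022
    n_cells: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_CELLS))
    noise_sd_pa: float = 5.0
    f_mut: float = 0.5
    dn_rule: str = "all-WT-required"
    protocol: VoltageProtocol = field(default_factory=VoltageProtocol)
    pacing: PacingConfig = field(default_factory=PacingConfig)
    variant_group: str = "HET"
    anchor_g_ks: float = G_KS_DEFAULT
    outdir: str = "ikslab_results"

    def __post_init__(self) -> None:
        for grp, n in self.n_cells.items():
            if grp not in ("WT", "HOM", "HET"):
                raise ValueError(f"unknown group {grp!r}")
            if n < 1:
                raise ValueError(f"group {grp}: n_cells must be >= 1")
        if self.variant_group not in self.n_cells:
            raise ValueError("variant_group must be one of the simulated groups")
        DNMixture(self.f_mut, self.dn_rule)  # validates

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_cells": dict(self.n_cells),
            "noise_sd_pa": self.noise_sd_pa,
            "f_mut": self.f_mut,
            "dn_rule": self.dn_rule,
            "protocol": self.protocol.to_dict(),
            "pacing": self.pacing.to_dict(),
            "variant_group": self.variant_group,
            "anchor_g_ks": self.anchor_g_ks,
            "outdir": self.outdir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "protocol" in d:
            d["protocol"] = VoltageProtocol.from_dict(d["protocol"])
        if "pacing" in d:
            d["pacing"] = PacingConfig(**d["pacing"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ResultsBundle:
    """All numeric results of one pipeline run plus provenance."""

    config: RunConfig
    tail_iv: TailIV
    boltzmann: pd.DataFrame          # per-cell Boltzmann fits
    boltzmann_group: pd.DataFrame    # group mean +- SEM of V50 / k
    iks_fits: Dict[str, FitResult]
    anchored_params: Dict[str, IKsParams]
    comparison: "object"             # ap_model.VariantComparison
    provenance: dict


# ---------------------------------------------------------------------------
# sweep IO
# ---------------------------------------------------------------------------

def write_sweeps(cells: Iterable[SweepSet], csv_path, sidecar_path) -> None:
    """Long-format sweep CSV plus JSON sidecar with capacitances/config."""
    frames = []
    sidecar = {"cells": {}}
    for cell in cells:
        for step_mv, (t, i) in sorted(cell.sweeps.items()):
            frames.append(
                pd.DataFrame(
                    {
                        "cell_id": cell.cell_id,
                        "group": cell.group,
                        "step_mv": step_mv,
                        "t_ms": t,
                        "i_pa": i,
                    }
                )
            )
        sidecar["cells"][cell.cell_id] = {
            "capacitance_pf": cell.capacitance_pf,
            "group": cell.group,
            "meta": _json_safe(cell.meta),
        }
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_sweeps(csv_path, sidecar_path) -> List[SweepSet]:
    """Inverse of :func:`write_sweeps`; numeric fields round-trip at full
    precision up to CSV float formatting."""
    df = pd.read_csv(csv_path)
    missing_cols = [c for c in SWEEP_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"sweep CSV missing columns {missing_cols}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    cells = []
    for cell_id, sub in df.groupby("cell_id", sort=True):
        entry = sidecar.get("cells", {}).get(str(cell_id))
        if entry is None:
            raise ValueError(f"sidecar missing capacitance for cell {cell_id!r}")
        sweeps = {}
        for step_mv, seg in sub.groupby("step_mv"):
            seg = seg.sort_values("t_ms")
            sweeps[float(step_mv)] = (
                seg["t_ms"].to_numpy(), seg["i_pa"].to_numpy()
            )
        group = str(sub["group"].iloc[0]) if "group" in sub else entry.get("group", "")
        cells.append(
            SweepSet(
                cell_id=str(cell_id),
                capacitance_pf=float(entry["capacitance_pf"]),
                sweeps=sweeps,
                group=group,
                meta=entry.get("meta", {}),
            )
        )
    return cells


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def analyze_cells(cells: List[SweepSet], protocol: VoltageProtocol):
    """Tail I-V plus per-cell and per-group Boltzmann summaries."""
    iv = build_tail_iv(cells, protocol)
    rows = []
    for cell_id, dens in iv.densities.iterrows():
        fit = fit_boltzmann(iv.potentials_mv, dens.to_numpy())
        rows.append(
            {
                "cell_id": cell_id,
                "group": iv.groups[cell_id],
                "i_max": fit.i_max,
                "v50_mv": fit.v50_mv,
                "k_mv": fit.k_mv,
                "residual_norm": fit.residual_norm,
                "success": fit.success,
            }
        )
    per_cell = pd.DataFrame.from_records(rows).set_index("cell_id")
    grp_rows = []
    for grp, sub in per_cell.groupby("group"):
        ok = sub[sub["success"]]
        for col in ("v50_mv", "k_mv", "i_max"):
            vals = ok[col].to_numpy()
            grp_rows.append(
                {
                    "group": grp,
                    "parameter": col,
                    "mean": float(np.mean(vals)),
                    "sem": float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                    if len(vals) > 1 else 0.0,
                    "n": int(len(vals)),
                }
            )
    return iv, per_cell, pd.DataFrame.from_records(grp_rows)


def anchor_conductances(
    fits: Dict[str, FitResult], anchor_g_ks: float = G_KS_DEFAULT
) -> Dict[str, IKsParams]:
    """Rescale all fitted g_ks by the factor mapping the WT fit to the
    published myocyte conductance; v50/slope pass through unchanged."""
    if "WT" not in fits:
        raise ValueError("anchoring requires a WT fit")
    wt_g = fits["WT"].params.g_ks
    if wt_g <= 0:
        raise ValueError("WT fitted conductance must be positive for anchoring")
    scale = anchor_g_ks / wt_g
    out = {}
    for grp, fr in fits.items():
        p = fr.params
        out[grp] = IKsParams(g_ks=p.g_ks * scale, v50=p.v50, slope=p.slope,
                             tau_scale=p.tau_scale)
    return out


def run_pipeline(config: RunConfig, outdir: Optional[Path] = None) -> ResultsBundle:
    """Execute the full chain and write the results bundle."""
    t_start = time.time()
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mixture = DNMixture(config.f_mut, config.dn_rule)

    log.info("stage simulate-ephys: generating %s", config.n_cells)
    cells: List[SweepSet] = []
    for grp, n in config.n_cells.items():
        cells.extend(
            generate_cell_population(
                grp, n, seed=config.seed, protocol=config.protocol,
                mixture=mixture, noise_sd_pa=config.noise_sd_pa,
            )
        )
    write_sweeps(cells, outdir / "sweeps.csv", outdir / "sweeps_meta.json")

    log.info("stage analyze-ephys: %d cells", len(cells))
    iv, per_cell, per_group = analyze_cells(cells, config.protocol)
    iv.summary.to_csv(outdir / "tail_iv.csv", index=False)
    iv.densities.to_csv(outdir / "tail_densities.csv")
    per_cell.to_csv(outdir / "boltzmann_cells.csv")
    per_group.to_csv(outdir / "boltzmann_groups.csv", index=False)

    log.info("stage fit-iks")
    fits: Dict[str, FitResult] = {}
    reports = {}
    for grp in config.n_cells:
        problem = FitProblem.from_tail_iv(iv, grp, config.protocol)
        fits[grp] = fit_iks_params(problem, seed=config.seed)
        reports[grp] = fit_report(fits[grp], problem)
        if not fits[grp].converged:
            raise RuntimeError(f"stage fit-iks: group {grp} fit did not converge")
    anchored = anchor_conductances(fits, config.anchor_g_ks)

    log.info("stage ap-compare: WT vs %s", config.variant_group)
    comparison = compare_variants(
        anchored["WT"], anchored[config.variant_group], config.pacing
    )
    trace_df = pd.DataFrame(
        {
            "t_ms": comparison.wt.trace.t_ms,
            "v_wt_mv": comparison.wt.trace.v_mv,
            "v_variant_mv": comparison.variant.trace.v_mv,
            "iks_wt_apf": comparison.wt.trace.iks,
            "iks_variant_apf": comparison.variant.trace.iks,
        }
    )
    trace_df.to_csv(outdir / "ap_traces.csv", index=False)

    provenance = {
        "config_hash": config.config_hash(),
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "elapsed_s": round(time.time() - t_start, 3),
        "seed": config.seed,
    }
    bundle = ResultsBundle(
        config=config,
        tail_iv=iv,
        boltzmann=per_cell,
        boltzmann_group=per_group,
        iks_fits=fits,
        anchored_params=anchored,
        comparison=comparison,
        provenance=provenance,
    )
    write_bundle(bundle, outdir, reports)
    log.info("pipeline done in %.1f s", provenance["elapsed_s"])
    return bundle


def write_bundle(bundle: ResultsBundle, outdir: Path, reports: dict) -> None:
    """JSON results + manifest of every file written."""
    outdir = Path(outdir)
    results = {
        "config": bundle.config.to_dict(),
        "provenance": bundle.provenance,
        "iks_fits": {g: _json_safe(r) for g, r in reports.items()},
        "anchored_params": {g: p.to_dict() for g, p in bundle.anchored_params.items()},
        "comparison": bundle.comparison.to_dict(),
        "boltzmann_groups": bundle.boltzmann_group.to_dict(orient="records"),
    }
    with open(outdir / "results.json", "w") as fh:
        json.dump(_json_safe(results), fh, indent=1)
    files = sorted(
        p.name for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config_hash": bundle.config.config_hash(),
        "package_version": __version__,
        "files": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
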