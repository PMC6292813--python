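"""End-to-end simulation ladder: SAN -> SAP -> SAP-TBX18 -> SAP-TBX18+RYR2.

For each preparation the ladder rescales the base cell parameters to that
preparation's transcript abundances, simulates spontaneous activity to the
limit cycle, extracts action-potential features, and computes the simulated
funny-current I-V relation.  The report collects rate/cycle-length/DD/MDP
per preparation and is deterministic for a given configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .ionic_model import CellParams, SolverConfig, default_cell_params, simulate, voltage_clamp_iv
from .ap_metrics import compute_ap_metrics
from .transcript_scaling import AbundanceTable, default_abundance_table, scale_conductances

__all__ = ["Preparation", "RunConfig", "params_for_preparation", "run_ladder",
           "DEFAULT_IV_PROTOCOL"]


class Preparation(str, Enum):
    SAN = "SAN"
    SAP = "SAP"
    SAP_TBX18 = "SAP_TBX18"
    SAP_TBX18_RYR2 = "SAP_TBX18_RYR2"


# abundance-table row and RYR2 handling per ladder rung
_PREP_ROW = {
    Preparation.SAN: ("SAN", False),
    Preparation.SAP: ("SAP", False),
    Preparation.SAP_TBX18: ("SAP_TBX18", False),
    Preparation.SAP_TBX18_RYR2: ("SAP_TBX18", True),
}

DEFAULT_IV_PROTOCOL = [(-35.0, v, 2000.0) for v in np.arange(-120.0, -19.9, 10.0)]


@dataclass
class RunConfig:
    """Configuration of one ladder run."""

    preparations: list[Preparation] = field(
        default_factory=lambda: list(Preparation))
    base_params: CellParams | None = None
    abundance: AbundanceTable | None = None
    duration_s: float = 10.0
    discard_beats: int = 20
    solver: SolverConfig = field(default_factory=SolverConfig)
    out_dir: str | None = None
    seed: int = 0   # the ladder itself is deterministic; kept for provenance


def params_for_preparation(prep: Preparation | str,
                           base: CellParams | None = None,
                           table: AbundanceTable | None = None) -> CellParams:
    """Cell parameters for one ladder rung.

    SAN returns the base parameters unchanged; the others apply the
    transcript-to-conductance scaling against the SAN reference row, with
    the RYR2 fold applied only on the SAP_TBX18_RYR2 rung.
    """
    prep = Preparation(prep)
    base = base or default_cell_params()
    table = table or default_abundance_table()
    row, use_ryr2 = _PREP_ROW[prep]
    if prep is Preparation.SAN:
        return base
    return scale_conductances(base, table.row(row), table.row("SAN"),
                              include_ryr2=use_ryr2)


def _config_digest(cfg: RunConfig) -> str:
    from .io import params_to_dict

    payload = {
        "preparations": [p.value for p in cfg.preparations],
        "base_params": params_to_dict(cfg.base_params or default_cell_params()),
        "abundance": (cfg.abundance or default_abundance_table()).df.to_dict(),
        "duration_s": cfg.duration_s,
        "discard_beats": cfg.discard_beats,
        "solver": vars(cfg.solver),
        "seed": cfg.seed,
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_ladder(cfg: RunConfig | None = None) -> dict:
    """Run the simulation ladder and return the structured report.

    The report maps each preparation to its rate (bpm), cycle length (ms),
    DD slope (V/s), MDP (mV), total funny-current conductance, and I-V
    curve; provenance carries the package version and a configuration hash.
    If ``cfg.out_dir`` is set, per-preparation traces (CSV) and the report
    (JSON + CSV) are written there.
    """
    from . import __version__
    from .io import save_trace_csv

    cfg = cfg or RunConfig()
    base = cfg.base_params or default_cell_params()
    table = cfg.abundance or default_abundance_table()
    report: dict = {
        "provenance": {"package": "biopace", "version": __version__,
                       "config_sha256": _config_digest(cfg)},
        "preparations": {},
    }
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    for prep in cfg.preparations:
        try:
            p = params_for_preparation(prep, base, table)
            trace = simulate(p, cfg.duration_s, cfg.solver)
            m = compute_ap_metrics(trace, discard_beats=cfg.discard_beats)
            iv = voltage_clamp_iv(p, DEFAULT_IV_PROTOCOL)
        except Exception as exc:
            raise RuntimeError(f"ladder stage {prep.value} failed: {exc}") from exc
        report["preparations"][prep.value] = {
            "rate_bpm": m.rate,
            "cycle_length_ms": m.cycle_length,
            "dd_slope_v_per_s": m.dd_slope,
            "mdp_mv": m.mdp,
            "n_beats": m.n_beats,
            "g_f_total": p.g_f_total,
            "ryr2_scale": p.ryr2_scale,
            "iv": {"v_mv": iv.v_test.tolist(), "i_pa_per_pf": iv.i_f.tolist()},
        }
        if out:
            save_trace_csv(trace, out / f"trace_{prep.value}.csv")
    if out:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        _report_csv(report, out / "report.csv")
    return report


def _report_csv(report: dict, path) -> None:
    import pandas as pd

    rows = {
        prep: {k: v for k, v in vals.items() if not isinstance(v, dict)}
        for prep, vals in report["preparations"].items()
    }
    pd.DataFrame(rows).T.to_csv(path, index_label="preparation")
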