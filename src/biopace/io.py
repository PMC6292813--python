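"""YAML/CSV serialisation of parameter sets and traces."""

from __future__ import annotations

from dataclasses import asdict

import yaml

from .ionic_model import CellParams, IfIsoformParams, Isoform, TauParams, VoltageTrace

__all__ = ["params_to_dict", "params_from_dict", "save_params_yaml",
           "load_params_yaml", "save_trace_csv", "load_trace_csv"]


def params_to_dict(p: CellParams) -> dict:
    d = asdict(p)
    d["if_isoforms"] = {
        iso.value: {**asdict(ip), "isoform": iso.value}
        for iso, ip in p.if_isoforms.items()
    }
    return d


def params_from_dict(d: dict) -> CellParams:
    d = dict(d)
    iso_d = d.pop("if_isoforms", {})
    isoforms = {}
    for key, sub in iso_d.items():
        sub = dict(sub)
        iso = Isoform(sub.pop("isoform", key))
        tau = TauParams(**sub.pop("tau_params", {}))
        isoforms[iso] = IfIsoformParams(isoform=iso, tau_params=tau, **sub)
    p = CellParams(if_isoforms=isoforms, **d)
    p.validate()
    return p


def save_params_yaml(p: CellParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(p), fh, sort_keys=True)


def load_params_yaml(path) -> CellParams:
    with open(path) as fh:
        return params_from_dict(yaml.safe_load(fh))


def save_trace_csv(trace: VoltageTrace, path) -> None:
    trace.to_dataframe().to_csv(path, index=False)


def load_trace_csv(path) -> VoltageTrace:
    import pandas as pd

    df = pd.read_csv(path)
    currents = {c: df[c].to_numpy() for c in df.columns
                if c not in ("t_ms", "v_mV")}
    return VoltageTrace(t=df["t_ms"].to_numpy(), v=df["v_mV"].to_numpy(),
                        currents=currents)
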