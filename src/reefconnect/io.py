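"""File formats: NetCDF fields (scipy backend, NetCDF-3), CSV tables, JSON.

Writers are deterministic (sorted keys, fixed column order) so that
re-running a pipeline with the same configuration and seed produces
byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .deltamaps import Domain, FunctionalNetwork, NetworkLink

__all__ = [
    "save_field",
    "load_field",
    "save_labels",
    "load_labels",
    "save_domains",
    "load_domains",
    "save_network",
    "load_network",
    "save_json",
    "sha256_of",
]


def save_field(field: xr.DataArray, path) -> Path:
    path = Path(path)
    field.to_dataset(name=field.name or "field").to_netcdf(path, engine="scipy")
    return path


def load_field(path, name=None) -> xr.DataArray:
    ds = xr.load_dataset(path, engine="scipy")
    if name is None:
        name = list(ds.data_vars)[0]
    return ds[name]


def save_labels(labels: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({str(k): v for k, v in labels.items()}, sort_keys=True, indent=1))
    return path


def load_labels(path) -> dict:
    return {int(k): v for k, v in json.loads(Path(path).read_text()).items()}


def save_domains(domains, path) -> Path:
    """Sparse cell table: one row per (domain, cell)."""
    rows = [
        {"domain": d.id, "row": r, "col": c, "strength": d.strength}
        for d in domains
        for (r, c) in sorted(d.cells)
    ]
    df = pd.DataFrame(rows, columns=["domain", "row", "col", "strength"])
    df.to_csv(path, index=False)
    return Path(path)


def load_domains(path, field=None) -> list:
    from .deltamaps import domain_signal

    df = pd.read_csv(path)
    domains = []
    for did, grp in df.groupby("domain", sort=True):
        dom = Domain(
            id=str(did),
            cells=frozenset((int(r), int(c)) for r, c in zip(grp["row"], grp["col"])),
            strength=float(grp["strength"].iloc[0]),
        )
        if field is not None:
            dom.signal = domain_signal(dom, field)
        domains.append(dom)
    return domains


def save_network(net: FunctionalNetwork, csv_path, json_path=None) -> Path:
    rows = [
        {
            "a": ln.a,
            "b": ln.b,
            "weight": repr(ln.weight),
            "lag": ln.lag,
            "direction": ln.direction,
            "r_star": repr(ln.r_star),
            "significant_lags": ";".join(str(l) for l in ln.significant_lags),
        }
        for ln in net.links
    ]
    df = pd.DataFrame(
        rows, columns=["a", "b", "weight", "lag", "direction", "r_star", "significant_lags"]
    )
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        payload = {
            "parameters": net.parameters,
            "domains": [
                {"id": d.id, "strength": d.strength, "n_cells": len(d.cells)}
                for d in net.domains
            ],
            "links": rows,
        }
        Path(json_path).write_text(json.dumps(payload, sort_keys=True, indent=1, default=str))
    return Path(csv_path)


def load_network(csv_path, domains) -> FunctionalNetwork:
    df = pd.read_csv(csv_path)
    links = []
    for _, row in df.iterrows():
        sig = (
            tuple(int(x) for x in str(row["significant_lags"]).split(";"))
            if not pd.isna(row["significant_lags"]) and str(row["significant_lags"])
            else ()
        )
        links.append(
            NetworkLink(
                a=str(row["a"]),
                b=str(row["b"]),
                weight=float(row["weight"]),
                lag=int(row["lag"]),
                r_star=float(row["r_star"]),
                direction=str(row["direction"]),
                significant_lags=sig,
            )
        )
    net = FunctionalNetwork(domains=list(domains), links=links)
    strengths = net.strengths()
    for d in net.domains:
        d.strength = strengths[d.id]
    return net


def save_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, sort_keys=True, indent=1, default=str))
    return path


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
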