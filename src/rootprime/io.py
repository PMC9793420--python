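"""Saving simulation outputs and tissue snapshots.

Array data go into an HDF5 container; tabular data (cell table, traces,
events) are written as delimited text so they remain inspectable with
standard tools.
"""
from __future__ import annotations

import json
import os
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import yaml

from .geometry import CELL_TYPE_NAMES, ZONE_NAMES, Tissue
from .runner import SimulationOutputs


def cell_table(tissue: Tissue) -> pd.DataFrame:
    rows = []
    for cell in sorted(tissue.cells.values(), key=lambda c: c.id):
        rows.append({
            "id": cell.id, "type": CELL_TYPE_NAMES[cell.ctype],
            "side": cell.side, "zone": ZONE_NAMES[cell.zone],
            "c0": cell.c0, "c1": cell.c1, "r0": cell.r0, "r1": cell.r1,
            "length_cont": cell.length_cont, "birth_length": cell.birth_length,
            "mean_j": cell.mean_j, "celltypefactor": cell.ctf,
        })
    return pd.DataFrame(rows)


def save_tissue(tissue: Tissue, h5_path, csv_path=None) -> None:
    """point_kind / cell_id arrays in HDF5 plus a delimited-text cell table."""
    with h5py.File(h5_path, "w") as fh:
        fh.create_dataset("point_kind", data=tissue.point_kind)
        fh.create_dataset("cell_slot", data=tissue.cell_slot)
        fh.create_dataset("auxin", data=tissue.auxin)
        fh.attrs["dx"] = tissue.cfg.dx
    if csv_path is not None:
        cell_table(tissue).to_csv(csv_path, sep="\t", index=False)


def save_outputs(outputs: SimulationOutputs, outdir) -> None:
    """Write one run's outputs: config echo (YAML), array bundle (HDF5),
    traces and event log (TSV)."""
    os.makedirs(outdir, exist_ok=True)
    outputs.config.to_yaml(os.path.join(outdir, "config.yaml"))
    with h5py.File(os.path.join(outdir, "outputs.h5"), "w") as fh:
        fh.create_dataset("times", data=outputs.times)
        fh.create_dataset("kymo_signalling", data=outputs.kymo_signalling)
        fh.create_dataset("kymo_auxin", data=outputs.kymo_auxin)
        fh.create_dataset("inserts_below", data=outputs.inserts_below)
        fh.create_dataset("final_auxin", data=outputs.final_auxin)
        fh.attrs["dx"] = outputs.dx
    outputs.traces.to_csv(os.path.join(outdir, "traces.tsv"), sep="\t",
                          index=False)
    outputs.events.to_csv(os.path.join(outdir, "events.tsv"), sep="\t",
                          index=False)


def load_outputs(outdir) -> SimulationOutputs:
    from .params import ScenarioConfig
    config = ScenarioConfig.from_yaml(os.path.join(outdir, "config.yaml"))
    with h5py.File(os.path.join(outdir, "outputs.h5"), "r") as fh:
        times = fh["times"][()]
        ks = fh["kymo_signalling"][()]
        ka = fh["kymo_auxin"][()]
        ins = fh["inserts_below"][()]
        final = fh["final_auxin"][()]
        dx = float(fh.attrs["dx"])
    traces = pd.read_csv(os.path.join(outdir, "traces.tsv"), sep="\t")
    events = pd.read_csv(os.path.join(outdir, "events.tsv"), sep="\t")
    return SimulationOutputs(config=config, times=times, kymo_signalling=ks,
                             kymo_auxin=ka, inserts_below=ins, traces=traces,
                             events=events, final_auxin=final, dx=dx)
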