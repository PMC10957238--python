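"""Cohort container IO: one HDF5 file per cohort plus a JSON sidecar.

Layout::

    /participants          participant table (id, group, ability)
    /stimuli               stimulus table columns
    /<participant_id>/epochs        (trials × channels × samples)
    /<participant_id>/trials/<col>  per-trial metadata
    /time_ms, /channels_xyz, /channel_labels, /sfreq

The sidecar ``<path>.json`` carries the generation parameters and seed.
Stimulus and trial tables are additionally exportable as TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datasets import CohortDataset, EpochSet
from .stimuli import StimulusSet

__all__ = ["write_cohort", "read_cohort", "export_tables", "write_rdm", "read_rdm"]

_TRIAL_COLS = ("stimulus_id", "session", "is_repeat", "response_made")


def write_cohort(path, cohort: CohortDataset) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        part = cohort.participants
        grp = f.create_group("participants")
        grp.create_dataset(
            "participant_id",
            data=np.array(part["participant_id"], dtype=h5py.string_dtype()),
        )
        grp.create_dataset(
            "group", data=np.array(part["group"], dtype=h5py.string_dtype())
        )
        grp.create_dataset("ability", data=part["ability"].to_numpy(dtype=float))

        if cohort.stimuli is not None:
            sgrp = f.create_group("stimuli")
            table = cohort.stimuli.table
            for col in table.columns:
                vals = table[col]
                if vals.dtype == object:
                    data = np.array(
                        ["" if v is None or v != v else str(v) for v in vals],
                        dtype=h5py.string_dtype(),
                    )
                else:
                    data = vals.to_numpy()
                sgrp.create_dataset(col, data=data)

        first = True
        for pid, es in cohort.epochs.items():
            g = f.create_group(pid)
            g.create_dataset("epochs", data=es.data, compression="gzip", compression_opts=1)
            tg = g.create_group("trials")
            for col in _TRIAL_COLS:
                tg.create_dataset(col, data=es.trials[col].to_numpy())
            if first:
                f.create_dataset("time_ms", data=es.times_ms)
                f.create_dataset("channels_xyz", data=es.channel_positions)
                f.create_dataset(
                    "channel_labels",
                    data=np.array(es.channel_labels, dtype=h5py.string_dtype()),
                )
                f.attrs["sfreq"] = es.sfreq
                first = False
        for pid, sched in cohort.schedules.items():
            if pid in cohort.epochs:
                continue
            g = f.require_group(pid)
            tg = g.create_group("trials")
            for col in _TRIAL_COLS:
                if col in sched.columns:
                    tg.create_dataset(col, data=sched[col].to_numpy())
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(cohort.meta, indent=2, default=str)
    )


def read_cohort(path) -> CohortDataset:
    path = Path(path)
    with h5py.File(path, "r") as f:
        part = pd.DataFrame(
            dict(
                participant_id=[s.decode() for s in f["participants/participant_id"][()]],
                group=[s.decode() for s in f["participants/group"][()]],
                ability=f["participants/ability"][()],
            )
        )
        stimuli = None
        if "stimuli" in f:
            cols = {}
            for col in f["stimuli"]:
                vals = f["stimuli"][col][()]
                if vals.dtype.kind in ("S", "O"):
                    vals = np.array(
                        [v.decode() if isinstance(v, bytes) else v for v in vals],
                        dtype=object,
                    )
                    vals = np.where(vals == "", None, vals)
                cols[col] = vals
            table = pd.DataFrame(cols)
            if "identity" in table:
                table["identity"] = pd.to_numeric(table["identity"], errors="coerce")
            stimuli = StimulusSet(table)

        epochs = {}
        schedules = {}
        for pid in part["participant_id"]:
            if pid not in f:
                continue
            g = f[pid]
            trials = pd.DataFrame({c: g["trials"][c][()] for c in g["trials"]})
            trials["is_repeat"] = trials["is_repeat"].astype(bool)
            trials["response_made"] = trials["response_made"].astype(bool)
            if "epochs" in g:
                epochs[pid] = EpochSet(
                    data=g["epochs"][()],
                    times_ms=f["time_ms"][()],
                    sfreq=float(f.attrs["sfreq"]),
                    channel_labels=[s.decode() for s in f["channel_labels"][()]],
                    channel_positions=f["channels_xyz"][()],
                    trials=trials,
                )
            else:
                schedules[pid] = trials
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return CohortDataset(
        participants=part, epochs=epochs, schedules=schedules, stimuli=stimuli, meta=meta
    )


def export_tables(cohort: CohortDataset, out_dir) -> list[Path]:
    """Write the stimulus and per-trial tables as TSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if cohort.stimuli is not None:
        p = out / "stimuli.tsv"
        cohort.stimuli.to_tsv(p)
        written.append(p)
    p = out / "trials.tsv"
    cohort.trial_table().to_csv(p, sep="\t", index=False)
    written.append(p)
    p = out / "participants.tsv"
    cohort.participants.to_csv(p, sep="\t", index=False)
    written.append(p)
    return written


def write_rdm(path, rdm) -> None:
    """Write an RDM as a square CSV (header row = stimulus ids) plus a JSON
    sidecar carrying the metric."""
    path = Path(path)
    df = pd.DataFrame(rdm.matrix, columns=[str(s) for s in rdm.stimulus_ids])
    df.to_csv(path, index=False)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps({"metric": rdm.metric, "stimulus_ids": [int(s) for s in rdm.stimulus_ids]})
    )


def read_rdm(path):
    """Read an RDM written by :func:`write_rdm`."""
    from .rdm import RDM

    path = Path(path)
    df = pd.read_csv(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return RDM(df.to_numpy(dtype=float), sidecar["metric"], np.asarray(sidecar["stimulus_ids"]))
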