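"""Serialization: HDF5 session bundles, JSON model documents, table exports.

Session bundle layout (HDF5)::

    attrs: session_id, task
    /units/unit_id, /units/cell_class          (string arrays)
    /trials/<field>                            (one dataset per trial field)
    /epochs                                    (n_trials x 4 onset times, s)
    /binned/values, /binned/bin_epoch, /binned/bin_centers_s
    /binned attrs: bin_width_ms, is_rate
    /spikes/t<i>/u<j>                          (optional ragged spike times)
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .model import EDLDSParams, EpochSchedule, FitTrace
from .session import (BinnedTensor, CellClass, SessionData, Task, TrialMeta,
                      TrialType, UnitMeta)

__all__ = ["save_session", "load_session", "save_model", "load_model"]

_TRIAL_FIELDS = ("trial_index", "trial_type", "correct", "early_lick",
                 "reaction_time_ms", "prev_outcome", "prev_choice",
                 "prev_stimulus", "prev_early_lick")


def save_session(session: SessionData, path):
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["session_id"] = session.session_id
        f.attrs["task"] = session.task.value
        g = f.create_group("units")
        g.create_dataset("unit_id", data=[u.unit_id for u in session.units])
        g.create_dataset("cell_class", data=[u.cell_class.value for u in session.units])
        g = f.create_group("trials")
        for fld in _TRIAL_FIELDS:
            vals = [getattr(t, fld) for t in session.trials]
            if fld == "trial_type":
                vals = [v.value for v in vals]
            elif fld == "reaction_time_ms":
                vals = [np.nan if v is None else float(v) for v in vals]
            elif fld in ("prev_outcome", "prev_choice", "prev_stimulus"):
                vals = ["" if v is None else str(v) for v in vals]
            elif fld == "prev_early_lick":
                vals = [-1 if v is None else int(v) for v in vals]
            g.create_dataset(fld, data=vals)
        f.create_dataset("epochs", data=session.epoch_times)
        if session.binned is not None:
            b = f.create_group("binned")
            b.create_dataset("values", data=session.binned.values)
            b.create_dataset("bin_epoch",
                             data=[str(x) for x in session.binned.bin_epoch])
            b.create_dataset("bin_centers_s", data=session.binned.bin_centers_s)
            b.attrs["bin_width_ms"] = session.binned.bin_width_ms
            b.attrs["is_rate"] = session.binned.is_rate
        if session.spikes is not None:
            sp = f.create_group("spikes")
            for i, tr in enumerate(session.spikes):
                gi = sp.create_group(f"t{i}")
                for j, st in enumerate(tr):
                    gi.create_dataset(f"u{j}", data=np.asarray(st, dtype=float))


def load_session(path) -> SessionData:
    with h5py.File(path, "r") as f:
        def _s(x):
            return x.decode() if isinstance(x, bytes) else str(x)

        units = [UnitMeta(unit_id=_s(uid), cell_class=CellClass(_s(cc)))
                 for uid, cc in zip(f["units/unit_id"][:], f["units/cell_class"][:])]
        g = f["trials"]
        n = len(g["trial_index"])
        trials = []
        for i in range(n):
            rt = float(g["reaction_time_ms"][i])
            pel = int(g["prev_early_lick"][i])
            trials.append(TrialMeta(
                trial_index=int(g["trial_index"][i]),
                trial_type=TrialType(_s(g["trial_type"][i])),
                correct=bool(g["correct"][i]),
                early_lick=bool(g["early_lick"][i]),
                reaction_time_ms=None if np.isnan(rt) else rt,
                prev_outcome=_s(g["prev_outcome"][i]),
                prev_choice=_s(g["prev_choice"][i]) or None,
                prev_stimulus=_s(g["prev_stimulus"][i]) or None,
                prev_early_lick=None if pel < 0 else bool(pel)))
        binned = None
        if "binned" in f:
            b = f["binned"]
            binned = BinnedTensor(
                values=b["values"][:],
                bin_width_ms=float(b.attrs["bin_width_ms"]),
                bin_epoch=np.asarray([_s(x) for x in b["bin_epoch"][:]]),
                bin_centers_s=b["bin_centers_s"][:],
                is_rate=bool(b.attrs["is_rate"]))
        spikes = None
        if "spikes" in f:
            spikes = []
            for i in range(n):
                gi = f[f"spikes/t{i}"]
                spikes.append([gi[f"u{j}"][:] for j in range(len(units))])
        return SessionData(session_id=_s(f.attrs["session_id"]),
                           task=Task(_s(f.attrs["task"])),
                           units=units, trials=trials,
                           epoch_times=f["epochs"][:],
                           spikes=spikes, binned=binned)


def save_model(params: EDLDSParams, schedule: EpochSchedule, path,
               trace: FitTrace | None = None, meta: dict | None = None):
    """JSON model document; round-trips exactly (float repr)."""
    doc = {
        "params": params.to_dict(),
        "schedule": {"last_bins": [int(b) for b in schedule.last_bins],
                     "labels": [str(l) for l in schedule.labels]},
        "meta": meta or {},
    }
    if trace is not None:
        doc["fit"] = {"logliks": [float(x) for x in trace.logliks],
                      "converged": bool(trace.converged),
                      "n_iter": int(trace.n_iter),
                      "seed": trace.seed}
    Path(path).write_text(json.dumps(doc))


def load_model(path):
    doc = json.loads(Path(path).read_text())
    params = EDLDSParams.from_dict(doc["params"])
    schedule = EpochSchedule(tuple(doc["schedule"]["last_bins"]),
                             tuple(doc["schedule"]["labels"]))
    return params, schedule, doc.get("meta", {}), doc.get("fit")
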