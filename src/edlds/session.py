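"""Trial-based population-recording sessions: containers, binning, screening,
and single-neuron trial-type selectivity.

A session holds simultaneously recorded units across trials of a delayed
two-alternative task with four behavioral epochs (pre-sample, sample, delay,
response).  Times are in seconds, aligned so the go cue (response-epoch
onset) is at 0.  The canonical observable is the binned firing rate in
non-overlapping 67-ms bins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .model import EpochSchedule, EPOCH_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "Task",
    "TrialType",
    "CellClass",
    "UnitMeta",
    "TrialMeta",
    "SessionData",
    "BinnedTensor",
    "SelectivityProfile",
    "TASK_EPOCH_DURATIONS",
    "bin_session",
    "screen_sessions",
    "classify_selectivity",
]


class Task(str, Enum):
    pole = "pole"
    sound = "sound"


class TrialType(str, Enum):
    contra = "contra"
    ipsi = "ipsi"


class CellClass(str, Enum):
    pyramidal = "pyramidal"
    interneuron = "interneuron"
    unknown = "unknown"


# sample/delay durations are task-variant constants; pre-sample and response
# are analysis-window choices (see docs/methods.md)
TASK_EPOCH_DURATIONS = {
    Task.pole: {"pre_sample": 0.8, "sample": 1.3, "delay": 1.3, "response": 1.0},
    Task.sound: {"pre_sample": 0.8, "sample": 1.15, "delay": 2.0, "response": 1.0},
}


@dataclass(frozen=True)
class UnitMeta:
    unit_id: str
    cell_class: CellClass = CellClass.unknown


@dataclass(frozen=True)
class TrialMeta:
    trial_index: int
    trial_type: TrialType
    correct: bool
    early_lick: bool = False
    reaction_time_ms: float | None = None
    prev_outcome: str = "none"          # rewarded | unrewarded | none
    prev_choice: str | None = None
    prev_stimulus: str | None = None
    prev_early_lick: bool | None = None


@dataclass
class BinnedTensor:
    """Binned activity: ``values`` is (trials, neurons, bins) of firing rate
    (spikes/s) or counts, on one shared bin grid."""

    values: np.ndarray
    bin_width_ms: float
    bin_epoch: np.ndarray              # per-bin epoch label (str)
    bin_centers_s: np.ndarray
    is_rate: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.bin_epoch = np.asarray(self.bin_epoch)
        self.bin_centers_s = np.asarray(self.bin_centers_s, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be trials x neurons x bins")
        if self.values.shape[2] != len(self.bin_epoch):
            raise ValueError("bin_epoch length must match number of bins")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("binned values must be finite")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.values.shape[1]

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]

    def schedule(self) -> EpochSchedule:
        return EpochSchedule.from_bin_epochs(self.bin_epoch)

    def model_array(self) -> np.ndarray:
        """(trials, bins, neurons) view for the state-space routines."""
        return np.transpose(self.values, (0, 2, 1))

    def bins_in_epoch(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.bin_epoch == label)

    def subset_trials(self, idx) -> "BinnedTensor":
        return BinnedTensor(self.values[idx], self.bin_width_ms,
                            self.bin_epoch, self.bin_centers_s, self.is_rate)


@dataclass
class SessionData:
    session_id: str
    task: Task
    units: list
    trials: list
    epoch_times: np.ndarray            # (n_trials, 4) epoch onsets, s rel. go cue
    spikes: list | None = None         # per trial: list per unit of spike-time arrays
    binned: BinnedTensor | None = None

    def __post_init__(self):
        self.epoch_times = np.asarray(self.epoch_times, dtype=float)
        if self.epoch_times.shape != (len(self.trials), 4):
            raise ValueError("epoch_times must be (n_trials, 4)")
        if np.any(np.diff(self.epoch_times, axis=1) <= 0):
            raise ValueError("epoch onsets must be strictly increasing per trial")
        idx = [t.trial_index for t in self.trials]
        # unique and increasing; subsets of a session keep their original
        # ordinal positions so temporal-order analyses stay meaningful
        if len(set(idx)) != len(idx) or any(a >= b for a, b in zip(idx, idx[1:])):
            raise ValueError("trial_index must be unique and increasing")

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def trial_types(self) -> np.ndarray:
        return np.array([t.trial_type.value for t in self.trials])

    def correct_mask(self) -> np.ndarray:
        return np.array([t.correct for t in self.trials], dtype=bool)

    def early_lick_mask(self) -> np.ndarray:
        return np.array([t.early_lick for t in self.trials], dtype=bool)

    def subset(self, idx) -> "SessionData":
        idx = np.atleast_1d(np.asarray(idx))
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        trials = [self.trials[i] for i in idx]
        # reindex to keep trial_index contiguous while preserving order info
        return SessionData(
            session_id=self.session_id,
            task=self.task,
            units=self.units,
            trials=trials,
            epoch_times=self.epoch_times[idx],
            spikes=[self.spikes[i] for i in idx] if self.spikes is not None else None,
            binned=self.binned.subset_trials(idx) if self.binned is not None else None,
        )


@dataclass
class SelectivityProfile:
    """Per-neuron, per-bin contra-vs-ipsi test results and the derived
    selectivity category."""

    p_values: np.ndarray               # (neurons, bins), NaN when undefined
    preferred_side: np.ndarray         # (neurons, bins), +1 contra, -1 ipsi, 0 none
    category: list                     # per neuron: nonselective | contra_monophasic
                                       # | ipsi_monophasic | multiphasic

    def to_frame(self):
        import pandas as pd

        n, b = self.p_values.shape
        return pd.DataFrame({
            "neuron": np.repeat(np.arange(n), b),
            "bin": np.tile(np.arange(b), n),
            "p_value": self.p_values.ravel(),
            "preferred_side": self.preferred_side.ravel(),
            "category": np.repeat(self.category, b),
        })


# ---------------------------------------------------------------------------

def _bin_grid(task: Task, bin_width_ms: float):
    dur = TASK_EPOCH_DURATIONS[task]
    w = bin_width_ms / 1000.0
    counts = [max(1, round(dur[e] / w)) for e in EPOCH_NAMES]
    # anchor the grid at the go cue: a bin edge falls exactly at t = 0
    n_before = sum(counts[:3])
    edges = w * (np.arange(sum(counts) + 1) - n_before)
    labels = np.repeat(list(EPOCH_NAMES), counts)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return edges, labels, centers


def bin_session(session: SessionData, bin_width_ms: float = 67.0,
                sliding: dict | None = None) -> BinnedTensor:
    """Bin spike times into firing rates on the session's epoch grid.

    Default: non-overlapping bins (67 ms).  ``sliding={'window_ms': 250,
    'step_ms': 10}`` gives the overlapping smoothing-control variant.  Spike
    times outside the trial window are dropped (counted in a log message);
    a trial with no spike data at all raises.
    """
    if session.spikes is None:
        if session.binned is not None and session.binned.bin_width_ms == bin_width_ms \
                and sliding is None:
            return session.binned
        raise ValueError("session has no spike times to bin")
    edges, labels, centers = _bin_grid(session.task, bin_width_ms)
    if sliding is not None:
        w = sliding["window_ms"] / 1000.0
        step = sliding["step_ms"] / 1000.0
        t0, t1 = edges[0], edges[-1]
        starts = np.arange(t0, t1 - w + 1e-9, step)
        centers = starts + w / 2
        # label each sliding bin by the epoch containing its center
        nonover_edges = edges
        idx = np.clip(np.searchsorted(nonover_edges, centers, side="right") - 1,
                      0, len(labels) - 1)
        labels = labels[idx]
        width = w
    else:
        starts = edges[:-1]
        width = bin_width_ms / 1000.0

    n_tr, n_un, n_bins = session.n_trials, session.n_units, len(starts)
    values = np.zeros((n_tr, n_un, n_bins))
    dropped = 0
    for i in range(n_tr):
        tr = session.spikes[i]
        if len(tr) != n_un:
            raise ValueError(f"trial {i} has no spike data for every unit")
        for u in range(n_un):
            st = np.asarray(tr[u], dtype=float)
            inside = (st >= edges[0]) & (st < edges[-1])
            dropped += int((~inside).sum())
            st = st[inside]
            if sliding is not None:
                for b, s0 in enumerate(starts):
                    values[i, u, b] = np.count_nonzero((st >= s0) & (st < s0 + width))
            else:
                values[i, u], _ = np.histogram(st, bins=edges)
    if dropped:
        logger.info("bin_session: dropped %d spikes outside the trial window", dropped)
    values = values / width                      # rate in spikes/s
    return BinnedTensor(values=values, bin_width_ms=(sliding["window_ms"] if sliding
                                                     else bin_width_ms),
                        bin_epoch=np.asarray(labels), bin_centers_s=centers)


def screen_sessions(sessions: list) -> tuple[list, list]:
    """Apply the study's inclusion rule.

    Early-lick trials are removed first; a session is then kept iff it has
    more than 5 units and strictly more than twice as many correct trials as
    units.  Returns ``(kept_sessions, report)`` where the report lists one
    dict per input session.
    """
    kept, report = [], []
    for sess in sessions:
        no_early = sess.subset(~sess.early_lick_mask()) if sess.early_lick_mask().any() else sess
        n_correct = int(no_early.correct_mask().sum())
        ok = no_early.n_units > 5 and n_correct > 2 * no_early.n_units
        report.append({
            "session_id": sess.session_id,
            "n_units": no_early.n_units,
            "n_correct": n_correct,
            "n_early_lick_removed": int(sess.early_lick_mask().sum()),
            "kept": bool(ok),
        })
        if ok:
            kept.append(no_early)
    return kept, report


def classify_selectivity(tensor: BinnedTensor, labels, equal_var: bool = True,
                         alpha: float = 0.05, min_run: int = 5) -> SelectivityProfile:
    """Per-bin contra-vs-ipsi two-sample t-tests and the run-length rule.

    A neuron is monophasic if it holds the same sign of significant
    (p < alpha) selectivity for at least ``min_run`` consecutive bins
    (5 bins of 67 ms > 335 ms), multiphasic if it shows significant runs of
    both signs each at least ``min_run`` bins long, otherwise nonselective.
    No multiple-comparison correction is applied; the consecutive-bin
    requirement takes its place.
    """
    labels = np.asarray([l.value if isinstance(l, TrialType) else str(l) for l in labels])
    contra = tensor.values[labels == "contra"]
    ipsi = tensor.values[labels == "ipsi"]
    n_neur, n_bins = tensor.n_neurons, tensor.n_bins
    p = np.full((n_neur, n_bins), np.nan)
    side = np.zeros((n_neur, n_bins))
    if len(contra) < 2 or len(ipsi) < 2:
        warnings.warn("fewer than 2 trials in a trial type; selectivity undefined")
        return SelectivityProfile(p, side, ["nonselective"] * n_neur)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(contra, ipsi, axis=0, equal_var=equal_var)
    p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    diff = contra.mean(axis=0) - ipsi.mean(axis=0)
    side = np.sign(diff)

    category = []
    for i in range(n_neur):
        sig = p[i] < alpha
        runs = _signed_runs(sig, side[i])
        long_runs = [sgn for sgn, length in runs if length >= min_run]
        if not long_runs:
            category.append("nonselective")
        elif len(set(long_runs)) == 1:
            category.append("contra_monophasic" if long_runs[0] > 0 else "ipsi_monophasic")
        else:
            category.append("multiphasic")
    return SelectivityProfile(np.asarray(p), np.asarray(side), category)


def _signed_runs(sig, sign):
    """Maximal runs of significant bins with constant sign -> [(sign, len)]."""
    runs = []
    cur_sign, cur_len = 0, 0
    for s_flag, s_sign in zip(sig, sign):
        if s_flag and s_sign != 0:
            if s_sign == cur_sign:
                cur_len += 1
            else:
                if cur_len:
                    runs.append((cur_sign, cur_len))
                cur_sign, cur_len = s_sign, 1
        else:
            if cur_len:
                runs.append((cur_sign, cur_len))
            cur_sign, cur_len = 0, 0
    if cur_len:
        runs.append((cur_sign, cur_len))
    return runs
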