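"""Population FRET-vs-time heatmaps, synchronized or raw.

Transition synchronization shifts each trace so t = 0 at its folded-band
entry (the helicase-mode convention); flow synchronization uses the enzyme
arrival time; ``none`` overlays raw time axes (the exonuclease-mode
convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .stepkin import FoldingCall, ONE_STEP, MULTI_STEP, PREFOLDED
from .traceproc import FretTrace

SYNC_MODES = ("transition", "flow", "none")


@dataclass
class AlignedSamples:
    """Pooled (time, FRET) samples after per-trace time shifting."""

    times: np.ndarray
    frets: np.ndarray
    n_traces: int
    n_dropped: int
    sync_mode: str


@dataclass
class Heatmap:
    time_edges: np.ndarray
    fret_edges: np.ndarray
    counts: np.ndarray       # shape (n_fret_bins, n_time_bins)
    n_traces: int
    sync_mode: str

    def column_normalized(self) -> np.ndarray:
        """Counts normalized to unit maximum per time column (display)."""
        out = self.counts.astype(float).copy()
        colmax = out.max(axis=0)
        nz = colmax > 0
        out[:, nz] /= colmax[nz]
        return out


def align_traces(traces: Iterable[FretTrace],
                 calls: Optional[dict] = None,
                 sync_mode: str = "transition",
                 t_arrival: float = 0.0) -> AlignedSamples:
    """Shift each trace's time axis so t = 0 at the chosen event.

    ``transition`` requires a folded :class:`FoldingCall` per molecule (in
    ``calls``, keyed by molecule id); traces lacking the event are dropped
    and counted.  ``flow`` subtracts the enzyme arrival time; ``none`` is
    the identity.
    """
    if sync_mode not in SYNC_MODES:
        raise ValueError(f"unknown sync_mode {sync_mode!r}")
    t_all, e_all = [], []
    n_used = n_dropped = 0
    for tr in traces:
        if tr.donor_only or len(tr) == 0:
            n_dropped += 1
            continue
        if sync_mode == "transition":
            call = (calls or {}).get(tr.molecule_id)
            if call is None or call.call not in (ONE_STEP, MULTI_STEP,
                                                 PREFOLDED) \
                    or not np.isfinite(call.t_fold_s):
                n_dropped += 1
                continue
            shift = call.t_fold_s
        elif sync_mode == "flow":
            shift = t_arrival
        else:
            shift = 0.0
        t_all.append(tr.time_s - shift)
        e_all.append(tr.E)
        n_used += 1
    if n_used == 0:
        raise ValueError("no traces left after alignment")
    return AlignedSamples(times=np.concatenate(t_all),
                          frets=np.concatenate(e_all),
                          n_traces=n_used, n_dropped=n_dropped,
                          sync_mode=sync_mode)


def make_heatmap(aligned: AlignedSamples,
                 time_edges: Optional[np.ndarray] = None,
                 fret_edges: Optional[np.ndarray] = None) -> Heatmap:
    """2-D occupancy counts of the aligned samples (FRET rows, time cols).

    Default grid: 0.2 s time bins spanning the aligned data, 0.02 FRET bins
    on [-0.1, 1.1].
    """
    if aligned.n_traces < 1:
        raise ValueError("need at least one aligned trace")
    if time_edges is None:
        lo = np.floor(aligned.times.min() / 0.2) * 0.2
        hi = np.ceil(aligned.times.max() / 0.2) * 0.2 + 0.2
        time_edges = np.arange(lo, hi + 1e-9, 0.2)
    if fret_edges is None:
        fret_edges = np.arange(-0.1, 1.1 + 1e-9, 0.02)
    counts, _, _ = np.histogram2d(aligned.frets, aligned.times,
                                  bins=[fret_edges, time_edges])
    return Heatmap(time_edges=np.asarray(time_edges),
                   fret_edges=np.asarray(fret_edges),
                   counts=counts, n_traces=aligned.n_traces,
                   sync_mode=aligned.sync_mode)
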