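"""Trace-level preprocessing: apparent FRET, ALEX donor-only exclusion,
donor-leakage estimation/correction and photobleach truncation.

FRET efficiency is the uncorrected proximity ratio ``E = I_A / (I_D + I_A)``;
no gamma (detection-efficiency) or direct-excitation corrections are applied.
Leakage is estimated per dataset from donor-only molecules and removed at the
intensity level (``I_A_corr = I_A - l * I_D``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .simulator import IntensityTrace

#: red-excitation acceptor counts below this flag a dark acceptor
RED_THRESHOLD_DEFAULT = 200.0
#: donor bleach: total green intensity below this fraction of its initial
#: median for >= BLEACH_MIN_FRAMES consecutive green frames
BLEACH_FRACTION = 0.25
BLEACH_MIN_FRAMES = 5


@dataclass
class FretTrace:
    """Cleaned per-molecule FRET time series (green-excitation frames only)."""

    molecule_id: str
    time_s: np.ndarray
    E: np.ndarray
    donor_only: bool = False
    bleach_time_s: Optional[float] = None
    leakage_l: float = 0.0
    frame_s: float = 0.1

    def __len__(self):
        return len(self.time_s)


def apparent_fret(I_D, I_A):
    """Proximity ratio I_A / (I_D + I_A); NaN where the total signal is zero."""
    I_D = np.asarray(I_D, float)
    I_A = np.asarray(I_A, float)
    total = I_D + I_A
    with np.errstate(invalid="ignore", divide="ignore"):
        E = np.where(total > 0, I_A / np.where(total > 0, total, 1.0), np.nan)
    if E.ndim == 0:
        return float(E)
    return E


def detect_donor_only(trace: IntensityTrace,
                      red_threshold: float = RED_THRESHOLD_DEFAULT,
                      n_blocks: int = 2) -> bool:
    """True iff the median red-excitation acceptor signal is below threshold.

    Only the first ``n_blocks`` red-excitation blocks (ALEX cycles) are
    used, so a molecule whose acceptor photobleaches mid-trace is not
    mistaken for one that never had an acceptor.  Requires alternating-laser
    excitation: raises if the trace carries no red-excitation frames.
    """
    red = trace.red()
    if not red.any():
        raise ValueError("donor-only detection requires red-excitation frames")
    t_r = trace.time_s[red]
    starts = np.nonzero(np.diff(t_r, prepend=-np.inf) >
                        1.5 * trace.frame_s)[0]
    stop = starts[n_blocks] if len(starts) > n_blocks else len(t_r)
    return bool(np.median(trace.I_A[red][:stop]) < red_threshold)


def estimate_leakage(donor_only_traces: Iterable[IntensityTrace]) -> float:
    """Leakage fraction l from the apparent FRET of donor-only molecules.

    With no acceptor, the measured acceptor channel holds only leakage, so
    the mean apparent FRET E0 satisfies l = E0 / (1 - E0).  Only green
    frames with appreciable donor signal (pre donor-bleach) contribute.
    """
    pooled = []
    for tr in donor_only_traces:
        g = tr.green()
        I_D, I_A = tr.I_D[g], tr.I_A[g]
        total = I_D + I_A
        alive = total > 0.25 * np.median(total[:10])
        E = apparent_fret(I_D[alive], I_A[alive])
        pooled.append(E[np.isfinite(E)])
    if not pooled or sum(len(p) for p in pooled) == 0:
        raise ValueError("need at least one donor-only trace")
    E0 = float(np.mean(np.concatenate(pooled)))
    if E0 >= 1.0:
        raise ValueError("mean donor-only FRET >= 1 is impossible")
    return max(E0 / (1.0 - E0), 0.0)


def _first_run_at_least(mask: np.ndarray, run: int) -> int:
    """Index where the first run of ``run`` consecutive True begins, or -1."""
    if len(mask) < run:
        return -1
    conv = np.convolve(mask.astype(int), np.ones(run, int), mode="valid")
    hits = np.nonzero(conv == run)[0]
    return int(hits[0]) if len(hits) else -1


def correct_and_extract(trace: IntensityTrace, l: float,
                        red_threshold: float = RED_THRESHOLD_DEFAULT,
                        donor_only: Optional[bool] = None) -> FretTrace:
    """Leakage-corrected FRET series with photobleached frames dropped.

    Donor bleach is called at the first sustained collapse of the corrected
    total green intensity below ``BLEACH_FRACTION`` of its initial median;
    acceptor bleach is called from the red-excitation blocks (ALEX), with the
    truncation placed one ALEX cycle before the first dark red block so that
    no post-bleach green frames (which would masquerade as a low-FRET state)
    survive.  Donor-only traces carry no samples downstream.
    """
    if not 0.0 <= l < 0.3:
        raise ValueError("leakage must lie in [0, 0.3)")
    if donor_only is None:
        try:
            donor_only = detect_donor_only(trace, red_threshold)
        except ValueError:
            donor_only = False

    g = trace.green()
    t_g = trace.time_s[g]
    I_D = trace.I_D[g].astype(float)
    I_A_corr = np.maximum(trace.I_A[g] - l * I_D, 0.0)
    total = I_D + I_A_corr

    if donor_only:
        return FretTrace(molecule_id=trace.molecule_id,
                         time_s=np.empty(0), E=np.empty(0), donor_only=True,
                         bleach_time_s=None, leakage_l=l,
                         frame_s=trace.frame_s)

    bleach_time: Optional[float] = None
    if len(total):
        init = np.median(total[:min(len(total), 10)])
        idx = _first_run_at_least(total < BLEACH_FRACTION * init,
                                  BLEACH_MIN_FRAMES)
        if idx >= 0:
            bleach_time = float(t_g[idx])

    red = trace.red()
    if red.any():
        t_r = trace.time_s[red]
        I_r = trace.I_A[red]
        # group red frames into ALEX blocks and call the acceptor dark at
        # the first block whose median signal is below threshold; truncate
        # a full cycle earlier so no post-bleach green frame can survive
        starts = np.nonzero(np.diff(t_r, prepend=-np.inf) >
                            1.5 * trace.frame_s)[0]
        edges = np.append(starts, len(t_r))
        cycle_s = float(np.median(np.diff(t_r[starts]))) \
            if len(starts) > 1 else trace.frame_s * 21
        for a, b in zip(edges[:-1], edges[1:]):
            if np.median(I_r[a:b]) < red_threshold:
                t_acc = max(float(t_r[a]) - cycle_s, 0.0)
                bleach_time = t_acc if bleach_time is None \
                    else min(bleach_time, t_acc)
                break

    keep = np.ones(len(t_g), bool)
    if bleach_time is not None:
        keep &= t_g < bleach_time
    if red.any():
        # frames after the last red block carry no acceptor verification:
        # a bleach there would be undetectable, so drop them
        keep &= t_g < trace.time_s[red][-1]

    with np.errstate(invalid="ignore", divide="ignore"):
        E = np.where(total > 0, I_A_corr / np.where(total > 0, total, 1.0),
                     np.nan)
    E = np.clip(E, -0.05, 1.05)
    ok = keep & np.isfinite(E)
    return FretTrace(molecule_id=trace.molecule_id, time_s=t_g[ok], E=E[ok],
                     donor_only=False, bleach_time_s=bleach_time,
                     leakage_l=l, frame_s=trace.frame_s)


def process_cohort(traces: Iterable[IntensityTrace],
                   red_threshold: float = RED_THRESHOLD_DEFAULT,
                   leakage: Optional[float] = None) -> tuple:
    """Full preprocessing of a cohort of intensity traces.

    Classifies donor-only molecules, estimates the dataset leakage from them
    (unless ``leakage`` is given), and returns ``(fret_traces, qc_table)``
    where ``fret_traces`` excludes donor-only molecules.
    """
    import pandas as pd

    traces = list(traces)
    flags = []
    for tr in traces:
        try:
            flags.append(detect_donor_only(tr, red_threshold))
        except ValueError:
            flags.append(False)
    if leakage is None:
        donly = [tr for tr, f in zip(traces, flags) if f]
        leakage = estimate_leakage(donly) if donly else 0.0
    out, rows = [], []
    for tr, f in zip(traces, flags):
        ft = correct_and_extract(tr, leakage, red_threshold, donor_only=f)
        rows.append(dict(molecule_id=tr.molecule_id, donor_only=f,
                         bleach_time_s=ft.bleach_time_s, leakage_l=leakage,
                         n_samples=len(ft)))
        if not f:
            out.append(ft)
    return out, pd.DataFrame(rows)
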