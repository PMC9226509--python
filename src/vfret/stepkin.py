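"""Step-finding and kinetics: trace idealization, folding-pathway
classification, dwell-time and bound-fraction exponential fits.

Idealization is penalized least-squares segmentation into piecewise-constant
levels (optimal-partitioning dynamic program, L2 cost) — deterministic for
fixed inputs.  Classification matches segment means against a preset's FRET
levels with a +-0.07 tolerance band: the folding dwell runs from full strand
release (end of the unwinding ramp, i.e. entry into the single-strand
plateau) to the first entry into the band of the molecule's final conformer;
transitions strictly between those levels count as folding intermediates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .presets import KineticPreset
from .traceproc import FretTrace

#: half-width of the FRET tolerance band around preset levels
BAND = 0.07
#: segment means below this are "bound" (midpoint between the bound level
#: 0.30 and the lowest folded level in use)
BOUND_THRESHOLD = 0.45

ONE_STEP = "one_step"
MULTI_STEP = "multi_step"
NO_FOLD = "no_fold"
PREFOLDED = "prefolded"


@dataclass
class ChangePointSet:
    """Piecewise-constant idealization of one FRET trace."""

    molecule_id: str
    breakpoints: np.ndarray       # sample indices where new segments start
    segment_means: np.ndarray
    time_s: np.ndarray            # sample times the indices refer to
    penalty: float
    values: Optional[np.ndarray] = None   # the segmented samples

    @property
    def n_segments(self) -> int:
        return len(self.segment_means)

    def segments(self):
        """Yield (t_start, t_end, mean) per segment.

        Interior boundaries are placed midway between the last sample of one
        segment and the first sample of the next, which keeps event times
        unbiased when a transition falls inside a dark/red excitation gap.
        """
        t = self.time_s
        bounds = np.concatenate([[0], self.breakpoints,
                                 [len(t)]]).astype(int)
        half = (t[1] - t[0]) / 2.0 if len(t) > 1 else 0.0
        for a, b, m in zip(bounds[:-1], bounds[1:], self.segment_means):
            t0 = float(t[a]) if a == 0 else float(0.5 * (t[a - 1] + t[a]))
            t1 = float(t[-1]) + half if b == len(t) else \
                float(0.5 * (t[b - 1] + t[b]))
            yield t0, t1, float(m)


@dataclass
class FoldingCall:
    molecule_id: str
    n_steps: int
    call: str                      # one_step | multi_step | no_fold | prefolded
    dwell_s: float = math.nan      # full release -> folded-band entry
    t_fold_s: float = math.nan
    t_release_s: float = math.nan
    final_level: float = math.nan
    ramp_end_s: float = math.nan


@dataclass
class RateFit:
    rate: float                    # s^-1
    amplitude: float = 1.0
    stderr: float = math.nan
    amplitude_stderr: float = math.nan
    n: int = 0
    method: str = "dwell_exp"
    converged: bool = True
    plateau_reached: bool = True


# ---------------------------------------------------------------------------
# change-point detection
# ---------------------------------------------------------------------------

def estimate_noise_sd(x: np.ndarray) -> float:
    """Robust per-sample noise from median absolute first differences."""
    if len(x) < 3:
        return 0.0
    d = np.diff(x)
    return float(1.4826 * np.median(np.abs(d)) / math.sqrt(2.0))


#: multiplier for the automatic segmentation penalty (x sigma^2 log n)
PENALTY_SCALE = 3.0


def detect_changepoints(trace: FretTrace, penalty: Optional[float] = None,
                        min_segment_frames: int = 2) -> ChangePointSet:
    """Optimal-partitioning segmentation with an L2 cost and linear penalty.

    Minimizes ``sum_j SSE(segment_j) + penalty * (#segments - 1)`` over all
    partitions with segments of at least ``min_segment_frames`` samples.
    ``penalty=None`` uses ``PENALTY_SCALE * sigma^2 * log(n)`` with a robust
    noise estimate (floored so noiseless traces segment exactly).
    """
    x = np.asarray(trace.E, float)
    n = len(x)
    m = max(int(min_segment_frames), 1)
    if n < 2 * m:
        return ChangePointSet(trace.molecule_id, np.empty(0, int),
                              np.array([np.mean(x)] if n else []),
                              np.asarray(trace.time_s), 0.0, x)
    if penalty is None:
        sd = estimate_noise_sd(x)
        penalty = max(PENALTY_SCALE * sd * sd * math.log(n), 1e-12)

    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    F = np.full(n + 1, np.inf)
    F[0] = -penalty
    last = np.zeros(n + 1, int)
    valid = np.zeros(n + 1, bool)
    valid[0] = True
    for j in range(m, n + 1):
        i = np.nonzero(valid[:j - m + 1])[0]
        length = j - i
        sse = (s2[j] - s2[i]) - (s1[j] - s1[i]) ** 2 / length
        tot = F[i] + sse + penalty
        k = int(np.argmin(tot))
        F[j] = tot[k]
        last[j] = i[k]
        valid[j] = True

    # backtrack
    bounds = [n]
    j = n
    while j > 0:
        j = last[j]
        bounds.append(j)
    bounds = np.array(bounds[::-1])
    bps = bounds[1:-1]
    means = np.array([(s1[b] - s1[a]) / (b - a)
                      for a, b in zip(bounds[:-1], bounds[1:])])
    return ChangePointSet(trace.molecule_id, bps.astype(int), means,
                          np.asarray(trace.time_s), float(penalty), x)


# ---------------------------------------------------------------------------
# pathway classification
# ---------------------------------------------------------------------------

def _in_band(value: float, level: float, band: float = BAND) -> bool:
    return abs(value - level) <= band


def _matched_boundary(x: np.ndarray, tt: np.ndarray, left: float,
                      right: float, sigma: float, dead_level: float = None,
                      dead_band: float = BAND):
    """Best split of samples ``x`` into a ``left``-level prefix and a
    ``right``-level suffix, with both levels fixed.

    Returns ``(t_boundary, b)`` where ``b`` is the first right-side sample
    index (``b == len(x)`` if no right side is supported).  Near-ties are
    broken toward the latest boundary with a margin proportional to the
    noise, which cancels the early-boundary drift noise otherwise induces.
    ``dead_level``: samples beyond this level (away from ``left``) carry no
    evidence and vote zero — used to ignore frames already transitioning
    toward a further level.
    """
    votes = (x - left) ** 2 - (x - right) ** 2
    if dead_level is not None:
        away = np.sign(dead_level - left) * (x - dead_level)
        votes[away > dead_band] = 0.0
    suffix = np.concatenate([np.cumsum(votes[::-1])[::-1], [0.0]])
    eps = TIEBREAK_SCALE * abs(right - left) * sigma
    b = int(np.nonzero(suffix >= suffix.max() - eps)[0].max())
    if b == len(x):
        return None, b
    t = float(tt[b]) if b == 0 else float(0.5 * (tt[b - 1] + tt[b]))
    return t, b


#: chain-rescue acceptance threshold, in units of the per-sample variance
CHAIN_RESCUE_THRESHOLD = 15.0
#: late-boundary tie-break margin of the matched step filters, in units of
#: (level gap x per-sample noise); cancels the early-boundary noise drift
TIEBREAK_SCALE = 1.5


def _chain_rescue_gain(x: np.ndarray, levels: tuple, min_int: int = 2
                       ) -> float:
    """SSE improvement of the duplex->ss->intermediate->final level chain
    over the chain without the intermediate run (all levels fixed).

    Used to rescue short folding intermediates that free-mean segmentation
    smooths over; a large positive gain means the data demand a visit to
    the intermediate level of at least ``min_int`` frames.
    """
    Ed, Es, Ei, Ef = levels
    m = len(x)
    if m < min_int + 2:
        return 0.0
    Pd = np.concatenate([[0.0], np.cumsum((x - Ed) ** 2)])
    Ps = np.concatenate([[0.0], np.cumsum((x - Es) ** 2)])
    Pi = np.concatenate([[0.0], np.cumsum((x - Ei) ** 2)])
    Pf = np.concatenate([[0.0], np.cumsum((x - Ef) ** 2)])
    Amin = np.minimum.accumulate(Pd - Ps)
    Bmin = np.minimum.accumulate(Amin + Ps - Pi)
    cost2 = float(np.min(Amin + Ps - Pf) + Pf[m])
    c2 = np.arange(min_int, m + 1)
    cost3 = float(np.min(Bmin[c2 - min_int] + Pi[c2] - Pf[c2]) + Pf[m])
    return cost2 - cost3


def classify_folding(cps: ChangePointSet, preset: KineticPreset,
                     band: float = BAND) -> FoldingCall:
    """Classify one idealized trace against the preset's FRET levels.

    The final folded level is the conformer matched by the last segment
    lying in any conformer band; the folding dwell runs from entry into the
    last single-strand-band segment (ramp completion) to the first segment
    in the final conformer's band.  Distinct upward levels strictly between
    the single-strand level and the final level (by more than ``band``)
    count as intermediate steps.  Traces that never reach a conformer band
    (e.g. bleached early) are ``no_fold``; traces that start inside one are
    ``prefolded``.
    """
    segs = list(cps.segments())
    mol = cps.molecule_id
    if not segs:
        return FoldingCall(mol, 0, NO_FOLD)
    confs = preset.conformer_means

    def conf_match(mean, i=None):
        # The intermediate level competes as a decoy: a segment closer to it
        # than to every conformer is a folding intermediate, not a fold —
        # unless the segment is followed by a persistent bound-band tail
        # (irreversible ligand capture proves the fold completed).
        d = [abs(mean - c) for c in confs]
        k = int(np.argmin(d))
        if d[k] > band:
            return None
        if preset.p_multistep > 0 and \
                abs(mean - preset.E_intermediate) < d[k]:
            bound_tail = i is not None and i + 1 < len(segs) and \
                all(s[2] < BOUND_THRESHOLD for s in segs[i + 1:])
            if not bound_tail:
                return None
        return k

    if conf_match(segs[0][2], 0) is not None:
        lvl = confs[conf_match(segs[0][2], 0)]
        return FoldingCall(mol, 0, PREFOLDED, t_fold_s=segs[0][0],
                           final_level=lvl, dwell_s=math.nan)

    matched = [i for i, s in enumerate(segs)
               if conf_match(s[2], i) is not None]
    if not matched:
        return FoldingCall(mol, 0, NO_FOLD)
    final_level = confs[conf_match(segs[matched[-1]][2], matched[-1])]

    # first entry into the band of the final level
    fold_idx = next(i for i, s in enumerate(segs)
                    if _in_band(s[2], final_level, band))
    t_fold = segs[fold_idx][0]

    # intermediate steps: departures strictly between ss and final levels.
    # A run must hold at least two samples near the intermediate level
    # itself — a frame that integrates across the fold transition pairs
    # with a neighbour into a spurious between-levels segment otherwise.
    seg_bounds = np.concatenate([[0], cps.breakpoints,
                                 [len(cps.time_s)]]).astype(int)
    lo = preset.E_ss + band
    hi = final_level - band
    inter = []
    for i in range(fold_idx):
        mean = segs[i][2]
        if lo < mean < hi and not _in_band(mean, preset.E_duplex, band) \
                and not _in_band(mean, preset.E_ss, band):
            if cps.values is not None:
                sx = np.asarray(cps.values[seg_bounds[i]:seg_bounds[i + 1]])
                if np.sum(np.abs(sx - preset.E_intermediate) <= band) < 2:
                    continue
            inter.append(i)

    # Boundary refinement by matched two-level step fits with the preset's
    # levels held fixed: immune to the level-merging ambiguity of free-mean
    # segmentation and resolves plateaus down to a single frame.
    bounds = np.concatenate([[0], cps.breakpoints,
                             [len(cps.time_s)]]).astype(int)
    t_release, dwell = math.nan, math.nan
    if cps.values is not None and len(cps.values):
        xs = np.asarray(cps.values, float)
        ts = np.asarray(cps.time_s, float)
        sigma = estimate_noise_sd(xs)

        # fold entry: pre-fold level (ss, or the intermediate when one was
        # visited) -> final conformer level
        sf = bounds[fold_idx]
        w0, w1 = max(0, sf - 30), min(len(xs), sf + 30)
        pre_level = preset.E_intermediate if inter else preset.E_ss
        t_mf, _ = _matched_boundary(xs[w0:w1].copy(), ts[w0:w1],
                                    pre_level, final_level, sigma)
        if t_mf is not None:
            t_fold = t_mf

        # ramp completion: duplex -> single-strand plateau, on the samples
        # before the fold (or first intermediate) transition
        stop = bounds[inter[0]] if inter else \
            int(np.searchsorted(ts, t_fold))
        s0 = max(0, stop - 60)
        if stop > s0:
            left = preset.E_duplex
            if preset.mode == "vf_exo" and preset.pife_factor > 1:
                # the level just before release is the digestion endpoint
                # seen through PIFE (donor boosted, apparent FRET lowered)
                e = preset.E_ss
                left = e / (preset.pife_factor * (1 - e) + e)
            t_rel, b = _matched_boundary(
                xs[s0:stop].copy(), ts[s0:stop], left,
                preset.E_ss, sigma, dead_level=preset.E_ss, dead_band=band)
            if t_rel is None:
                # no resolvable plateau before the next transition
                t_release = segs[inter[0]][0] if inter else t_fold
            else:
                t_release = t_rel
            dwell = max(t_fold - t_release, 0.0)
    # merge adjacent qualifying segments into distinct steps
    n_inter = 0
    prev = None
    for i in inter:
        if prev is None or i != prev + 1 or \
                abs(segs[i][2] - segs[prev][2]) > band:
            n_inter += 1
        prev = i
    call = MULTI_STEP if n_inter >= 1 else ONE_STEP

    # rescue short intermediates that segmentation smoothed over: a fixed-
    # level chain fit around the fold transition must improve by more than
    # CHAIN_RESCUE_THRESHOLD sample-variances to overturn a one-step call
    if call == ONE_STEP and preset.p_multistep > 0 \
            and cps.values is not None and len(cps.values):
        xs = np.asarray(cps.values, float)
        ts = np.asarray(cps.time_s, float)
        sf = int(np.searchsorted(ts, t_fold))
        a, b2 = max(0, sf - 80), min(len(xs), sf + 10)
        sig = estimate_noise_sd(xs)
        if b2 - a >= 6 and sig > 0:
            gain = _chain_rescue_gain(
                xs[a:b2], (preset.E_duplex, preset.E_ss,
                           preset.E_intermediate, final_level))
            if gain > CHAIN_RESCUE_THRESHOLD * sig * sig:
                call, n_inter = MULTI_STEP, 1
    return FoldingCall(mol, n_steps=1 + n_inter, call=call, dwell_s=dwell,
                       t_fold_s=t_fold, t_release_s=t_release,
                       final_level=final_level,
                       ramp_end_s=t_release)


# ---------------------------------------------------------------------------
# exponential kinetics
# ---------------------------------------------------------------------------

def fit_dwell_exponential(dwells: Sequence[float], method: str = "mle",
                          t_min: float = 0.0, bins: int = 30) -> RateFit:
    """Exponential rate from a set of dwell times.

    ``mle``: rate = 1 / mean(dwell - t_min) — the maximum-likelihood
    estimate for (left-truncated) uncensored exponential data.  ``binned``:
    least-squares fit of A*exp(-k t) to the dwell histogram, for parity with
    histogram-based fitting.
    """
    d = np.asarray([x for x in dwells if np.isfinite(x)], float)
    if len(d) < 10:
        raise ValueError("need at least 10 finite dwells")
    if np.ptp(d) == 0:
        raise ValueError("degenerate fit: all dwells identical")
    if method == "mle":
        mean = float(np.mean(d)) - t_min
        if mean <= 0:
            raise ValueError("t_min exceeds the dwell mean")
        rate = 1.0 / mean
        return RateFit(rate=rate, stderr=rate / math.sqrt(len(d)),
                       n=len(d), method="dwell_exp")
    if method == "binned":
        from scipy.optimize import curve_fit
        counts, edges = np.histogram(d, bins=bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        use = counts > 0
        p0 = [counts.max(), 1.0 / max(np.mean(d), 1e-9)]
        popt, pcov = curve_fit(lambda t, A, k: A * np.exp(-k * t),
                               centers[use], counts[use], p0=p0,
                               maxfev=20000)
        err = math.sqrt(max(pcov[1, 1], 0.0)) if np.all(np.isfinite(pcov)) \
            else math.nan
        return RateFit(rate=float(popt[1]), amplitude=float(popt[0]),
                       stderr=err, n=len(d), method="dwell_exp_binned")
    raise ValueError(f"unknown method {method!r}")


def _fit_saturating_exponential(t: np.ndarray, F: np.ndarray,
                                n: int, method: str) -> RateFit:
    """Least-squares fit of A*(1 - exp(-k t)) to a cumulative fraction."""
    from scipy.optimize import curve_fit

    Fmax = float(np.max(F)) if len(F) else 0.0
    t_half = t[np.searchsorted(F, Fmax / 2.0)] if Fmax > 0 else np.max(t)
    p0 = [max(Fmax, 1e-3), 1.0 / max(t_half, 1e-6)]

    def model(tt, A, k):
        return A * (1.0 - np.exp(-k * tt))

    popt, pcov = curve_fit(model, t, F, p0=p0, maxfev=20000,
                           bounds=([0.0, 1e-9], [1.1, np.inf]))
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf)) \
        if np.all(np.isfinite(pcov)) else [math.nan, math.nan]
    A, k = float(popt[0]), float(popt[1])
    plateau = k * float(np.max(t)) > 2.0
    return RateFit(rate=k, amplitude=A, stderr=float(perr[1]),
                   amplitude_stderr=float(perr[0]), n=n, method=method,
                   plateau_reached=plateau)


def folding_fraction_curve(calls: Iterable[FoldingCall], n_total: int,
                           t_arrival: float,
                           t_grid: Optional[np.ndarray] = None) -> RateFit:
    """Overall folding rate from the cumulative folded fraction vs time.

    The fraction of molecules whose detected folding time has passed,
    measured from enzyme arrival, is fitted with ``A*(1 - exp(-k t))``.
    Since every molecule that will fold has folded by the end of the
    observation (the curve is flat there), the amplitude is anchored at the
    observed plateau and only the rate is free — a two-parameter fit of a
    lagged sigmoid with an exponential is ill-posed and can collapse into a
    small-k/large-A minimum.
    """
    from scipy.optimize import curve_fit

    t_fold = np.asarray([c.t_fold_s for c in calls
                         if c.call in (ONE_STEP, MULTI_STEP)
                         and np.isfinite(c.t_fold_s)], float) - t_arrival
    if len(t_fold) < 10:
        raise ValueError("need at least 10 folded molecules")
    if t_grid is None:
        t_grid = np.arange(0.0, max(np.max(t_fold) * 1.5, 1.0), 0.2)
    F = (t_fold[None, :] <= t_grid[:, None]).sum(axis=1) / float(n_total)
    A = float(F[-1])
    t_half = float(t_grid[int(np.searchsorted(F, A / 2.0))])
    popt, pcov = curve_fit(lambda t, k: A * (1.0 - np.exp(-k * t)),
                           t_grid, F, p0=[math.log(2.0) / max(t_half, 1e-6)],
                           bounds=([1e-9], [np.inf]), maxfev=20000)
    err = math.sqrt(max(pcov[0, 0], 0.0)) if np.all(np.isfinite(pcov)) \
        else math.nan
    return RateFit(rate=float(popt[0]), amplitude=A, stderr=err,
                   n=len(t_fold), method="fraction_exp",
                   plateau_reached=float(popt[0]) * float(t_grid[-1]) > 2.0)


# ---------------------------------------------------------------------------
# ligand-capture kinetics
# ---------------------------------------------------------------------------

@dataclass
class BindingTime:
    molecule_id: str
    duration_s: float      # fold -> bind, or fold -> censor time
    event: bool            # False = censored (never irreversibly bound)


def binding_time(cps: ChangePointSet, call: FoldingCall,
                 bound_threshold: float = BOUND_THRESHOLD,
                 min_tail_s: float = 1.0) -> BindingTime:
    """Irreversible-capture time: first post-folding entry into the bound
    band with no later segment returning above it; censored otherwise.

    The bound stretch must persist at least ``min_tail_s`` before the trace
    ends, so a handful of dark frames at a truncation boundary cannot fake
    an irreversible capture.
    """
    if call.call == NO_FOLD:
        raise ValueError("binding_time requires a folded trace")
    segs = list(cps.segments())
    t_fold = call.t_fold_s
    t_end = segs[-1][1]
    for i, (t0, t1, mean) in enumerate(segs):
        if t0 < t_fold or mean >= bound_threshold:
            continue
        if all(s[2] < bound_threshold for s in segs[i:]) \
                and t_end - t0 >= min_tail_s:
            return BindingTime(cps.molecule_id, max(t0 - t_fold, 0.0), True)
        # transient dip that returns high: keep scanning later segments
    return BindingTime(cps.molecule_id, max(t_end - t_fold, 0.0), False)


def bound_fraction_kinetics(times: Iterable[BindingTime],
                            t_grid: Optional[np.ndarray] = None) -> RateFit:
    """Accessibility plateau A and capture rate k from bound-fraction data.

    The cumulative bound fraction vs time since folding is estimated with
    Kaplan-Meier (censored molecules retained, not discarded) and fitted
    with ``A*(1 - exp(-k t))``; A estimates the accessible fraction.
    """
    times = list(times)
    if len(times) < 10:
        raise ValueError("need at least 10 molecules")
    durations = np.array([b.duration_s for b in times])
    events = np.array([b.event for b in times], bool)
    if events.sum() == 0:
        return RateFit(rate=math.nan, amplitude=0.0, n=len(times),
                       method="fraction_exp", converged=True,
                       plateau_reached=False)
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(durations, event_observed=events)
    if t_grid is None:
        t_grid = np.arange(0.0, float(np.max(durations)), 0.5)
    t_grid = np.asarray(t_grid, float)
    S = km.survival_function_at_times(t_grid).to_numpy()
    F = 1.0 - S
    # when the curve has clearly plateaued, anchor the amplitude at the
    # Kaplan-Meier plateau and fit only the rate (better conditioned than
    # the joint fit); otherwise fit both and flag the wide amplitude error
    fit = _fit_saturating_exponential(t_grid, F, n=len(times),
                                      method="fraction_exp")
    if fit.plateau_reached and fit.rate * float(t_grid[-1]) > 4.0 \
            and int(events.sum()) >= 30:
        from scipy.optimize import curve_fit

        A = float(F[-1])
        popt, pcov = curve_fit(lambda t, k: A * (1.0 - np.exp(-k * t)),
                               t_grid, F, p0=[max(fit.rate, 1e-6)],
                               bounds=([1e-9], [np.inf]), maxfev=20000)
        err = math.sqrt(max(pcov[0, 0], 0.0)) \
            if np.all(np.isfinite(pcov)) else math.nan
        return RateFit(rate=float(popt[0]), amplitude=A, stderr=err,
                       n=len(times), method="fraction_exp",
                       plateau_reached=True)
    return fit
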