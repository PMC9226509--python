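"""Stochastic trajectory sampler and ALEX intensity renderer.

The generative picture: a surface-tethered FRET pair reports on a telomeric
overhang held in a duplex.  At a configured arrival time an enzyme (Rep-X
helicase or lambda-exonuclease) releases the G-rich strand one nucleotide at
a time, each release step an independent exponential waiting time.  When the
last nucleotide is free the strand folds abruptly (exponential waiting at
``k_fold``), either directly into a G-quadruplex conformer (one-step) or via
a transient intermediate (multi-step, probability ``p_multistep``).  A
capture ligand (C-rich strand or POT1), when present, irreversibly binds a
per-molecule Bernoulli-gated "accessible" subpopulation after folding.

Rendering converts the piecewise-constant state record into per-frame donor
and acceptor photon counts under alternating-laser excitation with shot-like
Gaussian noise, donor leakage, PIFE (exonuclease mode) and photobleaching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .presets import KineticPreset

# mechanistic states
DUPLEX = "DUPLEX"
UNWINDING = "UNWINDING"
UNFOLDED_SS = "UNFOLDED_SS"
INTERMEDIATE = "INTERMEDIATE"
FOLDED = "FOLDED"
BOUND = "BOUND"

GREEN, DARK, RED = "green", "dark", "red"

#: ALEX pattern for ensemble-histogram movies (the dense red interleave the
#: donor-only filter was designed around)
HISTOGRAM_ALEX = (10, 1, 10)
#: ALEX pattern for real-time kinetics movies: mostly continuous green with
#: a sparse red probe, enough to flag dark acceptors and acceptor bleaching
#: without hiding sub-second folding events in excitation gaps
KINETICS_ALEX = (40, 1, 2)


@dataclass
class StateTrajectory:
    """Ground-truth piecewise-constant record of mechanistic state vs time.

    ``events`` is an ordered list of ``(time_s, state, info)`` tuples where
    ``info`` is the released-nucleotide count for UNWINDING events and the
    conformer index for FOLDED events (else ``None``).  The state entered at
    ``events[i]`` persists until ``events[i+1]``.
    """

    molecule_id: str
    duration_s: float
    events: list
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        times = [t for t, _, _ in self.events]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        nt = [info for _, s, info in self.events if s == UNWINDING]
        if nt != sorted(nt):
            raise ValueError("released-nucleotide count must increase")

    def state_at(self, t: float) -> tuple:
        """(state, info) in effect at time t."""
        current = self.events[0][1:]
        for et, s, info in self.events:
            if et > t:
                break
            current = (s, info)
        return current


@dataclass
class PhotophysicsParams:
    """Measurement model: intensities, noise, leakage, bleaching, ALEX."""

    total_intensity: float = 1000.0   # mean counts/frame from the FRET pair
    noise_sd: float = 60.0            # additive Gaussian counts per channel
    leakage_l: float = 0.07           # donor counts leaking into acceptor
    k_bleach_donor: float = 1.0 / 200.0    # s^-1
    k_bleach_acceptor: float = 1.0 / 200.0  # s^-1
    frame_s: float = 0.1
    alex_pattern: tuple = (10, 1, 10)  # green, dark, red frames per cycle
    p_donor_only: float = 0.0          # fraction lacking an active acceptor

    def __post_init__(self):
        if not 0.0 <= self.leakage_l < 0.3:
            raise ValueError("leakage_l must lie in [0, 0.3)")
        if self.frame_s <= 0:
            raise ValueError("frame_s must be positive")
        if self.total_intensity <= 0:
            raise ValueError("total_intensity must be positive")


@dataclass
class IntensityTrace:
    """Per-frame measured donor/acceptor counts with excitation labels."""

    molecule_id: str
    frame: np.ndarray        # frame index
    time_s: np.ndarray
    I_D: np.ndarray
    I_A: np.ndarray
    excitation: np.ndarray   # "green" | "dark" | "red"
    frame_s: float = 0.1

    def __len__(self):
        return len(self.frame)

    def green(self) -> np.ndarray:
        return self.excitation == GREEN

    def red(self) -> np.ndarray:
        return self.excitation == RED


# ---------------------------------------------------------------------------
# trajectory sampling
# ---------------------------------------------------------------------------

def _draw_conformer(rng, means, weights):
    w = np.asarray(weights, float)
    w = w / w.sum()
    return int(rng.choice(len(means), p=w))


def sample_state_trajectory(preset: KineticPreset, duration: float,
                            seed) -> StateTrajectory:
    """Draw one ground-truth state trajectory under a kinetic preset.

    Vectorial modes wait until ``t_enzyme_arrival``, release the overhang
    nucleotide by nucleotide (exponential per-nt waiting times), then fold;
    ``pf`` starts folded, ``salt_exchange`` starts at the LiCl mid-FRET level
    and folds after the buffer-exchange time.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    vectorial = preset.mode in ("vf_repx", "vf_exo")
    if vectorial and preset.overhang_len_nt <= 0:
        raise ValueError("vectorial mode requires a nonzero overhang")
    if vectorial and duration <= preset.t_enzyme_arrival:
        raise ValueError("duration must exceed the enzyme arrival time")

    rng = np.random.default_rng(seed)
    means = preset.conformer_means
    events: list = []
    gt: dict = {"pathway": None, "conformer": None, "fold_time_s": np.nan,
                "release_time_s": np.nan, "bind_time_s": np.nan,
                "eligible": False, "ss_dwell_s": np.nan}

    multi = bool(rng.random() < preset.p_multistep) if vectorial else False
    gt["pathway"] = "multi_step" if multi else "one_step"
    # enzyme arrival (or buffer exchange) with per-molecule flow jitter
    t_arrival = preset.t_enzyme_arrival
    if preset.arrival_jitter_s > 0 and preset.mode != "pf":
        t_arrival += rng.uniform(0.0, preset.arrival_jitter_s)
    gt["t_arrival_s"] = t_arrival

    if preset.mode == "pf":
        conf = _draw_conformer(rng, means, [w for _, w in preset.conformers])
        if preset.construct == "polyT":
            events.append((0.0, UNFOLDED_SS, None))
            gt["pathway"] = "none"
        else:
            events.append((0.0, FOLDED, conf))
            gt["conformer"] = conf
            gt["fold_time_s"] = 0.0
        t_fold: float = 0.0
    elif preset.mode == "salt_exchange":
        events.append((0.0, UNFOLDED_SS, None))
        t = t_arrival + rng.exponential(1.0 / preset.k_fold)
        conf = _draw_conformer(rng, means,
                               preset.pathway_weights(multistep=False))
        gt["pathway"] = "one_step"
        if t < duration:
            events.append((t, FOLDED, conf))
            gt["conformer"] = conf
            gt["fold_time_s"] = t
        t_fold = t
    else:
        events.append((0.0, DUPLEX, None))
        t = t_arrival
        k_nt = preset.release_rate_per_nt
        if k_nt <= 0:
            raise ValueError("per-nt release rate must be positive")
        waits = rng.exponential(1.0 / k_nt, size=preset.overhang_len_nt)
        n_released = 0
        for i, w in enumerate(waits, start=1):
            t += w
            if t >= duration:
                break
            n_released = i
            if i < preset.overhang_len_nt:
                events.append((t, UNWINDING, i))
        released = n_released == preset.overhang_len_nt
        if released:
            events.append((t, UNFOLDED_SS, None))
            gt["release_time_s"] = t
        ss_dwell = rng.exponential(1.0 / preset.k_fold)
        gt["ss_dwell_s"] = ss_dwell
        t += ss_dwell
        conf = _draw_conformer(rng, means, preset.pathway_weights(multi))
        if multi:
            t_int = t
            t += rng.exponential(1.0 / preset.k_intermediate)
            if released and t_int < duration:
                events.append((t_int, INTERMEDIATE, None))
        if released and t < duration:
            events.append((t, FOLDED, conf))
            gt["conformer"] = conf
            gt["fold_time_s"] = t
        t_fold = t

    # conformer relaxation: re-draw from the relax (pf) weights at k_relax
    if preset.k_relax > 0 and np.isfinite(gt["fold_time_s"]):
        weights = preset.relax_weights or [w for _, w in preset.conformers]
        t = gt["fold_time_s"]
        while True:
            t += rng.exponential(1.0 / preset.k_relax)
            if t >= duration:
                break
            conf = _draw_conformer(rng, means, weights)
            events.append((t, FOLDED, conf))
            gt["conformer"] = conf

    # irreversible ligand capture of the Bernoulli-gated accessible fraction
    lig = preset.ligand
    if lig.name != "none" and lig.rate > 0:
        gt["eligible"] = bool(rng.random() < lig.accessible_fraction)
        if gt["eligible"] and np.isfinite(gt["fold_time_s"]):
            t_bind = gt["fold_time_s"] + rng.exponential(1.0 / lig.rate)
            if t_bind < duration:
                # BOUND is absorbing: drop any later relaxation events
                events = [e for e in events if e[0] < t_bind]
                events.append((t_bind, BOUND, None))
                gt["bind_time_s"] = t_bind

    events.sort(key=lambda e: e[0])
    return StateTrajectory(molecule_id="", duration_s=duration, events=events,
                           ground_truth=gt)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _step_functions(traj: StateTrajectory, preset: KineticPreset):
    """Times, true FRET level and PIFE flag for each trajectory epoch."""
    times, levels, pife = [], [], []
    L = max(preset.overhang_len_nt, 1)
    for t, state, info in traj.events:
        times.append(t)
        if state == DUPLEX:
            levels.append(preset.E_duplex)
            pife.append(False)
        elif state == UNWINDING:
            frac = info / L
            levels.append(preset.E_duplex
                          + frac * (preset.E_ss - preset.E_duplex))
            pife.append(True)
        elif state == UNFOLDED_SS:
            levels.append(preset.E_ss)
            pife.append(False)
        elif state == INTERMEDIATE:
            levels.append(preset.E_intermediate)
            pife.append(False)
        elif state == FOLDED:
            levels.append(preset.conformer_means[info])
            pife.append(False)
        elif state == BOUND:
            levels.append(preset.E_bound)
            pife.append(False)
        else:  # pragma: no cover
            raise ValueError(f"unknown state {state}")
    return (np.asarray(times), np.asarray(levels, float),
            np.asarray(pife, bool))


def _frame_average(edges: np.ndarray, step_t: np.ndarray,
                   step_v: np.ndarray) -> np.ndarray:
    """Average of a right-continuous step function over each frame window."""
    # cumulative integral of the step function at each knot
    seg = np.concatenate([[0.0], np.cumsum(step_v[:-1] * np.diff(step_t))]) \
        if len(step_t) > 1 else np.array([0.0])

    def cum(t):
        i = np.searchsorted(step_t, t, side="right") - 1
        i = np.clip(i, 0, len(step_t) - 1)
        return seg[i] + step_v[i] * (t - step_t[i])

    c = cum(edges)
    return np.diff(c) / np.diff(edges)


def alex_labels(n_frames: int, pattern: tuple) -> np.ndarray:
    """Cyclic excitation labels for the ALEX pattern (green, dark, red)."""
    n_g, n_d, n_r = pattern
    cycle = [GREEN] * n_g + [DARK] * n_d + [RED] * n_r
    if not cycle:
        raise ValueError("empty ALEX pattern")
    reps = int(np.ceil(n_frames / len(cycle)))
    return np.array((cycle * reps)[:n_frames])


def render_intensity_trace(traj: StateTrajectory, phys: PhotophysicsParams,
                           preset: KineticPreset, seed,
                           donor_only: Optional[bool] = None,
                           bleach_times: Optional[tuple] = None
                           ) -> IntensityTrace:
    """Render a state trajectory into a measured ALEX intensity trace.

    Per green-excitation frame the noiseless signals are
    ``I_A = E * I_tot`` and ``I_D = (1 - E) * I_tot`` (frame-integrated over
    the true level), donor leakage adds ``l * I_D`` to the measured acceptor
    channel, PIFE multiplies the donor by ``pife_factor`` while the
    exonuclease is in contact, and Gaussian noise is added per channel.
    Red frames report the direct acceptor signal; photobleaching truncates
    the respective dye.  ``donor_only`` / ``bleach_times`` override the
    random draws (used for ground-truth bookkeeping by the cohort sampler).
    """
    rng = np.random.default_rng(seed)
    n_frames = int(np.floor(traj.duration_s / phys.frame_s))
    frames = np.arange(n_frames)
    t0 = frames * phys.frame_s
    edges = np.append(t0, n_frames * phys.frame_s)
    exc = alex_labels(n_frames, phys.alex_pattern)

    if donor_only is None:
        donor_only = bool(rng.random() < phys.p_donor_only)
    if bleach_times is None:
        t_bl_d = rng.exponential(1.0 / phys.k_bleach_donor) \
            if phys.k_bleach_donor > 0 else np.inf
        t_bl_a = rng.exponential(1.0 / phys.k_bleach_acceptor) \
            if phys.k_bleach_acceptor > 0 else np.inf
    else:
        t_bl_d, t_bl_a = bleach_times
    if donor_only:
        t_bl_a = 0.0

    step_t, step_E, step_pife = _step_functions(traj, preset)
    pife_gain = np.where(step_pife & (preset.mode == "vf_exo"),
                         preset.pife_factor, 1.0)
    # frame-averaged donor and acceptor emission (pre-bleach, green exc.)
    don = _frame_average(edges, step_t, (1.0 - step_E) * pife_gain)
    acc = _frame_average(edges, step_t, step_E)

    donor_alive = t0 < t_bl_d
    acceptor_alive = t0 < t_bl_a

    I_tot = phys.total_intensity
    I_D = np.zeros(n_frames)
    I_A = np.zeros(n_frames)

    g = exc == GREEN
    # with an active acceptor: FRET partitions the excitation
    ga = g & donor_alive & acceptor_alive
    I_D[ga] = don[ga] * I_tot
    I_A[ga] = acc[ga] * I_tot
    # acceptor dark (bleached / donor-only): donor emits unquenched
    gd = g & donor_alive & ~acceptor_alive
    pife_only = _frame_average(edges, step_t, pife_gain)
    I_D[gd] = pife_only[gd] * I_tot
    # donor leakage into the measured acceptor channel
    I_A[g] += phys.leakage_l * I_D[g]
    # red excitation probes the acceptor directly
    r = exc == RED
    I_A[r & acceptor_alive] = I_tot

    if phys.noise_sd > 0:
        I_D = I_D + rng.normal(0.0, phys.noise_sd, n_frames)
        I_A = I_A + rng.normal(0.0, phys.noise_sd, n_frames)
        np.clip(I_D, 0.0, None, out=I_D)
        np.clip(I_A, 0.0, None, out=I_A)

    return IntensityTrace(molecule_id=traj.molecule_id, frame=frames,
                          time_s=t0, I_D=I_D, I_A=I_A, excitation=exc,
                          frame_s=phys.frame_s)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """A simulated ensemble: traces, ground-truth trajectories, manifest."""

    preset: KineticPreset
    phys: PhotophysicsParams
    seed: int
    duration_s: float
    trajectories: list
    traces: list
    manifest: "object"  # pandas.DataFrame

    def __len__(self):
        return len(self.traces)


def simulate_cohort(preset: KineticPreset, phys: PhotophysicsParams, n: int,
                    seed, duration_s: float = 60.0) -> Cohort:
    """Simulate ``n`` independent molecules with reproducible derived seeds.

    Per-molecule seeds come from ``numpy.random.SeedSequence(seed).spawn``,
    so cohorts are reproducible from the master seed and order-independent.
    """
    import pandas as pd

    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n)
    trajectories, traces, rows = [], [], []
    seen = set()
    for i, child in enumerate(children):
        mol_id = f"{preset.name}_{i:04d}"
        if mol_id in seen:
            raise ValueError(f"duplicate molecule_id {mol_id}")
        seen.add(mol_id)
        traj_seed, phot_seed, aux_seed = child.spawn(3)
        traj = sample_state_trajectory(preset, duration_s, traj_seed)
        traj.molecule_id = mol_id
        aux = np.random.default_rng(aux_seed)
        donor_only = bool(aux.random() < phys.p_donor_only)
        t_bl_d = aux.exponential(1.0 / phys.k_bleach_donor) \
            if phys.k_bleach_donor > 0 else np.inf
        t_bl_a = aux.exponential(1.0 / phys.k_bleach_acceptor) \
            if phys.k_bleach_acceptor > 0 else np.inf
        if donor_only:
            t_bl_a = 0.0
        trace = render_intensity_trace(traj, phys, preset, phot_seed,
                                       donor_only=donor_only,
                                       bleach_times=(t_bl_d, t_bl_a))
        gt = traj.ground_truth
        rows.append(dict(molecule_id=mol_id, preset=preset.name,
                         seed_entropy=str(child.entropy),
                         spawn_key=i,
                         pathway=gt["pathway"], conformer=gt["conformer"],
                         t_arrival_s=gt.get("t_arrival_s", preset.t_enzyme_arrival),
                         release_time_s=gt["release_time_s"],
                         fold_time_s=gt["fold_time_s"],
                         ss_dwell_s=gt["ss_dwell_s"],
                         bind_time_s=gt["bind_time_s"],
                         eligible=gt["eligible"], donor_only=donor_only,
                         bleach_donor_s=t_bl_d, bleach_acceptor_s=t_bl_a))
        trajectories.append(traj)
        traces.append(trace)
    manifest = pd.DataFrame(rows)
    try:
        master = int(seed)
    except (TypeError, ValueError):
        master = -1
    return Cohort(preset=preset, phys=phys, seed=master,
                  duration_s=duration_s, trajectories=trajectories,
                  traces=traces, manifest=manifest)
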