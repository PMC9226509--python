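"""Cohort-level analysis orchestration: preprocessing -> histograms ->
step kinetics -> heatmaps, with all tables persisted as TSV.

This is the library behind both the ``vfret analyze`` command and the
numbered analysis drivers; every threshold has a keyword with a default
matching the documented conventions and is echoed into the run log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .simulator import Cohort
from . import traceproc, histmix, stepkin, heatmap as hm


@dataclass
class AnalysisConfig:
    red_threshold: float = traceproc.RED_THRESHOLD_DEFAULT
    leakage: Optional[float] = None      # None: estimate from donor-only
    cp_penalty: Optional[float] = None   # None: auto (3 sigma^2 log n)
    min_segment_frames: int = 2
    band: float = stepkin.BAND
    bound_threshold: float = stepkin.BOUND_THRESHOLD
    hist_bins: int = 65
    frames_per_molecule: int = histmix.FRAMES_PER_MOLECULE
    hist_window: Optional[tuple] = None  # None: post-folding tail
    K_max: int = 3
    mixture_seed: int = 0
    sync_mode: str = "transition"

    def to_dict(self) -> dict:
        d = dict(vars(self))
        d["hist_window"] = list(self.hist_window) if self.hist_window else None
        return d


@dataclass
class AnalysisResult:
    qc: pd.DataFrame
    fret_table: pd.DataFrame
    calls: pd.DataFrame
    call_objects: dict
    fret_traces: list
    changepoints: dict
    histogram: histmix.FretHistogram
    mixture: Optional[histmix.MixtureFit]
    dwell_fit: Optional[stepkin.RateFit]
    fold_curve: Optional[stepkin.RateFit]
    binding: Optional[pd.DataFrame]
    binding_fit: Optional[stepkin.RateFit]
    heatmap: Optional[hm.Heatmap]
    summary: dict = field(default_factory=dict)


def analyze_cohort(cohort: Cohort, config: AnalysisConfig = None
                   ) -> AnalysisResult:
    """Run the full trace-to-kinetics analysis on one cohort."""
    cfg = config or AnalysisConfig()
    preset = cohort.preset

    fret_traces, qc = traceproc.process_cohort(
        cohort.traces, red_threshold=cfg.red_threshold, leakage=cfg.leakage)

    # idealization + pathway calls
    cps_by_mol, call_rows, call_objs = {}, [], {}
    for ft in fret_traces:
        cps = stepkin.detect_changepoints(ft, penalty=cfg.cp_penalty,
                                          min_segment_frames=cfg.min_segment_frames)
        cps_by_mol[ft.molecule_id] = cps
        call = stepkin.classify_folding(cps, preset, band=cfg.band)
        call_objs[ft.molecule_id] = call
        call_rows.append(dict(molecule_id=ft.molecule_id, call=call.call,
                              n_steps=call.n_steps, dwell_s=call.dwell_s,
                              t_fold_s=call.t_fold_s,
                              t_release_s=call.t_release_s,
                              final_level=call.final_level))
    calls = pd.DataFrame(call_rows)

    folded = [c for c in call_objs.values()
              if c.call in (stepkin.ONE_STEP, stepkin.MULTI_STEP)]
    dwells = [c.dwell_s for c in folded if np.isfinite(c.dwell_s)]
    dwell_fit = None
    if len(dwells) >= 10 and np.ptp(dwells) > 0:
        dwell_fit = stepkin.fit_dwell_exponential(dwells)

    fold_curve = None
    if preset.mode in ("vf_repx", "vf_exo") and len(folded) >= 10:
        # reference the cohort's mean enzyme arrival (flow spread included)
        t_arr = preset.t_enzyme_arrival + 0.5 * preset.arrival_jitter_s
        fold_curve = stepkin.folding_fraction_curve(
            folded, n_total=len(fret_traces), t_arrival=t_arr)

    # histogram over the post-folding window (or configured window)
    window = cfg.hist_window
    if window is None:
        if preset.mode in ("vf_repx", "vf_exo", "salt_exchange"):
            t_folded = [c.t_fold_s for c in folded if np.isfinite(c.t_fold_s)]
            w0 = (np.percentile(t_folded, 90) + 2.0) if t_folded \
                else preset.t_enzyme_arrival
            window = (float(w0), cohort.duration_s)
        else:
            window = (0.0, cohort.duration_s)
    histogram = histmix.build_histogram(
        fret_traces, frames_per_molecule=cfg.frames_per_molecule,
        bins=cfg.hist_bins, window=window)
    try:
        mixture = histmix.fit_mixture(histogram, K_max=cfg.K_max,
                                      seed=cfg.mixture_seed)
    except RuntimeError:
        mixture = None

    # ligand-capture kinetics
    binding_df = binding_fit = None
    if preset.ligand.name != "none":
        bts = []
        for mol, call in call_objs.items():
            if call.call == stepkin.NO_FOLD:
                continue
            bts.append(stepkin.binding_time(cps_by_mol[mol], call,
                                            cfg.bound_threshold))
        if bts:
            binding_df = pd.DataFrame([vars(b) for b in bts])
            if len(bts) >= 10 and any(b.event for b in bts):
                binding_fit = stepkin.bound_fraction_kinetics(bts)

    # heatmap
    heat = None
    try:
        sync = cfg.sync_mode
        if preset.mode == "vf_exo":
            sync = "none"
        aligned = hm.align_traces(fret_traces, call_objs, sync_mode=sync,
                                  t_arrival=preset.t_enzyme_arrival)
        heat = hm.make_heatmap(aligned)
    except ValueError:
        pass

    fret_table = pd.concat([
        pd.DataFrame({"molecule_id": ft.molecule_id, "time_s": ft.time_s,
                      "E_corr": ft.E})
        for ft in fret_traces], ignore_index=True) if fret_traces else \
        pd.DataFrame(columns=["molecule_id", "time_s", "E_corr"])

    n_folded = len(folded)
    n_one = sum(c.call == stepkin.ONE_STEP for c in folded)
    summary = dict(
        preset=preset.name, n_molecules=len(cohort.traces),
        n_donor_only=int(qc["donor_only"].sum()),
        leakage=float(qc["leakage_l"].iloc[0]) if len(qc) else math.nan,
        n_folded=n_folded,
        pct_one_step=100.0 * n_one / n_folded if n_folded else math.nan,
        pct_multi_step=100.0 * (n_folded - n_one) / n_folded
        if n_folded else math.nan,
        mean_dwell_s=float(np.mean(dwells)) if dwells else math.nan,
        n_dwells=len(dwells),
        fold_rate=fold_curve.rate if fold_curve else math.nan,
        fold_amplitude=fold_curve.amplitude if fold_curve else math.nan,
        binding_rate=binding_fit.rate if binding_fit else math.nan,
        accessibility=binding_fit.amplitude if binding_fit else math.nan,
        mixture_K=mixture.K if mixture else 0,
        mixture_means=[float(m) for m in np.round(mixture.means, 4)]
        if mixture else [],
        mixture_weights=[float(w) for w in np.round(mixture.weights, 4)]
        if mixture else [],
        hist_window=[float(w) for w in np.round(window, 2)],
    )
    return AnalysisResult(qc=qc, fret_table=fret_table, calls=calls,
                          call_objects=call_objs, fret_traces=fret_traces,
                          changepoints=cps_by_mol, histogram=histogram,
                          mixture=mixture, dwell_fit=dwell_fit,
                          fold_curve=fold_curve, binding=binding_df,
                          binding_fit=binding_fit, heatmap=heat,
                          summary=summary)


def write_results(res: AnalysisResult, outdir, config: AnalysisConfig = None,
                  ground_truth: Optional[pd.DataFrame] = None,
                  plots: bool = False) -> Path:
    """Persist all tables (TSV) plus a run log and summary JSON; with
    ``plots=True`` also render the histogram-fit and heatmap figures."""
    from .cohio import write_json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if plots:
        from .plots import plot_histogram_fit, plot_heatmap

        plot_histogram_fit(res.histogram, res.mixture,
                           outdir / "histogram.png",
                           title=res.summary.get("preset", ""))
        if res.heatmap is not None:
            plot_heatmap(res.heatmap, outdir / "heatmap.png",
                         title=res.summary.get("preset", ""))
    res.qc.to_csv(outdir / "qc.tsv", sep="\t", index=False)
    res.calls.to_csv(outdir / "calls.tsv", sep="\t", index=False)
    res.fret_table.to_csv(outdir / "fret.tsv", sep="\t", index=False,
                          float_format="%.4f")
    hist = pd.DataFrame({"bin_left": res.histogram.bin_edges[:-1],
                         "bin_right": res.histogram.bin_edges[1:],
                         "density": res.histogram.densities})
    hist.to_csv(outdir / "histogram.tsv", sep="\t", index=False,
                float_format="%.5f")
    if res.mixture:
        mix = pd.DataFrame({"mean": res.mixture.means,
                            "sd": res.mixture.sds,
                            "weight": res.mixture.weights})
        mix.to_csv(outdir / "mixture.tsv", sep="\t", index=False,
                   float_format="%.4f")
    if res.binding is not None:
        res.binding.to_csv(outdir / "binding.tsv", sep="\t", index=False)
    if res.heatmap is not None:
        h = res.heatmap
        with open(outdir / "heatmap.tsv", "w") as fh:
            fh.write("# time_edges\t" +
                     "\t".join(f"{t:.2f}" for t in h.time_edges) + "\n")
            fh.write("# fret_edges\t" +
                     "\t".join(f"{e:.3f}" for e in h.fret_edges) + "\n")
            pd.DataFrame(h.counts).to_csv(fh, sep="\t", header=False,
                                          index=False, float_format="%.0f")
    if ground_truth is not None and len(res.calls):
        comp = res.calls.merge(ground_truth, on="molecule_id", how="left")
        comp["pathway_match"] = comp["call"] == comp["pathway"]
        comp.to_csv(outdir / "recovery.tsv", sep="\t", index=False)
    log = dict(vfret_version=__version__,
               config=(config or AnalysisConfig()).to_dict(),
               summary=res.summary)
    write_json(log, outdir / "run_log.json")
    return outdir
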