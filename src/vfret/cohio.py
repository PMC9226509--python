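"""Cohort disk format: per-molecule tab-separated trace files, a manifest
and a ground-truth table, plus optional FASTA export of the overhang."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .presets import KineticPreset
from .simulator import Cohort, IntensityTrace, PhotophysicsParams

TRACE_COLUMNS = ["frame", "time_s", "I_D", "I_A", "excitation"]


def write_cohort(cohort: Cohort, outdir, overwrite: bool = False) -> Path:
    """Write traces, manifest, ground truth and preset to ``outdir``."""
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.tsv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists (use overwrite=True)")
    (outdir / "traces").mkdir(parents=True, exist_ok=True)

    files = []
    for trace in cohort.traces:
        fname = f"traces/{trace.molecule_id}.tsv"
        df = pd.DataFrame({"frame": trace.frame,
                           "time_s": np.round(trace.time_s, 4),
                           "I_D": np.round(trace.I_D, 2),
                           "I_A": np.round(trace.I_A, 2),
                           "excitation": trace.excitation})
        df.to_csv(outdir / fname, sep="\t", index=False)
        files.append(fname)

    manifest = cohort.manifest.copy()
    manifest["trace_file"] = files
    manifest.to_csv(manifest_path, sep="\t", index=False)
    gt_cols = ["molecule_id", "pathway", "conformer", "release_time_s",
               "fold_time_s", "ss_dwell_s", "bind_time_s", "eligible",
               "donor_only", "bleach_donor_s", "bleach_acceptor_s"]
    manifest[gt_cols].to_csv(outdir / "ground_truth.tsv", sep="\t",
                             index=False)
    with open(outdir / "preset.yaml", "w") as fh:
        yaml.safe_dump({"preset": cohort.preset.to_dict(),
                        "photophysics": vars(cohort.phys),
                        "seed": cohort.seed,
                        "duration_s": cohort.duration_s,
                        "n": len(cohort)}, fh, sort_keys=True)
    with open(outdir / "overhang.fasta", "w") as fh:
        fh.write(f">{cohort.preset.name} {cohort.preset.construct} "
                 f"overhang\n{cohort.preset.overhang_sequence()}\n")
    return outdir


def read_trace(path, molecule_id: Optional[str] = None,
               frame_s: float = 0.1) -> IntensityTrace:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace file {path} lacks columns {sorted(missing)}")
    if molecule_id is None:
        molecule_id = Path(path).stem
    return IntensityTrace(molecule_id=molecule_id,
                          frame=df["frame"].to_numpy(),
                          time_s=df["time_s"].to_numpy(float),
                          I_D=df["I_D"].to_numpy(float),
                          I_A=df["I_A"].to_numpy(float),
                          excitation=df["excitation"].to_numpy(str),
                          frame_s=frame_s)


def read_cohort(indir, strict: bool = False) -> Cohort:
    """Load a cohort directory written by :func:`write_cohort`.

    Missing trace files produce warnings; more than 10 % missing is an
    error (always an error with ``strict=True``).
    """
    import warnings

    indir = Path(indir)
    with open(indir / "preset.yaml") as fh:
        meta = yaml.safe_load(fh)
    preset = KineticPreset.from_dict(meta["preset"])
    phys = PhotophysicsParams(**{k: tuple(v) if k == "alex_pattern" else v
                                 for k, v in meta["photophysics"].items()})
    manifest = pd.read_csv(indir / "manifest.tsv", sep="\t")
    traces, missing = [], 0
    for _, row in manifest.iterrows():
        path = indir / row["trace_file"]
        if not path.exists():
            missing += 1
            warnings.warn(f"missing trace file {path}")
            continue
        traces.append(read_trace(path, row["molecule_id"], phys.frame_s))
    if missing and (strict or missing > 0.1 * len(manifest)):
        raise FileNotFoundError(f"{missing}/{len(manifest)} trace files "
                                "missing")
    present = manifest[manifest["trace_file"].map(
        lambda f: (indir / f).exists())].reset_index(drop=True)
    return Cohort(preset=preset, phys=phys, seed=meta["seed"],
                  duration_s=meta["duration_s"], trajectories=[],
                  traces=traces, manifest=present)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
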