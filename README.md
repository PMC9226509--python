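# vfret

Simulation and analysis of single-molecule FRET experiments on **vectorial
G-quadruplex folding** — the folding of a telomeric TTAGGG-repeat overhang
as it is released one nucleotide at a time (by a processive helicase, a
λ-exonuclease, or, in vivo, telomerase synthesis), in contrast to
conventional *post-folding* of a free strand.

The package is for single-molecule biophysicists who want a fully
synthetic, ground-truthed test bed for the standard smFRET analysis chain:
it pairs a stochastic trace generator (directional strand release → abrupt
folding → conformer selection → irreversible ligand capture, rendered with
full ALEX photophysics) with the estimators used on such data —
donor-leakage correction and donor-only exclusion, change-point
idealization, folding-pathway classification, dwell-time and
bound-fraction exponential kinetics, Gaussian-mixture histograms, and
population heatmaps. Because every cohort carries its generative manifest,
each estimator can be validated molecule-by-molecule against ground truth.

## Model in brief

A molecule is a continuous-time state machine

```
DUPLEX → UNWINDING(1…L nt) → UNFOLDED_SS → [INTERMEDIATE] → FOLDED(cᵢ) → BOUND
```

with exponential waiting times throughout: per-nucleotide release at
k_nt(ATP) (Hill law, 1 nt/s at 50 µM ATP — telomerase speed — and
sub-frame release at 1 mM), folding at k_fold = 1/0.41 s⁻¹, an
intermediate-bearing pathway with probability p_multistep (0.27 for G3,
0.33 for G4), and gated irreversible capture by a complementary C-strand
(C2) or the telomere-binding protein POT1. Measured FRET is the proximity
ratio E = I_A/(I_D+I_A) after leakage correction. See
[docs/methods.md](docs/methods.md) for the full model and estimator
documentation.

## Worked example

```python
from vfret import PhotophysicsParams, simulate_cohort, analyze_cohort
from vfret.presets import get_preset
from vfret.simulator import KINETICS_ALEX

preset = get_preset("vf-G4")            # Rep-X vectorial folding, 1 mM ATP
phys = PhotophysicsParams(p_donor_only=0.10, alex_pattern=KINETICS_ALEX)
cohort = simulate_cohort(preset, phys, n=300, seed=31, duration_s=40.0)
result = analyze_cohort(cohort)
s = result.summary
print(f"folded {s['n_folded']}, one-step {s['pct_one_step']:.1f}%, "
      f"mean dwell {s['mean_dwell_s']:.2f} s")
print("conformer peaks:", s["mixture_means"], "weights:", s["mixture_weights"])
```

prints

```
folded 242, one-step 67.4%, mean dwell 1.80 s
conformer peaks: [0.7003, 0.847] weights: [0.5583, 0.4417]
```

i.e. about two thirds of folded G4 molecules fold in a single ~0.4 s step
(the mean dwell is pulled up by the seconds-long intermediates of the
multi-step third), and the post-folding ensemble splits between the ~0.70
and ~0.85 conformers. The same pipeline is available from the shell:

```bash
vfret presets                         # list the named conditions
vfret simulate --preset vf-G4 -n 300 --seed 31 --duration 40 --out coh/
vfret analyze coh/                    # tables under coh/results/
vfret report coh/results              # one-page summary
```

## Analysis scripts

The numbered drivers under `analysis/` reproduce the study's main
comparisons on synthetic cohorts and write small TSV tables under
`results/`: conformer histograms pf vs vf (`01`), real-time pathway
fractions and dwells (`02`), ATP titration of the folding rate (`03`),
C2/POT1 accessibility (`04`), and the λ-exonuclease direction-independence
test (`05`).

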