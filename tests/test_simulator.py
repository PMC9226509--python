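"""Trajectory sampler and renderer: kinetic contracts, photophysics
arithmetic, reproducibility."""

import numpy as np
import pytest
from scipy import stats

from vfret import (PhotophysicsParams, sample_state_trajectory,
                   render_intensity_trace, simulate_cohort)
from vfret.presets import get_preset
from vfret.simulator import (DUPLEX, UNWINDING, UNFOLDED_SS, INTERMEDIATE,
                             FOLDED, BOUND, StateTrajectory, KINETICS_ALEX)


def _states(traj):
    return [s for _, s, _ in traj.events]


class TestSampleStateTrajectory:
    def test_zero_multistep_probability_never_yields_intermediates(self):
        p = get_preset("vf-G2")
        assert p.p_multistep == 0.0
        for seed in range(30):
            traj = sample_state_trajectory(p, 60.0, seed)
            assert INTERMEDIATE not in _states(traj)

    def test_vf_g4_intermediate_fraction_matches_pathway_probability(self):
        p = get_preset("vf-G4")
        n = 4000
        hits = sum(INTERMEDIATE in _states(
            sample_state_trajectory(p, 120.0, seed)) for seed in range(n))
        # binomial 4 sigma around p_multistep = 0.33 (long-duration cohort
        # so virtually every drawn intermediate is realized)
        assert hits / n == pytest.approx(0.33, abs=4 * 0.0075)

    def test_single_strand_dwell_is_exponential_with_0p41s_mean(self):
        p = get_preset("vf-cMyc")
        dwells = [sample_state_trajectory(p, 300.0, s).ground_truth
                  ["ss_dwell_s"] for s in range(5000)]
        assert np.mean(dwells) == pytest.approx(0.41, abs=4 * 0.41 /
                                                np.sqrt(5000))
        # KS conformity against the configured exponential at alpha = 0.01
        d, pval = stats.kstest(dwells, "expon", args=(0, 0.41))
        assert pval > 0.01

    def test_event_times_increase_and_unwinding_counter_monotone(self):
        p = get_preset("vf-G4-atp50")
        for seed in range(10):
            traj = sample_state_trajectory(p, 300.0, seed)
            times = [t for t, _, _ in traj.events]
            assert all(t1 < t2 for t1, t2 in zip(times, times[1:]))
            nts = [i for _, s, i in traj.events if s == UNWINDING]
            assert nts == sorted(nts)
            assert traj.events[0][1] == DUPLEX

    def test_bound_state_is_absorbing(self):
        p = get_preset("vf-G4-C2")
        found = 0
        for seed in range(200):
            traj = sample_state_trajectory(p, 300.0, seed)
            states = _states(traj)
            if BOUND in states:
                assert states.index(BOUND) == len(states) - 1
                found += 1
        assert found > 50

    def test_nearly_all_molecules_fold_within_300s_at_saturating_atp(self):
        p = get_preset("vf-G4")
        folded = sum(np.isfinite(sample_state_trajectory(p, 300.0, s)
                                 .ground_truth["fold_time_s"])
                     for s in range(200))
        assert folded / 200 >= 0.95

    def test_eligibility_converges_to_accessible_fraction(self):
        p = get_preset("vf-G4-POT1")
        elig = [sample_state_trajectory(p, 60.0, s).ground_truth["eligible"]
                for s in range(2000)]
        assert np.mean(elig) == pytest.approx(0.85, abs=4 * 0.008)

    def test_polyT_has_single_level_and_no_transitions(self):
        traj = sample_state_trajectory(get_preset("pf-polyT"), 60.0, 1)
        assert len(traj.events) == 1
        assert traj.events[0][1] == UNFOLDED_SS

    def test_rejects_bad_durations_and_empty_overhang(self):
        p = get_preset("vf-G4")
        with pytest.raises(ValueError):
            sample_state_trajectory(p, -1.0, 0)
        with pytest.raises(ValueError):
            sample_state_trajectory(p, 5.0, 0)  # before enzyme arrival


class TestRenderIntensityTrace:
    def _folded_traj(self, conf=0):
        return StateTrajectory(molecule_id="m", duration_s=10.0,
                               events=[(0.0, FOLDED, conf)])

    def test_noiseless_partition_at_E_075(self, noiseless_phys):
        p = get_preset("pf-G2")  # conformer 0 at E = 0.75
        tr = render_intensity_trace(self._folded_traj(), noiseless_phys, p,
                                    seed=0, donor_only=False,
                                    bleach_times=(np.inf, np.inf))
        g = tr.green()
        assert np.allclose(tr.I_D[g], 250.0)
        assert np.allclose(tr.I_A[g], 750.0)

    def test_leakage_adds_to_measured_acceptor(self):
        phys = PhotophysicsParams(noise_sd=0.0, leakage_l=0.1,
                                  k_bleach_donor=0.0, k_bleach_acceptor=0.0)
        p = get_preset("pf-G2")
        tr = render_intensity_trace(self._folded_traj(), phys, p, seed=0,
                                    donor_only=False,
                                    bleach_times=(np.inf, np.inf))
        g = tr.green()
        assert np.allclose(tr.I_A[g], 750.0 + 0.1 * 250.0)

    def test_donor_bleach_darkens_green_but_not_red_frames(self,
                                                           noiseless_phys):
        p = get_preset("pf-G2")
        tr = render_intensity_trace(self._folded_traj(), noiseless_phys, p,
                                    seed=0, donor_only=False,
                                    bleach_times=(0.0, np.inf))
        g, r = tr.green(), tr.red()
        assert np.allclose(tr.I_D[g], 0.0)
        assert np.allclose(tr.I_A[g], 0.0)
        assert np.allclose(tr.I_A[r], 1000.0)

    def test_unwinding_interpolates_between_duplex_and_ss_levels(
            self, noiseless_phys):
        p = get_preset("vf-G4")
        traj = StateTrajectory(molecule_id="m", duration_s=3.0,
                               events=[(0.0, DUPLEX, None),
                                       (1.0, UNWINDING, 12),
                                       (2.0, UNFOLDED_SS, None)])
        tr = render_intensity_trace(traj, noiseless_phys, p, seed=0,
                                    donor_only=False,
                                    bleach_times=(np.inf, np.inf))
        g = tr.green()
        E = tr.I_A[g] / (tr.I_D[g] + tr.I_A[g])
        mid = (p.E_duplex + p.E_ss) / 2.0
        sel = (tr.time_s[g] > 1.1) & (tr.time_s[g] < 1.9)
        assert np.allclose(E[sel], mid, atol=1e-9)

    def test_energy_conservation_without_noise_or_leakage(
            self, g4_cohort_noiseless):
        for tr in g4_cohort_noiseless.traces[:20]:
            g = tr.green()
            assert np.allclose(tr.I_D[g] + tr.I_A[g], 1000.0, atol=1e-6)

    def test_pife_boosts_donor_during_exonuclease_digestion(
            self, noiseless_phys):
        p = get_preset("vf-exo-G4")
        traj = StateTrajectory(molecule_id="m", duration_s=4.0,
                               events=[(0.0, DUPLEX, None),
                                       (1.0, UNWINDING, 1),
                                       (3.0, UNFOLDED_SS, None)])
        tr = render_intensity_trace(traj, noiseless_phys, p, seed=0,
                                    donor_only=False,
                                    bleach_times=(np.inf, np.inf))
        g = tr.green()
        before = tr.I_D[g][(tr.time_s[g] < 0.9)]
        during = tr.I_D[g][(tr.time_s[g] > 1.2) & (tr.time_s[g] < 2.8)]
        assert during.mean() > 1.3 * before.mean()


class TestSimulateCohort:
    def test_fixed_seed_reproduces_byte_identical_cohorts(self,
                                                          default_phys):
        p = get_preset("vf-G2")
        a = simulate_cohort(p, default_phys, n=5, seed=7, duration_s=30.0)
        b = simulate_cohort(p, default_phys, n=5, seed=7, duration_s=30.0)
        for ta, tb in zip(a.traces, b.traces):
            np.testing.assert_array_equal(ta.I_D, tb.I_D)
            np.testing.assert_array_equal(ta.I_A, tb.I_A)
        assert a.manifest.equals(b.manifest)

    def test_different_seeds_differ(self, default_phys):
        p = get_preset("vf-G2")
        a = simulate_cohort(p, default_phys, n=3, seed=7, duration_s=30.0)
        b = simulate_cohort(p, default_phys, n=3, seed=8, duration_s=30.0)
        assert not np.array_equal(a.traces[0].I_D, b.traces[0].I_D)

    def test_manifest_records_ground_truth_per_molecule(self, default_phys):
        p = get_preset("vf-G4-C2")
        coh = simulate_cohort(p, default_phys, n=8, seed=3,
                              duration_s=60.0)
        m = coh.manifest
        assert len(m) == 8
        assert m.molecule_id.is_unique
        for col in ("pathway", "fold_time_s", "bind_time_s", "eligible",
                    "donor_only", "t_arrival_s"):
            assert col in m.columns
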