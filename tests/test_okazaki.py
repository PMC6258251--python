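"""Behaviour of the lagging-strand simulator and its summaries."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import ks_2samp

from replichrom import okazaki as ok
from replichrom.errors import InputError


def pooled_lengths(params, n_reps):
    return np.concatenate(
        [r.fragment_lengths() for r in ok.run_replicates(params, n_reps)]
    )


@pytest.fixture(scope="module")
def wt():
    return ok.get_preset("wt")


@pytest.fixture(scope="module")
def elg1d():
    return ok.get_preset("elg1d")


class TestSimulateLaggingStrand:
    def test_deterministic_limit_gives_exact_repeat_lengths(self, wt):
        # jitter-free, instantaneous deposition, instant unloading, primer
        # spacing below the repeat: every interior fragment is exactly one
        # repeat long, forced by the nucleosome-edge termination rule
        params = replace(
            wt,
            strand_length=50_000,
            deposition_jitter_sd=0.0,
            deposition_rate=1000.0,
            k_elg1=1000.0,
            primer_spacing_min=100.0,
            primer_spacing_mean=101.0,
            seed=3,
        )
        lengths = ok.simulate_lagging_strand(params).fragment_lengths()
        assert set(lengths[1:-1]) == {float(params.repeat)}

    def test_no_deposition_caps_nick_translation(self, wt):
        # without nucleosome barriers every fragment nick-translates the full
        # displacement cap past the preceding primer; the simulation still
        # terminates and the ligated pieces still tile the strand
        params = replace(wt, strand_length=30_000, deposition_rate=0.0, seed=1)
        res = ok.simulate_lagging_strand(params)
        lengths = res.fragment_lengths()
        assert lengths.sum() == pytest.approx(params.strand_length)
        # junction position = previous fragment's primer - cap, and the
        # previous fragment's primer is its ligation position (fork speed 1)
        for prev, frag in zip(res.fragments[1:-1], res.fragments[2:-1]):
            displacement = prev.ligation_time * params.fork_speed - frag.start
            assert displacement == pytest.approx(params.max_displacement)

    def test_zero_length_strand_gives_empty_result(self, wt):
        res = ok.simulate_lagging_strand(replace(wt, strand_length=0))
        assert res.fragments == [] and len(res.dyad_positions) == 0

    @pytest.mark.parametrize("preset", list(ok.PRESET_NAMES))
    def test_fragments_tile_strand_exactly(self, preset):
        params = replace(ok.get_preset(preset), strand_length=30_000, seed=5)
        res = ok.simulate_lagging_strand(params)
        starts = np.array([f.start for f in res.fragments])
        ends = np.array([f.end for f in res.fragments])
        assert starts[0] == 0.0
        assert ends[-1] == pytest.approx(params.strand_length)
        assert np.allclose(ends[:-1], starts[1:])  # no gaps, no overlaps
        assert res.fragment_lengths().sum() == pytest.approx(params.strand_length)

    @pytest.mark.parametrize("preset", ["wt", "elg1d"])
    def test_dyads_keep_footprint_spacing(self, preset):
        params = replace(ok.get_preset(preset), strand_length=30_000, seed=2)
        res = ok.simulate_lagging_strand(params)
        assert np.diff(res.dyad_positions).min() >= params.nucleosome_footprint

    def test_no_dyad_violates_pcna_exclusion_at_deposition(self, elg1d):
        params = replace(elg1d, strand_length=30_000, seed=7)
        res = ok.simulate_lagging_strand(params)
        exclusion = params.nucleosome_footprint // 2 + params.pcna_block_halfwidth
        for d, t in zip(res.dyad_positions, res.dyad_times):
            for ev in res.pcna_events:
                if ev.load_time < t < ev.unload_time:
                    assert abs(ev.position - d) > exclusion

    def test_delayed_unloading_lengthens_fragments(self, wt, elg1d):
        # the central in-vivo phenotype: clamp retention removes nucleosome
        # barriers and extends Okazaki fragments
        small_wt = replace(wt, strand_length=100_000)
        small_mut = replace(elg1d, strand_length=100_000)
        means_wt, means_mut = [], []
        for r in range(10):
            means_wt.append(
                ok.simulate_lagging_strand(replace(small_wt, seed=r)).fragment_lengths().mean()
            )
            means_mut.append(
                ok.simulate_lagging_strand(replace(small_mut, seed=r)).fragment_lengths().mean()
            )
        assert np.mean(means_mut) > np.mean(means_wt)

    def test_deterministic_given_seed(self, wt):
        params = replace(wt, strand_length=20_000, seed=9)
        a = ok.simulate_lagging_strand(params)
        b = ok.simulate_lagging_strand(params)
        assert a.fragments == b.fragments
        assert np.array_equal(a.dyad_positions, b.dyad_positions)
        assert a.pcna_events == b.pcna_events

    def test_mean_length_non_increasing_in_deposition_rate(self, wt):
        means = []
        for rate in (0.008, 0.05, 2.0):
            params = replace(wt, strand_length=100_000, deposition_rate=rate)
            means.append(pooled_lengths(params, 5).mean())
        # adjacent pairs within Monte-Carlo noise; extremes strictly ordered
        assert means[0] >= means[1] - 5.0
        assert means[1] >= means[2] - 5.0
        assert means[0] > means[2]

    def test_mean_length_non_decreasing_in_block_halfwidth(self, elg1d):
        means = []
        for hw in (5.0, 15.0, 40.0):
            params = replace(
                elg1d, strand_length=100_000, pcna_block_halfwidth=hw
            )
            means.append(pooled_lengths(params, 5).mean())
        assert means[1] >= means[0] - 5.0
        assert means[2] >= means[1] - 5.0
        assert means[2] > means[0]

    def test_fast_spontaneous_unloading_converges_to_wild_type(self, wt, elg1d):
        # trimer-instability limit: k_spont large with no Elg1 pathway is
        # indistinguishable from intact Elg1 unloading
        fast = replace(elg1d, k_spont=50.0, seed=100)
        lengths_fast = pooled_lengths(fast, 10)
        lengths_wt = pooled_lengths(wt, 10)
        assert min(len(lengths_fast), len(lengths_wt)) >= 8_000
        assert ks_2samp(lengths_fast, lengths_wt).statistic < 0.05


class TestLengthDistribution:
    def test_single_value_fills_one_bin(self):
        dist = ok.length_distribution([180.0] * 100, 5)
        assert (dist.bin_counts > 0).sum() == 1
        assert dist.n == 100

    def test_uniform_lengths_have_no_outlier_bin(self):
        rng = np.random.default_rng(0)
        lengths = rng.uniform(100, 500, size=20_000)
        dist = ok.length_distribution(lengths, 10)
        occupied = dist.bin_counts[10:50]  # bins fully inside [100, 500)
        expected = 20_000 / 40
        sigma = np.sqrt(expected)
        assert np.all(np.abs(occupied - expected) < 3.5 * sigma)

    def test_counts_sum_to_n(self):
        lengths = np.random.default_rng(1).exponential(200, size=5000)
        dist = ok.length_distribution(lengths, 7)
        assert dist.bin_counts.sum() == dist.n == 5000

    def test_empty_input(self):
        dist = ok.length_distribution([], 5)
        assert dist.n == 0
        assert ok.find_modes(dist) == []


class TestFindModes:
    def test_recovers_constructed_mixture(self):
        rng = np.random.default_rng(4)
        lengths = np.concatenate(
            [rng.normal(180, 15, 7000), rng.normal(360, 15, 3000)]
        )
        dist = ok.length_distribution(lengths, 5)
        modes = ok.find_modes(dist, min_separation=100, min_fraction=0.005)
        assert len(modes) == 2
        assert modes[0] == pytest.approx(180, abs=5)
        assert modes[1] == pytest.approx(360, abs=5)

    def test_single_delta_gives_one_mode(self):
        dist = ok.length_distribution([250.0] * 500, 5)
        modes = ok.find_modes(dist)
        assert len(modes) == 1
        assert modes[0] == pytest.approx(250, abs=5)

    def test_flat_histogram_gives_no_modes(self):
        # every bin holds 0.5% of the mass, below the default 1% floor
        dist = ok.LengthDistribution(
            bin_width=5, bin_counts=np.full(200, 10, dtype=np.int64), n=2000
        )
        assert ok.find_modes(dist) == []

    def test_min_separation_below_bin_width_rejected(self):
        dist = ok.length_distribution([100.0], 5)
        with pytest.raises(InputError):
            ok.find_modes(dist, min_separation=2)


def lattice_result(strand_length=10_000, repeat=180):
    """A hand-built SimResult with a perfect nucleosome lattice."""
    params = ok.SimParams(strand_length=strand_length)
    half = params.nucleosome_footprint // 2
    dyads = np.arange(half, strand_length - half, repeat, dtype=float)
    return ok.SimResult(
        fragments=[],
        dyad_positions=dyads,
        dyad_times=np.zeros_like(dyads),
        pcna_events=[],
        params=params,
        end_time=float(strand_length),
    )


class TestMnaseReadout:
    def test_saturating_digestion_releases_mononucleosomes(self):
        res = lattice_result()
        readout = ok.mnase_readout(res, sample_time=10_000, cut_coeff=100.0)
        assert readout.mono_fraction > 0.9
        assert readout.di_fraction < 0.05

    def test_no_digestion_leaves_no_mononucleosomes(self):
        res = lattice_result()
        readout = ok.mnase_readout(res, sample_time=10_000, cut_coeff=1e-9)
        assert readout.mono_fraction < 0.01
        assert readout.higher_fraction > 0.95

    def test_sample_before_synthesis_is_all_subnucleosomal(self):
        res = lattice_result()
        readout = ok.mnase_readout(res, sample_time=0.0, cut_coeff=0.01)
        assert readout.total_mass == 0.0
        # a moment after synthesis starts, before any deposition, the only
        # mass is unprotected
        res_nodyads = ok.SimResult(
            [], np.array([]), np.array([]), [], ok.SimParams(strand_length=10_000), 10_000.0
        )
        early = ok.mnase_readout(res_nodyads, sample_time=500.0, cut_coeff=0.01)
        assert early.sub_fraction == pytest.approx(1.0)

    def test_fractions_sum_to_one(self):
        res = lattice_result()
        r = ok.mnase_readout(res, sample_time=6_000, cut_coeff=0.02)
        total = r.mono_fraction + r.di_fraction + r.sub_fraction + r.higher_fraction
        assert total == pytest.approx(1.0)

    def test_delayed_unloading_increases_mono_to_di_ratio(self):
        wt = replace(ok.get_preset("wt"), strand_length=100_000)
        mut = replace(ok.get_preset("elg1d"), strand_length=100_000)
        for r in range(10):
            res_wt = ok.simulate_lagging_strand(replace(wt, seed=r))
            res_mut = ok.simulate_lagging_strand(replace(mut, seed=r))
            t = 0.6 * 100_000
            m_wt = ok.mnase_readout(res_wt, t)
            m_mut = ok.mnase_readout(res_mut, t)
            ratio_wt = m_wt.mono_fraction / (m_wt.mono_fraction + m_wt.di_fraction)
            ratio_mut = m_mut.mono_fraction / (m_mut.mono_fraction + m_mut.di_fraction)
            assert ratio_mut > ratio_wt


class TestCompareConditions:
    def test_same_condition_has_small_ks_distance(self):
        wt = ok.get_preset("wt")
        other = replace(wt, seed=100)
        cmp = ok.compare_conditions(wt, other, n_reps=10)
        assert cmp.n_fragments_a >= 8_000
        assert cmp.ks_distance < 0.05

    def test_rescue_is_closer_to_wild_type_than_mutant(self):
        wt = ok.get_preset("wt")
        mutant = ok.get_preset("elg1d")
        rescue = replace(mutant, k_spont=1.0)
        ks_mut = ok.compare_conditions(mutant, wt, n_reps=10).ks_distance
        ks_res = ok.compare_conditions(rescue, wt, n_reps=10).ks_distance
        assert ks_res < ks_mut

    def test_mutant_mono_fold_change_exceeds_one(self):
        cmp = ok.compare_conditions(
            ok.get_preset("elg1d"), ok.get_preset("wt"), n_reps=5
        )
        assert cmp.mono_fold_change > 1.0
        assert cmp.mean_length_diff > 0

    def test_rejects_zero_replicates(self):
        wt = ok.get_preset("wt")
        with pytest.raises(InputError):
            ok.compare_conditions(wt, wt, n_reps=0)
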