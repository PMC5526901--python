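"""Synthetic-sample generator: label bookkeeping, dilution arithmetic,
spike-in mixing, and distributional sanity of the channel model."""

import numpy as np
import pytest

from cytogate.io import ChannelMismatchError
from cytogate.simulate import (
    CHANNEL_MODELS,
    LIVE_SINGLE_LABELS,
    MULTIMER_LABEL,
    POPULATIONS,
    LabProfile,
    SpikeInDesign,
    make_dilution_series,
    mix_spikein,
    panel_populations,
    preset_populations,
    preset_profile,
    simulate_donor,
    theoretical_frequency,
    true_frequencies,
)


def donor(preset, n, seed):
    return simulate_donor(preset_populations(preset), preset_profile(preset),
                          n, seed)


class TestSimulateDonor:
    def test_every_event_labeled_once(self):
        t = donor("519-EBV", 20_000, seed=1)
        assert t.labels is not None and len(t.labels) == t.n_events
        assert set(np.unique(t.labels)) <= set(POPULATIONS)

    def test_zero_multimer_fraction_gives_zero_positives(self):
        t = donor("spikein1-negative", 50_000, seed=2)
        assert (t.labels == MULTIMER_LABEL).sum() == 0

    def test_multimer_count_within_three_binomial_sd(self):
        t = donor("spikein1-positive", 100_000, seed=3)
        tr = true_frequencies(t)
        n, p = tr["n_live_single"], 0.017
        sd = np.sqrt(n * p * (1 - p))
        assert abs(tr["n_multimer_pos"] - n * p) <= 3 * sd

    def test_high_frequency_preset_cd8_ratio(self):
        t = donor("519-EBV", 100_000, seed=4)
        tr = true_frequencies(t)
        n, p = tr["n_cd8"], 0.0533
        sd = np.sqrt(n * p * (1 - p))
        assert abs(tr["n_multimer_pos"] - n * p) <= 3 * sd

    def test_reproducible_by_seed(self):
        a = donor("519-FLU", 5_000, seed=5)
        b = donor("519-FLU", 5_000, seed=5)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_doublets_sit_near_double_fsc_a(self):
        t = donor("519-EBV", 100_000, seed=6)
        dbl = t.labels == "doublet"
        sgl = np.isin(t.labels, list(LIVE_SINGLE_LABELS))
        ratio_dbl = (t.get_role("FSC-A")[dbl] / t.get_role("FSC-H")[dbl]).mean()
        ratio_sgl = (t.get_role("FSC-A")[sgl] / t.get_role("FSC-H")[sgl]).mean()
        assert ratio_dbl == pytest.approx(2.0, rel=0.05)
        assert ratio_sgl == pytest.approx(1.0 / 0.95, rel=0.05)

    def test_lognormal_medians_track_configured_means(self):
        # at n = 1e5, per-population channel medians should match the
        # configured mean * exp(-sigma^2/2) within 3 standard errors
        t = donor("519-EBV", 100_000, seed=7)
        pop = "CD8pos_multimer_neg"
        mask = t.labels == pop
        for role in ("CD3", "CD8"):
            mean, cv = CHANNEL_MODELS[pop][role]
            sigma2 = np.log1p(cv**2)
            med_expected = mean * np.exp(-sigma2 / 2)
            med = np.median(t.get_role(role)[mask])
            # ~20k events: the median's 3-SE band is well under 2% relative
            assert med == pytest.approx(med_expected, rel=0.02)

    def test_panel_without_multimer_rejected(self):
        with pytest.raises(ValueError, match="multimer"):
            LabProfile(panel=("viability", "CD3", "CD8"))

    def test_gain_shift_scales_channel(self):
        pops = preset_populations("519-EBV")
        shifted = LabProfile(gain_shift={"CD8": 2.0},
                             panel=("viability", "CD3", "CD8", "multimer-PE"))
        plain = LabProfile(panel=("viability", "CD3", "CD8", "multimer-PE"))
        a = simulate_donor(pops, shifted, 50_000, seed=8)
        b = simulate_donor(pops, plain, 50_000, seed=8)
        ratio = a.get_role("CD8").mean() / b.get_role("CD8").mean()
        assert ratio == pytest.approx(2.0, rel=0.05)


class TestPanelPopulations:
    def test_fractions_sum_to_one(self):
        for kwargs in ({"multimer_pct_lsl": 1.7}, {"multimer_pct_cd8": 5.33}):
            specs = panel_populations(**kwargs)
            assert sum(p.fraction for p in specs) == pytest.approx(1.0, abs=1e-12)

    def test_cd8_parameterization_consistent(self):
        specs = panel_populations(multimer_pct_cd8=4.0)
        frac = {p.name: p.fraction for p in specs}
        cd8_total = frac["CD8pos_multimer_neg"] + frac["CD8pos_multimer_pos"]
        assert frac["CD8pos_multimer_pos"] / cd8_total == pytest.approx(0.04)

    def test_both_parameterizations_rejected(self):
        with pytest.raises(ValueError, match="exactly one"):
            panel_populations(multimer_pct_lsl=1.0, multimer_pct_cd8=1.0)


class TestTheoreticalFrequency:
    def test_first_step_is_f0(self):
        d = SpikeInDesign(f0=1.7, dilution_factor=5, n_steps=7)
        assert theoretical_frequency(d, 1) == 1.7

    def test_closed_form_twofold(self):
        d = SpikeInDesign(f0=0.87, dilution_factor=2, n_steps=9)
        assert theoretical_frequency(d, 4) == pytest.approx(0.10875, abs=1e-12)

    def test_strictly_decreasing_in_k(self):
        d = SpikeInDesign(f0=1.7, dilution_factor=5, n_steps=7)
        freqs = [theoretical_frequency(d, k) for k in range(1, 8)]
        assert all(a > b for a, b in zip(freqs, freqs[1:]))

    def test_out_of_range_step_rejected(self):
        d = SpikeInDesign(f0=1.7, dilution_factor=5, n_steps=7)
        with pytest.raises(IndexError):
            theoretical_frequency(d, 8)
        with pytest.raises(IndexError):
            theoretical_frequency(d, 0)


@pytest.fixture(scope="module")
def donors():
    pos = donor("spikein1-positive", 50_000, seed=10)
    neg = donor("spikein1-negative", 50_000, seed=11)
    return pos, neg


class TestMixSpikein:
    def test_pure_positive_fraction(self, donors):
        pos, neg = donors
        out = mix_spikein(pos, neg, 1.0, 20_000, seed=0)
        assert (out.source_index == 1).all()

    def test_output_size_exact(self, donors):
        pos, neg = donors
        out = mix_spikein(pos, neg, 0.3, 12_345, seed=1)
        assert out.n_events == 12_345

    def test_diluted_multimer_frequency(self, donors):
        # 20% of a 1.7% donor -> 0.34% of live single lymphocytes
        pos, neg = donors
        out = mix_spikein(pos, neg, 0.2, 200_000, seed=2)
        tr = true_frequencies(out)
        n, p = tr["n_live_single"], 0.0034
        sd = np.sqrt(n * p * (1 - p))
        assert abs(tr["n_multimer_pos"] - n * p) <= 3 * sd

    def test_channel_mismatch_rejected(self, donors):
        pos, _ = donors
        other = donor("519-EBV", 1_000, seed=12)  # different panel
        with pytest.raises(ChannelMismatchError):
            mix_spikein(pos, other, 0.5, 100, seed=0)


class TestDilutionSeries:
    def test_fivefold_series_shape_and_order(self):
        pos = donor("spikein1-positive", 20_000, seed=13)
        neg = donor("spikein1-negative", 20_000, seed=14)
        design = SpikeInDesign(f0=1.7, dilution_factor=5, n_steps=7,
                               n_events_per_sample=5_000, duplicates=2, seed=1)
        series = make_dilution_series(design, pos, neg)
        assert len(series) == 14
        theos = [s.theoretical_pct for s in series[::2]]
        assert all(a > b for a, b in zip(theos, theos[1:]))
        assert series[0].theoretical_pct == 1.7

    def test_pure_negative_appended(self):
        pos = donor("spikein2-positive", 10_000, seed=15)
        neg = donor("spikein2-negative", 10_000, seed=16)
        design = SpikeInDesign(f0=0.87, dilution_factor=2, n_steps=3,
                               n_events_per_sample=4_000, duplicates=1,
                               include_pure_negative=True, seed=2)
        series = make_dilution_series(design, pos, neg)
        last = series[-1]
        assert last.theoretical_pct == 0.0
        assert (last.table.labels == MULTIMER_LABEL).sum() == 0
        assert (last.table.source_index == 0).all()

    def test_duplicates_differ_in_realized_events(self):
        pos = donor("spikein1-positive", 20_000, seed=17)
        neg = donor("spikein1-negative", 20_000, seed=18)
        design = SpikeInDesign(f0=1.7, dilution_factor=5, n_steps=1,
                               n_events_per_sample=10_000, duplicates=2, seed=3)
        a, b = make_dilution_series(design, pos, neg)
        assert a.theoretical_pct == b.theoretical_pct
        assert a.seed != b.seed
        assert not np.array_equal(a.table.values, b.table.values)
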