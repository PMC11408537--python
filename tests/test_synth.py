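"""Generator contracts: layout geometry, map separation, dwell-time bounds,
coverage convergence, modality-specific signal properties, event bookkeeping
and determinism."""

import numpy as np
import pytest

from megms import synth
from megms.containers import MicrostateSet
from megms.errors import GenerationError, InvalidArgumentError
from megms.fit import backfit, extract_segments


class TestLayout:
    def test_too_few_channels_rejected(self):
        with pytest.raises(InvalidArgumentError):
            synth.make_layout(7)

    def test_eight_channels_have_six_neighbors(self):
        lay = synth.make_layout(8, seed=0)
        assert lay.neighbor_table.shape == (8, 6)
        for c, row in enumerate(lay.neighbor_table):
            assert c not in row
            assert len(set(row)) == 6

    def test_determinism(self):
        a = synth.make_layout(20, seed=42)
        b = synth.make_layout(20, seed=42)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.neighbor_table, b.neighbor_table)

    def test_neighbors_match_exhaustive_distance_sort(self):
        """Brute-force oracle: listed neighbors are the 6 smallest distances."""
        lay = synth.make_layout(64, seed=3)
        for c in range(64):
            d = [
                (np.linalg.norm(lay.positions[c] - lay.positions[j]), j)
                for j in range(64)
                if j != c
            ]
            expected = {j for _, j in sorted(d)[:6]}
            assert set(lay.neighbor_table[c]) == expected


class TestTopographies:
    def test_eeg_maps_average_referenced(self, layout32):
        maps = synth.make_topographies(2, layout32, "eeg", seed=1)
        assert np.all(np.abs(maps.mean(axis=1)) < 1e-12)

    def test_meg_maps_nonnegative(self, layout32):
        maps = synth.make_topographies(6, layout32, "meg", seed=2)
        assert maps.min() >= 0

    @pytest.mark.parametrize("mode", ["meg", "eeg"])
    def test_pairwise_separation(self, layout32, mode):
        maps = synth.make_topographies(6, layout32, mode, seed=3)
        S = maps @ maps.T
        off = np.abs(S[~np.eye(6, dtype=bool)])
        assert off.max() <= 0.7 + 1e-12

    def test_unsatisfiable_separation_raises(self, layout32):
        with pytest.raises(GenerationError):
            synth.make_topographies(8, layout32, "meg", seed=4,
                                    max_abs_cosine=0.01, max_retries=20)


class TestResting:
    def test_noiseless_backfit_recovers_labels(self, layout32, meg_maps):
        rec, gt = synth.simulate_resting(
            layout32, meg_maps, 10.0, 250.0, snr=np.inf, seed=5
        )
        seg = backfit(rec, MicrostateSet(meg_maps, "meg"), threshold=0.5)
        active = gt.envelope > 0.05  # frames with usable signal power
        assert np.array_equal(seg.labels[active], gt.label_sequence[active])

    def test_dwell_runs_within_bounds(self, layout32, meg_maps):
        _, gt = synth.simulate_resting(
            layout32, meg_maps, 60.0, 250.0, dwell_ms_range=(50, 150), seed=6
        )
        lo_f, hi_f = round(50 * 0.25), round(150 * 0.25)
        for _, _, length in extract_segments(gt.label_sequence):
            assert lo_f <= length <= hi_f

    def test_two_state_coverage_within_sampling_error(self, layout32):
        maps = synth.make_topographies(2, layout32, "meg", seed=7)
        covs = []
        for s in range(20):
            _, gt = synth.simulate_resting(
                layout32, maps, 300.0, 250.0, coverage_weights=(0.5, 0.5),
                seed=100 + s,
            )
            covs.append(np.mean(gt.label_sequence == 1))
        # with ~3000 runs per draw, binomial error keeps each within +-0.05
        assert all(abs(c - 0.5) < 0.05 for c in covs)

    def test_coverage_converges_at_long_duration(self, layout32, meg_maps):
        w = np.array([0.4, 0.3, 0.2, 0.1])
        _, gt = synth.simulate_resting(
            layout32, meg_maps, 600.0, 250.0, coverage_weights=w, seed=8
        )
        emp = np.array([np.mean(gt.label_sequence == m) for m in (1, 2, 3, 4)])
        assert np.all(np.abs(emp - w) < 0.03)

    def test_modality_signal_contracts(self, layout32, meg_maps, eeg_maps):
        rec_meg, _ = synth.simulate_resting(
            layout32, meg_maps, 5.0, 250.0, mode="meg", seed=9
        )
        assert rec_meg.data.min() >= 0
        rec_eeg, _ = synth.simulate_resting(
            layout32, eeg_maps, 5.0, 250.0, mode="eeg", seed=9
        )
        assert np.abs(rec_eeg.data.mean(axis=0)).max() < 1e-9

    def test_same_seed_bit_identical(self, layout32, meg_maps):
        a, _ = synth.simulate_resting(layout32, meg_maps, 5.0, 250.0, seed=10)
        b, _ = synth.simulate_resting(layout32, meg_maps, 5.0, 250.0, seed=10)
        assert np.array_equal(a.data, b.data)

    def test_degenerate_weights_rejected(self, layout32, meg_maps):
        with pytest.raises(InvalidArgumentError):
            synth.simulate_resting(
                layout32, meg_maps, 5.0, 250.0, coverage_weights=(0, 0, 0, 0)
            )


class TestEvoked:
    def test_oddball_bookkeeping(self, layout32, meg_maps):
        _, events, _ = synth.simulate_evoked(
            layout32, meg_maps, n_std=612, n_dev=55, seed=11, snr=np.inf
        )
        assert events.n_events == 667
        assert (np.asarray(events.types) == "deviant").sum() == 55
        # every deviant is preceded by a flagged standard
        assert events.std_preceding_deviant.sum() == 55

    def test_full_boost_forces_deviant_state_in_window(self, layout32, meg_maps):
        rec, events, gt = synth.simulate_evoked(
            layout32, meg_maps, n_std=40, n_dev=8, deviant_state=2,
            boost=1.0, snr=np.inf, seed=12,
        )
        fs = rec.fs
        lo = int(np.ceil(150 * fs / 1000))
        hi = int(np.floor(300 * fs / 1000))
        dev_onsets = events.onsets[np.asarray(events.types) == "deviant"]
        for onset in dev_onsets:
            assert np.all(gt.label_sequence[onset + lo: onset + hi + 1] == 2)

    def test_zero_boost_is_null(self, layout32, meg_maps):
        """Monte-Carlo null: without a boost the in-window deviant-standard
        prevalence difference of the target state averages to ~0."""
        diffs = []
        for s in range(50):
            _, events, gt = synth.simulate_evoked(
                layout32, meg_maps, n_std=30, n_dev=6, deviant_state=2,
                boost=0.0, snr=np.inf, seed=300 + s,
            )
            fs = 250.0
            lo, hi = int(np.ceil(150 * fs / 1000)), int(np.floor(300 * fs / 1000))
            rates = {}
            for typ in ("standard", "deviant"):
                onsets = events.onsets[np.asarray(events.types) == typ]
                win = np.concatenate(
                    [gt.label_sequence[o + lo: o + hi + 1] for o in onsets]
                )
                rates[typ] = np.mean(win == 2)
            diffs.append(rates["deviant"] - rates["standard"])
        assert abs(np.mean(diffs)) < 0.02


class TestParcels:
    def test_injected_effect_raises_labeled_mean(self, layout32, meg_maps):
        _, gt = synth.simulate_resting(layout32, meg_maps, 60.0, 250.0, seed=13)
        noise_sd = 0.2
        ps = synth.simulate_parcels(
            gt.label_sequence, 10, [(3, 2, 5 * noise_sd)],
            noise_sd=noise_sd, seed=14,
        )
        sel = gt.label_sequence == 2
        assert ps.values[3, sel].mean() > ps.values[3, ~sel].mean() + 3 * noise_sd / 10

    def test_unknown_state_rejected(self, layout32, meg_maps):
        _, gt = synth.simulate_resting(layout32, meg_maps, 5.0, 250.0, seed=15)
        with pytest.raises(InvalidArgumentError):
            synth.simulate_parcels(gt.label_sequence, 4, [(0, 99, 1.0)])

    def test_determinism(self, layout32, meg_maps):
        _, gt = synth.simulate_resting(layout32, meg_maps, 5.0, 250.0, seed=16)
        a = synth.simulate_parcels(gt.label_sequence, 4, seed=17)
        b = synth.simulate_parcels(gt.label_sequence, 4, seed=17)
        assert np.array_equal(a.values, b.values)


class TestPairedModalities:
    def test_full_coupling_shares_label_sequence(self, layout32, meg_maps, eeg_maps):
        _, _, (gt_m, gt_e) = synth.simulate_paired_modalities(
            layout32, layout32, meg_maps, eeg_maps, 20.0, 250.0,
            coupling=1.0, seed=18,
        )
        assert np.array_equal(gt_m.label_sequence, gt_e.label_sequence)

    def test_zero_coupling_independent(self, layout32, meg_maps, eeg_maps):
        _, _, (gt_m, gt_e) = synth.simulate_paired_modalities(
            layout32, layout32, meg_maps, eeg_maps, 60.0, 250.0,
            coupling=0.0, seed=19,
        )
        agree = np.mean(gt_m.label_sequence == gt_e.label_sequence)
        assert agree < 0.4  # chance is 1/K = 0.25 for K=4

    def test_determinism(self, layout32, meg_maps, eeg_maps):
        a = synth.simulate_paired_modalities(
            layout32, layout32, meg_maps, eeg_maps, 5.0, 250.0, seed=20
        )
        b = synth.simulate_paired_modalities(
            layout32, layout32, meg_maps, eeg_maps, 5.0, 250.0, seed=20
        )
        assert np.array_equal(a[0].data, b[0].data)
        assert np.array_equal(a[1].data, b[1].data)
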