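import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ecog_biomarkers.connectivity import (
    BinaryBurstSeries,
    binarize_bursts,
    channel_ec,
    ec_matrix,
    transfer_entropy,
)

FS = 1000.0


def te_oracle(x, y):
    """Independent exhaustive-enumeration plug-in TE (k = 1), via explicit dict counts."""
    triplets = [(int(y[t + 1]), int(y[t]), int(x[t])) for t in range(len(x) - 1)]
    n = len(triplets)
    c_fhx, c_hx, c_fh, c_h = {}, {}, {}, {}
    for f, h, s in triplets:
        c_fhx[(f, h, s)] = c_fhx.get((f, h, s), 0) + 1
        c_hx[(h, s)] = c_hx.get((h, s), 0) + 1
        c_fh[(f, h)] = c_fh.get((f, h), 0) + 1
        c_h[h] = c_h.get(h, 0) + 1
    te = 0.0
    for (f, h, s), cnt in c_fhx.items():
        p = cnt / n
        ratio = (cnt / c_hx[(h, s)]) / (c_fh[(f, h)] / c_h[h])
        te += p * math.log2(ratio)
    return max(te, 0.0)


class TestTransferEntropyOracle:
    def test_exhaustive_length_six(self):
        """Plug-in TE equals the enumeration oracle on every pair of length-6 sequences."""
        seqs = [np.array(bits, dtype=float) for bits in itertools.product((0, 1), repeat=6)]
        for x in seqs[:: 4]:  # every 4th source sequence: 16 x 64 = 1024 pairs
            for y in seqs:
                if np.all(y[1:] == y[1]):
                    continue  # constant-future destinations degenerate to 0 by contract
                assert transfer_entropy(x, y, min_triplets=1) == pytest.approx(
                    te_oracle(x, y), abs=1e-12
                )

    def test_random_length_twelve(self, rng):
        for _ in range(50):
            x = rng.integers(0, 2, 12).astype(float)
            y = rng.integers(0, 2, 12).astype(float)
            if np.all(y[1:] == y[1]):
                continue
            assert transfer_entropy(x, y, min_triplets=1) == pytest.approx(
                te_oracle(x, y), abs=1e-12
            )


class TestClosedForms:
    def test_identity_map_one_bit(self, rng):
        x = rng.integers(0, 2, 10_001).astype(float)
        y = np.concatenate([[0.0], x[:-1]])
        assert transfer_entropy(x, y) == pytest.approx(1.0, abs=0.01)

    def test_ten_percent_flip(self, rng):
        x = rng.integers(0, 2, 10_001).astype(float)
        y = np.concatenate([[0.0], x[:-1]])
        flip = rng.random(y.size) < 0.1
        y[flip] = 1.0 - y[flip]
        h01 = -(0.1 * math.log2(0.1) + 0.9 * math.log2(0.9))
        assert transfer_entropy(x, y) == pytest.approx(1.0 - h01, abs=0.01)

    def test_independent_near_zero(self, rng):
        x = rng.integers(0, 2, 100_000).astype(float)
        y = rng.integers(0, 2, 100_000).astype(float)
        assert transfer_entropy(x, y) < 0.001


class TestTransferEntropyContracts:
    def test_non_negative(self, rng):
        for _ in range(20):
            x = (rng.random(300) < 0.3).astype(float)
            y = (rng.random(300) < 0.3).astype(float)
            assert transfer_entropy(x, y, min_triplets=10) >= 0.0

    def test_constant_destination_degenerate(self, rng):
        x = rng.integers(0, 2, 200).astype(float)
        with pytest.warns(UserWarning, match="constant"):
            assert transfer_entropy(x, np.zeros(200), min_triplets=10) == 0.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="different bin grids"):
            transfer_entropy(np.zeros(10), np.zeros(11), min_triplets=1)

    def test_too_few_triplets_rejected(self, rng):
        x = rng.integers(0, 2, 30).astype(float)
        y = rng.integers(0, 2, 30).astype(float)
        with pytest.raises(ValueError, match="triplets"):
            transfer_entropy(x, y, min_triplets=50)

    def test_missing_bins_dropped_not_zeroed(self, rng):
        x = rng.integers(0, 2, 5000).astype(float)
        y = np.concatenate([[0.0], x[:-1]])
        x_nan, y_nan = x.copy(), y.copy()
        x_nan[::7] = np.nan
        # dropping triplets must keep the estimate near 1 bit (imputing 0 would not)
        assert transfer_entropy(x_nan, y_nan) == pytest.approx(1.0, abs=0.02)

    def test_history_k2_on_markov_destination(self, rng):
        """With k = 2 the destination's own order-2 memory is explained away."""
        n = 20_000
        y = np.zeros(n)
        for t in range(2, n):
            y[t] = y[t - 2] if rng.random() < 0.9 else rng.integers(0, 2)
        x = rng.integers(0, 2, n).astype(float)
        assert transfer_entropy(x, y, k=2) < 0.005


class TestBinarization:
    def test_delta_saturated(self):
        """z = 3 for 10 s: five 2-s bins, all 1."""
        bb = binarize_bursts(np.full(10_000, 3.0), FS, "delta")
        assert bb.bin_duration_s == 2.0
        np.testing.assert_array_equal(bb.bits, np.ones(5))

    def test_delta_run_too_short(self):
        """0.5 s above threshold is less than 3 cycles at 3 Hz (1 s): bin stays 0."""
        z = np.zeros(4000)
        z[1000:1500] = 3.0
        np.testing.assert_array_equal(binarize_bursts(z, FS, "delta").bits, [0.0, 0.0])

    def test_hfo_run_long_enough(self):
        """40 ms above z = 2 exceeds 3 cycles at 80 Hz (37.5 ms): its bin reads 1."""
        z = np.zeros(1500)
        z[100:140] = 2.5  # inside bin 1 (samples 75..150)
        bits = binarize_bursts(z, FS, "hfo").bits
        assert bits[1] == 1.0
        assert bits[[0, 2, 3]].sum() == 0.0

    def test_boundary_spanning_run_credits_both_bins(self):
        z = np.zeros(1500)
        z[130:170] = 2.5  # spans bins 1 and 2 (boundary at sample 150)
        bits = binarize_bursts(z, FS, "hfo").bits
        assert bits[1] == 1.0 and bits[2] == 1.0

    def test_masked_bin_missing_not_zero(self):
        z = np.full(10_000, 3.0)
        z[4100:4200] = np.nan
        bits = binarize_bursts(z, FS, "delta").bits
        assert np.isnan(bits[2])
        assert np.nansum(bits) == 4.0

    def test_exact_threshold_not_a_burst(self):
        """The rule is strictly above z = 2."""
        bits = binarize_bursts(np.full(4000, 2.0), FS, "delta").bits
        np.testing.assert_array_equal(bits, [0.0, 0.0])

    def test_epoch_shorter_than_bin_rejected(self):
        with pytest.raises(ValueError, match="shorter than one"):
            binarize_bursts(np.zeros(500), FS, "delta")

    def test_bin_at_least_six_cycles(self):
        with pytest.raises(ValueError, match="six wave-cycles"):
            BinaryBurstSeries(np.zeros(10), bin_duration_s=1.0, cycle_freq_hz=3.0, band="delta")


def _series(bits, label, band="hfo"):
    return BinaryBurstSeries(np.asarray(bits, float), 0.075, 80.0, band, label)


class TestEcMatrix:
    def test_two_channels_two_entries(self, rng):
        a = _series(rng.integers(0, 2, 200), "A1-A2")
        b = _series(rng.integers(0, 2, 200), "B1-B2")
        m = ec_matrix([a, b], min_triplets=10)
        assert np.isnan(m.te[0, 0]) and np.isnan(m.te[1, 1])
        assert np.isfinite(m.te[0, 1]) and np.isfinite(m.te[1, 0])

    def test_shared_contact_pairs_excluded(self, rng):
        a = _series(rng.integers(0, 2, 200), "A1-A2")
        b = _series(rng.integers(0, 2, 200), "A2-A3")
        c = _series(rng.integers(0, 2, 200), "A3-A4")
        m = ec_matrix([a, b, c], min_triplets=10)
        assert np.isnan(m.te[0, 1]) and np.isnan(m.te[1, 0])  # share A2
        assert np.isnan(m.te[1, 2]) and np.isnan(m.te[2, 1])  # share A3
        assert np.isfinite(m.te[0, 2]) and np.isfinite(m.te[2, 0])

    def test_grid_mismatch_rejected(self, rng):
        a = _series(rng.integers(0, 2, 200), "A1-A2")
        b = BinaryBurstSeries(rng.integers(0, 2, 200).astype(float), 2.0, 3.0, "delta", "B1-B2")
        with pytest.raises(ValueError, match="common bin grid"):
            ec_matrix([a, b])

    def test_single_channel_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            ec_matrix([_series(rng.integers(0, 2, 100), "A1-A2")])

    def test_independent_channels_near_zero(self, rng):
        series = [_series(rng.integers(0, 2, 10_000), f"E{i}1-E{i}2") for i in range(4)]
        m = ec_matrix(series)
        assert np.nanmax(m.te) < 0.005


class TestChannelEc:
    def test_constant_matrix(self):
        te = np.full((3, 3), 0.2)
        np.fill_diagonal(te, np.nan)
        from ecog_biomarkers.connectivity import EcMatrix

        mat = EcMatrix(te, ["a", "b", "c"], "hfo")
        assert (channel_ec(mat, "combined") == 0.2).all()

    def test_single_edge_arithmetic(self):
        from ecog_biomarkers.connectivity import EcMatrix

        te = np.zeros((3, 3))
        np.fill_diagonal(te, np.nan)
        te[0, 1] = 0.4
        mat = EcMatrix(te, ["a", "b", "c"], "hfo")
        assert channel_ec(mat, "efferent")["a"] == pytest.approx(0.2)
        assert channel_ec(mat, "afferent")["b"] == pytest.approx(0.2)
        assert channel_ec(mat, "combined")["a"] == pytest.approx(0.1)

    def test_combined_is_mean_of_efferent_afferent(self, rng):
        from ecog_biomarkers.connectivity import EcMatrix

        for _ in range(5):
            te = rng.random((5, 5))
            np.fill_diagonal(te, np.nan)
            mat = EcMatrix(te, list("abcde"), "hfo")
            comb = channel_ec(mat, "combined")
            eff = channel_ec(mat, "efferent")
            aff = channel_ec(mat, "afferent")
            pd.testing.assert_series_equal(
                comb, ((eff + aff) / 2).rename(comb.name), atol=1e-12
            )

    def test_unknown_mode_rejected(self, rng):
        from ecog_biomarkers.connectivity import EcMatrix

        te = rng.random((2, 2))
        with pytest.raises(ValueError, match="mode"):
            channel_ec(EcMatrix(te, ["a", "b"], "hfo"), "sideways")


class TestPlantedEdgeRecovery:
    def test_planted_edge_is_matrix_max(self):
        """A forced src->dst edge at full transmission dominates the EC matrix (>= 9/10 seeds)."""
        from ecog_biomarkers.synthetic_data import SimConfig, generate_cohort
        from ecog_biomarkers.spectral import wavelet_amplitude, zscore_to_control
        from conftest import const_map

        hits = 0
        for seed in range(10):
            sim = SimConfig(
                n_patients=1,
                n_channels_per_patient=3,
                frac_epileptogenic=0.0,
                frac_two_stage=0.0,
                forced_edges=[(0, 2)],
                stage_schedule=[("Iso", 150.0)],
                p_propagate_hfo=const_map(1.0),
                p_propagate_delta=const_map(0.0),
                burst_rate_by_stage_class=const_map(1.0),
                kappa_by_stage_class=const_map(0.2),
                seed=seed,
            )
            recs, _ = generate_cohort(sim)
            rec = recs[0]
            amp = wavelet_amplitude(rec, "hfo")
            z = zscore_to_control(amp, "Iso", [(0, int(60 * rec.fs))])
            sl = slice(int(60 * rec.fs), int(150 * rec.fs))
            series = [
                binarize_bursts(z.values[i, sl], rec.fs, "hfo", channel_label=f"E{i}")
                for i in range(3)
            ]
            m = ec_matrix(series, exclude_shared_contacts=False)
            if np.nanargmax(m.te) == np.ravel_multi_index((0, 2), m.te.shape):
                hits += 1
        assert hits >= 9
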