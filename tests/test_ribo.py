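import numpy as np
import pandas as pd
import pytest

from mrnafate.core_io import InputError
from mrnafate.ribo import (
    ProfileSet,
    apply_psite_offset,
    codon_counts,
    log2fc_counts,
    metagene_binned,
    normalized_occupancy,
    occupancy_delta,
    select_read_lengths,
    stability_groups,
    tpm,
    translational_efficiency,
)


class TestSelectReadLengths:
    def test_dominant_frame_retained(self):
        hist = {28: 1000}
        frames = {28: (0.7, 0.2, 0.1)}
        assert select_read_lengths(hist, frames) == [28]

    def test_uniform_frames_rejected(self):
        assert select_read_lengths({30: 500}, {30: (1 / 3, 1 / 3, 1 / 3)}) == []

    def test_perfect_periodicity_only_that_length(self):
        hist = {27: 100, 28: 1000, 29: 80}
        frames = {27: (0.4, 0.3, 0.3), 28: (1.0, 0.0, 0.0), 29: (0.35, 0.35, 0.3)}
        assert select_read_lengths(hist, frames) == [28]

    def test_paper_range_retained_under_threshold(self):
        lengths = range(25, 36)
        hist = {l: 100 for l in lengths}
        frames = {l: ((0.75, 0.15, 0.1) if 27 <= l <= 31 else (0.4, 0.3, 0.3)) for l in lengths}
        assert select_read_lengths(hist, frames) == [27, 28, 29, 30, 31]

    def test_empty_histogram_errors(self):
        with pytest.raises(InputError):
            select_read_lengths({}, {})


class TestPsiteOffsets:
    def test_p_site_at_plus_12(self):
        sites, dropped = apply_psite_offset([100], cds_start=0, cds_len=600)
        assert sites["P"].tolist() == [112]
        assert sites["E"].tolist() == [109] and sites["A"].tolist() == [115]

    def test_out_of_cds_dropped(self):
        sites, dropped = apply_psite_offset([595], cds_start=0, cds_len=600)
        assert sites["P"].size == 0 and dropped >= 1

    def test_epa_are_consecutive_codons(self):
        sites, _ = apply_psite_offset([90], cds_start=0, cds_len=300)
        e, p, a = sites["E"][0], sites["P"][0], sites["A"][0]
        assert (p - e, a - p) == (3, 3)

    def test_unknown_site_key_errors(self):
        with pytest.raises(InputError):
            apply_psite_offset([0], 0, 30, offsets={"X": 5})


class TestCodonCounts:
    def test_same_codon_accumulates(self):
        counts = codon_counts([0, 1, 2], cds_start=0, n_codons=10)
        assert counts[0] == 3 and counts.sum() == 3

    def test_next_codon(self):
        counts = codon_counts([3], cds_start=0, n_codons=10)
        assert counts[1] == 1

    def test_conservation(self):
        rng = np.random.default_rng(0)
        pos = rng.integers(0, 300, size=500)
        counts = codon_counts(pos, cds_start=0, n_codons=100)
        assert counts.sum() == 500


class TestTpm:
    def test_single_transcript(self):
        out = tpm(pd.Series({"a": 50}), pd.Series({"a": 1000}))
        assert out["a"] == pytest.approx(1e6)

    def test_length_adjustment(self):
        out = tpm(pd.Series({"a": 100, "b": 100}), pd.Series({"a": 1000, "b": 2000}))
        assert out["a"] == pytest.approx(666666.6667, rel=1e-6)
        assert out["b"] == pytest.approx(333333.3333, rel=1e-6)

    def test_sums_to_a_million(self):
        rng = np.random.default_rng(1)
        counts = pd.Series(rng.integers(1, 1000, 50), index=[f"t{i}" for i in range(50)])
        lengths = pd.Series(rng.integers(300, 3000, 50), index=counts.index)
        assert tpm(counts, lengths).sum() == pytest.approx(1e6)


class TestNormalizedOccupancy:
    def test_library_size_invariance(self):
        counts = np.array([1.0, 2, 3])
        a = normalized_occupancy(counts, 1e6, 5.0)
        b = normalized_occupancy(2 * counts, 2e6, 5.0)
        assert np.allclose(a, b)

    def test_doubling_tpm_halves_rates(self):
        counts = np.array([4.0, 8.0])
        assert np.allclose(
            normalized_occupancy(counts, 1e6, 10.0),
            2 * normalized_occupancy(counts, 1e6, 20.0),
        )

    def test_zero_library_errors(self):
        with pytest.raises(InputError):
            normalized_occupancy(np.ones(3), 0, 1.0)


class TestOccupancyDelta:
    def _profile_set(self, ctrl, kd):
        ps = ProfileSet()
        for rep, (c, k) in enumerate(zip(ctrl, kd), 1):
            ps.add("tx", "ctrl", f"r{rep}", np.asarray(c, float))
            ps.add("tx", "kd", f"r{rep}", np.asarray(k, float))
        return ps

    def test_identity_zero(self):
        arr = [1.0, 2, 3]
        deltas = occupancy_delta(self._profile_set([arr] * 3, [arr] * 3))
        assert np.allclose(deltas["tx"], 0.0)

    def test_doubling(self):
        arr = np.array([1.0, 2, 3])
        deltas = occupancy_delta(self._profile_set([arr] * 3, [2 * arr] * 3))
        assert np.allclose(deltas["tx"], arr)

    def test_replicate_averaging(self):
        base = np.zeros(3)
        kd = [base + 1, base, base - 1]
        deltas = occupancy_delta(self._profile_set([base] * 3, kd))
        assert np.allclose(deltas["tx"], 0.0)

    def test_replicate_mismatch_errors(self):
        ps = ProfileSet()
        ps.add("tx", "ctrl", "r1", np.ones(3))
        ps.add("tx", "kd", "r2", np.ones(3))
        with pytest.raises(InputError):
            occupancy_delta(ps)


class TestMetagene:
    def test_bin_edges_at_120_codons(self):
        from mrnafate.seqfeat import positional_bins

        bins = positional_bins(120, 40)
        assert np.all(np.bincount(bins) == 3)
        assert bins[119] == 39

    def test_zero_deltas_zero_medians(self):
        deltas = {f"t{i}": np.zeros(120) for i in range(5)}
        med = metagene_binned(deltas, deltas.keys(), 40)
        assert np.allclose(med, 0.0)

    def test_five_prime_ramp_down_shape(self):
        rng = np.random.default_rng(0)
        deltas = {}
        for i in range(50):
            L = rng.integers(100, 300)
            d = rng.normal(0, 0.05, L)
            d[: L // 10] -= 1.0
            deltas[f"t{i}"] = d
        med = metagene_binned(deltas, deltas.keys(), 40)
        assert med[:4].max() < med[10:].min()

    def test_empty_group_errors(self):
        with pytest.raises(InputError):
            metagene_binned({}, [], 40)


class TestLog2fcCounts:
    def _counts(self, kd_mean, ctrl_mean, n=1):
        data = {f"kd_{i}": [kd_mean] * n for i in range(3)}
        data.update({f"ctrl_{i}": [ctrl_mean] * n for i in range(3)})
        return pd.DataFrame(data, index=[f"t{i}" for i in range(n)])

    def test_equal_means_zero(self):
        counts = self._counts(50, 50)
        out = log2fc_counts(counts, [c for c in counts if c.startswith("kd")],
                            [c for c in counts if c.startswith("ctrl")])
        assert np.allclose(out, 0.0)

    def test_pseudocounted_arithmetic(self):
        counts = self._counts(20, 10)
        out = log2fc_counts(counts, [c for c in counts if c.startswith("kd")],
                            [c for c in counts if c.startswith("ctrl")])
        # size factors equalize the two conditions around the geometric mean,
        # so the normalized means are 20/sqrt(2) and 10*sqrt(2)
        assert out.iloc[0] == pytest.approx(
            np.log2((20 / np.sqrt(2) + 0.5) / (10 * np.sqrt(2) + 0.5))
        )

    def test_low_count_filter(self):
        counts = pd.DataFrame(
            {"kd_0": [5, 50], "kd_1": [5, 50], "kd_2": [5, 50],
             "ctrl_0": [5, 50], "ctrl_1": [5, 50], "ctrl_2": [5, 50]},
            index=["low", "high"],
        )
        out = log2fc_counts(counts, ["kd_0", "kd_1", "kd_2"], ["ctrl_0", "ctrl_1", "ctrl_2"])
        assert list(out.index) == ["high"]

    def test_planted_twofold_subset_recovered(self):
        # median-of-ratios anchors on the unchanged majority, so a 2-fold
        # change planted in a 20% subset is recovered on that subset
        rng = np.random.default_rng(3)
        n = 500
        base = rng.lognormal(5, 1, n)
        fold = np.where(np.arange(n) < 100, 2.0, 1.0)
        data = {}
        for i in range(3):
            data[f"ctrl_{i}"] = rng.poisson(base)
            data[f"kd_{i}"] = rng.poisson(fold * base)
        counts = pd.DataFrame(data, index=[f"t{i}" for i in range(n)])
        out = log2fc_counts(counts, [f"kd_{i}" for i in range(3)], [f"ctrl_{i}" for i in range(3)])
        planted = out[[f"t{i}" for i in range(100) if f"t{i}" in out.index]]
        rest = out[[i for i in out.index if i not in planted.index]]
        assert abs(planted.mean() - 1.0) < 0.1
        assert abs(rest.mean()) < 0.1


class TestTranslationalEfficiency:
    @pytest.mark.parametrize(
        "rpf,rna,te,label",
        [
            (1.0, 0.4, 0.6, "increased"),
            (0.3, 0.28, 0.02, "none"),
            (0.15, 0.0, 0.15, "unclassified"),
            (-0.5, 0.1, -0.6, "decreased"),
        ],
    )
    def test_thresholds(self, rpf, rna, te, label):
        out = translational_efficiency(pd.Series({"t": rpf}), pd.Series({"t": rna}))
        assert out.loc["t", "log2fc_te"] == pytest.approx(te)
        assert out.loc["t", "te_class"] == label

    def test_identity_identical_tables(self):
        rng = np.random.default_rng(0)
        fc = pd.Series(rng.normal(size=100), index=[f"t{i}" for i in range(100)])
        out = translational_efficiency(fc, fc.copy())
        assert np.allclose(out["log2fc_te"], 0.0)
        assert (out["te_class"] == "none").all()

    def test_te_identity_holds(self):
        rng = np.random.default_rng(1)
        idx = [f"t{i}" for i in range(50)]
        rpf = pd.Series(rng.normal(size=50), index=idx)
        rna = pd.Series(rng.normal(size=50), index=idx)
        out = translational_efficiency(rpf, rna)
        assert np.allclose(out["log2fc_te"], out["log2fc_rpf"] - out["log2fc_rna"], atol=1e-9)


class TestStabilityGroups:
    def test_median_split_halves(self):
        idx = [f"t{i}" for i in range(40)]
        te_class = pd.Series(["increased"] * 40, index=idx)
        hl = pd.Series(np.arange(40, dtype=float), index=idx)
        labels = stability_groups(te_class, hl)
        high = labels.str.contains("high").sum()
        low = labels.str.contains("low").sum()
        assert abs(high - low) <= 1

    def test_cross_labels(self):
        te_class = pd.Series({"a": "increased", "b": "none", "c": "decreased", "d": "unclassified"})
        hl = pd.Series({"a": 3.0, "b": 1.0, "c": 0.2, "d": 2.0})
        labels = stability_groups(te_class, hl, split=1.5)
        assert labels["a"] == "increased-TE/high-stability"
        assert labels["b"] == "none-TE/low-stability"
        assert labels["c"] == "decreased-TE/low-stability"
        assert pd.isna(labels["d"])
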