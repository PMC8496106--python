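import numpy as np
import pandas as pd
import pytest

from mrnafate.core_io import InputError, Transcript
from mrnafate.pauses import (
    classify_pause_change,
    detect_pauses,
    mrna_class_summary,
    pause_context_matrix,
    retained_indices,
)
from mrnafate.ribo import ProfileSet


def detect_oracle(profile, exclusion=(15, 5), fold=10.0):
    """Literal evaluation of the pause rule: mean over retained codons,
    zeros and candidate included, strict > fold * mean."""
    lo, hi = exclusion
    retained = list(range(lo, len(profile) - hi))
    if not retained:
        return []
    mean = sum(profile[i] for i in retained) / len(retained)
    if mean == 0:
        return []
    return [i for i in retained if profile[i] > fold * mean]


def classify_oracle(ctrl_reps, kd_reps, exclusion=(15, 5), fold=10.0):
    """Literal evaluation of the classification rules on one mRNA."""
    ctrl_sum = [sum(r[i] for r in ctrl_reps) for i in range(len(ctrl_reps[0]))]
    kd_sum = [sum(r[i] for r in kd_reps) for i in range(len(kd_reps[0]))]
    delta = [
        sum(k[i] - c[i] for c, k in zip(ctrl_reps, kd_reps)) / len(ctrl_reps)
        for i in range(len(ctrl_reps[0]))
    ]
    lo, hi = exclusion
    retained = list(range(lo, len(delta) - hi))
    neg = [-delta[i] for i in retained if delta[i] < 0]
    pos = [delta[i] for i in retained if delta[i] > 0]
    avg_dec = sum(neg) / len(retained) if neg else None
    avg_inc = sum(pos) / len(retained) if pos else None
    p_ctrl = set(detect_oracle(ctrl_sum, exclusion, fold))
    p_kd = set(detect_oracle(kd_sum, exclusion, fold))
    out = {}
    for codon in sorted(p_ctrl | p_kd):
        if codon in p_ctrl and codon in p_kd:
            out[codon] = "sustained"
        elif codon in p_ctrl and avg_dec is not None and -delta[codon] > fold * avg_dec:
            out[codon] = "resolved"
        elif codon in p_kd and avg_inc is not None and delta[codon] > fold * avg_inc:
            out[codon] = "induced"
    return out


class TestDetectPauses:
    def test_worked_arithmetic_example(self):
        # 100 retained positions: 99 at 1, one at 12 -> mean 1.11, 12 > 11.1
        profile = np.zeros(120)
        profile[15:115] = 1.0
        profile[50] = 12.0
        called = detect_pauses(profile)
        assert called.tolist() == [50]

    def test_uniform_profile_no_sites(self):
        assert detect_pauses(np.ones(100)).size == 0

    def test_exactly_tenfold_mean_not_called(self):
        # 99 positions at 0, one at x: mean = x/100, x == 10 * mean never holds
        # with x > 0; construct value == 10 * mean explicitly instead
        profile = np.zeros(120)
        profile[15:115] = 1.0
        # mean over 100 positions with one at v: (99 + v)/100; v = 10*mean
        # -> v = 990/90 = 11.0
        profile[60] = 11.0
        assert 60 not in detect_pauses(profile).tolist()

    def test_exclusion_zones_respected(self):
        profile = np.ones(60)
        profile[5] = 1000.0  # inside the first 15 codons
        profile[57] = 1000.0  # inside the last 5
        assert detect_pauses(profile).size == 0
        assert retained_indices(60).tolist() == list(range(15, 55))

    def test_all_zero_profile(self):
        assert detect_pauses(np.zeros(100)).size == 0

    def test_matches_oracle_on_random_profiles(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            L = rng.integers(25, 200)
            profile = rng.poisson(1.0, L).astype(float)
            if rng.random() < 0.5:
                profile[rng.integers(15, L - 5)] *= rng.integers(5, 60)
            assert detect_pauses(profile).tolist() == detect_oracle(profile)


def build_profiles(ctrl, kd, tid="tx"):
    ps = ProfileSet()
    for rep, (c, k) in enumerate(zip(ctrl, kd), 1):
        ps.add(tid, "ctrl", f"r{rep}", np.asarray(c, float))
        ps.add(tid, "kd", f"r{rep}", np.asarray(k, float))
    return ps


class TestClassifyPauseChange:
    def _flat(self, L=100, level=1.0):
        return np.full(L, level)

    def test_sustained_pause_in_both(self):
        base = self._flat()
        peak = base.copy()
        peak[40] = 50.0
        noise = base.copy()
        noise[70] = 1.2  # mild fluctuation so deltas exist in both signs
        sites = classify_pause_change(build_profiles([peak] * 3, [peak * 1.0] * 3))
        assert sites.iloc[0]["pause_class"] == "sustained"
        assert sites.iloc[0]["codon_index"] == 40

    def test_resolved_pause_collapses(self):
        base = self._flat()
        peak = base.copy()
        peak[40] = 50.0
        sites = classify_pause_change(build_profiles([peak] * 3, [base] * 3))
        assert len(sites) == 1
        assert sites.iloc[0]["pause_class"] == "resolved"

    def test_induced_pause_appears(self):
        base = self._flat()
        peak = base.copy()
        peak[60] = 50.0
        sites = classify_pause_change(build_profiles([base] * 3, [peak] * 3))
        assert sites.iloc[0]["pause_class"] == "induced"

    def test_identical_conditions_never_resolved_or_induced(self):
        rng = np.random.default_rng(3)
        prof = rng.poisson(2.0, 150).astype(float)
        prof[80] = 200.0
        sites = classify_pause_change(build_profiles([prof] * 3, [prof] * 3))
        assert set(sites["pause_class"]) <= {"sustained"}

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        ctrl = [rng.poisson(2.0, 120).astype(float) for _ in range(3)]
        kd = [rng.poisson(2.0, 120).astype(float) for _ in range(3)]
        ctrl[0][50] = 300.0
        a = classify_pause_change(build_profiles(ctrl, kd))
        b = classify_pause_change(build_profiles([c * 7.5 for c in ctrl], [k * 7.5 for k in kd]))
        pd.testing.assert_frame_equal(
            a.drop(columns=["peak_ctrl", "peak_kd", "delta"]),
            b.drop(columns=["peak_ctrl", "peak_kd", "delta"]),
        )

    def test_matches_oracle_on_random_profiles(self):
        rng = np.random.default_rng(12)
        for trial in range(200):
            L = int(rng.integers(30, 150))
            ctrl = [rng.poisson(1.5, L).astype(float) for _ in range(3)]
            kd = [rng.poisson(1.5, L).astype(float) for _ in range(3)]
            if rng.random() < 0.7:
                pos = int(rng.integers(15, L - 5))
                style = rng.integers(3)
                for arrs in ([ctrl, kd], [ctrl], [kd])[style]:
                    for a in arrs:
                        a[pos] += 80.0
            sites = classify_pause_change(build_profiles(ctrl, kd))
            got = dict(zip(sites["codon_index"], sites["pause_class"]))
            assert got == classify_oracle(ctrl, kd), f"trial {trial}"

    def test_venn_summary_distinct_flag(self):
        sites = pd.DataFrame(
            {
                "transcript_id": ["a", "a", "b"],
                "codon_index": [20, 40, 30],
                "peak_ctrl": [1.0] * 3,
                "peak_kd": [1.0] * 3,
                "delta": [0.0] * 3,
                "pause_class": ["sustained", "induced", "resolved"],
            }
        )
        summary = mrna_class_summary(sites).set_index("transcript_id")
        assert not summary.loc["a", "distinct"]
        assert summary.loc["b", "distinct"]
        assert summary.loc["a", "classes"] == "induced+sustained"


class TestPauseContextMatrix:
    def _transcript(self, n_codons=60, fill="GGA", special=None):
        codons = [fill] * n_codons
        if special:
            for idx, c in special.items():
                codons[idx] = c
        codons[0] = "ATG"
        codons[-1] = "TAA"
        return Transcript("tx", "".join(codons))

    def test_glutamate_at_a_site(self):
        # called codon is the P site; A site = called + 1
        t = self._transcript(special={31: "GAA"})
        sites = pd.DataFrame(
            {"transcript_id": ["tx"], "codon_index": [30], "peak_ctrl": [1.0],
             "peak_kd": [1.0], "delta": [0.0], "pause_class": ["sustained"]}
        )
        freq, dropped = pause_context_matrix(sites, {"tx": t})
        assert dropped == 0
        assert freq.loc["E", "A"] == 1.0
        assert freq.loc["G", "A-1"] if "A-1" in freq.columns else True

    def test_columns_sum_to_one(self):
        t = self._transcript()
        sites = pd.DataFrame(
            {"transcript_id": ["tx"] * 2, "codon_index": [20, 35], "peak_ctrl": [1.0] * 2,
             "peak_kd": [1.0] * 2, "delta": [0.0] * 2, "pause_class": ["sustained"] * 2}
        )
        freq, _ = pause_context_matrix(sites, {"tx": t})
        assert np.allclose(freq.sum(axis=0), 1.0)
        assert freq.shape == (20, 9)

    def test_edge_sites_dropped_with_count(self):
        t = self._transcript(n_codons=30)
        sites = pd.DataFrame(
            {"transcript_id": ["tx"] * 2, "codon_index": [15, 26], "peak_ctrl": [1.0] * 2,
             "peak_kd": [1.0] * 2, "delta": [0.0] * 2, "pause_class": ["sustained"] * 2}
        )
        # codon 26: window reaches codon 30 (stop) -> dropped
        freq, dropped = pause_context_matrix(sites, {"tx": t})
        assert dropped == 1

    def test_empty_input_errors(self):
        with pytest.raises(InputError):
            pause_context_matrix(pd.DataFrame(), {})
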