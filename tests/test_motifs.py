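"""Motif enrichment tests, incl. a brute-force PWM offset-enumeration oracle."""

import math

import numpy as np
import pytest
from scipy import stats

from devsplice.motifs import (
    ALL_HEXAMERS,
    PWM,
    annotate_hexamers,
    combined_enrichment,
    hexamer_fisher,
    hexamer_scan,
    irwin_hall_cdf,
    irwin_hall_combine,
    positional_profile,
    pwm_hexamer_prob,
    read_pwm_file,
    resampled_enrichment,
)

NUC_IDX = {c: k for k, c in enumerate("ACGT")}


def oracle_pwm_prob(hexamer, freqs):
    """Independent offset enumeration of the hexamer-generation probability."""
    lm = len(freqs)
    product = 1.0
    for o in range(1 - lm, 6):
        p_o = 1.0
        m = 0
        for j in range(1, 7):
            motif_pos = j - o
            if 1 <= motif_pos <= lm:
                p_o = p_o * freqs[motif_pos - 1][NUC_IDX[hexamer[j - 1]]]
            else:
                m += 1
        product *= 1.0 - p_o * 0.25**m
    return 1.0 - product


class TestHexamerFisher:
    def test_perfect_separation(self):
        target = ["AAAAAA" + "C" * 20] * 10
        background = ["C" * 26] * 10
        p = hexamer_fisher(target, background, "AAAAAA")
        assert p == pytest.approx(1 / math.comb(20, 10), rel=1e-9)

    def test_equal_frequencies_not_enriched(self):
        seqs = ["ACGTACGTACGT", "TTTTTTTTTTTT"]
        p = hexamer_fisher(seqs, seqs, "ACGTAC")
        assert p >= 0.5

    def test_absent_hexamer_p_one(self):
        p = hexamer_fisher(["ACACAC"] * 5, ["GTGTGT"] * 5, "AAAAAA")
        assert p == 1.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            hexamer_fisher([], ["ACGTAC"], "ACGTAC")

    def test_scan_matches_single_tests(self, rng):
        target = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(12)]
        background = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(15)]
        scan = hexamer_scan(target, background)
        for hexamer in ("ACGTAC", "AAAAAA", target[0][:6], background[0][10:16]):
            assert scan[hexamer] == pytest.approx(
                hexamer_fisher(target, background, hexamer), abs=1e-10
            )


class TestIrwinHall:
    def test_identity_k1(self):
        assert irwin_hall_combine([0.07]) == pytest.approx(0.07, abs=1e-12)

    def test_symmetry_k7(self):
        assert irwin_hall_combine([0.5] * 7) == pytest.approx(0.5, abs=1e-10)

    def test_closed_form_k2(self):
        assert irwin_hall_combine([0.1, 0.1]) == pytest.approx(0.02, abs=1e-10)

    def test_against_scipy(self, rng):
        for _ in range(50):
            k = int(rng.integers(1, 8))
            p = rng.random(k)
            ref = stats.irwinhall(k).cdf(p.sum())
            assert irwin_hall_combine(p) == pytest.approx(ref, abs=1e-10)

    def test_monte_carlo_k2(self, rng):
        draws = rng.random((100_000, 2)).sum(axis=1)
        assert irwin_hall_cdf(0.2, 2) == pytest.approx(np.mean(draws <= 0.2), abs=3e-3)

    def test_uniformity_small(self, rng):
        combined = [irwin_hall_combine(rng.random(5)) for _ in range(2000)]
        assert stats.kstest(combined, "uniform").pvalue > 0.01

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            irwin_hall_combine([])
        with pytest.raises(ValueError):
            irwin_hall_combine([1.2])


class TestPwmProb:
    def test_exact_match_probability_one(self):
        freqs = np.zeros((6, 4))
        for j, c in enumerate("ACGTAC"):
            freqs[j, NUC_IDX[c]] = 1.0
        pwm = PWM("m", freqs)
        assert pwm_hexamer_prob("ACGTAC", pwm) == 1.0

    def test_impossible_hexamer_probability_zero(self):
        freqs = np.zeros((6, 4))
        for j, c in enumerate("ACGTAC"):
            freqs[j, NUC_IDX[c]] = 1.0
        pwm = PWM("m", freqs)
        assert pwm_hexamer_prob("TTTTTT", pwm) == 0.0

    def test_uniform_pwm_closed_form(self):
        pwm = PWM("u", np.full((4, 4), 0.25))
        # every offset contributes 0.25^6; offsets run 1-lm..5 -> lm+5 of them
        expected = 1.0 - (1.0 - 0.25**6) ** 9
        assert pwm_hexamer_prob("ACGTAC", pwm) == pytest.approx(expected, abs=1e-15)

    def test_n_in_hexamer_gives_zero(self):
        pwm = PWM("u", np.full((4, 4), 0.25))
        assert pwm_hexamer_prob("ACGTAN", pwm) == 0.0

    def test_brute_force_oracle(self, rng):
        for _ in range(100):
            lm = int(rng.integers(1, 10))
            raw = rng.random((lm, 4)) + 0.01
            freqs = raw / raw.sum(axis=1, keepdims=True)
            hexamer = "".join(rng.choice(list("ACGT"), 6))
            pwm = PWM("m", freqs)
            assert pwm_hexamer_prob(hexamer, pwm) == pytest.approx(
                oracle_pwm_prob(hexamer, freqs.tolist()), abs=1e-12
            )

    def test_probability_in_unit_interval(self, rng):
        for _ in range(20):
            lm = int(rng.integers(1, 15))
            raw = rng.random((lm, 4)) + 1e-3
            pwm = PWM("m", raw / raw.sum(axis=1, keepdims=True))
            hexamer = "".join(rng.choice(list("ACGT"), 6))
            assert 0.0 <= pwm_hexamer_prob(hexamer, pwm) <= 1.0


class TestAnnotateHexamers:
    def test_deterministic_pwm_annotates_best(self):
        freqs = np.zeros((6, 4))
        for j, c in enumerate("ACGTAC"):
            freqs[j, NUC_IDX[c]] = 1.0
        ann = annotate_hexamers([PWM("m", freqs)])
        assert "m" in ann["ACGTAC"]
        assert "m" not in ann["TTTTTT"]

    def test_uniform_pwm_annotates_all(self):
        ann = annotate_hexamers([PWM("u", np.full((4, 4), 0.25))])
        assert all("u" in v for v in ann.values())

    def test_half_max_rule(self):
        # 0.9/0.1-style PWM: single-mismatch hexamers annotated iff >= max/2
        freqs = np.full((6, 4), 0.1 / 3)
        for j, c in enumerate("ACGTAC"):
            freqs[j] = 0.1 / 3
            freqs[j, NUC_IDX[c]] = 0.9
        pwm = PWM("m", freqs)
        probs = {h: pwm_hexamer_prob(h, pwm) for h in ALL_HEXAMERS}
        cutoff = max(probs.values()) / 2
        ann = annotate_hexamers([pwm])
        for h in ("ACGTAC", "CCGTAC", "ACGTAT"):
            assert ("m" in ann[h]) == (probs[h] >= cutoff)

    def test_read_pwm_file(self, tmp_path):
        path = tmp_path / "m1.pwm"
        path.write_text(
            "Pos\tA\tC\tG\tU\n1\t0.7\t0.1\t0.1\t0.1\n2\t0.1\t0.7\t0.1\t0.1\n"
        )
        pwm = read_pwm_file(str(path))
        assert pwm.motif_id == "m1"
        assert pwm.length == 2
        assert pwm.freqs[0, 0] == pytest.approx(0.7)


class TestPositionalProfile:
    def test_absent_hexamer_zero_profile(self):
        profile = positional_profile("AAAAAA", ["CGCGCGCGCGCGCG"] * 3, 5)
        assert profile.sum() == 0

    def test_planted_positions(self):
        seq = "C" * 10 + "AAAAAA" + "C" * 84 + "AAAAAA" + "C" * 94
        assert len(seq) == 200
        profile = positional_profile("AAAAAA", [seq] * 7, 50)
        assert profile[0] == 7 and profile[2] == 7
        assert profile[1] == 0 and profile[3] == 0

    def test_uniform_on_random_sequences(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 200)) for _ in range(2000)]
        profile = positional_profile("ACGTAC", seqs, 50)
        chi2 = stats.chisquare(profile)
        assert chi2.pvalue > 0.01

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            positional_profile("ACGTAC", ["ACGTACGT"], 0)


class TestCombinedEnrichment:
    def test_planted_motif_detected(self, rng):
        targets, background = {}, {}
        for sp in ("s1", "s2", "s3"):
            t = ["".join(rng.choice(list("ACGT"), 200)) for _ in range(40)]
            b = ["".join(rng.choice(list("ACGT"), 200)) for _ in range(100)]
            for k in range(16):  # plant in 40% of targets
                t[k] = "ACTAAC" + t[k][6:]
            for k in range(10):  # 10% of background
                b[k] = "ACTAAC" + b[k][6:]
            targets[sp], background[sp] = t, b
        df = combined_enrichment(targets, background)
        assert df.loc["ACTAAC", "padj"] < 0.05

    def test_mismatched_species_raise(self):
        with pytest.raises(ValueError):
            combined_enrichment({"a": ["ACGTAC"]}, {"b": ["ACGTAC"]})

    def test_resampling_wrapper_deterministic(self, rng):
        t = ["ACTAAC" + "G" * 30] * 20
        b = ["G" * 36] * 20
        p1 = resampled_enrichment(t, b, "ACTAAC", 10, 5, seed=3)
        p2 = resampled_enrichment(t, b, "ACTAAC", 10, 5, seed=3)
        np.testing.assert_array_equal(p1, p2)
        assert np.all(p1 < 0.01)
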