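import numpy as np
import pytest

from tactovoc import (
    PAIRS,
    TokenSpec,
    f0_ncf,
    generate_corpus,
    pair_is_exempt,
    simulated_listener,
    summarize_f0,
    synthesize_token,
    vocode,
)
from tactovoc.corpus import PHONEME_TABLE, TALKER_F0_HZ
from tactovoc.stimulus import assemble_trial

RATE = 16000.0


class TestPairInventory:
    def test_53_pairs_with_contrast_labels(self):
        assert len(PAIRS) == 53
        contrasts = {c for _, _, c in PAIRS}
        assert {
            "voicing",
            "manner",
            "manner_place",
            "place_voicing",
            "monophthong",
            "diphthong",
            "monophthong_diphthong",
        } <= contrasts

    def test_all_pair_members_defined(self):
        for a, b, _ in PAIRS:
            assert a in PHONEME_TABLE and b in PHONEME_TABLE

    def test_voicing_pairs_are_cognates(self):
        # voicing pairs differ only in the voiced flag
        for a, b, contrast in PAIRS:
            if contrast != "voicing":
                continue
            pa, pb = PHONEME_TABLE[a], PHONEME_TABLE[b]
            assert pa["voiced"] != pb["voiced"]
            assert pa["noise_peak"] == pb["noise_peak"]
            assert pa["klass"] == pb["klass"]

    def test_exemption_rule(self):
        assert pair_is_exempt("g", "b")  # exempt consonant
        assert pair_is_exempt("oi", "ei")  # diphthongs
        assert not pair_is_exempt("s", "z")
        assert not pair_is_exempt("ae", "e")


class TestSynthesizeToken:
    def test_voiced_fricative_has_low_frequency_energy(self):
        rng = np.random.default_rng(2)
        voiced = TokenSpec(
            "z", "fricative", True, 0.25, "male",
            f0_hz=140.0, noise_peak_hz=6000.0, noise_bw_hz=1400.0,
        )
        voiceless = TokenSpec(
            "s", "fricative", False, 0.25, "male",
            noise_peak_hz=6000.0, noise_bw_hz=1400.0,
        )

        def low_band_db(spec):
            tok = synthesize_token(spec, rng=rng)
            ps = np.abs(np.fft.rfft(tok.samples)) ** 2
            freqs = np.fft.rfftfreq(tok.n_samples, 1 / RATE)
            return 10 * np.log10(ps[freqs < 400].sum() / ps.sum())

        assert low_band_db(voiced) - low_band_db(voiceless) >= 10.0

    def test_vowel_formant_peaks_at_spec(self):
        from tactovoc import ltas

        rng = np.random.default_rng(3)
        spec = TokenSpec(
            "x", "vowel", True, 2.0, "male", f0_hz=100.0, formants_hz=(500.0, 1900.0)
        )
        res = ltas([synthesize_token(spec, rng=rng)], RATE)

        def peak(lo, hi):
            m = (res.freqs_hz >= lo) & (res.freqs_hz <= hi)
            return res.freqs_hz[m][np.argmax(res.level_db[m])]

        assert abs(peak(250, 900) - 500) < 50
        assert abs(peak(1200, 2600) - 1900) < 50

    def test_plosive_is_burst_like(self):
        rng = np.random.default_rng(4)
        spec = TokenSpec(
            "t", "plosive", False, 0.14, "male", noise_peak_hz=3800.0, noise_bw_hz=1800.0
        )
        tok = synthesize_token(spec, rng=rng)
        env = np.abs(tok.samples)
        # energy front-loaded: first quarter holds most of it
        q = tok.n_samples // 4
        assert np.sum(env[:q] ** 2) / np.sum(env**2) > 0.6

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            TokenSpec("x", "vowel", True, 0.0, "male", f0_hz=145.0, formants_hz=(500.0, 1500.0))

    def test_voiced_without_f0_rejected(self):
        with pytest.raises(ValueError):
            TokenSpec("x", "vowel", True, 0.3, "male", formants_hz=(500.0, 1500.0))

    def test_unordered_formants_rejected(self):
        with pytest.raises(ValueError):
            TokenSpec("x", "vowel", True, 0.3, "male", f0_hz=145.0, formants_hz=(1500.0, 500.0))


class TestGenerateCorpus:
    def test_full_inventory_and_pairs(self, corpus):
        assert len(corpus.pairs) == 53
        assert corpus.talkers == ["female", "male"]
        # four tokens of each phoneme per talker
        assert all(len(toks) == 4 for toks in corpus.tokens.values())
        assert len(corpus.tokens) == 2 * len(PHONEME_TABLE)

    def test_deterministic_under_seed(self):
        a = generate_corpus(seed=42, phonemes=["s", "z", "ae"])
        b = generate_corpus(seed=42, phonemes=["s", "z", "ae"])
        for key in a.tokens:
            for ta, tb in zip(a.tokens[key], b.tokens[key]):
                assert np.array_equal(ta.samples, tb.samples)

    def test_talker_f0_recovered_within_5_hz(self, corpus):
        for talker, (target, _) in TALKER_F0_HZ.items():
            means = []
            for (tk, ph), toks in corpus.tokens.items():
                if tk != talker or not PHONEME_TABLE[ph]["voiced"]:
                    continue
                for tok in toks:
                    try:
                        means.append(summarize_f0(f0_ncf(tok)).mean_hz)
                    except ValueError:
                        continue
            assert len(means) > 50
            assert abs(np.mean(means) - target) < 5.0

    def test_manifest_columns(self, corpus):
        m = corpus.manifest()
        assert {"talker", "phoneme", "token", "klass", "voiced", "f0_hz"} <= set(m.columns)
        assert len(m) == 2 * 4 * len(PHONEME_TABLE)


@pytest.fixture(scope="module")
def pair_stims(corpus):
    a = vocode(corpus.tokens[("male", "s")][0], "8FB8T", apply_rove=False)
    b = vocode(corpus.tokens[("male", "z")][0], "8FB8T", apply_rove=False)
    return a, b


class TestSimulatedListener:

    def test_identical_intervals_score_at_chance(self, pair_stims):
        rng = np.random.default_rng(5)
        a, _ = pair_stims
        n = 900
        correct = 0
        for _ in range(n):
            trial = assemble_trial(a, a, rng)
            correct += simulated_listener(trial, 0.3, rng) == trial.odd_interval
        p = correct / n
        assert abs(p - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / n)

    def test_gross_difference_zero_noise_always_correct(self, pair_stims):
        rng = np.random.default_rng(6)
        a, b = pair_stims
        for _ in range(20):
            trial = assemble_trial(a, b, rng)
            assert simulated_listener(trial, 0.0, rng) == trial.odd_interval

    def test_fixed_seed_reproducible(self, pair_stims):
        a, b = pair_stims
        trial = assemble_trial(a, b, np.random.default_rng(7))
        r1 = simulated_listener(trial, 0.3, np.random.default_rng(8))
        r2 = simulated_listener(trial, 0.3, np.random.default_rng(8))
        assert r1 == r2

    def test_missing_interval_rejected(self, pair_stims):
        a, b = pair_stims
        trial = assemble_trial(a, b, np.random.default_rng(9))
        trial.interval_stimuli[1] = None
        with pytest.raises(ValueError):
            simulated_listener(trial, 0.3, np.random.default_rng(10))
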