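"""PWM scanning, exact null thresholds, enrichment, QDA and conservation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from promevo.motifs import (PWM, GaussianQDA, cooccurrence_clusters,
                            core_promoter_pwms, enrichment, iupac_find,
                            log_transform_scores,
                            motif_functional_conservation, pwm_scan,
                            qda_phase_classifier, scan_promoters,
                            score_threshold)


def consensus_pwm(word="TATAAA", eps=1e-6):
    return PWM.from_iupac("test", word, eps=eps)


def enumerate_threshold(pwm: PWM, pvalue: float) -> float:
    """Oracle: exact null threshold by enumerating all 4^L words."""
    L = len(pwm)
    lo = pwm.log_odds[:, :4]
    codes = np.array(list(itertools.product(range(4), repeat=L)))
    scores = lo[np.arange(L)[None, :], codes].sum(axis=1)
    probs = np.prod(pwm.background[codes], axis=1)
    # aggregate tied scores: the tail at s counts every word scoring >= s
    uniq, inv = np.unique(np.round(scores, 9), return_inverse=True)
    mass = np.zeros(uniq.size)
    np.add.at(mass, inv, probs)
    tail = np.cumsum(mass[::-1])[::-1]  # tail[k] = P(S >= uniq[k])
    ok = np.flatnonzero(tail <= pvalue + 1e-12)
    if ok.size == 0:
        return float(uniq[-1])
    return float(uniq[ok[0]])


class TestPwmScan:
    def test_consensus_match_scores_two_bits_per_base(self):
        pwm = consensus_pwm()
        window = "GGGGG" + "TATAAA" + "GGGGG"
        hit = pwm_scan(window, pwm, threshold=10.0)
        assert hit.score == pytest.approx(12.0, abs=1e-4)
        assert hit.present
        assert hit.offset == 5 - len(window) // 2

    def test_all_c_window_scores_strongly_negative(self):
        pwm = consensus_pwm()
        hit = pwm_scan("C" * 40, pwm, threshold=0.0)
        assert hit.score < -20
        assert not hit.present

    def test_consensus_attains_maximal_score(self):
        for pwm in core_promoter_pwms():
            hit = pwm_scan("A" * 10 + pwm.consensus + "A" * 10, pwm,
                           threshold=None)
            assert hit.score == pytest.approx(pwm.max_score, abs=1e-9)

    def test_non_acgt_bases_contribute_zero(self):
        pwm = consensus_pwm("AC")
        hit = pwm_scan("NN", pwm)
        assert hit.score == pytest.approx(0.0)

    def test_window_shorter_than_motif_raises(self):
        with pytest.raises(ValueError):
            pwm_scan("AC", consensus_pwm("ACGTACGT"))

    def test_both_strand_policy_finds_reverse_complement(self):
        pwm = PWM.from_iupac("tf", "ACCGGT"[:5] + "A", eps=1e-6,
                             strand_policy="both")
        word = pwm.consensus
        rc = word.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        hit = pwm_scan("GGGG" + rc + "GGGG", pwm, threshold=10.0)
        assert hit.present and hit.strand == "-"

    def test_exact_null_threshold_matches_enumeration(self):
        bgs = [None, np.array([0.3, 0.2, 0.2, 0.3])]
        for pwm_id in ("TATA", "INR", "DRE", "TCT"):
            for bg in bgs:
                pwm = PWM.from_iupac(pwm_id,
                                     dict(TATA="STATAAA", INR="TCAGTY",
                                          DRE="TATCGATA",
                                          TCT="YYCTTTYY")[pwm_id],
                                     background=bg)
                for p in (2e-4, 1e-3, 1e-2):
                    dp = score_threshold(pwm, p)
                    oracle = enumerate_threshold(pwm, p)
                    assert dp == pytest.approx(oracle, abs=0.02)


class TestEnrichment:
    def _presence(self, rng, n=600, frac=0.3):
        return pd.DataFrame({"m1": rng.random(n) < frac},
                            index=[f"t{i}" for i in range(n)])

    def test_uniform_presence_is_unenriched(self, rng):
        n = 900
        pres = pd.DataFrame({"m1": np.tile([True, False, False], n // 3)},
                            index=range(n))
        groups = pd.Series(np.repeat(["a", "b", "c"], n // 3), index=range(n))
        out = enrichment(pres, groups)
        assert np.allclose(out["ratio_vs_rest"], 1.0, atol=1e-9)
        assert (out["q_value"] > 0.9).all()

    def test_exclusive_motif_strongly_significant(self):
        n = 1000
        idx = range(n)
        pres = pd.DataFrame({"m1": [i < 250 for i in idx]}, index=idx)
        groups = pd.Series(["a" if i < 500 else "b" for i in idx], index=idx)
        out = enrichment(pres, groups).set_index("group")
        assert np.isinf(out.loc["a", "ratio_vs_rest"])
        assert out.loc["a", "q_value"] < 0.05

    def test_weighted_overall_ratios_average_to_one(self, rng):
        n = 600
        idx = [f"t{i}" for i in range(n)]
        pres = pd.DataFrame({m: rng.random(n) < p
                             for m, p in [("m1", 0.2), ("m2", 0.5)]},
                            index=idx)
        groups = pd.Series(rng.choice(["a", "b", "c"], n), index=idx)
        out = enrichment(pres, groups)
        for m in ("m1", "m2"):
            sub = out[out.motif == m]
            w = sub["n_group"] / sub["n_group"].sum()
            assert np.nansum(w * sub["ratio_vs_overall"]) == pytest.approx(
                1.0, abs=1e-9)

    def test_sparse_table_falls_back_to_fisher(self):
        idx = range(20)
        pres = pd.DataFrame({"m1": [i == 0 for i in idx]}, index=idx)
        groups = pd.Series(["a"] * 10 + ["b"] * 10, index=idx)
        out = enrichment(pres, groups)
        assert (out["test"] == "fisher").all()


class TestCooccurrence:
    def test_always_copresent_motifs_group_together(self, rng):
        n = 300
        a = rng.random(n) < 0.4
        b = rng.random(n) < 0.4
        pres = pd.DataFrame({"m1": a, "m2": a, "m3": b, "m4": b})
        labels, _ = cooccurrence_clusters(pres, n_groups=2)
        assert labels["m1"] == labels["m2"]
        assert labels["m3"] == labels["m4"]
        assert labels["m1"] != labels["m3"]

    def test_anti_associated_motifs_split(self, rng):
        n = 400
        a = rng.random(n) < 0.5
        pres = pd.DataFrame({"m1": a, "m2": ~a})
        labels, _ = cooccurrence_clusters(pres, n_groups=2)
        assert labels["m1"] != labels["m2"]

    def test_constant_motifs_excluded(self, rng):
        pres = pd.DataFrame({"m1": rng.random(50) < 0.5,
                             "m2": rng.random(50) < 0.5,
                             "m3": np.ones(50, bool)})
        labels, excluded = cooccurrence_clusters(pres, n_groups=2)
        assert excluded == ["m3"]
        assert "m3" not in labels.index

    def test_three_embedded_sets_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score
        n = 600
        drivers = [rng.random(n) < 0.5 for _ in range(3)]
        cols, truth = {}, []
        for g, d in enumerate(drivers):
            for k in range(3):
                noise = rng.random(n) < 0.05
                cols[f"g{g}m{k}"] = d ^ noise
                truth.append(g)
        labels, _ = cooccurrence_clusters(pd.DataFrame(cols), n_groups=3)
        assert adjusted_rand_score(truth, labels.values) == 1.0


class TestQda:
    def _blobs(self, rng, n_per=150, sep=6.0, d=4, classes=("E", "I", "L")):
        X, y = [], []
        for k, c in enumerate(classes):
            mu = np.zeros(d)
            mu[k % d] = sep  # class means 6 sigma apart (unit variance)
            X.append(rng.normal(0, 1, (n_per, d)) + mu)
            y += [c] * n_per
        return np.vstack(X), np.array(y)

    def test_well_separated_classes_near_perfect(self, rng):
        X, y = self._blobs(rng, n_per=100, sep=6.0, classes=("a", "b"))
        idx = [f"t{i}" for i in range(len(y))]
        scores = pd.DataFrame(X, index=idx)
        res = qda_phase_classifier(scores, pd.Series(y, index=idx))
        assert res.accuracy >= 0.99

    def test_permuted_labels_fall_to_chance(self, rng):
        X, y = self._blobs(rng, n_per=50, sep=6.0)
        y = rng.permutation(y)
        idx = [f"t{i}" for i in range(len(y))]
        res = qda_phase_classifier(pd.DataFrame(X, index=idx),
                                   pd.Series(y, index=idx))
        n = len(y)
        band = 1.96 * np.sqrt((1 / 3) * (2 / 3) / n)
        assert abs(res.accuracy - 1 / 3) <= band + 0.03

    def test_duplicate_samples_predicted_identically(self, rng):
        X, y = self._blobs(rng, n_per=30, sep=4.0, classes=("a", "b"))
        X2 = np.vstack([X, X])
        y2 = np.concatenate([y, y])
        idx = [f"t{i}" for i in range(len(y2))]
        res = qda_phase_classifier(pd.DataFrame(X2, index=idx),
                                   pd.Series(y2, index=idx))
        n = len(y)
        assert (res.predictions.values[:n] == res.predictions.values[n:]).all()

    def test_decision_invariant_under_feature_rescaling(self, rng):
        X, y = self._blobs(rng, n_per=40, sep=3.0, classes=("a", "b"))
        m1 = GaussianQDA(ridge=0.0).fit(X, y)
        X2 = X.copy()
        X2[:, 0] = X2[:, 0] * 7.0 - 3.0
        m2 = GaussianQDA(ridge=0.0).fit(X2, y)
        probe = X[:20]
        probe2 = probe.copy()
        probe2[:, 0] = probe2[:, 0] * 7.0 - 3.0
        assert np.array_equal(m1.predict(probe), m2.predict(probe2))

    def test_agrees_with_sklearn_qda(self, rng):
        from sklearn.discriminant_analysis import \
            QuadraticDiscriminantAnalysis
        X, y = self._blobs(rng, n_per=80, sep=2.0)
        ours = GaussianQDA(ridge=0.0).fit(X, y).predict(X)
        sk = QuadraticDiscriminantAnalysis(reg_param=0.0).fit(X, y).predict(X)
        assert (ours == sk).mean() >= 0.99

    def test_tiny_class_raises(self, rng):
        X = rng.normal(0, 1, (10, 4))
        y = np.array(["a"] * 8 + ["b"] * 2)
        with pytest.raises(ValueError, match="n_features"):
            GaussianQDA().fit(X, y)

    def test_log_transform_handles_negative_scores(self, rng):
        scores = pd.DataFrame(rng.normal(-5, 3, (10, 3)))
        out = log_transform_scores(scores)
        assert np.isfinite(out.values).all()
        assert out.values.min() == pytest.approx(0.0)


class TestMotifConservation:
    def _windows(self, rng, n, pwms, embed_prob=0.6, L=101):
        # same motif content embedded into independent backgrounds, so real
        # motifs are conserved while chance matches of shuffled controls
        # are not
        ref, tgt = {}, {}
        for i in range(n):
            inserts = {}
            for k, pwm in enumerate(pwms):
                if rng.random() < embed_prob:
                    pos = 10 + 25 * k
                    inserts[pos] = pwm.consensus
            for store in (ref, tgt):
                s = list("".join(rng.choice(list("ACGT"), L)))
                for pos, word in inserts.items():
                    s[pos:pos + len(word)] = list(word)
                store[f"t{i}"] = "".join(s)
        return ref, tgt

    def test_identical_windows_fully_conserved(self, rng):
        pwms = core_promoter_pwms()[:3]
        ref, _ = self._windows(rng, 40, pwms)
        out = motif_functional_conservation(ref, ref, pwms, shuffles=3)
        real = out[out["n_ref_present"] > 0]
        assert (real["rate"] == 1.0).all()

    def test_random_target_matches_shuffled_baseline(self, rng):
        pwms = core_promoter_pwms()[:2]
        ref, _ = self._windows(rng, 60, pwms)
        random_tgt = {k: "".join(rng.choice(list("ACGT"), 101)) for k in ref}
        out = motif_functional_conservation(ref, random_tgt, pwms,
                                            shuffles=10)
        assert (out["q_value"].dropna() > 0.05).all()

    def test_preserved_motifs_beat_shuffled_baseline(self, rng):
        pwms = core_promoter_pwms()[:3]
        ref, tgt = self._windows(rng, 120, pwms)
        out = motif_functional_conservation(ref, tgt, pwms, shuffles=10)
        real = out[out["n_ref_present"] >= 20]
        assert (real["rate"] > real["shuffled_rate"] + 0.2).all()
        assert (real["q_value"] < 0.05).all()

    def test_no_shared_promoters_raises(self):
        with pytest.raises(ValueError):
            motif_functional_conservation({"a": "ACGT"}, {"b": "ACGT"},
                                          core_promoter_pwms()[:1])


class TestIupacAndScanning:
    def test_iupac_find_degenerate_patterns(self):
        assert iupac_find("STATAAA", "GGCTATAAAGG") == [2]
        assert iupac_find("TCAGTY", "TCAGTT" + "TCAGTC") == [0, 6]
        assert iupac_find("AAA", "GGGG") == []

    def test_scan_promoters_shapes_and_presence(self, rng):
        pwms = core_promoter_pwms()[:2]
        windows = {"a": "G" * 20 + pwms[0].consensus + "G" * 20,
                   "b": "".join(rng.choice(list("ACGT"), 60))}
        scores, presence = scan_promoters(windows, pwms, pvalue=1e-3)
        assert scores.shape == (2, 2) and presence.shape == (2, 2)
        assert presence.loc["a", pwms[0].id]
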