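"""Syntenic filtering, coordinate projection and conservation calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promevo.tsc import TSC, TagTrack
from promevo.xspecies import (STATUS_ALNGAP, STATUS_ASMGAP, STATUS_ORTH,
                              AlignmentMap, MapBlock, ScoreTrack,
                              build_character_matrix, conservation_call,
                              conservation_metaprofile, harmonize_pair,
                              project_interval, quantile_correlation,
                              selection_fractions, subclade_conservation,
                              syntenic_filter)


def _tsc(start, end, strand="+", species="mel", tid=None):
    return TSC(tid or f"{start}-{end}", species, "chr1", strand, start, end,
               start, 100)


def _block(rs, re, status, tcontig="chr1", ts=None, strand="+"):
    status = np.asarray(status, dtype=np.uint8)
    n_orth = int((status == STATUS_ORTH).sum())
    ts = rs if ts is None else ts
    return MapBlock("chr1", rs, re, tcontig, ts, ts + n_orth, strand, status)


def identity_blocks(n=10_000):
    return [_block(0, n, np.zeros(n))]


class TestSyntenicFilter:
    def test_documented_pass_case(self):
        # 240 O, 240 G, 320 A inside one block; both ends map; 60% aligned,
        # 30% orthologous -> pass at the 50%/25% thresholds
        status = np.concatenate([np.zeros(240), np.full(320, STATUS_ASMGAP),
                                 np.full(240, STATUS_ALNGAP)])
        amap = AlignmentMap("mel", "sim", [_block(100, 900, status)])
        assert syntenic_filter(_tsc(480, 520), amap)

    def test_aligned_fraction_below_half_fails(self):
        # 47.5% aligned
        status = np.concatenate([np.zeros(240), np.full(420, STATUS_ASMGAP),
                                 np.full(140, STATUS_ALNGAP)])
        amap = AlignmentMap("mel", "sim", [_block(100, 900, status)])
        assert not syntenic_filter(_tsc(480, 520), amap)

    @pytest.mark.parametrize("n_aligned,expected", [(400, True), (399, False)])
    def test_aligned_fraction_flips_exactly_at_half(self, n_aligned, expected):
        status = np.concatenate([
            np.zeros(200), np.full(800 - n_aligned, STATUS_ASMGAP),
            np.full(n_aligned - 200, STATUS_ALNGAP)])
        amap = AlignmentMap("mel", "sim", [_block(100, 900, status)])
        assert syntenic_filter(_tsc(480, 520), amap) is expected

    @pytest.mark.parametrize("n_orth,expected", [(200, True), (199, False)])
    def test_orth_fraction_flips_exactly_at_quarter(self, n_orth, expected):
        status = np.concatenate([np.zeros(n_orth),
                                 np.full(800 - n_orth, STATUS_ALNGAP)])
        amap = AlignmentMap("mel", "sim", [_block(100, 900, status)])
        assert syntenic_filter(_tsc(480, 520), amap) is expected

    def test_endpoints_on_different_contigs_fail(self):
        blocks = [_block(0, 500, np.zeros(500), tcontig="chr1"),
                  _block(500, 1000, np.zeros(500), tcontig="chr2", ts=0)]
        amap = AlignmentMap("mel", "sim", blocks)
        assert not syntenic_filter(_tsc(480, 520), amap)

    def test_endpoints_on_different_strands_fail(self):
        blocks = [_block(0, 500, np.zeros(500)),
                  _block(500, 1000, np.zeros(500), strand="-")]
        amap = AlignmentMap("mel", "sim", blocks)
        assert not syntenic_filter(_tsc(480, 520), amap)


def random_map(rng, length=4000):
    """Random mix of identity-orthologous, gap and unaligned runs."""
    blocks = []
    pos = 0
    while pos < length:
        run = int(rng.integers(50, 400))
        run = min(run, length - pos)
        kind = rng.choice(["O", "G", "A", "U"], p=[0.55, 0.15, 0.15, 0.15])
        if kind == "O":
            blocks.append(_block(pos, pos + run, np.zeros(run)))
        elif kind == "G":
            blocks.append(_block(pos, pos + run,
                                 np.full(run, STATUS_ALNGAP)))
        elif kind == "A":
            blocks.append(_block(pos, pos + run,
                                 np.full(run, STATUS_ASMGAP)))
        pos += run
    return AlignmentMap("mel", "sim", blocks)


class TestProjection:
    def test_identity_map_preserves_coordinates(self):
        amap = AlignmentMap("mel", "sim", identity_blocks())
        assert project_interval("chr1", 120, 340, amap) == \
            ("chr1", 120, 340, "+")

    def test_unaligned_interval_is_not_alignable(self):
        amap = AlignmentMap("mel", "sim", identity_blocks(100))
        assert project_interval("chr1", 500, 600, amap) is None

    def test_minus_strand_projection_reverses(self):
        n = 100
        blocks = [MapBlock("chr1", 0, n, "chr9", 1000, 1000 + n, "-",
                           np.zeros(n, np.uint8))]
        amap = AlignmentMap("mel", "sim", blocks)
        tc, ts, te, strand = project_interval("chr1", 10, 20, amap)
        assert (tc, strand) == ("chr9", "-")
        assert (ts, te) == (1000 + n - 20, 1000 + n - 10)
        # base-level round trip through the inverse
        inv = amap.invert()
        for pos in (10, 19):
            t = amap.project_base("chr1", pos)
            back = inv.project_base(t[0], t[1])
            assert back == ("chr1", pos, "-")

    def test_round_trip_contains_orthologous_bases(self, rng):
        for _ in range(10):
            amap = random_map(rng)
            inv = amap.invert()
            start = int(rng.integers(0, 3000))
            end = start + int(rng.integers(10, 800))
            proj = project_interval("chr1", start, end, amap)
            if proj is None:
                continue
            back = project_interval(proj[0], proj[1], proj[2], inv)
            assert back is not None
            orth = [p for p in range(start, end)
                    if amap.project_base("chr1", p) is not None]
            assert back[1] <= min(orth) and max(orth) < back[2]


class TestConservationCall:
    @pytest.mark.parametrize("ref,target,expected", [
        (1000, 9, "absent"),     # 100-fold rule
        (1000, 10, "absent"),    # boundary inclusive
        (1000, 11, "present"),   # 91-fold only
        (100, 1, "absent"),      # exactly at the low_ref boundary: fold rule
        (99, 0, "absent"),       # weak reference: zero-signal rule
        (99, 1, "present"),
        (50, 0, "absent"),
        (50, 1, "present"),
        (15, 0, "absent"),       # eligibility boundary itself
    ])
    def test_rule_table(self, ref, target, expected):
        assert conservation_call(ref, target) == expected

    def test_below_eligibility_raises(self):
        with pytest.raises(ValueError):
            conservation_call(14, 0)

    @settings(max_examples=100, deadline=None)
    @given(ref=st.integers(min_value=15, max_value=10**5),
           t1=st.integers(min_value=0, max_value=10**5),
           t2=st.integers(min_value=0, max_value=10**5))
    def test_monotone_in_target_signal(self, ref, t1, t2):
        lo, hi = sorted((t1, t2))
        if conservation_call(ref, lo) == "present":
            assert conservation_call(ref, hi) == "present"


class TestSubcladeConservation:
    def test_all_present_gives_one(self):
        calls = {(f"t{i}", sp): "present"
                 for i in range(4) for sp in ("a", "b")}
        out = subclade_conservation([f"t{i}" for i in range(4)], calls,
                                    {"ab": ["a", "b"]})
        assert out.loc["ab", "frac_of_all"] == 1.0

    def test_half_lost_in_one_species(self):
        ids = [f"t{i}" for i in range(10)]
        calls = {}
        for i, tid in enumerate(ids):
            calls[(tid, "a")] = "present"
            calls[(tid, "b")] = "present" if i < 5 else "absent"
        out = subclade_conservation(ids, calls, {"a": ["a"], "ab": ["a", "b"]})
        assert out.loc["a", "frac_of_all"] == 1.0
        assert out.loc["ab", "frac_of_all"] == 0.5

    def test_not_alignable_separated_from_absent(self):
        ids = ["t0", "t1", "t2", "t3"]
        calls = {("t0", "a"): "present", ("t1", "a"): "present",
                 ("t2", "a"): "absent", ("t3", "a"): "not_alignable"}
        out = subclade_conservation(ids, calls, {"a": ["a"]})
        assert out.loc["a", "n_alignable"] == 3
        assert out.loc["a", "frac_of_all"] == pytest.approx(0.5)
        assert out.loc["a", "frac_of_alignable"] == pytest.approx(2 / 3)

    def test_matches_branchwise_survival_on_simulated_presence(self):
        from promevo.synth import CladeSpec, simulate_presence
        p = 0.1
        spec = CladeSpec(n_tscs=10_000, gain=0.0, loss=p,
                         root_absent_frac=0.0)
        presence, _ = simulate_presence(spec, np.random.default_rng(5))
        frac = presence.all(axis=0).mean()
        n_branches = 8  # rooted 5-taxon binary tree
        expect = (1 - p) ** n_branches
        sd = np.sqrt(expect * (1 - expect) / spec.n_tscs)
        assert abs(frac - expect) < 3 * sd


class TestCharacterMatrix:
    def _clade_sets(self, taxa=("a", "b", "c", "d", "e")):
        sets = {sp: [_tsc(100, 160, species=sp, tid=f"{sp}.shared")]
                for sp in taxa}
        sets[taxa[1]].append(_tsc(3000, 3060, species=taxa[1], tid="private"))
        maps = {sp: AlignmentMap(taxa[0], sp, identity_blocks())
                for sp in taxa[1:]}
        return sets, maps

    def test_shared_and_private_characters(self):
        sets, maps = self._clade_sets()
        m = build_character_matrix(sets, maps, ref_species="a")
        assert m.n_characters == 2
        shared = m.states[:, 0]
        assert np.all(shared == 1)
        private = m.states[:, 1]
        assert private[m.taxa.index("b")] == 1 and (private == 1).sum() == 1

    def test_invariant_under_species_relabeling(self):
        sets1, maps1 = self._clade_sets()
        m1 = build_character_matrix(sets1, maps1, ref_species="a")
        taxa2 = ("e", "d", "c", "b", "a")
        sets2 = {sp: [_tsc(100, 160, species=sp)] for sp in taxa2}
        sets2["d"].append(_tsc(3000, 3060, species="d"))
        maps2 = {sp: AlignmentMap("e", sp, identity_blocks())
                 for sp in ("a", "b", "c", "d")}
        m2 = build_character_matrix(sets2, maps2, ref_species="e")
        # same multiset of row-sums per character once sorted
        s1 = sorted(map(tuple, np.sort(m1.states, axis=0).T))
        s2 = sorted(map(tuple, np.sort(m2.states, axis=0).T))
        assert s1 == s2

    def test_recovers_ground_truth_presence(self):
        from promevo.synth import CladeSpec, simulate_clade
        from promevo.tsc import call_tscs
        spec = CladeSpec(n_tscs=250, depth=2e5, seed=21,
                         indel_model={"assembly_gap": 0.0,
                                      "alignment_gap": 0.0,
                                      "synteny_break": 0.0})
        clade = simulate_clade(spec)
        sets = {sp: [t for s in "+-"
                     for t in call_tscs(clade.pooled[sp][s])]
                for sp in spec.taxa}
        m = build_character_matrix(sets, clade.maps, ref_species="mel")
        truth = clade.truth
        match = total = 0
        for j in range(m.n_characters):
            if not m.metadata or j >= len(m.metadata):
                continue
            contig, s, e, strand = m.metadata[j]
            locus = (s + e) // 2 // spec.spacing
            if truth.strands[locus] != strand:
                continue
            total += 1
            if np.array_equal(m.states[:, j],
                              truth.presence[[truth.taxa.index(t)
                                              for t in m.taxa], locus]):
                match += 1
        assert total >= 200
        assert match / total >= 0.99


class TestHarmonizePair:
    def _setup(self, n_tags):
        ref = [_tsc(480, 540, tid="ref1")]
        ref[0].gene_id = "gA"
        amap = AlignmentMap("mel", "sim", identity_blocks(2000))
        counts = {500 + i: 1 for i in range(n_tags)}
        pooled = {("chr1", "+"): TagTrack("sim", "chr1", "+", counts)}
        return ref, amap, pooled

    @pytest.mark.parametrize("n_tags,rescued", [(12, True), (10, True),
                                                (9, False)])
    def test_rescue_boundary(self, n_tags, rescued):
        ref, amap, pooled = self._setup(n_tags)
        augmented, _ = harmonize_pair(ref, [], pooled, amap)
        assert bool(augmented) is rescued
        if rescued:
            assert augmented[0].labels.get("rescued")
            assert augmented[0].gene_id == "gA"

    def test_already_called_untouched_and_gene_copied(self):
        ref, amap, pooled = self._setup(12)
        target = [_tsc(480, 540, species="sim", tid="sim1")]
        augmented, updates = harmonize_pair(ref, target, pooled, amap)
        assert len(augmented) == 1 and augmented[0] is target[0]
        assert target[0].gene_id == "gA"
        assert updates == []

    def test_gene_copied_back_to_reference(self):
        ref, amap, pooled = self._setup(12)
        ref[0].gene_id = None
        target = [_tsc(480, 540, species="sim", tid="sim1")]
        target[0].gene_id = "gB"
        _, updates = harmonize_pair(ref, target, pooled, amap)
        assert updates == [("ref1", "gB")]


class TestScoreSummaries:
    def _track(self, values, kind="phastcons", start=0):
        return ScoreTrack(kind, {"chr1": (start, np.asarray(values, float))})

    def test_constant_score_gives_flat_profile_and_zero_se(self):
        track = self._track(np.full(2000, 0.7))
        tscs = [_tsc(500, 520), _tsc(900, 920)]
        for t in tscs:
            t.main_tss = t.start + 5
        med, se = conservation_metaprofile(tscs, track, flank=50, n_boot=20)
        assert np.allclose(med, 0.7)
        assert np.allclose(se, 0.0)

    def test_no_bootstrap_omits_envelope(self):
        track = self._track(np.full(2000, 0.5))
        t = _tsc(500, 520)
        t.main_tss = 505
        med, se = conservation_metaprofile([t], track, flank=10, n_boot=0)
        assert se is None

    def test_median_matches_brute_force(self, rng):
        vals = rng.random(3000)
        track = self._track(vals)
        tscs = []
        for s in (400, 900, 1500, 2200):
            t = _tsc(s, s + 30)
            t.main_tss = s + 10
            tscs.append(t)
        flank = 40
        med, _ = conservation_metaprofile(tscs, track, flank=flank, n_boot=0)
        expected = np.median(np.vstack(
            [vals[t.main_tss - flank:t.main_tss + flank + 1] for t in tscs]),
            axis=0)
        assert np.allclose(med, expected)

    def test_selection_fractions_examples(self, rng):
        t = _tsc(1000, 1020)
        t.main_tss = 1010
        zero = self._track(np.zeros(3000), kind="phylop")
        out = selection_fractions([t], zero, {"Inr": (-10, 10)})
        assert out.loc["Inr", "frac_purifying"] == 0.0
        assert out.loc["Inr", "frac_positive"] == 0.0
        alt = self._track(np.tile([1.0, -1.0], 1500), kind="phylop")
        out = selection_fractions([t], alt, {"Inr": (-10, 10)})
        assert out.loc["Inr", "frac_purifying"] == pytest.approx(0.5)
        assert out.loc["Inr", "frac_positive"] == pytest.approx(0.5)
        rand = self._track(rng.normal(0, 0.3, 3000), kind="phylop")
        out = selection_fractions([t], rand, {"Up": (-50, -20)})
        window = rand.values("chr1", t.main_tss - 50, t.main_tss - 20)
        assert out.loc["Up", "frac_purifying"] == pytest.approx(
            np.mean(window > 0.1))

    def test_fractions_sum_bounded(self, rng):
        t = _tsc(1000, 1020)
        t.main_tss = 1010
        rand = self._track(rng.normal(0, 1, 3000), kind="phylop")
        out = selection_fractions([t], rand, {"w": (-100, 100)})
        assert out["frac_purifying"].iloc[0] + out["frac_positive"].iloc[0] <= 1


class TestQuantileCorrelation:
    def _promoters(self, n, rng, spacing=1000):
        tscs = []
        for i in range(n):
            t = _tsc(i * spacing + 500, i * spacing + 520, tid=f"t{i}")
            t.main_tss = i * spacing + 505
            tscs.append(t)
        return tscs

    def test_perfectly_coupled_scores_give_r_one(self, rng):
        n = 40
        tscs = self._promoters(n, rng)
        cons = {f"t{i}": i / n for i in range(n)}
        vals = np.zeros(n * 1000)
        for i in range(n):
            vals[i * 1000:(i + 1) * 1000] = i / n
        track = ScoreTrack("phastcons", {"chr1": (0, vals)})
        out = quantile_correlation(cons, tscs, track,
                                   {"Upstream": (-300, -50)}, n_quantiles=5)
        assert out.loc["Upstream", "pearson_r"] == pytest.approx(1.0)

    def test_permutation_destroys_coupling(self, rng):
        n = 200
        tscs = self._promoters(n, rng)
        base = rng.random(n)
        vals = np.repeat(base, 1000)
        track = ScoreTrack("phastcons", {"chr1": (0, vals)})
        cons = {f"t{i}": base[i] for i in range(n)}
        perm = rng.permutation(n)
        cons_perm = {f"t{i}": base[perm[i]] for i in range(n)}
        r_true = quantile_correlation(cons, tscs, track,
                                      {"w": (-20, 20)}).loc["w", "pearson_r"]
        r_perm = quantile_correlation(cons_perm, tscs, track,
                                      {"w": (-20, 20)}).loc["w", "pearson_r"]
        assert r_true == pytest.approx(1.0)
        assert abs(r_perm) < 0.3

    def test_independent_values_yield_null_correlation(self):
        n = 1000
        passing = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            tscs = self._promoters(n, rng)
            vals = rng.random(n * 1000)
            track = ScoreTrack("phastcons", {"chr1": (0, vals)})
            cons = {f"t{i}": rng.random() for i in range(n)}
            out = quantile_correlation(cons, tscs, track, {"w": (-20, 20)})
            if abs(out.loc["w", "pearson_r"]) < 0.1 and \
                    out.loc["w", "p_value"] > 0.01:
                passing += 1
        assert passing >= 9

    def test_too_few_promoters_raise(self, rng):
        tscs = self._promoters(2, rng)
        track = ScoreTrack("phastcons", {"chr1": (0, np.zeros(3000))})
        with pytest.raises(ValueError):
            quantile_correlation({"t0": 0.1, "t1": 0.2}, tscs, track)
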