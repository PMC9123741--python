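import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from conftest import oracle_hmm_enumerate, oracle_kmer_count, random_sequence
from xtclass.profiles import (
    Pssm,
    build_profile_features,
    build_profile_hmm,
    build_pssm,
    columns_for_kind,
    compile_prosite,
    flank_calibrated,
    hmm_forward_log2,
    hmm_score,
    map_regions_to_columns,
    prosite_features,
    pssm_features,
)
from xtclass.seqio import (
    Msa,
    RegionAnnotation,
    SequenceRecord,
    XtclassError,
)
from xtclass.synthetic import SynthConfig, generate

LOG20 = np.log2(20)


class TestProsite:
    @pytest.mark.parametrize("raw,seq,expected", [
        ("G-x-G", "GAG", 1),
        ("[LIVM]-K", "LKVK", 2),
        ("A-x(2)-C", "AGGC", 1),
        ("A-x(1,3)-C", "AGCXAGGGC", 2),
        ("{P}-K", "PKAK", 1),
        ("<M-K", "MKMK", 1),
        ("K-V>", "KVKV", 1),
    ])
    def test_match_counts(self, raw, seq, expected):
        pat = compile_prosite(raw)
        assert pat.count(SequenceRecord("s", seq)) == expected

    def test_malformed_pattern(self):
        with pytest.raises(XtclassError):
            compile_prosite("A--x(")

    def test_counts_match_window_oracle(self, rng):
        pat = compile_prosite("G-F-V")
        for _ in range(10):
            s = random_sequence(rng, 80)
            assert pat.count(SequenceRecord("s", s)) == oracle_kmer_count(s, "GFV")

    def test_feature_pairs(self):
        pats = [compile_prosite("G-x-G"), compile_prosite("W-W-W")]
        f = prosite_features(SequenceRecord("s", "GAGCG"), pats)
        assert (f["PROSITE.1.count"], f["PROSITE.1.presence"]) == (2.0, 1.0)
        assert (f["PROSITE.2.count"], f["PROSITE.2.presence"]) == (0.0, 0.0)


class TestRegionMapping:
    def test_gap_mapping_forced(self):
        msa = Msa([("ref", "A-CD"), ("x", "AACD")])
        ann = RegionAnnotation("ref", [(2, 3, "non_cytoplasmic")])
        assert map_regions_to_columns(msa, ann) == [3, 4]

    def test_ungapped_full_cover(self):
        msa = Msa([("ref", "ACDE")])
        ann = RegionAnnotation("ref", [(1, 4, "non_cytoplasmic")])
        assert map_regions_to_columns(msa, ann) == [1, 2, 3, 4]

    def test_random_row_against_position_walk(self, rng):
        residues = random_sequence(rng, 30)
        gapped = "".join(
            ch + ("-" if rng.random() < 0.3 else "") for ch in residues
        )
        msa = Msa([("ref", gapped)])
        start, end = sorted(rng.sample(range(1, 31), 2))
        ann = RegionAnnotation("ref", [(start, end, "binding_site")])
        # oracle: walk the gapped row position by position
        expect, pos = [], 0
        for col, ch in enumerate(gapped, start=1):
            if ch != "-":
                pos += 1
                if start <= pos <= end:
                    expect.append(col)
        assert columns_for_kind(msa, ann, "binding_site") == expect

    def test_region_exceeding_reference(self):
        msa = Msa([("ref", "AC")])
        ann = RegionAnnotation("ref", [(1, 5, "non_cytoplasmic")])
        with pytest.raises(XtclassError):
            map_regions_to_columns(msa, ann)

    def test_missing_reference_row(self):
        msa = Msa([("a", "AC")])
        ann = RegionAnnotation("zz", [(1, 2, "non_cytoplasmic")])
        with pytest.raises(XtclassError):
            map_regions_to_columns(msa, ann)


class TestPssm:
    def test_unanimous_column(self):
        msa = Msa([("a", "A"), ("b", "A"), ("c", "A")])
        pssm = build_pssm(msa, [1], alpha=0.0)
        assert pssm.probs[0, 0] == 1.0
        assert pssm.log_odds[0, 0] == pytest.approx(LOG20)

    def test_pseudocount_formula(self):
        msa = Msa([("a", "A"), ("b", "A"), ("c", "C"), ("d", "C")])
        pssm = build_pssm(msa, [1], alpha=1.0)
        assert pssm.probs[0, 0] == pytest.approx(3 / 24)

    def test_counts_match_oracle(self, rng):
        rows = [(f"r{i}", random_sequence(rng, 12)) for i in range(6)]
        msa = Msa(rows)
        cols = [2, 5, 9]
        pssm = build_pssm(msa, cols, alpha=0.5)
        from xtclass.aaindex import ALPHABET

        for ci, col in enumerate(cols):
            letters = [s[col - 1] for _, s in rows]
            for ai, a in enumerate(ALPHABET):
                expect = (letters.count(a) + 0.5) / (len(rows) + 10)
                assert pssm.probs[ci, ai] == pytest.approx(expect)

    def test_row_permutation_invariance(self, rng):
        rows = [(f"r{i}", random_sequence(rng, 8)) for i in range(5)]
        msa1, msa2 = Msa(rows), Msa(rows[::-1])
        p1 = build_pssm(msa1, [1, 4], alpha=1.0)
        p2 = build_pssm(msa2, [1, 4], alpha=1.0)
        assert np.allclose(p1.probs, p2.probs)

    def test_all_gap_column_zero_alpha(self):
        msa = Msa([("a", "A-"), ("b", "C-")])
        with pytest.raises(XtclassError):
            build_pssm(msa, [2], alpha=0.0)

    def test_json_roundtrip(self, tmp_path, rng):
        msa = Msa([(f"r{i}", random_sequence(rng, 6)) for i in range(4)])
        pssm = build_pssm(msa, [1, 3, 5], alpha=1.0)
        pssm.to_json(tmp_path / "p.json")
        back = Pssm.from_json(tmp_path / "p.json")
        assert np.allclose(back.log_odds, pssm.log_odds)
        assert back.consensus == pssm.consensus


class TestPssmFeatures:
    def test_consensus_query_scores_log20(self):
        rows = [(c, "ACDEF") for c in "abc"]
        pssm = build_pssm(Msa(rows), [1, 2, 3, 4, 5], alpha=0.0)
        f = pssm_features(SequenceRecord("q", "ACDEF"), pssm)
        assert f["PSSM.mean"] == pytest.approx(LOG20)
        assert f["PSSM.max"] == pytest.approx(LOG20)
        assert f["PSSM.coverage"] == pytest.approx(1.0)

    def test_toy_profile_against_hand_lookup(self):
        # 4-column profile from a 2-row alignment; query aligns exactly
        msa = Msa([("a", "ACDE"), ("b", "ACDE")])
        pssm = build_pssm(msa, [1, 2, 3, 4], alpha=1.0)
        q = "ACDE"
        f = pssm_features(SequenceRecord("q", q), pssm)
        from xtclass.aaindex import ALPHABET

        hand = [
            pssm.log_odds[j, ALPHABET.index(ch)] for j, ch in enumerate(q)
        ]
        assert f["PSSM.mean"] == pytest.approx(np.mean(hand))
        assert f["PSSM.max"] == pytest.approx(np.max(hand))

    def test_feature_vector_width(self, rng):
        msa = Msa([(f"r{i}", random_sequence(rng, 10)) for i in range(3)])
        pssm = build_pssm(msa, list(range(1, 11)), alpha=1.0)
        f = pssm_features(SequenceRecord("q", random_sequence(rng, 30)), pssm)
        assert len(f) == 23


class TestProfileHmm:
    def test_two_match_state_deterministic_path(self):
        hmm = build_profile_hmm(Msa([("r", "AC"), ("s", "AC")]), [1, 2], alpha=0.0)
        assert hmm.n_match == 2
        assert hmm.amm[0] == 1.0 and hmm.amm[1] == 1.0 and hmm.amm[2] == 1.0

    def test_all_gap_columns_error(self):
        msa = Msa([("a", "A--C"), ("b", "C--A")])
        with pytest.raises(XtclassError, match="occupancy|match"):
            build_profile_hmm(msa, [2, 3], alpha=1.0)

    def test_transition_counts_hand_example(self):
        # rows: ACA -> M1 M2 M3; A-A -> M1 D2 M3; ACA with insert col
        msa = Msa([("a", "AC-A"), ("b", "A--A"), ("c", "ACCA")])
        # columns 1,2,4 selected as match-eligible; column 3 insert-feeding
        hmm = build_profile_hmm(msa, [1, 2, 3, 4], alpha=0.0, occupancy=0.5)
        # occupancy: col1 3/3, col2 2/3, col3 1/3 (insert), col4 3/3
        assert hmm.n_match == 3
        # from M2: a->M3, c->I2 ; b is in D2
        assert hmm.ami[2] == pytest.approx(1 / 2)   # M2->I2 (row c)
        assert hmm.amm[2] == pytest.approx(1 / 2)   # M2->M3 (row a)
        assert hmm.adm[2] == pytest.approx(1.0)     # D2->M3 (row b)
        assert hmm.aim[2] == pytest.approx(1.0)     # I2->M3 (row c)
        assert hmm.amd[1] == pytest.approx(1 / 3)   # M1->D2 (row b)

    def test_row_permutation_invariance(self, rng):
        rows = [(f"r{i}", random_sequence(rng, 6)) for i in range(5)]
        h1 = build_profile_hmm(Msa(rows), [1, 3, 5], alpha=1.0)
        h2 = build_profile_hmm(Msa(rows[::-1]), [1, 3, 5], alpha=1.0)
        assert np.allclose(h1.match_emissions, h2.match_emissions)
        assert np.allclose(h1.amm, h2.amm)

    def test_json_roundtrip(self, tmp_path):
        msa = Msa([("a", "AC-A"), ("b", "ACCA")])
        hmm = build_profile_hmm(msa, [1, 2, 3, 4], alpha=1.0)
        hmm.to_json(tmp_path / "h.json")
        from xtclass.profiles import ProfileHmm

        back = ProfileHmm.from_json(tmp_path / "h.json")
        s = SequenceRecord("q", "ACA")
        assert hmm_score(back, s) == pytest.approx(hmm_score(hmm, s))


class TestForward:
    def test_single_training_sequence_forced_score(self):
        hmm = build_profile_hmm(Msa([("r", "AC")]), [1, 2], alpha=0.0)
        score = hmm_score(hmm, SequenceRecord("q", "AC"))
        assert score == pytest.approx(2 * LOG20)

    def test_forward_equals_path_enumeration(self, rng):
        msa = Msa([("a", "AC-A"), ("b", "A-CA"), ("c", "ACCA")])
        for alpha in (1.0, 0.5):
            hmm = build_profile_hmm(msa, [1, 2, 3, 4], alpha=alpha)
            for s in ("AC", "ACA", "A", "ACCA", "WWWWW"):
                p_dp = 2 ** hmm_forward_log2(hmm, SequenceRecord("q", s))
                p_enum = oracle_hmm_enumerate(hmm, s)
                assert abs(p_dp - p_enum) < 1e-9

    def test_calibrated_forward_equals_enumeration(self):
        msa = Msa([("a", "ACA"), ("b", "AGA")])
        hmm = flank_calibrated(
            build_profile_hmm(msa, [1, 2, 3], alpha=1.0), 5
        )
        for s in ("ACA", "WACAW", "MK"):
            p_dp = 2 ** hmm_forward_log2(hmm, SequenceRecord("q", s))
            assert abs(p_dp - oracle_hmm_enumerate(hmm, s)) < 1e-9

    def test_total_probability_mass_bounded(self):
        """Forward sums over the sequence space stay below 1 and grow."""
        from itertools import product
        from xtclass.aaindex import ALPHABET

        hmm = build_profile_hmm(Msa([("a", "AC"), ("b", "AA")]), [1, 2], alpha=1.0)
        masses = []
        total = 0.0
        for L in (1, 2, 3):
            for tup in product(ALPHABET, repeat=L):
                total += 2 ** hmm_forward_log2(
                    hmm, SequenceRecord("q", "".join(tup))
                )
            masses.append(total)
        assert masses[0] < masses[1] < masses[2] <= 1.0

    def test_poor_match_low_score_not_error(self):
        hmm = build_profile_hmm(Msa([("a", "ACDEF")]), [1, 2, 3, 4, 5], alpha=1.0)
        score = hmm_score(hmm, SequenceRecord("q", "WWWWWWWW"))
        assert np.isfinite(score) and score < 0


class TestHmmDiscrimination:
    def test_positive_scores_exceed_negative_rank_sum(self):
        fx = generate(
            SynthConfig(
                n_pos=30, n_neg=30, length_range=(120, 160),
                motif_region=(41, 90), mutation_rate=0.1, seed=11,
            )
        )
        pf = build_profile_features(fx.msa, annotation=fx.annotation)
        feats = pf.features(fx.dataset.records)
        y = np.array([fx.dataset.labels[i] for i in feats.index])
        scores = feats["HMM.non_cytoplasmic"].to_numpy()
        stat = mannwhitneyu(scores[y == 1], scores[y == 0], alternative="greater")
        assert stat.pvalue < 0.01
        assert scores[y == 1].mean() > scores[y == 0].mean()
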