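"""uORF detection, translatability scores, Kozak and distance analyses."""

import math

import numpy as np
import pandas as pd
import pytest

from riboscape.uorf import (
    HexamerTable,
    UorfThresholds,
    classify_translated,
    detect_uorfs,
    dinucleotide_shuffle,
    fickett_score,
    hexamer_score,
    kozak_chi_square,
    kozak_context,
    kozak_pwm,
    last_uorf_per_gene,
    orfscore,
    rrs,
    train_hexamer_table,
    uorf_distance,
    uorf_morf_relation,
)
from tests.conftest import make_transcript


class TestDetectUorfs:
    def test_hand_scanned_example(self):
        # UTR AAATGGCTTAAGG: ATG at 2, codons ATG GCT TAA -> [2, 11)
        m = make_transcript("AAATGGCTTAAGG", "ATGAAATAA")
        res = detect_uorfs({"tx1": m}, min_len=9)
        assert len(res) == 1
        row = res.iloc[0]
        assert (row["start"], row["end"], row["length"]) == (2, 11, 9)

    def test_utr_without_atg_yields_nothing(self):
        m = make_transcript("CCCCCCCCCCCC", "ATGAAATAA")
        assert len(detect_uorfs({"tx1": m})) == 0

    def test_atg_without_inframe_stop_excluded_by_default(self):
        m = make_transcript("AAATGGCTGCAGG", "ATGAAATAA")
        assert len(detect_uorfs({"tx1": m})) == 0
        res = detect_uorfs({"tx1": m}, allow_overlap=True)
        assert len(res) == 1 and res.iloc[0]["overlaps_cds"]

    def test_nested_atg_sharing_stop_keeps_most_5prime(self):
        # two in-frame ATGs, one stop
        utr = "ATGATGGCTTAA" + "CC"
        m = make_transcript(utr, "ATGAAATAA")
        res = detect_uorfs({"tx1": m}, min_len=9)
        assert len(res) == 1 and res.iloc[0]["start"] == 0
        res_all = detect_uorfs({"tx1": m}, min_len=9, keep_nested=True)
        assert len(res_all) == 2

    def test_min_len_inclusive_of_stop(self):
        m = make_transcript("AAATGGCTTAAGG", "ATGAAATAA")
        assert len(detect_uorfs({"tx1": m}, min_len=12)) == 0

    def test_emitted_records_satisfy_invariants(self, sim_uorf):
        res = detect_uorfs(sim_uorf.models)
        for _, r in res.iterrows():
            m = sim_uorf.models[r["transcript_id"]]
            assert m.sequence[r["start"] : r["start"] + 3] == "ATG"
            assert r["end"] <= m.utr5_len
            assert r["length"] % 3 == 0 and r["length"] >= 9
        # every planted uORF is found at exact coordinates
        truth = sim_uorf.truth.uorfs
        found = set(zip(res["transcript_id"], res["start"], res["end"]))
        planted = set(
            zip(truth["transcript_id"], truth["start"], truth["end"])
        )
        assert planted <= found


class TestOrfscore:
    def test_uniform_frames_score_zero(self):
        assert orfscore((10, 10, 10)) == 0.0

    def test_closed_form_frame0_only(self):
        assert orfscore((30, 0, 0)) == pytest.approx(math.log2(61))

    def test_sign_rule_on_all_permutations(self):
        from itertools import permutations

        for f in set(permutations((30, 0, 0))):
            expected = math.log2(61) if f[0] == 30 else -math.log2(61)
            assert orfscore(f) == pytest.approx(expected)

    def test_magnitude_preserved_when_max_frame_moves(self, rng):
        for _ in range(50):
            f = rng.integers(0, 50, size=3)
            if f.sum() == 0:
                continue
            scores = [orfscore(np.roll(f, k)) for k in range(3)]
            assert len({round(abs(s), 9) for s in scores}) == 1

    def test_empty_is_missing(self):
        assert math.isnan(orfscore((0, 0, 0)))


class TestRrs:
    def test_definition_arithmetic(self):
        assert rrs(10, 30, 1, 30) == pytest.approx(5.0)

    def test_zero_uorf_reads(self):
        assert rrs(0, 30, 5, 30) == 0.0

    def test_short_gap_missing(self):
        assert math.isnan(rrs(10, 30, 0, 10))


class TestFickett:
    def test_homopolymer_value_fixed_by_tables(self):
        # A*60: A position value 20/21 -> 0.22, content 1.0 -> 0.28;
        # C/G/T position 0 -> (0.23, 0.08, 0.09), content 0 -> (0.31, 0.29, 0.58)
        expected = (
            0.22 * 0.26 + 0.23 * 0.18 + 0.08 * 0.31 + 0.09 * 0.33
            + 0.28 * 0.11 + 0.31 * 0.12 + 0.29 * 0.15 + 0.58 * 0.14
        )
        assert fickett_score("A" * 60) == pytest.approx(expected)

    def test_codon_repeat_invariance(self):
        # composition and the binned position asymmetry are unchanged when
        # a codon-periodic sequence is extended in frame
        short, long = "ATCGGA" * 10, "ATCGGA" * 20
        assert fickett_score(long) == pytest.approx(fickett_score(short), abs=1e-12)

    def test_scores_within_table_bounded_range(self, rng):
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            assert 0.16 <= fickett_score(seq) <= 1.31

    def test_ambiguous_content_rejected(self):
        with pytest.raises(ValueError):
            fickett_score("N" * 60)


class TestHexamer:
    def test_identical_tables_score_zero(self, rng):
        f = rng.dirichlet(np.ones(4096))
        table = HexamerTable(coding=f, noncoding=f.copy())
        assert hexamer_score("ATGGCTGATCCA", table) == pytest.approx(0.0)

    def test_single_hexamer_log_ratio(self):
        coding = np.full(4096, (1 - 0.02) / 4095)
        noncoding = np.full(4096, (1 - 0.01) / 4095)
        idx = 0  # AAAAAA
        coding[idx], noncoding[idx] = 0.02, 0.01
        table = HexamerTable(coding=coding, noncoding=noncoding)
        assert hexamer_score("AAAAAA", table) == pytest.approx(math.log(2))

    def test_short_sequence_missing(self):
        f = np.full(4096, 1 / 4096)
        assert math.isnan(hexamer_score("ATG", HexamerTable(coding=f, noncoding=f)))

    def test_training_is_deterministic(self, sim_small):
        t1 = train_hexamer_table(sim_small.models, seed=4)
        t2 = train_hexamer_table(sim_small.models, seed=4)
        assert np.array_equal(t1.coding, t2.coding)
        assert np.array_equal(t1.noncoding, t2.noncoding)

    def test_frequencies_normalised(self, sim_small):
        t = train_hexamer_table(sim_small.models, seed=1)
        assert t.coding.sum() == pytest.approx(1.0)
        assert t.noncoding.sum() == pytest.approx(1.0)

    def test_coding_sequences_score_above_shuffled(self, sim_small, rng):
        table = train_hexamer_table(sim_small.models, seed=2)
        cds = [m.cds_seq for m in list(sim_small.models.values())[:40]]
        coding_scores = [hexamer_score(s, table) for s in cds]
        shuffled_scores = [
            hexamer_score(dinucleotide_shuffle(s, rng), table) for s in cds
        ]
        assert np.mean(coding_scores) > 0 > np.mean(shuffled_scores)


class TestDinucleotideShuffle:
    def test_preserves_dinucleotide_counts(self, rng):
        from collections import Counter

        for _ in range(30):
            seq = "".join(rng.choice(list("ACGT"), size=rng.integers(10, 200)))
            shuf = dinucleotide_shuffle(seq, rng)
            assert len(shuf) == len(seq)
            assert shuf[0] == seq[0] and shuf[-1] == seq[-1]
            assert Counter(zip(seq, seq[1:])) == Counter(zip(shuf, shuf[1:]))


class TestClassifyTranslated:
    def _frame(self, **kw):
        base = dict(
            orfscore=7.0, rrs=3.0, fickett=0.9, hexamer=0.5, mean_fpkm=10.0
        )
        base.update(kw)
        return pd.DataFrame([base])

    def test_all_passing_is_translated(self):
        assert classify_translated(self._frame()).iloc[0]

    def test_missing_rrs_fails_policy(self):
        assert not classify_translated(self._frame(rrs=np.nan, orfscore=10.0)).iloc[0]

    @pytest.mark.parametrize(
        "kw",
        [
            {"orfscore": 5.9},
            {"rrs": 1.9},
            {"fickett": 0.73},
            {"hexamer": 0.0},       # strict inequality on hexamer
            {"mean_fpkm": 0.5},
        ],
    )
    def test_each_threshold_is_binding(self, kw):
        assert not classify_translated(self._frame(**kw)).iloc[0]

    def test_thresholds_configurable(self):
        lax = UorfThresholds(orfscore=0, rrs=0, fickett=0, hexamer=-10, min_fpkm=0)
        assert classify_translated(self._frame(orfscore=1.0, rrs=0.1), lax).iloc[0]


class TestKozak:
    def test_context_window_and_padding(self):
        m = make_transcript("CCAAAATGGGGCTTAAGGCC", "ATGAAATAA")
        # start at 5: left context clipped at the cap, N-padded to 6
        assert kozak_context(m, 5) == "NCCAAAATGG"
        assert len(kozak_context(m, 2)) == 10
        assert kozak_context(m, 2).startswith("NNNN")

    def test_one_hot_pwm_from_identical_contexts(self):
        pwm = kozak_pwm(["AAAAAAATGC"] * 6)
        assert pwm.loc[-6, "A"] == 1.0
        assert pwm.loc[1, "A"] == 1.0 and pwm.loc[2, "T"] == 1.0 and pwm.loc[3, "G"] == 1.0
        assert np.allclose(pwm.sum(axis=1), 1.0)

    def test_identical_sets_give_p_one(self):
        ctxs = ["ACGTACATGA"] * 20
        p = kozak_chi_square(ctxs, ctxs)
        assert (p == 1.0).all()

    def test_planted_minus5_difference_detected(self):
        a = ["ACCGTAATGG"] * 50   # C at -5
        b = ["AGCGTAATGG"] * 50   # G at -5
        p = kozak_chi_square(a, b)
        assert p.loc[-5] < 1e-10
        assert p.loc[-4] == 1.0

    def test_minimum_set_size(self):
        with pytest.raises(ValueError):
            kozak_chi_square(["AAAAAATGGC"] * 2, ["AAAAAATGGC"] * 20)


class TestDistances:
    def test_distance_definition(self):
        m = make_transcript("A" * 100, "ATGAAATAA")
        m2 = make_transcript("C" * 100, "ATGAAATAA")
        assert uorf_distance(m, 50, 80) == (20, pytest.approx(0.2))
        assert uorf_distance(m2, 70, 100) == (0, 0.0)

    def test_last_uorf_selected_per_gene(self):
        df = pd.DataFrame(
            {
                "transcript_id": ["t1", "t1", "t2"],
                "start": [0, 30, 5],
                "end": [12, 60, 20],
            },
            index=["u1", "u2", "u3"],
        )
        last = last_uorf_per_gene(df)
        assert set(last.index) == {"u2", "u3"}


class TestUorfMorfRelation:
    def test_duplicated_vector_perfect_correlation(self, rng):
        x = pd.Series(rng.normal(size=100))
        res = uorf_morf_relation(x, x.copy())
        assert res["pearson"]["r"] == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self, rng):
        x = pd.Series(rng.normal(size=500))
        y = pd.Series(rng.normal(size=500))
        assert abs(uorf_morf_relation(x, y)["pearson"]["r"]) < 0.1

    def test_too_few_pairs_suppressed(self, rng):
        x = pd.Series(rng.normal(size=5))
        assert uorf_morf_relation(x, x)["pearson"] is None

    def test_ks_detects_planted_te_suppression(self, rng):
        te_none = pd.Series(rng.lognormal(0.0, 0.5, 400))
        te_transl = pd.Series(rng.lognormal(-1.0, 0.5, 400))  # suppressed TE
        res = uorf_morf_relation(
            pd.Series(dtype=float),
            pd.Series(dtype=float),
            te_by_class={"none": te_none, "translated": te_transl},
        )
        assert res["ks_tests"]["none_vs_translated"]["p"] < 0.01

    def test_identical_te_distributions_not_flagged(self, rng):
        te = pd.Series(rng.lognormal(0.0, 0.5, 300))
        res = uorf_morf_relation(
            pd.Series(dtype=float),
            pd.Series(dtype=float),
            te_by_class={"a": te, "b": te.sample(frac=1.0, random_state=1)},
        )
        assert res["ks_tests"]["a_vs_b"]["p"] > 0.5

    def test_te_regressions_on_features(self, rng):
        te = pd.Series(rng.normal(size=200))
        feats = pd.DataFrame({"length": te * 2 + rng.normal(size=200) * 0.1})
        res = uorf_morf_relation(
            pd.Series(dtype=float), pd.Series(dtype=float), te=te, uorf_features=feats
        )
        assert res["regressions"]["length"]["r"] > 0.9
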