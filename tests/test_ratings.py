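import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from affectnorm import ratings as rt
from conftest import make_panel
import oracles


class TestLoadRatings:
    def test_parses_long_format_csv(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text(
            "rater_id,word,response\nr1,Haus,4\nr1,Krieg,1\nr2,Haus,5\nr2,Krieg,2\n"
        )
        db = rt.load_ratings(p, 1, 5)
        assert db.n_raters == 2 and db.n_words == 2
        assert db.responses["response"].tolist() == [4, 1, 5, 2]

    def test_unknown_marker_stored_as_unknown(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("rater_id,word,response\nr1,Haus,4\nr1,Krieg,?\n")
        db = rt.load_ratings(p, 1, 5, unknown_marker="?")
        resp = db.responses.set_index("word")["response"]
        assert np.isnan(resp["Krieg"]) and resp["Haus"] == 4

    def test_out_of_scale_names_row(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("rater_id,word,response\nr1,Haus,4\nr1,Krieg,6\n")
        with pytest.raises(ValueError, match="row 3"):
            rt.load_ratings(p, 1, 5)

    def test_duplicate_pair_names_pair(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("rater_id,word,response\nr1,Haus,4\nr1,Haus,5\n")
        with pytest.raises(ValueError, match="Haus"):
            rt.load_ratings(p, 1, 5)


class TestExclusions:
    def test_majority_unknown_word_removed(self):
        rows = [(f"r{i}", "w", None if i < 6 else 3) for i in range(10)]
        rows += [(f"r{i}", "ok", 2 + (i % 3)) for i in range(10)]
        db = make_panel(rows)
        _, rep = rt.apply_exclusions(db)
        assert rep.words_removed_unknown == ["w"]

    def test_clean_panel_untouched(self):
        rows = [(f"r{i}", w, 1 + (i + j) % 5)
                for i in range(4) for j, w in enumerate("abcd")]
        db = make_panel(rows)
        out, rep = rt.apply_exclusions(db)
        assert len(out.responses) == len(db.responses)
        assert not rep.words_removed_unknown
        assert not rep.raters_removed_uniform
        assert not rep.raters_removed_lowknowledge

    def test_hand_enumerated_panel(self):
        # r1 keeps; r2 modal 2/3 > .6; r4 knows 1/4 < .5 (and is trivially
        # uniform on its single answer); r5 modal 4/4; w4 unknown 3/5 > .5
        rows = [
            ("r1", "w1", 1), ("r1", "w2", 2), ("r1", "w3", 3), ("r1", "w4", None),
            ("r2", "w1", 2), ("r2", "w2", 2), ("r2", "w3", 4), ("r2", "w4", None),
            ("r3", "w1", 5), ("r3", "w2", 4), ("r3", "w3", 2), ("r3", "w4", None),
            ("r4", "w1", 3), ("r4", "w2", None), ("r4", "w3", None), ("r4", "w4", None),
            ("r5", "w1", 3), ("r5", "w2", 3), ("r5", "w3", 3), ("r5", "w4", 3),
        ]
        out, rep = rt.apply_exclusions(make_panel(rows))
        assert rep.words_removed_unknown == ["w4"]
        assert rep.raters_removed_uniform == ["r2", "r4", "r5"]
        assert rep.raters_removed_lowknowledge == ["r4"]
        assert rep.n_words_after == 3 and rep.n_raters_after == 2
        assert sorted(out.responses["rater_id"].unique()) == ["r1", "r3"]

    def test_row_order_invariance(self):
        rows = [
            ("r1", "w1", 1), ("r1", "w2", 2), ("r1", "w3", 3), ("r1", "w4", None),
            ("r2", "w1", 2), ("r2", "w2", 2), ("r2", "w3", 4), ("r2", "w4", None),
            ("r3", "w1", 5), ("r3", "w2", 4), ("r3", "w3", 2), ("r3", "w4", None),
            ("r5", "w1", 3), ("r5", "w2", 3), ("r5", "w3", 3), ("r5", "w4", 3),
        ]
        fwd, rep_fwd = rt.apply_exclusions(make_panel(rows))
        rev, rep_rev = rt.apply_exclusions(make_panel(rows[::-1]))
        assert rep_fwd == rep_rev
        a = fwd.responses.sort_values(["rater_id", "word"]).reset_index(drop=True)
        b = rev.responses.sort_values(["rater_id", "word"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_everything_excluded_is_error(self):
        rows = [("r1", "w1", None), ("r2", "w1", None), ("r2", "w2", None),
                ("r1", "w2", 3)]
        with pytest.raises(ValueError):
            rt.apply_exclusions(make_panel(rows))


class TestRescale:
    @pytest.mark.parametrize("resp,expected", [(1, -3.0), (3, 0.0), (2, -1.5),
                                               (5, 3.0)])
    def test_five_point_to_seven_point(self, resp, expected):
        db = make_panel([("r1", "w", resp)])
        out = rt.rescale_responses(db)
        assert out.responses["response"].iloc[0] == pytest.approx(expected)

    def test_unknowns_untouched(self):
        out = rt.rescale_responses(make_panel([("r1", "w", None), ("r1", "v", 3)]))
        assert out.responses["response"].isna().tolist() == [True, False]

    def test_degenerate_target_errors(self):
        with pytest.raises(ValueError):
            rt.rescale_responses(make_panel([("r1", "w", 3)]), 2, 2)

    @given(resp=st.integers(min_value=1, max_value=5))
    @settings(max_examples=20, deadline=None)
    def test_roundtrip_and_idempotence(self, resp):
        db = make_panel([("r1", "w", resp)])
        once = rt.rescale_responses(db, -3, 3)
        twice = rt.rescale_responses(once, -3, 3)  # matching scales: identity
        back = rt.rescale_responses(once, 1, 5)
        assert twice.responses["response"].iloc[0] == pytest.approx(
            once.responses["response"].iloc[0]
        )
        assert back.responses["response"].iloc[0] == pytest.approx(resp)

    def test_order_preserving(self):
        db = make_panel([("r1", "a", 1), ("r1", "b", 3), ("r1", "c", 5)])
        out = rt.rescale_responses(db)
        assert out.responses["response"].is_monotonic_increasing


class TestSummarize:
    def test_arithmetic_and_n(self):
        db = make_panel([("r1", "w", 2), ("r2", "w", 4)], scale=(1, 5))
        s = rt.summarize(db)
        assert s.mean_of("w") == pytest.approx(3.0)
        assert s.table.loc["w", "sd"] == pytest.approx(np.sqrt(2))
        assert s.table.loc["w", "n"] == 2

    def test_constant_panel(self):
        db = make_panel([(f"r{i}", w, 4) for i in range(3) for w in "abc"])
        s = rt.summarize(db)
        assert s.grand_mean == pytest.approx(4.0)
        assert s.grand_sd == pytest.approx(0.0)

    def test_five_word_toy_matches_hand_value(self):
        db = make_panel([
            ("r1", "a", 1), ("r2", "a", 2),         # mean 1.5
            ("r1", "b", 3),                          # 3
            ("r1", "c", 5), ("r2", "c", 4),          # 4.5
            ("r1", "d", 2), ("r2", "d", 2),          # 2
            ("r1", "e", 4), ("r2", "e", 5), ("r3", "e", 3),  # 4
        ])
        s = rt.summarize(db)
        assert s.grand_mean == pytest.approx((1.5 + 3 + 4.5 + 2 + 4) / 5)
        # grand mean is the unweighted mean of per-word means
        assert s.grand_mean == pytest.approx(s.table["mean"].mean(), abs=1e-10)

    def test_unknown_only_word_dropped_with_warning(self):
        db = make_panel([("r1", "w", None), ("r2", "w", None), ("r1", "v", 3)])
        with pytest.warns(UserWarning, match="no known responses"):
            s = rt.summarize(db)
        assert s.words == ["v"]


class TestICC:
    def test_perfect_agreement_is_one(self):
        db = make_panel([(f"r{i}", w, 1 + j) for i in range(4)
                         for j, w in enumerate("abcd")])
        assert rt.compute_icc(db) == pytest.approx(1.0)

    def test_pure_noise_is_near_zero(self):
        rng = np.random.default_rng(11)
        rows = [(f"r{i}", f"w{j}", rng.integers(1, 6))
                for j in range(2000) for i in range(15)]
        assert abs(rt.compute_icc(make_panel(rows))) < 0.05

    def test_matches_anova_oracle_and_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        word_effect = rng.normal(0, 1, size=50)
        rows = []
        for j in range(50):
            for i in range(10):
                rows.append((f"r{i}", f"w{j:02d}",
                             float(word_effect[j] + rng.normal(0, 0.8))))
        db = make_panel(rows, scale=(-10, 10))
        icc = rt.compute_icc(db)
        groups = [g["response"].to_numpy()
                  for _, g in db.responses.groupby("word")]
        assert icc == pytest.approx(oracles.anova_icc1k(groups), abs=1e-12)
        pg = pingouin.intraclass_corr(
            data=db.responses, targets="word", raters="rater_id",
            ratings="response"
        ).set_index("Type")
        assert icc == pytest.approx(pg.loc["ICC(1,k)", "ICC"], abs=1e-6)

    def test_added_noise_lowers_icc(self):
        rng = np.random.default_rng(3)
        word_effect = rng.normal(0, 1.2, size=40)
        for rep in range(20):
            base = rng.normal(0, 0.3, size=(40, 8))
            extra = rng.normal(0, 0.8, size=(40, 8))
            def panel(noise):
                rows = [(f"r{i}", f"w{j:02d}",
                         float(word_effect[j] + base[j, i] + noise[j, i]))
                        for j in range(40) for i in range(8)]
                return make_panel(rows, scale=(-20, 20))
            assert rt.compute_icc(panel(extra)) < rt.compute_icc(panel(np.zeros_like(extra)))

    def test_single_rating_everywhere_errors(self):
        db = make_panel([("r1", "a", 2), ("r2", "b", 3), ("r1", "c", 4)])
        with pytest.raises(ValueError, match="reliability undefined"):
            rt.compute_icc(db)


class TestReliabilityCorrections:
    @pytest.mark.parametrize("r1,k,expected", [
        (0.5, 2, 2 / 3), (0.7, 1, 0.7), (0.0, 5, 0.0), (1.0, 3, 1.0),
    ])
    def test_spearman_brown_closed_form(self, r1, k, expected):
        assert rt.spearman_brown(r1, k) == pytest.approx(expected)

    @given(r1=st.floats(0.01, 0.99), k=st.floats(0.1, 20))
    @settings(max_examples=50, deadline=None)
    def test_spearman_brown_roundtrip(self, r1, k):
        fwd = rt.spearman_brown(r1, k)
        assert rt.spearman_brown(fwd, 1 / k) == pytest.approx(r1, abs=1e-12)

    @given(r1=st.floats(0.05, 0.95), k=st.floats(1.0, 10), dk=st.floats(0.1, 5),
           dr=st.floats(0.001, 0.04))
    @settings(max_examples=50, deadline=None)
    def test_spearman_brown_monotone(self, r1, k, dk, dr):
        assert rt.spearman_brown(r1, k + dk) > rt.spearman_brown(r1, k)
        assert rt.spearman_brown(r1 + dr, k) > rt.spearman_brown(r1, k)

    def test_spearman_brown_rejects_bad_k(self):
        with pytest.raises(ValueError):
            rt.spearman_brown(0.5, 0)

    def test_disattenuate_identity_and_zero(self):
        assert rt.disattenuate(0.62, 1.0, 1.0) == pytest.approx(0.62)
        assert rt.disattenuate(0.0, 0.5, 0.7) == 0.0

    def test_disattenuate_formula_value(self):
        expected = 0.6 / np.sqrt(0.86 * 0.95)
        assert rt.disattenuate(0.6, 0.86, 0.95) == pytest.approx(expected)
        assert rt.disattenuate(0.6, 0.86, 0.95) == pytest.approx(0.6638, abs=1e-4)

    def test_disattenuate_clips_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            assert rt.disattenuate(0.95, 0.5, 0.5) == 1.0

    def test_disattenuate_rejects_zero_reliability(self):
        with pytest.raises(ValueError):
            rt.disattenuate(0.5, 0.0, 0.9)
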