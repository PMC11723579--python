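"""Mixed models, bin ANOVAs, comprehension model and Benjamini-Hochberg FDR."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from mdesmap.models import (anova_across_bins, fdr_bh, lmm_comprehension,
                            lmm_gradient_thought, lmm_thought_by_movie,
                            partial_eta_sq)


def bh_oracle(p, q):
    """Literal step-up definition: largest i with p_(i) <= i/m * q."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    thresh = (np.arange(1, m + 1) / m) * q
    below = p[order] <= thresh
    k = np.max(np.nonzero(below)[0]) + 1 if below.any() else 0
    reject = np.zeros(m, bool)
    reject[order[:k]] = True
    adj = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    p_adj = np.empty(m)
    p_adj[order] = np.minimum(adj, 1)
    return reject, p_adj


class TestFdrBH:
    def test_hand_computed_cases(self):
        rej, adj = fdr_bh([0.001, 0.001, 0.001], q=0.05)
        assert rej.all()
        rej, adj = fdr_bh([0.01, 0.04, 0.90], q=0.05)
        assert rej.tolist() == [True, False, False]
        np.testing.assert_allclose(adj, [0.03, 0.06, 0.90])

    def test_matches_definitional_oracle_on_random_vectors(self, rng):
        for _ in range(100):
            m = rng.integers(1, 30)
            p = rng.uniform(0, 1, m)
            q = rng.uniform(0.01, 0.2)
            rej, adj = fdr_bh(p, q)
            o_rej, o_adj = bh_oracle(p, q)
            assert rej.tolist() == o_rej.tolist()
            np.testing.assert_allclose(adj, o_adj, atol=1e-12)

    def test_empty_and_invalid_input(self):
        rej, adj = fdr_bh([], q=0.05)
        assert len(rej) == 0
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5], q=0.05)


def simulate_scores(rng, n_p=50, offset=0.0, n_probes=5):
    rows = []
    for i in range(n_p):
        b = rng.normal(0, 0.5)
        for m in range(3):
            for _ in range(n_probes):
                rows.append({
                    "participant_id": f"p{i}", "movie_id": f"mov{m}",
                    "c1": (offset if m == 1 else 0.0) + b + rng.normal(0, 1),
                })
    return pd.DataFrame(rows)


class TestThoughtByMovie:
    def test_planted_movie_offset_recovered(self, rng):
        df = simulate_scores(rng, offset=0.5)
        res = lmm_thought_by_movie(df, ["c1"])["c1"]
        term = res.terms["movie_id"]
        assert term["significant_fdr"]
        lsm = res.lsmeans
        assert lsm["mov1"]["M"] - lsm["mov0"]["M"] == pytest.approx(0.5, abs=0.2)
        pw = {(p["a"], p["b"]): p for p in res.pairwise}
        assert pw[("mov0", "mov1")]["p_adjusted"] < 0.01
        assert pw[("mov0", "mov2")]["p_adjusted"] > 0.05

    def test_invariance_to_participant_relabelling(self, rng):
        df = simulate_scores(rng, offset=0.4, n_p=30)
        res1 = lmm_thought_by_movie(df, ["c1"])["c1"]
        relabel = {f"p{i}": f"z{99 - i}" for i in range(30)}
        df2 = df.assign(participant_id=df["participant_id"].map(relabel))
        res2 = lmm_thought_by_movie(df2, ["c1"])["c1"]
        assert res1.terms["movie_id"]["statistic"] == pytest.approx(
            res2.terms["movie_id"]["statistic"], rel=1e-6)

    def test_requires_two_movies(self, rng):
        df = simulate_scores(rng)
        with pytest.raises(ValueError):
            lmm_thought_by_movie(df[df.movie_id == "mov0"], ["c1"])


class TestAnovaAcrossBins:
    def test_null_f_near_one_on_average(self, rng):
        fs = []
        for _ in range(200):
            df = pd.DataFrame({
                "bin_index": rng.integers(0, 40, 120),
                "c": rng.standard_normal(120),
                "movie_id": "m",
            })
            fs.append(anova_across_bins(df, "c").terms["bin_index"]["statistic"])
        assert np.mean(fs) == pytest.approx(1.0, abs=0.25)

    def test_perfect_trend_degenerates_to_infinite_f(self):
        df = pd.DataFrame({"bin_index": np.arange(40.0), "c": 2 * np.arange(40.0) + 1})
        res = anova_across_bins(df, "c")
        assert np.isinf(res.terms["bin_index"]["statistic"])
        assert res.terms["Residuals"]["SumSq"] == pytest.approx(0.0, abs=1e-8)

    def test_table_shape_matches_single_df_layout(self, rng):
        df = pd.DataFrame({"bin_index": rng.integers(0, 40, 714),
                           "c": rng.standard_normal(714)})
        res = anova_across_bins(df, "c")
        assert res.terms["bin_index"]["Df"] == 1
        assert res.terms["Residuals"]["Df"] == 712

    def test_single_bin_errors(self):
        df = pd.DataFrame({"bin_index": [3, 3, 3], "c": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="bin"):
            anova_across_bins(df, "c")


class TestComprehension:
    def comprehension_data(self, rng, b2=-1.0, b4=1.0):
        rows_c, rows_p = [], []
        for i in range(120):
            for m in range(3):
                pats = rng.standard_normal(4)
                score = np.clip(np.round(2.5 + b2 * pats[1] + b4 * pats[3]
                                         + rng.normal(0, 0.8)), 0, 4)
                rows_c.append({"participant_id": f"p{i}", "movie_id": f"mov{m}",
                               "score": int(score)})
                rows_p.append({"participant_id": f"p{i}", "movie_id": f"mov{m}",
                               **{f"pat_{k + 1}": pats[k] for k in range(4)}})
        return pd.DataFrame(rows_c), pd.DataFrame(rows_p)

    def test_planted_effects_recovered_with_correct_signs(self, rng):
        comp, pats = self.comprehension_data(rng)
        res = lmm_comprehension(comp, pats, [f"pat_{k + 1}" for k in range(4)])
        assert res.terms["pat_2"]["estimate"] < 0
        assert res.terms["pat_2"]["significant_fdr"]
        assert res.terms["pat_4"]["estimate"] > 0
        assert res.terms["pat_4"]["significant_fdr"]
        assert not res.terms["pat_1"]["significant_fdr"]
        assert len([k for k in res.terms]) == 9

    def test_missing_join_keys_error(self, rng):
        comp, pats = self.comprehension_data(rng)
        with pytest.raises(ValueError, match="missing"):
            lmm_comprehension(comp, pats.iloc[:-5], [f"pat_{k + 1}" for k in range(4)])

    def test_simple_slopes_follow_planted_interaction(self, rng):
        rows_c, rows_p = [], []
        for i in range(150):
            for m in range(3):
                pat = rng.standard_normal()
                slope = {0: 1.2, 1: 0.0, 2: -1.2}[m]
                score = np.clip(np.round(2.0 + slope * pat + rng.normal(0, 0.6)), 0, 4)
                rows_c.append({"participant_id": f"p{i}", "movie_id": f"mov{m}",
                               "score": int(score)})
                rows_p.append({"participant_id": f"p{i}", "movie_id": f"mov{m}",
                               "pat_1": pat})
        res = lmm_comprehension(pd.DataFrame(rows_c), pd.DataFrame(rows_p), ["pat_1"])
        assert res.terms["movie_id:pat_1"]["significant_fdr"]
        slopes = res.simple_slopes["pat_1"]
        assert slopes["mov0"]["b"] > 0.5
        assert slopes["mov2"]["b"] < -0.5
        assert abs(slopes["mov1"]["b"]) < 0.3


class TestGradientThought:
    def test_planted_coupling_and_calibration(self, rng):
        rows = []
        for i in range(80):
            b = rng.normal(0, 0.4)
            for _ in range(15):
                g = rng.standard_normal(5) * 0.3
                score = -1.5 * g[0] + b + rng.normal(0, 1)
                rows.append({"participant_id": f"p{i}", "score_x": score,
                             **{f"g{k + 1}": g[k] for k in range(5)}})
        df = pd.DataFrame(rows)
        res = lmm_gradient_thought(df, ["score_x"])["score_x"]
        assert res.terms["g1"]["estimate"] < 0
        assert res.terms["g1"]["significant_fdr"]
        assert not any(res.terms[f"g{k}"]["significant_fdr"] for k in range(2, 6))

    def test_affine_rescaling_of_predictor_rescales_coefficient(self, rng):
        rows = []
        for i in range(40):
            for _ in range(10):
                g = rng.standard_normal(5)
                rows.append({"participant_id": f"p{i}",
                             "s": g[0] * 0.5 + rng.normal(0, 1),
                             **{f"g{k + 1}": g[k] for k in range(5)}})
        df = pd.DataFrame(rows)
        r1 = lmm_gradient_thought(df, ["s"])["s"]
        df2 = df.assign(g1=df["g1"] * 10)
        r2 = lmm_gradient_thought(df2, ["s"])["s"]
        assert r2.terms["g1"]["estimate"] == pytest.approx(
            r1.terms["g1"]["estimate"] / 10, rel=1e-4)

    def test_rank_deficient_predictors_error(self, rng):
        df = pd.DataFrame({
            "participant_id": ["p1"] * 20 + ["p2"] * 20,
            "s": rng.standard_normal(40),
            **{f"g{k + 1}": rng.standard_normal(40) for k in range(4)},
        })
        df["g5"] = df["g1"] * 2
        with pytest.raises(ValueError, match="rank deficient"):
            lmm_gradient_thought(df, ["s"])


def test_partial_eta_sq_bounds():
    assert partial_eta_sq(0.0, 1, 100) == 0.0
    assert partial_eta_sq(np.inf, 1, 100) == 1.0
    assert 0 < partial_eta_sq(5.0, 2, 100) < 1


def test_mixed_model_agrees_with_lme4_oracle(rng, tmp_path):
    """Cross-check random-intercept fixed effects against R's lmer on one fixture."""
    rows = []
    for i in range(40):
        b = rng.normal(0, 0.7)
        for m in range(3):
            rows.append({"participant_id": f"p{i:02d}", "movie_id": f"mov{m}",
                         "score": (0.6 if m == 2 else 0.0) + b + rng.normal(0, 1)})
    df = pd.DataFrame(rows)
    csv = tmp_path / "fixture.csv"
    df.to_csv(csv, index=False)
    rscript = tmp_path / "fit.R"
    rscript.write_text(textwrap.dedent(f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        fit <- lmer(score ~ movie_id + (1|participant_id), d, REML=TRUE)
        cat(fixef(fit), sep="\\n")
    """))
    proc = subprocess.run(["Rscript", str(rscript)], capture_output=True, text=True)
    if proc.returncode != 0:
        pytest.skip(f"Rscript unavailable or failed: {proc.stderr[:200]}")
    want = [float(x) for x in proc.stdout.strip().splitlines()]
    res = lmm_thought_by_movie(df, ["score"])["score"]
    got = [res.lsmeans["mov0"]["M"],
           res.lsmeans["mov1"]["M"] - res.lsmeans["mov0"]["M"],
           res.lsmeans["mov2"]["M"] - res.lsmeans["mov0"]["M"]]
    np.testing.assert_allclose(got, want, atol=1e-4)
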