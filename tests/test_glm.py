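import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from refugeo import glm
from refugeo.errors import SeparationWarning
from refugeo.simulate import OccurrenceSimConfig, simulate_occurrence


def log_or_closed_form(n11, n10, n01, n00):
    """2x2-table log odds ratio and its SE (independent oracle)."""
    beta = np.log((n11 / n10) / (n01 / n00))
    se = np.sqrt(1 / n11 + 1 / n10 + 1 / n01 + 1 / n00)
    return beta, se


class TestFitBinomialGLM:
    def test_intercept_only_balanced(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        fit = glm.fit_binomial_glm(y, pd.DataFrame(index=range(20)))
        assert fit.params.iloc[0] == pytest.approx(0.0, abs=1e-10)
        assert fit.null_deviance == pytest.approx(fit.residual_deviance)
        assert fit.d2 == pytest.approx(0.0, abs=1e-10)

    def test_matches_2x2_closed_form(self):
        # x=0: 10 present / 10 absent; x=1: 5 present / 15 absent
        y = np.r_[np.ones(10), np.zeros(10), np.ones(5), np.zeros(15)]
        x = np.r_[np.zeros(20), np.ones(20)]
        fit = glm.fit_binomial_glm(y, pd.DataFrame({"x": x}))
        beta, se = log_or_closed_form(5, 15, 10, 10)
        assert fit.params.iloc[1] == pytest.approx(beta, abs=1e-6)  # -1.0986
        assert fit.bse.iloc[1] == pytest.approx(se, abs=1e-6)  # 0.68313
        assert fit.zvalues.iloc[1] == pytest.approx(beta / se, abs=1e-6)

    def test_random_2x2_tables_match_closed_form(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(3, 30, size=4)  # n11, n10, n01, n00
            y = np.r_[
                np.ones(counts[0]), np.zeros(counts[1]), np.ones(counts[2]), np.zeros(counts[3])
            ]
            x = np.r_[np.ones(counts[0] + counts[1]), np.zeros(counts[2] + counts[3])]
            fit = glm.fit_binomial_glm(y, pd.DataFrame({"x": x}))
            beta, se = log_or_closed_form(*counts)
            assert fit.params.iloc[1] == pytest.approx(beta, abs=1e-6)
            assert fit.bse.iloc[1] == pytest.approx(se, abs=1e-6)

    def test_perfect_separation_flagged(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = glm.fit_binomial_glm(x.copy(), pd.DataFrame({"x": x}))
        assert fit.separation

    def test_rank_deficient_names_aliased(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(30)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="b"):
            glm.fit_binomial_glm(rng.integers(0, 2, 30), X)

    def test_adjusted_d2_below_d2_and_deviance_ordering(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((60, 3)), columns=list("abc"))
        y = rng.integers(0, 2, 60)
        fit = glm.fit_binomial_glm(y, X)
        assert fit.adj_d2 <= fit.d2
        assert fit.residual_deviance <= fit.null_deviance + 1e-8
        assert 0 <= fit.d2 <= 1

    def test_d2_monotone_in_nested_models_adjusted_not(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((40, 6)), columns=list("abcdef"))
        y = rng.integers(0, 2, 40)
        d2s = [glm.fit_binomial_glm(y, X.iloc[:, :k]).d2 for k in range(1, 7)]
        assert all(d2s[i] <= d2s[i + 1] + 1e-10 for i in range(5))
        # adjusted D2 can decrease when useless columns are added
        adj = [glm.fit_binomial_glm(y, X.iloc[:, :k]).adj_d2 for k in range(1, 7)]
        assert any(adj[i] > adj[i + 1] for i in range(5))


class TestScreen:
    def test_bonferroni_multiplication_and_cap(self):
        rng = np.random.default_rng(4)
        n = 200
        x_strong = rng.standard_normal(n)
        y = rng.binomial(1, 1 / (1 + np.exp(-2.0 * x_strong)))
        x_null = rng.standard_normal(n)
        out = glm.single_predictor_screen(
            y, pd.DataFrame({"strong": x_strong, "null": x_null}), family_size=12
        )
        strong = out.set_index("predictor").loc["strong"]
        null = out.set_index("predictor").loc["null"]
        assert strong["p_adj"] == pytest.approx(min(1.0, strong["p"] * 12))
        assert null["p_adj"] == pytest.approx(min(1.0, null["p"] * 12))

    def test_familywise_error_controlled(self):
        # k orthogonal null predictors: familywise rejection rate <= alpha
        rng = np.random.default_rng(5)
        k, n, sims = 5, 80, 400
        rejections = 0
        for _ in range(sims):
            y = rng.integers(0, 2, n)
            X = pd.DataFrame(rng.standard_normal((n, k)), columns=[f"x{i}" for i in range(k)])
            out = glm.single_predictor_screen(y, X, family_size=k)
            rejections += out["significant"].any()
        assert rejections / sims <= 0.05 + 0.03

    def test_family_size_must_cover_screen(self):
        with pytest.raises(ValueError):
            glm.single_predictor_screen(
                np.r_[np.ones(5), np.zeros(5)],
                pd.DataFrame(np.random.default_rng(0).standard_normal((10, 3))),
                family_size=2,
            )


class TestVarpart:
    def _blocks(self, rng, n=300):
        A = pd.DataFrame(rng.standard_normal((n, 3)), columns=["a1", "a2", "a3"])
        B = pd.DataFrame(rng.standard_normal((n, 1)), columns=["b1"])
        C = pd.DataFrame(rng.standard_normal((n, 2)), columns=["c1", "c2"])
        return A, B, C

    def test_additivity_identity(self):
        rng = np.random.default_rng(6)
        A, B, C = self._blocks(rng)
        y = rng.integers(0, 2, len(A))
        fr = glm.varpart3(y, A, B, C)
        total = (
            fr.a_eco + fr.b_hist + fr.c_apo + fr.d_eco_hist + fr.e_hist_apo + fr.f_eco_apo + fr.g_all
        )
        assert total == pytest.approx(fr.adj_d2_full, abs=1e-10)
        assert fr.residual == pytest.approx(1 - fr.adj_d2_full, abs=1e-12)

    def test_true_generator_in_A_only(self):
        rng = np.random.default_rng(7)
        n = 2000
        A, B, C = self._blocks(rng, n)
        logit = 1.2 * A["a1"] - 0.8 * A["a2"]
        y = rng.binomial(1, 1 / (1 + np.exp(-logit)))
        fr = glm.varpart3(y, A, B, C)
        for frac in (fr.b_hist, fr.c_apo, fr.d_eco_hist, fr.e_hist_apo, fr.f_eco_apo, fr.g_all):
            assert abs(frac) < 0.03
        assert fr.a_eco == pytest.approx(fr.adj_d2_full, abs=0.05)

    def test_duplicated_block_moves_signal_to_shared(self):
        rng = np.random.default_rng(8)
        n = 1500
        A = pd.DataFrame({"a1": rng.standard_normal(n)})
        B = pd.DataFrame({"b1": rng.standard_normal(n)})
        C = A.rename(columns={"a1": "c1"})
        y = rng.binomial(1, 1 / (1 + np.exp(-1.5 * A["a1"])))
        fr = glm.varpart3(y, A, B, C)
        assert abs(fr.a_eco) < 0.02
        assert abs(fr.c_apo) < 0.02
        assert fr.f_eco_apo > 0.1  # shared eco/apo fraction absorbs the signal

    def test_label_permutation_symmetry(self):
        rng = np.random.default_rng(9)
        A, B, C = self._blocks(rng, 250)
        y = rng.integers(0, 2, 250)
        fr = glm.varpart3(y, A, B, C)
        fr_perm = glm.varpart3(y, C, A, B)  # (A,B,C) -> (C,A,B)
        assert fr_perm.a_eco == pytest.approx(fr.c_apo, abs=1e-10)
        assert fr_perm.b_hist == pytest.approx(fr.a_eco, abs=1e-10)
        assert fr_perm.c_apo == pytest.approx(fr.b_hist, abs=1e-10)
        assert fr_perm.g_all == pytest.approx(fr.g_all, abs=1e-10)


class TestCrossOccurrence:
    def test_z_symmetric_across_directions(self, occurrence_table):
        out = glm.apomict_cross_occurrence(occurrence_table)
        assert len(out) == 3
        # symmetry was asserted internally to 1e-6; D2 differs by direction
        assert (out["d2_fwd"] != out["d2_rev"]).any()

    def test_identical_occurrences_flag_separation(self):
        rng = np.random.default_rng(10)
        z = rng.binomial(1, 0.5, 120)
        table = pd.DataFrame(
            {"present_5x": z, "present_7x": z, "present_8x": rng.binomial(1, 0.3, 120)}
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SeparationWarning)
            out = glm.apomict_cross_occurrence(table)
        assert out.set_index("pair").loc["present_5x~present_7x", "separation"]

    def test_null_false_positive_rate_unrestricted(self):
        # independent occurrences analysed without union conditioning:
        # Bonferroni keeps the familywise error at or below nominal
        rng = np.random.default_rng(11)
        sims, hits = 300, 0
        for _ in range(sims):
            table = pd.DataFrame(
                {
                    "present_5x": rng.binomial(1, 0.5, 133),
                    "present_7x": rng.binomial(1, 0.4, 133),
                    "present_8x": rng.binomial(1, 0.3, 133),
                }
            )
            out = glm.apomict_cross_occurrence(table, restrict=False)
            hits += (out["p_adj"] < 0.05).any()
        assert hits / sims <= 0.05 + 0.03

    def test_union_conditioning_induces_negative_association(self):
        # restricting to apomict-containing populations makes marginally
        # independent occurrences negatively associated by construction
        rng = np.random.default_rng(13)
        coefs = []
        for _ in range(60):
            table = pd.DataFrame(
                {
                    "present_5x": rng.binomial(1, 0.5, 200),
                    "present_7x": rng.binomial(1, 0.4, 200),
                    "present_8x": rng.binomial(1, 0.3, 200),
                }
            )
            out = glm.apomict_cross_occurrence(table, restrict=True)
            coefs.append(out["coef"].mean())
        assert np.mean(coefs) < -0.2

    def test_absent_cytotype_skipped(self):
        rng = np.random.default_rng(12)
        table = pd.DataFrame(
            {
                "present_5x": rng.binomial(1, 0.5, 60),
                "present_7x": rng.binomial(1, 0.4, 60),
                "present_8x": np.zeros(60, dtype=int),
            }
        )
        out = glm.apomict_cross_occurrence(table)
        assert len(out) == 1


class TestParameterRecovery:
    def test_joint_apo_model_recovers_generator(self):
        # data generated with known apomict effects; jointly specified fit
        truth = np.array([-3.65, -1.56, -2.49])
        hits = np.zeros(3)
        reps = 120
        for rep in range(reps):
            cfg = OccurrenceSimConfig(
                seed=rep, beta_eco=(0.0,) * 8, beta_hist=0.0, beta0=1.5
            )
            tab = simulate_occurrence(cfg)
            X = tab[["present_5x", "present_7x", "present_8x"]]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", SeparationWarning)
                fit = glm.fit_binomial_glm(tab["present_4x"].to_numpy(), X)
            lo = fit.params.iloc[1:] - 1.96 * fit.bse.iloc[1:]
            hi = fit.params.iloc[1:] + 1.96 * fit.bse.iloc[1:]
            hits += ((lo.to_numpy() <= truth) & (truth <= hi.to_numpy())).astype(float)
        coverage = hits / reps
        assert (np.abs(coverage - 0.95) < 0.06).all()
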