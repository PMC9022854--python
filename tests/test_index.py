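"""Index fitting, orientation, rescaling, and the eigendecomposition oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import qcindex as qc
from qcindex.errors import DegenerateInputError, InsufficientDataError
from qcindex.ratios import RATIO_COLUMNS

from conftest import random_ratio_table


def eig_oracle(ratios, log_transform=False):
    """Independent route: brute-force symmetric eigendecomposition of the
    correlation matrix, scores by direct projection of z-scores."""
    X = ratios[RATIO_COLUMNS].to_numpy(dtype=float)
    if log_transform:
        X = np.log(X)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    C = np.corrcoef(X, rowvar=False)
    lam, vec = np.linalg.eigh(C)
    lead = vec[:, -1]
    return lam[::-1], lead, Z @ lead


def align_sign(a, b):
    return a if np.dot(a, b) >= 0 else -a


class TestFitAgainstOracle:
    def test_random_tables_match_eigendecomposition(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 201))
            ratios = random_ratio_table(rng, n=n)
            model = qc.fit_qci(ratios)
            lam, lead, raw = eig_oracle(ratios)
            got = align_sign(model.loadings, lead)
            np.testing.assert_allclose(got, lead, atol=1e-8)
            assert model.explained_fraction == pytest.approx(
                lam[0] / lam.sum(), abs=1e-8
            )
            scored = qc.score_qci(model, ratios)["qci"].to_numpy()
            oriented = raw if np.dot(model.oriented_loadings(), lead) >= 0 else -raw
            expected = 100 * (oriented - oriented.min()) / (oriented.max() - oriented.min())
            np.testing.assert_allclose(scored, expected, atol=1e-8)

    def test_collinear_columns_explain_everything(self):
        base = np.linspace(1, 2, 30)
        ratios = pd.DataFrame(
            {
                "mir": base,
                "prev_inc": 3 * base,
                "daly_prev": 0.5 * base,
                "yll_yld": 10 * base,
            }
        )
        model = qc.fit_qci(ratios)
        assert qc.explained_variance(model) == pytest.approx(1.0, abs=1e-9)

    def test_two_informative_columns_closed_form(self, rng):
        """With two constant-plus-noise-free informative columns of pairwise
        correlation r, the leading eigenvalue of their 2x2 correlation matrix
        is 1 + |r|, so the explained fraction over those two is (1+|r|)/2."""
        n = 500
        x = rng.normal(size=n)
        e = rng.normal(size=n)
        a = 0.6
        y = a * x + np.sqrt(1 - a**2) * e
        two = pd.DataFrame({"u": x, "v": y})
        r = np.corrcoef(x, y)[0, 1]
        lam = np.linalg.eigvalsh(two.corr().to_numpy())
        assert lam.max() == pytest.approx(1 + abs(r), abs=1e-12)
        # and the same variance split drives a 4-column fit built from them
        ratios = pd.DataFrame(
            {"mir": x, "prev_inc": y, "daly_prev": x, "yll_yld": y}
        )
        model = qc.fit_qci(ratios)
        C = ratios.corr().to_numpy()
        lam4 = np.linalg.eigvalsh(C)
        assert model.explained_fraction == pytest.approx(lam4.max() / 4, abs=1e-9)

    def test_too_few_strata(self, rng):
        with pytest.raises(InsufficientDataError):
            qc.fit_qci(random_ratio_table(rng, n=2))

    def test_zero_variance_column_named(self, rng):
        ratios = random_ratio_table(rng, n=20)
        ratios["daly_prev"] = 0.7
        with pytest.raises(DegenerateInputError, match="daly_prev"):
            qc.fit_qci(ratios)


class TestOrientation:
    @pytest.mark.parametrize(
        "loadings, sign",
        [
            ((0.5, -0.5, 0.5, 0.5), -1),  # mir positive -> flip
            ((-0.5, 0.5, -0.5, -0.5), +1),
            ((0.0, 0.2, -0.3, 0.7), -1),  # mir tie -> yll_yld decides
            ((0.0, 0.2, -0.3, -0.7), +1),
            ((0.0, 0.2, 0.98, 0.0), -1),  # falls to daly_prev
            ((0.0, -1.0, 0.0, 0.0), -1),  # falls to -prev_inc
            ((0.0, 1.0, 0.0, 0.0), +1),
        ],
    )
    def test_sign_rules(self, loadings, sign):
        l = np.asarray(loadings, dtype=float)
        l = l / np.linalg.norm(l)
        assert qc.orient_component(l) == sign

    def test_all_zero_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            qc.orient_component(np.zeros(4))

    def test_oriented_mir_loading_nonpositive(self, rng):
        for _ in range(20):
            model = qc.fit_qci(random_ratio_table(rng, n=int(rng.integers(10, 100))))
            assert model.oriented_loadings()[0] <= 0


class TestScoring:
    def test_fitting_frame_spans_zero_to_hundred(self, rng):
        ratios = random_ratio_table(rng, n=80)
        model = qc.fit_qci(ratios)
        scored = qc.score_qci(model, ratios)["qci"]
        assert scored.min() == pytest.approx(0.0, abs=1e-9)
        assert scored.max() == pytest.approx(100.0, abs=1e-9)

    def test_midpoint_maps_to_fifty(self):
        base = np.array([1.0, 2.0, 3.0])  # equally spaced raw scores
        ratios = pd.DataFrame(
            {"mir": base, "prev_inc": base * 2, "daly_prev": base, "yll_yld": base}
        )
        model = qc.fit_qci(ratios)
        scored = qc.score_qci(model, ratios)["qci"].to_numpy()
        assert sorted(scored) == pytest.approx([0.0, 50.0, 100.0], abs=1e-9)

    def test_affine_invariance_in_correlation_mode(self, rng):
        ratios = random_ratio_table(rng, n=60)
        base = qc.score_qci(qc.fit_qci(ratios), ratios)["qci"].to_numpy()
        warped = ratios.copy()
        warped["mir"] = 3.7 * warped["mir"] + 11.0
        warped["yll_yld"] = 0.2 * warped["yll_yld"]
        again = qc.score_qci(qc.fit_qci(warped), warped)["qci"].to_numpy()
        np.testing.assert_allclose(again, base, atol=1e-8)

    def test_row_permutation_changes_nothing(self, rng):
        ratios = random_ratio_table(rng, n=40)
        perm = ratios.sample(frac=1.0, random_state=7).reset_index(drop=True)
        m1, m2 = qc.fit_qci(ratios), qc.fit_qci(perm)
        np.testing.assert_allclose(
            align_sign(m1.loadings, m2.loadings), m2.loadings, atol=1e-10
        )
        assert m1.explained_fraction == pytest.approx(m2.explained_fraction, abs=1e-12)
        s1 = qc.score_qci(m1, ratios).set_index("location")["qci"]
        s2 = qc.score_qci(m2, perm).set_index("location")["qci"]
        np.testing.assert_allclose(s1.sort_index(), s2.sort_index(), atol=1e-9)

    def test_raising_mir_never_raises_qci(self, rng):
        ratios = random_ratio_table(rng, n=50)
        model = qc.fit_qci(ratios)
        bumped = ratios.copy()
        bumped.loc[7, "mir"] *= 1.5
        before = qc.score_qci(model, ratios).loc[7, "qci"]
        after = qc.score_qci(model, bumped).loc[7, "qci"]
        assert after <= before + 1e-12

    def test_out_of_frame_scores_flagged_not_clamped(self, rng):
        ratios = random_ratio_table(rng, n=30)
        model = qc.fit_qci(ratios)
        extreme = ratios.iloc[[0]].copy()
        extreme["mir"] = ratios["mir"].max() * 10
        extreme["yll_yld"] = ratios["yll_yld"].max() * 10
        scored = qc.score_qci(model, extreme)
        assert not scored.loc[0, "in_frame"]
        assert scored.loc[0, "qci"] < 0
        clamped = qc.score_qci(model, extreme, clamp=True)
        assert clamped.loc[0, "qci"] == 0.0

    def test_degenerate_rescale_rejected(self, rng):
        ratios = random_ratio_table(rng, n=10)
        model = qc.fit_qci(ratios)
        model.score_max = model.score_min
        with pytest.raises(DegenerateInputError):
            qc.score_qci(model, ratios)

    def test_log_transform_recorded_and_applied(self, rng):
        ratios = random_ratio_table(rng, n=40)
        model = qc.fit_qci(ratios, log_transform=True)
        assert model.log_transform
        lam, lead, _ = eig_oracle(ratios, log_transform=True)
        np.testing.assert_allclose(
            align_sign(model.loadings, lead), lead, atol=1e-8
        )


class TestModelSerialization:
    def test_round_trip_reproduces_scores(self, rng, tmp_path):
        ratios = random_ratio_table(rng, n=30)
        model = qc.fit_qci(ratios)
        path = tmp_path / "model.txt"
        model.to_file(path)
        back = qc.QCIModel.from_file(path)
        np.testing.assert_allclose(
            qc.score_qci(back, ratios)["qci"],
            qc.score_qci(model, ratios)["qci"],
            atol=1e-12,
        )


class TestExplainedVariance:
    def test_independent_columns_near_quarter(self, rng):
        n = 4000
        ratios = pd.DataFrame(
            rng.normal(size=(n, 4)) + 5.0, columns=RATIO_COLUMNS
        )
        model = qc.fit_qci(ratios)
        # isotropic correlation: each of 4 components carries ~1/4
        assert model.explained_fraction == pytest.approx(0.25, abs=0.04)

    def test_equals_leading_eigenvalue_over_four(self, rng):
        ratios = random_ratio_table(rng, n=70)
        model = qc.fit_qci(ratios)
        lam = np.linalg.eigvalsh(ratios[RATIO_COLUMNS].corr().to_numpy())
        assert model.explained_fraction == pytest.approx(lam.max() / 4, abs=1e-10)


class TestReferenceCorrelation:
    def test_identity_and_negation(self, rng):
        ratios = random_ratio_table(rng, n=20)
        qci = qc.score_qci(qc.fit_qci(ratios), ratios)
        ref = qci.rename(columns={"qci": "value"})[
            ["location", "year", "sex", "age_group", "value"]
        ]
        r, n = qc.correlate_with_reference(qci, ref)
        assert r == pytest.approx(1.0) and n == 20
        neg = ref.assign(value=-ref["value"])
        r, _ = qc.correlate_with_reference(qci, neg)
        assert r == pytest.approx(-1.0)

    def test_too_few_matches(self, rng):
        ratios = random_ratio_table(rng, n=20)
        qci = qc.score_qci(qc.fit_qci(ratios), ratios)
        ref = qci.head(2).rename(columns={"qci": "value"})
        with pytest.raises(InsufficientDataError):
            qc.correlate_with_reference(qci, ref)

    def test_recovers_latent_quality_on_synthetic_data(self, default_run):
        _, latent, _, result = default_run
        joined = qc.truth_join(latent, result.qci)
        ref = joined[["location", "year", "sex"]].assign(value=joined["q"])
        r, n = qc.correlate_with_reference(result.qci, ref, on=["location", "year", "sex"])
        assert r >= 0.9 and n == len(joined)
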