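import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rgmnet as rg
from rgmnet.data_model import IdentifiabilityError


def brute_force_rows_lacking(D):
    """Exhaustive private-column scan, independent of the implementation."""
    p, k = D.shape
    bad = []
    for i in range(p):
        has_private = any(
            D[i, j] == 1 and all(D[l, j] == 0 for l in range(p) if l != i)
            for j in range(k)
        )
        if not has_private:
            bad.append(i)
    return bad


class TestInstrumentAssignment:
    def test_identity_is_identifiable_on_every_path(self):
        D = np.eye(3, dtype=int)
        for path in ("individual", "exact_summary", "regression_summary"):
            rep = rg.validate_instrument_assignment(D, path)
            assert rep.severity == "ok" and rep.identifiable

    def test_shared_instrument_fails_on_regression_path(self):
        D = np.array([[1, 0], [1, 1]])
        rep = rg.validate_instrument_assignment(D, "regression_summary")
        assert rep.severity == "error"
        assert rep.rows_lacking_unique_instrument == [0]
        with pytest.raises(IdentifiabilityError, match=r"\[0\]"):
            rep.raise_or_warn()

    @pytest.mark.parametrize("path", ["individual", "exact_summary"])
    def test_shared_instrument_warns_and_proceeds_elsewhere(self, path):
        D = np.array([[1, 0], [1, 1]])
        rep = rg.validate_instrument_assignment(D, path)
        assert rep.severity == "warn"
        assert rep.rows_lacking_unique_instrument == [0]
        with pytest.warns(UserWarning):
            rep.raise_or_warn()

    def test_non_binary_entries_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            rg.InstrumentAssignment(np.array([[1, 2], [0, 1]]))

    def test_exhaustive_agreement_with_brute_force(self):
        # all binary matrices with p = 2..3, k = 1..3 (8 + ... + 512 cases)
        for p, k in itertools.product((2, 3), (1, 2, 3)):
            for bits in itertools.product((0, 1), repeat=p * k):
                D = np.array(bits).reshape(p, k)
                rep = rg.validate_instrument_assignment(D, "individual")
                assert rep.rows_lacking_unique_instrument == brute_force_rows_lacking(D)


class TestComputeSummaryStatistics:
    def test_hand_examples(self):
        data = rg.IndividualData(X=np.array([[1.0], [-1.0]]), Y=np.array([[1.0], [-1.0]]))
        S = rg.compute_summary_statistics(data)
        for M in (S.Sxx, S.Syx, S.Syy):
            np.testing.assert_allclose(M, [[1.0]])
        data = rg.IndividualData(X=np.array([[2.0]]), Y=np.array([[3.0]]))
        S = rg.compute_summary_statistics(data)
        np.testing.assert_allclose(S.Sxx, [[4.0]])
        np.testing.assert_allclose(S.Syx, [[6.0]])
        np.testing.assert_allclose(S.Syy, [[9.0]])
        assert S.n == 1

    def test_exact_symmetry(self, rng):
        data = rg.IndividualData(
            X=rng.standard_normal((37, 4)), Y=rng.standard_normal((37, 3))
        )
        S = rg.compute_summary_statistics(data)
        assert np.array_equal(S.Syy, S.Syy.T)
        assert np.array_equal(S.Sxx, S.Sxx.T)

    def test_row_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="row counts"):
            rg.IndividualData(X=rng.standard_normal((5, 2)), Y=rng.standard_normal((6, 2)))


class TestReconstructSummary:
    def test_single_instrument_inversion(self):
        # beta = Syx/Sxx inverted, and Syy_ii = MSE + beta^2 Sxx_jj
        D = np.eye(2, dtype=int)
        reg = rg.RegressionSummaries(
            Beta=np.diag([0.5, 1.0]),
            SigmaHat=np.array([[1.0, 1.0], [1.0, 2.0]]),
            Sxx=np.diag([2.0, 1.0]),
            n=10,
        )
        S = rg.reconstruct_summary(reg, D)
        assert S.Syx[0, 0] == pytest.approx(1.0)
        assert S.Syy[0, 0] == pytest.approx(1.0 + 0.25 * 2)
        assert S.Syx[0, 1] == 0.0 and S.Syx[1, 0] == 0.0
        assert np.isnan(S.Syy[0, 1]) and np.isnan(S.Syy[1, 0])
        assert S.missing_offdiag

    def test_round_trip_against_regression_oracle(self, rng):
        """Fitting per-cell no-intercept regressions and reconstructing
        recovers Syx on D=1 cells and the Syy diagonal exactly."""
        # response 0 has two private instruments (exercises the averaging)
        D = rg.InstrumentAssignment(
            np.array([[1, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1]])
        )
        p, k, n = 3, 4, 300
        X = rng.standard_normal((n, k))
        Y = rng.standard_normal((n, p))
        data = rg.IndividualData(X=X, Y=Y)
        # independent brute-force per-cell regressions
        Beta = np.zeros((p, k))
        SigmaHat = np.ones((p, k))
        for i, j in np.argwhere(D.D == 1):
            b = float(np.sum(Y[:, i] * X[:, j]) / np.sum(X[:, j] ** 2))
            Beta[i, j] = b
            SigmaHat[i, j] = float(np.mean((Y[:, i] - b * X[:, j]) ** 2))
        reg = rg.RegressionSummaries(
            Beta=Beta, SigmaHat=SigmaHat,
            Sxx=rg.compute_summary_statistics(data).Sxx, n=n,
        )
        S_rec = rg.reconstruct_summary(reg, D)
        S = rg.compute_summary_statistics(data)
        mask = D.D == 1
        np.testing.assert_allclose(S_rec.Syx[mask], S.Syx[mask], atol=1e-8)
        np.testing.assert_allclose(np.diag(S_rec.Syy), np.diag(S.Syy), atol=1e-8)

    def test_nonpositive_mse_rejected(self):
        reg_kwargs = dict(Beta=np.eye(2), Sxx=np.eye(2), n=5)
        with pytest.raises(ValueError, match="SigmaHat"):
            rg.reconstruct_summary(
                rg.RegressionSummaries(SigmaHat=np.array([[0.0, 1], [1, 1.0]]), **reg_kwargs),
                np.eye(2, dtype=int),
            )


class TestMatrixIO:
    def test_round_trip(self, rng, tmp_path):
        M = rng.standard_normal((3, 3))
        fp = tmp_path / "m.csv"
        rg.write_matrix_file(M, fp)
        assert np.array_equal(rg.read_matrix_file(fp), M)

    def test_headerless_and_tab_delimited(self, tmp_path):
        fp = tmp_path / "m.tsv"
        fp.write_text("1.5\t2\n3\t4\n")
        assert np.array_equal(rg.read_matrix_file(fp), [[1.5, 2], [3, 4]])

    def test_na_cell_names_location(self, tmp_path):
        fp = tmp_path / "bad.csv"
        fp.write_text("1,2\n3,NA\n")
        with pytest.raises(ValueError, match="row 2, column 2"):
            rg.read_matrix_file(fp)

    def test_ragged_rows_rejected(self, tmp_path):
        fp = tmp_path / "ragged.csv"
        fp.write_text("1,2,3\n4,5\n")
        with pytest.raises(ValueError, match="ragged"):
            rg.read_matrix_file(fp)

    def test_header_and_rownames_stripped(self, tmp_path):
        fp = tmp_path / "named.csv"
        fp.write_text(",v1,v2\nr1,1,2\nr2,3,4\n")
        assert np.array_equal(rg.read_matrix_file(fp), [[1, 2], [3, 4]])

    def test_expected_shape_enforced(self, tmp_path):
        fp = tmp_path / "m.csv"
        fp.write_text("1,2\n3,4\n")
        with pytest.raises(ValueError, match="expected shape"):
            rg.read_matrix_file(fp, expected_shape=(3, 2))


class TestWriteFitOutputs:
    def test_all_documented_outputs_written(self, small_fit, tmp_path):
        written = rg.write_fit_outputs(small_fit, tmp_path)
        for name in ("AEst", "BEst", "GammaEst", "zAEst", "summary", "edges", "GammaPst"):
            assert name in written
        A_back = rg.read_matrix_file(written["AEst"])
        assert np.array_equal(A_back, small_fit.AEst)
        stack = np.load(written["GammaPst"])
        assert np.array_equal(stack, small_fit.GammaPst)


@given(
    st.integers(2, 3).flatmap(
        lambda p: st.integers(1, 3).flatmap(
            lambda k: st.lists(
                st.integers(0, 1), min_size=p * k, max_size=p * k
            ).map(lambda bits: np.array(bits).reshape(p, k))
        )
    )
)
@settings(max_examples=100)
def test_validation_matches_brute_force_property(D):
    rep = rg.validate_instrument_assignment(D, "exact_summary")
    assert rep.rows_lacking_unique_instrument == brute_force_rows_lacking(D)
    assert rep.identifiable == (not brute_force_rows_lacking(D))
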