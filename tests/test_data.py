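"""Sample I/O, validation, and covariate partialling."""
import numpy as np
import pandas as pd
import pytest

from ts2sls import (Sample, UnderIdentifiedError, ValidationError, fit_ts2sls,
                    partial_out, read_sample_csv, validate_design,
                    write_sample_csv)
from ts2sls.exceptions import SingularMatrixError


class TestReadSampleCSV:
    def test_minimal_well_formed_input(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("y,z\n1.0,2.0\n3.0,4.0\n")
        s = read_sample_csv(p, {"y": "outcome", "z": "instrument"})
        assert s.n == 2
        assert s.instrument_cols == ["z"]
        np.testing.assert_allclose(s.y, [1.0, 3.0])

    def test_missing_value_names_row_and_column(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("y,z\n1.0,2.0\n3.0,\n")
        with pytest.raises(ValidationError, match=r"'z'.*row 1"):
            read_sample_csv(p, {"y": "outcome", "z": "instrument"})

    def test_absent_column_named_in_error(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("y,z\n1.0,2.0\n3.0,4.0\n")
        with pytest.raises(ValidationError, match="'w'"):
            read_sample_csv(p, {"y": "outcome", "w": "instrument"})

    def test_non_numeric_value_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("y,z\n1.0,a\n3.0,b\n")
        with pytest.raises(ValidationError, match="numeric"):
            read_sample_csv(p, {"y": "outcome", "z": "instrument"})

    def test_round_trip_exact(self, tmp_path):
        df = pd.DataFrame({"y": [1.25, -3.5], "z": [0.125, 7.0]})
        s = Sample(df, {"y": "outcome", "z": "instrument"})
        p = tmp_path / "out.csv"
        write_sample_csv(s, p)
        s2 = read_sample_csv(p, {"y": "outcome", "z": "instrument"})
        pd.testing.assert_frame_equal(s.data, s2.data)

    def test_two_cluster_columns_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "g": [0, 1], "h": [0, 1]})
        with pytest.raises(ValidationError, match="cluster"):
            Sample(df, {"y": "outcome", "g": "cluster_id", "h": "cluster_id"})


class TestPartialOut:
    def test_constant_covariate_equals_demeaning(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "y": rng.normal(size=10), "z": rng.normal(size=10),
            "const": np.ones(10),
        })
        s = Sample(df, {"y": "outcome", "z": "instrument", "const": "covariate"})
        out = partial_out(s)
        np.testing.assert_allclose(out.y, df["y"] - df["y"].mean(), atol=1e-12)
        np.testing.assert_allclose(out.Z[:, 0], df["z"] - df["z"].mean(), atol=1e-12)
        assert out.covariate_cols == []

    def test_self_projection_gives_zero_residuals(self):
        rng = np.random.default_rng(1)
        w = rng.normal(size=8)
        df = pd.DataFrame({"y": w.copy(), "w": w, "z": rng.normal(size=8)})
        s = Sample(df, {"y": "outcome", "z": "instrument", "w": "covariate"})
        out = partial_out(s)
        np.testing.assert_allclose(out.y, 0.0, atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "y": rng.normal(size=20), "z": rng.normal(size=20),
            "const": np.ones(20), "w": rng.normal(size=20),
        })
        roles = {"y": "outcome", "z": "instrument",
                 "const": "covariate", "w": "covariate"}
        once = partial_out(Sample(df, roles))
        df2 = once.data.copy()
        df2["const"] = 1.0
        df2["w"] = df["w"]
        twice = partial_out(Sample(df2, roles))
        np.testing.assert_allclose(twice.y, once.y, atol=1e-12)
        np.testing.assert_allclose(twice.Z, once.Z, atol=1e-12)

    def test_rank_deficient_covariates_raise(self):
        df = pd.DataFrame({
            "y": [1.0, 2.0, 3.0, 4.0], "z": [0.0, 1.0, 0.5, 2.0],
            "w1": [1.0, 2.0, 3.0, 4.0], "w2": [2.0, 4.0, 6.0, 8.0],
        })
        s = Sample(df, {"y": "outcome", "z": "instrument",
                        "w1": "covariate", "w2": "covariate"})
        with pytest.raises(SingularMatrixError):
            partial_out(s)

    def test_cluster_ids_preserved(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0], "c": np.ones(3),
                           "g": ["a", "a", "b"], "z": [0.1, 0.4, 0.2]})
        s = Sample(df, {"y": "outcome", "z": "instrument",
                        "c": "covariate", "g": "cluster_id"})
        out = partial_out(s)
        assert out.cluster_col == "g"
        assert list(out.clusters) == ["a", "a", "b"]


class TestValidateDesign:
    def _mk(self, kz, kx, n1=10, n2=12):
        rng = np.random.default_rng(3)
        znames = [f"z{a}" for a in range(kz)]
        xnames = [f"x{r}" for r in range(kx)]
        df1 = pd.DataFrame(rng.normal(size=(n1, 1 + kz)),
                           columns=["y"] + znames)
        df2 = pd.DataFrame(rng.normal(size=(n2, kx + kz)),
                           columns=xnames + znames)
        s1 = Sample(df1, {"y": "outcome", **{z: "instrument" for z in znames}})
        s2 = Sample(df2, {**{x: "exposure" for x in xnames},
                          **{z: "instrument" for z in znames}})
        return s1, s2

    @pytest.mark.parametrize("kz,kx,just", [(1, 1, True), (3, 1, False),
                                            (3, 3, True)])
    def test_identification_flag(self, kz, kx, just):
        info = validate_design(*self._mk(kz, kx))
        assert info.just_identified is just
        assert info.kz == kz and info.kx == kx

    def test_under_identified_raises(self):
        with pytest.raises(UnderIdentifiedError, match="under-identified"):
            validate_design(*self._mk(1, 2))

    def test_alpha_hat(self):
        info = validate_design(*self._mk(2, 1, n1=30, n2=12))
        assert info.alpha_hat == pytest.approx(2.5)

    def test_instrument_name_mismatch(self):
        s1, _ = self._mk(2, 1)
        _, s2 = self._mk(2, 1)
        df2 = s2.data.rename(columns={"z0": "w0"})
        s2bad = Sample(df2, {"x0": "exposure", "w0": "instrument",
                             "z1": "instrument"})
        with pytest.raises(ValidationError, match="match in name and order"):
            validate_design(s1, s2bad)


class TestFrischWaugh:
    def test_partialling_equals_included_instruments(self):
        """Exposure coefficients agree between the two covariate routes."""
        rng = np.random.default_rng(7)
        n1, n2 = 120, 100
        w1 = np.column_stack([np.ones(n1), rng.normal(size=n1)])
        w2 = np.column_stack([np.ones(n2), rng.normal(size=n2)])
        z1, z2 = rng.normal(size=(n1, 2)), rng.normal(size=(n2, 2))
        x2 = z2 @ np.array([1.0, 0.7]) + w2 @ np.array([0.5, -0.2]) \
            + rng.normal(size=n2)
        x1 = z1 @ np.array([1.0, 0.7]) + w1 @ np.array([0.5, -0.2]) \
            + rng.normal(size=n1)
        y1 = 2.0 * x1 + w1 @ np.array([1.0, 0.3]) + rng.normal(size=n1)
        cols = ["const", "w"]
        df1 = pd.DataFrame(np.column_stack([y1, z1, w1]),
                           columns=["y", "za", "zb"] + cols)
        df2 = pd.DataFrame(np.column_stack([x2, z2, w2]),
                           columns=["x", "za", "zb"] + cols)
        roles1 = {"y": "outcome", "za": "instrument", "zb": "instrument",
                  "const": "covariate", "w": "covariate"}
        roles2 = {"x": "exposure", "za": "instrument", "zb": "instrument",
                  "const": "covariate", "w": "covariate"}
        s1, s2 = Sample(df1, roles1), Sample(df2, roles2)
        partialled = fit_ts2sls(s1, s2, covariates="partial_out")
        included = fit_ts2sls(s1, s2, covariates="include")
        assert included.params["x"] == pytest.approx(
            partialled.params["x"], abs=1e-8)
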