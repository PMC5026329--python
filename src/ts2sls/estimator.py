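"""The two-sample 2SLS point estimator and its variance estimators.

The structural model is y = x'beta + eps with instruments z, but y and x
are never observed together: sample 1 holds (y, z), sample 2 holds (x, z).
The estimator combines the sample-1 reduced form pi_y1 with the sample-2
first stage Pi_x2:

    beta_hat = (X1_hat' X1_hat)^-1 X1_hat' y1,   X1_hat = Z1 Pi_hat_x2.

Because beta_hat is a smooth function of two OLS stage estimators, its
asymptotic variance follows from the stage covariances. Four estimators
are provided:

``robust`` / ``cluster``
    C_hat Var(pi_y1) C_hat' + (beta'⊗C_hat) Var(vec Pi_x2) (beta⊗C_hat')
    with heteroskedasticity- (or cluster-) robust stage covariances and
    C_hat the coefficients from regressing the columns of Z1 on X1_hat.
``homoskedastic``
    sigma_u^2 (X1_hat'X1_hat)^-1 + (beta' Sigma_v beta) C_hat (Z2'Z2)^-1 C_hat',
    the collapse of the robust form under conditional homoskedasticity of
    both stages. Note it keeps the two samples' instrument information
    separate: the first-stage part uses Z2'Z2, never a rescaled Z1'Z1.
``inoue_solon``
    (sigma_u_tilde^2 + (n1/n2) beta' Sigma_v beta)(X1_hat'X1_hat)^-1, the
    earlier homoskedastic-case estimator that additionally forces
    E(z1 z1') = E(z2 z2'). It is inconsistent when the two samples'
    instrument second moments differ by a scale factor c != 1, a scenario
    the test suite exercises.
``scalar_delta``
    (Var(pi_y1) + beta^2 Var(pi_x2)) / pi_x2^2, the delta-method formula
    for the just-identified single-exposure case; the robust form reduces
    to it algebraically when kx = kz = 1.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .data import DesignInfo, Sample, prepare_samples, validate_design
from .exceptions import ValidationError
from .linalg import check_nonsingular, inv_psd, symmetrize
from .stages import EquationFit, ThetaFit, ols_fit, sandwich_vcov

VCOV_METHODS = ("robust", "cluster", "homoskedastic", "inoue_solon", "scalar_delta")

#: stage-vcov flavor each variance method requires
_METHOD_FLAVOR = {
    "robust": "HC0",
    "cluster": "cluster",
    "homoskedastic": "homoskedastic",
    "inoue_solon": "homoskedastic",
    "scalar_delta": "HC0",
}


def ts2sls_point(y1: np.ndarray, Z1: np.ndarray, first_stage: EquationFit):
    """Point estimate: OLS of y1 on the predicted exposures Z1 Pi_hat_x2.

    Returns ``(beta_hat, X1_hat)``. Raises SingularMatrixError when
    X1_hat'X1_hat is numerically singular (weak or collinear first stage).
    """
    Pi = np.asarray(first_stage.coefficients, dtype=float).reshape(first_stage.kz, -1)
    Z1 = np.asarray(Z1, dtype=float)
    if Z1.shape[1] != Pi.shape[0]:
        raise ValidationError(
            f"sample-1 instruments ({Z1.shape[1]}) not conformable with "
            f"first stage ({Pi.shape[0]} instruments)"
        )
    X1_hat = Z1 @ Pi
    gram = X1_hat.T @ X1_hat
    check_nonsingular(gram, "predicted-exposure cross-product X1_hat'X1_hat")
    beta = np.linalg.solve(gram, X1_hat.T @ np.asarray(y1, dtype=float))
    return beta, X1_hat


def c_hat(X1_hat: np.ndarray, Z1: np.ndarray) -> np.ndarray:
    """kx × kz coefficients from regressing each column of Z1 on X1_hat.

    Equals (Pi' Z1'Z1 Pi)^-1 Pi' Z1'Z1; in just-identified designs this is
    Pi_hat_x2^-1. Satisfies C_hat @ Pi_hat = I_kx identically.
    """
    gram = X1_hat.T @ X1_hat
    check_nonsingular(gram, "X1_hat'X1_hat")
    return np.linalg.solve(gram, X1_hat.T @ Z1)


def variance(method: str,
             beta_hat: np.ndarray,
             C: np.ndarray,
             reduced_form: EquationFit,
             first_stage: EquationFit,
             X1_hat: np.ndarray,
             y1: np.ndarray | None = None,
             alpha_hat: float | None = None) -> np.ndarray:
    """kx × kx variance estimate of beta_hat under the chosen method.

    The stage fits must already carry vcovs of a flavor compatible with
    the method (robust/cluster need HC0/cluster stage vcovs; the
    homoskedastic and Inoue–Solon methods need homoskedastic ones).
    """
    if method not in VCOV_METHODS:
        raise ValidationError(f"unknown variance method {method!r}")
    beta_hat = np.atleast_1d(np.asarray(beta_hat, dtype=float))
    kx = beta_hat.shape[0]

    if method in ("robust", "cluster", "scalar_delta"):
        want = ("HC0", "cluster")
        for fit, name in ((reduced_form, "reduced form"), (first_stage, "first stage")):
            if fit.vcov is None or fit.vcov_flavor not in want:
                raise ValidationError(
                    f"method {method!r} needs a robust ({'/'.join(want)}) "
                    f"{name} vcov, got {fit.vcov_flavor!r}"
                )
    else:
        for fit, name in ((reduced_form, "reduced form"), (first_stage, "first stage")):
            if fit.vcov is None or fit.vcov_flavor != "homoskedastic":
                raise ValidationError(
                    f"method {method!r} needs a homoskedastic {name} vcov, "
                    f"got {fit.vcov_flavor!r}"
                )

    if method == "scalar_delta":
        if kx != 1 or reduced_form.kz != 1:
            raise ValidationError("scalar_delta requires kx = kz = 1")
        pi_x2 = float(np.asarray(first_stage.coefficients).reshape(()))
        v = (float(reduced_form.vcov[0, 0])
             + float(beta_hat[0]) ** 2 * float(first_stage.vcov[0, 0])) / pi_x2 ** 2
        return np.array([[v]])

    if method in ("robust", "cluster"):
        Vy = reduced_form.vcov
        Vx = first_stage.vcov
        bC = np.kron(beta_hat[None, :], C)          # kx × (kx·kz)
        V = C @ Vy @ C.T + bC @ Vx @ bC.T
        return symmetrize(np.atleast_2d(V))

    # homoskedastic-family methods
    sigma_u2 = reduced_form.sigma2()                 # (y1 - Z1 pi_y1)'(...)/n1
    Sigma_v = np.atleast_2d(first_stage.sigma2())    # V'V/n2
    XtX_inv = inv_psd(X1_hat.T @ X1_hat, "X1_hat'X1_hat")
    bSb = float(beta_hat @ Sigma_v @ beta_hat)
    if method == "homoskedastic":
        Z2 = first_stage.Z
        CZ2C = C @ inv_psd(Z2.T @ Z2, "Z2'Z2") @ C.T
        return symmetrize(sigma_u2 * XtX_inv + bSb * CZ2C)
    # inoue_solon
    if y1 is None or alpha_hat is None:
        raise ValidationError("inoue_solon needs y1 and alpha_hat = n1/n2")
    u_tilde = np.asarray(y1, dtype=float) - X1_hat @ beta_hat
    sigma_u2_tilde = float(u_tilde @ u_tilde) / len(u_tilde)
    return symmetrize((sigma_u2_tilde + alpha_hat * bSb) * XtX_inv)


def first_stage_F(first_stage: EquationFit) -> np.ndarray:
    """Per-exposure Wald F diagnostic that all instrument coefficients are 0.

    Uses whatever vcov flavor the stage carries. Reported as a weak-
    instrument diagnostic only; it never alters the estimator.
    """
    if first_stage.vcov is None:
        raise ValidationError("first stage carries no vcov")
    kz, m = first_stage.kz, first_stage.n_responses
    Pi = np.asarray(first_stage.coefficients).reshape(kz, m)
    F = np.empty(m)
    for r in range(m):
        block = first_stage.vcov[r * kz:(r + 1) * kz, r * kz:(r + 1) * kz]
        F[r] = float(Pi[:, r] @ inv_psd(block, "first-stage vcov block") @ Pi[:, r]) / kz
    return F


@dataclass
class TS2SLSResults:
    """Estimates, uncertainty and diagnostics from a two-sample IV fit.

    Mirrors the usual regression-results interface: ``params``, ``bse``,
    ``cov_params()``, ``conf_int()``, ``zvalues``, ``pvalues`` and a
    plain-text ``summary()``. Confidence intervals use normal critical
    values — the theory is asymptotic and defines no finite-sample dof.
    """

    params: pd.Series
    vcov: np.ndarray
    vcov_method: str
    stage_flavor: str
    design: DesignInfo
    C_hat: np.ndarray
    X1_hat: np.ndarray
    reduced_form: EquationFit
    first_stage: EquationFit | list[EquationFit]
    sigma_u2_hat: float
    sigma_u2_tilde: float
    Sigma_v_hat: np.ndarray | None
    fs_F: np.ndarray
    theta_fit: Optional[ThetaFit] = None
    estimator: str = "ts2sls"

    @property
    def beta_hat(self) -> np.ndarray:
        return self.params.to_numpy()

    @property
    def exog_names(self) -> list[str]:
        return list(self.params.index)

    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(self.vcov, index=self.params.index,
                            columns=self.params.index)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov)), index=self.params.index)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.zvalues)),
                         index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.norm.ppf(1 - alpha / 2)
        lo = self.params - q * self.bse
        hi = self.params + q * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def summary(self, alpha: float = 0.05) -> str:
        d = self.design
        ci = self.conf_int(alpha)
        lines = [
            "Two-Sample 2SLS Results",
            "=" * 78,
            f"Estimator:      {self.estimator:<24s} vcov: {self.vcov_method}",
            f"n1 (outcome):   {d.n1:<24d} n2 (exposure): {d.n2}",
            f"kz:             {d.kz:<24d} kx:            {d.kx}",
            f"identification: {'just identified' if d.just_identified else 'over-identified':<24s}"
            f" n1/n2:         {d.alpha_hat:.4f}",
            "-" * 78,
            f"{'':<14s}{'coef':>12s}{'std err':>12s}{'z':>10s}{'P>|z|':>10s}"
            f"{'[' + format(alpha / 2, '.3f'):>10s}{format(1 - alpha / 2, '.3f') + ']':>10s}",
            "-" * 78,
        ]
        for name in self.params.index:
            lines.append(
                f"{str(name):<14s}{self.params[name]:>12.6f}{self.bse[name]:>12.6f}"
                f"{self.zvalues[name]:>10.3f}{self.pvalues[name]:>10.3f}"
                f"{ci.loc[name, 'lower']:>10.4f}{ci.loc[name, 'upper']:>10.4f}"
            )
        lines.append("-" * 78)
        Fs = ", ".join(f"{f:.1f}" for f in np.atleast_1d(self.fs_F))
        lines.append(f"first-stage F (per exposure): {Fs}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        ci = self.conf_int()
        return {
            "estimator": self.estimator,
            "vcov_method": self.vcov_method,
            "n1": self.design.n1,
            "n2": self.design.n2,
            "kz": self.design.kz,
            "kx": self.design.kx,
            "exposures": [str(i) for i in self.params.index],
            "beta_hat": self.params.tolist(),
            "se": self.bse.tolist(),
            "ci95_lower": ci["lower"].tolist(),
            "ci95_upper": ci["upper"].tolist(),
            "first_stage_F": np.atleast_1d(self.fs_F).tolist(),
        }


def fit_ts2sls(sample1: Sample, sample2: Sample,
               vcov_method: str = "robust",
               stage_flavor: str | None = None,
               covariates: str = "partial_out",
               hc1: bool = False,
               cluster_correction: bool = False) -> TS2SLSResults:
    """End-to-end two-sample 2SLS fit on the standard design.

    Wires covariate handling, the two OLS stages with sandwich vcovs of a
    flavor compatible with ``vcov_method``, the point estimate, C_hat, the
    requested variance, and normal-approximation confidence intervals.
    """
    if vcov_method not in VCOV_METHODS:
        raise ValidationError(f"unknown vcov method {vcov_method!r}")
    s1, s2 = prepare_samples(sample1, sample2, covariates)
    design = validate_design(s1, s2)
    flavor = stage_flavor or _METHOD_FLAVOR[vcov_method]

    y1, Z1 = s1.y, s1.Z
    X2, Z2 = s2.X, s2.Z

    rf = ols_fit(y1, Z1, names=s1.instrument_cols)
    fs = ols_fit(X2, Z2, names=s2.instrument_cols)
    cl1 = s1.clusters if flavor == "cluster" else None
    cl2 = s2.clusters if flavor == "cluster" else None
    if flavor == "cluster" and (cl1 is None or cl2 is None):
        raise ValidationError("cluster vcov requires a cluster_id column in both samples")
    sandwich_vcov(rf, flavor, clusters=cl1, hc1=hc1, cluster_correction=cluster_correction)
    sandwich_vcov(fs, flavor, clusters=cl2, hc1=hc1, cluster_correction=cluster_correction)

    beta, X1_hat = ts2sls_point(y1, Z1, fs)
    beta = np.atleast_1d(beta)
    C = c_hat(X1_hat, Z1)

    V = variance(vcov_method, beta, C, rf, fs, X1_hat, y1=y1,
                 alpha_hat=design.alpha_hat)

    u_tilde = y1 - X1_hat @ beta
    names = s2.exposure_cols
    res = TS2SLSResults(
        params=pd.Series(beta, index=names),
        vcov=V,
        vcov_method=vcov_method,
        stage_flavor=flavor,
        design=design,
        C_hat=C,
        X1_hat=X1_hat,
        reduced_form=rf,
        first_stage=fs,
        sigma_u2_hat=float(rf.sigma2()),
        sigma_u2_tilde=float(u_tilde @ u_tilde) / design.n1,
        Sigma_v_hat=np.atleast_2d(fs.sigma2()),
        fs_F=first_stage_F(fs),
    )
    return res
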