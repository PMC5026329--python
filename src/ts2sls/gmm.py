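"""Nonlinear GMM for the two-sample design, with the Hansen J test.

The moment conditions in psi = (beta', vec(Pi)')' are

    g1(psi) = (1/n1) sum_i z1i (y1i - z1i' Pi beta)        (kz,)
    g2(psi) = (1/n2) sum_j (x2j - Pi' z2j) ⊗ z2j           (kz*kx,)

(the second block uses the response-major v ⊗ z ordering so vec/Kronecker
conventions match the stage machinery). The criterion g' W g is quadratic
in beta for fixed Pi and quadratic in vec(Pi) for fixed beta, so it is
minimized by alternating exact linear solves — deterministic and
derivative-free — initialized at the two-sample 2SLS solution. In
just-identified designs the minimizer reproduces TS2SLS exactly; in
over-identified designs the two differ in finite samples but share a
limiting distribution.

Scaling convention (frozen here and validated by the simulated size of
the J test): all moment variances are expressed on the n1 scale, i.e. the
weight is the inverse of

    S = blockdiag(S1, alpha_hat * S2),  alpha_hat = n1/n2,

with S1 = (1/n1) sum z1 z1' u^2 and S2 = (1/n2) sum (v v') ⊗ (z2 z2')
(homoskedastic analogues in step 1), so that J = n1 * g' S^-1 g is
asymptotically chi-square(kz - kx) under valid moments. With the
homoskedastic step-1 blocks this weight makes the criterion identical to
the minimum-distance form in the unrestricted stage estimates weighted by
the inverses of their estimated covariances.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import Sample, prepare_samples, validate_design
from .exceptions import ConvergenceError, ValidationError
from .estimator import fit_ts2sls
from .linalg import check_nonsingular, inv_psd, symmetrize
from .stages import ols_fit


def _split_psi(psi: np.ndarray, kz: int, kx: int):
    beta = psi[:kx]
    Pi = psi[kx:].reshape(kz, kx, order="F")
    return beta, Pi


def moment_conditions(psi: np.ndarray, y1, Z1, X2, Z2) -> np.ndarray:
    """Stacked sample moments, length kz + kz*kx."""
    Z1 = np.asarray(Z1, float)
    Z2 = np.asarray(Z2, float)
    y1 = np.asarray(y1, float)
    X2 = np.asarray(X2, float).reshape(len(Z2), -1)
    kz = Z1.shape[1]
    kx = X2.shape[1]
    psi = np.asarray(psi, float)
    if psi.shape[0] != kx + kz * kx:
        raise ValidationError(
            f"psi has length {psi.shape[0]}, expected {kx + kz * kx}"
        )
    beta, Pi = _split_psi(psi, kz, kx)
    n1, n2 = len(Z1), len(Z2)
    g1 = Z1.T @ (y1 - Z1 @ (Pi @ beta)) / n1
    V = X2 - Z2 @ Pi                                   # (n2, kx)
    g2 = np.einsum("jr,ja->ra", V, Z2).reshape(-1) / n2  # v ⊗ z, response-major
    return np.concatenate([g1, g2])


def _moment_variance(psi, y1, Z1, X2, Z2, homoskedastic: bool) -> np.ndarray:
    """S = blockdiag(S1, alpha_hat*S2): variance of sqrt(n1) * moments."""
    kz = Z1.shape[1]
    X2 = X2.reshape(len(Z2), -1)
    kx = X2.shape[1]
    n1, n2 = len(Z1), len(Z2)
    alpha_hat = n1 / n2
    beta, Pi = _split_psi(psi, kz, kx)
    u = y1 - Z1 @ (Pi @ beta)
    V = X2 - Z2 @ Pi
    if homoskedastic:
        s_u2 = float(u @ u) / n1
        Sigma_v = V.T @ V / n2
        S1 = s_u2 * (Z1.T @ Z1) / n1
        S2 = np.kron(Sigma_v, Z2.T @ Z2 / n2)
    else:
        S1 = (Z1 * (u ** 2)[:, None]).T @ Z1 / n1
        Sc = np.einsum("jr,ja->jra", V, Z2).reshape(n2, -1)
        S2 = Sc.T @ Sc / n2
    S = np.zeros((kz + kz * kx, kz + kz * kx))
    S[:kz, :kz] = S1
    S[kz:, kz:] = alpha_hat * S2
    return symmetrize(S)


def _criterion(psi, W, y1, Z1, X2, Z2) -> float:
    g = moment_conditions(psi, y1, Z1, X2, Z2)
    return float(g @ W @ g)


def solve_gmm(y1, Z1, X2, Z2, weight: np.ndarray,
              psi0: np.ndarray | None = None,
              tol: float = 1e-10, max_iter: int = 500):
    """Minimize the GMM criterion by alternating exact linear solves.

    Given Pi the criterion is quadratic in beta; given beta it is
    quadratic in vec(Pi); each partial problem is a weighted least-squares
    solve. Iterates until the relative parameter change drops below
    ``tol``. Returns ``(psi, history)`` where history holds the criterion
    value after every full alternating iteration; each iteration minimizes
    exactly over one block then the other, so the history is
    non-increasing (asserted at run time).
    """
    Z1 = np.asarray(Z1, float)
    Z2 = np.asarray(Z2, float)
    y1 = np.asarray(y1, float)
    X2 = np.asarray(X2, float).reshape(len(Z2), -1)
    kz, kx = Z1.shape[1], X2.shape[1]
    n1, n2 = len(Z1), len(Z2)
    W = np.asarray(weight, float)
    if W.shape != (kz + kz * kx,) * 2:
        raise ValidationError("weight matrix has wrong dimension")

    if psi0 is None:
        fs = ols_fit(X2, Z2)
        res = fit_ts2sls_arrays(y1, Z1, X2, Z2)
        psi0 = np.concatenate([res, np.asarray(fs.coefficients).reshape(-1, order="F")])
    psi = np.asarray(psi0, float).copy()

    a1 = Z1.T @ y1 / n1
    Z1Z1 = Z1.T @ Z1
    Z2Z2 = Z2.T @ Z2
    c2 = (Z2.T @ X2).T.reshape(-1) / n2          # vec(Z2'X2), response-major
    history = [_criterion(psi, W, y1, Z1, X2, Z2)]

    for _ in range(max_iter):
        beta, Pi = _split_psi(psi, kz, kx)
        # --- beta step: g = g0 - M beta, M = [Z1'Z1 Pi / n1; 0]
        M = np.zeros((kz + kz * kx, kx))
        M[:kz] = Z1Z1 @ Pi / n1
        g0 = np.concatenate([a1, c2 - np.kron(np.eye(kx), Z2Z2 / n2) @
                             Pi.reshape(-1, order="F")])
        A = M.T @ W @ M
        check_nonsingular(A, "GMM beta-step normal matrix")
        beta_new = np.linalg.solve(A, M.T @ W @ g0)
        # --- Pi step: g = c0 - D vec(Pi)
        D = np.zeros((kz + kz * kx, kz * kx))
        D[:kz] = np.kron(beta_new[None, :], Z1Z1) / n1
        D[kz:] = np.kron(np.eye(kx), Z2Z2) / n2
        c0 = np.concatenate([a1, c2])
        A = D.T @ W @ D
        check_nonsingular(A, "GMM Pi-step normal matrix")
        pi_new = np.linalg.solve(A, D.T @ W @ c0)
        psi_new = np.concatenate([beta_new, pi_new])
        history.append(_criterion(psi_new, W, y1, Z1, X2, Z2))
        if history[-1] > history[-2] * (1 + 1e-8) + 1e-14:
            raise ConvergenceError(
                "GMM criterion increased across an alternating step",
                last_iterate=psi_new, history=history,
            )
        delta = np.linalg.norm(psi_new - psi) / max(np.linalg.norm(psi), 1.0)
        psi = psi_new
        if delta < tol:
            return psi, history
    raise ConvergenceError(
        f"GMM alternating solver did not converge in {max_iter} iterations",
        last_iterate=psi, history=history,
    )


def fit_ts2sls_arrays(y1, Z1, X2, Z2) -> np.ndarray:
    """Bare-array TS2SLS point estimate (initialization helper)."""
    fs = ols_fit(X2, Z2)
    Pi = np.asarray(fs.coefficients).reshape(Z2.shape[1], -1)
    X1h = Z1 @ Pi
    gram = X1h.T @ X1h
    check_nonsingular(gram, "X1_hat'X1_hat")
    return np.atleast_1d(np.linalg.solve(gram, X1h.T @ y1))


@dataclass
class GMMResults:
    """Two-step efficient GMM estimates with the Hansen J test."""

    params: pd.Series                       # beta block
    psi: np.ndarray
    vcov_psi: np.ndarray
    kz: int
    kx: int
    n1: int
    n2: int
    j_stat: float
    criterion_history: list = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = True

    @property
    def j_df(self) -> int:
        return self.kz - self.kx

    @property
    def j_pvalue(self) -> float | None:
        """Upper-tail chi-square p; None for just-identified designs."""
        if self.j_df == 0:
            return None
        return float(stats.chi2.sf(self.j_stat, self.j_df))

    @property
    def beta_hat(self) -> np.ndarray:
        return self.params.to_numpy()

    @property
    def vcov(self) -> np.ndarray:
        return self.vcov_psi[:self.kx, :self.kx]

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov)), index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame({"lower": self.params - q * self.bse,
                             "upper": self.params + q * self.bse})

    def summary(self) -> str:
        lines = [
            "Two-Sample Nonlinear GMM Results (two-step efficient)",
            "=" * 70,
            f"n1: {self.n1}   n2: {self.n2}   kz: {self.kz}   kx: {self.kx}   "
            f"iterations: {self.n_iterations}",
            "-" * 70,
            f"{'':<14s}{'coef':>12s}{'std err':>12s}",
        ]
        for name in self.params.index:
            lines.append(f"{str(name):<14s}{self.params[name]:>12.6f}"
                         f"{self.bse[name]:>12.6f}")
        lines.append("-" * 70)
        if self.j_df > 0:
            lines.append(f"Hansen J: {self.j_stat:.4f}   df: {self.j_df}   "
                         f"p-value: {self.j_pvalue:.4f}")
        else:
            lines.append("Hansen J: not applicable (just identified, df = 0)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "estimator": "two-step GMM",
            "n1": self.n1, "n2": self.n2, "kz": self.kz, "kx": self.kx,
            "beta_hat": self.params.tolist(),
            "se": self.bse.tolist(),
            "J": self.j_stat,
            "J_df": self.j_df,
            "J_pvalue": self.j_pvalue,
            "converged": self.converged,
            "iterations": self.n_iterations,
        }


def two_step_fit(sample1: Sample, sample2: Sample,
                 covariates: str = "partial_out") -> GMMResults:
    """Two-step efficient GMM with a Hansen overidentification test.

    Step 1 uses the homoskedastic block-diagonal weight; step 2 rebuilds
    the weight as the inverse of the heteroskedasticity-robust covariance
    of the stacked moments at the step-1 residuals (block-diagonal across
    the two independent samples) and re-solves. J = n1 g'Wg at the step-2
    solution.
    """
    s1, s2 = prepare_samples(sample1, sample2, covariates)
    design = validate_design(s1, s2)
    y1, Z1 = s1.y, s1.Z
    X2, Z2 = s2.X, s2.Z
    kz, kx = design.kz, design.kx

    fs = ols_fit(X2, Z2)
    beta0 = fit_ts2sls_arrays(y1, Z1, X2, Z2)
    psi0 = np.concatenate([beta0, np.asarray(fs.coefficients).reshape(-1, order="F")])

    # step 1: homoskedastic weight at the TS2SLS/OLS starting values
    S1w = _moment_variance(psi0, y1, Z1, X2, Z2, homoskedastic=True)
    W1 = inv_psd(S1w, "step-1 moment covariance")
    psi1, hist1 = solve_gmm(y1, Z1, X2, Z2, W1, psi0=psi0)

    # step 2: robust weight at step-1 residuals
    S2w = _moment_variance(psi1, y1, Z1, X2, Z2, homoskedastic=False)
    W2 = inv_psd(S2w, "step-2 moment covariance")
    psi2, hist2 = solve_gmm(y1, Z1, X2, Z2, W2, psi0=psi1)

    g = moment_conditions(psi2, y1, Z1, X2, Z2)
    J = float(design.n1 * g @ W2 @ g)

    # sandwich covariance of psi: (G'WG)^-1 G'W S W G (G'WG)^-1 / n1,
    # with S re-evaluated at the step-2 solution
    G = _jacobian(psi2, Z1, Z2, kx)
    S = _moment_variance(psi2, y1, Z1, X2, Z2, homoskedastic=False)
    A = G.T @ W2 @ G
    Ainv = inv_psd(A, "GMM Jacobian normal matrix")
    vcov_psi = symmetrize(Ainv @ G.T @ W2 @ S @ W2 @ G @ Ainv) / design.n1

    names = s2.exposure_cols
    return GMMResults(
        params=pd.Series(psi2[:kx], index=names),
        psi=psi2,
        vcov_psi=vcov_psi,
        kz=kz, kx=kx, n1=design.n1, n2=design.n2,
        j_stat=J,
        criterion_history=hist1 + hist2,
        n_iterations=len(hist1) + len(hist2) - 2,
        converged=True,
    )


def _jacobian(psi: np.ndarray, Z1, Z2, kx: int) -> np.ndarray:
    """d moments / d psi' (constant in the data given psi)."""
    kz = Z1.shape[1]
    n1, n2 = len(Z1), len(Z2)
    beta, Pi = _split_psi(np.asarray(psi, float), kz, kx)
    G = np.zeros((kz + kz * kx, kx + kz * kx))
    Z1Z1 = Z1.T @ Z1
    G[:kz, :kx] = -Z1Z1 @ Pi / n1
    G[:kz, kx:] = -np.kron(beta[None, :], Z1Z1) / n1
    G[kz:, kx:] = -np.kron(np.eye(kx), Z2.T @ Z2) / n2
    return G
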