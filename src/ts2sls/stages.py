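"""OLS stage regressions and sandwich covariance estimators.

The two-sample estimator is a function of two OLS stages: the *reduced
form* (outcome on instruments, sample 1) and the *first stage* (exposures
on instruments, sample 2). Its asymptotic variance is a function of the
variances of these stage coefficient estimators, so everything here is
about computing those stage fits and their heteroskedasticity- or
cluster-robust sandwich covariances, including the joint ("stacked")
covariance of several stages that may share observations.

Conventions frozen package-wide
-------------------------------
* ``vec`` stacks matrix **columns** (column-major). The covariance of
  ``vec(Pi_hat)`` for a multi-response stage therefore has the Kronecker
  structure ``(I_kx ⊗ (Z'Z)^-1) Omega (I_kx ⊗ (Z'Z)^-1)`` with per-
  observation score ``v_i ⊗ z_i`` (response-major).
* Robust flavors carry no small-sample correction by default: HC0, and a
  plain sum-over-clusters meat. The variance formulas downstream are
  plim-justified; HC1-style rescaling and a G/(G-1) cluster factor are
  available as explicit options.
* Error-variance estimates divide by n, not n - kz.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import TS2SLSError, ValidationError
from .linalg import check_nonsingular, inv_psd, symmetrize

FLAVORS = ("homoskedastic", "HC0", "cluster")


@dataclass
class EquationFit:
    """One OLS stage: coefficients, residuals and (optionally) a vcov.

    For a single-response stage ``coefficients`` is a (kz,) vector and
    ``residuals`` an (n,) vector; for a multi-response stage (the first
    stage with kx exposures) they are (kz, kx) and (n, kx) and ``vcov`` is
    the (kz*kx, kz*kx) covariance of ``vec(coefficients)``.
    """

    coefficients: np.ndarray
    residuals: np.ndarray
    Z: np.ndarray
    vcov: np.ndarray | None = None
    vcov_flavor: str | None = None
    names: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def kz(self) -> int:
        return self.Z.shape[1]

    @property
    def n_responses(self) -> int:
        return 1 if self.coefficients.ndim == 1 else self.coefficients.shape[1]

    @property
    def n_params(self) -> int:
        return self.kz * self.n_responses

    def scores(self) -> np.ndarray:
        """Per-observation score contributions ``v_i ⊗ z_i``, shape (n, kz*m)."""
        V = self.residuals.reshape(self.n, -1)
        # response-major: column block r holds z * v[:, r]
        return np.einsum("ir,ia->ira", V, self.Z).reshape(self.n, -1)

    def sigma2(self) -> np.ndarray:
        """Residual (co)variance with divisor n: scalar or (m, m) matrix."""
        V = self.residuals.reshape(self.n, -1)
        S = V.T @ V / self.n
        return float(S[0, 0]) if self.n_responses == 1 else S


def ols_fit(Y: np.ndarray, Z: np.ndarray, names: list[str] | None = None) -> EquationFit:
    """OLS of ``Y`` (single or multi response) on ``Z``: (Z'Z)^-1 Z'Y.

    Raises :class:`SingularMatrixError` on a rank-deficient regressor
    matrix — no silent pseudo-inverse.
    """
    Z = np.asarray(Z, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Z.ndim != 2:
        raise ValidationError("Z must be 2-dimensional (n, kz)")
    n, kz = Z.shape
    if Y.shape[0] != n:
        raise ValidationError(f"Y has {Y.shape[0]} rows but Z has {n}")
    if n < kz:
        raise ValidationError(f"need n >= kz, got n={n} < kz={kz}")
    gram = Z.T @ Z
    check_nonsingular(gram, "regressor cross-product Z'Z")
    coef = np.linalg.solve(gram, Z.T @ Y)
    resid = Y - Z @ coef
    return EquationFit(coefficients=coef, residuals=resid, Z=Z, names=names or [])


def _meat(fit: EquationFit, flavor: str, clusters: np.ndarray | None,
          cluster_correction: bool) -> np.ndarray:
    S = fit.scores()
    if flavor == "HC0":
        return S.T @ S
    if flavor == "homoskedastic":
        Sigma = np.atleast_2d(fit.sigma2())
        return np.kron(Sigma, fit.Z.T @ fit.Z)
    if flavor == "cluster":
        if clusters is None:
            raise ValidationError("flavor='cluster' requires a cluster id vector")
        clusters = np.asarray(clusters)
        if clusters.shape[0] != fit.n:
            raise ValidationError("cluster id vector length mismatch")
        _, inv = np.unique(clusters, return_inverse=True)
        G = inv.max() + 1
        sums = np.zeros((G, S.shape[1]))
        np.add.at(sums, inv, S)
        M = sums.T @ sums
        if cluster_correction and G > 1:
            M *= G / (G - 1)
        return M
    raise ValidationError(f"unknown vcov flavor {flavor!r}; choose from {FLAVORS}")


def sandwich_vcov(fit: EquationFit, flavor: str = "HC0",
                  clusters: np.ndarray | None = None,
                  hc1: bool = False, cluster_correction: bool = False) -> np.ndarray:
    """Sandwich covariance of the (vectorized) stage coefficients.

    bread * meat * bread with bread ``I_m ⊗ (Z'Z)^-1`` and meat the sum of
    per-observation (HC0) or per-cluster score outer products, or
    ``Sigma_v ⊗ Z'Z`` under homoskedasticity. Returns the finite-sample
    covariance estimate Va^r (no n-scaling); the fit's ``vcov`` and
    ``vcov_flavor`` are set as a side effect.

    ``hc1`` applies the n/(n-kz) degrees-of-freedom rescale;
    ``cluster_correction`` the G/(G-1) factor. Both are off by default.
    """
    bread_small = inv_psd(fit.Z.T @ fit.Z, "Z'Z")
    bread = np.kron(np.eye(fit.n_responses), bread_small)
    M = _meat(fit, flavor, clusters, cluster_correction)
    V = bread @ M @ bread
    if hc1:
        if fit.n <= fit.kz:
            raise ValidationError("HC1 rescale needs n > kz")
        V = V * fit.n / (fit.n - fit.kz)
    V = symmetrize(V)
    fit.vcov = V
    fit.vcov_flavor = flavor
    return V


@dataclass
class ThetaFit:
    """Stacked stage coefficients with their joint sandwich covariance.

    ``theta`` concatenates the vectorized coefficients of each equation in
    order; ``blocks`` maps each equation index to its slice of theta.
    Equations estimated on disjoint samples have exactly-zero cross-blocks.
    """

    theta: np.ndarray
    vcov: np.ndarray
    blocks: list[slice]
    flavor: str

    def block(self, i: int, j: int) -> np.ndarray:
        return self.vcov[self.blocks[i], self.blocks[j]]


def stacked_theta_vcov(fits: list[EquationFit],
                       obs_ids: list[np.ndarray],
                       flavor: str = "HC0",
                       clusters: np.ndarray | None = None,
                       cluster_correction: bool = False) -> ThetaFit:
    """Joint sandwich covariance of several stage-coefficient vectors.

    Each equation ``e`` is tagged with the integer ids of the underlying
    observations it used (``obs_ids[e]``, parallel to its rows). For every
    underlying observation the scores of all equations that use it are
    stacked (zeros elsewhere); the meat sums outer products of stacked
    scores per observation (HC0), per cluster (cluster flavor), or takes
    the block-diagonal homoskedastic form. The bread is block-diagonal
    ``(Z_e'Z_e)^-1``. Cross-blocks between equations on disjoint
    observation sets are exactly zero by construction.

    ``clusters`` maps *global* observation id -> cluster label (length =
    number of distinct underlying observations).
    """
    if len(fits) != len(obs_ids):
        raise ValidationError("fits and obs_ids must have equal length")
    sizes = [f.n_params for f in fits]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    blocks = [slice(int(offsets[e]), int(offsets[e + 1])) for e in range(len(fits))]
    p = int(offsets[-1])

    all_ids = np.concatenate([np.asarray(ids) for ids in obs_ids])
    uniq = np.unique(all_ids)
    N = len(uniq)
    pos = {int(g): k for k, g in enumerate(uniq)}

    # stacked score matrix: one row per underlying observation
    S = np.zeros((N, p))
    used = np.zeros((N, len(fits)), dtype=bool)
    for e, (fit, ids) in enumerate(zip(fits, obs_ids)):
        ids = np.asarray(ids)
        if ids.shape[0] != fit.n:
            raise ValidationError(
                f"equation {e}: {fit.n} rows but {ids.shape[0]} observation tags"
            )
        rows = np.fromiter((pos[int(g)] for g in ids), dtype=int, count=fit.n)
        if used[rows, e].any():  # pragma: no cover - defensive
            raise ValidationError(f"equation {e}: duplicated observation tag")
        used[rows, e] = True
        S[rows, blocks[e]] = fit.scores()

    if flavor == "homoskedastic":
        M = np.zeros((p, p))
        for e, fit in enumerate(fits):
            M[blocks[e], blocks[e]] = _meat(fit, "homoskedastic", None, False)
        # cross-equation homoskedastic blocks for shared observations:
        # E(v_e v_f' | z) Z_shared'Z_shared, estimated from shared rows
        for e in range(len(fits)):
            for f in range(e + 1, len(fits)):
                shared = used[:, e] & used[:, f]
                if not shared.any():
                    continue
                Se = S[shared, blocks[e]]
                Sf = S[shared, blocks[f]]
                M[blocks[e], blocks[f]] = Se.T @ Sf
                M[blocks[f], blocks[e]] = Sf.T @ Se
    elif flavor == "HC0":
        M = S.T @ S
    elif flavor == "cluster":
        if clusters is None:
            raise ValidationError("flavor='cluster' requires cluster ids")
        clusters = np.asarray(clusters)
        if clusters.shape[0] != N:
            raise ValidationError(
                "clusters must give one label per underlying observation "
                f"({N}), got {clusters.shape[0]}"
            )
        _, inv = np.unique(clusters, return_inverse=True)
        G = inv.max() + 1
        sums = np.zeros((G, p))
        np.add.at(sums, inv, S)
        M = sums.T @ sums
        if cluster_correction and G > 1:
            M *= G / (G - 1)
    else:
        raise ValidationError(f"unknown flavor {flavor!r}")

    bread = np.zeros((p, p))
    for e, fit in enumerate(fits):
        bread[blocks[e], blocks[e]] = np.kron(
            np.eye(fit.n_responses), inv_psd(fit.Z.T @ fit.Z, "Z'Z")
        )
    V = symmetrize(bread @ M @ bread)

    # enforce exact zeros between equations that share no meat terms:
    # no common observations (HC0/homoskedastic) or no common clusters
    if flavor == "cluster":
        eq_clusters = [set(inv[used[:, e]]) for e in range(len(fits))]
        disjoint = lambda e, f: not (eq_clusters[e] & eq_clusters[f])  # noqa: E731
    else:
        disjoint = lambda e, f: not (used[:, e] & used[:, f]).any()  # noqa: E731
    for e in range(len(fits)):
        for f in range(e + 1, len(fits)):
            if disjoint(e, f):
                V[blocks[e], blocks[f]] = 0.0
                V[blocks[f], blocks[e]] = 0.0

    theta = np.concatenate([np.asarray(f.coefficients).reshape(-1, order="F")
                            for f in fits])
    return ThetaFit(theta=theta, vcov=V, blocks=blocks, flavor=flavor)
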