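"""Two-sample IV for arbitrary variable-availability patterns.

The standard design observes every exposure in sample 2 only. More
generally each exposure may be observed in sample 1 only, in sample 2
only, or in both. The estimator is unchanged in form,

    beta_hat = (Pi_hat' Z1'Z1 Pi_hat)^-1 Pi_hat' Z1'Z1 pi_hat_y1,

but the columns of the first-stage matrix Pi_hat now come from OLS runs
on different row sets: sample-1-only exposures on Z1, sample-2-only on
Z2, and exposures observed in both samples on the stacked rows (Z1' Z2')'
with equal weight. Stages that share rows have correlated coefficient
estimates, so the variance

    Var(beta_hat) = (delta'⊗C_hat) Var(theta_hat) (delta⊗C_hat'),
    delta = (1, -beta_hat')',  theta_hat = (pi_hat_y1', vec(Pi_hat)')',

is built from the *joint* stacked sandwich covariance of all stage
coefficients, whose cross-blocks are derived from observation sharing —
never from formula special cases. On a standard all-sample-2 design the
cross-blocks are exactly zero and this expression collapses to the
standard robust variance.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .data import DesignInfo, Sample, prepare_samples
from .exceptions import UnderIdentifiedError, ValidationError
from .estimator import TS2SLSResults, c_hat, first_stage_F
from .linalg import check_nonsingular, symmetrize
from .stages import EquationFit, ols_fit, stacked_theta_vcov

AVAILABILITIES = ("sample1_only", "sample2_only", "both")


@dataclass(frozen=True)
class AvailabilityDesign:
    """Which sample observes each exposure.

    ``availability`` maps exposure name -> one of ``sample1_only``,
    ``sample2_only``, ``both``. The outcome always lives in sample 1 only.
    """

    availability: Mapping[str, str]

    def __post_init__(self):
        object.__setattr__(self, "availability", dict(self.availability))
        if not self.availability:
            raise ValidationError("need at least one exposure")
        for name, a in self.availability.items():
            if a not in AVAILABILITIES:
                raise ValidationError(
                    f"exposure {name!r}: unknown availability {a!r}; "
                    f"choose from {AVAILABILITIES}"
                )

    @property
    def exposures(self) -> list[str]:
        return list(self.availability)

    @classmethod
    def standard(cls, exposures: list[str]) -> "AvailabilityDesign":
        return cls({x: "sample2_only" for x in exposures})


def _check_columns(design: AvailabilityDesign, sample1: Sample, sample2: Sample):
    x1 = set(sample1.exposure_cols)
    x2 = set(sample2.exposure_cols)
    for name, a in design.availability.items():
        need1 = a in ("sample1_only", "both")
        need2 = a in ("sample2_only", "both")
        if need1 and name not in x1:
            raise ValidationError(
                f"exposure {name!r} declared available in sample1 but not mapped there"
            )
        if need2 and name not in x2:
            raise ValidationError(
                f"exposure {name!r} declared available in sample2 but not mapped there"
            )


def fit_general_two_sample(sample1: Sample, sample2: Sample,
                           design: AvailabilityDesign,
                           flavor: str = "HC0",
                           covariates: str = "partial_out",
                           cluster_correction: bool = False) -> TS2SLSResults:
    """Two-sample IV fit under an arbitrary availability pattern.

    Algorithm: (1) run each stage OLS on the rows its availability
    dictates and build the joint stacked sandwich covariance of
    (pi_hat_y1', vec(Pi_hat)')'; (2) regress y1 on X1_hat = Z1 Pi_hat;
    (3) collect C_hat from regressing the columns of Z1 on X1_hat;
    (4) sandwich the stacked covariance with delta = (1, -beta_hat')'.
    """
    s1, s2 = prepare_samples(sample1, sample2, covariates)
    _check_columns(design, s1, s2)
    z1cols, z2cols = s1.instrument_cols, s2.instrument_cols
    if z1cols != z2cols:
        raise ValidationError(
            f"instrument columns must match in name and order across samples; "
            f"sample1 has {z1cols}, sample2 has {z2cols}"
        )
    kz = len(z1cols)
    kx = len(design.exposures)
    if kz < kx:
        raise UnderIdentifiedError(f"kz={kz} < kx={kx}")
    n1, n2 = s1.n, s2.n
    y1, Z1, Z2 = s1.y, s1.Z, s2.Z
    Zpool = np.vstack([Z1, Z2])
    ids1 = np.arange(n1)
    ids2 = n1 + np.arange(n2)
    idpool = np.concatenate([ids1, ids2])

    # stage plan: reduced form first, then one stage per exposure
    fits = [ols_fit(y1, Z1, names=z1cols)]
    obs = [ids1]
    for name in design.exposures:
        a = design.availability[name]
        if a == "sample1_only":
            fits.append(ols_fit(s1.data[name].to_numpy(float), Z1, names=z1cols))
            obs.append(ids1)
        elif a == "sample2_only":
            fits.append(ols_fit(s2.data[name].to_numpy(float), Z2, names=z2cols))
            obs.append(ids2)
        else:  # both: plain OLS on the equally-weighted stacked rows
            x = np.concatenate([s1.data[name].to_numpy(float),
                                s2.data[name].to_numpy(float)])
            fits.append(ols_fit(x, Zpool, names=z1cols))
            obs.append(idpool)

    clusters = None
    if flavor == "cluster":
        c1, c2 = s1.clusters, s2.clusters
        if c1 is None or c2 is None:
            raise ValidationError("cluster flavor requires cluster ids in both samples")
        # prefix with the sample so labels never collide across samples
        clusters = np.concatenate([
            np.char.add("s1:", c1.astype(str)),
            np.char.add("s2:", c2.astype(str)),
        ])
    theta = stacked_theta_vcov(fits, obs, flavor=flavor, clusters=clusters,
                               cluster_correction=cluster_correction)

    Pi = np.column_stack([np.asarray(f.coefficients).reshape(kz) for f in fits[1:]])
    X1_hat = Z1 @ Pi
    gram = X1_hat.T @ X1_hat
    check_nonsingular(gram, "X1_hat'X1_hat")
    beta = np.atleast_1d(np.linalg.solve(gram, X1_hat.T @ y1))
    C = c_hat(X1_hat, Z1)

    delta = np.concatenate([[1.0], -beta])
    dC = np.kron(delta[None, :], C)              # kx × ((1+kx)·kz)
    V = symmetrize(np.atleast_2d(dC @ theta.vcov @ dC.T))

    rf = fits[0]
    u_tilde = y1 - X1_hat @ beta
    # per-exposure F from each stage's own coefficient block of theta
    fs_F = np.empty(kx)
    for r, f in enumerate(fits[1:], start=1):
        block = theta.block(r, r)
        fit_like = EquationFit(coefficients=f.coefficients, residuals=f.residuals,
                               Z=f.Z, vcov=block, vcov_flavor=flavor)
        fs_F[r - 1] = first_stage_F(fit_like)[0]

    if len({f.n for f in fits[1:]}) == 1:
        resid_cols = np.column_stack([f.residuals for f in fits[1:]])
        Sigma_v = resid_cols.T @ resid_cols / resid_cols.shape[0]
    else:  # stages on different row sets: no common Sigma_v
        Sigma_v = None

    return TS2SLSResults(
        params=pd.Series(beta, index=design.exposures),
        vcov=V,
        vcov_method={"HC0": "robust"}.get(flavor, flavor),
        stage_flavor=flavor,
        design=DesignInfo(kz=kz, kx=kx, n1=n1, n2=n2),
        C_hat=C,
        X1_hat=X1_hat,
        reduced_form=rf,
        first_stage=fits[1:],
        sigma_u2_hat=float(rf.sigma2()),
        sigma_u2_tilde=float(u_tilde @ u_tilde) / n1,
        Sigma_v_hat=Sigma_v,
        fs_F=fs_F,
        theta_fit=theta,
        estimator="two-sample IV (general availability)",
    )
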