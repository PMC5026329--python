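"""Two-sample data containers, CSV input, validation and covariate partialling.

The two-sample instrumental-variable design works with two rectangular
tables: *sample 1* holds the outcome ``y`` and the instruments ``z``,
*sample 2* holds the exposures ``x`` and the same instruments. Columns are
assigned semantic roles (outcome / exposure / instrument / covariate /
cluster_id) rather than relying on positional conventions, and instruments
are matched across samples **by name**: silent positional misalignment is
the most dangerous user error in two-sample designs.

Exogenous covariates (including the constant) are handled by within-sample
partialling: every outcome, exposure and instrument column is replaced by
its residual from an OLS regression on the covariates, after which the
analysis proceeds covariate-free (Frisch–Waugh).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import SingularMatrixError, UnderIdentifiedError, ValidationError
from .linalg import check_nonsingular

ROLES = ("outcome", "exposure", "instrument", "covariate", "cluster_id")


@dataclass(frozen=True)
class Sample:
    """One observational sample with a role map over its columns.

    Parameters
    ----------
    data : pandas.DataFrame
        The observations, one row per unit. Row order is preserved.
    roles : mapping of column name -> role
        Each mapped column gets one of ``outcome``, ``exposure``,
        ``instrument``, ``covariate``, ``cluster_id``. Unmapped columns are
        ignored.
    label : str
        Free-text label ("sample1"/"sample2") used in error messages.
    """

    data: pd.DataFrame
    roles: Mapping[str, str]
    label: str = "sample"

    def __post_init__(self):
        object.__setattr__(self, "roles", dict(self.roles))
        validate_sample(self)

    # -- role accessors (insertion order of the role map is preserved) ------
    def columns_with_role(self, role: str) -> list[str]:
        return [c for c, r in self.roles.items() if r == role]

    @property
    def outcome_cols(self) -> list[str]:
        return self.columns_with_role("outcome")

    @property
    def exposure_cols(self) -> list[str]:
        return self.columns_with_role("exposure")

    @property
    def instrument_cols(self) -> list[str]:
        return self.columns_with_role("instrument")

    @property
    def covariate_cols(self) -> list[str]:
        return self.columns_with_role("covariate")

    @property
    def cluster_col(self) -> str | None:
        cols = self.columns_with_role("cluster_id")
        return cols[0] if cols else None

    @property
    def n(self) -> int:
        return len(self.data)

    # -- numeric views -------------------------------------------------------
    def _matrix(self, cols: list[str]) -> np.ndarray:
        return self.data[cols].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """Outcome vector (n,)."""
        cols = self.outcome_cols
        if not cols:
            raise ValidationError(f"{self.label}: no outcome column mapped")
        return self._matrix(cols)[:, 0]

    @property
    def X(self) -> np.ndarray:
        """Exposure matrix (n, kx)."""
        return self._matrix(self.exposure_cols)

    @property
    def Z(self) -> np.ndarray:
        """Instrument matrix (n, kz)."""
        return self._matrix(self.instrument_cols)

    @property
    def W(self) -> np.ndarray:
        """Covariate matrix (n, kw)."""
        return self._matrix(self.covariate_cols)

    @property
    def clusters(self) -> np.ndarray | None:
        c = self.cluster_col
        return None if c is None else self.data[c].to_numpy()


def validate_sample(sample: Sample) -> None:
    df, roles = sample.data, sample.roles
    for col, role in roles.items():
        if role not in ROLES:
            raise ValidationError(
                f"{sample.label}: unknown role {role!r} for column {col!r}; "
                f"valid roles are {ROLES}"
            )
        if col not in df.columns:
            raise ValidationError(
                f"{sample.label}: role map references absent column {col!r}"
            )
    if len(df) < 2:
        raise ValidationError(f"{sample.label}: need at least 2 rows, got {len(df)}")
    if len(sample.columns_with_role("cluster_id")) > 1:
        raise ValidationError(f"{sample.label}: at most one cluster_id column allowed")
    for col, role in roles.items():
        s = df[col]
        if s.isna().any():
            row = int(s.index[s.isna()][0])
            raise ValidationError(
                f"{sample.label}: missing value in column {col!r} at row {row}"
            )
        if role != "cluster_id" and not pd.api.types.is_numeric_dtype(s):
            bad = s[pd.to_numeric(s, errors="coerce").isna()]
            where = f" (first offending row {int(bad.index[0])})" if len(bad) else ""
            raise ValidationError(
                f"{sample.label}: column {col!r} with role {role!r} must be "
                f"numeric{where}"
            )


def read_sample_csv(path, role_map: Mapping[str, str], label: str | None = None) -> Sample:
    """Read one sample from a CSV file and validate it against a role map.

    Raises
    ------
    ValidationError
        If a mapped column is absent, contains a missing value (the error
        names the row and column), or a numeric-role column is non-numeric.
    """
    df = pd.read_csv(path)
    return Sample(df, role_map, label=label or str(path))


def write_sample_csv(sample: Sample, path) -> None:
    sample.data.to_csv(path, index=False)


@dataclass(frozen=True)
class DesignInfo:
    """Dimensions and identification status of a two-sample design."""

    kz: int
    kx: int
    n1: int
    n2: int

    @property
    def just_identified(self) -> bool:
        return self.kz == self.kx

    @property
    def alpha_hat(self) -> float:
        """Sample-size ratio n1/n2."""
        return self.n1 / self.n2


def partial_out(sample: Sample) -> Sample:
    """Residualize all analysis columns on the sample's covariates.

    Every outcome, exposure and instrument column is replaced by its
    residual from an OLS regression on *all* covariate columns of this
    sample; the covariate columns are then dropped from the returned
    Sample. A cluster_id column, if any, is preserved. Residuals carry no
    degrees-of-freedom correction: the downstream variance formulas are
    plim-justified.
    """
    wcols = sample.covariate_cols
    if not wcols:
        raise ValidationError(
            f"{sample.label}: partial_out requires at least one covariate column"
        )
    if sample.n <= len(wcols):
        raise ValidationError(
            f"{sample.label}: n={sample.n} must exceed the number of "
            f"covariates ({len(wcols)})"
        )
    W = sample.W
    gram = W.T @ W
    try:
        check_nonsingular(gram, f"{sample.label}: covariate matrix W'W")
    except SingularMatrixError:
        raise
    targets = [c for c, r in sample.roles.items() if r in ("outcome", "exposure", "instrument")]
    A = sample.data[targets].to_numpy(dtype=float)
    coef = np.linalg.solve(gram, W.T @ A)
    resid = A - W @ coef

    keep = {c: r for c, r in sample.roles.items() if r not in ("covariate",)}
    df = sample.data[list(keep)].copy()
    df[targets] = resid
    return Sample(df, keep, label=sample.label)


def validate_design(sample1: Sample, sample2: Sample) -> DesignInfo:
    """Check cross-sample consistency and return the design dimensions.

    Sample 1 must carry the outcome and the instruments; sample 2 the
    exposures and the *same* instruments (same names, same order).
    """
    if not sample1.outcome_cols:
        raise ValidationError("sample1 must contain an outcome column")
    z1, z2 = sample1.instrument_cols, sample2.instrument_cols
    if not z1 or not z2:
        raise ValidationError("both samples must contain instrument columns")
    if z1 != z2:
        raise ValidationError(
            f"instrument columns must match in name and order across samples; "
            f"sample1 has {z1}, sample2 has {z2}"
        )
    kx = len(sample2.exposure_cols)
    if kx < 1:
        raise ValidationError("sample2 must contain at least one exposure column")
    kz = len(z1)
    if kz < kx:
        raise UnderIdentifiedError(
            f"model is under-identified: kz={kz} instruments < kx={kx} exposures"
        )
    return DesignInfo(kz=kz, kx=kx, n1=sample1.n, n2=sample2.n)


def _augment_with_covariates(sample: Sample, as_exposure: bool) -> Sample:
    """Carry covariates through all stages as included instruments.

    The covariate columns are re-mapped as additional instruments (and,
    when ``as_exposure``, additional exposures that instrument themselves).
    Used by the ``covariates='include'`` option; exposure coefficients are
    identical to the partialling route by the Frisch–Waugh theorem.
    """
    roles = dict(sample.roles)
    extra = {}
    for c in sample.covariate_cols:
        roles[c] = "instrument"
        if as_exposure:
            extra[c + "__as_x"] = "exposure"
    df = sample.data.copy()
    for c in sample.covariate_cols:
        if as_exposure:
            df[c + "__as_x"] = df[c]
    roles.update(extra)
    return Sample(df, roles, label=sample.label)


def prepare_samples(sample1: Sample, sample2: Sample, covariates: str = "partial_out"):
    """Apply the chosen covariate handling to both samples.

    Parameters
    ----------
    covariates : {"partial_out", "include", "none"}
        ``partial_out`` residualizes on covariates within each sample
        (default); ``include`` carries them as included instruments /
        self-instrumenting exposures through every stage; ``none`` requires
        that no covariates are mapped.
    """
    if covariates == "partial_out":
        s1 = partial_out(sample1) if sample1.covariate_cols else sample1
        s2 = partial_out(sample2) if sample2.covariate_cols else sample2
    elif covariates == "include":
        s1 = _augment_with_covariates(sample1, as_exposure=False)
        s2 = _augment_with_covariates(sample2, as_exposure=True)
    elif covariates == "none":
        if sample1.covariate_cols or sample2.covariate_cols:
            raise ValidationError(
                "covariates='none' but covariate columns are mapped"
            )
        s1, s2 = sample1, sample2
    else:
        raise ValidationError(f"unknown covariate handling {covariates!r}")
    return s1, s2
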