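"""Model-object facade over the two-sample IV estimators.

Follows the familiar modelling-package pattern: a model object is built
from data (``TwoSampleIV(sample1, sample2)`` or the ``from_dataframes`` /
``from_csv`` constructors), ``fit`` returns a results object carrying
estimates, covariances and a ``summary()`` table, and ``fit_gmm`` returns
the two-step GMM results with the Hansen J test.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .data import Sample, read_sample_csv, validate_design
from .estimator import TS2SLSResults, fit_ts2sls
from .exceptions import ValidationError
from .generalized import AvailabilityDesign, fit_general_two_sample
from .gmm import GMMResults, two_step_fit


def _role_map(outcome=None, exposures=(), instruments=(), covariates=(),
              cluster=None) -> dict[str, str]:
    roles: dict[str, str] = {}
    if outcome is not None:
        roles[outcome] = "outcome"
    for x in exposures:
        roles[x] = "exposure"
    for z in instruments:
        roles[z] = "instrument"
    for w in covariates:
        roles[w] = "covariate"
    if cluster is not None:
        roles[cluster] = "cluster_id"
    return roles


class TwoSampleIV:
    """Two-sample instrumental-variable model.

    Parameters
    ----------
    sample1, sample2 : Sample
        Sample 1 carries the outcome and instruments; sample 2 the
        exposures and the same instruments. Under a general availability
        pattern exposures may also live in sample 1 or in both.
    availability : mapping exposure -> {"sample1_only","sample2_only","both"}, optional
        Omit for the standard design (all exposures in sample 2).

    Examples
    --------
    >>> model = TwoSampleIV.from_dataframes(
    ...     df1, df2, outcome="y", exposures=["bmi"],
    ...     instruments=["z1", "z2", "z3"])
    >>> res = model.fit(vcov="robust")
    >>> print(res.summary())
    """

    def __init__(self, sample1: Sample, sample2: Sample,
                 availability: Mapping[str, str] | None = None):
        self.sample1 = sample1
        self.sample2 = sample2
        self.availability = None if availability is None \
            else AvailabilityDesign(availability)
        if self.availability is None:
            self.design = validate_design(sample1, sample2)

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframes(cls, df1: pd.DataFrame, df2: pd.DataFrame, *,
                        outcome: str,
                        exposures: Sequence[str],
                        instruments: Sequence[str],
                        covariates: Sequence[str] = (),
                        cluster: str | None = None,
                        availability: Mapping[str, str] | None = None
                        ) -> "TwoSampleIV":
        av = dict(availability) if availability else None
        x1 = [x for x in exposures
              if av and av.get(x) in ("sample1_only", "both")]
        x2 = [x for x in exposures
              if av is None or av.get(x) in ("sample2_only", "both")]
        s1 = Sample(df1, _role_map(outcome, x1, instruments, covariates,
                                   cluster), label="sample1")
        s2 = Sample(df2, _role_map(None, x2, instruments, covariates,
                                   cluster), label="sample2")
        return cls(s1, s2, availability=av)

    @classmethod
    def from_csv(cls, path1, path2, **kwargs) -> "TwoSampleIV":
        """Build the model from two CSV files; keywords as in from_dataframes."""
        availability = kwargs.pop("availability", None)
        df1 = pd.read_csv(path1)
        df2 = pd.read_csv(path2)
        return cls.from_dataframes(df1, df2, availability=availability, **kwargs)

    # ------------------------------------------------------------------
    def fit(self, vcov: str = "robust", stage_flavor: str | None = None,
            covariates: str = "partial_out", **kwargs) -> TS2SLSResults:
        """Fit the two-sample estimator with the requested variance method.

        ``vcov`` is one of robust (HC0, default), cluster, homoskedastic,
        inoue_solon or scalar_delta for the standard design; robust or
        cluster for general availability patterns.
        """
        if self.availability is None:
            return fit_ts2sls(self.sample1, self.sample2, vcov_method=vcov,
                              stage_flavor=stage_flavor,
                              covariates=covariates, **kwargs)
        flavor = {"robust": "HC0", "cluster": "cluster"}.get(vcov)
        if flavor is None:
            raise ValidationError(
                f"vcov {vcov!r} is not available under a general "
                "availability pattern; use 'robust' or 'cluster'"
            )
        return fit_general_two_sample(self.sample1, self.sample2,
                                      self.availability, flavor=flavor,
                                      covariates=covariates, **kwargs)

    def fit_gmm(self, covariates: str = "partial_out") -> GMMResults:
        """Two-step efficient GMM with the Hansen J overidentification test."""
        if self.availability is not None:
            raise ValidationError(
                "the GMM estimator is defined for the standard design only"
            )
        return two_step_fit(self.sample1, self.sample2, covariates=covariates)
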