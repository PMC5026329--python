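"""Monte Carlo harness: bias, RMSE, SE calibration, CI coverage, J size.

Replicates draws from a :class:`~ts2sls.simulate.DGPSpec`, fits the
requested estimator/variance-method combinations, and aggregates:

* mean and bias of beta_hat, empirical SD and RMSE (population SD, so
  RMSE^2 = bias^2 + SD^2 holds exactly),
* mean estimated standard error against the empirical SD,
* coverage of the nominal 95% normal-approximation confidence interval,
* rejection rate of the Hansen J test at the 5% level (GMM only).

Per-replication seeds are derived from the master seed by a counter
construction (``SeedSequence([seed, rep])``), so any single replication
can be re-run in isolation with an identical draw and the full study is
reproducible across processes. Replications in which a fit raises a
singularity or convergence error are excluded and counted rather than
aborting the study; the report warns when more than 1% are lost.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import ConvergenceError, SingularMatrixError, ValidationError
from .estimator import fit_ts2sls
from .generalized import AvailabilityDesign, fit_general_two_sample
from .gmm import two_step_fit
from .simulate import DGPSpec, generate

TS2SLS_METHODS = ("robust", "cluster", "homoskedastic", "inoue_solon")


def coverage_interval(nominal: float, reps: int, confidence: float = 0.99):
    """Exact binomial acceptance band for an observed coverage proportion.

    If a CI procedure attains its nominal level, the number of covering
    replications is Binomial(reps, nominal); the returned ``(lo, hi)`` are
    the ``(1-confidence)/2`` and ``1-(1-confidence)/2`` quantiles of that
    law, divided by reps.
    """
    if not 0 < nominal < 1:
        raise ValidationError("nominal must lie in (0, 1)")
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    if not 0 < confidence < 1:
        raise ValidationError("confidence must lie in (0, 1)")
    tail = (1 - confidence) / 2
    lo = stats.binom.ppf(tail, reps, nominal) / reps
    hi = stats.binom.ppf(1 - tail, reps, nominal) / reps
    return float(lo), float(hi)


@dataclass
class MethodStats:
    """Aggregates for one estimator/variance-method combination."""

    method: str
    mean_beta: np.ndarray
    bias: np.ndarray
    sd: np.ndarray
    rmse: np.ndarray
    mean_se: np.ndarray
    coverage: np.ndarray
    n_used: int
    n_excluded: int
    j_reject_rate: float | None = None
    degenerate: bool = False

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "mean_beta": self.mean_beta.tolist(),
            "bias": self.bias.tolist(),
            "sd": self.sd.tolist(),
            "rmse": self.rmse.tolist(),
            "mean_se": self.mean_se.tolist(),
            "coverage": self.coverage.tolist(),
            "n_used": self.n_used,
            "n_excluded": self.n_excluded,
            "degenerate": self.degenerate,
        }
        if self.j_reject_rate is not None:
            d["j_reject_rate"] = self.j_reject_rate
        return d


@dataclass
class MCReport:
    """Full Monte Carlo study report."""

    spec: DGPSpec
    reps: int
    seed: int
    stats: dict[str, MethodStats]
    warnings: list[str] = field(default_factory=list)

    def __getitem__(self, method: str) -> MethodStats:
        return self.stats[method]

    def to_dict(self) -> dict:
        return {
            "reps": self.reps,
            "seed": self.seed,
            "n1": self.spec.n1,
            "n2": self.spec.n2,
            "kz": self.spec.kz,
            "kx": self.spec.kx,
            "true_beta": self.spec.beta.tolist(),
            "methods": {m: s.to_dict() for m, s in self.stats.items()},
            "warnings": list(self.warnings),
        }

    def table(self) -> str:
        hdr = (f"{'method':<14s}{'mean':>10s}{'bias':>10s}{'SD':>10s}"
               f"{'RMSE':>10s}{'mean SE':>10s}{'cover95':>9s}{'J rej':>8s}")
        lines = [f"Monte Carlo report: reps={self.reps} seed={self.seed} "
                 f"n1={self.spec.n1} n2={self.spec.n2}", hdr, "-" * len(hdr)]
        for m, s in self.stats.items():
            for r in range(len(s.mean_beta)):
                jr = f"{s.j_reject_rate:.3f}" if s.j_reject_rate is not None else ""
                lines.append(
                    f"{(m if r == 0 else ''):<14s}{s.mean_beta[r]:>10.4f}"
                    f"{s.bias[r]:>10.4f}{s.sd[r]:>10.4f}{s.rmse[r]:>10.4f}"
                    f"{s.mean_se[r]:>10.4f}{s.coverage[r]:>9.3f}{jr:>8s}"
                )
        for w in self.warnings:
            lines.append(f"WARNING: {w}")
        return "\n".join(lines)


def _fit_one(method: str, s1, s2, spec: DGPSpec, alpha: float):
    """Fit one method on one draw; return (beta, se, cover, j_reject)."""
    av = spec.availability_map()
    standard = all(a == "sample2_only" for a in av.values())
    if method == "gmm":
        res = two_step_fit(s1, s2)
        beta = res.beta_hat
        se = res.bse.to_numpy()
        j_rej = None
        if res.j_df > 0:
            j_rej = bool(res.j_stat > stats.chi2.ppf(0.95, res.j_df))
    elif standard:
        res = fit_ts2sls(s1, s2, vcov_method=method)
        beta, se, j_rej = res.beta_hat, res.bse.to_numpy(), None
    else:
        if method not in ("robust", "cluster"):
            raise ValidationError(
                f"method {method!r} is not available for general-availability designs"
            )
        flavor = "HC0" if method == "robust" else "cluster"
        res = fit_general_two_sample(s1, s2, AvailabilityDesign(av), flavor=flavor)
        beta, se, j_rej = res.beta_hat, res.bse.to_numpy(), None
    q = stats.norm.ppf(1 - alpha / 2)
    cover = np.abs(beta - spec.beta) <= q * se
    return beta, se, cover, j_rej


def run_mc(spec: DGPSpec, methods: list[str], reps: int, seed: int,
           alpha: float = 0.05) -> MCReport:
    """Run a replicated study of the given methods under one DGP."""
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    known = set(TS2SLS_METHODS) | {"gmm"}
    for m in methods:
        if m not in known:
            raise ValidationError(f"unknown method {m!r}; choose from {sorted(known)}")

    rec: dict[str, dict[str, list]] = {
        m: {"beta": [], "se": [], "cover": [], "jrej": []} for m in methods
    }
    excluded = {m: 0 for m in methods}
    for r in range(reps):
        s1, s2, _ = generate(spec, seed=np.random.SeedSequence([seed, r]))
        for m in methods:
            try:
                beta, se, cover, j_rej = _fit_one(m, s1, s2, spec, alpha)
            except (SingularMatrixError, ConvergenceError):
                excluded[m] += 1
                continue
            rec[m]["beta"].append(beta)
            rec[m]["se"].append(se)
            rec[m]["cover"].append(cover)
            if j_rej is not None:
                rec[m]["jrej"].append(j_rej)

    out: dict[str, MethodStats] = {}
    warnings: list[str] = []
    for m in methods:
        B = np.asarray(rec[m]["beta"], dtype=float)
        if B.size == 0:
            warnings.append(f"method {m}: every replication failed")
            continue
        SE = np.asarray(rec[m]["se"], dtype=float)
        CV = np.asarray(rec[m]["cover"], dtype=float)
        mean_beta = B.mean(axis=0)
        bias = mean_beta - spec.beta
        sd = B.std(axis=0, ddof=0)
        rmse = np.sqrt(np.mean((B - spec.beta) ** 2, axis=0))
        jr = rec[m]["jrej"]
        out[m] = MethodStats(
            method=m,
            mean_beta=mean_beta,
            bias=bias,
            sd=sd,
            rmse=rmse,
            mean_se=SE.mean(axis=0),
            coverage=CV.mean(axis=0),
            n_used=B.shape[0],
            n_excluded=excluded[m],
            j_reject_rate=float(np.mean(jr)) if jr else None,
            degenerate=bool(np.all(sd <= 1e-12 * np.maximum(1.0, np.abs(mean_beta)))),
        )
        if excluded[m] > 0.01 * reps:
            warnings.append(
                f"method {m}: {excluded[m]}/{reps} replications excluded (>1%)"
            )
    return MCReport(spec=spec, reps=reps, seed=seed, stats=out, warnings=warnings)
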