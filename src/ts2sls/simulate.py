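"""Synthetic two-sample data with the structure the asymptotic theory assumes.

The generator draws two independent i.i.d. samples from one population:

    z ~ N(0, Sigma_z)                       (instruments, shared law)
    x = Pi' z + v                           (first stage)
    y = x' beta + eps                       (structural equation)

with (eps, v) jointly normal, correlated with each other (endogeneity)
but independent of z, and optionally scaled by the conditional-
heteroskedasticity multiplier sqrt(exp(gamma' z)) — always positive,
smooth, strength tunable through ||gamma||, and gamma = 0 recovers
homoskedasticity. Sample 1 exposes (y, z), sample 2 exposes (x, z).

Two adversarial knobs used by the test suite:

* ``c`` rescales sample-1 instruments by sqrt(c), so E(z1 z1') =
  c * E(z2 z2') while the first-stage matrix Pi is common. The TS2SLS
  estimator remains consistent and asymptotically normal under this
  scenario, but the Inoue–Solon variance estimator (which forces the two
  samples' instrument moments equal) does not remain consistent.
* an optional cluster structure adds a shared normal effect to the errors
  of every unit in a cluster (equicorrelation rho within clusters),
  breaking the independence that HC0 assumes but not the cluster sandwich.

:func:`default_test_spec` is the package's canonical test bed: kz = 3
instruments with unit covariance, one exposure, beta = 1,
Pi = (1, 0.8, 0.6)', endogeneity 0.5, gamma = (0.5, 0, 0) on both error
scales, n1 = n2 = 2000. The first stage is deliberately strong
(population first-stage F far above 10) so variance and coverage studies
are not confounded by weak instruments. A bare ``DGPSpec()`` is the same
design with gamma = 0 (conditionally homoskedastic).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .data import Sample
from .exceptions import ValidationError


def _as_array(x, shape, name) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.shape != tuple(shape):
        raise ValidationError(f"{name} must have shape {tuple(shape)}, got {a.shape}")
    return a


@dataclass(frozen=True)
class DGPSpec:
    """Parameters of the synthetic two-sample data-generating process.

    Attributes
    ----------
    kz, kx : int
        Numbers of instruments and exposures.
    beta : array (kx,)
        True structural coefficients.
    Pi : array (kz, kx)
        True first-stage matrix (common to both samples).
    sigma_z : array (kz, kz)
        Instrument covariance (must be PSD).
    endogeneity : array (kx,)
        Correlations between the structural error eps and each first-stage
        error v_r (v components mutually uncorrelated at unit variance).
    gamma_eps, gamma_v : array (kz,)
        Log-variance slopes of the heteroskedasticity multipliers
        sqrt(exp(gamma' z)) for eps and for every v column. Zero vectors
        give conditional homoskedasticity.
    c : float
        Sample-1 instrument scaling: z1 = sqrt(c) * z. Default 1.
    error_scale : float
        Common scale on (eps, v); 0 gives a noise-free draw.
    n1, n2 : int
        Sample sizes.
    n_clusters, cluster_rho : int | None, float
        Optional cluster structure: units are split evenly over
        ``n_clusters`` groups and every error component receives a shared
        cluster-level normal term with weight sqrt(cluster_rho).
    availability : "standard" or mapping exposure index -> availability
        "standard" exposes all exposures in sample 2 only. A mapping like
        ``{"x1": "sample1_only", "x2": "sample2_only", "x3": "both"}``
        produces the general variable-availability layout.
    seed : int
        Base seed; the two samples use independent child streams, so
        changing n1 never perturbs sample 2's draws.
    """

    kz: int = 3
    kx: int = 1
    beta: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    Pi: np.ndarray = field(default_factory=lambda: np.array([[1.0], [0.8], [0.6]]))
    sigma_z: np.ndarray | None = None
    endogeneity: np.ndarray = field(default_factory=lambda: np.array([0.5]))
    gamma_eps: np.ndarray | None = None
    gamma_v: np.ndarray | None = None
    c: float = 1.0
    error_scale: float = 1.0
    n1: int = 2000
    n2: int = 2000
    n_clusters: int | None = None
    cluster_rho: float = 0.3
    availability: str | Mapping[str, str] = "standard"
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "beta", _as_array(self.beta, (self.kx,), "beta"))
        object.__setattr__(self, "Pi", _as_array(self.Pi, (self.kz, self.kx), "Pi"))
        sz = np.eye(self.kz) if self.sigma_z is None else \
            _as_array(self.sigma_z, (self.kz, self.kz), "sigma_z")
        object.__setattr__(self, "sigma_z", sz)
        object.__setattr__(self, "endogeneity",
                           _as_array(self.endogeneity, (self.kx,), "endogeneity"))
        ge = np.zeros(self.kz) if self.gamma_eps is None else \
            _as_array(self.gamma_eps, (self.kz,), "gamma_eps")
        gv = np.zeros(self.kz) if self.gamma_v is None else \
            _as_array(self.gamma_v, (self.kz,), "gamma_v")
        object.__setattr__(self, "gamma_eps", ge)
        object.__setattr__(self, "gamma_v", gv)
        self.validate()

    def validate(self) -> None:
        if self.kz < self.kx or self.kx < 1:
            raise ValidationError(f"need kz >= kx >= 1, got kz={self.kz}, kx={self.kx}")
        if self.c <= 0:
            raise ValidationError(f"c must be positive, got {self.c}")
        if self.error_scale < 0:
            raise ValidationError("error_scale must be non-negative")
        nmin = self.kz + 2
        if self.n1 < nmin or self.n2 < nmin:
            raise ValidationError(f"need n1, n2 >= kz + 2 = {nmin}")
        ev = np.linalg.eigvalsh(self.sigma_z)
        if ev.min() < -1e-10:
            raise ValidationError("sigma_z is not positive semi-definite")
        if np.any(np.abs(self.endogeneity) >= 1):
            raise ValidationError("endogeneity correlations must lie in (-1, 1)")
        if np.linalg.eigvalsh(self._error_cov()).min() < 1e-12:
            raise ValidationError(
                "endogeneity correlations make the (eps, v) covariance singular"
            )
        if self.n_clusters is not None:
            if self.n_clusters < 2:
                raise ValidationError("need at least 2 clusters")
            if not 0 <= self.cluster_rho < 1:
                raise ValidationError("cluster_rho must lie in [0, 1)")
        if self.availability != "standard":
            av = dict(self.availability)
            if len(av) != self.kx:
                raise ValidationError(
                    f"availability maps {len(av)} exposures but kx={self.kx}"
                )

    def _error_cov(self) -> np.ndarray:
        """Base covariance of (eps, v_1..v_kx): unit variances, corr(eps, v_r)."""
        S = np.eye(1 + self.kx)
        S[0, 1:] = self.endogeneity
        S[1:, 0] = self.endogeneity
        return S

    @property
    def exposure_names(self) -> list[str]:
        return [f"x{r + 1}" for r in range(self.kx)]

    @property
    def instrument_names(self) -> list[str]:
        return [f"z{a + 1}" for a in range(self.kz)]

    def availability_map(self) -> dict[str, str]:
        if self.availability == "standard":
            return {x: "sample2_only" for x in self.exposure_names}
        return dict(self.availability)

    def population_first_stage_F(self) -> np.ndarray:
        """Rough per-exposure population F at the sample-2 design size."""
        num = np.einsum("ar,ab,br->r", self.Pi, self.sigma_z, self.Pi)
        return self.n2 * num / (self.kz * 1.0)


@dataclass(frozen=True)
class TruthRecord:
    """Immutable echo of the parameters a draw was generated from."""

    beta: np.ndarray
    Pi: np.ndarray
    spec: DGPSpec


def _draw_sample(rng: np.random.Generator, spec: DGPSpec, n: int,
                 scale_z: float) -> dict[str, np.ndarray]:
    kz, kx = spec.kz, spec.kx
    L = np.linalg.cholesky(spec.sigma_z + 1e-14 * np.eye(kz))
    z = rng.standard_normal((n, kz)) @ L.T * np.sqrt(scale_z)
    Lerr = np.linalg.cholesky(spec._error_cov())
    err = rng.standard_normal((n, 1 + kx)) @ Lerr.T * spec.error_scale
    if spec.n_clusters is not None:
        G = spec.n_clusters
        cid = np.arange(n) % G
        shared = rng.standard_normal((G, 1 + kx)) @ Lerr.T
        rho = spec.cluster_rho
        err = np.sqrt(1 - rho) * err + np.sqrt(rho) * shared[cid]
    else:
        cid = None
    eps = err[:, 0] * np.sqrt(np.exp(z @ spec.gamma_eps))
    v = err[:, 1:] * np.sqrt(np.exp(z @ spec.gamma_v))[:, None]
    x = z @ spec.Pi + v
    y = x @ spec.beta + eps
    out = {"y": y, "x": x, "z": z, "eps": eps, "v": v}
    if cid is not None:
        out["cluster"] = cid
    return out


def generate(spec: DGPSpec, seed: int | np.random.SeedSequence | None = None,
             diagnostics: bool = False):
    """Draw one two-sample dataset.

    Returns ``(sample1, sample2, truth)``. With ``diagnostics=True`` the
    samples additionally expose the latent error columns (and sample 1 the
    latent exposures) as unmapped columns, for generator self-checks only.

    The two samples consume independent child streams spawned from the
    seed, and the same seed always reproduces the same draw exactly.
    """
    spec.validate()
    if seed is None:
        seed = spec.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss1, ss2 = ss.spawn(2)
    d1 = _draw_sample(np.random.default_rng(ss1), spec, spec.n1, spec.c)
    d2 = _draw_sample(np.random.default_rng(ss2), spec, spec.n2, 1.0)

    znames = spec.instrument_names
    xnames = spec.exposure_names
    av = spec.availability_map()

    df1 = pd.DataFrame({"y": d1["y"]})
    roles1: dict[str, str] = {"y": "outcome"}
    for r, xn in enumerate(xnames):
        if av[xn] in ("sample1_only", "both"):
            df1[xn] = d1["x"][:, r]
            roles1[xn] = "exposure"
    for a, zn in enumerate(znames):
        df1[zn] = d1["z"][:, a]
        roles1[zn] = "instrument"

    df2 = pd.DataFrame()
    roles2: dict[str, str] = {}
    for r, xn in enumerate(xnames):
        if av[xn] in ("sample2_only", "both"):
            df2[xn] = d2["x"][:, r]
            roles2[xn] = "exposure"
    for a, zn in enumerate(znames):
        df2[zn] = d2["z"][:, a]
        roles2[zn] = "instrument"

    if spec.n_clusters is not None:
        df1["cluster"] = d1["cluster"]
        df2["cluster"] = d2["cluster"]
        roles1["cluster"] = "cluster_id"
        roles2["cluster"] = "cluster_id"

    if diagnostics:
        df1["_eps"] = d1["eps"]
        df2["_eps"] = d2["eps"]
        for r, xn in enumerate(xnames):
            df1["_v_" + xn] = d1["v"][:, r]
            df2["_v_" + xn] = d2["v"][:, r]
            if xn not in df1.columns:
                df1["_latent_" + xn] = d1["x"][:, r]

    truth = TruthRecord(beta=spec.beta.copy(), Pi=spec.Pi.copy(), spec=spec)
    return (Sample(df1, roles1, label="sample1"),
            Sample(df2, roles2, label="sample2"),
            truth)


def default_test_spec(**overrides) -> DGPSpec:
    """The canonical heteroskedastic study design (see module docstring)."""
    base = dict(
        kz=3, kx=1,
        beta=np.array([1.0]),
        Pi=np.array([[1.0], [0.8], [0.6]]),
        endogeneity=np.array([0.5]),
        gamma_eps=np.array([0.5, 0.0, 0.0]),
        gamma_v=np.array([0.5, 0.0, 0.0]),
        n1=2000, n2=2000,
    )
    base.update(overrides)
    return DGPSpec(**base)


def general_availability_spec(**overrides) -> DGPSpec:
    """Three-exposure layout: x1 in sample 1 only, x2 in sample 2 only,
    x3 in both. beta = (1, -0.5, 2); diagonally dominant first stage for
    strong identification."""
    base = dict(
        kz=3, kx=3,
        beta=np.array([1.0, -0.5, 2.0]),
        Pi=np.array([[1.0, 0.3, 0.2],
                     [0.3, 0.9, 0.3],
                     [0.2, 0.3, 0.8]]),
        endogeneity=np.array([0.5, 0.3, 0.2]),
        availability={"x1": "sample1_only", "x2": "sample2_only", "x3": "both"},
        n1=2000, n2=2000,
    )
    base.update(overrides)
    return DGPSpec(**base)


def with_options(spec: DGPSpec, **kwargs) -> DGPSpec:
    """Return a copy of ``spec`` with the given fields replaced."""
    return replace(spec, **kwargs)


def spec_from_dict(d: Mapping) -> DGPSpec:
    """Build a DGPSpec from a plain (e.g. YAML-loaded) mapping."""
    d = dict(d)
    for key in ("beta", "Pi", "sigma_z", "endogeneity", "gamma_eps", "gamma_v"):
        if key in d and d[key] is not None:
            d[key] = np.asarray(d[key], dtype=float)
    return DGPSpec(**d)
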