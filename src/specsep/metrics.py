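"""Pairwise Gaussian class-separability criteria.

Four criteria are provided, each symmetric in its two arguments and zero
for identical class summaries:

* ``m_statistic`` — mean separation scaled by the summed standard
  deviations (univariate only).
* ``bhattacharyya`` — the Gaussian Bhattacharyya distance, unbounded.
* ``jeffries_matusita`` — a bounded transform of the Bhattacharyya
  distance; two conventions exist (bound 2 or bound sqrt(2)).
* ``divergence`` / ``transformed_divergence`` — the symmetric divergence
  between two Gaussians and its bounded-by-2 transform.

All criteria are invariant under a common positive rescaling of means
and standard deviations, so they do not depend on reflectance units.

Some published renderings of the Bhattacharyya distance and the
divergence carry sign typos (a difference of covariances where the
pooled average belongs, or a difference of inverse covariances in the
mean term); those variants evaluate to zero or negative values for
identical classes and are therefore not separabilities.  This module
implements the standard textbook forms, which are the ones consistent
with the bounded transforms built on top of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GaussianClassSummary",
    "MetricValue",
    "m_statistic",
    "bhattacharyya",
    "jeffries_matusita",
    "divergence",
    "transformed_divergence",
    "normalize_metric",
    "METRIC_NAMES",
]

#: canonical metric identifiers, in reporting order
METRIC_NAMES = ("M", "B", "JM", "TD")

#: variance entries below this are considered degenerate and trigger
#: ridge regularization
DEGENERATE_VAR = 1e-12

#: default ridge added to degenerate covariances
DEFAULT_RIDGE = 1e-10


@dataclass(frozen=True)
class GaussianClassSummary:
    """First two moments of a class-conditional Gaussian.

    Parameters
    ----------
    mu : array-like, shape (d,)
        Mean vector.  A scalar is promoted to d = 1.
    cov : array-like, shape (d, d)
        Covariance matrix.  For d = 1 a scalar variance is accepted.
    """

    mu: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        cov = np.asarray(self.cov, dtype=float)
        if cov.ndim == 0:
            cov = cov.reshape(1, 1)
        elif cov.ndim == 1:
            cov = np.diag(cov)
        if mu.ndim != 1 or cov.shape != (mu.size, mu.size):
            raise ValueError(
                f"dimension mismatch: mu has length {mu.size}, cov has shape {cov.shape}"
            )
        if not np.allclose(cov, cov.T, rtol=1e-8, atol=1e-12):
            raise ValueError("covariance matrix must be symmetric")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "cov", cov)

    @property
    def dim(self) -> int:
        return self.mu.size

    @classmethod
    def univariate(cls, mu: float, sigma: float) -> "GaussianClassSummary":
        """Build a d = 1 summary from a mean and a standard deviation."""
        return cls(mu=np.array([float(mu)]), cov=np.array([[float(sigma) ** 2]]))


@dataclass(frozen=True)
class MetricValue:
    """A named separability value together with its [0, 1] normalization."""

    metric: str
    value: float
    normalized: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.metric not in METRIC_NAMES:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.value < 0 and not np.isnan(self.value):
            raise ValueError(f"{self.metric} value must be nonnegative, got {self.value}")


def _regularize(cov: np.ndarray, ridge: float) -> np.ndarray:
    """Add ridge * I where any variance entry is degenerate."""
    if np.any(np.diag(cov) < DEGENERATE_VAR):
        return cov + ridge * np.eye(cov.shape[0])
    return cov


def _check_pair(a: GaussianClassSummary, b: GaussianClassSummary) -> None:
    if a.dim != b.dim:
        raise ValueError(f"dimension mismatch: {a.dim} vs {b.dim}")


def m_statistic(a: GaussianClassSummary, b: GaussianClassSummary) -> MetricValue:
    """M = |mu_a - mu_b| / (sigma_a + sigma_b), univariate only.

    The absolute value makes M a separability: it is zero exactly when
    the two class means coincide, regardless of argument order.
    """
    _check_pair(a, b)
    if a.dim != 1:
        raise ValueError("the M-statistic is defined for univariate summaries only")
    sa = float(np.sqrt(a.cov[0, 0]))
    sb = float(np.sqrt(b.cov[0, 0]))
    if sa + sb <= 0.0:
        raise ValueError("both standard deviations are zero; M is undefined")
    m = abs(float(a.mu[0]) - float(b.mu[0])) / (sa + sb)
    return normalize_metric(MetricValue("M", m))


def bhattacharyya(
    a: GaussianClassSummary,
    b: GaussianClassSummary,
    ridge: float = DEFAULT_RIDGE,
) -> MetricValue:
    """Gaussian Bhattacharyya distance.

    B = 1/8 (mu_a - mu_b)^T [(S_a + S_b)/2]^-1 (mu_a - mu_b)
        + 1/2 ln( |(S_a + S_b)/2| / sqrt(|S_a| |S_b|) )

    equal to -ln integral sqrt(p_a p_b) for Gaussian densities.
    Degenerate covariances are floored with ``ridge * I``.
    """
    _check_pair(a, b)
    ca = _regularize(a.cov, ridge)
    cb = _regularize(b.cov, ridge)
    pooled = (ca + cb) / 2.0
    dm = a.mu - b.mu
    try:
        sol = np.linalg.solve(pooled, dm)
    except np.linalg.LinAlgError as exc:
        raise ValueError("pooled covariance is singular") from exc
    term_mean = float(dm @ sol) / 8.0
    sign_p, logdet_p = np.linalg.slogdet(pooled)
    sign_a, logdet_a = np.linalg.slogdet(ca)
    sign_b, logdet_b = np.linalg.slogdet(cb)
    if min(sign_p, sign_a, sign_b) <= 0:
        raise ValueError("covariance matrices must be positive definite")
    term_cov = 0.5 * (logdet_p - 0.5 * (logdet_a + logdet_b))
    value = term_mean + term_cov
    # numerical noise can leave a tiny negative residue at near-identical inputs
    value = max(value, 0.0)
    return normalize_metric(MetricValue("B", value))


def jeffries_matusita(b: MetricValue | float, sqrt_convention: bool = False) -> MetricValue:
    """Jeffries–Matusita distance from a Bhattacharyya distance.

    Default: JM = 2 (1 - exp(-B)), bounded by 2.  With
    ``sqrt_convention=True`` returns sqrt(2 (1 - exp(-B))), bounded by
    sqrt(2); both are strictly increasing in B and zero at B = 0.
    """
    bval = b.value if isinstance(b, MetricValue) else float(b)
    if bval < 0:
        raise ValueError(f"Bhattacharyya distance must be nonnegative, got {bval}")
    jm = 2.0 * (1.0 - np.exp(-bval))
    if sqrt_convention:
        jm = float(np.sqrt(jm))
    return normalize_metric(MetricValue("JM", float(jm)), sqrt_convention=sqrt_convention)


def divergence(
    a: GaussianClassSummary,
    b: GaussianClassSummary,
    ridge: float = DEFAULT_RIDGE,
) -> float:
    """Symmetric divergence between two Gaussians.

    D = 1/2 tr[(C_a - C_b)(C_b^-1 - C_a^-1)]
        + 1/2 tr[(C_a^-1 + C_b^-1)(mu_a - mu_b)(mu_a - mu_b)^T]

    Nonnegative and symmetric; zero iff the summaries coincide.
    """
    _check_pair(a, b)
    ca = _regularize(a.cov, ridge)
    cb = _regularize(b.cov, ridge)
    try:
        ca_inv = np.linalg.inv(ca)
        cb_inv = np.linalg.inv(cb)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular covariance matrix") from exc
    dm = (a.mu - b.mu).reshape(-1, 1)
    term_cov = 0.5 * float(np.trace((ca - cb) @ (cb_inv - ca_inv)))
    term_mean = 0.5 * float(np.trace((ca_inv + cb_inv) @ (dm @ dm.T)))
    return max(term_cov + term_mean, 0.0)


def transformed_divergence(
    a: GaussianClassSummary,
    b: GaussianClassSummary,
    ridge: float = DEFAULT_RIDGE,
) -> MetricValue:
    """TD = 2 (1 - exp(-D / 8)), bounded in [0, 2]."""
    d = divergence(a, b, ridge=ridge)
    td = 2.0 * (1.0 - np.exp(-d / 8.0))
    return normalize_metric(MetricValue("TD", float(td)))


def normalize_metric(v: MetricValue, sqrt_convention: bool = False) -> MetricValue:
    """Attach the [0, 1] normalization for a metric value.

    JM -> JM/2 (JM^2/2 under the sqrt convention); TD -> TD/2;
    B -> 1 - exp(-B); M -> M/(1+M).  Each map sends 0 to 0, is strictly
    increasing, and has limit 1, so metrics on different raw scales
    become averageable.
    """
    x = v.value
    if v.metric == "JM":
        norm = (x * x / 2.0) if sqrt_convention else (x / 2.0)
    elif v.metric == "TD":
        norm = x / 2.0
    elif v.metric == "B":
        norm = 1.0 - float(np.exp(-x))
    elif v.metric == "M":
        norm = x / (1.0 + x)
    else:  # pragma: no cover - guarded by MetricValue
        raise ValueError(f"unknown metric {v.metric!r}")
    return MetricValue(v.metric, x, float(norm))


def all_metrics(
    a: GaussianClassSummary,
    b: GaussianClassSummary,
    metrics: tuple[str, ...] = METRIC_NAMES,
    sqrt_convention: bool = False,
    ridge: float = DEFAULT_RIDGE,
) -> dict[str, MetricValue]:
    """Evaluate the requested metrics for one pair of class summaries.

    B is computed once and reused for JM.  Unknown metric names raise.
    """
    unknown = set(metrics) - set(METRIC_NAMES)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    out: dict[str, MetricValue] = {}
    if "M" in metrics:
        out["M"] = m_statistic(a, b)
    if "B" in metrics or "JM" in metrics:
        bv = bhattacharyya(a, b, ridge=ridge)
        if "B" in metrics:
            out["B"] = bv
        if "JM" in metrics:
            out["JM"] = jeffries_matusita(bv, sqrt_convention=sqrt_convention)
    if "TD" in metrics:
        out["TD"] = transformed_divergence(a, b, ridge=ridge)
    return out
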