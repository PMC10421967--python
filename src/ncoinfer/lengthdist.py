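"""Negative-binomial length components and mixtures.

NCO event lengths ``L`` are positive integers; we model ``L - 1`` as a
negative binomial with size (dispersion) ``r`` and mean ``m - 1``, so the
support is {1, 2, ...} and a 1 bp event is attainable.  ``r = 1`` recovers
the (shifted) geometric distribution.  The variance on the length scale is
``(m - 1) + (m - 1)**2 / r``: ``r -> inf`` approaches a shifted Poisson,
small ``r`` is strongly overdispersed.

A mixture carries two weight vectors:

* ``alpha`` — weights among *all* NCO events (the underlying distribution);
* ``alpha_hat`` — weights among events that produced an observable tract.

They are linked through the per-component detection mass
``d_i = sum_x D(x) f_i(x)``: ``alpha_hat_i`` is proportional to
``alpha_i * d_i``.  Long components are detected more often, so they are
over-represented among observed tracts; fits happen in the detected space
(``alpha_hat``) and are converted back for reporting.

Infinite sums over lengths are truncated where every component's upper tail
mass drops below a tolerance (1e-9 by default), re-evaluated whenever
parameters move.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .io import ValidationError

__all__ = [
    "NBComponent",
    "NBMixture",
    "nb_pmf",
    "truncation_point",
    "detection_mass",
    "convert_weights",
    "invert_weights",
    "mixture_mean",
    "size_from_variance",
]

DEFAULT_TAIL_TOL = 1e-9


@dataclass(frozen=True)
class NBComponent:
    """One negative-binomial length component, parameterised by its mean
    length ``m`` (bp, > 1) and size ``r`` (> 0)."""

    mean: float
    size: float

    def __post_init__(self) -> None:
        if not self.mean > 1.0:
            raise ValidationError(f"component mean must be > 1 bp, got {self.mean}")
        if not self.size > 0.0:
            raise ValidationError(f"component size must be > 0, got {self.size}")

    @property
    def _mu(self) -> float:
        return self.mean - 1.0

    @property
    def _prob(self) -> float:
        # scipy's success probability: r / (r + mu)
        return self.size / (self.size + self._mu)

    @property
    def variance(self) -> float:
        return self._mu + self._mu**2 / self.size

    def pmf(self, x) -> np.ndarray:
        """f(x) = Pr(L = x) for integer x >= 1."""
        return np.exp(self.logpmf(x))

    def logpmf(self, x) -> np.ndarray:
        # direct gammaln evaluation; equivalent to scipy.stats.nbinom at
        # (x - 1, r, r / (r + mu)) but without distribution-object overhead
        x = np.asarray(x)
        if np.any(x < 1):
            raise ValidationError("length must be >= 1")
        k = np.asarray(x, dtype=np.float64) - 1.0
        r = self.size
        pr = self._prob
        return (
            special.gammaln(k + r)
            - special.gammaln(r)
            - special.gammaln(k + 1.0)
            + r * np.log(pr)
            + k * np.log1p(-pr)
        )

    def sf(self, x) -> np.ndarray:
        """Pr(L > x): regularised incomplete beta tail of the NB cdf."""
        k = np.asarray(x, dtype=np.float64) - 1.0
        out = special.betainc(np.maximum(k, 0.0) + 1.0, self.size, 1.0 - self._prob)
        return np.where(k < 0.0, 1.0, out)


def nb_pmf(component: NBComponent, x) -> np.ndarray:
    return component.pmf(x)


def size_from_variance(mean: float, variance: float) -> float:
    """Size r giving the requested variance at the given mean length.

    The minimum attainable variance is ``mean - 1`` (the r -> inf Poisson
    limit of the shifted negative binomial).
    """
    mu = mean - 1.0
    if variance <= mu:
        raise ValidationError(
            f"variance {variance} not attainable at mean {mean}: must exceed {mu}"
        )
    return mu**2 / (variance - mu)


def truncation_point(
    obj: "NBComponent | NBMixture", tail_tol: float = DEFAULT_TAIL_TOL
) -> int:
    """Smallest X such that Pr(L > X) < tail_tol for every component."""
    if not (0.0 < tail_tol < 1.0):
        raise ValidationError("tail_tol must be in (0, 1)")
    comps = obj.components if isinstance(obj, NBMixture) else [obj]
    x_max = 1
    for c in comps:
        hi = max(2, int(c._mu + 8.0 * np.sqrt(c.variance)) + 2)
        while c.sf(hi) >= tail_tol:
            hi *= 2
        lo = 1
        while lo < hi:  # smallest X with Pr(L > X) < tail_tol
            mid = (lo + hi) // 2
            if c.sf(mid) < tail_tol:
                hi = mid
            else:
                lo = mid + 1
        x_max = max(x_max, lo)
    return x_max


def detection_mass(component: NBComponent, d: np.ndarray,
                   tail_tol: float = DEFAULT_TAIL_TOL) -> float:
    """``sum_x D(x) f(x)``: the probability that an event from this component
    produces an observable tract."""
    d = np.asarray(d, dtype=np.float64)
    # the tabulated range must leave at most (a whisker above) the tail
    # tolerance uncovered
    if float(component.sf(d.size)) >= 10.0 * tail_tol:
        need = truncation_point(component, tail_tol)
        raise ValidationError(
            f"detection function tabulated to {d.size} but the component needs "
            f"x_max >= {need}; recompute the kernel with a larger x_max"
        )
    xs = np.arange(1, d.size + 1)
    return float(np.dot(d, component.pmf(xs)))


def convert_weights(alpha: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Underlying weights -> detected-space weights: alpha_hat_i ∝ alpha_i d_i."""
    alpha = np.asarray(alpha, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    _check_simplex(alpha)
    if np.any((d <= 0.0) & (alpha > 0.0)):
        raise ValidationError("component with positive weight is undetectable (d=0)")
    w = alpha * d
    return w / w.sum()


def invert_weights(alpha_hat: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Detected-space weights -> underlying weights: alpha_i ∝ alpha_hat_i / d_i."""
    alpha_hat = np.asarray(alpha_hat, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    _check_simplex(alpha_hat)
    if np.any((d <= 0.0) & (alpha_hat > 0.0)):
        raise ValidationError("component with positive weight is undetectable (d=0)")
    w = np.where(alpha_hat > 0.0, alpha_hat / np.where(d > 0, d, 1.0), 0.0)
    return w / w.sum()


def _check_simplex(w: np.ndarray, tol: float = 1e-8) -> None:
    if np.any(w < -tol) or abs(w.sum() - 1.0) > tol:
        raise ValidationError(f"weights {w} are not on the probability simplex")


@dataclass
class NBMixture:
    """A mixture of negative-binomial length components.

    ``alpha_hat`` are the detected-space weights (what the EM fits);
    ``d`` and ``alpha`` are filled in once a detection function is available.
    """

    components: list[NBComponent]
    alpha_hat: np.ndarray
    d: np.ndarray | None = None  # per-component detection mass
    alpha: np.ndarray | None = None  # underlying weights

    def __post_init__(self) -> None:
        self.alpha_hat = np.asarray(self.alpha_hat, dtype=np.float64)
        if len(self.components) != self.alpha_hat.size:
            raise ValidationError("one weight per component required")
        _check_simplex(self.alpha_hat)
        self.alpha_hat = self.alpha_hat / self.alpha_hat.sum()

    @property
    def n_components(self) -> int:
        return len(self.components)

    def with_detection(self, D: np.ndarray, tail_tol: float = DEFAULT_TAIL_TOL) -> "NBMixture":
        """Return a copy with detection masses and underlying weights filled in."""
        d = np.array([detection_mass(c, D, tail_tol) for c in self.components])
        alpha = invert_weights(self.alpha_hat, d)
        return NBMixture(list(self.components), self.alpha_hat.copy(), d, alpha)

    def pmf(self, x) -> np.ndarray:
        """Pmf of the underlying event-length distribution, sum_i alpha_i f_i(x)."""
        if self.alpha is None:
            raise ValidationError("underlying weights unknown; call with_detection first")
        out = np.zeros(np.shape(np.asarray(x)), dtype=np.float64)
        for wi, c in zip(self.alpha, self.components):
            out = out + wi * c.pmf(x)
        return out

    def mean(self) -> float:
        return mixture_mean(self)

    def detection_probability(self) -> float:
        """Pr(S != empty): probability that a random NCO event is observed."""
        if self.d is None or self.alpha is None:
            raise ValidationError("detection masses unknown; call with_detection first")
        return float(np.dot(self.alpha, self.d))


def mixture_mean(mix: NBMixture) -> float:
    """Mean of the underlying event-length distribution (bp)."""
    if mix.alpha is None:
        raise ValidationError("underlying weights unknown; call with_detection first")
    return float(np.dot(mix.alpha, [c.mean for c in mix.components]))


# ---------------------------------------------------------------------------
# serialization


def write_mixture(mix: NBMixture, path) -> None:
    import pandas as pd

    rows = []
    for i, c in enumerate(mix.components):
        rows.append(
            {
                "component": i,
                "mean": c.mean,
                "size": c.size,
                "alpha_hat": mix.alpha_hat[i],
                "alpha": np.nan if mix.alpha is None else mix.alpha[i],
                "d": np.nan if mix.d is None else mix.d[i],
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_mixture(path) -> NBMixture:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    comps = [NBComponent(m, s) for m, s in zip(df["mean"], df["size"])]
    mix = NBMixture(comps, df["alpha_hat"].to_numpy())
    if "d" in df.columns and not df["d"].isna().any():
        mix.d = df["d"].to_numpy()
        mix.alpha = df["alpha"].to_numpy()
    return mix
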