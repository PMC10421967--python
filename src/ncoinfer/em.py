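"""Likelihood and EM fit of the length-distribution mixture.

The probability of observing tract ``t`` given that it was observed at all,
under a single length component with pmf ``f``, is the ratio

    Pr(O = o_t | S != 0, f)  =  sum_x T_t(x) f(x)  /  sum_x D(x) f(x),

and the data log-likelihood is the sum over tracts of the log of the
``alpha_hat``-weighted mixture of these ratios.  The EM alternates

* E-step: membership weights ``w_it`` proportional to
  ``alpha_hat_i * Pr(O = o_t | theta_i, S != 0)``;
* M-step: ``alpha_hat_i <- mean_t w_it`` and each ``theta_i`` re-optimised
  numerically (Nelder-Mead over ``(log(m - 1), log r)``) against the
  weighted sum of log tract probabilities, keeping the previous value if
  the optimiser fails to improve it — which preserves the EM guarantee of
  a monotonically nondecreasing log-likelihood.

Iteration stops when the Euclidean norm of the parameter changes (weights
on the probability scale, mean and size on the log scale, i.e. relative
changes) drops below the configured tolerance (1e-7 by default).

Internally, tracts with bit-identical tract-function rows are collapsed
with multiplicities; this changes nothing numerically and makes bootstrap
resamples and dense-marker datasets (where many tracts share a row) cheap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, sparse, special

from .io import ValidationError
from .kernel import KernelTable
from .lengthdist import (
    DEFAULT_TAIL_TOL,
    NBComponent,
    NBMixture,
    detection_mass,
    invert_weights,
    truncation_point,
)

logger = logging.getLogger(__name__)

__all__ = ["FitConfig", "FitResult", "tract_prob", "loglikelihood", "e_step", "m_step", "fit_em"]

_COLLAPSE_TOL = 1e-6
_LOG_FLOOR = 1e-300
# optimiser box in (log(mean - 1), log size) space
_LOG_MU_BOUNDS = (np.log(1e-3), np.log(1e8))
_LOG_R_BOUNDS = (np.log(1e-3), np.log(1e3))


@dataclass
class FitConfig:
    """Settings for one EM fit."""

    n_components: int = 1
    tol: float = 1e-7
    max_iter: int = 500
    seed: int | None = None
    restarts: int = 1
    tail_tol: float = DEFAULT_TAIL_TOL
    geometric: bool = False  # fix all component sizes at r = 1
    inner_tol: float = 1e-10  # M-step objective tolerance
    length_cap: int | None = None  # largest event length the fit may request
    # stop early when the log-likelihood has gained less than this for
    # several consecutive iterations (a flat ridge, e.g. a redundant
    # component); the parameter-change criterion remains the primary rule
    stall_tol: float = 1e-6
    stall_iters: int = 8

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValidationError("tol must be > 0")
        if self.restarts < 1:
            raise ValidationError("restarts must be >= 1")
        if self.n_components < 1:
            raise ValidationError("n_components must be >= 1")


@dataclass
class FitResult:
    """A converged (or max-iteration) EM fit."""

    mixture: NBMixture
    loglik: float
    trace: list[float]
    weights: np.ndarray  # tracts x components, original tract order
    converged: bool
    n_iter: int
    n_tracts: int
    collapsed: int = 0  # components dropped during the fit
    restart: int = 0  # index of the winning restart

    def summary(self) -> dict:
        mix = self.mixture
        out = {
            "n_components": mix.n_components,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "mean_length": mix.mean() if mix.alpha is not None else None,
        }
        for i, c in enumerate(mix.components):
            out[f"mean_{i}"] = c.mean
            out[f"size_{i}"] = c.size
            out[f"alpha_hat_{i}"] = float(mix.alpha_hat[i])
            if mix.alpha is not None:
                out[f"alpha_{i}"] = float(mix.alpha[i])
        return out


# ---------------------------------------------------------------------------
# plain (ungrouped) likelihood pieces — the reference path used by tests


def tract_prob(T_t: np.ndarray, D: np.ndarray, component: NBComponent,
               tail_tol: float = DEFAULT_TAIL_TOL) -> float:
    """Pr(O = o_t | S != 0) under one component: ratio of f-weighted sums."""
    T_t = np.asarray(T_t, dtype=np.float64)
    D = np.asarray(D, dtype=np.float64)
    if float(component.sf(min(D.size, T_t.size))) >= 10.0 * tail_tol:
        need = truncation_point(component, tail_tol)
        raise ValidationError(
            f"kernel tabulated to {min(D.size, T_t.size)} but component needs {need}"
        )
    f = component.pmf(np.arange(1, D.size + 1))
    denom = float(np.dot(D, f))
    if denom <= 0.0:
        raise ValidationError("component is undetectable: sum_x D(x) f(x) = 0")
    return float(np.dot(T_t, f)) / denom


def _prob_matrix(kernel: KernelTable, mix: NBMixture, tail_tol: float) -> np.ndarray:
    """tracts x components matrix of tract probabilities."""
    need = max(truncation_point(c, tail_tol) for c in mix.components)
    kernel.ensure(need)
    xs = np.arange(1, kernel.x_max + 1)
    cols = []
    for c in mix.components:
        f = c.pmf(xs)
        denom = float(np.dot(kernel.D, f))
        if denom <= 0.0:
            raise ValidationError("component is undetectable: sum_x D(x) f(x) = 0")
        cols.append((kernel.T @ f) / denom)
    return np.column_stack(cols)


def loglikelihood(kernel: KernelTable, mix: NBMixture,
                  tail_tol: float = DEFAULT_TAIL_TOL) -> float:
    """Sum over tracts of log sum_i alpha_hat_i Pr(O = o_t | theta_i, S != 0).

    Returns -inf (and logs the offending tract ids) if some tract has zero
    probability under every component.
    """
    u = _prob_matrix(kernel, mix, tail_tol)
    lik = u @ mix.alpha_hat
    if np.any(lik <= 0.0):
        bad = [kernel.tract_ids[i] for i in np.nonzero(lik <= 0.0)[0]]
        logger.warning("tract(s) impossible under the model: %s", bad[:10])
        return float("-inf")
    return float(np.log(lik).sum())


def e_step(kernel: KernelTable, mix: NBMixture,
           tail_tol: float = DEFAULT_TAIL_TOL) -> np.ndarray:
    """Membership weights w_it; each row sums to 1."""
    u = _prob_matrix(kernel, mix, tail_tol)
    num = u * mix.alpha_hat
    tot = num.sum(axis=1)
    if np.any(tot <= 0.0):
        bad = [kernel.tract_ids[i] for i in np.nonzero(tot <= 0.0)[0]]
        raise ValidationError(f"tract(s) impossible under every component: {bad[:10]}")
    return num / tot[:, None]


def m_step(kernel: KernelTable, w: np.ndarray, mix: NBMixture,
           config: FitConfig | None = None) -> NBMixture:
    """One M-step: update alpha_hat and re-optimise each component.

    Components whose weight column is (numerically) all zero are flagged
    collapsed: their alpha_hat becomes 0 and theta is left untouched.
    """
    config = config or FitConfig(n_components=mix.n_components)
    w = np.asarray(w, dtype=np.float64)
    state = _FitState(kernel, config)
    alpha_hat = w.sum(axis=0) / w.shape[0]
    comps = []
    for i, comp in enumerate(mix.components):
        if alpha_hat[i] <= 0.0:
            logger.warning("component %d collapsed (zero weight)", i)
            comps.append(comp)
            continue
        comps.append(state.optimize_component(comp, state.collapse_weights(w[:, i]), config))
    return NBMixture(comps, alpha_hat / alpha_hat.sum())


# ---------------------------------------------------------------------------
# grouped fit state


class _FitState:
    """Kernel view with duplicate tract-function rows collapsed.

    Grouping is keyed on the kernel's structural row keys, so it is stable
    under kernel extension; only the grouped matrix is re-sliced when the
    table grows.  ``tract_weights`` carries per-tract multiplicities
    (bootstrap resample counts); the default is one each.
    """

    def __init__(self, kernel: KernelTable, config: FitConfig,
                 tract_weights: np.ndarray | None = None):
        self.kernel = kernel
        self.tail_tol = config.tail_tol
        # lengths at or beyond the shortest chromosome have no placement
        # distribution, so that is always a hard cap
        hard = kernel._genome.min_length - 1
        self.length_cap = hard if config.length_cap is None else min(config.length_cap, hard)
        self._synced_at = -1
        self._trunc_cache: dict[tuple[float, float], int] = {}
        self._tract_weights = (
            np.ones(kernel.n_tracts) if tract_weights is None
            else np.asarray(tract_weights, dtype=np.float64)
        )
        self._sync()

    def set_weights(self, tract_weights: np.ndarray) -> None:
        """Swap the per-tract multiplicities (used by bootstrap resamples)."""
        self._tract_weights = np.asarray(tract_weights, dtype=np.float64)
        self.counts = np.bincount(
            self.inverse, weights=self._tract_weights, minlength=len(self._rows)
        )

    def _sync(self) -> None:
        if self._synced_at == self.kernel.x_max:
            return
        T = self.kernel.T
        if self._synced_at < 0:
            # group by the kernel's structural row keys: equal keys mean
            # identical rows at every x, so the grouping survives extensions
            groups: dict[bytes, int] = {}
            inverse = np.empty(T.shape[0], dtype=np.int64)
            rows: list[int] = []
            for i, key in enumerate(self.kernel.row_keys):
                g = groups.get(key)
                if g is None:
                    g = len(rows)
                    groups[key] = g
                    rows.append(i)
                inverse[i] = g
            self.inverse = inverse
            self._rows = rows
            self.counts = np.bincount(
                inverse, weights=self._tract_weights, minlength=len(rows)
            )
        Tu = T[self._rows]
        density = np.count_nonzero(Tu) / max(1, Tu.size)
        # CSR only pays off for near-singleton rows (dense marker maps);
        # wide-support rows are cheaper as a dense slice per evaluation
        if density < 0.05 and Tu.size > 2_000_000:
            csr = sparse.csr_array(Tu)
            # restrict to the columns that actually carry mass, so an
            # objective evaluation only prices the pmf at those lengths
            self._cols = np.unique(csr.indices)
            self.Tu = csr[:, self._cols]
            self._k_cols = self._cols.astype(np.float64)  # k = x - 1
            self._lgk1_cols = special.gammaln(self._k_cols + 1.0)
        else:
            self._cols = None
            self.Tu = Tu
        # cached gammaln(k + 1) over the full length range, k = x - 1
        self._k_full = np.arange(self.kernel.x_max, dtype=np.float64)
        self._lgk1_full = special.gammaln(self._k_full + 1.0)
        self.D = self.kernel.D
        # beyond this index the detection function has saturated (D = 1)
        # to machine precision, letting the denominator use the closed
        # tail sum 1 - Pr(L > x)
        nonsat = np.nonzero(1.0 - self.D > 1e-15)[0]
        self._d_sat = int(nonsat[-1]) + 1 if nonsat.size else 0
        self._synced_at = self.kernel.x_max
        logger.debug(
            "kernel grouped: %d tracts -> %d unique rows (density %.3f)",
            T.shape[0], len(self._rows), density,
        )

    @property
    def n_tracts(self) -> int:
        return int(self.counts.sum())

    def ensure(self, x_max: int) -> None:
        if x_max > self.kernel.x_max:
            # grow geometrically to avoid repeated rebuilds, but never past
            # the configured cap or the genome's hard limit
            target = max(x_max, 2 * self.kernel.x_max)
            if self.length_cap is not None:
                target = min(target, max(self.length_cap, x_max))
            target = min(target, self.kernel._genome.min_length - 1)
            self.kernel.ensure(target)
            self._sync()

    def collapse_weights(self, w_full: np.ndarray) -> np.ndarray:
        """Per-tract weights -> per-group totals."""
        return np.bincount(self.inverse, weights=w_full, minlength=self.counts.size)

    def expand(self, w_groups: np.ndarray) -> np.ndarray:
        return w_groups[self.inverse]

    # -- likelihood pieces ------------------------------------------------

    def _fast_pmf(self, comp: NBComponent, k: np.ndarray, lgk1: np.ndarray) -> np.ndarray:
        """NB pmf at lengths k + 1 with the gammaln(k+1) term precomputed."""
        r = comp.size
        pr = comp._prob
        logp = special.gammaln(k + r) - lgk1
        logp += k * math.log1p(-pr) + (r * math.log(pr) - special.gammaln(r))
        return np.exp(logp, out=logp)

    def required_length(self, comp: NBComponent) -> int:
        """A verified (slightly generous) bound on the truncation point.

        Exactness is not needed here — any X with tail mass below the
        tolerance is valid — so a cheap moment-based bound plus one tail
        check replaces the bisection, and nearby candidates share a cache
        slot keyed on quantised log-parameters.
        """
        key = (round(math.log(comp.mean - 1.0), 3), round(math.log(comp.size), 3))
        out = self._trunc_cache.get(key)
        if out is None:
            # geometric tail rate -log(1 - pr) dominates for small sizes,
            # the Gaussian-style moment bound for large ones
            rate = -np.log1p(-comp._prob)
            guess = max(
                comp.mean - 1.0 + 4.0 * np.sqrt(comp.variance),
                -np.log(self.tail_tol) / rate,
            )
            out = int(guess) + 50
            while comp.sf(out) >= self.tail_tol:
                out = int(1.3 * out) + 1
            self._trunc_cache[key] = out
        return out

    def component_probs(self, comp: NBComponent) -> np.ndarray:
        """Grouped tract probabilities under one component.

        Sums run only to the component's own truncation point: beyond it the
        pmf mass is below the tail tolerance and contributes nothing, so the
        cost tracks the candidate's scale instead of the table width.  Where
        the detection function has saturated at 1, the denominator tail is
        the closed-form cumulative mass, so the pmf is only evaluated where
        the kernel actually varies.
        """
        need = self.required_length(comp)
        self.ensure(need)
        if self._cols is not None:
            # sparse path: pmf only at the columns carrying tract mass
            num = np.asarray(self.Tu @ self._fast_pmf(comp, self._k_cols, self._lgk1_cols))
            sat = min(self._d_sat, need)
            denom = 0.0
            if sat:
                f_head = self._fast_pmf(comp, self._k_full[:sat], self._lgk1_full[:sat])
                denom += float(np.dot(self.D[:sat], f_head))
            if sat < need:  # mass on (sat, need], where D has saturated at 1
                denom += float(comp.sf(sat) - comp.sf(need))
        else:
            f = self._fast_pmf(comp, self._k_full[:need], self._lgk1_full[:need])
            num = self.Tu[:, :need] @ f
            denom = float(np.dot(self.D[:need], f))
        if denom <= 0.0:
            raise ValidationError("component is undetectable: sum_x D(x) f(x) = 0")
        return num / denom

    def optimize_component(self, comp: NBComponent, w_groups: np.ndarray,
                           config: FitConfig, xatol: float = 1e-8,
                           step: float = 0.05, fatol: float | None = None) -> NBComponent:
        """Maximise sum_g w_g log Pr(O = o_g | theta, S != 0) over theta,
        warm-started at ``comp``; falls back to ``comp`` on failure.

        ``step`` sets the initial Nelder-Mead simplex size in log-parameter
        space: generous on cold starts, small once the outer EM is taking
        small steps, so warm restarts do not re-explore a wide basin.
        """
        active = w_groups > 1e-12
        if not np.any(active):
            return comp
        w = w_groups[active]
        cap = self.length_cap

        def neg(z: np.ndarray) -> float:
            mean = 1.0 + np.exp(z[0])
            size = np.exp(z[1]) if z.size > 1 else 1.0
            cand = NBComponent(mean, size)
            need = self.required_length(cand)
            if cap is not None and need > cap:
                # soft barrier: the kernel cannot be tabulated this far
                return 1e12 * (1.0 + np.log(need / cap))
            u = self.component_probs(cand)
            return -float(np.dot(w, np.log(np.maximum(u[active], _LOG_FLOOR))))

        z0 = np.array([np.log(comp.mean - 1.0)] if config.geometric
                      else [np.log(comp.mean - 1.0), np.log(comp.size)])
        bounds = [_LOG_MU_BOUNDS] if config.geometric else [_LOG_MU_BOUNDS, _LOG_R_BOUNDS]
        simplex = np.vstack([z0] + [z0 + step * np.eye(z0.size)[i]
                                    for i in range(z0.size)])
        f0 = neg(z0)
        res = optimize.minimize(
            neg, z0, method="Nelder-Mead", bounds=bounds,
            options={"xatol": xatol,
                     "fatol": config.inner_tol if fatol is None else fatol,
                     "maxfev": 600, "initial_simplex": simplex},
        )
        if not np.isfinite(res.fun) or res.fun > f0:
            logger.warning("M-step optimiser failed to improve; keeping previous theta")
            return comp
        mean = 1.0 + float(np.exp(res.x[0]))
        size = 1.0 if config.geometric else float(np.exp(res.x[1]))
        return NBComponent(mean, size)


# ---------------------------------------------------------------------------
# initialisation and the full fit


def _spans(kernel: KernelTable) -> np.ndarray:
    return np.array([t.span for t in kernel._tracts], dtype=np.float64)


def _initial_mixtures(kernel: KernelTable, config: FitConfig,
                      rng: np.random.Generator) -> list[NBMixture]:
    """Span-quantile initialisation plus seeded random jitters.

    Spans lower-bound event lengths; dividing by the penetrance corrects
    the expected fraction of the event covered by converted markers, and
    log-spaced quantiles separate short and long components.
    """
    n = config.n_components
    spans = _spans(kernel)
    qs = (2 * np.arange(n) + 1) / (2 * n)
    base = np.quantile(spans, qs) / kernel.p
    base = np.maximum(base, 2.0)
    # guarantee distinct, increasing means
    for i in range(1, n):
        base[i] = max(base[i], base[i - 1] * 1.5)
    inits = [NBMixture([NBComponent(m, 1.0) for m in base], np.full(n, 1.0 / n))]
    for _ in range(config.restarts - 1):
        means = np.maximum(base * rng.lognormal(0.0, 0.5, n), 2.0)
        sizes = np.ones(n) if config.geometric else rng.lognormal(0.0, 0.5, n)
        ah = rng.dirichlet(np.full(n, 2.0))
        inits.append(NBMixture([NBComponent(m, s) for m, s in zip(means, sizes)], ah))
    return inits


def _param_vector(mix: NBMixture) -> np.ndarray:
    return np.concatenate(
        [
            mix.alpha_hat,
            [np.log(c.mean - 1.0) for c in mix.components],
            [np.log(c.size) for c in mix.components],
        ]
    )


def _run_em(state: _FitState, init: NBMixture, config: FitConfig,
            warm: bool = False):
    comps = list(init.components)
    alpha_hat = init.alpha_hat.copy()
    trace: list[float] = []
    converged = False
    collapsed = 0
    it = 0
    # norm of the last parameter change; a warm start (e.g. a bootstrap
    # refit from the full-data estimate) is already near its optimum
    delta = 0.05 if warm else np.inf
    for it in range(1, config.max_iter + 1):
        # grow the kernel up front so every column sees the same grouping
        state.ensure(max(state.required_length(c) for c in comps))
        u = np.column_stack([state.component_probs(c) for c in comps])
        lik = u @ alpha_hat
        if np.any(lik <= 0.0):
            bad = np.nonzero(lik <= 0.0)[0]
            logger.warning("%d tract group(s) numerically impossible; flooring", bad.size)
            lik = np.maximum(lik, _LOG_FLOOR)
        ll = float(np.dot(state.counts, np.log(lik)))
        trace.append(ll)
        if len(trace) > config.stall_iters and (
            trace[-1] - trace[-1 - config.stall_iters]
            < config.stall_tol * config.stall_iters
        ):
            logger.info("log-likelihood plateau after %d iterations; stopping", it)
            break
        w = (u * alpha_hat) / lik[:, None]  # grouped E-step
        old = _param_vector(NBMixture(comps, alpha_hat))
        alpha_new = (state.counts @ w) / state.n_tracts
        # component collapse: drop and continue with a smaller mixture
        dead = np.nonzero(alpha_new < _COLLAPSE_TOL)[0]
        if dead.size and len(comps) > 1:
            keep = [i for i in range(len(comps)) if i not in set(dead.tolist())]
            logger.warning("dropping %d collapsed component(s)", dead.size)
            comps = [comps[i] for i in keep]
            alpha_hat = alpha_new[keep] / alpha_new[keep].sum()
            collapsed += dead.size
            continue
        # the inner search only needs to out-resolve the current EM step
        # size; both its stopping width and its initial simplex tighten as
        # the outer iteration approaches convergence
        xatol = float(np.clip(0.03 * delta, 1e-8, 3e-3))
        step = float(np.clip(delta, 0.02, 0.25))
        fatol = float(np.clip(0.1 * delta, config.inner_tol, 1e-3))
        for i, comp in enumerate(comps):
            wg = state.counts * w[:, i]
            comps[i] = state.optimize_component(comp, wg, config, xatol, step, fatol)
        alpha_hat = alpha_new / alpha_new.sum()
        new = _param_vector(NBMixture(comps, alpha_hat))
        if old.size == new.size:
            delta = float(np.linalg.norm(new - old))
            if delta < config.tol:
                converged = True
                break
    # final likelihood at the converged parameters
    state.ensure(max(state.required_length(c) for c in comps))
    u = np.column_stack([state.component_probs(c) for c in comps])
    lik = np.maximum(u @ alpha_hat, _LOG_FLOOR)
    ll = float(np.dot(state.counts, np.log(lik)))
    trace.append(ll)
    w = (u * alpha_hat) / lik[:, None]
    return NBMixture(comps, alpha_hat), ll, trace, w, converged, it, collapsed


def fit_em(kernel: KernelTable, config: FitConfig | None = None,
           init: NBMixture | None = None,
           tract_weights: np.ndarray | None = None,
           state: "_FitState | None" = None) -> FitResult:
    """Fit the length-distribution mixture to the tracts behind ``kernel``.

    Runs ``config.restarts`` EM chains (the first from the span-quantile
    initialisation, the rest from seeded jitters, unless ``init`` is given)
    and returns the chain with the highest final log-likelihood; ties break
    to the earliest chain.  Deterministic given ``config.seed``.

    ``tract_weights`` gives per-tract multiplicities (e.g. bootstrap
    resample counts); the kernel itself is untouched.
    """
    config = config or FitConfig()
    if kernel.n_tracts < 1:
        raise ValidationError("at least one tract is required")
    if np.all(kernel.D <= 0.0):
        raise ValidationError("no tract has positive detection probability")
    if state is None:
        state = _FitState(kernel, config, tract_weights)
    elif tract_weights is not None:
        state.set_weights(tract_weights)
    state.ensure(int(max(_spans(kernel))))
    rng = np.random.default_rng(config.seed)
    if init is not None:
        inits = [init]
    else:
        inits = _initial_mixtures(kernel, config, rng)
    if config.length_cap is None:
        # sparse maps make spans undershoot event lengths badly, so leave
        # ample headroom above both the spans and the initial truncation
        x0 = max(truncation_point(c, config.tail_tol)
                 for mx in inits for c in mx.components)
        config.length_cap = int(
            min(kernel._genome.min_length - 1,
                max(16 * int(max(_spans(kernel))), 4 * x0, 2000))
        )
        state.length_cap = min(state.length_cap, config.length_cap)
    best = None
    for ridx, start in enumerate(inits):
        mix, ll, trace, w, conv, it, collapsed = _run_em(
            state, start, config, warm=init is not None)
        logger.info("restart %d: loglik %.6f after %d iteration(s)%s",
                    ridx, ll, it, "" if conv else " (not converged)")
        if best is None or ll > best[1]:
            best = (mix, ll, trace, w, conv, it, collapsed, ridx)
    mix, ll, trace, w, conv, it, collapsed, ridx = best
    mix = mix.with_detection(kernel.D, config.tail_tol)
    return FitResult(
        mixture=mix,
        loglik=ll,
        trace=trace,
        weights=state.expand(w),
        converged=conv,
        n_iter=it,
        n_tracts=int(round(state.n_tracts)),
        collapsed=collapsed,
        restart=ridx,
    )
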