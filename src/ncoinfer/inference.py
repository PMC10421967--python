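"""Model selection, event-count estimation and bootstrap confidence intervals.

*Model selection* walks a ladder of nested models — geometric, one
negative binomial (one extra degree of freedom), then ``n`` vs ``n + 1``
negative-binomial components (three extra degrees of freedom: a weight and
two component parameters) — and keeps adding components while the
likelihood-ratio test is significant at the chosen level.  The chi-squared
reference is the usual Wilks approximation; it is known to be approximate
at mixture boundaries but is adopted here deliberately.

*Event count*: tracts are the detected subset of NCO events, each event
being observed with probability ``Pr(S != 0) = sum_i alpha_i d_i``.  The
plug-in estimate of the total number of events is therefore
``n_tracts / Pr(S != 0)``, divided by the number of meioses for a
per-meiosis rate.

*Confidence intervals* are percentile bootstrap over resampled tracts:
the kernel rows are reused (resampling never changes D or any T_t), each
resample is refit with EM warm-started at the full-data estimate, and the
2.5th/97.5th percentiles of the replicate summaries form the 95% CI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import ValidationError
from .kernel import KernelTable
from .em import FitConfig, FitResult, fit_em
from .lengthdist import NBMixture

logger = logging.getLogger(__name__)

__all__ = [
    "LRTResult",
    "NCOCountEstimate",
    "BootstrapCI",
    "SelectionResult",
    "lrt",
    "select_components",
    "estimate_nco_count",
    "bootstrap_ci",
]


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test of a smaller nested model against a larger one."""

    statistic: float  # 2 * (ll_large - ll_small), clamped at 0
    df: int  # 1 for geometric -> NB, 3 per added NB component
    pvalue: float


def lrt(ll_small: float, ll_large: float, df: int) -> LRTResult:
    """Chi-squared likelihood-ratio test for the two supported nestings."""
    if df not in (1, 3):
        raise ValidationError(f"df must be 1 or 3, got {df}")
    stat = max(0.0, 2.0 * (ll_large - ll_small))
    return LRTResult(stat, df, float(stats.chi2.sf(stat, df)))


@dataclass
class SelectionResult:
    """Outcome of the component-count ladder."""

    chosen: FitResult
    chosen_label: str
    fits: dict[str, FitResult]
    tests: list[tuple[str, str, LRTResult]]  # (small label, large label, test)


def select_components(
    kernel: KernelTable,
    config: FitConfig | None = None,
    alpha: float = 0.05,
    max_components: int = 5,
) -> SelectionResult:
    """Add mixture components while the likelihood ratio stays significant.

    Fits geometric, then a single negative binomial (tested with 1 df),
    then ``n + 1`` vs ``n`` components (3 df each), stopping at the first
    p-value >= ``alpha``; the last accepted model is returned together with
    the whole ladder.
    """
    config = config or FitConfig()
    fits: dict[str, FitResult] = {}
    tests: list[tuple[str, str, LRTResult]] = []

    def cfg(n: int, geometric: bool) -> FitConfig:
        return FitConfig(
            n_components=n, tol=config.tol, max_iter=config.max_iter,
            seed=config.seed, restarts=config.restarts, tail_tol=config.tail_tol,
            geometric=geometric, inner_tol=config.inner_tol,
            length_cap=config.length_cap,
        )

    from .em import _FitState

    c0 = cfg(1, True)
    state = _FitState(kernel, c0)  # shared: extensions/grouping are rung-independent
    fits["geometric"] = fit_em(kernel, c0, state=state)
    config.length_cap = c0.length_cap  # settle the cap once

    fits["nb1"] = fit_em(kernel, cfg(1, False), state=state)
    test = lrt(fits["geometric"].loglik, fits["nb1"].loglik, df=1)
    tests.append(("geometric", "nb1", test))
    if test.pvalue >= alpha:
        return SelectionResult(fits["geometric"], "geometric", fits, tests)
    chosen = "nb1"
    for n in range(2, max_components + 1):
        label = f"nb{n}"
        fits[label] = fit_em(kernel, cfg(n, False), state=state)
        test = lrt(fits[chosen].loglik, fits[label].loglik, df=3)
        tests.append((chosen, label, test))
        if test.pvalue >= alpha:
            break
        chosen = label
    return SelectionResult(fits[chosen], chosen, fits, tests)


@dataclass(frozen=True)
class NCOCountEstimate:
    """Expected NCO event counts behind the observed tracts."""

    total_events: float
    events_per_meiosis: float
    detection_probability: float  # Pr(S != 0) under the fitted mixture
    n_tracts: int
    n_meioses: int


def estimate_nco_count(
    n_tracts: int, mix: NBMixture, D: np.ndarray | None = None, n_meioses: int = 1
) -> NCOCountEstimate:
    """Inverse-detection plug-in estimate of the number of NCO events."""
    if n_meioses < 1:
        raise ValidationError("n_meioses must be >= 1")
    if mix.d is None or mix.alpha is None:
        if D is None:
            raise ValidationError("mixture lacks detection masses and no D was given")
        mix = mix.with_detection(D)
    pr = mix.detection_probability()
    if pr <= 0.0:
        raise ValidationError("Pr(S != 0) = 0: events are undetectable")
    total = n_tracts / pr
    return NCOCountEstimate(total, total / n_meioses, pr, n_tracts, n_meioses)


@dataclass
class BootstrapCI:
    """Percentile bootstrap confidence intervals for the fit summaries."""

    level: float
    n_replicates: int
    n_failed: int
    point: dict[str, float]
    lower: dict[str, float]
    upper: dict[str, float]
    replicates: dict[str, np.ndarray] = field(repr=False)


def _fit_summaries(fit: FitResult, n_meioses: int) -> dict[str, float]:
    mix = fit.mixture
    count = estimate_nco_count(fit.n_tracts, mix, n_meioses=n_meioses)
    out = {
        "mean_length": mix.mean(),
        "total_events": count.total_events,
        "events_per_meiosis": count.events_per_meiosis,
    }
    for i, c in enumerate(mix.components):
        out[f"mean_{i}"] = c.mean
        out[f"size_{i}"] = c.size
        out[f"alpha_hat_{i}"] = float(mix.alpha_hat[i])
    return out


def bootstrap_ci(
    kernel: KernelTable,
    base_fit: FitResult,
    config: FitConfig | None = None,
    B: int = 200,
    level: float = 0.95,
    seed: int | None = None,
    n_meioses: int = 1,
) -> BootstrapCI:
    """Resample tracts with replacement, refit, and take percentile CIs.

    The kernel is shared across replicates (D and the per-tract rows do not
    depend on which tracts were drawn); each replicate reweights the rows
    by its resample counts and warm-starts EM at the full-data fit.
    Deterministic given ``seed``.  Replicates whose fit raises are dropped
    and counted; more than 10% failures triggers a warning.
    """
    from .em import _FitState, _run_em  # shared state across replicates

    config = config or FitConfig(n_components=base_fit.mixture.n_components)
    rng = np.random.default_rng(seed)
    n = kernel.n_tracts
    point = _fit_summaries(base_fit, n_meioses)
    reps: dict[str, list[float]] = {k: [] for k in point}
    failed = 0
    state = _FitState(kernel, config)
    if config.length_cap is None:
        # reuse (or mirror) the cap the base fit settled on
        state.length_cap = config.length_cap = kernel.x_max * 4
    for b in range(B):
        counts = np.bincount(rng.integers(0, n, size=n), minlength=n).astype(np.float64)
        try:
            state.set_weights(counts)
            mix, ll, trace, w, conv, it, collapsed = _run_em(
                state, base_fit.mixture, config, warm=True)
            fit = FitResult(
                mixture=mix.with_detection(kernel.D, config.tail_tol),
                loglik=ll, trace=trace, weights=state.expand(w), converged=conv,
                n_iter=it, n_tracts=int(round(counts.sum())), collapsed=collapsed,
            )
        except (ValidationError, FloatingPointError) as exc:  # pragma: no cover
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
            failed += 1
            continue
        summ = _fit_summaries(fit, n_meioses)
        for k in reps:
            reps[k].append(summ.get(k, np.nan))
    if failed > 0.1 * B:
        logger.warning("%d of %d bootstrap replicates failed", failed, B)
    lo_q, hi_q = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
    replicates = {k: np.asarray(v) for k, v in reps.items()}
    lower = {k: float(np.nanquantile(v, lo_q)) if v.size else np.nan
             for k, v in replicates.items()}
    upper = {k: float(np.nanquantile(v, hi_q)) if v.size else np.nan
             for k, v in replicates.items()}
    return BootstrapCI(level, B - failed, failed, point, lower, upper, replicates)


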