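"""Synthetic marker maps and gene-conversion tract datasets with ground truth.

The generator reproduces the assumed observation process exactly: NCO
events are drawn from a negative-binomial mixture, placed uniformly over
all starts that keep them inside a chromosome, and every informative
marker they overlap is converted independently with the penetrance
probability.  Events converting at least one marker emit a tract; the
rest are invisible, and the generator records how many there were — the
ground truth the estimators are judged against.

Marker maps come in three flavours: explicit positions, a homogeneous
random map with a target mean spacing (the spacing of human informative
markers is around 1.5 kb), or candidate sites with allele frequencies
where a site is heterozygous (hence informative) with probability
``2 f (1 - f)``.

Two experiment grids are provided: a single-component grid over means
{100, 300, 1000} bp, seven dispersion levels (variance = mean^2 * k) and
penetrances {0.5, 0.75, 1.0} with 1000 tracts each, and a two-component
grid pairing the mean-100 and mean-1000 components over all 7 x 7
dispersion pairs and the three penetrances, with 1000 tracts from each
component (equal probability of producing a tract from either, i.e.
detected-space weights 1/2, 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Dataset, Genome, MarkerMap, Tract, ValidationError
from .lengthdist import NBComponent, NBMixture, size_from_variance

__all__ = [
    "MarkerModel",
    "SimConfig",
    "SimResult",
    "synth_markers",
    "simulate_events",
    "simulate_dataset",
    "e1_grid",
    "e2_grid",
    "E1_MEANS",
    "K_GRID",
    "PENETRANCES",
]

# dispersion grid: variance = mean^2 * k; k = 1 matches the geometric
# distribution's variance, smaller k is underdispersed, larger overdispersed
K_GRID = (1 / 16, 1 / 8, 1 / 4, 1 / 2, 1.0, 2.0, 4.0)
E1_MEANS = (100.0, 300.0, 1000.0)
PENETRANCES = (0.5, 0.75, 1.0)

HUMAN_MEAN_SPACING = 1465  # bp between consecutive informative markers
HUMAN_MEDIAN_SPACING = 754  # markers are clustered: median gap ~ half the mean


@dataclass(frozen=True)
class MarkerModel:
    """How to build the informative-marker map (exactly one mode set).

    Density mode draws i.i.d. gaps with the requested *mean* spacing.  With
    only ``spacing`` set the gaps are geometric (a homogeneous map).  Human
    informative markers are strongly clustered — the printed map statistics
    have a median gap roughly half the mean gap — so ``median_spacing`` may
    additionally be given, in which case gaps are discretised lognormals
    matching both statistics.
    """

    positions: tuple[int, ...] | None = None  # explicit 1-based positions
    spacing: float | None = None  # mean gap between consecutive markers
    median_spacing: float | None = None  # optional median gap (clustering)
    sites: tuple[int, ...] | None = None  # candidate sites ...
    freqs: tuple[float, ...] | None = None  # ... kept w.p. 2 f (1 - f)

    def __post_init__(self) -> None:
        modes = sum(x is not None for x in (self.positions, self.spacing, self.sites))
        if modes != 1:
            raise ValidationError("exactly one marker model mode must be set")
        if self.median_spacing is not None:
            if self.spacing is None:
                raise ValidationError("median_spacing requires density mode")
            if not (0 < self.median_spacing <= self.spacing):
                raise ValidationError("median gap must be in (0, mean gap]")
        if self.sites is not None and (
            self.freqs is None or len(self.freqs) != len(self.sites)
        ):
            raise ValidationError("allele-frequency mode needs one frequency per site")


@dataclass(frozen=True)
class SimConfig:
    """One simulated study condition."""

    genome: Genome
    marker_model: MarkerModel
    components: tuple[NBComponent, ...]
    weights: tuple[float, ...]  # underlying mixture weights alpha
    penetrance: float
    n_tracts: int | None = None  # stop after this many tracts ...
    n_events: int | None = None  # ... or after this many events (exactly one)
    tracts_per_component: tuple[int, ...] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.penetrance <= 1.0):
            raise ValidationError("penetrance must be in (0, 1]")
        rules = sum(
            x is not None
            for x in (self.n_tracts, self.n_events, self.tracts_per_component)
        )
        if rules != 1:
            raise ValidationError("exactly one stopping rule must be set")
        if len(self.weights) != len(self.components):
            raise ValidationError("one weight per component required")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValidationError("weights must sum to 1")


@dataclass
class SimResult:
    """A simulated dataset plus the latent truth behind it."""

    dataset: Dataset
    n_events: int  # events generated, observed or not
    events_per_component: np.ndarray
    true_mixture: NBMixture  # underlying weights = alpha
    true_mean: float
    penetrance: float
    # per tract: (component, start, length) of the generating event
    tract_events: list[tuple[int, int, int]] = field(default_factory=list)


def synth_markers(
    genome: Genome,
    model: MarkerModel,
    rng: np.random.Generator,
    parent_id: str = "P1",
) -> MarkerMap:
    """Draw an informative-marker map for one parent."""
    by_chrom: dict[str, np.ndarray] = {}
    if model.positions is not None:
        if len(genome.lengths) != 1:
            raise ValidationError("explicit positions require a single chromosome")
        (chrom,) = genome.lengths
        by_chrom[chrom] = np.asarray(sorted(model.positions), dtype=np.int64)
    elif model.spacing is not None:
        if model.median_spacing is not None:
            # lognormal gaps matching the requested mean and median
            mu = np.log(model.median_spacing)
            sigma = np.sqrt(2.0 * np.log(model.spacing / model.median_spacing))

            def draw(n: int) -> np.ndarray:
                return np.maximum(1, np.rint(rng.lognormal(mu, sigma, n))).astype(np.int64)

        else:
            # geometric gaps: a discrete homogeneous process

            def draw(n: int) -> np.ndarray:
                return rng.geometric(1.0 / model.spacing, size=n)

        for chrom, length in genome.lengths.items():
            n_est = int(2 * length / model.spacing) + 20
            pos = np.cumsum(draw(n_est))
            while pos.size and pos[-1] <= length:
                pos = np.concatenate([pos, pos[-1] + np.cumsum(draw(n_est))])
            by_chrom[chrom] = pos[pos <= length].astype(np.int64)
    else:
        if len(genome.lengths) != 1:
            raise ValidationError("allele-frequency mode requires a single chromosome")
        (chrom,) = genome.lengths
        sites = np.asarray(model.sites, dtype=np.int64)
        freqs = np.asarray(model.freqs, dtype=np.float64)
        keep = rng.random(sites.size) < 2.0 * freqs * (1.0 - freqs)
        by_chrom[chrom] = np.sort(sites[keep])
    if all(v.size == 0 for v in by_chrom.values()):
        raise ValidationError("marker model produced an empty marker set")
    mm = MarkerMap({parent_id: by_chrom})
    mm.validate_against(genome)
    return mm


def _draw_events(
    mixture_alpha: np.ndarray,
    components: tuple[NBComponent, ...],
    genome: Genome,
    rng: np.random.Generator,
    n: int,
    component: int | None = None,
):
    """Draw n events: (component index, chromosome index, start, length)."""
    if component is None:
        comp_idx = rng.choice(len(components), size=n, p=mixture_alpha)
    else:
        comp_idx = np.full(n, component)
    lengths = np.empty(n, dtype=np.int64)
    for i, c in enumerate(components):
        sel = comp_idx == i
        if np.any(sel):
            lengths[sel] = 1 + rng.negative_binomial(c.size, c._prob, size=int(sel.sum()))
    # uniform placement over all (chromosome, start) pairs that fit
    chrom_lengths = np.array(list(genome.lengths.values()), dtype=np.int64)
    lengths = np.minimum(lengths, int(chrom_lengths.max()))  # cannot exceed genome
    n_place = np.maximum(chrom_lengths[None, :] - lengths[:, None] + 1, 0)
    totals = n_place.sum(axis=1)
    u = rng.random(n) * totals
    cum = np.cumsum(n_place, axis=1)
    chrom_idx = (u[:, None] >= cum).sum(axis=1)
    prev = np.where(chrom_idx > 0, np.take_along_axis(cum, np.maximum(chrom_idx - 1, 0)[:, None], 1)[:, 0], 0)
    starts = 1 + np.floor(u - prev).astype(np.int64)
    return comp_idx, chrom_idx, starts, lengths


def simulate_events(
    markers: MarkerMap,
    genome: Genome,
    components: tuple[NBComponent, ...],
    alpha: np.ndarray,
    penetrance: float,
    rng: np.random.Generator,
    n_tracts: int | None = None,
    n_events: int | None = None,
    component: int | None = None,
    max_events: int = 50_000_000,
    tract_prefix: str = "t",
):
    """Generate events until the stopping rule is met.

    Returns (tracts, tract_events, n_events_generated, events_per_component).
    """
    parent = markers.parents[0]
    chroms = list(genome.lengths)
    pos_by_chrom = {c: markers.get(parent, c) for c in chroms}
    p = penetrance
    tracts: list[Tract] = []
    tract_events: list[tuple[int, int, int]] = []
    total_events = 0
    per_comp = np.zeros(len(components), dtype=np.int64)
    batch = max(1000, (n_tracts or 0) * 2, (n_events or 0))
    done = False
    while not done:
        if n_events is not None:
            size = n_events - total_events
            if size <= 0:
                break
        else:
            if len(tracts) >= (n_tracts or 0):
                break
            if total_events >= max_events:
                raise ValidationError(
                    f"generated {total_events} events without reaching "
                    f"{n_tracts} tracts; the mixture may be undetectable"
                )
            size = batch
        comp_idx, chrom_idx, starts, lengths = _draw_events(
            np.asarray(alpha), components, genome, rng, size, component
        )
        ends = starts + lengths - 1
        # vectorised marker lookups per chromosome
        lo = np.empty(size, dtype=np.int64)
        hi = np.empty(size, dtype=np.int64)
        for ci, chrom in enumerate(chroms):
            sel = chrom_idx == ci
            if np.any(sel):
                pos = pos_by_chrom[chrom]
                lo[sel] = np.searchsorted(pos, starts[sel], "left")
                hi[sel] = np.searchsorted(pos, ends[sel], "right")
        # events are consumed strictly in order so that the recorded event
        # total is exact: counting stops at the event that met the quota
        for i in range(size):
            total_events += 1
            per_comp[comp_idx[i]] += 1
            if hi[i] > lo[i]:
                pos = pos_by_chrom[chroms[chrom_idx[i]]]
                inside = pos[lo[i]:hi[i]]
                conv = inside[rng.random(hi[i] - lo[i]) < p]
                if conv.size:
                    tracts.append(
                        Tract(
                            f"{tract_prefix}{len(tracts):05d}",
                            parent,
                            chroms[chrom_idx[i]],
                            tuple(int(v) for v in conv),
                        )
                    )
                    tract_events.append((int(comp_idx[i]), int(starts[i]), int(lengths[i])))
                    if n_tracts is not None and len(tracts) >= n_tracts:
                        done = True
                        break
        if n_tracts is not None and len(tracts) < n_tracts and len(tracts) > 10:
            # adapt the batch to the observed detection rate
            rate = len(tracts) / total_events
            batch = int(1.3 * (n_tracts - len(tracts)) / rate) + 100
    return tracts, tract_events, total_events, per_comp


def simulate_dataset(config: SimConfig, seed: int | None = None,
                     markers: MarkerMap | None = None) -> SimResult:
    """Draw a marker map and a tract dataset for one study condition.

    Pass ``markers`` to hold the informative-marker map fixed across
    replicate datasets (the usual design: one genotyped map, many
    simulated meioses); otherwise a fresh map is drawn from the seed.
    """
    rng = np.random.default_rng(seed)
    if markers is None:
        markers = synth_markers(config.genome, config.marker_model, rng)
    alpha = np.asarray(config.weights, dtype=np.float64)
    if config.tracts_per_component is not None:
        tracts: list[Tract] = []
        events: list[tuple[int, int, int]] = []
        n_ev = 0
        per_comp = np.zeros(len(config.components), dtype=np.int64)
        for ci, quota in enumerate(config.tracts_per_component):
            ts, te, ne, pc = simulate_events(
                markers, config.genome, config.components, alpha,
                config.penetrance, rng, n_tracts=quota, component=ci,
                tract_prefix=f"c{ci}_t",
            )
            tracts += ts
            events += te
            n_ev += ne
            per_comp += pc
    else:
        tracts, events, n_ev, per_comp = simulate_events(
            markers, config.genome, config.components, alpha,
            config.penetrance, rng,
            n_tracts=config.n_tracts, n_events=config.n_events,
        )
    # realised underlying weights: by construction for alpha-driven draws,
    # empirical for quota-driven ones
    if config.tracts_per_component is not None and n_ev > 0:
        alpha_true = per_comp / per_comp.sum()
    else:
        alpha_true = alpha
    mix = NBMixture(
        list(config.components),
        alpha_hat=np.full(len(config.components), 1.0 / len(config.components)),
        alpha=np.asarray(alpha_true, dtype=np.float64),
    )
    true_mean = float(np.dot(alpha_true, [c.mean for c in config.components]))
    ds = Dataset(config.genome, markers, tracts)
    return SimResult(ds, n_ev, per_comp, mix, true_mean, config.penetrance, events)


# ---------------------------------------------------------------------------
# experiment grids


def _default_genome(total: int = 10_000_000) -> Genome:
    return Genome({"chr1": total})


def _component(mean: float, k: float) -> NBComponent:
    return NBComponent(mean, size_from_variance(mean, mean * mean * k))


def e1_grid(
    genome: Genome | None = None,
    spacing: float = HUMAN_MEAN_SPACING,
    n_tracts: int = 1000,
) -> list[SimConfig]:
    """Single-component grid: 3 means x 7 dispersions x 3 penetrances."""
    genome = genome or _default_genome()
    model = MarkerModel(spacing=spacing)
    out = []
    for mean in E1_MEANS:
        for k in K_GRID:
            for p in PENETRANCES:
                out.append(
                    SimConfig(
                        genome, model, (_component(mean, k),), (1.0,), p,
                        n_tracts=n_tracts,
                        label=f"e1_m{mean:g}_k{k:g}_p{p:g}",
                    )
                )
    return out


def e2_grid(
    genome: Genome | None = None,
    spacing: float = HUMAN_MEAN_SPACING,
    tracts_per_component: int = 1000,
) -> list[SimConfig]:
    """Two-component grid: (mean 100, mean 1000), 7 x 7 dispersion pairs,
    3 penetrances; each component contributes the same number of tracts
    (equal probability of producing a tract from either component)."""
    genome = genome or _default_genome()
    model = MarkerModel(spacing=spacing)
    out = []
    for k_short in K_GRID:
        for k_long in K_GRID:
            for p in PENETRANCES:
                out.append(
                    SimConfig(
                        genome, model,
                        (_component(100.0, k_short), _component(1000.0, k_long)),
                        (0.5, 0.5), p,
                        tracts_per_component=(tracts_per_component, tracts_per_component),
                        label=f"e2_k{k_short:g}_k{k_long:g}_p{p:g}",
                    )
                )
    return out
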