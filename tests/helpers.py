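"""Shared test utilities: naive enumeration oracles and small dataset builders.

The oracles re-derive the detection and tract functions by looping over
every placement (and, for the completeness check, every conversion
outcome), independently of the package's closed-form machinery.
"""

from __future__ import annotations

import itertools

import numpy as np

from ncoinfer import Genome, MarkerMap, SimConfig, MarkerModel, Tract
from ncoinfer.lengthdist import NBComponent, size_from_variance


def component(mean: float, k: float) -> NBComponent:
    """NB component with variance = mean^2 * k (the experiment-grid scale)."""
    return NBComponent(mean, size_from_variance(mean, mean * mean * k))


def naive_detection(markers: MarkerMap, genome: Genome, p: float, x_max: int) -> np.ndarray:
    total_w = markers.total_meioses
    out = np.zeros(x_max)
    for x in range(1, x_max + 1):
        n_place = genome.n_placements(x)
        acc = 0.0
        for parent in markers.parents:
            w = markers.meioses[parent] / total_w
            hit = 0.0
            for chrom, length in genome.lengths.items():
                pos = markers.get(parent, chrom)
                for m in range(1, length - x + 2):
                    n = int(np.sum((pos >= m) & (pos <= m + x - 1)))
                    hit += 1.0 - (1.0 - p) ** n
            acc += w * hit / n_place
        out[x - 1] = acc
    return out


def naive_tract(tract: Tract, markers: MarkerMap, genome: Genome, p: float,
                x_max: int) -> np.ndarray:
    total_w = markers.total_meioses
    parent_w = markers.meioses[tract.parent_id] / total_w
    length = genome.lengths[tract.chrom]
    pos = markers.get(tract.parent_id, tract.chrom)
    s = set(tract.positions)
    out = np.zeros(x_max)
    for x in range(1, x_max + 1):
        n_place = genome.n_placements(x)
        tot = 0.0
        for m in range(1, length - x + 2):
            win = set(int(v) for v in pos[(pos >= m) & (pos <= m + x - 1)])
            if s <= win:
                tot += p ** len(s) * (1.0 - p) ** (len(win) - len(s))
        out[x - 1] = parent_w * tot / n_place
    return out


def enumerate_tracts(markers: MarkerMap, genome: Genome, p: float, x_max: int) -> list[Tract]:
    """All distinct tracts with positive probability for events of length
    <= x_max: non-empty marker subsets contained in some length-x window
    (every subset if p < 1, only full window contents if p == 1)."""
    seen: set[tuple[str, str, tuple[int, ...]]] = set()
    out: list[Tract] = []
    for parent in markers.parents:
        for chrom, length in genome.lengths.items():
            pos = markers.get(parent, chrom)
            for x in range(1, x_max + 1):
                for m in range(1, length - x + 2):
                    win = [int(v) for v in pos[(pos >= m) & (pos <= m + x - 1)]]
                    if not win:
                        continue
                    if p >= 1.0:
                        subsets = [tuple(win)]
                    else:
                        subsets = [
                            c for r in range(1, len(win) + 1)
                            for c in itertools.combinations(win, r)
                        ]
                    for sub in subsets:
                        key = (parent, chrom, sub)
                        if key not in seen:
                            seen.add(key)
                            out.append(Tract(f"e{len(out)}", parent, chrom, sub))
    return out


def random_tiny_case(rng: np.random.Generator):
    """A random small genome, marker map and penetrance for oracle checks."""
    n_chrom = int(rng.integers(1, 3))
    lengths = {f"c{i}": int(rng.integers(40, 300)) for i in range(n_chrom)}
    genome = Genome(lengths)
    positions = {}
    meioses = {}
    for pi in range(int(rng.integers(1, 3))):
        by_chrom = {}
        for chrom, length in lengths.items():
            k = int(rng.integers(0, 8))
            by_chrom[chrom] = np.sort(
                rng.choice(np.arange(1, length + 1), size=k, replace=False)
            )
        positions[f"P{pi}"] = by_chrom
        meioses[f"P{pi}"] = int(rng.integers(1, 4))
    markers = MarkerMap(positions, meioses)
    p = float(rng.choice([0.3, 0.5, 1.0]))
    x_max = int(min(30, min(lengths.values()) - 2))
    x_max = max(1, int(rng.integers(1, x_max + 1)))
    return genome, markers, p, x_max


def sim_config(mean: float, k: float, penetrance: float, n_tracts: int,
               genome_length: int = 5_000_000, spacing: float = 1465.0) -> SimConfig:
    return SimConfig(
        Genome({"chr1": genome_length}),
        MarkerModel(spacing=spacing),
        (component(mean, k),),
        (1.0,),
        penetrance,
        n_tracts=n_tracts,
    )


def seeds_for(label: int, n: int) -> list[int]:
    """Deterministic per-replicate seeds below 2**31."""
    ss = np.random.SeedSequence(label)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]
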