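"""Penetrance, detection function and tract functions.

An NCO event is modelled as a random interval ``[M, M + L - 1]`` placed
uniformly over all starts that keep it inside one chromosome, in a random
transmitting parent (chosen proportionally to meiosis counts).  Every
informative marker it overlaps is converted independently with probability
``p`` (the penetrance).  Two ingredients of the likelihood follow:

``D(x)``
    probability that an event of length ``x`` converts at least one marker
    (produces an observable tract), averaged over placements and parents;
``T_t(x)``
    probability that an event of length ``x`` produces *exactly* the
    observed tract ``t`` — the right parent, the converted markers of ``t``
    converted, and every other overlapped marker left unconverted.

Both are computed exactly, not by sampling.  For a window of length ``x``
the set of contained markers is a consecutive run ``i..j`` of the sorted
marker positions, and the number of start positions yielding that exact run
is a trapezoid-shaped piecewise-linear function of ``x``.  Summing
runs weighted by ``(1-p)^(run size)`` therefore reduces to accumulating
trapezoids, which is done in closed form with difference arrays; runs large
enough that ``(1-p)^size`` is below 1e-15 are dropped, keeping the result
exact to well below the 1e-12 documented accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import Dataset, Genome, MarkerMap, Tract, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Penetrance",
    "KernelTable",
    "estimate_penetrance",
    "detect_prob_given_n",
    "detection_function",
    "tract_function",
]

# contributions weighted below this are dropped from the exact enumeration
_NEGLIGIBLE = 1e-15


@dataclass(frozen=True)
class Penetrance:
    """Probability that a marker overlapped by an NCO event is converted.

    When estimated from data, ``p`` is the fraction of converted markers
    among the informative markers strictly between each tract's outermost
    converted markers.  Boundary markers are excluded because they are
    converted by construction and would bias ``p`` upward.
    """

    p: float
    n_internal_markers: int = 0
    n_converted_internal: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValidationError(f"penetrance must be in (0, 1], got {self.p}")


def estimate_penetrance(tracts: list[Tract], markers: MarkerMap) -> Penetrance:
    """Estimate penetrance from interior markers of the observed tracts."""
    n_internal = 0
    n_converted = 0
    for t in tracts:
        pos = markers.get(t.parent_id, t.chrom)
        lo, hi = t.positions[0], t.positions[-1]
        if hi == lo:
            continue  # single-marker tract: no interior
        # informative markers strictly between the outermost converted markers
        n_internal += int(np.searchsorted(pos, hi, "left") - np.searchsorted(pos, lo, "right"))
        n_converted += t.n_converted - 2  # drop first and last (always converted)
    if n_internal == 0:
        raise ValidationError(
            "cannot estimate penetrance: no tract has informative markers strictly "
            "between its first and last converted marker; supply p explicitly"
        )
    return Penetrance(n_converted / n_internal, n_internal, n_converted)


def detect_prob_given_n(n: int | np.ndarray, p: float) -> float | np.ndarray:
    """Probability that an event overlapping ``n`` informative markers converts
    at least one of them: ``1 - (1-p)**n``."""
    return 1.0 - (1.0 - p) ** np.asarray(n)


# ---------------------------------------------------------------------------
# trapezoid accumulation machinery


def _ramp_curve(x_max: int, a: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Evaluate ``f(x) = sum_j w_j * max(0, x - a_j)`` for x = 1..x_max.

    Returned array is indexed by ``x - 1``.  ``a`` are integers (may lie
    outside [1, x_max]).
    """
    a = np.asarray(a, dtype=np.int64)
    w = np.asarray(w, dtype=np.float64)
    out = np.zeros(x_max, dtype=np.float64)
    left = a <= 0
    base_val = float(np.dot(w[left], 1.0 - a[left]))
    base_slope = float(np.sum(w[left]))
    # a ramp with 1 <= a <= x_max-1 adds slope w from the step x=a -> x=a+1
    sel = (a >= 1) & (a <= x_max - 1)
    inc = np.zeros(x_max, dtype=np.float64)
    np.add.at(inc, a[sel], w[sel])  # inc[k] affects step from x=k to x=k+1
    slope = base_slope + np.cumsum(inc)  # slope[k] = f(k+1) - f(k) for x=k
    out[0] = base_val
    if x_max > 1:
        out[1:] = base_val + np.cumsum(slope[1:x_max])
    return out


def _trapezoid_curve(
    x_max: int, s: np.ndarray, h: np.ndarray, e: np.ndarray, w: np.ndarray
) -> np.ndarray:
    """Sum of trapezoids ``w * max(0, min(x - s + 1, h, e - x))`` over x=1..x_max.

    Each trapezoid rises with slope 1 from ``x = s``, plateaus at height
    ``h`` and falls back to 0 at ``x = e``; by construction of the window
    counts, ``2h <= e - s + 1`` always holds, so the decomposition into four
    ramps ``relu(x-(s-1)) - relu(x-(s-1+h)) - relu(x-(e-h)) + relu(x-e)``
    is exact.
    """
    s = np.asarray(s, dtype=np.int64)
    h = np.asarray(h, dtype=np.int64)
    e = np.asarray(e, dtype=np.int64)
    w = np.asarray(w, dtype=np.float64)
    a = np.concatenate([s - 1, s - 1 + h, e - h, e])
    ww = np.concatenate([w, -w, -w, w])
    return _ramp_curve(x_max, a, ww)


def _run_cap(q: float, n_markers: int) -> int:
    """Largest run size whose weight ``q**size`` is non-negligible."""
    if q <= 0.0:
        return 0
    return min(n_markers, int(np.ceil(np.log(_NEGLIGIBLE) / np.log(q))))


def _run_trapezoids(ext: np.ndarray, c: int):
    """Trapezoid parameters (span, height, end) for all marker runs of size
    ``c`` on a chromosome.

    ``ext`` is the marker position array with sentinels 0 and length+1
    prepended/appended; the window [m, m+x-1] contains exactly the run
    ``i..i+c-1`` (1-based marker indices) iff
    ``max(pos[i-1]+1, pos[i+c-1]-x+1) <= m <= min(pos[i], pos[i+c]-x)``,
    with m implicitly restricted to [1, length-x+1] by the sentinels.
    """
    k = ext.size - 2
    i = np.arange(1, k - c + 2)
    a = ext[i - 1] + 1
    cc = ext[i]
    b = ext[i + c - 1] + 1
    ee = ext[i + c]
    span = b - cc  # pos[i+c-1] - pos[i] + 1
    h = np.minimum(cc - a, ee - b) + 1
    e = ee - a + 1
    return span, h, e


def _empty_window_curve(ext: np.ndarray, x_max: int) -> np.ndarray:
    """Number of length-x windows containing no marker, for x = 1..x_max."""
    gaps = np.diff(ext) - 1  # free run lengths between consecutive markers
    gs = np.sort(gaps[gaps > 0])
    xs = np.arange(1, x_max + 1)
    idx = np.searchsorted(gs, xs, side="left")
    tail_cnt = gs.size - idx
    csum = np.concatenate([[0.0], np.cumsum(gs + 1.0)])
    tail_sum = csum[-1] - csum[idx]
    return tail_sum - xs * tail_cnt


def _chrom_miss_curve(pos: np.ndarray, length: int, q: float, x_max: int) -> np.ndarray:
    """``sum_m q**n(m, x)`` over all placements on one chromosome, x=1..x_max.

    ``n(m, x)`` is the number of markers in the window starting at m.  This
    is the expected number of *undetected* placements; the per-chromosome
    detection count is ``(length - x + 1) - miss``.
    """
    ext = np.concatenate([[0], pos, [length + 1]]).astype(np.int64)
    g = _empty_window_curve(ext, x_max)
    k = pos.size
    cap = _run_cap(q, k)
    if cap >= 1:
        ss, hh, ee, ww = [], [], [], []
        for c in range(1, cap + 1):
            span, h, e = _run_trapezoids(ext, c)
            ss.append(span)
            hh.append(h)
            ee.append(e)
            ww.append(np.full(span.size, q**c))
        g = g + _trapezoid_curve(
            x_max,
            np.concatenate(ss),
            np.concatenate(hh),
            np.concatenate(ee),
            np.concatenate(ww),
        )
    return g


def _placement_counts(genome: Genome, x_max: int) -> np.ndarray:
    """Total number of valid placements N(x) for x = 1..x_max."""
    if x_max >= genome.min_length:
        raise ValidationError(
            f"x_max={x_max} is not smaller than the shortest chromosome "
            f"({genome.min_length}); the placement convention is undefined there"
        )
    xs = np.arange(1, x_max + 1, dtype=np.float64)
    n = np.zeros(x_max)
    for length in genome.lengths.values():
        n += length - xs + 1
    return n


def detection_function(
    markers: MarkerMap, genome: Genome, p: float | Penetrance, x_max: int
) -> np.ndarray:
    """D(x) for x = 1..x_max (index x-1): the probability that an event of
    length x, placed uniformly and assigned a parent by meiosis weight,
    converts at least one informative marker."""
    p = p.p if isinstance(p, Penetrance) else float(p)
    if not (0.0 < p <= 1.0):
        raise ValidationError(f"penetrance must be in (0, 1], got {p}")
    if x_max < 1:
        raise ValidationError("x_max must be >= 1")
    n_place = _placement_counts(genome, x_max)
    q = 1.0 - p
    total_w = markers.total_meioses
    d = np.zeros(x_max)
    for parent in markers.parents:
        miss = np.zeros(x_max)
        for chrom, length in genome.lengths.items():
            pos = markers.get(parent, chrom)
            miss += _chrom_miss_curve(pos, length, q, x_max)
        d += (markers.meioses[parent] / total_w) * (n_place - miss) / n_place
    return d


def tract_function(
    tract: Tract,
    markers: MarkerMap,
    genome: Genome,
    p: float | Penetrance,
    x_max: int,
) -> np.ndarray:
    """T_t(x) for x = 1..x_max: the probability that an event of length x
    produces exactly the observed tract (right parent, converted set equal to
    the tract, all other overlapped markers unconverted)."""
    p = p.p if isinstance(p, Penetrance) else float(p)
    if not (0.0 < p <= 1.0):
        raise ValidationError(f"penetrance must be in (0, 1], got {p}")
    n_place = _placement_counts(genome, x_max)
    return _tract_numerator(tract, markers, genome, p, x_max) / n_place


def _tract_trapezoids(
    tract: Tract, markers: MarkerMap, genome: Genome, p: float,
    ext: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Trapezoid parameters (span, height, end, weight) whose sum is the
    unnormalised tract function.  The parameter set fully determines
    T_t(x) for *every* x, so it doubles as a grouping key for tracts with
    identical tract functions."""
    pos = markers.get(tract.parent_id, tract.chrom)
    length = genome.lengths[tract.chrom]
    if ext is None:
        ext = np.concatenate(
            [[0], pos, [length + 1]]).astype(np.int64)
    idx = np.searchsorted(pos, tract.positions)
    q = 1.0 - p
    k = tract.n_converted
    i0, j0 = int(idx[0]), int(idx[-1])  # 0-based marker indices
    run_size = j0 - i0 + 1
    base_miss = run_size - k  # unconverted markers between the outermost converted
    parent_w = markers.meioses[tract.parent_id] / markers.total_meioses
    base = parent_w * p**k * q**base_miss if base_miss else parent_w * p**k
    empty = (np.empty(0, np.int64),) * 3 + (np.empty(0),)
    if base <= 0.0:
        return empty
    ext_cap = _run_cap(q, pos.size) if q > 0 else 0
    li = np.arange(max(0, i0 - ext_cap), i0 + 1)  # run start marker index
    rj = np.arange(j0, min(pos.size - 1, j0 + ext_cap) + 1)
    # grid of runs i..j containing the tract's marker run
    ii, jj = np.meshgrid(li, rj, indexing="ij")
    ii = ii.ravel()
    jj = jj.ravel()
    extra = (i0 - ii) + (jj - j0)
    w = base * q**extra
    # 1-based run indices into ext
    a = ext[ii] + 1  # pos[i-1] + 1 with sentinel
    cc = ext[ii + 1]  # pos[i]
    b = ext[jj + 1] + 1  # pos[j] + 1
    ee = ext[jj + 2]  # pos[j+1] with sentinel
    span = b - cc
    h = np.minimum(cc - a, ee - b) + 1
    e = ee - a + 1
    return span, h, e, w


def _tract_numerator(
    tract: Tract, markers: MarkerMap, genome: Genome, p: float, x_max: int
) -> np.ndarray:
    """Unnormalised T_t: sum over placements of the event-outcome probability,
    including the parent-choice weight, before dividing by N(x)."""
    span, h, e, w = _tract_trapezoids(tract, markers, genome, p)
    return _trapezoid_curve(x_max, span, h, e, w)


def _tract_row_key(tract: Tract, markers: MarkerMap, genome: Genome, p: float) -> bytes:
    span, h, e, w = _tract_trapezoids(tract, markers, genome, p)
    return b"".join(np.ascontiguousarray(a).tobytes() for a in (span, h, e, w))


# ---------------------------------------------------------------------------
# kernel table


@dataclass
class KernelTable:
    """Tabulated D(x) and per-tract T_t(x) over event lengths x = 1..x_max.

    Rows of ``T`` follow ``tract_ids``.  The table can be extended in place
    to a larger ``x_max`` (values at smaller x are unchanged by extension,
    since D(x) and T_t(x) are defined per length).
    """

    x_max: int
    D: np.ndarray
    T: np.ndarray
    tract_ids: list[str]
    p: float
    _markers: MarkerMap = field(repr=False)
    _genome: Genome = field(repr=False)
    _tracts: list[Tract] = field(repr=False)
    # grouping keys: tracts with equal keys have identical T rows at every x
    row_keys: list[bytes] = field(default_factory=list, repr=False)

    @classmethod
    def compute(
        cls,
        tracts: list[Tract],
        markers: MarkerMap,
        genome: Genome,
        p: float | Penetrance,
        x_max: int,
    ) -> "KernelTable":
        p = p.p if isinstance(p, Penetrance) else float(p)
        d = detection_function(markers, genome, p, x_max)
        n_place = _placement_counts(genome, x_max)
        t = np.empty((len(tracts), x_max))
        keys = []
        ext_cache: dict[tuple[str, str], np.ndarray] = {}
        for row, tr in enumerate(tracts):
            ck = (tr.parent_id, tr.chrom)
            if ck not in ext_cache:
                pos = markers.get(tr.parent_id, tr.chrom)
                ext_cache[ck] = np.concatenate(
                    [[0], pos, [genome.lengths[tr.chrom] + 1]]).astype(np.int64)
            span, h, e, w = _tract_trapezoids(tr, markers, genome, p, ext_cache[ck])
            t[row] = _trapezoid_curve(x_max, span, h, e, w) / n_place
            keys.append(b"".join(np.ascontiguousarray(a).tobytes()
                                 for a in (span, h, e, w)))
        return cls(x_max, d, t, [tr.tract_id for tr in tracts], p,
                   markers, genome, tracts, keys)

    @classmethod
    def from_dataset(cls, ds: Dataset, p: float | Penetrance, x_max: int) -> "KernelTable":
        return cls.compute(ds.tracts, ds.markers, ds.genome, p, x_max)

    @property
    def n_tracts(self) -> int:
        return len(self.tract_ids)

    def ensure(self, x_max: int) -> None:
        """Grow the table so that it covers lengths up to ``x_max``."""
        if x_max <= self.x_max:
            return
        if x_max >= self._genome.min_length:
            raise ValidationError(
                f"requested x_max={x_max} reaches the shortest chromosome "
                f"({self._genome.min_length}); lengths that large have no "
                "placement distribution"
            )
        logger.info("extending kernel table from x_max=%d to %d", self.x_max, x_max)
        new = KernelTable.compute(self._tracts, self._markers, self._genome, self.p, x_max)
        self.x_max = new.x_max
        self.D = new.D
        self.T = new.T
        self.row_keys = new.row_keys

    # -- cache file -------------------------------------------------------

    def write(self, path) -> None:
        """Write the table as TSV: columns x, D, then one column per tract."""
        import pandas as pd

        df = pd.DataFrame({"x": np.arange(1, self.x_max + 1), "D": self.D})
        for i, tid in enumerate(self.tract_ids):
            df[tid] = self.T[i]
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def read(cls, path, tracts, markers, genome, p) -> "KernelTable":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        tract_ids = [c for c in df.columns if c not in ("x", "D")]
        t = df[tract_ids].to_numpy().T.copy()
        p = p.p if isinstance(p, Penetrance) else float(p)
        keys = [_tract_row_key(tr, markers, genome, p) for tr in tracts]
        return cls(len(df), df["D"].to_numpy(), t, tract_ids, p,
                   markers, genome, tracts, keys)
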