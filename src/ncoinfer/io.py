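"""Domain types and TSV input/output.

The package works with three plain-text tables, all tab-delimited with a
header row (UTF-8):

``genome``
    columns ``chrom``, ``length`` — one row per chromosome, length in bp.
``markers``
    columns ``parent_id``, ``chrom``, ``pos`` (1-based), optionally
    ``meioses`` (constant per parent; number of transmissions observed).
``tracts``
    columns ``tract_id``, ``parent_id``, ``chrom``, ``positions`` —
    converted marker positions, comma-separated without spaces.

Coordinates are 1-based and intervals inclusive: an event of length ``L``
starting at ``M`` covers ``[M, M + L - 1]``.  Every converted position of a
tract must be an informative marker of the transmitting parent on that
chromosome (the model only sees conversions at heterozygous sites).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Genome",
    "MarkerMap",
    "Tract",
    "Dataset",
    "ParseError",
    "ValidationError",
    "read_genome",
    "write_genome",
    "read_markers",
    "write_markers",
    "read_tracts",
    "write_tracts",
]


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed input violates a model invariant."""


@dataclass(frozen=True)
class Genome:
    """Chromosome name -> length in bp (positive integers, unique names)."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, length in self.lengths.items():
            if int(length) < 1:
                raise ValidationError(f"chromosome {chrom!r} has non-positive length {length}")
        object.__setattr__(
            self, "lengths", {str(c): int(l) for c, l in self.lengths.items()}
        )

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    @property
    def min_length(self) -> int:
        return min(self.lengths.values())

    def n_placements(self, x: int) -> int:
        """Number of start positions for an event of length ``x`` that fits
        entirely inside one chromosome, summed over chromosomes."""
        if x < 1 or x > self.min_length:
            raise ValidationError(f"event length {x} outside [1, {self.min_length}]")
        return sum(l - x + 1 for l in self.lengths.values())


@dataclass
class MarkerMap:
    """Informative (heterozygous, QC-passing) markers of each transmitting parent.

    ``positions[parent][chrom]`` is a strictly increasing int64 array of
    1-based positions.  ``meioses[parent]`` is the number of transmissions
    observed for that parent (defaults to 1); it weights the parent's
    contribution to pooled detection probabilities and normalises event
    counts per meiosis.
    """

    positions: dict[str, dict[str, np.ndarray]]
    meioses: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, dict[str, np.ndarray]] = {}
        for parent, by_chrom in self.positions.items():
            clean[parent] = {}
            for chrom, pos in by_chrom.items():
                arr = np.asarray(pos, dtype=np.int64)
                arr = np.sort(arr)
                if arr.size and np.any(np.diff(arr) == 0):
                    raise ValidationError(
                        f"duplicate marker positions for parent {parent!r} on {chrom!r}"
                    )
                clean[parent][chrom] = arr
        self.positions = clean
        for parent in self.positions:
            self.meioses.setdefault(parent, 1)

    @property
    def parents(self) -> list[str]:
        return list(self.positions)

    @property
    def total_meioses(self) -> int:
        return sum(self.meioses[p] for p in self.positions)

    def get(self, parent: str, chrom: str) -> np.ndarray:
        return self.positions.get(parent, {}).get(chrom, np.empty(0, dtype=np.int64))

    def validate_against(self, genome: Genome) -> None:
        for parent, by_chrom in self.positions.items():
            for chrom, pos in by_chrom.items():
                if chrom not in genome.lengths:
                    raise ValidationError(
                        f"parent {parent!r}: unknown chromosome {chrom!r}"
                    )
                if pos.size and (pos[0] < 1 or pos[-1] > genome.lengths[chrom]):
                    raise ValidationError(
                        f"parent {parent!r}: marker position outside [1, "
                        f"{genome.lengths[chrom]}] on {chrom!r}"
                    )


@dataclass(frozen=True)
class Tract:
    """One gene-conversion tract: the set of converted markers produced by a
    single NCO event in one parent-offspring transmission."""

    tract_id: str
    parent_id: str
    chrom: str
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.positions) == 0:
            raise ValidationError(f"tract {self.tract_id!r} has no converted markers")
        pos = tuple(sorted(int(p) for p in self.positions))
        if len(set(pos)) != len(pos):
            raise ValidationError(f"tract {self.tract_id!r} has duplicate positions")
        object.__setattr__(self, "positions", pos)

    @property
    def span(self) -> int:
        """Distance covered by the converted markers, inclusive (>= 1)."""
        return self.positions[-1] - self.positions[0] + 1

    @property
    def n_converted(self) -> int:
        return len(self.positions)

    def validate_against(self, markers: MarkerMap) -> None:
        pos = markers.get(self.parent_id, self.chrom)
        idx = np.searchsorted(pos, self.positions)
        ok = bool(np.all(idx < pos.size)) and np.array_equal(
            pos[np.minimum(idx, pos.size - 1)], np.asarray(self.positions)
        )
        if not ok:
            raise ValidationError(
                f"tract {self.tract_id!r}: converted position not in the "
                f"informative-marker map of parent {self.parent_id!r} on {self.chrom!r}"
            )


@dataclass
class Dataset:
    """A genome, the informative markers of the transmitting parents, and the
    observed gene-conversion tracts."""

    genome: Genome
    markers: MarkerMap
    tracts: list[Tract]
    n_meioses: int | None = None

    def __post_init__(self) -> None:
        if self.n_meioses is None:
            self.n_meioses = self.markers.total_meioses
        if self.n_meioses < 1:
            raise ValidationError("n_meioses must be >= 1")
        ids = [t.tract_id for t in self.tracts]
        if len(set(ids)) != len(ids):
            raise ValidationError("tract ids are not unique")
        self.markers.validate_against(self.genome)
        for t in self.tracts:
            if t.parent_id not in self.markers.positions:
                raise ValidationError(
                    f"tract {t.tract_id!r}: unknown parent {t.parent_id!r}"
                )
            t.validate_against(self.markers)


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path, columns: list[str], optional: list[str] | None = None) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=columns)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def _to_int(df: pd.DataFrame, col: str, path) -> np.ndarray:
    raw = df[col].to_numpy()
    try:
        return raw.astype(np.int64)
    except (ValueError, TypeError):
        for i, v in enumerate(raw):
            try:
                int(v)
            except (ValueError, TypeError):
                # +2: one for the header row, one for 1-based numbering
                raise ParseError(
                    f"{path}: line {i + 2}: cannot parse {col}={v!r} as an integer"
                ) from None
        raise


def read_genome(path) -> Genome:
    """Read a chromosome-length table (columns ``chrom``, ``length``)."""
    df = _read_table(path, ["chrom", "length"])
    lengths = _to_int(df, "length", path)
    chroms = df["chrom"].tolist()
    if len(set(chroms)) != len(chroms):
        dup = sorted({c for c in chroms if chroms.count(c) > 1})
        raise ValidationError(f"{path}: duplicated chromosome row(s) {dup}")
    return Genome(dict(zip(chroms, lengths.tolist())))


def write_genome(genome: Genome, path) -> None:
    pd.DataFrame(
        {"chrom": list(genome.lengths), "length": list(genome.lengths.values())}
    ).to_csv(path, sep="\t", index=False)


def read_markers(path, genome: Genome) -> MarkerMap:
    """Read a marker table (``parent_id``, ``chrom``, ``pos``[, ``meioses``])."""
    df = _read_table(path, ["parent_id", "chrom", "pos"])
    if df.empty:
        logger.warning("%s: no informative markers found (empty file)", path)
        return MarkerMap({})
    pos = _to_int(df, "pos", path)
    positions: dict[str, dict[str, np.ndarray]] = {}
    meioses: dict[str, int] = {}
    if "meioses" in df.columns:
        mei = _to_int(df, "meioses", path)
    else:
        mei = np.ones(len(df), dtype=np.int64)
    for (parent, chrom), idx in df.groupby(["parent_id", "chrom"]).indices.items():
        positions.setdefault(parent, {})[chrom] = pos[idx]
        m = np.unique(mei[idx])
        if m.size > 1:
            raise ValidationError(
                f"{path}: parent {parent!r} has inconsistent meioses values"
            )
        prev = meioses.setdefault(parent, int(m[0]))
        if prev != int(m[0]):
            raise ValidationError(
                f"{path}: parent {parent!r} has inconsistent meioses values"
            )
    mm = MarkerMap(positions, meioses)
    mm.validate_against(genome)
    return mm


def write_markers(markers: MarkerMap, path) -> None:
    rows = []
    for parent, by_chrom in markers.positions.items():
        for chrom, pos in by_chrom.items():
            for p in pos.tolist():
                rows.append((parent, chrom, p, markers.meioses[parent]))
    pd.DataFrame(rows, columns=["parent_id", "chrom", "pos", "meioses"]).to_csv(
        path, sep="\t", index=False
    )


def read_tracts(path, markers: MarkerMap) -> list[Tract]:
    """Read a tract table (``tract_id``, ``parent_id``, ``chrom``, ``positions``)."""
    df = _read_table(path, ["tract_id", "parent_id", "chrom", "positions"])
    tracts: list[Tract] = []
    for i, row in enumerate(df.itertuples(index=False)):
        raw = str(row.positions).strip()
        if not raw:
            raise ValidationError(
                f"{path}: line {i + 2}: tract {row.tract_id!r} has no converted "
                "markers (a tract is a non-empty set)"
            )
        try:
            pos = tuple(int(v) for v in raw.split(","))
        except ValueError:
            raise ParseError(
                f"{path}: line {i + 2}: cannot parse positions {raw!r}"
            ) from None
        t = Tract(str(row.tract_id), str(row.parent_id), str(row.chrom), pos)
        t.validate_against(markers)
        tracts.append(t)
    ids = [t.tract_id for t in tracts]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: tract ids are not unique")
    return tracts


def write_tracts(tracts: list[Tract], path) -> None:
    pd.DataFrame(
        [
            (t.tract_id, t.parent_id, t.chrom, ",".join(str(p) for p in t.positions))
            for t in tracts
        ],
        columns=["tract_id", "parent_id", "chrom", "positions"],
    ).to_csv(path, sep="\t", index=False)
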