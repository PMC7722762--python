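"""Genome coordinates, interval sets and exact interval algebra.

All coordinates are 0-based half-open (BED convention) everywhere, including
internal bin indices: bin ``i`` of size ``b`` covers ``[i*b, (i+1)*b)`` and
the final partial bin of each chromosome is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Genome",
    "Interval",
    "IntervalSet",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
]


@dataclass(frozen=True)
class Genome:
    """Ordered chromosome names with lengths; defines binning grids and bounds."""

    chroms: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chroms) != len(set(self.chroms)):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")
        if len(self.chroms) != len(self.lengths):
            raise ValueError("chroms and lengths differ in length")

    @classmethod
    def from_dict(cls, sizes: Mapping[str, int]) -> "Genome":
        return cls(tuple(sizes.keys()), tuple(int(v) for v in sizes.values()))

    def __len__(self) -> int:
        return len(self.chroms)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._index

    @property
    def _index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.chroms)}

    def length(self, chrom: str) -> int:
        return self.lengths[self._index[chrom]]

    @property
    def total_bp(self) -> int:
        return int(sum(self.lengths))

    def items(self) -> Iterator[tuple[str, int]]:
        return iter(zip(self.chroms, self.lengths))

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return -(-self.length(chrom) // bin_size)


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


class IntervalSet:
    """Sorted genomic intervals (0-based, half-open) with optional labels/scores.

    The currency of domains, LADs, chromatin states and blacklists. Sorted by
    (chrom, start, end) on construction; a *flat* set additionally has no
    overlaps within a chromosome (the output of :meth:`merge`).
    """

    def __init__(self, intervals: Iterable[Interval] = (), genome: Genome | None = None):
        ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        if genome is not None:
            for iv in ivs:
                if iv.chrom not in genome:
                    raise ValueError(f"unknown chromosome {iv.chrom!r}")
                if iv.end > genome.length(iv.chrom):
                    raise ValueError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                        f"chromosome length {genome.length(iv.chrom)}"
                    )
        self._ivs: list[Interval] = ivs
        self._flat_cache: dict[str, np.ndarray] | None = None

    @classmethod
    def from_tuples(
        cls, tuples: Iterable[tuple], genome: Genome | None = None
    ) -> "IntervalSet":
        """Build from (chrom, start, end[, name[, score]]) tuples."""
        return cls((Interval(*t) for t in tuples), genome=genome)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self._ivs)

    def __len__(self) -> int:
        return len(self._ivs)

    def __getitem__(self, i) -> Interval:
        return self._ivs[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return [(i.chrom, i.start, i.end, i.name, i.score) for i in self] == [
            (i.chrom, i.start, i.end, i.name, i.score) for i in other
        ]

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)}, bp={self.total_bp()})"

    @property
    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self._ivs:
            seen.setdefault(iv.chrom)
        return list(seen)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Per-chromosome (n, 2) arrays of [start, end), in sorted order."""
        out: dict[str, list[list[int]]] = {}
        for iv in self._ivs:
            out.setdefault(iv.chrom, []).append([iv.start, iv.end])
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}

    # ---- algebra ------------------------------------------------------

    def merge(self) -> "IntervalSet":
        """Flatten: the minimal sorted non-overlapping cover of the union.

        Book-ended intervals ([0,10) + [10,20)) are joined, matching the
        behaviour of ``bedtools merge``.
        """
        merged: list[Interval] = []
        for chrom, arr in self.by_chrom().items():
            cur_s, cur_e = arr[0]
            for s, e in arr[1:]:
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    merged.append(Interval(chrom, int(cur_s), int(cur_e)))
                    cur_s, cur_e = s, e
            merged.append(Interval(chrom, int(cur_s), int(cur_e)))
        return IntervalSet(merged)

    def total_bp(self) -> int:
        return int(sum(iv.length for iv in self.merge()))

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Base-pair-exact intersection (both sides flattened first)."""
        a, b = self.merge().by_chrom(), other.merge().by_chrom()
        out: list[Interval] = []
        for chrom in a.keys() & b.keys():
            ia = ib = 0
            aa, bb = a[chrom], b[chrom]
            while ia < len(aa) and ib < len(bb):
                s = max(aa[ia, 0], bb[ib, 0])
                e = min(aa[ia, 1], bb[ib, 1])
                if s < e:
                    out.append(Interval(chrom, int(s), int(e)))
                if aa[ia, 1] <= bb[ib, 1]:
                    ia += 1
                else:
                    ib += 1
        return IntervalSet(out)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Base pairs of self not covered by other (both flattened)."""
        a, b = self.merge().by_chrom(), other.merge().by_chrom()
        out: list[Interval] = []
        for chrom, aa in a.items():
            bb = b.get(chrom)
            if bb is None:
                out.extend(Interval(chrom, int(s), int(e)) for s, e in aa)
                continue
            for s, e in aa:
                cur = s
                for bs, be in bb:
                    if be <= cur or bs >= e:
                        continue
                    if bs > cur:
                        out.append(Interval(chrom, int(cur), int(bs)))
                    cur = max(cur, be)
                    if cur >= e:
                        break
                if cur < e:
                    out.append(Interval(chrom, int(cur), int(e)))
        return IntervalSet(out)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(list(self) + list(other)).merge()

    def complement(self, genome: Genome) -> "IntervalSet":
        """Genome minus self, as a flat set."""
        whole = IntervalSet(
            Interval(c, 0, l) for c, l in genome.items()
        )
        return whole.subtract(self)

    def _flat_by_chrom(self) -> dict[str, np.ndarray]:
        # lazily cached merged view (IntervalSet is treated as immutable)
        if self._flat_cache is None:
            self._flat_cache = self.merge().by_chrom()
        return self._flat_cache

    def overlap_bp(self, chrom: str, start: int, end: int) -> int:
        """Total bp of [start, end) covered by this (flattened) set."""
        arr = self._flat_by_chrom().get(chrom)
        if arr is None or not len(arr):
            return 0
        # only intervals that can reach [start, end)
        lo = int(np.searchsorted(arr[:, 1], start, side="right"))
        hi = int(np.searchsorted(arr[:, 0], end, side="left"))
        if lo >= hi:
            return 0
        s = np.maximum(arr[lo:hi, 0], start)
        e = np.minimum(arr[lo:hi, 1], end)
        return int(np.clip(e - s, 0, None).sum())


# ---- file formats -----------------------------------------------------


def read_bed(path, genome: Genome | None = None) -> IntervalSet:
    """Read BED3/BED6 into a sorted IntervalSet.

    Coordinates are 0-based half-open. Malformed lines are rejected with the
    offending line number; when a genome is supplied, chromosome names and
    bounds are validated too.
    """
    ivs: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as err:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from err
            if start >= end:
                raise ValueError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                score = float(fields[4])
            try:
                ivs.append(Interval(chrom, start, end, name, score))
            except ValueError as err:
                raise ValueError(f"{path}: line {lineno}: {err}") from err
    try:
        return IntervalSet(ivs, genome=genome)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def write_bed(intervals: IntervalSet, path) -> None:
    """Write BED3 or BED6 (6 columns whenever any name/score is present)."""
    six = any(iv.name is not None or iv.score is not None for iv in intervals)
    with open(path, "w") as fh:
        for iv in intervals:
            if six:
                score = "." if iv.score is None else format(iv.score, "g")
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t.\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_chrom_sizes(path) -> Genome:
    """Read a UCSC-style chrom.sizes file (name<TAB>length per line)."""
    chroms: list[str] = []
    lengths: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            name, length = fields[0], int(fields[1])
            if name in chroms:
                raise ValueError(f"{path}: line {lineno}: duplicate chromosome {name!r}")
            if length <= 0:
                raise ValueError(f"{path}: line {lineno}: non-positive length")
            chroms.append(name)
            lengths.append(length)
    if not chroms:
        warnings.warn(f"{path}: empty chrom.sizes file", stacklevel=2)
    return Genome(tuple(chroms), tuple(lengths))


def write_chrom_sizes(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.items():
            fh.write(f"{chrom}\t{length}\n")
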