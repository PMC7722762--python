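"""Binned coverage tracks, log-ratio tracks and smoothed differential signal.

Reads are aligned-fragment midpoints, carried as a pandas DataFrame with
columns ``chrom`` (str) and ``midpoint`` (int). Coverage is counted on a
fixed bin grid per chromosome (final partial bin kept); the differential
signal is a Gaussian-kernel density difference between two read sets,
evaluated on a regular grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .genome import Genome

__all__ = [
    "READ_COLUMNS",
    "as_read_frame",
    "BinnedTrack",
    "SignalTrack",
    "bin_and_normalize",
    "log_ratio_track",
    "smoothed_difference",
    "downsample_reads",
    "read_bedgraph",
    "write_bedgraph",
]

READ_COLUMNS = ("chrom", "midpoint")


def as_read_frame(reads) -> pd.DataFrame:
    """Coerce reads (DataFrame or iterable of (chrom, midpoint)) to a frame."""
    if isinstance(reads, pd.DataFrame):
        return reads
    rows = [(r[0], int(r[1])) for r in reads]
    return pd.DataFrame(rows, columns=list(READ_COLUMNS))


@dataclass
class BinnedTrack:
    """Per-chromosome real values on a fixed bin grid.

    ``data[chrom][i]`` is the value of bin ``[i*bin_size, (i+1)*bin_size)``.
    """

    genome: Genome
    bin_size: int
    data: dict[str, np.ndarray]
    library_size: int | None = None
    normalization: str = "none"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, arr in self.data.items():
            expect = self.genome.n_bins(chrom, self.bin_size)
            if len(arr) != expect:
                raise ValueError(
                    f"{chrom}: {len(arr)} bins, expected {expect} "
                    f"(length {self.genome.length(chrom)}, bin {self.bin_size})"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{chrom}: non-finite track values")

    @property
    def n_bins(self) -> int:
        return int(sum(len(a) for a in self.data.values()))

    def values(self) -> np.ndarray:
        """All bin values concatenated in genome chromosome order."""
        return np.concatenate([self.data[c] for c in self.genome.chroms if c in self.data])

    def same_grid(self, other: "BinnedTrack") -> bool:
        return (
            self.genome == other.genome
            and self.bin_size == other.bin_size
            and set(self.data) == set(other.data)
        )


@dataclass
class SignalTrack:
    """Real-valued signal sampled at regular grid points per chromosome.

    Grid point ``j`` of chromosome ``c`` sits at position ``j * step``.
    """

    genome: Genome
    step: int
    data: dict[str, np.ndarray]
    bandwidth: float = 0.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.bandwidth < 0:
            raise ValueError("bandwidth must be non-negative")

    def values(self) -> np.ndarray:
        return np.concatenate([self.data[c] for c in self.genome.chroms if c in self.data])


def bin_and_normalize(
    reads, genome: Genome, bin_size: int, normalize: str = "none"
) -> BinnedTrack:
    """Count read midpoints in fixed-size bins, optionally CPM-normalized.

    Parameters
    ----------
    reads : read frame or iterable of (chrom, midpoint)
    normalize : {"none", "cpm"}
        ``cpm`` rescales so the track sums to 1e6 (counts per million).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if normalize not in ("none", "cpm"):
        raise ValueError(f"unknown normalization {normalize!r}")
    frame = as_read_frame(reads)
    data = {
        chrom: np.zeros(genome.n_bins(chrom, bin_size), dtype=float)
        for chrom in genome.chroms
    }
    total = 0
    if len(frame):
        for chrom, grp in frame.groupby("chrom", sort=False):
            if chrom not in genome:
                raise ValueError(f"read on unknown chromosome {chrom!r}")
            mids = grp["midpoint"].to_numpy()
            if mids.min() < 0 or mids.max() >= genome.length(chrom):
                bad = mids[(mids < 0) | (mids >= genome.length(chrom))][0]
                raise ValueError(
                    f"read midpoint {bad} outside {chrom} "
                    f"(length {genome.length(chrom)})"
                )
            counts = np.bincount(mids // bin_size, minlength=len(data[chrom]))
            data[chrom] += counts
            total += len(mids)
    if normalize == "cpm":
        if total == 0:
            warnings.warn("CPM normalization of empty read set; returning zeros",
                          stacklevel=2)
        else:
            for chrom in data:
                data[chrom] *= 1e6 / total
    return BinnedTrack(genome, bin_size, data, library_size=total,
                       normalization=normalize)


def log_ratio_track(
    target: BinnedTrack, reference: BinnedTrack, pseudocount: float = 0.5
) -> BinnedTrack:
    """Library-normalized per-bin log2 ratio of target over reference.

    value_i = log2( ((t_i + c) / T_eff) / ((r_i + c) / R_eff) ) with effective
    library sizes T_eff = library + c * n_bins (likewise R_eff), so the track
    is finite everywhere and invariant under a global rescaling of either
    library. The pseudocount ``c`` defaults to 0.5 reads per bin and is
    recorded in the output metadata.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if not target.same_grid(reference):
        raise ValueError("target and reference are on different grids")
    if target.normalization != "none" or reference.normalization != "none":
        raise ValueError("log_ratio_track expects raw-count tracks")
    n_bins = target.n_bins
    t_eff = (target.library_size or 0) + pseudocount * n_bins
    r_eff = (reference.library_size or 0) + pseudocount * n_bins
    data = {}
    for chrom in target.data:
        t = target.data[chrom] + pseudocount
        r = reference.data[chrom] + pseudocount
        data[chrom] = np.log2((t / t_eff) / (r / r_eff))
    out = BinnedTrack(target.genome, target.bin_size, data,
                      library_size=target.library_size, normalization="log2ratio")
    out.meta["pseudocount"] = pseudocount
    out.meta["reference_library_size"] = reference.library_size
    return out


def smoothed_difference(
    reads_a,
    reads_b,
    genome: Genome,
    bandwidth: float = 150.0,
    step: int = 50,
    scale_by_library: bool = False,
    truncate_sd: float = 8.0,
) -> SignalTrack:
    """Gaussian-kernel smoothed density difference between two read sets.

    At each grid point x, D(x) = sum_a K_h(x - m_a) * s_a
                               - sum_b K_h(x - m_b) * s_b
    with a Gaussian kernel of standard deviation ``bandwidth`` bp and
    per-read scale s = 1/library size when ``scale_by_library`` else 1.
    The kernel is truncated at ``truncate_sd`` standard deviations; within
    that radius the evaluation is exact (per-read, not grid-quantized).
    """
    if bandwidth <= 0 or step <= 0:
        raise ValueError("bandwidth and step must be positive")
    fa, fb = as_read_frame(reads_a), as_read_frame(reads_b)
    if len(fa) == 0 and len(fb) == 0:
        raise ValueError("both read sets are empty")

    def blank():
        return {
            chrom: np.zeros(genome.length(chrom) // step + 1, dtype=float)
            for chrom in genome.chroms
        }

    radius = truncate_sd * bandwidth
    norm = 1.0 / (np.sqrt(2 * np.pi) * bandwidth)

    def accumulate(frame: pd.DataFrame, data: dict) -> None:
        if not len(frame):
            return
        scale = 1.0 / len(frame) if scale_by_library else 1.0
        for chrom, grp in frame.groupby("chrom", sort=False):
            grid = data[chrom]
            mids = grp["midpoint"].to_numpy(dtype=float)
            j_lo = np.ceil((mids - radius) / step).astype(np.int64)
            width = int(2 * radius / step) + 2
            for chunk in range(0, len(mids), 200_000):
                m = mids[chunk:chunk + 200_000]
                lo = np.clip(j_lo[chunk:chunk + 200_000], 0, None)
                idx = lo[:, None] + np.arange(width)[None, :]
                x = idx * float(step)
                w = np.exp(-0.5 * ((x - m[:, None]) / bandwidth) ** 2)
                w[np.abs(x - m[:, None]) > radius] = 0.0
                valid = idx < len(grid)
                np.add.at(grid, idx[valid], scale * norm * w[valid])

    # accumulate each side separately so swapping a and b negates the
    # result bit-exactly
    da, db = blank(), blank()
    accumulate(fa, da)
    accumulate(fb, db)
    data = {chrom: da[chrom] - db[chrom] for chrom in da}
    return SignalTrack(genome, step, data, bandwidth=bandwidth)


def downsample_reads(reads, fraction: float, seed: int) -> pd.DataFrame:
    """Bernoulli thinning: keep each read independently with given probability."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    frame = as_read_frame(reads)
    if fraction == 1.0:
        return frame.copy()
    rng = np.random.default_rng(seed)
    keep = rng.random(len(frame)) < fraction
    return frame[keep].reset_index(drop=True)


# ---- bedGraph ---------------------------------------------------------


def write_bedgraph(track: BinnedTrack, path) -> None:
    """Serialize a binned track as 4-column bedGraph (zero bins skipped)."""
    with open(path, "w") as fh:
        for chrom in track.genome.chroms:
            arr = track.data.get(chrom)
            if arr is None:
                continue
            clen = track.genome.length(chrom)
            for i, v in enumerate(arr):
                if v == 0:
                    continue
                start = i * track.bin_size
                end = min(start + track.bin_size, clen)
                fh.write(f"{chrom}\t{start}\t{end}\t{v:.6g}\n")


def write_bigwig(track: BinnedTrack, path) -> None:
    """Optional bigWig export (requires the pyBigWig backend)."""
    try:
        import pyBigWig
    except ImportError as err:  # pragma: no cover
        raise RuntimeError("bigWig export requires pyBigWig") from err
    bw = pyBigWig.open(str(path), "w")
    header = [(c, l) for c, l in track.genome.items()]
    bw.addHeader(header)
    for chrom, clen in track.genome.items():
        arr = track.data.get(chrom)
        if arr is None:
            continue
        starts = np.arange(len(arr)) * track.bin_size
        ends = np.minimum(starts + track.bin_size, clen)
        bw.addEntries([chrom] * len(arr), [int(s) for s in starts],
                      ends=[int(e) for e in ends],
                      values=[float(v) for v in arr])
    bw.close()


def read_bedgraph(path, genome: Genome, bin_size: int) -> BinnedTrack:
    """Read a non-overlapping bedGraph onto a fixed bin grid.

    Records must be bin-aligned to ``bin_size`` (the writer's convention);
    unseen bins are zero.
    """
    data = {
        chrom: np.zeros(genome.n_bins(chrom, bin_size), dtype=float)
        for chrom in genome.chroms
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split("\t")
            start, value = int(start), float(value)
            if chrom not in genome:
                raise ValueError(f"{path}: line {lineno}: unknown chromosome {chrom!r}")
            if start % bin_size != 0:
                raise ValueError(f"{path}: line {lineno}: record not bin-aligned")
            data[chrom][start // bin_size] = value
    return BinnedTrack(genome, bin_size, data, normalization="file")
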