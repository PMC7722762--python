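"""Average signal metaprofiles around domain borders and TSSs.

Border profiles sample a binned signal in a ±K-bin window around each domain
border; start and end borders are both laid out on the genomic axis, so for
a start border the domain interior lies at positive relative positions and
for an end border at negative ones. TSS profiles orient windows by strand.
The smoothed curve is a cubic smoothing spline with a GCV-chosen penalty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .genome import Genome, IntervalSet
from .tracks import BinnedTrack, SignalTrack

__all__ = ["Metaprofile", "border_profile", "tss_profile", "common_peak_gene_set"]


@dataclass
class Metaprofile:
    positions: np.ndarray  # relative positions in bp (bin centers offsets)
    mean: np.ndarray
    sem: np.ndarray
    n_regions: int
    smoothed: np.ndarray
    lo: np.ndarray
    hi: np.ndarray

    def to_table(self):
        import pandas as pd

        return pd.DataFrame({
            "relative_bp": self.positions, "mean": self.mean, "sem": self.sem,
            "smoothed": self.smoothed, "lo": self.lo, "hi": self.hi,
            "n": self.n_regions,
        })


def _smooth(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Cubic smoothing spline, GCV penalty; falls back to y on failure."""
    ok = np.isfinite(y)
    if ok.sum() < 5:
        return y.copy()
    try:
        spl = make_smoothing_spline(x[ok].astype(float), y[ok])
        out = y.copy()
        out[ok] = spl(x[ok].astype(float))
        return out
    except Exception:  # degenerate inputs (constant y etc.)
        return y.copy()


def _finalize(positions, windows, n_regions) -> Metaprofile:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean = np.nanmean(windows, axis=0)
        counts = np.sum(np.isfinite(windows), axis=0)
        sd = np.nanstd(windows, axis=0, ddof=1)
    sem = np.where(counts > 1, sd / np.sqrt(np.maximum(counts, 1)), 0.0)
    if n_regions == 1:
        warnings.warn("single region: SEM coded as 0", stacklevel=3)
    smoothed = _smooth(positions, mean)
    lo = _smooth(positions, mean - 1.96 * sem)
    hi = _smooth(positions, mean + 1.96 * sem)
    return Metaprofile(positions, mean, sem, n_regions, smoothed, lo, hi)


def _track_bins(signal, chrom: str):
    if isinstance(signal, BinnedTrack):
        return signal.data[chrom], signal.bin_size
    if isinstance(signal, SignalTrack):
        return signal.data[chrom], signal.step
    raise TypeError("signal must be a BinnedTrack or SignalTrack")


def border_profile(
    signal,
    domains: IntervalSet,
    side: str = "start",
    k_bins: int = 50,
    bin_size: int = 10_000,
    exclude_neighbor_overlap: bool = False,
) -> Metaprofile:
    """Mean signal in a ±k_bins window (bin_size bp) around domain borders.

    For a start border, window position j (−K..+K) is centered on the first
    bin inside the domain; for an end border, on the last bin inside (the
    half-open convention makes these the two symmetric choices), so on a
    symmetric signal the start profile equals the reversed end profile
    exactly. Positions beyond chromosome bounds are missing and excluded
    from that position's mean/SEM. With ``exclude_neighbor_overlap``,
    borders whose window touches a *different* domain are dropped.
    """
    if side not in ("start", "end"):
        raise ValueError("side must be 'start' or 'end'")
    if not len(domains):
        raise ValueError("empty domain set")
    offsets = np.arange(-k_bins, k_bins + 1)
    rows = []
    for iv in domains:
        if exclude_neighbor_overlap:
            border = iv.start if side == "start" else iv.end - 1
            w_lo = max(border // bin_size * bin_size - k_bins * bin_size, 0)
            w_hi = (border // bin_size + k_bins + 1) * bin_size
            others = IntervalSet(d for d in domains if d != iv)
            if others.overlap_bp(iv.chrom, w_lo, w_hi) > 0:
                continue
        border = iv.start if side == "start" else iv.end - 1
        arr, res = _track_bins(signal, iv.chrom)
        if res != bin_size:
            raise ValueError(
                f"signal resolution {res} does not match bin_size {bin_size}"
            )
        idx = border // bin_size + offsets
        row = np.full(len(offsets), np.nan)
        ok = (idx >= 0) & (idx < len(arr))
        row[ok] = arr[idx[ok]]
        rows.append(row)
    if not rows:
        raise ValueError("no border windows left after neighbor exclusion")
    windows = np.asarray(rows)
    if not np.isfinite(windows).any():
        raise ValueError("all border windows fall outside chromosome bounds")
    return _finalize(offsets * bin_size, windows, len(rows))


def tss_profile(
    signal,
    tss_list: list[tuple[str, int, str]],
    flank: int = 5000,
    bin: int = 100,
) -> Metaprofile:
    """Strand-oriented mean signal around TSSs (±flank, one value per bin).

    Produces 2 * flank / bin + 1 relative positions; minus-strand windows
    are reversed so position +x is always downstream of the TSS.
    """
    if not tss_list:
        raise ValueError("empty TSS list")
    k = flank // bin
    offsets = np.arange(-k, k + 1)
    rows = []
    for chrom, pos, strand in tss_list:
        arr, res = _track_bins(signal, chrom)
        if res != bin:
            raise ValueError(f"signal resolution {res} does not match bin {bin}")
        idx = pos // bin + offsets
        row = np.full(len(offsets), np.nan)
        ok = (idx >= 0) & (idx < len(arr))
        row[ok] = arr[idx[ok]]
        if strand == "-":
            row = row[::-1]
        rows.append(row)
    return _finalize(offsets * bin, np.asarray(rows), len(rows))


def common_peak_gene_set(
    peak_sets: list[IntervalSet],
    tss_table: list[tuple[str, str, int]],
    window: int = 500,
) -> list[str]:
    """Genes whose TSS ± window overlaps a peak common to ALL peak sets.

    Common regions are the strict intersection across peak sets; a gene is
    selected when [TSS - window, TSS + window) overlaps one by >= 1 bp.
    Returns a deduplicated gene list in input order.
    """
    if not peak_sets:
        raise ValueError("need at least one peak set")
    if not tss_table:
        raise ValueError("empty TSS table")
    common = peak_sets[0].merge()
    for ps in peak_sets[1:]:
        common = common.intersect(ps)
    selected: list[str] = []
    seen: set[str] = set()
    for gene, chrom, pos in tss_table:
        lo = max(pos - window, 0)
        if common.overlap_bp(chrom, lo, pos + window) > 0 and gene not in seen:
            selected.append(gene)
            seen.add(gene)
    return selected
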