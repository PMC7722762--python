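"""Synthetic data with the statistical structure of sequential chromatin
fractionation experiments.

The generator plants megabase-scale closed-chromatin (LAD-like) domains on a
toy genome and emits, per chromatin fraction, aligned-read midpoints drawn
from a genome-wide multinomial whose per-base weight is elevated inside the
planted domains for the condensed fractions (S4, and intermediately S3) and
depressed for the accessible fraction (S2). Around that core it generates
correlated/anti-correlated mark tracks, a Roadmap-style chromatin-state
painting, transcript differential-expression tables with a planted bivalent
signal, and fluorescence nucleus images with peripherally biased foci.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import math
from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregation import TranscriptRecord
from .genome import Genome, Interval, IntervalSet

__all__ = [
    "DomainArchitecture",
    "SimRead",
    "FRACTIONS",
    "STATE_LABELS",
    "make_architecture",
    "simulate_fraction_reads",
    "simulate_mark_track",
    "paint_chromatin_states",
    "simulate_transcript_table",
    "simulate_nuclei",
    "SimulatedNuclei",
]

SimRead = namedtuple("SimRead", ["chrom", "midpoint"])

FRACTIONS = ("S2", "S3", "S4")

#: Roadmap 15-state mnemonics used by the painting (subset relevant here).
STATE_LABELS = (
    "TssBiv", "BivFlnk", "EnhBiv", "ReprPC", "ReprPCWk",
    "Het", "Tx", "TxWk", "ZNF/Rpts", "Quies",
)

BIVALENT_STATES = ("TssBiv", "BivFlnk", "EnhBiv")


@dataclass(frozen=True)
class DomainArchitecture:
    """A genome plus planted compacted (closed-chromatin) domains.

    enrichment_factor is the relative per-base read density of the most
    condensed fraction (S4) inside the planted domains; the accessible
    fraction (S2) uses its reciprocal, so the S4/S2 density contrast inside
    domains is enrichment_factor**2.
    """

    genome: Genome
    closed_domains: IntervalSet
    enrichment_factor: float
    condition_label: str = "control"

    def __post_init__(self) -> None:
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be at least 1")
        if self.condition_label not in ("control", "disrupted"):
            raise ValueError(f"unknown condition {self.condition_label!r}")
        prev: Interval | None = None
        for iv in self.closed_domains:
            if iv.end > self.genome.length(iv.chrom):
                raise ValueError("domain exceeds chromosome bounds")
            if prev is not None and prev.chrom == iv.chrom and iv.start < prev.end:
                raise ValueError("closed domains overlap")
            prev = iv


def _place_disjoint(
    genome: Genome,
    sizes: list[int],
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> IntervalSet:
    """Uniform random non-overlapping placement by rejection, longest first."""
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chroms}
    lengths = np.array(genome.lengths, dtype=float)
    for size in sorted(sizes, reverse=True):
        ok = False
        for _ in range(max_tries):
            ci = rng.choice(len(genome.chroms), p=lengths / lengths.sum())
            chrom = genome.chroms[ci]
            clen = genome.lengths[ci]
            if clen < size:
                continue
            start = int(rng.integers(0, clen - size + 1))
            end = start + size
            if all(end <= s or start >= e for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place a {size}-bp domain without overlap after "
                f"{max_tries} tries: genome too crowded"
            )
    return IntervalSet(
        Interval(c, s, e) for c, ivs in placed.items() for s, e in ivs
    )


def make_architecture(
    chrom_sizes,
    n_domains: int,
    size_range: tuple[int, int],
    enrichment_factor: float = 3.0,
    seed: int = 0,
    condition_label: str = "control",
) -> DomainArchitecture:
    """Plant ``n_domains`` non-overlapping closed domains uniformly at random.

    Domain sizes are drawn uniformly from ``size_range`` (bp). Deterministic
    given the seed; fails loudly when placement is impossible.
    """
    genome = chrom_sizes if isinstance(chrom_sizes, Genome) else Genome.from_dict(chrom_sizes)
    lo, hi = size_range
    if not (0 < lo <= hi):
        raise ValueError("invalid size_range")
    if hi > max(genome.lengths):
        raise ValueError("size_range exceeds the largest chromosome")
    rng = np.random.default_rng(seed)
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(n_domains)]
    domains = _place_disjoint(genome, sizes, rng)
    return DomainArchitecture(genome, domains, enrichment_factor, condition_label)


# ---- fraction reads ---------------------------------------------------


def _cum_lengths(ivs: IntervalSet) -> tuple[list[Interval], np.ndarray]:
    lst = list(ivs)
    lens = np.array([iv.length for iv in lst], dtype=np.int64)
    return lst, np.concatenate([[0], np.cumsum(lens)])


def _uniform_in(ivs: IntervalSet, n: int, rng: np.random.Generator) -> list[tuple[str, int]]:
    """n positions uniform over the base pairs covered by a flat set."""
    if n == 0:
        return []
    lst, cum = _cum_lengths(ivs)
    offsets = rng.integers(0, cum[-1], size=n)
    which = np.searchsorted(cum, offsets, side="right") - 1
    return [
        (lst[w].chrom, int(lst[w].start + offsets[i] - cum[w]))
        for i, w in enumerate(which)
    ]


def fraction_weight(fraction: str, enrichment_factor: float,
                    s3_factor: float | None = None) -> float:
    """In-domain per-base weight multiplier for a fraction (out-of-domain = 1)."""
    if fraction == "S4":
        return enrichment_factor
    if fraction == "S3":
        return s3_factor if s3_factor is not None else math.sqrt(enrichment_factor)
    if fraction == "S2":
        return 1.0 / enrichment_factor
    raise ValueError(f"unknown fraction {fraction!r}: expected one of {FRACTIONS}")


def simulate_fraction_reads(
    arch: DomainArchitecture,
    fraction: str,
    n_reads: int,
    seed: int,
    s3_factor: float | None = None,
    disruption_rho: float = 0.5,
) -> pd.DataFrame:
    """Draw read midpoints from the fraction's genome-wide multinomial.

    Per-base weight is the fraction's in-domain multiplier inside the planted
    domains and 1 elsewhere. Under the "disrupted" condition each read's
    domain bias is, with probability ``disruption_rho``, taken from a
    uniformly random re-placement of the domains instead, flattening the
    planted contrast. Returns a read frame (columns chrom, midpoint).
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    w = fraction_weight(fraction, arch.enrichment_factor, s3_factor)
    rng = np.random.default_rng(seed)
    genome = arch.genome
    true_dom = arch.closed_domains.merge()

    if arch.condition_label == "disrupted" and disruption_rho > 0:
        alt_rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
        sizes = [iv.length for iv in true_dom]
        alt_dom = _place_disjoint(genome, sizes, alt_rng)
        rho = disruption_rho
        strata = [
            (true_dom.intersect(alt_dom), w),
            (true_dom.subtract(alt_dom), (1 - rho) * w + rho),
            (alt_dom.subtract(true_dom), (1 - rho) + rho * w),
            (true_dom.union(alt_dom).complement(genome), 1.0),
        ]
    else:
        strata = [
            (true_dom, w),
            (true_dom.complement(genome), 1.0),
        ]

    weights = np.array([wt * s.total_bp() for s, wt in strata], dtype=float)
    counts = rng.multinomial(n_reads, weights / weights.sum())
    rows: list[tuple[str, int]] = []
    for (s, _), k in zip(strata, counts):
        rows.extend(_uniform_in(s, int(k), rng))
    frame = pd.DataFrame(rows, columns=["chrom", "midpoint"])
    return frame.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)


# ---- mark tracks ------------------------------------------------------


def _bin_domain_fraction(arch: DomainArchitecture, bin_size: int) -> dict[str, np.ndarray]:
    """Per-bin fraction of base pairs inside closed domains."""
    out = {}
    dom = arch.closed_domains.merge().by_chrom()
    for chrom, clen in arch.genome.items():
        n = arch.genome.n_bins(chrom, bin_size)
        frac = np.zeros(n)
        for s, e in dom.get(chrom, np.empty((0, 2), dtype=np.int64)):
            b0, b1 = int(s // bin_size), int((e - 1) // bin_size)
            for b in range(b0, b1 + 1):
                lo, hi = b * bin_size, min((b + 1) * bin_size, clen)
                frac[b] += (min(e, hi) - max(s, lo)) / (hi - lo)
        out[chrom] = frac
    return out


def simulate_mark_track(
    arch: DomainArchitecture,
    polarity: int,
    noise_sd: float,
    bin_size: int,
    seed: int,
):
    """Synthetic reference mark track: ±1 square wave over domains plus noise.

    polarity +1 emulates lamina/heterochromatin marks (high inside closed
    domains); −1 emulates open-chromatin/active marks. A bin counts as inside
    when ≥ half its base pairs overlap a domain.
    """
    from .tracks import BinnedTrack

    if polarity not in (+1, -1):
        raise ValueError("polarity must be +1 or -1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rng = np.random.default_rng(seed)
    frac = _bin_domain_fraction(arch, bin_size)
    data = {}
    for chrom, f in frac.items():
        base = np.where(f >= 0.5, 1.0, -1.0) * polarity
        data[chrom] = base + (rng.normal(0, noise_sd, size=len(f)) if noise_sd else 0.0)
    return BinnedTrack(arch.genome, bin_size, data, normalization="synthetic-mark")


# ---- chromatin state painting -----------------------------------------

_INSIDE_STATE_P = {
    "Het": 0.42, "Quies": 0.30, "ReprPC": 0.08, "ReprPCWk": 0.07,
    "TssBiv": 0.05, "BivFlnk": 0.02, "EnhBiv": 0.02, "ZNF/Rpts": 0.02,
    "Tx": 0.01, "TxWk": 0.01,
}
_OUTSIDE_STATE_P = {
    "Tx": 0.30, "TxWk": 0.28, "Quies": 0.28, "TssBiv": 0.03,
    "BivFlnk": 0.01, "EnhBiv": 0.01, "ReprPC": 0.03, "ReprPCWk": 0.03,
    "Het": 0.02, "ZNF/Rpts": 0.01,
}


def _chunk_and_label(
    region: Interval,
    probs: dict[str, float],
    rng: np.random.Generator,
    chunk_range: tuple[int, int],
) -> list[Interval]:
    labels = list(probs)
    p = np.array([probs[s] for s in labels])
    p = p / p.sum()
    out = []
    pos = region.start
    while pos < region.end:
        size = int(rng.integers(chunk_range[0], chunk_range[1] + 1))
        end = min(pos + size, region.end)
        state = labels[rng.choice(len(labels), p=p)]
        out.append(Interval(region.chrom, pos, end, name=state))
        pos = end
    return out


def paint_chromatin_states(
    arch: DomainArchitecture,
    seed: int,
    chunk_range: tuple[int, int] = (50_000, 200_000),
) -> IntervalSet:
    """Partition the genome into labelled chromatin-state segments.

    Closed domains are painted mostly heterochromatic/quiescent with minority
    Polycomb-repressed and bivalent islands; the rest of the genome mostly
    transcribed/quiescent. Every base gets exactly one label.
    """
    rng = np.random.default_rng(seed)
    dom = arch.closed_domains.merge()
    outside = dom.complement(arch.genome)
    segs: list[Interval] = []
    for iv in dom:
        segs.extend(_chunk_and_label(iv, _INSIDE_STATE_P, rng, chunk_range))
    for iv in outside:
        segs.extend(_chunk_and_label(iv, _OUTSIDE_STATE_P, rng, chunk_range))
    return IntervalSet(segs, genome=arch.genome)


# ---- transcript table -------------------------------------------------


def simulate_transcript_table(
    states: IntervalSet,
    n_transcripts: int,
    bivalent_effect: float,
    seed: int,
    upregulated_prob: float = 0.8,
) -> list[TranscriptRecord]:
    """Transcripts with uniform null p-values and a planted bivalent signal.

    Transcripts whose ±100-nt TSS window overlaps a bivalent state
    (TssBiv/BivFlnk/EnhBiv) by ≥ 100 nt draw p ~ Beta(bivalent_effect, 1)
    and get a positive signed effect with probability ``upregulated_prob``;
    all others are null (p uniform, effect sign symmetric).
    ``bivalent_effect = 1`` is the global null.
    """
    if n_transcripts <= 0:
        raise ValueError("n_transcripts must be positive")
    if not (0 < bivalent_effect <= 1):
        raise ValueError("bivalent_effect must be in (0, 1]")
    rng = np.random.default_rng(seed)
    extents: dict[str, int] = {}
    biv = IntervalSet(iv for iv in states if iv.name in BIVALENT_STATES).merge()
    for iv in states:
        extents[iv.chrom] = max(extents.get(iv.chrom, 0), iv.end)
    chroms = list(extents)
    lens = np.array([extents[c] for c in chroms], dtype=float)
    records: list[TranscriptRecord] = []
    for i in range(n_transcripts):
        ci = rng.choice(len(chroms), p=lens / lens.sum())
        chrom, clen = chroms[ci], int(lens[ci])
        body_len = int(np.clip(rng.lognormal(np.log(20_000), 0.8), 2_000, 200_000))
        body_len = min(body_len, clen - 1)
        start = int(rng.integers(0, clen - body_len))
        end = start + body_len
        strand = "+" if rng.random() < 0.5 else "-"
        tss = start if strand == "+" else end
        is_biv = biv.overlap_bp(chrom, max(tss - 100, 0), tss + 100) >= 100
        if is_biv and bivalent_effect < 1:
            p = float(max(rng.beta(bivalent_effect, 1.0), 1e-300))
            sign = 1.0 if rng.random() < upregulated_prob else -1.0
            effect = sign * abs(rng.normal(1.0, 0.5))
        else:
            p = float(1.0 - rng.random())  # in (0, 1]
            effect = float(rng.normal(0.0, 1.0))
        records.append(
            TranscriptRecord(
                transcript_id=f"tx{i:05d}", gene_id=f"g{i:05d}",
                chrom=chrom, start=start, end=end, strand=strand,
                tss=tss, p_value=p, effect=effect, weight=2.0,
            )
        )
    return records


# ---- nuclei images ----------------------------------------------------

SimulatedNuclei = namedtuple("SimulatedNuclei", ["images", "foci", "nuclei"])


def _ellipse_boundary(cx, cy, a, b, theta, n=4096):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    ct, st = np.cos(theta), np.sin(theta)
    return cx + x * ct - y * st, cy + x * st + y * ct


def simulate_nuclei(
    n_nuclei: int,
    radius_px: int,
    n_foci_range: tuple[int, int],
    periphery_bias: float,
    pixel_size_um: float,
    seed: int,
    background: float = 300.0,
    nucleus_intensity: float = 3000.0,
    focus_amplitude_ratio: float = 5.0,
) -> SimulatedNuclei:
    """Elliptical nuclei with bright Gaussian foci and exact ground truth.

    One nucleus per image. Focus radial position f (0 = centroid, 1 =
    boundary) is drawn area-uniformly between ``0.84 * periphery_bias`` and
    0.96, so ``periphery_bias = 1`` confines foci to the outer shell (true
    proximity ≤ 0.2). Ground truth lists, per focus, the exact minimum
    distance to the elliptical boundary and the size-independent proximity
    (min distance over centroid-to-nearest-boundary-point distance).
    """
    if radius_px < 10:
        raise ValueError("radius_px must be at least 10")
    if not (0 <= periphery_bias <= 1):
        raise ValueError("periphery_bias must be in [0, 1]")
    lo_n, hi_n = n_foci_range
    rng = np.random.default_rng(seed)
    size = int(radius_px * 3)
    images = np.zeros((n_nuclei, size, size), dtype=np.uint16)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    foci_rows, nuc_rows = [], []
    f_lo, f_hi = 0.84 * periphery_bias, 0.96
    for ni in range(n_nuclei):
        cx = cy = size / 2 + rng.uniform(-2, 2)
        a = radius_px * rng.uniform(0.95, 1.05)
        b = a * rng.uniform(0.85, 1.0)
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        img = rng.normal(background, background * 0.1, size=(size, size))
        img[inside] = rng.normal(nucleus_intensity, nucleus_intensity * 0.05,
                                 size=int(inside.sum()))
        bx, by = _ellipse_boundary(cx, cy, a, b, theta)
        nuc_rows.append({
            "nucleus": ni, "cx": cx, "cy": cy, "a_px": a, "b_px": b,
            "radius_um": radius_px * pixel_size_um,
            "area_px2": float(inside.sum()),
        })
        n_foci = int(rng.integers(lo_n, hi_n + 1))
        centers: list[tuple[float, float]] = []
        for fi in range(n_foci):
            for _ in range(200):
                phi = rng.uniform(0, 2 * np.pi)
                f = f_lo + (f_hi - f_lo) * np.sqrt(rng.random())
                fx = cx + f * (a * np.cos(phi) * ct - b * np.sin(phi) * st)
                fy = cy + f * (a * np.cos(phi) * st + b * np.sin(phi) * ct)
                un = (fx - cx) * ct + (fy - cy) * st
                vn = -(fx - cx) * st + (fy - cy) * ct
                if (un / a) ** 2 + (vn / b) ** 2 > (f_hi) ** 2:
                    continue
                if all((fx - ox) ** 2 + (fy - oy) ** 2 >= 8.0 ** 2
                       for ox, oy in centers):
                    break
            else:  # could not separate; accept last draw
                pass
            centers.append((fx, fy))
            sigma = rng.uniform(1.6, 2.4)
            amp = nucleus_intensity * (focus_amplitude_ratio - 1.0)
            img += amp * np.exp(-(((xx - fx) ** 2 + (yy - fy) ** 2)
                                  / (2 * sigma ** 2))) * inside
            d = np.hypot(bx - fx, by - fy)
            k = int(np.argmin(d))
            min_dist = float(d[k])
            centroid_to_b = float(np.hypot(bx[k] - cx, by[k] - cy))
            foci_rows.append({
                "nucleus": ni, "focus": fi, "x": fx, "y": fy,
                "sigma_px": sigma, "radial_frac": f,
                "min_dist_px": min_dist,
                "min_dist_um": min_dist * pixel_size_um,
                "proximity": min(min_dist / centroid_to_b, 1.0),
            })
        images[ni] = np.clip(img, 0, 65535).astype(np.uint16)
    foci = pd.DataFrame(foci_rows, columns=[
        "nucleus", "focus", "x", "y", "sigma_px", "radial_frac",
        "min_dist_px", "min_dist_um", "proximity"])
    nuclei = pd.DataFrame(nuc_rows)
    return SimulatedNuclei(images, foci, nuclei)


# ---- writers ----------------------------------------------------------


def write_reads_bed(reads, path) -> None:
    """Emit read midpoints as BED3 1-bp intervals."""
    from .tracks import as_read_frame

    frame = as_read_frame(reads)
    with open(path, "w") as fh:
        for chrom, mid in zip(frame["chrom"], frame["midpoint"]):
            fh.write(f"{chrom}\t{mid}\t{mid + 1}\n")


def read_reads_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, _end = line.split("\t")[:3]
            rows.append((chrom, int(start)))
    return pd.DataFrame(rows, columns=["chrom", "midpoint"])
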