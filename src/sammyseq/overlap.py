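"""Agreement statistics between genomic interval sets.

Base-pair Jaccard index, asymmetric coverage fractions (precision /
sensitivity), an empirical overlap test that re-places one set uniformly at
random along the genome (shuffle randomization, lengths preserved), a binned
Fisher exact overlap test, and multi-sample consensus / conservation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome import Genome, Interval, IntervalSet

__all__ = [
    "ShuffleResult",
    "jaccard",
    "coverage_fraction",
    "shuffle_intervals",
    "empirical_overlap_test",
    "fisher_overlap_test",
    "multi_sample_overlap",
]

logger = logging.getLogger(__name__)


@dataclass
class ShuffleResult:
    observed_ji: float
    random_jis: np.ndarray
    empirical_p: float
    random_mean: float
    random_sem: float


def jaccard(a: IntervalSet, b: IntervalSet) -> float:
    """Base-pair intersection over union; 0 (with a warning) when both empty."""
    fa, fb = a.merge() if len(a) else a, b.merge() if len(b) else b
    inter = fa.intersect(fb).total_bp() if len(fa) and len(fb) else 0
    union = fa.union(fb).total_bp() if (len(fa) or len(fb)) else 0
    if union == 0:
        warnings.warn("jaccard of two empty sets is 0 by convention", stacklevel=2)
        return 0.0
    return inter / union


def coverage_fraction(query: IntervalSet, subject: IntervalSet) -> float:
    """Fraction of query base pairs covered by subject (asymmetric).

    coverage_fraction(calls, reference) is the calls' precision against the
    reference; coverage_fraction(reference, calls) their sensitivity.
    """
    qbp = query.total_bp()
    if qbp == 0:
        raise ValueError("empty query set")
    return query.intersect(subject).total_bp() / qbp


# ---- shuffle randomization --------------------------------------------


def shuffle_intervals(
    intervals: IntervalSet,
    genome: Genome,
    blacklist: IntervalSet | None = None,
    no_overlap: bool = True,
    preserve_chrom: bool = False,
    rng: np.random.Generator | None = None,
    max_tries: int = 50,
) -> IntervalSet:
    """Re-place every interval uniformly at random in genome minus blacklist.

    Interval lengths and count are preserved; with ``no_overlap`` the placed
    intervals are mutually disjoint. Placement is sequential, longest first,
    choosing uniformly among all feasible start positions in the remaining
    free space (so it only fails when the set genuinely does not fit).
    """
    rng = np.random.default_rng() if rng is None else rng
    free: dict[str, list[tuple[int, int]]] = {}
    avail = (
        blacklist.complement(genome) if blacklist is not None and len(blacklist)
        else IntervalSet(Interval(c, 0, l) for c, l in genome.items())
    )
    for iv in avail:
        free.setdefault(iv.chrom, []).append((iv.start, iv.end))
    placed: list[Interval] = []
    order = sorted(intervals, key=lambda iv: -iv.length)
    for iv in order:
        L = iv.length
        chrom_pool = [iv.chrom] if preserve_chrom else list(free)
        segs = [
            (chrom, s, e)
            for chrom in chrom_pool
            for s, e in free.get(chrom, ())
            if e - s >= L
        ]
        weights = np.array([e - s - L + 1 for _, s, e in segs], dtype=float)
        if not segs:
            raise RuntimeError(
                f"cannot place a {L}-bp interval: no free segment long enough "
                f"(set too dense for the available space)"
            )
        k = rng.choice(len(segs), p=weights / weights.sum())
        chrom, s, e = segs[k]
        start = int(s + rng.integers(0, e - s - L + 1))
        placed.append(Interval(chrom, start, start + L))
        if no_overlap:
            fl = free[chrom]
            fl.remove((s, e))
            if start > s:
                fl.append((s, start))
            if start + L < e:
                fl.append((start + L, e))
    return IntervalSet(placed)


def empirical_overlap_test(
    a: IntervalSet,
    b: IntervalSet,
    genome: Genome,
    blacklist: IntervalSet | None = None,
    n: int = 10_000,
    randomize: str = "a",
    no_overlap: bool = True,
    preserve_chrom: bool = False,
    seed: int = 0,
) -> ShuffleResult:
    """One-tail shuffle test of the Jaccard index between two sets.

    The chosen set is re-placed ``n`` times; empirical p =
    (1 + #{random JI >= observed}) / (1 + n), so p is never 0 and its floor
    is 1/(n+1). Reports the mean and SEM of the random JIs.
    """
    if randomize not in ("a", "b"):
        raise ValueError("randomize must be 'a' or 'b'")
    rng = np.random.default_rng(seed)
    observed = jaccard(a, b)
    moving, fixed = (a, b) if randomize == "a" else (b, a)
    random_jis = np.empty(n)
    for i in range(n):
        shuffled = shuffle_intervals(
            moving, genome, blacklist, no_overlap=no_overlap,
            preserve_chrom=preserve_chrom, rng=rng,
        )
        random_jis[i] = jaccard(shuffled, fixed)
    k = int((random_jis >= observed).sum())
    p = (1.0 + k) / (1.0 + n)
    sem = float(random_jis.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    logger.info("overlap shuffle test: observed JI %.4f, p %.3g (n=%d)",
                observed, p, n)
    return ShuffleResult(observed, random_jis, p, float(random_jis.mean()), sem)


# ---- Fisher overlap test ----------------------------------------------


def fisher_overlap_test(
    a: IntervalSet, b: IntervalSet, genome: Genome, bin_size: int = 10_000
) -> tuple[float, float, np.ndarray]:
    """Upper-tail Fisher exact test on binned joint occupancy.

    The genome is tiled into fixed bins; each bin is classified by whether
    it overlaps a (>= 1 bp) and b (>= 1 bp); the 2x2 count table is tested
    one-tailed for enrichment. Returns (odds ratio, p, table); degenerate
    margins give p = 1 with a warning. The table is returned for audit.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    fa, fb = a.merge().by_chrom(), b.merge().by_chrom()
    in_a, in_b = [], []
    for chrom, clen in genome.items():
        nb = genome.n_bins(chrom, bin_size)
        for src, acc in ((fa, in_a), (fb, in_b)):
            mask = np.zeros(nb, dtype=bool)
            for s, e in src.get(chrom, ()):
                mask[int(s // bin_size): int(-(-e // bin_size))] = True
            acc.append(mask)
    ma, mb = np.concatenate(in_a), np.concatenate(in_b)
    table = np.array([
        [int((ma & mb).sum()), int((ma & ~mb).sum())],
        [int((~ma & mb).sum()), int((~ma & ~mb).sum())],
    ])
    if ma.all() or not ma.any() or mb.all() or not mb.any():
        warnings.warn("degenerate margins in Fisher overlap test; p = 1",
                      stacklevel=2)
        return float("nan"), 1.0, table
    res = stats.fisher_exact(table, alternative="greater")
    odds = float("inf") if table[0, 1] == 0 or table[1, 0] == 0 else float(res.statistic)
    return odds, float(res.pvalue), table


# ---- consensus / conservation across samples --------------------------


def multi_sample_overlap(
    sets: list[IntervalSet], min_support: int
) -> tuple[IntervalSet, list[float]]:
    """Consensus (bases in >= min_support sets) and per-sample conservation.

    The conserved fraction of sample i is the fraction of its base pairs
    covered by ALL samples (the strict intersection), mirroring per-sample
    domain-conservation percentages.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 interval sets")
    if not (2 <= min_support <= len(sets)):
        raise ValueError("min_support out of range")
    # sweep over start/end events per chromosome, counting support
    events: dict[str, list[tuple[int, int]]] = {}
    for s in sets:
        for iv in s.merge():
            events.setdefault(iv.chrom, []).append((iv.start, +1))
            events[iv.chrom].append((iv.end, -1))
    consensus: list[Interval] = []
    for chrom, evs in events.items():
        evs.sort()
        depth = 0
        open_start: int | None = None
        for pos, delta in evs:
            new_depth = depth + delta
            if depth < min_support <= new_depth and open_start is None:
                open_start = pos
            elif open_start is not None and new_depth < min_support <= depth:
                if pos > open_start:
                    consensus.append(Interval(chrom, open_start, pos))
                open_start = None
            depth = new_depth
    consensus_set = IntervalSet(consensus).merge() if consensus else IntervalSet()
    strict = sets[0]
    for s in sets[1:]:
        strict = strict.intersect(s)
    fractions = []
    for s in sets:
        bp = s.total_bp()
        fractions.append(s.intersect(strict).total_bp() / bp if bp else 0.0)
    return consensus_set, fractions
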