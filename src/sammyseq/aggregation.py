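"""Chromatin-state-stratified aggregation of transcript-level p-values.

Transcripts from an upstream differential-expression test are assigned to
chromatin contexts (Roadmap-style state mnemonics), their uncorrected
p-values are combined per context (and per effect direction) with the
Lancaster method — the weighted generalization of Fisher's combined-p test
via gamma quantile transforms; all weights equal to 2 recovers Fisher —
and the aggregate p-values are BH-corrected across the run's rows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import IntervalSet

__all__ = [
    "TranscriptRecord",
    "AggregationRow",
    "BODY_STATES",
    "BIVALENT_STATES",
    "assign_chromatin_context",
    "lancaster",
    "aggregate_by_group",
    "rank_groups_across_conditions",
    "bivalent_enrichment_test",
]

logger = logging.getLogger(__name__)

#: Body-overlap states: assigned when ≥ 50% of the transcript body lies in the state.
BODY_STATES = ("Tx", "TxWk", "ReprPC", "ReprPCWk", "Het", "ZNF/Rpts")
#: Bivalent states: assigned on the ±100-nt TSS window (≥ 100 nt overlap).
BIVALENT_STATES = ("TssBiv", "BivFlnk", "EnhBiv")
KNOWN_STATES = set(BODY_STATES) | set(BIVALENT_STATES) | {"Quies"}

P_FLOOR = 1e-300  # gamma quantile diverges at p = 0


@dataclass
class TranscriptRecord:
    transcript_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    tss: int
    p_value: float
    effect: float
    weight: float = 2.0
    contexts: tuple[str, ...] = ()
    pathways: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            if self.p_value == 0:
                warnings.warn(
                    f"{self.transcript_id}: p-value 0 clamped to {P_FLOOR}",
                    stacklevel=2,
                )
                self.p_value = P_FLOOR
            else:
                raise ValueError(f"{self.transcript_id}: p-value out of (0, 1]")
        if self.weight <= 0:
            raise ValueError("weight must be positive")

    @property
    def bivalent(self) -> bool:
        return any(c in BIVALENT_STATES for c in self.contexts)


@dataclass
class AggregationRow:
    group: str
    direction: str  # up | down | all
    n_transcripts: int
    T: float
    df: float
    p: float
    q: float = float("nan")


def assign_chromatin_context(
    transcripts: list[TranscriptRecord],
    states: IntervalSet,
    domain_filter: IntervalSet | None = None,
    tss_window: int = 200,
) -> list[TranscriptRecord]:
    """Assign chromatin-state contexts to transcripts.

    Body states (Tx, TxWk, ReprPC, ReprPCWk, Het, ZNF/Rpts) are assigned when
    the transcript body overlaps the state over ≥ 50% of its length; bivalent
    states (TssBiv, BivFlnk, EnhBiv) when the ``tss_window``-nt window
    centered on the TSS overlaps the state by at least half the window. A
    transcript may carry several context labels. With ``domain_filter``,
    transcripts whose body does not intersect the filter are dropped.
    """
    for iv in states:
        if iv.name not in KNOWN_STATES:
            raise ValueError(f"unknown state label {iv.name!r}")
    by_state: dict[str, IntervalSet] = {}
    for label in set(iv.name for iv in states):
        by_state[label] = IntervalSet(iv for iv in states if iv.name == label).merge()
    filt = domain_filter.merge() if domain_filter is not None else None
    half = tss_window // 2
    out: list[TranscriptRecord] = []
    for tx in transcripts:
        if filt is not None and filt.overlap_bp(tx.chrom, tx.start, tx.end) == 0:
            continue
        ctx: list[str] = []
        body_len = tx.end - tx.start
        for label in BODY_STATES:
            sset = by_state.get(label)
            if sset is None:
                continue
            if sset.overlap_bp(tx.chrom, tx.start, tx.end) / body_len >= 0.5:
                ctx.append(label)
        w_lo, w_hi = max(tx.tss - half, 0), tx.tss + half
        for label in BIVALENT_STATES:
            sset = by_state.get(label)
            if sset is None:
                continue
            if sset.overlap_bp(tx.chrom, w_lo, w_hi) >= half:
                ctx.append(label)
        out.append(replace(tx, contexts=tuple(ctx)))
    return out


def lancaster(p_values, weights) -> tuple[float, float, float]:
    """Lancaster combined-p: gamma quantile transform, chi-square reference.

    T = sum_i GammaInv(shape = w_i / 2, scale = 2; 1 - p_i); under the null
    T ~ chi-square with df = sum_i w_i, and the combined p is that upper
    tail. Weights all equal to 2 recover Fisher's method exactly.
    """
    p = np.asarray(p_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if p.shape != w.shape:
        raise ValueError("p_values and weights differ in length")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if np.any(p == 0):
        warnings.warn(f"p-value 0 clamped to {P_FLOOR}", stacklevel=2)
        p = np.maximum(p, P_FLOOR)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    # isf(p) == ppf(1 - p) but keeps precision for small p
    T = float(np.sum(stats.gamma.isf(p, a=w / 2.0, scale=2.0)))
    df = float(np.sum(w))
    return T, df, float(stats.chi2.sf(T, df))


def aggregate_by_group(
    transcripts: list[TranscriptRecord],
    group_by: str = "context",
    direction_split: bool = True,
    weights_mode: str = "equal",
) -> list[AggregationRow]:
    """Lancaster-aggregate transcript p-values per group, BH across all rows.

    group_by "context" groups on chromatin-state labels, "pathway" on
    pathway ids. With ``direction_split``, upregulated (effect > 0) and
    downregulated (effect < 0) transcripts are aggregated separately;
    otherwise one "all" row per group. ``weights_mode`` "equal" uses weight
    2 for every transcript (Fisher); "supplied" uses each record's weight.
    """
    if group_by not in ("context", "pathway"):
        raise ValueError("group_by must be 'context' or 'pathway'")
    if weights_mode not in ("equal", "supplied"):
        raise ValueError("weights_mode must be 'equal' or 'supplied'")
    groups: dict[str, list[TranscriptRecord]] = {}
    for tx in transcripts:
        labels = tx.contexts if group_by == "context" else tx.pathways
        for label in labels:
            groups.setdefault(label, []).append(tx)
    logger.info("aggregating %d groups (%s, weights=%s, split=%s)",
                len(groups), group_by, weights_mode, direction_split)
    rows: list[AggregationRow] = []
    directions = ("up", "down") if direction_split else ("all",)
    for label in sorted(groups):
        members = groups[label]
        for direction in directions:
            if direction == "up":
                sel = [t for t in members if t.effect > 0]
            elif direction == "down":
                sel = [t for t in members if t.effect < 0]
            else:
                sel = members
            if not sel:
                logger.info("group %s/%s: no members, skipped", label, direction)
                continue
            p = [t.p_value for t in sel]
            w = [2.0] * len(sel) if weights_mode == "equal" else [t.weight for t in sel]
            T, df, pv = lancaster(p, w)
            rows.append(AggregationRow(label, direction, len(sel), T, df, pv))
    if rows:
        _, q, _, _ = multipletests([r.p for r in rows], method="fdr_bh")
        for row, qv in zip(rows, q):
            row.q = float(qv)
    return rows


def rank_groups_across_conditions(
    runs: list[list[AggregationRow]],
) -> list[tuple[str, float]]:
    """Rank groups by the sum over conditions of -log10 aggregate p."""
    score: dict[str, float] = {}
    for rows in runs:
        for row in rows:
            score[row.group] = score.get(row.group, 0.0) + float(-np.log10(max(row.p, P_FLOOR)))
    return sorted(score.items(), key=lambda kv: -kv[1])


def bivalent_enrichment_test(
    n_bivalent_hits: int, n_hits: int, n_bivalent_total: int, n_total: int
) -> tuple[float, float]:
    """Upper-tail Fisher exact test for bivalent-gene enrichment among hits.

    2×2 table: rows = (hit, not hit), columns = (bivalent, not bivalent).
    Returns (odds ratio, one-tail p); the odds ratio is inf-coded when a
    denominator cell is empty.
    """
    a = n_bivalent_hits
    b = n_hits - n_bivalent_hits
    c = n_bivalent_total - n_bivalent_hits
    d = (n_total - n_hits) - c
    if min(a, b, c, d) < 0:
        raise ValueError(f"invalid 2x2 table ({a}, {b}, {c}, {d})")
    res = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(res.statistic), float(res.pvalue)
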