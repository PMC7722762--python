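"""End-to-end orchestration: simulate or load data, call domains per
fraction pair, compute overlap statistics, metaprofiles, kernel correlations
and expression aggregation, and write a deterministic artifact tree.

The run is configured by a plain YAML file (see :class:`RunConfig`); every
random stage draws its generator from the single run seed, so two runs of
the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregation import aggregate_by_group, assign_chromatin_context
from .domains import call_domains, calls_to_intervals
from .genome import Genome, IntervalSet, read_bed, read_chrom_sizes, write_bed
from .kernelcorr import kernel_correlation
from .metaprofile import border_profile
from .overlap import coverage_fraction, empirical_overlap_test, jaccard
from .synthetic import (
    make_architecture,
    paint_chromatin_states,
    simulate_fraction_reads,
    simulate_mark_track,
    simulate_transcript_table,
)
from .tracks import bin_and_normalize, log_ratio_track

logger = logging.getLogger(__name__)

DEFAULT_PAIRS = (("S3", "S2"), ("S4", "S3"), ("S4", "S2"))


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Exactly one of ``simulate`` (generator parameters) or ``inputs`` (file
    paths: chrom_sizes plus per-fraction read BEDs) must be present. Every
    stage's randomness derives from ``seed``.
    """

    output_dir: str
    seed: int = 0
    simulate: dict | None = None
    inputs: dict | None = None
    pairs: tuple = DEFAULT_PAIRS
    caller: dict = field(default_factory=dict)
    overlap: dict = field(default_factory=dict)
    kernel: dict = field(default_factory=dict)
    aggregation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in raw.items()})
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("config needs exactly one of 'simulate' or 'inputs'")
        if self.inputs is not None and "chrom_sizes" not in self.inputs:
            raise ValueError("inputs mode requires 'chrom_sizes'")
        if self.simulate is not None and "chrom_sizes" not in self.simulate:
            raise ValueError("simulate mode requires 'chrom_sizes'")
        self.pairs = tuple(tuple(p) for p in self.pairs)
        for a, b in self.pairs:
            for f in (a, b):
                if f not in ("S2", "S3", "S4"):
                    raise ValueError(f"unknown fraction {f!r} in pairs")

    def to_dict(self) -> dict:
        return {
            "output_dir": self.output_dir, "seed": self.seed,
            "simulate": self.simulate, "inputs": self.inputs,
            "pairs": [list(p) for p in self.pairs], "caller": self.caller,
            "overlap": self.overlap, "kernel": self.kernel,
            "aggregation": self.aggregation,
        }


def _stage_rng(seed: int, stage: int) -> int:
    """Stable per-stage sub-seed below 2**31."""
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _digest(frame: pd.DataFrame) -> str:
    return hashlib.sha256(
        frame.to_csv(index=False, float_format="%.10g").encode()
    ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the report directory.

    Stages: data (simulate or load) → domain calling per fraction pair →
    overlap statistics against the references → border metaprofiles →
    kernel-correlation matrix → chromatin-state expression aggregation.
    Any stage failure aborts with the stage name.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"version": __version__, "seed": config.seed,
                 "config": config.to_dict(), "stages": {}}
    state: dict = {}

    stages = [
        ("data", _stage_data),
        ("domains", _stage_domains),
        ("overlap", _stage_overlap),
        ("metaprofile", _stage_metaprofile),
        ("kernelcorr", _stage_kernelcorr),
        ("aggregation", _stage_aggregation),
        ("foci", _stage_foci),
    ]
    for name, fn in stages:
        try:
            fn(config, state, out, log)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
        logger.info("stage %s done", name)
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)
    return out


def _stage_data(config: RunConfig, state: dict, out: Path, log: dict) -> None:
    if config.simulate is not None:
        sim = dict(config.simulate)
        genome = Genome.from_dict(sim["chrom_sizes"])
        arch = make_architecture(
            genome,
            n_domains=sim.get("n_domains", 10),
            size_range=tuple(sim.get("size_range", (1_000_000, 5_000_000))),
            enrichment_factor=sim.get("enrichment_factor", 3.0),
            seed=_stage_rng(config.seed, 1),
            condition_label=sim.get("condition", "control"),
        )
        n_reads = sim.get("n_reads", 1_000_000)
        reads = {
            f: simulate_fraction_reads(arch, f, n_reads,
                                       seed=_stage_rng(config.seed, 10 + i))
            for i, f in enumerate(("S2", "S3", "S4"))
        }
        state.update(genome=genome, arch=arch, reads=reads, blacklist=None)
        state["references"] = {"planted": arch.closed_domains.merge()}
        bsz = config.caller.get("bin_size", sim.get("bin_size", 10_000))
        state["marks"] = {
            "lamin_like": simulate_mark_track(arch, +1, sim.get("mark_noise_sd", 0.5),
                                              bsz, _stage_rng(config.seed, 20)),
            "open_chromatin_like": simulate_mark_track(arch, -1, sim.get("mark_noise_sd", 0.5),
                                                       bsz, _stage_rng(config.seed, 21)),
        }
        state["states"] = paint_chromatin_states(arch, _stage_rng(config.seed, 30))
        state["transcripts"] = simulate_transcript_table(
            state["states"], sim.get("n_transcripts", 2000),
            sim.get("bivalent_effect", 0.2), _stage_rng(config.seed, 31),
        )
        write_bed(arch.closed_domains, out / "planted_domains.bed")
        log["stages"]["data"] = {"mode": "simulate", "n_reads": n_reads,
                                 "n_domains": len(arch.closed_domains)}
    else:
        from .synthetic import read_reads_bed

        inputs = config.inputs
        genome = read_chrom_sizes(inputs["chrom_sizes"])
        reads = {f: read_reads_bed(inputs[f"reads_{f.lower()}"])
                 for f in ("S2", "S3", "S4") if f"reads_{f.lower()}" in inputs}
        blacklist = (read_bed(inputs["blacklist"], genome)
                     if "blacklist" in inputs else None)
        references = {
            name: read_bed(path, genome)
            for name, path in inputs.get("references", {}).items()
        }
        state.update(genome=genome, reads=reads, blacklist=blacklist,
                     references=references, marks={}, states=None,
                     transcripts=None, arch=None)
        log["stages"]["data"] = {"mode": "inputs",
                                 "fractions": sorted(reads)}


def _stage_domains(config: RunConfig, state: dict, out: Path, log: dict) -> None:
    caller = config.caller
    bsz = caller.get("bin_size", 10_000)
    calls = {}
    for i, (target, reference) in enumerate(config.pairs):
        if target not in state["reads"] or reference not in state["reads"]:
            continue
        cs = call_domains(
            state["reads"][target], state["reads"][reference], state["genome"],
            bin_size=bsz,
            gap_penalty=caller.get("gap_penalty", 25.0),
            fdr=caller.get("fdr", 0.05),
            blacklist=state["blacklist"],
            required_informative_fraction=caller.get("required_informative_fraction", 0.98),
            n_permutations=caller.get("n_permutations", 1000),
            seed=_stage_rng(config.seed, 40 + i),
        )
        label = f"{target}vs{reference}"
        calls[label] = calls_to_intervals(cs)
        write_bed(calls[label], out / f"domains_{label}.bed")
        _write_tsv(pd.DataFrame([
            {"chrom": c.interval.chrom, "start": c.interval.start,
             "end": c.interval.end, "segment_score": c.segment_score,
             "p_value": c.p_value, "q_value": c.q_value,
             "informative_fraction": c.informative_fraction}
            for c in cs
        ]), out / f"domains_{label}.tsv")
    state["calls"] = calls
    log["stages"]["domains"] = {k: len(v) for k, v in calls.items()}


def _stage_overlap(config: RunConfig, state: dict, out: Path, log: dict) -> None:
    calls, refs = state["calls"], state["references"]
    rows = []
    names = list(calls) + [f"ref:{r}" for r in refs]
    sets = {**{k: v for k, v in calls.items()},
            **{f"ref:{k}": v for k, v in refs.items()}}
    for i, x in enumerate(names):
        for y in names[i + 1:]:
            if len(sets[x]) and len(sets[y]):
                rows.append({"a": x, "b": y, "jaccard": jaccard(sets[x], sets[y]),
                             "precision_a_in_b": coverage_fraction(sets[x], sets[y]),
                             "sensitivity_b_by_a": coverage_fraction(sets[y], sets[x])})
    _write_tsv(pd.DataFrame(rows), out / "overlap_matrix.tsv")
    srows = []
    n = config.overlap.get("n_shuffles", 1000)
    for i, (label, cset) in enumerate(sorted(calls.items())):
        for j, (rname, rset) in enumerate(sorted(refs.items())):
            if not len(cset) or not len(rset):
                continue
            res = empirical_overlap_test(
                cset, rset, state["genome"], state["blacklist"], n=n,
                seed=_stage_rng(config.seed, 50 + 10 * i + j),
            )
            srows.append({"calls": label, "reference": rname,
                          "observed_ji": res.observed_ji,
                          "random_mean": res.random_mean,
                          "random_sem": res.random_sem,
                          "empirical_p": res.empirical_p, "n_shuffles": n})
    _write_tsv(pd.DataFrame(srows), out / "overlap_shuffle.tsv")
    log["stages"]["overlap"] = {"n_shuffles": n, "pairs": len(rows)}


def _stage_metaprofile(config: RunConfig, state: dict, out: Path, log: dict) -> None:
    bsz = config.caller.get("bin_size", 10_000)
    n_done = 0
    for label, cset in sorted(state["calls"].items()):
        if not len(cset):
            continue
        target, reference = label.split("vs")
        t = bin_and_normalize(state["reads"][target], state["genome"], bsz)
        r = bin_and_normalize(state["reads"][reference], state["genome"], bsz)
        lr = log_ratio_track(t, r)
        for side in ("start", "end"):
            prof = border_profile(lr, cset, side=side, k_bins=50, bin_size=bsz)
            _write_tsv(prof.to_table(), out / f"metaprofile_{label}_{side}.tsv")
            n_done += 1
    log["stages"]["metaprofile"] = {"profiles": n_done}


def _stage_kernelcorr(config: RunConfig, state: dict, out: Path, log: dict) -> None:
    marks = state["marks"]
    if not marks:
        log["stages"]["kernelcorr"] = {"skipped": "no mark tracks"}
        return
    bsz = config.caller.get("bin_size", 10_000)
    sd = config.kernel.get("sd_bins", 3.0)
    rows = []
    for label in sorted(state["calls"]):
        target, reference = label.split("vs")
        t = bin_and_normalize(state["reads"][target], state["genome"], bsz)
        r = bin_and_normalize(state["reads"][reference], state["genome"], bsz)
        lr = log_ratio_track(t, r)
        for mname, mtrack in sorted(marks.items()):
            rows.append({"signal": label, "mark": mname,
                         "kernel_r": kernel_correlation(lr, mtrack, sd)})
    _write_tsv(pd.DataFrame(rows), out / "kernelcorr.tsv")
    log["stages"]["kernelcorr"] = {"kernel_sd_bins": sd}


def _stage_aggregation(config: RunConfig, state: dict, out: Path, log: dict) -> None:
    if state.get("transcripts") is None or state.get("states") is None:
        log["stages"]["aggregation"] = {"skipped": "no transcript table"}
        return
    domain_filter = state["calls"].get("S4vsS2")
    assigned = assign_chromatin_context(
        state["transcripts"], state["states"],
        domain_filter=domain_filter if domain_filter and len(domain_filter) else None,
    )
    rows = aggregate_by_group(
        assigned, group_by="context",
        direction_split=config.aggregation.get("direction_split", True),
        weights_mode=config.aggregation.get("weights_mode", "equal"),
    )
    _write_tsv(pd.DataFrame([
        {"group": r.group, "direction": r.direction, "n": r.n_transcripts,
         "T": r.T, "df": r.df, "p": r.p, "q": r.q}
        for r in rows
    ]), out / "aggregation.tsv")
    log["stages"]["aggregation"] = {"rows": len(rows),
                                    "n_transcripts": len(assigned)}


def _stage_foci(config: RunConfig, state: dict, out: Path, log: dict) -> None:
    sim = config.simulate or {}
    nuc = sim.get("nuclei")
    if not nuc:
        log["stages"]["foci"] = {"skipped": "no images configured"}
        return
    from .foci import analyze_image, summarize_periphery
    from .synthetic import simulate_nuclei

    pixel_size = nuc.get("pixel_size_um", 0.1)
    stack = simulate_nuclei(
        nuc.get("n", 20), nuc.get("radius_px", 50),
        tuple(nuc.get("n_foci_range", (3, 6))),
        nuc.get("periphery_bias", 0.7), pixel_size,
        seed=_stage_rng(config.seed, 60),
    )
    measures = [m for img in stack.images
                for m in analyze_image(img, pixel_size)]
    rows = [
        {"nucleus": i, "focus": f.focus_id, "area_px2": f.area_px2,
         "min_dist_um": f.min_dist_um, "proximity": f.proximity}
        for i, m in enumerate(measures) for f in m.foci
    ]
    _write_tsv(pd.DataFrame(rows), out / "foci.tsv")
    n_cells, n_bodies, n_within, pct = summarize_periphery(
        measures, nuc.get("cutoff_um", 1.0))
    _write_tsv(pd.DataFrame([{
        "n_cells": n_cells, "n_bodies": n_bodies, "n_within": n_within,
        "percent_within": pct,
    }]), out / "foci_summary.tsv")
    log["stages"]["foci"] = {"n_cells": n_cells, "n_bodies": n_bodies}
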