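# sammyseq

Downstream analysis of sequential chromatin-fractionation sequencing
(SAMMY-seq): from per-fraction aligned-fragment coordinates to
chromatin-compaction domains and their biological read-outs.

SAMMY-seq separates chromatin into sequentially extracted pools of
decreasing accessibility — S2 (DNase-released), S3 (high-salt-released)
and S4 (urea-solubilized, most condensed) — and sequences each pool.
Genomic regions enriched in a less accessible fraction relative to a more
accessible one (**SAMMY-seq domains**, e.g. S4 vs S2) mark compacted,
heterochromatic, lamina-associated chromatin, and their disruption is a
hallmark of laminopathies such as Hutchinson–Gilford progeria. This
package is for computational biologists who have such fraction-level
coordinate data (or want a fully synthetic benchmark) and need the
downstream statistics:

- **Domain calling** (EDD-style): bin the target/reference pair, form the
  library-normalized log2 ratio, score bins +1 / −G (gap penalty G) by a
  polarity split, extract all maximal-scoring segments (Ruzzo–Tompa), and
  test them against a genome-wide score-permutation null with BH
  correction; calls must also be ≥ 98% informative bins. Broad peaks from
  a single mark via Poisson z-scores on fixed windows.
- **Overlap statistics**: base-pair Jaccard index, precision/sensitivity
  coverage fractions, empirical randomization tests (`bedtools
  shuffle`-style re-placement, p = (k+1)/(N+1)), binned Fisher exact
  overlap tests, multi-sample consensus and conservation.
- **Metaprofiles**: mean signal ± SEM around domain borders (±50 bins)
  and TSSs (±5 kb / 100 bp), with a GCV smoothing-spline curve; common-peak
  TSS gene sets.
- **Kernel correlation**: genome-wide correlation of two tracks after
  Gaussian smoothing (tolerant of imperfect positional overlap), with a
  circular-shift null.
- **Expression aggregation**: transcripts assigned to Roadmap-style
  chromatin states (≥ 50% body overlap; bivalent states by the TSS
  ± 100 nt window), p-values combined per state and effect direction with
  the **Lancaster method** — T = Σᵢ Q_Γ(wᵢ/2, 2; 1 − pᵢ) ~ χ²(Σwᵢ) under
  the null; all weights 2 reduces to Fisher — then BH-corrected; Fisher
  test for bivalent-gene enrichment.
- **Foci imaging**: nuclei by global two-class Otsu, foci by per-nucleus
  three-class Otsu, and each focus's periphery **proximity** =
  (min Euclidean distance to the boundary) / (centroid-to-that-boundary-
  point distance), with percent-within-1-µm summaries.
- **Synthetic data**: a generator that plants megabase-scale closed
  domains, draws fraction reads from the corresponding multinomial,
  paints chromatin states, simulates transcript tables with a bivalent
  signal, and renders nucleus images with exact ground truth — so the
  whole pipeline is testable end-to-end without external data.

See `docs/methods.md` for models, parameters and limitations.

## Worked example

```python
import sammyseq as sq

# plant a compacted-chromatin architecture and simulate one sample
arch = sq.make_architecture(
    {"chr1": 30_000_000, "chr2": 30_000_000},
    n_domains=10, size_range=(1_000_000, 5_000_000),
    enrichment_factor=3.0, seed=7,
)
s4 = sq.simulate_fraction_reads(arch, "S4", 1_000_000, seed=1)
s2 = sq.simulate_fraction_reads(arch, "S2", 1_000_000, seed=2)

calls = sq.call_domains(s4, s2, arch.genome, bin_size=10_000,
                        gap_penalty=25.0, fdr=0.05,
                        n_permutations=1000, seed=3)
domains = sq.calls_to_intervals(calls)
print(f"{len(calls)} domains called, "
      f"mean size {domains.total_bp() / len(calls) / 1e6:.2f} Mb")
print(f"Jaccard vs planted truth: "
      f"{sq.jaccard(domains, arch.closed_domains):.3f}")
res = sq.empirical_overlap_test(domains, arch.closed_domains, arch.genome,
                                n=1000, seed=4)
print(f"shuffle test: observed JI {res.observed_ji:.3f}, "
      f"random mean {res.random_mean:.3f}, p = {res.empirical_p:.4g}")
```

prints

```
10 domains called, mean size 3.37 Mb
Jaccard vs planted truth: 0.998
shuffle test: observed JI 0.998, random mean 0.421, p = 0.000999
```

All ten planted domains are recovered essentially exactly (Jaccard 0.998
against the planted truth; boundary error is at most one 10-kb bin per
border), and the randomization test says an agreement this strong occurs
in none of 1000 random re-placements of the called domains (the floor
p = 1/1001 of the (k+1)/(N+1) estimator).

A `sammy` CLI exposes the same steps as subcommands (`simulate`, `bin`,
`signal`, `call-domains`, `broad-peaks`, `overlap`, `metaprofile`,
`kernelcorr`, `aggregate`, `foci`, `run`); `sammy run --config run.yaml`
executes the whole pipeline from a YAML config into a deterministic
report directory.

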