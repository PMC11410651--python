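# Methods

This note documents the models behind `epicenmap`: what the synthetic
epigenome emulates, the statistics the analysis modules compute, the
numerical and design choices that were genuinely open, and what the
planted-truth tests do and do not demonstrate.

## The study design being modelled

The package targets a classic plant epigenetics design. A chromatin
remodeler (DDM1-type) maintains CG/CHG methylation over pericentromeric
repeats; its loss hypomethylates those repeats *heritably*, so that after
backcrossing to wild type, chromosomes remain mosaics of methylated
(wild-type-derived) and hypomethylated (mutant-derived) segments. These
segments behave as alleles ("epigenotypes") and can be mapped like genetic
markers. Three analyses follow:

1. **Bulked-segregant epigenotype mapping.** Individuals are phenotyped
   (fertile/sterile), pooled, bisulfite-sequenced, and the pools compared
   in fixed 100-kb windows; the phenotype-linked region is the run of
   windows where the sterile pool is hypomethylated relative to the fertile
   pool. Fine mapping uses McrBC digestion + PCR: McrBC cuts methylated
   templates, so amplification is a *dominant presence marker* for a
   hypomethylated epiallele.
2. **Suppressor hyper-DMR calling.** Independent suppressor lines that
   regain the phenotype are screened for hypermethylated regions shared by
   all of them: 300-bp windows, total methylation summed over the three
   contexts, retention < 40% in the mutant and recovery > 60% in the
   suppressor, adjacent qualifying windows merged, the per-suppressor DMR
   unions intersected at base-pair level.
3. **Cytology.** Mitotic mis-segregation rates (~100 cells per genotype),
   FISH attribution of the lagging chromosome, and cohesion scored as FISH
   focus counts per nucleus (2 = cohesed, 3–4 = cohesion lost).

## Synthetic epigenome

**Genome.** Default: five 600-kb chromosomes; centromere = the middle third
(200–400 kb). Chromosome arms are i.i.d. uniform nucleotides. Centromeres
are tandem arrays of one genome-wide 178-bp satellite monomer with 5%
per-base divergence, interrupted by annotated retrotransposon elements:
8 elements of the target family (`ATHILA5`) in the centromere of Chr5 and
20 background elements (`ATHILA_other`) spread across all centromeres,
3 kb each. Sequence composition matters only through the densities of CG,
CHG and CHH cytosines; the 600-kb chromosome length is a scaled-down
analysis size chosen once — it gives six 100-kb mapping windows per
chromosome and ~75 k cytosines per chromosome, ample for every windowed
statistic. Real genomes differ in scale (30 Mb chromosomes), in repeat
heterogeneity, and in mappability artefacts, none of which this generator
attempts to model.

**Epigenotypes.** A haplotype is a run-length list of (start, end, state)
segments tiling each chromosome, state ∈ {METH, HYPO, HYPER}. Default
per-read methylation probabilities:

| state | CG | CHG | CHH | meaning |
|-------|----|-----|-----|---------|
| METH  | 0.90 | 0.50 | 0.20 | wild-type heterochromatin |
| HYPO  | 0.02 | 0.02 | 0.10 | remodeler-mutant-derived: CG/CHG lost, CHH partly retained |
| HYPER | 0.90 | 0.70 | 0.50 | suppressor epiallele: gain in all contexts |

The HYPO CHH value (0.10) is a placeholder for partial RdDM retention and
is exposed in the scenario file. METH CHH (0.20) exceeds HYPO CHH because
target elements lose CHH in the quadruple-mutant analogue and regain it
under RNAi — the CHH gap is what the hairpin rescue restores.

**Read model.** Per cytosine: coverage `N ~ Poisson(λ)` (λ = 20 by default;
split evenly across the two haplotypes of a diploid sample) and methylated
count `k | N ~ BetaBinomial(N, p, ρ)` with overdispersion ρ = 0.1
(bisulfite data are overdispersed; the exact value is a modelling choice,
configurable). Sampling uses the exact Poisson-thinning factorization:
with `p' ~ Beta(mean p, var p(1−p)ρ)`, drawing
`k ~ Poisson(λp')` and `N−k ~ Poisson(λ(1−p'))` independently reproduces
the joint law exactly while staying fully vectorized.

Each (chromosome, haplotype, state, context) gets its own deterministic
substream, drawn over *all* sites of that context: a site's counts depend
only on its own assigned state, so editing states elsewhere (a hairpin
override, a planted DMR) leaves every other site's draw bit-identical at
the same seed. `simulate_pool_methylome` draws the count-level pool of many
individuals directly — pooled methylated counts are
`Poisson(λ · Σ p'_i)` over the member haplotypes' beta chances — which is
distributionally identical to simulating members individually and summing
counts (moment-tested), and an order of magnitude faster for replicate
studies. The pooled sampler uses one sequential stream; its determinism
contract is per-(inputs, seed).

**Crosses.** One recombinant haplotype per individual is formed from a
fully-HYPO and a fully-METH parental haplotype: crossover count per
chromosome ~ Poisson(1.5), positions uniform with rejection inside the
centromere at acceptance probability 0.05 (centromeric crossover
suppression; the literature motivates rarity, not a value). The second
haplotype is fully METH (recurrent parent). Phenotype: sterile iff any
haplotype is HYPO across the entire causal locus (dominant rule; a
recessive mode exists behind the scenario flag). No crossover interference
is modelled beyond the centromere rejection.

**Suppressors and hairpin rescue.** Each suppressor overwrites the shared
planted 1-kb interval to HYPER plus 0–3 private 1-kb HYPER loci placed
uniformly outside the shared interval (stream keyed by suppressor index).
Hairpin rescue attaches per-context overrides to target-family elements:
CHG and CHH sites inside them are simulated at METH-level probabilities
while CG keeps the underlying HYPO level, matching RNA-directed
methylation's context signature.

## Analysis choices

- **Weighted levels.** Window methylation is count-weighted
  (Σmeth / Σreads), robust to uneven coverage; mean-of-site-fractions is
  available (`method="mean"`) for sensitivity checks. Strands are combined.
- **Mapping contrast.** Per-window `delta = fertile − sterile` in one
  context; the default context is CG (largest METH–HYPO gap) and the
  default threshold 0.3 (roughly two-thirds of the expected pooled-signal
  delta of ≈0.44 when every sterile pool member is heterozygous HYPO/METH:
  fertile ≈ 0.90 vs sterile ≈ (0.90+0.02)/2 ≈ 0.46). Missing windows break
  runs — conservative interval calls. How the original comparison was
  operationalized (difference vs ratio, thresholds) is not stated anywhere
  authoritative; difference-with-threshold is this package's choice.
- **Pools.** The sterile/fertile pools take the first 10 individuals of
  each phenotype by identifier, mirroring 10+10 pooling; configurable.
- **Fine mapping.** A marker co-segregates iff present in all steriles and
  absent in all fertiles (undetermined calls ignored); the candidate
  interval spans the best run of co-segregating markers, bounded
  *exclusively* by the nearest contradicting markers or chromosome ends —
  the interval-between-flanking-markers convention.
- **DMR rule.** "Total methylation" is the sum of the three per-context
  weighted levels (range 0–3), not pooled counts (a pooled-count variant
  was considered and rejected as a different statistic; the summed-levels
  reading matches the stated procedure). Inequalities are strict. Windows
  with zero/missing control totals are ineligible. Merge gap is 0: only
  directly adjacent qualifying windows merge, which reproduces ~1-kb DMRs
  at 300-bp granularity. Window-level (not region-level) passing is
  required. Recovery uses the control as denominator; an incremental
  variant `(sup−mut)/(ctrl−mut)` is available.
- **Metaprofiles.** Element bodies are scaled to `body_bins` (default 100)
  equal-width bins, flanks fixed-width (2 kb in 20 bins); minus-strand
  elements are reversed so bin 1 is the 5′ end. Bins average per-element
  means with equal element weights — the "mean of n elements" convention —
  and report per-bin contributing counts. Missing data are excluded from
  means. Log-ratio tracks use pseudocount 0.5.
- **Cytology.** Exact methods throughout (n = 50–100): Clopper–Pearson via
  beta quantiles, Fisher's exact test via the hypergeometric law. One
  attributed chromosome per abnormal cell (multi-laggard cells resolved
  uniformly). Cohesion loss = more than two foci; the 1-focus class is
  reported but excluded from the loss definition. The attribution
  denominator is abnormal cells (not mis-segregation events).

## Numerical notes

- Coordinates are 0-based half-open internally; cytosine reports are
  1-based and BED/bedGraph 0-based, converted only at I/O.
- Beta sampling degenerates gracefully: ρ ≤ 1e−9 or p ∈ {0, 1} uses the
  point mass (the binomial limit).
- Cytosines within two bases of the relevant sequence end have no defined
  context and are skipped genome-wide.
- Linked regions rank by (window count, mean delta, leftmost); DMR windows
  qualify strictly; interval utilities treat adjacency (end == start) as
  non-overlap.
- Crossover rejection sampling aborts with an error if the acceptance
  region is degenerate (e.g. suppression 0 with a genome-spanning
  centromere).

## What the planted-truth tests show

The recovery studies (shared-DMR recovery in 50/50 replicates; top linked
region containing the causal locus in ≥95/100 replicates; hairpin CHH
specificity at α = 0.01 in 20/20 replicates) demonstrate that the
implemented rules recover what the generator plants *under the generator's
assumptions*: independent beta-binomial counts, clean epigenotype
boundaries, uniform coverage, no mapping bias. They do not establish
performance on real bisulfite data, where repeat mappability, conversion
failure and copy-number variation add structured noise the generator
deliberately omits. The replicate studies hold the reference genome fixed
(as resequencing replicates would) and vary crossover and sequencing
randomness only.

## Known limitations

- No small-RNA, ChIP read-level or long-read signal simulation; enrichment
  tracks enter as bedGraph inputs.
- No statistical significance model for the mapping contrast (none is used
  in the procedure modelled); the threshold is a tuning parameter.
- No hypo-DMR calling and no per-cytosine DMR tests — the implemented rule
  is the deterministic threshold rule.
- The crossover model has no interference and integer-uniform placement;
  fine-scale recombination structure is out of scope.
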