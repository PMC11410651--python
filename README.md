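# epicenmap

Simulation-backed pipeline for mapping **epigenetically inherited phenotypes**
and analysing **centromeric methylomes** in plants. It targets the study
design in which a chromatin-remodeler mutant (a *ddm1*-type background)
heritably hypomethylates pericentromeric repeats, a dominant phenotype
(sterility) travels with one hypomethylated centromere through crosses, and
epiallelic suppressors or hairpin RNAi restore methylation at the causal
retrotransposon locus.

The package provides, as tested reusable components:

- **Synthetic epigenome generator** — genomes with satellite-array
  centromeres interrupted by retrotransposon elements; run-length
  epigenotype haplotypes (METH / HYPO / HYPER); bisulfite methylomes with
  Poisson coverage and beta-binomial counts per (epigenotype, context);
  epi-recombinant populations with centromere-suppressed crossovers;
  suppressor epialleles and hairpin-RNAi rescue.
- **Bulked-segregant epigenotype mapping** — count-level pooling of fertile
  vs sterile methylomes, fixed-window (100 kb) weighted-methylation
  contrast, linked-region calling, McrBC-marker epigenotyping and
  fine mapping.
- **Suppressor hyper-DMR calling** — 300-bp windows, total methylation
  `m = m_CG + m_CHG + m_CHH`, the retention/recovery rule
  (`mutant/control < 0.40` and `suppressor/control > 0.60`), adjacent-window
  merging, multi-suppressor intersection and Venn partitioning.
- **Metaprofiles** — log2(IP/input) enrichment tracks, fixed-window track
  averaging, and element-anchored metaplots with scaled bodies and fixed
  flanks (equal element weighting).
- **Cytology statistics** — anaphase mis-segregation simulation and rates
  with exact Clopper–Pearson intervals, FISH chromosome attribution, FISH
  cohesion-focus distributions, Fisher's exact comparisons.

## The statistics in brief

Weighted methylation of a region, per context `c`:
`m_c = sum(methylated reads) / sum(all reads)` over covered cytosines.
The mapping contrast per window is `delta = m_CG(fertile) − m_CG(sterile)`;
maximal runs of windows with `delta ≥ 0.3` are candidate linked regions,
ranked by run length, then mean delta. The hyper-DMR rule on 300-bp windows
uses the total level `m = m_CG + m_CHG + m_CHH ∈ [0, 3]`: a window is a
suppressor DMR window iff `m_mut/m_ctrl < 0.40` and `m_sup/m_ctrl > 0.60`.
Read counts are simulated per cytosine as coverage `N ~ Poisson(λ)` and
methylated count `k | N ~ BetaBinomial(N, p, ρ)` with `p` set by the
(epigenotype, context) pair and overdispersion `ρ = 0.1`.

## Worked example

```python
import epicenmap as em

scenario = em.default_scenario()          # 5 chromosomes, causal locus in Cen5
result = em.run_mapping_scenario(scenario, seed=1)
top = result.top_region
print(top.chrom, top.start, top.end, round(top.mean_delta, 3))
```

prints

```
Chr5 200000 400000 0.432
```

— the top-ranked phenotype-linked hypomethylated region spans the centromere
of chromosome 5 (the packaged scenario plants the dominant sterility locus at
Chr5:295,000–297,000) with a mean fertile-minus-sterile CG difference of
0.432, i.e. the sterile pool is hypomethylated there, as expected when every
sterile individual carries the HYPO epiallele over the locus while the
recurrent-parent haplotype stays methylated.

The same pipeline is available from the shell:

```bash
epicenmap simulate --seed 1 --out-dir cohort/
epicenmap map --fertile cohort/fertile_pool.cx.gz \
              --sterile cohort/sterile_pool.cx.gz \
              --window 100000 --context CG --threshold 0.3
# -> top linked region: Chr5:200000-400000 (2 windows, mean delta 0.431)
```

plus `epicenmap dmr`, `epicenmap metaplot` and `epicenmap cytology` for the
other analyses (see `--help`).

## Layout

```
src/epicenmap/
  config.py      scenario files (flat key=value; packaged default in data/)
  genome.py      synthetic genomes, cytosine context classification
  haplotypes.py  run-length epigenotype haplotypes with context overrides
  methylome.py   beta-binomial methylome simulation (single and pooled)
  cross.py       epi-recombinant crosses, suppressors, hairpin rescue
  io.py          cytosine reports, BED, bedGraph, FASTA (gzip transparent)
  windows.py     fixed windows, weighted levels, count-level pooling
  mapping.py     pooled contrast, linked regions, McrBC markers, fine mapping
  dmr.py         hyper-DMR rule, intersection, Venn counts
  tracks.py      signal tracks, log2 enrichment, element metaprofiles
  cytology.py    mis-segregation / cohesion statistics
  scenarios.py   end-to-end drivers for the packaged study designs
  cli.py         the `epicenmap` command
```
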