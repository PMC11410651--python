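# Default synthetic-epigenome scenario: five chromosomes with a dominant,
# epigenetically inherited sterility locus in the centromere of Chr5,
# mirroring the layout of a ddm1-derived epi-recombinant mapping study.
# Coordinates are 0-based half-open; probabilities are per-read methylation
# chances for each (epigenotype, context) pair.

n_chromosomes = 5
chromosome_length = 600000
centromere_start = 200000
centromere_end = 400000

element_chromosome = Chr5
athila5_count = 8
athila_other_count = 20
element_length = 3000
satellite_monomer_length = 178
satellite_divergence = 0.05

causal_chrom = Chr5
causal_start = 295000
causal_end = 297000
dominant = true

crossover_mean = 1.5
centromere_suppression = 0.05

population_size = 200
pool_size = 10

planted_dmr_chrom = Chr5
planted_dmr_start = 300600
planted_dmr_end = 301600
private_locus_min = 0
private_locus_max = 3
private_locus_length = 1000

hairpin_family = ATHILA5

coverage = 20
overdispersion = 0.10
meth_cg = 0.90
meth_chg = 0.50
meth_chh = 0.20
hypo_cg = 0.02
hypo_chg = 0.02
hypo_chh = 0.10
hyper_cg = 0.90
hyper_chg = 0.70
hyper_chh = 0.50

seed = 0
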