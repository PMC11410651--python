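"""End-to-end drivers for the packaged study designs.

Each driver runs one complete analysis on synthetic data: bulked-segregant
mapping of the sterility epiallele, suppressor hyper-DMR calling with
four-way intersection, and hairpin-rescue methylation profiling.  All
randomness derives from a single seed; a prebuilt genome may be supplied
to hold the reference assembly fixed across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ScenarioConfig, default_scenario
from .cross import (FERTILE, STERILE, SimIndividual, apply_hairpin_rescue,
                    apply_suppressor, simulate_cross)
from .dmr import DMRSet, call_hyper_dmrs, intersect_dmr_sets, venn_counts
from .errors import InputError
from .genome import GenomeModel, build_genome
from .haplotypes import EpiHaplotype
from .mapping import LinkedRegion, call_linked_region, pool_contrast
from .methylome import (MethylationParams, simulate_methylome,
                        simulate_pool_methylome)
from .tracks import TrackIndex, methylation_track
from .windows import make_windows, pool_profiles, window_table


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2 ** 31)) for s in state]


def select_pools(individuals: list[SimIndividual], pool_size: int):
    """First ``pool_size`` fertile and sterile individuals by identifier."""
    fertile = [i for i in individuals if i.phenotype == FERTILE][:pool_size]
    sterile = [i for i in individuals if i.phenotype == STERILE][:pool_size]
    if len(fertile) < pool_size or len(sterile) < pool_size:
        raise InputError(
            f"population yields {len(fertile)} fertile / {len(sterile)} sterile "
            f"individuals; pools of {pool_size} requested"
        )
    return fertile, sterile


@dataclass
class MappingResult:
    regions: list[LinkedRegion]
    contrast: pd.DataFrame
    genome: GenomeModel
    individuals: list[SimIndividual]
    fertile_pool: list[SimIndividual]
    sterile_pool: list[SimIndividual]

    @property
    def top_region(self) -> LinkedRegion | None:
        return self.regions[0] if self.regions else None


def run_mapping_scenario(
    scenario: ScenarioConfig | None = None,
    seed: int = 0,
    genome: GenomeModel | None = None,
    window_size: int = 100_000,
    context: str = "CG",
    threshold: float = 0.3,
    method: str = "individual",
) -> MappingResult:
    """Pooled fertile-vs-sterile contrast mapping on one simulated cohort.

    Simulates the epi-recombinant population, pools the first
    ``pool_size`` sterile and fertile individuals at count level, computes
    the fixed-window contrast in ``context`` and calls linked regions.
    ``method="individual"`` simulates each pool member's methylome and sums
    counts; ``method="pooled"`` draws the pooled counts directly from their
    identical joint law (faster for replicate studies).
    """
    scenario = scenario or default_scenario()
    if method not in ("individual", "pooled"):
        raise InputError(f"unknown method {method!r}")
    genome_seed, cross_seed, fertile_seed, sterile_seed = _child_seeds(seed, 4)
    if genome is None:
        genome = build_genome(scenario, genome_seed)
    individuals = simulate_cross(genome, scenario, cross_seed)
    fertile, sterile = select_pools(individuals, scenario.pool_size)
    params = MethylationParams.from_scenario(scenario)
    contexts = (context,)

    def pool_profile(members, pool_seed):
        if method == "pooled":
            return simulate_pool_methylome(
                genome, [m.haplotypes for m in members], params, pool_seed,
                contexts=contexts,
            )
        member_seeds = _child_seeds(pool_seed, len(members))
        profiles = [
            simulate_methylome(genome, m.haplotypes, params, s, contexts=contexts)
            for m, s in zip(members, member_seeds)
        ]
        return pool_profiles(profiles)

    fertile_prof = pool_profile(fertile, fertile_seed)
    sterile_prof = pool_profile(sterile, sterile_seed)
    windows = make_windows(genome.chromosomes, window_size)
    fertile_wt = window_table(fertile_prof, windows)
    sterile_wt = window_table(sterile_prof, windows)
    contrast = pool_contrast(fertile_wt, sterile_wt, context)
    regions = call_linked_region(contrast, threshold)
    return MappingResult(regions, contrast, genome, individuals, fertile, sterile)


@dataclass
class SuppressorResult:
    dmr_sets: list[DMRSet]
    shared: list[tuple[str, int, int]]
    venn: dict[tuple[str, ...], int]
    planted: tuple[str, int, int]
    private_loci: dict[str, list[tuple[str, int, int]]]
    genome: GenomeModel = field(repr=False)


def run_suppressor_scenario(
    scenario: ScenarioConfig | None = None,
    seed: int = 0,
    genome: GenomeModel | None = None,
    n_suppressors: int = 4,
    window_size: int = 300,
    chromosomes: tuple[str, ...] = ("Chr5",),
) -> SuppressorResult:
    """Suppressor hyper-DMR calling with multi-suppressor intersection.

    Control is the fully methylated epigenotype, the mutant fully
    hypomethylated; each suppressor adds the shared planted HYPER locus
    plus its private loci.  DMRs are called on ``window_size`` windows of
    the selected chromosomes and intersected across suppressors.
    """
    scenario = scenario or default_scenario()
    seeds = _child_seeds(seed, 3 + 2 * n_suppressors)
    genome_seed, control_seed, mutant_seed = seeds[:3]
    if genome is None:
        genome = build_genome(scenario, genome_seed)
    params = MethylationParams.from_scenario(scenario)
    control_hap = EpiHaplotype.uniform(genome.chromosomes, "METH")
    mutant_hap = EpiHaplotype.uniform(genome.chromosomes, "HYPO")

    windows = make_windows(
        {c: genome.chrom_length(c) for c in chromosomes}, window_size
    )
    control_wt = window_table(
        simulate_methylome(genome, control_hap, params, control_seed,
                           chromosomes=chromosomes),
        windows,
    )
    mutant_wt = window_table(
        simulate_methylome(genome, mutant_hap, params, mutant_seed,
                           chromosomes=chromosomes),
        windows,
    )
    shared_iv = (scenario.planted_dmr_chrom, scenario.planted_dmr_start,
                 scenario.planted_dmr_end)
    dmr_sets = []
    private_loci: dict[str, list[tuple[str, int, int]]] = {}
    for i in range(n_suppressors):
        plant_seed, meth_seed = seeds[3 + 2 * i], seeds[4 + 2 * i]
        label = f"sup{i + 1}"
        sup_hap = apply_suppressor(mutant_hap, scenario, i, plant_seed)
        private_loci[label] = [
            (chrom, s, e)
            for chrom, segs in sup_hap.segments.items()
            for s, e, st in segs
            if st == "HYPER" and (chrom, s, e) != shared_iv
        ]
        sup_wt = window_table(
            simulate_methylome(genome, sup_hap, params, meth_seed,
                               chromosomes=chromosomes),
            windows,
        )
        dmr_sets.append(call_hyper_dmrs(control_wt, mutant_wt, sup_wt, label=label))
    shared = intersect_dmr_sets(dmr_sets)
    return SuppressorResult(
        dmr_sets, shared, venn_counts(dmr_sets), shared_iv, private_loci, genome
    )


@dataclass
class HairpinResult:
    target_means: dict[str, np.ndarray]      # context -> per-element means
    other_means: dict[str, np.ndarray]
    genome: GenomeModel = field(repr=False)


def run_hairpin_scenario(
    scenario: ScenarioConfig | None = None,
    seed: int = 0,
    genome: GenomeModel | None = None,
    contexts: tuple[str, ...] = ("CG", "CHH"),
    chromosomes: tuple[str, ...] = ("Chr5",),
    other_family: str = "ATHILA_other",
) -> HairpinResult:
    """Hairpin-RNAi rescue profiling over target vs non-target elements.

    Simulates a hypomethylated epigenotype carrying the hairpin rescue
    (CHG/CHH restored to METH levels over the target family, CG untouched)
    and returns per-element mean methylation for target and non-target
    element families, per context.
    """
    scenario = scenario or default_scenario()
    genome_seed, meth_seed = _child_seeds(seed, 2)
    if genome is None:
        genome = build_genome(scenario, genome_seed)
    params = MethylationParams.from_scenario(scenario)
    base = EpiHaplotype.uniform(genome.chromosomes, "HYPO")
    rescued = apply_hairpin_rescue(base, genome, scenario.hairpin_family)
    profile = simulate_methylome(
        genome, rescued, params, meth_seed, contexts=contexts,
        chromosomes=chromosomes,
    )
    chrom_set = set(chromosomes)
    target = genome.elements_of(scenario.hairpin_family)
    target = target[target["chrom"].isin(chrom_set)]
    other = genome.elements_of(other_family)
    other = other[other["chrom"].isin(chrom_set)]
    target_means: dict[str, np.ndarray] = {}
    other_means: dict[str, np.ndarray] = {}
    for context in contexts:
        index = TrackIndex(methylation_track(profile, context))
        target_means[context] = np.array(
            [index.mean(r.chrom, r.start, r.end) for r in target.itertuples()]
        )
        other_means[context] = np.array(
            [index.mean(r.chrom, r.start, r.end) for r in other.itertuples()]
        )
    return HairpinResult(target_means, other_means, genome)
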