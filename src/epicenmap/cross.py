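"""Epi-recombinant population simulation and epiallele transforms.

Models the backcross design in which chromosomes carry mosaics of
ddm1-derived hypomethylated (HYPO) and wild-type methylated (METH)
segments: a recombinant haplotype is formed from a fully-HYPO and a
fully-METH parental haplotype with Poisson crossover counts and
centromere-suppressed crossover placement; the recurrent-parent haplotype
is fully METH.  Sterility follows a dominant rule at the causal locus.
Suppressor epialleles plant a shared hypermethylated interval plus private
ones; hairpin rescue restores CHG/CHH (not CG) methylation over a target
element family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ScenarioConfig
from .errors import ConfigurationError, InputError
from .genome import GenomeModel
from .haplotypes import ContextOverride, EpiHaplotype, normalize_segments

STERILE = "sterile"
FERTILE = "fertile"


@dataclass(frozen=True)
class SimIndividual:
    identifier: str
    haplotypes: tuple[EpiHaplotype, EpiHaplotype]
    phenotype: str


def sample_breakpoints(rng, length: int, centromere: tuple[int, int],
                       mean: float, suppression: float,
                       count: int | None = None) -> list[int]:
    """Draw crossover breakpoints for one chromosome.

    The number of crossovers is Poisson(``mean``) unless ``count`` is given.
    Positions are uniform, thinned by rejection inside the centromere with
    acceptance probability ``suppression`` (0 forbids centromeric
    crossovers entirely).
    """
    k = int(rng.poisson(mean)) if count is None else count
    lo, hi = centromere
    points: list[int] = []
    attempts = 0
    while len(points) < k:
        attempts += 1
        if attempts > 1000 * (k + 1):
            raise InputError("crossover rejection sampling failed to converge")
        x = int(rng.integers(0, length))
        if lo <= x < hi and rng.random() >= suppression:
            continue
        points.append(x)
    return sorted(points)


def gamete_segments(length: int, breakpoints, first_state: str,
                    second_state: str):
    """Alternate parental states along a chromosome at the breakpoints."""
    states = (first_state, second_state)
    parity = 0
    cursor = 0
    segs = []
    for bp in breakpoints:
        segs.append((cursor, bp, states[parity]))
        cursor = bp
        parity ^= 1
    segs.append((cursor, length, states[parity]))
    return normalize_segments(segs)


def phenotype_of(haplotypes, scenario: ScenarioConfig) -> str:
    """Apply the inheritance rule at the causal locus.

    Dominant (default): sterile iff any haplotype is HYPO over the entire
    causal locus.  Recessive mode requires all haplotypes to be.
    """
    chrom = scenario.causal_chrom
    a, b = scenario.causal_start, scenario.causal_end
    hypo = [h.is_uniform(chrom, a, b, "HYPO") for h in haplotypes]
    affected = any(hypo) if scenario.dominant else all(hypo)
    return STERILE if affected else FERTILE


def simulate_cross(genome: GenomeModel, scenario: ScenarioConfig,
                   seed: int) -> list[SimIndividual]:
    """Simulate the epi-recombinant population.

    Each individual carries one recombinant haplotype (fully-HYPO x
    fully-METH gamete) and one fully-METH recurrent-parent haplotype.
    Deterministic given seed.
    """
    if scenario.population_size <= 0:
        raise ConfigurationError("population_size must be positive")
    rng = np.random.default_rng(seed)
    lengths = dict(genome.chromosomes)
    meth_hap = EpiHaplotype.uniform(genome.chromosomes, "METH")
    out = []
    for i in range(scenario.population_size):
        segs = {}
        for chrom, length in genome.chromosomes:
            bps = sample_breakpoints(
                rng, length, genome.centromeres[chrom],
                scenario.crossover_mean, scenario.centromere_suppression,
            )
            first = "HYPO" if rng.integers(2) == 0 else "METH"
            second = "METH" if first == "HYPO" else "HYPO"
            segs[chrom] = gamete_segments(length, bps, first, second)
        recombinant = EpiHaplotype(segs)
        recombinant.validate(lengths)
        haps = (recombinant, meth_hap)
        out.append(
            SimIndividual(f"ind{i:04d}", haps, phenotype_of(haps, scenario))
        )
    return out


def apply_suppressor(base: EpiHaplotype, scenario: ScenarioConfig,
                     suppressor_index: int, seed: int) -> EpiHaplotype:
    """Plant the shared suppressor hyper-DMR plus private HYPER loci.

    The shared interval comes from the scenario and is identical for every
    suppressor index; private loci (count drawn from the configured range)
    are placed uniformly in the genome outside the shared interval, with a
    stream unique to ``(seed, suppressor_index)``.
    """
    chrom = scenario.planted_dmr_chrom
    s, e = scenario.planted_dmr_start, scenario.planted_dmr_end
    if chrom not in base.segments:
        raise ConfigurationError(f"planted DMR chromosome {chrom!r} not in haplotype")
    length = base.segments[chrom][-1][1]
    if not (0 <= s < e <= length):
        raise ConfigurationError("planted DMR interval outside chromosome")
    out = base.with_state(chrom, s, e, "HYPER")

    rng = np.random.default_rng([seed, suppressor_index])
    k = int(rng.integers(scenario.private_locus_min,
                         scenario.private_locus_max + 1))
    chroms = list(base.segments)
    lens = np.array([base.segments[c][-1][1] for c in chroms], dtype=float)
    weights = lens / lens.sum()
    plen = scenario.private_locus_length
    placed: list[tuple[str, int, int]] = [(chrom, s, e)]
    for _ in range(k):
        for _attempt in range(10_000):
            ci = int(rng.choice(len(chroms), p=weights))
            c = chroms[ci]
            start = int(rng.integers(0, base.segments[c][-1][1] - plen + 1))
            if all(cc != c or start + plen <= ps or start >= pe
                   for cc, ps, pe in placed):
                break
        else:
            raise ConfigurationError("could not place private locus")
        placed.append((c, start, start + plen))
        out = out.with_state(c, start, start + plen, "HYPER")
    return out


def apply_hairpin_rescue(base: EpiHaplotype, genome: GenomeModel,
                         target_family: str) -> EpiHaplotype:
    """Mark target-family elements for CHG/CHH (not CG) METH-level rescue.

    Over every element of ``target_family`` subsequent methylome simulation
    uses METH probabilities for CHG and CHH sites while CG keeps the
    underlying state; everything else is unchanged.
    """
    elements = genome.elements_of(target_family)
    if elements.empty:
        raise InputError(f"no elements of family {target_family!r}")
    out = base
    for row in elements.itertuples():
        out = out.with_override(
            ContextOverride(row.chrom, row.start, row.end, ("CHG", "CHH"), "METH")
        )
    return out
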