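"""Scenario configuration: the knobs of the synthetic epigenome.

A scenario describes a scaled-down five-chromosome genome, an epigenetically
inherited dominant sterility locus inside the centromere of the fifth
chromosome, an epi-recombinant mapping population, a planted suppressor
hyper-DMR, and a hairpin-RNAi target family.  Scenarios are stored as flat
``key = value`` text files; the packaged default lives in
``epicenmap/data/default_scenario.cfg``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import ConfigurationError, ParseError

STATES = ("METH", "HYPO", "HYPER")
CONTEXTS = ("CG", "CHG", "CHH")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of a synthetic-epigenome study.

    Coordinates are 0-based half-open.  Methylation probabilities are the
    per-read methylation chance for each (epigenotype state, cytosine
    context) pair; ``overdispersion`` is the beta-binomial rho.
    """

    # genome
    n_chromosomes: int = 5
    chromosome_length: int = 600_000
    centromere_start: int = 200_000
    centromere_end: int = 400_000
    element_chromosome: str = "Chr5"
    athila5_count: int = 8
    athila_other_count: int = 20
    element_length: int = 3_000
    satellite_monomer_length: int = 178
    satellite_divergence: float = 0.05
    # causal locus / inheritance
    causal_chrom: str = "Chr5"
    causal_start: int = 295_000
    causal_end: int = 297_000
    dominant: bool = True
    # meiosis
    crossover_mean: float = 1.5
    centromere_suppression: float = 0.05
    # population
    population_size: int = 200
    pool_size: int = 10
    # suppressor epialleles
    planted_dmr_chrom: str = "Chr5"
    planted_dmr_start: int = 300_600
    planted_dmr_end: int = 301_600
    private_locus_min: int = 0
    private_locus_max: int = 3
    private_locus_length: int = 1_000
    # hairpin rescue
    hairpin_family: str = "ATHILA5"
    # sequencing model
    coverage: float = 20.0
    overdispersion: float = 0.10
    meth_cg: float = 0.90
    meth_chg: float = 0.50
    meth_chh: float = 0.20
    hypo_cg: float = 0.02
    hypo_chg: float = 0.02
    hypo_chh: float = 0.10
    hyper_cg: float = 0.90
    hyper_chg: float = 0.70
    hyper_chh: float = 0.50
    # reference-genome seed (the assembly the scenario is defined on)
    seed: int = 0

    def __post_init__(self):
        if self.n_chromosomes < 1:
            raise ConfigurationError("need at least one chromosome")
        if self.chromosome_length <= 0:
            raise ConfigurationError("chromosome_length must be positive")
        L = self.chromosome_length
        if not (0 <= self.centromere_start < self.centromere_end <= L):
            raise ConfigurationError("centromere interval outside chromosome")
        names = set(self.chromosome_names)
        for chrom, lo, hi, what in [
            (self.causal_chrom, self.causal_start, self.causal_end, "causal locus"),
            (self.planted_dmr_chrom, self.planted_dmr_start, self.planted_dmr_end,
             "planted DMR"),
        ]:
            if chrom not in names:
                raise ConfigurationError(f"{what} chromosome {chrom!r} not in genome")
            if not (0 <= lo < hi <= L):
                raise ConfigurationError(f"{what} interval outside chromosome")
        if not (0.0 <= self.centromere_suppression <= 1.0):
            raise ConfigurationError("centromere_suppression must be in [0, 1]")
        if self.pool_size <= 0 or self.population_size <= 0:
            raise ConfigurationError("population and pool sizes must be positive")
        if self.private_locus_min > self.private_locus_max:
            raise ConfigurationError("private locus range reversed")
        if self.coverage <= 0:
            raise ConfigurationError("coverage must be positive")
        if not (0.0 <= self.overdispersion < 1.0):
            raise ConfigurationError("overdispersion must be in [0, 1)")
        for state, ctx in [(s, c) for s in STATES for c in CONTEXTS]:
            p = self.probability(state, ctx)
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{state}/{ctx} probability outside [0, 1]")

    # -- derived views ------------------------------------------------------

    @property
    def chromosome_names(self) -> tuple[str, ...]:
        return tuple(f"Chr{i + 1}" for i in range(self.n_chromosomes))

    @property
    def chromosomes(self) -> list[tuple[str, int]]:
        return [(name, self.chromosome_length) for name in self.chromosome_names]

    def probability(self, state: str, context: str) -> float:
        return getattr(self, f"{state.lower()}_{context.lower()}")

    def probabilities(self) -> dict[tuple[str, str], float]:
        return {(s, c): self.probability(s, c) for s in STATES for c in CONTEXTS}

    def replace(self, **changes) -> "ScenarioConfig":
        return dataclasses.replace(self, **changes)

    # -- file I/O -----------------------------------------------------------

    @classmethod
    def from_file(cls, path) -> "ScenarioConfig":
        values = {}
        fieldmap = {f.name: f for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ParseError("expected 'key = value'", lineno)
                key, _, value = (t.strip() for t in line.partition("="))
                if key not in fieldmap:
                    raise ParseError(f"unknown scenario key {key!r}", lineno)
                values[key] = _coerce(value, fieldmap[key].type, key, lineno)
        return cls(**values)

    def to_file(self, path) -> None:
        lines = [
            f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def _coerce(value: str, typ, key: str, lineno: int):
    typ = str(typ)
    try:
        if "bool" in typ:
            if value.lower() in ("true", "1", "yes"):
                return True
            if value.lower() in ("false", "0", "no"):
                return False
            raise ValueError(value)
        if "int" in typ:
            return int(value)
        if "float" in typ:
            return float(value)
        return value
    except ValueError as exc:
        raise ParseError(f"bad value for {key!r}: {value!r}", lineno) from exc


def default_scenario() -> ScenarioConfig:
    """The packaged mapping/suppressor scenario."""
    ref = resources.files("epicenmap.data").joinpath("default_scenario.cfg")
    with resources.as_file(ref) as path:
        return ScenarioConfig.from_file(path)
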