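"""Synthetic genome models: chromosomes, centromeres, repeat annotations.

The genome emulates the layout of a plant chromosome whose centromere is a
tandem satellite array interrupted by retrotransposon insertions: uniform
random arm sequence, a centromeric interval filled with diverged copies of a
short satellite monomer, and annotated retrotransposon elements (the target
family plus a background family) embedded in the satellite array.  Sequence
composition only matters insofar as it yields realistic densities of CG, CHG
and CHH cytosines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CONTEXTS, ScenarioConfig
from .errors import ConfigurationError, ContextBoundaryError, InputError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = (ord(b) for b in "ACGT")

CONTEXT_CODES = {c: i for i, c in enumerate(CONTEXTS)}  # CG=0, CHG=1, CHH=2


def classify_context(sequence: str, position: int, strand: str) -> str:
    """Assign the methylation context of one cytosine.

    Parameters
    ----------
    sequence : str
        Plus-strand nucleotide sequence.
    position : int
        1-based position of the cytosine.  On the minus strand this is the
        position of the plus-strand G.
    strand : {"+", "-"}

    Returns
    -------
    str
        "CG", "CHG" or "CHH", read 5'->3' on the given strand.

    Raises
    ------
    InputError
        If the base at ``position`` is not a cytosine on ``strand``.
    ContextBoundaryError
        If fewer than two bases follow the cytosine in reading direction.
    """
    if strand not in ("+", "-"):
        raise InputError(f"strand must be '+' or '-', got {strand!r}")
    i = position - 1
    if not (0 <= i < len(sequence)):
        raise InputError(f"position {position} outside sequence")
    if strand == "+":
        if sequence[i] != "C":
            raise InputError(f"base at position {position} (+) is not C")
        if i + 2 >= len(sequence):
            raise ContextBoundaryError(f"position {position} too close to 3' end")
        nxt, nxt2 = sequence[i + 1], sequence[i + 2]
        if nxt == "G":
            return "CG"
        return "CHG" if nxt2 == "G" else "CHH"
    if sequence[i] != "G":
        raise InputError(f"base at position {position} (-) is not C (plus-strand G)")
    if i - 2 < 0:
        raise ContextBoundaryError(f"position {position} too close to 5' end")
    # 5'->3' on the minus strand runs leftward on the plus strand; the next
    # minus-strand base is the complement of the plus-strand base to the left.
    if sequence[i - 1] == "C":  # complement G
        return "CG"
    return "CHG" if sequence[i - 2] == "C" else "CHH"


@dataclass
class GenomeModel:
    """A synthetic genome with centromeres and element annotations."""

    chromosomes: list[tuple[str, int]]
    sequences: dict[str, str]
    centromeres: dict[str, tuple[int, int]]
    elements: pd.DataFrame  # columns: chrom, start, end, family, strand
    _site_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate chromosome names")
        lengths = dict(self.chromosomes)
        for name, length in self.chromosomes:
            if length <= 0:
                raise ConfigurationError(f"{name}: non-positive length")
            if len(self.sequences[name]) != length:
                raise ConfigurationError(f"{name}: sequence/length mismatch")
            lo, hi = self.centromeres[name]
            if not (0 <= lo < hi <= length):
                raise ConfigurationError(f"{name}: centromere outside chromosome")
        for row in self.elements.itertuples():
            if row.chrom not in lengths:
                raise ConfigurationError(f"element on unknown chromosome {row.chrom}")
            if not (0 <= row.start < row.end <= lengths[row.chrom]):
                raise ConfigurationError(
                    f"element {row.chrom}:{row.start}-{row.end} outside chromosome"
                )

    @property
    def chromosome_names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def chrom_length(self, chrom: str) -> int:
        return dict(self.chromosomes)[chrom]

    def elements_of(self, family: str) -> pd.DataFrame:
        return self.elements[self.elements["family"] == family].reset_index(drop=True)

    def cytosine_sites(self, chrom: str, contexts=None):
        """All strand-resolved cytosines of a chromosome.

        Returns ``(pos0, minus, ctx)``: 0-based positions, a boolean
        minus-strand flag and int8 context codes (CG=0, CHG=1, CHH=2), sorted
        by (position, strand) with '+' first.  Cytosines within two bases of
        the relevant sequence end are skipped.  Cached per chromosome.
        """
        key = (chrom, tuple(contexts) if contexts is not None else None)
        if key not in self._site_cache:
            base_key = (chrom, None)
            if base_key not in self._site_cache:
                self._site_cache[base_key] = _scan_contexts(self.sequences[chrom])
            pos0, minus, ctx = self._site_cache[base_key]
            if contexts is not None:
                codes = [CONTEXT_CODES[c] for c in contexts]
                keep = np.isin(ctx, codes)
                self._site_cache[key] = (pos0[keep], minus[keep], ctx[keep])
        return self._site_cache[key]


def _scan_contexts(sequence: str):
    b = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    n = b.size
    # plus strand: C with two downstream bases
    pc = np.flatnonzero(b == _C)
    pc = pc[pc <= n - 3]
    nxt, nxt2 = b[pc + 1], b[pc + 2]
    ctx_p = np.where(nxt == _G, 0, np.where(nxt2 == _G, 1, 2)).astype(np.int8)
    # minus strand: plus-strand G with two upstream bases
    mc = np.flatnonzero(b == _G)
    mc = mc[mc >= 2]
    prv, prv2 = b[mc - 1], b[mc - 2]
    ctx_m = np.where(prv == _C, 0, np.where(prv2 == _C, 1, 2)).astype(np.int8)

    pos0 = np.concatenate([pc, mc])
    minus = np.concatenate(
        [np.zeros(pc.size, dtype=bool), np.ones(mc.size, dtype=bool)]
    )
    ctx = np.concatenate([ctx_p, ctx_m])
    order = np.lexsort((minus, pos0))
    return pos0[order], minus[order], ctx[order]


def build_genome(config: ScenarioConfig, seed: int) -> GenomeModel:
    """Construct the reference genome of a scenario.

    Deterministic for identical ``(config, seed)``.  Arms and element bodies
    are i.i.d. uniform nucleotides; centromeric satellite intervals are
    tandem copies of one genome-wide monomer with per-base divergence.
    """
    rng = np.random.default_rng(seed)
    monomer = rng.integers(0, 4, size=config.satellite_monomer_length)

    element_rows = []
    for chrom in config.chromosome_names:
        cen = (config.centromere_start, config.centromere_end)
        placed: list[tuple[int, int]] = []
        fams = []
        if chrom == config.element_chromosome:
            fams += ["ATHILA5"] * config.athila5_count
        n_other, extra = divmod(config.athila_other_count, config.n_chromosomes)
        fams += ["ATHILA_other"] * (
            n_other + (1 if config.chromosome_names.index(chrom) < extra else 0)
        )
        for fam in fams:
            start = _place(rng, cen, config.element_length, placed)
            placed.append((start, start + config.element_length))
            strand = "+" if rng.random() < 0.5 else "-"
            element_rows.append(
                (chrom, start, start + config.element_length, fam, strand)
            )
        # satellite = centromeric complement of the elements
        for s, e in _complement(cen, placed):
            element_rows.append((chrom, s, e, "satellite", "+"))

    elements = (
        pd.DataFrame(element_rows, columns=["chrom", "start", "end", "family", "strand"])
        .sort_values(["chrom", "start"], kind="stable")
        .reset_index(drop=True)
    )

    sequences = {}
    for chrom, length in config.chromosomes:
        arr = rng.integers(0, 4, size=length)
        sat = elements[(elements.chrom == chrom) & (elements.family == "satellite")]
        for row in sat.itertuples():
            span = row.end - row.start
            tiled = np.tile(monomer, span // len(monomer) + 1)[:span].copy()
            mut = rng.random(span) < config.satellite_divergence
            tiled[mut] = rng.integers(0, 4, size=int(mut.sum()))
            arr[row.start:row.end] = tiled
        sequences[chrom] = _BASES[arr].tobytes().decode("ascii")

    return GenomeModel(
        chromosomes=list(config.chromosomes),
        sequences=sequences,
        centromeres={c: (config.centromere_start, config.centromere_end)
                     for c in config.chromosome_names},
        elements=elements,
    )


def _place(rng, bounds, length, placed, max_tries=10_000):
    lo, hi = bounds
    if length > hi - lo:
        raise ConfigurationError("element longer than centromere")
    for _ in range(max_tries):
        start = int(rng.integers(lo, hi - length + 1))
        if all(start + length <= s or start >= e for s, e in placed):
            return start
    raise ConfigurationError("could not place element without overlap")


def _complement(bounds, placed):
    lo, hi = bounds
    out, cursor = [], lo
    for s, e in sorted(placed):
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < hi:
        out.append((cursor, hi))
    return out
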