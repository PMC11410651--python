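"""Bisulfite methylome simulation.

Per cytosine site the read model is Poisson sequencing coverage with a
beta-binomial methylated-read count whose mean is the (epigenotype state,
context) methylation probability and whose overdispersion is the
beta-binomial rho.  Sampling uses the exact Poisson-thinning factorization:
with coverage m ~ Poisson(lam) and per-site methylation chance p' ~
Beta(mean=p, rho), drawing meth ~ Poisson(lam p') and unmeth ~
Poisson(lam (1-p')) independently yields the identical joint law of
(meth, unmeth) while permitting fully vectorized sampling.

A methylome ("MethylationProfile") is a pandas DataFrame with columns
``chrom, pos, strand, meth, unmeth, context`` — one row per strand-resolved
cytosine, ``pos`` 1-based, sorted by (chrom, pos, strand).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import CONTEXTS, STATES, ScenarioConfig
from .errors import InputError
from .genome import GenomeModel
from .haplotypes import EpiHaplotype

PROFILE_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth", "context"]

_RHO_EPS = 1e-9


@dataclass(frozen=True)
class MethylationParams:
    """Per-(state, context) methylation probabilities and the read model.

    ``overdispersion`` is the beta-binomial rho in [0, 1); rho -> 0 recovers
    plain binomial counts.  ``coverage`` is the mean per-cytosine coverage of
    one sample; with a two-haplotype (diploid) sample it is split evenly.
    """

    probabilities: Mapping[tuple[str, str], float] = field(default_factory=dict)
    overdispersion: float = 0.10
    coverage: float = 20.0

    def __post_init__(self):
        if self.coverage <= 0:
            raise InputError("coverage must be positive")
        if not (0.0 <= self.overdispersion < 1.0):
            raise InputError("overdispersion must be in [0, 1)")
        for (state, ctx), p in self.probabilities.items():
            if state not in STATES or ctx not in CONTEXTS:
                raise InputError(f"unknown state/context pair {(state, ctx)!r}")
            if not (0.0 <= p <= 1.0):
                raise InputError(f"probability for {(state, ctx)} outside [0, 1]")

    @classmethod
    def from_scenario(cls, scenario: ScenarioConfig) -> "MethylationParams":
        return cls(
            probabilities=scenario.probabilities(),
            overdispersion=scenario.overdispersion,
            coverage=scenario.coverage,
        )

    def probability(self, state: str, context: str) -> float:
        return self.probabilities[(state, context)]


def default_params(**kwargs) -> MethylationParams:
    """Parameters of the packaged default scenario."""
    from .config import default_scenario

    base = MethylationParams.from_scenario(default_scenario())
    if kwargs:
        from dataclasses import replace

        base = replace(base, **kwargs)
    return base


def _site_chance(rng, p: float, rho: float, size: int) -> np.ndarray:
    """Draw per-site methylation chances Beta(mean=p, var=p(1-p)rho)."""
    if size == 0:
        return np.empty(0)
    if rho <= _RHO_EPS or p <= 0.0 or p >= 1.0:
        return np.full(size, p)
    nu = (1.0 - rho) / rho
    return rng.beta(p * nu, (1.0 - p) * nu, size)


def _normalize_haplotypes(haplotypes) -> tuple[EpiHaplotype, ...]:
    if isinstance(haplotypes, EpiHaplotype):
        haps = (haplotypes,)
    else:
        haps = tuple(haplotypes)
    if not 1 <= len(haps) <= 2:
        raise InputError("expected one or two haplotypes")
    return haps


def simulate_methylome(
    genome: GenomeModel,
    haplotypes,
    params: MethylationParams,
    seed: int,
    contexts: Sequence[str] | None = None,
    chromosomes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Simulate one sample's cytosine-resolution methylome.

    ``haplotypes`` is one :class:`EpiHaplotype` or a pair (diploid sample;
    coverage split evenly).  Every cytosine of the selected chromosomes and
    contexts is emitted, including zero-coverage sites.  Bit-reproducible
    for identical inputs and seed.
    """
    haps = _normalize_haplotypes(haplotypes)
    chroms = list(chromosomes) if chromosomes is not None else genome.chromosome_names
    for hap in haps:
        missing = set(chroms) - set(hap.chromosome_names)
        if missing:
            raise InputError(f"haplotype lacks chromosomes {sorted(missing)}")
    if seed < 0:
        raise InputError("seed must be non-negative")
    lam = params.coverage / len(haps)
    chrom_index = {c: i for i, c in enumerate(genome.chromosome_names)}

    frames = []
    for chrom in chroms:
        pos0, minus, ctx = genome.cytosine_sites(chrom, contexts)
        n = pos0.size
        meth = np.zeros(n, dtype=np.int64)
        unmeth = np.zeros(n, dtype=np.int64)
        for hi, hap in enumerate(haps):
            codes = hap.state_codes(chrom, pos0, ctx)
            for ci, context in enumerate(CONTEXTS):
                ctx_sites = np.flatnonzero(ctx == ci)
                if ctx_sites.size == 0:
                    continue
                ctx_codes = codes[ctx_sites]
                for si, state in enumerate(STATES):
                    local = ctx_codes == si
                    if not local.any():
                        continue
                    # One independent substream per (chromosome, haplotype,
                    # state, context), drawn over every site of the context:
                    # a site's counts depend only on its own state, so
                    # reassigning states elsewhere (e.g. a hairpin override)
                    # leaves all other sites' draws untouched.
                    sub = np.random.default_rng(
                        [seed, chrom_index[chrom], hi, si, ci]
                    )
                    p = params.probability(state, context)
                    chance = _site_chance(sub, p, params.overdispersion,
                                          ctx_sites.size)
                    meth_all = sub.poisson(lam * chance)
                    un_all = sub.poisson(lam * (1.0 - chance))
                    sel = ctx_sites[local]
                    meth[sel] += meth_all[local]
                    unmeth[sel] += un_all[local]
        frames.append(_assemble(chrom, pos0, minus, ctx, meth, unmeth))
    return pd.concat(frames, ignore_index=True) if frames else empty_profile()


def simulate_pool_methylome(
    genome: GenomeModel,
    members,
    params: MethylationParams,
    seed: int,
    contexts: Sequence[str] | None = None,
    chromosomes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Simulate the count-level pool of several samples' methylomes.

    ``members`` is a sequence of haplotypes or haplotype pairs (one entry
    per pooled individual).  The returned counts follow exactly the law of
    simulating each member with :func:`simulate_methylome` and summing
    counts per site, obtained via the Poisson-thinning identity: pooled
    meth ~ Poisson(lam * S) with S the summed per-site beta chances of all
    haplotypes.  Much faster for replicate studies of pooled designs.
    """
    member_haps = [_normalize_haplotypes(m) for m in members]
    if not member_haps:
        raise InputError("empty pool")
    ploidies = {len(h) for h in member_haps}
    if len(ploidies) != 1:
        raise InputError("pool members must have equal haplotype counts")
    lam = params.coverage / ploidies.pop()
    all_haps = [h for member in member_haps for h in member]
    chroms = list(chromosomes) if chromosomes is not None else genome.chromosome_names
    rng = np.random.default_rng(seed)

    frames = []
    for chrom in chroms:
        pos0, minus, ctx = genome.cytosine_sites(chrom, contexts)
        n = pos0.size
        counts = np.zeros((len(STATES), n), dtype=np.int32)
        for hap in all_haps:
            codes = hap.state_codes(chrom, pos0, ctx)
            for si in range(len(STATES)):
                counts[si] += codes == si
        total = np.float64(len(all_haps))
        summed = np.zeros(n)
        for si, state in enumerate(STATES):
            for ci, context in enumerate(CONTEXTS):
                sel = np.flatnonzero(ctx == ci)
                if sel.size == 0:
                    continue
                n_sc = counts[si, sel]
                needed = int(n_sc.sum())
                if needed == 0:
                    continue
                p = params.probability(state, context)
                rho = params.overdispersion
                if rho <= _RHO_EPS or p <= 0.0 or p >= 1.0:
                    summed[sel] += n_sc * p
                    continue
                nu = (1.0 - rho) / rho
                # one beta variate per (site, haplotype) in this group,
                # summed per site via cumulative-sum differences
                flat = rng.beta(p * nu, (1.0 - p) * nu, size=needed)
                cs = np.concatenate([[0.0], np.cumsum(flat)])
                ends = np.cumsum(n_sc)
                summed[sel] += cs[ends] - cs[ends - n_sc]
        meth = rng.poisson(lam * summed)
        unmeth = rng.poisson(lam * (total - summed))
        frames.append(_assemble(chrom, pos0, minus, ctx, meth, unmeth))
    return pd.concat(frames, ignore_index=True) if frames else empty_profile()


def _assemble(chrom, pos0, minus, ctx, meth, unmeth) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos0 + 1,
            "strand": np.where(minus, "-", "+"),
            "meth": np.asarray(meth, dtype=np.int64),
            "unmeth": np.asarray(unmeth, dtype=np.int64),
            "context": pd.Categorical.from_codes(ctx, categories=list(CONTEXTS)),
        }
    )


def empty_profile() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "meth": pd.Series(dtype=np.int64),
            "unmeth": pd.Series(dtype=np.int64),
            "context": pd.Categorical([], categories=list(CONTEXTS)),
        }
    )
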