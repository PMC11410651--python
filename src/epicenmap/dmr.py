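"""Suppressor hyper-DMR calling and multi-suppressor intersection.

A 300-bp window qualifies when the mutant retains less than 40% of the
control's total methylation (sum of the CG, CHG and CHH weighted levels,
range 0-3) while the suppressor recovers more than 60% of it; adjacent
qualifying windows merge into one DMR.  The shared suppressor locus is the
base-pair intersection of the per-suppressor DMR unions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CONTEXTS
from .errors import InputError
from .intervals import by_chrom, intersect_many, partition_membership
from .windows import same_grid


@dataclass(frozen=True)
class DMR:
    chrom: str
    start: int
    end: int
    control_level: float   # mean window total in the control
    mutant_level: float
    suppressor_level: float
    retention: float       # mutant / control of the mean totals
    recovery: float        # suppressor / control (or incremental variant)
    n_windows: int


@dataclass(frozen=True)
class DMRSet:
    label: str
    dmrs: tuple[DMR, ...]

    def intervals(self) -> list[tuple[str, int, int]]:
        return [(d.chrom, d.start, d.end) for d in self.dmrs]


def total_level(levels) -> float:
    """Total methylation of one window: sum of per-context levels (0-3).

    Contexts without covered cytosines contribute 0 when at least one
    context is defined; missing when all three are missing.
    """
    values = np.asarray(
        [levels.get(f"{c}_level", levels.get(c, np.nan)) for c in CONTEXTS]
        if hasattr(levels, "get")
        else list(levels),
        dtype=float,
    )
    if np.isnan(values).all():
        return float("nan")
    return float(np.nansum(values))


def total_levels(table: pd.DataFrame) -> np.ndarray:
    """Vectorized :func:`total_level` over a window table."""
    stack = np.vstack([table[f"{c}_level"].to_numpy(dtype=float) for c in CONTEXTS])
    out = np.nansum(stack, axis=0)
    out[np.isnan(stack).all(axis=0)] = np.nan
    return out


def call_hyper_dmrs(
    control: pd.DataFrame,
    mutant: pd.DataFrame,
    suppressor: pd.DataFrame,
    retention_max: float = 0.40,
    recovery_min: float = 0.60,
    label: str = "suppressor",
    recovery_denominator: str = "control",
) -> DMRSet:
    """Call suppressor-hypermethylated DMRs on aligned window tables.

    A window qualifies iff ``mutant/control < retention_max`` and
    ``suppressor/control > recovery_min`` (strict, as stated); windows with
    zero or missing control total, or any missing total, are ineligible.
    ``recovery_denominator="incremental"`` uses
    ``(suppressor - mutant) / (control - mutant)`` instead.
    """
    if not (same_grid(control, mutant) and same_grid(control, suppressor)):
        raise InputError("window grids differ between genotypes")
    if recovery_denominator not in ("control", "incremental"):
        raise InputError(f"unknown recovery denominator {recovery_denominator!r}")
    ctrl = total_levels(control)
    mut = total_levels(mutant)
    supp = total_levels(suppressor)
    eligible = (~np.isnan(ctrl)) & (~np.isnan(mut)) & (~np.isnan(supp)) & (ctrl > 0)
    retention = np.full(ctrl.shape, np.nan)
    recovery = np.full(ctrl.shape, np.nan)
    with np.errstate(over="ignore"):
        retention[eligible] = mut[eligible] / ctrl[eligible]
    if recovery_denominator == "control":
        with np.errstate(over="ignore"):
            recovery[eligible] = supp[eligible] / ctrl[eligible]
    else:
        denom = ctrl[eligible] - mut[eligible]
        with np.errstate(invalid="ignore", divide="ignore"):
            rec = (supp[eligible] - mut[eligible]) / denom
        recovery[eligible] = np.where(denom > 0, rec, np.nan)
    qualifies = eligible & (retention < retention_max) & (recovery > recovery_min)

    chroms = control["chrom"].to_numpy()
    starts = control["start"].to_numpy()
    ends = control["end"].to_numpy()
    dmrs = []
    i = 0
    while i < len(qualifies):
        if not qualifies[i]:
            i += 1
            continue
        j = i
        # merge gap 0: only directly adjacent windows of one chromosome
        while (
            j + 1 < len(qualifies)
            and qualifies[j + 1]
            and chroms[j + 1] == chroms[i]
            and starts[j + 1] == ends[j]
        ):
            j += 1
        sl = slice(i, j + 1)
        c_mean, m_mean, s_mean = (float(np.mean(x[sl])) for x in (ctrl, mut, supp))
        dmrs.append(
            DMR(
                chrom=str(chroms[i]),
                start=int(starts[i]),
                end=int(ends[j]),
                control_level=c_mean,
                mutant_level=m_mean,
                suppressor_level=s_mean,
                retention=m_mean / c_mean,
                recovery=(
                    s_mean / c_mean
                    if recovery_denominator == "control"
                    else (s_mean - m_mean) / (c_mean - m_mean)
                ),
                n_windows=j - i + 1,
            )
        )
        i = j + 1
    return DMRSet(label=label, dmrs=tuple(dmrs))


def intersect_dmr_sets(sets) -> list[tuple[str, int, int]]:
    """Base-pair intersection of the DMR unions of all sets (>=2 required)."""
    sets = list(sets)
    if len(sets) < 2:
        raise InputError("need at least two DMR sets to intersect")
    per_chrom = [by_chrom(s.intervals()) for s in sets]
    chroms = set(per_chrom[0])
    for other in per_chrom[1:]:
        chroms &= set(other)
    out = []
    for chrom in sorted(chroms):
        for start, end in intersect_many([pc[chrom] for pc in per_chrom]):
            out.append((chrom, start, end))
    return out


def venn_counts(sets) -> dict[tuple[str, ...], int]:
    """Counts of distinct constant-membership intervals per suppressor subset.

    The combined genomic span is partitioned into maximal intervals covered
    by the same subset of suppressors; every non-empty subset of labels maps
    to its interval count (0 included).
    """
    sets = list(sets)
    if len(sets) < 2:
        raise InputError("need at least two DMR sets")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise InputError("duplicate DMR set labels")
    counts = {
        tuple(sorted(combo)): 0
        for r in range(1, len(labels) + 1)
        for combo in itertools.combinations(labels, r)
    }
    chroms = set()
    per_set = []
    for s in sets:
        pc = by_chrom(s.intervals())
        per_set.append(pc)
        chroms |= set(pc)
    for chrom in sorted(chroms):
        named = {
            label: pc.get(chrom, []) for label, pc in zip(labels, per_set)
        }
        for _start, _end, members in partition_membership(named):
            counts[tuple(sorted(members))] += 1
    return counts
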