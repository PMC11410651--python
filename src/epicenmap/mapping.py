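"""Bulked-segregant epigenotype mapping and McrBC fine mapping.

The pooled contrast compares fertile and sterile pool window tables
(fertile minus sterile level per window); runs of windows whose delta
clears a threshold are candidate phenotype-linked hypomethylated regions.
Fine mapping uses methylation-sensitive-digestion PCR markers: McrBC
digests methylated templates, so amplification ("present") is a dominant
marker for a hypomethylated epiallele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cross import STERILE, SimIndividual
from .errors import InputError
from .windows import same_grid, weighted_level

PRESENT = "present"
ABSENT = "absent"
UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class LinkedRegion:
    chrom: str
    start: int
    end: int
    n_windows: int
    mean_delta: float


def pool_contrast(fertile: pd.DataFrame, sterile: pd.DataFrame,
                  context: str = "CG") -> pd.DataFrame:
    """Per-window fertile-minus-sterile methylation difference.

    Both window tables must share the window grid; windows missing in
    either pool get a missing delta.
    """
    if not same_grid(fertile, sterile):
        raise InputError("window grids differ between pools")
    col = f"{context}_level"
    out = fertile[["chrom", "start", "end"]].copy()
    out["fertile"] = fertile[col].to_numpy()
    out["sterile"] = sterile[col].to_numpy()
    out["delta"] = out["fertile"] - out["sterile"]
    return out


def call_linked_region(contrast: pd.DataFrame,
                       threshold: float = 0.3) -> list[LinkedRegion]:
    """Maximal runs of consecutive windows with delta >= threshold.

    Missing deltas break runs.  Regions are ranked by window count, then
    mean delta, then leftmost position.  Empty list when nothing qualifies.
    """
    if not 0.0 < threshold <= 1.0:
        raise InputError("threshold must be in (0, 1]")
    regions = []
    chrom_order = {c: i for i, c in enumerate(dict.fromkeys(contrast["chrom"]))}
    for chrom, sub in contrast.groupby("chrom", sort=False):
        deltas = sub["delta"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        qualifying = np.nan_to_num(deltas, nan=-np.inf) >= threshold
        i = 0
        while i < len(qualifying):
            if qualifying[i]:
                j = i
                while j + 1 < len(qualifying) and qualifying[j + 1]:
                    j += 1
                regions.append(
                    LinkedRegion(
                        chrom=chrom,
                        start=int(starts[i]),
                        end=int(ends[j]),
                        n_windows=j - i + 1,
                        mean_delta=float(np.mean(deltas[i:j + 1])),
                    )
                )
                i = j + 1
            else:
                i += 1
    regions.sort(
        key=lambda r: (-r.n_windows, -r.mean_delta, chrom_order[r.chrom], r.start)
    )
    return regions


def mcrbc_marker(individual, amplicon: tuple[str, int, int],
                 level_threshold: float = 0.2) -> str:
    """McrBC-digestion PCR call for one amplicon.

    Haplotype mode (a :class:`SimIndividual`): amplification succeeds iff
    either haplotype is hypomethylated (HYPO) over the entire amplicon —
    one undigested template suffices, hence a dominant marker.

    Profile mode (a methylome DataFrame): present iff the CG weighted level
    over the amplicon is below ``level_threshold``; amplicons with no
    covered CG site give an undetermined call.
    """
    chrom, start, end = amplicon
    if isinstance(individual, SimIndividual):
        return (
            PRESENT
            if any(h.is_uniform(chrom, start, end, "HYPO")
                   for h in individual.haplotypes)
            else ABSENT
        )
    prof = individual
    sub = prof[
        (prof["chrom"] == chrom)
        & (prof["pos"] - 1 >= start)
        & (prof["pos"] - 1 < end)
    ]
    level = weighted_level(sub, "CG")
    if np.isnan(level):
        return UNDETERMINED
    return PRESENT if level < level_threshold else ABSENT


@dataclass(frozen=True)
class FineMapResult:
    chrom: str | None
    interval: tuple[int, int] | None
    consistent_markers: tuple[str, ...] = ()
    contradictions: tuple[tuple[str, str, str, str], ...] = field(default=())
    # contradictions: (marker, individual, phenotype, call)


def fine_map(markers: pd.DataFrame, phenotypes: dict[str, str],
             chrom_lengths=None) -> FineMapResult:
    """Locate the causal interval from dominant marker observations.

    ``markers`` has one row per (individual, marker) with columns
    ``individual, marker, chrom, start, end, call``.  Under the dominant
    model, a marker co-segregates iff it is present in every sterile and
    absent in every fertile individual (undetermined calls ignored).  The
    returned interval spans the best run of co-segregating markers and is
    bounded exclusively by the nearest flanking contradicting markers (or
    by chromosome ends).  With no co-segregating marker the interval is
    empty and the contradictions are reported.
    """
    required = {"individual", "marker", "chrom", "start", "end", "call"}
    if missing := required - set(markers.columns):
        raise InputError(f"marker table lacks columns {sorted(missing)}")
    if markers.empty:
        raise InputError("need at least one marker observation")
    unphenotyped = set(markers["individual"]) - set(phenotypes)
    if unphenotyped:
        raise InputError(f"individuals without phenotype: {sorted(unphenotyped)}")

    lengths = dict(chrom_lengths) if chrom_lengths is not None else {}
    status: dict[str, str] = {}
    marker_pos: dict[str, tuple[str, int, int]] = {}
    contradictions = []
    for marker_id, sub in markers.groupby("marker", sort=False):
        chrom = sub["chrom"].iloc[0]
        marker_pos[marker_id] = (chrom, int(sub["start"].iloc[0]),
                                 int(sub["end"].iloc[0]))
        determined = sub[sub["call"] != UNDETERMINED]
        if determined.empty:
            status[marker_id] = "uninformative"
            continue
        bad = [
            (marker_id, row.individual, phenotypes[row.individual], row.call)
            for row in determined.itertuples()
            if (phenotypes[row.individual] == STERILE) != (row.call == PRESENT)
        ]
        if bad:
            status[marker_id] = "contradicting"
            contradictions.extend(bad)
        else:
            status[marker_id] = "consistent"

    if not any(s == "consistent" for s in status.values()):
        return FineMapResult(None, None, (), tuple(contradictions))

    # best run of consistent markers per chromosome (uninformative skipped)
    best = None
    for chrom in dict.fromkeys(c for c, _, _ in marker_pos.values()):
        ordered = sorted(
            (m for m, (c, _, _) in marker_pos.items()
             if c == chrom and status[m] != "uninformative"),
            key=lambda m: marker_pos[m][1],
        )
        i = 0
        while i < len(ordered):
            if status[ordered[i]] != "consistent":
                i += 1
                continue
            j = i
            while j + 1 < len(ordered) and status[ordered[j + 1]] == "consistent":
                j += 1
            run = ordered[i:j + 1]
            left = marker_pos[ordered[i - 1]][2] if i > 0 else 0
            right = (
                marker_pos[ordered[j + 1]][1]
                if j + 1 < len(ordered)
                else lengths.get(chrom, marker_pos[ordered[j]][2])
            )
            cand = (len(run), -marker_pos[run[0]][1], chrom, left, right, run)
            if best is None or cand[:2] > best[:2]:
                best = cand
            i = j + 1

    _, _, chrom, left, right, run = best
    return FineMapResult(chrom, (left, right), tuple(run), tuple(contradictions))
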