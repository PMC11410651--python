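"""Epigenotype haplotypes: run-length chromosome states.

An :class:`EpiHaplotype` describes one chromosome set as ordered
``(start, end, state)`` segments with state METH (wild-type methylated),
HYPO (ddm1-derived hypomethylated) or HYPER (suppressor hypermethylated).
Segments tile each chromosome exactly.  Hairpin-RNAi rescue is expressed as
per-context overrides: within targeted elements CHG/CHH sites behave as
METH while CG keeps the underlying state.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple

import numpy as np

from .config import CONTEXTS, STATES
from .errors import InputError

STATE_CODES = {s: i for i, s in enumerate(STATES)}
_CTX_CODES = {c: i for i, c in enumerate(CONTEXTS)}

Segment = tuple[int, int, str]


class ContextOverride(NamedTuple):
    chrom: str
    start: int
    end: int
    contexts: tuple[str, ...]
    state: str


def normalize_segments(segments: Iterable[Segment]) -> list[Segment]:
    """Sort, drop empty segments and merge adjacent equal states."""
    out: list[Segment] = []
    for start, end, state in sorted(segments):
        if state not in STATE_CODES:
            raise InputError(f"unknown state {state!r}")
        if end <= start:
            continue
        if out and out[-1][2] == state and out[-1][1] == start:
            out[-1] = (out[-1][0], end, state)
        else:
            out.append((start, end, state))
    return out


@dataclass(frozen=True)
class EpiHaplotype:
    segments: dict[str, list[Segment]]
    overrides: tuple[ContextOverride, ...] = ()

    @classmethod
    def uniform(cls, chrom_lengths, state: str) -> "EpiHaplotype":
        items = dict(chrom_lengths).items()
        return cls({c: [(0, length, state)] for c, length in items})

    @property
    def chromosome_names(self) -> list[str]:
        return list(self.segments)

    def validate(self, chrom_lengths=None) -> None:
        """Check that segments tile each chromosome: no gaps, no overlaps."""
        lengths = dict(chrom_lengths) if chrom_lengths is not None else None
        for chrom, segs in self.segments.items():
            if not segs:
                raise InputError(f"{chrom}: no segments")
            cursor = 0
            for start, end, state in segs:
                if state not in STATE_CODES:
                    raise InputError(f"{chrom}: unknown state {state!r}")
                if start != cursor or end <= start:
                    raise InputError(f"{chrom}: segments do not tile at {start}")
                cursor = end
            if lengths is not None and cursor != lengths[chrom]:
                raise InputError(f"{chrom}: segments end at {cursor}, "
                                 f"expected {lengths[chrom]}")

    # -- queries ------------------------------------------------------------

    def state_at(self, chrom: str, pos0: int) -> str:
        for start, end, state in self.segments[chrom]:
            if start <= pos0 < end:
                return state
        raise InputError(f"{chrom}:{pos0} not covered by any segment")

    def state_codes(self, chrom: str, pos0: np.ndarray,
                    ctx_codes: np.ndarray | None = None) -> np.ndarray:
        """Vectorized state lookup, applying per-context overrides."""
        segs = self.segments[chrom]
        starts = np.array([s for s, _, _ in segs])
        seg_codes = np.array([STATE_CODES[st] for _, _, st in segs], dtype=np.int8)
        idx = np.searchsorted(starts, pos0, side="right") - 1
        if (idx < 0).any() or (pos0 >= segs[-1][1]).any():
            raise InputError(f"positions outside segments of {chrom}")
        codes = seg_codes[idx]
        for ov in self.overrides:
            if ov.chrom != chrom:
                continue
            mask = (pos0 >= ov.start) & (pos0 < ov.end)
            if ctx_codes is not None:
                ctx_sel = np.isin(
                    ctx_codes, [_CTX_CODES[c] for c in ov.contexts]
                )
                mask &= ctx_sel
            codes = np.where(mask, np.int8(STATE_CODES[ov.state]), codes)
        return codes

    def is_uniform(self, chrom: str, start: int, end: int, state: str) -> bool:
        """True if every position of [start, end) carries ``state``.

        Overrides are ignored: this queries the underlying epigenotype.
        """
        if end <= start:
            raise InputError("empty interval")
        covered = start
        for s, e, st in self.segments[chrom]:
            if e <= covered or s >= end:
                continue
            if st != state:
                return False
            covered = max(covered, e)
            if covered >= end:
                return True
        return covered >= end

    # -- transforms ---------------------------------------------------------

    def with_state(self, chrom: str, start: int, end: int,
                   state: str) -> "EpiHaplotype":
        """Return a copy with [start, end) overwritten to ``state``."""
        if chrom not in self.segments:
            raise InputError(f"unknown chromosome {chrom!r}")
        if end <= start:
            raise InputError("empty interval")
        pieces: list[Segment] = []
        for s, e, st in self.segments[chrom]:
            if e <= start or s >= end:
                pieces.append((s, e, st))
            else:
                if s < start:
                    pieces.append((s, start, st))
                if e > end:
                    pieces.append((end, e, st))
        pieces.append((start, end, state))
        new = dict(self.segments)
        new[chrom] = normalize_segments(pieces)
        return replace(self, segments=new)

    def with_override(self, override: ContextOverride) -> "EpiHaplotype":
        return replace(self, overrides=self.overrides + (override,))
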