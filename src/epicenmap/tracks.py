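"""Signal tracks, log-ratio enrichment and element-anchored metaprofiles.

A signal track is a DataFrame (chrom, start, end, value) of sorted,
non-overlapping 0-based half-open intervals carrying a piecewise-constant
value — the in-memory form of a bedGraph.  Metaprofiles average a track
over a set of elements scaled to a common body length with fixed flanks,
weighting every element equally (mean of per-element bin means), the way
published retrotransposon metaplots average "n = 8" elements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

TRACK_COLUMNS = ["chrom", "start", "end", "value"]


def validate_track(track: pd.DataFrame) -> None:
    if list(track.columns[:4]) != TRACK_COLUMNS:
        raise InputError(f"track needs columns {TRACK_COLUMNS}")
    for chrom, sub in track.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if (starts >= ends).any():
            raise InputError(f"{chrom}: empty interval in track")
        if (starts[1:] < ends[:-1]).any():
            raise InputError(f"{chrom}: track intervals overlap or are unsorted")


def methylation_track(profile: pd.DataFrame,
                      context: str | None = None) -> pd.DataFrame:
    """Per-position methylation fractions of a methylome as a signal track.

    Counts from the two strands of one position are combined; positions
    without coverage are omitted.
    """
    sub = profile if context is None else profile[profile["context"] == context]
    grouped = sub.groupby(["chrom", "pos"], sort=True, observed=True).agg(
        meth=("meth", "sum"), unmeth=("unmeth", "sum")
    )
    cov = grouped["meth"] + grouped["unmeth"]
    grouped = grouped[cov > 0]
    cov = cov[cov > 0]
    out = grouped.reset_index()
    return pd.DataFrame(
        {
            "chrom": out["chrom"],
            "start": out["pos"] - 1,
            "end": out["pos"],
            "value": (out["meth"] / cov.to_numpy()).to_numpy(),
        }
    )


def log2_enrichment(ip: pd.DataFrame, input_track: pd.DataFrame,
                    pseudocount: float = 0.5) -> pd.DataFrame:
    """log2((IP + pc) / (input + pc)) over every co-covered interval piece."""
    for t, name in ((ip, "IP"), (input_track, "input")):
        validate_track(t)
        if (t["value"].to_numpy() < 0).any():
            raise InputError(f"negative values in {name} track")
    rows = []
    for chrom in dict.fromkeys(ip["chrom"]):
        a = ip[ip["chrom"] == chrom]
        b = input_track[input_track["chrom"] == chrom]
        if b.empty:
            continue
        ai = bi = 0
        av = list(zip(a["start"], a["end"], a["value"]))
        bv = list(zip(b["start"], b["end"], b["value"]))
        while ai < len(av) and bi < len(bv):
            lo = max(av[ai][0], bv[bi][0])
            hi = min(av[ai][1], bv[bi][1])
            if lo < hi:
                value = np.log2((av[ai][2] + pseudocount) / (bv[bi][2] + pseudocount))
                rows.append((chrom, lo, hi, value))
            if av[ai][1] < bv[bi][1]:
                ai += 1
            else:
                bi += 1
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


class TrackIndex:
    """Integral queries against one track: bp-weighted means over spans."""

    def __init__(self, track: pd.DataFrame):
        validate_track(track)
        self._by_chrom = {}
        for chrom, sub in track.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy(dtype=float)
            ends = sub["end"].to_numpy(dtype=float)
            values = sub["value"].to_numpy(dtype=float)
            width = ends - starts
            cum_v = np.concatenate([[0.0], np.cumsum(values * width)])
            cum_w = np.concatenate([[0.0], np.cumsum(width)])
            self._by_chrom[chrom] = (starts, ends, values, cum_v, cum_w)

    def mean(self, chrom: str, start: float, end: float) -> float:
        """Mean value over covered positions in [start, end); NaN if none."""
        if chrom not in self._by_chrom or end <= start:
            return float("nan")
        starts, ends, values, cum_v, cum_w = self._by_chrom[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if lo >= hi:
            return float("nan")
        total_v = cum_v[hi] - cum_v[lo]
        total_w = cum_w[hi] - cum_w[lo]
        # trim the partially overlapping first and last intervals
        left_trim = max(0.0, start - starts[lo])
        total_v -= left_trim * values[lo]
        total_w -= left_trim
        right_trim = max(0.0, ends[hi - 1] - end)
        total_v -= right_trim * values[hi - 1]
        total_w -= right_trim
        return total_v / total_w if total_w > 0 else float("nan")


def average_track(signal: pd.DataFrame, window: int,
                  chrom_lengths=None) -> pd.DataFrame:
    """Mean signal per fixed window; windows without data are omitted."""
    if window <= 0:
        raise InputError("window must be positive")
    if signal.empty:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    index = TrackIndex(signal)
    lengths = (
        dict(chrom_lengths)
        if chrom_lengths is not None
        else signal.groupby("chrom", sort=False)["end"].max().to_dict()
    )
    rows = []
    for chrom, length in lengths.items():
        for start in range(0, int(length), window):
            end = min(start + window, int(length))
            value = index.mean(chrom, start, end)
            if not np.isnan(value):
                rows.append((chrom, start, end, value))
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


@dataclass(frozen=True)
class MetaProfile:
    upstream: np.ndarray        # flank bins, 5' of the element
    body: np.ndarray            # scaled body bins
    downstream: np.ndarray      # flank bins, 3' of the element
    upstream_counts: np.ndarray
    body_counts: np.ndarray
    downstream_counts: np.ndarray
    n_elements: int

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.upstream, self.body, self.downstream])


def _element_bins(start, end, strand, body_bins, flank_bp, flank_bins):
    """Bin edge spans of one element, oriented 5'->3'."""
    body_edges = np.linspace(start, end, body_bins + 1)
    body = list(zip(body_edges[:-1], body_edges[1:]))
    if flank_bins > 0 and flank_bp > 0:
        up_edges = np.linspace(start - flank_bp, start, flank_bins + 1)
        down_edges = np.linspace(end, end + flank_bp, flank_bins + 1)
        up = list(zip(up_edges[:-1], up_edges[1:]))
        down = list(zip(down_edges[:-1], down_edges[1:]))
    else:
        up, down = [], []
    if strand == "-":
        up, down = [(a, b) for a, b in reversed(down)], \
                   [(a, b) for a, b in reversed(up)]
        body = [(a, b) for a, b in reversed(body)]
    return up, body, down


def element_metaprofile(signal: pd.DataFrame, elements: pd.DataFrame,
                        body_bins: int = 100, flank_bp: int = 2000,
                        flank_bins: int = 20) -> MetaProfile:
    """Average a signal over elements scaled to a common length.

    Element bodies are split into ``body_bins`` equal-width bins and flanks
    into fixed-width bins; minus-strand elements are reversed so bin 1 is
    the element 5' end.  Each element contributes the bp-weighted mean of
    its bin, and bins average elements with data (equal element weights).
    Elements shorter than ``body_bins`` fall back to overlap-weighted
    fractional bins automatically.
    """
    if body_bins < 1:
        raise InputError("body_bins must be >= 1")
    if elements.empty:
        raise InputError("empty element set")
    index = TrackIndex(signal)
    n_up = n_down = flank_bins if flank_bp > 0 else 0
    sums = {
        "up": np.zeros(n_up), "body": np.zeros(body_bins), "down": np.zeros(n_down)
    }
    counts = {
        "up": np.zeros(n_up, dtype=int),
        "body": np.zeros(body_bins, dtype=int),
        "down": np.zeros(n_down, dtype=int),
    }
    strands = elements["strand"] if "strand" in elements.columns else None
    for i, row in enumerate(elements.itertuples(index=False)):
        strand = strands.iloc[i] if strands is not None else "+"
        up, body, down = _element_bins(
            row.start, row.end, strand, body_bins, flank_bp, flank_bins
        )
        for part, bins in (("up", up), ("body", body), ("down", down)):
            for k, (a, b) in enumerate(bins):
                value = index.mean(row.chrom, a, b)
                if not np.isnan(value):
                    sums[part][k] += value
                    counts[part][k] += 1
    with np.errstate(invalid="ignore"):
        mean = {
            part: np.where(counts[part] > 0, sums[part] / np.maximum(counts[part], 1),
                           np.nan)
            for part in sums
        }
    return MetaProfile(
        upstream=mean["up"], body=mean["body"], downstream=mean["down"],
        upstream_counts=counts["up"], body_counts=counts["body"],
        downstream_counts=counts["down"], n_elements=len(elements),
    )
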