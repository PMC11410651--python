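"""Fixed-window weighted methylation: the substrate of mapping and DMR calls.

A window table holds, per window and per context, the summed methylated and
total read counts, the count-weighted methylation level (sum meth / sum
total; missing where no reads) and the number of covered cytosines.
Count-weighted levels are the default because they are robust to uneven
coverage; a mean-of-site-fractions mode exists for sensitivity checks.
Strands are combined.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .config import CONTEXTS
from .errors import InputError

WINDOW_KEY = ["chrom", "start", "end"]


def make_windows(chrom_lengths, size: int, step: int | None = None) -> pd.DataFrame:
    """Tile chromosomes with fixed windows; the final partial window is kept.

    ``chrom_lengths`` is a mapping or sequence of (name, length).  ``step``
    defaults to ``size``; ``0 < step <= size`` (overlapping windows allowed).
    """
    if size <= 0:
        raise InputError("window size must be positive")
    step = size if step is None else step
    if not 0 < step <= size:
        raise InputError("step must satisfy 0 < step <= size")
    items = dict(chrom_lengths).items()
    rows = []
    for chrom, length in items:
        if length <= 0:
            raise InputError(f"{chrom}: non-positive length")
        start = 0
        while start < length:
            rows.append((chrom, start, min(start + size, length)))
            start += step
    return pd.DataFrame(rows, columns=WINDOW_KEY)


def weighted_level(records: pd.DataFrame, context: str | None = None) -> float:
    """Count-weighted methylation of a record set: sum meth / sum coverage.

    Returns NaN when no reads cover any site of the requested context.
    """
    sub = records if context is None else records[records["context"] == context]
    total = int(sub["meth"].sum() + sub["unmeth"].sum())
    return float(sub["meth"].sum()) / total if total else float("nan")


def window_table(profile: pd.DataFrame, windows: pd.DataFrame,
                 method: str = "weighted") -> pd.DataFrame:
    """Aggregate a methylome into per-window, per-context statistics.

    Output columns per context ``X``: ``X_meth``, ``X_total``, ``X_sites``
    (covered cytosines) and ``X_level``; plus a ``partial`` flag on windows
    shorter than the modal width.  ``method="mean"`` replaces the weighted
    level by the mean of per-site fractions over covered sites.
    """
    if method not in ("weighted", "mean"):
        raise InputError(f"unknown method {method!r}")
    out = windows.reset_index(drop=True).copy()
    width = (out["end"] - out["start"]).max() if len(out) else 0
    out["partial"] = (out["end"] - out["start"]) < width

    chrom_max = out.groupby("chrom")["end"].max()
    bad_chroms = set(profile["chrom"].unique()) - set(chrom_max.index)
    if bad_chroms:
        raise InputError(f"records on chromosomes without windows: {sorted(bad_chroms)}")

    n = len(out)
    cols = {}
    for ctx in CONTEXTS:
        for stat in ("meth", "total", "sites"):
            cols[f"{ctx}_{stat}"] = np.zeros(n, dtype=np.int64)
        cols[f"{ctx}_level"] = np.full(n, np.nan)

    for chrom, win_idx in out.groupby("chrom", sort=False).groups.items():
        win = out.loc[win_idx]
        prof = profile[profile["chrom"] == chrom]
        if prof.empty:
            continue
        pos0 = prof["pos"].to_numpy() - 1
        if pos0.max() >= chrom_max[chrom]:
            raise InputError(
                f"record at {chrom}:{pos0.max() + 1} beyond chromosome length"
            )
        order = np.argsort(pos0, kind="stable")
        pos0 = pos0[order]
        meth = prof["meth"].to_numpy()[order]
        cov = meth + prof["unmeth"].to_numpy()[order]
        ctx_codes = prof["context"].astype(str).to_numpy()[order]
        idx = np.asarray(win_idx)
        lo_all = win["start"].to_numpy()
        hi_all = win["end"].to_numpy()
        for ctx in CONTEXTS:
            sel = ctx_codes == ctx
            if not sel.any():
                continue
            p = pos0[sel]
            cm = np.concatenate([[0], np.cumsum(meth[sel])])
            cc = np.concatenate([[0], np.cumsum(cov[sel])])
            covered = cov[sel] > 0
            cs = np.concatenate([[0], np.cumsum(covered)])
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(covered, meth[sel] / np.maximum(cov[sel], 1), 0.0)
            cf = np.concatenate([[0], np.cumsum(frac)])
            lo = np.searchsorted(p, lo_all)
            hi = np.searchsorted(p, hi_all)
            w_meth = cm[hi] - cm[lo]
            w_cov = cc[hi] - cc[lo]
            w_sites = cs[hi] - cs[lo]
            cols[f"{ctx}_meth"][idx] = w_meth
            cols[f"{ctx}_total"][idx] = w_cov
            cols[f"{ctx}_sites"][idx] = w_sites
            if method == "weighted":
                with np.errstate(invalid="ignore", divide="ignore"):
                    level = np.where(w_cov > 0, w_meth / np.maximum(w_cov, 1), np.nan)
            else:
                w_frac = cf[hi] - cf[lo]
                with np.errstate(invalid="ignore", divide="ignore"):
                    level = np.where(
                        w_sites > 0, w_frac / np.maximum(w_sites, 1), np.nan
                    )
            cols[f"{ctx}_level"][idx] = level

    for name, values in cols.items():
        out[name] = values
    return out


def same_grid(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    return len(a) == len(b) and all(
        (a[k].to_numpy() == b[k].to_numpy()).all() for k in WINDOW_KEY
    )


def pool_profiles(profiles: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Sum per-site counts across samples (count-level pooling).

    Emulates sequencing a pool of individuals.  Raises on an empty input or
    when a site carries conflicting context labels.
    """
    profiles = list(profiles)
    if not profiles:
        raise InputError("cannot pool zero profiles")
    if len(profiles) == 1:
        return profiles[0].copy()
    first = profiles[0]
    key_cols = ["chrom", "pos", "strand"]
    aligned = all(
        len(p) == len(first)
        and all((p[k].to_numpy() == first[k].to_numpy()).all() for k in key_cols)
        for p in profiles[1:]
    )
    if aligned:
        # identical site grids (the common case for simulated cohorts)
        for p in profiles[1:]:
            if not (p["context"].to_numpy() == first["context"].to_numpy()).all():
                raise InputError("conflicting context labels at pooled sites")
        out = first.copy()
        out["meth"] = np.sum([p["meth"].to_numpy() for p in profiles], axis=0)
        out["unmeth"] = np.sum([p["unmeth"].to_numpy() for p in profiles], axis=0)
        return out
    stacked = pd.concat(profiles, ignore_index=True)
    stacked["context"] = stacked["context"].astype(str)
    grouped = stacked.groupby(key_cols, sort=True)
    if (grouped["context"].nunique() > 1).any():
        raise InputError("conflicting context labels at pooled sites")
    out = grouped.agg(
        meth=("meth", "sum"), unmeth=("unmeth", "sum"), context=("context", "first")
    ).reset_index()
    out["context"] = pd.Categorical(out["context"], categories=list(CONTEXTS))
    return out[["chrom", "pos", "strand", "meth", "unmeth", "context"]]


def window_bedgraph(table: pd.DataFrame, context: str) -> pd.DataFrame:
    """Per-context window levels as a signal track (missing windows dropped)."""
    level = table[f"{context}_level"]
    keep = level.notna()
    return pd.DataFrame(
        {
            "chrom": table.loc[keep, "chrom"],
            "start": table.loc[keep, "start"],
            "end": table.loc[keep, "end"],
            "value": level[keep],
        }
    ).reset_index(drop=True)
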