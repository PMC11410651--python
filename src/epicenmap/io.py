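"""Readers and writers for the text formats the pipeline touches.

Formats: the seven-column cytosine report (tab-separated: chrom, 1-based
pos, strand, methylated count, unmethylated count, context, trinucleotide),
BED3/BED6, four-column bedGraph and FASTA.  Cytosine reports are 1-based;
BED and bedGraph are 0-based half-open; all internal computation is 0-based
half-open and conversion happens only here.  Files ending in ``.gz`` are
read and written transparently.
"""

from __future__ import annotations

import gzip
from typing import NamedTuple

import numpy as np
import pandas as pd

from .config import CONTEXTS
from .errors import ParseError
from .genome import GenomeModel

_STRANDS = ("+", "-")


class CytosineRecord(NamedTuple):
    """One strand-resolved cytosine with read counts."""

    chrom: str
    pos: int  # 1-based
    strand: str
    meth: int
    unmeth: int
    context: str

    @property
    def level(self) -> float:
        total = self.meth + self.unmeth
        return self.meth / total if total else float("nan")


def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_cytosine_report(path) -> pd.DataFrame:
    """Parse a cytosine report into a methylome DataFrame.

    Validates strand, context and count columns, reporting the first
    offending line.  Extra columns beyond the seventh are ignored; the
    trinucleotide column is kept (as ``tri``) so that write -> read ->
    write round-trips byte-identically.  Records are sorted by
    (chrom, pos, strand).
    """
    rows = []
    with _open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"expected >=6 tab-separated columns, "
                                 f"got {len(parts)}", lineno)
            chrom, pos_s, strand, meth_s, unmeth_s, context = parts[:6]
            tri = parts[6] if len(parts) > 6 else context
            if strand not in _STRANDS:
                raise ParseError(f"bad strand {strand!r}", lineno)
            if context not in CONTEXTS:
                raise ParseError(f"bad context {context!r}", lineno)
            try:
                pos, meth, unmeth = int(pos_s), int(meth_s), int(unmeth_s)
            except ValueError:
                raise ParseError("non-integer position or counts", lineno) from None
            if pos <= 0:
                raise ParseError(f"non-positive position {pos}", lineno)
            if meth < 0 or unmeth < 0:
                raise ParseError("negative counts", lineno)
            rows.append((chrom, pos, strand, meth, unmeth, context, tri))
    frame = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "meth", "unmeth", "context", "tri"]
    )
    if frame.empty:
        frame = frame.astype(
            {"pos": np.int64, "meth": np.int64, "unmeth": np.int64}
        )
    frame["context"] = pd.Categorical(frame["context"], categories=list(CONTEXTS))
    return frame.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(
        drop=True
    )


def write_cytosine_report(profile: pd.DataFrame, path) -> None:
    """Write a methylome DataFrame as a seven-column cytosine report."""
    frame = profile.sort_values(["chrom", "pos", "strand"], kind="stable")
    tri = frame["tri"] if "tri" in frame.columns else frame["context"].astype(str)
    with _open(path, "wt") as fh:
        for chrom, pos, strand, meth, unmeth, context, t in zip(
            frame["chrom"], frame["pos"], frame["strand"],
            frame["meth"], frame["unmeth"], frame["context"].astype(str), tri,
        ):
            fh.write(f"{chrom}\t{pos}\t{strand}\t{meth}\t{unmeth}\t{context}\t{t}\n")


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6 into a DataFrame (chrom, start, end[, name, score, strand])."""
    rows = []
    n_cols = 3
    with _open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("BED needs >=3 columns", lineno)
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError("non-integer BED coordinates", lineno) from None
            if start < 0 or start >= end:
                raise ParseError(f"invalid interval [{start}, {end})", lineno)
            name = parts[3] if len(parts) > 3 else "."
            score = parts[4] if len(parts) > 4 else "."
            strand = parts[5] if len(parts) > 5 else "."
            if strand not in ("+", "-", "."):
                raise ParseError(f"bad strand {strand!r}", lineno)
            n_cols = max(n_cols, min(len(parts), 6))
            rows.append((chrom, start, end, name, score, strand))
    cols = ["chrom", "start", "end", "name", "score", "strand"][:n_cols]
    frame = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )[cols]
    if frame.empty:
        frame = frame.astype({"start": np.int64, "end": np.int64})
    return frame


def write_bed(intervals: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"]
    for extra in ("name", "score", "strand"):
        if extra in intervals.columns:
            cols.append(extra)
        else:
            break
    with _open(path, "wt") as fh:
        for row in intervals[cols].itertuples(index=False):
            fh.write("\t".join(str(v) for v in row) + "\n")


def elements_to_bed(genome: GenomeModel, path) -> None:
    """Export genome element annotations as BED6 (name = family)."""
    frame = genome.elements.rename(columns={"family": "name"}).copy()
    frame["score"] = 0
    write_bed(frame[["chrom", "start", "end", "name", "score", "strand"]], path)


def read_bedgraph(path) -> pd.DataFrame:
    """Read a four-column bedGraph into a signal track DataFrame."""
    rows = []
    with _open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError("bedGraph needs 4 columns", lineno)
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError:
                raise ParseError("malformed bedGraph fields", lineno) from None
            if start < 0 or start >= end:
                raise ParseError(f"invalid interval [{start}, {end})", lineno)
            rows.append((parts[0], start, end, value))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    if frame.empty:
        frame = frame.astype({"start": np.int64, "end": np.int64, "value": float})
    return frame


def write_bedgraph(track: pd.DataFrame, path) -> None:
    """Write a signal track as bedGraph; values use 6 significant digits."""
    with _open(path, "wt") as fh:
        for chrom, start, end, value in zip(
            track["chrom"], track["start"], track["end"], track["value"]
        ):
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


def write_fasta(genome: GenomeModel, path, width: int = 70) -> None:
    """Export genome sequences as FASTA."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(genome.sequences[name]), id=name, description="")
        for name, _ in genome.chromosomes
    ]
    with _open(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")
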