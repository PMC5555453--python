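"""Readers and writers for the plain-text genomics formats used here.

Internal coordinates are 0-based half-open everywhere.  BED and bedGraph
are already 0-based half-open; RepeatMasker ``.out`` and GFF3 are 1-based
inclusive and are converted at this boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into ``{seq_id: sequence}`` (uppercased)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | os.PathLike, seqs: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | os.PathLike) -> list[tuple[str, int, int, str]]:
    """Read BED3/BED6; returns (seq_id, start, end, name) with name '' if absent."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: line {ln}: expected >=3 BED columns")
            name = parts[3] if len(parts) > 3 else ""
            rows.append((parts[0], int(parts[1]), int(parts[2]), name))
    return rows


def write_bed(path: str | os.PathLike, rows: Iterable[tuple]) -> None:
    """Write rows of (seq_id, start, end[, name[, score[, strand]]]) as BED."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# bedGraph signal tracks

@dataclass
class SignalTrack:
    """Stepwise per-base signal on one sequence (bedGraph semantics).

    Runs are non-overlapping, sorted, 0-based half-open.  Bases not covered
    by any run have value 0.
    """

    seq_id: str
    starts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    ends: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    values: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.starts) == len(self.ends) == len(self.values)):
            raise ValueError("starts/ends/values length mismatch")
        if np.any(self.ends <= self.starts):
            raise ValueError("empty or inverted run")
        if np.any(self.starts[1:] < self.ends[:-1]):
            raise ValueError("runs overlap or are unsorted")

    @classmethod
    def from_dense(cls, seq_id: str, dense: np.ndarray) -> "SignalTrack":
        dense = np.asarray(dense, dtype=float)
        if len(dense) == 0:
            return cls(seq_id)
        change = np.flatnonzero(dense[1:] != dense[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(dense)]))
        return cls(seq_id, starts, ends, dense[starts])

    def to_dense(self, length: int | None = None, fill: float = 0.0) -> np.ndarray:
        n = int(length) if length is not None else (int(self.ends[-1]) if len(self.ends) else 0)
        out = np.full(n, fill, dtype=float)
        starts = np.clip(self.starts, 0, n)
        ends = np.clip(self.ends, 0, n)
        lens = ends - starts
        keep = lens > 0
        starts, lens = starts[keep], lens[keep]
        if len(starts):
            total = int(lens.sum())
            shift = np.repeat(np.cumsum(lens) - lens, lens)
            idx = np.arange(total) - shift + np.repeat(starts, lens)
            out[idx] = np.repeat(self.values[keep], lens)
        return out

    @property
    def span(self) -> int:
        return int(self.ends[-1]) if len(self.ends) else 0


def read_bedgraph(path: str | os.PathLike) -> dict[str, SignalTrack]:
    per: dict[str, list[list]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}: line {ln}: expected 4 bedGraph columns")
            per.setdefault(parts[0], []).append([int(parts[1]), int(parts[2]), float(parts[3])])
    tracks = {}
    for seq_id, rows in per.items():
        rows.sort()
        arr = np.array(rows, dtype=float)
        tracks[seq_id] = SignalTrack(seq_id, arr[:, 0].astype(np.int64),
                                     arr[:, 1].astype(np.int64), arr[:, 2])
    return tracks


def write_bedgraph(path: str | os.PathLike, tracks: Iterable[SignalTrack]) -> None:
    with open(path, "w") as fh:
        for tr in tracks:
            for s, e, v in zip(tr.starts, tr.ends, tr.values):
                fh.write(f"{tr.seq_id}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# RepeatMasker .out dialect

RM_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def write_repeatmasker_out(path: str | os.PathLike, rows: Iterable[tuple]) -> None:
    """Write rows of (score, seq_id, start, end, strand, name, raw_class)
    in the RepeatMasker ``.out`` dialect (1-based inclusive, C for minus)."""
    with open(path, "w") as fh:
        fh.write(RM_HEADER)
        for i, (score, seq_id, start, end, strand, name, raw_class) in enumerate(rows, 1):
            st = "C" if strand == "-" else "+"
            fh.write(
                f"{score:7.1f}  0.0  0.0  0.0  {seq_id}  {start + 1}  {end}  "
                f"(0)  {st}  {name}  {raw_class}  1  {end - start}  (0)  {i}\n"
            )
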