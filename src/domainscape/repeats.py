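"""Repeat ledger: parse repeat annotations, merge fragments with
class-conflict reclassification, compute densities, rank repeats, filter
foreign-genome matches by score, attribute matches to known repeats, and
build alignment-coverage tracks.

The merge rule follows the convention used for repeat-density figures in
comparative heterochromatin studies: overlapping fragments of the *same*
transposon class are merged into one interval, while bases covered by two
or more *different* classes are reclassified as "Overlapping".  Only the
overlap bases are reclassified; the non-overlapping flanks of a partially
overlapping fragment keep their class, so class-specific bp is conserved.
"""

from __future__ import annotations

import logging
import os
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import intersect, merge_intervals, total_length

logger = logging.getLogger(__name__)

#: Canonical repeat classes used in density reports.
CANONICAL_CLASSES = (
    "LINE", "LTR", "DNA", "RC_Helitron", "Satellite",
    "Simple_LowComplexity", "Other", "Overlapping",
)


def normalize_repeat_class(raw_class: str) -> str:
    """Map a RepeatMasker class/family string to a canonical class.

    Prefix-based and total: "LINE/CR1" -> LINE, "LTR/Gypsy" -> LTR,
    "DNA/hAT" -> DNA, "RC/Helitron" -> RC_Helitron, "Satellite" ->
    Satellite, "Simple_repeat"/"Low_complexity" -> Simple_LowComplexity,
    anything else -> Other.
    """
    rc = raw_class.strip()
    if rc.startswith("LINE"):
        return "LINE"
    if rc.startswith("LTR"):
        return "LTR"
    if rc.startswith("DNA"):
        return "DNA"
    if rc.startswith(("RC", "Helitron")):
        return "RC_Helitron"
    if rc.startswith("Satellite"):
        return "Satellite"
    if rc.startswith(("Simple_repeat", "Low_complexity")):
        return "Simple_LowComplexity"
    return "Other"


@dataclass
class RepeatFeature:
    """One annotated repeat fragment on an assembly."""

    seq_id: str
    start: int
    end: int
    strand: str
    repeat_name: str
    raw_class: str
    canonical_class: str
    score: float
    overridden: bool = False  # RepeatMasker '*' flag (overlapped by a higher-scoring match)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"repeat {self.repeat_name} on {self.seq_id}: start {self.start} >= end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ClassedSegment:
    """A merged, class-labelled segment; output of :func:`merge_by_class`."""

    seq_id: str
    start: int
    end: int
    canonical_class: str
    contributing_names: frozenset = field(default_factory=frozenset)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnalysisRegion:
    """A named set of genomic intervals defining one comparison group."""

    name: str
    intervals: list  # of (seq_id, start, end)

    def __post_init__(self) -> None:
        per_seq: dict[str, list] = defaultdict(list)
        for seq_id, s, e in self.intervals:
            per_seq[seq_id].append((s, e))
        for seq_id, ivs in per_seq.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"region {self.name}: overlapping intervals on {seq_id}")
        if self.total_bp <= 0:
            raise ValueError(f"region {self.name}: total_bp must be > 0")

    @property
    def total_bp(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    def per_seq(self) -> dict[str, list[tuple[int, int]]]:
        out: dict[str, list] = defaultdict(list)
        for seq_id, s, e in self.intervals:
            out[seq_id].append((s, e))
        return {k: sorted(v) for k, v in out.items()}

    @classmethod
    def from_bed(cls, path: str | os.PathLike, name: str | None = None) -> "AnalysisRegion":
        from .io import read_bed

        rows = read_bed(path)
        return cls(name or os.path.basename(str(path)), [(r[0], r[1], r[2]) for r in rows])


@dataclass
class DensityReport:
    region_name: str
    per_class: dict  # canonical_class -> fraction of region bp
    total: float

    def to_frame(self) -> pd.DataFrame:
        rows = [{"region": self.region_name, "class": c, "density": round(d, 4)}
                for c, d in sorted(self.per_class.items())]
        rows.append({"region": self.region_name, "class": "TOTAL", "density": round(self.total, 4)})
        return pd.DataFrame(rows)


@dataclass
class CoverageTrack:
    """Run-length encoded per-base match counts on one target sequence."""

    seq_id: str
    runs: list  # of (start, end, count)
    max_coverage: int

    def to_dense(self, length: int) -> np.ndarray:
        out = np.zeros(length, dtype=np.int64)
        for s, e, c in self.runs:
            out[s:e] = c
        return out


# ---------------------------------------------------------------------------
# Parsing

def parse_repeatmasker_out(path: str | os.PathLike) -> list[RepeatFeature]:
    """Parse the RepeatMasker ``.out`` dialect into RepeatFeatures.

    Expects the standard three header lines followed by whitespace-
    delimited rows (score, div, del, ins, query, begin, end, (left),
    strand C/+, repeat name, class/family, ...).  1-based inclusive query
    coordinates are converted to 0-based half-open.  Rows flagged with a
    trailing ``*`` (overridden by a higher-scoring match) are kept and
    marked; drop them with ``score_filter`` or a list comprehension.
    """
    feats: list[RepeatFeature] = []
    with open(path) as fh:
        lines = fh.readlines()
    for ln, line in enumerate(lines, 1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(("SW", "score", "bit")):
            continue
        parts = stripped.split()
        if len(parts) < 11:
            raise ValueError(f"{path}: line {ln}: malformed RepeatMasker row "
                             f"({len(parts)} fields, expected >= 11)")
        try:
            score = float(parts[0])
            begin = int(parts[5])
            end = int(parts[6])
        except ValueError as exc:
            raise ValueError(f"{path}: line {ln}: malformed RepeatMasker row: {exc}") from None
        strand = "-" if parts[8] == "C" else ("+" if parts[8] == "+" else "?")
        raw_class = parts[10]
        feats.append(RepeatFeature(
            seq_id=parts[4], start=begin - 1, end=end, strand=strand,
            repeat_name=parts[9], raw_class=raw_class,
            canonical_class=normalize_repeat_class(raw_class),
            score=score, overridden=parts[-1] == "*",
        ))
    return feats


# ---------------------------------------------------------------------------
# Merging with class-conflict reclassification

def merge_by_class(features: list[RepeatFeature]) -> list[ClassedSegment]:
    """Merge repeat fragments per sequence; bases covered by >=2 distinct
    canonical classes become "Overlapping" segments.

    The output partitions the covered bases exactly: every covered base
    belongs to exactly one segment, uncovered bases to none.  Adjacent
    segments with identical class are coalesced.
    """
    per_seq: dict[str, list[RepeatFeature]] = defaultdict(list)
    for f in features:
        per_seq[f.seq_id].append(f)

    out: list[ClassedSegment] = []
    for seq_id in sorted(per_seq):
        feats = sorted(per_seq[seq_id], key=lambda f: (f.start, f.end))
        bounds = sorted({x for f in feats for x in (f.start, f.end)})
        # active-feature sweep over elementary intervals
        segs: list[tuple[int, int, str, frozenset]] = []
        fi = 0
        active: list[RepeatFeature] = []
        for lo, hi in zip(bounds, bounds[1:]):
            while fi < len(feats) and feats[fi].start <= lo:
                active.append(feats[fi])
                fi += 1
            active = [f for f in active if f.end > lo]
            covering = [f for f in active if f.start <= lo]
            if not covering:
                continue
            classes = {f.canonical_class for f in covering}
            label = classes.pop() if len(classes) == 1 else "Overlapping"
            names = frozenset(f.repeat_name for f in covering)
            segs.append((lo, hi, label, names))
        # coalesce contiguous same-class segments
        for lo, hi, label, names in segs:
            if out and out[-1].seq_id == seq_id and out[-1].end == lo \
                    and out[-1].canonical_class == label:
                out[-1] = ClassedSegment(seq_id, out[-1].start, hi, label,
                                         out[-1].contributing_names | names)
            else:
                out.append(ClassedSegment(seq_id, lo, hi, label, names))
    return out


def class_density(segments: list[ClassedSegment], region: AnalysisRegion) -> DensityReport:
    """Fraction of region bp covered by each canonical class (merged bp)."""
    if region.total_bp == 0:
        raise ValueError(f"region {region.name} has zero length")
    region_ivs = region.per_seq()
    per_class: dict[str, int] = defaultdict(int)
    for seg in segments:
        if seg.seq_id not in region_ivs:
            continue
        overl = intersect([(seg.start, seg.end)], region_ivs[seg.seq_id])
        per_class[seg.canonical_class] += sum(e - s for s, e in overl)
    dens = {c: bp / region.total_bp for c, bp in per_class.items()}
    return DensityReport(region.name, dens, sum(dens.values()))


def top_repeat_table(features: list[RepeatFeature], region: AnalysisRegion,
                     n: int = 10) -> pd.DataFrame:
    """The n most common repeats by cumulative (unmerged) fragment size.

    Fragment count is the number of annotation rows intersecting the
    region; cumulative sizes are clipped to the region.  "% of all repeat
    bp" uses the unmerged cumulative-size denominator (sum over all
    fragments), not merged coverage.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    region_ivs = region.per_seq()
    acc: dict[str, dict] = {}
    total_repeat_bp = 0
    for f in features:
        ivs = region_ivs.get(f.seq_id)
        if not ivs:
            continue
        bp = sum(e - s for s, e in intersect([(f.start, f.end)], ivs))
        if bp == 0:
            continue
        total_repeat_bp += bp
        a = acc.setdefault(f.repeat_name, {"total_size": 0, "fragments": 0,
                                           "canonical_class": f.canonical_class})
        a["total_size"] += bp
        a["fragments"] += 1
    rows = [{"repeat_name": name, **v} for name, v in acc.items()]
    rows.sort(key=lambda r: (-r["total_size"], r["repeat_name"]))
    rows = rows[:n]
    for r in rows:
        r["pct_region"] = 100.0 * r["total_size"] / region.total_bp
        r["pct_all_repeats"] = (100.0 * r["total_size"] / total_repeat_bp
                                if total_repeat_bp else 0.0)
    cols = ["repeat_name", "total_size", "fragments", "canonical_class",
            "pct_region", "pct_all_repeats"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Foreign-match forensics

def score_filter(features: list[RepeatFeature], min_score: float) -> list[RepeatFeature]:
    """Keep features with alignment score >= min_score.

    Used to remove spurious matches from cross-assembly searches (e.g.
    endosymbiont scaffolds vs a host genome) with a user-supplied cutoff.
    """
    if not np.isfinite(min_score) and min_score > 0:
        raise ValueError("min_score must not be +inf")
    kept = [f for f in features if f.score >= min_score]
    removed = [f for f in features if f.score < min_score]
    if removed:
        logger.info("score_filter: removed %d features (%d bp) below score %.3f",
                    len(removed), sum(f.length for f in removed), min_score)
    return kept


@dataclass
class AttributionResult:
    status: str                    # "ok" or "no matches"
    fraction: float | None         # overall fraction of query bp overlapping annotations
    query_bp: int
    overlapped_bp: int
    per_name: pd.DataFrame         # repeat_name, overlapped_bp, share


def overlap_attribution(query_matches: list[RepeatFeature],
                        annotations: list[RepeatFeature]) -> AttributionResult:
    """Fraction of query-match bp overlapping an annotation set, with a
    per-repeat-name breakdown of the overlapped bp.

    The overall fraction uses the union of query intervals and the union
    of all annotation intervals; the per-name breakdown intersects the
    query union with each name's own union (names may share bases)."""
    if not query_matches:
        return AttributionResult("no matches", None, 0, 0,
                                 pd.DataFrame(columns=["repeat_name", "overlapped_bp", "share"]))
    q_per_seq: dict[str, list] = defaultdict(list)
    for f in query_matches:
        q_per_seq[f.seq_id].append((f.start, f.end))
    q_union = {s: merge_intervals(v) for s, v in q_per_seq.items()}
    query_bp = sum(total_length(v) for v in q_union.values())

    a_all: dict[str, list] = defaultdict(list)
    a_by_name: dict[str, dict[str, list]] = defaultdict(lambda: defaultdict(list))
    for f in annotations:
        a_all[f.seq_id].append((f.start, f.end))
        a_by_name[f.repeat_name][f.seq_id].append((f.start, f.end))

    overlapped = sum(
        total_length(intersect(q_union[s], a_all[s])) for s in q_union if s in a_all
    )
    rows = []
    for name, per_seq in a_by_name.items():
        bp = sum(total_length(intersect(q_union[s], per_seq[s]))
                 for s in q_union if s in per_seq)
        if bp:
            rows.append({"repeat_name": name, "overlapped_bp": bp})
    rows.sort(key=lambda r: (-r["overlapped_bp"], r["repeat_name"]))
    df = pd.DataFrame(rows, columns=["repeat_name", "overlapped_bp"])
    df["share"] = df["overlapped_bp"] / overlapped if overlapped else 0.0
    return AttributionResult("ok", overlapped / query_bp, query_bp, overlapped, df)


def coverage_track(matches: list[tuple[str, int, int]],
                   target_lengths: dict[str, int]) -> dict[str, CoverageTrack]:
    """Per-base match counts on each target sequence, run-length encoded.

    ``matches`` are (target_seq_id, start, end) intervals, e.g. foreign-
    assembly coordinates of cross-genome alignments; count at base b is
    the number of intervals containing b."""
    per_seq: dict[str, list] = {s: [] for s in target_lengths}
    for rec in matches:
        seq_id, s, e = rec
        if seq_id not in target_lengths:
            raise ValueError(f"match {rec}: unknown target {seq_id}")
        if s < 0 or e > target_lengths[seq_id]:
            raise ValueError(f"match {rec}: exceeds declared length "
                             f"{target_lengths[seq_id]} of {seq_id}")
        per_seq[seq_id].append((s, e))
    out = {}
    for seq_id, ivs in per_seq.items():
        L = target_lengths[seq_id]
        if not ivs:
            out[seq_id] = CoverageTrack(seq_id, [(0, L, 0)] if L else [], 0)
            continue
        events = sorted({0, L} | {x for iv in ivs for x in iv})
        starts = np.array(sorted(s for s, _ in ivs))
        ends = np.array(sorted(e for _, e in ivs))
        runs = []
        for lo, hi in zip(events, events[1:]):
            c = int(np.searchsorted(starts, lo, "right") - np.searchsorted(ends, lo, "right"))
            if runs and runs[-1][2] == c and runs[-1][1] == lo:
                runs[-1] = (runs[-1][0], hi, c)
            else:
                runs.append((lo, hi, c))
        out[seq_id] = CoverageTrack(seq_id, runs, max(c for _, _, c in runs))
    return out


def coverage_to_bedgraph(tracks: dict[str, CoverageTrack], path: str | os.PathLike) -> None:
    from .io import SignalTrack, write_bedgraph

    sts = []
    for seq_id in sorted(tracks):
        t = tracks[seq_id]
        if t.runs:
            arr = np.array(t.runs)
            sts.append(SignalTrack(seq_id, arr[:, 0], arr[:, 1], arr[:, 2].astype(float)))
    write_bedgraph(path, sts)
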