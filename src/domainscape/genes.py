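"""Gene architecture: most-comprehensive-isoform selection, coding-span
metrics, region partitioning into coding/intronic/intergenic space, and
ortholog difference records.

Only coding regions are considered: an isoform is its ordered CDS
segments, the coding span runs from start codon to stop codon (introns
included), and "introns" means only the gaps between coding exons.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .intervals import merge_intervals, subtract, intersect
from .repeats import AnalysisRegion


@dataclass
class IsoformModel:
    """Strand-aware ordered CDS segments of one transcript.

    ``cds_segments`` are genomic 0-based half-open (start, end) pairs,
    ordered 5'->3' in transcript orientation (descending genomic start on
    the minus strand).  A total CDS length not divisible by 3 is flagged,
    not rejected (partial models occur in draft annotations).
    """

    gene_id: str
    isoform_id: str
    seq_id: str
    strand: str
    cds_segments: list

    def __post_init__(self) -> None:
        if not self.cds_segments:
            raise ValueError(f"{self.isoform_id}: isoform without CDS segments")
        segs = sorted(self.cds_segments)
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if s2 < e1:
                raise ValueError(f"{self.isoform_id}: overlapping CDS segments")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.isoform_id}: strand must be + or -")
        # store in transcript orientation regardless of input order
        segs = [tuple(x) for x in segs]
        self.cds_segments = segs if self.strand == "+" else segs[::-1]
        self.frame_ok = self.total_cds_size % 3 == 0

    @property
    def genomic_segments(self) -> list:
        return sorted(self.cds_segments)

    @property
    def total_cds_size(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    @property
    def span(self) -> tuple[int, int]:
        segs = self.genomic_segments
        return segs[0][0], segs[-1][1]


@dataclass
class GeneMetrics:
    coding_span_size: int
    total_intron_size: int
    total_cds_size: int
    cds_count: int
    median_cds_size: float
    median_intron_size: float | None  # undefined for single-CDS genes

    FIELDS = ("coding_span_size", "total_intron_size", "total_cds_size",
              "cds_count", "median_cds_size", "median_intron_size")


@dataclass
class DifferenceRecord:
    """Per-metric difference metric(A) - metric(B) for one ortholog pair."""

    gene_a: str
    gene_b: str
    differences: dict  # metric name -> difference (None where undefined)


def select_comprehensive_isoform(isoforms: list[IsoformModel]) -> IsoformModel:
    """The isoform with the largest total coding-exon size; ties broken by
    lexicographically smallest isoform_id so output is deterministic."""
    if not isoforms:
        raise ValueError("no isoforms supplied")
    return min(isoforms, key=lambda iso: (-iso.total_cds_size, iso.isoform_id))


def coding_metrics(isoform: IsoformModel) -> GeneMetrics:
    """Coding-span architecture metrics for one isoform.

    Introns are the gaps between genomically adjacent CDS segments; the
    coding span runs from the leftmost segment start to the rightmost
    segment end.  Strand never changes a size.  Conservation holds by
    construction: span = total CDS + total intron.
    """
    segs = isoform.genomic_segments
    cds_sizes = [e - s for s, e in segs]
    intron_sizes = [s2 - e1 for (_, e1), (s2, _) in zip(segs, segs[1:])]
    span = segs[-1][1] - segs[0][0]
    return GeneMetrics(
        coding_span_size=span,
        total_intron_size=sum(intron_sizes),
        total_cds_size=sum(cds_sizes),
        cds_count=len(segs),
        median_cds_size=float(np.median(cds_sizes)),
        median_intron_size=float(np.median(intron_sizes)) if intron_sizes else None,
    )


def partition_regions(genes: list[IsoformModel], region: AnalysisRegion
                      ) -> dict[str, list[tuple[str, int, int]]]:
    """Partition a region into coding / intronic / intergenic interval sets.

    coding = union of CDS segments; intronic = union of within-span gaps
    minus coding; intergenic = region minus all coding spans.  Overlapping
    genes resolve in favour of coding, then intronic, never intergenic;
    the three sets partition the region exactly.
    """
    region_ivs = region.per_seq()
    coding: dict[str, list] = {s: [] for s in region_ivs}
    spans: dict[str, list] = {s: [] for s in region_ivs}
    for g in genes:
        if g.seq_id not in region_ivs:
            continue
        coding[g.seq_id].extend(g.genomic_segments)
        spans[g.seq_id].append(g.span)
    out = {"coding": [], "intronic": [], "intergenic": []}
    for seq_id, rivs in region_ivs.items():
        cod = intersect(merge_intervals(coding[seq_id]), rivs)
        spn = intersect(merge_intervals(spans[seq_id]), rivs)
        intr = subtract(spn, cod)
        inter = subtract(rivs, spn)
        out["coding"] += [(seq_id, s, e) for s, e in cod]
        out["intronic"] += [(seq_id, s, e) for s, e in intr]
        out["intergenic"] += [(seq_id, s, e) for s, e in inter]
    return out


def ortholog_difference(a: GeneMetrics, b: GeneMetrics,
                        gene_a: str, gene_b: str) -> DifferenceRecord:
    """Per-metric difference a - b (species A ortholog minus species B).

    Antisymmetric under swapping the pair; the median-intron difference is
    undefined (None) when either side is an intronless gene.
    """
    diffs = {}
    for f in GeneMetrics.FIELDS:
        va, vb = getattr(a, f), getattr(b, f)
        diffs[f] = None if va is None or vb is None else va - vb
    return DifferenceRecord(gene_a, gene_b, diffs)


# ---------------------------------------------------------------------------
# GFF3 plumbing

def read_isoforms(gff_path: str | os.PathLike) -> dict[str, list[IsoformModel]]:
    """Read a GFF3 gene -> mRNA -> CDS hierarchy into isoform models.

    Only CDS features are consumed (UTRs and exons, if present, are
    ignored).  Isoforms whose CDS features sit on more than one sequence
    or strand (trans-spliced models) are rejected with a named error.
    """
    import gffutils

    db = gffutils.create_db(str(gff_path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    out: dict[str, list[IsoformModel]] = {}
    for gene in db.features_of_type("gene"):
        isoforms = []
        for mrna in db.children(gene, featuretype="mRNA"):
            cds = list(db.children(mrna, featuretype="CDS"))
            if not cds:
                continue
            seqs = {c.seqid for c in cds}
            strands = {c.strand for c in cds}
            if len(seqs) > 1 or len(strands) > 1:
                raise ValueError(f"isoform {mrna.id}: CDS features on multiple "
                                 "sequences/strands (trans-spliced models unsupported)")
            segs = sorted((c.start - 1, c.end) for c in cds)  # GFF3 is 1-based inclusive
            if strands == {"-"}:
                segs = segs[::-1]
            isoforms.append(IsoformModel(gene.id, mrna.id, cds[0].seqid,
                                         cds[0].strand, segs))
        if isoforms:
            out[gene.id] = isoforms
    return out


def metrics_table(isoforms_by_gene: dict[str, list[IsoformModel]],
                  log_pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene metrics of the most comprehensive isoform, with
    log10(x + pseudocount) companion columns for plotting-scale tables."""
    rows = []
    for gene_id in sorted(isoforms_by_gene):
        iso = select_comprehensive_isoform(isoforms_by_gene[gene_id])
        m = coding_metrics(iso)
        row = {"gene_id": gene_id, "isoform_id": iso.isoform_id,
               "seq_id": iso.seq_id, "strand": iso.strand}
        for f in GeneMetrics.FIELDS:
            v = getattr(m, f)
            row[f] = v
            row[f"log10_{f}"] = (math.log10(v + log_pseudocount)
                                 if v is not None else None)
        rows.append(row)
    return pd.DataFrame(rows)


def difference_table(metrics_a: dict[str, GeneMetrics], metrics_b: dict[str, GeneMetrics],
                     pairs: Iterable[tuple[str, str]]) -> pd.DataFrame:
    """Difference records for a list of (gene_in_A, gene_in_B) ortholog pairs."""
    rows = []
    for ga, gb in pairs:
        if ga not in metrics_a or gb not in metrics_b:
            continue
        rec = ortholog_difference(metrics_a[ga], metrics_b[gb], ga, gb)
        rows.append({"gene_a": ga, "gene_b": gb,
                     **{f"d_{k}": v for k, v in rec.differences.items()}})
    return pd.DataFrame(rows)
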