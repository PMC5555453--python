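"""Synthetic genomes, annotations and signal tracks with known truth.

The generator emulates the statistical structure the comparative analysis
assumes: a repeat-dense region built from planted, truncated (optionally
nested) transposon copies of known classes; genes with a two-component
(bimodal) intron-size mixture and controllable codon composition;
promoter-localized "active" and body-localized "silencing" enrichment
signals; and ortholog pairs whose intron inflation is recorded.  Every
emitted file is a pure function of (config, seed), and the truth tables
are kept consistent with the files at generation time.

Nesting model: a later insertion occludes the bases of any earlier
fragment it overlaps, and the annotation writer emits the *visible*
pieces of each fragment — what an annotator of the final sequence could
see — so planted per-class density truth is exact.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codons import FAMILIES, CodonCounts
from .genes import IsoformModel
from .intervals import merge_intervals, subtract
from .io import SignalTrack, write_bedgraph, write_bed, write_fasta, write_repeatmasker_out
from .repeats import RepeatFeature, normalize_repeat_class

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class TransposonElement:
    name: str
    raw_class: str       # as printed in annotation files, e.g. "LTR/Gypsy"
    consensus_length: int
    gc: float

    @property
    def canonical_class(self) -> str:
        return normalize_repeat_class(self.raw_class)


#: A small default library spanning the major transposon classes.
DEFAULT_LIBRARY = (
    TransposonElement("Gypsy-SIM", "LTR/Gypsy", 7000, 0.45),
    TransposonElement("Copia-SIM", "LTR/Copia", 5200, 0.48),
    TransposonElement("CR1-SIM", "LINE/CR1", 4500, 0.42),
    TransposonElement("Jockey-SIM", "LINE/Jockey", 5000, 0.40),
    TransposonElement("hAT-SIM", "DNA/hAT", 3000, 0.38),
    TransposonElement("Helitron-SIM", "RC/Helitron", 4000, 0.35),
)


@dataclass
class IntronMixture:
    """Two log-normal components (natural-log parameters) mimicking the
    short/long bimodal intron-size distribution of Drosophila genes."""

    mu_short: float = float(np.log(65.0))
    sigma_short: float = 0.25
    mu_long: float = float(np.log(3500.0))
    sigma_long: float = 0.6
    weight_short: float = 0.6

    def __post_init__(self) -> None:
        if not 0 < self.weight_short < 1:
            raise ValueError("mixing weight must be in (0, 1)")

    def draw(self, rng: np.random.Generator, cap: float | None = None) -> tuple[int, bool]:
        is_short = rng.random() < self.weight_short
        mu, sg = ((self.mu_short, self.sigma_short) if is_short
                  else (self.mu_long, self.sigma_long))
        v = float(np.exp(rng.normal(mu, sg)))
        if cap is not None:
            v = min(v, cap)
        return max(int(round(v)), 30), is_short


@dataclass
class SignalModel:
    promoter_peak_width: float = 150.0   # Gaussian sigma, bp
    promoter_peak_height: float = 8.0
    body_level: float = 3.0
    background: float = 1.0
    noise_sd: float = 0.3
    bin_size: int = 10                    # pileup tracks are step functions


@dataclass
class SimulationConfig:
    seed: int = 0
    region_length: int = 1_000_000
    background_gc: float = 0.40
    library: tuple = DEFAULT_LIBRARY
    class_densities: dict = field(default_factory=lambda: {"LTR": 0.40, "LINE": 0.20,
                                                           "DNA": 0.05})
    min_fragment_fraction: float = 0.2   # 5'/3' truncation leaves U(frac, 1) of consensus
    nesting: bool = True
    spurious_matches: int = 0            # planted low-score decoy rows
    spurious_score: float = 50.0
    gene_count: int = 60
    cds_exons: tuple = (2, 6)            # inclusive range
    cds_exon_bp: tuple = (90, 450)
    intron_mixture: IntronMixture = field(default_factory=IntronMixture)
    gene_gc3: float = 0.40               # third-position GC target of gene CDSs
    ortholog_inflation: float = 8.6      # long-intron inflation factor for species B
    ortholog_inflate_fraction: float = 1.0  # fraction of long introns inflated

    def __post_init__(self) -> None:
        total = sum(self.class_densities.values())
        if not all(0 <= d <= 1 for d in self.class_densities.values()) or total > 0.95:
            raise ValueError(f"class densities must lie in [0,1] and sum <= 0.95 "
                             f"(got total {total:.3f})")
        if self.ortholog_inflation < 1:
            raise ValueError("ortholog inflation factor must be >= 1")


# ---------------------------------------------------------------------------
# Codon-level sequence models

def sample_codons(rng: np.random.Generator, n: int, gc3: float | None = None,
                  frequency: dict | None = None,
                  optimal: dict | None = None, optimal_prob: float = 0.75) -> list[str]:
    """Sample n sense codons from one of three regimes.

    - ``frequency``: explicit codon->probability vector;
    - ``optimal``: family->codon map, picked with ``optimal_prob`` else a
      uniform family codon (selection-like bias);
    - ``gc3``: third-position GC target; a codon slot picks a uniform
      multi-codon family, then a G/C-ending family codon with probability
      gc3, an A/T-ending one otherwise (mutational-bias-like).
    """
    if frequency is not None:
        codons = sorted(frequency)
        p = np.array([frequency[c] for c in codons], dtype=float)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-6):
            raise ValueError("frequency vector must be non-negative and sum to 1")
        return list(rng.choice(codons, size=n, p=p / p.sum()))
    fams = sorted(aa for aa, cods in FAMILIES.items() if len(cods) > 1)
    out = []
    for aa in rng.choice(fams, size=n):
        cods = FAMILIES[aa]
        if optimal is not None:
            if rng.random() < optimal_prob:
                out.append(optimal[aa])
            else:
                out.append(cods[rng.integers(len(cods))])
            continue
        target = 0.5 if gc3 is None else gc3
        gc_end = [c for c in cods if c[2] in "GC"]
        at_end = [c for c in cods if c[2] in "AT"]
        pool = gc_end if (rng.random() < target and gc_end) else (at_end or gc_end)
        out.append(pool[rng.integers(len(pool))])
    return out


def make_reference_counts(gc3: float = 0.65, per_family: int = 1000,
                          optimal_share: float = 0.7) -> tuple[CodonCounts, dict]:
    """A synthetic CAI reference: in each family one designated optimal
    codon (the alphabetically first G/C-ending one, mirroring the GC-rich
    optimal codons of highly expressed Drosophila genes) carries
    ``optimal_share`` of the counts.  Returns (counts, family->optimal)."""
    counts = {c: 0 for c in sum((list(v) for v in FAMILIES.values()), [])}
    optimal = {}
    for aa, cods in FAMILIES.items():
        if len(cods) == 1:
            counts[cods[0]] = per_family
            continue
        gc_end = sorted(c for c in cods if c[2] in "GC") or sorted(cods)
        opt = gc_end[0]
        optimal[aa] = opt
        rest = [c for c in cods if c != opt]
        counts[opt] = int(per_family * optimal_share)
        for c in rest:
            counts[c] = int(per_family * (1 - optimal_share) / len(rest))
    return CodonCounts(counts), optimal


# ---------------------------------------------------------------------------
# Region simulation

@dataclass
class SimulatedRegion:
    """In-memory result of :func:`simulate_region`; ``write`` emits the
    standard-format files."""

    config: SimulationConfig
    seq_id: str
    sequence: str
    visible_fragments: list          # RepeatFeature (visible pieces, truth == .out)
    isoforms: list                   # IsoformModel, one per gene
    gene_truth: pd.DataFrame
    class_bp: dict                   # canonical class -> visible planted bp
    signal_active: SignalTrack
    signal_silencing: SignalTrack
    peak_positions: pd.DataFrame

    def write(self, outdir: str | os.PathLike) -> dict:
        os.makedirs(outdir, exist_ok=True)
        p = lambda name: os.path.join(str(outdir), name)
        write_fasta(p("region.fasta"), {self.seq_id: self.sequence})
        write_repeatmasker_out(p("repeats.out"), [
            (f.score, f.seq_id, f.start, f.end, f.strand, f.repeat_name, f.raw_class)
            for f in self.visible_fragments])
        with open(p("genes.gff3"), "w") as fh:
            fh.write("##gff-version 3\n")
            for iso in self.isoforms:
                s0, e0 = iso.span
                fh.write(f"{iso.seq_id}\tsim\tgene\t{s0 + 1}\t{e0}\t.\t{iso.strand}\t.\t"
                         f"ID={iso.gene_id}\n")
                fh.write(f"{iso.seq_id}\tsim\tmRNA\t{s0 + 1}\t{e0}\t.\t{iso.strand}\t.\t"
                         f"ID={iso.isoform_id};Parent={iso.gene_id}\n")
                for k, (s, e) in enumerate(iso.genomic_segments):
                    fh.write(f"{iso.seq_id}\tsim\tCDS\t{s + 1}\t{e}\t.\t{iso.strand}\t0\t"
                             f"ID={iso.isoform_id}.cds{k};Parent={iso.isoform_id}\n")
        write_bed(p("region.bed"), [(self.seq_id, 0, len(self.sequence), "sim_region")])
        write_bedgraph(p("signal_active.bedgraph"), [self.signal_active])
        write_bedgraph(p("signal_silencing.bedgraph"), [self.signal_silencing])
        self.gene_truth.to_csv(p("gene_truth.tsv"), sep="\t", index=False)
        pd.DataFrame([{"class": c, "planted_bp": bp} for c, bp in sorted(self.class_bp.items())]
                     ).to_csv(p("repeat_truth.tsv"), sep="\t", index=False)
        self.peak_positions.to_csv(p("peak_truth.tsv"), sep="\t", index=False)
        return {name: p(name) for name in
                ("region.fasta", "repeats.out", "genes.gff3", "region.bed",
                 "signal_active.bedgraph", "signal_silencing.bedgraph",
                 "gene_truth.tsv", "repeat_truth.tsv", "peak_truth.tsv")}


def _element_consensus(rng: np.random.Generator, el: TransposonElement) -> str:
    p = [(1 - el.gc) / 2, el.gc / 2, el.gc / 2, (1 - el.gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=el.consensus_length, p=p))


def _plant_repeats(rng, cfg: SimulationConfig, seq: np.ndarray):
    """Plant truncated transposon copies until per-class visible-bp
    targets are met; returns visible fragment records and class bp."""
    L = cfg.region_length
    by_class: dict[str, list[TransposonElement]] = {}
    for el in cfg.library:
        by_class.setdefault(el.canonical_class, []).append(el)
    for cls in cfg.class_densities:
        if cfg.class_densities[cls] > 0 and cls not in by_class:
            raise ValueError(f"no library element of class {cls}")
    consensus = {el.name: _element_consensus(rng, el) for el in cfg.library}

    fragments = []  # dict: name, raw_class, cls, start, end, strand, score, visible list
    visible_bp = {cls: 0 for cls in cfg.class_densities}
    targets = {cls: int(d * L) for cls, d in cfg.class_densities.items()}
    attempts = 0
    # rounds: planting one class can occlude another below its target, so
    # keep topping up until every class holds its target simultaneously
    while any(visible_bp[c] < targets[c] for c in targets):
        cls = min((c for c in sorted(targets) if visible_bp[c] < targets[c]),
                  key=lambda c: visible_bp[c] - targets[c])
        target = targets[cls]
        attempts += 1
        if attempts > 200_000:
            raise RuntimeError(f"cannot reach density target for {cls}; "
                               "targets infeasible at this region length")
        els = by_class[cls]
        el = els[rng.integers(len(els))]
        frac = rng.uniform(cfg.min_fragment_fraction, 1.0)
        flen = max(int(el.consensus_length * frac), 30)
        flen = min(flen, max(target - visible_bp[cls], 30))
        if flen > L:
            continue
        start = int(rng.integers(0, L - flen + 1))
        end = start + flen
        overl = [f for f in fragments
                 if f["start"] < end and start < f["end"]]
        if overl and not cfg.nesting:
            continue
        # occlude earlier fragments
        for f in overl:
            lost = sum(e - s for s, e in f["visible"]) \
                - sum(e - s for s, e in subtract(f["visible"], [(start, end)]))
            f["visible"] = subtract(f["visible"], [(start, end)])
            visible_bp[f["cls"]] = visible_bp.get(f["cls"], 0) - lost
        strand = "+" if rng.random() < 0.5 else "-"
        off = int(rng.integers(0, el.consensus_length - flen + 1))
        piece = consensus[el.name][off : off + flen]
        if strand == "-":
            piece = _revcomp(piece)
        seq[start:end] = np.frombuffer(piece.encode(), dtype=np.uint8)
        score = flen * rng.uniform(2.0, 3.5)
        fragments.append({"name": el.name, "raw_class": el.raw_class, "cls": cls,
                          "start": start, "end": end, "strand": strand,
                          "score": score, "visible": [(start, end)]})
        visible_bp[cls] += flen
    return fragments, visible_bp, consensus


def _make_gene_structure(rng, cfg: SimulationConfig, max_span: int):
    """Draw CDS exon and intron sizes; returns (exons, introns) or None if
    nothing fits in ``max_span``."""
    for _ in range(40):
        n_ex = int(rng.integers(cfg.cds_exons[0], cfg.cds_exons[1] + 1))
        exons = [int(rng.integers(cfg.cds_exon_bp[0], cfg.cds_exon_bp[1] + 1))
                 for _ in range(n_ex)]
        rem = sum(exons) % 3
        if rem:
            exons[-1] += 3 - rem
        introns = []
        for _ in range(n_ex - 1):
            cap = max_span - sum(exons) - sum(introns) - 30 * (n_ex - 1 - len(introns))
            size, _ = cfg.intron_mixture.draw(rng, cap=max(cap, 30))
            introns.append(size)
        if sum(exons) + sum(introns) <= max_span:
            return exons, introns
    return None


def simulate_region(config: SimulationConfig, outdir: str | os.PathLike | None = None
                    ) -> SimulatedRegion:
    """Generate one region: background sequence, planted repeats, genes in
    repeat-free windows, and promoter/body enrichment signals.

    Deterministic in ``config.seed``; if ``outdir`` is given, the standard
    files (FASTA, GFF3, .out, BEDs, bedGraphs, truth TSVs) are written.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    L = cfg.region_length
    gc = cfg.background_gc
    seq = np.frombuffer(
        "".join(np.random.default_rng(cfg.seed + 1).choice(
            list("ACGT"), size=L, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        ).encode(), dtype=np.uint8).copy()

    fragments, visible_bp, _ = _plant_repeats(rng, cfg, seq)
    for _ in range(cfg.spurious_matches):
        flen = int(rng.integers(40, 120))
        start = int(rng.integers(0, L - flen))
        fragments.append({"name": "SpuriousHit", "raw_class": "Unknown", "cls": "Other",
                          "start": start, "end": start + flen, "strand": "+",
                          "score": cfg.spurious_score, "visible": [(start, start + flen)]})

    occupied = merge_intervals([(f["start"], f["end"]) for f in fragments])
    free = subtract([(0, L)], occupied)

    isoforms: list[IsoformModel] = []
    gene_rows = []
    gaps = sorted(free, key=lambda iv: iv[0])
    gap_cursor = {i: s for i, (s, e) in enumerate(gaps)}
    gi = 0
    placed = 0
    tries = 0
    while placed < cfg.gene_count:
        tries += 1
        if tries > cfg.gene_count * 200:
            raise RuntimeError("cannot place requested genes in repeat-free space")
        i = gi % len(gaps)
        gi += 1
        s, e = gaps[i]
        cursor = gap_cursor[i]
        room = e - cursor - 100  # keep a margin between neighbours
        if room < 300:
            continue
        struct = _make_gene_structure(rng, cfg, room)
        if struct is None:
            continue
        exons, introns = struct
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursor + 50
        segs = []
        pos = start
        for k, ex in enumerate(exons):
            segs.append((pos, pos + ex))
            pos += ex + (introns[k] if k < len(introns) else 0)
        gap_cursor[i] = pos + 50
        gene_id = f"gene{placed:04d}"
        iso = IsoformModel(gene_id, f"{gene_id}.t1", "sim_region", strand, segs)
        # fill CDS with a codon-model sequence (ATG ... stop)
        n_codons = sum(exons) // 3
        body = sample_codons(rng, n_codons - 2, gc3=cfg.gene_gc3)
        cds = "ATG" + "".join(body) + "TAA"
        genomic = cds if strand == "+" else _revcomp(cds)
        # lay the genomic-orientation CDS across the exon segments
        offset = 0
        for (a, b) in segs:
            seq[a:b] = np.frombuffer(genomic[offset : offset + (b - a)].encode(),
                                     dtype=np.uint8)
            offset += b - a
        span0, span1 = iso.span
        gene_rows.append({
            "gene_id": gene_id, "strand": strand,
            "coding_span_size": span1 - span0,
            "total_cds_size": sum(exons), "total_intron_size": sum(introns),
            "cds_count": len(exons),
            "median_cds_size": float(np.median(exons)),
            "median_intron_size": float(np.median(introns)) if introns else np.nan,
            "gc3_target": cfg.gene_gc3,
            "tss": span0 if strand == "+" else span1,
        })
        isoforms.append(iso)
        placed += 1

    gene_truth = pd.DataFrame(gene_rows)

    # signals: binned step functions, background + noise, promoter peak /
    # body enrichment
    sig = SignalModel()
    nb = (L + sig.bin_size - 1) // sig.bin_size
    centers = (np.arange(nb) + 0.5) * sig.bin_size
    active = sig.background + rng.normal(0, sig.noise_sd, nb)
    silenc = sig.background + rng.normal(0, sig.noise_sd, nb)
    for row, iso in zip(gene_rows, isoforms):
        tss = row["tss"]
        active += sig.promoter_peak_height * np.exp(
            -0.5 * ((centers - tss) / sig.promoter_peak_width) ** 2)
        s0, e0 = iso.span
        silenc[(centers >= s0) & (centers < e0)] += sig.body_level
    active = np.clip(active, 0, None)
    silenc = np.clip(silenc, 0, None)

    def binned_track(vals: np.ndarray) -> SignalTrack:
        starts = np.arange(nb, dtype=np.int64) * sig.bin_size
        ends = np.minimum(starts + sig.bin_size, L)
        return SignalTrack("sim_region", starts, ends, np.round(vals, 4))

    peaks = pd.DataFrame({"gene_id": [r["gene_id"] for r in gene_rows],
                          "peak_position": [r["tss"] for r in gene_rows]})

    visible_feats = []
    for f in sorted(fragments, key=lambda f: f["start"]):
        for (vs, ve) in f["visible"]:
            visible_feats.append(RepeatFeature(
                "sim_region", vs, ve, f["strand"], f["name"], f["raw_class"],
                normalize_repeat_class(f["raw_class"]), round(f["score"], 1)))

    region = SimulatedRegion(
        config=cfg, seq_id="sim_region", sequence=seq.tobytes().decode(),
        visible_fragments=visible_feats, isoforms=isoforms, gene_truth=gene_truth,
        class_bp={c: bp for c, bp in visible_bp.items()},
        signal_active=binned_track(active), signal_silencing=binned_track(silenc),
        peak_positions=peaks)
    if outdir is not None:
        region.write(outdir)
    return region


# ---------------------------------------------------------------------------
# Codon-regime gene sets

def simulate_codon_genes(seed: int = 0, genes_per_group: int = 30,
                         codons_per_gene: int = 3000,
                         low_gc3: float = 0.30, high_gc3: float = 0.65,
                         optimal_prob: float = 0.75,
                         outdir: str | os.PathLike | None = None):
    """CDS sets under three codon regimes with truth labels.

    - "uniform": every synonymous codon equally likely (Nc near 61);
    - "mutational": AT-shifted wobble positions (low GC3), agnostic to
      any reference weights;
    - "selected": shifted toward the reference-optimal codons of a
      GC-rich synthetic reference (high CAI against those weights).

    Returns (seqs, truth, reference_counts, optimal_map).
    """
    rng = np.random.default_rng(seed)
    reference, optimal = make_reference_counts(gc3=high_gc3)
    seqs: dict[str, str] = {}
    rows = []
    for group in ("uniform", "mutational", "selected"):
        for i in range(genes_per_group):
            if group == "uniform":
                codons = sample_codons(rng, codons_per_gene, gc3=None)
                gc3 = None
            elif group == "mutational":
                codons = sample_codons(rng, codons_per_gene, gc3=low_gc3)
                gc3 = low_gc3
            else:
                codons = sample_codons(rng, codons_per_gene, optimal=optimal,
                                       optimal_prob=optimal_prob)
                gc3 = high_gc3
            name = f"{group}_{i:03d}"
            seqs[name] = "".join(codons)
            rows.append({"gene_id": name, "group": group, "gc3_target": gc3})
    truth = pd.DataFrame(rows)
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        write_fasta(os.path.join(str(outdir), "codon_genes.fasta"), seqs)
        truth.to_csv(os.path.join(str(outdir), "codon_truth.tsv"), sep="\t", index=False)
    return seqs, truth, reference, optimal


# ---------------------------------------------------------------------------
# Ortholog pairs

def simulate_ortholog_pairs(seed: int = 0, n_pairs: int = 40,
                            inflation: float = 8.6, inflate_fraction: float = 1.0,
                            intron_mixture: IntronMixture | None = None,
                            cds_exons: tuple = (2, 6), cds_exon_bp: tuple = (90, 450),
                            outdir: str | os.PathLike | None = None):
    """Ortholog pairs where species B copies species A's exon structure
    but inflates a configured fraction of the *long-component* introns by
    ``inflation``; total CDS sizes are equal by construction.

    Returns (isoforms_a, isoforms_b, pairs, truth) with per-species
    isoform dicts keyed by gene id.
    """
    if inflation < 1:
        raise ValueError("inflation factor must be >= 1")
    rng = np.random.default_rng(seed)
    mix = intron_mixture or IntronMixture()
    iso_a: dict[str, IsoformModel] = {}
    iso_b: dict[str, IsoformModel] = {}
    pairs = []
    rows = []
    for i in range(n_pairs):
        n_ex = int(rng.integers(cds_exons[0], cds_exons[1] + 1))
        exons = [int(rng.integers(cds_exon_bp[0], cds_exon_bp[1] + 1)) for _ in range(n_ex)]
        draws = [mix.draw(rng) for _ in range(n_ex - 1)]
        introns_a = [d[0] for d in draws]
        inflated = []
        introns_b = []
        for size, is_short in draws:
            if not is_short and rng.random() < inflate_fraction:
                introns_b.append(int(round(size * inflation)))
                inflated.append(True)
            else:
                introns_b.append(size)
                inflated.append(False)
        ga, gb = f"speciesA_g{i:03d}", f"speciesB_g{i:03d}"
        for gid, intr, store, chrom in ((ga, introns_a, iso_a, f"chrA_{i}"),
                                        (gb, introns_b, iso_b, f"chrB_{i}")):
            segs = []
            pos = 100
            for k, ex in enumerate(exons):
                segs.append((pos, pos + ex))
                pos += ex + (intr[k] if k < len(intr) else 0)
            store[gid] = IsoformModel(gid, f"{gid}.t1", chrom, "+", segs)
        pairs.append((gb, ga))  # B (inflated) is the minuend
        rows.append({"gene_a": gb, "gene_b": ga, "n_introns": n_ex - 1,
                     "n_inflated": int(sum(inflated)),
                     "intron_bp_a": sum(introns_a), "intron_bp_b": sum(introns_b)})
    truth = pd.DataFrame(rows)
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        for tag, store in (("speciesA", iso_a), ("speciesB", iso_b)):
            with open(os.path.join(str(outdir), f"{tag}.gff3"), "w") as fh:
                fh.write("##gff-version 3\n")
                for iso in store.values():
                    s0, e0 = iso.span
                    fh.write(f"{iso.seq_id}\tsim\tgene\t{s0 + 1}\t{e0}\t.\t+\t.\tID={iso.gene_id}\n")
                    fh.write(f"{iso.seq_id}\tsim\tmRNA\t{s0 + 1}\t{e0}\t.\t+\t.\t"
                             f"ID={iso.isoform_id};Parent={iso.gene_id}\n")
                    for k, (s, e) in enumerate(iso.genomic_segments):
                        fh.write(f"{iso.seq_id}\tsim\tCDS\t{s + 1}\t{e}\t.\t+\t0\t"
                                 f"ID={iso.isoform_id}.cds{k};Parent={iso.isoform_id}\n")
        pd.DataFrame(pairs, columns=["gene_a", "gene_b"]).to_csv(
            os.path.join(str(outdir), "pairs.tsv"), sep="\t", index=False)
        truth.to_csv(os.path.join(str(outdir), "ortholog_truth.tsv"), sep="\t", index=False)
    return iso_a, iso_b, pairs, truth
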