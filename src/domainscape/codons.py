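"""Codon-bias suite: codon counting, Wright's effective number of codons
(Nc), relative adaptiveness and the codon adaptation index (CAI), the
equal-usage CAI threshold, GC partitions (GC1/2/3, fourfold-degenerate
sites), and per-family codon-frequency tables.

Nc measures departure from uniform synonymous-codon usage: 61 means every
synonymous codon is used equally, 20 means exactly one codon per amino
acid.  Under the standard genetic code the degeneracy classes are 9
twofold families, 1 threefold (Ile), 5 fourfold, 3 sixfold (Leu, Ser,
Arg, kept whole so the 20/61 bounds are exact: 61 = 2 + 18 + 3 + 20 + 18)
and 2 single-codon amino acids (Met, Trp).

CAI is the geometric mean of each codon's relative adaptiveness w against
a reference gene set; it measures usage of translationally optimal codons
and so reflects selection, while low GC3 with low Nc reflects mutational
bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

BASES = "TCAG"
ALL_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)


def _code_tables(genetic_code: int = 1):
    table = unambiguous_dna_by_id[genetic_code]
    aa_of = dict(table.forward_table)
    stops = tuple(table.stop_codons)
    families: dict[str, tuple[str, ...]] = {}
    for codon in ALL_CODONS:
        if codon in stops:
            continue
        families.setdefault(aa_of[codon], ())
        families[aa_of[codon]] += (codon,)
    return aa_of, stops, families


AA_OF, STOP_CODONS, FAMILIES = _code_tables(1)
#: number of families per degeneracy class under the standard code
DEGENERACY_CLASS_COUNTS = {2: 9, 3: 1, 4: 5, 6: 3}
#: third-position-fourfold amino acids used for 4D-site GC
FOURFOLD_AAS = ("A", "G", "P", "T", "V")
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)
#: sense codons entering CAI (Met, Trp and stops excluded) — 59 of them
CAI_CODONS = tuple(c for c in SENSE_CODONS if len(FAMILIES[AA_OF[c]]) > 1)


@dataclass
class CodonCounts:
    """64-slot codon tally; stops are tallied but excluded from bias
    statistics, codons containing N are excluded and counted separately."""

    counts: dict = field(default_factory=lambda: {c: 0 for c in ALL_CODONS})
    ambiguous: int = 0

    def __post_init__(self) -> None:
        full = {c: 0 for c in ALL_CODONS}
        for c, n in self.counts.items():
            if c not in full:
                raise KeyError(f"not a codon: {c}")
            if n < 0:
                raise ValueError(f"negative count for {c}")
            full[c] = int(n)
        self.counts = full

    def family_counts(self, aa: str) -> dict[str, int]:
        return {c: self.counts[c] for c in FAMILIES[aa]}

    def family_proportions(self, aa: str) -> dict[str, float]:
        fam = self.family_counts(aa)
        tot = sum(fam.values())
        if tot == 0:
            return {}
        return {c: n / tot for c, n in fam.items()}

    def family_homozygosity(self, aa: str, mode: str = "finite_sample") -> float | None:
        """F for one synonymous family: Sum p_i^2 in proportions mode, or
        the finite-sample estimator (n*Sum p^2 - 1)/(n - 1).  None when
        the family is unobserved (or has n < 2 in finite-sample mode)."""
        fam = self.family_counts(aa)
        n = sum(fam.values())
        if n == 0:
            return None
        sp2 = sum((c / n) ** 2 for c in fam.values())
        if mode == "proportions":
            return sp2
        if mode == "finite_sample":
            if n < 2:
                return None
            return (n * sp2 - 1) / (n - 1)
        raise ValueError(f"unknown mode {mode!r}")

    @property
    def total_sense(self) -> int:
        return sum(self.counts[c] for c in SENSE_CODONS)

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        return CodonCounts({c: self.counts[c] + other.counts[c] for c in ALL_CODONS},
                           self.ambiguous + other.ambiguous)


@dataclass
class CodonWeights:
    """Relative adaptiveness w per sense codon (1 for each family's most
    frequent reference codon); Met, Trp and stops carry no weight."""

    w: dict
    source: str = ""

    def __post_init__(self) -> None:
        for c, v in self.w.items():
            if c not in CAI_CODONS:
                raise KeyError(f"codon {c} is not CAI-eligible")
            if not (0 < v <= 1):
                raise ValueError(f"w[{c}]={v} outside (0, 1]")


@dataclass
class CodonBiasResult:
    nc: float
    cai: float
    gc_coding: float
    gc1: float
    gc2: float
    gc3: float
    gc_4d: float | None


def count_codons(cds_sequence: str, genetic_code: int = 1) -> CodonCounts:
    """Tally codons of an in-frame CDS (A/C/G/T/N alphabet).

    The sequence length must be divisible by 3; codons containing N are
    skipped and counted in ``ambiguous``.
    """
    if genetic_code != 1:
        raise NotImplementedError("only the standard genetic code is wired up")
    seq = cds_sequence.upper().replace("U", "T")
    if len(seq) % 3:
        raise ValueError(f"CDS length {len(seq)} not divisible by 3")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"unexpected characters in CDS: {sorted(bad)}")
    cc = CodonCounts()
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            cc.ambiguous += 1
        else:
            cc.counts[codon] += 1
    return cc


def extract_cds(genome: dict[str, str], isoform) -> str:
    """Spliced CDS sequence of an isoform (reverse-complemented on -)."""
    seq = genome[isoform.seq_id]
    parts = [seq[s:e] for s, e in isoform.genomic_segments]
    cds = "".join(parts)
    if isoform.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def effective_number_of_codons(counts: CodonCounts, mode: str = "finite_sample") -> float:
    """Wright's Nc from per-family homozygosities.

    Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 with Fk the mean homozygosity over
    observed k-fold families.  Families that are absent (or unusable in
    finite-sample mode: n < 2, or a non-positive estimate) are imputed by
    the mean F of their degeneracy class; if a whole class is unobserved
    its mean is taken as 1/k (the no-bias value).
    """
    class_F: dict[int, list[float]] = {k: [] for k in DEGENERACY_CLASS_COUNTS}
    n_usable = 0
    for aa, codons in FAMILIES.items():
        k = len(codons)
        if k == 1:
            continue
        F = counts.family_homozygosity(aa, mode)
        if F is not None and F > 0:
            class_F[k].append(F)
            n_usable += 1
    if n_usable == 0:
        raise ValueError("no usable synonymous family (empty or single-count gene)")
    nc = 2.0  # Met + Trp
    for k, n_fams in DEGENERACY_CLASS_COUNTS.items():
        observed = class_F[k]
        mean_F = sum(observed) / len(observed) if observed else 1.0 / k
        nc += n_fams / mean_F
    return nc


def relative_adaptiveness(reference: CodonCounts) -> CodonWeights:
    """w_ij = count_ij / max_j(count_ij) within each synonymous family.

    Zero-count codons are floored at w = 0.01; a family entirely absent
    from the reference is neutral (all w = 1).  Met, Trp and stops are
    excluded.
    """
    if reference.total_sense == 0:
        raise ValueError("empty reference counts")
    w = {}
    for aa, codons in FAMILIES.items():
        if len(codons) == 1:
            continue
        fam = reference.family_counts(aa)
        mx = max(fam.values())
        for c in codons:
            w[c] = max(fam[c] / mx, 0.01) if mx > 0 else 1.0
    return CodonWeights(w, source="relative_adaptiveness(reference)")


def codon_adaptation_index(codons: CodonCounts, weights: CodonWeights) -> float:
    """Geometric mean of w over all codon occurrences, excluding Met, Trp
    and stop codons: CAI = exp((1/L) * Sum ln w)."""
    L = 0
    log_sum = 0.0
    for c in CAI_CODONS:
        n = codons.counts[c]
        if n:
            L += n
            log_sum += n * math.log(weights.w[c])
    if L == 0:
        raise ValueError("no CAI-eligible codons in gene")
    return math.exp(log_sum / L)


def equal_usage_cai(weights: CodonWeights) -> float:
    """CAI of a hypothetical gene using each family's synonymous codons
    equally, every included sense codon weighted once (codon-weighted
    geometric mean over the weight table's codons)."""
    codons = sorted(weights.w)
    return math.exp(sum(math.log(weights.w[c]) for c in codons) / len(codons))


def gc_partition(counts: CodonCounts) -> dict[str, float]:
    """GC fractions by codon position over all non-stop codons, plus GC at
    fourfold-degenerate sites (third position of Ala/Gly/Pro/Thr/Val)."""
    tot = counts.total_sense
    if tot == 0:
        raise ValueError("zero codons")
    gc_pos = [0, 0, 0]
    for c in SENSE_CODONS:
        n = counts.counts[c]
        if not n:
            continue
        for k in range(3):
            if c[k] in "GC":
                gc_pos[k] += n
    four_tot = sum(counts.counts[c] for aa in FOURFOLD_AAS for c in FAMILIES[aa])
    four_gc = sum(counts.counts[c] for aa in FOURFOLD_AAS for c in FAMILIES[aa]
                  if c[2] in "GC")
    return {
        "GC_coding": sum(gc_pos) / (3 * tot),
        "GC1": gc_pos[0] / tot,
        "GC2": gc_pos[1] / tot,
        "GC3": gc_pos[2] / tot,
        "GC_4D": four_gc / four_tot if four_tot else None,
    }


def codon_frequency(counts: CodonCounts):
    """Per-family synonymous-codon fractions as a tidy DataFrame.

    Families with zero counts are reported as missing (NaN fractions),
    never as 0/0.
    """
    import pandas as pd

    rows = []
    for aa in sorted(FAMILIES):
        fam = counts.family_counts(aa)
        tot = sum(fam.values())
        for c in FAMILIES[aa]:
            rows.append({"aa": aa, "codon": c, "count": fam[c],
                         "fraction": fam[c] / tot if tot else float("nan")})
    return pd.DataFrame(rows)


def codon_bias(counts: CodonCounts, weights: CodonWeights,
               nc_mode: str = "finite_sample") -> CodonBiasResult:
    gc = gc_partition(counts)
    return CodonBiasResult(
        nc=effective_number_of_codons(counts, nc_mode),
        cai=codon_adaptation_index(counts, weights),
        gc_coding=gc["GC_coding"], gc1=gc["GC1"], gc2=gc["GC2"],
        gc3=gc["GC3"], gc_4d=gc["GC_4D"],
    )
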