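"""End-to-end orchestration: regions -> repeat ledger -> gene metrics ->
codon bias -> metagenes -> statistics, from one validated config.

Each analysis region supplies a genome (FASTA), a gene annotation (GFF3),
a repeat annotation (RepeatMasker ``.out``), a region BED, and optional
treatment/control pileup tracks (bedGraph).  Optional run-wide inputs: a
codon reference-count table for CAI weights, ortholog pairs between two
named regions, and a precomputed expression matrix.  Stages whose inputs
are absent are skipped with a note in the manifest; reruns into a
non-empty directory require ``force``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .codons import (CodonCounts, codon_adaptation_index, codon_frequency, count_codons,
                     effective_number_of_codons, equal_usage_cai, extract_cds,
                     gc_partition, relative_adaptiveness, ALL_CODONS)
from .genes import coding_metrics, metrics_table, partition_regions, read_isoforms, \
    select_comprehensive_isoform, difference_table
from .io import read_bedgraph, read_fasta, write_bed
from .profiles import TmParams, build_metagene, loglik_enrichment, signal_profile, window_tm
from .io import SignalTrack
from .repeats import (AnalysisRegion, class_density, merge_by_class,
                      parse_repeatmasker_out, score_filter, top_repeat_table)
from .stats import dunn_holm, hypergeom_upper, spearman

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        super().__init__("invalid run config:\n" + "\n".join(f"  - {e}" for e in errors))
        self.errors = errors


@dataclass
class RegionInput:
    name: str
    bed: str
    genome: str
    annotation: str
    repeats: str | None = None
    treatment: str | None = None
    control: str | None = None
    min_score: float | None = None


@dataclass
class RunConfig:
    regions: list            # of RegionInput
    out_dir: str
    seed: int = 0
    alpha: float = 0.05
    tm: TmParams = field(default_factory=TmParams)
    metagene_span: int = 3000
    metagene_flank: int = 2000
    reference_counts: str | None = None   # TSV codon\tcount
    ortholog_pairs: str | None = None     # TSV gene_a\tgene_b (A = first region)
    expression: str | None = None         # TSV gene_id\tvalue
    drop_simple_repeats: bool = True      # emulate -nolow transposon accounting
    force: bool = False

    def canonical(self) -> dict:
        d = asdict(self)
        d.pop("force")
        return d


_REGION_KEYS = {"name", "bed", "genome", "annotation", "repeats",
                "treatment", "control", "min_score"}
_TOP_KEYS = {"regions", "out_dir", "seed", "alpha", "tm", "metagene_span",
             "metagene_flank", "reference_counts", "ortholog_pairs",
             "expression", "drop_simple_repeats", "force"}


def validate_config(path: str | os.PathLike) -> RunConfig:
    """Load and schema-check a YAML run config, collecting *all* errors.

    Defaults: alpha 0.05, metagene span 3000 / flank 2000, 9-bp Tm window.
    Raises ConfigError carrying the full error list.
    """
    errors: list[str] = []
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    base = os.path.dirname(os.path.abspath(str(path)))
    if not isinstance(doc, dict):
        raise ConfigError(["config root must be a mapping"])
    for key in doc:
        if key not in _TOP_KEYS:
            errors.append(f"unknown key: {key}")
    regions = []
    names = set()
    for i, rd in enumerate(doc.get("regions") or []):
        for key in rd:
            if key not in _REGION_KEYS:
                errors.append(f"regions[{i}]: unknown key: {key}")
        missing = {"name", "bed", "genome", "annotation"} - set(rd)
        if missing:
            errors.append(f"regions[{i}]: missing required keys: {sorted(missing)}")
            continue
        if rd["name"] in names:
            errors.append(f"regions[{i}]: duplicate region name {rd['name']!r}")
        names.add(rd["name"])
        kw = {k: rd.get(k) for k in _REGION_KEYS if k in rd}
        for k in ("bed", "genome", "annotation", "repeats", "treatment", "control"):
            if kw.get(k):
                kw[k] = os.path.join(base, kw[k]) if not os.path.isabs(kw[k]) else kw[k]
                if not os.path.exists(kw[k]):
                    errors.append(f"regions[{i}]: {k} file not found: {kw[k]}")
        regions.append(RegionInput(**kw))
    if not regions and not errors:
        errors.append("no regions defined")
    tm_kwargs = doc.get("tm") or {}
    try:
        tm = TmParams(**tm_kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"tm: {exc}")
        tm = TmParams()
    for k in ("reference_counts", "ortholog_pairs", "expression"):
        v = doc.get(k)
        if v:
            p = os.path.join(base, v) if not os.path.isabs(v) else v
            doc[k] = p
            if not os.path.exists(p):
                errors.append(f"{k} file not found: {p}")
    if "out_dir" not in doc:
        errors.append("missing required key: out_dir")
    alpha = doc.get("alpha", 0.05)
    if not 0 < alpha < 1:
        errors.append(f"alpha must be in (0, 1): {alpha}")
    if errors:
        raise ConfigError(errors)
    out_dir = doc["out_dir"]
    if not os.path.isabs(out_dir):
        out_dir = os.path.join(base, out_dir)
    return RunConfig(
        regions=regions, out_dir=out_dir, seed=int(doc.get("seed", 0)),
        alpha=float(alpha), tm=tm,
        metagene_span=int(doc.get("metagene_span", 3000)),
        metagene_flank=int(doc.get("metagene_flank", 2000)),
        reference_counts=doc.get("reference_counts"),
        ortholog_pairs=doc.get("ortholog_pairs"),
        expression=doc.get("expression"),
        drop_simple_repeats=bool(doc.get("drop_simple_repeats", True)),
        force=bool(doc.get("force", False)),
    )


def read_reference_counts(path: str) -> CodonCounts:
    df = pd.read_csv(path, sep="\t")
    cod_col, val_col = df.columns[:2]
    counts = {c: 0 for c in ALL_CODONS}
    for _, row in df.iterrows():
        counts[str(row[cod_col]).upper()] = int(row[val_col])
    return CodonCounts(counts)


@dataclass
class ReportBundle:
    out_dir: str
    manifest: dict
    tables: dict = field(default_factory=dict)   # name -> DataFrame


def _stage(manifest, name, t0, **info):
    manifest["stages"].append({"stage": name, "seconds": round(time.time() - t0, 2), **info})
    logger.info("stage %-18s %6.2fs %s", name, time.time() - t0, info)


def run_compare(config: RunConfig) -> ReportBundle:
    """Execute the full comparative analysis and write the report bundle."""
    cfg = config
    if os.path.isdir(cfg.out_dir) and os.listdir(cfg.out_dir) and not cfg.force:
        raise FileExistsError(f"output directory {cfg.out_dir} is not empty; "
                              "use a new directory or force=True")
    os.makedirs(cfg.out_dir, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    manifest = {
        "version": __version__, "seed": cfg.seed,
        "config_hash": hashlib.sha256(
            json.dumps(cfg.canonical(), sort_keys=True, default=str).encode()).hexdigest(),
        "stages": [], "skipped": [],
    }
    tables: dict[str, pd.DataFrame] = {}

    def save(name: str, df: pd.DataFrame):
        tables[name] = df
        df.to_csv(os.path.join(cfg.out_dir, f"{name}.tsv"), sep="\t", index=False)

    weights = None
    eq_threshold = None
    if cfg.reference_counts:
        ref = read_reference_counts(cfg.reference_counts)
        weights = relative_adaptiveness(ref)
        eq_threshold = equal_usage_cai(weights)
    else:
        manifest["skipped"].append("codon CAI (no reference_counts)")

    density_rows, top_tables, partition_rows = [], [], []
    metric_frames, codon_frames, freq_frames, gc_region_rows = {}, {}, [], []
    metagene_frames = []
    per_region_metrics: dict[str, pd.DataFrame] = {}
    isoforms_by_region: dict[str, dict] = {}

    for reg_in in cfg.regions:
        region = AnalysisRegion.from_bed(reg_in.bed, reg_in.name)
        genome = read_fasta(reg_in.genome)

        # --- repeat ledger
        t0 = time.time()
        if reg_in.repeats:
            feats = parse_repeatmasker_out(reg_in.repeats)
            if reg_in.min_score is not None:
                feats = score_filter(feats, reg_in.min_score)
            tx_feats = ([f for f in feats if f.canonical_class != "Simple_LowComplexity"]
                        if cfg.drop_simple_repeats else feats)
            segs = merge_by_class(tx_feats)
            rep = class_density(segs, region)
            density_rows.append(rep.to_frame())
            tt = top_repeat_table(tx_feats, region, 10)
            tt.insert(0, "region", reg_in.name)
            top_tables.append(tt)
            write_bed(os.path.join(cfg.out_dir, f"{reg_in.name}.merged_repeats.bed"),
                      [(s.seq_id, s.start, s.end, s.canonical_class) for s in segs])
            _stage(manifest, f"repeats[{reg_in.name}]", t0,
                   fragments=len(feats), segments=len(segs))
        else:
            manifest["skipped"].append(f"repeats[{reg_in.name}] (no .out)")

        # --- gene architecture
        t0 = time.time()
        isoforms = read_isoforms(reg_in.annotation)
        isoforms_by_region[reg_in.name] = isoforms
        mt_df = metrics_table(isoforms)
        mt_df.insert(0, "region", reg_in.name)
        per_region_metrics[reg_in.name] = mt_df
        metric_frames[reg_in.name] = mt_df
        comp = {g: select_comprehensive_isoform(v) for g, v in isoforms.items()}
        parts = partition_regions(list(comp.values()), region)
        sizes = {k: sum(e - s for _, s, e in v) for k, v in parts.items()}
        partition_rows.append({"region": reg_in.name, **sizes,
                               "total_bp": region.total_bp})
        _stage(manifest, f"genes[{reg_in.name}]", t0, genes=len(isoforms))

        # --- codon bias
        t0 = time.time()
        crow, all_counts = [], CodonCounts()
        for g, iso in sorted(comp.items()):
            cds = extract_cds(genome, iso)
            if len(cds) % 3:
                logger.warning("%s: CDS length not divisible by 3; skipped", g)
                continue
            cc = count_codons(cds)
            gc = gc_partition(cc)
            row = {"region": reg_in.name, "gene_id": g,
                   "nc": effective_number_of_codons(cc, "finite_sample"), **gc}
            if weights is not None:
                row["cai"] = codon_adaptation_index(cc, weights)
            crow.append(row)
            all_counts = all_counts + cc
        codon_frames[reg_in.name] = pd.DataFrame(crow)
        gc_all = gc_partition(all_counts)
        gc_region_rows.append({"region": reg_in.name,
                               "codons": all_counts.total_sense, **gc_all})
        fr = codon_frequency(all_counts)
        fr.insert(0, "region", reg_in.name)
        freq_frames.append(fr)
        _stage(manifest, f"codons[{reg_in.name}]", t0, genes=len(crow))

        # --- metagenes (Tm always; LLR when tracks supplied)
        t0 = time.time()
        gene_list = list(comp.values())
        tm_dense = {sid: window_tm(seq, cfg.tm) for sid, seq in genome.items()}
        tm_profiles = []
        for iso in gene_list:
            tm = tm_dense[iso.seq_id]
            track = SignalTrack(iso.seq_id, [0], [len(tm)], [0.0])
            up, span, down = signal_profile(track, iso, cfg.metagene_flank,
                                            seq_length=len(tm), dense=tm)
            if len(span) >= 2:
                tm_profiles.append((up, span, down))
        if tm_profiles:
            mg = build_metagene(tm_profiles, cfg.metagene_span, cfg.metagene_flank).smooth()
            df = mg.to_frame()
            df.insert(0, "signal", "tm")
            df.insert(0, "region", reg_in.name)
            metagene_frames.append(df)
        if reg_in.treatment and reg_in.control:
            tr = read_bedgraph(reg_in.treatment)
            cl = read_bedgraph(reg_in.control)
            llr_dense = {sid: loglik_enrichment(tr[sid], cl[sid]).to_dense(len(genome[sid]))
                         for sid in tr if sid in cl}
            prof_list = []
            for iso in gene_list:
                if iso.seq_id not in llr_dense:
                    continue
                d = llr_dense[iso.seq_id]
                track = SignalTrack(iso.seq_id, [0], [len(d)], [0.0])
                up, span, down = signal_profile(track, iso, cfg.metagene_flank,
                                                seq_length=len(d), dense=d)
                if len(span) >= 2:
                    prof_list.append((up, span, down))
            if prof_list:
                mg = build_metagene(prof_list, cfg.metagene_span, cfg.metagene_flank).smooth()
                df = mg.to_frame()
                df.insert(0, "signal", "llr")
                df.insert(0, "region", reg_in.name)
                metagene_frames.append(df)
        else:
            manifest["skipped"].append(f"llr_metagene[{reg_in.name}] (no tracks)")
        _stage(manifest, f"metagene[{reg_in.name}]", t0, genes=len(tm_profiles))

    if density_rows:
        dens = pd.concat(density_rows, ignore_index=True)
        totals = dens[dens["class"] == "TOTAL"].sort_values("density", ascending=False)
        dens["region"] = pd.Categorical(dens["region"], totals["region"].tolist())
        save("repeat_density", dens.sort_values(["region", "class"]))
        save("top_repeats", pd.concat(top_tables, ignore_index=True))
    save("region_partitions", pd.DataFrame(partition_rows))
    save("gene_metrics", pd.concat(metric_frames.values(), ignore_index=True))
    codon_df = pd.concat(codon_frames.values(), ignore_index=True)
    if eq_threshold is not None:
        codon_df["equal_usage_cai"] = eq_threshold
    save("codon_bias", codon_df)
    save("region_gc", pd.DataFrame(gc_region_rows))
    save("codon_frequency", pd.concat(freq_frames, ignore_index=True))
    if metagene_frames:
        save("metagenes", pd.concat(metagene_frames, ignore_index=True))

    # --- statistics across regions
    t0 = time.time()
    stat_rows, pair_frames = [], []
    metrics_all = tables["gene_metrics"]
    for col in ("coding_span_size", "total_intron_size", "total_cds_size",
                "median_cds_size", "median_intron_size"):
        groups, labels = [], []
        for name, df in metric_frames.items():
            vals = np.log10(df[col].dropna().to_numpy(dtype=float) + 1.0)
            if len(vals):
                groups.append(vals)
                labels.append(name)
        if len(groups) >= 2:
            gcmp = dunn_holm(groups, labels, alpha=cfg.alpha)
            stat_rows.append({"variable": f"log10_{col}", "kw_h": gcmp.kw_h,
                              "kw_p": gcmp.kw_p, "posthoc": gcmp.posthoc_run})
            if gcmp.posthoc_run:
                pf = gcmp.pairs.copy()
                pf.insert(0, "variable", f"log10_{col}")
                pair_frames.append(pf)
    for col in ("nc", "cai", "GC3"):
        groups, labels = [], []
        for name, df in codon_frames.items():
            if col in df.columns:
                vals = df[col].dropna().to_numpy(dtype=float)
                if len(vals):
                    groups.append(vals)
                    labels.append(name)
        if len(groups) >= 2:
            gcmp = dunn_holm(groups, labels, alpha=cfg.alpha)
            stat_rows.append({"variable": col, "kw_h": gcmp.kw_h, "kw_p": gcmp.kw_p,
                              "posthoc": gcmp.posthoc_run})
            if gcmp.posthoc_run:
                pf = gcmp.pairs.copy()
                pf.insert(0, "variable", col)
                pair_frames.append(pf)
    save("kw_tests", pd.DataFrame(stat_rows))
    if pair_frames:
        save("dunn_pairs", pd.concat(pair_frames, ignore_index=True))
    _stage(manifest, "stats", t0, variables=len(stat_rows))

    # --- ortholog differences and CAI enrichment
    if cfg.ortholog_pairs and len(cfg.regions) >= 2:
        t0 = time.time()
        pairs = pd.read_csv(cfg.ortholog_pairs, sep="\t")
        a_name, b_name = cfg.regions[0].name, cfg.regions[1].name
        met = {}
        for name in (a_name, b_name):
            met[name] = {g: coding_metrics(select_comprehensive_isoform(v))
                         for g, v in isoforms_by_region[name].items()}
        dt = difference_table(met[a_name], met[b_name],
                              pairs.itertuples(index=False, name=None))
        save("ortholog_differences", dt)
        if weights is not None and not dt.empty and "cai" in codon_frames[a_name]:
            cai_a = dict(zip(codon_frames[a_name]["gene_id"], codon_frames[a_name]["cai"]))
            dt2 = dt[dt["gene_a"].isin(cai_a)]
            high_cai = {g for g in dt2["gene_a"] if cai_a[g] > eq_threshold}
            smaller = {g for g, d in zip(dt2["gene_a"], dt2["d_total_intron_size"])
                       if d is not None and d < 0}
            N, K = len(dt2), len(high_cai)
            n, k = len(smaller), len(high_cai & smaller)
            if N and K and n:
                er = hypergeom_upper(N, K, n, k)
                save("cai_enrichment", pd.DataFrame([{
                    "population": N, "high_cai": K, "smaller_intron": n,
                    "overlap": k, "p_value": er.p_value,
                    "equal_usage_cai": eq_threshold}]))
        _stage(manifest, "orthologs", t0, pairs=len(dt))
    elif cfg.ortholog_pairs:
        manifest["skipped"].append("orthologs (need >= 2 regions)")
    else:
        manifest["skipped"].append("orthologs (no pairs file)")

    # --- expression comparison
    if cfg.expression:
        t0 = time.time()
        expr = pd.read_csv(cfg.expression, sep="\t")
        gcol, vcol = expr.columns[:2]
        expr_map = dict(zip(expr[gcol], expr[vcol]))
        groups, labels = [], []
        rows = []
        for name, df in metric_frames.items():
            vals = [expr_map[g] for g in df["gene_id"] if g in expr_map]
            if vals:
                groups.append(np.asarray(vals, dtype=float))
                labels.append(name)
            cdf = codon_frames.get(name)
            if cdf is not None and "cai" in cdf.columns:
                paired = [(c, expr_map[g]) for g, c in zip(cdf["gene_id"], cdf["cai"])
                          if g in expr_map]
                if len(paired) >= 3:
                    rho, p, status = spearman([x for x, _ in paired],
                                              [y for _, y in paired])
                    rows.append({"region": name, "rho": rho, "p": p,
                                 "status": status, "n": len(paired)})
        if len(groups) >= 2:
            gcmp = dunn_holm(groups, labels, alpha=cfg.alpha)
            save("expression_kw", pd.DataFrame([{
                "kw_h": gcmp.kw_h, "kw_p": gcmp.kw_p, "posthoc": gcmp.posthoc_run}]))
            if gcmp.posthoc_run:
                save("expression_dunn", gcmp.pairs)
        if rows:
            save("expression_cai_spearman", pd.DataFrame(rows))
        _stage(manifest, "expression", t0, groups=len(groups))
    else:
        manifest["skipped"].append("expression (no matrix)")

    for name, df in tables.items():
        manifest.setdefault("tables", {})[name] = len(df)
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return ReportBundle(cfg.out_dir, manifest, tables)
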