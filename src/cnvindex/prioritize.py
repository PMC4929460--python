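"""Candidate-gene prioritization: module x critical exons x CNV evidence.

The final candidate set is the triple intersection of (i) the co-expression
module whose functional enrichment best matches a keyword (the analysis's
"blue module" step), (ii) genes in the genome's top quartile of
critical-exon fraction — by default required in both developmental periods —
and (iii) genes inside case-exclusive pathogenic/VOUS CNVs.  Enrichment
statistics are reported evidence; candidacy never depends on a p-value.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnv_sets, coexpression, enrichment, exon_index, io, synthetic

logger = logging.getLogger(__name__)

INTERSECTION_MODES = ("both_periods", "either_period")


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Everything needed for one end-to-end run.

    Exactly one of ``sim`` (self-generate synthetic inputs) or ``paths``
    (load the declared TSV/GMT files: keys annotation, expression,
    sample_meta, proteome, tissue_meta, cases, controls, gene_sets) must be
    given.
    """

    sim: synthetic.SimConfig | None = None
    paths: dict | None = None
    critical: exon_index.CriticalExonConfig = dataclasses.field(
        default_factory=exon_index.CriticalExonConfig)
    wgcna: coexpression.WgcnaConfig = dataclasses.field(
        default_factory=coexpression.WgcnaConfig)
    enrich: enrichment.EnrichmentConfig = dataclasses.field(
        default_factory=enrichment.EnrichmentConfig)
    cnv_filter: cnv_sets.CnvFilterConfig = dataclasses.field(
        default_factory=cnv_sets.CnvFilterConfig)
    module_keywords: tuple[str, ...] = ("synaptic",)
    intersection_mode: str = "both_periods"

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.paths is None):
            raise ValueError("exactly one of sim / paths must be provided")
        if self.intersection_mode not in INTERSECTION_MODES:
            raise ValueError(f"intersection_mode must be one of {INTERSECTION_MODES}")


@dataclasses.dataclass
class PipelineResult:
    report: pd.DataFrame  # the candidate report, one row per critical-module gene
    candidates: set[str]
    selected_module: str
    partition: coexpression.ModulePartition
    top_prenatal: set[str]
    top_adult: set[str]
    critical_module: set[str]
    exclusive_sets: dict
    enrichment_battery: pd.DataFrame
    cohort: dict
    ground_truth: dict | None = None


def select_module(partition: coexpression.ModulePartition,
                  collection: enrichment.GeneSetCollection,
                  background: set[str], keywords) -> str:
    """Pick the module whose best keyword-matching term is most significant.

    Each module's genes are tested against every term (FET, Bonferroni over
    the collection); the module whose smallest corrected p among
    keyword-matching terms is lowest wins.  Ties break to the larger module,
    then lexicographic label.
    """
    kw = [k.lower() for k in keywords]
    matching = [t for t in collection.names() if any(k in t.lower() for k in kw)]
    if not matching:
        raise ValueError(f"no term in the collection matches keywords {list(keywords)}")
    best: tuple | None = None
    for m in partition.modules:
        genes = partition.genes_in(m)
        table = enrichment.term_enrichment(
            genes, collection, background,
            enrichment.EnrichmentConfig(top_k_terms=len(collection)))
        hit = table[table["term"].isin(matching)]
        if hit.empty:
            continue
        p = float(hit["p_bonferroni"].iloc[0])
        key = (p, -len(genes), m)
        if best is None or key < best:
            best = key
    if best is None:
        raise ValueError("no module could be scored against the keyword terms")
    return best[2]


def critical_module_genes(module_genes: set[str], top_prenatal: set[str],
                          top_adult: set[str], mode: str = "both_periods") -> set[str]:
    """Intersect module membership with top-critical calls per the chosen mode."""
    if mode == "both_periods":
        return set(module_genes) & set(top_prenatal) & set(top_adult)
    if mode == "either_period":
        return set(module_genes) & (set(top_prenatal) | set(top_adult))
    raise ValueError(f"unknown intersection mode {mode!r}")


def cnv_candidates(critical_module: set[str], exclusive_sets: dict,
                   case_hits: pd.DataFrame) -> pd.DataFrame:
    """Annotate critical-module genes with CNV evidence and flag candidates.

    A gene is a candidate iff it lies in the union of the case-exclusive
    pathogenic/VOUS sets.  Hit counts per (class, type) stratum, de novo hit
    counts, and recurrence (>= 2 distinct case samples) are annotation only.
    """
    exclusive_union: set[str] = set()
    for genes in exclusive_sets.values():
        exclusive_union |= set(genes)
    rows = []
    by_gene = dict(tuple(case_hits.groupby("gene_id"))) if len(case_hits) else {}
    for gene in sorted(critical_module):
        h = by_gene.get(gene)
        counts = {f"{cls}_{typ}_hits": 0 for cls, typ in cnv_sets.CASE_STRATA}
        n_de_novo = 0
        n_samples = 0
        if h is not None:
            for (cls, typ), sub in h.groupby(["class", "type"]):
                counts[f"{cls}_{typ}_hits"] = int(len(sub))
            n_de_novo = int((h["inheritance"] == "de_novo").sum())
            n_samples = int(h["sample_id"].nunique())
        rows.append({
            "gene_id": gene,
            **counts,
            "total_case_hits": sum(counts.values()),
            "de_novo_hits": n_de_novo,
            "n_case_samples": n_samples,
            "recurrent": n_samples >= 2,
            "candidate": gene in exclusive_union,
        })
    return pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["candidate"], index=pd.Index([], name="gene_id"))


def _load_inputs(cfg: PipelineConfig, seed: int | None):
    if cfg.sim is not None:
        sim = cfg.sim if seed is None else cfg.sim.replace(seed=seed)
        art = synthetic.generate_all(sim)
        truth = {"planted_genes": list(art["model"].planted_genes),
                 "module_labels": dict(art["proteome"].module_labels)}
        return art, truth
    p = cfg.paths
    annot = io.read_annotation(p["annotation"])
    expr = synthetic.ExpressionMatrix(
        values=io.read_matrix(p["expression"]),
        sample_meta=io.read_meta(p["sample_meta"], io.SAMPLE_META_COLUMNS))
    prot = synthetic.ProteinMatrix(
        values=io.read_matrix(p["proteome"]),
        tissue_meta=io.read_meta(p["tissue_meta"], io.TISSUE_META_COLUMNS))
    art = {
        "model": synthetic.GeneModel(
            exons=annot, planted_genes=(),
            chrom=str(annot["chrom"].iloc[0]),
            chrom_length=int(annot["end"].max())),
        "expression": expr,
        "proteome": prot,
        "cases": io.read_cnv_table(p["cases"]),
        "controls": io.read_cnv_table(p["controls"]),
        "gene_sets": enrichment.GeneSetCollection.from_gmt(p["gene_sets"]),
    }
    return art, None


def run_pipeline(cfg: PipelineConfig, outdir=None, seed: int | None = None) -> PipelineResult:
    """Execute the full analysis; deterministic given the seed.

    Stages: (simulate or load) -> critical exons -> CNV sets -> co-expression
    modules -> enrichment battery -> candidate prioritization.  When
    ``outdir`` is given every intermediate table, a JSON run summary, and
    per-stage timings are written there.
    """
    t0 = time.time()
    timings: dict[str, float] = {}
    art, truth = _load_inputs(cfg, seed)
    model: synthetic.GeneModel = art["model"]
    timings["inputs"] = time.time() - t0

    # critical exons
    t = time.time()
    ranks = exon_index.burden_percentiles(model.exons,
                                          length_normalized=cfg.critical.length_normalized)
    calls = exon_index.classify_critical(art["expression"], ranks, cfg.critical)
    fractions = exon_index.gene_fraction(calls, model.exons)
    meta = art["expression"].sample_meta
    top_prenatal = exon_index.top_critical_genes(fractions, meta, "prenatal", cfg.critical)
    top_adult = exon_index.top_critical_genes(fractions, meta, "adult", cfg.critical)
    regions = exon_index.region_summary(fractions, meta)
    timings["critical_exons"] = time.time() - t

    # CNV sets
    t = time.time()
    cases = cnv_sets.filter_by_size(art["cases"], cfg.cnv_filter)
    controls = cnv_sets.filter_by_size(art["controls"], cfg.cnv_filter)
    case_hits = cnv_sets.exonic_gene_hits(cases, model.exons)
    control_hits = cnv_sets.exonic_gene_hits(controls, model.exons)
    exclusive = cnv_sets.case_exclusive_sets(case_hits, control_hits)
    cohort = cnv_sets.cohort_summary(cases, case_hits)
    timings["cnv_sets"] = time.time() - t

    # co-expression network
    t = time.time()
    partition = coexpression.blockwise_modules(art["proteome"], cfg.wgcna)
    timings["coexpression"] = time.time() - t

    # enrichment battery
    t = time.time()
    proteome_bg = set(art["proteome"].values.index[(art["proteome"].values > 0).any(axis=1)])
    transcriptome_bg = set(model.exons.loc[
        model.exons["exon_id"].isin(art["expression"].values.index), "gene_id"])
    pt_bg = proteome_bg & transcriptome_bg
    collection = art["gene_sets"]
    selected = select_module(partition, collection, proteome_bg, cfg.module_keywords)
    module_genes = partition.genes_in(selected)

    perm_seed = int(np.random.SeedSequence(
        entropy=cfg.enrich.seed if seed is None else seed,
        spawn_key=(97,)).generate_state(1)[0] % (2**31))
    battery_rows = []
    tests = [("top_critical_prenatal_in_module", top_prenatal, module_genes, pt_bg),
             ("top_critical_adult_in_module", top_adult, module_genes, pt_bg)]
    control_genes = {"del": set(control_hits.loc[control_hits["type"] == "del", "gene_id"]),
                     "dup": set(control_hits.loc[control_hits["type"] == "dup", "gene_id"])}
    for (cls, typ), genes in exclusive.items():
        tests.append((f"{cls}_{typ}_exclusive_in_module", genes, module_genes, proteome_bg))
    for typ, genes in control_genes.items():
        tests.append((f"control_{typ}_in_module", genes, module_genes, proteome_bg))
    m_tests = len(tests)
    for i, (name, query, target, bg) in enumerate(tests):
        if not query:
            logger.warning("enrichment test %s skipped: empty query", name)
            continue
        ecfg = dataclasses.replace(cfg.enrich, seed=(perm_seed + i) % (2**31))
        res = enrichment.enrichment_with_permutation(query, target, bg, ecfg, m_tests=m_tests)
        battery_rows.append({
            "test": name, "a": res.table.a, "b": res.table.b,
            "c": res.table.c, "d": res.table.d,
            "odds_ratio": res.odds_ratio, "p": res.p_value,
            "p_bonferroni": res.p_bonferroni, "p_empirical": res.p_empirical,
            "n_perm": res.n_permutations,
        })
    battery = pd.DataFrame(battery_rows)
    timings["enrichment"] = time.time() - t

    # prioritization
    t = time.time()
    critical_module = critical_module_genes(module_genes, top_prenatal, top_adult,
                                            cfg.intersection_mode)
    report = cnv_candidates(critical_module, exclusive, case_hits)
    candidates = set(report.index[report["candidate"]]) if len(report) else set()
    timings["prioritize"] = time.time() - t

    result = PipelineResult(
        report=report, candidates=candidates, selected_module=selected,
        partition=partition, top_prenatal=top_prenatal, top_adult=top_adult,
        critical_module=critical_module, exclusive_sets=exclusive,
        enrichment_battery=battery, cohort=cohort, ground_truth=truth)

    if outdir is not None:
        _write_artifacts(result, cfg, art, fractions, regions, timings, seed, Path(outdir))
    return result


def _write_artifacts(result: PipelineResult, cfg: PipelineConfig, art: dict,
                     fractions, regions: pd.DataFrame, timings: dict,
                     seed: int | None, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    if cfg.sim is not None:
        synthetic.write_all(art, out / "inputs")
    io.write_matrix(fractions.values, out / "gene_fractions.tsv", index_label="gene_id")
    regions.to_csv(out / "region_summary.tsv", sep="\t", index=False)
    io.write_gene_list(result.top_prenatal, out / "top_critical_prenatal.txt")
    io.write_gene_list(result.top_adult, out / "top_critical_adult.txt")
    part = result.partition
    pd.DataFrame({
        "module": part.labels,
        "kTotal": part.connectivity["kTotal"],
        "kWithin": part.connectivity["kWithin"],
    }).to_csv(out / "module_partition.tsv", sep="\t", index_label="gene_id")
    io.write_matrix(part.eigengenes, out / "eigengenes.tsv", index_label="module")
    gmt = {f"{cls.upper()}_{typ.upper()}_EXCL": (f"case-exclusive {cls} {typ} genes",
                                                 tuple(sorted(genes)))
           for (cls, typ), genes in result.exclusive_sets.items() if genes}
    if gmt:
        io.write_gmt(gmt, out / "case_exclusive_sets.gmt")
    result.enrichment_battery.to_csv(out / "enrichment_battery.tsv", sep="\t", index=False)
    result.report.to_csv(out / "candidate_report.tsv", sep="\t")
    io.write_gene_list(result.candidates, out / "candidates.txt")
    summary = {
        "seed": seed if seed is not None else (cfg.sim.seed if cfg.sim else None),
        "selected_module": result.selected_module,
        "n_candidates": len(result.candidates),
        "n_critical_module": len(result.critical_module),
        "intersection_mode": cfg.intersection_mode,
        "cohort": _jsonable(result.cohort),
        "timings_sec": {k: round(v, 3) for k, v in timings.items()},
    }
    io.write_json(summary, out / "run_summary.json")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def recovery_metrics(candidates: set[str], planted: set[str],
                     universe: set[str] | None = None) -> dict:
    """Sensitivity and precision of a candidate set against planted truth."""
    planted = set(planted)
    candidates = set(candidates)
    tp = len(candidates & planted)
    sens = tp / len(planted) if planted else float("nan")
    prec = tp / len(candidates) if candidates else float("nan")
    return {"sensitivity": sens, "precision": prec,
            "n_candidates": len(candidates), "n_planted": len(planted)}
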