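"""Synthetic inputs for the CNV-indexing pipeline, with planted ground truth.

The generators emulate the statistical structure of the real data the
analysis was designed for, at desk scale:

* a gene/exon annotation on one synthetic chromosome, with per-exon rare
  deleterious-variant burden counts (Poisson; planted "neuro risk" genes get a
  low rate, background genes a high one);
* an exon x brain-sample RPKM matrix over 16 regions x {prenatal, adult},
  with planted genes drawn from a high-mean log-normal stratum;
* a gene x tissue spectral-count matrix (24 tissues, 7 prenatal) from a
  latent-factor model with planted co-expression modules;
* case/control CNV cohorts whose pathogenic/VOUS calls preferentially cover
  planted genes, against uniformly placed control CNVs;
* a GMT gene-set collection containing one "planted_synaptic" term.

All randomness flows from ``SimConfig.seed`` through a named-stage
seed-splitting scheme, so the same config always yields byte-identical
outputs and individual stages can be re-run reproducibly.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import io

#: the 16 BrainSpan brain-region labels (11 neocortical + 5 other)
BRAIN_REGIONS = (
    "A1C", "AMY", "CBC", "DFC", "HIP", "IPC", "ITC", "M1C",
    "MD", "MFC", "OFC", "S1C", "STC", "STR", "V1C", "VFC",
)
PERIODS = ("prenatal", "adult")

_STAGES = ("gene_model", "expression", "proteome", "cnv", "gene_sets")


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the shape of the source datasets (16 brain regions in two
    developmental periods; 24 proteome tissues of which 7 prenatal) at a size
    a single CPU handles comfortably.  Effect sizes (burden rates, expression
    strata, within-module correlation) are set so the planted signal is
    strong, i.e. the conditions the method assumes, not borderline ones.
    """

    seed: int = 0
    # gene model
    n_genes: int = 800
    exons_per_gene_mean: float = 8.0
    n_planted: int = 50
    exon_length: int = 150
    intron_length: int = 2_000
    intergenic_gap: int = 20_000_000
    chrom: str = "chrS"
    # burden (per-exon Poisson means)
    burden_rate_planted: float = 0.5
    burden_rate_background: float = 5.0
    # brain expression
    regions: tuple[str, ...] = BRAIN_REGIONS
    periods: tuple[str, ...] = PERIODS
    samples_per_region_period: int = 3
    expr_meanlog_planted: float = 3.0
    expr_meanlog_background: float = 0.0
    expr_sdlog: float = 1.0
    # proteome
    n_tissues: int = 24
    n_prenatal_tissues: int = 7
    n_modules: int = 5
    module_sizes: tuple[int, ...] = (50, 50, 50, 50, 50)
    within_module_cor: float = 0.8
    protein_meanlog: float = 3.0
    protein_sdlog: float = 0.5
    protein_dropout: float = 0.05
    # CNV cohorts
    n_cases: int = 500
    n_controls: int = 500
    p_pathogenic: float = 0.10
    p_vous: float = 0.50
    p_female: float = 0.315
    p_de_novo: float = 0.25
    p_inherited: float = 0.55
    planted_overlap_prob: float = 0.9
    cnv_size_range: tuple[int, int] = (5_000, 5_500_000)
    # gene sets
    n_random_sets: int = 50
    set_noise_fraction: float = 0.1

    def __post_init__(self) -> None:
        counts = dict(
            n_genes=self.n_genes, n_planted=self.n_planted,
            samples_per_region_period=self.samples_per_region_period,
            n_tissues=self.n_tissues, n_modules=self.n_modules,
            n_cases=self.n_cases, n_controls=self.n_controls,
            exon_length=self.exon_length,
        )
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        probs = dict(
            p_pathogenic=self.p_pathogenic, p_vous=self.p_vous,
            p_female=self.p_female, p_de_novo=self.p_de_novo,
            p_inherited=self.p_inherited,
            planted_overlap_prob=self.planted_overlap_prob,
            protein_dropout=self.protein_dropout,
            set_noise_fraction=self.set_noise_fraction,
        )
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if not 0.0 <= self.within_module_cor <= 1.0:
            raise ValueError("within_module_cor must be in [0, 1]")
        if self.exons_per_gene_mean < 1:
            raise ValueError("exons_per_gene_mean must be >= 1")
        if self.p_de_novo + self.p_inherited > 1.0:
            raise ValueError("inheritance probabilities exceed 1")
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("sum(module_sizes) must be <= n_genes")
        if any(s <= 0 for s in self.module_sizes):
            raise ValueError("module sizes must be > 0")
        if self.n_planted > self.n_genes:
            raise ValueError("n_planted must be <= n_genes")
        if self.n_prenatal_tissues >= self.n_tissues:
            raise ValueError("n_prenatal_tissues must be < n_tissues")
        lo, hi = self.cnv_size_range
        if not (0 < lo < hi):
            raise ValueError("cnv_size_range must satisfy 0 < min < max")
        if not self.regions:
            raise ValueError("regions must be non-empty")

    def rng(self, stage: str) -> np.random.Generator:
        """A generator for one named stage, split off the master seed."""
        key = _STAGES.index(stage)
        return np.random.default_rng(np.random.SeedSequence(entropy=self.seed, spawn_key=(key,)))

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclasses.dataclass
class GeneModel:
    """Exon annotation plus the planted ground truth it was drawn under."""

    exons: pd.DataFrame  # gene_id, exon_id, chrom, start, end, burden_count
    planted_genes: tuple[str, ...]
    chrom: str
    chrom_length: int

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.exons["gene_id"].unique())


@dataclasses.dataclass
class ExpressionMatrix:
    """Exon x sample RPKM values with (region, period) sample metadata."""

    values: pd.DataFrame
    sample_meta: pd.DataFrame  # sample_id, region, period

    def samples_for(self, period: str) -> list[str]:
        m = self.sample_meta
        return list(m.loc[m["period"] == period, "sample_id"])


@dataclasses.dataclass
class ProteinMatrix:
    """Gene x tissue spectral counts with per-tissue period metadata."""

    values: pd.DataFrame
    tissue_meta: pd.DataFrame  # tissue_id, period
    module_labels: pd.Series | None = None  # planted ground truth, if simulated


def generate_gene_model(cfg: SimConfig) -> GeneModel:
    """Tile non-overlapping genes on one synthetic chromosome.

    Exon counts are 1 + Poisson(mean - 1) so the mean matches
    ``exons_per_gene_mean`` with a hard floor of one exon.  Burden counts are
    Poisson with the planted rate for the first ``n_planted`` genes (the
    planted risk genes) and the background rate otherwise, emulating the low
    rare missense/LOF burden of constrained neurodevelopmental genes.
    """
    rng = cfg.rng("gene_model")
    n_exons = 1 + rng.poisson(cfg.exons_per_gene_mean - 1.0, size=cfg.n_genes)
    records = []
    cursor = cfg.intergenic_gap
    planted = [f"G{i:04d}" for i in range(cfg.n_planted)]
    for gi in range(cfg.n_genes):
        gene_id = f"G{gi:04d}"
        rate = cfg.burden_rate_planted if gi < cfg.n_planted else cfg.burden_rate_background
        burdens = rng.poisson(rate, size=n_exons[gi])
        for ei in range(n_exons[gi]):
            start = cursor + ei * (cfg.exon_length + cfg.intron_length)
            records.append((gene_id, f"{gene_id}_E{ei:02d}", cfg.chrom,
                            start, start + cfg.exon_length, int(burdens[ei])))
        gene_span = n_exons[gi] * cfg.exon_length + (n_exons[gi] - 1) * cfg.intron_length
        cursor += gene_span + cfg.intergenic_gap
    exons = pd.DataFrame.from_records(records, columns=io.ANNOT_COLUMNS)
    return GeneModel(exons=exons, planted_genes=tuple(planted),
                     chrom=cfg.chrom, chrom_length=int(cursor))


def generate_brain_expression(model: GeneModel, cfg: SimConfig) -> ExpressionMatrix:
    """Draw an exon x sample RPKM matrix over the region x period grid.

    Values are i.i.d. log-normal per exon per sample, with the mean-log set by
    whether the exon's gene is planted.  Planted exons therefore sit in the
    genome's upper expression tail in every brain sample, which is the
    "highly expressed in brain" half of the critical-exon definition.
    """
    if not cfg.regions:
        raise ValueError("region list is empty")
    rng = cfg.rng("expression")
    sample_ids, regions, periods = [], [], []
    for region in cfg.regions:
        for period in cfg.periods:
            for rep in range(cfg.samples_per_region_period):
                sample_ids.append(f"{region}_{period}_{rep + 1:02d}")
                regions.append(region)
                periods.append(period)
    meta = pd.DataFrame({"sample_id": sample_ids, "region": regions, "period": periods})
    exon_ids = model.exons["exon_id"].to_numpy()
    is_planted = model.exons["gene_id"].isin(model.planted_genes).to_numpy()
    meanlog = np.where(is_planted, cfg.expr_meanlog_planted, cfg.expr_meanlog_background)
    z = rng.standard_normal((len(exon_ids), len(sample_ids)))
    values = np.exp(meanlog[:, None] + cfg.expr_sdlog * z)
    df = pd.DataFrame(values, index=exon_ids, columns=sample_ids)
    df.index.name = "exon_id"
    return ExpressionMatrix(values=df, sample_meta=meta)


def generate_proteome(model: GeneModel, cfg: SimConfig) -> ProteinMatrix:
    """Draw a gene x tissue spectral-count matrix with planted modules.

    Modules occupy disjoint consecutive gene blocks starting at the first
    gene, so module 1 coincides with the planted risk genes when
    ``module_sizes[0] == n_planted`` (the default).  Each member's latent
    profile is sqrt(rho) * module factor + sqrt(1 - rho) * noise across
    tissues, giving expected latent correlation rho = ``within_module_cor``;
    counts are round(exp(mu + sigma * latent)) with a dropout mask providing
    zero inflation (the pipeline's >=90%-zero filter needs zeros to exist).
    """
    rng = cfg.rng("proteome")
    genes = list(model.gene_ids)
    n = len(genes)
    periods = ["prenatal"] * cfg.n_prenatal_tissues + ["adult"] * (cfg.n_tissues - cfg.n_prenatal_tissues)
    tissue_ids = [f"T{i:02d}_{p}" for i, p in enumerate(periods)]
    meta = pd.DataFrame({"tissue_id": tissue_ids, "period": periods})

    rho = cfg.within_module_cor
    factors = rng.standard_normal((cfg.n_modules, cfg.n_tissues))
    latent = rng.standard_normal((n, cfg.n_tissues))  # noise for every gene
    labels = np.array(["unassigned"] * n, dtype=object)
    offset = 0
    for m, size in enumerate(cfg.module_sizes):
        block = slice(offset, offset + size)
        latent[block] = math.sqrt(rho) * factors[m] + math.sqrt(1.0 - rho) * latent[block]
        labels[block] = f"M{m + 1}"
        offset += size

    counts = np.rint(np.exp(cfg.protein_meanlog + cfg.protein_sdlog * latent))
    if cfg.protein_dropout > 0:
        counts[rng.random(counts.shape) < cfg.protein_dropout] = 0.0
    df = pd.DataFrame(counts, index=genes, columns=tissue_ids)
    df.index.name = "gene_id"
    truth = pd.Series(labels, index=genes, name="module")
    return ProteinMatrix(values=df, tissue_meta=meta, module_labels=truth)


def _log_uniform_sizes(rng: np.random.Generator, lo: int, hi: int, n: int) -> np.ndarray:
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size=n)).astype(np.int64)


def generate_cnv_cohort(model: GeneModel, cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate case and control CNV tables.

    Each case independently carries a pathogenic CNV with probability
    ``p_pathogenic`` and a VOUS with probability ``p_vous``; each such call
    covers an exon of a uniformly chosen planted gene with probability
    ``planted_overlap_prob``, otherwise it is placed uniformly.  Each control
    carries one uniformly placed rare CNV.  Sizes are log-uniform over
    ``cnv_size_range``, which straddles the 30 kb and 5 Mb analysis bounds so
    the size filter is exercised in both directions.
    """
    if model.exons.empty:
        raise ValueError("empty gene model")
    rng = cfg.rng("cnv")
    lo, hi = cfg.cnv_size_range
    exons_by_gene = {g: sub[["start", "end"]].to_numpy()
                     for g, sub in model.exons.groupby("gene_id", sort=False)}
    planted = list(model.planted_genes)

    def place_targeted(size: int) -> tuple[int, int]:
        gene = planted[rng.integers(len(planted))]
        ex = exons_by_gene[gene]
        es, ee = ex[rng.integers(len(ex))]
        start = int(rng.integers(max(0, es - size + 1), ee))
        end = min(start + size, model.chrom_length)
        return start, end

    def place_uniform(size: int) -> tuple[int, int]:
        start = int(rng.integers(0, max(1, model.chrom_length - size)))
        return start, start + size

    def inheritance() -> str:
        u = rng.random()
        if u < cfg.p_de_novo:
            return "de_novo"
        if u < cfg.p_de_novo + cfg.p_inherited:
            return "inherited"
        return "unknown"

    case_rows = []
    for ci in range(cfg.n_cases):
        sid = f"case_{ci:04d}"
        sex = "F" if rng.random() < cfg.p_female else "M"
        for cls, p in (("pathogenic", cfg.p_pathogenic), ("vous", cfg.p_vous)):
            if rng.random() >= p:
                continue
            size = int(_log_uniform_sizes(rng, lo, hi, 1)[0])
            if rng.random() < cfg.planted_overlap_prob:
                start, end = place_targeted(size)
            else:
                start, end = place_uniform(size)
            typ = "del" if rng.random() < 0.5 else "dup"
            case_rows.append((sid, model.chrom, start, end, typ, cls, inheritance(), sex))

    control_rows = []
    for ki in range(cfg.n_controls):
        sid = f"ctrl_{ki:04d}"
        sex = "F" if rng.random() < cfg.p_female else "M"
        size = int(_log_uniform_sizes(rng, lo, hi, 1)[0])
        start, end = place_uniform(size)
        typ = "del" if rng.random() < 0.5 else "dup"
        control_rows.append((sid, model.chrom, start, end, typ, "control", "unknown", sex))

    cases = pd.DataFrame.from_records(case_rows, columns=io.CNV_COLUMNS)
    controls = pd.DataFrame.from_records(control_rows, columns=io.CNV_COLUMNS)
    return cases, controls


def generate_gene_sets(model: GeneModel, cfg: SimConfig):
    """Build a GMT-style collection: one planted term plus random same-size sets.

    The planted term ("planted_synaptic") contains the planted genes plus a
    configurable fraction of random background genes as annotation noise;
    random terms are uniform draws from all genes and calibrate the
    enrichment null.
    """
    from .enrichment import GeneSetCollection

    rng = cfg.rng("gene_sets")
    genes = np.array(model.gene_ids)
    background = [g for g in genes if g not in set(model.planted_genes)]
    n_noise = int(round(cfg.set_noise_fraction * cfg.n_planted))
    noise = list(rng.choice(background, size=n_noise, replace=False)) if n_noise else []
    sets = {"planted_synaptic": ("synaptic transmission (planted term)",
                                 tuple(list(model.planted_genes) + noise))}
    size = cfg.n_planted + n_noise
    for k in range(cfg.n_random_sets):
        members = tuple(rng.choice(genes, size=size, replace=False))
        sets[f"random_{k:03d}"] = ("random control term", members)
    return GeneSetCollection(sets=sets)


def generate_all(cfg: SimConfig):
    """Run every generator off one config; returns a dict of artifacts."""
    model = generate_gene_model(cfg)
    expr = generate_brain_expression(model, cfg)
    prot = generate_proteome(model, cfg)
    cases, controls = generate_cnv_cohort(model, cfg)
    collection = generate_gene_sets(model, cfg)
    return {
        "model": model,
        "expression": expr,
        "proteome": prot,
        "cases": cases,
        "controls": controls,
        "gene_sets": collection,
    }


def write_all(artifacts: dict, outdir) -> None:
    """Write every generated artifact in the declared plain-text formats."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    model: GeneModel = artifacts["model"]
    expr: ExpressionMatrix = artifacts["expression"]
    prot: ProteinMatrix = artifacts["proteome"]
    io.write_annotation(model.exons, out / "annotation.tsv")
    io.write_matrix(expr.values, out / "expression.tsv", index_label="exon_id")
    io.write_meta(expr.sample_meta, out / "sample_meta.tsv")
    io.write_matrix(prot.values, out / "proteome.tsv", index_label="gene_id")
    io.write_meta(prot.tissue_meta, out / "tissue_meta.tsv")
    io.write_cnv_table(artifacts["cases"], out / "cases.tsv")
    io.write_cnv_table(artifacts["controls"], out / "controls.tsv")
    artifacts["gene_sets"].to_gmt(out / "gene_sets.gmt")
    truth = {
        "planted_genes": list(model.planted_genes),
        "module_labels": {g: l for g, l in prot.module_labels.items()},
        "chrom_length": model.chrom_length,
    }
    io.write_json(truth, out / "ground_truth.json")
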