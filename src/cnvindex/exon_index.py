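"""Critical-exon classification and gene-level critical-exon fractions.

A *critical exon* couples two genome-wide percentile gates: a low burden of
rare (<5% allele frequency) missense/LOF variants (below the genome's 75th
burden percentile) and high expression in a brain sample (above the sample's
75th expression percentile).  Genes are then scored by the fraction of their
annotated exons that are critical, and a gene is called a *top critical gene*
for a developmental period when that fraction reaches the genome's top
quartile in at least half of the period's brain samples.

Percentile conventions (all configurable but deliberately strict):

* burden percentile rank of exon ``e`` = 100 * (# exons with strictly smaller
  burden) / (N - 1); the burden gate is strict ``rank < cut``;
* the expression gate compares against the within-sample nearest-rank
  percentile RPKM with strict ``>``, so ties at the threshold fail;
* the gene-level top-quartile gate is inclusive ``>=`` and the sample
  majority is inclusive at exactly half.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .synthetic import ExpressionMatrix

logger = logging.getLogger(__name__)

#: consequence strings counted as deleterious (missense + canonical LOF)
DELETERIOUS_CONSEQUENCES = frozenset(
    {"missense", "stop_gained", "frameshift", "splice_donor", "splice_acceptor"}
)
#: recognised but non-deleterious consequences (silently ignored)
BENIGN_CONSEQUENCES = frozenset({"synonymous", "intronic", "utr", "intergenic"})


@dataclasses.dataclass(frozen=True)
class CriticalExonConfig:
    af_max: float = 0.05
    burden_percentile_cut: float = 75.0
    expr_percentile_cut: float = 75.0
    gene_top_quantile: float = 0.75
    sample_majority: float = 0.5
    length_normalized: bool = False  # burden per bp instead of raw counts

    def __post_init__(self) -> None:
        for name in ("burden_percentile_cut", "expr_percentile_cut"):
            v = getattr(self, name)
            if not 0.0 < v < 100.0:
                raise ValueError(f"{name} must be in (0, 100), got {v}")
        if not 0.0 < self.gene_top_quantile < 1.0:
            raise ValueError("gene_top_quantile must be in (0, 1)")
        if not 0.0 < self.sample_majority <= 1.0:
            raise ValueError("sample_majority must be in (0, 1]")
        if not 0.0 < self.af_max <= 1.0:
            raise ValueError("af_max must be in (0, 1]")


@dataclasses.dataclass(frozen=True)
class CriticalCallMatrix:
    """Boolean exon x sample call matrix plus the config that produced it."""

    values: pd.DataFrame
    config: CriticalExonConfig


@dataclasses.dataclass(frozen=True)
class GeneFractionMatrix:
    """Gene x sample critical-exon fractions and per-gene exon totals."""

    values: pd.DataFrame
    exon_counts: pd.Series


def nearest_rank(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank (inverse empirical CDF) percentile of a 1-D array."""
    v = np.sort(np.asarray(values))
    n = len(v)
    if n == 0:
        raise ValueError("empty array")
    idx = max(int(math.ceil(percentile / 100.0 * n)) - 1, 0)
    return float(v[idx])


def count_rare_deleterious(variants: pd.DataFrame, annot: pd.DataFrame,
                           af_max: float = 0.05) -> pd.DataFrame:
    """Recompute per-exon burden from a rare-variant table.

    A variant contributes to an exon's burden when its allele frequency is
    strictly below ``af_max``, its consequence is deleterious (missense or
    LOF), and its 1-based position falls inside the exon's 0-based half-open
    interval.  Unknown consequence strings are skipped with a logged warning.
    Genes that no variant of any kind touches are flagged ``gene_excluded``
    (they carry no evidence either way and are removed before ranking).
    """
    out = annot.copy()
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in annot.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), i) for i, (s, e) in zip(sub.index, zip(sub["start"], sub["end"]))
        )
    burden = np.zeros(len(annot), dtype=np.int64)
    touched = np.zeros(len(annot), dtype=bool)
    row_pos = {idx: i for i, idx in enumerate(annot.index)}
    n_unknown = 0
    for rec in variants.itertuples(index=False):
        pos = rec.pos
        if pd.isna(pos) or int(pos) < 1:
            raise ValueError(f"malformed 1-based position: {pos!r}")
        cons = rec.consequence
        known = cons in DELETERIOUS_CONSEQUENCES or cons in BENIGN_CONSEQUENCES
        if not known:
            n_unknown += 1
            continue
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        p0 = int(pos) - 1  # 0-based coordinate of the variant base
        for iv in tree.at(p0):
            touched[row_pos[iv.data]] = True
            if cons in DELETERIOUS_CONSEQUENCES and rec.allele_freq < af_max:
                burden[row_pos[iv.data]] += 1
    if n_unknown:
        logger.warning("skipped %d variants with unknown consequence strings", n_unknown)
    out["burden_count"] = burden
    gene_touched = pd.Series(touched, index=annot.index).groupby(annot["gene_id"]).any()
    out["gene_excluded"] = (~annot["gene_id"].map(gene_touched)).to_numpy()
    return out


def burden_percentiles(annot: pd.DataFrame, length_normalized: bool = False) -> pd.Series:
    """Genome-wide burden percentile rank per exon.

    rank(e) = 100 * #{exons with strictly smaller burden} / (N - 1), so ties
    share a rank and an all-equal genome ranks everything 0.  Callers must
    first remove genes flagged excluded (no variant calls).
    """
    if len(annot) < 2:
        raise ValueError("need at least 2 exons to rank")
    burden = annot["burden_count"].to_numpy(dtype=float)
    if length_normalized:
        burden = burden / (annot["end"] - annot["start"]).to_numpy(dtype=float)
    order = np.sort(burden)
    below = np.searchsorted(order, burden, side="left")
    ranks = 100.0 * below / (len(burden) - 1)
    return pd.Series(ranks, index=annot["exon_id"].to_numpy(), name="burden_rank")


def classify_critical(expr: ExpressionMatrix, ranks: pd.Series,
                      cfg: CriticalExonConfig | None = None) -> CriticalCallMatrix:
    """Call critical exons per brain sample.

    Exon ``e`` is critical in sample ``s`` iff its burden rank is strictly
    below ``burden_percentile_cut`` and its RPKM strictly exceeds the
    within-sample nearest-rank ``expr_percentile_cut`` percentile taken over
    all exons.  An all-zero sample column has threshold 0 and the strict
    inequality then calls nothing; this is accepted and logged.
    """
    cfg = cfg or CriticalExonConfig()
    vals = expr.values
    missing = vals.index.difference(ranks.index)
    if len(missing):
        raise ValueError(f"burden ranks missing for {len(missing)} expression rows")
    burden_ok = (ranks.reindex(vals.index).to_numpy() < cfg.burden_percentile_cut)
    arr = vals.to_numpy(dtype=float)
    thresholds = np.empty(arr.shape[1])
    for j in range(arr.shape[1]):
        thresholds[j] = nearest_rank(arr[:, j], cfg.expr_percentile_cut)
        if thresholds[j] == 0.0 and not np.any(arr[:, j] > 0):
            logger.warning("sample %s is all zero; no critical exons called",
                           vals.columns[j])
    calls = burden_ok[:, None] & (arr > thresholds[None, :])
    out = pd.DataFrame(calls, index=vals.index, columns=vals.columns)
    return CriticalCallMatrix(values=out, config=cfg)


def gene_fraction(calls: CriticalCallMatrix, annot: pd.DataFrame) -> GeneFractionMatrix:
    """Per-gene, per-sample fraction of critical exons over *all* annotated exons.

    The denominator is the gene's full exon count from the annotation;
    annotated exons absent from the expression matrix count as non-critical,
    reading "over all exons" as the annotation universe.
    """
    exon_counts = annot.groupby("gene_id")["exon_id"].count()
    if (exon_counts == 0).any():
        raise ValueError("gene with zero exons in annotation")
    gene_of = annot.set_index("exon_id")["gene_id"]
    unmapped = calls.values.index.difference(gene_of.index)
    if len(unmapped):
        raise ValueError(f"{len(unmapped)} call rows have no gene in the annotation")
    crit = calls.values.groupby(gene_of.reindex(calls.values.index)).sum()
    crit = crit.reindex(exon_counts.index, fill_value=0)
    fractions = crit.div(exon_counts, axis=0)
    fractions.index.name = "gene_id"
    return GeneFractionMatrix(values=fractions, exon_counts=exon_counts)


def top_critical_genes(fractions: GeneFractionMatrix, sample_meta: pd.DataFrame,
                       period: str, cfg: CriticalExonConfig | None = None) -> set[str]:
    """Genes in the genome's top quartile of critical-exon fraction for the period.

    A gene qualifies when, in at least ``ceil(sample_majority * n_samples)``
    samples of the period, its fraction is >= the within-sample nearest-rank
    ``100 * gene_top_quantile`` percentile over all genes ("at least 50% of
    the brain samples" is read inclusively).
    """
    cfg = cfg or CriticalExonConfig()
    if period not in set(sample_meta["period"]):
        raise ValueError(f"unknown period {period!r}")
    samples = sample_meta.loc[sample_meta["period"] == period, "sample_id"]
    samples = [s for s in samples if s in fractions.values.columns]
    if not samples:
        raise ValueError(f"no samples of period {period!r} in the fraction matrix")
    sub = fractions.values[samples].to_numpy(dtype=float)
    passes = np.zeros(sub.shape, dtype=bool)
    for j in range(sub.shape[1]):
        thr = nearest_rank(sub[:, j], 100.0 * cfg.gene_top_quantile)
        passes[:, j] = sub[:, j] >= thr
    need = math.ceil(cfg.sample_majority * len(samples))
    keep = passes.sum(axis=1) >= need
    return set(fractions.values.index[keep])


def region_summary(fractions: GeneFractionMatrix, sample_meta: pd.DataFrame,
                   genes: set[str] | None = None) -> pd.DataFrame:
    """Mean critical-exon fraction per (region, period) over a gene set.

    For each region x period cell: average over genes of the per-gene mean
    fraction across that cell's samples.  Output is sorted by region label.
    """
    if genes is None:
        genes = set(fractions.values.index)
    if not genes:
        raise ValueError("empty gene set")
    sub = fractions.values.loc[sorted(genes)]
    rows = []
    for (region, period), grp in sample_meta.groupby(["region", "period"]):
        cols = [s for s in grp["sample_id"] if s in sub.columns]
        if not cols:
            continue
        per_gene = sub[cols].mean(axis=1)
        rows.append((region, period, float(per_gene.mean())))
    out = pd.DataFrame(rows, columns=["region", "period", "mean_fraction"])
    return out.sort_values(["region", "period"], kind="stable").reset_index(drop=True)
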