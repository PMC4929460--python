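"""CNV cohort handling: size filtering, exonic gene hits, case-exclusive sets.

Calls are BED-convention intervals (0-based half-open) labelled with variant
type (del/dup), clinical class (pathogenic/VOUS for cases, control for
controls), inheritance and carrier sex.  The analysis window is 30 kb - 5 Mb
inclusive, a gene counts as *exonically hit* when a call overlaps at least
one base of at least one of its exons, and the case-exclusive gene set for a
(class, type) stratum removes every gene hit by any control call.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io import read_cnv_table, write_cnv_table  # noqa: F401  (module surface)

HIT_COLUMNS = ["sample_id", "gene_id", "type", "class", "inheritance", "call_idx"]
CASE_STRATA = [("pathogenic", "del"), ("pathogenic", "dup"), ("vous", "del"), ("vous", "dup")]


@dataclasses.dataclass(frozen=True)
class CnvFilterConfig:
    """Inclusive CNV length window, default 30 kb to 5 Mb."""

    min_len: int = 30_000
    max_len: int = 5_000_000

    def __post_init__(self) -> None:
        if not 0 < self.min_len <= self.max_len:
            raise ValueError("need 0 < min_len <= max_len")


def filter_by_size(calls: pd.DataFrame, cfg: CnvFilterConfig | None = None) -> pd.DataFrame:
    """Keep calls whose length satisfies min_len <= end - start <= max_len."""
    cfg = cfg or CnvFilterConfig()
    length = calls["end"] - calls["start"]
    return calls.loc[(length >= cfg.min_len) & (length <= cfg.max_len)].copy()


def exonic_gene_hits(calls: pd.DataFrame, annot: pd.DataFrame) -> pd.DataFrame:
    """One record per (call, gene) where the call overlaps >=1 bp of an exon.

    Overlap is the half-open test ``call.start < exon.end and
    call.end > exon.start``; a call entirely within an intron hits nothing.
    ``call_idx`` (the input row label) identifies the variant so downstream
    recurrence counts can distinguish calls.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in annot.groupby("chrom"):
        # exons of one gene may tile; one entry per (interval, gene) suffices
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), g) for s, e, g in zip(sub["start"], sub["end"], sub["gene_id"])
        )
    rows = []
    for idx, rec in calls.iterrows():
        tree = trees.get(rec["chrom"])
        if tree is None:
            continue
        genes = {iv.data for iv in tree.overlap(int(rec["start"]), int(rec["end"]))}
        for g in sorted(genes):
            rows.append((rec["sample_id"], g, rec["type"], rec["class"],
                         rec["inheritance"], idx))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def case_exclusive_sets(case_hits: pd.DataFrame, control_hits: pd.DataFrame,
                        per_type_controls: bool = False) -> dict[tuple[str, str], set[str]]:
    """Case gene sets per (class, type) stratum, minus control-hit genes.

    By default control deletions and duplications are pooled into one
    exclusion universe ("not found in unaffected controls" does not stratify
    by type); ``per_type_controls=True`` excludes only control hits of the
    same variant type.
    """
    out: dict[tuple[str, str], set[str]] = {}
    for cls, typ in CASE_STRATA:
        mask = (case_hits["class"] == cls) & (case_hits["type"] == typ)
        genes = set(case_hits.loc[mask, "gene_id"])
        if per_type_controls:
            excl = set(control_hits.loc[control_hits["type"] == typ, "gene_id"])
        else:
            excl = set(control_hits["gene_id"])
        out[(cls, typ)] = genes - excl
    return out


def cohort_summary(calls: pd.DataFrame, hits: pd.DataFrame | None = None) -> dict:
    """Descriptive statistics for a case cohort.

    Per (class, type) stratum: number of calls, carrier percentage (distinct
    samples with >=1 such call over all samples in the table), de novo call
    count, and mean genes per call when a hit table is supplied.  Also
    reports the class breakdown of de novo calls and, for pathogenic
    deletions, the sex-stratified carrier 2x2 with a one-sided Fisher exact
    p (alternative: higher carrier rate in females).
    """
    samples = calls["sample_id"].unique()
    n_samples = len(samples)
    if n_samples == 0:
        raise ValueError("zero samples in cohort")
    strata = {}
    for (cls, typ), sub in calls.groupby(["class", "type"]):
        entry = {
            "n_calls": int(len(sub)),
            "carrier_pct": 100.0 * sub["sample_id"].nunique() / n_samples,
            "n_de_novo": int((sub["inheritance"] == "de_novo").sum()),
        }
        if hits is not None:
            h = hits[(hits["class"] == cls) & (hits["type"] == typ)]
            per_call = h.groupby("call_idx")["gene_id"].nunique()
            per_call = per_call.reindex(sub.index, fill_value=0)
            entry["mean_genes_per_variant"] = float(per_call.mean()) if len(sub) else math.nan
        strata[f"{cls}_{typ}"] = entry

    dn = calls[calls["inheritance"] == "de_novo"]
    n_dn = len(dn)
    de_novo = {"n_total": int(n_dn)}
    for cls in ("pathogenic", "vous"):
        n_cls = int((dn["class"] == cls).sum())
        de_novo[f"n_{cls}"] = n_cls
        de_novo[f"pct_{cls}"] = round(100.0 * n_cls / n_dn) if n_dn else math.nan

    sex_test = None
    sex_of = calls.drop_duplicates("sample_id").set_index("sample_id")["sex"]
    if set(sex_of) & {"M", "F"}:
        pdel = calls[(calls["class"] == "pathogenic") & (calls["type"] == "del")]
        carriers = set(pdel["sample_id"])
        n_f = int((sex_of == "F").sum())
        n_m = int((sex_of == "M").sum())
        car_f = sum(1 for s in carriers if sex_of.get(s) == "F")
        car_m = sum(1 for s in carriers if sex_of.get(s) == "M")
        if n_f and n_m:
            sex_test = sex_difference_test(car_f, n_f, car_m, n_m)
    return {"n_samples": int(n_samples), "strata": strata,
            "de_novo": de_novo, "sex_pathogenic_del": sex_test}


def sex_difference_test(carriers_f: int, n_f: int, carriers_m: int, n_m: int) -> dict:
    """One-sided FET for a higher pathogenic-deletion carrier rate in females."""
    table = np.array([[carriers_f, n_f - carriers_f],
                      [carriers_m, n_m - carriers_m]])
    if (table < 0).any():
        raise ValueError("carrier counts exceed sample counts")
    res = stats.fisher_exact(table, alternative="greater")
    return {
        "table": table.tolist(),
        "rate_f_pct": 100.0 * carriers_f / n_f,
        "rate_m_pct": 100.0 * carriers_m / n_m,
        "odds_ratio": float(res[0]),
        "p_one_sided": float(res[1]),
    }
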