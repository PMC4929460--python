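"""Fisher's exact tests, Bonferroni correction, and permutation nulls.

Gene-set overrepresentation is tested on a 2x2 contingency table drawn over
an explicit background universe; the caller chooses the background, with two
named presets mirroring the analysis design: ``proteome_transcriptome`` (for
critical-gene-in-module tests: genes with both protein and mRNA expression)
and ``proteome`` (for CNV-gene-in-module tests: all genes with protein
expression).  Empirical significance uses the add-one (Davison-Hinkley)
estimator p = (1 + #{perm >= obs}) / (n_perm + 1), which can never return 0.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from . import io

logger = logging.getLogger(__name__)

BACKGROUND_PRESETS = ("proteome_transcriptome", "proteome")


@dataclasses.dataclass(frozen=True)
class ContingencyTable:
    """Counts (a, b, c, d) = (query&target, query only, target only, neither)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclasses.dataclass(frozen=True)
class EnrichmentConfig:
    alpha: float = 0.05
    n_perm: int = 100_000
    seed: int = 0
    top_k_terms: int = 20

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclasses.dataclass
class EnrichmentResult:
    table: ContingencyTable
    p_value: float
    odds_ratio: float
    direction: str
    haldane: bool = False
    p_bonferroni: float | None = None
    p_empirical: float | None = None
    n_permutations: int | None = None
    n_dropped: int = 0


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT semantics)."""

    sets: dict[str, tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        for name, (_desc, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> set[str]:
        return set(self.sets[name][1])

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        return cls(sets=io.read_gmt(path))

    def to_gmt(self, path) -> None:
        io.write_gmt(self.sets, path)


def fisher_exact(table: ContingencyTable, alternative: str = "greater"):
    """Exact conditional test on a 2x2 table.

    Returns ``(p, odds_ratio)``.  The odds ratio is the sample ad/bc; when
    any cell is zero the Haldane +0.5 correction is applied to every cell
    (the caller can detect this via :func:`set_enrichment`'s flag).
    """
    if table.total == 0:
        raise ValueError("all-zero contingency table")
    alt = {"two_sided": "two-sided"}.get(alternative, alternative)
    _, p = stats.fisher_exact(table.as_array(), alternative=alt)
    odds = _odds_ratio(table)[0]
    return float(p), odds


def _odds_ratio(table: ContingencyTable) -> tuple[float, bool]:
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        return (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5)), True
    return a * d / (b * c), False


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """min(1, m*p) per p-value; m defaults to the number of tests."""
    ps = list(p_values)
    if any(not 0.0 <= p <= 1.0 for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(ps) if m is None else m
    return [min(1.0, m * p) for p in ps]


def build_table(query: set, target: set, background: set) -> tuple[ContingencyTable, int]:
    """2x2 membership table over the background; returns (table, n_dropped)."""
    if not background:
        raise ValueError("empty background")
    q = set(query) & background
    t = set(target) & background
    n_dropped = (len(set(query)) - len(q)) + (len(set(target)) - len(t))
    if n_dropped:
        logger.info("dropped %d query/target genes outside the background", n_dropped)
    a = len(q & t)
    b = len(q - t)
    c = len(t - q)
    d = len(background) - a - b - c
    return ContingencyTable(a, b, c, d), n_dropped


def set_enrichment(query: set, target: set, background: set,
                   alternative: str = "greater") -> EnrichmentResult:
    """One-sided (by default) FET for overrepresentation of target in query."""
    table, n_dropped = build_table(query, target, background)
    p, odds = fisher_exact(table, alternative=alternative)
    _, haldane = _odds_ratio(table)
    return EnrichmentResult(table=table, p_value=p, odds_ratio=odds,
                            direction=alternative, haldane=haldane,
                            n_dropped=n_dropped)


def permutation_p(query: set, target: set, background: set,
                  cfg: EnrichmentConfig | None = None) -> float:
    """Empirical p for the query/target overlap against random draws.

    The null statistic — the overlap of ``|query|`` genes drawn without
    replacement from the background with the target set — follows the
    hypergeometric law exactly, so permutations are drawn from that
    distribution directly; this is sampling-equivalent to materialising gene
    draws and independent of background ordering by construction.
    """
    cfg = cfg or EnrichmentConfig()
    if not background:
        raise ValueError("empty background")
    bg = set(background)
    q = set(query) & bg
    t = set(target) & bg
    if len(set(query)) > len(bg):
        raise ValueError("query larger than background")
    obs = len(q & t)
    rng = np.random.default_rng(cfg.seed)
    draws = rng.hypergeometric(len(t), len(bg) - len(t), len(q), size=cfg.n_perm)
    return float((1 + int((draws >= obs).sum())) / (cfg.n_perm + 1))


def term_enrichment(query: set, collection: GeneSetCollection, background: set,
                    cfg: EnrichmentConfig | None = None) -> pd.DataFrame:
    """Per-term FET with Bonferroni over all terms tested; top-k by corrected p."""
    cfg = cfg or EnrichmentConfig()
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    rows = []
    for name in collection.names():
        res = set_enrichment(query, collection.genes(name), background)
        t = res.table
        rows.append((name, t.a, t.b, t.c, t.d, res.odds_ratio, res.p_value))
    df = pd.DataFrame(rows, columns=["term", "a", "b", "c", "d", "odds_ratio", "p"])
    df["p_bonferroni"] = bonferroni(df["p"], m=len(df))
    df = df.sort_values(["p_bonferroni", "p", "term"], kind="stable").reset_index(drop=True)
    return df.head(cfg.top_k_terms)


def enrichment_with_permutation(query: set, target: set, background: set,
                                cfg: EnrichmentConfig | None = None,
                                m_tests: int = 1) -> EnrichmentResult:
    """FET + Bonferroni + permutation empirical p in one record."""
    cfg = cfg or EnrichmentConfig()
    res = set_enrichment(query, target, background)
    res.p_bonferroni = bonferroni([res.p_value], m=m_tests)[0]
    res.p_empirical = permutation_p(query, target, background, cfg)
    res.n_permutations = cfg.n_perm
    return res
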