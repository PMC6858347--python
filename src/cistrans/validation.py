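"""In-silico validation of Rank-1 driver predictions.

* enrichment of Rank-1 vs non-Rank-1 cis genes in reference driver lists
  (direction-aware one-sided Fisher tests);
* copy-number-associated gene dependencies: per-gene OLS of dependency score
  on copy number with a one-sided test for negative slope, and Fisher
  enrichment of dependent genes among Rank-1 calls;
* recurrence ranking of genes across cohorts;
* Kolmogorov-Smirnov aggregation of per-cohort enrichment p-values against
  Uniform[0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import (
    AMPLIFICATION,
    DELETION,
    DriverReference,
    ValidationError,
)
from .diffexp import bh_fdr
from .enrichment import fisher_one_sided

DIRECTION_OG = "OG"          # amplification cis genes vs oncogenes
DIRECTION_TN = "TN"          # deletion cis genes vs tumor suppressors
DIRECTION_COMBINED = "COMBINED"  # all cis genes vs union of both classes
ENRICH_DIRECTIONS = (DIRECTION_OG, DIRECTION_TN, DIRECTION_COMBINED)

MODE_RANK1 = "rank1"
MODE_TOP_DE = "top_de"
MODE_ALL_CIS = "all_cis"
RECURRENCE_MODES = (MODE_RANK1, MODE_TOP_DE, MODE_ALL_CIS)


@dataclass(frozen=True)
class DriverEnrichment:
    database: str
    direction: str
    rank1_driver: int
    rank1_other: int
    nonrank1_driver: int
    nonrank1_other: int
    p: float

    @property
    def table(self) -> list[list[int]]:
        return [[self.rank1_driver, self.rank1_other],
                [self.nonrank1_driver, self.nonrank1_other]]


def driver_enrichment(
    rank1: Iterable[str],
    cis_universe: Iterable[str],
    reference: DriverReference,
    direction: str = DIRECTION_COMBINED,
    source: str | None = None,
) -> DriverEnrichment:
    """One-sided Fisher test for over-representation of known drivers among
    Rank-1 cis genes relative to the remaining cis genes.

    ``direction`` selects the reference class (OG: oncogenes, TN: tumor
    suppressors, COMBINED: both); the caller supplies ``rank1`` and
    ``cis_universe`` already restricted to the matching alteration direction.
    ``source`` restricts to one database; None pools all sources (the "ANY"
    column of pan-cohort reports).
    """
    if direction not in ENRICH_DIRECTIONS:
        raise ValidationError(f"direction must be one of {ENRICH_DIRECTIONS}")
    classes = {
        DIRECTION_OG: ("oncogene",),
        DIRECTION_TN: ("tumor_suppressor",),
        DIRECTION_COMBINED: ("oncogene", "tumor_suppressor"),
    }[direction]
    sources = None if source is None else (source,)
    drivers = reference.genes(classes=classes, sources=sources)
    universe = set(cis_universe)
    rank1_set = set(rank1)
    if not rank1_set <= universe:
        raise ValidationError("rank1 genes must be a subset of the cis universe")
    nonrank1 = universe - rank1_set
    a = len(rank1_set & drivers)
    b = len(rank1_set - drivers)
    c = len(nonrank1 & drivers)
    d = len(nonrank1 - drivers)
    p = fisher_one_sided([[a, b], [c, d]])
    return DriverEnrichment(source or "ANY", direction, a, b, c, d, p)


def driver_enrichment_from_ranking(
    ranking: pd.DataFrame, reference: DriverReference
) -> pd.DataFrame:
    """All (database, direction) driver-enrichment tests from a ranking table.

    ``ranking`` needs columns alt_id, direction, cis_gene, is_rank1 (the
    stacked per-alteration ranking output).  A gene that is Rank-1 anywhere
    counts as Rank-1; the cis universe is every ranked cis gene.
    """
    rank1_any = set(ranking.loc[ranking["is_rank1"], "cis_gene"])
    by_dir = {
        AMPLIFICATION: set(ranking.loc[ranking["direction"] == AMPLIFICATION, "cis_gene"]),
        DELETION: set(ranking.loc[ranking["direction"] == DELETION, "cis_gene"]),
    }
    universe_all = by_dir[AMPLIFICATION] | by_dir[DELETION]
    rows = []
    for source in [None] + reference.sources:
        for direction in ENRICH_DIRECTIONS:
            if direction == DIRECTION_OG:
                universe = by_dir[AMPLIFICATION]
            elif direction == DIRECTION_TN:
                universe = by_dir[DELETION]
            else:
                universe = universe_all
            if not universe:
                continue
            res = driver_enrichment(
                rank1_any & universe, universe, reference, direction, source
            )
            rows.append({
                "database": res.database, "direction": res.direction,
                "rank1_driver": res.rank1_driver, "rank1_other": res.rank1_other,
                "nonrank1_driver": res.nonrank1_driver,
                "nonrank1_other": res.nonrank1_other, "p": res.p,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dependency screens


@dataclass(frozen=True)
class DependencyFit:
    gene: str
    alpha: float  # slope of dependency score on copy number
    se: float
    t: float
    p: float  # one-sided, alternative alpha < 0
    n: int


def dependency_regression(
    dep: Sequence[float], cn: Sequence[float], gene: str = ""
) -> DependencyFit:
    """OLS of dependency score on copy number with a lower-tail slope test.

    A negative slope means higher copy number comes with stronger essentiality
    (more negative dependency score).
    """
    dep = np.asarray(dep, dtype=float)
    cn = np.asarray(cn, dtype=float)
    ok = np.isfinite(dep) & np.isfinite(cn)
    dep, cn = dep[ok], cn[ok]
    n = dep.size
    if n < 3:
        raise ValidationError("dependency regression needs >=3 paired observations")
    if cn.min() == cn.max():
        raise ValidationError("constant copy number; slope undefined")
    x = cn - cn.mean()
    sxx = float(x @ x)
    alpha = float(x @ dep) / sxx
    resid = dep - dep.mean() - alpha * x
    sigma2 = float(resid @ resid) / (n - 2)
    se = float(np.sqrt(sigma2 / sxx))
    if se == 0.0:
        t = -np.inf if alpha < 0 else (np.inf if alpha > 0 else 0.0)
    else:
        t = alpha / se
    p = float(stats.t.cdf(t, n - 2))
    return DependencyFit(gene, alpha, se, t, p, n)


def dependency_screen(
    dep_table: pd.DataFrame, cn_table: pd.DataFrame, fdr_max: float = 0.05
) -> pd.DataFrame:
    """Per-gene dependency regressions over shared cell lines, with BH FDR.

    Both tables are gene x cell line; genes and cell lines are intersected.
    Genes with constant copy number across the shared lines are skipped with
    ``skipped=True`` and excluded from the FDR family.
    """
    genes = sorted(set(dep_table.index) & set(cn_table.index))
    lines = sorted(set(dep_table.columns) & set(cn_table.columns))
    if len(lines) < 3:
        raise ValidationError("need >=3 shared cell lines")
    rows = []
    for gene in genes:
        dep = dep_table.loc[gene, lines].to_numpy(dtype=float)
        cn = cn_table.loc[gene, lines].to_numpy(dtype=float)
        try:
            fit = dependency_regression(dep, cn, gene)
        except ValidationError:
            rows.append({"gene": gene, "alpha": np.nan, "se": np.nan,
                         "t": np.nan, "p": np.nan, "n": len(lines),
                         "skipped": True})
            continue
        rows.append({"gene": gene, "alpha": fit.alpha, "se": fit.se,
                     "t": fit.t, "p": fit.p, "n": fit.n, "skipped": False})
    table = pd.DataFrame(rows)
    table["fdr"] = np.nan
    ok = ~table["skipped"]
    if ok.any():
        table.loc[ok, "fdr"] = bh_fdr(table.loc[ok, "p"].to_numpy())
    table["dependent"] = table["fdr"] < fdr_max
    return table


def dependency_enrichment(
    rank1: Iterable[str],
    cis_universe: Iterable[str],
    dependent_genes: Iterable[str],
) -> DriverEnrichment:
    """One-sided Fisher test of dependency-gene over-representation among
    Rank-1 cis genes (rows: Rank-1 vs not; columns: dependent vs not)."""
    universe = set(cis_universe)
    rank1_set = set(rank1)
    if not rank1_set <= universe:
        raise ValidationError("rank1 genes must be a subset of the cis universe")
    dep = set(dependent_genes) & universe
    nonrank1 = universe - rank1_set
    a = len(rank1_set & dep)
    b = len(rank1_set - dep)
    c = len(nonrank1 & dep)
    d = len(nonrank1 - dep)
    return DriverEnrichment(
        "dependency", "AMP_DEPENDENCY", a, b, c, d, fisher_one_sided([[a, b], [c, d]])
    )


# ---------------------------------------------------------------------------
# cross-cohort recurrence and p-value aggregation


def recurrence_rank(per_cohort_lists: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Order genes by the number of cohorts they occur in (desc, then gene id)."""
    if not per_cohort_lists:
        raise ValidationError("need at least one cohort")
    counts: dict[str, int] = {}
    for genes in per_cohort_lists.values():
        for gene in set(genes):
            counts[gene] = counts.get(gene, 0) + 1
    table = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["gene", "n_cohorts"],
    )
    return table


def select_cohort_genes(
    cis_tables: Mapping[str, pd.DataFrame], mode: str
) -> list[str]:
    """Per-cohort gene list feeding :func:`recurrence_rank`.

    ``cis_tables`` maps alt_id -> cis differential-expression table (the
    ``DETable.table`` frame).  Modes: ``rank1`` is handled by the caller from
    rankings; ``top_de`` takes each alteration's best significant cis gene
    (smallest FDR, ties by larger |log2fc| then gene id); ``all_cis`` takes
    every significant cis gene.
    """
    if mode not in (MODE_TOP_DE, MODE_ALL_CIS):
        raise ValidationError("mode must be 'top_de' or 'all_cis' here")
    out: list[str] = []
    for table in cis_tables.values():
        sig = table[table["significant"]].copy()
        if sig.empty:
            continue
        if mode == MODE_ALL_CIS:
            out.extend(sig["gene_id"].tolist())
        else:
            sig["abs_fc"] = sig["log2fc"].abs()
            sig = sig.sort_values(
                ["fdr", "abs_fc", "gene_id"],
                ascending=[True, False, True],
                kind="mergesort",
            )
            out.append(str(sig["gene_id"].iloc[0]))
    return out


def ks_uniform(pvals: Sequence[float]) -> tuple[float, float]:
    """One-sample KS test of p-values against Uniform[0, 1]."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    stat, pval = stats.kstest(p, "uniform")
    return float(stat), float(pval)
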