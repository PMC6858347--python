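"""Gene-set enrichment of cis/trans signatures and subtype association tests.

Signature enrichment uses the hypergeometric upper tail (equivalently a
one-sided Fisher exact test) against a fixed gene universe; subtype
specificity of alterations and of pathway enrichments use one-sided Fisher
tests on 2x2 count tables.  FDR is Benjamini-Hochberg across the family of
tests stated for each function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import AlterationSet, GeneSetCollection, ValidationError
from .diffexp import bh_fdr

DEFAULT_REPORT_FDR_MAX = 0.25
DEFAULT_SUBTYPE_FDR_MAX = 0.05

MODE_UNION = "union"
MODE_SEPARATE = "separate"


@dataclass(frozen=True)
class EnrichmentResult:
    alt_id: str
    set_name: str
    overlap: int
    signature_size: int
    set_size: int
    universe_size: int
    p: float


def hypergeom_enrich(
    signature: Iterable[str],
    geneset: Iterable[str],
    universe: Iterable[str],
    alt_id: str = "",
    set_name: str = "",
) -> EnrichmentResult:
    """Upper-tail hypergeometric p for overlap of signature and gene set.

    Genes outside the universe are dropped (with a warning) before testing.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValidationError("empty gene universe")
    sig = set(signature)
    gs = set(geneset)
    outside = (sig | gs) - universe_set
    if outside:
        warnings.warn(
            f"{len(outside)} genes outside the universe dropped from enrichment",
            stacklevel=2,
        )
    sig &= universe_set
    gs &= universe_set
    k = len(sig & gs)
    M, K, N = len(universe_set), len(gs), len(sig)
    # P(overlap >= k) under sampling N genes from a universe with K marked
    p = float(stats.hypergeom.sf(k - 1, M, K, N))
    return EnrichmentResult(alt_id, set_name, k, N, K, M, min(p, 1.0))


def enrich_signatures(
    signatures: Mapping[str, tuple[Iterable[str], Iterable[str]]],
    collection: GeneSetCollection,
    universe: Iterable[str],
    mode: str = MODE_UNION,
) -> pd.DataFrame:
    """Enrich each alteration's signature in every set of a collection.

    ``signatures`` maps alt_id -> (cis significant genes, trans significant
    genes).  ``mode='union'`` tests the cis+trans union per alteration;
    ``'separate'`` tests each role on its own.  BH FDR is computed across all
    (alteration, set[, role]) rows of the collection.
    """
    if mode not in (MODE_UNION, MODE_SEPARATE):
        raise ValidationError(f"unknown mode {mode!r}")
    universe_list = list(universe)
    rows = []
    for alt_id, (cis_sig, trans_sig) in signatures.items():
        if mode == MODE_UNION:
            parts = [("union", set(cis_sig) | set(trans_sig))]
        else:
            parts = [("cis", set(cis_sig)), ("trans", set(trans_sig))]
        for role, sig in parts:
            for set_name in collection.names():
                res = hypergeom_enrich(
                    sig, collection[set_name], universe_list, alt_id, set_name
                )
                rows.append({
                    "alt_id": alt_id, "role": role, "set_name": set_name,
                    "overlap": res.overlap, "signature_size": res.signature_size,
                    "set_size": res.set_size, "universe_size": res.universe_size,
                    "p": 1.0 if res.signature_size == 0 else res.p,
                })
    table = pd.DataFrame(rows)
    if not table.empty:
        table["fdr"] = bh_fdr(table["p"].to_numpy())
    else:
        table["fdr"] = []
    return table


def fisher_one_sided(table2x2: Sequence[Sequence[int]]) -> float:
    """One-sided (greater) Fisher exact p for a 2x2 count table."""
    return float(stats.fisher_exact(np.asarray(table2x2), alternative="greater")[1])


def subtype_specific_alterations(
    alts: AlterationSet,
    labels: Mapping[str, str],
    fdr_max: float = DEFAULT_SUBTYPE_FDR_MAX,
) -> pd.DataFrame:
    """One-sided Fisher test of each alteration's over-representation per subtype.

    ``labels`` maps every sample id to a subtype label.  FDR is computed
    across all (alteration, subtype) pairs; ``specific`` marks fdr < fdr_max.
    A subtype covering all (or no) samples yields a degenerate, untestable
    table flagged with ``degenerate=True``.
    """
    unlabeled = [s for s in alts.sample_ids if s not in labels]
    if unlabeled:
        raise ValidationError(f"unlabeled samples: {unlabeled}")
    label_vec = np.array([labels[s] for s in alts.sample_ids])
    subtypes = sorted(set(label_vec))
    rows = []
    for alt in alts.usable:
        altered = alt.status.astype(bool)
        for subtype in subtypes:
            inside = label_vec == subtype
            a = int((altered & inside).sum())
            b = int((altered & ~inside).sum())
            c = int((~altered & inside).sum())
            d = int((~altered & ~inside).sum())
            degenerate = inside.all() or not inside.any()
            p = np.nan if degenerate else fisher_one_sided([[a, b], [c, d]])
            rows.append({
                "alt_id": alt.alt_id, "subtype": subtype,
                "altered_in": a, "altered_out": b,
                "unaltered_in": c, "unaltered_out": d,
                "p": p, "degenerate": degenerate,
            })
    table = pd.DataFrame(rows)
    table["fdr"] = np.nan
    ok = ~table["degenerate"]
    if ok.any():
        table.loc[ok, "fdr"] = bh_fdr(table.loc[ok, "p"].to_numpy())
    table["specific"] = table["fdr"] < fdr_max
    return table


def subtype_specific_pathways(
    enrichments: pd.DataFrame,
    subtype_assoc: pd.DataFrame,
    enrich_fdr_max: float = DEFAULT_REPORT_FDR_MAX,
    subtype_fdr_max: float = DEFAULT_SUBTYPE_FDR_MAX,
) -> pd.DataFrame:
    """Test whether a pathway's enrichments concentrate in subtype-specific
    alterations: per (pathway, subtype), a one-sided Fisher test on alteration
    counts (pathway-enriched x subtype-specific)."""
    alt_ids = sorted(set(enrichments["alt_id"]) & set(subtype_assoc["alt_id"]))
    enriched_by_set = {
        set_name: set(sub.loc[sub["fdr"] < enrich_fdr_max, "alt_id"])
        for set_name, sub in enrichments.groupby("set_name")
    }
    specific_by_subtype = {
        subtype: set(sub.loc[sub["fdr"] < subtype_fdr_max, "alt_id"])
        for subtype, sub in subtype_assoc.groupby("subtype")
    }
    rows = []
    for set_name in sorted(enriched_by_set):
        enriched = enriched_by_set[set_name] & set(alt_ids)
        for subtype in sorted(specific_by_subtype):
            specific = specific_by_subtype[subtype] & set(alt_ids)
            a = len(enriched & specific)
            b = len(enriched - specific)
            c = len(specific - enriched)
            d = len(set(alt_ids) - enriched - specific)
            rows.append({
                "set_name": set_name, "subtype": subtype,
                "enriched_specific": a, "enriched_other": b,
                "not_enriched_specific": c, "not_enriched_other": d,
                "p": fisher_one_sided([[a, b], [c, d]]),
            })
    table = pd.DataFrame(rows)
    if not table.empty:
        table["fdr"] = bh_fdr(table["p"].to_numpy())
    else:
        table["fdr"] = []
    return table
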