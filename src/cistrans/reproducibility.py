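"""Bootstrap stability of Rank-1 driver calls and WFTM-entropy diagnostics.

Samples are resampled with replacement (same size as the original cohort),
the differential-expression and mediation stages are rerun on each resample,
and each originally predicted Rank-1 gene receives an inclusion fraction:
the share of resamples in which it is again Rank-1 for the same alteration.
Resamples in which an alteration's status becomes constant are skipped for
that alteration and its denominator reduced.

The spread of mediation across an alteration's cis genes is summarized by
the Shannon entropy of its WFTM vector: a single dominant mediator gives
entropy near zero, k near-tied mediators give entropy near log2(k).
Inclusion fractions are regressed on WFTM and on entropy to quantify the
expected trends (positive and negative slope, respectively).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import AlterationSet, ExpressionMatrix, ValidationError
from .pipeline import RunConfig, StudyResult, analyze_study

DEFAULT_B = 100


def wftm_entropy(wftm: np.ndarray | list[float]) -> float:
    """Shannon entropy (base 2) of a WFTM vector, normalized to a distribution.

    Zero entries contribute nothing (0*log 0 = 0); an all-zero vector is
    undefined.
    """
    w = np.asarray(wftm, dtype=float)
    if (w < 0).any():
        raise ValidationError("WFTM values must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValidationError("entropy undefined for an all-zero WFTM vector")
    p = w[w > 0] / total
    return float(-(p * np.log2(p)).sum())


def regress_reproducibility(
    scores: np.ndarray | list[float], covariate: np.ndarray | list[float]
) -> tuple[float, float]:
    """OLS slope of inclusion scores on a covariate with a two-sided t test."""
    y = np.asarray(scores, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.size != x.size:
        raise ValidationError("scores and covariate must have equal length")
    if y.size < 3:
        raise ValidationError("regression needs at least 3 points")
    if x.min() == x.max():
        raise ValidationError("constant covariate; slope undefined")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.pvalue)


@dataclass(frozen=True)
class BootstrapReport:
    B: int
    inclusion: pd.DataFrame   # alt_id, gene, wftm, entropy, inclusion_fraction, n_effective
    new_rank1: pd.DataFrame   # genes Rank-1 only in resamples: alt_id, gene, n_resamples
    slope_wftm: float
    p_wftm: float
    slope_entropy: float
    p_entropy: float


def _alteration_entropies(result: StudyResult) -> dict[str, float]:
    out = {}
    for alt_id, res in result.per_alteration.items():
        if res.mediation is None or res.mediation.ranking is None:
            continue
        wftm = res.mediation.ranking.table["wftm"].to_numpy()
        out[alt_id] = wftm_entropy(wftm) if wftm.sum() > 0 else 0.0
    return out


def bootstrap_rank1(
    expr: ExpressionMatrix,
    alts: AlterationSet,
    config: RunConfig | None = None,
    B: int = DEFAULT_B,
    seed: int = 0,
    original: StudyResult | None = None,
) -> BootstrapReport:
    """Inclusion fractions of the original Rank-1 genes over ``B`` resamples."""
    if B < 1:
        raise ValidationError("B must be >= 1")
    config = config or RunConfig()
    if original is None:
        original = analyze_study(expr, alts, config)
    rank1 = original.rank1_genes()
    if not rank1:
        raise ValidationError("original run produced no Rank-1 genes")
    entropies = _alteration_entropies(original)

    n = len(expr.sample_ids)
    rng = np.random.default_rng(seed)
    hits = {alt_id: 0 for alt_id in rank1}
    effective = {alt_id: 0 for alt_id in rank1}
    novel: dict[tuple[str, str], int] = {}
    sample_ids = list(expr.sample_ids)
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        # positional subsetting keeps duplicated samples distinct
        expr_b = ExpressionMatrix(
            expr.data.iloc[:, idx].set_axis([f"R{j}" for j in range(n)], axis=1)
        )
        alt_b = AlterationSet(
            tuple(a.subset_samples(idx) for a in alts.alterations),
            tuple(f"R{j}" for j in range(n)),
        )
        result_b = analyze_study(expr_b, alt_b, config)
        rank1_b = result_b.rank1_genes()
        for alt_id, gene in rank1.items():
            alt_res = alt_b.get(alt_id)
            if not alt_res.testable:
                continue  # too few samples in a group this resample: reduce denominator
            effective[alt_id] += 1
            gene_b = rank1_b.get(alt_id)
            if gene_b == gene:
                hits[alt_id] += 1
            elif gene_b is not None:
                novel[(alt_id, gene_b)] = novel.get((alt_id, gene_b), 0) + 1

    rows = []
    for alt_id, gene in rank1.items():
        res = original.per_alteration[alt_id]
        wftm = res.mediation.ranking.wftm(gene)
        denom = effective[alt_id]
        rows.append({
            "alt_id": alt_id, "gene": gene, "wftm": wftm,
            "entropy": entropies.get(alt_id, np.nan),
            "inclusion_fraction": hits[alt_id] / denom if denom else np.nan,
            "n_effective": denom,
        })
    inclusion = pd.DataFrame(rows).sort_values("alt_id", kind="mergesort")
    new_rank1 = pd.DataFrame(
        [{"alt_id": a, "gene": g, "n_resamples": c} for (a, g), c in sorted(novel.items())],
        columns=["alt_id", "gene", "n_resamples"],
    )

    def _safe_regress(covariate: str) -> tuple[float, float]:
        sub = inclusion.dropna(subset=["inclusion_fraction", covariate])
        try:
            return regress_reproducibility(
                sub["inclusion_fraction"].to_numpy(), sub[covariate].to_numpy()
            )
        except ValidationError:
            return float("nan"), float("nan")

    slope_w, p_w = _safe_regress("wftm")
    slope_h, p_h = _safe_regress("entropy")
    return BootstrapReport(B, inclusion.reset_index(drop=True), new_rank1,
                           slope_w, p_w, slope_h, p_h)
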