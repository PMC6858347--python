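"""Two-group differential expression of genes against an alteration's status.

Each gene is tested with a pooled-variance two-sample t-test on log2
expression.  Optionally the gene-wise variances are shrunk toward a common
prior before forming the t-statistics (empirical-Bayes moderation: the sample
variances are modelled as scaled F-deviates around a prior variance s0^2 with
prior degrees of freedom d0, both estimated by moment matching on
log-variances; the posterior variance (d0*s0^2 + d*s^2)/(d0 + d) replaces the
sample variance and the residual degrees of freedom increase by d0).

Cis genes are assessed one-sided in the direction expected from the
alteration (up for amplifications, down for deletions); trans genes
two-sided.  Benjamini-Hochberg FDR is computed within one (alteration, role)
family before threshold filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .data_io import (
    AMPLIFICATION,
    Alteration,
    ExpressionMatrix,
    ValidationError,
)

ROLE_CIS = "cis"
ROLE_TRANS = "trans"

UP = "up"
DOWN = "down"


@dataclass(frozen=True)
class DEThresholds:
    """Natural-scale fold-change floor and FDR ceiling for calling significance."""

    fc_min: float
    fdr_max: float


#: defaults for cis genes (lenient: small within-peak dosage effects)
CIS_THRESHOLDS = DEThresholds(fc_min=1.2, fdr_max=0.25)
#: defaults for trans genes (strict: large downstream signatures)
TRANS_THRESHOLDS = DEThresholds(fc_min=1.5, fdr_max=0.01)


def expected_direction(direction: str) -> str:
    """Expected cis expression change: amplification -> up, deletion -> down."""
    return UP if direction == AMPLIFICATION else DOWN


# ---------------------------------------------------------------------------
# core statistics


def _group_masks(status: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    status = np.asarray(status)
    g1 = status == 1
    g0 = status == 0
    if g1.sum() < 2 or g0.sum() < 2:
        raise ValidationError(
            f"both groups need >=2 samples (got {int(g1.sum())} altered, "
            f"{int(g0.sum())} unaltered)"
        )
    return g0, g1


def two_group_test(
    values: Sequence[float], status: Sequence[int]
) -> tuple[float, float, float, float]:
    """Pooled-variance two-sample t-test for a single gene.

    Returns ``(log2fc, t, p_two, df)`` where log2fc is the altered-minus-
    unaltered mean difference of the log2 values.
    """
    values = np.asarray(values, dtype=float)
    status = np.asarray(status)
    if values.shape != status.shape:
        raise ValidationError("values and status must have the same length")
    table = _test_matrix(values[None, :], status)
    row = table.iloc[0]
    return float(row.log2fc), float(row.t), float(row.p_two), float(row.df)


def _test_matrix(
    matrix: np.ndarray, status: np.ndarray, moderation: bool = False
) -> pd.DataFrame:
    """Vectorized pooled (optionally moderated) t-tests for all rows of ``matrix``."""
    g0, g1 = _group_masks(status)
    n0, n1 = int(g0.sum()), int(g1.sum())
    df_resid = n0 + n1 - 2
    m0 = matrix[:, g0].mean(axis=1)
    m1 = matrix[:, g1].mean(axis=1)
    diff = m1 - m0
    ss0 = ((matrix[:, g0] - m0[:, None]) ** 2).sum(axis=1)
    ss1 = ((matrix[:, g1] - m1[:, None]) ** 2).sum(axis=1)
    s2 = (ss0 + ss1) / df_resid
    inv_n = 1.0 / n0 + 1.0 / n1

    if moderation:
        d0, s0 = fit_variance_prior(s2, df_resid)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0)
            df_total = np.inf
        else:
            s2_post = (d0 * s0 + df_resid * s2) / (d0 + df_resid)
            df_total = df_resid + d0
    else:
        s2_post = s2
        df_total = float(df_resid)

    degenerate = s2_post <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(s2_post * inv_n)
    t_degen = np.where(diff == 0, 0.0, np.where(diff > 0, np.inf, -np.inf))
    t = np.where(degenerate, t_degen, t)
    if np.isinf(df_total):
        p_two = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p_two = 2.0 * stats.t.sf(np.abs(t), df_total)
    p_two = np.where(degenerate & (diff == 0), 1.0, p_two)
    return pd.DataFrame(
        {
            "log2fc": diff,
            "t": t,
            "p_two": p_two,
            "df": np.inf if np.isinf(df_total) else float(df_total),
            "degenerate": degenerate,
        }
    )


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching fit of (d0, s0^2) for the scaled-F variance model.

    Works on z = log(s^2): Var(z) in excess of trigamma(df/2) identifies d0
    through the trigamma function; the mean identifies s0^2.  Returns
    ``(inf, s0^2)`` when the observed variances are no more dispersed than
    sampling alone explains.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return y


def one_sided_p(
    t_stat: float | np.ndarray, df: float, direction: str
) -> float | np.ndarray:
    """One-sided tail probability in the expected direction (up/down)."""
    if direction not in (UP, DOWN):
        raise ValidationError(f"direction must be {UP!r} or {DOWN!r}")
    t_stat = np.asarray(t_stat, dtype=float)
    dist = stats.norm if np.isinf(df) else stats.t(df)
    p = dist.sf(t_stat) if direction == UP else dist.cdf(t_stat)
    return p if p.ndim else float(p)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# per-alteration driver


@dataclass(frozen=True)
class DETable:
    """Differential-expression statistics of one (alteration, role) family."""

    alt_id: str
    role: str
    table: pd.DataFrame  # gene_id, log2fc, fold_change, t, df, p_two, p_one, p, fdr, significant
    thresholds: DEThresholds

    @property
    def significant_genes(self) -> list[str]:
        return self.table.loc[self.table["significant"], "gene_id"].tolist()


def run_de(
    expr: ExpressionMatrix,
    alteration: Alteration,
    genes: Sequence[str],
    role: str,
    thresholds: DEThresholds | None = None,
    moderation: bool = True,
) -> DETable:
    """Test every gene of a role against the alteration status.

    FDR is computed over all tested genes of this (alteration, role) family;
    the significant set is ``fold_change > fc_min`` and ``fdr < fdr_max``,
    using the one-sided p for cis genes and the two-sided p for trans genes.
    """
    if role not in (ROLE_CIS, ROLE_TRANS):
        raise ValidationError(f"role must be {ROLE_CIS!r} or {ROLE_TRANS!r}")
    if thresholds is None:
        thresholds = CIS_THRESHOLDS if role == ROLE_CIS else TRANS_THRESHOLDS
    columns = [
        "gene_id", "log2fc", "fold_change", "t", "df",
        "p_two", "p_one", "p", "fdr", "significant",
    ]
    if len(genes) == 0:
        warnings.warn(f"{alteration.alt_id}/{role}: no genes to test", stacklevel=2)
        return DETable(alteration.alt_id, role, pd.DataFrame(columns=columns), thresholds)
    matrix = expr.gene_matrix(genes)
    stats_df = _test_matrix(matrix, alteration.status, moderation=moderation)
    stats_df.insert(0, "gene_id", list(genes))
    stats_df["fold_change"] = 2.0 ** np.abs(stats_df["log2fc"])
    df_val = stats_df["df"].iloc[0]
    stats_df["p_one"] = one_sided_p(
        stats_df["t"].to_numpy(), df_val, expected_direction(alteration.direction)
    )
    stats_df["p"] = stats_df["p_one"] if role == ROLE_CIS else stats_df["p_two"]
    stats_df["fdr"] = bh_fdr(stats_df["p"].to_numpy())
    stats_df["significant"] = (
        (stats_df["fold_change"] > thresholds.fc_min)
        & (stats_df["fdr"] < thresholds.fdr_max)
    )
    return DETable(alteration.alt_id, role, stats_df[columns + ["degenerate"]], thresholds)
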