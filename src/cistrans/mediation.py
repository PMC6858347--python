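"""Sobel mediation testing and mediation-based ranking of cis genes.

For every (alteration, cis gene, trans gene) triplet three OLS fits are made:

* ``trans ~ 1 + status``          -> total effect tau
* ``trans ~ 1 + status + cis``    -> direct effect tau' and cis coefficient b
* ``cis  ~ 1 + status``           -> a

The mediated (indirect) effect is ``delta_tau = tau - tau'``, which for nested
OLS equals ``a*b`` exactly.  Its first-order standard error is
``sqrt(b^2 SE(a)^2 + a^2 SE(b)^2)`` and ``t = delta_tau/SE`` is referred to a
standard normal.

Each significant trans gene is then assigned to at most one mediating cis
gene (smallest triplet FDR; ties broken by larger |delta_tau|, then by gene
id), the mediation weight is ``w = delta_tau/tau`` clipped into [0, 1], and
a cis gene's score is the weighted fraction of trans mediation

    WFTM_i = sum_j w_ij I_ij / m

with m the number of significant trans genes of the alteration.  The cis gene
with maximal WFTM is the Rank-1 candidate driver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import Alteration, ExpressionMatrix, ValidationError
from .diffexp import bh_fdr

#: a trans gene counts as mediated only below this triplet-FDR cutoff
DEFAULT_ASSIGN_FDR_MAX = 0.25

#: relative tolerance for declaring the cis vector collinear with status
_COLLINEAR_RTOL = 1e-12

TRIPLET_COLUMNS = [
    "alt_id", "cis_gene", "trans_gene", "tau", "tau_prime", "delta_tau",
    "a_hat", "b_hat", "se", "t", "p", "fdr", "weight", "degenerate",
]


@dataclass(frozen=True)
class SobelResult:
    """Core statistics of one mediation triplet."""

    tau: float
    tau_prime: float
    delta_tau: float
    a_hat: float
    b_hat: float
    se: float
    t: float
    p: float
    degenerate: bool = False


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """OLS fit returning (coefficients, standard errors, residual SS)."""
    n, k = X.shape
    gram_inv = np.linalg.pinv(X.T @ X)
    beta = gram_inv @ (X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - k
    sigma2 = rss / df if df > 0 else 0.0
    se = np.sqrt(np.clip(np.diag(gram_inv) * sigma2, 0.0, None))
    return beta, se, rss


def sobel_triplet(
    status: Sequence[int], cis: Sequence[float], trans: Sequence[float]
) -> SobelResult:
    """Sobel test of mediation of the status->trans effect by the cis gene."""
    s = np.asarray(status, dtype=float)
    c = np.asarray(cis, dtype=float)
    z = np.asarray(trans, dtype=float)
    n = s.size
    if c.size != n or z.size != n:
        raise ValidationError("status, cis and trans must have equal length")
    if n < 4:
        raise ValidationError("mediation needs at least 4 samples")
    if s.min() == s.max():
        raise ValidationError("status is constant; mediation undefined")

    ones = np.ones(n)
    X1 = np.column_stack([ones, s])
    beta_z, _, _ = _ols(X1, z)
    tau = float(beta_z[1])

    beta_c, se_c, rss_c = _ols(X1, c)
    a_hat, se_a = float(beta_c[1]), float(se_c[1])
    if rss_c <= _COLLINEAR_RTOL * max(float(c @ c), 1.0):
        # cis perfectly determined by status: the full model is unidentifiable
        return SobelResult(tau, np.nan, np.nan, a_hat, np.nan, np.nan,
                           np.nan, np.nan, degenerate=True)

    X2 = np.column_stack([ones, s, c])
    beta_f, se_f, _ = _ols(X2, z)
    tau_prime, b_hat, se_b = float(beta_f[1]), float(beta_f[2]), float(se_f[2])

    delta_tau = tau - tau_prime
    se = float(np.sqrt(b_hat**2 * se_a**2 + a_hat**2 * se_b**2))
    if se == 0.0:
        t = 0.0 if delta_tau == 0.0 else float(np.sign(delta_tau) * np.inf)
    else:
        t = delta_tau / se
    p = 1.0 if (se == 0.0 and delta_tau == 0.0) else float(2.0 * stats.norm.sf(abs(t)))
    return SobelResult(tau, tau_prime, delta_tau, a_hat, b_hat, se, t, p)


def mediation_weight(
    delta_tau: float | np.ndarray, tau: float | np.ndarray
) -> float | np.ndarray:
    """Fraction of the total effect mediated, clipped into [0, 1]; NaN at tau=0.

    The ratio is signed relative to the total effect (delta_tau/tau), so full
    mediation gives 1 for amplifications and deletions alike, while indirect
    effects opposing the total effect clip to 0.
    """
    delta = np.asarray(delta_tau, dtype=float)
    tau_arr = np.asarray(tau, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.clip(delta / tau_arr, 0.0, 1.0)
    w = np.where(tau_arr == 0, np.nan, w)
    return w if w.ndim else float(w)


# ---------------------------------------------------------------------------
# batch testing over all (cis, trans) pairs of one alteration


def mediation_table(
    expr: ExpressionMatrix,
    alteration: Alteration,
    cis_genes: Sequence[str],
    trans_genes: Sequence[str],
) -> pd.DataFrame:
    """All |cis| x |trans| Sobel triplets of one alteration, with BH FDR.

    Vectorized over trans genes for each cis gene; identical to calling
    :func:`sobel_triplet` per triplet.
    """
    s = alteration.status.astype(float)
    n = s.size
    if n < 4:
        raise ValidationError("mediation needs at least 4 samples")
    if not alteration.usable:
        raise ValidationError(f"{alteration.alt_id}: status is constant")

    T = expr.gene_matrix(trans_genes)  # (m, n)
    ones = np.ones(n)
    X1 = np.column_stack([ones, s])
    G1 = np.linalg.pinv(X1.T @ X1)
    H1 = G1 @ X1.T
    B1 = H1 @ T.T  # (2, m)
    tau = B1[1]

    frames = []
    for cis_gene in cis_genes:
        c = expr.gene_matrix([cis_gene])[0]
        beta_c = H1 @ c
        resid_c = c - X1 @ beta_c
        rss_c = float(resid_c @ resid_c)
        sigma2_c = rss_c / (n - 2)
        a_hat = float(beta_c[1])
        se_a = float(np.sqrt(sigma2_c * G1[1, 1]))
        if rss_c <= _COLLINEAR_RTOL * max(float(c @ c), 1.0):
            frames.append(pd.DataFrame({
                "cis_gene": cis_gene, "trans_gene": list(trans_genes),
                "tau": tau, "tau_prime": np.nan, "delta_tau": np.nan,
                "a_hat": a_hat, "b_hat": np.nan, "se": np.nan,
                "t": np.nan, "p": np.nan, "degenerate": True,
            }))
            continue
        X2 = np.column_stack([ones, s, c])
        G2 = np.linalg.pinv(X2.T @ X2)
        H2 = G2 @ X2.T
        B2 = H2 @ T.T  # (3, m)
        tau_prime = B2[1]
        b_hat = B2[2]
        R = T.T - X2 @ B2
        sigma2 = (R * R).sum(axis=0) / (n - 3)
        se_b = np.sqrt(np.clip(sigma2 * G2[2, 2], 0.0, None))
        delta = tau - tau_prime
        se = np.sqrt(b_hat**2 * se_a**2 + a_hat**2 * se_b**2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = delta / se
        t = np.where(se == 0, np.where(delta == 0, 0.0, np.sign(delta) * np.inf), t)
        p = 2.0 * stats.norm.sf(np.abs(t))
        p = np.where((se == 0) & (delta == 0), 1.0, p)
        frames.append(pd.DataFrame({
            "cis_gene": cis_gene, "trans_gene": list(trans_genes),
            "tau": tau, "tau_prime": tau_prime, "delta_tau": delta,
            "a_hat": a_hat, "b_hat": b_hat, "se": se,
            "t": t, "p": p, "degenerate": False,
        }))
    table = pd.concat(frames, ignore_index=True)
    table.insert(0, "alt_id", alteration.alt_id)
    ok = ~table["degenerate"]
    table["fdr"] = np.nan
    table.loc[ok, "fdr"] = bh_fdr(table.loc[ok, "p"].to_numpy())
    table["weight"] = mediation_weight(
        table["delta_tau"].to_numpy(), table["tau"].to_numpy()
    )
    return table[TRIPLET_COLUMNS]


@dataclass(frozen=True)
class MediatorAssignment:
    """Per trans gene, the single best mediating cis gene (if any)."""

    alt_id: str
    table: pd.DataFrame  # trans_gene, cis_gene, fdr, delta_tau, weight, assigned

    @property
    def assigned(self) -> pd.DataFrame:
        return self.table[self.table["assigned"]]


def assign_mediators(
    triplets: pd.DataFrame, assign_fdr_max: float = DEFAULT_ASSIGN_FDR_MAX
) -> MediatorAssignment:
    """Pick each trans gene's best mediator: minimal FDR, ties by larger
    |delta_tau| then lexicographic cis gene; unassigned when the best FDR is
    not below ``assign_fdr_max``."""
    usable = triplets[~triplets["degenerate"] & triplets["fdr"].notna()].copy()
    alt_ids = triplets["alt_id"].unique()
    if len(alt_ids) != 1:
        raise ValidationError("assign_mediators expects triplets of one alteration")
    usable["abs_delta"] = usable["delta_tau"].abs()
    usable = usable.sort_values(
        ["trans_gene", "fdr", "abs_delta", "cis_gene"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    best = usable.groupby("trans_gene", sort=True).head(1).copy()
    best["assigned"] = best["fdr"] < assign_fdr_max
    out = best[["trans_gene", "cis_gene", "fdr", "delta_tau", "weight", "assigned"]]
    return MediatorAssignment(str(alt_ids[0]), out.reset_index(drop=True))


@dataclass(frozen=True)
class CisRanking:
    """WFTM scores and the Rank-1 call for one alteration."""

    alt_id: str
    table: pd.DataFrame  # cis_gene, wftm, n_trans_mediated, rank, is_rank1
    m: int  # number of significant trans genes (WFTM denominator)

    @property
    def rank1_gene(self) -> str:
        return str(self.table.loc[self.table["is_rank1"], "cis_gene"].iloc[0])

    def wftm(self, cis_gene: str) -> float:
        row = self.table[self.table["cis_gene"] == cis_gene]
        if row.empty:
            raise KeyError(cis_gene)
        return float(row["wftm"].iloc[0])


def compute_wftm(
    assignment: MediatorAssignment,
    cis_genes: Iterable[str],
    m: int,
    alt_id: str | None = None,
) -> CisRanking:
    """WFTM per cis gene and deterministic ranking (Rank-1 = max WFTM)."""
    if m < 1:
        raise ValidationError("WFTM denominator m must be >= 1")
    alt_id = assignment.alt_id if alt_id is None else alt_id
    assigned = assignment.assigned
    sums = assigned.groupby("cis_gene")["weight"].sum()
    counts = assigned.groupby("cis_gene")["weight"].size()
    rows = []
    for gene in cis_genes:
        rows.append({
            "cis_gene": gene,
            "wftm": float(sums.get(gene, 0.0)) / m,
            "n_trans_mediated": int(counts.get(gene, 0)),
        })
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["wftm", "n_trans_mediated", "cis_gene"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table["is_rank1"] = table["rank"] == 1
    table.insert(0, "alt_id", alt_id)
    return CisRanking(alt_id, table, m)


@dataclass(frozen=True)
class MediationOutput:
    alt_id: str
    triplets: pd.DataFrame
    assignment: MediatorAssignment | None
    ranking: CisRanking | None


def run_mediation(
    expr: ExpressionMatrix,
    alteration: Alteration,
    cis_sig: Sequence[str],
    trans_sig: Sequence[str],
    assign_fdr_max: float = DEFAULT_ASSIGN_FDR_MAX,
    trans_restrict: Iterable[str] | None = None,
) -> MediationOutput:
    """Full mediation analysis of one alteration.

    ``trans_restrict`` (e.g. one pathway's genes) limits both the tested trans
    genes and the WFTM denominator m to the restriction set.
    """
    trans_used = list(trans_sig)
    if trans_restrict is not None:
        restrict = set(trans_restrict)
        trans_used = [g for g in trans_used if g in restrict]
    if len(cis_sig) == 0 or len(trans_used) == 0:
        warnings.warn(
            f"{alteration.alt_id}: no significant cis or trans genes; "
            "no mediation ranking",
            stacklevel=2,
        )
        return MediationOutput(
            alteration.alt_id, pd.DataFrame(columns=TRIPLET_COLUMNS), None, None
        )
    triplets = mediation_table(expr, alteration, cis_sig, trans_used)
    assignment = assign_mediators(triplets, assign_fdr_max)
    ranking = compute_wftm(assignment, cis_sig, m=len(trans_used))
    return MediationOutput(alteration.alt_id, triplets, assignment, ranking)
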