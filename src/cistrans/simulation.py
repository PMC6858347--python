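"""Forward simulation: Sobel-test benchmarking and full synthetic studies.

Two generative systems benchmark the mediation test.  True positives follow
the causal chain

    Y = a1 + b1*X + N(0, s1^2),   Z = a2 + b2*Y + N(0, s2^2)

(X binary alteration status, Y the mediating cis gene, Z the trans gene);
true negatives share the common cause X but break the chain:

    Y = a1 + b1*X + N(0, s1^2),   Z = a2 + b2*X + N(0, s2^2)

so Y and Z are conditionally independent given X.  Both regression
coefficients default to 0.7.  Performance over replicate sets is summarized
as Mann-Whitney AUC of the p-values, sensitivity (positives called at
p < p_cut) and specificity (negatives not called).

``generate_synthetic_study`` builds a complete small study — expression
matrix, alterations with cis membership, gene sets and a driver reference —
with planted mediation structure recorded as ground truth, for end-to-end
testing of the whole pipeline.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import (
    AMPLIFICATION,
    DELETION,
    Alteration,
    AlterationSet,
    DriverReference,
    ExpressionMatrix,
    GeneSetCollection,
    ValidationError,
    write_alterations,
    write_driver_reference,
    write_expression,
    write_gmt,
)
from .mediation import sobel_triplet


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two generative systems."""

    n: int = 500
    sigma1: float = 0.5
    sigma2: float = 0.5
    beta1: float = 0.7
    beta2: float = 0.7
    alpha1: float = 0.0
    alpha2: float = 0.0
    reps_pos: int = 1000
    reps_neg: int = 1000
    p_cut: float = 0.05
    altered_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValidationError("n must be >= 4")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValidationError("noise standard deviations must be positive")
        if self.reps_pos < 1 or self.reps_neg < 1:
            raise ValidationError("replicate counts must be >= 1")
        if not 0 < self.altered_fraction < 1:
            raise ValidationError("altered_fraction must lie in (0, 1)")


def _status_vector(n: int, fraction: float) -> np.ndarray:
    n1 = max(1, min(n - 1, int(round(n * fraction))))
    return np.concatenate([np.zeros(n - n1), np.ones(n1)])


def simulate_positive(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One true-mediation replicate (X -> Y -> Z chain)."""
    x = _status_vector(config.n, config.altered_fraction)
    y = config.alpha1 + config.beta1 * x + rng.normal(0.0, config.sigma1, config.n)
    z = config.alpha2 + config.beta2 * y + rng.normal(0.0, config.sigma2, config.n)
    return x, y, z


def simulate_negative(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One no-mediation replicate (common cause only; Y and Z independent | X)."""
    x = _status_vector(config.n, config.altered_fraction)
    y = config.alpha1 + config.beta1 * x + rng.normal(0.0, config.sigma1, config.n)
    z = config.alpha2 + config.beta2 * x + rng.normal(0.0, config.sigma2, config.n)
    return x, y, z


def sigma_to_correlation(
    sigma1: float, beta1: float = 0.7, altered_fraction: float = 0.5
) -> float:
    """Population Pearson correlation between X and Y implied by the noise level.

    For binary X with Var(X) = f(1-f):  r = b1*sd(X)/sqrt(b1^2 Var(X) + s1^2).
    """
    if sigma1 <= 0:
        raise ValidationError("sigma1 must be positive")
    var_x = altered_fraction * (1.0 - altered_fraction)
    return float(beta1 * np.sqrt(var_x) / np.sqrt(beta1**2 * var_x + sigma1**2))


def correlation_to_sigma(
    r: float, beta1: float = 0.7, altered_fraction: float = 0.5
) -> float:
    """Inverse of :func:`sigma_to_correlation` (0 < r < 1)."""
    if not 0 < r < 1:
        raise ValidationError("r must lie in (0, 1)")
    var_x = altered_fraction * (1.0 - altered_fraction)
    return float(beta1 * np.sqrt(var_x) * np.sqrt(1.0 / r**2 - 1.0))


@dataclass(frozen=True)
class PerfMetrics:
    auc: float
    sensitivity: float
    specificity: float
    corr_xy: float  # mean empirical corr(X, Y) over positive replicates
    n_degenerate: int = 0


def _pvalue_auc(p_pos: np.ndarray, p_neg: np.ndarray) -> float:
    """Mann-Whitney probability that a positive's p is below a negative's
    (ties credited 1/2)."""
    combined = np.concatenate([p_pos, p_neg])
    ranks = stats.rankdata(combined)
    rank_sum_neg = ranks[p_pos.size:].sum()
    n_pos, n_neg = p_pos.size, p_neg.size
    return float((rank_sum_neg - n_neg * (n_neg + 1) / 2.0) / (n_pos * n_neg))


def evaluate_sobel(config: SimulationConfig) -> PerfMetrics:
    """Run the Sobel test over both replicate sets and summarize performance."""
    rng = np.random.default_rng(config.seed)
    p_pos, p_neg, corrs = [], [], []
    n_degenerate = 0
    for _ in range(config.reps_pos):
        x, y, z = simulate_positive(config, rng)
        res = sobel_triplet(x, y, z)
        if res.degenerate:
            n_degenerate += 1
            continue
        p_pos.append(res.p)
        corrs.append(np.corrcoef(x, y)[0, 1])
    for _ in range(config.reps_neg):
        x, y, z = simulate_negative(config, rng)
        res = sobel_triplet(x, y, z)
        if res.degenerate:
            n_degenerate += 1
            continue
        p_neg.append(res.p)
    p_pos_arr = np.asarray(p_pos)
    p_neg_arr = np.asarray(p_neg)
    return PerfMetrics(
        auc=_pvalue_auc(p_pos_arr, p_neg_arr),
        sensitivity=float((p_pos_arr < config.p_cut).mean()),
        specificity=float((p_neg_arr >= config.p_cut).mean()),
        corr_xy=float(np.mean(corrs)),
        n_degenerate=n_degenerate,
    )


def simulate_grid(
    n_values: Sequence[int],
    sigma_values: Sequence[float],
    reps: int = 1000,
    beta: float = 0.7,
    p_cut: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Performance table over an (n, sigma) grid, common seed per grid point."""
    rows = []
    for n in n_values:
        for sigma in sigma_values:
            cfg = SimulationConfig(
                n=n, sigma1=sigma, sigma2=sigma, beta1=beta, beta2=beta,
                reps_pos=reps, reps_neg=reps, p_cut=p_cut, seed=seed,
            )
            perf = evaluate_sobel(cfg)
            rows.append({
                "n": n, "sigma": sigma,
                "corr_xy": sigma_to_correlation(sigma, beta),
                "auc": perf.auc, "sensitivity": perf.sensitivity,
                "specificity": perf.specificity,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full synthetic studies


@dataclass(frozen=True)
class StudySpec:
    """Shape and effect sizes of a planted synthetic study.

    Per alteration one (or ``n_drivers``) cis genes truly drive a fraction of
    the significant trans genes through the expression chain; the remaining
    cis genes are decoys that track alteration status but carry no downstream
    signal.  Effects are in log2 expression units.
    """

    n_samples: int = 300
    n_alterations: int = 2
    n_cis: int = 5
    n_drivers: int = 1
    n_trans: int = 20
    n_background: int = 200
    mediated_fraction: float = 0.8
    cis_effect: float = 1.0
    cis_noise_sd: float = 0.5
    trans_beta: float = 0.7
    trans_noise_sd: float = 0.5
    direct_effect: float = 1.0
    altered_fraction: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_alterations < 1:
            raise ValidationError("need at least one alteration")
        if self.n_cis < 2:
            raise ValidationError("need at least 2 cis genes per alteration")
        if self.n_trans < 5:
            raise ValidationError("need at least 5 trans genes per alteration")
        if self.n_drivers < 0 or self.n_drivers > self.n_cis:
            raise ValidationError("n_drivers must lie in [0, n_cis]")
        if not 0 <= self.mediated_fraction <= 1:
            raise ValidationError("mediated_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticStudy:
    expr: ExpressionMatrix
    alterations: AlterationSet
    genesets: GeneSetCollection
    drivers: DriverReference
    truth: dict
    spec: StudySpec
    seed: int


_CYTOBANDS = ["1q21", "8q24", "11q13", "17q12", "3p21", "9p21", "10q23", "13q14"]


def generate_synthetic_study(spec: StudySpec | None = None, seed: int = 0) -> SyntheticStudy:
    """Build a complete study with planted mediation structure.

    Alterations alternate amplification/deletion.  For each alteration the
    driver cis genes follow status with effect ``cis_effect`` (sign from the
    direction) and mediate ``mediated_fraction`` of the trans genes through
    ``Z = trans_beta * Y + noise``; the remaining significant trans genes
    respond to status directly; decoy cis genes respond to status with the
    same effect but independent noise.  Background genes are pure noise.
    """
    spec = spec or StudySpec()
    rng = np.random.default_rng(seed)
    n = spec.n_samples
    samples = [f"S{i:04d}" for i in range(n)]

    gene_rows: dict[str, np.ndarray] = {}
    alterations: list[Alteration] = []
    truth: dict = {"alterations": {}}
    geneset_dict: dict[str, frozenset[str]] = {}
    driver_rows: list[dict] = []

    for a in range(spec.n_alterations):
        direction = AMPLIFICATION if a % 2 == 0 else DELETION
        band = _CYTOBANDS[a % len(_CYTOBANDS)]
        alt_id = f"{'amp' if direction == AMPLIFICATION else 'del'}_{band}_{a}"
        status = np.zeros(n, dtype=np.int8)
        n1 = int(round(n * spec.altered_fraction))
        status[rng.choice(n, size=n1, replace=False)] = 1
        sign = 1.0 if direction == AMPLIFICATION else -1.0

        cis_names = [f"{alt_id.upper()}_CIS{j}" for j in range(spec.n_cis)]
        driver_names = cis_names[: spec.n_drivers]
        cis_exprs = {}
        for name in cis_names:
            base = rng.normal(spec.baseline_mean, spec.baseline_sd)
            cis_exprs[name] = (
                base + sign * spec.cis_effect * status
                + rng.normal(0.0, spec.cis_noise_sd, n)
            )
        gene_rows.update(cis_exprs)

        trans_names = [f"{alt_id.upper()}_TRA{j:02d}" for j in range(spec.n_trans)]
        n_mediated = int(round(spec.mediated_fraction * spec.n_trans))
        mediated = trans_names[:n_mediated] if driver_names else []
        direct = trans_names[len(mediated):]
        mediated_by: dict[str, str] = {}
        for j, name in enumerate(mediated):
            drv = driver_names[j % len(driver_names)]
            mediated_by[name] = drv
            base = rng.normal(spec.baseline_mean, spec.baseline_sd)
            centered = cis_exprs[drv] - cis_exprs[drv].mean()
            gene_rows[name] = (
                base + spec.trans_beta * centered
                + rng.normal(0.0, spec.trans_noise_sd, n)
            )
        for name in direct:
            base = rng.normal(spec.baseline_mean, spec.baseline_sd)
            direct_sign = sign * rng.choice([1.0, -1.0])
            gene_rows[name] = (
                base + direct_sign * spec.direct_effect * status
                + rng.normal(0.0, spec.trans_noise_sd, n)
            )

        alterations.append(
            Alteration(alt_id, direction, status, frozenset(cis_names))
        )
        truth["alterations"][alt_id] = {
            "direction": direction,
            "drivers": driver_names,
            "decoys": cis_names[spec.n_drivers:],
            "mediated_trans": mediated,
            "mediated_by": mediated_by,
            "direct_trans": direct,
        }
        if trans_names:
            geneset_dict[f"{alt_id.upper()}_TARGETS"] = frozenset(trans_names)
        for drv in driver_names:
            driver_rows.append({
                "gene": drv,
                "class": "oncogene" if direction == AMPLIFICATION else "tumor_suppressor",
                "source": "synthetic_db",
            })

    for b in range(spec.n_background):
        name = f"BG{b:04d}"
        base = rng.normal(spec.baseline_mean, spec.baseline_sd)
        gene_rows[name] = base + rng.normal(0.0, spec.cis_noise_sd, n)

    # a couple of decoy reference drivers outside any alteration
    background_names = [f"BG{b:04d}" for b in range(min(2, spec.n_background))]
    for name in background_names:
        driver_rows.append({"gene": name, "class": "oncogene", "source": "synthetic_db"})
    if spec.n_background >= 5:
        geneset_dict["RANDOM_BACKGROUND"] = frozenset(
            f"BG{b:04d}" for b in range(min(20, spec.n_background))
        )

    expr = ExpressionMatrix(
        pd.DataFrame(gene_rows, index=samples).T.loc[sorted(gene_rows)]
    )
    alt_set = AlterationSet(tuple(alterations), tuple(samples))
    genesets = GeneSetCollection(geneset_dict, source_name="synthetic_sets")
    drivers = DriverReference(pd.DataFrame(driver_rows).drop_duplicates())
    return SyntheticStudy(expr, alt_set, genesets, drivers, truth, spec, seed)


def write_study(study: SyntheticStudy, out_dir: str | Path) -> None:
    """Write the full study file set (expression, lesions with continuous
    amplitudes, cis map, GMT, driver TSV, truth and spec JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(study.expr, out / "expression.tsv")

    # emit continuous amplitudes consistent with the binarized status so the
    # lesions file exercises the amplitude-threshold reading path
    rng = np.random.default_rng(study.seed + 1_000_003)
    rows = []
    for alt in study.alterations:
        sign = 1.0 if alt.direction == AMPLIFICATION else -1.0
        amp_altered = sign * rng.uniform(0.3, 1.5, alt.status.size)
        amp_normal = rng.uniform(-0.09, 0.09, alt.status.size)
        amps = np.where(alt.status == 1, amp_altered, amp_normal)
        rec = {"alt_id": alt.alt_id, "direction": alt.direction}
        rec.update({s: round(float(v), 4) for s, v in zip(study.alterations.sample_ids, amps)})
        rows.append(rec)
    pd.DataFrame(rows).to_csv(out / "lesions.tsv", sep="\t", index=False)

    pairs = [
        {"alt_id": alt.alt_id, "gene_id": g}
        for alt in study.alterations
        for g in sorted(alt.cis_genes)
    ]
    pd.DataFrame(pairs).to_csv(out / "cis_map.tsv", sep="\t", index=False)
    write_gmt(study.genesets, out / "genesets.gmt")
    write_driver_reference(study.drivers, out / "drivers.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump({"seed": study.seed, "spec": asdict(study.spec),
                   "truth": study.truth}, fh, indent=2, sort_keys=True)
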