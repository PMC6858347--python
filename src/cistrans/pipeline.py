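"""Top-level pipeline: configuration, per-alteration analysis, report writing.

The pipeline chains data_io -> diffexp -> mediation -> enrichment ->
validation.  All randomness flows from the single ``seed`` in the run
configuration, every output is a TSV/JSON/YAML text file with stable column
and row order, and a rerun with the same configuration and seed is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import sys
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .data_io import (
    AlterationSet,
    ExpressionMatrix,
    ValidationError,
    match_samples,
    partition_cis_trans,
    read_alterations,
    read_driver_reference,
    read_expression,
    read_gmt,
)
from .diffexp import (
    DEThresholds,
    DETable,
    ROLE_CIS,
    ROLE_TRANS,
    run_de,
)
from .enrichment import (
    enrich_signatures,
    subtype_specific_alterations,
    subtype_specific_pathways,
)
from .mediation import MediationOutput, run_mediation
from .validation import driver_enrichment_from_ranking

_FLOAT_FORMAT = "%.10g"


@dataclass
class RunConfig:
    """All pipeline thresholds, paths and the root seed."""

    expression: str | None = None
    lesions: str | None = None
    cis_map: str | None = None
    gene_sets: str | None = None
    drivers: str | None = None
    subtypes: str | None = None
    out_dir: str = "cistrans_out"
    binarize_threshold: float = 0.1
    cis_fc_min: float = 1.2
    cis_fdr_max: float = 0.25
    trans_fc_min: float = 1.5
    trans_fdr_max: float = 0.01
    moderation: bool = True
    assign_fdr_max: float = 0.25
    trans_restrict: str | None = None  # gene-set name within gene_sets
    enrichment_fdr_max: float = 0.25
    subtype_fdr_max: float = 0.05
    run_enrichment: bool = True
    run_validation: bool = True
    seed: int = 0

    @property
    def cis_thresholds(self) -> DEThresholds:
        return DEThresholds(self.cis_fc_min, self.cis_fdr_max)

    @property
    def trans_thresholds(self) -> DEThresholds:
        return DEThresholds(self.trans_fc_min, self.trans_fdr_max)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValidationError(f"unknown configuration keys: {unknown}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass(frozen=True)
class AlterationResult:
    alt_id: str
    direction: str
    cis: DETable
    trans: DETable
    mediation: MediationOutput | None


@dataclass(frozen=True)
class StudyResult:
    per_alteration: Mapping[str, AlterationResult]
    skipped: tuple[str, ...] = field(default_factory=tuple)

    def rank1_table(self) -> pd.DataFrame:
        """Stacked per-alteration ranking (alt_id, direction, cis_gene, wftm,
        n_trans_mediated, rank, is_rank1)."""
        frames = []
        for res in self.per_alteration.values():
            if res.mediation is None or res.mediation.ranking is None:
                continue
            table = res.mediation.ranking.table.copy()
            table.insert(1, "direction", res.direction)
            frames.append(table)
        if not frames:
            return pd.DataFrame(
                columns=["alt_id", "direction", "cis_gene", "wftm",
                         "n_trans_mediated", "rank", "is_rank1"]
            )
        return pd.concat(frames, ignore_index=True)

    def rank1_genes(self) -> dict[str, str]:
        """alt_id -> Rank-1 cis gene, for alterations with a ranking."""
        out = {}
        for alt_id, res in self.per_alteration.items():
            if res.mediation is not None and res.mediation.ranking is not None:
                out[alt_id] = res.mediation.ranking.rank1_gene
        return out

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for alt_id, res in self.per_alteration.items():
            ranking = res.mediation.ranking if res.mediation else None
            rows.append({
                "alt_id": alt_id,
                "direction": res.direction,
                "n_cis_tested": len(res.cis.table),
                "n_cis_significant": len(res.cis.significant_genes),
                "n_trans_tested": len(res.trans.table),
                "n_trans_significant": len(res.trans.significant_genes),
                "rank1_gene": ranking.rank1_gene if ranking is not None else "",
                "rank1_wftm": (
                    ranking.wftm(ranking.rank1_gene) if ranking is not None else float("nan")
                ),
            })
        return pd.DataFrame(rows)


def analyze_study(
    expr: ExpressionMatrix,
    alts: AlterationSet,
    config: RunConfig | None = None,
    trans_restrict: set[str] | None = None,
) -> StudyResult:
    """Differential expression plus mediation for every usable alteration."""
    config = config or RunConfig()
    universe = expr.gene_ids
    per_alteration: dict[str, AlterationResult] = {}
    skipped = []
    for alt in alts:
        if not alt.testable:
            skipped.append(alt.alt_id)
            continue
        cis_genes, trans_genes = partition_cis_trans(alt, universe)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cis = run_de(expr, alt, cis_genes, ROLE_CIS,
                         config.cis_thresholds, config.moderation)
            trans = run_de(expr, alt, trans_genes, ROLE_TRANS,
                           config.trans_thresholds, config.moderation)
            mediation = run_mediation(
                expr, alt,
                cis.significant_genes, trans.significant_genes,
                assign_fdr_max=config.assign_fdr_max,
                trans_restrict=trans_restrict,
            )
        per_alteration[alt.alt_id] = AlterationResult(
            alt.alt_id, alt.direction, cis, trans, mediation
        )
    return StudyResult(per_alteration, tuple(skipped))


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages and write all outputs to ``out_dir``.

    Returns the output directory.  Stage wall-clock timings go to stderr;
    the run log written to disk is deterministic.
    """
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"cistrans {__version__}", f"seed: {config.seed}"]

    def stage(msg: str) -> None:
        log_lines.append(msg)
        print(f"[{time.perf_counter() - t0:7.2f}s] {msg}", file=sys.stderr)

    if not (config.expression and config.lesions and config.cis_map):
        raise ValidationError("expression, lesions and cis_map paths are required")
    stage("stage data_io: reading inputs")
    expr = read_expression(config.expression)
    alts = read_alterations(config.lesions, config.cis_map, config.binarize_threshold)
    expr, alts = match_samples(expr, alts)
    log_lines.append(
        f"harmonized: {expr.shape[0]} genes x {expr.shape[1]} samples, "
        f"{len(alts)} alterations ({len(alts.usable)} usable)"
    )
    unusable = [a.alt_id for a in alts if not a.usable]
    if unusable:
        log_lines.append(f"alterations with constant status (excluded): {unusable}")

    collection = read_gmt(config.gene_sets) if config.gene_sets else None
    restrict = None
    if config.trans_restrict:
        if collection is None:
            raise ValidationError("trans_restrict requires gene_sets")
        restrict = set(collection[config.trans_restrict])

    stage("stage diffexp+mediation: per-alteration analysis")
    result = analyze_study(expr, alts, config, trans_restrict=restrict)

    cis_frames, trans_frames, triplet_frames = [], [], []
    for res in result.per_alteration.values():
        for frame_list, table in ((cis_frames, res.cis), (trans_frames, res.trans)):
            df = table.table.copy()
            df.insert(0, "alt_id", res.alt_id)
            df.insert(1, "role", table.role)
            frame_list.append(df)
        if res.mediation is not None and len(res.mediation.triplets):
            triplet_frames.append(res.mediation.triplets)
    if cis_frames:
        _write_tsv(pd.concat(cis_frames, ignore_index=True), out / "de_cis.tsv")
        _write_tsv(pd.concat(trans_frames, ignore_index=True), out / "de_trans.tsv")
    if triplet_frames:
        _write_tsv(pd.concat(triplet_frames, ignore_index=True),
                   out / "mediation_triplets.tsv")
    ranking = result.rank1_table()
    _write_tsv(ranking, out / "ranking.tsv")
    _write_tsv(ranking[ranking.get("is_rank1", pd.Series(dtype=bool))] if len(ranking)
               else ranking, out / "rank1.tsv")
    summary = result.summary_table()
    _write_tsv(summary, out / "summary.tsv")
    log_lines.append(
        "significant cis genes per alteration: "
        + ", ".join(f"{r.alt_id}={r.n_cis_significant}" for r in summary.itertuples())
    )

    if config.run_enrichment and collection is not None:
        stage("stage enrichment: hypergeometric gene-set tests")
        signatures = {
            alt_id: (res.cis.significant_genes, res.trans.significant_genes)
            for alt_id, res in result.per_alteration.items()
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            enr = enrich_signatures(signatures, collection, expr.gene_ids)
        _write_tsv(enr, out / "enrichment.tsv")
        if config.subtypes:
            labels = pd.read_csv(config.subtypes, sep="\t", dtype=str)
            label_map = dict(zip(labels.iloc[:, 0], labels.iloc[:, 1]))
            assoc = subtype_specific_alterations(alts, label_map, config.subtype_fdr_max)
            _write_tsv(assoc, out / "subtype_alterations.tsv")
            pathways = subtype_specific_pathways(
                enr, assoc, config.enrichment_fdr_max, config.subtype_fdr_max
            )
            _write_tsv(pathways, out / "subtype_pathways.tsv")

    if config.run_validation and config.drivers:
        stage("stage validation: driver-reference enrichment")
        reference = read_driver_reference(config.drivers)
        ranked_sig = ranking.merge(
            pd.concat(cis_frames, ignore_index=True)[["alt_id", "gene_id", "significant"]],
            left_on=["alt_id", "cis_gene"], right_on=["alt_id", "gene_id"], how="left",
        )
        ranked_sig = ranked_sig[ranked_sig["significant"].fillna(False)]
        if len(ranked_sig):
            enr_drivers = driver_enrichment_from_ranking(ranked_sig, reference)
            _write_tsv(enr_drivers, out / "driver_enrichment.tsv")

    config.to_yaml(out / "config.yaml")
    stage("done")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    summary_json = {
        "seed": config.seed,
        "n_alterations": len(alts),
        "n_usable_alterations": len(alts.usable),
        "rank1": result.rank1_genes(),
        "n_cis_significant": {
            r.alt_id: int(r.n_cis_significant) for r in summary.itertuples()
        },
        "n_trans_significant": {
            r.alt_id: int(r.n_trans_significant) for r in summary.itertuples()
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary_json, fh, indent=2, sort_keys=True)
    return out
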