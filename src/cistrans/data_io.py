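"""Reading, validation and harmonization of the tabular inputs.

All inputs are plain TSV (or GMT for gene sets):

* expression — genes x samples, first column ``gene_id``, log2 units;
* lesions — one row per alteration: ``alt_id``, ``direction``
  (``amplification``/``deletion``), then one amplitude column per sample.
  Amplitudes may already be 0/1, in which case they are taken as status;
* cis map — two columns ``alt_id``, ``gene_id`` listing wide-peak membership;
* driver reference — columns ``gene``, ``class``
  (``oncogene``/``tumor_suppressor``), ``source``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

AMPLIFICATION = "amplification"
DELETION = "deletion"
DIRECTIONS = (AMPLIFICATION, DELETION)

#: default amplitude cutoff for calling a sample altered
DEFAULT_AMPLITUDE_THRESHOLD = 0.1


class ValidationError(ValueError):
    """An input violates a structural invariant."""


class ParseError(ValueError):
    """A file could not be parsed into the documented schema."""


# ---------------------------------------------------------------------------
# expression


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log2 expression values, genes x samples, unique identifiers on both axes."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ValidationError(f"duplicate gene identifiers: {dups}")
        if df.columns.has_duplicates:
            dups = sorted(df.columns[df.columns.duplicated()].unique())
            raise ValidationError(f"duplicate sample identifiers: {dups}")
        if df.shape[1] < 2:
            raise ValidationError("expression matrix needs at least 2 samples")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
            raise ValidationError(f"non-numeric expression columns: {bad}")
        if not np.isfinite(values).all():
            bad_genes = df.index[~np.isfinite(values).all(axis=1)].tolist()
            raise ValidationError(f"non-finite expression values in genes: {bad_genes}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"samples absent from expression matrix: {missing}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])

    def gene_matrix(self, gene_ids: Sequence[str]) -> np.ndarray:
        """Rows for ``gene_ids`` as a (len(gene_ids), n_samples) array."""
        return self.data.loc[list(gene_ids)].to_numpy(dtype=float)


def read_expression(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ParseError(f"{path}: empty file")
    cols = header.rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    dups: set[str] = set()
    for c in cols:
        (dups if c in seen else seen).add(c)
    if dups:
        raise ParseError(f"{path}: duplicate sample identifiers {sorted(dups)}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    df.index = df.index.astype(str)
    df.columns = [str(c).strip() for c in df.columns]
    df.index = [str(g).strip() for g in df.index]
    if df.index.has_duplicates:
        dup = sorted(pd.Index(df.index)[pd.Index(df.index).duplicated()].unique())
        raise ParseError(f"{path}: duplicate gene rows: {dup}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
            raise ParseError(f"{path}: non-numeric values in column {col!r}, genes {bad[:5]}")
    if df.isna().to_numpy().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ParseError(f"{path}: missing values in genes {bad[:5]}")
    try:
        return ExpressionMatrix(df)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# alterations


def binarize_amplitude(
    t: float | np.ndarray,
    direction: str,
    threshold: float = DEFAULT_AMPLITUDE_THRESHOLD,
) -> np.ndarray | int:
    """Call altered status from a continuous amplitude.

    Amplifications are altered when the amplitude strictly exceeds ``threshold``;
    deletions when it falls strictly below ``-threshold``.  Values at the
    boundary are not altered.
    """
    if direction not in DIRECTIONS:
        raise ValidationError(f"unknown direction {direction!r}")
    if not threshold > 0:
        raise ValidationError("threshold must be positive")
    arr = np.asarray(t, dtype=float)
    if not np.isfinite(arr).all():
        raise ValidationError("non-finite amplitude")
    if direction == AMPLIFICATION:
        out = (arr > threshold).astype(np.int8)
    else:
        out = (arr < -threshold).astype(np.int8)
    return out if arr.ndim else int(out)


@dataclass(frozen=True)
class Alteration:
    """One focal alteration: direction, per-sample 0/1 status, cis-gene membership."""

    alt_id: str
    direction: str
    status: np.ndarray
    cis_genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"{self.alt_id}: unknown direction {self.direction!r}")
        status = np.asarray(self.status, dtype=np.int8)
        if not np.isin(status, (0, 1)).all():
            raise ValidationError(f"{self.alt_id}: status values must be 0/1")
        object.__setattr__(self, "status", status)
        object.__setattr__(self, "cis_genes", frozenset(self.cis_genes))

    @property
    def n_altered(self) -> int:
        return int(self.status.sum())

    @property
    def usable(self) -> bool:
        """True when both status groups are non-empty (two-group tests defined)."""
        return 0 < self.n_altered < self.status.size

    @property
    def testable(self) -> bool:
        """True when both status groups have >=2 samples (t-tests well-posed)."""
        return 2 <= self.n_altered <= self.status.size - 2

    def subset_samples(self, indices: Sequence[int]) -> "Alteration":
        return replace(self, status=self.status[np.asarray(indices, dtype=int)])


@dataclass(frozen=True)
class AlterationSet:
    alterations: tuple[Alteration, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alterations", tuple(self.alterations))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        ids = [a.alt_id for a in self.alterations]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate alteration identifiers: {dup}")
        n = len(self.sample_ids)
        for a in self.alterations:
            if a.status.size != n:
                raise ValidationError(
                    f"{a.alt_id}: status length {a.status.size} != {n} samples"
                )

    def __iter__(self):
        return iter(self.alterations)

    def __len__(self) -> int:
        return len(self.alterations)

    def get(self, alt_id: str) -> Alteration:
        for a in self.alterations:
            if a.alt_id == alt_id:
                return a
        raise KeyError(alt_id)

    @property
    def usable(self) -> tuple[Alteration, ...]:
        return tuple(a for a in self.alterations if a.usable)

    def subset_samples(self, sample_ids: Sequence[str]) -> "AlterationSet":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise ValidationError(f"samples absent from alteration set: {missing}")
        idx = [index[s] for s in sample_ids]
        return AlterationSet(
            tuple(a.subset_samples(idx) for a in self.alterations), tuple(sample_ids)
        )


def read_alterations(
    lesions_path: str | Path,
    cis_map_path: str | Path,
    threshold: float = DEFAULT_AMPLITUDE_THRESHOLD,
) -> AlterationSet:
    """Read the lesions table and cis-gene map into an :class:`AlterationSet`.

    Amplitudes are binarized with :func:`binarize_amplitude` unless every value
    in the table is already 0/1, in which case they are taken as status.
    Alterations whose status is constant are retained but flagged unusable.
    """
    lesions = pd.read_csv(lesions_path, sep="\t", dtype={"alt_id": str})
    for col in ("alt_id", "direction"):
        if col not in lesions.columns:
            raise ParseError(f"{lesions_path}: missing required column {col!r}")
    sample_cols = [c for c in lesions.columns if c not in ("alt_id", "direction")]
    if not sample_cols:
        raise ParseError(f"{lesions_path}: no sample columns")
    amplitudes = lesions[sample_cols].to_numpy(dtype=float)
    if not np.isfinite(amplitudes).all():
        raise ParseError(f"{lesions_path}: non-finite amplitudes")
    prebinarized = np.isin(amplitudes, (0.0, 1.0)).all()

    cis_map = pd.read_csv(cis_map_path, sep="\t", dtype=str)
    for col in ("alt_id", "gene_id"):
        if col not in cis_map.columns:
            raise ParseError(f"{cis_map_path}: missing required column {col!r}")
    cis_by_alt: dict[str, set[str]] = {}
    for alt_id, gene in zip(cis_map["alt_id"], cis_map["gene_id"]):
        cis_by_alt.setdefault(alt_id, set()).add(gene)

    lesion_ids = set(lesions["alt_id"])
    only_map = sorted(set(cis_by_alt) - lesion_ids)
    only_lesions = sorted(lesion_ids - set(cis_by_alt))
    if only_map or only_lesions:
        raise ValidationError(
            "alt_id mismatch between lesions and cis map; "
            f"only in cis map: {only_map}; only in lesions: {only_lesions}"
        )

    alterations = []
    for row, amps in zip(lesions.itertuples(index=False), amplitudes):
        if prebinarized:
            status = amps.astype(np.int8)
        else:
            status = binarize_amplitude(amps, row.direction, threshold)
        alterations.append(
            Alteration(row.alt_id, row.direction, status, frozenset(cis_by_alt[row.alt_id]))
        )
    alt_set = AlterationSet(tuple(alterations), tuple(sample_cols))
    unusable = [a.alt_id for a in alt_set if not a.usable]
    if unusable:
        warnings.warn(
            f"alterations with constant status excluded from testing: {unusable}",
            stacklevel=2,
        )
    return alt_set


def write_alterations(alts: AlterationSet, lesions_path: str | Path, cis_map_path: str | Path) -> None:
    rows = [
        {"alt_id": a.alt_id, "direction": a.direction,
         **dict(zip(alts.sample_ids, a.status.tolist()))}
        for a in alts
    ]
    pd.DataFrame(rows).to_csv(lesions_path, sep="\t", index=False)
    pairs = [
        {"alt_id": a.alt_id, "gene_id": g} for a in alts for g in sorted(a.cis_genes)
    ]
    pd.DataFrame(pairs, columns=["alt_id", "gene_id"]).to_csv(
        cis_map_path, sep="\t", index=False
    )


def partition_cis_trans(
    alteration: Alteration, universe: Sequence[str]
) -> tuple[list[str], list[str]]:
    """Split the expressed-gene universe into cis and trans lists (universe order).

    cis = wide-peak members present in the universe; trans = everything else.
    The two lists are disjoint and cover the universe exactly.
    """
    if len(universe) == 0:
        raise ValidationError("empty gene universe")
    cis_members = alteration.cis_genes
    cis = [g for g in universe if g in cis_members]
    trans = [g for g in universe if g not in cis_members]
    if not cis:
        warnings.warn(
            f"{alteration.alt_id}: no cis genes present in the expression universe",
            stacklevel=2,
        )
    return cis, trans


def match_samples(
    expr: ExpressionMatrix, alts: AlterationSet
) -> tuple[ExpressionMatrix, AlterationSet]:
    """Restrict both objects to their common samples, in expression-matrix order."""
    alt_samples = set(alts.sample_ids)
    common = [s for s in expr.sample_ids if s in alt_samples]
    if len(common) < 2:
        raise ValidationError(
            f"only {len(common)} samples shared between expression and alterations"
        )
    return expr.subset_samples(common), alts.subset_samples(common)


# ---------------------------------------------------------------------------
# gene sets / driver references


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets, e.g. one GMT compendium."""

    sets: Mapping[str, frozenset[str]]
    source_name: str = ""

    def __post_init__(self) -> None:
        frozen = {name: frozenset(members) for name, members in self.sets.items()}
        empty = sorted(name for name, members in frozen.items() if not members)
        if empty:
            raise ValidationError(f"empty gene sets: {empty}")
        object.__setattr__(self, "sets", frozen)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str | Path, source_name: str | None = None) -> GeneSetCollection:
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT rows need name, description, >=1 gene")
            name = parts[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = frozenset(g for g in parts[2:] if g)
            if not members:
                raise ParseError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets, source_name or Path(path).stem)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            members = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{collection.source_name}\t{members}\n")


DRIVER_CLASSES = ("oncogene", "tumor_suppressor")


@dataclass(frozen=True)
class DriverReference:
    """Reference lists of known driver genes: (gene, class, source) records."""

    entries: pd.DataFrame  # columns gene, class, source

    def __post_init__(self) -> None:
        df = self.entries
        required = {"gene", "class", "source"}
        if not required.issubset(df.columns):
            raise ValidationError(f"driver reference needs columns {sorted(required)}")
        bad = sorted(set(df["class"]) - set(DRIVER_CLASSES))
        if bad:
            raise ValidationError(f"unknown driver classes: {bad}")
        if df.duplicated(subset=["gene", "class", "source"]).any():
            raise ValidationError("duplicate (gene, class, source) driver records")
        object.__setattr__(self, "entries", df.reset_index(drop=True))

    def genes(
        self,
        classes: Iterable[str] | None = None,
        sources: Iterable[str] | None = None,
    ) -> frozenset[str]:
        df = self.entries
        if classes is not None:
            df = df[df["class"].isin(set(classes))]
        if sources is not None:
            df = df[df["source"].isin(set(sources))]
        return frozenset(df["gene"])

    @property
    def sources(self) -> list[str]:
        return sorted(self.entries["source"].unique())


def read_driver_reference(path: str | Path) -> DriverReference:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return DriverReference(df)


def write_driver_reference(ref: DriverReference, path: str | Path) -> None:
    ref.entries.to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Generic numeric matrix keyed by the first column (e.g. gene x cell line)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = sorted(df.index[df.index.duplicated()].unique())
        raise ParseError(f"{path}: duplicate row identifiers: {dup}")
    return df


# ---------------------------------------------------------------------------
# GISTIC convenience converter


def convert_gistic_lesions(path: str | Path) -> pd.DataFrame:
    """Best-effort conversion of a GISTIC "all lesions" table to the lesions schema.

    Keeps the actual-copy-change rows ("CN values"), derives the direction from
    the "Unique Name" prefix and uses the Descriptor (cytoband) plus direction
    as ``alt_id``.  Cis-gene membership is a separate GISTIC output and must be
    supplied through the two-column cis map.
    """
    raw = pd.read_csv(path, sep="\t")
    name_col = raw.columns[0]
    desc_col = next(c for c in raw.columns if c.lower().startswith("descriptor"))
    meta_prefixes = (
        "wide peak", "peak limits", "region limits", "q values",
        "residual q", "broad or focal", "amplitude threshold",
    )
    sample_cols = [
        c for c in raw.columns[2:]
        if not c.lower().startswith(meta_prefixes) and not c.startswith("Unnamed")
    ]
    rows = []
    for _, row in raw.iterrows():
        unique_name = str(row[name_col])
        if "CN values" not in unique_name:
            continue
        lowered = unique_name.lower()
        if lowered.startswith("amp"):
            direction = AMPLIFICATION
        elif lowered.startswith("del"):
            direction = DELETION
        else:
            continue
        prefix = "amp" if direction == AMPLIFICATION else "del"
        alt_id = f"{prefix}_{str(row[desc_col]).strip()}"
        rec = {"alt_id": alt_id, "direction": direction}
        rec.update({c: float(row[c]) for c in sample_cols})
        rows.append(rec)
    if not rows:
        raise ParseError(f"{path}: no amplitude ('CN values') rows found")
    return pd.DataFrame(rows)
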