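"""Core data types and TSV I/O for matched multi-omics feature tables.

The study design this package targets is two exposure groups (``high`` /
``low`` house ammonia) of matched subjects (rabbits) profiled on up to five
omic layers: nasal and colonic microbiota (relative abundances or counts at
phylum/genus/OTU level), lung and colon transcriptomes (gene counts or
expression summaries), and a muscle metabolome (positive intensities).

Tables are features-in-rows / samples-in-columns TSV with a mandatory header
row of sample ids and the feature id in the first column.  Subjects are
matched across layers by an explicit ``subject_id`` in the sample metadata,
never by column position: cross-omic correlation is only meaningful over the
same animals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

LAYERS = (
    "nasal_microbiome",
    "colonic_microbiome",
    "lung_transcriptome",
    "colon_transcriptome",
    "muscle_metabolome",
)
LEVELS = ("phylum", "genus", "otu", "ko", "pathway", "gene", "metabolite", "diversity")

#: levels holding compositional relative abundances (columns must sum to 1)
#: unless the table is integer counts awaiting normalisation
ABUNDANCE_LEVELS = frozenset({"phylum", "genus", "otu", "ko", "pathway"})

GROUPS = ("high", "low")

REL_SUM_TOL = 1e-6


class FormatError(ValueError):
    """Malformed input table (duplicate ids, non-numeric cells...)."""


class ValidationError(ValueError):
    """Well-formed table violating a domain invariant."""


class AlignmentError(ValueError):
    """Layers cannot be aligned on enough matched subjects."""


@dataclass
class FeatureTable:
    """One omic layer's features x samples numeric matrix.

    ``data`` is a pandas DataFrame indexed by feature id with sample-id
    columns.  Negative values are forbidden for abundance/count/intensity
    levels; fractional abundance-level tables must be closed compositions
    (column sums within ``REL_SUM_TOL`` of 1).
    """

    layer: str
    level: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}")
        if self.level not in LEVELS:
            raise ValidationError(f"unknown level {self.level!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValidationError("degenerate table: empty feature or sample set")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric values in table")
        if not np.isfinite(values).all():
            raise ValidationError("non-finite value in table")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative value at feature {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}"
            )
        if self.level in ABUNDANCE_LEVELS and not self.is_counts:
            sums = values.sum(axis=0)
            bad = np.abs(sums - 1.0) > REL_SUM_TOL
            if bad.any():
                j = int(np.argmax(bad))
                raise ValidationError(
                    f"relative-abundance column {self.data.columns[j]!r} "
                    f"sums to {sums[j]:.6g}, expected 1"
                )

    @property
    def feature_ids(self) -> List[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def is_counts(self) -> bool:
        v = self.data.to_numpy()
        return bool(np.allclose(v, np.round(v)) and v.max(initial=0) > 1.0 + REL_SUM_TOL)

    @property
    def is_relative(self) -> bool:
        return bool(np.all(np.abs(self.values.sum(axis=0) - 1.0) <= REL_SUM_TOL))

    def to_relative(self) -> "FeatureTable":
        """Column-normalise counts to relative abundances (closure)."""
        sums = self.values.sum(axis=0)
        if (sums <= 0).any():
            raise ValidationError("cannot normalise a column with zero total")
        return FeatureTable(self.layer, self.level, self.data / sums)

    def restrict_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise AlignmentError(f"samples absent from table: {missing}")
        return FeatureTable(self.layer, self.level, self.data.loc[:, list(sample_ids)])

    @property
    def key(self) -> Tuple[str, str]:
        return (self.layer, self.level)


@dataclass
class SampleMetadata:
    """Per-sample annotations: sample_id, subject_id, group (high/low), sex."""

    data: pd.DataFrame

    REQUIRED = ("sample_id", "subject_id", "group")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise FormatError(f"metadata missing required column {col!r}")
        if "sex" not in self.data.columns:
            self.data = self.data.assign(sex="")
        if self.data["sample_id"].duplicated().any():
            dup = self.data.loc[self.data["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample id {dup!r} in metadata")
        bad = set(self.data["group"]) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown group label(s): {sorted(bad)}")
        for g in GROUPS:
            if not (self.data["group"] == g).any():
                raise ValidationError(f"group {g!r} has no samples")

    def subject_of(self) -> Dict[str, str]:
        return dict(zip(self.data["sample_id"], self.data["subject_id"]))

    def group_of_subject(self) -> Dict[str, str]:
        return dict(zip(self.data["subject_id"], self.data["group"]))

    def samples_in_group(self, group: str) -> List[str]:
        return list(self.data.loc[self.data["group"] == group, "sample_id"])


@dataclass
class AlignedDataset:
    """Feature tables restricted to a shared ordered subject set.

    After alignment every table's columns correspond, position by position,
    to ``subject_order`` (ordered by subject id), so row vectors from any two
    layers are directly comparable across the same rabbits.
    """

    tables: Dict[Tuple[str, str], FeatureTable]
    metadata: SampleMetadata
    subject_order: List[str]
    dropped_samples: List[str] = field(default_factory=list)

    def groups(self) -> Dict[str, str]:
        """subject -> group, restricted to the aligned subjects."""
        g = self.metadata.group_of_subject()
        return {s: g[s] for s in self.subject_order}

    def subjects_in_group(self, group: str) -> List[str]:
        g = self.groups()
        if group == "both":
            return list(self.subject_order)
        return [s for s in self.subject_order if g[s] == group]

    def group_indices(self, group: str) -> np.ndarray:
        keep = set(self.subjects_in_group(group))
        return np.array([i for i, s in enumerate(self.subject_order) if s in keep])

    def table(self, layer: str, level: str) -> FeatureTable:
        return self.tables[(layer, level)]


# ---------------------------------------------------------------------------
# TSV I/O


def read_feature_table(path: str | Path, layer: str, level: str) -> FeatureTable:
    """Read a features x samples TSV (first column feature ids, header row
    sample ids) into a validated :class:`FeatureTable`, preserving order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r} in {path}"
        )
    return FeatureTable(layer=layer, level=level, data=numeric.astype(float))


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Serialise with 17 significant digits so read(write(t)) == t exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.data.to_csv(path, sep="\t", float_format="%.17g")


def read_metadata(path: str | Path) -> SampleMetadata:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return SampleMetadata(pd.read_csv(path, sep="\t", dtype=str))


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sample alignment


def align_samples(
    tables: Iterable[FeatureTable],
    metadata: SampleMetadata,
    min_per_group: int = 3,
) -> AlignedDataset:
    """Restrict all layers to the subjects common to every table.

    Columns are reordered by subject id identically in every layer; samples
    whose subject is absent from any layer are dropped and reported in
    ``dropped_samples``.  Fails if fewer than ``min_per_group`` subjects per
    exposure group survive the intersection.
    """
    tables = list(tables)
    if not tables:
        raise AlignmentError("no tables to align")
    subj_of = metadata.subject_of()
    grp_of = metadata.group_of_subject()

    per_table_subjects: List[Dict[str, str]] = []
    for t in tables:
        mapping = {}
        for s in t.sample_ids:
            if s not in subj_of:
                raise AlignmentError(f"sample {s!r} in {t.layer}:{t.level} has no metadata")
            subj = subj_of[s]
            if subj in mapping:
                raise AlignmentError(
                    f"subject {subj!r} appears twice in {t.layer}:{t.level}"
                )
            mapping[subj] = s
        per_table_subjects.append(mapping)

    common = set.intersection(*(set(m) for m in per_table_subjects))
    subject_order = sorted(common)
    for g in GROUPS:
        n = sum(1 for s in subject_order if grp_of.get(s) == g)
        if n < min_per_group:
            raise AlignmentError(
                f"only {n} matched subjects in group {g!r} (need >= {min_per_group})"
            )

    dropped = sorted(
        {m[s] for m in per_table_subjects for s in m if s not in common}
    )
    aligned: Dict[Tuple[str, str], FeatureTable] = {}
    for t, mapping in zip(tables, per_table_subjects):
        cols = [mapping[s] for s in subject_order]
        aligned[t.key] = t.restrict_samples(cols)
    return AlignedDataset(
        tables=aligned,
        metadata=metadata,
        subject_order=subject_order,
        dropped_samples=dropped,
    )
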