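"""Core data model and tabular IO.

The unit of inference throughout the package is the *paired set*: the four
samples (control, metabolic stress, humoral stress, combined stress) derived
from one animal's cells at one passage, cultured and treated together.  This
module loads gene x sample count matrices (featureCounts-style TSV) and the
sample sheet describing the design, groups samples into paired sets, and
normalizes counts to fragments per million (FPM).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("CTRL", "MET", "HUM", "ALL")
CELL_TYPES = ("WT_VSMC", "KO_VSMC", "EC")
SEXES = ("male", "female")

#: featureCounts-style annotation columns silently ignored when reading counts
ANNOTATION_COLUMNS = frozenset(
    {"Chr", "Start", "End", "Strand", "Length", "gene_name", "gene_biotype"}
)

SAMPLE_SHEET_COLUMNS = (
    "sample_id",
    "animal_id",
    "cell_type",
    "sex",
    "passage",
    "condition",
)


class FormatError(ValueError):
    """Malformed input table (duplicate ids, bad labels, negative counts...)."""


@dataclass
class CountMatrix:
    """Integer read-count matrix, genes in rows, samples in columns.

    Invariants enforced at construction: unique gene and sample ids,
    non-negative integer counts, at least one gene and one sample.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if counts.size == 0:
            raise FormatError("count matrix needs at least 1 gene and 1 sample")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids in count matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids in count matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(np.asarray(counts, dtype=float))
            if not np.allclose(counts.astype(float), rounded, rtol=0, atol=0):
                raise FormatError("counts must be integers")
            counts = rounded.astype(np.int64)
        if (counts < 0).any():
            raise FormatError("counts must be non-negative")
        self.counts = counts.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.sample_ids,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class SampleSheet:
    """Validated sample annotation: one row per sequenced/assayed sample."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        df = df.loc[:, list(SAMPLE_SHEET_COLUMNS)].copy()
        for col in ("sample_id", "animal_id", "cell_type", "sex", "condition"):
            df[col] = df[col].astype(str).str.strip()
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise FormatError(f"duplicate sample_id(s): {dupes}")
        bad = sorted(set(df["condition"]) - set(CONDITIONS))
        if bad:
            raise FormatError(
                f"unknown condition label(s) {bad}; expected one of {CONDITIONS}"
            )
        bad = sorted(set(df["cell_type"]) - set(CELL_TYPES))
        if bad:
            raise FormatError(
                f"unknown cell_type label(s) {bad}; expected one of {CELL_TYPES}"
            )
        bad = sorted(set(df["sex"]) - set(SEXES))
        if bad:
            raise FormatError(f"unknown sex label(s) {bad}; expected {SEXES}")
        try:
            df["passage"] = df["passage"].astype(int)
        except (TypeError, ValueError) as exc:
            raise FormatError("passage must be an integer") from exc
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def samples_for_condition(self, condition: str) -> list[str]:
        sub = self.frame[self.frame["condition"] == condition]
        return list(sub["sample_id"])


@dataclass(frozen=True)
class PairedSet:
    """One animal's strictly connected four-condition sample quadruple."""

    animal_id: str
    cell_type: str
    sex: str
    passage: int
    sample_ids_by_condition: Mapping[str, str] = field(hash=False)

    def __post_init__(self) -> None:
        missing = [c for c in CONDITIONS if c not in self.sample_ids_by_condition]
        if missing:
            raise FormatError(
                f"paired set for animal {self.animal_id} missing conditions: {missing}"
            )

    def sample(self, condition: str) -> str:
        return self.sample_ids_by_condition[condition]


def load_counts(path: str | Path) -> CountMatrix:
    """Read a featureCounts-style TSV (gene ids in the first column, sample
    ids in the header).  Known annotation columns are ignored."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty count file: {path}") from exc
    df = df.drop(columns=[c for c in df.columns if c in ANNOTATION_COLUMNS])
    if df.empty:
        raise FormatError(f"no count data in {path}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError("non-numeric values in count matrix")
    if np.isnan(arr.astype(float)).any():
        raise FormatError("missing values in count matrix")
    return CountMatrix(list(df.index), list(df.columns), arr)


def load_sample_sheet(path: str | Path) -> SampleSheet:
    """Read and validate a CSV/TSV sample sheet (separator sniffed)."""
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty sample sheet: {path}") from exc
    return SampleSheet(df)


def build_paired_sets(sheet: SampleSheet) -> list[PairedSet]:
    """Group samples into complete four-condition paired sets.

    The pairing key is (animal_id, cell_type, passage): samples from the same
    animal at the same passage treated in parallel.  Groups missing one of the
    four conditions are dropped with a warning rather than erroring.
    """
    sets: list[PairedSet] = []
    dropped: list[tuple] = []
    grouped = sheet.frame.groupby(["animal_id", "cell_type", "passage"], sort=True)
    for (animal, cell_type, passage), sub in grouped:
        by_cond = dict(zip(sub["condition"], sub["sample_id"]))
        if sub["condition"].duplicated().any():
            raise FormatError(
                f"animal {animal} passage {passage}: repeated condition within one paired set"
            )
        if set(CONDITIONS) <= set(by_cond):
            sexes = set(sub["sex"])
            if len(sexes) != 1:
                raise FormatError(f"animal {animal}: inconsistent sex annotation")
            sets.append(
                PairedSet(
                    animal_id=str(animal),
                    cell_type=str(cell_type),
                    sex=sexes.pop(),
                    passage=int(passage),
                    sample_ids_by_condition={c: by_cond[c] for c in CONDITIONS},
                )
            )
        else:
            dropped.append((animal, cell_type, passage, sorted(set(CONDITIONS) - set(by_cond))))
    for animal, cell_type, passage, missing in dropped:
        warnings.warn(
            f"dropping incomplete paired set (animal={animal}, cell_type={cell_type}, "
            f"passage={passage}): missing conditions {missing}",
            stacklevel=2,
        )
    if not sets:
        raise FormatError("no complete paired sets in sample sheet")
    return sets


def compute_fpm(
    counts: CountMatrix, library_sizes: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """Fragments per million: count * 1e6 / library size.

    Library size defaults to the per-sample column total of the matrix; an
    explicit mapping (e.g. total mapped reads) may be supplied instead.
    Returns a genes x samples DataFrame.
    """
    frame = counts.to_frame().astype(float)
    if library_sizes is None:
        libs = frame.sum(axis=0)
    else:
        missing = [s for s in counts.sample_ids if s not in library_sizes]
        if missing:
            raise FormatError(f"library sizes missing for samples: {missing}")
        libs = pd.Series({s: float(library_sizes[s]) for s in counts.sample_ids})
    if (libs <= 0).any():
        bad = list(libs.index[libs <= 0])
        raise FormatError(f"zero/negative library size for sample(s): {bad}")
    return frame * 1e6 / libs


def group_mean_fpm(
    fpm: pd.DataFrame, sheet: SampleSheet, grouping: str = "condition"
) -> pd.DataFrame:
    """Arithmetic mean FPM per gene per group (default: condition)."""
    if grouping not in sheet.frame.columns:
        raise FormatError(f"unknown grouping column: {grouping}")
    out = {}
    for group, sub in sheet.frame.groupby(grouping, sort=True):
        samples = [s for s in sub["sample_id"] if s in fpm.columns]
        if not samples:
            raise FormatError(f"group {group!r} has no samples in the FPM matrix")
        out[str(group)] = fpm[samples].mean(axis=1)
    return pd.DataFrame(out)


def write_run_metadata(path: str | Path, metadata: Mapping) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(dict(metadata), fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
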