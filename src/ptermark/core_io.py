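"""Shared tabular data model and readers/writers for every file the pipeline touches.

The pipeline consumes gene-level count tables in the featureCounts output
layout (``Geneid  Chr  Start  End  Strand  Length  <sample> ...``), a sample
sheet assigning each sample a tissue class and a cohort, and gene-set
collections in GMT format.  All outputs are plain TSV.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleSheet",
    "GeneSetCollection",
    "COHORT_TRAINING",
    "COHORT_VALIDATION",
    "read_featurecounts",
    "read_sample_sheet",
    "read_gmt",
    "write_table",
]

COHORT_TRAINING = "training"
COHORT_VALIDATION = "validation"

_FEATURECOUNTS_META = ["Geneid", "Chr", "Start", "End", "Strand", "Length"]


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with optional feature lengths.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per row. Identifiers are opaque strings;
        no symbol mapping is performed.
    sample_ids
        Unique sample identifiers, one per column.
    counts
        ``(n_genes, n_samples)`` array of non-negative integers.
    feature_lengths
        Per-gene feature length in bases (positive), or ``None`` when the
        source table carried no ``Length`` column.  Differential expression
        does not need lengths; TPM computation does.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    feature_lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D gene x sample array")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene identifiers: {dupes}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.asarray(self.counts).astype(np.int64, casting="unsafe")
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integral")
            self.counts = as_int
        else:
            self.counts = self.counts.astype(np.int64, copy=False)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.feature_lengths is not None:
            self.feature_lengths = np.asarray(self.feature_lengths, dtype=np.int64)
            if self.feature_lengths.shape != (len(self.gene_ids),):
                raise ValueError("feature_lengths must have one entry per gene")
            if (self.feature_lengths <= 0).any():
                raise ValueError("feature_lengths must be positive")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, keep: np.ndarray | list) -> "CountMatrix":
        """Row subset by boolean mask or integer index, order preserving."""
        idx = np.asarray(keep)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        lengths = None if self.feature_lengths is None else self.feature_lengths[idx]
        return CountMatrix(
            [self.gene_ids[i] for i in idx],
            list(self.sample_ids),
            self.counts[idx],
            lengths,
        )

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples absent from count matrix: {missing}")
        cols = [pos[s] for s in sample_ids]
        return CountMatrix(
            list(self.gene_ids), list(sample_ids), self.counts[:, cols], self.feature_lengths
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def hstack(self, other: "CountMatrix") -> "CountMatrix":
        """Concatenate samples of two matrices sharing an identical gene axis."""
        if self.gene_ids != other.gene_ids:
            raise ValueError("gene axes differ; join genes first")
        return CountMatrix(
            list(self.gene_ids),
            list(self.sample_ids) + list(other.sample_ids),
            np.hstack([self.counts, other.counts]),
            self.feature_lengths,
        )


@dataclass
class SampleSheet:
    """Per-sample tissue class and cohort labels driving all group contrasts.

    Exactly one tissue class is designated the *target* of the marker
    analysis.  Validation-cohort samples must all carry the target class:
    the validation cohort consists of target-tissue samples only (no
    validation controls exist in the design this pipeline implements).
    """

    frame: pd.DataFrame  # index sample_id; columns tissue_class, cohort, covariates...
    target_class: str

    def __post_init__(self) -> None:
        f = self.frame
        if f.index.has_duplicates:
            raise ValueError("duplicate sample_id in sample sheet")
        if len(f) == 0:
            raise ValueError("no samples in sample sheet")
        bad = set(f["cohort"]) - {COHORT_TRAINING, COHORT_VALIDATION}
        if bad:
            raise ValueError(f"unknown cohort value(s): {sorted(bad)}")
        train = f[f["cohort"] == COHORT_TRAINING]
        if self.target_class not in set(train["tissue_class"]):
            raise ValueError(
                f"target class {self.target_class!r} absent from training cohort"
            )
        val = f[f["cohort"] == COHORT_VALIDATION]
        nontarget = val[val["tissue_class"] != self.target_class]
        if len(nontarget):
            raise ValueError(
                "validation cohort must contain only target-class samples; "
                f"offending samples: {list(nontarget.index)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def ids(self, cohort: str | None = None, tissue_class: str | None = None) -> list[str]:
        f = self.frame
        if cohort is not None:
            f = f[f["cohort"] == cohort]
        if tissue_class is not None:
            f = f[f["tissue_class"] == tissue_class]
        return list(f.index)

    def training_classes(self) -> list[str]:
        """Distinct tissue classes in the training cohort, target first."""
        train = self.frame[self.frame["cohort"] == COHORT_TRAINING]
        seen: list[str] = []
        for c in train["tissue_class"]:
            if c not in seen:
                seen.append(c)
        seen.sort(key=lambda c: (c != self.target_class, c))
        return seen

    def control_classes(self) -> list[str]:
        return [c for c in self.training_classes() if c != self.target_class]


@dataclass
class GeneSetCollection:
    """Mapping term_id -> (term_name, member gene list); GMT-file shaped."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {term!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def _strip_sample_name(name: str) -> str:
    base = os.path.basename(name.replace("\\", "/"))
    return re.sub(r"\.(bam|sam|cram)$", "", base, flags=re.IGNORECASE)


def read_featurecounts(path: str, strip_sample_paths: bool = False) -> CountMatrix:
    """Read a featureCounts gene-level count table.

    Accepts at most one leading comment line beginning with ``#`` (the
    program line featureCounts writes), then a header with the six metadata
    columns ``Geneid Chr Start End Strand Length`` followed by one column per
    sample.  Sample headers that look like alignment-file paths are rejected
    unless ``strip_sample_paths`` is set, in which case the directory part
    and a ``.bam``/``.sam``/``.cram`` suffix are removed.
    """
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        skip = 1 if first.startswith("#") else 0
    df = pd.read_csv(path, sep="\t", skiprows=skip, dtype=str)
    missing = [c for c in _FEATURECOUNTS_META if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory featureCounts column(s): {missing}")
    sample_cols = [c for c in df.columns if c not in _FEATURECOUNTS_META]
    if not sample_cols:
        raise ValueError("no sample columns found after the metadata columns")

    pathlike = [c for c in sample_cols if "/" in c or "\\" in c
                or re.search(r"\.(bam|sam|cram)$", c, flags=re.IGNORECASE)]
    if pathlike and not strip_sample_paths:
        raise ValueError(
            f"sample headers look like alignment-file paths {pathlike[:3]}; "
            "pass strip_sample_paths=True (--strip-sample-paths) to accept them"
        )
    sample_ids = [_strip_sample_name(c) if strip_sample_paths else c for c in sample_cols]

    gene_ids = df["Geneid"].tolist()
    dupes = df["Geneid"][df["Geneid"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate Geneid: {dupes}")

    counts = np.empty((len(df), len(sample_cols)), dtype=np.int64)
    for j, col in enumerate(sample_cols):
        for i, cell in enumerate(df[col]):
            try:
                counts[i, j] = int(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-integer count {cell!r} at gene {gene_ids[i]!r} "
                    f"(row {i + 1}), sample column {col!r}"
                ) from None
    try:
        lengths = df["Length"].astype(np.int64).to_numpy()
    except ValueError as exc:
        raise ValueError(f"non-integer Length value: {exc}") from None
    return CountMatrix(gene_ids, sample_ids, counts, lengths)


def read_sample_sheet(path: str, target_class: str) -> SampleSheet:
    """Read the TSV sample sheet (``sample_id  tissue_class  cohort`` + covariates)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "tissue_class", "cohort"):
        if col not in df.columns:
            raise ValueError(f"sample sheet missing mandatory column {col!r}")
    if len(df) == 0:
        raise ValueError("no samples in sample sheet")
    df = df.set_index("sample_id")
    return SampleSheet(df, target_class)


def read_gmt(path: str) -> GeneSetCollection:
    """Read a GMT gene-set file: ``term_id TAB description TAB gene1 TAB ...``."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            term, desc, genes = fields[0], fields[1], fields[2:]
            if term in sets:
                raise ValueError(f"GMT line {lineno}: duplicate term_id {term!r}")
            deduped = list(dict.fromkeys(g for g in genes if g))
            sets[term] = (desc, deduped)
    return GeneSetCollection(sets)


def write_table(rows: pd.DataFrame, path: str) -> None:
    """Write a result table as UTF-8 TSV, missing values rendered ``NA``.

    Floats are written with 12 significant digits so a write/read round trip
    preserves values at that precision; row order is written as given.
    """
    rows.to_csv(path, sep="\t", index=False, na_rep="NA",
                float_format="%.12g", encoding="utf-8")


def write_counts_featurecounts(cm: CountMatrix, path: str) -> None:
    """Write a CountMatrix back out in featureCounts layout (round-trip helper)."""
    lengths = cm.feature_lengths
    if lengths is None:
        lengths = np.ones(cm.n_genes, dtype=np.int64)
    df = pd.DataFrame({
        "Geneid": cm.gene_ids,
        "Chr": "chr1",
        "Start": 1,
        "End": lengths,
        "Strand": "+",
        "Length": lengths,
    })
    for j, s in enumerate(cm.sample_ids):
        df[s] = cm.counts[:, j]
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")
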