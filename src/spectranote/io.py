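"""Data model and strict TSV I/O for spectral-count proteomics tables.

The canonical orientation everywhere is proteins in rows, samples in
columns.  Counts are peptide-spectrum-match (PSM) totals per protein and
sample; "detected" means a PSM count strictly greater than zero.  Missing
cells are rejected at parse time: a zero and an absence mean different
things downstream (the absence branch of the differential-expression rule),
so ambiguity is not allowed into the model.

All files are tab-separated, UTF-8, header required, no quoting, "." as
the decimal separator.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Annotation",
    "CountMatrix",
    "NSAFMatrix",
    "read_annotations",
    "read_counts",
    "read_design",
    "write_counts",
    "write_design",
    "write_table",
    "UNASSIGNED_BIN",
]

#: Functional bin used for proteins absent from the annotation file.
UNASSIGNED_BIN = "not assigned.unknown"


class TableFormatError(ValueError):
    """A TSV file violated the strict dialect or a model invariant."""


@dataclasses.dataclass(frozen=True)
class Annotation:
    """Functional annotation of one protein: a dot-separated bin path and GO ids."""

    bin: str
    go_terms: frozenset[str]

    @property
    def top_level_bin(self) -> str:
        return self.bin.split(".", 1)[0]


def _validate_design(design: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "treatment", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise TableFormatError(f"design table missing columns: {sorted(missing)}")
    design = design.copy()
    design["replicate"] = design["replicate"].astype(int)
    if (design["replicate"] < 1).any():
        bad = design.loc[design["replicate"] < 1, "sample_id"].iloc[0]
        raise TableFormatError(f"replicate index < 1 for sample {bad!r}")
    dup = design.duplicated(subset=["treatment", "replicate"])
    if dup.any():
        pair = design.loc[dup, ["treatment", "replicate"]].iloc[0]
        raise TableFormatError(
            f"duplicate (treatment, replicate) pair: ({pair.treatment!r}, {pair.replicate})"
        )
    if design["sample_id"].duplicated().any():
        sid = design.loc[design["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise TableFormatError(f"duplicate sample id {sid!r}")
    return design.reset_index(drop=True)


@dataclasses.dataclass
class CountMatrix:
    """Integer PSM counts per protein x sample with protein lengths.

    Parameters
    ----------
    counts
        DataFrame indexed by accession, one column per sample in the
        design's order, dtype integer, all values >= 0.
    lengths
        Protein lengths in amino acids, indexed like ``counts``; >= 1.
    design
        Sample design with columns sample_id, treatment, replicate.
    descriptions
        Optional free-text protein descriptions indexed like ``counts``.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    design: pd.DataFrame
    descriptions: pd.Series | None = None

    def __post_init__(self) -> None:
        self.design = _validate_design(pd.DataFrame(self.design))
        if self.counts.index.duplicated().any():
            acc = self.counts.index[self.counts.index.duplicated()][0]
            raise TableFormatError(f"duplicate accession {acc!r}")
        if list(self.counts.columns) != list(self.design["sample_id"]):
            raise TableFormatError(
                "count columns do not match design sample order: "
                f"{list(self.counts.columns)} vs {list(self.design['sample_id'])}"
            )
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            frac = arr != np.floor(arr)
            if np.isnan(arr).any() or frac.any():
                i, j = np.argwhere(np.isnan(arr) | frac)[0]
                raise TableFormatError(
                    f"non-integer count at protein {self.counts.index[i]!r}, "
                    f"sample {self.counts.columns[j]!r}: {arr[i, j]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise TableFormatError(
                f"negative count at protein {self.counts.index[i]!r}, "
                f"sample {self.counts.columns[j]!r}: {arr[i, j]}"
            )
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            acc = self.lengths.index[self.lengths.isna()][0]
            raise TableFormatError(f"missing length for protein {acc!r}")
        self.lengths = self.lengths.astype(np.int64)
        if (self.lengths < 1).any():
            acc = self.lengths.index[self.lengths < 1][0]
            raise TableFormatError(f"length < 1 for protein {acc!r}")

    # -- convenience -----------------------------------------------------
    @property
    def accessions(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def treatments(self) -> list[str]:
        """Treatment labels in design order of first appearance."""
        return list(dict.fromkeys(self.design["treatment"]))

    def samples_of(self, treatment: str) -> list[str]:
        sel = self.design.loc[self.design["treatment"] == treatment, "sample_id"]
        if sel.empty:
            raise KeyError(f"unknown treatment {treatment!r}")
        return list(sel)

    def detected(self) -> pd.DataFrame:
        """Boolean detection mask: PSM count > 0."""
        return self.counts > 0


@dataclasses.dataclass
class NSAFMatrix:
    """Normalized spectral abundance factors, proteins x samples.

    ``values`` are on the reporting scale (raw NSAF times ``scale_factor``);
    ``raw`` recovers the compositional values, which sum to 1 within every
    sample that has at least one detection.
    """

    values: pd.DataFrame
    scale_factor: float
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        self.design = _validate_design(pd.DataFrame(self.design))

    @property
    def raw(self) -> pd.DataFrame:
        return self.values / self.scale_factor

    @property
    def accessions(self) -> list[str]:
        return list(self.values.index)

    @property
    def treatments(self) -> list[str]:
        return list(dict.fromkeys(self.design["treatment"]))

    def samples_of(self, treatment: str) -> list[str]:
        sel = self.design.loc[self.design["treatment"] == treatment, "sample_id"]
        if sel.empty:
            raise KeyError(f"unknown treatment {treatment!r}")
        return list(sel)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(
            path, sep="\t", dtype=str, header=0, quoting=3, keep_default_na=False
        )
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TableFormatError(f"{path}: {exc}") from exc


def read_design(path: str | Path) -> pd.DataFrame:
    """Read a sample-design TSV (sample_id, treatment, replicate)."""
    df = _read_tsv(path)
    return _validate_design(df)


def read_counts(path: str | Path, design_path: str | Path) -> CountMatrix:
    """Read a PSM count TSV plus its design table into a ``CountMatrix``.

    The count file's first columns are ``accession`` and ``length``
    (optionally ``description``); remaining columns are sample ids.  Column
    order in the result follows the design file, not the count file.
    """
    design = read_design(design_path)
    df = _read_tsv(path)
    for col in ("accession", "length"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing required column {col!r}")
    meta_cols = {"accession", "length", "description"}
    sample_cols = [c for c in df.columns if c not in meta_cols]
    extra = set(sample_cols) - set(design["sample_id"])
    if extra:
        raise TableFormatError(
            f"{path}: sample column(s) {sorted(extra)} absent from design"
        )
    missing = set(design["sample_id"]) - set(sample_cols)
    if missing:
        raise TableFormatError(
            f"{path}: design sample(s) {sorted(missing)} absent from count header"
        )
    df = df.set_index("accession")
    counts = pd.DataFrame(index=df.index)
    for sid in design["sample_id"]:
        col = df[sid]
        for acc, cell in col.items():
            if cell == "" or not _is_int(cell):
                raise TableFormatError(
                    f"{path}: non-integer count {cell!r} at protein {acc!r}, sample {sid!r}"
                )
        counts[sid] = col.astype(np.int64)
    try:
        lengths = df["length"].astype(np.int64)
    except ValueError as exc:
        raise TableFormatError(f"{path}: non-integer length column: {exc}") from exc
    desc = df["description"] if "description" in df.columns else None
    return CountMatrix(counts=counts, lengths=lengths, design=design, descriptions=desc)


def _is_int(cell: str) -> bool:
    try:
        return float(cell) == int(cell)
    except ValueError:
        return False


def read_annotations(path: str | Path) -> dict[str, Annotation]:
    """Read accession -> (bin, GO terms) from a MapMan-style mapping TSV.

    Columns: ``accession``, ``bin``, ``go_terms`` (semicolon separated,
    possibly empty).  Exact duplicate rows collapse silently; two rows giving
    the same accession conflicting bins are an error.  GO terms from
    duplicate rows are unioned.
    """
    df = _read_tsv(path)
    for col in ("accession", "bin"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing required column {col!r}")
    has_go = "go_terms" in df.columns
    bins: dict[str, str] = {}
    gos: dict[str, set[str]] = {}
    conflicts: list[str] = []
    for row in df.itertuples(index=False):
        acc = row.accession
        terms = set()
        if has_go and row.go_terms:
            terms = {t.strip() for t in row.go_terms.split(";") if t.strip()}
        if acc in bins:
            if bins[acc] != row.bin:
                conflicts.append(acc)
            gos[acc] |= terms
        else:
            bins[acc] = row.bin
            gos[acc] = terms
    if conflicts:
        raise TableFormatError(
            f"{path}: conflicting bins for accession(s) {sorted(set(conflicts))}"
        )
    return {a: Annotation(bin=b, go_terms=frozenset(gos[a])) for a, b in bins.items()}


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _format_cell(v) -> str:
    if isinstance(v, float) and np.isinf(v):
        return "Inf" if v > 0 else "-Inf"
    if isinstance(v, float) and np.isnan(v):
        return "NA"
    return str(v)


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as strict TSV with deterministic ordering.

    Rows sort by an ``accession`` column when present and no ``rank`` column
    exists (a rank column means the producer already ordered the rows).
    The "absent" fold sentinel serializes as Inf/-Inf, missing values as NA.
    """
    df = records.copy()
    if "accession" in df.columns and "rank" not in df.columns:
        df = df.sort_values("accession", kind="stable")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_format_cell(v) for v in row) + "\n")


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    """Write a CountMatrix back to the count-TSV dialect read_counts accepts."""
    df = cm.counts.copy()
    df.insert(0, "length", cm.lengths)
    if cm.descriptions is not None:
        df.insert(1, "description", cm.descriptions)
    df.insert(0, "accession", df.index)
    write_table(df.reset_index(drop=True), path)


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    write_table(design[["sample_id", "treatment", "replicate"]], path)


def write_annotations(annotations: Mapping[str, Annotation], path: str | Path) -> None:
    rows = [
        {"accession": acc, "bin": ann.bin, "go_terms": ";".join(sorted(ann.go_terms))}
        for acc, ann in sorted(annotations.items())
    ]
    write_table(pd.DataFrame(rows, columns=["accession", "bin", "go_terms"]), path)
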