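"""Readers and writers for alignments, sample metadata, and labelled matrices.

All tabular formats are plain TSV; alignments are FASTA (via Biopython);
trees are newick. Triangular matrix files carry a leading label column and
blank or "-"/"–" cells on the unused triangle, mirroring how published
FST/distance tables are usually transcribed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_DNA = set("ACGTRYSWKMBDHVN-")


class AlignmentError(ValueError):
    """Raised for malformed or inconsistent alignments."""


class MetadataError(ValueError):
    """Raised for malformed sample metadata tables."""


class MatrixError(ValueError):
    """Raised for malformed labelled-matrix files."""


@dataclass(frozen=True)
class Alignment:
    """Equal-length DNA sequences with unique sample ids.

    Sequences are stored upper-case with 'U' mapped to 'T'. ``length`` is the
    common site count L.
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ids:
            raise AlignmentError("alignment has no records")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate sample ids: {dupes}")
        L = len(self.seqs[0])
        if L == 0:
            raise AlignmentError("zero-length sequences")
        for sid, s in zip(self.ids, self.seqs):
            if len(s) != L:
                raise AlignmentError(
                    f"record {sid!r} has length {len(s)}, expected {L}"
                )
            bad = set(s) - IUPAC_DNA
            if bad:
                raise AlignmentError(f"record {sid!r} has invalid symbols {bad}")

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "Alignment":
        ids, seqs = [], []
        for sid, s in records:
            ids.append(str(sid))
            seqs.append(str(s).upper().replace("U", "T"))
        return cls(tuple(ids), tuple(seqs))

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def n(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:
        return self.n

    def trim(self, start: int, end: int) -> "Alignment":
        """Restrict to the half-open column window [start, end)."""
        if not (0 <= start < end <= self.length):
            raise AlignmentError(f"bad trim window [{start}, {end})")
        return Alignment(self.ids, tuple(s[start:end] for s in self.seqs))

    def to_matrix(self) -> np.ndarray:
        """Sites as a (n, L) array of single characters."""
        return np.frombuffer(
            "".join(self.seqs).encode(), dtype="S1"
        ).reshape(self.n, self.length).astype("U1")


@dataclass(frozen=True)
class SampleTable:
    """Per-sample metadata: population, country, group, host plant, lat/lon."""

    df: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "population")
    OPTIONAL = ("country", "group", "host_plant", "lat", "lon")

    def __post_init__(self) -> None:
        df = self.df
        for col in self.REQUIRED:
            if col not in df.columns:
                raise MetadataError(f"missing required column {col!r}")
        if df["sample_id"].duplicated().any():
            dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
            raise MetadataError(f"duplicate sample ids: {dupes}")
        for coord, lo, hi in (("lat", -90, 90), ("lon", -180, 180)):
            if coord in df.columns:
                vals = pd.to_numeric(df[coord], errors="coerce")
                present = df[coord].notna()
                bad = present & ((vals < lo) | (vals > hi) | vals.isna())
                if bad.any():
                    raise MetadataError(
                        f"{coord} out of [{lo},{hi}] for samples "
                        f"{sorted(df.loc[bad, 'sample_id'])}"
                    )
        # each population must map to exactly one country and one group
        for parent in ("country", "group"):
            if parent in df.columns:
                counts = df.groupby("population")[parent].nunique(dropna=True)
                multi = counts[counts > 1]
                if not multi.empty:
                    raise MetadataError(
                        f"populations mapped to multiple {parent} values: "
                        f"{sorted(multi.index)}"
                    )

    def __len__(self) -> int:
        return len(self.df)

    def labels_for(self, ids: Sequence[str], column: str = "population") -> list[str]:
        """Column values in the order of ``ids``; errors on unknown ids."""
        lookup = self.df.set_index("sample_id")[column]
        missing = [i for i in ids if i not in lookup.index]
        if missing:
            raise MetadataError(f"unknown sample ids: {missing}")
        return [lookup[i] for i in ids]

    def pop_to_group(self) -> dict[str, str]:
        if "group" not in self.df.columns:
            raise MetadataError("no 'group' column in sample table")
        return dict(
            self.df.dropna(subset=["group"])
            .groupby("population")["group"]
            .first()
        )

    @property
    def groups(self) -> list[str]:
        return sorted(self.df["group"].dropna().unique())


@dataclass(frozen=True)
class LabeledMatrix:
    """Square symmetric matrix with ordered row/column labels."""

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise MatrixError(f"matrix is not square: shape {v.shape}")
        if v.shape[0] != len(self.labels):
            raise MatrixError("label count does not match matrix size")
        if len(set(self.labels)) != len(self.labels):
            raise MatrixError("duplicate labels")
        finite = np.isfinite(v)
        if not np.allclose(
            np.where(finite, v, 0.0), np.where(finite.T, v.T, 0.0), atol=1e-12
        ):
            raise MatrixError("matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)

    def submatrix(self, labels: Sequence[str]) -> "LabeledMatrix":
        idx = [self.labels.index(l) for l in labels]
        return LabeledMatrix(tuple(labels), self.values[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        """Lower-triangle off-diagonal entries, row-major over (i>j)."""
        n = self.n
        return np.array(
            [self.values[i, j] for i in range(1, n) for j in range(i)]
        )


# ---------------------------------------------------------------- FASTA I/O


def read_alignment(path: str | Path) -> Alignment:
    """Read a FASTA alignment; all sequences must share one length."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        L0 = len(records[0].seq)
        for r in records:
            if len(r.seq) != L0:
                raise AlignmentError(
                    f"record {r.id!r} has length {len(r.seq)}, others {L0}"
                )
    return Alignment.from_records((r.id, str(r.seq)) for r in records)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(recs, str(path), "fasta")


# ------------------------------------------------------------- metadata I/O


def read_samples(path: str | Path) -> SampleTable:
    """Read a TSV sample table with a header row."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "population": str})
    for coord in ("lat", "lon"):
        if coord in df.columns:
            df[coord] = pd.to_numeric(df[coord], errors="coerce")
    return SampleTable(df)


def write_samples(table: SampleTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------- matrix I/O

_EMPTY_CELLS = {"", "-", "–", "—", "na", "NA", "nan", "NaN"}


def _parse_cell(raw: str, row: str, col: int) -> float:
    txt = raw.strip().replace(",", "")
    if txt in _EMPTY_CELLS:
        return np.nan
    try:
        return float(txt)
    except ValueError as exc:
        raise MatrixError(
            f"non-numeric cell {raw!r} at row {row!r}, column {col}"
        ) from exc


def read_labeled_matrix(
    path: str | Path, triangle: str = "full"
) -> LabeledMatrix:
    """Read a labelled square or triangular TSV matrix.

    ``triangle`` is one of 'lower', 'upper', 'full'. Triangular reads are
    symmetrized by transpose fill; the diagonal is forced to zero.
    """
    if triangle not in {"lower", "upper", "full"}:
        raise ValueError(f"triangle must be lower|upper|full, got {triangle!r}")
    lines = [
        ln.rstrip("\n") for ln in Path(path).read_text().splitlines() if ln.strip()
    ]
    header = lines[0].split("\t")
    body = [ln.split("\t") for ln in lines[1:]]
    labels = tuple(row[0].strip() for row in body)
    n = len(labels)
    if any(len(row) - 1 > n for row in body):
        raise MatrixError("matrix has more value columns than rows")
    m = np.full((n, n), np.nan)
    for i, row in enumerate(body):
        for j, raw in enumerate(row[1:]):
            m[i, j] = _parse_cell(raw, labels[i], j + 1)
    if triangle == "lower":
        full = np.tril(np.nan_to_num(m, nan=0.0), -1)
        full = full + full.T
    elif triangle == "upper":
        full = np.triu(np.nan_to_num(m, nan=0.0), 1)
        full = full + full.T
    else:
        if np.isnan(m).any():
            raise MatrixError("missing cells in a full matrix read")
        full = m.copy()
    np.fill_diagonal(full, 0.0)
    return LabeledMatrix(labels, full)


def write_labeled_matrix(
    m: LabeledMatrix,
    path: str | Path,
    upper: LabeledMatrix | None = None,
    fmt: str = "%.6g",
) -> None:
    """Write a full labelled matrix; optionally merge a second matrix above
    the diagonal (the published FST-below / km-above layout)."""
    vals = m.values.copy()
    if upper is not None:
        if upper.labels != m.labels:
            raise MatrixError("merged matrices must share labels and order")
        iu = np.triu_indices(m.n, 1)
        vals[iu] = upper.values[iu]
    with open(path, "w") as fh:
        fh.write("label\t" + "\t".join(m.labels) + "\n")
        for lab, row in zip(m.labels, vals):
            cells = ["NA" if not np.isfinite(v) else fmt % v for v in row]
            fh.write(lab + "\t" + "\t".join(cells) + "\n")
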