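"""Sequence, alignment and per-residue table I/O.

All on-disk artifacts of the pipeline live here: FASTA sequences and
alignments (read through Biopython), and the shared per-residue TSV schema
(``residue``, ``aa``, then named value columns; tab separated, header row
required, ``NA`` for missing, '.' decimal separator).

Missing values are represented in memory as ``numpy.nan`` and on disk as the
literal string ``NA``.  They are an explicit sentinel, never zero: a proline
has no amide hydrogen, so its steady-state NOE cannot be measured at all.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "GAP",
    "SequenceRecord",
    "DynamicsProfile",
    "PredictionProfile",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_residue_table",
    "write_residue_table",
    "percent_identity",
    "map_aligned_positions",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


class FormatError(ValueError):
    """Raised when an input file violates the expected on-disk format."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named amino-acid sequence, optionally gapped (aligned context).

    Parameters
    ----------
    identifier:
        Short label, e.g. a homologue name ("human", "dog").
    residues:
        One-letter amino-acid string, uppercase.  The gap character '-' is
        permitted only when ``aligned`` is true.
    numbering_offset:
        Position ``i`` (1-based) in ``residues`` carries residue number
        ``i + numbering_offset``.  Default 0, i.e. plain 1-based numbering
        in each homologue's own construct coordinates.
    aligned:
        Whether this record is a row of an alignment (gaps allowed).
    """

    identifier: str
    residues: str
    numbering_offset: int = 0
    aligned: bool = False

    def __post_init__(self) -> None:
        if len(self.residues) == 0:
            raise FormatError(f"sequence {self.identifier!r} is empty")
        allowed = set(AMINO_ACIDS) | ({GAP} if self.aligned else set())
        bad = sorted(set(self.residues) - allowed)
        if bad:
            raise FormatError(
                f"sequence {self.identifier!r} contains non-amino-acid "
                f"characters: {''.join(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> "SequenceRecord":
        """The same record with alignment gaps removed."""
        if not self.aligned:
            return self
        return replace(
            self, residues=self.residues.replace(GAP, ""), aligned=False
        )

    def residue_numbers(self) -> np.ndarray:
        """Residue numbers of the ungapped sequence, in order."""
        n = len(self.ungapped())
        return np.arange(1, n + 1) + self.numbering_offset

    def aa_at(self, residue_number: int) -> str:
        """One-letter code at a residue number (ungapped coordinates)."""
        idx = residue_number - self.numbering_offset - 1
        seq = self.ungapped().residues
        if not 0 <= idx < len(seq):
            raise KeyError(
                f"residue {residue_number} outside {self.identifier!r} "
                f"({self.numbering_offset + 1}..{self.numbering_offset + len(seq)})"
            )
        return seq[idx]

    def composition(self) -> dict[str, int]:
        """Counts per amino-acid type (gaps ignored)."""
        seq = self.ungapped().residues
        return {aa: seq.count(aa) for aa in AMINO_ACIDS}


def _validate_entries(
    protein: SequenceRecord | None,
    residue_numbers: np.ndarray,
    aa: Sequence[str],
) -> None:
    if len(residue_numbers) == 0:
        raise FormatError("profile has no rows")
    if len(residue_numbers) != len(aa):
        raise FormatError("residue/aa column length mismatch")
    if np.any(np.diff(residue_numbers) <= 0):
        raise FormatError("residue numbers must be strictly increasing")
    if protein is not None:
        for num, letter in zip(residue_numbers, aa):
            expected = protein.aa_at(int(num))
            if letter != expected:
                raise FormatError(
                    f"residue {num}: table says {letter!r} but sequence "
                    f"{protein.identifier!r} has {expected!r}"
                )


@dataclass
class DynamicsProfile:
    """Per-residue backbone-dynamics record for one protein.

    Holds the raw steady-state NOE ratio per residue and, once computed, the
    normalized NHNOE* statistic (antilog of the NOE divided by the maximum
    antilog over the protein; range (0, 1], 1 = least flexible residue).
    Prolines are always missing (no amide hydrogen).
    """

    residue_numbers: np.ndarray
    aa: list[str]
    noe_raw: np.ndarray
    nhnoe_star: np.ndarray | None = None
    protein: SequenceRecord | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.noe_raw = np.asarray(self.noe_raw, dtype=float)
        if self.nhnoe_star is not None:
            self.nhnoe_star = np.asarray(self.nhnoe_star, dtype=float)
        self.aa = list(self.aa)
        _validate_entries(self.protein, self.residue_numbers, self.aa)
        if len(self.noe_raw) != len(self.residue_numbers):
            raise FormatError("noe column length mismatch")
        for letter, value in zip(self.aa, self.noe_raw):
            if letter == "P" and not math.isnan(value):
                raise FormatError(
                    "proline has a measured NOE; prolines must be NA "
                    "(no amide hydrogen)"
                )
        if self.nhnoe_star is not None:
            present = self.nhnoe_star[~np.isnan(self.nhnoe_star)]
            if present.size and not math.isclose(
                float(present.max()), 1.0, rel_tol=0, abs_tol=1e-9
            ):
                raise FormatError("max NHNOE* over present values must be 1")

    def __len__(self) -> int:
        return len(self.residue_numbers)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "residue": self.residue_numbers,
            "aa": self.aa,
            "noe_raw": self.noe_raw,
        }
        if self.nhnoe_star is not None:
            data["nhnoe_star"] = self.nhnoe_star
        return pd.DataFrame(data)


@dataclass
class PredictionProfile:
    """Per-residue disorder probabilities from one predictor on one protein.

    Values lie in [0, 1]; a residue at or above ``threshold`` is
    conventionally called disordered.
    """

    residue_numbers: np.ndarray
    values: np.ndarray
    predictor_name: str
    protein: SequenceRecord | None = None
    threshold: float = 0.5
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.residue_numbers):
            raise FormatError("value column length mismatch")
        if len(self.residue_numbers) == 0:
            raise FormatError("profile has no rows")
        if np.any(np.diff(self.residue_numbers) != 1):
            raise FormatError(
                "prediction residue numbers must form a contiguous run"
            )
        present = self.values[~np.isnan(self.values)]
        if present.size and (present.min() < 0 or present.max() > 1):
            raise FormatError("disorder probabilities must lie in [0, 1]")
        if self.protein is not None:
            for num in self.residue_numbers:
                self.protein.aa_at(int(num))  # raises if out of span

    def __len__(self) -> int:
        return len(self.residue_numbers)

    def aa_letters(self) -> list[str] | None:
        if self.protein is None:
            return None
        return [self.protein.aa_at(int(n)) for n in self.residue_numbers]

    def to_frame(self) -> pd.DataFrame:
        data = {"residue": self.residue_numbers}
        letters = self.aa_letters()
        if letters is not None:
            data["aa"] = letters
        data[self.predictor_name] = self.values
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, aligned: bool = False) -> list[SequenceRecord]:
    """Read a (possibly aligned) FASTA file into SequenceRecords.

    The header token before the first whitespace becomes the identifier and
    the sequence is uppercased.  Non-amino-acid characters (other than '-'
    in aligned mode) raise :class:`FormatError` naming the offender.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(
                identifier=rec.id,
                residues=str(rec.seq).upper(),
                aligned=aligned,
            )
        )
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    if aligned:
        lengths = {len(r) for r in records}
        if len(lengths) > 1:
            raise FormatError(
                f"{path}: aligned FASTA rows differ in length: {sorted(lengths)}"
            )
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.identifier}\n{rec.residues}\n")


# ---------------------------------------------------------------------------
# Per-residue TSV

_FLOAT_FMT = "%.6g"


def _read_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(
        path, sep="\t", comment="#", na_values=["NA"], keep_default_na=False
    )
    if "residue" not in frame.columns or "aa" not in frame.columns:
        raise FormatError(
            f"{path}: per-residue tables need 'residue' and 'aa' columns"
        )
    if frame["residue"].duplicated().any():
        dups = frame.loc[frame["residue"].duplicated(), "residue"].tolist()
        raise FormatError(f"{path}: duplicate residue numbers {dups}")
    return frame


def read_residue_table(
    path: str | Path,
    kind: str,
    protein: SequenceRecord | None = None,
    value_column: str | None = None,
) -> DynamicsProfile | PredictionProfile:
    """Read a per-residue TSV as a dynamics or prediction profile.

    Parameters
    ----------
    kind:
        ``"dynamics"`` (expects a ``noe_raw`` column, optional
        ``nhnoe_star``) or ``"prediction"`` (one probability column; pass
        ``value_column`` to pick it when several are present, otherwise the
        first non-coordinate column is used and its header becomes the
        predictor name).
    protein:
        Optional sequence record; when given, the ``aa`` column is checked
        against it row by row.
    """
    frame = _read_tsv(path)
    residues = frame["residue"].to_numpy(dtype=int)
    aa = [str(x) for x in frame["aa"]]
    if kind == "dynamics":
        if "noe_raw" not in frame.columns:
            raise FormatError(f"{path}: dynamics table needs a 'noe_raw' column")
        star = (
            frame["nhnoe_star"].to_numpy(dtype=float)
            if "nhnoe_star" in frame.columns
            else None
        )
        return DynamicsProfile(
            residue_numbers=residues,
            aa=aa,
            noe_raw=frame["noe_raw"].to_numpy(dtype=float),
            nhnoe_star=star,
            protein=protein,
        )
    if kind == "prediction":
        candidates = [c for c in frame.columns if c not in ("residue", "aa")]
        if not candidates:
            raise FormatError(f"{path}: prediction table has no value column")
        name = value_column or candidates[0]
        if name not in frame.columns:
            raise FormatError(f"{path}: no column named {name!r}")
        return PredictionProfile(
            residue_numbers=residues,
            values=frame[name].to_numpy(dtype=float),
            predictor_name=name,
            protein=protein,
        )
    raise ValueError(f"unknown table kind {kind!r}")


def write_residue_table(
    profile: DynamicsProfile | PredictionProfile,
    path: str | Path,
    header_comments: Sequence[str] = (),
) -> None:
    """Write a profile to the shared TSV schema (``NA`` for missing)."""
    frame = profile.to_frame()
    buf = _io.StringIO()
    for line in header_comments:
        buf.write(f"# {line}\n")
    frame.to_csv(buf, sep="\t", index=False, na_rep="NA", float_format=_FLOAT_FMT)
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Alignment bookkeeping


def percent_identity(
    a: SequenceRecord, b: SequenceRecord, aligned: bool = True
) -> float:
    """Pairwise percent identity between two sequences.

    Identity is counted over columns where neither sequence has a gap and
    the denominator is the number of such columns, i.e. singly- and
    doubly-gapped columns are excluded.  Unaligned mode compares position by
    position and requires equal lengths.  The value is returned unrounded.
    """
    if len(a) != len(b):
        raise FormatError(
            f"percent_identity needs equal lengths, got {len(a)} and {len(b)}"
        )
    pairs = [
        (x, y)
        for x, y in zip(a.residues, b.residues)
        if not (aligned and (x == GAP or y == GAP))
    ]
    if not pairs:
        raise FormatError("no ungapped columns shared between sequences")
    matches = sum(x == y for x, y in pairs)
    return 100.0 * matches / len(pairs)


def map_aligned_positions(
    alignment: Sequence[SequenceRecord], reference_id: str
) -> dict[str, dict[int, int]]:
    """Map each sequence's residue numbers onto a reference's numbering.

    For every non-reference row the result holds ``{own residue number:
    reference residue number}`` over alignment columns where neither the row
    nor the reference is gapped; all other positions are simply absent from
    the map.  This is the bookkeeping that lets region statements like
    "residues 15-30" be carried across homologues.
    """
    by_id = {rec.identifier: rec for rec in alignment}
    if reference_id not in by_id:
        raise KeyError(
            f"reference {reference_id!r} not in alignment "
            f"({sorted(by_id)})"
        )
    ref = by_id[reference_id]
    lengths = {len(rec) for rec in alignment}
    if len(lengths) > 1:
        raise FormatError("alignment rows differ in length")

    # reference residue number per column (None in gap columns)
    ref_num_by_col: list[int | None] = []
    counter = ref.numbering_offset
    for ch in ref.residues:
        if ch == GAP:
            ref_num_by_col.append(None)
        else:
            counter += 1
            ref_num_by_col.append(counter)

    maps: dict[str, dict[int, int]] = {}
    for rec in alignment:
        own = rec.numbering_offset
        mapping: dict[int, int] = {}
        for col, ch in enumerate(rec.residues):
            if ch == GAP:
                continue
            own += 1
            ref_num = ref_num_by_col[col]
            if ref_num is not None:
                mapping[own] = ref_num
        maps[rec.identifier] = mapping
    return maps
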