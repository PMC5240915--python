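"""Read antigen sequences and peptide intensity tables, and classify every
measured peptide against the antigen(s).

A measured peptide is either an exact window of a target protein (*native*),
a single-amino-acid derivative of exactly one window (*substitution*), a
sequence matching more than one window or parent (*ambiguous*), or
*unmapped*.  Classification is done in O(1) per peptide by hashing every
L-window of every protein together with all of its one-substitution
neighbours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .alphabet import AMINO_ACIDS, AA_INDEX

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProteinRecord:
    """A target antigen sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideMeasurement:
    """One quantified peptide spot (arbitrary fluorescence units)."""

    sequence: str
    intensity: float
    replicate_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError(f"negative intensity for {self.sequence}")


class VariantKind(str, Enum):
    NATIVE = "native"
    SUBSTITUTION = "substitution"
    UNMAPPED = "unmapped"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class MappedPeptide:
    """A measurement placed on a protein (1-based, inclusive coordinates).

    For ``substitution`` records, ``frame_pos`` (1..L), ``replacing_aa`` and
    ``native_aa`` describe the single mismatch against the parent window.
    ``candidates`` lists every possible placement for ambiguous peptides.
    """

    measurement: PeptideMeasurement
    variant_kind: VariantKind
    protein_id: Optional[str] = None
    offset: Optional[int] = None
    frame_pos: Optional[int] = None
    replacing_aa: Optional[str] = None
    native_aa: Optional[str] = None
    candidates: tuple = field(default_factory=tuple)


def read_protein_fasta(path: str | Path, strict: bool = True) -> list[ProteinRecord]:
    """Read a (multi-)FASTA file of protein sequences, order preserved.

    Non-canonical characters raise in strict mode; otherwise they are
    replaced by ``X`` with a warning (such windows never match peptides).
    """
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = sorted({c for c in seq if c not in AA_INDEX})
        if bad:
            if strict:
                raise ValueError(
                    f"protein {rec.id!r}: non-amino-acid character(s) {''.join(bad)!r}"
                )
            logger.warning("protein %s: masking characters %s", rec.id, "".join(bad))
            seq = "".join(c if c in AA_INDEX else "X" for c in seq)
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def read_peptide_table(
    path: str | Path,
    length: int = 15,
    on_invalid_intensity: str = "error",
) -> list[PeptideMeasurement]:
    """Read a delimited peptide table with columns ``peptide``, ``intensity``
    and optionally ``replicate_id``.

    Rows whose peptide length differs from *length* are dropped and counted
    in the log.  ``on_invalid_intensity`` is ``"error"`` (default) or
    ``"drop"`` for non-numeric / negative intensities.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype={"peptide": str})
    missing = {"peptide", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")

    intensities = pd.to_numeric(df["intensity"], errors="coerce")
    invalid = intensities.isna() | (intensities < 0)
    if invalid.any():
        if on_invalid_intensity == "drop":
            logger.warning("%s: dropping %d rows with invalid intensity", path, int(invalid.sum()))
            df = df[~invalid]
            intensities = intensities[~invalid]
        else:
            raise ValueError(
                f"{path}: {int(invalid.sum())} rows with non-numeric or negative intensity"
            )

    peptides = df["peptide"].astype(str).str.upper()
    wrong_len = peptides.str.len() != length
    if wrong_len.any():
        logger.warning("%s: dropping %d rows with length != %d", path, int(wrong_len.sum()), length)
    keep = ~wrong_len
    reps = df["replicate_id"].astype(str) if "replicate_id" in df.columns else None
    out = []
    for i in df.index[keep]:
        out.append(
            PeptideMeasurement(
                sequence=peptides.at[i],
                intensity=float(intensities.at[i]),
                replicate_id=None if reps is None else reps.at[i],
            )
        )
    return out


class PeptideMapper:
    """Hash index over all L-windows and their single-substitution
    neighbours across a set of proteins."""

    def __init__(self, proteins: Sequence[ProteinRecord], length: int):
        if not proteins:
            raise ValueError("at least one protein required")
        self.length = length
        # seq -> list of (protein_id, offset)
        self._native: dict[str, list[tuple[str, int]]] = {}
        # seq -> list of (protein_id, offset, frame_pos, native_aa, replacing_aa)
        self._variant: dict[str, list[tuple[str, int, int, str, str]]] = {}
        for prot in proteins:
            seq = prot.sequence
            for off0 in range(len(seq) - length + 1):
                window = seq[off0 : off0 + length]
                self._native.setdefault(window, []).append((prot.id, off0 + 1))
        for prot in proteins:
            seq = prot.sequence
            for off0 in range(len(seq) - length + 1):
                window = seq[off0 : off0 + length]
                for j in range(length):
                    native_aa = window[j]
                    prefix, suffix = window[:j], window[j + 1 :]
                    for aa in AMINO_ACIDS:
                        if aa == native_aa:
                            continue
                        neighbour = prefix + aa + suffix
                        if neighbour in self._native:
                            continue  # native assignment takes precedence
                        self._variant.setdefault(neighbour, []).append(
                            (prot.id, off0 + 1, j + 1, native_aa, aa)
                        )

    def map_one(self, measurement: PeptideMeasurement) -> MappedPeptide:
        seq = measurement.sequence
        hits = self._native.get(seq)
        if hits is not None:
            if len(hits) > 1:
                return MappedPeptide(
                    measurement, VariantKind.AMBIGUOUS, candidates=tuple(hits)
                )
            pid, off = hits[0]
            return MappedPeptide(measurement, VariantKind.NATIVE, pid, off)
        vhits = self._variant.get(seq)
        if vhits is not None:
            if len(vhits) > 1:
                return MappedPeptide(
                    measurement, VariantKind.AMBIGUOUS, candidates=tuple(vhits)
                )
            pid, off, frame, native_aa, replacing_aa = vhits[0]
            return MappedPeptide(
                measurement,
                VariantKind.SUBSTITUTION,
                pid,
                off,
                frame_pos=frame,
                replacing_aa=replacing_aa,
                native_aa=native_aa,
            )
        return MappedPeptide(measurement, VariantKind.UNMAPPED)


def map_peptides(
    measurements: Iterable[PeptideMeasurement],
    proteins: Sequence[ProteinRecord],
    length: int = 15,
) -> list[MappedPeptide]:
    """Classify every measurement against every protein window.

    Native assignment takes precedence over substitution assignment; multiple
    possible placements yield ``ambiguous`` and are excluded downstream.
    """
    mapper = PeptideMapper(proteins, length)
    return [mapper.map_one(m) for m in measurements]
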