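"""Synthetic peptide-microarray substitution datasets with known truth.

Emulates the tiled single-substitution array design: L-mer windows of a
random protein at a fixed step, R replicate copies of every native window,
and one copy of each substitution variant (all 19 replacing amino acids per
frame position in ``full`` coverage, or a single alanine variant per
non-alanine position in ``alanine_only`` coverage).

Planted epitopes reduce the expected intensity of variants that replace an
epitope residue with a non-tolerated amino acid by a multiplicative effect
factor; peptides overlapping an epitope carry an additive signal gain so
that epitope-bearing windows bind above baseline.  Multiplicative
log-normal noise (given as a coefficient of variation) is applied last.
The generator records per-row ground truth so that mapping and calling can
be verified exhaustively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import math

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS
from .peptide_map import ProteinRecord


@dataclass(frozen=True)
class PlantedEpitope:
    """Contiguous epitope [start, end] (1-based, inclusive).

    ``tolerated`` maps protein positions to amino acids that retain binding
    when substituted in; unlisted positions tolerate nothing.  ``effect`` is
    the multiplicative intensity factor for non-tolerated substitutions.
    """

    start: int
    end: int
    effect: float = 0.1
    tolerated: Mapping[int, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.effect < 1.0):
            raise ValueError("effect factor must be in [0, 1)")
        if self.end < self.start:
            raise ValueError("end < start")

    @property
    def positions(self) -> range:
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class SimulationConfig:
    protein_length: int = 80
    peptide_length: int = 15
    step: int = 1
    native_copies: int = 5
    substitution_coverage: str = "full"  # or "alanine_only"
    epitopes: tuple[PlantedEpitope, ...] = ()
    baseline_intensity: float = 1000.0
    epitope_gain: float = 4000.0
    noise_cv: float = 0.1
    heteroclitic: tuple[tuple[int, str, float], ...] = ()  # (position, aa, factor)
    seed: int = 0
    protein_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.protein_length < self.peptide_length:
            raise ValueError("protein shorter than peptide length")
        if self.substitution_coverage not in ("full", "alanine_only"):
            raise ValueError(f"unknown coverage {self.substitution_coverage!r}")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.native_copies < 1 or self.step < 1:
            raise ValueError("native_copies and step must be >= 1")
        for ep in self.epitopes:
            if ep.start < 1 or ep.end > self.protein_length:
                raise ValueError("epitope outside protein bounds")
        for pos, aa, factor in self.heteroclitic:
            if factor <= 1.0:
                raise ValueError("heteroclitic factor must be > 1")
            if aa not in AMINO_ACIDS:
                raise ValueError(f"invalid amino acid {aa!r}")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: epitope residues, tolerated sets, per-row labels."""

    protein_id: str
    epitope_positions: frozenset[int]
    tolerated: Mapping[int, frozenset[str]]
    # one entry per table row: (kind, offset, frame_pos or None, replacing_aa or None)
    row_labels: tuple[tuple[str, int, Optional[int], Optional[str]], ...]


@dataclass(frozen=True)
class SyntheticDataset:
    protein: ProteinRecord
    peptides: pd.DataFrame  # columns: peptide, intensity, replicate_id
    truth: GroundTruth


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Build the peptide table for one simulated array experiment.

    Deterministic: identical config (including seed) gives a byte-identical
    table.  Rows appear window by window, native copies first, then
    variants in frame/alphabet order.
    """
    rng = np.random.default_rng(config.seed)
    L = config.peptide_length
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=config.protein_length))
    protein = ProteinRecord(id=config.protein_id, sequence=seq)

    epitope_positions = set()
    tolerated: dict[int, frozenset[str]] = {}
    effect_at: dict[int, float] = {}
    for ep in config.epitopes:
        for pos in ep.positions:
            epitope_positions.add(pos)
            effect_at[pos] = ep.effect
            if pos in ep.tolerated:
                tolerated[pos] = frozenset(ep.tolerated[pos])
    het = {(pos, aa): factor for pos, aa, factor in config.heteroclitic}

    rows_pep: list[str] = []
    rows_expected: list[float] = []
    rows_rep: list[str] = []
    labels: list[tuple[str, int, Optional[int], Optional[str]]] = []

    for off0 in range(0, config.protein_length - L + 1, config.step):
        offset = off0 + 1
        window = seq[off0 : off0 + L]
        overlaps = any(p in epitope_positions for p in range(offset, offset + L))
        base = config.baseline_intensity + (config.epitope_gain if overlaps else 0.0)
        for r in range(config.native_copies):
            rows_pep.append(window)
            rows_expected.append(base)
            rows_rep.append(f"n{offset}_{r + 1}")
            labels.append(("native", offset, None, None))
        for j in range(L):
            native_aa = window[j]
            pos = offset + j
            if config.substitution_coverage == "alanine_only":
                replacements = () if native_aa == "A" else ("A",)
            else:
                replacements = tuple(aa for aa in AMINO_ACIDS if aa != native_aa)
            for aa in replacements:
                expected = base
                if pos in epitope_positions and aa not in tolerated.get(pos, frozenset()):
                    expected *= effect_at[pos]
                if (pos, aa) in het:
                    expected *= het[(pos, aa)]
                rows_pep.append(window[:j] + aa + window[j + 1 :])
                rows_expected.append(expected)
                rows_rep.append(f"s{offset}_{j + 1}{aa}")
                labels.append(("substitution", offset, j + 1, aa))

    expected = np.asarray(rows_expected)
    if config.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + config.noise_cv**2))
        noise = np.exp(sigma * rng.standard_normal(expected.size) - 0.5 * sigma**2)
        intensity = expected * noise
    else:
        intensity = expected

    table = pd.DataFrame(
        {"peptide": rows_pep, "intensity": intensity, "replicate_id": rows_rep}
    )
    truth = GroundTruth(
        protein_id=config.protein_id,
        epitope_positions=frozenset(epitope_positions),
        tolerated=tolerated,
        row_labels=tuple(labels),
    )
    return SyntheticDataset(protein=protein, peptides=table, truth=truth)


def expected_peptide_count(config: SimulationConfig) -> int:
    """Closed-form row count of :func:`generate_dataset` for full coverage."""
    n_windows = (config.protein_length - config.peptide_length) // config.step + 1
    if config.substitution_coverage == "full":
        per_window = config.native_copies + 19 * config.peptide_length
        return n_windows * per_window
    raise ValueError("count formula defined for full coverage only")


def truth_comparison(
    selective_positions: Sequence[int],
    regions: Sequence,
    truth: GroundTruth,
    tolerance: int = 1,
) -> dict:
    """Residue- and region-level confusion summary against the planted truth.

    ``fp_beyond_tolerance`` counts called positions farther than *tolerance*
    residues from any true epitope residue; a region matches when its
    [start, end] interval, expanded by *tolerance*, overlaps a planted
    epitope residue.
    """
    called = set(int(p) for p in selective_positions)
    true_pos = set(truth.epitope_positions)
    tp = called & true_pos
    fp = called - true_pos
    fn = true_pos - called
    fp_beyond = {
        p for p in fp if all(abs(p - t) > tolerance for t in true_pos)
    }
    region_matches = 0
    for region in regions:
        lo, hi = region.start - tolerance, region.end + tolerance
        if any(lo <= t <= hi for t in true_pos):
            region_matches += 1
    sensitivity = len(tp) / len(true_pos) if true_pos else float("nan")
    return {
        "tp": len(tp),
        "fp": len(fp),
        "fn": len(fn),
        "fp_beyond_tolerance": len(fp_beyond),
        "sensitivity": sensitivity,
        "n_regions": len(regions),
        "region_matches": region_matches,
    }


def write_fasta(protein: ProteinRecord, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{protein.id}\n")
        for i in range(0, len(protein.sequence), 60):
            fh.write(protein.sequence[i : i + 60] + "\n")


def write_peptide_table(table: pd.DataFrame, path: str | Path) -> None:
    # full repr precision: intensities must round-trip through text exactly
    table.to_csv(path, sep="\t", index=False)


def write_truth_table(truth: GroundTruth, path: str | Path) -> None:
    rows = []
    for pos in sorted(truth.epitope_positions):
        tol = "".join(sorted(truth.tolerated.get(pos, frozenset())))
        rows.append({"protein_id": truth.protein_id, "position": pos, "tolerated": tol})
    pd.DataFrame(rows, columns=["protein_id", "position", "tolerated"]).to_csv(
        path, sep="\t", index=False
    )
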