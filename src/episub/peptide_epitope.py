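"""Per-native-peptide epitope calling.

For one native peptide, substitution values are arranged as a
position-specific scoring matrix (PSSM; replacing amino acids x frame
positions, native cells absent).  The mean substitution value of each
position is compared against the no-selectivity reference mu_0 = 1 with a
one-tailed Dunnett many-to-one procedure: position i is part of the epitope
when the mean relative signal loss exceeds the least significant difference,

    1 - mu_i > LSD_i,   LSD_i = t_d * SE_i,   SE_i = sqrt(S^2 / n_i),

where S^2 is the variance pooled within columns over the whole PSSM and t_d
is the one-tailed Dunnett quantile at the chosen level with m = L - 1
comparisons and df = (sum_i n_i) - L.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .alphabet import AMINO_ACIDS, AA_INDEX
from .dunnett import cached_quantile
from .substitution_values import NativeGroup, SubstitutionRecord

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """PSSM has too few substitution values for the pooled-variance test
    (e.g. single-substitution / alanine-only designs)."""


@dataclass(frozen=True)
class PSSM:
    """Substitution values for one native peptide.

    ``values`` is a 20 x L array in the fixed amino-acid order of
    :data:`episub.alphabet.AMINO_ACIDS`; absent cells (including all native
    cells) are NaN.
    """

    protein_id: str
    offset: int
    native_sequence: str
    values: np.ndarray

    @property
    def length(self) -> int:
        return len(self.native_sequence)

    @property
    def n_per_column(self) -> np.ndarray:
        return (~np.isnan(self.values)).sum(axis=0)

    @property
    def column_means(self) -> np.ndarray:
        present = ~np.isnan(self.values)
        n = present.sum(axis=0)
        with np.errstate(invalid="ignore"):
            mu = np.where(n > 0, np.nansum(self.values, axis=0) / np.maximum(n, 1), np.nan)
        return mu


@dataclass(frozen=True)
class EpitopeCall:
    """Per-position epitope flags for one native peptide."""

    protein_id: str
    offset: int
    native_sequence: str
    flags: tuple[bool, ...]
    mu: tuple[float, ...]
    lsd: tuple[float, ...]
    alpha: float
    native_median: float


def build_pssm(group: NativeGroup, records: Iterable[SubstitutionRecord]) -> PSSM:
    """Arrange substitution values into the 20 x L matrix.

    Duplicate measurements of the same (amino acid, frame) cell are
    averaged.  A record claiming to replace the native residue with itself
    indicates a mapping bug and raises.
    """
    seq = group.native_sequence
    length = len(seq)
    sums = np.zeros((20, length))
    counts = np.zeros((20, length), dtype=int)
    for rec in records:
        j = rec.frame_pos - 1
        if rec.replacing_aa == seq[j]:
            raise ValueError(
                f"substitution record at {group.protein_id}:{group.offset} frame "
                f"{rec.frame_pos} replaces native {seq[j]} with itself"
            )
        i = AA_INDEX[rec.replacing_aa]
        sums[i, j] += rec.value
        counts[i, j] += 1
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return PSSM(group.protein_id, group.offset, seq, values)


def pooled_variance(pssm: PSSM) -> float:
    """Within-column deviations pooled over all L columns:
    S^2 = sum_ij (x_ij - mu_i)^2 / (sum_i n_i - L)."""
    n = pssm.n_per_column
    total = int(n.sum())
    k = pssm.length
    if total <= k:
        raise InsufficientDataError(
            f"peptide {pssm.protein_id}:{pssm.offset}: {total} substitution values "
            f"for {k} positions; pooled variance undefined"
        )
    mu = pssm.column_means
    dev = pssm.values - mu[None, :]
    ss = float(np.nansum(dev * dev))
    return ss / (total - k)


def call_epitope_positions(pssm: PSSM, alpha: float,
                           native_median: float = float("nan")) -> EpitopeCall:
    """Flag frame positions whose mean signal loss exceeds the LSD.

    One-tailed: only reductions (1 - mu_i > LSD_i) can flag a position;
    heteroclitic increases never do.  Columns with no data are uncallable
    and never flagged.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    length = pssm.length
    if length < 2:
        raise ValueError("peptide length must be >= 2")
    s2 = pooled_variance(pssm)
    n = pssm.n_per_column
    total = int(n.sum())
    m = length - 1
    df = total - length
    t_d = cached_quantile(1.0 - alpha, m, float(df))
    mu = pssm.column_means
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(s2 / np.where(n > 0, n, np.nan))
    lsd = t_d * se
    with np.errstate(invalid="ignore"):
        flags = (1.0 - mu) > lsd
    flags = np.where(n > 0, flags, False)
    return EpitopeCall(
        protein_id=pssm.protein_id,
        offset=pssm.offset,
        native_sequence=pssm.native_sequence,
        flags=tuple(bool(f) for f in flags),
        mu=tuple(float(x) for x in mu),
        lsd=tuple(float(x) for x in lsd),
        alpha=alpha,
        native_median=native_median,
    )


def format_epitope_string(native_sequence: str, flags: Sequence[bool]) -> str:
    """Native letters at flagged positions, dashes elsewhere."""
    if len(flags) != len(native_sequence):
        raise ValueError("flags length must equal peptide length")
    return "".join(c if f else "-" for c, f in zip(native_sequence, flags))


def call_all_peptides(
    groups: dict[tuple[str, int], NativeGroup],
    records: Sequence[SubstitutionRecord],
    alpha: float,
) -> tuple[dict[tuple[str, int], EpitopeCall], int]:
    """Run per-peptide calling over all native groups.

    Returns the calls plus the number of peptides skipped for insufficient
    substitution data (the single-substitution-scan degenerate case, for
    which the sliding per-peptide output is not produced).
    """
    by_parent: dict[tuple[str, int], list[SubstitutionRecord]] = {}
    for rec in records:
        by_parent.setdefault((rec.protein_id, rec.offset), []).append(rec)
    calls: dict[tuple[str, int], EpitopeCall] = {}
    skipped = 0
    for key, group in groups.items():
        recs = by_parent.get(key, [])
        if not recs:
            skipped += 1
            continue
        pssm = build_pssm(group, recs)
        try:
            calls[key] = call_epitope_positions(pssm, alpha, native_median=group.reference)
        except InsufficientDataError:
            skipped += 1
    return calls, skipped
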