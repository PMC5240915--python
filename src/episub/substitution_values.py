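"""Rescale raw spot intensities into substitution values.

A substitution value is the intensity of a single-substitution peptide
divided by the reference intensity of its parent native peptide (the median
across native copies).  1 means no effect, < 1 signal loss, > 1 a
heteroclitic increase.  Native-copy variability is summarised by a bootstrap
standard error of the median, exported for QC only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .peptide_map import MappedPeptide, VariantKind


@dataclass(frozen=True)
class NativeGroup:
    """All measured copies of one native window."""

    protein_id: str
    offset: int
    native_sequence: str
    copy_intensities: tuple[float, ...]
    reference: float
    bootstrap_se: Optional[float] = None

    @property
    def n_copies(self) -> int:
        return len(self.copy_intensities)


@dataclass(frozen=True)
class SubstitutionRecord:
    """One substitution value attached to its parent native group."""

    protein_id: str
    offset: int
    frame_pos: int
    native_aa: str
    replacing_aa: str
    value: float


def native_reference(copy_intensities: Sequence[float]) -> float:
    """Median of the native copies; midpoint of the central pair for even N."""
    if len(copy_intensities) == 0:
        raise ValueError("no native copies")
    return float(np.median(np.asarray(copy_intensities, dtype=float)))


def substitution_value(intensity: float, reference: float, floor: float = 1.0) -> float:
    """intensity / max(reference, floor); guards against near-zero medians."""
    denom = max(reference, floor)
    if denom <= 0:
        raise ValueError("reference and floor are both non-positive")
    return intensity / denom


def bootstrap_native_se(
    copy_intensities: Sequence[float],
    n_reps: int = 10_000,
    seed: int = 0,
) -> Optional[float]:
    """Bootstrap SE of the median of the native copies.

    Resamples N copies with replacement *n_reps* times and returns the
    standard deviation of the resampled medians.  Returns None for N < 2
    (the statistic is undefined from a single copy).
    """
    arr = np.asarray(copy_intensities, dtype=float)
    n = arr.size
    if n < 2:
        return None
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_reps, n))
    medians = np.median(arr[idx], axis=1)
    return float(medians.std(ddof=1))


def group_natives(
    mapped: Iterable[MappedPeptide],
    bootstrap_reps: int = 10_000,
    seed: int = 0,
    min_native_intensity: Optional[float] = None,
) -> dict[tuple[str, int], NativeGroup]:
    """Collect native copies per (protein_id, offset) window.

    Groups whose reference falls below *min_native_intensity* (if set) are
    dropped entirely.  Bootstrap SEs are seeded deterministically per group
    from the run seed and the window offset.
    """
    copies: dict[tuple[str, int], list[float]] = {}
    seqs: dict[tuple[str, int], str] = {}
    for mp in mapped:
        if mp.variant_kind is not VariantKind.NATIVE:
            continue
        key = (mp.protein_id, mp.offset)
        copies.setdefault(key, []).append(mp.measurement.intensity)
        seqs[key] = mp.measurement.sequence
    groups: dict[tuple[str, int], NativeGroup] = {}
    for key in sorted(copies):
        vals = tuple(copies[key])
        ref = native_reference(vals)
        if min_native_intensity is not None and ref < min_native_intensity:
            continue
        se = bootstrap_native_se(vals, n_reps=bootstrap_reps, seed=seed + key[1])
        groups[key] = NativeGroup(
            protein_id=key[0],
            offset=key[1],
            native_sequence=seqs[key],
            copy_intensities=vals,
            reference=ref,
            bootstrap_se=se,
        )
    return groups


def compute_substitution_records(
    mapped: Iterable[MappedPeptide],
    groups: dict[tuple[str, int], NativeGroup],
    floor: float = 1.0,
) -> tuple[list[SubstitutionRecord], int]:
    """Turn mapped substitution peptides into substitution values.

    Returns the records plus the number of substitution peptides dropped
    because their parent native window was never measured (no reference).
    """
    records: list[SubstitutionRecord] = []
    orphans = 0
    for mp in mapped:
        if mp.variant_kind is not VariantKind.SUBSTITUTION:
            continue
        group = groups.get((mp.protein_id, mp.offset))
        if group is None:
            orphans += 1
            continue
        records.append(
            SubstitutionRecord(
                protein_id=mp.protein_id,
                offset=mp.offset,
                frame_pos=mp.frame_pos,
                native_aa=mp.native_aa,
                replacing_aa=mp.replacing_aa,
                value=substitution_value(mp.measurement.intensity, group.reference, floor),
            )
        )
    return records, orphans


def native_ratios(group: NativeGroup, floor: float = 1.0) -> np.ndarray:
    """Per-copy intensity / reference ratios of a native group (around 1)."""
    denom = max(group.reference, floor)
    return np.asarray(group.copy_intensities, dtype=float) / denom
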