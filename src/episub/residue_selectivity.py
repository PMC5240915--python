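"""Residue-level selectivity from overlapping peptides.

All substitution values touching one protein residue are pooled across the
overlapping peptides into a residue substitution matrix (replacing amino
acid x peptide frame).  Each replacing amino acid's mean mu_i is tested
against the global mean mu_g of the matrix with

    t_i = (mu_i - mu_g) / SE_i,

where SE_i comes from the variance pooled within amino-acid columns.  The
p-value is the one-tailed Dunnett tail at |t_i| with m = number of
replacing (non-native) amino acids observed and df = total values - m; the
direction of the effect is carried by sign(t_i).  With a single replacing
amino acid (an alanine scan) the procedure condenses to a two-sample
Student's t-test of the replacing column against the native column.

Selective residues are rendered as signed, rescaled logo scores

    s_i = -sign(t_i) * log10(p_i),  rescaled so  sum_i |s_i| = 1 - mu_g,

and grouped into gap-tolerant epitope regions (>= 4 selective residues,
internal gaps of at most 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .alphabet import AMINO_ACIDS
from .dunnett import DunnettParams, cached_quantile, dunnett_cdf
from .peptide_epitope import EpitopeCall
from .substitution_values import NativeGroup, SubstitutionRecord, native_ratios

P_MIN = 1e-300  # clamp for numerically zero p-values before log10


@dataclass(frozen=True)
class ResidueSubstitutionMatrix:
    """Substitution values of one protein residue pooled over frames.

    ``columns`` maps each amino acid (replacing, plus the native residue)
    to the vector of values observed across included frames; the native
    column holds native replicate ratios, which distribute around 1.
    """

    protein_id: str
    position: int
    native_aa: str
    columns: Mapping[str, np.ndarray]
    included_frames: tuple[int, ...] = ()

    @property
    def n_total(self) -> int:
        return sum(len(v) for v in self.columns.values())

    @property
    def is_empty(self) -> bool:
        return self.n_total == 0


@dataclass(frozen=True)
class SelectivityProfile:
    """Per-amino-acid test results and logo scores for one residue."""

    protein_id: str
    position: int
    native_aa: str
    amino_acids: tuple[str, ...]   # columns with data, fixed alphabet order
    n: tuple[int, ...]
    mu: tuple[float, ...]
    mu_g: float
    t: tuple[float, ...]
    p: tuple[float, ...]
    s: tuple[float, ...]           # rescaled logo scores, same order
    selective: bool
    m: int
    df: float


@dataclass(frozen=True)
class EpitopeRegion:
    """Gap-tolerant run of selective residues (1-based, inclusive)."""

    protein_id: str
    start: int
    end: int
    region_string: str
    n_selective: int


def build_residue_matrix(
    protein_id: str,
    position: int,
    native_aa: str,
    groups: Mapping[tuple[str, int], NativeGroup],
    records_by_parent: Mapping[tuple[str, int], Sequence[SubstitutionRecord]],
    epitope_calls: Optional[Mapping[tuple[str, int], EpitopeCall]],
    length: int,
    inclusion_mode: str = "position",
    floor: float = 1.0,
) -> ResidueSubstitutionMatrix:
    """Pool substitution values for one residue across overlapping peptides.

    A covering peptide contributes its frame j = position - offset + 1 when
    that frame was flagged epitopic in its own peptide-level call
    (``inclusion_mode="position"``) or when any frame of the peptide was
    flagged (``"peptide"``).  When peptide-level calls are unavailable
    (single-substitution designs) every covering peptide is included.  The
    native column receives the peptide's native replicate ratios.
    """
    if inclusion_mode not in ("position", "peptide", "all"):
        raise ValueError(f"unknown inclusion_mode {inclusion_mode!r}")
    cols: dict[str, list[float]] = {}
    frames: list[int] = []
    for offset in range(max(1, position - length + 1), position + 1):
        key = (protein_id, offset)
        group = groups.get(key)
        if group is None:
            continue
        j = position - offset + 1
        if epitope_calls is None or inclusion_mode == "all":
            include = True
        else:
            call = epitope_calls.get(key)
            if call is None:
                include = False  # peptide had no usable call
            elif inclusion_mode == "position":
                include = call.flags[j - 1]
            else:
                include = any(call.flags)
        if not include:
            continue
        frames.append(j)
        for rec in records_by_parent.get(key, ()):
            if rec.frame_pos == j:
                cols.setdefault(rec.replacing_aa, []).append(rec.value)
        for ratio in native_ratios(group, floor):
            cols.setdefault(native_aa, []).append(float(ratio))
    columns = {aa: np.asarray(v, dtype=float) for aa, v in cols.items()}
    return ResidueSubstitutionMatrix(
        protein_id=protein_id,
        position=position,
        native_aa=native_aa,
        columns=columns,
        included_frames=tuple(sorted(frames)),
    )


def _degenerate_profile(matrix: ResidueSubstitutionMatrix) -> SelectivityProfile:
    aas = tuple(aa for aa in AMINO_ACIDS if aa in matrix.columns)
    n = tuple(len(matrix.columns[aa]) for aa in aas)
    mu = tuple(float(matrix.columns[aa].mean()) for aa in aas) if aas else ()
    all_vals = np.concatenate([matrix.columns[aa] for aa in aas]) if aas else np.array([])
    mu_g = float(all_vals.mean()) if all_vals.size else float("nan")
    zeros = tuple(0.0 for _ in aas)
    ones = tuple(1.0 for _ in aas)
    return SelectivityProfile(
        protein_id=matrix.protein_id, position=matrix.position,
        native_aa=matrix.native_aa, amino_acids=aas, n=n, mu=mu, mu_g=mu_g,
        t=zeros, p=ones, s=zeros, selective=False, m=0, df=float("nan"),
    )


def selectivity_stats(matrix: ResidueSubstitutionMatrix, alpha: float) -> SelectivityProfile:
    """Test every amino-acid column of the residue matrix.

    The residue is reported selective when at least one replacing amino
    acid exceeds its column LSD (equivalently |t_i| > t_d at *alpha*).
    Degenerate matrices (no data, no replacing amino acid, zero pooled
    variance, or df < 1) yield p_i = 1 everywhere and a non-selective call.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    aas = tuple(aa for aa in AMINO_ACIDS if aa in matrix.columns)
    if len(aas) < 2:
        return _degenerate_profile(matrix)
    cols = [matrix.columns[aa] for aa in aas]
    n = np.array([len(c) for c in cols])
    mu = np.array([c.mean() for c in cols])
    all_vals = np.concatenate(cols)
    total = all_vals.size
    k_cols = len(aas)
    mu_g = float(all_vals.mean())
    if total <= k_cols:
        return _degenerate_profile(matrix)
    ss = sum(float(((c - c.mean()) ** 2).sum()) for c in cols)
    s2 = ss / (total - k_cols)
    native_idx = aas.index(matrix.native_aa) if matrix.native_aa in aas else None
    m = k_cols - (1 if native_idx is not None else 0)
    if s2 <= 0.0 or m < 1:
        return _degenerate_profile(matrix)

    if m == 1 and native_idx is not None:
        # Alanine-scan degeneracy: the many-to-one procedure condenses to a
        # two-sample Student's t-test of replacing vs native column means.
        sub_idx = next(i for i in range(k_cols) if i != native_idx)
        n0, n1 = n[native_idx], n[sub_idx]
        df = float(total - 2)
        t_two = (mu[sub_idx] - mu[native_idx]) / math.sqrt(s2 * (1.0 / n0 + 1.0 / n1))
        p_two = float(stats.t.sf(abs(t_two), df))
        # direction relative to mu_g carries the logo sign
        signs = np.sign(mu - mu_g)
        t_vec = np.abs(t_two) * signs
        p_vec = np.full(k_cols, p_two)
        selective = p_two < alpha
    else:
        se = np.sqrt(s2 / n)
        t_vec = (mu - mu_g) / se
        df = float(total - m)
        if df < 1:
            return _degenerate_profile(matrix)
        params = DunnettParams(m=m, df=df)
        p_vec = 1.0 - np.asarray(dunnett_cdf(np.abs(t_vec), params))
        t_d = cached_quantile(1.0 - alpha, m, df)
        non_native = np.array([i != native_idx for i in range(k_cols)])
        selective = bool(np.any(non_native & (np.abs(t_vec) > t_d)))

    profile = SelectivityProfile(
        protein_id=matrix.protein_id, position=matrix.position,
        native_aa=matrix.native_aa, amino_acids=aas,
        n=tuple(int(x) for x in n), mu=tuple(float(x) for x in mu), mu_g=mu_g,
        t=tuple(float(x) for x in t_vec), p=tuple(float(x) for x in p_vec),
        s=(), selective=selective, m=m, df=df,
    )
    return replace(profile, s=tuple(float(x) for x in logo_scores(profile)))


def logo_scores(profile: SelectivityProfile, p_min: float = P_MIN) -> np.ndarray:
    """Signed, rescaled logo scores s_i.

    raw_i = -sign(t_i) * log10(p_i); rescaled so that sum_i |s_i| equals the
    mean substitution effect 1 - mu_g.  All-null profiles give all zeros.
    """
    t = np.asarray(profile.t)
    p = np.clip(np.asarray(profile.p), p_min, 1.0)
    raw = -np.sign(t) * np.log10(p)
    denom = np.abs(raw).sum()
    if denom == 0.0:
        return np.zeros_like(raw)
    return raw * (1.0 - profile.mu_g) / denom


def call_epitope_regions(
    protein_id: str,
    sequence: str,
    selective: Sequence[bool],
    min_residues: int = 4,
    max_gap: int = 2,
) -> list[EpitopeRegion]:
    """Group selective residues into regions.

    Successive selective residues separated by at most *max_gap*
    non-selective residues belong to one region; regions with fewer than
    *min_residues* selective residues are discarded.  Region strings print
    native letters at selective positions and dashes in internal gaps.
    """
    if len(selective) != len(sequence):
        raise ValueError("selective vector length must equal protein length")
    positions = [i + 1 for i, f in enumerate(selective) if f]
    regions: list[EpitopeRegion] = []
    if not positions:
        return regions
    run = [positions[0]]
    for pos in positions[1:]:
        if pos - run[-1] - 1 <= max_gap:
            run.append(pos)
        else:
            regions.extend(_finalize_run(protein_id, sequence, run, min_residues))
            run = [pos]
    regions.extend(_finalize_run(protein_id, sequence, run, min_residues))
    return regions


def _finalize_run(protein_id: str, sequence: str, run: list[int],
                  min_residues: int) -> list[EpitopeRegion]:
    if len(run) < min_residues:
        return []
    start, end = run[0], run[-1]
    members = set(run)
    region_string = "".join(
        sequence[pos - 1] if pos in members else "-" for pos in range(start, end + 1)
    )
    return [EpitopeRegion(protein_id, start, end, region_string, len(run))]


def profile_protein(
    protein_id: str,
    sequence: str,
    groups: Mapping[tuple[str, int], NativeGroup],
    records: Sequence[SubstitutionRecord],
    epitope_calls: Optional[Mapping[tuple[str, int], EpitopeCall]],
    length: int,
    alpha: float,
    inclusion_mode: str = "position",
    floor: float = 1.0,
) -> list[SelectivityProfile]:
    """Selectivity profiles for every residue of one protein."""
    by_parent: dict[tuple[str, int], list[SubstitutionRecord]] = {}
    for rec in records:
        if rec.protein_id == protein_id:
            by_parent.setdefault((rec.protein_id, rec.offset), []).append(rec)
    profiles = []
    for pos in range(1, len(sequence) + 1):
        matrix = build_residue_matrix(
            protein_id, pos, sequence[pos - 1], groups, by_parent,
            epitope_calls, length, inclusion_mode, floor,
        )
        profiles.append(selectivity_stats(matrix, alpha))
    return profiles
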