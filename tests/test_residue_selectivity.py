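from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special

from episub.alphabet import AMINO_ACIDS
from episub.residue_selectivity import (
    ResidueSubstitutionMatrix,
    build_residue_matrix,
    call_epitope_regions,
    logo_scores,
    selectivity_stats,
)
from episub.peptide_epitope import EpitopeCall
from episub.substitution_values import NativeGroup, SubstitutionRecord


def matrix_from(native_aa: str, columns: dict[str, list[float]],
                position: int = 5) -> ResidueSubstitutionMatrix:
    return ResidueSubstitutionMatrix(
        protein_id="p",
        position=position,
        native_aa=native_aa,
        columns={aa: np.asarray(v, float) for aa, v in columns.items()},
    )


def brute_force_regions(flags: list[bool], min_residues: int = 4, max_gap: int = 2):
    """Independent enumerator of the region rule: walk flagged positions and
    chain while the next one is within max_gap + 1."""
    positions = [i + 1 for i, f in enumerate(flags) if f]
    chains: list[list[int]] = []
    for pos in positions:
        if chains and pos - chains[-1][-1] <= max_gap + 1:
            chains[-1].append(pos)
        else:
            chains.append([pos])
    return [(c[0], c[-1], len(c)) for c in chains if len(c) >= min_residues]


class TestBuildResidueMatrix:
    def _setup(self, length=5, n_offsets=5, flag_all=True):
        # protein AAAAA...; groups at offsets 1..n_offsets, each covering pos 5
        groups, records, calls = {}, {}, {}
        for off in range(1, n_offsets + 1):
            key = ("p", off)
            seq = "ACDEF"
            groups[key] = NativeGroup("p", off, seq, (90.0, 100.0, 110.0), 100.0)
            j = 5 - off + 1
            recs = [
                SubstitutionRecord("p", off, j, seq[j - 1], aa, 0.3)
                for aa in AMINO_ACIDS
                if aa != seq[j - 1]
            ]
            records[key] = recs
            flags = [False] * length
            if flag_all:
                flags[j - 1] = True
            calls[key] = EpitopeCall("p", off, seq, tuple(flags),
                                     (1.0,) * length, (0.1,) * length, 1e-4, 100.0)
        return groups, records, calls

    def test_full_coverage_rows_and_native_column(self):
        groups, records, calls = self._setup()
        matrix = build_residue_matrix(
            "p", 5, "A", groups, records, calls, length=5, inclusion_mode="position"
        )
        assert matrix.included_frames == (1, 2, 3, 4, 5)
        # native replicate ratios (3 copies x 5 frames) distribute around 1;
        # frames whose letter is not A also contribute their A-substitution (0.3)
        assert sorted(set(np.round(matrix.columns["A"], 12))) == [0.3, 0.9, 1.0, 1.1]
        assert len(matrix.columns["A"]) == 19

    def test_unflagged_residue_gives_empty_matrix(self):
        groups, records, calls = self._setup(flag_all=False)
        matrix = build_residue_matrix(
            "p", 5, "A", groups, records, calls, length=5, inclusion_mode="position"
        )
        assert matrix.is_empty

    def test_no_calls_includes_all_frames(self):
        groups, records, _ = self._setup(flag_all=False)
        matrix = build_residue_matrix(
            "p", 5, "A", groups, records, None, length=5
        )
        assert matrix.included_frames == (1, 2, 3, 4, 5)

    def test_peptide_mode_includes_any_flagged_peptide(self):
        groups, records, calls = self._setup(flag_all=False)
        # flag an unrelated position of the offset-2 peptide only
        key = ("p", 2)
        flags = [True, False, False, False, False]
        calls[key] = EpitopeCall("p", 2, "ACDEF", tuple(flags),
                                 (1.0,) * 5, (0.1,) * 5, 1e-4, 100.0)
        matrix = build_residue_matrix(
            "p", 5, "A", groups, records, calls, length=5, inclusion_mode="peptide"
        )
        assert matrix.included_frames == (4,)

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            build_residue_matrix("p", 1, "A", {}, {}, None, 5, inclusion_mode="bogus")


class TestSelectivityStats:
    def test_all_ones_nonselective(self):
        cols = {aa: [1.0, 1.0, 1.0] for aa in "ACDEFG"}
        profile = selectivity_stats(matrix_from("A", cols), alpha=1e-4)
        assert not profile.selective
        assert all(p == 1.0 for p in profile.p)
        assert all(s == 0.0 for s in profile.s)

    def test_native_retains_binding(self):
        rng = np.random.default_rng(0)
        cols = {"E": list(1.0 + 0.03 * rng.standard_normal(8))}
        for aa in AMINO_ACIDS:
            if aa != "E":
                cols[aa] = list(0.05 + 0.03 * rng.standard_normal(8))
        profile = selectivity_stats(matrix_from("E", cols), alpha=1e-4)
        assert profile.selective
        i = profile.amino_acids.index("E")
        assert profile.t[i] > 0
        assert profile.p[i] < 1e-10
        assert profile.s[i] > 0

    def test_alanine_condenses_to_two_sample_t(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n0, n1 = rng.integers(3, 12, size=2)
            native = rng.normal(1.0, 0.1, n0)
            ala = rng.normal(0.6, 0.1, n1)
            matrix = matrix_from("E", {"E": list(native), "A": list(ala)})
            profile = selectivity_stats(matrix, alpha=0.01)
            # oracle: pooled two-sample t-test via the incomplete beta tail
            s2 = (((native - native.mean()) ** 2).sum()
                  + ((ala - ala.mean()) ** 2).sum()) / (n0 + n1 - 2)
            t = (ala.mean() - native.mean()) / math.sqrt(s2 * (1 / n0 + 1 / n1))
            df = n0 + n1 - 2
            p_one_sided = 0.5 * special.betainc(df / 2, 0.5, df / (df + t * t))
            i = profile.amino_acids.index("A")
            assert profile.p[i] == pytest.approx(p_one_sided, abs=1e-9)

    def test_degenerate_variance(self):
        cols = {"A": [0.5, 0.5], "E": [0.5, 0.5, 0.5]}
        profile = selectivity_stats(matrix_from("E", cols), alpha=0.01)
        assert not profile.selective
        assert all(p == 1.0 for p in profile.p)

    def test_empty_matrix(self):
        profile = selectivity_stats(matrix_from("E", {}), alpha=0.01)
        assert not profile.selective
        assert profile.m == 0

    def test_antisymmetry_under_reflection(self):
        rng = np.random.default_rng(2)
        cols = {aa: list(rng.uniform(0.1, 1.2, 6)) for aa in "ACDEFGHIK"}
        matrix = matrix_from("E", cols)
        profile = selectivity_stats(matrix, alpha=0.01)
        mu_g = profile.mu_g
        reflected = matrix_from(
            "E", {aa: list(2 * mu_g - np.asarray(v)) for aa, v in cols.items()}
        )
        profile_r = selectivity_stats(reflected, alpha=0.01)
        assert profile_r.mu_g == pytest.approx(mu_g, abs=1e-12)
        for t1, t2 in zip(profile.t, profile_r.t):
            assert t2 == pytest.approx(-t1, rel=1e-9, abs=1e-12)
        for s1, s2 in zip(profile.s, profile_r.s):
            assert s2 == pytest.approx(-s1, rel=1e-6, abs=1e-12)


class TestLogoScores:
    def test_normalization(self):
        rng = np.random.default_rng(3)
        cols = {aa: list(rng.uniform(0.1, 1.0, 5)) for aa in "ACDEFGHIKLMNPQ"}
        profile = selectivity_stats(matrix_from("E", cols), alpha=0.01)
        total = sum(abs(s) for s in profile.s)
        assert total == pytest.approx(1.0 - profile.mu_g, abs=1e-12)

    def test_all_null_gives_zeros(self):
        cols = {aa: [1.0, 1.0] for aa in "ACDE"}
        profile = selectivity_stats(matrix_from("A", cols), alpha=0.01)
        assert all(s == 0.0 for s in profile.s)

    def test_two_aa_hand_computed(self):
        # deterministic two-column case checked against a hand-computed
        # two-sample t and Student-t tail
        native = np.array([1.0, 1.1, 0.9, 1.0])
        ala = np.array([0.5, 0.6, 0.4])
        profile = selectivity_stats(
            matrix_from("E", {"E": list(native), "A": list(ala)}), alpha=0.01
        )
        s2 = (((native - 1.0) ** 2).sum() + ((ala - 0.5) ** 2).sum()) / 5
        t = (0.5 - 1.0) / math.sqrt(s2 * (1 / 4 + 1 / 3))
        df = 5
        p = 0.5 * special.betainc(df / 2, 0.5, df / (df + t * t))
        # raw scores: -sign(t_i) * log10(p); A is below mu_g, E above
        mu_g = np.concatenate([native, ala]).mean()
        scale = (1.0 - mu_g) / (2 * abs(math.log10(p)))
        i_a = profile.amino_acids.index("A")
        i_e = profile.amino_acids.index("E")
        assert profile.s[i_a] == pytest.approx(math.log10(p) * scale, rel=1e-9)
        assert profile.s[i_e] == pytest.approx(-math.log10(p) * scale, rel=1e-9)

    def test_planted_profile_sign_recovery(self):
        # one tolerated substitution class: tolerated amino acids score
        # positive, disfavoured ones negative, in >= 95% of seeded runs
        tolerated = {"S", "T"}
        successes = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cols = {"D": list(1.0 + 0.08 * rng.standard_normal(8))}
            for aa in AMINO_ACIDS:
                if aa == "D":
                    continue
                level = 0.9 if aa in tolerated else 0.15
                cols[aa] = list(level + 0.08 * rng.standard_normal(8))
            profile = selectivity_stats(matrix_from("D", cols), alpha=1e-4)
            scores = dict(zip(profile.amino_acids, profile.s))
            ok = all(scores[aa] > 0 for aa in tolerated) and all(
                scores[aa] < 0 for aa in AMINO_ACIDS if aa not in tolerated | {"D"}
            )
            successes += ok
        assert successes >= 19


class TestRegionCaller:
    def _flags(self, positions, length=40):
        flags = [False] * length
        for p in positions:
            flags[p - 1] = True
        return flags

    def test_simple_run(self):
        regions = call_epitope_regions("p", "A" * 40, self._flags({10, 11, 12, 13}))
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (10, 13)
        assert regions[0].region_string == "AAAA"

    def test_gap_of_two_bridged(self):
        flags = self._flags({10, 11, 12, 13, 16, 17, 18, 19})
        regions = call_epitope_regions("p", "A" * 40, flags)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (10, 19)
        assert regions[0].region_string == "AAAA--AAAA"

    def test_gap_of_three_splits(self):
        flags = self._flags({10, 11, 12, 13, 17, 18, 19, 20})
        regions = call_epitope_regions("p", "A" * 40, flags)
        assert [(r.start, r.end) for r in regions] == [(10, 13), (17, 20)]

    def test_short_run_discarded(self):
        assert call_epitope_regions("p", "A" * 40, self._flags({30, 31, 32})) == []

    def test_region_string_uses_native_letters(self):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 2
        flags = self._flags({3, 4, 5, 8}, length=40)
        [region] = call_epitope_regions("p", seq, flags)
        assert region.region_string == "DEF--I"

    @given(st.lists(st.booleans(), min_size=1, max_size=120))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force(self, flags):
        regions = call_epitope_regions("p", "A" * len(flags), flags)
        assert [
            (r.start, r.end, r.n_selective) for r in regions
        ] == brute_force_regions(flags)
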