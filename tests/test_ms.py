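import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sslock.ms import (
    ASPN_D,
    ASPN_DE,
    DISULFIDE_DELTA,
    MONOISOTOPIC_RESIDUE_MASS,
    PROTON,
    TRYPSIN,
    WATER,
    Mutation,
    PeptideFragment,
    ProteaseRule,
    apply_mutations,
    digest,
    disulfide_crosslink_mass,
    enumerate_diagnostic_crosslinks,
    match_observed_peaks,
    mz_for_charge,
    parse_mutations,
    peptide_monoisotopic_mass,
    sequential_digest,
)

peptides = st.text(alphabet=sorted(MONOISOTOPIC_RESIDUE_MASS), min_size=1,
                   max_size=60)


# ---------------------------------------------------------------------------
# independent digestion oracle


def oracle_sites(sequence, rules):
    """Cleavage boundaries recomputed from scratch, per position."""
    sites = set()
    for b in range(1, len(sequence)):
        for rule in rules:
            if rule.cleave_after is not None:
                if (sequence[b - 1] in rule.cleave_after
                        and sequence[b] not in rule.blocked_by_next):
                    sites.add(b)
            else:
                if sequence[b] in rule.cleave_before:
                    sites.add(b)
    return sorted(sites)


def oracle_digest(sequence, rules, max_missed):
    """Brute force: every pair of boundaries whose interior site count is
    within the missed-cleavage budget."""
    bounds = [0] + oracle_sites(sequence, rules) + [len(sequence)]
    frags = set()
    for i, j in itertools.combinations(range(len(bounds)), 2):
        missed = j - i - 1
        if missed <= max_missed:
            frags.add((bounds[i] + 1, bounds[j],
                       sequence[bounds[i]:bounds[j]], missed))
    return frags


def as_set(fragments):
    return {(f.span[0], f.span[1], f.sequence, f.missed_cleavages)
            for f in fragments}


# ---------------------------------------------------------------------------
# masses


class TestPeptideMass:
    @pytest.mark.parametrize("sequence,expected", [
        ("VELCVR", 717.3843),
        ("CLAEVGR", 746.3745),
        ("EVC", 349.1308),
        ("CLA", 305.1409),
        ("G", 75.0320),
    ])
    def test_reference_masses(self, sequence, expected):
        assert peptide_monoisotopic_mass(sequence) == pytest.approx(
            expected, abs=1e-4)

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ValueError):
            peptide_monoisotopic_mass("PEPTIDEX")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            peptide_monoisotopic_mass("")

    def test_fixed_modifications_shift_mass(self):
        base = peptide_monoisotopic_mass("ACDK")
        mod = peptide_monoisotopic_mass("ACDK",
                                        fixed_mods={"C": 57.02146})
        assert mod - base == pytest.approx(57.02146, abs=1e-9)

    @settings(max_examples=100, deadline=None)
    @given(peptides, peptides)
    def test_mass_additivity(self, a, b):
        total = peptide_monoisotopic_mass(a + b)
        assert total == pytest.approx(
            peptide_monoisotopic_mass(a) + peptide_monoisotopic_mass(b)
            - WATER, abs=1e-6)

    @settings(max_examples=50, deadline=None)
    @given(peptides)
    def test_cross_check_against_biopython(self, sequence):
        from Bio.SeqUtils import molecular_weight

        expected = molecular_weight(sequence, seq_type="protein",
                                    monoisotopic=True)
        assert peptide_monoisotopic_mass(sequence) == pytest.approx(
            expected, abs=2e-3)


# ---------------------------------------------------------------------------
# mutations


class TestMutations:
    def test_apply_single(self):
        seq = "A" * 357 + "E" + "A" * 10
        out = apply_mutations(seq, [Mutation("B", 358, "E", "C")])
        assert out[357] == "C"
        assert out[:357] == seq[:357] and out[358:] == seq[358:]
        assert len(out) == len(seq)

    def test_empty_list_is_identity(self):
        assert apply_mutations("PEPTIDE", []) == "PEPTIDE"

    def test_reference_mismatch_names_position(self):
        seq = "A" * 320 + "R" + "A" * 5
        with pytest.raises(ValueError, match="321.*'K'.*'R'"):
            apply_mutations(seq, [Mutation("A", 321, "K", "C")])

    def test_position_out_of_range(self):
        with pytest.raises(ValueError):
            apply_mutations("SHORT", [Mutation("A", 99, "K", "C")])

    def test_parse_mutation_string(self):
        muts = parse_mutations("A:K321C,B:E358C,B:R360C")
        assert {m.position for m in muts["B"]} == {358, 360}
        assert muts["A"][0] == Mutation("A", 321, "K", "C")

    def test_parse_rejects_garbage(self):
        with pytest.raises(ValueError):
            parse_mutations("K321C")  # no chain
        with pytest.raises(ValueError):
            parse_mutations("A:K321")

    def test_mutation_validation(self):
        with pytest.raises(ValueError):
            Mutation("A", 10, "K", "K")
        with pytest.raises(ValueError):
            Mutation("A", 10, "X", "C")


# ---------------------------------------------------------------------------
# digestion


class TestDigest:
    def test_proline_rule(self):
        frags = digest("AKRPGK", TRYPSIN, max_missed=0)
        assert [f.sequence for f in frags] == ["AK", "RPGK"]
        assert [f.span for f in frags] == [(1, 2), (3, 6)]

    def test_no_cleavage_sites_single_peptide(self):
        frags = digest("GGAVLM", TRYPSIN, max_missed=2)
        assert len(frags) == 1
        assert frags[0].sequence == "GGAVLM"
        assert frags[0].span == (1, 6)

    def test_missed_cleavage_enumeration(self):
        frags = digest("AKGKV", TRYPSIN, max_missed=1)
        assert as_set(frags) == {
            (1, 2, "AK", 0), (3, 4, "GK", 0), (5, 5, "V", 0),
            (1, 4, "AKGK", 1), (3, 5, "GKV", 1)}

    def test_fragment_mass_consistency(self):
        for f in digest("MKTAYIAKQRQISFVK", TRYPSIN, max_missed=2):
            assert f.mass == pytest.approx(
                peptide_monoisotopic_mass(f.sequence), abs=1e-9)
            assert f.span[1] - f.span[0] + 1 == len(f.sequence)

    def test_aspn_cleaves_before_d(self):
        frags = digest("GADGD", ASPN_D, max_missed=0)
        assert [f.sequence for f in frags] == ["GA", "DG", "D"]

    @settings(max_examples=150, deadline=None)
    @given(peptides, st.integers(0, 2))
    def test_matches_brute_force(self, sequence, max_missed):
        got = digest(sequence, TRYPSIN, max_missed=max_missed)
        assert as_set(got) == oracle_digest(sequence, [TRYPSIN], max_missed)

    @settings(max_examples=100, deadline=None)
    @given(peptides)
    def test_zero_missed_fragments_tile_the_sequence(self, sequence):
        frags = [f for f in digest(sequence, TRYPSIN, max_missed=2)
                 if f.missed_cleavages == 0]
        frags.sort(key=lambda f: f.span)
        assert "".join(f.sequence for f in frags) == sequence
        # spans are contiguous
        pos = 1
        for f in frags:
            assert f.span[0] == pos
            pos = f.span[1] + 1

    @settings(max_examples=100, deadline=None)
    @given(peptides, st.integers(0, 3))
    def test_fragment_count_formula(self, sequence, k):
        n_sites = len(oracle_sites(sequence, [TRYPSIN]))
        expected = sum(n_sites + 1 - m for m in range(min(k, n_sites) + 1))
        assert len(digest(sequence, TRYPSIN, max_missed=k)) == expected

    def test_rule_validation(self):
        with pytest.raises(ValueError):
            ProteaseRule("bad", cleave_after=frozenset("K"),
                         cleave_before=frozenset("D"))
        with pytest.raises(ValueError):
            ProteaseRule("bad", None, None)
        with pytest.raises(ValueError):
            digest("PEPTIDE", TRYPSIN, max_missed=-1)


class TestSequentialDigest:
    def test_trypsin_plus_aspn_toy(self):
        frags = sequential_digest("EVCDCLA", [TRYPSIN, ASPN_D], max_missed=0)
        assert [f.sequence for f in frags] == ["EVC", "DCLA"]

    def test_single_rule_reduces_to_digest(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        assert as_set(sequential_digest(seq, [TRYPSIN], 2)) == as_set(
            digest(seq, TRYPSIN, 2))

    @settings(max_examples=150, deadline=None)
    @given(peptides, st.integers(0, 2))
    def test_matches_merged_site_oracle(self, sequence, max_missed):
        got = sequential_digest(sequence, [TRYPSIN, ASPN_DE], max_missed)
        assert as_set(got) == oracle_digest(sequence, [TRYPSIN, ASPN_DE],
                                            max_missed)

    def test_cysteine_mutation_removes_cleavage_site(self):
        """Mutating an R cleavage site to C removes exactly that site."""
        wild = "AVKGGRGGDLK"
        mutant = apply_mutations(wild, [Mutation("B", 6, "R", "C")])
        wt_sites = oracle_sites(wild, [TRYPSIN])
        mut_sites = oracle_sites(mutant, [TRYPSIN])
        assert set(wt_sites) - set(mut_sites) == {6}
        assert set(mut_sites) <= set(wt_sites)


# ---------------------------------------------------------------------------
# crosslink masses and m/z


class TestCrosslinkMass:
    def test_velcvr_claevgr(self):
        assert disulfide_crosslink_mass("VELCVR", "CLAEVGR") == pytest.approx(
            1461.7432, abs=1e-4)

    def test_evc_cla(self):
        assert disulfide_crosslink_mass("EVC", "CLA") == pytest.approx(
            652.2560, abs=1e-4)

    def test_cys_free_peptide_rejected(self):
        with pytest.raises(ValueError):
            disulfide_crosslink_mass("VELAVR", "CLAEVGR")
        with pytest.raises(ValueError):
            disulfide_crosslink_mass("VELCVR", "GLAEVGR")

    @settings(max_examples=100, deadline=None)
    @given(peptides, peptides)
    def test_conservation_delta(self, a, b):
        a, b = a + "C", b + "C"
        ma = peptide_monoisotopic_mass(a)
        mb = peptide_monoisotopic_mass(b)
        assert disulfide_crosslink_mass(a, b) == pytest.approx(
            ma + mb - 2.01565, abs=1e-6)
        assert DISULFIDE_DELTA == pytest.approx(-2.01565, abs=1e-7)


class TestMzForCharge:
    def test_singly_protonated_closed_form(self):
        for mass in (100.0, 652.2560292, 5000.123):
            assert mz_for_charge(mass, 1) == mass + PROTON

    def test_evc_cla_z1(self):
        mz = mz_for_charge(disulfide_crosslink_mass("EVC", "CLA"), 1)
        assert mz == pytest.approx(653.2633, abs=1e-4)

    def test_velcvr_claevgr_z3(self):
        mz = mz_for_charge(
            disulfide_crosslink_mass("VELCVR", "CLAEVGR"), 3)
        assert mz == pytest.approx(488.2550, abs=1e-4)

    def test_invalid_charge(self):
        with pytest.raises(ValueError):
            mz_for_charge(1000.0, 0)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(50, 1e5), st.integers(1, 8))
    def test_mass_recovery_and_monotonicity(self, mass, z):
        mz = mz_for_charge(mass, z)
        assert mz * z - z * PROTON == pytest.approx(mass, abs=1e-6)
        if z > 1:
            assert mz < mz_for_charge(mass, z - 1)


# ---------------------------------------------------------------------------
# diagnostic enumeration and peak matching


class TestEnumerateDiagnosticCrosslinks:
    def build(self, wt_a, wt_b, pos_a, pos_b, rules, missed=1):
        mut_a = apply_mutations(wt_a, [Mutation("A", pos_a, wt_a[pos_a - 1], "C")])
        mut_b = apply_mutations(wt_b, [Mutation("B", pos_b, wt_b[pos_b - 1], "C")])
        return enumerate_diagnostic_crosslinks(
            sequential_digest(mut_a, rules, missed),
            sequential_digest(mut_b, rules, missed),
            [pos_a], [pos_b],
            charges=(1, 2, 3),
            wildtype_digest_a=sequential_digest(wt_a, rules, missed),
            wildtype_digest_b=sequential_digest(wt_b, rules, missed))

    def test_hand_enumerable_pair_set(self):
        # trypsin, 0 missed: mutants digest to AC|K + GGK|VCK
        species = enumerate_diagnostic_crosslinks(
            digest("ACK", TRYPSIN, 0), digest("GGKVCK", TRYPSIN, 0),
            [2], [5], charges=(1, 2),
            wildtype_digest_a=digest("AEK", TRYPSIN, 0),
            wildtype_digest_b=digest("GGKVGK", TRYPSIN, 0))
        assert [(s.peptide_a.sequence, s.peptide_b.sequence)
                for s in species] == [("ACK", "VCK")]
        sp = species[0]
        assert sp.diagnostic
        assert sp.neutral_mass == pytest.approx(
            disulfide_crosslink_mass("ACK", "VCK"), abs=1e-9)
        mzs = dict(sp.mz_by_charge)
        assert set(mzs) == {1, 2} and mzs[1] > mzs[2]

    def test_no_covering_peptide_gives_empty(self):
        species = enumerate_diagnostic_crosslinks(
            digest("ACK", TRYPSIN, 0), digest("GGK", TRYPSIN, 0),
            [2], [99], charges=(1,))
        assert species == []

    def test_wildtype_shared_peptide_not_diagnostic(self):
        # peptide CAK exists in both wild type and mutant digests of chain A
        species = enumerate_diagnostic_crosslinks(
            digest("CAK", TRYPSIN, 0), digest("VCK", TRYPSIN, 0),
            [1], [2], charges=(1,),
            wildtype_digest_a=digest("CAK", TRYPSIN, 0),
            wildtype_digest_b=digest("VGK", TRYPSIN, 0))
        assert len(species) == 1 and not species[0].diagnostic

    def test_sorted_by_neutral_mass(self):
        species = self.build("AAKSGGKWWWK", "GGSK", 4, 3,
                             [TRYPSIN], missed=2)
        masses = [s.neutral_mass for s in species]
        assert masses == sorted(masses)


class TestMatchObservedPeaks:
    def species(self):
        return enumerate_diagnostic_crosslinks(
            digest("ACK", TRYPSIN, 0), digest("VCK", TRYPSIN, 0),
            [2], [2], charges=(1, 2, 3))

    def test_exact_peak_matches_within_1ppm(self):
        sp = self.species()[0]
        mz1 = sp.mz(1)
        matches = match_observed_peaks([sp], [(mz1, 1)])
        assert len(matches) == 1
        assert abs(matches[0].ppm_error) <= 1.0

    def test_peak_50ppm_away_does_not_match(self):
        sp = self.species()[0]
        off = sp.mz(1) * (1 + 50e-6)
        assert match_observed_peaks([sp], [(off, 1)]) == []

    def test_wrong_charge_does_not_match(self):
        sp = self.species()[0]
        assert match_observed_peaks([sp], [(sp.mz(1), 2)]) == []

    def test_widening_tolerance_is_monotone(self):
        sp = self.species()[0]
        peaks = [(sp.mz(1) * (1 + d * 1e-6), 1) for d in (0, 5, 25, 60)]
        narrow = {m.mz_observed
                  for m in match_observed_peaks([sp], peaks, tol_ppm=10)}
        wide = {m.mz_observed
                for m in match_observed_peaks([sp], peaks, tol_ppm=100)}
        assert narrow <= wide

    def test_tolerance_validation(self):
        with pytest.raises(ValueError):
            match_observed_peaks([], [], tol_ppm=0)
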