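"""Gapless alignment, proteome scoring, and permutation p-values."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import immunosig as ims
from immunosig.array_io import ProteinRecord
from immunosig.epitope_mapping import SubstitutionMatrix

IDENTITY = SubstitutionMatrix.identity()
BLOSUM62 = SubstitutionMatrix.blosum62()
AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_best_placement(peptide, protein, matrix):
    """Exhaustive offset enumeration oracle."""
    best = None
    for offset in range(len(protein) - len(peptide) + 1):
        score = sum(
            matrix.score(a, b)
            for a, b in zip(peptide, protein[offset:offset + len(peptide)])
        )
        if best is None or score > best[0]:
            best = (score, offset)
    return best


class TestSubstitutionMatrix:
    def test_blosum62_is_symmetric_with_dominant_diagonal(self):
        m = BLOSUM62
        aa_idx = [m.alphabet.index(c) for c in AA]
        sub = m.scores[np.ix_(aa_idx, aa_idx)]
        assert np.allclose(sub, sub.T)
        assert (np.diag(sub) >= sub.max(axis=1) - 1e-9).all()

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError, match="alphabet"):
            IDENTITY.encode("AJC")


class TestGaplessLocalAlign:
    def test_identity_self_alignment(self):
        p = ims.gapless_local_align("ACD", "ACD", IDENTITY)
        assert (p.offset, p.score) == (0, 3.0)
        assert p.per_position == (1.0, 1.0, 1.0)

    def test_blosum62_embedded_match(self):
        p = ims.gapless_local_align("ACD", "XACDY", BLOSUM62)
        expected = sum(BLOSUM62.score(c, c) for c in "ACD")
        assert p.offset == 1
        assert p.score == pytest.approx(expected)

    def test_ties_break_to_the_smallest_offset(self):
        p = ims.gapless_local_align("AA", "AAAA", IDENTITY)
        assert p.offset == 0

    def test_protein_shorter_than_peptide_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            ims.gapless_local_align("ACDEF", "ACD", IDENTITY)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        data=st.data(),
        pep_len=st.integers(1, 20),
        prot_len=st.integers(20, 50),
        use_blosum=st.booleans(),
    )
    def test_matches_exhaustive_enumeration(self, data, pep_len, prot_len, use_blosum):
        peptide = data.draw(st.text(AA, min_size=pep_len, max_size=pep_len))
        protein = data.draw(st.text(AA, min_size=prot_len, max_size=prot_len))
        matrix = BLOSUM62 if use_blosum else IDENTITY
        placement = ims.gapless_local_align(peptide, protein, matrix)
        score, offset = brute_force_best_placement(peptide, protein, matrix)
        assert placement.score == pytest.approx(score)
        assert placement.offset == offset
        assert sum(placement.per_position) == pytest.approx(score)


class TestScoreProteome:
    def test_single_peptide_summary_is_its_best_placement(self):
        prot = [ProteinRecord("p", "", "WWWWACDWWWW")]
        scores = ims.score_proteome([("x", "ACD")], prot, IDENTITY, trim_linker=None)
        assert scores[0].summary == 3.0
        assert scores[0].rank == 1

    def test_overlapping_placements_sum_and_disjoint_take_the_larger(self):
        protein = ProteinRecord("p", "", "ACDEF" + "W" * 5 + "KLMNP" + "W" * 15)
        overlap = ims.score_proteome(
            [("x", "ACDEF"), ("y", "CDEFW")], [protein], IDENTITY, trim_linker=None
        )[0]
        # x places at 0 (score 5), y at 1 (score 5); positions 1-4 carry both
        assert overlap.summary == 10.0
        disjoint = ims.score_proteome(
            [("x", "ACDEF"), ("y", "KLMNP")], [protein], IDENTITY, trim_linker=None
        )[0]
        assert disjoint.summary == 5.0

    def test_profile_conserves_deposited_mass(self, rng):
        peptides = [
            (f"x{i}", "".join(rng.choice(list(AA), size=rng.integers(5, 12))))
            for i in range(8)
        ]
        proteome = ims.generate_proteome(n_proteins=5, length_range=(40, 80), seed=3)
        for ps in ims.score_proteome(peptides, proteome, BLOSUM62, trim_linker=None):
            total = 0.0
            for pid, seq in peptides:
                placement = ims.gapless_local_align(
                    seq, next(p.sequence for p in proteome
                              if p.protein_id == ps.protein_id), BLOSUM62
                )
                total += placement.score * len(seq)
            assert ps.profile.sum() == pytest.approx(total)

    def test_peptide_order_does_not_change_the_ranking(self, rng):
        peptides = [(f"x{i}", "".join(rng.choice(list(AA), size=8))) for i in range(6)]
        proteome = ims.generate_proteome(n_proteins=8, length_range=(40, 60), seed=5)
        fwd = ims.score_proteome(peptides, proteome, BLOSUM62, trim_linker=None)
        rev = ims.score_proteome(peptides[::-1], proteome, BLOSUM62, trim_linker=None)
        assert [(p.protein_id, p.rank) for p in fwd] == [
            (p.protein_id, p.rank) for p in rev
        ]

    def test_linker_is_trimmed_before_alignment(self):
        prot = [ProteinRecord("p", "", "WWACDWW")]
        scored = ims.score_proteome([("x", "ACDGSC")], prot, IDENTITY,
                                    trim_linker="GSC")
        assert scored[0].summary == 3.0  # GSC tail did not have to fit

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError, match="empty proteome"):
            ims.score_proteome([("x", "ACD")], [], IDENTITY)


def _pset_from(items):
    members = pd.DataFrame(
        {"sequence": [s for _, s in items]},
        index=pd.Index([i for i, _ in items], name="peptide_id"),
    )
    return ims.PeptideSet("test", members, {})


class TestEmpiricalPvalues:
    def test_unreachable_observed_score_gives_the_add_one_minimum(self):
        # the test peptides match the protein perfectly; the library offers
        # only weak matchers, so no null draw can reach the observed summary
        protein = [ProteinRecord("p", "", "ACDEFGHIKLMNPQRSTVWY")]
        test = _pset_from([("t1", "ACDEF"), ("t2", "GHIKL")])
        library = ims.PeptideLibrary.from_records(
            [(f"w{i}", "WWWWW", 1, 1, i + 1) for i in range(4)]
        )
        scored = ims.empirical_pvalues(test, library, protein, IDENTITY,
                                       n_perm=19, seed=0, trim_linker=None)
        assert scored[0].p_value == pytest.approx(1 / 20)

    def test_pvalues_match_brute_force_recomputation_of_the_same_draws(self):
        rng_lib = np.random.default_rng(12)
        library = ims.PeptideLibrary.from_records(
            [
                (f"l{i}", "".join(rng_lib.choice(list(AA), size=6)), 1, 1, i + 1)
                for i in range(8)
            ]
        )
        proteome = ims.generate_proteome(n_proteins=4, length_range=(30, 40), seed=12)
        test = _pset_from([("t1", "ACDEFG"), ("t2", "IKLMNP")])
        n_perm, seed = 12, 7
        scored = ims.empirical_pvalues(test, library, proteome, IDENTITY,
                                       n_perm=n_perm, seed=seed, trim_linker=None)

        # oracle: replay the identical draw sequence and recompute every
        # summary with the single-pair alignment routine
        def summaries(items):
            out = []
            for prot in proteome:
                profile = np.zeros(len(prot))
                for pid, seq in items:
                    pl = ims.gapless_local_align(seq, prot.sequence, IDENTITY)
                    profile[pl.offset:pl.offset + len(seq)] += pl.score
                out.append(profile.max())
            return np.array(out)

        obs = summaries([("t1", "ACDEFG"), ("t2", "IKLMNP")])
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(404,)))
        lib_items = list(library.sequences.items())
        exceed = np.zeros(len(proteome))
        for _ in range(n_perm):
            rows = rng.choice(len(lib_items), size=2, replace=False)
            exceed += summaries([lib_items[int(i)] for i in rows]) >= obs
        expected_p = (1 + exceed) / (n_perm + 1)
        by_id = {p.protein_id: p.p_value for p in scored}
        for prot, e in zip(proteome, expected_p):
            assert by_id[prot.protein_id] == pytest.approx(e)

    def test_null_test_set_is_roughly_calibrated(self):
        library = ims.generate_library(n=200, seed=31)
        proteome = ims.generate_proteome(n_proteins=30, length_range=(60, 120), seed=31)
        rng = np.random.default_rng(31)
        chosen = rng.choice(library.ids.to_numpy(), size=10, replace=False)
        test = _pset_from([(pid, library.sequences[pid]) for pid in chosen])
        scored = ims.empirical_pvalues(test, library, proteome, BLOSUM62,
                                       n_perm=99, seed=5)
        ps = np.array([p.p_value for p in scored])
        assert 0.25 <= np.median(ps) <= 0.75
        assert (ps > 0).all() and (ps <= 1).all()

    def test_zero_permutations_rejected(self, tiny_library):
        test = _pset_from([("t1", "ACD")])
        with pytest.raises(ValueError, match="n_perm"):
            ims.empirical_pvalues(test, tiny_library,
                                  [ProteinRecord("p", "", "ACDEF")], IDENTITY,
                                  n_perm=0, seed=0)
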