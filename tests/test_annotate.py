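import math
import random

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from rfpep.annotate import (Criteria, annotate_sequence, assign_variable_region,
                            database_residue_count, e_value,
                            match_constant_region, smith_waterman)
from rfpep.digest import digest

from .oracles import sw_score_oracle

B62 = substitution_matrices.load("BLOSUM62")
AA = "ACDEFGHIKLMNPQRSTVWY"


class TestSmithWaterman:
    def test_self_alignment_scores_diagonal_sum(self):
        pep = "QVQLVESGGGLVK"
        expected = sum(B62[a, a] for a in pep)
        res = smith_waterman(pep, pep)
        assert res.score == expected
        assert res.n_gaps == 0
        assert res.peptide_span == (0, len(pep))

    def test_no_homology_gives_empty_alignment(self):
        res = smith_waterman("WWW", "PPP")
        assert res.score == 0.0
        assert res.aligned_pairs == ()

    def test_equals_dp_oracle_on_random_pairs(self):
        rng = random.Random(42)
        for _ in range(60):
            pep = "".join(rng.choices(AA, k=8))
            germ = "".join(rng.choices(AA, k=120))
            assert smith_waterman(pep, germ).score == sw_score_oracle(pep, germ)

    def test_rejects_invalid_input(self):
        with pytest.raises(ValueError):
            smith_waterman("", "ACD")
        with pytest.raises(ValueError):
            smith_waterman("ACO", "ACD")


class TestEValue:
    def test_closed_form_arithmetic(self):
        expected = 0.041 * 12 * 3000 * math.exp(-0.267 * 35)
        assert e_value(35, 12, 3000) == pytest.approx(expected, rel=1e-12)

    def test_monotone_decreasing_in_score(self):
        scores = [10, 20, 40, 80, 200]
        evs = [e_value(s, 10, 2000) for s in scores]
        assert all(a > b for a, b in zip(evs, evs[1:]))
        assert evs[-1] < 1e-15

    def test_linear_in_database_size(self):
        assert e_value(30, 10, 4000) == pytest.approx(
            2 * e_value(30, 10, 2000), rel=1e-12)

    def test_invalid_lengths(self):
        with pytest.raises(ValueError):
            e_value(30, 0, 1000)


class TestConstantRegion:
    def test_unique_peptide_assigned_to_its_isotype(self, constants):
        igg2 = next(g for g in constants if g.name == "P01859")
        others = [g for g in constants if g.name != "P01859"]
        pep = next(p for p in sorted(digest(igg2.sequence, 0, min_length=6))
                   if all(p not in o.sequence for o in others))
        hit = match_constant_region(pep, constants)
        assert hit.category == "constant"
        assert hit.isotype_group == "IgG2"
        assert hit.unique_to_isotype

    def test_igg_shared_block_peptide_is_not_unique(self, constants):
        seqs = {g.name: g.sequence for g in constants}
        # the four IgG subclasses share a 60-residue block
        shared = next(p for p in sorted(digest(seqs["P01857"], 0, min_length=6))
                      if p in seqs["P01859"])
        hit = match_constant_region(shared, constants)
        assert hit.category == "constant"
        assert not hit.unique_to_isotype
        assert hit.isotype_group is None
        assert len(hit.matched_isotypes) > 1

    def test_duplicate_accession_pair_counts_as_one_group(self, constants):
        seqs = {g.name: g.sequence for g in constants}
        pep = next(p for p in sorted(digest(seqs["P01857"], 0, min_length=6))
                   if p in seqs["P0DOX5"]
                   and all(p not in s for n, s in seqs.items()
                           if n not in ("P01857", "P0DOX5")))
        hit = match_constant_region(pep, constants)
        assert hit.unique_to_isotype
        assert hit.isotype_group == "IgG1"
        assert set(hit.matched_accessions) == {"P01857", "P0DOX5"}

    def test_il_equivalence_is_optional(self, constants):
        igm = next(g for g in constants if g.name == "P01871")
        others = [g for g in constants if g.name not in ("P01871", "P0DOX6")]
        pep = next(p for p in sorted(digest(igm.sequence, 0, min_length=6))
                   if "I" in p and all(p not in o.sequence for o in others))
        flipped = pep.replace("I", "L")
        assert match_constant_region(flipped, constants).category == "non_ig"
        hit = match_constant_region(flipped, constants, il_equivalent=True)
        assert hit.category == "constant"


class TestVariableRegion:
    def test_framework_peptides_accepted_as_variable(self, germlines):
        for pep, segment in [("QVQLVESGGGLVK", "FR1"), ("PGQAPRLL", "FR2"),
                             ("SLSPGERATL", "FR1")]:
            a = assign_variable_region(pep, germlines)
            assert a.category == "variable"
            assert a.e_value <= 1.0 and a.sw_score > 30.0
            assert a.region_label == "FR"
            assert a.segments == (segment,)

    def test_fewer_than_three_cdr_residues_stays_fr(self, germlines):
        # FR2 tail of an IGKV3 gene plus the first two CDR2 residues
        a = assign_variable_region("PGQAPRLLIYGA", germlines)
        assert a.category == "variable"
        assert a.n_cdr_residues == 2
        assert a.region_label == "FR"

    def test_three_cdr_residues_label_cdr(self, germlines):
        a = assign_variable_region("PGQAPRLLIYGAS", germlines)
        assert a.n_cdr_residues == 3
        assert a.region_label == "FR+CDR"
        assert any(s.startswith("CDR") for s in a.segments)

    def test_low_scoring_peptide_is_non_ig(self, germlines):
        a = assign_variable_region("WPWNPHMW", germlines)
        assert a.category == "non_ig"
        assert a.sw_score is None or a.sw_score <= 30 or a.e_value > 1

    def test_invariant_to_germline_order(self, germlines):
        rng = random.Random(5)
        shuffled = list(germlines)
        rng.shuffle(shuffled)
        a1 = assign_variable_region("SLSPGERATL", germlines)
        a2 = assign_variable_region("SLSPGERATL", shuffled,
                                    db_residues=database_residue_count(germlines))
        assert (a1.germline_gene, a1.sw_score, a1.segments) == \
            (a2.germline_gene, a2.sw_score, a2.segments)


class TestPrecedence:
    def test_constant_match_preempts_variable_scoring(self, germlines, constants):
        pep = next(iter(sorted(digest(constants[0].sequence, 0, min_length=8))))
        a = annotate_sequence(pep, germlines)
        assert a.category == "constant"
        assert a.sw_score is None

    def test_every_sequence_gets_exactly_one_category(self, germlines):
        rng = np.random.default_rng(1)
        for _ in range(20):
            pep = "".join(rng.choice(list(AA), size=9))
            a = annotate_sequence(pep, germlines)
            assert a.category in ("constant", "variable", "non_ig")
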