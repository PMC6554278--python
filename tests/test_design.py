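"""H-method / C-method / deoptimization vs a fold-everything oracle."""

import itertools

import numpy as np
import pytest

import codonopt.design as design_mod
from codonopt.codon_data import GeneticCode
from codonopt.design import (
    CapacityError,
    InfeasibleDesignError,
    VariantRecord,
    c_method,
    count_head_variants,
    deoptimize,
    enumerate_head_variants,
    h_method,
)
from codonopt.folding import HeadRegionSpec, dG_UH
from codonopt.seq_features import CodingSequence, cai_head, translate
from conftest import oracle_design, random_sense_cds


def protein_cds(protein: str, code=None, tail_codons=8) -> CodingSequence:
    """Deterministic CDS for a protein (lexicographically first codons) with
    a fixed GC-rich tail to give the folding window something to pair."""
    code = code or GeneticCode.standard()
    nt = "".join(sorted(code.families[aa])[0] for aa in protein)
    return CodingSequence(id=protein, nt=nt + "GGCGCC" * tail_codons, require_start=True)


class TestCountVariants:
    def test_two_singletons(self):
        seq = CodingSequence("mw", "ATGTGG")
        assert count_head_variants(seq, 11) == 1

    def test_eleven_residue_head(self):
        # M K L L I N S T Q A F -> 1*2*6*6*3*2*6*4*2*4*2
        seq = protein_cds("MKLLINSTQAF", tail_codons=0)
        assert count_head_variants(seq, 11) == 165_888

    def test_truncated_to_sequence(self):
        seq = CodingSequence("mk", "ATGAAA")
        assert count_head_variants(seq, 11) == 2


class TestEnumerate:
    def test_all_singleton_head_is_wild_type(self):
        seq = CodingSequence("mw", "ATGTGGGCC")
        variants = list(enumerate_head_variants(seq, head_codons=2))
        assert len(variants) == 1
        assert variants[0].full_cds == seq.nt

    def test_mkf_head_exhaustive(self):
        seq = CodingSequence("mkf", "ATGAAATTT")
        variants = list(enumerate_head_variants(seq, head_codons=3))
        assert len(variants) == 4
        assert len({v.head_nt for v in variants}) == 4
        for v in variants:
            assert translate(CodingSequence("v", v.full_cds)) == "MKF"
        # deterministic lexicographic emission
        assert [v.head_nt for v in variants] == sorted(v.head_nt for v in variants)

    def test_forbid_filters_positions(self):
        seq = CodingSequence("mkf", "ATGAAATTT")
        variants = list(enumerate_head_variants(seq, head_codons=3, forbid={"AAA"}))
        assert len(variants) == 2
        assert all("AAA" not in v.head_nt[:6] for v in variants)

    def test_capacity_error_reports_count(self):
        seq = protein_cds("MKLLINSTQAF", tail_codons=0)
        with pytest.raises(CapacityError, match="165888"):
            list(enumerate_head_variants(seq, head_codons=11, allow_sampling=False, cap=10))


class TestOracleEquivalence:
    def test_methods_match_fold_everything_reference(
        self, backend, short_spec, gc_cai, gc_rare
    ):
        rng = np.random.default_rng(101)
        cache: dict = {}
        for i in range(20):
            seq = random_sense_cds(rng, 12, f"g{i}")
            h = h_method(seq, short_spec, backend, k=3, cache=cache)
            l = deoptimize(seq, short_spec, backend, k=3, cache=cache)
            oh = oracle_design(seq, short_spec, backend, "H", 3)
            ol = oracle_design(seq, short_spec, backend, "L", 3)
            assert [v.head_nt for v in h.ranked] == [t[1] for t in oh]
            assert [v.head_nt for v in l.ranked] == [t[1] for t in ol]
            assert [v.dG_UH for v in h.ranked] == pytest.approx([t[0] for t in oh])
            try:
                c = c_method(seq, short_spec, backend, gc_cai, gc_rare, 0.75, k=1, cache=cache)
                oc = oracle_design(
                    seq, short_spec, backend, "C", 1, gc_cai, gc_rare, 0.75
                )
                assert c.ranked[0].head_nt == oc[0][1]
            except InfeasibleDesignError:
                pytest.fail("C-method must be feasible: the all-optimal head qualifies")

    def test_sandwich_property(self, backend, short_spec):
        rng = np.random.default_rng(103)
        cache: dict = {}
        for i in range(10):
            seq = random_sense_cds(rng, 10, f"s{i}")
            wt = dG_UH(seq, short_spec, backend)
            hi = h_method(seq, short_spec, backend, k=1, cache=cache).ranked[0].dG_UH
            lo = deoptimize(seq, short_spec, backend, k=1, cache=cache).ranked[0].dG_UH
            assert lo - 1e-9 <= wt <= hi + 1e-9


class TestHMethod:
    def test_single_variant_truncates_k(self, backend, short_spec):
        seq = CodingSequence("mw", "ATGTGGATGTGG")
        with pytest.warns(UserWarning, match="only 1"):
            res = h_method(seq, short_spec, backend, k=3)
        assert len(res.ranked) == 1
        assert res.ranked[0].full_cds == seq.nt
        assert res.search_mode == "exhaustive"
        assert res.n_variants_considered == 1

    def test_result_metadata(self, backend, short_spec):
        seq = CodingSequence("m", "ATGAAATTTGCA")
        res = h_method(seq, short_spec, backend, k=2)
        assert res.method == "H"
        assert res.labels() == ("H1", "H2")
        assert res.n_variants_considered == count_head_variants(seq, 4)

    def test_lexicographic_tie_break(self, backend):
        # A/G-only regions without C or U admit no canonical pairs: every
        # variant folds to exactly 0, so ranking must fall back to head order
        spec = HeadRegionSpec(utr="AAAAA", head_nt=6, utr_take=0)
        seq = CodingSequence("kk", "AAAAAA", require_start=False)
        res = h_method(seq, spec, backend, k=2)
        assert [v.dG_UH for v in res.ranked] == [0.0, 0.0]
        assert res.ranked[0].head_nt == "AAAAAA" < res.ranked[1].head_nt == "AAAAAG"


class TestCMethod:
    def test_reduces_to_h_method_without_constraints(self, backend, short_spec, gc_cai):
        rng = np.random.default_rng(107)
        seq = random_sense_cds(rng, 10)
        h1 = h_method(seq, short_spec, backend, k=1).ranked[0]
        c1 = c_method(seq, short_spec, backend, gc_cai, set(), 0.0, k=1).ranked[0]
        assert c1.head_nt == h1.head_nt

    def test_threshold_dominates_energy(self, backend, short_spec, gc_table, gc_cai, code):
        rng = np.random.default_rng(109)
        seq = random_sense_cds(rng, 10)
        res = c_method(seq, short_spec, backend, gc_cai, set(), 1.0, k=1)
        best_head = "".join(
            seq.sense_codons[0] if i == 0
            else max(code.synonyms(c), key=lambda s: (gc_table.counts[s], s))
            for i, c in enumerate(seq.sense_codons[:4])
        )
        assert res.ranked[0].head_nt == best_head
        assert res.ranked[0].cai_h == pytest.approx(1.0)

    def test_constraints_satisfied(self, backend, short_spec, gc_cai, gc_rare):
        rng = np.random.default_rng(113)
        for thr in (0.60, 0.75, 0.90):
            seq = random_sense_cds(rng, 10)
            res = c_method(seq, short_spec, backend, gc_cai, gc_rare, thr, k=3)
            for v in res.ranked:
                assert v.cai_h > thr - 1e-9
                assert v.rare_count == 0
                assert cai_head(
                    CodingSequence("v", v.full_cds), gc_cai, 4
                ) == pytest.approx(v.cai_h)

    def test_infeasible_whole_family_forbidden(self, backend, short_spec, gc_cai):
        seq = CodingSequence("mk", "ATGAAAGGGAAA")
        with pytest.raises(InfeasibleDesignError, match="forbidden"):
            c_method(seq, short_spec, backend, gc_cai, {"AAA", "AAG"}, 0.5, k=1)


class TestDeoptimize:
    def test_single_variant(self, backend, short_spec):
        seq = CodingSequence("mw", "ATGTGGATGTGG")
        with pytest.warns(UserWarning):
            res = deoptimize(seq, short_spec, backend, k=3)
        assert res.method == "L"
        assert res.labels() == ("L1",)

    def test_ascending_order(self, backend, short_spec):
        rng = np.random.default_rng(127)
        seq = random_sense_cds(rng, 10)
        res = deoptimize(seq, short_spec, backend, k=3)
        dgs = [v.dG_UH for v in res.ranked]
        assert dgs == sorted(dgs)


class TestInvariants:
    def test_synonymy_and_downstream_immutability(self, backend, short_spec):
        rng = np.random.default_rng(131)
        for i in range(5):
            seq = random_sense_cds(rng, 15, f"p{i}")
            wt_aa = translate(seq)
            for method in (h_method, deoptimize):
                res = method(seq, short_spec, backend, k=3)
                for v in res.ranked:
                    assert translate(CodingSequence("v", v.full_cds)) == wt_aa
                    assert v.full_cds[12:] == seq.nt[12:]
                    assert v.full_cds[:3] == "ATG"  # start never mutated

    def test_determinism(self, backend, short_spec):
        seq = random_sense_cds(np.random.default_rng(137), 10)
        r1 = h_method(seq, short_spec, backend, k=3)
        r2 = h_method(seq, short_spec, backend, k=3)
        assert [v.head_nt for v in r1.ranked] == [v.head_nt for v in r2.ranked]
        assert [v.dG_UH for v in r1.ranked] == [v.dG_UH for v in r2.ranked]


class TestSampledSearch:
    def test_sampling_above_cap(self, backend, short_spec, monkeypatch):
        monkeypatch.setattr(design_mod, "ENUMERATION_CAP", 10)
        monkeypatch.setattr(design_mod, "SAMPLE_SIZE", 8)
        seq = CodingSequence("m", "ATGCTGCTGCTG")  # 3 Leu positions: 216 > 10
        r1 = h_method(seq, short_spec, backend, k=3, seed=5)
        r2 = h_method(seq, short_spec, backend, k=3, seed=5)
        assert r1.search_mode == "sampled"
        assert r1.n_variants_considered == 8
        assert [v.head_nt for v in r1.ranked] == [v.head_nt for v in r2.ranked]
        r3 = h_method(seq, short_spec, backend, k=3, seed=6)
        assert r3.search_mode == "sampled"  # different seed still valid
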