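"""Codon counts, RSCU, positional GC, ENc and CAI."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plastidkit import (
    CodingSequence,
    build_cai_weights,
    compute_cai,
    compute_enc,
    compute_rscu,
    count_codons,
    enc_expected,
    gc_by_position,
    summarize_usage,
    synonymous_third_position,
)
from plastidkit.codon import CodonCountTable, EncUndefinedError
from plastidkit._genetics import ALL_CODONS, FAMILIES, STOP_CODONS

from .conftest import random_count_table
from .oracles import cai_bruteforce, enc_bruteforce, rscu_bruteforce


def _table(**counts) -> CodonCountTable:
    full = {c: 0 for c in ALL_CODONS}
    full.update(counts)
    return CodonCountTable(full)


def _uniform_sense(per_codon=100) -> CodonCountTable:
    return _table(**{c: per_codon for c in ALL_CODONS if c not in STOP_CODONS})


class TestCountCodons:
    def test_simple_gene(self):
        t = count_codons([CodingSequence("g", "ATGAAATAA")])
        assert t.counts["ATG"] == t.counts["AAA"] == t.counts["TAA"] == 1
        assert t.n_codons == 3

    def test_additivity(self):
        g = CodingSequence("g", "ATGAAATAA")
        once = count_codons([g])
        twice = count_codons([g, g])
        assert all(twice.counts[c] == 2 * once.counts[c] for c in ALL_CODONS)

    def test_sum_of_per_gene_tables(self, small_spec):
        from plastidkit.simulate import gen_biased_cds

        genes = gen_biased_cds(dataclasses.replace(small_spec, n_genes=10))
        pooled = count_codons(genes)
        summed = count_codons([genes[0]])
        for g in genes[1:]:
            summed = summed + count_codons([g])
        assert pooled.counts == summed.counts

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            count_codons([])


class TestRSCU:
    def test_uniform_usage_is_one_everywhere(self):
        r = compute_rscu(_uniform_sense())
        assert all(v == pytest.approx(1.0) for c, v in r.rscu.items()
                   if c not in STOP_CODONS)

    def test_single_codon_six_fold_family(self):
        leu = FAMILIES["L"]
        r = compute_rscu(_table(TTA=10))
        assert r.rscu["TTA"] == pytest.approx(6.0)
        assert all(r.rscu[c] == 0.0 for c in leu if c != "TTA")

    def test_hand_computed_partial_family(self):
        r = compute_rscu(_table(TTA=3, TTG=1))
        assert r.rscu["TTA"] == pytest.approx(3 * 6 / 4)

    def test_stop_codons_form_a_family_by_default(self):
        r = compute_rscu(_table(TAA=2, TGA=1, TAG=0))
        assert r.rscu["TAA"] == pytest.approx(2.0)
        assert r.rscu["TGA"] == pytest.approx(1.0)

    def test_empty_family_flagged_with_zeros(self):
        r = compute_rscu(_table(AAA=5))
        assert "G" in r.empty_families
        assert all(r.rscu[c] == 0.0 for c in FAMILIES["G"])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_family_mean_is_one_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        t = CodonCountTable(random_count_table(rng))
        r = compute_rscu(t)
        oracle = rscu_bruteforce(dict(t.counts))
        for aa, codons in FAMILIES.items():
            if sum(t.counts[c] for c in codons) == 0:
                continue
            mean = sum(r.rscu[c] for c in codons) / len(codons)
            assert mean == pytest.approx(1.0, abs=1e-9)
        for c in ALL_CODONS:
            assert r.rscu[c] == pytest.approx(oracle[c], abs=1e-9)


class TestPositionalGC:
    def test_all_gcg(self):
        assert gc_by_position(_table(GCG=50)) == (1, 1, 1, 1, 1)

    def test_all_ata(self):
        assert gc_by_position(_table(ATA=50)) == (0, 0, 0, 0, 0)

    def test_matches_direct_recount_of_concatenation(self, rng):
        t = CodonCountTable(random_count_table(rng))
        nt = "".join(c * x for c, x in t.counts.items())
        gc1, gc2, gc3, gc12, gc = gc_by_position(t)
        for p, val in enumerate((gc1, gc2, gc3)):
            bases = nt[p::3]
            direct = sum(b in "GC" for b in bases) / len(bases)
            assert val == pytest.approx(direct, abs=1e-12)
        assert gc12 == pytest.approx((gc1 + gc2) / 2)
        assert gc == pytest.approx((gc1 + gc2 + gc3) / 3)


class TestSynonymousThirdPosition:
    def test_nothing_synonymous_is_undefined(self):
        assert synonymous_third_position(_table(ATG=5, TGG=3)) is None

    def test_equal_glycine_codons(self):
        res = synonymous_third_position(_table(GGA=5, GGT=5, GGC=5, GGG=5))
        a3s, t3s, c3s, g3s, gc3s = res
        assert (a3s, t3s, c3s, g3s) == (0.25, 0.25, 0.25, 0.25)
        assert gc3s == 0.5

    def test_met_trp_and_stops_excluded(self):
        with_extras = synonymous_third_position(
            _table(GGA=5, GGT=5, GGC=5, GGG=5, ATG=100, TGG=100, TAA=50)
        )
        assert with_extras == synonymous_third_position(
            _table(GGA=5, GGT=5, GGC=5, GGG=5)
        )

    def test_generator_target_recovered(self):
        from plastidkit.simulate import SyntheticSpec, gen_biased_cds

        spec = SyntheticSpec(seed=7, n_genes=50, codons_per_gene=220,
                             gc3s_target=0.269)
        genes = gen_biased_cds(spec)
        t = count_codons(genes)
        gc3s = synonymous_third_position(t)[4]
        assert gc3s == pytest.approx(0.269, abs=0.01)


class TestENc:
    def test_one_codon_per_family_gives_twenty(self):
        counts = {FAMILIES[aa][0]: 1000 for aa in FAMILIES}
        assert compute_enc(_table(**counts)) == 20.0

    def test_uniform_usage_near_sixty_one(self):
        # ~6000 codons of perfectly even usage: unclamped estimate
        # slightly exceeds 61, so the clamp returns 61
        assert compute_enc(_uniform_sense(per_codon=100)) >= 60.9

    def test_matches_bruteforce_oracle_on_random_tables(self):
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(200):
            counts = random_count_table(rng, n_codons=3000)
            t = CodonCountTable(counts)
            try:
                ours = compute_enc(t, clamp=False)
            except EncUndefinedError:
                continue
            assert ours == pytest.approx(enc_bruteforce(counts), abs=1e-9)
            checked += 1
        assert checked >= 190

    def test_monotone_under_family_concentration(self):
        # interpolate every family from uniform to one codon
        values = []
        for lam in (0.0, 0.25, 0.5, 0.75, 0.95):
            counts = {}
            for aa, fam in FAMILIES.items():
                k = len(fam)
                for i, c in enumerate(fam):
                    uniform = 600 // k
                    peak = 600 if i == 0 else 0
                    counts[c] = round((1 - lam) * uniform + lam * peak)
            values.append(compute_enc(_table(**counts), clamp=False))
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_missing_isoleucine_class_imputed(self):
        counts = {FAMILIES[aa][0]: 50 for aa in FAMILIES if aa != "I"}
        counts.update({c: 50 for aa in FAMILIES if aa != "I"
                       for c in FAMILIES[aa]})
        enc = compute_enc(_table(**counts))
        assert 20 <= enc <= 61

    def test_empty_two_fold_class_is_an_error(self):
        # only glycine (4-fold) present: 2-fold and 6-fold unestimable
        with pytest.raises(EncUndefinedError, match="fold"):
            compute_enc(_table(GGA=10, GGC=10))


class TestEncExpected:
    @pytest.mark.parametrize("s,expected", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)])
    def test_analytic_values(self, s, expected):
        assert enc_expected(s) == pytest.approx(expected, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            enc_expected(1.2)

    def test_near_symmetry_in_s(self):
        # the curve is symmetric up to the linear term: f(s) - s == f(1-s) - (1-s)
        for s in (0.1, 0.3, 0.45):
            assert enc_expected(s) - s == pytest.approx(
                enc_expected(1 - s) - (1 - s), abs=1e-12
            )


class TestCAI:
    def test_reference_using_single_leu_codon(self):
        ref = [CodingSequence("r", "ATG" + "TTA" * 30 + "TAA")]
        w = build_cai_weights(ref)
        assert w.w["TTA"] == 1.0
        assert all(w.w[c] == 0.01 for c in FAMILIES["L"] if c != "TTA")

    def test_uniform_reference_all_weights_one(self):
        nt = "ATG" + "".join(c for c in ALL_CODONS if c not in STOP_CODONS)
        ref = [CodingSequence("r", nt + "TAA")]
        w = build_cai_weights(ref)
        assert all(v == 1.0 for v in w.w.values())

    def test_gene_of_optimal_codons_scores_one(self):
        ref = [CodingSequence("r", "ATG" + "AAATTAGGA" * 10 + "TAA")]
        w = build_cai_weights(ref)
        gene = CodingSequence("g", "AAATTAGGA" * 3)
        assert compute_cai(gene, w) == pytest.approx(1.0)

    def test_geometric_mean_of_two_codons(self):
        from plastidkit.codon import CAIWeights

        w = CAIWeights(w={"AAA": 0.25, "GGA": 1.0})
        gene = CodingSequence("g", "AAAGGA")
        assert compute_cai(gene, w) == pytest.approx(0.5)

    def test_matches_log_domain_bruteforce(self, small_spec):
        from plastidkit.simulate import gen_biased_cds

        genes = gen_biased_cds(small_spec)
        w = build_cai_weights(genes[:5])
        for g in genes[5:10]:
            ours = compute_cai(g, w)
            oracle = cai_bruteforce(g.sense_codons, dict(w.w))
            assert ours == pytest.approx(oracle, abs=1e-12)

    def test_scale_invariance(self):
        ref = [CodingSequence("r", "ATG" + "AAATTAGGA" * 10 + "TAA")]
        w = build_cai_weights(ref)
        gene = CodingSequence("g", "AAATTGGGA")
        doubled = CodingSequence("g2", "AAATTGGGA" * 2)
        assert compute_cai(gene, w) == pytest.approx(compute_cai(doubled, w))

    def test_only_unscorable_codons_is_missing(self):
        ref = [CodingSequence("r", "ATG" + "AAATTAGGA" * 10 + "TAA")]
        w = build_cai_weights(ref)
        gene = CodingSequence("g", "ATGTGG")
        assert compute_cai(gene, w) is None


class TestSummarizeUsage:
    def test_uniform_gene_set_with_self_reference(self):
        block = "".join(c for c in ALL_CODONS if c not in STOP_CODONS)
        gene = CodingSequence("g", "ATG" + block * 50 + "TAA")
        w = build_cai_weights([gene])
        s = summarize_usage([gene], weights=w, label="u")
        assert s.gc3s == pytest.approx(0.5, abs=0.01)
        assert s.enc == 61.0
        assert s.cai == pytest.approx(1.0)

    def test_generator_parameters_recovered(self, small_spec):
        import dataclasses

        from plastidkit.simulate import gen_biased_cds

        spec = dataclasses.replace(small_spec, n_genes=40,
                                   codons_per_gene=250, gc3s_target=0.29)
        genes = gen_biased_cds(spec)
        s = summarize_usage(genes, label="syn")
        assert s.gc3s == pytest.approx(0.29, abs=0.015)
        assert s.n_codons == 40 * 251
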