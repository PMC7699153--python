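"""GenBank I/O, CDS extraction, IR detection and junction arithmetic."""

import io

import pytest

from plastidkit import (
    CodingSequence,
    GeneFeature,
    GenomeRecord,
    detect_inverted_repeats,
    extract_cds,
    junction_report,
    read_genbank,
    region_gc,
    unique_cds_features,
    write_genbank,
)
from plastidkit.genome import CdsValidationError, GenomeFormatError, Interval
from plastidkit._genetics import revcomp

from .oracles import longest_rc_repeat_bruteforce


def _genbank(body_features: str, seq: str) -> io.StringIO:
    n = len(seq)
    lines = [
        f"LOCUS       test{' ' * 15}{n} bp    DNA     circular PLN 01-JAN-2020",
        "DEFINITION  test record.",
        "FEATURES             Location/Qualifiers",
        body_features.rstrip(),
        "ORIGIN",
    ]
    for i in range(0, n, 60):
        chunk = seq[i : i + 60].lower()
        groups = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {groups}")
    lines.append("//")
    return io.StringIO("\n".join(lines) + "\n")


class TestReadGenbank:
    def test_single_cds_coordinates_are_zero_based_half_open(self):
        fh = _genbank(
            '     CDS             1..6\n                     /gene="g1"',
            "ATGTAAGGGGGG",
        )
        g = read_genbank(fh)
        assert len(g.features) == 1
        f = g.features[0]
        assert f.exons == ((0, 6),)
        assert f.strand == "+"
        assert g.seq.startswith("ATGTAA")

    def test_join_complement_gives_two_exons_minus_strand(self):
        seq = "A" * 50
        fh = _genbank(
            "     CDS             complement(join(10..20,30..40))\n"
            '                     /gene="g2"',
            seq,
        )
        g = read_genbank(fh)
        f = g.features[0]
        assert f.strand == "-"
        assert sorted(f.exons) == [(9, 20), (29, 40)]

    def test_round_trip_preserves_record(self, small_genome, tmp_path):
        p = tmp_path / "g.gb"
        write_genbank(small_genome, p)
        back = read_genbank(p)
        assert back.seq == small_genome.seq
        assert sorted(f.exons for f in back.features) == sorted(
            f.exons for f in small_genome.features
        )
        assert {(f.gene_name, f.kind, f.strand) for f in back.features} == {
            (f.gene_name, f.kind, f.strand) for f in small_genome.features
        }

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(GenomeFormatError, match="ambiguity"):
            GenomeRecord(id="x", seq="ACGTRY")

    def test_feature_beyond_sequence_is_a_coordinate_error(self):
        with pytest.raises(GenomeFormatError):
            GenomeRecord(
                id="x",
                seq="ACGT" * 10,
                features=[GeneFeature("g", "CDS", ((30, 60),), "+")],
            )


class TestExtractCds:
    def test_forward_simple(self):
        g = GenomeRecord(
            id="x", seq="ATGAAATAA",
            features=[GeneFeature("g", "CDS", ((0, 9),), "+")],
        )
        cds = extract_cds(g, g.features[0])
        assert cds.codons == ["ATG", "AAA", "TAA"]
        assert cds.has_terminal_stop

    def test_minus_strand_gives_same_codons(self):
        fwd = "ATGAAATAA"
        g = GenomeRecord(
            id="x", seq=revcomp(fwd),
            features=[GeneFeature("g", "CDS", ((0, 9),), "-")],
        )
        assert extract_cds(g, g.features[0]).codons == ["ATG", "AAA", "TAA"]

    def test_split_mid_codon_equals_unsplit(self):
        gene = "ATGCCTGGTAAACAATAA"
        spacer = "GGGG"
        seq = gene[:7] + spacer + gene[7:]
        split = GenomeRecord(
            id="x", seq=seq,
            features=[GeneFeature("g", "CDS", ((0, 7), (11, 22)), "+")],
        )
        whole = GenomeRecord(
            id="y", seq=gene,
            features=[GeneFeature("g", "CDS", ((0, 18),), "+")],
        )
        assert (
            extract_cds(split, split.features[0]).codons
            == extract_cds(whole, whole.features[0]).codons
        )

    def test_codon_start_offset_trims_leading_bases(self):
        g = GenomeRecord(
            id="x", seq="CCATGAAATAA",
            features=[GeneFeature("g", "CDS", ((0, 11),), "+",
                                  codon_start_offset=2)],
        )
        assert extract_cds(g, g.features[0]).codons == ["ATG", "AAA", "TAA"]

    def test_internal_stop_names_gene_and_codon(self):
        g = GenomeRecord(
            id="x", seq="ATGTAAAAATAA",
            features=[GeneFeature("badgene", "CDS", ((0, 12),), "+")],
        )
        with pytest.raises(CdsValidationError, match="badgene.*codon index 1"):
            extract_cds(g, g.features[0])

    def test_frame_error(self):
        g = GenomeRecord(
            id="x", seq="ATGAAAT",
            features=[GeneFeature("g", "CDS", ((0, 7),), "+")],
        )
        with pytest.raises(CdsValidationError, match="divisible by 3"):
            extract_cds(g, g.features[0])


class TestInvertedRepeats:
    def test_planted_structure_recovered_exactly(self, small_genome, small_spec):
        part = detect_inverted_repeats(small_genome, min_len=3000)
        assert part == small_genome.partition
        L = small_genome.length
        assert part.irb.length(L) == part.ira.length(L)
        total = sum(
            getattr(part, r).length(L) for r in ("lsc", "irb", "ssc", "ira")
        )
        assert total == L

    def test_ir_arms_are_exact_reverse_complements(self, small_genome):
        part = detect_inverted_repeats(small_genome, min_len=3000)
        seq = small_genome.seq
        assert part.irb.extract(seq) == revcomp(part.ira.extract(seq))

    def test_random_sequence_has_no_structure(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=50_000))
        g = GenomeRecord(id="r", seq=seq)
        assert detect_inverted_repeats(g, min_len=10_000) is None

    def test_mismatched_ir_returns_longer_exact_arm(self, rng):
        # plant a 600 bp IR with one mismatch 200 bp in: exact arms are
        # 399 and 200 bp; detection must agree with brute-force enumeration
        arm = "".join(rng.choice(list("ACGT"), size=600))
        left = "".join(rng.choice(list("ACGT"), size=500))
        mid = "".join(rng.choice(list("ACGT"), size=300))
        broken = list(arm)
        broken[200] = {"A": "C", "C": "A", "G": "T", "T": "G"}[broken[200]]
        seq = left + arm + mid + revcomp("".join(broken))
        g = GenomeRecord(id="toy", seq=seq)
        part = detect_inverted_repeats(g, min_len=150)
        assert part is not None
        found_len = part.irb.length(len(seq))
        assert found_len == longest_rc_repeat_bruteforce(seq)

    def test_ir_duplicated_genes_deduplicate(self, small_genome):
        names = [f.gene_name for f in small_genome.features]
        cds_names = [f.gene_name for f in unique_cds_features(small_genome)]
        assert len(cds_names) == len(set(cds_names))
        assert set(cds_names) <= set(names)


class TestJunctions:
    def _genome_with_partition(self):
        # 1000 LSC + 200 IRb + 400 SSC + 200 IRa = 1800
        rng_seq = ("ACGT" * 450)
        seq = rng_seq + "G" * 200 + "AT" * 200 + "C" * 200
        g = GenomeRecord(id="j", seq=seq)
        from plastidkit.genome import QuadripartitePartition

        g.partition = QuadripartitePartition(
            lsc=Interval(0, 1000), irb=Interval(1000, 1200),
            ssc=Interval(1200, 1600), ira=Interval(1600, 1800),
        )
        return g

    def test_gene_spanning_lsc_irb_reports_ir_overlap(self):
        g = self._genome_with_partition()
        g.features.append(GeneFeature("rpl22", "CDS", ((900, 1050),), "+"))
        rep = junction_report(g)
        hits = [r for r in rep if r.junction == "LSC/IRb" and r.bases_in_ir]
        assert len(hits) == 1
        assert hits[0].gene_name == "rpl22"
        assert hits[0].bases_in_ir == 50
        assert hits[0].distance == 0

    def test_gene_inside_ssc_absent(self):
        g = self._genome_with_partition()
        g.features.append(GeneFeature("ndhA", "CDS", ((1350, 1450),), "+"))
        assert all(r.gene_name != "ndhA" for r in junction_report(g))

    def test_planted_ycf1_overlap_is_exact(self, small_genome, small_spec):
        rep = junction_report(small_genome)
        ycf1 = [r for r in rep if r.gene_name == "ycf1" and r.bases_in_ir]
        assert len(ycf1) == 1
        assert ycf1[0].junction == "SSC/IRa"
        assert ycf1[0].bases_in_ir == small_spec.ira_overlap

    def test_nearby_gene_reports_distance(self):
        g = self._genome_with_partition()
        g.features.append(GeneFeature("trnH", "tRNA", ((1210, 1260),), "+"))
        rep = [r for r in junction_report(g) if r.gene_name == "trnH"]
        assert any(r.junction == "IRb/SSC" and r.distance == 10 for r in rep)


class TestRegionGC:
    def test_all_gc_sequence(self):
        g = GenomeRecord(id="x", seq="GC" * 100)
        assert region_gc(g).total == 1.0

    def test_atgc_repeat_is_half(self):
        g = GenomeRecord(id="x", seq="ATGC" * 50)
        assert region_gc(g).total == 0.5

    def test_total_is_length_weighted_mean_of_regions(self, small_genome):
        gc = region_gc(small_genome)
        part = small_genome.partition
        L = small_genome.length
        w = {
            "lsc": part.lsc.length(L),
            "ir": part.irb.length(L) + part.ira.length(L),
            "ssc": part.ssc.length(L),
        }
        mean = sum(getattr(gc, r) * w[r] for r in w) / L
        assert gc.total == pytest.approx(mean, abs=1e-12)

    def test_generator_bookkeeping_matches_direct_recount(self, small_genome):
        part = small_genome.partition
        gc = region_gc(small_genome)
        lsc_seq = part.lsc.extract(small_genome.seq)
        direct = (lsc_seq.count("G") + lsc_seq.count("C")) / len(lsc_seq)
        assert gc.lsc == pytest.approx(direct, abs=1e-12)

    def test_n_only_region_is_missing(self):
        from plastidkit.genome import QuadripartitePartition

        g = GenomeRecord(id="x", seq="N" * 100 + "ACGT" * 100)
        g.partition = QuadripartitePartition(
            lsc=Interval(100, 500), irb=Interval(0, 50),
            ssc=Interval(50, 100), ira=Interval(0, 0),
        )
        gc = region_gc(g)
        assert gc.ir is None
        assert gc.ssc is None
        assert gc.lsc == 0.5
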