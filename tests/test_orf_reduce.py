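import random

import pytest

from zooclock.io_formats import ParseError, SeqRecord
from zooclock.orf_reduce import (Cluster, cluster_sequences,
                                 extract_final_transcripts, filter_min_length,
                                 find_best_orf, pairwise_identity,
                                 reduce_assembly, select_longest_isoform)
from zooclock.synthetic import back_translate
from tests.conftest import make_nt_record, random_dna
from tests.oracles import cluster_oracle, orf_oracle, random_cluster_instance


class TestLengthFilter:
    def test_boundary_at_200(self):
        short = make_nt_record("short", "A" * 199)
        exact = make_nt_record("exact", "A" * 200)
        assert filter_min_length([short, exact]) == [exact]

    def test_empty_and_identity(self):
        assert filter_min_length([]) == []
        recs = [make_nt_record(f"r{i}", "A" * (200 + i)) for i in range(3)]
        assert filter_min_length(recs) == recs


class TestFindBestOrf:
    def test_forced_complete_orf(self):
        # ATG..TGA dominates every other frame on both strands
        orf = find_best_orf(make_nt_record("t", "ATGAAATTATGA"), min_aa=1)
        assert orf.protein == "MKL"
        assert orf.strand == "+" and orf.completeness == "cmp"
        assert (orf.start, orf.end) == (0, 12)  # stop codon included

    def test_start_without_stop_is_3p(self):
        orf = find_best_orf(make_nt_record("t", "ATGAAAAAAAAA"), min_aa=1)
        assert orf.protein == "MKKK" and orf.completeness == "3p"

    def test_no_start_with_stop_is_5p(self):
        # open frame from the edge, terminated by TGA, no ATG upstream
        orf = find_best_orf(make_nt_record("t", "AAAAAATTATCATGA"), min_aa=1)
        assert orf.completeness == "5p" and orf.protein == "KKLS"

    def test_n_codon_terminates_span(self):
        # the N codon splits the frame; the best ORF cannot cross it
        orf = find_best_orf(make_nt_record("t", "ATGAAANNNAAAAAAAAAAAA"),
                            min_aa=1)
        assert orf.protein != "MK" + "K" * 5

    def test_min_aa_returns_none(self):
        assert find_best_orf(make_nt_record("t", "GGGATGAAATGACCC"),
                             min_aa=10) is None

    def test_protein_alphabet_rejected(self):
        rec = SeqRecord(id="p", residues="MKLV", alphabet="protein")
        with pytest.raises(ParseError):
            find_best_orf(rec)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = random.Random(seed)
        for _ in range(5):
            seq = random_dna(rng, 300)
            got = find_best_orf(make_nt_record("t", seq), min_aa=1)
            want = orf_oracle(seq, min_aa=1)
            if want is None:
                assert got is None
            else:
                assert (got.strand, got.frame, got.start, got.end,
                        got.protein, got.completeness) == want

    def test_back_translated_protein_recovered(self):
        rng = random.Random(3)
        protein = "M" + "".join(rng.choice("ACDEFGHIKLNPQRSTVWY")
                                for _ in range(150))
        nt = back_translate(protein, "TAAATAAATAA", "TAAATAAATAA")
        orf = find_best_orf(make_nt_record("t", nt))
        assert orf.protein == protein and orf.completeness == "cmp"


class TestClustering:
    def test_identical_sequences_one_cluster(self):
        a = make_nt_record("a", "ACGT" * 60)
        b = make_nt_record("b", "ACGT" * 60)
        clusters = cluster_sequences([a, b])
        assert len(clusters) == 1
        assert set(clusters[0].member_ids) == {"a", "b"}

    def test_dissimilar_sequences_stay_apart(self):
        rng = random.Random(1)
        a = make_nt_record("a", random_dna(rng, 200))
        b = make_nt_record("b", random_dna(rng, 200))
        assert len(cluster_sequences([a, b])) == 2

    def test_representative_is_longest_member(self):
        long = make_nt_record("long", "ACGT" * 60)
        short = make_nt_record("short", ("ACGT" * 60)[:-3])
        clusters = cluster_sequences([short, long])
        assert clusters[0].representative_id == "long"

    def test_mixed_alphabets_rejected(self):
        with pytest.raises(ParseError):
            cluster_sequences([
                make_nt_record("a", "ACGT" * 60),
                SeqRecord(id="b", residues="MKLV" * 30, alphabet="protein")])

    def test_clusters_partition_input(self):
        records = random_cluster_instance(seed=77)
        clusters = cluster_sequences(records)
        all_members = [m for c in clusters for m in c.member_ids]
        assert sorted(all_members) == sorted(r.id for r in records)
        for c in clusters:
            assert c.representative_id in c.member_ids

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_all_pairs_dp_oracle(self, seed):
        records = random_cluster_instance(seed)
        got = {frozenset(c.member_ids) for c in cluster_sequences(records)}
        assert got == cluster_oracle(records)

    def test_identity_is_symmetric_and_bounded(self):
        rng = random.Random(4)
        for _ in range(20):
            a, b = random_dna(rng, rng.randint(50, 150)), \
                random_dna(rng, rng.randint(50, 150))
            i1, i2 = pairwise_identity(a, b), pairwise_identity(b, a)
            assert i1 == i2 and 0.0 <= i1 <= 1.0


class TestIsoformSelection:
    def _prot(self, tid, length):
        return SeqRecord(id=tid, residues="M" + "K" * (length - 1),
                         alphabet="protein")

    def test_longest_isoform_wins(self):
        short = self._prot("TRINITY_DN1_c0_g1_i1.p1", 100)
        long = self._prot("TRINITY_DN1_c0_g1_i2.p1", 150)
        kept, sel = select_longest_isoform([short, long])
        assert [r.id for r in kept] == [long.id]
        assert sel[long.id] == [short.id]

    def test_single_isoform_unchanged(self):
        only = self._prot("TRINITY_DN2_c0_g1_i1.p1", 120)
        kept, sel = select_longest_isoform([only])
        assert kept == [only] and sel[only.id] == []

    def test_length_tie_prefers_lower_isoform_index(self):
        i2 = self._prot("TRINITY_DN3_c0_g1_i2.p1", 120)
        i1 = self._prot("TRINITY_DN3_c0_g1_i1.p1", 120)
        kept, _ = select_longest_isoform([i2, i1])
        assert kept[0].id == i1.id

    def test_unparseable_id_error(self):
        with pytest.raises(ParseError, match="badid"):
            select_longest_isoform(
                [SeqRecord(id="badid", residues="MK", alphabet="protein")])


class TestExtraction:
    def test_extracts_in_assembly_order(self):
        t1 = make_nt_record("TRINITY_DN1_c0_g1_i1", "A" * 300)
        t2 = make_nt_record("TRINITY_DN2_c0_g1_i1", "C" * 300)
        out = extract_final_transcripts(
            [t1, t2], ["TRINITY_DN2_c0_g1_i1.p1", "TRINITY_DN1_c0_g1_i1.p1"])
        assert [r.id for r in out] == [t1.id, t2.id]

    def test_missing_transcript_named(self):
        t1 = make_nt_record("TRINITY_DN1_c0_g1_i1", "A" * 300)
        with pytest.raises(ParseError, match="DN9"):
            extract_final_transcripts([t1], ["TRINITY_DN9_c0_g1_i1.p1"])


class TestReductionPipeline:
    def test_one_protein_per_gene_and_idempotence(
            self, small_universe_with_transcripts):
        universe, transcripts, _ = small_universe_with_transcripts
        for sp in universe.species:
            res = reduce_assembly(transcripts[sp])
            genes = [r.id.split("_i")[0] for r in res.proteome]
            assert len(genes) == len(set(genes))
            again = reduce_assembly(res.final_transcripts)
            assert [r.id for r in again.final_transcripts] == \
                [r.id for r in res.final_transcripts]

    def test_near_duplicates_cocluster(self, small_universe_with_transcripts):
        universe, transcripts, _ = small_universe_with_transcripts
        dup_pairs = universe.manifest.near_duplicate_pairs()
        assert dup_pairs, "generator planted no near-duplicates"
        flat = {r.id: r for sp in universe.species for r in transcripts[sp]}
        for orig, dup in dup_pairs:
            clusters = cluster_sequences([flat[orig], flat[dup]])
            assert len(clusters) == 1
            assert clusters[0].representative_id == orig

    def test_planted_tags_rederived(self, small_universe_with_transcripts):
        universe, transcripts, _ = small_universe_with_transcripts
        flat = {r.id: r for sp in universe.species for r in transcripts[sp]}
        for entry in universe.manifest.orthologs():
            orf = find_best_orf(flat[entry["transcript_id"]])
            assert orf is not None
            assert orf.completeness == entry["completeness"]
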