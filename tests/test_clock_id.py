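import random

import pandas as pd
import pytest

from zooclock.clock_id import (Bait, Candidate, ConfigError, STAGES,
                               accession_of, candidate_matrix,
                               compare_candidate_sets, confirm_swissprot,
                               extract_bait_orthologs, reference_found_pairs,
                               select_fallback_hits, tag_baits,
                               validate_against_references, vet_candidates)
from zooclock.io_formats import SeqRecord
from zooclock.reference_data import (BAIT_ACCESSIONS,
                                     CROSS_REFERENCE_EXPECTED,
                                     CROSS_REFERENCE_FOUND)


def _prot(pid, length=30):
    return SeqRecord(id=pid, residues="M" + "K" * (length - 1),
                     alphabet="protein")


def _pairs(rows):
    return pd.DataFrame(rows, columns=["species_a", "seq_a",
                                       "species_b", "seq_b"])


def _registry_one():
    bait = Bait(component="CLK", source_species="Dm", accession="O61735",
                seq_id="sp|O61735|CLK_DM_SOIREF",
                domains=frozenset({"PF00010", "PF00989"}),
                family="PTHR1", subfamily="PTHR1:SF1")
    return {"CLK": bait}


class TestTagBaits:
    def test_marker_appended(self):
        proteomes = {"Dm": [_prot("sp|O61735|CLK_DM"), _prot("sp|X1|OTHER")]}
        tagged, registry = tag_baits(proteomes, {"CLK": ("Dm", "O61735")})
        ids = [r.id for r in tagged["Dm"]]
        assert "sp|O61735|CLK_DM_SOIREF" in ids and "sp|X1|OTHER" in ids
        assert registry["CLK"].seq_id.endswith("_SOIREF")

    def test_missing_accession_error(self):
        with pytest.raises(ConfigError, match="O61735"):
            tag_baits({"Dm": [_prot("sp|X1|OTHER")]},
                      {"CLK": ("Dm", "O61735")})

    def test_preexisting_marker_rejected(self):
        with pytest.raises(ConfigError, match="SOIREF"):
            tag_baits({"Dm": [_prot("sp|X1|FAKE_SOIREF")]},
                      {"CLK": ("Dm", "X1")})


class TestExtraction:
    def test_single_pair_yields_candidate(self):
        table = _pairs([("Dm", "sp|O61735|CLK_DM_SOIREF", "spA", "seq1")])
        cands = extract_bait_orthologs(table, _registry_one())
        assert [(c.species, c.seq_id, c.component) for c in cands] == \
            [("spA", "seq1", "CLK")]

    def test_one_to_many_yields_multiple(self):
        table = _pairs([("Dm", "sp|O61735|CLK_DM_SOIREF", "spB", "s1"),
                        ("Dm", "sp|O61735|CLK_DM_SOIREF", "spB", "s2")])
        assert len(extract_bait_orthologs(table, _registry_one())) == 2

    def test_no_tagged_rows_empty(self):
        table = _pairs([("spA", "x", "spB", "y")])
        assert extract_bait_orthologs(table, _registry_one()) == []

    def test_double_tagged_skipped_with_warning(self):
        table = _pairs([("Dm", "a_SOIREF", "spB", "b_SOIREF")])
        with pytest.warns(UserWarning):
            assert extract_bait_orthologs(table, _registry_one()) == []

    def test_duplicates_collapsed(self):
        row = ("Dm", "sp|O61735|CLK_DM_SOIREF", "spA", "seq1")
        assert len(extract_bait_orthologs(_pairs([row, row]),
                                          _registry_one())) == 1


def _tables(rows_domains, rows_family):
    dom = pd.DataFrame(rows_domains,
                       columns=["seq_id", "db", "accession", "name",
                                "start", "end", "evalue"])
    fam = pd.DataFrame(rows_family,
                       columns=["seq_id", "family_acc", "subfamily_acc"])
    return dom, fam


BAIT_ROWS = ([("sp|O61735|CLK_DM_SOIREF", "Pfam", "PF00010", "bHLH",
               1, 50, 1e-30),
              ("sp|O61735|CLK_DM_SOIREF", "Pfam", "PF00989", "PAS",
               60, 120, 1e-30)],
             [("sp|O61735|CLK_DM_SOIREF", "PTHR1", "PTHR1:SF1")])


class TestVettingCascade:
    def _run(self, cands, extra_dom=(), extra_fam=()):
        dom, fam = _tables(BAIT_ROWS[0] + list(extra_dom),
                           BAIT_ROWS[1] + list(extra_fam))
        return vet_candidates(cands, dom, fam, _registry_one())

    def test_missing_family_fails_first_stage(self):
        cand = Candidate(species="spA", seq_id="c1", component="CLK")
        out = self._run([cand],
                        extra_dom=[("c1", "Pfam", "PF00010", "bHLH",
                                    1, 40, 1e-9)])
        assert not out[0].retained
        assert out[0].stage_status[-1][0] == STAGES[0]

    def test_no_shared_domain_fails_second_stage(self):
        cand = Candidate(species="spA", seq_id="c1", component="CLK")
        out = self._run([cand],
                        extra_dom=[("c1", "Pfam", "PF99999", "other",
                                    1, 40, 1e-9)],
                        extra_fam=[("c1", "PTHR1", "")])
        assert out[0].stage_status[-1][0] == STAGES[1]

    def test_wrong_family_decoy_fails_third_stage(self):
        # PAS-only decoy in an unrelated family
        cand = Candidate(species="spA", seq_id="decoy", component="CLK")
        out = self._run([cand],
                        extra_dom=[("decoy", "Pfam", "PF00989", "PAS",
                                    1, 60, 1e-9)],
                        extra_fam=[("decoy", "PTHR999", "")])
        assert out[0].stage_status[-1][0] == STAGES[2]
        assert not out[0].retained

    def test_subfamily_match_displaces_sibling(self):
        cands = [Candidate(species="spA", seq_id="good", component="CLK"),
                 Candidate(species="spA", seq_id="meh", component="CLK")]
        out = self._run(
            cands,
            extra_dom=[("good", "Pfam", "PF00989", "PAS", 1, 60, 1e-9),
                       ("meh", "Pfam", "PF00989", "PAS", 1, 60, 1e-9)],
            extra_fam=[("good", "PTHR1", "PTHR1:SF1"),
                       ("meh", "PTHR1", "PTHR1:SF9")])
        by_id = {c.seq_id: c for c in out}
        assert by_id["good"].retained and not by_id["meh"].retained
        assert by_id["meh"].stage_status[-1][0] == STAGES[3]

    def test_no_subfamily_match_keeps_all(self):
        cands = [Candidate(species="spA", seq_id="a", component="CLK"),
                 Candidate(species="spA", seq_id="b", component="CLK")]
        out = self._run(
            cands,
            extra_dom=[("a", "Pfam", "PF00989", "PAS", 1, 60, 1e-9),
                       ("b", "Pfam", "PF00010", "bHLH", 1, 40, 1e-9)],
            extra_fam=[("a", "PTHR1", "PTHR1:SF8"), ("b", "PTHR1", "")])
        assert all(c.retained for c in out)

    def test_unannotated_bait_is_config_error(self):
        bait = Bait(component="CLK", source_species="Dm", accession="O61735",
                    seq_id="sp|O61735|CLK_DM_SOIREF")
        dom, fam = _tables([], [])
        with pytest.raises(ConfigError):
            vet_candidates(
                [Candidate(species="s", seq_id="x", component="CLK")],
                dom, fam, {"CLK": bait})

    @pytest.mark.parametrize("seed", range(20))
    def test_monotone_stage_survivorship(self, seed):
        """Randomized annotation tables: survivors shrink monotonically
        through the cascade."""
        rng = random.Random(seed)
        cands = [Candidate(species=f"sp{i % 3}", seq_id=f"c{i}",
                           component="CLK") for i in range(12)]
        extra_dom, extra_fam = [], []
        for c in cands:
            if rng.random() < 0.8:
                acc = rng.choice(["PF00010", "PF00989", "PF77777"])
                extra_dom.append((c.seq_id, "Pfam", acc, "d", 1, 40, 1e-8))
            if rng.random() < 0.8:
                fam = rng.choice(["PTHR1", "PTHR2"])
                sub = rng.choice(["", "PTHR1:SF1", "PTHR1:SF2"])
                extra_fam.append((c.seq_id, fam, sub))
        out = self._run(cands, extra_dom, extra_fam)
        survivors = {stage: set() for stage in STAGES}
        for c in out:
            passed = {s: ok for s, ok, _ in c.stage_status}
            reached = set()
            for stage in STAGES:
                if passed.get(stage):
                    reached.add(stage)
                else:
                    break
            for stage in reached:
                survivors[stage].add(c.seq_id)
            # audit must stop at the first failed stage
            stages_seen = [s for s, _, _ in c.stage_status]
            assert stages_seen == list(STAGES[:len(stages_seen)])
        s1, s2, s3, s4 = (survivors[s] for s in STAGES)
        assert s4 <= s3 <= s2 <= s1 <= {c.seq_id for c in cands}

    def test_noise_free_universe_recovered_exactly(self, small_universe):
        u = small_universe
        raw = extract_bait_orthologs(u.pair_table, u.bait_registry)
        out = vet_candidates(raw, u.domain_table, u.family_table,
                             u.bait_registry)
        found = {(c.species, c.seq_id, c.component)
                 for c in out if c.retained}
        assert found == u.manifest.true_pairs()


class TestSwissprotConfirmation:
    def _annotations(self, rows):
        return pd.DataFrame(rows, columns=["seq_id", "swissprot_target"])

    def test_whitelisted_hit_confirmed(self):
        cands = [Candidate(species="s", seq_id="c1", component="CLK",
                           retained=True)]
        ann = self._annotations([("c1", "sp|O61735|CLK_DROME")])
        out = confirm_swissprot(cands, ann, {"O61735"})
        assert out[0].swissprot_confirmed and out[0].retained

    def test_no_hit_unconfirmed_but_retained(self):
        cands = [Candidate(species="s", seq_id="c1", component="CLK",
                           retained=True)]
        out = confirm_swissprot(cands, self._annotations([]), {"O61735"})
        assert out[0].swissprot_confirmed is False and out[0].retained

    def test_empty_whitelist_all_unconfirmed(self):
        cands = [Candidate(species="s", seq_id="c1", component="CLK",
                           retained=True)]
        ann = self._annotations([("c1", "sp|O61735|CLK_DROME")])
        out = confirm_swissprot(cands, ann, set())
        assert not out[0].swissprot_confirmed and out[0].retained


class TestCandidateMatrix:
    def test_counts_and_na(self):
        cands = [Candidate(species="At", seq_id="x1", component="CLK",
                           retained=True)] + \
                [Candidate(species="At", seq_id=f"p{i}", component="PDP1e",
                           retained=True) for i in range(3)]
        mat = candidate_matrix(cands)
        assert mat.at["At", "CLK"] == 1 and mat.at["At", "PDP1e"] == 3
        assert pd.isna(mat.at["At", "CYC"])

    def test_all_na_when_empty(self):
        mat = candidate_matrix([], species=["a"])
        assert mat.isna().all().all()


class TestValidation:
    @staticmethod
    def _flatten(mapping):
        return {(comp, acc) for comp, pairs in mapping.items()
                for _, acc in pairs}

    def test_published_reference_maps_give_single_fn(self):
        expected = self._flatten(CROSS_REFERENCE_EXPECTED)
        found = self._flatten(CROSS_REFERENCE_FOUND)
        out = validate_against_references(found, expected)
        assert len(out.false_negatives) == 1
        assert out.false_negatives == {("CLK", "O08785")}
        assert len(out.false_positives) == 0

    def test_perfect_recovery(self):
        expected = {("CLK", "A"), ("PER", "B")}
        out = validate_against_references(expected, expected)
        assert not out.false_negatives and not out.false_positives

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_set_arithmetic(self, seed):
        rng = random.Random(seed)
        universe = {(f"C{i}", f"ACC{i}") for i in range(20)}
        expected = {p for p in universe if rng.random() < 0.7}
        found = {p for p in universe if rng.random() < 0.7}
        out = validate_against_references(found, expected)
        assert out.true_positives == expected & found
        assert out.false_negatives == expected - found
        assert out.false_positives == found - expected
        assert out.true_positives | out.false_negatives == frozenset(expected)
        assert not (out.true_positives & out.false_negatives)


class TestRunComparison:
    def test_published_counts_reproduce_percentages(self):
        shared = {("s", f"x{i}", "CLK") for i in range(177)}
        only_a = {("s", f"a{i}", "CLK") for i in range(34)}
        only_b = {("s", f"b{i}", "CLK") for i in range(24)}
        out = compare_candidate_sets(shared | only_a, shared | only_b)
        assert (out["shared_pct"], out["only_a_pct"], out["only_b_pct"]) == \
            (75.3, 14.5, 10.2)

    def test_identical_sets(self):
        s = {("s", "x", "CLK")}
        out = compare_candidate_sets(s, s)
        assert (out["shared_pct"], out["only_a_pct"], out["only_b_pct"]) == \
            (100.0, 0.0, 0.0)

    def test_disjoint_sets(self):
        a = {("s", "a", "CLK")}
        b = {("s", f"b{i}", "CLK") for i in range(3)}
        out = compare_candidate_sets(a, b)
        assert (out["shared_pct"], out["only_a_pct"], out["only_b_pct"]) == \
            (0.0, 25.0, 75.0)

    def test_both_empty_error(self):
        with pytest.raises(ZeroDivisionError):
            compare_candidate_sets(set(), set())

    def test_percentages_sum_to_100(self):
        rng = random.Random(2)
        a = {("s", f"x{i}", "CLK") for i in range(rng.randint(1, 50))}
        b = {("s", f"x{i}", "CLK") for i in range(rng.randint(1, 50))}
        out = compare_candidate_sets(a, b)
        total = out["shared_pct"] + out["only_a_pct"] + out["only_b_pct"]
        assert abs(total - 100.0) <= 0.1


class TestFallbackHits:
    def _hits(self, rows):
        return pd.DataFrame(rows, columns=["species", "component", "target",
                                           "evalue", "bitscore",
                                           "qcov", "tcov"])

    def test_low_coverage_excluded_boundary_inclusive(self):
        hits = self._hits([("sp1", "CLK", "t1", 1e-30, 100, 0.15, 0.9),
                           ("sp1", "CLK", "t2", 1e-10, 50, 0.20, 0.20)])
        chosen, status = select_fallback_hits(
            hits, {"sp1": True}, set(), species=["sp1"])
        assert chosen["target"].tolist() == ["t2"]  # exactly 0.20 retained
        assert status.at["sp1", "CLK"] == "YES"

    def test_single_best_across_assemblies(self):
        hits = self._hits([("sp1", "PER", "a1_hit", 1e-30, 100, 0.9, 0.9),
                           ("sp1", "PER", "a2_hit", 1e-50, 90, 0.9, 0.9)])
        chosen, _ = select_fallback_hits(hits, {"sp1": True}, set(),
                                         species=["sp1"])
        per = chosen[chosen["component"] == "PER"]
        assert len(per) == 1 and per["target"].item() == "a2_hit"

    def test_no_data_is_nd_regardless_of_hits(self):
        hits = self._hits([("sp2", "CLK", "t", 1e-40, 100, 0.9, 0.9)])
        _, status = select_fallback_hits(hits, {"sp2": False}, set(),
                                         species=["sp2"])
        assert status.at["sp2", "CLK"] == "ND"

    def test_found_upstream_is_dash(self):
        _, status = select_fallback_hits(self._hits([]), {"sp1": True},
                                         {("sp1", "CLK")}, species=["sp1"])
        assert status.at["sp1", "CLK"] == "-"
        assert status.at["sp1", "PER"] == "NH"


def test_accession_extraction():
    assert accession_of("sp|O61735|CLK_DROME") == "O61735"
    assert accession_of("plainid") == "plainid"
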