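import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import enumerate_motif_8mers, lcs_length, mutate, random_protein
from conftest import candidates_from_fixture, hgcA_truth_ids
from hgcpipe.marker_screen import (
    CandidateGene,
    assign_taxonomy,
    check_hgcB,
    dedup_identical,
    filter_length,
    gate_by_evalue,
    global_identity,
    representatives,
    screen,
    select_representatives,
    verify_motif,
)


def make_cand(gene_id, seq, evalue=None, contig="c1", start=1, strand="+"):
    return CandidateGene(
        gene_id=gene_id, contig_id=contig, start=start,
        end=start + 3 * len(seq) - 1, strand=strand,
        aa_sequence=seq, evalue=evalue,
    )


SEQ120 = "ACDEFGHIKLMNPQRSTVWY" * 6


class TestCandidateGene:
    def test_rejects_bad_coordinates(self):
        with pytest.raises(ValueError, match="end < start"):
            CandidateGene("g", "c", 10, 5, "+", "MK")

    def test_rejects_lowercase_and_nonalphabet(self):
        with pytest.raises(ValueError):
            CandidateGene("g", "c", 1, 6, "+", "mk")
        with pytest.raises(ValueError):
            CandidateGene("g", "c", 1, 6, "+", "MJ")

    def test_rejects_empty_sequence(self):
        with pytest.raises(ValueError, match="empty"):
            CandidateGene("g", "c", 1, 6, "+", "")


class TestEvalueGate:
    def test_below_threshold_retained(self):
        c = make_cand("a", SEQ120, evalue=1e-30)
        assert gate_by_evalue([c]) == [c]

    def test_above_threshold_removed(self):
        c = make_cand("a", SEQ120, evalue=1e-20)
        assert gate_by_evalue([c]) == []

    def test_no_evalue_passes_through(self):
        c = make_cand("a", SEQ120, evalue=None)
        assert gate_by_evalue([c]) == [c]

    def test_counts_on_synthetic_set(self):
        # 40 candidates at/below 1e-25, 60 above, 5 without an e-value
        cands = [make_cand(f"lo{i}", SEQ120, evalue=1e-26) for i in range(40)]
        cands += [make_cand(f"hi{i}", SEQ120, evalue=1e-24) for i in range(60)]
        none_c = [make_cand(f"na{i}", SEQ120) for i in range(5)]
        kept = gate_by_evalue(cands + none_c)
        assert len(kept) == 45
        assert all(c.evalue is None or c.evalue <= 1e-25 for c in kept)

    def test_negative_evalue_rejected(self):
        c = make_cand("a", SEQ120)
        c.evalue = -1e-30  # bypass constructor check
        with pytest.raises(ValueError, match="negative"):
            gate_by_evalue([c])

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            gate_by_evalue([], threshold=0)


class TestVerifyMotif:
    def test_canonical_variant_in_context(self):
        seq = "MKLV" + "NVWCAAGK" + "TRRA"
        assert verify_motif(seq) == 5

    def test_alternate_degeneracies_alone(self):
        assert verify_motif("NIWCSGGK") == 1

    def test_disallowed_residue_fails(self):
        assert verify_motif("NLWCAAGK") is None

    def test_empty_sequence(self):
        assert verify_motif("") is None

    def test_x_never_matches_constrained_positions(self):
        for pos in range(8):
            seq = list("NVWCAAGK")
            seq[pos] = "X"
            assert verify_motif("".join(seq)) is None

    def test_enumeration_of_accepted_8mers(self):
        accepted = enumerate_motif_8mers()  # brute-force product oracle
        assert len(accepted) == 8
        for word in accepted:
            assert verify_motif(word) == 1
        # everything one substitution away from canonical, outside the
        # degenerate sets, must fail
        for pos in range(8):
            for aa in "LDQE":
                word = list("NVWCAAGK")
                word[pos] = aa
                if "".join(word) not in accepted:
                    assert verify_motif("".join(word)) is None

    @given(st.text(alphabet="ACDEFGHIKLMPQRSTVWY", min_size=0, max_size=300))
    def test_no_asparagine_no_match(self, seq):
        assert verify_motif(seq) is None

    @given(
        st.text(alphabet="ACDEFGHIKLMPQRSTVWY", min_size=0, max_size=100),
        st.sampled_from(sorted(enumerate_motif_8mers())),
    )
    def test_planted_variant_always_found(self, prefix, variant):
        assert verify_motif(prefix + variant) == len(prefix) + 1


class TestFilterLength:
    def test_99_discarded_100_retained(self):
        c99 = make_cand("a", "A" * 99)
        c100 = make_cand("b", "A" * 100)
        assert filter_length([c99]) == []
        assert filter_length([c100]) == [c100]

    def test_mixed_lengths(self):
        cands = {n: make_cand(f"g{n}", "A" * n) for n in (50, 99, 100, 350)}
        kept = filter_length(list(cands.values()))
        assert sorted(c.length_aa for c in kept) == [100, 350]

    def test_invalid_min(self):
        with pytest.raises(ValueError):
            filter_length([], min_aa=0)


class TestDedupIdentical:
    def test_exact_duplicates_collapse(self):
        a = make_cand("a", SEQ120)
        b = make_cand("b", SEQ120)
        clusters = dedup_identical([a, b])
        assert len(clusters) == 1
        _, members, rep = clusters[0]
        assert {m.gene_id for m in members} == {"a", "b"}
        assert rep.gene_id == "a"  # tie broken by smallest gene_id

    def test_prefix_joins_full_sequence(self):
        full = make_cand("full", SEQ120)
        pre = make_cand("pre", SEQ120[:80])
        clusters = dedup_identical([pre, full])
        assert len(clusters) == 1
        assert clusters[0][2].gene_id == "full"  # longest wins

    def test_unique_sequences_match_set_oracle(self):
        rng = np.random.default_rng(5)
        uniques = {random_protein(rng, int(rng.integers(110, 200))) for _ in range(25)}
        cands = [make_cand(f"u{i:02d}", s) for i, s in enumerate(sorted(uniques))]
        # add duplicates and substrings that must not create clusters
        cands.append(make_cand("zdup", cands[0].aa_sequence))
        cands.append(make_cand("zsub", cands[1].aa_sequence[10:90]))
        clusters = dedup_identical(cands)
        assert len(clusters) == len(uniques)  # oracle: exact-set dedup
        reps = {rep.aa_sequence for _, _, rep in clusters}
        assert reps == uniques

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dedup_identical([])


class TestIdentityAndRepresentatives:
    def test_identity_matches_lcs_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            a = random_protein(rng, int(rng.integers(30, 120)))
            b = random_protein(rng, int(rng.integers(30, 120)))
            expected = lcs_length(a, b) / min(len(a), len(b))
            assert global_identity(a, b) == pytest.approx(expected, abs=1e-12)

    def test_identical_sequences_single_representative(self):
        assert select_representatives({"a": SEQ120, "b": SEQ120}) == ["a"]

    def test_unrelated_random_sequences_stay_apart(self):
        rng = np.random.default_rng(3)
        a, b = random_protein(rng, 200), random_protein(rng, 200)
        assert lcs_length(a, b) / 200 < 0.5  # alignment oracle
        assert len(select_representatives({"a": a, "b": b})) == 2

    def test_twelve_planted_families(self):
        rng = np.random.default_rng(42)
        seqs = {}
        founders = []
        for f in range(12):
            founder = random_protein(rng, 200)
            founders.append(founder)
            for v in range(3):
                # <= 40% substitutions keeps within-family identity >= 60%
                seqs[f"fam{f:02d}_v{v}"] = (
                    founder if v == 0 else mutate(rng, founder, 70)
                )
        # verify the cross-family identities are below threshold (oracle)
        for x, y in itertools.combinations(founders, 2):
            assert lcs_length(x, y) / 200 < 0.5
        reps = select_representatives(seqs, identity=0.5)
        assert len(reps) == 12

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            select_representatives({"a": "MK"}, identity=0.0)


class TestCheckHgcB:
    def test_planted_tandem_pair(self, small_fixture):
        cands = {c.gene_id: c for c in candidates_from_fixture(small_fixture)}
        roles = small_fixture.truth.roles
        for gid in roles.loc[roles["role"] == "hgcA", "gene_id"]:
            hgcA = cands[gid]
            neighbors = [c for c in cands.values() if c.contig_id == hgcA.contig_id]
            partner = check_hgcB(hgcA, neighbors)
            assert partner == gid.replace("_hgcA", "_hgcB")

    def _pair(self, b_seq, gap=21, length_ok=True, strand="+"):
        hgcA = make_cand("ha", SEQ120, start=1000, strand=strand)
        b_start = hgcA.end + gap
        return hgcA, CandidateGene(
            "hb", "c1", b_start, b_start + 3 * len(b_seq) - 1, strand, b_seq
        )

    def test_single_motif_not_paired(self):
        one_motif = "CAACAACAAAC" + "G" * 60
        hgcA, hb = self._pair(one_motif)
        assert check_hgcB(hgcA, [hb]) is None

    def test_two_motifs_paired(self):
        two = "CAACAACAAAC" + "G" * 20 + "CAACAACAAAC" + "G" * 30
        hgcA, hb = self._pair(two)
        assert check_hgcB(hgcA, [hb]) == "hb"

    def test_distance_rule(self):
        two = "CAACAACAAAC" + "G" * 20 + "CAACAACAAAC" + "G" * 30
        hgcA, hb = self._pair(two, gap=2000)
        assert check_hgcB(hgcA, [hb]) is None

    def test_length_rule(self):
        two = "CAACAACAAAC" + "G" * 20 + "CAACAACAAAC" + "G" * 80  # >= 100 aa
        hgcA, hb = self._pair(two)
        assert check_hgcB(hgcA, [hb]) is None

    def test_minus_strand_downstream_is_upstream_in_coordinates(self):
        two = "CAACAACAAAC" + "G" * 20 + "CAACAACAAAC" + "G" * 30
        hgcA = CandidateGene("ha", "c1", 2000, 2000 + 3 * 120 - 1, "-", SEQ120)
        b_end = hgcA.start - 21
        hb = CandidateGene("hb", "c1", b_end - 3 * len(two) + 1, b_end, "-", two)
        assert check_hgcB(hgcA, [hb]) == "hb"
        # same gene on the plus strand is not downstream
        hb_plus = CandidateGene("hb2", "c1", hb.start, hb.end, "+", two)
        hgcA_plus = CandidateGene("ha2", "c1", 2000, hgcA.end, "+", SEQ120)
        assert check_hgcB(hgcA_plus, [hb_plus]) is None


class TestAssignTaxonomy:
    bin_map = pd.DataFrame(
        {"gene_id": ["g1"], "bin_id": ["bin7"], "taxonomy": ["Desulfobacterota"]}
    )
    best_hit = pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g2"],
            "taxonomy": ["WrongLabel", "Chloroflexota", "Planctomycetota"],
            "rank": [1, 2, 1],
        }
    )

    def test_bin_map_takes_precedence(self):
        assert assign_taxonomy("g1", self.bin_map, self.best_hit) == (
            "Desulfobacterota", "bin_map",
        )

    def test_best_hit_top_rank(self):
        assert assign_taxonomy("g2", self.bin_map, self.best_hit) == (
            "Planctomycetota", "best_hit",
        )

    def test_unassigned(self):
        assert assign_taxonomy("g3", self.bin_map, self.best_hit) == (
            "unassigned", "unassigned",
        )

    def test_conflicting_bin_rows_rejected(self):
        conflict = pd.DataFrame(
            {"gene_id": ["g1", "g1"], "bin_id": ["a", "b"], "taxonomy": ["X", "Y"]}
        )
        with pytest.raises(ValueError, match="conflicting"):
            assign_taxonomy("g1", conflict, None)


class TestScreen:
    def test_exact_recovery_on_decoy_fixture(self, decoy_fixture, decoy_candidates):
        validated = screen(decoy_candidates)
        reps = {v.gene_id for v in representatives(validated)}
        assert reps == hgcA_truth_ids(decoy_fixture)

    def test_only_decoys_empty_output(self, decoy_fixture, decoy_candidates):
        roles = decoy_fixture.truth.roles
        decoy_ids = set(roles.loc[roles["role"].str.endswith("decoy"), "gene_id"])
        only_decoys = [c for c in decoy_candidates if c.gene_id in decoy_ids]
        assert screen(only_decoys) == []

    def test_order_invariance(self, decoy_candidates):
        base = screen(decoy_candidates)
        rng = np.random.default_rng(0)
        shuffled = list(decoy_candidates)
        rng.shuffle(shuffled)
        assert screen(shuffled) == base

    def test_idempotence(self, decoy_candidates):
        first = screen(decoy_candidates)
        again = screen(
            [
                make_cand(v.gene_id, v.aa_sequence)
                for v in first
            ]
        )
        assert {v.gene_id for v in representatives(again)} == {
            v.gene_id for v in representatives(first)
        }
        assert {v.aa_sequence for v in again} == {v.aa_sequence for v in first}

    def test_soundness_invariant(self, decoy_candidates):
        for v in screen(decoy_candidates):
            assert verify_motif(v.aa_sequence) == v.motif_start
            assert len(v.aa_sequence) >= 100
        clusters = {}
        for v in screen(decoy_candidates):
            clusters.setdefault(v.cluster_id, []).append(v.is_representative)
        for flags in clusters.values():
            assert sum(flags) == 1  # exactly one representative per cluster

    def test_filter_order_does_not_matter(self, decoy_candidates):
        gated = gate_by_evalue(decoy_candidates)
        motif_then_length = filter_length(
            [c for c in gated if verify_motif(c.aa_sequence) is not None]
        )
        length_then_motif = [
            c for c in filter_length(gated) if verify_motif(c.aa_sequence) is not None
        ]
        assert {c.gene_id for c in motif_then_length} == {
            c.gene_id for c in length_then_motif
        }

    def test_taxonomy_attached(self, decoy_candidates):
        some_gene = screen(decoy_candidates)[0].gene_id
        bin_map = pd.DataFrame(
            {"gene_id": [some_gene], "bin_id": ["b"], "taxonomy": ["TestPhylum"]}
        )
        validated = screen(decoy_candidates, bin_map=bin_map)
        by_id = {v.gene_id: v for v in validated}
        assert by_id[some_gene].taxonomy_label == "TestPhylum"
        assert by_id[some_gene].taxonomy_source == "bin_map"
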