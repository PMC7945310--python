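import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from becorr.guides import enumerate_guides
from becorr.outcomes import (
    anchor_and_extract,
    assign_to_library,
    background_rates,
    call_edits,
    corrected_fractions,
    flag_recombinants,
    jaro_similarity,
    merge_and_pick_major,
    outcome_fraction,
    parse_outcome_key,
    tally_outcomes,
)
from oracles import fk_recount, jaro_reference

SCAFFOLD = "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGG"  # >=20 nt anchor


class TestJaro:
    def test_identity(self):
        assert jaro_similarity("ACGT", "ACGT") == 1.0

    def test_hand_evaluated_transposition(self):
        assert jaro_similarity("MARTHA", "MARHTA") == pytest.approx(17 / 18)

    def test_empty_conventions(self):
        assert jaro_similarity("", "ACGT") == 0.0
        assert jaro_similarity("", "") == 1.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", max_size=12), st.text(alphabet="ACGT", max_size=12))
    def test_symmetric_bounded_and_matches_reference(self, a, b):
        s = jaro_similarity(a, b)
        assert 0.0 <= s <= 1.0
        assert s == pytest.approx(jaro_similarity(b, a))
        assert s == pytest.approx(jaro_reference(a, b))


class TestAnchorExtract:
    SPACER = "ACGTACGTACGTACGTACGT"
    TARGET = "TTTACGTACGTACGTACGTACGTGGC"  # 26 nt

    def read(self, scaffold=SCAFFOLD):
        return self.SPACER + scaffold + self.TARGET

    def test_exact_construction(self):
        rec = anchor_and_extract(self.read(), SCAFFOLD, read_id="r1")
        assert rec is not None
        assert rec.spacer_obs == self.SPACER
        assert rec.target_obs == self.TARGET
        assert rec.scaffold_mismatches == 0

    @pytest.mark.parametrize("n_subs,accepted", [(3, True), (4, False)])
    def test_mismatch_threshold(self, n_subs, accepted):
        corrupted = list(SCAFFOLD)
        for i in range(n_subs):
            pos = 3 + 5 * i
            corrupted[pos] = "A" if corrupted[pos] != "A" else "C"
        rec = anchor_and_extract(self.read("".join(corrupted)), SCAFFOLD)
        assert (rec is not None) == accepted

    def test_ambiguous_double_scaffold_rejected(self):
        read = self.SPACER + SCAFFOLD + SCAFFOLD + self.TARGET
        assert anchor_and_extract(read, SCAFFOLD) is None

    def test_short_flanks_rejected(self):
        assert anchor_and_extract("ACGT" + SCAFFOLD + self.TARGET, SCAFFOLD) is None
        assert anchor_and_extract(self.SPACER + SCAFFOLD + "ACGT", SCAFFOLD) is None


@pytest.fixture()
def toy_library():
    seq1 = "TTT" + "AAAAACAAAAAAAAAAAAAA" + "AGG" + "TTTT"
    seq2 = "TTT" + "GGGGGCGGGGGGGGGGGGGG" + "TGG" + "TTTT"
    refs = {"k1": seq1, "k2": seq2}
    lib = []
    for contig in refs:
        g = [x for x in enumerate_guides({contig: refs[contig]}, "CBE", "NGG")
             if x.strand == "+" and x.protospacer_start == 3]
        lib.append(g[0])
    return refs, lib


class TestAssign:
    def _record(self, spacer, target):
        from becorr.outcomes import PairedReadRecord

        return PairedReadRecord(read_id="r", spacer_obs=spacer, target_obs=target)

    def test_exact_match(self, toy_library):
        refs, lib = toy_library
        target = "TTT" + lib[0].spacer + "AGG"
        recs = assign_to_library([self._record(lib[0].spacer, target)], lib)
        assert recs[0].guide_id == lib[0].guide_id

    def test_two_mismatches_unique_neighbor(self, toy_library):
        refs, lib = toy_library
        spacer = "TT" + lib[0].spacer[2:]
        target = "TTT" + lib[0].spacer + "AGG"
        recs = assign_to_library([self._record(spacer, target)], lib)
        assert recs[0].guide_id == lib[0].guide_id

    def test_four_mismatches_unassigned(self, toy_library):
        refs, lib = toy_library
        spacer = "TTTT" + lib[0].spacer[4:]
        target = "TTT" + lib[0].spacer + "AGG"
        recs = assign_to_library([self._record(spacer, target)], lib)
        assert recs[0].guide_id is None

    def test_equidistant_tie_unassigned(self):
        refs = {"k1": "TTT" + "AACCAACCAACCAACCAACC" + "AGG",
                "k2": "TTT" + "AACCAACCAACCAACCAATT" + "AGG"}
        lib = []
        for contig in refs:
            g = [x for x in enumerate_guides({contig: refs[contig]}, "CBE", "NGG")
                 if x.strand == "+" and x.protospacer_start == 3]
            lib.append(g[0])
        # one mismatch to each design
        spacer = "AACCAACCAACCAACCAACT"
        assert {g.spacer for g in lib} == {"AACCAACCAACCAACCAACC", "AACCAACCAACCAACCAATT"}
        target = "TTT" + spacer + "AGG"
        recs = assign_to_library([self._record(spacer, target)], lib)
        assert recs[0].guide_id is None

    def test_pam_inconsistent_unassigned(self, toy_library):
        refs, lib = toy_library
        target = "TTT" + lib[0].spacer + "ATT"  # not NGG
        recs = assign_to_library([self._record(lib[0].spacer, target)], lib)
        assert recs[0].guide_id is None


class TestCallEdits:
    def test_single_canonical_transition(self):
        ref = "TTT" + "AAACCTAAAAAAAAAAAAAA" + "AGG"
        obs = "TTT" + "AAACTTAAAAAAAAAAAAAA" + "AGG"  # C at position 5 -> T
        assert call_edits(obs, ref, "CBE") == "5:C>T"

    def test_two_cs_both_converted(self):
        ref = "TTT" + "AAACCTAAAAAAAAAAAAAA" + "AGG"
        obs = "TTT" + "AAATTTAAAAAAAAAAAAAA" + "AGG"
        assert call_edits(obs, ref, "CBE") == "4:C>T+5:C>T"

    def test_non_canonical_only_is_other(self):
        ref = "TTT" + "AAAGGTAAAAAAAAAAAAAA" + "AGG"
        obs = "TTT" + "AAAAGTAAAAAAAAAAAAAA" + "AGG"  # G->A: not canonical for ABE
        assert call_edits(obs, ref, "ABE") == "other"

    def test_unedited(self):
        ref = "TTT" + "AAACCTAAAAAAAAAAAAAA" + "AGG"
        assert call_edits(ref, ref, "CBE") == "unedited"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            call_edits("ACGT", "ACGTA", "CBE")

    def test_key_round_trip(self):
        assert parse_outcome_key("4:C>T+7:C>T") == [(4, "C", "T"), (7, "C", "T")]


class TestOutcomeFraction:
    def test_no_background(self):
        assert outcome_fraction([30], [100], 0.0) == pytest.approx(0.30)

    def test_with_background(self):
        assert outcome_fraction([30], [100], 0.1) == pytest.approx(20 / 90)

    def test_background_only_clamps_to_zero(self):
        assert outcome_fraction([10], [100], 0.1) == 0.0

    def test_zero_depth_sample_excluded(self):
        assert outcome_fraction([30, 0], [100, 0], 0.0) == pytest.approx(0.30)

    def test_all_zero_depth_raises(self):
        with pytest.raises(ValueError):
            outcome_fraction([0, 0], [0, 0], 0.0)


def test_fk_matches_per_read_recount(toy_library):
    """Formula-based f_k equals a brute-force recount over synthetic reads."""
    refs, lib = toy_library
    g = lib[0]
    rng = np.random.default_rng(9)
    ref_target = "TTT" + g.spacer + "AGGT"[:3]
    from becorr.outcomes import PairedReadRecord, reference_target

    rt = reference_target(g, refs)
    key = f"{g.target_offset}:C>T"
    edited_reads, control_reads = [], []
    for sample, p_edit, n in (("e1", 0.3, 400), ("e2", 0.25, 300)):
        ks = []
        for i in range(n):
            if rng.random() < p_edit:
                obs = list(rt)
                obs[3 + g.target_offset - 1] = "T"
                ks.append("".join(obs))
            else:
                ks.append(rt)
        edited_reads.append((sample, ks))
    for sample, p_bg, n in (("c1", 0.05, 500),):
        ks = []
        for i in range(n):
            obs = list(rt)
            if rng.random() < p_bg:
                obs[3 + g.target_offset - 1] = "T"
            ks.append("".join(obs))
        control_reads.append((sample, ks))

    def to_records(reads_per_sample):
        recs, owner = [], {}
        for sample, seqs in reads_per_sample:
            for i, t in enumerate(seqs):
                rid = f"{sample}.{i}"
                recs.append(PairedReadRecord(read_id=rid, spacer_obs=g.spacer,
                                             target_obs=t))
                owner[rid] = sample
        return recs, owner

    e_recs, e_owner = to_records(edited_reads)
    c_recs, c_owner = to_records(control_reads)
    e_recs = assign_to_library(e_recs, lib)
    c_recs = assign_to_library(c_recs, lib)
    e_tal = tally_outcomes(e_recs, lib, refs, e_owner, ["e1", "e2"])
    c_tal = tally_outcomes(c_recs, lib, refs, c_owner, ["c1"])
    h = background_rates(c_tal)
    frac = corrected_fractions(e_tal, h)
    got = frac.loc[frac["outcome_key"] == key, "f_k"].iloc[0]

    edited_keys = [[call_edits(t, rt, "CBE") for t in ks] for _s, ks in edited_reads]
    control_keys = [[call_edits(t, rt, "CBE") for t in ks] for _s, ks in control_reads]
    assert got == pytest.approx(fk_recount(edited_keys, control_keys, key), abs=1e-12)


class TestMergeAndMajor:
    def _fractions(self, rows):
        return pd.DataFrame(rows)

    def test_same_aa_outcomes_merge_and_sum(self):
        fractions = self._fractions([
            {"guide_id": "g", "outcome_key": "5:C>T", "f_k": 0.10, "h_c": 0.0,
             "f_e1": 0.1, "f_e2": 0.1, "R_e1": 100, "R_e2": 100, "D_e1": 1000, "D_e2": 1000},
            {"guide_id": "g", "outcome_key": "5:C>T+6:C>T", "f_k": 0.05, "h_c": 0.0,
             "f_e1": 0.05, "f_e2": 0.05, "R_e1": 50, "R_e2": 50, "D_e1": 1000, "D_e2": 1000},
        ])
        annotations = pd.DataFrame([
            {"guide_id": "g", "outcome_key": "5:C>T", "aa_changes": "Y2C",
             "mutational_type": "nonsynonymous", "nucleotide_changes": "8C>T"},
            {"guide_id": "g", "outcome_key": "5:C>T+6:C>T", "aa_changes": "Y2C",
             "mutational_type": "nonsynonymous", "nucleotide_changes": "8C>T;9C>T"},
        ])
        outcomes, eff = merge_and_pick_major(fractions, annotations, ["e1", "e2"])
        assert len(outcomes) == 1
        assert outcomes["f_k"].iloc[0] == pytest.approx(0.15)
        assert eff["q_raw"].iloc[0] == pytest.approx(0.15)
        assert bool(eff["passed_filters"].iloc[0])

    def test_low_coverage_in_all_replicates_removed(self):
        fractions = self._fractions([
            {"guide_id": "g", "outcome_key": "5:C>T", "f_k": 0.5, "h_c": 0.0,
             "f_e1": 0.5, "f_e2": 0.5, "R_e1": 25, "R_e2": 25, "D_e1": 50, "D_e2": 50},
        ])
        annotations = pd.DataFrame([
            {"guide_id": "g", "outcome_key": "5:C>T", "aa_changes": "Y2C",
             "mutational_type": "nonsynonymous", "nucleotide_changes": "8C>T"},
        ])
        _, eff = merge_and_pick_major(fractions, annotations, ["e1", "e2"])
        assert not bool(eff["passed_filters"].iloc[0])

    def test_one_good_replicate_is_enough(self):
        fractions = self._fractions([
            {"guide_id": "g", "outcome_key": "5:C>T", "f_k": 0.3, "h_c": 0.0,
             "f_e1": 0.3, "f_e2": 0.3, "R_e1": 25, "R_e2": 60, "D_e1": 80, "D_e2": 200},
        ])
        annotations = pd.DataFrame([
            {"guide_id": "g", "outcome_key": "5:C>T", "aa_changes": "Y2C",
             "mutational_type": "nonsynonymous", "nucleotide_changes": "8C>T"},
        ])
        _, eff = merge_and_pick_major(fractions, annotations, ["e1", "e2"])
        assert bool(eff["passed_filters"].iloc[0])

    def test_major_tie_breaks_by_fewer_positions(self):
        fractions = self._fractions([
            {"guide_id": "g", "outcome_key": "5:C>T+6:C>T", "f_k": 0.2, "h_c": 0.0,
             "f_e1": 0.2, "f_e2": 0.2, "R_e1": 200, "R_e2": 200, "D_e1": 1000, "D_e2": 1000},
            {"guide_id": "g", "outcome_key": "5:C>T", "f_k": 0.2, "h_c": 0.0,
             "f_e1": 0.2, "f_e2": 0.2, "R_e1": 200, "R_e2": 200, "D_e1": 1000, "D_e2": 1000},
        ])
        annotations = pd.DataFrame([
            {"guide_id": "g", "outcome_key": "5:C>T+6:C>T", "aa_changes": "Y2C;S3F",
             "mutational_type": "nonsynonymous", "nucleotide_changes": "a"},
            {"guide_id": "g", "outcome_key": "5:C>T", "aa_changes": "Y2C",
             "mutational_type": "nonsynonymous", "nucleotide_changes": "b"},
        ])
        outcomes, eff = merge_and_pick_major(fractions, annotations, ["e1", "e2"])
        major = outcomes[outcomes["is_major"]]
        assert major["outcome_key"].iloc[0] == "5:C>T"

    def test_priority_stop_gain_over_synonymous(self):
        fractions = self._fractions([
            {"guide_id": "g", "outcome_key": "4:C>T+5:C>T", "f_k": 0.2, "h_c": 0.0,
             "f_e1": 0.2, "f_e2": 0.2, "R_e1": 200, "R_e2": 200, "D_e1": 1000, "D_e2": 1000},
        ])
        annotations = pd.DataFrame([
            {"guide_id": "g", "outcome_key": "4:C>T+5:C>T", "aa_changes": "Q5*",
             "mutational_type": "stop_gain", "nucleotide_changes": "x"},
        ])
        outcomes, _ = merge_and_pick_major(fractions, annotations, ["e1", "e2"])
        assert outcomes["mutational_type"].iloc[0] == "stop_gain"


def test_coediting_counts_conserved():
    """Single-edit + co-edit tallies add up to the total edited reads."""
    from becorr.outcomes import PairedReadRecord, reference_target

    seq = "TTT" + "AAACCTAAAAAAAAAAAAAA" + "AGGT"
    refs = {"cc": seq}
    g = [x for x in enumerate_guides(refs, "CBE", "NGG")
         if x.strand == "+" and x.protospacer_start == 3][0]
    rt = reference_target(g, refs)
    rng = np.random.default_rng(1)
    recs, owner = [], {}
    n_single = n_co = n_unedited = 0
    for i in range(500):
        u = rng.random()
        obs = list(rt)
        if u < 0.3:
            obs[3 + 3] = "T"  # window position 4
            n_single += 1
        elif u < 0.5:
            obs[3 + 3] = "T"
            obs[3 + 4] = "T"  # positions 4 and 5
            n_co += 1
        else:
            n_unedited += 1
        rid = f"e1.{i}"
        recs.append(PairedReadRecord(read_id=rid, spacer_obs=g.spacer,
                                     target_obs="".join(obs)))
        owner[rid] = "e1"
    recs = assign_to_library(recs, [g])
    tal = tally_outcomes(recs, [g], refs, owner, ["e1"])
    r = tal.set_index("outcome_key")["R"]
    assert r["4:C>T"] == n_single
    assert r["4:C>T+5:C>T"] == n_co
    # conservation: canonical tallies account for every edited read
    assert int(tal["R"].sum()) == 500 - n_unedited
    assert tal["D"].iloc[0] == 500
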