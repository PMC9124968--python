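"""CDR3 anchoring and junction decomposition."""

import math

import pytest

import igjunction as ig
from igjunction.junction import decompose_junction, junction_length_stats, locate_cdr3
from igjunction.pipeline import RunConfig, annotate_read, annotate_reads
from igjunction.qc import Read
from igjunction.records import RearrangementRecord

from _oracles import (J_SEQ, V_SEQ, all_inserts, make_instance,
                      micro_germline, oracle_decompose)


# ---------------------------------------------------------------------------
# CDR3 anchoring


def test_cdr3_between_conserved_anchors(igh_run):
    """Simulated reads with recorded true CDR3: exact interval recovery."""
    _, truths, records, _ = igh_run
    located = 0
    for rec, truth in zip(records, truths):
        assert rec.cdr3 is not None
        assert (rec.cdr3.nt_start, rec.cdr3.nt_end) == (truth.cdr3_start, truth.cdr3_end)
        located += 1
    assert located == len(records)


def test_cdr3_anchor_motifs_flank_interval(toy_igh):
    """The nt before the CDR3 end with the Cys codon; WGXG follows it."""
    from igjunction._seq import translate

    cfg = ig.SimulationConfig(locus="IGH", n_reads=20, seed=44, shm_rate=0.0)
    reads, _, _ = ig.simulate_repertoire(cfg, toy_igh)
    records = annotate_reads(reads, toy_igh, RunConfig(locus="IGH"))
    for rec in records:
        c = rec.cdr3
        seq = rec.read.nt_sequence
        assert translate(seq[c.anchor_c_position : c.anchor_c_position + 3]) == "C"
        wgxg = translate(seq[c.anchor_wf_position : c.anchor_wf_position + 12])
        assert wgxg[0] == "W" and wgxg[1] == "G" and wgxg[3] == "G"


def test_anchor_shm_does_not_move_projected_anchor(toy_igh):
    """A mutated anchor codon is still placed by projection, flagged as mismatch."""
    cfg = ig.SimulationConfig(locus="IGH", n_reads=1, seed=9, shm_rate=0.0)
    reads, truths, _ = ig.simulate_repertoire(cfg, toy_igh)
    read, truth = reads[0], truths[0]
    rec0 = annotate_read(read, toy_igh, RunConfig(locus="IGH"))
    assert rec0.cdr3.anchor_mismatches == 0
    # mutate the middle base of the Cys-104 codon: TGT -> TAT (Ser frame kept)
    pos = truth.cdr3_start - 2
    seq = read.nt_sequence
    assert seq[pos] == "G"
    mutated = Read("m", seq[:pos] + "A" + seq[pos + 1 :])
    rec = annotate_read(mutated, toy_igh, RunConfig(locus="IGH"))
    assert (rec.cdr3.nt_start, rec.cdr3.nt_end) == (truth.cdr3_start, truth.cdr3_end)
    assert rec.cdr3.anchor_mismatches == 1


# ---------------------------------------------------------------------------
# decomposition: constructed cases


def test_blunt_join():
    gs = micro_germline()
    read_seq, v_aln, j_aln = make_instance(0, 0, "")
    d = decompose_junction(Read("r", read_seq), v_aln, j_aln, gs)
    assert d.v_deletion == 0 and d.j_deletion == 0
    assert d.p1 == d.p2 == d.n1 == ""
    assert not d.ambiguous


def test_palindromic_overhang():
    """V ends ...GATTC untrimmed; insert GA|T; GA is the P overhang."""
    gs = micro_germline()
    assert V_SEQ.endswith("GATTC")
    read_seq, v_aln, j_aln = make_instance(0, 0, "GAT")
    d = decompose_junction(Read("r", read_seq), v_aln, j_aln, gs)
    assert d.p1 == "GA" and d.n1 == "T" and d.p2 == ""
    assert d.v_deletion == 0 and d.j_deletion == 0


def test_p_legality_and_reconstruction_on_grid_sample():
    gs = micro_germline()
    for v_del in range(5):
        for j_del in range(5):
            for insert in ("", "A", "GA", "TTG"):
                read_seq, v_aln, j_aln = make_instance(v_del, j_del, insert)
                d = decompose_junction(Read("r", read_seq), v_aln, j_aln, gs)
                d.check()  # reconstruction + P legality invariants


def test_decomposition_matches_enumeration_oracle_small_grid():
    gs = micro_germline()
    n_checked = 0
    for v_del in range(5):
        for j_del in range(5):
            for insert in all_inserts(2):
                read_seq, v_aln, j_aln = make_instance(v_del, j_del, insert)
                d = decompose_junction(Read("r", read_seq), v_aln, j_aln, gs)
                o = oracle_decompose(read_seq)
                assert d.ambiguous == o["ambiguous"], (v_del, j_del, insert)
                if not o["ambiguous"]:
                    got = {"v_deletion": d.v_deletion, "j_deletion": d.j_deletion,
                           "p1": d.p1, "n1": d.n1, "p2": d.p2}
                    assert got == {k: o[k] for k in got}, (v_del, j_del, insert)
                n_checked += 1
    assert n_checked == 25 * 21


def test_trim_recovery_exact_on_clean_simulated_records(igk_run, toy_igk):
    from conftest import truth_trim_is_clean

    _, truths, records, _ = igk_run
    clean = checked = 0
    for rec, truth in zip(records, truths):
        if not truth_trim_is_clean(truth, toy_igk):
            continue
        clean += 1
        d = rec.decomposition
        assert d is not None
        assert d.v_deletion == truth.v_deletion
        assert d.j_deletion == truth.j_deletion
        checked += 1
    assert clean > 100 and checked == clean


# ---------------------------------------------------------------------------
# stats


def _stub_record(rid, cdr3_nt_len):
    from igjunction.junction import Cdr3

    nt = "GCT" * (cdr3_nt_len // 3) + "A" * (cdr3_nt_len % 3)
    cdr3 = Cdr3(nt_start=0, nt_end=cdr3_nt_len, nt_sequence=nt,
                aa_sequence="A" * (cdr3_nt_len // 3) if cdr3_nt_len % 3 == 0 else "",
                anchor_c_position=0, anchor_wf_position=cdr3_nt_len)
    return RearrangementRecord(read=Read(rid, nt or "A"), cdr3=cdr3)


def test_junction_length_stats_two_point_set():
    records = [_stub_record("a", 15), _stub_record("b", 129)]  # 5 and 43 AA
    stats = junction_length_stats(records)
    aa = stats["cdr3_aa_len"]
    assert aa["mean"] == pytest.approx(24.0)
    assert set(aa["counts"]) == {5, 43}
    assert aa["sd"] == pytest.approx(19.0)


def test_junction_length_stats_empty_and_missing():
    empty = junction_length_stats([])
    assert empty["cdr3_nt_len"]["n"] == 0
    assert math.isnan(empty["cdr3_nt_len"]["mean"])
    missing = RearrangementRecord(read=Read("x", "ACGT"))
    stats = junction_length_stats([missing, _stub_record("a", 30)])
    assert stats["excluded"] == 1
    assert stats["cdr3_nt_len"]["n"] == 1


def test_cdr3_length_consistency_with_decomposition(igk_run):
    """CDR3 nt length = retained V + p1 + n1 + p2 + retained J, per record."""
    _, _, records, _ = igk_run
    for rec in records:
        if rec.cdr3 is None or rec.decomposition is None:
            continue
        d = rec.decomposition
        total = (d.retained_v_len + len(d.p1) + len(d.n1) + len(d.p_d5)
                 + len(d.retained_d) + len(d.p_d3) + len(d.n2) + len(d.p2)
                 + d.retained_j_len)
        assert rec.cdr3.nt_length == total
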