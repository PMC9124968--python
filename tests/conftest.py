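import pytest

import igjunction as ig
from igjunction.pipeline import RunConfig, annotate_reads


@pytest.fixture(scope="session")
def toy_igh():
    return ig.make_toy_germline(0, "IGH")


@pytest.fixture(scope="session")
def toy_igk():
    return ig.make_toy_germline(0, "IGK")


@pytest.fixture(scope="session")
def igh_run(toy_igh):
    """A small annotated IGH simulation shared across tests."""
    cfg = ig.SimulationConfig(locus="IGH", n_reads=300, seed=11)
    reads, truths, rcfg = ig.simulate_repertoire(cfg, toy_igh)
    records = annotate_reads(reads, toy_igh, RunConfig(locus="IGH"))
    return reads, truths, records, rcfg


@pytest.fixture(scope="session")
def igk_run(toy_igk):
    cfg = ig.SimulationConfig(locus="IGK", n_reads=300, seed=12)
    reads, truths, rcfg = ig.simulate_repertoire(cfg, toy_igk)
    records = annotate_reads(reads, toy_igk, RunConfig(locus="IGK"))
    return reads, truths, records, rcfg


def truth_trim_is_clean(truth, germline_set):
    """Truth-side oracle: are the simulated trims recoverable unambiguously?

    A junction is clean when the read base adjacent to each trimmed germline
    end does not coincidentally continue the germline, so maximal templated
    attribution recovers the simulated deletions exactly.
    """
    vgene = germline_set[truth.v_id]
    jgene = germline_set[truth.j_id]
    v_tail = vgene.nt_sequence[vgene.region_bounds["FR3"][1] :]
    middle = truth.p1 + truth.n1
    if truth.d_id is not None:
        dgene = germline_set[truth.d_id]
        dl = len(dgene.nt_sequence)
        middle += (truth.p_d5
                   + dgene.nt_sequence[truth.d_deletion_5p : dl - truth.d_deletion_3p]
                   + truth.p_d3 + truth.n2)
    middle += truth.p2
    j_5p_ret = jgene.nt_sequence[truth.j_deletion :][: _anchor(jgene) - truth.j_deletion]
    insert_plus_j = middle + j_5p_ret
    if truth.v_deletion > 0:
        next_v = v_tail[len(v_tail) - truth.v_deletion]
        if insert_plus_j and insert_plus_j[0] == next_v:
            return False
    tail_ret = v_tail[: len(v_tail) - truth.v_deletion]
    before_j = tail_ret + middle
    if truth.j_deletion > 0:
        prev_j = jgene.nt_sequence[truth.j_deletion - 1]
        if before_j and before_j[-1] == prev_j:
            return False
    return True


def _anchor(jgene):
    from igjunction.germline import j_anchor_offset

    return j_anchor_offset(jgene)
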