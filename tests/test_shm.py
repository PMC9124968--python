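"""SHM frequency, per-site profiles, substitution spectrum, hotspot analysis."""

import math
import re

import numpy as np
import pytest

import igjunction as ig
from igjunction.pipeline import RunConfig, annotate_read, annotate_reads
from igjunction.qc import Read
from igjunction.shm import (hotspot_analysis, per_site_profile, scan_hotspots,
                            shm_frequency, substitution_spectrum)


def _reads_with_substitutions(toy, positions_to_base, n_reads=1, locus="IGH"):
    """Noise-free simulated reads with hand-placed substitutions in the V window."""
    cfg = ig.SimulationConfig(locus=locus, n_reads=n_reads, seed=3, shm_rate=0.0)
    reads, truths, _ = ig.simulate_repertoire(cfg, toy)
    v_start = len(ig.simulate.FWD_PRIMER)
    out = []
    for read, truth in zip(reads, truths):
        seq = list(read.nt_sequence)
        for pos, base in positions_to_base.items():
            seq[v_start + pos] = base
        out.append((Read(read.read_id, "".join(seq)), truth))
    return out


def test_shm_frequency_formula(toy_igh):
    """3 substitutions over the 312 nt aligned V window."""
    (_, truth), = _reads_with_substitutions(toy_igh, {})
    vseq = toy_igh[truth.v_id].v_region()
    # choose 3 positions and force a different base at each
    subs = {}
    for pos in (10, 150, 300):
        subs[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[vseq[pos]]
    (read, truth), = _reads_with_substitutions(toy_igh, subs)
    rec = annotate_read(read, toy_igh, RunConfig(locus="IGH"))
    stats = shm_frequency([rec], toy_igh)
    assert stats["mutated"] == 3
    assert stats["covered"] == 312
    assert stats["overall_percent"] == pytest.approx(100.0 * 3 / 312)
    assert stats["per_gene_percent"][truth.v_id] == stats["overall_percent"]


def test_shm_frequency_zero_and_empty(toy_igh):
    (read, _), = _reads_with_substitutions(toy_igh, {})
    rec = annotate_read(read, toy_igh, RunConfig(locus="IGH"))
    assert shm_frequency([rec], toy_igh)["overall_percent"] == 0.0
    assert math.isnan(shm_frequency([], toy_igh)["overall_percent"])


def test_shm_rate_recovery_within_binomial_ci(toy_igk):
    rate = 0.05
    n_reads = 400
    cfg = ig.SimulationConfig(locus="IGK", n_reads=n_reads, seed=17, shm_rate=rate,
                              cdr_rate_multiplier=1.0, hotspot_multiplier=1.0)
    reads, _, _ = ig.simulate_repertoire(cfg, toy_igk)
    records = annotate_reads(reads, toy_igk, RunConfig(locus="IGK"))
    stats = shm_frequency(records, toy_igk)
    total = stats["covered"]
    se = math.sqrt(rate * (1 - rate) / total)
    assert abs(stats["overall_percent"] / 100.0 - rate) < 3 * se


def test_per_site_planted_hotspot(toy_igh):
    vseq = toy_igh["IGHV1"].v_region()
    sub = {57: {"A": "G", "G": "A", "C": "T", "T": "C"}[vseq[57]]}
    pairs = []
    cfg = ig.SimulationConfig(locus="IGH", n_reads=10, seed=8, shm_rate=0.0,
                              v_weights={"IGHV1": 1.0})
    reads, truths, _ = ig.simulate_repertoire(cfg, toy_igh)
    mutated = []
    for read in reads:
        seq = list(read.nt_sequence)
        seq[len(ig.simulate.FWD_PRIMER) + 57] = sub[57]
        mutated.append(Read(read.read_id, "".join(seq)))
    records = annotate_reads(mutated, toy_igh, RunConfig(locus="IGH"))
    profiles = per_site_profile(records, toy_igh)
    prof = profiles["IGHV1"]
    assert prof.frequency[57] == 1.0
    others = np.delete(prof.frequency, 57)
    assert np.all(others == 0.0)
    assert prof.coverage[57] == 10


def test_per_site_empty_group(toy_igh):
    assert per_site_profile([], toy_igh) == {}


def test_spectrum_single_mutation(toy_igh):
    vseq = toy_igh["IGHV2"].v_region()
    pos = vseq.index("A")
    (read, _), = _reads_with_substitutions(toy_igh, {pos: "G"})
    # force the V2 template
    cfg = ig.SimulationConfig(locus="IGH", n_reads=1, seed=3, shm_rate=0.0,
                              v_weights={"IGHV2": 1.0})
    reads, _, _ = ig.simulate_repertoire(cfg, toy_igh)
    seq = list(reads[0].nt_sequence)
    seq[len(ig.simulate.FWD_PRIMER) + pos] = "G"
    rec = annotate_read(Read("r", "".join(seq)), toy_igh, RunConfig(locus="IGH"))
    spec = substitution_spectrum([rec])
    pct = spec.percentages()
    assert pct[("A", "G")] == 100.0
    assert sum(v for v in pct.values()) == pytest.approx(100.0)


def test_spectrum_weight_recovery(toy_igk):
    weights = {f"{a}>{b}": 0.7 / 11 for a in "ACGT" for b in "ACGT" if a != b}
    weights["A>G"] = 0.30
    cfg = ig.SimulationConfig(locus="IGK", n_reads=600, seed=23, shm_rate=0.05,
                              spectrum_weights=weights,
                              cdr_rate_multiplier=1.0, hotspot_multiplier=1.0)
    reads, _, _ = ig.simulate_repertoire(cfg, toy_igk)
    records = annotate_reads(reads, toy_igk, RunConfig(locus="IGK"))
    pct = substitution_spectrum(records).percentages()
    assert abs(pct[("A", "G")] - 30.0) < 2.0


def test_profile_conserves_assignment_mutations(igk_run, toy_igk):
    _, _, records, _ = igk_run
    profiles = per_site_profile(records, toy_igk)
    total_profile = sum(int(p.mutations.sum()) for p in profiles.values())
    total_assign = sum(
        len(r.v_call.best.mutated_positions)
        for r in records if r.v_call is not None and not r.v_call.ambiguous_flag)
    assert total_profile == total_assign
    spec = substitution_spectrum(records)
    assert spec.total == total_assign
    for prof in profiles.values():
        f = prof.frequency
        assert np.all((f >= 0.0) & (f <= 1.0))


def test_shm_frequency_equals_coverage_weighted_profile_mean(igk_run, toy_igk):
    _, _, records, _ = igk_run
    stats = shm_frequency(records, toy_igk)
    profiles = per_site_profile(records, toy_igk)
    mut = sum(int(p.mutations.sum()) for p in profiles.values())
    cov = sum(int(p.coverage.sum()) for p in profiles.values())
    assert stats["overall_percent"] == pytest.approx(100.0 * mut / cov)


# ---------------------------------------------------------------------------
# hotspots


def _regex_hotspot_oracle(seq, motif):
    pattern = {"WRCY": "(?=[AT][AG]C[CT])", "RGYW": "(?=[AG]G[CT][AT])",
               "DGYW": "(?=[AGT]G[CT][AT])", "WRCH": "(?=[AT][AG]C[ACT])"}[motif]
    off = 2 if motif in ("WRCY", "WRCH") else 1
    return [m.start() + off for m in re.finditer(pattern, seq)]


@pytest.mark.parametrize("motif", ["WRCY", "RGYW", "DGYW", "WRCH"])
def test_hotspot_scan_matches_regex_oracle(motif, toy_igh):
    for g in toy_igh.by_type("V", functional_only=True):
        seq = g.v_region()
        assert scan_hotspots(seq, motif) == _regex_hotspot_oracle(seq, motif)


def test_hotspot_constructed_frequency(toy_igh):
    """10 covering reads, 4 with C->T at one WRCY hotspot C -> frequency 0.4."""
    vseq = toy_igh["IGHV1"].v_region()
    hot = scan_hotspots(vseq, "WRCY")
    pos = hot[0]
    assert vseq[pos] == "C"
    cfg = ig.SimulationConfig(locus="IGH", n_reads=10, seed=4, shm_rate=0.0,
                              v_weights={"IGHV1": 1.0})
    reads, _, _ = ig.simulate_repertoire(cfg, toy_igh)
    out = []
    for i, read in enumerate(reads):
        seq = list(read.nt_sequence)
        if i < 4:
            seq[len(ig.simulate.FWD_PRIMER) + pos] = "T"
        out.append(Read(read.read_id, "".join(seq)))
    records = annotate_reads(out, toy_igh, RunConfig(locus="IGH"))
    report = hotspot_analysis(records, toy_igh, ("WRCY",))
    data = report.per_motif["WRCY"]
    n_hot = data["n_hotspot_positions"]
    assert data["hotspot_frequency"] == pytest.approx(4 / (10 * n_hot))
    assert data["per_substitution_frequency"]["C>T"] == pytest.approx(4 / (10 * n_hot))
    assert data["baseline_frequency"] == 0.0


def test_hotspot_empty_motif_set_rejected(toy_igh):
    with pytest.raises(ValueError, match="empty motif set"):
        hotspot_analysis([], toy_igh, ())


def test_hotspot_enrichment_recovery(toy_igk):
    cfg = ig.SimulationConfig(locus="IGK", n_reads=1500, seed=29, shm_rate=0.05,
                              cdr_rate_multiplier=1.0, hotspot_multiplier=5.0)
    reads, _, _ = ig.simulate_repertoire(cfg, toy_igk)
    records = annotate_reads(reads, toy_igk, RunConfig(locus="IGK"))
    report = hotspot_analysis(records, toy_igk, ("WRCY", "RGYW"))
    for motif in ("WRCY", "RGYW"):
        enr = report.per_motif[motif]["enrichment"]
        assert 3.5 < enr < 6.5, motif
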