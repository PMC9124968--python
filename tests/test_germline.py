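"""Germline loading, RSS scanning, functionality classification, clans."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from igjunction._seq import revcomp, translate, hamming
from igjunction.germline import (
    FUNCTIONAL, INCOMPLETE, ORF, PSEUDOGENE,
    GermlineGene, assign_clans, classify_j_gene, classify_v_gene,
    d_open_frames, find_rss, load_germline, pairwise_identity,
    RSS_HEPTAMER, RSS_NONAMER,
)

# ---------------------------------------------------------------------------
# loading


def _write_fasta(tmp_path, records, name="germ.fasta"):
    path = tmp_path / name
    path.write_text("".join(f">{h}\n{s}\n" for h, s in records))
    return path


def test_load_germline_with_region_table(tmp_path, toy_igh):
    v = toy_igh["IGHV1"]
    j = toy_igh["IGHJ1"]
    fasta = _write_fasta(tmp_path, [
        ("IGHV1", v.nt_sequence), ("IGHV2", toy_igh["IGHV2"].nt_sequence),
        ("IGHJ1", j.nt_sequence),
    ])
    regions = tmp_path / "regions.tsv"
    lines = ["gene_id\tregion\tstart\tend"]
    for gid in ("IGHV1", "IGHV2"):
        for name, (s, e) in toy_igh[gid].region_bounds.items():
            lines.append(f"{gid}\t{name}\t{s}\t{e}")
    regions.write_text("\n".join(lines) + "\n")
    gs = load_germline(fasta, regions)
    assert len(gs) == 3
    assert gs["IGHV1"].region_bounds == v.region_bounds
    assert gs["IGHJ1"].segment_type == "J"


def test_load_germline_degenerate_inputs(tmp_path):
    empty = tmp_path / "empty.fasta"
    empty.write_text("")
    with pytest.raises(ValueError, match="no records"):
        load_germline(empty)
    dup = _write_fasta(tmp_path, [("IGHV1", "ACGT"), ("IGHV1", "ACGT")], "dup.fasta")
    with pytest.raises(ValueError, match="IGHV1"):
        load_germline(dup)
    bad = _write_fasta(tmp_path, [("IGHV1", "ACGTQQ")], "bad.fasta")
    with pytest.raises(ValueError, match="IGHV1"):
        load_germline(bad)


# ---------------------------------------------------------------------------
# RSS scanning


def _rss_oracle(seq, spacer_class, max_hmm, max_nmm, tol=1):
    """Naive sliding-window Hamming scan, both strands, for cross-checking."""
    hits = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for pos in range(len(s) - 6):
            hept = s[pos : pos + 7]
            if len(hept) < 7 or hamming(hept, RSS_HEPTAMER) > max_hmm:
                continue
            for spacer in range(spacer_class - tol, spacer_class + tol + 1):
                non = s[pos + 7 + spacer : pos + 16 + spacer]
                if len(non) == 9 and hamming(non, RSS_NONAMER) <= max_nmm:
                    p = pos if strand == "+" else len(seq) - pos - 7
                    hits.append((p, strand, spacer))
    return sorted(hits)


def test_find_rss_planted_canonical():
    seq = "T" * 10 + RSS_HEPTAMER + "G" * 23 + RSS_NONAMER + "T" * 10
    hits = find_rss(seq, 23, 0, 0, spacer_tolerance=0)
    plus = [h for h in hits if h.strand == "+"]
    assert len(plus) == 1
    assert plus[0].position == 10
    assert plus[0].mismatches == (0, 0)


def test_find_rss_too_short():
    assert find_rss("ACGT", 12, 2, 2) == []


def test_find_rss_planted_mismatched_motifs_vs_oracle():
    rng = np.random.default_rng(7)
    seq = list("".join(rng.choice(list("ACGT")) for _ in range(10_000)))
    planted = []
    for k in range(5):
        pos = 500 + k * 1900
        hept = list(RSS_HEPTAMER)
        i = int(rng.integers(3, 7))  # mismatch outside the CAC core
        hept[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[hept[i]]
        motif = "".join(hept) + "".join(rng.choice(list("ACGT")) for _ in range(23)) + RSS_NONAMER
        seq[pos : pos + len(motif)] = list(motif)
        planted.append(pos)
    seq = "".join(seq)
    hits = find_rss(seq, 23, 1, 1, spacer_tolerance=0, strands="+")
    oracle = [h for h in _rss_oracle(seq, 23, 1, 1, tol=0) if h[1] == "+"]
    assert sorted(h.position for h in hits) == [p for p, _, _ in oracle]
    assert set(planted) <= {h.position for h in hits}


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 10_000), st.sampled_from([12, 23]))
def test_find_rss_matches_sliding_window_oracle(seed, spacer):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT")) for _ in range(300))
    # plant one motif so the comparison is not vacuously empty
    pos = int(rng.integers(0, 300 - 7 - spacer - 9))
    seq = seq[:pos] + RSS_HEPTAMER + seq[pos + 7 :]
    ns = pos + 7 + spacer
    seq = seq[:ns] + RSS_NONAMER + seq[ns + 9 :]
    hits = find_rss(seq, spacer, 1, 2)
    assert sorted((h.position, h.strand, h.spacer_length) for h in hits) == \
        _rss_oracle(seq, spacer, 1, 2)


def test_find_rss_minus_strand_mirrors_plus_of_revcomp():
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACGT")) for _ in range(400))
    pos = 100
    seq = seq[:pos] + revcomp(RSS_NONAMER) + seq[pos + 9 :]
    hs = pos + 9 + 12
    seq = seq[:hs] + revcomp(RSS_HEPTAMER) + seq[hs + 7 :]
    minus = [h for h in find_rss(seq, 12, 0, 0, spacer_tolerance=0) if h.strand == "-"]
    assert minus
    plus_rc = [h for h in find_rss(revcomp(seq), 12, 0, 0, spacer_tolerance=0)
               if h.strand == "+"]
    mirrored = sorted(len(seq) - h.position - 7 for h in plus_rc)
    assert sorted(h.position for h in minus) == mirrored


# ---------------------------------------------------------------------------
# classification


def test_classify_v_branches(toy_igh):
    assert toy_igh["IGHV1"].functionality == FUNCTIONAL
    assert toy_igh["IGHV7"].functionality == ORF      # Cys-104 -> Ser
    assert toy_igh["IGHV8"].functionality == PSEUDOGENE  # stop in FR2
    assert toy_igh["IGHV9"].functionality == INCOMPLETE  # FR1 truncated


def test_classify_v_stop_injection_is_monotone(toy_igh):
    """Injecting a stop codon into any functional V always yields pseudogene."""
    for gid in ("IGHV1", "IGHV4"):
        g = toy_igh[gid]
        assert classify_v_gene(g) == FUNCTIONAL
        for region in ("FR1", "FR2", "FR3"):
            s, _ = g.region_bounds[region]
            codon = s + 6
            seq = g.nt_sequence[:codon] + "TGA" + g.nt_sequence[codon + 3 :]
            mutant = GermlineGene(gene_id="mut", locus="IGH", segment_type="V",
                                  nt_sequence=seq, region_bounds=dict(g.region_bounds))
            assert classify_v_gene(mutant) == PSEUDOGENE


def test_classify_v_missing_bounds_incomplete():
    g = GermlineGene(gene_id="bare", locus="IGH", segment_type="V",
                     nt_sequence="ACGT" * 50)
    assert classify_v_gene(g) == INCOMPLETE


@pytest.mark.parametrize("nt, locus, expected", [
    ("TGGGGCCAAGGA", "IGH", FUNCTIONAL),          # W G Q G
    ("TTTGGCTCGGGG", "IGK", FUNCTIONAL),          # F G S G (X is any residue)
    ("AAACCCGGGTTTAAACCC", "IGH", PSEUDOGENE),    # no WGXG in any frame
])
def test_classify_j(nt, locus, expected):
    g = GermlineGene(gene_id="J", locus=locus, segment_type="J", nt_sequence=nt)
    assert classify_j_gene(g) == expected


def test_classify_j_toy_fixture(toy_igh):
    assert toy_igh["IGHJ1"].functionality == FUNCTIONAL
    assert toy_igh["IGHJ4"].functionality == PSEUDOGENE


@pytest.mark.parametrize("nt", ["GGTAGTGGT", "TAATAATAA", "GGCGGC", "ATGTAGCATTGA"])
def test_d_open_frames_matches_direct_translation(nt):
    g = GermlineGene(gene_id="D", locus="IGH", segment_type="D", nt_sequence=nt)
    expected = {f for f in range(3) if "*" not in translate(nt, f)}
    assert d_open_frames(g) == expected


def test_d_open_frames_examples():
    g = GermlineGene(gene_id="D", locus="IGH", segment_type="D",
                     nt_sequence="GGCGGC")
    assert d_open_frames(g) == {0, 1, 2}
    g2 = GermlineGene(gene_id="D2", locus="IGH", segment_type="D",
                      nt_sequence="TAATAATAA")
    assert 0 not in d_open_frames(g2)


# ---------------------------------------------------------------------------
# clans


def _v_gene(gid, seq, bounds):
    return GermlineGene(gene_id=gid, locus="IGH", segment_type="V",
                        nt_sequence=seq, region_bounds=dict(bounds))


def test_assign_clans_identical_and_distant(toy_igh):
    g = toy_igh["IGHV1"]
    trio = [_v_gene(f"A{i}", g.nt_sequence, g.region_bounds) for i in range(3)]
    labels, excluded = assign_clans(trio, 0.75)
    assert set(labels.values()) == {"I"} and not excluded

    far = toy_igh["IGHV4"]  # different clan seed, ~50% identity
    labels, _ = assign_clans([g, far], 0.75)
    assert labels[g.gene_id] != labels[far.gene_id]


def test_assign_clans_recovers_three_seeds_vs_bruteforce():
    rng = np.random.default_rng(42)
    bases = list("ACGT")
    seeds = ["".join(rng.choice(bases) for _ in range(120)) for _ in range(3)]
    bounds = {"FR1": (0, 24), "CDR1": (24, 36), "FR2": (36, 60),
              "CDR2": (60, 72), "FR3": (72, 120)}
    genes = []
    membership = {}
    for si, seed_seq in enumerate(seeds):
        for k in range(4):
            seq = list(seed_seq)
            for pos in rng.choice(120, size=5, replace=False):  # <=5% divergence
                seq[pos] = rng.choice([b for b in bases if b != seq[pos]])
            gid = f"V{si}_{k}"
            genes.append(_v_gene(gid, "".join(seq), bounds))
            membership[gid] = si
    labels, _ = assign_clans(genes, 0.75)

    # brute-force oracle: full identity matrix + connected components
    import itertools
    adj = {g.gene_id: set() for g in genes}
    for a, b in itertools.combinations(genes, 2):
        if pairwise_identity(a.v_region(), b.v_region()) >= 0.75:
            adj[a.gene_id].add(b.gene_id)
            adj[b.gene_id].add(a.gene_id)
    comps = []
    seen = set()
    for g in genes:
        if g.gene_id in seen:
            continue
        stack, comp = [g.gene_id], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        comps.append(comp)
    assert len(comps) == 3
    oracle_partition = {frozenset(c) for c in comps}
    ours = {}
    for gid, lab in labels.items():
        ours.setdefault(lab, set()).add(gid)
    assert {frozenset(v) for v in ours.values()} == oracle_partition
    # and clans match the generating seeds
    for members in ours.values():
        assert len({membership[m] for m in members}) == 1


def test_assign_clans_order_invariant(toy_igh):
    genes = [g for g in toy_igh.by_type("V") if g.has_v_bounds()]
    fwd, _ = assign_clans(genes, 0.75)
    rev, _ = assign_clans(genes[::-1], 0.75)
    assert fwd == rev
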