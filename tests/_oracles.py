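"""Independent brute-force oracles used by the junction tests.

The micro-instance oracle enumerates every consistent attribution of a toy
V-insert-J junction (20 nt V, 20 nt J, trims 0-4, short inserts) and picks
the maximal templated attribution with V precedence, then maximal P — the
same convention the implementation claims, derived here by exhaustive
enumeration rather than greedy extension.
"""

from igjunction._seq import revcomp
from igjunction.assign import SegmentAlignment
from igjunction.germline import GermlineGene, GermlineSet

V_SEQ = "ATGGCATGCATCGAGGATTC"   # FR1-FR3 = first 16 nt, 3' tail = ATTC
J_SEQ = "CCTGAAGTTGACGGTACGTA"   # trimmable 5' part = first 4 nt

_V_BOUNDS = {"FR1": (0, 3), "CDR1": (3, 6), "FR2": (6, 9),
             "CDR2": (9, 12), "FR3": (12, 16)}


def micro_germline(v_seq: str = V_SEQ, j_seq: str = J_SEQ) -> GermlineSet:
    genes = {
        "V": GermlineGene(gene_id="V", locus="IGK", segment_type="V",
                          nt_sequence=v_seq, region_bounds=dict(_V_BOUNDS)),
        "J": GermlineGene(gene_id="J", locus="IGK", segment_type="J",
                          nt_sequence=j_seq),
    }
    return GermlineSet(genes=genes, locus="IGK")


def make_instance(v_del: int, j_del: int, insert: str,
                  v_seq: str = V_SEQ, j_seq: str = J_SEQ):
    """Read + exact V/J alignments for one micro junction instance."""
    read_seq = v_seq[: len(v_seq) - v_del] + insert + j_seq[j_del:]
    v_aln = SegmentAlignment(
        gene_id="V", read_interval=(0, 16), germline_interval=(0, 16),
        score=16, percent_identity=1.0, cigar="16=")
    j_core = len(j_seq) - 4
    j_aln = SegmentAlignment(
        gene_id="J",
        read_interval=(len(read_seq) - j_core, len(read_seq)),
        germline_interval=(4, len(j_seq)),
        score=j_core, percent_identity=1.0, cigar=f"{j_core}=")
    return read_seq, v_aln, j_aln


def oracle_decompose(read_seq: str, v_seq: str = V_SEQ, j_seq: str = J_SEQ,
                     max_p_len: int = 4) -> dict:
    """Exhaustive enumeration of consistent (retention, P, N) splits."""
    tail = v_seq[16:]
    upstream = j_seq[:4]
    m = read_seq[16 : len(read_seq) - (len(j_seq) - 4)]
    gap = len(m)
    valid_a = [a for a in range(min(len(tail), gap) + 1) if m[:a] == tail[:a]]
    valid_b = [b for b in range(min(len(upstream), gap) + 1)
               if b == 0 or m[gap - b :] == upstream[len(upstream) - b :]]
    splits = [(a, b) for a in valid_a for b in valid_b if a + b <= gap]
    smax = max(a + b for a, b in splits)
    maximal = [s for s in splits if s[0] + s[1] == smax]
    ambiguous = len(maximal) > 1
    a, b = max(maximal)  # V precedence: largest a among maximal splits
    v_del = len(tail) - a
    j_del = len(upstream) - b
    insert = m[a : gap - b]
    p1 = ""
    if v_del == 0:
        for l in range(1, min(max_p_len, len(insert)) + 1):
            if insert[:l] == revcomp(v_seq[len(v_seq) - l :]):
                p1 = insert[:l]
    rest = insert[len(p1) :]
    p2 = ""
    if j_del == 0:
        for l in range(1, min(max_p_len, len(rest)) + 1):
            if rest[len(rest) - l :] == revcomp(j_seq[:l]):
                p2 = rest[len(rest) - l :]
    n1 = rest[: len(rest) - len(p2)]
    return {"v_deletion": v_del, "j_deletion": j_del,
            "p1": p1, "n1": n1, "p2": p2, "ambiguous": ambiguous}


def all_inserts(max_len: int):
    from itertools import product

    yield ""
    for ln in range(1, max_len + 1):
        for tup in product("ACGT", repeat=ln):
            yield "".join(tup)
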