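"""CDR3 anchoring and junction decomposition.

The CDR3 is the read segment strictly between the conserved Cys-104 codon
of the V gene (the C of the Tyr-Tyr-Cys motif ending FR3) and the
conserved Trp/Phe codon of the J gene (the W of WGXG for heavy chains, the
F of FGXG for light chains).  Anchors are placed by projecting the known
germline anchor positions through the V and J alignments; a motif scan in
the aligned frame is the fallback when no projection is possible.

The junction window between the V and J alignments is decomposed into
germline-retained, palindromic (P) and non-templated (N) nucleotides:

1. extend the V attribution rightward by the longest exact match to the
   germline V 3' continuation, then the J attribution leftward likewise —
   bases claimable by both resolve in favour of V (left precedence);
2. deletions are the germline nucleotides beyond the retained ends;
3. P nucleotides are read only at untrimmed coding ends: the longest
   insert prefix/suffix equal to the reverse complement of the terminal
   retained germline bases, capped at ``max_p_len``;
4. on IGH the best exact D-gene match inside the remaining insert gets its
   own deletions and P rules; everything left over is N.

The concatenation of all parts must reproduce the observed junction
byte-exactly; a violation is an internal error, never silently accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import revcomp, translate
from .assign import SegmentAlignment, SegmentCall, longest_common_substring
from .germline import GermlineSet, j_anchor_offset
from .qc import Read


@dataclass
class Cdr3:
    """A located CDR3: 0-based half-open read interval, exclusive of anchors."""

    nt_start: int
    nt_end: int
    nt_sequence: str
    aa_sequence: str
    anchor_c_position: int
    anchor_wf_position: int
    anchor_mismatches: int = 0

    @property
    def nt_length(self) -> int:
        return self.nt_end - self.nt_start

    @property
    def aa_length(self) -> int | None:
        return self.nt_length // 3 if self.nt_length % 3 == 0 else None


@dataclass
class JunctionDecomposition:
    """Attribution of every junction base to V / P / N / (D) / P / J."""

    v_deletion: int
    p1: str
    n1: str
    p_d5: str
    d_deletion_5p: int
    retained_d: str
    d_deletion_3p: int
    p_d3: str
    n2: str
    p2: str
    j_deletion: int
    retained_v_len: int
    retained_j_len: int
    retained_v_seq: str = ""
    retained_j_seq: str = ""
    junction_window: str = ""
    ambiguous: bool = False

    def reconstruct(self) -> str:
        return (
            self.retained_v_seq + self.p1 + self.n1 + self.p_d5 + self.retained_d
            + self.p_d3 + self.n2 + self.p2 + self.retained_j_seq
        )

    def check(self) -> None:
        if self.reconstruct() != self.junction_window:
            raise AssertionError(
                f"junction reconstruction failed: {self.reconstruct()!r} != "
                f"{self.junction_window!r}"
            )
        if self.p1 and self.v_deletion != 0:
            raise AssertionError("P1 present with a trimmed V end")
        if self.p2 and self.j_deletion != 0:
            raise AssertionError("P2 present with a trimmed J end")
        if self.p_d5 and self.d_deletion_5p != 0:
            raise AssertionError("P present at a trimmed D 5' end")
        if self.p_d3 and self.d_deletion_3p != 0:
            raise AssertionError("P present at a trimmed D 3' end")


def _scan_c_anchor(aa: str, upto: int) -> int | None:
    """Rightmost YYC-like anchor (C fixed, <=1 mismatch over the Ys) before ``upto``."""
    best = None
    for i in range(min(upto, len(aa)) - 2):
        if aa[i + 2] != "C":
            continue
        mm = (aa[i] != "Y") + (aa[i + 1] != "Y")
        if mm <= 1:
            best = i
    return best


def _scan_wf_anchor(aa: str, start: int, wf: str) -> int | None:
    """Leftmost W/F-G-X-G anchor (W/F fixed, <=1 mismatch over the Gs) from ``start``."""
    for i in range(max(start, 0), len(aa) - 3):
        if aa[i] != wf:
            continue
        mm = (aa[i + 1] != "G") + (aa[i + 3] != "G")
        if mm <= 1:
            return i
    return None


def locate_cdr3(
    read: Read,
    v_call: SegmentCall,
    j_call: SegmentCall,
    germline_set: GermlineSet,
) -> Cdr3 | None:
    """Place the CDR3 between the projected germline anchors.

    Returns None (caller flags ``cdr3_missing``) when no anchor can be
    located by projection or motif scan.
    """
    vgene = germline_set[v_call.best.gene_id]
    jgene = germline_set[j_call.best.gene_id]
    v_window_len = v_call.best.germline_interval[1]  # FR1-FR3 length
    # C anchor: last FR3 codon projected through the V alignment
    c_start = v_call.best.project(v_window_len - 3)
    c_end = v_call.best.project(v_window_len)
    # W/F anchor: J anchor codon projected through the J alignment
    anchor_off = j_anchor_offset(jgene)
    wf_start = j_call.best.project(anchor_off) if anchor_off is not None else None

    seq = read.nt_sequence
    if c_start is None or c_end is None or wf_start is None:
        # fallback: motif scan in the V-aligned frame
        frame = v_call.best.read_interval[0] % 3
        aa = translate(seq, frame)
        wf = "W" if germline_set.locus == "IGH" else "F"
        upto = ((wf_start - frame) // 3) if wf_start is not None else len(aa)
        c_aa = _scan_c_anchor(aa, upto)
        if c_aa is None:
            return None
        if c_start is None or c_end is None:
            c_start = frame + 3 * c_aa + 6
            c_end = c_start + 3
        if wf_start is None:
            wf_aa = _scan_wf_anchor(aa, (c_end - frame) // 3, wf)
            if wf_aa is None:
                return None
            wf_start = frame + 3 * wf_aa
    if wf_start <= c_end:
        return None

    nt = seq[c_end:wf_start]
    aa_seq = translate(nt) if len(nt) % 3 == 0 else ""
    wf_expected = "W" if germline_set.locus == "IGH" else "F"
    mismatches = int(translate(seq[c_start : c_start + 3]) != "C") + int(
        translate(seq[wf_start : wf_start + 3]) != wf_expected
    )
    return Cdr3(
        nt_start=c_end,
        nt_end=wf_start,
        nt_sequence=nt,
        aa_sequence=aa_seq,
        anchor_c_position=c_start,
        anchor_wf_position=wf_start,
        anchor_mismatches=mismatches,
    )


def _extend_right(read_seq: str, start: int, template: str, limit: int) -> int:
    """Longest exact match of ``template`` starting at ``start``, capped at limit."""
    k = 0
    while k < limit and k < len(template) and start + k < len(read_seq) and \
            read_seq[start + k] == template[k]:
        k += 1
    return k


def _extend_left(read_seq: str, end: int, template: str, limit: int) -> int:
    """Longest exact match of the template's tail ending at ``end`` (exclusive)."""
    k = 0
    while k < limit and k < len(template) and end - k - 1 >= 0 and \
            read_seq[end - k - 1] == template[len(template) - k - 1]:
        k += 1
    return k


def _p_prefix(insert: str, terminal: str, max_p_len: int) -> str:
    """Longest insert prefix equal to revcomp of the terminal retained bases."""
    best = 0
    for l in range(1, min(max_p_len, len(insert), len(terminal)) + 1):
        if insert[:l] == revcomp(terminal[-l:]):
            best = l
    return insert[:best]


def _p_suffix(insert: str, leading: str, max_p_len: int) -> str:
    """Longest insert suffix equal to revcomp of the leading retained bases."""
    best = 0
    for l in range(1, min(max_p_len, len(insert), len(leading)) + 1):
        if insert[-l:] == revcomp(leading[:l]):
            best = l
    return insert[len(insert) - best :]


def decompose_junction(
    read: Read,
    v_alignment: SegmentAlignment,
    j_alignment: SegmentAlignment,
    germline_set: GermlineSet,
    d_call: SegmentCall | None = None,
    max_p_len: int = 4,
    min_d_match: int = 5,
) -> JunctionDecomposition:
    """Decompose the V-J junction window into retained / P / N parts."""
    seq = read.nt_sequence
    vgene = germline_set[v_alignment.gene_id]
    fr3_end = vgene.region_bounds["FR3"][1]
    v_tail = vgene.nt_sequence[fr3_end:]  # germline V 3' continuation past FR3

    jgene = germline_set[j_alignment.gene_id]
    j_core_start_germ = j_alignment.germline_interval[0]
    j_upstream = jgene.nt_sequence[:j_core_start_germ]

    v_end = v_alignment.read_interval[1]
    j_core_start = j_alignment.read_interval[0]
    gap = j_core_start - v_end
    if gap < 0:
        raise ValueError("V and J alignments overlap on the read")

    # (1) maximal templated attribution, V precedence
    a_raw = _extend_right(seq, v_end, v_tail, limit=gap)
    b_raw = _extend_left(seq, j_core_start, j_upstream, limit=gap)
    a = a_raw
    b = min(b_raw, gap - a)
    ambiguous = a_raw + b_raw > gap

    v_deletion = len(v_tail) - a
    j_deletion = len(j_upstream) - b
    v_ext_end = v_end + a
    j_ret_start = j_core_start - b
    insert = seq[v_ext_end:j_ret_start]

    # (3) P nucleotides only at untrimmed coding ends
    p1 = _p_prefix(insert, vgene.nt_sequence, max_p_len) if v_deletion == 0 else ""
    rest = insert[len(p1) :]
    p2 = _p_suffix(rest, jgene.nt_sequence, max_p_len) if j_deletion == 0 else ""
    middle = rest[: len(rest) - len(p2)]

    # (4) D attribution inside the remaining insert
    p_d5 = retained_d = p_d3 = ""
    d_del5 = d_del3 = 0
    n1, n2 = middle, ""
    if d_call is not None:
        dgene = germline_set[d_call.best.gene_id]
        length, m_off, d_off = longest_common_substring(middle, dgene.nt_sequence)
        if length >= min_d_match:
            retained_d = middle[m_off : m_off + length]
            d_del5 = d_off
            d_del3 = len(dgene.nt_sequence) - (d_off + length)
            left = middle[:m_off]
            right = middle[m_off + length :]
            if d_del5 == 0:
                p_d5 = _p_suffix(left, dgene.nt_sequence, max_p_len)
            if d_del3 == 0:
                p_d3 = _p_prefix_from_tail(right, dgene.nt_sequence, max_p_len)
            n1 = left[: len(left) - len(p_d5)]
            n2 = right[len(p_d3) :]

    decomp = JunctionDecomposition(
        v_deletion=v_deletion,
        p1=p1,
        n1=n1,
        p_d5=p_d5,
        d_deletion_5p=d_del5,
        retained_d=retained_d,
        d_deletion_3p=d_del3,
        p_d3=p_d3,
        n2=n2,
        p2=p2,
        j_deletion=j_deletion,
        retained_v_len=a,
        retained_j_len=b,
        retained_v_seq=seq[v_end:v_ext_end],
        retained_j_seq=seq[j_ret_start:j_core_start],
        junction_window=seq[v_end:j_core_start],
        ambiguous=ambiguous,
    )
    decomp.check()
    return decomp


def _p_prefix_from_tail(insert: str, d_sequence: str, max_p_len: int) -> str:
    """P at the D 3' end: insert prefix equal to revcomp of the D's last bases."""
    best = 0
    for l in range(1, min(max_p_len, len(insert), len(d_sequence)) + 1):
        if insert[:l] == revcomp(d_sequence[-l:]):
            best = l
    return insert[:best]


def junction_length_stats(records) -> dict[str, dict]:
    """Histograms and mean +/- population SD for junction quantities.

    Records flagged ``cdr3_missing`` are excluded and counted under the
    ``excluded`` key.  AA lengths are reported only for in-frame CDR3s.
    """
    quantities: dict[str, list[int]] = {
        "v_deletion": [], "j_deletion": [],
        "p1_len": [], "p2_len": [], "n1_len": [], "n2_len": [],
        "cdr3_nt_len": [], "cdr3_aa_len": [],
    }
    excluded = 0
    for rec in records:
        if rec.cdr3 is None:
            excluded += 1
            continue
        quantities["cdr3_nt_len"].append(rec.cdr3.nt_length)
        if rec.cdr3.aa_length is not None:
            quantities["cdr3_aa_len"].append(rec.cdr3.aa_length)
        d = rec.decomposition
        if d is not None:
            quantities["v_deletion"].append(d.v_deletion)
            quantities["j_deletion"].append(d.j_deletion)
            quantities["p1_len"].append(len(d.p1))
            quantities["p2_len"].append(len(d.p2))
            quantities["n1_len"].append(len(d.n1))
            quantities["n2_len"].append(len(d.n2))
    out: dict[str, dict] = {"excluded": excluded}
    for name, values in quantities.items():
        if values:
            arr = np.asarray(values, dtype=float)
            counts = {int(v): int(c) for v, c in
                      zip(*np.unique(arr.astype(int), return_counts=True))}
            out[name] = {
                "counts": counts,
                "mean": float(arr.mean()),
                "sd": float(arr.std()),  # population SD
                "n": len(values),
            }
        else:
            out[name] = {"counts": {}, "mean": float("nan"), "sd": float("nan"), "n": 0}
    return out
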