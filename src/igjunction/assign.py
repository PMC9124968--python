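"""Template V/D/J identification by best-scoring germline alignment.

Each candidate germline segment is infix-aligned into the read (the whole
germline region must be covered; the read's flanks are free).  The best
score wins; exact score ties collapse to a clan-level call with an
explicit ambiguity flag, mirroring how highly homologous V genes within a
clan cannot be distinguished on SHM-bearing reads.

Scoring: match +1, mismatch -1, gap open -4, gap extend -1.  Alignments
are computed with edlib (edit distance) and rescored from the alignment
path; for the substitution-dominated reads this pipeline targets, the
minimum-edit-distance path is also the maximum-score path.  Substitutions
only are recorded as mutated positions (indels are excluded from the SHM
accounting).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib

from .germline import FUNCTIONAL, GermlineGene, GermlineSet, j_anchor_offset
from .qc import Read

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -1, -4, -1

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


@dataclass
class SegmentAlignment:
    """One germline-segment-to-read alignment.

    ``germline_interval`` is on the aligned germline window (for V genes
    this window is FR1-FR3, so position 0 is the FR1 start);
    ``read_interval`` is on the read; both 0-based half-open.
    ``mutated_positions`` lists substitutions as
    (germline_position, germline_base, read_base).
    """

    gene_id: str
    read_interval: tuple[int, int]
    germline_interval: tuple[int, int]
    score: int
    percent_identity: float
    mutated_positions: list[tuple[int, str, str]] = field(default_factory=list)
    cigar: str = ""

    def project(self, germline_pos: int) -> int | None:
        """Map a germline-window position to a read position through the cigar.

        Returns None if the position falls in a read gap.  Positions equal to
        the germline interval end map to the read interval end.
        """
        if germline_pos == self.germline_interval[1]:
            return self.read_interval[1]
        qpos = self.germline_interval[0]
        tpos = self.read_interval[0]
        for n, op in _CIGAR_RE.findall(self.cigar):
            n = int(n)
            if op in "=X":
                if qpos <= germline_pos < qpos + n:
                    return tpos + (germline_pos - qpos)
                qpos += n
                tpos += n
            elif op == "I":  # germline base absent from read
                if qpos <= germline_pos < qpos + n:
                    return None
                qpos += n
            else:  # 'D': read insertion
                tpos += n
        return None


@dataclass
class SegmentCall:
    best: SegmentAlignment
    ties: list[str] = field(default_factory=list)
    clan: str | None = None
    ambiguous_flag: bool = False


def _hamming_cigar(a: str, b: str) -> str:
    """Run-length =/X cigar for two equal-length strings."""
    parts = []
    run_op = None
    run_len = 0
    for x, y in zip(a, b):
        op = "=" if x == y else "X"
        if op == run_op:
            run_len += 1
        else:
            if run_op:
                parts.append(f"{run_len}{run_op}")
            run_op, run_len = op, 1
    if run_op:
        parts.append(f"{run_len}{run_op}")
    return "".join(parts)


def _score_cigar(cigar: str) -> int:
    score = 0
    for n, op in _CIGAR_RE.findall(cigar):
        n = int(n)
        if op == "=":
            score += MATCH * n
        elif op == "X":
            score += MISMATCH * n
        else:
            score += GAP_OPEN + GAP_EXTEND * (n - 1)
    return score


def _prefer_gapless(query: str, target: str, distance: int,
                    cigar: str, start: int, end: int) -> tuple[str, int, int]:
    if "I" not in cigar and "D" not in cigar:
        return cigar, start, end
    qlen = len(query)
    best = None  # (score, start)
    for s in range(max(0, start - 4), min(len(target) - qlen, start + 4) + 1):
        window = target[s : s + qlen]
        if len(window) != qlen:
            continue
        h = sum(x != y for x, y in zip(query, window))
        score = qlen - 2 * h
        if best is None or score > best[0]:
            best = (score, s)
    if best is not None and best[0] >= _score_cigar(cigar):
        s = best[1]
        return _hamming_cigar(query, target[s : s + qlen]), s, s + qlen - 1
    return cigar, start, end


def align_segment(
    gene_id: str, germline_seq: str, read_seq: str, read_offset: int = 0
) -> SegmentAlignment | None:
    """Infix-align a germline window into (a slice of) a read.

    ``read_offset`` shifts reported read coordinates when ``read_seq`` is a
    suffix of the full read.
    """
    if not germline_seq or not read_seq:
        return None
    res = edlib.align(germline_seq, read_seq, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = res["locations"][0]
    cigar = res["cigar"] or ""
    # Edit distance treats a terminal substitution and a terminal gap as
    # equal cost, which can shift the reported alignment end.  Canonicalize
    # to the gapless (substitution-only) alignment whenever one achieves the
    # same distance, so segment boundaries are stable under SHM.
    cigar, start, end = _prefer_gapless(
        germline_seq, read_seq, res["editDistance"], cigar, start, end)
    qpos = 0
    tpos = start
    score = 0
    muts: list[tuple[int, str, str]] = []
    for n, op in _CIGAR_RE.findall(cigar):
        n = int(n)
        if op == "=":
            score += MATCH * n
            qpos += n
            tpos += n
        elif op == "X":
            score += MISMATCH * n
            for k in range(n):
                muts.append((qpos + k, germline_seq[qpos + k], read_seq[tpos + k]))
            qpos += n
            tpos += n
        else:
            score += GAP_OPEN + GAP_EXTEND * (n - 1)
            if op == "I":
                qpos += n
            else:
                tpos += n
    identity = 1.0 - len(muts) / len(germline_seq)
    return SegmentAlignment(
        gene_id=gene_id,
        read_interval=(read_offset + start, read_offset + end + 1),
        germline_interval=(0, len(germline_seq)),
        score=score,
        percent_identity=identity,
        mutated_positions=muts,
        cigar=cigar,
    )


def _pick_best(
    alignments: list[SegmentAlignment],
    germline_set: GermlineSet,
    tie_margin: int,
) -> SegmentCall | None:
    if not alignments:
        return None
    alignments.sort(key=lambda a: (-a.score, a.gene_id))
    best_score = alignments[0].score
    ties = [a.gene_id for a in alignments if a.score >= best_score - tie_margin]
    ambiguous = len(ties) > 1
    clans = {germline_set[g].clan for g in ties}
    clan = clans.pop() if len(clans) == 1 else None
    return SegmentCall(
        best=alignments[0],
        ties=ties if ambiguous else [alignments[0].gene_id],
        clan=clan,
        ambiguous_flag=ambiguous,
    )


def v_templates(germline_set: GermlineSet) -> list[GermlineGene]:
    """V genes usable as alignment templates: FR1-FR3 bounds, functional if classified."""
    return [
        g
        for g in germline_set.by_type("V")
        if g.has_v_bounds() and g.functionality in (FUNCTIONAL, None)
    ]


def assign_v(
    read: Read,
    germline_set: GermlineSet,
    tie_margin: int = 0,
    min_identity: float = 0.5,
) -> SegmentCall | None:
    """Best-matching germline V over FR1-FR3; clan-level call on exact ties."""
    candidates = v_templates(germline_set)
    if not candidates:
        raise ValueError("germline set has no usable V templates")
    alignments = []
    for g in candidates:
        aln = align_segment(g.gene_id, g.v_region(), read.nt_sequence)
        if aln is not None and aln.percent_identity >= min_identity:
            alignments.append(aln)
    return _pick_best(alignments, germline_set, tie_margin)


def assign_j(
    read: Read,
    germline_set: GermlineSet,
    v_call: SegmentCall,
    tie_margin: int = 0,
    min_identity: float = 0.8,
) -> SegmentCall | None:
    """Best germline J downstream of the V alignment.

    The J is located by its never-trimmed 3' core (the conserved-anchor
    codon onward); the retained 5' part is attributed later by the junction
    decomposition.  Coordinates are reported on the full read.
    """
    suffix_start = v_call.best.read_interval[1]
    suffix = read.nt_sequence[suffix_start:]
    if not suffix:
        return None
    alignments = []
    for g in germline_set.by_type("J"):
        anchor = j_anchor_offset(g)
        core_start = anchor if anchor is not None else 0
        core = g.nt_sequence[core_start:]
        if len(core) < 6 or len(suffix) < len(core) // 2:
            continue
        aln = align_segment(g.gene_id, core, suffix, read_offset=suffix_start)
        if aln is None or aln.percent_identity < min_identity:
            continue
        # shift germline coordinates from the core window to the full J gene
        aln.germline_interval = (core_start, core_start + len(core))
        aln.mutated_positions = [
            (p + core_start, gb, rb) for p, gb, rb in aln.mutated_positions
        ]
        alignments.append(aln)
    return _pick_best(alignments, germline_set, tie_margin)


def longest_common_substring(a: str, b: str) -> tuple[int, int, int]:
    """(length, start_a, start_b) of the longest exact common substring.

    Ties resolve to the leftmost start in ``a``, then leftmost in ``b``.
    """
    best = (0, 0, 0)
    if not a or not b:
        return best
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                length = cur[j]
                if length > best[0]:
                    best = (length, i - length, j - length)
        prev = cur
    return best


def assign_d(
    read: Read,
    germline_set: GermlineSet,
    v_call: SegmentCall,
    j_call: SegmentCall,
    min_d_match: int = 5,
) -> SegmentCall | None:
    """Best exact germline-D match inside the V-J junction window (IGH only).

    Returns None when no D reaches ``min_d_match`` consecutive matching
    nucleotides — a valid outcome (the D may be trimmed away).
    """
    window_start = v_call.best.read_interval[1]
    window_end = j_call.best.read_interval[0]
    window = read.nt_sequence[window_start:window_end]
    if not window:
        return None
    alignments = []
    for g in germline_set.by_type("D"):
        length, wstart, dstart = longest_common_substring(window, g.nt_sequence)
        if length < min_d_match:
            continue
        alignments.append(
            SegmentAlignment(
                gene_id=g.gene_id,
                read_interval=(window_start + wstart, window_start + wstart + length),
                germline_interval=(dstart, dstart + length),
                score=length,
                percent_identity=1.0,
                cigar=f"{length}=",
            )
        )
    return _pick_best(alignments, germline_set, tie_margin=0)
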