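"""Coarse screening of 5'-RACE repertoire reads.

A read passes QC iff the forward primer occurs near its 5' end and the
reverse complement of the reverse primer near its 3' end (each within a
mismatch budget, searched inside a terminal window), and the untrimmed
read is at least ``min_length`` nucleotides.  Primer failure is attributed
before length failure, so the fate counts partition the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import IUPAC, iupac_match, revcomp


@dataclass
class Read:
    read_id: str
    nt_sequence: str
    quality: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.nt_sequence:
            raise ValueError(f"{self.read_id}: empty sequence")
        self.nt_sequence = self.nt_sequence.upper().replace("U", "T")

    def __len__(self) -> int:
        return len(self.nt_sequence)


@dataclass
class QcReport:
    n_input: int = 0
    n_kept: int = 0
    n_fail_primer: int = 0
    n_fail_length: int = 0
    fates: dict[str, str] = field(default_factory=dict)

    def check(self) -> None:
        assert self.n_input == self.n_kept + self.n_fail_primer + self.n_fail_length


def _find_primer(segment: str, primer: str, max_mm: int) -> int:
    """Leftmost offset of primer in segment within max_mm mismatches, or -1.

    IUPAC codes in the primer match their base sets; an N in the read
    matches nothing (it counts as a mismatch unless the primer base is N).
    """
    plen = len(primer)
    for off in range(len(segment) - plen + 1):
        mm = 0
        for s, p in zip(segment[off : off + plen], primer):
            if not iupac_match(s, p):
                mm += 1
                if mm > max_mm:
                    break
        else:
            return off
    return -1


def filter_reads(
    reads: list[Read],
    forward_primer: str,
    reverse_primer: str,
    min_length: int = 400,
    max_primer_mm: int = 2,
    *,
    window: int = 50,
    require: str = "both",
    trim: bool = False,
) -> tuple[list[Read], QcReport]:
    """Screen reads for primer presence and minimum length.

    ``require`` is "both" (default) or "either".  With ``trim`` the matched
    primers are cut off the kept reads; length is always measured on the
    untrimmed read.
    """
    for name, p in (("forward", forward_primer), ("reverse", reverse_primer)):
        if not p:
            raise ValueError(f"{name} primer is empty")
        if any(c not in IUPAC for c in p.upper()):
            raise ValueError(f"{name} primer contains non-IUPAC characters")
    if require not in ("both", "either"):
        raise ValueError("require must be 'both' or 'either'")
    fwd = forward_primer.upper()
    rev_rc = revcomp(reverse_primer.upper())

    report = QcReport(n_input=len(reads))
    kept: list[Read] = []
    for read in reads:
        seq = read.nt_sequence
        w = max(window, len(fwd), len(rev_rc))
        f_off = _find_primer(seq[:w], fwd, max_primer_mm)
        tail_start = max(0, len(seq) - w)
        r_off = _find_primer(seq[tail_start:], rev_rc, max_primer_mm)
        found = (f_off >= 0, r_off >= 0)
        ok = all(found) if require == "both" else any(found)
        if not ok:
            report.n_fail_primer += 1
            report.fates[read.read_id] = "fail_primer"
            continue
        if len(seq) < min_length:
            report.n_fail_length += 1
            report.fates[read.read_id] = "fail_length"
            continue
        if trim:
            start = f_off + len(fwd) if f_off >= 0 else 0
            end = tail_start + r_off if r_off >= 0 else len(seq)
            read = Read(read.read_id, seq[start:end],
                        read.quality[start:end] if read.quality else None)
        kept.append(read)
        report.n_kept += 1
        report.fates[read.read_id] = "kept"
    report.check()
    return kept, report
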