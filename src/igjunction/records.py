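"""The per-read annotation record tying all pipeline stages together."""

from __future__ import annotations

from dataclasses import dataclass, field

from .assign import SegmentCall
from .junction import Cdr3, JunctionDecomposition
from .qc import Read

ULTRALONG_AA = 40  # CDR3H length (AA) from which a read is flagged ultra-long


@dataclass
class RearrangementRecord:
    read: Read
    v_call: SegmentCall | None = None
    d_call: SegmentCall | None = None
    j_call: SegmentCall | None = None
    cdr3: Cdr3 | None = None
    decomposition: JunctionDecomposition | None = None
    productive: bool | None = None
    ultralong: bool = False
    flags: list[str] = field(default_factory=list)

    def label(self, segment: str, level: str = "gene") -> str | None:
        """Usage label for a segment call: gene id, tied-call label, or clan."""
        call = {"V": self.v_call, "D": self.d_call, "J": self.j_call}[segment]
        if call is None:
            return None
        if level == "clan":
            return call.clan if call.clan is not None else "unresolved"
        if call.ambiguous_flag:
            return "|".join(call.ties)
        return call.best.gene_id


def annotate_productivity(rec: RearrangementRecord) -> None:
    """Productive: in-frame CDR3, no stop codon, intact anchors."""
    if rec.cdr3 is None:
        rec.productive = False
        return
    in_frame = rec.cdr3.nt_length % 3 == 0
    no_stop = "*" not in rec.cdr3.aa_sequence
    rec.productive = in_frame and no_stop and rec.cdr3.anchor_mismatches == 0
    # flag on nt length / 3 so out-of-frame ultra-long junctions are still caught
    rec.ultralong = rec.cdr3.nt_length // 3 >= ULTRALONG_AA
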