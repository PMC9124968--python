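"""Repertoire usage statistics: segment usage, V(D)J combinations, CDR3 contributions.

Counting is per read, with no clonotype deduplication (every sequenced read
contributes one count); an optional deduplication hook collapses identical
junction sequences first.  Unassigned and ambiguous reads are always
reported, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class UsageTable:
    segment: str
    level: str                      # "gene" or "clan"
    table: pd.DataFrame             # columns: label, count, percent
    n_total: int                    # all reads seen
    n_assigned: int                 # reads with a call at this level
    n_unassigned: int

    def percent_of(self, label: str) -> float:
        row = self.table[self.table["label"] == label]
        return float(row["percent"].iloc[0]) if len(row) else 0.0


def _dedup(records):
    seen = set()
    for rec in records:
        key = rec.cdr3.nt_sequence if rec.cdr3 is not None else rec.read.nt_sequence
        if key in seen:
            continue
        seen.add(key)
        yield rec


def usage_frequencies(records, segment: str, level: str = "gene",
                      dedup: bool = False) -> UsageTable:
    """Per-read segment usage counts and percentages.

    Percentages are over assigned reads; the unassigned count is reported
    separately.  At clan level, reads with tied gene calls that share a clan
    are counted under that clan.
    """
    if segment not in ("V", "D", "J"):
        raise ValueError("segment must be V, D or J")
    if level not in ("gene", "clan"):
        raise ValueError("level must be gene or clan")
    records = list(_dedup(records)) if dedup else list(records)
    labels = [rec.label(segment, level) for rec in records]
    assigned = [lb for lb in labels if lb is not None]
    counts: dict[str, int] = {}
    for lb in assigned:
        counts[lb] = counts.get(lb, 0) + 1
    n_assigned = len(assigned)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    table = pd.DataFrame(
        [(lb, c, 100.0 * c / n_assigned) for lb, c in rows],
        columns=["label", "count", "percent"],
    )
    return UsageTable(
        segment=segment, level=level, table=table,
        n_total=len(records), n_assigned=n_assigned,
        n_unassigned=len(records) - n_assigned,
    )


def combination_table(records, level: str = "gene") -> pd.DataFrame:
    """Counts of (V, D, J) label triples, descending; D omitted when absent.

    Light-chain records (no D call on any read) yield (V, J) pairs.
    """
    rows = []
    any_d = any(rec.d_call is not None for rec in records)
    for rec in records:
        v = rec.label("V", level)
        j = rec.label("J", level)
        if v is None or j is None:
            continue
        if any_d:
            d = rec.label("D", "gene") or "none"
            rows.append((v, d, j))
        else:
            rows.append((v, j))
    cols = ["v_label", "d_label", "j_label"] if any_d else ["v_label", "j_label"]
    if not rows:
        return pd.DataFrame(columns=cols + ["count"])
    df = pd.DataFrame(rows, columns=cols)
    out = df.value_counts().reset_index(name="count")
    return out.sort_values(["count"] + cols, ascending=[False] + [True] * len(cols),
                           ignore_index=True)


def segment_contribution_stats(records) -> dict[str, dict]:
    """Mean +/- population SD of germline-segment contributions to the CDR3.

    Quantities: retained V / D / J nucleotide lengths inside the CDR3 and the
    CDR3 nucleotide length.  Records without a D call are excluded from the
    D contribution and counted under ``n_no_d``.
    """
    ret_v, ret_d, ret_j, cdr3_nt = [], [], [], []
    n_no_d = 0
    for rec in records:
        d = rec.decomposition
        if d is None or rec.cdr3 is None:
            continue
        ret_v.append(d.retained_v_len)
        ret_j.append(d.retained_j_len)
        cdr3_nt.append(rec.cdr3.nt_length)
        if rec.d_call is not None and d.retained_d:
            ret_d.append(len(d.retained_d))
        else:
            n_no_d += 1

    def _ms(values):
        if not values:
            return {"mean": float("nan"), "sd": float("nan"), "n": 0}
        arr = np.asarray(values, dtype=float)
        return {"mean": float(arr.mean()), "sd": float(arr.std()), "n": len(values)}

    return {
        "retained_v": _ms(ret_v),
        "retained_d": _ms(ret_d),
        "retained_j": _ms(ret_j),
        "cdr3_nt": _ms(cdr3_nt),
        "n_no_d": n_no_d,
    }
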