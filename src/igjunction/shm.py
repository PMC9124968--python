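"""Somatic hypermutation analytics over the V region (FR1-FR3).

SHM frequency is the number of observed mutant bases divided by the total
number of sequenced (germline-aligned, non-gap, non-N) bases, reported as
a percentage.  Per-site profiles, the 12-class substitution spectrum and
AID-hotspot (WRCY/RGYW, optionally DGYW/WRCH) mutation frequencies are all
derived from the substitutions recorded by the V alignments; indels and
ambiguous bases contribute to neither numerator nor denominator.

Reads whose V call is ambiguous (tied between germline genes) are excluded
by default, since their mutation sets depend on which tied gene is taken
as template.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .germline import GermlineSet, V_REGIONS

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}
_CIGAR_RE = re.compile(r"(\d+)([=XID])")

# mutable-base offset within each supported hotspot motif (0-based)
HOTSPOT_MOTIFS = {"WRCY": 2, "WRCH": 2, "RGYW": 1, "DGYW": 1}
_IUPAC_RE = {"W": "[AT]", "R": "[AG]", "Y": "[CT]", "D": "[AGT]", "H": "[ACT]",
             "A": "A", "C": "C", "G": "G", "T": "T"}


@dataclass
class SHMProfile:
    """Per-site coverage and mutation counts for one germline V (FR1-FR3)."""

    germline_v: str
    sequence: str                      # germline FR1-FR3 nucleotides
    coverage: np.ndarray               # (L,) int
    mut_counts: np.ndarray             # (L, 4) int, columns A/C/G/T
    region_labels: list[str] = field(default_factory=list)

    @property
    def mutations(self) -> np.ndarray:
        return self.mut_counts.sum(axis=1)

    @property
    def frequency(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.coverage > 0, self.mutations / np.maximum(self.coverage, 1), 0.0)


@dataclass
class SubstitutionSpectrum:
    counts: np.ndarray  # (4, 4), from x to, diagonal zero

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def percentages(self) -> dict[tuple[str, str], float]:
        """Each of the 12 substitution classes as a percent of all mutant bases."""
        total = self.total
        out = {}
        for i, fb in enumerate(_BASES):
            for j, tb in enumerate(_BASES):
                if i == j:
                    continue
                out[(fb, tb)] = 100.0 * self.counts[i, j] / total if total else float("nan")
        return out


@dataclass
class HotspotReport:
    motif_set: tuple[str, ...]
    per_motif: dict[str, dict] = field(default_factory=dict)


def _usable_records(records, include_ambiguous: bool):
    for rec in records:
        call = rec.v_call
        if call is None:
            continue
        if call.ambiguous_flag and not include_ambiguous:
            continue
        yield rec, call.best


def _covered_positions(alignment, read_seq: str) -> list[int]:
    """Germline positions aligned to a concrete (non-N) read base."""
    out = []
    qpos = alignment.germline_interval[0]
    tpos = alignment.read_interval[0]
    for n, op in _CIGAR_RE.findall(alignment.cigar):
        n = int(n)
        if op in "=X":
            for k in range(n):
                if read_seq[tpos + k] != "N":
                    out.append(qpos + k)
            qpos += n
            tpos += n
        elif op == "I":
            qpos += n
        else:
            tpos += n
    return out


def shm_frequency(records, germline_set: GermlineSet,
                  include_ambiguous: bool = False) -> dict:
    """Overall and per-germline-V SHM frequency, as percentages.

    frequency = observed mutant bases / total aligned non-gap non-N bases.
    Zero covered bases yields NaN.
    """
    mutated = 0
    covered = 0
    per_gene_m: dict[str, int] = {}
    per_gene_c: dict[str, int] = {}
    for rec, aln in _usable_records(records, include_ambiguous):
        seq = rec.read.nt_sequence
        cov = len(_covered_positions(aln, seq))
        mut = sum(1 for _, _, rb in aln.mutated_positions if rb != "N")
        mutated += mut
        covered += cov
        per_gene_m[aln.gene_id] = per_gene_m.get(aln.gene_id, 0) + mut
        per_gene_c[aln.gene_id] = per_gene_c.get(aln.gene_id, 0) + cov
    overall = 100.0 * mutated / covered if covered else float("nan")
    per_gene = {
        g: (100.0 * per_gene_m[g] / per_gene_c[g] if per_gene_c[g] else float("nan"))
        for g in per_gene_m
    }
    return {"overall_percent": overall, "per_gene_percent": per_gene,
            "mutated": mutated, "covered": covered}


def _region_labels(gene) -> list[str]:
    fr1_start = gene.region_bounds["FR1"][0]
    labels = []
    for name in V_REGIONS:
        s, e = gene.region_bounds[name]
        labels.extend([name] * (e - s))
        # annotation gaps between regions (unusual) are labelled as the next region
    total = gene.region_bounds["FR3"][1] - fr1_start
    if len(labels) < total:
        labels.extend(["FR3"] * (total - len(labels)))
    return labels[:total]


def per_site_profile(records, germline_set: GermlineSet,
                     include_ambiguous: bool = False) -> dict[str, SHMProfile]:
    """Per-site coverage/mutation profiles, one per germline V group."""
    profiles: dict[str, SHMProfile] = {}
    for rec, aln in _usable_records(records, include_ambiguous):
        gid = aln.gene_id
        if gid not in profiles:
            gene = germline_set[gid]
            vseq = gene.v_region()
            profiles[gid] = SHMProfile(
                germline_v=gid,
                sequence=vseq,
                coverage=np.zeros(len(vseq), dtype=int),
                mut_counts=np.zeros((len(vseq), 4), dtype=int),
                region_labels=_region_labels(gene),
            )
        prof = profiles[gid]
        for pos in _covered_positions(aln, rec.read.nt_sequence):
            prof.coverage[pos] += 1
        for pos, _gb, rb in aln.mutated_positions:
            if rb != "N":
                prof.mut_counts[pos, _BASE_IDX[rb]] += 1
    return profiles


def substitution_spectrum(records, include_ambiguous: bool = False) -> SubstitutionSpectrum:
    """Counts of mutations from each of A/T/C/G to the other three bases."""
    counts = np.zeros((4, 4), dtype=int)
    for _rec, aln in _usable_records(records, include_ambiguous):
        for _pos, gb, rb in aln.mutated_positions:
            if gb in _BASE_IDX and rb in _BASE_IDX:
                counts[_BASE_IDX[gb], _BASE_IDX[rb]] += 1
    return SubstitutionSpectrum(counts=counts)


def motif_regex(motif: str) -> re.Pattern:
    return re.compile("".join(_IUPAC_RE[c] for c in motif))


def scan_hotspots(sequence: str, motif: str) -> list[int]:
    """Positions of the mutable C/G of every (overlapping) motif occurrence."""
    if motif not in HOTSPOT_MOTIFS:
        raise ValueError(f"unsupported hotspot motif {motif!r}")
    off = HOTSPOT_MOTIFS[motif]
    pat = motif_regex(motif)
    out = []
    start = 0
    while True:
        m = pat.search(sequence, start)
        if m is None:
            return out
        out.append(m.start() + off)
        start = m.start() + 1


def hotspot_analysis(records, germline_set: GermlineSet,
                     motif_set=("WRCY", "RGYW"),
                     include_ambiguous: bool = False) -> HotspotReport:
    """Mutation frequency at AID-hotspot C/G positions vs the non-hotspot baseline.

    The mutable base is the C of WRCY/WRCH and the G of RGYW/DGYW.  For each
    motif: per-substitution-class frequencies at hotspot positions, baseline
    frequencies over all non-hotspot C (resp. G) positions, and the
    enrichment ratio of total mutation frequencies (NaN when the baseline
    has no coverage or no mutations).
    """
    motif_set = tuple(motif_set)
    if not motif_set:
        raise ValueError("empty motif set")
    profiles = per_site_profile(records, germline_set, include_ambiguous)
    report = HotspotReport(motif_set=motif_set)
    for motif in motif_set:
        base = "C" if HOTSPOT_MOTIFS[motif] == 2 else "G"
        hot_cov = hot_mut = base_cov = base_mut = 0
        n_hot = 0
        per_sub = {tb: [0, 0] for tb in _BASES if tb != base}  # [mut, cov]
        for gid, prof in profiles.items():
            hotspots = set(scan_hotspots(prof.sequence, motif))
            hotspots = {p for p in hotspots if prof.sequence[p] == base}
            n_hot += len(hotspots)
            for pos, gbase in enumerate(prof.sequence):
                if gbase != base:
                    continue
                cov = int(prof.coverage[pos])
                mut = int(prof.mutations[pos])
                if pos in hotspots:
                    hot_cov += cov
                    hot_mut += mut
                    for tb in per_sub:
                        per_sub[tb][0] += int(prof.mut_counts[pos, _BASE_IDX[tb]])
                        per_sub[tb][1] += cov
                else:
                    base_cov += cov
                    base_mut += mut
        hot_freq = hot_mut / hot_cov if hot_cov else float("nan")
        base_freq = base_mut / base_cov if base_cov else float("nan")
        enrichment = (hot_freq / base_freq
                      if base_cov and base_mut and hot_cov else float("nan"))
        report.per_motif[motif] = {
            "mutable_base": base,
            "n_hotspot_positions": n_hot,
            "hotspot_frequency": hot_freq,
            "baseline_frequency": base_freq,
            "enrichment": enrichment,
            "per_substitution_frequency": {
                f"{base}>{tb}": (m / c if c else float("nan"))
                for tb, (m, c) in per_sub.items()
            },
        }
    return report
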