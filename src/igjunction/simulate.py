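"""Synthetic V(D)J-rearranged, SHM-bearing repertoire reads with ground truth.

The generator emulates the statistical structure of 5'-RACE immunoglobulin
amplicons: one germline V, (D,) and J are drawn by configurable usage
weights (J usage heavily biased, as observed in bovid repertoires), coding
ends are exonucleolytically trimmed from discrete empirical distributions
(V 3' deletions concentrated at 0-3 bp with a maximum of 8; J 5' deletions
at 0/3/6 bp with a maximum of 12), palindromic P nucleotides appear only at
untrimmed ends (0-2 bp), non-templated N nucleotides are inserted (short
for light chains, longer for heavy), somatic hypermutation is applied over
FR1-FR3 with a transition-biased substitution spectrum, a CDR rate
multiplier and WRCY/RGYW hotspot enrichment, and reads are decorated with
the amplification primers.  An optional ultra-long CDR3H mode rearranges a
(YG)n-rich D segment with minimal trimming.

Every read carries a :class:`GroundTruth` record; replaying the truth
against the germline set reproduces the read byte-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import revcomp, CODON_TABLE, STOP_CODONS
from .germline import (
    FUNCTIONAL,
    GermlineGene,
    GermlineSet,
    Rss,
    assign_clans,
    classify_j_gene,
    classify_v_gene,
    j_anchor_offset,
)
from .qc import Read
from .shm import scan_hotspots

FWD_PRIMER = "AAGCAGTGGTATCAACGCAGAGT"
REV_PRIMERS = {"IGH": "AGCTCACGCAGGACACCAG",
               "IGK": "AGATGGATGGCTGAGCATCA",
               "IGL": "GTGACCGAGGGTGCGGACTT"}

_BASES = "ACGT"

# V-region layout (nt): IMGT-like region lengths, FR1 ends with the
# conserved Cys-23 four codons from its end, FR3 ends with Tyr-Tyr-Cys-104.
_V_LAYOUT = (("FR1", 78), ("CDR1", 36), ("FR2", 51), ("CDR2", 30), ("FR3", 117))
_V_LEN = sum(n for _, n in _V_LAYOUT)
_V_TAIL_LEN = 8          # germline 3' continuation past FR3 (CDR3-contributing)
_J_5P_LEN = 20           # J nucleotides 5' of the conserved anchor (trimmable)

_SAFE_CODONS = sorted(c for c in CODON_TABLE if c not in STOP_CODONS)


# ---------------------------------------------------------------------------
# Toy germline set


def _random_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_SAFE_CODONS) for _ in range(n))


def _mutate(rng: np.random.Generator, seq: str, n_sub: int,
            protected_codons: set[int]) -> str:
    """Apply n_sub random substitutions, avoiding protected codons and stops."""
    out = list(seq)
    done = 0
    while done < n_sub:
        pos = int(rng.integers(len(seq)))
        if pos // 3 in protected_codons:
            continue
        new = rng.choice([b for b in _BASES if b != out[pos]])
        old = out[pos]
        out[pos] = new
        codon_start = 3 * (pos // 3)
        if "".join(out[codon_start : codon_start + 3]) in STOP_CODONS:
            out[pos] = old
            continue
        done += 1
    return "".join(out)


def _build_v_sequence(rng: np.random.Generator) -> str:
    """A random functional V: FR1-FR3 with planted Cys-23, Tyr-Tyr-Cys-104, plus 3' tail."""
    n_codons = _V_LEN // 3
    seq = [str(rng.choice(_SAFE_CODONS)) for _ in range(n_codons)]
    seq[(78 // 3) - 4] = "TGT"            # Cys-23: 4th codon from FR1 end
    seq[n_codons - 3] = "TAT"             # Tyr
    seq[n_codons - 2] = "TAC"             # Tyr
    seq[n_codons - 1] = "TGT"             # Cys-104
    tail = "".join(rng.choice(list(_BASES)) for _ in range(_V_TAIL_LEN))
    return "".join(seq) + tail


_PROTECTED = {(78 // 3) - 4, _V_LEN // 3 - 3, _V_LEN // 3 - 2, _V_LEN // 3 - 1}


def _v_bounds() -> dict[str, tuple[int, int]]:
    bounds = {}
    pos = 0
    for name, n in _V_LAYOUT:
        bounds[name] = (pos, pos + n)
        pos += n
    return bounds


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES)) for _ in range(n))


def make_toy_germline(seed: int = 0, locus: str = "IGH") -> GermlineSet:
    """A deterministic small germline set exercising every classifier branch.

    Six functional V genes in two clans (three near-identical members each),
    one ORF V (Cys-104 lost), one pseudogene V (internal stop), one
    incomplete V (5'-truncated); for IGH four D genes including a (YG)n-rich
    ultra-long D; three functional J genes plus one lacking the conserved
    WGXG/FGXG motif; and a constant-region stub.
    """
    rng = np.random.default_rng(seed)
    genes: dict[str, GermlineGene] = {}
    bounds = _v_bounds()
    prefix = locus

    def add(gene: GermlineGene) -> None:
        genes[gene.gene_id] = gene

    # two clans of three functional V genes each
    seeds = [_build_v_sequence(rng), _build_v_sequence(rng)]
    vnum = 1
    for clan_seed in seeds:
        for _ in range(3):
            body = _mutate(rng, clan_seed[:_V_LEN], int(rng.integers(2, 7)), _PROTECTED)
            seq = body + clan_seed[_V_LEN:]
            add(GermlineGene(
                gene_id=f"{prefix}V{vnum}", locus=locus, segment_type="V",
                nt_sequence=seq, region_bounds=dict(bounds),
                rss=Rss("CACAGTG", 23, "ACAAAAACC", len(seq)),
            ))
            vnum += 1
    # ORF: Cys-104 codon TGT -> AGT (Ser)
    v1 = genes[f"{prefix}V1"].nt_sequence
    orf_seq = v1[: _V_LEN - 3] + "AGT" + v1[_V_LEN:]
    add(GermlineGene(gene_id=f"{prefix}V7", locus=locus, segment_type="V",
                     nt_sequence=orf_seq, region_bounds=dict(bounds)))
    # pseudogene: TAA planted mid-FR2
    v2 = genes[f"{prefix}V2"].nt_sequence
    fr2_mid = bounds["FR2"][0] + 24
    pseudo_seq = v2[:fr2_mid] + "TAA" + v2[fr2_mid + 3 :]
    add(GermlineGene(gene_id=f"{prefix}V8", locus=locus, segment_type="V",
                     nt_sequence=pseudo_seq, region_bounds=dict(bounds)))
    # incomplete: FR1 missing (5'-truncated annotation)
    v3 = genes[f"{prefix}V3"].nt_sequence
    trunc = v3[bounds["CDR1"][0] :]
    shift = bounds["CDR1"][0]
    trunc_bounds = {k: (s - shift, e - shift) for k, (s, e) in bounds.items() if k != "FR1"}
    add(GermlineGene(gene_id=f"{prefix}V9", locus=locus, segment_type="V",
                     nt_sequence=trunc, region_bounds=trunc_bounds))

    if locus == "IGH":
        for gid, n in ((f"{prefix}D1", 17), (f"{prefix}D2", 12), (f"{prefix}D3", 20)):
            while True:
                seq = _random_dna(rng, n)
                if any("*" not in _translate_frames(seq, f) for f in range(3)):
                    break
            add(GermlineGene(gene_id=gid, locus=locus, segment_type="D",
                             nt_sequence=seq))
        add(GermlineGene(gene_id=f"{prefix}D4", locus=locus, segment_type="D",
                         nt_sequence="TATGGT" * 15))  # (YG)n ultra-long D

    fr4 = {"IGH": ["TGGGGCCAAGGAACCACGGTCACCGTCTCCTCA",   # WGQGTTVTVSS
                   "TGGGGCAAAGGGACCCAGGTCACCGTCTCCTCA",   # WGKGTQVTVSS
                   "TGGGGCTCAGGCACCCTGGTCACTGTCTCCTCA"],  # WGSGTLVTVSS
           "IGK": ["TTTGGCTCGGGGACCAAGGTGGAAATCAAACGA",   # FGSGTKVEIKR
                   "TTCGGCCAAGGGACACGACTGGAGATTAAACGA",   # FGQGTRLEIKR
                   "TTTGGCGGAGGGACCAAGCTGGAGATCAAACGA"],  # FGGGTKLEIKR
           "IGL": ["TTCGGCGGAGGGACCCAGCTGACCGTCCTAGGT",   # FGGGTQLTVLG
                   "TTTGGCAGCGGGACCCAGGTGACCGTCCTAGGT",   # FGSGTQVTVLG
                   "TTCGGAACTGGGACCAAGGTCACCGTCCTAGGT"]}  # FGTGTKVTVLG
    def _j_5p(rng) -> str:
        # stop-free in the FR4-aligned frame so the anchor frame stays open
        lead = _J_5P_LEN % 3
        return (_random_dna(rng, lead)
                + _random_codons(rng, (_J_5P_LEN - lead) // 3))

    for i, core in enumerate(fr4[locus], 1):
        seq = _j_5p(rng) + core
        add(GermlineGene(gene_id=f"{prefix}J{i}", locus=locus, segment_type="J",
                         nt_sequence=seq))
    # pseudogene J: anchor W/F codon destroyed (W->R / F->L)
    broken = ("CGG" if locus == "IGH" else "CTG") + fr4[locus][0][3:]
    while True:
        j4 = _j_5p(rng) + broken
        probe = GermlineGene(gene_id="probe", locus=locus, segment_type="J",
                             nt_sequence=j4)
        if classify_j_gene(probe) != FUNCTIONAL:
            break
    add(GermlineGene(gene_id=f"{prefix}J4", locus=locus, segment_type="J",
                     nt_sequence=j4))

    add(GermlineGene(gene_id=f"{prefix}C", locus=locus, segment_type="C",
                     nt_sequence=_random_dna(rng, 60)))

    gs = GermlineSet(genes=genes, locus=locus,
                     metadata={"source": "synthetic toy germline", "seed": seed})
    for g in gs.by_type("V"):
        g.functionality = classify_v_gene(g)
    for g in gs.by_type("J"):
        g.functionality = classify_j_gene(g)
    for g in gs.by_type("D"):
        g.functionality = FUNCTIONAL
    labels, _ = assign_clans([g for g in gs.by_type("V")])
    for gid, label in labels.items():
        gs[gid].clan = label
    return gs


def _translate_frames(seq: str, frame: int) -> str:
    from ._seq import translate
    return translate(seq, frame)


# ---------------------------------------------------------------------------
# Simulation configuration


def _default_spectrum() -> dict[str, float]:
    """Transition-biased 12-class substitution weights (A<->G highest, C<->T next)."""
    w = {f"{a}>{b}": 0.0525 for a in _BASES for b in _BASES if a != b}
    w["A>G"] = w["G>A"] = 0.17
    w["C>T"] = w["T>C"] = 0.12
    return w


_DEL_DISTS = {
    # V 3' deletions: modes 0, 2 and 3 bp; maximum 8 bp
    "IGH_v": {0: 0.30, 1: 0.06, 2: 0.22, 3: 0.22, 4: 0.08, 5: 0.05, 6: 0.04, 7: 0.02, 8: 0.01},
    # J 5' deletions: modes 0, 3 and 6 bp (4 bp secondary); maximum 12 bp
    "IGH_j": {0: 0.28, 1: 0.04, 2: 0.05, 3: 0.20, 4: 0.12, 5: 0.05, 6: 0.15,
              7: 0.04, 8: 0.03, 9: 0.015, 10: 0.01, 11: 0.005, 12: 0.01},
    # light-chain deletions concentrated at 1-3 bp (kappa) / 0-3 bp (lambda)
    "IGK_v": {0: 0.15, 1: 0.25, 2: 0.25, 3: 0.25, 4: 0.07, 5: 0.03},
    "IGK_j": {0: 0.15, 1: 0.25, 2: 0.25, 3: 0.25, 4: 0.07, 5: 0.03},
    "IGL_v": {0: 0.28, 1: 0.24, 2: 0.24, 3: 0.16, 4: 0.05, 5: 0.03},
    "IGL_j": {0: 0.28, 1: 0.24, 2: 0.24, 3: 0.16, 4: 0.05, 5: 0.03},
}

_N_DISTS = {
    "IGH": {0: 0.05, 1: 0.08, 2: 0.12, 3: 0.15, 4: 0.15, 5: 0.13, 6: 0.10,
            7: 0.08, 8: 0.06, 9: 0.04, 10: 0.04},
    "IGK": {0: 0.55, 1: 0.35, 2: 0.10},
    "IGL": {0: 0.40, 1: 0.30, 2: 0.20, 3: 0.10},
}

_P_DISTS = {
    "IGH": {0: 0.55, 1: 0.30, 2: 0.15},
    "IGK": {0: 0.55, 1: 0.35, 2: 0.10},
    "IGL": {0: 0.45, 1: 0.35, 2: 0.20},
}

_SHM_RATES = {"IGH": 0.082, "IGK": 0.024, "IGL": 0.076}


@dataclass
class SimulationConfig:
    locus: str = "IGH"
    n_reads: int = 1000
    seed: int = 0
    germline_seed: int = 0
    v_weights: dict[str, float] | None = None    # None: uniform over functional V
    d_weights: dict[str, float] | None = None    # None: uniform over non-ultralong D
    j_weights: dict[str, float] | None = None    # None: heavily biased (0.95/0.04/0.01)
    v_del_dist: dict[int, float] | None = None
    j_del_dist: dict[int, float] | None = None
    d_del_dist: dict[int, float] = field(
        default_factory=lambda: {0: 0.35, 1: 0.25, 2: 0.20, 3: 0.12, 4: 0.08})
    p_len_dist: dict[int, float] | None = None
    n_len_dist: dict[int, float] | None = None
    shm_rate: float | None = None                # per-base over FR1-FR3
    cdr_rate_multiplier: float = 3.0
    hotspot_multiplier: float = 5.0
    hotspot_motifs: tuple[str, ...] = ("WRCY", "RGYW")
    spectrum_weights: dict[str, float] = field(default_factory=_default_spectrum)
    ultralong_fraction: float = 0.05             # IGH only
    ultralong_d_template: str | None = None      # default: the (YG)n D gene
    add_primers: bool = True
    error_rate: float = 0.0                      # separate uniform error channel, off

    def resolved(self, germline_set: GermlineSet) -> "SimulationConfig":
        """Fill locus-dependent defaults and validate against the germline set."""
        cfg = replace(self)
        loc = cfg.locus
        if cfg.v_del_dist is None:
            cfg.v_del_dist = dict(_DEL_DISTS[f"{loc}_v"])
        if cfg.j_del_dist is None:
            cfg.j_del_dist = dict(_DEL_DISTS[f"{loc}_j"])
        if cfg.n_len_dist is None:
            cfg.n_len_dist = dict(_N_DISTS[loc])
        if cfg.p_len_dist is None:
            cfg.p_len_dist = dict(_P_DISTS[loc])
        if cfg.shm_rate is None:
            cfg.shm_rate = _SHM_RATES[loc]
        functional_v = germline_set.by_type("V", functional_only=True)
        functional_j = germline_set.by_type("J", functional_only=True)
        if not functional_v or not functional_j:
            raise ValueError("germline set lacks functional V or J genes")
        if cfg.v_weights is None:
            cfg.v_weights = {g.gene_id: 1.0 for g in functional_v}
        if cfg.j_weights is None:
            biased = [0.95, 0.04, 0.01]
            cfg.j_weights = {
                g.gene_id: (biased[i] if i < len(biased) else 0.0)
                for i, g in enumerate(functional_j)
            }
        if loc == "IGH":
            d_genes = germline_set.by_type("D")
            if not d_genes:
                raise ValueError("IGH simulation requires D genes")
            if cfg.ultralong_d_template is None:
                cfg.ultralong_d_template = max(
                    d_genes, key=lambda g: len(g.nt_sequence)).gene_id
            if cfg.d_weights is None:
                cfg.d_weights = {g.gene_id: 1.0 for g in d_genes
                                 if g.gene_id != cfg.ultralong_d_template}
        # feasibility checks
        for gid in cfg.v_weights:
            gene = germline_set[gid]
            tail = len(gene.nt_sequence) - gene.region_bounds["FR3"][1]
            if max(cfg.v_del_dist) > tail:
                raise ValueError(
                    f"v_del_dist support {max(cfg.v_del_dist)} exceeds the "
                    f"{tail} nt 3' tail of {gid}")
        for gid in cfg.j_weights:
            anchor = j_anchor_offset(germline_set[gid])
            if anchor is not None and max(cfg.j_del_dist) > anchor:
                raise ValueError(
                    f"j_del_dist support {max(cfg.j_del_dist)} exceeds the "
                    f"{anchor} nt trimmable 5' part of {gid}")
        return cfg


@dataclass
class GroundTruth:
    """Per-read generative truth; replaying it reproduces the read exactly."""

    read_id: str
    v_id: str
    d_id: str | None
    j_id: str
    v_deletion: int
    j_deletion: int
    d_deletion_5p: int
    d_deletion_3p: int
    p1: str
    n1: str
    p_d5: str
    p_d3: str
    n2: str
    p2: str
    cdr3_start: int          # on the final (decorated) read, 0-based half-open
    cdr3_end: int
    shm_events: list[tuple[int, str, str]]  # (FR1-FR3 position, from, to)
    ultralong: bool = False


def _draw(rng: np.random.Generator, dist: dict) -> object:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]


def _apply_shm(rng: np.random.Generator, vseq: str, cfg: SimulationConfig,
               gene: GermlineGene) -> tuple[str, list[tuple[int, str, str]]]:
    """Mutate the FR1-FR3 window: Binomial(L, rate) events, spectrum-drawn
    classes, site choice weighted by CDR and hotspot multipliers."""
    L = len(vseq)
    n_mut = int(rng.binomial(L, cfg.shm_rate))
    if n_mut == 0:
        return vseq, []
    weights = np.ones(L)
    pos = 0
    fr1_start = gene.region_bounds["FR1"][0]
    for name in ("FR1", "CDR1", "FR2", "CDR2", "FR3"):
        s, e = gene.region_bounds[name]
        if name.startswith("CDR"):
            weights[s - fr1_start : e - fr1_start] *= cfg.cdr_rate_multiplier
        pos = e
    for motif in cfg.hotspot_motifs:
        for p in scan_hotspots(vseq, motif):
            weights[p] *= cfg.hotspot_multiplier

    classes = sorted(cfg.spectrum_weights)
    class_p = np.array([cfg.spectrum_weights[c] for c in classes])
    class_p = class_p / class_p.sum()
    out = list(vseq)
    mutated: set[int] = set()
    events: list[tuple[int, str, str]] = []
    by_base: dict[str, list[int]] = {b: [] for b in _BASES}
    for i, b in enumerate(vseq):
        if b in by_base:
            by_base[b].append(i)
    attempts = 0
    while len(events) < n_mut and attempts < 50 * n_mut:
        attempts += 1
        cls = classes[int(rng.choice(len(classes), p=class_p))]
        fb, tb = cls[0], cls[2]
        sites = [i for i in by_base[fb] if i not in mutated]
        if not sites:
            continue
        w = weights[sites]
        site = sites[int(rng.choice(len(sites), p=w / w.sum()))]
        out[site] = tb
        mutated.add(site)
        events.append((site, fb, tb))
    events.sort()
    return "".join(out), events


def simulate_repertoire(
    config: SimulationConfig, germline_set: GermlineSet | None = None
) -> tuple[list[Read], list[GroundTruth], SimulationConfig]:
    """Generate reads and their ground truth; returns the resolved config too."""
    if germline_set is None:
        germline_set = make_toy_germline(config.germline_seed, config.locus)
    cfg = config.resolved(germline_set)
    rng = np.random.default_rng(cfg.seed)
    heavy = cfg.locus == "IGH"
    fwd = FWD_PRIMER if cfg.add_primers else ""
    rev_rc = revcomp(REV_PRIMERS[cfg.locus]) if cfg.add_primers else ""
    c_genes = germline_set.by_type("C")
    c_seq = c_genes[0].nt_sequence if c_genes else ""

    reads: list[Read] = []
    truths: list[GroundTruth] = []
    for i in range(cfg.n_reads):
        rid = f"sim_{i:06d}"
        v_id = _draw(rng, cfg.v_weights)
        j_id = _draw(rng, cfg.j_weights)
        vgene = germline_set[v_id]
        jgene = germline_set[j_id]
        v_tail = vgene.nt_sequence[vgene.region_bounds["FR3"][1] :]
        anchor = j_anchor_offset(jgene)

        ultralong = heavy and rng.random() < cfg.ultralong_fraction
        d_id = None
        if heavy:
            d_id = cfg.ultralong_d_template if ultralong else _draw(rng, cfg.d_weights)
        v_del = int(_draw(rng, cfg.v_del_dist))
        j_del = int(_draw(rng, cfg.j_del_dist))
        p1 = pd5 = pd3 = p2 = ""
        if v_del == 0:
            l = int(_draw(rng, cfg.p_len_dist))
            p1 = revcomp(vgene.nt_sequence[len(vgene.nt_sequence) - l :]) if l else ""
        if j_del == 0:
            l = int(_draw(rng, cfg.p_len_dist))
            p2 = revcomp(jgene.nt_sequence[:l]) if l else ""
        n1 = "".join(rng.choice(list(_BASES))
                     for _ in range(int(_draw(rng, cfg.n_len_dist))))
        n2 = ""
        d_del5 = d_del3 = 0
        d_retained = ""
        if heavy:
            dgene = germline_set[d_id]
            dl = len(dgene.nt_sequence)
            d_del5 = int(_draw(rng, cfg.d_del_dist))
            d_del3 = int(_draw(rng, cfg.d_del_dist))
            if ultralong:
                d_del5, d_del3 = min(d_del5, 2), min(d_del3, 2)
            d_del5 = min(d_del5, dl)
            d_del3 = min(d_del3, dl - d_del5)
            d_retained = dgene.nt_sequence[d_del5 : dl - d_del3]
            if d_del5 == 0:
                l = int(_draw(rng, cfg.p_len_dist))
                pd5 = revcomp(dgene.nt_sequence[:l]) if l else ""
            if d_del3 == 0:
                l = int(_draw(rng, cfg.p_len_dist))
                pd3 = revcomp(dgene.nt_sequence[dl - l :]) if l else ""
            n2 = "".join(rng.choice(list(_BASES))
                         for _ in range(int(_draw(rng, cfg.n_len_dist))))

        vseq = vgene.v_region()
        mutated_v, events = _apply_shm(rng, vseq, cfg, vgene)
        tail_ret = v_tail[: len(v_tail) - v_del]
        j_ret = jgene.nt_sequence[j_del:]
        if heavy:
            insert = p1 + n1 + pd5 + d_retained + pd3 + n2 + p2
        else:
            insert = p1 + n1 + p2
        core = mutated_v + tail_ret + insert + j_ret + c_seq
        seq = fwd + core + rev_rc
        cdr3_start = len(fwd) + len(mutated_v)
        cdr3_end = cdr3_start + len(tail_ret) + len(insert) + (anchor - j_del)
        reads.append(Read(rid, seq))
        truths.append(GroundTruth(
            read_id=rid, v_id=v_id, d_id=d_id, j_id=j_id,
            v_deletion=v_del, j_deletion=j_del,
            d_deletion_5p=d_del5, d_deletion_3p=d_del3,
            p1=p1, n1=n1, p_d5=pd5, p_d3=pd3, n2=n2, p2=p2,
            cdr3_start=cdr3_start, cdr3_end=cdr3_end,
            shm_events=events, ultralong=ultralong,
        ))
    return reads, truths, cfg


def replay_truth(truth: GroundTruth, germline_set: GermlineSet,
                 cfg: SimulationConfig) -> str:
    """Rebuild a read from its ground truth; must equal the emitted read."""
    vgene = germline_set[truth.v_id]
    jgene = germline_set[truth.j_id]
    vseq = list(vgene.v_region())
    for pos, fb, tb in truth.shm_events:
        assert vseq[pos] == fb
        vseq[pos] = tb
    v_tail = vgene.nt_sequence[vgene.region_bounds["FR3"][1] :]
    tail_ret = v_tail[: len(v_tail) - truth.v_deletion]
    parts = [truth.p1, truth.n1]
    if truth.d_id is not None:
        dgene = germline_set[truth.d_id]
        dl = len(dgene.nt_sequence)
        parts += [truth.p_d5,
                  dgene.nt_sequence[truth.d_deletion_5p : dl - truth.d_deletion_3p],
                  truth.p_d3, truth.n2]
    parts.append(truth.p2)
    j_ret = jgene.nt_sequence[truth.j_deletion :]
    c_genes = germline_set.by_type("C")
    c_seq = c_genes[0].nt_sequence if c_genes else ""
    fwd = FWD_PRIMER if cfg.add_primers else ""
    rev_rc = revcomp(REV_PRIMERS[cfg.locus]) if cfg.add_primers else ""
    return fwd + "".join(vseq) + tail_ret + "".join(parts) + j_ret + c_seq + rev_rc
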