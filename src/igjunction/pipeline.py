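"""Pipeline orchestration: QC -> V/D/J assignment -> junction -> SHM -> usage stats.

Each stage consumes the previous stage's output; reruns with identical
inputs and seed are bit-identical (timestamps appear only in the stderr
log).  Stage failures abort with a stage-tagged error.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as igio
from .assign import assign_d, assign_j, assign_v
from .germline import GermlineSet, classify_j_gene, classify_v_gene, load_germline, assign_clans
from .junction import decompose_junction, junction_length_stats, locate_cdr3
from .qc import filter_reads
from .records import RearrangementRecord, annotate_productivity
from .repstats import combination_table, segment_contribution_stats, usage_frequencies
from .shm import hotspot_analysis, per_site_profile, shm_frequency, substitution_spectrum
from .simulate import FWD_PRIMER, REV_PRIMERS

log = logging.getLogger("igjunction")

STAGES = ("qc", "assign", "junction", "shm", "stats")


@dataclass
class RunConfig:
    locus: str = "IGH"
    germline_fasta: str = ""
    germline_regions: str | None = None
    reads_path: str = ""
    output_dir: str = "igjunction_out"
    seed: int = 0
    # qc
    forward_primer: str = FWD_PRIMER
    reverse_primer: str | None = None     # default: locus-specific
    min_length: int = 400
    max_primer_mm: int = 2
    primer_window: int = 50
    require_primers: str = "both"
    # assignment
    tie_margin: int = 0
    min_v_identity: float = 0.5
    min_j_identity: float = 0.8
    min_d_match: int = 5
    # junction
    max_p_len: int = 4
    # shm
    hotspot_motifs: tuple[str, ...] = ("WRCY", "RGYW")
    include_ambiguous_shm: bool = False
    # stats
    dedup: bool = False
    clan_identity_threshold: float = 0.75
    stop_after: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "hotspot_motifs" in data:
            data["hotspot_motifs"] = tuple(data["hotspot_motifs"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["hotspot_motifs"] = list(self.hotspot_motifs)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def prepare_germline(config: RunConfig) -> GermlineSet:
    gs = load_germline(config.germline_fasta, config.germline_regions)
    for g in gs.by_type("V"):
        if g.functionality is None:
            g.functionality = classify_v_gene(g)
    for g in gs.by_type("J"):
        if g.functionality is None:
            g.functionality = classify_j_gene(g)
    labels, _ = assign_clans(gs.by_type("V"), config.clan_identity_threshold)
    for gid, label in labels.items():
        gs[gid].clan = label
    return gs


def annotate_read(read, germline_set: GermlineSet, config: RunConfig) -> RearrangementRecord:
    rec = RearrangementRecord(read=read)
    rec.v_call = assign_v(read, germline_set, config.tie_margin, config.min_v_identity)
    if rec.v_call is None:
        rec.flags.append("v_unassigned")
        return rec
    rec.j_call = assign_j(read, germline_set, rec.v_call,
                          config.tie_margin, config.min_j_identity)
    if rec.j_call is None:
        rec.flags.append("j_unassigned")
        return rec
    if germline_set.locus == "IGH":
        rec.d_call = assign_d(read, germline_set, rec.v_call, rec.j_call,
                              config.min_d_match)
    rec.cdr3 = locate_cdr3(read, rec.v_call, rec.j_call, germline_set)
    if rec.cdr3 is None:
        rec.flags.append("cdr3_missing")
    try:
        rec.decomposition = decompose_junction(
            read, rec.v_call.best, rec.j_call.best, germline_set,
            d_call=rec.d_call, max_p_len=config.max_p_len,
            min_d_match=config.min_d_match,
        )
        if rec.decomposition.ambiguous:
            rec.flags.append("attribution_ambiguous")
        if rec.d_call is not None and not rec.decomposition.retained_d:
            rec.d_call = None  # D evidence did not survive P/N attribution
    except ValueError:
        rec.flags.append("junction_failed")
    annotate_productivity(rec)
    return rec


def annotate_reads(reads, germline_set: GermlineSet,
                   config: RunConfig | None = None) -> list[RearrangementRecord]:
    config = config or RunConfig(locus=germline_set.locus)
    return [annotate_read(r, germline_set, config) for r in reads]


def _write_stats(records, germline_set: GermlineSet, config: RunConfig,
                 out: Path) -> None:
    heavy = germline_set.locus == "IGH"
    segments = ("V", "D", "J") if heavy else ("V", "J")
    for segment in segments:
        for level in ("gene", "clan") if segment == "V" else ("gene",):
            tbl = usage_frequencies(records, segment, level, dedup=config.dedup)
            tbl.table.to_csv(out / f"usage_{segment.lower()}_{level}.tsv",
                             sep="\t", index=False)
    combination_table(records).to_csv(out / "combinations.tsv", sep="\t", index=False)
    contrib = segment_contribution_stats(records)
    rows = [{"quantity": k, **v} for k, v in contrib.items() if isinstance(v, dict)]
    pd.DataFrame(rows).to_csv(out / "segment_contributions.tsv", sep="\t", index=False)


def _write_shm(records, germline_set: GermlineSet, config: RunConfig,
               out: Path) -> None:
    freq = shm_frequency(records, germline_set, config.include_ambiguous_shm)
    rows = [{"group": "overall", "shm_percent": freq["overall_percent"],
             "mutated": freq["mutated"], "covered": freq["covered"]}]
    for g, pct in sorted(freq["per_gene_percent"].items()):
        rows.append({"group": g, "shm_percent": pct, "mutated": "", "covered": ""})
    pd.DataFrame(rows).to_csv(out / "shm_summary.tsv", sep="\t", index=False)

    profiles = per_site_profile(records, germline_set, config.include_ambiguous_shm)
    prow = []
    for gid in sorted(profiles):
        prof = profiles[gid]
        freqs = prof.frequency
        for pos in range(len(prof.sequence)):
            prow.append({
                "germline_v": gid, "position": pos,
                "region": prof.region_labels[pos] if pos < len(prof.region_labels) else "",
                "germline_base": prof.sequence[pos],
                "coverage": int(prof.coverage[pos]),
                "mutations": int(prof.mutations[pos]),
                "frequency": float(freqs[pos]),
            })
    pd.DataFrame(prow).to_csv(out / "shm_profile.tsv", sep="\t", index=False)

    spectrum = substitution_spectrum(records, config.include_ambiguous_shm)
    pct = spectrum.percentages()
    srow = [{"from_base": f, "to_base": t,
             "count": int(spectrum.counts["ACGT".index(f), "ACGT".index(t)]),
             "percent": pct[(f, t)]}
            for f in "ACGT" for t in "ACGT" if f != t]
    pd.DataFrame(srow).to_csv(out / "spectrum.tsv", sep="\t", index=False)

    report = hotspot_analysis(records, germline_set, config.hotspot_motifs,
                              config.include_ambiguous_shm)
    hrow = []
    for motif, data in report.per_motif.items():
        row = {"motif": motif, "mutable_base": data["mutable_base"],
               "n_hotspot_positions": data["n_hotspot_positions"],
               "hotspot_frequency": data["hotspot_frequency"],
               "baseline_frequency": data["baseline_frequency"],
               "enrichment": data["enrichment"]}
        row.update(data["per_substitution_frequency"])
        hrow.append(row)
    pd.DataFrame(hrow).to_csv(out / "hotspot.tsv", sep="\t", index=False)


def run_pipeline(config: RunConfig) -> Path:
    """Execute qc -> assign -> junction -> shm -> stats; returns the output dir."""
    logging.basicConfig(stream=sys.stderr, level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not Path(config.germline_fasta).exists():
        raise FileNotFoundError(f"germline FASTA not found: {config.germline_fasta}")
    if not Path(config.reads_path).exists():
        raise FileNotFoundError(f"reads file not found: {config.reads_path}")

    stage = "qc"
    try:
        germline_set = prepare_germline(config)
        reads = igio.read_sequences(config.reads_path)
        rev = config.reverse_primer or REV_PRIMERS[config.locus]
        kept, report = filter_reads(
            reads, config.forward_primer, rev, config.min_length,
            config.max_primer_mm, window=config.primer_window,
            require=config.require_primers,
        )
        pd.DataFrame([
            {"n_input": report.n_input, "n_kept": report.n_kept,
             "n_fail_primer": report.n_fail_primer,
             "n_fail_length": report.n_fail_length}
        ]).to_csv(out / "qc_report.tsv", sep="\t", index=False)
        log.info("qc: %d in, %d kept", report.n_input, report.n_kept)
        config.to_yaml(out / "config.resolved.yaml")
        if config.stop_after == "qc":
            return out

        stage = "assign/junction"
        records = annotate_reads(kept, germline_set, config)
        igio.write_airr(records, out / "airr.tsv", germline_set)
        log.info("annotate: %d records", len(records))
        if config.stop_after in ("assign", "junction"):
            return out

        stage = "junction-stats"
        jstats = junction_length_stats(records)
        rows = [{"quantity": k, **{kk: vv for kk, vv in v.items() if kk != "counts"},
                 "counts": ";".join(f"{a}:{b}" for a, b in sorted(v["counts"].items()))}
                for k, v in jstats.items() if isinstance(v, dict)]
        pd.DataFrame(rows).to_csv(out / "junction_stats.tsv", sep="\t", index=False)

        stage = "shm"
        _write_shm(records, germline_set, config, out)
        if config.stop_after == "shm":
            return out

        stage = "stats"
        _write_stats(records, germline_set, config, out)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
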