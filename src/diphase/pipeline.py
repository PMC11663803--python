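"""Six-stage pipeline driver: place -> link-snps -> filter-hic ->
detect-switches -> phase -> emit, with per-stage counts in report.json."""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

from . import emitter, hic_filter, phaser, placement, switch_detector, variant_link
from .fastaio import read_fasta, write_fasta
from .pafio import read_paf

log = logging.getLogger("diphase")
STAGES = ("place", "link-snps", "filter-hic", "detect-switches", "phase", "emit")

DEFAULTS = {
    "q": hic_filter.DEFAULT_MAPQ,
    "e": hic_filter.DEFAULT_EDIT_DIST,
    "bin_size": switch_detector.DEFAULT_BIN_SIZE,
    "min_support": None,
    "min_block_len": 1000,
    "seed": 42,
    "restarts": 100,
    "dedup": False,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_place(primary_fa, alternate_fa, paf, out_dir, min_block_len=1000) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    primary = read_fasta(primary_fa)
    alternate = read_fasta(alternate_fa)
    segments = read_paf(paf)
    if not segments:
        raise ValueError("no segments")
    placements, retained = placement.resolve_placements(segments)
    lengths = {c: len(s) for c, s in primary.items()}
    blocks, pairing = placement.mince(lengths, placements, min_block_len)
    for role, fname in (("hap1", "hap1.fasta"), ("hap2", "hap2.fasta"),
                        ("collapsed", "collapsed.fasta")):
        recs = [(b.block_id, placement.block_sequence(b, primary, alternate))
                for b in blocks if b.role == role]
        write_fasta(out / fname, recs)
    placement.write_blocks_bed(out / "blocks.bed", blocks)
    placement.write_pairing(out / "pairing.tsv", pairing, blocks)
    return {"segments": len(segments), "chained": len(retained),
            "placements": len(placements), "blocks": len(blocks),
            "hap_pairs": sum(1 for b in blocks if b.role == "hap2")}


def stage_link_snps(paf, primary_fa, alternate_fa, primary_vcf, alternate_vcf,
                    blocks_bed, out_dir) -> dict:
    out = Path(out_dir)
    primary = read_fasta(primary_fa)
    alternate = read_fasta(alternate_fa)
    segments = read_paf(paf)
    _, retained = placement.resolve_placements(segments)
    posmap = variant_link.build_position_map(retained, primary, alternate)
    pairs, stats = variant_link.cross_validate_snps(primary_vcf, alternate_vcf, posmap)
    variant_link.write_snp_tsv(out / "snps.tsv", pairs)
    blocks = placement.read_blocks_bed(blocks_bed)
    minced = variant_link.lift_to_minced(pairs, blocks)
    with open(out / "snps.minced.tsv", "w") as fh:
        for ref in sorted(minced):
            for pos in minced[ref]:
                fh.write(f"{ref}\t{pos}\n")
    stats["minced_positions"] = sum(len(v) for v in minced.values())
    return stats


def read_minced_snps(path) -> dict[str, list[int]]:
    snps: dict[str, list[int]] = {}
    with open(path) as fh:
        for line in fh:
            ref, pos = line.split()
            snps.setdefault(ref, []).append(int(pos))
    return {r: sorted(v) for r, v in snps.items()}


def stage_filter_hic(hic_sam, minced_snps_tsv, out_dir, q=None, e=None,
                     dedup=False) -> dict:
    out = Path(out_dir)
    q = DEFAULTS["q"] if q is None else q
    e = DEFAULTS["e"] if e is None else e
    snps = read_minced_snps(minced_snps_tsv) if minced_snps_tsv else {}
    pairs, prestats = hic_filter.prefilter_records(hic_sam)
    kept, fstats = hic_filter.filter_matepairs(pairs, snps, q=q, e=e, dedup=dedup)
    hic_filter.write_pairs_tsv(out / "pairs.tsv", kept)
    stats = {**prestats, **fstats}
    with open(out / "filter_summary.json", "w") as fh:
        json.dump(stats, fh, indent=2)
    return stats


def stage_detect_switches(pairs_tsv, blocks_bed, pairing_tsv, out_dir,
                          bin_size=None, min_support=None) -> dict:
    out = Path(out_dir)
    bin_size = DEFAULTS["bin_size"] if bin_size is None else bin_size
    blocks = placement.read_blocks_bed(blocks_bed)
    pairing = placement.read_pairing(pairing_tsv)
    ref_lengths = {b.block_id: b.src_end - b.src_start
                   for b in blocks if b.role in ("hap1", "hap2")}
    pairs_by_ref: dict[str, list] = {}
    for name, r1, s1, e1, r2, s2, e2 in hic_filter.read_pairs_tsv(pairs_tsv):
        if r1 == r2 and r1 in ref_lengths:
            pairs_by_ref.setdefault(r1, []).append((r1, s1, e1, r2, s2, e2))
    candidates = switch_detector.detect_candidates(pairs_by_ref, ref_lengths,
                                                   bin_size, min_support)
    paired_candidates = {r: sp for r, sp in candidates.items() if r in pairing}
    confirmed = switch_detector.confirm_switches(
        paired_candidates, pairing, blocks={b.block_id: b for b in blocks})
    new_blocks, new_pairing = switch_detector.split_blocks(blocks, pairing, confirmed)
    switch_detector.write_switch_bed(out / "switches.bed", confirmed)
    placement.write_blocks_bed(out / "blocks.switched.bed", new_blocks)
    placement.write_pairing(out / "pairing.switched.tsv", new_pairing, new_blocks)
    return {"candidates": len(candidates), "confirmed": len(confirmed),
            "blocks_after_split": len(new_blocks)}


def stage_phase(pairs_tsv, blocks_bed, pairing_tsv, out_dir, seed=None,
                restarts=None) -> dict:
    out = Path(out_dir)
    seed = DEFAULTS["seed"] if seed is None else seed
    restarts = DEFAULTS["restarts"] if restarts is None else restarts
    blocks = placement.read_blocks_bed(blocks_bed)
    pairing = placement.read_pairing(pairing_tsv)
    pairs = list(hic_filter.read_pairs_tsv(pairs_tsv))
    contacts, idx, cstats = phaser.count_contacts(pairs, blocks, pairing)
    assignment = phaser.phase_groups(contacts, idx, seed=seed, restarts=restarts)
    final_blocks, final_pairing, theta, dismissed = phaser.dismiss_same_phase_switches(
        assignment, blocks, pairing)
    cc = phaser.contig_contacts(contacts, idx, assignment.theta)
    contigs = sorted({b.contig for b in final_blocks})
    groups, unanchored = phaser.cluster_contigs(cc, contigs, seed=seed + 10_000,
                                                restarts=restarts)
    unit_contig = {b.block_id: b.contig for b in final_blocks if b.role == "hap2"}
    phaser.write_phases_tsv(out / "phases.tsv", theta, groups, unit_contig)
    placement.write_blocks_bed(out / "blocks.final.bed", final_blocks)
    placement.write_pairing(out / "pairing.final.tsv", final_pairing, final_blocks)
    with open(out / "groups.tsv", "w") as fh:
        for c in sorted(groups):
            fh.write(f"{c}\t{groups[c]}\n")
    report = {**cstats, "objective": assignment.objective,
              "rounds": assignment.rounds, "seed": seed, "restarts": restarts,
              "units": len(theta), "dismissed_switches": len(dismissed) // 2,
              "zero_contact_units": len(assignment.flagged),
              "unanchored_contigs": unanchored}
    with open(out / "phase_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def stage_emit(phases_tsv, blocks_bed, pairing_tsv, primary_fa, alternate_fa,
               out_dir) -> dict:
    out = Path(out_dir)
    blocks = placement.read_blocks_bed(blocks_bed)
    pairing = placement.read_pairing(pairing_tsv)
    theta, unit_groups = phaser.read_phases_tsv(phases_tsv)
    groups_path = Path(out) / "groups.tsv"
    groups: dict[str, str] = {}
    if groups_path.exists():
        with open(groups_path) as fh:
            for line in fh:
                c, g = line.split()
                groups[c] = g
    primary = read_fasta(primary_fa)
    alternate = read_fasta(alternate_fa)
    plans = emitter.build_plans(blocks, theta, pairing)
    stats = emitter.emit_fasta(plans, primary, alternate, groups, out)
    hap1_b = sum(b.src_end - b.src_start for b in blocks if b.role == "hap1")
    hap2_b = sum(b.src_end - b.src_start for b in blocks if b.role == "hap2")
    coll_b = sum(b.end - b.start for b in blocks if b.role == "collapsed")
    stats.update({"hap1_block_bases": hap1_b, "hap2_block_bases": hap2_b,
                  "collapsed_bases": coll_b,
                  "expected_total": hap1_b + hap2_b + 2 * coll_b})
    return stats


def run_pipeline(config: dict) -> dict:
    """Execute all stages; writes report.json into out_dir.

    ``config`` holds input paths (primary, alternate, paf, primary_vcf,
    alternate_vcf, hic_sam), out_dir, and optional parameter overrides.
    Any stage failure raises StageError naming the stage after the partial
    report is written.
    """
    cfg = {**DEFAULTS, **config}
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    for key in ("primary", "alternate", "paf", "primary_vcf", "alternate_vcf",
                "hic_sam"):
        if not Path(cfg[key]).exists():
            raise FileNotFoundError(f"missing input {key}: {cfg[key]}")
    report: dict = {"config": {k: str(v) for k, v in cfg.items()}, "stages": {}}

    def run_stage(name, fn, *args, **kw):
        try:
            counts = fn(*args, **kw)
        except Exception as exc:
            report["failed_stage"] = name
            _write_report(out, report)
            raise StageError(name, exc) from exc
        report["stages"][name] = counts
        log.info("stage=%s %s", name, json.dumps(counts, default=str))
        return counts

    run_stage("place", stage_place, cfg["primary"], cfg["alternate"], cfg["paf"],
              out, cfg["min_block_len"])
    run_stage("link-snps", stage_link_snps, cfg["paf"], cfg["primary"],
              cfg["alternate"], cfg["primary_vcf"], cfg["alternate_vcf"],
              out / "blocks.bed", out)
    run_stage("filter-hic", stage_filter_hic, cfg["hic_sam"],
              out / "snps.minced.tsv", out, cfg["q"], cfg["e"], cfg["dedup"])
    run_stage("detect-switches", stage_detect_switches, out / "pairs.tsv",
              out / "blocks.bed", out / "pairing.tsv", out, cfg["bin_size"],
              cfg["min_support"])
    run_stage("phase", stage_phase, out / "pairs.tsv",
              out / "blocks.switched.bed", out / "pairing.switched.tsv", out,
              cfg["seed"], cfg["restarts"])
    run_stage("emit", stage_emit, out / "phases.tsv", out / "blocks.final.bed",
              out / "pairing.final.tsv", cfg["primary"], cfg["alternate"], out)
    _write_report(out, report)
    return report


def _write_report(out: Path, report: dict) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)


def setup_logging() -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
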