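"""End-to-end orchestration: cleaning -> mapping/annotation -> conserved ->
novel -> differential -> targets -> enrichment, from one config, with a
machine-readable JSON run summary.

Execution is single-threaded and deterministic; every stage writes its
artifact as TSV/FASTA under the output directory.  When the inputs come
from the synthetic-data generator the summary includes a planted-recovery
block scoring each stage against the truth table.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import conserved as cons
from . import diffexpr as de
from . import enrich as en
from . import genomemap as gm
from . import hairpin as hp
from . import preprocess as pp
from . import targetscan as ts

log = logging.getLogger("brocmir")


@dataclass
class RunConfig:
    """Paths and per-stage parameters for a full run.

    Thresholds default to the study's printed values: <= 1 genome mismatch,
    <= 2 family edits, the MIREAP parameter set, |log2FC| > 1 and p < 0.01.
    """

    control_fastq: str = ""
    treated_fastq: str = ""
    genome_fasta: str = ""
    annotation_gff3: str = ""
    reference_fasta: str = ""
    transcripts_fasta: str = ""
    term_map_tsv: str = ""
    outdir: str = "brocmir_out"
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    phred_offset: int = 64
    max_mismatch: int = 1
    max_family_edits: int = 2
    log2fc_cut: float = 1.0
    p_cut: float = 0.01
    mfe_ratio_min: float = 0.75
    mireap: hp.MireapParams = field(default_factory=hp.MireapParams)
    stages: tuple = ("clean", "map", "conserved", "novel", "diffexpr", "targets")
    seed: int = 42

    @classmethod
    def from_yaml(cls, path):
        d = yaml.safe_load(Path(path).read_text())
        if "mireap" in d:
            d["mireap"] = hp.MireapParams(**d["mireap"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)


def read_fasta(path) -> dict[str, str]:
    seqs = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def run_all(config: RunConfig, truth=None) -> dict:
    """Execute the configured stages in order; returns the run summary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {"version": __version__, "seed": config.seed,
               "thresholds": {"log2fc_cut": config.log2fc_cut, "p_cut": config.p_cut,
                              "max_mismatch": config.max_mismatch,
                              "max_family_edits": config.max_family_edits,
                              "mfe_ratio_min": config.mfe_ratio_min},
               "stages": {}, "skipped": []}
    state: dict = {}
    order = ["clean", "map", "conserved", "novel", "diffexpr", "targets", "enrich"]
    for stage in order:
        if stage not in config.stages:
            summary["skipped"].append(stage)
            continue
        log.info("[%s] starting", stage)
        try:
            _STAGES[stage](config, state, summary, out)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    if truth is not None:
        summary["planted_recovery"] = score_against_truth(state, truth)
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


def _stage_clean(config, state, summary, out):
    tags, rep_c, rep_t = pp.clean_pair(config.control_fastq, config.treated_fastq,
                                       config.adapter, config.phred_offset)
    pp.write_tag_table(tags, out / "clean_tags.tsv")
    pp.write_collapsed_fasta(tags, out / "clean_tags.fa")
    rep_c.to_json(out / "cleaning_control.json")
    rep_t.to_json(out / "cleaning_treated.json")
    ld = pp.length_distribution(tags)
    ld.to_csv(out / "length_distribution.tsv", sep="\t")
    state["tags"], state["rep_c"], state["rep_t"] = tags, rep_c, rep_t
    summary["stages"]["clean"] = {
        "control": asdict(rep_c), "treated": asdict(rep_t),
        "unique_tags": int(len(tags))}


def _stage_map(config, state, summary, out):
    genome = read_fasta(config.genome_fasta)
    state["genome"] = genome
    state["index"] = gm.GenomeIndex(genome)
    tags = state["tags"]
    hits, multimapped = gm.map_tags(tags.seq, state["index"],
                                    config.max_mismatch, config.mireap.max_copies)
    gm.hits_to_bed(hits, out / "genome_hits.bed")
    track = gm.AnnotationTrack.from_gff3(config.annotation_gff3)
    table, assign = gm.annotate_tags(tags, hits, track)
    table.to_csv(out / "category_table.tsv", sep="\t")
    state.update(hits=hits, multimapped=multimapped, track=track,
                 categories=assign)
    summary["stages"]["map"] = {
        "mapped_tags": int(len({h.tag_seq for h in hits})),
        "multimapped_tags": int(len(multimapped)),
        "categories": {c: int(n) for c, n in
                       table.unique_tags.items() if n > 0}}


def _stage_conserved(config, state, summary, out):
    tags = state["tags"]
    fams = cons.assign_conserved(tags, config.reference_fasta, config.max_family_edits)
    real, pseudo = cons.flag_pseudo(fams, state["genome"],
                                    genome_index=state.get("index"),
                                    params=config.mireap)
    df = pd.DataFrame([{
        "family": f.family, "representative": f.representative_seq,
        "n_members": len(f.members), "count_control": f.count_control,
        "count_treated": f.count_treated, "pseudo": f.is_pseudo,
        "reason": f.pseudo_reason or ""} for f in fams])
    df.to_csv(out / "conserved_families.tsv", sep="\t", index=False)
    hist: dict[int, int] = {}
    for row in tags.itertuples():
        c = row.count_control + row.count_treated
        hist[c] = hist.get(c, 0) + 1
    thr = cons.noise_threshold(hist)
    (out / "noise_threshold.json").write_text(json.dumps(asdict(thr)))
    state["families"], state["pseudo"], state["threshold"] = real, pseudo, thr
    assigned = {m[0] for f in fams for m in f.members}
    state["conserved_tags"] = assigned
    summary["stages"]["conserved"] = {
        "families": int(len(real)), "pseudo": int(len(pseudo)),
        "noise_threshold": thr.threshold}


def _stage_novel(config, state, summary, out):
    tags = state["tags"]
    annotated = {s for s, c in state["categories"].items() if c != "unannotated"}
    excluded = annotated | state.get("conserved_tags", set())
    pool = {row.seq: (row.count_control, row.count_treated)
            for row in tags.itertuples() if row.seq not in excluded}
    hits = [h for h in state["hits"] if h.tag_seq in pool]
    cands = hp.predict_novel(pool, hits, state["genome"], config.mireap)
    rows = []
    with open(out / "novel_structures.txt", "w") as fh:
        for c in cands:
            rows.append({"id": c.id, "location": c.location, "strand": c.strand,
                         "energy": round(c.precursor.energy, 2),
                         "mature5p": c.mature5p or "-", "mature3p": c.mature3p or "-",
                         "count_control": c.count_control,
                         "count_treated": c.count_treated})
            fh.write(f">{c.id} {c.location}({c.strand}) {c.precursor.energy:.2f}\n"
                     f"{c.precursor.seq}\n{c.precursor.dotbracket}\n")
    pd.DataFrame(rows, columns=["id", "location", "strand", "energy", "mature5p",
                                "mature3p", "count_control", "count_treated"]
                 ).to_csv(out / "novel_candidates.tsv", sep="\t", index=False)
    state["novel"] = cands
    summary["stages"]["novel"] = {"candidates": int(len(cands))}


def _stage_diffexpr(config, state, summary, out):
    rep_c, rep_t = state["rep_c"], state["rep_t"]
    rows = [{"id": f.family, "count_control": f.count_control,
             "count_treated": f.count_treated} for f in state.get("families", [])]
    rows += [{"id": c.id, "count_control": c.count_control,
              "count_treated": c.count_treated} for c in state.get("novel", [])]
    counts = pd.DataFrame(rows, columns=["id", "count_control", "count_treated"])
    df = de.differential_table(counts, max(rep_c.clean_total, 1),
                               max(rep_t.clean_total, 1),
                               config.log2fc_cut, config.p_cut)
    df.to_csv(out / "differential.tsv", sep="\t", index=False)
    state["differential"] = df
    summary["stages"]["diffexpr"] = {
        "tested": int(len(df)),
        "significant": int(df.significant.sum()) if len(df) else 0,
        "up": int((df.direction == "up").sum()) if len(df) else 0,
        "down": int((df.direction == "down").sum()) if len(df) else 0}


def _stage_targets(config, state, summary, out):
    transcripts = read_fasta(config.transcripts_fasta)
    mirnas = {}
    for f in state.get("families", []):
        mirnas[f.family] = hp.transcribe(f.representative_seq)
    for c in state.get("novel", []):
        mirnas[c.id] = hp.transcribe(c.mature5p or c.mature3p)
    sites = ts.scan_targets(mirnas, {k: hp.transcribe(v) for k, v in transcripts.items()},
                            config.mfe_ratio_min)
    ts.sites_to_frame(sites).to_csv(out / "target_sites.tsv", sep="\t", index=False)
    state["sites"] = sites
    summary["stages"]["targets"] = {
        "mirnas_scanned": int(len(mirnas)), "accepted_sites": int(len(sites))}


def _stage_enrich(config, state, summary, out):
    term_map = en.TermMap.from_tsv(config.term_map_tsv)  # type: ignore[attr-defined]
    targets = {s.transcript_id for s in state.get("sites", [])}
    background = set(read_fasta(config.transcripts_fasta))
    df = en.enrich(targets, background, term_map)
    df.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    summary["stages"]["enrich"] = {"terms": int(len(df))}


_STAGES = {"clean": _stage_clean, "map": _stage_map, "conserved": _stage_conserved,
           "novel": _stage_novel, "diffexpr": _stage_diffexpr,
           "targets": _stage_targets, "enrich": _stage_enrich}


# ---------------------------------------------------------------------------
# Truth-table scoring
# ---------------------------------------------------------------------------

def score_against_truth(state, truth) -> dict:
    """Planted-recovery metrics for a run on synthetic inputs."""
    out: dict = {}
    if "novel" in state:
        planted = {(m.chrom, m.strand): m for m in truth.planted_mirnas}
        matched_truth = set()
        tp = fp = 0
        for c in state["novel"]:
            hit = None
            for m in truth.planted_mirnas:
                if (m.chrom == c.chrom and m.strand == c.strand
                        and c.start <= m.start and m.end <= c.end):
                    hit = m
                    break
            if hit is not None:
                tp += 1
                matched_truth.add(hit.id)
            else:
                fp += 1
        n_pred = tp + fp
        n_true = len(truth.planted_mirnas)
        out["novel"] = {
            "true_loci": n_true, "predicted": n_pred,
            "precision": tp / n_pred if n_pred else 1.0,
            "recall": len(matched_truth) / n_true if n_true else 1.0}
    if "differential" in state and len(state["differential"]):
        df = state["differential"]
        id2m = {m.id: m for m in truth.planted_mirnas}
        mature2id = {m.mature: m.id for m in truth.planted_mirnas}
        calls = {}
        for row in df.itertuples():
            mid = row.id
            if mid not in id2m and mid not in truth.true_log2fc:
                continue
            calls[mid] = row
        est = []
        for c in state.get("novel", []):
            mid = mature2id.get(c.mature5p or c.mature3p)
            row = df[df.id == c.id]
            if mid and len(row):
                r = row.iloc[0]
                est.append({"id": mid, "true": truth.true_log2fc[mid],
                            "log2fc": float(r.log2fc),
                            "significant": bool(r.significant)})
        if est:
            true_de = [e for e in est if abs(e["true"]) > 1]
            null = [e for e in est if e["true"] == 0]
            out["differential"] = {
                "planted_scored": len(est),
                "de_called": sum(e["significant"] for e in true_de),
                "de_total": len(true_de),
                "null_called": sum(e["significant"] for e in null),
                "null_total": len(null),
                "median_abs_lfc_error": float(pd.Series(
                    [abs(e["log2fc"] - e["true"]) for e in est]).median())}
    if "sites" in state:
        planted_ok = {(t.mirna_id, t.transcript_id, t.position)
                      for t in truth.true_targets if t.compliant}
        planted_bad = {(t.mirna_id, t.transcript_id, t.position)
                       for t in truth.true_targets if not t.compliant}
        mature2id = {m.mature: m.id for m in truth.planted_mirnas}
        novel_id2truth = {}
        for c in state.get("novel", []):
            tid = mature2id.get(c.mature5p or c.mature3p)
            if tid:
                novel_id2truth[c.id] = tid
        found = set()
        for s in state["sites"]:
            tid = novel_id2truth.get(s.mirna_id, s.mirna_id)
            found.add((tid, s.transcript_id, s.site_start))
        out["targets"] = {
            "compliant_recovered": len(planted_ok & found),
            "compliant_total": len(planted_ok),
            "violators_reported": len(planted_bad & found)}
    return out
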