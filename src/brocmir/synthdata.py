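"""Synthetic small-RNA study generator with machine-readable ground truth.

Builds everything the pipeline consumes — a genome with planted miRNA
hairpin loci, class-labelled contaminant features, a miRBase-style
reference of conserved families, two-condition FASTQ libraries with known
per-miRNA fold changes, and transcripts carrying target sites that satisfy
or violate each acceptance rule — together with a TruthTable recording
what was planted where.

Construction is generate-and-verify: every planted precursor is checked
with the hairpin module (both excision windows, exactly as the novel-miRNA
predictor sees them) and every planted target site with the target scanner;
rejected draws are resampled.  This guarantees the truth table by
construction rather than by hand-tuned sequences.  All randomness flows
from one integer seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hairpin as hp
from . import targetscan as ts
from .genomemap import revcomp
from .preprocess import encode_quality

CONTAMINANT_CLASSES = ["rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "exon", "intron"]
DNA = "ACGT"


class PlacementError(RuntimeError):
    """Genome too short to place the requested loci without overlap."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic two-condition sRNA experiment.

    Defaults are desk-scale: a 100 kb genome over two chromosomes, 20
    planted hairpin loci, 8 conserved families, 20 000 reads per library
    with per-miRNA expression around 200 reads, and true log2 fold changes
    cycling through (-2, 0, +2).
    """

    genome_length: int = 100_000
    n_chromosomes: int = 2
    n_hairpin_loci: int = 20
    n_conserved_families: int = 8
    n_contaminant_features: int = 3          # per class
    library_depth: int = 20_000
    mirna_expression: float = 200.0          # expected reads per planted miRNA
    contaminant_expression: float = 50.0     # expected reads per contaminant feature
    fold_changes: tuple = (-2.0, 0.0, 2.0)   # cycled over planted miRNAs
    noise_tag_rate: float = 0.05             # degradation-tag fraction of depth
    defect_rate: float = 0.0                 # per-read probability of a planted defect
    defect_kinds: tuple = ("n", "lowq", "q13", "short", "no_adapter")
    mature_len: int = 21
    adapter_seq: str = "TGGAATTCTCGGGTGCCAAGG"
    read_length: int = 36
    quality_offset: int = 64
    seed: int = 42

    def __post_init__(self):
        if self.n_hairpin_loci > 0 and self.genome_length < 10 * self.n_hairpin_loci * 300:
            raise ValueError("genome_length must be >= 10 * n_hairpin_loci * 300")
        for name in ("n_hairpin_loci", "n_conserved_families",
                     "n_contaminant_features", "library_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.quality_offset not in (33, 64):
            raise ValueError("quality_offset must be 33 or 64")

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path):
        d = yaml.safe_load(Path(path).read_text())
        for k in ("fold_changes", "defect_kinds"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class PlantedMirna:
    id: str
    chrom: str
    start: int        # 1-based inclusive precursor locus
    end: int
    strand: str
    arm: str          # which arm carries the mature: 5p | 3p
    mature5p: str
    mature3p: str
    precursor: str    # genome-sense DNA of the planted stem-loop

    @property
    def mature(self) -> str:
        return self.mature5p if self.arm == "5p" else self.mature3p

    @property
    def locus(self) -> str:
        return f"{self.chrom}:{self.start}:{self.end}"


@dataclass
class ConservedFamily:
    family: str
    reference_mature: str
    spiked_tag: str
    edits: int
    chrom: str = ""
    start: int = 0
    end: int = 0


@dataclass
class PlantedTarget:
    mirna_id: str
    transcript_id: str
    position: int       # 1-based site start on transcript
    kind: str           # perfect | compliant | violator
    violated_rule: str  # "" or one of i..v
    compliant: bool


@dataclass
class TruthTable:
    planted_mirnas: list = field(default_factory=list)
    true_log2fc: dict = field(default_factory=dict)
    conserved: list = field(default_factory=list)
    contaminant_intervals: dict = field(default_factory=dict)  # class -> [(chrom,s,e,strand)]
    true_targets: list = field(default_factory=list)
    source_counts: dict = field(default_factory=dict)          # library -> source -> reads
    defect_counts: dict = field(default_factory=dict)          # library -> n defective reads

    def write_tsv(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([asdict(m) for m in self.planted_mirnas]).to_csv(
            outdir / "truth_mirnas.tsv", sep="\t", index=False)
        pd.DataFrame([{"id": k, "log2fc": v} for k, v in self.true_log2fc.items()]
                     ).to_csv(outdir / "truth_log2fc.tsv", sep="\t", index=False)
        pd.DataFrame([asdict(c) for c in self.conserved]).to_csv(
            outdir / "truth_conserved.tsv", sep="\t", index=False)
        rows = [{"class": cls, "chrom": c, "start": s, "end": e, "strand": st}
                for cls, ivs in self.contaminant_intervals.items()
                for (c, s, e, st) in ivs]
        pd.DataFrame(rows).to_csv(outdir / "truth_contaminants.tsv", sep="\t", index=False)
        pd.DataFrame([asdict(t) for t in self.true_targets]).to_csv(
            outdir / "truth_targets.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reference simulation
# ---------------------------------------------------------------------------

def _rand_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(DNA) for _ in range(n))


def _mutate(rng: random.Random, seq: str, n_edits: int) -> str:
    """Apply n_edits random substitutions/indels (keeps length drift <= n)."""
    s = list(seq)
    for _ in range(n_edits):
        op = rng.choice(["sub", "ins", "del"])
        i = rng.randrange(len(s))
        if op == "sub":
            s[i] = rng.choice([b for b in DNA if b != s[i]])
        elif op == "ins":
            s.insert(i, rng.choice(DNA))
        elif len(s) > 18:
            del s[i]
    return "".join(s)


def _build_precursor(rng: random.Random, mature_len: int, arm: str):
    """Sample a mature and build a near-perfect stem-loop around it.

    2-3 stem positions are converted to G:U wobbles (on the star side).
    Besides realism, wobbles break reverse-complement symmetry: a G:U pair
    reads as an unpairable C:A on the opposite strand, so the planted
    strand folds strictly better than its mirror and the predictor can
    recover the strand from single-arm reads.
    """
    mature = _rand_dna(rng, mature_len)
    star = list(revcomp(mature))
    wobblable = [i for i, b in enumerate(mature) if b in "GT"]
    rng.shuffle(wobblable)
    for i in sorted(wobblable[:rng.randint(2, 3)]):
        # star index facing mature position i
        j = mature_len - 1 - i
        star[j] = "T" if mature[i] == "G" else "G"
    star = "".join(star)
    loop = _rand_dna(rng, rng.randint(8, 15))
    if arm == "5p":
        return mature, mature + loop + star
    return mature, star + loop + mature


def _window_check(chrom_seq: str, start: int, end: int, strand: str,
                  params: hp.MireapParams) -> bool:
    """Re-run the exact excision-window fold the novel predictor applies to
    a mature at [start, end] (1-based) and require a passing window."""
    clen = len(chrom_seq)
    for ws, we in ((start - params.flank, end + params.max_space),
                   (start - params.max_space, end + params.flank)):
        ws, we = max(1, ws), min(clen, we)
        sub = chrom_seq[ws - 1:we]
        if strand == "-":
            sub = revcomp(sub)
            off = we - end
        else:
            off = start - ws
        struct = hp.fold(sub)
        if hp.evaluate_criteria(struct, off, off + (end - start), params).passed:
            return True
    return False


class _Placer:
    """Non-overlapping interval placement with a safety margin."""

    def __init__(self, rng, chrom_lengths: dict[str, int], margin: int = 350):
        self.rng = rng
        self.lens = chrom_lengths
        self.margin = margin
        self.used: dict[str, list] = {c: [] for c in chrom_lengths}

    def place(self, length: int, max_tries: int = 2000):
        for _ in range(max_tries):
            chrom = self.rng.choice(sorted(self.lens))
            if self.lens[chrom] < length + 2 * self.margin:
                continue
            start = self.rng.randint(self.margin + 1, self.lens[chrom] - length - self.margin)
            end = start + length - 1
            if all(end + self.margin < s or start - self.margin > e
                   for s, e in self.used[chrom]):
                self.used[chrom].append((start, end))
                return chrom, start, end
        raise PlacementError("genome too short to place loci without overlap")


def simulate_reference(config: SimulationConfig,
                       params: hp.MireapParams | None = None):
    """Generate genome, annotation features, conserved reference and truth.

    Returns ``(genome, features, reference, truth)`` where genome is a dict
    chrom -> DNA, features is a list of (chrom, start, end, strand, class)
    1-based intervals, and reference a list of (family, kind, seq) records.
    """
    params = params or hp.MireapParams()
    rng = random.Random(config.seed)
    per = config.genome_length // config.n_chromosomes
    chrom_names = [f"A{k + 1:02d}" for k in range(config.n_chromosomes)]
    genome = {c: list(_rand_dna(rng, per)) for c in chrom_names}
    placer = _Placer(rng, {c: per for c in chrom_names})
    truth = TruthTable()
    features = []

    def plant(chrom, start, seq):
        genome[chrom][start - 1:start - 1 + len(seq)] = list(seq)

    def chrom_str(c):
        return "".join(genome[c])

    # --- novel hairpin loci -------------------------------------------------
    made = 0
    attempts = 0
    while made < config.n_hairpin_loci:
        attempts += 1
        if attempts > 200 * max(1, config.n_hairpin_loci):
            raise PlacementError("could not construct enough passing hairpins")
        arm = rng.choice(["5p", "3p"])
        strand = rng.choice(["+", "-"])
        mature, prec = _build_precursor(rng, config.mature_len, arm)
        struct = hp.fold(prec)
        off = prec.find(mature)
        if not hp.evaluate_criteria(struct, off, off + len(mature) - 1, params).passed:
            continue
        chrom, start, end = placer.place(len(prec))
        genome_prec = prec if strand == "+" else revcomp(prec)
        plant(chrom, start, genome_prec)
        # mature genomic coordinates inside the locus
        if strand == "+":
            ms, me = start + off, start + off + len(mature) - 1
        else:
            me = end - off
            ms = me - len(mature) + 1
        if not _window_check(chrom_str(chrom), ms, me, strand, params):
            placer.used[chrom].remove((start, end))
            plant(chrom, start, _rand_dna(rng, len(prec)))  # scrub and retry
            continue
        made += 1
        mid = f"syn-m{made:03d}"
        truth.planted_mirnas.append(PlantedMirna(
            mid, chrom, start, end, strand, arm,
            mature5p=mature if arm == "5p" else "",
            mature3p=mature if arm == "3p" else "",
            precursor=genome_prec))
        truth.true_log2fc[mid] = float(
            config.fold_changes[(made - 1) % len(config.fold_changes)])

    # --- conserved families: reference + spiked homolog loci ---------------
    reference = []
    for k in range(config.n_conserved_families):
        fam = f"miR{900 + k}"
        ref_mature = _rand_dna(rng, config.mature_len)
        edits = k % 3   # spike at 0, 1, 2 edits from the reference
        spiked = _mutate(rng, ref_mature, edits)
        loop = _rand_dna(rng, 10)
        ref_prec = ref_mature + loop + revcomp(ref_mature)
        reference.append((fam, "mature", ref_mature))
        reference.append((fam, "precursor", ref_prec))
        # plant a hairpin for the spiked homolog so it is a real miRNA locus
        prec = spiked + _rand_dna(rng, 10) + revcomp(spiked)
        chrom, start, end = placer.place(len(prec))
        plant(chrom, start, prec)
        features.append((chrom, start, end, "+", "miRNA"))
        truth.conserved.append(ConservedFamily(fam, ref_mature, spiked, edits,
                                               chrom, start, end))

    # --- contaminant features ----------------------------------------------
    for cls in CONTAMINANT_CLASSES:
        ivs = []
        for _ in range(config.n_contaminant_features):
            length = rng.randint(80, 300)
            chrom, start, end = placer.place(length)
            strand = rng.choice(["+", "-"])
            features.append((chrom, start, end, strand, cls))
            ivs.append((chrom, start, end, strand))
        truth.contaminant_intervals[cls] = ivs

    return {c: "".join(s) for c, s in genome.items()}, features, reference, truth


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------

@dataclass
class SimRead:
    id: str
    seq: str
    qual: str
    source: str       # mirna id | family | class | noise
    defect: str       # "" or defect kind


def _make_read(rng, insert: str, config: SimulationConfig, rid: str,
               source: str, defect: str) -> SimRead:
    adapter = config.adapter_seq
    if defect == "short":
        insert = insert[:rng.randint(10, 17)]
    seq = insert + adapter
    if defect == "no_adapter":
        seq = insert + _rand_dna(rng, config.read_length)  # junk instead of adapter
    if len(seq) < config.read_length:
        seq += _rand_dna(rng, config.read_length - len(seq))
    seq = seq[:config.read_length]
    quals = [rng.randint(30, 40) for _ in range(len(seq))]
    if defect == "n":
        i = rng.randrange(len(insert))
        seq = seq[:i] + "N" + seq[i + 1:]
    elif defect == "lowq":
        for i in rng.sample(range(len(seq)), 5):
            quals[i] = rng.randint(0, 9)
    elif defect == "q13":
        for i in rng.sample(range(len(seq)), 7):
            quals[i] = rng.randint(10, 12)
    return SimRead(rid, seq, encode_quality(quals, config.quality_offset),
                   source, defect)


def simulate_libraries(truth: TruthTable, config: SimulationConfig,
                       genome: dict[str, str] | None = None):
    """Two-condition read sets with Poisson per-source counts.

    Planted miRNA counts are Poisson(lambda) in the control library and
    Poisson(lambda * 2^log2fc) in the treated one; each contaminant feature
    emits Poisson-distributed random sense windows; degradation noise adds
    ``round(noise_tag_rate * library_depth)`` random tags.  Defects hit
    each read independently with probability ``defect_rate``.

    Returns (control_reads, treated_reads) as SimRead lists; per-source and
    defect totals are recorded in the truth table.
    """
    rng = random.Random(config.seed + 1)
    nprng = np.random.default_rng(config.seed + 1)
    libs = {}
    for lib, factor in (("control", 0.0), ("treated", 1.0)):
        reads = []
        counts = {}

        def emit(n, seq_fn, source):
            counts[source] = counts.get(source, 0) + n
            for _ in range(n):
                defect = ""
                if config.defect_rate > 0 and rng.random() < config.defect_rate:
                    defect = rng.choice(config.defect_kinds)
                rid = f"{lib}_{len(reads) + 1}"
                reads.append(_make_read(rng, seq_fn(), config, rid, source, defect))

        for m in truth.planted_mirnas:
            lam = config.mirna_expression * 2.0 ** (truth.true_log2fc[m.id] * factor)
            emit(int(nprng.poisson(lam)), lambda m=m: m.mature, m.id)
        for fam in truth.conserved:
            emit(int(nprng.poisson(config.mirna_expression)),
                 lambda f=fam: f.spiked_tag, fam.family)
        if genome is not None:
            for cls, ivs in truth.contaminant_intervals.items():
                for (chrom, s, e, strand) in ivs:
                    def win(chrom=chrom, s=s, e=e, strand=strand):
                        ln = rng.randint(18, min(30, e - s + 1))
                        p = rng.randint(s, e - ln + 1)
                        sub = genome[chrom][p - 1:p - 1 + ln]
                        return sub if strand == "+" else revcomp(sub)
                    emit(int(nprng.poisson(config.contaminant_expression)),
                         win, cls)
        n_noise = round(config.noise_tag_rate * config.library_depth)
        emit(n_noise, lambda: _rand_dna(rng, rng.randint(18, 30)), "noise")

        truth.source_counts[lib] = counts
        truth.defect_counts[lib] = sum(1 for r in reads if r.defect)
        rng.shuffle(reads)
        libs[lib] = reads
    return libs["control"], libs["treated"]


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


# ---------------------------------------------------------------------------
# Transcript / target simulation
# ---------------------------------------------------------------------------

_RULE_PLANS = {
    # (full-mismatch miRNA positions, target rule); chosen so only the
    # intended rule (plus possibly v, for heavy damage) is violated
    "i": (13, 15, 17, 19, 21),
    "ii": (5, 6),
    "iii": (15, 16, 17),
    "iv": (10,),
    "v": (1, 15, 17, 19),
}


def _site_with_mismatches(rng, mature_dna: str, positions) -> str:
    """Transcript window complementary to the mature except full mismatches
    at the given 1-based miRNA positions."""
    window = list(revcomp(mature_dna))
    L = len(mature_dna)
    for p in positions:
        widx = L - p                      # window index facing miRNA pos p
        mi_base = mature_dna[p - 1]
        forbidden = {"A": "T", "C": "G", "G": "C", "T": "A"}[mi_base]
        wobble = {"G": "T", "T": "G"}.get(mi_base)
        choices = [b for b in DNA if b != forbidden and b != wobble and b != mi_base]
        window[widx] = rng.choice(choices)
    return "".join(window)


def simulate_transcripts(truth: TruthTable, config: SimulationConfig,
                         max_tries: int = 300):
    """Transcripts carrying, per planted miRNA: a perfect site, a compliant
    imperfect site, and one violator for each rule i-v.

    Every site is verified with the target scanner at construction
    (compliant sites accepted, violators rejected with the intended rule
    flagged); the compliant site's mismatch placement is resampled until it
    passes all five rules.  Returns dict transcript_id -> sequence and
    appends PlantedTarget records to the truth table.
    """
    rng = random.Random(config.seed + 2)
    transcripts = {}
    flank = 60

    def embed(mid, label, window, rule, compliant):
        tx_id = f"tx_{mid}_{label}"
        seq = _rand_dna(rng, flank) + window + _rand_dna(rng, flank)
        transcripts[tx_id] = seq
        truth.true_targets.append(PlantedTarget(
            mid, tx_id, flank + 1, label, rule, compliant))

    for m in truth.planted_mirnas:
        mature = m.mature
        mirna_rna = hp.transcribe(mature)
        # (a) perfect complement
        perfect = revcomp(mature)
        assert ts.score_site(mirna_rna, hp.transcribe(perfect)).accepted
        embed(m.id, "perfect", perfect, "", True)
        # (b) compliant imperfect: 2 mismatches, resampled until accepted
        cand_pos = [3, 5, 7, 13, 15, 17, 19, 21]
        for _ in range(max_tries):
            pos = tuple(sorted(rng.sample(cand_pos, 2)))
            window = _site_with_mismatches(rng, mature, pos)
            if ts.score_site(mirna_rna, hp.transcribe(window)).accepted:
                break
        else:
            raise RuntimeError(f"no compliant imperfect site found for {m.id}")
        embed(m.id, "compliant", window, "", True)
        # (c) one violator per rule
        for rule, positions in _RULE_PLANS.items():
            for _ in range(max_tries):
                window = _site_with_mismatches(rng, mature, positions)
                score = ts.score_site(mirna_rna, hp.transcribe(window))
                if rule in score.violated_rules and not score.accepted:
                    break
            else:
                raise RuntimeError(f"could not construct rule-{rule} violator for {m.id}")
            embed(m.id, f"violator_{rule}", window, rule, False)
    return transcripts


# ---------------------------------------------------------------------------
# Whole-study convenience
# ---------------------------------------------------------------------------

def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n{seqs[name]}\n")


def write_gff3(features, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for k, (chrom, start, end, strand, cls) in enumerate(features, 1):
            fh.write(f"{chrom}\tsynthdata\t{cls}\t{start}\t{end}\t.\t{strand}\t.\t"
                     f"ID=feat{k};class={cls}\n")


def write_reference_fasta(reference, path) -> None:
    with open(path, "w") as fh:
        for fam, kind, seq in reference:
            fh.write(f">{fam}|{kind}\n{seq}\n")


def simulate_study(config: SimulationConfig, outdir) -> TruthTable:
    """Generate and write the complete synthetic study into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, features, reference, truth = simulate_reference(config)
    control, treated = simulate_libraries(truth, config, genome)
    transcripts = simulate_transcripts(truth, config)
    write_fasta(genome, outdir / "genome.fa")
    write_gff3(features, outdir / "annotation.gff3")
    write_reference_fasta(reference, outdir / "reference_mirnas.fa")
    write_fastq(control, outdir / "control.fastq")
    write_fastq(treated, outdir / "treated.fastq")
    write_fasta(transcripts, outdir / "transcripts.fa")
    truth.write_tsv(outdir)
    config.to_yaml(outdir / "config.yaml")
    return truth
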