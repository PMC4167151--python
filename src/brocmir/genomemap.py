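"""Genome mapping of clean tags (<= 1 mismatch, no indels) and annotation
by class priority.

Mapping is exact seed-and-extend over a k-mer index (k = 9): every <= 1
mismatch alignment of an 18-30 nt tag leaves at least one of the two
non-overlapping terminal 9-mers mismatch-free, so seeding with both and
verifying each candidate diagonal enumerates the complete hit set on both
strands.  Coordinates are 1-based inclusive throughout; the on-disk BED is
half-open and converted at the boundary.

Annotation assigns each mapped tag exactly one class under a fixed priority
(rRNA > known miRNA > tRNA > snRNA > snoRNA > repeat > exon > intron);
exon/intron are split sense/antisense by comparing hit and feature strands.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

DEFAULT_PRIORITY = ["rRNA", "miRNA", "tRNA", "snRNA", "snoRNA", "repeat", "exon", "intron"]
KNOWN_CLASSES = set(DEFAULT_PRIORITY)
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class AlignmentHit:
    tag_seq: str
    chrom: str
    start: int   # 1-based inclusive
    end: int
    strand: str
    mismatches: int


class GenomeIndex:
    """k-mer index of a genome for exact/1-mismatch short-tag lookup."""

    def __init__(self, genome: dict[str, str], k: int = 9):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.k = k
        self.index: dict[str, list] = defaultdict(list)
        for chrom, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if "N" not in kmer:
                    self.index[kmer].append((chrom, i))

    def _candidates(self, tag: str):
        """Candidate (chrom, start0) placements from the two terminal seeds."""
        k, L = self.k, len(tag)
        cands = set()
        for off in (0, L - k):
            for chrom, pos in self.index.get(tag[off:off + k], ()):
                s = pos - off
                if s >= 0 and s + L <= len(self.genome[chrom]):
                    cands.add((chrom, s))
        return cands

    def map_tag(self, tag: str, max_mismatch: int = 1) -> list[AlignmentHit]:
        tag = tag.upper()
        if "N" in tag:
            raise ValueError("tags with N must be removed upstream")
        if len(tag) < 2 * self.k:
            raise ValueError(f"tag shorter than {2 * self.k} nt")
        hits = []
        for strand, query in (("+", tag), ("-", revcomp(tag))):
            for chrom, s in sorted(self._candidates(query)):
                window = self.genome[chrom][s:s + len(query)]
                mm = sum(a != b for a, b in zip(query, window))
                if mm <= max_mismatch:
                    hits.append(AlignmentHit(tag, chrom, s + 1, s + len(query), strand, mm))
        hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
        return hits


def map_tags(tags, genome: dict[str, str], max_mismatch: int = 1,
             max_hits: int = 20):
    """Map every tag sequence; returns (hits, multimapped_tag_set).

    ``tags`` is an iterable of sequences.  Tags with more than ``max_hits``
    placements are flagged multi-mapped and return no hits (they are
    excluded from locus building downstream, not errors).
    """
    idx = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    all_hits: list[AlignmentHit] = []
    multimapped = set()
    for tag in tags:
        h = idx.map_tag(tag, max_mismatch)
        if len(h) > max_hits:
            multimapped.add(tag)
        else:
            all_hits.extend(h)
    return all_hits, multimapped


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

class AnnotationTrack:
    """Class-labelled genomic intervals with strand, held as interval trees."""

    def __init__(self, features):
        """``features``: iterable of (chrom, start, end, strand, cls), 1-based inclusive."""
        self.trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for chrom, start, end, strand, cls in features:
            if cls not in KNOWN_CLASSES:
                raise ValueError(f"unknown annotation class {cls!r}")
            self.trees[chrom].addi(start, end + 1, (strand, cls))

    @classmethod
    def from_gff3(cls, path):
        feats = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
                feats.append((f[0], int(f[3]), int(f[4]), f[6], attrs["class"]))
        return cls(feats)

    def overlapping(self, chrom, start, end):
        return [(iv.data[0], iv.data[1]) for iv in self.trees[chrom].overlap(start, end + 1)]


def _category_columns():
    cols = []
    for c in DEFAULT_PRIORITY:
        if c in ("exon", "intron"):
            cols += [f"{c}_sense", f"{c}_antisense"]
        else:
            cols.append(c)
    return cols + ["unannotated"]


def annotate_tags(tags: pd.DataFrame, hits, track: AnnotationTrack,
                  priority=None) -> tuple[pd.DataFrame, dict[str, str]]:
    """Assign one category per tag and tabulate per-library counts.

    ``tags`` is the CleanTag table; ``hits`` the output of :func:`map_tags`.
    A tag overlapping several classes (across all its hits) is counted once
    under the highest-priority class; genic classes are further split by
    sense/antisense of the *highest-priority overlapping feature*.  Unmapped
    tags and mapped tags with no feature overlap are ``unannotated``.

    Returns (CategoryTable, tag -> category map).
    """
    priority = priority or DEFAULT_PRIORITY
    rank = {c: i for i, c in enumerate(priority)}
    best: dict[str, tuple[int, str]] = {}
    mapped = set()
    for h in hits:
        mapped.add(h.tag_seq)
        for fstrand, cls in track.overlapping(h.chrom, h.start, h.end):
            if cls in ("exon", "intron"):
                label = f"{cls}_{'sense' if fstrand == h.strand else 'antisense'}"
            else:
                label = cls
            key = (rank[cls], label)
            if h.tag_seq not in best or key < best[h.tag_seq]:
                best[h.tag_seq] = key
    assign = {}
    for row in tags.itertuples():
        if row.seq in best:
            assign[row.seq] = best[row.seq][1]
        else:
            assign[row.seq] = "unannotated"

    cols = _category_columns()
    table = pd.DataFrame(0, index=cols,
                         columns=["unique_tags", "reads_control", "reads_treated"])
    table.index.name = "category"
    for row in tags.itertuples():
        cat = assign[row.seq]
        table.loc[cat, "unique_tags"] += 1
        table.loc[cat, "reads_control"] += row.count_control
        table.loc[cat, "reads_treated"] += row.count_treated
    for col in table.columns:
        tot = table[col].sum()
        table[f"{col}_pct"] = 100.0 * table[col] / tot if tot else 0.0
    return table, assign


def hits_to_bed(hits, path) -> None:
    """Write hits as BED-like TSV (half-open on disk)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.chrom}\t{h.start - 1}\t{h.end}\t{h.tag_seq}\t{h.mismatches}\t{h.strand}\n")
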