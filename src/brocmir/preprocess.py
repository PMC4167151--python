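"""Read cleaning: quality decoding, tag-rejection rules, adapter trimming
and collapsing to unique tags.

A raw small-RNA read survives iff it (i) contains no N, (ii) has at most 4
bases below Q10, (iii) at most 6 bases below Q13, and (iv) yields an insert
of 18-30 nt after 3'-adapter removal.  Quality filters are applied to the
full read before trimming; the filters are conjunctive, so their order only
affects which rejection counter a doubly-bad read increments (precedence:
N > Q10 > Q13 > adapter/length).

Adapter removal looks for the leftmost exact match of the adapter's first
8 nt anywhere in the read, falling back to a >= 6 nt suffix overlap with the
adapter's start; reads with no adapter evidence longer than 30 nt are
dropped as ``removed_no_adapter``.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

MIN_INSERT = 18
MAX_INSERT = 30


class MalformedQualityError(ValueError):
    pass


def decode_quality(qual: str, offset: int = 64) -> list[int]:
    """Phred scores from an ASCII quality string (score = ord(char) - offset)."""
    if offset not in (33, 64):
        raise ValueError("offset must be 33 or 64")
    scores = []
    for ch in qual:
        q = ord(ch) - offset
        if q < 0:
            raise MalformedQualityError(
                f"quality character {ch!r} below phred+{offset} offset")
        scores.append(q)
    return scores


def encode_quality(scores, offset: int = 64) -> str:
    return "".join(chr(q + offset) for q in scores)


@dataclass
class RawRead:
    id: str
    seq: str
    qual: str

    def __post_init__(self):
        if len(self.seq) != len(self.qual):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


@dataclass
class CleaningReport:
    total_raw: int = 0
    removed_N: int = 0
    removed_q10: int = 0
    removed_q13: int = 0
    removed_short: int = 0
    removed_no_adapter: int = 0
    clean_total: int = 0
    clean_unique: int = 0

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def parse_fastq(path) -> "iterator of RawRead":
    """Stream a plain or gzipped 4-line FASTQ as RawRead records."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lines = [fh.readline() for _ in range(3)]
            lineno += 4
            if not header.startswith("@") or not lines[1].startswith("+") or not lines[2]:
                raise ValueError(f"{path}: malformed FASTQ record at line {lineno - 3}")
            seq, qual = lines[0].strip(), lines[2].strip()
            if len(seq) != len(qual):
                raise ValueError(f"{path}: length mismatch at line {lineno - 3}")
            yield RawRead(header[1:].split()[0], seq.upper(), qual)


def trim_adapter(seq: str, adapter: str) -> str | None:
    """Insert left of the 3' adapter, or None if no adapter evidence.

    Leftmost exact match of the adapter's first 8 nt wins; otherwise the
    longest >= 6 nt read-suffix / adapter-prefix overlap.
    """
    probe = adapter[:8]
    idx = seq.find(probe)
    if idx >= 0:
        return seq[:idx]
    for k in range(min(len(adapter), len(seq)), 5, -1):
        if seq.endswith(adapter[:k]):
            return seq[:-k]
    return None


def check_read(read: RawRead, adapter: str, offset: int = 64):
    """Classify one read: (insert or None, rejection class or None)."""
    if "N" in read.seq:
        return None, "removed_N"
    scores = decode_quality(read.qual, offset)
    if sum(q < 10 for q in scores) > 4:
        return None, "removed_q10"
    if sum(q < 13 for q in scores) > 6:
        return None, "removed_q13"
    insert = trim_adapter(read.seq, adapter)
    if insert is None:
        if len(read.seq) > MAX_INSERT:
            return None, "removed_no_adapter"
        insert = read.seq
    if len(insert) < MIN_INSERT:
        return None, "removed_short"
    if len(insert) > MAX_INSERT:
        return None, "removed_no_adapter"
    return insert, None


def clean_reads(reads, adapter: str, offset: int = 64):
    """Filter and collapse one library.

    Returns ``(Counter seq -> count, CleaningReport)``.
    """
    if len(adapter) < 6:
        raise ValueError("adapter must be at least 6 nt")
    tags: Counter = Counter()
    rep = CleaningReport()
    for read in reads:
        rep.total_raw += 1
        insert, reason = check_read(read, adapter, offset)
        if reason is not None:
            setattr(rep, reason, getattr(rep, reason) + 1)
            continue
        tags[insert] += 1
        rep.clean_total += 1
    rep.clean_unique = len(tags)
    return tags, rep


def clean_pair(control_fq, treated_fq, adapter: str, offset: int = 64):
    """Clean two libraries and merge them into a CleanTag table.

    Returns ``(DataFrame[seq, count_control, count_treated], report_control,
    report_treated)``; rows sorted by total count (desc) then sequence.
    """
    tags_c, rep_c = clean_reads(parse_fastq(control_fq), adapter, offset)
    tags_t, rep_t = clean_reads(parse_fastq(treated_fq), adapter, offset)
    return merge_tag_counts(tags_c, tags_t), rep_c, rep_t


def merge_tag_counts(tags_c: Counter, tags_t: Counter) -> pd.DataFrame:
    seqs = sorted(set(tags_c) | set(tags_t))
    df = pd.DataFrame({
        "seq": seqs,
        "count_control": [tags_c.get(s, 0) for s in seqs],
        "count_treated": [tags_t.get(s, 0) for s in seqs],
    })
    df = df.sort_values(["seq"]).reset_index(drop=True)
    total = df.count_control + df.count_treated
    return df.loc[total.sort_values(ascending=False, kind="stable").index].reset_index(drop=True)


def length_distribution(tags: pd.DataFrame) -> pd.DataFrame:
    """Per-length read and unique-tag fractions over 18-30 nt.

    Returns a frame indexed by length with columns ``total_frac`` (count
    weighted, both libraries) and ``unique_frac``; empty input gives an
    all-zero frame.
    """
    lengths = range(MIN_INSERT, MAX_INSERT + 1)
    out = pd.DataFrame(0.0, index=list(lengths), columns=["total_frac", "unique_frac"])
    out.index.name = "length"
    if len(tags) == 0:
        return out
    ln = tags.seq.str.len()
    counts = tags.count_control + tags.count_treated
    total = counts.groupby(ln).sum()
    uniq = ln.value_counts()
    out.loc[total.index, "total_frac"] = (total / counts.sum()).to_numpy()
    out.loc[uniq.index, "unique_frac"] = (uniq / len(tags)).to_numpy()
    return out


def library_overlap(tags_a: pd.DataFrame, tags_b: pd.DataFrame) -> dict:
    """Common/specific tag summary between two libraries.

    Each input needs ``seq`` and a count column (the first ``count_*``
    column found, or summed counts).  Shared total fraction weights shared
    sequences by their summed counts across both libraries over the grand
    total.
    """
    def counts(df):
        cols = [c for c in df.columns if c.startswith("count")]
        return dict(zip(df.seq, df[cols].sum(axis=1)))

    ca, cb = counts(tags_a), counts(tags_b)
    shared = set(ca) & set(cb)
    n_union = len(set(ca) | set(cb))
    grand = sum(ca.values()) + sum(cb.values())
    shared_reads = sum(ca[s] for s in shared) + sum(cb[s] for s in shared)
    return {
        "unique_shared_fraction": len(shared) / n_union if n_union else 0.0,
        "total_shared_fraction": shared_reads / grand if grand else 0.0,
        "unique_specific_a": len(set(ca) - shared),
        "unique_specific_b": len(set(cb) - shared),
        "unique_shared": len(shared),
    }


def write_tag_table(tags: pd.DataFrame, path) -> None:
    tags.to_csv(path, sep="\t", index=False)


def read_tag_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_collapsed_fasta(tags: pd.DataFrame, path) -> None:
    """Collapsed tags as FASTA with >tagN_xCOUNT headers (summed counts)."""
    with open(path, "w") as fh:
        for k, row in enumerate(tags.itertuples(), 1):
            fh.write(f">tag{k}_x{row.count_control + row.count_treated}\n{row.seq}\n")
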