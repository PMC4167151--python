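"""Plant miRNA target prediction under the Allen/Schwab alignment rules.

A candidate site is an ungapped duplex between a miRNA (read 5'->3') and a
transcript window of the same length; positions are numbered from the
miRNA 5' end.  Each position is a Watson-Crick match, a G:U wobble
(half a mismatch) or a full mismatch, and a site is accepted iff

  i)   total mismatch score <= 4 (G:U = 0.5),
  ii)  no two adjacent mismatched positions within miRNA positions 2-12,
  iii) no run of three or more adjacent mismatches anywhere,
  iv)  no mismatch at positions 10-11 and mismatch score over positions
       1-12 at most 2.5,
  v)   duplex minimum free energy at least 75% of the energy of the miRNA
       paired to its perfect complement.

Duplex energies reuse the folding module's nearest-neighbor stack table:
consecutive paired positions (WC or G:U) contribute their stack, each
mismatch breaks stacking and adds a fixed penalty.  Wobbles count toward
the mismatch score but pair (and stack) energetically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .hairpin import ENERGY_MODEL, transcribe

MISMATCH_PENALTY = 0.5   # kcal/mol added per full mismatch in the duplex
_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}
_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass
class SiteScore:
    mirna_id: str
    transcript_id: str
    site_start: int               # 1-based on the transcript
    site_end: int
    mismatch_score: float
    wobbles: int
    mismatch_mask: list = field(repr=False, default_factory=list)
    max_adjacent_run: int = 0
    score_1_12: float = 0.0
    mfe_duplex: float = 0.0
    mfe_perfect: float = 0.0
    mfe_ratio: float = 0.0
    violated_rules: list = field(default_factory=list)

    @property
    def accepted(self) -> bool:
        return not self.violated_rules


def classify_positions(mirna: str, window: str):
    """Per-position duplex state against the transcript window.

    The window is the transcript subsequence read 5'->3'; position k of the
    miRNA faces the window base ``window[-(k+1)]`` (antiparallel duplex).
    Returns a list over miRNA positions of 'match' | 'wobble' | 'mismatch'.
    """
    if len(mirna) != len(window):
        raise ValueError("window length must equal miRNA length")
    mi = transcribe(mirna)
    win = transcribe(window)
    states = []
    for k in range(len(mi)):
        duo = (mi[k], win[len(win) - 1 - k])
        if duo in _WC:
            states.append("match")
        elif duo in _WOBBLE:
            states.append("wobble")
        else:
            states.append("mismatch")
    return states


def duplex_energy(mirna: str, states) -> float:
    """Nearest-neighbor energy of an ungapped duplex given position states.

    Paired positions (match/wobble) stack when consecutive; every full
    mismatch adds ``MISMATCH_PENALTY`` and breaks stacking.
    """
    mi = transcribe(mirna)
    stacks = ENERGY_MODEL["stacks"]
    e = 0.0
    for k in range(len(mi)):
        if states[k] == "mismatch":
            e += MISMATCH_PENALTY
            continue
        if k + 1 < len(mi) and states[k + 1] != "mismatch":
            top = mi[k] + mi[k + 1]
            pair1 = mi[k] + _partner(mi[k], states[k])
            pair2 = mi[k + 1] + _partner(mi[k + 1], states[k + 1])
            e += stacks[f"{pair1}/{pair2}"]
    return e


def _partner(base: str, state: str) -> str:
    if state == "wobble":
        return "U" if base == "G" else "G"
    return _COMP[base]


def perfect_mfe(mirna: str) -> float:
    """Energy of the miRNA bound to its exact Watson-Crick complement."""
    return duplex_energy(mirna, ["match"] * len(mirna))


def score_site(mirna: str, window: str, mirna_id: str = "mirna",
               transcript_id: str = "tx", site_start: int = 1,
               mfe_ratio_min: float = 0.75) -> SiteScore:
    """Score one miRNA/window duplex and evaluate rules i-v.

    ``site_start`` is the 1-based transcript position of the window's first
    base.  All violated rules are reported, not just the first.
    """
    states = classify_positions(mirna, window)
    n = len(states)
    score = sum(1.0 if s == "mismatch" else 0.5 if s == "wobble" else 0.0
                for s in states)
    wobbles = sum(s == "wobble" for s in states)
    mism = [s != "match" for s in states]   # wobble counts as a mismatch position

    # longest adjacent mismatch run, anywhere
    run = best_run = 0
    for m in mism:
        run = run + 1 if m else 0
        best_run = max(best_run, run)
    # adjacent mismatches within positions 2-12 (1-based)
    adj_2_12 = any(mism[k] and mism[k + 1] for k in range(1, min(11, n - 1)))
    score_1_12 = sum(1.0 if states[k] == "mismatch" else 0.5 if states[k] == "wobble" else 0.0
                     for k in range(min(12, n)))
    pos_10_11 = any(mism[k] for k in (9, 10) if k < n)

    mfe_d = duplex_energy(mirna, states)
    mfe_p = perfect_mfe(mirna)
    ratio = mfe_d / mfe_p if mfe_p < 0 else 0.0

    violated = []
    if score > 4.0:
        violated.append("i")
    if adj_2_12:
        violated.append("ii")
    if best_run >= 3:
        violated.append("iii")
    if pos_10_11 or score_1_12 > 2.5:
        violated.append("iv")
    if ratio < mfe_ratio_min:
        violated.append("v")

    return SiteScore(mirna_id, transcript_id, site_start, site_start + n - 1,
                     score, wobbles, mism, best_run, score_1_12,
                     mfe_d, mfe_p, ratio, violated)


def scan_targets(mirnas, transcripts, mfe_ratio_min: float = 0.75,
                 keep_rejected: bool = False) -> list[SiteScore]:
    """Slide every miRNA over every transcript and collect accepted sites.

    ``mirnas`` and ``transcripts`` are dicts id -> sequence (or lists of
    (id, seq)).  Sites are reported sorted by (transcript, position, miRNA);
    overlapping acceptances are all kept.
    """
    if not isinstance(mirnas, dict):
        mirnas = dict(mirnas)
    if not isinstance(transcripts, dict):
        transcripts = dict(transcripts)
    out = []
    for tx_id in sorted(transcripts):
        tx = transcripts[tx_id]
        for mid in sorted(mirnas):
            mi = mirnas[mid]
            L = len(mi)
            for s in range(0, len(tx) - L + 1):
                site = score_site(mi, tx[s:s + L], mid, tx_id, s + 1, mfe_ratio_min)
                if site.accepted or keep_rejected:
                    out.append(site)
    out.sort(key=lambda s: (s.transcript_id, s.site_start, s.mirna_id))
    return out


def sites_to_frame(sites):
    import pandas as pd
    return pd.DataFrame([{
        "mirna": s.mirna_id, "transcript": s.transcript_id,
        "site_start": s.site_start, "site_end": s.site_end,
        "mismatch_score": s.mismatch_score, "wobbles": s.wobbles,
        "mfe_duplex": s.mfe_duplex, "mfe_perfect": s.mfe_perfect,
        "mfe_ratio": s.mfe_ratio,
        "violated_rules": ",".join(s.violated_rules), "accepted": s.accepted,
    } for s in sites])


def render_duplex(mirna: str, window: str) -> str:
    """Three-line text rendering of a duplex (miRNA 5'->3' on top)."""
    states = classify_positions(mirna, window)
    mid = "".join("|" if s == "match" else "o" if s == "wobble" else " "
                  for s in states)
    return (f"miRNA  5' {transcribe(mirna)} 3'\n"
            f"          {mid}\n"
            f"target 3' {transcribe(window)[::-1]} 5'")
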