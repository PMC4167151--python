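"""RNA secondary-structure folding and stem-loop (pre-miRNA) evaluation.

The folding model is a self-contained nearest-neighbor scheme: Watson-Crick
and G:U pairs, Turner-like stacking energies for the 36 pair-on-pair stacks,
logarithmic hairpin/bulge/internal-loop penalties and an affine multiloop
cost.  It is exact for its own model (dynamic programming over all
pseudoknot-free structures) and reproduces the qualitative ranking a
thermodynamic folder gives at precursor scale.  All constants live in
:data:`ENERGY_MODEL` so an external folder can be swapped in by replacing
:func:`fold`.

Stem-loop candidates are screened with the MIREAP-style criterion set used
for plant novel-miRNA discovery: precursor energy at most -18 kcal/mol,
mature length 18-25 nt, at least 16 mature bases paired to the star arm,
mature bulge at most 4 nt, and duplex asymmetry at most 4 nt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._fold import INF, fill_tables

# ---------------------------------------------------------------------------
# Energy model
# ---------------------------------------------------------------------------

_BASES = "ACGU"
_ENC = {b: i for i, b in enumerate(_BASES)}
_PAIRS = ("AU", "UA", "GC", "CG", "GU", "UG")

# Stacking free energies (model kcal/mol) for pair (i,j) stacked on the inner
# pair (i+1, j-1); keys are "XY/WZ" = outer pair / inner pair read 5'->3' on
# the top strand.  Values follow the Turner nearest-neighbor measurements for
# Watson-Crick stacks.  Two model constraints depart from the measured
# values: weak G:U stacks are floored at -0.3 so extending a stem never
# raises the energy, and every stack involving a wobble pair is kept weaker
# than the same stack with the Watson-Crick pair in its place, so that a
# wobble substitution never stabilises a duplex (monotone target scoring).
_STACKS = {
    "AU/AU": -0.9, "AU/UA": -1.1, "AU/GC": -2.1, "AU/CG": -2.2, "AU/GU": -0.6, "AU/UG": -0.8,
    "UA/AU": -1.3, "UA/UA": -0.9, "UA/GC": -2.4, "UA/CG": -2.1, "UA/GU": -1.0, "UA/UG": -0.7,
    "CG/AU": -2.1, "CG/UA": -2.1, "CG/GC": -3.3, "CG/CG": -2.4, "CG/GU": -1.4, "CG/UG": -1.7,
    "GC/AU": -2.4, "GC/UA": -2.2, "GC/GC": -3.4, "GC/CG": -3.3, "GC/GU": -1.5, "GC/UG": -1.8,
    "GU/AU": -1.3, "GU/UA": -1.4, "GU/GC": -2.5, "GU/CG": -2.1, "GU/GU": -0.5, "GU/UG": -0.3,
    "UG/AU": -1.0, "UG/UA": -0.6, "UG/GC": -1.5, "UG/CG": -1.4, "UG/GU": -0.3, "UG/UG": -0.5,
}

ENERGY_MODEL = {
    "stacks": dict(_STACKS),
    "min_hairpin_loop": 3,      # nt
    # hairpin initiation (3-nt loop) net of terminal-mismatch stabilization
    "hairpin_base": 4.5,
    "hairpin_slope": 1.6,       # * ln(size/3)
    "bulge_base": 3.8,
    "bulge_slope": 1.6,         # * ln(size)
    "internal_base": 4.0,
    "internal_slope": 1.6,      # * ln(total/2)
    "internal_asym": 0.5,       # per nt of side-length difference
    "internal_asym_cap": 3.0,
    "multi_close": 4.6,         # multiloop closing penalty
    "multi_branch": 0.4,        # per branch (closing pair included)
    "max_internal": 30,         # DP bound on bulge/internal loop size
}


def _build_arrays():
    can = np.zeros((4, 4), dtype=np.bool_)
    for p in _PAIRS:
        can[_ENC[p[0]], _ENC[p[1]]] = True
    stack = np.full((16, 16), INF)
    for key, e in ENERGY_MODEL["stacks"].items():
        outer, inner = key.split("/")
        oi = _ENC[outer[0]] * 4 + _ENC[outer[1]]
        ii = _ENC[inner[0]] * 4 + _ENC[inner[1]]
        stack[oi, ii] = e
    return can, stack


_CAN_PAIR, _STACK_ARR = _build_arrays()


def _loop_energy(l1: int, l2: int, outer: str, inner: str) -> float:
    """Energy of the loop between an outer and inner pair with l1/l2 unpaired
    bases on the 5'/3' sides (0/0 = stack)."""
    m = ENERGY_MODEL
    if l1 == 0 and l2 == 0:
        return m["stacks"][f"{outer}/{inner}"]
    if l1 == 0 or l2 == 0:
        return m["bulge_base"] + m["bulge_slope"] * math.log(l1 + l2)
    asym = min(m["internal_asym"] * abs(l1 - l2), m["internal_asym_cap"])
    return m["internal_base"] + m["internal_slope"] * math.log((l1 + l2) / 2.0) + asym


def _hairpin_energy(size: int) -> float:
    m = ENERGY_MODEL
    return m["hairpin_base"] + m["hairpin_slope"] * math.log(size / m["min_hairpin_loop"])


def transcribe(seq: str) -> str:
    """DNA -> RNA (T to U), uppercased."""
    return seq.upper().replace("T", "U")


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

@dataclass
class SecondaryStructure:
    """A folded RNA: sequence, dot-bracket string and model energy.

    ``pairs[i]`` holds the 0-based partner of position i, or -1.
    """

    seq: str
    dotbracket: str
    energy: float
    pairs: np.ndarray = field(repr=False)

    def __post_init__(self):
        if len(self.dotbracket) != len(self.seq):
            raise ValueError("dotbracket length mismatch")

    @property
    def n_pairs(self) -> int:
        return int((self.pairs >= 0).sum()) // 2


def _pairs_to_dotbracket(pairs: np.ndarray) -> str:
    out = ["."] * len(pairs)
    for i, j in enumerate(pairs):
        if j > i:
            out[i] = "("
            out[int(j)] = ")"
    return "".join(out)


def dotbracket_to_pairs(db: str) -> np.ndarray:
    pairs = np.full(len(db), -1, dtype=np.int64)
    stack = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket")
            j = stack.pop()
            pairs[i] = j
            pairs[j] = i
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return pairs


def structure_energy(seq: str, pairs: np.ndarray) -> float:
    """Evaluate the model energy of an arbitrary (nested) structure.

    Decomposes the structure into its loops: hairpins, stacks, bulges,
    internal loops and multiloops, plus free external/multiloop bases.
    This is the definition the DP in :func:`fold` optimises.
    """
    rna = transcribe(seq)
    n = len(rna)
    pairs = np.asarray(pairs)

    def children_of(i: int, j: int) -> list[tuple[int, int]]:
        out = []
        k = i + 1
        while k < j:
            if pairs[k] > k:
                out.append((k, int(pairs[k])))
                k = int(pairs[k]) + 1
            else:
                k += 1
        return out

    m = ENERGY_MODEL
    total = 0.0
    # iterate over every pair as a loop-closing pair
    for i in range(n):
        j = int(pairs[i])
        if j <= i:
            continue
        kids = children_of(i, j)
        if not kids:
            size = j - i - 1
            if size < m["min_hairpin_loop"]:
                raise ValueError("hairpin loop shorter than minimum")
            total += _hairpin_energy(size)
        elif len(kids) == 1:
            p, q = kids[0]
            outer = rna[i] + rna[j]
            inner = rna[p] + rna[q]
            total += _loop_energy(p - i - 1, j - q - 1, outer, inner)
        else:
            total += m["multi_close"] + m["multi_branch"] * (len(kids) + 1)
    return total


# ---------------------------------------------------------------------------
# Folding
# ---------------------------------------------------------------------------

_MAX_FOLD_LEN = 500


def fold(seq: str) -> SecondaryStructure:
    """Fold an RNA (or DNA; T is transcribed) into its minimum-energy
    pseudoknot-free structure under the module's energy model.

    Exact dynamic programming; intended for precursor-scale input (the
    hard cap is 500 nt).  A sequence admitting no favourable pair returns
    the open chain at energy 0.
    """
    rna = transcribe(seq)
    n = len(rna)
    if n > _MAX_FOLD_LEN:
        raise ValueError(f"sequence longer than {_MAX_FOLD_LEN} nt")
    bad = set(rna) - set(_BASES)
    if bad:
        raise ValueError(f"non-RNA characters: {sorted(bad)}")
    if n == 0:
        return SecondaryStructure("", "", 0.0, np.empty(0, dtype=np.int64))
    enc = np.array([_ENC[c] for c in rna], dtype=np.int64)
    m = ENERGY_MODEL
    V, WM, W = fill_tables(
        enc, _CAN_PAIR, _STACK_ARR, m["min_hairpin_loop"], m["max_internal"],
        m["multi_close"], m["multi_branch"],
        m["hairpin_base"], m["hairpin_slope"],
        m["bulge_base"], m["bulge_slope"],
        m["internal_base"], m["internal_slope"],
        m["internal_asym"], m["internal_asym_cap"])
    energy = float(W[n])
    pairs = np.full(n, -1, dtype=np.int64)
    if energy < -1e-9:
        _traceback(rna, enc, V, WM, W, pairs)
        energy = structure_energy(rna, pairs)
    else:
        energy = 0.0
    return SecondaryStructure(rna, _pairs_to_dotbracket(pairs), energy, pairs)


_EPS = 1e-6


def _traceback(rna, enc, V, WM, W, pairs):
    n = len(rna)
    m = ENERGY_MODEL
    # external: walk the prefix table right to left
    stack_v: list[tuple[int, int]] = []
    k = n
    while k > 0:
        if abs(W[k] - W[k - 1]) < _EPS:
            k -= 1
            continue
        j = k - 1
        for i in range(0, j):
            if V[i, j] < INF / 2 and abs(W[k] - (W[i] + V[i, j])) < _EPS:
                stack_v.append((i, j))
                k = i
                break
        else:  # pragma: no cover - defensive
            raise RuntimeError("external traceback failed")

    def trace_wm(i, j):
        while True:
            if V[i, j] < INF / 2 and abs(WM[i, j] - (V[i, j] + m["multi_branch"])) < _EPS:
                stack_v.append((i, j))
                return
            if i + 1 <= j and abs(WM[i, j] - WM[i + 1, j]) < _EPS:
                i += 1
                continue
            if i <= j - 1 and abs(WM[i, j] - WM[i, j - 1]) < _EPS:
                j -= 1
                continue
            for k2 in range(i, j):
                if (WM[i, k2] < INF / 2 and WM[k2 + 1, j] < INF / 2
                        and abs(WM[i, j] - (WM[i, k2] + WM[k2 + 1, j])) < _EPS):
                    trace_wm(i, k2)
                    i = k2 + 1
                    break
            else:  # pragma: no cover - defensive
                raise RuntimeError("WM traceback failed")

    while stack_v:
        i, j = stack_v.pop()
        pairs[i], pairs[j] = j, i
        v = V[i, j]
        loop = j - i - 1
        if loop >= m["min_hairpin_loop"] and abs(v - _hairpin_energy(loop)) < _EPS:
            continue
        found = False
        for l1 in range(0, m["max_internal"] + 1):
            p = i + 1 + l1
            if p >= j - 1 or found:
                break
            for l2 in range(0, m["max_internal"] - l1 + 1):
                q = j - 1 - l2
                if q <= p:
                    break
                if not _CAN_PAIR[enc[p], enc[q]] or V[p, q] >= INF / 2:
                    continue
                e = _loop_energy(l1, l2, rna[i] + rna[j], rna[p] + rna[q])
                if abs(v - (V[p, q] + e)) < _EPS:
                    stack_v.append((p, q))
                    found = True
                    break
        if found:
            continue
        for k2 in range(i + 1, j - 1):
            wl, wr = WM[i + 1, k2], WM[k2 + 1, j - 1]
            if (wl < INF / 2 and wr < INF / 2
                    and abs(v - (m["multi_close"] + m["multi_branch"] + wl + wr)) < _EPS):
                trace_wm(i + 1, k2)
                trace_wm(k2 + 1, j - 1)
                found = True
                break
        if not found:  # pragma: no cover - defensive
            raise RuntimeError("pair traceback failed")


# ---------------------------------------------------------------------------
# MIREAP-style criteria
# ---------------------------------------------------------------------------

@dataclass
class MireapParams:
    """Novel-miRNA screening parameters (printed defaults of the MIREAP run)."""

    min_mature_len: int = 18
    max_mature_len: int = 25
    min_ref_len: int = 20       # bounds on the reported reference mature
    max_ref_len: int = 23
    max_copies: int = 20        # max genomic hits of a tag
    max_energy: float = -18.0   # kcal/mol, precursor ceiling
    max_space: int = 300        # nt, mature to far precursor edge
    min_mature_pair: int = 16
    max_mature_bulge: int = 4
    max_duplex_asymmetry: int = 4
    flank: int = 20


@dataclass
class CriteriaResult:
    passed: bool
    energy: float
    mature_len: int
    mature_pairs: int
    mature_bulge: int
    duplex_asymmetry: int
    failed: list[str]


def evaluate_criteria(struct: SecondaryStructure, mature_start: int,
                      mature_end: int, params: MireapParams | None = None,
                      energy: float | None = None) -> CriteriaResult:
    """Score a mature-arm placement inside a folded precursor.

    ``mature_start``/``mature_end`` are 0-based inclusive positions of the
    mature miRNA within ``struct.seq``.  Metrics:

    * mature_pairs — mature bases paired to the star arm (partners outside
      the mature, all on one side; pairs to the minority side or within the
      mature do not count),
    * mature_bulge — longest run of mature-duplex positions not paired to
      the star, measured between the first and last star-paired base,
    * duplex_asymmetry — |unpaired in mature span − unpaired in star span|.

    ``energy`` overrides the structure's energy (used when the mature sits
    inside a larger folded window).
    """
    params = params or MireapParams()
    n = len(struct.seq)
    if not (0 <= mature_start <= mature_end < n):
        raise ValueError("mature arm not contained in precursor")
    e = struct.energy if energy is None else energy
    mlen = mature_end - mature_start + 1
    pairs = struct.pairs

    partners_lo = [int(pairs[i]) for i in range(mature_start, mature_end + 1)
                   if 0 <= pairs[i] < mature_start]
    partners_hi = [int(pairs[i]) for i in range(mature_start, mature_end + 1)
                   if pairs[i] > mature_end]
    side = partners_hi if len(partners_hi) >= len(partners_lo) else partners_lo

    if side:
        lo, hi = min(side), max(side)
        star_in = [i for i in range(mature_start, mature_end + 1)
                   if lo <= pairs[i] <= hi and (pairs[i] < mature_start or pairs[i] > mature_end)]
        mature_pairs = len(star_in)
        dstart, dend = min(star_in), max(star_in)
        run = best = 0
        for i in range(dstart, dend + 1):
            if i in set(star_in):
                run = 0
            else:
                run += 1
                best = max(best, run)
        bulge = best
        unpaired_m = (dend - dstart + 1) - mature_pairs
        unpaired_s = (hi - lo + 1) - mature_pairs
        asym = abs(unpaired_m - unpaired_s)
    else:
        mature_pairs, bulge, asym = 0, mlen, mlen

    failed = []
    if not (e <= params.max_energy):
        failed.append("energy")
    if not (params.min_mature_len <= mlen <= params.max_mature_len):
        failed.append("mature_len")
    if mature_pairs < params.min_mature_pair:
        failed.append("mature_pair")
    if bulge > params.max_mature_bulge:
        failed.append("mature_bulge")
    if asym > params.max_duplex_asymmetry:
        failed.append("duplex_asymmetry")
    return CriteriaResult(not failed, e, mlen, mature_pairs, bulge, asym, failed)


# ---------------------------------------------------------------------------
# Novel-miRNA prediction
# ---------------------------------------------------------------------------

@dataclass
class NovelCandidate:
    id: str
    chrom: str
    start: int          # 1-based inclusive precursor window
    end: int
    strand: str
    precursor: SecondaryStructure
    mature5p: str | None
    mature3p: str | None
    mature_pairs: int
    mature_bulge: int
    duplex_asymmetry: int
    count_control: int
    count_treated: int

    @property
    def location(self) -> str:
        return f"{self.chrom}:{self.start}:{self.end}"


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _cluster_hits(hit_rows, gap: int):
    """Group (chrom, strand)-sorted hit rows into loci separated by > gap nt."""
    clusters = []
    cur = []
    for row in hit_rows:
        if cur and (row["chrom"] != cur[-1]["chrom"] or row["strand"] != cur[-1]["strand"]
                    or row["start"] - cur[-1]["end"] > gap):
            clusters.append(cur)
            cur = []
        cur.append(row)
    if cur:
        clusters.append(cur)
    return clusters


def predict_novel(tags, hits, genome: dict[str, str],
                  params: MireapParams | None = None,
                  cluster_gap: int = 30, id_prefix: str = "Bro-m") -> list[NovelCandidate]:
    """MIREAP-style novel-miRNA prediction.

    ``tags`` maps tag sequence -> (count_control, count_treated) for the
    unannotated surviving tags; ``hits`` is an iterable of alignment hits
    (dicts or objects with tag_seq, chrom, start, end, strand — 1-based
    inclusive).  Tags with more genomic hits than ``params.max_copies`` are
    excluded.  Reads are clustered into loci (gap <= ``cluster_gap``); per
    locus the most abundant tag is taken as the mature candidate and two
    precursor windows are excised (mature on the 5' arm: [start - flank,
    end + space]; mature on the 3' arm: [start - space, end + flank]),
    folded, and screened; the passing window with the lower energy wins.

    A tag that maps inside a hairpin can also map to the star arm on the
    opposite strand, which would duplicate the locus; candidates driven by
    the same mature tag whose precursor windows overlap are therefore
    merged, keeping the one with the lower energy.  Distinct tags whose
    windows merely overlap remain separate loci.
    """
    params = params or MireapParams()
    rows = []
    per_tag: dict[str, int] = {}
    for h in hits:
        d = h if isinstance(h, dict) else {
            "tag_seq": h.tag_seq, "chrom": h.chrom, "start": h.start,
            "end": h.end, "strand": h.strand}
        if d["tag_seq"] not in tags:
            continue
        per_tag[d["tag_seq"]] = per_tag.get(d["tag_seq"], 0) + 1
        rows.append(d)
    rows = [r for r in rows if per_tag[r["tag_seq"]] <= params.max_copies]
    rows.sort(key=lambda r: (r["chrom"], r["strand"], r["start"], r["end"]))

    candidates = []
    for cluster in _cluster_hits(rows, cluster_gap):
        best_row = max(cluster, key=lambda r: sum(tags[r["tag_seq"]]))
        chrom = best_row["chrom"]
        chrom_seq = genome[chrom]
        clen = len(chrom_seq)
        s0, e0 = best_row["start"], best_row["end"]   # 1-based
        windows = []
        for arm, (ws, we) in (("5p", (s0 - params.flank, e0 + params.max_space)),
                              ("3p", (s0 - params.max_space, e0 + params.flank))):
            ws, we = max(1, ws), min(clen, we)
            sub = chrom_seq[ws - 1:we]
            if best_row["strand"] == "-":
                sub = _revcomp(sub)
                off = we - e0          # mature offset within the window
            else:
                off = s0 - ws
            struct = fold(sub)
            res = evaluate_criteria(struct, off, off + (e0 - s0), params)
            windows.append((arm, ws, we, struct, off, res))
        passing = [w for w in windows if w[5].passed]
        if not passing:
            continue
        arm, ws, we, struct, off, res = min(passing, key=lambda w: w[3].energy)
        mature = best_row["tag_seq"]
        # arm label from position of the mature within the folded window
        mid = off + res.mature_len / 2
        is5p = mid < len(struct.seq) / 2
        candidates.append(NovelCandidate(
            id="", chrom=chrom, start=ws, end=we, strand=best_row["strand"],
            precursor=struct,
            mature5p=mature if is5p else None,
            mature3p=None if is5p else mature,
            mature_pairs=res.mature_pairs, mature_bulge=res.mature_bulge,
            duplex_asymmetry=res.duplex_asymmetry,
            count_control=tags[mature][0], count_treated=tags[mature][1]))
    candidates.sort(key=lambda c: (c.chrom, c.start, c.end, c.strand))
    merged: list[NovelCandidate] = []
    for c in candidates:
        mature = c.mature5p or c.mature3p
        dup = next((i for i, p in enumerate(merged)
                    if p.chrom == c.chrom and c.start <= p.end and p.start <= c.end
                    and (p.mature5p or p.mature3p) == mature), None)
        if dup is None:
            merged.append(c)
        elif c.precursor.energy < merged[dup].precursor.energy:
            merged[dup] = c
    merged.sort(key=lambda c: (c.chrom, c.start, c.end, c.strand))
    for k, c in enumerate(merged, 1):
        c.id = f"{id_prefix}{k:03d}"
    return merged
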