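"""Folding engine: DP vs exhaustive enumeration, energy monotonicity,
stem-loop criteria, novel-locus prediction mechanics."""

import math
import random

import numpy as np
import pytest

from brocmir import hairpin as hp

# ---------------------------------------------------------------------------
# independent structure enumeration + energy evaluation (test-side oracle)
# ---------------------------------------------------------------------------

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def enumerate_structures(seq):
    """All pseudoknot-free pair sets with hairpin loops >= 3 nt."""
    n = len(seq)

    def rec(positions):
        if not positions:
            yield []
            return
        first, rest = positions[0], positions[1:]
        # first unpaired
        for s in rec(rest):
            yield s
        # first paired with some j
        for idx, j in enumerate(rest):
            if j - first - 1 < 3:
                continue
            if (seq[first], seq[j]) not in _PAIRS:
                continue
            inside = [p for p in rest[:idx]]
            outside = rest[idx + 1:]
            for si in rec(inside):
                for so in rec(outside):
                    yield [(first, j)] + si + so

    yield from rec(list(range(n)))


def oracle_energy(seq, pairs):
    """Loop-decomposition energy, written independently of the package DP."""
    m = hp.ENERGY_MODEL
    pmap = dict(pairs)
    pmap.update({j: i for i, j in pairs})

    def children(i, j):
        out, k = [], i + 1
        while k < j:
            if k in pmap and pmap[k] > k:
                out.append((k, pmap[k]))
                k = pmap[k] + 1
            else:
                k += 1
        return out

    total = 0.0
    for (i, j) in pairs:
        kids = children(i, j)
        if not kids:
            total += m["hairpin_base"] + m["hairpin_slope"] * math.log((j - i - 1) / 3)
        elif len(kids) == 1:
            p, q = kids[0]
            l1, l2 = p - i - 1, j - q - 1
            if l1 == 0 and l2 == 0:
                total += m["stacks"][f"{seq[i]}{seq[j]}/{seq[p]}{seq[q]}"]
            elif l1 == 0 or l2 == 0:
                total += m["bulge_base"] + m["bulge_slope"] * math.log(l1 + l2)
            else:
                total += (m["internal_base"] + m["internal_slope"] * math.log((l1 + l2) / 2)
                          + min(m["internal_asym"] * abs(l1 - l2), m["internal_asym_cap"]))
        else:
            total += m["multi_close"] + m["multi_branch"] * (len(kids) + 1)
    return total


def oracle_mfe(seq):
    return min((oracle_energy(seq, p) for p in enumerate_structures(seq)),
               default=0.0)


# ---------------------------------------------------------------------------
# fold
# ---------------------------------------------------------------------------

def test_unpairable_sequence_is_open_chain():
    s = hp.fold("AAAA")
    assert s.dotbracket == "...." and s.energy == 0.0


def test_perfect_gc_stem_folds_below_minus18():
    s = hp.fold("GCGCGCGC" + "AAAA" + "GCGCGCGC")
    assert s.dotbracket == "((((((((....))))))))"
    assert s.energy < -18.0


def test_fold_matches_exhaustive_enumeration_on_18mers():
    rng = random.Random(11)
    for _ in range(30):
        seq = "".join(rng.choice("ACGU") for _ in range(18))
        mfe = min(oracle_mfe(seq), 0.0)
        got = hp.fold(seq).energy
        assert got == pytest.approx(mfe, abs=1e-6), seq


def test_reported_structure_energy_is_self_consistent():
    rng = random.Random(5)
    for _ in range(5):
        seq = "".join(rng.choice("ACGU") for _ in range(60))
        s = hp.fold(seq)
        assert hp.structure_energy(seq, s.pairs) == pytest.approx(s.energy, abs=1e-9)


def test_stem_extension_never_raises_energy():
    """Appending a stacking complementary pair is never penalised."""
    rng = random.Random(3)
    stems = ["GC", "CG", "AU", "UA", "GU", "UG"]
    for _ in range(50):
        inner = "".join(rng.choice("ACGU") for _ in range(12))
        e_inner = hp.fold(inner).energy
        p = rng.choice(stems)
        extended = p[0] + inner + p[1]
        assert hp.fold(extended).energy <= e_inner + 1e-9


def test_fold_rejects_bad_input():
    with pytest.raises(ValueError):
        hp.fold("ACGX")


# ---------------------------------------------------------------------------
# criteria
# ---------------------------------------------------------------------------

def _stem_loop(mature="GCAUGCAUGCAUGCAUGCAUG"):
    star = str.maketrans("ACGU", "UGCA")
    prec = mature + "GAAAACAAAA" + mature.translate(star)[::-1]
    return mature, hp.fold(prec)


def test_planted_stem_loop_passes_all_criteria():
    mature, s = _stem_loop()
    res = hp.evaluate_criteria(s, 0, len(mature) - 1)
    assert res.passed, res
    assert res.mature_pairs >= 16 and res.mature_bulge <= 4 and res.duplex_asymmetry <= 4


def test_energy_ceiling_enforced():
    mature, s = _stem_loop()
    res = hp.evaluate_criteria(s, 0, len(mature) - 1, energy=-10.0)
    assert not res.passed and "energy" in res.failed


def test_min_mature_pair_enforced():
    mature, s = _stem_loop()
    params = hp.MireapParams(min_mature_pair=22)   # unreachable for a 21-mer
    res = hp.evaluate_criteria(s, 0, len(mature) - 1, params)
    assert not res.passed and "mature_pair" in res.failed
    # and the boundary: 15 paired bases fails the printed minimum of 16
    assert hp.MireapParams().min_mature_pair == 16


def test_mature_outside_precursor_is_error():
    _, s = _stem_loop()
    with pytest.raises(ValueError):
        hp.evaluate_criteria(s, 0, len(s.seq))


# ---------------------------------------------------------------------------
# novel prediction mechanics
# ---------------------------------------------------------------------------

def test_multicopy_tag_excluded():
    rng = random.Random(2)
    mature = "GCAUGCAUGCAUGCAUGCAUG".replace("U", "T")
    unit = mature + "GAAAACAAAA" + hp._revcomp(mature)
    genome = {"c1": ("".join(rng.choice("ACGT") for _ in range(400))).join(
        [""] * 2)}
    # 25 copies of the locus, separated by random spacers
    parts = []
    for _ in range(25):
        parts.append("".join(rng.choice("ACGT") for _ in range(400)))
        parts.append(unit)
    genome = {"c1": "".join(parts)}
    hits = []
    pos = 0
    for _ in range(25):
        pos += 400
        hits.append({"tag_seq": mature, "chrom": "c1", "start": pos + 1,
                     "end": pos + len(mature), "strand": "+"})
        pos += len(unit)
    tags = {mature: (50, 60)}
    cands = hp.predict_novel(tags, hits, genome, hp.MireapParams(max_copies=20))
    assert cands == []


def test_single_planted_locus_recovered(study):
    truth = study["truth"]
    m = next(x for x in truth.planted_mirnas if x.strand == "+")
    L = len(m.mature)
    if m.arm == "5p":
        s0, e0 = m.start, m.start + L - 1
    else:
        s0, e0 = m.end - L + 1, m.end
    hits = [{"tag_seq": m.mature, "chrom": m.chrom, "start": s0, "end": e0,
             "strand": "+"}]
    cands = hp.predict_novel({m.mature: (10, 10)}, hits, study["genome"])
    assert len(cands) == 1
    c = cands[0]
    assert c.chrom == m.chrom and c.strand == "+"
    assert c.start <= m.start and m.end <= c.end
    assert (c.mature5p or c.mature3p) == m.mature
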