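"""Target-site scoring under the five alignment rules, vs a brute-force
oracle, plus the monotonicity property."""

import random

import pytest

from brocmir import targetscan as ts
from brocmir.hairpin import ENERGY_MODEL, transcribe

RC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def perfect_window(mirna):
    return "".join(RC[b] for b in reversed(mirna))


def set_positions(mirna, window, positions, kind="mismatch"):
    """Force the window bases facing the given miRNA positions (1-based)."""
    w = list(window)
    for p in positions:
        idx = len(w) - p
        if kind == "wobble":
            w[idx] = {"G": "U", "U": "G"}[mirna[p - 1]]
        else:
            bad = {RC[mirna[p - 1]], {"G": "U", "U": "G"}.get(mirna[p - 1]),
                   None}
            w[idx] = next(b for b in "ACGU" if b not in bad)
    return "".join(w)


MIRNA = "UGGAGCUCCCUUCAUUCCAAU"   # 21 nt, has G/U at wobble-test positions


def test_perfect_complement_accepted():
    s = ts.score_site(MIRNA, perfect_window(MIRNA))
    assert s.mismatch_score == 0.0
    assert s.mfe_ratio == pytest.approx(1.0)
    assert s.accepted


def test_mismatch_at_position_10_violates_rule_iv():
    w = set_positions(MIRNA, perfect_window(MIRNA), [10])
    s = ts.score_site(MIRNA, w)
    assert "iv" in s.violated_rules and not s.accepted


def test_three_wobbles_score_one_and_a_half():
    mirna = "UGGAGGUCCCUUCAUGCCAAU"   # G/U at positions 3, 6, 15
    assert mirna[2] in "GU" and mirna[5] in "GU" and mirna[14] in "GU"
    w = set_positions(mirna, perfect_window(mirna), [3, 6, 15], kind="wobble")
    s = ts.score_site(mirna, w)
    assert s.mismatch_score == pytest.approx(1.5)
    assert s.wobbles == 3
    for rule in ("i", "ii", "iii", "iv"):
        assert rule not in s.violated_rules


@pytest.mark.parametrize("positions,rule", [
    ((13, 15, 17, 19, 21), "i"),     # five full mismatches
    ((5, 6), "ii"),                  # adjacent inside 2-12
    ((15, 16, 17), "iii"),           # run of three
    ((11,), "iv"),                   # seed-cleavage position
])
def test_rule_violations_flagged(positions, rule):
    w = set_positions(MIRNA, perfect_window(MIRNA), list(positions))
    s = ts.score_site(MIRNA, w)
    assert rule in s.violated_rules and not s.accepted


def test_duplex_energy_sanity():
    s = ts.score_site(MIRNA, set_positions(MIRNA, perfect_window(MIRNA), [5]))
    assert s.mfe_perfect < 0
    assert s.mfe_duplex >= s.mfe_perfect
    assert 0 <= s.mfe_ratio < 1


def test_mismatch_never_rescues_a_site():
    """Converting a matched position to a mismatch never lowers the score
    and never flips rejected -> accepted."""
    rng = random.Random(6)
    for _ in range(30):
        mirna = "".join(rng.choice("ACGU") for _ in range(21))
        base = perfect_window(mirna)
        positions = rng.sample(range(1, 22), rng.randint(0, 4))
        w = set_positions(mirna, base, positions)
        s0 = ts.score_site(mirna, w)
        extra = rng.choice([p for p in range(1, 22) if p not in positions])
        w2 = set_positions(mirna, w, [extra])
        s1 = ts.score_site(mirna, w2)
        assert s1.mismatch_score >= s0.mismatch_score
        assert s1.mfe_duplex >= s0.mfe_duplex - 1e-9
        if not s0.accepted:
            assert not s1.accepted


# ---------------------------------------------------------------------------
# brute-force oracle for the scanner
# ---------------------------------------------------------------------------

def oracle_scan(mirnas, transcripts):
    """Naive double loop with independent rule logic."""
    wob = {("G", "U"), ("U", "G")}
    out = set()
    for tid, tx in transcripts.items():
        for mid, mi in mirnas.items():
            L = len(mi)
            for s0 in range(len(tx) - L + 1):
                win = tx[s0:s0 + L]
                scores = []
                for k in range(L):
                    a, b = mi[k], win[L - 1 - k]
                    if RC[a] == b:
                        scores.append(0.0)
                    elif (a, b) in wob:
                        scores.append(0.5)
                    else:
                        scores.append(1.0)
                if sum(scores) > 4:
                    continue
                mm = [s > 0 for s in scores]
                if any(mm[k] and mm[k + 1] for k in range(1, 11)):
                    continue
                if any(mm[k] and mm[k + 1] and mm[k + 2] for k in range(L - 2)):
                    continue
                if mm[9] or mm[10] or sum(scores[:12]) > 2.5:
                    continue
                # rule v with an independently summed stack energy
                stacks = ENERGY_MODEL["stacks"]
                def pair_of(k):
                    if scores[k] == 0.0:
                        return mi[k] + RC[mi[k]]
                    return mi[k] + {"G": "U", "U": "G"}[mi[k]]
                e = sum(0.5 for s in scores if s == 1.0)
                for k in range(L - 1):
                    if scores[k] < 1.0 and scores[k + 1] < 1.0:
                        e += stacks[f"{pair_of(k)}/{pair_of(k + 1)}"]
                ep = sum(stacks[f"{mi[k]}{RC[mi[k]]}/{mi[k+1]}{RC[mi[k+1]]}"]
                         for k in range(L - 1))
                if ep >= 0 or e / ep < 0.75:
                    continue
                out.add((mid, tid, s0 + 1))
    return out


def test_scanner_equals_bruteforce_oracle():
    rng = random.Random(77)
    mirnas = {f"m{k}": "".join(rng.choice("ACGU") for _ in range(21))
              for k in range(5)}
    transcripts = {}
    for k in range(20):
        seq = "".join(rng.choice("ACGU") for _ in range(120))
        if k < 10:   # plant a (possibly mutated) site so acceptances exist
            mid = rng.choice(list(mirnas))
            w = perfect_window(mirnas[mid])
            if rng.random() < 0.5:
                w = set_positions(mirnas[mid], w, rng.sample(range(1, 22), 2))
            pos = rng.randrange(0, len(seq) - len(w))
            seq = seq[:pos] + w + seq[pos + len(w):]
        transcripts[f"t{k}"] = seq
    got = {(s.mirna_id, s.transcript_id, s.site_start)
           for s in ts.scan_targets(mirnas, transcripts)}
    assert got == oracle_scan(mirnas, transcripts)
    assert got   # the comparison is not vacuous


def test_empty_transcripts():
    assert ts.scan_targets({"m": "ACGUACGUACGUACGUACGUA"}, {}) == []


def test_planted_truth_sites_roundtrip(study):
    """Every planted compliant site accepted; every violator rejected with
    the intended rule flagged."""
    truth = study["truth"]
    mirnas = {m.id: transcribe(m.mature) for m in truth.planted_mirnas}
    transcripts = {k: transcribe(v) for k, v in study["transcripts"].items()}
    accepted = {(s.mirna_id, s.transcript_id, s.site_start)
                for s in ts.scan_targets(mirnas, transcripts)}
    for t in truth.true_targets:
        key = (t.mirna_id, t.transcript_id, t.position)
        if t.compliant:
            assert key in accepted, t
        else:
            assert key not in accepted, t
            tx = transcripts[t.transcript_id]
            mi = mirnas[t.mirna_id]
            s = ts.score_site(mi, tx[t.position - 1:t.position - 1 + len(mi)])
            assert t.violated_rule in s.violated_rules
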