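"""Read cleaning: quality decoding, rejection rules, trimming, collapsing."""

import random
from collections import Counter

import pytest

from brocmir import preprocess as pp
from brocmir.preprocess import RawRead

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


def q(scores, offset=64):
    return "".join(chr(s + offset) for s in scores)


@pytest.mark.parametrize("char,offset,expected", [
    ("h", 64, 40), ("@", 64, 0), ("!", 33, 0), ("J", 33, 41),
])
def test_decode_quality_ascii_arithmetic(char, offset, expected):
    assert pp.decode_quality(char, offset) == [expected]


def test_decode_quality_below_offset_is_error():
    with pytest.raises(pp.MalformedQualityError):
        pp.decode_quality("!", 64)


def make_read(insert, quals=None, adapter=ADAPTER, rid="r1", pad=True):
    seq = insert + adapter
    if pad and len(seq) < 36:
        seq += "A" * (36 - len(seq))
    seq = seq[:36]
    if quals is None:
        quals = [40] * len(seq)
    return RawRead(rid, seq, q(quals[:len(seq)] + [40] * (len(seq) - len(quals))))


class TestRejectionRules:
    def test_any_n_base_rejected(self):
        read = make_read("ACGTN" + "ACGT" * 5)
        insert, reason = pp.check_read(read, ADAPTER)
        assert insert is None and reason == "removed_N"

    def test_five_bases_below_q10_rejected(self):
        quals = [9] * 5 + [40] * 31
        read = make_read("ACGT" * 6, quals)
        assert pp.check_read(read, ADAPTER)[1] == "removed_q10"

    def test_boundary_four_q9_and_six_q12_retained(self):
        # exactly 4 below Q10 and 6 (4+2) below Q13 satisfies both "more than" rules
        quals = [9] * 4 + [12] * 2 + [40] * 30
        insert, reason = pp.check_read(make_read("ACGTACGTACGTACGTACGTAC", quals), ADAPTER)
        assert reason is None
        assert insert == "ACGTACGTACGTACGTACGTAC"

    def test_seven_bases_below_q13_rejected(self):
        quals = [12] * 7 + [40] * 29
        assert pp.check_read(make_read("ACGT" * 6, quals), ADAPTER)[1] == "removed_q13"

    def test_short_insert_rejected(self):
        assert pp.check_read(make_read("ACGTACGTACGTACGT"), ADAPTER)[1] == "removed_short"

    def test_no_adapter_long_read_rejected(self):
        read = RawRead("r", "ACGT" * 9, q([40] * 36))
        assert pp.check_read(read, ADAPTER)[1] == "removed_no_adapter"

    def test_suffix_overlap_trimming(self):
        # 30-nt insert leaves only 6 adapter bases: suffix-overlap path
        insert = "ACGTACGTACGTACGTACGTACGTACGTAC"
        read = RawRead("r", (insert + ADAPTER)[:36], q([40] * 36))
        got, reason = pp.check_read(read, ADAPTER)
        assert reason is None and got == insert


def test_clean_reads_collapses_and_conserves():
    reads = [make_read("ACGTACGTACGTACGTACGTA", rid=f"r{i}") for i in range(5)]
    reads += [make_read("TTTTACGTACGTACGTACGTT", rid="x")]
    reads += [make_read("ACGTN" + "ACGT" * 4, rid="bad")]
    tags, rep = pp.clean_reads(reads, ADAPTER)
    assert rep.total_raw == 7 and rep.removed_N == 1
    assert rep.clean_total == sum(tags.values()) == 6
    assert rep.clean_unique == len(tags) == 2
    assert tags["ACGTACGTACGTACGTACGTA"] == 5


def test_survivor_set_matches_naive_oracle():
    """Cleaning equals an independent per-read re-check (multiset equality)."""
    rng = random.Random(7)
    reads = []
    for i in range(800):
        n = rng.randint(12, 30)
        insert = "".join(rng.choice("ACGT") for _ in range(n))
        kind = rng.choice(["ok", "ok", "ok", "n", "lowq", "q13", "noadapter"])
        seq = insert + (ADAPTER if kind != "noadapter"
                        else "".join(rng.choice("ACGT") for _ in range(21)))
        seq = (seq + "G" * 36)[:36]
        quals = [rng.randint(25, 40) for _ in range(36)]
        if kind == "n":
            p = rng.randrange(len(insert))
            seq = seq[:p] + "N" + seq[p + 1:]
        elif kind == "lowq":
            for p in rng.sample(range(36), 5):
                quals[p] = rng.randint(0, 9)
        elif kind == "q13":
            for p in rng.sample(range(36), 7):
                quals[p] = rng.randint(10, 12)
        reads.append(RawRead(f"r{i}", seq, q(quals)))
    tags, rep = pp.clean_reads(reads, ADAPTER)

    # oracle: direct re-statement of the rules, independent control flow
    oracle = Counter()
    for r in reads:
        scores = [ord(c) - 64 for c in r.qual]
        if "N" in r.seq:
            continue
        if len([s for s in scores if s < 10]) >= 5:
            continue
        if len([s for s in scores if s < 13]) >= 7:
            continue
        pos = r.seq.find(ADAPTER[:8])
        if pos < 0:
            best = None
            for k in range(6, min(len(ADAPTER), len(r.seq)) + 1):
                if r.seq.endswith(ADAPTER[:k]):
                    best = k
            if best is not None:
                ins = r.seq[:-best]
            elif len(r.seq) <= 30:
                ins = r.seq
            else:
                continue
        else:
            ins = r.seq[:pos]
        if 18 <= len(ins) <= 30:
            oracle[ins] += 1
    assert tags == oracle
    assert rep.clean_total == sum(oracle.values())


def test_filter_order_irrelevant_for_survivors():
    """Filters are conjunctive: a read failing several rules is rejected
    regardless of which counter claims it."""
    quals = [5] * 7 + [40] * 29
    read = make_read("ACGNACGTACGTACGTACGTAC", quals)   # N and low quality
    insert, reason = pp.check_read(read, ADAPTER)
    assert insert is None   # rejection independent of classification order


def test_length_distribution_fractions():
    import pandas as pd
    tags = pd.DataFrame({"seq": ["A" * 21, "C" * 24], "count_control": [1, 3],
                         "count_treated": [0, 0]})
    ld = pp.length_distribution(tags)
    assert ld.total_frac[21] == pytest.approx(0.25)
    assert ld.total_frac[24] == pytest.approx(0.75)
    assert ld.unique_frac[21] == ld.unique_frac[24] == pytest.approx(0.5)
    assert abs(ld.total_frac.sum() - 1) < 1e-9 and abs(ld.unique_frac.sum() - 1) < 1e-9


def test_length_distribution_single_tag():
    import pandas as pd
    tags = pd.DataFrame({"seq": ["G" * 24], "count_control": [10], "count_treated": [0]})
    ld = pp.length_distribution(tags)
    assert ld.total_frac[24] == 1.0 and ld.unique_frac[24] == 1.0


def test_library_overlap():
    import pandas as pd
    a = pd.DataFrame({"seq": ["AAA"], "count": [2]})
    b = pd.DataFrame({"seq": ["AAA", "CCC"], "count": [3, 5]})
    ov = pp.library_overlap(a, b)
    assert ov["unique_shared_fraction"] == pytest.approx(0.5)
    assert ov["total_shared_fraction"] == pytest.approx(0.5)
    same = pp.library_overlap(b, b)
    assert same["unique_shared_fraction"] == 1.0
    disjoint = pp.library_overlap(a, pd.DataFrame({"seq": ["GGG"], "count": [1]}))
    assert disjoint["unique_shared_fraction"] == 0.0
    assert disjoint["total_shared_fraction"] == 0.0
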