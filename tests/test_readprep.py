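import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hgscan.readprep import (MergedRead, QCConfig, ReadPair, merge_pairs,
                             preprocess_pairs, quality_filter, remove_adapters)
from hgscan.synthetic import revcomp

Q38 = lambda n: np.full(n, 38, dtype=np.uint8)
DNA = st.text(alphabet="ACGT", min_size=30, max_size=60)


def _pair(insert: str, rl: int, q1=None, q2=None) -> ReadPair:
    adapter = QCConfig().adapter_seq
    r1 = (insert + adapter * 3)[:rl]
    r2 = (revcomp(insert) + adapter * 3)[:rl]
    return ReadPair("p", r1, q1 if q1 is not None else Q38(rl),
                    r2, q2 if q2 is not None else Q38(rl))


def test_adapter_removal_exact():
    cfg = QCConfig()
    insert = "ACGTACGTAGCTAGCTAGGA"
    pair = _pair(insert, rl=30)
    trimmed = remove_adapters(pair, cfg.adapter_seq, cfg.max_mismatch_frac)
    assert trimmed.seq1 == insert
    assert trimmed.seq2 == revcomp(insert)
    assert len(trimmed.qual1) == len(insert)


def test_adapter_not_removed_when_absent():
    cfg = QCConfig()
    seq = "ACGTACGTAGCTAGCTAGGATTCCTGGTTT"
    pair = ReadPair("p", seq, Q38(30), seq, Q38(30))
    trimmed = remove_adapters(pair, cfg.adapter_seq, cfg.max_mismatch_frac)
    assert trimmed.seq1 == seq


def test_merge_exact_reconstruction():
    cfg = QCConfig(min_overlap_bp=5)
    insert = "ACGTACGTAGCTAGCTAGGATCCAG"   # 25 bp
    rl = 20
    pair = ReadPair("p", insert[:rl], Q38(rl), revcomp(insert)[:rl], Q38(rl))
    m = merge_pairs(pair, cfg)
    assert m is not None
    assert m.seq == insert
    assert m.overlap_len == 2 * rl - len(insert)
    # agreeing overlap bases take the max quality
    assert (m.qual == 38).all()


def test_merge_conflict_tie_is_N_and_symmetric():
    cfg = QCConfig(min_overlap_bp=5)
    insert = "ACGTACGTAGCTAGCTAGGATCCAG"
    rl = 20
    i = 12   # inside the 15 bp overlap
    r1 = list(insert[:rl])
    r1[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[r1[i]]
    r1 = "".join(r1)
    r2 = revcomp(insert)[:rl]
    m = merge_pairs(ReadPair("p", r1, Q38(rl), r2, Q38(rl)), cfg)
    assert m.seq[i] == "N" and m.qual[i] == 0
    # swapping mates reverse-complements the consensus, N included
    ms = merge_pairs(ReadPair("p", r2, Q38(rl), r1, Q38(rl)), cfg)
    assert ms.seq == revcomp(m.seq)


def test_merge_conflict_higher_quality_wins():
    cfg = QCConfig(min_overlap_bp=5)
    insert = "ACGTACGTAGCTAGCTAGGATCCAG"
    rl = 20
    i = 12
    r1 = list(insert[:rl])
    r1[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[r1[i]]
    r1 = "".join(r1)
    q1 = Q38(rl)
    q1[i] = 40
    m = merge_pairs(ReadPair("p", r1, q1, revcomp(insert)[:rl], Q38(rl)), cfg)
    assert m.seq[i] == r1[i]
    assert m.qual[i] == 2   # |40 - 38|


def test_merge_rejects_without_overlap():
    cfg = QCConfig(min_overlap_bp=10)
    m = merge_pairs(ReadPair("p", "ACGTACGTACGTACG", Q38(15),
                             "TTTTTTTTTTTTTTT", Q38(15)), cfg)
    assert m is None


@settings(max_examples=100, derandomize=True)
@given(seed=st.integers(0, 10**6), ilen=st.integers(30, 44))
def test_merge_roundtrip_property(seed, ilen):
    # uniform-random inserts: the true overlap offset is the score optimum
    # with overwhelming probability (periodic sequences are ambiguous by
    # construction and are not drawn here)
    rng = np.random.default_rng(seed)
    insert = "".join(rng.choice(list("ACGT"), size=ilen))
    rl = 25
    cfg = QCConfig(min_overlap_bp=5)
    pair = ReadPair("p", insert[:rl], Q38(rl), revcomp(insert)[:rl], Q38(rl))
    m = merge_pairs(pair, cfg)
    # error-free overlapping pairs must merge back to the insert
    assert m is not None and m.seq == insert


def test_quality_filter_thresholds():
    cfg = QCConfig(min_mean_q=20, min_len_bp=10)
    good = MergedRead("a", "A" * 10, np.full(10, 25, dtype=np.uint8), 5)
    short = MergedRead("b", "A" * 9, np.full(9, 25, dtype=np.uint8), 5)
    lowq = MergedRead("c", "A" * 10, np.full(10, 19, dtype=np.uint8), 5)
    assert quality_filter([good, short, lowq], cfg) == [good]


def test_preprocess_pipeline_end_to_end():
    cfg = QCConfig(min_len_bp=20, min_overlap_bp=5)
    inserts = ["ACGTACGTAGCTAGCTAGGATCCAG" + "TTGACA" * 2,
               "CCGGAATTCCGGAATTCCGGTACGTACG"]
    rl = 25
    pairs = []
    for k, ins in enumerate(inserts):
        q = chr(38 + 33) * rl
        pairs.append((f"r{k}", (ins + cfg.adapter_seq)[:rl], q,
                      (revcomp(ins) + cfg.adapter_seq)[:rl], q))
    merged = preprocess_pairs(pairs, cfg)
    got = {m.id: m.seq for m in merged}
    for k, ins in enumerate(inserts):
        if len(ins) >= 20:
            assert got[f"r{k}"] == ins


def test_readpair_validates_lengths():
    with pytest.raises(ValueError):
        ReadPair("p", "ACGT", np.zeros(3, dtype=np.uint8), "ACGT", Q38(4))
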