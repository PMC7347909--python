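import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from hgscan.orf import (DEFAULT_START_CODONS, Orf, OrfConfig, decode_protein,
                        encode_protein, predict_orfs, predict_orfs_batch)
from hgscan.synthetic import revcomp

STOPS = {"TAA", "TAG", "TGA"}


def brute_orfs(dna: str, min_len_aa: int, starts=DEFAULT_START_CODONS):
    """Reference six-frame strict ORF caller built on Biopython translation."""
    out = set()
    for strand, seq in (("+", dna), ("-", revcomp(dna))):
        L = len(dna)
        for frame in range(3):
            codons = [seq[frame + 3 * i:frame + 3 * i + 3]
                      for i in range((len(seq) - frame) // 3)]
            i = 0
            while i < len(codons):
                if codons[i] in starts:
                    for j in range(i, len(codons)):
                        if codons[j] in STOPS:
                            prot = "M" + str(Seq(
                                "".join(codons[i + 1:j])).translate(table=11))
                            if len(prot) >= min_len_aa:
                                a = frame + 3 * i
                                b = frame + 3 * (j + 1) - 1
                                if strand == "-":
                                    a, b = L - 1 - b, L - 1 - a
                                out.add((prot, a + 1, b + 1, strand))
                            i = j  # next start is sought after this stop
                            break
                    else:
                        break
                i += 1
    return out


def test_worked_example_atg():
    orfs = predict_orfs("ATGAAATAA", OrfConfig(min_len_aa=1))
    forward = [o for o in orfs if o.strand == "+"]
    assert len(forward) == 1
    o = forward[0]
    assert (o.protein, o.start, o.end) == ("MK", 1, 9)
    assert o.has_start and o.has_stop


@pytest.mark.parametrize("start", ["ATG", "GTG", "TTG"])
def test_alternative_starts_become_met(start):
    orfs = predict_orfs(start + "AAATAA", OrfConfig(min_len_aa=1))
    prots = {o.protein for o in orfs if o.strand == "+"}
    assert "MK" in prots


def test_min_length_filter():
    dna = "ATG" + "AAA" * 10 + "TAA"
    assert predict_orfs(dna, OrfConfig(min_len_aa=12)) == []
    assert any(o.protein == "M" + "K" * 10
               for o in predict_orfs(dna, OrfConfig(min_len_aa=11)))


def test_minus_strand_coordinates():
    plus = "ATGAAACCCTAA"
    dna = revcomp(plus)
    orfs = [o for o in predict_orfs(dna, OrfConfig(min_len_aa=1))
            if o.strand == "-"]
    assert len(orfs) == 1
    o = orfs[0]
    assert o.protein == "MKP"
    # the ORF occupies the whole sequence, in forward coordinates
    assert (o.start, o.end) == (1, len(dna))


def test_n_translates_to_x():
    orfs = predict_orfs("ATGANACCCTAA", OrfConfig(min_len_aa=1,
                                                  both_strands=False))
    assert orfs[0].protein == "MXP"


def test_partial_orfs_at_edges():
    # a gene fragment with no start and no stop still yields an ORF
    inner = "AAAGGGCCCTTTAAAGGGCCCTTT"
    orfs = predict_orfs(inner, OrfConfig(min_len_aa=5, allow_partial=True))
    frame0 = [o for o in orfs if o.strand == "+" and o.start == 1]
    assert any(not o.has_start and not o.has_stop for o in frame0)
    # strict mode finds nothing here
    assert predict_orfs(inner, OrfConfig(min_len_aa=5)) == []


def test_partial_contains_strict_translation():
    dna = "CC" + "ATG" + "GAAACCTTT" * 4 + "TAA" + "GG"
    strict = predict_orfs(dna, OrfConfig(min_len_aa=5))
    partial = predict_orfs(dna, OrfConfig(min_len_aa=5, allow_partial=True))
    strict_prots = {o.protein for o in strict}
    partial_prots = {o.protein for o in partial}
    for p in strict_prots:
        # every strict ORF is contained in some partial-mode ORF
        assert any(p[1:] in q for q in partial_prots)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10**6), n=st.integers(30, 220))
def test_strict_mode_matches_bruteforce(seed, n):
    rng = np.random.default_rng(seed)
    dna = "".join(rng.choice(list("ACGT"), size=n))
    cfg = OrfConfig(min_len_aa=3)
    got = {(o.protein, o.start, o.end, o.strand)
           for o in predict_orfs(dna, cfg)}
    assert got == brute_orfs(dna, 3)


def test_batch_matches_scalar():
    rng = np.random.default_rng(1)
    seqs = ["".join(rng.choice(list("ACGT"), size=90)) for _ in range(20)]
    cfg = OrfConfig(min_len_aa=3, allow_partial=True)
    batch = predict_orfs_batch(seqs, [f"s{i}" for i in range(20)], cfg)
    per_read = {}
    for o in batch.to_orfs():
        per_read.setdefault(o.source_id, set()).add(
            (o.protein, o.start, o.end, o.strand))
    for i, s in enumerate(seqs):
        solo = {(o.protein, o.start, o.end, o.strand)
                for o in predict_orfs(s, cfg)}
        assert per_read.get(f"s{i}", set()) == solo


def test_encode_decode_roundtrip():
    p = "ACDEFGHIKLMNPQRSTVWYX"
    assert decode_protein(encode_protein(p)) == p


def test_rejects_bad_input():
    with pytest.raises(ValueError):
        predict_orfs("AC", OrfConfig())
    with pytest.raises(ValueError):
        predict_orfs("ACGU", OrfConfig())
    with pytest.raises(ValueError):
        OrfConfig(translation_table=1)
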