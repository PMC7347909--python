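import json
import math

import numpy as np
import pytest

from hgscan.motifs import AMINO_ACIDS
from hgscan.profile import (Hit, NotCalibratedError, ProfileModel,
                            build_profile, calibrate, evalue_of,
                            prefilter_candidates, profile_from_family,
                            raw_score, score_sequence, search)


def test_build_profile_emissions_hand_example():
    aln = ["ACD", "ACD", "A-D", "AVD"]
    p = build_profile(aln, family_id="t", pseudocount_weight=1.0,
                      max_col_gap_frac=0.5)
    # all three columns have gap fraction <= 0.5
    assert list(p.column_map) == [1, 2, 3]
    bg = p.background_freqs
    a_idx = AMINO_ACIDS.index("A")
    c_idx = AMINO_ACIDS.index("C")
    v_idx = AMINO_ACIDS.index("V")
    # column 1: 4 x A -> (4 + bg)/(4 + 1)
    assert p.match_emissions[0, a_idx] == pytest.approx((4 + bg[a_idx]) / 5)
    # column 2: 2 x C, 1 x V, 3 non-gap residues
    assert p.match_emissions[1, c_idx] == pytest.approx((2 + bg[c_idx]) / 4)
    assert p.match_emissions[1, v_idx] == pytest.approx((1 + bg[v_idx]) / 4)
    assert p.match_emissions.sum(axis=1) == pytest.approx(np.ones(3))


def test_gappy_columns_are_dropped():
    aln = ["A-CD", "A-CD", "AW-D", "A--D"]
    p = build_profile(aln, max_col_gap_frac=0.5)
    # column 2 is 75% gaps, column 3 is 50% (kept at the boundary)
    assert list(p.column_map) == [1, 3, 4]
    with pytest.raises(ValueError):
        build_profile(["--", "--", "AA"], max_col_gap_frac=0.4)


def test_build_profile_input_validation():
    with pytest.raises(ValueError):
        build_profile(["ACD"])
    with pytest.raises(ValueError):
        build_profile(["ACD", "AC"])


def test_score_identical_alignment_manual():
    aln = ["ACDEFGHIKL"] * 4
    p = build_profile(aln)
    expected = 0.0
    for aa in "ACDEFGHIKL":
        bg = p.background_freqs[AMINO_ACIDS.index(aa)]
        expected += math.log2(((4 + bg) / 5) / bg)
    assert raw_score(p, "ACDEFGHIKL") == pytest.approx(expected)


def test_x_residue_is_score_neutral():
    aln = ["ACDEFGHIKL"] * 4
    p = build_profile(aln)
    full = raw_score(p, "ACDEFGHIKL")
    bg_f = p.background_freqs[AMINO_ACIDS.index("F")]
    col_f = math.log2(((4 + bg_f) / 5) / bg_f)
    assert raw_score(p, "ACDEXGHIKL") == pytest.approx(full - col_f)


def test_local_alignment_ignores_flanks():
    aln = ["ACDEFGHIKL"] * 4
    p = build_profile(aln)
    core = raw_score(p, "ACDEFGHIKL")
    flanked = raw_score(p, "WWWWACDEFGHIKLWWWW")
    assert flanked == pytest.approx(core)


def test_score_is_nonnegative():
    aln = ["ACDEFGHIKL"] * 4
    p = build_profile(aln)
    assert raw_score(p, "WWWWW") >= 0.0


def test_uncalibrated_evalue_raises():
    p = build_profile(["ACDEFGHIKL"] * 4)
    with pytest.raises(NotCalibratedError):
        score_sequence(p, "ACDEFGHIKL")
    with pytest.raises(NotCalibratedError):
        search(p, {"q": "ACDEFGHIKL"})


def test_calibration_deterministic_and_evalue_monotone(families):
    p = profile_from_family(families["recA"])
    c1 = calibrate(p, n_null=150, seed=7)
    c2 = calibrate(p, n_null=150, seed=7)
    assert c1.calibration == c2.calibration
    e_small = evalue_of(c1, 50.0)
    e_big = evalue_of(c1, 100.0)
    assert e_big < e_small


def test_calibration_degenerate_variance_raises():
    # emissions equal to background -> every alignment scores 0 bits
    bg = np.full(20, 0.05)
    p = ProfileModel("flat", np.tile(bg, (5, 1)), bg,
                     np.arange(1, 6), ref_median_len=30)
    with pytest.raises(ValueError, match="degenerate"):
        calibrate(p, n_null=50, seed=0)


def test_banded_equals_full_on_true_diagonal(families, profiles):
    p = profiles["recA"]
    for m in families["recA"].members[:10]:
        assert raw_score(p, m.protein, band=(-16, 16)) == pytest.approx(
            raw_score(p, m.protein))


def test_prefilter_finds_members(families, profiles):
    from hgscan.orf import encode_protein
    p = profiles["hgcA"]
    members = families["hgcA"].members[:20]
    enc = [encode_protein(m.protein) for m in members]
    offsets = np.zeros(len(enc) + 1, dtype=np.int64)
    for i, e in enumerate(enc):
        offsets[i + 1] = offsets[i] + e.size
    cat = np.concatenate(enc)
    cand, diags = prefilter_candidates(p, cat, offsets)
    assert set(cand.tolist()) == set(range(20))
    # ungapped members sit on the zero diagonal
    assert np.all(diags == 0)


def test_search_sorted_and_cutoff(families, profiles):
    p = profiles["recA"]
    rng = np.random.default_rng(0)
    queries = {f"m{i}": m.protein
               for i, m in enumerate(families["recA"].members[:5])}
    queries["junk"] = "".join(rng.choice(list(AMINO_ACIDS), size=350))
    hits = search(p, queries)
    ids = [h.query_id for h in hits]
    assert "junk" not in ids
    assert len(hits) == 5
    evs = [h.evalue for h in hits]
    assert evs == sorted(evs)
    for h in hits:
        assert h.evalue <= 1e-5
        assert h.aligned_len > 300


def test_hit_state_path_is_monotone(families, profiles):
    p = profiles["hgcA"]
    m = families["hgcA"].members[0]
    h = search(p, {"q": m.protein})[0]
    qs = list(h.state_path.keys())
    ss = list(h.state_path.values())
    assert qs == sorted(qs) and ss == sorted(ss)
    # an ungapped member aligns to the main diagonal almost everywhere;
    # short insert/delete excursions in low-information columns are allowed
    on_diag = sum(a == b for a, b in h.state_path.items())
    assert on_diag >= 0.95 * len(h.state_path)
    assert max(abs(a - b) for a, b in h.state_path.items()) <= 5


def test_json_round_trip(profiles):
    p = profiles["hgcA"]
    q = ProfileModel.from_json(p.to_json())
    assert q.calibration == p.calibration
    assert list(q.column_map) == list(p.column_map)
    seq = "ACDEFGHIKLMNPQRSTVWY" * 5
    assert raw_score(q, seq) == pytest.approx(raw_score(p, seq))
    anchors = {r.rule_id: (r.anchor_column, col)
               for r, col in q.motif_anchors}
    assert anchors["hgcA_cap_helix"] == (93, 90)


def test_pyhmmer_cross_check(families):
    """Independent oracle: pyhmmer trained on the same alignment must agree
    on which sequences belong to the family."""
    pyhmmer = pytest.importorskip("pyhmmer")
    fam = families["hgcB"]
    alphabet = pyhmmer.easel.Alphabet.amino()
    msa = pyhmmer.easel.TextMSA(
        name=b"hgcB",
        sequences=[pyhmmer.easel.TextSequence(name=f"m{i}".encode(),
                                              sequence=m.protein)
                   for i, m in enumerate(fam.members)])
    builder = pyhmmer.plan7.Builder(alphabet)
    hmm, _, _ = builder.build_msa(msa.digitize(alphabet),
                                  pyhmmer.plan7.Background(alphabet))
    member = fam.members[0].protein
    rng = np.random.default_rng(5)
    junk = "".join(rng.choice(list(AMINO_ACIDS), size=99))
    targets = pyhmmer.easel.TextSequenceBlock(
        [pyhmmer.easel.TextSequence(name=b"member", sequence=member),
         pyhmmer.easel.TextSequence(name=b"junk", sequence=junk)]
    ).digitize(alphabet)
    found = {hit.name if isinstance(hit.name, str) else hit.name.decode()
             for tophits in pyhmmer.hmmsearch([hmm], targets)
             for hit in tophits if hit.evalue <= 1e-5}
    assert found == {"member"}

    ours = calibrate(profile_from_family(fam), n_null=300, seed=0)
    hits = search(ours, {"member": member, "junk": junk})
    assert {h.query_id for h in hits} == {"member"}
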