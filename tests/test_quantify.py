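import numpy as np
import pytest
from scipy.stats import norm

from hgscan.profile import Hit
from hgscan.quantify import (_gene_detection, _insert_weights,
                             count_validated, default_fragment_of,
                             relative_abundance)
from hgscan.readprep import QCConfig
from hgscan.synthetic import SimulationConfig, recovery_community


def _hit(query_id, family_id, evalue, bitscore=100.0, aligned=40,
         validated=True):
    e = np.zeros(0, dtype=np.int64)
    return Hit(query_id, family_id, bitscore, evalue, 1, aligned, e, e,
               validated=validated)


def test_default_fragment_of():
    assert default_fragment_of("s1_frag7_orf3") == "s1_frag7"
    assert default_fragment_of("plain") == "plain"


def test_count_validated_dedup_rules():
    hits = [
        _hit("f1_orf1", "hgcA", 1e-30),
        _hit("f1_orf2", "hgcB", 1e-10),      # same fragment, worse E-value
        _hit("f2_orf1", "recA", 1e-20),
        _hit("f3_orf1", "hgcA", 1e-8, bitscore=60.0),
        _hit("f3_orf2", "hgcB", 1e-8, bitscore=80.0),  # tie on E: higher bits
        _hit("f4_orf1", "hgcB", 1e-8, bitscore=50.0),
        _hit("f4_orf2", "hgcA", 1e-8, bitscore=50.0),  # full tie: family id
        _hit("f5_orf1", "hgcA", 1e-40, validated=False),   # dropped
        _hit("f6_orf1", "hgcA", 1e-40, aligned=29),        # too short
    ]
    counts, assignments = count_validated(hits, min_aligned_aa=30)
    assert counts == {"hgcA": 2, "hgcB": 1, "recA": 1}
    by_frag = {a.fragment_id: a.family_id for a in assignments}
    assert by_frag == {"f1": "hgcA", "f2": "recA", "f3": "hgcB",
                       "f4": "hgcA"}
    # assignments are sorted by fragment id
    assert [a.fragment_id for a in assignments] == sorted(by_frag)


def test_relative_abundance_math_and_undefined():
    rec = relative_abundance({"recA": 200, "hgcA": 3})
    assert rec["hgcA"].rel_pct == pytest.approx(1.5)
    assert rec["hgcB"].rel_pct == pytest.approx(0.0)
    assert not rec["hgcA"].undefined
    # zero reference -> undefined, not zero
    rec0 = relative_abundance({"hgcA": 3})
    assert rec0["hgcA"].rel_pct is None
    assert rec0["hgcA"].undefined
    assert rec0["hgcA"].n_fragments == 3


def _brute_detection(gene, genome_len, insert, families, min_aligned_aa):
    """Reference implementation: error-free detection indicator per start."""
    from hgscan.quantify import _motif_spans_nt
    g0, g1 = gene.coding_span
    out = []
    for s in range(genome_len - insert + 1):
        f0, f1 = s, s + insert
        # complete in-frame codons of the gene inside the fragment
        ncod = 0
        if gene.strand == "+":
            codons = [(g0 + 3 * k, g0 + 3 * k + 3)
                      for k in range((g1 - g0) // 3)]
        else:
            codons = [(g1 - 3 * k - 3, g1 - 3 * k)
                      for k in range((g1 - g0) // 3)]
        ncod = sum(1 for a, b in codons if a >= f0 and b <= f1)
        ok = ncod >= min_aligned_aa
        for a, b, _ in _motif_spans_nt(gene, families):
            ok = ok and f0 <= a and f1 >= b
        out.append(1.0 if ok else 0.0)
    return np.array(out)


@pytest.mark.parametrize("family_id,insert", [("hgcA", 330), ("hgcB", 310),
                                              ("recA", 360)])
def test_gene_detection_matches_bruteforce(families, family_id, insert):
    comm = recovery_community(0.01, families, seed=3)
    cfg = SimulationConfig(per_base_error=0.0)
    gene = next(g for g in comm.placed_genes
                if g.family_id == family_id and g.genome_id == "carrier")
    L = len(comm.genomes["carrier"])
    got = _gene_detection(gene, L, insert, families, cfg, min_aligned_aa=30)
    want = _brute_detection(gene, L, insert, families, 30)
    assert np.array_equal(got, want)
    assert want.sum() > 0  # the case is non-trivial


def test_gene_detection_error_rate_reduces_probability(families):
    comm = recovery_community(0.01, families, seed=3)
    gene = next(g for g in comm.placed_genes if g.family_id == "hgcA")
    L = len(comm.genomes["carrier"])
    d0 = _gene_detection(gene, L, 340, families,
                         SimulationConfig(per_base_error=0.0), 30)
    d1 = _gene_detection(gene, L, 340, families,
                         SimulationConfig(per_base_error=0.01), 30)
    mask = d0 > 0
    assert np.all(d1[mask] < d0[mask])
    assert np.all(d1[~mask] == 0.0)


def test_insert_weights_match_truncated_normal():
    cfg = SimulationConfig(insert_mean_bp=350.0, insert_sd_bp=30.0)
    qc = QCConfig()
    L = 2600
    ii, w = _insert_weights(cfg, qc, L)
    assert ii[0] >= qc.min_len_bp
    assert ii[-1] == 2 * cfg.read_length_bp - qc.min_overlap_bp
    # total weight = P(window) / P(simulator support), from the normal CDF
    mu, sd = cfg.insert_mean_bp, cfg.insert_sd_bp
    num = (norm.cdf((ii[-1] + 0.5 - mu) / sd)
           - norm.cdf((ii[0] - 0.5 - mu) / sd))
    den = (norm.cdf((L + 0.5 - mu) / sd)
           - norm.cdf((cfg.insert_floor - 0.5 - mu) / sd))
    assert w.sum() == pytest.approx(num / den)
    assert np.all(w >= 0)
    # the pmf peaks at the mean insert size
    assert ii[np.argmax(w)] == pytest.approx(mu, abs=1)
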