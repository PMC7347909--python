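import numpy as np
import pytest
from Bio.Seq import Seq

from hgscan.motifs import matches_at
from hgscan.synthetic import (CommunityTruth, FamilySpec, GenePlacement,
                              HgTableSpec, SimulationConfig, back_translate,
                              default_families, default_family_specs,
                              make_community, make_hg_table, make_ko_table,
                              make_reference_family, recovery_community,
                              revcomp, simulate_reads)


def test_family_is_deterministic():
    spec = default_family_specs(seed=3)["hgcA"]
    a = make_reference_family(spec)
    b = make_reference_family(spec)
    assert [m.protein for m in a.members] == [m.protein for m in b.members]
    assert [m.lineage for m in a.members] == [m.lineage for m in b.members]


def test_members_carry_motifs_at_stated_columns(families):
    for fam in families.values():
        for rule, col in fam.motif_rules:
            for m in fam.members:
                assert matches_at(rule.pattern, m.protein, col - 1), (
                    fam.family_id, m.member_id)


def test_hgcb_has_two_motifs(families):
    cols = [col for _, col in families["hgcB"].motif_rules]
    assert len(cols) == 2
    # non-overlapping occurrences
    assert cols[1] - cols[0] >= 11


def test_member_divergence(families):
    fam = families["hgcA"]
    a = fam.members[0].protein
    b = fam.members[1].protein
    diff = sum(x != y for x, y in zip(a, b))
    assert 0 < diff / len(a) < 0.45   # diverged but clearly homologous


def test_spec_validation():
    with pytest.raises(ValueError):
        FamilySpec("f", n_members=1, length_aa=100)
    with pytest.raises(ValueError):
        FamilySpec("f", n_members=5, length_aa=100, substitution_rate=1.5)


def test_back_translate_round_trip():
    rng = np.random.default_rng(0)
    prot = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
    cds = back_translate(prot, rng)
    assert len(cds) == 3 * (len(prot) + 1)
    assert str(Seq(cds).translate(table=11)) == prot + "*"


def test_make_community_places_translatable_genes(families):
    truth = CommunityTruth(
        genomes=[("g1", 3000, 0.4), ("g2", 2000, 0.6)],
        gene_placements=[GenePlacement("g1", "hgcA", 100),
                         GenePlacement("g2", "recA", 500, strand="-")])
    comm = make_community(truth, families, seed=1)
    for gene in comm.placed_genes:
        seq = comm.genomes[gene.genome_id][gene.start_bp:gene.end_bp]
        if gene.strand == "-":
            seq = revcomp(seq)
        assert str(Seq(seq).translate(table=11)) == gene.protein + "*"


def test_community_rejects_bad_abundance(families):
    with pytest.raises(ValueError):
        CommunityTruth(genomes=[("g1", 1000, 0.7)], gene_placements=[])


def test_community_rejects_overlapping_genes(families):
    truth = CommunityTruth(
        genomes=[("g1", 3000, 1.0)],
        gene_placements=[GenePlacement("g1", "hgcA", 100),
                         GenePlacement("g1", "recA", 200)])
    with pytest.raises(ValueError, match="overlap"):
        make_community(truth, families, seed=0)


def test_expected_copy_ratio(families):
    comm = recovery_community(0.02, families, seed=0)
    assert comm.truth.expected_copy_ratio("hgcA") == pytest.approx(0.02)
    assert comm.truth.expected_copy_ratio("hgcB") == pytest.approx(0.02)


def test_simulated_reads_match_genome_when_error_free(families):
    comm = recovery_community(0.5, families, seed=0)
    cfg = SimulationConfig(n_pairs=60, per_base_error=0.0, frac_bad_reads=0.0,
                           p_low_good=0.0, seed=4)
    sim = simulate_reads(comm, cfg)
    assert len(sim.pairs) == 60
    for (pid, s1, q1, s2, q2), frag in zip(sim.pairs, sim.fragments):
        g = comm.genomes[frag.genome_id]
        ins = g[frag.start_bp:frag.start_bp + frag.insert_bp]
        if frag.flipped:
            ins = revcomp(ins)
        rl = cfg.read_length_bp
        assert s1[:min(rl, len(ins))] == ins[:rl]
        assert s2[:min(rl, len(ins))] == revcomp(ins)[:rl]
        assert len(s1) == len(q1) == rl


def test_simulated_insert_bounds(families):
    comm = recovery_community(0.5, families, seed=0)
    cfg = SimulationConfig(n_pairs=300, seed=5)
    sim = simulate_reads(comm, cfg)
    inserts = np.array([f.insert_bp for f in sim.fragments])
    assert inserts.min() >= cfg.insert_floor
    assert abs(inserts.mean() - cfg.insert_mean_bp) < 10


def test_hg_table_censoring_and_ordering():
    spec = HgTableSpec(seed=2)
    df = make_hg_table(spec)
    assert len(df) == len(spec.stations) * len(spec.depths_m)
    for _, row in df.iterrows():
        if row["mehg_pM"] != "ND":
            assert row["mehg_pM"] >= spec.mdl_mehg_pM
            if row["thg_pM"] != "ND":
                assert row["mehg_pM"] <= row["thg_pM"]
    # surface MeHg is tiny -> expect at least one ND
    assert (df["mehg_pM"] == "ND").any()


def test_ko_table_sparsity():
    dense = make_ko_table(5, ["K1", "K2"], sparsity=0.0, seed=0)
    assert (dense.to_numpy() > 0).all()
    sparse = make_ko_table(50, ["K1", "K2"], sparsity=0.9, seed=0)
    assert (sparse.to_numpy() == 0).mean() > 0.7
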