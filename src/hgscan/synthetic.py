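"""Synthetic reference families, communities, reads, and geochemistry tables.

Everything downstream of sequencing is testable against known ground truth:
reference protein families with embedded conserved motifs stand in for the
curated hgcA/hgcB/recA sets, communities place back-translated gene copies at
known coordinates and relative abundances, and the read simulator emulates a
2x250 bp paired-end library with ~350 bp inserts, substitution errors, and a
two-state per-base quality model.  Hg chemistry tables carry depth-structured
THg/MeHg profiles with below-detection censoring ("ND").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .motifs import MotifRule, CAP_HELIX_RULE, FERREDOXIN_RULE, AMINO_ACIDS

# Robinson & Robinson amino-acid background frequencies (order = AMINO_ACIDS)
BACKGROUND_FREQS = np.array([
    0.0787, 0.0169, 0.0535, 0.0629, 0.0407, 0.0695, 0.0229, 0.0590,
    0.0595, 0.0963, 0.0224, 0.0414, 0.0484, 0.0340, 0.0512, 0.0682,
    0.0585, 0.0673, 0.0110, 0.0304,
])
BACKGROUND_FREQS = BACKGROUND_FREQS / BACKGROUND_FREQS.sum()

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_CODONS_FOR_AA: dict[str, list[str]] = {}
for _codon, _aa in _TABLE11.forward_table.items():
    _CODONS_FOR_AA.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_FOR_AA:
    _CODONS_FOR_AA[_aa].sort()
STOP_CODONS = tuple(sorted(_TABLE11.stop_codons))


def revcomp(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def back_translate(protein: str, rng: np.random.Generator,
                   add_stop: bool = True) -> str:
    """Back-translate with uniform synonymous codon choice (seeded)."""
    codons = []
    for aa in protein:
        options = _CODONS_FOR_AA[aa]
        codons.append(options[rng.integers(len(options))])
    if add_stop:
        codons.append(STOP_CODONS[rng.integers(len(STOP_CODONS))])
    return "".join(codons)


# ---------------------------------------------------------------------------
# reference families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilySpec:
    """Recipe for one synthetic aligned protein family."""

    family_id: str
    n_members: int
    length_aa: int
    substitution_rate: float = 0.1
    #: (rule, 1-based start column) pairs to embed; realizations are drawn
    #: once and shared by all members, so motif columns are identical
    motif_rules: tuple[tuple[MotifRule, int], ...] = ()
    conserved_positions: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_members < 2:
            raise ValueError("a family needs at least 2 members")
        if self.length_aa < 1:
            raise ValueError("length_aa must be >= 1")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must be in [0, 1]")
        for rule, col in self.motif_rules:
            if col < 1 or col + rule.span - 1 > self.length_aa:
                raise ValueError(
                    f"motif {rule.rule_id!r} at column {col} exceeds family "
                    f"length {self.length_aa}"
                )
        if self.motif_rules:
            longest = max(r.span for r, _ in self.motif_rules)
            if self.length_aa < longest + 1:
                raise ValueError("length_aa must exceed the longest motif span")


@dataclass
class FamilyMember:
    member_id: str
    protein: str
    lineage: str


@dataclass
class ReferenceFamily:
    """A gap-free synthetic reference alignment plus its motif anchors."""

    family_id: str
    members: list[FamilyMember]
    motif_rules: tuple[tuple[MotifRule, int], ...] = ()

    @property
    def aligned_length(self) -> int:
        return len(self.members[0].protein)

    @property
    def alignment(self) -> list[str]:
        return [m.protein for m in self.members]

    def __len__(self) -> int:
        return len(self.members)


_LINEAGES = (
    "Nitrospina-like", "Deltaproteobacteria-like", "Firmicutes-like",
    "Spirochaetes-like", "Dehalococcoidia-like", "Methanomicrobia-like",
)


def make_reference_family(spec: FamilySpec) -> ReferenceFamily:
    """Generate an aligned family from a seeded ancestor.

    Motif realizations and conserved positions are never mutated, so every
    member carries each embedded motif at its specified columns.  With
    substitution_rate 0 all members are identical to the ancestor.
    """
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(AMINO_ACIDS))
    ancestor = aa[rng.choice(20, size=spec.length_aa, p=BACKGROUND_FREQS)]

    protected = np.zeros(spec.length_aa, dtype=bool)
    from .motifs import sample_realization
    for rule, col in spec.motif_rules:
        realization = sample_realization(rule.pattern, rng)
        for k, res in enumerate(realization):
            ancestor[col - 1 + k] = res
            protected[col - 1 + k] = True
    for col in spec.conserved_positions:
        protected[col - 1] = True

    members = []
    for i in range(spec.n_members):
        seq = ancestor.copy()
        mutate = (rng.random(spec.length_aa) < spec.substitution_rate) & ~protected
        for pos in np.flatnonzero(mutate):
            choices = [c for c in AMINO_ACIDS if c != seq[pos]]
            seq[pos] = choices[rng.integers(19)]
        members.append(FamilyMember(
            member_id=f"{spec.family_id}_ref{i:03d}",
            protein="".join(seq),
            lineage=_LINEAGES[i % len(_LINEAGES)],
        ))
    return ReferenceFamily(spec.family_id, members, spec.motif_rules)


def default_family_specs(seed: int = 0) -> dict[str, FamilySpec]:
    """Canonical study families: 145 hgcA (349 aa, cap helix anchored at
    column 93), 128 hgcB (99 aa, two ferredoxin motifs), a recA family
    (350 aa, PF00154-style, no motif rule) and a motif-free decoy paralog."""
    return {
        "hgcA": FamilySpec(
            "hgcA", n_members=145, length_aa=349,
            motif_rules=((CAP_HELIX_RULE, 90),), seed=seed * 4 + 1,
        ),
        "hgcB": FamilySpec(
            "hgcB", n_members=128, length_aa=99,
            motif_rules=((FERREDOXIN_RULE, 60), (FERREDOXIN_RULE, 75)),
            seed=seed * 4 + 2,
        ),
        "recA": FamilySpec("recA", n_members=60, length_aa=350,
                           seed=seed * 4 + 3),
        "decoy": FamilySpec("decoy", n_members=80, length_aa=330,
                            seed=seed * 4 + 4),
    }


def default_families(seed: int = 0) -> dict[str, ReferenceFamily]:
    return {k: make_reference_family(s)
            for k, s in default_family_specs(seed).items()}


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenePlacement:
    genome_id: str
    family_id: str
    start_bp: int            # 0-based
    strand: str = "+"        # '+' or '-'
    copy_number: int = 1


@dataclass
class CommunityTruth:
    """Ground truth for a synthetic community.

    ``genomes`` is a list of (genome_id, genome_length_bp, relative_abundance)
    and gene placements carry 0-based start coordinates.
    """

    genomes: list[tuple[str, int, float]]
    gene_placements: list[GenePlacement]

    def __post_init__(self):
        total = sum(a for _, _, a in self.genomes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"relative abundances sum to {total}, not 1")
        ids = {g for g, _, _ in self.genomes}
        for p in self.gene_placements:
            if p.genome_id not in ids:
                raise ValueError(f"placement on unknown genome {p.genome_id}")
            if p.strand not in "+-":
                raise ValueError(f"bad strand {p.strand!r}")

    def expected_copy_ratio(self, family_id: str,
                            reference: str = "recA") -> float:
        """Abundance-weighted copy ratio family:reference (a fraction)."""
        abund = {g: a for g, _, a in self.genomes}
        num = sum(abund[p.genome_id] * p.copy_number
                  for p in self.gene_placements if p.family_id == family_id)
        den = sum(abund[p.genome_id] * p.copy_number
                  for p in self.gene_placements if p.family_id == reference)
        if den == 0:
            raise ValueError(f"no {reference} placements in truth")
        return num / den


@dataclass
class PlacedGene:
    genome_id: str
    family_id: str
    member_id: str
    start_bp: int
    end_bp: int              # exclusive; includes the stop codon
    strand: str
    protein: str

    @property
    def coding_span(self) -> tuple[int, int]:
        """Genome interval of the coding region (stop codon excluded),
        0-based half-open, in genome coordinates."""
        if self.strand == "+":
            return self.start_bp, self.end_bp - 3
        return self.start_bp + 3, self.end_bp


@dataclass
class Community:
    truth: CommunityTruth
    genomes: dict[str, str]
    placed_genes: list[PlacedGene]


def make_community(truth: CommunityTruth,
                   families: dict[str, ReferenceFamily],
                   seed: int = 0) -> Community:
    """Materialize genome sequences with genes at the stated coordinates.

    Each placement draws one family member (seeded) and inserts its uniform
    back-translation (plus stop codon); translating the placed interval under
    table 11 reproduces the member protein.
    """
    rng = np.random.default_rng(seed)
    genomes: dict[str, list[str]] = {}
    lengths = {}
    for gid, glen, _ in truth.genomes:
        genomes[gid] = list(random_dna(glen, rng))
        lengths[gid] = glen

    placed: list[PlacedGene] = []
    occupied: dict[str, list[tuple[int, int]]] = {gid: [] for gid in genomes}
    for p in truth.gene_placements:
        fam = families[p.family_id]
        start = p.start_bp
        for copy in range(p.copy_number):
            member = fam.members[rng.integers(len(fam.members))]
            cds = back_translate(member.protein, rng)
            end = start + len(cds)
            if end > lengths[p.genome_id]:
                raise ValueError(
                    f"{p.family_id} placement at {start} exceeds genome "
                    f"{p.genome_id} length {lengths[p.genome_id]}"
                )
            for a, b in occupied[p.genome_id]:
                if start < b and a < end:
                    raise ValueError(
                        f"overlapping gene placements on {p.genome_id}"
                    )
            occupied[p.genome_id].append((start, end))
            insert = cds if p.strand == "+" else revcomp(cds)
            genomes[p.genome_id][start:end] = list(insert)
            placed.append(PlacedGene(p.genome_id, p.family_id,
                                     member.member_id, start, end, p.strand,
                                     member.protein))
            start = end + 30  # spacer between extra copies

    return Community(truth, {g: "".join(s) for g, s in genomes.items()}, placed)


def recovery_community(ratio: float,
                       families: dict[str, ReferenceFamily],
                       seed: int = 0) -> Community:
    """Two-genome community with a known hgcA:recA copy ratio.

    A 'carrier' genome holds hgcA, hgcB and recA; a 'host' genome holds recA
    only.  Carrier relative abundance = ``ratio`` (a fraction), so the
    abundance-weighted hgcA:recA copy ratio equals ``ratio``.
    """
    truth = CommunityTruth(
        genomes=[("carrier", 2600, ratio), ("host", 1300, 1.0 - ratio)],
        gene_placements=[
            GenePlacement("carrier", "recA", 25),
            GenePlacement("carrier", "hgcB", 1110),
            GenePlacement("carrier", "hgcA", 1440),
            GenePlacement("host", "recA", 120),
        ],
    )
    return make_community(truth, families, seed=seed)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Paired-end library model: 2x250 bp reads, ~350 bp inserts."""

    n_pairs: int = 10000
    read_length_bp: int = 250
    insert_mean_bp: float = 350.0
    insert_sd_bp: float = 30.0
    per_base_error: float = 0.001
    adapter_seq: str = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
    seed: int = 0
    #: lower truncation of the fragment-length distribution; defaults to the
    #: read length (no read-through); set lower to exercise adapter trimming
    min_insert_bp: int | None = None
    # two-state quality model: a small fraction of degraded reads gives the
    # mean-Q >= 20 filter real work
    q_high: int = 38
    q_low: int = 12
    p_low_good: float = 0.03
    p_low_bad: float = 0.7
    frac_bad_reads: float = 0.05

    def __post_init__(self):
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if not self.adapter_seq:
            raise ValueError("adapter_seq must be nonempty")

    @property
    def insert_floor(self) -> int:
        return (self.read_length_bp if self.min_insert_bp is None
                else self.min_insert_bp)


@dataclass
class FragmentTruth:
    pair_id: str
    genome_id: str
    start_bp: int
    insert_bp: int
    flipped: bool  # R1 read from the genome minus strand


@dataclass
class SimulatedReads:
    """Paired reads plus per-fragment ground-truth coordinates."""

    pairs: list[tuple[str, str, str, str, str]]  # (id, seq1, qual1, seq2, qual2)
    fragments: list[FragmentTruth]


_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_IDX = np.zeros(256, dtype=np.uint8)
for _i, _a in enumerate(b"ACGT"):
    _BASE_IDX[_a] = _i


def sample_inserts(n: int, rng: np.random.Generator,
                   cfg: SimulationConfig, max_bp: int) -> np.ndarray:
    """Truncated-normal insert sizes (lower bound = read length by default)."""
    lo = min(cfg.insert_floor, max_bp)
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = rng.normal(cfg.insert_mean_bp, cfg.insert_sd_bp,
                          size=2 * (n - filled) + 16).round().astype(np.int64)
        ok = draw[(draw >= lo) & (draw <= max_bp)]
        take = min(ok.size, n - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def _error_positions(rng: np.random.Generator, n_reads: int, rl: int,
                     p: float) -> list[np.ndarray]:
    """Per-read substitution-error positions, drawn in one block."""
    if p <= 0:
        return [np.empty(0, dtype=np.int64)] * n_reads
    rows, cols = np.nonzero(rng.random((n_reads, rl)) < p)
    bounds = np.searchsorted(rows, np.arange(n_reads + 1))
    return [cols[bounds[i]:bounds[i + 1]] for i in range(n_reads)]


def simulate_reads(community: Community, cfg: SimulationConfig) -> SimulatedReads:
    """Simulate a paired-end run over a community.

    Fragments are drawn from genomes proportional to relative abundance x
    genome length; R2 is the reverse-complement strand; adapter read-through
    is appended when the fragment is shorter than the read length.
    Deterministic for a fixed seed.
    """
    if not community.genomes:
        raise ValueError("empty genome set")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_pairs
    rl = cfg.read_length_bp
    gids = [g for g, _, _ in community.truth.genomes]
    lens = np.array([l for _, l, _ in community.truth.genomes], dtype=np.int64)
    abund = np.array([a for _, _, a in community.truth.genomes], dtype=float)
    w = abund * lens
    w = w / w.sum()
    genome_arr = [np.frombuffer(community.genomes[g].encode(), dtype=np.uint8)
                  for g in gids]
    adapter = np.frombuffer(cfg.adapter_seq.encode(), dtype=np.uint8)

    choice = rng.choice(len(gids), size=n, p=w)
    inserts = np.empty(n, dtype=np.int64)
    for gi in range(len(gids)):
        mask = choice == gi
        if mask.any():
            inserts[mask] = sample_inserts(int(mask.sum()), rng, cfg,
                                           max_bp=int(lens[gi]))
    starts = rng.integers(0, lens[choice] - inserts + 1)
    flipped = rng.random(n) < 0.5
    bad = rng.random(n) < cfg.frac_bad_reads

    err1 = _error_positions(rng, n, rl, cfg.per_base_error)
    err2 = _error_positions(rng, n, rl, cfg.per_base_error)
    # quality matrices (two-state model), one block per mate
    p_low = np.where(bad, cfg.p_low_bad, cfg.p_low_good)
    qm1 = np.where(rng.random((n, rl)) < p_low[:, None],
                   cfg.q_low, cfg.q_high).astype(np.uint8) + 33
    qm2 = np.where(rng.random((n, rl)) < p_low[:, None],
                   cfg.q_low, cfg.q_high).astype(np.uint8) + 33

    def _substitute(r: np.ndarray, pos: np.ndarray) -> None:
        pos = pos[pos < r.size]
        if pos.size:
            sh = rng.integers(1, 4, size=pos.size)
            r[pos] = _BASES[(_BASE_IDX[r[pos]] + sh) % 4]

    pairs = []
    fragments = []
    for i in range(n):
        garr = genome_arr[choice[i]]
        ins = int(inserts[i])
        start = int(starts[i])
        frag = garr[start:start + ins]
        if flipped[i]:
            frag = _COMP[frag][::-1]

        def _read(template: np.ndarray, err: np.ndarray) -> np.ndarray:
            if template.size >= rl:
                r = template[:rl].copy()
            else:
                fill = np.resize(adapter, rl - template.size)
                r = np.concatenate([template, fill])
            _substitute(r, err)
            return r

        r1 = _read(frag, err1[i])
        r2 = _read(_COMP[frag][::-1], err2[i])
        pid = f"frag{i:07d}"
        pairs.append((pid, r1.tobytes().decode(), qm1[i].tobytes().decode(),
                      r2.tobytes().decode(), qm2[i].tobytes().decode()))
        fragments.append(FragmentTruth(pid, gids[choice[i]], start, ins,
                                       bool(flipped[i])))
    return SimulatedReads(pairs, fragments)


# ---------------------------------------------------------------------------
# geochemistry and KO tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HgTableSpec:
    """Generative model for depth-structured THg/MeHg profiles.

    MeHg rises linearly with depth (slope in pM per m); THg is a baseline
    plus the MeHg signal, which guarantees MeHg <= THg at every depth.
    Values below the method detection limit are emitted as "ND".
    """

    stations: tuple[str, ...] = ("St0", "St1")
    depths_m: tuple[float, ...] = (0, 100, 200, 500, 800)
    thg_base_pM: float = 0.4
    mehg_slope_per_m: float = 0.00075
    noise_sd_pM: float = 0.02
    mdl_thg_pM: float = 0.25
    mdl_mehg_pM: float = 0.007
    seed: int = 0

    def __post_init__(self):
        if not self.depths_m:
            raise ValueError("depths_m must be nonempty")
        if self.mdl_thg_pM < 0 or self.mdl_mehg_pM < 0:
            raise ValueError("detection limits must be nonnegative")


ND = "ND"


def make_hg_table(spec: HgTableSpec) -> pd.DataFrame:
    """Station/depth THg and MeHg table with "ND" censoring below the MDL."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for st in spec.stations:
        for d in spec.depths_m:
            mehg = max(0.0, spec.mehg_slope_per_m * d
                       + rng.normal(0, spec.noise_sd_pM))
            thg = spec.thg_base_pM + mehg + abs(rng.normal(0, spec.noise_sd_pM))
            rows.append({
                "station": st,
                "depth_m": float(d),
                "thg_pM": ND if thg < spec.mdl_thg_pM else round(thg, 4),
                "mehg_pM": ND if mehg < spec.mdl_mehg_pM else round(mehg, 4),
            })
    return pd.DataFrame(rows)


def make_ko_table(n_samples: int, ko_ids: list[str], sparsity: float,
                  seed: int = 0, mean_count: float = 200.0) -> pd.DataFrame:
    """Nonnegative integer KO x sample abundance table.

    ``sparsity`` is the probability that a cell is a structural zero; with
    sparsity 0 every count is strictly positive.
    """
    if not ko_ids:
        raise ValueError("ko_ids must be nonempty")
    rng = np.random.default_rng(seed)
    cols = [f"S{i + 1}" for i in range(n_samples)]
    zero = rng.random((len(ko_ids), n_samples)) < sparsity
    counts = 1 + rng.poisson(mean_count, size=(len(ko_ids), n_samples))
    counts[zero] = 0
    return pd.DataFrame(counts, index=pd.Index(ko_ids, name="ko"), columns=cols)
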