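"""Marker-gene counting and single-copy-gene normalization.

Counting is fragment-level: each sequenced fragment contributes at most one
count, assigned to the family of its lowest-E-value validated hit, and only
when the hit aligns at least ``min_aligned_aa`` residues (30 by default).
Marker abundance is then expressed relative to the single-copy housekeeping
gene recA: rel = 100 x n_family / n_recA (percent of cells carrying the
marker).  With zero recA fragments the ratio is undefined and reported as
such — never as zero abundance.

``recovery_report`` compares observed ratios on simulated libraries against
an analytic oracle that integrates the detection geometry exactly: for every
insert length in the QC-retained window and every fragment start position it
checks whether the fragment contains >= min_aligned_aa complete in-frame
codons of the gene and fully covers the required motif span(s), weighting by
the discretized truncated-normal insert distribution.  Sequencing errors
enter through a first-order motif-survival factor; quality-based read
dropout is independent of genomic position, so it cancels in ratios.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy.stats import norm

from .motifs import AMINO_ACIDS, parse_pattern
from .profile import Hit
from .readprep import QCConfig
from .synthetic import Community, PlacedGene, SimulationConfig

_ORF_SUFFIX = re.compile(r"_orf\d+$")


def default_fragment_of(query_id: str) -> str:
    """Map an ORF id (``<fragment>_orf<k>``) back to its fragment id."""
    return _ORF_SUFFIX.sub("", query_id)


@dataclass
class FragmentAssignment:
    fragment_id: str
    family_id: str
    evalue: float
    bitscore: float


def count_validated(hits: Iterable[Hit],
                    min_aligned_aa: int = 30,
                    fragment_of: Callable[[str], str] = default_fragment_of,
                    ) -> tuple[dict[str, int], list[FragmentAssignment]]:
    """Fragment-level marker counts from validated hits.

    Rules, in order: drop non-validated hits and hits aligning fewer than
    ``min_aligned_aa`` residues; collapse multiple hits from the same
    fragment (including hits to different families) to the single hit with
    the lowest E-value (ties broken by higher bit score, then family id).
    Returns (counts per family, per-fragment assignments).
    """
    best: dict[str, Hit] = {}
    for h in hits:
        if not h.validated or h.aligned_len < min_aligned_aa:
            continue
        frag = fragment_of(h.query_id)
        cur = best.get(frag)
        if cur is None or (h.evalue, -h.bitscore, h.family_id) < (
                cur.evalue, -cur.bitscore, cur.family_id):
            best[frag] = h
    counts: dict[str, int] = {}
    assignments = []
    for frag in sorted(best):
        h = best[frag]
        counts[h.family_id] = counts.get(h.family_id, 0) + 1
        assignments.append(FragmentAssignment(frag, h.family_id, h.evalue,
                                              h.bitscore))
    return counts, assignments


@dataclass
class AbundanceRecord:
    family_id: str
    n_fragments: int
    reference_id: str
    n_reference: int
    rel_pct: float | None        # None when the reference count is zero

    @property
    def undefined(self) -> bool:
        return self.rel_pct is None


def relative_abundance(counts: dict[str, int],
                       families: Iterable[str] = ("hgcA", "hgcB"),
                       reference: str = "recA") -> dict[str, AbundanceRecord]:
    """Percent of cells carrying each marker, via single-copy normalization.

    rel = 100 x n_family / n_reference.  A zero reference count makes the
    ratio undefined (``rel_pct`` is None): no information is not the same as
    zero abundance.
    """
    n_ref = counts.get(reference, 0)
    out = {}
    for fam in families:
        n = counts.get(fam, 0)
        rel = (100.0 * n / n_ref) if n_ref > 0 else None
        out[fam] = AbundanceRecord(fam, n, reference, n_ref, rel)
    return out


# ---------------------------------------------------------------------------
# analytic recovery oracle
# ---------------------------------------------------------------------------

def _constrained_residues(pattern: str) -> list[int]:
    """Pattern offsets whose token restricts the residue (non-'x')."""
    return [k for k, tok in enumerate(parse_pattern(pattern))
            if tok != AMINO_ACIDS]


def _motif_spans_nt(gene: PlacedGene, families) -> list[tuple[int, int, list[int]]]:
    """(nt_start, nt_end, constrained_nt_positions) per motif of the gene,
    in genome coordinates."""
    fam = families[gene.family_id]
    g0, g1 = gene.coding_span
    spans = []
    for rule, col in fam.motif_rules:
        r0 = col - 1
        r1 = r0 + rule.span
        if gene.strand == "+":
            a, b = g0 + 3 * r0, g0 + 3 * r1
        else:
            a, b = g1 - 3 * r1, g1 - 3 * r0
        constrained = []
        for off in _constrained_residues(rule.pattern):
            r = r0 + off
            if gene.strand == "+":
                c0 = g0 + 3 * r
            else:
                c0 = g1 - 3 * (r + 1)
            constrained.extend((c0, c0 + 1, c0 + 2))
        spans.append((a, b, constrained))
    return spans


def _gene_detection(gene: PlacedGene, genome_len: int, insert: int,
                    families, cfg: SimulationConfig,
                    min_aligned_aa: int) -> np.ndarray:
    """Per-start detection probability for one gene at one insert length.

    Index s runs over fragment starts 0..L-insert; the value combines the
    exact coverage geometry (complete in-frame codons, motif spans) with the
    first-order motif-survival factor under the per-base error rate.
    """
    L = genome_len
    ns = L - insert + 1
    if ns <= 0:
        return np.zeros(0)
    s = np.arange(ns)
    g0, g1 = gene.coding_span
    if gene.strand == "+":
        lo = np.maximum(s, g0) - g0
        hi = np.minimum(s + insert, g1) - g0
    else:
        # mirror: residue k occupies [g1-3k-3, g1-3k)
        lo = g1 - np.minimum(s + insert, g1)
        hi = g1 - np.maximum(s, g0)
    ncod = np.maximum(0, hi // 3 - (lo + 2) // 3)
    ok = ncod >= min_aligned_aa

    e = cfg.per_base_error
    rl = cfg.read_length_bp
    surv = np.ones(ns)
    for a, b, constrained in _motif_spans_nt(gene, families):
        ok &= (s <= a) & (s + insert >= b)
        if e > 0 and constrained:
            # overlap region of the two mates within the fragment
            pos = np.array(constrained)
            off = pos[None, :] - s[:, None]
            dbl = (off >= insert - rl) & (off < rl)
            n_dbl = dbl.sum(axis=1)
            n_sgl = len(constrained) - n_dbl
            # a double-covered error makes the consensus 'N' (rate ~2e);
            # a single-covered error substitutes, ~3/4 non-synonymous
            surv = surv * (1 - 2 * e) ** n_dbl * (1 - 0.75 * e) ** n_sgl
    return ok * surv


def _insert_weights(cfg: SimulationConfig, qc: QCConfig, genome_len: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Discretized truncated-normal insert pmf, restricted to the merge/QC
    window [min_len, 2 x read_length - min_overlap]."""
    lo = min(cfg.insert_floor, genome_len)
    hi = min(genome_len, 2 * cfg.read_length_bp - qc.min_overlap_bp)
    lo_eff = max(lo, qc.min_len_bp)
    if hi < lo_eff:
        return np.empty(0, dtype=np.int64), np.empty(0)
    ii = np.arange(lo_eff, hi + 1)
    mu, sd = cfg.insert_mean_bp, cfg.insert_sd_bp
    pmf = norm.cdf((ii + 0.5 - mu) / sd) - norm.cdf((ii - 0.5 - mu) / sd)
    # normalization of the simulator's rejection sampler (full support)
    z = norm.cdf((genome_len + 0.5 - mu) / sd) - norm.cdf((lo - 0.5 - mu) / sd)
    return ii, pmf / z


def expected_family_rates(community: Community, cfg: SimulationConfig,
                          qc: QCConfig, families,
                          min_aligned_aa: int = 30) -> dict[str, float]:
    """Expected counted fragments per simulated pair, by family.

    Ignores the position-independent quality dropout (a common factor across
    families) and error-induced premature stops (sub-percent, also common).
    """
    lens = {g: l for g, l, _ in community.truth.genomes}
    abund = {g: a for g, _, a in community.truth.genomes}
    w = {g: abund[g] * lens[g] for g in lens}
    ztot = sum(w.values())

    by_genome: dict[str, list[PlacedGene]] = {}
    for gene in community.placed_genes:
        by_genome.setdefault(gene.genome_id, []).append(gene)

    fam_ids = sorted({g.family_id for g in community.placed_genes})
    rates = {f: 0.0 for f in fam_ids}
    for gid, genes in by_genome.items():
        L = lens[gid]
        ii, pmf = _insert_weights(cfg, qc, L)
        for fam in fam_ids:
            fam_genes = [g for g in genes if g.family_id == fam]
            if not fam_genes:
                continue
            r = 0.0
            for insert, p in zip(ii, pmf):
                miss = None
                for gene in fam_genes:
                    d = _gene_detection(gene, L, int(insert), families, cfg,
                                        min_aligned_aa)
                    miss = (1.0 - d) if miss is None else miss * (1.0 - d)
                r += p * float(np.mean(1.0 - miss))
            rates[fam] += (w[gid] / ztot) * r
    return rates


def recovery_report(community: Community, cfg: SimulationConfig,
                    qc: QCConfig, observed_counts: dict[str, int],
                    families, reference: str = "recA",
                    min_aligned_aa: int = 30) -> pd.DataFrame:
    """Observed vs expected recovery, per family and as recA-relative ratios.

    ``expected_count`` scales the analytic rate by the number of simulated
    pairs and so sits above the observation by the (common) quality-dropout
    factor; the ``*_ratio_pct`` columns are the meaningful comparison.
    """
    rates = expected_family_rates(community, cfg, qc, families,
                                  min_aligned_aa=min_aligned_aa)
    ref_rate = rates.get(reference, 0.0)
    n_ref = observed_counts.get(reference, 0)
    rows = []
    for fam in sorted(rates):
        n_obs = observed_counts.get(fam, 0)
        exp_ratio = (100.0 * rates[fam] / ref_rate) if ref_rate > 0 else None
        obs_ratio = (100.0 * n_obs / n_ref) if n_ref > 0 else None
        rel_err = (obs_ratio / exp_ratio - 1.0
                   if exp_ratio not in (None, 0.0) and obs_ratio is not None
                   else None)
        rows.append({
            "family_id": fam,
            "expected_rate": rates[fam],
            "expected_count": rates[fam] * cfg.n_pairs,
            "observed_count": n_obs,
            "expected_ratio_pct": exp_ratio,
            "observed_ratio_pct": obs_ratio,
            "ratio_rel_error": rel_err,
        })
    return pd.DataFrame(rows)
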