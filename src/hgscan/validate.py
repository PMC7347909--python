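"""Motif-based validation of marker hits and lineage assignment.

Profile hits are only counted as marker genes when the catalytic motif is
confirmed on the hit itself: for hgcA the conserved cap-helix cysteine must
be the residue aligned to reference column 93 and sit inside an intact
cap-helix motif window; for hgcB at least two non-overlapping ferredoxin
C-x(2)-C-x(2)-C-x(3)-C motifs must be present.  Fragments whose alignment
does not reach the motif region are rejected with an explicit reason rather
than silently dropped.

Length/gap plausibility rules (hgcA >= 175 aa, hgcB >= 50 aa, gap fraction
<= 0.5) apply to assembled or full-length sequences ahead of phylogenetic
placement; they are deliberately not part of read-level counting, where
fragments are expected to be short.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .motifs import (MotifRule, CAP_HELIX_RULE, FERREDOXIN_RULE,
                     count_occurrences, matches_at, pattern_regex)
from .profile import Hit, ProfileModel


def validate_hgca(hit: Hit, protein: str, profile: ProfileModel,
                  rule: MotifRule = CAP_HELIX_RULE) -> Hit:
    """Confirm the anchored cap-helix Cys on an hgcA hit (mutates the hit).

    The residue aligned to the anchor column must be Cys and the pattern
    window around it (anchor offset positions upstream) must match the
    cap-helix motif on the query.
    """
    if rule.anchor_column is None:
        raise ValueError("hgcA validation needs an anchored rule")
    state = profile.match_state_for_column(rule.anchor_column)
    if state is None:
        raise ValueError(
            f"anchor column {rule.anchor_column} is not a match state of "
            f"profile {profile.family_id!r}")
    target = state + 1  # state_path is 1-based
    qpos = None
    for qp, st in hit.state_path.items():
        if st == target:
            qpos = qp
            break
    if qpos is None:
        hit.validated = False
        hit.reason = "motif region not covered"
        return hit
    if protein[qpos - 1] != "C":
        hit.validated = False
        hit.reason = f"anchored residue is {protein[qpos - 1]!r}, not Cys"
        return hit
    win_start = (qpos - 1) - rule.cys_offset
    if win_start < 0 or win_start + rule.span > len(protein):
        hit.validated = False
        hit.reason = "motif window truncated by fragment edge"
        return hit
    if not matches_at(rule.pattern, protein, win_start):
        hit.validated = False
        hit.reason = "cap-helix motif mismatch"
        return hit
    hit.validated = True
    hit.reason = ""
    return hit


def validate_hgcb(hit: Hit, protein: str,
                  rule: MotifRule = FERREDOXIN_RULE) -> Hit:
    """Require >= ``rule.min_occurrences`` non-overlapping ferredoxin motifs."""
    n = count_occurrences(rule.pattern, protein)
    if n >= rule.min_occurrences:
        hit.validated = True
        hit.reason = ""
    else:
        hit.validated = False
        hit.reason = (f"found {n} ferredoxin motif(s), "
                      f"need {rule.min_occurrences}")
    return hit


def validate_hit(hit: Hit, protein: str, profile: ProfileModel) -> Hit:
    """Dispatch validation by family; non-marker families pass through as
    validated (no motif requirement)."""
    if hit.family_id == "hgcA":
        return validate_hgca(hit, protein, profile)
    if hit.family_id == "hgcB":
        return validate_hgcb(hit, protein)
    hit.validated = True
    return hit


@dataclass(frozen=True)
class LengthRule:
    family_id: str
    min_len_aa: int
    max_gap_frac: float = 0.5

    def __post_init__(self):
        if self.min_len_aa < 1:
            raise ValueError("min_len_aa must be >= 1")
        if not 0.0 <= self.max_gap_frac <= 1.0:
            raise ValueError("max_gap_frac must be in [0, 1]")


DEFAULT_LENGTH_RULES = {
    "hgcA": LengthRule("hgcA", 175),
    "hgcB": LengthRule("hgcB", 50),
}


def apply_length_rules(sequence: str, family_id: str,
                       rules: dict[str, LengthRule] | None = None) -> bool:
    """Length/gap plausibility screen for assembled marker sequences.

    ``sequence`` may contain '-' gaps (e.g. an aligned sequence); the rule
    requires >= min_len_aa residues and gap fraction <= max_gap_frac.
    Unknown families raise (screening against a rule that does not exist is
    a caller error, not a pass).
    """
    rules = DEFAULT_LENGTH_RULES if rules is None else rules
    if family_id not in rules:
        raise KeyError(f"no length rule for family {family_id!r}")
    rule = rules[family_id]
    if not sequence:
        return False
    n_gap = sequence.count("-")
    n_res = len(sequence) - n_gap
    return (n_res >= rule.min_len_aa
            and n_gap / len(sequence) <= rule.max_gap_frac)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


def assign_lineage(protein: str, family) -> tuple[str, float]:
    """Nearest-reference lineage label by global pairwise identity.

    Returns (lineage, percent identity over alignment columns).  Ties on
    identity go to the lexicographically smallest member id.
    """
    if not protein:
        raise ValueError("empty query protein")
    aligner = _make_aligner()
    best = None  # (neg identity not needed; compare tuples)
    for member in family.members:
        aln = aligner.align(protein, member.protein)[0]
        counts = aln.counts()
        ident = 100.0 * counts.identities / aln.length
        key = (-ident, member.member_id)
        if best is None or key < best[0]:
            best = (key, member.lineage, ident)
    return best[1], best[2]
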