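"""Conserved-motif rules for marker-gene validation.

HgcA carries a catalytically required cysteine in its "cap helix" (reference
alignment position 93); HgcB is a small ferredoxin with two strictly conserved
C-x(2)-C-x(2)-C-x(3)-C metal-binding motifs.  Both are expressed here as
fixed-length patterns over the amino-acid alphabet in a small notation:

* an upper-case letter is a literal residue,
* ``x`` matches any residue,
* ``[..]`` matches any residue in the bracketed set.

The same pattern object drives three things: embedding concrete motif
realizations into synthetic reference families, scanning candidate proteins,
and anchoring a specific pattern position to a reference alignment column.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: default cap-helix pattern; the anchored Cys is pattern offset 3, mapped to
#: reference column 93 of the hgcA alignment
CAP_HELIX_PATTERN = "N[VI]WCA[AG]GK"
#: ferredoxin metal-binding motif of hgcB
FERREDOXIN_PATTERN = "CxxCxxCxxxC"


def parse_pattern(pattern: str) -> list[str]:
    """Tokenize a motif pattern into per-position alternatives.

    Returns one string of allowed residues per pattern position.
    """
    if not pattern:
        raise ValueError("motif pattern must be nonempty")
    tokens: list[str] = []
    i = 0
    while i < len(pattern):
        c = pattern[i]
        if c == "[":
            j = pattern.index("]", i)
            choices = pattern[i + 1 : j]
            if not choices:
                raise ValueError(f"empty residue set in pattern {pattern!r}")
            bad = [ch for ch in choices if ch not in AMINO_ACIDS]
            if bad:
                raise ValueError(
                    f"invalid residue(s) {bad} in set of pattern {pattern!r}")
            tokens.append(choices)
            i = j + 1
        elif c == "x":
            tokens.append(AMINO_ACIDS)
            i += 1
        elif c in AMINO_ACIDS:
            tokens.append(c)
            i += 1
        else:
            raise ValueError(f"invalid pattern character {c!r} in {pattern!r}")
    return tokens


def pattern_span(pattern: str) -> int:
    """Number of residues a pattern covers."""
    return len(parse_pattern(pattern))


def pattern_regex(pattern: str) -> re.Pattern:
    parts = []
    for tok in parse_pattern(pattern):
        if len(tok) == 1:
            parts.append(tok)
        elif tok == AMINO_ACIDS:
            parts.append(".")
        else:
            parts.append(f"[{tok}]")
    return re.compile("".join(parts))


def sample_realization(pattern: str, rng) -> str:
    """Draw one concrete sequence matching the pattern (seeded)."""
    return "".join(tok[rng.integers(len(tok))] for tok in parse_pattern(pattern))


def count_occurrences(pattern: str, protein: str) -> int:
    """Non-overlapping occurrences, scanning left to right."""
    return sum(1 for _ in pattern_regex(pattern).finditer(protein))


def matches_at(pattern: str, protein: str, start: int) -> bool:
    """Whether the pattern matches ``protein`` at 0-based offset ``start``."""
    if start < 0 or start + pattern_span(pattern) > len(protein):
        return False
    return pattern_regex(pattern).match(protein, start) is not None


@dataclass(frozen=True)
class MotifRule:
    """A motif requirement attached to a marker family.

    ``anchor_column`` is the 1-based reference-alignment column that the
    anchored residue (pattern offset ``anchor_offset``) must align to; it is
    None for purely occurrence-counted motifs such as the hgcB ferredoxin
    pattern.  When ``anchor_offset`` is None it defaults to the first literal
    Cys in the pattern.
    """

    rule_id: str
    pattern: str
    min_occurrences: int = 1
    anchor_column: int | None = None
    anchor_offset: int | None = None

    def __post_init__(self):
        parse_pattern(self.pattern)  # validates
        if self.min_occurrences < 1:
            raise ValueError("min_occurrences must be >= 1")

    @property
    def span(self) -> int:
        return pattern_span(self.pattern)

    @property
    def cys_offset(self) -> int:
        """Pattern offset of the anchored residue."""
        if self.anchor_offset is not None:
            return self.anchor_offset
        for k, tok in enumerate(parse_pattern(self.pattern)):
            if tok == "C":
                return k
        raise ValueError(
            f"rule {self.rule_id!r} has no literal Cys and no anchor_offset"
        )


CAP_HELIX_RULE = MotifRule(
    rule_id="hgcA_cap_helix",
    pattern=CAP_HELIX_PATTERN,
    min_occurrences=1,
    anchor_column=93,
)

FERREDOXIN_RULE = MotifRule(
    rule_id="hgcB_ferredoxin",
    pattern=FERREDOXIN_PATTERN,
    min_occurrences=2,
)
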