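"""Pathway-module completion and abundance summaries over KO count tables.

A module is a list of components; each component is satisfied when any of
its KEGG-ortholog (KO) alternatives has a nonzero count in the sample.  The
module completion ratio (MCR) is the percentage of satisfied components,
reported as an integer (half-up rounding).  The reductive acetyl-CoA
(Wood-Ljungdahl) pathway used as the anaerobe indicator ships as a packaged
fixture: ten single-KO components with their observed counts across the
nineteen water-column samples.

Module *abundance* sums member-KO counts and is normalized against the
summed ribosomal-protein counts of the same sample; profiles across samples
are standardized to mean 0 / SD 1 for heatmap-style comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

_TABLE2_RESOURCE = "table2_acetyl_coa_ko.tsv"


@dataclass(frozen=True)
class ModuleDefinition:
    """A pathway module as an ordered tuple of components, each component an
    ordered tuple of alternative KO ids (any nonzero alternative satisfies
    the component)."""

    module_id: str
    components: tuple[tuple[str, ...], ...]

    def __post_init__(self):
        if not self.components:
            raise ValueError("module must have at least one component")
        for comp in self.components:
            if not comp:
                raise ValueError("empty component in module definition")

    @property
    def ko_ids(self) -> tuple[str, ...]:
        return tuple(k for comp in self.components for k in comp)


@dataclass
class ModuleResult:
    module_id: str
    sample_id: str
    n_components: int
    n_satisfied: int
    mcr_pct: int


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def mcr(module: ModuleDefinition, ko_counts: dict[str, int] | pd.Series,
        sample_id: str = "sample") -> ModuleResult:
    """Module completion ratio for one sample.

    ``ko_counts`` must cover every KO the module references — a missing KO
    is a data error, not a zero.  A component is satisfied when any of its
    KO alternatives has count > 0.
    """
    if isinstance(ko_counts, pd.Series):
        ko_counts = ko_counts.to_dict()
    missing = [k for k in module.ko_ids if k not in ko_counts]
    if missing:
        raise KeyError(
            f"sample {sample_id!r} lacks counts for KO(s) {missing}")
    for k in module.ko_ids:
        if ko_counts[k] < 0:
            raise ValueError(f"negative count for {k}")
    sat = sum(1 for comp in module.components
              if any(ko_counts[k] > 0 for k in comp))
    n = len(module.components)
    return ModuleResult(module.module_id, sample_id, n, sat,
                        _round_half_up(100.0 * sat / n))


def mcr_profile(module: ModuleDefinition, table: pd.DataFrame) -> pd.Series:
    """MCR per sample for a KO-indexed count table (samples as columns)."""
    return pd.Series(
        {c: mcr(module, table[c], sample_id=c).mcr_pct for c in table.columns},
        name=f"{module.module_id}_mcr_pct")


def module_abundance(module: ModuleDefinition,
                     ko_counts: dict[str, int] | pd.Series,
                     ribosomal_total: int,
                     sample_id: str = "sample") -> float | None:
    """Summed module-KO counts normalized by the ribosomal-protein total.

    Returns None (undefined) when the ribosomal total is zero.
    """
    if isinstance(ko_counts, pd.Series):
        ko_counts = ko_counts.to_dict()
    missing = [k for k in module.ko_ids if k not in ko_counts]
    if missing:
        raise KeyError(
            f"sample {sample_id!r} lacks counts for KO(s) {missing}")
    if ribosomal_total < 0:
        raise ValueError("ribosomal_total must be >= 0")
    if ribosomal_total == 0:
        return None
    total = sum(ko_counts[k] for k in module.ko_ids)
    return total / ribosomal_total


def standardize(profiles: pd.DataFrame) -> pd.DataFrame:
    """Row-standardize module-by-sample abundances to mean 0, SD 1
    (population SD).  Constant rows become all zeros, with a warning."""
    values = profiles.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    flat = sd[:, 0] < 1e-12
    if flat.any():
        warnings.warn(
            f"constant module profile(s) standardized to zeros: "
            f"{list(profiles.index[flat])}", stacklevel=2)
    sd[flat] = 1.0
    out = (values - mean) / sd
    out[flat] = 0.0
    return pd.DataFrame(out, index=profiles.index, columns=profiles.columns)


def load_acetyl_coa_table() -> pd.DataFrame:
    """Packaged acetyl-CoA pathway KO counts: rows = KO ids, columns = the
    nineteen station/depth samples."""
    ref = resources.files("hgscan").joinpath(f"data/{_TABLE2_RESOURCE}")
    with ref.open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col="ko_id")
    return df.drop(columns=["definition"])


def acetyl_coa_module() -> ModuleDefinition:
    """The reductive acetyl-CoA pathway as ten single-KO components, in
    fixture row order."""
    table = load_acetyl_coa_table()
    return ModuleDefinition(
        module_id="acetyl_coa_pathway",
        components=tuple((k,) for k in table.index),
    )
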