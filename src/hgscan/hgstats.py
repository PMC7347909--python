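"""Mercury-species statistics: unit conversion, ND censoring, and rank
correlation with small-sample exact p-values.

Field tables report total mercury (THg) and methylmercury (MeHg) in mass
concentration (pg/L); comparisons are done in molar units (pM, via the Hg
molar mass 200.59 g/mol).  Values below the method detection limit are
reported as "ND" and treated as zeros for correlation — a deliberate,
documented censoring convention rather than sample dropping.

Correlation is Spearman's rho on mid-ranks.  With fewer than ten pairs the
two-sided p-value comes from the exact permutation null (all n! orderings);
from ten pairs on, from the usual t approximation with n-2 degrees of
freedom.  Constant inputs make rho undefined and are reported as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import ND

HG_MOLAR_MASS_G_PER_MOL = 200.59

#: exact-permutation p-values below this sample size, t approximation at or
#: above it
EXACT_P_MAX_N = 10


def mass_to_molar(value_pg_per_l: float) -> float:
    """pg/L -> pM using the Hg molar mass (200.59 pg/pmol)."""
    if value_pg_per_l < 0:
        raise ValueError("mass concentration must be >= 0")
    return value_pg_per_l / HG_MOLAR_MASS_G_PER_MOL


def censor(values) -> np.ndarray:
    """Replace "ND" (below detection limit) entries with 0.0.

    Accepts a sequence of floats and/or "ND" strings; idempotent (already
    censored numeric input passes through unchanged).
    """
    out = np.empty(len(values), dtype=float)
    for i, v in enumerate(values):
        if isinstance(v, str):
            if v != ND:
                raise ValueError(f"unexpected non-numeric value {v!r}")
            out[i] = 0.0
        else:
            if not np.isfinite(v):
                raise ValueError("non-finite measurement")
            out[i] = float(v)
    return out


@dataclass
class CorrelationResult:
    rho: float | None
    p_value: float | None
    n: int
    method: str

    @property
    def defined(self) -> bool:
        return self.rho is not None


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx * rx).sum() * (ry * ry).sum()))
    return float((rx * ry).sum()) / denom


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with exact small-sample p-values.

    Two-sided p; exact over all n! permutations for n < 10 (ties handled via
    mid-ranks), t approximation otherwise.  Constant x or y -> undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(None, None, n, "undefined-constant-input")
    rx = _midranks(x)
    ry = _midranks(y)
    rho = _rho_of_ranks(rx, ry)
    if n < EXACT_P_MAX_N:
        perms = np.array(list(permutations(range(n))), dtype=np.intp)
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt(float((rxc * rxc).sum() * (ryc * ryc).sum()))
        null = (rxc[perms] * ryc[None, :]).sum(axis=1) / denom
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
        return CorrelationResult(rho, p, n, "exact-permutation")
    t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return CorrelationResult(rho, min(1.0, p), n, "t-approximation")


def correlate_profiles(abundance: pd.DataFrame, hg_table: pd.DataFrame,
                       families=("hgcA", "hgcB"),
                       deep_min_depth_m: float = 200.0,
                       deep_stations=None) -> pd.DataFrame:
    """Marker abundance vs mercury species across stations and depths.

    ``abundance`` needs columns station, depth_m and one column per family
    (recA-relative percent); ``hg_table`` needs station, depth_m, thg_pM,
    mehg_pM (possibly "ND").  Rows are produced for each family x
    {THg, MeHg, MeHg:THg} x {all samples, a "deep" subset}; the deep subset
    is all samples at depth >= ``deep_min_depth_m``, or — when
    ``deep_stations`` is given — all samples of the named (deep-water)
    stations.  Subsets with fewer than 3 joined rows are flagged
    insufficient instead of correlated.
    """
    joined = abundance.merge(hg_table, on=["station", "depth_m"], how="inner")
    thg = censor(list(joined["thg_pM"]))
    mehg = censor(list(joined["mehg_pM"]))
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(thg > 0, mehg / np.where(thg > 0, thg, 1.0), 0.0)
    predictors = {"thg_pM": thg, "mehg_pM": mehg, "mehg_to_thg": frac}
    if deep_stations is not None:
        deep = joined["station"].isin(set(deep_stations)).to_numpy()
    else:
        deep = joined["depth_m"].to_numpy(dtype=float) >= deep_min_depth_m
    subsets = {"all": np.ones(len(joined), dtype=bool), "deep": deep}

    rows = []
    for fam in families:
        a = joined[fam].to_numpy(dtype=float)
        for pname, pvals in predictors.items():
            for sname, mask in subsets.items():
                n = int(mask.sum())
                if n < 3:
                    rows.append({"family_id": fam, "predictor": pname,
                                 "subset": sname, "n": n, "rho": None,
                                 "p_value": None, "method": "insufficient-n"})
                    continue
                res = spearman(a[mask], pvals[mask])
                rows.append({"family_id": fam, "predictor": pname,
                             "subset": sname, "n": res.n, "rho": res.rho,
                             "p_value": res.p_value, "method": res.method})
    return pd.DataFrame(rows)
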