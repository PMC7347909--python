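"""Profile models for marker-protein families and calibrated local search.

A :class:`ProfileModel` is a position-specific description of a protein
family built from a multiple alignment: columns with at most 50% gaps become
match states with pseudocount-smoothed emission probabilities; scoring is a
local Viterbi log-odds alignment (bits) with affine insert/delete penalties
derived from fixed transition probabilities.  Statistical significance uses a
Gumbel law fitted by maximum likelihood to the scores of random background
sequences, giving per-target E-values E = exp(-(S - mu)/beta), scaled by the
number of target sequences searched.

``search`` accelerates large inputs hmmsearch-style: a seeded 6-mer prefilter
proposes a diagonal, and the Viterbi pass is banded around it.  The unbanded
dynamic program (``score_sequence`` with ``band=None``) is the reference
scoring path and is what calibration uses.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy import stats

from .motifs import MotifRule, AMINO_ACIDS
from .orf import AA_TO_IDX, X_IDX, encode_protein

NEG = -1.0e30

#: fixed transition probabilities (match->insert, insert->insert,
#: match->delete, delete->delete, match->match)
DEFAULT_TRANSITIONS = {
    "p_mi": 0.05, "p_ii": 0.4, "p_md": 0.05, "p_dd": 0.4, "p_mm": 0.9,
}


def _gap_penalties(t: dict) -> tuple[float, float, float, float]:
    go_i = math.log2(t["p_mi"] / t["p_mm"])
    ge_i = math.log2(t["p_ii"] / t["p_mm"])
    go_d = math.log2(t["p_md"] / t["p_mm"])
    ge_d = math.log2(t["p_dd"] / t["p_mm"])
    return go_i, ge_i, go_d, ge_d


class NotCalibratedError(RuntimeError):
    pass


@dataclass
class ProfileModel:
    family_id: str
    match_emissions: np.ndarray          # (M, 20)
    background_freqs: np.ndarray         # (20,)
    column_map: np.ndarray               # (M,) 1-based alignment columns
    motif_anchors: tuple[tuple[MotifRule, int], ...] = ()
    transition_params: dict = field(default_factory=lambda: dict(DEFAULT_TRANSITIONS))
    ref_median_len: int = 0
    calibration: tuple[float, float] | None = None   # Gumbel (mu, beta)
    #: residues of the reference members at match columns, for the k-mer seed
    _match_seqs: list[np.ndarray] | None = None
    _emit_lo: np.ndarray | None = None
    _kmer_keys: np.ndarray | None = None
    _kmer_states: np.ndarray | None = None

    @property
    def n_match_states(self) -> int:
        return self.match_emissions.shape[0]

    def __post_init__(self):
        e = np.asarray(self.match_emissions, dtype=np.float64)
        if not np.allclose(e.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("emission vectors must each sum to 1")
        bg = np.asarray(self.background_freqs, dtype=np.float64)
        if abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")
        cm = np.asarray(self.column_map)
        if not (np.diff(cm) > 0).all():
            raise ValueError("column_map must be strictly increasing")
        cols = set(cm.tolist())
        for rule, col in self.motif_anchors:
            anchor = col + (rule.cys_offset if rule.anchor_column else 0)
            if rule.anchor_column is not None and rule.anchor_column not in cols:
                raise ValueError(
                    f"motif anchor column {rule.anchor_column} is not a match state"
                )

    @property
    def emit_lo(self) -> np.ndarray:
        """(M, 21) log2 odds; the X column scores 0 (background-neutral)."""
        if self._emit_lo is None:
            lo = np.log2(self.match_emissions / self.background_freqs[None, :])
            self._emit_lo = np.concatenate(
                [lo, np.zeros((lo.shape[0], 1))], axis=1)
        return self._emit_lo

    def match_state_for_column(self, column: int) -> int | None:
        """0-based match-state index for a 1-based alignment column."""
        hits = np.flatnonzero(self.column_map == column)
        return int(hits[0]) if hits.size else None

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "family_id": self.family_id,
            "match_emissions": self.match_emissions.tolist(),
            "background_freqs": self.background_freqs.tolist(),
            "column_map": np.asarray(self.column_map).tolist(),
            "transition_params": self.transition_params,
            "ref_median_len": self.ref_median_len,
            "calibration": list(self.calibration) if self.calibration else None,
            "motif_anchors": [
                {"rule_id": r.rule_id, "pattern": r.pattern,
                 "min_occurrences": r.min_occurrences,
                 "anchor_column": r.anchor_column,
                 "anchor_offset": r.anchor_offset, "start_column": col}
                for r, col in self.motif_anchors
            ],
        })

    @classmethod
    def from_json(cls, text: str) -> "ProfileModel":
        d = json.loads(text)
        anchors = tuple(
            (MotifRule(a["rule_id"], a["pattern"], a["min_occurrences"],
                       a["anchor_column"], a["anchor_offset"]),
             a["start_column"])
            for a in d["motif_anchors"]
        )
        return cls(
            family_id=d["family_id"],
            match_emissions=np.array(d["match_emissions"]),
            background_freqs=np.array(d["background_freqs"]),
            column_map=np.array(d["column_map"], dtype=np.int64),
            motif_anchors=anchors,
            transition_params=d["transition_params"],
            ref_median_len=d["ref_median_len"],
            calibration=tuple(d["calibration"]) if d["calibration"] else None,
        )


def build_profile(alignment: list[str], family_id: str = "family",
                  pseudocount_weight: float = 1.0,
                  max_col_gap_frac: float = 0.5,
                  motif_anchors: tuple[tuple[MotifRule, int], ...] = (),
                  ) -> ProfileModel:
    """Build a profile from an aligned family ('-' gaps).

    Columns with gap fraction <= ``max_col_gap_frac`` become match states;
    emissions are (observed count + pseudocount_weight x background) /
    (n_non_gap + pseudocount_weight) with the background pooled over the
    whole alignment (one pooled pseudo-observation per residue keeps the
    background strictly positive).
    """
    if len(alignment) < 2:
        raise ValueError("need at least 2 aligned sequences")
    L = len(alignment[0])
    if any(len(s) != L for s in alignment):
        raise ValueError("aligned sequences must have equal length")
    n = len(alignment)

    counts = np.zeros((L, 20))
    for seq in alignment:
        for c, aa in enumerate(seq):
            if aa == "-":
                continue
            idx = AA_TO_IDX.get(aa)
            if idx is None or idx == X_IDX:
                continue
            counts[c, idx] += 1
    pooled = counts.sum(axis=0) + 1.0
    background = pooled / pooled.sum()

    gap_frac = 1.0 - counts.sum(axis=1) / n
    match_cols = np.flatnonzero(gap_frac <= max_col_gap_frac)
    if match_cols.size == 0:
        raise ValueError("alignment has zero match columns")

    non_gap = counts[match_cols].sum(axis=1, keepdims=True)
    emissions = ((counts[match_cols] + pseudocount_weight * background[None, :])
                 / (non_gap + pseudocount_weight))

    col_is_match = np.zeros(L, dtype=bool)
    col_is_match[match_cols] = True
    match_seqs = []
    for seq in alignment:
        states = []
        res = []
        for st, c in enumerate(match_cols):
            aa = seq[c]
            if aa != "-" and aa in AA_TO_IDX and aa != "X":
                states.append(st)
                res.append(AA_TO_IDX[aa])
        match_seqs.append(np.array(list(zip(states, res)), dtype=np.int64)
                          if res else np.empty((0, 2), dtype=np.int64))

    lens = sorted(sum(1 for aa in s if aa != "-") for s in alignment)
    median_len = lens[len(lens) // 2]

    return ProfileModel(
        family_id=family_id,
        match_emissions=emissions,
        background_freqs=background,
        column_map=match_cols + 1,
        motif_anchors=tuple(motif_anchors),
        ref_median_len=median_len,
        _match_seqs=match_seqs,
    )


def profile_from_family(family, pseudocount_weight: float = 1.0) -> ProfileModel:
    """Build a profile directly from a synthetic ReferenceFamily."""
    return build_profile(family.alignment, family_id=family.family_id,
                         pseudocount_weight=pseudocount_weight,
                         motif_anchors=tuple(family.motif_rules))


# ---------------------------------------------------------------------------
# Viterbi kernels
# ---------------------------------------------------------------------------

# Both kernels use band-relative storage: cell (i, j) lives at column
# c = j - i - dlo + 1 of a (L+1, W+2) array with W = dhi - dlo + 1, so the
# sentinel columns 0 and W+1 stay at NEG.  Moving to (i-1, j-1) keeps c;
# (i-1, j) is c+1; (i, j-1) is c-1.

@njit(cache=True)
def _viterbi_score(q, emit_lo, go_i, ge_i, go_d, ge_d, dlo, dhi):
    """Best local alignment score (bits); band restricts j - i to [dlo, dhi]."""
    L = q.size
    M = emit_lo.shape[0]
    if dlo < 1 - L:
        dlo = 1 - L
    if dhi > M - 1 + L:
        dhi = M - 1 + L
    W = dhi - dlo + 1
    if W < 1:
        return 0.0
    prevM = np.full(W + 2, NEG)
    prevI = np.full(W + 2, NEG)
    prevD = np.full(W + 2, NEG)
    curM = np.full(W + 2, NEG)
    curI = np.full(W + 2, NEG)
    curD = np.full(W + 2, NEG)
    best = 0.0
    for i in range(1, L + 1):
        jmin = i + dlo
        if jmin < 1:
            jmin = 1
        jmax = i + dhi
        if jmax > M:
            jmax = M
        cmin = jmin - i - dlo + 1
        cmax = jmax - i - dlo + 1
        for c in range(W + 2):
            curM[c] = NEG
            curI[c] = NEG
            curD[c] = NEG
        qi = q[i - 1]
        for c in range(cmin, cmax + 1):
            j = c + i + dlo - 1
            prev_best = 0.0
            if prevM[c] > prev_best:
                prev_best = prevM[c]
            if prevI[c] > prev_best:
                prev_best = prevI[c]
            if prevD[c] > prev_best:
                prev_best = prevD[c]
            m = emit_lo[j - 1, qi] + prev_best
            curM[c] = m
            if m > best:
                best = m
            vi = prevM[c + 1] + go_i
            vi2 = prevI[c + 1] + ge_i
            if vi2 > vi:
                vi = vi2
            curI[c] = vi
            vd = curM[c - 1] + go_d
            vd2 = curD[c - 1] + ge_d
            if vd2 > vd:
                vd = vd2
            curD[c] = vd
        tmp = prevM
        prevM = curM
        curM = tmp
        tmp = prevI
        prevI = curI
        curI = tmp
        tmp = prevD
        prevD = curD
        curD = tmp
    return best


@njit(cache=True)
def _viterbi_align(q, emit_lo, go_i, ge_i, go_d, ge_d, dlo, dhi,
                   path_q, path_s):
    """Local Viterbi with traceback.

    Returns (score, qstart, qend, n_path); path arrays receive the
    (query position, match state) pairs (1-based) of aligned match states.
    """
    L = q.size
    M = emit_lo.shape[0]
    if dlo < 1 - L:
        dlo = 1 - L
    if dhi > M - 1 + L:
        dhi = M - 1 + L
    W = dhi - dlo + 1
    if W < 1:
        return 0.0, 0, 0, 0
    Mm = np.full((L + 1, W + 2), NEG)
    Im = np.full((L + 1, W + 2), NEG)
    Dm = np.full((L + 1, W + 2), NEG)
    # pointers: M: 0=open,1=M,2=I,3=D ; I: 0=fromM,1=fromI ; D: 0=fromM,1=fromD
    Mp = np.zeros((L + 1, W + 2), dtype=np.uint8)
    Ip = np.zeros((L + 1, W + 2), dtype=np.uint8)
    Dp = np.zeros((L + 1, W + 2), dtype=np.uint8)
    best = 0.0
    bi = 0
    bc = 0
    for i in range(1, L + 1):
        jmin = i + dlo
        if jmin < 1:
            jmin = 1
        jmax = i + dhi
        if jmax > M:
            jmax = M
        cmin = jmin - i - dlo + 1
        cmax = jmax - i - dlo + 1
        qi = q[i - 1]
        for c in range(cmin, cmax + 1):
            j = c + i + dlo - 1
            pb = 0.0
            ptr = 0
            if Mm[i - 1, c] > pb:
                pb = Mm[i - 1, c]
                ptr = 1
            if Im[i - 1, c] > pb:
                pb = Im[i - 1, c]
                ptr = 2
            if Dm[i - 1, c] > pb:
                pb = Dm[i - 1, c]
                ptr = 3
            m = emit_lo[j - 1, qi] + pb
            Mm[i, c] = m
            Mp[i, c] = ptr
            if m > best:
                best = m
                bi = i
                bc = c
            vi = Mm[i - 1, c + 1] + go_i
            pi = 0
            if Im[i - 1, c + 1] + ge_i > vi:
                vi = Im[i - 1, c + 1] + ge_i
                pi = 1
            Im[i, c] = vi
            Ip[i, c] = pi
            vd = Mm[i, c - 1] + go_d
            pd = 0
            if Dm[i, c - 1] + ge_d > vd:
                vd = Dm[i, c - 1] + ge_d
                pd = 1
            Dm[i, c] = vd
            Dp[i, c] = pd
    # traceback
    n_path = 0
    if best <= 0.0:
        return 0.0, 0, 0, 0
    i = bi
    c = bc
    qend = bi
    qstart = bi
    state = 0  # 0=M, 1=I, 2=D
    while True:
        if state == 0:
            path_q[n_path] = i
            path_s[n_path] = c + i + dlo - 1
            n_path += 1
            qstart = i
            ptr = Mp[i, c]
            i -= 1
            if ptr == 0:
                break
            state = 0 if ptr == 1 else (1 if ptr == 2 else 2)
        elif state == 1:
            qstart = i
            ptr = Ip[i, c]
            i -= 1
            c += 1
            state = 0 if ptr == 0 else 1
        else:
            ptr = Dp[i, c]
            c -= 1
            state = 0 if ptr == 0 else 2
    # path was collected backwards
    for k in range(n_path // 2):
        t = path_q[k]
        path_q[k] = path_q[n_path - 1 - k]
        path_q[n_path - 1 - k] = t
        t = path_s[k]
        path_s[k] = path_s[n_path - 1 - k]
        path_s[n_path - 1 - k] = t
    return best, qstart, qend, n_path


_FULL_BAND = (-(1 << 30), 1 << 30)


def raw_score(profile: ProfileModel, protein, band: tuple[int, int] | None = None
              ) -> float:
    """Local Viterbi bit score without significance (no calibration needed)."""
    q = encode_protein(protein) if isinstance(protein, str) else np.asarray(protein, dtype=np.uint8)
    if q.size < 1:
        raise ValueError("protein must have length >= 1")
    go_i, ge_i, go_d, ge_d = _gap_penalties(profile.transition_params)
    dlo, dhi = band if band is not None else _FULL_BAND
    return float(_viterbi_score(q, profile.emit_lo, go_i, ge_i, go_d, ge_d,
                                dlo, dhi))


def evalue_of(profile: ProfileModel, score: float, n_targets: int = 1) -> float:
    if profile.calibration is None:
        raise NotCalibratedError(
            f"profile {profile.family_id!r} has no Gumbel calibration; "
            "run calibrate() first")
    mu, beta = profile.calibration
    return float(n_targets * math.exp(-(score - mu) / beta))


def score_sequence(profile: ProfileModel, protein,
                   n_targets: int = 1,
                   band: tuple[int, int] | None = None) -> tuple[float, float]:
    """(bit score, E-value) of a protein against a calibrated profile."""
    s = raw_score(profile, protein, band=band)
    return s, evalue_of(profile, s, n_targets)


def calibrate(profile: ProfileModel, n_null: int = 1000, seed: int = 0,
              null_len: int | None = None) -> ProfileModel:
    """Fit the Gumbel null law from scores of random background sequences.

    Null sequences are drawn i.i.d. from the profile background with length
    equal to the median reference length; the fit is maximum likelihood.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    L = null_len or max(profile.ref_median_len, profile.n_match_states, 10)
    go_i, ge_i, go_d, ge_d = _gap_penalties(profile.transition_params)
    scores = np.empty(n_null)
    dlo, dhi = _FULL_BAND
    for i in range(n_null):
        q = rng.choice(20, size=L, p=profile.background_freqs).astype(np.uint8)
        scores[i] = _viterbi_score(q, profile.emit_lo, go_i, ge_i, go_d, ge_d,
                                   dlo, dhi)
    if np.std(scores) < 1e-9:
        raise ValueError("degenerate null score variance; cannot calibrate")
    mu, beta = stats.gumbel_r.fit(scores)
    out = replace(profile, calibration=(float(mu), float(beta)))
    out._match_seqs = profile._match_seqs
    out._emit_lo = profile._emit_lo
    out._kmer_keys = profile._kmer_keys
    out._kmer_states = profile._kmer_states
    return out


# ---------------------------------------------------------------------------
# seeded search
# ---------------------------------------------------------------------------

KMER_K = 6
_POW21 = (21 ** np.arange(KMER_K - 1, -1, -1)).astype(np.int64)


def _profile_kmers(profile: ProfileModel) -> tuple[np.ndarray, np.ndarray]:
    """Sorted unique 6-mer keys of the reference members at match states,
    with the match-state position of (the first occurrence of) each key."""
    if profile._kmer_keys is not None:
        return profile._kmer_keys, profile._kmer_states
    if profile._match_seqs is None:
        raise ValueError("profile lacks reference k-mer index "
                         "(build it with build_profile)")
    keys = []
    states = []
    for ms in profile._match_seqs:
        st = ms[:, 0]
        res = ms[:, 1]
        # require k consecutive match states for a seed k-mer
        for t in range(res.size - KMER_K + 1):
            if st[t + KMER_K - 1] - st[t] != KMER_K - 1:
                continue
            keys.append(int((res[t:t + KMER_K] * _POW21).sum()))
            states.append(int(st[t]))
    if not keys:
        karr = np.empty(0, dtype=np.int64)
        sarr = np.empty(0, dtype=np.int64)
    else:
        karr = np.array(keys, dtype=np.int64)
        sarr = np.array(states, dtype=np.int64)
        order = np.argsort(karr, kind="stable")
        karr = karr[order]
        sarr = sarr[order]
        uniq = np.ones(karr.size, dtype=bool)
        uniq[1:] = karr[1:] != karr[:-1]
        karr = karr[uniq]
        sarr = sarr[uniq]
    profile._kmer_keys = karr
    profile._kmer_states = sarr
    return karr, sarr


@njit(cache=True)
def _window_keys_kernel(cat, pow21, k):
    n = cat.size - k + 1
    keys = np.empty(n, dtype=np.int64)
    for i in range(n):
        v = np.int64(0)
        for t in range(k):
            v += np.int64(cat[i + t]) * pow21[t]
        keys[i] = v
    return keys


def _window_keys(cat: np.ndarray) -> np.ndarray:
    if cat.size < KMER_K:
        return np.empty(0, dtype=np.int64)
    return _window_keys_kernel(cat, _POW21, KMER_K)


def precompute_windows(cat: np.ndarray, offsets: np.ndarray):
    """Shared per-sample window data reused across family prefilters."""
    keys = _window_keys(cat)
    pos = np.arange(keys.size)
    # windows crossing protein boundaries are invalid
    owner = np.repeat(np.arange(offsets.size - 1),
                      np.diff(offsets))[:keys.size]
    valid = pos + KMER_K <= offsets[owner + 1]
    return keys, pos, owner, valid


def prefilter_candidates(profile: ProfileModel, cat: np.ndarray,
                         offsets: np.ndarray, min_seed_hits: int = 2,
                         windows=None) -> tuple[np.ndarray, np.ndarray]:
    """Seeded 6-mer prefilter over concatenated encoded proteins.

    Returns (candidate protein indices, their seed diagonals).  A protein is
    a candidate when at least ``min_seed_hits`` reference 6-mers occur in it;
    the diagonal is the modal (query_pos - match_state) offset of the seeds.
    """
    kkeys, kstates = _profile_kmers(profile)
    nprot = offsets.size - 1
    if kkeys.size == 0 or cat.size < KMER_K:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    keys, pos, owner, valid = (windows if windows is not None
                               else precompute_windows(cat, offsets))
    idx = np.searchsorted(kkeys, keys)
    idx[idx == kkeys.size] = 0
    matched = (kkeys[idx] == keys) & valid
    mpos = pos[matched]
    mowner = owner[matched]
    mstate = kstates[idx[matched]]
    diag = (mpos - offsets[mowner]) - mstate
    counts = np.bincount(mowner, minlength=nprot)
    cand = np.flatnonzero(counts >= min_seed_hits)
    bounds = np.searchsorted(mowner, cand)
    bounds_hi = np.searchsorted(mowner, cand, side="right")
    diags = _modal_diags(diag, bounds, bounds_hi)
    return cand, diags


@njit(cache=True)
def _modal_diags(diag, bounds, bounds_hi):
    """Most frequent seed diagonal per candidate (seed hits are grouped)."""
    out = np.zeros(bounds.size, dtype=np.int64)
    for k in range(bounds.size):
        d = np.sort(diag[bounds[k]:bounds_hi[k]])
        best_v = d[0]
        best_n = 1
        run_v = d[0]
        run_n = 1
        for t in range(1, d.size):
            if d[t] == run_v:
                run_n += 1
            else:
                run_v = d[t]
                run_n = 1
            if run_n > best_n:
                best_n = run_n
                best_v = run_v
        out[k] = best_v
    return out


@dataclass
class Hit:
    query_id: str
    family_id: str
    bitscore: float
    evalue: float
    qstart: int                 # 1-based inclusive on the query protein
    qend: int
    path_q: np.ndarray          # 1-based query positions of match states
    path_s: np.ndarray          # corresponding 1-based match states
    validated: bool = False
    lineage: str | None = None
    reason: str = ""

    @property
    def aligned_len(self) -> int:
        return self.qend - self.qstart + 1

    @property
    def state_path(self) -> dict:
        """1-based query position -> 1-based match state."""
        return {int(a): int(b) for a, b in zip(self.path_q, self.path_s)}


def align_candidate(profile: ProfileModel, q: np.ndarray,
                    band: tuple[int, int] | None = None
                    ) -> tuple[float, int, int, np.ndarray, np.ndarray]:
    """Score with traceback; returns (score, qstart, qend, path_q, path_s)."""
    go_i, ge_i, go_d, ge_d = _gap_penalties(profile.transition_params)
    dlo, dhi = band if band is not None else _FULL_BAND
    cap = q.size + 2
    path_q = np.zeros(cap, dtype=np.int64)
    path_s = np.zeros(cap, dtype=np.int64)
    score, qstart, qend, n = _viterbi_align(
        q, profile.emit_lo, go_i, ge_i, go_d, ge_d, dlo, dhi, path_q, path_s)
    return (float(score), int(qstart), int(qend),
            path_q[:n].copy(), path_s[:n].copy())


@njit(cache=True)
def _align_batch(cat, offsets, cand, diags, use_band, band, emit_lo,
                 go_i, ge_i, go_d, ge_d,
                 scores, qstarts, qends, path_len, path_q_buf, path_s_buf):
    """Banded align every candidate; paths are packed back to back."""
    cur = 0
    for k in range(cand.size):
        i = cand[k]
        a = offsets[i]
        b = offsets[i + 1]
        if b == a:
            path_len[k] = 0
            continue
        if use_band:
            d = -diags[k]
            dlo = d - band
            dhi = d + band
        else:
            dlo = -(1 << 30)
            dhi = 1 << 30
        s, qs, qe, n = _viterbi_align(cat[a:b], emit_lo, go_i, ge_i, go_d,
                                      ge_d, dlo, dhi,
                                      path_q_buf[cur:cur + (b - a) + 2],
                                      path_s_buf[cur:cur + (b - a) + 2])
        scores[k] = s
        qstarts[k] = qs
        qends[k] = qe
        path_len[k] = n
        cur += n
    return cur


def search_encoded(profile: ProfileModel, cat: np.ndarray,
                   offsets: np.ndarray, ids: list[str],
                   evalue_cutoff: float = 1e-5,
                   prefilter: bool = True, band: int = 16,
                   n_targets: int | None = None,
                   windows=None) -> list[Hit]:
    """Search concatenated encoded proteins; hits sorted by E-value, ties by
    query id."""
    if profile.calibration is None:
        raise NotCalibratedError(
            f"profile {profile.family_id!r} must be calibrated before search")
    nprot = offsets.size - 1
    n_targets = nprot if n_targets is None else n_targets
    if prefilter:
        cand, diags = prefilter_candidates(profile, cat, offsets,
                                           windows=windows)
        use_band = True
    else:
        cand = np.arange(nprot, dtype=np.int64)
        diags = np.zeros(nprot, dtype=np.int64)
        use_band = False
    if cand.size == 0:
        return []
    go_i, ge_i, go_d, ge_d = _gap_penalties(profile.transition_params)
    # diag = qpos - state (0-based); the DP band on (j - i) with 1-based
    # indices is centered at -diag
    scores = np.zeros(cand.size)
    qstarts = np.zeros(cand.size, dtype=np.int64)
    qends = np.zeros(cand.size, dtype=np.int64)
    path_len = np.zeros(cand.size, dtype=np.int64)
    pcap = int((offsets[cand + 1] - offsets[cand]).sum()) + 2 * cand.size
    path_q_buf = np.zeros(pcap, dtype=np.int64)
    path_s_buf = np.zeros(pcap, dtype=np.int64)
    _align_batch(cat, np.ascontiguousarray(offsets, dtype=np.int64),
                 np.ascontiguousarray(cand, dtype=np.int64),
                 np.ascontiguousarray(diags, dtype=np.int64),
                 use_band, band, profile.emit_lo,
                 go_i, ge_i, go_d, ge_d, scores, qstarts, qends, path_len,
                 path_q_buf, path_s_buf)
    mu, beta = profile.calibration
    with np.errstate(over="ignore"):
        evalues = n_targets * np.exp(-(scores - mu) / beta)
    path_off = np.zeros(cand.size + 1, dtype=np.int64)
    np.cumsum(path_len, out=path_off[1:])
    hits: list[Hit] = []
    for k in np.flatnonzero(evalues <= evalue_cutoff):
        i = int(cand[k])
        o0, o1 = path_off[k], path_off[k + 1]
        hits.append(Hit(ids[i], profile.family_id, float(scores[k]),
                        float(evalues[k]), int(qstarts[k]), int(qends[k]),
                        path_q_buf[o0:o1].copy(), path_s_buf[o0:o1].copy()))
    hits.sort(key=lambda h: (h.evalue, h.query_id))
    return hits


def search(profile: ProfileModel, proteins, evalue_cutoff: float = 1e-5,
           prefilter: bool = True, band: int = 16) -> list[Hit]:
    """Search a set of proteins against a calibrated profile.

    ``proteins`` is a mapping id -> sequence or an iterable of (id, sequence)
    pairs; only hits with E-value <= ``evalue_cutoff`` are returned.
    """
    items = (list(proteins.items()) if isinstance(proteins, dict)
             else list(proteins))
    ids = [i for i, _ in items]
    enc = [encode_protein(s) for _, s in items]
    offsets = np.zeros(len(enc) + 1, dtype=np.int64)
    for i, e in enumerate(enc):
        offsets[i + 1] = offsets[i] + e.size
    cat = np.concatenate(enc) if enc else np.empty(0, dtype=np.uint8)
    return search_encoded(profile, cat, offsets, ids,
                          evalue_cutoff=evalue_cutoff, prefilter=prefilter,
                          band=band)
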