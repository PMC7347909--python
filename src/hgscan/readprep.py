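"""Adapter removal, paired-end overlap merging, and quality/length filtering.

Merging evaluates every overlap offset between mate 1 and the reverse
complement of mate 2 and keeps the offset maximizing matches - mismatches,
subject to a mismatch-fraction cap and a minimum overlap.  Consensus bases
take the higher-quality read at conflicts (an exact quality tie yields 'N',
which keeps merging symmetric under swapping the mates); consensus quality is
the max Phred at agreements and the absolute quality difference at conflicts.

The quality filter retains merged fragments with mean Phred >= 20 and length
>= 300 bp, the thresholds used for the metagenomic read sets this package
targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

logger = logging.getLogger(__name__)

_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b
_N = ord("N")


@dataclass(frozen=True)
class QCConfig:
    min_mean_q: float = 20.0
    min_len_bp: int = 300
    min_overlap_bp: int = 10
    max_mismatch_frac: float = 0.1
    adapter_seq: str = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

    def __post_init__(self):
        if (self.min_mean_q < 0 or self.min_len_bp < 0
                or self.min_overlap_bp < 0 or self.max_mismatch_frac < 0):
            raise ValueError("QC thresholds must be nonnegative")


@dataclass
class ReadPair:
    id: str
    seq1: str
    qual1: np.ndarray
    seq2: str
    qual2: np.ndarray

    def __post_init__(self):
        self.qual1 = np.asarray(self.qual1, dtype=np.uint8)
        self.qual2 = np.asarray(self.qual2, dtype=np.uint8)
        if len(self.seq1) != self.qual1.size or len(self.seq2) != self.qual2.size:
            raise ValueError("sequence and quality lengths differ")


@dataclass
class MergedRead:
    id: str
    seq: str
    qual: np.ndarray
    overlap_len: int

    def mean_q(self) -> float:
        return float(np.mean(self.qual)) if self.qual.size else 0.0


# ---------------------------------------------------------------------------
# adapter removal
# ---------------------------------------------------------------------------

def _adapter_keep_len(read: np.ndarray, adapter: np.ndarray,
                      max_mismatch_frac: float, min_match: int = 3) -> int:
    """Length to keep after removing the longest 3' suffix that matches an
    adapter prefix with at most ``max_mismatch_frac`` mismatches."""
    n = read.size
    for k in range(min(n, adapter.size), min_match - 1, -1):
        mm = int(np.count_nonzero(read[n - k:] != adapter[:k]))
        if mm <= max_mismatch_frac * k:
            return n - k
    return n


def remove_adapters(pair: ReadPair, adapter: str,
                    max_mismatch_frac: float = 0.1) -> ReadPair:
    """Trim adapter read-through from the 3' end of both mates.

    Qualities are trimmed in lockstep; a pair without adapter is returned
    unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be nonempty")
    ad = np.frombuffer(adapter.encode(), dtype=np.uint8)
    r1 = np.frombuffer(pair.seq1.encode(), dtype=np.uint8)
    r2 = np.frombuffer(pair.seq2.encode(), dtype=np.uint8)
    k1 = _adapter_keep_len(r1, ad, max_mismatch_frac)
    k2 = _adapter_keep_len(r2, ad, max_mismatch_frac)
    if k1 == r1.size and k2 == r2.size:
        return pair
    return ReadPair(pair.id, pair.seq1[:k1], pair.qual1[:k1],
                    pair.seq2[:k2], pair.qual2[:k2])


def trim_adapters_batch(seqs: np.ndarray, adapter: np.ndarray,
                        max_mismatch_frac: float = 0.1,
                        min_match: int = 3) -> np.ndarray:
    """Vectorized keep-lengths for an (n_reads, read_len) base matrix."""
    n, rl = seqs.shape
    keep = np.full(n, rl, dtype=np.int64)
    undecided = np.ones(n, dtype=bool)
    for k in range(min(rl, adapter.size), min_match - 1, -1):
        mm = (seqs[:, rl - k:] != adapter[:k]).sum(axis=1)
        hit = undecided & (mm <= max_mismatch_frac * k)
        keep[hit] = rl - k
        undecided &= ~hit
    return keep


# ---------------------------------------------------------------------------
# overlap merging (numba kernel)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _merge_kernel(s1, q1, s2, q2, len1, len2, min_ov, max_mm_frac,
                  comp, out_seq, out_qual, out_len, out_ov, out_ok):
    n = s1.shape[0]
    maxlen = out_seq.shape[1]
    rc2 = np.empty(s2.shape[1], dtype=np.uint8)
    rq2 = np.empty(s2.shape[1], dtype=np.uint8)
    for i in range(n):
        L1 = len1[i]
        L2 = len2[i]
        for j in range(L2):
            rc2[j] = comp[s2[i, L2 - 1 - j]]
            rq2[j] = q2[i, L2 - 1 - j]
        best_score = -1
        best_off = 0
        best_ov = 0
        found = False
        for off in range(min_ov - L2, L1 - min_ov + 1):
            a0 = 0 if off > 0 else -off + off  # max(0, off)
            if off > 0:
                a0 = off
            a1 = L1 if off + L2 > L1 else off + L2
            ov = a1 - a0
            if ov < min_ov:
                continue
            mm_cap = int(max_mm_frac * ov)
            mm = 0
            bad = False
            for k in range(a0, a1):
                if s1[i, k] != rc2[k - off]:
                    mm += 1
                    if mm > mm_cap:
                        bad = True
                        break
            if bad:
                continue
            score = ov - 2 * mm
            if (score > best_score
                    or (score == best_score and ov > best_ov)
                    or (score == best_score and ov == best_ov
                        and off < best_off)):
                best_score = score
                best_off = off
                best_ov = ov
                found = True
        if not found:
            out_ok[i] = 0
            out_len[i] = 0
            out_ov[i] = 0
            continue
        off = best_off
        lo = 0 if off > 0 else off
        hi = L1 if off + L2 < L1 else off + L2
        mlen = hi - lo
        if mlen > maxlen:
            out_ok[i] = 0
            continue
        pos = 0
        a0 = off if off > 0 else 0
        a1 = L1 if off + L2 > L1 else off + L2
        # left overhang
        if off > 0:
            for k in range(off):
                out_seq[i, pos] = s1[i, k]
                out_qual[i, pos] = q1[i, k]
                pos += 1
        elif off < 0:
            for j in range(-off):
                out_seq[i, pos] = rc2[j]
                out_qual[i, pos] = rq2[j]
                pos += 1
        # overlap consensus
        for k in range(a0, a1):
            b1 = s1[i, k]
            b2 = rc2[k - off]
            c1 = q1[i, k]
            c2 = rq2[k - off]
            if b1 == b2:
                out_seq[i, pos] = b1
                out_qual[i, pos] = c1 if c1 > c2 else c2
            elif c1 > c2:
                out_seq[i, pos] = b1
                out_qual[i, pos] = c1 - c2
            elif c2 > c1:
                out_seq[i, pos] = b2
                out_qual[i, pos] = c2 - c1
            else:
                out_seq[i, pos] = 78  # 'N'
                out_qual[i, pos] = 0
            pos += 1
        # right overhang
        if off + L2 > L1:
            for j in range(a1 - off, L2):
                out_seq[i, pos] = rc2[j]
                out_qual[i, pos] = rq2[j]
                pos += 1
        else:
            for k in range(a1, L1):
                out_seq[i, pos] = s1[i, k]
                out_qual[i, pos] = q1[i, k]
                pos += 1
        out_len[i] = pos
        out_ov[i] = best_ov
        out_ok[i] = 1


def merge_batch(ids: list[str], s1: np.ndarray, q1: np.ndarray,
                s2: np.ndarray, q2: np.ndarray, len1: np.ndarray,
                len2: np.ndarray, cfg: QCConfig) -> list[MergedRead | None]:
    """Merge encoded read pairs; None marks unmergeable pairs."""
    n = s1.shape[0]
    maxlen = s1.shape[1] + s2.shape[1]
    out_seq = np.empty((n, maxlen), dtype=np.uint8)
    out_qual = np.empty((n, maxlen), dtype=np.uint8)
    out_len = np.zeros(n, dtype=np.int64)
    out_ov = np.zeros(n, dtype=np.int64)
    out_ok = np.zeros(n, dtype=np.uint8)
    _merge_kernel(s1, q1, s2, q2,
                  np.asarray(len1, dtype=np.int64),
                  np.asarray(len2, dtype=np.int64),
                  cfg.min_overlap_bp, cfg.max_mismatch_frac, _COMP,
                  out_seq, out_qual, out_len, out_ov, out_ok)
    merged: list[MergedRead | None] = []
    for i in range(n):
        if not out_ok[i]:
            merged.append(None)
            continue
        L = int(out_len[i])
        merged.append(MergedRead(ids[i], out_seq[i, :L].tobytes().decode(),
                                 out_qual[i, :L].copy(), int(out_ov[i])))
    return merged


def merge_pairs(pair: ReadPair, cfg: QCConfig) -> MergedRead | None:
    """Overlap-merge one pair; returns None when no admissible offset exists."""
    rl1, rl2 = len(pair.seq1), len(pair.seq2)
    s1 = np.frombuffer(pair.seq1.encode(), dtype=np.uint8).reshape(1, -1)
    s2 = np.frombuffer(pair.seq2.encode(), dtype=np.uint8).reshape(1, -1)
    if rl1 == 0 or rl2 == 0:
        return None
    out = merge_batch([pair.id], s1, pair.qual1.reshape(1, -1), s2,
                      pair.qual2.reshape(1, -1),
                      np.array([rl1]), np.array([rl2]), cfg)
    return out[0]


# ---------------------------------------------------------------------------
# quality filter
# ---------------------------------------------------------------------------

def quality_filter(reads: list[MergedRead], cfg: QCConfig) -> list[MergedRead]:
    """Retain reads with mean Phred >= min_mean_q and length >= min_len_bp."""
    kept = [r for r in reads
            if len(r.seq) >= cfg.min_len_bp and r.mean_q() >= cfg.min_mean_q]
    removed = len(reads) - len(kept)
    if removed:
        logger.info("quality_filter removed %d of %d reads", removed, len(reads))
    return kept


def preprocess_pairs(pairs: list[tuple[str, str, str, str, str]],
                     cfg: QCConfig) -> list[MergedRead]:
    """Full preprocessing: adapter trim -> overlap merge -> quality filter.

    ``pairs`` are (id, seq1, qual1_phred33, seq2, qual2_phred33) tuples with
    equal-length mates, as produced by the simulator or a FASTQ reader.
    """
    if not pairs:
        return []
    n = len(pairs)
    rl1 = max(len(p[1]) for p in pairs)
    rl2 = max(len(p[3]) for p in pairs)
    s1 = np.zeros((n, rl1), dtype=np.uint8)
    q1 = np.zeros((n, rl1), dtype=np.uint8)
    s2 = np.zeros((n, rl2), dtype=np.uint8)
    q2 = np.zeros((n, rl2), dtype=np.uint8)
    len1 = np.empty(n, dtype=np.int64)
    len2 = np.empty(n, dtype=np.int64)
    ids = []
    for i, (pid, a, qa, b, qb) in enumerate(pairs):
        ids.append(pid)
        s1[i, :len(a)] = np.frombuffer(a.encode(), dtype=np.uint8)
        q1[i, :len(a)] = np.frombuffer(qa.encode(), dtype=np.uint8) - 33
        s2[i, :len(b)] = np.frombuffer(b.encode(), dtype=np.uint8)
        q2[i, :len(b)] = np.frombuffer(qb.encode(), dtype=np.uint8) - 33
        len1[i] = len(a)
        len2[i] = len(b)
    adapter = np.frombuffer(cfg.adapter_seq.encode(), dtype=np.uint8)
    if rl1 and (len1 == rl1).all():
        keep1 = trim_adapters_batch(s1, adapter, cfg.max_mismatch_frac)
        len1 = np.minimum(len1, keep1)
    else:
        for i in range(n):
            len1[i] = _adapter_keep_len(s1[i, :len1[i]], adapter,
                                        cfg.max_mismatch_frac)
    if rl2 and (len2 == rl2).all():
        keep2 = trim_adapters_batch(s2, adapter, cfg.max_mismatch_frac)
        len2 = np.minimum(len2, keep2)
    else:
        for i in range(n):
            len2[i] = _adapter_keep_len(s2[i, :len2[i]], adapter,
                                        cfg.max_mismatch_frac)
    merged = merge_batch(ids, s1, q1, s2, q2, len1, len2, cfg)
    return quality_filter([m for m in merged if m is not None], cfg)
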