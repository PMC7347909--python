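"""Six-frame ORF prediction under the bacterial translation table (11).

Merged metagenomic fragments are short (~350 bp), so a full gene-model caller
adds little: maximal ORFs are enumerated on both strands in all three frames.
In the strict mode an ORF runs from a start codon (ATG/GTG/TTG by default) to
the next stop codon; ``allow_partial`` additionally emits ORFs truncated at
the fragment edges (no start codon at the 5' edge, no stop at the 3' edge),
matching how gene callers treat genes cut by fragment boundaries — a fragment
internal to a gene contains neither.

Proteins are handled as uint8 arrays over the 20 canonical residues plus 'X'
(index 20) for codons containing N; the first codon of a start-codon ORF is
reported as Met, the usual convention for alternative initiators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from Bio.Data import CodonTable

from .motifs import AMINO_ACIDS

AA_ALPHABET = AMINO_ACIDS + "X"
AA_TO_IDX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
X_IDX = 20
_STOP_IDX = 21
_M_IDX = AA_TO_IDX["M"]

_BASE_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_IDX[_b] = _i
_BASE_IDX[ord("N")] = 4

_T11 = CodonTable.unambiguous_dna_by_id[11]
#: codon index (16a+4b+c) -> aa index; 64 = any codon containing N -> X
CODON_AA = np.full(65, X_IDX, dtype=np.uint8)
for _c1 in "ACGT":
    for _c2 in "ACGT":
        for _c3 in "ACGT":
            _codon = _c1 + _c2 + _c3
            _idx = (_BASE_IDX[ord(_c1)] * 16 + _BASE_IDX[ord(_c2)] * 4
                    + _BASE_IDX[ord(_c3)])
            if _codon in _T11.stop_codons:
                CODON_AA[_idx] = _STOP_IDX
            else:
                CODON_AA[_idx] = AA_TO_IDX[_T11.forward_table[_codon]]

DEFAULT_START_CODONS = ("ATG", "GTG", "TTG")


def _start_table(start_codons) -> np.ndarray:
    table = np.zeros(64, dtype=np.uint8)
    for codon in start_codons:
        idx = 0
        for ch in codon:
            idx = idx * 4 + int(_BASE_IDX[ord(ch)])
        table[idx] = 1
    return table


@dataclass(frozen=True)
class OrfConfig:
    translation_table: int = 11
    min_len_aa: int = 30
    start_codons: tuple[str, ...] = DEFAULT_START_CODONS
    both_strands: bool = True
    #: emit ORFs truncated at fragment edges (used for merged reads)
    allow_partial: bool = False

    def __post_init__(self):
        if self.translation_table != 11:
            raise ValueError("only the bacterial table (11) is supported")
        if self.min_len_aa < 1:
            raise ValueError("min_len_aa must be >= 1")


@dataclass
class Orf:
    """One predicted ORF with 1-based inclusive forward-strand coordinates
    (the stop codon, when present, is included in the span)."""

    id: str
    protein: str
    start: int
    end: int
    strand: str
    frame: int
    has_start: bool = True
    has_stop: bool = True
    source_id: str = ""


def encode_protein(protein: str) -> np.ndarray:
    out = np.empty(len(protein), dtype=np.uint8)
    for i, aa in enumerate(protein):
        out[i] = AA_TO_IDX.get(aa, X_IDX)
    return out


def decode_protein(arr: np.ndarray) -> str:
    return "".join(AA_ALPHABET[i] for i in arr)


@njit(cache=True)
def _orf_kernel(seqcat, offsets, codon_aa, start64, min_len_aa, allow_partial,
                do_minus, out_read, out_start, out_end, out_strand,
                out_has_start, out_has_stop, out_poff, out_plen, prot_buf):
    """Enumerate ORFs for all reads; returns (n_orfs, prot_cursor) or (-1, -1)
    on buffer overflow."""
    n_reads = offsets.size - 1
    cap = out_read.size
    pcap = prot_buf.size
    n_out = 0
    pcur = 0
    for r in range(n_reads):
        a = offsets[r]
        b = offsets[r + 1]
        L = b - a
        for strand in range(2 if do_minus else 1):
            for frame in range(3):
                ncod = (L - frame) // 3
                if ncod < min_len_aa:
                    continue
                seg_start = 0
                have_start = -1
                for c in range(ncod + 1):
                    is_end = c == ncod
                    if not is_end:
                        if strand == 0:
                            p = a + frame + 3 * c
                            b0 = seqcat[p]
                            b1 = seqcat[p + 1]
                            b2 = seqcat[p + 2]
                        else:
                            # minus strand: read right-to-left, complemented
                            p = b - 1 - frame - 3 * c
                            b0 = 3 - seqcat[p] if seqcat[p] < 4 else 4
                            b1 = 3 - seqcat[p - 1] if seqcat[p - 1] < 4 else 4
                            b2 = 3 - seqcat[p - 2] if seqcat[p - 2] < 4 else 4
                        if b0 > 3 or b1 > 3 or b2 > 3:
                            cidx = 64
                        else:
                            cidx = 16 * b0 + 4 * b1 + b2
                        aa = codon_aa[cidx]
                        if have_start < 0 and cidx < 64 and start64[cidx] == 1:
                            have_start = c
                        if aa != 21:
                            continue
                    # segment [seg_start, c) ended by stop (or sequence end)
                    ostart = -1
                    partial5 = False
                    if allow_partial and seg_start == 0:
                        ostart = 0
                        partial5 = True
                    elif have_start >= 0:
                        ostart = have_start
                        partial5 = False
                    if ostart >= 0 and (is_end and allow_partial or not is_end):
                        plen = c - ostart
                        if plen >= min_len_aa:
                            if n_out >= cap or pcur + plen > pcap:
                                return -1, -1
                            # translate
                            for k in range(plen):
                                cc = ostart + k
                                if strand == 0:
                                    p = a + frame + 3 * cc
                                    b0 = seqcat[p]
                                    b1 = seqcat[p + 1]
                                    b2 = seqcat[p + 2]
                                else:
                                    p = b - 1 - frame - 3 * cc
                                    b0 = 3 - seqcat[p] if seqcat[p] < 4 else 4
                                    b1 = 3 - seqcat[p - 1] if seqcat[p - 1] < 4 else 4
                                    b2 = 3 - seqcat[p - 2] if seqcat[p - 2] < 4 else 4
                                if b0 > 3 or b1 > 3 or b2 > 3:
                                    cidx = 64
                                else:
                                    cidx = 16 * b0 + 4 * b1 + b2
                                aa_k = codon_aa[cidx]
                                if k == 0 and not partial5:
                                    aa_k = 10  # Met, initiator convention
                                prot_buf[pcur + k] = aa_k
                            # nt span in read-local coordinates (0-based,
                            # inclusive of stop codon when present)
                            span_cod = plen + (0 if is_end else 1)
                            if strand == 0:
                                nt0 = frame + 3 * ostart
                                nt1 = frame + 3 * (ostart + span_cod) - 1
                            else:
                                nt1 = L - 1 - frame - 3 * ostart
                                nt0 = L - frame - 3 * (ostart + span_cod)
                            out_read[n_out] = r
                            out_start[n_out] = nt0
                            out_end[n_out] = nt1
                            out_strand[n_out] = strand
                            out_has_start[n_out] = 0 if partial5 else 1
                            out_has_stop[n_out] = 0 if is_end else 1
                            out_poff[n_out] = pcur
                            out_plen[n_out] = plen
                            pcur += plen
                            n_out += 1
                    seg_start = c + 1
                    have_start = -1
    return n_out, pcur


@dataclass
class OrfSet:
    """Batch ORF predictions over a list of source sequences.

    Proteins live in one uint8 buffer (aa indices); per-ORF slices are
    available via :meth:`protein_arr`.
    """

    source_ids: list[str]
    read_idx: np.ndarray
    start0: np.ndarray       # 0-based inclusive, forward strand of the source
    end0: np.ndarray
    strand: np.ndarray       # 0 = '+', 1 = '-'
    has_start: np.ndarray
    has_stop: np.ndarray
    prot_offset: np.ndarray
    prot_len: np.ndarray
    prot_buf: np.ndarray

    def __len__(self) -> int:
        return self.read_idx.size

    def protein_arr(self, i: int) -> np.ndarray:
        o = self.prot_offset[i]
        return self.prot_buf[o:o + self.prot_len[i]]

    def protein(self, i: int) -> str:
        return decode_protein(self.protein_arr(i))

    def orf_id(self, i: int) -> str:
        return f"{self.source_ids[self.read_idx[i]]}_orf{i}"

    def to_orfs(self) -> list[Orf]:
        out = []
        for i in range(len(self)):
            out.append(Orf(
                id=self.orf_id(i),
                protein=self.protein(i),
                start=int(self.start0[i]) + 1,
                end=int(self.end0[i]) + 1,
                strand="+" if self.strand[i] == 0 else "-",
                frame=0,
                has_start=bool(self.has_start[i]),
                has_stop=bool(self.has_stop[i]),
                source_id=self.source_ids[self.read_idx[i]],
            ))
        return out


def _encode_dna(seq: str) -> np.ndarray:
    arr = _BASE_IDX[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted({seq[i] for i in np.flatnonzero(arr == 255)})
        raise ValueError(f"non-ACGTN characters in sequence: {bad}")
    return arr


def predict_orfs_batch(seqs: list[str], ids: list[str],
                       cfg: OrfConfig) -> OrfSet:
    """Six-frame ORF enumeration over many sequences at once."""
    enc = [_encode_dna(s) for s in seqs]
    offsets = np.zeros(len(enc) + 1, dtype=np.int64)
    for i, e in enumerate(enc):
        offsets[i + 1] = offsets[i] + e.size
    seqcat = (np.concatenate(enc) if enc else np.empty(0, dtype=np.uint8))
    start64 = _start_table(cfg.start_codons)
    cap = max(64, int(offsets[-1] // max(cfg.min_len_aa, 1)) * 2 + 64)
    pcap = max(256, int(offsets[-1]))
    while True:
        out_read = np.empty(cap, dtype=np.int64)
        out_start = np.empty(cap, dtype=np.int64)
        out_end = np.empty(cap, dtype=np.int64)
        out_strand = np.empty(cap, dtype=np.uint8)
        out_has_start = np.empty(cap, dtype=np.uint8)
        out_has_stop = np.empty(cap, dtype=np.uint8)
        out_poff = np.empty(cap, dtype=np.int64)
        out_plen = np.empty(cap, dtype=np.int64)
        prot_buf = np.empty(pcap, dtype=np.uint8)
        n, pcur = _orf_kernel(seqcat, offsets, CODON_AA, start64,
                              cfg.min_len_aa, cfg.allow_partial,
                              cfg.both_strands, out_read, out_start, out_end,
                              out_strand, out_has_start, out_has_stop,
                              out_poff, out_plen, prot_buf)
        if n >= 0:
            break
        cap *= 2
        pcap *= 2
    return OrfSet(ids, out_read[:n].copy(), out_start[:n].copy(),
                  out_end[:n].copy(), out_strand[:n].copy(),
                  out_has_start[:n].copy(), out_has_stop[:n].copy(),
                  out_poff[:n].copy(), out_plen[:n].copy(),
                  prot_buf[:pcur].copy())


def predict_orfs(dna: str, cfg: OrfConfig | None = None) -> list[Orf]:
    """Predict ORFs in one sequence (see module docstring for the contract)."""
    cfg = cfg or OrfConfig()
    if len(dna) < 3:
        raise ValueError("sequence shorter than one codon")
    return predict_orfs_batch([dna], ["seq"], cfg).to_orfs()
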