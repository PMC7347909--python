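"""File I/O: FASTQ/FASTA via Biopython, TSV tables, profile JSON."""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .profile import ProfileModel


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq_pairs(path1, path2) -> list[tuple[str, str, str, str, str]]:
    """Read mate files into (id, seq1, qual1, seq2, qual2) phred33 tuples."""
    pairs = []
    with _open_text(path1) as f1, _open_text(path2) as f2:
        it2 = SeqIO.parse(f2, "fastq")
        for r1 in SeqIO.parse(f1, "fastq"):
            try:
                r2 = next(it2)
            except StopIteration:
                raise ValueError(f"{path2} has fewer records than {path1}")
            q1 = "".join(chr(q + 33)
                         for q in r1.letter_annotations["phred_quality"])
            q2 = "".join(chr(q + 33)
                         for q in r2.letter_annotations["phred_quality"])
            pairs.append((r1.id, str(r1.seq), q1, str(r2.seq), q2))
        if next(it2, None) is not None:
            raise ValueError(f"{path2} has more records than {path1}")
    return pairs


def write_fastq_pairs(pairs, path1, path2) -> None:
    recs1, recs2 = [], []
    for pid, s1, q1, s2, q2 in pairs:
        r1 = SeqRecord(Seq(s1), id=pid, description="")
        r1.letter_annotations["phred_quality"] = [ord(c) - 33 for c in q1]
        r2 = SeqRecord(Seq(s2), id=pid, description="")
        r2.letter_annotations["phred_quality"] = [ord(c) - 33 for c in q2]
        recs1.append(r1)
        recs2.append(r2)
    with _open_text(path1, "wt") as f1:
        SeqIO.write(recs1, f1, "fastq")
    with _open_text(path2, "wt") as f2:
        SeqIO.write(recs2, f2, "fastq")


def read_fasta(path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {r.id: str(r.seq) for r in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    with _open_text(path, "wt") as fh:
        SeqIO.write((SeqRecord(Seq(s), id=i, description="")
                     for i, s in seqs.items()), fh, "fasta")


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def save_profile(profile: ProfileModel, path) -> None:
    Path(path).write_text(profile.to_json())


def load_profile(path) -> ProfileModel:
    return ProfileModel.from_json(Path(path).read_text())
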