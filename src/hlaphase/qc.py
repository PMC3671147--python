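"""Read containers, FASTQ I/O and quality filtering.

The QC contract mirrors the preprocessing applied to 2 x 250 bp MiSeq
amplicon reads before alignment: adapter removal, 3'-trimming of the
low-quality (< Q30) suffix, and rejection of pairs in which either mate
ends up at <= 200 bp.  Trimming is suffix-only (never per-base masking)
so that downstream phasing sees contiguous read coordinates.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import numpy as np

__all__ = ["ReadPair", "qc_filter", "read_fastq_pairs", "write_fastq"]


@dataclass
class ReadPair:
    """A paired-end read; qualities are Phred scores (not ASCII)."""

    id: str
    seq1: str
    qual1: np.ndarray
    seq2: str
    qual2: np.ndarray

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


def _trim_mate(seq: str, qual: np.ndarray, min_base_quality: int,
               adapter: str | None) -> tuple[str, np.ndarray]:
    if adapter:
        hit = seq.find(adapter)
        if hit >= 0:
            seq, qual = seq[:hit], qual[:hit]
    # longest suffix in which every base is < Q30 is removed
    end = len(seq)
    while end > 0 and qual[end - 1] < min_base_quality:
        end -= 1
    return seq[:end], qual[:end]


def qc_filter(pair: ReadPair, min_base_quality: int = 30, min_length: int = 200,
              adapter: str | None = None) -> ReadPair | None:
    """Adapter/quality trim both mates; keep the pair iff both stay > min_length.

    Returns the (possibly trimmed) pair, or ``None`` when rejected.
    """
    s1, q1 = _trim_mate(pair.seq1, pair.qual1, min_base_quality, adapter)
    s2, q2 = _trim_mate(pair.seq2, pair.qual2, min_base_quality, adapter)
    if len(s1) <= min_length or len(s2) <= min_length:
        return None
    if len(s1) == len(pair.seq1) and len(s2) == len(pair.seq2):
        return pair
    return ReadPair(pair.id, s1, q1, s2, q2)


def _open(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _parse_fastq(path: str) -> list[tuple[str, str, np.ndarray]]:
    records = []
    with _open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        raise ValueError(f"{path}: truncated FASTQ ({len(lines)} lines)")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i:i + 4]
        if not head.startswith("@") or not plus.startswith("+"):
            raise ValueError(f"{path}: malformed FASTQ record at index {i // 4}")
        if len(seq) != len(qual):
            raise ValueError(f"{path}: seq/qual length mismatch at record {i // 4}")
        name = head[1:].split()[0]
        q = np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int16) - 33
        records.append((name, seq.upper(), q))
    return records


def read_fastq_pairs(path1: str, path2: str) -> list[ReadPair]:
    """Read two mate FASTQ files (Phred+33, plain or gzip) into pairs."""
    r1, r2 = _parse_fastq(path1), _parse_fastq(path2)
    if len(r1) != len(r2):
        raise ValueError("mate FASTQ files have different record counts")
    pairs = []
    for (n1, s1, q1), (n2, s2, q2) in zip(r1, r2):
        base1 = n1.removesuffix("/1")
        base2 = n2.removesuffix("/2")
        if base1 != base2:
            raise ValueError(f"mate name mismatch: {n1} vs {n2}")
        pairs.append(ReadPair(base1, s1, q1, s2, q2))
    return pairs


def write_fastq(pairs: list[ReadPair], path1: str, path2: str) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n"
                     + "".join(chr(int(q) + 33) for q in p.qual1) + "\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n"
                     + "".join(chr(int(q) + 33) for q in p.qual2) + "\n")
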