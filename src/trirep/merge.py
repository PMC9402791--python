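"""Paired-end read joining by overlap alignment.

Mates of an amplicon read pair overlap in the middle of the fragment; the
merger reverse-complements mate 2 and scores every suffix(mate1) /
prefix(revcomp mate2) overlap with a free-end-gap (glocal) alignment,
match +1 / mismatch -1, internal gaps disallowed — the overlap dialect of
Needleman-Wunsch appropriate for a substitution-dominated error profile.
Within the chosen overlap, disagreeing bases resolve to the higher-quality
base (mate 1 wins quality ties) and agreeing bases keep the higher of the
two qualities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReadPair",
    "MergedRead",
    "MergeFailure",
    "revcomp",
    "merge_pair",
    "merge_pairs",
    "read_fastq_pairs",
    "write_fastq",
]

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class MergedRead:
    read_id: str
    sequence: str
    quality: str
    overlap_len: int
    overlap_mismatches: int


@dataclass(frozen=True)
class MergeFailure:
    read_id: str
    reason: str  # "empty-read" | "no-overlap"


def _best_overlap(
    s1: str, s2rc: str, min_overlap: int, max_mismatch_rate: float
) -> tuple[int, int] | None:
    """Return (overlap_len, mismatches) of the best admissible overlap.

    Scans every overlap length; score = ov - 2*mm.  Ties prefer the longer
    overlap (i.e. the smaller offset of mate 2 on mate 1).
    """
    l1, l2 = len(s1), len(s2rc)
    best: tuple[int, int, int] | None = None  # (score, ov, mm)
    for ov in range(min_overlap, min(l1, l2) + 1):
        a = s1[l1 - ov :]
        b = s2rc[:ov]
        mm = sum(x != y for x, y in zip(a, b))
        if mm > ov * max_mismatch_rate:
            continue
        score = ov - 2 * mm
        if best is None or score > best[0] or (score == best[0] and ov > best[1]):
            best = (score, ov, mm)
    if best is None:
        return None
    return best[1], best[2]


def _consensus(
    s1: str, q1: str, s2rc: str, q2rc: str, ov: int
) -> tuple[str, str]:
    l1 = len(s1)
    pre_s, pre_q = s1[: l1 - ov], q1[: l1 - ov]
    mid_s, mid_q = [], []
    for i in range(ov):
        b1, c1 = s1[l1 - ov + i], q1[l1 - ov + i]
        b2, c2 = s2rc[i], q2rc[i]
        if b1 == b2:
            mid_s.append(b1)
            mid_q.append(max(c1, c2))
        elif c2 > c1:
            mid_s.append(b2)
            mid_q.append(c2)
        else:
            mid_s.append(b1)
            mid_q.append(c1)
    return pre_s + "".join(mid_s) + s2rc[ov:], pre_q + "".join(mid_q) + q2rc[ov:]


def merge_pair(
    pair: ReadPair, min_overlap: int = 30, max_mismatch_rate: float = 0.1
) -> MergedRead | MergeFailure:
    """Merge one read pair, or report why it cannot be merged."""
    if not pair.seq1 or not pair.seq2:
        return MergeFailure(pair.read_id, "empty-read")
    s2rc = revcomp(pair.seq2)
    q2rc = pair.qual2[::-1]
    hit = _best_overlap(pair.seq1, s2rc, min_overlap, max_mismatch_rate)
    if hit is None:
        return MergeFailure(pair.read_id, "no-overlap")
    ov, mm = hit
    seq, qual = _consensus(pair.seq1, pair.qual1, s2rc, q2rc, ov)
    return MergedRead(pair.read_id, seq, qual, ov, mm)


def _merge_batch_uniform(
    pairs: Sequence[ReadPair], min_overlap: int, max_mismatch_rate: float
) -> list[MergedRead | MergeFailure]:
    """Vectorized merge for pairs with uniform mate lengths.

    Exactly equivalent to mapping :func:`merge_pair`; the per-offset
    mismatch counts are computed for all pairs at once.
    """
    n = len(pairs)
    l1 = len(pairs[0].seq1)
    l2 = len(pairs[0].seq2)
    a1 = np.frombuffer("".join(p.seq1 for p in pairs).encode(), np.uint8).reshape(n, l1)
    a2 = np.frombuffer(
        "".join(revcomp(p.seq2) for p in pairs).encode(), np.uint8
    ).reshape(n, l2)
    q1 = np.frombuffer("".join(p.qual1 for p in pairs).encode(), np.uint8).reshape(n, l1)
    q2 = np.frombuffer(
        "".join(p.qual2[::-1] for p in pairs).encode(), np.uint8
    ).reshape(n, l2)

    best_score = np.full(n, np.iinfo(np.int32).min, np.int32)
    best_ov = np.zeros(n, np.int32)
    best_mm = np.zeros(n, np.int32)
    for ov in range(min_overlap, min(l1, l2) + 1):
        mm = (a1[:, l1 - ov :] != a2[:, :ov]).sum(1).astype(np.int32)
        valid = mm <= ov * max_mismatch_rate
        score = ov - 2 * mm
        take = valid & ((score > best_score) | (score == best_score))
        best_score = np.where(take, score, best_score)
        best_mm = np.where(take, mm, best_mm)
        best_ov = np.where(take, ov, best_ov)

    out: list[MergedRead | MergeFailure] = []
    for i, p in enumerate(pairs):
        if best_ov[i] == 0:
            out.append(MergeFailure(p.read_id, "no-overlap"))
            continue
        ov = int(best_ov[i])
        s2 = a2[i]
        pick2 = np.concatenate(
            [
                np.zeros(l1 - ov, bool),
                (a1[i, l1 - ov :] != s2[:ov]) & (q2[i, :ov] > q1[i, l1 - ov :]),
            ]
        )
        seq_arr = np.where(pick2, np.concatenate([a1[i, : l1 - ov], s2[:ov]]), a1[i])
        qual_arr = np.concatenate(
            [
                q1[i, : l1 - ov],
                np.where(
                    a1[i, l1 - ov :] == s2[:ov],
                    np.maximum(q1[i, l1 - ov :], q2[i, :ov]),
                    np.where(q2[i, :ov] > q1[i, l1 - ov :], q2[i, :ov], q1[i, l1 - ov :]),
                ),
            ]
        )
        seq = seq_arr.tobytes().decode() + s2[ov:].tobytes().decode()
        qual = qual_arr.tobytes().decode() + q2[i, ov:].tobytes().decode()
        out.append(MergedRead(p.read_id, seq, qual, ov, int(best_mm[i])))
    return out


def merge_pairs(
    pairs: Sequence[ReadPair],
    min_overlap: int = 30,
    max_mismatch_rate: float = 0.1,
) -> tuple[list[MergedRead], pd.DataFrame]:
    """Merge a collection of pairs; returns merged reads and a merge log.

    The log has one row per input pair: (read_id, status, overlap_len,
    mismatches).  Unmerged pairs are dropped from the merged list.
    """
    if pairs and all(
        len(p.seq1) == len(pairs[0].seq1) and len(p.seq2) == len(pairs[0].seq2)
        for p in pairs[: min(len(pairs), 64)]
    ) and len({(len(p.seq1), len(p.seq2)) for p in pairs}) == 1 and pairs[0].seq1:
        results = _merge_batch_uniform(pairs, min_overlap, max_mismatch_rate)
    else:
        results = [merge_pair(p, min_overlap, max_mismatch_rate) for p in pairs]

    merged: list[MergedRead] = []
    rows = []
    for r in results:
        if isinstance(r, MergedRead):
            merged.append(r)
            rows.append((r.read_id, "merged", r.overlap_len, r.overlap_mismatches))
        else:
            rows.append((r.read_id, r.reason, 0, 0))
    log = pd.DataFrame(rows, columns=["read_id", "status", "overlap_len", "mismatches"])
    return merged, log


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> list[ReadPair]:
    """Load mate-ordered paired FASTQ files (Phred+33)."""
    from Bio import SeqIO

    recs1 = list(SeqIO.parse(str(r1_path), "fastq"))
    recs2 = list(SeqIO.parse(str(r2_path), "fastq"))
    if len(recs1) != len(recs2):
        raise ValueError("mate files differ in record count")
    pairs = []
    for a, b in zip(recs1, recs2):
        qa = "".join(chr(q + 33) for q in a.letter_annotations["phred_quality"])
        qb = "".join(chr(q + 33) for q in b.letter_annotations["phred_quality"])
        pairs.append(ReadPair(a.id, str(a.seq), str(b.seq), qa, qb))
    return pairs


def write_fastq(reads: Iterable[MergedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")
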