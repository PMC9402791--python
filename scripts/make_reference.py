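"""Regenerate the packaged synthetic TRB germline reference.

Provenance script for ``src/trirep/data/trb_synthetic.fasta``: 12 V segments
(72 nt, Y[YFLI]C anchor with the Cys codon at offset 60, i.e. 12 nt before the
3' end), 6 J segments (48 nt, [FW]GXGT anchor at offset 18) and one C segment
(30 nt).  Sequences are random stop-free codons, constrained so that

  * the intended motif occurrence is the one `locate_anchor` reports,
  * no 12-mer is shared between any two segments (keeps seeded alignment
    unambiguous for simulated reads).

Run from the repository root:  python scripts/make_reference.py
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from trirep.germline import locate_anchor, translate, write_germline_fasta, GermlineSegment

SEED = 20260919
OUT = Path(__file__).resolve().parents[1] / "src" / "trirep" / "data" / "trb_synthetic.fasta"

CODONS = {
    "Y": ["TAT", "TAC"], "F": ["TTT", "TTC"], "W": ["TGG"], "C": ["TGT", "TGC"],
    "G": ["GGA", "GGC", "GGG", "GGT"], "T": ["ACA", "ACC", "ACG", "ACT"],
    "A": ["GCA", "GCC", "GCG", "GCT"], "S": ["AGC", "AGT", "TCA", "TCC"],
}
# codons for the random filler positions: everything but stops
_BASES = "ACGT"
FILLER = [a + b + c for a in _BASES for b in _BASES for c in _BASES
          if translate(a + b + c) != "*"]


def _rand_codons(rng: np.random.Generator, n: int) -> list[str]:
    return [FILLER[i] for i in rng.integers(0, len(FILLER), n)]


def _kmers(seq: str, k: int = 12) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def make_v(rng: np.random.Generator) -> str:
    x2 = ["Y", "F", "L", "I"][rng.integers(0, 4)]
    motif = [CODONS["Y"][rng.integers(0, 2)],
             {"Y": CODONS["Y"], "F": CODONS["F"], "L": ["CTG", "CTC", "TTA"], "I": ["ATA", "ATC", "ATT"]}[x2][0],
             CODONS["C"][rng.integers(0, 2)]]
    tail = [CODONS["A"][rng.integers(0, 4)], CODONS["S"][rng.integers(0, 4)], CODONS["S"][rng.integers(0, 4)]]
    seq = "".join(_rand_codons(rng, 18) + motif + tail)
    assert len(seq) == 72
    return seq


def make_j(rng: np.random.Generator) -> str:
    fw = ["F", "W"][rng.integers(0, 2)]
    motif = [CODONS[fw][rng.integers(0, len(CODONS[fw]))],
             CODONS["G"][rng.integers(0, 4)],
             _rand_codons(rng, 1)[0],
             CODONS["G"][rng.integers(0, 4)],
             CODONS["T"][rng.integers(0, 4)]]
    seq = "".join(_rand_codons(rng, 6) + motif + _rand_codons(rng, 5))
    assert len(seq) == 48
    return seq


def main() -> None:
    rng = np.random.default_rng(SEED)
    segs: list[GermlineSegment] = []
    seen_kmers: set[str] = set()

    def admit(seq: str, sid: str, cls: str, anchor: int | None) -> bool:
        if cls != "C" and locate_anchor(seq, cls) != anchor:
            return False
        if _kmers(seq) & seen_kmers:
            return False
        seen_kmers.update(_kmers(seq))
        segs.append(GermlineSegment(sid, cls, seq, anchor, True))
        return True

    for i in range(1, 13):
        while not admit(make_v(rng), f"TRBV{i}", "V", 60):
            pass
    for i in range(1, 7):
        while not admit(make_j(rng), f"TRBJ{i}", "J", 18):
            pass
    while not admit("".join(_rand_codons(rng, 10)), "TRBC1", "C", None):
        pass

    OUT.parent.mkdir(parents=True, exist_ok=True)
    write_germline_fasta(segs, OUT)
    print(f"wrote {OUT} ({len(segs)} segments)")


if __name__ == "__main__":
    main()
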