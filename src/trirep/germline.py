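"""Germline TRB segment libraries and conserved CDR3 anchor motifs.

The CDR3 interval of a rearranged TCR beta chain is delimited by two
conserved motifs carried by the germline segments themselves: the
``Y[YFLI]C`` motif whose cysteine codon sits near the 3' end of every
functional V segment, and the ``[FW]GXGT`` motif whose phenylalanine /
tryptophan codon sits in the 5' half of every J segment.  Locating those
two codons on the germline references once, ahead of time, is what lets
the annotation stage project CDR3 boundaries onto reads through an
alignment instead of re-searching every read for the motif.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GermlineSegment",
    "GermlineLibrary",
    "locate_anchor",
    "load_germline_fasta",
    "write_germline_fasta",
    "enumerate_vj_combinations",
    "builtin_library",
]

_V_MOTIF = re.compile(r"Y[YFLI]C")
_J_MOTIF = re.compile(r"[FW]GXGT".replace("X", "."))
_VALID = set("ACGTN")


def translate(nt: str) -> str:
    """Translate a nucleotide string, ignoring a trailing partial codon."""
    n = len(nt) - len(nt) % 3
    return str(Seq(nt[:n]).translate()) if n else ""


@dataclass(frozen=True)
class GermlineSegment:
    """One germline V, J or C gene sequence with its anchor codon located.

    ``anchor_offset`` is the 0-based nucleotide offset of the conserved
    cysteine codon (V) or the F/W codon (J); it is ``None`` for C segments
    and for records whose motif could not be located (``functional=False``).
    """

    segment_id: str
    segment_class: str  # "V" | "J" | "C"
    sequence: str
    anchor_offset: int | None = None
    functional: bool = True

    def __post_init__(self) -> None:
        if self.segment_class not in ("V", "J", "C"):
            raise ValueError(f"segment_class must be V/J/C, got {self.segment_class!r}")
        if not self.sequence:
            raise ValueError(f"{self.segment_id}: empty sequence")

    @property
    def anchor_codon(self) -> str | None:
        if self.anchor_offset is None:
            return None
        return self.sequence[self.anchor_offset : self.anchor_offset + 3]


def locate_anchor(sequence: str, segment_class: str) -> int | None:
    """Locate the CDR3 anchor codon on a germline segment.

    Scans the three forward reading frames.  For V segments, returns the
    nucleotide offset of the Cys codon of the 3'-most ``Y[YFLI]C``
    occurrence (the motif marks the V segment's 3' end, so the last hit
    is the biological anchor).  For J segments, returns the offset of the
    F/W codon of the 5'-most ``[FW]GXGT`` occurrence.  Returns ``None``
    when no frame contains the motif.
    """
    if segment_class == "V":
        motif, pick_last, codon_in_motif = _V_MOTIF, True, 2
    elif segment_class == "J":
        motif, pick_last, codon_in_motif = _J_MOTIF, False, 0
    else:
        raise ValueError("anchors are defined for V and J segments only")

    best: int | None = None
    for frame in range(3):
        aa = translate(sequence[frame:])
        for m in motif.finditer(aa):
            off = frame + 3 * (m.start() + codon_in_motif)
            if best is None or (pick_last and off > best) or (not pick_last and off < best):
                best = off
    return best


@dataclass
class GermlineLibrary:
    """A named collection of germline segments with unique ids."""

    segments: list[GermlineSegment] = field(default_factory=list)
    name: str = "library"

    def __post_init__(self) -> None:
        ids = [s.segment_id for s in self.segments]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate segment_id in library {self.name!r}")
        self._by_id = {s.segment_id: s for s in self.segments}

    def __iter__(self) -> Iterator[GermlineSegment]:
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def __getitem__(self, segment_id: str) -> GermlineSegment:
        return self._by_id[segment_id]

    def __contains__(self, segment_id: str) -> bool:
        return segment_id in self._by_id

    def of_class(self, segment_class: str, functional_only: bool = False) -> list[GermlineSegment]:
        out = [s for s in self.segments if s.segment_class == segment_class]
        if functional_only:
            out = [s for s in out if s.functional]
        return out

    @property
    def v_segments(self) -> list[GermlineSegment]:
        return self.of_class("V")

    @property
    def j_segments(self) -> list[GermlineSegment]:
        return self.of_class("J")

    def add(self, segment: GermlineSegment) -> None:
        if segment.segment_id in self._by_id:
            raise ValueError(f"duplicate segment_id {segment.segment_id!r}")
        self.segments.append(segment)
        self._by_id[segment.segment_id] = segment

    def validate(self) -> None:
        """Assert the anchor-translation invariant over all functional V/J."""
        for s in self.segments:
            if s.segment_class == "C" or not s.functional:
                continue
            aa = translate(s.sequence[s.anchor_offset :])[:1]
            want = {"C"} if s.segment_class == "V" else {"F", "W"}
            if aa not in want:
                raise ValueError(
                    f"{s.segment_id}: anchor codon translates to {aa!r}, expected {want}"
                )


def _classify_record(rec_id: str, seq: str, segment_class: str) -> GermlineSegment:
    seq = seq.upper()
    if set(seq) - _VALID:
        return GermlineSegment(rec_id, segment_class, seq, None, functional=False)
    if segment_class == "C":
        return GermlineSegment(rec_id, "C", seq, None, functional=True)
    anchor = locate_anchor(seq, segment_class)
    return GermlineSegment(rec_id, segment_class, seq, anchor, functional=anchor is not None)


def load_germline_fasta(path: str | Path, segment_class: str) -> list[GermlineSegment]:
    """Load one class of germline segments from FASTA.

    The first whitespace-delimited header token is the segment id.  A
    ``functional=no`` key in the description forces the flag off; records
    whose anchor motif cannot be located, or that contain non-ACGTN
    characters, are returned flagged non-functional rather than dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    segments: list[GermlineSegment] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seg = _classify_record(rec.id, str(rec.seq), segment_class)
        if "functional=no" in rec.description.split():
            seg = replace(seg, functional=False)
        segments.append(seg)
    if not segments:
        raise ValueError(f"{path}: no FASTA records")
    return segments


def write_germline_fasta(segments: Iterable[GermlineSegment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in segments:
            flag = "yes" if s.functional else "no"
            fh.write(f">{s.segment_id} functional={flag}\n{s.sequence}\n")


def enumerate_vj_combinations(
    library: GermlineLibrary, functional_only: bool = True
) -> tuple[int, list[tuple[str, str]]]:
    """Enumerate potential (V, J) segment pairings of a library.

    Returns ``(count, pairs)`` — the Cartesian product of the V and J
    segment sets, restricted to functional segments when requested.
    """
    vs = library.of_class("V", functional_only)
    js = library.of_class("J", functional_only)
    pairs = [(v.segment_id, j.segment_id) for v in vs for j in js]
    return len(pairs), pairs


def builtin_library() -> GermlineLibrary:
    """The packaged synthetic TRB reference (12 V, 6 J, 1 C).

    A compact stand-in for an IMGT-style human TRB reference: every V
    carries a Y[YFLI]C motif ending 12 nt before its 3' end, every J a
    [FW]GXGT motif 18 nt from its 5' end, so junctions built between them
    have realistic anchored geometry.  Synthetic — sequences are not
    human germline.
    """
    from importlib.resources import files

    path = files("trirep.data").joinpath("trb_synthetic.fasta")
    segs: list[GermlineSegment] = []
    with path.open() as fh:  # type: ignore[union-attr]
        header, buf = None, []
        for line in list(fh) + [">"]:
            line = line.strip()
            if line.startswith(">"):
                if header is not None:
                    sid = header.split()[0]
                    cls = "V" if sid.startswith("TRBV") else "J" if sid.startswith("TRBJ") else "C"
                    segs.append(_classify_record(sid, "".join(buf), cls))
                header, buf = line[1:], []
            else:
                buf.append(line)
    lib = GermlineLibrary(segs, name="trb-synthetic")
    lib.validate()
    return lib
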