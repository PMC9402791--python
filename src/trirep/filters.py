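"""Five-checkpoint artifact-removal cascade for clonotype tables.

Amplicon repertoire sequencing inflates diversity with artifacts: PCR and
sequencing substitutions spawn satellite clonotypes around real ones,
template-switching produces two-parent mosaic reads, multiplex primers
amplify some V segments disproportionately, and a long tail of singletons
is dominated by noise.  The cascade applies five checkpoints in fixed
order:

1. sequencing-error filter — absorb low-abundance clonotypes within a
   small Hamming distance of a much larger same-V/J parent into that
   parent (copy mass is conserved, not deleted);
2. mosaic filter — remove clonotypes whose supporting reads carry a
   two-parent V-region signature (5' and 3' halves of the V block
   best-aligning to different V segments);
3. amplification filter — down-weight (not remove) clonotypes of V
   segments whose total read share is a median+k*MAD outlier;
4. reference filter — discard reads whose germline V/J blocks outside
   the junction fall below an identity floor;
5. frequency filter — discard clonotypes at or below the copy threshold
   (default: singletons).

Every stage is an explicit, documented stand-in: the assay vendor's own
cascade internals are unpublished, so these are this package's algorithms
honoring the five checkpoint names and their stated intent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .annotate import (
    AnnotationResult,
    AnnotatedSequence,
    Repertoire,
    SegmentIndex,
)
from .germline import GermlineLibrary

__all__ = [
    "FilterConfig",
    "StageReport",
    "FilterReport",
    "CascadeResult",
    "filter_sequencing_errors",
    "filter_mosaic",
    "filter_amplification",
    "filter_reference",
    "filter_frequency",
    "run_cascade",
    "mosaic_signature",
]

_BASES = "ACGT"
STAGE_ORDER = ("sequencing-error", "mosaic", "amplification", "reference", "frequency")


@dataclass(frozen=True)
class FilterConfig:
    child_parent_max_hamming: int = 1
    child_parent_min_ratio: float = 10.0
    chimera_score_margin: int = 6
    amplification_mad_k: float = 5.0
    reference_min_identity: float = 0.9
    frequency_threshold: int = 1  # copies must exceed this to survive

    def __post_init__(self) -> None:
        if self.child_parent_max_hamming < 1 or self.child_parent_min_ratio <= 0:
            raise ValueError("absorption thresholds must be positive")
        if self.frequency_threshold < 0:
            raise ValueError("frequency_threshold must be >= 0")


@dataclass
class StageReport:
    stage: str
    n_in: int
    n_removed: int
    n_retained: int
    removed: list[tuple[str, str]] = field(default_factory=list)  # (junction, reason)
    notes: str = ""

    def __post_init__(self) -> None:
        if self.n_in != self.n_removed + self.n_retained:
            raise ValueError(f"{self.stage}: accounting broken")


@dataclass
class FilterReport:
    stages: list[StageReport] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.stage,
                    "input": s.n_in,
                    "removed": s.n_removed,
                    "retained": s.n_retained,
                    "notes": s.notes,
                }
                for s in self.stages
            ]
        )

    @property
    def removed_junctions(self) -> set[str]:
        return {j for s in self.stages for j, _ in s.removed}


# ---------------------------------------------------------------------------
# stage 1: sequencing-error filter (parent/child absorption)
# ---------------------------------------------------------------------------


def _hamming_neighbors(seq: str) -> Iterable[str]:
    for i, c in enumerate(seq):
        for b in _BASES:
            if b != c:
                yield seq[:i] + b + seq[i + 1 :]


def filter_sequencing_errors(
    rep: Repertoire, cfg: FilterConfig = FilterConfig()
) -> tuple[Repertoire, StageReport]:
    """Absorb satellite clonotypes into their abundant same-V/J parents.

    A clonotype within Hamming distance <= child_parent_max_hamming of a
    clonotype carrying >= child_parent_min_ratio times its copies, with
    the same V and J call, is merged into that parent (copies added).
    Absorption iterates to a fixed point, so the stage is idempotent.
    """
    out = rep.copy()
    by_junction = {c.junction_nt: c for c in out.clonotypes}
    removed: list[tuple[str, str]] = []

    changed = True
    while changed:
        changed = False
        for c in sorted(out.clonotypes, key=lambda c: (c.copies, c.junction_nt)):
            if c.junction_nt not in by_junction:
                continue
            best_parent = None
            candidates = (
                _hamming_neighbors(c.junction_nt)
                if cfg.child_parent_max_hamming == 1
                else [
                    p.junction_nt
                    for p in out.clonotypes
                    if len(p.junction_nt) == len(c.junction_nt)
                    and sum(a != b for a, b in zip(p.junction_nt, c.junction_nt))
                    <= cfg.child_parent_max_hamming
                ]
            )
            for nb in candidates:
                p = by_junction.get(nb)
                if p is None or p is c:
                    continue
                if (p.v_id, p.j_id) != (c.v_id, c.j_id):
                    continue
                if p.copies >= cfg.child_parent_min_ratio * c.copies:
                    if best_parent is None or p.copies > best_parent.copies:
                        best_parent = p
            if best_parent is not None:
                best_parent.copies += c.copies
                del by_junction[c.junction_nt]
                removed.append((c.junction_nt, f"absorbed-into:{best_parent.junction_nt}"))
                changed = True
        out.clonotypes = [c for c in out.clonotypes if c.junction_nt in by_junction]

    out.renormalize()
    report = StageReport(
        "sequencing-error", len(rep), len(removed), len(out), removed
    )
    return out, report


# ---------------------------------------------------------------------------
# stage 2: mosaic (chimera) filter
# ---------------------------------------------------------------------------


def mosaic_signature(
    a: AnnotatedSequence,
    v_index: SegmentIndex,
    library: GermlineLibrary,
    margin: int,
) -> bool:
    """True when the read's V block halves best-align to different V segments.

    The pre-anchor V block is split in half; each half is assigned its
    best V segment independently.  The read carries a mosaic signature
    when the halves disagree and the split assignment beats re-scoring
    both halves against the read's single assigned V by at least
    ``margin`` score points.
    """
    ann = a.annotation
    v_seg = library[ann.v_id]
    v_anchor = v_seg.anchor_offset + ann.v_diag
    lo = max(0, ann.v_diag)
    if v_anchor - lo < 2 * v_index.k + 2:
        return False  # block too short to split informatively
    mid = (lo + v_anchor) // 2
    h5 = v_index.best(a.sequence, lo, mid)
    h3 = v_index.best(a.sequence, mid, v_anchor)
    if h5 is None or h3 is None:
        return False
    if h5[0].segment_id == h3[0].segment_id:
        return False

    def _score_against(seg, diag, lo_, hi_) -> int:
        s = seg.sequence
        aa_ = max(lo_, diag)
        bb = min(hi_, diag + len(s))
        if bb <= aa_:
            return -(hi_ - lo_)
        m = sum(a.sequence[i] == s[i - diag] for i in range(aa_, bb))
        return 2 * m - (bb - aa_)

    own5 = _score_against(v_seg, ann.v_diag, lo, mid)
    own3 = _score_against(v_seg, ann.v_diag, mid, v_anchor)
    return (h5[2] + h3[2]) - (own5 + own3) >= margin


def filter_mosaic(
    rep: Repertoire,
    ann_result: AnnotationResult,
    library: GermlineLibrary,
    cfg: FilterConfig = FilterConfig(),
) -> tuple[Repertoire, StageReport]:
    """Remove clonotypes supported mostly by two-parent mosaic reads."""
    v_index = SegmentIndex(library.of_class("V", True))
    support: dict[str, list[AnnotatedSequence]] = {}
    for a in ann_result.accepted:
        support.setdefault(a.junction_nt, []).append(a)

    out = rep.copy()
    removed = []
    keep = []
    for c in out.clonotypes:
        seqs = support.get(c.junction_nt, [])
        total = sum(s.copies for s in seqs)
        if total == 0:
            keep.append(c)
            continue
        mosaic = sum(
            s.copies
            for s in seqs
            if mosaic_signature(s, v_index, library, cfg.chimera_score_margin)
        )
        if mosaic * 2 > total:
            removed.append((c.junction_nt, "mosaic-majority"))
        else:
            keep.append(c)
    out.clonotypes = keep
    out.renormalize()
    return out, StageReport("mosaic", len(rep), len(removed), len(out), removed)


# ---------------------------------------------------------------------------
# stage 3: PCR amplification performance filter
# ---------------------------------------------------------------------------


def filter_amplification(
    rep: Repertoire, cfg: FilterConfig = FilterConfig()
) -> tuple[Repertoire, StageReport]:
    """Down-weight clonotypes of over-amplified V segments.

    Uneven multiplex-primer efficiency distorts quantity, not identity,
    so outlier V segments (share > median + k*MAD across V segments) have
    their clonotype copies rescaled to the median share; nothing is
    removed.  Requires >= 3 distinct V segments, otherwise a logged no-op.
    """
    out = rep.copy()
    shares: dict[str, float] = {}
    for c in out.clonotypes:
        shares[c.v_id] = shares.get(c.v_id, 0.0) + c.copies
    if len(shares) < 3:
        return out, StageReport(
            "amplification", len(rep), 0, len(out),
            notes="no-op: fewer than 3 distinct V segments",
        )
    total = sum(shares.values())
    vals = np.array([s / total for s in shares.values()])
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    flagged = {
        v for v, s in shares.items() if s / total > med + cfg.amplification_mad_k * mad
    }
    for c in out.clonotypes:
        if c.v_id in flagged:
            c.copies *= med / (shares[c.v_id] / total)
    out.renormalize()
    notes = f"flagged V segments: {sorted(flagged)}" if flagged else ""
    return out, StageReport("amplification", len(rep), 0, len(out), notes=notes)


# ---------------------------------------------------------------------------
# stage 4: reference sequence filter
# ---------------------------------------------------------------------------


def filter_reference(
    ann_result: AnnotationResult, cfg: FilterConfig = FilterConfig()
) -> tuple[AnnotationResult, StageReport, dict[str, float]]:
    """Discard reads whose germline blocks outside the junction are degraded.

    Returns the filtered annotation set plus, per junction, the retained
    copy fraction (used to deflate clonotype copies built before the
    stage ran).
    """
    kept: list[AnnotatedSequence] = []
    removed_reads = 0
    tot: dict[str, int] = {}
    keep: dict[str, int] = {}
    for a in ann_result.accepted:
        tot[a.junction_nt] = tot.get(a.junction_nt, 0) + a.copies
        ok = (
            a.annotation.v_identity >= cfg.reference_min_identity
            and a.annotation.j_identity >= cfg.reference_min_identity
        )
        if ok:
            kept.append(a)
            keep[a.junction_nt] = keep.get(a.junction_nt, 0) + a.copies
        else:
            removed_reads += a.copies
    fractions = {j: keep.get(j, 0) / t for j, t in tot.items()}
    out = AnnotationResult(
        kept, ann_result.n_reads_in, ann_result.n_assigned, ann_result.rejections
    )
    n_in = len(ann_result.accepted)
    report = StageReport(
        "reference", n_in, n_in - len(kept), len(kept),
        notes=f"{removed_reads} read copies below identity {cfg.reference_min_identity}",
    )
    return out, report, fractions


def _apply_reference_to_repertoire(
    rep: Repertoire, fractions: dict[str, float]
) -> tuple[Repertoire, StageReport]:
    out = rep.copy()
    removed = []
    keep = []
    for c in out.clonotypes:
        f = fractions.get(c.junction_nt, 1.0)
        c.copies *= f
        if c.copies > 0:
            keep.append(c)
        else:
            removed.append((c.junction_nt, "reference-identity"))
    out.clonotypes = keep
    out.renormalize()
    return out, StageReport("reference", len(rep), len(removed), len(out), removed)


# ---------------------------------------------------------------------------
# stage 5: frequency threshold filter
# ---------------------------------------------------------------------------


def filter_frequency(
    rep: Repertoire, threshold: int = 1
) -> tuple[Repertoire, StageReport]:
    """Discard clonotypes whose copies do not exceed the threshold.

    With the default threshold of 1, all single-copy variants are
    discarded.
    """
    out = rep.copy()
    removed = [
        (c.junction_nt, "frequency") for c in out.clonotypes if c.copies <= threshold
    ]
    out.clonotypes = [c for c in out.clonotypes if c.copies > threshold]
    out.renormalize()
    return out, StageReport("frequency", len(rep), len(removed), len(out), removed)


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------


@dataclass
class CascadeResult:
    repertoire: Repertoire
    annotations: AnnotationResult
    report: FilterReport


def run_cascade(
    rep: Repertoire,
    ann_result: AnnotationResult,
    library: GermlineLibrary,
    cfg: FilterConfig = FilterConfig(),
) -> CascadeResult:
    """Apply the five checkpoints in their fixed order.

    sequencing-error -> mosaic -> amplification -> reference -> frequency.
    The returned annotation set reflects the reference-stage read
    discards, so re-running the cascade on its own output is a no-op for
    the idempotent stages.
    """
    report = FilterReport()

    r1, s1 = filter_sequencing_errors(rep, cfg)
    report.stages.append(s1)
    r2, s2 = filter_mosaic(r1, ann_result, library, cfg)
    report.stages.append(s2)
    r3, s3 = filter_amplification(r2, cfg)
    report.stages.append(s3)
    ann_out, _, fractions = filter_reference(ann_result, cfg)
    r4, s4 = _apply_reference_to_repertoire(r3, fractions)
    report.stages.append(s4)
    r5, s5 = filter_frequency(r4, cfg.frequency_threshold)
    report.stages.append(s5)
    return CascadeResult(r5, ann_out, report)
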