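"""End-to-end composition: read pairs -> merged reads -> clonotypes -> filtered repertoire."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .annotate import AnnotationResult, Repertoire, annotate_reads, build_repertoire
from .filters import CascadeResult, FilterConfig, run_cascade
from .germline import GermlineLibrary
from .merge import MergedRead, ReadPair, merge_pairs

__all__ = ["PipelineResult", "process_pairs"]


@dataclass
class PipelineResult:
    repertoire: Repertoire  # after the filter cascade
    unfiltered: Repertoire  # straight from annotation
    annotations: AnnotationResult
    cascade: CascadeResult
    merge_log: pd.DataFrame

    @property
    def accounting(self) -> dict[str, float]:
        """Per-stage read/clonotype conservation counts for the run log."""
        merged = int((self.merge_log["status"] == "merged").sum())
        rej = self.annotations.rejections
        return {
            "pairs_in": int(len(self.merge_log)),
            "merged": merged,
            "merge_failed": int(len(self.merge_log)) - merged,
            "assigned": int(self.annotations.n_assigned),
            "unassigned": int(rej.get("unassigned", 0)),
            "cdr3_rejected": int(sum(v for k, v in rej.items() if k != "unassigned")),
            "clonotypes_unfiltered": len(self.unfiltered),
            "clonotypes_final": len(self.repertoire),
        }


def process_pairs(
    pairs: Sequence[ReadPair],
    library: GermlineLibrary,
    donor_id: str = "donor",
    lineage: str = "sample",
    min_overlap: int = 30,
    max_mismatch_rate: float = 0.1,
    min_identity: float = 0.85,
    filter_config: FilterConfig = FilterConfig(),
) -> PipelineResult:
    """Run the full analysis on in-memory read pairs.

    Merging drops unmergeable pairs (logged); annotation assigns V/J and
    extracts junctions; the unfiltered repertoire is then cleaned by the
    five-checkpoint cascade.
    """
    merged, merge_log = merge_pairs(pairs, min_overlap, max_mismatch_rate)
    ann = annotate_reads(merged, library, min_identity)
    unfiltered = build_repertoire(ann.records, donor_id, lineage, library)
    cascade = run_cascade(unfiltered, ann, library, filter_config)
    cascade.repertoire.donor_id = donor_id
    cascade.repertoire.lineage = lineage
    return PipelineResult(cascade.repertoire, unfiltered, ann, cascade, merge_log)
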