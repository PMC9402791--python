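"""Multi-repertoire set analyses: sharing, exclusivity, turnover.

All comparisons are presence/absence on CDR3 junction sequences
(nucleotide level by default, amino-acid level by flag); clonal
frequencies play no role in sharing counts.  Percentages are per-side:
the denominator is always the repertoire whose perspective is reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotate import Repertoire

__all__ = [
    "SharingReport",
    "pairwise_overlap",
    "exclusive_variants",
    "trilineage_common",
    "public_private",
    "turnover",
    "build_sharing_report",
]


def _sets(reps: Sequence[Repertoire], level: str) -> list[set[str]]:
    return [r.junction_set(level) for r in reps]


def pairwise_overlap(
    rep_a: Repertoire, rep_b: Repertoire, level: str = "nt"
) -> tuple[set[str], float, float]:
    """Shared junction set and the per-side shared percentages.

    pct_a is the percentage of A's unique variants also present in B
    (and vice versa); an empty repertoire reports 0.
    """
    sa, sb = rep_a.junction_set(level), rep_b.junction_set(level)
    shared = sa & sb
    pct_a = 100.0 * len(shared) / len(sa) if sa else 0.0
    pct_b = 100.0 * len(shared) / len(sb) if sb else 0.0
    return shared, pct_a, pct_b


def exclusive_variants(
    samples: Mapping[tuple[str, str], Repertoire], level: str = "nt"
) -> dict[tuple[str, str], set[str]]:
    """Variants expressed by exactly one (donor, lineage) sample.

    A variant is exclusive to a sample iff it appears in no other sample
    of the grouping — one individual AND one lineage.
    """
    if len(samples) < 2:
        raise ValueError("exclusivity needs at least two samples")
    keys = list(samples)
    sets = {k: samples[k].junction_set(level) for k in keys}
    out: dict[tuple[str, str], set[str]] = {}
    for k in keys:
        others: set[str] = set()
        for k2 in keys:
            if k2 != k:
                others |= sets[k2]
        out[k] = sets[k] - others
    return out


def trilineage_common(
    rep_1: Repertoire, rep_2: Repertoire, rep_3: Repertoire, level: str = "nt"
) -> tuple[set[str], float]:
    """Triple intersection and its percentage of the combined pool.

    The combined pool is the union of the three repertoires' unique
    variants; the fraction is reported as a percentage.
    """
    s1, s2, s3 = _sets([rep_1, rep_2, rep_3], level)
    common = s1 & s2 & s3
    union = s1 | s2 | s3
    fraction = 100.0 * len(common) / len(union) if union else 0.0
    return common, fraction


def public_private(
    donors: Mapping[str, Repertoire], level: str = "nt"
) -> tuple[set[str], dict[str, float], dict[str, set[str]]]:
    """Public set and per-donor private percentages within one lineage.

    Public variants are expressed by *all* donors; a donor's private
    variants appear in no other donor.  Private percentages are relative
    to each donor's own repertoire size.
    """
    if len(donors) < 2:
        raise ValueError("public/private analysis needs at least two donors")
    sets = {d: r.junction_set(level) for d, r in donors.items()}
    public = set.intersection(*sets.values())
    private: dict[str, set[str]] = {}
    pct: dict[str, float] = {}
    for d, s in sets.items():
        others: set[str] = set()
        for d2, s2 in sets.items():
            if d2 != d:
                others |= s2
        private[d] = s - others
        pct[d] = 100.0 * len(private[d]) / len(s) if s else 0.0
    return public, pct, private


def turnover(
    rep_before: Repertoire, rep_after: Repertoire, level: str = "nt"
) -> tuple[float, set[str], set[str]]:
    """Repertoire turnover across a state change (e.g. differentiation).

    Returns (retained_pct_of_after, lost, gained): the percentage of the
    after-state repertoire already present before, the variants lost, and
    the variants newly gained.
    """
    sb, sa = rep_before.junction_set(level), rep_after.junction_set(level)
    if not sa:
        raise ValueError("after-state repertoire is empty; retention undefined")
    retained = 100.0 * len(sb & sa) / len(sa)
    return retained, sb - sa, sa - sb


@dataclass
class SharingReport:
    """Sharing analysis over a (donor, lineage) sample grid."""

    labels: list[tuple[str, str]]
    shared_counts: pd.DataFrame  # symmetric matrix of |A ∩ B|
    shared_pct: pd.DataFrame  # row-perspective percentages
    exclusive: dict[tuple[str, str], set[str]]
    public_per_lineage: dict[str, set[str]]
    trilineage_common_pct: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "samples": [f"{d}/{l}" for d, l in self.labels],
            "shared_counts": self.shared_counts.to_dict(),
            "shared_pct": self.shared_pct.round(4).to_dict(),
            "exclusive_counts": {
                f"{d}/{l}": len(s) for (d, l), s in self.exclusive.items()
            },
            "public_counts": {l: len(s) for l, s in self.public_per_lineage.items()},
            "trilineage_common_pct": self.trilineage_common_pct,
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def build_sharing_report(
    samples: Mapping[tuple[str, str], Repertoire], level: str = "nt"
) -> SharingReport:
    """Full sharing analysis of a donor x lineage sample grid.

    Computes the pairwise shared-count and per-side percentage matrices,
    exclusive sets, per-lineage public sets (across donors), and — for
    donors with three or more lineages — the multi-lineage common
    percentage of each donor's combined pool.
    """
    keys = list(samples)
    names = [f"{d}/{l}" for d, l in keys]
    sets = {k: samples[k].junction_set(level) for k in keys}

    counts = pd.DataFrame(0, index=names, columns=names)
    pct = pd.DataFrame(0.0, index=names, columns=names)
    for i, ki in enumerate(keys):
        for j, kj in enumerate(keys):
            shared = sets[ki] & sets[kj]
            counts.iloc[i, j] = len(shared)
            pct.iloc[i, j] = 100.0 * len(shared) / len(sets[ki]) if sets[ki] else 0.0

    exclusive = exclusive_variants(samples, level) if len(samples) > 1 else {}

    lineages = sorted({l for _, l in keys})
    public: dict[str, set[str]] = {}
    for lin in lineages:
        per_donor = {d: samples[(d, l)] for d, l in keys if l == lin}
        if len(per_donor) >= 2:
            public[lin], _, _ = public_private(per_donor, level)

    tri: dict[str, float] = {}
    donors = sorted({d for d, _ in keys})
    for d in donors:
        reps = [samples[k] for k in keys if k[0] == d]
        if len(reps) >= 3:
            common = set.intersection(*[r.junction_set(level) for r in reps])
            union = set.union(*[r.junction_set(level) for r in reps])
            tri[d] = 100.0 * len(common) / len(union) if union else 0.0

    return SharingReport(keys, counts, pct, exclusive, public, tri)
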