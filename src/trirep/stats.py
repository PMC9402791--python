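"""Per-repertoire diversity and composition statistics.

Covers the quantities a repertoire profiling study reports per sample:
unique clonotype counts (nucleotide- and amino-acid-level), V-J usage
and its coverage of the potential combination space, CDR3 length spectra
with a Gaussianity score (the computational analog of spectratyping),
trim/insert profiles of the junction decomposition, and mean +/- SD
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotate import Repertoire, decompose_junction
from .germline import GermlineLibrary, enumerate_vj_combinations

__all__ = [
    "UsageMatrix",
    "LengthSpectrum",
    "SummaryStat",
    "count_unique",
    "vj_usage",
    "vj_coverage",
    "length_spectrum",
    "trim_insert_profiles",
    "gaussianity_score",
    "summarize",
]


@dataclass
class UsageMatrix:
    """Clonotype-frequency mass per (V, J) combination."""

    table: pd.DataFrame  # rows: V labels, cols: J labels, values: freq mass

    @property
    def v_labels(self) -> list[str]:
        return list(self.table.index)

    @property
    def j_labels(self) -> list[str]:
        return list(self.table.columns)

    @property
    def observed_combinations(self) -> int:
        return int((self.table.values > 0).sum())

    @property
    def total_mass(self) -> float:
        return float(self.table.values.sum())


@dataclass
class LengthSpectrum:
    masses: dict[int, float]  # CDR3 length (aa) -> clonotype-frequency mass
    gaussianity_score: float


@dataclass
class SummaryStat:
    n: int
    mean: float
    sd: float
    min: float
    max: float
    sd_convention: str  # "population" | "sample"


def count_unique(rep: Repertoire, level: str = "nt") -> int:
    """Number of distinct CDR3 variants at the nucleotide or amino-acid level."""
    return len(rep.junction_set(level))


def vj_usage(rep: Repertoire) -> UsageMatrix:
    """Frequency-mass usage matrix over the (V, J) combinations present."""
    acc: dict[tuple[str, str], float] = {}
    for c in rep.clonotypes:
        acc[(c.v_id, c.j_id)] = acc.get((c.v_id, c.j_id), 0.0) + c.frequency
    vs = sorted({v for v, _ in acc})
    js = sorted({j for _, j in acc})
    tab = pd.DataFrame(0.0, index=vs, columns=js)
    for (v, j), m in acc.items():
        tab.loc[v, j] = m
    return UsageMatrix(tab)


def vj_coverage(
    usage: UsageMatrix, library: GermlineLibrary | None = None, potential: int | None = None
) -> tuple[int, int, float]:
    """Observed vs potential V-J combinations and the coverage percentage.

    ``potential`` may be given directly (e.g. the size of a full IMGT
    catalog) or derived from a library's functional segments.  The
    percentage is rounded to one decimal.
    """
    if potential is None:
        if library is None:
            raise ValueError("provide a library or an explicit potential count")
        potential, _ = enumerate_vj_combinations(library, functional_only=True)
    if potential == 0:
        raise ZeroDivisionError("potential combination count is zero")
    observed = usage.observed_combinations
    return observed, potential, round(100.0 * observed / potential, 1)


def gaussianity_score(values: Sequence[float], weights: Sequence[float]) -> float:
    """1 - sup-distance between a weighted discrete CDF and a matched normal.

    A continuity-corrected KS-style statistic: the empirical CDF of the
    integer-valued observable is compared at each support point x against
    Phi((x + 0.5 - mu) / sigma), with mu, sigma the weighted mean and SD.
    1.0 means indistinguishable from a discretized Gaussian; degenerate
    (single-support) inputs score 0 by convention.
    """
    v = np.asarray(values, float)
    w = np.asarray(weights, float)
    if len(v) == 0:
        raise ValueError("empty spectrum")
    w = w / w.sum()
    order = np.argsort(v)
    v, w = v[order], w[order]
    uniq, inv = np.unique(v, return_inverse=True)
    mass = np.zeros(len(uniq))
    np.add.at(mass, inv, w)
    if len(uniq) < 2:
        return 0.0
    mu = float((uniq * mass).sum())
    sd = float(np.sqrt((mass * (uniq - mu) ** 2).sum()))
    if sd == 0:
        return 0.0
    ecdf = np.cumsum(mass)
    ncdf = sps.norm.cdf(uniq + 0.5, loc=mu, scale=sd)
    return float(1.0 - np.max(np.abs(ecdf - ncdf)))


def length_spectrum(rep: Repertoire) -> LengthSpectrum:
    """CDR3 amino-acid length distribution weighted by clonotype frequency."""
    if not rep.clonotypes:
        raise ValueError("empty repertoire has no length spectrum")
    masses: dict[int, float] = {}
    for c in rep.clonotypes:
        l = len(c.junction_aa) if c.junction_aa else len(c.junction_nt) // 3
        masses[l] = masses.get(l, 0.0) + c.frequency
    score = gaussianity_score(list(masses), list(masses.values()))
    return LengthSpectrum(masses, score)


def trim_insert_profiles(
    decompositions: Iterable[tuple[int, int, int]],
    weights: Iterable[float] | None = None,
) -> dict[str, dict[int, float]]:
    """Frequency-weighted histograms of v_trim, j_trim and insert length.

    Returns {"v_trim": hist, "j_trim": hist, "n_len": hist} with each
    histogram's masses summing to 1, plus the insert-length Gaussianity
    under the key "n_len_gaussianity" (a scalar stored beside the
    histograms in the returned mapping's "_scores" entry).
    """
    decs = list(decompositions)
    if weights is None:
        w = [1.0] * len(decs)
    else:
        w = list(weights)
    if not decs:
        raise ValueError("no decompositions")
    total = sum(w)
    hists: dict[str, dict[int, float]] = {"v_trim": {}, "j_trim": {}, "n_len": {}}
    for (vt, jt, nl), wt in zip(decs, w):
        for key, val in (("v_trim", vt), ("j_trim", jt), ("n_len", nl)):
            hists[key][val] = hists[key].get(val, 0.0) + wt / total
    n_hist = hists["n_len"]
    score = gaussianity_score(list(n_hist), list(n_hist.values()))
    out: dict = dict(hists)
    out["_scores"] = {"n_len_gaussianity": score}
    return out


def summarize(values: Sequence[float], sd_convention: str = "population") -> SummaryStat:
    """Mean, SD (population n-divisor by default), min and max.

    The population convention is the replication default for printed
    ``mean +/- SD`` figures in this package's domain.
    """
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("summarize requires at least one value")
    if sd_convention == "population":
        sd = float(v.std(ddof=0))
    elif sd_convention == "sample":
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    else:
        raise ValueError("sd_convention must be 'population' or 'sample'")
    return SummaryStat(
        n=int(v.size), mean=float(v.mean()), sd=sd,
        min=float(v.min()), max=float(v.max()), sd_convention=sd_convention,
    )
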