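"""Ground-truth V(D)J repertoire and amplicon read simulation.

The simulator emulates the structure of per-donor, per-lineage TCR-beta
amplicon sequencing runs: a repertoire of unique rearranged junctions with
Zipf-skewed clonal abundances, paired-end reads spanning the junction,
compounded PCR substitution errors with clonal propagation of early-cycle
errors, independent per-base sequencing errors, and a configurable
fraction of two-parent chimeric reads.  Every operation is deterministic
given its seed.

A rearrangement is assembled exactly as

    full_nt = V[: len(V) - v_trim] + n_region + J[j_trim:] + C

so the junction (anchor-Cys codon through anchor-F/W codon, both
inclusive) is the interval the downstream annotation stage must recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .germline import GermlineLibrary, GermlineSegment, translate
from .merge import ReadPair, revcomp

__all__ = [
    "TrueClonotype",
    "TrueRepertoire",
    "ErrorModel",
    "ReadSet",
    "simulate_repertoire",
    "share_clonotypes",
    "simulate_reads",
    "mix_repertoires",
]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class TrueClonotype:
    """One simulated rearrangement with its junction decomposition."""

    v_id: str
    j_id: str
    v_trim: int
    j_trim: int
    n_region: str
    full_nt: str
    junction_nt: str
    junction_aa: str
    abundance: float
    productive: bool = True
    junction_start: int = 0  # offset of the junction on full_nt (= V anchor offset)

    @property
    def junction_interval(self) -> tuple[int, int]:
        return self.junction_start, self.junction_start + len(self.junction_nt)


@dataclass
class TrueRepertoire:
    donor_id: str
    lineage: str
    clonotypes: list[TrueClonotype]
    seed: int = 0

    def __post_init__(self) -> None:
        juncs = [c.junction_nt for c in self.clonotypes]
        if len(juncs) != len(set(juncs)):
            raise ValueError("junction_nt not unique within TrueRepertoire")

    def __len__(self) -> int:
        return len(self.clonotypes)

    @property
    def junctions(self) -> set[str]:
        return {c.junction_nt for c in self.clonotypes}

    @property
    def abundances(self) -> np.ndarray:
        return np.array([c.abundance for c in self.clonotypes])

    def check_normalized(self, tol: float = 1e-9) -> None:
        if self.clonotypes and abs(self.abundances.sum() - 1.0) > tol:
            raise ValueError("abundances do not sum to 1")

    def to_repertoire(self, copies_scale: float = 1000.0):
        """View the ground truth as an observed-style clonotype table.

        Copies are abundances scaled by ``copies_scale``; useful for
        running set-level comparisons directly on simulator output.
        """
        from .annotate import Clonotype, Repertoire

        clonos = [
            Clonotype(c.junction_nt, c.junction_aa, c.v_id, c.j_id,
                      c.abundance * copies_scale)
            for c in self.clonotypes
        ]
        rep = Repertoire(self.donor_id, self.lineage, clonos,
                         sum(c.copies for c in clonos))
        rep.renormalize()
        return rep


@dataclass(frozen=True)
class ErrorModel:
    """Noise configuration for read simulation.

    ``pcr_error_rate`` is per base per cycle; early-cycle errors are
    propagated to all PCR descendants of the molecule they arose in.
    ``chimera_rate`` is the fraction of reads built from two parent
    templates spliced inside the V region.
    """

    seq_error_rate: float = 1e-3
    pcr_error_rate: float = 1e-4
    pcr_cycles: int = 20
    chimera_rate: float = 0.005
    read_length: int = 100
    min_overlap: int = 30
    quality_char: str = "?"  # constant Phred+33 symbol, Q30

    def __post_init__(self) -> None:
        for r in (self.seq_error_rate, self.pcr_error_rate, self.chimera_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.read_length < self.min_overlap:
            raise ValueError("read_length too short for the overlap geometry")

    @classmethod
    def noiseless(cls, **kw) -> "ErrorModel":
        return cls(seq_error_rate=0.0, pcr_error_rate=0.0, chimera_rate=0.0, **kw)


@dataclass
class ReadSet:
    """Simulated paired reads plus the read-to-truth map.

    ``truth`` columns: read_id, parent_id (5' parent junction_nt),
    second_parent_id ('.' unless chimeric; then the 3' parent whose
    junction the read carries), junction_error_flag (True when any PCR or
    sequencing substitution fell inside the junction interval).
    """

    pairs: list[ReadPair]
    truth: pd.DataFrame

    def write_fastq(self, prefix: str | Path) -> tuple[Path, Path]:
        p1, p2 = Path(f"{prefix}_R1.fastq"), Path(f"{prefix}_R2.fastq")
        with open(p1, "w") as f1, open(p2, "w") as f2:
            for p in self.pairs:
                f1.write(f"@{p.read_id}\n{p.seq1}\n+\n{p.qual1}\n")
                f2.write(f"@{p.read_id}\n{p.seq2}\n+\n{p.qual2}\n")
        return p1, p2

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# repertoire generation
# ---------------------------------------------------------------------------


def _zipf_abundances(n: int, shape: float, rng: np.random.Generator) -> np.ndarray:
    """Rank-frequency power law f_r ~ r^-shape with mild lognormal jitter."""
    ranks = np.arange(1, n + 1, dtype=float)
    w = ranks ** (-shape) * np.exp(0.1 * rng.standard_normal(n))
    w /= w.sum()
    return rng.permutation(w)


def _sample_n_len(
    dist: tuple | Mapping[int, float], rng: np.random.Generator, n_max: int
) -> int:
    if isinstance(dist, Mapping):
        lens = np.array(sorted(dist))
        p = np.array([dist[k] for k in lens], float)
        return int(rng.choice(lens, p=p / p.sum()))
    kind = dist[0]
    if kind == "gaussian":
        _, mu, sigma = dist
        return int(np.clip(round(rng.normal(mu, sigma)), 0, n_max))
    raise ValueError(f"unknown n-length distribution {dist!r}")


def make_clonotype(
    v: GermlineSegment,
    j: GermlineSegment,
    v_trim: int,
    j_trim: int,
    n_region: str,
    c_seq: str = "",
    abundance: float = 1.0,
) -> TrueClonotype:
    """Assemble a clonotype from explicit junction parts (no sampling)."""
    if v.anchor_offset is None or j.anchor_offset is None:
        raise ValueError("V and J segments must carry located anchors")
    v_part = v.sequence[: len(v.sequence) - v_trim]
    j_part = j.sequence[j_trim:]
    full = v_part + n_region + j_part + c_seq
    jstart = v.anchor_offset
    jend = len(v_part) + len(n_region) + (j.anchor_offset - j_trim + 3)
    junction = full[jstart:jend]
    aa = translate(junction) if len(junction) % 3 == 0 else ""
    productive = bool(aa) and "*" not in aa and aa[:1] == "C" and aa[-1:] in ("F", "W")
    return TrueClonotype(
        v.segment_id, j.segment_id, v_trim, j_trim, n_region, full, junction, aa,
        abundance, productive, jstart,
    )


def simulate_repertoire(
    library: GermlineLibrary,
    n_clonotypes: int,
    abundance_shape: float = 1.0,
    trim_max: int = 6,
    n_len_distribution: tuple | Mapping[int, float] = ("gaussian", 6.0, 2.0),
    productive_only: bool = True,
    seed: int = 0,
    donor_id: str = "donor",
    lineage: str = "CD3",
    n_len_max: int = 15,
) -> TrueRepertoire:
    """Draw a ground-truth repertoire of unique rearranged junctions.

    V and J are drawn uniformly from the functional segments, coding-end
    trims uniformly from {0..trim_max}, the inserted-nucleotide length
    from ``n_len_distribution`` (nudged up by at most 2 nt to keep
    productive rearrangements in frame), and clonal abundances from a
    Zipf rank-frequency law with exponent ``abundance_shape``.
    """
    rng = np.random.default_rng(seed)
    vs = library.of_class("V", functional_only=True)
    js = library.of_class("J", functional_only=True)
    if n_clonotypes and (not vs or not js):
        raise ValueError("library must contain functional V and J segments")
    c_segs = library.of_class("C")
    c_seq = c_segs[0].sequence if c_segs else ""

    clonotypes: list[TrueClonotype] = []
    seen: set[str] = set()
    attempts, max_attempts = 0, 200 * max(n_clonotypes, 1)
    while len(clonotypes) < n_clonotypes:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not realize {n_clonotypes} unique junctions under the "
                f"configured trim/insert limits ({len(clonotypes)} found)"
            )
        v = vs[rng.integers(len(vs))]
        j = js[rng.integers(len(js))]
        v_trim = int(rng.integers(0, trim_max + 1))
        j_trim = int(rng.integers(0, trim_max + 1))
        n_len = _sample_n_len(n_len_distribution, rng, n_len_max)
        if productive_only:
            base = (len(v.sequence) - v_trim - v.anchor_offset) + (j.anchor_offset - j_trim + 3)
            n_len += (-(base + n_len)) % 3
        n_region = "".join(_BASES[b] for b in rng.integers(0, 4, n_len))
        ct = make_clonotype(v, j, v_trim, j_trim, n_region, c_seq)
        if productive_only and not ct.productive:
            continue
        if ct.junction_nt in seen:
            continue
        # keep junctions mutually >= 2 substitutions apart: the real
        # junction space is sparse enough that adjacent true clonotypes
        # are vanishingly rare, but a compact synthetic reference would
        # produce them by chance, making ground truth ambiguous for
        # denoising evaluation
        jn = ct.junction_nt
        if any(
            jn[:i] + b + jn[i + 1 :] in seen
            for i in range(len(jn))
            for b in _BASES
            if b != jn[i]
        ):
            continue
        seen.add(jn)
        clonotypes.append(ct)

    ab = _zipf_abundances(n_clonotypes, abundance_shape, rng) if n_clonotypes else []
    clonotypes = [replace(c, abundance=float(a)) for c, a in zip(clonotypes, ab)]
    rep = TrueRepertoire(donor_id, lineage, clonotypes, seed)
    rep.check_normalized()
    return rep


# ---------------------------------------------------------------------------
# sharing construction
# ---------------------------------------------------------------------------


def _regenerate_junction(
    ct: TrueClonotype,
    library: GermlineLibrary,
    taken: set[str],
    rng: np.random.Generator,
) -> TrueClonotype:
    """Resample a clonotype's insert to give it a globally unused junction."""
    v, j = library[ct.v_id], library[ct.j_id]
    c_segs = library.of_class("C")
    c_seq = c_segs[0].sequence if c_segs else ""
    n_len = len(ct.n_region) or 3  # empty inserts get a frame-neutral 3-mer
    for _ in range(500):
        n = "".join(_BASES[b] for b in rng.integers(0, 4, n_len))
        cand = make_clonotype(v, j, ct.v_trim, ct.j_trim, n, c_seq, ct.abundance)
        if cand.junction_nt in taken:
            continue
        if ct.productive and not cand.productive:
            continue
        return cand
    raise RuntimeError("could not regenerate a unique junction")


def share_clonotypes(
    repertoires: Sequence[TrueRepertoire],
    pairwise: Mapping[tuple[int, int], int] | None = None,
    triples: Mapping[tuple[int, int, int], int] | None = None,
    seed: int = 0,
    library: GermlineLibrary | None = None,
) -> list[TrueRepertoire]:
    """Impose an exact sharing design on independently simulated repertoires.

    ``pairwise[(i, j)]`` is the *total* designed ``|i ∩ j|`` (inclusive of
    any triple overlaps); ``triples[(i, j, k)]`` the designed triple
    intersection.  Sharing is created by overwriting recipient clonotypes
    with copies of donor clonotypes (the recipient slot keeps its own
    abundance, so each repertoire stays normalized).

    Independently simulated repertoires can collide by chance in the
    low-complexity part of junction space; when ``library`` is given such
    accidental overlaps are repaired by resampling the colliding
    clonotype's insert, so the realized intersections are *exactly* the
    designed ones.  Without a library an accidental collision raises.
    """
    rng = np.random.default_rng(seed)
    pairwise = {tuple(sorted(k)): v for k, v in (pairwise or {}).items()}
    triples = {tuple(sorted(k)): v for k, v in (triples or {}).items()}

    reps = [list(r.clonotypes) for r in repertoires]
    locked: list[set[int]] = [set() for _ in reps]

    if library is not None:
        taken: set[str] = set()
        for cts in reps:
            for si, ct in enumerate(cts):
                if ct.junction_nt in taken:
                    cts[si] = _regenerate_junction(ct, library, taken, rng)
                taken.add(cts[si].junction_nt)

    def _take_slots(ri: int, n: int) -> list[int]:
        free = [i for i in range(len(reps[ri])) if i not in locked[ri]]
        if len(free) < n:
            raise ValueError(f"sharing design infeasible: repertoire {ri} too small")
        picks = [free[i] for i in rng.permutation(len(free))[:n]]
        locked[ri].update(picks)
        return picks

    def _transplant(src_ct: TrueClonotype, ri: int, slot: int) -> None:
        reps[ri][slot] = replace(src_ct, abundance=reps[ri][slot].abundance)

    pair_budget = dict(pairwise)
    for (i, j, k), t in triples.items():
        for a, b in ((i, j), (i, k), (j, k)):
            if (a, b) in pair_budget:
                pair_budget[(a, b)] -= t
                if pair_budget[(a, b)] < 0:
                    raise ValueError("triple overlap exceeds a pairwise target")
        donors = _take_slots(i, t)
        for recip in (j, k):
            for d, slot in zip(donors, _take_slots(recip, t)):
                _transplant(reps[i][d], recip, slot)
        locked[i].update(donors)

    for (i, j), extra in pair_budget.items():
        if extra < 0:
            raise ValueError("triple overlap exceeds a pairwise target")
        donors = _take_slots(i, extra)
        for d, slot in zip(donors, _take_slots(j, extra)):
            _transplant(reps[i][d], j, slot)

    out = []
    for r, cts in zip(repertoires, reps):
        # transplanting cannot create duplicate junctions within one
        # repertoire unless the design itself collides; fail loudly if so
        out.append(TrueRepertoire(r.donor_id, r.lineage, cts, r.seed))

    # audit: undesigned intersections must be empty, designed ones exact
    for a in range(len(out)):
        for b in range(a + 1, len(out)):
            got = len(out[a].junctions & out[b].junctions)
            want = pairwise.get((a, b), 0)
            if got != want:
                raise ValueError(
                    f"sharing design not realized for pair ({a},{b}): "
                    f"{got} != {want} (accidental junction collision?)"
                )
    return out


def mix_repertoires(
    major: TrueRepertoire,
    minor: TrueRepertoire,
    minor_fraction: float,
    seed: int = 0,
) -> TrueRepertoire:
    """Blend two repertoires: abundances (1-f)*major + f*minor, renormalized.

    Emulates the cell-titration semiquantitation control in which a known
    number of cells of one population is spiked into another.
    """
    if not 0.0 <= minor_fraction <= 1.0:
        raise ValueError("minor_fraction must lie in [0, 1]")
    f = minor_fraction
    acc: dict[str, TrueClonotype] = {}
    for ct in major.clonotypes:
        acc[ct.junction_nt] = replace(ct, abundance=(1 - f) * ct.abundance)
    for ct in minor.clonotypes:
        if ct.junction_nt in acc:
            prev = acc[ct.junction_nt]
            acc[ct.junction_nt] = replace(prev, abundance=prev.abundance + f * ct.abundance)
        else:
            acc[ct.junction_nt] = replace(ct, abundance=f * ct.abundance)
    cts = [c for c in acc.values() if c.abundance > 0.0]
    total = sum(c.abundance for c in cts)
    if total > 0:
        cts = [replace(c, abundance=c.abundance / total) for c in cts]
    rep = TrueRepertoire(major.donor_id, f"{major.lineage}+{minor.lineage}", cts, seed)
    rep.check_normalized()
    return rep


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

_PCR_TREE_DEPTH = 10  # doublings tracked with explicit error inheritance


def _mutate(seq: bytearray, pos: int, rng: np.random.Generator) -> None:
    old = _BASES.index(chr(seq[pos]))
    seq[pos] = ord(_BASES[(old + int(rng.integers(1, 4))) % 4])


def _pcr_events(
    length: int, model: ErrorModel, rng: np.random.Generator
) -> list[tuple[int, int, int, int]]:
    """Sample inheritable PCR error events for one clonotype's amplification.

    Returns (cycle, ancestor, position, base_step) tuples; the event is
    carried by every final lineage slot whose ancestor at that cycle is
    ``ancestor``.
    """
    depth = min(model.pcr_cycles, _PCR_TREE_DEPTH)
    events = []
    for c in range(1, depth + 1):
        k = rng.binomial((1 << c) * length, model.pcr_error_rate)
        for _ in range(k):
            events.append(
                (c, int(rng.integers(1 << c)), int(rng.integers(length)),
                 int(rng.integers(1, 4)))
            )
    return events


def simulate_reads(
    repertoire: TrueRepertoire,
    n_reads: int,
    model: ErrorModel,
    seed: int = 0,
    read_prefix: str = "r",
) -> ReadSet:
    """Simulate paired-end amplicon reads from a ground-truth repertoire.

    Reads are drawn from clonotypes proportionally to abundance; mate 1 is
    the first ``read_length`` bases of the (error-bearing) template, mate
    2 the reverse complement of its last ``read_length`` bases, so each
    pair covers the junction and overlaps in the middle.  PCR errors are
    applied per cycle (with early-cycle errors shared by descendant
    molecules) before sequencing errors.
    """
    rng = np.random.default_rng(seed)
    cts = repertoire.clonotypes
    if n_reads and not cts:
        raise ValueError("cannot draw reads from an empty repertoire")

    pairs: list[ReadPair] = [None] * n_reads  # type: ignore[list-item]
    rows: list[tuple[str, str, str, bool]] = [None] * n_reads  # type: ignore[list-item]

    if n_reads == 0:
        return ReadSet([], pd.DataFrame(columns=[
            "read_id", "parent_id", "second_parent_id", "junction_error_flag"]))

    ab = repertoire.abundances
    ab = ab / ab.sum()
    n_chim = rng.binomial(n_reads, model.chimera_rate) if len(cts) > 1 else 0
    chim_idx = set(rng.choice(n_reads, size=n_chim, replace=False).tolist()) if n_chim else set()

    # assign a clonotype to every non-chimeric read
    parent_of = rng.choice(len(cts), size=n_reads, p=ab)

    L = model.read_length
    qconst = model.quality_char

    def _emit(idx: int, template: str, parent: TrueClonotype,
              second: str, tpl_err_pos: list[int]) -> None:
        tl = len(template)
        r1 = template[: min(L, tl)]
        r2 = revcomp(template[max(0, tl - L) :])
        b1, b2 = bytearray(r1.encode()), bytearray(r2.encode())
        e1 = rng.binomial(len(b1), model.seq_error_rate)
        e2 = rng.binomial(len(b2), model.seq_error_rate)
        err_pos = list(tpl_err_pos)
        for _ in range(e1):
            p = int(rng.integers(len(b1)))
            _mutate(b1, p, rng)
            err_pos.append(p)
        for _ in range(e2):
            p = int(rng.integers(len(b2)))
            _mutate(b2, p, rng)
            err_pos.append(tl - 1 - p)
        js, je = parent.junction_interval
        flag = any(js <= p < je for p in err_pos)
        rid = f"{read_prefix}{idx:08d}"
        pairs[idx] = ReadPair(rid, b1.decode(), b2.decode(),
                              qconst * len(b1), qconst * len(b2))
        rows[idx] = (rid, parent.junction_nt, second, flag)

    # --- chimeric reads -----------------------------------------------------
    for idx in sorted(chim_idx):
        a = int(rng.choice(len(cts), p=ab))
        b = int(rng.choice(len(cts), p=ab))
        for _ in range(10):
            if b != a:
                break
            b = int(rng.choice(len(cts), p=ab))
        ca, cb = cts[a], cts[b]
        # junction-proximal breakpoint inside the shared pre-anchor V region
        bp_hi = min(ca.junction_start, cb.junction_start)
        bp = int(rng.integers(min(20, bp_hi - 1), bp_hi))
        template = ca.full_nt[:bp] + cb.full_nt[bp:]
        _emit(idx, template, cb, ca.junction_nt, [])

    # --- clonal reads with PCR lineage errors -------------------------------
    depth = min(model.pcr_cycles, _PCR_TREE_DEPTH)
    late_cycles = model.pcr_cycles - depth
    by_ct: dict[int, list[int]] = {}
    for idx in range(n_reads):
        if idx in chim_idx:
            continue
        by_ct.setdefault(int(parent_of[idx]), []).append(idx)

    for ci in sorted(by_ct):
        ct = cts[ci]
        tl = len(ct.full_nt)
        events = _pcr_events(tl, model, rng) if model.pcr_error_rate > 0 else []
        slot_cache: dict[int, list[tuple[int, int]]] = {}
        late_p = 1.0 - (1.0 - model.pcr_error_rate) ** late_cycles if late_cycles else 0.0
        for idx in by_ct[ci]:
            slot = int(rng.integers(1 << depth)) if events else 0
            if events:
                inherited = slot_cache.get(slot)
                if inherited is None:
                    inherited = [
                        (pos, step) for c, anc, pos, step in events
                        if (slot >> (depth - c)) == anc
                    ]
                    slot_cache[slot] = inherited
            else:
                inherited = []
            n_late = rng.binomial(tl, late_p) if late_p else 0
            if inherited or n_late:
                tpl = bytearray(ct.full_nt.encode())
                err_pos = []
                for pos, step in inherited:
                    old = _BASES.index(chr(tpl[pos]))
                    tpl[pos] = ord(_BASES[(old + step) % 4])
                    err_pos.append(pos)
                for _ in range(n_late):
                    p = int(rng.integers(tl))
                    _mutate(tpl, p, rng)
                    err_pos.append(p)
                _emit(idx, tpl.decode(), ct, ".", err_pos)
            else:
                _emit(idx, ct.full_nt, ct, ".", [])

    truth = pd.DataFrame(
        rows, columns=["read_id", "parent_id", "second_parent_id", "junction_error_flag"]
    )
    return ReadSet(pairs, truth)
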