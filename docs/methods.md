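# Methods

This note documents the models, algorithms and parameter choices behind
`trirep`, what the synthetic-data generator does and does not emulate,
and the package's known limitations.

## 1. Germline reference and anchors

The packaged reference (`src/trirep/data/trb_synthetic.fasta`) is
**synthetic**: 12 V segments (72 nt), 6 J segments (48 nt) and one C
segment (30 nt) of random stop-free codons, constrained so that each V
carries exactly one `Y[YFLI]C` motif with its Cys codon 12 nt before the
3′ end, each J exactly one `[FW]GXGT` motif with its F/W codon at offset
18, and no 12-mer is shared between segments (so seeded alignment is
unambiguous). It stands in for an IMGT-style catalog at a scale where
whole simulations run in seconds; a loader for real IMGT-formatted FASTA
(`load_germline_fasta`) is provided but has not been exercised against
live IMGT downloads.

Anchor location scans the three forward frames only (amplicon
orientation is fixed by primer design; reverse-complement inputs are
handled upstream by the annotator). For V the 3′-most motif occurrence
wins, because the motif marks the segment's 3′ end; for J the 5′-most.
The potential V–J combination count is a property of the loaded
reference (12 × 6 = 72 for the packaged one), never a constant: coverage
percentages accept an explicit catalog size for references of any scale.

D segments are not modeled as alignable entities; D-derived nucleotides
are part of the simulator's insert region. Rearrangement analyses here
never report D calls, and short D remnants are not reliably assignable
at these read lengths anyway.

## 2. The simulator

A ground-truth clonotype is assembled exactly as

```
full_nt = V[: len(V) − v_trim] + n_region + J[j_trim:] + C
```

with `v_trim, j_trim ~ Uniform{0..6}` and the insert length drawn from a
configurable law — Gaussian N(6, 2²) rounded and clipped to [0, 15] by
default, or an arbitrary histogram (e.g. bimodal, to emulate the
non-Gaussian spectratype shapes some lineages show). For productive-only
repertoires the insert length is nudged up by at most 2 nt to keep the
junction in frame, and insert bases are resampled until the junction
translation is stop-free.

**Abundances** follow a Zipf rank-frequency law `f_r ∝ r^(−s)` with mild
lognormal jitter (σ = 0.1 in log space) and a random rank-to-clonotype
assignment. The default exponent is s = 1.0, the classic Zipf slope and
a standard description of clone-size skew in bulk repertoires; it is
configurable per lineage.

**Junction sparsity.** Junctions within one repertoire are kept mutually
≥ 2 substitutions apart. Real junction space (tens of random insert
bases against a full V/J catalog) is sparse enough that two independent
rearrangements landing one substitution apart is vanishingly rare, but
the compact synthetic reference would produce such neighbors by chance —
and a true clonotype one substitution from a dominant same-V/J clone is
inherently indistinguishable from its error satellite, making ground
truth ambiguous. The constraint restores the sparsity the error-model
evaluation presumes.

**Reads.** Each pair covers the whole amplicon from both ends: mate 1 is
the first `read_length` (default 100) bases, mate 2 the reverse
complement of the last `read_length` bases, so the pair overlaps in the
middle (≥ 30 nt for the packaged geometry) and always spans the
junction. Qualities are a constant Q30 symbol; quality information is
used only to resolve merge disagreements.

**PCR errors with clonal propagation.** Substitutions are applied per
cycle *before* sequencing errors. The first `min(cycles, 10)` doublings
are simulated as an explicit lineage tree: error events are drawn per
cycle (Binomial over molecules × bases), attached to a random ancestor,
and inherited by every final lineage slot descending from it; each read
then samples a uniform lineage slot. Later cycles contribute independent
per-read substitutions at the compounded rate. Early-cycle errors can
thus reach copy numbers comparable to their parent clone — exactly the
expanded artifacts a copy-count threshold alone cannot remove, and the
reason the absorption filter exists. The vendor's actual artifact
pipeline is unpublished; this error model and the entire filter cascade
(§4) are this package's own explicit constructions.

**Chimeras.** A configurable read fraction (default 0.5 %) is built from
two abundance-weighted parents spliced at a uniform breakpoint in the
junction-proximal pre-anchor V region. Such a read carries the 3′
parent's junction with a mosaic V block. Consequences: chimeras do not
create novel junction sequences under this breakpoint model (most are
rejected at annotation for degraded V-block identity; the rest join the
3′ parent's clonotype as a minority), so the mosaic filter's prey is
exercised by constructed majority-chimeric fixtures in the tests rather
than arising spontaneously at the default rate.

**Truth map.** One row per read: parent junction, second parent (for
chimeras), and a flag marking whether any substitution fell inside the
junction interval. Benchmark scoring uses the true junction *set*:
a recovered junction is error-derived iff it is not in the ground truth.

**Sharing construction.** `share_clonotypes` imposes exact designed
intersections (pairwise totals, optional triple overlaps) by
transplanting donor clonotypes into recipient slots that keep their own
abundances, then audits the result by set arithmetic. Accidental
collisions between independently simulated repertoires — common in the
low-complexity (short-insert) corner of the synthetic junction space —
are repaired by resampling the colliding insert when the germline
library is supplied; otherwise the audit raises.

## 3. Merging and annotation

**Merging** scores every suffix(mate 1)/prefix(revcomp mate 2) overlap
with match +1, mismatch −1, free end gaps, and no internal gaps (the
error model is substitution-only, so indel tolerance would only add
failure modes). An overlap is admissible if it is ≥ `min_overlap`
(default 30) and its mismatch fraction is ≤ `max_mismatch_rate` (default
0.1); among admissible overlaps the highest score wins, ties preferring
the longer overlap. Disagreeing bases resolve to the higher-quality
base, mate 1 winning exact ties; agreed bases keep the max quality.
Unmerged pairs are dropped and logged, not rescued single-ended. A
vectorized batch path handles uniform-length files and is
property-tested equal to the per-pair implementation, which is itself
property-tested against a brute-force all-offsets oracle.

**Annotation** is a seeded ungapped diagonal aligner: exact 12-mers vote
for (segment, diagonal) pairs; the top diagonals are rescored by full
ungapped comparison (+1/−1). There is no external mapper dependency —
"default parameters" of an external tool would not be a reproducible
contract, and for substitution-only data the ungapped diagonal is the
exact alignment. Both strands are tried and reads canonicalized to V→J
orientation. Acceptance requires the germline block *outside* the
junction to reach 0.85 identity on both sides (with minimum informative
block lengths of 18 nt for V and 12 nt for J) and the anchor codons to
be covered. CDR3 boundaries are projected from germline anchor
coordinates through the alignment diagonal; the junction includes both
anchor residues. Extraction rejects, with typed reasons, junctions whose
anchors are missing or mutated (the projected codon must still translate
to C / F / W), out-of-frame junctions, and in-frame stops.

**Decomposition** splits a junction into (v_trim, j_trim, insert) by
greedy maximal exact matching from both ends against the germline V tail
and J head. When an insert base coincides with the base trimming
removed, greediness attributes it to the germline: recovered trims never
exceed true trims and the recovered insert never exceeds the true one
(bias bounded by a geometric(3/4) overrun per end, < 0.7 nt on average);
overlapping matches on very short junctions split the tie toward V.

**Clonotype tables** are keyed by junction nucleotide sequence, with an
amino-acid-level view available throughout (`level="aa"`), since
uniqueness can be defined at either level; the nucleotide level is the
default. Discordant V/J calls for one junction resolve to the
plurality call, ties breaking lexicographically. Tables round-trip
through AIRR-rearrangement-style TSV (sequence_id, v_call, j_call,
junction, junction_aa, productive, duplicate_count, frequency).

## 4. The filter cascade

Five checkpoints, fixed order, chained accounting; every stage is an
explicit documented algorithm (the stage *names* and their intent follow
standard artifact taxonomy; the implementations are this package's own):

1. **Sequencing-error filter.** A clonotype within Hamming distance ≤ 1
   (configurable) of a same-V/J clonotype with ≥ 10× its copies is
   *absorbed* into it — copies added, not deleted, conserving read mass
   as standard denoising practice. Absorption iterates to a fixed point,
   making the stage idempotent.
2. **Mosaic filter.** A read carries a mosaic signature when the two
   halves of its pre-anchor V block best-align to different V segments
   and the split assignment beats re-scoring both halves against the
   read's single assigned V by ≥ 6 score points. Clonotypes whose
   supporting copies are majority-mosaic are removed.
3. **Amplification filter.** Per-V read shares exceeding
   median + 5×MAD are down-weighted to the median share (copies
   rescaled, nothing removed): uneven multiplex amplification distorts
   quantity, not identity. No-op below 3 distinct V segments.
4. **Reference filter.** Reads whose V or J germline block outside the
   junction falls below 0.9 identity are discarded; clonotype copies
   deflate by the per-junction retained fraction. The returned
   annotation set reflects the discards, so re-running the cascade on
   its own output is a no-op.
5. **Frequency filter.** Clonotypes with copies ≤ 1 are discarded —
   singleton variants are noise-dominated. The threshold applies to
   post-absorption copies: absorption consolidates genuine reads first,
   so a true clone seen once as itself and once as a corrected satellite
   is not lost.

Copies are integers in normal operation but become floats after the
amplification/reference down-weighting; the frequency threshold compares
numerically.

Under the default benchmark (1,000 clonotypes, 2×10⁵ pairs, sequencing
error 10⁻³/base, PCR 10⁻⁴/base × 20 cycles, 0.5 % chimeras) the cascade
removes ≥ 99 % of error-derived unique junctions at recall 1.0; the
surviving handful are mostly early-cycle PCR expansions whose copy
numbers approach their parents', which no abundance-ratio rule can
separate without losing real minority variants.

## 5. Statistics

* `summarize` defaults to the **population** (n-divisor) SD: printed
  "mean ± SD" panels in this domain are consistent with that convention
  for small per-donor panels; the sample convention is a flag away.
* The **Gaussianity score** is `1 − sup|F̂(x) − Φ((x+½−μ)/σ)|`, a
  continuity-corrected KS-style distance between the frequency-weighted
  discrete CDF of an integer observable (CDR3 aa length, insert length)
  and the moment-matched normal. It is a continuous score, deliberately
  not a hypothesis test — no p-value is asserted. Degenerate
  single-support spectra score 0 by convention.
* V–J coverage reports `100·observed/potential` rounded to one decimal,
  with the potential count taken from the reference (or given
  explicitly).
* Diversity indices not used by the analyses (Shannon, Gini, clonality)
  are intentionally out of scope.

## 6. Comparisons

All sharing analyses are presence/absence on junction sets; frequencies
are ignored because variant counts, not mass overlap, are the reported
quantities. Percentages are per-side (denominator = the perspective
sample's own unique-variant count). Sharing defaults to nucleotide-level
identity for consistency with the clonotype key; public-clonotype counts
are sensitive to the nt/aa choice, so the level is an explicit flag on
every operation. `turnover` reports the after-state retention
`100·|before ∩ after|/|after|` plus lost/gained sets.

## 7. Diversity tree plot

Mosaic layout: column widths ∝ V-marginal frequency mass, cell heights
within a column ∝ the cell's share of the column, so cell area ∝ cell
mass. Spot area ∝ clonal frequency with one global constant fixed by an
area budget (default 15 % of the canvas). Within a cell, spots pack on a
deterministic golden-angle spiral ordered by descending frequency — the
packing is a design choice; published figures of this kind do not
specify one, and cosmetic fidelity is not asserted. Colors are a
bijective scramble of 24-bit RGB, unique per clonotype for ≥ 10⁵ spots.
`nominal_radius` preserves exact proportionality; the rendered radius
applies a visibility floor (default 0.2 px) and, in degenerately thin
cells, a fit clamp — both recorded in a sidecar log, so proportionality
claims are auditable before those adjustments. SVG output is plain text
and byte-stable for identical layouts.

## 8. Problem sizes and determinism

The benchmark scales were chosen to exercise every mechanism (PCR
expansion needs depth; titration needs a resolvable 1 % spike) while
keeping any single experiment in the minutes range on one CPU: 2×10⁵
pairs / 1,000 clonotypes for the cascade and zero-noise benchmarks,
4 × 5×10⁴ pairs for the titration (400 + 100 clonotypes), 2×10⁴-pair
runs in the unit suite. Every stochastic component takes an explicit
seed (numpy `default_rng`); identical seeds and parameters give
bit-identical repertoires, reads, tables and SVGs.

## 9. What passing tests do and do not show

The simulator reproduces the *statistical structure* the analysis
assumes — clonal skew, junction diversity, substitution noise, expanded
PCR artifacts, chimeras, designed sharing — on a miniature germline
catalog. It does not emulate: indel errors (the assay analysis is
substitution-dominated; the merger and aligner are deliberately
indel-free), quality-score degradation profiles (constant Q30 unless
configured), primer-specific amplification bias beyond the per-V
outlier model, allele-level reference variation, or real IMGT segment
homology (real V segments share family-level identity that would stress
V-call disambiguation harder than this reference does). Pipeline
performance on real HiSeq data — particularly V-call accuracy among
homologous family members and chimera detection under realistic
template-switch breakpoint distributions — is therefore not certified
by this suite; headline dataset-scale counts from any particular study
(millions of unique variants from ~4×10⁷ reads) require the original
deposited data and are out of scope by design.
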