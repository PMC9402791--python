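"""Load the packaged germline reference and inspect its CDR3 anchors.

Every functional V segment carries a Y[YFLI]C motif whose cysteine codon
opens the CDR3 junction; every J segment carries an [FW]GXGT motif whose
F/W codon closes it.  The product of functional V and J sets is the
space of potential V-J combinations a repertoire can use.
"""

from trirep import builtin_library, enumerate_vj_combinations
from trirep.germline import translate

lib = builtin_library()
print(f"library {lib.name!r}: {len(lib.v_segments)} V, {len(lib.j_segments)} J, "
      f"{len(lib.of_class('C'))} C")

for seg in list(lib.v_segments)[:3] + list(lib.j_segments)[:2]:
    print(f"  {seg.segment_id:7s} anchor at {seg.anchor_offset:3d} "
          f"codon {seg.anchor_codon} -> {translate(seg.anchor_codon)}")

count, _ = enumerate_vj_combinations(lib, functional_only=True)
print(f"potential V-J combinations: {count}")
# The count is the denominator for repertoire V-J coverage percentages:
# a sample using every combination would report 100% coverage.
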