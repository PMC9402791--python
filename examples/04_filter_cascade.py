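"""The five-checkpoint artifact filter cascade on noisy reads.

Sequencing and PCR substitutions inflate the unfiltered clonotype table
several-fold with error-derived junctions; the cascade removes them
while keeping the true clonotypes.  Scored against the simulator truth.
"""

from trirep.experiments import smart_cascade_efficacy

out = smart_cascade_efficacy(seed=42, n_clonotypes=1000, n_reads=200_000)

print("per-stage accounting:")
print(out["result"].cascade.report.to_frame().to_string(index=False))
print()
print(f"error-derived unique junctions before filtering: "
      f"{out['n_error_junctions_unfiltered']}")
print(f"surviving after the cascade: {out['n_error_junctions_final']}")
print(f"removed: {out['pct_error_junctions_removed']:.2f}%  "
      f"(true-clonotype recall {out['true_recall']:.3f})")
# the cascade targets > 99% artifact removal at >= 0.95 recall
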