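"""Reproducible in-silico experiments composed from the pipeline stages.

These functions define the package's benchmark conditions — clonotype
counts, read depths, noise levels — in one place, so the test suite, the
acceptance script and the examples all run the same experiments.
"""

from __future__ import annotations

import numpy as np

from .filters import FilterConfig
from .germline import builtin_library
from .pipeline import PipelineResult, process_pairs
from .simulate import ErrorModel, mix_repertoires, simulate_reads, simulate_repertoire

__all__ = ["smart_cascade_efficacy", "zero_noise_identity", "titration_curve"]


def smart_cascade_efficacy(
    seed: int = 1,
    n_clonotypes: int = 1000,
    n_reads: int = 200_000,
    model: ErrorModel | None = None,
) -> dict:
    """Measure the artifact-removal efficacy of the five-stage cascade.

    Simulates a repertoire with the default noise model (substitution
    sequencing error 1e-3/base, PCR error 1e-4/base over 20 cycles with
    error propagation, 0.5% chimeric reads), runs the full pipeline, and
    scores against the simulator's true junction set:

    * ``pct_error_junctions_removed`` — percentage of erroneous unique
      junction sequences present in the unfiltered clonotype table that
      the cascade eliminated;
    * ``true_recall`` — fraction of true clonotypes surviving the
      cascade.
    """
    lib = builtin_library()
    model = model or ErrorModel()
    rep = simulate_repertoire(lib, n_clonotypes, seed=seed)
    reads = simulate_reads(rep, n_reads, model, seed=seed + 1)
    result = process_pairs(reads.pairs, lib)

    truth = rep.junctions
    unfiltered = result.unfiltered.junctions
    final = result.repertoire.junctions
    err_before = unfiltered - truth
    err_after = final - truth
    pct_removed = (
        100.0 * len(err_before - final) / len(err_before) if err_before else 100.0
    )
    return {
        "n_reads": n_reads,
        "n_true_clonotypes": n_clonotypes,
        "n_error_junctions_unfiltered": len(err_before),
        "n_error_junctions_final": len(err_after),
        "pct_error_junctions_removed": pct_removed,
        "true_recall": len(final & truth) / len(truth),
        "result": result,
        "true_repertoire": rep,
        "truth_map": reads.truth,
    }


def zero_noise_identity(
    seed: int = 1, n_clonotypes: int = 1000, n_reads: int = 200_000
) -> dict:
    """End-to-end run at zero error rates; clonotype recovery should be exact."""
    lib = builtin_library()
    rep = simulate_repertoire(lib, n_clonotypes, seed=seed)
    reads = simulate_reads(rep, n_reads, ErrorModel.noiseless(), seed=seed + 1)
    result = process_pairs(reads.pairs, lib)
    truth = rep.junctions
    got = result.repertoire.junctions
    return {
        "precision": len(got & truth) / len(got) if got else 0.0,
        "recall": len(got & truth) / len(truth),
        "result": result,
    }


def titration_curve(
    seed: int = 1,
    fractions: tuple[float, ...] = (0.01, 0.05, 0.1, 0.2),
    n_major: int = 400,
    n_minor: int = 100,
    n_reads: int = 50_000,
    model: ErrorModel | None = None,
) -> dict:
    """Semiquantitation control: recover a spiked-in minor repertoire.

    A minor repertoire is mixed into a major one at each input fraction
    f; the pipeline-recovered summed frequency of minor-exclusive
    clonotypes should grow linearly with f.  Returns the recovered
    frequencies and their Pearson correlation with the input fractions.
    """
    lib = builtin_library()
    model = model or ErrorModel()
    major = simulate_repertoire(lib, n_major, seed=seed, lineage="CD15")
    minor = simulate_repertoire(lib, n_minor, seed=seed + 1000, lineage="CD3")
    minor_only = minor.junctions - major.junctions

    recovered = []
    for i, f in enumerate(fractions):
        mixed = mix_repertoires(major, minor, f, seed=seed + i)
        reads = simulate_reads(mixed, n_reads, model, seed=seed + 10 + i)
        result = process_pairs(reads.pairs, lib)
        rec = sum(
            c.frequency for c in result.repertoire.clonotypes
            if c.junction_nt in minor_only
        )
        recovered.append(rec)

    x = np.asarray(fractions)
    y = np.asarray(recovered)
    r = float(np.corrcoef(x, y)[0, 1]) if len(x) > 1 else float("nan")
    return {"fractions": list(fractions), "recovered": recovered, "pearson_r": r}
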