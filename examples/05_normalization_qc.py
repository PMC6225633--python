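"""Count filtering, TMM normalization and MDS quality control.

The MDS plot uses leading log-fold-change distances; in polysome
experiments dimension 1 typically separates polysome-derived from total
cytoplasmic samples.
"""

from translatomix import (
    SimulationSpec,
    filter_min_reads,
    log_cpm,
    mds_coordinates,
    simulate_study,
    tmm_factors,
)

study = simulate_study(SimulationSpec(n_genes=1000, n_fractions=2,
                                      n_replicates=3, seed=5))

tx_samples = [s for s, (c, f) in study.design.assignment.items() if f == 0]
filtered = filter_min_reads(study.matrix, threshold=256, subset=tx_samples)
print(f"{study.matrix.n_genes} genes -> {filtered.n_genes} with > 256 reads "
      "in every total-RNA sample")

factors = tmm_factors(filtered)
print("\nTMM scale factors (geometric mean 1):")
print(factors.round(3).to_string())

coords = mds_coordinates(log_cpm(filtered, factors), top=500)
print("\nMDS coordinates (dim1/dim2):")
print(coords.round(2).to_string())
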