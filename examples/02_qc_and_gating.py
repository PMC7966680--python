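"""QC, CLR normalization, double-positive gating and the paired
frequency-shift test.

Cells outside the UMI/gene/ADT/mito bounds are removed, surface-marker
counts are CLR-normalized, cells are gated ITGA4+/ITGB1+ with automatic
mixture-midpoint thresholds, and per-cluster double-positive frequencies
are compared between treated and untreated time points with paired
t-tests (BH-adjusted). Only the homing cluster should come out
significant."""

from homingtrack import (
    CohortSimConfig,
    GateDefinition,
    clr_adt,
    filter_cells,
    filter_genes,
    frequency_table,
    gate_double_positive,
    paired_frequency_shift,
    simulate_cohort,
)

cells, adt, truth = simulate_cohort(CohortSimConfig(seed=1))
cells, adt, report = filter_cells(cells, adt)
cells = filter_genes(cells)
print("QC report (non-exclusive removal counts):")
print(report.to_string(index=False))
print(f"retained {report.attrs['n_retained']}/{report.attrs['n_input']} cells\n")

flags = gate_double_positive(clr_adt(adt), GateDefinition())
print(f"gate thresholds (CLR scale): {flags.attrs['thresholds']}")
shift = paired_frequency_shift(frequency_table(cells, flags))
print("\nper-cluster treated-minus-untreated double-positive shift:")
print(shift.sort_values("padj").to_string(index=False))
# mean_delta ~ +0.2 with padj << 0.05 for T09; other clusters are null.
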