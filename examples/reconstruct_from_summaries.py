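"""Rebuild individual-level cytokine values from published mean +/- SD/SEM.

Places n evenly spaced percentiles inside the central 99.7% of a normal
distribution and maps them through the inverse CDF. The published mean is
recovered exactly; the SD comes back slightly shrunk by the truncation, a
documented constant rather than noise.
"""

from cytoms import (
    ReconstructionConfig,
    SummaryStat,
    grid_sd_shrinkage,
    reconstruct_cohort,
)

stats = [
    SummaryStat("IL2", "MS", "usa_like", mean=4.8, dispersion=0.21,
                dispersion_kind="SEM", n=120),
    SummaryStat("TNFa", "MS", "usa_like", mean=9.6, dispersion=3.1,
                dispersion_kind="SD", n=120),
    SummaryStat("IL2", "control", "usa_like", mean=3.1, dispersion=0.18,
                dispersion_kind="SEM", n=60),
    SummaryStat("TNFa", "control", "usa_like", mean=7.2, dispersion=2.8,
                dispersion_kind="SD", n=60),
]

table = reconstruct_cohort(stats, ReconstructionConfig(seed=1))
ms = table[table.status == "MS"]

print(f"reconstructed {len(table)} subjects (120 MS / 60 controls)")
print(f"IL2 MS mean: published 4.80, reconstructed {ms['IL2'].mean():.6f}")
sd_in = 0.21 * 120 ** 0.5  # SEM converted to SD
print(f"TNFa MS SD: published 3.10, reconstructed {ms['TNFa'].std(ddof=0):.4f} "
      f"(expected shrinkage factor {grid_sd_shrinkage(120):.4f})")
print("\nMeans are preserved to machine precision; SDs shrink by a known "
      "deterministic constant because the outer 0.3% of mass is excluded.")
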