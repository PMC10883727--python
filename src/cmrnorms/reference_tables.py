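"""Published diagnostic-accuracy medians used as comparison inputs.

These are the study's printed median (Q1-Q3) accuracies, in percent,
for each scenario of the default grid. They are inputs for
:func:`cmrnorms.cli.compare_to_reference`, never outputs of this
package.
"""

from __future__ import annotations

__all__ = ["REFERENCE_ACCURACY"]

#: scenario name -> (median %, Q1 %, Q3 %)
REFERENCE_ACCURACY: dict[str, tuple[int, int, int]] = {
    # same scanner, mixed-balanced 15-subject ranges
    "trio_t1_male_vs_trio_mixed_balanced": (93, 88, 96),
    "trio_t1_female_vs_trio_mixed_balanced": (97, 97, 97),
    "prisma_t1_male_vs_prisma_mixed_balanced": (96, 96, 100),
    "prisma_t1_female_vs_prisma_mixed_balanced": (96, 88, 96),
    "prisma_t2_male_vs_prisma_mixed_balanced": (92, 88, 96),
    "prisma_t2_female_vs_prisma_mixed_balanced": (96, 88, 100),
    # same scanner, opposite-sex ranges
    "trio_t1_male_vs_trio_female_only": (81, 74, 86),
    "trio_t1_female_vs_trio_male_only": (86, 74, 94),
    "prisma_t1_male_vs_prisma_female_only": (64, 52, 72),
    "prisma_t1_female_vs_prisma_male_only": (64, 48, 64),
    "prisma_t2_male_vs_prisma_female_only": (88, 88, 92),
    "prisma_t2_female_vs_prisma_male_only": (84, 84, 88),
    # cross-scanner, mixed-balanced ranges (T1 only)
    "trio_t1_male_vs_prisma_mixed_balanced": (86, 82, 91),
    "trio_t1_female_vs_prisma_mixed_balanced": (51, 40, 54),
    "prisma_t1_male_vs_trio_mixed_balanced": (56, 28, 76),
    "prisma_t1_female_vs_trio_mixed_balanced": (100, 96, 100),
    # cross-scanner, opposite-sex ranges (T1 only)
    "trio_t1_male_vs_prisma_female_only": (84, 81, 86),
    "trio_t1_female_vs_prisma_male_only": (12, 8, 16),
    "prisma_t1_male_vs_trio_female_only": (12, 12, 16),
    "prisma_t1_female_vs_trio_male_only": (100, 100, 100),
}
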