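"""Small published/constructed worked-example inputs.

These are *inputs* to worked examples — a printed scaffold summary of the
YerA41 phage genome assembly, its published temporal class counts, and a
synthetic one-step growth curve shaped like the reported experiment — used by
the documentation, tests and the acceptance script to exercise the summary
arithmetic without re-sequencing anything.
"""

from __future__ import annotations

#: (scaffold id, length bp, GC %) of the nine assembled YerA41 scaffolds.
YERA41_SCAFFOLDS: list[tuple[str, int, float]] = [
    ("scaffold_1", 42_987, 34.5),
    ("scaffold_2", 27_377, 31.6),
    ("scaffold_3", 26_591, 31.7),
    ("scaffold_4", 15_134, 32.0),
    ("scaffold_5", 11_502, 32.8),
    ("scaffold_6", 8_240, 29.6),
    ("scaffold_7", 5_287, 28.9),
    ("scaffold_8", 3_672, 29.6),
    ("scaffold_9", 2_506, 29.6),
]

#: published temporal class sizes of the 201 predicted YerA41 genes
YERA41_CLASS_COUNTS: dict[str, int] = {"early": 47, "middle": 101, "late": 51,
                                       "artifact": 2}
YERA41_N_GENES = 201  # percentages are reported over the 201 predicted genes

#: synthetic one-step growth curve (PFU/mL) mirroring the reported YerA41
#: kinetics: intracellular particles appear by 30 min, lysis starts by 40 min,
#: a 20-min rise, and a ~138-fold plateau. Times in minutes; the raw scale
#: (2e5 infected cells) divides out on normalization.
YERA41_GROWTH_CURVE: dict[str, list[float]] = {
    "time_min": [0, 10, 20, 30, 40, 50, 60, 70, 80, 90],
    "pfu_untreated": [2.0e5, 2.0e5, 2.0e5, 2.2e5, 7.0e5, 1.2e7,
                      2.76e7, 2.76e7, 2.80e7, 2.72e7],
    "pfu_chloroform": [2.0e3, 2.0e3, 4.0e3, 5.0e5, 6.0e6, 1.6e7,
                       2.76e7, 2.76e7, 2.80e7, 2.72e7],
}
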