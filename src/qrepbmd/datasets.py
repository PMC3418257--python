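"""Published summary inputs for the RUNX2 Q-repeat carrier analysis.

These are the printed per-carrier characteristics and per-cohort carrier
counts from the multi-cohort screen of postmenopausal/adult women that this
package models.  They are inputs, not outputs: the femoral-neck Z-scores
below are the only per-subject carrier data published, and the pooled
femoral-neck deficit is recomputed from them at run time.
"""

from __future__ import annotations

import pandas as pd

#: Per-carrier records: allele, age (years), weight (kg), height (cm) and
#: within-study age-weight^-1 adjusted femoral-neck BMD Z-score.  Rows for
#: monozygotic twin pairs are already pair-averaged (one genetically unique
#: individual per row).
CARRIER_TABLE: pd.DataFrame = pd.DataFrame(
    [
        ("15Q", 41, 69, 159, -0.33),
        ("16Q", 30, 79, 171, -1.42),
        ("16Q", 45, 56, 166, 0.07),
        ("16Q", 47, 68, 174, -1.52),
        ("16Q", 49, 66, 161, -1.07),
        ("16Q", 69, 71, 165, -0.15),
        ("16Q", 70, 56, 152, -0.34),
        ("16Q", 72, 80, 168, 0.89),
        ("16Q", 75, 71, 165, -1.69),
        ("16Q", 76, 52, 156, -0.91),
        ("16Q", 78, 61, 152, -0.70),
        ("16Q", 79, 65, 167, -0.31),
        ("16Q", 85, 70, 147, -0.13),
        ("18Q", 65, 66, 161, -0.21),
        ("18Q", 74, 69, 156, -0.24),
        ("30Q", 39, 97, 161, -1.34),
        ("30Q", 48, 62, 160, -1.37),
        ("30Q", 72, 57, 161, 0.07),
        ("30Q", 74, 54, 162, -0.02),
        ("30Q", 87, 50, 155, -1.18),
    ],
    columns=["allele", "age", "weight", "height", "z_fn"],
)

#: Q-variant carriers observed per volunteer-recruited cohort
#: (cohort -> (carriers, genotyped)).  Fracture-recruited and clinic series
#: are excluded so the frequency estimate is not enriched by ascertainment.
VOLUNTEER_CARRIER_COUNTS: dict[str, tuple[int, int]] = {
    "Western Australian": (8, 1078),
    "GOS random": (3, 822),
    "TASOAC": (0, 385),
    "Aberdeen": (2, 991),
}

#: Incident-fracture counts over five years in the elderly cohort:
#: 4 of 8 carriers fractured; the non-carrier fracture rate was 17.8 % of
#: 1036 subjects (184 events is the nearest integer reconstruction).
WA_FRACTURE_TABLE: tuple[int, int, int, int] = (4, 4, 184, 852)

#: Relative frequency weights of the variant alleles, proportional to the
#: observed counts in the carrier table above.
ALLELE_WEIGHTS: dict[str, float] = {
    "15Q": 1 / 20,
    "16Q": 12 / 20,
    "18Q": 2 / 20,
    "30Q": 5 / 20,
}
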