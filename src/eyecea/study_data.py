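"""Published pooled estimates from the reference multi-provider costing
study of eye-care case finding in India (financial year 2019-20, 2020 USD).

These are *inputs*: the published tables report annualized category costs
per 100,000 screened (and per facility for vision centers and
teleophthalmology), screening volumes, per-100,000 treatment rates, and
strategy-level societal costs and DALYs averted. The package's reproduction
checks recompute every derived quantity — totals, per-person costs, the
efficient frontier and its ICERs, DALY and spectacle reconstructions, and
the national budget extrapolation — from these raw cells.
"""

from __future__ import annotations

from .cea_frontier import StrategyOutcome
from .data_model import Category, Strategy

# --- Annualized costs per 100,000 screened, by reporting category ----------

COSTS_PER_100K: dict[Strategy, dict[Category, float]] = {
    Strategy.vision_centers: {
        Category.planning_preparation: 25_049,
        Category.clinical_equipment: 56_947,
        Category.human_resources: 143_190,
        Category.other_operating: 77_299,
    },
    Strategy.eye_camps: {
        Category.planning_preparation: 119_154,
        Category.clinical_equipment: 18_585,
        Category.human_resources: 100_594,
        Category.other_operating: 147_408,
    },
    Strategy.door_to_door: {
        Category.planning_preparation: 14_212,
        Category.clinical_equipment: 4_227,
        Category.human_resources: 32_906,
        Category.other_operating: 45_586,
        Category.vc_followup_ure: 202_816,
    },
    Strategy.school_screening: {
        Category.planning_preparation: 3_800,
        Category.clinical_equipment: 12_599,
        Category.human_resources: 55_010,
        Category.other_operating: 14_853,
    },
}

#: Printed totals per 100,000 screened (point estimate, 95% CI)
TOTAL_PER_100K: dict[Strategy, tuple[float, float, float]] = {
    Strategy.vision_centers: (302_485, 225_355, 400_289),
    Strategy.eye_camps: (385_742, 170_111, 699_504),
    Strategy.door_to_door: (299_748, 243_637, 511_093),
    Strategy.school_screening: (86_262, 45_555, 146_067),
}

N_SCREENED: dict[Strategy, float] = {
    Strategy.vision_centers: 1_373_925,
    Strategy.eye_camps: 307_718,
    Strategy.door_to_door: 286_652,
    Strategy.school_screening: 332_237,
}

#: Treatments per 100,000 screened (None = not applicable)
SPECTACLES_PER_100K: dict[Strategy, float] = {
    Strategy.vision_centers: 17_574,
    Strategy.eye_camps: 17_329,
    Strategy.door_to_door: 9_563,
    Strategy.school_screening: 2_459,
}
SURGERIES_PER_100K: dict[Strategy, float | None] = {
    Strategy.vision_centers: 5_409,
    Strategy.eye_camps: 17_752,
    Strategy.door_to_door: 4_543,
    Strategy.school_screening: None,
}

#: Published per-case CFTI costs (point, lo, hi); None = not reported
CFTI_URE: dict[Strategy, tuple[float, float, float]] = {
    Strategy.vision_centers: (10.8, 8.0, 14.4),
    Strategy.eye_camps: (8.0, 3.4, 14.4),
    Strategy.door_to_door: (25.8, 24.1, 30.7),
    Strategy.school_screening: (29.3, 15.5, 49.6),
}
CFTI_CATARACT: dict[Strategy, tuple[float, float, float] | None] = {
    Strategy.vision_centers: (11.9, 8.8, 15.9),
    Strategy.eye_camps: (13.7, 5.6, 27.0),
    Strategy.door_to_door: (11.3, 2.2, 56.2),
    Strategy.school_screening: None,
}

# --- Per-facility vision-center and teleophthalmology costs ----------------

VISION_CENTER_PER_FACILITY: dict[Category, float] = {
    Category.planning_preparation: 969,
    Category.clinical_equipment: 2_204,
    Category.human_resources: 5_542,
    Category.other_operating: 2_992,
}
VISION_CENTER_PER_FACILITY_TOTAL = (11_707, 8_722, 15_492)
VISION_CENTER_WITH_SPECTACLES_TOTAL = (14_954, 11_782, 18_913)

TELE_PER_FACILITY: dict[Category, float] = {
    Category.tele_planning: 57,
    Category.tele_it: 164,
    Category.tele_doctor: 766,
    Category.tele_internet: 284,
}
TELE_INCREMENT_TOTAL = (1_271, 181, 3_340)

#: Additional annual treatments needed for teleophthalmology to break even
#: with the most efficient alternatives (published scenario range)
TELE_BREAKEVEN_SPECTACLES = (54, 95)
TELE_BREAKEVEN_SURGERIES = (26, 47)

# --- Cost-effectiveness table (societal costs, DALYs averted) --------------

CEA_OUTCOMES: list[StrategyOutcome] = [
    StrategyOutcome("school_screening", 278_303, 178),
    StrategyOutcome("door_to_door", 2_304_941, 11_669),
    StrategyOutcome("eye_camps", 6_826_524, 47_599),
    StrategyOutcome("vision_centers", 12_293_868, 68_435),
]

ICER_EYE_CAMPS = (143, 93, 251)
ICER_VISION_CENTERS = (262, 175, 431)
VISION_CENTERS_INCREMENTAL_COST = 5_467_344

# --- Aggregates and extrapolations -----------------------------------------

TOTAL_SPECTACLES = 330_360
TOTAL_SURGERIES = 141_962
TOTAL_DX_URE = 478_276
TOTAL_DX_CATARACT = 223_093

#: Vision centers needed for national primary eye-care coverage
NATIONAL_FACILITY_TARGET = 26_400
#: Published national budget range, USD millions per year
NATIONAL_BUDGET_RANGE_MUSD = (230, 410)

#: One-way sensitivity ICER ranges across published scenarios
ONE_WAY_ICER_EYE_CAMPS = (107, 221)
ONE_WAY_ICER_VISION_CENTERS = (204, 369)
#: Counterfactual self-presentation ICERs at f = 0.1, 0.2, 0.3 (eye camps)
COUNTERFACTUAL_ICERS = {0.1: 150, 0.2: 165, 0.3: 221}
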