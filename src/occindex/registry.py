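"""Registries of hazards, indicator columns and areal strata used across the pipeline."""

WORK_YEAR_DAYS = 250.0

#: Workplace-condition items scored on the 0-100 frequency scale
#: (0 = never ... 100 = every day).
HAZARDS = (
    "pollutants",
    "hazardous_equipment",
    "hazardous_conditions",
    "noise",
    "disease_infection",
    "physical_proximity",
)

#: Hazards reported as day-count frequency indicators (the noise item feeds the
#: Monte Carlo prevalence estimator instead).
FREQUENCY_HAZARDS = (
    "pollutants",
    "hazardous_equipment",
    "hazardous_conditions",
    "disease_infection",
    "physical_proximity",
)

#: The three day-count indicators averaged into the hazardous-workplace indicator.
HAZARDOUS_WORKPLACE_COMPONENTS = (
    "pollutants_days",
    "hazardous_equipment_days",
    "hazardous_conditions_days",
)

#: The four indicators whose percentile ranks are averaged into the overall
#: occupational percentile compared against the SVI.
CORE_PERCENTILE_COLUMNS = (
    "noise_prevalence_pct",
    "hazardous_workplace_pct",
    "physical_proximity_pct",
    "disease_infection_pct",
)

REGIONS = ("Northeast", "Midwest", "South", "West")

#: Population-density strata, people per square mile.
DENSITY_BINS = (0.0, 1000.0, 10000.0, float("inf"))
DENSITY_LABELS = ("<1000", "1000-10000", ">10000")

OUTCOMES = ("diabetes", "asthma", "high_blood_pressure")

#: Exposure indicator used to stratify each health outcome.
OUTCOME_EXPOSURE_PAIRS = {
    "diabetes": "noise_prevalence",
    "asthma": "pollutants_days",
    "high_blood_pressure": "disease_infection_days",
}


def group_ids(n_groups: int) -> list[str]:
    """Opaque ids for the major occupational groups (g01, g02, ...)."""
    return [f"g{i + 1:02d}" for i in range(n_groups)]
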