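"""Published per-whale migration summaries for the 2020-2023 Arctic Norway
adult male sperm whale cohort.

These are the printed event dates (GMT) for the twelve migrating whales:
start of the N-S transit, arrival at the breeding area (south of 45 degN),
departure from the breeding area, and return to the northern feeding
grounds, where observed. They serve as reference inputs for the cohort
phenology arithmetic (leg durations, cohort means, departure-date span) —
no track data are needed to reproduce those numbers.
"""

from __future__ import annotations

from datetime import date

# whale id -> (start N-S, arrival breeding, departure breeding, return north)
MIGRATION_EVENT_DATES: dict[str, tuple[date | None, date | None, date | None, date | None]] = {
    "196721": (date(2021, 2, 3), date(2021, 3, 3), None, None),
    "196724": (date(2021, 4, 21), None, None, None),
    "201357": (date(2021, 1, 26), date(2021, 3, 3), None, None),
    "220659": (date(2022, 1, 18), date(2022, 2, 18), None, None),
    "220665": (date(2021, 7, 10), date(2021, 9, 1), date(2021, 10, 22), None),
    "220666": (date(2021, 6, 9), date(2021, 7, 20), None, None),
    "235819": (date(2023, 6, 1), None, None, None),
    "235820": (date(2023, 4, 4), date(2023, 5, 13), date(2023, 8, 23), date(2023, 9, 26)),
    "235821": (date(2023, 2, 9), date(2023, 3, 12), None, None),
    "235822": (date(2022, 10, 6), date(2022, 12, 8), date(2023, 3, 2), date(2023, 4, 4)),
    "235823": (date(2023, 4, 5), date(2023, 5, 15), date(2023, 7, 22), None),
    "245465": (date(2023, 6, 17), date(2023, 7, 22), None, None),
}

# printed maximum great-circle displacement from the tagging location, km,
# for the boundary case closest to the 1,000 km migrant threshold
MAX_DISPLACEMENT_KM = {"235819": 1010.0}
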