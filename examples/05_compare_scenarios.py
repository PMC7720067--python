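"""Run the full pipeline: current deployment vs microplanning A and B.

`current` walks a seeded random order at 12.5 min/child (emulating
un-mapped CHW movement), `microplan_a` optimises the itinerary and the
treatment time, and `microplan_b` additionally raises the CHW count to
the unmet-needs estimate. Scenario contrasts use Yates-corrected
chi-square tests.
"""

import json
from pathlib import Path

from smcplan import run_pipeline

config = {
    "seed": 7,
    "village": {
        "synthetic": {
            "name": "rakolo-like",
            "n_households": 60,
            "dispersion": "uniform",
            "extent_km": 2.0,
        }
    },
    "campaign": {"campaign_days": 4.0, "workday_hours": 8.0, "walk_min_per_km": 20.0},
    "scenarios": [
        {"name": "current", "mode": "current"},
        {"name": "microplan_a", "mode": "microplan_a"},
        {"name": "microplan_b", "mode": "microplan_b"},
    ],
}

summary = run_pipeline(config, out_dir="pipeline_out")
for row in summary["results"]:
    print(
        f"{row['scenario']:<12} coverage {row['coverage_pct']:5.1f}%  "
        f"walked {row['walking_km']:6.2f} km  "
        f"visited {row['visited_households']:3d}  "
        f"CHWs needed {row['chws_needed']:.2f}"
    )
print()
for comp in summary["comparisons"]:
    print(
        f"{comp['scenario_a']} vs {comp['scenario_b']}: "
        f"chi2(households) = {comp['chi2_households']}, "
        f"coverage change = {comp['coverage_change_points']} points, "
        f"walking change = {comp['walking_change_pct']}%"
    )
print(f"\nfull report: {Path('pipeline_out/report.json').resolve()}")
# Microplanning shortens the walk and stretches the same campaign window
# over more households; plan B sizes the workforce so coverage reaches 100%.
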