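"""Division modes, cycle times and fate indexes from simulated lineages.

Simulates wild-type-calibrated lineages over a 72 h movie, classifies every
completed division from the daughters' MYOG fates, and reports cycle-time
means (with the censoring correction), the division-mode spectrum and the
endpoint differentiation / proliferation indexes.
"""

import fibretrack as ft
from fibretrack.lineage import (
    cell_cycle_durations,
    division_records,
    fate_index_report,
    mean_cycle_duration,
    mode_fractions,
)

preset = ft.preset("wt")
scene = ft.simulate_lineages(preset, n_founders=150, seed=3)

records = division_records(scene.lineage, scene.observed_tracks, fate_mode="labels")
fractions = mode_fractions(records)
durations = cell_cycle_durations(scene.lineage)
g1 = mean_cycle_duration(durations, generation=1, censoring_corrected=True)
g2 = mean_cycle_duration(durations, min_generation=2, censoring_corrected=True)
report = fate_index_report(
    scene.lineage, scene.observed_tracks, 0.0, preset.movie_h * 60.0
)

print(f"founders / cells / divisions:  150 / {len(scene.lineage)} / {len(records)}")
print(f"first-division mean:           {g1:.1f} h")
print(f"later-cycle mean:              {g2:.1f} h")
print(
    "division modes:                "
    f"SCDp {fractions['SCDp']:.1%}  SCDd {fractions['SCDd']:.1%}  "
    f"ACD {fractions['ACD']:.1%}"
)
print(f"differentiation index (72 h):  {report.differentiation_index:.1%}")
print(f"proliferation index:           {report.proliferation_index:.2f}")
print()
print("Activation takes ~2 days, later cycles under 9 h; symmetric")
print("proliferative divisions dominate the wild-type spectrum, and just")
print("over a third of the final population is MYOG-positive.")
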