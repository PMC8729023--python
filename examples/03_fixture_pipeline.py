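"""Run the full pipeline on the 12-participant hand-built cohort.

The fixture hits every classification boundary exactly once (myopia at
SE -1.00, both hyperopia thresholds, both astigmatism thresholds, the
1.25 D anisometropia cutoff and the 2.00 D severity edge), so the printed
category counts are a worked truth table.
"""

import tempfile
from pathlib import Path

from anisoprev import PipelineConfig, make_fixture, run_pipeline, write_cohort

fixture = make_fixture()
with tempfile.TemporaryDirectory() as tmp:
    csv = Path(tmp) / "fixture.csv"
    write_cohort(fixture.data, csv)
    result = run_pipeline(PipelineConfig(input_csv=str(csv)))

print("\n".join(result.summary_lines()))
print()
print("per-participant labels vs embedded truth:")
merged = result.labeled.merge(fixture.truth, on="id", suffixes=("", "_exp"))
for _, row in merged.iterrows():
    ok = "ok " if row["category"] == row["category_exp"] else "FAIL"
    print(f"  [{ok}] {row['id']:32s} -> {row['category']}")
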