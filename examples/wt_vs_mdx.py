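"""Healthy vs dystrophic presets through the full pipeline.

Runs the end-to-end pipeline (simulate → register → metrics → lineage →
report) for the wild-type and mdx calibrations and contrasts the headline
numbers: mobile fraction, mobile speed, SCDd share and differentiation
index.  The report bundles (CSV tables + manifest) land in
``scratch/wt_vs_mdx/``.
"""

import pandas as pd

import fibretrack as ft
from fibretrack.pipeline import PipelineConfig, run_pipeline

for name in ("wt", "mdx"):
    paths = run_pipeline(
        PipelineConfig(
            preset=name,
            n_founders=120,
            seed=42,
            output_dir=f"scratch/wt_vs_mdx/{name}",
        )
    )
    metrics = pd.read_csv(paths["metrics"])
    divisions = pd.read_csv(paths["divisions"])
    indexes = pd.read_csv(paths["indexes"])
    per_cycle = metrics[metrics["segment"] != "merged"]
    classified = per_cycle[per_cycle["mobility_class"].isin(["mobile", "static"])]
    mobile = classified[classified["mobility_class"] == "mobile"]
    modes = divisions[divisions["mode"] != "unclassified"]["mode"].value_counts(
        normalize=True
    )
    print(f"--- {name} ---")
    print(f"mobile fraction:        {len(mobile) / len(classified):.2f}")
    print(f"mobile mean speed:      {mobile['average_speed_um_h'].mean():.1f} μm/h")
    print(f"SCDd share:             {modes.get('SCDd', 0.0):.1%}")
    print(f"differentiation index:  {indexes['differentiation_index'].iloc[0]:.1%}")

print()
print("Dystrophic (mdx) cells are largely static, migrate more slowly when")
print("mobile, divide differentiatively twice as often and end the movie")
print("with roughly twice the differentiation index of wild type.")
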