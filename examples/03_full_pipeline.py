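"""The complete workflow on a synthetic survey with known ground truth.

Simulates the default field survey (13 fields, 51 plots, 2000 ASVs, 30
positively and 20 negatively planted taxa), runs detrending, the clr screen,
the balance index and alpha diversity, then prints how well the screen
recovered the planted taxa and how each index tracks residual yield.
"""

from sbipy import SimulationConfig, simulate_dataset
from sbipy.pipeline import run_pipeline_frames

ds = simulate_dataset(SimulationConfig(seed=20130515))
res = run_pipeline_frames(ds.feature_table, ds.metadata, ds.weather, ds.taxonomy)

truth = ds.truth
pos, neg = set(res.sbi.positive_set), set(res.sbi.negative_set)
print(f"ASVs after contingency filter: {res.stage_log['asvs_after_filter']}")
print(f"selected: {len(pos)} positive, {len(neg)} negative")
print(f"sensitivity (positive planted): "
      f"{len(pos & set(truth.positive_asvs)) / len(truth.positive_asvs):.2f}")
print(f"sensitivity (negative planted): "
      f"{len(neg & set(truth.negative_asvs)) / len(truth.negative_asvs):.2f}")
print(f"yield model R^2: {res.yield_model.r_squared:.2f}")
print()
print("Pearson r with yield and residual yield:")
print(res.index_correlations.round(3))
print()
print("The balance index (sbi_py) tracks residual yield strongly — partly by")
print("construction, since its ASV sets were selected on this same sample —")
print("while generic alpha diversity barely correlates. Selections beyond the")
print("50 planted taxa are the ~5% false positives expected at alpha = 0.05.")
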