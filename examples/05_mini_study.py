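"""A miniature end-to-end study sweep.

Runs the full decisions-on-inferred / outcomes-on-truth pipeline on a scaled
herd: scenario A lethal panel, strategy 2 (carrier-mating avoidance), three
genotyping tiers, two penalty weightings, three replicates.  Prints the
per-cell summary and the profit-maximizing weighting per tier.

Takes about a minute.
"""

from lofmate.experiments import StudyConfig, profit_max_weighting, summarize, sweep
from lofmate.matesel import ObjectiveConfig

cfg = StudyConfig(
    scenario="A",
    strategy=2,
    weighting_grid=(0.0, 100.0),
    tiers=(0, 50, 100),
    n_replicates=3,
    master_seed=42,
    n_ancestors=30,
    n_male_candidates=8,
    n_female_candidates=20,
    n_pedigree_generations=3,
    burn_in_population=120,
    burn_in_generations=40,
    objective=ObjectiveConfig(
        n_matings=12, max_per_sire=4, target_degrees=0.0,
        pop_size=24, max_generations=150, stall_generations=40,
    ),
)

results = sweep(cfg)
summary = summarize(results)

cols = ["weighting", "pct_genotyped", "mean_P", "mean_affected", "mean_MB", "mean_gls"]
print("per-cell summary (means over replicates):")
print(summary[cols].round(3).to_string(index=False))

print("\nprofit-maximizing weighting per genotyping tier:")
print(profit_max_weighting(summary).round(3).to_string(index=False))

print("\nReading the table: with the heavy weighting, more genotyping lets "
      "the optimizer see more carriers and re-pair them, lowering realized "
      "affected conceptions; with weighting 0 genotyping changes nothing, "
      "because the information is never acted upon.")
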