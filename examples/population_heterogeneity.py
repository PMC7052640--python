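"""Population heterogeneity across the three dentate-gyrus sectors.

Samples small per-sector populations (suprapyramidal blade, crest,
infrapyramidal blade), runs every cell through the full measurement battery,
and prints per-sector summary statistics, the weak-correlation fraction of
the pairwise Pearson matrix, and the variance explained by the leading
principal components. Use `dgephys run` (or a larger n_per_sector) for
paper-scale populations.
"""

from dgephys import RunConfig
from dgephys.pipeline import run_pipeline
from dgephys.popstats import WEAK_R

cfg = RunConfig({
    "population": {"n_per_sector": 10},
    "seed": 7,
    "output": {"figures": False},
})
table, stats = run_pipeline(cfg, outdir="dgephys_out/example_population")

print("per-sector means (n = 10 cells each):")
cols = ["R_in", "V_RMP", "S_alpha", "sag", "f_R", "Q", "f_250"]
print(table.groupby("sector")[cols].mean().round(2).to_string())

corr = stats["correlation"]
weak = (abs(corr.r_values) < WEAK_R).mean()
print(f"\npairwise correlations: {len(corr.r_values)} pairs, "
      f"{weak * 100:.0f}% weak (|R| < {WEAK_R})")

pca = stats["pca"]
frac = pca.explained_fraction[:3]
print(f"PCA: first 3 components explain {frac.sum() * 100:.0f}% "
      f"({', '.join(f'{f * 100:.0f}%' for f in frac)})")
print(
    "\nEach measurement is heterogeneous within every sector, most"
    "\nmeasurement pairs are only weakly correlated, and the sector clouds"
    "\noverlap in PC space - heterogeneity without sector-specific clustering."
)
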