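"""Rank-z multivariate model of elongation-rate determinants.

Generates a gene cohort whose rates depend on exon density, CpG content and
H3K79me2 (30% of variance explained), plus proxy features (intron 1 length,
CpG methylation) that are derived from the primaries.  Fits the nested
linear model and runs the dependency analysis that separates primary from
proxy determinants.
"""

import pandas as pd

from polwave import rate_determinants as det
from polwave import synthetic_data as syn

df, truth = syn.gen_feature_table(938, [0.4, -0.3, 0.25], target_r2=0.30,
                                  seed=11)
cols = ["exon_density", "CpG_content", "H3K79me2"]
z = pd.DataFrame({c: det.rank_z_transform(df[c], seed=1) for c in
                  cols + ["intron1_length", "CpG_methylation"]})
rate_z = det.rank_z_transform(df["rate_z"], seed=1)

fit = det.multivariate_fit(rate_z, z, cols)
print("nested R^2 ladder:",
      [f"{r:.3f}" for r in fit.nested_r2], f"(planted 0.30)")

frac_proxy, dep_proxy = det.iterative_linear_model(
    rate_z, z, "exon_density", "intron1_length")
frac_indep, dep_indep = det.iterative_linear_model(
    rate_z, z, "exon_density", "CpG_content")
print(f"exon_density explains {100 * frac_proxy:.0f}% of intron1_length's "
      f"correlation -> dependent: {dep_proxy}")
print(f"exon_density explains {100 * frac_indep:.0f}% of CpG_content's "
      f"correlation -> dependent: {dep_indep}")
# The R^2 ladder climbs to ~0.30 with the three planted features; the
# dependency analysis flags intron 1 length as a proxy of exon density
# (>66% of its correlation explained) while CpG content stays independent.
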