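"""Dashboard statistics on a synthetic time series with a community shift.

Builds an 8-timepoint abundance series whose first taxon expands 10-fold at
timepoint 4, then computes effort-normalized counts, alpha diversity,
Bray-Curtis/PCoA ordination, a taxonomy-metadata correlation, and the
horizon transform that visualizes the shift.
"""

import pandas as pd

from nanomon.simulate import SimSpec, simulate_time_series
from nanomon.stats import (
    alpha_diversity_table,
    beta_diversity_matrix,
    horizon_series,
    pcoa,
    taxon_metadata_correlations,
)
from nanomon.store import TimeSeriesTable, normalize_counts, top_n_with_other

spec = SimSpec(seed=11, timepoints=8, changepoint=4, effect_taxa=(0,), effect_multiplier=10.0)
profiles, metadata = simulate_time_series(spec)

sample_ids = [f"t{i}" for i in range(spec.timepoints)]
counts = pd.DataFrame(
    [{f"taxon_{t}": p * 1000 for t, p in profile.items()} for profile in profiles],
    index=sample_ids,
)
table = TimeSeriesTable(
    data=counts,
    timestamps=pd.Series(pd.date_range("2024-07-01", periods=len(sample_ids), tz="UTC"), index=sample_ids),
)
# pretend later samples were sequenced deeper
normalized = normalize_counts(table, {s: 100_000 + 20_000 * i for i, s in enumerate(sample_ids)})
print(f"scaling factor f = {normalized.scaling_factor:.0f} aligned bases")

alpha = alpha_diversity_table(normalized)
print("\nalpha diversity (Shannon bits / Gini-Simpson):")
print(alpha.round(3).to_string())

ordination = pcoa(beta_diversity_matrix(normalized), n_axes=2)
print("\nPCoA axis 1 (separates pre/post-shift communities):")
print(ordination.coordinates["PC1"].round(3).to_string())
print("variance explained:", [f"{v:.0%}" for v in ordination.proportion_explained[:2]])

meta = pd.DataFrame({"variable": metadata["variable"].to_numpy()}, index=sample_ids)
corr = taxon_metadata_correlations(normalized, meta, method="spearman")
print("\nspearman correlation with the metadata variable:")
print(corr.coefficients["variable"].round(2).to_string())

dev = horizon_series(table.data["taxon_0"].to_numpy(), mode="vs_mean")
print("\nhorizon deviations for taxon_0 (negative before the shift, positive after):")
print([round(d, 1) for d in dev.deviations])

reduced = top_n_with_other(normalized, 3)
print("\ntop-3 + Other display columns:", reduced.taxa)
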