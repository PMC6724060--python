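"""Build the synthetic sky-island landscape and the study sampling design.

Prints the size of the suitability lattice and the locality table: 22
localities in 7 groups totalling 327 sampled individuals, with the
expansion origin flagged.
"""

from demescape import table1_bundle

land, grid, table, sampling = table1_bundle()

print(f"landscape: {land.n_rows}x{land.n_cols} cells, "
      f"{grid.n_demes} suitable demes above {grid.threshold_m:.0f} m")
print(f"localities: {len(table)} in {sampling.n_groups} groups, "
      f"{sampling.total_samples} individuals")
origin = table.loc[table.is_origin].iloc[0]
print(f"expansion origin: {origin['name']} at deme "
      f"({origin.row}, {origin.col})")
print()
print(table[["name", "acronym", "sample_size", "group"]]
      .groupby("group").agg(localities=("name", "count"),
                            samples=("sample_size", "sum")))
# Each group is one massif of the west-east sky-island chain; the sample
# counts per group are what the coalescent sampler draws from its deme.
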