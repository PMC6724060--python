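"""From demography to sequences: coalescent plus mutation.

Conditions a backward coalescent on a recorded expansion, drops mutations
on the genealogy and prints per-group diversity of the simulated 575 bp
alignment — the same statistics later fed to ABC.
"""

import numpy as np

from demescape import (SimParams, diversity_stats, mutate_sequences,
                       simulate_coalescent, simulate_forward, table1_bundle,
                       write_newick)

land, grid, table, sampling = table1_bundle()
params = SimParams(model="GDD", t_onset=2000, n_ancestral=500,
                   growth_rate=0.5, migration_rate=0.15,
                   carrying_capacity=300, seed=11)
trace = simulate_forward(grid, params, sampling.origin_deme,
                         collapse_stationary=True)
gen = simulate_coalescent(trace, grid, sampling, rng=1)
aln = mutate_sequences(gen, mu=2e-6, n_sites=575,
                       rng=np.random.default_rng(2))

print(f"{aln.n_sequences} sequences of {aln.n_sites} bp, "
      f"TMRCA {gen.tmrca:.0f} generations")
print(f"{'group':>5} {'n':>4} {'haplotypes':>10} {'Hd':>6} {'pi':>9}")
for g in sorted(set(aln.groups)):
    codes = aln.codes[aln.groups == g]
    n_hap, hd, pi, _tw = diversity_stats(codes)
    print(f"{g:>5} {codes.shape[0]:>4} {n_hap:>10} {hd:>6.3f} {pi:>9.5f}")
print("newick (first 80 chars):", write_newick(gen)[:80], "...")
# Hd is the chance two sequences from the group differ; pi the mean
# per-site difference. Groups near the origin tend to be more diverse.
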