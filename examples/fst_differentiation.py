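"""Weir-Cockerham F_ST between two demes of an island model."""

import math

import numpy as np

from regionpop import coalsim, fst

rng = np.random.default_rng(2)
model = coalsim.TwoDemeModel(N=1000, M=9.0)  # scaled migration M = 9
comps = []
for _ in range(300):
    g = coalsim.sample_structured_genealogy((20, 20), model, rng)
    sim = coalsim._drop_mutations(g, 5.0, 1000, rng)
    for j in range(sim.S):
        col = sim.matrix[:, j]
        c = fst.wc_fst_site([int(col[:20].sum()), int(col[20:].sum())],
                            [20, 20])
        if not math.isnan(c.a):
            comps.append(c)
out = fst.wc_fst_mean(comps)
print(f"{out['n_sites']} sites; weighted F_ST = {out['weighted']:.4f}, "
      f"mean of ratios = {out['mean']:.4f}; island-model expectation "
      f"1/(1+M) = {1/10:.3f}")

value = 0.069
pct, flag = fst.empirical_percentile(value, [c.fst for c in comps])
print(f"a site with F_ST = {value} sits at the {pct:.0f}th percentile of "
      f"this background ({flag})")
print("-> the multi-locus weighted estimator recovers the equilibrium "
      "differentiation set by migration; percentile ranks place single "
      "sites against a genome-wide background.")
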