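"""The coding-sensitivity experiment on synthetic data.

Draws 10 random 20-marker subsets from a simulated 200-line panel and
fits the pairwise-interaction model under three codings, twice: once
penalizing additive and interaction effects (eRRBLUP-1), once with the
additive effects fixed and only interactions penalized (eRRBLUP-2).
Reports the cross-coding Pearson correlation of the interaction
estimates and the largest rank change of any single interaction.
"""

import errblup as eb

ds = eb.simulate_dataset(eb.SimulationConfig(n_lines=200, n_markers=60,
                                             seed=9))

for penalize_additive, label in [(True, "eRRBLUP-1 (additive penalized)"),
                                 (False, "eRRBLUP-2 (additive fixed)")]:
    cfg = eb.ExperimentConfig(codings=("original", "symmetric", "centered"),
                              n_markers=20, repetitions=10,
                              penalize_additive=penalize_additive, seed=9)
    res = eb.coding_comparison(ds.markers, ds.phenotype, cfg)
    print(f"\n{label}  [lambda1={res.lambda1:.3f}, lambda2={res.lambda2:.3f}]")
    for (a, b), (mean, se) in res.pairwise_correlations.items():
        stats = res.rank_stats[(a, b)]
        print(f"  corr({a:>9}, {b:>9}) = {mean:.4f} +/- {se:.4f}   "
              f"max rank change {stats['max_change_max']:4d} "
              f"of {20 * 19 // 2} interactions")

print("""
With the additive effects penalized, the 190 interaction estimates only
correlate ~0.8-0.95 between codings and a single interaction can move
far down the ranking - the coding choice is part of the answer.  With
additive effects fixed, every correlation is 1 and no rank moves
(differences of order 1e-8 are numerical): only the penalty on the
highest-degree terms sees the coding.""")
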