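"""Permutation diagnostic for heterogeneity of marker effects.

Marker effects are estimated by ridge regression within each of two groups
and correlated; the same statistic under label permutations gives the null
distribution expected when group labels carry no information about the
genetic architecture.  Estimation noise keeps even the null correlations well
below 1, which is why the permutation reference (not 0 or 1) is the right
yardstick.
"""

import wgreg as w

for label, (var_main, var_int) in {
    "homogeneous effects": (0.45, [0.0, 0.0]),
    "group-specific effects": (0.0, [0.45, 0.45]),
}.items():
    geno, geno_std, groups, phenos, _ = w.simulate_dataset(
        n_k=[130, 130], p=120, var_main=var_main, var_int=var_int,
        differentiation=0.2, sigma2=[0.5, 0.5], seed=73,
    )
    res = w.permutation_effect_correlation(
        geno_std, phenos, groups, n_perm=500, seed=6
    )
    print(f"{label}:")
    print(f"  observed correlation of estimates: {res.observed:.3f}")
    print(f"  permutation null: mean {res.null_mean:.3f}, "
          f"median {res.null_median:.3f}, 2nd percentile {res.null_p2:.3f}")
    print(f"  empirical p-value (observed below null): {res.p_value:.4f}")
print(
    "\nWith homogeneous effects the observed value sits inside the null; "
    "with group-specific\neffects it falls below the 2nd percentile, "
    "evidence that effects differ between groups."
)
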