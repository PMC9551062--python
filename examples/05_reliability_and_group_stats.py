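"""Test-retest reliability and group contrasts on a synthetic cohort.

Simulates 7-day biomarker panels for three self-reported walking-pace
groups with a known variance-components model, then computes ICC(2,k)
test-retest reliability of maximal walking speed and the Kruskal-Wallis /
Dunn contrast between pace groups.
"""

from watchwalk.cohortstats import icc_2k, kruskal_dunn
from watchwalk.simulate import simulate_cohort

effects = {
    "slow": {"speed_p95": -0.03},
    "steady": {},
    "brisk": {"speed_p95": +0.03},
}
panel, groups, truth = simulate_cohort(
    n_per_group=60, group_effects=effects, n_days=7, master_seed=5
)

# reliability: subjects x days matrix of one biomarker
mat = panel.pivot(index="subject_id", columns="day_index", values="speed_p95")
icc = icc_2k(mat.to_numpy())
print(f"ICC(2,k) of maximal speed over {icc.k} days, n={icc.n}: {icc.icc:.3f}")
print(f"  generating-model ICC: {truth['icc']['speed_p95']:.3f}")

# convergent validity: weekly means contrasted between pace groups
weekly = panel.groupby("subject_id")["speed_p95"].mean()
res = kruskal_dunn(weekly[groups.index], groups.values)
print(f"\nKruskal-Wallis chi-square={res.statistic:.1f}, df={res.df}, p={res.p:.2e}")
print(res.pairwise.to_string(index=False))
print()
print("An ICC near the generating model's value shows the estimator is")
print("calibrated; adjusted pairwise p-values below 0.05 separate the groups")
print("whose latent speeds truly differ.")
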