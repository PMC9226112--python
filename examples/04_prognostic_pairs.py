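"""Evaluate candidate pairs as two-gene prognostic signatures.

Each pair passing the univariate Cox screen (p < 0.1 per gene) gets a risk
score beta1*x1 + beta2*x2 from a two-covariate Cox fit, a median split into
high/low risk groups, a Kaplan-Meier/log-rank comparison, and a multivariable
Cox adjusted for age, ER, PR, and stage; BH FDR < 0.05 across pairs flags
prognostic signatures.
"""

from drivenet import CohortConfig, generate_cohort, generate_network, top_pairs
from drivenet.survival import evaluate_pairs, km_estimate, prognosis_frame

config = CohortConfig(seed=7)
cohort, truth = generate_cohort(config)
network = generate_network(config, truth)

candidates = top_pairs(network, sorted(truth.meth_driven), sorted(truth.drg),
                       category="methylation", k=100)
results = evaluate_pairs(candidates, cohort.expression, cohort.clinical)
frame = prognosis_frame(results)

evaluated = frame[~frame["dropped"]]
print(f"{len(frame)} candidates, {len(evaluated)} passed the screen, "
      f"{int(frame['flagged'].sum())} flagged at FDR < 0.05")

d0, r0 = truth.surv_pair
row = frame[(frame["driver"] == d0) & (frame["drg"] == r0)].iloc[0]
print(f"planted pair {d0}-{r0}: adjusted HR = {row['adjusted_hr']:.2f} "
      f"[{row['adjusted_hr_low']:.2f}, {row['adjusted_hr_high']:.2f}], "
      f"log-rank chi2 = {row['logrank_chi2']:.1f}, FDR = {row['fdr']:.2e}, "
      f"3-year AUC = {row['td_auc_1095']:.2f}")

planted = next(r for r in results if (r.driver, r.drg) == (d0, r0))
clin = cohort.clinical.table.loc[planted.risk_group.index]
for grp in ("high", "low"):
    sel = planted.risk_group == grp
    curve = km_estimate(clin.loc[sel.values, "os_time"], clin.loc[sel.values, "os_event"])
    print(f"  {grp}-risk group: {sel.sum()} patients, "
          f"3-year survival = {curve.at(1095):.2f}")
# An HR well above 1 with a small FDR says the planted pair separates risk
# groups beyond what age/ER/PR/stage explain, exactly as constructed.
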