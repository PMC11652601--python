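"""Model evaluation: goodness of fit, VPC and bootstrap on one fit.

Fits a 40-subject cohort, then prints residual summaries (iWRES should
be ~N(0,1) when the model is right), the VPC bin table, and the
bootstrap parameter summary with the bias statistic
(median - estimate)/estimate x 100%.
"""

from quetipk.diagnostics import bootstrap, gof, vpc
from quetipk.popmodel import fit, initial_model
from quetipk.synthetic_cohort import default_paper_spec, sample_cohort

sample = sample_cohort(default_paper_spec().resized(40), seed=9)
result = fit(initial_model(sample.dataset), sample.dataset, compute_se=False)

table = gof(result, sample.dataset).table
print(f"GOF over {len(table)} observations: "
      f"mean iWRES = {table.iwres.mean():+.3f}, sd = {table.iwres.std():.3f}")

v = vpc(result, sample.dataset, n_replicates=200, seed=1)
print("\nVPC (observed vs simulated median, 90% envelope):")
for _, b in v.bins.iterrows():
    print(f"  t in [{b.t_lo:5.1f}, {b.t_hi:5.1f}] h  obs p50 = {b.obs_p50:6.1f}  "
          f"sim p50 = {b.sim_p50:6.1f}  [{b.sim_p50_lo:6.1f}, {b.sim_p50_hi:6.1f}]")

summary = bootstrap(result, sample.dataset, n_resamples=100, seed=2)
print(f"\nbootstrap: {summary.n_kept}/{summary.n_resamples} replicates kept")
print(summary.table.round(3).to_string(index=False))
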