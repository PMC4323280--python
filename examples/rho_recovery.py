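"""Calibrate the generator to a target validity correlation and measure
how well small cohorts recover it.

The loading scale is tuned by large-n simulation so the population Spearman
correlation between the risk sum score and the global stress composite hits
the target; replicate cohorts at the validation-subsample size (n = 67)
then show the sampling spread an analyst should expect at that scale.
"""

from kindex import GeneratorConfig, recovery_experiment

report = recovery_experiment(GeneratorConfig(seed=3), target_rho=0.45,
                             replicates=50)
print(f"target population rho : {report.target_rho}")
print(f"calibrated loading    : {report.loading_scale:.3f}")
print(f"replicates x n        : {report.replicates} x {report.n_per_cohort}")
print(f"mean estimated rho    : {report.rho_mean:.3f}")
print(f"SD of estimates       : {report.rho_sd:.3f}")
print(f"share with p <= .05   : {report.rejection_rate:.2f}")
# At n = 67 a true rho of 0.45 is recovered without bias but with sizable
# spread (SD ~ 0.1): single-study correlation estimates in this regime
# carry that much sampling uncertainty.
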