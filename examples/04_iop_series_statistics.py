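"""Run a full 13-level IOP series and compute the dose-response statistics.

Generates one phantom volume per pressure level (14-105 mmHg), quantifies all
four metrics per volume and reports Spearman correlations, regression slopes,
the two-phase scleral fit and the hemifield comparison — the tabular summary
of the whole experiment.
"""

from psoct_iop.pipeline import ExperimentConfig, export_report, run_experiment
from psoct_iop.stats import birefringence_to_dimensionless

report = run_experiment(ExperimentConfig(seed=0))

print("per-metric statistics (rho, slope) per IOP range:")
cols = ["metric", "iop_lo", "iop_hi", "n", "rho", "p", "class", "slope"]
print(report.statistics[cols].to_string(index=False))

below = report.two_phase["below"]
above = report.two_phase["above"]
print(f"\nscleral two-phase fit : {below.slope:.3e} deg/um/mmHg below 45 mmHg, "
      f"{above.slope:.3e} above")
print(f"dimensionless slope   : "
      f"{report.two_phase['dimensionless_slope_per_mmHg']:.3e} 1/mmHg")
print(f"hemifield rank-sum p  : {report.hemifield_p:.3f}")

paths = export_report(report, "scratch/example_run")
print(f"\nfull report exported to {paths['metrics'].parent}")

# Expected shape of the result: a strong positive birefringence-IOP
# correlation that is steep below 45 mmHg and flat above (two-phase response),
# a monotone negative reflectivity-ratio slope of about -1e-2 per mmHg, a
# depression that only develops above 45 mmHg, and an RNFL retardation that
# stays near 9 degrees throughout.
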