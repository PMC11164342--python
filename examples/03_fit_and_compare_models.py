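"""Fit model variants to one synthetic patient and compare them.

Generates a noisy four-line patient from the pre-existing-resistance model,
fits the matching variant and the single-cell model by constrained least
squares on log CA-125, and prints the recovered rates alongside the ground
truth plus the comparison metrics: RSS ratio against the reference smoother
(closer to 1 is better), AIC (lower is better), and R-squared.
"""
from ca125kin import FitConfig, GeneratorConfig, evaluate_fit, fit_patient, generate_cohort

config = GeneratorConfig(
    n_patients=1, seed=29, noise_sd=0.15, n_lines_range=(4, 4),
    pattern_weights=(0.0, 1.0, 0.0),  # primary resistance: a large R(0) fraction
    gap_points=3, base_log_hazard=-12.0,
)
cohort, truth = generate_cohort(config)
patient = cohort[cohort.patient_ids[0]]
row = truth.iloc[0]

fit_sr = fit_patient(patient, "sr_r0", "all", FitConfig(seed=1, n_restarts=8))
fit_single = fit_patient(patient, "single", "all", FitConfig(seed=1, n_restarts=8))

print(f"patient with {patient.n_measurements} CA-125 values over "
      f"{patient.schedule.n_lines} treatment lines\n")
print("parameter   truth      sr_r0 fit")
for name in ("gamma_S", "gamma_R", "delta_S", "delta_R"):
    print(f"{name:9s}  {row[name]: .5f}   {fit_sr.theta[name]: .5f}")
f_true = row.R0 / patient.values[0]
print(f"{'r0_frac':9s}  {f_true: .5f}   {fit_sr.theta['r0_frac']: .5f}")

for fit in (fit_sr, fit_single):
    ev = evaluate_fit(fit, patient)
    print(f"\n{fit.variant:7s}: rss={fit.rss:7.3f}  ratio={ev.ratio:.3f}  "
          f"aic={ev.aic:7.1f}  r2_fitted={ev.r2_fitted:.3f}")
print()
print("The two-type variant tracks the weakening response across lines, so its")
print("ratio sits near 1 and its AIC is lower; the single-cell model cannot")
print("bend its fixed decline rate and is penalized despite fewer parameters.")
print("The resistant-cell parameters (gamma_R, delta_R, r0_frac), which drive")
print("this patient's dynamics, are recovered closely; the sensitive-cell rates")
print("are only weakly identified once that compartment has been eliminated.")
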