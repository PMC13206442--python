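"""End-to-end workflow: screen, split, select, calibrate, compare.

Runs the whole pipeline on synthetic data and prints the method-
comparison table (one row per wavelength-selection strategy plus the
full-spectrum reference) and the test-set bias t-test.
"""

from nirselect import RunConfig, SynthConfig, run_pipeline

cfg = RunConfig(
    synth=SynthConfig(n_samples=150, n_channels=400, seed=6),
    preprocessing=None,          # generator output is already smooth
    outlier_screening=True, outlier_iters=200,
    var_thresh=0.05,             # variance rule on this data's scale
    selectors=("ensemble", "CARS", "UVE"),
    seed=6)
results = run_pipeline(cfg)

print("split summary (% protein):")
print(results["split_summary"].round(3).to_string(index=False))

print("\nmodel comparison:")
print(results["comparison"].to_string(index=False))

bt = results["bias_test"]
verdict = "no significant bias" if abs(bt["t"]) < bt["critical"] else "bias!"
print(f"\ntest-set bias ({bt['method']}): t = {bt['t']:.3f}, "
      f"p = {bt['p']:.3f}, critical value {bt['critical']:.3f} -> {verdict}")
# rrmse columns are RMSE as a percent of the set mean; rpd_test > 3
# indicates a calibration usable for quantitative screening.
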