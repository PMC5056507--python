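"""Full study: which acquisition condition yields the best signature?

Runs simulate -> extract -> screen -> fit -> evaluate -> compare with the
study-sized cohorts (30 benign / 90 malignant per cohort), then prints the
per-group performance table and the three pre-registered paired
comparisons (contrast, slice thickness, convolution kernel).
"""

from spnradiomics import PipelineConfig, run_study

report = run_study(PipelineConfig(seed=1))

print("Diagnostic performance of the radiomics signature per group:")
print(report.performance_table().round(3).to_string(index=False))
print()
print("Paired comparisons (DeLong test on AUC difference, two-category NRI):")
print(report.comparison_table().round(3).to_string(index=False))
print()
print("Positive delta_AUC / NRI_total favour the first group of the pair; "
      "the reference acquisition (group 1: non-contrast, 1.25 mm, standard "
      "kernel) tends to discriminate best, mirroring the degradations the "
      "other groups apply.")
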