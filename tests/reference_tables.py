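"""Reference per-participant spatio-temporal summary rows.

Three clinical summary tables (a laboratory training set, a laboratory test
cohort, and a wearable-sensor validation cohort) with their published grand
Mean/std rows, used to cross-check the summary arithmetic: unweighted means,
sample (n-1) standard deviations, pairwise-complete handling of missing
cells, and the step-count bookkeeping of the training-fraction claims.
``None`` marks a genuinely missing cell.
"""

# condition, step_length_left_mean_m, step_length_right_mean_m,
# step_length_left_std_m, step_length_right_std_m, gait_speed_mps, n_steps
TRAINING_SET = {
    "rows": [
        ("barefoot", 0.37, 0.389, 0.052, 0.038, 0.876, 1),
        ("barefoot", 0.465, 0.473, 0.013, 0.03, 1.019, 1),
        ("barefoot", 0.282, 0.444, 0.037, 0.013, 0.389, 2),
        ("barefoot", 0.457, 0.417, 0.012, 0.02, 0.797, 1),
    ],
    "mean": (0.394, 0.431, 0.029, 0.025, 0.770),
    "std": (0.086, 0.036, 0.019, 0.011, 0.270),
    "total_steps": 5,
}

# condition, sl_left, sl_right, sl_left_std, sl_right_std, speed,
# n_steps_left, n_steps_right
LAB_TEST_COHORT = {
    "rows": [
        ("barefoot", 0.56, 0.609, 0.047, 0.043, 1.292, 16, 16),
        ("barefoot", 0.318, 0.345, 0.027, 0.021, 0.837, 24, 23),
        ("shoes_orthotics", 0.341, 0.36, 0.052, 0.041, 0.87, 7, 7),
        ("barefoot", 0.471, 0.496, 0.032, 0.044, 1.053, 23, 21),
        ("barefoot", 0.451, 0.452, 0.036, 0.037, 1.028, 20, 20),
        ("barefoot", 0.298, 0.315, 0.037, 0.045, 0.823, 23, 22),
        ("barefoot", 0.306, 0.457, 0.022, 0.016, 0.399, 5, 4),
        ("barefoot", 0.507, 0.501, 0.049, 0.013, 1.256, 19, 19),
        ("barefoot", 0.446, 0.423, 0.022, 0.016, 0.814, 25, 22),
        ("barefoot", 0.538, 0.502, 0.026, 0.063, 1.153, 24, 23),
        ("barefoot", 0.389, 0.439, 0.043, 0.025, 0.771, 21, 20),
        ("barefoot", 0.573, 0.604, 0.023, 0.017, 0.998, 20, 18),
        ("barefoot", 0.511, 0.521, 0.05, 0.03, 1.092, 23, 21),
        ("barefoot", 0.336, 0.341, 0.036, 0.024, 0.845, 32, 30),
        ("barefoot", None, 0.446, None, 0.015, 0.699, 9, 10),
    ],
    "mean": (0.432, 0.454, 0.036, 0.030, 0.929, 19.4, 18.4),
    "std": (0.099, 0.089, 0.011, 0.015, 0.231, 7.3, 6.7),
    "total_steps_left": 291,
    "total_steps_right": 276,
    "n_hints": 6,
    "max_hint_fraction_pct": 2.0,
}

SENSOR_COHORT = {
    "rows": [
        ("barefoot", 0.149, 0.24, 0.06, 0.056, 0.134, 7, 7),
        ("barefoot", 0.467, 0.501, 0.046, 0.045, 1.133, 29, 30),
        ("shoes_orthotics", 0.439, 0.485, 0.053, 0.053, 0.979, 43, 41),
        ("barefoot", 0.254, 0.032, 0.014, 0.01, 0.184, 27, 21),
        ("shoes_orthotics", 0.278, 0.058, 0.017, 0.025, 0.228, 11, 12),
        ("barefoot", 0.222, 0.25, 0.023, 0.011, 0.287, 10, 11),
        ("shoes_orthotics", 0.284, 0.362, 0.024, 0.022, 0.449, 8, 8),
        ("barefoot", 0.475, 0.14, 0.024, 0.022, 0.237, 24, 22),
        ("shoes_orthotics", 0.478, 0.186, 0.02, 0.042, 0.273, 29, 28),
    ],
    # the published speed mean (0.433) recomputes to 0.4338 from the rows
    # (upstream rounding); step means/stds are asserted exactly
    "mean_steps": (20.9, 20.0),
    "total_steps": 368,
    "n_hints": 9,
    "max_hint_fraction_pct": 3.0,
}


def as_dataframe(table: dict, with_counts: bool = True):
    import pandas as pd

    cols = [
        "condition",
        "step_length_left_mean_m",
        "step_length_right_mean_m",
        "step_length_left_std_m",
        "step_length_right_std_m",
        "gait_speed_mps",
    ]
    if with_counts:
        cols += ["n_steps_left", "n_steps_right"]
    return pd.DataFrame([dict(zip(cols, row)) for row in table["rows"]])
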