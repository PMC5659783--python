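"""Bundled fitted parameter sets and frozen reference predictions.

``FITTED_PARAMS`` holds the best-fitting parameter set for each model,
obtained by chi-square quantile fitting to the JC1 food-choice experiment
(4-level value scale, two alternatives, D=100, dt=10 ms, T0=150 ms),
together with the training/test objective values of those fits.

``REFERENCE_ROWS`` freezes, for each model simulated at its fitted
parameters with 20,000 trials per input vector, the coefficients of the
full regression battery — choice accuracy (logistic, raw coefficients) and
RT for correct/incorrect/indifferent choices (linear, constant in seconds
and the other coefficients constant-normalized) — as ``(estimate, SE)``
pairs.  They serve as the canonical regression oracle for
:func:`vssm.design.reproduce_model_rows`.
"""

from __future__ import annotations

from .models import ModelParams

__all__ = ["FITTED_PARAMS", "FIT_CHI2", "REFERENCE_ROWS", "MODEL_ORDER"]

#: models in descending order of fit performance
MODEL_ORDER = ("SSCA", "SCA", "DCA", "CA", "SNFI", "DNFI", "NDD", "RACE")

FITTED_PARAMS: dict[str, ModelParams] = {
    "SSCA": ModelParams("SSCA", b=1.434, g=0.085, sigma=2.265,
                        i_v=0.465, i_d=0.0180, a=1.373),
    "SCA": ModelParams("SCA", b=1.195, g=0.187, sigma=2.665,
                       i_v=0.470, i_d=0.0154),
    "DCA": ModelParams("DCA", b=3.073, g=5.117, sigma=2.571,
                       s=13.80, i_d=0.0174),
    "CA": ModelParams("CA", b=1.219, g=0.233, sigma=1.933, i_d=0.0252),
    "SNFI": ModelParams("SNFI", b=0.614, g=0.225, sigma=3.968, i_v=0.733),
    "DNFI": ModelParams("DNFI", b=0.109, g=2.212, sigma=3.970, s=1.697),
    "NDD": ModelParams("NDD", b=0.761, g=0.185, sigma=3.803),
    "RACE": ModelParams("RACE", b=0.336, g=0.233, sigma=3.569),
}

#: chi-square objective of each fitted model on the training / held-out
#: halves of the source experiment (null and saturated benchmarks included)
FIT_CHI2: dict[str, tuple[float, float]] = {
    "SSCA": (153.26, 186.84),
    "SCA": (189.50, 227.41),
    "DCA": (240.03, 295.48),
    "CA": (278.85, 296.49),
    "SNFI": (322.65, 354.44),
    "DNFI": (422.12, 461.82),
    "NDD": (437.77, 501.84),
    "RACE": (1257.36, 1255.40),
    "Saturated": (0.10, 87.91),
    "Null": (26606.0, 26165.0),
}

# (estimate, SE) per term.  Accuracy terms are raw logistic coefficients;
# RT terms are constant-normalized except 'const', which is in seconds.
REFERENCE_ROWS: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "SSCA": {
        "accuracy": {"const": (-0.325, 0.025), "greater": (3.319, 0.042),
                     "lesser": (-2.890, 0.043), "absdiff": (3.104, 0.039),
                     "sum": (0.214, 0.016)},
        "rt_correct": {"const": (1.101, 0.003), "greater": (-0.306, 0.004),
                       "lesser": (0.146, 0.004), "absdiff": (-0.226, 0.004),
                       "sum": (-0.080, 0.002)},
        "rt_incorrect": {"const": (1.094, 0.007), "greater": (-0.114, 0.012),
                         "lesser": (-0.036, 0.012), "absdiff": (-0.039, 0.011),
                         "sum": (-0.075, 0.004)},
        "rt_indifferent": {"const": (1.058, 0.002), "sum": (-0.078, 0.002)},
    },
    "SCA": {
        "accuracy": {"const": (-0.035, 0.026), "greater": (3.229, 0.045),
                     "lesser": (-3.373, 0.045), "absdiff": (3.301, 0.042),
                     "sum": (-0.072, 0.016)},
        "rt_correct": {"const": (1.095, 0.003), "greater": (-0.299, 0.004),
                       "lesser": (0.142, 0.004), "absdiff": (-0.220, 0.003),
                       "sum": (-0.079, 0.002)},
        "rt_incorrect": {"const": (1.130, 0.008), "greater": (-0.162, 0.012),
                         "lesser": (-0.025, 0.012), "absdiff": (-0.068, 0.012),
                         "sum": (-0.093, 0.004)},
        "rt_indifferent": {"const": (1.089, 0.002), "sum": (-0.096, 0.002)},
    },
    "DCA": {
        "accuracy": {"const": (0.172, 0.026), "greater": (2.990, 0.045),
                     "lesser": (-3.485, 0.044), "absdiff": (3.237, 0.042),
                     "sum": (-0.248, 0.016)},
        "rt_correct": {"const": (1.093, 0.003), "greater": (-0.300, 0.004),
                       "lesser": (0.169, 0.004), "absdiff": (-0.235, 0.004),
                       "sum": (-0.066, 0.002)},
        "rt_incorrect": {"const": (1.147, 0.008), "greater": (-0.159, 0.013),
                         "lesser": (-0.032, 0.013), "absdiff": (-0.063, 0.012),
                         "sum": (-0.095, 0.004)},
        "rt_indifferent": {"const": (1.107, 0.002), "sum": (-0.097, 0.002)},
    },
    "CA": {
        "accuracy": {"const": (-0.084, 0.025), "greater": (2.955, 0.041),
                     "lesser": (-3.005, 0.041), "absdiff": (2.980, 0.038),
                     "sum": (-0.025, 0.016)},
        "rt_correct": {"const": (1.099, 0.004), "greater": (-0.303, 0.004),
                       "lesser": (0.133, 0.004), "absdiff": (-0.218, 0.004),
                       "sum": (-0.085, 0.002)},
        "rt_incorrect": {"const": (1.164, 0.008), "greater": (-0.084, 0.012),
                         "lesser": (-0.168, 0.012), "absdiff": (0.042, 0.011),
                         "sum": (-0.126, 0.004)},
        "rt_indifferent": {"const": (1.106, 0.002), "sum": (-0.107, 0.002)},
    },
    "SNFI": {
        "accuracy": {"const": (-0.052, 0.027), "greater": (3.415, 0.047),
                     "lesser": (-3.514, 0.047), "absdiff": (3.465, 0.044),
                     "sum": (-0.050, 0.016)},
        "rt_correct": {"const": (1.078, 0.003), "greater": (-0.278, 0.004),
                       "lesser": (0.157, 0.004), "absdiff": (-0.217, 0.003),
                       "sum": (-0.060, 0.002)},
        "rt_incorrect": {"const": (1.073, 0.007), "greater": (-0.196, 0.013),
                         "lesser": (0.074, 0.013), "absdiff": (-0.135, 0.012),
                         "sum": (-0.061, 0.004)},
        "rt_indifferent": {"const": (1.048, 0.002), "sum": (-0.073, 0.002)},
    },
    "DNFI": {
        "accuracy": {"const": (0.582, 0.025), "greater": (2.096, 0.040),
                     "lesser": (-3.211, 0.039), "absdiff": (2.653, 0.036),
                     "sum": (-0.558, 0.016)},
        "rt_correct": {"const": (0.980, 0.003), "greater": (-0.221, 0.004),
                       "lesser": (0.101, 0.004), "absdiff": (-0.161, 0.003),
                       "sum": (-0.060, 0.002)},
        "rt_incorrect": {"const": (0.998, 0.006), "greater": (-0.156, 0.009),
                         "lesser": (0.007, 0.009), "absdiff": (-0.082, 0.009),
                         "sum": (-0.074, 0.003)},
        "rt_indifferent": {"const": (1.032, 0.002), "sum": (-0.110, 0.001)},
    },
    "NDD": {
        "accuracy": {"const": (-0.053, 0.026), "greater": (3.331, 0.046),
                     "lesser": (-3.357, 0.046), "absdiff": (3.344, 0.043),
                     "sum": (-0.013, 0.016)},
        "rt_correct": {"const": (1.009, 0.003), "greater": (-0.214, 0.004),
                       "lesser": (0.212, 0.004), "absdiff": (-0.213, 0.004),
                       "sum": (-0.001, 0.002)},
        "rt_incorrect": {"const": (1.012, 0.007), "greater": (-0.149, 0.013),
                         "lesser": (0.154, 0.013), "absdiff": (-0.152, 0.012),
                         "sum": (0.003, 0.004)},
        "rt_indifferent": {"const": (0.972, 0.002), "sum": (-0.001, 0.002)},
    },
    "RACE": {
        "accuracy": {"const": (0.127, 0.022), "greater": (1.944, 0.034),
                     "lesser": (-2.252, 0.034), "absdiff": (2.098, 0.031),
                     "sum": (-0.154, 0.015)},
        "rt_correct": {"const": (1.202, 0.003), "greater": (-0.314, 0.003),
                       "lesser": (-0.087, 0.003), "absdiff": (-0.114, 0.003),
                       "sum": (-0.201, 0.002)},
        "rt_incorrect": {"const": (1.211, 0.005), "greater": (-0.262, 0.006),
                         "lesser": (-0.150, 0.006), "absdiff": (-0.056, 0.006),
                         "sum": (-0.206, 0.003)},
        "rt_indifferent": {"const": (1.228, 0.002), "sum": (-0.220, 0.001)},
    },
}
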