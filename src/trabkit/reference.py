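"""Published cohort summary statistics used as generator defaults.

Per-age-group means and coefficients of variation of the five univariate
trabecular metrics in the proximal humerus and femur of *Procyon lotor*,
together with the ontogenetic group sizes.  These numbers parameterize the
synthetic cohort generator so the statistics stage can be exercised with a
realistic ontogenetic signal.

Thickness and spacing are stored in cm as published; the generator converts
to the package's working unit (mm).
"""

from __future__ import annotations

import pandas as pd

AGE_GROUPS = ["2mo", "4-12mo", "14-24mo", "26-38mo", "46+mo"]
GROUP_SIZES = {"2mo": 13, "4-12mo": 11, "14-24mo": 10, "26-38mo": 7, "46+mo": 14}
ELEMENTS = ["humerus", "femur"]
METRICS = ["da", "bvtv", "tbth", "tbsp", "tbn"]

# Group means: {element: {metric: [per age group]}}.  tbth/tbsp in cm.
GROUP_MEANS = {
    "humerus": {
        "da":   [0.19, 0.342, 0.355, 0.351, 0.386],
        "bvtv": [0.276, 0.437, 0.369, 0.314, 0.311],
        "tbth": [0.0135, 0.0185, 0.0177, 0.0174, 0.0174],
        "tbsp": [0.0311, 0.0315, 0.0354, 0.0386, 0.0419],
        "tbn":  [1.71, 1.87, 1.69, 1.51, 1.45],
    },
    "femur": {
        "da":   [0.16, 0.333, 0.411, 0.399, 0.434],
        "bvtv": [0.358, 0.477, 0.468, 0.412, 0.404],
        "tbth": [0.0137, 0.0214, 0.0252, 0.0228, 0.0226],
        "tbsp": [0.0245, 0.028, 0.0319, 0.0358, 0.0361],
        "tbn":  [2.13, 1.86, 1.62, 1.52, 1.57],
    },
}

# Coefficients of variation in percent, same layout.
GROUP_CVS = {
    "humerus": {
        "da":   [22.1, 15.6, 16.0, 20.2, 19.2],
        "bvtv": [22.7, 14.6, 20.5, 25.2, 17.1],
        "tbth": [11.3, 15.8, 7.59, 13.3, 8.9],
        "tbsp": [14.1, 10.8, 11.8, 10.8, 8.7],
        "tbn":  [19.5, 11.8, 12.6, 10.7, 10.4],
    },
    "femur": {
        "da":   [42.1, 20.7, 19.5, 14.6, 14.0],
        "bvtv": [29.1, 12.2, 16.4, 13.1, 12.5],
        "tbth": [12.9, 27.6, 26.1, 10.6, 13.1],
        "tbsp": [20.0, 9.61, 10.9, 5.77, 8.6],
        "tbn":  [21.8, 13.9, 13.2, 6.14, 17.1],
    },
}

# Estimated log10 body mass (kg) per age group: means and CVs are free
# parameters of the generator (the source tables do not print them); chosen
# to match the qualitative ontogenetic trajectory of a mid-sized procyonid
# (~1.4 kg at two months rising to ~10 kg in aged adults).
LOGBM_MEANS = [0.15, 0.75, 0.92, 0.98, 1.02]
LOGBM_CVS = [30.0, 12.0, 8.0, 6.0, 6.0]

# Primary fabric orientation defaults, degrees.  Young animals carry
# near-horizontal struts aligned with the anterior/posterior (X) axis that
# reorient toward vertical with age; the femur lags the humerus by roughly
# one age class.  sd / kappa values set the dispersion of the wrapped draws.
ORIENTATION_DEFAULTS = {
    "humerus": {
        "plunge_mean": [15.0, 70.0, 75.0, 78.0, 80.0],
        "plunge_sd":   [12.0, 8.0, 6.0, 5.0, 5.0],
        "azimuth_mean": [0.0, 0.0, 0.0, 0.0, 0.0],
        "azimuth_kappa": [4.0, 0.5, 0.3, 0.3, 0.3],
    },
    "femur": {
        "plunge_mean": [15.0, 35.0, 72.0, 75.0, 78.0],
        "plunge_sd":   [12.0, 12.0, 6.0, 5.0, 5.0],
        "azimuth_mean": [0.0, 0.0, 0.0, 0.0, 0.0],
        "azimuth_kappa": [4.0, 2.0, 0.3, 0.3, 0.3],
    },
}


def group_mean_table() -> pd.DataFrame:
    """Long-format table of reference group means (tbth/tbsp in cm)."""
    rows = []
    for element in ELEMENTS:
        for metric in METRICS:
            for g, m in zip(AGE_GROUPS, GROUP_MEANS[element][metric]):
                rows.append({"element": element, "metric": metric,
                             "age_group": g, "mean": m,
                             "cv_percent": GROUP_CVS[element][metric][AGE_GROUPS.index(g)]})
    return pd.DataFrame(rows)
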