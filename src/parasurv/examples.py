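"""Worked-example coefficient tables.

Point estimates reported by a published endometrial-cancer overall-survival
study that fitted the same Weibull and Cox models to clinical (age, tumour
grade) plus three T2-weighted-MRI radiomic covariates on a 411-subject
training and an 80-subject testing cohort. The underlying patient data are
not public; these printed estimates serve as inputs for the closed-form
effect arithmetic (HR = exp(beta), ETR = exp(-beta/gamma)) and as the
generative truth of the study-mimicking simulation defaults.
"""

from __future__ import annotations

import pandas as pd

# Weibull baseline parameters reported per dataset
WEIBULL_SHAPE = {"training": 0.9929, "testing": 1.8057}
WEIBULL_SCALE = {"training": 3.0447e-05, "testing": 1.2608e-07}

_COLUMNS = ["predictor", "weibull_coef", "weibull_hr", "weibull_etr",
            "cph_coef", "cph_hr"]

_TRAINING = [
    ("age",     0.5620, 1.7541, 0.5678, 0.5476, 1.7292),
    ("grade2",  0.2038, 1.2261, 0.8144, 0.2178, 1.2433),
    ("grade3",  1.9327, 6.9080, 0.1428, 1.9048, 6.7183),
    ("gldm",    0.2676, 1.3068, 0.7638, 0.2738, 1.3149),
    ("glrlm",   0.4012, 1.4936, 0.6676, 0.3846, 1.4691),
    ("glszm",   0.1636, 1.1778, 0.8481, 0.1546, 1.1672),
]

_TESTING = [
    ("age",     0.2427, 1.2746, 0.8743,  0.2123, 1.2365),
    ("grade2", -0.6262, 0.5346, 1.4145, -0.7579, 0.4687),
    ("grade3",  0.8632, 2.3707, 0.6200,  0.7667, 2.1526),
    ("gldm",    1.3011, 3.6733, 0.4865,  1.1876, 3.2792),
    ("glrlm",  -0.6376, 0.5286, 1.4235, -0.5363, 0.5849),
    ("glszm",  -0.4999, 0.6066, 1.3189, -0.4383, 0.6451),
]


def published_estimates(dataset: str = "training") -> pd.DataFrame:
    """Printed coefficient/HR/ETR table for 'training' or 'testing'."""
    if dataset not in ("training", "testing"):
        raise ValueError("dataset must be 'training' or 'testing'")
    rows = _TRAINING if dataset == "training" else _TESTING
    return pd.DataFrame(rows, columns=_COLUMNS)
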