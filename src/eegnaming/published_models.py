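"""Published per-participant reference models for the naming study.

The original study reported, for each of eight participants with aphasia
(identifiers 1501-1607), the three-channel elastic-net coefficient sets for
the accuracy model together with training/test degrees of freedom, and the
Pearson correlations between predicted and observed outcomes.  Those printed
values are reproduced here so the package can instantiate the published
models (e.g., to verify that prediction at the zero-feature point returns
the printed intercept) and report its own results alongside them.

The published feature labels name each band by a single nominal frequency
("8 Hz Fz", "12 Hz Cz", ...).  The analysis bands are 6-9, 10-13, 14-17,
18-21, 22-25 and 26-29 Hz; the nominal labels are mapped onto the bands in
ascending order (8 -> 6-9, 12 -> 10-13, ..., 28 -> 26-29).  The mapping is
positional: the published report never states it explicitly.

Note: for some participants the count of printed nonzero coefficients
disagrees with the printed df numerator (e.g., nine coefficients against
"8/590"); the tables are stored exactly as printed.
"""

from __future__ import annotations

import numpy as np

from .elastic_net import ElasticNetModel
from .session_model import CHANNELS_3
from .spectral_features import DEFAULT_BANDS, SpectralConfig, feature_labels

#: printed nominal band frequency -> analysis band, ascending positional map
NOMINAL_BAND = {8: (6, 9), 12: (10, 13), 16: (14, 17), 20: (18, 21),
                24: (22, 25), 28: (26, 29)}

#: three-channel accuracy models as printed: intercept, nonzero coefficients
#: keyed by "<nominal Hz> <channel>", and the printed df pairs (k, residual)
PUBLISHED_MODELS = {
    "1501": {
        "intercept": 0.5437,
        "coefficients": {"12 Cz": 0.0101, "24 Cz": 0.0278, "28 Fz": 0.0060},
        "df_train": (3, 596),
        "df_test": (3, 296),
    },
    "1503": {
        "intercept": -0.0742,
        "coefficients": {
            "8 Cz": -0.0125, "12 Fz": -0.0284, "12 Pz": 0.0962,
            "16 Fz": -0.0107, "20 Fz": -0.0064, "24 Cz": 0.0159,
            "28 Fz": 0.0062, "28 Cz": 0.0428, "28 Pz": -0.1091,
        },
        "df_train": (8, 590),
        "df_test": (8, 290),
    },
    "1601": {
        "intercept": -0.8258,
        "coefficients": {"8 Fz": 0.0347, "12 Pz": 0.0124, "16 Fz": 0.0240},
        "df_train": (3, 585),
        "df_test": (3, 295),
    },
    "1602": {
        "intercept": 0.7295,
        "coefficients": {"8 Fz": 0.0001, "12 Cz": 0.0003},
        "df_train": (1, 597),
        "df_test": (1, 297),
    },
    "1603": {
        "intercept": 0.3214,
        "coefficients": {"24 Cz": 0.0352, "28 Pz": -0.0381},
        "df_train": (1, 596),
        "df_test": (1, 297),
    },
    "1605": {
        "intercept": 0.6840,
        "coefficients": {
            "8 Fz": -0.0092, "12 Fz": 0.0168, "12 Cz": -0.0190,
            "12 Pz": 0.0237, "16 Cz": -0.0029, "16 Pz": -0.0378,
            "20 Fz": -0.0105, "20 Cz": 0.0649, "24 Cz": -0.0058,
            "28 Fz": 0.0524, "28 Cz": -0.0563,
        },
        "df_train": (10, 588),
        "df_test": (10, 288),
    },
    "1606": {
        "intercept": 0.7284,
        "coefficients": {
            "8 Fz": 0.0050, "12 Fz": 0.0029, "12 Cz": 0.0086,
            "12 Pz": 0.0003, "20 Fz": -0.0014,
        },
        "df_train": (4, 593),
        "df_test": (4, 295),
    },
    "1607": {
        "intercept": 0.8471,
        "coefficients": {
            "8 Fz": -0.0002, "12 Fz": -0.0029, "12 Cz": -0.0041,
            "24 Cz": 0.0513, "24 Pz": -0.0147, "28 Fz": -0.0053,
            "28 Pz": -0.0560,
        },
        "df_train": (6, 592),
        "df_test": (6, 292),
    },
}

#: published Pearson correlations (accuracy: train/test 3-channel, test
#: 9-channel; error correction: train/test 3-channel); None where the study
#: reported none
PUBLISHED_CORRELATIONS = {
    "1501": {"acc_train_3": 0.2148, "acc_test_3": 0.2456, "acc_test_9": 0.2535,
             "corr_train_3": 0.1392, "corr_test_3": 0.1950},
    "1503": {"acc_train_3": 0.4673, "acc_test_3": 0.2589, "acc_test_9": 0.3098,
             "corr_train_3": 0.4176, "corr_test_3": 0.1607},
    "1601": {"acc_train_3": 0.4710, "acc_test_3": 0.4570, "acc_test_9": 0.5085,
             "corr_train_3": 0.2296, "corr_test_3": 0.1234},
    "1602": {"acc_train_3": 0.0409, "acc_test_3": -0.0516, "acc_test_9": None,
             "corr_train_3": None, "corr_test_3": None},
    "1603": {"acc_train_3": 0.2442, "acc_test_3": 0.1244, "acc_test_9": 0.2037,
             "corr_train_3": 0.1531, "corr_test_3": 0.0627},
    "1605": {"acc_train_3": 0.3081, "acc_test_3": 0.2588, "acc_test_9": 0.2781,
             "corr_train_3": 0.2550, "corr_test_3": 0.2113},
    "1606": {"acc_train_3": 0.1989, "acc_test_3": 0.2044, "acc_test_9": None,
             "corr_train_3": 0.1701, "corr_test_3": 0.2142},
    "1607": {"acc_train_3": 0.3921, "acc_test_3": 0.2980, "acc_test_9": 0.3433,
             "corr_train_3": 0.2538, "corr_test_3": 0.1332},
}


def _canonical_label(published_key: str, config: SpectralConfig) -> str:
    hz, ch = published_key.split()
    lo, hi = NOMINAL_BAND[int(hz)]
    return f"{ch}_{lo}-{hi}"


def published_model(
    participant: str, config: SpectralConfig = SpectralConfig()
) -> ElasticNetModel:
    """Instantiate a published three-channel accuracy model.

    Standardization parameters are not published, so the model is expressed
    on the standardized feature scale (means 0, SDs 1): applying it to the
    all-zero feature vector returns the printed intercept.
    """
    spec = PUBLISHED_MODELS[str(participant)]
    labels = feature_labels(CHANNELS_3, config)
    beta = np.zeros(len(labels))
    for key, value in spec["coefficients"].items():
        beta[labels.index(_canonical_label(key, config))] = value
    return ElasticNetModel(
        intercept=spec["intercept"],
        beta=beta,
        lam1=float("nan"),
        lam2=float("nan"),
        column_labels=labels,
        feature_means=np.zeros(len(labels)),
        feature_sds=np.ones(len(labels)),
    )
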