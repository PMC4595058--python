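"""Published reference measurements used as calibration surrogates.

``ALGAL_ISOLATES`` transcribes the comparison of eight algal strains —
intensity ratio I1650/I1440 (532 nm, post-photobleach) against the measured
number of C=C bonds and measured N_C=C/N_CH2.  Ordinary least squares over
this table yields a field-measured linear calibration for 532 nm data,
used where a real-instrument calibration is needed instead of the
synthetic-standard one.
"""

from __future__ import annotations

import pandas as pd

from .calibration import CalibrationModel, fit_linear

__all__ = ["ALGAL_ISOLATES", "isolate_calibration", "CC503_RATIO_532",
           "CC503_RATIO_785"]

#: Benchmark ratios for the reference strain C. reinhardtii CC-503.
CC503_RATIO_532 = 0.52
CC503_RATIO_785 = 0.30

_ROWS = [
    # strain, ratio I1650/I1440, measured C=C, measured N_C=C/N_CH2
    ("Chloroidium sp. DN1", 0.55, 0.86, 0.08),
    ("Dunaliella sp. DN1", 0.57, 0.89, 0.08),
    ("MG8 (unknown lineage)", 0.48, 0.74, 0.07),
    ("Picochloris sp. DN1", 0.75, 1.17, 0.11),
    ("RSSF (unknown lineage)", 1.07, 1.70, 0.15),
    ("Chlamydomonas sp. KSA1", 0.79, 1.30, 0.11),
    ("Chlamydomonas reinhardtii 503", 0.52, 0.80, 0.07),
    ("Chlamydomonas sp. HC1", 1.04, 1.66, 0.15),
]

ALGAL_ISOLATES = pd.DataFrame(
    _ROWS, columns=["strain", "ratio_1650_1440", "c_double_bonds",
                    "n_cc_over_n_ch2"])


def isolate_calibration() -> dict[str, CalibrationModel]:
    """Linear 532 nm calibrations (ratio -> C=C, ratio -> N_C=C/N_CH2)
    fitted by OLS over the eight-strain reference table."""
    c_bonds = fit_linear(
        ALGAL_ISOLATES[["ratio_1650_1440", "c_double_bonds"]].to_numpy(),
        "ratio_1650_1440", "c_double_bonds", excitation_nm=532)
    n_ratio = fit_linear(
        ALGAL_ISOLATES[["ratio_1650_1440", "n_cc_over_n_ch2"]].to_numpy(),
        "ratio_1650_1440", "n_cc_over_n_ch2", excitation_nm=532)
    return {"c_bonds": c_bonds, "n_ratio": n_ratio}
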