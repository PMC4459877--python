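"""Published dose-response and D37 reference values.

Two small datasets ship with the package:

* :func:`mung_bean_elongation` — normalized sprout elongation rates (%) for
  ten groups of mung beans irradiated with 6 MV X-rays on the dose grid
  {0, 1, 2, 5, 10, 20, 50, 100, 200, 400} Gy. The groups received their
  first watering 2-20 h before exposure, so they were in different
  elongation states and show different radiosensitivities.
* :func:`d37_survey` — a compilation of D37 doses and the effective-target
  diameters derived from them (single-hit model, epsilon = 1 eV,
  rho = 1000 kg/m^3) for the ten mung-bean groups plus literature targets
  ranging from prostate tumour cell lines to viruses, seeds and ornamental
  plants.

The ``diameter_nm`` column of the survey carries the *published* (3
significant figure) values; recompute from ``d37_gy`` via
:func:`targetkit.hitmodel.d37_to_volume` for full precision.
"""

from __future__ import annotations

import pandas as pd

#: The experimental dose grid (Gy), shared by all ten groups.
DOSE_GRID_GY = (0.0, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0, 400.0)

#: Normalized sprout elongation rate (%) per dose (rows) and group 1-10
#: (columns). Values above 100% occur and are genuine measurement scatter.
_ELONGATION_PERCENT = {
    0.0: (100.0, 100.0, 100.0, 100.0, 100.0, 100.0, 100.0, 100.0, 100.0, 100.0),
    1.0: (99.9, 98.7, 95.8, 100.6, 98.3, 124.9, 95.8, 87.1, 93.0, 99.9),
    2.0: (108.9, 98.9, 84.4, 100.7, 103.6, 106.3, 105.1, 86.3, 85.3, 108.9),
    5.0: (99.1, 81.6, 84.9, 86.2, 105.3, 105.3, 85.8, 75.8, 79.9, 99.1),
    10.0: (103.7, 91.1, 89.4, 83.1, 100.4, 115.9, 100.8, 85.6, 71.2, 103.7),
    20.0: (104.0, 88.0, 88.8, 81.2, 98.4, 111.8, 90.4, 69.5, 90.0, 104.0),
    50.0: (77.3, 86.1, 96.0, 83.8, 103.3, 98.0, 85.6, 75.2, 79.1, 77.3),
    100.0: (83.9, 76.4, 88.3, 74.2, 91.7, 102.5, 97.9, 64.1, 77.7, 83.9),
    200.0: (76.7, 63.2, 63.0, 75.6, 88.7, 87.5, 70.3, 71.6, 86.5, 76.7),
    400.0: (67.3, 72.2, 64.8, 73.0, 81.5, 89.6, 85.0, 59.3, 78.5, 67.3),
}

#: D37 doses (Gy) attributed to the ten mung-bean groups (group id -> Gy).
GROUP_D37_GY = {
    "group1": 985.0,
    "group2": 1102.0,
    "group3": 893.0,
    "group4": 1449.0,
    "group5": 1684.0,
    "group6": 1560.0,
    "group7": 1863.0,
    "group8": 957.0,
    "group9": 8058.0,
    "group10": 8740.0,
}

# (label, exposure source, D37 in Gy, published diameter in nm)
_D37_SURVEY = [
    ("PC3", "Ionizing radiation", 2.60, 49.0),
    ("LNCaP", "Ionizing radiation", 2.40, 50.3),
    ("CWR22R", "Ionizing radiation", 3.30, 45.2),
    ("FMDV", "Gamma ray", 2700.0, 4.84),
    ("RLV", "Gamma ray", 570.0, 8.12),
    ("HSV", "Gamma ray", 1120.0, 6.49),
    ("Medical herb", "Gamma ray", 550.0, 8.22),
    ("U-87 MG tumor cell", "LINAC", 6.00, 37.1),
    ("PQ30", "Gamma ray", 321.0, 9.84),
    ("OG100", "Gamma ray", 178.0, 12.0),
    ("IN99", "Gamma ray", 20.3, 24.7),
    ("IN602", "Gamma ray", 20.3, 24.7),
    ("ME-180", "Gamma ray", 5.50, 38.2),
    ("HeLa-S3", "Gamma ray", 6.00, 37.1),
    ("Nipponbare", "12C-ion", 52.0, 18.0),
    ("Norin 1", "12C-ion", 36.0, 20.4),
    ("Sasanishiki", "12C-ion", 30.0, 21.7),
    ("Curcuma alismatifolia", "Gamma ray", 28.0, 22.2),
    # published as the range 28.0-20.0 Gy / 22.2-24.8 nm over six cultivars;
    # stored as its two endpoints
    ("Euphorbia pulcherrima (most sensitive cultivar)", "60Co Gamma ray", 28.0, 22.2),
    ("Euphorbia pulcherrima (least sensitive cultivar)", "60Co Gamma ray", 20.0, 24.8),
    ("group1", "6 MV X-ray by LINAC", 985.0, 6.77),
    ("group2", "6 MV X-ray by LINAC", 1102.0, 6.52),
    ("group3", "6 MV X-ray by LINAC", 893.0, 6.99),
    ("group4", "6 MV X-ray by LINAC", 1449.0, 5.95),
    ("group5", "6 MV X-ray by LINAC", 1684.0, 5.66),
    ("group6", "6 MV X-ray by LINAC", 1560.0, 5.81),
    ("group7", "6 MV X-ray by LINAC", 1863.0, 5.47),
    ("group8", "6 MV X-ray by LINAC", 957.0, 6.83),
    ("group9", "6 MV X-ray by LINAC", 8058.0, 3.36),
    ("group10", "6 MV X-ray by LINAC", 8740.0, 3.27),
]


def mung_bean_elongation() -> pd.DataFrame:
    """Normalized sprout elongation rates for the ten irradiated groups.

    Returns a long-format frame with columns ``group`` (group1..group10),
    ``dose_gy`` and ``rate_percent`` (dose 0 is the control, 100% by
    construction). Feed rows per group into
    :class:`targetkit.doseresponse.HitTargetModel` or write them out with
    :func:`targetkit.io.write_dose_response_csv`.
    """
    records = []
    for dose, row in _ELONGATION_PERCENT.items():
        for i, rate in enumerate(row, start=1):
            records.append({"group": f"group{i}", "dose_gy": dose, "rate_percent": rate})
    frame = pd.DataFrame.from_records(records)
    return frame.sort_values(["group", "dose_gy"], key=_group_sort_key).reset_index(drop=True)


def _group_sort_key(col: pd.Series) -> pd.Series:
    if col.name == "group":
        return col.str.extract(r"(\d+)$", expand=False).astype(float)
    return col


def d37_survey() -> pd.DataFrame:
    """Compiled (target, exposure, D37, published diameter) survey rows."""
    return pd.DataFrame(
        _D37_SURVEY, columns=["label", "exposure", "d37_gy", "diameter_nm"]
    )
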