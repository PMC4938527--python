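"""Published reference summaries from the 2012–13 Sri Lanka national
community snakebite survey, used as worked-example inputs and
cross-checks for the estimation code.

Three tables are embedded: province-level reported and extrapolated
bite/envenoming counts with design-based rates, sex-specific incidence
rates, and recalled clinical features among victims.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "province_summary",
    "sex_incidence",
    "clinical_features",
    "NATIONAL_RATES",
    "SAMPLED_POPULATION",
    "N_CLUSTERS",
]

#: Individuals covered by the survey sample and number of sampled clusters.
SAMPLED_POPULATION = 165_665
N_CLUSTERS = 1118

#: National per-100 000 incidence rates (point estimate, 95% CI).
NATIONAL_RATES = {
    "bites": (398.0, 356.0, 441.0),
    "envenoming": (151.0, 130.0, 173.0),
    "deaths": (2.3, 0.2, 4.4),
}

_PROVINCES = [
    # province, zone, bites_reported, bites_estimated, bites_rate,
    # bites_ci, env_reported, env_estimated, env_rate, env_ci
    ("Western", "wet", 61, 18910, 325.0, (217.0, 432.0),
     12, 3720, 64.0, (27.0, 101.0)),
    ("Central", "wet", 45, 7065, 277.0, (182.0, 371.0),
     15, 2355, 92.0, (42.0, 142.0)),
    ("Sabaragamuwa", "wet", 102, 10506, 548.0, (438.0, 658.0),
     35, 3605, 188.0, (127.0, 249.0)),
    ("Northwestern", "wet/intermediate", 92, 11776, 499.0, (392.0, 605.0),
     34, 4352, 184.0, (118.0, 251.0)),
    ("Southern", "wet/intermediate", 87, 11310, 461.0, (338.0, 584.0),
     18, 2340, 95.0, (47.0, 144.0)),
    ("Uva", "dry/intermediate", 63, 4095, 328.0, (242.0, 414.0),
     39, 2535, 203.0, (137.0, 270.0)),
    ("Northern", "dry", 59, 3422, 324.0, (219.0, 428.0),
     42, 2436, 230.0, (145.0, 316.0)),
    ("Eastern", "dry", 67, 5695, 368.0, (227.0, 509.0),
     44, 3740, 242.0, (119.0, 365.0)),
    ("Northcentral", "dry", 119, 7735, 623.0, (487.0, 760.0),
     84, 5460, 440.0, (325.0, 555.0)),
]


def province_summary() -> pd.DataFrame:
    """Province-level reported sample counts, extrapolated national
    counts and per-100 000 rates with 95% CIs, for bites and
    envenomings."""
    rows = []
    for (prov, zone, br, be, brate, bci, er, ee, erate, eci) in _PROVINCES:
        rows.append({
            "province": prov,
            "climate_zone": zone,
            "bites_reported": br,
            "bites_estimated": be,
            "bites_rate": brate,
            "bites_ci_low": bci[0],
            "bites_ci_high": bci[1],
            "envenoming_reported": er,
            "envenoming_estimated": ee,
            "envenoming_rate": erate,
            "envenoming_ci_low": eci[0],
            "envenoming_ci_high": eci[1],
        })
    return pd.DataFrame(rows)


def sex_incidence() -> pd.DataFrame:
    """Sex-specific per-100 000 incidence rates (95% CI) of bites and
    envenoming."""
    return pd.DataFrame([
        {"sex": "male", "bites_rate": 478.0, "bites_ci_low": 414.0,
         "bites_ci_high": 541.0, "envenoming_rate": 176.0,
         "envenoming_ci_low": 146.0, "envenoming_ci_high": 207.0},
        {"sex": "female", "bites_rate": 320.0, "bites_ci_low": 273.0,
         "bites_ci_high": 367.0, "envenoming_rate": 126.0,
         "envenoming_ci_low": 100.0, "envenoming_ci_high": 154.0},
    ])


def clinical_features() -> pd.DataFrame:
    """Recalled clinical features among all bite victims (n = 695) and
    among significantly envenomed victims (n = 323)."""
    rows = [
        ("all_victims", 695, "swelling_at_site", 606),
        ("all_victims", 695, "neurological", 197),
        ("all_victims", 695, "abdominal_pain", 169),
        ("all_victims", 695, "tissue_necrosis", 110),
        ("all_victims", 695, "bleeding", 104),
        ("all_victims", 695, "renal_impairment", 33),
        ("envenomed", 323, "neurological", 120),
        ("envenomed", 323, "bleeding", 27),
        ("envenomed", 323, "neurological_and_bleeding", 77),
        ("envenomed", 323, "other", 99),
    ]
    return pd.DataFrame(rows, columns=["group", "group_n", "feature",
                                       "count"])
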