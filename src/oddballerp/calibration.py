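"""Calibration tables for the synthetic cohort generator.

Two kinds of numbers live here:

``REFERENCE_SUMMARY``
    Group-level summary statistics (mean, SD, group sizes, printed test
    statistics) of the reference clinical cohort the generator is calibrated
    to: 239 cognitively normal (CN) and 95 mild-cognitive-impairment (MCI)
    participants of an auditory-oddball study on a two-channel prefrontal EEG
    device.  These rows are *inputs* to the package: the simulator targets
    their means, and ``reproduce-tables`` recomputes the pooled-t /
    chi-squared statistics directly from them.

``DEFAULT_CALIBRATION``
    Per-group generative parameter distributions (mean, SD, truncation
    bounds) for the subject-level simulator.  Where the reference cohort
    reports a measure directly (age, MMSE, hit rate, response times) the
    distribution is taken from its mean/SD; latent waveform parameters
    (P300 width, background-noise level) have no published counterpart and
    are set to values that place the measured difference-wave features in
    the reference range.  See docs/methods.md for the reasoning.

All distributions are truncated normals; sex is Bernoulli.
"""

from __future__ import annotations

import copy
import hashlib
import json
from typing import Any

from .exceptions import ConfigurationError

GROUPS = ("CN", "MCI")

#: The nine difference-wave (ERP) measures, in report order.
ERP_FEATURES = ("FAL", "AUC", "AMP", "LAT", "T1", "T2", "FALT1", "T2FAL", "T2T1")

#: The six task-performance (behavioral) measures, in report order.
BEHAVIORAL_FEATURES = ("NI", "ER", "ACC", "WER", "RT", "RTSD")

ALL_FEATURES = ERP_FEATURES + BEHAVIORAL_FEATURES

#: Demographic / neuropsychological columns used by the statistics battery.
DEMOGRAPHIC_COLS = ("age_years", "education_years")
NEUROPSYCH_COLS = (
    "mmse",
    "snsb_attention",
    "snsb_language",
    "snsb_visuospatial",
    "snsb_memory",
    "snsb_frontal",
)

# ---------------------------------------------------------------------------
# Reference cohort summaries (mean, sd) per group, with group sizes and the
# published test statistic for each row.  Units: years for age/education,
# points for MMSE/SNSB, ms for latencies, uV for AMP, uV*ms for AUC,
# percent for ACC, counts for NI, dimensionless for ER/WER.
# ---------------------------------------------------------------------------

REFERENCE_N = {"CN": 239, "MCI": 95}

REFERENCE_SEX_COUNTS = {  # (female, male)
    "CN": (140, 99),
    "MCI": (53, 42),
}

REFERENCE_SUMMARY: dict[str, dict[str, Any]] = {
    # demographics & neuropsychological scores
    "age_years": {"CN": (72.17, 5.72), "MCI": (74.13, 6.27), "t": -2.747},
    "education_years": {"CN": (10.58, 4.37), "MCI": (9.40, 4.78), "t": 2.165},
    "mmse": {"CN": (27.62, 1.91), "MCI": (26.04, 2.54), "t": 6.192},
    "snsb_attention": {"CN": (9.49, 2.21), "MCI": (8.38, 1.90), "t": 4.292},
    "snsb_language": {"CN": (0.21, 0.25), "MCI": (-0.13, 0.49), "t": 8.251},
    "snsb_visuospatial": {"CN": (0.52, 0.37), "MCI": (0.00, 0.88), "t": 7.541},
    "snsb_memory": {"CN": (0.32, 0.59), "MCI": (-0.55, 0.67), "t": 11.621},
    "snsb_frontal": {"CN": (0.22, 0.55), "MCI": (-0.42, 0.71), "t": 8.940},
    # ERP difference-wave measures
    "FAL": {"CN": (390.88, 53.42), "MCI": (392.21, 49.52), "t": -0.21},
    "AUC": {"CN": (245.88, 297.27), "MCI": (321.52, 281.66), "t": -2.13},
    "AMP": {"CN": (6.58, 7.12), "MCI": (7.99, 6.80), "t": -1.65},
    "LAT": {"CN": (388.35, 62.41), "MCI": (393.35, 63.52), "t": -0.66},
    "T1": {"CN": (247.21, 101.51), "MCI": (218.32, 96.81), "t": 2.38},
    "T2": {"CN": (484.75, 98.34), "MCI": (503.66, 91.35), "t": -1.62},
    "FALT1": {"CN": (143.67, 79.94), "MCI": (173.89, 82.99), "t": -3.08},
    "T2FAL": {"CN": (93.87, 65.18), "MCI": (111.45, 62.10), "t": -2.25},
    "T2T1": {"CN": (237.54, 119.41), "MCI": (285.35, 119.62), "t": -3.30},
    # behavioral measures
    "NI": {"CN": (1.52, 2.19), "MCI": (2.71, 3.96), "t": -3.49},
    "ER": {"CN": (0.04, 0.05), "MCI": (0.09, 0.12), "t": -5.82},
    "ACC": {"CN": (98.80, 2.23), "MCI": (96.30, 7.02), "t": 4.92},
    "WER": {"CN": (0.01, 0.01), "MCI": (0.02, 0.04), "t": -5.47},
    "RT": {"CN": (347.80, 64.15), "MCI": (348.80, 75.60), "t": -0.12},
    "RTSD": {"CN": (92.76, 39.96), "MCI": (106.89, 40.72), "t": -2.90},
}

#: Published sex chi-squared statistic for the reference cohort.
REFERENCE_SEX_CHI2 = 0.217

#: Features whose group difference is reported significant (p <= 0.05) in the
#: reference cohort; direction checks on simulated cohorts are run on these.
SIGNIFICANT_FEATURES = (
    "AUC", "T1", "FALT1", "T2FAL", "T2T1", "NI", "ER", "ACC", "WER", "RTSD",
)

# ---------------------------------------------------------------------------
# Generative defaults: parameter -> (mean, sd, lower, upper) per group.
# None bounds mean unbounded on that side.
# ---------------------------------------------------------------------------

_PARAM_SPEC = (
    # name                          CN                          MCI
    ("p300_amplitude_uv", (6.58, 4.50, 0.8, None), (7.99, 4.50, 0.8, None)),
    ("p300_latency_ms", (388.0, 45.0, 315.0, 585.0), (393.0, 45.0, 315.0, 585.0)),
    ("p300_width_ms", (55.0, 14.0, 25.0, 110.0), (66.0, 15.0, 25.0, 120.0)),
    ("n100_amplitude_uv", (2.5, 1.0, 0.0, None), (2.5, 1.0, 0.0, None)),
    ("n100_latency_ms", (100.0, 15.0, 60.0, 160.0), (100.0, 15.0, 60.0, 160.0)),
    ("hit_rate", (0.9880, 0.0223, 0.0, 1.0), (0.9630, 0.0702, 0.0, 1.0)),
    ("commission_rate", (0.00594, 0.00856, 0.0, 1.0), (0.01059, 0.01547, 0.0, 1.0)),
    ("rt_mu_ms", (278.0, 50.0, 150.0, None), (264.0, 55.0, 150.0, None)),
    ("rt_sigma_ms", (60.0, 10.0, 5.0, None), (65.0, 12.0, 5.0, None)),
    ("rt_tau_ms", (70.0, 25.0, 1.0, None), (85.0, 30.0, 1.0, None)),
    ("noise_sd_uv", (10.0, 2.5, 1.0, None), (10.0, 2.5, 1.0, None)),
    ("alpha_power", (2.0, 0.8, 0.0, None), (2.0, 0.8, 0.0, None)),
    ("age_years", (72.17, 5.72, 55.0, 95.0), (74.13, 6.27, 55.0, 95.0)),
    ("education_years", (10.58, 4.37, 0.0, 25.0), (9.40, 4.78, 0.0, 25.0)),
    ("mmse", (27.62, 1.91, 10.0, 30.0), (26.04, 2.54, 10.0, 30.0)),
    ("snsb_attention", (9.49, 2.21, 0.0, 20.0), (8.38, 1.90, 0.0, 20.0)),
    ("snsb_language", (0.21, 0.25, -4.0, 4.0), (-0.13, 0.49, -4.0, 4.0)),
    ("snsb_visuospatial", (0.52, 0.37, -4.0, 4.0), (0.00, 0.88, -4.0, 4.0)),
    ("snsb_memory", (0.32, 0.59, -4.0, 4.0), (-0.55, 0.67, -4.0, 4.0)),
    ("snsb_frontal", (0.22, 0.55, -4.0, 4.0), (-0.42, 0.71, -4.0, 4.0)),
)

#: Probability that a simulated subject is male, per group (reference counts).
_MALE_P = {"CN": 99 / 239, "MCI": 42 / 95}


def default_calibration() -> dict[str, Any]:
    """Return a fresh copy of the default calibration table.

    Structure::

        {"CN": {"male_p": float, params: {name: {"mean","sd","low","high"}}},
         "MCI": {...}}
    """
    table: dict[str, Any] = {}
    for group in GROUPS:
        params = {}
        for name, cn_spec, mci_spec in _PARAM_SPEC:
            mean, sd, low, high = cn_spec if group == "CN" else mci_spec
            params[name] = {"mean": mean, "sd": sd, "low": low, "high": high}
        table[group] = {"male_p": _MALE_P[group], "params": params}
    return table


def merge_calibration(overrides: dict | None) -> dict[str, Any]:
    """Merge a (possibly partial) override mapping into the defaults.

    Overrides use the same nesting as :func:`default_calibration`; a parameter
    entry may be a full ``{"mean","sd","low","high"}`` mapping or a
    ``[mean, sd]`` / ``[mean, sd, low, high]`` sequence.
    """
    table = default_calibration()
    if not overrides:
        return table
    for group, block in overrides.items():
        if group not in table:
            raise ConfigurationError(f"unknown group {group!r}")
        if "male_p" in block:
            table[group]["male_p"] = float(block["male_p"])
        for name, entry in block.get("params", {}).items():
            if name not in table[group]["params"]:
                raise ConfigurationError(f"unknown calibration parameter {name!r}")
            slot = table[group]["params"][name]
            if isinstance(entry, dict):
                for key in entry:
                    if key not in slot:
                        raise ConfigurationError(
                            f"unknown calibration field {key!r} for {name!r}"
                        )
                slot.update(entry)
            else:
                vals = list(entry)
                if len(vals) == 2:
                    slot["mean"], slot["sd"] = map(float, vals)
                elif len(vals) == 4:
                    slot["mean"], slot["sd"] = float(vals[0]), float(vals[1])
                    slot["low"] = None if vals[2] is None else float(vals[2])
                    slot["high"] = None if vals[3] is None else float(vals[3])
                else:
                    raise ConfigurationError(
                        f"calibration entry for {name!r} must have 2 or 4 values"
                    )
    return table


def calibration_digest(table: dict, seed: int | None = None) -> str:
    """Stable short digest identifying a calibration table (and master seed)."""
    payload = {"calibration": table, "seed": seed}
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def get_param(table: dict, group: str, name: str) -> dict[str, Any]:
    """Fetch one parameter block, raising :class:`ConfigurationError` if absent."""
    try:
        return table[group]["params"][name]
    except KeyError as exc:  # missing group or parameter
        raise ConfigurationError(
            f"calibration entry missing for group={group!r}, parameter={name!r}"
        ) from exc


def copy_calibration(table: dict) -> dict:
    return copy.deepcopy(table)
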