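"""Cohort assembly and the two-group statistical battery.

:func:`build_cohort_table` turns a :class:`~oddballerp.simulate.CohortBundle`
into one analysis row per included subject (demographics + the nine ERP and
six behavioral measures), keeping an exclusion ledger with the three
inclusion-rule categories: ``no_target_responses``, ``extreme_errors`` and
``no_discernible_peak``.

:class:`GroupComparison` is the model object over a cohort table; ``fit()``
returns a :class:`GroupComparisonResults` carrying

* a demographics table (pooled t per continuous row, chi-squared for sex),
* a feature comparison table (mean (SD) per group, t, p, stars) for the 15
  ERP/behavioral measures,
* the 15 x 3 nested logistic odds-ratio table (per-SD ORs, Wald 95% CI),
* per-group correlation matrices (raw Pearson and partial, adjusted for age,
  sex and education) between the neuropsychological scores and the measures,

with ``summary()`` rendering the lot as text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import behavior, erp, stats
from .calibration import (
    ALL_FEATURES,
    ERP_FEATURES,
    BEHAVIORAL_FEATURES,
    GROUPS,
    NEUROPSYCH_COLS,
    REFERENCE_N,
    REFERENCE_SEX_COUNTS,
    REFERENCE_SUMMARY,
    default_calibration,
)
from .exceptions import FitError, RankError, ReportError
from .simulate import CohortBundle, generate_cohort

EXCLUSION_CATEGORIES = ("no_target_responses", "extreme_errors", "no_discernible_peak")

#: Columns every analysis row must carry.
SUBJECT_COLS = ("subject_id", "group", "age_years", "sex", "education_years") + NEUROPSYCH_COLS


def _classify_exclusion(behav, feats) -> str | None:
    if not behav.valid:
        return behav.reason  # no_target_responses | extreme_errors
    if not feats.valid:
        return "no_discernible_peak"
    return None


def build_cohort_table(
    bundle: CohortBundle,
    *,
    window_ms=erp.ATTRIBUTION_WINDOW_MS,
    taps: int = erp.SMOOTHING_TAPS,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Extract features for every session and assemble the analysis table.

    Returns ``(table, ledger)``.  The ledger satisfies
    ``n_generated == n_included + sum(len(ids) per category)``.
    """
    rows = []
    ledger: dict[str, Any] = {cat: [] for cat in EXCLUSION_CATEGORIES}
    for subject, recording in bundle.subjects:
        trials, n_stray = erp.attribute_responses(
            recording.stimuli, recording.responses, window_ms
        )
        n_target = sum(s.kind == "target" for s in recording.stimuli)
        n_standard = len(recording.stimuli) - n_target
        behav = behavior.compute_behavioral(trials, n_target, n_standard)
        feats = erp.extract_erp_features(
            recording, window_ms=window_ms, taps=taps, trials=trials
        )
        category = _classify_exclusion(behav, feats)
        if category is not None:
            reason = feats.reason if category == "no_discernible_peak" else behav.reason
            ledger[category].append(
                {"subject_id": subject.subject_id, "detail": reason}
            )
            continue
        row = subject.to_dict()
        row.update(feats.to_dict())
        row.update(behav.to_dict())
        row["n_stray_presses"] = n_stray
        rows.append(row)

    table = pd.DataFrame(rows)
    ledger["n_generated"] = len(bundle.subjects)
    ledger["n_included"] = len(table)
    ledger["config_digest"] = bundle.config_digest
    return table, ledger


def simulate_cohort_table(
    n_cn: int,
    n_mci: int,
    config: dict | None = None,
    seed: int | None = None,
    **cohort_kwargs,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Generate a cohort and extract its analysis table in one call."""
    bundle = generate_cohort(n_cn, n_mci, config or default_calibration(), seed,
                             **cohort_kwargs)
    return build_cohort_table(bundle)


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

_DEMOGRAPHIC_ROWS = ("age_years", "education_years") + NEUROPSYCH_COLS


@dataclass
class GroupComparisonResults:
    """Fitted tables of the two-group battery; see module docstring."""

    demographics: pd.DataFrame
    feature_tests: pd.DataFrame
    logistic: pd.DataFrame
    correlations: dict[str, dict[str, pd.DataFrame]]
    correlation_pvalues: dict[str, dict[str, pd.DataFrame]]
    n_cn: int
    n_mci: int
    alpha: float

    def summary(self) -> str:
        lines = [
            "Two-group oddball ERP cohort comparison",
            f"  included subjects: CN={self.n_cn}, MCI={self.n_mci}  (alpha={self.alpha})",
            "",
            "Demographics / neuropsychological scores",
            self.demographics.to_string(index=False),
            "",
            "ERP and behavioral measures (mean (SD), pooled t)",
            self.feature_tests.to_string(index=False),
            "",
            "Odds ratios per SD (logistic models 1-3)",
            self.logistic.to_string(index=False),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_cn": self.n_cn,
            "n_mci": self.n_mci,
            "alpha": self.alpha,
            "demographics": self.demographics.to_dict(orient="records"),
            "feature_tests": self.feature_tests.to_dict(orient="records"),
            "logistic": self.logistic.to_dict(orient="records"),
            "correlations": {
                g: {kind: df.round(6).to_dict() for kind, df in kinds.items()}
                for g, kinds in self.correlations.items()
            },
        }


class GroupComparison:
    """Model object: the full statistical battery over a cohort table."""

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in SUBJECT_COLS + ALL_FEATURES if c not in table.columns]
        if missing:
            raise ReportError(f"cohort table is missing columns: {missing}")
        for g in GROUPS:
            if (table["group"] == g).sum() == 0:
                raise ReportError(f"group {g!r} is empty")
        self.table = table.reset_index(drop=True).copy()
        self.table["sex_male"] = (self.table["sex"] == "male").astype(float)
        self.table["mci"] = (self.table["group"] == "MCI").astype(float)

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame) -> "GroupComparison":
        return cls(table)

    def _groups(self, col: str):
        cn = self.table.loc[self.table["group"] == "CN", col].to_numpy(dtype=float)
        mci = self.table.loc[self.table["group"] == "MCI", col].to_numpy(dtype=float)
        return cn, mci

    def fit(self, alpha: float = stats.DEFAULT_ALPHA,
            standardize: bool = True) -> GroupComparisonResults:
        tab = self.table

        # --- demographics (t for continuous rows, chi-squared for sex) ---
        demo_rows = []
        for col in _DEMOGRAPHIC_ROWS:
            cn, mci = self._groups(col)
            res = stats.students_t(cn, mci)
            demo_rows.append({
                "variable": col,
                "cn_mean": res.mean1, "cn_sd": res.sd1,
                "mci_mean": res.mean2, "mci_sd": res.sd2,
                "statistic": res.t, "p": res.p, "sig": stats.star(res.p, alpha),
                "test": "t",
            })
        sex_counts = pd.crosstab(tab["sex"], tab["group"])
        chi = stats.chi_squared(
            sex_counts.reindex(index=["female", "male"], columns=["CN", "MCI"])
            .fillna(0).to_numpy()
        )
        demo_rows.append({
            "variable": "sex", "cn_mean": np.nan, "cn_sd": np.nan,
            "mci_mean": np.nan, "mci_sd": np.nan,
            "statistic": chi.statistic, "p": chi.p, "sig": stats.star(chi.p, alpha),
            "test": "chi2",
        })
        demographics = pd.DataFrame(demo_rows)

        # --- feature t-tests ---
        feat_rows = []
        for col in ALL_FEATURES:
            cn, mci = self._groups(col)
            res = stats.students_t(cn, mci)
            feat_rows.append({
                "feature": col,
                "cn_mean": res.mean1, "cn_sd": res.sd1,
                "mci_mean": res.mean2, "mci_sd": res.sd2,
                "t": res.t, "p": res.p, "sig": stats.star(res.p, alpha),
            })
        feature_tests = pd.DataFrame(feat_rows)

        # --- nested logistic models ---
        # a single separating/degenerate fit is reported as a failed row
        # rather than aborting the whole battery
        logi_rows = []
        for col in ALL_FEATURES:
            for mid in (1, 2, 3):
                covs = {1: (), 2: stats.DEMOGRAPHIC_COVARIATES,
                        3: stats.DEMOGRAPHIC_COVARIATES + ("mmse",)}[mid]
                try:
                    res = stats.fit_logistic(
                        tab["mci"], tab[col],
                        covariates=tab[list(covs)] if covs else None,
                        standardize=standardize, model_id=mid, predictor_name=col,
                    )
                    row = {
                        "feature": col, "model": mid,
                        "odds_ratio": res.odds_ratio,
                        "ci_low": res.ci_low, "ci_high": res.ci_high,
                        "p": res.p_value, "sig": stats.star(res.p_value, alpha),
                    }
                except (FitError, RankError) as exc:
                    row = {
                        "feature": col, "model": mid,
                        "odds_ratio": np.nan, "ci_low": np.nan,
                        "ci_high": np.nan, "p": np.nan, "sig": f"failed: {exc}",
                    }
                logi_rows.append(row)
        logistic = pd.DataFrame(logi_rows)

        # --- per-group correlation matrices (raw + adjusted) ---
        cov_cols = list(stats.DEMOGRAPHIC_COVARIATES)
        correlations: dict[str, dict[str, pd.DataFrame]] = {}
        pvalues: dict[str, dict[str, pd.DataFrame]] = {}
        for g in GROUPS:
            sub = tab[tab["group"] == g]
            correlations[g] = {}
            pvalues[g] = {}
            for kind, covs in (("raw", None), ("adjusted", sub[cov_cols])):
                rmat = pd.DataFrame(index=NEUROPSYCH_COLS, columns=ALL_FEATURES, dtype=float)
                pmat = rmat.copy()
                for ny in NEUROPSYCH_COLS:
                    for ft in ALL_FEATURES:
                        try:
                            res = stats.partial_correlation(
                                sub[ny], sub[ft], covariates=covs,
                                covariate_names=tuple(cov_cols) if covs is not None else (),
                            )
                            rmat.loc[ny, ft] = res.r
                            pmat.loc[ny, ft] = res.p
                        except (ValueError, RankError):
                            # group too small or degenerate for this adjustment
                            rmat.loc[ny, ft] = np.nan
                            pmat.loc[ny, ft] = np.nan
                correlations[g][kind] = rmat
                pvalues[g][kind] = pmat

        return GroupComparisonResults(
            demographics=demographics,
            feature_tests=feature_tests,
            logistic=logistic,
            correlations=correlations,
            correlation_pvalues=pvalues,
            n_cn=int((tab["group"] == "CN").sum()),
            n_mci=int((tab["group"] == "MCI").sum()),
            alpha=alpha,
        )


# ---------------------------------------------------------------------------
# reference-table recomputation
# ---------------------------------------------------------------------------

def recompute_reference_tests() -> pd.DataFrame:
    """Recompute the pooled t (and sex chi-squared) of every reference-summary
    row from its printed means/SDs and group sizes.

    Columns: variable, cn_mean, cn_sd, mci_mean, mci_sd, t_recomputed,
    t_reference, p.
    """
    n1, n2 = REFERENCE_N["CN"], REFERENCE_N["MCI"]
    rows = []
    for name, entry in REFERENCE_SUMMARY.items():
        m1, s1 = entry["CN"]
        m2, s2 = entry["MCI"]
        res = stats.students_t_from_summary(m1, s1, n1, m2, s2, n2)
        rows.append({
            "variable": name,
            "cn_mean": m1, "cn_sd": s1, "mci_mean": m2, "mci_sd": s2,
            "t_recomputed": res.t, "t_reference": entry["t"], "p": res.p,
        })
    f_cn, m_cn = REFERENCE_SEX_COUNTS["CN"]
    f_mci, m_mci = REFERENCE_SEX_COUNTS["MCI"]
    chi = stats.chi_squared([[f_cn, f_mci], [m_cn, m_mci]])
    rows.append({
        "variable": "sex", "cn_mean": np.nan, "cn_sd": np.nan,
        "mci_mean": np.nan, "mci_sd": np.nan,
        "t_recomputed": chi.statistic, "t_reference": 0.217, "p": chi.p,
    })
    return pd.DataFrame(rows)
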