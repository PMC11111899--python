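"""Descriptive tables and sex-stratified odds-ratio analysis.

The descriptive side reproduces the usual case-characteristics table for a
spontaneous-report cohort: sex, age bins (<18, 18-64, 65-85, >85 — the 65-85
bin is inclusive at both ends, >85 strictly greater), weight bins (<50,
50-100, >100 kg), reporter occupation, top reporting countries, serious
outcome codes and time-to-onset bins ([0,30], [31,60], [61,90], [91,180],
[181,360], >360 days).  Demographic percentages use the full case count as
denominator; onset percentages use the cases with a valid (non-negative,
day-precision) onset interval.

The analytic side is a case/non-case comparison within the drug's own
reports: the unadjusted odds ratio from the 2x2 table with a Wald CI, and a
maximum-likelihood logistic model for the covariate-adjusted estimate.  With
a single binary exposure and no covariates, the logistic MLE equals the
closed-form cross-product ratio — an identity the test suite asserts.
Missing data are handled complete-case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "SubgroupTable",
    "RegressionSpec",
    "SeparationError",
    "descriptive_table",
    "onset_bin_table",
    "two_by_two_or",
    "adjusted_logistic",
]

_Z95 = 1.96

AGE_BINS = ((None, 18, "<18"), (18, 65, "18-64"), (65, 85.0001, "65-85"),
            (85.0001, None, ">85"))
WEIGHT_BINS = ((None, 50, "<50 kg"), (50, 100.0001, "50-100 kg"), (100.0001, None, ">100 kg"))
ONSET_BINS = ((0, 30, "0-30"), (31, 60, "31-60"), (61, 90, "61-90"),
              (91, 180, "91-180"), (181, 360, "181-360"), (361, None, ">360"))
OUTCOME_LABELS = {"DE": "Death", "LT": "Life-Threatening",
                  "HO": "Hospitalization", "DS": "Disability",
                  "CA": "Congenital Anomaly", "RI": "Required Intervention",
                  "OT": "Other Serious"}
REPORTER_LABELS = {"MD": "Physician", "PH": "Pharmacist", "CN": "Consumer",
                   "OT": "Others"}


class SeparationError(RuntimeError):
    """Perfect separation: the logistic MLE does not exist."""


class SubgroupTable(NamedTuple):
    """2x2 outcome-by-exposure counts.

    n11: exposed cases, n10: exposed controls,
    n01: unexposed cases, n00: unexposed controls.
    """

    n11: float
    n10: float
    n01: float
    n00: float


@dataclass(frozen=True)
class RegressionSpec:
    """What goes into the adjusted logistic model."""

    outcome: str = "y"
    exposure: str = "female"
    covariates: tuple[str, ...] = ("age", "weight", "reporter", "outcome_code")
    _ALLOWED = frozenset({"age", "weight", "reporter", "outcome_code"})

    def __post_init__(self) -> None:
        bad = set(self.covariates) - self._ALLOWED
        if bad:
            raise ValueError(f"unsupported covariates: {sorted(bad)}")


def _pct(count: float, denom: float) -> float:
    return round(100.0 * count / denom, 1) if denom else float("nan")


def _bin_counts(values: pd.Series, bins) -> list[tuple[str, int]]:
    out = []
    v = values.dropna().astype(float)
    for lo, hi, label in bins:
        mask = pd.Series(True, index=v.index)
        if lo is not None:
            mask &= v >= lo
        if hi is not None:
            mask &= v < hi
        out.append((label, int(mask.sum())))
    return out


def descriptive_table(cases: pd.DataFrame,
                      outcomes: pd.DataFrame | None = None,
                      top_countries: int = 5) -> pd.DataFrame:
    """Case-characteristics table with counts and one-decimal percentages.

    ``cases`` is the deduplicated case-level frame (columns sex, age, wt,
    occp_cod, reporter_country); ``outcomes`` the OUTC rows restricted to
    those cases.  Percentages of demographic sections use the total case
    count as denominator, so 'Unknown' rows make sections sum to ~100.
    """
    if cases.empty:
        return pd.DataFrame(columns=["section", "category", "count", "pct"])
    n = len(cases)
    rows: list[tuple[str, str, int, float]] = []

    sex = cases["sex"].fillna("").astype(str).str.upper()
    for label, code in (("Female", "F"), ("Male", "M")):
        rows.append(("Gender", label, int((sex == code).sum()), _pct(int((sex == code).sum()), n)))
    unk = n - int(sex.isin(["F", "M"]).sum())
    rows.append(("Gender", "Unknown", unk, _pct(unk, n)))

    age = pd.to_numeric(cases["age"], errors="coerce")
    for label, count in _bin_counts(age, AGE_BINS):
        rows.append(("Age", label, count, _pct(count, n)))
    rows.append(("Age", "Unknown", int(age.isna().sum()), _pct(int(age.isna().sum()), n)))

    wt = pd.to_numeric(cases["wt"], errors="coerce")
    for label, count in _bin_counts(wt, WEIGHT_BINS):
        rows.append(("Weight", label, count, _pct(count, n)))
    rows.append(("Weight", "Unknown", int(wt.isna().sum()), _pct(int(wt.isna().sum()), n)))

    occ = cases["occp_cod"].fillna("").astype(str)
    for code in ("PH", "MD", "CN", "OT"):
        cnt = int((occ == code).sum())
        rows.append(("Reporter", REPORTER_LABELS[code], cnt, _pct(cnt, n)))
    unk = n - int(occ.isin(list(REPORTER_LABELS)).sum())
    rows.append(("Reporter", "Unknown", unk, _pct(unk, n)))

    country = cases["reporter_country"].fillna("").astype(str)
    for value, cnt in country[country != ""].value_counts().head(top_countries).items():
        rows.append(("Reported Countries", value, int(cnt), _pct(int(cnt), n)))

    if outcomes is not None and not outcomes.empty:
        per_case = outcomes.drop_duplicates(["primaryid", "outc_cod"])
        counts = per_case["outc_cod"].value_counts()
        for code in ("DE", "LT", "HO", "DS", "CA", "RI", "OT"):
            if code in counts:
                rows.append(("Serious Outcomes", OUTCOME_LABELS[code],
                             int(counts[code]), _pct(int(counts[code]), n)))

    return pd.DataFrame(rows, columns=["section", "category", "count", "pct"])


def onset_bin_table(onset: pd.Series) -> pd.DataFrame:
    """Binned time-to-onset with percentages over cases with a valid onset.

    Returns an empty-count table with denominator 0 when no onset is valid.
    """
    valid = pd.to_numeric(onset, errors="coerce").dropna()
    valid = valid[valid >= 0]
    denom = len(valid)
    rows = []
    for lo, hi, label in ONSET_BINS:
        mask = valid >= lo
        if hi is not None:
            mask &= valid <= hi
        cnt = int(mask.sum())
        rows.append(("Onset (days)", label, cnt, _pct(cnt, denom)))
    frame = pd.DataFrame(rows, columns=["section", "category", "count", "pct"])
    frame.attrs["denominator"] = denom
    return frame


def two_by_two_or(table: SubgroupTable) -> tuple[float, float, float, float]:
    """Unadjusted odds ratio with Wald 95% CI and two-sided p.

    OR = (n11*n00)/(n10*n01); SE(lnOR) = sqrt(sum 1/cell).  A zero cell
    triggers the Haldane +0.5 correction on all four cells; if a full margin
    is zero even then the result is undefined (NaN).
    """
    cells = np.array(table, dtype=float)
    if (cells < 0).any():
        raise ValueError("counts must be non-negative")
    if cells.sum() <= 0:
        raise ValueError("empty table")
    if (cells == 0).any():
        cells = cells + 0.5
    n11, n10, n01, n00 = cells
    if (n11 + n10) == 0 or (n01 + n00) == 0 or (n11 + n01) == 0 or (n10 + n00) == 0:
        return float("nan"), float("nan"), float("nan"), float("nan")
    orr = (n11 * n00) / (n10 * n01)
    se = math.sqrt((1 / cells).sum())
    lo, hi = orr * math.exp(-_Z95 * se), orr * math.exp(_Z95 * se)
    z = math.log(orr) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return orr, lo, hi, p


def _design_matrix(records: pd.DataFrame, spec: RegressionSpec
                   ) -> tuple[pd.Series, pd.DataFrame]:
    cols = [spec.outcome, spec.exposure, *spec.covariates]
    data = records[cols].copy()
    for col in (spec.outcome, spec.exposure):
        data[col] = pd.to_numeric(data[col], errors="coerce")
    for col in spec.covariates:
        if col in ("age", "weight"):
            data[col] = pd.to_numeric(data[col], errors="coerce")
    data = data.dropna()
    y = data[spec.outcome].astype(int)
    X = pd.DataFrame({spec.exposure: data[spec.exposure].astype(float)})
    for col in spec.covariates:
        if col in ("age", "weight"):
            X[col] = data[col].astype(float)
        else:
            # categorical with the largest class as reference
            series = data[col].astype(str)
            ref = series.value_counts().idxmax()
            for level in sorted(series.unique()):
                if level != ref:
                    X[f"{col}[{level}]"] = (series == level).astype(float)
    X = sm.add_constant(X, has_constant="add")
    return y, X


def adjusted_logistic(records: pd.DataFrame, spec: RegressionSpec
                      ) -> pd.DataFrame:
    """Maximum-likelihood logistic fit; one row per term with OR, CI and p.

    Complete-case on the modelled columns.  Perfect separation (including a
    constant outcome) raises :class:`SeparationError` rather than emitting a
    spurious estimate.  A warning-level situation — fewer than 10 complete
    records per parameter — is annotated in the result's ``attrs``.
    """
    y, X = _design_matrix(records, spec)
    if y.nunique() < 2:
        raise SeparationError("outcome is constant in the complete-case records")
    low_n = len(y) < 10 * X.shape[1]
    try:
        fit = sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-10, maxiter=200)
    except (np.linalg.LinAlgError, PerfectSeparationError) as exc:
        raise SeparationError(str(exc)) from exc
    params = fit.params
    if not np.all(np.isfinite(fit.bse)) or np.abs(params).max() > 25:
        raise SeparationError("separation suspected: unbounded coefficient")
    ci = fit.conf_int(alpha=0.05)
    out = pd.DataFrame({
        "term": params.index,
        "coef": params.to_numpy(),
        "or": np.exp(params.to_numpy()),
        "or_lo95": np.exp(ci[0].to_numpy()),
        "or_hi95": np.exp(ci[1].to_numpy()),
        "p": fit.pvalues.to_numpy(),
    })
    out = out[out["term"] != "const"].reset_index(drop=True)
    out.attrs["n"] = int(len(y))
    out.attrs["low_n_warning"] = bool(low_n)
    out.attrs["converged"] = bool(fit.mle_retvals.get("converged", True))
    return out
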