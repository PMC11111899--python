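"""Disproportionality statistics for spontaneous-report signal detection.

For every (target drug, preferred term) pair, the universe of unique
(case, PT) counting units is partitioned into the classic 2x2 table

====================  ==================  =====================
                      target PT           other PTs
====================  ==================  =====================
target drug (PS)      a                   b
all other drugs       c                   d
====================  ==================  =====================

and four frequentist / Bayesian statistics are computed:

* ROR  = ad/bc, with Wald 95% CI on the log scale,
  SE(lnROR) = sqrt(1/a + 1/b + 1/c + 1/d);
* PRR  = [a/(a+b)] / [c/(c+d)], with the Pearson chi-squared
  chi2 = (ad-bc)^2 N / [(a+b)(c+d)(a+c)(b+d)] (no continuity correction);
* EBGM = aN/[(a+b)(a+c)] — the simplified closed-form relative reporting
  ratio used as the MGPS point estimate here (no gamma-mixture fit) — with
  EBGM05/EBGM95 = exp(lnEBGM -/+ 1.96 * SE(lnROR));
* BCPNN information component IC = log2(aN/[(a+b)(a+c)]), with the
  conjugate-prior posterior moments E(IC), V(IC) and the lower credibility
  bound IC-2SD = E(IC) - 2*sqrt(V(IC)).

Note the algebraic identity EBGM = 2**IC under these closed forms; it is a
deliberate property of the simplified estimator pair and is asserted in the
test suite.  "IC025" in reports is this IC-2SD bound.

A pair is a *consensus signal* when all four method-specific thresholds are
met simultaneously: a>=3 & lower ROR CI > 1; a>=3 & PRR>=2 & chi2>=4;
EBGM05 > 2; IC-2SD > 0.  Statistics undefined because of zero margins are
flagged false, never silently NaN-propagated into a signal.

Zero-cell policy: when any of b, c, d is zero, ROR and its CI use the
Haldane–Anscombe +0.5 correction on all four cells; PRR, EBGM and IC use the
raw cells and come back undefined (NaN) on zero denominators.  The a>=3
gates dominate real decisions, so the correction only affects reported
magnitudes of non-signals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .ingest import UNMAPPED_SOC, PtDictionary

__all__ = [
    "ContingencyTable",
    "BcpnnHyperparams",
    "SignalThresholds",
    "EmptyUniverseError",
    "build_contingency",
    "ror_stat",
    "prr_stat",
    "ebgm_stat",
    "bcpnn_stat",
    "evaluate_thresholds",
    "score_pairs",
    "aggregate_soc",
]

_LN2 = math.log(2.0)
_Z95 = 1.96


class EmptyUniverseError(ValueError):
    """No (case, PT) units to tabulate."""


class ContingencyTable(NamedTuple):
    a: float
    b: float
    c: float
    d: float

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def validate(self) -> "ContingencyTable":
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.n <= 0:
            raise EmptyUniverseError("empty universe: N = 0")
        return self


@dataclass(frozen=True)
class BcpnnHyperparams:
    """Conjugate-prior hyperparameters; defaults give prior independence."""

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0

    def gamma(self, table: ContingencyTable) -> float:
        n = table.n
        return (self.gamma11 * (n + self.alpha) * (n + self.beta)
                / ((table.a + table.b + self.alpha1) * (table.a + table.c + self.beta1)))


@dataclass(frozen=True)
class SignalThresholds:
    """Per-method signal criteria (the conventional pharmacovigilance set)."""

    a_min: int = 3
    ror_lo_min: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ebgm05_min: float = 2.0
    ic025_min: float = 0.0


def build_contingency(pairs: pd.DataFrame, target_pt: str) -> ContingencyTable:
    """2x2 table for one PT over a (primaryid, pt, exposed) pair universe."""
    if pairs.empty:
        raise EmptyUniverseError("empty universe: no (case, PT) pairs")
    is_pt = pairs["pt"] == target_pt
    exp = pairs["exposed"].to_numpy(dtype=bool)
    a = int((is_pt & exp).sum())
    b = int((~is_pt & exp).sum())
    c = int((is_pt & ~exp).sum())
    d = int((~is_pt & ~exp).sum())
    return ContingencyTable(a, b, c, d).validate()


def ror_stat(table: ContingencyTable) -> tuple[float, float, float]:
    """Reporting odds ratio with Wald 95% CI (Haldane +0.5 if b, c or d is 0)."""
    table.validate()
    a, b, c, d = table
    if min(b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if a == 0:
        return 0.0, float("nan"), float("nan")
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * math.exp(-_Z95 * se), ror * math.exp(_Z95 * se)


def prr_stat(table: ContingencyTable) -> tuple[float, float]:
    """Proportional reporting ratio and Pearson chi-squared (uncorrected)."""
    table.validate()
    a, b, c, d = table
    n = table.n
    if (a + b) == 0 or (c + d) == 0 or c == 0:
        return float("nan"), float("nan")
    prr = (a / (a + b)) / (c / (c + d))
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = (a * d - b * c) ** 2 * n / denom if denom > 0 else float("nan")
    return prr, chi2


def ebgm_stat(table: ContingencyTable) -> tuple[float, float, float]:
    """Closed-form EBGM = aN/[(a+b)(a+c)] with log-normal style 95% bounds."""
    table.validate()
    a, b, c, d = table
    n = table.n
    if (a + b) == 0 or (a + c) == 0:
        return float("nan"), float("nan"), float("nan")
    ebgm = a * n / ((a + b) * (a + c))
    if min(a, b, c, d) == 0:
        return ebgm, float("nan"), float("nan")
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ebgm, ebgm * math.exp(-_Z95 * se), ebgm * math.exp(_Z95 * se)


def bcpnn_stat(table: ContingencyTable,
               hyper: BcpnnHyperparams = BcpnnHyperparams()
               ) -> tuple[float, float, float, float]:
    """Information component with posterior moments.

    Returns (ic, e_ic, v_ic, ic_minus_2sd).  The point IC is NaN when any
    margin is zero; the posterior quantities are defined for all tables with
    non-negative cells, which is the point of the Bayesian smoothing.
    """
    table.validate()
    a, b, c, d = table
    n = table.n
    if a > 0 and (a + b) > 0 and (a + c) > 0:
        ic = math.log2(a * n / ((a + b) * (a + c)))
    else:
        ic = float("nan")
    g = hyper.gamma(table)
    a1, b1, al, be, g11 = (hyper.alpha1, hyper.beta1, hyper.alpha,
                           hyper.beta, hyper.gamma11)
    e_ic = math.log2((a + g11) * (n + al) * (n + be)
                     / ((n + g) * (a + b + a1) * (a + c + b1)))
    v_ic = (1.0 / _LN2**2) * (
        (n - a + g - g11) / ((a + g11) * (1 + n + g))
        + (n - (a + b) + al - a1) / ((a + b + a1) * (1 + n + al))
        + (n - (a + c) + be - b1) / ((a + c + b1) * (1 + n + be)))
    return ic, e_ic, v_ic, e_ic - 2.0 * math.sqrt(v_ic)


def evaluate_thresholds(score: pd.Series | dict,
                        thresholds: SignalThresholds = SignalThresholds()
                        ) -> dict[str, bool]:
    """Per-method flags and the all-four consensus for one scored pair.

    NaN statistics never satisfy a criterion (comparisons with NaN are
    False), so undefined methods simply cannot vote a signal.
    """
    a = score["a"]
    flags = {
        "flag_ror": bool(a >= thresholds.a_min and score["ror_lo95"] > thresholds.ror_lo_min),
        "flag_prr": bool(a >= thresholds.a_min and score["prr"] >= thresholds.prr_min
                         and score["chi2"] >= thresholds.chi2_min),
        "flag_mgps": bool(score["ebgm05"] > thresholds.ebgm05_min),
        "flag_bcpnn": bool(score["ic_minus_2sd"] > thresholds.ic025_min),
    }
    flags["consensus"] = all(flags.values())
    return flags


def _vector_scores(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray,
                   hyper: BcpnnHyperparams) -> dict[str, np.ndarray]:
    """Vectorised statistics over parallel cell arrays (float64)."""
    n = a + b + c + d
    out: dict[str, np.ndarray] = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        # ROR with Haldane correction where b, c or d is zero
        corr = (np.minimum(np.minimum(b, c), d) == 0)
        ah, bh, ch, dh = (x + np.where(corr, 0.5, 0.0) for x in (a, b, c, d))
        ror = (ah * dh) / (bh * ch)
        se_h = np.sqrt(1 / ah + 1 / bh + 1 / ch + 1 / dh)
        out["ror"] = np.where(ah > 0, ror, 0.0)
        out["ror_lo95"] = np.where(ah > 0, ror * np.exp(-_Z95 * se_h), np.nan)
        out["ror_hi95"] = np.where(ah > 0, ror * np.exp(_Z95 * se_h), np.nan)

        prr = (a / (a + b)) / (c / (c + d))
        prr[(c == 0) | (a + b == 0) | (c + d == 0)] = np.nan
        out["prr"] = prr
        denom = (a + b) * (c + d) * (a + c) * (b + d)
        chi2 = (a * d - b * c) ** 2 * n / denom
        chi2[denom == 0] = np.nan
        out["chi2"] = chi2

        ebgm = a * n / ((a + b) * (a + c))
        ebgm[(a + b == 0) | (a + c == 0)] = np.nan
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        zero = np.minimum(np.minimum(a, b), np.minimum(c, d)) == 0
        out["ebgm"] = ebgm
        out["ebgm05"] = np.where(zero, np.nan, ebgm * np.exp(-_Z95 * se))
        out["ebgm95"] = np.where(zero, np.nan, ebgm * np.exp(_Z95 * se))

        ic = np.log2(a * n / ((a + b) * (a + c)))
        ic[(a == 0) | (a + b == 0) | (a + c == 0)] = np.nan
        out["ic"] = ic
        a1, b1, al, be, g11 = (hyper.alpha1, hyper.beta1, hyper.alpha,
                               hyper.beta, hyper.gamma11)
        g = g11 * (n + al) * (n + be) / ((a + b + a1) * (a + c + b1))
        e_ic = np.log2((a + g11) * (n + al) * (n + be)
                       / ((n + g) * (a + b + a1) * (a + c + b1)))
        v_ic = (1.0 / _LN2**2) * (
            (n - a + g - g11) / ((a + g11) * (1 + n + g))
            + (n - (a + b) + al - a1) / ((a + b + a1) * (1 + n + al))
            + (n - (a + c) + be - b1) / ((a + c + b1) * (1 + n + be)))
        out["e_ic"] = e_ic
        out["v_ic"] = v_ic
        out["ic_minus_2sd"] = e_ic - 2.0 * np.sqrt(v_ic)
    return out


def score_pairs(pairs: pd.DataFrame, drug: str = "target",
                dictionary: PtDictionary | None = None,
                thresholds: SignalThresholds = SignalThresholds(),
                hyper: BcpnnHyperparams = BcpnnHyperparams()) -> pd.DataFrame:
    """Score every PT against the target drug over a pair universe.

    ``pairs`` must hold one row per unique (primaryid, pt) with a boolean
    ``exposed`` column.  Returns one row per PT, sorted by ``a`` descending
    then PT, with statistics, per-method flags and the consensus column.
    """
    if pairs.empty:
        raise EmptyUniverseError("empty universe: no (case, PT) pairs")
    units = pairs.drop_duplicates(["primaryid", "pt"])
    n_units = len(units)
    n_exposed = int(units["exposed"].sum())
    per_pt = units.groupby("pt", sort=True)["exposed"].agg(["sum", "count"])
    a = per_pt["sum"].to_numpy(dtype=float)
    pt_total = per_pt["count"].to_numpy(dtype=float)
    b = float(n_exposed) - a
    c = pt_total - a
    d = float(n_units) - a - b - c
    stats = _vector_scores(a, b, c, d, hyper)
    frame = pd.DataFrame({"drug": drug, "pt": per_pt.index,
                          "a": a.astype(int), "b": b.astype(int),
                          "c": c.astype(int), "d": d.astype(int), **stats})
    if dictionary is not None:
        frame.insert(2, "soc", dictionary.map_series(frame["pt"]))
    with np.errstate(invalid="ignore"):
        frame["flag_ror"] = (frame["a"] >= thresholds.a_min) & (
            frame["ror_lo95"].to_numpy() > thresholds.ror_lo_min)
        frame["flag_prr"] = ((frame["a"] >= thresholds.a_min)
                             & (frame["prr"].to_numpy() >= thresholds.prr_min)
                             & (frame["chi2"].to_numpy() >= thresholds.chi2_min))
        frame["flag_mgps"] = frame["ebgm05"].to_numpy() > thresholds.ebgm05_min
        frame["flag_bcpnn"] = frame["ic_minus_2sd"].to_numpy() > thresholds.ic025_min
    frame["consensus"] = (frame["flag_ror"] & frame["flag_prr"]
                          & frame["flag_mgps"] & frame["flag_bcpnn"])
    return (frame.sort_values(["a", "pt"], ascending=[False, True], kind="stable")
            .reset_index(drop=True))


def aggregate_soc(pairs: pd.DataFrame, dictionary: PtDictionary,
                  drug: str = "target", dedup_within_case: bool = True,
                  hyper: BcpnnHyperparams = BcpnnHyperparams()) -> pd.DataFrame:
    """System-organ-class level report burden and ROR.

    The counting unit becomes the (case, SOC) pair: by default a case with
    several PTs in the same SOC contributes once to that SOC (set-based
    collapse), which is the natural reading of SOC-level report counts.
    ``dedup_within_case=False`` switches to summing PT-level units instead.
    ``n`` is the number of exposed units in the SOC.
    """
    if pairs.empty:
        return pd.DataFrame(columns=["drug", "soc", "n", "a", "b", "c", "d",
                                     "ror", "ror_lo95", "ror_hi95"])
    units = pairs.drop_duplicates(["primaryid", "pt"]).copy()
    units["soc"] = dictionary.map_series(units["pt"])
    if dedup_within_case:
        units = units.drop_duplicates(["primaryid", "soc"])
    n_units = len(units)
    n_exposed = int(units["exposed"].sum())
    per_soc = units.groupby("soc", sort=True)["exposed"].agg(["sum", "count"])
    a = per_soc["sum"].to_numpy(dtype=float)
    b = float(n_exposed) - a
    c = per_soc["count"].to_numpy(dtype=float) - a
    d = float(n_units) - a - b - c
    stats = _vector_scores(a, b, c, d, hyper=hyper)
    frame = pd.DataFrame({"drug": drug, "soc": per_soc.index,
                          "n": a.astype(int), "a": a.astype(int),
                          "b": b.astype(int), "c": c.astype(int),
                          "d": d.astype(int),
                          "ror": stats["ror"], "ror_lo95": stats["ror_lo95"],
                          "ror_hi95": stats["ror_hi95"]})
    return (frame.sort_values(["n", "soc"], ascending=[False, True], kind="stable")
            .reset_index(drop=True))
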