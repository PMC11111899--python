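"""Parsing and assembly of FAERS-style '$'-delimited quarterly tables.

The stages here mirror standard spontaneous-report cleaning practice:

* strict parsing of the ASCII dialect (header-driven column order, empty
  fields become missing values, ragged lines are an error);
* deduplication keeping, per case, the highest version — ties broken by the
  latest receipt date, then the largest primaryid — after collapsing exact
  row copies (the FDA's published recommendation, operationalised);
* target-drug selection by whole-name match against a list of name variants
  restricted to a role code (default "PS", primary suspect);
* PT -> system organ class mapping with an explicit "UNMAPPED" bucket so
  dictionary gaps are counted, never silently dropped.

Dates are day-precision YYYYMMDD integers; month-precision values (YYYYMM)
are treated as missing for any date arithmetic but are not an error — FAERS
contains them, and fabricating a day would bias onset intervals.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "PtDictionary",
    "parse_table",
    "parse_date",
    "parse_date_series",
    "load_quarter",
    "assemble_demo",
    "deduplicate",
    "select_target_cases",
    "map_pt_to_soc",
    "case_pt_pairs",
    "onset_days",
]

UNMAPPED_SOC = "UNMAPPED"

TABLE_COLUMNS = {
    "DEMO": ["primaryid", "caseid", "caseversion", "fda_dt", "event_dt",
             "sex", "age", "wt", "occp_cod", "reporter_country"],
    "DRUG": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname"],
    "REAC": ["primaryid", "caseid", "pt"],
    "OUTC": ["primaryid", "caseid", "outc_cod"],
    "THER": ["primaryid", "caseid", "dsg_drug_seq", "start_dt"],
}

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})


class FormatError(ValueError):
    """Malformed FAERS-style input."""


def parse_table(path: str | Path, expected_columns: Sequence[str]) -> pd.DataFrame:
    """Read one '$'-delimited table into a string-typed DataFrame.

    Column order is taken from the header, not from position.  Empty fields
    become ``None``.  A header missing any of ``expected_columns`` or a data
    line whose field count differs from the header raises :class:`FormatError`
    (naming the column, or the 1-based line number).
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="$")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, no header") from None
        missing = [c for c in expected_columns if c not in header]
        if missing:
            raise FormatError(f"{path}: missing mandatory column(s) {missing}")
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise FormatError(
                    f"{path}: line {lineno} has {len(row)} fields, expected {len(header)}")
            rows.append([v if v != "" else None for v in row])
    return pd.DataFrame(rows, columns=header, dtype=object)


def parse_date(value: object) -> pd.Timestamp | None:
    """One FAERS date field -> Timestamp, or None.

    Eight digits are parsed as YYYYMMDD; six digits (month precision) and
    anything unparseable are treated as absent, with a debug-level log line
    (the caller decides whether partial dates matter).
    """
    if value is None or value == "" or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if len(s) == 6 and s.isdigit():
        logger.debug("month-precision date %r treated as absent", s)
        return None
    ts = pd.to_datetime(s, format="%Y%m%d", errors="coerce")
    if pd.isna(ts):
        logger.debug("unparseable date %r treated as absent", s)
        return None
    return ts


def parse_date_series(values: pd.Series) -> tuple[pd.Series, int]:
    """Vectorised :func:`parse_date`; returns (dates, n_partial).

    ``n_partial`` counts month-precision values, which are kept as text by
    callers that need provenance but excluded from date arithmetic.
    """
    s = values.astype("string").str.strip()
    partial = s.str.fullmatch(r"\d{6}").fillna(False)
    n_partial = int(partial.sum())
    if n_partial:
        logger.warning("%d month-precision date(s) treated as absent", n_partial)
    parsed = pd.to_datetime(s.where(~partial), format="%Y%m%d", errors="coerce")
    return parsed, n_partial


def load_quarter(directory: str | Path, quarter: str) -> dict[str, pd.DataFrame]:
    """Load the five tables of one quarter (files named like DEMO23Q1.txt)."""
    directory = Path(directory)
    out = {}
    for stem, cols in TABLE_COLUMNS.items():
        out[stem] = parse_table(directory / f"{stem}{quarter}.txt", cols)
    return out


def assemble_demo(demo: pd.DataFrame) -> pd.DataFrame:
    """Type the DEMO table for deduplication and descriptive analysis.

    Returns a copy with integer primaryid/caseid/caseversion, parsed
    ``fda_dt``/``event_dt`` (month-precision kept as text in ``event_dt_raw``),
    and numeric age / weight.
    """
    out = demo.copy()
    for col in ("primaryid", "caseid", "caseversion"):
        out[col] = pd.to_numeric(out[col], errors="raise").astype("int64")
    out["fda_dt"], _ = parse_date_series(out["fda_dt"])
    out["event_dt_raw"] = out["event_dt"]
    out["event_dt"], _ = parse_date_series(out["event_dt"])
    out["age"] = pd.to_numeric(out["age"], errors="coerce")
    out["wt"] = pd.to_numeric(out["wt"], errors="coerce")
    out["sex"] = out["sex"].fillna("").astype(str)
    return out


def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """One report per case: highest version, then latest receipt, then largest id.

    Exact row copies are collapsed first.  Output is sorted by caseid, so the
    operation is deterministic and idempotent.  Expects the typed frame from
    :func:`assemble_demo` (caseversion and primaryid must sort numerically).
    """
    if demo.empty:
        return demo.copy()
    d = demo.drop_duplicates()
    d = d.sort_values(["caseid", "caseversion", "fda_dt", "primaryid"],
                      kind="stable", na_position="first")
    d = d.groupby("caseid", sort=True).tail(1)
    return d.sort_values("caseid", kind="stable").reset_index(drop=True)


def _normalize_name(name: object) -> str:
    return str(name).strip().casefold()


def select_target_cases(drug: pd.DataFrame, name_variants: Iterable[str],
                        role: str = "PS") -> np.ndarray:
    """primaryids of reports listing a target drug under ``role``.

    Matching is whole-name equality on trimmed, case-folded names — not a
    substring match, so salt forms ("BEDAQUILINE FUMARATE") do not hit the
    plain variant unless listed explicitly.
    """
    variants = {_normalize_name(v) for v in name_variants}
    if not variants:
        raise ValueError("name_variants must be non-empty")
    if role not in ROLE_CODES:
        raise ValueError(f"role must be one of {sorted(ROLE_CODES)}")
    names = drug["drugname"].map(_normalize_name)
    hit = names.isin(variants) & (drug["role_cod"] == role)
    ids = pd.to_numeric(drug.loc[hit, "primaryid"]).astype("int64")
    return np.unique(ids.to_numpy())


@dataclass
class PtDictionary:
    """Total PT -> SOC mapping with case-insensitive, trimmed lookup."""

    mapping: dict[str, str]
    unmapped_seen: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PtDictionary":
        mapping = {}
        for pt, soc in zip(frame["pt"], frame["soc"]):
            key = _normalize_name(pt)
            if key in mapping and mapping[key] != soc:
                raise FormatError(f"PT {pt!r} maps to multiple SOCs")
            mapping[key] = str(soc)
        return cls(mapping)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PtDictionary":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        if not {"pt", "soc"} <= set(frame.columns):
            raise FormatError(f"{path}: dictionary needs 'pt' and 'soc' columns")
        return cls.from_frame(frame)

    def lookup(self, pt: str) -> str:
        soc = self.mapping.get(_normalize_name(pt))
        if soc is None:
            self.unmapped_seen[str(pt)] = self.unmapped_seen.get(str(pt), 0) + 1
            return UNMAPPED_SOC
        return soc

    def map_series(self, pts: pd.Series) -> pd.Series:
        return pts.map(self.lookup)


def map_pt_to_soc(pt: str, dictionary: PtDictionary) -> str:
    """The unique SOC of ``pt``, or the reserved "UNMAPPED" bucket."""
    return dictionary.lookup(pt)


def case_pt_pairs(reac: pd.DataFrame, kept_primaryids: Iterable[int],
                  exposed_primaryids: Iterable[int]) -> pd.DataFrame:
    """Unique (case, PT) counting units with an exposure flag.

    ``kept_primaryids`` are the deduplicated reports forming the analysis
    universe; ``exposed_primaryids`` those listing the target drug as primary
    suspect.  One row per distinct (primaryid, pt).
    """
    kept = np.asarray(sorted(set(map(int, kept_primaryids))), dtype="int64")
    exposed = set(map(int, exposed_primaryids))
    pid = pd.to_numeric(reac["primaryid"]).astype("int64")
    sub = pd.DataFrame({"primaryid": pid, "pt": reac["pt"].astype(str)})
    sub = sub[sub["primaryid"].isin(kept)].drop_duplicates()
    sub["exposed"] = sub["primaryid"].isin(exposed)
    return sub.sort_values(["primaryid", "pt"], kind="stable").reset_index(drop=True)


def onset_days(demo_dedup: pd.DataFrame, ther: pd.DataFrame,
               target_primaryids: Iterable[int]) -> pd.Series:
    """Days from earliest therapy start to the event, per target report.

    Month-precision or missing dates yield NaN; negative intervals are set to
    NaN as well (an event before therapy start cannot be treatment-emergent).
    """
    ids = sorted(set(map(int, target_primaryids)))
    t = ther.copy()
    t["primaryid"] = pd.to_numeric(t["primaryid"]).astype("int64")
    t = t[t["primaryid"].isin(ids)]
    t["start"], _ = parse_date_series(t["start_dt"])
    starts = t.groupby("primaryid")["start"].min()
    d = demo_dedup.set_index("primaryid").loc[
        demo_dedup["primaryid"].isin(ids).to_numpy(), "event_dt"]
    aligned = pd.DataFrame({"event": d}).join(starts.rename("start"), how="left")
    days = (aligned["event"] - aligned["start"]).dt.days.astype("float64")
    days[days < 0] = np.nan
    return days
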