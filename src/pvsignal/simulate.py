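"""Synthetic spontaneous-report data with planted disproportionality signals.

This module emulates the record structure of FDA Adverse Event Reporting
System (FAERS) quarterly extracts closely enough to exercise every stage of
the analysis pipeline offline: versioned case reports with deliberate
duplicates, drug entries with suspect/concomitant role codes, multiple
MedDRA-style preferred terms (PTs) per case, demographics with realistic
missingness, outcome codes, and therapy/event dates.  Known drug-event
reporting-rate ratios ("planted signals") provide ground truth for signal
recovery studies.

The reporting model
-------------------
Every case receives exactly one primary-suspect (PS) drug, drawn uniformly,
plus a Poisson number of concomitant drugs.  Background adverse events are
drawn per case as a truncated-geometric number of PTs (mean
``pt_multiplicity_mean``) sampled from the non-planted PT pool.  Each
planted signal ``(drug, pt, r)`` turns its PT into an independent Bernoulli
event: probability ``baseline_event_rate`` for every case, raised to
``min(1, r * baseline_event_rate)`` for cases whose PS drug is the planted
drug.  The per-case reporting-rate ratio between exposed and unexposed cases
therefore equals ``r`` exactly (up to the cap).

A ``duplicate_fraction`` share of cases is re-submitted with an incremented
version number and a later receipt date, and a tenth of that rate is emitted
as verbatim row copies, so downstream deduplication has real work to do.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "SimConfig",
    "QuarterBundle",
    "GeneFixtures",
    "generate_quarter",
    "generate_pt_dictionary",
    "generate_gene_fixtures",
    "generate_subgroup_records",
    "drug_name",
    "pt_name",
    "write_gmt",
]

OUTCOME_CODES = ("HO", "DE", "LT", "DS", "CA", "RI", "OT")
_OUTCOME_P = (0.35, 0.20, 0.08, 0.04, 0.02, 0.06, 0.25)
_REPORTER_CODES = ("MD", "PH", "CN", "OT")
_REPORTER_P = (0.75, 0.03, 0.03, 0.19)
_COUNTRIES = ("CN", "ZA", "IN", "UZ", "BY", "US")
_COUNTRY_P = (0.25, 0.15, 0.15, 0.10, 0.08, 0.27)

#: fraction of date fields emitted at month precision (YYYYMM) to exercise
#: the partial-date parsing policy downstream
PARTIAL_DATE_FRACTION = 0.05


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def drug_name(i: int) -> str:
    return f"DRUG{i + 1:03d}"


def pt_name(j: int) -> str:
    return f"PT{j + 1:04d}"


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic quarter.

    ``planted_signals`` is a sequence of ``(drug_id, pt_id, rate_ratio)``
    triples; ids are zero-based indices into the drug / PT ranges.
    """

    n_cases: int = 20_000
    n_drugs: int = 60
    n_pts: int = 200
    baseline_event_rate: float = 0.01
    planted_signals: tuple[tuple[int, int, float], ...] = ()
    duplicate_fraction: float = 0.05
    missing_demo_fraction: float = 0.10
    seed: int = 0
    pt_multiplicity_mean: float = 3.0
    quarter: str = "23Q1"

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_drugs <= 0 or self.n_pts <= 0:
            raise ConfigError("n_cases, n_drugs and n_pts must be positive")
        for name in ("baseline_event_rate", "duplicate_fraction", "missing_demo_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1], got {v}")
        if self.pt_multiplicity_mean < 1.0:
            raise ConfigError("pt_multiplicity_mean must be >= 1")
        object.__setattr__(self, "planted_signals", tuple(tuple(s) for s in self.planted_signals))
        seen = set()
        for d, p, r in self.planted_signals:
            if not (0 <= d < self.n_drugs) or not (0 <= p < self.n_pts):
                raise ConfigError(f"planted signal ({d}, {p}, {r}) outside declared id ranges")
            if r < 1.0:
                raise ConfigError(f"planted rate ratio must be >= 1, got {r}")
            if (d, p) in seen:
                raise ConfigError(f"duplicate planted pair ({d}, {p})")
            seen.add((d, p))
        if len({p for _, p, _ in self.planted_signals}) != len(self.planted_signals):
            raise ConfigError("planted signals must use distinct PT ids")


@dataclass
class QuarterBundle:
    """The five FAERS-style tables of one quarter, held as DataFrames."""

    quarter: str
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {"DEMO": self.demo, "DRUG": self.drug, "REAC": self.reac,
                "OUTC": self.outc, "THER": self.ther}

    def write(self, outdir: str | Path) -> list[Path]:
        """Emit the FAERS quarterly ASCII dialect: '$'-delimited text files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for stem, frame in self.tables().items():
            path = outdir / f"{stem}{self.quarter}.txt"
            lines = ["$".join(frame.columns)]
            cols = [frame[c].astype(str).where(frame[c].notna() & (frame[c] != ""), "")
                    for c in frame.columns]
            body = pd.Series(cols[0].values, dtype=object)
            for c in cols[1:]:
                body = body + "$" + c.values
            lines.extend(body.tolist())
            path.write_text("\n".join(lines) + "\n", encoding="utf-8")
            paths.append(path)
        return paths


def _quarter_window(quarter: str) -> tuple[np.datetime64, int]:
    """Start date and day count of a 'YYQq' quarter label."""
    year = 2000 + int(quarter[:2])
    q = int(quarter[-1])
    start = np.datetime64(f"{year}-{3 * (q - 1) + 1:02d}-01", "D")
    end = (np.datetime64(f"{year + 1}-01-01", "D") if q == 4
           else np.datetime64(f"{year}-{3 * q + 1:02d}-01", "D"))
    return start, int((end - start) / np.timedelta64(1, "D"))


def _format_dates(days: np.ndarray, partial: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """YYYYMMDD strings; YYYYMM where ``partial``; empty where ``missing``."""
    as_dt = pd.Series(days.astype("datetime64[D]"))
    full = as_dt.dt.strftime("%Y%m%d").to_numpy(dtype=object)
    month = as_dt.dt.strftime("%Y%m").to_numpy(dtype=object)
    out = np.where(partial, month, full)
    out[missing] = ""
    return out


def generate_quarter(config: SimConfig) -> QuarterBundle:
    """Simulate one quarter of spontaneous reports under ``config``.

    Returns the five tables (DEMO/DRUG/REAC/OUTC/THER).  Identical configs
    (including seed) produce identical output, byte for byte once written.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    case_id = 100_000_000 + np.arange(n, dtype=np.int64)
    ps_drug = rng.integers(0, config.n_drugs, size=n)

    # --- reactions -------------------------------------------------------
    planted_pts = sorted({p for _, p, _ in config.planted_signals})
    pool = np.setdiff1d(np.arange(config.n_pts), np.array(planted_pts, dtype=int))
    if pool.size == 0:
        raise ConfigError("no non-planted PTs left in the pool")
    # truncated geometric multiplicity (support 1..10); sampling PT slots with
    # replacement and collapsing duplicates slightly shrinks the realised mean
    k = np.minimum(rng.geometric(1.0 / config.pt_multiplicity_mean, size=n), 10)
    slots_case = np.repeat(np.arange(n), k)
    slots_pt = pool[rng.integers(0, pool.size, size=slots_case.size)]
    pair_case = [slots_case]
    pair_pt = [slots_pt]
    for d, p, r in config.planted_signals:
        prob = np.where(ps_drug == d,
                        min(1.0, r * config.baseline_event_rate),
                        config.baseline_event_rate)
        hit = rng.random(n) < prob
        pair_case.append(np.nonzero(hit)[0])
        pair_pt.append(np.full(int(hit.sum()), p, dtype=int))
    pairs = pd.DataFrame({
        "case": np.concatenate(pair_case),
        "pt": np.concatenate(pair_pt),
    }).drop_duplicates().sort_values(["case", "pt"], kind="stable")

    # every case must report at least one PT; k >= 1 guarantees it
    # --- drugs -----------------------------------------------------------
    n_conc = rng.poisson(0.8, size=n)
    conc_case = np.repeat(np.arange(n), n_conc)
    conc_drug = rng.integers(0, config.n_drugs, size=conc_case.size)
    conc_role = rng.choice(["SS", "C", "I"], p=[0.3, 0.5, 0.2], size=conc_case.size)

    # --- dates -----------------------------------------------------------
    start, n_days = _quarter_window(config.quarter)
    start_i = start.astype("datetime64[D]").astype(np.int64)
    fda = start_i + rng.integers(0, n_days, size=n)
    event = fda - rng.integers(0, 180, size=n)
    onset = np.minimum(np.floor(rng.exponential(90.0, size=n)).astype(np.int64), 400)
    ther_start = event - onset

    miss = config.missing_demo_fraction
    event_missing = rng.random(n) < miss
    event_partial = rng.random(n) < PARTIAL_DATE_FRACTION
    ther_missing = rng.random(n) < miss
    ther_partial = rng.random(n) < PARTIAL_DATE_FRACTION

    # --- demographics ----------------------------------------------------
    sex = rng.choice(["F", "M"], size=n)
    sex[rng.random(n) < miss] = ""
    age = np.clip(np.round(rng.normal(45, 16, size=n)), 1, 95).astype(int).astype(object)
    age[rng.random(n) < miss] = ""
    wt = np.round(np.clip(rng.normal(62, 13, size=n), 30, 140), 1).astype(object)
    wt[rng.random(n) < miss] = ""
    occp = rng.choice(_REPORTER_CODES, p=_REPORTER_P, size=n)
    country = rng.choice(_COUNTRIES, p=_COUNTRY_P, size=n)

    # --- outcomes --------------------------------------------------------
    n_outc = rng.choice([0, 1, 2], p=[0.30, 0.55, 0.15], size=n)
    outc_case = np.repeat(np.arange(n), n_outc)
    outc_code = rng.choice(OUTCOME_CODES, p=_OUTCOME_P, size=outc_case.size)

    # --- assemble version-1 tables --------------------------------------
    def pid(case_idx: np.ndarray, version: int) -> np.ndarray:
        return case_id[case_idx] * 10 + version

    demo = pd.DataFrame({
        "primaryid": case_id * 10 + 1,
        "caseid": case_id,
        "caseversion": 1,
        "fda_dt": _format_dates(fda, np.zeros(n, bool), np.zeros(n, bool)),
        "event_dt": _format_dates(event, event_partial, event_missing),
        "sex": sex,
        "age": age,
        "wt": wt,
        "occp_cod": occp,
        "reporter_country": country,
    })
    drug_rows = pd.DataFrame({
        "primaryid": np.concatenate([pid(np.arange(n), 1), pid(conc_case, 1)]),
        "caseid": np.concatenate([case_id, case_id[conc_case]]),
        "drug_seq": np.concatenate([np.ones(n, int), 2 + np.arange(conc_case.size) % 5]),
        "role_cod": np.concatenate([np.full(n, "PS", dtype=object), conc_role]),
        "drugname": np.concatenate([
            np.array([drug_name(i) for i in ps_drug], dtype=object),
            np.array([drug_name(i) for i in conc_drug], dtype=object),
        ]),
    })
    reac = pd.DataFrame({
        "primaryid": pid(pairs["case"].to_numpy(), 1),
        "caseid": case_id[pairs["case"].to_numpy()],
        "pt": np.array([pt_name(j) for j in pairs["pt"]], dtype=object),
    })
    outc = pd.DataFrame({
        "primaryid": pid(outc_case, 1),
        "caseid": case_id[outc_case],
        "outc_cod": outc_code,
    })
    ther = pd.DataFrame({
        "primaryid": case_id * 10 + 1,
        "caseid": case_id,
        "dsg_drug_seq": 1,
        "start_dt": _format_dates(ther_start, ther_partial, ther_missing),
    })

    # --- duplicates ------------------------------------------------------
    # re-submissions: same case, version 2, later receipt date
    dup = np.nonzero(rng.random(n) < config.duplicate_fraction)[0]
    if dup.size:
        fda2 = fda[dup] + rng.integers(7, 90, size=dup.size)
        demo2 = demo.iloc[dup].copy()
        demo2["primaryid"] = case_id[dup] * 10 + 2
        demo2["caseversion"] = 2
        demo2["fda_dt"] = _format_dates(fda2, np.zeros(dup.size, bool), np.zeros(dup.size, bool))
        demo = pd.concat([demo, demo2], ignore_index=True)
        for name, frame in (("drug", drug_rows), ("reac", reac), ("outc", outc), ("ther", ther)):
            sub = frame[frame["caseid"].isin(case_id[dup])].copy()
            sub["primaryid"] = sub["caseid"] * 10 + 2
            if name == "drug":
                drug_rows = pd.concat([drug_rows, sub], ignore_index=True)
            elif name == "reac":
                reac = pd.concat([reac, sub], ignore_index=True)
            elif name == "outc":
                outc = pd.concat([outc, sub], ignore_index=True)
            else:
                ther = pd.concat([ther, sub], ignore_index=True)

    # verbatim row copies at a tenth of the duplicate rate
    copy = np.nonzero(rng.random(n) < config.duplicate_fraction / 10.0)[0]
    if copy.size:
        pids = set((case_id[copy] * 10 + 1).tolist())
        demo = pd.concat([demo, demo[demo["primaryid"].isin(pids)]], ignore_index=True)
        reac = pd.concat([reac, reac[reac["primaryid"].isin(pids)]], ignore_index=True)

    return QuarterBundle(config.quarter, demo, drug_rows, reac, outc, ther)


def generate_pt_dictionary(n_soc: int, n_pt: int, seed: int) -> pd.DataFrame:
    """Synthetic PT -> SOC dictionary (stands in for a licensed MedDRA table).

    Every PT maps to exactly one system organ class; every SOC receives at
    least one PT.  Deterministic for a given seed.
    """
    if n_soc < 1 or n_pt < n_soc:
        raise ConfigError("need n_pt >= n_soc >= 1")
    rng = np.random.default_rng(seed)
    soc_ids = np.concatenate([np.arange(n_soc), rng.integers(0, n_soc, size=n_pt - n_soc)])
    return pd.DataFrame({
        "pt": [pt_name(j) for j in range(n_pt)],
        "soc": [f"SOC{int(i) + 1:02d}" for i in soc_ids],
    })


@dataclass
class GeneFixtures:
    """Gene-level fixtures for the network-pharmacology stage.

    All content is synthetic: gene symbols, scores, edges and annotation sets
    are generated, not exported from any real database.
    """

    universe: list[str]
    drug_table: pd.DataFrame      # gene, source, score  (probability-like scores)
    disease_table: pd.DataFrame   # gene, source, score  (relevance-like scores)
    edges: pd.DataFrame           # gene_a, gene_b, combined_score
    annotations: dict[str, set[str]]
    namespaces: dict[str, str]    # annotation set -> namespace label

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.drug_table.to_csv(outdir / "drug_targets.tsv", sep="\t", index=False)
        self.disease_table.to_csv(outdir / "disease_genes.tsv", sep="\t", index=False)
        self.edges.to_csv(outdir / "ppi_edges.tsv", sep="\t", index=False)
        (outdir / "universe.txt").write_text("\n".join(self.universe) + "\n")
        write_gmt(self.annotations, outdir / "annotations.gmt", self.namespaces)


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    lines = []
    for name in sets:
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *sorted(sets[name])]))
    Path(path).write_text("\n".join(lines) + "\n")


def _hub_degree_sequence(n_nodes: int, n_edges: int, n_hubs: int,
                         cutoff: int) -> list[int]:
    """A graphical degree sequence with exactly ``n_hubs`` nodes above ``cutoff``."""
    total = 2 * n_edges
    hubs = [cutoff + 1 + (i % 5) for i in range(n_hubs)]
    rest = total - sum(hubs)
    n_rest = n_nodes - n_hubs
    if n_rest <= 0 or rest < n_rest or rest > n_rest * cutoff:
        raise ConfigError("hub degree sequence infeasible for these sizes")
    base = rest // n_rest
    seq = hubs + [base + 1] * (rest - base * n_rest) + [base] * (n_rest - (rest - base * n_rest))
    if not nx.is_graphical(seq):
        raise ConfigError("degree sequence not graphical")
    return seq


def generate_gene_fixtures(n_universe: int, n_drug_targets: int,
                           n_disease_genes: int, overlap: int, n_edges: int,
                           seed: int, n_hubs: int = 0, hub_degree_cutoff: int = 10,
                           n_annotation_sets: int = 12,
                           n_decoy_edges: int = 20) -> GeneFixtures:
    """Scored gene tables, a PPI-style edge list and annotation sets.

    The drug-target and disease-gene tables intersect in exactly ``overlap``
    symbols once filtered at their documented score cutoffs (>0 for the
    probability-like drug scores, >=10 for the relevance-like disease scores);
    sub-threshold decoy rows are included so the filters are exercised.  The
    confidence-filtered edge list (combined_score >= 0.7) spans the overlap
    genes with exactly ``n_edges`` edges; when ``n_hubs`` > 0 the degree
    sequence is constructed so exactly that many nodes exceed
    ``hub_degree_cutoff``.
    """
    if overlap > min(n_drug_targets, n_disease_genes):
        raise ConfigError("overlap cannot exceed either set size")
    if max(n_drug_targets, n_disease_genes) > n_universe:
        raise ConfigError("set sizes cannot exceed the universe")
    if n_drug_targets + n_disease_genes - overlap > n_universe:
        raise ConfigError("universe too small for the requested sets")
    rng = np.random.default_rng(seed)
    universe = [f"G{i + 1:04d}" for i in range(n_universe)]
    order = rng.permutation(n_universe)
    shared = [universe[i] for i in order[:overlap]]
    drug_only = [universe[i] for i in order[overlap:n_drug_targets]]
    disease_only = [universe[i] for i in
                    order[n_drug_targets:n_drug_targets + n_disease_genes - overlap]]
    drug_set = shared + drug_only
    disease_set = shared + disease_only

    n_decoy = max(3, n_drug_targets // 10)
    decoy_drug = [universe[i] for i in order[-n_decoy:]]
    drug_table = pd.DataFrame({
        "gene": drug_set + decoy_drug,
        "source": (["target_db_a"] * (len(drug_set) // 2)
                   + ["target_db_b"] * (len(drug_set) - len(drug_set) // 2)
                   + ["target_db_a"] * n_decoy),
        "score": np.concatenate([
            np.round(rng.uniform(0.05, 1.0, size=len(drug_set)), 4),
            np.zeros(n_decoy),
        ]),
    })
    decoy_dis = [universe[i] for i in order[-2 * n_decoy:-n_decoy]]
    disease_table = pd.DataFrame({
        "gene": disease_set + decoy_dis,
        "source": (["disease_db_a"] * (len(disease_set) // 2)
                   + ["disease_db_b"] * (len(disease_set) - len(disease_set) // 2)
                   + ["disease_db_b"] * n_decoy),
        "score": np.concatenate([
            np.round(rng.uniform(10.0, 60.0, size=len(disease_set)), 2),
            np.round(rng.uniform(0.5, 9.9, size=n_decoy), 2),
        ]),
    })

    # PPI edges over the overlap genes
    pool = sorted(shared)
    if n_edges > len(pool) * (len(pool) - 1) // 2:
        raise ConfigError("n_edges exceeds the possible simple-graph edges")
    if n_hubs > 0:
        seq = _hub_degree_sequence(len(pool), n_edges, n_hubs, hub_degree_cutoff)
        g = nx.havel_hakimi_graph(seq)
    else:
        g = nx.gnm_random_graph(len(pool), n_edges, seed=int(rng.integers(2**31)))
    relabel = dict(enumerate(rng.permutation(pool)))
    g = nx.relabel_nodes(g, relabel)
    edge_rows = sorted(tuple(sorted(e)) for e in g.edges())
    edges = pd.DataFrame(edge_rows, columns=["gene_a", "gene_b"])
    edges["combined_score"] = np.round(rng.uniform(0.70, 0.999, size=len(edges)), 3)
    # low-confidence decoys, removed by the 0.7 filter on load
    if n_decoy_edges and len(pool) >= 2:
        ia = rng.integers(0, len(pool), size=n_decoy_edges)
        ib = rng.integers(0, len(pool), size=n_decoy_edges)
        decoys = pd.DataFrame({
            "gene_a": [pool[i] for i in np.minimum(ia, ib)],
            "gene_b": [pool[i] for i in np.maximum(ia, ib)],
            "combined_score": np.round(rng.uniform(0.15, 0.69, size=n_decoy_edges), 3),
        })
        decoys = decoys[decoys.gene_a != decoys.gene_b]
        existing = set(map(tuple, edges[["gene_a", "gene_b"]].to_numpy()))
        decoys = decoys[~decoys.apply(lambda r: (r.gene_a, r.gene_b) in existing, axis=1)]
        decoys = decoys.drop_duplicates(["gene_a", "gene_b"])
        edges = pd.concat([edges, decoys], ignore_index=True)

    # annotation sets: background sets plus two genuinely enriched in the overlap
    ns_cycle = itertools.cycle(["BP", "CC", "MF", "KEGG"])
    annotations: dict[str, set[str]] = {}
    namespaces: dict[str, str] = {}
    for i in range(n_annotation_sets):
        size = int(rng.integers(20, 80))
        members = set(rng.choice(universe, size=size, replace=False))
        name = f"SET{i + 1:02d}"
        annotations[name] = members
        namespaces[name] = next(ns_cycle)
    for i, frac in enumerate((0.6, 0.4)):
        take = max(3, int(frac * len(shared)))
        members = set(rng.choice(pool, size=min(take, len(pool)), replace=False))
        members |= set(rng.choice(universe, size=15, replace=False))
        name = f"ENRICHED{i + 1:02d}"
        annotations[name] = members
        namespaces[name] = "BP" if i == 0 else "KEGG"
    return GeneFixtures(universe, drug_table, disease_table, edges,
                        annotations, namespaces)


def generate_subgroup_records(n: int, beta_female: float, seed: int,
                              intercept: float = -0.3) -> pd.DataFrame:
    """Individual-level records for logistic parameter recovery.

    Outcome probability follows logit(p) = intercept + beta_female * female
    + 0.01*(age-45) - 0.005*(weight-60), with categorical reporter and
    outcome-code columns carrying no true effect.
    """
    rng = np.random.default_rng(seed)
    female = rng.integers(0, 2, size=n)
    age = np.clip(rng.normal(45, 15, size=n), 18, 90)
    weight = np.clip(rng.normal(62, 12, size=n), 35, 130)
    reporter = rng.choice(_REPORTER_CODES, p=_REPORTER_P, size=n)
    outcome_code = rng.choice(OUTCOME_CODES, p=_OUTCOME_P, size=n)
    eta = (intercept + beta_female * female
           + 0.01 * (age - 45.0) - 0.005 * (weight - 60.0))
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return pd.DataFrame({
        "y": y, "female": female, "age": np.round(age, 1),
        "weight": np.round(weight, 1), "reporter": reporter,
        "outcome_code": outcome_code,
    })
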