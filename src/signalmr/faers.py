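"""Spontaneous-report ETL: read quarterly tables, deduplicate, build cohorts.

The reader consumes the '$'-delimited quarterly ASCII dialect (DEMO, DRUG,
REAC and optionally OUTC tables keyed by PRIMARYID).  Deduplication keeps
one report per CASEID: the latest FDA_DT wins, ties broken by the highest
PRIMARYID.  Cohort construction matches target drugs by case-insensitive
substring against drug name and active ingredient, matches events by exact
case-insensitive preferred-term (PT) comparison, and assembles the 2x2
contingency table under either the full-database background or a
lipid-lowering-class background, with optional gender/age stratification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .disproportionality import ContingencyTable
from .synthetic import TARGET_DRUG_TERMS, MEMORY_LOSS_PTS

__all__ = [
    "SafetyReport",
    "CohortDefinition",
    "LIPID_LOWERING_TERMS",
    "read_quarterly_tables",
    "deduplicate",
    "match_drug",
    "match_event",
    "build_contingency",
    "stratify",
    "reports_from_synthetic",
]

# Generic-name list standing in for ATC class C10 (lipid-modifying agents):
# statins, ezetimibe, fibrates, bile-acid sequestrants, bempedoic acid,
# niacin and the PCSK9-directed agents.  Editable; FAERS itself carries no
# ATC codes.
LIPID_LOWERING_TERMS = (
    "atorvastatin", "simvastatin", "rosuvastatin", "pravastatin",
    "lovastatin", "fluvastatin", "pitavastatin",
    "ezetimibe", "fenofibrate", "gemfibrozil", "bezafibrate", "ciprofibrate",
    "bempedoic", "niacin", "nicotinic acid",
    "colesevelam", "cholestyramine", "colestipol",
    "lomitapide", "mipomersen", "evinacumab",
) + TARGET_DRUG_TERMS

_SERIOUS_CODES = {"DE": "death", "HO": "hospitalization",
                  "LT": "life-threatening", "DS": "disability",
                  "OT": "other"}
_OCCP_CODES = {"CN": "consumer", "HP": "health professional",
               "MD": "physician", "PH": "pharmacist", "OT": "other"}


@dataclass
class SafetyReport:
    """One spontaneous report after deduplication."""

    primary_id: int
    case_id: int
    fda_dt: int                      # YYYYMMDD integer, locale-free ordering
    age_years: float | None
    gender: str                      # 'male' / 'female' / 'missing'
    reporter: str
    country: str
    drugs: list[tuple[str, str, str]] = field(default_factory=list)  # (name, ai, role)
    reactions: list[str] = field(default_factory=list)
    serious_outcomes: list[str] = field(default_factory=list)


@dataclass
class CohortDefinition:
    """Target drugs, target events, background universe and strata filters."""

    drug_terms: tuple[str, ...] = TARGET_DRUG_TERMS
    event_pts: tuple[str, ...] = MEMORY_LOSS_PTS
    background: str = "full"                       # 'full' | 'lipid_lowering'
    lipid_lowering_terms: tuple[str, ...] = LIPID_LOWERING_TERMS
    counting: str = "event"                        # 'event' | 'report'
    roles: tuple[str, ...] | None = None           # None = all role codes
    gender: str | None = None                      # restrict to one stratum
    age_stratum: str | None = None

    def __post_init__(self):
        if not self.drug_terms or not self.event_pts:
            raise ValueError("drug_terms and event_pts must be non-empty")
        if self.background not in ("full", "lipid_lowering"):
            raise ValueError("background must be 'full' or 'lipid_lowering'")
        if self.background == "lipid_lowering":
            if not self.lipid_lowering_terms:
                raise ValueError("lipid_lowering_terms required under the "
                                 "lipid-lowering background")
            universe = {t.lower() for t in self.lipid_lowering_terms}
            missing = [t for t in self.drug_terms if t.lower() not in universe]
            if missing:
                raise ValueError(
                    f"target drug terms {missing} are not part of the "
                    "lipid-lowering term universe")
        if self.counting not in ("event", "report"):
            raise ValueError("counting must be 'event' or 'report'")


# --------------------------------------------------------------------------
# reading

_DEMO_REQUIRED = ["PRIMARYID", "CASEID", "FDA_DT"]


def read_quarterly_tables(directory, quarters=None):
    """Read '$'-delimited quarterly DEMO/DRUG/REAC (and OUTC) files.

    ``directory`` holds files named ``DEMO<quarter>.txt`` etc.  Returns
    ``(records, counters)``: one raw record dict per DEMO row with its
    drugs and reactions attached, and a counter dict of malformed rows
    (excluded and counted, never silently dropped).
    """
    directory = Path(directory)
    demo_files = sorted(directory.glob("DEMO*.txt"))
    if quarters is not None:
        demo_files = [directory / f"DEMO{q}.txt" for q in quarters]
    if not demo_files:
        raise FileNotFoundError(f"no DEMO*.txt files in {directory}")

    counters = {"malformed_fda_dt": 0, "missing_caseid": 0, "demo_rows": 0}
    records: dict[int, dict] = {}
    for demo_path in demo_files:
        label = demo_path.stem[len("DEMO"):]
        demo = _read_table(demo_path, _DEMO_REQUIRED)
        drug = _read_table(directory / f"DRUG{label}.txt",
                           ["PRIMARYID", "DRUGNAME"])
        reac = _read_table(directory / f"REAC{label}.txt", ["PRIMARYID", "PT"])
        outc_path = directory / f"OUTC{label}.txt"
        outc = (_read_table(outc_path, ["PRIMARYID", "OUTC_COD"])
                if outc_path.exists() else None)

        counters["demo_rows"] += len(demo)
        fda = pd.to_numeric(demo["FDA_DT"], errors="coerce")
        bad = fda.isna()
        counters["malformed_fda_dt"] += int(bad.sum())
        case = pd.to_numeric(demo["CASEID"], errors="coerce")
        bad_case = case.isna() & ~bad
        counters["missing_caseid"] += int(bad_case.sum())
        demo = demo[~bad & ~bad_case].copy()
        demo["FDA_DT"] = fda[~bad & ~bad_case].astype(int)
        demo["CASEID"] = case[~bad & ~bad_case].astype(int)

        drugs_by_pid: dict[int, list] = {}
        for row in drug.itertuples(index=False):
            pid = int(row.PRIMARYID)
            ai = getattr(row, "PROD_AI", "") or ""
            role = getattr(row, "ROLE_COD", "") or ""
            drugs_by_pid.setdefault(pid, []).append(
                (str(row.DRUGNAME), str(ai), str(role)))
        reac_by_pid: dict[int, list] = {}
        for row in reac.itertuples(index=False):
            reac_by_pid.setdefault(int(row.PRIMARYID), []).append(str(row.PT))
        outc_by_pid: dict[int, list] = {}
        if outc is not None:
            for row in outc.itertuples(index=False):
                outc_by_pid.setdefault(int(row.PRIMARYID), []).append(
                    _SERIOUS_CODES.get(str(row.OUTC_COD), "other"))

        for row in demo.itertuples(index=False):
            pid = int(row.PRIMARYID)
            age = pd.to_numeric(getattr(row, "AGE", None), errors="coerce")
            sex = str(getattr(row, "SEX", "") or "").strip().upper()
            records[pid] = {
                "primary_id": pid,
                "case_id": int(row.CASEID),
                "fda_dt": int(row.FDA_DT),
                "age_years": None if pd.isna(age) else float(age),
                "gender": {"M": "male", "F": "female"}.get(sex, "missing"),
                "reporter": _OCCP_CODES.get(
                    str(getattr(row, "OCCP_COD", "") or "").strip(), "other"),
                "country": str(getattr(row, "REPORTER_COUNTRY", "") or ""),
                "drugs": drugs_by_pid.get(pid, []),
                "reactions": reac_by_pid.get(pid, []),
                "serious_outcomes": outc_by_pid.get(pid, []),
            }
    return list(records.values()), counters


def _read_table(path, required):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False,
                     na_values=[""])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing mandatory column(s) {missing}")
    return df


# --------------------------------------------------------------------------
# deduplication and matching

def deduplicate(raw_records) -> list[SafetyReport]:
    """One report per CASEID: latest FDA_DT, ties to the highest PRIMARYID.

    Output sorted by case_id, so the result is order-independent and the
    operation idempotent.
    """
    best: dict[int, dict] = {}
    for rec in raw_records:
        r = rec if isinstance(rec, dict) else vars(rec)
        key = r["case_id"]
        cur = best.get(key)
        if cur is None or (r["fda_dt"], r["primary_id"]) > (
                cur["fda_dt"], cur["primary_id"]):
            best[key] = r
    out = []
    for key in sorted(best):
        r = best[key]
        out.append(SafetyReport(**{k: r.get(k) for k in (
            "primary_id", "case_id", "fda_dt", "age_years", "gender",
            "reporter", "country")},
            drugs=list(r.get("drugs", [])),
            reactions=list(r.get("reactions", [])),
            serious_outcomes=list(r.get("serious_outcomes", []))))
    return out


def match_drug(report: SafetyReport, terms, roles=None) -> bool:
    """True iff any drug name or active ingredient contains any term
    (case-insensitive substring), optionally restricted to role codes."""
    if not terms:
        raise ValueError("terms must be non-empty")
    lterms = [t.lower() for t in terms]
    for name, ai, role in report.drugs:
        if roles is not None and role not in roles:
            continue
        hay = f"{name} {ai}".lower()
        if any(t in hay for t in lterms):
            return True
    return False


def match_event(report: SafetyReport, event_pts) -> list[str]:
    """Matched PT occurrences (exact, case-insensitive), one per occurrence.

    A report may contribute more than one matched PT, so event-level counts
    can exceed patient-level counts.
    """
    wanted = {p.lower() for p in event_pts}
    return [r for r in report.reactions if r.lower() in wanted]


# --------------------------------------------------------------------------
# stratification and contingency construction

def age_stratum(age) -> str:
    if age is None:
        return "missing"
    if age < 18:
        return "<18"
    if age < 65:
        return "18-64"
    return ">=65"


def stratify(reports, by: str) -> dict[str, list[SafetyReport]]:
    """Partition reports by gender or age group.

    Age strata are the adult bands 18-64 and >=65; missing values form
    their own stratum, and under-18 reports get a separate '<18' stratum so
    they never contaminate the adult bands.
    """
    out: dict[str, list[SafetyReport]] = {}
    for r in reports:
        if by == "gender":
            key = r.gender
        elif by == "age":
            key = age_stratum(r.age_years)
        else:
            raise ValueError("stratify by must be 'gender' or 'age'")
        out.setdefault(key, []).append(r)
    return out


def _apply_strata(reports, cohort: CohortDefinition):
    sel = reports
    if cohort.gender is not None:
        sel = [r for r in sel if r.gender == cohort.gender]
    if cohort.age_stratum is not None:
        sel = [r for r in sel if age_stratum(r.age_years) == cohort.age_stratum]
    return sel


def build_contingency(reports, cohort: CohortDefinition,
                      label: str = "") -> ContingencyTable:
    """Assemble the 2x2 table for the cohort.

    Under the lipid-lowering background the universe is first restricted to
    reports matching the lipid-lowering term list.  At the default
    event-level counting unit each reaction occurrence counts once (a
    report with two matched PTs contributes 2 to the a cell); report-level
    counts each report once, in the a cell when it has >= 1 matched PT.
    """
    universe = _apply_strata(reports, cohort)
    if cohort.background == "lipid_lowering":
        universe = [r for r in universe
                    if match_drug(r, cohort.lipid_lowering_terms,
                                  roles=cohort.roles)]
    if not universe:
        raise ValueError("empty background universe")
    if not any(r.reactions for r in universe):
        raise ValueError("no reactions in the background universe")
    a = b = c = d = 0
    for r in universe:
        is_target = match_drug(r, cohort.drug_terms, roles=cohort.roles)
        matched = match_event(r, cohort.event_pts)
        if cohort.counting == "event":
            n_hit = len(matched)
            n_miss = len(r.reactions) - n_hit
        else:
            n_hit = 1 if matched else 0
            n_miss = 1 - n_hit
        if is_target:
            a += n_hit
            b += n_miss
        else:
            c += n_hit
            d += n_miss
    assert min(a, b, c, d) >= 0
    return ContingencyTable(a=a, b=b, c=c, d=d,
                            label=label or f"{cohort.background}/{cohort.counting}")


def pair_counts(reports) -> "pd.DataFrame":
    """Drug-event co-report counts over the whole matrix.

    One count per (drug name, reaction occurrence) pair per report — the
    matrix the MGPS prior is fitted to.
    """
    counts: dict[tuple[str, str], int] = {}
    for r in reports:
        names = {name for name, _ai, _role in r.drugs}
        for name in names:
            for pt in r.reactions:
                key = (name, pt)
                counts[key] = counts.get(key, 0) + 1
    return pd.DataFrame(
        [(d, e, c) for (d, e), c in sorted(counts.items())],
        columns=["drug", "event", "count"])


def reports_from_synthetic(sim_output) -> list[SafetyReport]:
    """Deduplicated SafetyReports straight from in-memory generator output."""
    demo, drug, reac, outc = (sim_output.demo, sim_output.drug,
                              sim_output.reac, sim_output.outc)
    drugs_by_pid: dict[int, list] = {}
    for row in drug.itertuples(index=False):
        drugs_by_pid.setdefault(int(row.PRIMARYID), []).append(
            (str(row.DRUGNAME), str(row.PROD_AI), str(row.ROLE_COD)))
    reac_by_pid: dict[int, list] = {}
    for row in reac.itertuples(index=False):
        reac_by_pid.setdefault(int(row.PRIMARYID), []).append(str(row.PT))
    outc_by_pid: dict[int, list] = {}
    for row in outc.itertuples(index=False):
        outc_by_pid.setdefault(int(row.PRIMARYID), []).append(
            _SERIOUS_CODES.get(str(row.OUTC_COD), "other"))
    raw = []
    for row in demo.itertuples(index=False):
        pid = int(row.PRIMARYID)
        age = row.AGE
        sex = str(row.SEX or "").strip().upper()
        raw.append({
            "primary_id": pid,
            "case_id": int(row.CASEID),
            "fda_dt": int(row.FDA_DT),
            "age_years": None if age in ("", None) or pd.isna(age)
            else float(age),
            "gender": {"M": "male", "F": "female"}.get(sex, "missing"),
            "reporter": _OCCP_CODES.get(str(row.OCCP_COD), "other"),
            "country": str(row.REPORTER_COUNTRY),
            "drugs": drugs_by_pid.get(pid, []),
            "reactions": reac_by_pid.get(pid, []),
            "serious_outcomes": outc_by_pid.get(pid, []),
        })
    return deduplicate(raw)
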