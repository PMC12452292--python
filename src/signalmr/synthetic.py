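"""Synthetic spontaneous-report tables and two-sample GWAS summary statistics.

Two generators with known ground truth so every downstream stage is
testable at desk scale without any external download:

* :func:`simulate_faers` writes quarterly DEMO/DRUG/REAC (plus OUTC)
  tables in the '$'-delimited FAERS ASCII dialect, with configurable
  drug-event association lifts, duplicate CASEIDs and missing
  demographics, together with a plain-text truth ledger carrying the
  exact expected 2x2 cell counts implied by the generator.
* :func:`simulate_gwas_pair` produces exposure and outcome summary
  statistics for a cis region with block-diagonal LD, a configurable
  causal effect and pleiotropy model, and deliberately messy allele
  encodings (swaps, strand flips, palindromic variants) to exercise
  harmonization.

Reports are single-case multinomial draws over the joint (drug family,
event) cell, with the lift applied relative to independence; extra drugs
are drawn within the primary drug's class and extra reactions from
non-target terms, so the 2x2 membership of a report is decided entirely
by its primary draw and the expected cells are available in closed form.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .disproportionality import ContingencyTable

__all__ = [
    "FaersSimConfig",
    "GwasSimConfig",
    "FaersSimOutput",
    "GwasSimOutput",
    "simulate_faers",
    "simulate_gwas_pair",
    "simulate_contingency_tables",
    "expected_cells",
    "TARGET_DRUG_TERMS",
    "MEMORY_LOSS_PTS",
    "DEFAULT_DRUG_VOCAB",
    "DEFAULT_EVENT_VOCAB",
]

# The seven target-drug search terms (brand and generic names of the three
# PCSK9-directed agents plus the target itself).
TARGET_DRUG_TERMS = (
    "inclisiran", "alirocumab", "evolocumab", "pcsk9",
    "praluent", "leqvio", "repatha",
)

# The nine memory-loss preferred terms.
MEMORY_LOSS_PTS = (
    "Memory impairment",
    "Amnesia",
    "Amnestic disorder",
    "Anterograde amnesia",
    "Korsakoff's syndrome",
    "Post-traumatic memory disorder",
    "Retrograde amnesia",
    "Transient global amnesia",
    "Wernicke-Korsakoff syndrome",
)

# drug name -> active ingredient; the order fixes the probability vector.
DEFAULT_DRUG_VOCAB: dict[str, str] = {
    # target family (PCSK9-directed lipid-lowering agents)
    "REPATHA": "EVOLOCUMAB",
    "PRALUENT": "ALIROCUMAB",
    "LEQVIO": "INCLISIRAN",
    "EVOLOCUMAB": "EVOLOCUMAB",
    "ALIROCUMAB": "ALIROCUMAB",
    "INCLISIRAN": "INCLISIRAN",
    "PCSK9 INHIBITOR NOS": "PCSK9 INHIBITOR NOS",
    # other lipid-lowering drugs (ATC C10 class)
    "ATORVASTATIN": "ATORVASTATIN",
    "SIMVASTATIN": "SIMVASTATIN",
    "ROSUVASTATIN": "ROSUVASTATIN",
    "PRAVASTATIN": "PRAVASTATIN",
    "EZETIMIBE": "EZETIMIBE",
    "FENOFIBRATE": "FENOFIBRATE",
    "GEMFIBROZIL": "GEMFIBROZIL",
    "BEMPEDOIC ACID": "BEMPEDOIC ACID",
    # everything else
    "ASPIRIN": "ACETYLSALICYLIC ACID",
    "METFORMIN": "METFORMIN",
    "LISINOPRIL": "LISINOPRIL",
    "OMEPRAZOLE": "OMEPRAZOLE",
    "IBUPROFEN": "IBUPROFEN",
    "AMOXICILLIN": "AMOXICILLIN",
    "LEVOTHYROXINE": "LEVOTHYROXINE",
    "SERTRALINE": "SERTRALINE",
    "ADALIMUMAB": "ADALIMUMAB",
    "PARACETAMOL": "PARACETAMOL",
}

LIPID_LOWERING_NAMES = (
    "ATORVASTATIN", "SIMVASTATIN", "ROSUVASTATIN", "PRAVASTATIN",
    "EZETIMIBE", "FENOFIBRATE", "GEMFIBROZIL", "BEMPEDOIC ACID",
)

DEFAULT_EVENT_VOCAB: tuple[str, ...] = MEMORY_LOSS_PTS + (
    "Nausea", "Headache", "Dizziness", "Fatigue", "Rash", "Diarrhoea",
    "Arthralgia", "Myalgia", "Insomnia", "Pruritus", "Dyspnoea",
    "Injection site pain",
)


def _default_drug_probs(vocab):
    """Targets ~3% of reports, other lipid agents ~17%, the rest elsewhere."""
    names = list(vocab)
    target = [n for n in names if _is_target(n, vocab)]
    lipid = [n for n in names if n in LIPID_LOWERING_NAMES and n not in target]
    other = [n for n in names if n not in target and n not in lipid]
    p = np.empty(len(names))
    for group, mass in ((target, 0.03), (lipid, 0.17), (other, 0.80)):
        for n in group:
            p[names.index(n)] = mass / len(group)
    return p


def _default_event_probs(vocab):
    """Memory-loss terms ~2% of primary reactions in total."""
    vocab = list(vocab)
    mem = [e for e in vocab if e in MEMORY_LOSS_PTS]
    oth = [e for e in vocab if e not in MEMORY_LOSS_PTS]
    p = np.empty(len(vocab))
    mem_each = 0.02 / len(mem) if mem else 0.0
    oth_each = (1.0 - 0.02 * bool(mem)) / len(oth)
    for e in vocab:
        p[vocab.index(e)] = mem_each if e in mem else oth_each
    return p


def _is_target(name, vocab):
    hay = (name + " " + vocab.get(name, "")).lower()
    return any(t in hay for t in TARGET_DRUG_TERMS)


@dataclass
class FaersSimConfig:
    """Study conditions for the spontaneous-report generator."""

    n_reports: int = 10_000
    drug_vocabulary: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_DRUG_VOCAB))
    event_vocabulary: tuple[str, ...] = DEFAULT_EVENT_VOCAB
    baseline_drug_probs: np.ndarray | None = None
    baseline_event_probs: np.ndarray | None = None
    # (drug name, event PT) -> reporting rate ratio relative to independence
    association_lift: dict[tuple[str, str], float] = field(default_factory=dict)
    duplicate_fraction: float = 0.05
    missing_age_fraction: float = 0.30
    missing_gender_fraction: float = 0.05
    serious_fraction: float = 0.30
    extra_drug_probs: tuple[float, ...] = (0.6, 0.3, 0.1)       # 0,1,2 extras
    extra_event_probs: tuple[float, ...] = (0.55, 0.25, 0.15, 0.05)  # 0..3
    quarters: tuple[str, ...] = ("2022Q1", "2022Q2", "2022Q3", "2022Q4")
    seed: int = 0

    def __post_init__(self):
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        if len(self.drug_vocabulary) < 2 or len(self.event_vocabulary) < 2:
            raise ValueError(
                "degenerate vocabulary: need >= 2 drugs and >= 2 events "
                "to form a 2x2 background")
        if not 0.0 <= self.duplicate_fraction < 1.0:
            raise ValueError("duplicate_fraction must lie in [0, 1)")
        for nm in ("missing_age_fraction", "missing_gender_fraction",
                   "serious_fraction"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm} must lie in [0, 1]")
        if self.baseline_drug_probs is None:
            self.baseline_drug_probs = _default_drug_probs(self.drug_vocabulary)
        self.baseline_drug_probs = np.asarray(self.baseline_drug_probs, float)
        if self.baseline_event_probs is None:
            self.baseline_event_probs = _default_event_probs(self.event_vocabulary)
        self.baseline_event_probs = np.asarray(self.baseline_event_probs, float)
        for nm, p, k in (
            ("baseline_drug_probs", self.baseline_drug_probs,
             len(self.drug_vocabulary)),
            ("baseline_event_probs", self.baseline_event_probs,
             len(self.event_vocabulary)),
        ):
            if len(p) != k:
                raise ValueError(f"{nm} length must match its vocabulary")
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{nm} must be a simplex vector (sum 1 within 1e-9)")
        if any(l < 0 for l in self.association_lift.values()):
            raise ValueError("association lifts must be >= 0")

    # -- derived structure ---------------------------------------------------

    @property
    def drug_names(self) -> list[str]:
        return list(self.drug_vocabulary)

    def drug_category(self, name: str) -> str:
        if _is_target(name, self.drug_vocabulary):
            return "target"
        if name in LIPID_LOWERING_NAMES:
            return "lipid"
        return "other"

    def joint_probs(self) -> np.ndarray:
        """Normalised joint (drug, event) cell probabilities with lifts applied."""
        q = np.outer(self.baseline_drug_probs, self.baseline_event_probs)
        names, events = self.drug_names, list(self.event_vocabulary)
        for (d, e), lift in self.association_lift.items():
            q[names.index(d), events.index(e)] *= lift
        return q / q.sum()

    @property
    def mean_extra_events(self) -> float:
        return float(np.dot(np.arange(len(self.extra_event_probs)),
                            self.extra_event_probs))


def expected_cells(config: FaersSimConfig, background: str = "full",
                   unit: str = "report", target_drugs=None,
                   target_events=None) -> dict:
    """Closed-form expected 2x2 cells implied by the generator.

    By default the target rows are the whole target-drug family and the
    target columns the memory-loss terms; pass ``target_drugs`` /
    ``target_events`` (vocabulary names) for any other pair, e.g. the
    single cell that carries a configured lift.  Under
    ``background='lipid_lowering'`` the universe is restricted to reports
    whose primary drug is any lipid-lowering agent (the target family is a
    subset of that class).  At ``unit='event'`` each reaction occurrence
    counts once; extra reactions are always non-memory terms, so they land
    in the b and d cells.
    """
    q = config.joint_probs()
    names, events = config.drug_names, list(config.event_vocabulary)
    if target_drugs is None:
        is_t = np.array([config.drug_category(n) == "target" for n in names])
    else:
        is_t = np.array([n in set(target_drugs) for n in names])
    is_l = np.array([config.drug_category(n) in ("target", "lipid") for n in names])
    if target_events is None:
        is_m = np.array([e in MEMORY_LOSS_PTS for e in events])
    else:
        is_m = np.array([e in set(target_events) for e in events])
    if background == "full":
        drug_universe = np.ones(len(names), bool)
    elif background == "lipid_lowering":
        drug_universe = is_l
    else:
        raise ValueError("background must be 'full' or 'lipid_lowering'")
    qa = q[np.ix_(is_t, is_m)].sum()
    qb = q[np.ix_(is_t, ~is_m)].sum()
    qc = q[np.ix_(drug_universe & ~is_t, is_m)].sum()
    qd = q[np.ix_(drug_universe & ~is_t, ~is_m)].sum()
    n = config.n_reports
    if unit == "report":
        cells = dict(a=n * qa, b=n * qb, c=n * qc, d=n * qd)
    elif unit == "event":
        if target_events is not None and not set(target_events) <= set(MEMORY_LOSS_PTS):
            raise ValueError("event-level closed form requires target events "
                             "within the memory-loss terms (extras are drawn "
                             "from the other terms)")
        m = config.mean_extra_events
        cells = dict(a=n * qa, b=n * (qb * (1 + m) + qa * m),
                     c=n * qc, d=n * (qd * (1 + m) + qc * m))
    else:
        raise ValueError("unit must be 'report' or 'event'")
    cells["ror"] = (qa * qd) / (qb * qc) if qb * qc > 0 else np.inf
    cells["probs"] = (qa, qb, qc, qd)
    return cells


def simulate_contingency_tables(config: FaersSimConfig, n_tables: int,
                                seed: int, background: str = "full",
                                target_drugs=None, target_events=None):
    """Draw report-level 2x2 tables directly from the generator's joint law.

    Equivalent in distribution to running the full file pipeline on
    independent replicates; used for repeated-table calibration checks.
    """
    probs = np.array(expected_cells(config, background,
                                    target_drugs=target_drugs,
                                    target_events=target_events)["probs"])
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(config.n_reports, probs, size=n_tables)
    return [ContingencyTable(*map(int, row), label=f"sim{j}")
            for j, row in enumerate(draws)]


# --------------------------------------------------------------------------
# report-table generation

_QUARTER_MONTH = {"Q1": 1, "Q2": 4, "Q3": 7, "Q4": 10}


def quarter_range(label: str) -> tuple[_dt.date, _dt.date]:
    year, q = int(label[:4]), label[4:].upper()
    m = _QUARTER_MONTH[q]
    start = _dt.date(year, m, 1)
    end = (_dt.date(year + 1, 1, 1) if m == 10 else _dt.date(year, m + 3, 1))
    return start, end - _dt.timedelta(days=1)


def _date_to_int(d: _dt.date) -> int:
    return d.year * 10000 + d.month * 100 + d.day


@dataclass
class FaersSimOutput:
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ledger: dict
    paths: dict = field(default_factory=dict)


def simulate_faers(config: FaersSimConfig, outdir=None) -> FaersSimOutput:
    """Generate quarterly report tables with a truth ledger.

    When ``outdir`` is given, writes '$'-delimited DEMO/DRUG/REAC/OUTC
    files per quarter plus ``ledger.txt``; output is bit-for-bit fixed by
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    names = config.drug_names
    events = list(config.event_vocabulary)
    D, E = len(names), len(events)

    q = config.joint_probs()
    cell = rng.choice(D * E, size=n, p=q.ravel())
    drug_idx, event_idx = cell // E, cell % E

    categories = np.array([config.drug_category(nm) for nm in names])
    cat_of_report = categories[drug_idx]

    # extra drugs: within the primary drug's class, baseline-weighted
    n_extra_drugs = rng.choice(len(config.extra_drug_probs), size=n,
                               p=config.extra_drug_probs)
    extra_drug_lists: list[list[int]] = [[] for _ in range(n)]
    for cat in ("target", "lipid", "other"):
        members = np.flatnonzero(categories == cat)
        if len(members) == 0:
            continue
        pcat = config.baseline_drug_probs[members]
        pcat = pcat / pcat.sum()
        rows = np.flatnonzero(cat_of_report == cat)
        need = int(n_extra_drugs[rows].sum())
        if need == 0:
            continue
        pool = rng.choice(members, size=need, p=pcat)
        k = 0
        for r in rows:
            c = n_extra_drugs[r]
            extra_drug_lists[r] = list(pool[k:k + c])
            k += c

    # extra reactions: never target (memory) terms, so 2x2 membership is
    # fixed by the primary draw
    non_mem = np.array([i for i, e in enumerate(events)
                        if e not in MEMORY_LOSS_PTS])
    p_nm = config.baseline_event_probs[non_mem]
    p_nm = p_nm / p_nm.sum()
    n_extra_events = rng.choice(len(config.extra_event_probs), size=n,
                                p=config.extra_event_probs)
    total_extra_ev = int(n_extra_events.sum())
    extra_ev_pool = rng.choice(non_mem, size=total_extra_ev, p=p_nm)

    # demographics
    age = np.clip(np.round(rng.normal(66, 12, size=n)), 18, 95).astype(int)
    age_missing = rng.random(n) < config.missing_age_fraction
    sex = np.where(rng.random(n) < 0.55, "F", "M")
    sex_missing = rng.random(n) < config.missing_gender_fraction
    occp = rng.choice(["CN", "MD", "PH", "HP", "OT"], size=n,
                      p=[0.70, 0.08, 0.04, 0.12, 0.06])
    country = rng.choice(["US", "CA", "GB", "DE", "FR", "JP"], size=n,
                         p=[0.88, 0.03, 0.03, 0.02, 0.02, 0.02])
    serious = rng.random(n) < config.serious_fraction
    outc_code = rng.choice(["HO", "OT", "DS", "LT", "DE"], size=n,
                           p=[0.30, 0.55, 0.07, 0.03, 0.05])

    # dates: uniform within a uniformly chosen quarter
    q_idx = rng.integers(0, len(config.quarters), size=n)
    ranges = [quarter_range(lbl) for lbl in config.quarters]
    spans = np.array([(b - a).days + 1 for a, b in ranges])
    day_off = rng.integers(0, spans[q_idx])
    dates = [ranges[qi][0] + _dt.timedelta(days=int(off))
             for qi, off in zip(q_idx, day_off)]
    last_day = max(b for _, b in ranges)

    caseid = 10_000_000 + np.arange(1, n + 1)
    primaryid = caseid * 10 + 1

    # duplicates: clone a case with a later receipt date and higher PRIMARYID;
    # the clone may mutate one demographic field
    n_dup = int(round(config.duplicate_fraction * n))
    dup_rows = rng.choice(n, size=n_dup, replace=False) if n_dup else np.array([], int)
    dup_shift = rng.integers(1, 91, size=n_dup)
    dup_mutate = rng.random(n_dup)

    demo_rows, drug_rows, reac_rows, outc_rows = [], [], [], []

    def emit(row_i, pid, date, age_i, sex_i):
        qlbl = None
        for lbl, (a0, b0) in zip(config.quarters, ranges):
            if a0 <= date <= b0:
                qlbl = lbl
                break
        demo_rows.append((
            qlbl, pid, int(caseid[row_i]), _date_to_int(date),
            "" if age_missing[row_i] else int(age_i),
            "" if age_missing[row_i] else "YR",
            "" if sex_missing[row_i] else sex_i,
            occp[row_i], country[row_i],
        ))
        drugs = [int(drug_idx[row_i])] + extra_drug_lists[row_i]
        for seq, di in enumerate(drugs, start=1):
            nm = names[di]
            drug_rows.append((qlbl, pid, seq, "PS" if seq == 1 else "SS",
                              nm, config.drug_vocabulary.get(nm, nm)))
        reac_rows.append((qlbl, pid, events[int(event_idx[row_i])]))
        for e in report_extra_events[row_i]:
            reac_rows.append((qlbl, pid, events[int(e)]))
        if serious[row_i]:
            outc_rows.append((qlbl, pid, outc_code[row_i]))

    # distribute the extra-event pool per report
    report_extra_events: list[np.ndarray] = []
    k = 0
    for c in n_extra_events:
        report_extra_events.append(extra_ev_pool[k:k + c])
        k += c

    for i in range(n):
        emit(i, int(primaryid[i]), dates[i], int(age[i]), sex[i])
    for j, i in enumerate(dup_rows):
        d2 = min(dates[i] + _dt.timedelta(days=int(dup_shift[j])), last_day)
        age_i, sex_i = int(age[i]), sex[i]
        if dup_mutate[j] < 0.4:
            age_i = int(np.clip(age_i + (1 + j % 5), 18, 99))
        elif dup_mutate[j] < 0.6:
            sex_i = "M" if sex_i == "F" else "F"
        emit(i, int(primaryid[i]) + 1, d2, age_i, sex_i)

    demo = pd.DataFrame(demo_rows, columns=[
        "quarter", "PRIMARYID", "CASEID", "FDA_DT", "AGE", "AGE_COD", "SEX",
        "OCCP_COD", "REPORTER_COUNTRY"])
    drug = pd.DataFrame(drug_rows, columns=[
        "quarter", "PRIMARYID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME", "PROD_AI"])
    reac = pd.DataFrame(reac_rows, columns=["quarter", "PRIMARYID", "PT"])
    outc = pd.DataFrame(outc_rows, columns=["quarter", "PRIMARYID", "OUTC_COD"])
    for df in (demo, drug, reac, outc):
        df.sort_values([c for c in ("quarter", "PRIMARYID", "DRUG_SEQ")
                        if c in df.columns], inplace=True, kind="mergesort")
        df.reset_index(drop=True, inplace=True)

    ledger = {
        "n_reports": n,
        "unique_cases": n,
        "n_raw_rows": n + n_dup,
        "n_duplicates": n_dup,
        "mean_extra_events": config.mean_extra_events,
        "seed": config.seed,
    }
    for bg in ("full", "lipid_lowering"):
        for unit in ("report", "event"):
            cells = expected_cells(config, bg, unit)
            for key in ("a", "b", "c", "d"):
                ledger[f"expected_{key}_{bg}_{unit}"] = cells[key]
        ledger[f"true_ror_{bg}"] = expected_cells(config, bg)["ror"]
    for (d, e), lift in sorted(config.association_lift.items()):
        ledger[f"lift[{d}|{e}]"] = lift

    paths = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for lbl in config.quarters:
            for stem, df in (("DEMO", demo), ("DRUG", drug),
                             ("REAC", reac), ("OUTC", outc)):
                sub = df[df["quarter"] == lbl].drop(columns="quarter")
                p = outdir / f"{stem}{lbl}.txt"
                sub.to_csv(p, sep="$", index=False, lineterminator="\n")
                paths.setdefault(lbl, {})[stem] = p
        lp = outdir / "ledger.txt"
        with open(lp, "w") as fh:
            for k, v in ledger.items():
                fh.write(f"{k}={v}\n")
        paths["ledger"] = lp
    return FaersSimOutput(demo.drop(columns="quarter"),
                          drug.drop(columns="quarter"),
                          reac.drop(columns="quarter"),
                          outc.drop(columns="quarter"), ledger, paths)


# --------------------------------------------------------------------------
# GWAS summary-statistic generation

@dataclass
class GwasSimConfig:
    """Study conditions for the cis-region two-sample GWAS generator.

    Defaults mirror a PCSK9-type locus: ~100 variants in a region on
    chromosome 1, genome-wide-significant exposure associations, standard
    errors coupled to allele frequency and sample size by the per-allele
    approximation se = scale / sqrt(2 * MAF * (1-MAF) * n).
    """

    n_snps: int = 100
    chrom: str = "1"
    region_start: int = 55_505_221
    region_end: int = 55_530_525
    ld_block_size: int = 5
    within_block_r: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    exposure_effect_scale: float = 0.05
    n_exposure: int = 500_000
    n_outcome: int = 50_000
    causal_theta: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    palindromic_fraction: float = 0.10
    strand_flip_fraction: float = 0.20
    swap_fraction: float = 0.20
    neg_beta_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")
        if self.region_start >= self.region_end:
            raise ValueError("region_start must be below region_end")
        if not 0.0 <= self.within_block_r < 1.0:
            raise ValueError("within_block_r must lie in [0, 1)")
        if self.n_exposure <= 0 or self.n_outcome <= 0:
            raise ValueError("GWAS sample sizes must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")


@dataclass
class GwasSimOutput:
    exposure: pd.DataFrame
    outcome: pd.DataFrame
    ld: pd.DataFrame
    truth: dict
    paths: dict = field(default_factory=dict)


_NONPAL_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PAL_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


def simulate_gwas_pair(config: GwasSimConfig, outdir=None) -> GwasSimOutput:
    """Exposure/outcome summary statistics, LD matrix and truth ledger.

    Outcome effects follow beta_Y = causal_theta * beta_X(true) + alpha +
    noise, with alpha drawn from N(pleiotropy_mean, pleiotropy_sd^2).  The
    outcome table re-encodes a configurable fraction of SNPs with swapped
    and/or strand-complemented alleles (frequency-consistent) to exercise
    harmonization.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_snps
    pos = np.sort(rng.choice(
        np.arange(config.region_start, config.region_end + 1), size=m,
        replace=False))
    snps = [f"rs{100000 + i}" for i in range(m)]
    maf = rng.uniform(*config.maf_range, size=m)

    sign = np.where(rng.random(m) < config.neg_beta_fraction, -1.0, 1.0)
    beta_true = sign * config.exposure_effect_scale * (0.5 + rng.random(m))
    se_x = config.exposure_effect_scale / np.sqrt(
        2 * maf * (1 - maf) * config.n_exposure)
    beta_x = beta_true + rng.normal(0, se_x)
    p_x = np.clip(2 * stats.norm.sf(np.abs(beta_x / se_x)), 1e-300, 1.0)

    alpha = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=m)
    se_y = config.exposure_effect_scale / np.sqrt(
        2 * maf * (1 - maf) * config.n_outcome)
    beta_y = config.causal_theta * beta_true + alpha + rng.normal(0, se_y)
    p_y = np.clip(2 * stats.norm.sf(np.abs(beta_y / se_y)), 1e-300, 1.0)

    is_pal = rng.random(m) < config.palindromic_fraction
    pair_idx = rng.integers(0, len(_NONPAL_PAIRS), size=m)
    pal_idx = rng.integers(0, len(_PAL_PAIRS), size=m)
    ea = np.where(is_pal, [ _PAL_PAIRS[i][0] for i in pal_idx],
                  [_NONPAL_PAIRS[i][0] for i in pair_idx])
    oa = np.where(is_pal, [ _PAL_PAIRS[i][1] for i in pal_idx],
                  [_NONPAL_PAIRS[i][1] for i in pair_idx])

    exposure = pd.DataFrame({
        "SNP": snps, "CHR": config.chrom, "POS": pos, "EA": ea, "OA": oa,
        "EAF": maf, "BETA": beta_x, "SE": se_x, "P": p_x,
    })

    # outcome allele encoding: swap and/or strand-complement some SNPs
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    o_ea, o_oa = ea.copy(), oa.copy()
    o_beta, o_eaf = beta_y.copy(), maf.copy()
    swap = rng.random(m) < config.swap_fraction
    flip = (rng.random(m) < config.strand_flip_fraction) & ~is_pal
    for i in range(m):
        if swap[i]:
            o_ea[i], o_oa[i] = o_oa[i], o_ea[i]
            o_beta[i] = -o_beta[i]
            o_eaf[i] = 1 - o_eaf[i]
        if flip[i]:
            o_ea[i], o_oa[i] = comp[o_ea[i]], comp[o_oa[i]]
    outcome = pd.DataFrame({
        "SNP": snps, "CHR": config.chrom, "POS": pos, "EA": o_ea, "OA": o_oa,
        "EAF": o_eaf, "BETA": o_beta, "SE": se_y, "P": p_y,
    })

    # block-diagonal constant-correlation LD
    r = config.within_block_r
    ldm = np.eye(m)
    for start in range(0, m, config.ld_block_size):
        stop = min(start + config.ld_block_size, m)
        ldm[start:stop, start:stop] = r
    np.fill_diagonal(ldm, 1.0)
    ld = pd.DataFrame(ldm, index=snps, columns=snps)

    truth = {
        "causal_theta": config.causal_theta,
        "pleiotropy_mean": config.pleiotropy_mean,
        "pleiotropy_sd": config.pleiotropy_sd,
        "n_snps": m,
        "n_exposure": config.n_exposure,
        "n_outcome": config.n_outcome,
        "seed": config.seed,
        "beta_true": beta_true,
        "swapped": swap,
        "strand_flipped": flip,
        "palindromic": is_pal,
    }

    paths = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths["exposure"] = outdir / "exposure.tsv"
        paths["outcome"] = outdir / "outcome.tsv"
        paths["ld"] = outdir / "ld.txt"
        paths["truth"] = outdir / "gwas_truth.txt"
        exposure.to_csv(paths["exposure"], sep="\t", index=False,
                        lineterminator="\n")
        outcome.to_csv(paths["outcome"], sep="\t", index=False,
                       lineterminator="\n")
        ld.to_csv(paths["ld"], sep="\t", lineterminator="\n")
        with open(paths["truth"], "w") as fh:
            for k, v in truth.items():
                if isinstance(v, np.ndarray):
                    continue
                fh.write(f"{k}={v}\n")
    return GwasSimOutput(exposure, outcome, ld, truth, paths)
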