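"""Descriptive summaries, rendered result tables and end-to-end orchestration.

Percentages throughout use round-half-up to two decimals, the convention of
published pharmacovigilance characteristic tables.  ``run_all`` drives the
whole pipeline — simulate, ETL, disproportionality under both backgrounds
with strata and per-drug splits, then MR with the positive control first —
and writes a JSON manifest with every seed, counter and output checksum so
a fixed-seed run is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np

from . import faers
from .disproportionality import DisproportionalityModel, fit_mgps_prior
from .faers import CohortDefinition, build_contingency, match_event
from .mr import MRModel, harmonize, positive_control, select_instruments
from .synthetic import (FaersSimConfig, GwasSimConfig, MEMORY_LOSS_PTS,
                        simulate_faers, simulate_gwas_pair)

__all__ = [
    "round_half_up",
    "fmt2",
    "summarize_counts",
    "descriptive_summary",
    "render_signal_table",
    "RunConfig",
    "run_all",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def fmt2(x: float) -> str:
    """Two-decimal half-up string, e.g. 0.785 -> '0.79'."""
    return f"{round_half_up(x, 2):.2f}"


def summarize_counts(counts: dict, denominator: float | None = None):
    """(name, count, percent) rows with half-up two-decimal percentages.

    The denominator defaults to the sum of the counts; an explicit value
    supports categories reported against a different base (e.g. events per
    patient).  A zero denominator yields explicit 0.0 percentages.
    """
    denom = sum(counts.values()) if denominator is None else denominator
    rows = []
    for name, cnt in counts.items():
        pct = round_half_up(100.0 * cnt / denom, 2) if denom else 0.0
        rows.append((name, cnt, pct))
    return rows


def descriptive_summary(reports, event_pts=MEMORY_LOSS_PTS,
                        drug_groups=None) -> dict:
    """Characteristics table for a matched cohort.

    Sections: matched event PTs (denominator = total matched occurrences),
    drug groups, gender, age band, reporter, country, report year, and
    serious outcomes (denominator = serious-outcome mentions).  An empty
    cohort returns all-zero sections with explicit zero denominators.
    """
    pt_counts: dict[str, int] = {}
    for r in reports:
        for pt in match_event(r, event_pts):
            key = pt.capitalize()
            pt_counts[key] = pt_counts.get(key, 0) + 1
    n_events = sum(pt_counts.values())
    n_patients = len(reports)

    gender = {"male": 0, "female": 0, "missing": 0}
    ages = {"18-64": 0, ">=65": 0, "missing": 0, "<18": 0}
    reporter: dict[str, int] = {}
    country: dict[str, int] = {}
    years: dict[str, int] = {}
    serious: dict[str, int] = {}
    drugs: dict[str, int] = {}
    drug_groups = drug_groups or {}
    for r in reports:
        gender[r.gender] = gender.get(r.gender, 0) + 1
        ages[faers.age_stratum(r.age_years)] += 1
        reporter[r.reporter] = reporter.get(r.reporter, 0) + 1
        country[r.country] = country.get(r.country, 0) + 1
        yr = str(r.fda_dt)[:4]
        years[yr] = years.get(yr, 0) + 1
        for s in r.serious_outcomes:
            serious[s] = serious.get(s, 0) + 1
        for grp, terms in drug_groups.items():
            if faers.match_drug(r, terms):
                drugs[grp] = drugs.get(grp, 0) + 1
    if not ages["<18"]:
        del ages["<18"]
    return {
        "n_patients": n_patients,
        "n_events": n_events,
        "events": summarize_counts(pt_counts, denominator=n_events),
        "drugs": summarize_counts(drugs, denominator=n_patients),
        "gender": summarize_counts(gender, denominator=n_patients),
        "age": summarize_counts(ages, denominator=n_patients),
        "reporter": summarize_counts(reporter, denominator=n_patients),
        "country": summarize_counts(country, denominator=n_patients),
        "year": summarize_counts(years, denominator=n_patients),
        "serious_outcomes": summarize_counts(serious),
    }


def render_signal_table(results, min_cases: int = 3) -> str:
    """Signal-table rows: AEs, N, ROR (95% CI), PRR, chi2, EBGM05, IC025.

    Rows with fewer than ``min_cases`` a-cell reports are excluded (the
    minimum-case criterion); callers record exclusions in the manifest.
    """
    lines = ["AEs\tN\tROR (95% CI)\tPRR\tchi2\tEBGM05\tIC025\tsignal"]
    for r in results:
        if r.table.a < min_cases:
            continue
        lines.append(
            f"{r.table.label}\t{r.table.a}\t"
            f"{fmt2(r.ror)} ({fmt2(r.ror_low)}, {fmt2(r.ror_high)})\t"
            f"{fmt2(r.prr)}\t{fmt2(r.chi2)}\t{fmt2(r.ebgm05)}\t{fmt2(r.ic025)}\t"
            f"{'yes' if r.flags['overall'] else 'no'}"
        )
    return "\n".join(lines) + "\n"


def parse_signal_table(text: str):
    """Inverse of :func:`render_signal_table` at the printed precision."""
    rows = []
    lines = [ln for ln in text.strip().splitlines()[1:] if ln]
    for ln in lines:
        label, n, ror_ci, prr, chi2, ebgm05, ic025, sig = ln.split("\t")
        ror, rest = ror_ci.split(" (")
        lo, hi = rest.rstrip(")").split(", ")
        rows.append({
            "label": label, "N": int(n), "ror": float(ror),
            "ror_low": float(lo), "ror_high": float(hi), "prr": float(prr),
            "chi2": float(chi2), "ebgm05": float(ebgm05),
            "ic025": float(ic025), "signal": sig == "yes",
        })
    return rows


# --------------------------------------------------------------------------
# end-to-end run

@dataclass
class RunConfig:
    """Declarative configuration for a full pipeline run."""

    outdir: str = "signalmr_run"
    faers: FaersSimConfig = field(default_factory=FaersSimConfig)
    cohort: CohortDefinition = field(default_factory=CohortDefinition)
    gwas_control: GwasSimConfig = field(
        default_factory=lambda: GwasSimConfig(causal_theta=-0.65, seed=11))
    gwas_outcome: GwasSimConfig = field(
        default_factory=lambda: GwasSimConfig(causal_theta=0.0, seed=12))
    region: tuple[str, int, int] = ("1", 55_505_221, 55_530_525)
    p_threshold: float = 5e-8
    r2_max: float = 0.3
    window_kb: float = 100.0
    n_boot: int = 1000
    seed: int = 0
    per_drug: dict = field(default_factory=lambda: {
        "alirocumab": ("alirocumab", "praluent"),
        "evolocumab": ("evolocumab", "repatha"),
        "inclisiran": ("inclisiran", "leqvio"),
    })

    def to_json(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                d = dataclasses.asdict(o)
                d.pop("baseline_drug_probs", None)
                d.pop("baseline_event_probs", None)
                return d
            if hasattr(o, "tolist"):
                return o.tolist()
            if isinstance(o, tuple):
                return list(o)
            return str(o)
        d = dataclasses.asdict(self)
        for k in ("faers",):
            d[k].pop("baseline_drug_probs", None)
            d[k].pop("baseline_event_probs", None)
            d[k]["association_lift"] = {
                f"{dk}|{ek}": v for (dk, ek), v
                in self.faers.association_lift.items()}
        return json.dumps(d, indent=2, sort_keys=True, default=default)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Simulate -> ETL -> disproportionality -> MR; returns the manifest.

    The positive-control MR runs before the outcome MR; a direction failure
    raises :class:`signalmr.mr.PositiveControlError` after persisting the
    partial manifest.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    (out / "run_config.json").write_text(config.to_json())

    def persist():
        txt = json.dumps(manifest, indent=2, sort_keys=True, default=str)
        (out / "manifest.json").write_text(txt)

    try:
        stage = "simulate"
        sim = simulate_faers(config.faers, outdir=out / "faers")
        manifest["stages"]["simulate"] = {
            "n_reports": sim.ledger["n_reports"],
            "n_raw_rows": sim.ledger["n_raw_rows"],
        }

        stage = "etl"
        raw, counters = faers.read_quarterly_tables(out / "faers")
        reports = faers.deduplicate(raw)
        manifest["stages"]["etl"] = {
            "raw_records": len(raw), "deduplicated": len(reports),
            **counters,
        }
        matched = [r for r in reports
                   if faers.match_drug(r, config.cohort.drug_terms)
                   and match_event(r, config.cohort.event_pts)]
        summary = descriptive_summary(
            matched, event_pts=config.cohort.event_pts,
            drug_groups=config.per_drug)
        (out / "table1.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True))

        stage = "disproportionality"
        # MGPS prior fitted once, over the full drug-event pair matrix
        pairs = faers.pair_counts(reports)
        pivot = pairs.pivot_table(index="drug", columns="event",
                                  values="count", aggfunc="sum", fill_value=0)
        counts = pivot.values.ravel().astype(float)
        expected = np.outer(pivot.sum(axis=1), pivot.sum(axis=0)).ravel()
        expected = expected / pivot.values.sum()
        keep = expected > 0
        prior = fit_mgps_prior(counts[keep], expected[keep])
        sig_meta = {"mgps_pairs": int(keep.sum()),
                    "mgps_loglik": prior.loglik}
        for bg in ("full", "lipid_lowering"):
            runs = {"all": dataclasses.replace(config.cohort, background=bg)}
            for drug, terms in config.per_drug.items():
                runs[drug] = dataclasses.replace(
                    config.cohort, background=bg, drug_terms=terms)
            for sex in ("male", "female"):
                runs[f"gender_{sex}"] = dataclasses.replace(
                    config.cohort, background=bg, gender=sex)
            for band in ("18-64", ">=65"):
                runs[f"age_{band}"] = dataclasses.replace(
                    config.cohort, background=bg, age_stratum=band)
            tables = []
            for name, cohort in runs.items():
                try:
                    tables.append(build_contingency(
                        reports, cohort, label=name))
                except ValueError as exc:
                    sig_meta[f"{bg}/{name}"] = f"skipped: {exc}"
            res = DisproportionalityModel(
                tables, prior=prior, zero_cell="haldane").fit()
            text = render_signal_table(res.results, min_cases=3)
            excluded = [r.table.label for r in res.results if r.table.a < 3]
            sig_meta[bg] = {"n_tables": len(tables),
                            "below_min_cases": excluded,
                            "prior_source": res.prior_source}
            (out / f"signal_{bg}.tsv").write_text(text)
        manifest["stages"]["disproportionality"] = sig_meta

        stage = "mr_positive_control"
        ctrl = simulate_gwas_pair(config.gwas_control, outdir=out / "gwas_control")
        snps = select_instruments(
            ctrl.exposure, config.region, ctrl.ld,
            p_threshold=config.p_threshold, r2_max=config.r2_max,
            window_kb=config.window_kb)
        inst = harmonize(ctrl.exposure, ctrl.outcome, snps=snps)
        direction = ("protective" if config.gwas_control.causal_theta < 0
                     else "risk" if config.gwas_control.causal_theta > 0
                     else None)
        ctrl_res = positive_control(inst, direction, n_boot=config.n_boot,
                                    seed=config.seed)
        (out / "mr_positive_control.tsv").write_text(
            ctrl_res.to_frame().to_csv(sep="\t", index=False,
                                       float_format="%.6g"))
        manifest["stages"]["mr_positive_control"] = {
            "n_instruments": len(inst), "direction": direction,
            "ivw_or": round_half_up(ctrl_res["IVW"].or_hat, 4),
        }

        stage = "mr_outcome"
        outc = simulate_gwas_pair(config.gwas_outcome, outdir=out / "gwas_outcome")
        snps = select_instruments(
            outc.exposure, config.region, outc.ld,
            p_threshold=config.p_threshold, r2_max=config.r2_max,
            window_kb=config.window_kb)
        inst = harmonize(outc.exposure, outc.outcome, snps=snps)
        mr_res = MRModel(inst, n_boot=config.n_boot,
                         exposure="target inhibition",
                         outcome="outcome").fit(seed=config.seed + 1)
        (out / "mr_outcome.tsv").write_text(
            mr_res.to_frame().to_csv(sep="\t", index=False,
                                     float_format="%.6g"))
        manifest["stages"]["mr_outcome"] = {
            "n_instruments": len(inst),
            "harmonization_dropped": sum(
                1 for line in inst.log if "dropped" in line),
        }

        for p in sorted(out.rglob("*")):
            if p.is_file() and p.name != "manifest.json":
                manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
        persist()
        return manifest
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        persist()
        raise
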