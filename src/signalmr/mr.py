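"""Two-sample drug-target Mendelian randomization from GWAS summary statistics.

Pipeline: select cis-region instruments (p-value filter + greedy LD
clumping), harmonize exposure and outcome alleles, then estimate the causal
effect with five estimators — inverse-variance weighted (IVW, the primary
analysis), MR-Egger regression, weighted median, simple mode and weighted
mode.  Estimates are reported on the log scale and as odds ratios with 95%
CIs; a positive-control run asserts the expected effect direction before
the outcome analyses are trusted.

Summary statistics are pandas DataFrames with the columns
SNP, CHR, POS, EA, OA, EAF, BETA, SE, P (tab-separated text on disk).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GWAS_COLUMNS",
    "InstrumentSet",
    "MrResult",
    "MRModel",
    "MRResults",
    "read_gwas",
    "read_ld_matrix",
    "select_instruments",
    "harmonize",
    "ivw",
    "mr_egger",
    "weighted_median",
    "mode_estimators",
    "positive_control",
    "PositiveControlError",
]

GWAS_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P"]
Z_95 = 1.959963984540054
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class PositiveControlError(RuntimeError):
    """The positive-control IVW direction contradicts the configured truth."""


def read_gwas(path) -> pd.DataFrame:
    """Read tab-separated GWAS summary statistics, validating columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing GWAS columns {missing}")
    return df


def read_ld_matrix(path) -> pd.DataFrame:
    """Read a plain-text square LD (r) matrix with an SNP-ID header row."""
    ld = pd.read_csv(path, sep="\t", index_col=0)
    if list(ld.index) != list(ld.columns):
        ld.index = ld.columns
    return ld


def is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea.upper()) == oa.upper()


def select_instruments(
    exposure: pd.DataFrame,
    region: tuple[str, int, int],
    ld: pd.DataFrame,
    p_threshold: float = 5e-8,
    r2_max: float = 0.3,
    window_kb: float = 100.0,
) -> list[str]:
    """Greedy p-value clumping of cis-region instruments.

    Keep SNPs inside ``region`` (chrom, start, end; 1-based inclusive) with
    P < p_threshold; then sort ascending by P, accept the best remaining SNP
    and discard every SNP that is both within ``window_kb`` of an accepted
    SNP and has r^2 > ``r2_max`` with it.  The distance rule is to *any*
    accepted SNP, not only the original index variant.
    """
    chrom, start, end = region
    cand = exposure[
        (exposure["CHR"].astype(str) == str(chrom))
        & (exposure["POS"] >= start)
        & (exposure["POS"] <= end)
        & (exposure["P"] < p_threshold)
    ].copy()
    if cand.empty:
        raise ValueError("no instruments: no SNP passes the region/p filter")
    missing_ld = set(cand["SNP"]) - set(ld.columns)
    if missing_ld:
        raise ValueError(f"LD matrix does not cover candidate SNPs: {sorted(missing_ld)[:5]}")
    cand = cand.sort_values(["P", "SNP"], kind="mergesort")
    accepted: list[str] = []
    pos = dict(zip(cand["SNP"], cand["POS"]))
    window_bp = window_kb * 1000.0
    for snp in cand["SNP"]:
        clumped = False
        for kept in accepted:
            if abs(pos[snp] - pos[kept]) <= window_bp:
                r2 = float(ld.loc[snp, kept]) ** 2
                if r2 > r2_max:
                    clumped = True
                    break
        if not clumped:
            accepted.append(snp)
    return accepted


@dataclass
class InstrumentSet:
    """Harmonized per-SNP effect estimates ready for the MR estimators.

    After harmonization every ``beta_x`` is positive: each instrument is
    oriented to the exposure-increasing allele, the convention MR-Egger
    requires.  ``log`` records every flip and drop.
    """

    snps: list[str]
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    orientation: str = "exposure-increasing"
    log: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.beta_x = np.asarray(self.beta_x, dtype=float)
        self.se_x = np.asarray(self.se_x, dtype=float)
        self.beta_y = np.asarray(self.beta_y, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        n = len(self.snps)
        if not (len(self.beta_x) == len(self.se_x) == len(self.beta_y)
                == len(self.se_y) == n):
            raise ValueError("instrument arrays must share one length")
        if np.any(self.se_x <= 0) or np.any(self.se_y <= 0):
            raise ValueError("standard errors must be positive")
        # canonical SNP order, so estimates and seeded bootstrap SEs are
        # invariant to input order
        order = np.argsort(np.asarray(self.snps, dtype=object))
        self.snps = [self.snps[i] for i in order]
        self.beta_x = self.beta_x[order]
        self.se_x = self.se_x[order]
        self.beta_y = self.beta_y[order]
        self.se_y = self.se_y[order]

    def __len__(self):
        return len(self.snps)


def _orient(snps, bx, sx, by, sy, log):
    """Flip instruments so every exposure beta is positive."""
    bx = np.asarray(bx, float).copy()
    by = np.asarray(by, float).copy()
    neg = bx < 0
    for s in np.asarray(snps)[neg]:
        log.append(f"{s}: oriented to exposure-increasing allele (sign flip)")
    by[neg] *= -1
    bx[neg] *= -1
    return bx, np.asarray(sx, float), by, np.asarray(sy, float)


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    snps: list[str] | None = None,
    palindromic_band: tuple[float, float] = (0.42, 0.58),
) -> InstrumentSet:
    """Align outcome alleles to the exposure effect allele.

    Handles four encodings: identical alleles, swapped alleles (outcome
    beta sign is flipped), strand-complemented alleles, and complemented +
    swapped.  Palindromic (A/T, C/G) variants are resolved by allele
    frequency when both frequencies lie outside ``palindromic_band``;
    otherwise they are dropped.  Irreconcilable allele pairs are dropped
    with a reason; an error is raised only when nothing survives.
    """
    exp = exposure.set_index("SNP")
    out = outcome.set_index("SNP")
    if snps is None:
        snps = [s for s in exp.index if s in out.index]
    log: list[str] = []
    kept, bx, sx, by, sy = [], [], [], [], []
    lo, hi = palindromic_band
    for snp in snps:
        if snp not in exp.index or snp not in out.index:
            log.append(f"{snp}: dropped, absent from one dataset")
            continue
        e, o = exp.loc[snp], out.loc[snp]
        ea, oa = str(e["EA"]).upper(), str(e["OA"]).upper()
        yea, yoa = str(o["EA"]).upper(), str(o["OA"]).upper()
        beta_y = float(o["BETA"])
        eaf_y = o["EAF"]
        if is_palindromic(ea, oa):
            eaf_x = e["EAF"]
            if pd.isna(eaf_x) or pd.isna(eaf_y):
                log.append(f"{snp}: dropped, palindromic with missing EAF")
                continue
            if lo < float(eaf_x) < hi or lo < float(eaf_y) < hi:
                log.append(f"{snp}: dropped, palindromic with ambiguous EAF")
                continue
            if {yea, yoa} not in ({ea, oa},):
                log.append(f"{snp}: dropped, palindromic with foreign alleles")
                continue
            # alleles alone cannot distinguish swap from strand flip:
            # align by frequency side
            same_side = (float(eaf_x) < 0.5) == (float(eaf_y) < 0.5)
            if not same_side:
                beta_y = -beta_y
                log.append(f"{snp}: palindromic, aligned by EAF (sign flip)")
            else:
                log.append(f"{snp}: palindromic, aligned by EAF")
        else:
            cea, coa = _COMPLEMENT.get(ea, "?"), _COMPLEMENT.get(oa, "?")
            if (yea, yoa) == (ea, oa):
                pass
            elif (yea, yoa) == (oa, ea):
                beta_y = -beta_y
                log.append(f"{snp}: swapped alleles, outcome sign flipped")
            elif (yea, yoa) == (cea, coa):
                log.append(f"{snp}: strand flip resolved by complementation")
            elif (yea, yoa) == (coa, cea):
                beta_y = -beta_y
                log.append(f"{snp}: strand flip + swap, outcome sign flipped")
            else:
                log.append(
                    f"{snp}: dropped, irreconcilable alleles "
                    f"{ea}/{oa} vs {yea}/{yoa}"
                )
                continue
        kept.append(snp)
        bx.append(float(e["BETA"]))
        sx.append(float(e["SE"]))
        by.append(beta_y)
        sy.append(float(o["SE"]))
    if not kept:
        raise ValueError("harmonization dropped every SNP; see log")
    bx, sx, by, sy = _orient(kept, bx, sx, by, sy, log)
    return InstrumentSet(kept, bx, sx, by, sy, log=log)


# --------------------------------------------------------------------------
# Estimators

@dataclass(frozen=True)
class MrResult:
    """One estimator's causal-effect estimate (Tables-style row)."""

    method: str
    n_snps: int
    beta: float
    se: float
    pval: float
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    q: float | None = None
    q_df: int | None = None

    @property
    def or_hat(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - Z_95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + Z_95 * self.se)


def ivw(inst: InstrumentSet) -> MrResult:
    """Inverse-variance weighted estimate (zero-intercept weighted regression).

    beta = sum(w * bx * by) / sum(w * bx^2) with w = 1/se_y^2.  The standard
    error uses multiplicative random-effects scaling max(1, sqrt(Q/(L-1)));
    Cochran's Q and its df are reported.
    """
    L = len(inst)
    if L < 2:
        raise ValueError("IVW requires at least 2 instruments")
    w = 1.0 / inst.se_y**2
    denom = float(np.sum(w * inst.beta_x**2))
    beta = float(np.sum(w * inst.beta_x * inst.beta_y)) / denom
    q = float(np.sum(w * (inst.beta_y - beta * inst.beta_x) ** 2))
    scale = max(1.0, math.sqrt(q / (L - 1)))
    se = math.sqrt(1.0 / denom) * scale
    p = 2 * stats.norm.sf(abs(beta / se))
    return MrResult("IVW", L, beta, se, float(p), q=q, q_df=L - 1)


def mr_egger(inst: InstrumentSet) -> MrResult:
    """MR-Egger: weighted regression of beta_Y on beta_X with an intercept.

    The slope estimates the causal effect under InSIDE; the intercept
    estimates average directional pleiotropy.  Weights 1/se_y^2; p-values
    from t with L-2 df; residual scaling floored at 1 (never deflating).
    """
    L = len(inst)
    if L < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    w = 1.0 / inst.se_y**2
    X = np.column_stack([np.ones(L), inst.beta_x])
    XtW = X.T * w
    xtwx = XtW @ X
    coef = np.linalg.solve(xtwx, XtW @ inst.beta_y)
    resid = inst.beta_y - X @ coef
    rss = float(np.sum(w * resid**2))
    sigma2 = max(1.0, rss / (L - 2))
    cov = np.linalg.inv(xtwx) * sigma2
    icpt, slope = coef
    icpt_se, slope_se = np.sqrt(np.diag(cov))
    tdist = stats.t(df=L - 2)
    return MrResult(
        "MR-Egger", L, float(slope), float(slope_se),
        float(2 * tdist.sf(abs(slope / slope_se))),
        intercept=float(icpt), intercept_se=float(icpt_se),
        intercept_p=float(2 * tdist.sf(abs(icpt / icpt_se))),
    )


def _ratio_estimates(inst: InstrumentSet):
    """Per-SNP Wald ratios and their MR weights; zero-beta_x SNPs dropped."""
    ok = inst.beta_x != 0
    theta = inst.beta_y[ok] / inst.beta_x[ok]
    w = inst.beta_x[ok] ** 2 / inst.se_y[ok] ** 2
    return theta, w, int(np.sum(~ok))


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    """Cumulative-weight interpolated 50th percentile of the ratio estimates."""
    order = np.argsort(theta, kind="mergesort")
    th = theta[order]
    ww = w[order]
    cum = (np.cumsum(ww) - ww / 2.0) / np.sum(ww)
    return float(np.interp(0.5, cum, th))


def _parametric_boot(inst: InstrumentSet, statistic, n_boot: int, seed: int):
    """SE of ``statistic(theta, w)`` under parametric resampling of the betas."""
    rng = np.random.default_rng(seed)
    L = len(inst)
    bx = rng.normal(inst.beta_x, inst.se_x, size=(n_boot, L))
    by = rng.normal(inst.beta_y, inst.se_y, size=(n_boot, L))
    vals = np.empty(n_boot)
    for i in range(n_boot):
        ok = bx[i] != 0
        theta = by[i][ok] / bx[i][ok]
        w = bx[i][ok] ** 2 / inst.se_y[ok] ** 2
        vals[i] = statistic(theta, w)
    return float(np.std(vals, ddof=1))


def weighted_median(inst: InstrumentSet, n_boot: int = 1000,
                    seed: int = 0) -> MrResult:
    """Weighted median of the per-SNP ratio estimates.

    Consistent when instruments carrying at least half the total weight are
    valid.  Standard error by parametric bootstrap of the summary betas.
    """
    if len(inst) < 3:
        raise ValueError("weighted median requires at least 3 instruments")
    theta, w, n_dropped = _ratio_estimates(inst)
    if n_dropped:
        import warnings

        warnings.warn(f"{n_dropped} SNP(s) with zero exposure beta dropped",
                      stacklevel=2)
    est = _weighted_median_point(theta, w)
    se = _parametric_boot(inst, _weighted_median_point, n_boot, seed)
    p = 2 * stats.norm.sf(abs(est / se)) if se > 0 else 0.0
    return MrResult("Weighted median", len(theta), est, se, float(p))


def _silverman_bandwidth(theta: np.ndarray, phi: float) -> float:
    """Modified Silverman rule: phi * 0.9 * min(sd, mad/0.6745) * L^(-1/5)."""
    sd = float(np.std(theta, ddof=1)) if len(theta) > 1 else 0.0
    mad = float(stats.median_abs_deviation(theta, scale=1.0)) / 0.6744897501960817
    s = min(x for x in (sd, mad) if x > 0) if max(sd, mad) > 0 else 0.0
    return phi * 0.9 * s * len(theta) ** (-1.0 / 5.0)


def _kde_mode(theta: np.ndarray, weights: np.ndarray, phi: float) -> float:
    """Argmax of a Gaussian KDE over the ratio estimates."""
    h = _silverman_bandwidth(theta, phi)
    if h == 0.0:  # all ratios identical
        return float(theta[0])
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, 512)
    z = (grid[:, None] - theta[None, :]) / h
    dens = np.exp(-0.5 * z**2) @ weights
    return float(grid[np.argmax(dens)])


def mode_estimators(inst: InstrumentSet, bandwidth_phi: float = 1.0,
                    n_boot: int = 1000, seed: int = 0):
    """Simple-mode and weighted-mode estimates.

    The mode of the kernel-smoothed ratio-estimate density (unweighted for
    the simple mode, inverse-variance weighted for the weighted mode), with
    bandwidth phi times the modified Silverman rule.  SEs by parametric
    bootstrap.  Returns (simple, weighted) MrResult pair.
    """
    if len(inst) < 3:
        raise ValueError("mode estimators require at least 3 instruments")
    theta, w, _ = _ratio_estimates(inst)

    def simple_stat(th, ww):
        return _kde_mode(th, np.ones_like(th), bandwidth_phi)

    def weighted_stat(th, ww):
        return _kde_mode(th, ww / np.sum(ww), bandwidth_phi)

    out = []
    for name, stat_fn, boot_seed in (
        ("Simple mode", simple_stat, seed),
        ("Weighted mode", weighted_stat, seed + 1),
    ):
        est = stat_fn(theta, w)
        se = _parametric_boot(inst, stat_fn, n_boot, boot_seed)
        p = 2 * stats.norm.sf(abs(est / se)) if se > 0 else 0.0
        out.append(MrResult(name, len(theta), est, se, float(p)))
    return tuple(out)


# --------------------------------------------------------------------------
# Model / results surface

class MRModel:
    """Five-estimator MR analysis over a harmonized instrument set.

    Built either directly from an :class:`InstrumentSet` or from raw
    exposure/outcome summary statistics via :meth:`from_summary_stats`
    (which runs instrument selection and harmonization).
    """

    def __init__(self, instruments: InstrumentSet, n_boot: int = 1000,
                 bandwidth_phi: float = 1.0,
                 exposure: str = "exposure", outcome: str = "outcome"):
        self.instruments = instruments
        self.n_boot = n_boot
        self.bandwidth_phi = bandwidth_phi
        self.exposure = exposure
        self.outcome = outcome

    @classmethod
    def from_summary_stats(cls, exposure_df, outcome_df, region, ld,
                           p_threshold: float = 5e-8, r2_max: float = 0.3,
                           window_kb: float = 100.0, **kwargs):
        snps = select_instruments(exposure_df, region, ld,
                                  p_threshold=p_threshold, r2_max=r2_max,
                                  window_kb=window_kb)
        inst = harmonize(exposure_df, outcome_df, snps=snps)
        return cls(inst, **kwargs)

    def fit(self, seed: int = 0) -> "MRResults":
        inst = self.instruments
        results = [ivw(inst), mr_egger(inst),
                   weighted_median(inst, n_boot=self.n_boot, seed=seed)]
        results.extend(mode_estimators(inst, bandwidth_phi=self.bandwidth_phi,
                                       n_boot=self.n_boot, seed=seed + 1000))
        return MRResults(self, results)


class MRResults:
    """The five estimates with CIs, p-values and heterogeneity diagnostics."""

    def __init__(self, model: MRModel, results: list[MrResult]):
        self.model = model
        self.results = list(results)

    def __iter__(self):
        return iter(self.results)

    def __getitem__(self, method: str) -> MrResult:
        for r in self.results:
            if r.method.lower() == method.lower():
                return r
        raise KeyError(method)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append({
                "exposure": self.model.exposure,
                "outcome": self.model.outcome,
                "method": r.method, "n_snps": r.n_snps,
                "beta": r.beta, "se": r.se,
                "or": r.or_hat, "ci_low": r.ci_low, "ci_high": r.ci_high,
                "pval": r.pval,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"MR analysis: {self.model.exposure} -> {self.model.outcome}",
            "Method\tSNPs\tOR (95% CI)\tp",
        ]
        from .reporting import fmt2

        for r in self.results:
            pv = "<0.001" if r.pval < 0.001 else f"{r.pval:.3f}"
            lines.append(
                f"{r.method}\t{r.n_snps}\t"
                f"{fmt2(r.or_hat)} ({fmt2(r.ci_low)}, {fmt2(r.ci_high)})\t{pv}"
            )
        egger = self["MR-Egger"]
        if egger.intercept is not None:
            lines.append(
                f"Egger intercept {egger.intercept:.4g} "
                f"(SE {egger.intercept_se:.4g}, p {egger.intercept_p:.3f})"
            )
        ivw_r = self["IVW"]
        if ivw_r.q is not None:
            lines.append(f"Cochran Q {ivw_r.q:.2f} on {ivw_r.q_df} df")
        return "\n".join(lines)


def positive_control(instruments: InstrumentSet, expected_direction: str | None,
                     n_boot: int = 1000, seed: int = 0,
                     alpha: float = 0.05) -> MRResults:
    """Run the full battery on the positive-control outcome and check direction.

    ``expected_direction`` is 'protective' (IVW OR < 1 required) or 'risk'
    (OR > 1); a mismatch with p < alpha support raises PositiveControlError
    — a hard validation failure for the pipeline run.  ``None`` skips the
    assertion with a warning (misconfigured control).
    """
    res = MRModel(instruments, n_boot=n_boot, outcome="positive control").fit(seed=seed)
    r = res["IVW"]
    if expected_direction is None:
        import warnings

        warnings.warn("positive control run without a configured truth "
                      "direction; direction not asserted", stacklevel=2)
        return res
    if expected_direction not in ("protective", "risk"):
        raise ValueError("expected_direction must be 'protective', 'risk' or None")
    ok = r.beta < 0 if expected_direction == "protective" else r.beta > 0
    if not ok or r.pval >= alpha:
        raise PositiveControlError(
            f"positive control failed: IVW OR {r.or_hat:.3f} "
            f"(p={r.pval:.3g}) vs expected {expected_direction}"
        )
    return res
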