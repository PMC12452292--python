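"""Disproportionality signal statistics for spontaneous-report 2x2 tables.

Implements the four classical pharmacovigilance signal-detection statistics
computed from a drug-event contingency table:

* ROR  — reporting odds ratio with a Woolf (log-scale Wald) 95% CI,
* PRR  — proportional reporting ratio with a Yates-corrected chi-square
         (the MHRA criterion pair),
* EBGM — empirical-Bayes geometric mean of the posterior reporting-rate
         multiplier under the two-gamma-mixture gamma-Poisson shrinker
         (MGPS), with its 5th posterior percentile EBGM05,
* IC   — the BCPNN information component, a shrunk log2 observed/expected
         ratio, with its 2.5% credibility bound IC025.

The signal criteria applied are the conventional ones: ROR lower 95% bound
> 1 with at least 3 cases; PRR >= 2 together with chi-square >= 4;
EBGM05 >= 2; IC025 > 0.  A pair is flagged as an overall signal only when
all four criteria agree.

The model-level surface is :class:`DisproportionalityModel` /
:class:`DisproportionalityResults`; the per-statistic functions underneath
(:func:`ror_ci`, :func:`prr_chi2`, :func:`ebgm`, :func:`bcpnn_ic`) are
public and stateless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "ContingencyTable",
    "MgpsPrior",
    "SignalResult",
    "DisproportionalityModel",
    "DisproportionalityResults",
    "ror_ci",
    "prr_chi2",
    "bcpnn_ic",
    "fit_mgps_prior",
    "ebgm",
    "classify_signal",
    "ConvergenceError",
    "ZeroCellError",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class ZeroCellError(ValueError):
    """A cell required by the requested statistic is zero."""


class ConvergenceError(RuntimeError):
    """The MGPS hyperparameter optimiser failed; carries the scipy trace."""

    def __init__(self, message: str, result=None):
        super().__init__(message)
        self.result = result


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 drug-event table.

    a: target drug & target event; b: target drug & other events;
    c: other drugs & target event; d: other drugs & other events.
    """

    a: int
    b: int
    c: int
    d: int
    label: str = ""

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"cell {name} is negative: {v}")
        if self.n == 0:
            raise ValueError("empty table: a+b+c+d must be positive")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected a-cell count under row/column independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    def haldane(self) -> "ContingencyTable":
        """Return a continuity-corrected copy with +0.5 added to every cell."""
        return replace(self, a=self.a + 0.5, b=self.b + 0.5,
                       c=self.c + 0.5, d=self.d + 0.5)


def ror_ci(table: ContingencyTable, zero_cell: str = "error"):
    """Reporting odds ratio with Woolf 95% CI.

    ror = (a*d)/(b*c); CI = exp(ln ror +/- 1.96*sqrt(1/a+1/b+1/c+1/d)).

    zero_cell: 'error' (default) raises ZeroCellError naming the offending
    cell; 'haldane' adds 0.5 to every cell first.
    """
    t = table
    zeros = [nm for nm in ("a", "b", "c", "d") if getattr(t, nm) == 0]
    if zeros:
        if zero_cell == "haldane":
            t = t.haldane()
        else:
            raise ZeroCellError(
                f"zero cell(s) {','.join(zeros)} in table {t.label!r}; "
                "pass zero_cell='haldane' to apply the +0.5 correction"
            )
    ror = (t.a * t.d) / (t.b * t.c)
    se = np.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    lo = float(np.exp(np.log(ror) - Z_95 * se))
    hi = float(np.exp(np.log(ror) + Z_95 * se))
    return float(ror), lo, hi


def prr_chi2(table: ContingencyTable, yates: bool = True):
    """Proportional reporting ratio and Pearson chi-square.

    prr = [a/(a+b)] / [c/(c+d)].  chi2 is the Pearson statistic on the 2x2
    table, by default with the Yates continuity correction
    sum((|O-E|-0.5)^2/E), the corrected deviation clipped at zero.
    Returns (prr, chi2); prr is +inf when c == 0 (flagged by the caller).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + b == 0 or c + d == 0:
        raise ValueError("prr undefined: an entire drug arm is empty")
    exposed = a / (a + b)
    if c == 0:
        prr = np.inf
    else:
        prr = exposed / (c / (c + d))
    n = table.n
    obs = np.array([a, b, c, d], dtype=float)
    exp = np.array(
        [
            (a + b) * (a + c),
            (a + b) * (b + d),
            (c + d) * (a + c),
            (c + d) * (b + d),
        ],
        dtype=float,
    ) / n
    dev = np.abs(obs - exp)
    if yates:
        dev = np.clip(dev - 0.5, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(exp > 0, dev**2 / exp, 0.0)
    return float(prr), float(terms.sum())


def bcpnn_ic(table: ContingencyTable):
    """BCPNN information component and its 2.5% credibility bound.

    ic = log2((a + 0.5) / (E + 0.5)) with E the independence expectation of
    the a cell; ic025 = log2 of the 2.5th percentile of the
    Gamma(shape = a + 0.5, rate = E + 0.5) posterior on the rate multiplier.
    """
    a, e = table.a, table.expected
    ic = float(np.log2((a + 0.5) / (e + 0.5)))
    q = stats.gamma.ppf(0.025, a + 0.5, scale=1.0 / (e + 0.5))
    return ic, float(np.log2(q))


# --------------------------------------------------------------------------
# MGPS / EBGM

@dataclass(frozen=True)
class MgpsPrior:
    """Two-gamma mixture prior on the Poisson reporting-rate multiplier.

    lambda ~ pi * Gamma(alpha1, rate=beta1) + (1-pi) * Gamma(alpha2, rate=beta2).
    """

    alpha1: float = 0.2
    beta1: float = 0.1
    alpha2: float = 2.0
    beta2: float = 4.0
    pi_mix: float = 1.0 / 3.0
    loglik: float = field(default=np.nan, compare=False)
    converged: bool = field(default=False, compare=False)

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be positive")
        if not 0.0 < self.pi_mix < 1.0:
            raise ValueError("pi_mix must lie in the open interval (0, 1)")


def _mixture_logpmf(counts, expected, params):
    """Marginal log-pmf of the counts under the two-gamma mixture prior.

    The gamma-Poisson marginal is negative binomial with size alpha and
    success probability beta/(beta+E).
    """
    a1, b1, a2, b2, pi = params
    lp1 = stats.nbinom.logpmf(counts, a1, b1 / (b1 + expected))
    lp2 = stats.nbinom.logpmf(counts, a2, b2 / (b2 + expected))
    return np.logaddexp(np.log(pi) + lp1, np.log1p(-pi) + lp2)


def fit_mgps_prior(
    counts,
    expected,
    start: MgpsPrior | None = None,
    bound: tuple[float, float] = (1e-6, 1e6),
    tol: float = 1e-8,
) -> MgpsPrior:
    """Fit the 5 MGPS hyperparameters by maximum marginal likelihood.

    counts/expected are the observed a-cells and their independence
    expectations over the whole drug-event matrix.  Optimisation is
    L-BFGS-B on log-transformed gamma parameters and logit-transformed
    mixing weight, from the canonical starting point
    (0.2, 0.1, 2, 4, 1/3).  Non-convergence raises ConvergenceError with
    the scipy result attached; there is no silent fallback.
    """
    counts = np.asarray(counts, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if counts.shape != expected.shape:
        raise ValueError("counts and expected must have the same shape")
    if counts.size < 100:
        warnings.warn(
            f"fitting the MGPS prior on only {counts.size} drug-event pairs; "
            ">= 100 recommended",
            stacklevel=2,
        )
    if np.any(expected <= 0):
        raise ValueError("all expected counts must be positive")
    start = start or MgpsPrior()

    lo, hi = np.log(bound[0]), np.log(bound[1])

    def unpack(x):
        a1, b1, a2, b2 = np.exp(x[:4])
        pi = special.expit(x[4])
        return a1, b1, a2, b2, pi

    def nll(x):
        return -float(np.sum(_mixture_logpmf(counts, expected, unpack(x))))

    x0 = np.array(
        [
            np.log(start.alpha1),
            np.log(start.beta1),
            np.log(start.alpha2),
            np.log(start.beta2),
            special.logit(start.pi_mix),
        ]
    )
    res = optimize.minimize(
        nll,
        x0,
        method="L-BFGS-B",
        bounds=[(lo, hi)] * 4 + [(-13.8, 13.8)],
        options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
    )
    if not res.success or not np.isfinite(res.fun):
        raise ConvergenceError(
            f"MGPS hyperparameter optimisation failed: {res.message}", result=res
        )
    a1, b1, a2, b2, pi = unpack(res.x)
    return MgpsPrior(a1, b1, a2, b2, pi, loglik=-res.fun, converged=True)


def _posterior_mixture(a, e, prior: MgpsPrior):
    """Posterior over lambda: mixture of Gamma(alpha_k + a, rate beta_k + E).

    Returns (weights, shapes, rates).
    """
    params = (prior.alpha1, prior.beta1, prior.alpha2, prior.beta2, prior.pi_mix)
    a1, b1, a2, b2, pi = params
    lw1 = np.log(pi) + stats.nbinom.logpmf(a, a1, b1 / (b1 + e))
    lw2 = np.log1p(-pi) + stats.nbinom.logpmf(a, a2, b2 / (b2 + e))
    m = max(lw1, lw2)
    w1 = np.exp(lw1 - m)
    w2 = np.exp(lw2 - m)
    tot = w1 + w2
    return (
        np.array([w1 / tot, w2 / tot]),
        np.array([a1 + a, a2 + a]),
        np.array([b1 + e, b2 + e]),
    )


def ebgm(table: ContingencyTable, prior: MgpsPrior):
    """EBGM and EBGM05 for one table under a fitted MGPS prior.

    EBGM = 2**E[log2 lambda | a] = exp(sum_k Q_k (psi(shape_k) - ln rate_k));
    EBGM05 is the 5th posterior percentile, found by root-finding on the
    mixture CDF to |CDF - 0.05| < 1e-8.
    """
    a, e = table.a, table.expected
    if e <= 0:
        raise ValueError("expected count must be positive for EBGM")
    w, shape, rate = _posterior_mixture(a, e, prior)
    mean_log = float(np.sum(w * (special.digamma(shape) - np.log(rate))))
    geo_mean = float(np.exp(mean_log))

    def cdf(x):
        return float(np.sum(w * stats.gamma.cdf(x, shape, scale=1.0 / rate)))

    hi = max(a / e * 10 + 10, 10.0)
    while cdf(hi) < 0.05:  # pragma: no cover - defensive bracket growth
        hi *= 10
    q05 = optimize.brentq(lambda x: cdf(x) - 0.05, 0.0, hi, xtol=1e-14,
                          rtol=8.9e-16)
    assert abs(cdf(q05) - 0.05) < 1e-8
    return geo_mean, float(q05)


# --------------------------------------------------------------------------
# Classification and the model/results surface

@dataclass(frozen=True)
class SignalResult:
    """All four statistics for one table, plus per-criterion signal flags."""

    table: ContingencyTable
    ror: float
    ror_low: float
    ror_high: float
    prr: float
    chi2: float
    ebgm: float
    ebgm05: float
    ic: float
    ic025: float
    corrected: bool = False  # Haldane correction applied to ROR

    @property
    def n_reports(self) -> int:
        return self.table.a

    @property
    def flags(self) -> dict:
        return classify_signal(self)


def classify_signal(result: SignalResult) -> dict:
    """Apply the four signal criteria.

    ROR: lower 95% bound > 1 and at least 3 cases; MHRA: PRR >= 2 and
    chi-square >= 4; MGPS: EBGM05 >= 2; BCPNN: IC025 > 0.  The overall flag
    requires all four.
    """
    flags = {
        "criterion_ror": bool(result.ror_low > 1.0 and result.table.a >= 3),
        "criterion_mhra": bool(result.prr >= 2.0 and result.chi2 >= 4.0),
        "criterion_ebgm": bool(result.ebgm05 >= 2.0),
        "criterion_ic": bool(result.ic025 > 0.0),
    }
    flags["overall"] = all(flags.values())
    return flags


class DisproportionalityModel:
    """Signal-detection model over one or more 2x2 contingency tables.

    Parameters
    ----------
    tables : ContingencyTable or sequence of ContingencyTable
    prior : MgpsPrior, optional
        A fitted MGPS prior for EBGM.  When omitted and several tables are
        given, the prior is fitted to their (a, E) pairs at ``fit()`` time;
        with a single table the canonical default prior is used and the
        results object records ``prior_source = 'default'``.
    zero_cell : 'error' or 'haldane'
        Zero-cell policy for the ROR (see :func:`ror_ci`).
    yates : bool
        Continuity-correct the chi-square (default True).
    """

    def __init__(self, tables, prior: MgpsPrior | None = None,
                 zero_cell: str = "error", yates: bool = True):
        if isinstance(tables, ContingencyTable):
            tables = [tables]
        self.tables = list(tables)
        if not self.tables:
            raise ValueError("at least one contingency table is required")
        if zero_cell not in ("error", "haldane"):
            raise ValueError("zero_cell must be 'error' or 'haldane'")
        self.prior = prior
        self.zero_cell = zero_cell
        self.yates = yates

    @classmethod
    def from_pairs(cls, pairs, **kwargs):
        """Build from a drug-event count matrix.

        ``pairs`` is a DataFrame with columns drug, event, count; the 2x2
        margins of every pair are computed internally and the MGPS prior is
        fitted over the full matrix.
        """
        import pandas as pd

        pairs = pd.DataFrame(pairs, columns=["drug", "event", "count"])
        pivot = pairs.pivot_table(index="drug", columns="event", values="count",
                                  aggfunc="sum", fill_value=0)
        total = int(pivot.values.sum())
        row = pivot.sum(axis=1)
        col = pivot.sum(axis=0)
        tables = []
        for drug in pivot.index:
            for event in pivot.columns:
                a = int(pivot.loc[drug, event])
                r, c = int(row[drug]), int(col[event])
                tables.append(ContingencyTable(
                    a=a, b=r - a, c=c - a, d=total - r - c + a,
                    label=f"{drug}|{event}"))
        return cls(tables, **kwargs)

    def fit(self) -> "DisproportionalityResults":
        prior = self.prior
        prior_source = "supplied"
        if prior is None:
            if len(self.tables) >= 2:
                counts = np.array([t.a for t in self.tables], dtype=float)
                expected = np.array([t.expected for t in self.tables])
                keep = expected > 0
                prior = fit_mgps_prior(counts[keep], expected[keep])
                prior_source = "fitted"
            else:
                prior = MgpsPrior()
                prior_source = "default"
        results = []
        for t in self.tables:
            has_zero = 0 in (t.a, t.b, t.c, t.d)
            r, lo, hi = ror_ci(t, zero_cell=self.zero_cell)
            prr, chi2 = prr_chi2(t, yates=self.yates)
            eb, eb05 = ebgm(t, prior)
            ic, ic025 = bcpnn_ic(t)
            results.append(SignalResult(
                table=t, ror=r, ror_low=lo, ror_high=hi, prr=prr, chi2=chi2,
                ebgm=eb, ebgm05=eb05, ic=ic, ic025=ic025,
                corrected=has_zero and self.zero_cell == "haldane"))
        return DisproportionalityResults(self, results, prior, prior_source)


class DisproportionalityResults:
    """Fitted signal statistics for each table, with a printable summary."""

    def __init__(self, model, results, prior, prior_source):
        self.model = model
        self.results = list(results)
        self.prior = prior
        self.prior_source = prior_source

    def __iter__(self):
        return iter(self.results)

    def __len__(self):
        return len(self.results)

    def to_frame(self):
        import pandas as pd

        rows = []
        for r in self.results:
            row = {
                "label": r.table.label,
                "N": r.table.a,
                "ror": r.ror, "ror_low": r.ror_low, "ror_high": r.ror_high,
                "prr": r.prr, "chi2": r.chi2,
                "ebgm": r.ebgm, "ebgm05": r.ebgm05,
                "ic": r.ic, "ic025": r.ic025,
            }
            row.update(r.flags)
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        from .reporting import render_signal_table

        header = (
            f"Disproportionality analysis ({len(self.results)} table(s); "
            f"MGPS prior: {self.prior_source})\n"
            f"prior: alpha1={self.prior.alpha1:.4g} beta1={self.prior.beta1:.4g} "
            f"alpha2={self.prior.alpha2:.4g} beta2={self.prior.beta2:.4g} "
            f"pi={self.prior.pi_mix:.4g}\n"
        )
        return header + render_signal_table(self.results, min_cases=0)
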