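"""Disproportionality statistics for 2x2 spontaneous-report tables.

For a (drug, term) cell within one stratum the table is

    =============  ==========  ===============
                   term        all other terms
    target drug    a           b
    other drugs    c           d
    =============  ==========  ===============

with N = a+b+c+d counted at *case* level (a case contributes at most once
per term, however many times the PT repeats on the report).

Four frequentist/Bayesian signal-mining statistics are computed:

* ROR  = ad/bc with a Wald 95% CI on the log scale;
* PRR  = [a/(a+b)] / [c/(c+d)] with a Pearson chi-square;
* IC   = log2(a N / ((a+b)(a+c))), the BCPNN information component, with a
  lower credibility bound IC025 = IC - 2*sqrt(V);
* EBGM = a N / ((a+b)(a+c)) in "simple" mode (the observed/expected relative
  reporting ratio, so IC = log2 EBGM exactly), with
  EB05 = exp(ln EBGM - 1.64 sqrt(1/a+1/b+1/c+1/d)); or the full DuMouchel
  two-component gamma-Poisson shrinkage posterior in "full" mode.

A cell is a *positive signal* only when it passes all four algorithms'
criteria simultaneously (a >= 3 and ROR025 > 1; a >= 3, PRR >= 2 and
chi2 >= 4; IC025 > 0; EB05 > 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .dictionary import MiniDictionary
from .preprocess import CaseReport

Z95 = 1.96  # conventional two-sided 95% multiplier (as printed tables use)


class EmptyStratumError(ValueError):
    """No cases in the requested stratum."""


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.N == 0:
            raise ValueError("empty contingency table (N = 0)")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected_a(self) -> float:
        """Independence expectation E = (a+b)(a+c)/N."""
        return (self.a + self.b) * (self.a + self.c) / self.N

    def with_haldane(self, k: float = 0.5) -> "ContingencyTable":
        """Continuity-corrected copy (adds k to every cell); counts become
        floats only transiently so the corrected table is built directly."""
        t = object.__new__(ContingencyTable)
        object.__setattr__(t, "a", self.a + k)
        object.__setattr__(t, "b", self.b + k)
        object.__setattr__(t, "c", self.c + k)
        object.__setattr__(t, "d", self.d + k)
        return t


@dataclass
class SignalStatistics:
    ror: float = math.nan
    ror_lo95: float = math.nan
    ror_hi95: float = math.nan
    prr: float = math.nan
    chi2: float = math.nan
    ic: float = math.nan
    ic025: float = math.nan
    ebgm: float = math.nan
    ebgm05: float = math.nan
    notes: List[str] = field(default_factory=list)


@dataclass(frozen=True)
class SignalCriteria:
    """Per-algorithm positivity thresholds (the conventional defaults)."""

    min_count: int = 3
    ror_lo_gt: float = 1.0
    prr_ge: float = 2.0
    chi2_ge: float = 4.0
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0


@dataclass(frozen=True)
class SignalVerdict:
    pass_ror: bool
    pass_prr: bool
    pass_bcpnn: bool
    pass_mgps: bool

    @property
    def positive(self) -> bool:
        return self.pass_ror and self.pass_prr and self.pass_bcpnn and self.pass_mgps


def build_contingency(
    cases: Sequence[CaseReport],
    term: str,
    level: str = "PT",
    stratum: Optional[str] = None,
    dictionary: Optional[MiniDictionary] = None,
) -> ContingencyTable:
    """Case-level 2x2 table for one term within one stratum.

    The background (rows c, d) is every non-target case in the same
    stratum of the supplied universe; ``is_target`` must already be set.
    """
    if level == "SOC" and dictionary is None:
        raise ValueError("SOC-level tables need a PT->SOC dictionary")
    norm = term.strip().casefold()
    sub = [c for c in cases if stratum is None or c.stratum == stratum]
    if not sub:
        raise EmptyStratumError(f"no cases in stratum {stratum!r}")
    a = b = c_ = d = 0
    for case in sub:
        if level == "PT":
            terms = {pt.strip().casefold() for pt in case.reactions}
        else:
            terms = {
                dictionary.soc_of(pt).strip().casefold() for pt in case.reactions
            }
        has = norm in terms
        if case.is_target:
            a, b = (a + 1, b) if has else (a, b + 1)
        else:
            c_, d = (c_ + 1, d) if has else (c_, d + 1)
    return ContingencyTable(a, b, c_, d)


# ---------------------------------------------------------------------------
# the four statistics


def ror_stat(t: ContingencyTable) -> Tuple[float, float, float]:
    """Reporting odds ratio ad/bc with Wald 95% CI; NaN on any zero cell."""
    if min(t.a, t.b, t.c, t.d) <= 0:
        return math.nan, math.nan, math.nan
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return ror, ror * math.exp(-Z95 * se), ror * math.exp(Z95 * se)


def prr_stat(t: ContingencyTable, yates: bool = False) -> Tuple[float, float]:
    """Proportional reporting ratio and Pearson chi-square.

    PRR is undefined (NaN) when a margin or the background rate is zero.
    The chi-square is the textbook 2x2 Pearson statistic; the Yates
    continuity correction is off by default.
    """
    n1, n0 = t.a + t.b, t.c + t.d
    if n1 == 0 or n0 == 0 or t.c == 0:
        prr = math.nan
    else:
        prr = (t.a / n1) / (t.c / n0)
    col1, col0 = t.a + t.c, t.b + t.d
    if n1 == 0 or n0 == 0 or col1 == 0 or col0 == 0:
        return prr, math.nan
    diff = abs(t.a * t.d - t.b * t.c)
    if yates:
        diff = max(diff - t.N / 2, 0.0)
    chi2 = t.N * diff * diff / (n1 * n0 * col1 * col0)
    return prr, chi2


def bcpnn_ic(t: ContingencyTable, variant: str = "bate") -> Tuple[float, float]:
    """BCPNN information component and its lower credibility bound.

    ic = log2(a N / ((a+b)(a+c))).  Two IC025 variants are supported:

    * ``"bate"`` (default): ic - 2*sqrt(V) with V the closed-form moment
      approximation of the posterior variance under the standard BCPNN
      priors (alpha1 = beta1 = 1, alpha = beta = 2, gamma11 chosen so the
      prior IC expectation is 0);
    * ``"count"``: the count-based approximation
      ic - 3.3 a^(-1/2) - 2.1 a^(-3/2).
    """
    if t.a <= 0:
        return math.nan, math.nan
    n1, col1, N = t.a + t.b, t.a + t.c, t.N
    expected = n1 * col1 / N
    if expected <= 0:
        return math.nan, math.nan
    ic = math.log2(t.a * N / (n1 * col1))
    if variant == "count":
        return ic, ic - 3.3 * t.a ** -0.5 - 2.1 * t.a ** -1.5
    if variant != "bate":
        raise ValueError(f"unknown IC variant {variant!r}")
    a, N = float(t.a), float(N)
    alpha1 = beta1 = 1.0
    alpha = beta = 2.0
    gamma11 = 1.0
    gamma = gamma11 * (N + alpha) * (N + beta) / ((n1 + alpha1) * (col1 + beta1))
    ln2sq = math.log(2) ** 2
    v = (
        (N - a + gamma - gamma11) / ((a + gamma11) * (1 + N + gamma))
        + (N - n1 + alpha - alpha1) / ((n1 + alpha1) * (1 + N + alpha))
        + (N - col1 + beta - beta1) / ((col1 + beta1) * (1 + N + beta))
    ) / ln2sq
    return ic, ic - 2.0 * math.sqrt(v)


def ebgm_simple(t: ContingencyTable) -> Tuple[float, float]:
    """Relative reporting ratio a/E and its lower-5% bound.

    ebgm = a N / ((a+b)(a+c)); ebgm05 = exp(ln ebgm - 1.64 * sqrt(1/a +
    1/b + 1/c + 1/d)).  Both NaN on any zero cell.
    """
    if min(t.a, t.b, t.c, t.d) <= 0:
        return math.nan, math.nan
    ebgm = t.a * t.N / ((t.a + t.b) * (t.a + t.c))
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return ebgm, math.exp(math.log(ebgm) - 1.64 * se)


def compute_statistics(
    t: ContingencyTable,
    ic_variant: str = "bate",
    yates: bool = False,
    haldane: bool = False,
    eb_fit: Optional["GammaMixtureFit"] = None,
) -> SignalStatistics:
    """All four statistics for one table.

    With *haldane* a +0.5 continuity correction is applied first.  When an
    *eb_fit* (full DuMouchel posterior) is supplied it replaces the simple
    EBGM/EB05.
    """
    tt = t.with_haldane() if haldane else t
    s = SignalStatistics()
    s.ror, s.ror_lo95, s.ror_hi95 = ror_stat(tt)
    if math.isnan(s.ror):
        s.notes.append("ror undefined: zero cell")
    s.prr, s.chi2 = prr_stat(tt, yates=yates)
    if math.isnan(s.prr):
        s.notes.append("prr undefined: zero margin or background rate")
    s.ic, s.ic025 = bcpnn_ic(tt, variant=ic_variant)
    if math.isnan(s.ic):
        s.notes.append("ic undefined: zero observed or expected count")
    if eb_fit is None:
        s.ebgm, s.ebgm05 = ebgm_simple(tt)
        if math.isnan(s.ebgm):
            s.notes.append("ebgm undefined: zero cell")
    else:
        if t.a > 0 and t.expected_a > 0:
            s.ebgm = eb_fit.ebgm(t.a, t.expected_a)
            s.ebgm05 = eb_fit.eb05(t.a, t.expected_a)
        else:
            s.notes.append("ebgm undefined: zero observed or expected count")
    return s


def is_positive(
    stats: SignalStatistics, a: int, criteria: SignalCriteria = SignalCriteria()
) -> SignalVerdict:
    """Joint positivity rule: all four algorithms must pass.

    Undefined (NaN) components fail their flag.
    """
    def ok(x: float) -> bool:
        return not math.isnan(x)

    pass_ror = a >= criteria.min_count and ok(stats.ror_lo95) and stats.ror_lo95 > criteria.ror_lo_gt
    pass_prr = (
        a >= criteria.min_count
        and ok(stats.prr)
        and ok(stats.chi2)
        and stats.prr >= criteria.prr_ge
        and stats.chi2 >= criteria.chi2_ge
    )
    pass_bcpnn = ok(stats.ic025) and stats.ic025 > criteria.ic025_gt
    pass_mgps = ok(stats.ebgm05) and stats.ebgm05 > criteria.ebgm05_gt
    return SignalVerdict(pass_ror, pass_prr, pass_bcpnn, pass_mgps)


# ---------------------------------------------------------------------------
# full DuMouchel gamma-Poisson shrinker


@dataclass
class GammaMixtureFit:
    """Fitted two-component gamma prior on the relative reporting ratio.

    Prior: lambda ~ w * Gamma(alpha1, rate beta1) + (1-w) * Gamma(alpha2,
    rate beta2); observed counts a ~ Poisson(lambda * E), so marginally a
    is a mixture of negative binomials.  Posterior per cell is again a
    two-component gamma mixture.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float
    loglik: float = math.nan
    converged: bool = False
    n_iter: int = 0

    @property
    def component_means(self) -> Tuple[float, float]:
        return self.alpha1 / self.beta1, self.alpha2 / self.beta2

    def _log_marginals(self, a, E):
        a = np.asarray(a, dtype=float)
        E = np.asarray(E, dtype=float)
        lm1 = _nbinom_logpmf(a, self.alpha1, self.beta1, E)
        lm2 = _nbinom_logpmf(a, self.alpha2, self.beta2, E)
        return lm1, lm2

    def posterior_weight(self, a, E):
        """P(component 1 | a, E)."""
        lm1, lm2 = self._log_marginals(a, E)
        m = np.maximum(lm1, lm2)
        p1 = np.exp(lm1 - m) * self.w
        p2 = np.exp(lm2 - m) * (1.0 - self.w)
        return p1 / (p1 + p2)

    def ebgm(self, a, E):
        """Posterior geometric mean exp(E[ln lambda | a, E])."""
        q = self.posterior_weight(a, E)
        a = np.asarray(a, dtype=float)
        E = np.asarray(E, dtype=float)
        eln1 = special.digamma(self.alpha1 + a) - np.log(self.beta1 + E)
        eln2 = special.digamma(self.alpha2 + a) - np.log(self.beta2 + E)
        out = np.exp(q * eln1 + (1.0 - q) * eln2)
        return float(out) if out.ndim == 0 else out

    def eb05(self, a: float, E: float, prob: float = 0.05) -> float:
        """Posterior *prob* quantile of lambda (EB05 by default)."""
        q = float(self.posterior_weight(a, E))
        g1 = stats.gamma(self.alpha1 + a, scale=1.0 / (self.beta1 + E))
        g2 = stats.gamma(self.alpha2 + a, scale=1.0 / (self.beta2 + E))

        def cdf(x):
            return q * g1.cdf(x) + (1.0 - q) * g2.cdf(x) - prob

        lo = min(g1.ppf(1e-9), g2.ppf(1e-9))
        hi = max(g1.ppf(1.0 - 1e-9), g2.ppf(1.0 - 1e-9))
        return float(optimize.brentq(cdf, lo, hi))

    def loglik_of(self, a, E) -> float:
        lm1, lm2 = self._log_marginals(a, E)
        m = np.maximum(lm1, lm2)
        return float(
            np.sum(m + np.log(self.w * np.exp(lm1 - m) + (1 - self.w) * np.exp(lm2 - m)))
        )


class GammaMixtureError(RuntimeError):
    """Non-convergence; carries the best-so-far fit."""

    def __init__(self, message: str, best: GammaMixtureFit):
        super().__init__(message)
        self.best = best


def _nbinom_logpmf(a, alpha, beta, E):
    """log P(a) under lambda ~ Gamma(alpha, rate beta), a ~ Poisson(lambda E):
    negative binomial with size alpha and success prob beta/(beta+E)."""
    p = beta / (beta + E)
    return stats.nbinom.logpmf(a, alpha, p)


def fit_gamma_mixture(
    cells: Sequence[Tuple[float, float]],
    init: Tuple[float, float, float, float, float] = (0.2, 0.1, 2.0, 4.0, 1 / 3),
    maxiter: int = 2000,
) -> GammaMixtureFit:
    """Maximum-marginal-likelihood fit of the two-component gamma prior.

    *cells* is a sequence of (observed count a, expected count E) pairs,
    at least 20 of them.  Optimization is over log shapes/rates and
    logit(w) with Nelder-Mead restarts.  Raises :class:`GammaMixtureError`
    (carrying the best fit so far) on non-convergence.
    """
    cells = list(cells)
    if len(cells) < 20:
        raise ValueError("need at least 20 (a, E) cells to fit the prior")
    a = np.array([c[0] for c in cells], dtype=float)
    E = np.array([c[1] for c in cells], dtype=float)
    if np.any(E <= 0):
        raise ValueError("all expected counts must be positive")

    def unpack(theta):
        a1, b1, a2, b2 = np.exp(np.clip(theta[:4], -12, 12))
        w = 1.0 / (1.0 + math.exp(-np.clip(theta[4], -30, 30)))
        return a1, b1, a2, b2, w

    def negloglik(theta):
        a1, b1, a2, b2, w = unpack(theta)
        lm1 = _nbinom_logpmf(a, a1, b1, E)
        lm2 = _nbinom_logpmf(a, a2, b2, E)
        m = np.maximum(lm1, lm2)
        ll = m + np.log(w * np.exp(lm1 - m) + (1 - w) * np.exp(lm2 - m))
        if not np.all(np.isfinite(ll)):
            return 1e12
        return -float(np.sum(ll))

    x0 = np.array(
        [math.log(init[0]), math.log(init[1]), math.log(init[2]), math.log(init[3]),
         math.log(init[4] / (1 - init[4]))]
    )
    best = None
    for attempt, start in enumerate([x0, x0 + 0.5, x0 - 0.5]):
        res = optimize.minimize(
            negloglik, start, method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            best = res if res.fun <= best.fun else best
            break
    a1, b1, a2, b2, w = unpack(best.x)
    fit = GammaMixtureFit(
        alpha1=a1, beta1=b1, alpha2=a2, beta2=b2, w=w,
        loglik=-best.fun, converged=bool(best.success), n_iter=int(best.nit),
    )
    if not best.success:
        raise GammaMixtureError("gamma-mixture fit did not converge", fit)
    return fit


# ---------------------------------------------------------------------------
# screening


def screen(
    cases: Sequence[CaseReport],
    level: str = "PT",
    stratum: Optional[str] = None,
    dictionary: Optional[MiniDictionary] = None,
    criteria: SignalCriteria = SignalCriteria(),
    ic_variant: str = "bate",
    yates: bool = False,
    haldane: bool = False,
    eb_mode: str = "simple",
) -> pd.DataFrame:
    """Screen every term observed in a stratum and rank the signals.

    Returns one row per term with the 2x2 counts, the four statistics,
    the per-algorithm flags and the joint verdict.  Positive rows sort
    first by descending ROR; ties break by descending frequency then by
    term name.  ``eb_mode="full"`` fits the DuMouchel gamma-mixture prior
    across all screened cells and uses the posterior EBGM/EB05.
    """
    if level == "SOC" and dictionary is None:
        raise ValueError("SOC-level screening needs a PT->SOC dictionary")
    sub = [c for c in cases if stratum is None or c.stratum == stratum]
    if not sub:
        raise EmptyStratumError(f"no cases in stratum {stratum!r}")

    # one pass: distinct terms per case, counted once per case
    terms: Dict[str, str] = {}  # normalized -> display form
    a_count: Dict[str, int] = {}
    any_count: Dict[str, int] = {}
    n_target = 0
    n_total = len(sub)
    for case in sub:
        if level == "PT":
            its = case.reactions
        else:
            its = [dictionary.soc_of(pt) for pt in case.reactions]
        case_terms = set()
        for term in its:
            norm = term.strip().casefold()
            terms.setdefault(norm, term.strip())
            case_terms.add(norm)
        if case.is_target:
            n_target += 1
        for norm in case_terms:
            any_count[norm] = any_count.get(norm, 0) + 1
            if case.is_target:
                a_count[norm] = a_count.get(norm, 0) + 1

    tables = {}
    for norm in terms:
        a = a_count.get(norm, 0)
        c = any_count.get(norm, 0) - a
        tables[norm] = ContingencyTable(a, n_target - a, c, n_total - n_target - c)

    eb_fit = None
    if eb_mode == "full":
        cells = [(t.a, t.expected_a) for t in tables.values()
                 if t.a > 0 and t.expected_a > 0]
        eb_fit = fit_gamma_mixture(cells)
    elif eb_mode != "simple":
        raise ValueError(f"unknown eb_mode {eb_mode!r}")

    rows = []
    for norm, t in tables.items():
        s = compute_statistics(t, ic_variant=ic_variant, yates=yates,
                               haldane=haldane, eb_fit=eb_fit)
        v = is_positive(s, t.a, criteria)
        row = {
            "term": terms[norm],
            "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "ror": s.ror, "ror_lo95": s.ror_lo95, "ror_hi95": s.ror_hi95,
            "prr": s.prr, "chi2": s.chi2,
            "ebgm": s.ebgm, "ebgm05": s.ebgm05,
            "ic": s.ic, "ic025": s.ic025,
            "pass_ror": v.pass_ror, "pass_prr": v.pass_prr,
            "pass_bcpnn": v.pass_bcpnn, "pass_mgps": v.pass_mgps,
            "positive": v.positive,
        }
        rows.append(row)
    df = pd.DataFrame(rows)
    df["_ror_sort"] = df["ror"].fillna(-math.inf)
    df = df.sort_values(
        by=["positive", "_ror_sort", "a", "term"],
        ascending=[False, False, False, True],
        kind="mergesort",
    ).drop(columns="_ror_sort").reset_index(drop=True)
    return df


def format_signal_table(df: pd.DataFrame) -> pd.DataFrame:
    """Render a screen() frame in the conventional published layout:
    term, frequency, "ROR (95% CI)", "PRR (chi2)", "EBGM (EBGM05)",
    "IC (IC025)", positive."""
    def f(x, nd=2):
        return "" if (x is None or (isinstance(x, float) and math.isnan(x))) else f"{x:.{nd}f}"

    out = pd.DataFrame({
        "term": df["term"],
        "frequency": df["a"],
        "ROR (95% CI)": [
            f"{f(r.ror)} ({f(r.ror_lo95)}-{f(r.ror_hi95)})" for r in df.itertuples()
        ],
        "PRR (chi2)": [f"{f(r.prr)} ({f(r.chi2)})" for r in df.itertuples()],
        "EBGM (EBGM05)": [f"{f(r.ebgm)} ({f(r.ebgm05)})" for r in df.itertuples()],
        "IC (IC025)": [f"{f(r.ic)} ({f(r.ic025)})" for r in df.itertuples()],
        "positive": df["positive"],
    })
    return out
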