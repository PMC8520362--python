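"""Two-group comparison of morphometry tables.

Independent-sample t-tests per measurement site, computable either from raw
per-subject values or directly from published summary statistics
(mean, SD, n per group).  The reference study design compared primiparas
after vaginal delivery (group 1, n = 77) with primiparas after Caesarean
section (group 2, n = 80), reporting per-site mean +/- SD tables for
maternal covariates and for IAS/EAS/PRM wall thicknesses; those printed
cells ship with the package (``load_reference_tables``) so the full report
regenerates from summary statistics alone.

No multiple-testing correction is applied: the reference analysis reports
raw per-site p-values at alpha = 0.05 and this module mirrors that choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError

__all__ = [
    "GroupSummary",
    "TTestResult",
    "t_from_summary",
    "t_from_raw",
    "compare_table",
    "load_reference_tables",
    "simulate_two_group_study",
    "format_p",
]

#: |recomputed t| - |printed t| beyond which a published cell is treated as
#: internally inconsistent (its printed statistic cannot follow from its own
#: mean/SD/n entries under any standard two-sample t-test).
PRINT_CONSISTENCY_TOL = 0.3


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics of one group at one site: mean +/- SD, n."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise DomainError("sd must be non-negative")
        if self.n < 2:
            raise DomainError("n must be >= 2")


@dataclass(frozen=True)
class TTestResult:
    """Independent two-sample t-test outcome."""

    t: float
    df: float
    p: float
    method: str  # "welch" or "pooled"

    @property
    def significant_at_0_05(self) -> bool:
        return self.p < 0.05


def t_from_summary(g1: GroupSummary, g2: GroupSummary, method: str = "welch") -> TTestResult:
    """Independent-sample t-test from per-group mean/SD/n.

    ``method="welch"`` (default) uses the unequal-variance statistic with
    Welch-Satterthwaite degrees of freedom; ``"pooled"`` the classical
    equal-variance statistic with ``n1 + n2 - 2`` df.  The sign convention
    is group 1 minus group 2; the p-value is two-sided.

    Degenerate inputs: two zero-SD groups give t = 0, p = 1 when the means
    agree, and an infinite t with p = 0 when they differ.
    """
    if method not in ("welch", "pooled"):
        raise DomainError(f"method must be 'welch' or 'pooled', got {method!r}")
    d = g1.mean - g2.mean
    v1, v2 = g1.sd**2, g2.sd**2
    if v1 == 0.0 and v2 == 0.0:
        if d == 0.0:
            return TTestResult(t=0.0, df=float(g1.n + g2.n - 2), p=1.0, method=method)
        return TTestResult(t=float(np.sign(d)) * np.inf, df=float(g1.n + g2.n - 2),
                           p=0.0, method=method)
    if method == "welch":
        se2 = v1 / g1.n + v2 / g2.n
        df = se2**2 / ((v1 / g1.n) ** 2 / (g1.n - 1) + (v2 / g2.n) ** 2 / (g2.n - 1))
    else:
        sp2 = ((g1.n - 1) * v1 + (g2.n - 1) * v2) / (g1.n + g2.n - 2)
        se2 = sp2 * (1.0 / g1.n + 1.0 / g2.n)
        df = float(g1.n + g2.n - 2)
    t = d / np.sqrt(se2)
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(min(p, 1.0)), method=method)


def t_from_raw(values1, values2, method: str = "welch") -> TTestResult:
    """Independent-sample t-test from raw per-subject values.

    Computes each group's mean/SD (ddof = 1)/n and delegates to
    :func:`t_from_summary`, with which it agrees exactly.
    """
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    if v1.size < 2 or v2.size < 2:
        raise DomainError("each group needs at least two values")
    g1 = GroupSummary("group1", float(v1.mean()), float(v1.std(ddof=1)), v1.size)
    g2 = GroupSummary("group2", float(v2.mean()), float(v2.std(ddof=1)), v2.size)
    return t_from_summary(g1, g2, method=method)


def format_p(p: float) -> str:
    """Render a p-value the way the reference tables do: '<0.01' below 0.01."""
    return "<0.01" if p < 0.01 else f"{p:.2f}"


def load_reference_tables() -> pd.DataFrame:
    """The published per-site summary cells (Tables of the reference study).

    One row per site with each group's mean/SD/n, the printed t and p, and
    the table of origin ('covariates', 'IAS', 'EAS_PRM').
    """
    with resources.files("sonokr.data").joinpath("reference_tables.csv").open() as f:
        return pd.read_csv(f)


def compare_table(sites, method: str = "welch") -> pd.DataFrame:
    """Recompute the two-group comparison for a list of sites.

    ``sites`` is either an iterable of ``(label, GroupSummary, GroupSummary)``
    triples or a DataFrame as returned by :func:`load_reference_tables`.
    The report has one row per site with t, df, p and the alpha = 0.05
    significance flag.  When printed t values are available the report also
    carries ``consistent_with_printed``: False marks cells whose printed
    statistic is irreconcilable with their own printed mean/SD/n (absolute
    difference of |t| beyond ``PRINT_CONSISTENCY_TOL``); such cells are
    reported but should be excluded from any printed-value comparison.
    """
    rows = []
    if isinstance(sites, pd.DataFrame):
        has_printed = "printed_t" in sites.columns
        triples = [
            (
                r["site"],
                GroupSummary("group1", r["g1_mean"], r["g1_sd"], int(r["g1_n"])),
                GroupSummary("group2", r["g2_mean"], r["g2_sd"], int(r["g2_n"])),
                float(r["printed_t"]) if has_printed else np.nan,
            )
            for _, r in sites.iterrows()
        ]
    else:
        triples = [(label, g1, g2, np.nan) for label, g1, g2 in sites]
    for label, g1, g2, printed_t in triples:
        res = t_from_summary(g1, g2, method=method)
        row = {
            "site": label,
            "t": res.t,
            "df": res.df,
            "p": res.p,
            "p_printed_style": format_p(res.p),
            "significant": res.significant_at_0_05,
        }
        if np.isfinite(printed_t):
            row["printed_t"] = printed_t
            row["consistent_with_printed"] = (
                abs(abs(res.t) - abs(printed_t)) <= PRINT_CONSISTENCY_TOL
            )
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_two_group_study(site_effects, n1: int, n2: int, seed: int) -> dict:
    """Draw raw two-group measurement tables from per-site normal models.

    ``site_effects`` maps site label -> (mean1, sd1, mean2, sd2).  Returns
    ``{site: (values1, values2)}`` with ``values1`` of length ``n1`` etc.
    Reproducible for a fixed seed.
    """
    if n1 < 2 or n2 < 2:
        raise DomainError("each group needs n >= 2")
    rng = np.random.default_rng(seed)
    out = {}
    for site, (m1, s1, m2, s2) in site_effects.items():
        if s1 < 0 or s2 < 0:
            raise DomainError("standard deviations must be non-negative")
        out[site] = (rng.normal(m1, s1, n1), rng.normal(m2, s2, n2))
    return out
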