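"""Cohort-level statistics for the spectral parameters.

Implements Silver-Dunlap (Fisher-Z) correlation averaging, normality-gated
choice between parametric and rank tests, the Descriptive Data Analysis
multiple-testing control over contiguous electrode sets (Rüger areas), a
Fisher z-test for comparing independent correlations, and the H1-H7
hypothesis battery that exercises all of them on a per-subject/channel
parameter table.

A Rüger area is a connected set of electrodes with descriptively significant
(p < 0.05) results; the area is globally significant when at least 1/3 of its
members pass p <= 0.05/3 AND at least 1/2 pass p <= 0.05/2 (the conjunctive
reading of the two refined thresholds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .montage import ADJACENCY_EDGES, CHANNELS_18

RUEGER_P_DESCRIPTIVE = 0.05
RUEGER_P_THIRD = 0.05 / 3
RUEGER_P_HALF = 0.05 / 2


@dataclass
class ElectrodeAdjacency:
    """Symmetric scalp-neighborhood graph over electrode labels."""

    nodes: tuple[str, ...] = CHANNELS_18
    edges: tuple[tuple[str, str], ...] = ADJACENCY_EDGES

    def __post_init__(self) -> None:
        known = set(self.nodes)
        for a, b in self.edges:
            if a not in known or b not in known:
                raise ValueError(f"edge ({a}, {b}) references a node outside {known}")

    def components(self, subset: list[str]) -> list[list[str]]:
        """Connected components of the subgraph induced by ``subset``."""
        if not subset:
            return []
        idx = {ch: i for i, ch in enumerate(subset)}
        rows, cols = [], []
        for a, b in self.edges:
            if a in idx and b in idx:
                rows += [idx[a], idx[b]]
                cols += [idx[b], idx[a]]
        graph = csr_matrix((np.ones(len(rows)), (rows, cols)),
                           shape=(len(subset), len(subset)))
        n, labels = connected_components(graph, directed=False)
        return [[ch for ch in subset if labels[idx[ch]] == k] for k in range(n)]


DEFAULT_ADJACENCY = ElectrodeAdjacency()


def fisher_average(r_values, return_sd: bool = False):
    """Silver-Dunlap average of correlations: back-transformed mean Fisher Z.

    With ``return_sd`` the SD is also computed on the transformed scale and
    back-transformed.
    """
    r = np.asarray(r_values, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("all correlations must satisfy |r| < 1")
    z = np.arctanh(r)
    mean = float(np.tanh(z.mean()))
    if return_sd:
        return mean, float(np.tanh(z.std(ddof=1))) if r.size > 1 else float("nan")
    return mean


@dataclass
class RuegerResult:
    area_channels: tuple[str, ...]
    pvals: tuple[float, ...]
    n_p017: int
    n_p025: int
    significant: bool


def rueger_test(
    pvals: dict[str, float],
    adjacency: ElectrodeAdjacency = DEFAULT_ADJACENCY,
    conjunction: bool = True,
) -> list[RuegerResult]:
    """Score every Rüger area formed by descriptively significant channels.

    Channels with p < 0.05 are grouped into connected components of the scalp
    graph (singletons allowed); each area of size k is significant when at
    least ceil(k/3) members have p <= 0.05/3 and at least ceil(k/2) have
    p <= 0.05/2.  ``conjunction=False`` switches to the disjunctive reading
    (for sensitivity analysis only).
    """
    known = set(adjacency.nodes)
    for ch, p in pvals.items():
        if ch not in known:
            raise ValueError(f"channel {ch!r} absent from the adjacency graph")
        if not 0 <= p <= 1 and not math.isnan(p):
            raise ValueError(f"p-value for {ch} outside [0, 1]: {p}")
    descriptive = [ch for ch, p in pvals.items()
                   if not math.isnan(p) and p < RUEGER_P_DESCRIPTIVE]
    results = []
    for comp in adjacency.components(descriptive):
        ps = [pvals[ch] for ch in comp]
        k = len(comp)
        n_third = sum(p <= RUEGER_P_THIRD for p in ps)
        n_half = sum(p <= RUEGER_P_HALF for p in ps)
        ok_third = n_third >= math.ceil(k / 3)
        ok_half = n_half >= math.ceil(k / 2)
        sig = (ok_third and ok_half) if conjunction else (ok_third or ok_half)
        results.append(RuegerResult(
            area_channels=tuple(comp), pvals=tuple(ps),
            n_p017=n_third, n_p025=n_half, significant=sig,
        ))
    return results


@dataclass
class AssociationReport:
    test: str
    statistic: float
    p: float
    effect_size: float
    n: int
    gaussian: bool


def _shapiro_ok(x: np.ndarray, alpha: float = 0.05) -> bool:
    if np.ptp(x) < 1e-12:
        raise ValueError("constant input: distribution tests undefined")
    return stats.shapiro(x).pvalue > alpha


def gated_association(x, y, kind: str = "correlation") -> AssociationReport:
    """Normality-gated association test.

    ``kind='correlation'``: Shapiro-Wilk on both variables; Pearson if both
    Gaussian, Spearman otherwise.  ``kind='two-group'``: ``x`` are values,
    ``y`` binary group labels; independent-sample t-test if both groups
    Gaussian, Mann-Whitney U otherwise.  Effect sizes: r itself for
    correlations, eta² for group contrasts (t²/(t²+df), or z²/(n-1) for the
    rank test).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    m = ~(np.isnan(x) | pd.isna(y))
    x, y = x[m], y[m]
    if kind == "correlation":
        y = y.astype(float)
        if x.size < 5:
            raise ValueError(f"need n >= 5 per variable, got {x.size}")
        gaussian = _shapiro_ok(x) and _shapiro_ok(y)
        if gaussian:
            res = stats.pearsonr(x, y)
            name = "pearson"
        else:
            res = stats.spearmanr(x, y)
            name = "spearman"
        r = float(res.statistic)
        return AssociationReport(name, r, float(res.pvalue), r, x.size, gaussian)
    if kind != "two-group":
        raise ValueError("kind must be 'correlation' or 'two-group'")
    groups = pd.unique(y)
    if len(groups) != 2:
        raise ValueError(f"two-group test needs exactly 2 groups, got {len(groups)}")
    a, b = x[y == groups[0]], x[y == groups[1]]
    if min(a.size, b.size) < 5:
        raise ValueError("need n >= 5 per group")
    n = a.size + b.size
    gaussian = _shapiro_ok(a) and _shapiro_ok(b)
    if gaussian:
        res = stats.ttest_ind(a, b)
        t = float(res.statistic)
        eta2 = t * t / (t * t + n - 2)
        return AssociationReport("t-test", t, float(res.pvalue), eta2, n, True)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    p = float(res.pvalue)
    # z recovered from the two-sided p; eta² = z²/(n-1)
    z = float(stats.norm.isf(p / 2)) if p > 0 else float("inf")
    eta2 = z * z / (n - 1) if np.isfinite(z) else 1.0
    return AssociationReport("mann-whitney", float(res.statistic), p, eta2, n, False)


def compare_independent_correlations(r1: float, n1: int, r2: float, n2: int) -> float:
    """Two-sided Fisher z-test for the difference of independent correlations."""
    if n1 < 4 or n2 < 4:
        raise ValueError("need n >= 4 in both samples")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("correlations must satisfy |r| < 1")
    z = (np.arctanh(r1) - np.arctanh(r2)) / math.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    return float(2 * stats.norm.sf(abs(z)))


@dataclass
class HypothesisResult:
    name: str
    description: str
    per_channel: pd.DataFrame
    rueger: list[RuegerResult] = field(default_factory=list)

    @property
    def any_significant_area(self) -> bool:
        return any(r.significant for r in self.rueger)


def _channel_battery(table, channels, param, covariate, kind, adjacency):
    rows, pvals = [], {}
    for ch in channels:
        sub = table[table["channel"] == ch]
        x = sub[param].to_numpy(dtype=float)
        y = sub[covariate].to_numpy()
        try:
            rep = gated_association(x, y, kind=kind)
        except ValueError:
            continue
        rows.append({"channel": ch, "test": rep.test, "statistic": rep.statistic,
                     "p": rep.p, "effect_size": rep.effect_size, "n": rep.n})
        pvals[ch] = rep.p
    df = pd.DataFrame(rows)
    return df, rueger_test(pvals, adjacency) if pvals else []


def run_hypotheses(
    param_table: pd.DataFrame,
    covariates: pd.DataFrame,
    intercept_anchor: str = "lnC_2.5",
    adjacency: ElectrodeAdjacency = DEFAULT_ADJACENCY,
) -> dict[str, HypothesisResult]:
    """Run the H1-H7 battery of the parameter/covariate associations.

    H1 age-alpha, H2 age-peak amplitude, H3 age-peak frequency (per-channel
    gated correlations), H4 sex-intercept (two-group, plus a peak-amplitude
    companion expected null), H5 sex-peak frequency, H6 IQ-peak amplitude
    separately by sex, H7 age-alpha correlations compared between IQ groups
    with the Fisher z-test.  Every per-channel p-value map is followed by the
    Rüger-area control.
    """
    for col in ("age_years", "sex"):
        if col not in covariates.columns:
            raise ValueError(f"missing covariate column {col!r}")
        if covariates[col].isna().all():
            raise ValueError(f"covariate column {col!r} is empty")
    table = param_table.merge(covariates, on="subject_id")
    channels = [ch for ch in CHANNELS_18 if ch in set(table["channel"])]
    out: dict[str, HypothesisResult] = {}

    correlation_specs = [
        ("H1", "age vs spectral exponent alpha", "alpha", "age_years"),
        ("H2", "age vs whitened maximal peak amplitude", "lnPPeak", "age_years"),
        ("H3", "age vs maximal peak frequency", "f_maxPeak", "age_years"),
    ]
    for name, desc, param, cov in correlation_specs:
        df, rg = _channel_battery(table, channels, param, cov, "correlation",
                                  adjacency)
        out[name] = HypothesisResult(name, desc, df, rg)

    for name, desc, param in [
        ("H4", "sex difference in the slope-free intercept", intercept_anchor),
        ("H4_peak_amplitude", "sex difference in whitened peak amplitude "
                              "(expected null companion)", "lnPPeak"),
        ("H5", "sex difference in maximal peak frequency", "f_maxPeak"),
    ]:
        df, rg = _channel_battery(table, channels, param, "sex", "two-group",
                                  adjacency)
        out[name] = HypothesisResult(name, desc, df, rg)

    if "iq_score" in covariates.columns and covariates["iq_score"].notna().any():
        for sex_label in pd.unique(table["sex"]):
            sub = table[table["sex"] == sex_label]
            df, rg = _channel_battery(sub, channels, "lnPPeak", "iq_score",
                                      "correlation", adjacency)
            out[f"H6_{sex_label}"] = HypothesisResult(
                f"H6_{sex_label}",
                f"IQ vs whitened peak amplitude in group {sex_label}", df, rg)

    if "iq_group" in covariates.columns and covariates["iq_group"].notna().any():
        rows = []
        for ch in channels:
            per_group = {}
            for grp in pd.unique(table["iq_group"].dropna()):
                sub = table[(table["channel"] == ch) & (table["iq_group"] == grp)]
                x = sub["age_years"].to_numpy(dtype=float)
                y = sub["alpha"].to_numpy(dtype=float)
                m = ~(np.isnan(x) | np.isnan(y))
                if m.sum() >= 5:
                    rep = gated_association(x[m], y[m], kind="correlation")
                    per_group[grp] = (rep.statistic, rep.p, int(m.sum()))
            if len(per_group) == 2:
                (g1, (r1, p1, n1)), (g2, (r2, p2, n2)) = sorted(per_group.items())
                rows.append({
                    "channel": ch,
                    f"r_{g1}": r1, f"p_{g1}": p1, f"n_{g1}": n1,
                    f"r_{g2}": r2, f"p_{g2}": p2, f"n_{g2}": n2,
                    "p_difference": compare_independent_correlations(r1, n1, r2, n2),
                })
        df = pd.DataFrame(rows)
        rg = []
        if len(df):
            rg = rueger_test(dict(zip(df["channel"], df["p_difference"])), adjacency)
        out["H7"] = HypothesisResult(
            "H7", "difference of age-alpha correlations between IQ groups", df, rg)
    return out
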