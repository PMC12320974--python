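"""Nonparametric statistics for the paired BTP/ATP study design.

Within each strain x treatment cell the paired before/after-pacing endpoint
values are compared with the Wilcoxon signed-rank test; between-strain
contrasts use the Kruskal-Wallis rank test.  Group summaries report mean and
s.e.m., and significance stars follow the 0.05 / 0.01 / 0.001 / 0.0001
thresholds.

Wilcoxon p values are exact (full tie-aware enumeration of all 2^n sign
assignments) up to n = 12 nonzero pairs, and use the continuity- and
tie-corrected normal approximation above that; the result records which path
ran.  Zero differences are dropped by default (classic Wilcoxon); the Pratt
convention, which ranks zeros and then discards them, is available.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

from .exceptions import DegenerateDataError

__all__ = [
    "StatResult",
    "GroupSummary",
    "wilcoxon_signed_rank",
    "kruskal_wallis",
    "summarize_groups",
    "run_study_comparisons",
    "significance_stars",
]

logger = logging.getLogger(__name__)

_STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))

EXACT_CUTOFF = 16  # largest n for full 2^n sign enumeration (covers n=15 cells)


def significance_stars(p: float) -> str:
    """Stars per the study's legend: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    for threshold, stars in _STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


@dataclass
class StatResult:
    """Outcome of one hypothesis test."""

    test: str
    statistic: float
    p: float
    n: int
    method: str
    group_ns: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p value {self.p} outside [0, 1]")

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


@dataclass
class GroupSummary:
    """Per-group mean and s.e.m. (sample SD / sqrt(n); undefined for n = 1)."""

    label: str
    n: int
    mean: float
    sem: float = field(default=np.nan)

    @property
    def sem_defined(self) -> bool:
        return np.isfinite(self.sem)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _signed_ranks(d: np.ndarray, zero_method: str) -> np.ndarray:
    """Midranks of |d| for the retained differences, per zero convention."""
    if zero_method == "wilcox":
        d = d[d != 0]
        ranks = rankdata(np.abs(d))
    elif zero_method == "pratt":
        ranks = rankdata(np.abs(d))
        ranks = ranks[d != 0]
        d = d[d != 0]
    else:
        raise ValueError("zero_method must be 'wilcox' or 'pratt'")
    return np.where(d > 0, ranks, -ranks)


@lru_cache(maxsize=8)
def _sign_matrix(n: int) -> np.ndarray:
    """All 2^n binary sign vectors as a (2^n, n) float32 matrix."""
    return (((np.arange(2**n, dtype=np.uint32)[:, None] >> np.arange(n)) & 1)
            .astype(np.float32))


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Tie-aware exact two-sided p over all 2^n equiprobable sign vectors.

    The null distribution of W+ is symmetric about sum(ranks)/2 regardless of
    ties, so the two-sided p is P(|W - mu| >= |w_obs - mu|).
    """
    n = ranks.size
    dist = _sign_matrix(n) @ ranks.astype(np.float32)
    mu = ranks.sum() / 2.0
    return float(np.mean(np.abs(dist - mu) >= abs(w_plus - mu) - 1e-9))


def _approx_two_sided_p(signed: np.ndarray, w_plus: float) -> float:
    """Normal approximation with continuity and tie corrections."""
    n = signed.size
    ranks = np.abs(signed)
    mu = n * (n + 1) / 4.0
    tie_counts = np.unique(ranks, return_counts=True)[1]
    tie_term = np.sum(tie_counts**3 - tie_counts) / 2.0
    var = (n * (n + 1) * (2 * n + 1) - tie_term) / 24.0
    if var <= 0:
        raise DegenerateDataError("zero variance in signed-rank statistic")
    diff = w_plus - mu
    # continuity correction shifts the statistic half a unit towards the mean
    diff -= 0.5 * np.sign(diff)
    z = diff / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def wilcoxon_signed_rank(
    x, y, *, zero_method: str = "wilcox", exact_cutoff: int = EXACT_CUTOFF
) -> StatResult:
    """Two-sided paired Wilcoxon signed-rank test of ``y - x``.

    Exact tie-aware enumeration for up to ``exact_cutoff`` nonzero pairs,
    continuity/tie-corrected normal approximation above.  All-zero
    differences raise :class:`DegenerateDataError`.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    d = y - x
    if np.all(d == 0):
        raise DegenerateDataError("no nonzero pairs: all differences are zero")
    signed = _signed_ranks(d, zero_method)
    n = signed.size
    if n < 2:
        raise DegenerateDataError(f"only {n} nonzero pair(s); need at least 2")
    w_plus = float(signed[signed > 0].sum())
    if n <= exact_cutoff:
        p = _exact_two_sided_p(np.abs(signed), w_plus)
        method = f"exact enumeration (2^{n} sign vectors, zero_method={zero_method})"
    else:
        p = _approx_two_sided_p(signed, w_plus)
        method = f"normal approximation, continuity + tie corrected (zero_method={zero_method})"
    return StatResult(
        test="wilcoxon_signed_rank", statistic=w_plus, p=p, n=n, method=method
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis


def kruskal_wallis(*groups) -> StatResult:
    """Kruskal-Wallis rank test across two or more samples.

    H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2, computed on pooled
    midranks and divided by the tie-correction factor
    1 - sum(t^3 - t)/(N^3 - N); p from chi-square with k-1 df.
    """
    groups = [np.asarray(g, float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("every group needs at least one value")
    pooled = np.concatenate(groups)
    n_total = pooled.size
    if n_total < 3:
        raise ValueError("need at least 3 values in total")
    if np.all(pooled == pooled[0]):
        raise DegenerateDataError("no variation: all values identical")

    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r_mean = ranks[start : start + g.size].mean()
        h += g.size * (r_mean - (n_total + 1) / 2.0) ** 2
        start += g.size
    h *= 12.0 / (n_total * (n_total + 1))

    tie_counts = np.unique(pooled, return_counts=True)[1]
    correction = 1.0 - np.sum(tie_counts**3 - tie_counts) / (n_total**3 - n_total)
    if correction <= 0:
        raise DegenerateDataError("tie correction degenerate")
    h /= correction

    df = len(groups) - 1
    p = float(chi2.sf(h, df))
    return StatResult(
        test="kruskal_wallis",
        statistic=float(h),
        p=p,
        n=n_total,
        method=f"chi-square approximation, {df} df, tie corrected",
        group_ns=tuple(g.size for g in groups),
    )


# ---------------------------------------------------------------------------
# summaries and the full study comparison


def summarize_groups(table: pd.DataFrame, value: str, by) -> list[GroupSummary]:
    """Mean and s.e.m. of ``value`` per group defined by column(s) ``by``."""
    summaries = []
    for label, g in table.groupby(by, sort=False):
        vals = g[value].dropna().to_numpy(float)
        if vals.size == 0:
            raise DegenerateDataError(f"group {label!r} has no values for {value!r}")
        sem = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan
        if vals.size == 1:
            logger.warning("group %r has a single value; s.e.m. undefined", label)
        lab = label if isinstance(label, str) else "/".join(map(str, np.atleast_1d(label)))
        summaries.append(GroupSummary(label=lab, n=vals.size, mean=float(vals.mean()), sem=sem))
    return summaries


_ENDPOINTS = {"hr_bpm": "HR", "ai_au": "AI", "fs_pct": "FS"}
# contractile dysfunction: significant reduction in HR, increase in AI,
# or reduction in FS
_DYSFUNCTION_SIGN = {"hr_bpm": -1.0, "ai_au": +1.0, "fs_pct": -1.0}


def _paired_table(metrics: pd.DataFrame) -> pd.DataFrame:
    """Pivot long metrics to one row per animal with BTP/ATP columns."""
    required = {"animal_id", "strain", "treatment", "condition"}
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table missing columns {sorted(missing)}")
    wide = metrics.pivot_table(
        index=["animal_id", "strain", "treatment"],
        columns="condition",
        values=list(_ENDPOINTS),
        aggfunc="first",
    )
    complete = wide.dropna()
    dropped = wide.index.difference(complete.index)
    for animal in dropped.get_level_values("animal_id"):
        logger.warning("animal %s missing a BTP or ATP recording; excluded from pairing", animal)
    return complete.reset_index()


def run_study_comparisons(
    metrics: pd.DataFrame,
    *,
    alpha: float = 0.05,
    pairwise: bool = True,
    holm: bool = False,
) -> dict[str, pd.DataFrame]:
    """Run the study's statistical layer on a long metrics table.

    Input columns: animal_id, strain, treatment, condition (BTP/ATP),
    hr_bpm, ai_au, fs_pct.  Returns a dict of tables:

    ``paired``
        Per (strain, treatment, endpoint): Wilcoxon signed-rank of ATP vs
        BTP, the mean paired delta, stars, and the contractile-dysfunction
        flag (p < alpha with the deleterious direction: HR down, AI up, FS
        down).
    ``between``
        Per (treatment, condition, endpoint): Kruskal-Wallis omnibus across
        strains (skipped with a log note when only one strain is present).
    ``pairwise`` (optional)
        All two-strain rank tests within (treatment, condition, endpoint),
        uncorrected by default and flagged as such; Holm-adjusted p when
        ``holm=True``.
    """
    paired = _paired_table(metrics)
    rows = []
    for (strain, treatment), g in paired.groupby(["strain", "treatment"], sort=False):
        for col, name in _ENDPOINTS.items():
            btp = g[(col, "BTP")].to_numpy(float)
            atp = g[(col, "ATP")].to_numpy(float)
            try:
                res = wilcoxon_signed_rank(btp, atp)
            except DegenerateDataError as e:
                logger.warning("%s/%s %s: %s", strain, treatment, name, e)
                continue
            delta = float(np.mean(atp - btp))
            dysfunctional = res.p < alpha and np.sign(delta) == _DYSFUNCTION_SIGN[col]
            rows.append(
                {
                    "strain": strain,
                    "treatment": treatment,
                    "endpoint": name,
                    "test": res.test,
                    "statistic": res.statistic,
                    "p": res.p,
                    "stars": res.stars,
                    "n_pairs": res.n,
                    "mean_delta": delta,
                    "dysfunction": bool(dysfunctional),
                    "method": res.method,
                }
            )
    paired_df = pd.DataFrame(rows)

    between_rows, pairwise_rows = [], []
    long = metrics.dropna(subset=list(_ENDPOINTS))
    for (treatment, condition), g in long.groupby(["treatment", "condition"], sort=False):
        strains = list(g["strain"].unique())
        if len(strains) < 2:
            logger.info(
                "treatment %s condition %s: single strain, Kruskal-Wallis skipped", treatment, condition
            )
            continue
        for col, name in _ENDPOINTS.items():
            samples = [g.loc[g["strain"] == s, col].to_numpy(float) for s in strains]
            try:
                res = kruskal_wallis(*samples)
            except DegenerateDataError as e:
                logger.warning("%s/%s %s: %s", treatment, condition, name, e)
                continue
            between_rows.append(
                {
                    "treatment": treatment,
                    "condition": condition,
                    "endpoint": name,
                    "test": res.test,
                    "statistic": res.statistic,
                    "p": res.p,
                    "stars": res.stars,
                    "strains": ",".join(strains),
                    "n": res.n,
                }
            )
            if pairwise:
                for sa, sb in itertools.combinations(strains, 2):
                    a = g.loc[g["strain"] == sa, col].to_numpy(float)
                    b = g.loc[g["strain"] == sb, col].to_numpy(float)
                    try:
                        r2 = kruskal_wallis(a, b)
                    except DegenerateDataError:
                        continue
                    pairwise_rows.append(
                        {
                            "treatment": treatment,
                            "condition": condition,
                            "endpoint": name,
                            "strain_a": sa,
                            "strain_b": sb,
                            "statistic": r2.statistic,
                            "p": r2.p,
                        }
                    )

    out = {"paired": paired_df, "between": pd.DataFrame(between_rows)}
    if pairwise:
        pw = pd.DataFrame(pairwise_rows)
        if not pw.empty:
            if holm:
                pw["p_adj"] = _holm(pw["p"].to_numpy())
                pw["correction"] = "holm"
            else:
                pw["p_adj"] = pw["p"]
                pw["correction"] = "none (uncorrected)"
            pw["stars"] = [significance_stars(p) for p in pw["p_adj"]]
        out["pairwise"] = pw
    return out


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p values."""
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
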