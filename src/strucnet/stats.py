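"""Group-comparison and reproducibility statistics for connectome cohorts.

Procedures implemented here, on top of the cohort container of
:mod:`strucnet.synthetic`:

* pooled-variance (Student's) two-sample t-tests — whole-brain metrics are
  compared with Bonferroni control over the family of six measures, while
  the mass-univariate node (strength) and edge (FA) screens use
  Benjamini-Hochberg FDR within their own family;
* Pearson correlation screens of nodal strength and edge FA against
  cognitive z-scores, computed over the patient group only (healthy
  volunteers are not cognitively tested), FDR within each family and score;
* ICC(2,1): two-way random-effects, absolute-agreement, single-measure
  intraclass correlation for test-retest agreement of connectivity
  matrices, computed on the upper-triangle edges that are nonzero in at
  least one session (all-zero items carry no agreement information);
* the attentional-executive composite ``zAttention`` as the mean of the
  zPASAT and zSDMT test z-scores.

Edge-wise tests cover all ``n (n - 1) / 2`` possible connections with absent
edges contributing weight 0; a minimum-presence filter is available behind
``min_presence`` but off by default, because reported edge fractions refer to
the full connection count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .connectome import ConnectivityMatrix
from .metrics import GLOBAL_METRIC_NAMES, global_metrics
from .synthetic import Cohort

__all__ = [
    "ICCResult",
    "zattention",
    "two_sample_t",
    "bonferroni_alpha",
    "bh_fdr",
    "pearson_r",
    "icc_absolute_agreement",
    "icc_matrices",
    "compare_global_metrics",
    "compare_nodes",
    "compare_edges",
    "correlate_with_cognition",
]

STAT_TABLE_COLUMNS = ["element", "statistic", "p", "q", "direction", "significant"]


class DegenerateInputError(ValueError):
    """The statistic is undefined on this input (zero variance, etc.)."""


@dataclass
class ICCResult:
    """Intraclass correlation estimate with its variant recorded."""

    estimate: float
    variant: str = "two-way absolute agreement, single measure"
    n_items: int = 0


def zattention(zpasat: float, zsdmt: float) -> float:
    """Attentional-executive composite: mean of the two test z-scores."""
    if not (np.isfinite(zpasat) and np.isfinite(zsdmt)):
        raise ValueError("both z-scores must be finite")
    return (zpasat + zsdmt) / 2.0


def two_sample_t(x, y) -> tuple[float, float]:
    """Two-sided Student's (pooled-variance) t-test.

    Zero pooled variance with equal means yields ``(0, 1)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
        return 0.0, 1.0
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def bonferroni_alpha(alpha: float, m: int, decimals: int | None = None) -> float:
    """Per-comparison threshold ``alpha / m`` for a family of ``m`` tests.

    ``decimals`` rounds for reporting (0.05 over six whole-brain metrics is
    conventionally printed as 0.008).
    """
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    out = alpha / m
    return round(out, decimals) if decimals is not None else out


def bh_fdr(p_values, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted p-values and rejection flags.

    Adjusted values are ``min over j >= i of p_(j) m / j`` (capped at 1) in
    the original input order; rejection iff adjusted <= ``q_level``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return p_adj, p_adj <= q_level


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("samples must have equal length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# --------------------------------------------------------------------------
# ICC

def icc_absolute_agreement(session1, session2) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    With ``n`` items (edges) and ``k = 2`` sessions,

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    where MSR, MSC and MSE are the item (row), session (column) and error
    mean squares of the two-way layout.  Systematic between-session shifts
    lower the estimate: absolute agreement, not consistency.
    """
    x = np.asarray(session1, dtype=float)
    y = np.asarray(session2, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("sessions must be equal-length vectors of >= 2 items")
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    if np.allclose(data, grand):
        raise DegenerateInputError("zero total variance: ICC undefined")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise DegenerateInputError("degenerate ANOVA layout: ICC undefined")
    return ICCResult(estimate=float((msr - mse) / denom), n_items=n)


def icc_matrices(
    a: ConnectivityMatrix, b: ConnectivityMatrix
) -> ICCResult:
    """Test-retest ICC of two connectivity matrices.

    Items are the upper-triangle edges nonzero in at least one session.
    """
    if a.node_labels != b.node_labels or a.n != b.n:
        raise ValueError("matrices must share the node set")
    va, vb = a.upper_triangle(), b.upper_triangle()
    keep = (va > 0) | (vb > 0)
    if keep.sum() < 2:
        raise DegenerateInputError("fewer than 2 nonzero edges")
    return icc_absolute_agreement(va[keep], vb[keep])


# --------------------------------------------------------------------------
# Vectorized mass-univariate screens

def _vectorized_pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise pooled-variance t and two-sided p for (n, m) samples.

    Columns with zero pooled variance give t = 0, p = 1 when the means agree
    and t = +/-inf, p = 0 when they differ.
    """
    n1, n2 = x.shape[0], y.shape[0]
    m1, m2 = x.mean(axis=0), y.mean(axis=0)
    v1 = x.var(axis=0, ddof=1)
    v2 = y.var(axis=0, ddof=1)
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
        t = np.where(se == 0, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    p = np.where(
        np.isinf(t), 0.0, 2.0 * sps.t.sf(np.abs(np.where(np.isinf(t), 0, t)), df)
    )
    p = np.where((se == 0) & (diff == 0), 1.0, p)
    return t, p


def _vectorized_pearson(scores: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise Pearson r of ``values`` (n, m) against ``scores`` (n,).

    Zero-variance columns yield r = NaN, p = 1 (never significant).
    """
    n = scores.size
    xc = scores - scores.mean()
    yc = values - values.mean(axis=0)
    sx = np.sqrt((xc ** 2).sum())
    sy = np.sqrt((yc ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / (sx * sy)
    r = np.where(sy == 0, np.nan, np.clip(r, -1.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = np.where(
        np.isnan(r), 1.0,
        np.where(np.abs(r) >= 1.0, 0.0, 2.0 * sps.t.sf(np.abs(t), n - 2)),
    )
    return r, p


def _stat_table(
    elements, statistic: np.ndarray, p: np.ndarray, q_level: float
) -> pd.DataFrame:
    p_for_fdr = np.where(np.isnan(statistic), 1.0, p)
    q, reject = bh_fdr(p_for_fdr, q_level)
    return pd.DataFrame({
        "element": elements,
        "statistic": statistic,
        "p": p,
        "q": q,
        "direction": np.sign(np.nan_to_num(statistic)).astype(int),
        "significant": reject,
    })


def _require_groups(cohort: Cohort) -> tuple[list, list]:
    hv, ms = cohort.group("HV"), cohort.group("MS")
    if len(hv) < 2 or len(ms) < 2:
        raise ValueError("both groups need at least 2 subjects")
    return hv, ms


def compare_global_metrics(cohort: Cohort, alpha: float = 0.05) -> pd.DataFrame:
    """Whole-brain metric comparison, MS vs HV, Bonferroni over six tests.

    ``statistic`` is the t for MS minus HV, so decreases in patients carry a
    negative direction.  Subjects whose assortativity is undefined are
    dropped from that metric's test.
    """
    hv, ms = _require_groups(cohort)
    records = {
        "HV": [global_metrics(s.matrix).as_dict() for s in hv],
        "MS": [global_metrics(s.matrix).as_dict() for s in ms],
    }
    threshold = bonferroni_alpha(alpha, len(GLOBAL_METRIC_NAMES))
    rows = []
    for name in GLOBAL_METRIC_NAMES:
        a = np.array([r[name] for r in records["MS"]], dtype=float)
        b = np.array([r[name] for r in records["HV"]], dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if a.size < 2 or b.size < 2:
            t, p = np.nan, np.nan
        else:
            t, p = two_sample_t(a, b)
        rows.append({
            "element": name,
            "statistic": t,
            "p": p,
            "q": np.nan,  # Bonferroni family: threshold-based, no adjusted p
            "direction": int(np.sign(np.nan_to_num(t))),
            "significant": bool(np.isfinite(p) and p < threshold),
        })
    table = pd.DataFrame(rows)
    table.attrs["bonferroni_threshold"] = threshold
    return table


def compare_nodes(cohort: Cohort, q_level: float = 0.05) -> pd.DataFrame:
    """Node-wise strength comparison (MS vs HV) with FDR over all nodes."""
    _require_groups(cohort)
    x = cohort.strength_array("MS")
    y = cohort.strength_array("HV")
    t, p = _vectorized_pooled_t(x, y)
    return _stat_table(np.arange(cohort.n_nodes), t, p, q_level)


def _edge_elements(n: int) -> list[tuple[int, int]]:
    iu = np.triu_indices(n, k=1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))


def compare_edges(
    cohort: Cohort, q_level: float = 0.05, min_presence: float = 0.0
) -> pd.DataFrame:
    """Edge-wise FA comparison (MS vs HV) with FDR over all possible pairs.

    Absent edges contribute weight 0.  ``min_presence`` (fraction of
    subjects in which an edge must be nonzero) restricts the tested family;
    the default 0 tests all ``n (n - 1) / 2`` connections.
    """
    _require_groups(cohort)
    x = cohort.edge_array("MS")
    y = cohort.edge_array("HV")
    elements = np.array(_edge_elements(cohort.n_nodes), dtype=object)
    if min_presence > 0:
        presence = (np.vstack([x, y]) > 0).mean(axis=0)
        keep = presence >= min_presence
        x, y = x[:, keep], y[:, keep]
        elements = elements[keep]
    t, p = _vectorized_pooled_t(x, y)
    return _stat_table([tuple(e) for e in elements], t, p, q_level)


def correlate_with_cognition(
    cohort: Cohort, score: str = "zAttention", q_level: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson screens of nodal strength and edge FA against a cognitive score.

    Computed over MS subjects carrying the score (healthy volunteers are not
    tested); FDR is applied separately within the node and edge families.
    Returns ``(node_table, edge_table)``.
    """
    attr = {"zPASAT": "zpasat", "zSDMT": "zsdmt", "zAttention": "zattention"}
    if score not in attr:
        raise ValueError(f"unknown score {score!r}; expected one of {list(attr)}")
    ms = [s for s in cohort.group("MS") if getattr(s, attr[score]) is not None]
    if len(ms) < 3:
        raise ValueError(f"need >= 3 MS subjects with {score}")
    scores = np.array([getattr(s, attr[score]) for s in ms], dtype=float)
    if scores.std() == 0:
        raise DegenerateInputError(f"{score} is constant across subjects")
    sub = Cohort(ms)
    strengths = sub.strength_array()
    edges = sub.edge_array()
    r_n, p_n = _vectorized_pearson(scores, strengths)
    r_e, p_e = _vectorized_pearson(scores, edges)
    node_table = _stat_table(np.arange(cohort.n_nodes), r_n, p_n, q_level)
    edge_table = _stat_table(_edge_elements(cohort.n_nodes), r_e, p_e, q_level)
    return node_table, edge_table
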