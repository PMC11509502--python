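"""Per-protein paired differential expression and min-rank aggregation.

Three tests are run per protein on the paired intensity vectors (missing
values enter as 0): a paired t-test, a Wilcoxon signed-rank test with zeros
dropped, and the two-proportion appearance test.  P-values are BH-corrected
within each test family, each family is ranked by ascending p, and the
per-protein minimum of the three ranks drives the final ranked list.

Undefined test outcomes (zero-variance differences, too few nonzero
differences) are marked NaN: they are excluded from BH's m and receive the
maximal rank, so the ranked list stays total without fabricating
significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from proteopair.appearance import binarize, condition_presence_counts, proportion_z_test
from proteopair.io import IntensityMatrix, PairedDesign

__all__ = [
    "DifferentialResultTable",
    "RESULT_COLUMNS",
    "paired_t_test",
    "wilcoxon_signed_rank",
    "benjamini_hochberg",
    "run_differential_expression",
    "min_rank_list",
    "volcano_table",
]

RESULT_COLUMNS = [
    "protein_id",
    "effect",
    "t_stat",
    "t_p",
    "q_t",
    "w_stat",
    "w_p",
    "q_w",
    "prop_p",
    "q_prop",
    "rank_t",
    "rank_w",
    "rank_prop",
    "min_rank",
]

#: Maximum number of nonzero differences for exact Wilcoxon enumeration.
EXACT_WILCOXON_LIMIT = 12


@dataclass
class DifferentialResultTable:
    """Per-protein test statistics, BH q-values, ranks and min-rank."""

    table: pd.DataFrame  # columns RESULT_COLUMNS, one row per protein

    @property
    def n_proteins(self) -> int:
        return len(self.table)

    def protein_ids(self) -> list[str]:
        return self.table["protein_id"].tolist()


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Paired Student t-test on differences d = x - y.

    Returns (t, p) with a two-sided p from the t distribution with n-1
    degrees of freedom.  Zero-variance differences give (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    n = len(x)
    if n < 2:
        raise ValueError("paired t-test requires n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        return (math.nan, math.nan)
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return (float(t), float(min(p, 1.0)))


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float], min_nonzero: int = 3
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired differences, zeros dropped.

    Returns (W, p) where W is the positive-rank sum.  Two-sided p is exact
    (full sign-pattern enumeration) when the nonzero-difference count is at
    most `EXACT_WILCOXON_LIMIT` and the absolute differences are tie-free;
    otherwise a normal approximation with tie correction is used.  Fewer
    than `min_nonzero` nonzero differences gives (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    d = x - y
    d = d[d != 0]
    m = len(d)
    if m < min_nonzero:
        return (math.nan, math.nan)
    ranks = stats.rankdata(np.abs(d))  # average ranks for ties
    w = float(ranks[d > 0].sum())
    mu = m * (m + 1) / 4.0
    has_ties = len(np.unique(np.abs(d))) < m
    if m <= EXACT_WILCOXON_LIMIT and not has_ties:
        # Exact null: all 2^m sign assignments equally likely; two-sided p
        # counts assignments at least as far from the null mean as observed.
        masks = (np.arange(2**m)[:, None] >> np.arange(m)) & 1
        w_all = masks @ ranks
        p = float(np.mean(np.abs(w_all - mu) >= np.abs(w - mu) - 1e-12))
        return (w, p)
    tie_counts = np.unique(ranks, return_counts=True)[1]
    var = m * (m + 1) * (2 * m + 1) / 24.0 - float(((tie_counts**3 - tie_counts) / 48.0).sum())
    if var <= 0:
        return (w, 1.0)
    z = (w - mu) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return (w, float(min(p, 1.0)))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are treated as undefined: excluded from the test count m
    and returned as NaN.  Values outside [0, 1] raise.
    """
    p = np.asarray(p_values, dtype=float)
    defined = ~np.isnan(p)
    if ((p[defined] < 0) | (p[defined] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, math.nan)
    m = int(defined.sum())
    if m == 0:
        return q
    idx = np.flatnonzero(defined)
    order = idx[np.argsort(p[idx], kind="stable")]
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    q[order] = np.minimum(adj, 1.0)
    return q


def _ranks_ascending_p(p: np.ndarray, protein_ids: Sequence[str]) -> np.ndarray:
    """Ordinal ranks 1..n_defined by ascending p, ties broken by protein id.

    Undefined (NaN) p-values all get the maximal rank n_proteins.
    """
    n = len(p)
    ranks = np.full(n, n, dtype=int)
    defined = np.flatnonzero(~np.isnan(p))
    order = sorted(defined, key=lambda i: (p[i], protein_ids[i]))
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    return ranks


def run_differential_expression(
    m: IntensityMatrix,
    d: PairedDesign,
    transform: str = "raw",
    min_nonzero: int = 3,
) -> DifferentialResultTable:
    """Run all three paired tests per protein and aggregate ranks.

    Parameters
    ----------
    m, d
        Intensity matrix and paired design; design samples must all be
        matrix columns.
    transform
        "raw" (default, mirrors feeding label-free intensities directly) or
        "log2p1" (log2(x + 1) before the t and Wilcoxon tests).
    min_nonzero
        Minimum nonzero paired differences for a defined Wilcoxon p.
    """
    if transform not in ("raw", "log2p1"):
        raise ValueError(f"unknown transform {transform!r}")
    col = {s: j for j, s in enumerate(m.sample_ids)}
    missing = [s for s in d.all_samples() if s not in col]
    if missing:
        raise ValueError(f"design samples absent from matrix: {missing}")
    idx_a = [col[s] for s in d.samples_for(d.condition_a)]
    idx_b = [col[s] for s in d.samples_for(d.condition_b)]
    xa = m.values[:, idx_a]
    xb = m.values[:, idx_b]
    if transform == "log2p1":
        xa = np.log2(xa + 1.0)
        xb = np.log2(xb + 1.0)

    k_a, k_b = condition_presence_counts(binarize(m), d)
    n = d.n_subjects

    rows = []
    for i, pid in enumerate(m.protein_ids):
        t_stat, t_p = paired_t_test(xa[i], xb[i])
        w_stat, w_p = wilcoxon_signed_rank(xa[i], xb[i], min_nonzero=min_nonzero)
        if k_a[i] == 0 and k_b[i] == 0:
            prop_p = math.nan  # protein never observed: nothing to test
        else:
            prop_p = proportion_z_test(int(k_a[i]), n, int(k_b[i]), n).p_value
        rows.append(
            {
                "protein_id": pid,
                "effect": float(np.median(xa[i] - xb[i])),
                "t_stat": t_stat,
                "t_p": t_p,
                "w_stat": w_stat,
                "w_p": w_p,
                "prop_p": prop_p,
            }
        )
    df = pd.DataFrame(rows)
    df["q_t"] = benjamini_hochberg(df["t_p"].to_numpy())
    df["q_w"] = benjamini_hochberg(df["w_p"].to_numpy())
    df["q_prop"] = benjamini_hochberg(df["prop_p"].to_numpy())
    pids = df["protein_id"].tolist()
    df["rank_t"] = _ranks_ascending_p(df["t_p"].to_numpy(), pids)
    df["rank_w"] = _ranks_ascending_p(df["w_p"].to_numpy(), pids)
    df["rank_prop"] = _ranks_ascending_p(df["prop_p"].to_numpy(), pids)
    df["min_rank"] = df[["rank_t", "rank_w", "rank_prop"]].min(axis=1)
    return DifferentialResultTable(table=df[RESULT_COLUMNS].copy())


def min_rank_list(t: DifferentialResultTable) -> list[str]:
    """Ranked protein list: ascending min_rank, ties by prop_p then id."""
    df = t.table
    keys = sorted(
        range(len(df)),
        key=lambda i: (
            df["min_rank"].iat[i],
            df["prop_p"].iat[i] if not math.isnan(df["prop_p"].iat[i]) else math.inf,
            df["protein_id"].iat[i],
        ),
    )
    return [df["protein_id"].iat[i] for i in keys]


def volcano_table(t: DifferentialResultTable, test: str = "wilcoxon") -> pd.DataFrame:
    """(effect, -log10 p) pairs for plotting; undefined p omitted."""
    pcol = {"wilcoxon": "w_p", "t": "t_p", "proportion": "prop_p"}.get(test)
    if pcol is None:
        raise ValueError(f"unknown test {test!r}")
    df = t.table[["protein_id", "effect", pcol]].dropna(subset=[pcol]).copy()
    with np.errstate(divide="ignore"):
        df["neg_log10_p"] = -np.log10(df[pcol])
    return df[["protein_id", "effect", "neg_log10_p"]].reset_index(drop=True)
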