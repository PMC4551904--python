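"""Reference association tests: mean-table Pearson/Fisher, CMH, and BH.

These are the single-test methods the ranked chi-square approach is compared
against.  Pearson and Fisher cannot use replicate information, so they are
applied to the 2x2 table of replicate means; CMH stratifies over paired
replicates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import RaxError
from .core import TwoByTwoSeries, pearson_chi2


def mean_table_pvalues(series: TwoByTwoSeries, method: str = "pearson",
                       rounding: str = "round") -> float:
    """P-value of the mean-count 2x2 table.

    ``pearson``: upper tail of chi-square(1 df) at the closed-form statistic.
    ``fisher``: two-sided exact test on the mean table rounded (or floored)
    to integers.  A zero grand total yields p = 1 with a warning.
    """
    mean = series.cells.mean(axis=2)
    if mean.sum() <= 0:
        warnings.warn(f"zero grand total for tag {series.tag_id!r}; p = 1")
        return 1.0
    if method == "pearson":
        stat = pearson_chi2(mean)
        return float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    if method == "fisher":
        if rounding == "round":
            tab = np.rint(mean).astype(int)
        elif rounding == "floor":
            tab = np.floor(mean).astype(int)
        else:
            raise RaxError(f"unknown rounding {rounding!r} (round or floor)")
        if tab.sum() <= 0:
            warnings.warn(f"zero rounded total for tag {series.tag_id!r}; p = 1")
            return 1.0
        return float(stats.fisher_exact(tab, alternative="two-sided")[1])
    raise RaxError(f"unknown method {method!r} (pearson or fisher)")


def cmh_statistic(strata: np.ndarray) -> tuple[float, float, float]:
    """CMH components over ``(k, 2, 2)`` strata: (numerator term, variance
    sum, statistic).  No continuity correction; degenerate strata (zero
    variance) contribute nothing."""
    strata = np.asarray(strata, dtype=float)
    n11 = strata[:, 0, 0]
    r1 = strata[:, 0, :].sum(axis=1)
    r2 = strata[:, 1, :].sum(axis=1)
    c1 = strata[:, :, 0].sum(axis=1)
    c2 = strata[:, :, 1].sum(axis=1)
    n = r1 + r2
    ok = n > 1
    e11 = np.zeros_like(n11)
    var = np.zeros_like(n11)
    e11[ok] = r1[ok] * c1[ok] / n[ok]
    var[ok] = r1[ok] * r2[ok] * c1[ok] * c2[ok] / (n[ok] ** 2 * (n[ok] - 1))
    num = float((n11[ok] - e11[ok]).sum())
    den = float(var.sum())
    stat = num * num / den if den > 0 else 0.0
    return num, den, stat


def cmh_pvalue(series: TwoByTwoSeries) -> float:
    """Cochran-Mantel-Haenszel p-value over replicate strata.

    Stratum ``v`` pairs replicate v of condition 1 with replicate v of
    condition 2 (rows = tag states, columns = conditions).  All-degenerate
    strata yield p = 1 with a warning.
    """
    c = series.cells
    strata = np.stack([c[:, :, v] for v in range(series.r)])  # (r, 2, 2) [i, j]
    num, den, stat = cmh_statistic(strata)
    if den <= 0:
        warnings.warn(f"all CMH strata degenerate for tag {series.tag_id!r}; p = 1")
        return 1.0
    return float(stats.chi2.sf(stat, df=1))


def cmh_pvalues_matrix(cells: np.ndarray) -> np.ndarray:
    """Vectorized CMH p-values for a stacked ``(S, 2, 2, r)`` cell array."""
    cells = np.asarray(cells, dtype=float)
    n11 = cells[:, 0, 0, :]
    r1 = cells[:, 0, :, :].sum(axis=1)
    r2 = cells[:, 1, :, :].sum(axis=1)
    c1 = cells[:, :, 0, :].sum(axis=1)
    c2 = cells[:, :, 1, :].sum(axis=1)
    n = r1 + r2
    ok = n > 1
    e11 = np.where(ok, r1 * c1 / np.where(ok, n, 1.0), 0.0)
    var = np.where(ok, r1 * r2 * c1 * c2 / np.where(ok, n ** 2 * (n - 1), 1.0), 0.0)
    num = np.where(ok, n11 - e11, 0.0).sum(axis=1)
    den = var.sum(axis=1)
    stat = np.where(den > 0, num ** 2 / np.where(den > 0, den, 1.0), 0.0)
    return np.where(den > 0, stats.chi2.sf(stat, df=1), 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise RaxError("bh_adjust expects a non-empty 1-D p-value vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise RaxError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def pvalue_profile(series_list: list[TwoByTwoSeries],
                   methods: tuple[str, ...] = ("pearson", "fisher", "cmh")) -> pd.DataFrame:
    """Per-tag p-values and BH-adjusted values for the requested methods."""
    valid = {"pearson", "fisher", "cmh"}
    bad = [m for m in methods if m not in valid]
    if bad:
        raise RaxError(f"unknown method(s) {bad}; valid methods: {sorted(valid)}")
    rows = {"tagid": [s.tag_id for s in series_list]}
    frames = []
    for method in methods:
        if method == "cmh":
            ps = [cmh_pvalue(s) for s in series_list]
        else:
            ps = [mean_table_pvalues(s, method) for s in series_list]
        ps = np.asarray(ps)
        frames.append(pd.DataFrame({
            "tagid": rows["tagid"], "method": method,
            "p": ps, "bh_q": bh_adjust(ps),
        }))
    return pd.concat(frames, ignore_index=True)
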