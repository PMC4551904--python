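"""Ranked chi-square association analysis of replicated 2x2 tag tables.

For every tag ``s`` of a multi-tag gene we form ``r`` replicate 2x2 tables
(tag vs rest-of-gene x condition).  Two statistics are derived per tag:

* the *treatment* chi-square -- Pearson chi-square of the table of replicate
  means; and
* the *null* chi-square -- Pearson chi-squares of within-condition
  replicate-pair tables (rows = tag states, columns = the two replicates),
  averaged per condition with the noisier condition's average taken as the
  tag's null level: a noise-only analogue of a within-group variance.

Both statistic vectors are ranked ascending and compared position-by-
position.  Scanning a grid of thresholds on the rank-matched difference
yields the number of declarations and a nonparametric estimate of the false
discovery rate at each threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import RaxError
from .io import TagCountTable


# ---------------------------------------------------------------------------
# 2x2 series construction
# ---------------------------------------------------------------------------

@dataclass
class TwoByTwoSeries:
    """The ``r`` replicate 2x2 tables of one tag.

    ``cells[i, j, v]``: ``i`` = 0 for the tag itself, 1 for the rest of its
    gene; ``j`` = 0 for condition 1 (rest), 1 for condition 2 (stim);
    ``v`` = replicate 0..r-1.
    """

    tag_id: str
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float)
        if self.cells.ndim != 3 or self.cells.shape[:2] != (2, 2):
            raise RaxError("cells must have shape (2, 2, r)")
        if (self.cells < 0).any():
            raise RaxError(f"negative cell count in series for tag {self.tag_id!r}")

    @property
    def r(self) -> int:
        return self.cells.shape[2]

    @property
    def n_total(self) -> float:
        return float(self.cells.sum())


def series_matrix(t: TagCountTable,
                  tag_ids: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Stack all per-tag 2x2 series of a table into one ``(S, 2, 2, r)`` array.

    Only tags of multi-tag genes are eligible (the rest-of-gene row would be
    empty otherwise).  Row ``[s, 1]`` is the sum of the other tags of the
    same gene, library by library.
    """
    r = t.r
    cols = [t.condition_columns(1), t.condition_columns(2)]
    counts = t.counts
    sizes = t.meta.groupby("geneid", sort=False)["tagid"].transform("size").to_numpy()
    if tag_ids is None:
        rows = np.flatnonzero(sizes >= 2)
    else:
        idx = {tag: k for k, tag in enumerate(t.meta["tagid"])}
        rows = np.array([idx[tag] for tag in tag_ids], dtype=int)
        if (sizes[rows] < 2).any():
            bad = t.meta["tagid"].iloc[rows[sizes[rows] < 2].tolist()[0]]
            raise RaxError(f"tag {bad!r} belongs to a single-tag gene")
    if len(rows) == 0:
        raise RaxError("no tags from multi-tag genes to analyze")

    gene_tot = (
        pd.DataFrame(counts)
        .groupby(t.meta["geneid"].to_numpy(), sort=False)
        .transform("sum")
        .to_numpy()
    )
    S = len(rows)
    cells = np.empty((S, 2, 2, r), dtype=float)
    for j in (0, 1):
        cj = cols[j]
        cells[:, 0, j, :] = counts[np.ix_(rows, cj)]
        cells[:, 1, j, :] = gene_tot[np.ix_(rows, cj)] - counts[np.ix_(rows, cj)]
    return cells, t.meta["tagid"].iloc[rows].tolist()


def build_two_by_two(t: TagCountTable, tag_id: str) -> TwoByTwoSeries:
    """The replicate 2x2 series (tag vs rest-of-gene x condition) of one tag."""
    row = t.row_of(tag_id)
    gene = t.meta["geneid"].iloc[row]
    if len(t.gene_rows(gene)) < 2:
        raise RaxError(f"tag {tag_id!r} belongs to a single-tag gene")
    cells, _ = series_matrix(t, [tag_id])
    return TwoByTwoSeries(tag_id=tag_id, cells=cells[0])


# ---------------------------------------------------------------------------
# chi-square statistics
# ---------------------------------------------------------------------------

def _pearson_vec(n11, n12, n21, n22):
    """Vectorized closed-form Pearson chi-square; 0 where a marginal is 0."""
    r1 = n11 + n12
    r2 = n21 + n22
    c1 = n11 + n21
    c2 = n12 + n22
    n = r1 + r2
    denom = r1 * r2 * c1 * c2
    det = n11 * n22 - n12 * n21
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = np.where(denom > 0, n * det * det / np.where(denom > 0, denom, 1.0), 0.0)
    return chi


def pearson_chi2(table) -> float:
    """Pearson chi-square of a single 2x2 table of non-negative reals.

    Returns 0 when any marginal is zero (no evidence rather than NaN).
    """
    a = np.asarray(table, dtype=float)
    if a.shape != (2, 2):
        raise RaxError("pearson_chi2 expects a 2x2 table")
    if (a < 0).any():
        raise RaxError("negative entry in 2x2 table")
    return float(_pearson_vec(a[0, 0], a[0, 1], a[1, 0], a[1, 1]))


def treatment_chi2(series: TwoByTwoSeries) -> float:
    """Chi-square of the 2x2 table of replicate means."""
    return pearson_chi2(series.cells.mean(axis=2))


def null_chi2(series: TwoByTwoSeries) -> float:
    """Noise-only chi-square from within-condition replicate pairs.

    For each condition and each unordered replicate pair (u, v), a 2x2 table
    is formed with rows = tag states and columns = the pair's counts.  The
    pair chi-squares are averaged within each condition, and the null
    chi-square is the larger of the two condition averages -- the noisier
    condition sets the tag's null level, the same way the larger within-
    group variance conservatively bounds a null variance.

    A two-single-replicate table carries r times the sampling noise of the
    r-replicate mean table behind the treatment statistic, so this null
    statistic stochastically dominates the treatment statistic under pure
    noise; declarations therefore require association signal well clear of
    the noise level, which keeps the downstream FDR estimate conservative.
    """
    if series.r < 2:
        raise RaxError("replicates required for null estimation (r >= 2)")
    c = series.cells
    cond_means = [
        float(np.mean([
            pearson_chi2([[c[0, j, u], c[0, j, v]], [c[1, j, u], c[1, j, v]]])
            for u, v in combinations(range(series.r), 2)
        ]))
        for j in (0, 1)
    ]
    return max(cond_means)


def _pair_chi2_matrix(cells: np.ndarray) -> np.ndarray:
    """All within-condition replicate-pair chi-squares, ``(S, n_pairs)``.

    The first r(r-1)/2 columns belong to condition 1, the rest to
    condition 2.
    """
    S, _, _, r = cells.shape
    cols = []
    for j in (0, 1):
        for u, v in combinations(range(r), 2):
            cols.append(_pearson_vec(cells[:, 0, j, u], cells[:, 0, j, v],
                                     cells[:, 1, j, u], cells[:, 1, j, v]))
    return np.stack(cols, axis=1)


def compute_chi2_pairs(cells: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Treatment and null chi-squares for a stacked ``(S, 2, 2, r)`` array.

    Vectorized equivalent of :func:`treatment_chi2` / :func:`null_chi2`.
    """
    cells = np.asarray(cells, dtype=float)
    S, _, _, r = cells.shape
    if r < 2:
        raise RaxError("replicates required for null estimation (r >= 2)")
    mean = cells.mean(axis=3)
    treat = _pearson_vec(mean[:, 0, 0], mean[:, 0, 1], mean[:, 1, 0], mean[:, 1, 1])
    pm = _pair_chi2_matrix(cells)
    half = pm.shape[1] // 2
    null = np.maximum(pm[:, :half].mean(axis=1), pm[:, half:].mean(axis=1))
    return treat, null


@dataclass(frozen=True)
class ChiSquarePair:
    tag_id: str
    chi2_treat: float
    chi2_null: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.chi2_treat) and np.isfinite(self.chi2_null)):
            raise RaxError(f"non-finite chi-square for tag {self.tag_id!r}")
        if self.chi2_treat < 0 or self.chi2_null < 0:
            raise RaxError(f"negative chi-square for tag {self.tag_id!r}")


def chi2_pairs(t: TagCountTable,
               tag_ids: list[str] | None = None) -> list[ChiSquarePair]:
    """Per-tag (treatment, null) chi-square pairs for all multi-tag-gene tags."""
    cells, tags = series_matrix(t, tag_ids)
    treat, null = compute_chi2_pairs(cells)
    return [ChiSquarePair(tag, float(a), float(b))
            for tag, a, b in zip(tags, treat, null)]


# ---------------------------------------------------------------------------
# ranking and threshold scan
# ---------------------------------------------------------------------------

@dataclass
class RankedProfiles:
    """Both chi-square vectors ranked ascending, with tag back-maps."""

    sorted_treat: np.ndarray
    sorted_null: np.ndarray
    treat_tags: list[str]          # tag at each treatment rank (1-based rank = index+1)
    null_tags: list[str]
    pairs: list[ChiSquarePair]

    @property
    def S(self) -> int:
        return len(self.sorted_treat)

    @property
    def chi2_null_max(self) -> float:
        return float(self.sorted_null[-1])

    def rank_of(self, tag_id: str) -> int:
        """1-based position of a tag in the treatment ranking."""
        return self.treat_tags.index(tag_id) + 1


def rank_profiles(pairs: list[ChiSquarePair]) -> RankedProfiles:
    """Rank treatment and null chi-squares ascending, independently.

    Ties in the treatment statistic are broken by tag id (stable,
    deterministic); the null vector is ranked by value alone.
    """
    if len(pairs) < 2:
        raise RaxError("at least 2 chi-square pairs required for ranking")
    order_t = sorted(range(len(pairs)), key=lambda k: (pairs[k].chi2_treat, pairs[k].tag_id))
    order_e = sorted(range(len(pairs)), key=lambda k: (pairs[k].chi2_null, pairs[k].tag_id))
    sorted_treat = np.array([pairs[k].chi2_treat for k in order_t])
    sorted_null = np.array([pairs[k].chi2_null for k in order_e])
    if sorted_null[-1] <= 0:
        raise RaxError("degenerate null distribution: all null chi-squares are 0")
    return RankedProfiles(
        sorted_treat=sorted_treat,
        sorted_null=sorted_null,
        treat_tags=[pairs[k].tag_id for k in order_t],
        null_tags=[pairs[k].tag_id for k in order_e],
        pairs=list(pairs),
    )


@dataclass
class FdrCurve:
    """Per-threshold scan records.

    ``a`` and ``b`` are 1-based ranked positions; records with no position
    satisfying the declaration rule have ``defined=False`` (N=0, F=0, FDR
    meaningless).  ``x`` is the exponent of the false-positive probability.
    """

    table: pd.DataFrame   # columns: U, delta, a, b, N, F, fdr, defined
    x: float
    r: int

    def defined(self) -> pd.DataFrame:
        return self.table[self.table["defined"]]


def scan_thresholds(p: RankedProfiles, r: int, n_grid: int = 100,
                    x: float | None = None) -> FdrCurve:
    """Scan thresholds ``delta = U * max(null chi-square)``, U on a uniform grid.

    At each delta: ``a`` is the smallest rank such that the rank-matched
    difference d = chi2_treat - chi2_null exceeds delta at *every* rank >= a
    (longest qualifying suffix); N = S - a + 1 declarations.  ``b`` is the
    smallest null rank whose null chi-square exceeds the null value at rank
    ``a`` by more than delta; the expected false positives F sum the
    positional probabilities ((chi2_null[t] * t) / (chi2_null_max * S))**x
    over ranks t >= b, and FDR = min(1, F/N).

    ``x`` defaults to (2r / chi2_null_max)**2; pass ``x=0`` to force the
    maximally conservative p = 1 variant.
    """
    if n_grid < 1:
        raise RaxError("n_grid must be >= 1")
    S = p.S
    null = p.sorted_null
    null_max = p.chi2_null_max
    d = p.sorted_treat - null
    if x is None:
        x = (2.0 * r / null_max) ** 2
    ranks = np.arange(1, S + 1, dtype=float)
    with np.errstate(divide="ignore"):
        p_false = ((null * ranks) / (null_max * S)) ** x
    # suffix sums of p(t*) so F is O(1) per grid point
    suffix = np.concatenate([np.cumsum(p_false[::-1])[::-1], [0.0]])

    rows = []
    for g in range(n_grid + 1):
        U = g / n_grid
        delta = U * null_max
        bad = np.flatnonzero(d <= delta)
        if len(bad) == 0:
            a = 1
        elif bad[-1] == S - 1:
            rows.append((U, delta, 0, 0, 0, 0.0, np.nan, False))
            continue
        else:
            a = int(bad[-1]) + 2
        N = S - a + 1
        over = np.flatnonzero(null - null[a - 1] > delta)
        if len(over) == 0:
            b, F = 0, 0.0
        else:
            b = int(over[0]) + 1
            F = float(suffix[b - 1])
        fdr = min(1.0, F / N)
        rows.append((U, delta, a, b, N, F, fdr, True))
    table = pd.DataFrame(
        rows, columns=["U", "delta", "a", "b", "N", "F", "fdr", "defined"]
    )
    return FdrCurve(table=table, x=float(x), r=r)


def declared_at(p: RankedProfiles, a: int) -> list[str]:
    """Tags at treatment ranks >= a (the declared set of one threshold)."""
    return p.treat_tags[a - 1:]


def declared_sets(p: RankedProfiles, c: FdrCurve) -> list[set[str] | None]:
    """Declared tag set per curve record (None where the record is undefined)."""
    out = []
    for rec in c.table.itertuples():
        out.append(set(declared_at(p, int(rec.a))) if rec.defined else None)
    return out


@dataclass
class Declaration:
    """Result of choosing the smallest threshold meeting the FDR bound."""

    declared: set[str]
    report: pd.DataFrame  # tagid, geneid-free per-tag report
    delta: float | None
    fdr: float | None
    record: pd.Series | None


def declare(p: RankedProfiles, c: FdrCurve, alpha: float = 0.05) -> Declaration:
    """Declare tags at the smallest scanned threshold whose FDR < ``alpha``.

    The per-tag report carries both chi-squares, the treatment rank, the
    declared flag and -- for every tag declared at *some* defined threshold --
    the FDR at the smallest threshold where it first enters a declared set
    (a step-function q-value analogue).
    """
    defined = c.defined()
    chosen = defined[defined["fdr"] < alpha]
    if len(chosen) == 0:
        warnings.warn(f"no threshold achieves FDR < {alpha}; declaring nothing")
        rec = None
        declared: set[str] = set()
    else:
        rec = chosen.iloc[0]  # grid is scanned in increasing delta order
        declared = set(declared_at(p, int(rec["a"])))

    # per-tag first-entry FDR: iterate defined records in increasing delta
    first_fdr = np.full(p.S, np.nan)
    first_delta = np.full(p.S, np.nan)
    for row in defined.itertuples():
        a = int(row.a)
        block = slice(a - 1, p.S)
        unset = np.isnan(first_fdr[block])
        first_fdr[block] = np.where(unset, row.fdr, first_fdr[block])
        first_delta[block] = np.where(unset, row.delta, first_delta[block])

    by_tag = {pair.tag_id: pair for pair in p.pairs}
    report = pd.DataFrame({
        "tagid": p.treat_tags,
        "chi2_treat": [by_tag[tag].chi2_treat for tag in p.treat_tags],
        "chi2_null": [by_tag[tag].chi2_null for tag in p.treat_tags],
        "rank": np.arange(1, p.S + 1),
        "declared": [tag in declared for tag in p.treat_tags],
        "fdr": first_fdr,
        "delta_at_declaration": first_delta,
    })
    return Declaration(
        declared=declared,
        report=report,
        delta=float(rec["delta"]) if rec is not None else None,
        fdr=float(rec["fdr"]) if rec is not None else None,
        record=rec,
    )
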