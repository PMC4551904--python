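"""Switch / accordance pattern classification for declared multi-tag genes.

For each tag, the *condition ratio* is the share of its total count observed
in one condition (summed over replicates).  The difference
``d = ratio(stim) - ratio(rest)`` lies in [-1, 1].  For an ordered tag pair
(proximal, distal) with differences (x, y):

* x > 0, y > 0 -> positive accordance (both isoforms rise with stimulation)
* x < 0, y < 0 -> negative accordance
* x < 0, y > 0 -> forward switch (usage moves proximal -> distal)
* x > 0, y < 0 -> backward switch (usage moves distal -> proximal)
* any zero (or undefined) -> unclassified
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import RaxError
from .io import TagCountTable

PATTERNS = ("forward_switch", "backward_switch",
            "positive_accordance", "negative_accordance", "unclassified")


@dataclass(frozen=True)
class PatternCall:
    gene_id: str
    pair: tuple[str, str]       # (more proximal tag, more distal tag)
    pair_label: str             # e.g. proximal_distal
    dx: float
    dy: float
    pattern: str


def _sign_pattern(dx: float, dy: float) -> str:
    if not (np.isfinite(dx) and np.isfinite(dy)) or dx == 0 or dy == 0:
        return "unclassified"
    if dx > 0 and dy > 0:
        return "positive_accordance"
    if dx < 0 and dy < 0:
        return "negative_accordance"
    if dx < 0 and dy > 0:
        return "forward_switch"
    return "backward_switch"


def condition_ratio_diff(t: TagCountTable, tag_id: str) -> float:
    """ratio(stim) - ratio(rest), each ratio = condition sum / overall sum.

    NaN (the unclassified marker) when the tag's total count is zero.
    """
    row = t.row_of(tag_id)
    rest = t.counts[row, t.condition_columns(1)].sum()
    stim = t.counts[row, t.condition_columns(2)].sum()
    total = rest + stim
    if total <= 0:
        return math.nan
    return (stim - rest) / total  # stim/total - rest/total


def fold_change(t: TagCountTable, tag_id: str) -> float:
    """Symmetric fold change: max of the two directional ratios of
    condition means.  One zero mean -> +inf; both zero -> 1."""
    row = t.row_of(tag_id)
    m1 = t.counts[row, t.condition_columns(1)].mean()
    m2 = t.counts[row, t.condition_columns(2)].mean()
    if m1 == 0 and m2 == 0:
        return 1.0
    if m1 == 0 or m2 == 0:
        return math.inf
    return max(m1 / m2, m2 / m1)


def _ordered_declared(t: TagCountTable, gene_id: str,
                      declared_tags: set[str]) -> list[str]:
    rows = t.gene_rows(gene_id)  # proximal -> distal by construction
    return [t.meta["tagid"].iloc[k] for k in rows
            if t.meta["tagid"].iloc[k] in declared_tags]


def classify_two_tag(t: TagCountTable, gene_id: str,
                     declared_tags: set[str]) -> PatternCall:
    """Sign-rule pattern for a gene with exactly two declared tags."""
    tags = _ordered_declared(t, gene_id, declared_tags)
    if len(tags) != 2:
        raise RaxError(
            f"gene {gene_id!r} has {len(tags)} declared tags; exactly 2 required"
        )
    dx = condition_ratio_diff(t, tags[0])
    dy = condition_ratio_diff(t, tags[1])
    return PatternCall(gene_id, (tags[0], tags[1]), "proximal_distal",
                       dx, dy, _sign_pattern(dx, dy))


def classify_three_tag(t: TagCountTable, gene_id: str,
                       declared_tags: set[str]) -> list[PatternCall]:
    """Pairwise sign-rule patterns for a gene with exactly three declared
    tags: (proximal, middle), (proximal, distal), (middle, distal)."""
    tags = _ordered_declared(t, gene_id, declared_tags)
    if len(tags) != 3:
        raise RaxError(
            f"gene {gene_id!r} has {len(tags)} declared tags; exactly 3 required"
        )
    d = {tag: condition_ratio_diff(t, tag) for tag in tags}
    labels = [("proximal_middle", 0, 1), ("proximal_distal", 0, 2),
              ("middle_distal", 1, 2)]
    return [
        PatternCall(gene_id, (tags[i], tags[j]), label,
                    d[tags[i]], d[tags[j]], _sign_pattern(d[tags[i]], d[tags[j]]))
        for label, i, j in labels
    ]


def classify_genes(t: TagCountTable, declared_tags: set[str]) -> pd.DataFrame:
    """Pattern calls for all genes with exactly 2 or 3 declared tags.

    Columns: geneid, n_declared, pair, proximal, distal, dx, dy, pattern.
    """
    calls: list[PatternCall] = []
    n_declared: list[int] = []
    for gene in t.gene_ids:
        tags = _ordered_declared(t, gene, declared_tags)
        if len(tags) == 2:
            calls.append(classify_two_tag(t, gene, declared_tags))
            n_declared.append(2)
        elif len(tags) == 3:
            calls.extend(classify_three_tag(t, gene, declared_tags))
            n_declared.extend([3, 3, 3])
    return pd.DataFrame({
        "geneid": [c.gene_id for c in calls],
        "n_declared": n_declared,
        "pair": [c.pair_label for c in calls],
        "proximal": [c.pair[0] for c in calls],
        "distal": [c.pair[1] for c in calls],
        "dx": [c.dx for c in calls],
        "dy": [c.dy for c in calls],
        "pattern": [c.pattern for c in calls],
    })


def pattern_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts of each pattern per pair label."""
    if len(calls) == 0:
        return pd.DataFrame(columns=["pair", "pattern", "count"])
    out = (calls.groupby(["pair", "pattern"]).size()
           .rename("count").reset_index())
    return out
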