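"""Tag-level count table I/O, library normalization and tag filters.

A *tag* is a transcript isoform defined by its poly(A) site; the count table
has one row per tag and one column per sequencing library.  Libraries belong
to one of exactly two conditions (``1`` = rest / normal state, ``2`` =
stimulated / treatment state) with an equal number of replicates each.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import RaxError

META_COLUMNS = ["tagid", "geneid", "name", "strand", "pos", "annotation"]

_REST_LABELS = {"1", "rest", "ns", "normal"}
_STIM_LABELS = {"2", "stim", "ts", "treatment", "stimulated"}


@dataclass(frozen=True)
class Library:
    """One sequencing library: id, condition (1=rest, 2=stim), replicate index."""

    library_id: str
    condition: int
    replicate: int


@dataclass
class SizeFactors:
    """Per-library positive scale factors with geometric mean 1."""

    library_ids: list[str]
    factors: np.ndarray

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(self.factors <= 0):
            raise RaxError("size factors must be positive")
        log_gm = float(np.mean(np.log(self.factors)))
        if abs(log_gm) > 1e-6:
            raise RaxError("size factors must have geometric mean 1")


@dataclass
class TagCountTable:
    """Per-tag, per-library counts with gene grouping.

    Rows are grouped by gene and ordered proximal -> distal within each gene.
    ``meta`` carries the 6 metadata columns (``tagid, geneid, name, strand,
    pos, annotation``); ``counts`` is a dense ``(n_tags, n_libraries)`` float
    matrix aligned with ``libraries``.
    """

    meta: pd.DataFrame
    counts: np.ndarray
    libraries: list[Library]
    position_space: str = "transcript"
    _gene_rows: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise RaxError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.meta), len(self.libraries)):
            raise RaxError("counts shape does not match meta/libraries")
        self._gene_rows = None

    # -- basic accessors -------------------------------------------------
    @property
    def n_tags(self) -> int:
        return len(self.meta)

    @property
    def tag_ids(self) -> list[str]:
        return self.meta["tagid"].tolist()

    @property
    def gene_ids(self) -> list[str]:
        """Unique gene ids in table order."""
        return self.meta["geneid"].drop_duplicates().tolist()

    @property
    def r(self) -> int:
        """Replicates per condition (equal for both by construction)."""
        return sum(1 for lib in self.libraries if lib.condition == 1)

    def condition_columns(self, condition: int) -> list[int]:
        """Column indices of one condition, ordered by replicate index."""
        cols = [(lib.replicate, k) for k, lib in enumerate(self.libraries)
                if lib.condition == condition]
        return [k for _, k in sorted(cols)]

    def gene_rows(self, gene_id: str) -> np.ndarray:
        """Row indices of a gene's tags, proximal -> distal."""
        if self._gene_rows is None:
            # groupby().indices returns positional indices
            self._gene_rows = {
                g: np.asarray(v) for g, v in
                self.meta.groupby("geneid", sort=False).indices.items()
            }
        return self._gene_rows[gene_id]

    def gene_sizes(self) -> pd.Series:
        return self.meta.groupby("geneid", sort=False).size()

    def row_of(self, tag_id: str) -> int:
        hits = np.flatnonzero((self.meta["tagid"] == tag_id).to_numpy())
        if len(hits) == 0:
            raise RaxError(f"unknown tag id {tag_id!r}")
        return int(hits[0])

    def subset(self, rows: Sequence[int]) -> "TagCountTable":
        rows = np.asarray(rows, dtype=int)
        return TagCountTable(
            meta=self.meta.iloc[rows].reset_index(drop=True),
            counts=self.counts[rows],
            libraries=list(self.libraries),
            position_space=self.position_space,
        )


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

def _parse_condition(label: object, library_id: str) -> int:
    s = str(label).strip().lower()
    if s in _REST_LABELS:
        return 1
    if s in _STIM_LABELS:
        return 2
    raise RaxError(
        f"exactly two conditions required (rest/stim or 1/2); "
        f"library {library_id!r} has condition {label!r}"
    )


def read_design(design_path) -> list[Library]:
    df = pd.read_csv(design_path, comment="#", dtype=str)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    required = {"library_id", "condition", "replicate"}
    if not required.issubset(cols):
        raise RaxError(f"design file must have columns {sorted(required)}")
    libs = []
    for _, row in df.iterrows():
        lib_id = str(row["library_id"]).strip()
        cond = _parse_condition(row["condition"], lib_id)
        try:
            rep = int(row["replicate"])
        except (TypeError, ValueError):
            raise RaxError(f"non-integer replicate index for library {lib_id!r}")
        libs.append(Library(lib_id, cond, rep))
    if len({lib.library_id for lib in libs}) != len(libs):
        raise RaxError("duplicate library_id in design file")
    by_cond = {1: [], 2: []}
    for lib in libs:
        by_cond[lib.condition].append(lib.replicate)
    if not by_cond[1] or not by_cond[2]:
        raise RaxError("exactly two conditions required; one condition has no libraries")
    for cond, reps in by_cond.items():
        if sorted(reps) != list(range(1, len(reps) + 1)):
            raise RaxError(f"replicate indices of condition {cond} must be 1..r")
    if len(by_cond[1]) != len(by_cond[2]):
        raise RaxError("both conditions must have the same number of replicates")
    if len(by_cond[1]) < 2:
        raise RaxError("at least 2 replicates per condition required")
    return libs


def _sort_table(meta: pd.DataFrame, counts: np.ndarray,
                position_space: str) -> tuple[pd.DataFrame, np.ndarray]:
    """Group by gene (first-appearance order), proximal -> distal within gene.

    ``transcript`` space: positions are along the transcription unit, so
    ascending order is proximal-first on either strand.  ``genomic`` space:
    strand-aware (on '-' the larger coordinate is more proximal).
    """
    meta = meta.reset_index(drop=True)
    gene_order = {g: k for k, g in enumerate(meta["geneid"].drop_duplicates())}
    gkey = meta["geneid"].map(gene_order).to_numpy()
    pos = meta["pos"].to_numpy(dtype=float)
    if position_space == "genomic":
        minus = (meta["strand"] == "-").to_numpy()
        pos = np.where(minus, -pos, pos)
    elif position_space != "transcript":
        raise RaxError(f"unknown position_space {position_space!r}")
    order = np.lexsort((meta["tagid"].to_numpy(), pos, gkey))
    return meta.iloc[order].reset_index(drop=True), counts[order]


def read_tag_table(count_path, design_path, *,
                   position_space: str = "transcript") -> TagCountTable:
    """Read a count CSV plus design CSV into a :class:`TagCountTable`.

    The count CSV has the 6 metadata columns ``tagid,geneid,name,strand,pos,
    annotation`` followed by one count column per library.  Every count
    column must be mapped by the design file and vice versa.
    """
    libraries = read_design(design_path)
    df = pd.read_csv(count_path, comment="#", dtype={"tagid": str, "geneid": str})
    df.columns = [str(c).strip() for c in df.columns]
    missing_meta = [c for c in META_COLUMNS if c not in df.columns]
    if missing_meta:
        raise RaxError(f"count file missing metadata columns {missing_meta}")
    count_cols = [c for c in df.columns if c not in META_COLUMNS]
    lib_ids = [lib.library_id for lib in libraries]
    unknown = [lib for lib in lib_ids if lib not in count_cols]
    if unknown:
        raise RaxError(f"design refers to unknown library column(s) {unknown}")
    unmapped = [c for c in count_cols if c not in lib_ids]
    if unmapped:
        raise RaxError(f"count column(s) {unmapped} not mapped in design file")

    dup = df["tagid"][df["tagid"].duplicated()]
    if len(dup):
        raise RaxError(f"duplicate tag_id {dup.iloc[0]!r}")

    meta = df[META_COLUMNS].copy()
    meta["tagid"] = meta["tagid"].astype(str)
    meta["geneid"] = meta["geneid"].astype(str)
    meta["strand"] = meta["strand"].astype(str).str.strip().replace({"−": "-"})
    bad_strand = meta.loc[~meta["strand"].isin(["+", "-"]), "tagid"]
    if len(bad_strand):
        raise RaxError(f"invalid strand for tag {bad_strand.iloc[0]!r} (must be + or -)")
    meta["annotation"] = meta["annotation"].fillna("").astype(str)
    meta["name"] = meta["name"].fillna("").astype(str)

    counts = df[lib_ids].to_numpy(dtype=float)
    if np.isnan(counts).any():
        tag = meta["tagid"].iloc[int(np.argwhere(np.isnan(counts))[0][0])]
        raise RaxError(f"missing count for tag {tag!r}")
    if (counts < 0).any():
        i, j = np.argwhere(counts < 0)[0]
        raise RaxError(
            f"negative count for tag {meta['tagid'].iloc[int(i)]!r} "
            f"in library {lib_ids[int(j)]!r}"
        )

    meta, counts = _sort_table(meta, counts, position_space)
    return TagCountTable(meta=meta, counts=counts, libraries=libraries,
                         position_space=position_space)


def write_tag_table(t: TagCountTable, count_path, design_path,
                    header_comment: str | None = None) -> None:
    """Write count + design CSVs in the dialect accepted by :func:`read_tag_table`."""
    df = t.meta.copy()
    for lib, col in zip(t.libraries, t.counts.T):
        df[lib.library_id] = col
    with open(count_path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)
    cond_name = {1: "rest", 2: "stim"}
    with open(design_path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("library_id,condition,replicate\n")
        for lib in t.libraries:
            fh.write(f"{lib.library_id},{cond_name[lib.condition]},{lib.replicate}\n")


# ---------------------------------------------------------------------------
# normalization and filters
# ---------------------------------------------------------------------------

def normalize_libraries(t: TagCountTable) -> tuple[TagCountTable, SizeFactors]:
    """Median-of-ratios size-factor normalization (DESeq-style), tag level.

    The reference is the per-tag geometric mean over libraries, computed over
    tags with all-positive counts; each library's factor is the median ratio
    to the reference, centred so the factors' geometric mean is exactly 1.
    Counts are divided by the factors.  Idempotent: re-application yields
    factors of 1.
    """
    counts = t.counts
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise RaxError(
            "no tag has positive counts in every library; "
            "pre-filter low-coverage tags before normalization"
        )
    logs = np.log(counts[positive])
    log_ref = logs.mean(axis=1)
    log_factors = np.median(logs - log_ref[:, None], axis=0)
    log_factors -= log_factors.mean()  # centre: geometric mean of factors = 1
    factors = np.exp(log_factors)
    out = replace(t, counts=counts / factors, meta=t.meta.copy())
    sf = SizeFactors([lib.library_id for lib in t.libraries], factors)
    return out, sf


def filter_minor_tags(t: TagCountTable, coverage: float = 0.9) -> TagCountTable:
    """Keep, per gene, the highest-frequency tags covering > ``coverage`` of
    the gene's aggregate count; discard the rest.

    Tags are ranked by aggregate count (descending); ties are broken
    proximal-first, then by tag id.  The minimal prefix whose share strictly
    exceeds ``coverage`` is retained; if no prefix exceeds it (e.g.
    ``coverage=1``), all tags are kept.
    """
    if not (0 < coverage <= 1):
        raise RaxError("coverage must be in (0, 1]")
    agg = t.counts.sum(axis=1)
    keep = np.zeros(t.n_tags, dtype=bool)
    for gene in t.gene_ids:
        rows = t.gene_rows(gene)
        a = agg[rows]
        total = a.sum()
        if total <= 0:
            keep[rows] = True
            continue
        # rows are already proximal-first; stable sort keeps that tiebreak
        order = np.argsort(-a, kind="stable")
        cum = np.cumsum(a[order])
        exceed = np.flatnonzero(cum > coverage * total)
        k = int(exceed[0]) + 1 if len(exceed) else len(rows)
        keep[rows[order[:k]]] = True
    return t.subset(np.flatnonzero(keep))


def filter_single_tag_genes(t: TagCountTable) -> TagCountTable:
    """Drop transcription units with a single tag (association needs >= 2)."""
    sizes = t.meta.groupby("geneid", sort=False)["tagid"].transform("size")
    keep = np.flatnonzero((sizes >= 2).to_numpy())
    if len(keep) == 0:
        raise RaxError("no multi-tag genes remain after filtering")
    return t.subset(keep)
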