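"""Negative-binomial null count simulation with injected association effects.

The protocol mirrors the evaluation design for the ranked chi-square test:

1. estimate four cell means and four cell variances per tag from a template
   table's replicate 2x2 series;
2. for each tag pick one mean and one variance at random and draw a null
   2x2 x r series from a negative binomial with that mean as ``mu`` and that
   variance as the dispersion (``size``) parameter (Poisson fallback when
   the variance is non-positive, non-finite, or mean-degenerate);
3. add an association effect n_ij = U_ij N_i N_j / (sum of N's), with
   N ~ Normal(100, 50) truncated positive and U ~ Uniform(0, 1], to a random
   subset of tags, identically across the replicates of each cell.

Each simulated tag is materialized as a 2-tag gene (the tag plus an explicit
"rest-of-gene" row drawn from the i=2 cell moments), so the per-tag 2x2
tables reconstructed downstream are mutually independent and truth labels
stay clean.  Rest rows carry annotation ``"rest"`` and are excluded from
analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import RaxError
from .io import Library, TagCountTable
from .core import FdrCurve, series_matrix

REST_ANNOTATION = "rest"


@dataclass
class SimConfig:
    seed: int
    r: int = 3
    effect_fraction: float = 0.1
    normal_mean: float = 100.0
    normal_sd: float = 50.0
    template: TagCountTable | None = None
    u_mode: str = "cell"   # "cell": one uniform per cell; "product": U_i * U_j

    def __post_init__(self) -> None:
        if not (0 < self.effect_fraction < 1):
            raise RaxError("effect_fraction must be in (0, 1)")
        if self.r < 2:
            raise RaxError("r must be >= 2")
        if self.u_mode not in ("cell", "product"):
            raise RaxError("u_mode must be 'cell' or 'product'")


@dataclass
class CellMoments:
    """Per-tag mean and sample variance of each 2x2 cell over replicates."""

    tag_ids: list[str]
    means: np.ndarray   # (S, 2, 2)
    variances: np.ndarray

    @property
    def S(self) -> int:
        return len(self.tag_ids)


@dataclass
class SimTruth:
    table: TagCountTable
    effect_tags: set[str]
    effect_sizes: dict[str, np.ndarray]  # tag -> rounded 2x2 injected counts


@dataclass
class CalibrationResult:
    table: pd.DataFrame  # delta, N, true_F, true_FDR, est_FDR, defined


# ---------------------------------------------------------------------------
# template moments
# ---------------------------------------------------------------------------

def estimate_cell_moments(t: TagCountTable) -> CellMoments:
    """Four means and four variances per tag from its replicate 2x2 series."""
    if t.r < 2:
        raise RaxError("moment estimation needs r >= 2 replicates")
    cells, tags = series_matrix(t)
    return CellMoments(
        tag_ids=tags,
        means=cells.mean(axis=3),
        variances=cells.var(axis=3, ddof=1),
    )


def synthetic_template(n_tags: int, r: int = 3, seed: int = 0,
                       gene_sizes: tuple[int, ...] = (2, 3, 4),
                       mean_log: float = math.log(8.0),
                       sd_log: float = 0.7,
                       dispersion: float = 10.0) -> TagCountTable:
    """Built-in template generator (no external data needed).

    Genes of 2-4 tags; each tag has a log-normal baseline expression and its
    library counts are negative binomial around that baseline, identical in
    distribution across conditions (a null template).  Defaults mimic
    depth-normalized 3'-end tag counts: small per-library counts (median 8)
    with mild overdispersion, the regime where injected effects of the
    Normal(100, 50) family are informative.
    """
    rng = np.random.default_rng([seed, 0])
    sizes = []
    total = 0
    while total < n_tags:
        z = int(rng.choice(gene_sizes))
        sizes.append(z)
        total += z
    sizes[-1] -= total - n_tags
    if sizes[-1] < 2:
        sizes[-1] = 2
    rows = []
    n = sum(sizes)
    mu = rng.lognormal(mean_log, sd_log, size=n)
    p_nb = dispersion / (dispersion + mu)
    counts = rng.negative_binomial(dispersion, p_nb[:, None], size=(n, 2 * r)).astype(float)
    k = 0
    for g, z in enumerate(sizes):
        for zz in range(z):
            rows.append({
                "tagid": f"t{k:06d}",
                "geneid": f"g{g:05d}",
                "name": f"gene{g:05d}",
                "strand": "+",
                "pos": zz + 1,
                "annotation": "",
            })
            k += 1
    libs = [Library(f"rest_{v}", 1, v) for v in range(1, r + 1)] + \
           [Library(f"stim_{v}", 2, v) for v in range(1, r + 1)]
    return TagCountTable(meta=pd.DataFrame(rows), counts=counts, libraries=libs)


# ---------------------------------------------------------------------------
# null generation
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, size_param: np.ndarray,
             shape: tuple[int, ...]) -> np.ndarray:
    """NB draws with mean ``mu`` and dispersion ``size_param`` (R's size).

    Falls back to Poisson where the dispersion is non-positive, non-finite
    or mean-degenerate (size <= mu, where a sample variance used as the
    size parameter would imply more-than-doubled variance); draws zeros
    where the mean is non-positive.  With this rule the simulated variance
    is always in (mu, 2*mu].

    ``mu`` and ``size_param`` broadcast against ``shape`` (tag axis first).
    """
    mu = np.broadcast_to(np.asarray(mu, dtype=float), shape)
    sz = np.broadcast_to(np.asarray(size_param, dtype=float), shape)
    out = np.zeros(shape, dtype=float)
    ok_mu = mu > 0
    nb = ok_mu & (sz > mu) & np.isfinite(sz)
    pois = ok_mu & ~nb
    if nb.any():
        p = sz[nb] / (sz[nb] + mu[nb])
        out[nb] = rng.negative_binomial(sz[nb], p)
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    return out


def generate_null(moments: CellMoments, r: int, seed: int) -> TagCountTable:
    """Simulate a null table: per tag, one randomly chosen cell mean and one
    randomly chosen cell variance parameterize NB draws for all 2x2 x r cells.

    Every template tag becomes a 2-tag simulated gene: the tag row (cells
    i=1) plus an explicit rest-of-gene row (cells i=2, annotation "rest"),
    so downstream 2x2 reconstruction recovers exactly the drawn tables.
    """
    rng = np.random.default_rng([seed, 1])
    S = moments.S
    means = moments.means.reshape(S, 4)
    varis = moments.variances.reshape(S, 4)
    pick_mu = means[np.arange(S), rng.integers(0, 4, size=S)]
    pick_var = varis[np.arange(S), rng.integers(0, 4, size=S)]
    if (pick_mu <= 0).any():
        warnings.warn(f"{int((pick_mu <= 0).sum())} tag(s) drew a zero mean; "
                      "their simulated counts are all zero")
    cells = _nb_draw(rng, pick_mu[:, None, None, None],
                     pick_var[:, None, None, None], (S, 2, 2, r))

    rows = []
    counts = np.empty((2 * S, 2 * r), dtype=float)
    for s, tag in enumerate(moments.tag_ids):
        gene = f"sim_{tag}"
        rows.append({"tagid": tag, "geneid": gene, "name": gene,
                     "strand": "+", "pos": 1, "annotation": ""})
        rows.append({"tagid": f"{tag}:rest", "geneid": gene, "name": gene,
                     "strand": "+", "pos": 2, "annotation": REST_ANNOTATION})
        # library order: rest_1..rest_r, stim_1..stim_r
        counts[2 * s, :r] = cells[s, 0, 0]
        counts[2 * s, r:] = cells[s, 0, 1]
        counts[2 * s + 1, :r] = cells[s, 1, 0]
        counts[2 * s + 1, r:] = cells[s, 1, 1]
    libs = [Library(f"rest_{v}", 1, v) for v in range(1, r + 1)] + \
           [Library(f"stim_{v}", 2, v) for v in range(1, r + 1)]
    return TagCountTable(meta=pd.DataFrame(rows), counts=counts, libraries=libs)


def primary_tags(t: TagCountTable) -> list[str]:
    """Tags that are analysis units (excludes explicit rest-of-gene rows)."""
    m = t.meta
    return m.loc[m["annotation"] != REST_ANNOTATION, "tagid"].tolist()


# ---------------------------------------------------------------------------
# effect injection
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size=size)
    while (out <= 0).any():
        bad = out <= 0
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return out


def inject_effects(null_table: TagCountTable, cfg: SimConfig) -> SimTruth:
    """Add association effects to a random subset of tags.

    For an effect tag, cell (i, j) gains ``round(U_ij N_i N_j / N_tot)``
    counts in every replicate, where N ~ Normal(normal_mean, normal_sd)
    truncated positive and U ~ Uniform(0, 1]; the tag row and its gene's
    rest row are updated consistently.

    With ``u_mode="cell"`` (default) the four U_ij are independent, so the
    injected table is a randomly perturbed product structure carrying a
    genuine association component.  ``u_mode="product"`` uses
    U_ij = U_i * U_j, which makes the effect matrix exactly rank one -- an
    effect with *no* association signal of its own (its chi-square is 0
    before baseline interaction), kept for reference.
    """
    prim = primary_tags(null_table)
    S = len(prim)
    n_eff = round(cfg.effect_fraction * S)
    if n_eff < 1:
        raise RaxError("effect_fraction x S < 1: no tags to assign effects to")
    rng = np.random.default_rng([cfg.seed, 2])
    chosen = rng.choice(S, size=n_eff, replace=False)
    effect_tags = {prim[k] for k in chosen}

    table = null_table.subset(np.arange(null_table.n_tags))  # deep-ish copy
    cols = [table.condition_columns(1), table.condition_columns(2)]
    effect_sizes: dict[str, np.ndarray] = {}
    tag_row = {tag: k for k, tag in enumerate(table.meta["tagid"])}
    gene_of = dict(zip(table.meta["tagid"], table.meta["geneid"]))
    rest_row = {}
    for tag in effect_tags:
        gene = gene_of[tag]
        rows = table.gene_rows(gene)
        others = [k for k in rows if k != tag_row[tag]]
        rest_row[tag] = others

    for k in sorted(chosen):
        tag = prim[k]
        n_i = _truncated_normal(rng, cfg.normal_mean, cfg.normal_sd, 2)
        n_j = _truncated_normal(rng, cfg.normal_mean, cfg.normal_sd, 2)
        n_tot = n_i.sum() + n_j.sum()
        if cfg.u_mode == "cell":
            u = 1.0 - rng.random((2, 2))  # (0, 1], one per cell
        else:
            u_i = 1.0 - rng.random(2)
            u_j = 1.0 - rng.random(2)
            u = np.outer(u_i, u_j)
        eff = np.rint(u * np.outer(n_i, n_j) / n_tot)
        effect_sizes[tag] = eff
        for j in (0, 1):
            table.counts[tag_row[tag], cols[j]] += eff[0, j]
            # spread the rest-of-gene effect across the gene's other rows
            others = rest_row[tag]
            share = eff[1, j] / len(others)
            for o in others:
                table.counts[o, cols[j]] += share
    return SimTruth(table=table, effect_tags=effect_tags, effect_sizes=effect_sizes)


def simulate_dataset(n_tags: int, r: int, effect_fraction: float,
                     seed: int, template: TagCountTable | None = None) -> SimTruth:
    """End-to-end protocol: template (built-in unless given) -> moments ->
    null table -> injected effects."""
    cfg = SimConfig(seed=seed, r=r, effect_fraction=effect_fraction,
                    template=template)
    tmpl = template if template is not None else synthetic_template(
        n_tags, r=r, seed=seed)
    moments = estimate_cell_moments(tmpl)
    null = generate_null(moments, r=r, seed=seed)
    return inject_effects(null, cfg)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def evaluate_calibration(truth: SimTruth, curve: FdrCurve,
                         declared_per_delta: list[set[str] | None]) -> CalibrationResult:
    """True-vs-estimated FDR per scanned threshold, from truth labels."""
    if len(declared_per_delta) != len(curve.table):
        raise RaxError("declared_per_delta must align with the curve records")
    rows = []
    for rec, declared in zip(curve.table.itertuples(), declared_per_delta):
        if not rec.defined or declared is None:
            rows.append((rec.delta, 0, 0, 0.0, np.nan, False))
            continue
        n = len(declared)
        true_f = len(declared - truth.effect_tags)
        true_fdr = true_f / n if n else 0.0
        rows.append((rec.delta, n, true_f, true_fdr, rec.fdr, True))
    return CalibrationResult(table=pd.DataFrame(
        rows, columns=["delta", "N", "true_F", "true_FDR", "est_FDR", "defined"]
    ))
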