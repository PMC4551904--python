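import numpy as np
import pandas as pd
import pytest

from rax2.io import Library, TagCountTable


def make_table(gene_sizes, counts, strand=None, positions=None,
               gene_prefix="g", tag_prefix="t", r=None):
    """Build a TagCountTable from a per-tag count matrix.

    ``gene_sizes``: list of tags-per-gene; ``counts``: (n_tags, 2r) array,
    columns rest_1..rest_r then stim_1..stim_r.
    """
    counts = np.asarray(counts, dtype=float)
    n_tags = counts.shape[0]
    assert sum(gene_sizes) == n_tags
    if r is None:
        assert counts.shape[1] % 2 == 0
        r = counts.shape[1] // 2
    rows = []
    k = 0
    for g, z in enumerate(gene_sizes):
        for zz in range(z):
            rows.append({
                "tagid": f"{tag_prefix}{k:03d}",
                "geneid": f"{gene_prefix}{g:03d}",
                "name": f"name{g:03d}",
                "strand": "+" if strand is None else strand[k],
                "pos": zz + 1 if positions is None else positions[k],
                "annotation": "",
            })
            k += 1
    libs = [Library(f"rest_{v}", 1, v) for v in range(1, r + 1)] + \
           [Library(f"stim_{v}", 2, v) for v in range(1, r + 1)]
    return TagCountTable(meta=pd.DataFrame(rows), counts=counts, libraries=libs)


@pytest.fixture
def toy_table():
    """2 genes, 3 tags, 6 libraries (r = 3): Z = {2, 1}, S = 3."""
    counts = np.array([
        [1, 2, 3, 4, 5, 6],
        [6, 5, 4, 3, 2, 1],
        [10, 10, 10, 10, 10, 10],
    ], dtype=float)
    return make_table([2, 1], counts)


@pytest.fixture
def two_tag_table():
    """One 2-tag gene, r = 3: series of tag A has row 2 = tag B's counts."""
    counts = np.array([
        [1, 2, 3, 4, 5, 6],
        [6, 5, 4, 3, 2, 1],
    ], dtype=float)
    return make_table([2], counts)


def write_csvs(table, tmp_path, name="toy"):
    from rax2.io import write_tag_table
    cpath = tmp_path / f"{name}_counts.csv"
    dpath = tmp_path / f"{name}_design.csv"
    write_tag_table(table, cpath, dpath)
    return cpath, dpath
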