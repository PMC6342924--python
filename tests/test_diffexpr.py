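"""Differential cluster expression: Venn, PCA, Fisher/BH machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pirnascape.diffexpr import (ExpressionMatrix, bh_adjust, build_matrix,
                                 differential_test, pca_scores,
                                 presence_overlap)
from pirnascape.types import Cluster

from _oracles import bh_stepup, fisher_two_sided_hypergeom


def _matrix(counts: dict, groups, lengths=None, totals=None):
    df = pd.DataFrame(counts).T  # clusters x libraries
    libs = list(df.columns)
    lengths = pd.Series(lengths or {c: 1000 for c in df.index})
    totals = totals or {lib: max(int(df[lib].sum()), 1) * 10 for lib in libs}
    rpkm = df.astype(float)
    for lib in libs:
        rpkm[lib] = df[lib] * 1e6 / (totals[lib] * lengths[df.index] / 1000).values
    return ExpressionMatrix(counts=df, rpkm=rpkm, groups=groups,
                            lengths=lengths, library_totals=totals)


GROUPS = {"Ma1": "Ma", "Ma2": "Ma", "Go1": "Go", "Go2": "Go"}


def test_presence_overlap_partition():
    m = _matrix({
        "c1": {"Ma1": 5, "Ma2": 3, "Go1": 2, "Go2": 1},
        "c2": {"Ma1": 0, "Ma2": 0, "Go1": 4, "Go2": 0},
        "c3": {"Ma1": 1, "Ma2": 0, "Go1": 0, "Go2": 0},
        "c4": {"Ma1": 0, "Ma2": 0, "Go1": 0, "Go2": 0},
    }, GROUPS)
    venn = presence_overlap(m)
    assert venn[frozenset({"Ma", "Go"})] == 1
    assert venn[frozenset({"Go"})] == 1  # gonad-exclusive
    assert venn[frozenset({"Ma"})] == 1
    assert sum(venn.values()) == 4  # regions partition the cluster set


def test_pca_duplicate_columns_and_variance_order(rng):
    counts = {f"c{i}": {"Ma1": int(x), "Ma2": int(x), "Go1": int(y), "Go2": int(y + 1)}
              for i, (x, y) in enumerate(zip(rng.integers(0, 200, 40),
                                             rng.integers(0, 200, 40)))}
    m = _matrix(counts, GROUPS)
    scores = pca_scores(m, n_components=3)
    # duplicated library columns -> identical scores
    assert np.allclose(scores.loc["Ma1"], scores.loc["Ma2"])
    var = scores.attrs["explained_variance"]
    assert all(a >= b - 1e-12 for a, b in zip(var, var[1:]))


def test_pca_needs_nonconstant_rows():
    m = _matrix({"c1": {"Ma1": 2, "Ma2": 2, "Go1": 2, "Go2": 2}}, GROUPS)
    with pytest.raises(ValueError):
        pca_scores(m)


def test_bh_matches_textbook_stepup(rng):
    for _ in range(20):
        p = rng.random(int(rng.integers(1, 200)))
        assert np.allclose(bh_adjust(p), bh_stepup(p))


def test_fisher_p_equals_hypergeometric_sum():
    a, b, c, d = 10, 990, 1000, 99000
    p_scipy = stats.fisher_exact([[a, b], [c, d]])[1]
    p_oracle = fisher_two_sided_hypergeom(a, b, c, d)
    assert np.isclose(p_scipy, p_oracle, rtol=1e-8)


def test_identical_counts_not_significant():
    m = _matrix({
        "c1": {"Ma1": 50, "Ma2": 50, "Go1": 50, "Go2": 50},
        "c2": {"Ma1": 10, "Ma2": 10, "Go1": 10, "Go2": 10},
    }, GROUPS, totals={lib: 1000 for lib in GROUPS})
    res = differential_test(m, "Ma", "Go")
    for r in res:
        assert r.log2_ratio == 0.0 and not r.significant


def test_zero_count_tissue_raises():
    m = _matrix({"c1": {"Ma1": 5, "Ma2": 5, "Go1": 0, "Go2": 0}}, GROUPS)
    with pytest.raises(ValueError, match="Go"):
        differential_test(m, "Ma", "Go")


def test_significance_requires_both_criteria(rng):
    """A strong planted fold change is called; a matched cluster is not."""
    counts = {"null%d" % i: {"Ma1": 100, "Ma2": 100, "Go1": 100, "Go2": 100}
              for i in range(30)}
    counts["up"] = {"Ma1": 400, "Ma2": 400, "Go1": 40, "Go2": 40}
    m = _matrix(counts, GROUPS, totals={lib: 5000 for lib in GROUPS})
    res = {r.cluster: r for r in differential_test(m, "Ma", "Go")}
    assert res["up"].significant and res["up"].log2_ratio > 1
    assert not res["null0"].significant


def test_monotone_in_effect_size(rng):
    """More planted fold change never yields fewer significant clusters
    (in expectation; averaged over seeds)."""
    def n_sig(fold, seed):
        r = np.random.default_rng(seed)
        counts = {}
        for i in range(60):
            base = int(r.integers(50, 200))
            up = i < 15
            counts[f"c{i}"] = {
                "Ma1": r.poisson(base * (fold if up else 1)),
                "Ma2": r.poisson(base * (fold if up else 1)),
                "Go1": r.poisson(base), "Go2": r.poisson(base)}
        m = _matrix(counts, GROUPS, totals={lib: 30_000 for lib in GROUPS})
        return sum(r_.significant for r_ in differential_test(m, "Ma", "Go"))

    means = [np.mean([n_sig(f, s) for s in range(10)]) for f in (1.5, 3, 6)]
    assert means[0] <= means[1] + 0.5 and means[1] <= means[2] + 0.5


def test_build_matrix_from_clusters():
    clusters = [
        Cluster("s1.cl1", "s1", 0, 2000, counts={"Ma1": 30, "Go1": 10}),
        Cluster("s1.cl2", "s1", 5000, 5500, counts={"Go1": 50}),
    ]
    totals = {"Ma1": 1000, "Go1": 1000}
    m = build_matrix(clusters, totals, {"Ma1": "Ma", "Go1": "Go"})
    assert m.counts.loc["s1.cl2", "Ma1"] == 0
    assert np.isclose(m.rpkm.loc["s1.cl1", "Ma1"], 30 * 1e6 / (1000 * 2.0))
    assert m.counts[["Ma1", "Go1"]].sum().tolist() == [30, 60]
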