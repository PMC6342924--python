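"""Cluster-level expression analysis: presence overlaps, PCA, and
somatic-vs-gonadal differential expression.

Replicates are pooled per tissue (two libraries each); each cluster is
tested with a two-sided Fisher exact test on the 2×2 table

    [reads in cluster, reads in all other clusters] × [tissue A, tissue B]

followed by Benjamini–Hochberg FDR across clusters. A cluster is called
significant when FDR < 0.01 and |log2 ratio| > 1, where the ratio is
taken between pooled-tissue RPKM values stabilised with a pseudocount
(0.01 RPKM by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .clustercall import cluster_rpkm
from .types import Cluster

DEFAULT_FDR = 0.01
DEFAULT_MIN_ABS_LOG2 = 1.0
DEFAULT_EPSILON_RPKM = 0.01

# library -> tissue assignment used by the standard eight-library design
DEFAULT_GROUPS = {"Ma1": "Ma", "Ma2": "Ma", "Ad1": "Ad", "Ad2": "Ad",
                  "Gi1": "Gi", "Gi2": "Gi", "Go1": "Go", "Go2": "Go"}
SOMATIC_TISSUES = ("Ma", "Ad", "Gi")
GONADAL_TISSUES = ("Go",)


@dataclass(slots=True)
class ExpressionMatrix:
    """Cluster × library expression: raw counts and RPKM layers.

    ``counts``/``rpkm`` are DataFrames with cluster names as the index
    and library labels as columns; ``groups`` maps library -> tissue.
    """

    counts: pd.DataFrame
    rpkm: pd.DataFrame
    groups: dict[str, str]
    lengths: pd.Series  # cluster genomic lengths, bp
    library_totals: dict[str, int]

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.rpkm.index) or \
           not self.counts.columns.equals(self.rpkm.columns):
            raise ValueError("counts and RPKM layers must share dimensions")

    @property
    def tissues(self) -> list[str]:
        return sorted(set(self.groups.values()))

    def tissue_libraries(self, tissue: str) -> list[str]:
        return [lib for lib in self.counts.columns if self.groups.get(lib) == tissue]


@dataclass(slots=True)
class DEResult:
    """Differential-expression verdict for one cluster in one comparison."""

    cluster: str
    comparison: str
    log2_ratio: float
    p_value: float
    fdr: float
    significant: bool


def build_matrix(clusters: Sequence[Cluster], library_totals: dict[str, int],
                 groups: dict[str, str] | None = None) -> ExpressionMatrix:
    """Assemble the expression matrix from called clusters."""
    groups = dict(DEFAULT_GROUPS if groups is None else groups)
    libs = [lib for lib in library_totals if lib in groups]
    names = [cl.name for cl in clusters]
    counts = pd.DataFrame(0, index=names, columns=libs, dtype=np.int64)
    lengths = pd.Series({cl.name: cl.length for cl in clusters}, dtype=np.int64)
    for cl in clusters:
        for lib, n in cl.counts.items():
            if lib in counts.columns:
                counts.loc[cl.name, lib] = n
    rpkm = counts.astype(float)
    for lib in libs:
        rpkm[lib] = [cluster_rpkm(int(c), library_totals[lib], int(lengths[name]))
                     for name, c in counts[lib].items()]
    return ExpressionMatrix(counts=counts, rpkm=rpkm, groups=groups,
                            lengths=lengths, library_totals=dict(library_totals))


def presence_overlap(matrix: ExpressionMatrix) -> dict[frozenset, int]:
    """Venn-region membership counts over tissues.

    A cluster is present in a tissue when it has ≥1 read in ≥1 of the
    tissue's libraries (replicates pooled). Returns counts keyed by the
    exact tissue combination (2^T − 1 regions plus the empty key for
    clusters with no reads anywhere); regions partition the cluster set.
    """
    tissues = matrix.tissues
    present = {}
    for t in tissues:
        libs = matrix.tissue_libraries(t)
        present[t] = matrix.counts[libs].sum(axis=1) > 0
    out: dict[frozenset, int] = {}
    for name in matrix.counts.index:
        key = frozenset(t for t in tissues if bool(present[t][name]))
        out[key] = out.get(key, 0) + 1
    return out


def pca_scores(matrix: ExpressionMatrix, n_components: int = 2) -> pd.DataFrame:
    """Library scores on principal components of log2(RPKM + 1).

    Libraries are observations, clusters features; constant clusters are
    dropped and features are centred. Raises when fewer than two
    non-constant clusters remain.
    """
    if matrix.rpkm.shape[1] < 2:
        raise ValueError("PCA needs at least two libraries")
    x = np.log2(matrix.rpkm.to_numpy(dtype=float).T + 1.0)
    keep = x.std(axis=0) > 0
    x = x[:, keep]
    if x.shape[1] < 2:
        raise ValueError("PCA needs at least two non-constant clusters")
    n_components = min(n_components, *x.shape)
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    df = pd.DataFrame(scores, index=matrix.rpkm.columns,
                      columns=[f"PC{i + 1}" for i in range(scores.shape[1])])
    df.attrs["explained_variance"] = model.explained_variance_.tolist()
    return df


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def differential_test(
    matrix: ExpressionMatrix,
    tissue_a: str,
    tissue_b: str,
    fdr_threshold: float = DEFAULT_FDR,
    min_abs_log2: float = DEFAULT_MIN_ABS_LOG2,
    epsilon_rpkm: float = DEFAULT_EPSILON_RPKM,
) -> list[DEResult]:
    """Per-cluster differential expression between two tissues.

    Counts are pooled across replicates; the test is a two-sided Fisher
    exact test of cluster reads vs all-other-cluster reads between the
    tissues. The log2 ratio compares pooled-tissue RPKM values with an
    ``epsilon_rpkm`` pseudocount on both sides.
    """
    libs_a = matrix.tissue_libraries(tissue_a)
    libs_b = matrix.tissue_libraries(tissue_b)
    if not libs_a or not libs_b:
        raise ValueError(f"no libraries for comparison {tissue_a} vs {tissue_b}")
    a = matrix.counts[libs_a].sum(axis=1).to_numpy(dtype=np.int64)
    b = matrix.counts[libs_b].sum(axis=1).to_numpy(dtype=np.int64)
    total_a, total_b = int(a.sum()), int(b.sum())
    for total, tissue, libs in ((total_a, tissue_a, libs_a),
                                (total_b, tissue_b, libs_b)):
        if total == 0:
            raise ValueError(
                f"tissue {tissue} (libraries {libs}) has zero in-cluster reads")

    pooled_total_a = sum(matrix.library_totals[l] for l in libs_a)
    pooled_total_b = sum(matrix.library_totals[l] for l in libs_b)
    lengths = matrix.lengths.loc[matrix.counts.index].to_numpy(dtype=np.int64)
    rpkm_a = a * 1e6 / (pooled_total_a * lengths / 1000)
    rpkm_b = b * 1e6 / (pooled_total_b * lengths / 1000)
    log2_ratio = np.log2((rpkm_a + epsilon_rpkm) / (rpkm_b + epsilon_rpkm))

    p = np.empty(len(a))
    for i in range(len(a)):
        table = [[int(a[i]), total_a - int(a[i])],
                 [int(b[i]), total_b - int(b[i])]]
        p[i] = stats.fisher_exact(table, alternative="two-sided")[1]
    fdr = bh_adjust(p)

    comparison = f"{tissue_a}_vs_{tissue_b}"
    return [
        DEResult(cluster=name, comparison=comparison,
                 log2_ratio=float(log2_ratio[i]), p_value=float(p[i]),
                 fdr=float(fdr[i]),
                 significant=bool(fdr[i] < fdr_threshold
                                  and abs(log2_ratio[i]) > min_abs_log2))
        for i, name in enumerate(matrix.counts.index)
    ]


def all_pairwise_tests(matrix: ExpressionMatrix, **kwargs) -> pd.DataFrame:
    """Every pairwise tissue comparison, as one tidy DataFrame."""
    rows = []
    for ta, tb in combinations(matrix.tissues, 2):
        for r in differential_test(matrix, ta, tb, **kwargs):
            rows.append(vars(r) if not hasattr(r, "__slots__") else {
                s: getattr(r, s) for s in r.__slots__})
    return pd.DataFrame(rows)


def results_table(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame([{s: getattr(r, s) for s in r.__slots__} for r in results])
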