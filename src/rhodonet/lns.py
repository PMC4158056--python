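"""Local Network Similarity (LNS): gene-level expression conservation.

For two datasets sharing n ortholog pairs, let W^A and W^B be the n x n
matrices of atanh-transformed (Fisher z) co-expression correlations among
the orthologs, each aligned to the ortholog-pair order.  The LNS of a
pair is the Pearson correlation between the pair's matched correlation
vectors (the corresponding rows of W^A and W^B) after removing the pair's
own self-entry — the atanh of the unit diagonal is unbounded and carries
no neighbourhood information.

The randomization null shuffles the ortholog mapping table, leaving each
network's topology untouched; shuffling node labels inside one matrix is
a different null (it breaks the per-node connectivity pattern) and is
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExprMatrix, ModulePartition, OrthologMap, ValidationError
from .network import CorrMatrix, bicor_matrix

ATANH_CLIP = 1.0 - 1e-12


@dataclass
class AtanhCorrMatrix:
    """atanh-transformed correlation matrix over ortholog genes."""

    data: pd.DataFrame
    clip: float = ATANH_CLIP

    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class LnsNull:
    """Pooled randomized-map null distribution of LNS scores."""

    values: np.ndarray  # n_perm x n_pairs
    mean: float
    sd: float
    min: float
    max: float


def atanh_corr(cor: CorrMatrix) -> AtanhCorrMatrix:
    """Entrywise Fisher z transform after clipping |r| to 1 - 1e-12."""
    R = np.clip(cor.values, -ATANH_CLIP, ATANH_CLIP)
    W = np.arctanh(R)
    return AtanhCorrMatrix(
        pd.DataFrame(W, index=cor.gene_ids, columns=cor.gene_ids)
    )


def _aligned(
    WA: AtanhCorrMatrix, WB: AtanhCorrMatrix, mapping: OrthologMap
) -> tuple[np.ndarray, np.ndarray]:
    """Reindex both matrices to the ortholog-pair order of the map."""
    for genes, W, col in (
        (mapping.ref_genes, WA, "ref"),
        (mapping.test_genes, WB, "test"),
    ):
        missing = [g for g in genes if g not in W.data.index]
        if missing:
            raise ValidationError(
                f"{col} genes absent from correlation matrix: {missing[:5]}"
            )
    A = WA.data.loc[mapping.ref_genes, mapping.ref_genes].to_numpy(dtype=float)
    B = WB.data.loc[mapping.test_genes, mapping.test_genes].to_numpy(dtype=float)
    return A, B


def _lns_core(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """LNS per pair for pair-aligned matrices (pair k <-> row/col k).

    Pearson correlation of rows k of A and B over the other n-1 matched
    components, via sufficient statistics with the self-entry removed.
    """
    n = A.shape[0]
    if n < 4:
        raise ValidationError("need at least 4 ortholog genes")
    da = np.diagonal(A)
    db = np.diagonal(B)
    m = n - 1
    sa = A.sum(axis=1) - da
    sb = B.sum(axis=1) - db
    saa = (A**2).sum(axis=1) - da**2
    sbb = (B**2).sum(axis=1) - db**2
    sab = (A * B).sum(axis=1) - da * db
    va = saa - sa**2 / m
    vb = sbb - sb**2 / m
    num = sab - sa * sb / m
    denom = np.where(va == vb, va, np.sqrt(va) * np.sqrt(vb))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / denom
    r[~np.isfinite(r)] = np.nan
    return np.clip(r, -1.0, 1.0)


def _lns_rows_general(A: np.ndarray, B: np.ndarray, tidx: np.ndarray) -> np.ndarray:
    """LNS of pair k = (row k of A, row tidx[k] of B) with components kept
    in the original pair order; positions {k, tidx[k]} (the two self
    entries) are deleted from both vectors before correlating."""
    n = A.shape[0]
    k = np.arange(n)
    t = np.asarray(tidx)
    Bt = B[t]
    drop_a = np.stack([A[k, k], A[k, t]], axis=1)
    drop_b = np.stack([Bt[k, k], Bt[k, t]], axis=1)
    if n < 4:
        raise ValidationError("need at least 4 ortholog genes")
    same = t == k
    m = np.where(same, n - 1, n - 2).astype(float)

    def sums(M, drop):
        s1 = M.sum(axis=1) - drop[:, 0] - np.where(same, 0.0, drop[:, 1])
        s2 = (M**2).sum(axis=1) - drop[:, 0] ** 2 - np.where(
            same, 0.0, drop[:, 1] ** 2
        )
        return s1, s2

    sa, saa = sums(A, drop_a)
    sb, sbb = sums(Bt, drop_b)
    sab = (A * Bt).sum(axis=1) - drop_a[:, 0] * drop_b[:, 0] - np.where(
        same, 0.0, drop_a[:, 1] * drop_b[:, 1]
    )
    va = saa - sa**2 / m
    vb = sbb - sb**2 / m
    num = sab - sa * sb / m
    denom = np.where(va == vb, va, np.sqrt(va) * np.sqrt(vb))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / denom
    r[~np.isfinite(r)] = np.nan
    return np.clip(r, -1.0, 1.0)


def lns_all(
    WA: AtanhCorrMatrix, WB: AtanhCorrMatrix, mapping: OrthologMap
) -> pd.DataFrame:
    """LNS score for every ortholog pair in the map."""
    A, B = _aligned(WA, WB, mapping)
    scores = _lns_core(A, B)
    return pd.DataFrame(
        {
            "ref_gene": mapping.ref_genes,
            "test_gene": mapping.test_genes,
            "lns": scores,
        }
    )


def lns_null(
    WA: AtanhCorrMatrix,
    WB: AtanhCorrMatrix,
    mapping: OrthologMap,
    n_perm: int = 100,
    seed: int = 0,
    per_pair: bool = False,
    shuffle_nodes: bool = False,
) -> tuple[pd.DataFrame, LnsNull]:
    """Randomized-ortholog-map null and per-pair empirical p-values.

    Each permutation shuffles which test gene is paired with which
    reference gene (full shuffles; fixed points allowed) and recomputes
    all LNS scores.  empirical_p = (1 + #null >= observed) / (1 + #null)
    against the pooled null by default, or against the pair's own null
    column when ``per_pair``.  ``shuffle_nodes`` switches to the
    alternative null that permutes node labels inside the test matrix.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    A, B = _aligned(WA, WB, mapping)
    observed = _lns_core(A, B)
    n = A.shape[0]
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, n))
    for p in range(n_perm):
        sigma = rng.permutation(n)
        if shuffle_nodes:
            # node labels permuted on the lookup axis only: each pair reads
            # another node's correlation vector while components stay in
            # the original pair order (two self entries to delete).
            null[p] = _lns_rows_general(A, B, sigma)
        else:
            # shuffled mapping table: pair k becomes (ref_k, test_sigma(k))
            # and the component matching follows the shuffled table, i.e.
            # B is reindexed on both axes and pairs sit on the diagonal.
            Bp = B[np.ix_(sigma, sigma)]
            null[p] = _lns_core(A, Bp)
    pooled = null[np.isfinite(null)]
    summary = LnsNull(
        values=null,
        mean=float(pooled.mean()),
        sd=float(pooled.std(ddof=1)),
        min=float(pooled.min()),
        max=float(pooled.max()),
    )
    if per_pair:
        n_null = np.isfinite(null).sum(axis=0)
        n_ge = np.nansum(null >= observed[None, :], axis=0)
    else:
        n_null = pooled.size
        n_ge = np.array([(pooled >= o).sum() for o in observed])
    emp_p = (1.0 + n_ge) / (1.0 + n_null)
    table = pd.DataFrame(
        {
            "ref_gene": mapping.ref_genes,
            "test_gene": mapping.test_genes,
            "lns": observed,
            "null_mean": summary.mean,
            "null_sd": summary.sd,
            "null_max": summary.max,
            "empirical_p": emp_p,
        }
    )
    return table, summary


def lns_from_expr(
    ref: ExprMatrix, test: ExprMatrix, mapping: OrthologMap
) -> tuple[AtanhCorrMatrix, AtanhCorrMatrix]:
    """Convenience: bicor + atanh for both datasets restricted to the map."""
    ref_r = ref.subset_genes([g for g in mapping.ref_genes])
    test_r = test.subset_genes([g for g in mapping.test_genes])
    return (
        atanh_corr(bicor_matrix(ref_r)),
        atanh_corr(bicor_matrix(test_r)),
    )


def within_species_lns(
    expr: ExprMatrix, n_rep: int = 100, seed: int = 0
) -> tuple[pd.Series, pd.DataFrame]:
    """Split-half LNS within one dataset.

    Each repeat randomly divides the conditions into two (near-)equal
    disjoint halves, computes a bicor matrix per half and the per-gene LNS
    between the halves with the identity mapping.  Returns the per-gene
    mean over repeats and the full per-repeat table.
    """
    if expr.n_conditions < 8:
        raise ValidationError("need at least 8 conditions for split-half LNS")
    if n_rep < 1:
        raise ValidationError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    cols = np.asarray(expr.condition_ids, dtype=object)
    half = len(cols) // 2
    ident = OrthologMap.identity(expr.gene_ids)
    reps = {}
    for r in range(n_rep):
        perm = rng.permutation(len(cols))
        e1 = expr.subset_conditions(list(cols[perm[:half]]))
        e2 = expr.subset_conditions(list(cols[perm[half:]]))
        W1 = atanh_corr(bicor_matrix(e1))
        W2 = atanh_corr(bicor_matrix(e2))
        reps[r] = lns_all(W1, W2, ident)["lns"].to_numpy()
    table = pd.DataFrame(reps, index=expr.gene_ids)
    return table.mean(axis=1), table


def median_lns_per_module(
    table: pd.DataFrame, part: ModulePartition
) -> pd.Series:
    """Median LNS over pairs whose reference gene belongs to each module.

    Unassigned genes (label 0) are reported as their own group; modules
    with no pairs are omitted with a warning.
    """
    labels = part.labels.reindex(table["ref_gene"])
    if labels.isna().any():
        bad = sorted(table["ref_gene"][labels.isna().to_numpy()])[:5]
        raise ValidationError(f"pairs with unlabelled reference genes: {bad}")
    grouped = table["lns"].groupby(labels.to_numpy()).median()
    missing = [m for m in part.module_labels if m not in grouped.index]
    if missing:
        import warnings

        warnings.warn(f"modules with no ortholog pairs omitted: {missing}",
                      stacklevel=2)
    grouped.index.name = "module"
    return grouped


def lns_vs_kmeall(
    medians: pd.Series, preservation: pd.DataFrame
) -> tuple[float, float, pd.DataFrame]:
    """Pearson correlation across modules of median-LNS vs cor.kMEall.

    Returns (r, two-sided p, paired table).  NaN with a warning when one
    vector is constant.
    """
    from scipy import stats

    common = [
        m
        for m in medians.index
        if m in preservation.index and np.isfinite(preservation.loc[m, "cor.kMEall"])
        and np.isfinite(medians.loc[m]) and m != 0
    ]
    if len(common) < 3:
        raise ValidationError("need at least 3 modules with both statistics")
    x = medians.loc[common].to_numpy(dtype=float)
    y = preservation.loc[common, "cor.kMEall"].to_numpy(dtype=float)
    paired = pd.DataFrame({"median_lns": x, "cor.kMEall": y}, index=common)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        import warnings

        warnings.warn("constant vector: correlation undefined", stacklevel=2)
        return np.nan, np.nan, paired
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), paired
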