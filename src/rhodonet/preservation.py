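"""Permutation-based module quality and preservation statistics.

Given modules defined in a reference dataset, these statistics ask two
questions about a test dataset sharing (a subset of) the genes: do the
module's genes remain densely inter-connected (density), and is the
pattern of connections similar (connectivity)?  Observed statistics are
compared against a null built by permuting module membership among the
common genes, yielding per-statistic Z scores that are summarized as

    Zdensity      = median(Z.meanCor, Z.meanAdj, Z.propVarExplained, Z.meanKME)
    Zconnectivity = median(Z.cor.kIM, Z.cor.kME, Z.cor.cor)
    Zsummary      = (Zdensity + Zconnectivity) / 2

Zsummary > 2 is weak-to-moderate and > 10 strong evidence of preservation.
medianRank complements Zsummary: for each observed statistic modules are
ranked (rank 1 = most preserved) and the per-module median rank reported;
it is less sensitive to module size.  The same machinery applied with
test := reference gives "quality" statistics; in that self-comparison the
connectivity components are identically 1 for observed and null alike, so
their Z scores are undefined and Zsummary.qual rests on the density side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExprMatrix, ModulePartition, OrthologMap, ValidationError
from .network import (
    NetworkParams,
    _biweight_transform,
    _corr_from_transformed,
    _eigengene,
    bicor_matrix,
    signed_adjacency,
)

DENSITY_STATS = ("meanCor", "meanAdj", "propVarExplained", "meanKME")
CONNECTIVITY_STATS = ("cor.kIM", "cor.kME", "cor.cor")
ALL_STATS = DENSITY_STATS + CONNECTIVITY_STATS


@dataclass
class PreservationReport:
    """Quality (ref vs itself) and preservation (ref vs test) statistics."""

    quality: pd.DataFrame
    preservation: pd.DataFrame
    n_permutations: int
    seed: int


def restrict_to_common(
    ref: ExprMatrix,
    test: ExprMatrix,
    mapping: OrthologMap,
    part: ModulePartition,
) -> tuple[ExprMatrix, ExprMatrix, ModulePartition]:
    """Restrict both datasets to mapped genes present in both.

    The test matrix is re-indexed by the reference ortholog ids so that all
    downstream statistics are plain aligned-matrix operations.  Modules
    reduced below 2 genes are dropped (label set to 0) with a warning.
    """
    if len(mapping) == 0:
        raise ValidationError("ortholog map is empty")
    ref_set = set(ref.gene_ids)
    test_set = set(test.gene_ids)
    pairs = [
        (a, b)
        for a, b in zip(mapping.ref_genes, mapping.test_genes)
        if a in ref_set and b in test_set
    ]
    if not pairs:
        raise ValidationError("no ortholog pair present in both datasets")
    ref_genes = [a for a, _ in pairs]
    ref_r = ref.subset_genes(ref_genes)
    test_r = test.subset_genes([b for _, b in pairs]).rename_genes(
        {b: a for a, b in pairs}
    )
    labels = part.labels.reindex(ref_genes).fillna(0).astype(int)
    sizes = labels[labels != 0].value_counts()
    dropped = sorted(sizes.index[sizes < 2])
    if dropped:
        warnings.warn(
            f"modules reduced below 2 genes dropped: {dropped}", stacklevel=2
        )
        labels[labels.isin(dropped)] = 0
    return ref_r, test_r, ModulePartition(labels)


class _DatasetContext:
    """Precomputed matrices for fast per-module statistics."""

    def __init__(self, expr: ExprMatrix, params: NetworkParams, min_obs: int = 4):
        self.X = expr.values
        self.min_obs = min_obs
        cor = bicor_matrix(expr, min_obs=min_obs)
        self.cor = cor.values
        self.adj = signed_adjacency(cor, params).values
        self.Xt, _ = _biweight_transform(self.X)

    def kme_to(self, profile: np.ndarray) -> np.ndarray:
        """bicor of every gene with a single condition profile."""
        Et, _ = _biweight_transform(profile[None, :])
        return _corr_from_transformed(self.Xt, Et, min_obs=min(self.min_obs, 4)).ravel()


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    dx = float(xc @ xc)
    dy = float(yc @ yc)
    if dx == 0 or dy == 0:
        return np.nan
    num = float(xc @ yc)
    denom = dx if dx == dy else float(np.sqrt(dx) * np.sqrt(dy))
    return float(np.clip(num / denom, -1.0, 1.0))


def _offdiag_mean(M: np.ndarray) -> float:
    n = M.shape[0]
    if n < 2:
        return np.nan
    return float((M.sum() - np.trace(M)) / (n * (n - 1)))


def _module_components(
    cr: _DatasetContext, ct: _DatasetContext, idx: np.ndarray
) -> dict[str, float]:
    """The 4 density + 3 connectivity component statistics for one module."""
    sub_ct = ct.cor[np.ix_(idx, idx)]
    sub_cr = cr.cor[np.ix_(idx, idx)]
    me_t, pve_t = _eigengene(ct.X[idx])
    me_r, _ = _eigengene(cr.X[idx])
    kme_t = ct.kme_to(me_t)
    kme_r = cr.kme_to(me_r)
    kim_r = cr.adj[np.ix_(idx, idx)].sum(axis=1) - 1.0
    kim_t = ct.adj[np.ix_(idx, idx)].sum(axis=1) - 1.0
    iu = np.triu_indices(len(idx), k=1)
    return {
        "meanCor": _offdiag_mean(sub_ct),
        "meanAdj": _offdiag_mean(ct.adj[np.ix_(idx, idx)]),
        "propVarExplained": pve_t,
        "meanKME": float(np.mean(kme_t[idx])),
        "cor.kIM": _pearson(kim_r, kim_t),
        "cor.kME": _pearson(kme_r[idx], kme_t[idx]),
        "cor.cor": _pearson(sub_cr[iu], sub_ct[iu]),
    }


def _cor_kme_all(
    cr: _DatasetContext, ct: _DatasetContext, idx: np.ndarray, method: str
) -> float:
    """Correlation over ALL common genes of kME to the module eigengene."""
    me_r, _ = _eigengene(cr.X[idx])
    me_t, _ = _eigengene(ct.X[idx])
    kr = cr.kme_to(me_r)
    kt = ct.kme_to(me_t)
    if method == "pearson":
        return _pearson(kr, kt)
    r = _corr_from_transformed(
        _biweight_transform(kr[None, :])[0], _biweight_transform(kt[None, :])[0]
    )
    return float(r[0, 0])


def observed_stats(
    ref: ExprMatrix,
    test: ExprMatrix,
    part: ModulePartition,
    params: NetworkParams | None = None,
    kme_all_method: str = "bicor",
    min_obs: int = 4,
) -> pd.DataFrame:
    """Per-module raw preservation statistics (no permutation).

    Inputs must already be restricted to common genes (see
    :func:`restrict_to_common`); density statistics are computed in the
    test data, connectivity statistics compare reference against test.
    Modules of size < 3 get NaN statistics.
    """
    params = params or NetworkParams()
    if ref.gene_ids != test.gene_ids:
        raise ValidationError("ref and test must share an identical gene axis")
    cr = _DatasetContext(ref, params, min_obs)
    ct = _DatasetContext(test, params, min_obs)
    labels = part.labels.loc[ref.gene_ids].to_numpy()
    rows = {}
    for m in part.module_labels:
        idx = np.nonzero(labels == m)[0]
        row: dict[str, float] = {"size": len(idx)}
        if len(idx) < 3:
            row.update({s: np.nan for s in ALL_STATS})
            row["cor.kMEall"] = np.nan
        else:
            row.update(_module_components(cr, ct, idx))
            row["cor.kMEall"] = _cor_kme_all(cr, ct, idx, kme_all_method)
        rows[m] = row
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("module")


def _median_rank(observed: pd.DataFrame) -> pd.Series:
    """Median over component statistics of the per-statistic module rank
    (descending: rank 1 = most preserved)."""
    ranks = observed[list(ALL_STATS)].rank(ascending=False, na_option="keep")
    return ranks.median(axis=1, skipna=True)


def _one_pass(
    cr: _DatasetContext,
    ct: _DatasetContext,
    labels: np.ndarray,
    modules: list[int],
    n_perm: int,
    rng: np.random.Generator,
    observed: pd.DataFrame,
) -> pd.DataFrame:
    """Z statistics for one (reference, test) pass given observed stats."""
    null_acc: dict[int, dict[str, list[float]]] = {
        m: {s: [] for s in ALL_STATS} for m in modules
    }
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        for m in modules:
            idx = np.nonzero(perm == m)[0]
            if len(idx) < 3:
                continue
            comp = _module_components(cr, ct, idx)
            for s in ALL_STATS:
                null_acc[m][s].append(comp[s])
    out = observed.copy()
    for s in ALL_STATS:
        zcol = []
        for m in modules:
            vals = np.asarray(null_acc[m][s], dtype=float)
            vals = vals[np.isfinite(vals)]
            obs = observed.loc[m, s]
            if len(vals) < 2 or not np.isfinite(obs):
                zcol.append(np.nan)
                continue
            sd = vals.std(ddof=1)
            if sd == 0:
                zcol.append(np.nan)
            else:
                zcol.append((obs - vals.mean()) / sd)
        out["Z." + s] = zcol
    zd = out[["Z." + s for s in DENSITY_STATS]]
    zc = out[["Z." + s for s in CONNECTIVITY_STATS]]
    out["Zdensity"] = zd.median(axis=1, skipna=True)
    out["Zconnectivity"] = zc.median(axis=1, skipna=True)
    out["Zsummary"] = out[["Zdensity", "Zconnectivity"]].mean(axis=1, skipna=True)
    out["medianRank"] = _median_rank(observed)
    return out


def module_preservation(
    ref: ExprMatrix,
    test: ExprMatrix,
    part: ModulePartition,
    params: NetworkParams | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    kme_all_method: str = "bicor",
    min_obs: int = 4,
) -> PreservationReport:
    """Quality and preservation Z statistics with a permuted-label null.

    The null shuffles module membership among the common genes (module
    sizes preserved, expression untouched) and recomputes every component
    statistic.  ``n_perm >= 50`` is recommended.  The quality pass applies
    the same machinery with test := ref.
    """
    params = params or NetworkParams()
    if n_perm < 2:
        raise ValidationError("n_perm must be >= 2")
    if seed is None:
        seed = params.seed
    if ref.gene_ids != test.gene_ids:
        raise ValidationError("ref and test must share an identical gene axis")
    modules = part.module_labels
    if not modules:
        raise ValidationError("partition contains no modules")
    labels = part.labels.loc[ref.gene_ids].to_numpy()
    cr = _DatasetContext(ref, params, min_obs)
    ct = _DatasetContext(test, params, min_obs)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        obs_pres = observed_stats(ref, test, part, params, kme_all_method, min_obs)
        obs_qual = observed_stats(ref, ref, part, params, kme_all_method, min_obs)
        rng = np.random.default_rng(seed)
        pres = _one_pass(cr, ct, labels, modules, n_perm, rng, obs_pres)
        rng_q = np.random.default_rng(seed + 1)
        qual = _one_pass(cr, cr, labels, modules, n_perm, rng_q, obs_qual)
    for df in (pres, qual):
        # fall back to the defined side when a whole class is degenerate
        only_dens = df["Zconnectivity"].isna() & df["Zdensity"].notna()
        df.loc[only_dens, "Zsummary"] = df.loc[only_dens, "Zdensity"]
    return PreservationReport(qual, pres, n_perm, seed)


def reproducibility_in_subset(
    ref: ExprMatrix,
    excluded_conditions: list,
    part: ModulePartition,
    params: NetworkParams | None = None,
    n_perm: int = 200,
    seed: int | None = None,
) -> PreservationReport:
    """Module reproducibility when some conditions are held out.

    Runs :func:`module_preservation` with test := reference minus the
    excluded condition columns and flags which modules exceed the
    Zsummary thresholds 2, 5 and 10.
    """
    keep = [c for c in ref.condition_ids if c not in set(excluded_conditions)]
    if not keep:
        raise ValidationError("cannot exclude every condition")
    if len(keep) < 4:
        raise ValidationError("fewer than 4 conditions remain after exclusion")
    test = ref.subset_conditions(keep)
    report = module_preservation(ref, test, part, params, n_perm, seed)
    for th in (2, 5, 10):
        report.preservation[f"th{th}"] = report.preservation["Zsummary"] > th
    return report
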