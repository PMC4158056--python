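"""Gene-set over-representation and the rank-based packaging test.

Over-representation uses the upper-tail hypergeometric probability of the
module / gene-set overlap, with Benjamini-Hochberg FDR across all tests
jointly.  The packaging test asks whether a module's genes sit unusually
high (or low) in a genome-wide ranking of a per-gene signal (robust
z-scores of DNA-packaging intensity): the module's ranks are compared by
one-sided rank-sum tests against many random gene sets of the same size,
and a module is called differentially packaged only when it beats a large
fraction of random sets with none beating it in the opposite direction.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .containers import GeneSetCollection, ModulePartition, ValidationError


def hypergeom_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` successes in a draw of ``n`` from a universe of ``N`` containing
    ``K`` marked elements; summed in log space for numerical stability.
    """
    if not (0 <= k <= min(n, K) <= N) or n > N:
        raise ValidationError(
            f"inconsistent counts: k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    support = np.arange(k, min(n, K) + 1)
    logp = stats.hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order kept)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora(
    part: ModulePartition,
    sets: GeneSetCollection,
    universe: set,
    min_set_size: int = 3,
    fdr_threshold: float = 0.05,
) -> tuple[pd.DataFrame, int]:
    """Hypergeometric over-representation of every set in every module.

    Sets are intersected with the universe first; intersections below
    ``min_set_size`` are dropped (their count is returned).  FDR is
    applied across all module x set tests jointly.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    module_genes = {
        m: set(part.members(m)) & universe for m in part.module_labels
    }
    not_in_universe = [
        g for m in part.module_labels for g in part.members(m) if g not in universe
    ]
    if not_in_universe:
        raise ValidationError(
            f"module genes outside the universe: {sorted(not_in_universe)[:5]}"
        )
    kept_sets = {}
    n_dropped = 0
    for name, members in sets.sets.items():
        inter = members & universe
        if len(inter) < min_set_size:
            n_dropped += 1
        else:
            kept_sets[name] = inter
    N = len(universe)
    rows = []
    for m, mg in module_genes.items():
        for name, sg in kept_sets.items():
            k = len(mg & sg)
            rows.append(
                {
                    "module": m,
                    "set": name,
                    "category": sets.categories.get(name, ""),
                    "overlap": k,
                    "module_size": len(mg),
                    "set_size": len(sg),
                    "universe_size": N,
                    "p_value": hypergeom_test(k, len(mg), len(sg), N),
                }
            )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["fdr"] = bh_fdr(table["p_value"])
        table["significant"] = table["fdr"] < fdr_threshold
    return table, n_dropped


def _rank_sum_p(
    module_ranks: np.ndarray, random_rank_matrix: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-sided rank-sum (Mann-Whitney, normal approximation)
    of one module against many random sets of the same size.

    Returns (p_module_greater, p_module_less) per random set.  Ties (a
    module gene drawn into a random set) contribute 1/2 to U.
    """
    s = module_ranks.size
    m_sorted = np.sort(module_ranks)
    gt = s - np.searchsorted(m_sorted, random_rank_matrix, side="right")
    ge = s - np.searchsorted(m_sorted, random_rank_matrix, side="left")
    ties = ge - gt
    U = gt.sum(axis=1) + 0.5 * ties.sum(axis=1)  # pairs where module > random
    mu = s * s / 2.0
    sigma = np.sqrt(s * s * (2 * s + 1) / 12.0)
    z = (U - mu) / sigma
    return stats.norm.sf(z), stats.norm.cdf(z)


def packaging_test(
    scores: Mapping,
    part: ModulePartition,
    n_random: int = 1000,
    alpha: float = 0.01,
    frac: float = 0.85,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank-based permutation test for preferential packaging per module.

    Genes are ranked ascending by the robust z-score of their signal
    (rank 1 = lowest).  For each module, ``n_random`` random gene sets of
    the same size are drawn from the full scored universe and compared to
    the module by one-sided rank-sum tests in both directions at level
    ``alpha``.  Verdict "packaged": the module is significantly greater
    than at least ``frac * n_random`` random sets and no random set is
    significantly greater than the module; "excluded" is the mirror
    criterion; otherwise "neutral".  Rank-based, hence invariant to any
    strictly monotone transform of the scores.
    """
    score_s = pd.Series(dict(scores), dtype=float)
    missing = [g for m in part.module_labels for g in part.members(m)
               if g not in score_s.index]
    if missing:
        raise ValidationError(f"genes without scores: {sorted(missing)[:5]}")
    med = score_s.median()
    mad = (score_s - med).abs().median()
    robust = (score_s - med) / mad if mad > 0 else score_s - med
    ranks = pd.Series(stats.rankdata(robust.to_numpy()), index=score_s.index)
    N = len(ranks)
    rng = np.random.default_rng(seed)
    rows = []
    for m in part.module_labels:
        members = part.members(m)
        s = len(members)
        if s > N / 2:
            warnings.warn(
                f"module {m} covers more than half the universe; "
                "the rank-sum comparison loses power",
                stacklevel=2,
            )
        mranks = ranks.loc[members].to_numpy()
        idx = np.argsort(rng.random((n_random, N)), axis=1)[:, :s]
        rvals = ranks.to_numpy()[idx]
        p_greater, p_less = _rank_sum_p(mranks, rvals)
        n_sig_lower = int((p_greater < alpha).sum())   # module above random set
        n_sig_greater = int((p_less < alpha).sum())    # random set above module
        median_rank = float(np.median(mranks))
        if n_sig_lower >= frac * n_random and n_sig_greater == 0:
            verdict = "packaged"
        elif n_sig_greater >= frac * n_random and n_sig_lower == 0:
            verdict = "excluded"
        else:
            verdict = "neutral"
        rows.append(
            {
                "module": m,
                "module_size": s,
                "median_rank": median_rank,
                "count_significantly_lower": n_sig_lower,
                "count_significantly_greater": n_sig_greater,
                "n_random": n_random,
                "verdict": verdict,
            }
        )
    return pd.DataFrame(rows).set_index("module")
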