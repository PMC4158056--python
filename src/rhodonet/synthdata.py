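"""Synthetic two-species expression data with planted module structure.

The generator emulates the data regime of a bacterial comparative
co-expression study: a reference species A with a few thousand genes
measured over a few dozen conditions, a test species B sharing a
one-to-one ortholog subset, planted co-expression modules (each member
gene g of module m is rho * e_m + sqrt(1 - rho^2) * noise for a latent
standard-normal module profile e_m), a small proteomics-like layer with
missing values, and a per-gene packaging signal with one module shifted.

Modules flagged preserved keep their membership in species B (with a
fresh latent profile over B's own conditions); for non-preserved modules
the membership signal is destroyed in B while the module-size spectrum is
held constant: fresh groups of the same sizes are drawn from the pool of
non-preserved-module and background genes, so connectivity and density
differences are not confounded with size.  All layers are deterministic
functions of (spec, seed) via fixed per-layer substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExprMatrix, OrthologMap, ValidationError

_STREAM_A = 1
_STREAM_B = 2
_STREAM_ORTHO = 3
_STREAM_PROTEOME = 4
_STREAM_PACKAGING = 5


@dataclass
class SynthSpec:
    """Parameters of the synthetic two-species scenario.

    Defaults mirror the study regime this package targets: ~1500 genes over
    30 (species A) and 40 (species B) conditions, a module-size spectrum
    from 15 to 300 genes, ~60% of genes in one-to-one orthologs, a
    1000-protein x 6-condition proteomics layer with missing values, and a
    +3 MAD packaging shift on one module.
    """

    n_genes_A: int = 1500
    n_conditions_A: int = 30
    n_conditions_B: int = 40
    module_sizes: list[int] = field(
        default_factory=lambda: [300, 150, 100, 80, 60, 40, 40, 25, 20, 15]
    )
    preserved_flags: list[bool] = field(
        default_factory=lambda: [True, True, False, True, False,
                                 True, False, True, False, True]
    )
    within_module_cor: float = 0.8
    background_fraction: float = 0.35
    ortholog_fraction: float = 0.6
    proteome_n_genes: int = 1000
    proteome_n_conditions: int = 6
    proteome_noise_sd: float = 0.5
    proteome_missing_rate: float = 0.1
    packaging_shift: float = 3.0
    packaged_module: int | None = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.preserved_flags) != len(self.module_sizes):
            raise ValidationError(
                "preserved_flags must have one entry per module"
            )
        if any(s < 2 for s in self.module_sizes):
            raise ValidationError("all module_sizes must be >= 2")
        if sum(self.module_sizes) > self.n_genes_A:
            raise ValidationError("sum(module_sizes) exceeds n_genes_A")
        if not 0 < self.within_module_cor < 1:
            raise ValidationError("within_module_cor must lie in (0, 1)")
        if not 0 <= self.background_fraction <= 1:
            raise ValidationError("background_fraction must lie in [0, 1]")
        if sum(self.module_sizes) > (1 - self.background_fraction) * self.n_genes_A + 1e-9:
            raise ValidationError(
                "module_sizes leave less than background_fraction of genes "
                "unplanted"
            )
        if not 0 < self.ortholog_fraction <= 1:
            raise ValidationError("ortholog_fraction must lie in (0, 1]")
        if self.proteome_n_conditions > self.n_conditions_A:
            raise ValidationError(
                "proteome_n_conditions exceeds n_conditions_A"
            )
        if not 0 <= self.proteome_missing_rate < 1:
            raise ValidationError("proteome_missing_rate must lie in [0, 1)")
        if self.proteome_noise_sd < 0:
            raise ValidationError("proteome_noise_sd must be >= 0")
        if self.packaged_module is not None and self.module_sizes:
            if not 1 <= self.packaged_module <= len(self.module_sizes):
                raise ValidationError(
                    f"packaged_module {self.packaged_module} does not exist"
                )


@dataclass
class SynthTruth:
    """Ground truth of a generated scenario."""

    module_of_gene: dict  # gene id -> module label (0 = background), species A
    preserved: dict[int, bool]
    ortholog_pairs: list[tuple]
    packaged_module: int | None
    module_of_gene_B: dict = field(default_factory=dict)

    def labels_series(self) -> pd.Series:
        return pd.Series(self.module_of_gene, dtype=int)


def _rng(spec: SynthSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, spec.seed])


def _planted_matrix(
    rng: np.random.Generator,
    n_conditions: int,
    groups: dict[int, np.ndarray],
    n_genes: int,
    rho: float,
) -> np.ndarray:
    """Genes x conditions: group members share a latent profile at
    correlation rho, everything else is standard-normal noise."""
    X = rng.standard_normal((n_genes, n_conditions))
    for label, idx in groups.items():
        profile = rng.standard_normal(n_conditions)
        X[idx] = rho * profile[None, :] + np.sqrt(1 - rho**2) * X[idx]
    return X


def gen_two_species(
    spec: SynthSpec,
) -> tuple[ExprMatrix, ExprMatrix, OrthologMap, SynthTruth]:
    """Generate species A and B expression, the ortholog map and truth."""
    n = spec.n_genes_A
    genes_a = [f"gA{i:05d}" for i in range(n)]
    rng_a = _rng(spec, _STREAM_A)

    if spec.background_fraction == 1.0:
        sizes: list[int] = []
        flags: list[bool] = []
    else:
        sizes = list(spec.module_sizes)
        flags = list(spec.preserved_flags)

    # planted membership in A: a seeded shuffle decides which genes are
    # module members, so membership is not confounded with gene order
    order = rng_a.permutation(n)
    labels_a = np.zeros(n, dtype=int)
    pos = 0
    groups_a: dict[int, np.ndarray] = {}
    for m, s in enumerate(sizes, start=1):
        idx = order[pos : pos + s]
        labels_a[idx] = m
        groups_a[m] = np.sort(idx)
        pos += s

    XA = _planted_matrix(rng_a, spec.n_conditions_A, groups_a, n,
                         spec.within_module_cor)
    exprA = ExprMatrix(
        pd.DataFrame(
            XA, index=genes_a,
            columns=[f"condA{j:02d}" for j in range(spec.n_conditions_A)],
        ),
        standardization="averaged",
    )

    # ortholog subset
    rng_o = _rng(spec, _STREAM_ORTHO)
    n_orth = int(round(spec.ortholog_fraction * n))
    orth_pos = np.sort(rng_o.choice(n, size=n_orth, replace=False))
    pairs = [(genes_a[i], f"gB{i:05d}") for i in orth_pos]
    mapping = OrthologMap(pd.DataFrame(pairs, columns=["ref", "test"]))

    # species B structure over the ortholog genes
    rng_b = _rng(spec, _STREAM_B)
    genes_b = [b for _, b in pairs]
    a_of_b = {b: a for a, b in pairs}
    pos_of_a = {g: i for i, g in enumerate(genes_a)}
    labels_b = np.zeros(n_orth, dtype=int)

    preserved = {m: bool(f) for m, f in zip(range(1, len(sizes) + 1), flags)}
    groups_b: dict[int, np.ndarray] = {}
    nonpreserved_pool: list[int] = []
    nonpreserved_sizes: dict[int, int] = {}
    for i, b in enumerate(genes_b):
        m = int(labels_a[pos_of_a[a_of_b[b]]])
        if m != 0 and preserved.get(m, False):
            labels_b[i] = m
        elif m != 0:
            nonpreserved_pool.append(i)
            nonpreserved_sizes[m] = nonpreserved_sizes.get(m, 0) + 1
        else:
            nonpreserved_pool.append(i)
    for m in sorted(set(labels_b) - {0}):
        groups_b[m] = np.nonzero(labels_b == m)[0]
    # re-partition: fresh groups of the original (ortholog-restricted)
    # sizes drawn from the non-preserved + background pool
    pool = np.array(nonpreserved_pool, dtype=int)
    pool = pool[rng_b.permutation(len(pool))]
    pos2 = 0
    next_label = len(sizes) + 1
    for m in sorted(nonpreserved_sizes):
        s = nonpreserved_sizes[m]
        groups_b[next_label] = np.sort(pool[pos2 : pos2 + s])
        pos2 += s
        next_label += 1

    XB = _planted_matrix(rng_b, spec.n_conditions_B, groups_b, n_orth,
                         spec.within_module_cor)
    exprB = ExprMatrix(
        pd.DataFrame(
            XB, index=genes_b,
            columns=[f"condB{j:02d}" for j in range(spec.n_conditions_B)],
        ),
        standardization="averaged",
    )

    labels_b_full = np.zeros(n_orth, dtype=int)
    for m, idx in groups_b.items():
        labels_b_full[idx] = m
    module_of_gene_B = {b: int(l) for b, l in zip(genes_b, labels_b_full)}
    truth = SynthTruth(
        module_of_gene={g: int(l) for g, l in zip(genes_a, labels_a)},
        preserved=preserved,
        ortholog_pairs=pairs,
        packaged_module=spec.packaged_module if sizes else None,
        module_of_gene_B=module_of_gene_B,
    )
    return exprA, exprB, mapping, truth


def gen_proteomics(exprA: ExprMatrix, spec: SynthSpec) -> ExprMatrix:
    """Proteomics-like layer: a gene and condition subset of species A with
    added Gaussian noise and missing-at-random entries."""
    if spec.proteome_n_conditions > exprA.n_conditions:
        raise ValidationError("proteome condition subset larger than source")
    rng = _rng(spec, _STREAM_PROTEOME)
    n_genes = min(spec.proteome_n_genes, exprA.n_genes)
    gpick = np.sort(rng.choice(exprA.n_genes, size=n_genes, replace=False))
    cpick = np.sort(
        rng.choice(exprA.n_conditions, size=spec.proteome_n_conditions,
                   replace=False)
    )
    sub = exprA.data.iloc[gpick, cpick].copy()
    if spec.proteome_noise_sd > 0:
        sub += spec.proteome_noise_sd * rng.standard_normal(sub.shape)
    if spec.proteome_missing_rate > 0:
        mask = rng.random(sub.shape) < spec.proteome_missing_rate
        sub = sub.mask(mask)
    sub.index = [g.replace("gA", "pA") for g in sub.index]
    return ExprMatrix(sub, standardization="averaged")


def gen_packaging_signal(truth: SynthTruth, spec: SynthSpec) -> pd.Series:
    """Per-gene packaging signal: standard-normal background with the
    packaged module's genes shifted by ``packaging_shift``."""
    labels = truth.labels_series()
    target = spec.packaged_module
    if target is not None and target not in set(labels.unique()):
        raise ValidationError(f"packaged module {target} not present in truth")
    rng = _rng(spec, _STREAM_PACKAGING)
    scores = pd.Series(rng.standard_normal(len(labels)), index=labels.index)
    if target is not None and spec.packaging_shift != 0:
        scores[labels == target] += spec.packaging_shift
    return scores
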