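"""End-to-end orchestration: simulate -> preprocess -> network ->
preservation -> LNS -> enrichment/packaging, with a JSON manifest.

Every stage output is a commented TSV under the run directory; the
manifest records the tool version, the seed, all parameters and a sha256
digest of each artifact, so a rerun with the same configuration can be
compared file-by-file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .containers import (
    ExprMatrix,
    GeneSetCollection,
    ModulePartition,
    OrthologMap,
    ValidationError,
)
from .genesets import ora, packaging_test
from .lns import (
    atanh_corr,
    lns_all,
    lns_null,
    lns_vs_kmeall,
    median_lns_per_module,
    within_species_lns,
)
from .network import NetworkParams, bicor_matrix, detect_modules, module_stability
from .preprocess import central_tendency_normalize, filter_missing, robust_z, zscore
from .preservation import module_preservation, restrict_to_common
from .synthdata import SynthSpec, gen_packaging_signal, gen_proteomics, gen_two_species

log = logging.getLogger("rhodonet")


@dataclass
class RunConfig:
    """Parameters of a full synthetic-scenario pipeline run."""

    synth: SynthSpec = field(default_factory=SynthSpec)
    network: NetworkParams = field(default_factory=NetworkParams)
    n_perm_preservation: int = 200
    lns_n_perm: int = 100
    lns_n_rep: int = 0  # within-species split-half repeats (0 = skip)
    n_random_packaging: int = 1000
    packaging_alpha: float = 0.01
    packaging_frac: float = 0.85
    n_stability: int = 0  # module-stability resamples (0 = skip)
    n_random_sets_ora: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        # one global seed drives every stochastic stage
        self.synth.seed = self.seed
        self.network.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = SynthSpec(**raw.pop("synth", {}))
        network = NetworkParams(**raw.pop("network", {}))
        return cls(synth=synth, network=network, **raw)

    def digest(self) -> str:
        payload = {"synth": asdict(self.synth), "network": asdict(self.network)}
        payload.update(
            {
                k: v
                for k, v in asdict(self).items()
                if k not in ("synth", "network")
            }
        )
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _truth_gene_sets(truth, n_random: int, rng) -> GeneSetCollection:
    """Gene sets for the synthetic ORA stage: one set per planted module
    plus random decoy sets of matching sizes."""
    sets, cats = {}, {}
    labels = truth.labels_series()
    genes = np.asarray(labels.index, dtype=object)
    for m in sorted(set(labels) - {0}):
        sets[f"planted_module_{m}"] = set(labels.index[labels == m])
        cats[f"planted_module_{m}"] = "pathway"
    sizes = [len(s) for s in sets.values()] or [20]
    for i in range(n_random):
        size = sizes[i % len(sizes)]
        pick = rng.choice(len(genes), size=size, replace=False)
        sets[f"random_set_{i}"] = set(genes[pick])
        cats[f"random_set_{i}"] = "pathway"
    return GeneSetCollection(sets, cats)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    digest = config.digest()
    header = io.format_header(seed=config.seed, params_digest=digest)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "params_digest": digest,
        "stages": [],
        "outputs": {},
    }

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"].append(name)

    def persist(name, writer, obj, with_header=True, **kw):
        path = out / name
        if with_header:
            writer(obj, path, header, **kw)
        else:
            writer(obj, path, **kw)
        manifest["outputs"][name] = _sha256(path)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")

            stage("simulate")
            exprA, exprB, mapping, truth = gen_two_species(config.synth)
            proteome = gen_proteomics(exprA, config.synth)
            packaging = gen_packaging_signal(truth, config.synth)
            persist("exprA.tsv", io.write_expr_tsv, exprA)
            persist("exprB.tsv", io.write_expr_tsv, exprB)
            persist("orthologs.tsv", io.write_orthologs_tsv, mapping)
            persist("proteome.tsv", io.write_expr_tsv, proteome)
            persist("packaging.tsv", io.write_scores_tsv, packaging)
            persist("truth.json", io.write_truth_json, truth, with_header=False)

            stage("preprocess")
            zA, _ = robust_z(exprA)
            zB, _ = robust_z(exprB)
            prot = central_tendency_normalize(proteome)
            prot, _ = filter_missing(prot, max_missing=2)
            prot_f, _ = zscore(prot)
            persist("exprA.robust_z.tsv", io.write_expr_tsv, zA)
            persist("exprB.robust_z.tsv", io.write_expr_tsv, zB)
            persist("proteome.z.tsv", io.write_expr_tsv, prot_f)

            stage("network")
            part, megs, kmat = detect_modules(zA, config.network)
            persist("partition.tsv", io.write_partition_tsv, part)
            persist(
                "eigengenes.tsv",
                io.write_table_tsv,
                megs.profiles.rename(columns=str),
            )
            persist("kme.tsv", io.write_table_tsv, kmat.rename(columns=str))
            if config.n_stability >= 2:
                stab = module_stability(zA, config.network, config.n_stability)
                persist("stability.tsv", io.write_table_tsv, stab.table)

            stage("preservation")
            refc, testc, partc = restrict_to_common(zA, zB, mapping, part)
            report = module_preservation(
                refc, testc, partc, config.network,
                n_perm=config.n_perm_preservation, seed=config.seed,
            )
            persist("preservation_B.tsv", io.write_table_tsv,
                    report.preservation, index_label="module")
            persist("quality_B.tsv", io.write_table_tsv, report.quality,
                    index_label="module")

            # mRNA-protein preservation within species A
            prot_map = OrthologMap(
                pd.DataFrame(
                    {
                        "ref": [g.replace("pA", "gA") for g in prot_f.gene_ids],
                        "test": prot_f.gene_ids,
                    }
                )
            )
            refp, testp, partp = restrict_to_common(zA, prot_f, prot_map, part)
            report_p = module_preservation(
                refp, testp, partp, config.network,
                n_perm=config.n_perm_preservation, seed=config.seed + 1,
                min_obs=2,
            )
            persist("preservation_proteome.tsv", io.write_table_tsv,
                    report_p.preservation, index_label="module")

            stage("lns")
            WA = atanh_corr(bicor_matrix(refc))
            WB = atanh_corr(bicor_matrix(testc))
            ident = OrthologMap.identity(refc.gene_ids)
            lns_table, null = lns_null(
                WA, WB, ident, n_perm=config.lns_n_perm, seed=config.seed + 2
            )
            medians = median_lns_per_module(lns_table, partc)
            lns_table["module"] = part.labels.reindex(
                lns_table["ref_gene"]
            ).to_numpy()
            persist("lns.tsv", io.write_table_tsv, lns_table)
            persist("median_lns.tsv", io.write_table_tsv,
                    medians.rename("median_lns").to_frame(),
                    index_label="module")
            try:
                r, p, paired = lns_vs_kmeall(medians, report.preservation)
                manifest["lns_vs_kmeall"] = {"r": r, "p": p}
            except ValidationError:
                manifest["lns_vs_kmeall"] = None
            if config.lns_n_rep > 0:
                per_gene, _ = within_species_lns(
                    zA, n_rep=config.lns_n_rep, seed=config.seed + 3
                )
                persist("within_species_lns.tsv", io.write_table_tsv,
                        per_gene.rename("mean_lns").to_frame(),
                        index_label="gene")

            stage("genesets")
            rng = np.random.default_rng(config.seed + 4)
            sets = _truth_gene_sets(truth, config.n_random_sets_ora, rng)
            universe = set(exprA.gene_ids)
            enr, _ = ora(part, sets, universe)
            persist("enrichment.tsv", io.write_table_tsv, enr)
            pack = packaging_test(
                packaging.to_dict(), part,
                n_random=config.n_random_packaging,
                alpha=config.packaging_alpha,
                frac=config.packaging_frac,
                seed=config.seed + 5,
            )
            persist("packaging_verdicts.tsv", io.write_table_tsv, pack,
                    index_label="module")
    except Exception as exc:
        manifest["failed_stage"] = manifest["stages"][-1] if manifest["stages"] else None
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
        raise

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest
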