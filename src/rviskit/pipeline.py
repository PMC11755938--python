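"""End-to-end pipeline: simulate -> qc -> rvis -> stats -> gsea -> overlap.

Stages are plain functions over files so that `run-all` output is
byte-identical to running the subcommands manually in order.  All
randomness flows from one global seed via per-stage derived seeds
(stage-name hashed), so adding a stage does not shift the streams of the
others.  Every written artifact lands in a JSON manifest with its
SHA-256, producing a reproducibility record.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
import yaml

from . import enrichment as enr
from . import liftover as lo
from . import qc as qcmod
from . import rvis as rvismod
from . import stats as statsmod
from . import synthetic as synth

log = logging.getLogger("rviskit")

EXIT_MISSING_INPUT = 3
EXIT_BAD_CONFIG = 4
EXIT_STAGE_FAILURE = 5


class MissingInputError(FileNotFoundError):
    pass


class ConfigError(ValueError):
    pass


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    workdir: pathlib.Path
    seed: int = 0
    qual_min: float = 30.0
    depth_min: int = 10
    depth_max: int = 50
    maf_threshold: float = rvismod.DEFAULT_MAF_THRESHOLD
    outlier_threshold: float = rvismod.DEFAULT_OUTLIER_THRESHOLD
    residual_flavor: str = "external"
    tail_fraction: float = 0.02
    n_perm: int = 2000
    simulate: Optional[dict] = None  # SimConfig overrides, or None to skip
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = pathlib.Path(path)
        if not path.exists():
            raise MissingInputError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        if "workdir" not in raw:
            raise ConfigError("config must define 'workdir'")
        raw["workdir"] = pathlib.Path(raw["workdir"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"bad config key: {exc}") from exc

    def validate(self) -> None:
        if self.depth_min > self.depth_max:
            raise ConfigError("depth_min exceeds depth_max")
        if not 0 < self.tail_fraction < 1:
            raise ConfigError("tail_fraction must be in (0, 1)")
        if self.n_perm < 100:
            raise ConfigError("n_perm must be >= 100")
        if self.outlier_threshold <= 0:
            raise ConfigError("outlier_threshold must be positive")


def _sha256(path: pathlib.Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class Manifest:
    seed: int
    artifacts: list = field(default_factory=list)

    def record(self, stage: str, path: pathlib.Path, **params) -> None:
        self.artifacts.append(
            {
                "stage": stage,
                "file": str(path.name),
                "sha256": _sha256(path),
                "parameters": params,
            }
        )

    def write(self, path: pathlib.Path) -> None:
        path.write_text(
            json.dumps({"seed": self.seed, "artifacts": self.artifacts},
                       indent=2, sort_keys=True) + "\n"
        )


def _require(path: pathlib.Path, what: str) -> pathlib.Path:
    if not pathlib.Path(path).exists():
        raise MissingInputError(f"{what} not found: {path}")
    return pathlib.Path(path)


def stage_simulate(config: PipelineConfig, manifest: Manifest) -> synth.SimBundle:
    overrides = dict(config.simulate or {})
    overrides.setdefault("seed", derive_seed(config.seed, "simulate"))
    if "set_specs" in overrides:
        overrides["set_specs"] = tuple(
            synth.SetSpec(**s) for s in overrides["set_specs"]
        )
    if "qc_noise" in overrides:
        overrides["qc_noise"] = synth.QCNoise(**overrides["qc_noise"])
    sim = synth.SimConfig(**overrides)
    bundle = synth.generate_catalog(sim, config.workdir / "bundle")
    for p in (bundle.vcf, bundle.gene_models, bundle.disease_variants,
              bundle.damaging_variants, bundle.chain, bundle.truth):
        manifest.record("simulate", p, seed=sim.seed)
    for p in bundle.gene_sets.values():
        manifest.record("simulate", p, seed=sim.seed)
    log.info("simulate: bundle written to %s", bundle.root)
    return bundle


def stage_qc(config: PipelineConfig, vcf_path, out_dir, manifest: Manifest
             ) -> tuple[list, qcmod.QCSummary]:
    vcf_path = _require(vcf_path, "variant catalog VCF")
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = list(qcmod.read_catalog(vcf_path))
    retained, summary = qcmod.qc_filter(
        records, qual_min=config.qual_min, depth_min=config.depth_min,
        depth_max=config.depth_max,
    )
    report = out_dir / "qc_summary.tsv"
    report.write_text(qcmod.summarize_qc(summary))
    manifest.record("qc", report, qual_min=config.qual_min,
                    depth_min=config.depth_min, depth_max=config.depth_max)
    log.info("qc: %d/%d records retained", summary.n_retained, summary.n_input)
    return retained, summary


def stage_rvis(config: PipelineConfig, retained, gene_models_path, out_dir,
               manifest: Manifest) -> rvismod.RVISTable:
    gene_models = synth.read_gene_models(
        _require(gene_models_path, "gene models table")
    )
    counts = rvismod.count_gene_variants(
        retained, gene_models, maf_threshold=config.maf_threshold
    )
    table = rvismod.compute_rvis(counts, residual_flavor=config.residual_flavor)
    table = rvismod.remove_outliers(table, threshold=config.outlier_threshold)
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    out = out_dir / "rvis.tsv"
    rvismod.write_rvis_table(table, out)
    manifest.record("rvis", out, maf_threshold=config.maf_threshold,
                    outlier_threshold=config.outlier_threshold,
                    residual_flavor=config.residual_flavor)
    log.info("rvis: fitted %d genes (slope %.4f)", table.n_genes_fit, table.slope)
    return table


def _load_sets(set_paths) -> list[statsmod.GeneSet]:
    sets = []
    for p in set_paths:
        sets.append(statsmod.GeneSet.from_file(p))
    if not sets:
        raise MissingInputError("no gene-set files given")
    return sets


def stage_stats(config: PipelineConfig, table: rvismod.RVISTable, set_paths,
                out_dir, manifest: Manifest) -> pd.DataFrame:
    scores = table.scores()
    results = [statsmod.gene_set_constraint_test(scores, gs)
               for gs in _load_sets(set_paths)]
    df = statsmod.results_table(results)
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    out = out_dir / "set_stats.tsv"
    df.to_csv(out, sep="\t", index=False)
    manifest.record("stats", out)
    return df


def stage_gsea(config: PipelineConfig, table: rvismod.RVISTable, set_paths,
               out_dir, manifest: Manifest) -> tuple[pd.DataFrame, pd.DataFrame]:
    ranked = enr.rank_genes(table.scores())
    seed = derive_seed(config.seed, "gsea")
    es_rows, over_rows = [], []
    for gs in _load_sets(set_paths):
        es_rows.append(enr.permutation_pvalue(ranked, gs, n_perm=config.n_perm,
                                              seed=seed))
        over_rows.append(
            enr.hypergeometric_overrep(ranked, gs, fraction=config.tail_fraction)
        )
    es_df = enr.enrichment_table(es_rows)
    over_df = enr.enrichment_table(over_rows)
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    es_path, over_path = out_dir / "gsea.tsv", out_dir / "overrep.tsv"
    es_df.to_csv(es_path, sep="\t", index=False)
    over_df.to_csv(over_path, sep="\t", index=False)
    manifest.record("gsea", es_path, n_perm=config.n_perm, seed=seed,
                    tail_fraction=config.tail_fraction)
    manifest.record("gsea", over_path, tail_fraction=config.tail_fraction)
    return es_df, over_df


def stage_overlap(config: PipelineConfig, chain_path, damaging_path,
                  disease_path, set_paths, out_dir, manifest: Manifest
                  ) -> dict:
    index = lo.parse_chain(_require(chain_path, "chain file"))
    damaging = lo.read_damaging_table(_require(damaging_path, "damaging table"))
    disease = lo.read_disease_catalog(_require(disease_path, "disease catalog"))
    matches = lo.overlap_disease_variants(damaging, index, disease)
    report = lo.set_damage_report(_load_sets(set_paths), damaging)
    ranked = lo.rank_by_cadd(damaging)
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matches": out_dir / "disease_matches.tsv",
        "damage_report": out_dir / "set_damage_report.tsv",
        "cadd_top": out_dir / "cadd_top.tsv",
    }
    matches.to_csv(paths["matches"], sep="\t", index=False)
    report.to_csv(paths["damage_report"], sep="\t", index=False)
    ranked.to_csv(paths["cadd_top"], sep="\t", index=False)
    for p in paths.values():
        manifest.record("overlap", p)
    return {"matches": matches, "damage_report": report, "cadd_top": ranked}


def run_all(config: PipelineConfig) -> Manifest:
    """Run every stage in order; returns the manifest (also written).

    Any stage failure propagates after removing nothing: artifacts of
    completed stages are valid on their own.  Rerunning with identical
    config and inputs reproduces identical manifest hashes.
    """
    config.validate()
    workdir = pathlib.Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(seed=config.seed)

    bundle = stage_simulate(config, manifest)
    retained, _ = stage_qc(config, bundle.vcf, workdir / "qc", manifest)
    table = stage_rvis(config, retained, bundle.gene_models, workdir / "rvis",
                       manifest)
    set_paths = sorted(bundle.gene_sets.values())
    stage_stats(config, table, set_paths, workdir / "stats", manifest)
    stage_gsea(config, table, set_paths, workdir / "gsea", manifest)
    stage_overlap(config, bundle.chain, bundle.damaging_variants,
                  bundle.disease_variants, set_paths, workdir / "overlap",
                  manifest)
    manifest.write(workdir / "manifest.json")
    log.info("run-all complete: %d artifacts", len(manifest.artifacts))
    return manifest
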