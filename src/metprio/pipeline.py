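"""End-to-end orchestration: networks -> encoding -> PCA -> SVM -> ranking.

Stages communicate through serialized files when run via the CLI, so users
can substitute their own similarity matrices or embeddings at any stage;
:func:`run_study` is the in-memory equivalent used by tests and scripts.
All randomness derives from the single config seed, and every artifact is
written deterministically, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from ._errors import DataError, StageError
from . import assoc as assoc_mod
from . import gcn as gcn_mod
from . import networks as net_mod
from . import reduce as reduce_mod
from .assoc import AssociationSet, EvaluationReport
from .gcn import EncoderConfig
from .networks import DescriptorMatrix
from .reduce import DEFAULT_VARIANCE_THRESHOLD

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Full run configuration; serialized into the output directory."""

    descriptors: str = ""
    disease_similarity: str = ""
    associations: str = ""
    no_disease: str | None = None
    focal_disease: str = ""
    outdir: str = "metprio_out"
    mode: str = "SP"
    k: int = 10
    ratio: float = 1.0
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD
    combine: str = "concat"
    min_similarity: float | None = None
    clamp_negative: bool = False
    impute_missing: bool = False
    seed: int = 0
    encoder: EncoderConfig = field(default_factory=EncoderConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        enc = EncoderConfig(**raw.pop("encoder", {}))
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise DataError(f"unknown config fields: {sorted(unknown)}")
        return cls(encoder=enc, **raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def validate_paths(self) -> None:
        for name in ("descriptors", "disease_similarity", "associations"):
            p = getattr(self, name)
            if not p:
                raise DataError(f"config field {name!r} is required")
            if not Path(p).exists():
                raise DataError(f"config field {name!r}: no such file {p}")
        if self.no_disease is not None and not Path(self.no_disease).exists():
            raise DataError(f"config field 'no_disease': no such file {self.no_disease}")
        if not self.focal_disease:
            raise DataError("config field 'focal_disease' is required")


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds (< 2^31) derived from the config seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_study(
    desc: DescriptorMatrix,
    disease_table: list[tuple[str, str, float]],
    associations: AssociationSet,
    mode: str = "SP",
    k: int = 10,
    ratio: float = 1.0,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
    combine: str = "concat",
    encoder: EncoderConfig | None = None,
    seed: int = 0,
    min_similarity: float | None = None,
    clamp_negative: bool = False,
):
    """Run the whole method in memory.

    Returns ``(report, ranking, artifacts)`` where ``artifacts`` is a dict of
    every intermediate object (networks, embeddings, reduced features, pair
    dataset, final model).
    """
    enc_seed, pair_seed, cv_seed, dis_seed = _spawn_seeds(seed, 4)
    base_enc = encoder or EncoderConfig()

    t0 = time.perf_counter()
    met_net = net_mod.build_metabolite_network(
        desc, min_similarity=min_similarity, clamp_negative=clamp_negative)
    dis_net = net_mod.build_disease_network(disease_table, associations.focal_disease)
    logger.info("networks: %d metabolites, %d diseases (%.2fs)",
                met_net.n_nodes, dis_net.n_nodes, time.perf_counter() - t0)

    t0 = time.perf_counter()
    met_cfg = _with_seed(base_enc, enc_seed)
    dis_cfg = _with_seed(base_enc, dis_seed)
    met_emb = gcn_mod.encode_network(met_net, met_cfg)
    dis_emb = gcn_mod.encode_network(dis_net, dis_cfg)
    logger.info("encoded: metabolite %s, disease %s (%.2fs)",
                met_emb.values.shape, dis_emb.values.shape,
                time.perf_counter() - t0)

    met_red = reduce_mod.pca_reduce(met_emb, variance_threshold)
    dis_red = reduce_mod.pca_reduce(dis_emb, variance_threshold)
    logger.info("reduced: metabolite r=%d (%.4f), disease r=%d (%.4f)",
                met_red.r, met_red.explained_fraction,
                dis_red.r, dis_red.explained_fraction)

    ds = assoc_mod.make_pairs(associations, dis_red, met_red, mode=mode,
                              ratio=ratio, seed=pair_seed, combine=combine)
    report = assoc_mod.cross_validate(ds, k=k, seed=cv_seed)
    logger.info("cross-validation (%s, k=%d): pooled AUC %.4f, AUPR %.4f",
                mode, k, report.pooled_auc, report.pooled_aupr)

    model = assoc_mod.train_svm(ds)
    ranking = assoc_mod.rank_candidates(
        model, dis_red, met_red, associations.focal_disease,
        exclude=associations.focal_positives, combine=combine)

    artifacts = {
        "metabolite_network": met_net,
        "disease_network": dis_net,
        "metabolite_embedding": met_emb,
        "disease_embedding": dis_emb,
        "metabolite_reduced": met_red,
        "disease_reduced": dis_red,
        "pairs": ds,
        "model": model,
    }
    return report, ranking, artifacts


def _with_seed(cfg: EncoderConfig, seed: int) -> EncoderConfig:
    d = asdict(cfg)
    d["seed"] = seed
    return EncoderConfig(**d)


def run_pipeline(config: PipelineConfig) -> tuple[EvaluationReport, list]:
    """File-based pipeline run: read inputs, execute every stage, write all
    intermediate and final artifacts into ``config.outdir``."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except DataError as exc:
            raise StageError(name, str(exc)) from exc

    desc = stage("read-descriptors", net_mod.read_descriptor_matrix,
                 config.descriptors, impute_missing=config.impute_missing)
    table = stage("read-disease-similarity", net_mod.read_disease_similarity,
                  config.disease_similarity)
    associations = stage("read-associations", assoc_mod.read_association_list,
                         config.associations, config.focal_disease,
                         config.no_disease)

    report, ranking, art = stage(
        "run", run_study, desc, table, associations,
        mode=config.mode, k=config.k, ratio=config.ratio,
        variance_threshold=config.variance_threshold, combine=config.combine,
        encoder=config.encoder, seed=config.seed,
        min_similarity=config.min_similarity,
        clamp_negative=config.clamp_negative,
    )

    net_mod.write_network(art["metabolite_network"], outdir / "metabolite_network.tsv")
    net_mod.write_network(art["disease_network"], outdir / "disease_network.tsv")
    gcn_mod.write_embeddings(art["metabolite_embedding"], outdir / "metabolite_embeddings.tsv")
    gcn_mod.write_embeddings(art["disease_embedding"], outdir / "disease_embeddings.tsv")
    reduce_mod.write_reduced(art["metabolite_reduced"],
                             outdir / "metabolite_reduced.tsv",
                             outdir / "metabolite_reduced.json")
    reduce_mod.write_reduced(art["disease_reduced"],
                             outdir / "disease_reduced.tsv",
                             outdir / "disease_reduced.json")
    assoc_mod.write_report(report, outdir / "report.json",
                           outdir / "roc_curve.tsv", outdir / "pr_curve.tsv")
    assoc_mod.write_ranking(ranking, outdir / "ranking.tsv")
    config.to_yaml(outdir / "config_used.yaml")
    return report, ranking
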