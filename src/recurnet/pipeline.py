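"""Configuration-driven orchestration of the full synthetic study.

Stages hand off through plain-text files in the output directory so each one
is independently runnable and replaceable: simulate -> de -> diffcor -> ora ->
train -> evaluate -> qpcr. A manifest records every artifact's SHA-256, the
config snapshot and the seed; identical config + seed reproduces identical
hashes. All stage randomness derives from the single global seed through
fixed per-stage offsets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de as de_mod
from . import diffcor as dc
from . import metrics as ev
from . import nn
from . import ora as ora_mod
from . import qpcr as qpcr_mod
from . import simulate as sim
from .io import (
    read_counts_tsv,
    read_ct_csv,
    read_edges_tsv,
    read_gmt,
    read_json,
    read_meta_tsv,
    read_mirna_annotation,
    write_ct_csv,
    write_edges_tsv,
    write_gmt,
    write_json,
    write_meta_tsv,
    write_mirna_annotation,
)

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "de", "diffcor", "ora", "train", "evaluate", "qpcr")
_STAGE_SEED_OFFSET = {name: 101 + 17 * i for i, name in enumerate(ALL_STAGES)}

__all__ = ["PipelineConfig", "run_pipeline", "ALL_STAGES"]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs: paths, stage toggles, thresholds, seeds.

    The defaults are the bundled demo study: two cohorts of 30 samples per
    prognosis group, 5% planted DE features at fold change 4, 20 planted
    differentially-correlated miRNA-target pairs (latent rho 0.8 in BCR vs
    -0.2 in BRF) among 200 decoy catalog edges, a 6-predictor classifier
    benchmark, and a 31-sample qPCR validation set.
    """

    outdir: str = "results"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # simulation
    n_samples_per_group: int = 30
    n_mirna: int = 60
    n_mrna: int = 300
    frac_de: float = 0.05
    de_fc: float = 4.0
    n_planted_pairs: int = 20
    rho_bcr: float = 0.8
    rho_brf: float = -0.2
    n_decoy_edges: int = 200
    n_ppi_edges: int = 10
    n_tf_edges: int = 10
    # differential expression
    de_alpha: float = 0.05
    stability_median_log2cpm: float = 1.0
    stability_detection_rate: float = 0.8
    # differential correlation
    diffcor_alpha: float = 0.05
    diffcor_select_on: str = "fdr"
    diffcor_min_abs_delta: float = 0.0
    # pathway ORA
    ora_alpha: float = 0.05
    # classifier
    n_train_per_class: int = 100
    n_test_per_class: int = 100
    expression_effect: float = 1.5
    epochs: int = 200
    batch_size: int = 8
    learning_rate: float = 0.003
    # qPCR validation
    qpcr_n_bcr: int = 16
    qpcr_n_brf: int = 15
    qpcr_alpha: float = 0.05

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(s for s in ALL_STAGES if s in self.stages)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "stages" in doc:
            doc["stages"] = tuple(doc["stages"])
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["stages"] = list(doc["stages"])
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1_000_003 + _STAGE_SEED_OFFSET[stage]) % (2**31)

    def sim_config(self, cohort_offset: int = 0) -> sim.SimConfig:
        cfg = sim.SimConfig(
            n_samples_per_group=self.n_samples_per_group,
            n_mirna=self.n_mirna,
            n_mrna=self.n_mrna,
            frac_de=self.frac_de,
            de_fc=self.de_fc,
            n_decoy_edges=self.n_decoy_edges,
            n_ppi_edges=self.n_ppi_edges,
            n_tf_edges=self.n_tf_edges,
            seed=self.stage_seed("simulate") + cohort_offset,
        )
        mirnas, genes = cfg.mirna_ids(), cfg.mrna_ids()
        if self.n_planted_pairs > min(len(mirnas), len(genes)):
            raise ValueError("more planted pairs than available features")
        cfg.planted_pairs = [
            (mirnas[i], genes[i], self.rho_bcr, self.rho_brf)
            for i in range(self.n_planted_pairs)
        ]
        return cfg


def _require(outdir: Path, stage: str, *names: str) -> None:
    missing = [n for n in names if not (outdir / n).exists()]
    if missing:
        raise FileNotFoundError(
            f"stage '{stage}' needs upstream outputs missing from {outdir}: {missing}"
        )


def _stage_simulate(config: PipelineConfig, outdir: Path) -> list[str]:
    files: list[str] = []
    for cohort, offset in (("A", 0), ("B", 7919)):
        cfg = config.sim_config(offset)
        mirna, mrna, meta, truth = sim.generate_cohort(cfg)
        for name, obj in ((f"mirna_counts_{cohort}.tsv", mirna),
                          (f"mrna_counts_{cohort}.tsv", mrna)):
            obj.write_tsv(outdir / name)
            files.append(name)
        write_meta_tsv(meta, outdir / f"meta_{cohort}.tsv")
        truth.to_json(outdir / f"truth_{cohort}.json")
        files += [f"meta_{cohort}.tsv", f"truth_{cohort}.json"]
        if cohort == "A":
            catalog = sim.generate_interaction_catalog(truth, cfg)
            write_edges_tsv(catalog, outdir / "catalog.tsv")
            sets, annotation = sim.generate_gene_sets(cfg)
            write_gmt(sets, outdir / "gene_sets.gmt")
            write_mirna_annotation(annotation, outdir / "mirna_annotation.tsv")
            files += ["catalog.tsv", "gene_sets.gmt", "mirna_annotation.tsv"]

    # classifier benchmark table
    n_total = config.n_train_per_class + config.n_test_per_class
    x, y = sim.generate_predictor_table(
        n_per_class=n_total,
        expression_effect=config.expression_effect,
        seed=config.stage_seed("simulate") + 31337,
    )
    table = x.copy()
    table["label"] = y
    table.to_csv(outdir / "predictors.tsv", sep="\t", index_label="sample")
    files.append("predictors.tsv")

    # qPCR validation set: 4 gene assays (one null, mirroring a marker that
    # fails validation), 2 miRNA assays, plus the two reference assays
    rng = np.random.default_rng(config.stage_seed("simulate") + 4242)
    nq = config.qpcr_n_bcr + config.qpcr_n_brf
    yq = np.array([1] * config.qpcr_n_bcr + [0] * config.qpcr_n_brf)
    assays = {
        "ALDH3A2": -1.0,
        "CHKA": 0.0,
        "ODF2": 1.0,
        "QSOX2": 1.0,
        "miR-200b": 0.8,
        "miR-503": 0.8,
    }
    expr = pd.DataFrame(
        {a: 2.0 ** (eff * yq + 0.7 * rng.standard_normal(nq))
         for a, eff in assays.items()},
        index=[f"Q{i + 1:03d}" for i in range(nq)],
    )
    expr["RPN1"] = 1.0
    expr["miR-28"] = 1.0
    ct = sim.generate_ct_table(expr, config.sim_config(), rng=rng)
    write_ct_csv(ct, outdir / "ct_table.csv")
    qmeta = pd.DataFrame({"group": np.where(yq == 1, "BCR", "BRF")}, index=expr.index)
    write_meta_tsv(qmeta, outdir / "qpcr_meta.tsv")
    ref_map = {a: "miR-28" if a.startswith("miR") else "RPN1"
               for a in expr.columns}
    write_json(ref_map, outdir / "assay_references.json")
    files += ["ct_table.csv", "qpcr_meta.tsv", "assay_references.json"]
    return files


def _stage_de(config: PipelineConfig, outdir: Path) -> list[str]:
    _require(outdir, "de", "mirna_counts_A.tsv", "meta_A.tsv",
             "mirna_counts_B.tsv", "meta_B.tsv")
    results = {}
    cohorts = {}
    for cohort in ("A", "B"):
        counts = read_counts_tsv(outdir / f"mirna_counts_{cohort}.tsv")
        meta = read_meta_tsv(outdir / f"meta_{cohort}.tsv")
        res = de_mod.call_de(counts, meta, alpha=config.de_alpha)
        res.to_csv(outdir / f"de_mirna_{cohort}.tsv", sep="\t", index=False)
        results[cohort] = res
        cohorts[cohort] = (counts, meta)
    venn = de_mod.cross_cohort_de(results["A"], results["B"])
    stable = de_mod.expression_stability_filter(
        venn["shared"], cohorts,
        median_log2cpm=config.stability_median_log2cpm,
        detection_rate=config.stability_detection_rate,
    )
    write_json(
        {
            "shared": sorted(venn["shared"]),
            "shared_stable": sorted(stable),
            "n_up_a": len(venn["up_a"]),
            "n_down_a": len(venn["down_a"]),
            "n_up_b": len(venn["up_b"]),
            "n_down_b": len(venn["down_b"]),
        },
        outdir / "venn_summary.json",
    )
    return ["de_mirna_A.tsv", "de_mirna_B.tsv", "venn_summary.json"]


def _stage_diffcor(config: PipelineConfig, outdir: Path) -> list[str]:
    _require(outdir, "diffcor", "mirna_counts_A.tsv", "mrna_counts_A.tsv",
             "meta_A.tsv", "catalog.tsv")
    mirna = read_counts_tsv(outdir / "mirna_counts_A.tsv")
    mrna = read_counts_tsv(outdir / "mrna_counts_A.tsv")
    meta = read_meta_tsv(outdir / "meta_A.tsv")
    catalog = read_edges_tsv(outdir / "catalog.tsv")
    log_mirna = de_mod.cpm_matrix(mirna, de_mod.tmm_factors(mirna), log=True)
    log_mrna = de_mod.cpm_matrix(mrna, de_mod.tmm_factors(mrna), log=True)
    expr_all = pd.concat([log_mirna, log_mrna])
    pairs = catalog[catalog["edge_type"] == "miRNA-target"]
    corrs, skipped = dc.pair_correlations(log_mirna, log_mrna, meta, pairs)
    res = dc.differential_correlation_scan(
        corrs,
        alpha=config.diffcor_alpha,
        min_abs_delta=config.diffcor_min_abs_delta,
        select_on=config.diffcor_select_on,
    )
    res.to_csv(outdir / "diffcor.tsv", sep="\t", index=False)
    if skipped:
        pd.DataFrame(skipped).to_csv(outdir / "diffcor_skipped.tsv", sep="\t", index=False)

    annotations: dict[str, dict] = {}
    for cohort, flag in (("A", "de_cohortA"), ("B", "de_cohortB")):
        path = outdir / f"de_mirna_{cohort}.tsv"
        if path.exists():
            der = pd.read_csv(path, sep="\t")
            for r in der[der["is_DE"]].itertuples(index=False):
                annotations.setdefault(r.feature, {})[flag] = True
                annotations[r.feature]["direction"] = r.direction
    # annotate supplementary (non miRNA-target) catalog edges with correlations
    other = catalog[catalog["edge_type"] != "miRNA-target"]
    if len(other):
        extra_corrs, _ = dc.pair_correlations(expr_all, expr_all, meta, other)
        extra = dc.differential_correlation_scan(
            extra_corrs, alpha=config.diffcor_alpha,
            select_on=config.diffcor_select_on)
        res = pd.concat([res, extra], ignore_index=True)
    network = dc.build_network(res, catalog, annotations)
    dc.export_network(network, outdir / "network.graphml", "graphml")
    dc.export_network(network, outdir / "network.json", "json")
    dc.export_network(network, outdir / "network_edges.tsv", "tsv")
    dc.degree_table(network).to_csv(outdir / "network_degree.tsv", sep="\t", index=False)
    return ["diffcor.tsv", "network.graphml", "network.json",
            "network_edges.tsv", "network_degree.tsv"]


def _stage_ora(config: PipelineConfig, outdir: Path) -> list[str]:
    _require(outdir, "ora", "network.json", "gene_sets.gmt", "mirna_annotation.tsv")
    network = dc.import_network(outdir / "network.json", "json")
    query = set(network.nodes)
    if not query:
        log.warning("empty network; ORA skipped")
        write_json({"note": "empty query"}, outdir / "ora_empty.json")
        return ["ora_empty.json"]
    collection = ora_mod.GeneSetCollection(
        sets=read_gmt(outdir / "gene_sets.gmt"),
        mirna_members=read_mirna_annotation(outdir / "mirna_annotation.tsv"),
    )
    res = ora_mod.run_ora(query, collection, alpha=config.ora_alpha)
    res.to_csv(outdir / "ora.tsv", sep="\t", index=False)
    return ["ora.tsv"]


def _split_train_test(
    x: pd.DataFrame, y: np.ndarray, n_train_per_class: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    train_idx = []
    for cls in (0, 1):
        cls_idx = np.where(y == cls)[0]
        pick = rng.choice(cls_idx, size=n_train_per_class, replace=False)
        train_idx.append(pick)
    train = np.sort(np.concatenate(train_idx))
    mask = np.zeros(y.size, dtype=bool)
    mask[train] = True
    return mask, ~mask


def _stage_train(config: PipelineConfig, outdir: Path) -> list[str]:
    _require(outdir, "train", "predictors.tsv")
    table = pd.read_csv(outdir / "predictors.tsv", sep="\t", index_col=0)
    y = table.pop("label").to_numpy()
    if table.isna().any().any():
        raise ValueError("predictor table contains missing values")
    train_mask, test_mask = _split_train_test(
        table, y, config.n_train_per_class, config.stage_seed("train")
    )
    spec = nn.FCNNSpec(
        n_inputs=table.shape[1],
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        batch_size=config.batch_size,
        seed=config.stage_seed("train"),
    )
    model = nn.init_model(spec)
    nn.train_model(model, table.to_numpy()[train_mask], y[train_mask])
    model.save(outdir / "model.json")
    scores = nn.predict_proba(model, table.to_numpy())[:, 1]
    preds = pd.DataFrame(
        {
            "sample": table.index,
            "score": scores,
            "predicted": (scores > 0.5).astype(int),
            "label": y,
            "split": np.where(train_mask, "train", "test"),
        }
    )
    preds.to_csv(outdir / "predictions.tsv", sep="\t", index=False)
    return ["model.json", "predictions.tsv"]


def _stage_evaluate(config: PipelineConfig, outdir: Path) -> list[str]:
    _require(outdir, "evaluate", "predictions.tsv")
    preds = pd.read_csv(outdir / "predictions.tsv", sep="\t")
    rows = []
    roc_frames = []
    for split in ("test", "train"):
        sub = preds[preds["split"] == split]
        cm = ev.confusion_metrics(sub["predicted"], sub["label"])
        curve = ev.roc_auc(sub["score"].to_numpy(), sub["label"].to_numpy())
        rows.append(
            {
                "split": split,
                "Se": cm.sensitivity,
                "Sp": cm.specificity,
                "Ka": cm.kappa,
                "Pr": cm.precision,
                "AUC": curve.auc,
                "youden_threshold": ev.youden_threshold(curve),
            }
        )
        rf = curve.to_frame()
        rf.insert(0, "split", split)
        roc_frames.append(rf)
    pd.DataFrame(rows).to_csv(outdir / "metrics.tsv", sep="\t", index=False)
    pd.concat(roc_frames).to_csv(outdir / "roc.tsv", sep="\t", index=False)
    return ["metrics.tsv", "roc.tsv"]


def _stage_qpcr(config: PipelineConfig, outdir: Path) -> list[str]:
    _require(outdir, "qpcr", "ct_table.csv", "qpcr_meta.tsv", "assay_references.json")
    ct = read_ct_csv(outdir / "ct_table.csv")
    meta = read_meta_tsv(outdir / "qpcr_meta.tsv")
    ref_map = read_json(outdir / "assay_references.json")
    records = qpcr_mod.relative_expression(ct, ref_map)
    records.to_csv(outdir / "relative_expression.tsv", sep="\t", index=False)
    stats_ = qpcr_mod.qpcr_group_stats(
        records, meta, alpha=config.qpcr_alpha,
        exclude_assays=set(ref_map.values()),
    )
    stats_.to_csv(outdir / "qpcr_stats.tsv", sep="\t", index=False)
    return ["relative_expression.tsv", "qpcr_stats.tsv"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "de": _stage_de,
    "diffcor": _stage_diffcor,
    "ora": _stage_ora,
    "train": _stage_train,
    "evaluate": _stage_evaluate,
    "qpcr": _stage_qpcr,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    produced: list[str] = []
    for stage in config.stages:
        log.info("running stage %s", stage)
        try:
            produced += _STAGE_FUNCS[stage](config, outdir)
        except Exception:
            log.exception("stage %s failed", stage)
            raise
    manifest = {
        "seed": config.seed,
        "stages": list(config.stages),
        "config": {**dataclasses.asdict(config), "stages": list(config.stages)},
        "files": {name: _sha256(outdir / name) for name in produced},
    }
    write_json(manifest, outdir / "manifest.json")
    return manifest
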