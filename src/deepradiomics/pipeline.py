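"""End-to-end orchestration: simulate -> preprocess -> train/extract ->
normalize/cluster -> genomic features -> association scan -> classification.

A run is driven by one YAML config with per-stage sections.  Every stage
seed is derived deterministically from the global seed, every artifact is
written under the output directory with a SHA-256 checksum, and a JSON
manifest records files, seeds, package versions and stage wall times so a
run can be audited and reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import count_per_kernel, run_scan, top_features, top_gfs
from .classify import classify_clinical, classify_signatures
from .dae import DAEConfig, build_dae, extract_drfs, train_dae
from .features import (aggregate_patient, cluster_enrichment, hcluster,
                       quantile_normalize, tsne_embed)
from .genomics import GeneSet, assemble_gf_table, binarize_top_quartile
from .preprocess import scale_images, split_train_test
from .simulate import SimConfig, generate_cohort, write_cohort

__all__ = ["RunConfig", "run_pipeline", "make_report"]

logger = logging.getLogger(__name__)

REQUIRED_SECTIONS = ("sim", "preprocess", "dae", "features", "genomics",
                     "assoc", "classify")


@dataclass
class RunConfig:
    """Validated run configuration with per-stage sections."""

    seed: int
    outdir: str
    sections: dict[str, dict[str, Any]] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        for key in ("seed", "outdir"):
            if key not in data:
                raise ValueError(f"config missing required key: {key!r}")
        missing = [s for s in REQUIRED_SECTIONS if s not in data]
        if missing:
            raise ValueError(f"config missing section(s): {missing}")
        sections = {s: dict(data[s] or {}) for s in REQUIRED_SECTIONS}
        return cls(seed=int(data["seed"]), outdir=str(data["outdir"]),
                   sections=sections)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict[str, Any]:
        return {"seed": self.seed, "outdir": self.outdir, **self.sections}

    def stage_seed(self, stage: str) -> int:
        idx = REQUIRED_SECTIONS.index(stage)
        return (self.seed * 1000003 + 7919 * (idx + 1)) % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def minimal_config(outdir: str, seed: int = 0, n_patients: int = 10,
                   image_size: int = 32, epochs: int = 5) -> RunConfig:
    """A small, fast end-to-end configuration (smoke-test scale)."""
    return RunConfig.from_dict({
        "seed": seed,
        "outdir": outdir,
        "sim": {"n_patients": n_patients, "image_size": image_size,
                "images_per_patient_range": [3, 6], "n_risk_genes": 60,
                "n_planted_genes": 9, "effect_size": 1.0, "n_pathways": 5,
                "pathway_size_range": [5, 15]},
        "preprocess": {"ratio": 0.8, "group_by_patient": False},
        "dae": {"learning_rate": 1e-3, "epochs": epochs, "batch_size": 32},
        "features": {"k_clusters": 2, "tsne_perplexity": 2.0},
        "genomics": {"n_risk_gfs": 15, "n_signature_gfs": 2,
                     "n_pathway_gfs": 3, "alpha": 0.25},
        "assoc": {"alpha": 0.05, "bh_family": "category"},
        "classify": {"n_lambda": 20, "cv_folds": 3, "split_ratio": 0.7,
                     "backends": ["gradient-boosted-trees"]},
    })


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage, writing artifacts and a manifest under outdir.

    Any stage failure aborts with the stage name; artifacts from completed
    stages are left on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": config.to_dict(),
        "seeds": {s: config.stage_seed(s) for s in REQUIRED_SECTIONS},
        "versions": {"deepradiomics": __version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
        "files": {},
        "wall_times": {},
    }
    state: dict[str, Any] = {}

    def record(path: Path) -> None:
        manifest["files"][str(path.relative_to(outdir))] = _sha256(path)

    stages = [
        ("sim", _stage_sim), ("preprocess", _stage_preprocess),
        ("dae", _stage_dae), ("features", _stage_features),
        ("genomics", _stage_genomics), ("assoc", _stage_assoc),
        ("classify", _stage_classify),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            fn(config, state, outdir, record)
        except Exception as exc:  # persist prior outputs, name the stage
            _write_manifest(outdir, manifest)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["wall_times"][name] = round(time.perf_counter() - t0, 3)
    _write_manifest(outdir, manifest)
    return manifest


def _write_manifest(outdir: Path, manifest: dict[str, Any]) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _stage_sim(cfg: RunConfig, state: dict, outdir: Path, record) -> None:
    sec = dict(cfg.sections["sim"])
    for key in ("images_per_patient_range", "pathway_size_range"):
        if key in sec:
            sec[key] = tuple(sec[key])
    sim_cfg = SimConfig(seed=cfg.stage_seed("sim"), **sec)
    cohort = generate_cohort(sim_cfg)
    paths = write_cohort(cohort, outdir / "cohort")
    for p in paths.values():
        if p.is_file():
            record(p)
    state["cohort"] = cohort


def _stage_preprocess(cfg: RunConfig, state: dict, outdir: Path, record) -> None:
    sec = cfg.sections["preprocess"]
    cohort = state["cohort"]
    scaled = scale_images(cohort.images)
    train, test = split_train_test(
        scaled, ratio=sec.get("ratio", 0.8), seed=cfg.stage_seed("preprocess"),
        group_by_patient=sec.get("group_by_patient", False))
    manifest_df = pd.DataFrame(
        {"image_id": [r.image_id for r in scaled],
         "patient_id": [r.patient_id for r in scaled],
         "split": ["train" if r in train else "test" for r in scaled]})
    p = outdir / "split_manifest.tsv"
    manifest_df.to_csv(p, sep="\t", index=False)
    record(p)
    state.update(scaled=scaled, train=train, test=test)


def _stage_dae(cfg: RunConfig, state: dict, outdir: Path, record) -> None:
    sec = cfg.sections["dae"]
    sim_size = state["cohort"].images[0].pixels.shape[0]
    dae_cfg = DAEConfig(input_size=sec.get("input_size", sim_size),
                        learning_rate=sec.get("learning_rate", 1e-3),
                        batch_size=sec.get("batch_size", 64),
                        epochs=sec.get("epochs", 100),
                        noise_level=sec.get("noise_level", 0.05),
                        seed=cfg.stage_seed("dae"))
    model = build_dae(dae_cfg)
    report = train_dae(model, state["train"], validation_images=state["test"])
    model.save(outdir / "dae_weights.npz")
    loss = pd.DataFrame({"epoch": np.arange(1, len(report.train_mse) + 1),
                         "train_mse": report.train_mse,
                         "val_mse": report.val_mse or np.nan})
    p = outdir / "training_loss.tsv"
    loss.to_csv(p, sep="\t", index=False)
    record(p)
    drfs = extract_drfs(model, state["scaled"])
    drfs.to_tsv(outdir / "drfs_image_level.tsv", outdir / "kernel_map.tsv")
    record(outdir / "drfs_image_level.tsv")
    record(outdir / "kernel_map.tsv")
    state.update(model=model, drfs=drfs, train_report=report)


def _stage_features(cfg: RunConfig, state: dict, outdir: Path, record) -> None:
    sec = cfg.sections["features"]
    drfs = state["drfs"]
    norm_values = quantile_normalize(drfs.values)
    norm_frame = pd.DataFrame(norm_values, columns=drfs.feature_ids)
    norm_frame.insert(0, "patient_id", drfs.image_index["patient_id"].values)
    norm_frame.insert(0, "image_id", drfs.image_index["image_id"].values)
    p = outdir / "drfs_normalized.tsv"
    norm_frame.to_csv(p, sep="\t", index=False)
    record(p)

    patient_feats = aggregate_patient(norm_frame)
    p = outdir / "drfs_patient_level.tsv"
    patient_feats.to_csv(p, sep="\t")
    record(p)

    k = sec.get("k_clusters", 2)
    clusters = hcluster(patient_feats, k=k)
    clinical = state["cohort"].clinical.loc[patient_feats.index]
    enrichment = {}
    for label in clinical.columns:
        col = clinical[label]
        if col.notna().sum() and col.dropna().nunique() == 2:
            try:
                enrichment[label] = cluster_enrichment(
                    clusters.labels, col, seed=cfg.stage_seed("features"))
            except ValueError:
                continue
    clusters.enrichment = enrichment
    cl = pd.DataFrame({"patient_id": patient_feats.index,
                       "cluster": clusters.labels})
    p = outdir / "clusters.tsv"
    cl.to_csv(p, sep="\t", index=False)
    record(p)
    p = outdir / "cluster_enrichment.tsv"
    pd.Series(enrichment, name="fisher_p").rename_axis("label").to_csv(p, sep="\t")
    record(p)

    perp = sec.get("tsne_perplexity", 30.0)
    if patient_feats.shape[0] > 3 * perp:
        emb = tsne_embed(patient_feats, perplexity=perp,
                         seed=cfg.stage_seed("features"))
        ts = pd.DataFrame(emb, columns=["tsne1", "tsne2"],
                          index=patient_feats.index)
        p = outdir / "tsne_patient_level.tsv"
        ts.to_csv(p, sep="\t")
        record(p)
    state.update(norm_frame=norm_frame, patient_feats=patient_feats,
                 clusters=clusters)


def _stage_genomics(cfg: RunConfig, state: dict, outdir: Path, record) -> None:
    sec = cfg.sections["genomics"]
    cohort = state["cohort"]
    expr = cohort.expression
    rng = np.random.default_rng(cfg.stage_seed("genomics"))

    n_risk = min(sec.get("n_risk_gfs", 30), expr.shape[0])
    risk_ids = list(expr.index[:n_risk])

    n_sig = sec.get("n_signature_gfs", 2)
    sig_sets = {}
    for s in range(n_sig):
        genes = rng.choice(expr.index, size=min(10, expr.shape[0]),
                           replace=False)
        sig_sets[f"signature_{s + 1}"] = {
            g: float(w) for g, w in zip(genes, rng.normal(size=genes.size))}

    n_path = min(sec.get("n_pathway_gfs", 5), len(cohort.gene_sets))
    pathway_sets = [GeneSet(name, members) for name, members
                    in list(cohort.gene_sets.items())[:n_path]]

    gf_table = assemble_gf_table(expr, risk_ids, sig_sets, pathway_sets,
                                 alpha=sec.get("alpha", 0.25))
    p = outdir / "gf_table.tsv"
    gf_table.to_tsv(p)
    record(p)
    state["gf_table"] = gf_table
    state["signature_sets"] = sig_sets


def _stage_assoc(cfg: RunConfig, state: dict, outdir: Path, record) -> None:
    sec = cfg.sections["assoc"]
    from .dae import DRFMatrix
    norm = DRFMatrix.from_frame(state["norm_frame"],
                                kernel_map=state["drfs"].kernel_map)
    table = run_scan(norm, state["gf_table"], alpha=sec.get("alpha", 0.05),
                     bh_family=sec.get("bh_family", "category"))
    p = outdir / "associations.tsv"
    table.to_csv(p, sep="\t", index=False)
    record(p)
    p = outdir / "kernel_counts.tsv"
    count_per_kernel(table).to_csv(p, sep="\t")
    record(p)
    p = outdir / "top_features.tsv"
    top_features(table, k=30).to_csv(p, sep="\t", index=False)
    record(p)
    tg = top_gfs(table, k_per_category=5)
    p = outdir / "top_gfs.tsv"
    pd.concat([df.assign(category=cat) for cat, df in tg.items()],
              ignore_index=True).to_csv(p, sep="\t", index=False)
    record(p)
    state["assoc_table"] = table


def _stage_classify(cfg: RunConfig, state: dict, outdir: Path, record) -> None:
    sec = cfg.sections["classify"]
    cohort = state["cohort"]
    results = classify_clinical(
        state["norm_frame"], cohort.clinical, level="image",
        n_lambda=sec.get("n_lambda", 100), cv_folds=sec.get("cv_folds", 5),
        split_ratio=sec.get("split_ratio", 0.7),
        seed=cfg.stage_seed("classify"),
        group_by_patient=sec.get("group_by_patient", False))
    rows = []
    path_rows = []
    for label, res in results.items():
        rows.append((label, res.best_lambda, res.test_auc,
                     float(res.cv_auc.max())))
        for lam, nz, cv in zip(res.lambda_grid, res.n_nonzero, res.cv_auc):
            path_rows.append((label, lam, nz, cv))
    p = outdir / "clinical_auc.tsv"
    pd.DataFrame(rows, columns=["label", "best_lambda", "test_auc",
                                "best_cv_auc"]).to_csv(p, sep="\t", index=False)
    record(p)
    p = outdir / "lasso_paths.tsv"
    pd.DataFrame(path_rows, columns=["label", "lambda", "n_nonzero",
                                     "cv_auc"]).to_csv(p, sep="\t", index=False)
    record(p)

    # signature targets: binarize synthetic signature scores at the top quartile
    sig_cols = state["gf_table"].columns_of("signature")
    if sig_cols:
        patient_feats = state["patient_feats"]
        scores = state["gf_table"].values.loc[patient_feats.index, sig_cols]
        try:
            targets = scores.apply(binarize_top_quartile)
        except ValueError:
            targets = None
        if targets is not None:
            sig_rows = []
            for backend in sec.get("backends", ["gradient-boosted-trees"]):
                try:
                    res = classify_signatures(
                        patient_feats, targets, backend=backend,
                        split_ratio=sec.get("split_ratio", 0.7),
                        seed=cfg.stage_seed("classify"))
                    sig_rows.append(res)
                except ValueError as exc:
                    logger.warning("signature classification skipped: %s", exc)
            if sig_rows:
                p = outdir / "signature_auc.tsv"
                pd.concat(sig_rows, ignore_index=True).to_csv(
                    p, sep="\t", index=False)
                record(p)
    state["clinical_results"] = results


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------

def make_report(run_dir: str | Path) -> Path:
    """Assemble a Markdown report (with figures) from a completed run.

    Regeneration is idempotent; the report references only files recorded
    in the manifest.  An incomplete run raises with the missing artifacts.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json under {run_dir}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    files = manifest["files"]
    needed = ["drfs_image_level.tsv", "associations.tsv", "clinical_auc.tsv"]
    missing = [f for f in needed if f not in files]
    if missing:
        raise FileNotFoundError(f"incomplete run; missing artifacts: {missing}")

    lines = ["# Radiogenomic pipeline report", "",
             f"Seed: {manifest['config']['seed']}", ""]
    fig_dir = run_dir / "figures"
    fig_dir.mkdir(exist_ok=True)

    # kernel heatmaps of the first image
    from .dae import N_KERNELS, kernel_heatmap
    drf_df = pd.read_csv(run_dir / "drfs_image_level.tsv", sep="\t")
    feat_cols = [c for c in drf_df.columns if c.startswith("fea_")]
    input_size = int(4 * np.sqrt(len(feat_cols) / N_KERNELS))
    row = drf_df.iloc[0][feat_cols].to_numpy(dtype=float)
    fig, axes = plt.subplots(4, 4, figsize=(8, 8))
    for k, ax in enumerate(axes.ravel(), start=1):
        ax.imshow(kernel_heatmap(row, k, input_size), cmap="viridis")
        ax.set_title(f"kernel {k}", fontsize=7)
        ax.axis("off")
    fig.suptitle(f"Bottleneck kernels, image {drf_df.iloc[0]['image_id']}")
    fig.savefig(fig_dir / "kernel_heatmaps.png", dpi=100)
    plt.close(fig)
    lines += ["## Kernel feature maps", "",
              "![kernels](figures/kernel_heatmaps.png)", ""]

    # clustering / embedding
    if "tsne_patient_level.tsv" in files:
        ts = pd.read_csv(run_dir / "tsne_patient_level.tsv", sep="\t",
                         index_col=0)
        cl = pd.read_csv(run_dir / "clusters.tsv", sep="\t")
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(ts["tsne1"], ts["tsne2"],
                   c=cl.set_index("patient_id").loc[ts.index, "cluster"],
                   cmap="tab10", s=25)
        ax.set_xlabel("t-SNE 1")
        ax.set_ylabel("t-SNE 2")
        fig.savefig(fig_dir / "tsne.png", dpi=100)
        plt.close(fig)
        lines += ["## Patient embedding", "", "![tsne](figures/tsne.png)", ""]

    if "cluster_enrichment.tsv" in files:
        enr = pd.read_csv(run_dir / "cluster_enrichment.tsv", sep="\t")
        lines += ["## Cluster / clinical enrichment (Fisher exact)", "",
                  enr.to_markdown(index=False), ""]

    # associations
    assoc = pd.read_csv(run_dir / "associations.tsv", sep="\t")
    n_sig = int(assoc["significant"].sum())
    lines += ["## Radiogenomic associations", ""]
    if n_sig == 0:
        lines += ["No significant associations at the adjusted-p threshold.", ""]
    else:
        n_drf = assoc.loc[assoc["significant"], "drf_id"].nunique()
        n_gf = assoc.loc[assoc["significant"], "gf_id"].nunique()
        lines += [f"{n_sig} significant (DRF, GF) pairs covering {n_drf} DRFs "
                  f"and {n_gf} GFs.", ""]
        if "kernel_counts.tsv" in files:
            kc = pd.read_csv(run_dir / "kernel_counts.tsv", sep="\t")
            lines += ["### Significant associations per kernel", "",
                      kc.to_markdown(index=False), ""]
        if "top_features.tsv" in files:
            tf = pd.read_csv(run_dir / "top_features.tsv", sep="\t")
            if len(tf):
                lines += ["### Top DRFs by associated GFs", "",
                          tf.head(10).to_markdown(index=False), ""]

    # classification
    ca = pd.read_csv(run_dir / "clinical_auc.tsv", sep="\t")
    lines += ["## Clinical classification (lasso path)", "",
              ca.to_markdown(index=False), ""]
    paths = pd.read_csv(run_dir / "lasso_paths.tsv", sep="\t")
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, sub in paths.groupby("label"):
        sub = sub.sort_values("n_nonzero")
        ax.plot(sub["n_nonzero"], sub["cv_auc"], label=label, alpha=0.8)
    ax.set_xlabel("active features")
    ax.set_ylabel("CV AUC")
    ax.legend(fontsize=7)
    fig.savefig(fig_dir / "lasso_paths.png", dpi=100)
    plt.close(fig)
    lines += ["![paths](figures/lasso_paths.png)", ""]

    if "signature_auc.tsv" in files:
        sa = pd.read_csv(run_dir / "signature_auc.tsv", sep="\t")
        lines += ["## Signature classification", "",
                  sa.to_markdown(index=False), ""]

    report_path = run_dir / "report.md"
    report_path.write_text("\n".join(lines))
    return report_path
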