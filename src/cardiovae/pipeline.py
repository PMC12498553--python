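"""Pipeline orchestration: simulate → preprocess → train → analyze →
validate → report, writing every artifact as delimited text (plus npz
model weights and png figures) into a run directory.

Each stage reads its inputs from the run directory, so stages can be
re-run in isolation; a manifest records completed stages and the seeds
used, and a completed run is fully reproducible from config + seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis as ana
from . import io as cio
from . import preprocess as prep
from . import stats as vstats
from . import vae as jvae
from .config import STAGES, RunConfig
from .preprocess import GENE_PREFIX, MET_PREFIX
from .simulate import OmicsDataset, SimConfig, with_two_batches

log = logging.getLogger("cardiovae")


class StageError(RuntimeError):
    pass


def _manifest_path(rundir: Path) -> Path:
    return rundir / "manifest.json"


def _update_manifest(rundir: Path, stage: str, config: RunConfig) -> None:
    path = _manifest_path(rundir)
    manifest = json.loads(path.read_text()) if path.exists() else {
        "stages_completed": [], "seeds": {}, "global_seed": config.seed,
    }
    if stage not in manifest["stages_completed"]:
        manifest["stages_completed"].append(stage)
    manifest["seeds"][stage] = config.stage_seed(stage)
    path.write_text(json.dumps(manifest, indent=1))


def read_manifest(rundir: str | Path) -> dict:
    return json.loads(_manifest_path(Path(rundir)).read_text())


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: RunConfig, rundir: Path) -> OmicsDataset:
    from .simulate import generate_dataset

    sim = SimConfig(
        n_per_group=config.sim.n_per_group,
        noise_cv=config.sim.noise_cv,
        seed=config.stage_seed("simulate"),
    )
    if config.sim.two_batches:
        sim = with_two_batches(sim, config.sim.batch_shift, config.sim.batch_scale)
    data = generate_dataset(sim)
    data.to_dir(rundir / "dataset")
    return data


def _load_dataset(rundir: Path) -> OmicsDataset:
    return OmicsDataset.from_dir(rundir / "dataset")


def stage_preprocess(config: RunConfig, rundir: Path) -> prep.PreprocessedData:
    data = _load_dataset(rundir)
    pp = prep.preprocess(
        data,
        pseudocount=config.prep.pseudocount,
        outlier_threshold=config.prep.outlier_threshold,
    )
    d = rundir / "preprocessed"
    cio.write_matrix(pp.x_t, d / "metabolites_01.tsv")
    cio.write_matrix(pp.y_t, d / "expression_01.tsv")
    pp.scaling.to_json(d / "scaling_params.json")
    flags = pd.DataFrame({"outlier": pp.outlier_flags.astype(int)})
    flags.to_csv(d / "outlier_flags.tsv", sep="\t", index_label="sample_id")

    de = prep.select_top_genes(data.y, data.group, reference="A",
                               n=config.analysis.top_genes)
    de.table.to_csv(d / "de_selection.tsv", sep="\t")
    (d / "top_genes.txt").write_text("\n".join(de.selected) + "\n")
    return pp


def _load_preprocessed(rundir: Path) -> prep.PreprocessedData:
    d = rundir / "preprocessed"
    data = _load_dataset(rundir)
    x_t = cio.read_matrix(d / "metabolites_01.tsv")
    y_t = cio.read_matrix(d / "expression_01.tsv")
    scaling = prep.ScalingParams.from_json(d / "scaling_params.json")
    if (d / "outlier_flags.tsv").exists():
        flags = pd.read_csv(d / "outlier_flags.tsv", sep="\t", index_col=0)
        outl = flags["outlier"].astype(int).astype(bool)
        outl.index = x_t.index
    else:
        outl = pd.Series(False, index=x_t.index)
    return prep.PreprocessedData(
        x_t=x_t, y_t=y_t, scaling=scaling, outlier_flags=outl,
        group=data.group.loc[x_t.index], batch=data.batch.loc[x_t.index],
    )


def stage_train(config: RunConfig, rundir: Path):
    pp = _load_preprocessed(rundir)
    vc = jvae.VAEConfig(
        latent_dim=config.vae.latent_dim,
        hidden=config.vae.hidden,
        activation=config.vae.activation,
        learning_rate=config.vae.learning_rate,
        iterations=config.vae.iterations,
        beta=config.vae.beta,
        kl_warmup=config.vae.kl_warmup,
        val_fraction=config.vae.val_fraction,
        seed=config.stage_seed("train"),
        tol=config.vae.tol,
        patience=config.vae.patience,
    )
    params, trace = jvae.train(pp, vc)
    d = rundir / "model"
    d.mkdir(parents=True, exist_ok=True)
    jvae.save_params(params, d / "vae_params.npz")
    trace.to_frame().to_csv(d / "training_trace.tsv", sep="\t", index=False)
    (d / "convergence.json").write_text(json.dumps(
        {"convergence_iteration": trace.convergence_iteration}
    ))
    return params, trace


def _standardized_features(data: OmicsDataset,
                           pseudocount: float) -> pd.DataFrame:
    """log metabolites and raw TPM, each column standardized (ddof=1),
    concatenated with modality prefixes — the feature space of the LASSO
    and PCA-contribution analyses."""
    x_log = prep.log_transform(data.x, pseudocount)
    feats = pd.concat(
        [x_log.add_prefix(MET_PREFIX), data.y.add_prefix(GENE_PREFIX)], axis=1
    )
    sds = feats.std(axis=0, ddof=1).replace(0, np.nan)
    feats = ((feats - feats.mean(axis=0)) / sds).dropna(axis=1)
    return feats


def stage_analyze(config: RunConfig, rundir: Path) -> dict:
    data = _load_dataset(rundir)
    pp = _load_preprocessed(rundir)
    params = jvae.load_params(rundir / "model" / "vae_params.npz")
    d = rundir / "analysis"
    d.mkdir(parents=True, exist_ok=True)

    latent = jvae.extract_latent(pp, params)
    cio.write_matrix(latent, d / "latent.tsv")
    groups = pp.groups(include_outliers=False)

    report = ana.classify_latent(
        latent, groups, n_trees=config.analysis.n_trees,
        n_folds=config.analysis.n_folds, seed=config.stage_seed("analyze"),
    )
    report.metrics.to_csv(d / "classification_metrics.tsv", sep="\t")

    overlay = None
    if config.analysis.overlay_metabolite in data.x.columns:
        overlay = data.x[config.analysis.overlay_metabolite].loc[latent.index]
    emb = ana.embed_tsne(
        latent, perplexity=config.analysis.perplexity,
        iterations=config.analysis.tsne_iterations,
        seed=config.stage_seed("analyze"), overlay=overlay,
    )
    coords = emb.coordinates.copy()
    coords["group"] = groups
    if overlay is not None:
        coords["overlay"] = overlay
    coords.to_csv(d / "tsne_coordinates.tsv", sep="\t")

    feats = _standardized_features(data, config.prep.pseudocount)
    assoc = ana.lasso_associations(
        feats, data.group, regularization=config.analysis.regularization
    )
    assoc.coefficients.to_csv(d / "lasso_coefficients.tsv", sep="\t")

    contribs = ana.pca_contributions_by_group(
        feats, data.group, top_n=config.analysis.top_n
    )
    rows = []
    for g, cr in contribs.items():
        for rank, name in enumerate(cr.top, start=1):
            rows.append((g, rank, name, cr.scores[name]))
    pd.DataFrame(
        rows, columns=["group", "rank", "feature", "contribution"]
    ).to_csv(d / "pca_contributions.tsv", sep="\t", index=False)

    _write_plots(d, emb, groups, assoc, contribs)
    return {
        "classification": report, "embedding": emb,
        "associations": assoc, "contributions": contribs, "latent": latent,
    }


def _write_plots(d: Path, emb, groups, assoc, contribs) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5))
    for g in sorted(set(groups)):
        rows = groups == g
        axes[0].scatter(emb.coordinates.loc[rows, "tsne1"],
                        emb.coordinates.loc[rows, "tsne2"], s=18, label=g)
    axes[0].legend(title="condition", fontsize=8)
    axes[0].set_title("t-SNE of latent features")
    if emb.overlay is not None:
        sc = axes[1].scatter(emb.coordinates["tsne1"], emb.coordinates["tsne2"],
                             c=emb.overlay, s=18, cmap="viridis")
        fig.colorbar(sc, ax=axes[1], label=emb.overlay.name)
        axes[1].set_title(f"{emb.overlay.name} overlay")
    fig.tight_layout()
    fig.savefig(d / "embedding.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(10, 3.5))
    im = ax.imshow(assoc.coefficients.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_yticks(range(len(assoc.coefficients.index)),
                  assoc.coefficients.index)
    ax.set_xticks(range(len(assoc.coefficients.columns)),
                  assoc.coefficients.columns, rotation=90, fontsize=6)
    fig.colorbar(im, ax=ax, label="coefficient")
    ax.set_title(f"LASSO associations (lambda={assoc.regularization})")
    fig.tight_layout()
    fig.savefig(d / "lasso_heatmap.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(2, 3, figsize=(13, 6))
    for ax, (g, cr) in zip(axes.ravel(), sorted(contribs.items())):
        vals = [cr.scores[f] for f in cr.top]
        ax.barh(range(len(cr.top)), vals)
        ax.set_yticks(range(len(cr.top)), cr.top, fontsize=7)
        ax.invert_yaxis()
        ax.set_title(f"group {g}", fontsize=9)
    fig.suptitle("Top PCA feature contributions per condition")
    fig.tight_layout()
    fig.savefig(d / "pca_contributions.png", dpi=120)
    plt.close(fig)


def stage_validate(config: RunConfig, rundir: Path) -> vstats.ValidationReport:
    data = _load_dataset(rundir)
    report = vstats.run_validation_report(dataset=data)
    report.write(rundir / "validation" / "report")
    return report


def stage_report(config: RunConfig, rundir: Path) -> None:
    """Human-readable run summary assembled from stage artifacts."""
    lines = ["cardiovae run summary", "=" * 21, ""]
    m = read_manifest(rundir)
    lines.append(f"global seed: {m['global_seed']}")
    lines.append(f"stages completed: {', '.join(m['stages_completed'])}")
    cm = rundir / "analysis" / "classification_metrics.tsv"
    if cm.exists():
        metrics = pd.read_csv(cm, sep="\t", index_col=0)
        lines += ["", "classification metrics (one-vs-rest):",
                  metrics.to_string(float_format="%.3f"),
                  f"minimum metric: {metrics.min().min():.3f}"]
    conv = rundir / "model" / "convergence.json"
    if conv.exists():
        lines.append(
            f"VAE convergence iteration: "
            f"{json.loads(conv.read_text())['convergence_iteration']}"
        )
    (rundir / "summary.txt").write_text("\n".join(lines) + "\n")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "train": stage_train,
    "analyze": stage_analyze,
    "validate": stage_validate,
    "report": stage_report,
}


def run_stage(stage: str, config: RunConfig, rundir: str | Path):
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    try:
        out = _STAGE_FUNCS[stage](config, rundir)
    except Exception as exc:  # noqa: BLE001 - halt with the stage name
        raise StageError(f"stage {stage!r} failed: {exc}") from exc
    _update_manifest(rundir, stage, config)
    log.info("stage %s completed", stage)
    return out


def run_pipeline(config: RunConfig, rundir: str | Path) -> Path:
    """Execute every stage in order; returns the run directory."""
    rundir = Path(rundir)
    for stage in STAGES:
        run_stage(stage, config, rundir)
    return rundir
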