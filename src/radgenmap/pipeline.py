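"""End-to-end pipeline: simulate -> extract -> screen -> score-genes -> map -> predict.

Each stage reads the previous stage's on-disk artifacts, so stages can be
re-run individually from saved intermediates.  A single global seed is fanned
out to per-stage substreams by stable hashing of the stage name, and a
checksum manifest of every written artifact makes end-to-end determinism
checkable byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._util import sha256_file, stage_rng
from .genomics import (
    DEFAULT_QC_THRESHOLD,
    default_panel,
    qc_filter,
    read_metadata,
    read_panel,
    read_segments,
    score_genes,
)
from .predict import MODES, build_design, compare_modes
from .radiomap import cluster_map, correlate, export_heatmap
from .screening import screen_features
from .synthetic import CohortConfig, generate_cohort, read_fixtures, write_fixtures
from .texture import (
    DEFAULT_HISTOGRAM_BINS,
    DEFAULT_LEVELS,
    DEFAULT_OFFSETS,
    extract_features,
)

logger = logging.getLogger("radgenmap")

__all__ = ["PipelineConfig", "run_all", "STAGES"]

STAGES = ("simulate", "extract", "screen", "score-genes", "map", "predict")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run (serialisable to YAML)."""

    outdir: str = "radgenmap_out"
    seed: int = 0
    simulate: bool = True
    fixture_dir: str | None = None  # required when simulate=False
    cohort: CohortConfig = field(default_factory=CohortConfig)
    levels: int = DEFAULT_LEVELS
    offsets: tuple = DEFAULT_OFFSETS
    symmetric: bool = True
    histogram_bins: int = DEFAULT_HISTOGRAM_BINS
    qc_threshold: float = DEFAULT_QC_THRESHOLD
    screening_alpha: float = 0.05
    screening_fdr: bool = False
    map_alpha: float = 0.05
    render_heatmaps: bool = True
    cv_scheme: str = "kfold"
    n_splits: int = 5
    n_boot: int = 2000
    boost_params: dict | None = None  # overrides for the boosted model

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_raw = raw.pop("cohort", None)
        cfg = cls(**raw)
        if cohort_raw is not None:
            from .synthetic import TextureParams

            tp = cohort_raw.pop("texture_params", None)
            cohort = CohortConfig(**cohort_raw)
            if tp is not None:
                cohort.texture_params = {
                    int(k): TextureParams(*v) if isinstance(v, (list, tuple)) else TextureParams(**v)
                    for k, v in tp.items()
                }
            cfg.cohort = cohort
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["planted_links"] = [list(l) for l in
                                        [(p.gene, p.feature, p.target_r) for p in self.cohort.planted_links]]
        return d


def _write_json(obj: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)


def run_all(config: PipelineConfig) -> Path:
    """Execute every stage and write a manifest; returns the output directory.

    Any stage failure aborts with the stage name in the raised error; partial
    outputs are retained for inspection.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, dict] = {}
    stage = "configure"
    try:
        echo = config.to_dict()
        echo.pop("outdir", None)  # implied by the file's own location
        echo.pop("fixture_dir", None)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(echo, fh, sort_keys=True)

        stage = "simulate"
        if config.simulate:
            cohort_cfg = dataclasses.replace(config.cohort)
            # fan the global seed into the generator stream
            cohort_cfg.seed = int(stage_rng(config.seed, "simulate").integers(2**31))
            cohort = generate_cohort(cohort_cfg)
            fixture_dir = out / "fixtures"
            write_fixtures(cohort, fixture_dir)
            logger.info("simulate: %d patients -> %s", len(cohort), fixture_dir)
        else:
            if not config.fixture_dir:
                raise ValueError("fixture_dir is required when simulate=False")
            fixture_dir = Path(config.fixture_dir)
            cohort = read_fixtures(fixture_dir)
        counts["simulate"] = {"n_patients": len(cohort)}

        stage = "extract"
        images = [img for p in cohort for img in p.images.values()]
        features = extract_features(
            images,
            levels=config.levels,
            offsets=config.offsets,
            symmetric=config.symmetric,
            histogram_bins=config.histogram_bins,
        )
        metadata = read_metadata(fixture_dir / "metadata.tsv")
        feat_out = features.copy()
        feat_out.insert(
            0, "grade_group",
            metadata.set_index("patient_id").loc[features.index, "grade_group"],
        )
        feat_out.to_csv(out / "features.csv")
        counts["extract"] = {"n_rows": len(features), "n_features": features.shape[1]}
        logger.info("extract: %d patients x %d feature columns", *features.shape)

        stage = "screen"
        grade = metadata.set_index("patient_id")["grade_group"]
        screening = screen_features(
            features, grade, alpha=config.screening_alpha, fdr=config.screening_fdr
        )
        screening.to_csv(out / "screening.csv", index=False)
        selected = screening.loc[screening["selected"], "feature"].tolist()
        counts["screen"] = {"n_tested": len(screening), "n_selected": len(selected)}
        logger.info("screen: %d/%d features selected", len(selected), len(screening))
        if not selected:
            logger.warning("no feature passed screening; mapping all features")
            selected = list(features.columns)

        stage = "score-genes"
        panel = read_panel(fixture_dir / "panel.tsv")
        retained, excluded = qc_filter(metadata, config.qc_threshold)
        excluded.to_csv(out / "qc_exclusions.csv", index=False)
        segments = read_segments(fixture_dir / "segments.tsv")
        retained_ids = retained["patient_id"].tolist()
        segments = [s for s in segments if s.sample_id in set(retained_ids)]
        scores = score_genes(segments, panel, sample_ids=retained_ids)
        scores.to_csv(out / "gene_scores.csv")
        counts["score-genes"] = {
            "n_retained": len(retained_ids),
            "n_excluded": len(excluded),
            "n_segments": len(segments),
        }
        logger.info(
            "score-genes: %d samples retained (QC >= %g%%), %d excluded",
            len(retained_ids), config.qc_threshold, len(excluded),
        )

        stage = "map"
        map_dir = out / "maps"
        map_dir.mkdir(exist_ok=True)
        n_maps = 0
        for pathway in ("hypoxia", "androgen", "apoptosis"):
            pathway_genes = panel.pathway_genes(pathway)
            display = {g: panel.display_name(g) for g in pathway_genes}
            for group in (1, 2, 3):
                cmap = correlate(
                    scores[pathway_genes], features[selected], metadata,
                    grade_group=group,
                )
                cmap.r.rename(index=display, inplace=True)
                cmap.p.rename(index=display, inplace=True)
                cluster_map(cmap)
                export_heatmap(
                    cmap, map_dir / f"map_{pathway}_group{group}",
                    render=config.render_heatmaps, annotate_alpha=config.map_alpha,
                )
                n_maps += 1
        counts["map"] = {"n_maps": n_maps}
        logger.info("map: wrote %d pathway x grade-group maps", n_maps)

        stage = "predict"
        meta_retained = retained
        feats_retained = features.loc[retained_ids, selected]
        designs = {
            mode: build_design(feats_retained, scores, meta_retained, mode=mode)
            for mode in MODES
        }
        pred_seed = int(stage_rng(config.seed, "predict").integers(2**31))
        results = compare_modes(
            designs, cv_scheme=config.cv_scheme, n_boot=config.n_boot,
            seed=pred_seed, n_splits=config.n_splits,
            hyperparams=config.boost_params,
        )
        summary = {mode: res.summary() for mode, res in results.items()}
        _write_json(summary, out / "roc_summary.json")
        for mode, res in results.items():
            pd.DataFrame(
                {"threshold": res.thresholds, "fpr": res.fpr, "tpr": res.tpr}
            ).to_csv(out / f"roc_{mode}.csv", index=False)
        if config.render_heatmaps:
            _plot_roc(results, out / "roc.png")
        counts["predict"] = {m: round(r.auc, 4) for m, r in results.items()}
        logger.info("predict: AUCs %s", counts["predict"])

        stage = "manifest"
        files = sorted(
            p for p in out.rglob("*")
            if p.is_file() and p.name != "manifest.json" and p.name != "run_log.json"
        )
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "stage_counts": counts,
            "files": {str(p.relative_to(out)): sha256_file(p) for p in files},
        }
        _write_json(manifest, out / "manifest.json")
        return out
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _plot_roc(results: dict, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for mode, res in results.items():
        ax.plot(res.fpr, res.tpr, label=f"{mode} (AUC={res.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=1)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title("Clinically significant PCa prediction")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
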