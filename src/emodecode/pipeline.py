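"""End-to-end orchestration: simulate -> decode -> identify -> encode -> structure.

``run_pipeline`` executes every stage on either synthetic data (generated
from the config) or inputs loaded from disk, writes each stage's outputs
as TSV/CSV/JSON under the output directory, and returns a manifest
(versions, seeds, input digests, per-stage outputs and timings). A run is
reproducible from its config: reruns produce identical manifests apart
from timing.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .data import (
    load_parcellation,
    load_scores,
    make_parcellation,
    save_parcellation,
    save_scores,
)
from .decoding import ensemble_decode, region_decode
from .encoding import (
    encode_voxelwise,
    feature_set_from_scores,
    fold_deleted_accuracies,
    slope_compare,
    count_significant,
    split_dimensions,
)
from .identification import congruency_stats, emotion_identify, video_identify
from .regression import CVScheme, permutation_threshold
from .structure import (
    cluster_patterns,
    fit_embedding,
    map_reconstruction_corr,
    profile_emotions,
    select_emotion_voxels,
)
from .synth import GroundTruth, generate_dataset, generate_scores

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    With ``scores_path`` unset, synthetic data are generated from the
    ``synth_*`` settings; otherwise scores/parcellation/responses are
    loaded from the given paths.
    """

    out_dir: str = "emodecode_run"
    seed: int = 0

    # inputs (optional; synthetic generation when scores_path is None)
    scores_path: str | None = None
    parcellation_path: str | None = None
    response_paths: list[str] = field(default_factory=list)

    # synthetic-data settings
    synth_n_videos: int = 300
    synth_n_cat: int = 10
    synth_n_dim: int = 4
    synth_sparsity: float = 0.7
    synth_n_regions: int = 20
    synth_voxels_per_region: int = 30
    synth_informative_frac: float = 0.3
    synth_gain: float = 1.0
    synth_noise_sd: float = 3.0
    synth_n_subjects: int = 2

    # analysis settings
    n_outer_folds: int = 6
    n_inner_folds: int = 5
    lam_grid: list[float] = field(default_factory=lambda: list(np.logspace(-3, 3, 7)))
    perm_alpha: float = 0.01
    perm_n: int = 0  # 0 -> smallest count resolving alpha / n_tests
    set_size: int = 5
    n_resamples: int = 2000
    k_clusters: int = 27
    top_frac: float = 0.05
    run_embedding: bool = True

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, payload: dict | str | Path) -> "RunConfig":
        if not isinstance(payload, dict):
            payload = json.loads(Path(payload).read_text())
        return cls(**payload)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _perm_count(cfg: RunConfig, n_tests: int) -> int:
    minimum = int(np.ceil(10 * n_tests / cfg.perm_alpha))
    return max(cfg.perm_n, minimum)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": config.to_json(),
        "stages": {},
        "timing_s": {},
    }
    rng = np.random.default_rng(config.seed)

    def _stage(name):
        logger.info("stage: %s", name)
        return time.perf_counter()

    def _done(name, t0, outputs):
        manifest["timing_s"][name] = round(time.perf_counter() - t0, 3)
        manifest["stages"][name] = outputs

    # ------------------------------------------------------------------ data
    t0 = _stage("data")
    if config.scores_path is None:
        scores = generate_scores(
            config.synth_n_videos,
            config.synth_n_cat,
            config.synth_n_dim,
            config.synth_sparsity,
            seed=int(rng.integers(2**31)),
        )
        region_names = [f"region{i:03d}" for i in range(config.synth_n_regions)]
        parc = make_parcellation(
            region_names=region_names,
            voxels_per_region=config.synth_voxels_per_region,
        )
        n_emotions = config.synth_n_cat + config.synth_n_dim
        gains = np.zeros((config.synth_n_regions, n_emotions))
        informative = rng.random((config.synth_n_regions, n_emotions)) < config.synth_informative_frac
        gains[informative] = config.synth_gain
        truth = GroundTruth(gains, noise_sd=config.synth_noise_sd)
        datasets = [
            generate_dataset(
                scores, parc, truth, subject_seed=int(rng.integers(2**31)), subject_id=f"sub-{i:02d}"
            )
            for i in range(config.synth_n_subjects)
        ]
        np.savetxt(out / "informativeness_map.tsv", gains, delimiter="\t")
    else:
        scores = load_scores(config.scores_path)
        parc = load_parcellation(config.parcellation_path)
        from .data import load_responses

        datasets = [load_responses(p) for p in config.response_paths]
        for ds in datasets:
            if ds.video_ids != scores.video_ids:
                raise ValueError(f"{ds.subject_id}: responses not aligned to scores")
    save_scores(scores, out / "scores.csv")
    save_parcellation(parc, out / "parcellation.tsv")
    _done("data", t0, {
        "n_videos": scores.n_videos,
        "n_regions": parc.n_regions,
        "n_voxels": parc.n_voxels,
        "subjects": [ds.subject_id for ds in datasets],
        "scores_digest": _digest(out / "scores.csv"),
    })

    scheme = CVScheme(scores.n_videos, config.n_outer_folds, config.n_inner_folds)

    # ---------------------------------------------------------------- decode
    t0 = _stage("decode")
    n_regions = parc.n_regions
    thr_regions = permutation_threshold(
        scores.matrix()[:, 0],
        _perm_count(config, n_regions),
        alpha=config.perm_alpha,
        n_tests=n_regions,
        seed=config.seed,
    )
    tables = []
    for ds in datasets:
        table = region_decode(ds, scores, scheme, config.lam_grid)
        table.to_tsv(out / f"decoding_accuracy_{ds.subject_id}.tsv")
        tables.append(table)
    (out / "decode_threshold.json").write_text(json.dumps(thr_regions.to_json(), indent=1))
    n_sig = int((tables[0].values > thr_regions.r_threshold).sum())
    _done("decode", t0, {
        "tables": [f"decoding_accuracy_{ds.subject_id}.tsv" for ds in datasets],
        "r_threshold": thr_regions.r_threshold,
        "significant_cells_subject0": n_sig,
    })

    # -------------------------------------------------------------- ensemble
    t0 = _stage("ensemble")
    ensembles = []
    for ds in datasets:
        ens = ensemble_decode(ds, scores, scheme, config.lam_grid)
        ens.to_frame().rename_axis("video_id").to_csv(out / f"ensemble_decoded_{ds.subject_id}.csv")
        ensembles.append(ens)
    (out / "ensemble_accuracy.json").write_text(
        json.dumps(
            {
                ens.subject_id: dict(zip(ens.emotion_names, map(float, ens.accuracy)))
                for ens in ensembles
            },
            indent=1,
        )
    )
    _done("ensemble", t0, {
        "mean_accuracy": {ens.subject_id: float(np.nanmean(ens.accuracy)) for ens in ensembles},
    })

    # -------------------------------------------------------------- identify
    t0 = _stage("identify")
    ident: dict = {}
    if len(tables) >= 2:
        res = emotion_identify(
            tables[0], tables[1], config.set_size, config.n_resamples, seed=config.seed
        )
        congr, incongr = congruency_stats(tables[0], tables[1])
        ident["emotion"] = res.to_json()
        ident["congruent_mean_r"] = congr
        ident["incongruent_mean_r"] = incongr
    else:
        logger.warning("fewer than 2 subjects: emotion identification skipped")
    vid_acc = video_identify(ensembles[0].decoded, scores.matrix())
    ident["video_mean_accuracy_percent"] = float(vid_acc.mean())
    np.savetxt(out / "video_identification_accuracy.tsv", vid_acc, delimiter="\t")
    (out / "identification.json").write_text(json.dumps(ident, indent=1))
    _done("identify", t0, {k: v for k, v in ident.items() if not isinstance(v, dict)})

    # ---------------------------------------------------------------- encode
    t0 = _stage("encode")
    ds0 = datasets[0]
    feats = {w: feature_set_from_scores(scores, w) for w in ("category", "dimension", "joint")}
    acc: dict[str, np.ndarray] = {}
    preds: dict[str, np.ndarray] = {}
    for name, fs in feats.items():
        acc[name], preds[name] = encode_voxelwise(fs, ds0, scheme, config.lam_grid, return_predictions=True)
    thr_vox = permutation_threshold(
        ds0.responses[:, 0],
        _perm_count(config, ds0.n_voxels),
        alpha=config.perm_alpha,
        n_tests=ds0.n_voxels,
        seed=config.seed,
    )
    counts = {name: count_significant(a, thr_vox) for name, a in acc.items()}
    jack = [
        (a, b)
        for a, b in zip(
            fold_deleted_accuracies(preds["category"], ds0.responses, scheme),
            fold_deleted_accuracies(preds["dimension"], ds0.responses, scheme),
        )
    ]
    slope = slope_compare(acc["category"], acc["dimension"], jackknife_replicates=jack)
    np.savetxt(
        out / "encoding_accuracy.tsv",
        np.column_stack([acc[n] for n in feats]),
        delimiter="\t",
        header="\t".join(feats),
        comments="",
    )
    (out / "encoding_comparison.json").write_text(
        json.dumps(
            {
                "voxel_r_threshold": thr_vox.r_threshold,
                "significant_voxels": counts,
                "slope_category_vs_dimension": slope.to_json(),
            },
            indent=1,
        )
    )
    _done("encode", t0, {
        "significant_voxels": counts,
        "slope_deviation_deg": slope.deviation_deg,
        "slope_p": slope.p_value,
    })

    # ------------------------------------------------------------- structure
    t0 = _stage("structure")
    mask = select_emotion_voxels(acc["category"], acc["dimension"], thr_vox)
    struct: dict = {"n_selected_voxels": int(mask.sum())}
    if mask.sum() >= 2:
        profile = cluster_patterns(ds0.responses, mask, k=config.k_clusters, seed=config.seed)
        profile = profile_emotions(
            profile,
            scores.category_scores,
            [f"{c}" for c in scores.category_names],
            top_frac=config.top_frac,
            seed=config.seed,
        )
        dim_split = split_dimensions(scores)
        dim_profile = cluster_patterns(ds0.responses, mask, k=config.k_clusters, seed=config.seed)
        dim_profile = profile_emotions(
            dim_profile,
            dim_split.matrix,
            dim_split.feature_names,
            top_frac=config.top_frac,
            seed=config.seed,
        )
        (out / "cluster_profile_categories.json").write_text(json.dumps(profile.to_json(), indent=1))
        (out / "cluster_profile_dimensions.json").write_text(json.dumps(dim_profile.to_json(), indent=1))
        struct["mean_entropy_categories_bits"] = float(np.mean(list(profile.entropies.values())))
        struct["mean_entropy_dimensions_bits"] = float(np.mean(list(dim_profile.entropies.values())))
        struct["baseline_entropy_bits"] = profile.baseline_entropy
    else:
        logger.warning("no significant emotion voxels: clustering skipped")
    if config.run_embedding:
        model = fit_embedding(scores.category_scores, seed=config.seed)
        decoded_cat = ensembles[0].decoded[:, : scores.n_categories]
        projected = model.project(decoded_cat)
        r_x, r_y = map_reconstruction_corr(model.training_coords, projected)
        np.savetxt(out / "embedding_true.tsv", model.training_coords, delimiter="\t")
        np.savetxt(out / "embedding_decoded.tsv", projected, delimiter="\t")
        struct["map_reconstruction_r"] = {"x": r_x, "y": r_y}
    (out / "structure.json").write_text(json.dumps(struct, indent=1))
    _done("structure", t0, struct)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest
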