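"""Configuration-driven end-to-end runs of the visual-homogeneity analysis.

A run chains: trial filtering -> 1/RT dissimilarities -> MDS embedding ->
display responses by averaging -> VH center fit -> LOOCV -> group summary,
with an optional synthetic searchlight stage.  Inputs are either synthetic
(generated here from the config's ground-truth parameters) or trial tables
read from disk.  Every numeric artifact is written deterministically: the
same config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import sys
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import io, synthetic_data, vh_model
from .display_model import build_display_responses, displays_from_frame, displays_to_frame
from .perceptual_space import dissimilarity_from_trials, embed_mds, filter_trials, split_half_consistency
from .searchlight import define_region, rt_correlation_map, vh_correlation_map


@dataclass
class RunConfig:
    """All knobs for one end-to-end run; serialized into the output bundle."""

    mode: str = "search_study"  # or "symmetry_study"
    seed: int = 0
    out_dir: str | None = None

    # synthetic inputs (used when no trial files are given)
    n_objects: int = 32
    k_true: int = 5
    spread: float = 0.55
    n_participants: int = 16
    trials_per_pair: int = 2
    search_noise_sigma: float = 0.1
    rt_noise_frac: float = 0.1

    # file inputs (override synthetic generation)
    search_trials_path: str | None = None
    decision_trials_path: str | None = None
    displays_path: str | None = None

    # analysis
    k: int | None = None  # embedding dims; default 5 (search) / 3 (symmetry)
    mds_criterion: str = "metric_stress"
    mds_n_init: int = 4
    search_min_rt: float = 0.3
    search_max_rt: float = 3.0
    decision_min_rt: float | None = None
    decision_max_rt: float = 5.0
    decision_min_accuracy: float | None = None
    fit_restarts: int = 20
    loocv_restarts: int = 2
    w_target: float = 0.5

    # searchlight (synthetic volumes; skipped when disabled)
    searchlight: bool = False
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    voxel_noise_sigma: float = 0.3
    region_threshold: float = 0.5

    def resolved(self) -> "RunConfig":
        cfg = RunConfig(**asdict(self))
        symmetry = cfg.mode == "symmetry_study"
        if cfg.k is None:
            cfg.k = 3 if symmetry else 5
        if cfg.decision_min_rt is None:
            cfg.decision_min_rt = 0.1 if symmetry else 0.05
        if symmetry and cfg.decision_min_accuracy is None:
            cfg.decision_min_accuracy = 0.8
        return cfg


def validate_config(config: RunConfig) -> list[str]:
    """All config violations at once (empty list when valid)."""
    errors = []
    if config.mode not in ("search_study", "symmetry_study"):
        errors.append(f"unknown mode {config.mode!r}")
    if config.n_objects < 3:
        errors.append("n_objects must be >= 3")
    cfg = config.resolved()
    if not 1 <= cfg.k <= config.n_objects - 1:
        errors.append(f"k must satisfy 1 <= k <= n_objects-1 = {config.n_objects - 1}")
    if not cfg.search_min_rt < cfg.search_max_rt:
        errors.append("search_min_rt must be smaller than search_max_rt")
    if not cfg.decision_min_rt < cfg.decision_max_rt:
        errors.append("decision_min_rt must be smaller than decision_max_rt")
    if config.fit_restarts < 0:
        errors.append("fit_restarts must be non-negative")
    for attr in ("search_trials_path", "decision_trials_path", "displays_path"):
        path = getattr(config, attr)
        if path is not None and not Path(path).exists():
            errors.append(f"{attr}: no such file {path}")
    return errors


def _log(msg: str, log_lines: list[str]) -> None:
    print(f"[vishom] {msg}", file=sys.stderr)
    log_lines.append(msg)


def _run(config: RunConfig) -> dict:
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    cfg = config.resolved()
    symmetry = cfg.mode == "symmetry_study"
    log: list[str] = []
    rng_seed = cfg.seed

    # ------------------------------------------------------ inputs
    if cfg.search_trials_path is None:
        if symmetry:
            gt, displays = synthetic_data.make_symmetric_design(
                n_per_group=cfg.n_objects // 2, k=cfg.k_true, seed=rng_seed,
                rt_noise_frac=cfg.rt_noise_frac,
            )
        else:
            gt, displays = synthetic_data.make_ground_truth(
                n_objects=cfg.n_objects, k=cfg.k_true, spread=cfg.spread,
                seed=rng_seed, search_noise_sigma=cfg.search_noise_sigma,
                rt_noise_frac=cfg.rt_noise_frac,
            )
        search_trials = synthetic_data.gen_search_trials(
            gt, trials_per_pair=cfg.trials_per_pair,
            n_participants=cfg.n_participants,
        )
        decision_trials = synthetic_data.gen_decision_trials(
            gt, displays, n_participants=cfg.n_participants,
            group_a_label="asymmetric" if symmetry else "present",
            group_b_label="symmetric" if symmetry else "absent",
        )
        _log(f"generated synthetic study: {gt.n_objects} objects, k_true={gt.k}", log)
    else:
        search_trials = io.read_trials(cfg.search_trials_path)
        decision_trials = io.read_trials(cfg.decision_trials_path)
        import pandas as pd

        displays = displays_from_frame(pd.read_csv(cfg.displays_path, sep="\t"))
        _log(f"loaded trials from {cfg.search_trials_path}", log)

    # ------------------------------------------------------ behavioral chain
    filtered, filt_report = filter_trials(
        search_trials, min_rt=cfg.search_min_rt, max_rt=cfg.search_max_rt
    )
    _log(f"filtered search trials: removed {filt_report['fraction_removed']:.3%}", log)
    decision_trials, dec_report = filter_trials(
        decision_trials, min_rt=cfg.decision_min_rt, max_rt=cfg.decision_max_rt,
        min_accuracy=cfg.decision_min_accuracy,
    )
    _log(f"filtered decision trials: removed {dec_report['fraction_removed']:.3%}", log)
    consistency = split_half_consistency(filtered)
    d = dissimilarity_from_trials(filtered)
    emb = embed_mds(d, k=cfg.k, criterion=cfg.mds_criterion,
                    n_init=cfg.mds_n_init, seed=rng_seed)
    _log(f"MDS k={cfg.k}: stress={emb.stress:.4f}, fit_r={emb.fit_r:.4f}", log)

    labels = np.array([spec.label for spec in displays])
    groups_present = set(labels)
    expect = {"asymmetric", "symmetric"} if symmetry else {"present", "absent"}
    missing_groups = expect - groups_present
    if missing_groups:
        raise ValueError(f"labeling stage: no displays labeled {sorted(missing_groups)}")

    responses = build_display_responses(emb, displays, w_target=cfg.w_target)
    rts = synthetic_data.mean_decision_rts(decision_trials, displays)
    fit = vh_model.fit_center(responses, rts, labels,
                              n_restarts=cfg.fit_restarts, seed=rng_seed)
    _log(
        f"fit: r_A={fit.r_group_a:.3f}, r_B={fit.r_group_b:.3f}, "
        f"objective={fit.objective:.3f}", log,
    )
    loocv = vh_model.loocv_fit(
        responses, rts, labels,
        display_objects=[spec.object_ids for spec in displays],
        n_restarts=cfg.loocv_restarts, seed=rng_seed, warm_start=fit.center,
    )
    summary = vh_model.vh_group_summary(fit.vh, labels)

    from ._utils import pearson

    cfg_payload = asdict(cfg)
    cfg_payload.pop("out_dir")  # environment detail; keeps reports byte-comparable
    report = {
        "config": cfg_payload,
        "filter": {"search": filt_report, "decision": dec_report},
        "split_half_r": consistency.r,
        "mds": {"k": emb.k, "stress": emb.stress, "fit_r": emb.fit_r},
        "fit": fit.to_dict(),
        "loocv": {"r_group_a": loocv.r_group_a, "r_group_b": loocv.r_group_b,
                  "n_folds": loocv.n_folds},
        "pooled_r": pearson(fit.vh, rts),
        "vh_summary": summary,
    }

    # ------------------------------------------------------ searchlight stage
    if cfg.searchlight:
        layout = synthetic_data.make_layout(
            grid_shape=tuple(cfg.grid_shape), noise_sigma=cfg.voxel_noise_sigma
        )
        data = synthetic_data.gen_voxel_data(
            layout, vh=fit.vh, rt=rts, seed=rng_seed,
            conditions=[spec.display_id for spec in displays],
        )
        vh_map = vh_correlation_map(data, fit.vh, labels)
        rt_map = rt_correlation_map(data, rts, labels)
        regions = define_region(vh_map, threshold=cfg.region_threshold, min_cluster=2)
        peak = np.unravel_index(np.nanargmax(vh_map.values), vh_map.values.shape)
        report["searchlight"] = {
            "vh_map_max_r": float(np.nanmax(vh_map.values)),
            "vh_map_peak_voxel": [int(i) for i in peak],
            "peak_in_planted_region": bool(layout.vh_region[peak]),
            "rt_map_mean_abs_r_in_vh_region": float(
                np.nanmean(np.abs(rt_map.values[layout.vh_region]))
            ),
            "n_regions": len(regions),
            "region_sizes": [r.size for r in regions],
        }
        _log(f"searchlight: {len(regions)} suprathreshold region(s)", log)
    report["log"] = log

    # ------------------------------------------------------ artifacts
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_trials(search_trials, out / "search_trials.tsv")
        io.write_trials(decision_trials, out / "decision_trials.tsv")
        displays_to_frame(displays).to_csv(out / "displays.tsv", sep="\t", index=False)
        io.write_dissimilarity(d, out / "dissimilarity.tsv")
        io.write_embedding(emb, out / "embedding.tsv", out / "embedding_meta.json")
        import pandas as pd

        pd.DataFrame(
            {
                "display_id": [spec.display_id for spec in displays],
                "label": labels,
                "vh": fit.vh,
                "rt_seconds": rts,
                "loocv_vh": loocv.vh_pred,
            }
        ).to_csv(out / "display_vh.tsv", sep="\t", index=False)
        io.write_json(report, out / "report.json")
    return report


def run_search_study(config: RunConfig) -> dict:
    """Present/absent analysis chain (embedding default: 5 dimensions)."""
    if config.mode != "search_study":
        raise ValueError("config.mode must be 'search_study'")
    return _run(config)


def run_symmetry_study(config: RunConfig) -> dict:
    """Symmetric/asymmetric analysis chain (embedding default: 3 dimensions,
    <100 ms RT filter and 80% per-object accuracy filter)."""
    if config.mode != "symmetry_study":
        raise ValueError("config.mode must be 'symmetry_study'")
    return _run(config)


def run(config: RunConfig) -> dict:
    return run_symmetry_study(config) if config.mode == "symmetry_study" else run_search_study(config)
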