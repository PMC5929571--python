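"""End-to-end workflows: feature-based virtual dissection and curation.

:func:`run_dissection` wires the modules into the gastrulation analysis
workflow: import -> temporal crop -> spatial crop -> span filter ->
displacement-ratio clustering of the long tracks -> label propagation to
the short tracks -> Butterworth smoothing -> deformation invariants ->
per-group median time courses.  :func:`run_curation` performs the
automatic gap-closing pass with optional decision-log replay.  Each run
writes its outputs plus a manifest (config echo + seed + log) into a run
directory, sufficient to reproduce the run.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import io as tio
from .model import LineageForest, crop_space, crop_time, filter_by_span, region_from_dict
from .features import single_features, smooth_tracks, aggregate_group
from .deformation import deformation_table
from .selection import SelectionTree, propagate_labels, replay_tree
from .curation import auto_link, curation_summary, replay_decision_log

__all__ = ["PipelineConfig", "run_dissection", "run_curation", "load_forest"]


@dataclass
class PipelineConfig:
    """Serializable configuration of a pipeline run."""

    input_path: str | None = None
    input_format: str = "csv"  # csv | ctc | trackmate | tgmm
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    time_window: tuple[float, float] | None = None
    time_unit: str = "frame"  # frame | hpf
    spatial_region: dict | None = None  # region descriptor (Box/Polygon dict)
    span_fraction: float = 0.7
    smoothing_order: int = 2
    smoothing_cutoff: float = 0.01
    smooth_before_deformation: bool = True
    cluster_feature: str = "displacement_ratio"
    cluster_k: int = 2
    propagation_k: int = 5
    propagation_radius: float = 40.0
    deformation_radius: float = 40.0
    compute_deformation: bool = True
    make_plots: bool = True
    auto_link_max_gap: int = 3
    auto_link_threshold: float = 5.0
    decision_log: str | None = None
    out_dir: str = "run"
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        cfg = cls(**data)
        if cfg.time_window is not None:
            cfg.time_window = tuple(cfg.time_window)
        cfg.voxel_size = tuple(cfg.voxel_size)
        return cfg


def load_forest(config: PipelineConfig) -> LineageForest:
    """Import the configured input into a lineage forest."""
    fmt = config.input_format
    if config.input_path is None:
        raise ValueError("config.input_path is not set")
    if fmt == "csv":
        forest, _ = tio.read_csv(config.input_path)
    elif fmt == "ctc":
        p = Path(config.input_path)
        track_file = p if p.is_file() else p / "res_track.txt"
        csv = track_file.parent / "res_centroids.csv"
        mask_dir = track_file.parent if not csv.exists() else None
        forest, _ = tio.read_ctc(
            track_file,
            mask_dir=mask_dir,
            centroid_csv=csv if csv.exists() else None,
            voxel_size=config.voxel_size,
        )
    elif fmt == "trackmate":
        forest, _ = tio.read_trackmate(config.input_path)
    elif fmt == "tgmm":
        forest, _ = tio.read_tgmm(config.input_path, voxel_size=config.voxel_size)
    else:
        raise ValueError(f"unknown input format {fmt!r}")
    return forest


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str, fn, log: list[str]):
    try:
        result = fn()
    except Exception as err:  # noqa: BLE001 - report stage + cause
        log.append(f"FAILED {name}: {err}")
        raise StageError(name, err) from err
    log.append(f"ok {name}")
    return result


def run_dissection(
    config: PipelineConfig,
    forest: LineageForest | None = None,
    template: dict | None = None,
) -> Path:
    """Run the virtual-dissection workflow; returns the run directory.

    ``forest`` may be passed directly (e.g. fresh from the simulator),
    otherwise it is imported per the config.  ``template`` is an exported
    selection-tree document to replay instead of developing the selection
    anew.  Outputs: ``groups.csv``, ``selection_tree.json``,
    ``deformation.csv``, per-group median time courses, plots and
    ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    if forest is None:
        forest = _stage("import", lambda: load_forest(config), log)

    if config.time_window is not None:
        t0, t1 = config.time_window
        forest = _stage(
            "crop_time", lambda: crop_time(forest, t0, t1, unit=config.time_unit), log
        )
    if config.spatial_region is not None:
        region = region_from_dict(config.spatial_region)
        forest = _stage("crop_space", lambda: crop_space(forest, region), log)

    kept, short = _stage(
        "filter_by_span", lambda: filter_by_span(forest, config.span_fraction), log
    )
    log.append(
        f"span filter: {kept.n_tracks} long tracks, {short.n_tracks} short tracks"
    )

    def _select():
        if template is not None:
            tree = replay_tree(template, kept)
            children = [
                n
                for n in tree.nodes.values()
                if n.predicate.get("kind") == "cluster"
            ]
            children.sort(key=lambda n: n.predicate["index"])
        else:
            tree = SelectionTree(kept)
            children = tree.cluster_members(
                tree.root, [config.cluster_feature], config.cluster_k
            )
        return tree, children

    tree, children = _stage("cluster", _select, log)

    def _group_labels():
        # semantics tied to the feature: the low-ratio cluster is the
        # U-shaped, involuting-like group
        table = single_features(kept, [config.cluster_feature])
        med = {
            n.node_id: table.loc[sorted(n.members), config.cluster_feature].median()
            for n in children
        }
        order = sorted(children, key=lambda n: med[n.node_id])
        names = {}
        names[order[0].node_id] = "hypoblast-like"
        for n in order[1:]:
            names[n.node_id] = (
                "epiblast-like" if n is order[-1] else f"group-{n.predicate['index']}"
            )
        for n in children:
            n.label = names[n.node_id]
        return {tid: names[n.node_id] for n in children for tid in n.members}

    labeled = _stage("label_groups", _group_labels, log)

    def _propagate():
        if not short.n_tracks:
            return {}, []
        return propagate_labels(
            forest,
            labeled,
            unlabeled=set(short.tracks),
            k=config.propagation_k,
            radius=config.propagation_radius,
        )

    propagated, unassigned = _stage("propagate_labels", _propagate, log)
    if unassigned:
        log.append(f"{len(unassigned)} short tracks had no labeled neighbor in range")

    groups = pd.DataFrame(
        [
            {"track_id": tid, "group": grp, "source": "cluster"}
            for tid, grp in sorted(labeled.items())
        ]
        + [
            {"track_id": tid, "group": grp, "source": "propagated"}
            for tid, grp in sorted(propagated.items())
        ]
        + [
            {"track_id": tid, "group": "", "source": "unassigned"}
            for tid in sorted(unassigned)
        ]
    )
    groups.to_csv(out / "groups.csv", index=False)
    tree.to_json(out / "selection_tree.json")

    if config.compute_deformation:
        if config.smooth_before_deformation:
            smoothed = _stage(
                "smooth",
                lambda: smooth_tracks(
                    forest, config.smoothing_order, config.smoothing_cutoff
                ),
                log,
            )
        else:
            smoothed = forest
            log.append("smoothing disabled by config")
        table = _stage(
            "deformation_table",
            lambda: deformation_table(smoothed, radius=config.deformation_radius),
            log,
        )
        table.to_csv(out / "deformation.csv")

        all_groups = {**labeled, **propagated}
        medians = {}
        for grp in sorted(set(all_groups.values())):
            members = {t for t, g in all_groups.items() if g == grp}
            members &= set(table.index.get_level_values("track_id"))
            if not members:
                continue
            agg = aggregate_group(
                table[["speed", "P", "D", "Q_d"]], members, "median"
            )
            agg.to_csv(out / f"median_{grp.replace(' ', '_')}.csv")
            medians[grp] = agg
        if config.make_plots and medians:
            from .plotting import plot_group_medians

            _stage(
                "plots",
                lambda: plot_group_medians(medians, out / "deformation_medians.png"),
                log,
            )

    manifest = {
        "workflow": "dissection",
        "config": asdict(config),
        "seed": config.seed,
        "log": log,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def run_curation(
    config: PipelineConfig, forest: LineageForest | None = None
) -> Path:
    """Automatic gap closing plus optional decision-log replay.

    Emits the corrected forest (native CSV + CTC), the auto-link log, a
    per-decision summary CSV and the run manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    if forest is None:
        forest = _stage("import", lambda: load_forest(config), log)

    def _auto():
        if config.auto_link_threshold <= 0:
            log.append("auto-link disabled (threshold <= 0)")
            return forest, []
        return auto_link(
            forest,
            max_gap=config.auto_link_max_gap,
            distance_threshold=config.auto_link_threshold,
        )

    linked, link_log = _stage("auto_link", _auto, log)
    log.append(f"auto-link: {len(link_log)} links")

    if config.decision_log is not None:
        linked = _stage(
            "replay_decisions",
            lambda: replay_decision_log(
                linked,
                config.decision_log,
                max_gap=config.auto_link_max_gap,
            ),
            log,
        )

    tio.write_csv(linked, out / "corrected.csv")
    tio.write_ctc(linked, out / "ctc")
    with open(out / "links.jsonl", "w") as fh:
        for entry in link_log:
            fh.write(json.dumps(entry) + "\n")
    summary = curation_summary(
        [
            {
                "track_id": e["end_track_id"],
                "candidates": [e],
                "choice": "rank",
                "rank": 1,
                "distance": e["distance"],
            }
            for e in link_log
        ]
    )
    summary.to_csv(out / "curation_summary.csv", index=False)

    manifest = {
        "workflow": "curation",
        "config": asdict(config),
        "seed": config.seed,
        "log": log,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
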