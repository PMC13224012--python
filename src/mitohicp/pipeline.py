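"""End-to-end screen orchestration.

Maps the screening workflow onto discrete stages — simulate, segment,
quantify, features, profile, couple, stats, report — each reading the
previous stage's artifacts from a run directory and writing its own
(CSV/JSON/TIFF/PNG), with a run manifest recording the seed, a config
hash and per-artifact checksums so that identical (config, seed) runs are
verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import coupling as cpl
from . import features as feat
from . import profiling, quantify, segment, simgen, stats
from .manifest import CATALOGUE_SIZE, default_manifest

log = logging.getLogger("mitohicp")

STAGES = ("simulate", "segment", "quantify", "features", "profile", "couple",
          "stats", "report")

DEFAULT_CONFIG: dict = {
    "schema_version": 1,
    "seed": 1,
    "out_dir": "mitohicp_run",
    "plate": {
        "cells_per_field": 30,
        "fields_per_well": 4,
        "wells_per_group": 2,
        "wells": None,          # optional {group name: [well, ...]} override
    },
    "geometry": {},             # FieldGeometry overrides
    "segmentation": {
        "smooth_sigma": 2.0,
        "min_area": 40,
        "split": True,
        "max_cell_distance": 12.0,
        "tophat_radius": 3,
    },
    "background": {"method": "percentile", "percentile": 5.0},
    "coupling": {"control_label": "control"},
    "recovery_tolerance": 0.10,
}


class StageError(RuntimeError):
    pass


def load_config(path_or_dict) -> dict:
    """Load + validate a YAML config, filling defaults."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    if cfg.get("schema_version") != 1:
        raise StageError(f"unsupported config schema_version {cfg.get('schema_version')}")
    wells = cfg["plate"].get("wells")
    if wells:
        for group, wlist in wells.items():
            for w in wlist:
                if w not in simgen.VALID_WELLS:
                    raise simgen.ValidationError(f"invalid 96-well ID {w!r}")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _layout_from_config(cfg: dict) -> simgen.PlateLayout:
    plate = cfg["plate"]
    layout = simgen.default_screen_layout(
        cells_per_field=plate["cells_per_field"],
        fields_per_well=plate["fields_per_well"],
        wells_per_group=plate["wells_per_group"],
    )
    if plate.get("wells"):
        groups = {}
        from dataclasses import replace

        for name, spec in layout.groups.items():
            if name in plate["wells"]:
                spec = replace(spec, wells=tuple(plate["wells"][name]))
            groups[name] = spec
        layout = simgen.PlateLayout(plate_id=layout.plate_id, groups=groups)
    return layout


class Run:
    """A run directory with its manifest."""

    def __init__(self, cfg: dict):
        self.cfg = cfg
        self.dir = Path(cfg["out_dir"])
        self.dir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.dir / "run_manifest.json"
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {
                "pipeline_version": "0.1.0",
                "seed": cfg["seed"],
                "config_hash": _config_hash(cfg),
                "stages": {},
                "artifacts": {},
            }

    def record(self, stage: str, artifacts: list[Path]) -> None:
        self.manifest["stages"][stage] = {"completed_at": time.time()}
        for p in artifacts:
            self.manifest["artifacts"][str(p.relative_to(self.dir))] = _file_hash(p)
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1, sort_keys=True))

    def require(self, artifact: str, stage: str) -> Path:
        p = self.dir / artifact
        if not p.exists():
            raise StageError(f"missing artifact {artifact!r}: run stage {stage!r} first")
        return p

    def artifact_hashes(self) -> dict[str, str]:
        return dict(self.manifest["artifacts"])


# ---------------------------------------------------------------------- stages

def stage_simulate(run: Run) -> None:
    cfg = run.cfg
    layout = _layout_from_config(cfg)
    geom = simgen.default_geometry(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in cfg["geometry"].items()
    })
    simgen.generate_plate(layout, geom, cfg["seed"], run.dir / "plate")
    log.info("simulated plate with %d fields",
             len(json.loads((run.dir / "plate/manifest.json").read_text())["fields"]))
    run.record("simulate", [run.dir / "plate/manifest.json",
                            run.dir / "plate/ground_truth.csv"])


def _iter_fields(run: Run):
    manifest = json.loads(run.require("plate/manifest.json", "simulate").read_text())
    for entry in manifest["fields"]:
        yield manifest, entry


def stage_segment(run: Run) -> None:
    import tifffile

    seg_cfg = run.cfg["segmentation"]
    params = segment.NucleiParams(
        smooth_sigma=seg_cfg["smooth_sigma"], min_area=seg_cfg["min_area"],
        split=seg_cfg["split"],
    )
    out = run.dir / "segmentation"
    out.mkdir(exist_ok=True)
    counts = []
    for _, entry in _iter_fields(run):
        stack = simgen.read_field(run.dir / "plate", entry)
        maps = segment.segment_field(
            stack, params,
            max_cell_distance=seg_cfg["max_cell_distance"],
            tophat_radius=seg_cfg["tophat_radius"],
        )
        stem = f"{entry['well']}_f{entry['field']}"
        path = out / f"{stem}_labels.tiff"
        tifffile.imwrite(
            path,
            np.stack([maps["nuclei"], maps["cells"], maps["mito"]]).astype(np.uint16),
            photometric="minisblack",
            description=json.dumps({"pages": ["nuclei", "cells", "mito"]}),
        )
        n = int(maps["cells"].max())
        counts.append({"well": entry["well"], "field": entry["field"], "n_objects": n})
        log.info("segmented %s: %d cells", stem, n)
    counts_path = out / "object_counts.csv"
    pd.DataFrame(counts).to_csv(counts_path, index=False)
    run.record("segment", [counts_path])


def stage_quantify(run: Run) -> None:
    import tifffile

    run.require("segmentation/object_counts.csv", "segment")
    bg_cfg = run.cfg["background"]
    tables = []
    for _, entry in _iter_fields(run):
        stack = simgen.read_field(run.dir / "plate", entry)
        stem = f"{entry['well']}_f{entry['field']}"
        pages = tifffile.imread(run.dir / "segmentation" / f"{stem}_labels.tiff")
        nuclei, cells, mito = (p.astype(np.int32) for p in pages)
        background = {
            role: quantify.estimate_background(
                stack[role], cells, method=bg_cfg["method"],
                percentile=bg_cfg["percentile"],
            )
            for role in simgen.CHANNEL_ORDER
        }
        t = quantify.measure_cells(
            stack, cells, nuclei, mito, background,
            metadata={
                "well": entry["well"], "field": entry["field"],
                "cell_line": entry["cell_line"], "compound": entry["compound"],
                "dose": entry["dose"],
            },
        )
        if len(t):
            tables.append(t)
    pooled = quantify.pool_screen(tables)
    path = run.dir / "cells.csv"
    pooled.to_csv(path, index=False)
    log.info("quantified %d cells", len(pooled))
    run.record("quantify", [path])


def stage_features(run: Run) -> None:
    import tifffile

    run.require("segmentation/object_counts.csv", "segment")
    manifest = default_manifest()
    tables = []
    for _, entry in _iter_fields(run):
        stack = simgen.read_field(run.dir / "plate", entry)
        stem = f"{entry['well']}_f{entry['field']}"
        pages = tifffile.imread(run.dir / "segmentation" / f"{stem}_labels.tiff")
        nuclei, cells, mito = (p.astype(np.int32) for p in pages)
        t = feat.extract_features(
            stack, {"nuclei": nuclei, "cells": cells, "mito": mito}, manifest,
            metadata={
                "well": entry["well"], "field": entry["field"],
                "cell_line": entry["cell_line"], "compound": entry["compound"],
                "dose": entry["dose"],
            },
        )
        tables.append(t)
        log.info("features for %s: %d cells", stem, len(t))
    allfeat = pd.concat(tables, ignore_index=True)
    fpath = run.dir / "features.csv"
    allfeat.to_csv(fpath, index=False)
    profiles = feat.aggregate_image_profiles(
        allfeat, keys=("well", "field"), feature_names=manifest.names
    )
    ppath = run.dir / "profiles.csv"
    profiles.to_csv(ppath, index=False)
    run.record("features", [fpath, ppath])


def stage_profile(run: Run) -> None:
    profiles = pd.read_csv(run.require("profiles.csv", "features"))
    manifest = default_manifest()
    X = profiles[[c for c in manifest.names if c in profiles.columns]]
    X = X.dropna(axis=1, how="any")
    normalized, dropped = profiling.zscore_normalize(X)
    res = profiling.pca_embed(normalized, k=2, dropped_features=dropped)

    out = run.dir / "profiling"
    out.mkdir(exist_ok=True)
    scores = res.scores.copy()
    for c in ("well", "field", "cell_line", "compound", "dose"):
        if c in profiles.columns:
            scores[c] = profiles[c].to_numpy()
    scores.to_csv(out / "pca_scores.csv", index=False)
    res.loadings.to_csv(out / "pca_loadings.csv")
    pd.DataFrame(
        {"component": [f"PC{i+1}" for i in range(len(res.variance_explained_full))],
         "variance_explained": res.variance_explained_full}
    ).to_csv(out / "pca_variance.csv", index=False)
    fam = profiling.rank_family_contributions(res, manifest.subset(names=list(normalized.columns)))
    fam.to_csv(out / "family_contributions.csv", index=False)

    fig, ax = plt.subplots(figsize=(6, 5))
    if "compound" in profiles.columns:
        for (line, comp), sub in scores.groupby(["cell_line", "compound"]):
            ax.scatter(sub["PC1"], sub["PC2"], label=f"{line}:{comp}", s=18)
        ax.legend(fontsize=6)
    else:
        ax.scatter(scores["PC1"], scores["PC2"], s=18)
    ax.set_xlabel(f"PC1 ({100 * res.variance_explained[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * res.variance_explained[1]:.1f}%)")
    fig.savefig(out / "pca.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    # per-group median profiles -> clustered heatmap
    if "compound" in profiles.columns:
        med = normalized.join(profiles[["cell_line", "compound"]]).groupby(
            ["cell_line", "compound"]
        ).median()
        med.index = [f"{a}:{b}" for a, b in med.index]
        try:
            hm = profiling.cluster_heatmap(med)
            with open(out / "dendrogram.txt", "w") as fh:
                fh.write(_linkage_to_newick(hm["linkage"], list(med.index)))
            fig, ax = plt.subplots(figsize=(7, 4))
            ax.imshow(hm["matrix"].to_numpy(), aspect="auto", cmap="RdBu_r",
                      vmin=-3, vmax=3)
            ax.set_yticks(range(len(hm["row_labels"])), hm["row_labels"], fontsize=6)
            ax.set_xticks([])
            fig.savefig(out / "heatmap.png", dpi=120, bbox_inches="tight")
            plt.close(fig)
        except ValueError as err:
            log.warning("heatmap skipped: %s", err)
    run.record("profile", [out / "pca_scores.csv", out / "pca_loadings.csv",
                           out / "pca_variance.csv", out / "family_contributions.csv"])


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    n = len(labels)
    nodes: dict[int, str] = {i: labels[i] for i in range(n)}
    heights: dict[int, float] = {i: 0.0 for i in range(n)}
    for i, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        nodes[n + i] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + i] = h
    return nodes[n + len(Z) - 1] + ";"


def stage_couple(run: Run) -> None:
    cells = pd.read_csv(run.require("cells.csv", "quantify"))
    results, comparisons = cpl.coupling_profile(
        cells, control_label=run.cfg["coupling"]["control_label"]
    )
    res_t, cmp_t = cpl.coupling_tables(results, comparisons)
    res_t.to_csv(run.dir / "coupling.csv", index=False)
    cmp_t.to_csv(run.dir / "coupling_tests.csv", index=False)

    out = run.dir / "profiling"
    out.mkdir(exist_ok=True)
    fig, ax = plt.subplots(figsize=(8, 4))
    data = [r.per_image_r for r in results if r.per_image_r]
    if data:
        labels = [f"{r.group}\n{r.pair}" for r in results if r.per_image_r]
        finite = [[v for v in d if np.isfinite(v)] for d in data]
        keep = [i for i, d in enumerate(finite) if d]
        if keep:
            ax.violinplot([finite[i] for i in keep], showmeans=True, showmedians=True)
            ax.set_xticks(range(1, len(keep) + 1),
                          [labels[i] for i in keep], fontsize=5, rotation=90)
            ax.set_ylabel("per-image PCC (r)")
    fig.savefig(out / "coupling_violins.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
    run.record("couple", [run.dir / "coupling.csv", run.dir / "coupling_tests.csv"])


def stage_stats(run: Run) -> None:
    cells = pd.read_csv(run.require("cells.csv", "quantify"))
    frames = []
    for readout in ("mmp_mito_corr_mean", "ros_corr_mean", "mtros_mito_corr_mean"):
        s = stats.summarize_groups(
            cells, value=readout, group="compound",
            control_label=run.cfg["coupling"]["control_label"],
            extra_keys=("cell_line",),
        )
        s.insert(0, "readout", readout)
        frames.append(s)
    path = run.dir / "group_summary.csv"
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    run.record("stats", [path])


def stage_report(run: Run) -> None:
    report: dict = {"sections": {}}
    tol = run.cfg["recovery_tolerance"]

    if (run.dir / "cells.csv").exists():
        cells = pd.read_csv(run.dir / "cells.csv")
        per_group = cells.groupby(["cell_line", "compound"]).size()
        report["sections"]["screen"] = {
            "n_cells": int(len(cells)),
            "groups": {":".join(k): int(v) for k, v in per_group.items()},
            "min_cells_per_group": int(per_group.min()),
            "meets_200_cell_floor": bool(per_group.min() >= 200),
        }
    else:
        report["sections"]["screen"] = {"status": "not run"}

    if (run.dir / "features.csv").exists():
        manifest = default_manifest()
        header = pd.read_csv(run.dir / "features.csv", nrows=0).columns
        n_feat = sum(c in set(manifest.names) for c in header)
        report["sections"]["features"] = {
            "n_feature_columns": int(n_feat),
            "catalogue_complete": bool(n_feat == CATALOGUE_SIZE),
        }
    else:
        report["sections"]["features"] = {"status": "not run"}

    # latent-correlation recovery vs the generator's rho
    if (run.dir / "coupling.csv").exists() and (run.dir / "plate/manifest.json").exists():
        plate = json.loads((run.dir / "plate/manifest.json").read_text())
        coupling_t = pd.read_csv(run.dir / "coupling.csv")
        recovery = []
        for name, g in plate["groups"].items():
            rho = np.asarray(g["rho"])
            truth = {"MMP-ROS": rho[0, 1], "MMP-mtROS": rho[0, 2]}
            gname = f"{g['cell_line']}:{g['compound']}"
            for pair, rho_true in truth.items():
                row = coupling_t[(coupling_t["group"] == gname)
                                 & (coupling_t["pair"] == pair)]
                if len(row):
                    r = float(row["r"].iloc[0])
                    recovery.append({
                        "group": gname, "pair": pair, "rho_generating": rho_true,
                        "r_measured": r, "delta": abs(r - rho_true),
                        "within_tolerance": bool(abs(r - rho_true) <= tol),
                    })
        report["sections"]["recovery"] = {
            "tolerance": tol, "rows": recovery,
            "flagged": [r for r in recovery if not r["within_tolerance"]],
        }
    else:
        report["sections"]["recovery"] = {"status": "not run"}

    path = run.dir / "report.json"
    path.write_text(json.dumps(report, indent=1, sort_keys=True))
    lines = ["# Screen report", ""]
    for name, sec in report["sections"].items():
        lines.append(f"## {name}")
        lines.append("```json")
        lines.append(json.dumps(sec, indent=1, sort_keys=True))
        lines.append("```")
    (run.dir / "report.md").write_text("\n".join(lines))
    run.record("report", [path])


_STAGE_FN = {
    "simulate": stage_simulate, "segment": stage_segment,
    "quantify": stage_quantify, "features": stage_features,
    "profile": stage_profile, "couple": stage_couple,
    "stats": stage_stats, "report": stage_report,
}


def run_stage(stage: str, config) -> Run:
    """Run one stage (or ``"all"``) against a config path/dict."""
    cfg = load_config(config)
    run = Run(cfg)
    stages = STAGES if stage == "all" else (stage,)
    for s in stages:
        if s not in _STAGE_FN:
            raise StageError(f"unknown stage {s!r}; choose from {STAGES + ('all',)}")
        log.info("running stage %s", s)
        _STAGE_FN[s](run)
    return run
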