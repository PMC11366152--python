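"""End-to-end orchestration: simulate → segment → integrate → statistics.

All randomness flows from named seeds in the config; re-running an
identical config reproduces identical output hashes, recorded in a
``RunManifest``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .cohort import CohortDesign, generate_cohort, generate_rater_pairs
from .errors import ConfigurationError, StageError
from .geometry import QUADRANTS, ScanGeometry
from .network import NetworkParams, analytic_capillary_volume, generate_network
from .render import RenderParams, render_stack
from .reconstruction import compute_ppcv
from .segmentation import SegmentationSettings
from .stats import fit_linear_model, gee_group_comparison, icc_two_rater

log = logging.getLogger("ppcv")

__version__ = "0.1.0"

#: keys every pipeline config must spell out explicitly (no silent defaults
#: for quantities that define the measurement)
_REQUIRED = {
    "segmentation": ("threshold",),
    "seeds": ("network", "render", "cohort", "raters"),
}


@dataclass(frozen=True)
class PipelineConfig:
    geometry: ScanGeometry
    network: NetworkParams
    render: RenderParams
    segmentation: SegmentationSettings
    cohort: CohortDesign
    seeds: dict
    output_dir: str = "ppcv_run"
    n_stacks_per_quadrant: int = 1
    alpha: float = 0.05

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        for block, keys in _REQUIRED.items():
            if block not in d:
                raise ConfigurationError(f"config missing block {block!r}")
            for k in keys:
                if k not in d[block]:
                    raise ConfigurationError(
                        f"config block {block!r} missing required key {k!r}")
        return cls(
            geometry=ScanGeometry.from_dict(d.get("geometry", {})),
            network=NetworkParams.from_dict(d.get("network", {})),
            render=RenderParams.from_dict(d.get("render", {})),
            segmentation=SegmentationSettings.from_dict(d["segmentation"]),
            cohort=CohortDesign.from_dict(d.get("cohort", {})),
            seeds=dict(d["seeds"]),
            output_dir=d.get("output_dir", "ppcv_run"),
            n_stacks_per_quadrant=int(d.get("n_stacks_per_quadrant", 1)),
            alpha=float(d.get("alpha", 0.05)),
        )

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return {
            "geometry": self.geometry.to_dict(),
            "network": self.network.to_dict(),
            "render": self.render.to_dict(),
            "segmentation": self.segmentation.to_dict(),
            "cohort": self.cohort.to_dict(),
            "seeds": self.seeds,
            "output_dir": self.output_dir,
            "n_stacks_per_quadrant": self.n_stacks_per_quadrant,
            "alpha": self.alpha,
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    version: str
    outputs: dict = field(default_factory=dict)  # relative path -> sha256
    stages: dict = field(default_factory=dict)   # stage -> list of outputs

    def record(self, stage: str, path: Path, root: Path):
        rel = str(path.relative_to(root))
        self.outputs[rel] = pio.file_sha256(path)
        self.stages.setdefault(stage, []).append(rel)

    def to_dict(self) -> dict:
        return {"config_hash": self.config_hash, "version": self.version,
                "stages": self.stages, "outputs": self.outputs}


def run_full(config: PipelineConfig, output_dir=None) -> RunManifest:
    """Run the whole pipeline, writing every intermediate artifact.

    Stages: phantom simulation (one stack per quadrant), per-stack
    segmentation + PPCV integration, cohort simulation, and statistics
    (regression fit, per-quadrant GEE comparisons of healthy vs DR at
    baseline, and the two-rater ICC).
    """
    root = Path(output_dir or config.output_dir)
    root.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.config_hash(), __version__)

    pio.write_json(config.to_dict(), root / "config.json")
    manifest.record("config", root / "config.json", root)

    # --- simulate + segment + integrate -----------------------------------
    ppcv_rows = []
    stack_index = 0
    for q in QUADRANTS:
        for rep in range(config.n_stacks_per_quadrant):
            stage = "simulate"
            try:
                geom = ScanGeometry(**{**config.geometry.to_dict(), "quadrant": q})
                net_seed = int(config.seeds["network"]) + stack_index
                ren_seed = int(config.seeds["render"]) + stack_index
                net = generate_network(config.network, geom, net_seed)
                gt = analytic_capillary_volume(net, geom)
                stack = render_stack(net, geom, config.render, ren_seed)
                spath = root / "stacks" / f"stack_{q}_{rep:02d}.tif"
                pio.write_stack(stack, spath, ground_truth=gt)
                manifest.record(stage, spath, root)
                manifest.record(stage, pio.sidecar_path(spath), root)

                stage = "segment+integrate"
                from .segmentation import stack_area_profile
                profile = stack_area_profile(stack, config.segmentation)
                ppath = root / "profiles" / f"profile_{q}_{rep:02d}.csv"
                pio.write_profile(profile, ppath)
                manifest.record(stage, ppath, root)
                result = compute_ppcv(stack, config.segmentation, quadrant=q)
                row = result.to_dict()
                row["true_capillary_volume_um3"] = gt.capillary_volume_um3
                ppcv_rows.append(row)
            except Exception as exc:
                log.error("stage %s failed on stack %s/%d: %s", stage, q, rep, exc)
                raise StageError(stage, str(exc), input_id=f"{q}/{rep}") from exc
            stack_index += 1

    ppcv_path = root / "ppcv_results.csv"
    pd.DataFrame(ppcv_rows).to_csv(ppcv_path, index=False)
    manifest.record("segment+integrate", ppcv_path, root)

    # --- cohort + statistics -----------------------------------------------
    try:
        cohort = generate_cohort(config.cohort, int(config.seeds["cohort"]))
        cpath = root / "cohort.csv"
        pio.write_cohort(cohort, cpath)
        manifest.record("cohort", cpath, root)
    except Exception as exc:
        log.error("stage cohort failed: %s", exc)
        raise StageError("cohort", str(exc)) from exc

    try:
        healthy = cohort[cohort["group"] == "healthy"]
        fit = fit_linear_model(healthy, "ppcv_um3", ["age_years", "sex", "hemisphere"])
        pio.write_json({"regression": fit.__dict__}, root / "stats" / "regression.json")
        manifest.record("stats", root / "stats" / "regression.json", root)

        comparisons = []
        baseline_dr = cohort[(cohort["group"] != "healthy") &
                             (cohort["timepoint"] == "baseline")]
        merged = pd.concat([healthy, baseline_dr])
        merged = merged.assign(status=np.where(merged["group"] == "healthy",
                                               "healthy", "dr"))
        for q in QUADRANTS:
            res = gee_group_comparison(merged[merged["quadrant"] == q],
                                       "dr", "healthy", group_col="status",
                                       alpha=config.alpha,
                                       label=f"DR vs healthy [{q}]")
            comparisons.append({
                "label": res.label, "estimate": res.estimate,
                "statistic": res.statistic, "p_value": res.p_value,
                "method": res.method, "alpha": res.alpha,
                "significant": res.significant,
            })
        comp_path = root / "stats" / "comparisons.csv"
        pd.DataFrame(comparisons).to_csv(comp_path, index=False)
        manifest.record("stats", comp_path, root)

        pairs = generate_rater_pairs(
            healthy["ppcv_um3"].to_numpy(), config.cohort.icc_target,
            sigma_between=float(healthy["ppcv_um3"].std(ddof=1)),
            seed=int(config.seeds["raters"]))
        rel = icc_two_rater(pairs)
        pio.write_json({"icc": rel.icc, "variance_components": rel.variance_components,
                        "n": rel.n}, root / "stats" / "reliability.json")
        manifest.record("stats", root / "stats" / "reliability.json", root)
    except Exception as exc:
        log.error("stage stats failed: %s", exc)
        raise StageError("stats", str(exc)) from exc

    pio.write_json(manifest.to_dict(), root / "manifest.json")
    return manifest
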