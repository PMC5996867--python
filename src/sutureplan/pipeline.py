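"""End-to-end orchestration: phantom/stack -> V, T, B -> J -> suture plan.

This is the library surface behind the command-line interface: a single
:class:`PipelineConfig` collects every stage's parameters, and
:func:`run_pipeline` executes the whole flow deterministically (the only
randomness is the phantom seed), optionally writing all artifacts — maps,
plan table, overlays and a machine-readable run log — to an output
directory.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as spio
from .classify import (
    BiteDepthParams,
    ClassMap,
    TrainingField,
    bite_depth_map,
    classify_pixels,
    extract_cut_edge,
    train_discriminant,
)
from .io import MultispectralStack, ScoreMap
from .phantom import GroundTruth, PhantomSpec, generate_phantom
from .sam import SpectralLibrary, build_reference, sam_classify, thickness_map
from .suturemap import SuturePlan, fuse, local_maxima, refine_equidistant
from .vesselness import FrangiParams, VesselMapParams, binarize_vesselness, frangi_vesselness, vessel_map

#: Default training rectangles, matched to the default phantom geometry.
DEFAULT_TRAINING_FIELDS: list[tuple[str, tuple[int, int, int, int]]] = [
    ("background", (2, 12, 2, 120)),
    ("mesentery", (20, 36, 60, 200)),
    ("inner_lumen", (100, 180, 40, 90)),
    ("outer_lumen", (60, 140, 170, 186)),
    ("outer_lumen", (60, 140, 226, 238)),
]

#: Default reference regions for the spectral library: five disjoint patches
#: per endmember, as is customary when averaging reference spectra.
DEFAULT_SAM_REGIONS: dict[str, list[tuple[int, int, int, int]]] = {
    "nonincised": [
        (56, 62, 166, 172),
        (70, 76, 174, 180),
        (84, 90, 166, 172),
        (98, 104, 174, 180),
        (112, 118, 166, 172),
    ],
    "thin_serosa": [
        (60, 66, 224, 230),
        (74, 80, 230, 236),
        (88, 94, 224, 230),
        (102, 108, 230, 236),
        (116, 122, 224, 230),
    ],
    "incised": [
        (60, 66, 40, 46),
        (80, 86, 60, 66),
        (100, 106, 40, 46),
        (120, 126, 60, 66),
        (140, 146, 40, 46),
    ],
}


@dataclass
class PipelineConfig:
    """Everything needed to run the full suture-planning flow."""

    phantom: PhantomSpec | None = None
    input_path: str | None = None
    vessel_band_nm: float = 470.0
    frangi: FrangiParams = field(default_factory=FrangiParams)
    vessel: VesselMapParams = field(default_factory=VesselMapParams)
    sam_regions: dict[str, list[tuple[int, int, int, int]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_SAM_REGIONS.items()}
    )
    sam_angle_threshold_rad: float = 0.10
    thick_label: str = "nonincised"
    thickness_sigma_mm: float = 0.3
    training_fields: list[tuple[str, tuple[int, int, int, int]]] = field(
        default_factory=lambda: list(DEFAULT_TRAINING_FIELDS)
    )
    bite: BiteDepthParams = field(default_factory=lambda: BiteDepthParams(tau_mm=1.0))
    dilation_radius_px: int = 2
    fusion_threshold: float = 0.5
    spacing_tolerance_frac: float = 0.25
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phantom is None and self.input_path is None:
            self.phantom = PhantomSpec(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "phantom" in raw:
            kwargs["phantom"] = PhantomSpec(**raw["phantom"])
        if "frangi" in raw:
            kwargs["frangi"] = FrangiParams(**raw["frangi"])
        if "vessel" in raw:
            kwargs["vessel"] = VesselMapParams(**raw["vessel"])
        if "bite" in raw:
            kwargs["bite"] = BiteDepthParams(**raw["bite"])
        if "training_fields" in raw:
            kwargs["training_fields"] = [
                (f["label"], tuple(f["rect"])) for f in raw["training_fields"]
            ]
        if "sam_regions" in raw:
            kwargs["sam_regions"] = {
                k: [tuple(r) for r in v] for k, v in raw["sam_regions"].items()
            }
        for key in (
            "input_path",
            "vessel_band_nm",
            "sam_angle_threshold_rad",
            "thick_label",
            "thickness_sigma_mm",
            "dilation_radius_px",
            "fusion_threshold",
            "spacing_tolerance_frac",
            "out_dir",
            "seed",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """In-memory bundle of every pipeline intermediate and output."""

    stack: MultispectralStack
    ground_truth: GroundTruth | None
    vessel_binary: np.ndarray
    v_map: ScoreMap
    class_map: ClassMap
    library: SpectralLibrary
    sam_labels: np.ndarray
    t_map: ScoreMap
    edge_mask: np.ndarray
    b_map: ScoreMap
    j_map: ScoreMap
    candidates: list
    plan: SuturePlan
    out_dir: Path | None = None


def plan_table(plan: SuturePlan) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "row": p.position[0],
                "col": p.position[1],
                "score": round(p.score, 6),
                "arc_mm": round(p.arc_position_mm, 4)
                if p.arc_position_mm is not None
                else float("nan"),
            }
            for p in plan.points
        ],
        columns=["row", "col", "score", "arc_mm"],
    )


def _stage(name: str):
    """Decorate stage failures with the stage name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full planning flow described by ``config``.

    Identical config and seed give identical outputs; any stage failure
    aborts with the stage name and cause.
    """
    with _stage("input"):
        if config.input_path is not None:
            stack = spio.read_stack(config.input_path)
            gt = None
        else:
            spec = dataclasses.replace(config.phantom, seed=config.seed)
            stack, gt = generate_phantom(spec)

    with _stage("vessel_map"):
        band = stack.band(config.vessel_band_nm)
        resp = frangi_vesselness(band, config.frangi)
        vessel_binary = binarize_vesselness(resp, config.vessel)
        v_map = vessel_map(resp, config.vessel, stack.pixel_pitch_mm, vessel_binary)

    with _stage("classification"):
        fields = [TrainingField(lab, rect) for lab, rect in config.training_fields]
        model = train_discriminant(stack, fields)
        class_map = classify_pixels(stack, model)

    with _stage("thickness_map"):
        endmembers = [
            (label, build_reference(stack, regions))
            for label, regions in config.sam_regions.items()
        ]
        library = SpectralLibrary(endmembers, config.sam_angle_threshold_rad)
        sam_labels, _ = sam_classify(stack, library)
        exclude = class_map.mask("mesentery") | vessel_binary
        t_map = thickness_map(
            sam_labels,
            library.index(config.thick_label),
            config.thickness_sigma_mm,
            stack.pixel_pitch_mm,
            exclude_mask=exclude,
        )

    with _stage("bite_depth"):
        edge_mask = extract_cut_edge(class_map, config.dilation_radius_px)
        b_map = bite_depth_map(edge_mask, class_map, config.bite, stack.pixel_pitch_mm)

    with _stage("suture_plan"):
        j_map = fuse(v_map, t_map, b_map)
        candidates = local_maxima(j_map, config.fusion_threshold)
        plan = refine_equidistant(
            candidates,
            edge_mask,
            spacing_target_mm=1.5 * config.bite.tau_mm,
            spacing_tolerance_frac=config.spacing_tolerance_frac,
            pixel_pitch_mm=stack.pixel_pitch_mm,
        )

    result = PipelineResult(
        stack=stack,
        ground_truth=gt,
        vessel_binary=vessel_binary,
        v_map=v_map,
        class_map=class_map,
        library=library,
        sam_labels=sam_labels,
        t_map=t_map,
        edge_mask=edge_mask,
        b_map=b_map,
        j_map=j_map,
        candidates=candidates,
        plan=plan,
    )
    if config.out_dir is not None:
        result.out_dir = write_artifacts(result, config)
    return result


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            k: _jsonable(v)
            for k, v in dataclasses.asdict(obj).items()
            if not k.startswith("_")
        }
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_artifacts(result: PipelineResult, config: PipelineConfig) -> Path:
    """Write maps, plan table, overlays and the run log to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.write_stack(result.stack, out / "stack.tif")
    for name, smap in [
        ("V", result.v_map),
        ("T", result.t_map),
        ("B", result.b_map),
        ("J", result.j_map),
    ]:
        spio.write_score_map(smap, out / f"map_{name}.tif")
    plan_table(result.plan).to_csv(out / "plan.csv", index=False)

    band = result.stack.band(config.vessel_band_nm)
    spio.write_overlay_png(
        spio.render_overlay(band, result.vessel_binary, color=(1, 0, 0), alpha=1.0),
        out / "overlay_vessels.png",
    )
    spio.write_overlay_png(
        spio.render_overlay(band, result.j_map, cmap="viridis"),
        out / "overlay_suture_map.png",
    )
    spio.write_overlay_png(
        spio.render_overlay(band, result.plan.points, color=(0, 1, 0)),
        out / "overlay_recommendations.png",
    )

    log = {
        "seed": config.seed,
        "config": _jsonable(config),
        "n_candidates": len(result.candidates),
        "n_recommended": len(result.plan.points),
        "bite_sigma_mm": config.bite.sigma_mm,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    return out
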