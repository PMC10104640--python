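"""Pipeline orchestration, configuration and file I/O.

Ties the stages into the four-step workflow: segment the vessels,
skeletonize the mask, build and classify the vessel graph, then derive
intravascular concentration maps and extravascular diffusion metrics.
Each run writes its outputs together with a manifest (inputs, parameters,
checksums) so that reruns with an identical configuration reproduce
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .photometry import CalibrationModel, DEFAULT_EPSILON, propagate_concentration
from .skeleton import prune_spurs, skeletonize
from .topology import VesselGraph, Edge, Node, build_graph, classify_levels, detect_root, summarize_levels

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "read_image",
    "write_image",
    "read_graph",
    "write_graph",
    "read_table",
    "write_table",
]


# ---------------------------------------------------------------------------
# image / graph / table I/O
# ---------------------------------------------------------------------------


def read_image(path, allow_rescale: bool = False) -> np.ndarray:
    """Read a grayscale image (TIFF or PNG) as float64 in [0, 255].

    16-bit inputs are linearly rescaled to 8-bit range when
    ``allow_rescale`` is set, otherwise an error suggests the conversion.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    if arr.dtype == np.uint8:
        return arr.astype(float)
    if arr.dtype == np.uint16:
        if not allow_rescale:
            raise ValueError(
                f"{path.name} is 16-bit; pass allow_rescale=True (CLI: --allow-rescale) "
                "to map it linearly onto 0-255"
            )
        return arr.astype(float) * (255.0 / 65535.0)
    if np.issubdtype(arr.dtype, np.floating):
        return np.asarray(arr, dtype=float)
    raise ValueError(f"unsupported bit depth {arr.dtype} in {path.name}")


def write_image(path, image) -> None:
    """Write an image as 8-bit (values clamped to 0-255 and rounded)."""
    path = Path(path)
    arr = np.clip(np.asarray(image, dtype=float), 0, 255)
    arr8 = np.round(arr).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr8)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr8)


def write_mask(path, mask) -> None:
    write_image(path, (np.asarray(mask) != 0) * 255)


def read_mask(path) -> np.ndarray:
    return (read_image(path) > 127).astype(np.uint8)


def write_graph(path, graph: VesselGraph) -> None:
    """Serialize a vessel graph to JSON (nodes, edges with pixel paths)."""
    doc = {
        "shape": list(graph.shape),
        "pixel_pitch_um": graph.pixel_pitch_um,
        "nodes": [
            {"id": n.id, "rc": list(n.rc), "kind": n.kind} for n in sorted(graph.nodes.values(), key=lambda n: n.id)
        ],
        "edges": [
            {
                "id": e.id,
                "u": e.u,
                "v": e.v,
                "path": [list(p) for p in e.path],
                "length_px": e.length_px,
                "mean_diameter_px": e.mean_diameter_px,
                "level": e.level,
            }
            for e in sorted(graph.edges.values(), key=lambda e: e.id)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_graph(path) -> VesselGraph:
    doc = json.loads(Path(path).read_text())
    g = VesselGraph(shape=tuple(doc["shape"]), pixel_pitch_um=doc["pixel_pitch_um"])
    for n in doc["nodes"]:
        g.nodes[n["id"]] = Node(n["id"], tuple(n["rc"]), n["kind"])
    for e in doc["edges"]:
        g.edges[e["id"]] = Edge(
            e["id"],
            e["u"],
            e["v"],
            [tuple(p) for p in e["path"]],
            e["length_px"],
            e["mean_diameter_px"],
            e["level"],
        )
    return g


def write_table(path, df) -> None:
    """CSV with stable column order and full float precision."""
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def read_table(path):
    import pandas as pd

    return pd.read_csv(path)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end run description (loadable from YAML).

    Inputs are either bright-field image paths (``bright_paths``, one per
    time point) plus optional fluorescent paths, or a phantom request
    (``phantom: true``) that generates ``n_time_points`` synthetic frames.
    """

    out_dir: str = "vasq_out"
    bright_paths: list[str] = field(default_factory=list)
    fluor_paths: list[str] = field(default_factory=list)
    phantom: bool = False
    n_time_points: int = 1
    pixel_pitch_um: float = 20.0
    seed: int = 0
    segmentation: str = "classical"  # or path to a trained model (unsupported here)
    invert: bool = False
    spur_min_px: int = 5
    include_satellites: bool = False
    max_level: int = 5
    c0_mg_ml: float = 5.0
    epsilon: float = DEFAULT_EPSILON
    concentration_max_level: int = 2
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def _load_inputs(cfg: RunConfig):
    if cfg.phantom:
        from .phantom import PhantomSpec, generate_phantom

        frames = []
        base = generate_phantom(PhantomSpec(pixel_pitch_um=cfg.pixel_pitch_um, seed=cfg.seed))
        rng = np.random.default_rng(cfg.seed + 1)
        for t in range(cfg.n_time_points):
            # emulate washout: intravascular contrast fades over time
            fade = 1.0 / (1.0 + t)
            bright = base.spec.background_gray - (base.spec.background_gray - base.bright_field) * fade
            bright = np.clip(bright + rng.normal(0, 0.0, bright.shape), 0, 255)
            fluor = np.clip(base.fluorescent * fade, 0, 255)
            frames.append((f"phantom_t{t}", bright, fluor))
        return frames
    frames = []
    for i, bp in enumerate(cfg.bright_paths):
        try:
            bright = read_image(bp)
        except Exception as err:
            raise RuntimeError(f"stage segment: cannot read input image {bp}: {err}") from err
        fluor = None
        if i < len(cfg.fluor_paths):
            fluor = read_image(cfg.fluor_paths[i])
        frames.append((Path(bp).stem, bright, fluor))
    return frames


def run_pipeline(config: RunConfig) -> dict:
    """Execute segment -> skeletonize -> topology -> photometry -> diffusion.

    Returns the run manifest (also written to ``<out_dir>/manifest.json``),
    listing the stages completed, parameters, and SHA-256 checksums of the
    written artifacts.  Any stage failure aborts with the stage name and
    the offending file in the error message.
    """
    from . import diffusion as diff
    from .segmentation import classical_segment

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    frames = _load_inputs(config)
    if not frames:
        raise ValueError("no input frames configured")

    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": [],
        "outputs": {},
        "frames": [name for name, _, _ in frames],
    }
    graphs = []
    cov_rows = []
    conc_tables = []
    for t, (name, bright, fluor) in enumerate(frames):
        # (i) segmentation
        try:
            mask = classical_segment(bright, invert=config.invert)
        except Exception as err:
            raise RuntimeError(f"stage segment failed on {name}: {err}") from err
        write_mask(out / f"{name}_mask.png", mask)
        # (ii) skeleton
        skel = prune_spurs(skeletonize(mask), config.spur_min_px)
        write_mask(out / f"{name}_skeleton.png", skel)
        # (iii) topology
        try:
            graph = build_graph(
                skel,
                mask,
                pixel_pitch_um=config.pixel_pitch_um,
                include_satellites=config.include_satellites,
                spur_min_px=config.spur_min_px,
            )
            root = detect_root(graph)
            classify_levels(graph, root, max_level=config.max_level)
            graph.nodes[root].kind = "root"
        except Exception as err:
            raise RuntimeError(f"stage topology failed on {name}: {err}") from err
        write_graph(out / f"{name}_graph.json", graph)
        graphs.append(graph)
        # (iv) photometry
        calib = CalibrationModel(epsilon=config.epsilon, k=0.0)
        cmap = propagate_concentration(
            graph, bright, calib, config.c0_mg_ml, max_level=config.concentration_max_level, root=root
        )
        import pandas as pd

        conc_df = pd.DataFrame(
            {
                "time": t,
                "edge_id": sorted(cmap.concentration),
                "c_mg_ml": [cmap.concentration[e] for e in sorted(cmap.concentration)],
                "c_over_c0": [cmap.normalized[e] for e in sorted(cmap.concentration)],
                "clipped": [e in cmap.clipped for e in sorted(cmap.concentration)],
            }
        )
        conc_tables.append(conc_df)
        # (v) diffusion coverage (fluorescent channel, when present)
        if fluor is not None:
            rec = diff.coverage(fluor, mask, pixel_pitch_um=config.pixel_pitch_um, time=t)
            cov_rows.append(
                {
                    "time": t,
                    "total_px": rec.total_px,
                    "intra_px": rec.intra_px,
                    "extra_px": rec.extra_px,
                    "extra_intra_ratio": rec.extra_intra_ratio,
                }
            )
    import pandas as pd

    levels = summarize_levels(graphs, max_level=config.max_level)
    write_table(out / "levels.csv", levels)
    write_table(out / "concentration.csv", pd.concat(conc_tables, ignore_index=True))
    manifest["stages"] = ["segment", "skeleton", "topology", "photometry"]
    if cov_rows:
        write_table(out / "coverage.csv", pd.DataFrame(cov_rows))
        manifest["stages"].append("diffusion")
    for p in sorted(out.glob("*")):
        if p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
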