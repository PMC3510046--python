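"""File I/O: multi-page TIFF stacks, truth JSON/CSV, YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .synthetic_data import ParticleTruth, TransportSimSpec

__all__ = [
    "write_stack",
    "read_stack",
    "write_truth_json",
    "read_truth_json",
    "truth_summary_csv",
    "load_yaml",
    "load_transport_spec",
    "read_path_csv",
]


def write_stack(stack: np.ndarray, path) -> None:
    """Write a (frames, H, W) stack as a multi-page TIFF, one page per frame."""
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32))


def read_stack(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_truth_json(truth: ParticleTruth, path) -> None:
    doc = {
        "spec": {k: v for k, v in vars(truth.spec).items()},
        "insertion_times": truth.insertion_times,
        "particles": [
            {
                "id": p.particle_id,
                "class": p.klass,
                "t": p.t.tolist(),
                "x": p.x.tolist(),
                "insertion_time": p.insertion_time,
                "speed": p.speed,
            }
            for p in truth.particles
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_truth_json(path) -> ParticleTruth:
    from .synthetic_data import Particle

    doc = json.loads(Path(path).read_text())
    spec_doc = dict(doc["spec"])
    spec_doc["bleach_window"] = tuple(spec_doc["bleach_window"])
    spec = TransportSimSpec(**spec_doc)
    particles = [
        Particle(p["id"], p["class"], np.asarray(p["t"]), np.asarray(p["x"]),
                 p["insertion_time"], p["speed"])
        for p in doc["particles"]
    ]
    return ParticleTruth(particles, spec, doc["insertion_times"])


def truth_summary_csv(truth: ParticleTruth, path) -> pd.DataFrame:
    """Per-particle summary table (id, class, net displacement, speed)."""
    df = pd.DataFrame(
        {
            "particle_id": [p.particle_id for p in truth.particles],
            "class": [p.klass for p in truth.particles],
            "net_displacement_um": [p.net_displacement for p in truth.particles],
            "speed_um_s": [p.speed for p in truth.particles],
            "n_samples": [len(p.t) for p in truth.particles],
        }
    )
    df.to_csv(path, index=False)
    return df


def load_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def load_transport_spec(path) -> TransportSimSpec:
    doc = load_yaml(path)
    if "bleach_window" in doc:
        doc["bleach_window"] = tuple(doc["bleach_window"])
    return TransportSimSpec(**doc)


def read_path_csv(path, um_per_px: float):
    """Read a nerve-path polyline CSV with columns x_px, y_px."""
    from .kymotrace import NervePath

    df = pd.read_csv(path)
    return NervePath(df[["x_px", "y_px"]].to_numpy(), um_per_px)
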