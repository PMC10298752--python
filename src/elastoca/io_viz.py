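"""Rendering and serialization: frames, time-series CSV, configs, fixtures.

Frame rendering follows the model's color convention: red monomer content
with opacity proportional to value, light-blue free TE spheres, dark-blue
collagen cables and attached spheres, white background. Upscaling is
nearest-neighbor so individual lattice cells stay auditable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .engine import (
    OBSERVABLE_COLUMNS,
    ObservableSeries,
    SimulationConfig,
    SimulationState,
    initial_state,
)
from .monomer_field import MonomerField
from .sphere_dynamics import SphereSet

__all__ = [
    "FrameStyle",
    "render_frame",
    "save_frame",
    "write_timeseries",
    "read_timeseries",
    "write_spheres",
    "save_config",
    "load_config",
    "make_fixture",
]

FIXTURE_KINDS = ("tiny-domain", "preloaded-field", "two-spheres", "scaffold-only")


@dataclass(frozen=True)
class FrameStyle:
    """Colors (RGB, 0-255) and integer upscale factor for rendered frames."""

    monomer_rgb: tuple[int, int, int] = (220, 30, 30)
    free_sphere_rgb: tuple[int, int, int] = (120, 190, 235)
    scaffold_rgb: tuple[int, int, int] = (25, 40, 130)
    background_rgb: tuple[int, int, int] = (255, 255, 255)
    scale: int = 3
    #: monomer content mapped to full opacity at this value
    monomer_saturation: float = 1.0


def _disk_cells(n: int, cx: int, cy: int, radius: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(np.ceil(radius))
    dx, dy = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    inside = dx**2 + dy**2 <= radius**2
    return (cx + dx[inside]) % n, (cy + dy[inside]) % n


def render_frame(state: SimulationState, style: FrameStyle = FrameStyle()) -> np.ndarray:
    """Deterministic RGB image of the state (identical states, identical bytes).

    Draw order: scaffold, monomer layer (alpha-blended), sphere disks of
    radius sqrt(area/pi) colored by attachment class.
    """
    n = state.field.n
    img = np.full((n, n, 3), np.array(style.background_rgb, dtype=float))
    img[state.scaffold.grid] = style.scaffold_rgb

    alpha = np.clip(state.field.grid / style.monomer_saturation, 0.0, 1.0)[..., None]
    img = img * (1 - alpha) + np.array(style.monomer_rgb, dtype=float) * alpha

    sp = state.spheres
    radii = sp.radius
    for i in np.argsort(sp.ids):  # deterministic draw order
        color = style.scaffold_rgb if sp.attached[i] else style.free_sphere_rgb
        xs, ys = _disk_cells(n, int(sp.x[i]), int(sp.y[i]), float(radii[i]))
        img[xs, ys] = color

    out = np.rint(img).astype(np.uint8)
    if style.scale > 1:
        out = np.repeat(np.repeat(out, style.scale, axis=0), style.scale, axis=1)
    return out


def save_frame(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, image)
    return path


def write_timeseries(series: ObservableSeries, path: str | Path) -> Path:
    """Write the observable series as CSV with the fixed canonical header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    series.to_dataframe().to_csv(path, index=False, columns=list(OBSERVABLE_COLUMNS))
    return path


def read_timeseries(path: str | Path) -> ObservableSeries:
    return ObservableSeries.from_dataframe(pd.read_csv(path))


def write_field(field: MonomerField, path: str | Path) -> Path:
    """Write the monomer grid as a plain CSV matrix (one row per lattice row)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, field.grid, delimiter=",")
    return path


def read_field(path: str | Path, parity: int = 0) -> MonomerField:
    return MonomerField(np.loadtxt(path, delimiter=",", ndmin=2), parity=parity)


def write_spheres(spheres: SphereSet, path: str | Path) -> Path:
    """Serialize a sphere set to CSV (id, x, y, mass, area_px, attached)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "id": spheres.ids,
            "x": spheres.x,
            "y": spheres.y,
            "mass": spheres.mass,
            "area_px": spheres.area_px,
            "attached": spheres.attached.astype(int),
        }
    ).to_csv(path, index=False)
    return path


def save_config(config: SimulationConfig, path: str | Path) -> Path:
    """Write a config as YAML or JSON (by extension; standard field names)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    d = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    return path


def load_config(path: str | Path) -> SimulationConfig:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return SimulationConfig.from_dict(d)


def write_run_meta(config: SimulationConfig, path: str | Path) -> Path:
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"config": config.to_dict(), "seed": config.seed, "code_version": __version__}
    path.write_text(json.dumps(meta, indent=2) + "\n")
    return path


def make_fixture(kind: str, seed: int = 0) -> SimulationState:
    """Small deterministic states for unit tests.

    - ``tiny-domain``: empty 20x20 standard-ish config.
    - ``preloaded-field``: tiny domain with a seeded random sub-threshold field.
    - ``two-spheres``: two free unit spheres one cell apart (merge path).
    - ``scaffold-only``: square scaffold, no monomer, no spheres.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")
    cfg = SimulationConfig(n=20, tile_area_px=100.0, linewidth_px=2, total_Time=50,
                           generate_Time=20, seed=seed)
    state = initial_state(cfg)
    if kind == "preloaded-field":
        rng = np.random.default_rng(seed)
        state.field = MonomerField(rng.uniform(0.0, 0.05, size=(20, 20)))
        state.produced_total = state.field.total()
    elif kind == "two-spheres":
        state.spheres.add(10, 8, 0.7)
        state.spheres.add(10, 9, 0.7)
        state.produced_total = 1.4
    return state
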