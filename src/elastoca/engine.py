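"""Simulation engine: the full cellular-automaton loop and its observables.

One step applies, in order: monomer production (within the production
window), Margolus diffusion of the monomer field, sphere nucleation, droplet
splitting, scaffold attachment, sphere random walk, and contact coalescence.
A single master seed drives named sub-streams for each stochastic process,
so identical configs give bit-identical runs and sweeps can vary one
process's randomness independently.

The conserved bookkeeping quantity is monomer content ("mass"): at every
step, cumulative produced content equals field content plus total sphere
mass (plus directly bound content in the monomer-only ablation).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import sphere_dynamics as sd
from .monomer_field import MonomerField, ProductionSchedule, margolus_step, production_step
from .scaffold_geometry import ScaffoldConfigError, ScaffoldMask, adjacency_map, build_scaffold

__all__ = [
    "SimulationConfig",
    "SimulationState",
    "ObservableSeries",
    "step",
    "run",
    "compute_observables",
    "completion_time",
]

logger = logging.getLogger(__name__)

#: names of the independent RNG sub-streams spawned from the master seed
RNG_STREAMS = ("production", "monomer_motion", "nucleation", "sphere_motion", "split", "misc")

OBSERVABLE_COLUMNS = (
    "step",
    "monomer_content_sum",
    "monomer_cell_count",
    "n_attached",
    "area_attached",
    "n_unattached",
    "area_unattached",
    "mean_area_unattached_ge3",
)


@dataclass
class SimulationConfig:
    """All model parameters plus experiment knobs.

    Field names for the physical parameters match the model's standard parameter
    table verbatim (``generate_Time``, ``generate_Tol``, ...) so config files
    read naturally against it; defaults reproduce that table exactly.
    """

    total_Time: int = 2400
    generate_Time: int = 500
    n: int = 200
    generate_Tol: float = 0.04
    generate_Rate: float = 0.032
    sigma1: float = 0.7
    sigma2: float = 2.0
    delta1: int = 42
    delta2: int = 38
    shape: str = "square"
    tile_area_px: float = 2500.0
    linewidth_px: int = 4
    seed: int = 0
    brownian_multiplier: float = 1.0
    spatial_fraction: float = 1.0
    production_mode: str = "constant"
    gaussian_mean: float = 0.0
    gaussian_sd: float = 1.0
    ablation_monomer_only: bool = False
    p_bind: float | None = None
    bind_whole_cell: bool = False
    attach_to_attached: bool = False
    spheres_absorb_monomer: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n <= 0 or self.n % 2:
            raise ScaffoldConfigError(f"n must be a positive even integer, got {self.n}")
        if self.total_Time < 0 or self.generate_Time < 0:
            raise ScaffoldConfigError("total_Time and generate_Time must be >= 0")
        if self.generate_Tol < 0 or self.generate_Rate < 0:
            raise ScaffoldConfigError("generate_Tol and generate_Rate must be >= 0")
        if not (0 <= self.generate_Rate <= 1):
            raise ScaffoldConfigError("generate_Rate is a probability; must lie in [0, 1]")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ScaffoldConfigError("sigma1 and sigma2 must be positive")
        if self.delta1 < 2:
            raise ScaffoldConfigError("delta1 must be >= 2")
        if self.delta2 >= self.delta1:
            raise ScaffoldConfigError(
                f"delta2 ({self.delta2}) must be < delta1 ({self.delta1}): after splitting, "
                "no sphere could ever exceed the attachment gate"
            )
        if self.brownian_multiplier < 0:
            raise ScaffoldConfigError("brownian_multiplier must be >= 0")
        if not 0 < self.spatial_fraction <= 1:
            raise ScaffoldConfigError("spatial_fraction must lie in (0, 1]")
        if self.p_bind is not None and not 0 <= self.p_bind <= 1:
            raise ScaffoldConfigError("p_bind must lie in [0, 1]")

    @property
    def effective_p_bind(self) -> float:
        """Direct-binding probability of the ablation (defaults to generate_Rate)."""
        return self.generate_Rate if self.p_bind is None else self.p_bind

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ScaffoldConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def schedule(self) -> ProductionSchedule:
        region = None
        if self.spatial_fraction < 1.0:
            region = ProductionSchedule.centered_region(self.n, self.spatial_fraction)
        return ProductionSchedule(
            generate_time=self.generate_Time,
            generate_tol=self.generate_Tol,
            generate_rate=self.generate_Rate,
            region=region,
            spatial_fraction=self.spatial_fraction,
            mode=self.production_mode,
            gaussian_mean=self.gaussian_mean,
            gaussian_sd=self.gaussian_sd,
        )


@dataclass
class SimulationState:
    """Mutable state of one run."""

    config: SimulationConfig
    field: MonomerField
    spheres: sd.SphereSet
    scaffold: ScaffoldMask
    schedule: ProductionSchedule
    rngs: dict[str, np.random.Generator]
    t: int = 0
    produced_total: float = 0.0
    bound_grid: np.ndarray | None = None  # ablation-only direct-binding ledger
    _adjacency: np.ndarray = dc_field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def bound_total(self) -> float:
        return 0.0 if self.bound_grid is None else float(self.bound_grid.sum())

    def mass_ledger_error(self) -> float:
        """Relative mismatch between produced and accounted-for content."""
        accounted = self.field.total() + self.spheres.total_mass() + self.bound_total
        denom = max(self.produced_total, 1e-300)
        return abs(accounted - self.produced_total) / denom


def _spawn_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(RNG_STREAMS))
    return {name: np.random.default_rng(s) for name, s in zip(RNG_STREAMS, children)}


def initial_state(config: SimulationConfig) -> SimulationState:
    scaffold = build_scaffold(config.shape, config.n, config.tile_area_px, config.linewidth_px)
    state = SimulationState(
        config=config,
        field=MonomerField.zeros(config.n),
        spheres=sd.SphereSet(config.n, config.sigma1),
        scaffold=scaffold,
        schedule=config.schedule(),
        rngs=_spawn_rngs(config.seed),
    )
    if config.ablation_monomer_only:
        state.bound_grid = np.zeros((config.n, config.n))
    state._adjacency = adjacency_map(scaffold)
    return state


def _n_applications(multiplier: float, rng: np.random.Generator) -> int:
    """Integer part plus a Bernoulli draw on the fractional part."""
    k = int(multiplier)
    frac = multiplier - k
    if frac > 0 and rng.random() < frac:
        k += 1
    return k


def step(state: SimulationState, config: SimulationConfig | None = None) -> SimulationState:
    """Advance the automaton by one step, in place (also returns the state)."""
    cfg = config or state.config
    if cfg.n != state.field.n:
        raise RuntimeError(f"config n={cfg.n} inconsistent with state grid {state.field.n}")
    rngs = state.rngs

    if state.t < cfg.generate_Time:
        state.produced_total += production_step(
            state.field, state.schedule, state.t, rngs["production"]
        )

    for _ in range(_n_applications(cfg.brownian_multiplier, rngs["monomer_motion"])):
        margolus_step(state.field, rngs["monomer_motion"])

    if cfg.ablation_monomer_only:
        _bind_monomer_directly(state, cfg)
    else:
        sd.nucleate(state.field, state.spheres, cfg.sigma1, cfg.sigma2, rngs["nucleation"])
        sd.split_oversized(state.spheres, cfg.delta1, rngs["split"])
        sd.attach_spheres(state.spheres, state.scaffold, cfg.delta2)
        for _ in range(_n_applications(cfg.brownian_multiplier, rngs["sphere_motion"])):
            sd.move_spheres(state.spheres, state.scaffold, rngs["sphere_motion"])
        sd.merge_contacting(state.spheres)
        sd.split_oversized(state.spheres, cfg.delta1, rngs["split"])

    state.t += 1
    return state


def _bind_monomer_directly(state: SimulationState, cfg: SimulationConfig) -> None:
    """Ablation rule: scaffold-adjacent monomer binds the cable directly.

    Each scaffold-adjacent cell fires with probability ``p_bind`` per step;
    a firing cell transfers one production quantum (``generate_Tol``) of its
    content — monomers bind individually, mirroring the production rule in
    reverse — or, with ``bind_whole_cell`` set, its entire content at once.
    """
    p = cfg.effective_p_bind
    if p == 0.0:
        return
    adj = state._adjacency
    hits = state.rngs["nucleation"].random(int(adj.sum())) < p
    vals = state.field.grid[adj]
    amount = vals if cfg.bind_whole_cell else np.minimum(vals, cfg.generate_Tol)
    transfer = np.where(hits, amount, 0.0)
    state.bound_grid[adj] += transfer
    state.field.grid[adj] = vals - transfer


class ObservableSeries:
    """Per-step record of the run's summary observables."""

    def __init__(self) -> None:
        self._rows: list[tuple] = []

    def append(self, row: dict) -> None:
        prev_att = self._rows[-1][3] if self._rows else 0
        if row["n_attached"] < 0 or row["n_unattached"] < 0:
            raise ValueError("counts must be non-negative")
        if row["n_attached"] < prev_att:
            raise RuntimeError("attached sphere count decreased; absorbing-attachment broken")
        self._rows.append(tuple(row[c] for c in OBSERVABLE_COLUMNS))

    def __len__(self) -> int:
        return len(self._rows)

    def __getitem__(self, col: str) -> np.ndarray:
        i = OBSERVABLE_COLUMNS.index(col)
        return np.array([r[i] for r in self._rows])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows, columns=list(OBSERVABLE_COLUMNS))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ObservableSeries":
        missing = set(OBSERVABLE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"missing observable columns: {sorted(missing)}")
        out = cls()
        out._rows = [tuple(rec) for rec in df[list(OBSERVABLE_COLUMNS)].itertuples(index=False)]
        return out

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ObservableSeries) and self._rows == other._rows


def compute_observables(state: SimulationState) -> dict:
    """One observable row for the current state.

    ``mean_area_unattached_ge3`` averages unattached sphere areas ignoring
    spheres smaller than 3 px (0 when no sphere qualifies). In the
    monomer-only ablation, the directly bound content plays the role of
    attached area via the same mass-to-area conversion.
    """
    sp = state.spheres
    areas = sp.area_px
    att = sp.attached
    if state.bound_grid is not None:
        n_att = int((state.bound_grid > 0).sum())
        area_att = int(np.rint(state.bound_total / sp.mass_per_area))
    else:
        n_att = int(att.sum())
        area_att = int(areas[att].sum())
    free_areas = areas[~att]
    big = free_areas[free_areas >= 3]
    return {
        "step": state.t,
        "monomer_content_sum": state.field.total(),
        "monomer_cell_count": int((state.field.grid > 0).sum()),
        "n_attached": n_att,
        "area_attached": area_att,
        "n_unattached": int((~att).sum()),
        "area_unattached": int(free_areas.sum()),
        "mean_area_unattached_ge3": float(big.mean()) if len(big) else 0.0,
    }


def run(
    config: SimulationConfig,
    frames_every: int | None = None,
    check_ledger: bool = False,
) -> tuple[ObservableSeries, SimulationState, list[tuple[int, np.ndarray]] | None]:
    """Execute ``total_Time`` steps from an empty domain.

    Returns the per-step observable series, the final state and, when
    ``frames_every`` is set, rendered frames as (step, RGB array) pairs.
    Identical configs (including seed) give byte-identical series.
    ``check_ledger`` asserts content conservation every step (slower; used
    by the test suite).
    """
    state = initial_state(config)
    series = ObservableSeries()
    frames: list[tuple[int, np.ndarray]] | None = [] if frames_every else None
    if frames_every:
        from .io_viz import FrameStyle, render_frame  # lazy: optional path

        style = FrameStyle()
    for _ in range(config.total_Time):
        step(state)
        row = compute_observables(state)
        series.append(row)
        if check_ledger and state.mass_ledger_error() > 1e-6:
            raise RuntimeError(f"mass ledger broken at step {state.t}")
        if frames_every and (state.t % frames_every == 0 or state.t == config.total_Time):
            frames.append((state.t, render_frame(state, style)))
        if state.t % 100 == 0:
            logger.info(
                "step %d: monomer=%.1f attached=%d free=%d",
                state.t, row["monomer_content_sum"], row["n_attached"], row["n_unattached"],
            )
    return series, state, frames


NOT_REACHED = None


def completion_time(series: ObservableSeries, q: float = 0.95) -> int | None:
    """First step at which attached area reaches q x its end-of-run value.

    Returns None ("not reached") when the final attached area is 0. This
    operationalizes "formation of the cable line element" as the attached
    area having essentially plateaued.
    """
    if not 0 < q <= 1:
        raise ValueError(f"q must lie in (0, 1], got {q}")
    if len(series) == 0:
        raise ValueError("empty series")
    area = series["area_attached"]
    final = area[-1]
    if final <= 0:
        return None
    idx = int(np.argmax(area >= q * final))
    return int(series["step"][idx])
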