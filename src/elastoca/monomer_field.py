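"""Tropoelastin-monomer content field: stochastic production and lattice diffusion.

Each cell of the N x N torus carries a non-negative real "content" of
tropoelastin (TE) monomer. During a finite production window, region cells
independently gain a quantum of content with a fixed per-cell probability per
step; diffusion is the Margolus block-rotation automaton, which conserves
total content exactly and reproduces an unbiased lattice random walk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scaffold_geometry import ScaffoldConfigError

__all__ = [
    "MonomerField",
    "ProductionSchedule",
    "production_step",
    "margolus_step",
    "moore_sum",
    "margolus_tracers",
]


@dataclass
class MonomerField:
    """Monomer content grid plus the Margolus block-alignment phase.

    ``parity`` 0 aligns 2x2 blocks with the even grid, 1 with the odd grid
    (offset by one cell on both axes, wrapping at the torus edge).
    """

    grid: np.ndarray
    parity: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        n0, n1 = self.grid.shape
        if n0 != n1 or n0 % 2:
            raise ScaffoldConfigError(f"domain must be square with even side, got {self.grid.shape}")
        if (self.grid < 0).any():
            raise ValueError("monomer content must be non-negative")

    @classmethod
    def zeros(cls, n: int) -> "MonomerField":
        if n % 2:
            raise ScaffoldConfigError(f"domain side must be even, got n={n}")
        return cls(np.zeros((n, n)))

    @property
    def n(self) -> int:
        return self.grid.shape[0]

    def total(self) -> float:
        return float(self.grid.sum())


@dataclass
class ProductionSchedule:
    """Where, when and how much monomer is produced.

    Parameters
    ----------
    generate_time : length of the production window in steps.
    generate_tol : content quantum added on a successful draw (per cell).
    generate_rate : per-cell per-step probability of a successful draw,
        before rescaling for a restricted region.
    region : boolean mask of producing cells; None means the full domain.
    spatial_fraction : fraction of the domain the region covers. The per-cell
        rate is divided by this so the expected total production is invariant
        under spatial concentration.
    mode : ``constant`` or ``gaussian``. In gaussian mode the per-step quantum
        follows a normal pdf profile over the window (see ``tol_profile``),
        normalized so the expected total matches constant mode exactly.
    gaussian_mean, gaussian_sd : profile parameters; the window [0, T) is
        mapped linearly onto [mean - 3 sd, mean + 3 sd].
    """

    generate_time: int
    generate_tol: float
    generate_rate: float
    region: np.ndarray | None = None
    spatial_fraction: float = 1.0
    mode: str = "constant"
    gaussian_mean: float = 0.0
    gaussian_sd: float = 1.0
    _profile: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.generate_time < 0 or self.generate_tol < 0 or self.generate_rate < 0:
            raise ScaffoldConfigError("production parameters must be non-negative")
        if not 0 < self.spatial_fraction <= 1:
            raise ScaffoldConfigError("spatial_fraction must lie in (0, 1]")
        if self.mode not in ("constant", "gaussian"):
            raise ScaffoldConfigError(f"unknown production mode {self.mode!r}")
        if self.effective_rate > 1.0 + 1e-12:
            raise ScaffoldConfigError(
                f"effective per-cell rate {self.effective_rate:.3f} exceeds 1; "
                "spatial_fraction too small for this generate_Rate"
            )
        self._profile = self._build_profile()

    @property
    def effective_rate(self) -> float:
        return self.generate_rate / self.spatial_fraction

    def _build_profile(self) -> np.ndarray:
        T = self.generate_time
        if T == 0:
            return np.zeros(0)
        if self.mode == "constant":
            return np.full(T, self.generate_tol)
        if self.gaussian_sd <= 0:
            raise ScaffoldConfigError("gaussian_sd must be positive")
        # map window steps onto mean +/- 3 sd and normalize so the window-mean
        # quantum equals generate_tol (total production preserved)
        z = self.gaussian_mean + self.gaussian_sd * (-3.0 + 6.0 * (np.arange(T) + 0.5) / T)
        pdf = np.exp(-0.5 * ((z - self.gaussian_mean) / self.gaussian_sd) ** 2)
        return self.generate_tol * pdf / pdf.mean()

    def tol_at(self, t: int) -> float:
        """Content quantum added on a successful draw at step t."""
        if t >= self.generate_time:
            return 0.0
        return float(self._profile[t])

    def region_mask(self, n: int) -> np.ndarray:
        if self.region is not None:
            return self.region
        return np.ones((n, n), dtype=bool)

    @staticmethod
    def centered_region(n: int, spatial_fraction: float) -> np.ndarray:
        """Centered square region covering ``spatial_fraction`` of the domain."""
        if not 0 < spatial_fraction <= 1:
            raise ScaffoldConfigError("spatial_fraction must lie in (0, 1]")
        side = max(1, int(round(n * np.sqrt(spatial_fraction))))
        side = min(side, n)
        lo = (n - side) // 2
        mask = np.zeros((n, n), dtype=bool)
        mask[lo : lo + side, lo : lo + side] = True
        return mask


def production_step(
    field: MonomerField,
    schedule: ProductionSchedule,
    t: int,
    rng: np.random.Generator,
) -> float:
    """One production sweep at step ``t``; returns the content actually added.

    Each region cell independently gains the step's quantum with probability
    ``schedule.effective_rate``. Outside the production window this is a
    no-op. The field is updated in place.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    tol = schedule.tol_at(t)
    if tol == 0.0 or schedule.effective_rate == 0.0:
        return 0.0
    region = schedule.region_mask(field.n)
    hits = rng.random(int(region.sum())) < schedule.effective_rate
    added = tol * hits
    field.grid[region] += added
    return float(added.sum())


# clockwise rotation of a 2x2 block [[a00, a01], [a10, a11]] (axis0 = x down,
# axis1 = y right): each value advances one corner in the cycle
# (0,0)->(0,1)->(1,1)->(1,0)->(0,0); counterclockwise is the inverse.
def margolus_step(field: MonomerField, rng: np.random.Generator) -> None:
    """One Margolus diffusion step, in place.

    The torus is partitioned into 2x2 blocks at the current parity offset;
    each block rotates its four values one position clockwise or
    counterclockwise with probability 1/2, independently per block. The grid
    sum is conserved exactly; parity flips.
    """
    n = field.n
    odd = field.parity & 1
    g = np.roll(field.grid, (-1, -1), axis=(0, 1)) if odd else field.grid
    b = g.reshape(n // 2, 2, n // 2, 2)
    a00 = b[:, 0, :, 0].copy()
    a01 = b[:, 0, :, 1].copy()
    a10 = b[:, 1, :, 0].copy()
    a11 = b[:, 1, :, 1].copy()
    cw = rng.random((n // 2, n // 2)) < 0.5
    b[:, 0, :, 1] = np.where(cw, a00, a11)
    b[:, 1, :, 1] = np.where(cw, a01, a10)
    b[:, 1, :, 0] = np.where(cw, a11, a00)
    b[:, 0, :, 0] = np.where(cw, a10, a01)
    if odd:
        field.grid = np.roll(g, (1, 1), axis=(0, 1))
    field.parity ^= 1


def moore_sum(field: MonomerField, cell: tuple[int, int]) -> float:
    """Sum of the cell's value and its 8 periodic-wrap neighbors."""
    i, j = cell
    n = field.n
    ii = [(i - 1) % n, i % n, (i + 1) % n]
    jj = [(j - 1) % n, j % n, (j + 1) % n]
    return float(field.grid[np.ix_(ii, jj)].sum())


def moore_sums(grid: np.ndarray) -> np.ndarray:
    """All Moore-neighborhood sums at once (periodic wrap)."""
    out = np.zeros_like(grid)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            out += np.roll(grid, (dx, dy), axis=(0, 1))
    return out


# displacement of a value at block corner c under clockwise / counterclockwise
# rotation, indexed by corner code 2*cx + cy
_CW_DELTA = np.array([[0, 1], [1, 0], [-1, 0], [0, -1]])  # corners 00, 01, 10, 11
_CCW_DELTA = np.array([[1, 0], [0, -1], [0, 1], [-1, 0]])


def margolus_tracers(
    positions: np.ndarray,
    steps: int,
    rng: np.random.Generator,
    parity0: int = 0,
) -> np.ndarray:
    """Evolve point tracers under the Margolus rule on an unbounded lattice.

    Tracers sharing a 2x2 block at a given step share that block's rotation
    coin, exactly as cell contents do in :func:`margolus_step`. Positions are
    unwrapped (no modulo), which is what mean-squared-displacement analysis
    needs. Returns an array of shape (steps + 1, n_tracers, 2).

    Each rotation moves a tracer exactly one lattice cell, so after a single
    step every tracer's squared displacement is exactly 1.
    """
    pos = np.asarray(positions, dtype=np.int64).copy()
    out = np.empty((steps + 1,) + pos.shape, dtype=np.int64)
    out[0] = pos
    for s in range(steps):
        o = (parity0 + s) & 1
        corner = ((pos - o) & 1)  # position within the 2x2 block
        block = (pos - o) >> 1
        # one coin per occupied block
        uniq, inv = np.unique(block, axis=0, return_inverse=True)
        cw = rng.random(len(uniq)) < 0.5
        cw_t = cw[inv]
        code = corner[:, 0] * 2 + corner[:, 1]
        delta = np.where(cw_t[:, None], _CW_DELTA[code], _CCW_DELTA[code])
        pos = pos + delta
        out[s + 1] = pos
    return out
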