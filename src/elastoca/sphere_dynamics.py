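"""Tropoelastin-sphere life cycle: nucleation, motion, coalescence, splitting, attachment.

TE spheres are discrete droplet agents on the lattice, each with an integer
center, a real conserved mass (in monomer-content units) and a derived pixel
area ``max(1, round(mass / sigma1))`` — one nucleation-threshold quantum of
content per pixel of sphere, so a bare sigma1-triggered nucleation yields the
minimum 1-px (1 um) sphere. A sphere's footprint is the disk of radius
``sqrt(area / pi)`` around its center.

Threshold semantics follow the most explicit statements of the model: the
nucleation thresholds sigma1/sigma2 fire at >= ("reaches a threshold"),
while the size gates delta1 (split) and delta2 (attach) are strict >
("larger than").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .monomer_field import MonomerField, moore_sums
from .scaffold_geometry import ScaffoldMask

__all__ = [
    "Sphere",
    "SphereSet",
    "nucleate",
    "move_spheres",
    "merge_contacting",
    "split_oversized",
    "attach_spheres",
]

#: von Neumann step directions (x, y)
_DIRS = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]])


@dataclass(frozen=True)
class Sphere:
    """Read-only view of a single TE sphere."""

    id: int
    x: int
    y: int
    mass: float
    area_px: int
    attached: bool


class SphereSet:
    """Collection of TE spheres stored as parallel arrays.

    Parameters
    ----------
    domain_size : torus side length N.
    mass_per_area : content units per pixel of sphere area (the nucleation
        threshold sigma1 under the standard calibration).
    """

    def __init__(self, domain_size: int, mass_per_area: float):
        if mass_per_area <= 0:
            raise ValueError("mass_per_area must be positive")
        self.n = int(domain_size)
        self.mass_per_area = float(mass_per_area)
        self.ids = np.zeros(0, dtype=np.int64)
        self.x = np.zeros(0, dtype=np.int64)
        self.y = np.zeros(0, dtype=np.int64)
        self.mass = np.zeros(0, dtype=float)
        self.attached = np.zeros(0, dtype=bool)
        self.next_id = 0

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def area_px(self) -> np.ndarray:
        if len(self) == 0:
            return np.zeros(0, dtype=np.int64)
        return np.maximum(1, np.rint(self.mass / self.mass_per_area)).astype(np.int64)

    @property
    def radius(self) -> np.ndarray:
        return np.sqrt(self.area_px / np.pi)

    def total_mass(self) -> float:
        return float(self.mass.sum())

    def add(self, x: int, y: int, mass: float, attached: bool = False) -> int:
        if mass <= 0:
            raise ValueError("sphere mass must be positive")
        sid = self.next_id
        self.ids = np.append(self.ids, sid)
        self.x = np.append(self.x, int(x) % self.n)
        self.y = np.append(self.y, int(y) % self.n)
        self.mass = np.append(self.mass, float(mass))
        self.attached = np.append(self.attached, bool(attached))
        self.next_id += 1
        return sid

    def _replace(self, keep: np.ndarray, new_rows: list[tuple[int, int, float, bool]]) -> None:
        """Keep a subset of spheres and append freshly numbered ones."""
        self.ids = self.ids[keep]
        self.x = self.x[keep]
        self.y = self.y[keep]
        self.mass = self.mass[keep]
        self.attached = self.attached[keep]
        for x, y, m, att in new_rows:
            self.add(x, y, m, att)

    def spheres(self) -> list[Sphere]:
        areas = self.area_px
        return [
            Sphere(int(self.ids[i]), int(self.x[i]), int(self.y[i]), float(self.mass[i]),
                   int(areas[i]), bool(self.attached[i]))
            for i in range(len(self))
        ]

    def copy(self) -> "SphereSet":
        out = SphereSet(self.n, self.mass_per_area)
        out.ids = self.ids.copy()
        out.x = self.x.copy()
        out.y = self.y.copy()
        out.mass = self.mass.copy()
        out.attached = self.attached.copy()
        out.next_id = self.next_id
        return out


def nucleate(
    field: MonomerField,
    spheres: SphereSet,
    sigma1: float,
    sigma2: float,
    rng: np.random.Generator,
) -> int:
    """Turn super-threshold monomer content into new spheres; returns how many.

    Candidate cells (single value >= sigma1, or Moore-neighborhood sum >=
    sigma2) are visited in a seeded random order. A sigma1 cell spawns a
    sphere consuming its own content; otherwise a cell whose *current* Moore
    sum still reaches sigma2 spawns a sphere consuming all nine neighborhood
    values. Consumed cells are zeroed, so no content is consumed twice;
    sphere mass equals the consumed content exactly.
    """
    if sigma1 > sigma2:
        warnings.warn("sigma1 > sigma2: single-cell nucleation dominates", stacklevel=2)
    g = field.grid
    n = field.n
    cand = (g >= sigma1) | (moore_sums(g) >= sigma2)
    idx = np.argwhere(cand)
    if len(idx) == 0:
        return 0
    order = rng.permutation(len(idx))
    created = 0
    for k in order:
        i, j = int(idx[k, 0]), int(idx[k, 1])
        v = g[i, j]
        if v >= sigma1:
            g[i, j] = 0.0
            spheres.add(i, j, v)
            created += 1
            continue
        ii = [(i - 1) % n, i, (i + 1) % n]
        jj = [(j - 1) % n, j, (j + 1) % n]
        block = g[np.ix_(ii, jj)]
        s = block.sum()
        if s >= sigma2 and s > 0:
            g[np.ix_(ii, jj)] = 0.0
            spheres.add(i, j, s)
            created += 1
    return created


def move_spheres(
    spheres: SphereSet,
    scaffold: ScaffoldMask,
    rng: np.random.Generator,
) -> None:
    """One random-walk step for every unattached sphere, in place.

    Each free sphere proposes one cell of motion in a uniformly random von
    Neumann direction (periodic wrap). The move is cancelled if the
    destination footprint would overlap a cable cell — i.e. if the periodic
    distance from the destination to the nearest scaffold cell does not
    exceed the sphere radius. Attached spheres never move.
    """
    free = ~spheres.attached
    nfree = int(free.sum())
    if nfree == 0:
        return
    d = _DIRS[rng.integers(0, 4, size=nfree)]
    nx = (spheres.x[free] + d[:, 0]) % spheres.n
    ny = (spheres.y[free] + d[:, 1]) % spheres.n
    dist = scaffold.distance_to_scaffold()
    ok = dist[nx, ny] > spheres.radius[free]
    fidx = np.flatnonzero(free)[ok]
    spheres.x[fidx] = nx[ok]
    spheres.y[fidx] = ny[ok]


def _wrap_delta(d: np.ndarray, n: int) -> np.ndarray:
    """Map coordinate differences onto the torus to the range [-n/2, n/2)."""
    return (d + n // 2) % n - n // 2


def _contact_pairs(spheres: SphereSet, i_idx: np.ndarray, j_idx: np.ndarray) -> np.ndarray:
    """Pairs (rows into the set) whose disk footprints are in contact."""
    pos = np.column_stack([spheres.x, spheres.y]).astype(float)
    rad = spheres.radius
    sub = np.concatenate([i_idx, j_idx])
    if len(sub) < 2:
        return np.zeros((0, 2), dtype=np.int64)
    tree = cKDTree(pos[sub], boxsize=spheres.n)
    rmax = rad[sub].max()
    pairs = tree.query_pairs(r=2 * rmax + 1.0 + 1e-9, output_type="ndarray")
    if len(pairs) == 0:
        return pairs
    a, b = sub[pairs[:, 0]], sub[pairs[:, 1]]
    dx = _wrap_delta(spheres.x[a] - spheres.x[b], spheres.n)
    dy = _wrap_delta(spheres.y[a] - spheres.y[b], spheres.n)
    dist = np.hypot(dx, dy)
    ok = dist <= rad[a] + rad[b] + 1.0 + 1e-9
    return np.column_stack([a[ok], b[ok]])


def merge_contacting(spheres: SphereSet) -> None:
    """Coalesce contacting spheres, in place; total mass is conserved exactly.

    Contact means center distance <= r_i + r_j + 1 cell (periodic metric).
    Free spheres in contact are grouped by transitive closure; each group
    becomes one sphere at the mass-weighted centroid (wrapped, rounded to the
    nearest cell). A free sphere in contact with attached spheres is instead
    absorbed by the nearest one: attached spheres are crosslinked in place,
    so they gain mass but never move, and never merge with each other.
    """
    m = len(spheres)
    if m < 2:
        return
    att_idx = np.flatnonzero(spheres.attached)
    free_idx = np.flatnonzero(~spheres.attached)
    if len(free_idx) == 0:
        return
    pairs = _contact_pairs(spheres, free_idx, att_idx)
    if len(pairs) == 0:
        return

    # 1) absorb free spheres touching an attached sphere (nearest wins)
    both_att = spheres.attached[pairs[:, 0]] & spheres.attached[pairs[:, 1]]
    pairs = pairs[~both_att]
    mixed = spheres.attached[pairs[:, 0]] ^ spheres.attached[pairs[:, 1]]
    absorbed = np.zeros(m, dtype=bool)
    if mixed.any():
        mp = pairs[mixed]
        fr = np.where(spheres.attached[mp[:, 0]], mp[:, 1], mp[:, 0])
        at = np.where(spheres.attached[mp[:, 0]], mp[:, 0], mp[:, 1])
        dx = _wrap_delta(spheres.x[fr] - spheres.x[at], spheres.n)
        dy = _wrap_delta(spheres.y[fr] - spheres.y[at], spheres.n)
        dist = np.hypot(dx, dy)
        order = np.lexsort((dist, fr))  # per free sphere, nearest attached first
        seen: set[int] = set()
        for k in order:
            f, a = int(fr[k]), int(at[k])
            if f in seen:
                continue
            seen.add(f)
            spheres.mass[a] += spheres.mass[f]
            absorbed[f] = True

    # 2) transitive closure among the remaining free-free contacts
    ff = pairs[~mixed] if mixed.any() else pairs
    ff = ff[~(absorbed[ff[:, 0]] | absorbed[ff[:, 1]])]
    new_rows: list[tuple[int, int, float, bool]] = []
    merged = np.zeros(m, dtype=bool)
    if len(ff):
        parent = np.arange(m)

        def find(u: int) -> int:
            while parent[u] != u:
                parent[u] = parent[parent[u]]
                u = parent[u]
            return u

        for a, b in ff:
            ra, rb = find(int(a)), find(int(b))
            if ra != rb:
                parent[ra] = rb
        groups: dict[int, list[int]] = {}
        for u in np.unique(ff):
            groups.setdefault(find(int(u)), []).append(int(u))
        for root in sorted(groups, key=lambda r: min(groups[r])):
            members = groups[root]
            if len(members) < 2:
                continue
            mem = np.array(members)
            merged[mem] = True
            masses = spheres.mass[mem]
            ax, ay = int(spheres.x[mem[0]]), int(spheres.y[mem[0]])
            dx = _wrap_delta(spheres.x[mem] - ax, spheres.n)
            dy = _wrap_delta(spheres.y[mem] - ay, spheres.n)
            cx = int(np.rint(ax + np.average(dx, weights=masses))) % spheres.n
            cy = int(np.rint(ay + np.average(dy, weights=masses))) % spheres.n
            new_rows.append((cx, cy, float(masses.sum()), False))

    drop = absorbed | merged
    if drop.any() or new_rows:
        spheres._replace(~drop, new_rows)


def split_oversized(spheres: SphereSet, delta1: int, rng: np.random.Generator) -> None:
    """Split every unattached sphere larger than delta1 pixels, in place.

    A sphere of area a > delta1 splits into areas ceil(a/2) and floor(a/2);
    mass is partitioned in the same proportion (conserved exactly), and the
    two centers end up one cell apart along a uniformly random axis. Repeats
    until no free sphere exceeds delta1. Attached (crosslinked) spheres do
    not split.
    """
    if delta1 < 2:
        raise ValueError("delta1 must be >= 2")
    while True:
        areas = spheres.area_px
        over = np.flatnonzero((areas > delta1) & ~spheres.attached)
        if len(over) == 0:
            return
        new_rows: list[tuple[int, int, float, bool]] = []
        for i in over:
            a = int(areas[i])
            m = float(spheres.mass[i])
            x, y = int(spheres.x[i]), int(spheres.y[i])
            a1 = (a + 1) // 2
            m1 = m * a1 / a
            d = _DIRS[rng.integers(0, 4)]
            new_rows.append((x, y, m1, False))
            new_rows.append(((x + d[0]) % spheres.n, (y + d[1]) % spheres.n, m - m1, False))
        keep = np.ones(len(spheres), dtype=bool)
        keep[over] = False
        spheres._replace(keep, new_rows)


def attach_spheres(spheres: SphereSet, scaffold: ScaffoldMask, delta2: int) -> int:
    """Crosslink eligible spheres to the scaffold, in place; returns how many.

    A free sphere attaches iff its area is strictly larger than delta2 pixels
    and its footprint touches the cable adjacency map (some adjacency cell
    lies within the footprint radius of its center). Attachment is permanent.
    """
    if len(spheres) == 0:
        return 0
    dist = scaffold.distance_to_adjacency()
    eligible = (
        ~spheres.attached
        & (spheres.area_px > delta2)
        & (dist[spheres.x, spheres.y] <= spheres.radius)
    )
    spheres.attached |= eligible
    return int(eligible.sum())
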