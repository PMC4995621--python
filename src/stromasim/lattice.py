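"""Bounded 3D integer lattice: cell occupancy, ECM density, neighborhoods.

One lattice site is a 5 μm cube and holds at most one cell.  Adjacency is
the 26-site Moore neighborhood, chosen for growth isotropy on a cubic
lattice.  ECM density is a per-site value in [0, 1], initialized to 1.0;
degradation multiplies it down and gates tumor-cell motility.
"""

from __future__ import annotations

from typing import Iterator, Optional

import numpy as np

__all__ = [
    "SITE_MICRONS",
    "MOORE_OFFSETS",
    "microns_to_sites",
    "World",
]

#: Physical edge length of one lattice site, in micrometers.
SITE_MICRONS = 5.0

#: The 26 Moore offsets in deterministic nearest-first order:
#: 6 face neighbors, then 12 edge neighbors, then 8 corner neighbors,
#: lexicographic within each shell.
MOORE_OFFSETS: tuple[tuple[int, int, int], ...] = tuple(
    sorted(
        (
            (dx, dy, dz)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)
        ),
        key=lambda o: (o[0] * o[0] + o[1] * o[1] + o[2] * o[2], o),
    )
)


def microns_to_sites(d: float) -> int:
    """Convert a length in μm to a site count (1 site = 5 μm, rounded)."""
    if d < 0:
        raise ValueError(f"length must be non-negative, got {d}")
    return round(d / SITE_MICRONS)


class World:
    """Occupancy and ECM state of the simulation volume.

    ``occupancy`` stores 0 for an empty site or a positive cell id;
    id bookkeeping is the caller's.  All coordinates are 0-based
    integer triples ``(x, y, z)`` with ``0 <= x < dims[0]`` etc.
    """

    __slots__ = ("dims", "occupancy", "ecm", "_occ_flat", "_ecm_flat",
                 "_ny", "_nz", "_flat_offsets")

    def __init__(self, dims: tuple[int, int, int], ecm_density: float = 1.0):
        if len(dims) != 3 or any(int(d) < 1 for d in dims):
            raise ValueError(f"dims must be three positive integers, got {dims!r}")
        if not 0.0 <= ecm_density <= 1.0:
            raise ValueError(f"ECM density must lie in [0, 1], got {ecm_density}")
        self.dims = (int(dims[0]), int(dims[1]), int(dims[2]))
        self.occupancy = np.zeros(self.dims, dtype=np.int32)
        self.ecm = np.full(self.dims, float(ecm_density), dtype=np.float64)
        self._occ_flat = memoryview(self.occupancy.reshape(-1))
        self._ecm_flat = self.ecm.reshape(-1)
        self._ny, self._nz = self.dims[1], self.dims[2]
        ny, nz = self._ny, self._nz
        self._flat_offsets = tuple((dx * ny + dy) * nz + dz
                                   for dx, dy, dz in MOORE_OFFSETS)

    # -- coordinates ------------------------------------------------------
    def in_bounds(self, pos: tuple[int, int, int]) -> bool:
        x, y, z = pos
        nx, ny, nz = self.dims
        return 0 <= x < nx and 0 <= y < ny and 0 <= z < nz

    def _check(self, pos: tuple[int, int, int]) -> None:
        if not self.in_bounds(pos):
            raise ValueError(f"position {pos} outside world of dims {self.dims}")

    def neighbors(self, pos: tuple[int, int, int]) -> list[tuple[int, int, int]]:
        """In-bounds Moore neighbors of ``pos`` in deterministic nearest-first order."""
        self._check(pos)
        x, y, z = pos
        nx, ny, nz = self.dims
        if 0 < x < nx - 1 and 0 < y < ny - 1 and 0 < z < nz - 1:
            return [(x + dx, y + dy, z + dz) for dx, dy, dz in MOORE_OFFSETS]
        out = []
        for dx, dy, dz in MOORE_OFFSETS:
            q = (x + dx, y + dy, z + dz)
            if 0 <= q[0] < nx and 0 <= q[1] < ny and 0 <= q[2] < nz:
                out.append(q)
        return out

    # -- occupancy --------------------------------------------------------
    def occupant(self, pos: tuple[int, int, int]) -> int:
        """Cell id at ``pos`` (0 if empty)."""
        return int(self.occupancy[pos])

    def is_empty(self, pos: tuple[int, int, int]) -> bool:
        return self.occupancy[pos] == 0

    def place(self, cell_id: int, pos: tuple[int, int, int]) -> None:
        self._check(pos)
        if cell_id <= 0:
            raise ValueError("cell ids must be positive")
        if self.occupancy[pos] != 0:
            raise ValueError(f"site {pos} already occupied by cell {int(self.occupancy[pos])}")
        self.occupancy[pos] = cell_id

    def clear(self, pos: tuple[int, int, int]) -> None:
        self.occupancy[pos] = 0

    def move(self, src: tuple[int, int, int], dst: tuple[int, int, int]) -> None:
        if self.occupancy[dst] != 0:
            raise ValueError(f"cannot move into occupied site {dst}")
        self.occupancy[dst] = self.occupancy[src]
        self.occupancy[src] = 0

    def has_empty_neighbor(self, pos: tuple[int, int, int]) -> bool:
        """Cheap test for any unoccupied Moore neighbor."""
        occ = self.occupancy
        x, y, z = pos
        nx, ny, nz = self.dims
        if 0 < x < nx - 1 and 0 < y < ny - 1 and 0 < z < nz - 1:
            mv = self._occ_flat
            fx = (x * ny + y) * nz + z
            for d in self._flat_offsets:
                if mv[fx + d] == 0:
                    return True
            return False
        return bool(self.empty_neighbors(pos))

    def empty_neighbors(self, pos: tuple[int, int, int]) -> list[tuple[int, int, int]]:
        occ = self.occupancy
        return [q for q in self.neighbors(pos) if occ[q] == 0]

    def random_empty_neighbor(
        self, pos: tuple[int, int, int], rng: np.random.Generator
    ) -> Optional[tuple[int, int, int]]:
        """Uniformly chosen unoccupied neighbor of ``pos``, or None if all occupied."""
        empties = self.empty_neighbors(pos)
        if not empties:
            return None
        return empties[int(rng.integers(len(empties)))]

    # -- ECM ---------------------------------------------------------------
    def degrade_ecm(self, pos: tuple[int, int, int], rate: float) -> None:
        """Multiply ECM density at ``pos`` and its neighbors by (1 - rate)."""
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"degradation rate must lie in [0, 1], got {rate}")
        keep = 1.0 - rate
        ecm = self.ecm
        ecm[pos] *= keep
        for q in self.neighbors(pos):
            ecm[q] *= keep

    def iter_occupied(self) -> Iterator[tuple[tuple[int, int, int], int]]:
        for idx in np.argwhere(self.occupancy != 0):
            pos = (int(idx[0]), int(idx[1]), int(idx[2]))
            yield pos, int(self.occupancy[pos])
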