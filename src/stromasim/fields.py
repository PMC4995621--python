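"""Lattice fields for the diffusing molecular species (oxygen, VEGF, FGF, HGF).

Molecules perform an unbiased lattice random walk: each tick a molecule
stays put with probability ``stay_prob`` (default 1/27) and otherwise
steps to one of its 26 Moore neighbors with equal probability; a step
that would leave the lattice is not taken.  The field stores the
*expected* occupancy of that process as a real amount per site, so
diffusion is the deterministic one-step transition kernel of the walk.
Amounts are unit-less ("units"), as are all concentrations in the model.

Mass changes only through :meth:`Field.deposit` and the consumption
methods, never through diffusion; every field keeps a running ledger so
the balance ``initial + deposited - consumed - current = 0`` can be
asserted at any time.

:func:`monte_carlo_diffuse` simulates the same walk with discrete
molecules and is retained purely as an independent oracle for testing
the kernel.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage

from .lattice import MOORE_OFFSETS

__all__ = ["SPECIES", "Field", "monte_carlo_diffuse"]

#: The four molecular species of the model.
SPECIES = ("oxygen", "vegf", "fgf", "hgf")

_OFFSETS = np.array(MOORE_OFFSETS, dtype=np.int64)

#: offset of each cell of a raveled 3x3x3 cube relative to its center
_CUBE_OFFSETS = tuple(
    (dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
)

# cache of per-shape boundary data: number of out-of-bounds Moore
# neighbors for every site (only nonzero on the faces/edges/corners)
_KOUT_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _k_out(dims: tuple[int, int, int]) -> np.ndarray:
    arr = _KOUT_CACHE.get(dims)
    if arr is None:
        ones = np.ones(dims, dtype=np.float64)
        in_count = ndimage.uniform_filter(ones, size=3, mode="constant", cval=0.0) * 27.0 - 1.0
        arr = 26.0 - np.rint(in_count)
        _KOUT_CACHE[dims] = arr
    return arr


class Field:
    """Non-negative per-site amounts of one molecular species."""

    __slots__ = ("species", "a", "mv", "stay_prob", "deposited", "consumed",
                 "initial", "_buf", "_flat_offsets", "_nynz", "_nz")

    def __init__(
        self,
        dims: tuple[int, int, int],
        species: str,
        initial: float = 0.0,
        stay_prob: float = 1.0 / 27.0,
    ):
        if initial < 0:
            raise ValueError("initial amount must be non-negative")
        if not 0.0 <= stay_prob < 1.0:
            raise ValueError("stay_prob must lie in [0, 1)")
        self.species = species
        self.stay_prob = float(stay_prob)
        self.a = np.full(dims, float(initial), dtype=np.float64)
        self._buf = np.empty(dims, dtype=np.float64)
        self.mv = memoryview(self.a.reshape(-1))
        ny, nz = dims[1], dims[2]
        self._nynz, self._nz = ny * nz, nz
        # flat-index steps to the 26 Moore neighbors, nearest shells first
        self._flat_offsets = tuple(
            (dx * ny + dy) * nz + dz for dx, dy, dz in MOORE_OFFSETS
        )
        self.initial = float(self.a.sum())
        self.deposited = 0.0
        self.consumed = 0.0

    # -- bookkeeping -------------------------------------------------------
    @property
    def total_mass(self) -> float:
        return float(self.a.sum())

    def ledger_error(self) -> float:
        """Absolute mass-balance error: initial + deposits - consumption - current."""
        return self.initial + self.deposited - self.consumed - self.total_mass

    # -- sources and sinks ---------------------------------------------------
    def deposit(self, pos: tuple[int, int, int], amount: float) -> None:
        """Add ``amount`` units at ``pos``."""
        if amount < 0:
            raise ValueError(f"deposit amount must be non-negative, got {amount}")
        self.a[pos] += amount
        self.deposited += amount

    def take(self, pos: tuple[int, int, int], requested: float) -> float:
        """Remove up to ``requested`` units from ``pos`` only (no pooling)."""
        if requested < 0:
            raise ValueError("requested amount must be non-negative")
        a = self.a
        avail = a[pos]
        granted = requested if avail >= requested else avail
        if granted > 0.0:
            a[pos] = avail - granted
            self.consumed += granted
        return float(granted)

    def consume(self, pos: tuple[int, int, int], requested: float) -> float:
        """Remove up to ``requested`` units pooled over ``pos`` and its
        Moore neighbors, drawing nearest-first (own site, then face, edge,
        corner neighbors in deterministic order).  Returns the granted amount.
        """
        if requested < 0:
            raise ValueError("requested amount must be non-negative")
        a = self.a
        x, y, z = pos
        nx, ny, nz = a.shape
        need = requested
        if 0 < x < nx - 1 and 0 < y < ny - 1 and 0 < z < nz - 1:
            mv = self.mv
            fx = x * self._nynz + y * self._nz + z
            avail = mv[fx]
            if avail >= need:
                mv[fx] = avail - need
                self.consumed += requested
                return float(requested)
            if avail > 0.0:
                mv[fx] = 0.0
                need -= avail
            for d in self._flat_offsets:
                avail = mv[fx + d]
                if avail <= 0.0:
                    continue
                if avail >= need:
                    mv[fx + d] = avail - need
                    need = 0.0
                    break
                mv[fx + d] = 0.0
                need -= avail
            granted = requested - need
            self.consumed += granted
            return float(granted)
        avail = a[pos]
        if avail >= need:
            a[pos] = avail - need
            self.consumed += requested
            return float(requested)
        if avail > 0.0:
            a[pos] = 0.0
            need -= avail
        for dx, dy, dz in MOORE_OFFSETS:
            q = (x + dx, y + dy, z + dz)
            if not (0 <= q[0] < nx and 0 <= q[1] < ny and 0 <= q[2] < nz):
                continue
            avail = a[q]
            if avail <= 0.0:
                continue
            if avail >= need:
                a[q] = avail - need
                need = 0.0
                break
            a[q] = 0.0
            need -= avail
        granted = requested - need
        self.consumed += granted
        return float(granted)

    def neighborhood_sum(self, pos: tuple[int, int, int]) -> float:
        """Total amount over ``pos`` and its in-bounds Moore neighbors."""
        a = self.a
        x, y, z = pos
        nx, ny, nz = a.shape
        x0, x1 = max(x - 1, 0), min(x + 2, nx)
        y0, y1 = max(y - 1, 0), min(y + 2, ny)
        z0, z1 = max(z - 1, 0), min(z + 2, nz)
        return float(a[x0:x1, y0:y1, z0:z1].sum())

    # -- transport ----------------------------------------------------------
    def diffuse(self, steps: int = 1) -> None:
        """Apply the random-walk expectation kernel ``steps`` times.

        Each site keeps ``stay_prob`` of its mass and sends
        ``(1 - stay_prob)/26`` along each Moore direction; the share of any
        direction leaving the lattice stays at the source.  Total mass is
        conserved to float round-off.
        """
        if steps < 1:
            raise ValueError("steps must be >= 1")
        a, buf = self.a, self._buf
        stay = self.stay_prob
        move = (1.0 - stay) / 26.0
        kout = _k_out(a.shape)
        for _ in range(steps):
            # uniform_filter = (self + 26 neighbors)/27 with zero padding
            ndimage.uniform_filter(a, size=3, mode="constant", cval=0.0, output=buf)
            np.multiply(buf, 27.0 * move, out=buf)
            # self keeps stay_prob (filter already credited it `move`)
            # plus the share of every out-of-bounds direction
            buf += a * (stay - move + move * kout)
            a, buf = buf, a
        self.a, self._buf = a, buf
        self.mv = memoryview(a.reshape(-1))

    # -- sensing --------------------------------------------------------------
    def gradient_direction(
        self, pos: tuple[int, int, int], rng: np.random.Generator
    ) -> tuple[int, int, int]:
        """Unit lattice step toward the in-bounds neighbor holding the most
        of this species; ties (including a completely flat neighborhood)
        are broken uniformly at random.
        """
        a = self.a
        x, y, z = pos
        nx, ny, nz = a.shape
        if 0 < x < nx - 1 and 0 < y < ny - 1 and 0 < z < nz - 1:
            cube = a[x - 1:x + 2, y - 1:y + 2, z - 1:z + 2].ravel()
            vals = cube.copy()
            vals[13] = -np.inf  # exclude the center site
            best = vals.max()
            ties = np.flatnonzero(vals == best)
            pick = int(ties[0]) if len(ties) == 1 else int(ties[rng.integers(len(ties))])
            return _CUBE_OFFSETS[pick]
        best = -1.0
        best_offsets: list[tuple[int, int, int]] = []
        for off in MOORE_OFFSETS:
            q = (x + off[0], y + off[1], z + off[2])
            if not (0 <= q[0] < nx and 0 <= q[1] < ny and 0 <= q[2] < nz):
                continue
            v = a[q]
            if v > best:
                best = v
                best_offsets = [off]
            elif v == best:
                best_offsets.append(off)
        if len(best_offsets) == 1:
            return best_offsets[0]
        return best_offsets[int(rng.integers(len(best_offsets)))]


def monte_carlo_diffuse(
    initial: np.ndarray,
    steps: int,
    rng: np.random.Generator,
    stay_prob: float = 1.0 / 27.0,
    walkers_per_unit: int = 1,
) -> np.ndarray:
    """Independent discrete-molecule oracle for :meth:`Field.diffuse`.

    Places ``initial[site] * walkers_per_unit`` walkers per site and steps
    each one through the same lattice random walk (stay with probability
    ``stay_prob``, else a uniform Moore step, steps off the lattice not
    taken).  Returns mean occupancy per site in units of ``initial``.
    """
    counts = np.rint(np.asarray(initial) * walkers_per_unit).astype(np.int64)
    sites = np.argwhere(counts > 0)
    pos = np.repeat(sites, counts[tuple(sites.T)], axis=0)
    dims = np.array(initial.shape, dtype=np.int64)
    n = len(pos)
    for _ in range(steps):
        moving = rng.random(n) >= stay_prob
        step = _OFFSETS[rng.integers(26, size=n)]
        cand = pos + step * moving[:, None]
        ok = np.all((cand >= 0) & (cand < dims), axis=1)
        pos = np.where(ok[:, None], cand, pos)
    out = np.zeros(initial.shape, dtype=np.float64)
    np.add.at(out, tuple(pos.T), 1.0)
    return out / walkers_per_unit
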