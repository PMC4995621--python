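"""Scenario presets, initialization, the seeded time-stepping loop, sweeps.

A run starts from a single tumor cell at the world center, a set of
initial vessels (straight chains of quiescent endothelial cells placed
around the border, at random, or at a fixed distance from the center —
the default is the 200 μm / 40-site distance), fibroblasts scattered in
a shell around the center, a uniform oxygen background, and empty
VEGF/FGF/HGF fields.

Each tick: (1) all four fields diffuse one kernel step; (2) every active
agent acts once, in a freshly drawn seeded random permutation (so lattice
artifacts from a fixed sweep order are avoided); (3) population and mass
metrics are appended to the time series and the tick's events to the log.
All randomness flows from the single seeded generator, so a run is fully
determined by (scenario, horizon, seed).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import agents as _ag
from .agents import (
    EndothelialCell,
    Fibroblast,
    TumorCell,
    Vessel,
    build_endothelial_machine,
    build_fibroblast_machine,
    build_tumor_machine,
)
from .fields import SPECIES, Field
from .io_export import Snapshot
from .lattice import World, microns_to_sites
from .params import Params

__all__ = [
    "ScenarioSpec",
    "ScenarioError",
    "Simulation",
    "RunResult",
    "preset",
    "PRESET_NAMES",
    "run",
    "sweep",
    "named_grid",
]

#: columns of the per-tick time series
TS_COLUMNS = [
    "tick", "living_tumor", "hypoxic_tumor", "necrotic", "endothelial",
    "activated_endothelial", "cafs", "vegf_mass", "oxygen_mass", "branch_events",
]


class ScenarioError(ValueError):
    """Scenario geometry or configuration that cannot be realized."""


@dataclass(frozen=True)
class ScenarioSpec:
    """A fully concrete simulation setup."""

    name: str = "baseline"
    params: Params = field(default_factory=Params)
    dims: tuple[int, int, int] = (100, 100, 100)
    placement: str = "distance"  # border | random | distance
    horizon: int = 1200
    proliferative: bool = True
    angiogenesis: bool = True
    initial_tumor: bool = True

    def __post_init__(self):
        if self.placement not in ("border", "random", "distance"):
            raise ScenarioError(f"unknown vessel placement mode {self.placement!r}")
        if any(d < 3 for d in self.dims):
            raise ScenarioError(f"world dims must be at least 3 sites, got {self.dims}")


def preset(name: str, **param_overrides) -> ScenarioSpec:
    """Resolve a named scenario preset to a concrete :class:`ScenarioSpec`.

    The low/high presets scale the relevant parameter by 1/4 or 4 relative
    to the shipped calibration (absolute values from the original study
    are not published).
    """
    base = Params(**param_overrides) if param_overrides else Params()
    if name == "baseline":
        return ScenarioSpec(name=name, params=base)
    if name == "no_angiogenesis":
        return ScenarioSpec(name=name, params=base, angiogenesis=False)
    if name == "non_proliferating":
        return ScenarioSpec(name=name, params=base, proliferative=False, angiogenesis=False)
    if name == "far_vessels":
        p = base.replace(initial_vessel_distance=microns_to_sites(300.0))
        return ScenarioSpec(name=name, params=p, dims=(130, 130, 130))
    if name == "low_oxygen":
        return ScenarioSpec(name=name, params=base.scaled(oxygen_secretion_amount=0.25))
    if name == "high_oxygen":
        return ScenarioSpec(name=name, params=base.scaled(oxygen_secretion_amount=4.0))
    if name == "low_vegf":
        return ScenarioSpec(name=name, params=base.scaled(vegf_secretion_amount=0.25))
    if name == "high_vegf":
        return ScenarioSpec(name=name, params=base.scaled(vegf_secretion_amount=4.0))
    if name == "low_switch":
        return ScenarioSpec(name=name, params=base.scaled(angiogenic_switch_threshold=0.25))
    if name == "high_switch":
        # branching needs more VEGF than activation; keep that ordering
        p = base.scaled(angiogenic_switch_threshold=4.0)
        p = p.replace(branch_threshold=max(p.branch_threshold, 1.3 * p.angiogenic_switch_threshold))
        return ScenarioSpec(name=name, params=p)
    raise ScenarioError(f"unknown preset {name!r}; known: {sorted(PRESET_NAMES)}")


PRESET_NAMES = (
    "baseline", "no_angiogenesis", "non_proliferating", "far_vessels",
    "low_oxygen", "high_oxygen", "low_vegf", "high_vegf", "low_switch", "high_switch",
)


def named_grid(name: str) -> dict:
    """Parameter grids for the shipped sweeps over the fate thresholds."""
    base = Params()
    if name == "oxygen":
        return {"oxygen_secretion_amount": [base.oxygen_secretion_amount * f
                                            for f in (0.02, 0.1, 0.25, 1.0, 4.0)]}
    if name == "vegf":
        return {"vegf_secretion_amount": [base.vegf_secretion_amount * f
                                          for f in (0.0, 0.25, 1.0, 4.0)]}
    if name == "hypoxia":
        return {"hypoxia_level": [35, 70, 140, 280]}
    if name == "anoxia":
        return {"anoxia_level": [200, 340, 680, 5000]}
    raise ScenarioError(f"unknown sweep grid {name!r}")


class Simulation:
    """Mutable state of one run; create via ``Simulation(scenario, seed)``."""

    def __init__(self, scenario: ScenarioSpec, seed: int):
        self.scenario = scenario
        self.params = scenario.params
        self.seed = int(seed)
        self.rng = np.random.default_rng(np.random.SeedSequence(self.seed))
        self.world = World(scenario.dims)
        p = self.params
        self.fields: dict[str, Field] = {
            s: Field(scenario.dims, s, initial=(p.oxygen_initial if s == "oxygen" else 0.0))
            for s in SPECIES
        }
        self.angiogenesis_enabled = scenario.angiogenesis
        self.batch_fgf = True
        self.tick = 0
        self._next_id = 1
        self._next_vessel = 1
        self.agents: list = []          # creation order; permuted each tick
        self.cells_by_id: dict[int, object] = {}
        self.tumor_cells: list[TumorCell] = []
        self.ecs: list[EndothelialCell] = []
        self.fibroblasts: list[Fibroblast] = []
        self.vessels: dict[int, Vessel] = {}
        self.events: list[tuple] = []
        self._ts_rows: list[tuple] = []
        self._branch_this_tick = 0
        self._n_necrotic = 0
        self._n_tumor_living = 0
        self._n_ec_alive = 0
        self._n_ec_activated = 0
        self._n_cafs = 0
        self._tumor_tree = None
        self._tumor_rmax = 0.0
        self._center = tuple(d // 2 for d in scenario.dims)
        self._m_tumor = build_tumor_machine(p)
        self._m_ec = build_endothelial_machine(p)
        self._m_fibro = build_fibroblast_machine(p)
        self._init_contents()

    # -- construction ------------------------------------------------------
    def _init_contents(self) -> None:
        sc = self.scenario
        if sc.initial_tumor:
            self.spawn_tumor(self._center, proliferative=sc.proliferative)
        self._place_vessels()
        self._place_fibroblasts()

    def _chain_sites(self, anchor, axis, length):
        """Straight run of ``length`` sites along ``axis``, centered at anchor."""
        sites = []
        for k in range(length):
            offset = k - length // 2
            pos = list(anchor)
            pos[axis] += offset
            sites.append(tuple(pos))
        return sites

    def _place_vessels(self) -> None:
        p = self.params
        if p.num_vessels == 0 or p.vessel_length == 0:
            return
        cx, cy, cz = self._center
        d = p.initial_vessel_distance
        if self.scenario.placement == "border":
            d = min(self._center) - 1
        anchors: list[tuple[tuple[int, int, int], int]] = []
        if self.scenario.placement == "random":
            L = p.vessel_length
            for _ in range(p.num_vessels):
                axis = int(self.rng.integers(3))
                pos = [int(self.rng.integers(0, s)) for s in self.scenario.dims]
                # keep the whole chain inside the world along its axis
                lo, hi = L // 2, self.scenario.dims[axis] - (L - L // 2)
                if hi < lo:
                    raise ScenarioError(
                        f"vessel length {L} exceeds world dimension {self.scenario.dims[axis]}"
                    )
                pos[axis] = min(max(pos[axis], lo), hi)
                anchors.append((tuple(pos), axis))
        else:
            # 6 axis directions, then 8 diagonals if more vessels are asked for
            dirs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
            dirs += [(sx, sy, sz) for sx in (1, -1) for sy in (1, -1) for sz in (1, -1)]
            for i in range(p.num_vessels):
                ux, uy, uz = dirs[i % len(dirs)]
                norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                anchor = (cx + round(d * ux / norm), cy + round(d * uy / norm),
                          cz + round(d * uz / norm))
                # chain runs perpendicular to the anchor direction
                axis = 1 if ux else (2 if uy else 0)
                anchors.append((anchor, axis))
        for anchor, axis in anchors:
            sites = self._chain_sites(anchor, axis, p.vessel_length)
            if not all(self.world.in_bounds(s) for s in sites):
                raise ScenarioError(
                    f"vessel chain at {anchor} (distance {d}) does not fit in world "
                    f"{self.scenario.dims}"
                )
            vessel = self.new_vessel(parent=None)
            for s in sites:
                if self.world.is_empty(s):
                    ec = self.spawn_endothelial(s, vessel=vessel.id, newly_formed=False)
                    vessel.members.append(ec.id)

    def _place_fibroblasts(self) -> None:
        p = self.params
        if p.fibroblast_count == 0:
            return
        lo, hi = p.fibroblast_shell
        cx, cy, cz = self._center
        placed = 0
        attempts = 0
        while placed < p.fibroblast_count and attempts < 200 * p.fibroblast_count:
            attempts += 1
            r = lo + (hi - lo) * self.rng.random()
            u = self.rng.normal(size=3)
            n = math.sqrt(float(u @ u)) or 1.0
            pos = (int(round(cx + r * u[0] / n)), int(round(cy + r * u[1] / n)),
                   int(round(cz + r * u[2] / n)))
            if self.world.in_bounds(pos) and self.world.is_empty(pos):
                self.spawn_fibroblast(pos)
                placed += 1
        if placed < p.fibroblast_count:
            raise ScenarioError("could not place the requested number of fibroblasts")

    # -- agent management ----------------------------------------------------
    def _new_id(self) -> int:
        i = self._next_id
        self._next_id += 1
        return i

    def spawn_tumor(self, pos, proliferative: bool = True) -> TumorCell:
        cell = TumorCell(self._new_id(), pos, self._m_tumor, self.params,
                         proliferative=proliferative)
        self.world.place(cell.id, pos)
        self.agents.append(cell)
        self.cells_by_id[cell.id] = cell
        self.tumor_cells.append(cell)
        self._n_tumor_living += 1
        r = math.dist(pos, self._center)
        if r > self._tumor_rmax:
            self._tumor_rmax = r
        return cell

    def spawn_endothelial(self, pos, vessel: int, newly_formed: bool,
                          tip: bool = False) -> EndothelialCell:
        cell = EndothelialCell(self._new_id(), pos, self._m_ec, self.params,
                               vessel=vessel, newly_formed=newly_formed)
        self.world.place(cell.id, pos)
        self.agents.append(cell)
        self.cells_by_id[cell.id] = cell
        self.ecs.append(cell)
        self._n_ec_alive += 1
        if tip:
            cell.machine.dispatch("activate")
            self._n_ec_activated += 1
        return cell

    def spawn_fibroblast(self, pos) -> Fibroblast:
        cell = Fibroblast(self._new_id(), pos, self._m_fibro)
        self.world.place(cell.id, pos)
        self.agents.append(cell)
        self.cells_by_id[cell.id] = cell
        self.fibroblasts.append(cell)
        return cell

    def new_vessel(self, parent: Optional[int]) -> Vessel:
        v = Vessel(self._next_vessel, parent=parent)
        self._next_vessel += 1
        self.vessels[v.id] = v
        return v

    # -- callbacks from agent behavior ---------------------------------------
    def record(self, event: str, cell) -> None:
        x, y, z = cell.pos
        self.events.append((self.tick, event, cell.id, x, y, z))
        if event == "branch":
            self._branch_this_tick += 1
        elif event == "caf_conversion":
            self._n_cafs += 1

    def on_necrosis(self, cell: TumorCell) -> None:
        cell.active = False
        self._n_necrotic += 1
        self._n_tumor_living -= 1
        self.record("necrosis", cell)
        if self.params.remove_necrotic:
            self.world.clear(cell.pos)

    def on_activation(self, cell: EndothelialCell) -> None:
        """Delta-notch lateral inhibition around a newly activated cell."""
        self.record("activation", cell)
        self._n_ec_activated += 1
        occ = self.world.occupancy
        for q in self.world.neighbors(cell.pos):
            cid = int(occ[q])
            if cid:
                other = self.cells_by_id[cid]
                if other.kind == "endothelial" and not other.inhibited:
                    other.inhibited = True
                    other.inhibited_at = self.tick

    def on_vessel_starvation(self, cell: EndothelialCell) -> None:
        """A starved new cell dies along with the newly formed cells distal to it."""
        vessel = self.vessels[cell.vessel]
        try:
            idx = vessel.members.index(cell.id)
        except ValueError:
            idx = len(vessel.members)
        doomed = [cell]
        for cid in vessel.members[idx + 1:]:
            other = self.cells_by_id.get(cid)
            if other is not None and other.alive and other.newly_formed:
                doomed.append(other)
        for ec in doomed:
            if ec.alive:
                ec.machine.dispatch("die")
            ec.active = False
            self._n_ec_alive -= 1
            if ec.role != "quiescent":
                self._n_ec_activated -= 1
            self.world.clear(ec.pos)
            self.record("ec_death", ec)
        vessel.members = [cid for cid in vessel.members
                          if self.cells_by_id[cid].alive]

    def tumor_within(self, pos, radius: float) -> bool:
        """Is any living tumor cell within ``radius`` sites of ``pos``?"""
        if math.dist(pos, self._center) > radius + self._tumor_rmax:
            return False
        tree = self._tumor_tree
        if tree is None:
            living = [c.pos for c in self.tumor_cells if c.state != "necrotic"]
            if not living:
                return False
            from scipy.spatial import cKDTree
            tree = self._tumor_tree = cKDTree(np.asarray(living, dtype=np.float64))
        dist, _ = tree.query(pos, k=1)
        return bool(dist <= radius)

    # -- the loop ---------------------------------------------------------------
    def step(self) -> None:
        """Advance the simulation by one tick."""
        for s in SPECIES:
            f = self.fields[s]
            if f.initial == 0.0 and f.deposited == 0.0:
                continue  # an identically empty field is a diffusion fixed point
            f.diffuse(self.params.vegf_diffusion_substeps if s == "vegf" else 1)
        active = [c for c in self.agents if c.active]
        self._tumor_tree = None
        self._branch_this_tick = 0
        tumor_pre = None
        if active:
            order = self.rng.permutation(len(active))
            draws = self.rng.random(len(active))
            tumor_pre = [c for c in active if c.kind == "tumor"]
            tumor_step = _ag.tumor_step
            endothelial_step = _ag.endothelial_step
            fibroblast_step = _ag.fibroblast_step
            for i in order:
                cell = active[i]
                if not cell.active:
                    continue  # killed earlier this tick
                kind = cell.kind
                if kind == "tumor":
                    tumor_step(cell, self, float(draws[i]))
                elif kind == "endothelial":
                    endothelial_step(cell, self)
                else:
                    fibroblast_step(cell, self)
        if self.batch_fgf and tumor_pre:
            # one commuted deposit per tick for every cell that acted and
            # is still alive (cells necrosing mid-tick secreted nothing)
            amount = self.params.fgf_secretion_amount
            if amount > 0.0:
                alive = [c.pos for c in tumor_pre if c.state != "necrotic"]
                if alive:
                    idx = np.array(alive, dtype=np.intp)
                    fgf = self.fields["fgf"]
                    fgf.a[idx[:, 0], idx[:, 1], idx[:, 2]] += amount
                    fgf.deposited += amount * len(alive)
        self._append_metrics(active)
        self.tick += 1

    def _append_metrics(self, active=None) -> None:
        living = self._n_tumor_living
        n_ec = self._n_ec_alive
        act_ec = self._n_ec_activated
        cafs = self._n_cafs
        # only the hypoxic split needs a scan, over live tumor cells
        hypoxic = 0
        if active is not None:
            for c in active:
                if c.kind == "tumor" and c.state == "hypoxic":
                    hypoxic += 1
        else:
            for c in self.tumor_cells:
                if c.state == "hypoxic":
                    hypoxic += 1
        self._ts_rows.append((
            self.tick, living, hypoxic, self._n_necrotic, n_ec, act_ec, cafs,
            self.fields["vegf"].total_mass, self.fields["oxygen"].total_mass,
            self._branch_this_tick,
        ))

    def run(self, horizon: Optional[int] = None) -> None:
        horizon = self.scenario.horizon if horizon is None else horizon
        while self.tick < horizon:
            self.step()

    # -- outputs -----------------------------------------------------------------
    @property
    def timeseries(self) -> pd.DataFrame:
        return pd.DataFrame(self._ts_rows, columns=TS_COLUMNS)

    @property
    def event_log(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["tick", "event", "cell_id", "x", "y", "z"])

    def snapshot(self) -> Snapshot:
        cells = []
        for c in self.tumor_cells:
            cells.append((c.id, "tumor", c.state, *c.pos))
        for c in self.ecs:
            if c.alive:
                cells.append((c.id, "endothelial", c.role, *c.pos))
        for c in self.fibroblasts:
            cells.append((c.id, "fibroblast", "caf" if c.caf else "resting", *c.pos))
        vessels = {
            v.id: {"members": list(v.members), "parent": v.parent, "joined_to": v.joined_to}
            for v in self.vessels.values()
        }
        return Snapshot(
            tick=self.tick,
            dims=self.scenario.dims,
            cells=cells,
            fields={s: self.fields[s].a.copy() for s in SPECIES},
            vessels=vessels,
        )


@dataclass
class RunResult:
    scenario: ScenarioSpec
    seed: int
    timeseries: pd.DataFrame
    events: pd.DataFrame
    snapshot: Snapshot


def run(scenario: ScenarioSpec | str, horizon: Optional[int] = None,
        seed: int = 0) -> RunResult:
    """Run a scenario to its horizon and collect the recorded trajectory."""
    if isinstance(scenario, str):
        scenario = preset(scenario)
    sim = Simulation(scenario, seed)
    sim.run(horizon)
    return RunResult(scenario, seed, sim.timeseries, sim.event_log, sim.snapshot())


def sweep(grid: dict, replicates: int = 1, horizon: Optional[int] = None,
          base_seed: int = 0, scenario: Optional[ScenarioSpec] = None) -> pd.DataFrame:
    """Run every point of a parameter grid and classify each run's fate.

    ``grid`` maps Params field names (or config keys) to lists of values;
    the cartesian product is run ``replicates`` times each with seeds
    derived deterministically from ``base_seed``.
    """
    from .analysis import classify_fate, detect_turning_point
    from .params import _KEY_TO_FIELD

    sc = scenario or ScenarioSpec()
    names = [(_KEY_TO_FIELD.get(k, k)) for k in grid]
    values = [list(v) for v in grid.values()]
    rows = []
    for i, point in enumerate(itertools.product(*values)):
        overrides = dict(zip(names, point))
        params = sc.params.replace(**overrides)
        point_sc = replace(sc, params=params)
        for rep in range(replicates):
            seed = int(np.random.SeedSequence([base_seed, i, rep]).generate_state(1)[0] % (2**31))
            res = run(point_sc, horizon=horizon, seed=seed)
            series = res.timeseries["living_tumor"].to_numpy()
            if len(series) >= 50:
                fate = classify_fate(series, len(series))
                tp = detect_turning_point(series)
            else:
                fate, tp = None, None
            rows.append({
                **{k: v for k, v in zip(names, point)},
                "replicate": rep,
                "seed": seed,
                "fate": fate,
                "turning_point": tp,
                "final_living": int(series[-1]),
                "final_endothelial": int(res.timeseries["endothelial"].iloc[-1]),
                "final_necrotic": int(res.timeseries["necrotic"].iloc[-1]),
            })
    return pd.DataFrame(rows)
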