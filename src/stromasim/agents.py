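"""The three cell behaviors: tumor cell, endothelial cell, fibroblast/CAF.

Each cell carries a running statechart (see :mod:`stromasim.statechart`)
that owns its discrete state; the step functions below sense the
environment, feed events and timer ticks into the machine, and apply the
resulting effects (consumption, secretion, division, movement) to the
world and fields.  The machines themselves are declarative and contain
no engine-specific code.

Tumor cell: consumes oxygen every tick.  A tick of shortfall starts a
deficit counter; ``HypoxiaLevel`` consecutive short ticks make the cell
hypoxic (no proliferation, pulsed VEGF secretion), ``AnoxiaLevel`` make
it necrotic (permanently inert).  A single sufficient tick resets the
deficit and returns a hypoxic cell to normal.  Normal proliferative
cells divide into a random empty neighbor on a clock, faster when local
HGF is present, and move with a small probability gated by how degraded
the local ECM is.

Endothelial cell: binds local VEGF (up to a per-tick capacity) into a
rolling window and secretes oxygen at a constant rate.  A quiescent,
uninhibited cell whose window sum crosses ``AngiogenicSwitchThreshold``
becomes a sprout tip and laterally inhibits its neighbors (delta-notch).
A tip elongates one site per tick up the VEGF gradient by spawning a new
(tip) cell and becoming stalk; meeting another endothelial cell fuses
the sprouts (anastomosis).  A stalk that binds a high amount of VEGF in
a short window spawns a branch (a new vessel with parent lineage).
Newly formed cells that keep binding less than ``EndothelialMinVEGF``
starve and, after ``StarvationLimit`` ticks, die together with the newly
formed cells distal to them in their vessel.

Fibroblast: near the tumor and with enough oxygen it converts to a CAF
with a per-tick probability.  A CAF secretes VEGF in proportion to its
own oxygen deficit, secretes HGF, degrades the surrounding ECM, and
migrates up the FGF gradient laid down by the tumor.
"""

from __future__ import annotations

from typing import Optional

from .params import Params
from .statechart import TIMEOUT, MachineInstance, MachineSpec, StateSpec, TransitionSpec

__all__ = [
    "TumorCell",
    "EndothelialCell",
    "Fibroblast",
    "Vessel",
    "build_tumor_machine",
    "build_endothelial_machine",
    "build_fibroblast_machine",
    "tumor_step",
    "endothelial_step",
    "fibroblast_step",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# machine definitions
# ---------------------------------------------------------------------------

def _set_state(value: str):
    def action(cell):
        cell.state = value
    return action


def build_tumor_machine(params: Params) -> MachineSpec:
    """Oxygen-status machine of a tumor cell.

    Normal/Satisfied -> Normal/Starving on a shortage tick; the Starving
    timer (``HypoxiaLevel`` ticks) expires into Hypoxic, whose own timer
    (``AnoxiaLevel - HypoxiaLevel`` further ticks) expires into Necrotic.
    A 'fed' event anywhere short of Necrotic returns to Normal/Satisfied,
    resetting both timers.
    """
    def on_hypoxic(cell):
        cell.state = "hypoxic"
        cell.pulse = 0  # first VEGF pulse due immediately

    states = [
        StateSpec("Cell"),
        StateSpec("Normal", parent="Cell", initial=True, on_enter=_set_state("normal")),
        StateSpec("Satisfied", parent="Normal", initial=True),
        StateSpec("Starving", parent="Normal", timer=params.hypoxia_level),
        StateSpec("Hypoxic", parent="Cell", on_enter=on_hypoxic,
                  timer=params.anoxia_level - params.hypoxia_level),
        StateSpec("Necrotic", parent="Cell", on_enter=_set_state("necrotic")),
    ]
    transitions = [
        TransitionSpec("Satisfied", "Starving", "shortage"),
        TransitionSpec("Starving", "Satisfied", "fed"),
        TransitionSpec("Starving", "Hypoxic", TIMEOUT),
        TransitionSpec("Hypoxic", "Normal", "fed"),
        TransitionSpec("Hypoxic", "Necrotic", TIMEOUT),
    ]
    return MachineSpec("tumor_cell", states, transitions)


def build_endothelial_machine(params: Params) -> MachineSpec:
    """Role and viability of an endothelial cell as two concurrent regions."""
    def on_dead(cell):
        cell.alive = False

    states = [
        StateSpec("EC"),
        StateSpec("Alive", parent="EC", initial=True, parallel=True),
        StateSpec("Role", parent="Alive"),
        StateSpec("Quiescent", parent="Role", initial=True, on_enter=_set_role("quiescent")),
        StateSpec("Tip", parent="Role", on_enter=_set_role("tip")),
        StateSpec("Stalk", parent="Role", on_enter=_set_role("stalk")),
        StateSpec("Viability", parent="Alive"),
        StateSpec("Secure", parent="Viability", initial=True),
        StateSpec("VStarving", parent="Viability", timer=params.starvation_limit),
        StateSpec("Dead", parent="EC", on_enter=on_dead),
    ]
    transitions = [
        TransitionSpec("Quiescent", "Tip", "activate",
                       guard=lambda c: not c.inhibited),
        TransitionSpec("Tip", "Stalk", "demote"),
        TransitionSpec("Secure", "VStarving", "vegf_short",
                       guard=lambda c: c.newly_formed),
        TransitionSpec("VStarving", "Secure", "vegf_ok"),
        TransitionSpec("VStarving", "Dead", TIMEOUT),
        TransitionSpec("Alive", "Dead", "die"),
    ]
    return MachineSpec("endothelial_cell", states, transitions)


def _set_role(value: str):
    def action(cell):
        cell.role = value
    return action


def build_fibroblast_machine(params: Params) -> MachineSpec:
    def on_caf(cell):
        cell.caf = True

    states = [
        StateSpec("Fibroblast"),
        StateSpec("Resting", parent="Fibroblast", initial=True),
        StateSpec("CAF", parent="Fibroblast", on_enter=on_caf),
    ]
    transitions = [TransitionSpec("Resting", "CAF", "activate_caf")]
    return MachineSpec("fibroblast", states, transitions)


# ---------------------------------------------------------------------------
# cell containers
# ---------------------------------------------------------------------------

class TumorCell:
    __slots__ = ("id", "pos", "state", "machine", "clock", "pulse", "proliferative", "active")
    kind = "tumor"

    def __init__(self, cell_id: int, pos, machine_spec: MachineSpec, params: Params,
                 proliferative: bool = True):
        self.id = cell_id
        self.pos = pos
        self.state = "normal"
        self.proliferative = proliferative
        self.clock = params.proliferation_period
        self.pulse = 0
        self.active = True
        self.machine = MachineInstance(machine_spec, context=self)

    @property
    def deficit(self) -> int:
        """Consecutive ticks of insufficient oxygen (derived from the machine timers)."""
        m = self.machine
        if "Starving" in m.timers:
            return self.machine.spec.states["Starving"].timer - m.timers["Starving"]
        if "Hypoxic" in m.timers:
            h = self.machine.spec.states["Starving"].timer
            return h + self.machine.spec.states["Hypoxic"].timer - m.timers["Hypoxic"]
        if self.state == "necrotic":
            h = self.machine.spec.states["Starving"].timer
            return h + self.machine.spec.states["Hypoxic"].timer
        return 0


class EndothelialCell:
    __slots__ = (
        "id", "pos", "vessel", "role", "machine", "inhibited", "inhibited_at",
        "newly_formed", "age_new", "has_branched", "branch_retry", "alive", "active",
        "win", "win_idx", "win_sum", "branch_sum",
    )
    kind = "endothelial"

    def __init__(self, cell_id: int, pos, machine_spec: MachineSpec, params: Params,
                 vessel: int, newly_formed: bool = False):
        self.id = cell_id
        self.pos = pos
        self.vessel = vessel
        self.role = "quiescent"
        self.inhibited = False
        self.inhibited_at = -1
        self.newly_formed = newly_formed
        self.age_new = 0
        self.has_branched = False
        self.branch_retry = 0
        self.alive = True
        self.active = True
        self.win = [0.0] * params.activation_window
        self.win_idx = 0
        self.win_sum = 0.0
        self.branch_sum = 0.0
        self.machine = MachineInstance(machine_spec, context=self)

    def push_bound(self, b: float, branch_window: int) -> None:
        """Record this tick's bound VEGF in the rolling windows."""
        win = self.win
        idx = self.win_idx
        w = len(win)
        self.branch_sum += b - win[(idx - branch_window) % w]
        self.win_sum += b - win[idx]
        win[idx] = b
        self.win_idx = (idx + 1) % w

    @property
    def starve(self) -> int:
        m = self.machine
        if "VStarving" in m.timers:
            return self.machine.spec.states["VStarving"].timer - m.timers["VStarving"]
        return 0


class Fibroblast:
    __slots__ = ("id", "pos", "caf", "deficit", "machine", "active")
    kind = "fibroblast"

    def __init__(self, cell_id: int, pos, machine_spec: MachineSpec):
        self.id = cell_id
        self.pos = pos
        self.caf = False
        self.deficit = 0
        self.active = True
        self.machine = MachineInstance(machine_spec, context=self)


class Vessel:
    """A blood vessel: an ordered chain of endothelial cell ids."""

    __slots__ = ("id", "members", "parent", "joined_to")

    def __init__(self, vessel_id: int, members: Optional[list[int]] = None,
                 parent: Optional[int] = None):
        self.id = vessel_id
        self.members = list(members) if members else []
        self.parent = parent
        self.joined_to: Optional[int] = None


# ---------------------------------------------------------------------------
# per-agent behavior
# ---------------------------------------------------------------------------

def tumor_step(cell: TumorCell, sim, motility_draw: Optional[float] = None) -> None:
    """One tick of tumor-cell behavior (necrotic cells never act).

    ``motility_draw`` lets the caller supply this tick's pre-drawn
    uniform variate for the movement gate; when None it is drawn from
    the simulation stream directly.  FGF secretion is accounted by the
    driving loop in one batched deposit per tick (deposits commute, so
    the resulting field is identical).
    """
    p: Params = sim.params
    oxy = sim.fields["oxygen"]
    pos = cell.pos
    need = p.oxygen_need_per_step
    # upkeep is drawn at the cell's own site: a molecule is consumed where
    # it meets the cell, so survival needs an actual local concentration
    # (inlined own-site take: this is the hottest line in the model)
    fx = pos[0] * oxy._nynz + pos[1] * oxy._nz + pos[2]
    mv = oxy.mv
    avail = mv[fx]
    if avail >= need:
        mv[fx] = avail - need
        granted = need
    else:
        mv[fx] = 0.0
        granted = avail
    oxy.consumed += granted
    m = cell.machine
    if granted + _EPS < need:
        if "Satisfied" in m.active:
            m.dispatch("shortage")
        m.tick()
        if cell.state == "necrotic":
            sim.on_necrosis(cell)
            return
    elif "Satisfied" not in m.active:
        m.dispatch("fed")

    if not sim.batch_fgf:
        sim.fields["fgf"].deposit(pos, p.fgf_secretion_amount)

    if cell.state == "hypoxic":
        # pulsed VEGF secretion for as long as hypoxia lasts
        if cell.pulse <= 0:
            sim.fields["vegf"].deposit(pos, p.vegf_secretion_amount)
            cell.pulse = p.vegf_pulse_period
        cell.pulse -= 1
        return  # hypoxic cells neither proliferate nor advance their clock

    if cell.proliferative:
        cell.clock -= 1
        if cell.clock <= 0:
            if not sim.world.has_empty_neighbor(pos):
                cell.clock = 5  # boxed in; look again shortly
            else:
                # dividing takes an oxygen reserve on top of per-tick upkeep:
                # a cell in a drained neighborhood defers until supply returns
                cost = p.division_oxygen_cost
                pool = oxy.neighborhood_sum(pos)
                if cost <= 0.0 or pool >= cost:
                    target = sim.world.random_empty_neighbor(pos, sim.rng)
                    if target is not None:
                        if cost > 0.0:
                            oxy.consume(pos, cost)
                        sim.spawn_tumor(target, proliferative=cell.proliferative)
                        sim.record("division", cell)
                        # HGF shortens the next cycle, but growth-factor
                        # acceleration takes the metabolic headroom of a
                        # well-supplied (vascularized) neighborhood
                        hgf = sim.fields["hgf"]
                        if (hgf.deposited > 0.0 and hgf.a[pos] > p.hgf_threshold
                                and pool >= p.hgf_boost_min_pool):
                            cell.clock = max(1, round(p.proliferation_period / p.hgf_boost))
                        else:
                            cell.clock = p.proliferation_period

    if p.base_motility > 0.0:
        ecm = sim.world.ecm[pos]
        if ecm < 1.0:
            u = sim.rng.random() if motility_draw is None else motility_draw
            if u < p.base_motility * (1.0 - ecm):
                target = sim.world.random_empty_neighbor(pos, sim.rng)
                if target is not None:
                    sim.world.move(pos, target)
                    cell.pos = target


def endothelial_step(cell: EndothelialCell, sim) -> None:
    """One tick of endothelial-cell behavior."""
    p: Params = sim.params
    vegf = sim.fields["vegf"]
    pos = cell.pos
    # inlined own-site VEGF binding and oxygen release (hot path: the
    # endothelial population reaches tens of thousands of cells)
    if vegf.deposited > 0.0:
        fx = pos[0] * vegf._nynz + pos[1] * vegf._nz + pos[2]
        mv = vegf.mv
        avail = mv[fx]
        cap = p.binding_capacity
        bound = cap if avail >= cap else avail
        if bound > 0.0:
            mv[fx] = avail - bound
            vegf.consumed += bound
    else:
        bound = 0.0
    cell.push_bound(bound, p.branch_window)
    oxy = sim.fields["oxygen"]
    fx = pos[0] * oxy._nynz + pos[1] * oxy._nz + pos[2]
    oxy.mv[fx] += p.oxygen_secretion_amount
    oxy.deposited += p.oxygen_secretion_amount
    m = cell.machine

    if cell.newly_formed:
        cell.age_new += 1
        if p.maturation_time and cell.age_new >= p.maturation_time:
            cell.newly_formed = False
            if "VStarving" in m.active:
                m.dispatch("vegf_ok")
        elif bound + _EPS < p.endothelial_min_vegf:
            if "Secure" in m.active:
                m.dispatch("vegf_short")
            m.tick()
            if not cell.alive:
                sim.on_vessel_starvation(cell)
                return
        elif "VStarving" in m.active:
            m.dispatch("vegf_ok")

    if p.inhibition_ttl and cell.inhibited and sim.tick - cell.inhibited_at >= p.inhibition_ttl:
        cell.inhibited = False

    role = cell.role
    if role == "quiescent":
        if (
            sim.angiogenesis_enabled
            and not cell.inhibited
            and cell.win_sum >= p.angiogenic_switch_threshold
        ):
            m.dispatch("activate")
            sim.on_activation(cell)
    elif role == "tip":
        # sprouting continues only while the tip keeps binding VEGF
        if bound >= p.elongation_min_vegf:
            _elongate(cell, sim)
    elif role == "stalk":
        if (
            not cell.has_branched
            and cell.branch_sum >= p.branch_threshold
            and sim.angiogenesis_enabled
            and sim.tick >= cell.branch_retry
        ):
            _branch(cell, sim)


def _elongate(cell: EndothelialCell, sim) -> None:
    """Tip behavior: grow the sprout one site up the VEGF gradient."""
    vegf = sim.fields["vegf"]
    dx, dy, dz = vegf.gradient_direction(cell.pos, sim.rng)
    target = (cell.pos[0] + dx, cell.pos[1] + dy, cell.pos[2] + dz)
    occupant_id = sim.world.occupant(target)
    if occupant_id == 0:
        new = sim.spawn_endothelial(target, vessel=cell.vessel, newly_formed=True, tip=True)
        cell.machine.dispatch("demote")
        sim.vessels[cell.vessel].members.append(new.id)
    else:
        other = sim.cells_by_id.get(occupant_id)
        if other is not None and other.kind == "endothelial" and other.alive:
            # anastomosis: the sprout fuses with the vessel it ran into
            cell.machine.dispatch("demote")
            sim.vessels[cell.vessel].joined_to = other.vessel
            sim.record("anastomosis", cell)
        # a site blocked by any other cell just stalls the tip this tick


def _branch(cell: EndothelialCell, sim) -> None:
    """Stalk behavior: sprout a second tip into a new vessel (once per cell)."""
    vegf = sim.fields["vegf"]
    dx, dy, dz = vegf.gradient_direction(cell.pos, sim.rng)
    target = (cell.pos[0] + dx, cell.pos[1] + dy, cell.pos[2] + dz)
    if sim.world.occupant(target) != 0:
        target = sim.world.random_empty_neighbor(cell.pos, sim.rng)
        if target is None:
            # boxed in; look again once the neighborhood has had time to change
            cell.branch_retry = sim.tick + 15
            return
    vessel = sim.new_vessel(parent=cell.vessel)
    sim.spawn_endothelial(target, vessel=vessel.id, newly_formed=True, tip=True)
    cell.has_branched = True
    sim.record("branch", cell)


def fibroblast_step(cell: Fibroblast, sim) -> None:
    """One tick of fibroblast/CAF behavior."""
    p: Params = sim.params
    oxy = sim.fields["oxygen"]
    local_oxygen = float(oxy.a[cell.pos])
    need = p.fibroblast_oxygen_need
    granted = oxy.take(cell.pos, need) if need > 0.0 else 0.0
    if granted + _EPS < need:
        cell.deficit += 1
    else:
        cell.deficit = 0

    if not cell.caf:
        if (
            cell.deficit == 0
            and local_oxygen >= p.caf_oxygen_min
            and sim.tumor_within(cell.pos, p.caf_radius)
            and sim.rng.random() < p.caf_base_prob
        ):
            cell.machine.dispatch("activate_caf")
            sim.record("caf_conversion", cell)
        return

    # CAF: VEGF output scales with its own hypoxia deficit (capped at the
    # per-tick average output of a fully hypoxic tumor cell)
    frac = cell.deficit / p.hypoxia_level
    if frac > 0.0:
        if frac > 1.0:
            frac = 1.0
        sim.fields["vegf"].deposit(
            cell.pos, frac * p.vegf_secretion_amount / p.vegf_pulse_period
        )
    sim.fields["hgf"].deposit(cell.pos, p.hgf_secretion_amount)
    sim.world.degrade_ecm(cell.pos, p.ecm_degradation_rate)
    fgf = sim.fields["fgf"]
    if fgf.deposited > 0.0:
        dx, dy, dz = fgf.gradient_direction(cell.pos, sim.rng)
        target = (cell.pos[0] + dx, cell.pos[1] + dy, cell.pos[2] + dz)
        if sim.world.occupant(target) == 0:
            sim.world.move(cell.pos, target)
            cell.pos = target
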