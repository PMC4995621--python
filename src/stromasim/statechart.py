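"""Minimal hierarchical state-machine (statechart) engine.

States form a rooted tree; composite states declare exactly one *initial*
child, or are *parallel*, in which case every child is a concurrent region
entered together.  Transitions are triggered by named events or by a state
timer expiring, optionally guarded by a predicate over the machine context
and carrying an action callback.  Transition priority: the enabled
transition with the deepest source wins; ties are broken by declaration
order (strict mode turns a same-depth tie into an error).

The engine knows nothing about cells: the tumor, endothelial and
fibroblast behavior machines are declared elsewhere and compile onto it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Callable, Optional

__all__ = [
    "TIMEOUT",
    "StateSpec",
    "TransitionSpec",
    "MachineSpec",
    "MachineInstance",
    "StatechartError",
    "AmbiguityError",
]

#: Sentinel trigger for timed transitions (fired when the source's timer expires).
TIMEOUT = "__timeout__"


class StatechartError(ValueError):
    """Malformed machine specification or illegal runtime request."""


class AmbiguityError(StatechartError):
    """Two enabled transitions at the same depth in strict mode."""


@dataclass(frozen=True)
class StateSpec:
    """A single state: a node of the machine's state tree.

    ``timer`` is a duration in whole simulation ticks; entering the state
    (re-)arms it, leaving the state cancels it.  ``parallel`` marks every
    child as a concurrent region.
    """

    name: str
    parent: Optional[str] = None
    initial: bool = False
    parallel: bool = False
    timer: Optional[int] = None
    on_enter: Optional[Callable[[Any], None]] = None
    on_exit: Optional[Callable[[Any], None]] = None


@dataclass(frozen=True)
class TransitionSpec:
    """A guarded transition between two states of the same machine."""

    source: str
    target: str
    trigger: str
    guard: Optional[Callable[[Any], bool]] = None
    action: Optional[Callable[[Any], None]] = None


class MachineSpec:
    """Validated machine definition: a state tree plus a transition list."""

    def __init__(self, name: str, states: list[StateSpec], transitions: list[TransitionSpec]):
        self.name = name
        self.states = {s.name: s for s in states}
        if len(self.states) != len(states):
            raise StatechartError(f"duplicate state names in machine {name!r}")
        self.transitions = list(transitions)
        self.children: dict[str, list[str]] = {s.name: [] for s in states}
        roots = [s.name for s in states if s.parent is None]
        if len(roots) != 1:
            raise StatechartError(f"machine {name!r} must have exactly one root state, got {roots}")
        self.root = roots[0]
        for s in states:
            if s.parent is not None:
                if s.parent not in self.states:
                    raise StatechartError(f"state {s.name!r} has unknown parent {s.parent!r}")
                self.children[s.parent].append(s.name)
        # depth + cycle check via walk from root
        self.depth: dict[str, int] = {}
        stack = [(self.root, 0)]
        while stack:
            n, d = stack.pop()
            self.depth[n] = d
            for c in self.children[n]:
                stack.append((c, d + 1))
        if len(self.depth) != len(self.states):
            orphans = set(self.states) - set(self.depth)
            raise StatechartError(f"states unreachable from root (parent cycle?): {sorted(orphans)}")
        # initial-child discipline
        self.initial_child: dict[str, Optional[str]] = {}
        for n, kids in self.children.items():
            if not kids or self.states[n].parallel:
                self.initial_child[n] = None
                continue
            marked = [c for c in kids if self.states[c].initial]
            if len(marked) != 1:
                raise StatechartError(
                    f"composite state {n!r} must have exactly one initial child, got {marked}"
                )
            self.initial_child[n] = marked[0]
        for t in self.transitions:
            for end in (t.source, t.target):
                if end not in self.states:
                    raise StatechartError(f"transition endpoint {end!r} not a state of machine {name!r}")
        self.events = sorted({t.trigger for t in self.transitions if t.trigger != TIMEOUT})
        # timed states must declare what expiry does
        timeout_sources = {t.source for t in self.transitions if t.trigger == TIMEOUT}
        for s in states:
            if s.timer is not None and s.name not in timeout_sources:
                raise StatechartError(f"state {s.name!r} has a timer but no timeout transition")
            if s.timer is not None and s.timer < 1:
                raise StatechartError(f"state {s.name!r} timer must be >= 1 tick")
        # transition lookup: trigger -> list in declaration order
        self._by_trigger: dict[str, list[TransitionSpec]] = {}
        for t in self.transitions:
            self._by_trigger.setdefault(t.trigger, []).append(t)
        # precomputed firing plans: transition -> (state to exit, entry chain)
        self._plans: dict[int, tuple[str, tuple[str, ...]]] = {}
        for t in self.transitions:
            self._plans[id(t)] = self._make_plan(t)

    def _make_plan(self, t: TransitionSpec) -> tuple[str, tuple[str, ...]]:
        src_path = self.path_to_root(t.source)
        tgt_path = self.path_to_root(t.target)
        src_anc, tgt_anc = set(src_path), set(tgt_path)
        if t.source == t.target or t.target in src_anc or t.source in tgt_anc:
            lca = self.states[t.source].parent if t.source != self.root else None
        else:
            lca = next(s for s in src_path if s in tgt_anc)
        if lca is None:
            exit_top = self.root
        else:
            exit_top = next(s for s in src_path if self.states[s].parent == lca)
        entry_chain = tuple(
            s for s in reversed(tgt_path)
            if lca is None or self.depth[s] > self.depth[lca]
        )
        return exit_top, entry_chain

    def path_to_root(self, name: str) -> list[str]:
        out = []
        while name is not None:
            out.append(name)
            name = self.states[name].parent
        return out

    def to_json(self) -> str:
        """Serialize the structure (not the callables) for documentation/export."""
        doc = {
            "machine": self.name,
            "states": [
                {
                    "name": s.name,
                    "parent": s.parent,
                    "initial": s.initial,
                    "parallel": s.parallel,
                    "timer": s.timer,
                }
                for s in sorted(self.states.values(), key=lambda s: (self.depth[s.name], s.name))
            ],
            "transitions": [
                {"source": t.source, "target": t.target, "trigger": t.trigger,
                 "guarded": t.guard is not None}
                for t in self.transitions
            ],
            "events": self.events,
        }
        return json.dumps(doc, indent=2, sort_keys=False)


class MachineInstance:
    """A running copy of a :class:`MachineSpec` bound to an opaque context.

    ``active`` is closed under parents; each non-parallel composite has
    exactly one active child, each parallel composite has all its regions
    active.  ``timers`` maps active timed states to remaining ticks.
    """

    __slots__ = ("spec", "context", "active", "timers", "strict")

    def __init__(self, spec: MachineSpec, context: Any = None, strict: bool = False):
        self.spec = spec
        self.context = context
        self.strict = strict
        self.active: set[str] = set()
        self.timers: dict[str, int] = {}
        self._enter(spec.root)

    # -- configuration ----------------------------------------------------
    def in_state(self, name: str) -> bool:
        return name in self.active

    @property
    def configuration(self) -> frozenset:
        return frozenset(self.active)

    def leaf_states(self) -> set[str]:
        return {s for s in self.active if not any(c in self.active for c in self.spec.children[s])}

    # -- entry/exit -------------------------------------------------------
    def _enter(self, name: str) -> None:
        spec = self.spec
        self.active.add(name)
        st = spec.states[name]
        if st.timer is not None:
            self.timers[name] = st.timer
        if st.on_enter is not None:
            st.on_enter(self.context)
        if st.parallel:
            for c in spec.children[name]:
                self._enter(c)
        else:
            init = spec.initial_child[name]
            if init is not None:
                self._enter(init)

    def _exit(self, name: str) -> None:
        # inner -> outer
        for c in self.spec.children[name]:
            if c in self.active:
                self._exit(c)
        self.active.discard(name)
        self.timers.pop(name, None)
        st = self.spec.states[name]
        if st.on_exit is not None:
            st.on_exit(self.context)

    # -- event processing -------------------------------------------------
    def dispatch(self, event: str) -> bool:
        """Fire the highest-priority enabled transition for ``event``.

        Returns True if a transition fired; an event with no enabled
        transition leaves the configuration unchanged.
        """
        if event == TIMEOUT:
            raise StatechartError("the timeout trigger is fired by tick(), not dispatched")
        cands = self._by_trigger(event)
        if not cands:
            return False
        best = cands[0]
        if self.strict and len(cands) > 1 and self.spec.depth[cands[1].source] == self.spec.depth[best.source]:
            raise AmbiguityError(
                f"event {event!r}: transitions from {best.source!r} and {cands[1].source!r} "
                f"both enabled at depth {self.spec.depth[best.source]}"
            )
        self._fire(best)
        return True

    def _by_trigger(self, trigger: str, only_source: Optional[str] = None) -> list[TransitionSpec]:
        """Enabled transitions, deepest source first, declaration order within a depth."""
        candidates = self.spec._by_trigger.get(trigger)
        if not candidates:
            return []
        active = self.active
        depth = self.spec.depth
        out = []
        for t in candidates:
            if t.source not in active:
                continue
            if only_source is not None and t.source != only_source:
                continue
            if t.guard is not None and not t.guard(self.context):
                continue
            out.append(t)
        if len(out) > 1:
            out.sort(key=lambda t: -depth[t.source])
        return out

    def _fire(self, t: TransitionSpec) -> None:
        spec = self.spec
        exit_top, entry_chain = spec._plans[id(t)]
        # exit the subtree containing the source (inner->outer), then act,
        # then enter outer->inner down to the target's initial configuration
        self._exit(exit_top)
        if t.action is not None:
            t.action(self.context)
        for s in entry_chain[:-1]:
            self.active.add(s)
            st = spec.states[s]
            if st.timer is not None:
                self.timers[s] = st.timer
            if st.on_enter is not None:
                st.on_enter(self.context)
        self._enter(entry_chain[-1])

    def tick(self) -> None:
        """Advance timers of active states by one tick; fire expiries.

        All active timers decrement together; every timer reaching zero
        fires its timeout transition this tick (deepest source first),
        unless an earlier expiry already exited its state.
        """
        expired = []
        for name in list(self.timers):
            self.timers[name] -= 1
            if self.timers[name] <= 0:
                expired.append(name)
        expired.sort(key=lambda n: -self.spec.depth[n])
        for name in expired:
            if name not in self.active or self.timers.get(name, 1) > 0:
                continue  # an earlier expiry exited or re-armed this state
            del self.timers[name]
            cands = self._by_trigger(TIMEOUT, only_source=name)
            if cands:
                self._fire(cands[0])
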