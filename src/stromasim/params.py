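"""Model parameters and the shipped default calibration.

The model's quantities are unit-less "units" for molecular amounts and
whole simulation ticks for durations; one lattice site is 5 μm.  The five
behaviorally named parameters (``OxygenSecretionAmount``,
``VEGFSecretionAmount``, ``AngiogenicSwitchThreshold``, ``HypoxiaLevel``,
``AnoxiaLevel``) keep those names in configuration files; every other rate
and threshold is a calibrated default of this package (see
docs/methods.md for the rationale behind each value).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

__all__ = ["Params", "ParamsError", "CONFIG_KEYS"]


class ParamsError(ValueError):
    """A parameter value or combination violates the model's invariants."""


@dataclass
class Params:
    # -- named, behaviorally central parameters ---------------------------
    #: oxygen units every endothelial cell releases per tick
    oxygen_secretion_amount: float = 1.5
    #: VEGF units a hypoxic tumor cell releases per pulse
    vegf_secretion_amount: float = 30.0
    #: windowed bound-VEGF sum needed to activate an endothelial cell
    angiogenic_switch_threshold: float = 2.4
    #: consecutive oxygen-deficit ticks before a cell turns hypoxic
    hypoxia_level: int = 140
    #: consecutive oxygen-deficit ticks before a cell turns necrotic
    anoxia_level: int = 340
    # -- consumption and secretion ----------------------------------------
    #: oxygen units a cell must consume each tick to stay satisfied
    oxygen_need_per_step: float = 1.0
    #: ticks between successive VEGF pulses of a hypoxic tumor cell
    vegf_pulse_period: int = 5
    #: FGF units a tumor cell releases per tick (CAF chemoattractant)
    fgf_secretion_amount: float = 1.0
    #: HGF units a CAF releases per tick (proliferation enhancer)
    hgf_secretion_amount: float = 1.0
    # -- angiogenic switch and branching ----------------------------------
    #: length in ticks of the bound-VEGF window behind the switch
    activation_window: int = 90
    #: windowed bound-VEGF sum at which a stalk cell branches
    #: (a sustained binding rate well above the activation level,
    #: so branching concentrates where VEGF is dense)
    branch_threshold: float = 16.0
    #: length in ticks of the branching window (<= activation window)
    branch_window: int = 35
    #: VEGF units an endothelial cell can bind per tick
    binding_capacity: float = 2.0
    # -- vessel viability ---------------------------------------------------
    #: per-tick bound VEGF below which a newly formed cell starves
    endothelial_min_vegf: float = 0.02
    #: per-tick bound VEGF a tip needs in order to keep elongating
    elongation_min_vegf: float = 0.02
    #: consecutive starved ticks after which a newly formed cell dies
    starvation_limit: int = 40
    #: ticks after which a surviving new endothelial cell is mature
    #: (mature cells no longer starve; 0 disables maturation)
    maturation_time: int = 80
    # -- tumor growth --------------------------------------------------------
    #: ticks between divisions of a normoxic proliferative tumor cell
    proliferation_period: int = 30
    #: oxygen units a division consumes (pooled locally) on top of upkeep;
    #: a front without an oxygen reserve cannot keep proliferating
    division_oxygen_cost: float = 12.0
    #: divisor on the proliferation period while local HGF is present
    hgf_boost: float = 2.0
    #: local HGF amount above which the boost applies
    hgf_threshold: float = 0.1
    #: pooled local oxygen required for the HGF boost to act: growth-factor
    #: acceleration needs metabolic headroom, which only a vascularized
    #: neighborhood provides
    hgf_boost_min_pool: float = 100.0
    #: per-tick movement probability of a tumor cell at zero ECM density
    base_motility: float = 0.1
    # -- fibroblasts and ECM --------------------------------------------------
    #: distance (sites) to the nearest tumor cell within which a
    #: fibroblast may convert to a CAF
    caf_radius: int = 9
    #: per-tick CAF conversion probability when eligible
    caf_base_prob: float = 0.02
    #: fraction of ECM density removed per tick around a CAF
    ecm_degradation_rate: float = 0.05
    #: oxygen units a fibroblast consumes per tick (stromal cells are
    #: quiescent and draw far less than tumor cells)
    fibroblast_oxygen_need: float = 1.0
    #: local oxygen level a fibroblast needs to activate into a CAF
    #: on top of being deficit-free (0 disables the extra gate)
    caf_oxygen_min: float = 0.0
    # -- initial conditions ------------------------------------------------
    #: distance (sites) of the initial vessels from the world center
    initial_vessel_distance: int = 40
    #: number of initial vessel chains
    num_vessels: int = 6
    #: endothelial cells per initial vessel chain
    vessel_length: int = 40
    #: fibroblasts seeded around the tumor
    fibroblast_count: int = 700
    #: radial shell (sites from center) in which fibroblasts are seeded
    fibroblast_shell: tuple[int, int] = (16, 38)
    #: uniform background oxygen per site at tick 0
    oxygen_initial: float = 2.4
    #: diffusion kernel applications per tick for VEGF (its effective
    #: diffusivity relative to oxygen; VEGF is a small secreted protein
    #: that spreads through interstitium much faster than oxygen is
    #: transported through consuming tissue)
    vegf_diffusion_substeps: int = 5
    # -- documented switches --------------------------------------------------
    #: remove necrotic cells from the lattice instead of leaving inert obstacles
    remove_necrotic: bool = False
    #: ticks after which delta-notch inhibition expires (0 = permanent)
    inhibition_ttl: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        p = self
        if not p.hypoxia_level < p.anoxia_level:
            raise ParamsError(
                f"HypoxiaLevel ({p.hypoxia_level}) must be below AnoxiaLevel ({p.anoxia_level})"
            )
        if not p.branch_threshold > p.angiogenic_switch_threshold:
            raise ParamsError(
                f"BranchThreshold ({p.branch_threshold}) must exceed "
                f"AngiogenicSwitchThreshold ({p.angiogenic_switch_threshold})"
            )
        if not p.branch_window <= p.activation_window:
            raise ParamsError(
                f"BranchWindow ({p.branch_window}) must not exceed "
                f"ActivationWindow ({p.activation_window})"
            )
        for name in (
            "oxygen_secretion_amount", "vegf_secretion_amount",
            "angiogenic_switch_threshold", "oxygen_need_per_step",
            "fgf_secretion_amount", "hgf_secretion_amount", "branch_threshold",
            "binding_capacity", "endothelial_min_vegf", "elongation_min_vegf",
            "hgf_boost", "hgf_threshold", "hgf_boost_min_pool", "oxygen_initial", "division_oxygen_cost",
            "fibroblast_oxygen_need", "caf_oxygen_min",
        ):
            if getattr(p, name) < 0 or not math.isfinite(getattr(p, name)):
                raise ParamsError(f"{CONFIG_KEYS[name]} must be a finite non-negative number")
        for name in (
            "hypoxia_level", "anoxia_level", "vegf_pulse_period", "vegf_diffusion_substeps",
            "activation_window", "branch_window", "starvation_limit",
            "maturation_time", "proliferation_period", "caf_radius",
            "initial_vessel_distance", "num_vessels", "vessel_length",
            "fibroblast_count", "inhibition_ttl",
        ):
            if int(getattr(p, name)) != getattr(p, name) or getattr(p, name) < 0:
                raise ParamsError(f"{CONFIG_KEYS[name]} must be a non-negative integer")
        for name in ("caf_base_prob", "base_motility", "ecm_degradation_rate"):
            if not 0.0 <= getattr(p, name) <= 1.0:
                raise ParamsError(f"{CONFIG_KEYS[name]} must be a probability in [0, 1]")
        if p.hgf_boost < 1.0:
            raise ParamsError("HGFBoost must be >= 1 (it divides the proliferation period)")
        lo, hi = p.fibroblast_shell
        if not 0 <= lo <= hi:
            raise ParamsError(f"FibroblastShell must be an ordered pair of radii, got {p.fibroblast_shell}")

    # -- (de)serialization --------------------------------------------------
    def replace(self, **overrides) -> "Params":
        return dataclasses.replace(self, **overrides)

    def scaled(self, **multipliers) -> "Params":
        """Return a copy with each named field multiplied by a factor."""
        changes = {}
        for name, f in multipliers.items():
            v = getattr(self, name)
            changes[name] = type(v)(v * f) if isinstance(v, int) else v * f
        return self.replace(**changes)

    def to_config(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = list(v)
            out[CONFIG_KEYS[f.name]] = v
        return out

    @classmethod
    def from_config(cls, doc: dict) -> "Params":
        unknown = sorted(set(doc) - set(_KEY_TO_FIELD))
        if unknown:
            raise ParamsError(
                f"unknown parameter keys {unknown}; valid keys: {sorted(_KEY_TO_FIELD)}"
            )
        kwargs = {}
        for key, v in doc.items():
            name = _KEY_TO_FIELD[key]
            if name == "fibroblast_shell":
                v = tuple(int(x) for x in v)
            kwargs[name] = v
        return cls(**kwargs)


#: dataclass field -> configuration-file key (the field's standard names
#: for the behaviorally central parameters)
CONFIG_KEYS = {
    "oxygen_secretion_amount": "OxygenSecretionAmount",
    "vegf_secretion_amount": "VEGFSecretionAmount",
    "angiogenic_switch_threshold": "AngiogenicSwitchThreshold",
    "hypoxia_level": "HypoxiaLevel",
    "anoxia_level": "AnoxiaLevel",
    "oxygen_need_per_step": "OxygenNeedPerStep",
    "vegf_pulse_period": "VEGFPulsePeriod",
    "fgf_secretion_amount": "FGFSecretionAmount",
    "hgf_secretion_amount": "HGFSecretionAmount",
    "activation_window": "ActivationWindow",
    "branch_threshold": "BranchThreshold",
    "branch_window": "BranchWindow",
    "binding_capacity": "BindingCapacity",
    "endothelial_min_vegf": "EndothelialMinVEGF",
    "elongation_min_vegf": "ElongationMinVEGF",
    "starvation_limit": "StarvationLimit",
    "maturation_time": "MaturationTime",
    "proliferation_period": "ProliferationPeriod",
    "division_oxygen_cost": "DivisionOxygenCost",
    "hgf_boost": "HGFBoost",
    "hgf_threshold": "HGFThreshold",
    "hgf_boost_min_pool": "HGFBoostMinPool",
    "base_motility": "BaseMotility",
    "caf_radius": "CAFRadius",
    "caf_base_prob": "CAFBaseProb",
    "ecm_degradation_rate": "ECMDegradationRate",
    "fibroblast_oxygen_need": "FibroblastOxygenNeed",
    "caf_oxygen_min": "CAFOxygenMin",
    "initial_vessel_distance": "InitialVesselDistance",
    "num_vessels": "NumVessels",
    "vessel_length": "VesselLength",
    "fibroblast_count": "FibroblastCount",
    "fibroblast_shell": "FibroblastShell",
    "oxygen_initial": "OxygenInitial",
    "vegf_diffusion_substeps": "VEGFDiffusionSubsteps",
    "remove_necrotic": "RemoveNecrotic",
    "inhibition_ttl": "InhibitionTTL",
}
_KEY_TO_FIELD = {v: k for k, v in CONFIG_KEYS.items()}
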