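# Model and methods

`stromasim` is an executable, bottom-up model of a solid tumor and its
microenvironment.  Nothing about the system-level behavior is scripted:
each cell follows a small hierarchical statechart, and the phenomena the
package analyses — the necrotic core, the brush-border branching of
vessels, the angiogenic switch, the near-extinction "recovery turning
point", and the linear-to-exponential growth transition — emerge from
the interaction of those per-cell rules with four diffusing molecular
fields on a shared 3D lattice.

## World and units

Space is a bounded cubic lattice, one site = 5 μm, one cell per site;
the default world is 100×100×100 sites (a 500 μm cube).  Adjacency is
the 26-site Moore neighborhood, chosen so growth and diffusion are as
isotropic as a cubic lattice allows.  Time advances in abstract ticks;
molecular amounts are unit-less "units".  Only the 5 μm site size and
the 200 μm / 300 μm initial vessel distances are anchored to physical
length; everything else is calibrated relative, not measured.

Each tick: (1) all fields apply one diffusion kernel step (VEGF applies
several — see below); (2) every active agent acts once, in a fresh
seeded random permutation that avoids fixed-sweep lattice artifacts;
(3) metrics are appended to the time series.  A run is a pure function
of (scenario, horizon, seed).

## Molecular fields

Molecules perform an unbiased lattice random walk (stay probability
1/27, otherwise a uniform Moore step; steps off the lattice are not
taken, so the boundary reflects).  Fields store the expected occupancy
of that walk and diffusion applies its one-step transition kernel
deterministically; a discrete Monte-Carlo walker implementation of the
same process is kept solely as an independent oracle for tests.  Mass
is conserved by diffusion to float64 round-off and every field keeps a
ledger (initial + deposits − consumption − current = 0).

Species and their couplings:

| species | sources | sinks | role |
|---|---|---|---|
| oxygen  | endothelial cells (constant rate), uniform initial background | cell upkeep, division cost | survival and proliferation |
| VEGF    | hypoxic tumor cells (pulses), CAFs (∝ own deficit) | endothelial binding | angiogenic switch, sprout guidance |
| FGF     | tumor cells (constant) | none | CAF chemoattractant |
| HGF     | CAFs (constant) | none | shortens the tumor cell cycle |

VEGF applies 5 kernel steps per tick (`VEGFDiffusionSubsteps`): a small
secreted protein spreads through interstitium much faster than oxygen
is effectively transported through consuming tissue.  This relative
diffusivity decides every race in the model: the 40-site (200 μm)
transit takes roughly 480 ticks, so vessels at the standard distance
activate while crash survivors remain, whereas the 60-site (300 μm)
transit takes over a thousand — by which time a vesselless tumor's
VEGF production has died with it.

Consumption comes in two forms.  Per-tick *upkeep* draws from the
consumer's own site only — a molecule is eliminated where it meets the
cell — so surviving in place requires an actual local concentration of
order the per-tick need.  The pooled nearest-first `consume` operation
over the 27-site neighborhood is what discrete events (a division's
oxygen reserve) draw from.  A consumer is "satisfied" only when fully
granted; partial grants accumulate a deficit that resets on the first
fully granted tick.

## Tumor cells

The tumor statechart has states Normal (substates Satisfied/Starving),
Hypoxic and Necrotic.  `HypoxiaLevel` (140) consecutive deficit ticks
make a cell hypoxic: it stops proliferating and emits
`VEGFSecretionAmount` (30) units of VEGF every `VEGFPulsePeriod` (5)
ticks.  `AnoxiaLevel` (340) consecutive deficit ticks make it necrotic:
permanently inert, but left on the lattice as an obstacle
(`RemoveNecrotic` clears them instead).  A single sufficient tick
returns a hypoxic cell to normal and stops the pulses.

A normal proliferative cell divides into a uniformly random empty
neighbor every `ProliferationPeriod` (30) normoxic ticks, provided the
pooled local oxygen also covers `DivisionOxygenCost` (12 units).  The
division cost is the model's proliferation metabolism: without it, a
front of cells living on partial grants creeps outward indefinitely
and neither the growth halt nor avascular tumor death can occur; with
it, proliferation requires an actual local oxygen reserve, which the
fresh background or arriving vessels provide and a famine does not.
The division cycle halves (`HGFBoost` = 2) when local HGF exceeds a
small threshold *and* the pooled oxygen exceeds `HGFBoostMinPool`
(100): growth-factor acceleration takes metabolic headroom that only a
vascularized neighborhood provides — without that guard, CAF-derived
HGF fuels avascular front creep.  A space-blocked cell re-checks for
room every 5 ticks; an oxygen-blocked cell re-checks each tick.  Cells
move to a random empty neighbor with probability `BaseMotility` (0.1)
× (1 − local ECM density), so movement happens where CAFs have
degraded the matrix.

## Endothelial cells and vessels

Vessels are chains of endothelial cells; the default scenario places 6
straight chains of 40 quiescent cells with their closest approach
200 μm (40 sites) from the center.  Every endothelial cell, whatever
its role, secretes `OxygenSecretionAmount` (1.5) units of oxygen per
tick and binds up to `BindingCapacity` (2) units of local VEGF per
tick into a rolling window.

The angiogenic switch: a quiescent, uninhibited cell whose bound-VEGF
sum over `ActivationWindow` (90) ticks reaches
`AngiogenicSwitchThreshold` (2.4) becomes a sprout tip, and all
lattice-adjacent endothelial cells are permanently inhibited
(delta-notch lateral inhibition; `InhibitionTTL` can make it expire).
A tip elongates one site per tick toward the VEGF-richest neighbor on
ticks when it binds at least `ElongationMinVEGF` (0.02) — sprouting
continues only while enough VEGF keeps arriving.  The old tip becomes
stalk, the new cell the tip.  Running into another endothelial cell
fuses the sprouts (anastomosis) and ends elongation.  A stalk whose
bound-VEGF sum over `BranchWindow` (35) ticks reaches
`BranchThreshold` (16) spawns a second tip as a new vessel with parent
lineage; each stalk branches at most once, which keeps every branch
event a countable "vessel split" and stops a stalk sitting in dense
VEGF from branching every tick.

Newly formed cells that bind less than `EndothelialMinVEGF` (0.02) per
tick starve; after `StarvationLimit` (40) starved ticks the cell dies
together with every newly formed cell distal to it in its vessel.  A
new cell that survives `MaturationTime` (80) ticks is mature and no
longer starves.  The ordering matters: maturation must be reachable
before the VEGF silence that follows a well-fed tumor, or the entire
new vasculature dies retroactively after every rescue and no stable
vascularized state can exist.

## Fibroblasts and CAFs

700 fibroblasts are seeded uniformly in radius through a shell 16–38
sites from the center.  They consume oxygen like other cells
(`FibroblastOxygenNeed` = 1 per tick): the stroma competes for the
same supply, and this competition is load-bearing — the stromal shell
slowly wicks the central reservoir dry, which is what finally starves
the last tumor stragglers in avascular runs at around tick 900, while
a lone non-dividing cell, fresh when that famine arrives, still has
its full `AnoxiaLevel` grace period and outlives the standard
observation window.

A fibroblast currently in oxygen balance and within `CAFRadius` (9
sites) of a living tumor cell converts to a CAF with probability
`CAFBaseProb` (0.02) per tick.  CAFs secrete HGF each tick, secrete
VEGF in proportion to their own oxygen deficit (capped at the per-tick
average output of a fully hypoxic tumor cell), degrade the surrounding
ECM by `ECMDegradationRate` (0.05) per tick, and climb the FGF
gradient laid down by the tumor, which can carry them into it.

## The calibrated regime

The model's published description leaves all magnitudes unspecified,
so the shipped defaults are a calibration chosen to put the system in
the reported regime; the oxygen economy is the
load-bearing part.  The uniform background (`OxygenInitial` = 2.4 per
site) funds an avascular phase that grows a primary cluster of one to
two hundred cells in its first ~400 ticks; the cluster's collective
upkeep then outruns its drained bubble, proliferation halts (division
capital first, then upkeep), hypoxia spreads, and pulsed VEGF ramps
up.  From there the dynamics are a race between diffusion fronts:
VEGF must cover the 200 μm to the vasculature and the sprouts must
return before anoxia consumes the dormant tumor.  Under the defaults
the switch fires near tick 500, sprouts cross back within ~60 ticks,
and the survivors — often only a few dozen cells at the bottom of the
crash — regrow exponentially into a vascularized tumor of tens of
thousands of cells carried by a vessel bed of thousands to tens of
thousands of endothelial cells, with a small central necrotic core and
branching concentrated along the vessels' approach to the tumor
surface.  Remove the ability to activate, and the same calibration
runs to extinction at around tick 980; move the vessels to 300 μm and
the tumor dies before its signal can recruit them.

## Analyses

* Radial profiles anchor at the centroid of living tumor cells and
  histogram entities or field mass by Euclidean distance.
* The necrotic core is summarized as necrotic/(living+necrotic) and
  the 95th-percentile necrotic distance.
* Turning-point detection fits, for every candidate change point, a
  line (in counts) before and a line in log(count+1) after, by
  exhaustive O(n²) search; the change point stands only if the
  two-piece fit beats a single straight line by a likelihood-ratio
  margin (default 30) *and* the exponential segment's relative growth
  rate clearly exceeds the linear segment's at the junction (factor
  1.5), so halts and declines yield "no turning point".
* Fate classification: *extinct* (no living cell at the horizon),
  *developed* (a turning point exists and the final count is ≥10× the
  median pre-transition level — the median anchors the comparison to
  the avascular plateau rather than to wherever along the upswing the
  squared-error optimum happens to sit), else *arrested*.

## Problem sizes used in the shipped tests

Unit behavior runs on small worlds (≤ 40³); the scenario-level claims
run on the default 100³ world with horizons of 600–1200 ticks, sharing
one run per scenario across tests.  The robustness sweeps use a
64-cube world with vessels at 24 sites and a proportionally smaller
stroma — far enough that, as at full scale, passive oxygen from
resting vessels cannot reach the tumor within the horizon — where the
same threshold-and-delay structure appears at a fraction of the cost.

## Known limitations

* All magnitudes are relative; no quantity outside lengths maps to a
  measured biological value, and tick↔wall-time is deliberately left
  abstract.
* Oxygen stands for oxygen *and* nutrients; there is no glycolytic
  escape, no immune compartment, no lymphatics, no therapy.
* Diffusion is isotropic and unhindered by ECM or cells; vessels
  deliver oxygen per endothelial cell with no perfusion or flow model.
* The one-cell-per-site lattice caps density and makes growth
  surface-dominated once the interior is packed, so the interior of a
  well-fed tumor stays almost entirely vessel-free and branching
  statistics live on the approach side of the tumor surface.
* The distance effect (vessels at 300 μm never activating) is a
  transit-time race, not an absolute threshold: a far system observed
  for long enough after its tumor died would still never activate, but
  one whose tumor somehow survived longer would — consistent with the
  model's own robustness conclusion that any sustained VEGF source
  eventually recruits vessels.
* Synthetic scenarios start from a single transformed cell in an
  otherwise empty, uniformly oxygenated stroma — real tumor
  microenvironments are never this clean, so passing the scenario
  suite shows the mechanism set is sufficient for the listed
  phenomena, not that the calibration matches any particular tissue.
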