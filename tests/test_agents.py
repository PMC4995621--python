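"""Cell behaviors under controlled conditions: hypoxia/anoxia thresholds,
VEGF pulsing, the angiogenic switch, lateral inhibition, anastomosis,
vessel starvation, and CAF activation/chemotaxis."""

import numpy as np
import pytest

from stromasim.params import Params
from stromasim.simulation import ScenarioSpec, Simulation


def empty_sim(params=None, dims=(15, 15, 15), **scenario_kwargs):
    params = params or Params(num_vessels=0, fibroblast_count=0)
    sc = ScenarioSpec(params=params, dims=dims, initial_tumor=False, **scenario_kwargs)
    return Simulation(sc, seed=0)


def bare_params(**over):
    base = dict(num_vessels=0, fibroblast_count=0)
    base.update(over)
    return Params(**base)


class TestTumorOxygenStates:
    def test_deficit_run_reaches_hypoxia_then_anoxia_at_the_set_ticks(self):
        p = bare_params(hypoxia_level=5, anoxia_level=12, base_motility=0.0,
                        oxygen_initial=0.0)
        sim = empty_sim(p)
        cell = sim.spawn_tumor((7, 7, 7))
        for _ in range(4):
            sim.step()
        assert cell.state == "normal" and cell.deficit == 4
        sim.step()
        assert cell.state == "hypoxic" and cell.deficit == 5
        for _ in range(6):
            sim.step()
        assert cell.state == "hypoxic"
        sim.step()
        assert cell.state == "necrotic"
        assert cell.active is False

    def test_single_fed_tick_resets_the_deficit_and_recovers_hypoxia(self):
        p = bare_params(hypoxia_level=3, anoxia_level=10, base_motility=0.0,
                        oxygen_initial=0.0, proliferation_period=4)
        sim = empty_sim(p)
        cell = sim.spawn_tumor((7, 7, 7))
        for _ in range(3):
            sim.step()
        assert cell.state == "hypoxic"
        # a large local deposit gives one sufficient tick -> back to normal
        sim.fields["oxygen"].deposit((7, 7, 7), 200.0)
        sim.step()
        assert cell.state == "normal" and cell.deficit == 0
        # and with abundant oxygen the cell resumes proliferating
        before = len(sim.tumor_cells)
        for _ in range(10):
            sim.step()
        assert len(sim.tumor_cells) > before

    def test_necrotic_cell_never_acts_again(self):
        p = bare_params(hypoxia_level=2, anoxia_level=3, oxygen_initial=0.0)
        sim = empty_sim(p)
        cell = sim.spawn_tumor((7, 7, 7))
        for _ in range(3):
            sim.step()
        assert cell.state == "necrotic"
        sim.fields["oxygen"].deposit((7, 7, 7), 1000.0)
        fgf_before = sim.fields["fgf"].deposited
        for _ in range(5):
            sim.step()
        assert cell.state == "necrotic"
        assert sim.fields["fgf"].deposited == fgf_before  # no secretion while dead

    def test_hypoxic_cell_pulses_vegf_on_schedule(self):
        p = bare_params(hypoxia_level=2, anoxia_level=100, oxygen_initial=0.0,
                        vegf_pulse_period=4, vegf_secretion_amount=30.0,
                        fgf_secretion_amount=0.0)
        sim = empty_sim(p)
        sim.spawn_tumor((7, 7, 7))
        sim.step()
        sim.step()  # hypoxia begins on this tick, first pulse fires
        assert sim.fields["vegf"].deposited == pytest.approx(30.0)
        for _ in range(3 * 4 - 1):  # through 3 pulse periods in total
            sim.step()
        assert sim.fields["vegf"].deposited == pytest.approx(3 * 30.0)

    def test_no_division_when_every_neighbor_is_occupied(self):
        p = bare_params(proliferation_period=2, base_motility=0.0, oxygen_initial=5.0)
        sim = empty_sim(p)
        center = (7, 7, 7)
        cell = sim.spawn_tumor(center)
        for i, q in enumerate(sim.world.neighbors(center), start=1000):
            sim.world.place(i, q)  # inert blockers
        for _ in range(6):
            sim.step()
        assert len(sim.tumor_cells) == 1
        assert cell.state == "normal"  # blocked by space, not by oxygen


class TestEndothelialSwitch:
    def activated_setup(self, **over):
        """One EC bathed in VEGF so its window crosses the threshold."""
        p = bare_params(activation_window=5, angiogenic_switch_threshold=4.0,
                        branch_threshold=5.0, branch_window=5,
                        oxygen_secretion_amount=0.0, vegf_diffusion_substeps=1,
                        **over)
        sim = empty_sim(p)
        vessel = sim.new_vessel(parent=None)
        ec = sim.spawn_endothelial((7, 7, 7), vessel=vessel.id, newly_formed=False)
        vessel.members.append(ec.id)
        return sim, ec

    def feed(self, sim, pos, amount):
        sim.fields["vegf"].deposit(pos, amount)

    def test_window_sum_below_threshold_stays_quiescent(self):
        sim, ec = self.activated_setup()
        for _ in range(10):
            self.feed(sim, ec.pos, 0.7)  # bound 0.7/tick -> window sum 3.5 < 4
            sim.step()
        assert ec.role == "quiescent"

    def test_window_sum_reaching_threshold_activates(self):
        # a sustained local source; what the cell binds is what remains
        # after each tick's diffusion step spreads the deposit
        sim, ec = self.activated_setup()
        for _ in range(5):
            self.feed(sim, ec.pos, 30.0)
            sim.step()
        assert ec.role != "quiescent"
        assert (sim.event_log["event"] == "activation").sum() == 1

    def test_activation_inhibits_neighbors_for_good(self):
        sim, ec = self.activated_setup()
        vessel = sim.vessels[ec.vessel]
        nbr = sim.spawn_endothelial((7, 8, 7), vessel=vessel.id, newly_formed=False)
        for _ in range(40):
            self.feed(sim, ec.pos, 30.0)
            self.feed(sim, nbr.pos, 30.0)
            sim.step()
        acts = sim.event_log[sim.event_log["event"] == "activation"]
        assert len(acts) == 1  # the neighbor can never activate afterwards
        quiet = ec if ec.role == "quiescent" else nbr
        assert quiet.inhibited and quiet.role == "quiescent"

    def test_tip_elongates_up_the_vegf_gradient(self):
        p = bare_params(oxygen_secretion_amount=0.0, endothelial_min_vegf=0.0,
                        elongation_min_vegf=0.0)
        sim = empty_sim(p, dims=(21, 9, 9))
        vegf = sim.fields["vegf"]
        vegf.deposit((18, 4, 4), 3000.0)
        vegf.diffuse(10)  # a standing gradient before the sprout starts
        vessel = sim.new_vessel(parent=None)
        tip = sim.spawn_endothelial((3, 4, 4), vessel=vessel.id, newly_formed=False,
                                    tip=True)
        vessel.members.append(tip.id)
        for _ in range(12):
            vegf.deposit((18, 4, 4), 3000.0)
            sim.step()
        xs = [c.pos[0] for c in sim.ecs if c.alive]
        assert max(xs) >= 10  # the sprout marched toward the source
        assert sum(c.role == "tip" for c in sim.ecs if c.alive) == 1

    def test_two_sprouts_meeting_fuse_and_stop(self):
        p = bare_params(activation_window=5, angiogenic_switch_threshold=4.0,
                        branch_threshold=1000.0, branch_window=5,
                        oxygen_secretion_amount=0.0, endothelial_min_vegf=0.0,
                        elongation_min_vegf=0.0)
        sim = empty_sim(p, dims=(21, 9, 9))
        vegf = sim.fields["vegf"]
        vegf.deposit((10, 4, 4), 2000.0)
        vegf.diffuse(8)  # both sprouts see a ridge pointing at the middle
        va = sim.new_vessel(parent=None)
        vb = sim.new_vessel(parent=None)
        a = sim.spawn_endothelial((4, 4, 4), vessel=va.id, newly_formed=False, tip=True)
        b = sim.spawn_endothelial((16, 4, 4), vessel=vb.id, newly_formed=False, tip=True)
        va.members.append(a.id)
        vb.members.append(b.id)
        for _ in range(40):
            vegf.deposit((10, 4, 4), 2000.0)
            sim.step()
            if (sim.event_log["event"] == "anastomosis").any():
                break
        assert (sim.event_log["event"] == "anastomosis").any()
        assert sum(c.role == "tip" for c in sim.ecs if c.alive) <= 1
        joined = [v for v in sim.vessels.values() if v.joined_to is not None]
        assert joined  # the sprouts now form one connected vessel

    def test_starved_new_cells_die_with_their_distal_segment(self):
        p = bare_params(activation_window=5, angiogenic_switch_threshold=4.0,
                        branch_threshold=1000.0, branch_window=5,
                        oxygen_secretion_amount=0.0,
                        endothelial_min_vegf=0.5, starvation_limit=6,
                        maturation_time=0)
        sim = empty_sim(p, dims=(25, 9, 9))
        vessel = sim.new_vessel(parent=None)
        root = sim.spawn_endothelial((2, 4, 4), vessel=vessel.id, newly_formed=False,
                                     tip=True)
        vessel.members.append(root.id)
        # grow while VEGF is everywhere, then shut the supply off
        vegf = sim.fields["vegf"]
        for _ in range(8):
            vegf.a += 2.0
            vegf.deposited += float(2.0 * vegf.a.size)
            sim.step()
        grown = sum(1 for c in sim.ecs if c.alive)
        assert grown > 3
        vegf.consumed += vegf.total_mass  # drain the field: zero VEGF from now on
        vegf.a[:] = 0.0
        for _ in range(sim.params.starvation_limit + 3):
            sim.step()
        alive = [c for c in sim.ecs if c.alive]
        assert alive == [root]  # every newly formed cell starved and died
        # the tip kept wandering for a few ticks after the cutoff, so cells
        # born then also count among the dead
        assert (sim.event_log["event"] == "ec_death").sum() == len(sim.ecs) - 1


class TestFibroblasts:
    def test_far_from_tumor_never_activates(self):
        p = bare_params(caf_radius=3, caf_base_prob=1.0, oxygen_initial=5.0)
        sim = empty_sim(p)
        sim.spawn_tumor((2, 2, 2), proliferative=False)
        fib = sim.spawn_fibroblast((12, 12, 12))  # distance ~17 > 3
        for _ in range(10):
            sim.step()
        assert fib.caf is False

    def test_near_tumor_with_oxygen_activates(self):
        p = bare_params(caf_radius=5, caf_base_prob=1.0, oxygen_initial=5.0)
        sim = empty_sim(p)
        sim.spawn_tumor((7, 7, 7), proliferative=False)
        fib = sim.spawn_fibroblast((9, 7, 7))
        sim.step()
        assert fib.caf is True
        assert (sim.event_log["event"] == "caf_conversion").sum() == 1

    def test_caf_with_zero_deficit_secretes_no_vegf(self):
        p = bare_params(caf_radius=5, caf_base_prob=1.0, oxygen_initial=50.0,
                        fgf_secretion_amount=0.0)
        sim = empty_sim(p)
        sim.spawn_tumor((7, 7, 7), proliferative=False)
        fib = sim.spawn_fibroblast((9, 7, 7))
        for _ in range(5):
            sim.step()
        assert fib.caf is True and fib.deficit == 0
        assert sim.fields["vegf"].deposited == 0.0
        assert sim.fields["hgf"].deposited > 0.0  # HGF flows regardless

    def test_caf_climbs_an_fgf_ramp(self):
        p = bare_params(caf_base_prob=1.0, caf_radius=30, oxygen_initial=50.0,
                        ecm_degradation_rate=0.0)
        sim = empty_sim(p, dims=(30, 9, 9))
        sim.spawn_tumor((27, 4, 4), proliferative=False)
        fib = sim.spawn_fibroblast((3, 4, 4))
        ramp = np.arange(30, dtype=float)[:, None, None] * np.ones((30, 9, 9))
        sim.fields["fgf"].a += ramp
        sim.fields["fgf"].deposited += float(ramp.sum())
        start_x = fib.pos[0]
        for _ in range(50):
            sim.step()
        assert fib.pos[0] > start_x + 10  # net displacement toward the source


class TestPopulationInvariants:
    def test_occupancy_matches_cell_registry_after_many_steps(self):
        p = bare_params(proliferation_period=5, oxygen_initial=5.0)
        sim = empty_sim(p)
        sim.spawn_tumor((7, 7, 7))
        for _ in range(30):
            sim.step()
        occupied = {(int(x), int(y), int(z))
                    for x, y, z in np.argwhere(sim.world.occupancy != 0)}
        cells = {c.pos for c in sim.tumor_cells}
        assert occupied == cells
        assert len(cells) == len(sim.tumor_cells)  # one site per cell

    def test_necrotic_set_only_grows(self):
        p = bare_params(hypoxia_level=3, anoxia_level=8, proliferation_period=5,
                        oxygen_initial=1.0, division_oxygen_cost=0.0)
        sim = empty_sim(p)
        sim.spawn_tumor((7, 7, 7))
        seen = set()
        for _ in range(60):
            sim.step()
            now = {c.id for c in sim.tumor_cells if c.state == "necrotic"}
            assert seen <= now
            seen = now
        assert seen  # the starved cluster did necrose

    def test_zero_vegf_secretion_means_zero_activations(self):
        p = bare_params(vegf_secretion_amount=0.0, hypoxia_level=3, anoxia_level=300,
                        proliferation_period=10, oxygen_initial=1.0,
                        num_vessels=2, vessel_length=5, initial_vessel_distance=5)
        sc = ScenarioSpec(params=p, dims=(15, 15, 15))
        sim = Simulation(sc, seed=0)
        for _ in range(80):
            sim.step()
        assert (sim.event_log["event"] == "activation").sum() == 0
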