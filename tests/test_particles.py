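"""Brownian-dynamics engine: step rules, neighbour search, convergence."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from mesopolar import particles, scenarios
from mesopolar.model import (
    Compartment,
    ModelSpec,
    RateClass,
    SpeciesSpec,
    UnimolecularReaction,
)
from mesopolar.particles import (
    ParticleState,
    attempt_bimolecular,
    attempt_unimolecular,
    brownian_step,
    dissociate_place,
    neighbor_pairs,
)


def two_state_model(k_on=4.0, k_off=6.5):
    """Cytosol <-> membrane shuttling of a single species pair."""
    return ModelSpec(
        species=(
            SpeciesSpec("X_c", Compartment.CYTOSOL, 10.0, {"x": 1}),
            SpeciesSpec("X_m", Compartment.MEMBRANE, 0.0045, {"x": 1}),
        ),
        unimolecular=(
            UnimolecularReaction(
                "on", "X_c", ("X_m",), k_on, RateClass.CYTO_TO_MEM_FIRST_ORDER
            ),
            UnimolecularReaction(
                "off", "X_m", ("X_c",), k_off, RateClass.MEM_TO_CYTO_FIRST_ORDER
            ),
        ),
        initial_counts={"X_c": 200, "X_m": 0},
    )


class TestBrownianStep:
    def test_zero_diffusion_is_static(self, rng):
        pos = rng.random((50, 2))
        out = brownian_step(pos, 0.0, 1e-3, 1.0, rng)
        np.testing.assert_array_equal(out, pos)

    def test_free_msd(self, rng):
        """Ensemble MSD of free molecules equals 4 D t (3 SE)."""
        D, dt, nsteps, n = 0.5, 1e-3, 200, 4000
        L = 1e6  # effectively unbounded
        pos = np.full((n, 2), L / 2)
        start = pos.copy()
        for _ in range(nsteps):
            pos = brownian_step(pos, D, dt, L, rng)
        sq = ((pos - start) ** 2).sum(axis=1)
        se = sq.std() / math.sqrt(n)
        assert abs(sq.mean() - 4 * D * dt * nsteps) < 3 * se

    def test_cytosolic_species_decorrelates_across_box(self, rng):
        """D_cyto = 10 um^2/s mixes an 8 um box within seconds: positions
        started at a point become uniform (KS on each axis)."""
        L, D, dt = 8.0, 10.0, 0.01
        pos = np.full((800, 2), 1.23)
        for _ in range(int(2.0 / dt)):
            pos = brownian_step(pos, D, dt, L, rng)
        for ax in range(2):
            assert stats.kstest(pos[:, ax] / L, "uniform").pvalue > 1e-3


class TestUnimolecular:
    def test_zero_rate_never_fires(self, rng):
        model = two_state_model(k_on=0.0, k_off=0.0)
        state = ParticleState(
            positions=rng.random((20, 2)),
            species=np.zeros(20, dtype=int),
            species_names=("X_c", "X_m"),
            L=1.0,
        )
        out = attempt_unimolecular(state, model, 1.0, rng)
        np.testing.assert_array_equal(out.species, state.species)

    def test_exponential_lifetimes(self, rng):
        """Decay times of a first-order reaction follow Exp(k) (KS test)."""
        k, dt = 5.0, 2e-3
        model = ModelSpec(
            species=(
                SpeciesSpec("C", Compartment.MEMBRANE, 0.01),
                SpeciesSpec("X", Compartment.MEMBRANE, 0.01),
            ),
            unimolecular=(
                UnimolecularReaction(
                    "decay", "C", ("X",), k, RateClass.MEM_FIRST_ORDER
                ),
            ),
        )
        n = 600
        state = ParticleState(
            positions=rng.random((n, 2)),
            species=np.zeros(n, dtype=int),
            species_names=("C", "X"),
            L=1.0,
        )
        lifetimes = np.full(n, np.nan)
        for step in range(1, 4000):
            state = attempt_unimolecular(state, model, dt, rng)
            decayed = (state.species == 1) & np.isnan(lifetimes)
            lifetimes[decayed] = step * dt
            if not np.isnan(lifetimes).any():
                break
        assert not np.isnan(lifetimes).any()
        assert stats.kstest(lifetimes, "expon", args=(0, 1 / k)).pvalue > 1e-3

    def test_membrane_fraction_two_state(self):
        """X_c <-> X_m at 4 / 6.5 s^-1 settles at the closed-form membrane
        fraction 4/(4+6.5)."""
        model = two_state_model()
        cfg = particles.PbConfig(
            L=2.0, dt=1e-3, t_end=30.0, record_interval=0.1, seed=8,
            record_positions=False,
        )
        traj = particles.run(model, cfg)
        sel = traj.times >= 5.0
        frac = traj.totals[sel, 1] / traj.totals[sel].sum(axis=1)
        expected = 4.0 / 10.5
        assert abs(frac.mean() - expected) < 0.01


class TestDissociatePlace:
    def test_exact_separation_and_uniform_direction(self, rng):
        rho, eps, L = 0.02, 1e-4, 1.0
        origin = np.array([0.01, 0.99])  # near the corner: wrap matters
        angles = []
        for _ in range(500):
            p0, p1 = dissociate_place(origin, rho, eps, rng, L)
            np.testing.assert_array_equal(p0, origin)
            d = particles.min_image(p1 - p0, L)
            assert np.hypot(*d) == pytest.approx(rho + eps, rel=1e-12)
            assert np.hypot(*d) > rho  # not reaction-eligible
            angles.append(math.atan2(d[1], d[0]))
        # Rayleigh test: mean resultant length ~ sqrt(chi2_2/(2n)) under H0
        c = np.mean(np.cos(angles))
        s = np.mean(np.sin(angles))
        r2 = c * c + s * s
        assert 2 * len(angles) * r2 < stats.chi2.ppf(0.999, 2)


class TestNeighborSearch:
    @pytest.mark.parametrize("cutoff", [0.02, 0.07, 0.2, 0.45])
    def test_cell_list_equals_bruteforce(self, rng, cutoff):
        pts = rng.random((300, 2))
        a = neighbor_pairs(pts, cutoff, 1.0, method="cell")
        b = neighbor_pairs(pts, cutoff, 1.0, method="brute")
        np.testing.assert_array_equal(a, b)

    def test_periodic_pairs_found(self):
        pts = np.array([[0.001, 0.5], [0.999, 0.5]])
        pairs = neighbor_pairs(pts, 0.01, 1.0)
        assert pairs.tolist() == [[0, 1]]


class TestBimolecular:
    def _pair_state(self, dist):
        return ParticleState(
            positions=np.array([[0.5, 0.5], [0.5 + dist, 0.5]]),
            species=np.array([0, 1]),
            species_names=("A", "B", "C"),
            L=1.0,
        )

    def test_zero_lambda_never_reacts(self, rng):
        model = scenarios.association_model(1, lambda_rate=0.0)
        out = attempt_bimolecular(self._pair_state(0.001), model, 1.0, rng)
        assert len(out.species) == 2

    def test_static_pair_geometric_survival(self, rng):
        """A pair held within rho survives k steps with prob (e^-lambda dt)^k."""
        model = scenarios.association_model(1, D=1e-12)
        lam = 3183.1
        dt = 1e-5
        k_steps = 20
        survived = 0
        n = 400
        for _ in range(n):
            state = self._pair_state(0.004)
            for _ in range(k_steps):
                state = attempt_bimolecular(state, model, dt, rng)
                if len(state.species) == 1:
                    break
            else:
                survived += 1
        p_surv = math.exp(-lam * dt) ** k_steps
        se = math.sqrt(p_surv * (1 - p_surv) / n)
        assert abs(survived / n - p_surv) < 4 * se

    def test_out_of_range_pair_never_reacts(self, rng):
        model = scenarios.association_model(1)
        out = attempt_bimolecular(self._pair_state(0.0051), model, 1.0, rng)
        assert len(out.species) == 2


class TestRunProperties:
    def test_conservation_of_composition_totals(self):
        model = scenarios.association_model(30, k_micro_d=10.0)
        cfg = particles.PbConfig(
            L=0.4, dt=particles.benchmark_dt(0.005, 0.005), t_end=0.5,
            record_interval=0.05, seed=4, record_positions=False,
        )
        traj = particles.run(model, cfg)
        for unit, vec in model.conservation_vectors().items():
            totals = traj.totals @ vec
            assert (totals == totals[0]).all()

    def test_determinism_and_seed_sensitivity(self):
        model = scenarios.association_model(30)
        cfg = particles.PbConfig(
            L=0.4, dt=particles.benchmark_dt(0.005, 0.005), t_end=0.5,
            record_interval=0.05, seed=4,
        )
        a = particles.run(model, cfg)
        b = particles.run(model, cfg)
        np.testing.assert_array_equal(a.totals, b.totals)
        np.testing.assert_array_equal(a.positions[-1], b.positions[-1])
        c = particles.run(model, dataclasses.replace(cfg, seed=5))
        assert not np.array_equal(a.totals, c.totals)

    def test_dt_convergence(self):
        """Halving dt changes the benchmark mean curve by less than the
        Monte-Carlo error."""
        model = scenarios.association_model(40)
        L = 0.4
        dt = particles.benchmark_dt(0.005, 0.005)
        means = {}
        ses = {}
        for key, step in (("dt", dt), ("dt/2", dt / 2)):
            cfg = particles.PbConfig(
                L=L, dt=step, t_end=0.6, record_interval=0.15, seed=0,
                record_positions=False,
            )
            ens = scenarios.ensemble_totals(
                model, cfg, 16, seed=31 if key == "dt" else 32,
                engine="particle",
            )
            means[key], _ = ens.series("A")
            ses[key] = ens.sem[:, 0]
        diff = np.abs(means["dt"][1:] - means["dt/2"][1:])
        bound = 3 * np.hypot(ses["dt"][1:], ses["dt/2"][1:])
        assert (diff <= bound).all()

    def test_well_mixed_cme_oracle_reversible(self):
        """Fast-diffusing, reaction-limited A+B<->C with 2 pairs matches the
        exact stationary mean of the well-mixed chemical master equation."""
        rho, lam, kd, L, D = 0.05, 20.0, 1.0, 0.5, 5.0
        model = scenarios.association_model(
            2, k_micro_d=kd, lambda_rate=lam, rho=rho, D=D
        )
        k_macro = lam * math.pi * rho**2
        # birth-death chain on c = 0, 1, 2
        up = [k_macro * (2 - c) ** 2 / L**2 for c in (0, 1)]
        down = [kd * c for c in (1, 2)]
        pi = np.array([1.0, up[0] / down[0], up[0] * up[1] / (down[0] * down[1])])
        pi /= pi.sum()
        expected = float(pi @ np.arange(3))
        vals = []
        n_rep = 8
        for s in scenarios.child_seeds(55, n_rep):
            cfg = particles.PbConfig(
                L=L, dt=2e-5, t_end=24.0, record_interval=0.05, seed=s,
                record_positions=False,
            )
            traj = particles.run(model, cfg)
            vals.append(traj.totals[traj.times >= 4.0, 2].mean())
        se = np.std(vals) / math.sqrt(n_rep)
        assert abs(np.mean(vals) - expected) < 3 * se
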