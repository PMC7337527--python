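"""Free-energy machinery: CV gradients, Langevin sampling, meta-eABF,
PMF estimators, convergence and profile annotation.

Oracles: central finite differences for the CV gradient, the harmonic
equipartition closed form, the exact stationary distribution of the
extended harmonic system for CZAR, and hand-constructed profiles.
"""

import numpy as np
import pytest
from scipy import stats

from aptadyn.free_energy import (BiasState, FreeEnergyConfig, FreeEnergyProfile,
                                 LangevinState, annotate_profile, com_separation,
                                 convergence_report, double_well_validation_config,
                                 estimate_pmf, langevin_step, run_langevin,
                                 run_meta_eabf)
from aptadyn.model import AtomRecord, Frame, Topology
from aptadyn.synthetic import ToyPotentialSpec, make_toy_potential
from aptadyn.units import KBOLTZ


@pytest.fixture(scope="module")
def double_well():
    return make_toy_potential(ToyPotentialSpec(
        "double_well", {"barrier": 3.0, "half_separation": 2.0}))


@pytest.fixture(scope="module")
def eabf_run(double_well):
    """A medium-length meta-eABF run shared by estimator tests."""
    cfg = double_well_validation_config(seed=5, n_steps=400_000,
                                        checkpoints=(100_000, 200_000, 300_000))
    return cfg, run_meta_eabf(double_well.potential, double_well.gradient, cfg)


class TestComSeparation:
    def _two_atom_top(self):
        atoms = [AtomRecord(1, "C1", "C", "TOY", 1),
                 AtomRecord(2, "N1", "N", "TOY", 2)]
        return Topology(atoms, groups={"a": [0], "b": [1]})

    def test_two_single_atoms(self):
        top = self._two_atom_top()
        frame = Frame(np.array([[0.0, 0, 0], [12.0, 0, 0]]))
        xi, grad = com_separation(frame, top, [0], [1])
        assert xi == pytest.approx(12.0)
        # group a sits at the origin: moving it toward b shrinks ξ
        np.testing.assert_allclose(grad[0], [-1.0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(grad[1], [1.0, 0, 0], atol=1e-12)

    def test_coincident_groups_zero(self):
        top = self._two_atom_top()
        frame = Frame(np.zeros((2, 3)))
        xi, grad = com_separation(frame, top, [0], [1])
        assert xi == 0.0

    def test_gradient_matches_finite_differences(self, wt_small):
        top = wt_small.topology
        frame = wt_small.trajectory.frames[0]
        a = top.groups["ligand"]
        b = top.residue_atoms(22)
        xi, grad = com_separation(frame, top, a, b)
        rng = np.random.default_rng(2)
        h = 1e-5
        for atom in list(rng.choice(a, 2)) + list(rng.choice(b, 2)):
            for dim in range(3):
                plus = frame.coordinates.copy()
                plus[atom, dim] += h
                minus = frame.coordinates.copy()
                minus[atom, dim] -= h
                fd = (com_separation(Frame(plus), top, a, b)[0]
                      - com_separation(Frame(minus), top, a, b)[0]) / (2 * h)
                assert grad[atom, dim] == pytest.approx(fd, abs=1e-6)


class TestLangevin:
    def test_ballistic_limit(self):
        state = LangevinState(x=[0.0], v=[2.0])
        for _ in range(10):
            state = langevin_step(state, lambda x: np.zeros_like(x),
                                  dt=0.1, friction=0.0, temperature=0.0,
                                  rng=np.random.default_rng(0))
        assert state.x[0] == pytest.approx(2.0)  # uniform motion x = v·t
        assert state.v[0] == pytest.approx(2.0)

    def test_determinism_under_fixed_seed(self):
        def run(seed):
            rng = np.random.default_rng(seed)
            state = LangevinState(x=np.zeros(4), v=np.zeros(4))
            for _ in range(50):
                state = langevin_step(state, lambda x: -2.0 * x, dt=0.01,
                                      friction=1.0, temperature=298.0, rng=rng)
            return state.x
        np.testing.assert_array_equal(run(3), run(3))
        assert not np.array_equal(run(3), run(4))

    def test_harmonic_equipartition(self):
        """Long harmonic sampling: Var(x) = k_B·T/k within 5%."""
        k = 2.0
        samples = run_langevin(lambda x: k * x, n_steps=30_000, dt=0.02,
                               friction=1.0, temperature=298.0, seed=12,
                               n_walkers=128, sample_stride=50, burn_in=2000)
        expected = KBOLTZ * 298.0 / k
        assert np.var(samples) == pytest.approx(expected, rel=0.05)

    def test_nonfinite_force_rejected(self):
        state = LangevinState(x=[0.0], v=[0.0])
        with pytest.raises(FloatingPointError):
            langevin_step(state, lambda x: np.full_like(x, np.nan), dt=0.01,
                          friction=1.0, temperature=298.0,
                          rng=np.random.default_rng(0))


class TestBoltzmannSampling:
    def test_unbiased_histogram_matches_boltzmann(self):
        """χ² test of unbiased harmonic sampling vs the Boltzmann density."""
        kT = KBOLTZ * 298.0
        k = 2.0
        samples = run_langevin(lambda x: k * x, n_steps=34_000, dt=0.02,
                               friction=1.0, temperature=298.0, seed=0,
                               n_walkers=1400, sample_stride=400, burn_in=4000)
        assert samples.size >= 1e5
        sigma = np.sqrt(kT / k)
        edges = np.linspace(-4 * sigma, 4 * sigma, 26)
        obs, _ = np.histogram(samples, bins=edges)
        p_bins = np.diff(stats.norm.cdf(edges, scale=sigma))
        p_bins /= p_bins.sum()
        _, p_value = stats.chisquare(obs, p_bins * obs.sum())
        assert p_value > 0.01


class TestMetaEabf:
    def test_flat_potential_gives_flat_pmf(self):
        cfg = FreeEnergyConfig(xi_min=-3.0, xi_max=3.0, n_steps=500_000,
                               seed=2, x0=0.0, dt=0.02, friction=1.0,
                               coupling_k=150.0)
        res = run_meta_eabf(lambda x: 0.0, lambda x: 0.0, cfg)
        for method in ("czar", "naive"):
            prof = estimate_pmf(res.bias, method)
            inner = np.abs(prof.bin_centers) <= 2.0
            spread = prof.values[inner & prof.sampled]
            assert spread.max() - spread.min() < 0.4

    def test_determinism_and_hill_count(self, double_well):
        cfg = double_well_validation_config(seed=9, n_steps=20_000)
        r1 = run_meta_eabf(double_well.potential, double_well.gradient, cfg)
        r2 = run_meta_eabf(double_well.potential, double_well.gradient, cfg)
        assert len(r1.bias.hills) == cfg.n_steps // cfg.hill_period
        np.testing.assert_array_equal(r1.bias.lambda_counts, r2.bias.lambda_counts)
        np.testing.assert_array_equal(r1.xi_series, r2.xi_series)
        assert r1.bias.hills == r2.bias.hills

    def test_start_outside_range_rejected(self, double_well):
        with pytest.raises(ValueError):
            cfg = double_well_validation_config(seed=0, n_steps=100, x0=9.0)
            run_meta_eabf(double_well.potential, double_well.gradient, cfg)

    def test_double_well_barrier_recovered(self, double_well, eabf_run):
        cfg, res = eabf_run
        prof = estimate_pmf(res.bias, "czar")
        win = np.abs(prof.bin_centers) <= 3.5
        v = prof.values[win] - prof.values[win].min()
        ref = double_well.analytic_pmf(prof.bin_centers[win])
        rms = np.sqrt(np.mean((v - (ref - ref.min())) ** 2))
        assert rms < 0.35    # medium-length run; the long run is tighter
        barrier = v[np.abs(prof.bin_centers[win]) < 0.3].max() - v.min()
        assert barrier == pytest.approx(3.0, rel=0.2)


class TestEstimators:
    def test_czar_recovers_harmonic_pmf_from_exact_stationary_samples(self):
        """ρ(ξ, λ) ∝ exp(−β[κξ²/2 + k(ξ−λ)²/2]): ξ ~ N(0, kT/κ) and
        λ|ξ ~ N(ξ, kT/k).  CZAR must recover κξ²/2 to discretization error."""
        kappa = 1.0
        cfg = FreeEnergyConfig(xi_min=-2.0, xi_max=2.0, n_steps=1,
                               coupling_k=150.0)
        kT = KBOLTZ * cfg.temperature
        rng = np.random.default_rng(21)
        xi = rng.normal(0.0, np.sqrt(kT / kappa), 2_000_000)
        lam = xi + rng.normal(0.0, np.sqrt(kT / cfg.coupling_k), xi.size)
        state = BiasState.from_samples(xi, lam, cfg)
        prof = estimate_pmf(state, "czar")
        keep = prof.sampled & (np.abs(prof.bin_centers) <= 1.5)
        ref = 0.5 * kappa * prof.bin_centers ** 2
        err = prof.values[keep] - (ref[keep] - ref[keep].min())
        assert np.sqrt(np.mean(err ** 2)) < 0.05

    def test_single_bin_sampling_gives_zero_profile(self):
        cfg = FreeEnergyConfig(xi_min=0.0, xi_max=0.1, n_steps=1)
        state = BiasState.from_samples(np.full(10, 0.05), np.full(10, 0.05), cfg)
        prof = estimate_pmf(state, "czar")
        assert prof.values.shape == (1,)
        assert prof.values[0] == 0.0

    def test_czar_and_naive_agree_on_long_run(self, eabf_run):
        """Consistency over the thermally meaningful range (|A| ≲ 12 k_BT);
        binned mean-force estimators are expected to diverge only in the
        steep wall wings where the within-bin force variation exceeds k_BT."""
        cfg, res = eabf_run
        czar = estimate_pmf(res.bias, "czar")
        naive = estimate_pmf(res.bias, "naive")
        both = czar.sampled & naive.sampled & (np.abs(czar.bin_centers) <= 3.2)
        d = czar.values[both] - naive.values[both]
        d -= d.mean()   # estimators are each anchored at their own minimum
        assert np.sqrt(np.mean(d ** 2)) < 0.2

    def test_hills_only_estimator_uses_deposited_hills(self, eabf_run):
        cfg, res = eabf_run
        prof = estimate_pmf(res.bias, "hills_only")
        assert prof.values.min() == 0.0
        assert np.all(np.isfinite(prof.values))

    def test_empty_state_rejected(self):
        cfg = FreeEnergyConfig(xi_min=0.0, xi_max=1.0, n_steps=1)
        with pytest.raises(ValueError):
            estimate_pmf(BiasState.empty(cfg), "czar")


class TestConvergence:
    def _profile(self, values, centers=None):
        values = np.asarray(values, float)
        if centers is None:
            centers = np.arange(values.size) * 0.1
        return FreeEnergyProfile(centers, values, np.ones(values.size, bool))

    def test_identical_profiles_converge_immediately(self):
        p = self._profile(np.linspace(0, 5, 50))
        rep = convergence_report([p, p, p], tolerance=0.05)
        assert rep["converged_at"] == 0
        assert np.all(rep["rms_matrix"] == 0.0)

    def test_one_bin_difference_rms_arithmetic(self):
        a = np.zeros(100)
        b = np.zeros(100)
        b[40] = 1.0
        rep = convergence_report([self._profile(a), self._profile(b)],
                                 tolerance=0.05)
        assert rep["rms_to_final"][0] == pytest.approx(0.1)  # sqrt(1/100)
        assert rep["converged_at"] != 0

    def test_monotone_settling_sequence(self):
        final = np.linspace(0, 3, 40)
        profiles = [self._profile(final + off) for off in (2.0, 0.6, 0.03, 0.0)]
        rep = convergence_report(profiles, tolerance=0.05)
        assert rep["converged_at"] == 2

    def test_mismatched_bins_rejected(self):
        a = self._profile(np.zeros(10))
        b = self._profile(np.zeros(12))
        with pytest.raises(ValueError):
            convergence_report([a, b])


class TestAnnotation:
    def test_v_shaped_profile(self):
        centers = np.arange(2.0, 20.0, 0.1)
        vals = np.where(centers < 4.0, (4.0 - centers) * 3.0,
                        np.minimum((centers - 4.0) * (5.0 / 11.0), 5.0))
        prof = FreeEnergyProfile(centers, vals, np.ones(centers.size, bool))
        ann = annotate_profile(prof, (3.0, 6.0), (16.0, 19.0))
        assert ann.annotations["delta_g"] == pytest.approx(5.0, abs=0.01)
        assert ann.annotations["barrier_height"] == pytest.approx(5.0, abs=0.01)

    def test_interior_peak_profile(self):
        centers = np.arange(0.0, 30.0, 0.1)
        vals = np.interp(centers, [0, 4, 12, 15, 30], [6, 0, 7, 5, 5])
        prof = FreeEnergyProfile(centers, vals, np.ones(centers.size, bool))
        ann = annotate_profile(prof, (2.0, 6.0), (20.0, 28.0))
        assert ann.annotations["barrier_height"] == pytest.approx(7.0, abs=1e-9)
        assert ann.annotations["delta_g"] == pytest.approx(5.0, abs=1e-9)
        assert ann.annotations["delta_g_bind"] == pytest.approx(-5.0, abs=1e-9)
        assert ann.annotations["barrier_xi"] == pytest.approx(12.0, abs=0.05)

    def test_flat_profile(self):
        centers = np.arange(0.0, 10.0, 0.1)
        prof = FreeEnergyProfile(centers, np.zeros(centers.size),
                                 np.ones(centers.size, bool))
        ann = annotate_profile(prof, (0.0, 2.0), (8.0, 10.0))
        assert ann.annotations["delta_g"] == 0.0
        assert ann.annotations["barrier_height"] == 0.0

    def test_unsampled_region_rejected(self):
        centers = np.arange(0.0, 10.0, 0.1)
        sampled = centers < 5.0
        prof = FreeEnergyProfile(centers, np.zeros(centers.size), sampled)
        with pytest.raises(ValueError):
            annotate_profile(prof, (0.0, 2.0), (8.0, 10.0))
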