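"""Meta-eABF free-energy machinery on a one-dimensional collective variable.

The collective variable (CV) ξ is the mass-weighted center-of-mass
separation of two atom groups (:func:`com_separation`).  The sampling
engine itself runs on one-dimensional model systems: a Langevin particle
moving in a potential U(ξ), harmonically coupled to a fictitious extended
variable λ.  Two biases act on λ:

* adaptive biasing force (ABF): the running mean of the instantaneous
  free-energy-gradient estimate k(λ − ξ) is accrued per λ-bin and applied
  back (linearly ramped over ``n_full`` samples per bin) so that the mean
  force on λ vanishes and λ diffuses;
* metadynamics: Gaussian hills are deposited on λ at a fixed period,
  accelerating the escape from visited regions.

The unbiased potential of mean force is reconstructed either by the CZAR
estimator,

    A'(ξ) = −k_B·T · d/dξ ln ρ̃(ξ) + k·(⟨λ⟩_ξ − ξ),

where ρ̃ is the biased ξ histogram, or naively by integrating the per-bin
mean of k(λ − ξ), or from the negated metadynamics hill sum.  Profiles are
trapezoid-integrated on the bin grid and anchored so the sampled minimum
is zero.

Units: lengths Å, energies kcal/mol, k_B = 0.0019872041 kcal/mol/K.  The
toy dynamics use reduced masses (no kcal→amu·Å/ps² conversion), so the
timestep and friction are in matching reduced time units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .model import Frame, Topology
from .units import KBOLTZ, kj_to_kcal

__all__ = [
    "FreeEnergyConfig", "BiasState", "FreeEnergyProfile", "LangevinState",
    "com_separation", "langevin_step", "run_langevin", "run_meta_eabf",
    "estimate_pmf", "convergence_report", "annotate_profile",
]

#: Default metadynamics hill height: 0.1 kJ/mol expressed in kcal/mol.
DEFAULT_HILL_HEIGHT = kj_to_kcal(0.1)


def double_well_validation_config(seed: int = 0, n_steps: int = 1_000_000,
                                  **overrides) -> "FreeEnergyConfig":
    """Reference meta-eABF settings for the double-well estimator validation.

    The CV range extends 1 Å beyond the analysis window on each side so
    that reflecting-wall artifacts stay outside the compared region, the
    extended spring is soft (150 kcal/mol/Å²; the CZAR correction absorbs
    the softness while the noise of the k(λ−ξ) term scales like √k), and
    the timestep is the largest that keeps the coupled oscillation well
    resolved (ω·dt ≈ 0.25).
    """
    kw = dict(xi_min=-4.5, xi_max=4.5, n_steps=n_steps, seed=seed,
              x0=-2.0, dt=0.02, friction=1.0, coupling_k=150.0)
    kw.update(overrides)
    return FreeEnergyConfig(**kw)


# ------------------------------------------------------------------ CV

def com_separation(frame: Frame, topology: Topology,
                   group_a: Sequence[int], group_b: Sequence[int]
                   ) -> tuple[float, np.ndarray]:
    """Mass-weighted COM distance of two groups and its coordinate gradient.

    Returns (ξ in Å, N×3 gradient ∂ξ/∂r).  The gradient of atoms outside
    the two groups is zero.  ξ = 0 (coincident COMs) leaves the gradient
    undefined and returns zeros there.
    """
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ma = topology.masses(a)
    mb = topology.masses(b)
    if ma.sum() <= 0 or mb.sum() <= 0:
        raise ValueError("zero total mass in a CV group")
    ra = (ma[:, None] * frame.coordinates[a]).sum(axis=0) / ma.sum()
    rb = (mb[:, None] * frame.coordinates[b]).sum(axis=0) / mb.sum()
    diff = ra - rb
    xi = float(np.linalg.norm(diff))
    grad = np.zeros_like(frame.coordinates)
    if xi > 0:
        u = diff / xi
        grad[a] = (ma / ma.sum())[:, None] * u
        grad[b] = -(mb / mb.sum())[:, None] * u
    return xi, grad


# ------------------------------------------------------------ Langevin

@dataclass
class LangevinState:
    """Positions/velocities of one or many independent 1-D walkers."""

    x: np.ndarray
    v: np.ndarray
    mass: float = 1.0

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.v = np.atleast_1d(np.asarray(self.v, dtype=float))
        if self.x.shape != self.v.shape:
            raise ValueError("x and v must have the same shape")


def langevin_step(state: LangevinState, force_field: Callable[[np.ndarray], np.ndarray],
                  dt: float, friction: float, temperature: float,
                  rng: np.random.Generator) -> LangevinState:
    """One BAOAB Langevin update; deterministic given the generator state.

    *force_field* maps positions to forces (−dU/dx).  friction = 0 and
    temperature = 0 reduce to velocity-Verlet ballistic motion.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x, v, m = state.x.copy(), state.v.copy(), state.mass
    f = np.asarray(force_field(x), dtype=float)
    if not np.all(np.isfinite(f)):
        raise FloatingPointError("non-finite force")
    v = v + 0.5 * dt * f / m                     # B
    x = x + 0.5 * dt * v                         # A
    c1 = math.exp(-friction * dt)
    c2 = math.sqrt(KBOLTZ * temperature * (1.0 - c1 * c1) / m)
    v = c1 * v + c2 * rng.standard_normal(v.shape)   # O
    x = x + 0.5 * dt * v                         # A
    f = np.asarray(force_field(x), dtype=float)
    if not np.all(np.isfinite(f)):
        raise FloatingPointError("non-finite force")
    v = v + 0.5 * dt * f / m                     # B
    return LangevinState(x=x, v=v, mass=m)


def run_langevin(potential_gradient: Callable[[np.ndarray], np.ndarray],
                 n_steps: int, dt: float, friction: float, temperature: float,
                 seed: int, n_walkers: int = 1, x0: float | np.ndarray = 0.0,
                 mass: float = 1.0, sample_stride: int = 1,
                 burn_in: int = 0) -> np.ndarray:
    """Unbiased ensemble Langevin sampling; returns flattened position samples."""
    rng = np.random.default_rng(seed)
    x = np.full(n_walkers, x0, dtype=float) if np.isscalar(x0) else np.asarray(x0, float)
    state = LangevinState(x=x, v=np.zeros_like(x), mass=mass)
    force = lambda xx: -potential_gradient(xx)
    samples = []
    for step in range(n_steps):
        state = langevin_step(state, force, dt, friction, temperature, rng)
        if step >= burn_in and (step - burn_in) % sample_stride == 0:
            samples.append(state.x.copy())
    return np.concatenate(samples) if samples else np.empty(0)


# ------------------------------------------------------- configuration

@dataclass
class FreeEnergyConfig:
    """Parameters of one meta-eABF run on a 1-D CV.

    The extended coupling defaults to the stiff-spring regime
    (k·bin_width² ≈ 10 k_B·T) and the extended mass to a λ oscillation
    period of ≈ 50 timesteps; both may be overridden.
    """

    xi_min: float
    xi_max: float
    n_steps: int
    bin_width: float = 0.1            # Å
    hill_height: float = DEFAULT_HILL_HEIGHT   # kcal/mol (0.1 kJ/mol)
    hill_width: float = 1.2           # Å
    hill_period: int = 500            # steps between depositions
    coupling_k: float | None = None   # kcal/mol/Å²
    ext_mass: float | None = None     # reduced units
    temperature: float = 298.0        # K
    friction: float = 1.0             # 1/time (reduced)
    dt: float = 0.002                 # reduced time
    seed: int = 0
    n_full: int = 200                 # ABF ramp: samples/bin for full bias
    mass: float = 1.0                 # physical-particle reduced mass
    x0: float | None = None
    use_abf: bool = True
    use_metadynamics: bool = True
    record_stride: int = 10
    checkpoints: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.xi_max <= self.xi_min:
            raise ValueError("xi_max must exceed xi_min")
        if self.bin_width <= 0 or self.hill_width <= 0:
            raise ValueError("bin and hill widths must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.coupling_k is None:
            self.coupling_k = 10.0 * KBOLTZ * self.temperature / self.bin_width ** 2
        if self.ext_mass is None:
            # λ oscillation period ≈ 50 dt: m = k (period/2π)²
            self.ext_mass = self.coupling_k * (50.0 * self.dt / (2.0 * math.pi)) ** 2

    @property
    def n_bins(self) -> int:
        return max(1, int(round((self.xi_max - self.xi_min) / self.bin_width)))

    @property
    def bin_centers(self) -> np.ndarray:
        edges = self.xi_min + self.bin_width * np.arange(self.n_bins + 1)
        return 0.5 * (edges[:-1] + edges[1:])


@dataclass
class BiasState:
    """Accumulated eABF/metadynamics state of one run (or checkpoint)."""

    config: FreeEnergyConfig
    lambda_counts: np.ndarray          # samples per λ-bin
    grad_sum: np.ndarray               # Σ k(λ − ξ) per λ-bin (A' estimate)
    xi_counts: np.ndarray              # samples per ξ-bin (CZAR histogram)
    xi_dev_sum: np.ndarray             # Σ (λ − ξ) per ξ-bin (CZAR correction)
    hills: list[tuple[int, float, float, float]] = field(default_factory=list)
    step: int = 0

    @classmethod
    def empty(cls, config: FreeEnergyConfig) -> "BiasState":
        n = config.n_bins
        return cls(config=config,
                   lambda_counts=np.zeros(n), grad_sum=np.zeros(n),
                   xi_counts=np.zeros(n), xi_dev_sum=np.zeros(n))

    @classmethod
    def from_samples(cls, xi_samples: np.ndarray, lambda_samples: np.ndarray,
                     config: FreeEnergyConfig) -> "BiasState":
        """Build estimator state directly from (ξ, λ) sample pairs.

        Used when the joint distribution is available analytically, e.g.
        validating CZAR against a closed-form stationary distribution.
        """
        xi = np.asarray(xi_samples, float)
        lam = np.asarray(lambda_samples, float)
        if xi.shape != lam.shape:
            raise ValueError("xi and lambda sample arrays must align")
        state = cls.empty(config)
        k = config.coupling_k
        lo, w, n = config.xi_min, config.bin_width, config.n_bins
        bl = np.clip(((lam - lo) / w).astype(int), 0, n - 1)
        bx = np.clip(((xi - lo) / w).astype(int), 0, n - 1)
        np.add.at(state.lambda_counts, bl, 1.0)
        np.add.at(state.grad_sum, bl, k * (lam - xi))
        np.add.at(state.xi_counts, bx, 1.0)
        np.add.at(state.xi_dev_sum, bx, lam - xi)
        state.step = xi.size
        return state

    def snapshot(self) -> "BiasState":
        return BiasState(config=self.config,
                         lambda_counts=self.lambda_counts.copy(),
                         grad_sum=self.grad_sum.copy(),
                         xi_counts=self.xi_counts.copy(),
                         xi_dev_sum=self.xi_dev_sum.copy(),
                         hills=list(self.hills), step=self.step)


@dataclass
class MetaEABFResult:
    """Final bias state, checkpoint history and recorded (ξ, λ) series."""

    bias: BiasState
    checkpoints: list[BiasState]
    xi_series: np.ndarray
    lambda_series: np.ndarray


# ------------------------------------------------------------ sampling

def run_meta_eabf(potential: Callable[[float], float],
                  gradient: Callable[[float], float],
                  config: FreeEnergyConfig) -> MetaEABFResult:
    """Run meta-eABF Langevin dynamics of one particle on U(ξ).

    Both the physical coordinate and the extended variable evolve by BAOAB
    with reflecting walls at the CV range edges; everything is
    deterministic for a fixed config seed.
    """
    cfg = config
    lo, hi = cfg.xi_min, cfg.xi_max
    w = cfg.bin_width
    nb = cfg.n_bins
    k = float(cfg.coupling_k)
    kt = KBOLTZ * cfg.temperature
    dt = cfg.dt
    m, mlam = cfg.mass, float(cfg.ext_mass)
    c1 = math.exp(-cfg.friction * dt)
    c2x = math.sqrt(kt * (1.0 - c1 * c1) / m)
    c2l = math.sqrt(kt * (1.0 - c1 * c1) / mlam)

    x = cfg.x0 if cfg.x0 is not None else 0.5 * (lo + hi)
    if not (lo <= x <= hi):
        raise ValueError(f"start ξ={x} outside CV range [{lo}, {hi}]")
    lam = x
    vx = vlam = 0.0

    state = BiasState.empty(cfg)
    counts = state.lambda_counts
    gsum = state.grad_sum
    xic = state.xi_counts
    xil = state.xi_dev_sum
    centers = cfg.bin_centers
    meta_force = np.zeros(nb)  # metadynamics force tabulated at bin centers

    rng = np.random.default_rng(cfg.seed)
    n_steps = cfg.n_steps
    noise = rng.standard_normal((2, n_steps))
    checkpoints: list[BiasState] = []
    want_ckpt = set(int(c) for c in cfg.checkpoints)
    rec_n = n_steps // cfg.record_stride
    xi_series = np.empty(rec_n)
    lam_series = np.empty(rec_n)
    guard = 2.0 * cfg.hill_width

    fx = -gradient(x) - k * (x - lam)
    flam_bias_bin = -1  # invalidate cache
    inv_w = 1.0 / w
    n_full = float(cfg.n_full)
    for step in range(n_steps):
        # --- bias force on λ at current position
        bl = int((lam - lo) * inv_w)
        if bl < 0:
            bl = 0
        elif bl >= nb:
            bl = nb - 1
        flam = k * (x - lam)
        if cfg.use_abf:
            cnt = counts[bl]
            if cnt > 0.0:
                ramp = cnt / n_full
                if ramp > 1.0:
                    ramp = 1.0
                flam += ramp * (gsum[bl] / cnt)
        if cfg.use_metadynamics and state.hills:
            # linear interpolation of the tabulated hill force
            pos = (lam - centers[0]) * inv_w
            i0 = int(pos)
            if i0 < 0:
                flam += meta_force[0]
            elif i0 >= nb - 1:
                flam += meta_force[nb - 1]
            else:
                fr = pos - i0
                flam += meta_force[i0] * (1.0 - fr) + meta_force[i0 + 1] * fr

        # --- BAOAB for x and λ
        vx += 0.5 * dt * fx / m
        vlam += 0.5 * dt * flam / mlam
        x += 0.5 * dt * vx
        lam += 0.5 * dt * vlam
        vx = c1 * vx + c2x * noise[0, step]
        vlam = c1 * vlam + c2l * noise[1, step]
        x += 0.5 * dt * vx
        lam += 0.5 * dt * vlam
        if x < lo:
            x = 2.0 * lo - x
            vx = -vx
        elif x > hi:
            x = 2.0 * hi - x
            vx = -vx
        if lam < lo:
            lam = 2.0 * lo - lam
            vlam = -vlam
        elif lam > hi:
            lam = 2.0 * hi - lam
            vlam = -vlam
        if x < lo - guard or x > hi + guard:
            raise RuntimeError(
                f"CV left the sampling range at step {step}: ξ={x:.3f} "
                f"outside [{lo}, {hi}] by more than 2 hill widths")
        fx = -gradient(x) - k * (x - lam)

        # --- accumulate statistics
        bl = int((lam - lo) * inv_w)
        if bl < 0:
            bl = 0
        elif bl >= nb:
            bl = nb - 1
        counts[bl] += 1.0
        gsum[bl] += k * (lam - x)
        bx = int((x - lo) * inv_w)
        if bx < 0:
            bx = 0
        elif bx >= nb:
            bx = nb - 1
        xic[bx] += 1.0
        xil[bx] += lam - x

        # --- metadynamics deposition
        if cfg.use_metadynamics and (step + 1) % cfg.hill_period == 0:
            h, hw = cfg.hill_height, cfg.hill_width
            state.hills.append((step + 1, lam, h, hw))
            d = centers - lam
            meta_force += h * d / hw ** 2 * np.exp(-d * d / (2.0 * hw ** 2))

        if cfg.record_stride and (step + 1) % cfg.record_stride == 0:
            idx = step // cfg.record_stride
            if idx < rec_n:
                xi_series[idx] = x
                lam_series[idx] = lam
        state.step = step + 1
        if (step + 1) in want_ckpt:
            checkpoints.append(state.snapshot())
    return MetaEABFResult(bias=state, checkpoints=checkpoints,
                         xi_series=xi_series, lambda_series=lam_series)


# ---------------------------------------------------------- estimation

@dataclass
class FreeEnergyProfile:
    """Binned PMF, min-anchored at zero over the sampled bins."""

    bin_centers: np.ndarray
    values: np.ndarray
    sampled: np.ndarray
    method: str = ""
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, float)
        self.values = np.asarray(self.values, float)
        self.sampled = np.asarray(self.sampled, bool)

    @classmethod
    def from_callable(cls, fn: Callable[[np.ndarray], np.ndarray],
                      bin_centers: np.ndarray, method: str = "analytic"
                      ) -> "FreeEnergyProfile":
        centers = np.asarray(bin_centers, float)
        vals = np.asarray(fn(centers), float)
        vals = vals - vals.min()
        return cls(centers, vals, np.ones_like(centers, dtype=bool), method=method)


def _integrate_gradient(centers: np.ndarray, grad: np.ndarray) -> np.ndarray:
    out = np.zeros_like(grad)
    dx = np.diff(centers)
    out[1:] = np.cumsum(0.5 * (grad[:-1] + grad[1:]) * dx)
    return out


def estimate_pmf(bias_state: BiasState, method: str = "czar",
                 config: FreeEnergyConfig | None = None) -> FreeEnergyProfile:
    """Reconstruct the PMF from accumulated bias state.

    method 'czar' applies the corrected z-averaged restraint estimator,
    'naive' integrates the per-λ-bin mean-force estimate, 'hills_only'
    negates the metadynamics hill sum.  Unsampled bins carry the last
    integrated value and are flagged False in ``sampled``.
    """
    cfg = config or bias_state.config
    centers = cfg.bin_centers
    k = float(cfg.coupling_k)
    kt = KBOLTZ * cfg.temperature
    if method == "hills_only":
        v = np.zeros_like(centers)
        for (_, c, h, w) in bias_state.hills:
            v += h * np.exp(-((centers - c) ** 2) / (2.0 * w ** 2))
        prof = -v
        prof -= prof.min()
        return FreeEnergyProfile(centers, prof,
                                 np.ones_like(centers, dtype=bool), method=method)
    if method == "naive":
        counts = bias_state.lambda_counts
        if counts.sum() == 0:
            raise ValueError("no sampled bins")
        sampled = counts > 0
        grad = np.zeros_like(centers)
        grad[sampled] = bias_state.grad_sum[sampled] / counts[sampled]
    elif method == "czar":
        counts = bias_state.xi_counts
        if counts.sum() == 0:
            raise ValueError("no sampled bins")
        sampled = counts > 0
        lnrho = np.zeros_like(centers)
        lnrho[sampled] = np.log(counts[sampled])
        dlnrho = np.zeros_like(centers)
        n = centers.size
        w = cfg.bin_width
        for i in np.flatnonzero(sampled):
            left = i - 1 if i > 0 and sampled[i - 1] else i
            right = i + 1 if i < n - 1 and sampled[i + 1] else i
            if right > left:
                dlnrho[i] = (lnrho[right] - lnrho[left]) / ((right - left) * w)
        dev_mean = np.zeros_like(centers)
        dev_mean[sampled] = bias_state.xi_dev_sum[sampled] / counts[sampled]
        grad = np.zeros_like(centers)
        grad[sampled] = -kt * dlnrho[sampled] + k * dev_mean[sampled]
    else:
        raise ValueError(f"unknown estimator {method!r}")
    prof = _integrate_gradient(centers, grad)
    if sampled.any():
        prof -= prof[sampled].min()
    return FreeEnergyProfile(centers, prof, sampled, method=method)


def convergence_report(profiles: Sequence[FreeEnergyProfile],
                       tolerance: float = 0.5) -> dict:
    """Pairwise RMS differences and the first checkpoint converged to the last.

    Convergence at checkpoint t means RMS(profile_t − profile_final) ≤
    *tolerance* kcal/mol over bins sampled in both profiles.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    base = profiles[0].bin_centers
    for p in profiles[1:]:
        if p.bin_centers.shape != base.shape or not np.allclose(p.bin_centers, base):
            raise ValueError("profiles must share the same bin grid")
    n = len(profiles)
    rms = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = profiles[i].sampled & profiles[j].sampled
            if not both.any():
                rms[i, j] = rms[j, i] = np.inf
                continue
            d = profiles[i].values[both] - profiles[j].values[both]
            rms[i, j] = rms[j, i] = float(np.sqrt(np.mean(d ** 2)))
    converged_at = None
    for t in range(n):
        if rms[t, n - 1] <= tolerance:
            converged_at = t
            break
    return {"rms_matrix": rms, "rms_to_final": rms[:, n - 1],
            "converged_at": converged_at, "tolerance": tolerance}


def annotate_profile(profile: FreeEnergyProfile,
                     bound_region: tuple[float, float],
                     plateau_region: tuple[float, float]) -> FreeEnergyProfile:
    """Extract the dissociation ΔG and barrier from a PMF.

    ΔG = A(plateau mean) − A(bound minimum) (positive for a bound
    complex; the binding free energy is its negative).  The barrier is the
    maximum along the path from the bound minimum to the plateau region,
    relative to the bound minimum.  Annotations are stored on the returned
    profile.
    """
    c = profile.bin_centers
    in_bound = (c >= bound_region[0]) & (c <= bound_region[1]) & profile.sampled
    in_plateau = (c >= plateau_region[0]) & (c <= plateau_region[1]) & profile.sampled
    if not in_bound.any():
        raise ValueError("bound region contains no sampled bins")
    if not in_plateau.any():
        raise ValueError("plateau region contains no sampled bins")
    bound_idx = int(np.flatnonzero(in_bound)[np.argmin(profile.values[in_bound])])
    a_min = float(profile.values[bound_idx])
    plateau = float(np.mean(profile.values[in_plateau]))
    first_plateau = int(np.flatnonzero(in_plateau)[0])
    lo, hi = sorted((bound_idx, first_plateau))
    path = slice(lo, hi + 1)
    path_sampled = profile.sampled[path]
    path_vals = profile.values[path][path_sampled]
    barrier_rel = int(np.argmax(profile.values[path] - a_min))
    barrier_idx = lo + barrier_rel
    barrier = float(profile.values[barrier_idx] - a_min)
    ann = dict(profile.annotations)
    ann.update({
        "minimum_xi": float(c[bound_idx]), "minimum_bin": bound_idx,
        "barrier_xi": float(c[barrier_idx]), "barrier_bin": barrier_idx,
        "barrier_height": barrier,
        "plateau_value": plateau - a_min,
        "delta_g": plateau - a_min,           # dissociation free energy
        "delta_g_bind": -(plateau - a_min),   # binding free energy
    })
    return FreeEnergyProfile(profile.bin_centers, profile.values,
                             profile.sampled, method=profile.method,
                             annotations=ann)
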