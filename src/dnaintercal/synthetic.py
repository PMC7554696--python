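"""Synthetic-data generators with known ground truth for every analysis stage.

Each generator emulates one instrument or simulation output that the
analysis modules consume — two-state Beer-Lambert absorbance titrations,
1:1 static-quenching fluorescence titrations, TCSPC decay histograms with
Poisson counting noise, Wiseman-model ITC heats with dilution heats,
Metropolis-sampled umbrella-window distributions from a known reference
free-energy profile, and labelled multi-cluster conformer ensembles — so
that every estimator in the package has a parameter-recovery test
surface.  All randomness flows from an explicit per-call seed; with noise
disabled every generator is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy.interpolate import CubicSpline

from .constants import KT_KCAL_PER_MOL
from .exceptions import DegenerateModelError, InvalidInputError
from .itc import ITCData, InjectionSchedule, SingleSiteModel, wiseman_heats
from .quenching import DecayHistogram, QuenchSeries
from .uvvis import TitrationSeries
from .wham import UmbrellaWindow
from .clustering import ConformerEnsemble

__all__ = [
    "NoiseSpec",
    "ReferencePMF",
    "gen_uvvis_titration",
    "gen_fluor_titration",
    "gen_decay_histogram",
    "gen_itc_experiment",
    "gen_umbrella_samples",
    "gen_conformer_ensemble",
    "load_preset",
    "reference_pmf_from_preset",
]

_NOISE_KINDS = ("none", "gaussian_additive", "poisson_counting")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model applied by a generator.

    ``kind='none'`` makes the generator fully deterministic;
    ``gaussian_additive`` adds N(0, scale) per observation;
    ``poisson_counting`` replaces expectations with Poisson draws
    (``scale`` is ignored).
    """

    kind: str = "none"
    scale: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in _NOISE_KINDS:
            raise InvalidInputError(f"noise kind must be one of {_NOISE_KINDS}")
        if self.scale < 0:
            raise InvalidInputError("noise scale must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


NO_NOISE = NoiseSpec()


@dataclass
class ReferencePMF:
    """Ground-truth 1-D free-energy profile F(r) for the umbrella sampler.

    ``control_points`` are (r [nm], F [kcal/mol]) knots with strictly
    increasing r.  For ``r >= plateau_start`` the profile is held exactly
    constant at the plateau value, which defines the zero of F; below the
    first knot the profile is an infinite wall (samples are rejected
    there).  Interpolation between knots is a cubic spline or piecewise
    linear.
    """

    control_points: list
    interpolation: str = "cubic_spline"
    plateau_start: float | None = None
    _r: np.ndarray = field(init=False, repr=False, default=None)
    _F: np.ndarray = field(init=False, repr=False, default=None)
    _spline: object = field(init=False, repr=False, default=None)

    def __post_init__(self):
        pts = np.asarray(self.control_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise InvalidInputError("control_points must be >= 2 (r, F) pairs")
        if np.any(np.diff(pts[:, 0]) <= 0):
            raise InvalidInputError("control point r values must be strictly increasing")
        if self.interpolation not in ("cubic_spline", "piecewise_linear"):
            raise InvalidInputError("unknown interpolation")
        self._r, self._F = pts[:, 0].copy(), pts[:, 1].copy()
        if self.plateau_start is not None:
            if not (self._r[0] <= self.plateau_start <= self._r[-1]):
                raise InvalidInputError("plateau_start outside control-point range")
        if self.interpolation == "cubic_spline":
            self._spline = CubicSpline(self._r, self._F)
        # Shift so the plateau value (or nothing) defines zero.
        if self.plateau_start is not None:
            shift = self._interp(np.array([self.plateau_start]))[0]
            self._F -= shift
            if self.interpolation == "cubic_spline":
                self._spline = CubicSpline(self._r, self._F)

    @property
    def domain(self) -> tuple[float, float]:
        return float(self._r[0]), float(self._r[-1])

    def _interp(self, r: np.ndarray) -> np.ndarray:
        if self.interpolation == "cubic_spline":
            return self._spline(r)
        return np.interp(r, self._r, self._F)

    def __call__(self, r) -> np.ndarray:
        """F(r) in kcal/mol; +inf below the first knot (hard wall)."""
        r = np.asarray(r, dtype=float)
        r_clip = np.minimum(
            r, self.plateau_start if self.plateau_start is not None else self._r[-1]
        )
        out = self._interp(np.maximum(r_clip, self._r[0]))
        out = np.where(r < self._r[0], np.inf, out)
        return out

    def minimum(self, n_grid: int = 4001) -> tuple[float, float]:
        """(r, F) of the global minimum on a fine grid of the domain."""
        lo, hi = self.domain
        g = np.linspace(lo, hi, n_grid)
        Fg = self(g)
        i = int(np.argmin(Fg))
        return float(g[i]), float(Fg[i])


# ---------------------------------------------------------------------------
# optical titrations

def gen_uvvis_titration(
    K_A: float,
    eps_f: float,
    eps_b: float,
    ligand_total: float,
    dna_concs,
    mode: str = "excess_titrant_ideal",
    noise: NoiseSpec = NO_NOISE,
) -> TitrationSeries:
    """Two-state Beer-Lambert absorbance titration (1 cm path).

    In ``excess_titrant_ideal`` mode the bound fraction is
    ``K_A [DNA] / (1 + K_A [DNA])`` with [DNA] taken as free — the
    classical assumption that makes the Benesi-Hildebrand linearization
    exact.  In ``exact_mass_balance`` mode the 1:1 equilibrium quadratic
    is solved with depletion of both species, which is what a real
    titration with comparable ligand and titrant concentrations does; the
    linearized fit is then biased except in the dilute-ligand limit.
    """
    dna_concs = np.asarray(dna_concs, dtype=float)
    if ligand_total <= 0 or np.any(dna_concs <= 0):
        raise InvalidInputError("concentrations must be positive")
    if np.any(np.diff(dna_concs) <= 0):
        raise InvalidInputError("dna_concs must be strictly increasing")
    if K_A < 0:
        raise InvalidInputError("K_A must be >= 0")
    if eps_b == eps_f:
        raise DegenerateModelError("eps_b == eps_f: absorbance insensitive to binding")
    if mode not in ("excess_titrant_ideal", "exact_mass_balance"):
        raise InvalidInputError(f"unknown mode {mode!r}")

    L = ligand_total
    if mode == "excess_titrant_ideal":
        frac_bound = K_A * dna_concs / (1.0 + K_A * dna_concs)
        bound = L * frac_bound
    else:
        if K_A == 0:
            bound = np.zeros_like(dna_concs)
        else:
            b = L + dna_concs + 1.0 / K_A
            bound = 0.5 * (b - np.sqrt(b * b - 4.0 * L * dna_concs))
    A = eps_f * (L - bound) + eps_b * bound
    A0 = eps_f * L

    if noise.kind == "gaussian_additive":
        rng = noise.rng()
        A = A + rng.normal(0.0, noise.scale, A.shape)
        A0 = A0 + rng.normal(0.0, noise.scale)
    elif noise.kind == "poisson_counting":
        raise InvalidInputError("poisson_counting noise is not meaningful for absorbance")
    return TitrationSeries(
        ligand_total=L, dna_concs=dna_concs, absorbances=A, A0=float(A0)
    )


def gen_fluor_titration(
    K_A: float,
    F0: float,
    q_concs,
    noise: NoiseSpec = NO_NOISE,
) -> QuenchSeries:
    """1:1 static-quenching titration: noiseless F obeys F0/F = 1 + K_A [Q]."""
    q_concs = np.asarray(q_concs, dtype=float)
    if not F0 > 0:
        raise InvalidInputError("F0 must be positive")
    if np.any(q_concs < 0):
        raise InvalidInputError("quencher concentrations must be >= 0")
    if np.any(np.diff(q_concs) <= 0):
        raise InvalidInputError("q_concs must be strictly increasing")
    q = q_concs[q_concs > 0]
    F = F0 / (1.0 + K_A * q)
    if noise.kind == "gaussian_additive":
        F = F + noise.rng().normal(0.0, noise.scale, F.shape)
    elif noise.kind == "poisson_counting":
        raise InvalidInputError("poisson_counting noise is not meaningful here")
    return QuenchSeries(F0=F0, q_concs=q, F=F)


# ---------------------------------------------------------------------------
# fluorescence decays

def gen_decay_histogram(
    tau: float,
    n_channels: int = 256,
    channel_width: float = 0.05,
    total_counts: float = 1e6,
    background: float = 0.0,
    noise: NoiseSpec = NoiseSpec(kind="poisson_counting"),
) -> DecayHistogram:
    """Monoexponential TCSPC histogram with optional Poisson counting noise.

    Expected counts per channel are ``A exp(-t/tau) + background`` with A
    normalised so the total expectation equals ``total_counts``.  Channel
    times are bin centres.
    """
    if not tau > 0:
        raise InvalidInputError("tau must be positive")
    if not channel_width > 0:
        raise InvalidInputError("channel_width must be positive")
    if n_channels < 1:
        raise InvalidInputError("need at least one channel")
    if total_counts < 0 or background < 0:
        raise InvalidInputError("counts must be >= 0")
    t = (np.arange(n_channels) + 0.5) * channel_width
    shape = np.exp(-t / tau)
    decay_budget = total_counts - background * n_channels
    A = max(decay_budget, 0.0) / shape.sum()
    expected = A * shape + background
    if noise.kind == "poisson_counting":
        counts = noise.rng().poisson(expected).astype(float)
    elif noise.kind == "gaussian_additive":
        counts = np.maximum(expected + noise.rng().normal(0, noise.scale, expected.shape), 0.0)
    else:
        counts = expected
    return DecayHistogram(time_ns=t, counts=counts)


# ---------------------------------------------------------------------------
# ITC

def gen_itc_experiment(
    model: SingleSiteModel,
    schedule: InjectionSchedule,
    dilution_heat: float = 0.0,
    noise: NoiseSpec = NO_NOISE,
) -> ITCData:
    """Wiseman-model injection heats plus dilution heat, with matched blank.

    ``dilution_heat`` (ucal/injection) is added to every injection; the
    blank series contains only the dilution heat (with its own noise
    draws), so blank subtraction mirrors the real protocol.
    """
    chem = wiseman_heats(model, schedule)
    n = len(chem)
    if noise.kind == "gaussian_additive":
        rng = noise.rng()
        eps_t = rng.normal(0.0, noise.scale, n)
        eps_b = rng.normal(0.0, noise.scale, n)
    elif noise.kind == "none":
        eps_t = eps_b = np.zeros(n)
    else:
        raise InvalidInputError("ITC noise must be gaussian_additive or none")
    return ITCData(
        heats=chem + dilution_heat + eps_t,
        blank_heats=np.full(n, dilution_heat) + eps_b,
    )


# ---------------------------------------------------------------------------
# umbrella sampling

def _autocorr_ess(chains: np.ndarray) -> float:
    """Effective sample size from averaged per-chain autocorrelations.

    ``chains`` has shape (n_draws, n_chains).  Uses an initial positive
    sequence truncated at the first lag with mean autocorrelation below
    0.05 (capped at 100 lags); a crude but adequate mixing diagnostic.
    """
    n, m = chains.shape
    if n < 4:
        return float(n * m)
    x = chains - chains.mean(axis=0, keepdims=True)
    var = np.mean(x ** 2, axis=0)
    var = np.where(var > 0, var, 1.0)
    rho_sum = 0.0
    for lag in range(1, min(100, n - 1)):
        rho = np.mean(np.mean(x[lag:] * x[:-lag], axis=0) / var)
        if rho < 0.05:
            break
        rho_sum += rho
    return float(n * m / (1.0 + 2.0 * rho_sum))


def gen_umbrella_samples(
    ref: ReferencePMF,
    centers,
    force_const: float,
    n_samples: int,
    kT: float = KT_KCAL_PER_MOL,
    mcmc: dict | None = None,
) -> list[UmbrellaWindow]:
    """Metropolis Monte Carlo samples from each biased window density.

    For window centre r0 the target density is
    ``exp(-[F_ref(r) + k (r - r0)^2 / 2] / kT)``.  Sampling runs
    ``n_chains`` independent walkers in parallel (vectorised), discards
    ``burn_in`` sweeps and keeps every ``thin``-th sweep until
    ``n_samples`` total draws are pooled.  Acceptance rate and an
    autocorrelation-based effective sample size are recorded per window.

    ``mcmc`` keys (defaults): ``step_size`` (0.05 nm), ``burn_in`` (500),
    ``thin`` (2), ``seed`` (0), ``n_chains`` (50).
    """
    centers = np.asarray(centers, dtype=float)
    if not force_const > 0:
        raise InvalidInputError("force constant must be positive")
    if n_samples < 1:
        raise InvalidInputError("n_samples must be >= 1")
    lo, hi = ref.domain
    if np.any(centers < lo) or np.any(centers > hi):
        raise InvalidInputError("window centers must lie within the reference domain")
    opts = {"step_size": 0.05, "burn_in": 500, "thin": 2, "seed": 0, "n_chains": 50}
    opts.update(mcmc or {})
    step = float(opts["step_size"])
    burn = int(opts["burn_in"])
    thin = max(int(opts["thin"]), 1)
    n_chains = max(int(opts["n_chains"]), 1)
    draws_per_chain = math.ceil(n_samples / n_chains)
    total_sweeps = burn + draws_per_chain * thin
    if burn >= total_sweeps:
        raise InvalidInputError("burn_in consumes the whole chain")
    rng = np.random.default_rng(opts["seed"])

    windows = []
    for wi, r0 in enumerate(centers):
        def energy(x):
            return ref(x) + 0.5 * force_const * (x - r0) ** 2

        x = np.full(n_chains, float(np.clip(r0, lo, hi)))
        x += rng.normal(0.0, step / 10.0, n_chains)
        x = np.clip(x, lo, hi)
        u = energy(x)
        kept = []
        n_acc = 0
        n_prop = 0
        for sweep in range(total_sweeps):
            prop = x + rng.normal(0.0, step, n_chains)
            u_prop = energy(prop)
            with np.errstate(over="ignore", invalid="ignore"):
                log_alpha = -(u_prop - u) / kT
            accept = np.log(rng.random(n_chains)) < log_alpha
            accept &= np.isfinite(u_prop)
            x = np.where(accept, prop, x)
            u = np.where(accept, u_prop, u)
            n_acc += int(accept.sum())
            n_prop += n_chains
            if sweep >= burn and (sweep - burn) % thin == 0:
                kept.append(x.copy())
        chain_matrix = np.array(kept)                      # (draws, chains)
        samples = chain_matrix.T.reshape(-1)[:n_samples]
        windows.append(
            UmbrellaWindow(
                center=float(r0),
                force_const=force_const,
                samples=samples,
                label=f"window_{wi:02d}",
                acceptance_rate=n_acc / n_prop,
                effective_sample_size=_autocorr_ess(chain_matrix),
            )
        )
    return windows


# ---------------------------------------------------------------------------
# conformer ensembles

def gen_conformer_ensemble(
    n_frames: int,
    blueprint: list[dict],
    seed: int | None = None,
) -> tuple[ConformerEnsemble, np.ndarray]:
    """Gaussian-jittered multi-cluster conformer ensemble with true labels.

    ``blueprint`` entries: ``center_coords`` (atoms x 3, nm),
    ``population_fraction``, ``jitter_sd`` (nm), optional ``rotate_deg``
    and ``rotate_axis`` applying a rigid rotation about the centroid.
    Fractions must sum to 1.  Returns (ensemble, labels).
    """
    if not blueprint:
        raise InvalidInputError("blueprint must not be empty")
    fracs = np.array([b["population_fraction"] for b in blueprint], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise InvalidInputError("population fractions must sum to 1")
    if any(b.get("jitter_sd", 0.0) < 0 for b in blueprint):
        raise InvalidInputError("jitter_sd must be >= 0")
    centers = []
    for b in blueprint:
        c = np.asarray(b["center_coords"], dtype=float)
        if c.ndim != 2 or c.shape[1] != 3:
            raise InvalidInputError("center_coords must be atoms x 3")
        if b.get("rotate_deg"):
            from scipy.spatial.transform import Rotation

            axis = np.asarray(b.get("rotate_axis", [0, 0, 1]), dtype=float)
            axis = axis / np.linalg.norm(axis)
            rot = Rotation.from_rotvec(np.radians(b["rotate_deg"]) * axis)
            centroid = c.mean(axis=0)
            c = rot.apply(c - centroid) + centroid
        centers.append(c)
    n_atoms = centers[0].shape[0]
    if any(c.shape[0] != n_atoms for c in centers):
        raise InvalidInputError("all blueprint centers must share the atom count")

    rng = np.random.default_rng(seed)
    labels = rng.choice(len(blueprint), size=n_frames, p=fracs)
    coords = np.empty((n_frames, n_atoms, 3))
    for i, lab in enumerate(labels):
        sd = blueprint[lab].get("jitter_sd", 0.0)
        coords[i] = centers[lab] + rng.normal(0.0, sd, (n_atoms, 3))
    ensemble = ConformerEnsemble(
        coords=coords,
        selections={"ligand_heavy": np.arange(n_atoms)},
    )
    return ensemble, labels


# ---------------------------------------------------------------------------
# presets: parameter sets matching the published experimental conditions

def load_preset(name: str = "paper_like") -> dict:
    """Load a named parameter preset shipped with the package."""
    text = resources.files("dnaintercal.data").joinpath(f"{name}.yaml").read_text()
    return yaml.safe_load(text)


def reference_pmf_from_preset(preset: dict, profile: str) -> ReferencePMF:
    """Build a :class:`ReferencePMF` from a preset's ``pmf`` block."""
    block = preset["pmf"]["profiles"][profile]
    return ReferencePMF(
        control_points=[tuple(p) for p in block["control_points"]],
        interpolation=block.get("interpolation", "cubic_spline"),
        plateau_start=block.get("plateau_start_nm"),
    )
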