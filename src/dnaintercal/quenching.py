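"""Fluorescence quenching analysis and monoexponential lifetime fitting.

Implements the classical battery of titration linearizations for a
fluorophore quenched by dsDNA:

* Stern-Volmer, ``F0/F = 1 + K_SV [Q] = 1 + k_q tau0 [Q]`` — quenching
  constant and bimolecular rate;
* mechanism classification (static vs dynamic) from the magnitude of
  ``k_q`` relative to the diffusion-collision ceiling and from lifetime
  invariance;
* Lineweaver-Burk double reciprocal, ``F0/(F0-F) = 1 + K_D / [Q]`` —
  dissociation constant of the ground-state complex;
* double-logarithmic (Scatchard-type) plot,
  ``log10[(F0-F)/F] = log10 K_A + n log10 [Q]`` — binding-site number;
* Poisson maximum-likelihood fit of TCSPC decay histograms with a
  monoexponential model ``A exp(-t/tau) + B``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .constants import NS_TO_S
from .exceptions import (
    FitFailureError,
    InsufficientDataError,
    InvalidInputError,
    NonBindingSignalError,
)

__all__ = [
    "QuenchSeries",
    "SternVolmerFit",
    "LineweaverBurkFit",
    "DoubleLogFit",
    "DecayHistogram",
    "LifetimeFit",
    "stern_volmer_fit",
    "classify_mechanism",
    "lineweaver_burk_fit",
    "double_log_fit",
    "lifetime_fit",
    "SCATTER_COLLISION_LIMIT",
]

#: Maximum scatter-collision (diffusion-limited) quenching rate, 1/(M s).
SCATTER_COLLISION_LIMIT: float = 2.0e10


@dataclass
class QuenchSeries:
    """Fluorescence intensities at increasing quencher concentration."""

    F0: float
    q_concs: np.ndarray
    F: np.ndarray
    emission_wavelength: float = 594.0
    flagged_points: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.q_concs = np.asarray(self.q_concs, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.q_concs.shape != self.F.shape:
            raise InvalidInputError("q_concs and F must have equal length")
        if self.q_concs.size < 3:
            raise InsufficientDataError("need at least 3 quenching points")
        if np.any(self.q_concs <= 0):
            raise InvalidInputError("quencher concentrations must be > 0")
        if np.any(np.diff(self.q_concs) <= 0):
            raise InvalidInputError("quencher concentrations must be strictly increasing")
        if not self.F0 > 0:
            raise InvalidInputError("F0 must be positive")
        # F outside (0, F0] is physically suspect but tolerated: flag, don't drop.
        self.flagged_points = np.flatnonzero((self.F <= 0) | (self.F > self.F0))

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "q_conc_M": np.concatenate([[0.0], self.q_concs]),
                "fluorescence": np.concatenate([[self.F0], self.F]),
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, emission_wavelength: float = 594.0):
        df = pd.read_csv(path)
        for col in ("q_conc_M", "fluorescence"):
            if col not in df.columns:
                raise InvalidInputError(f"missing required column {col!r}")
        zero = df[df["q_conc_M"] == 0.0]
        if zero.empty:
            raise InvalidInputError("CSV must contain a q_conc_M = 0 row defining F0")
        rest = df[df["q_conc_M"] > 0.0].sort_values("q_conc_M")
        return cls(
            F0=float(zero["fluorescence"].iloc[0]),
            q_concs=rest["q_conc_M"].to_numpy(),
            F=rest["fluorescence"].to_numpy(),
            emission_wavelength=emission_wavelength,
        )


@dataclass
class SternVolmerFit:
    K_SV: float            # 1/M
    k_q: float             # 1/(M s)
    tau0: float            # ns
    intercept: float       # expected ~ 1
    r_squared: float
    mechanism: str         # static | dynamic | indeterminate


@dataclass
class LineweaverBurkFit:
    K_D: float             # M
    K_A: float             # 1/M
    slope: float
    intercept: float       # expected ~ 1
    r_squared: float


@dataclass
class DoubleLogFit:
    n_sites: float
    log_K_A: float
    r_squared: float


@dataclass
class DecayHistogram:
    """TCSPC-style decay: channel-centre times (ns) and counts."""

    time_ns: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.time_ns = np.asarray(self.time_ns, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.time_ns.shape != self.counts.shape:
            raise InvalidInputError("time and counts must have equal length")
        if np.any(self.counts < 0):
            raise InvalidInputError("counts must be non-negative")

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_ns": self.time_ns, "counts": self.counts}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path):
        df = pd.read_csv(path)
        return cls(df["time_ns"].to_numpy(), df["counts"].to_numpy())


@dataclass
class LifetimeFit:
    tau: float             # ns
    amplitude: float       # counts/channel at t=0
    background: float      # counts/channel
    tau_std_err: float     # ns, from observed Fisher information
    reduced_chi2: float
    converged: bool


def stern_volmer_fit(series: QuenchSeries, tau0: float) -> SternVolmerFit:
    """Linear fit of ``F0/F`` on [Q]; slope is K_SV, ``k_q = K_SV/tau0``.

    ``tau0`` is the unquenched fluorophore lifetime in ns; ``k_q`` is
    returned in 1/(M s).
    """
    if not tau0 > 0:
        raise InvalidInputError("tau0 must be positive")
    y = series.F0 / series.F
    res = stats.linregress(series.q_concs, y)
    if res.slope <= 0:
        raise NonBindingSignalError("no quenching: Stern-Volmer slope <= 0")
    K_SV = float(res.slope)
    k_q = K_SV / (tau0 * NS_TO_S)
    return SternVolmerFit(
        K_SV=K_SV,
        k_q=k_q,
        tau0=tau0,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        mechanism=classify_mechanism(k_q),
    )


def classify_mechanism(
    k_q: float,
    lifetimes_vs_Q: list[tuple[float, float]] | None = None,
    threshold: float = SCATTER_COLLISION_LIMIT,
    lifetime_tolerance: float = 0.05,
) -> str:
    """Static vs dynamic quenching call.

    Static quenching (ground-state complex) is diagnosed when the apparent
    bimolecular rate exceeds the diffusion-collision ceiling — no physical
    collisional process can quench faster — and, when lifetime data are
    supplied, the lifetime is invariant (``|tau0/tau - 1|`` within
    tolerance at every [Q]).  Dynamic quenching requires a sub-ceiling rate
    together with lifetimes that decrease monotonically with [Q].  The
    exact-threshold boundary is assigned to ``indeterminate``.
    """
    if not k_q > 0:
        raise InvalidInputError("k_q must be positive")
    taus = None
    if lifetimes_vs_Q:
        pairs = sorted(lifetimes_vs_Q)
        taus = np.array([t for _, t in pairs], dtype=float)
    if k_q > threshold:
        if taus is None:
            return "static"
        tau0 = taus[0]
        if np.max(np.abs(tau0 / taus - 1.0)) <= lifetime_tolerance:
            return "static"
        return "indeterminate"
    if k_q < threshold:
        if taus is not None and np.all(np.diff(taus) < 0):
            return "dynamic"
        return "indeterminate"
    return "indeterminate"


def _strict_quench_points(series: QuenchSeries):
    ok = series.F < series.F0
    if not np.all(ok):
        warnings.warn(
            f"excluding {int((~ok).sum())} points with F >= F0 (no net quenching)",
            stacklevel=3,
        )
    if ok.sum() < 3:
        raise InsufficientDataError("fewer than 3 points with F < F0")
    return series.q_concs[ok], series.F[ok]


def lineweaver_burk_fit(series: QuenchSeries) -> LineweaverBurkFit:
    """Double-reciprocal fit ``F0/(F0-F)`` on ``1/[Q]``; slope is K_D."""
    q, F = _strict_quench_points(series)
    x = 1.0 / q
    y = series.F0 / (series.F0 - F)
    res = stats.linregress(x, y)
    if res.slope <= 0:
        raise NonBindingSignalError("Lineweaver-Burk slope <= 0")
    K_D = float(res.slope)
    return LineweaverBurkFit(
        K_D=K_D,
        K_A=1.0 / K_D,
        slope=K_D,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
    )


def double_log_fit(series: QuenchSeries) -> DoubleLogFit:
    """Fit ``log10[(F0-F)/F]`` on ``log10 [Q]``: slope = n, intercept = log K_A.

    Invariant under a common rescaling of F and F0 (only ratios enter).
    """
    q, F = _strict_quench_points(series)
    x = np.log10(q)
    y = np.log10((series.F0 - F) / F)
    res = stats.linregress(x, y)
    return DoubleLogFit(
        n_sites=float(res.slope),
        log_K_A=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
    )


def _decay_model(t, A, tau, B):
    return A * np.exp(-t / tau) + B


def _decay_nll(params, t, c, fit_background):
    A, tau = params[0], params[1]
    B = params[2] if fit_background else 0.0
    m = _decay_model(t, A, tau, B)
    if np.any(m <= 0):
        return np.inf
    # Poisson NLL up to the additive ln(c!) constant.
    return float(np.sum(m - c * np.log(m)))


def lifetime_fit(
    decay: DecayHistogram,
    fit_background: bool = False,
    max_iter: int = 2000,
) -> LifetimeFit:
    """Monoexponential decay fit by Poisson maximum likelihood.

    Model: expected counts ``m(t) = A exp(-t/tau) + B``.  The Poisson
    likelihood is correct at arbitrarily low counts where Gaussian
    least-squares is biased; at high counts the two coincide.  The
    standard error of tau comes from the observed information (finite-
    difference Hessian of the negative log-likelihood at the optimum).
    """
    t, c = decay.time_ns, decay.counts
    if np.count_nonzero(c > 0) < 10:
        raise FitFailureError(
            "fewer than 10 channels with counts > 0",
            {"nonzero_channels": int(np.count_nonzero(c > 0))},
        )
    # Log-linear initialisation on the decaying part.
    pos = c > 0
    w = c[pos]
    slope = np.polyfit(t[pos], np.log(c[pos]), 1, w=np.sqrt(w))[0]
    tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0]) / 2.0
    A0 = max(c.max(), 1.0)
    B0 = max(float(np.median(c[-max(3, len(c) // 20):])), 1e-6) if fit_background else 0.0
    # Optimise in log parameters: A and tau differ by orders of magnitude
    # and the likelihood surface is far better conditioned in log space.
    z0 = np.log([A0, tau0] + ([max(B0, 1e-6)] if fit_background else []))

    def nll_log(z):
        x = np.exp(z)
        return _decay_nll(
            [x[0], x[1], x[2] if fit_background else 0.0], t, c, fit_background
        )

    res = optimize.minimize(
        nll_log, z0, method="Nelder-Mead",
        options={"maxiter": max_iter, "maxfev": 2 * max_iter,
                 "xatol": 1e-8, "fatol": 1e-8},
    )
    if not res.success:
        raise FitFailureError("lifetime fit did not converge", {"scipy": res.message})
    x_opt = np.exp(res.x)
    A, tau = float(x_opt[0]), float(x_opt[1])
    B = float(x_opt[2]) if fit_background else 0.0

    def nll(x):
        return _decay_nll(
            [x[0], x[1], x[2] if fit_background else 0.0], t, c, fit_background
        )

    tau_se = _tau_std_err(x_opt, nll)
    m = _decay_model(t, A, tau, B)
    good = m > 0
    dof = max(int(good.sum()) - len(res.x), 1)
    red_chi2 = float(np.sum((c[good] - m[good]) ** 2 / m[good]) / dof)
    return LifetimeFit(
        tau=tau,
        amplitude=A,
        background=B,
        tau_std_err=tau_se,
        reduced_chi2=red_chi2,
        converged=True,
    )


def _tau_std_err(x_opt, nll) -> float:
    """sqrt of the tau-diagonal of the inverse observed information."""
    k = len(x_opt)
    h = np.maximum(np.abs(x_opt), 1e-8) * 1e-4
    H = np.zeros((k, k))
    f0 = nll(x_opt)
    for i in range(k):
        for j in range(i, k):
            xpp = np.array(x_opt, float)
            xpm = np.array(x_opt, float)
            xmp = np.array(x_opt, float)
            xmm = np.array(x_opt, float)
            xpp[i] += h[i]; xpp[j] += h[j]
            xpm[i] += h[i]; xpm[j] -= h[j]
            xmp[i] -= h[i]; xmp[j] += h[j]
            xmm[i] -= h[i]; xmm[j] -= h[j]
            H[i, j] = H[j, i] = (nll(xpp) - nll(xpm) - nll(xmp) + nll(xmm)) / (
                4 * h[i] * h[j]
            )
    del f0
    try:
        cov = np.linalg.inv(H)
        var = cov[1, 1]
        return float(np.sqrt(var)) if var > 0 else float("nan")
    except np.linalg.LinAlgError:
        return float("nan")
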