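"""Isothermal titration calorimetry under the single-site (Wiseman) model.

A titrant (ligand) of syringe concentration ``L_syr`` is injected into an
overflow cell of volume ``V0`` containing the macromolecule at ``M0``.
Assuming ``n`` identical independent sites with association constant ``K``
and molar enthalpy ``dH``, the bound-ligand concentration after injection
``i`` follows the 1:1-per-site mass balance

    L_b = 1/2 { L_t + n M_t + 1/K - sqrt[(L_t + n M_t + 1/K)^2 - 4 n M_t L_t] }

and the evolved heat per injection is the increment of ``L_b dH V0`` with
the standard displaced-volume correction.  Fitting (n, logK, dH) to the
per-injection heats and decomposing via ``dG = -RT ln K = dH - T dS``
gives the full thermodynamic signature of binding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .constants import KCAL_TO_UCAL, R_KCAL_PER_MOL_K, T_STANDARD
from .exceptions import FitFailureError, InsufficientDataError, InvalidInputError

__all__ = [
    "InjectionSchedule",
    "ITCData",
    "SingleSiteModel",
    "SingleSiteFit",
    "dilute_concentrations",
    "wiseman_heats",
    "fit_single_site",
    "thermodynamic_decomposition",
    "integrate_thermogram",
    "paper_like_schedule",
]


@dataclass
class InjectionSchedule:
    """Injection program of an overflow-cell titration experiment."""

    injection_volumes_uL: np.ndarray
    syringe_conc_mM: float
    cell_conc_mM: float
    cell_volume_mL: float = 1.400
    temperature_K: float = T_STANDARD

    def __post_init__(self):
        self.injection_volumes_uL = np.asarray(self.injection_volumes_uL, dtype=float)
        if np.any(self.injection_volumes_uL <= 0):
            raise InvalidInputError("injection volumes must be positive")
        if self.syringe_conc_mM <= 0 or self.cell_conc_mM <= 0:
            raise InvalidInputError("concentrations must be positive")
        if self.cell_volume_mL <= 0:
            raise InvalidInputError("cell volume must be positive")
        total_uL = float(self.injection_volumes_uL.sum())
        cell_uL = self.cell_volume_mL * 1e3
        if total_uL >= cell_uL:
            raise InvalidInputError("cumulative injected volume exceeds cell volume")
        if total_uL > 0.10 * cell_uL:
            warnings.warn(
                f"cumulative injected volume is {100 * total_uL / cell_uL:.0f}% "
                "of the cell volume; dilution corrections are large",
                stacklevel=2,
            )

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes_uL)


def paper_like_schedule(
    syringe_conc_mM: float = 0.174,
    cell_conc_mM: float = 0.002,
    cell_volume_mL: float = 1.400,
) -> InjectionSchedule:
    """29 injections: 2 uL first, then 28 x 10.02 uL (a common autosampler
    program for this instrument class)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return InjectionSchedule(
            injection_volumes_uL=np.array([2.0] + [10.02] * 28),
            syringe_conc_mM=syringe_conc_mM,
            cell_conc_mM=cell_conc_mM,
            cell_volume_mL=cell_volume_mL,
        )


@dataclass
class ITCData:
    """Integrated per-injection heats (ucal), optionally with a blank run."""

    heats: np.ndarray
    blank_heats: np.ndarray | None = None
    first_injection_discarded: bool = False

    def __post_init__(self):
        self.heats = np.asarray(self.heats, dtype=float)
        if self.blank_heats is not None:
            self.blank_heats = np.asarray(self.blank_heats, dtype=float)
            if self.blank_heats.shape != self.heats.shape:
                raise InvalidInputError("blank must match titration length")

    def net_heats(self) -> np.ndarray:
        if self.blank_heats is None:
            return self.heats.copy()
        return self.heats - self.blank_heats

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "injection_index": np.arange(1, len(self.heats) + 1),
                "heat_ucal": self.heats,
            }
        )
        if self.blank_heats is not None:
            df["blank_heat_ucal"] = self.blank_heats
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path):
        df = pd.read_csv(path).sort_values("injection_index")
        blank = (
            df["blank_heat_ucal"].to_numpy() if "blank_heat_ucal" in df.columns else None
        )
        return cls(heats=df["heat_ucal"].to_numpy(), blank_heats=blank)


@dataclass
class SingleSiteModel:
    """(n, K, dH) triplet of the single-set-of-identical-sites model."""

    n: float                # sites per macromolecule
    K: float                # 1/M
    dH: float               # kcal/mol of ligand bound

    def __post_init__(self):
        if not self.n > 0:
            raise InvalidInputError("n must be positive")
        if not self.K > 0:
            raise InvalidInputError("K must be positive")

    @property
    def logK(self) -> float:
        return float(np.log10(self.K))

    def decomposition(self, temperature: float = T_STANDARD, R: float = R_KCAL_PER_MOL_K):
        return thermodynamic_decomposition(self.K, self.dH, temperature, R)


@dataclass
class SingleSiteFit:
    model: SingleSiteModel
    dG: float
    TdS: float
    std_errors: dict = field(default_factory=dict)   # keys n, logK, dH
    reduced_chi2: float = float("nan")
    c_value: float = float("nan")
    n_used: int = 0
    warnings: list = field(default_factory=list)


def dilute_concentrations(schedule: InjectionSchedule):
    """Cell concentrations after each injection under the overflow convention.

    After cumulative injected volume ``v`` into cell volume ``V0``::

        M_t = M0 (1 - v/2V0) / (1 + v/2V0)
        L_t = L_syr (v/V0) / (1 + v/2V0)

    Returns ``(M_t, L_t)`` arrays in M, one entry per injection.
    """
    V0 = schedule.cell_volume_mL * 1e-3          # L
    v = np.cumsum(schedule.injection_volumes_uL) * 1e-6   # L
    M0 = schedule.cell_conc_mM * 1e-3            # M
    Lsyr = schedule.syringe_conc_mM * 1e-3       # M
    ratio = v / V0
    M_t = M0 * (1 - ratio / 2) / (1 + ratio / 2)
    L_t = Lsyr * ratio / (1 + ratio / 2)
    return M_t, L_t


def _bound_ligand(n, K, M_t, L_t):
    b = L_t + n * M_t + 1.0 / K
    disc = b * b - 4.0 * n * M_t * L_t
    neg = disc < 0
    if np.any(neg):
        warnings.warn("negative discriminant clamped to 0", stacklevel=3)
        disc = np.where(neg, 0.0, disc)
    return 0.5 * (b - np.sqrt(disc))


def wiseman_heats(model: SingleSiteModel, schedule: InjectionSchedule) -> np.ndarray:
    """Noise-free per-injection chemical heats (ucal) of the 1:1-site model.

    Includes the displaced-volume correction
    ``dQ_i = Q_i - Q_{i-1} + (dV_i/V0)(Q_i + Q_{i-1})/2``.
    """
    V0 = schedule.cell_volume_mL * 1e-3
    M_t, L_t = dilute_concentrations(schedule)
    L_b = _bound_ligand(model.n, model.K, M_t, L_t)
    Q = L_b * model.dH * V0 * KCAL_TO_UCAL       # cumulative, ucal
    Qprev = np.concatenate([[0.0], Q[:-1]])
    dV = schedule.injection_volumes_uL * 1e-6
    return Q - Qprev + (dV / V0) * (Q + Qprev) / 2.0


def thermodynamic_decomposition(
    K: float,
    dH: float,
    temperature: float = T_STANDARD,
    R: float = R_KCAL_PER_MOL_K,
) -> tuple[float, float]:
    """``(dG, TdS)`` from K and dH: ``dG = -RT ln K``, ``TdS = dH - dG``."""
    if not K > 0:
        raise InvalidInputError("K must be positive")
    dG = -R * temperature * float(np.log(K))
    return dG, dH - dG


def _initial_guess(heats, schedule, used):
    M_t, L_t = dilute_concentrations(schedule)
    ratio = L_t / M_t
    cum = np.cumsum(np.abs(heats[used]))
    if cum[-1] <= 0:
        return SingleSiteModel(n=1.0, K=1e5, dH=-1.0)
    half = np.searchsorted(cum, cum[-1] / 2.0)
    idx = np.flatnonzero(used)[min(half, used.sum() - 1)]
    n0 = max(ratio[idx], 1e-3)
    K0 = 1.0 / max(M_t[idx], 1e-12)
    V0 = schedule.cell_volume_mL * 1e-3
    first = np.flatnonzero(used)[0]
    moles_first = schedule.injection_volumes_uL[first] * 1e-6 * schedule.syringe_conc_mM * 1e-3
    dH0 = heats[first] / (moles_first * KCAL_TO_UCAL)
    if dH0 == 0:
        dH0 = -1.0
    del V0
    return SingleSiteModel(n=n0, K=K0, dH=dH0)


def fit_single_site(
    data: ITCData,
    schedule: InjectionSchedule,
    init: SingleSiteModel | None = None,
    discard_first: bool = True,
    temperature: float | None = None,
    R: float = R_KCAL_PER_MOL_K,
) -> SingleSiteFit:
    """Nonlinear least-squares fit of (n, logK, dH) to injection heats.

    The blank series, when present, is subtracted first.  The first
    injection is discarded by default: a small priming injection suffers
    from syringe-tip diffusion and its heat is systematically low.
    Optimisation is performed in logK for conditioning; parameter standard
    errors come from the Jacobian at the optimum.
    """
    heats = data.net_heats()
    if len(heats) != schedule.n_injections:
        raise InvalidInputError("heats and schedule length mismatch")
    used = np.ones(len(heats), dtype=bool)
    if discard_first and not data.first_injection_discarded:
        used[0] = False
    if used.sum() < 6:
        raise InsufficientDataError("need at least 6 usable injections")
    temperature = temperature if temperature is not None else schedule.temperature_K

    guess = init if init is not None else _initial_guess(heats, schedule, used)
    x0 = np.array([guess.n, np.log10(guess.K), guess.dH])

    def residuals(x):
        n, logK, dH = x
        model = SingleSiteModel(n=max(n, 1e-9), K=10.0 ** logK, dH=dH)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = wiseman_heats(model, schedule)
        return pred[used] - heats[used]

    res = optimize.least_squares(
        residuals,
        x0,
        bounds=([1e-6, 0.0, -np.inf], [np.inf, 14.0, np.inf]),
        x_scale=[1.0, 1.0, max(abs(x0[2]), 1.0)],
        max_nfev=5000,
    )
    if not res.success:
        raise FitFailureError(
            "single-site fit did not converge",
            {"status": res.status, "message": res.message, "x": res.x.tolist()},
        )
    n_hat, logK_hat, dH_hat = res.x
    model = SingleSiteModel(n=float(n_hat), K=float(10.0 ** logK_hat), dH=float(dH_hat))
    dG, TdS = thermodynamic_decomposition(model.K, model.dH, temperature, R)

    dof = max(int(used.sum()) - 3, 1)
    s2 = float(2 * res.cost / dof)
    J = res.jac
    try:
        cov = np.linalg.inv(J.T @ J) * s2
        se = {k: float(np.sqrt(max(cov[i, i], 0.0)))
              for i, k in enumerate(("n", "logK", "dH"))}
    except np.linalg.LinAlgError:
        se = {k: float("nan") for k in ("n", "logK", "dH")}

    M0 = schedule.cell_conc_mM * 1e-3
    c_value = model.n * model.K * M0
    warns = []
    if not (1.0 <= c_value <= 1000.0):
        msg = f"c = n K M0 = {c_value:.3g} outside [1, 1000]: ill-conditioned fit"
        warns.append(msg)
        warnings.warn(msg, stacklevel=2)

    m = wiseman_heats(model, schedule)
    red_chi2 = float(np.sum((m[used] - heats[used]) ** 2) / dof)
    return SingleSiteFit(
        model=model,
        dG=dG,
        TdS=TdS,
        std_errors=se,
        reduced_chi2=red_chi2,
        c_value=float(c_value),
        n_used=int(used.sum()),
        warnings=warns,
    )


def integrate_thermogram(
    time_s: np.ndarray,
    power_ucal_per_s: np.ndarray,
    injection_times_s: np.ndarray,
    pre_s: float = 30.0,
    post_s: float = 30.0,
) -> np.ndarray:
    """Baseline-corrected per-injection heats from a raw thermogram.

    For each injection window (from its start to the next injection or the
    end of trace), a linear baseline is drawn between the median power of
    the quiescent ``pre_s`` seconds before the injection and the
    ``post_s`` seconds before the window end, then the baseline-subtracted
    power is integrated by the trapezoidal rule.
    """
    time_s = np.asarray(time_s, float)
    power = np.asarray(power_ucal_per_s, float)
    inj = np.asarray(injection_times_s, float)
    if np.any(np.diff(time_s) <= 0):
        raise InvalidInputError("time must be strictly increasing")
    edges = np.concatenate([inj, [time_s[-1]]])
    heats = np.empty(len(inj))
    for i, (t0, t1) in enumerate(zip(edges[:-1], edges[1:])):
        pre = power[(time_s >= t0 - pre_s) & (time_s < t0)]
        post = power[(time_s >= t1 - post_s) & (time_s < t1)]
        b0 = float(np.median(pre)) if pre.size else 0.0
        b1 = float(np.median(post)) if post.size else b0
        sel = (time_s >= t0) & (time_s < t1)
        tt, pp = time_s[sel], power[sel]
        if tt.size < 2:
            heats[i] = 0.0
            continue
        base = b0 + (b1 - b0) * (tt - t0) / max(t1 - t0, 1e-12)
        heats[i] = float(np.trapezoid(pp - base, tt))
    return heats
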