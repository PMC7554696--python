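"""Weighted histogram analysis of umbrella-sampling windows.

Umbrella sampling restrains a scalar reaction coordinate r — here the
separation between an intercalation site (two DNA base pairs) and the
ligand chromophore — with harmonic biases ``U_w(r) = k_w (r - r0_w)^2 / 2``
centred on a ladder of windows.  WHAM combines the biased histograms
``h_w`` into a single unbiased density by iterating the self-consistent
equations

    p(x) = sum_w h_w(x) / sum_w N_w exp[(f_w - U_w(x)) / kT]
    f_w  = -kT ln sum_x p(x) exp(-U_w(x) / kT)

to convergence of the window free-energy offsets ``f_w``; the potential
of mean force is ``F(x) = -kT ln p(x)`` up to an additive constant fixed
by a reference convention (zero at the dissociated plateau, or zero at
the global minimum).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import KT_KCAL_PER_MOL
from .exceptions import ConnectivityError, InvalidInputError

__all__ = [
    "UmbrellaWindow",
    "FreeEnergyProfile",
    "MinimumInfo",
    "wham_solve",
    "set_reference",
    "locate_minimum",
    "profile_difference",
    "binding_free_energy_1d",
    "write_window_file",
    "read_window_file",
    "read_windows",
    "write_profile",
]


@dataclass
class UmbrellaWindow:
    """Biased samples of the reaction coordinate plus the bias definition."""

    center: float               # nm
    force_const: float          # kcal/(mol nm^2)
    samples: np.ndarray         # nm
    label: str = ""
    acceptance_rate: float = float("nan")
    effective_sample_size: float = float("nan")

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.force_const > 0:
            raise InvalidInputError("force constant must be positive")
        if self.samples.size == 0:
            raise InvalidInputError("window has no samples")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidInputError("window samples must be finite")

    def bias(self, x: np.ndarray) -> np.ndarray:
        return 0.5 * self.force_const * (np.asarray(x) - self.center) ** 2


@dataclass
class FreeEnergyProfile:
    bin_centers: np.ndarray     # nm
    F: np.ndarray               # kcal/mol; NaN on empty bins
    window_offsets: np.ndarray  # f_w, kcal/mol
    kT: float
    n_iterations: int
    converged: bool
    reference: str = "min_zero"         # min_zero | plateau_zero
    counts: np.ndarray = field(default=None, repr=False)
    edge_diagnostics: dict = field(default_factory=dict, repr=False)
    self_consistency_residual: float = float("nan")

    def sampled_mask(self, min_counts: int = 1) -> np.ndarray:
        return self.counts >= min_counts


@dataclass
class MinimumInfo:
    r_min: float
    depth: float
    at_boundary: bool


def _histograms(windows, edges):
    H = np.empty((len(windows), len(edges) - 1))
    edge_diag = {}
    for i, w in enumerate(windows):
        H[i], _ = np.histogram(w.samples, bins=edges)
        below = int(np.sum(w.samples < edges[0]))
        above = int(np.sum(w.samples > edges[-1]))
        if below or above:
            edge_diag[w.label or f"window_{i}"] = {"below": below, "above": above}
    return H, edge_diag


def _check_connectivity(windows, H):
    order = np.argsort([w.center for w in windows])
    occupied = H > 0
    for a, b in zip(order[:-1], order[1:]):
        if not np.any(occupied[a] & occupied[b]):
            na = windows[a].label or f"window at {windows[a].center:g} nm"
            nb = windows[b].label or f"window at {windows[b].center:g} nm"
            raise ConnectivityError(
                f"no shared occupied bins between {na} and {nb}: "
                "histograms do not overlap"
            )


def wham_solve(
    windows: list[UmbrellaWindow],
    bins: dict | None = None,
    kT: float = KT_KCAL_PER_MOL,
    tol: float = 1e-6,
    max_iter: int = 100_000,
) -> FreeEnergyProfile:
    """Self-consistent WHAM solution on a uniform grid.

    Parameters
    ----------
    windows:
        Umbrella windows (>= 2) with harmonic bias metadata.
    bins:
        ``{"min": nm, "max": nm, "width": nm}``; defaults to the sample
        range padded by one bin with width 0.02 nm.
    kT:
        Thermal energy in kcal/mol.
    tol:
        Convergence threshold on ``max_w |delta f_w|`` in kcal/mol.
    max_iter:
        Direct-iteration cap; exceeding it returns ``converged=False``
        rather than raising.

    Samples falling outside the bin range are not silently dropped: they
    are counted into ``edge_diagnostics`` per window.
    """
    if len(windows) < 1:
        raise InvalidInputError("need at least one window")
    if bins is None:
        lo = min(w.samples.min() for w in windows)
        hi = max(w.samples.max() for w in windows)
        bins = {"min": lo - 0.02, "max": hi + 0.02, "width": 0.02}
    width = float(bins["width"])
    if width <= 0:
        raise InvalidInputError("bin width must be positive")
    edges = np.arange(bins["min"], bins["max"] + width / 2, width)
    centers = 0.5 * (edges[:-1] + edges[1:])

    H, edge_diag = _histograms(windows, edges)
    if len(windows) > 1:
        _check_connectivity(windows, H)

    N = np.array([w.samples.size for w in windows], dtype=float)
    U = np.stack([w.bias(centers) for w in windows])       # (W, B)
    C = np.exp(-U / kT)                                    # bias Boltzmann factors
    Htot = H.sum(axis=0)

    f = np.zeros(len(windows))
    n_it = 0
    converged = False
    for n_it in range(1, max_iter + 1):
        denom = (N * np.exp(f / kT)) @ C                   # (B,)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, Htot / denom, 0.0)
        z = C @ p                                          # (W,)
        f_new = -kT * np.log(z)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            converged = True
            break

    denom = (N * np.exp(f / kT)) @ C
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(denom > 0, Htot / denom, 0.0)
    residual = float(np.max(np.abs(-kT * np.log(C @ p) - (-kT * np.log(C @ p))[0] - f)))

    with np.errstate(divide="ignore"):
        F = np.where(p > 0, -kT * np.log(np.where(p > 0, p, 1.0)), np.nan)
    finite = np.isfinite(F)
    if finite.any():
        F = F - np.nanmin(F)
    profile = FreeEnergyProfile(
        bin_centers=centers,
        F=F,
        window_offsets=f,
        kT=kT,
        n_iterations=n_it,
        converged=converged,
        reference="min_zero",
        counts=Htot,
        edge_diagnostics=edge_diag,
        self_consistency_residual=residual,
    )
    if not converged:
        warnings.warn(
            f"WHAM did not converge in {max_iter} iterations "
            f"(last |delta f| = {residual:.2e})",
            stacklevel=2,
        )
    return profile


def set_reference(
    profile: FreeEnergyProfile,
    plateau_region: tuple[float, float],
    slope_warning_threshold: float = 1.0,
) -> FreeEnergyProfile:
    """Re-zero the profile on the mean F over a dissociated plateau.

    Warns when the plateau region has a residual slope above
    ``slope_warning_threshold`` (kcal/mol per nm), which indicates the
    chosen region is not actually flat.
    """
    lo, hi = plateau_region
    sel = (profile.bin_centers >= lo) & (profile.bin_centers <= hi) & np.isfinite(profile.F)
    if sel.sum() < 3:
        raise InvalidInputError("plateau region must contain at least 3 finite bins")
    x, y = profile.bin_centers[sel], profile.F[sel]
    slope = float(np.polyfit(x, y, 1)[0]) if len(x) > 1 else 0.0
    if abs(slope) > slope_warning_threshold:
        warnings.warn(
            f"plateau region has slope {slope:.2f} kcal/mol/nm: not flat",
            stacklevel=2,
        )
    return replace(profile, F=profile.F - float(np.mean(y)), reference="plateau_zero")


def locate_minimum(
    profile: FreeEnergyProfile,
    search_region: tuple[float, float] | None = None,
) -> MinimumInfo:
    """Argmin of F with parabolic sub-bin refinement.

    Ties are broken toward smaller r (numpy argmin convention on the
    ordered grid).  A minimum on the region boundary sets
    ``at_boundary=True`` instead of refining.
    """
    x, F = profile.bin_centers, profile.F
    sel = np.isfinite(F)
    if search_region is not None:
        sel &= (x >= search_region[0]) & (x <= search_region[1])
    if not sel.any():
        raise InvalidInputError("no finite bins in search region")
    idx_all = np.flatnonzero(sel)
    i = idx_all[np.argmin(F[sel])]
    at_boundary = i == idx_all[0] or i == idx_all[-1]
    if at_boundary or not (np.isfinite(F[i - 1]) and np.isfinite(F[i + 1])):
        return MinimumInfo(r_min=float(x[i]), depth=float(F[i]), at_boundary=at_boundary)
    # Parabola through the three bracketing bins.
    y0, y1, y2 = F[i - 1], F[i], F[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom <= 0:
        return MinimumInfo(r_min=float(x[i]), depth=float(F[i]), at_boundary=False)
    h = x[i + 1] - x[i]
    shift = 0.5 * (y0 - y2) / denom
    r_min = float(x[i] + shift * h)
    depth = float(y1 - 0.25 * (y0 - y2) * shift)
    return MinimumInfo(r_min=r_min, depth=depth, at_boundary=False)


def profile_difference(
    profile_a: FreeEnergyProfile,
    profile_b: FreeEnergyProfile,
    at: str = "min_depth",
    search_region: tuple[float, float] | None = None,
) -> float:
    """``depth(a) - depth(b)`` at the profile minima (shared reference)."""
    if profile_a.reference != profile_b.reference:
        raise InvalidInputError("profiles must share the reference convention")
    if at != "min_depth":
        raise InvalidInputError(f"unknown comparison point {at!r}")
    da = locate_minimum(profile_a, search_region).depth
    db = locate_minimum(profile_b, search_region).depth
    return da - db


def binding_free_energy_1d(
    profile: FreeEnergyProfile,
    bound_region: tuple[float, float],
    reference_region: tuple[float, float],
) -> float:
    """Convention-dependent 1-D bound/unbound free-energy ratio.

    Computes ``-kT ln[ int_bound exp(-F/kT) dr / int_ref exp(-F/kT) dr ]``
    with user-declared regions.  This is NOT a standard-state absolute
    binding free energy: it carries no volume correction and depends on
    the declared regions; it is provided for qualitative comparisons only.
    """
    x, F, kT = profile.bin_centers, profile.F, profile.kT

    def integral(region):
        sel = (x >= region[0]) & (x <= region[1]) & np.isfinite(F)
        if not sel.any():
            raise InvalidInputError(f"region {region} has no finite bins")
        return float(np.sum(np.exp(-F[sel] / kT)))

    return -kT * float(np.log(integral(bound_region) / integral(reference_region)))


# ---------------------------------------------------------------------------
# plain-text I/O (pull-coordinate style window files, profile CSV + JSON)

def write_window_file(window: UmbrellaWindow, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# umbrella window {window.label}\n")
        fh.write(f"# center_nm {window.center}\n")
        fh.write(f"# force_const_kcal_mol_nm2 {window.force_const}\n")
        for i, r in enumerate(window.samples):
            fh.write(f"{i} {r:.8g}\n")


def read_window_file(path, center: float, force_const: float, label: str = "") -> UmbrellaWindow:
    data = np.loadtxt(path, comments="#")
    samples = data[:, 1] if data.ndim == 2 else np.atleast_1d(data)
    return UmbrellaWindow(
        center=center, force_const=force_const, samples=samples,
        label=label or Path(path).stem,
    )


def read_windows(metadata_path) -> list[UmbrellaWindow]:
    """Load windows from a YAML metadata file.

    Schema::

        windows:
          - file: window_00.dat     # relative to the metadata file
            center_nm: 0.2
            force_const_kcal_mol_nm2: 143.05
    """
    meta_path = Path(metadata_path)
    meta = yaml.safe_load(meta_path.read_text())
    out = []
    for entry in meta["windows"]:
        out.append(
            read_window_file(
                meta_path.parent / entry["file"],
                center=float(entry["center_nm"]),
                force_const=float(entry["force_const_kcal_mol_nm2"]),
            )
        )
    return out


def write_profile(profile: FreeEnergyProfile, csv_path, json_path=None) -> None:
    pd.DataFrame({"r_nm": profile.bin_centers, "F_kcal_mol": profile.F}).to_csv(
        csv_path, index=False
    )
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps(
                {
                    "kT_kcal_mol": profile.kT,
                    "n_iterations": profile.n_iterations,
                    "converged": profile.converged,
                    "reference": profile.reference,
                    "window_offsets_kcal_mol": profile.window_offsets.tolist(),
                    "self_consistency_residual": profile.self_consistency_residual,
                    "edge_diagnostics": profile.edge_diagnostics,
                },
                indent=2,
            )
        )
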