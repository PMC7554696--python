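"""Benesi-Hildebrand analysis of absorbance titrations.

A planar aromatic ligand L (here an anthracycline chromophore) forming a
1:1 complex with double-stranded DNA changes its molar extinction
coefficient from ``eps_f`` (free) to ``eps_b`` (bound).  For a titration
at fixed total ligand and increasing [DNA], the Benesi-Hildebrand
linearization reads

    A0 / (A - A0) = eps_f/(eps_b - eps_f) + eps_f/(eps_b - eps_f) * 1/(K_A [DNA])

so that a straight-line fit of ``A0/(A - A0)`` against ``1/[DNA]`` yields
the association constant as intercept/slope, and the binding free energy
follows from ``dG = -R T ln K_A``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constants import R_KCAL_PER_MOL_K, T_STANDARD
from .exceptions import InsufficientDataError, InvalidInputError, NonBindingSignalError

__all__ = [
    "TitrationSeries",
    "BenesiHildebrandFit",
    "benesi_hildebrand_fit",
    "gibbs_from_binding_constant",
]


@dataclass
class TitrationSeries:
    """Absorbance titration at fixed total ligand concentration.

    Parameters
    ----------
    ligand_total:
        Total chromophore concentration in M (constant during titration).
    dna_concs:
        Titrant (dsDNA) concentrations in M, strictly increasing, > 0.
    absorbances:
        Absorbance at each titrant concentration (1 cm path).
    A0:
        Absorbance at zero titrant.
    wavelength:
        Observation wavelength in nm (metadata only).
    """

    ligand_total: float
    dna_concs: np.ndarray
    absorbances: np.ndarray
    A0: float
    wavelength: float = 480.0

    def __post_init__(self):
        self.dna_concs = np.asarray(self.dna_concs, dtype=float)
        self.absorbances = np.asarray(self.absorbances, dtype=float)
        if self.dna_concs.shape != self.absorbances.shape:
            raise InvalidInputError("dna_concs and absorbances must have equal length")
        if self.dna_concs.size < 3:
            raise InsufficientDataError("need at least 3 titration points")
        if np.any(self.dna_concs <= 0):
            raise InvalidInputError("titrant concentrations must be > 0")
        if np.any(np.diff(self.dna_concs) <= 0):
            raise InvalidInputError("titrant concentrations must be strictly increasing")
        if not self.A0 > 0:
            raise InvalidInputError("A0 must be positive")

    def to_csv(self, path) -> None:
        """Write ``dna_conc_M, absorbance`` rows; A0 is the [DNA]=0 row."""
        df = pd.DataFrame(
            {
                "dna_conc_M": np.concatenate([[0.0], self.dna_concs]),
                "absorbance": np.concatenate([[self.A0], self.absorbances]),
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, ligand_total: float = float("nan"), wavelength: float = 480.0):
        df = pd.read_csv(path)
        for col in ("dna_conc_M", "absorbance"):
            if col not in df.columns:
                raise InvalidInputError(f"missing required column {col!r}")
        zero = df[df["dna_conc_M"] == 0.0]
        if zero.empty:
            raise InvalidInputError("CSV must contain a dna_conc_M = 0 row defining A0")
        rest = df[df["dna_conc_M"] > 0.0].sort_values("dna_conc_M")
        return cls(
            ligand_total=ligand_total,
            dna_concs=rest["dna_conc_M"].to_numpy(),
            absorbances=rest["absorbance"].to_numpy(),
            A0=float(zero["absorbance"].iloc[0]),
            wavelength=wavelength,
        )


@dataclass
class BenesiHildebrandFit:
    """Result of the linearized 1:1 complexation fit."""

    K_A: float
    slope: float
    intercept: float
    r_squared: float
    eps_ratio: float
    delta_G: float
    temperature: float
    residuals: np.ndarray = field(repr=False, default=None)
    excluded_points: np.ndarray = field(repr=False, default=None)


def gibbs_from_binding_constant(
    K: float,
    temperature: float = T_STANDARD,
    R: float = R_KCAL_PER_MOL_K,
) -> float:
    """Binding free energy ``dG = -R T ln K`` in kcal/mol.

    Strictly decreasing in K; K = 1 maps to 0 (the standard-state
    convention of a unit association constant).
    """
    if not K > 0:
        raise InvalidInputError("binding constant must be positive")
    if not temperature > 0:
        raise InvalidInputError("temperature must be positive")
    return -R * temperature * float(np.log(K))


def benesi_hildebrand_fit(
    series: TitrationSeries,
    temperature: float = T_STANDARD,
    R: float = R_KCAL_PER_MOL_K,
    exclusion_floor: float = 1e-4,
) -> BenesiHildebrandFit:
    """Fit ``A0/(A - A0)`` vs ``1/[DNA]`` by ordinary least squares.

    Points with ``|A - A0|`` below ``exclusion_floor`` are excluded from
    the regression (the transform divides by A - A0, so points where
    binding has produced no measurable change contribute only noise);
    their indices are reported on the result.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 usable points after exclusion.
    NonBindingSignalError
        Slope or intercept non-positive (K_A undefined).
    """
    dA = series.absorbances - series.A0
    usable = np.abs(dA) >= exclusion_floor
    excluded = np.flatnonzero(~usable)
    if usable.sum() < 3:
        raise InsufficientDataError(
            f"only {int(usable.sum())} points with |A - A0| >= {exclusion_floor}"
        )
    # The absolute change |A - A0| is used so that hypochromic (eps_b <
    # eps_f) and hyperchromic titrations are handled identically; K_A =
    # intercept/slope is invariant to the common sign.
    x = 1.0 / series.dna_concs[usable]
    y = series.A0 / np.abs(dA[usable])
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    if slope <= 0 or intercept <= 0:
        raise NonBindingSignalError(
            f"non-binding signal: slope={slope:.4g}, intercept={intercept:.4g}"
        )
    K_A = intercept / slope
    return BenesiHildebrandFit(
        K_A=K_A,
        slope=slope,
        intercept=intercept,
        r_squared=float(res.rvalue) ** 2,
        eps_ratio=intercept,
        delta_G=gibbs_from_binding_constant(K_A, temperature, R),
        temperature=temperature,
        residuals=y - (slope * x + intercept),
        excluded_points=excluded,
    )
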