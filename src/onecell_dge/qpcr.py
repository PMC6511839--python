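"""Absolute quantification utilities for qPCR calibration.

Copy numbers of plasmid standards are derived from mass using 615 Da per
base pair of double-stranded DNA; standard curves are fit as crossing
point (Cp) against log10 template concentration; missing transcript-level
measurements are imputed as one tenth of the per-transcript minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AVOGADRO",
    "DALTON_PER_BP",
    "copies_from_mass",
    "StandardCurve",
    "fit_standard_curve",
    "quantify",
    "impute_missing",
    "sample_sd",
]

AVOGADRO = 6.02214076e23  # SI-exact, mol^-1
DALTON_PER_BP = 615.0     # g/mol per base pair of dsDNA


def copies_from_mass(plasmid_bp: int, mass_g: float) -> float:
    """Copy number of a double-stranded plasmid from its mass in grams.

    ``copies = mass / (bp × 615 / N_A)`` — linear in mass, inverse-linear
    in plasmid size.
    """
    if plasmid_bp <= 0:
        raise ValueError("plasmid size must be positive")
    if mass_g < 0:
        raise ValueError("mass must be non-negative")
    molecule_mass = plasmid_bp * DALTON_PER_BP / AVOGADRO
    return mass_g / molecule_mass


@dataclass(frozen=True)
class StandardCurve:
    """Linear Cp vs log10(concentration) calibration.

    A valid qPCR dilution series has a negative slope (about −3.32 per
    decade at 100% amplification efficiency).
    """

    slope: float
    intercept: float
    r2: float
    unit: str = "pg/ul"

    @property
    def efficiency(self) -> float:
        """Amplification efficiency implied by the slope (1.0 = perfect doubling)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


def fit_standard_curve(dilution_concs, cp_values, unit: str = "pg/ul") -> StandardCurve:
    """Least squares of Cp on log10(concentration) over a dilution series."""
    conc = np.asarray(dilution_concs, dtype=float)
    cp = np.asarray(cp_values, dtype=float)
    if conc.size != cp.size or conc.size < 3:
        raise ValueError("need at least 3 paired dilution points")
    if (conc <= 0).any():
        raise ValueError("concentrations must be positive")
    x = np.log10(conc)
    if np.unique(x).size < 2:
        raise ValueError("degenerate design: a single concentration")
    fit = sps.linregress(x, cp)
    return StandardCurve(slope=float(fit.slope), intercept=float(fit.intercept),
                         r2=float(fit.rvalue ** 2), unit=unit)


def quantify(cp: float, curve: StandardCurve) -> float:
    """Invert the standard curve: concentration for an observed Cp."""
    if curve.slope == 0:
        raise ValueError("flat standard curve cannot be inverted")
    return float(10.0 ** ((cp - curve.intercept) / curve.slope))


def impute_missing(values: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """Replace missing transcript-level values by one tenth of the row minimum.

    ``values`` is transcripts × replicates (or a single transcript Series);
    imputation is per transcript.  A transcript with no observed value at
    all is an error.
    """
    if isinstance(values, pd.Series):
        return impute_missing(values.to_frame().T).iloc[0]
    out = values.astype(float).copy()
    for idx, row in out.iterrows():
        if row.isna().all():
            raise ValueError(f"transcript {idx!r} has no observed values")
        if row.isna().any():
            out.loc[idx] = row.fillna(row.min() / 10.0)
    return out


def sample_sd(values) -> float:
    """Sample standard deviation (n − 1 denominator)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("sample sd needs at least 2 observations")
    return float(np.std(v, ddof=1))
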