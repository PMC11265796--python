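"""Absolute copy-number estimation and molar-ratio reporting.

RNA copies per cell come from a qPCR standard curve: Ct regressed on
log10(input copies) over a serial dilution of a known DNA fragment gives a
slope (cycles per decade) whose implied amplification efficiency is
E = 10^(-1/slope) (a perfect doubling gives slope -3.3219, E = 2).  A sample
Ct is inverted through the curve to copies in the reaction, then divided by
the number of cell-equivalents assayed (cells x assayed fraction).

Protein copies per cell come from calibrated densitometry: band intensity
regressed on known loaded mass inverts a sample intensity to nanograms,
converted to molecules via the molecular weight and Avogadro's number.

The X0 method gives relative RNA levels from raw Cts: X0 = E^(-Ct),
ratioed between target and reference.

The molar-ratio report flags a simple 1:1 competing-endogenous-RNA model as
implausible when protein outnumbers RNA by more than a threshold (default
100-fold).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "StandardCurve",
    "CopyEstimate",
    "ProteinCalibration",
    "fit_standard_curve",
    "copies_per_cell",
    "x0_relative",
    "fit_protein_calibration",
    "protein_copies_per_cell",
    "molar_ratio_report",
]

log = logging.getLogger(__name__)

AVOGADRO = 6.02214076e23
EFFICIENCY_SANITY = (1.0, 2.2)  # warn outside; E > 2 means super-doubling


@dataclass
class StandardCurve:
    """Ct = slope * log10(copies) + intercept; efficiency = 10^(-1/slope)."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("standard-curve slope must be negative (more input -> fewer cycles)")
        lo, hi = EFFICIENCY_SANITY
        if not (lo < self.efficiency <= hi):
            log.warning("amplification efficiency %.3f outside sanity band (%g, %g]",
                        self.efficiency, lo, hi)

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope)

    def ct_to_copies(self, ct: float) -> float:
        return 10.0 ** ((ct - self.intercept) / self.slope)

    def copies_to_ct(self, copies: float) -> float:
        return self.slope * math.log10(copies) + self.intercept


@dataclass
class CopyEstimate:
    molecules_per_cell: float
    ci_low: float
    ci_high: float
    n_replicates: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.molecules_per_cell <= self.ci_high):
            raise ValueError("CI must bracket the estimate")
        if self.ci_low < 0:
            self.ci_low = 0.0


def fit_standard_curve(copies, ct) -> StandardCurve:
    """Least-squares fit of Ct against log10(copies) over >= 3 dilution points."""
    copies = np.asarray(copies, dtype=float)
    ct = np.asarray(ct, dtype=float)
    if copies.shape != ct.shape or copies.size < 3:
        raise ValueError("need >= 3 (copies, Ct) points")
    if np.any(copies <= 0):
        raise ValueError("copies must be strictly positive")
    x = np.log10(copies)
    if np.unique(x).size < 2:
        raise ValueError("zero variance in copies")
    fit = stats.linregress(x, ct)
    return StandardCurve(slope=float(fit.slope), intercept=float(fit.intercept),
                         r_squared=float(fit.rvalue**2))


def copies_per_cell(
    ct_sample,
    curve: StandardCurve,
    n_cells: float,
    assay_fraction: float,
    confidence: float = 0.95,
) -> CopyEstimate:
    """Invert replicate sample Cts through the curve and normalise per cell.

    Replicates are averaged on the linear copy scale (copies, not Ct, are the
    quantity of interest); the CI is a t-interval over replicate copy
    estimates, collapsing to the point for a single replicate.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be > 0")
    if not (0.0 < assay_fraction <= 1.0):
        raise ValueError("assay_fraction must be in (0, 1]")
    cts = np.atleast_1d(np.asarray(ct_sample, dtype=float))
    cell_equivalents = n_cells * assay_fraction
    per_cell = np.array([curve.ct_to_copies(c) for c in cts]) / cell_equivalents
    est = float(per_cell.mean())
    n = per_cell.size
    if n > 1 and per_cell.std(ddof=1) > 0:
        half = stats.t.ppf(0.5 + confidence / 2, df=n - 1) * per_cell.std(ddof=1) / math.sqrt(n)
        lo, hi = max(0.0, est - half), est + half
    else:
        lo = hi = est
    return CopyEstimate(est, lo, hi, n)


def x0_relative(ct_target: float, ct_reference: float, efficiency: float) -> float:
    """Relative RNA level by the X0 method: E^(-Ct_target) / E^(-Ct_reference)."""
    if efficiency <= 1.0:
        raise ValueError("efficiency must be > 1")
    return efficiency ** (ct_reference - ct_target)


@dataclass
class ProteinCalibration:
    """intensity = slope * mass_ng + intercept, from known loaded amounts."""

    slope: float
    intercept: float
    molecular_weight: float  # g/mol, supplied by the user
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if self.molecular_weight <= 0:
            raise ValueError("molecular weight must be positive")

    def intensity_to_ng(self, intensity: float) -> float:
        mass = (intensity - self.intercept) / self.slope
        if mass < 0:
            log.warning("back-computed mass %.3g ng < 0; clamped to 0", mass)
            mass = 0.0
        return mass


def fit_protein_calibration(mass_ng, intensity, molecular_weight: float) -> ProteinCalibration:
    """Linear densitometry calibration from >= 3 known masses (e.g. a BSA ladder)."""
    mass_ng = np.asarray(mass_ng, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mass_ng.size < 3:
        raise ValueError("need >= 3 calibration points")
    fit = stats.linregress(mass_ng, intensity)
    return ProteinCalibration(slope=float(fit.slope), intercept=float(fit.intercept),
                              molecular_weight=molecular_weight,
                              r_squared=float(fit.rvalue**2))


def protein_copies_per_cell(
    sample_intensity,
    calibration: ProteinCalibration,
    n_cells: float,
    confidence: float = 0.95,
) -> CopyEstimate:
    """Band intensity -> ng -> molecules (Avogadro) -> per cell."""
    if n_cells <= 0:
        raise ValueError("n_cells must be > 0")
    intensities = np.atleast_1d(np.asarray(sample_intensity, dtype=float))
    per_cell = np.array(
        [
            calibration.intensity_to_ng(i) * 1e-9 / calibration.molecular_weight * AVOGADRO / n_cells
            for i in intensities
        ]
    )
    est = float(per_cell.mean())
    n = per_cell.size
    if n > 1 and per_cell.std(ddof=1) > 0:
        half = stats.t.ppf(0.5 + confidence / 2, df=n - 1) * per_cell.std(ddof=1) / math.sqrt(n)
        lo, hi = max(0.0, est - half), est + half
    else:
        lo = hi = est
    return CopyEstimate(est, lo, hi, n)


def molar_ratio_report(
    rna: CopyEstimate, protein: CopyEstimate, implausibility_threshold: float = 100.0
) -> dict:
    """Protein:RNA molar ratio and the 1:1 ceRNA plausibility verdict.

    A zero RNA estimate yields an infinite ratio with its own flag.
    """
    if rna.molecules_per_cell == 0:
        return {
            "protein_per_rna": math.inf,
            "log10_ratio": math.inf,
            "one_to_one_cerna_implausible": True,
            "zero_rna_estimate": True,
        }
    ratio = protein.molecules_per_cell / rna.molecules_per_cell
    return {
        "protein_per_rna": ratio,
        "log10_ratio": math.log10(ratio) if ratio > 0 else -math.inf,
        "one_to_one_cerna_implausible": ratio > implausibility_threshold,
        "zero_rna_estimate": False,
    }
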