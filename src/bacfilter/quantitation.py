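"""ATP-based biomass quantitation and qPCR anchoring of ASV abundances.

Two independent biomass proxies are combined here:

* Luminometric ATP assays on wet GAC. Luminescence is converted to an ATP
  concentration through a linear calibration curve fitted on standards, and
  ATP mass to cell equivalents through a fixed cellular ATP content
  ``F`` (default 8.9e-17 g ATP per cell).
* 16S rRNA gene qPCR totals. Per-sample relative ASV abundances are scaled
  by the sample's total copy number, yielding absolute abundances in
  16S copies per g wet GAC. No correction for 16S copy number per genome is
  applied (a documented limitation: totals are gene copies, not genomes).

The two proxies are expected to agree up to noise; :func:`correlate_biomass`
quantifies that agreement with a Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ATP_G_PER_CELL",
    "AtpCalibration",
    "fit_atp_calibration",
    "atp_to_cells",
    "absolute_abundance",
    "correlate_biomass",
    "depth_cell_density",
]

#: Cellular ATP content used to convert ATP mass to cell equivalents (g/cell).
ATP_G_PER_CELL = 8.9e-17


@dataclass(frozen=True)
class AtpCalibration:
    """Linear luminescence -> ATP-concentration calibration.

    ``luminescence = slope * concentration + intercept`` fitted by ordinary
    least squares on standards; inverted for queries. ``x_range`` is the
    concentration range spanned by the standards — queries mapping outside
    it set an extrapolation flag instead of failing silently.
    """

    slope: float
    intercept: float
    r_squared: float
    x_range: tuple[float, float]
    atp_per_cell: float = ATP_G_PER_CELL

    def __post_init__(self):
        if not self.slope > 0:
            raise ValueError("calibration slope must be positive")
        if not self.atp_per_cell > 0:
            raise ValueError("atp_per_cell must be positive")

    def luminescence_to_concentration(self, rlu) -> tuple[np.ndarray, np.ndarray]:
        """Invert the calibration line.

        Returns ``(concentration, extrapolated)`` where ``extrapolated``
        flags queries outside the standards' concentration range.
        """
        rlu = np.asarray(rlu, dtype=float)
        conc = (rlu - self.intercept) / self.slope
        lo, hi = self.x_range
        extrapolated = (conc < lo) | (conc > hi)
        return conc, extrapolated


def fit_atp_calibration(
    standards, atp_per_cell: float = ATP_G_PER_CELL
) -> AtpCalibration:
    """OLS line through ``(known ATP concentration, luminescence)`` standards.

    Requires at least 3 standards with non-degenerate concentrations
    (standards should span about a decade, e.g. 0.005-1 uM).
    """
    arr = np.asarray(standards, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("standards must be (concentration, luminescence) pairs")
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 calibration standards")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("calibration standards have zero concentration variance")
    res = stats.linregress(x, y)
    return AtpCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        x_range=(float(x.min()), float(x.max())),
        atp_per_cell=atp_per_cell,
    )


def atp_to_cells(atp_mass, cal: AtpCalibration | None = None, atp_per_cell: float | None = None):
    """Convert grams ATP (per g wet GAC) to cell equivalents (per g wet GAC).

    Pure division by the cellular ATP content; linear and scale-equivariant.
    """
    f = atp_per_cell if atp_per_cell is not None else (
        cal.atp_per_cell if cal is not None else ATP_G_PER_CELL
    )
    atp = np.asarray(atp_mass, dtype=float)
    if (atp < 0).any():
        raise ValueError("ATP mass must be non-negative")
    out = atp / f
    if np.isscalar(atp_mass) or np.ndim(atp_mass) == 0:
        return float(out)
    if isinstance(atp_mass, pd.Series):
        return pd.Series(out, index=atp_mass.index, name="cells_per_g")
    return out


def absolute_abundance(rel: pd.DataFrame, qpcr: pd.Series) -> pd.DataFrame:
    """Anchor relative abundances to qPCR totals.

    ``rel`` is taxa x samples with per-sample proportions; ``qpcr`` maps
    sample id -> total 16S copies. Each output column is the relative
    column scaled by the sample total, so column sums reproduce the qPCR
    totals exactly (conservation). All-zero relative columns produce
    all-zero output columns with a warning.
    """
    missing = [s for s in rel.columns if s not in qpcr.index]
    if missing:
        raise KeyError(f"samples missing a qPCR total: {missing}")
    colsums = rel.sum(axis=0)
    zero = colsums[colsums == 0].index.tolist()
    if zero:
        warnings.warn(f"all-zero relative-abundance column(s): {zero}")
    ok = colsums.replace(0, 1)
    # renormalise defensively so conservation holds to float tolerance even
    # if the input proportions carry rounding error
    return rel.div(ok, axis=1).mul(qpcr.reindex(rel.columns), axis=1)


def correlate_biomass(
    atp_cells: pd.Series, qpcr: pd.Series, log10: bool = False
) -> tuple[float, float]:
    """Pearson correlation between ATP-derived cells and qPCR totals.

    Matches the two series on shared sample ids; ``log10=True`` correlates
    log-transformed values (both proxies must then be positive).
    """
    shared = atp_cells.index.intersection(qpcr.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 paired samples, have {len(shared)}")
    x = atp_cells.loc[shared].to_numpy(float)
    y = qpcr.loc[shared].to_numpy(float)
    if log10:
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("log10 correlation requires strictly positive values")
        x, y = np.log10(x), np.log10(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the series")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def depth_cell_density(
    atp: pd.Series, meta: pd.DataFrame, profile, cal: AtpCalibration | None = None
) -> pd.DataFrame:
    """Replicate-averaged cell densities per (day, depth section).

    ``atp`` holds grams ATP per g wet GAC per filter sample. Samples are
    assigned to bed sections via their ``depth_cm`` and averaged
    (arithmetic mean) over replicates within each day x section cell.
    Returns a DataFrame indexed by day with one column per section label,
    in cells per g wet GAC.
    """
    filt = meta[meta["compartment"] == "filter"]
    shared = atp.index.intersection(filt.index)
    if len(shared) == 0:
        raise ValueError("no filter samples with ATP measurements")
    cells = atp_to_cells(atp.loc[shared], cal=cal)
    sect = filt.loc[shared, "depth_cm"].map(profile.section_for_depth)
    df = pd.DataFrame(
        {"day": filt.loc[shared, "day"], "section": sect, "cells": cells}
    )
    wide = df.groupby(["day", "section"])["cells"].mean().unstack("section")
    return wide.reindex(columns=list(profile.labels))
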