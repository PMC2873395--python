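"""PCR amplification efficiency from a dilution series.

A standard curve plots Cq against log10 template input for a serial dilution.
Ordinary least squares gives the slope b (cycles per log10 input); the
amplification efficiency in percent is

    E = (10^(-1/b) - 1) x 100

so perfect doubling per cycle (b = -1/log10 2 ≈ -3.3219) gives E = 100%.
The amplification factor used for relative quantification is 1 + E/100.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, ValidationError


@dataclass
class DilutionSeries:
    """(log10 input, Cq) pairs for one assay's standard curve."""

    assay_id: str
    log10_input: np.ndarray
    cq: np.ndarray

    def __post_init__(self) -> None:
        self.log10_input = np.asarray(self.log10_input, dtype=float)
        self.cq = np.asarray(self.cq, dtype=float)
        if self.log10_input.shape != self.cq.shape:
            raise ValidationError("log10_input and cq must have equal length")
        if len(self.log10_input) < 3:
            raise ValidationError("a dilution series needs at least 3 points")
        if np.allclose(self.log10_input, self.log10_input[0]):
            raise ValidationError("log10_input values are all equal; no dilution range")


@dataclass
class EfficiencyFit:
    assay_id: str
    slope: float
    intercept: float
    r_squared: float
    efficiency_percent: float
    amplification_factor: float


def efficiency_from_slope(slope: float) -> float:
    """E (%) from a standard-curve slope: (10^(-1/slope) - 1) x 100."""
    if slope >= 0:
        raise FitError(f"slope {slope:.4g} >= 0: no amplification signal")
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


def fit_standard_curve(series: DilutionSeries) -> EfficiencyFit:
    """OLS fit of Cq on log10 input; efficiency and amplification factor.

    Raises FitError when the slope is non-negative (no amplification signal).
    """
    res = stats.linregress(series.log10_input, series.cq)
    e = efficiency_from_slope(res.slope)
    return EfficiencyFit(
        assay_id=series.assay_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        efficiency_percent=e,
        amplification_factor=1.0 + e / 100.0,
    )


def load_dilution_series(path: str | Path) -> list[DilutionSeries]:
    """Read dilution series from CSV (assay_id, log10_input, cq), one per assay."""
    table = pd.read_csv(path, comment="#")
    for col in ("assay_id", "log10_input", "cq"):
        if col not in table.columns:
            raise ValidationError(f"dilution series file missing column {col!r}")
    out = []
    for assay, sub in table.groupby("assay_id", sort=True):
        out.append(
            DilutionSeries(
                assay_id=str(assay),
                log10_input=sub["log10_input"].to_numpy(float),
                cq=sub["cq"].to_numpy(float),
            )
        )
    return out


def fits_to_frame(fits: list[EfficiencyFit]) -> pd.DataFrame:
    return pd.DataFrame([vars(f) for f in fits])
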