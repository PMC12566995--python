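"""Assay-level arithmetic feeding the designed-experiment responses.

Covers the DPPH radical-scavenging percentage, the Folin–Ciocalteu
gallic-acid calibration line and total phenolic content (TPC) in
mg gallic-acid equivalents per gram of extract, the cytotoxicity
selectivity index, and the predicted-vs-observed relative error used for
model validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import AssayError, CalibrationError, InputError

__all__ = [
    "AssayReading",
    "CalibrationCurve",
    "CytotoxRecord",
    "dpph_inhibition",
    "fit_calibration",
    "tpc_from_absorbance",
    "selectivity_index",
    "relative_error",
]


@dataclass(frozen=True)
class AssayReading:
    """One spectrophotometric reading with its dilution bookkeeping.

    ``extract_conc`` is the concentration of the prepared extract solution
    in mg/mL; ``dilution_factor`` is the factor by which it was diluted
    before the reaction (>= 1).
    """

    absorbance_sample: float
    absorbance_control: float | None = None
    dilution_factor: float = 1.0
    extract_conc: float | None = None

    def __post_init__(self) -> None:
        if self.absorbance_sample < 0:
            raise AssayError(f"sample absorbance must be >= 0, got {self.absorbance_sample}")
        if self.dilution_factor < 1:
            raise AssayError(f"dilution factor must be >= 1, got {self.dilution_factor}")


@dataclass(frozen=True)
class CalibrationCurve:
    """Least-squares line absorbance = slope * conc(mg/L) + intercept."""

    slope: float
    intercept: float
    r2: float
    n_points: int
    conc_range: tuple[float, float]


@dataclass(frozen=True)
class CytotoxRecord:
    """IC50 (µg/mL) of an extract on one cell line, with CI and selectivity index."""

    cell_line: str
    ic50: float
    ci_low: float
    ci_high: float
    si: float

    def __post_init__(self) -> None:
        if not self.ic50 > 0:
            raise InputError(f"IC50 must be > 0, got {self.ic50}")
        if not self.ci_low <= self.ic50 <= self.ci_high:
            raise InputError(
                f"{self.cell_line}: IC50 {self.ic50} outside CI [{self.ci_low}, {self.ci_high}]"
            )


def dpph_inhibition(reading: AssayReading) -> float:
    """Percent inhibition of the DPPH radical.

    I% = (A_control - A_sample) / A_control * 100.  Negative values (a
    sample absorbing more than the control, a pro-oxidant artifact) are
    returned with a warning rather than rejected.
    """
    if reading.absorbance_control is None or reading.absorbance_control <= 0:
        raise AssayError("DPPH inhibition requires a positive control absorbance")
    i = (reading.absorbance_control - reading.absorbance_sample) / reading.absorbance_control * 100.0
    if i < 0:
        warnings.warn(f"negative DPPH inhibition ({i:.2f}%)", stacklevel=2)
    return float(i)


def fit_calibration(concs, absorbances) -> CalibrationCurve:
    """Ordinary least-squares calibration line; r2 is the squared Pearson r."""
    c = np.asarray(concs, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if c.shape != a.shape or c.size < 3:
        raise CalibrationError(f"need >= 3 matched points, got {c.size} and {a.size}")
    if np.ptp(c) == 0:
        raise CalibrationError("all calibration concentrations are equal")
    res = stats.linregress(c, a)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n_points=int(c.size),
        conc_range=(float(c.min()), float(c.max())),
    )


def tpc_from_absorbance(absorbance: float, curve: CalibrationCurve, reading: AssayReading) -> float:
    """Total phenolic content in mg GAE per g of extract.

    The calibration gives the gallic-acid-equivalent concentration in the
    reaction mixture in mg/L; multiplying by the dilution factor recovers
    the concentration of the undiluted extract solution.  The extract
    solution concentration is given in mg/mL, i.e. g/L, so the ratio
    (mg/L)/(g/L) lands directly in mg GAE per g — this operation owns the
    factor-of-1000 unit conversion.
    """
    if curve.slope == 0:
        raise CalibrationError("calibration slope is zero")
    if reading.extract_conc is None or reading.extract_conc <= 0:
        raise AssayError("TPC requires extract_conc > 0 (mg/mL)")
    conc_gae = (absorbance - curve.intercept) / curve.slope  # mg/L in the cuvette
    lo, hi = curve.conc_range
    if not lo <= conc_gae <= hi:
        warnings.warn(
            f"GAE concentration {conc_gae:.3g} mg/L outside calibration range [{lo}, {hi}]",
            stacklevel=2,
        )
    return float(conc_gae * reading.dilution_factor / reading.extract_conc)


def selectivity_index(ic50_normal: float, ic50_cancer: float) -> float:
    """SI = IC50 on the normal line / IC50 on the cancer line.

    SI >= 2 is conventionally read as preferential toxicity to cancer cells.
    """
    if not (ic50_normal > 0 and ic50_cancer > 0):
        raise InputError(f"IC50 values must be > 0, got {ic50_normal}, {ic50_cancer}")
    return float(ic50_normal / ic50_cancer)


def relative_error(predicted: float, observed: float) -> float:
    """Validation error |predicted - observed| / |predicted| * 100 (%)."""
    if predicted == 0:
        raise InputError("relative error undefined for predicted = 0")
    return float(abs(predicted - observed) / abs(predicted) * 100.0)
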