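"""Reduction of dual water-vapor equilibration measurements to nonexchangeable δ²H.

Carbohydrates carry hydroxyl hydrogen that exchanges with ambient water, so a
raw δ²H measurement mixes the biosynthetic (carbon-bound, nonexchangeable)
signal with whatever water the sample last saw.  The dual-equilibration method
measures each sample twice, after equilibration with water vapors of two very
different compositions (by default −160 and −428‰).  The spread between the
two measurements gives the exchanged fraction x_e,

    x_e = (δ²H_e1 − δ²H_e2) / (α_e−w · (δ²H_w1 − δ²H_w2)),

and either pair then yields the nonexchangeable value

    δ²H_ne = (δ²H_e − x_e·α_e−w·δ²H_w − 1000·x_e·(α_e−w − 1)) / (1 − x_e),

with α_e−w the equilibrium fractionation between exchangeable compound
hydrogen and water (1.082 for cellulose).  Both relations are implemented
exactly in delta notation as written, including the 1000·(α−1) term.

Raw deltas are first offset-corrected against an exchange-free standard
(IAEA-CH-7 polyethylene foil), reduced, and finally scaled to VSMOW with a
two-point (or least-squares) calibration against exchangeable in-house
standards.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .types import (
    PAIR_INCONSISTENT,
    X_E_OUT_OF_RANGE,
    CalibrationStandard,
    EquilibrationMeasurement,
    ExchangeResult,
)

__all__ = [
    "compute_exchange_fraction",
    "compute_delta_ne",
    "forward_equilibrate",
    "offset_correct",
    "calibrate_to_vsmow",
    "BatchConfig",
    "BatchOutcome",
    "process_equilibration_batch",
]


def compute_exchange_fraction(m: EquilibrationMeasurement) -> float:
    """Fraction of a sample's hydrogen that exchanged during equilibration.

    The value is *not* clamped: x_e outside [0, 1] indicates a measurement
    problem and is surfaced downstream as a QC flag rather than hidden.
    """
    denom = m.alpha_ew * (m.delta_w1 - m.delta_w2)
    if denom == 0.0:
        # unreachable through the type invariant, kept as a guard for raw dicts
        raise ZeroDivisionError("degenerate water pair: delta_w1 == delta_w2")
    return (m.delta_e1 - m.delta_e2) / denom


def compute_delta_ne(delta_e: float, x_e: float, delta_w: float, alpha_ew: float) -> float:
    """Nonexchangeable δ²H from one equilibrated measurement.

    Raises
    ------
    ZeroDivisionError
        If ``x_e == 1`` (fully exchanged hydrogen leaves no nonexchangeable
        signal to recover).
    """
    if x_e == 1.0:
        raise ZeroDivisionError("x_e == 1: fully exchanged, delta_ne undefined")
    return (delta_e - x_e * alpha_ew * delta_w - 1000.0 * x_e * (alpha_ew - 1.0)) / (1.0 - x_e)


def forward_equilibrate(delta_ne: float, x_e: float, delta_w: float, alpha_ew: float) -> float:
    """Predict the equilibrated δ²H of a sample with known δ²H_ne and x_e.

    Algebraic inverse of :func:`compute_delta_ne`; used by the simulator and
    by round-trip tests.
    """
    return (1.0 - x_e) * delta_ne + x_e * alpha_ew * delta_w + 1000.0 * x_e * (alpha_ew - 1.0)


def offset_correct(
    raw_deltas: Sequence[float], standard_measured: float, standard_known: float
) -> list[float]:
    """Shift raw deltas by the bias of an exchange-free standard.

    Adds ``standard_known − standard_measured`` to every value, preserving
    all differences between samples.
    """
    shift = standard_known - standard_measured
    return [d + shift for d in raw_deltas]


def calibrate_to_vsmow(
    delta_ne_values: Sequence[float], standards: Sequence[CalibrationStandard]
) -> list[float]:
    """Map measured δ²H_ne values onto the VSMOW scale.

    Fits the affine map measured → known over the supplied standards
    (exact two-point mapping for two standards, least squares for more)
    and applies it to every value.
    """
    if len(standards) < 2:
        raise ValueError("VSMOW calibration needs at least two standards")
    measured = np.array([s.measured_delta for s in standards], dtype=float)
    known = np.array([s.known_delta for s in standards], dtype=float)
    if np.ptp(measured) == 0.0:
        raise ValueError("standards have identical measured_delta; calibration is degenerate")
    slope, intercept = np.polyfit(measured, known, 1)
    return [slope * v + intercept for v in delta_ne_values]


@dataclass(frozen=True)
class BatchConfig:
    """Switches for :func:`process_equilibration_batch`.

    ``pair_tolerance`` is the ‰ threshold above which the (algebraically
    zero) residual between the two pair reductions raises PAIR_INCONSISTENT;
    it guards against data-entry pathologies, not measurement noise.
    ``amount_correction`` enables an optional linear-in-1/amount bias
    correction fitted on exchange-free standards that carry amounts.
    """

    offset_correction: bool = True
    vsmow_calibration: bool = True
    amount_correction: bool = False
    pair_tolerance: float = 1e-6


@dataclass(frozen=True)
class BatchOutcome:
    """Results plus per-record failures of a batch reduction."""

    results: list[ExchangeResult]
    failures: list[tuple[str, str]]  # (sample_id, message)


def _fit_amount_correction(standards: Sequence[CalibrationStandard]) -> float:
    """Least-squares coefficient c of the bias model measured = known + c/amount."""
    usable = [s for s in standards if not s.exchangeable and s.amount is not None]
    if not usable:
        raise ValueError("amount correction requested but no exchange-free standard has an amount")
    inv_amount = np.array([1.0 / s.amount for s in usable])
    bias = np.array([s.measured_delta - s.known_delta for s in usable])
    # single-coefficient least squares through the origin
    return float(inv_amount @ bias / (inv_amount @ inv_amount))


def process_equilibration_batch(
    measurements: Iterable[EquilibrationMeasurement],
    standards: Sequence[CalibrationStandard] = (),
    config: BatchConfig | None = None,
) -> BatchOutcome:
    """Reduce a batch of equilibration measurements to δ²H_ne with QC flags.

    Stages, in order: offset correction of the raw equilibrated deltas
    against exchange-free standards, the exchange-fraction and δ²H_ne
    reduction (pair 1), then VSMOW scaling against exchangeable standards.
    A record that fails validation is collected in ``failures`` without
    aborting the rest of the batch; output order matches input order.
    """
    config = config or BatchConfig()
    measurements = list(measurements)

    shift = 0.0
    if config.offset_correction:
        offset_standards = [s for s in standards if not s.exchangeable]
        if offset_standards:
            shift = float(
                np.mean([s.known_delta - s.measured_delta for s in offset_standards])
            )

    amount_coef = _fit_amount_correction(standards) if config.amount_correction else 0.0

    reduced: list[ExchangeResult | None] = []
    failures: list[tuple[str, str]] = []
    for m in measurements:
        try:
            if shift or amount_coef:
                corr = shift
                if amount_coef and m.amount is not None:
                    corr -= amount_coef / m.amount
                m = replace(m, delta_e1=m.delta_e1 + corr, delta_e2=m.delta_e2 + corr)
            x_e = compute_exchange_fraction(m)
            ne1 = compute_delta_ne(m.delta_e1, x_e, m.delta_w1, m.alpha_ew)
            ne2 = compute_delta_ne(m.delta_e2, x_e, m.delta_w2, m.alpha_ew)
            residual = abs(ne1 - ne2)
            flags = set()
            if not (0.0 <= x_e <= 1.0):
                flags.add(X_E_OUT_OF_RANGE)
            if residual > config.pair_tolerance:
                flags.add(PAIR_INCONSISTENT)
            reduced.append(
                ExchangeResult(
                    sample_id=m.sample_id,
                    x_e=x_e,
                    delta_ne=ne1,
                    pair_residual=residual,
                    qc_flags=frozenset(flags),
                )
            )
        except (ValueError, ZeroDivisionError) as exc:
            failures.append((m.sample_id, str(exc)))
            reduced.append(None)

    vsmow_standards = [s for s in standards if s.exchangeable]
    if config.vsmow_calibration and len(vsmow_standards) >= 2:
        ok = [r for r in reduced if r is not None]
        calibrated = calibrate_to_vsmow([r.delta_ne for r in ok], vsmow_standards)
        mapping = {id(r): v for r, v in zip(ok, calibrated)}
        reduced = [
            r if r is None else replace(r, delta_ne=mapping[id(r)]) for r in reduced
        ]

    return BatchOutcome(results=[r for r in reduced if r is not None], failures=failures)
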