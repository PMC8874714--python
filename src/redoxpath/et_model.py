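"""Exponential distance-decay model of non-adiabatic electron tunnelling.

The rate constant of electron transfer between a donor and an acceptor
separated by an edge-to-edge distance R (Å) is modelled as

    k_et(R) = A0 * exp(-beta * R)

with decay constant beta (Å⁻¹), which reflects how strongly the electronic
coupling falls off with distance through the protein medium, and
pre-exponential A0 (s⁻¹), the contact-limit rate.  Both parameters are fixed
by solving the two-point system through a pair of reference
(distance, rate) anchors; a third anchor can be used as an independent
consistency check (the system is over-determined, so it is verified, not
fitted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CalibrationPoint",
    "ETModelParams",
    "AnchorReport",
    "calibrate",
    "rate_from_distance",
    "distance_from_rate",
    "verify_anchor",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """A reference (distance, rate) pair used to pin the model."""

    distance: float  # Å
    rate: float  # s^-1

    def __post_init__(self) -> None:
        if not self.distance > 0:
            raise ValueError(f"calibration distance must be > 0, got {self.distance}")
        if not self.rate > 0:
            raise ValueError(f"calibration rate must be > 0, got {self.rate}")


@dataclass(frozen=True)
class ETModelParams:
    """Calibrated decay constant beta (Å⁻¹) and pre-exponential A0 (s⁻¹)."""

    beta: float
    A0: float

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if not self.A0 > 0:
            raise ValueError(f"A0 must be > 0, got {self.A0}")


@dataclass(frozen=True)
class AnchorReport:
    """Outcome of checking the model against an independent anchor point."""

    passed: bool
    predicted_rate: float
    anchor: CalibrationPoint
    ratio: float  # predicted / anchor, always >= 1 would be folded; kept signed
    tolerance_factor: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        verdict = "OK" if self.passed else "FAIL"
        return (
            f"anchor check {verdict}: k({self.anchor.distance:g} Å) = "
            f"{self.predicted_rate:.3g} s^-1 vs {self.anchor.rate:.3g} s^-1 "
            f"(ratio {self.ratio:.3f}, allowed x/{self.tolerance_factor:g})"
        )


def calibrate(p1: CalibrationPoint, p2: CalibrationPoint) -> ETModelParams:
    """Solve k = A0*exp(-beta*R) exactly through two reference points.

    beta = ln(k1/k2) / (R2 - R1), A0 = k1 * exp(beta * R1).  The rates must
    decrease with distance, otherwise beta would be non-positive and the
    tunnelling picture meaningless.
    """
    if p1.distance == p2.distance:
        raise ValueError("calibration points must have distinct distances")
    beta = math.log(p1.rate / p2.rate) / (p2.distance - p1.distance)
    if beta <= 0:
        raise ValueError(
            f"calibration gives beta = {beta:.4g} Å^-1 <= 0; "
            "rates must decay with distance"
        )
    a0 = p1.rate * math.exp(beta * p1.distance)
    return ETModelParams(beta=beta, A0=a0)


def rate_from_distance(model: ETModelParams, distance: float) -> float:
    """k_et(R) = A0 * exp(-beta * R), strictly decreasing in R (R >= 0, Å)."""
    if distance < 0:
        raise ValueError(f"distance must be >= 0, got {distance}")
    return model.A0 * math.exp(-model.beta * distance)


def distance_from_rate(model: ETModelParams, rate: float) -> float:
    """Inverse of :func:`rate_from_distance`: R = ln(A0/k)/beta."""
    if rate <= 0:
        raise ValueError(f"rate must be > 0, got {rate}")
    if rate > model.A0:
        raise ValueError(f"rate {rate:.3g} exceeds the contact limit A0 = {model.A0:.3g}")
    return math.log(model.A0 / rate) / model.beta


def verify_anchor(
    model: ETModelParams,
    anchor: CalibrationPoint,
    tolerance_factor: float = 1.2,
) -> AnchorReport:
    """Check the calibrated model against an independent (R, k) anchor.

    Passes when the predicted rate is within a multiplicative factor
    (x tolerance_factor / ÷ tolerance_factor) of the anchor rate.
    """
    if tolerance_factor < 1:
        raise ValueError("tolerance_factor must be >= 1")
    predicted = rate_from_distance(model, anchor.distance)
    ratio = predicted / anchor.rate
    passed = 1.0 / tolerance_factor <= ratio <= tolerance_factor
    return AnchorReport(
        passed=passed,
        predicted_rate=predicted,
        anchor=anchor,
        ratio=ratio,
        tolerance_factor=tolerance_factor,
    )
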