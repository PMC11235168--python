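"""Core domain types shared across the pipeline.

All delta values are per-mil (‰) deviations of the ²H/¹H ratio from VSMOW.
Physical deltas are bounded below by −1000‰ (a sample with no ²H at all);
anything at or below that bound is rejected as non-physical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "COMPOUNDS",
    "TISSUES",
    "ALKANE_CHAINS",
    "MIN_DELTA",
    "X_E_OUT_OF_RANGE",
    "PAIR_INCONSISTENT",
    "SampleRecord",
    "EquilibrationMeasurement",
    "ExchangeResult",
    "CalibrationStandard",
    "FractionationFactor",
    "AlkaneProfile",
    "REParameters",
    "REPrediction",
    "HSourcePartition",
]

#: Recognised compound labels for per-sample records.
ALKANE_CHAINS = (27, 29, 31, 33)
COMPOUNDS = frozenset(
    {"water", "sugars", "starch", "cellulose", "bulk"}
    | {f"alkane_C{n}" for n in ALKANE_CHAINS}
)
TISSUES = frozenset({"leaf", "root", "soil"})

#: Physical lower bound for a delta value (‰).
MIN_DELTA = -1000.0

# QC flag names used by the equilibration reduction.
X_E_OUT_OF_RANGE = "X_E_OUT_OF_RANGE"
PAIR_INCONSISTENT = "PAIR_INCONSISTENT"


def _check_delta(name: str, value: float) -> None:
    if not math.isfinite(value) or value <= MIN_DELTA:
        raise ValueError(f"{name}={value!r} is not a physical delta (finite, > {MIN_DELTA}‰)")


@dataclass(frozen=True)
class SampleRecord:
    """One per-sample isotope observation.

    ``treatment`` is either a NO₃⁻ percentage (integer, 100 … 0, encoding the
    NO₃⁻/NH₄⁺ fertilization ratio) or a genotype label (``"WT"`` / ``"pgm"``).
    """

    sample_id: str
    compound: str
    tissue: str
    treatment: object
    replicate: int
    delta2H: float

    def __post_init__(self) -> None:
        if self.compound not in COMPOUNDS:
            raise ValueError(f"unknown compound {self.compound!r}")
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if int(self.replicate) < 1:
            raise ValueError("replicate must be a positive integer")
        _check_delta("delta2H", self.delta2H)


@dataclass(frozen=True)
class EquilibrationMeasurement:
    """A sample's two water-vapor equilibrated δ²H values.

    ``delta_e1``/``delta_e2`` were measured after equilibration with water
    vapors of composition ``delta_w1``/``delta_w2``; ``alpha_ew`` is the
    equilibrium fractionation factor between exchangeable compound hydrogen
    and the equilibration water (1.082 for cellulose, taken as similar for
    other carbohydrates).
    """

    sample_id: str
    delta_e1: float
    delta_e2: float
    delta_w1: float = -160.0
    delta_w2: float = -428.0
    alpha_ew: float = 1.082
    amount: float | None = None  # mg, only needed for the optional amount correction

    def __post_init__(self) -> None:
        for name in ("delta_e1", "delta_e2", "delta_w1", "delta_w2"):
            _check_delta(name, getattr(self, name))
        if self.delta_w1 == self.delta_w2:
            raise ValueError("degenerate water pair: delta_w1 == delta_w2")
        if not (self.alpha_ew > 0):
            raise ValueError("alpha_ew must be positive")
        if self.amount is not None and not (self.amount > 0):
            raise ValueError("amount must be positive when given")


@dataclass(frozen=True)
class ExchangeResult:
    """Reduced equilibration result: exchanged fraction and nonexchangeable δ²H."""

    sample_id: str
    x_e: float
    delta_ne: float
    pair_residual: float
    qc_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.pair_residual < 0:
            raise ValueError("pair_residual must be non-negative")
        in_range = 0.0 <= self.x_e <= 1.0
        if in_range and X_E_OUT_OF_RANGE in self.qc_flags:
            raise ValueError("X_E_OUT_OF_RANGE flagged for in-range x_e")
        if not in_range and X_E_OUT_OF_RANGE not in self.qc_flags:
            raise ValueError("x_e outside [0, 1] must carry X_E_OUT_OF_RANGE")


@dataclass(frozen=True)
class CalibrationStandard:
    """A reference material with known and measured δ²H.

    ``exchangeable=False`` marks exchange-free materials such as IAEA-CH-7
    polyethylene foil (PEF), used for offset correction; exchangeable
    standards (in-house sucrose, cellulose) anchor the VSMOW scaling.
    """

    name: str
    known_delta: float
    measured_delta: float
    exchangeable: bool = True
    amount: float | None = None

    def __post_init__(self) -> None:
        _check_delta("known_delta", self.known_delta)
        _check_delta("measured_delta", self.measured_delta)


@dataclass(frozen=True)
class FractionationFactor:
    """An apparent fractionation factor ε bound to its contrast.

    ``kind`` is ``"epsilon_a"`` (compound vs. leaf water) or ``"epsilon_h"``
    (carbohydrate A vs. carbohydrate B, within or between tissues).
    """

    kind: str
    compound_a: str
    compound_b: str
    tissue_a: str
    tissue_b: str
    treatment: object
    replicate: int
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("epsilon_a", "epsilon_h"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "epsilon_a":
            if self.compound_b != "water" or self.tissue_a != "leaf" or self.tissue_b != "leaf":
                raise ValueError("epsilon_a contrasts a leaf compound against leaf water")


@dataclass(frozen=True)
class AlkaneProfile:
    """Relative abundances and δ²H of the measurable n-alkane chains (C27–C33)."""

    chains: tuple[tuple[int, float, float], ...]  # (chain_length, abundance, delta2H)

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("empty alkane profile")
        for length, abundance, delta in self.chains:
            if length not in ALKANE_CHAINS:
                raise ValueError(f"unsupported chain length {length}")
            if abundance < 0:
                raise ValueError("negative abundance")
            _check_delta(f"delta2H(C{length})", delta)
        total = sum(a for _, a, _ in self.chains)
        if not (0.98 <= total <= 1.02):
            raise ValueError(f"abundances sum to {total:.4f}, outside [0.98, 1.02]")


@dataclass(frozen=True)
class REParameters:
    """Parameters of the two-pool Roden–Ehleringer cellulose model.

    Defaults are the model's standard constants: autotrophic fractionation
    ε_a* = −171‰, heterotrophic fractionation ε_h* = +158‰, and exchange
    fraction f = 0.36.
    """

    eps_a_star: float = -171.0
    eps_h_star: float = 158.0
    f: float = 0.36

    def __post_init__(self) -> None:
        for name in ("eps_a_star", "eps_h_star", "f"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class REPrediction:
    """A modeled cellulose δ²H, optionally paired with an observation."""

    sample_id: str
    delta_modeled: float
    delta_observed: float | None = None
    residual: float | None = None
    source_water_used: str = "root"

    def __post_init__(self) -> None:
        if (self.delta_observed is None) != (self.residual is None):
            raise ValueError("residual present iff observed present")
        if self.residual is not None:
            expected = self.delta_observed - self.delta_modeled
            if abs(self.residual - expected) > 1e-9:
                raise ValueError("residual must equal observed - modeled")
        if self.source_water_used not in ("root", "soil"):
            raise ValueError("source_water_used must be 'root' or 'soil'")


@dataclass(frozen=True)
class HSourcePartition:
    """Carbon-bound hydrogen of a compound partitioned by biochemical source.

    Sources are NADPH, medium water, and the carbon precursor (triose
    phosphate / photorespiratory products for glucose; acetyl-CoA for
    n-alkanes). Fractions must sum to 1 within ±0.01.
    """

    compound: str  # "glucose" or "C<n>" for an n-alkane
    total_H: int
    fractions: tuple[tuple[str, float], ...]  # ordered (source, fraction)

    def __post_init__(self) -> None:
        if self.total_H < 1:
            raise ValueError("total_H must be positive")
        total = sum(f for _, f in self.fractions)
        if abs(total - 1.0) > 0.01:
            raise ValueError(f"source fractions sum to {total:.4f}, not 1 ± 0.01")

    def fraction_map(self) -> dict[str, float]:
        return dict(self.fractions)
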