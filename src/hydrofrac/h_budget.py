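"""Carbon-bound hydrogen accounting and isotope mass-balance mixing.

Different compound classes acquire their carbon-bound hydrogen from
different biochemical sources, which explains their distinct δ²H
sensitivities to treatments.  Glucose (the reference carbohydrate unit)
has 7 carbon-bound H atoms: 1 from NADPH, 3 from water, and 3 inherited
from the triose-phosphate / photorespiratory precursor (14/43/43%).
An unbranched n-alkane of n carbons has 2n + 2 carbon-bound H atoms; for
the dominant C29 chain (60 H), 47% come from NADPH, 24% from water, and
29% from acetyl-CoA precursors.  The alkane percentages are literature
accounting constants and are applied to the other measurable chains
(C27, C31, C33) as given.
"""

from __future__ import annotations

from typing import Mapping

from .types import HSourcePartition

__all__ = [
    "carbon_bound_h_count",
    "glucose_partition",
    "alkane_partition",
    "source_percentages",
    "mix_delta",
]

#: Glucose hydrogen by source, stored as integer atom counts out of 7.
_GLUCOSE_COUNTS = (("NADPH", 1), ("water", 3), ("precursor", 3))
#: n-Alkane hydrogen by source, stored as the published percentages (C29).
_ALKANE_FRACTIONS = (("NADPH", 0.47), ("water", 0.24), ("precursor", 0.29))

_SOURCES = ("NADPH", "water", "precursor")


def _parse_chain(compound) -> int | None:
    """Return the chain length for an n-alkane designator, else None."""
    if isinstance(compound, int):
        return compound
    if isinstance(compound, str):
        label = compound.removeprefix("alkane_").removeprefix("n_alkane_")
        if label.upper().startswith("C") and label[1:].isdigit():
            return int(label[1:])
    return None


def carbon_bound_h_count(compound) -> int:
    """Number of carbon-bound hydrogen atoms of glucose or an n-alkane.

    ``compound`` is ``"glucose"``, an integer chain length, or a chain label
    such as ``"C29"`` / ``"alkane_C29"``.  Glucose has 7 carbon-bound H; an
    unbranched saturated n-alkane of n carbons has 2n + 2.
    """
    if compound == "glucose":
        return 7
    n = _parse_chain(compound)
    if n is not None and n >= 1:
        return 2 * n + 2
    raise ValueError(f"unsupported compound {compound!r}")


def glucose_partition() -> HSourcePartition:
    """The 1:3:3 (NADPH:water:precursor) partition of glucose's 7 H atoms."""
    total = sum(c for _, c in _GLUCOSE_COUNTS)
    return HSourcePartition(
        compound="glucose",
        total_H=total,
        fractions=tuple((s, c / total) for s, c in _GLUCOSE_COUNTS),
    )


def alkane_partition(chain_length: int = 29) -> HSourcePartition:
    """H-source partition of an n-alkane (published C29 percentages)."""
    if chain_length < 1:
        raise ValueError("chain_length must be >= 1")
    return HSourcePartition(
        compound=f"C{chain_length}",
        total_H=carbon_bound_h_count(chain_length),
        fractions=_ALKANE_FRACTIONS,
    )


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (as printed percentages are)."""
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


def source_percentages(p: HSourcePartition) -> dict[str, int]:
    """Whole-number percentage of hydrogen from each source."""
    return {source: _round_half_away(100.0 * fraction) for source, fraction in p.fractions}


def mix_delta(
    p: HSourcePartition,
    source_deltas: Mapping[str, float],
    source_eps: Mapping[str, float] | None = None,
) -> float:
    """Isotope mass balance over a hydrogen-source partition.

    Each source contributes fraction × (δ²H_source + ε_source); ε defaults
    to zero.  Linear in every source delta, so scenario sensitivities are
    exact partial derivatives (the source fractions themselves).
    """
    eps = dict(source_eps or {})
    total = 0.0
    for source, fraction in p.fractions:
        if source not in source_deltas:
            raise ValueError(f"missing delta for source {source!r}")
        total += fraction * (source_deltas[source] + eps.get(source, 0.0))
    return total
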