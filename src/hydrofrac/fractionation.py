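"""Apparent hydrogen-isotope fractionation factors.

Two summary quantities compartmentalize the many enzymatic and transport
fractionations acting on plant hydrogen:

* the apparent autotrophic fractionation of a leaf compound,
  ε_a = δ²H_compound − δ²H_leaf water, which normalizes leaf compounds for
  leaf-water isotope variation, and
* the apparent heterotrophic fractionation between two carbohydrates,
  ε_h = δ²H_A − δ²H_B, evaluated within leaves (L), within roots (R), or
  between roots and leaves (R−L).

Both are implemented as plain delta differences.  The exact ratio-domain
form is available separately as :func:`epsilon_ratio` for users who prefer
1000·((1000+δ_A)/(1000+δ_B) − 1).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import as_frame
from .types import ALKANE_CHAINS, AlkaneProfile, FractionationFactor

__all__ = [
    "epsilon_a",
    "epsilon_h",
    "epsilon_ratio",
    "weighted_alkane_mean",
    "alkane_profile_from_frame",
    "tissue_offset",
    "fractionation_table",
    "EPSILON_H_CONTRASTS",
    "EPSILON_H_TISSUE_PAIRS",
]

#: Carbohydrate contrasts evaluated by :func:`fractionation_table`:
#: cellulose−sugars (C-S), cellulose−starch (C-St), starch−sugars (St-S).
EPSILON_H_CONTRASTS = (("cellulose", "sugars"), ("cellulose", "starch"), ("starch", "sugars"))
#: Tissue pairs: within leaves, within roots, roots vs. leaves.
EPSILON_H_TISSUE_PAIRS = (("leaf", "leaf"), ("root", "root"), ("root", "leaf"))


def epsilon_a(delta_compound: float, delta_leaf_water: float) -> float:
    """Apparent autotrophic fractionation: compound δ²H minus leaf-water δ²H (‰)."""
    return delta_compound - delta_leaf_water


def epsilon_h(delta_a: float, delta_b: float) -> float:
    """Apparent heterotrophic fractionation between two carbohydrates (‰).

    Antisymmetric: ``epsilon_h(a, b) == -epsilon_h(b, a)``.
    """
    return delta_a - delta_b


def epsilon_ratio(delta_a: float, delta_b: float) -> float:
    """Ratio-domain fractionation 1000·((1000+δ_A)/(1000+δ_B) − 1) in ‰."""
    return 1000.0 * ((1000.0 + delta_a) / (1000.0 + delta_b) - 1.0)


def weighted_alkane_mean(profile: AlkaneProfile) -> float:
    """Abundance-weighted mean δ²H over the n-alkane chains of a profile.

    Abundances are renormalized to sum exactly to one (the type invariant
    already bounds the raw sum to 1 ± 0.02).
    """
    abundances = np.array([a for _, a, _ in profile.chains], dtype=float)
    deltas = np.array([d for _, _, d in profile.chains], dtype=float)
    weights = abundances / abundances.sum()
    return float(weights @ deltas)


def alkane_profile_from_frame(
    group: pd.DataFrame, abundances: Mapping[int, float] | None = None
) -> AlkaneProfile | None:
    """Build an :class:`AlkaneProfile` from the alkane rows of one sample group.

    ``abundances`` maps chain length → relative abundance; chains absent from
    the data are dropped and the remaining abundances renormalized.  With no
    abundances given, chains are weighted equally.  Returns None if the group
    has no alkane rows.
    """
    rows = group[group["compound"].str.startswith("alkane_C")]
    if rows.empty:
        return None
    lengths = [int(c.removeprefix("alkane_C")) for c in rows["compound"]]
    if abundances is None:
        weights = {n: 1.0 / len(lengths) for n in lengths}
    else:
        present = {n: abundances.get(n, 0.0) for n in lengths}
        total = sum(present.values())
        if total <= 0:
            return None
        weights = {n: v / total for n, v in present.items()}
    chains = tuple(
        (n, weights[n], float(d)) for n, d in zip(lengths, rows["delta2H"]) if weights[n] > 0
    )
    return AlkaneProfile(chains=chains) if chains else None


def tissue_offset(data, compound: str, tissue_a: str, tissue_b: str) -> float:
    """Mean δ²H offset of ``tissue_a`` over ``tissue_b`` for one compound.

    Replicates are paired by index within each treatment; the per-treatment
    mean differences are then averaged with equal treatment weight, matching
    how treatment-level summaries are reported.
    """
    df = as_frame(data)
    sub = df[df["compound"] == compound]
    diffs = []
    for _, group in sub.groupby("treatment", sort=False):
        a = group[group["tissue"] == tissue_a].sort_values("replicate")
        b = group[group["tissue"] == tissue_b].sort_values("replicate")
        merged = a.merge(b, on="replicate", suffixes=("_a", "_b"))
        if not merged.empty:
            diffs.append(float((merged["delta2H_a"] - merged["delta2H_b"]).mean()))
    if not diffs:
        raise ValueError(f"no paired ({compound}, {tissue_a}/{tissue_b}) observations")
    return float(np.mean(diffs))


def _delta_lookup(df: pd.DataFrame, compound: str, tissue: str) -> dict[tuple, float]:
    sub = df[(df["compound"] == compound) & (df["tissue"] == tissue)]
    return {
        (t, r): float(d)
        for t, r, d in zip(sub["treatment"], sub["replicate"], sub["delta2H"])
    }


def fractionation_table(
    data, alkane_abundances: Mapping[int, float] | None = None
) -> pd.DataFrame:
    """Evaluate every ε_a and ε_h contrast over a samples table.

    One row per (kind, contrast, treatment, replicate).  ε_a is computed for
    leaf sugars, starch, cellulose, and the abundance-weighted alkane mean
    (reported as compound ``alkanes``), each against leaf water of the same
    treatment and replicate.  ε_h covers cellulose−sugars, cellulose−starch,
    and starch−sugars within leaves, within roots, and between roots and
    leaves.  Missing compounds simply produce no rows.
    """
    df = as_frame(data)
    rows: list[FractionationFactor] = []

    leaf_water = _delta_lookup(df, "water", "leaf")

    # epsilon_a of individual carbohydrates
    for compound in ("sugars", "starch", "cellulose"):
        for key, delta in _delta_lookup(df, compound, "leaf").items():
            if key in leaf_water:
                rows.append(
                    FractionationFactor(
                        kind="epsilon_a", compound_a=compound, compound_b="water",
                        tissue_a="leaf", tissue_b="leaf",
                        treatment=key[0], replicate=key[1],
                        value=epsilon_a(delta, leaf_water[key]),
                    )
                )

    # epsilon_a of the weighted alkane mean
    alkanes = df[(df["tissue"] == "leaf") & df["compound"].str.startswith("alkane_C")]
    for key, group in alkanes.groupby(["treatment", "replicate"], sort=False):
        if key not in leaf_water:
            continue
        profile = alkane_profile_from_frame(group, alkane_abundances)
        if profile is None:
            continue
        rows.append(
            FractionationFactor(
                kind="epsilon_a", compound_a="alkanes", compound_b="water",
                tissue_a="leaf", tissue_b="leaf",
                treatment=key[0], replicate=int(key[1]),
                value=epsilon_a(weighted_alkane_mean(profile), leaf_water[key]),
            )
        )

    # epsilon_h contrasts within and between tissues
    for compound_a, compound_b in EPSILON_H_CONTRASTS:
        for tissue_a, tissue_b in EPSILON_H_TISSUE_PAIRS:
            lookup_a = _delta_lookup(df, compound_a, tissue_a)
            lookup_b = _delta_lookup(df, compound_b, tissue_b)
            for key in lookup_a.keys() & lookup_b.keys():
                rows.append(
                    FractionationFactor(
                        kind="epsilon_h", compound_a=compound_a, compound_b=compound_b,
                        tissue_a=tissue_a, tissue_b=tissue_b,
                        treatment=key[0], replicate=key[1],
                        value=epsilon_h(lookup_a[key], lookup_b[key]),
                    )
                )

    table = pd.DataFrame(
        [
            (f.kind, f.compound_a, f.compound_b, f.tissue_a, f.tissue_b, f.treatment,
             f.replicate, f.value)
            for f in rows
        ],
        columns=["kind", "compound_a", "compound_b", "tissue_a", "tissue_b",
                 "treatment", "replicate", "value"],
    )
    return table.sort_values(
        ["kind", "compound_a", "compound_b", "tissue_a", "tissue_b", "treatment", "replicate"],
        kind="stable",
    ).reset_index(drop=True)
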