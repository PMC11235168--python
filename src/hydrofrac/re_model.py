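"""The two-pool Roden–Ehleringer (RE) model for cellulose δ²H.

The model treats cellulose hydrogen as a mixture of two pools: a fraction
1 − f carrying the leaf-water signal offset by a constant autotrophic
fractionation ε_a*, and a fraction f that exchanged with source (medium)
water during cellulose synthesis, offset by a constant heterotrophic
fractionation ε_h*:

    δ²H_cellulose = (1 − f)·(δ²H_leaf water + ε_a*) + f·(δ²H_source water + ε_h*)

with standard constants ε_a* = −171‰, ε_h* = +158‰, f = 0.36.  Source water
is approximated by root water by default, or soil water as a sensitivity
check (cryogenic extraction can bias root-water δ²H).

Because the model is affine in every argument, it can be rearranged exactly
for f (given ε_h*) or for ε_h* (given f), per sample or per treatment mean;
these single-parameter inversions probe whether constant exchange and
heterotrophic fractionation actually hold.  Inverted f values outside [0, 1]
are reported with a flag, never clamped — they are diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import REParameters, REPrediction

__all__ = [
    "re_forward",
    "re_residual",
    "invert_f",
    "invert_eps_h",
    "InvertedF",
    "source_sensitivity",
    "predict_table",
    "invert_table",
]


def re_forward(leaf_water: float, source_water: float, params: REParameters) -> float:
    """Modeled cellulose δ²H (‰) from leaf and source water."""
    return (1.0 - params.f) * (leaf_water + params.eps_a_star) + params.f * (
        source_water + params.eps_h_star
    )


def re_residual(observed: float, modeled: float) -> float:
    """Observed minus modeled cellulose δ²H; positive when the model underestimates."""
    return observed - modeled


@dataclass(frozen=True)
class InvertedF:
    """An inverted exchange fraction with its range diagnostic."""

    f: float
    out_of_range: bool


def invert_f(
    observed_cellulose: float,
    leaf_water: float,
    source_water: float,
    eps_a_used: float,
    eps_h_star: float,
) -> InvertedF:
    """Solve the model for the exchange fraction f, holding ε_h* fixed.

    ``eps_a_used`` may be the constant −171‰ or a measured (dynamic) ε_a of
    assimilates.  The returned f is flagged, not clamped, when outside
    [0, 1]: negative f means the observation sits below even the pure
    leaf-water pool.
    """
    autotrophic = leaf_water + eps_a_used
    denom = (source_water + eps_h_star) - autotrophic
    if denom == 0.0:
        raise ZeroDivisionError(
            "degenerate inversion: the two pool end-members coincide"
        )
    f = (observed_cellulose - autotrophic) / denom
    return InvertedF(f=f, out_of_range=not (0.0 <= f <= 1.0))


def invert_eps_h(
    observed_cellulose: float,
    leaf_water: float,
    source_water: float,
    f: float,
    eps_a_used: float,
) -> float:
    """Solve the model for ε_h*, holding f fixed."""
    if f == 0.0:
        raise ZeroDivisionError("f == 0: the exchanged pool is absent, eps_h* undefined")
    return (observed_cellulose - (1.0 - f) * (leaf_water + eps_a_used)) / f - source_water


def source_sensitivity(
    leaf_water: float, root_water: float, soil_water: float, params: REParameters
) -> float:
    """Shift in modeled cellulose δ²H when soil water replaces root water.

    Equals f·(soil − root) exactly, since the model is affine in source
    water; quantifies the maximum error a biased root-water extraction could
    introduce.
    """
    return re_forward(leaf_water, soil_water, params) - re_forward(
        leaf_water, root_water, params
    )


def predict_table(
    merged: pd.DataFrame,
    params: REParameters = REParameters(),
    source: str = "root",
) -> list[REPrediction]:
    """Run the model over a merged per-sample water/cellulose table.

    ``merged`` needs columns ``sample_id``, ``leaf_water``, ``root_water``
    (and ``soil_water`` when ``source="soil"``), plus optionally
    ``observed_cellulose``.
    """
    if source not in ("root", "soil"):
        raise ValueError("source must be 'root' or 'soil'")
    source_col = f"{source}_water"
    predictions = []
    for row in merged.itertuples(index=False):
        modeled = re_forward(row.leaf_water, getattr(row, source_col), params)
        observed = getattr(row, "observed_cellulose", None)
        observed = None if observed is None or pd.isna(observed) else float(observed)
        predictions.append(
            REPrediction(
                sample_id=str(row.sample_id),
                delta_modeled=modeled,
                delta_observed=observed,
                residual=None if observed is None else re_residual(observed, modeled),
                source_water_used=source,
            )
        )
    return predictions


def invert_table(
    merged: pd.DataFrame,
    params: REParameters = REParameters(),
    eps_a_mode: str = "constant",
    source: str = "root",
    per_replicate: bool = False,
) -> pd.DataFrame:
    """Invert the model for f and for ε_h* per treatment (or per replicate).

    ``eps_a_mode`` selects what stands in for the autotrophic offset:
    ``"constant"`` uses ε_a* from ``params``; ``"sugars"`` or ``"starch"``
    use the measured dynamic ε_a, which requires an ``eps_a_sugars`` /
    ``eps_a_starch`` column in ``merged``.  By default inputs are averaged
    per treatment before inversion; ``per_replicate=True`` inverts each row.
    Returns a frame with f, its out-of-range flag, and ε_h* (inverted with
    f held at ``params.f``).
    """
    if eps_a_mode == "constant":
        eps_a_col = None
    elif eps_a_mode in ("sugars", "starch"):
        eps_a_col = f"eps_a_{eps_a_mode}"
        if eps_a_col not in merged.columns:
            raise ValueError(f"eps_a_mode={eps_a_mode!r} needs column {eps_a_col!r}")
    else:
        raise ValueError("eps_a_mode must be 'constant', 'sugars', or 'starch'")
    source_col = f"{source}_water"

    needed = ["leaf_water", source_col, "observed_cellulose"]
    if eps_a_col:
        needed.append(eps_a_col)
    work = merged.dropna(subset=needed)
    if not per_replicate:
        work = work.groupby("treatment", sort=False, as_index=False)[needed].mean()

    out = []
    for row in work.itertuples(index=False):
        eps_a_used = params.eps_a_star if eps_a_col is None else getattr(row, eps_a_col)
        inv = invert_f(
            row.observed_cellulose, row.leaf_water, getattr(row, source_col),
            eps_a_used, params.eps_h_star,
        )
        eps_h = invert_eps_h(
            row.observed_cellulose, row.leaf_water, getattr(row, source_col),
            params.f, eps_a_used,
        )
        record = {
            "treatment": row.treatment,
            "eps_a_mode": eps_a_mode,
            "eps_a_used": eps_a_used,
            "f": inv.f,
            "f_out_of_range": inv.out_of_range,
            "eps_h_star": eps_h,
        }
        if per_replicate:
            record["replicate"] = row.replicate
        out.append(record)
    return pd.DataFrame(out)
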