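"""Synthetic datasets with the statistical structure of the two tobacco experiments.

The generator emulates (i) an N-fertilization gradient — seven NO₃⁻/NH₄⁺
ratios from 100/0 to 0/100, five replicate plants, leaf and root tissue —
and (ii) a wild-type vs. starch-deficient *pgm* knockout contrast, plus raw
dual-equilibration measurements and scenario tables for the cellulose model.
Default effect sizes are the published treatment-level summaries (tissue
offsets, leaf ranges, genotype offsets, the −128.8‰ alkane fractionation),
so that at zero noise every downstream summary reproduces its configured
truth exactly, and at the default 3‰ measurement noise the pipeline can be
exercised under realistic conditions.

Treatment effects on assimilates are piecewise linear in the NO₃⁻ fraction:
flat across NO₃⁻-dominated ratios, rising linearly beyond the 25/75 turning
point so that the full gradient spans the configured per-compound amplitude.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .equilibration import forward_equilibrate
from .re_model import re_forward
from .types import ALKANE_CHAINS, EquilibrationMeasurement, REParameters, SampleRecord

__all__ = [
    "SyntheticConfig",
    "generate_n_experiment",
    "generate_pgm_experiment",
    "generate_equilibration_raw",
    "generate_re_scenario",
]


class SyntheticConfig(BaseModel):
    """Effect sizes, noise, and replication for the synthetic experiments.

    All deltas and offsets in ‰ VSMOW. Defaults encode the study conditions:
    leaf water 29.6‰ above root water; root sugars/starch/cellulose enriched
    over leaves by 17.3/104.5/12.3‰; leaf alkanes at ε_a = −128.8‰; treatment
    amplitudes (max leaf range along the gradient) 128.8/77.6/35.4‰;
    irrigation water −79.3‰; chamber vapor −140.0‰; *pgm* enrichment
    152.7/75.0/38.7‰ for starch/sugars/cellulose; measurement noise 3‰
    (midpoint of the stated 2–4‰ precision).
    """

    model_config = ConfigDict(frozen=True)

    treatments: tuple[int, ...] = (100, 90, 75, 50, 25, 10, 0)
    n_replicates: int = Field(default=5, ge=1)
    seed: int = 0
    irrigation_water: float = -79.3
    vapor_water: float = -140.0
    leaf_root_water_offset: float = 29.6
    soil_minus_root_water: float = 6.7
    root_minus_leaf_offsets: dict[str, float] = Field(
        default_factory=lambda: {"sugars": 17.3, "starch": 104.5, "cellulose": 12.3}
    )
    base_eps_a: dict[str, float] = Field(
        default_factory=lambda: {"sugars": -161.8, "starch": -203.8, "cellulose": -73.5}
    )
    alkane_eps_a: float = -128.8
    treatment_breakpoint: int = 25
    treatment_amplitudes: dict[str, float] = Field(
        default_factory=lambda: {"sugars": 128.8, "starch": 77.6, "cellulose": 35.4}
    )
    noise_sd: float = Field(default=3.0, ge=0.0)
    pgm_offsets: dict[str, float] = Field(
        default_factory=lambda: {"starch": 152.7, "sugars": 75.0, "cellulose": 38.7}
    )
    # cellulose and alkanes at the two most NH4+-dominated ratios keep <= 3 replicates
    missing_treatments: tuple[int, ...] = (10, 0)
    missing_max_replicates: int = 3
    apply_missingness: bool = True

    # equilibration constants for raw-measurement simulation
    delta_w1: float = -160.0
    delta_w2: float = -428.0
    alpha_ew: float = 1.082

    @field_validator("treatment_amplitudes")
    @classmethod
    def _amplitudes_nonnegative(cls, v: dict[str, float]) -> dict[str, float]:
        if any(a < 0 for a in v.values()):
            raise ValueError("treatment amplitudes must be >= 0")
        return v


def _treatment_effect(no3_pct: int, breakpoint: int, amplitude: float) -> float:
    """Flat at 0 for NO₃⁻ ≥ breakpoint, rising linearly to `amplitude` at 0% NO₃⁻."""
    if no3_pct >= breakpoint:
        return 0.0
    return amplitude * (breakpoint - no3_pct) / breakpoint


def generate_n_experiment(config: SyntheticConfig | None = None) -> list[SampleRecord]:
    """Simulate the N-fertilization gradient experiment.

    Emits water (leaf, root, soil), sugars/starch/cellulose (leaf and root),
    and the four leaf n-alkane chains for every treatment × replicate, with
    independent Gaussian noise per record.  Deterministic for a given seed.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    noise = lambda: float(rng.normal(0.0, config.noise_sd)) if config.noise_sd else 0.0

    root_water_true = config.irrigation_water
    leaf_water_true = root_water_true + config.leaf_root_water_offset
    soil_water_true = root_water_true + config.soil_minus_root_water

    records: list[SampleRecord] = []

    def add(compound: str, tissue: str, treatment: int, replicate: int, true_delta: float):
        records.append(
            SampleRecord(
                sample_id=f"N{treatment:03d}-{tissue}-{compound}-r{replicate}",
                compound=compound,
                tissue=tissue,
                treatment=treatment,
                replicate=replicate,
                delta2H=true_delta + noise(),
            )
        )

    for treatment in config.treatments:
        for replicate in range(1, config.n_replicates + 1):
            add("water", "leaf", treatment, replicate, leaf_water_true)
            add("water", "root", treatment, replicate, root_water_true)
            add("water", "soil", treatment, replicate, soil_water_true)

            for compound in ("sugars", "starch", "cellulose"):
                effect = _treatment_effect(
                    treatment, config.treatment_breakpoint,
                    config.treatment_amplitudes[compound],
                )
                leaf_true = leaf_water_true + config.base_eps_a[compound] + effect
                sparse = (
                    config.apply_missingness
                    and compound == "cellulose"
                    and treatment in config.missing_treatments
                    and replicate > config.missing_max_replicates
                )
                if not sparse:
                    add(compound, "leaf", treatment, replicate, leaf_true)
                    add(compound, "root", treatment, replicate,
                        leaf_true + config.root_minus_leaf_offsets[compound])

            alkane_sparse = (
                config.apply_missingness
                and treatment in config.missing_treatments
                and replicate > config.missing_max_replicates
            )
            if not alkane_sparse:
                for chain in ALKANE_CHAINS:
                    add(f"alkane_C{chain}", "leaf", treatment, replicate,
                        leaf_water_true + config.alkane_eps_a)

    return records


def generate_pgm_experiment(config: SyntheticConfig | None = None) -> list[SampleRecord]:
    """Simulate the WT vs. starch-deficient *pgm* leaf experiment.

    The WT baseline uses the configured leaf-water and ε_a values; *pgm*
    carbohydrates are shifted by the configured genotype offsets while
    alkanes carry no genotype effect (the observed null result).
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed + 1)
    noise = lambda: float(rng.normal(0.0, config.noise_sd)) if config.noise_sd else 0.0

    leaf_water_true = config.irrigation_water + config.leaf_root_water_offset
    records: list[SampleRecord] = []
    for genotype in ("WT", "pgm"):
        for replicate in range(1, config.n_replicates + 1):
            def add(compound: str, true_delta: float):
                records.append(
                    SampleRecord(
                        sample_id=f"{genotype}-leaf-{compound}-r{replicate}",
                        compound=compound,
                        tissue="leaf",
                        treatment=genotype,
                        replicate=replicate,
                        delta2H=true_delta + noise(),
                    )
                )

            add("water", leaf_water_true)
            for compound in ("sugars", "starch", "cellulose"):
                true = leaf_water_true + config.base_eps_a[compound]
                if genotype == "pgm":
                    true += config.pgm_offsets[compound]
                add(compound, true)
            for chain in ALKANE_CHAINS:
                add(f"alkane_C{chain}", leaf_water_true + config.alkane_eps_a)
    return records


def generate_equilibration_raw(
    true_delta_ne: Sequence[float],
    true_x_e: Sequence[float],
    config: SyntheticConfig | None = None,
    seed: int | None = None,
) -> list[EquilibrationMeasurement]:
    """Forward-simulate raw dual-equilibration measurements.

    Each (δ²H_ne, x_e) truth yields an (e1, e2) pair from the forward
    equilibration model with independent Gaussian noise of sd ``noise_sd``
    on each equilibrated value.
    """
    config = config or SyntheticConfig()
    if len(true_delta_ne) != len(true_x_e):
        raise ValueError("true_delta_ne and true_x_e must have equal length")
    if any(not (0.0 <= x <= 1.0) for x in true_x_e):
        raise ValueError("true x_e values must lie in [0, 1]")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    measurements = []
    for i, (ne, x) in enumerate(zip(true_delta_ne, true_x_e)):
        e1 = forward_equilibrate(ne, x, config.delta_w1, config.alpha_ew)
        e2 = forward_equilibrate(ne, x, config.delta_w2, config.alpha_ew)
        if config.noise_sd:
            e1 += float(rng.normal(0.0, config.noise_sd))
            e2 += float(rng.normal(0.0, config.noise_sd))
        measurements.append(
            EquilibrationMeasurement(
                sample_id=f"sim-{i:04d}",
                delta_e1=e1,
                delta_e2=e2,
                delta_w1=config.delta_w1,
                delta_w2=config.delta_w2,
                alpha_ew=config.alpha_ew,
            )
        )
    return measurements


def generate_re_scenario(
    true_f: float,
    eps_a: float = -171.0,
    eps_h_star: float = 158.0,
    leaf_water_mean: float = -49.7,
    leaf_water_sd: float = 5.0,
    source_water: float = -79.3,
    noise_sd: float = 3.0,
    n: int = 100,
    seed: int = 0,
):
    """Simulate cellulose observations from the two-pool model for inversion tests.

    Leaf water varies across samples (Gaussian around ``leaf_water_mean``);
    source water is held at the irrigation value.  Observations are the
    forward model plus Gaussian noise of sd ``noise_sd``.  Returns a frame
    with sample_id, treatment, leaf_water, root_water, observed_cellulose.
    """
    import pandas as pd

    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    params = REParameters(eps_a_star=eps_a, eps_h_star=eps_h_star, f=true_f)
    leaf = leaf_water_mean + (rng.normal(0.0, leaf_water_sd, size=n) if leaf_water_sd else 0.0)
    leaf = np.broadcast_to(leaf, (n,)).astype(float)
    observed = np.array([re_forward(lw, source_water, params) for lw in leaf])
    if noise_sd:
        observed = observed + rng.normal(0.0, noise_sd, size=n)
    return pd.DataFrame(
        {
            "sample_id": [f"re-{i:04d}" for i in range(n)],
            "treatment": ["scenario"] * n,
            "leaf_water": leaf,
            "root_water": np.full(n, source_water),
            "observed_cellulose": observed,
        }
    )
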