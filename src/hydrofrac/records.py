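"""In-memory tabular form of sample records.

Most analysis operations work on a pandas DataFrame with one row per
:class:`~hydrofrac.types.SampleRecord`; these helpers convert and validate.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .types import COMPOUNDS, MIN_DELTA, TISSUES, SampleRecord

SAMPLE_COLUMNS = ["sample_id", "compound", "tissue", "treatment", "replicate", "delta2H"]

__all__ = ["SAMPLE_COLUMNS", "records_to_frame", "frame_to_records", "validate_samples_frame", "as_frame"]


def records_to_frame(records: Iterable[SampleRecord]) -> pd.DataFrame:
    """Stack sample records into the canonical samples table."""
    return pd.DataFrame(
        [
            (r.sample_id, r.compound, r.tissue, r.treatment, r.replicate, r.delta2H)
            for r in records
        ],
        columns=SAMPLE_COLUMNS,
    )


def frame_to_records(df: pd.DataFrame) -> list[SampleRecord]:
    return [
        SampleRecord(
            sample_id=str(row.sample_id),
            compound=row.compound,
            tissue=row.tissue,
            treatment=row.treatment,
            replicate=int(row.replicate),
            delta2H=float(row.delta2H),
        )
        for row in df.itertuples(index=False)
    ]


def validate_samples_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a samples table, raising with row numbers on bad content.

    Checks the schema, compound/tissue vocabularies, the physical delta
    bound, and uniqueness of (compound, tissue, treatment, replicate).
    """
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"samples table is missing columns: {missing}")
    df = df[SAMPLE_COLUMNS].copy()

    bad_compound = df.index[~df["compound"].isin(COMPOUNDS)].tolist()
    if bad_compound:
        values = sorted(df.loc[bad_compound, "compound"].unique())
        raise ValueError(f"unknown compounds {values} at rows {bad_compound}")
    bad_tissue = df.index[~df["tissue"].isin(TISSUES)].tolist()
    if bad_tissue:
        values = sorted(df.loc[bad_tissue, "tissue"].unique())
        raise ValueError(f"unknown tissues {values} at rows {bad_tissue}")

    deltas = pd.to_numeric(df["delta2H"], errors="coerce")
    bad_delta = df.index[~(deltas > MIN_DELTA) | ~deltas.apply(pd.notna)].tolist()
    if bad_delta:
        raise ValueError(
            f"delta2H values out of physical range (finite, > {MIN_DELTA}‰) at rows {bad_delta}"
        )
    df["delta2H"] = deltas.astype(float)
    df["replicate"] = df["replicate"].astype(int)

    key = ["compound", "tissue", "treatment", "replicate"]
    dup = df[df.duplicated(key, keep=False)]
    if not dup.empty:
        first = dup.iloc[0]
        raise ValueError(
            "duplicate sample key "
            f"(compound={first.compound!r}, tissue={first.tissue!r}, "
            f"treatment={first.treatment!r}, replicate={first.replicate})"
        )
    return df


def as_frame(data) -> pd.DataFrame:
    """Accept either a samples DataFrame or an iterable of SampleRecord."""
    if isinstance(data, pd.DataFrame):
        return data
    return records_to_frame(data)
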