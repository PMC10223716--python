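"""Telemetry CSV reading and writing.

One row per logging tick: supervisor phase, the three balance readings,
pump commands (V) and reported speeds (RPM), the current loss-in-weight
flow estimate, and true CSTR volumes.  Files carry a schema-versioned
comment header line so later schema changes stay detectable; numeric
columns round-trip at full precision (shortest-repr floats).
"""

from __future__ import annotations

import pandas as pd

from .control import TELEMETRY_COLUMNS

__all__ = [
    "SCHEMA_HEADER",
    "TelemetrySchemaError",
    "TelemetryMonotonicityError",
    "write_telemetry",
    "read_telemetry",
]

SCHEMA_HEADER = "# cstrtwin-telemetry v1"


class TelemetrySchemaError(ValueError):
    """Telemetry file header or columns do not match the schema."""


class TelemetryMonotonicityError(ValueError):
    """Telemetry timestamps are not strictly increasing."""


def write_telemetry(records: pd.DataFrame, path) -> None:
    """Write telemetry with the schema header; validates columns and time."""
    _validate(records)
    with open(path, "w", newline="") as fh:
        fh.write(SCHEMA_HEADER + "\n")
        records.to_csv(fh, index=False)


def read_telemetry(path) -> pd.DataFrame:
    """Read and validate a telemetry CSV written by :func:`write_telemetry`."""
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != SCHEMA_HEADER:
            raise TelemetrySchemaError(
                f"missing or unknown schema header (got {first!r}, "
                f"expected {SCHEMA_HEADER!r})"
            )
        df = pd.read_csv(fh, float_precision="round_trip")
    _validate(df)
    return df


def _validate(df: pd.DataFrame) -> None:
    missing = [c for c in TELEMETRY_COLUMNS if c not in df.columns]
    if missing:
        raise TelemetrySchemaError(f"telemetry missing column(s): {', '.join(missing)}")
    t = df["time_s"].to_numpy()
    if len(t) > 1:
        bad = (t[1:] <= t[:-1]).nonzero()[0]
        if bad.size:
            row = int(bad[0]) + 1
            raise TelemetryMonotonicityError(
                f"non-monotone time_s at row {row} "
                f"({t[row]} follows {t[row - 1]})"
            )
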