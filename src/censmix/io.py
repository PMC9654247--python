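"""Reading and writing the four-column detection-limit table.

The canonical on-disk form is a CSV with header ``Observations, LDL,
UDL, Cut`` (names remappable).  Unquantifiable entries are encoded as
the literal strings ``-Inf`` (below the LDL) and ``Inf``/``+Inf``
(above the UDL), case-insensitively.  An empty LDL means "no lower
limit" (0), an empty UDL means "no upper limit" (infinity) and an empty
Cut defaults to censored.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .likelihood import ObservationSet

__all__ = ["DEFAULT_COLUMNS", "read_table", "write_table", "observations_to_frame"]

DEFAULT_COLUMNS = {
    "values": "Observations",
    "ldl": "LDL",
    "udl": "UDL",
    "cut": "Cut",
}


def _parse_value(raw, row: int) -> float:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        raise ValueError(f"row {row}: missing observation (UnQ entries must be -Inf or Inf)")
    text = str(raw).strip().lower()
    if text in ("-inf", "-infinity"):
        return -math.inf
    if text in ("inf", "+inf", "infinity", "+infinity"):
        return math.inf
    try:
        return float(raw)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"row {row}: cannot parse observation {raw!r}") from exc


def read_table(path, column_map: dict[str, str] | None = None) -> ObservationSet:
    """Load an :class:`ObservationSet` from a four-column CSV.

    ``column_map`` remaps the logical names ``values``/``ldl``/``udl``/
    ``cut`` to the file's actual column headers.  Malformed rows are
    reported with their 1-based data row number, never dropped.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(cols)
        if unknown:
            raise ValueError(f"unknown column-map keys: {sorted(unknown)}")
        cols.update(column_map)
    frame = pd.read_csv(path, dtype=str, keep_default_na=True)
    if cols["values"] not in frame.columns:
        raise ValueError(f"missing observation column {cols['values']!r} in {path}")
    n = len(frame)
    if n == 0:
        raise ValueError(f"{path}: no data rows")

    values = np.array(
        [_parse_value(v, i + 1) for i, v in enumerate(frame[cols["values"]])]
    )

    def numeric_column(key: str, default: float) -> np.ndarray:
        name = cols[key]
        if name not in frame.columns:
            return np.full(n, default)
        out = np.empty(n)
        for i, raw in enumerate(frame[name]):
            if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
                out[i] = default
            else:
                try:
                    out[i] = float(raw)
                except (TypeError, ValueError) as exc:
                    raise ValueError(f"row {i + 1}: cannot parse {key.upper()} {raw!r}") from exc
        return out

    ldl = numeric_column("ldl", 0.0)
    udl = numeric_column("udl", math.inf)
    if cols["cut"] in frame.columns:
        cut = [
            "censored" if (c is None or (isinstance(c, float) and math.isnan(c)) or str(c).strip() == "") else str(c)
            for c in frame[cols["cut"]]
        ]
    else:
        cut = ["censored"] * n
    return ObservationSet(values, ldl, udl, cut)


def observations_to_frame(obs: ObservationSet) -> pd.DataFrame:
    """The canonical four-column representation of an observation set."""
    def fmt(v: float) -> str:
        if v == -math.inf:
            return "-Inf"
        if v == math.inf:
            return "Inf"
        return repr(float(v))

    return pd.DataFrame(
        {
            "Observations": [fmt(v) for v in obs.values],
            "LDL": obs.ldl,
            "UDL": ["" if math.isinf(u) else u for u in obs.udl],
            "Cut": list(obs.cut),
        }
    )


def write_table(obs: ObservationSet, path) -> None:
    observations_to_frame(obs).to_csv(path, index=False)
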