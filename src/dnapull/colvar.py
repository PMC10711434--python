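"""Reading and writing COLVAR-style whitespace tables.

The steering engine and the toy simulator exchange data through the same
plain-text format: a `#! FIELDS <names...>` header line, optional
`#! SET key value` metadata lines, then one whitespace-delimited row per
stored step. This keeps engine output and toy output interchangeable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import AnalysisError


def write_colvar(
    path,
    columns: Mapping[str, np.ndarray],
    meta: Mapping[str, object] | None = None,
) -> None:
    """Write named columns as a COLVAR table with a FIELDS header."""
    names = list(columns)
    arrays = [np.asarray(columns[n], dtype=float) for n in names]
    n = arrays[0].size
    for name, a in zip(names, arrays):
        if a.ndim != 1 or a.size != n:
            raise AnalysisError(f"column {name!r} is not a length-{n} vector")
    lines = ["#! FIELDS " + " ".join(names)]
    for key, value in (meta or {}).items():
        lines.append(f"#! SET {key} {value}")
    mat = np.column_stack(arrays)
    for row in mat:
        lines.append(" ".join(format(v, ".10g") for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_colvar(path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Parse a COLVAR table into a DataFrame plus `#! SET` metadata."""
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise AnalysisError(f"{path}: empty COLVAR file")
    header = lines[0]
    if not header.startswith("#! FIELDS"):
        raise AnalysisError(f"{path}: missing '#! FIELDS' header line")
    names = header.split()[2:]
    if not names:
        raise AnalysisError(f"{path}: FIELDS header names no columns")
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    for i, ln in enumerate(lines[1:], start=2):
        if ln.startswith("#! SET"):
            parts = ln.split(maxsplit=3)
            if len(parts) >= 4:
                meta[parts[2]] = parts[3]
            continue
        if ln.startswith("#"):
            continue
        values = ln.split()
        if len(values) != len(names):
            raise AnalysisError(
                f"{path}:{i}: expected {len(names)} columns, found {len(values)}"
            )
        try:
            rows.append([float(v) for v in values])
        except ValueError as exc:
            raise AnalysisError(f"{path}:{i}: non-numeric value ({exc})") from None
    if not rows:
        raise AnalysisError(f"{path}: no data rows")
    frame = pd.DataFrame(np.asarray(rows, dtype=float), columns=names)
    return frame, meta
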