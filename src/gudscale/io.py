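"""CSV round-tripping with provenance headers.

Every artifact the pipeline writes is a plain CSV preceded by ``#`` comment
lines recording the package version, the seed and a hash of the
configuration, so any table can be traced back to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

__all__ = ["config_hash", "write_table", "read_table"]


def config_hash(obj) -> str:
    """Stable short hash of an (arbitrarily nested) configuration object."""

    def default(o):
        if hasattr(o, "__dict__"):
            return {"__class__": type(o).__name__, **o.__dict__}
        if hasattr(o, "_asdict"):
            return o._asdict()
        return repr(o)

    payload = json.dumps(obj, default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    from . import __version__

    lines = [f"# gudscale {__version__}"]
    for key, val in (meta or {}).items():
        lines.append(f"# {key}={val}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
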