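"""CSV/JSON interchange with provenance headers.

Every artifact starts with ``#``-prefixed comment lines recording the
package version, the seed and a hash of the configuration, so a result can
always be traced to the run that produced it.  The pipeline's own readers
skip these lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance(seed=None, config: dict | None = None) -> dict:
    meta = {"bvitals_version": __version__}
    if seed is not None:
        meta["seed"] = seed
    if config is not None:
        meta["config_hash"] = config_hash(config)
    return meta


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p


def write_csv(df: pd.DataFrame, path, meta: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)
    return path


def read_csv(path, parse_dates=None) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", parse_dates=parse_dates)


def write_json(obj, path, meta: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"_meta": meta or {}}
    payload.update(obj)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
    return path


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
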