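"""Delimited-table I/O with provenance headers.

Every artifact the pipeline writes starts with comment lines of the form
``# pathgxe key=value``; the ``config_hash`` key lets downstream stages
refuse to mix artifacts produced under different configurations.
"""

from __future__ import annotations

import hashlib
import json
from typing import Mapping

import pandas as pd


class ProvenanceError(ValueError):
    pass


def config_hash(effective_config: Mapping) -> str:
    """Stable 12-hex digest of a JSON-serializable effective config."""
    canon = json.dumps(effective_config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, meta: Mapping[str, object] | None = None) -> None:
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# pathgxe {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path, expect_hash: str | None = None, **kwargs) -> pd.DataFrame:
    """Read a pathgxe TSV, checking the config hash if one is expected."""
    meta = read_meta(path)
    if expect_hash is not None:
        got = meta.get("config_hash")
        if got != expect_hash:
            raise ProvenanceError(
                f"{path}: config hash mismatch (artifact {got!r}, run {expect_hash!r}); "
                "refusing to mix artifacts from different configurations"
            )
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_meta(path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line.strip().lstrip("# ").split(maxsplit=1)
            if parts and parts[0] == "pathgxe" and len(parts) == 2 and "=" in parts[1]:
                key, value = parts[1].split("=", 1)
                meta[key] = value
    return meta
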