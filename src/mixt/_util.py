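"""Shared helpers: seed derivation, logging, TSV conventions."""

from __future__ import annotations

import hashlib
import logging

import pandas as pd

SCHEMA_VERSION = "1"

log = logging.getLogger("mixt")


def setup_logging(level: str = "INFO") -> None:
    """Configure plain-text logging to stderr (idempotent)."""
    root = logging.getLogger("mixt")
    if not root.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
        root.addHandler(handler)
    root.setLevel(level.upper())


def derive_seed(master: int, *identifiers) -> int:
    """Derive a reproducible sub-seed from a master seed and string identifiers.

    Stable across runs and platforms (blake2b of the joined key), so any single
    stage or test can be re-run in isolation with the same stream.
    """
    key = ":".join([str(int(master))] + [str(x) for x in identifiers])
    digest = hashlib.blake2b(key.encode(), digest_size=8).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a results table as TSV with a schema-version comment line."""
    with open(path, "w") as fh:
        fh.write(f"# mixt-schema-version: {SCHEMA_VERSION}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
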