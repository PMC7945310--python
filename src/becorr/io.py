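"""Plain-text table I/O with provenance headers.

Every TSV the pipeline writes starts with a single ``#`` comment line
naming the producing package version, the stage and its parameters, so
outputs are self-describing and diff-able.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

import becorr


def write_tsv(df: pd.DataFrame, path, stage: str, params: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    parts = [f"becorr v{becorr.__version__}", f"stage={stage}"]
    for k, v in (params or {}).items():
        parts.append(f"{k}={v}")
    with open(path, "w") as fh:
        fh.write("# " + " ".join(parts) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_sample_sheet(path) -> pd.DataFrame:
    df = read_tsv(path)
    required = {"sample_id"}
    if not required <= set(df.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    return df


def file_checksum(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, stages: list[dict]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump({"becorr_version": becorr.__version__, "stages": stages}, fh, indent=2)
        fh.write("\n")
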