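"""TSV output with self-describing commented metadata headers."""

from __future__ import annotations

import datetime
import hashlib
import json

import pandas as pd

from . import __version__


def metadata_lines(meta: dict, timestamp: bool = True) -> list[str]:
    lines = [f"# modact_version={__version__}"]
    if timestamp:
        lines.append(f"# timestamp={datetime.datetime.now().isoformat(timespec='seconds')}")
    for key, value in meta.items():
        lines.append(f"# {key}={value}")
    digest = hashlib.sha1(json.dumps(meta, sort_keys=True, default=str).encode()).hexdigest()[:12]
    lines.append(f"# config_hash={digest}")
    return lines


def write_tsv(df: pd.DataFrame, path, meta: dict, timestamp: bool = True, index_label: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in metadata_lines(meta, timestamp=timestamp):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
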