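"""Tab-separated readers/writers for every table the pipeline exchanges.

Annotations use 1-based inclusive coordinates (array-manifest style, not
BED); the dialect is stated in a comment header on write.  Matrices are
features x samples with the feature id as the first column.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

_COORD_HEADER = "# coordinates: 1-based, inclusive\n"


def write_annotation(df: pd.DataFrame, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_COORD_HEADER)
        df.to_csv(fh, sep="\t")


def read_annotation(path, index_col: int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, comment="#")


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
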