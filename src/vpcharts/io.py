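"""Reading and writing profile specifications, sample streams and limits.

Profile specifications are YAML or JSON mappings with keys ``B`` (row-major
coefficient matrix, rows = intercept then the q slopes), ``Sigma`` and
``designs`` (mapping from sample size to a design matrix; a leading ones
column is added if absent).  Sample streams are tidy CSV files with columns
``sample_id, x1..xq, y1..yp``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import ProfileModel


def load_profile_spec(path: str | Path) -> ProfileModel:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    B = np.asarray(data["B"], dtype=float)
    Sigma = np.asarray(data["Sigma"], dtype=float)
    q = B.shape[0] - 1
    designs = {}
    for key, mat in (data.get("designs") or {}).items():
        X = np.atleast_2d(np.asarray(mat, dtype=float))
        if X.shape[1] == q:  # covariates only: prepend the intercept column
            X = np.column_stack([np.ones(X.shape[0]), X])
        designs[int(key)] = X
    return ProfileModel(B=B, Sigma=Sigma, designs=designs)


def dump_profile_spec(model: ProfileModel, path: str | Path) -> None:
    data = {
        "B": model.B.tolist(),
        "Sigma": model.Sigma.tolist(),
        "designs": {int(n): X.tolist() for n, X in model.designs.items()},
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_stream(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError("stream file must have a sample_id column")
    return df


def write_stream(stream: pd.DataFrame, path: str | Path) -> None:
    stream.to_csv(path, index=False)


def write_limits(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_limits(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
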