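"""Delimited-text I/O for grids and fields, with JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np


def write_matrix(path, array: np.ndarray, sidecar: dict) -> None:
    """Write a 2-D array as TSV plus ``<path>.json`` metadata."""
    path = Path(path)
    np.savetxt(path, np.asarray(array), fmt="%.6g", delimiter="\t")
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)


def read_matrix(path):
    path = Path(path)
    arr = np.loadtxt(path, delimiter="\t")
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        sidecar = json.load(fh)
    return arr, sidecar


def write_letter_matrix(path, letters: np.ndarray) -> None:
    """Letter-coded matrix (service-level / region maps)."""
    with open(path, "w") as fh:
        for row in letters:
            fh.write("".join(row) + "\n")
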