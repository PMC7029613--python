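"""Minimal read-only support for the BIOM table format.

Handles the two dialects seen in the wild: BIOM 1.0 (JSON, sparse or dense)
and BIOM 2.x (HDF5 with CSR data under the ``observation/matrix`` group).
Only the abundance matrix and the observation/sample IDs are read; metadata
is ignored.  Returns a features x samples pandas DataFrame.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd


def _read_biom_json(path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    rows = [str(r["id"]) for r in doc["rows"]]
    cols = [str(c["id"]) for c in doc["columns"]]
    mat = np.zeros((len(rows), len(cols)))
    if doc.get("matrix_type", "sparse") == "dense":
        mat[:] = np.asarray(doc["data"], dtype=float)
    else:
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    return pd.DataFrame(mat, index=rows, columns=cols)


def _read_biom_hdf5(path) -> pd.DataFrame:
    import h5py
    from scipy.sparse import csr_matrix

    with h5py.File(path, "r") as fh:
        rows = [i.decode() if isinstance(i, bytes) else str(i)
                for i in fh["observation/ids"][:]]
        cols = [i.decode() if isinstance(i, bytes) else str(i)
                for i in fh["sample/ids"][:]]
        grp = fh["observation/matrix"]
        mat = csr_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
            shape=(len(rows), len(cols)),
        ).toarray()
    return pd.DataFrame(mat.astype(float), index=rows, columns=cols)


def read_biom(path) -> pd.DataFrame:
    """Read a BIOM file (JSON or HDF5 dialect) as a features x samples frame."""
    with open(path, "rb") as fh:
        magic = fh.read(8)
    if magic.startswith(b"\x89HDF"):
        return _read_biom_hdf5(path)
    return _read_biom_json(path)
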