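"""Matrix round-trip: dense TSV + coordinate-triplet TSV + JSON sidecar."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ..contacts.matrix import ContactMatrix


def _p(prefix, ext) -> Path:
    return Path(str(prefix) + ext)


def write_matrix(matrix: ContactMatrix, prefix) -> None:
    """Write ``<prefix>.dense.tsv``, ``<prefix>.triplet.tsv`` and
    ``<prefix>.json`` (bin size, chromosome layout, totals)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(_p(prefix, ".dense.tsv"), matrix.counts, delimiter="\t",
               fmt="%.12g")
    i, j = np.nonzero(np.triu(matrix.counts))
    pd.DataFrame({"bin1": i, "bin2": j, "count": matrix.counts[i, j]}).to_csv(
        _p(prefix, ".triplet.tsv"), sep="\t", index=False
    )
    meta = {
        "bin_size": matrix.bin_size,
        "chroms": [[c, int(L)] for c, L in matrix.chroms],
        "normalized": matrix.normalized,
        "total_contacts": matrix.total_contacts,
        "n": matrix.n,
    }
    _p(prefix, ".json").write_text(json.dumps(meta, indent=1))


def read_matrix(prefix) -> ContactMatrix:
    prefix = Path(prefix)
    sidecar = _p(prefix, ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar missing: {sidecar}")
    meta = json.loads(sidecar.read_text())
    counts = np.loadtxt(_p(prefix, ".dense.tsv"), delimiter="\t", ndmin=2)
    return ContactMatrix(
        counts,
        meta["bin_size"],
        [(c, L) for c, L in meta["chroms"]],
        normalized=meta["normalized"],
        total_contacts=meta["total_contacts"],
    )
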