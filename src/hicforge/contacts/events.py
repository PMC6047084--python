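"""Event-level operations: fragment assignment, artifact filtering,
subsampling.

Events live in a pandas DataFrame with columns ``chrom1 pos1 strand1 chrom2
pos2 strand2`` (canonically ordered so that (chrom1, pos1) <= (chrom2,
pos2)), plus optional ``frag1/frag2``, ``mapq1/mapq2`` and
``homolog1/homolog2`` columns.
"""
from __future__ import annotations

from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd

from .matrix import ContactMatrix, FragmentMap, _locate_column

EVENT_COLUMNS = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]


def assign_fragments(events: pd.DataFrame, fragment_map: FragmentMap) -> pd.DataFrame:
    """Attach global fragment indices (``frag1``, ``frag2``) and an
    ``intra_fragment`` flag to each event."""
    out = events.copy()
    if len(out) == 0:
        out["frag1"] = out["frag2"] = np.array([], dtype=np.int64)
        out["intra_fragment"] = np.array([], dtype=bool)
        return out
    out["frag1"] = _locate_column(out, "chrom1", "pos1", fragment_map)
    out["frag2"] = _locate_column(out, "chrom2", "pos2", fragment_map)
    out["intra_fragment"] = out["frag1"] == out["frag2"]
    return out


def _orientation(events: pd.DataFrame) -> pd.Series:
    """'tandem' (same strand), 'inward' (+/-) or 'outward' (-/+) under
    canonical pos1 <= pos2 ordering."""
    s1, s2 = events["strand1"], events["strand2"]
    out = pd.Series("tandem", index=events.index)
    out[(s1 == "+") & (s2 == "-")] = "inward"
    out[(s1 == "-") & (s2 == "+")] = "outward"
    return out


def filter_events(
    events: pd.DataFrame, mode: str = "matrix", min_dist: int = 1500
) -> pd.DataFrame:
    """Remove religation / self-circularization artifacts.

    ``matrix`` mode discards intra-fragment events and short-range
    (< ``min_dist``) convergent or divergent same-chromosome pairs, which
    are dominated by undigested and self-circularized molecules.  ``ps``
    mode keeps only same-orientation (tandem) intra-chromosomal pairs at
    distance >= ``min_dist``, the stricter guard used for distance-decay
    curves.  Trans-chromosomal pairs always pass.
    """
    if mode not in ("matrix", "ps"):
        raise ValueError("mode must be 'matrix' or 'ps'")
    if len(events) == 0:
        return events.copy()
    cis = events["chrom1"] == events["chrom2"]
    dist = (events["pos2"] - events["pos1"]).abs()
    orient = _orientation(events)
    if mode == "matrix":
        drop = cis & (orient != "tandem") & (dist < min_dist)
        if "intra_fragment" in events.columns:
            drop |= events["intra_fragment"]
        return events[~drop].copy()
    drop = cis & ((orient != "tandem") | (dist < min_dist))
    return events[~drop].copy()


def subsample(
    data: Union[pd.DataFrame, ContactMatrix],
    N: int,
    seed: Optional[Union[int, np.random.Generator]] = None,
) -> Union[pd.DataFrame, ContactMatrix]:
    """Uniform without-replacement draw of ``N`` contacts.

    Events: row subsample.  Matrix: multivariate hypergeometric draw over
    the upper triangle (symmetry preserved).  Seed-reproducible.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(data, pd.DataFrame):
        if N > len(data):
            raise ValueError(f"N={N} exceeds total {len(data)}")
        idx = rng.choice(len(data), size=N, replace=False)
        idx.sort()
        return data.iloc[idx].reset_index(drop=True)

    if data.normalized:
        raise ValueError("subsample operates on raw counts")
    counts = data.counts
    iu = np.triu_indices(data.n)
    vec = np.rint(counts[iu]).astype(np.int64)
    total = int(vec.sum())
    if N > total:
        raise ValueError(f"N={N} exceeds total {total}")
    drawn = rng.multivariate_hypergeometric(vec, N)
    M = np.zeros_like(counts)
    M[iu] = drawn
    M = M + M.T
    M[np.diag_indices(data.n)] /= 2.0
    out = data.copy()
    out.counts = M
    out.total_contacts = N
    return out
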