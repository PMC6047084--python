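"""Synthetic restriction maps, pair-probability models and read sampling."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from ..contacts.matrix import FragmentMap
from .config import SyntheticConfig


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def make_restriction_map(
    config: SyntheticConfig, seed=None
) -> FragmentMap:
    """Regular (fixed d) or geometric (i.i.d. gaps with mean d) fragment map."""
    rng = _rng(config.seed if seed is None else seed)
    L, d = config.L, config.d
    if config.map_mode == "regular":
        bounds = np.arange(0, L, d, dtype=np.int64)
        bounds = np.append(bounds, L) if bounds[-1] != L else bounds
    else:
        gaps = []
        total = 0
        while total < L:
            g = int(rng.geometric(1.0 / d))
            gaps.append(g)
            total += g
        bounds = np.concatenate([[0], np.cumsum(gaps)])
        bounds[-1] = L
        bounds = np.unique(bounds)
    return FragmentMap({config.chrom: bounds})


@dataclass
class ContactModel:
    """Discrete probability model over intra-chromosomal fragment pairs."""

    fragment_map: FragmentMap
    chrom: str
    i: np.ndarray  # left fragment (local index), i < j
    j: np.ndarray
    p: np.ndarray  # normalized pair probabilities
    weights: np.ndarray  # unnormalized weights
    anchors: Optional[np.ndarray] = None  # anchor fragment indices (meiotic overlay)

    @property
    def n_pairs(self) -> int:
        return self.p.size


def build_contact_model(
    fragment_map: FragmentMap,
    config: SyntheticConfig,
    seed=None,
) -> ContactModel:
    """Pair weights ``len_i^beta * len_j^beta * max(s_ij, s0)^-alpha *
    lambda_ij`` with ``lambda_ij`` lognormal (mean 1, CV c) drawn once per
    pair; the optional meiotic overlay multiplies anchor-pair and
    intra-domain weights."""
    rng = _rng(config.seed if seed is None else seed)
    chrom = config.chrom
    mids = fragment_map.midpoints(chrom)
    lens = fragment_map.lengths(chrom).astype(float)
    n = mids.size
    i, j = np.triu_indices(n, k=1)
    s = mids[j] - mids[i]
    w = (lens[i] ** config.beta) * (lens[j] ** config.beta)
    w = w * np.maximum(s, config.s0) ** (-config.alpha)
    if config.c > 0:
        sig2 = np.log1p(config.c**2)
        lam = rng.lognormal(mean=-sig2 / 2.0, sigma=np.sqrt(sig2), size=i.size)
        w = w * lam

    anchors = None
    if config.meiotic is not None:
        spec = config.meiotic
        # anchor positions with uniform spacings, mapped to fragments
        pos, cur = [], 0.0
        while True:
            cur += rng.uniform(spec.spacing_min, spec.spacing_max)
            if cur >= config.L:
                break
            pos.append(cur)
        anchors = fragment_map.locate(chrom, np.asarray(pos, dtype=np.int64)) - \
            fragment_map.offset(chrom)
        anchors = np.unique(anchors)
        aset = {int(a): k for k, a in enumerate(anchors)}
        # domain index of every fragment (between consecutive anchors)
        domain = np.searchsorted(anchors, np.arange(n), side="right")
        same_domain = domain[i] == domain[j]
        w = np.where(same_domain, w * spec.delta, w)
        ai = np.array([aset.get(int(x), -1) for x in i])
        aj = np.array([aset.get(int(x), -1) for x in j])
        both = (ai >= 0) & (aj >= 0)
        adj = both & (np.abs(aj - ai) == 1)
        nxt = both & (np.abs(aj - ai) == 2)
        w = np.where(adj, w * spec.kappa1, w)
        w = np.where(nxt, w * spec.kappa2, w)

    p = w / w.sum()
    return ContactModel(fragment_map, chrom, i, j, p, w, anchors)


def sample_reads(
    model: ContactModel, R: int, seed=None
) -> pd.DataFrame:
    """Draw R read pairs i.i.d. from the pair model.

    Per-pair counts are multinomial — approximately independent Poisson in
    the small-probability regime the crossover analysis assumes.  Each pair
    gets uniform positions inside its two fragments and random orientations.
    """
    rng = _rng(seed)
    if R < 0:
        raise ValueError("R must be nonnegative")
    fm, chrom = model.fragment_map, model.chrom
    b = fm.boundaries[chrom]
    starts, ends = b[:-1], b[1:]
    counts = rng.multinomial(R, model.p)
    nz = np.flatnonzero(counts)
    i = np.repeat(model.i[nz], counts[nz])
    j = np.repeat(model.j[nz], counts[nz])
    pos1 = rng.integers(starts[i], ends[i])
    pos2 = rng.integers(starts[j], ends[j])
    strands = np.array(["+", "-"])
    df = pd.DataFrame(
        {
            "chrom1": np.full(R, chrom, dtype=object),
            "pos1": pos1,
            "strand1": strands[rng.integers(0, 2, size=R)],
            "chrom2": np.full(R, chrom, dtype=object),
            "pos2": pos2,
            "strand2": strands[rng.integers(0, 2, size=R)],
            "frag1": i + fm.offset(chrom),
            "frag2": j + fm.offset(chrom),
        }
    )
    # canonical ordering holds by construction (i < j implies pos1 <= pos2
    # up to fragment boundaries); shuffle row order for realism
    perm = rng.permutation(len(df))
    return df.iloc[perm].reset_index(drop=True)


def mixed_poisson_counts(
    mu: float, c: float, n: int, seed=None
) -> np.ndarray:
    """Counts N ~ Poisson(mu * lambda), lambda lognormal with mean 1, CV c.

    The closed-form law Var(N) = mu + c^2 mu^2 makes this the oracle for
    the crossover fit.
    """
    rng = _rng(seed)
    if c > 0:
        sig2 = np.log1p(c**2)
        lam = rng.lognormal(mean=-sig2 / 2.0, sigma=np.sqrt(sig2), size=n)
    else:
        lam = np.ones(n)
    return rng.poisson(mu * lam)
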