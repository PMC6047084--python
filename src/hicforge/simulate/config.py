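"""Generator configuration and presets.

The generator is a statistical twin of a chromosome-conformation library,
not a polymer model: fragment maps are regular or geometric, pair
probabilities follow a truncated power-law distance decay with a
fragment-length capture bias and a latent per-pair heterogeneity factor,
and optional overlays add loop-anchor structure or a diploid homolog.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass
class LoopSpec:
    """Meiotic-like loop array: anchors at 5-50 kb spacings, contact
    enrichment between adjacent (kappa1) and next-adjacent (kappa2 < kappa1)
    anchors, and a milder intra-domain factor delta."""

    spacing_min: int = 5_000
    spacing_max: int = 50_000
    kappa1: float = 5.0
    kappa2: float = 2.0
    delta: float = 2.0

    def __post_init__(self):
        if not self.kappa1 >= self.kappa2 >= 1.0:
            raise ValueError("need kappa1 >= kappa2 >= 1")
        if self.delta < 1.0:
            raise ValueError("need delta >= 1")


@dataclass
class DiploidSpec:
    """Two homologs distinguished by substitutions only."""

    snp_rate: float = 0.02  # per-base substitution probability
    trans_rate: float = 0.07  # fraction of pairs bridging the homologs
    read_len: int = 75  # for the mappability (resolvable-end) flag
    pairing_scale: float = 10_000.0  # exponential scale of the trans offset kernel
    mappability: bool = False  # relabel unresolvable read ends as 'ambiguous'

    def __post_init__(self):
        if not 0 < self.snp_rate < 1:
            raise ValueError("snp_rate must be in (0, 1)")
        if not 0 <= self.trans_rate <= 1:
            raise ValueError("trans_rate must be in [0, 1]")


@dataclass
class SyntheticConfig:
    L: int = 150_000
    map_mode: str = "regular"  # regular | geometric
    d: int = 400  # fragment spacing (regular) or mean gap (geometric)
    alpha: float = 0.6  # distance-decay exponent
    s0: float = 1_000.0  # decay floor: kernel is max(s, s0)^-alpha
    beta: float = 1.0  # fragment-length capture-bias exponent
    c: float = 0.0  # latent pair heterogeneity CV
    R: int = 100_000  # read pairs
    seed: Optional[int] = None
    chrom: str = "chr_sim"
    meiotic: Optional[LoopSpec] = None
    diploid: Optional[DiploidSpec] = None

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.c < 0:
            raise ValueError("c must be nonnegative")
        if self.map_mode not in ("regular", "geometric"):
            raise ValueError("map_mode must be 'regular' or 'geometric'")
        if self.d >= self.L:
            raise ValueError("fragment spacing must be below region length")


def preset(name: str, **overrides) -> SyntheticConfig:
    """Named study conditions.

    - ``g1``: interphase library on a regularized 400-bp map; decay
      exponent 0.6, length bias 1, moderate latent heterogeneity
      (c = 0.316, crossover at ~10 reads/pair).
    - ``native_like``: same decay on a geometric map (mean fragment 400 bp)
      with strong heterogeneity (c = 1.0, crossover at ~1 read/pair).
    - ``meiotic``: g1 plus a loop-anchor overlay.
    - ``diploid``: g1 plus a substitution-diverged homolog with 7% trans
      contacts.
    """
    presets = {
        "g1": dict(map_mode="regular", d=400, alpha=0.6, beta=1.0, c=0.316),
        "native_like": dict(map_mode="geometric", d=400, alpha=0.6, beta=1.0, c=1.0),
        "meiotic": dict(
            map_mode="regular", d=400, alpha=0.6, beta=1.0, c=0.316,
            meiotic=LoopSpec(),
        ),
        "diploid": dict(
            map_mode="regular", d=400, alpha=0.6, beta=1.0, c=0.316,
            diploid=DiploidSpec(),
        ),
    }
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; known: {sorted(presets)}")
    kw = dict(presets[name])
    kw.update(overrides)
    return SyntheticConfig(**kw)
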