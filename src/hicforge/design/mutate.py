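"""Single-base site deletion and creation under mask / synonymy / panel rules.

Candidate ranking is fully deterministic: transitions (A<->G, C<->T) before
transversions, then leftmost position, then alphabetical alternate base.
A substitution is validated by rescanning a neighborhood of ``site length - 1``
on each side for every panel enzyme: a single substitution can only complete
a site that overlaps it, so this radius is sufficient.
"""
from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Set, Tuple

from .mask import CdsIndex, ForbiddenMask
from .records import Enzyme, Mutation, SiteEditError
from .sites import scan_sites

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _candidate_rank(ref: str, pos: int, alt: str) -> tuple:
    return (0 if TRANSITION[ref] == alt else 1, pos, alt)


def _neighborhood_sites(
    seq: Sequence[str], pos: int, panel: Iterable[Enzyme], alt: Optional[str] = None
) -> Set[Tuple[str, int]]:
    """(enzyme, site start) pairs found near ``pos`` (with ``alt`` applied
    when given)."""
    panel = list(panel)
    mmax = max(len(e) for e in panel)
    lo = max(0, pos - mmax + 1)
    hi = min(len(seq), pos + mmax)
    window = list(seq[lo:hi])
    if alt is not None:
        window[pos - lo] = alt
    text = "".join(window)
    found: Set[Tuple[str, int]] = set()
    for enz in panel:
        for p in scan_sites(text, enz):
            found.add((enz.name, lo + p))
    return found


def collateral_sites(
    seq: Sequence[str],
    pos: int,
    alt: str,
    panel: Iterable[Enzyme],
    allow: Set[Tuple[str, int]] = frozenset(),
) -> Set[Tuple[str, int]]:
    """Panel sites that the substitution would newly create (minus ``allow``)."""
    panel = list(panel)
    before = _neighborhood_sites(seq, pos, panel)
    after = _neighborhood_sites(seq, pos, panel, alt=alt)
    return (after - before) - set(allow)


def _in_protected(pos: int, protected: Iterable[Tuple[int, int]]) -> bool:
    return any(a <= pos < b for a, b in protected)


def delete_site(
    seq: Sequence[str],
    site_pos: int,
    enzyme: Enzyme,
    mask: ForbiddenMask,
    cds_index: CdsIndex,
    panel: Iterable[Enzyme],
    protected: Iterable[Tuple[int, int]] = (),
) -> Mutation:
    """Minimal substitution destroying the site at ``site_pos``.

    The chosen base change must sit on a free (non-forbidden, non-protected)
    position, be synonymous in every overlapping CDS, and create no new site
    of any panel enzyme.  Raises :class:`SiteEditError` with per-candidate
    reasons when no candidate qualifies.
    """
    panel = list(panel)
    protected = list(protected)
    site = enzyme.site
    if "".join(seq[site_pos : site_pos + len(site)]) != site:
        raise ValueError(f"no {enzyme.name} site at {site_pos}")
    reasons = {}
    candidates: List[Tuple[tuple, Mutation]] = []
    for off in range(len(site)):
        pos = site_pos + off
        ref = seq[pos]
        for alt in "ACGT":
            if alt == ref:
                continue
            key = (pos, alt)
            if mask[pos]:
                reasons[key] = "forbidden position"
                continue
            if _in_protected(pos, protected):
                reasons[key] = "inside a protected placed site"
                continue
            ctx = cds_index.codon_context(seq, pos, alt)
            if ctx is not None and not cds_index.is_synonymous(seq, pos, alt):
                reasons[key] = "nonsynonymous"
                continue
            created = collateral_sites(seq, pos, alt, panel)
            if created:
                reasons[key] = f"creates panel site(s) {sorted(created)}"
                continue
            candidates.append(
                (
                    _candidate_rank(ref, pos, alt),
                    Mutation(pos, ref, alt, "delete_site", enzyme.name, ctx),
                )
            )
    if not candidates:
        raise SiteEditError(
            f"cannot delete {enzyme.name} site at {site_pos}", reasons
        )
    return min(candidates)[1]


def create_site(
    seq: Sequence[str],
    putative: Tuple[int, Mutation],
    mask: ForbiddenMask,
    cds_index: CdsIndex,
    panel: Iterable[Enzyme],
    protected: Iterable[Tuple[int, int]] = (),
) -> Mutation:
    """Validate and finalize the substitution turning a putative window into
    a real site.  Fails if the position is forbidden/protected, the change is
    nonsynonymous inside CDS, or a second unintended panel site appears."""
    site_pos, mut = putative
    panel = list(panel)
    reasons = {}
    key = (mut.pos, mut.alt)
    if seq[mut.pos] != mut.ref:
        raise ValueError(f"stale putative: seq[{mut.pos}]={seq[mut.pos]!r} != {mut.ref!r}")
    if mask[mut.pos]:
        reasons[key] = "forbidden position"
    elif _in_protected(mut.pos, list(protected)):
        reasons[key] = "inside a protected placed site"
    else:
        ctx = cds_index.codon_context(seq, mut.pos, mut.alt)
        if ctx is not None and not cds_index.is_synonymous(seq, mut.pos, mut.alt):
            reasons[key] = "nonsynonymous"
        else:
            extra = collateral_sites(
                seq, mut.pos, mut.alt, panel, allow={(mut.enzyme, site_pos)}
            )
            if extra:
                reasons[key] = f"collateral site(s) {sorted(extra)}"
            else:
                return Mutation(
                    mut.pos, mut.ref, mut.alt, "create_site", mut.enzyme, ctx
                )
    raise SiteEditError(
        f"cannot create {mut.enzyme} site at {site_pos}: {reasons[key]}", reasons
    )
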