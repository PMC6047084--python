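"""Full redesign of a window: place regularly spaced sites, prune the rest.

The engine walks each assigned enzyme along the window placing one site per
target spacing step.  Existing sites are zero-cost candidates and win ties
against putative sites, which makes the procedure idempotent: a window whose
sites already sit on the target grid comes back untouched.  After placement,
every remaining off-chain site of every panel enzyme is destroyed with a
minimal synonymous substitution.  A verification block then asserts protein
identity, mask safety, zero residual sites and spacing compliance.
"""
from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .mask import CdsIndex, build_forbidden_mask, translate_cds
from .mutate import create_site, delete_site
from .records import (
    DesignError,
    DesignResult,
    Enzyme,
    Feature,
    GapRecord,
    Mutation,
    SequenceRecord,
    SiteEditError,
    VerificationReport,
)
from .chain import chain_sites
from .sites import find_putative_sites, scan_sites
from .windows import candidate_positions

log = logging.getLogger(__name__)


def _local_candidates(
    seq: List[str], enzyme: Enzyme, lo: int, hi: int
) -> List[Tuple[int, Optional[Mutation]]]:
    """Exact sites (mutation None) and putative sites within [lo, hi]."""
    m = len(enzyme.site)
    a, b = max(0, lo - 1), min(len(seq), hi + m + 1)
    text = "".join(seq[a:b])
    out: List[Tuple[int, Optional[Mutation]]] = []
    for p in scan_sites(text, enzyme):
        if lo <= a + p <= hi:
            out.append((a + p, None))
    for p, mut in find_putative_sites(text, enzyme):
        if lo <= a + p <= hi:
            out.append(
                (
                    a + p,
                    Mutation(mut.pos + a, mut.ref, mut.alt, "create_site", enzyme.name),
                )
            )
    return sorted(out, key=lambda t: t[0])


def _place_enzyme(
    seq: List[str],
    enzyme: Enzyme,
    spacing: int,
    tol: float,
    mask,
    cds_index: CdsIndex,
    panel: Sequence[Enzyme],
    protected: List[Tuple[int, int]],
    ledger: List[Mutation],
) -> Tuple[List[int], List[GapRecord]]:
    """Adaptive chain placement on the live sequence.

    The next ideal position is measured from the last *placed* site, so a
    slightly off-grid placement shifts the whole downstream ladder rather
    than accumulating error against a fixed grid.
    """
    L = len(seq)
    m = len(enzyme.site)
    placed: List[int] = []
    gaps: List[GapRecord] = []

    def try_place(lo: int, hi: int, ideal: int) -> Optional[int]:
        cands = _local_candidates(seq, enzyme, lo, hi)
        # minimal mutations first: an existing site within the band beats
        # any creation; then closest to ideal, then leftmost
        for pos, mut in sorted(
            cands, key=lambda t: (0 if t[1] is None else 1, abs(t[0] - ideal), t[0])
        ):
            if mut is None:
                return pos
            try:
                final = create_site(
                    seq, (pos, mut), mask, cds_index, panel, protected=protected
                )
            except SiteEditError:
                continue
            seq[final.pos] = final.alt
            ledger.append(final)
            return pos
        return None

    # first site: anywhere in [0, spacing]; an existing site wins over a
    # creation (zero cost and keeps the procedure idempotent), else leftmost
    def place_first() -> Optional[int]:
        cands = _local_candidates(seq, enzyme, 0, spacing)
        for pos, mut in sorted(
            cands, key=lambda t: (0 if t[1] is None else 1, t[0])
        ):
            if mut is None:
                return pos
            try:
                final = create_site(
                    seq, (pos, mut), mask, cds_index, panel, protected=protected
                )
            except SiteEditError:
                continue
            seq[final.pos] = final.alt
            ledger.append(final)
            return pos
        return None

    pos = place_first()
    missed_streak = 0
    if pos is None:
        anchor = 0
    else:
        placed.append(pos)
        protected.append((pos, pos + m))
        anchor = pos

    k = 1
    while True:
        ideal = anchor + k * spacing
        lo = int(ideal - spacing * tol)
        hi = int(ideal + spacing * tol)
        if lo >= L - m:
            break
        hi = min(hi, L - m)
        pos = try_place(lo, hi, ideal)
        if pos is None:
            missed_streak += 1
            k += 1
            continue
        if missed_streak:
            prev = placed[-1] if placed else None
            gaps.append(
                GapRecord(prev, pos, float(pos - (prev if prev is not None else 0)), missed_streak)
            )
            missed_streak = 0
        placed.append(pos)
        protected.append((pos, pos + m))
        anchor, k = pos, 1
    if missed_streak:
        prev = placed[-1] if placed else None
        gaps.append(
            GapRecord(prev, None, float(L - (prev if prev is not None else 0)), missed_streak)
        )
    return placed, gaps


def redesign_window(
    window: SequenceRecord,
    assignment: Dict[str, int],
    features: Sequence[Feature],
    panel: Sequence[Enzyme],
    tolerance_frac: float = 0.10,
    strict: bool = True,
) -> DesignResult:
    """Rewrite ``window`` so each assigned enzyme cuts on its spacing grid.

    ``assignment`` maps enzyme name -> target spacing (bp).  Panel enzymes
    without an assignment have all their sites removed.  With ``strict``
    (default) any verification failure raises :class:`DesignError` carrying
    the mutation ledger.
    """
    by_name = {e.name: e for e in panel}
    for name in assignment:
        if name not in by_name:
            raise ValueError(f"assigned enzyme {name!r} not in panel")
    L = len(window)
    mask = build_forbidden_mask(features, L)
    cds_index = CdsIndex(features)
    seq = list(window.seq)
    ledger: List[Mutation] = []
    protected: List[Tuple[int, int]] = []
    placed: Dict[str, List[int]] = {}
    gaps: Dict[str, List[GapRecord]] = {}
    residual: Dict[str, List[int]] = {e.name: [] for e in panel}

    def delete_offchain(keep_by_enzyme: Dict[str, set]) -> None:
        """Destroy every panel site not in its keep set, left to right."""
        for enz in panel:
            keep = keep_by_enzyme.get(enz.name, set())
            site, m = enz.site, len(enz.site)
            for p in scan_sites("".join(seq), enz):
                if p in keep or p in residual[enz.name]:
                    continue
                if "".join(seq[p : p + m]) != site:
                    continue  # destroyed by an earlier overlapping edit
                try:
                    mut = delete_site(
                        seq, p, enz, mask, cds_index, panel, protected=protected
                    )
                except SiteEditError as err:
                    residual[enz.name].append(p)
                    log.warning("residual %s site at %d: %s", enz.name, p, err)
                    continue
                seq[mut.pos] = mut.alt
                ledger.append(mut)

    # pass 0 (dry run): simulate the placement on a scratch copy to learn
    # which existing sites the chains will use
    scratch = list(seq)
    scratch_prot: List[Tuple[int, int]] = []
    provisional: Dict[str, set] = {}
    for name, spacing in sorted(assignment.items(), key=lambda t: t[1]):
        enz = by_name[name]
        exact = set(scan_sites("".join(seq), enz))
        dry, _ = _place_enzyme(
            scratch, enz, spacing, tolerance_frac, mask, cds_index, panel,
            scratch_prot, [],
        )
        provisional[name] = set(dry) & exact

    # pass 1: delete every other panel site up front, so no later placement
    # can trap an undeletable site under its footprint
    delete_offchain(provisional)

    # pass 2: adaptive placement on the cleaned sequence, smallest spacing
    # first (most constrained ladder); surviving exact sites are zero-cost
    # candidates, which makes the whole procedure idempotent
    for name, spacing in sorted(assignment.items(), key=lambda t: t[1]):
        enz = by_name[name]
        placed[name], gaps[name] = _place_enzyme(
            seq, enz, spacing, tolerance_frac, mask, cds_index, panel,
            protected, ledger,
        )

    # pass 3: cleanup of provisionally kept sites the adaptive chains ended
    # up not using
    delete_offchain({name: set(pos) for name, pos in placed.items()})

    new_seq = "".join(seq)
    redesigned = SequenceRecord(window.id + "_designed", new_seq, window.offset)
    verification = _verify(
        window, redesigned, features, panel, assignment, placed, residual,
        gaps, mask, ledger, tolerance_frac,
    )
    result = DesignResult(redesigned, ledger, placed, residual, verification)
    if strict and not verification.ok:
        raise DesignError(
            f"verification failed: {verification.messages}; ledger has "
            f"{len(ledger)} mutations"
        )
    return result


def _verify(
    native: SequenceRecord,
    redesigned: SequenceRecord,
    features: Sequence[Feature],
    panel: Sequence[Enzyme],
    assignment: Dict[str, int],
    placed: Dict[str, List[int]],
    residual: Dict[str, List[int]],
    gaps: Dict[str, List[GapRecord]],
    mask,
    ledger: Sequence[Mutation],
    tol: float,
) -> VerificationReport:
    messages = []

    protein_ok = True
    for f in features:
        if f.kind != "CDS":
            continue
        if translate_cds(native.seq, f) != translate_cds(redesigned.seq, f):
            protein_ok = False
            messages.append(f"protein changed in CDS {f.id or f.start}")

    mask_ok = all(not mask[m.pos] for m in ledger)
    if not mask_ok:
        messages.append("mutation on forbidden position")

    residual_ok = True
    for enz in panel:
        found = set(scan_sites(redesigned.seq, enz))
        expected = set(placed.get(enz.name, ()))
        stray = found - expected
        if stray - set(residual[enz.name]):
            residual[enz.name] = sorted(set(residual[enz.name]) | stray)
        if residual[enz.name]:
            residual_ok = False
            messages.append(
                f"{len(residual[enz.name])} residual {enz.name} site(s)"
            )
        missing = expected - found
        if missing:
            residual_ok = False
            messages.append(f"placed {enz.name} site(s) missing: {sorted(missing)}")

    import numpy as np

    compliance = {}
    gaps_ok = True
    for name, spacing in assignment.items():
        pos = placed.get(name, [])
        if len(pos) < 2:
            compliance[name] = 0.0
            continue
        d = np.diff(np.asarray(sorted(pos)))
        ok = (d >= spacing * (1 - tol)) & (d <= spacing * (1 + tol))
        compliance[name] = float(ok.mean())
        # every non-compliant gap must follow a flagged failed placement
        flagged = {g.until for g in gaps.get(name, [])} | {
            g.after for g in gaps.get(name, [])
        }
        for left, right, good in zip(pos[:-1], pos[1:], ok):
            if not good and left not in flagged and right not in flagged:
                gaps_ok = False
                messages.append(
                    f"{name}: unflagged non-compliant gap {right - left} bp "
                    f"at {left}"
                )

    return VerificationReport(
        protein_identity=protein_ok,
        mask_safe=mask_ok,
        residual_free=residual_ok,
        gaps_ok=gaps_ok,
        gap_compliance=compliance,
        gaps=gaps,
        messages=messages,
    )
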