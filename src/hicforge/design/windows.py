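"""Window scoring and genome-wide window scanning.

A window is scored by chaining each enzyme's candidate sites (exact sites
plus admissible putative sites) at each target spacing, scoring every
interval by the median absolute deviation of consecutive distances (plus a
gap penalty), then minimizing the summed score over all assignments of
distinct panel enzymes to the spacing classes.  Putative candidates whose
required substitution collides with a forbidden position are excluded from
chaining and counted as conflicts, degrading the score through the gaps
they leave.
"""
from __future__ import annotations

import itertools
import logging
from typing import Dict, Iterable, List, Sequence, Tuple

from .chain import chain_sites, interval_score
from .mask import CdsIndex, build_forbidden_mask
from .records import Enzyme, Feature, SequenceRecord, SpacingPlan, WindowScore
from .sites import find_putative_sites, scan_sites

log = logging.getLogger(__name__)


def candidate_positions(
    seq: SequenceRecord,
    enzyme: Enzyme,
    mask,
    cds_index: CdsIndex,
) -> Tuple[List[int], int]:
    """Sorted site-start candidates for one enzyme: exact sites plus putative
    windows whose single required substitution is free and synonymous.

    Returns ``(positions, conflicts)`` with ``conflicts`` the number of
    putative candidates lost to forbidden-position collisions.
    """
    s = seq.seq
    exact = set(scan_sites(s, enzyme))
    conflicts = 0
    usable = set(exact)
    for p, mut in find_putative_sites(s, enzyme):
        if mask[mut.pos]:
            conflicts += 1
            continue
        if not cds_index.is_synonymous(s, mut.pos, mut.alt):
            continue
        usable.add(p)
    return sorted(usable), conflicts


def score_window(
    window: SequenceRecord,
    features: Sequence[Feature],
    panel: Sequence[Enzyme],
    plan: SpacingPlan,
) -> WindowScore:
    """Best enzyme->spacing assignment for one window.

    Evaluates every ordered assignment of distinct panel enzymes to the
    plan's spacing classes and returns the minimizer.
    """
    L = len(window)
    mask = build_forbidden_mask(features, L)
    cds_index = CdsIndex(features)
    spacings = sorted(set(plan.assignments.values()))
    if len(panel) < len(spacings):
        raise ValueError("panel smaller than the number of spacing classes")

    per: Dict[Tuple[str, int], float] = {}
    conflicts_total = 0
    cands: Dict[str, List[int]] = {}
    for enz in panel:
        pos, conf = candidate_positions(window, enz, mask, cds_index)
        cands[enz.name] = pos
        conflicts_total += conf
        for sp in spacings:
            chain, gaps = chain_sites(pos, sp, plan.tolerance_frac, window_end=L)
            per[(enz.name, sp)] = interval_score(chain, sp, gaps)

    best_total, best_assign = float("inf"), None
    for combo in itertools.permutations([e.name for e in panel], len(spacings)):
        total = sum(per[(name, sp)] for name, sp in zip(combo, spacings))
        if total < best_total:
            best_total, best_assign = total, combo
    per_interval = {
        sp: (name, per[(name, sp)]) for name, sp in zip(best_assign, spacings)
    }
    return WindowScore(
        window=(window.offset, window.offset + L),
        per_interval=per_interval,
        total=best_total,
        conflicts=conflicts_total,
        chrom=window.id,
    )


def enumerate_windows(
    chrom_len: int,
    plan: SpacingPlan,
    features: Sequence[Feature] = (),
) -> List[Tuple[int, int]]:
    """Candidate window intervals on one chromosome at the plan's stride,
    excluding windows overlapping telomeres or within the centromere
    exclusion distance of a centromere."""
    W, step = plan.window_len, plan.step
    if chrom_len < W:
        return []
    excluded = []
    for f in features:
        if f.kind == "telomere":
            excluded.append((f.start, f.end))
        elif f.kind == "centromere":
            excluded.append(
                (f.start - plan.centromere_exclusion, f.end + plan.centromere_exclusion)
            )
    out = []
    for start in range(0, chrom_len - W + 1, step):
        end = start + W
        if any(start < b and a < end for a, b in excluded):
            continue
        out.append((start, end))
    return out


def scan_windows(
    genome: Iterable[Tuple[SequenceRecord, Sequence[Feature]]],
    panel: Sequence[Enzyme],
    plan: SpacingPlan,
) -> List[WindowScore]:
    """Score every admissible window of every chromosome; ranked ascending
    (lower = more regularizable)."""
    scores: List[WindowScore] = []
    for rec, feats in genome:
        if len(rec) < plan.window_len:
            log.info("skipping %s: shorter than window length", rec.id)
            continue
        for start, end in enumerate_windows(len(rec), plan, feats):
            sub = SequenceRecord(rec.id, rec.seq[start:end], offset=rec.offset + start)
            local = [
                Feature(f.kind, max(f.start - start, 0), min(f.end - start, end - start),
                        f.strand, f.frame, f.id)
                for f in feats
                if f.start < end and f.end > start and f.kind == "CDS"
                and f.start >= start and f.end <= end
            ] + [
                Feature(f.kind, max(f.start - start, 0), min(f.end - start, end - start),
                        f.strand, f.frame, f.id)
                for f in feats
                if f.start < end and f.end > start and f.kind != "CDS"
            ]
            scores.append(score_window(sub, local, panel, plan))
    scores.sort(key=lambda w: (w.total, w.chrom, w.window))
    return scores
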