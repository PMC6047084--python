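"""Core value types for the genome-redesign engine.

Coordinates are 0-based half-open internally; report writers convert to
1-based inclusive.  Interval length is always ``end - start``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

DNA_ALPHABET = frozenset("ACGT")

FEATURE_KINDS = (
    "CDS",
    "start_stop_codon",
    "TFBS",
    "ARS_core",
    "intron_border",
    "centromere",
    "tRNA",
    "telomere",
    "retrotransposon",
    "other",
)

#: Feature kinds whose body stays mutable.  CDS bodies may receive synonymous
#: substitutions (their start/stop codons are still protected) and
#: retrotransposons are dispensable repeats; everything else annotated is
#: off-limits.
MUTABLE_KINDS = frozenset({"CDS", "retrotransposon"})


class DesignError(Exception):
    """Unrecoverable failure of a redesign step."""


class SiteEditError(DesignError):
    """No admissible single-base substitution exists for a site edit.

    Carries ``reasons``: a mapping ``(pos, alt) -> str`` explaining why each
    candidate substitution was rejected.
    """

    def __init__(self, message: str, reasons: Optional[dict] = None):
        super().__init__(message)
        self.reasons = dict(reasons or {})


@dataclass
class SequenceRecord:
    """A named DNA sequence with a genomic offset for reporting."""

    id: str
    seq: str
    offset: int = 0

    def __post_init__(self):
        if not self.seq:
            raise ValueError("empty sequence")
        if self.offset < 0:
            raise ValueError("negative offset")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            pos = next(i for i, b in enumerate(self.seq) if b in bad)
            raise ValueError(
                f"non-ACGT character {self.seq[pos]!r} at position {pos} in {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Feature:
    """An annotated interval on a sequence."""

    kind: str
    start: int
    end: int
    strand: str = "+"
    frame: int = 0
    id: str = ""

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.start < self.end:
            raise ValueError(f"empty/inverted interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.frame not in (0, 1, 2):
            raise ValueError(f"bad frame {self.frame!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme with a palindromic recognition site."""

    name: str
    site: str
    cut_offset: int = 0
    overhang: str = "five_prime"

    def __post_init__(self):
        if set(self.site) - DNA_ALPHABET:
            raise ValueError(f"non-ACGT recognition site {self.site!r}")
        if not 0 <= self.cut_offset <= len(self.site):
            raise ValueError("cut_offset outside recognition site")
        if self.overhang not in ("five_prime", "three_prime", "blunt"):
            raise ValueError(f"bad overhang {self.overhang!r}")

    def __len__(self) -> int:
        return len(self.site)


@dataclass
class SpacingPlan:
    """Target spacing per enzyme plus window-scan geometry.

    ``assignments`` maps enzyme name -> target spacing (bp).  Each spacing
    class must be held by a distinct enzyme.  ``tolerance_frac`` is relative
    to the target spacing (a 400-bp spacing tolerates gaps of 360-440 bp at
    the default 0.10).
    """

    assignments: dict = field(
        default_factory=lambda: {"DpnII": 400, "XbaI": 1500, "HindIII": 2000, "NdeI": 6000}
    )
    tolerance_frac: float = 0.10
    window_len: int = 150_000
    step: int = 10_000
    centromere_exclusion: int = 75_000

    def __post_init__(self):
        if not 0 < self.tolerance_frac < 0.5:
            raise ValueError("tolerance_frac must be in (0, 0.5)")
        spacings = list(self.assignments.values())
        if len(set(spacings)) != len(spacings):
            raise ValueError("each spacing class needs a distinct enzyme")

    @property
    def spacings(self) -> list:
        return sorted(self.assignments.values())


@dataclass(frozen=True)
class Mutation:
    """A single-base substitution with its justification."""

    pos: int
    ref: str
    alt: str
    reason: str  # delete_site | create_site | pcrtag
    enzyme: Optional[str] = None
    codon_context: Optional[tuple] = None  # (feature id, codon index, synonymous)

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref == alt")
        if self.ref not in DNA_ALPHABET or self.alt not in DNA_ALPHABET:
            raise ValueError("ref/alt must be single ACGT bases")
        if self.reason not in ("delete_site", "create_site", "pcrtag"):
            raise ValueError(f"bad reason {self.reason!r}")


@dataclass
class GapRecord:
    """A failed placement stretch in a spacing chain."""

    after: Optional[int]  # last placed position before the gap (None = leading gap)
    until: Optional[int]  # restart position (None = terminal gap)
    length: float
    n_missed: int


@dataclass
class WindowScore:
    """Score of one candidate window under the best enzyme->spacing assignment."""

    window: tuple  # (start, end) in genome coordinates
    per_interval: dict  # spacing -> (enzyme name, MAD score)
    total: float
    conflicts: int
    chrom: str = ""


@dataclass
class VerificationReport:
    protein_identity: bool
    mask_safe: bool
    residual_free: bool
    gaps_ok: bool  # every out-of-tolerance gap is flagged in the gap report
    gap_compliance: dict  # enzyme -> fraction of gaps within tolerance
    gaps: dict  # enzyme -> list of GapRecord
    messages: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return (
            self.protein_identity
            and self.mask_safe
            and self.residual_free
            and self.gaps_ok
        )


@dataclass
class DesignResult:
    redesigned: SequenceRecord
    ledger: list  # ordered Mutations
    placed_sites: dict  # enzyme name -> sorted positions
    residual_sites: dict  # enzyme name -> positions not part of a chain (must be empty)
    verification: VerificationReport


def region_length(start: int, end: int) -> int:
    """Length of a printed genomic interval under the end-minus-start convention."""
    return end - start
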