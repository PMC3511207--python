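"""Segmentation of Pin-II proteinase-inhibitor precursors.

A Pin-II precursor is an N-terminal ER signal peptide (25 residues) followed
by 1-8 tandem inhibitory repeat domains (IRDs, ~50 aa each) separated by
short linker peptides.  Each IRD carries eight scaffold cysteines and one
protease reactive site whose P1 residue sets the inhibitory specificity:
Lys/Arg at P1 marks a trypsin inhibitor (TI), Leu/Pro a chymotrypsin
inhibitor (CI).

The annotator anchors on the reactive-site pentapeptide C-[P/T]-P1-X-C and
grows a candidate domain window around each anchor using a cysteine-spacing
template.  Candidates that do not recover enough of the scaffold are
rejected, overlaps are resolved greedily left to right, and everything
between accepted domains becomes linker.  Coordinates are 0-based,
half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from ._util import ValidationError, check_sequence

__all__ = [
    "AnnotationConfig",
    "PrecursorSequence",
    "ReactiveSite",
    "IRDRecord",
    "PrecursorAnnotation",
    "classify_reactive_site",
    "find_reactive_sites",
    "cysteine_profile",
    "extract_signal_peptide",
    "annotate_precursor",
]

#: P1 residues conferring trypsin specificity.
TI_P1 = frozenset("KR")
#: P1 residues conferring chymotrypsin specificity (Pro occurs in one
#: natural variant alongside the canonical Leu).
CI_P1 = frozenset("LP")

#: Reactive-site pentapeptide pattern: scaffold Cys, P2 in {P, T}, P1,
#: P1', scaffold Cys.  The wildcards accept any residue (including X);
#: residue validity is checked upstream.
_RS_PATTERN = re.compile(r"C[PT][A-Z][A-Z]C")


@dataclass(frozen=True)
class AnnotationConfig:
    """Tunable parameters of the segmentation.

    cys_template
        Offsets of the eight scaffold cysteines relative to the domain
        start.  The reactive-site cysteines are template positions
        ``rs_template_index`` and ``rs_template_index + 1`` and are the
        only pair exactly four residues apart, so the pentapeptide anchor
        is unambiguous within a canonical domain.
    cys_tolerance
        Allowed per-cysteine deviation from the template (residues).
    end_tolerances
        Per-position deviation bounds used for the scaffold-deviation
        flag; the last scaffold cysteine floats more because domain
        length varies mostly at the C-terminal end.
    tail_length
        Residues kept after the last scaffold cysteine; with the default
        template this yields the canonical 50-residue domain.
    max_missing_cys
        Scaffold positions that may go unmatched before a candidate
        window is rejected (tolerates natural cysteine variants).
    """

    sp_length: int = 25
    cys_template: tuple[int, ...] = (2, 8, 17, 22, 26, 33, 38, 43)
    rs_template_index: int = 3
    cys_tolerance: int = 2
    end_search: int = 4
    tail_length: int = 6
    max_missing_cys: int = 2
    min_template_positions: int = 4
    min_ird_length: int = 40
    max_ird_length: int = 60

    @property
    def rs_offset(self) -> int:
        """Offset of the reactive-site anchor cysteine from domain start."""
        return self.cys_template[self.rs_template_index]

    @property
    def nominal_length(self) -> int:
        return self.cys_template[-1] + 1 + self.tail_length

    def deviation_tolerances(self) -> tuple[int, ...]:
        tol = [self.cys_tolerance] * len(self.cys_template)
        tol[-1] = max(self.cys_tolerance, self.end_search)
        return tuple(tol)


DEFAULT_CONFIG = AnnotationConfig()


@dataclass(frozen=True)
class PrecursorSequence:
    """One precursor amino-acid sequence as read from FASTA."""

    id: str
    aa_seq: str
    is_partial: bool = False

    def __post_init__(self):
        object.__setattr__(self, "aa_seq", check_sequence(self.aa_seq, name=f"precursor {self.id!r}"))


@dataclass(frozen=True)
class ReactiveSite:
    """A classified reactive-site pentapeptide."""

    pentapeptide: str
    p1_residue: str
    inhibitor_class: str  # "TI", "CI" or "UNCLASSIFIED"


@dataclass(frozen=True)
class IRDRecord:
    """One inhibitory repeat domain located on a precursor."""

    start: int
    end: int
    aa_seq: str
    cys_positions: tuple[int, ...]
    cys_count: int
    reactive_site: Optional[ReactiveSite]
    scaffold_deviation: bool
    is_partial: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PrecursorAnnotation:
    """Full segmentation of one precursor.

    Segments (signal peptide, linkers, IRDs) are non-overlapping, ordered,
    and jointly reconstruct the input sequence exactly.
    """

    precursor_id: str
    aa_seq: str
    signal_peptide: Optional[str]
    sp_span: Optional[tuple[int, int]]
    irds: list[IRDRecord]
    linkers: list[tuple[tuple[int, int], str]]
    warnings: list[str] = field(default_factory=list)

    @property
    def n_irds(self) -> int:
        return len(self.irds)

    def segments(self) -> list[tuple[str, int, int]]:
        """All segments as (type, start, end), ordered by start."""
        out: list[tuple[str, int, int]] = []
        if self.sp_span is not None:
            out.append(("signal_peptide", *self.sp_span))
        out.extend(("linker", s, e) for (s, e), _ in self.linkers)
        out.extend(("ird", d.start, d.end) for d in self.irds)
        out.sort(key=lambda t: t[1])
        return out

    def reconstruct(self) -> str:
        """Concatenate all segments in coordinate order."""
        return "".join(self.aa_seq[s:e] for _, s, e in self.segments())


def classify_reactive_site(pentapeptide: str) -> ReactiveSite:
    """Classify a reactive-site pentapeptide by its P1 residue.

    The motif must be five residues with cysteines at both ends.  P1 is
    the third residue: K/R gives TI, L/P gives CI, anything else
    (including X) is UNCLASSIFIED.
    """
    pp = check_sequence(pentapeptide, name="pentapeptide")
    if len(pp) != 5:
        raise ValidationError(f"reactive-site motif {pp!r} must be 5 residues, got {len(pp)}")
    if pp[0] != "C" or pp[4] != "C":
        raise ValidationError(f"reactive-site motif {pp!r} must start and end with C")
    p1 = pp[2]
    if p1 in TI_P1:
        cls = "TI"
    elif p1 in CI_P1:
        cls = "CI"
    else:
        cls = "UNCLASSIFIED"
    return ReactiveSite(pentapeptide=pp, p1_residue=p1, inhibitor_class=cls)


def find_reactive_sites(aa_seq: str) -> list[tuple[int, ReactiveSite]]:
    """Locate every non-overlapping C-[P/T]-X-X-C motif, left to right.

    Returns 0-based positions with the classified site; an empty list when
    no motif occurs.
    """
    seq = check_sequence(aa_seq)
    return [(m.start(), classify_reactive_site(m.group())) for m in _RS_PATTERN.finditer(seq)]


def cysteine_profile(
    aa_seq: str,
    template: Sequence[int] = DEFAULT_CONFIG.cys_template,
    tolerance: int | Sequence[int] = DEFAULT_CONFIG.cys_tolerance,
) -> tuple[int, tuple[int, ...], bool]:
    """Count and locate cysteines and flag deviation from a spacing template.

    The deviation flag is true when the cysteine count differs from the
    template size, or when any cysteine (compared in order) sits more than
    the tolerance away from its template offset.  ``tolerance`` may be a
    single value or one bound per template position.
    """
    positions = tuple(i for i, a in enumerate(aa_seq) if a == "C")
    count = len(positions)
    if isinstance(tolerance, int):
        tols = [tolerance] * len(template)
    else:
        tols = list(tolerance)
    if count != len(template):
        return count, positions, True
    deviation = any(abs(p - t) > tol for p, t, tol in zip(positions, template, tols))
    return count, positions, deviation


def extract_signal_peptide(
    precursor: PrecursorSequence, sp_length: int = DEFAULT_CONFIG.sp_length
) -> tuple[Optional[str], tuple[int, int]]:
    """Split off the fixed-length N-terminal signal peptide.

    Returns ``(sp, (mature_start, end))``.  A precursor shorter than the
    signal peptide is an error unless flagged partial, in which case the
    signal peptide is reported absent and the whole sequence is scanned.
    """
    n = len(precursor.aa_seq)
    if n <= sp_length:
        if precursor.is_partial:
            return None, (0, n)
        raise ValidationError(
            f"precursor {precursor.id!r} ({n} aa) is shorter than the "
            f"{sp_length}-residue signal peptide and not flagged partial"
        )
    return precursor.aa_seq[:sp_length], (sp_length, n)


def _score_window(seq: str, window_start: int, config: AnnotationConfig) -> tuple[int, int]:
    """How much of the cysteine scaffold a candidate window recovers.

    Returns (matched template positions, template positions inside the
    sequence).  A position matches when a C lies within the tolerance of
    its expected location.
    """
    n = len(seq)
    matched = in_range = 0
    tol = config.cys_tolerance
    for off in config.cys_template:
        pos = window_start + off
        if pos < 0 or pos >= n:
            continue
        in_range += 1
        lo, hi = max(0, pos - tol), min(n, pos + tol + 1)
        if "C" in seq[lo:hi]:
            matched += 1
    return matched, in_range


def _locate_end_cysteine(seq: str, window_start: int, config: AnnotationConfig) -> Optional[int]:
    """Find the last scaffold cysteine near its expected position."""
    expect = window_start + config.cys_template[-1]
    lo = max(0, expect - config.end_search)
    hi = min(len(seq), expect + config.end_search + 1)
    region = seq[lo:hi]
    idx = region.rfind("C")
    return None if idx < 0 else lo + idx


def annotate_precursor(
    precursor: PrecursorSequence, config: AnnotationConfig = DEFAULT_CONFIG
) -> PrecursorAnnotation:
    """Segment a precursor into signal peptide, IRDs and linkers.

    Every reactive-site anchor in the mature region seeds a candidate
    window placed so the anchor cysteine falls on its template position.
    A candidate is kept when at least ``in-range template positions -
    max_missing_cys`` scaffold cysteines are recovered; accepted windows
    are resolved greedily left to right.  The domain end is set a fixed
    tail after the located last scaffold cysteine, so C-terminal length
    variation is followed; a domain running off the sequence end is
    flagged partial.  Zero anchors yield an annotation with ``n_irds == 0``
    and a warning record rather than an exception.
    """
    seq = precursor.aa_seq
    sp, (mature_start, n) = extract_signal_peptide(precursor, config.sp_length)
    sp_span = (0, mature_start) if sp is not None else None
    warnings: list[str] = []

    anchors = [
        (mature_start + pos, site)
        for pos, site in find_reactive_sites(seq[mature_start:])
    ]
    if not anchors:
        warnings.append(f"{precursor.id}: no reactive-site motif found; n_irds=0")

    # Candidate windows that recover enough of the cysteine scaffold.
    candidates: list[tuple[int, int, ReactiveSite]] = []
    for anchor, site in anchors:
        ws = anchor - config.rs_offset
        matched, in_range = _score_window(seq, ws, config)
        if in_range < config.min_template_positions:
            continue
        if matched < in_range - config.max_missing_cys:
            continue
        candidates.append((anchor, ws, site))

    # Greedy left-to-right acceptance by anchor position.
    accepted: list[tuple[int, int, ReactiveSite]] = []
    for anchor, ws, site in candidates:
        if accepted:
            prev_ws = accepted[-1][1]
            prev_end_min = prev_ws + config.cys_template[-1] + 1
            if ws < prev_end_min:
                continue
        accepted.append((anchor, ws, site))

    irds: list[IRDRecord] = []
    dev_tols = config.deviation_tolerances()
    for i, (anchor, ws, site) in enumerate(accepted):
        start = max(ws, mature_start)
        front_truncated = ws < mature_start
        end_cys = _locate_end_cysteine(seq, ws, config)
        if end_cys is None:
            end = ws + config.nominal_length
        else:
            end = end_cys + 1 + config.tail_length
        next_ws = accepted[i + 1][1] if i + 1 < len(accepted) else n
        end = min(end, next_ws)
        tail_truncated = end > n or (end_cys is None and ws + config.cys_template[-1] >= n)
        end = min(end, n)
        domain_seq = seq[start:end]
        count, cys_pos, deviation = cysteine_profile(
            domain_seq, config.cys_template, dev_tols
        )
        irds.append(
            IRDRecord(
                start=start,
                end=end,
                aa_seq=domain_seq,
                cys_positions=cys_pos,
                cys_count=count,
                reactive_site=site,
                scaffold_deviation=deviation,
                is_partial=front_truncated or tail_truncated,
            )
        )

    # Everything not covered by SP or an IRD is linker.
    linkers: list[tuple[tuple[int, int], str]] = []
    cursor = mature_start
    for d in irds:
        if d.start > cursor:
            linkers.append(((cursor, d.start), seq[cursor:d.start]))
        cursor = d.end
    if cursor < n:
        linkers.append(((cursor, n), seq[cursor:n]))

    ann = PrecursorAnnotation(
        precursor_id=precursor.id,
        aa_seq=seq,
        signal_peptide=sp,
        sp_span=sp_span,
        irds=irds,
        linkers=linkers,
        warnings=warnings,
    )
    assert ann.reconstruct() == seq
    return ann
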