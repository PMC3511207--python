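"""Masses of proteolytically processed single-IRD peptides and MALDI peak
assignment.

Precursors are cleaved by endogenous proteases within the linkers, releasing
single-domain peptides of roughly 5.5-6.3 kDa.  Linear-mode MALDI of such
peptides reports average (isotope-abundance-weighted) masses, so the
calculator defaults to average mass; a monoisotopic mode is available.
Disulfide formation removes two hydrogens per bond, and a fully oxidized
eight-cysteine domain (four bonds) is 8 x 1.008 Da lighter than its reduced
form.  Whether published peaks are neutral or protonated [M+H]+ species is
instrument-protocol dependent, so a proton offset is exposed as an option
and asserted nowhere.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from ._util import ValidationError
from .annotate import PrecursorAnnotation

__all__ = [
    "AVERAGE_RESIDUE_MASS",
    "MONOISOTOPIC_RESIDUE_MASS",
    "PeptideCandidate",
    "PeakList",
    "PeakAssignment",
    "average_mass",
    "enumerate_candidates",
    "match_peaks",
]

# Average residue (amino-acid minus water) masses in Da, computed from
# elemental compositions with IUPAC 2021 conventional atomic weights
# (H 1.008, C 12.011, N 14.007, O 15.999, S 32.06).
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "G": 57.052,
    "A": 71.079,
    "S": 87.078,
    "P": 97.117,
    "V": 99.133,
    "T": 101.105,
    "C": 103.139,
    "L": 113.160,
    "I": 113.160,
    "N": 114.104,
    "D": 115.088,
    "Q": 128.131,
    "K": 128.175,
    "E": 129.115,
    "M": 131.193,
    "H": 137.142,
    "F": 147.177,
    "R": 156.189,
    "Y": 163.176,
    "W": 186.214,
}

# Monoisotopic residue masses in Da (most abundant isotopes).
MONOISOTOPIC_RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

WATER_AVERAGE = 18.015
WATER_MONOISOTOPIC = 18.01056
#: Mass removed per disulfide bond (two hydrogen atoms).
DISULFIDE_LOSS = 2 * 1.008
#: Proton mass for the optional [M+H]+ interpretation of peak values.
PROTON = 1.007


def average_mass(aa_seq: str, n_disulfides: int = 0, *, monoisotopic: bool = False) -> float:
    """Peptide mass in Da: residue masses + one water - 2H per disulfide.

    ``n_disulfides`` must lie in [0, cys_count // 2].  An unknown residue
    (anything outside the 20 standard codes, including X) raises an error
    naming it, since it has no defined mass.
    """
    if not aa_seq:
        raise ValidationError("cannot compute the mass of an empty peptide")
    table = MONOISOTOPIC_RESIDUE_MASS if monoisotopic else AVERAGE_RESIDUE_MASS
    total = WATER_MONOISOTOPIC if monoisotopic else WATER_AVERAGE
    n_cys = 0
    for aa in aa_seq.upper():
        try:
            total += table[aa]
        except KeyError:
            raise ValidationError(f"residue {aa!r} has no defined mass") from None
        if aa == "C":
            n_cys += 1
    if not 0 <= n_disulfides <= n_cys // 2:
        raise ValidationError(
            f"n_disulfides={n_disulfides} outside [0, {n_cys // 2}] for a "
            f"{n_cys}-cysteine peptide"
        )
    return total - DISULFIDE_LOSS * n_disulfides


@dataclass(frozen=True)
class PeptideCandidate:
    """A processed single-IRD peptide with optional linker flanks."""

    gene_id: str
    ird_label: int
    flank_left: int
    flank_right: int
    aa_seq: str
    n_disulfides: int
    mass_reduced: float
    mass_oxidized: float

    def mass(self, *, oxidized: bool = True) -> float:
        return self.mass_oxidized if oxidized else self.mass_reduced


@dataclass
class PeakList:
    """Observed peak masses in Da, sorted ascending on construction."""

    values: list[float]
    tolerance: float = 3.0

    def __post_init__(self):
        if any(v <= 0 for v in self.values):
            raise ValidationError("peak masses must be positive")
        self.values = sorted(float(v) for v in self.values)

    @classmethod
    def from_text(cls, path: str | Path, tolerance: float = 3.0) -> "PeakList":
        """One numeric value per line; blank lines and # comments ignored."""
        vals = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                vals.append(float(line))
        return cls(values=vals, tolerance=tolerance)

    @classmethod
    def from_json(cls, path: str | Path, tolerance: float = 3.0) -> "PeakList":
        data = json.loads(Path(path).read_text())
        if isinstance(data, dict):
            tolerance = float(data.get("tolerance", tolerance))
            data = data["values"]
        return cls(values=[float(v) for v in data], tolerance=tolerance)


@dataclass(frozen=True)
class PeakAssignment:
    """A peak linked to its best candidate (or none) with the mass delta."""

    peak: float
    candidate: Optional[PeptideCandidate]
    delta: Optional[float]


def enumerate_candidates(
    annotation: PrecursorAnnotation,
    max_flank: int = 0,
    labels: Optional[Sequence[int]] = None,
) -> list[PeptideCandidate]:
    """All processed-peptide candidates of one annotated precursor.

    For each IRD the bare domain plus every flank extension of 0 to
    ``max_flank`` residues per side is emitted, bounded by the residues
    actually available in the adjacent linkers.  Duplicate sequences are
    dropped (first occurrence wins).  ``labels`` supplies catalog labels
    per domain; by default domains are numbered 1..n within the precursor.
    """
    seq = annotation.aa_seq
    linker_spans = [span for span, _ in annotation.linkers]
    cands: list[PeptideCandidate] = []
    seen: set[str] = set()
    for idx, d in enumerate(annotation.irds):
        label = labels[idx] if labels is not None else idx + 1
        left_avail = right_avail = 0
        for ls, le in linker_spans:
            if le == d.start:
                left_avail = le - ls
            if ls == d.end:
                right_avail = le - ls
        n_ss = d.cys_count // 2
        for fl in range(0, min(max_flank, left_avail) + 1):
            for fr in range(0, min(max_flank, right_avail) + 1):
                pep = seq[d.start - fl : d.end + fr]
                if pep in seen:
                    continue
                seen.add(pep)
                reduced = average_mass(pep, 0)
                cands.append(
                    PeptideCandidate(
                        gene_id=annotation.precursor_id,
                        ird_label=label,
                        flank_left=fl,
                        flank_right=fr,
                        aa_seq=pep,
                        n_disulfides=n_ss,
                        mass_reduced=reduced,
                        mass_oxidized=reduced - DISULFIDE_LOSS * n_ss,
                    )
                )
    return cands


def match_peaks(
    peaks: PeakList,
    candidates: Sequence[PeptideCandidate],
    tolerance: Optional[float] = None,
    *,
    oxidized: bool = True,
    protonated: bool = False,
) -> list[PeakAssignment]:
    """Assign each peak to the candidate with the smallest mass delta.

    A peak matches only within the tolerance; ties in |delta| go to the
    smaller candidate mass.  ``protonated=True`` interprets peak values as
    [M+H]+ and subtracts one proton before matching.  An empty candidate
    list leaves every peak unmatched with a warning.
    """
    tol = peaks.tolerance if tolerance is None else tolerance
    if tol <= 0:
        raise ValidationError("tolerance must be positive")
    if not candidates:
        warnings.warn("no candidates supplied; all peaks left unmatched")
    out: list[PeakAssignment] = []
    for peak in peaks.values:
        neutral = peak - PROTON if protonated else peak
        best: Optional[PeptideCandidate] = None
        best_delta = None
        for cand in candidates:
            delta = neutral - cand.mass(oxidized=oxidized)
            if abs(delta) > tol:
                continue
            if (
                best is None
                or abs(delta) < abs(best_delta)
                or (
                    abs(delta) == abs(best_delta)
                    and cand.mass(oxidized=oxidized) < best.mass(oxidized=oxidized)
                )
            ):
                best, best_delta = cand, delta
        out.append(PeakAssignment(peak=peak, candidate=best, delta=best_delta))
    return out
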