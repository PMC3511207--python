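"""Deduplication of IRDs and signal peptides across an annotated gene set.

"Unique" means exact amino-acid identity: single-residue variants are
distinct catalog entries, mirroring how natural variant domains are
tabulated separately.  Labels are opaque integers assigned in first
occurrence order; two genes with identical composition remain distinct
genes keyed by name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from ._util import ConsistencyError
from .annotate import PrecursorAnnotation

__all__ = [
    "IRDCatalog",
    "SPCatalog",
    "GeneComposition",
    "CatalogSummary",
    "build_catalog",
    "catalog_summary",
]


@dataclass
class IRDCatalog:
    """Unique IRD sequences keyed by opaque integer labels.

    ``entries`` may hold ``None`` sequences for label-only catalogs built
    from a transcribed composition table where the underlying sequences
    are not available; classes are then UNCLASSIFIED.
    """

    entries: dict[int, Optional[str]] = field(default_factory=dict)
    class_of: dict[int, str] = field(default_factory=dict)
    deviation_of: dict[int, Optional[bool]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def label_for(self, aa_seq: str) -> Optional[int]:
        for label, seq in self.entries.items():
            if seq == aa_seq:
                return label
        return None

    @classmethod
    def from_labels(cls, labels: Iterable[int]) -> "IRDCatalog":
        """Label-only catalog (sequences unknown, classes unassigned)."""
        cat = cls()
        for lab in sorted(set(labels)):
            cat.entries[lab] = None
            cat.class_of[lab] = "UNCLASSIFIED"
            cat.deviation_of[lab] = None
        return cat

    def _validate(self) -> None:
        seqs = [s for s in self.entries.values() if s is not None]
        if len(seqs) != len(set(seqs)):
            raise ConsistencyError("catalog sequences are not unique")


@dataclass
class SPCatalog:
    """Unique signal-peptide sequences keyed by integer labels."""

    entries: dict[int, Optional[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def label_for(self, aa_seq: str) -> Optional[int]:
        for label, seq in self.entries.items():
            if seq == aa_seq:
                return label
        return None


@dataclass
class GeneComposition:
    """One gene expressed as catalog labels.

    ``ird_labels`` is ordered N- to C-terminal; a ``None`` entry marks a
    partial trailing domain whose label is unknown but which still counts
    toward the domain number (that is how partial genes are tabulated).
    """

    gene_id: str
    sp_label: Optional[int]
    ird_labels: list[Optional[int]]
    is_partial: bool = False
    novel: Optional[bool] = None

    @property
    def n_irds(self) -> int:
        return len(self.ird_labels)

    def labeled(self) -> list[int]:
        return [l for l in self.ird_labels if l is not None]


@dataclass
class CatalogSummary:
    """Headline counts over a catalog and its gene compositions."""

    n_genes: int
    genes_by_n_irds: dict[int, int]
    n_unique_irds: int
    class_counts: dict[str, int]
    n_cys_variants: Optional[int]
    n_sp_variants: int
    n_novel: Optional[int]
    n_partial: int

    def to_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "genes_by_n_irds": dict(sorted(self.genes_by_n_irds.items())),
            "n_unique_irds": self.n_unique_irds,
            "class_counts": self.class_counts,
            "n_cys_variants": self.n_cys_variants,
            "n_sp_variants": self.n_sp_variants,
            "n_novel": self.n_novel,
            "n_partial": self.n_partial,
        }


def build_catalog(
    annotations: list[PrecursorAnnotation],
) -> tuple[IRDCatalog, SPCatalog, list[GeneComposition]]:
    """Deduplicate IRDs and signal peptides over an annotated precursor set.

    Labels are assigned by first occurrence (1-based); identical sequences
    reuse the same label everywhere.  Every annotation maps to one
    composition, in input order.
    """
    if not annotations:
        raise ValueError("need at least one annotation")
    ird_cat = IRDCatalog()
    sp_cat = SPCatalog()
    ird_index: dict[str, int] = {}
    sp_index: dict[str, int] = {}
    compositions: list[GeneComposition] = []
    for ann in annotations:
        labels: list[Optional[int]] = []
        for d in ann.irds:
            lab = ird_index.get(d.aa_seq)
            if lab is None:
                lab = len(ird_index) + 1
                ird_index[d.aa_seq] = lab
                ird_cat.entries[lab] = d.aa_seq
                ird_cat.class_of[lab] = (
                    d.reactive_site.inhibitor_class if d.reactive_site else "UNCLASSIFIED"
                )
                ird_cat.deviation_of[lab] = d.scaffold_deviation
            labels.append(lab)
        sp_label: Optional[int] = None
        if ann.signal_peptide is not None:
            sp_label = sp_index.get(ann.signal_peptide)
            if sp_label is None:
                sp_label = len(sp_index) + 1
                sp_index[ann.signal_peptide] = sp_label
                sp_cat.entries[sp_label] = ann.signal_peptide
        compositions.append(
            GeneComposition(
                gene_id=ann.precursor_id,
                sp_label=sp_label,
                ird_labels=labels,
                is_partial=any(d.is_partial for d in ann.irds),
            )
        )
    ird_cat._validate()
    return ird_cat, sp_cat, compositions


def catalog_summary(
    catalog: Optional[IRDCatalog],
    compositions: list[GeneComposition],
    sp_catalog: Optional[SPCatalog] = None,
) -> CatalogSummary:
    """Summarize gene counts, domain-number classes and catalog diversity.

    When ``catalog`` is given, every label referenced by a composition
    must exist in it (a missing label is a consistency error); class and
    cysteine-variant counts are taken from the catalog.  An empty
    composition list yields an all-zero summary.
    """
    if catalog is not None:
        known = set(catalog.entries)
        for comp in compositions:
            missing = set(comp.labeled()) - known
            if missing:
                raise ConsistencyError(
                    f"gene {comp.gene_id!r} references label(s) "
                    f"{sorted(missing)} absent from the catalog"
                )

    by_class: dict[int, int] = {}
    for comp in compositions:
        by_class[comp.n_irds] = by_class.get(comp.n_irds, 0) + 1

    if catalog is not None:
        n_unique = len(catalog)
        class_counts = {"TI": 0, "CI": 0, "UNCLASSIFIED": 0}
        for lab in catalog.entries:
            class_counts[catalog.class_of.get(lab, "UNCLASSIFIED")] += 1
        devs = [catalog.deviation_of.get(lab) for lab in catalog.entries]
        n_cys_variants = None if any(d is None for d in devs) else sum(devs)
    else:
        n_unique = len({l for c in compositions for l in c.labeled()})
        class_counts = {"TI": 0, "CI": 0, "UNCLASSIFIED": n_unique}
        n_cys_variants = None

    if sp_catalog is not None:
        n_sp = len(sp_catalog)
    else:
        n_sp = len({c.sp_label for c in compositions if c.sp_label is not None})

    novel_flags = [c.novel for c in compositions]
    n_novel = None if any(f is None for f in novel_flags) or not compositions else sum(novel_flags)

    return CatalogSummary(
        n_genes=len(compositions),
        genes_by_n_irds=by_class,
        n_unique_irds=n_unique,
        class_counts=class_counts,
        n_cys_variants=n_cys_variants,
        n_sp_variants=n_sp,
        n_novel=n_novel,
        n_partial=sum(c.is_partial for c in compositions),
    )
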