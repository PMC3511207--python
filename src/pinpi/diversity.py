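"""Clone-library frequency statistics.

Input is a genes x treatments table of sequenced-clone counts.  The study
design sequences a fixed number of clones per treatment (60 per induced
treatment, 25 uninduced), so percentages are computed against that
sequencing depth; a published count table may tabulate fewer clones than
were sequenced, which validation reports but does not repair.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._util import ConsistencyError, ValidationError, round_half_up
from .catalog import GeneComposition, IRDCatalog

__all__ = [
    "CloneCountTable",
    "ValidationReport",
    "ClassAbundance",
    "validate_table",
    "class_abundance",
    "gene_frequency",
    "shared_unique_partition",
    "ird_frequency",
    "class_specificity_summary",
    "plot_class_abundance",
]

#: Treatment labels of the study design: uninduced leaf, aphid-infested,
#: wound + water, wound + oral secretions.
DEFAULT_TREATMENTS = ("UL", "AI", "W+W", "W+OS")
DEFAULT_INDUCED = ("AI", "W+W", "W+OS")
DEFAULT_TOTALS = {"UL": 25, "AI": 60, "W+W": 60, "W+OS": 60}


@dataclass
class CloneCountTable:
    """Genes x treatments matrix of sequenced-clone counts.

    ``expected_totals`` records how many clones were sequenced per
    treatment; it is the denominator for abundance percentages.
    """

    counts: pd.DataFrame  # index: gene ids, columns: treatment labels
    expected_totals: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        arr = self.counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValidationError("clone counts must be integers")
            self.counts = self.counts.astype(int)
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("clone counts must be non-negative")
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate gene ids in clone-count table")

    @property
    def treatments(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def column_total(self, treatment: str) -> int:
        return int(self.counts[treatment].sum())

    def denominator(self, treatment: str) -> int:
        """Sequencing depth when configured, else the tabulated sum."""
        return int(self.expected_totals.get(treatment, self.column_total(treatment)))

    def scaled(self, factor: int) -> "CloneCountTable":
        return CloneCountTable(
            counts=self.counts * factor,
            expected_totals={t: v * factor for t, v in self.expected_totals.items()},
        )


@dataclass
class ValidationReport:
    """Per-treatment comparison of tabulated sums vs sequencing depth."""

    observed: dict[str, int]
    expected: dict[str, Optional[int]]

    @property
    def column_ok(self) -> dict[str, bool]:
        return {
            t: (self.expected[t] is None or self.observed[t] == self.expected[t])
            for t in self.observed
        }

    @property
    def ok(self) -> bool:
        return all(self.column_ok.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "observed_sum": pd.Series(self.observed),
                "expected_total": pd.Series(self.expected),
                "ok": pd.Series(self.column_ok),
            }
        )


@dataclass
class ClassAbundance:
    """Clone counts and percentages per domain-number class (1-4 IRDs)."""

    treatment: str
    class_counts: dict[int, int]
    column_total: int
    denominator: int
    percentages: dict[int, int]
    raw_percentages: dict[int, float]


def validate_table(table: CloneCountTable) -> ValidationReport:
    """Compare each column sum with its expected sequencing depth.

    Mismatches are reported, never raised; the table is not mutated.
    Negative or fractional counts raise at table construction.
    """
    observed = {t: table.column_total(t) for t in table.treatments}
    expected = {t: table.expected_totals.get(t) for t in table.treatments}
    return ValidationReport(observed=observed, expected=expected)


def _composition_index(compositions: Iterable[GeneComposition]) -> dict[str, GeneComposition]:
    return {c.gene_id: c for c in compositions}


def class_abundance(
    table: CloneCountTable,
    compositions: Iterable[GeneComposition],
    treatment: str,
) -> ClassAbundance:
    """Clone abundance of 1-, 2-, 3- and 4-IRD genes in one treatment.

    The class count is the summed clone count of genes with that many
    domains; the percentage divides by the sequencing depth and rounds
    half-up to an integer.
    """
    comp = _composition_index(compositions)
    missing = set(table.genes) - set(comp)
    if missing:
        raise ConsistencyError(f"no composition for gene(s): {sorted(missing)}")
    denom = table.denominator(treatment)
    if denom == 0:
        raise ValidationError(f"no clones in treatment {treatment!r}")
    col = table.counts[treatment]
    class_counts: dict[int, int] = {}
    for gene, count in col.items():
        k = comp[gene].n_irds
        class_counts[k] = class_counts.get(k, 0) + int(count)
    raw = {k: 100.0 * v / denom for k, v in class_counts.items()}
    return ClassAbundance(
        treatment=treatment,
        class_counts=class_counts,
        column_total=int(col.sum()),
        denominator=denom,
        percentages={k: round_half_up(v) for k, v in raw.items()},
        raw_percentages=raw,
    )


def gene_frequency(table: CloneCountTable) -> pd.DataFrame:
    """Per-gene, per-treatment clone fractions (count / sequencing depth).

    Genes with zero count in a treatment are absent from that treatment's
    rows.  Returns a tidy frame with columns gene, treatment, count,
    fraction.
    """
    rows = []
    for t in table.treatments:
        denom = table.denominator(t)
        if denom == 0:
            raise ValidationError(f"no clones in treatment {t!r}")
        for gene, count in table.counts[t].items():
            if count > 0:
                rows.append((gene, t, int(count), count / denom))
    return pd.DataFrame(rows, columns=["gene", "treatment", "count", "fraction"])


def shared_unique_partition(
    table: CloneCountTable, treatments: Optional[Sequence[str]] = None
) -> dict[tuple[str, ...], list[str]]:
    """Venn partition of expressed genes over the selected treatments.

    A gene is "expressed" in a treatment when its count is positive.  By
    default the three induced treatments are compared (the uninduced
    column is excluded).  Every expressed gene lands in exactly one
    region, keyed by the sorted tuple of treatments it occurs in; all
    non-empty regions of the Venn are present as keys (possibly with
    empty gene lists).
    """
    if treatments is None:
        treatments = [t for t in DEFAULT_INDUCED if t in table.treatments]
    treatments = list(treatments)
    if len(treatments) < 2:
        raise ValidationError("need at least two treatments for a partition")
    regions: dict[tuple[str, ...], list[str]] = {}
    for r in range(1, len(treatments) + 1):
        for combo in itertools.combinations(treatments, r):
            regions[combo] = []
    for gene in table.genes:
        present = tuple(t for t in treatments if table.counts.at[gene, t] > 0)
        if present:
            regions[present].append(gene)
    return regions


def ird_frequency(
    table: CloneCountTable,
    compositions: Iterable[GeneComposition],
    catalog: Optional[IRDCatalog] = None,
) -> pd.DataFrame:
    """Occurrence counts of each IRD label per treatment.

    An IRD occurring twice within one gene counts twice per clone of that
    gene.  Returns a labels x treatments frame of integer occurrence
    counts.  With a catalog given, every referenced label must exist.
    """
    comp = _composition_index(compositions)
    missing = set(table.genes) - set(comp)
    if missing:
        raise ConsistencyError(f"no composition for gene(s): {sorted(missing)}")
    if catalog is not None:
        known = set(catalog.entries)
        for c in comp.values():
            bad = set(c.labeled()) - known
            if bad:
                raise ConsistencyError(
                    f"gene {c.gene_id!r} references label(s) {sorted(bad)} "
                    "absent from the catalog"
                )
    labels = sorted({l for c in comp.values() for l in c.labeled()})
    out = pd.DataFrame(0, index=labels, columns=table.treatments, dtype=int)
    for gene in table.genes:
        for lab in comp[gene].labeled():
            out.loc[lab] += table.counts.loc[gene].astype(int)
    # multiplicity: the loop above adds once per occurrence of lab
    out.index.name = "ird_label"
    return out


def class_specificity_summary(
    table: CloneCountTable,
    compositions: Iterable[GeneComposition],
    catalog: IRDCatalog,
) -> pd.DataFrame:
    """Clone-weighted TI/CI composition of the IRD pool per treatment.

    For each treatment, the fraction of IRD occurrences (counted with
    multiplicity, weighted by clone counts) that are trypsin- vs
    chymotrypsin-inhibitory.
    """
    freq = ird_frequency(table, compositions, catalog)
    classes = ("TI", "CI", "UNCLASSIFIED")
    rows = {}
    for t in table.treatments:
        totals = {c: 0 for c in classes}
        for lab, count in freq[t].items():
            totals[catalog.class_of.get(lab, "UNCLASSIFIED")] += int(count)
        grand = sum(totals.values())
        rows[t] = {c: (totals[c] / grand if grand else 0.0) for c in classes}
    out = pd.DataFrame(rows).T
    out.index.name = "treatment"
    return out


def plot_class_abundance(abundances: Sequence[ClassAbundance], path: str) -> None:
    """Grouped bar chart of class percentages per treatment (SVG/PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = sorted({k for a in abundances for k in a.percentages})
    x = np.arange(len(abundances))
    width = 0.8 / max(len(classes), 1)
    fig, ax = plt.subplots(figsize=(6, 4))
    for i, k in enumerate(classes):
        vals = [a.percentages.get(k, 0) for a in abundances]
        ax.bar(x + i * width, vals, width, label=f"{k}-IRD")
    ax.set_xticks(x + width * (len(classes) - 1) / 2)
    ax.set_xticklabels([a.treatment for a in abundances])
    ax.set_ylabel("% of sequenced clones")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
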