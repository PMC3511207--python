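"""Clone-frequency statistics against the reference table and brute force."""

import numpy as np
import pandas as pd
import pytest

from pinpi._util import ValidationError
from pinpi.catalog import GeneComposition, IRDCatalog
from pinpi.diversity import (
    CloneCountTable,
    class_abundance,
    class_specificity_summary,
    gene_frequency,
    ird_frequency,
    shared_unique_partition,
    validate_table,
)


def _toy_table(data, totals=None):
    df = pd.DataFrame(data).T
    return CloneCountTable(counts=df, expected_totals=totals or {})


def test_validation_reports_column_sums(reference_table):
    table, _ = reference_table
    report = validate_table(table)
    assert report.observed["W+OS"] == 60
    assert report.observed["UL"] == 25
    assert report.column_ok["W+OS"] and report.column_ok["UL"]
    # the printed table tabulates fewer clones than were sequenced for
    # these two treatments; flagged, not raised
    assert not report.column_ok["AI"] and not report.column_ok["W+W"]


def test_validation_flags_without_exception():
    t = _toy_table({"g1": {"T": 30}, "g2": {"T": 29}}, totals={"T": 60})
    report = validate_table(t)
    assert report.observed["T"] == 59
    assert not report.ok


def test_empty_table_validates_to_empty_report():
    t = CloneCountTable(counts=pd.DataFrame(), expected_totals={})
    assert validate_table(t).observed == {}


def test_negative_counts_rejected():
    with pytest.raises(ValidationError):
        _toy_table({"g1": {"T": -1}})


def test_class_abundance_matches_published_percentages(reference_table):
    table, comps = reference_table
    assert class_abundance(table, comps, "W+OS").percentages[4] == 38
    assert class_abundance(table, comps, "AI").percentages[4] == 12
    assert class_abundance(table, comps, "W+W").percentages[4] == 17
    assert class_abundance(table, comps, "W+OS").percentages[2] == 10
    for t in table.treatments:
        assert class_abundance(table, comps, t).percentages[3] >= 40


def test_class_abundance_toy():
    t = _toy_table({"gA": {"T": 3}, "gB": {"T": 1}})
    comps = [
        GeneComposition("gA", 1, [1, 2, 3, 4]),
        GeneComposition("gB", 1, [1, 2]),
    ]
    ab = class_abundance(t, comps, "T")
    assert ab.class_counts == {4: 3, 2: 1}
    assert ab.percentages[4] == 75


def test_class_abundance_zero_column_errors():
    t = _toy_table({"gA": {"T": 0}})
    with pytest.raises(ValidationError, match="no clones"):
        class_abundance(t, [GeneComposition("gA", 1, [1])], "T")


def test_gene_frequency_fractions(reference_table):
    table, _ = reference_table
    freq = gene_frequency(table)
    wos = freq[freq.treatment == "W+OS"].set_index("gene")
    # the most frequent gene under wounding + oral secretions
    assert wos.fraction.idxmax() == "CanPI-7"
    assert wos.loc["CanPI-7", "count"] == 12
    assert wos.loc["CanPI-7", "fraction"] == pytest.approx(12 / 60)
    # a 12-of-60 gene would be 0.20
    t = _toy_table({"g": {"T": 12}}, totals={"T": 60})
    assert gene_frequency(t).fraction.iloc[0] == pytest.approx(0.20)
    # zero-count genes are absent
    never = set(table.genes) - set(freq.gene)
    assert "CanPI-9" in never  # not detected in any leaf library


def test_partition_regions():
    t = _toy_table({"g1": {"A": 1, "B": 0}, "g2": {"A": 1, "B": 1}})
    regions = shared_unique_partition(t, ["A", "B"])
    assert regions[("A",)] == ["g1"]
    assert regions[("A", "B")] == ["g2"]
    assert regions[("B",)] == []


def test_partition_is_complete_and_disjoint(reference_table):
    table, _ = reference_table
    regions = shared_unique_partition(table)
    seen = [g for genes in regions.values() for g in genes]
    assert len(seen) == len(set(seen))
    expressed = {
        g
        for g in table.genes
        if any(table.counts.at[g, t] > 0 for t in ("AI", "W+W", "W+OS"))
    }
    assert set(seen) == expressed


def test_ird_frequency_multiplicity():
    t = _toy_table({"g": {"T": 5}})
    comps = [GeneComposition("g", 1, [1, 1, 17])]
    freq = ird_frequency(t, comps)
    assert freq.loc[1, "T"] == 10
    assert freq.loc[17, "T"] == 5


def test_ird_frequency_reference_table(reference_table):
    table, comps = reference_table
    freq = ird_frequency(table, comps)
    # the two IRDs represented under every treatment
    for lab in (1, 17):
        assert (freq.loc[lab] > 0).all()


def test_ird_frequency_zero_column():
    t = _toy_table({"g": {"T": 0}})
    freq = ird_frequency(t, [GeneComposition("g", 1, [1, 2])])
    assert (freq["T"] == 0).all()


def _catalog_with_classes(classes):
    cat = IRDCatalog.from_labels(classes.keys())
    cat.class_of.update(classes)
    return cat


def test_class_specificity_all_ti():
    t = _toy_table({"g": {"T": 4}})
    cat = _catalog_with_classes({1: "TI", 2: "TI"})
    out = class_specificity_summary(t, [GeneComposition("g", 1, [1, 2])], cat)
    assert out.loc["T", "TI"] == 1.0


def test_class_specificity_symmetric_split():
    t = _toy_table({"gT": {"T": 3}, "gC": {"T": 3}})
    cat = _catalog_with_classes({1: "TI", 2: "CI"})
    comps = [GeneComposition("gT", 1, [1, 1]), GeneComposition("gC", 1, [2, 2])]
    out = class_specificity_summary(t, comps, cat)
    assert out.loc["T", "TI"] == pytest.approx(0.5)
    assert out.loc["T", "CI"] == pytest.approx(0.5)


def test_statistics_agree_with_brute_force():
    """All statistics equal a naive clone-by-clone recount on random tables."""
    rng = np.random.default_rng(17)
    for _ in range(10):
        n_genes = int(rng.integers(2, 10))
        genes = [f"g{i}" for i in range(n_genes)]
        comps = [
            GeneComposition(
                g, 1, [int(l) for l in rng.integers(1, 6, size=rng.integers(1, 5))]
            )
            for g in genes
        ]
        classes = {l: ("TI" if l % 2 else "CI") for l in range(1, 6)}
        cat = _catalog_with_classes(classes)
        counts = pd.DataFrame(
            rng.integers(0, 8, size=(n_genes, 4)),
            index=genes,
            columns=list("WXYZ"),
        )
        table = CloneCountTable(counts=counts)
        comp_of = {c.gene_id: c for c in comps}
        for t in "WXYZ":
            # expand to individual clones and recount naively
            clones = [g for g in genes for _ in range(counts.at[g, t])]
            if not clones:
                continue
            ab = class_abundance(table, comps, t)
            for k in set(ab.class_counts):
                assert ab.class_counts[k] == sum(
                    1 for g in clones if comp_of[g].n_irds == k
                )
            freq = ird_frequency(table, comps, cat)
            tally = {}
            for g in clones:
                for l in comp_of[g].ird_labels:
                    tally[l] = tally.get(l, 0) + 1
            for l in freq.index:
                assert freq.at[l, t] == tally.get(l, 0)
            spec = class_specificity_summary(table, comps, cat)
            ti = sum(v for l, v in tally.items() if classes[l] == "TI")
            assert spec.loc[t, "TI"] == pytest.approx(ti / sum(tally.values()))


def test_doubling_counts_preserves_percentages(reference_table):
    table, comps = reference_table
    doubled = table.scaled(2)
    for t in table.treatments:
        a, b = class_abundance(table, comps, t), class_abundance(doubled, comps, t)
        assert b.class_counts == {k: 2 * v for k, v in a.class_counts.items()}
        assert a.percentages == b.percentages
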