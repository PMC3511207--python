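"""File formats: FASTA in; TSV/CSV, GFF3, JSON, PHYLIP, Newick out.

Also ships the transcribed gene-composition / clone-count table of the
*Capsicum annuum* Pin-II inhibitor family (47 genes, four treatments) as a
packaged CSV fixture.  Fixture dialect: columns ``gene, sp, ird1..ird4,
partial, novel, count_UL, count_AI, count_WW, count_WOS``; an IRD cell
holds an integer label, optionally suffixed ``p`` for a partial trailing
domain, or a bare ``p`` when the partial domain's label is unknown; blank
cells are zero counts / absent domains, never missing data.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import ValidationError
from .annotate import PrecursorAnnotation, PrecursorSequence
from .catalog import GeneComposition, IRDCatalog, SPCatalog
from .diversity import DEFAULT_TOTALS, CloneCountTable

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_clone_table",
    "load_reference_table",
    "annotations_to_frame",
    "annotations_to_gff3",
    "catalog_to_frame",
    "run_metadata",
]

_FIXTURE = "table1_clone_counts.csv"


def read_fasta(path: str | Path) -> list[PrecursorSequence]:
    """Read amino-acid FASTA; a ``partial`` token in the description flags
    an incomplete precursor.  Duplicate ids are an error."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        is_partial = "partial" in rec.description.lower().split()
        records.append(
            PrecursorSequence(id=rec.id, aa_seq=str(rec.seq), is_partial=is_partial)
        )
    return records


def write_fasta(records: Iterable[PrecursorSequence], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.aa_seq), id=r.id, description="partial" if r.is_partial else "")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def _parse_ird_cell(cell) -> tuple[Optional[int], bool, bool]:
    """-> (label or None, present, partial)."""
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return None, False, False
    s = str(cell).strip()
    if not s or s.lower() == "nan":
        return None, False, False
    if s == "p":
        return None, True, True
    if s.endswith("p"):
        return int(s[:-1]), True, True
    return int(float(s)), True, False


def read_clone_table(path: str | Path) -> tuple[CloneCountTable, list[GeneComposition]]:
    """Read a fixture-dialect CSV into a count table plus compositions."""
    df = pd.read_csv(path, dtype=str)
    required = {"gene", "sp", "count_UL", "count_AI", "count_WW", "count_WOS"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"clone-table CSV lacks column(s): {sorted(missing)}")
    ird_cols = sorted(c for c in df.columns if c.startswith("ird"))
    compositions = []
    counts = {}
    for _, row in df.iterrows():
        gene = row["gene"].strip()
        labels: list[Optional[int]] = []
        partial = False
        for c in ird_cols:
            label, present, is_partial = _parse_ird_cell(row[c])
            if present:
                labels.append(label)
                partial = partial or is_partial
        sp_raw = row["sp"]
        sp_label = None if pd.isna(sp_raw) or not str(sp_raw).strip() else int(float(sp_raw))
        novel = None
        if "novel" in df.columns and not pd.isna(row.get("novel")):
            novel = bool(int(row["novel"]))
        if "partial" in df.columns and not pd.isna(row.get("partial")):
            partial = partial or bool(int(row["partial"]))
        compositions.append(
            GeneComposition(
                gene_id=gene,
                sp_label=sp_label,
                ird_labels=labels,
                is_partial=partial,
                novel=novel,
            )
        )
        counts[gene] = {
            "UL": _count(row["count_UL"]),
            "AI": _count(row["count_AI"]),
            "W+W": _count(row["count_WW"]),
            "W+OS": _count(row["count_WOS"]),
        }
    table = CloneCountTable(
        counts=pd.DataFrame(counts).T[["UL", "AI", "W+W", "W+OS"]],
        expected_totals=dict(DEFAULT_TOTALS),
    )
    return table, compositions


def _count(cell) -> int:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return 0
    s = str(cell).strip()
    if not s or s.lower() in ("nan", "nd"):
        return 0
    return int(float(s))


def load_reference_table() -> tuple[CloneCountTable, list[GeneComposition]]:
    """The packaged 47-gene composition and clone-abundance table."""
    with resources.as_file(resources.files("pinpi.data") / _FIXTURE) as p:
        return read_clone_table(p)


def fixture_catalogs(
    compositions: list[GeneComposition],
) -> tuple[IRDCatalog, SPCatalog]:
    """Label-only catalogs (no sequences) from a transcribed table."""
    ird = IRDCatalog.from_labels(l for c in compositions for l in c.labeled())
    sp = SPCatalog()
    for lab in sorted({c.sp_label for c in compositions if c.sp_label is not None}):
        sp.entries[lab] = None
    return ird, sp


def annotations_to_frame(annotations: Iterable[PrecursorAnnotation]) -> pd.DataFrame:
    """Flat segment table: one row per SP / IRD / linker segment."""
    rows = []
    for ann in annotations:
        if ann.sp_span:
            rows.append((ann.precursor_id, "signal_peptide", *ann.sp_span, "", "", "", ""))
        for d in ann.irds:
            rows.append(
                (
                    ann.precursor_id,
                    "ird",
                    d.start,
                    d.end,
                    d.reactive_site.inhibitor_class if d.reactive_site else "",
                    d.cys_count,
                    int(d.scaffold_deviation),
                    int(d.is_partial),
                )
            )
        for (s, e), _ in ann.linkers:
            rows.append((ann.precursor_id, "linker", s, e, "", "", "", ""))
    return pd.DataFrame(
        rows,
        columns=[
            "precursor_id",
            "segment_type",
            "start",
            "end",
            "class",
            "cys_count",
            "scaffold_deviation",
            "is_partial",
        ],
    ).sort_values(["precursor_id", "start"], kind="stable", ignore_index=True)


_GFF_TYPES = {"signal_peptide": "signal_peptide", "ird": "repeat_region", "linker": "propeptide"}


def annotations_to_gff3(annotations: Iterable[PrecursorAnnotation]) -> str:
    """GFF3 rendering of the segmentation (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for ann in annotations:
        idx = 0
        for seg_type, start, end in ann.segments():
            idx += 1
            attrs = [f"ID={ann.precursor_id}.seg{idx}"]
            if seg_type == "ird":
                d = next(x for x in ann.irds if x.start == start)
                if d.reactive_site:
                    attrs.append(f"inhibitor_class={d.reactive_site.inhibitor_class}")
                attrs.append(f"cys_count={d.cys_count}")
            lines.append(
                "\t".join(
                    [
                        ann.precursor_id,
                        "pinpi",
                        _GFF_TYPES[seg_type],
                        str(start + 1),
                        str(end),
                        ".",
                        "+",
                        ".",
                        ";".join(attrs),
                    ]
                )
            )
    return "\n".join(lines) + "\n"


def catalog_to_frame(catalog: IRDCatalog) -> pd.DataFrame:
    rows = [
        (lab, catalog.class_of.get(lab, ""), catalog.deviation_of.get(lab), seq)
        for lab, seq in catalog.entries.items()
    ]
    return pd.DataFrame(rows, columns=["label", "class", "cys_variant", "aa_seq"])


def run_metadata(seed: Optional[int] = None, inputs: Iterable[str | Path] = ()) -> dict:
    """Provenance block written next to CLI outputs: version, seed, input hashes."""
    from . import __version__

    hashes = {}
    for p in inputs:
        p = Path(p)
        if p.is_file():
            hashes[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return {"tool": "pinpi", "version": __version__, "seed": seed, "input_sha256": hashes}


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
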