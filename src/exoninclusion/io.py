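"""Readers and writers for the pipeline's on-disk formats.

Tables are TSV with a header row; missing values are written as ``NA``;
lines starting with ``#`` are provenance comments (the pipeline stamps a
config hash there) and are skipped on read.  Exon annotations round-trip
through TSV and GFF3 (1-based inclusive on disk, 0-based half-open in
memory); sequences through FASTA; summaries through JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .inclusion import (
    ANNOTATION_COLUMNS,
    DesignError,
    ExpressionBundle,
    InclusionMatrix,
    validate_design,
)

__all__ = [
    "MalformedTableError",
    "DuplicateIdError",
    "SampleMismatchError",
    "read_table",
    "write_table",
    "read_expression",
    "read_design",
    "read_bundle",
    "write_bundle",
    "read_inclusion",
    "write_inclusion",
    "read_exon_annotation",
    "write_exon_annotation",
    "write_gff3",
    "read_gff3",
    "read_fasta",
    "write_fasta",
    "read_json",
    "write_json",
]

NA = "NA"


class MalformedTableError(ValueError):
    """A TSV file lacks the expected header or columns."""


class DuplicateIdError(ValueError):
    """An id column contains duplicated entries."""


class SampleMismatchError(ValueError):
    """Expression and design tables disagree on the sample set."""


def write_table(df: pd.DataFrame, path, *, index: bool = True,
                comments: list[str] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, na_rep=NA)


def read_table(path, *, index_col: int | None = 0) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", index_col=index_col,
                           comment="#", na_values=[NA])
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise MalformedTableError(f"{path}: {exc}") from exc


def read_expression(path) -> pd.DataFrame:
    """Probeset (or metaprobeset) x sample log2 intensity matrix."""
    df = read_table(path)
    if df.index.has_duplicates:
        raise DuplicateIdError(f"{path}: duplicated row ids")
    if df.shape[1] == 0:
        raise MalformedTableError(f"{path}: no sample columns")
    return df.astype(float)


def read_design(path) -> pd.DataFrame:
    df = read_table(path, index_col=None)
    missing = {"sample", "pair", "status"} - set(df.columns)
    if missing:
        raise MalformedTableError(
            f"{path}: design missing columns {sorted(missing)}")
    try:
        return validate_design(df)
    except DesignError:
        raise


def read_probeset_annotation(path) -> pd.DataFrame:
    df = read_table(path)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise MalformedTableError(
            f"{path}: annotation missing columns {sorted(missing)}")
    if df.index.has_duplicates:
        raise DuplicateIdError(f"{path}: duplicated probeset ids")
    df["cross_hyb"] = df["cross_hyb"].astype(bool)
    return df


def _check_samples(matrix: pd.DataFrame, design: pd.DataFrame,
                   what: str) -> None:
    if set(matrix.columns) != set(design["sample"]):
        raise SampleMismatchError(
            f"{what} samples do not match the design sample set")


def write_bundle(bundle: ExpressionBundle, outdir,
                 comments: list[str] | None = None) -> dict[str, Path]:
    """Write the five bundle tables; returns the path of each."""
    outdir = Path(outdir)
    paths = {
        "probesets": outdir / "expression_probesets.tsv",
        "metaprobesets": outdir / "expression_metaprobesets.tsv",
        "annotation": outdir / "probeset_annotation.tsv",
        "detection": outdir / "detection_calls.tsv",
        "design": outdir / "design.tsv",
    }
    write_table(bundle.probesets, paths["probesets"], comments=comments)
    write_table(bundle.metaprobesets, paths["metaprobesets"],
                comments=comments)
    write_table(bundle.annotation, paths["annotation"], comments=comments)
    write_table(bundle.detection.astype(int), paths["detection"],
                comments=comments)
    write_table(bundle.design, paths["design"], index=False,
                comments=comments)
    return paths


def read_bundle(outdir) -> ExpressionBundle:
    outdir = Path(outdir)
    probes = read_expression(outdir / "expression_probesets.tsv")
    meta = read_expression(outdir / "expression_metaprobesets.tsv")
    annotation = read_probeset_annotation(outdir / "probeset_annotation.tsv")
    detection = read_table(outdir / "detection_calls.tsv").astype(bool)
    design = read_design(outdir / "design.tsv")
    _check_samples(probes, design, "probeset matrix")
    _check_samples(meta, design, "metaprobeset matrix")
    return ExpressionBundle(
        probesets=probes,
        metaprobesets=meta,
        annotation=annotation,
        detection=detection,
        design=design,
    )


def write_inclusion(incl: InclusionMatrix, path,
                    comments: list[str] | None = None) -> None:
    notes = list(comments or []) + [f"filters: {'; '.join(incl.filters)}"]
    write_table(incl.values, path, comments=notes)


def read_inclusion(path) -> InclusionMatrix:
    values = read_expression(path)
    return InclusionMatrix(values=values)


# ---------------------------------------------------------------------------
# exon annotation: TSV and GFF3

def write_exon_annotation(table: pd.DataFrame, path,
                          comments: list[str] | None = None) -> None:
    write_table(table, path, comments=comments)


def read_exon_annotation(path) -> pd.DataFrame:
    df = read_table(path)
    if df.index.has_duplicates:
        raise DuplicateIdError(f"{path}: duplicated exon ids")
    return df


def write_gff3(table: pd.DataFrame, path) -> None:
    """Export gene and exon records as GFF3 (1-based inclusive on disk)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        genes = table.drop_duplicates("gene_id")
        for _, row in genes.iterrows():
            fh.write(
                "\t".join([
                    str(row["chrom"]), "exoninclusion", "gene",
                    str(int(row["gene_start"]) + 1),
                    str(int(row["gene_end"])),
                    ".", row["strand"], ".",
                    f"ID={row['gene_id']}",
                ]) + "\n"
            )
        for exon_id, row in table.iterrows():
            fh.write(
                "\t".join([
                    str(row["chrom"]), "exoninclusion", "exon",
                    str(int(row["start"]) + 1), str(int(row["end"])),
                    ".", row["strand"], ".",
                    f"ID={exon_id};Parent={row['gene_id']}",
                ]) + "\n"
            )


def read_gff3(path) -> pd.DataFrame:
    """Read gene/exon records back into the internal 0-based table."""
    db = gffutils.create_db(str(path), dbfn=":memory:",
                            merge_strategy="create_unique",
                            keep_order=True)
    genes = {}
    for gene in db.features_of_type("gene"):
        genes[gene.id] = (gene.start - 1, gene.end, gene.strand)
    rows = []
    for exon in db.features_of_type("exon"):
        parent = exon.attributes.get("Parent", [None])[0]
        if parent is None or parent not in genes:
            raise MalformedTableError(
                f"exon {exon.id} has no known parent gene")
        gstart, gend, gstrand = genes[parent]
        rows.append({
            "exon_id": exon.id,
            "chrom": exon.seqid,
            "start": exon.start - 1,   # to 0-based half-open
            "end": exon.end,
            "strand": exon.strand,
            "gene_id": parent,
            "gene_start": gstart,
            "gene_end": gend,
        })
    return pd.DataFrame(rows).set_index("exon_id")


# ---------------------------------------------------------------------------
# FASTA, JSON

def write_fasta(sequences: dict[str, str], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
    }


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
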