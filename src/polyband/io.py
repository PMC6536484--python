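"""Readers and writers for the remaining text formats.

BED interval sets live in :mod:`polyband.intervals`; the state track in
:mod:`polyband.state_track`.  Here: point-feature BED, bedGraph step
signals, GFF3 gene models (parsed with gffutils), and the small TSV tables
(expression breadth, cytological anchors, class overrides).
"""

from __future__ import annotations

import gffutils
import numpy as np
import pandas as pd

from .intervals import InputFormatError
from .structures import GeneModel


def read_points_bed(path) -> pd.DataFrame:
    """Read point features (1-bp or zero-length BED records) as chrom/pos."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputFormatError(f"{path}:{lineno}: expected at least 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end - start > 1:
                raise InputFormatError(
                    f"{path}:{lineno}: record {chrom}:{start}-{end} is not a point"
                )
            rows.append((chrom, start))
    return pd.DataFrame(rows, columns=["chrom", "pos"])


def write_points_bed(points: pd.DataFrame, path) -> None:
    df = pd.DataFrame(
        {"chrom": points["chrom"], "start": points["pos"], "end": points["pos"] + 1}
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    """Read a bedGraph step signal; steps must be finite and non-overlapping."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    if not np.isfinite(df["value"]).all():
        bad = int(df.index[~np.isfinite(df["value"])][0])
        raise InputFormatError(f"{path}: non-finite value at record {bad}")
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    same = df["chrom"].to_numpy()[1:] == df["chrom"].to_numpy()[:-1]
    if len(df) > 1 and (same & (df["start"].to_numpy()[1:] < df["end"].to_numpy()[:-1])).any():
        raise InputFormatError(f"{path}: overlapping bedGraph steps")
    return df


def write_bedgraph(signal: pd.DataFrame, path) -> None:
    signal[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False, float_format="%.6g"
    )


# ---------------------------------------------------------------------------
# GFF3 gene models

def read_genes_gff3(path, transcript_counts: dict[str, int] | None = None) -> list[GeneModel]:
    """Read gene models from GFF3 (1-based, converted to 0-based half-open).

    Transcript counts are inferred from mRNA children; an explicit
    ``transcript_counts`` mapping (gene id -> count) overrides the
    inference.  Expression breadth, when present, is read from a
    ``breadth`` attribute.
    """
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        n = sum(1 for _ in db.children(feat, featuretype="mRNA"))
        if transcript_counts and gid in transcript_counts:
            n = transcript_counts[gid]
        breadth = feat.attributes.get("breadth", [None])[0]
        genes.append(
            GeneModel(
                gid, feat.seqid, feat.start - 1, feat.end, feat.strand,
                max(n, 1), int(breadth) if breadth is not None else None,
            )
        )
    return sorted(genes, key=lambda g: (g.chrom, g.start))


def write_genes_gff3(genes: list[GeneModel], path) -> None:
    """Write gene models as GFF3 with one mRNA child per transcript."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            attrs = f"ID={g.gene_id}"
            if g.expression_breadth is not None:
                attrs += f";breadth={g.expression_breadth}"
            fh.write(
                f"{g.chrom}\tpolyband\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for k in range(g.n_transcripts):
                fh.write(
                    f"{g.chrom}\tpolyband\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.t{k + 1};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Small TSV tables

def read_breadth_tsv(path) -> dict[str, int]:
    """Expression-breadth table: gene id -> number of tissues."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise InputFormatError(f"{path}: expected (gene_id, n_tissues) columns")
    df = df.iloc[:, :2]
    df.columns = ["gene_id", "n_tissues"]
    return {str(r.gene_id): int(r.n_tissues) for r in df.itertuples(index=False)}


def attach_breadth(genes: list[GeneModel], breadth: dict[str, int]) -> list[GeneModel]:
    for g in genes:
        if g.gene_id in breadth:
            g.expression_breadth = breadth[g.gene_id]
    return genes


def read_anchors_tsv(path) -> pd.DataFrame:
    """Cytological anchor table with columns chrom, pos (or start/end), name."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    if "pos" not in cols and "start" in cols:
        df["pos"] = (df[cols["start"]] + df[cols.get("end", cols["start"])]) // 2
    need = {"chrom", "pos", "name"}
    if not need.issubset({c.lower() for c in df.columns}):
        raise InputFormatError(f"{path}: expected columns chrom, pos (or start/end), name")
    df.columns = [c.lower() for c in df.columns]
    return df[["chrom", "pos", "name"]]


def read_overrides_tsv(path) -> dict[str, str]:
    """Manual class overrides: structure name -> forced class."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["name", "klass"])
    return {str(r.name): str(r.klass) for r in df.itertuples(index=False)}
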