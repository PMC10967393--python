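"""Gene annotation container, multi-source merging, and GTF/BED round-tripping.

The analysis rests on a nonredundant gene-level annotation combining a
GENCODE-like protein-coding set with lncRNAs from a LNCipedia-like catalog
plus de novo assembled lncRNAs.  Coordinates are 0-based half-open
internally; GTF is 1-based closed on disk and converted on read/write.
"""

from __future__ import annotations

import pandas as pd

BIOTYPES = ("lncRNA", "protein_coding")
SOURCES = ("gencode", "lncipedia", "denovo", "synthetic")

#: merge precedence, highest first
SOURCE_PRECEDENCE = {"gencode": 0, "lncipedia": 1, "denovo": 2, "synthetic": 3}

COLUMNS = ["gene_id", "biotype", "source", "chrom", "start", "end", "strand", "length"]


class AnnotationError(ValueError):
    pass


def make_annotation(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a gene annotation table.

    Expects columns gene_id, biotype, chrom, start, end and optionally
    source, strand, length.  Returns a copy with the canonical column set,
    ``length`` defaulting to ``end - start``.
    """
    df = df.copy()
    if "source" not in df:
        df["source"] = "synthetic"
    if "strand" not in df:
        df["strand"] = "."
    if "length" not in df or df["length"].isna().any():
        df["length"] = df.get("length", pd.Series(index=df.index, dtype=float))
        df["length"] = df["length"].fillna(df["end"] - df["start"])
    df["length"] = df["length"].astype(int)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)

    bad_bt = set(df["biotype"]) - set(BIOTYPES)
    if bad_bt:
        raise AnnotationError(f"unknown biotypes: {sorted(bad_bt)}")
    bad_src = set(df["source"]) - set(SOURCES)
    if bad_src:
        raise AnnotationError(f"unknown sources: {sorted(bad_src)}")
    if (df["start"] >= df["end"]).any():
        bad = df.loc[df["start"] >= df["end"], "gene_id"].tolist()
        raise AnnotationError(f"start >= end for genes: {bad[:5]}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].unique().tolist()
        raise AnnotationError(f"duplicate gene ids: {dups[:5]}")
    return df[COLUMNS].reset_index(drop=True)


def merge_annotations(sources: list[pd.DataFrame], dedup_coordinates: bool = False) -> pd.DataFrame:
    """Merge annotation tables into one nonredundant gene set.

    Duplicate ``gene_id`` records are collapsed keeping the record from the
    highest-precedence source (gencode > lncipedia > denovo > synthetic).
    With ``dedup_coordinates`` the same collapse is additionally applied to
    records sharing (chrom, start, end, strand).  Conflicting biotypes for
    one gene_id are an error.

    Returns the merged table; per-biotype counts are available via
    ``biotype_counts``.
    """
    frames = [make_annotation(s) for s in sources]
    cat = pd.concat(frames, ignore_index=True)

    conflicts = (
        cat.groupby("gene_id")["biotype"].nunique()
    )
    offenders = conflicts[conflicts > 1].index.tolist()
    if offenders:
        raise AnnotationError(f"conflicting biotypes for gene ids: {offenders[:10]}")

    cat["_prec"] = cat["source"].map(SOURCE_PRECEDENCE)
    cat = cat.sort_values(["_prec"], kind="stable")
    cat = cat.drop_duplicates(subset="gene_id", keep="first")
    if dedup_coordinates:
        cat = cat.drop_duplicates(subset=["chrom", "start", "end", "strand"], keep="first")
    return cat.drop(columns="_prec").sort_values("gene_id", kind="stable").reset_index(drop=True)


def biotype_counts(annotation: pd.DataFrame) -> dict[str, int]:
    """Number of genes per biotype."""
    return annotation["biotype"].value_counts().to_dict()


# ---------------------------------------------------------------------------
# GTF / BED IO.  Only gene-level features are modeled; attributes use the
# Ensembl dialect (`gene_id "X"; gene_biotype "Y";`).
# ---------------------------------------------------------------------------

def write_gtf(annotation: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for rec in annotation.itertuples(index=False):
            attrs = (
                f'gene_id "{rec.gene_id}"; gene_biotype "{rec.biotype}"; '
                f'gene_source "{rec.source}"; gene_length "{rec.length}";'
            )
            fields = [
                rec.chrom, rec.source, "gene",
                str(rec.start + 1), str(rec.end),  # 1-based closed on disk
                ".", rec.strand, ".", attrs,
            ]
            fh.write("\t".join(fields) + "\n")


def _parse_attributes(raw: str) -> dict[str, str]:
    out = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gtf(path) -> pd.DataFrame:
    """Read gene features from a GTF file into an annotation table.

    Disk coordinates are 1-based closed; internal are 0-based half-open.
    Malformed lines raise with the offending line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}")
            chrom, src, feature, start, end, _score, strand, _frame, raw_attrs = fields
            if feature != "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: non-integer coordinates") from exc
            attrs = _parse_attributes(raw_attrs)
            if "gene_id" not in attrs:
                raise AnnotationError(f"{path}:{lineno}: missing gene_id attribute")
            rows.append({
                "gene_id": attrs["gene_id"],
                "biotype": attrs.get("gene_biotype", "protein_coding"),
                "source": attrs.get("gene_source", src if src in SOURCES else "synthetic"),
                "chrom": chrom,
                "start": start_i - 1,
                "end": end_i,
                "strand": strand,
                "length": int(attrs["gene_length"]) if "gene_length" in attrs else None,
            })
    if not rows:
        return make_annotation(pd.DataFrame(columns=COLUMNS))
    return make_annotation(pd.DataFrame(rows))


def write_bed(annotation: pd.DataFrame, path) -> None:
    """Write as BED6 plus biotype/source/length columns (BED is already 0-based half-open)."""
    out = annotation[["chrom", "start", "end", "gene_id", "length", "strand",
                      "biotype", "source"]].copy()
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "gene_id", "length", "strand", "biotype", "source"],
        )
    except pd.errors.EmptyDataError:
        return make_annotation(pd.DataFrame(columns=COLUMNS))
    return make_annotation(df)
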