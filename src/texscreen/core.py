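"""Data model, file I/O and RPKM normalization.

The pipeline operates on three tables:

* a gene table (``gene_id``, ``length_bp``, ``annotation``),
* a count matrix (genes x libraries, non-negative integers) with library
  metadata marking the target tissue, and
* an RPKM expression matrix derived from the two.

All on-disk formats are plain tab-separated text so that fixtures remain
human-readable and diffable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RPKM_SCALE = 1e9  # reads * kb^-1 * million mapped reads^-1 == 1e9 / (N * L)


class TexscreenError(Exception):
    """Base class for all pipeline errors."""


class FormatError(TexscreenError):
    """Malformed table contents (negative counts, duplicate ids, ...)."""


class SchemaError(TexscreenError):
    """Structurally invalid inputs (missing columns, no target library)."""


class LinkageError(TexscreenError):
    """Cross-table references that do not resolve."""


class NormalizationError(TexscreenError):
    """Inputs on which RPKM is undefined (zero library total)."""


class ParameterError(TexscreenError):
    """Invalid configuration values."""


@dataclass
class CountMatrix:
    """Read counts (genes x libraries) plus library metadata.

    ``counts`` is indexed by gene_id with one integer column per library;
    ``samples`` is indexed by library name with columns ``label`` (sample
    condition) and ``is_target`` (bool).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise SchemaError(
                "count matrix libraries do not match sample metadata: "
                f"{list(self.counts.columns)} vs {list(self.samples.index)}"
            )
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise FormatError(f"duplicate gene_id in counts: {list(dups)[:5]}")
        if not self.samples["is_target"].any():
            raise SchemaError("no library flagged is_target=1")
        if self.samples["is_target"].all():
            raise SchemaError("every library flagged is_target=1; need a contrast")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            # accept float columns only if every entry is integral
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                bad = np.argwhere(arr != np.floor(arr))
                g, j = bad[0]
                raise FormatError(
                    f"non-integer count for gene {self.counts.index[g]!r} "
                    f"in library {self.counts.columns[j]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if np.any(arr < 0):
            g, j = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count for gene {self.counts.index[g]!r} "
                f"in library {self.counts.columns[j]!r}"
            )

    @property
    def target_libraries(self) -> list[str]:
        return list(self.samples.index[self.samples["is_target"]])

    @property
    def nontarget_libraries(self) -> list[str]:
        return list(self.samples.index[~self.samples["is_target"]])


@dataclass
class ExpressionMatrix:
    """RPKM values with the provenance of the normalization."""

    values: pd.DataFrame
    samples: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def target_libraries(self) -> list[str]:
        return list(self.samples.index[self.samples["is_target"]])

    @property
    def nontarget_libraries(self) -> list[str]:
        return list(self.samples.index[~self.samples["is_target"]])


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def read_gene_table(genes_path: str | Path) -> pd.DataFrame:
    """Load genes.tsv (gene_id, length_bp, annotation) indexed by gene_id."""
    df = _read_tsv(genes_path, ["gene_id", "length_bp"])
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise FormatError(f"duplicate gene_id in gene table: {dups[:5]}")
    try:
        lengths = pd.to_numeric(df["length_bp"])
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric length_bp in {genes_path}") from exc
    if (lengths < 1).any() or (lengths != np.floor(lengths)).any():
        bad = df.loc[(lengths < 1) | (lengths != np.floor(lengths)), "gene_id"]
        raise FormatError(f"length_bp must be a positive integer; bad genes: {list(bad)[:5]}")
    out = df.set_index("gene_id")
    out["length_bp"] = lengths.astype(np.int64).to_numpy()
    if "annotation" not in out.columns:
        out["annotation"] = ""
    out["annotation"] = out["annotation"].fillna("")
    return out[["length_bp", "annotation"]]


def read_samples(samples_path: str | Path) -> pd.DataFrame:
    """Load samples.tsv (library, label, is_target) indexed by library."""
    df = _read_tsv(samples_path, ["library", "label", "is_target"])
    if df["library"].duplicated().any():
        raise FormatError(f"duplicate library names in {samples_path}")
    if not set(df["is_target"]) <= {"0", "1"}:
        raise FormatError(f"{samples_path}: is_target must be 0 or 1")
    out = df.set_index("library")
    out["is_target"] = out["is_target"] == "1"
    return out[["label", "is_target"]]


def read_counts(
    counts_path: str | Path,
    genes_path: str | Path,
    samples_path: str | Path,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Load and cross-validate the count matrix, gene table and sample sheet.

    The gene sets of counts.tsv and genes.tsv must coincide exactly; the
    libraries of counts.tsv must coincide with samples.tsv. Returns the
    validated :class:`CountMatrix` and the gene table.
    """
    genes = read_gene_table(genes_path)
    samples = read_samples(samples_path)
    raw = _read_tsv(counts_path, ["gene_id"])
    libs = [c for c in raw.columns if c != "gene_id"]
    if set(libs) != set(samples.index):
        raise SchemaError(
            f"libraries in counts {libs} do not match samples.tsv {list(samples.index)}"
        )
    if raw["gene_id"].duplicated().any():
        dups = raw.loc[raw["gene_id"].duplicated(), "gene_id"].tolist()
        raise FormatError(f"duplicate gene_id in counts: {dups[:5]}")
    counts = raw.set_index("gene_id")[list(samples.index)]
    for lib in counts.columns:
        col = pd.to_numeric(counts[lib], errors="coerce")
        if col.isna().any():
            gene = counts.index[col.isna()][0]
            raise FormatError(f"non-numeric count for gene {gene!r} in library {lib!r}")
        if (col != np.floor(col)).any():
            gene = counts.index[col != np.floor(col)][0]
            raise FormatError(f"non-integer count for gene {gene!r} in library {lib!r}")
        if (col < 0).any():
            gene = counts.index[col < 0][0]
            raise FormatError(f"negative count for gene {gene!r} in library {lib!r}")
        counts[lib] = col.astype(np.int64)
    only_counts = set(counts.index) - set(genes.index)
    only_genes = set(genes.index) - set(counts.index)
    if only_counts or only_genes:
        raise LinkageError(
            f"gene sets differ between counts and gene table: "
            f"{len(only_counts)} only in counts (e.g. {sorted(only_counts)[:3]}), "
            f"{len(only_genes)} only in gene table (e.g. {sorted(only_genes)[:3]})"
        )
    genes = genes.loc[counts.index]
    return CountMatrix(counts=counts, samples=samples), genes


def _merged_length(intervals: list[tuple[int, int]]) -> int:
    """Total bp covered by the union of 1-based inclusive intervals."""
    total = 0
    cur_start = cur_end = None
    for start, end in sorted(intervals):
        if cur_end is None:
            cur_start, cur_end = start, end
        elif start <= cur_end + 1:
            cur_end = max(cur_end, end)
        else:
            total += cur_end - cur_start + 1
            cur_start, cur_end = start, end
    if cur_end is not None:
        total += cur_end - cur_start + 1
    return total


def gene_lengths_from_gff3(gff3_path: str | Path) -> pd.DataFrame:
    """Derive per-gene exonic lengths from a GFF3 file.

    The length of a gene is the size of the union of its exon intervals,
    merged across transcripts (the conventional length for RPKM). Genes
    with no exon features fall back to the gene span, with a warning.
    GFF3 coordinates are 1-based inclusive.
    """
    import gffutils

    path = Path(gff3_path)
    if not path.exists():
        raise SchemaError(f"GFF3 file not found: {path}")
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    gene_ids = [g.id for g in db.features_of_type("gene")]
    known = set(gene_ids)
    exons: dict[str, list[tuple[int, int]]] = {g: [] for g in gene_ids}
    for exon in db.features_of_type("exon"):
        parents = [p.id for p in db.parents(exon, featuretype="gene")]
        if not parents:
            # exon whose Parent chain never reaches a known gene
            declared = exon.attributes.get("Parent", ["<missing>"])
            raise LinkageError(
                f"exon at {exon.seqid}:{exon.start}-{exon.end} references "
                f"unknown gene (Parent={declared})"
            )
        for gid in parents:
            if gid not in known:
                raise LinkageError(f"exon parent {gid!r} is not a gene feature")
            exons[gid].append((exon.start, exon.end))
    rows = []
    for gid in gene_ids:
        if exons[gid]:
            length = _merged_length(exons[gid])
        else:
            g = db[gid]
            length = g.end - g.start + 1
            logger.warning(
                "gene %s has no exon features; falling back to gene span (%d bp)",
                gid,
                length,
            )
        rows.append((gid, length))
    return pd.DataFrame(rows, columns=["gene_id", "length_bp"]).set_index("gene_id")


def rpkm(counts: CountMatrix, genes: pd.DataFrame) -> ExpressionMatrix:
    """Reads per kilobase of transcript per million mapped reads.

    RPKM(g, j) = 1e9 * C(g, j) / (N(j) * L(g)), with N(j) the column total
    of the count matrix (the standard proxy for total mapped reads when
    starting from a counts table) and L(g) the gene length in bp.
    """
    missing = set(counts.counts.index) - set(genes.index)
    if missing:
        raise LinkageError(f"genes without a length: {sorted(missing)[:5]}")
    lengths = genes.loc[counts.counts.index, "length_bp"].to_numpy(dtype=float)
    totals = counts.counts.sum(axis=0).to_numpy(dtype=float)
    zero = counts.counts.columns[totals == 0]
    if len(zero):
        raise NormalizationError(f"zero library total for {list(zero)}; RPKM undefined")
    values = RPKM_SCALE * counts.counts.to_numpy(dtype=float) / np.outer(lengths, totals)
    df = pd.DataFrame(values, index=counts.counts.index, columns=counts.counts.columns)
    provenance = {
        "total_counts_per_library": {
            lib: int(t) for lib, t in zip(counts.counts.columns, totals)
        },
        "library_total_definition": "column sum of the supplied count matrix",
        "length_source": "gene table length_bp",
    }
    return ExpressionMatrix(values=df, samples=counts.samples, provenance=provenance)


def write_rpkm(expr: ExpressionMatrix, path: str | Path, decimals: int = 4) -> None:
    """Write rpkm.tsv mirroring the counts.tsv layout (rounded for display)."""
    out = expr.values.round(decimals)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_rpkm(path: str | Path, samples_path: str | Path) -> ExpressionMatrix:
    """Load an rpkm.tsv written by :func:`write_rpkm` with its sample sheet."""
    samples = read_samples(samples_path)
    raw = _read_tsv(path, ["gene_id"])
    libs = [c for c in raw.columns if c != "gene_id"]
    if set(libs) != set(samples.index):
        raise SchemaError(
            f"libraries in {path} do not match samples.tsv: {libs} vs {list(samples.index)}"
        )
    values = raw.set_index("gene_id")[list(samples.index)].astype(float)
    return ExpressionMatrix(values=values, samples=samples, provenance={"source": str(path)})
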