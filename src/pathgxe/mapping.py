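"""SNP-to-gene and gene-to-pathway mapping.

SNPs are assigned to protein-coding genes through extended gene windows
(gene start - 20 kb to gene end + 20 kb, closed interval at both ends),
and genes to pathways through gene-set (GMT) libraries.  The resulting
per-feature SNP sets are the units that the ADABF and ORA stages test.

Coordinates are 1-based inclusive internally.  BED input/output uses the
standard 0-based half-open convention and is converted on the way in/out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

DEFAULT_WINDOW_BP = 20_000

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "window_start", "window_end"]


class MappingError(ValueError):
    """Malformed annotation input or violated mapping contract."""


@dataclass
class GeneSetLibrary:
    """A named collection of gene sets (pathways).

    ``sets`` maps pathway id -> tuple of member gene ids (deduplicated,
    order of first appearance preserved).
    """

    name: str
    sets: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def manifest_count(self) -> int:
        return len(self.sets)

    def gene_universe(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out.update(members)
        return out


def manifest_total(libraries: Iterable[GeneSetLibrary]) -> int:
    """Total pathway count across a collection of libraries."""
    return sum(lib.manifest_count for lib in libraries)


def make_gene_intervals(
    gene_ids: Iterable[str],
    chroms: Iterable[str],
    starts: Iterable[int],
    ends: Iterable[int],
    window_bp: int = DEFAULT_WINDOW_BP,
) -> pd.DataFrame:
    """Build a gene-interval table with flanking windows.

    ``start``/``end`` are 1-based inclusive.  The window extends exactly
    ``window_bp`` on each side, floored at position 1 on the 5' end.
    """
    df = pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "chrom": list(chroms),
            "start": np.asarray(list(starts), dtype=np.int64),
            "end": np.asarray(list(ends), dtype=np.int64),
        }
    )
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise MappingError(f"duplicate gene ids: {dups}")
    bad = df["start"] > df["end"]
    if bad.any():
        raise MappingError(
            f"gene start > end for: {df.loc[bad, 'gene_id'].tolist()}"
        )
    if (df["start"] < 1).any():
        raise MappingError("gene start must be >= 1 (1-based coordinates)")
    df["window_start"] = np.maximum(df["start"] - window_bp, 1)
    df["window_end"] = df["end"] + window_bp
    return df[GENE_COLUMNS]


def read_gene_intervals(path, window_bp: int = DEFAULT_WINDOW_BP) -> pd.DataFrame:
    """Read gene bodies from a BED file (>=4 columns, name in column 4).

    BED's 0-based half-open [chromStart, chromEnd) becomes 1-based
    inclusive [chromStart + 1, chromEnd].
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise MappingError(
                    f"{path}:{lineno}: expected >=4 tab-separated BED columns"
                )
            chrom, cstart, cend, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if cend <= cstart:
                raise MappingError(
                    f"{path}:{lineno}: chromEnd ({cend}) <= chromStart ({cstart})"
                )
            rows.append((name, chrom, cstart + 1, cend))
    if not rows:
        raise MappingError(f"{path}: no gene intervals found")
    ids, chroms, starts, ends = zip(*rows)
    return make_gene_intervals(ids, chroms, starts, ends, window_bp=window_bp)


def write_gene_intervals(genes: pd.DataFrame, path, header_comments: Iterable[str] = ()) -> None:
    """Write gene bodies as BED (0-based half-open); windows are recomputed on read."""
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        for row in genes.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.gene_id}\n")


def read_gmt(path) -> GeneSetLibrary:
    """Read one gene-set library from a GMT file.

    Each line: set name, description, then member gene ids, tab-separated.
    Genes are deduplicated within a set; an empty set after dedup is an error.
    """
    import os

    name = os.path.splitext(os.path.basename(str(path)))[0]
    sets: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise MappingError(
                    f"{path}:{lineno}: GMT line needs >=3 fields (name, description, genes...)"
                )
            set_name = fields[0]
            genes = tuple(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise MappingError(f"{path}:{lineno}: gene set '{set_name}' is empty")
            if set_name in sets:
                raise MappingError(f"{path}:{lineno}: duplicate pathway id '{set_name}'")
            sets[set_name] = genes
    return GeneSetLibrary(name=name, sets=sets)


def write_gmt(library: GeneSetLibrary, path, header_comments: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        for set_name, genes in library.sets.items():
            fh.write("\t".join([set_name, library.name, *genes]) + "\n")


def assign_snps_to_genes(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    allow_disjoint: bool = False,
) -> pd.DataFrame:
    """Assign SNPs to every gene whose extended window covers them.

    ``snps`` needs columns ``snp_id``, ``chrom``, ``pos`` (1-based).
    Containment is inclusive at both window ends.  SNPs covered by no
    window are retained with ``gene_id`` = NA so callers can count and
    exclude them; SNPs in overlapping windows yield one row per gene.

    If the two tables share no chromosome label at all, the naming
    conventions almost certainly differ; this raises unless
    ``allow_disjoint`` is set.
    """
    for col in ("snp_id", "chrom", "pos"):
        if col not in snps.columns:
            raise MappingError(f"snps table missing column '{col}'")
    snp_chroms = set(snps["chrom"].unique())
    gene_chroms = set(genes["chrom"].unique())
    if snp_chroms and gene_chroms and not (snp_chroms & gene_chroms):
        msg = (
            "no chromosome label shared between SNPs and genes "
            f"(snps: {sorted(snp_chroms)[:5]}..., genes: {sorted(gene_chroms)[:5]}...)"
        )
        if not allow_disjoint:
            raise MappingError(msg + "; pass allow_disjoint=True to override")
        warnings.warn(msg)

    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples(index=False):
        # +1: IntervalTree is half-open, our windows are closed.
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.window_start, row.window_end + 1, row.gene_id
        )

    out_snp, out_gene = [], []
    for row in snps.itertuples(index=False):
        tree = trees.get(row.chrom)
        hits = sorted(iv.data for iv in tree[row.pos]) if tree is not None else []
        if hits:
            for g in hits:
                out_snp.append(row.snp_id)
                out_gene.append(g)
        else:
            out_snp.append(row.snp_id)
            out_gene.append(None)
    return pd.DataFrame({"snp_id": out_snp, "gene_id": pd.array(out_gene, dtype="string")})


def build_feature_snp_sets(
    assignments: pd.DataFrame,
    libraries: Iterable[GeneSetLibrary],
) -> tuple[dict[str, frozenset[str]], dict[tuple[str, str], frozenset[str]], dict[str, int]]:
    """Build per-gene and per-pathway SNP id sets.

    A pathway's SNP set is the union of its member genes' SNP sets.
    Features that end up with zero SNPs are dropped and counted.

    Returns ``(gene_sets, pathway_sets, dropped)`` where ``pathway_sets``
    is keyed by ``(library_name, pathway_id)`` and ``dropped`` holds
    counts of empty gene and pathway features.
    """
    if assignments.empty:
        raise MappingError("empty SNP assignment table")
    mapped = assignments.dropna(subset=["gene_id"])
    gene_sets: dict[str, frozenset[str]] = {
        gene: frozenset(group)
        for gene, group in mapped.groupby("gene_id", observed=True)["snp_id"]
    }
    empty_genes: set[str] = set()
    n_empty_pathways = 0
    pathway_sets: dict[tuple[str, str], frozenset[str]] = {}
    for lib in libraries:
        for pid, members in lib.sets.items():
            snps: set[str] = set()
            for g in members:
                got = gene_sets.get(g)
                if got is None:
                    empty_genes.add(g)
                else:
                    snps.update(got)
            if snps:
                pathway_sets[(lib.name, pid)] = frozenset(snps)
            else:
                n_empty_pathways += 1
    dropped = {
        "genes_without_snps": len(empty_genes),
        "pathways_without_snps": n_empty_pathways,
    }
    return gene_sets, pathway_sets, dropped
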