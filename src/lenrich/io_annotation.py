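"""Tabular I/O and assembly of the shared gene universe.

All files are plain TSV (UTF-8, '.' decimal separator); gzip-compressed
inputs are accepted by '.gz' extension.  Category maps can come either from
two-column gene/category TSVs or from GAF 2.x association files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from lenrich.errors import FormatError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GeneTable:
    """Per-gene record table for a two-condition count experiment.

    The underlying frame is indexed by unique gene_id and carries columns
    ``length_bp``, ``count_1``, ``count_2`` plus, once the corresponding
    stage has run, ``de_pvalue``, ``de_qvalue``, ``de_flag`` and
    ``pwf_weight``.
    """

    frame: pd.DataFrame
    lib_sizes: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.frame.index.is_unique:
            dup = self.frame.index[self.frame.index.duplicated()][0]
            raise ValidationError(f"duplicate gene_id {dup!r}")
        if (self.frame["length_bp"] <= 0).any():
            bad = self.frame.index[self.frame["length_bp"] <= 0][0]
            raise ValidationError(f"non-positive length for gene {bad!r}")
        for i, col in enumerate(("count_1", "count_2")):
            if (self.frame[col] < 0).any():
                bad = self.frame.index[self.frame[col] < 0][0]
                raise ValidationError(f"negative count for gene {bad!r}")
            if self.lib_sizes[i] <= 0:
                raise ValidationError("library sizes must be positive")
            if (self.frame[col] > self.lib_sizes[i]).any():
                bad = self.frame.index[self.frame[col] > self.lib_sizes[i]][0]
                raise ValidationError(
                    f"count exceeds library size for gene {bad!r}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def n_genes(self) -> int:
        return len(self.frame)

    @property
    def lengths(self) -> np.ndarray:
        return self.frame["length_bp"].to_numpy(dtype=float)

    @property
    def counts(self) -> np.ndarray:
        """(n_genes, 2) integer count matrix."""
        return self.frame[["count_1", "count_2"]].to_numpy(dtype=np.int64)

    @property
    def total_counts(self) -> np.ndarray:
        """Per-gene sum of counts across both conditions (the read-count bias covariate)."""
        return self.counts.sum(axis=1).astype(float)

    def covariate(self, kind: str) -> np.ndarray:
        if kind == "length":
            return self.lengths
        if kind == "total_count":
            return self.total_counts
        raise ValidationError(f"unknown covariate kind {kind!r}")

    def restrict(self, gene_ids: Iterable[str]) -> "GeneTable":
        wanted = set(gene_ids)
        keep = [g for g in self.gene_ids if g in wanted]
        return GeneTable(self.frame.loc[keep].copy(), self.lib_sizes)

    def drop_zero_count_genes(self) -> "GeneTable":
        mask = self.counts.sum(axis=1) > 0
        dropped = int((~mask).sum())
        if dropped:
            logger.info("dropping %d genes with zero counts in both conditions", dropped)
        return GeneTable(self.frame.loc[mask].copy(), self.lib_sizes)


@dataclass
class CategoryMap:
    """Bidirectional gene<->category index over a fixed gene universe."""

    category_to_genes: dict[str, frozenset[str]]
    gene_to_categories: dict[str, frozenset[str]] = field(init=False)
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        g2c: dict[str, set[str]] = {}
        for cat, genes in self.category_to_genes.items():
            for g in genes:
                if self.universe and g not in self.universe:
                    raise ValidationError(
                        f"gene {g!r} in category {cat!r} not in universe"
                    )
                g2c.setdefault(g, set()).add(cat)
        self.gene_to_categories = {g: frozenset(c) for g, c in g2c.items()}

    @property
    def categories(self) -> list[str]:
        return sorted(self.category_to_genes)

    @property
    def n_categories(self) -> int:
        return len(self.category_to_genes)

    def genes_in(self, category_id: str) -> frozenset[str]:
        return self.category_to_genes[category_id]

    def categories_of(self, gene_id: str) -> frozenset[str]:
        return self.gene_to_categories.get(gene_id, frozenset())

    @property
    def annotated_genes(self) -> frozenset[str]:
        return frozenset(self.gene_to_categories)

    def restrict(self, universe: Iterable[str]) -> "CategoryMap":
        """Restrict to a universe, removing categories that become empty. Idempotent."""
        uni = frozenset(universe)
        c2g = {}
        for cat, genes in self.category_to_genes.items():
            kept = genes & uni
            if kept:
                c2g[cat] = kept
        return CategoryMap(c2g, universe=uni)

    def membership_matrix(self, gene_order: list[str]) -> tuple[np.ndarray, list[str]]:
        """Boolean (n_genes, n_categories) matrix in sorted category order."""
        cats = self.categories
        idx = {g: i for i, g in enumerate(gene_order)}
        mat = np.zeros((len(gene_order), len(cats)), dtype=bool)
        for j, cat in enumerate(cats):
            rows = [idx[g] for g in self.category_to_genes[cat] if g in idx]
            mat[rows, j] = True
        return mat, cats


def read_gene_table(
    counts_path,
    lengths_path,
    lib_sizes: tuple[int, int] | None = None,
    drop_zeros: bool = False,
) -> GeneTable:
    """Read a two-condition count TSV and a length TSV into one GeneTable.

    The counts file must have a header with gene_id plus two count columns;
    the lengths file has columns gene_id, length_bp.  The table is restricted
    to genes present in both files; drops are logged.  Library sizes default
    to the count column sums.
    """
    counts = _read_tsv(counts_path, min_cols=3, what="counts")
    lengths = _read_tsv(lengths_path, min_cols=2, what="lengths")
    counts = counts.iloc[:, :3]
    counts.columns = ["gene_id", "count_1", "count_2"]
    lengths = lengths.iloc[:, :2]
    lengths.columns = ["gene_id", "length_bp"]

    for col in ("count_1", "count_2"):
        vals = pd.to_numeric(counts[col], errors="coerce")
        if vals.isna().any():
            raise FormatError(f"non-numeric value in column {col}")
        if (vals < 0).any():
            bad = counts.loc[vals < 0, "gene_id"].iloc[0]
            raise ValidationError(f"negative count for gene {bad!r}")
        counts[col] = vals.astype(np.int64)
    lengths["length_bp"] = pd.to_numeric(lengths["length_bp"], errors="coerce")
    if lengths["length_bp"].isna().any():
        raise FormatError("non-numeric length value")
    if (lengths["length_bp"] <= 0).any():
        bad = lengths.loc[lengths["length_bp"] <= 0, "gene_id"].iloc[0]
        raise ValidationError(f"non-positive length for gene {bad!r}")

    merged = counts.merge(lengths, on="gene_id", how="inner")
    n_drop = (len(counts) - len(merged)) + (len(lengths) - len(merged))
    if n_drop:
        logger.info(
            "dropped %d gene records absent from one of the two input files", n_drop
        )
    if merged.empty:
        raise FormatError("no genes shared between counts and lengths files")
    frame = merged.set_index("gene_id")[["length_bp", "count_1", "count_2"]]
    if lib_sizes is None:
        lib_sizes = (int(frame["count_1"].sum()), int(frame["count_2"].sum()))
    table = GeneTable(frame, lib_sizes)
    if drop_zeros:
        table = table.drop_zero_count_genes()
    return table


def _read_tsv(path, min_cols: int, what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot read {what} file {path}: {exc}") from exc
    if df.shape[1] < min_cols:
        raise FormatError(
            f"{what} file {path} has {df.shape[1]} columns, expected >= {min_cols}"
        )
    return df


def read_category_map(path, format: str = "tsv2col", universe=None) -> CategoryMap:
    """Read gene->category associations and restrict them to a universe.

    ``tsv2col``: two columns gene_id, category_id, header optional.
    ``gaf``: GAF 2.x — gene from column 2, category from column 5, '!' comment
    lines skipped.  Duplicate pairs are deduplicated; categories left empty
    after universe restriction are removed.
    """
    pairs: set[tuple[str, str]] = set()
    try:
        opener = _opener(path)
        with opener(path, "rt", encoding="utf-8") as fh:
            if format == "tsv2col":
                for line in fh:
                    line = line.rstrip("\n")
                    if not line or line.startswith("#"):
                        continue
                    parts = line.split("\t")
                    if len(parts) < 2:
                        continue
                    gene, cat = parts[0].strip(), parts[1].strip()
                    if gene == "gene_id" and cat == "category_id":
                        continue  # optional header
                    if gene and cat:
                        pairs.add((gene, cat))
            elif format == "gaf":
                for line in fh:
                    if line.startswith("!"):
                        continue
                    parts = line.rstrip("\n").split("\t")
                    if len(parts) < 5:
                        continue
                    gene, cat = parts[1].strip(), parts[4].strip()
                    if gene and cat:
                        pairs.add((gene, cat))
            else:
                raise ValidationError(f"unknown category-map format {format!r}")
    except OSError as exc:
        raise FormatError(f"cannot read category file {path}: {exc}") from exc
    if not pairs:
        raise FormatError(f"no parseable associations in {path}")

    c2g: dict[str, set[str]] = {}
    for gene, cat in pairs:
        c2g.setdefault(cat, set()).add(gene)
    cmap = CategoryMap({c: frozenset(g) for c, g in c2g.items()})
    if universe is not None:
        cmap = cmap.restrict(universe)
        if not cmap.category_to_genes:
            raise FormatError("no associations left after universe restriction")
    return cmap


def _opener(path):
    import gzip

    return gzip.open if str(path).endswith(".gz") else open


RESULT_COLUMNS = [
    "category_id",
    "n_category",
    "n_de_in_category",
    "odds",
    "p_over",
    "p_under",
    "fdr_over",
    "method",
]


def write_enrichment_results(results, path, header_comments: list[str] | None = None) -> None:
    """Write enrichment results as a TSV sorted by (p_over, category_id).

    Floats are written with 12 significant digits so a round-trip read
    reproduces values.  Optional '#'-prefixed comment lines record run
    provenance (seed, method, parameters).
    """
    if not results:
        raise ValidationError("no results to write")
    rows = sorted(results, key=lambda r: (r.p_over, r.category_id))
    try:
        with open(path, "w", encoding="utf-8") as fh:
            for line in header_comments or []:
                fh.write(f"# {line}\n")
            fh.write("\t".join(RESULT_COLUMNS) + "\n")
            for r in rows:
                fh.write(
                    "\t".join(
                        [
                            r.category_id,
                            str(r.counts.K),
                            str(r.counts.k),
                            _fmt(r.odds),
                            _fmt(r.p_over),
                            _fmt(r.p_under),
                            _fmt(r.fdr_over),
                            r.method,
                        ]
                    )
                    + "\n"
                )
    except OSError as exc:
        raise IOError(f"cannot write results to {path}: {exc}") from exc


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def read_enrichment_results(path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_enrichment_results`."""
    return pd.read_csv(path, sep="\t", comment="#")


def build_universe(
    table: GeneTable, cmap: CategoryMap, keep_unannotated: bool = False
) -> tuple[GeneTable, CategoryMap]:
    """Assemble the shared analysis universe.

    By default the universe is the intersection of genes having counts, a
    length, and at least one category; ``keep_unannotated=True`` retains
    annotated-universe outsiders in the gene table (they still dilute the
    weighting but can never contribute k).  The resulting N is logged because
    it enters every p-value.
    """
    if keep_unannotated:
        universe = set(table.gene_ids)
    else:
        universe = set(table.gene_ids) & set(cmap.annotated_genes)
        dropped = table.n_genes - len(universe)
        if dropped:
            logger.info("excluding %d unannotated genes from the universe", dropped)
    if not universe:
        raise ValidationError("empty universe after annotation restriction")
    table = table.restrict(universe)
    cmap = cmap.restrict(universe)
    logger.info(
        "universe: N=%d genes, %d categories", table.n_genes, cmap.n_categories
    )
    return table, cmap
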