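"""Core data containers and plain-text I/O.

The central object is :class:`ExpressionDataset`, a genes × cells RPKM
matrix bundled with a gene annotation table (chromosome, position, length,
spike-in flag) and a cell metadata table (embryo, embryonic day, sex, QC
flag).  Everything downstream — quality control, variable-gene selection,
pseudo-time, lineage calls, dosage statistics — consumes and annotates this
object.  Allele-level read counts travel separately as a tidy table
(:data:`ALLELE_COLUMNS`).

Matrices are stored as TSV (genes as rows, header row of cell IDs) or
MatrixMarket (.mtx plus two one-column ID files); both encodings round-trip
losslessly up to float formatting.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

GENE_COLUMNS = ["chrom", "start", "length_bp", "is_spikein"]
CELL_COLUMNS = ["embryo_id", "day", "subday", "sex", "qc_pass"]
ALLELE_COLUMNS = ["cell_id", "snv_id", "chrom", "pos", "gene_id",
                  "ref_reads", "alt_reads"]


class DatasetError(ValueError):
    """Raised for malformed inputs (dimension mismatch, duplicates, ...)."""


@dataclasses.dataclass
class ExpressionDataset:
    """Genes × cells expression values with annotation.

    Attributes
    ----------
    values : pd.DataFrame
        Non-negative RPKM values, index = gene IDs, columns = cell IDs.
    genes : pd.DataFrame
        Indexed by gene ID with columns ``chrom``, ``start`` (1-based),
        ``length_bp`` and ``is_spikein``.
    cells : pd.DataFrame
        Indexed by cell ID with columns ``embryo_id``, ``day`` (integer
        embryonic day, 3–7), ``subday`` (free-text tag, may be empty),
        ``sex`` (``female``/``male``/``unknown``) and ``qc_pass``.
    """

    values: pd.DataFrame
    genes: pd.DataFrame
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- contracts -------------------------------------------------------
    def validate(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise DatasetError(f"duplicate gene ID: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise DatasetError(f"duplicate cell ID: {dup!r}")
        if not self.values.index.equals(self.genes.index):
            raise DatasetError("gene annotation does not match matrix rows")
        if not self.values.columns.equals(self.cells.index):
            raise DatasetError("cell metadata does not match matrix columns")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            bad = self.values.index[np.where(~np.isfinite(arr))[0][0]]
            raise DatasetError(f"non-finite value in gene {bad!r}")
        if (arr < 0).any():
            bad = self.values.index[np.where((arr < 0).any(axis=1))[0][0]]
            raise DatasetError(f"negative value in gene {bad!r}")

    # -- convenience -----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def biological(self) -> "ExpressionDataset":
        """Dataset restricted to non-spike-in genes."""
        keep = ~self.genes["is_spikein"].to_numpy(bool)
        return self.subset(genes=self.genes.index[keep])

    def spikeins(self) -> "ExpressionDataset":
        keep = self.genes["is_spikein"].to_numpy(bool)
        return self.subset(genes=self.genes.index[keep])

    def subset(self, genes=None, cells=None) -> "ExpressionDataset":
        v = self.values
        g = self.genes
        c = self.cells
        if genes is not None:
            v = v.loc[genes]
            g = g.loc[genes]
        if cells is not None:
            v = v[list(cells)]
            c = c.loc[list(cells)]
        return ExpressionDataset(v, g, c)

    def log_values(self, genes=None, cells=None) -> pd.DataFrame:
        """log2(RPKM + 1), the transform used for all correlation/PCA work."""
        v = self.values
        if genes is not None:
            v = v.loc[genes]
        if cells is not None:
            v = v[list(cells)]
        return np.log2(v + 1.0)

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(self.values.copy(), self.genes.copy(),
                                 self.cells.copy())


def _normalize_cells(cells: pd.DataFrame) -> pd.DataFrame:
    cells = cells.copy()
    if "subday" not in cells:
        cells["subday"] = ""
    cells["subday"] = cells["subday"].fillna("")
    if "sex" not in cells:
        cells["sex"] = "unknown"
    cells["sex"] = cells["sex"].fillna("unknown")
    if "qc_pass" not in cells:
        cells["qc_pass"] = True
    cells["day"] = cells["day"].astype(int)
    return cells[CELL_COLUMNS]


def compute_rpkm(counts: pd.DataFrame, lengths_bp: pd.Series,
                 totals: pd.Series,
                 genes: pd.DataFrame | None = None,
                 cells: pd.DataFrame | None = None) -> ExpressionDataset:
    """Reads per kilobase of transcript per million mapped reads.

    value = count / (length/1e3) / (total/1e6).  ``totals`` are per-cell
    mapped-read counts; RPKM is invariant to jointly scaling counts and
    totals.
    """
    lengths_bp = lengths_bp.reindex(counts.index)
    totals = totals.reindex(counts.columns)
    if (lengths_bp <= 0).any():
        raise DatasetError("gene lengths must be positive")
    if (totals <= 0).any():
        raise DatasetError("per-cell totals must be positive")
    rpkm = counts.div(lengths_bp / 1e3, axis=0).div(totals / 1e6, axis=1)
    if genes is None:
        genes = pd.DataFrame({"chrom": "chr1", "start": 1,
                              "length_bp": lengths_bp, "is_spikein": False},
                             index=counts.index)
    if cells is None:
        cells = pd.DataFrame({"embryo_id": "NA", "day": 3},
                             index=counts.columns)
    return ExpressionDataset(rpkm.astype(float), genes, _normalize_cells(cells))


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

def read_dataset(matrix_path, genes_path, cells_path) -> ExpressionDataset:
    """Read a dataset from TSV or MatrixMarket plus annotation TSVs.

    ``matrix_path`` ending in ``.mtx`` selects MatrixMarket; the gene and
    cell order of the annotation files then defines row/column identity.
    """
    genes = pd.read_csv(genes_path, sep="\t", index_col=0)
    cells = pd.read_csv(cells_path, sep="\t", index_col=0)
    genes["is_spikein"] = genes["is_spikein"].astype(bool)
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        mat = scipy.io.mmread(matrix_path)
        mat = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat,
                         dtype=float)
        if mat.shape != (len(genes), len(cells)):
            raise DatasetError(
                f"matrix is {mat.shape}, annotation says "
                f"({len(genes)}, {len(cells)})")
        values = pd.DataFrame(mat, index=genes.index, columns=cells.index)
    else:
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        if values.shape[0] != len(genes) or values.shape[1] != len(cells):
            raise DatasetError(
                f"matrix is {values.shape}, annotation says "
                f"({len(genes)}, {len(cells)})")
        if not values.index.equals(genes.index):
            raise DatasetError("matrix gene IDs disagree with annotation")
        if list(values.columns) != list(cells.index):
            raise DatasetError("matrix cell IDs disagree with metadata")
    genes.index.name = "gene_id"
    cells.index.name = "cell_id"
    values.index.name = "gene_id"
    values.columns.name = "cell_id"
    return ExpressionDataset(values.astype(float), genes,
                             _normalize_cells(cells))


def write_dataset(dataset: ExpressionDataset, matrix_path, genes_path,
                  cells_path) -> None:
    matrix_path = Path(matrix_path)
    dataset.genes.to_csv(genes_path, sep="\t")
    dataset.cells.to_csv(cells_path, sep="\t")
    if matrix_path.suffix == ".mtx":
        scipy.io.mmwrite(str(matrix_path),
                         scipy.sparse.csr_matrix(dataset.values.to_numpy()))
    else:
        dataset.values.to_csv(matrix_path, sep="\t")


def read_allele_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(ALLELE_COLUMNS) - set(table.columns)
    if missing:
        raise DatasetError(f"allele table misses columns {sorted(missing)}")
    if (table[["ref_reads", "alt_reads"]] < 0).any().any():
        raise DatasetError("negative allele read counts")
    return table[ALLELE_COLUMNS]


def write_allele_table(table: pd.DataFrame, path) -> None:
    table[ALLELE_COLUMNS].to_csv(path, sep="\t", index=False)


def snv_catalog_from_vcf(path) -> pd.DataFrame:
    """Extract (snv_id, chrom, pos) from an uncompressed VCF.

    Only the site coordinates are read; genotype fields are ignored (the
    allelic statistics are phase-free).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            chrom, pos, snv_id = parts[0], int(parts[1]), parts[2]
            rows.append((snv_id, chrom, pos))
    return pd.DataFrame(rows, columns=["snv_id", "chrom", "pos"])
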