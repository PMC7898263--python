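"""Domain containers and readers/writers shared by every pipeline stage.

The on-disk interchange format is the 10x Genomics triplet layout
(MatrixMarket ``matrix.mtx`` plus ``barcodes.tsv`` and ``features.tsv``),
genes in rows and cells in columns, with counts stored as non-negative
integers.  Gene-set collections come in as tab-separated GMT files.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

log = logging.getLogger("mammaging")

YOUNG = "young"
AGED = "aged"


class ValidationError(ValueError):
    """Raised when an input violates a structural contract."""


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with cell-to-sample assignment.

    Parameters
    ----------
    values
        ``scipy.sparse`` matrix of shape ``(n_genes, n_cells)`` holding
        non-negative integer UMI counts.
    gene_ids
        Ordered, unique gene identifiers (symbols by default).
    barcodes
        Ordered, unique cell barcodes.
    sample_of_cell
        Mapping ``barcode -> sample id``; every barcode must be assigned.
    """

    values: sp.spmatrix
    gene_ids: np.ndarray
    barcodes: np.ndarray
    sample_of_cell: dict[str, str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.barcodes)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValidationError("duplicate barcodes")
        data = self.values.data
        if data.size:
            if (data < 0).any():
                raise ValidationError("negative counts")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("non-integer counts")
        missing = [b for b in self.barcodes if b not in self.sample_of_cell]
        if missing:
            raise ValidationError(
                f"{len(missing)} barcodes lack a sample assignment "
                f"(first: {missing[0]})"
            )

    # -- convenience ------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def samples(self) -> pd.Series:
        """Per-cell sample id, aligned with ``barcodes``."""
        return pd.Series(
            [self.sample_of_cell[b] for b in self.barcodes],
            index=self.barcodes, name="sample", dtype=object,
        )

    def gene_index(self, genes) -> np.ndarray:
        """Row indices of ``genes``; raises on a miss."""
        lut = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lut[g] for g in genes], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"gene {exc.args[0]!r} not in matrix") from exc

    def subset_cells(self, keep_barcodes) -> "CountMatrix":
        """Column subset preserving the given order."""
        lut = {b: i for i, b in enumerate(self.barcodes)}
        idx = np.array([lut[b] for b in keep_barcodes], dtype=int)
        return CountMatrix(
            self.values[:, idx],
            self.gene_ids.copy(),
            np.asarray(list(keep_barcodes), dtype=object),
            {b: self.sample_of_cell[b] for b in keep_barcodes},
        )

    def subset_genes(self, genes) -> "CountMatrix":
        idx = self.gene_index(genes)
        return CountMatrix(
            self.values[idx, :],
            np.asarray(list(genes), dtype=object),
            self.barcodes.copy(),
            dict(self.sample_of_cell),
        )

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


def concat_matrices(parts: list[CountMatrix]) -> CountMatrix:
    """Column-concatenate per-sample matrices over the union of genes.

    Counts for genes absent from a part are zero; per-cell column sums and
    the total cell count are preserved.
    """
    if not parts:
        raise ValidationError("nothing to concatenate")
    union: list[str] = []
    seen = set()
    for p in parts:
        for g in p.gene_ids:
            if g not in seen:
                seen.add(g)
                union.append(g)
    lut = {g: i for i, g in enumerate(union)}
    blocks = []
    for p in parts:
        rows = np.array([lut[g] for g in p.gene_ids], dtype=int)
        coo = p.values.tocoo()
        blocks.append(
            sp.coo_matrix(
                (coo.data, (rows[coo.row], coo.col)),
                shape=(len(union), p.n_cells),
            )
        )
    barcodes = np.concatenate([p.barcodes for p in parts])
    sample_of_cell: dict[str, str] = {}
    for p in parts:
        sample_of_cell.update(p.sample_of_cell)
    return CountMatrix(sp.hstack(blocks).tocsr(), np.asarray(union, dtype=object),
                       barcodes, sample_of_cell)


@dataclass
class SampleMeta:
    """One profiled animal: its sample id and age group."""

    sample_id: str
    age_group: str
    n_cells_loaded: int | None = None

    def __post_init__(self) -> None:
        if self.age_group not in (YOUNG, AGED):
            raise ValidationError(f"age_group must be '{YOUNG}' or '{AGED}'")


def age_of_samples(meta: list[SampleMeta]) -> dict[str, str]:
    ids = [m.sample_id for m in meta]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample ids")
    return {m.sample_id: m.age_group for m in meta}


@dataclass
class QCThresholds:
    """Cell-level filters; cells exactly at a bound are kept (elimination
    rules are strict inequalities)."""

    umi_min: int = 1000
    umi_max: int = 60000
    genes_min: int = 500
    genes_max: int = 2500
    mito_max: float = 0.10

    def __post_init__(self) -> None:
        if self.umi_min > self.umi_max or self.genes_min > self.genes_max:
            raise ValidationError("min threshold exceeds max")
        if not 0.0 <= self.mito_max <= 1.0:
            raise ValidationError("mito_max must be a fraction")


@dataclass
class DEConfig:
    """Thresholds of the three-criteria consensus DE procedure."""

    fc_grouped_min: float = 1.5
    fc_persample_min: float = 1.25
    alpha_adj: float = 0.05
    detect_frac_min: float = 0.10
    fc_pseudocount: float = 0.01
    scale_factor: float = 10000.0
    min_cells_per_sample: int = 3
    shrink_dispersion_trend: bool = False

    def __post_init__(self) -> None:
        if self.fc_grouped_min <= 1 or self.fc_persample_min <= 1:
            raise ValidationError("fold-change thresholds must exceed 1")
        if not 0 < self.alpha_adj < 1:
            raise ValidationError("alpha_adj must lie in (0, 1)")
        if not 0 <= self.detect_frac_min < 1:
            raise ValidationError("detect_frac_min must lie in [0, 1)")


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) with one description per set."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _find(dir_path: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dir_path / name
        if p.exists():
            return p
    raise FileNotFoundError(f"missing {stem}[.gz] in {dir_path}")


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, dtype=str)


def read_10x_mtx(dir_path, sample_id: str | None = None,
                 gene_column: str = "symbol") -> CountMatrix:
    """Read a 10x-style triplet directory into a :class:`CountMatrix`.

    The feature table may carry ``(id, symbol, type)`` triples; gene identity
    defaults to the symbol column (set ``gene_column="id"`` to use ids).
    MatrixMarket triplet indices are 1-based on disk and 0-based in memory.
    All cells are assigned to ``sample_id`` (default: the directory name).
    """
    dir_path = Path(dir_path)
    mtx_path = _find(dir_path, "matrix.mtx")
    barcodes = _read_tsv(_find(dir_path, "barcodes.tsv"))[0].to_numpy(dtype=object)
    try:
        features_path = _find(dir_path, "features.tsv")
    except FileNotFoundError:
        features_path = _find(dir_path, "genes.tsv")
    features = _read_tsv(features_path)
    if gene_column == "symbol":
        col = 1 if features.shape[1] >= 2 else 0
    elif gene_column == "id":
        col = 0
    else:
        raise ValidationError("gene_column must be 'symbol' or 'id'")
    gene_ids = features[col].to_numpy(dtype=object)

    opener = gzip.open if mtx_path.suffix == ".gz" else open
    with opener(mtx_path, "rb") as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.csr_matrix(mat)
    if mat.shape != (len(gene_ids), len(barcodes)):
        raise ValidationError(
            f"matrix is {mat.shape} but tables describe "
            f"{len(gene_ids)} genes x {len(barcodes)} cells"
        )
    if sample_id is None:
        sample_id = dir_path.name
    return CountMatrix(mat, gene_ids, barcodes,
                       {b: sample_id for b in barcodes})


def write_10x_mtx(m: CountMatrix, dir_path) -> None:
    """Write the triplet layout read back by :func:`read_10x_mtx`."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(dir_path / "matrix.mtx", m.values.tocoo(), field="integer")
    pd.Series(m.barcodes).to_csv(dir_path / "barcodes.tsv", sep="\t",
                                 header=False, index=False)
    feats = pd.DataFrame({
        "id": m.gene_ids, "symbol": m.gene_ids,
        "type": ["Gene Expression"] * m.n_genes,
    })
    feats.to_csv(dir_path / "features.tsv", sep="\t", header=False, index=False)


def read_dense_csv(path, sample_of_cell: dict[str, str] | None = None,
                   sample_id: str = "sample0") -> CountMatrix:
    """Read a dense genes x cells CSV (gene ids in the first column)."""
    df = pd.read_csv(path, index_col=0)
    counts = df.to_numpy()
    barcodes = df.columns.to_numpy(dtype=object)
    if sample_of_cell is None:
        sample_of_cell = {b: sample_id for b in barcodes}
    return CountMatrix(sp.csr_matrix(counts), df.index.to_numpy(dtype=object),
                       barcodes, sample_of_cell)


def read_gmt(path, uppercase: bool = False) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene...`` per line.

    Duplicate genes within a line are collapsed; blank lines are skipped.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValidationError(
                f"{path}:{lineno}: GMT line needs name, description and "
                f"at least one gene (got {len(fields)} fields)"
            )
        name, desc, *genes = fields
        if uppercase:
            genes = [g.upper() for g in genes]
        uniq = list(dict.fromkeys(g for g in genes if g))
        if name in sets:
            raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = uniq
        descriptions[name] = desc
    if not sets:
        log.warning("GMT file %s contains no gene sets", path)
    return GeneSetCollection(sets, descriptions)


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in coll.sets.items():
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines and ``#`` comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
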