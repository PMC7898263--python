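"""Per-cell quality metrics and the pre-filtering of cells and genes.

Cells are eliminated when UMI total, detected-gene count or mitochondrial
UMI fraction falls strictly outside the configured window (UMI < 1,000 or
> 60,000; genes < 500 or > 2,500; mito fraction > 10% by default), so a
cell exactly at a bound is kept.  Gene-level filtering keeps genes detected
(raw count > 0) in at least a minimum fraction of cells of either
comparison group.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import CountMatrix, QCThresholds, ValidationError

log = logging.getLogger("mammaging")

DEFAULT_MITO_PREFIX = "mt-"


def mito_gene_set(m: CountMatrix, prefix: str = DEFAULT_MITO_PREFIX) -> list[str]:
    """Mitochondrial genes by symbol prefix (mouse convention ``mt-``)."""
    return [g for g in m.gene_ids if str(g).startswith(prefix)]


def compute_cell_qc(m: CountMatrix, mito_genes=None,
                    thresholds: QCThresholds | None = None) -> pd.DataFrame:
    """Per-cell QC table: UMI total, genes detected, mito fraction, pass flag.

    An all-zero cell has mito fraction 0 by convention and never passes.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    if mito_genes is None:
        mito_genes = mito_gene_set(m)
    present = [g for g in mito_genes if g in set(m.gene_ids)]
    missing = set(mito_genes) - set(present)
    if missing:
        log.warning("%d mitochondrial genes absent from matrix", len(missing))
    if m.n_cells == 0:
        log.warning("empty matrix: QC table has no rows")

    csc = m.values.tocsc()
    umi = np.asarray(csc.sum(axis=0)).ravel()
    genes_detected = np.asarray((csc > 0).sum(axis=0)).ravel()
    if present:
        mito_umi = np.asarray(csc[m.gene_index(present), :].sum(axis=0)).ravel()
    else:
        mito_umi = np.zeros(m.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(umi > 0, mito_umi / np.maximum(umi, 1), 0.0)

    qc = pd.DataFrame({
        "barcode": m.barcodes,
        "sample": m.samples.to_numpy(),
        "umi_total": umi.astype(int),
        "genes_detected": genes_detected.astype(int),
        "mito_fraction": mito_frac,
    })
    t = thresholds
    qc["pass"] = (
        (qc.umi_total >= t.umi_min) & (qc.umi_total <= t.umi_max)
        & (qc.genes_detected >= t.genes_min) & (qc.genes_detected <= t.genes_max)
        & (qc.mito_fraction <= t.mito_max) & (qc.umi_total > 0)
    )
    return qc


def filter_cells(qc: pd.DataFrame, thresholds: QCThresholds) -> list[str]:
    """Barcodes kept under the thresholds, preserving input order.

    Keeping is inclusive at every boundary (the elimination rules use
    strict inequalities).
    """
    t = thresholds
    keep = (
        (qc.umi_total >= t.umi_min) & (qc.umi_total <= t.umi_max)
        & (qc.genes_detected >= t.genes_min) & (qc.genes_detected <= t.genes_max)
        & (qc.mito_fraction <= t.mito_max)
    )
    return qc.loc[keep, "barcode"].tolist()


def summarize_depth(m: CountMatrix, kept=None,
                    convention: str = "interpolated") -> tuple[float, float]:
    """Median genes per cell and median UMI per cell over the kept cells.

    ``convention`` is ``"interpolated"`` (mean of central pair for even n,
    the default) or ``"lower"``.
    """
    sub = m if kept is None else m.subset_cells(list(kept))
    if sub.n_cells == 0:
        raise ValidationError("no cells to summarize")
    csc = sub.values.tocsc()
    umi = np.asarray(csc.sum(axis=0)).ravel()
    genes = np.asarray((csc > 0).sum(axis=0)).ravel()
    if convention == "interpolated":
        return float(np.median(genes)), float(np.median(umi))
    if convention == "lower":
        def lower_median(x):
            x = np.sort(x)
            return float(x[(len(x) - 1) // 2])
        return lower_median(genes), lower_median(umi)
    raise ValidationError(f"unknown median convention {convention!r}")


def filter_detected_genes(m: CountMatrix, group_a, group_b,
                          min_frac: float = 0.10) -> list[str]:
    """Genes detected (count > 0) in at least ``min_frac`` of cells of
    either group; the boundary is inclusive."""
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValidationError("both comparison groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValidationError("comparison groups overlap")
    lut = {b: i for i, b in enumerate(m.barcodes)}
    ia = np.array([lut[b] for b in group_a])
    ib = np.array([lut[b] for b in group_b])
    det = (m.values > 0)
    frac_a = np.asarray(det[:, ia].sum(axis=1)).ravel() / len(ia)
    frac_b = np.asarray(det[:, ib].sum(axis=1)).ravel() / len(ib)
    keep = (frac_a >= min_frac) | (frac_b >= min_frac)
    return [g for g, k in zip(m.gene_ids, keep) if k]
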