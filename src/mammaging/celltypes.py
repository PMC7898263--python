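"""Normalization, clustering, marker scoring, cell-cycle calls and
cell-type-specific signature derivation.

Signatures are one-vs-each: a gene belongs to a type's signature only when
it beats *every* other type in pairwise fold change (> 1.25 by default)
with a BH-adjusted Wilcoxon p < 0.05, the adjustment applied within each
pairwise comparison.  A hybrid population is profiled against both parents
separately, requiring the same direction in both comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de import bh_adjust, fold_change, wilcoxon_vector
from .io import CountMatrix, ValidationError

log = logging.getLogger("mammaging")


@dataclass
class NormalizedMatrix:
    """Log-normalized expression: ``log1p(count * scale_factor / cell_total)``.

    Values are dense ``(genes x cells)`` float64; an all-zero cell maps to
    an all-zero column.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    barcodes: np.ndarray
    scale_factor: float = 10000.0

    def gene_index(self, genes) -> np.ndarray:
        lut = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lut[g] for g in genes], dtype=int)

    def cell_index(self, barcodes) -> np.ndarray:
        lut = {b: i for i, b in enumerate(self.barcodes)}
        return np.array([lut[b] for b in barcodes], dtype=int)

    def linear(self) -> np.ndarray:
        """De-logged normalized expression (``expm1`` of the stored values)."""
        return np.expm1(self.values)


def log_normalize(m: CountMatrix, scale_factor: float = 10000.0) -> NormalizedMatrix:
    """Column-wise library-size normalization followed by ``log1p``."""
    counts = m.dense().astype(np.float64)
    totals = counts.sum(axis=0)
    n_zero = int((totals == 0).sum())
    if n_zero:
        log.warning("%d all-zero cells map to all-zero columns", n_zero)
    vals = np.log1p(counts * (scale_factor / np.maximum(totals, 1.0))[None, :])
    return NormalizedMatrix(vals, m.gene_ids.copy(), m.barcodes.copy(),
                            scale_factor)


# ---------------------------------------------------------------------------
# Clustering (scanpy-backed)
# ---------------------------------------------------------------------------

def cluster_cells(nm: NormalizedMatrix, n_hvg: int = 2000, n_pcs: int = 30,
                  k: int = 20, resolution: float = 1.0,
                  seed: int = 0) -> pd.Series:
    """Graph clustering: dispersion-based HVG selection, PCA, kNN graph and
    Leiden community detection; deterministic for a fixed seed."""
    import anndata as ad
    import scanpy as sc

    n_cells = len(nm.barcodes)
    if n_cells < k + 1:
        raise ValidationError(f"need at least {k + 1} cells for k = {k}")
    adata = ad.AnnData(
        X=np.ascontiguousarray(nm.values.T, dtype=np.float32),
        obs=pd.DataFrame(index=pd.Index(nm.barcodes.astype(str))),
        var=pd.DataFrame(index=pd.Index(nm.gene_ids.astype(str))),
    )
    n_top = min(n_hvg, adata.n_vars)
    sc.pp.highly_variable_genes(adata, n_top_genes=n_top, flavor="seurat")
    adata = adata[:, adata.var.highly_variable].copy()
    sc.pp.scale(adata, max_value=10)
    n_comps = min(n_pcs, n_cells - 1, adata.n_vars - 1)
    if n_comps < n_pcs:
        log.warning("reducing n_pcs from %d to %d", n_pcs, n_comps)
    sc.tl.pca(adata, n_comps=n_comps, random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=min(k, n_cells - 1), random_state=seed)
    sc.tl.leiden(adata, resolution=resolution, random_state=seed,
                 flavor="igraph", n_iterations=2, directed=False)
    return pd.Series(adata.obs["leiden"].astype(str).to_numpy(),
                     index=nm.barcodes, name="cluster")


# ---------------------------------------------------------------------------
# Signature scoring and cell cycle
# ---------------------------------------------------------------------------

def score_signature(nm: NormalizedMatrix, genes, n_bins: int = 25,
                    n_ctrl: int = 50, seed: int = 0) -> pd.Series:
    """Bin-matched module score per cell.

    Score = mean expression of the signature genes minus the mean of a
    control set sampled (without replacement, ``n_ctrl`` per signature gene)
    from the same average-expression bin, so the control matches the
    signature's abundance profile.
    """
    genes = list(genes)
    present = [g for g in genes if g in set(nm.gene_ids)]
    missing = sorted(set(genes) - set(present))
    if not present:
        raise ValidationError(f"no signature gene found in matrix; "
                              f"missing: {missing[:10]}")
    if missing:
        log.warning("%d signature genes absent (e.g. %s)", len(missing),
                    missing[:3])
    rng = np.random.default_rng(seed)
    avg = nm.values.mean(axis=1)
    order = pd.Series(avg).rank(method="first")
    n_bins = min(n_bins, len(nm.gene_ids))
    bins = pd.qcut(order, n_bins, labels=False).to_numpy()
    sig_idx = nm.gene_index(present)
    sig_set = set(sig_idx.tolist())
    ctrl: set[int] = set()
    for gi in sig_idx:
        pool = np.flatnonzero(bins == bins[gi])
        pool = np.array([i for i in pool if i not in sig_set])
        if pool.size == 0:
            continue
        take = min(n_ctrl, pool.size)
        ctrl.update(rng.choice(pool, size=take, replace=False).tolist())
    sig_mean = nm.values[sig_idx, :].mean(axis=0)
    if ctrl:
        ctrl_mean = nm.values[sorted(ctrl), :].mean(axis=0)
    else:  # every bin-mate is itself a signature gene
        ctrl_mean = np.zeros_like(sig_mean)
    return pd.Series(sig_mean - ctrl_mean, index=nm.barcodes, name="score",
                     dtype=float)


def assign_cell_cycle(s_score: float, g2m_score: float) -> str:
    """Phase call from the two cycle scores: G1 when both are non-positive,
    else the larger score's phase; exact ties break toward S."""
    if not (np.isfinite(s_score) and np.isfinite(g2m_score)):
        raise ValidationError("cycle scores must be finite")
    if s_score <= 0 and g2m_score <= 0:
        return "G1"
    return "S" if s_score >= g2m_score else "G2M"


def cell_cycle_phases(nm: NormalizedMatrix, s_genes, g2m_genes,
                      seed: int = 0) -> pd.DataFrame:
    """Per-cell S/G2M scores and phase calls."""
    s = score_signature(nm, s_genes, seed=seed)
    g2m = score_signature(nm, g2m_genes, seed=seed + 1)
    phase = [assign_cell_cycle(a, b) for a, b in zip(s, g2m)]
    return pd.DataFrame({"s_score": s, "g2m_score": g2m, "phase": phase},
                        index=pd.Index(nm.barcodes, name="barcode"))


# ---------------------------------------------------------------------------
# Cluster annotation
# ---------------------------------------------------------------------------

def annotate_clusters(clusters: pd.Series, nm: NormalizedMatrix,
                      panel: dict[str, list[str]],
                      hybrid_labels: dict[str, tuple[str, str]] | None = None,
                      margin: float = 0.25, seed: int = 0,
                      ) -> tuple[pd.Series, pd.DataFrame]:
    """Label each cluster by its best-scoring marker program.

    Each cluster takes the panel type with the highest mean module score.
    When ``hybrid_labels`` declares a hybrid (e.g. a population co-expressing
    two lineages' programs) and a cluster's top two types are exactly that
    hybrid's parents with the runner-up within ``margin`` of the best
    (relative), the hybrid label is assigned instead.  Clusters whose scores
    are all non-positive are labelled ``"unassigned"``.  Returns the per-cell
    labels and a per-cluster report with scores and the ambiguity margin.
    """
    if not panel:
        raise ValidationError("marker panel is empty")
    scores = pd.DataFrame(
        {t: score_signature(nm, genes, seed=seed) for t, genes in panel.items()},
        index=nm.barcodes,
    )
    cl = clusters.reindex(nm.barcodes)
    cluster_means = scores.groupby(cl.to_numpy()).mean()
    rows = []
    label_of_cluster: dict[str, str] = {}
    for cluster_id, row in cluster_means.iterrows():
        ranked = row.sort_values(ascending=False)
        top, second = ranked.index[0], (ranked.index[1] if len(ranked) > 1 else None)
        rel_margin = (
            float((ranked.iloc[0] - ranked.iloc[1]) / abs(ranked.iloc[0]))
            if second is not None and ranked.iloc[0] != 0 else np.inf
        )
        label = top
        if (row <= 0).all():
            label = "unassigned"
        elif hybrid_labels and second is not None and rel_margin <= margin:
            for hyb, parents in hybrid_labels.items():
                if {top, second} == set(parents):
                    label = hyb
                    break
        label_of_cluster[str(cluster_id)] = label
        rows.append({"cluster": str(cluster_id), "label": label,
                     "top_type": top, "second_type": second,
                     "ambiguity_margin": rel_margin,
                     **{f"score_{t}": row[t] for t in panel}})
    labels = cl.astype(str).map(label_of_cluster)
    labels.name = "cell_type"
    return labels, pd.DataFrame(rows).set_index("cluster")


# ---------------------------------------------------------------------------
# Signature derivation
# ---------------------------------------------------------------------------

@dataclass
class SignatureSet:
    """Per-type one-vs-each marker signatures plus the pairwise evidence."""

    up: dict[str, list[str]] = field(default_factory=dict)
    evidence: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"cell_type": t, "gene": g}
                for t, genes in self.up.items() for g in genes]
        return pd.DataFrame(rows, columns=["cell_type", "gene"])


def _pairwise_tests(nm: NormalizedMatrix, cells_a, cells_b,
                    pseudocount: float = 0.01,
                    lin: np.ndarray | None = None) -> pd.DataFrame:
    """Per-gene fold (A over B, de-logged normalized means) plus Wilcoxon p
    and BH-adjusted p for one pairwise comparison."""
    if lin is None:
        lin = nm.linear()
    ia, ib = nm.cell_index(cells_a), nm.cell_index(cells_b)
    xa, xb = lin[:, ia], lin[:, ib]
    fold = fold_change(xa.mean(axis=1), xb.mean(axis=1), pseudocount)
    p = wilcoxon_vector(xa, xb)
    return pd.DataFrame({"fold": fold, "p": p, "padj": bh_adjust(p)},
                        index=pd.Index(nm.gene_ids, name="gene"))


def derive_type_signatures(nm: NormalizedMatrix, labels: pd.Series,
                           min_fc: float = 1.25, alpha: float = 0.05,
                           min_cells: int = 3,
                           pseudocount: float = 0.01) -> SignatureSet:
    """One-vs-each signatures: a gene enters type T's signature only if its
    fold over *every* other type strictly exceeds ``min_fc`` with adjusted
    p < ``alpha`` in each pairwise test."""
    lab = labels.reindex(nm.barcodes)
    counts = lab.value_counts()
    types = [t for t in counts.index if counts[t] >= min_cells]
    dropped = [t for t in counts.index if counts[t] < min_cells]
    if dropped:
        log.warning("excluding types with < %d cells: %s", min_cells, dropped)
    if len(types) < 2:
        raise ValidationError("need at least two types with enough cells")
    cells_of = {t: nm.barcodes[(lab == t).to_numpy()] for t in types}
    lin = nm.linear()
    sig = SignatureSet()
    for t in types:
        keep = np.ones(len(nm.gene_ids), dtype=bool)
        for other in types:
            if other == t:
                continue
            ev = _pairwise_tests(nm, cells_of[t], cells_of[other], pseudocount,
                                 lin=lin)
            sig.evidence[(t, other)] = ev
            keep &= (ev["fold"].to_numpy() > min_fc) & \
                (ev["padj"].to_numpy() < alpha)
        sig.up[t] = [g for g, k in zip(nm.gene_ids, keep) if k]
    # one-vs-each conjunction makes signatures disjoint by construction
    flat = [g for genes in sig.up.values() for g in genes]
    assert len(flat) == len(set(flat)), "signatures overlap across types"
    return sig


def derive_hybrid_signature(nm: NormalizedMatrix, labels: pd.Series,
                            hybrid: str = "hs-av",
                            parents: tuple[str, str] = ("hs", "av"),
                            min_fc: float = 1.25, alpha: float = 0.05,
                            restrict=None, pseudocount: float = 0.01,
                            ) -> tuple[list[str], list[str]]:
    """Genes at least ``min_fc``-fold higher (or lower) in the hybrid than in
    *both* parents, with adjusted p < ``alpha`` in both pairwise tests and
    agreeing direction.  ``restrict`` optionally limits the comparison to a
    subset of barcodes (e.g. young cells only).  Returns ``(up, down)``."""
    lab = labels.reindex(nm.barcodes)
    keep_cells = np.ones(len(nm.barcodes), dtype=bool)
    if restrict is not None:
        allowed = set(restrict)
        keep_cells = np.array([b in allowed for b in nm.barcodes])
    for name in (hybrid, *parents):
        if not ((lab == name).to_numpy() & keep_cells).any():
            raise ValidationError(f"label {name!r} missing from comparison cells")
    hyb_cells = nm.barcodes[(lab == hybrid).to_numpy() & keep_cells]
    up = np.ones(len(nm.gene_ids), dtype=bool)
    down = np.ones(len(nm.gene_ids), dtype=bool)
    lin = nm.linear()
    for parent in parents:
        par_cells = nm.barcodes[(lab == parent).to_numpy() & keep_cells]
        ev = _pairwise_tests(nm, hyb_cells, par_cells, pseudocount, lin=lin)
        signif = ev["padj"].to_numpy() < alpha
        up &= (ev["fold"].to_numpy() >= min_fc) & signif
        down &= (ev["fold"].to_numpy() <= 1.0 / min_fc) & signif
    genes = nm.gene_ids
    return ([g for g, k in zip(genes, up) if k],
            [g for g, k in zip(genes, down) if k])


def derive_pairwise_markers(nm: NormalizedMatrix, labels: pd.Series,
                            type_a: str, type_b: str, min_fc: float = 2.0,
                            alpha: float = 0.05,
                            pseudocount: float = 0.01) -> pd.DataFrame:
    """Markers separating two populations: |fold| at least ``min_fc`` with
    adjusted p < ``alpha``, signed by direction."""
    lab = labels.reindex(nm.barcodes)
    for name in (type_a, type_b):
        if not (lab == name).any():
            raise ValidationError(f"label {name!r} missing")
    ev = _pairwise_tests(nm, nm.barcodes[(lab == type_a).to_numpy()],
                         nm.barcodes[(lab == type_b).to_numpy()], pseudocount)
    hit = ((ev["fold"] >= min_fc) | (ev["fold"] <= 1.0 / min_fc)) & \
        (ev["padj"] < alpha)
    out = ev[hit].copy()
    out["direction"] = np.where(out["fold"] > 1.0, f"up_in_{type_a}",
                                f"up_in_{type_b}")
    return out.sort_values("padj")
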