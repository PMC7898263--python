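"""Young-vs-aged consensus differential expression.

The procedure declares a gene differentially expressed only when three
criteria agree:

(i)  grouped criterion — at least 1.5-fold difference between pooled young
     and pooled aged cells with a Benjamini-Hochberg adjusted p < 0.05,
     required separately for a Wilcoxon rank-sum engine and a
     zero-inflation-weighted negative-binomial (ZINB) engine;
(ii) per-sample criterion — at least 1.25-fold in the same direction in
     every young-sample x aged-sample pairwise comparison (12 pairs for
     3 young and 4 aged animals);
(iii) cross-method criterion — the final list is the intersection of the
     engines' grouped calls with the per-sample calls.

Fold changes are ratios of de-logged normalized group means with a small
pseudocount; genes must be detected in at least 10% of cells of either age
group to enter a comparison.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .io import AGED, YOUNG, CountMatrix, DEConfig, SampleMeta, ValidationError, age_of_samples
from .qc import filter_detected_genes

log = logging.getLogger("mammaging")

UP = "up_in_aged"
DOWN = "down_in_aged"

_EXACT_MAX_N = 12


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test
# ---------------------------------------------------------------------------

def _rank_sum_stats(ranks: np.ndarray, n_a: int):
    """Rank-sum W of the first group plus its null mean/variance with the
    tie-corrected normal approximation."""
    n = ranks.size
    n_b = n - n_a
    w = ranks[:n_a].sum()
    mean_w = n_a * (n + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts ** 3 - counts).sum()
    var_w = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    return w, mean_w, var_w


def wilcoxon_test(x_a, x_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with midranks.

    Exact enumeration of all rank assignments for combined n <= 12 (valid
    under ties); otherwise the normal approximation with tie-corrected
    variance and a 0.5 continuity correction.  Returns ``(U, p)``.  A
    comparison with zero overall variance yields p = 1.
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if x_a.size == 0 or x_b.size == 0:
        raise ValidationError("both groups must be non-empty")
    n_a, n = x_a.size, x_a.size + x_b.size
    ranks = stats.rankdata(np.concatenate([x_a, x_b]))
    w, mean_w, var_w = _rank_sum_stats(ranks, n_a)
    u = w - n_a * (n_a + 1) / 2.0
    if var_w <= 0:
        return float(u), 1.0
    if n <= _EXACT_MAX_N:
        obs_dev = abs(w - mean_w)
        hits = total = 0
        for comb in itertools.combinations(range(n), n_a):
            total += 1
            if abs(ranks[list(comb)].sum() - mean_w) >= obs_dev - 1e-12:
                hits += 1
        return float(u), hits / total
    z = (abs(w - mean_w) - 0.5) / math.sqrt(var_w)
    return float(u), float(min(1.0, 2.0 * stats.norm.sf(z)))


def wilcoxon_vector(x_a: np.ndarray, x_b: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p-values for ``(genes x cells)`` blocks.

    Uses the tie-corrected normal approximation (intended for the grouped
    comparison where both groups are large).
    """
    n_a = x_a.shape[1]
    z_all = np.concatenate([x_a, x_b], axis=1)
    n = z_all.shape[1]
    n_b = n - n_a
    ranks = stats.rankdata(z_all, axis=1)
    w = ranks[:, :n_a].sum(axis=1)
    mean_w = n_a * (n + 1) / 2.0
    tie_term = np.empty(z_all.shape[0])
    for i in range(z_all.shape[0]):
        _, counts = np.unique(z_all[i], return_counts=True)
        tie_term[i] = (counts.astype(float) ** 3 - counts).sum()
    var_w = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    p = np.ones(z_all.shape[0])
    ok = var_w > 0
    z = (np.abs(w[ok] - mean_w) - 0.5) / np.sqrt(var_w[ok])
    p[ok] = np.minimum(1.0, 2.0 * stats.norm.sf(z))
    return p


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1.

    NaN entries propagate as NaN and do not count toward the family size.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Fold changes
# ---------------------------------------------------------------------------

def fold_change(mean_a, mean_b, pseudocount: float = 0.01):
    """Ratio of group means of normalized expression with a pseudocount
    guarding zero denominators: ``(mean_a + c) / (mean_b + c)``."""
    return (np.asarray(mean_a, dtype=float) + pseudocount) / \
        (np.asarray(mean_b, dtype=float) + pseudocount)


# ---------------------------------------------------------------------------
# ZINB engine
# ---------------------------------------------------------------------------

@dataclass
class ZinbFit:
    """Per-gene zero-inflated NB fit: mixture pi * delta_0 + (1 - pi) *
    NB(mu, phi) with variance mu + phi * mu**2 and posterior weights
    w = P(count drawn from the NB component)."""

    pi_hat: np.ndarray                 # (G,)
    mu_hat: dict[str, np.ndarray]      # group -> (G,) NB mean coefficients
    phi_hat: np.ndarray                # (G,)
    weights: np.ndarray                # (G, N)
    size_factors: np.ndarray           # (N,)
    group_of_cell: np.ndarray          # (N,) labels
    n_iter: int = 0


def _nb_log_zero(mu: np.ndarray, phi) -> np.ndarray:
    """log P(Y = 0) for NB(mu, phi); Poisson limit below phi = 1e-8."""
    phi = np.asarray(phi, dtype=float)
    mu = np.maximum(mu, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            phi > 1e-8,
            -np.log1p(phi * mu) / np.maximum(phi, 1e-300),
            -mu,
        )
    return out


def nb_logpmf(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """NB log-pmf in (mean, dispersion) parameterization; Poisson limit for
    phi below 1e-8."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-12)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mu.shape)
    small = phi <= 1e-8
    r = 1.0 / np.where(small, 1.0, phi)
    nb = (gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
          + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu)))
    poisson = y * np.log(mu) - mu - gammaln(y + 1.0)
    return np.where(small, poisson, nb)


def fit_zinb_weights(counts: np.ndarray, libsize: np.ndarray, groups,
                     max_iter: int = 100, tol: float = 1e-6) -> ZinbFit:
    """EM fit of the per-gene ZINB mixture with library-size offsets.

    ``counts`` is a dense ``(genes x cells)`` integer array, ``libsize`` the
    per-cell totals (over all genes) and ``groups`` a per-cell two-level
    label vector.  The NB mean of cell ``c`` in group ``g`` is ``s_c *
    beta_g`` with size factor ``s_c`` proportional to library size.  The
    E-step computes posterior NB-membership weights (exactly 1 wherever the
    count is positive); the M-step updates ``pi`` from the structural-zero
    mass, the group means by weighted averages, and a per-gene dispersion by
    a weighted method of moments floored at 1e-8.  Each gene iterates until
    its largest (relative, for scale parameters) update drops below ``tol``
    or ``max_iter`` is reached; genes converge independently.
    """
    y = np.asarray(counts, dtype=float)
    if y.ndim != 2:
        raise ValidationError("counts must be genes x cells")
    if (y.sum(axis=1) == 0).any():
        raise ValidationError("all-zero gene passed to ZINB fit; "
                              "apply the detection filter first")
    groups = np.asarray(groups)
    levels = list(dict.fromkeys(groups))
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 groups, got {levels}")
    n_genes, n_cells = y.shape
    s = np.asarray(libsize, dtype=float)
    s = s / s.mean()
    col_of_cell = np.where(groups == levels[0], 0, 1)

    # Weights are exactly 1 at positive counts, so every nonzero-entry
    # contribution to the M-step is a constant; per-iteration work touches
    # only the zero entries.
    zr, zc = np.nonzero(y == 0)          # flat zero entries
    z_gene, z_s = zr, s[zc]
    z_key = zr * 2 + col_of_cell[zc]     # (gene, group) aggregation key
    nzr, nzc = np.nonzero(y != 0)
    nz_key = nzr * 2 + col_of_cell[nzc]
    nz_y, nz_s = y[nzr, nzc], s[nzc]
    size = 2 * n_genes

    def agg(key, vals):
        return np.bincount(key, weights=vals, minlength=size).reshape(n_genes, 2)

    sum_y = agg(nz_key, nz_y)            # per gene x group constants
    sum_y2 = agg(nz_key, nz_y ** 2)
    sum_sy = agg(nz_key, nz_s * nz_y)
    sum_s_nz = agg(nz_key, nz_s)
    sum_s2_nz = agg(nz_key, nz_s ** 2)
    sum_s_all = agg(z_key, z_s) + sum_s_nz

    beta = (sum_y + 0.1) / np.maximum(sum_s_all, 1e-300)
    phi = np.full(n_genes, 0.5)
    pi = 0.5 * np.bincount(zr, minlength=n_genes) / n_cells

    w_z = np.ones(zr.size)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step at the zero entries: posterior of the NB component
        mu_z = beta[z_gene, col_of_cell[zc]] * z_s
        p0 = np.exp(np.clip(_nb_log_zero(mu_z, phi[z_gene]), -700, 0))
        pi_z = pi[z_gene]
        w_z = (1.0 - pi_z) * p0 / np.maximum(pi_z + (1.0 - pi_z) * p0, 1e-300)
        # M-step from sufficient statistics
        pi_new = np.bincount(z_gene, weights=1.0 - w_z,
                             minlength=n_genes) / n_cells
        ws_z = agg(z_key, w_z * z_s)
        ws2_z = agg(z_key, w_z * z_s ** 2)
        beta_new = sum_y / np.maximum(sum_s_nz + ws_z, 1e-300)
        # weighted method of moments: sum w ((y - mu)^2 - mu) / sum w mu^2
        s2 = sum_s2_nz + ws2_z
        num = (sum_y2 - 2.0 * beta_new * sum_sy + beta_new ** 2 * s2
               - beta_new * (sum_s_nz + ws_z)).sum(axis=1)
        den = (beta_new ** 2 * s2).sum(axis=1)
        phi_new = np.maximum(num / np.maximum(den, 1e-8), 1e-8)

        delta = max(
            np.abs(pi_new - pi).max(initial=0.0),
            (np.abs(beta_new - beta).max(axis=1)
             / (np.abs(beta).max(axis=1) + 1.0)).max(initial=0.0),
            (np.abs(phi_new - phi) / (phi + 1.0)).max(initial=0.0),
        )
        pi, beta, phi = pi_new, beta_new, phi_new
        if delta < tol:
            break

    w = np.ones_like(y)
    w[zr, zc] = w_z

    return ZinbFit(
        pi_hat=pi,
        mu_hat={g: beta[:, j] for j, g in enumerate(levels)},
        phi_hat=phi,
        weights=w,
        size_factors=s,
        group_of_cell=groups,
        n_iter=n_iter,
    )


def _irls_nb_mean(y: np.ndarray, w: np.ndarray, s: np.ndarray,
                  phi: np.ndarray, max_iter: int = 50,
                  tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Weighted NB maximum-likelihood mean coefficient per gene.

    Fisher-scoring (IRLS) for ``mu_c = s_c * beta`` with fixed per-gene
    dispersion, observation weights ``w``.  Returns ``(beta, converged)``.
    """
    beta = (w * y).sum(axis=1) / np.maximum((w * s[None, :]).sum(axis=1),
                                            1e-300)
    beta = np.maximum(beta, 1e-12)
    converged = np.zeros(beta.shape, dtype=bool)
    for _ in range(max_iter):
        mu = beta[:, None] * s[None, :]
        denom = 1.0 + phi[:, None] * mu
        score = (w * s[None, :] * (y - mu) / np.maximum(mu * denom, 1e-300)
                 ).sum(axis=1)
        info = (w * s[None, :] / np.maximum(beta[:, None] * denom, 1e-300)
                ).sum(axis=1)
        step = score / np.maximum(info, 1e-300)
        beta_new = beta + step
        # half-step toward zero when scoring overshoots the positive domain
        beta_new = np.where(beta_new <= 0, beta / 2.0, beta_new)
        converged = np.abs(beta_new - beta) <= tol * (np.abs(beta) + 1e-12)
        beta = beta_new
        if converged.all():
            break
    return beta, converged


def zinb_nb_lrt(fit: ZinbFit, counts: np.ndarray) -> np.ndarray:
    """Weighted NB likelihood-ratio p-values for a group-mean difference.

    Observations are weighted by the posterior NB-membership weights from
    the EM fit, so structural zeros contribute (almost) nothing.  Group
    means (one per group under the alternative, one common under the null)
    are re-fitted as weighted NB maximum-likelihood estimates by Fisher
    scoring (IRLS), with the per-gene dispersion profiled under the
    alternative and shared by both models.  The statistic is scaled by the
    per-gene effective sample-size fraction (mean weight) and referred to
    chi-square with 1 degree of freedom.  A gene whose IRLS fails to
    converge within 50 iterations reports NaN.
    """
    y = np.asarray(counts, dtype=float)
    w = fit.weights
    s = fit.size_factors
    groups = fit.group_of_cell
    levels = list(fit.mu_hat)
    phi = fit.phi_hat
    mu_alt = np.empty_like(y)
    ok = np.ones(y.shape[0], dtype=bool)
    for g in levels:
        cols = np.flatnonzero(groups == g)
        beta_g, conv = _irls_nb_mean(y[:, cols], w[:, cols], s[cols], phi)
        ok &= conv
        mu_alt[:, cols] = beta_g[:, None] * s[cols][None, :]
    beta_null, conv = _irls_nb_mean(y, w, s, phi)
    ok &= conv
    mu_null = beta_null[:, None] * s[None, :]
    ll_alt = (w * nb_logpmf(y, mu_alt, phi[:, None])).sum(axis=1)
    ll_null = (w * nb_logpmf(y, mu_null, phi[:, None])).sum(axis=1)
    lrt = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    # effective-sample-size adjustment: with estimated membership weights
    # the information in the data is sum(w), not n, so the statistic is
    # scaled by the per-gene mean weight before the chi-square reference
    # (exactly 1 when no zero inflation is detected)
    lrt *= w.mean(axis=1)
    p = stats.chi2.sf(lrt, df=1)
    if not ok.all():
        log.warning("IRLS failed to converge for %d genes; p set to NaN",
                    int((~ok).sum()))
        p[~ok] = np.nan
    return p


def nb_lrt(counts: np.ndarray, libsize: np.ndarray, groups) -> np.ndarray:
    """Plain (unweighted) NB likelihood-ratio test between two groups.

    The degenerate limit of the ZINB engine: with no zero inflation the EM
    weights are identically 1 and :func:`zinb_nb_lrt` collapses to this
    test.
    """
    y = np.asarray(counts, dtype=float)
    groups = np.asarray(groups)
    levels = list(dict.fromkeys(groups))
    s = np.asarray(libsize, dtype=float)
    s = s / s.mean()
    w = np.ones_like(y)
    beta = np.column_stack([
        y[:, groups == g].sum(axis=1) / s[groups == g].sum() for g in levels
    ])
    col_of_cell = np.where(groups == levels[0], 0, 1)
    mu = beta[:, col_of_cell] * s[None, :]
    phi = np.maximum(((y - mu) ** 2 - mu).sum(axis=1)
                     / np.maximum((mu ** 2).sum(axis=1), 1e-8), 1e-8)
    fit = ZinbFit(pi_hat=np.zeros(y.shape[0]),
                  mu_hat={g: beta[:, j] for j, g in enumerate(levels)},
                  phi_hat=phi, weights=w, size_factors=s,
                  group_of_cell=groups)
    return zinb_nb_lrt(fit, y)


def shrink_dispersion_trend(phi: np.ndarray, mean_expr: np.ndarray,
                            weight: float = 0.5) -> np.ndarray:
    """Shrink per-gene dispersions halfway toward a loess trend on the mean.

    Off by default in the consensus pipeline; per-gene method-of-moments
    dispersions are noisy, and shrinking toward a mean-dispersion trend
    (as edgeR-style pipelines do with empirical Bayes) trades bias for
    variance.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    x = np.log(np.maximum(mean_expr, 1e-8))
    z = np.log(np.maximum(phi, 1e-8))
    fitted = lowess(z, x, frac=0.5, return_sorted=False)
    return np.exp((1.0 - weight) * z + weight * fitted)


# ---------------------------------------------------------------------------
# Criteria
# ---------------------------------------------------------------------------

def grouped_criterion(fold: float, padj: float, cfg: DEConfig) -> bool:
    """Criterion (i): at least ``fc_grouped_min``-fold in either direction
    (inclusive) and adjusted p strictly below ``alpha_adj``."""
    if np.isnan(padj):
        return False
    fc = cfg.fc_grouped_min
    return bool((fold >= fc or fold <= 1.0 / fc) and padj < cfg.alpha_adj)


def per_sample_criterion(folds, cfg: DEConfig) -> bool:
    """Criterion (ii): every young-vs-aged per-sample fold at least
    ``fc_persample_min`` in the same direction; a missing entry fails."""
    f = np.asarray(folds, dtype=float).ravel()
    if f.size == 0 or np.isnan(f).any():
        return False
    fc = cfg.fc_persample_min
    return bool((f >= fc).all() or (f <= 1.0 / fc).all())


# ---------------------------------------------------------------------------
# Consensus driver
# ---------------------------------------------------------------------------

def _normalized(counts: np.ndarray, libsize: np.ndarray,
                scale_factor: float) -> np.ndarray:
    """Linear normalized expression ``count * scale / cell_total``."""
    return counts * (scale_factor / np.maximum(libsize, 1.0))[None, :]


def consensus_de(m: CountMatrix, labels: pd.Series, meta: list[SampleMeta],
                 cell_type: str, cfg: DEConfig | None = None) -> pd.DataFrame:
    """Run the full three-criteria young-vs-aged comparison for one cell type.

    ``labels`` maps barcode -> cell-type label.  Returns one row per gene
    passing the detection filter, with fold changes (aged over young),
    per-engine p and BH-adjusted p (one BH family per engine within this
    comparison), the per-sample fold table, criterion flags, the consensus
    verdict and the direction of change.
    """
    if cfg is None:
        cfg = DEConfig()
    age_of = age_of_samples(meta)
    samples = m.samples
    in_type = np.array([labels.get(b) == cell_type for b in m.barcodes])
    age_of_cell = samples.map(age_of)
    young_cells = m.barcodes[in_type & (age_of_cell == YOUNG).to_numpy()]
    aged_cells = m.barcodes[in_type & (age_of_cell == AGED).to_numpy()]
    for group_name, cells in ((YOUNG, young_cells), (AGED, aged_cells)):
        if len(cells) == 0:
            raise ValidationError(
                f"cell type {cell_type!r} absent from the {group_name} group"
            )

    libsize_all = np.asarray(m.values.sum(axis=0)).ravel()
    lib_of = dict(zip(m.barcodes, libsize_all))

    genes = filter_detected_genes(m, young_cells, aged_cells,
                                  cfg.detect_frac_min)
    if not genes:
        log.warning("no genes pass the %.0f%% detection filter",
                    100 * cfg.detect_frac_min)
        return pd.DataFrame()
    sub = m.subset_cells(list(young_cells) + list(aged_cells)).subset_genes(genes)
    counts = sub.dense().astype(float)
    libsize = np.array([lib_of[b] for b in sub.barcodes])
    norm = _normalized(counts, libsize, cfg.scale_factor)
    n_young = len(young_cells)
    norm_y, norm_a = norm[:, :n_young], norm[:, n_young:]
    counts_y, counts_a = counts[:, :n_young], counts[:, n_young:]

    fold_grouped = fold_change(norm_a.mean(axis=1), norm_y.mean(axis=1),
                               cfg.fc_pseudocount)
    p_wilcoxon = wilcoxon_vector(norm_a, norm_y)
    padj_wilcoxon = bh_adjust(p_wilcoxon)

    groups = np.array([YOUNG] * n_young + [AGED] * len(aged_cells))
    fit = fit_zinb_weights(counts, libsize, groups)
    if cfg.shrink_dispersion_trend:
        fit.phi_hat = shrink_dispersion_trend(fit.phi_hat,
                                              counts.mean(axis=1))
    p_zinb = zinb_nb_lrt(fit, counts)
    padj_zinb = bh_adjust(p_zinb)

    # per-sample fold table: one column per young x aged sample pair
    young_ids = [s.sample_id for s in meta if s.age_group == YOUNG]
    aged_ids = [s.sample_id for s in meta if s.age_group == AGED]
    sample_of_col = np.array([m.sample_of_cell[b] for b in sub.barcodes])
    sample_means: dict[str, np.ndarray] = {}
    for sid in young_ids + aged_ids:
        cols = np.flatnonzero(sample_of_col == sid)
        if cols.size < cfg.min_cells_per_sample:
            log.warning("sample %s has %d %s cells (< %d); per-sample "
                        "criterion will fail", sid, cols.size, cell_type,
                        cfg.min_cells_per_sample)
            sample_means[sid] = np.full(len(genes), np.nan)
        else:
            sample_means[sid] = norm[:, cols].mean(axis=1)
    ps_folds = {}
    for sy in young_ids:
        for sa in aged_ids:
            ps_folds[f"psfold_{sy}_{sa}"] = fold_change(
                sample_means[sa], sample_means[sy], cfg.fc_pseudocount)
    ps_block = np.column_stack(list(ps_folds.values()))

    fc = cfg.fc_persample_min
    with np.errstate(invalid="ignore"):
        ps_up = np.all(ps_block >= fc, axis=1) & ~np.isnan(ps_block).any(axis=1)
        ps_down = np.all(ps_block <= 1.0 / fc, axis=1) & \
            ~np.isnan(ps_block).any(axis=1)
    pass_per_sample = ps_up | ps_down

    gw = (fold_grouped >= cfg.fc_grouped_min) | \
        (fold_grouped <= 1.0 / cfg.fc_grouped_min)
    pass_w = gw & (padj_wilcoxon < cfg.alpha_adj)
    pass_z = gw & (padj_zinb < cfg.alpha_adj)
    direction = np.where(fold_grouped > 1.0, UP, DOWN)
    dir_consistent = np.where(ps_up, direction == UP,
                              np.where(ps_down, direction == DOWN, False))
    consensus = pass_w & pass_z & pass_per_sample & dir_consistent

    out = pd.DataFrame({
        "fold_grouped": fold_grouped,
        "p_wilcoxon": p_wilcoxon,
        "padj_wilcoxon": padj_wilcoxon,
        "p_zinb": p_zinb,
        "padj_zinb": padj_zinb,
        **ps_folds,
        "pass_grouped_wilcoxon": pass_w,
        "pass_grouped_zinb": pass_z,
        "pass_per_sample": pass_per_sample,
        "consensus": consensus,
        "direction": direction,
    }, index=pd.Index(genes, name="gene"))
    # structural invariant: consensus within the engines' intersection
    assert not (out.consensus & ~(out.pass_grouped_wilcoxon
                                  & out.pass_grouped_zinb)).any()
    return out


def de_summary(result: pd.DataFrame) -> dict[str, int]:
    """Counts of consensus genes up and down in aged."""
    hits = result[result.consensus] if len(result) else result
    return {
        "n_up_in_aged": int((hits.direction == UP).sum()) if len(hits) else 0,
        "n_down_in_aged": int((hits.direction == DOWN).sum()) if len(hits) else 0,
    }
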