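"""Cell-type composition by age group and its statistical comparison.

Each cell type is tested with a 2x2 table of (this type vs all other types
in the compartment) x (young vs aged), pooling cells across samples within
an age group, using Fisher's exact test and the Pearson chi-square test.
Because proportions within a compartment sum to one, an expansion of one
type necessarily depresses the apparent proportions of the others
(compositional closure); replicate-aware multivariate tests are
deliberately out of scope.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import AGED, YOUNG, SampleMeta, ValidationError, age_of_samples

log = logging.getLogger("mammaging")


def fisher_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on ``[[a, b], [c, d]]``.

    The two-sided p sums hypergeometric tables (margins fixed) whose point
    probability does not exceed the observed table's.  The odds ratio is
    ``ad / bc`` with 0/inf conventions; a zero margin gives p = 1 and an
    undefined (NaN) odds ratio.
    """
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    if (table < 0).any():
        raise ValidationError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), 1.0
    res = stats.fisher_exact(table, alternative="two-sided")
    ad, bc = float(a) * d, float(b) * c
    if bc == 0:
        odds = float("inf") if ad > 0 else float("nan")
    else:
        odds = ad / bc
    return odds, float(res.pvalue)


def chisq_2x2(a: int, b: int, c: int, d: int,
              correction: bool = False) -> float:
    """Pearson chi-square p-value (1 df) for ``[[a, b], [c, d]]``; no
    continuity correction by default.  A zero expected count yields NaN."""
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    if (table < 0).any():
        raise ValidationError("counts must be non-negative")
    n = table.sum()
    if n == 0:
        log.warning("empty table: chi-square undefined")
        return float("nan")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if (expected == 0).any():
        log.warning("zero expected count: chi-square undefined")
        return float("nan")
    stat = ((table - expected) ** 2 / expected).sum()
    return float(stats.chi2.sf(stat, df=1))


def composition_table(labels: pd.Series, meta: list[SampleMeta],
                      sample_of_cell: dict[str, str],
                      compartment=None) -> pd.DataFrame:
    """Counts, within-compartment proportions and per-type tests by age.

    ``labels`` maps barcode -> cell type; ``compartment`` optionally
    restricts to a subset of types (e.g. the epithelial lineages), within
    which proportions are renormalized.  Fold change is the aged-over-young
    proportion ratio; the odds ratio is oriented the same way (> 1 means
    expanded with age).
    """
    age_of = age_of_samples(meta)
    age_of_cell = pd.Series(
        {b: age_of[sample_of_cell[b]] for b in labels.index}, dtype=object)
    df = pd.DataFrame({"cell_type": labels, "age": age_of_cell}).dropna()
    if compartment is not None:
        compartment = list(compartment)
        present = set(df.cell_type)
        missing = [t for t in compartment if t not in present]
        if len(missing) == len(compartment):
            raise ValidationError(f"no compartment type present: {compartment}")
        df = df[df.cell_type.isin(compartment)]
    if df.empty:
        raise ValidationError("no cells in the requested compartment")

    counts = (df.groupby(["cell_type", "age"]).size()
                .unstack("age", fill_value=0)
                .reindex(columns=[YOUNG, AGED], fill_value=0))
    if compartment is not None:
        counts = counts.reindex(compartment, fill_value=0)
    totals = counts.sum(axis=0)
    props = counts / totals.replace(0, np.nan)

    rows = []
    for t in counts.index:
        ny, na = int(counts.loc[t, YOUNG]), int(counts.loc[t, AGED])
        oy, oa = int(totals[YOUNG] - ny), int(totals[AGED] - na)
        odds, fisher_p = fisher_2x2(na, oa, ny, oy)
        chi_p = chisq_2x2(na, oa, ny, oy)
        py, pa = props.loc[t, YOUNG], props.loc[t, AGED]
        fold = pa / py if py > 0 else float("inf") if pa > 0 else float("nan")
        rows.append({
            "cell_type": t, "n_young": ny, "n_aged": na,
            "prop_young": py, "prop_aged": pa,
            "fold_change": fold,
            "direction": "increase" if fold > 1 else
                         "decrease" if fold < 1 else "unchanged",
            "odds_ratio": odds, "fisher_p": fisher_p, "chisq_p": chi_p,
        })
    return pd.DataFrame(rows).set_index("cell_type")


def proportion_fold(table: pd.DataFrame, cell_type: str) -> tuple[float, str]:
    """Proportion ratio reported in the direction of change.

    Returns ``(ratio >= 1, direction)``; a type absent at young age with
    aged cells present reports an infinite increase.
    """
    if cell_type not in table.index:
        raise ValidationError(f"type {cell_type!r} not in table")
    py = table.loc[cell_type, "prop_young"]
    pa = table.loc[cell_type, "prop_aged"]
    if py == 0 and pa == 0:
        return float("nan"), "unchanged"
    if py == 0:
        return float("inf"), "increase"
    if pa == 0:
        return float("inf"), "decrease"
    ratio = pa / py
    if ratio >= 1:
        return float(ratio), "increase" if ratio > 1 else "unchanged"
    return float(py / pa), "decrease"
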