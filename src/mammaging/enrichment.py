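"""Over-representation analysis (ORA) of DE gene lists against curated
gene-set collections, with homolog mapping and BH FDR control.

Each gene set is tested with the upper-tail hypergeometric probability of
the observed overlap given the universe (by default, the genes that passed
the detection filter in the originating comparison), followed by BH
adjustment across the collection.  Sets with FDR < 0.05 are reported,
ranked by p, up to a configurable top-N.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust
from .io import GeneSetCollection, ValidationError

log = logging.getLogger("mammaging")


def map_homologs(genes, mapping: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Translate gene symbols through a two-column homolog table.

    ``mapping`` has the source symbols in the first column and targets in
    the second (many-to-one allowed).  Returns the deduplicated mapped list
    (input order preserved) and the list of unmapped genes; unmapped genes
    are reported, never silently dropped.
    """
    if mapping is None or len(mapping) == 0:
        raise ValidationError("empty homolog mapping")
    src, dst = mapping.columns[0], mapping.columns[1]
    lut = dict(zip(mapping[src].astype(str), mapping[dst].astype(str)))
    mapped: list[str] = []
    seen = set()
    unmapped: list[str] = []
    for g in genes:
        h = lut.get(str(g))
        if h is None:
            unmapped.append(g)
        elif h not in seen:
            seen.add(h)
            mapped.append(h)
        else:
            log.info("homolog %s already mapped (many-to-one collapse)", h)
    if unmapped:
        log.warning("%d genes had no homolog (e.g. %s)", len(unmapped),
                    unmapped[:3])
    return mapped, unmapped


def ora_hypergeom(de_list, universe, collection: GeneSetCollection,
                  alpha_fdr: float = 0.05, top_n: int = 30,
                  min_set_size: int = 3,
                  return_all: bool = False) -> pd.DataFrame:
    """Hypergeometric over-representation of ``de_list`` in each gene set.

    For a universe of size N, a set of size K (after intersection with the
    universe) and a list of size n, the p-value is P(X >= overlap) with
    X ~ Hypergeom(N, K, n).  BH adjustment runs across the collection.
    By default only sets with FDR < ``alpha_fdr`` are returned, ranked by
    p and truncated at ``top_n``; ``return_all`` disables the filter.
    """
    universe = list(dict.fromkeys(universe))
    uni = set(universe)
    de = list(dict.fromkeys(de_list))
    outside = [g for g in de if g not in uni]
    if outside:
        log.warning("%d DE genes outside the universe dropped (e.g. %s)",
                    len(outside), outside[:3])
    de = [g for g in de if g in uni]
    if not de:
        log.warning("empty DE list: no enrichment computed")
        return pd.DataFrame(columns=["set_name", "overlap", "set_size",
                                     "list_size", "universe_size", "p", "fdr",
                                     "genes"]).set_index("set_name")
    n_uni, n_list = len(uni), len(de)
    de_set = set(de)
    rows = []
    for name, genes in collection.sets.items():
        members = [g for g in genes if g in uni]
        if len(members) < min_set_size:
            log.info("skipping %s: only %d genes in universe", name,
                     len(members))
            continue
        hit = sorted(de_set & set(members))
        k = len(hit)
        p = float(stats.hypergeom.sf(k - 1, n_uni, len(members), n_list))
        rows.append({"set_name": name, "overlap": k, "set_size": len(members),
                     "list_size": n_list, "universe_size": n_uni,
                     "p": min(p, 1.0), "genes": ",".join(hit)})
    out = pd.DataFrame(rows)
    if out.empty:
        return out.set_index(pd.Index([], name="set_name")) \
            if "set_name" not in out else out
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out = out.sort_values(["p", "set_name"]).set_index("set_name")
    out = out[["overlap", "set_size", "list_size", "universe_size",
               "p", "fdr", "genes"]]
    if return_all:
        return out
    return out[out["fdr"] < alpha_fdr].head(top_n)
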