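"""Synthetic two-age-group mammary atlas generator with ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: two age groups (3 young, 4 aged animals), cell types defined by
multiplicative marker programs (including one rare hybrid type expressing
both parents' programs at reduced amplitude), zero-inflated negative
binomial counts with lognormal library sizes, per-sample random effects,
planted age-dependent proportion shifts, and planted per-cell-type
age-differential genes at stated fold changes.

Counts are drawn as ``ZINB(mu, phi, pi)``: with probability ``pi`` the
observation is a structural zero, otherwise NB with mean ``mu`` and
variance ``mu + phi * mu**2`` (gamma-Poisson mixture).  ``phi -> 0``
degenerates to Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import AGED, YOUNG, CountMatrix, SampleMeta, ValidationError

_N_MITO = 10


@dataclass
class CellTypeSpec:
    """One simulated cell type: its abundance, markers and planted age effects.

    ``marker_genes`` are expressed ``marker_fold`` times above baseline in
    this type.  ``age_de`` maps gene -> log2 fold change applied to aged
    cells of this type (positive = up in aged).  ``hybrid_of`` names two
    parent types whose marker programs this type co-expresses at
    ``hybrid_level`` of the parents' amplitude.
    """

    name: str
    prop_young: float
    prop_aged: float
    marker_genes: list[str] = field(default_factory=list)
    marker_fold: float = 8.0
    age_de: dict[str, float] = field(default_factory=dict)
    hybrid_of: tuple[str, str] | None = None
    hybrid_level: float = 0.6

    def __post_init__(self) -> None:
        for g, lfc in self.age_de.items():
            if lfc == 0:
                raise ValidationError(f"planted DE gene {g!r} has log2FC = 0")


@dataclass
class SimConfig:
    """Full specification of a simulated atlas."""

    cell_types: list[CellTypeSpec]
    n_samples_young: int = 3
    n_samples_aged: int = 4
    cells_per_sample: tuple[int, int] = (1200, 2800)
    n_genes: int = 2000
    libsize_lognormal: tuple[float, float] = (8.5, 0.35)
    nb_dispersion: float = 0.4
    zero_inflation_pi: float = 0.1
    doublet_rate: float = 0.0
    sample_effect_sd: float = 0.1
    mito_fraction: float = 0.05
    mito_cell_sd: float = 0.5
    baseline_gamma_shape: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for age, attr in ((YOUNG, "prop_young"), (AGED, "prop_aged")):
            total = sum(getattr(t, attr) for t in self.cell_types)
            if abs(total - 1.0) > 1e-8:
                raise ValidationError(
                    f"{age} proportions sum to {total!r}, not 1"
                )
        for rate in (self.zero_inflation_pi, self.doublet_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValidationError("rates must lie in [0, 1]")
        names = [t.name for t in self.cell_types]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate cell type names")
        # marker programs may overlap only through a declared hybrid
        by_name = {t.name: t for t in self.cell_types}
        for t in self.cell_types:
            if t.hybrid_of is not None:
                for parent in t.hybrid_of:
                    if parent not in by_name:
                        raise ValidationError(
                            f"hybrid {t.name!r} names unknown parent {parent!r}"
                        )
        for i, a in enumerate(self.cell_types):
            for b in self.cell_types[i + 1:]:
                overlap = set(a.marker_genes) & set(b.marker_genes)
                if overlap:
                    raise ValidationError(
                        f"marker overlap between {a.name!r} and {b.name!r}: "
                        f"{sorted(overlap)[:3]}"
                    )


@dataclass
class SimTruth:
    """Ground truth of one simulated atlas."""

    type_of_cell: pd.Series                      # barcode -> cell type
    planted_de: dict[tuple[str, str], float]     # (type, gene) -> log2FC
    planted_props: pd.DataFrame                  # type x {young, aged}
    doublet_flags: pd.Series                     # barcode -> bool


def truth_de_table(truth: SimTruth, cell_type: str) -> pd.DataFrame:
    """Planted age-DE genes for one cell type, with signed log2FC.

    Raises ``KeyError`` for an unknown type; an empty table means the type
    exists but has no planted DE genes.
    """
    if cell_type not in truth.planted_props.index:
        raise KeyError(f"unknown cell type {cell_type!r}")
    rows = [
        {"gene": g, "log2fc": lfc,
         "direction": "up_in_aged" if lfc > 0 else "down_in_aged"}
        for (t, g), lfc in truth.planted_de.items() if t == cell_type
    ]
    return pd.DataFrame(rows, columns=["gene", "log2fc", "direction"])


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _gene_universe(cfg: SimConfig) -> np.ndarray:
    """Order: declared marker / DE genes, mito genes, then filler."""
    special: list[str] = []
    seen = set()
    for t in cfg.cell_types:
        for g in list(t.marker_genes) + list(t.age_de):
            if g not in seen:
                seen.add(g)
                special.append(g)
    mito = [f"mt-{i+1}" for i in range(_N_MITO)]
    n_fill = cfg.n_genes - len(special) - len(mito)
    if n_fill < 0:
        raise ValidationError("n_genes too small for declared marker/DE genes")
    filler = [f"g{i:04d}" for i in range(n_fill)]
    return np.asarray(special + mito + filler, dtype=object)


def _type_program(cfg: SimConfig, base: np.ndarray, gene_idx: dict[str, int],
                  spec: CellTypeSpec, age: str) -> np.ndarray:
    """Expected relative abundance per gene for one (type, age) stratum."""
    p = base.copy()
    by_name = {t.name: t for t in cfg.cell_types}
    if spec.hybrid_of is not None:
        for parent in spec.hybrid_of:
            pt = by_name[parent]
            fold = 1.0 + spec.hybrid_level * (pt.marker_fold - 1.0)
            for g in pt.marker_genes:
                p[gene_idx[g]] *= fold
    for g in spec.marker_genes:
        p[gene_idx[g]] *= spec.marker_fold
    if age == AGED:
        for g, lfc in spec.age_de.items():
            p[gene_idx[g]] *= 2.0 ** lfc
    return p


def _zinb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float,
               pi: float) -> np.ndarray:
    if phi > 1e-12:
        lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    else:
        lam = mu
    y = rng.poisson(lam)
    if pi > 0:
        y[rng.random(mu.shape) < pi] = 0
    return y


def simulate_atlas(cfg: SimConfig) -> tuple[CountMatrix, list[SampleMeta], SimTruth]:
    """Draw one atlas: counts, per-sample metadata and ground truth.

    Identical configuration and seed give bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_universe(cfg)
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    mito_rows = np.array([gene_idx[f"mt-{i+1}"] for i in range(_N_MITO)])

    # baseline relative abundance; mito genes fixed to their share of mass.
    # Declared marker / planted-DE genes are floored at the median baseline
    # so planted effects sit at detectable expression: the recovery
    # benchmark should measure the testing procedure, not the detection
    # floor.
    base = rng.gamma(cfg.baseline_gamma_shape, 1.0, size=n_genes)
    special: set[str] = set()
    for t in cfg.cell_types:
        special.update(t.marker_genes)
        special.update(t.age_de)
    if special:
        floor = float(np.median(base))
        rows = np.array([gene_idx[g] for g in special])
        base[rows] = np.maximum(base[rows], floor)
    base[mito_rows] = 0.0
    base *= (1.0 - cfg.mito_fraction) / base.sum()
    base[mito_rows] = cfg.mito_fraction / _N_MITO

    meta = [SampleMeta(f"Y{i+1}", YOUNG) for i in range(cfg.n_samples_young)]
    meta += [SampleMeta(f"A{i+1}", AGED) for i in range(cfg.n_samples_aged)]

    # per-(type, age) expected programs
    programs = {
        (t.name, age): _type_program(cfg, base, gene_idx, t, age)
        for t in cfg.cell_types for age in (YOUNG, AGED)
    }
    props = {
        YOUNG: np.array([t.prop_young for t in cfg.cell_types]),
        AGED: np.array([t.prop_aged for t in cfg.cell_types]),
    }
    type_names = [t.name for t in cfg.cell_types]

    blocks: list[sp.csr_matrix] = []
    barcodes: list[str] = []
    sample_of_cell: dict[str, str] = {}
    type_of_cell: dict[str, str] = {}
    doublet_flags: dict[str, bool] = {}

    lo, hi = cfg.cells_per_sample
    for m in meta:
        n_cells = int(rng.integers(lo, hi + 1))
        m.n_cells_loaded = n_cells
        # per-sample x gene random effect (inter-animal variation)
        if cfg.sample_effect_sd > 0:
            sample_eff = rng.lognormal(0.0, cfg.sample_effect_sd, size=n_genes)
        else:
            sample_eff = np.ones(n_genes)
        types = rng.choice(len(type_names), size=n_cells, p=props[m.age_group])
        libsize = rng.lognormal(*cfg.libsize_lognormal, size=n_cells)
        mito_mult = rng.lognormal(0.0, cfg.mito_cell_sd, size=n_cells)

        counts = np.zeros((n_genes, n_cells), dtype=np.int64)
        for k, tname in enumerate(type_names):
            cols = np.flatnonzero(types == k)
            if cols.size == 0:
                continue
            q = programs[(tname, m.age_group)] * sample_eff
            mu = np.repeat(q[:, None], cols.size, axis=1)
            mu[mito_rows, :] *= mito_mult[cols]
            mu *= libsize[cols] / mu.sum(axis=0)
            counts[:, cols] = _zinb_draw(rng, mu, cfg.nb_dispersion,
                                         cfg.zero_inflation_pi)
        sample_barcodes = [f"{m.sample_id}_c{i:05d}" for i in range(n_cells)]

        if cfg.doublet_rate > 0:
            n_doub = int(round(cfg.doublet_rate * n_cells))
            pairs = rng.integers(0, n_cells, size=(n_doub, 2))
            doub = counts[:, pairs[:, 0]] + counts[:, pairs[:, 1]]
            counts = np.hstack([counts, doub])
            for j in range(n_doub):
                b = f"{m.sample_id}_d{j:05d}"
                sample_barcodes.append(b)
                types = np.append(types, types[pairs[j, 0]])
                doublet_flags[b] = True

        for b, k in zip(sample_barcodes, types):
            sample_of_cell[b] = m.sample_id
            type_of_cell[b] = type_names[k]
            doublet_flags.setdefault(b, False)
        barcodes.extend(sample_barcodes)
        blocks.append(sp.csr_matrix(counts))

    matrix = CountMatrix(sp.hstack(blocks).tocsr(), genes,
                         np.asarray(barcodes, dtype=object), sample_of_cell)
    planted_de = {
        (t.name, g): lfc for t in cfg.cell_types for g, lfc in t.age_de.items()
    }
    planted_props = pd.DataFrame(
        {YOUNG: props[YOUNG], AGED: props[AGED]}, index=type_names
    )
    truth = SimTruth(
        type_of_cell=pd.Series(type_of_cell, name="cell_type"),
        planted_de=planted_de,
        planted_props=planted_props,
        doublet_flags=pd.Series(doublet_flags, name="is_doublet"),
    )
    return matrix, meta, truth


# ---------------------------------------------------------------------------
# Canonical configurations
# ---------------------------------------------------------------------------

def _named_markers(canonical: list[str], prefix: str, n: int) -> list[str]:
    fill = [f"mk_{prefix}_{i:02d}" for i in range(n - len(canonical))]
    return canonical + fill


def _planted_de(prefix: str, n_up: int = 15, n_down: int = 15,
                lfc: float = 1.0) -> dict[str, float]:
    de = {f"de_{prefix}_u{i:02d}": lfc for i in range(n_up)}
    de.update({f"de_{prefix}_d{i:02d}": -lfc for i in range(n_down)})
    return de


def recovery_config(seed: int = 0) -> SimConfig:
    """Default recovery atlas: 3 young / 4 aged samples, four cell types,
    ~300 cells per type per sample, 30 planted age-DE genes per type at
    |log2FC| = 1, and planted proportion shifts."""
    cell_types = [
        CellTypeSpec("myoepithelial", 0.35, 0.20,
                     _named_markers(["Krt14", "Krt5", "Krt17", "Acta2", "Myl9"],
                                    "myo", 20),
                     age_de=_planted_de("myo")),
        CellTypeSpec("hs", 0.25, 0.10,
                     _named_markers(["Prlr", "Pgr", "Esr1", "Cited1", "Prom1"],
                                    "hs", 20),
                     age_de=_planted_de("hs")),
        CellTypeSpec("av", 0.25, 0.45,
                     _named_markers(["Mfge8", "Trf", "Csn3", "Wfdc18", "Ltf"],
                                    "av", 20),
                     age_de=_planted_de("av")),
        CellTypeSpec("fibroblast", 0.15, 0.25,
                     _named_markers(["Col1a1", "Col1a2", "Col3a1", "Fn1", "Pdgfra"],
                                    "fib", 20),
                     age_de=_planted_de("fib")),
    ]
    return SimConfig(cell_types=cell_types, cells_per_sample=(1200, 1200),
                     seed=seed)


def null_config(seed: int = 0, n_genes: int = 300,
                cells_per_sample: int = 100) -> SimConfig:
    """Calibration atlas: one cell type, no planted DE, no proportion shift
    and no per-sample effects, so pooled two-group tests face their own iid
    null."""
    cell_types = [CellTypeSpec("epithelium", 1.0, 1.0)]
    return SimConfig(cell_types=cell_types, n_genes=n_genes,
                     cells_per_sample=(cells_per_sample, cells_per_sample),
                     sample_effect_sd=0.0, seed=seed)


def hybrid_config(seed: int = 0) -> SimConfig:
    """Three luminal types including the rare hybrid co-expressing both
    parents' programs plus a private signature of its own."""
    hs_markers = _named_markers(["Prlr", "Pgr", "Esr1", "Cited1", "Prom1"], "hs", 20)
    av_markers = _named_markers(["Mfge8", "Trf", "Csn3", "Wfdc18", "Ltf"], "av", 20)
    hyb_markers = _named_markers(["Sox9", "Kit", "Aldh1a3"], "hsav", 20)
    cell_types = [
        CellTypeSpec("hs", 0.45, 0.50, hs_markers),
        CellTypeSpec("av", 0.44, 0.49, av_markers),
        CellTypeSpec("hs-av", 0.11, 0.01, hyb_markers, marker_fold=4.0,
                     hybrid_of=("hs", "av")),
    ]
    return SimConfig(cell_types=cell_types, cells_per_sample=(800, 800),
                     n_genes=1000, seed=seed)


def study_config(seed: int = 0) -> SimConfig:
    """Atlas emulating the study design: 13 cell types across epithelial,
    stromal and immune compartments, 1,200-2,800 cells per sample, and the
    reported compositional shifts (epithelium 45% -> 82% of all cells; within
    the epithelium, alveolar cells 26% -> 69% and hormone-sensing 53% -> 9%)."""
    epi = {YOUNG: 0.45, AGED: 0.82}
    # within-compartment proportions (young, aged)
    within_epi = {
        "myoepithelial": (0.10, 0.217), "hs": (0.53, 0.09),
        "av": (0.26, 0.69), "hs-av": (0.11, 0.003),
    }
    within_stroma = {
        "fibroblast": (0.52, 0.17), "vascular_endothelial": (0.28, 0.56),
        "pericyte": (0.07, 0.10), "lymphatic_endothelial": (0.008, 0.008),
        "dendritic": (0.054, 0.027), "macrophage_Ma": (0.036, 0.001),
        "macrophage_Mb": (0.012, 0.045), "nk": (0.005, 0.011),
        "t_cell": (0.015, 0.078),
    }
    markers = {
        "myoepithelial": ["Krt17", "Krt14", "Krt5", "Acta2", "Myl9", "Mylk"],
        "hs": ["Prlr", "Pgr", "Esr1", "Cited1", "Prom1"],
        "av": ["Mfge8", "Trf", "Csn3", "Wfdc18", "Ltf", "Elf5"],
        "hs-av": ["Sox9", "Kit", "Aldh1a3"],
        "fibroblast": ["Col1a1", "Col1a2", "Col3a1", "Fn1", "Pdgfra"],
        "vascular_endothelial": ["Pecam1", "Cdh5", "Sox17", "Sele"],
        "pericyte": ["Rgs5", "Des", "Notch3"],
        "lymphatic_endothelial": ["Mmrn1", "Prox1", "Flt4", "Ccl21a"],
        "dendritic": ["Napsa", "Traf1", "Cd209a", "Flt3"],
        "macrophage_Ma": ["Mrc1", "Cd209f", "Cd163"],
        "macrophage_Mb": ["Mmp12", "Mmp13", "Spic"],
        "nk": ["Gzma", "Ncr1", "Itgae"],
        "t_cell": ["Cd3d", "Cd3e", "Cd8a"],
    }
    cell_types = []
    for name, (py, pa) in within_epi.items():
        cell_types.append(CellTypeSpec(
            name, py * epi[YOUNG], pa * epi[AGED],
            _named_markers(markers[name], name.replace("-", ""), 15),
            hybrid_of=("hs", "av") if name == "hs-av" else None,
            age_de=_planted_de(name.replace("-", ""), 10, 10)
            if name in ("myoepithelial", "av", "hs") else {},
        ))
    for name, (py, pa) in within_stroma.items():
        cell_types.append(CellTypeSpec(
            name, py * (1 - epi[YOUNG]), pa * (1 - epi[AGED]),
            _named_markers(markers[name], name, 15),
        ))
    # force exact closure against float rounding
    for age_attr in ("prop_young", "prop_aged"):
        total = sum(getattr(t, age_attr) for t in cell_types)
        for t in cell_types:
            setattr(t, age_attr, getattr(t, age_attr) / total)
    return SimConfig(cell_types=cell_types, n_genes=2000, seed=seed)
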