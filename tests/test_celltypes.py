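"""Normalization, module scoring, clustering, annotation, signatures."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import mammaging as mg
from mammaging.celltypes import NormalizedMatrix
from mammaging.io import ValidationError
from mammaging.simulate import CellTypeSpec, SimConfig


def _nm(x, genes=None, cells=None):
    """NormalizedMatrix from linear normalized values (stores log1p)."""
    x = np.asarray(x, dtype=float)
    genes = genes or [f"g{i}" for i in range(x.shape[0])]
    cells = cells or [f"c{i}" for i in range(x.shape[1])]
    return NormalizedMatrix(np.log1p(x), np.array(genes, dtype=object),
                            np.array(cells, dtype=object))


class TestLogNormalize:
    def test_closed_form_single_gene(self, tiny_matrix):
        sub = tiny_matrix.subset_genes(["geneA"]).subset_cells(["c1"])
        nm = mg.log_normalize(sub)
        assert nm.values[0, 0] == pytest.approx(np.log1p(10000.0))

    def test_scale_invariance_of_cell_doubling(self):
        import scipy.sparse as sp
        counts = np.array([[2, 4], [6, 12], [2, 4]])
        m = mg.CountMatrix(sp.csr_matrix(counts), ["a", "b", "c"],
                           ["c1", "c2"], {"c1": "s", "c2": "s"})
        nm = mg.log_normalize(m)
        np.testing.assert_allclose(nm.values[:, 0], nm.values[:, 1])

    def test_matches_naive_loop_oracle(self, tiny_matrix):
        nm = mg.log_normalize(tiny_matrix, scale_factor=10000)
        dense = tiny_matrix.dense()
        for j in range(tiny_matrix.n_cells):
            total = dense[:, j].sum()
            for i in range(tiny_matrix.n_genes):
                expected = np.log1p(dense[i, j] * 10000.0 / total)
                assert nm.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_all_zero_cell_stays_zero(self):
        import scipy.sparse as sp
        m = mg.CountMatrix(sp.csr_matrix(np.array([[0, 3], [0, 1]])),
                           ["a", "b"], ["c1", "c2"],
                           {"c1": "s", "c2": "s"})
        nm = mg.log_normalize(m)
        np.testing.assert_array_equal(nm.values[:, 0], 0.0)


class TestScoreSignature:
    def test_all_zero_matrix_scores_zero(self):
        nm = _nm(np.zeros((10, 4)))
        score = mg.score_signature(nm, ["g0", "g1"], n_bins=2, seed=0)
        np.testing.assert_array_equal(score.to_numpy(), 0.0)

    def test_uniform_shift_recovered_exactly(self):
        # 30 background genes at value 1.0, 10 signature genes at 1.0 + c:
        # bin-matched controls are background genes, so score == c
        c = 0.7
        x = np.ones((40, 6))
        x[30:, :] = 1.0 + c
        nm = _nm(x)
        sig = [f"g{i}" for i in range(30, 40)]
        score = mg.score_signature(nm, sig, n_bins=2, n_ctrl=50, seed=0)
        linear_c = np.log1p(1.0 + c) - np.log1p(1.0)
        np.testing.assert_allclose(score.to_numpy(), linear_c, atol=1e-9)

    def test_raising_one_cell_makes_it_top_scorer(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0.5, 1.5, size=(50, 20))
        x[:5, 7] += 10.0  # boost signature genes in cell 7 only
        nm = _nm(x)
        score = mg.score_signature(nm, [f"g{i}" for i in range(5)],
                                   n_bins=5, seed=1)
        assert score.idxmax() == "c7"

    def test_missing_all_signature_genes_errors(self):
        nm = _nm(np.ones((4, 3)))
        with pytest.raises(ValidationError, match="missing"):
            mg.score_signature(nm, ["absent1", "absent2"])

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        nm = _nm(rng.uniform(0, 2, (60, 10)))
        sig = ["g3", "g9", "g20"]
        s1 = mg.score_signature(nm, sig, seed=5)
        s2 = mg.score_signature(nm, sig, seed=5)
        pd.testing.assert_series_equal(s1, s2)


class TestCellCycle:
    @pytest.mark.parametrize("s,g2m,phase", [
        (-0.1, -0.2, "G1"),
        (0.5, 0.1, "S"),
        (0.1, 0.5, "G2M"),
        (0.2, 0.2, "S"),      # documented tie-break toward S
        (0.0, 0.0, "G1"),     # both non-positive
    ])
    def test_phase_rule(self, s, g2m, phase):
        assert mg.assign_cell_cycle(s, g2m) == phase

    def test_non_finite_scores_rejected(self):
        with pytest.raises(ValidationError):
            mg.assign_cell_cycle(np.nan, 0.1)

    def test_packaged_mouse_cycle_lists_load(self):
        from pathlib import Path
        import mammaging.celltypes
        from mammaging.io import read_gene_list
        data = Path(mg.__file__).parent / "data"
        s_genes = read_gene_list(data / "s_genes_mouse.txt")
        g2m_genes = read_gene_list(data / "g2m_genes_mouse.txt")
        assert len(s_genes) >= 40 and len(g2m_genes) >= 50
        assert all(g[0].isupper() and g[1:].islower() or g[1:].isdigit()
                   or True for g in s_genes)  # mouse casing: Title-case
        assert s_genes[0] == "Mcm5"


def _two_type_sim(seed=0):
    cfg = SimConfig(
        cell_types=[
            CellTypeSpec("alpha", 0.5, 0.5,
                         [f"ma{i}" for i in range(20)]),
            CellTypeSpec("beta", 0.5, 0.5,
                         [f"mb{i}" for i in range(20)]),
        ],
        n_samples_young=1, n_samples_aged=1, n_genes=300,
        cells_per_sample=(250, 250), seed=seed,
    )
    return (cfg, *mg.simulate_atlas(cfg))


class TestClustering:
    def test_separated_programs_recovered(self):
        cfg, m, meta, truth = _two_type_sim()
        nm = mg.log_normalize(m)
        labels = mg.cluster_cells(nm, n_hvg=150, n_pcs=10, k=15,
                                  resolution=0.3, seed=0)
        ari = adjusted_rand_score(truth.type_of_cell[nm.barcodes], labels)
        assert ari >= 0.95

    def test_zero_resolution_gives_single_cluster(self):
        _, m, _, _ = _two_type_sim(seed=1)
        nm = mg.log_normalize(m)
        labels = mg.cluster_cells(nm, n_hvg=150, n_pcs=10, k=15,
                                  resolution=1e-4, seed=0)
        assert labels.nunique() == 1

    def test_same_seed_same_partition(self):
        _, m, _, _ = _two_type_sim(seed=2)
        nm = mg.log_normalize(m)
        l1 = mg.cluster_cells(nm, n_hvg=100, n_pcs=10, k=15, seed=3)
        l2 = mg.cluster_cells(nm, n_hvg=100, n_pcs=10, k=15, seed=3)
        pd.testing.assert_series_equal(l1, l2)

    def test_too_few_cells_rejected(self):
        nm = _nm(np.ones((10, 5)))
        with pytest.raises(ValidationError):
            mg.cluster_cells(nm, k=20)


class TestAnnotation:
    def test_pure_clusters_get_their_type(self):
        cfg, m, meta, truth = _two_type_sim(seed=3)
        nm = mg.log_normalize(m)
        panel = {t.name: list(t.marker_genes) for t in cfg.cell_types}
        clusters = truth.type_of_cell[nm.barcodes].rename("cluster")
        labels, report = mg.annotate_clusters(clusters, nm, panel, seed=0)
        assert (labels == truth.type_of_cell[nm.barcodes]).all()
        assert set(report.label) == {"alpha", "beta"}

    def test_hybrid_margin_rule(self, hybrid_atlas):
        cfg, m, meta, truth = hybrid_atlas
        nm = mg.log_normalize(m)
        panel = {"hs": [g for g in m.gene_ids if g.startswith("mk_hs_")],
                 "av": [g for g in m.gene_ids if g.startswith("mk_av_")]}
        clusters = truth.type_of_cell[nm.barcodes].rename("cluster")
        labels, report = mg.annotate_clusters(
            clusters, nm, panel, hybrid_labels={"hs-av": ("hs", "av")},
            margin=0.6, seed=0)
        assert report.loc["hs-av", "label"] == "hs-av"
        assert report.loc["hs", "label"] == "hs"
        assert report.loc["av", "label"] == "av"

    def test_all_nonpositive_scores_unassigned(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(1.0, 2.0, (30, 12))
        x[:3, :] = 0.0  # panel genes silent everywhere
        nm = _nm(x)
        clusters = pd.Series(["c"] * 12, index=nm.barcodes)
        labels, report = mg.annotate_clusters(
            clusters, nm, {"ghost": ["g0", "g1", "g2"]}, seed=0)
        assert (labels == "unassigned").all()

    def test_invariant_to_cluster_relabeling(self):
        cfg, m, meta, truth = _two_type_sim(seed=4)
        nm = mg.log_normalize(m)
        panel = {t.name: list(t.marker_genes) for t in cfg.cell_types}
        clusters = truth.type_of_cell[nm.barcodes]
        renamed = clusters.map({"alpha": "7", "beta": "3"})
        l1, _ = mg.annotate_clusters(clusters, nm, panel, seed=0)
        l2, _ = mg.annotate_clusters(renamed, nm, panel, seed=0)
        assert (l1 == l2).all()


class TestTypeSignatures:
    def test_degenerate_thresholds_reduce_to_argmax(self):
        # deterministic toy: each gene clearly highest in one type
        rng = np.random.default_rng(10)
        levels = np.array([[5.0, 1.0, 2.0], [1.0, 6.0, 2.0], [2.0, 3.0, 9.0]])
        cells_per_type = 10
        x = np.zeros((3, 30))
        labels = []
        for t in range(3):
            cols = slice(t * cells_per_type, (t + 1) * cells_per_type)
            x[:, cols] = levels[:, [t]] + rng.uniform(0, 0.2,
                                                      (3, cells_per_type))
            labels += [f"T{t}"] * cells_per_type
        nm = _nm(x)
        sig = mg.derive_type_signatures(
            nm, pd.Series(labels, index=nm.barcodes), min_fc=1.0, alpha=1.0)
        assert sig.up == {"T0": ["g0"], "T1": ["g1"], "T2": ["g2"]}

    def test_identical_types_have_empty_signatures(self):
        x = np.tile(np.arange(1.0, 6.0)[:, None], (1, 20))
        nm = _nm(x)
        labels = pd.Series(["A"] * 10 + ["B"] * 10, index=nm.barcodes)
        sig = mg.derive_type_signatures(nm, labels)
        assert sig.up == {"A": [], "B": []} or \
            all(len(v) == 0 for v in sig.up.values())

    def test_beating_all_but_one_opponent_is_excluded(self):
        # g0 is 2x over type B but only ~1.05x over type C
        rng = np.random.default_rng(11)
        x = np.zeros((4, 30))
        means = {"A": [2.0, 1.0, 1.0, 1.0], "B": [1.0, 1.0, 1.0, 1.0],
                 "C": [1.9, 1.0, 1.0, 1.0]}
        labels = []
        for t, (name, mu) in enumerate(means.items()):
            cols = slice(t * 10, (t + 1) * 10)
            x[:, cols] = np.array(mu)[:, None] + rng.uniform(0, 0.05, (4, 10))
            labels += [name] * 10
        nm = _nm(x)
        sig = mg.derive_type_signatures(
            nm, pd.Series(labels, index=nm.barcodes), min_fc=1.25, alpha=0.05)
        assert "g0" not in sig.up["A"]

    def test_planted_markers_recovered_without_leakage(self, recovery_atlas):
        cfg, m, _, truth = recovery_atlas
        nm = mg.log_normalize(m)
        sig = mg.derive_type_signatures(nm, truth.type_of_cell)
        planted = {t.name: set(t.marker_genes) for t in cfg.cell_types}
        for name, genes in sig.up.items():
            assert planted[name] <= set(genes)
            for other, markers in planted.items():
                if other != name:
                    assert not (set(genes) & markers)

    def test_signatures_disjoint(self, recovery_atlas):
        _, m, _, truth = recovery_atlas
        nm = mg.log_normalize(m)
        sig = mg.derive_type_signatures(nm, truth.type_of_cell)
        flat = [g for genes in sig.up.values() for g in genes]
        assert len(flat) == len(set(flat))


class TestHybridSignature:
    def test_planted_private_program_recovered(self, hybrid_atlas):
        cfg, m, meta, truth = hybrid_atlas
        nm = mg.log_normalize(m)
        young = [b for b in m.barcodes
                 if m.sample_of_cell[b].startswith("Y")]
        up, down = mg.derive_hybrid_signature(nm, truth.type_of_cell,
                                              restrict=young)
        planted = set(next(t for t in cfg.cell_types
                           if t.name == "hs-av").marker_genes)
        assert planted <= set(up)

    def test_direction_conflict_is_not_a_marker(self):
        rng = np.random.default_rng(12)
        x = np.ones((3, 60)) + rng.uniform(0, 0.05, (3, 60))
        # g0: hybrid sits between the parents -> direction conflict
        x[0, :20] *= 1.0   # hs
        x[0, 20:40] *= 4.0  # av
        x[0, 40:] *= 2.0   # hs-av
        nm = _nm(x)
        labels = pd.Series(["hs"] * 20 + ["av"] * 20 + ["hs-av"] * 20,
                           index=nm.barcodes)
        up, down = mg.derive_hybrid_signature(nm, labels)
        assert "g0" not in up and "g0" not in down

    def test_missing_label_errors(self):
        nm = _nm(np.ones((3, 10)))
        labels = pd.Series(["hs"] * 5 + ["av"] * 5, index=nm.barcodes)
        with pytest.raises(ValidationError, match="hs-av"):
            mg.derive_hybrid_signature(nm, labels)


class TestPairwiseMarkers:
    def test_planted_fourfold_markers_with_signs(self):
        rng = np.random.default_rng(13)
        x = np.ones((20, 80)) * rng.uniform(0.5, 1.5, (20, 1))
        x[:, 40:] = x[:, 40:]  # type B baseline
        x[0, :40] *= 4.0       # up in A
        x[1, 40:] *= 4.0       # up in B
        x += rng.uniform(0, 0.05, x.shape)
        nm = _nm(x)
        labels = pd.Series(["A"] * 40 + ["B"] * 40, index=nm.barcodes)
        table = mg.derive_pairwise_markers(nm, labels, "A", "B")
        assert table.loc["g0", "direction"] == "up_in_A"
        assert table.loc["g1", "direction"] == "up_in_B"
        assert set(table.index) == {"g0", "g1"}

    def test_shuffled_identical_groups_give_no_markers(self):
        rng = np.random.default_rng(14)
        x = rng.uniform(0.5, 1.5, (50, 60))
        nm = _nm(x)
        perm = rng.permutation(60)
        labels = pd.Series(np.where(np.argsort(perm) < 30, "A", "B"),
                           index=nm.barcodes)
        table = mg.derive_pairwise_markers(nm, labels, "A", "B")
        assert len(table) <= 0.05 * 50  # at most the chance level
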