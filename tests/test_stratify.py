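"""Tests for composition stratification, naming, projection and PCA."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score, silhouette_score

from ctap import (CELL_TYPES, CompositionMatrix, cluster_samples,
                  composition_pca, compute_composition, cytokine_categorize,
                  default_config, generate_cohort, mix_pseudobulk,
                  name_ctaps, project_samples)
from ctap.stratify import CTAPModel


def _corner_comp(n_per=1, counts_per=10_000):
    """Three samples sitting at three simplex corners."""
    counts = np.zeros((3 * n_per, 6), dtype=int)
    for i in range(3 * n_per):
        counts[i, i % 3] = counts_per
    ids = [f"s{i}" for i in range(3 * n_per)]
    return CompositionMatrix.from_counts(counts, ids)


class TestComputeComposition:
    def test_direct_count_ratio(self):
        cells = pd.DataFrame({
            "sample_id": ["s1"] * 4,
            "cell_type": ["T", "T", "NK", "myeloid"],
        })
        comp = compute_composition(cells)
        assert comp.cell_types == CELL_TYPES
        assert np.allclose(comp.proportions[0],
                           [0.5, 0.0, 0.25, 0.25, 0.0, 0.0])

    def test_single_type_indicator_row(self):
        cells = pd.DataFrame({"sample_id": ["s"] * 5,
                              "cell_type": ["stromal"] * 5})
        comp = compute_composition(cells)
        assert np.allclose(comp.proportions[0], [0, 0, 0, 0, 1, 0])

    def test_atlas_lineage_counts_pool(self):
        # printed per-lineage totals for the pooled atlas-scale pseudo-sample
        counts = {"T": 94_046, "B/plasma": 30_691, "NK": 8_495,
                  "myeloid": 76_181, "stromal": 79_555, "endothelial": 25_043}
        cells = pd.DataFrame({
            "sample_id": ["pool"] * 6,
            "cell_type": list(counts),
        })
        comp = compute_composition(cells)  # one cell each: shape check only
        row = np.array([counts[t] for t in CELL_TYPES], dtype=float)
        pooled = CompositionMatrix.from_counts(row[None, :], ["pool"])
        assert pooled.proportions.sum() == pytest.approx(1.0, abs=1e-9)
        assert pooled.proportions[0, 0] == pytest.approx(94_046 / 314_011)

    def test_unknown_type_rejected(self):
        cells = pd.DataFrame({"sample_id": ["s"], "cell_type": ["Fibroblast"]})
        with pytest.raises(ValueError, match="unknown cell types"):
            compute_composition(cells)

    def test_small_samples_excluded_with_warning(self):
        cells = pd.DataFrame({
            "sample_id": ["big"] * 10 + ["tiny"],
            "cell_type": ["T"] * 11,
        })
        with pytest.warns(UserWarning, match="tiny"):
            comp = compute_composition(cells, min_cells=5)
        assert comp.sample_ids == ["big"]


class TestClusterSamples:
    def test_three_corners_perfectly_stable(self):
        comp = _corner_comp(n_per=2)
        model = cluster_samples(comp, k_range=range(3, 4), n_boot=30,
                                min_size=2, seed=0)
        assert model.k == 3
        assert model.stability[3] == pytest.approx(1.0)
        corner = comp.proportions.argmax(axis=1)
        assert adjusted_rand_score(corner, model.labels) == 1.0

    def test_duplicate_rows_always_cocluster(self):
        rng = np.random.default_rng(0)
        base = rng.dirichlet(np.ones(6), size=5)
        counts = np.round(np.vstack([base, base]) * 10_000).astype(int) + 1
        comp = CompositionMatrix.from_counts(
            counts, [f"s{i}" for i in range(10)])
        for k in range(2, 5):
            model = cluster_samples(comp, k_range=range(k, k + 1), n_boot=5,
                                    min_size=1, seed=1)
            assert np.array_equal(model.labels[:5], model.labels[5:])

    def test_planted_six_phenotypes_recovered(self):
        cfg = default_config(n_samples=80, cells_per_sample=(2000, 2200),
                             n_genes=12, alpha=200.0, seed=21)
        cohort = generate_cohort(cfg)
        comp = compute_composition(cohort.cells)
        model = cluster_samples(comp, n_boot=60, seed=2)
        truth = cohort.truth.phenotype.loc[model.sample_ids]
        assert model.k == 6
        assert adjusted_rand_score(truth, model.labels) >= 0.9

    def test_row_order_invariance(self, preset_cohort):
        comp = compute_composition(preset_cohort.cells)
        rng = np.random.default_rng(3)
        perm = rng.permutation(comp.n_samples)
        shuffled = CompositionMatrix(
            comp.proportions[perm],
            [comp.sample_ids[i] for i in perm],
            comp.cell_types, counts=comp.counts[perm])
        a = cluster_samples(comp, n_boot=30, seed=5)
        b = cluster_samples(shuffled, n_boot=30, seed=5)
        aligned = pd.Series(b.labels, index=b.sample_ids).loc[a.sample_ids]
        assert a.k == b.k
        assert adjusted_rand_score(a.labels, aligned) == 1.0

    def test_stability_bounded(self, preset_cohort):
        comp = compute_composition(preset_cohort.cells)
        model = cluster_samples(comp, n_boot=20, seed=0)
        assert all(-1.0 <= v <= 1.0 for v in model.stability.values())

    def test_infeasible_k_range_rejected(self):
        comp = _corner_comp(n_per=2)  # 6 samples
        with pytest.raises(ValueError, match="infeasible"):
            cluster_samples(comp, k_range=range(4, 5), n_boot=5, min_size=3,
                            seed=0)

    def test_needs_counts_for_bootstrap(self):
        comp = CompositionMatrix(np.eye(3)[:, list(range(3)) + [0, 1, 2]]
                                 [:, :6] * 0 + np.eye(3, 6),
                                 ["a", "b", "c"])
        with pytest.raises(ValueError, match="cell counts"):
            cluster_samples(comp, k_range=range(2, 3), n_boot=5, min_size=1)

    def test_argmax_rule_available(self):
        comp = _corner_comp(n_per=2)
        model = cluster_samples(comp, k_range=range(2, 4), n_boot=20,
                                min_size=2, seed=0, k_tol=None)
        assert model.k in (2, 3)

    def test_force_k_override(self, preset_cohort):
        comp = compute_composition(preset_cohort.cells)
        model = cluster_samples(comp, n_boot=5, seed=0, force_k=4)
        assert model.k == 4


class TestWardOracle:
    """Scipy's Ward linkage must match a brute-force Lance-Williams update."""

    def test_matches_scipy_on_four_points(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(4, 3))
        Z = linkage(X, method="ward")

        # brute-force Lance-Williams on squared distances
        dist = {frozenset((i, j)): float(np.sum((X[i] - X[j]) ** 2))
                for i in range(4) for j in range(i + 1, 4)}
        sizes = {i: 1 for i in range(4)}
        merges = []
        next_id = 4
        while len(sizes) > 1:
            (i, j), sq = min(dist.items(),
                             key=lambda kv: (kv[1], sorted(kv[0])))
            i, j = sorted(i for i in (i, j))
            merges.append((i, j, np.sqrt(sq), sizes[i] + sizes[j]))
            n_i, n_j = sizes.pop(i), sizes.pop(j)
            new_sq = {}
            for k in sizes:
                n_k = sizes[k]
                d_ik = dist[frozenset((i, k))]
                d_jk = dist[frozenset((j, k))]
                new_sq[k] = ((n_i + n_k) * d_ik + (n_j + n_k) * d_jk
                             - n_k * sq) / (n_i + n_j + n_k)
            dist = {pair: v for pair, v in dist.items()
                    if i not in pair and j not in pair}
            for k, v in new_sq.items():
                dist[frozenset((next_id, k))] = v
            sizes[next_id] = n_i + n_j
            next_id += 1

        for row, (i, j, height, size) in zip(Z, merges):
            assert sorted(row[:2]) == sorted((i, j))
            assert row[2] == pytest.approx(height, abs=1e-12)
            assert row[3] == size


class TestNaming:
    def test_fallback_single_letter(self):
        rng = np.random.default_rng(1)
        props = rng.dirichlet(np.ones(6) * 50, size=12)
        comp = CompositionMatrix(props, [f"s{i}" for i in range(12)])
        model = CTAPModel(
            linkage=np.empty((0, 4)), stability={}, k=1,
            labels=np.ones(12, dtype=int), sample_ids=comp.sample_ids,
            centroids=props.mean(axis=0, keepdims=True),
            cell_types=CELL_TYPES)
        names = name_ctaps(model, comp)
        assert len(names) == 1 and len(names[0]) == 1
        assert names[0] in set("EFMTB")

    def test_ordering_by_decreasing_z(self):
        # cluster 1 high in T then B; clusters separated enough for z > 0.5
        rows = []
        for _ in range(6):
            rows.append([0.45, 0.30, 0.05, 0.10, 0.05, 0.05])
        for _ in range(6):
            rows.append([0.10, 0.10, 0.10, 0.30, 0.30, 0.10])
        comp = CompositionMatrix(np.array(rows),
                                 [f"s{i}" for i in range(12)])
        model = CTAPModel(
            linkage=np.empty((0, 4)), stability={}, k=2,
            labels=np.array([1] * 6 + [2] * 6),
            sample_ids=comp.sample_ids,
            centroids=np.array([rows[0], rows[6]]), cell_types=CELL_TYPES)
        names = name_ctaps(model, comp)
        assert names[0] == "TB"

    def test_preset_names_recovered(self, naming_cohort):
        comp = compute_composition(naming_cohort.cells)
        model = cluster_samples(comp, n_boot=40, seed=7)
        assert sorted(model.names) == sorted(
            ["EFM", "F", "TF", "TB", "TM", "M"])

    def test_zero_sd_type_skipped(self):
        rows = np.array([[0.5, 0.5, 0, 0, 0, 0],
                         [0.4, 0.6, 0, 0, 0, 0],
                         [0.6, 0.4, 0, 0, 0, 0]])
        comp = CompositionMatrix(rows, ["a", "b", "c"])
        model = CTAPModel(
            linkage=np.empty((0, 4)), stability={}, k=1,
            labels=np.ones(3, dtype=int), sample_ids=comp.sample_ids,
            centroids=rows.mean(axis=0, keepdims=True),
            cell_types=CELL_TYPES)
        with pytest.warns(UserWarning, match="zero cohort sd"):
            names = name_ctaps(model, comp)
        assert names[0] in {"T", "B"}


class TestProjection:
    def test_centroid_maps_to_itself(self, preset_cohort):
        comp = compute_composition(preset_cohort.cells)
        model = cluster_samples(comp, n_boot=20, seed=0)
        centro = CompositionMatrix(model.centroids,
                                   [f"c{i}" for i in range(model.k)])
        proj = project_samples(model, centro)
        assert np.array_equal(proj.labels, np.arange(1, model.k + 1))
        assert np.allclose(np.min(proj.distances, axis=1), 0.0)

    def test_tie_flagged_lowest_index(self):
        centroids = np.array([[1, 0, 0, 0, 0, 0.0],
                              [0, 1, 0, 0, 0, 0.0]])
        model = CTAPModel(
            linkage=np.empty((0, 4)), stability={}, k=2,
            labels=np.array([1, 2]), sample_ids=["a", "b"],
            centroids=centroids, cell_types=CELL_TYPES)
        mid = CompositionMatrix(np.array([[0.5, 0.5, 0, 0, 0, 0.0]]), ["m"])
        proj = project_samples(model, mid)
        assert proj.labels[0] == 1
        assert proj.ties[0]

    def test_column_mismatch_rejected(self, preset_cohort):
        comp = compute_composition(preset_cohort.cells)
        model = cluster_samples(comp, n_boot=10, seed=0)
        wrong = CompositionMatrix(comp.proportions[:, ::-1],
                                  comp.sample_ids, comp.cell_types[::-1])
        with pytest.raises(ValueError, match="mismatch"):
            project_samples(model, wrong)

    def test_heldout_assignment_accuracy(self):
        cfg = default_config(n_samples=120, cells_per_sample=(400, 600),
                             alpha=200.0, seed=17)
        cohort = generate_cohort(cfg)
        comp = compute_composition(cohort.cells)
        train = comp.subset(comp.sample_ids[:60])
        test = comp.subset(comp.sample_ids[60:])
        model = cluster_samples(train, n_boot=40, seed=1)
        if model.k != 6:
            pytest.skip("training stratification missed k=6")
        proj = project_samples(model, test)
        # map clusters to phenotypes via the training majority
        truth = cohort.truth.phenotype
        mapping = {}
        for c in range(1, 7):
            members = [s for s, lab in zip(model.sample_ids, model.labels)
                       if lab == c]
            mapping[c] = truth.loc[members].mode().iloc[0]
        pred = [mapping[lab] for lab in proj.labels]
        acc = np.mean(pred == truth.loc[test.sample_ids].to_numpy())
        assert acc >= 0.9

    def test_training_labels_reproduced(self, preset_cohort):
        comp = compute_composition(preset_cohort.cells)
        model = cluster_samples(comp, n_boot=20, seed=0)
        proj = project_samples(model, comp)
        assert np.mean(proj.labels == model.labels) >= 0.95


class TestCompositionPCA:
    def test_two_samples_single_component(self):
        comp = CompositionMatrix(
            np.array([[0.6, 0.4, 0, 0, 0, 0], [0.2, 0.8, 0, 0, 0, 0.0]]),
            ["a", "b"])
        pca = composition_pca(comp)
        assert pca.variance_fractions[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self, preset_cohort):
        comp = compute_composition(preset_cohort.cells)
        pca = composition_pca(comp)
        assert pca.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_scores_preserve_pairwise_distances(self, preset_cohort):
        comp = compute_composition(preset_cohort.cells)
        pca = composition_pca(comp)
        centred = comp.proportions - comp.proportions.mean(axis=0)
        assert np.allclose(pdist(pca.scores), pdist(centred), atol=1e-8)

    def test_ctap_separation_in_pc_space(self, naming_cohort):
        comp = compute_composition(naming_cohort.cells)
        model = cluster_samples(comp, n_boot=20, seed=0)
        pca = composition_pca(comp)
        sil = silhouette_score(pca.scores[:, :2], model.labels)
        assert sil > 0

    def test_single_sample_rejected(self):
        comp = CompositionMatrix(np.array([[1.0, 0, 0, 0, 0, 0]]), ["a"])
        with pytest.raises(ValueError, match="2 samples"):
            composition_pca(comp)


class TestCytokineCategorize:
    def test_identical_partition_gives_ari_one(self, preset_cohort):
        bulk = mix_pseudobulk(preset_cohort, 0.0)
        genes = [f"g{i:05d}" for i in range(100, 110)]
        labels, ari = cytokine_categorize(bulk, genes, k=3,
                                          ctap_labels=np.asarray([0] * 60))
        _, ari_self = cytokine_categorize(bulk, genes, k=3,
                                          ctap_labels=labels)
        assert ari_self == pytest.approx(1.0)

    def test_random_labels_ari_near_zero(self, preset_cohort):
        bulk = mix_pseudobulk(preset_cohort, 0.0)
        genes = [f"g{i:05d}" for i in range(100, 110)]
        rng = np.random.default_rng(0)
        aris = []
        for _ in range(50):
            labels, ari = cytokine_categorize(
                bulk, genes, k=4,
                ctap_labels=rng.integers(0, 4, bulk.shape[1]))
            aris.append(ari)
        assert abs(np.mean(aris)) < 0.05

    def test_cytokine_partition_beats_permuted_null(self, naming_cohort):
        cfg = naming_cohort.config
        bulk = mix_pseudobulk(naming_cohort, 0.0)
        genes = sorted({f"g{g:05d}" for v in cfg.cytokine_genes.values()
                        for g in v})
        truth = naming_cohort.truth.phenotype.loc[bulk.columns].to_numpy()
        _, ari = cytokine_categorize(bulk, genes, k=6, ctap_labels=truth)
        rng = np.random.default_rng(1)
        null = []
        for _ in range(100):
            _, a = cytokine_categorize(bulk, genes, k=6,
                                       ctap_labels=rng.permutation(truth))
            null.append(a)
        assert ari > np.quantile(null, 0.95)

    def test_too_few_genes_rejected(self, preset_cohort):
        bulk = mix_pseudobulk(preset_cohort, 0.0)
        with pytest.raises(ValueError, match="fewer than 2"):
            cytokine_categorize(bulk, ["nope"], k=2,
                                ctap_labels=np.zeros(bulk.shape[1]))
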