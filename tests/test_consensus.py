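"""Clustering, consensus matrices, ARI and cluster-number selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omicsfuse.consensus import (
    ConsensusResult,
    adjusted_rand_index,
    cdf_area,
    cdf_delta_area,
    consensus_labels,
    gmm_on_embedding,
    run_consensus,
    select_optimal_k,
    spectral_cluster,
    type_combinations,
)
from omicsfuse.containers import OmicsFuseError


def ari_pair_counting_oracle(l1, l2):
    """Brute-force ARI over all subject pairs (chance-corrected Rand)."""
    n = len(l1)
    ss = sd = ds = dd = 0
    for i, j in itertools.combinations(range(n), 2):
        same1, same2 = l1[i] == l1[j], l2[i] == l2[j]
        if same1 and same2:
            ss += 1
        elif same1:
            sd += 1
        elif same2:
            ds += 1
        else:
            dd += 1
    a, b = ss + sd, ss + ds
    total = ss + sd + ds + dd
    expected = a * b / total if total else 0.0
    max_index = (a + b) / 2
    if max_index == expected:
        return 1.0 if ss == max_index else 0.0
    return (ss - expected) / (max_index - expected)


class TestARI:
    def test_identical_labelings(self):
        assert adjusted_rand_index([1, 2, 2, 3], [5, 7, 7, 9]) == pytest.approx(1.0)

    def test_crossed_pairs_hand_value(self):
        assert adjusted_rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)

    @given(
        st.lists(st.integers(0, 3), min_size=2, max_size=8),
        st.data(),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_pair_counting_oracle(self, l1, data):
        l2 = data.draw(st.lists(st.integers(0, 3), min_size=len(l1), max_size=len(l1)))
        assert adjusted_rand_index(l1, l2) == pytest.approx(
            ari_pair_counting_oracle(l1, l2), abs=1e-12
        )
        assert adjusted_rand_index(l2, l1) == pytest.approx(
            adjusted_rand_index(l1, l2), abs=1e-12
        )

    def test_length_mismatch(self):
        with pytest.raises(OmicsFuseError):
            adjusted_rand_index([1, 2], [1, 2, 3])


def _two_clique_network(n_per=3):
    n = 2 * n_per
    w = np.zeros((n, n))
    w[:n_per, :n_per] = 1.0
    w[n_per:, n_per:] = 1.0
    np.fill_diagonal(w, 1.0)
    return pd.DataFrame(w, index=[f"s{i}" for i in range(n)], columns=[f"s{i}" for i in range(n)])


class TestClustering:
    def test_spectral_exact_on_disconnected_cliques(self):
        w = _two_clique_network()
        labels = spectral_cluster(w, 2, seed=0).labels
        assert labels.iloc[:3].nunique() == 1
        assert labels.iloc[3:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[5]

    def test_k_below_two_rejected(self):
        with pytest.raises(OmicsFuseError):
            spectral_cluster(_two_clique_network(), 1)
        with pytest.raises(OmicsFuseError):
            gmm_on_embedding(_two_clique_network(), 1)

    def test_more_components_than_k_rejected(self):
        w = np.zeros((9, 9))
        for s in (slice(0, 3), slice(3, 6), slice(6, 9)):
            w[s, s] = 1.0
        with pytest.raises(OmicsFuseError, match="components"):
            spectral_cluster(pd.DataFrame(w), 2, seed=0)

    def test_gmm_separated_blobs_and_determinism(self, rng):
        w = _two_clique_network(5)
        noise = rng.uniform(0, 0.05, size=w.shape)
        w = pd.DataFrame(
            w.to_numpy() + (noise + noise.T) / 2, index=w.index, columns=w.columns
        )
        a1 = gmm_on_embedding(w, 2, seed=3).labels
        a2 = gmm_on_embedding(w, 2, seed=3).labels
        pd.testing.assert_series_equal(a1, a2)
        assert adjusted_rand_index(a1, [0] * 5 + [1] * 5) == pytest.approx(1.0)

    def test_gmm_agrees_with_spectral_on_planted_clusters(self, small_dataset):
        from omicsfuse.affinity import block_affinity, snf_fuse

        ds, truth = small_dataset
        asthma = ds.asthmatic_subjects
        affs = [block_affinity(b.subset_subjects(asthma), K=8) for b in ds.blocks]
        fused = snf_fuse(affs, K=8)
        sp = spectral_cluster(fused, 5, seed=0).labels
        gm = gmm_on_embedding(fused, 5, seed=0).labels
        assert adjusted_rand_index(sp, gm) >= 0.8
        assert adjusted_rand_index(sp, truth.labels.loc[sp.index]) >= 0.9


class TestConsensus:
    def test_reproducible_and_valid_proportions(self, small_dataset):
        ds, _ = small_dataset
        kwargs = dict(
            dataset=ds, combo=("transcriptomics",), k_range=[2, 5], reps=5,
            subsample_fraction=0.8, method="spectral", seed=4, K=8,
        )
        r1 = run_consensus(**kwargs)
        r2 = run_consensus(**kwargs)
        for k in (2, 5):
            assert np.allclose(r1.consensus[k], r2.consensus[k])
            m = r1.consensus[k]
            assert ((m >= 0) & (m <= 1)).all()
            assert np.allclose(m, m.T)

    def test_within_consensus_exceeds_between_on_planted_structure(self, small_dataset):
        ds, truth = small_dataset
        result = run_consensus(
            ds, ("transcriptomics", "proteomics", "microbiome"), [5],
            reps=10, method="spectral", seed=0, K=8,
        )
        m = result.consensus[5]
        lab = truth.labels.loc[result.subjects].to_numpy()
        same = lab[:, None] == lab[None, :]
        off = ~np.eye(len(lab), dtype=bool)
        assert m[same & off].mean() > m[~same].mean()
        # near-noiseless planted structure: consensus concentrates at 0/1
        extreme = (m[off] < 0.2) | (m[off] > 0.8)
        assert extreme.mean() > 0.9

    def test_subsample_smaller_than_neighbourhood_rejected(self, small_dataset):
        ds, _ = small_dataset
        with pytest.raises(OmicsFuseError, match="smaller K"):
            run_consensus(
                ds, ("transcriptomics",), [2], reps=2,
                subsample_fraction=0.5, method="spectral", seed=0, K=20,
            )

    def test_more_reps_reduce_monte_carlo_variance(self, small_dataset):
        ds, _ = small_dataset
        def mk(reps, seed):
            return run_consensus(
                ds, ("transcriptomics",), [3], reps=reps,
                method="spectral", seed=seed, K=8,
            ).consensus[3]
        lo = [mk(4, s) for s in range(4)]
        hi = [mk(16, s) for s in range(4)]
        var_lo = np.var([m[np.triu_indices_from(m, 1)] for m in lo], axis=0).mean()
        var_hi = np.var([m[np.triu_indices_from(m, 1)] for m in hi], axis=0).mean()
        assert var_hi < var_lo


class TestCDF:
    @staticmethod
    def _result_from_matrix(m, k=2):
        n = m.shape[0]
        return ConsensusResult(
            subjects=pd.Index(range(n)), consensus={k: m, k + 1: m},
            cosample=np.ones((n, n)), labels={}, reps=2,
            subsample_fraction=0.8, method="spectral",
        )

    def test_all_ones_matrix_has_zero_area(self):
        m = np.ones((4, 4))
        assert cdf_area(m) == pytest.approx(0.0)

    def test_hand_integration(self):
        # 4 subjects, 6 upper-triangle values: {0, 0, 1, 1, 1, 1}
        m = np.ones((4, 4))
        m[0, 1] = m[1, 0] = 0.0
        m[2, 3] = m[3, 2] = 0.0
        # left-Riemann: CDF is 2/6 on [0, 1), jumps to 1 at 1 -> area 1/3
        assert cdf_area(m) == pytest.approx(2 / 6)
        # mixed values: {0, 0.5, 0.5, 1, 1, 1}: F=1/6 on [0,.5), 3/6 on [.5,1)
        m2 = np.ones((4, 4))
        m2[0, 1] = m2[1, 0] = 0.0
        m2[0, 2] = m2[2, 0] = 0.5
        m2[1, 2] = m2[2, 1] = 0.5
        assert cdf_area(m2) == pytest.approx(1 / 6 * 0.5 + 3 / 6 * 0.5)

    def test_delta_definition(self):
        m_low = np.eye(3)
        m_high = np.ones((3, 3))
        result = ConsensusResult(
            subjects=pd.Index(range(3)),
            consensus={2: m_low, 3: m_low, 4: m_high},
            cosample=np.ones((3, 3)), labels={}, reps=2,
            subsample_fraction=0.8, method="spectral",
        )
        _, areas, deltas = cdf_delta_area(result)
        assert deltas[2] == pytest.approx(areas[2])
        assert deltas[3] == pytest.approx(0.0)
        assert deltas[4] == pytest.approx((areas[4] - areas[3]) / areas[3])

    def test_single_k_rejected(self):
        result = self._result_from_matrix(np.ones((3, 3)))
        result.consensus = {2: np.ones((3, 3))}
        with pytest.raises(OmicsFuseError):
            cdf_delta_area(result)


class TestSelectK:
    def test_two_cluster_recovery_small(self):
        from omicsfuse.simulate import SimulationConfig, generate_dataset

        cfg = SimulationConfig(
            cluster_sizes=(12, 12), n_healthy=4, n_genes=80, n_somascan=50,
            n_shotgun=40, n_taxa_16s=40, n_taxa_meta=40,
            marker_genes_per_cluster=10, marker_proteins_per_cluster=8,
            quad_set_size=5, indicator_taxa_per_cluster=5, n_decoy_sets=5,
            rng_seed=2,
        )
        ds, truth = generate_dataset(cfg)
        report = select_optimal_k(ds, k_range=range(2, 5), reps=10, seed=0, K=8)
        assert report.chosen_k == 2
        assert adjusted_rand_index(
            report.final_labels, truth.labels.loc[report.final_labels.index]
        ) >= 0.9

    def test_empty_combo_list_rejected(self, small_dataset):
        ds, _ = small_dataset
        with pytest.raises(OmicsFuseError):
            select_optimal_k(ds, combos=[], reps=2, K=8)

    def test_seven_type_combinations(self):
        combos = type_combinations()
        assert len(combos) == 7
        assert ("transcriptomics", "proteomics", "microbiome") in combos

    def test_consensus_labels_recover_block_matrix(self):
        m = np.zeros((6, 6))
        m[:3, :3] = 1.0
        m[3:, 3:] = 1.0
        labels = consensus_labels(m, 2, pd.Index(range(6)))
        assert labels.iloc[:3].nunique() == 1 and labels.iloc[3:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[5]
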