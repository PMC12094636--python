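import numpy as np
import pytest
from scipy.stats import special_ortho_group

from msgradient.gradients import (
    align_gradients,
    build_affinity,
    diffusion_embedding,
    principal_gradient_table,
)
from msgradient.msnet import subject_ms_matrices

from ._oracles import affinity_brute, diffusion_dense_oracle


def _random_ms(n, rng, nonnegative=False):
    x = rng.standard_normal((n, 6))
    m = np.corrcoef(x)
    if nonnegative:
        m = np.abs(m)
    np.fill_diagonal(m, 0.0)
    return m


class TestAffinity:
    def test_identical_rows_have_affinity_one(self, rng):
        # rows 0 and 1 share an identical profile (zero mutual similarity,
        # same tail), so their angle is 0 and the kernel returns 1
        tail = rng.uniform(0.3, 0.9, 3)
        m = np.zeros((5, 5))
        m[0, 2:] = m[1, 2:] = tail
        m[2:, 0] = m[2:, 1] = tail
        m[2, 3] = m[3, 2] = 0.5
        m[3, 4] = m[4, 3] = 0.6
        m[2, 4] = m[4, 2] = 0.4
        aff = build_affinity(m, sparsity=0.0)
        assert aff[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_rows_give_half(self):
        # two blocks with disjoint support: cross-block rows are orthogonal
        block = np.array([[0.0, 0.9, 0.8], [0.9, 0.0, 0.7], [0.8, 0.7, 0.0]])
        m = np.zeros((6, 6))
        m[:3, :3] = block
        m[3:, 3:] = block
        aff = build_affinity(m, sparsity=0.0)
        assert aff[0, 3] == pytest.approx(0.5, abs=1e-12)
        assert aff[0, 1] > 0.5

    def test_matches_brute_force_arccos_oracle(self, rng):
        m = _random_ms(6, rng, nonnegative=True)
        aff = build_affinity(m, sparsity=0.5)
        brute = affinity_brute(m, sparsity=0.5)
        assert np.abs(aff - brute).max() < 1e-12

    def test_sparsity_leaves_enough_neighbors(self, rng):
        m = _random_ms(6, rng)
        with pytest.raises(ValueError, match="lower the sparsity"):
            build_affinity(m, sparsity=0.95)

    def test_entries_in_unit_interval(self, rng):
        aff = build_affinity(_random_ms(30, rng), sparsity=0.9)
        assert aff.min() >= 0 and aff.max() <= 1
        assert np.abs(aff - aff.T).max() == 0


class TestDiffusionEmbedding:
    def test_matches_dense_eigensolver_oracle(self, rng):
        aff = build_affinity(_random_ms(40, rng), sparsity=0.7)
        emb = diffusion_embedding(aff, n_components=6)
        comps, lam = diffusion_dense_oracle(aff, n_components=6)
        for j in range(6):
            a, b = emb.components[:, j], comps[:, j]
            sign = np.sign(a @ b)
            assert np.abs(a - sign * b).max() < 1e-8
        assert np.abs(emb.eigenvalues - np.maximum(lam, 0)).max() < 1e-10

    def test_block_structure_separated_by_sign(self, rng):
        n = 20
        w = np.full((n, n), 0.01)
        w[:10, :10] = 1.0
        w[10:, 10:] = 1.0
        np.fill_diagonal(w, 0.0)
        emb = diffusion_embedding(w, n_components=2)
        g1 = emb.components[:, 0]
        assert len(np.unique(np.sign(g1[:10]))) == 1
        assert np.sign(g1[0]) != np.sign(g1[-1])

    def test_ring_lattice_degenerate_pair(self):
        """A circulant ring affinity has a two-fold rotationally symmetric
        spectrum: the first two non-trivial eigenvalues coincide."""
        n = 24
        w = np.zeros((n, n))
        for i in range(n):
            for d in (1, 2):
                w[i, (i + d) % n] = w[i, (i - d) % n] = 1.0 / d
        emb = diffusion_embedding(w, n_components=4)
        assert abs(emb.eigenvalues[0] - emb.eigenvalues[1]) < 1e-9

    def test_disconnected_graph_rejected(self):
        w = np.zeros((6, 6))
        w[:3, :3] = 1.0
        w[3:, 3:] = 1.0
        np.fill_diagonal(w, 0.0)
        with pytest.raises(ValueError, match="disconnected.*\\[3, 3\\]"):
            diffusion_embedding(w, n_components=2)

    def test_asymmetric_and_negative_rejected(self, rng):
        w = np.abs(rng.standard_normal((5, 5)))
        with pytest.raises(ValueError, match="symmetric"):
            diffusion_embedding(w)
        w = (w + w.T) / 2
        w[0, 1] = w[1, 0] = -0.5
        with pytest.raises(ValueError, match="nonnegative"):
            diffusion_embedding(w, n_components=2)

    def test_explained_variance_scale_invariant(self, rng):
        aff = build_affinity(_random_ms(25, rng), sparsity=0.6)
        a = diffusion_embedding(aff, n_components=5)
        b = diffusion_embedding(3.7 * aff, n_components=5)
        assert np.abs(a.explained_variance - b.explained_variance).max() < 1e-12

    def test_region_permutation_equivariance(self, rng):
        aff = build_affinity(_random_ms(25, rng), sparsity=0.6)
        perm = rng.permutation(25)
        a = diffusion_embedding(aff, n_components=4)
        b = diffusion_embedding(aff[np.ix_(perm, perm)], n_components=4)
        for j in range(4):
            x, y = a.components[perm, j], b.components[:, j]
            sign = np.sign(x @ y)
            assert np.abs(x - sign * y).max() < 1e-8


class TestAlignment:
    def _sets(self, rng, n_subj=5, n_regions=20, k=4):
        base = rng.standard_normal((n_regions, k))
        sets = []
        for i in range(n_subj):
            noisy = base + 0.05 * rng.standard_normal((n_regions, k))
            aff = build_affinity(np.corrcoef(noisy) - np.eye(n_regions) * 0, sparsity=0.5)
            emb = diffusion_embedding(aff, n_components=k, subject_id=f"s{i}")
            sets.append(emb)
        return sets

    def test_self_alignment_is_identity(self, rng):
        sets = self._sets(rng, n_subj=1)
        aligned, _ = align_gradients(sets, reference=sets[0])
        assert np.abs(aligned[0].components - sets[0].components).max() < 1e-10

    def test_sign_flip_recovered(self, rng):
        from dataclasses import replace

        sets = self._sets(rng, n_subj=1)
        flipped = replace(sets[0], components=sets[0].components * np.array([-1, 1, -1, 1]))
        aligned, _ = align_gradients([flipped], reference=sets[0])
        assert np.abs(aligned[0].components - sets[0].components).max() < 1e-8

    def test_random_rotation_recovered(self, rng):
        from dataclasses import replace

        sets = self._sets(rng, n_subj=1)
        rot = special_ortho_group.rvs(4, random_state=3)
        rotated = replace(sets[0], components=sets[0].components @ rot)
        aligned, _ = align_gradients([rotated], reference=sets[0])
        assert np.abs(aligned[0].components - sets[0].components).max() < 1e-8

    def test_k_mismatch_rejected(self, rng):
        sets = self._sets(rng, n_subj=2)
        from dataclasses import replace

        short = replace(
            sets[1],
            components=sets[1].components[:, :3],
            eigenvalues=sets[1].eigenvalues[:3],
            explained_variance=sets[1].explained_variance[:3] ,
        )
        with pytest.raises(ValueError, match="component-count mismatch"):
            align_gradients([sets[0], short])


class TestPrincipalTable:
    def test_requires_alignment(self, rng):
        sets = TestAlignment()._sets(rng, n_subj=2)
        with pytest.raises(ValueError, match="not aligned"):
            principal_gradient_table(sets)

    def test_canonical_subject_ordering(self, rng):
        sets = TestAlignment()._sets(rng, n_subj=3)
        aligned, _ = align_gradients(sets)
        t1 = principal_gradient_table(aligned)
        t2 = principal_gradient_table(aligned[::-1])
        assert t1.equals(t2)
        assert list(t1.index) == sorted(t1.index)

    def test_k1_table_equals_stacked_components(self, cohort):
        table, _ = cohort
        mats = subject_ms_matrices(table)[:4]
        sets = [
            diffusion_embedding(build_affinity(m), n_components=1,
                                subject_id=m.subject_id, region_ids=m.region_ids)
            for m in mats
        ]
        aligned, _ = align_gradients(sets)
        tab = principal_gradient_table(aligned)
        for g in aligned:
            assert np.allclose(tab.loc[g.subject_id].to_numpy(), g.components[:, 0])
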