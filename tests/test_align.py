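import itertools

import numpy as np
import pytest
from scipy.stats import spearmanr

from sdm_phylo import (
    compute_pfte,
    import_alignment,
    iterative_align,
    kabsch_superpose,
    make_template,
)
from sdm_phylo.align import write_alignment_tsv
from sdm_phylo.errors import DegenerateInputError, FormatError
from sdm_phylo.structure_io import from_arrays

from _oracles import grid_search_rmsd


def _rotation(axis, angle):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


class TestKabsch:
    def test_identity_case(self, rng):
        a = rng.normal(size=(6, 3))
        rot, trans, rmsd = kabsch_superpose(a, a)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rot, np.eye(3), atol=1e-9)
        assert np.allclose(trans, 0.0, atol=1e-9)

    def test_recovers_known_rigid_transform(self, rng):
        a = rng.normal(size=(8, 3))
        true_rot = _rotation([1, 2, 3], 1.1)
        true_trans = np.array([4.0, -2.0, 7.5])
        b = a @ true_rot.T + true_trans
        rot, trans, rmsd = kabsch_superpose(a, b)
        assert rmsd <= 1e-8
        assert np.allclose(b @ rot.T + trans, a, atol=1e-8)

    def test_rotation_is_proper(self, rng):
        for _ in range(10):
            a = rng.normal(size=(5, 3))
            b = rng.normal(size=(5, 3))
            rot, _, _ = kabsch_superpose(a, b)
            assert np.allclose(rot @ rot.T, np.eye(3), atol=1e-6)
            assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-6)

    def test_matches_rotation_grid_oracle(self, rng):
        """Closed-form optimum agrees with brute-force rotation search."""
        for _ in range(20):
            a = rng.normal(scale=2.0, size=(4, 3))
            b = a + rng.normal(scale=0.5, size=(4, 3))
            _, _, rmsd = kabsch_superpose(a, b)
            grid = grid_search_rmsd(a, b)
            assert grid >= rmsd - 1e-9  # the oracle cannot beat the optimum
            assert abs(grid - rmsd) <= 1e-3

    def test_degenerate_inputs(self, rng):
        with pytest.raises(DegenerateInputError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        # collinear points: solution still returned, rotation proper
        a = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        rot, _, rmsd = kabsch_superpose(a, a)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-6)


class TestIterativeAlign:
    def test_self_alignment_is_the_diagonal(self, template160):
        aln = iterative_align(template160, template160)
        assert aln.n_equivalent == template160.length
        assert aln.pairs == [(i, i) for i in range(template160.length)]
        assert aln.rmsd == pytest.approx(0.0, abs=1e-9)
        assert aln.converged

    def test_rigid_copy_full_equivalence(self, template160):
        rot = _rotation([0.3, -1.0, 0.2], 2.0)
        moved = from_arrays(
            "moved", template160.coords @ rot.T + np.array([10.0, -5.0, 3.0]),
            template160.sequence,
        )
        aln = iterative_align(template160, moved)
        assert aln.n_equivalent == template160.length
        assert aln.rmsd <= 1e-6

    def test_gaussian_noise_rmsd_matches_expectation(self, template160):
        """Isotropic sigma-noise on one copy gives RMSD near sigma*sqrt(3)."""
        sigma = 0.3
        noise_rng = np.random.default_rng(1)
        noisy = from_arrays(
            "noisy", template160.coords + noise_rng.normal(0, sigma, (160, 3)),
            template160.sequence,
        )
        aln = iterative_align(template160, noisy)
        assert aln.n_equivalent >= 0.95 * template160.length
        assert 0.8 * sigma * np.sqrt(3) <= aln.rmsd <= 1.2 * sigma * np.sqrt(3)

    def test_equivalences_satisfy_cutoff_and_order(self, family8, family8_alignments):
        for (la, lb), aln in family8_alignments.items():
            arr = np.array(aln.pairs)
            assert (np.diff(arr[:, 0]) > 0).all() and (np.diff(arr[:, 1]) > 0).all()
            moved = aln.transform(family8[lb].coords)
            dists = np.linalg.norm(
                family8[la].coords[arr[:, 0]] - moved[arr[:, 1]], axis=1)
            assert (dists <= aln.cutoff + 1e-9).all()
            assert np.linalg.det(aln.rotation) == pytest.approx(1.0, abs=1e-6)

    def test_near_symmetry_of_direction(self, family8):
        labels = list(family8)
        for la, lb in [(labels[0], labels[4]), (labels[2], labels[7])]:
            fwd = iterative_align(family8[la], family8[lb])
            rev = iterative_align(family8[lb], family8[la])
            min_len = min(family8[la].length, family8[lb].length)
            assert abs(fwd.n_equivalent - rev.n_equivalent) <= 0.02 * min_len
            assert abs(fwd.rmsd - rev.rmsd) <= 0.05

    def test_noise_monotonicity(self):
        """RMSD rises and PFTE falls with the noise scale."""
        template = make_template(120, 3)
        sigmas = [0.1, 0.5, 1.0, 1.5]
        rows = []
        noise_rng = np.random.default_rng(9)
        for sigma in sigmas:
            for _ in range(50):
                noisy = from_arrays(
                    "n", template.coords + noise_rng.normal(0, sigma, (120, 3)),
                    template.sequence,
                )
                aln = iterative_align(template, noisy)
                pfte = compute_pfte(aln.n_equivalent, 120, 120)
                rows.append((sigma, aln.rmsd, pfte))
        rows = np.array(rows)
        rho_rmsd = spearmanr(rows[:, 0], rows[:, 1]).statistic
        rho_pfte = spearmanr(rows[:, 0], rows[:, 2]).statistic
        assert rho_rmsd > 0.8
        assert rho_pfte < -0.3
        mean_rmsd = [rows[rows[:, 0] == s, 1].mean() for s in sigmas]
        assert all(x <= y + 1e-9 for x, y in zip(mean_rmsd, mean_rmsd[1:]))

    def test_too_short_structure_raises(self):
        tiny = from_arrays("tiny", np.random.default_rng(0).normal(size=(5, 3)), "AAAAA")
        with pytest.raises(DegenerateInputError):
            iterative_align(tiny, tiny)


class TestImportAlignment:
    def test_diagonal_import_gives_zero_rmsd(self, template160, tmp_path):
        path = tmp_path / "pairs.tsv"
        aln = iterative_align(template160, template160)
        write_alignment_tsv(aln, path)
        imported = import_alignment(path, template160, template160)
        assert imported.rmsd == pytest.approx(0.0, abs=1e-9)
        assert imported.pairs == aln.pairs

    def test_crossing_pairs_rejected(self, template160, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("index_a\tindex_b\n1\t2\n2\t1\n")
        with pytest.raises(FormatError, match="crossing"):
            import_alignment(path, template160, template160)

    def test_out_of_range_and_empty(self, template160, tmp_path):
        path = tmp_path / "oob.tsv"
        path.write_text("index_a\tindex_b\n0\t500\n")
        with pytest.raises(FormatError, match="out of range"):
            import_alignment(path, template160, template160)
        empty = tmp_path / "empty.tsv"
        empty.write_text("index_a\tindex_b\n")
        with pytest.raises(FormatError, match="no equivalence"):
            import_alignment(empty, template160, template160)

    def test_rmsd_matches_direct_kabsch(self, template160, tmp_path, rng):
        other = from_arrays(
            "o", template160.coords + rng.normal(0, 1.0, (160, 3)),
            template160.sequence,
        )
        idx = np.sort(rng.choice(160, 10, replace=False))
        path = tmp_path / "ten.tsv"
        path.write_text("index_a\tindex_b\n" +
                        "".join(f"{i}\t{i}\n" for i in idx))
        imported = import_alignment(path, template160, other)
        _, _, expected = kabsch_superpose(template160.coords[idx], other.coords[idx])
        assert imported.rmsd == pytest.approx(expected, abs=1e-12)
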