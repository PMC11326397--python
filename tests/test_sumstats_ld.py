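"""Summary-statistics I/O, allele alignment and the low-rank LD projection."""

import numpy as np
import pytest

from gwfm.ldmatrix import (
    LdValidationError,
    build_pseudo_data,
    eigendecompose_block,
    empirical_correlation,
    load_ld_store,
    save_ld_store,
    BlockLd,
)
from gwfm.simulate import SimConfig, run_gwas, simulate_genotypes, simulate_phenotype
from gwfm.sumstats import (
    MaFormatError,
    SummaryStatRecord,
    read_ma,
    standardize_effects,
    write_ma,
)


def _rec(**kw):
    base = dict(snp_id="rs1", a1="A", a2="G", freq=0.3, b=0.1, se=0.05, p=0.05, n=1000.0)
    base.update(kw)
    return SummaryStatRecord(**base)


class TestReadMa:
    def test_single_row_z_is_b_over_se(self, tmp_path):
        p = tmp_path / "x.ma"
        p.write_text("SNP A1 A2 freq b se p N\nrs1 A G 0.3 0.12 0.04 0.0027 5000\n")
        recs = read_ma(p)
        assert len(recs) == 1
        assert recs[0].z == pytest.approx(0.12 / 0.04)

    def test_invalid_rows_dropped(self, tmp_path):
        p = tmp_path / "x.ma"
        p.write_text(
            "SNP A1 A2 freq b se p N\n"
            "rs1 A G 0.3 0.1 0.0 0.5 5000\n"  # se = 0
            "rs2 A G 1.2 0.1 0.1 0.5 5000\n"  # freq out of range
            "rs3 A G 0.3 0.1 0.1 0.5 5000\n"
        )
        recs = read_ma(p)
        assert [r.snp_id for r in recs] == ["rs3"]

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "x.ma"
        p.write_text("SNP A1 A2 freq b se p\nrs1 A G 0.3 0.1 0.1 0.5\n")
        with pytest.raises(MaFormatError, match="N"):
            read_ma(p)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "x.ma"
        p.write_text("")
        with pytest.raises(MaFormatError):
            read_ma(p)

    def test_write_read_round_trip_from_simulation(self, tmp_path):
        cfg = SimConfig(m=100, n=500, block_size=50, seed=3)
        geno, meta = simulate_genotypes(cfg)
        y, _ = simulate_phenotype(geno, cfg)
        recs = run_gwas(geno, y, meta)
        p = tmp_path / "sim.ma"
        write_ma(recs, p)
        back = read_ma(p)
        assert len(back) == len(recs)
        for a, b in zip(recs, back):
            assert a.snp_id == b.snp_id
            assert a.b == pytest.approx(b.b, abs=1e-6)
            assert a.se == pytest.approx(b.se, abs=1e-6)
            assert a.freq == pytest.approx(b.freq, abs=1e-6)


class TestStandardizeEffects:
    def test_zero_z_gives_zero_bstd(self):
        recs, n_excl = standardize_effects([_rec(b=0.0)], {"rs1": ("A", "G")})
        assert n_excl == 0
        assert recs[0].b_std == 0.0

    def test_swapped_alleles_negate(self):
        direct, _ = standardize_effects([_rec()], {"rs1": ("A", "G")})
        swapped, _ = standardize_effects([_rec()], {"rs1": ("G", "A")})
        assert swapped[0].b_std == pytest.approx(-direct[0].b_std)
        assert abs(swapped[0].b_std) == pytest.approx(abs(direct[0].b_std))
        assert swapped[0].freq == pytest.approx(1 - 0.3)

    def test_mismatch_and_ambiguous_excluded(self):
        recs, n_excl = standardize_effects(
            [_rec(), _rec(snp_id="rs2", a1="A", a2="T"), _rec(snp_id="rs3", a1="C", a2="T")],
            {"rs1": ("A", "G"), "rs2": ("A", "T"), "rs3": ("A", "G")},
        )
        assert len(recs) == 1 and n_excl == 2

    def test_alignment_is_involution(self):
        ref = {"rs1": ("G", "A")}
        once, _ = standardize_effects([_rec()], ref)
        twice, _ = standardize_effects(once, ref)
        assert twice[0].b_std == pytest.approx(once[0].b_std)
        assert twice[0].a1 == once[0].a1

    def test_bstd_squared_tracks_variance_explained(self):
        """For an isolated causal SNP, b_std^2 estimates its variance explained."""
        rng = np.random.default_rng(0)
        n, v = 2000, 0.02
        vals = []
        for _ in range(50):
            x = rng.binomial(2, 0.4, n).astype(float)
            xs = (x - x.mean()) / x.std()
            y = xs * np.sqrt(v) + rng.normal(0, np.sqrt(1 - v), n)
            r = np.corrcoef(xs, y)[0, 1]
            z = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
            b_std = z / np.sqrt(z * z + n - 2)
            vals.append(b_std**2)
        mc_se = np.std(vals) / np.sqrt(len(vals))
        assert np.mean(vals) == pytest.approx(v, abs=2 * mc_se + 1e-4)


class TestEigendecompose:
    def test_identity_keeps_full_rank(self):
        basis = eigendecompose_block(np.eye(3), 1.0)
        assert basis.q == 3
        np.testing.assert_allclose(basis.eigenvalues, [1, 1, 1])

    def test_perfect_ld_pair_is_rank_one(self):
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        for frac in (0.5, 0.995, 1.0):
            basis = eigendecompose_block(R, frac)
            assert basis.q == 1
            assert basis.eigenvalues[0] == pytest.approx(2.0)

    def test_trace_conservation(self, rng):
        x = rng.standard_normal((200, 5))
        R = empirical_correlation(x)
        basis = eigendecompose_block(R, 1.0)
        assert basis.eigenvalues.sum() == pytest.approx(5.0, abs=1e-8)

    def test_orthonormal_columns(self, rng):
        x = rng.standard_normal((500, 8))
        basis = eigendecompose_block(empirical_correlation(x), 0.9)
        gram = basis.eigenvectors.T @ basis.eigenvectors
        np.testing.assert_allclose(gram, np.eye(basis.q), atol=1e-8)

    def test_validation_errors(self):
        with pytest.raises(LdValidationError):
            eigendecompose_block(np.array([[1.0, 0.5], [0.1, 1.0]]))
        with pytest.raises(LdValidationError):
            eigendecompose_block(np.array([[2.0, 0.0], [0.0, 1.0]]))


class TestPseudoData:
    def test_single_null_snp(self):
        basis = eigendecompose_block(np.eye(1), 1.0)
        pdat = build_pseudo_data(np.zeros(1), 100, basis)
        np.testing.assert_allclose(pdat.w, [0.0])

    def test_matches_individual_level_projection(self, rng):
        """w from summary stats equals L^-1/2 U' X'y/sqrt(n) from genotypes."""
        n, m = 3000, 12
        rho = 0.6
        z = rng.standard_normal((n, m))
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * z[:, j]
        X = z
        y = X[:, 4] * 0.1 + rng.standard_normal(n)
        Xs = (X - X.mean(0)) / X.std(0)
        ys = (y - y.mean()) / y.std()
        b_std = Xs.T @ ys / n
        basis = eigendecompose_block(empirical_correlation(X), 1.0)
        pdat = build_pseudo_data(b_std, n, basis)
        direct = (
            (basis.eigenvectors.T @ Xs.T @ ys) / np.sqrt(basis.eigenvalues) / np.sqrt(n)
        )
        np.testing.assert_allclose(pdat.w, direct, atol=1e-6)

    def test_qtq_reconstructs_n_times_r(self, rng):
        n, m = 2000, 10
        X = rng.standard_normal((n, m)) + rng.standard_normal((n, 1))
        R = empirical_correlation(X)
        frac = 0.95
        basis = eigendecompose_block(R, frac)
        pdat = build_pseudo_data(rng.standard_normal(m) * 0.01, n, basis)
        recon = pdat.q_mat.T @ pdat.q_mat
        # ||sum of discarded eigenpairs||_F <= discarded eigenvalue mass,
        # so the error relative to the trace n*m is bounded by 1 - fraction kept
        rel = np.linalg.norm(recon - n * R) / (n * m)
        assert rel < (1 - basis.variance_fraction_kept) + 1e-8

    def test_projection_contract_residual_sd(self, rng):
        """Full-rank single-block projection: w = Q beta + eps with sd(eps) ~ resid sd."""
        n, m = 4000, 30
        ratios = []
        for rep in range(20):
            X = rng.standard_normal((n, m))
            beta = np.zeros(m)
            beta[3] = 0.15
            g = X @ beta
            h2 = g.var() / (g.var() + 1.0)
            y = g + rng.standard_normal(n)
            Xs = (X - X.mean(0)) / X.std(0)
            ys = (y - y.mean()) / y.std()
            b_std = Xs.T @ ys / n
            basis = eigendecompose_block(empirical_correlation(X), 1.0)
            pdat = build_pseudo_data(b_std, n, basis)
            beta_std = beta * X.std(0) / y.std()
            eps = pdat.w - pdat.q_mat @ beta_std
            ratios.append(eps.std() / np.sqrt(1 - h2))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)

    def test_length_mismatch_errors(self):
        basis = eigendecompose_block(np.eye(3), 1.0)
        with pytest.raises(ValueError):
            build_pseudo_data(np.zeros(2), 100, basis)


def test_block_definitions_read_and_assignment(tmp_path):
    from gwfm.ldmatrix import assign_snps_to_blocks, read_block_definitions

    p = tmp_path / "blocks.txt"
    p.write_text(
        "block_id chrom start end\n"
        "b1 1 1000 5000\n"
        "b2 1 5001 9000\n"
    )
    blocks = read_block_definitions(p)
    assert [b.block_id for b in blocks] == ["b1", "b2"]
    chrom = np.array(["1"] * 6, dtype=object)
    pos = np.array([1000, 2500, 5000, 5001, 8999, 9500])
    blocks = assign_snps_to_blocks(blocks, chrom, pos)
    assert list(blocks[0].snp_indices) == [0, 1, 2]  # 1-based inclusive interval
    assert list(blocks[1].snp_indices) == [3, 4]  # position 9500 unassigned


def test_ld_store_round_trip(tmp_path, rng):
    x = rng.standard_normal((300, 6))
    basis = eigendecompose_block(empirical_correlation(x), 0.99)
    blk = BlockLd(
        block_id="0",
        chrom="1",
        start_bp=1000,
        end_bp=6000,
        snp_ids=[f"rs{i}" for i in range(6)],
        pos_bp=np.arange(1000, 7000, 1000),
        a1=["A"] * 6,
        a2=["G"] * 6,
        basis=basis,
    )
    path = tmp_path / "ld.h5"
    save_ld_store(path, [blk])
    back = load_ld_store(path)
    assert len(back) == 1
    np.testing.assert_allclose(back[0].basis.eigenvalues, basis.eigenvalues)
    np.testing.assert_allclose(back[0].basis.eigenvectors, basis.eigenvectors)
    assert back[0].snp_ids == blk.snp_ids
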