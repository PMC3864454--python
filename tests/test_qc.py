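import math

import numpy as np
import pandas as pd
import pytest

from trapcycle.errors import ContractError, ValidationError
from trapcycle.io_tables import CountMatrix, SampleMeta
from trapcycle.qc import (
    best_cosine_correlation,
    control_gene_qc,
    ddct_relative_abundance,
    reference_bank,
    replicate_correlation,
)

WITHIN_DAY = np.array([0.0, 4.0, 8.0, 12.0, 16.0, 20.0])


def _two_rep_matrix(col_a, col_b):
    meta = [SampleMeta("sA", 0.0, 1, "A"), SampleMeta("sB", 0.0, 1, "B")]
    df = pd.DataFrame(
        {"sA": col_a, "sB": col_b},
        index=pd.Index([f"g{i}" for i in range(len(col_a))], name="gene_id"),
    )
    return CountMatrix(values=df.astype(float)), meta


class TestReplicateCorrelation:
    def test_identical_replicates(self):
        m, meta = _two_rep_matrix([1, 5, 9, 2], [1, 5, 9, 2])
        (pair,) = replicate_correlation(m, meta)
        assert pair.r == pytest.approx(1.0)
        assert pair.n_genes == 4

    def test_scaled_replicate_still_perfect(self):
        m, meta = _two_rep_matrix([1, 5, 9, 2], [2, 10, 18, 4])
        (pair,) = replicate_correlation(m, meta)
        assert pair.r == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        a, b = np.array([3.0, 1.0, 4.0, 1.0, 5.0]), np.array([2.0, 7.0, 1.0, 8.0, 2.0])
        m, meta = _two_rep_matrix(a.tolist(), b.tolist())
        (pair,) = replicate_correlation(m, meta)
        expected = np.sum((a - a.mean()) * (b - b.mean())) / math.sqrt(
            np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)
        )
        assert pair.r == pytest.approx(expected, abs=1e-12)

    def test_wrong_replicate_count_rejected(self):
        meta = [SampleMeta(s, 0.0, 1, r) for s, r in [("sA", "A"), ("sB", "B"), ("sC", "C")]]
        df = pd.DataFrame(
            {"sA": [1.0, 2, 3], "sB": [1.0, 2, 3], "sC": [1.0, 2, 3]},
            index=pd.Index(["g0", "g1", "g2"], name="gene_id"),
        )
        with pytest.raises(ContractError, match="expected 2"):
            replicate_correlation(CountMatrix(values=df), meta)


class TestReferenceBank:
    def test_canonical_bank_has_48_curves(self):
        phases, curves = reference_bank(24.0, 0.5, WITHIN_DAY)
        assert len(phases) == 48
        assert curves.shape == (48, 6)
        assert np.abs(curves).max() <= 1.0

    def test_half_period_step_gives_antiphase_pair(self):
        _, curves = reference_bank(24.0, 12.0, WITHIN_DAY)
        assert curves.shape[0] == 2
        np.testing.assert_allclose(curves[0], -curves[1], atol=1e-12)

    def test_antiphase_curves_are_negatives_everywhere(self):
        phases, curves = reference_bank(24.0, 0.5, WITHIN_DAY)
        half = len(phases) // 2
        np.testing.assert_allclose(curves[:half], -curves[half:], atol=1e-12)

    def test_non_divisor_step_rejected(self):
        with pytest.raises(ContractError, match="divide"):
            reference_bank(24.0, 0.7, WITHIN_DAY)


class TestBestCosineCorrelation:
    def test_exact_bank_member_scores_one(self):
        y = np.cos(2 * np.pi * (WITHIN_DAY - 8.0) / 24.0)
        res = best_cosine_correlation(y, WITHIN_DAY)
        assert res.best_r == pytest.approx(1.0)
        assert res.best_phase == pytest.approx(8.0)
        assert not res.undefined

    def test_constant_series_undefined(self):
        res = best_cosine_correlation(np.full(6, 7.0), WITHIN_DAY)
        assert res.undefined and math.isnan(res.best_r)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(11)
        y = np.cos(2 * np.pi * (WITHIN_DAY - 13.0) / 24.0) + rng.normal(0, 0.3, 6)
        res = best_cosine_correlation(y, WITHIN_DAY)
        best_r, best_phase = -np.inf, None
        for phi in np.arange(0, 24, 0.5):
            curve = np.cos(2 * np.pi * (WITHIN_DAY - phi) / 24.0)
            r = np.corrcoef(y, curve)[0, 1]
            if r > best_r:
                best_r, best_phase = r, phi
        assert res.best_r == pytest.approx(best_r, abs=1e-12)
        assert res.best_phase == pytest.approx(best_phase)

    def test_invariant_to_positive_affine_transform(self):
        rng = np.random.default_rng(5)
        y = rng.random(6)
        a = best_cosine_correlation(y, WITHIN_DAY)
        b = best_cosine_correlation(3.5 * y + 11.0, WITHIN_DAY)
        assert a.best_r == pytest.approx(b.best_r, abs=1e-12)
        assert a.best_phase == b.best_phase

    def test_finer_grid_never_worse(self):
        rng = np.random.default_rng(6)
        y = rng.random(6)
        coarse = best_cosine_correlation(y, WITHIN_DAY, phase_step=2.0)
        fine = best_cosine_correlation(y, WITHIN_DAY, phase_step=0.5)
        assert fine.best_r >= coarse.best_r - 1e-12


class TestControlGeneQC:
    def _matrix(self, rows, genes):
        df = pd.DataFrame(
            np.asarray(rows, dtype=float),
            index=pd.Index(genes, name="gene_id"),
            columns=[f"ct{int(c)}" for c in WITHIN_DAY],
        )
        return CountMatrix(values=df, normalized=True)

    def test_noiseless_controls_pass(self):
        rows = [100 + 50 * np.cos(2 * np.pi * (WITHIN_DAY - p) / 24.0) for p in (2, 9, 16)]
        m = self._matrix(rows, ["per", "tim", "vri"])
        passed, results = control_gene_qc(m, WITHIN_DAY, ["per", "tim", "vri"])
        assert passed
        assert all(r.best_r > 0.99 for r in results)

    def test_constant_controls_fail(self):
        m = self._matrix([[7.0] * 6] * 3, ["a", "b", "c"])
        passed, results = control_gene_qc(m, WITHIN_DAY, ["a", "b", "c"])
        assert not passed
        assert all(r.undefined for r in results)

    def test_missing_control_named(self):
        m = self._matrix([[1, 2, 3, 4, 5, 6]], ["per"])
        with pytest.raises(ValidationError, match="clk"):
            control_gene_qc(m, WITHIN_DAY, ["per", "clk"])


class TestDdct:
    def test_constant_delta_ct_gives_unit_abundance(self):
        out = ddct_relative_abundance([20, 21, 22], [15, 16, 17], baseline_index=0)
        np.testing.assert_allclose(out, [1.0, 1.0, 1.0])

    def test_one_cycle_below_baseline_doubles(self):
        # point 1 is one PCR cycle below baseline's delta-Ct
        out = ddct_relative_abundance([20.0, 19.0], [15.0, 15.0], baseline_index=0)
        np.testing.assert_allclose(out, [1.0, 2.0])

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(8)
        tgt, ref = rng.uniform(18, 30, 7), rng.uniform(12, 20, 7)
        out = ddct_relative_abundance(tgt.tolist(), ref.tolist(), baseline_index=3)
        dct = tgt - ref
        np.testing.assert_allclose(out, 2.0 ** (-(dct - dct[3])), rtol=1e-12)
        assert out[3] == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractError):
            ddct_relative_abundance([1, 2], [1], baseline_index=0)
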