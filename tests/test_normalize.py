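import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmtbridge import (
    IntensityMatrix,
    StudyDesign,
    complete_case_filter,
    irs_normalize,
    normalize_pipeline,
    sample_loading_normalize,
    simulate_dataset,
    tmm_factors,
    tmm_normalize,
    SimConfig,
)
from _oracles import tmm_oracle


class TestSampleLoading:
    def test_equal_column_sums_is_identity(self):
        data = pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 2.0]},
                            index=pd.Index(["P1", "P2"], name="protein"))
        out, rec = sample_loading_normalize(IntensityMatrix("B1", data))
        pd.testing.assert_frame_equal(out.data, data)
        assert (rec.factors == 1).all()

    def test_hand_computed_factors(self, tiny_matrix):
        out, rec = sample_loading_normalize(tiny_matrix)
        np.testing.assert_allclose(rec.factors, [2.0, 1.0, 2.0 / 3.0])
        np.testing.assert_allclose(out.data.sum(axis=0), [20.0, 20.0, 20.0])

    def test_single_column_unchanged(self):
        data = pd.DataFrame({"a": [1.0, 2.0]}, index=pd.Index(["P1", "P2"], name="protein"))
        out, _ = sample_loading_normalize(IntensityMatrix("B1", data))
        pd.testing.assert_frame_equal(out.data, data)

    def test_zero_column_sum_raises(self):
        data = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]},
                            index=pd.Index(["P1", "P2"], name="protein"))
        with pytest.raises(ValueError, match="column sum"):
            sample_loading_normalize(IntensityMatrix("B1", data))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(2, 30), st.integers(2, 8), st.integers(0, 10_000))
    def test_column_sums_equal_grand_mean(self, n_rows, n_cols, seed):
        rng = np.random.default_rng(seed)
        data = pd.DataFrame(
            rng.uniform(0.1, 1000.0, (n_rows, n_cols)),
            index=pd.Index([f"P{i}" for i in range(n_rows)], name="protein"),
            columns=[f"c{j}" for j in range(n_cols)],
        )
        out, _ = sample_loading_normalize(IntensityMatrix("B1", data))
        sums = out.data.sum(axis=0)
        grand = data.sum(axis=0).mean()
        assert float(np.abs(sums / grand - 1).max()) < 1e-12


def _irs_inputs(bridge_means):
    """Two 1-bridge batches with prescribed per-protein bridge intensities."""
    rows = []
    for cond, rep, batch, tag in [
        ("Py-only", 1, "B1", "s1"), ("Py-only", 2, "B2", "s1"),
        ("Py/Fu", 1, "B1", "s2"), ("Py/Fu", 2, "B2", "s2"),
        ("La/Fu", 1, "B1", "s3"), ("La/Fu", 2, "B2", "s3"),
        ("H2/Fu", 1, "B1", "s4"), ("H2/Fu", 2, "B2", "s4"),
        ("H2/ClOHPA", 1, "B1", "s5"), ("H2/ClOHPA", 2, "B2", "s5"),
        ("La/ClOHPA", 1, "B1", "s6"), ("La/ClOHPA", 2, "B2", "s6"),
    ]:
        rows.append((batch, tag, f"{cond}-{rep}", cond, rep, False))
    rows.append(("B1", "br", "bridge1", "BRIDGE", 1, True))
    rows.append(("B2", "br", "bridge2", "BRIDGE", 1, True))
    design = StudyDesign(pd.DataFrame(
        rows, columns=["batch", "channel", "sample", "condition", "replicate", "is_bridge"]))
    proteins = pd.Index([f"P{i}" for i in range(len(bridge_means))], name="protein")
    mats = []
    for bi, batch in enumerate(design.batches):
        chans = design.channels(batch)
        data = pd.DataFrame(50.0, index=proteins, columns=chans)
        data["br"] = [bm[bi] for bm in bridge_means]
        mats.append(IntensityMatrix(batch, data))
    return mats, design


class TestIRS:
    def test_equal_bridge_means_is_identity(self):
        mats, design = _irs_inputs([(100.0, 100.0), (7.0, 7.0)])
        merged, rec = irs_normalize(mats, design)
        assert np.allclose(rec.factors, 1.0)

    def test_hand_computed_geometric_reference(self):
        """Bridge means 100 and 400 -> reference 200, factors (2, 1/2)."""
        mats, design = _irs_inputs([(100.0, 400.0)])
        merged, rec = irs_normalize(mats, design)
        np.testing.assert_allclose(rec.factors.loc["P0"], [2.0, 0.5])
        b1 = merged.data.loc["P0", "B1.br"]
        b2 = merged.data.loc["P0", "B2.br"]
        assert b1 == pytest.approx(200.0) and b2 == pytest.approx(200.0)

    def test_bridge_means_equal_after_irs(self, default_sim):
        _, matrices, design, _ = default_sim
        merged, _ = complete_case_filter(matrices, design)
        per_batch = []
        for batch in design.batches:
            cols = [f"{batch}.{c}" for c in design.channels(batch)]
            block = merged.data[cols].copy()
            block.columns = design.channels(batch)
            per_batch.append(IntensityMatrix(batch, block))
        out, rec = irs_normalize(per_batch, design)
        assert rec.extra["bridge_max_rel_disagreement"] < 1e-12

    def test_single_batch_is_noop(self):
        rows = [("B1", "s1", "a1", "Py-only", 1, False),
                ("B1", "s2", "a2", "Py-only", 2, False),
                ("B1", "br", "bridge", "BRIDGE", 1, True)]
        design = StudyDesign(pd.DataFrame(
            rows, columns=["batch", "channel", "sample", "condition", "replicate", "is_bridge"]))
        data = pd.DataFrame({"s1": [1.0, 2.0], "s2": [3.0, 4.0], "br": [2.0, 3.0]},
                            index=pd.Index(["P1", "P2"], name="protein"))
        merged, rec = irs_normalize([IntensityMatrix("B1", data)], design)
        assert np.allclose(rec.factors, 1.0)
        np.testing.assert_allclose(merged.data.to_numpy(), data.to_numpy())

    def test_zero_bridge_mean_drops_protein_with_warning(self):
        mats, design = _irs_inputs([(100.0, 400.0), (100.0, 100.0)])
        mats[0].data.loc["P1", "br"] = np.nan  # undefined bridge -> NaN mean
        mats[0].data.loc["P1", "br"] = 0.0
        mats[0].data = mats[0].data.mask(mats[0].data == 0)
        with pytest.warns(UserWarning, match="zero bridge mean"):
            merged, rec = irs_normalize(mats, design)
        assert "P1" not in merged.protein_ids
        assert rec.extra["dropped"] == ["P1"]


class TestTMM:
    @staticmethod
    def _matrix(values, columns=None):
        arr = np.asarray(values, float)
        cols = columns or [f"c{j}" for j in range(arr.shape[1])]
        return IntensityMatrix("M", pd.DataFrame(
            arr, index=pd.Index([f"P{i}" for i in range(arr.shape[0])], name="protein"),
            columns=cols))

    def test_identical_columns_give_unit_factors(self):
        m = self._matrix(np.tile([[10.0], [20.0], [30.0], [40.0]], (1, 2)))
        rec = tmm_factors(m)
        np.testing.assert_allclose(rec.factors, [1.0, 1.0])

    def test_scale_invariance_of_composition(self):
        base = np.array([[10.0], [20.0], [30.0], [40.0]])
        m = self._matrix(np.hstack([base, 3 * base]))
        rec = tmm_factors(m)
        np.testing.assert_allclose(rec.factors, [1.0, 1.0], atol=1e-12)

    def test_hand_enumerated_trim_example(self):
        """One 5x-outlier row: surviving M all -1 -> factors (sqrt2, 1/sqrt2)."""
        m = self._matrix(np.array([
            [100.0, 100.0], [100.0, 100.0], [100.0, 100.0], [100.0, 500.0],
        ]))
        rec = tmm_factors(m)
        np.testing.assert_allclose(rec.factors, [np.sqrt(2), 1 / np.sqrt(2)], rtol=1e-12)

    def test_geometric_mean_one_and_column_rescaling_invariance(self):
        rng = np.random.default_rng(42)
        y = rng.lognormal(5, 1, (120, 5))
        rec = tmm_factors(self._matrix(y))
        assert np.exp(np.mean(np.log(rec.factors))) == pytest.approx(1.0, abs=1e-12)
        y2 = y.copy()
        y2[:, 2] *= 37.5  # global rescaling of one column: proportions unchanged
        rec2 = tmm_factors(self._matrix(y2))
        np.testing.assert_allclose(rec2.factors, rec.factors, rtol=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            y = rng.lognormal(6, 1.2, (200, 6))
            rec = tmm_factors(self._matrix(y))
            np.testing.assert_allclose(rec.factors, tmm_oracle(y), rtol=1e-9)

    def test_requires_strictly_positive_matrix(self):
        with pytest.raises(ValueError, match="positive"):
            tmm_factors(self._matrix([[1.0, 0.0], [2.0, 3.0]]))

    def test_tmm_normalize_equalizes_effective_totals(self):
        rng = np.random.default_rng(3)
        y = rng.lognormal(6, 1, (150, 4))
        m = self._matrix(y)
        out, rec = tmm_normalize(m)
        # each column was divided by factor * (sum/mean-sum)
        expected = y / (rec.factors.to_numpy() * (y.sum(0) / y.sum(0).mean()))
        np.testing.assert_allclose(out.data.to_numpy(), expected, rtol=1e-12)


class TestPipeline:
    def test_noise_free_recovery_up_to_batch_constant(self, clean_sim):
        cfg, matrices, design, truth = clean_sim
        norm, report = normalize_pipeline(matrices, design)
        assert report["quantified"] == cfg.n_proteins
        expected = {}
        ann = design.column_annotation()
        for col, row in ann[~ann["is_bridge"]].iterrows():
            expected[col] = truth.baseline + truth.effects[row["condition"]]
        expected = pd.DataFrame(expected)
        diff = norm.data[expected.columns] - expected
        # residual is a per-column constant (columns may shift, patterns exact)
        assert float((diff - diff.mean(axis=0)).abs().to_numpy().max()) < 1e-9

    def test_batch_effect_removed_by_bridges(self, default_norm):
        norm, _ = default_norm
        irs = [r for r in norm.applied_steps if r.step == "IRS"][0]
        assert irs.extra["bridge_max_rel_disagreement"] < 1e-9

    def test_disabling_irs_leaves_bridge_disagreement(self, default_sim):
        _, matrices, design, _ = default_sim
        norm, _ = normalize_pipeline(matrices, design, apply_irs=False)
        linear = 2.0 ** norm.data
        means = pd.DataFrame({
            b: linear[[f"{b}.{c}" for c in design.channels(b, bridges="only")]].mean(axis=1)
            for b in design.batches})
        rel = ((means.max(axis=1) - means.min(axis=1)) / means.mean(axis=1)).max()
        assert rel > 0.01  # positive control: batch effects visible in bridges

    def test_applied_steps_record_order(self, default_norm):
        norm, _ = default_norm
        assert [r.step for r in norm.applied_steps] == ["SL", "SL", "IRS", "TMM"]

    def test_row_permutation_equivariance(self):
        cfg = SimConfig(n_proteins=120, dropout_rate=0.0, seed=21)
        matrices, design, _ = simulate_dataset(cfg)
        norm1, _ = normalize_pipeline(matrices, design)
        perm = np.random.default_rng(0).permutation(cfg.n_proteins)
        shuffled = [IntensityMatrix(m.batch_id, m.data.iloc[perm]) for m in matrices]
        norm2, _ = normalize_pipeline(shuffled, design)
        pd.testing.assert_frame_equal(norm2.data.sort_index(), norm1.data.sort_index())
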