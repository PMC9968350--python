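"""Probe filtering, SRS normalisation, and differential-stability selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from braintx.expression import (
    ExpressionBundle,
    differential_stability,
    filter_genes_ds,
    filter_probes_intensity,
    filter_samples,
    preprocess,
    select_probes_rnaseq,
    srs_normalize,
    _srs_vector,
)
from braintx.synthetic import ProbeTable, SyntheticTruth, gen_expression_dataset


def _probe_table(expr: dict[str, list[float]], gene_of: dict[str, str],
                 above: dict[str, list[bool]] | None = None,
                 samples: pd.DataFrame | None = None) -> ProbeTable:
    pids = list(expr)
    n = len(next(iter(expr.values())))
    cols = [f"S{i}" for i in range(n)]
    expression = pd.DataFrame([expr[p] for p in pids],
                              index=pd.Index(pids, name="probe_id"), columns=cols)
    if above is None:
        ab = pd.DataFrame(True, index=expression.index, columns=cols)
    else:
        ab = pd.DataFrame([above[p] for p in pids], index=expression.index, columns=cols)
    if samples is None:
        samples = pd.DataFrame(
            {"donor": "d1", "region": "r1", "hemisphere": "left", "structure": "cortex",
             "x": 0.0, "y": 0.0, "z": 0.0}, index=pd.Index(cols, name="sample_id"))
    probes = pd.DataFrame({"gene_id": [gene_of[p] for p in pids]},
                          index=expression.index)
    return ProbeTable(probes=probes, expression=expression, above_background=ab,
                      samples=samples)


class TestIntensityFilter:
    @pytest.mark.parametrize("n_above,kept", [(51, True), (49, False), (50, True)])
    def test_threshold_is_at_least_half(self, n_above, kept):
        above = [True] * n_above + [False] * (100 - n_above)
        pt = _probe_table({"p1": list(np.arange(100.0))}, {"p1": "g1"},
                          above={"p1": above})
        out = filter_probes_intensity(pt, min_frac=0.5)
        assert ("p1" in out.probes.index) is kept


class TestRnaseqSelection:
    def _table_with_two_probes(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=30)
        good = ref + rng.normal(0, 0.3, 30)          # high correlation
        poor = 0.05 * ref + rng.normal(0, 1.0, 30)   # low correlation
        pt = _probe_table({"pa": list(poor), "pb": list(good)},
                          {"pa": "g1", "pb": "g1"})
        rnaseq = pd.DataFrame([ref], index=pd.Index(["g1"], name="gene_id"),
                              columns=pt.expression.columns)
        return pt, rnaseq

    def test_highest_correlated_probe_represents_the_gene(self):
        pt, rnaseq = self._table_with_two_probes()
        bundle = select_probes_rnaseq(pt, rnaseq)
        assert list(bundle.expression.columns) == ["g1"]
        np.testing.assert_allclose(bundle.expression["g1"].to_numpy(),
                                   pt.expression.loc["pb"].to_numpy())

    def test_gene_with_only_low_correlation_probes_dropped(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=30)
        noise = rng.normal(size=30)
        pt = _probe_table({"p1": list(noise)}, {"p1": "g1"})
        rnaseq = pd.DataFrame([ref], index=pd.Index(["g1"], name="gene_id"),
                              columns=pt.expression.columns)
        bundle = select_probes_rnaseq(pt, rnaseq, min_r=0.2)
        assert bundle.expression.shape[1] == 0

    def test_probe_identical_to_reference_always_wins(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=20)
        pt = _probe_table({"p1": list(ref), "p2": list(ref + rng.normal(0, 1, 20))},
                          {"p1": "g1", "p2": "g1"})
        rnaseq = pd.DataFrame([ref], index=pd.Index(["g1"], name="gene_id"),
                              columns=pt.expression.columns)
        bundle = select_probes_rnaseq(pt, rnaseq)
        np.testing.assert_allclose(bundle.expression["g1"].to_numpy(), ref)

    def test_gene_missing_from_reference_dropped(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=20)
        pt = _probe_table({"p1": list(ref)}, {"p1": "g_absent"})
        rnaseq = pd.DataFrame([ref], index=pd.Index(["g_other"], name="gene_id"),
                              columns=pt.expression.columns)
        bundle = select_probes_rnaseq(pt, rnaseq)
        assert bundle.expression.shape[1] == 0


class TestSampleFilter:
    def _bundle(self, grid):
        samples = pd.DataFrame(
            {
                "donor": ["d1"] * 4,
                "region": ["r1"] * 4,
                "hemisphere": ["left", "right", "left", "left"],
                "structure": ["cortex", "cortex", "subcortex", "cortex"],
                "x": [0.0, 0.0, 0.0, 500.0],  # last one far outside the mask
                "y": [0.0] * 4,
                "z": [0.0] * 4,
            },
            index=pd.Index([f"S{i}" for i in range(4)], name="sample_id"),
        )
        expr = pd.DataFrame(np.arange(8.0).reshape(4, 2), index=samples.index,
                            columns=["g1", "g2"])
        return ExpressionBundle(expression=expr, samples=samples)

    def test_decoy_samples_removed(self, grid):
        out = filter_samples(self._bundle(grid), grid)
        assert list(out.expression.index) == ["S0"]

    def test_clean_input_is_a_noop(self, grid):
        b = self._bundle(grid)
        b.samples.loc[:, ["hemisphere", "structure"]] = ["left", "cortex"]
        b.samples.loc[:, "x"] = 0.0
        out = filter_samples(b, grid)
        pd.testing.assert_frame_equal(out.expression, b.expression)


class TestSrsNormalize:
    def test_hand_worked_three_point_vector(self):
        s = 1.0 / (1.0 + np.exp(-(np.array([1.0, 2.0, 3.0]) - 2.0) / (1.0 / 1.35)))
        np.testing.assert_allclose(s, [0.2059, 0.5, 0.7941], atol=5e-5)
        out = _srs_vector(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out, [0.0, 0.5, 1.0], atol=1e-12)

    def test_monotone_input_preserves_order(self):
        x = np.array([3.0, -1.0, 10.0, 2.5, 7.0])
        out = _srs_vector(x)
        assert np.array_equal(np.argsort(out), np.argsort(x))

    def test_outlier_leaves_other_ranks_unchanged(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        with_outlier = np.append(x, 1e6)
        out = _srs_vector(with_outlier)
        assert np.array_equal(np.argsort(out[:5]), np.argsort(x))

    def test_zero_iqr_vector_maps_to_half(self):
        np.testing.assert_allclose(_srs_vector(np.full(5, 3.0)), 0.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-50, 50), min_size=4, max_size=12, unique=True),
        st.floats(-10, 10),
        st.floats(0.1, 10),
    )
    def test_invariant_to_affine_transforms(self, values, shift, scale):
        x = np.array(values)
        np.testing.assert_allclose(_srs_vector(x), _srs_vector(scale * x + shift),
                                   atol=1e-9)

    def test_two_stage_output_in_unit_interval(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(size=(10, 6)))
        out = srs_normalize(m)
        assert out.shape == m.shape
        assert out.to_numpy().min() >= 0.0 and out.to_numpy().max() <= 1.0


class TestDifferentialStability:
    def _bundle(self, profiles: dict[str, np.ndarray]):
        # two donors sampling the same five regions
        regions = [f"r{i}" for i in range(5)]
        rows = []
        idx = []
        ann = []
        for d, prof in profiles.items():
            for i, reg in enumerate(regions):
                idx.append(f"{d}_{reg}")
                rows.append(prof[:, i])
                ann.append({"donor": d, "region": reg, "hemisphere": "left",
                            "structure": "cortex", "x": 0.0, "y": 0.0, "z": 0.0})
        expr = pd.DataFrame(rows, index=pd.Index(idx, name="sample_id"),
                            columns=[f"g{j}" for j in range(profiles["d1"].shape[0])])
        samples = pd.DataFrame(ann, index=expr.index)
        return ExpressionBundle(expression=expr, samples=samples)

    def test_identical_profiles_give_ds_one(self):
        prof = np.arange(10.0).reshape(2, 5)
        b = self._bundle({"d1": prof, "d2": prof.copy()})
        ds = differential_stability(b)
        np.testing.assert_allclose(ds.to_numpy(), 1.0)

    def test_reversed_profiles_give_ds_minus_one(self):
        prof = np.arange(10.0).reshape(2, 5)
        b = self._bundle({"d1": prof, "d2": prof[:, ::-1].copy()})
        ds = differential_stability(b)
        np.testing.assert_allclose(ds.to_numpy(), -1.0)

    def test_independent_profiles_have_near_zero_mean_ds(self):
        rng = np.random.default_rng(6)
        profiles = {f"d{i}": rng.normal(size=(40, 30)) for i in range(1, 7)}
        regions = [f"r{i}" for i in range(30)]
        rows, idx, ann = [], [], []
        for d, prof in profiles.items():
            for i, reg in enumerate(regions):
                idx.append(f"{d}_{reg}")
                rows.append(prof[:, i])
                ann.append({"donor": d, "region": reg, "hemisphere": "left",
                            "structure": "cortex", "x": 0.0, "y": 0.0, "z": 0.0})
        expr = pd.DataFrame(rows, index=pd.Index(idx, name="sample_id"),
                            columns=[f"g{j}" for j in range(40)])
        b = ExpressionBundle(expression=expr, samples=pd.DataFrame(ann, index=expr.index))
        ds = differential_stability(b)
        assert abs(ds.mean()) < 0.1

    def test_single_donor_rejected(self):
        prof = np.arange(10.0).reshape(2, 5)
        b = self._bundle({"d1": prof})
        with pytest.raises(ValueError, match="2 donors"):
            differential_stability(b)


class TestDsFilter:
    def _bundle_with_ds(self, ds_values):
        genes = [f"g{j:02d}" for j in range(len(ds_values))]
        expr = pd.DataFrame(np.zeros((4, len(genes))),
                            index=pd.Index([f"S{i}" for i in range(4)], name="sample_id"),
                            columns=genes)
        samples = pd.DataFrame({"donor": "d1", "region": "r", "hemisphere": "left",
                                "structure": "cortex", "x": 0.0, "y": 0.0, "z": 0.0},
                               index=expr.index)
        return ExpressionBundle(expression=expr, samples=samples,
                                ds=pd.Series(ds_values, index=genes, name="DS"))

    def test_keeps_ceil_of_fraction(self):
        b = self._bundle_with_ds(np.linspace(0, 1, 10))
        assert filter_genes_ds(b, 0.5).expression.shape[1] == 5
        assert filter_genes_ds(b, 0.45).expression.shape[1] == 5  # ceil(4.5)

    def test_thresholds_are_nested(self):
        rng = np.random.default_rng(7)
        b = self._bundle_with_ds(rng.normal(size=30))
        kept = {f: set(filter_genes_ds(b, f).expression.columns) for f in (0.4, 0.5, 0.6)}
        assert kept[0.4] <= kept[0.5] <= kept[0.6]

    def test_all_equal_ds_breaks_ties_lexicographically(self):
        b = self._bundle_with_ds(np.full(10, 0.5))
        out = filter_genes_ds(b, 0.5)
        assert sorted(out.expression.columns) == [f"g{j:02d}" for j in range(5)]


class TestFullPreprocess:
    def test_pipeline_output_is_clean(self, grid, z_map, truth):
        data = gen_expression_dataset(grid, z_map, n_donors=4, n_samples_per_donor=30,
                                      n_genes=40, probes_per_gene=3, truth=truth,
                                      seed=5, decoy_sample_frac=0.1)
        bundle = preprocess(data.probe_table, data.rnaseq, grid)
        m = bundle.expression
        assert m.notna().all().all()
        assert m.to_numpy().min() >= 0.0 and m.to_numpy().max() <= 1.0
        # decoy samples are gone
        ann = bundle.samples.loc[m.index]
        assert (ann["hemisphere"] == "left").all()
        assert (ann["structure"] == "cortex").all()
        # DS filter kept half (ceil) of the represented genes
        assert m.shape[1] <= 40
        assert bundle.ds is not None and len(bundle.ds) == m.shape[1]
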