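import io

import numpy as np
import pandas as pd
import pytest

from tme_ecotypes import (
    build_composition,
    ecotype_group_distribution,
    export_dendrogram,
    infer_ecotypes,
    scale_composition,
)
from tme_ecotypes.composition import label_ecotypes_by_lineage, silhouette_scan

from oracles import brute_force_ward_partition


def cells_from_counts(spec: dict) -> pd.DataFrame:
    """{sample: {subtype: count}} -> cell table."""
    rows = []
    for sample, counts in spec.items():
        for subtype, n in counts.items():
            for i in range(n):
                rows.append(
                    {
                        "cell_id": f"{sample}_{subtype}_{i}",
                        "sample_id": sample,
                        "subtype": subtype,
                        "lineage": subtype[0],  # first letter as toy lineage
                    }
                )
    return pd.DataFrame(rows)


class TestBuildComposition:
    def test_even_split(self):
        comp = build_composition(cells_from_counts({"s1": {"A": 2, "B": 2}}))
        assert comp.fractions.loc["s1", "A"] == 0.5
        assert comp.fractions.loc["s1", "B"] == 0.5

    def test_absent_subtype_is_zero_column(self):
        comp = build_composition(
            cells_from_counts({"s1": {"A": 1, "C": 1}, "s2": {"A": 2}})
        )
        assert comp.fractions.loc["s2", "C"] == 0.0
        assert "C" in comp.subtypes

    def test_random_table_matches_tally_oracle(self, rng):
        spec = {
            f"s{i}": {
                f"T{j}": int(rng.integers(0, 20)) for j in range(6)
            }
            for i in range(8)
        }
        cells = cells_from_counts(spec)
        comp = build_composition(cells)
        for sample in comp.samples:
            total = sum(spec[sample].values())
            for subtype in comp.subtypes:
                expected = spec[sample].get(subtype, 0) / total
                assert comp.fractions.loc[sample, subtype] == pytest.approx(expected)

    def test_rows_sum_to_one(self, small_cohort):
        comp = build_composition(small_cohort.cells)
        assert np.allclose(comp.fractions.sum(axis=1), 1.0, atol=1e-12)

    def test_parent_lineage_denominator(self):
        cells = cells_from_counts({"s1": {"A1": 3, "A2": 1, "B1": 4}})
        comp = build_composition(cells, denominator="parent_lineage")
        assert comp.fractions.loc["s1", "A1"] == pytest.approx(0.75)
        assert comp.fractions.loc["s1", "A2"] == pytest.approx(0.25)
        assert comp.fractions.loc["s1", "B1"] == pytest.approx(1.0)

    def test_unknown_level_raises(self, small_cohort):
        with pytest.raises(ValueError, match="level"):
            build_composition(small_cohort.cells, level="cluster")
        with pytest.raises(ValueError, match="denominator"):
            build_composition(small_cohort.cells, denominator="none")


class TestScaleComposition:
    def test_hand_standardization(self):
        frac = pd.DataFrame({"A": [0.1, 0.3], "B": [0.9, 0.7]}, index=["s1", "s2"])
        scaled = scale_composition(frac)
        assert scaled.matrix["A"].to_numpy() == pytest.approx(
            [-0.70710678, 0.70710678]
        )

    def test_constant_column_maps_to_zero(self):
        frac = pd.DataFrame({"A": [0.5, 0.5, 0.5], "B": [0.1, 0.2, 0.3]})
        scaled = scale_composition(frac)
        assert (scaled.matrix["A"] == 0).all()

    def test_columns_standardized(self, small_cohort):
        comp = build_composition(small_cohort.cells)
        scaled = scale_composition(comp)
        means = scaled.matrix.mean(axis=0)
        assert np.allclose(means, 0.0, atol=1e-9)
        sds = scaled.matrix.std(axis=0, ddof=1)
        nonconst = scaled.spread > 0
        assert np.allclose(sds[nonconst], 1.0, atol=1e-9)

    def test_single_sample_raises(self):
        with pytest.raises(ValueError):
            scale_composition(pd.DataFrame({"A": [0.5]}))


class TestInferEcotypes:
    def test_one_dimensional_two_groups(self):
        mat = pd.DataFrame({"x": [0.0, 0.1, 10.0, 10.1]}, index=list("abcd"))
        model = infer_ecotypes(mat, k=2)
        groups = {
            frozenset(model.assignments.index[model.assignments == e])
            for e in model.assignments.unique()
        }
        assert groups == {frozenset({"a", "b"}), frozenset({"c", "d"})}

    def test_k_equals_n(self):
        mat = pd.DataFrame(np.random.default_rng(0).normal(size=(6, 3)))
        model = infer_ecotypes(mat, k=6)
        assert model.assignments.nunique() == 6

    def test_k_out_of_range(self):
        mat = pd.DataFrame(np.eye(4))
        with pytest.raises(ValueError):
            infer_ecotypes(mat, k=5)
        with pytest.raises(ValueError):
            infer_ecotypes(mat, k=0)

    def test_labels_ordered_by_size(self, rng):
        X = np.vstack(
            [rng.normal(0, 0.1, (8, 2)), rng.normal(10, 0.1, (3, 2))]
        )
        model = infer_ecotypes(pd.DataFrame(X), k=2)
        sizes = model.assignments.value_counts()
        assert sizes["E1"] == 8 and sizes["E2"] == 3

    def test_merge_heights_monotone(self, rng):
        model = infer_ecotypes(pd.DataFrame(rng.normal(size=(15, 4))), k=3)
        heights = model.linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_matches_brute_force_ward(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 14))
            k = int(rng.integers(2, min(5, n)))
            X = rng.normal(size=(n, 3))
            model = infer_ecotypes(pd.DataFrame(X), k=k)
            mine = {
                frozenset(
                    i for i, e in enumerate(model.assignments) if e == label
                )
                for label in model.assignments.unique()
            }
            assert mine == brute_force_ward_partition(X, k)

    def test_permutation_invariance(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 5)), index=[f"s{i}" for i in range(12)])
        model_a = infer_ecotypes(X, k=3)
        perm = rng.permutation(12)
        model_b = infer_ecotypes(X.iloc[perm], k=3)
        part_a = {
            frozenset(model_a.assignments.index[model_a.assignments == e])
            for e in model_a.assignments.unique()
        }
        part_b = {
            frozenset(model_b.assignments.index[model_b.assignments == e])
            for e in model_b.assignments.unique()
        }
        assert part_a == part_b

    def test_silhouette_scan_reports_only(self, rng):
        scan = silhouette_scan(pd.DataFrame(rng.normal(size=(20, 4))))
        assert set(scan.index) <= set(range(2, 11))
        assert scan.notna().all()


class TestGroupDistribution:
    @staticmethod
    def model_with(assignments: dict):
        from tme_ecotypes.composition import EcotypeModel

        s = pd.Series(assignments, name="ecotype")
        return EcotypeModel(linkage=np.empty((0, 4)), k=s.nunique(), assignments=s, ordering=list(s.index))

    def test_eighty_percent_early(self):
        model = self.model_with({f"s{i}": "E1" for i in range(5)})
        samples = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(5)],
                "stage": ["early"] * 4 + ["advanced"],
                "cancer_type": ["BCC"] * 5,
            }
        )
        dist = ecotype_group_distribution(model, samples, by="stage")
        assert dist.ecotype_percent.loc["E1", "early"] == pytest.approx(80.0)
        assert dist.ecotype_percent.sum(axis=1).iloc[0] == pytest.approx(100.0)

    def test_single_group_is_100(self):
        model = self.model_with({"a": "E1", "b": "E2"})
        samples = pd.DataFrame(
            {"sample_id": ["a", "b"], "stage": ["early", "early"], "cancer_type": ["CM", "CM"]}
        )
        dist = ecotype_group_distribution(model, samples, by="stage")
        assert (dist.ecotype_percent["early"] == 100.0).all()

    def test_missing_metadata_raises(self):
        model = self.model_with({"a": "E1", "b": "E1"})
        samples = pd.DataFrame({"sample_id": ["a"], "stage": ["early"]})
        with pytest.raises(ValueError, match="b"):
            ecotype_group_distribution(model, samples, by="stage")

    def test_combined_grouping(self):
        model = self.model_with({"a": "E1", "b": "E1"})
        samples = pd.DataFrame(
            {
                "sample_id": ["a", "b"],
                "stage": ["early", "advanced"],
                "cancer_type": ["BCC", "SCC"],
            }
        )
        dist = ecotype_group_distribution(model, samples, by="cancer_type:stage")
        assert set(dist.counts.columns) == {"BCC:early", "SCC:advanced"}


class TestDendrogram:
    def test_two_leaves_half_height(self):
        mat = pd.DataFrame({"x": [0.0, 2.0]}, index=["A", "B"])
        model = infer_ecotypes(mat, k=1)
        nwk = export_dendrogram(model)
        height = model.linkage[0, 2]
        assert nwk == f"(A:{height / 2:.10g},B:{height / 2:.10g});"

    def test_round_trip_preserves_leaves(self, rng):
        from Bio import Phylo

        X = pd.DataFrame(rng.normal(size=(9, 3)), index=[f"s{i}" for i in range(9)])
        model = infer_ecotypes(X, k=3)
        tree = Phylo.read(io.StringIO(export_dendrogram(model)), "newick")
        leaves = {leaf.name for leaf in tree.get_terminals()}
        assert leaves == set(X.index)
        assert tree.count_terminals() == 9


def test_label_ecotypes_by_lineage(small_cohort):
    cells = small_cohort.cells
    comp = build_composition(cells)
    model = infer_ecotypes(scale_composition(comp), k=4)
    lineage_map = dict(cells[["subtype", "lineage"]].drop_duplicates().to_numpy())
    names = label_ecotypes_by_lineage(
        model, comp, lineage_map, archetypes={"T_NK": "T_cell_dominant"}
    )
    assert set(names) == set(model.assignments.unique())
    assert all(isinstance(v, str) and v for v in names.values())
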