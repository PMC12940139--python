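import numpy as np
import pandas as pd
import pytest

from bloodsig.origins import OriginAssignment
from bloodsig.qc import filter_low_depth, remove_contaminants, to_relative_abundance
from bloodsig.signatures import (
    cohort_origin_stats,
    compute_prevalence,
    origin_proportions,
    prevalence_compare,
    select_common,
    top_taxa_by_abundance,
)
from bloodsig.synth import GeneratorConfig, simulate_dataset


def metadata_for(samples, studies, groups):
    return pd.DataFrame(
        {
            "sample_id": samples,
            "study_id": studies,
            "group": groups,
            "cohort_label": "x",
        }
    )


@pytest.fixture
def toy_rel():
    rel = pd.DataFrame(
        {
            "G1": [0.5, 0.0, 0.2, 0.0],
            "G2": [0.5, 1.0, 0.8, 0.0],
            "G3": [0.0, 0.0, 0.0, 1.0],
        },
        index=["a1", "a2", "b1", "b2"],
    )
    md = metadata_for(
        ["a1", "a2", "b1", "b2"],
        ["S1", "S1", "S2", "S2"],
        ["Ct", "NCt", "Ct", "NCt"],
    )
    return rel, md


class TestPrevalence:
    def test_overall_fraction_of_samples(self, toy_rel):
        rel, md = toy_rel
        prev = compute_prevalence(rel, md)
        assert prev.loc["G3", "overall_prevalence"] == pytest.approx(0.25)
        assert prev.loc["G1", "overall_prevalence"] == pytest.approx(0.5)

    def test_study_prevalence_counts_detecting_studies(self, toy_rel):
        rel, md = toy_rel
        prev = compute_prevalence(rel, md)
        assert prev.loc["G1", "study_prevalence"] == pytest.approx(1.0)
        assert prev.loc["G3", "study_prevalence"] == pytest.approx(0.5)

    def test_all_zero_taxon_has_zero_prevalence(self, toy_rel):
        rel, md = toy_rel
        rel = rel.assign(G4=0.0)
        prev = compute_prevalence(rel, md)
        assert prev.loc["G4", "overall_prevalence"] == 0.0
        assert prev.loc["G4", "study_prevalence"] == 0.0

    def test_invariant_to_abundance_transform(self, small_dataset):
        ds = small_dataset
        ft, _ = filter_low_depth(ds["table"], 100)
        rel = to_relative_abundance(ft)
        p_counts = compute_prevalence(ft.counts, ds["metadata"])
        p_rel = compute_prevalence(rel, ds["metadata"])
        pd.testing.assert_frame_equal(p_counts, p_rel)


class TestSelectCommon:
    def test_strict_boundary(self):
        records = pd.DataFrame(
            {"overall_prevalence": [0.50, 0.51], "study_prevalence": [1.0, 1.0]},
            index=["at", "above"],
        )
        out = select_common(records, overall_threshold=0.50)
        assert list(out.index) == ["above"]

    def test_zero_threshold_keeps_detected(self):
        records = pd.DataFrame(
            {"overall_prevalence": [0.1, 0.0], "study_prevalence": [0.5, 0.0]},
            index=["seen", "never"],
        )
        out = select_common(records, overall_threshold=0.0)
        assert list(out.index) == ["seen"]

    def test_monotone_in_threshold(self, small_dataset):
        ds = small_dataset
        ft, _ = filter_low_depth(ds["table"], 100)
        prev = compute_prevalence(to_relative_abundance(ft), ds["metadata"])
        previous = None
        for thr in (0.0, 0.2, 0.5, 0.8):
            selected = set(select_common(prev, overall_threshold=thr).index)
            if previous is not None:
                assert selected <= previous
            previous = selected

    def test_core_taxa_recovered_from_sparse_design(self):
        """With shallow sequencing the generator's high-abundance core set
        is exactly the set of taxa above a high prevalence cut."""
        cfg = GeneratorConfig(
            n_studies=3,
            n_control=10,
            n_case=10,
            n_taxa=80,
            n_core=10,
            core_boost=6.0,
            n_amplified=4,
            batch_scale=0.5,
            depth_log_mean=np.log(400.0),
            depth_min=200,
            depth_max=800,
            contaminants_per_study=0,
            rng_seed=7,
        )
        ds = simulate_dataset(cfg, seed=7, with_contaminants=False)
        rel = to_relative_abundance(ds["table"])
        prev = compute_prevalence(rel, ds["metadata"])
        selected = set(select_common(prev, overall_threshold=0.95).index)
        assert selected == set(ds["truth"].core_taxa)


class TestOriginProportions:
    def test_category_mass(self):
        rel = pd.DataFrame(
            {"G1": [0.5], "G2": [0.3], "G3": [0.2]}, index=["s1"]
        )
        assignments = {
            "G1": OriginAssignment("G1", frozenset({"gut"})),
            "G2": OriginAssignment("G2", frozenset({"gut", "oral"})),
            "G3": OriginAssignment("G3", frozenset()),
        }
        props = origin_proportions(rel, assignments)
        assert props.loc["s1", "gut"] == pytest.approx(0.5)
        assert props.loc["s1", "multi"] == pytest.approx(0.3)
        assert props.loc["s1", "unidentified"] == pytest.approx(0.2)

    def test_unassigned_taxa_default_to_unidentified(self):
        rel = pd.DataFrame({"G1": [1.0]}, index=["s1"])
        props = origin_proportions(rel, {})
        assert props.loc["s1", "unidentified"] == pytest.approx(1.0)

    def test_rows_partition_unit_mass(self, small_dataset, rng):
        ds = small_dataset
        ft, _ = filter_low_depth(ds["table"], 100)
        rel = to_relative_abundance(ft)
        assignments = {
            t: OriginAssignment(t, s) for t, s in ds["truth"].origins.items()
        }
        props = origin_proportions(rel, assignments)
        assert np.allclose(props.sum(axis=1), 1.0, atol=1e-9)


class TestCohortOriginStats:
    def test_hand_computed_summary(self):
        props = pd.DataFrame({"gut": [0.6, 0.0, 0.3]})
        out = cohort_origin_stats(props)
        assert out.loc["gut", "mean"] == pytest.approx(0.3)
        assert out.loc["gut", "frac_gt_half"] == pytest.approx(1 / 3)
        assert out.loc["gut", "frac_zero"] == pytest.approx(1 / 3)

    def test_all_zero_category(self):
        out = cohort_origin_stats(pd.DataFrame({"skin": [0.0, 0.0]}))
        assert out.loc["skin", "mean"] == 0.0
        assert out.loc["skin", "frac_zero"] == 1.0

    def test_fractions_bounded(self, small_dataset):
        ds = small_dataset
        ft, _ = filter_low_depth(ds["table"], 100)
        rel = to_relative_abundance(ft)
        assignments = {
            t: OriginAssignment(t, s) for t, s in ds["truth"].origins.items()
        }
        out = cohort_origin_stats(origin_proportions(rel, assignments))
        assert ((out >= 0) & (out <= 1)).all().all()
        assert ((out["frac_gt_half"] + out["frac_zero"]) <= 1 + 1e-12).all()

    def test_zero_noise_generator_means_match_truth_partition(self, small_dataset):
        """With the exact truth assignments, category means must equal the
        abundance-weighted category partition computed independently."""
        ds = small_dataset
        ft, _ = filter_low_depth(ds["table"], 100)
        rel = to_relative_abundance(ft)
        truth = ds["truth"]
        assignments = {t: OriginAssignment(t, s) for t, s in truth.origins.items()}
        stats = cohort_origin_stats(origin_proportions(rel, assignments))
        # independent recomputation from the truth's category map
        expected_gut = rel[
            [t for t in rel.columns if truth.origin_category(t) == "gut"]
        ].sum(axis=1).mean()
        assert stats.loc["gut", "mean"] == pytest.approx(expected_gut, abs=1e-9)


class TestPrevalenceCompare:
    def test_group_prevalence_pair(self):
        samples = [f"c{i}" for i in range(10)] + [f"n{i}" for i in range(10)]
        md = metadata_for(samples, ["S1"] * 20, ["Ct"] * 10 + ["NCt"] * 10)
        detections = [1, 1] + [0] * 8 + [1] * 6 + [0] * 4
        rel = pd.DataFrame({"G1": [0.5 * d for d in detections]}, index=samples)
        prev = pd.DataFrame(
            {"overall_prevalence": [0.4], "study_prevalence": [1.0]}, index=["G1"]
        )
        pooled, per_study = prevalence_compare(
            rel, md, ["G1"], study_threshold=0.5, prevalence=prev
        )
        assert pooled.loc["G1", "ct_prevalence"] == pytest.approx(0.2)
        assert pooled.loc["G1", "nct_prevalence"] == pytest.approx(0.6)
        assert set(per_study["group"]) == {"Ct", "NCt"}

    def test_low_study_prevalence_taxon_excluded(self, toy_rel):
        rel, md = toy_rel
        pooled, _ = prevalence_compare(rel, md, ["G3"], study_threshold=0.5)
        assert pooled.empty

    def test_amplified_taxa_more_prevalent_in_cases(self):
        """Across seeds, generator-amplified taxa are detected at least as
        often in NCt as in Ct on average."""
        diffs = []
        for seed in range(20):
            cfg = GeneratorConfig(
                n_studies=2,
                n_control=8,
                n_case=8,
                n_taxa=50,
                n_core=6,
                n_amplified=4,
                depth_log_mean=np.log(2000.0),
                depth_min=500,
                depth_max=8000,
                rng_seed=seed,
            )
            ds = simulate_dataset(cfg, seed=seed, with_contaminants=False)
            rel = to_relative_abundance(ds["table"])
            md = ds["metadata"].set_index("sample_id")
            for taxon in ds["truth"].amplified_taxa:
                det = rel[taxon] > 0
                nct = det[md["group"] == "NCt"].mean()
                ct = det[md["group"] == "Ct"].mean()
                diffs.append(nct - ct)
        assert np.mean(diffs) > 0


def test_top_taxa_ranking():
    rel = pd.DataFrame(
        {"low": [0.1, 0.1], "high": [0.8, 0.7], "mid": [0.1, 0.2]},
        index=["s1", "s2"],
    )
    assert top_taxa_by_abundance(rel, n=2) == ["high", "mid"]
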