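"""Relative-estimate, filtering/ranking, and report-writing tests."""

import csv
import json
import random

import pytest

from dnazymekit import (
    ArmSpec,
    ContextEntry,
    DnazymeRecord,
    EstimateBasis,
    FilterSpec,
    ReactionType,
    SortKey,
    SubstrateClass,
    apply_filters,
    attach_estimates,
    design_site,
    estimate,
    find_sites,
    match_context,
    substrate_from_string,
    write_detail,
    write_summary,
)
from dnazymekit.errors import FilterSpecificationError
from dnazymekit.estimator_report import SUMMARY_COLUMNS, detail_document
from test_designer import random_designs


def classified_site(substrate_text, record, index=0):
    sub = substrate_from_string(substrate_text, "RNA")
    sites = find_sites(sub, record)
    return sub, match_context(sub, sites[index], record)


class TestEstimate:
    def test_original_context(self, context_record):
        _, site = classified_site("AAGUCAGUA", context_record, 0)
        est = estimate(site, context_record)
        assert est.basis is EstimateBasis.ORIGINAL_CONTEXT
        assert (est.rrk_percent, est.rry_percent, est.rcy_percent) == (100, 100, 85)

    def test_mutant_context_ratios(self, context_record):
        _, site = classified_site("AAGUCAGUA", context_record, 1)
        est = estimate(site, context_record)
        assert est.basis is EstimateBasis.REPORTED_MUTANT_CONTEXT
        assert est.rrk_percent == pytest.approx(25.0)   # 100 * 0.5 / 2.0
        assert est.rry_percent == pytest.approx(100 * 40 / 85)
        assert est.rcy_percent == 40.0

    def test_no_contexts_unavailable(self, toy_record):
        _, site = classified_site("AAAAAGUCCCCC", toy_record)
        est = estimate(site, toy_record)
        assert est.basis is EstimateBasis.UNAVAILABLE
        assert est.rrk_percent is est.rry_percent is est.rcy_percent is None

    def test_model_fallback_averages_near_contexts(self):
        rec = DnazymeRecord(
            name="m", variant_id="", substrate_class=SubstrateClass.RNA,
            reaction_type=ReactionType.TRANSESTERIFICATION,
            core_sequence="GGCTAGC", rs_pattern="GU", cleavage_offset=1,
            contexts=(
                ContextEntry("AGUC", 1, 1, k_obs=1.0, yield_percent=80.0,
                             is_original=True),
                ContextEntry("CGUC", 1, 1, k_obs=0.2, yield_percent=40.0),
            ),
        )
        # observed window GGUC matches neither but is 1 mismatch from both
        _, site = classified_site("AGGUCA", rec)
        assert site.matched_context is None
        est = estimate(site, rec, model_distance=1)
        assert est.basis is EstimateBasis.MODEL
        assert est.rcy_percent == pytest.approx(60.0)  # mean(80, 40)
        assert est.rrk_percent is None and est.rry_percent is None
        # distance 0 admits nothing
        assert estimate(site, rec, model_distance=0).rcy_percent is None

    def test_missing_original_kobs_gives_null_ratio(self):
        rec = DnazymeRecord(
            name="m", variant_id="", substrate_class=SubstrateClass.RNA,
            reaction_type=ReactionType.TRANSESTERIFICATION,
            core_sequence="GGCTAGC", rs_pattern="GU", cleavage_offset=1,
            contexts=(
                ContextEntry("AGUC", 1, 1, is_original=True),
                ContextEntry("CGUC", 1, 1, k_obs=0.2, yield_percent=40.0),
            ),
        )
        _, site = classified_site("CCGUCA", rec)
        est = estimate(site, rec)
        assert est.basis is EstimateBasis.REPORTED_MUTANT_CONTEXT
        assert est.rrk_percent is None and est.rry_percent is None
        assert est.rcy_percent == 40.0


def build_results(n=40, seed=23):
    results = []
    for _, _, design in random_designs(n, seed=seed):
        results.append(attach_estimates(design))
    return results


class TestFilters:
    def test_tm_constraint_applies_to_both_arms(self, toy_substrate, toy_record):
        site = find_sites(toy_substrate, toy_record)[0]
        result = attach_estimates(design_site(toy_substrate, site, ArmSpec(length=6)))
        assert result.arms.tm1_C == 22.0 and result.arms.tm2_C == 14.0
        assert apply_filters([result], FilterSpec(tm_min=20.0)) == []   # arm2 fails
        assert apply_filters([result], FilterSpec(tm_min=14.0)) == [result]

    def test_empty_spec_sorts_by_kobs_desc_nulls_last(self):
        results = build_results(30)
        ranked = apply_filters(results, None)
        assert len(ranked) == len(results)
        from dnazymekit.estimator_report import result_k_obs
        ks = [result_k_obs(r) for r in ranked]
        non_null = [k for k in ks if k is not None]
        assert non_null == sorted(non_null, reverse=True)
        assert all(k is None for k in ks[len(non_null):])

    def test_region_excludes_everything(self, toy_substrate, toy_record):
        site = find_sites(toy_substrate, toy_record)[0]
        result = attach_estimates(design_site(toy_substrate, site, ArmSpec(length=6)))
        assert apply_filters([result], FilterSpec(region=(100, 200))) == []

    def test_contradictory_spec_rejected(self):
        with pytest.raises(FilterSpecificationError):
            apply_filters([], FilterSpec(tm_min=30.0, tm_max=20.0))

    def test_repeated_runs_identical_order(self):
        results = build_results(25)
        a = apply_filters(results, FilterSpec(sort_key=SortKey.POSITION))
        b = apply_filters(list(results), FilterSpec(sort_key=SortKey.POSITION))
        assert a == b

    def test_monotonicity_under_tightening(self):
        """Adding/tightening any constraint never increases the result count."""
        results = build_results(60, seed=31)
        rng = random.Random(777)
        mechs = [None, ReactionType.TRANSESTERIFICATION, ReactionType.HYDROLYSIS]
        violations = 0
        for _ in range(500):
            base = FilterSpec(
                tm_min=rng.choice([None, 10.0, 20.0]),
                tm_max=rng.choice([None, 40.0, 60.0]),
                region=rng.choice([None, (1, 80)]),
                mechanism=rng.choice(mechs),
                ph_min=rng.choice([None, 5.0]),
                ph_max=rng.choice([None, 9.0]),
            )
            kind = rng.randrange(5)
            if kind == 0:
                tighter = FilterSpec(**{**base.__dict__,
                                        "tm_min": (base.tm_min or 0.0) + 6.0})
            elif kind == 1:
                tighter = FilterSpec(**{**base.__dict__,
                                        "tm_max": (base.tm_max or 60.0) - 10.0})
            elif kind == 2:
                lo, hi = base.region or (1, 80)
                tighter = FilterSpec(**{**base.__dict__,
                                        "region": (lo + 5, max(lo + 5, hi - 10))})
            elif kind == 3:
                tighter = FilterSpec(**{**base.__dict__,
                                        "mechanism": ReactionType.TRANSESTERIFICATION})
                if base.mechanism is ReactionType.HYDROLYSIS:
                    continue  # switching mechanism is not a tightening
            else:
                tighter = FilterSpec(**{**base.__dict__, "max_results": 3})
            if len(apply_filters(results, tighter)) > len(apply_filters(results, base)):
                violations += 1
        assert violations == 0


class TestReports:
    def test_header_only_csv_for_zero_results(self, tmp_path):
        path = tmp_path / "summary.csv"
        write_summary([], path, "csv")
        rows = list(csv.reader(path.open()))
        assert rows == [list(SUMMARY_COLUMNS)]

    def test_worked_example_row(self, tmp_path, toy_substrate, toy_record):
        site = find_sites(toy_substrate, toy_record)[0]
        result = attach_estimates(design_site(toy_substrate, site, ArmSpec(length=6)))
        path = tmp_path / "summary.csv"
        write_summary([result], path, "csv")
        row = next(csv.DictReader(path.open()))
        assert row["name"] == "toy"
        assert float(row["tm_arm1_C"]) == 22.0
        assert float(row["tm_arm2_C"]) == 14.0
        assert row["rrk_percent"] == ""  # no contexts -> unavailable

    def test_csv_and_json_agree(self, tmp_path):
        results = build_results(10)
        cpath, jpath = tmp_path / "s.csv", tmp_path / "s.json"
        write_summary(results, cpath, "csv")
        write_summary(results, jpath, "json")
        csv_rows = list(csv.DictReader(cpath.open()))
        json_rows = json.loads(jpath.read_text())
        assert len(csv_rows) == len(json_rows)
        for crow, jrow in zip(csv_rows, json_rows):
            for col in SUMMARY_COLUMNS:
                jval = jrow[col]
                cval = crow[col]
                if jval is None:
                    assert cval == ""
                elif isinstance(jval, float):
                    assert float(cval) == pytest.approx(jval)
                else:
                    assert str(jval) == cval

    def test_detail_components_concatenate(self, tmp_path, toy_substrate, toy_record):
        site = find_sites(toy_substrate, toy_record)[0]
        result = attach_estimates(design_site(toy_substrate, site, ArmSpec(length=6)))
        path = tmp_path / "detail.json"
        write_detail(result, path)
        doc = json.loads(path.read_text())
        full = doc["assembly"]["full_sequence"]
        parts = "".join(
            full[c["start"] - 1 : c["end"]] for c in doc["assembly"]["components"]
        )
        assert parts == full
        assert doc["products"]["product_5p"]["sequence"] == "AAAAAG"

    def test_detail_notes_model_distance_and_clipping(self):
        rec = DnazymeRecord(
            name="m", variant_id="", substrate_class=SubstrateClass.RNA,
            reaction_type=ReactionType.TRANSESTERIFICATION,
            core_sequence="GGCTAGC", rs_pattern="GU", cleavage_offset=1,
            contexts=(
                ContextEntry("AGUC", 1, 1, k_obs=1.0, yield_percent=80.0,
                             is_original=True),
            ),
        )
        sub = substrate_from_string("CCCCCGGUAAAAA", "RNA")
        site = match_context(sub, find_sites(sub, rec)[0], rec)
        assert site.matched_context is None
        result = attach_estimates(design_site(sub, site, ArmSpec(length=5)))
        doc = detail_document(result)
        assert doc["estimates"]["basis"] == "model"
        assert any("nearest-context model" in n for n in doc["notes"])
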