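import itertools
import json

import numpy as np
import pytest

from ldlr_varstruct.stability import StabilityRecord
from ldlr_varstruct.stats_report import (
    AnnotatedVariant, class_counts, conservation_vs_stability,
    ddg_distribution_compare, generate_report, rank_sum_test,
    residue_coverage, spearman_rho,
)
from ldlr_varstruct.structural_annotation import RoleFlags
from ldlr_varstruct.variant_catalog import Variant, VariantChange


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_rho([1, 2, 3, 4], [1, 2, 3, 4]) == 1.0
        assert spearman_rho([1, 2, 3, 4], [10, 20, 25, 90]) == 1.0

    def test_reversed(self):
        assert spearman_rho([1, 2, 3], [3, 2, 1]) == -1.0

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1], [1, 2, 3])

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            # independent oracle: average ranks then Pearson formula
            def ranks(v):
                order = np.argsort(v)
                r = np.empty(len(v))
                r[order] = np.arange(1, len(v) + 1)
                return r
            rx, ry = ranks(x), ranks(y)
            num = np.sum((rx - rx.mean()) * (ry - ry.mean()))
            den = np.sqrt(np.sum((rx - rx.mean()) ** 2)
                          * np.sum((ry - ry.mean()) ** 2))
            assert spearman_rho(x, y) == pytest.approx(num / den, abs=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        assert spearman_rho(x, y) == pytest.approx(-spearman_rho(x, -y),
                                                   abs=1e-12)


class TestRankSum:
    def test_statistic_matches_manual_ranks(self):
        x, y = [1.0, 3.0, 5.0], [2.0, 4.0, 6.0]
        w, _ = rank_sum_test(x, y)
        assert w == 1 + 3 + 5  # ranks of x in the pooled sample

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=5)
        y = rng.normal(1.0, 1.0, size=6)
        w_obs, p = rank_sum_test(x, y)
        pooled = np.concatenate([x, y])
        ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
        all_ws = [sum(ranks[pooled[i]] for i in combo)
                  for combo in itertools.combinations(range(11), 5)]
        mean_w = np.mean(all_ws)
        extreme = sum(abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-9
                      for w in all_ws)
        assert p == pytest.approx(extreme / len(all_ws), abs=1e-12)

    def test_identical_distributions_give_large_p(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        _, p = rank_sum_test(x, y)
        assert p > 0.05

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3.0, 1.5, size=50)
        y = rng.normal(0.0, 1.5, size=50)
        _, p = rank_sum_test(x, y)
        assert p < 0.001


def _annotated(pos, clin="vus", flags=None, extra=None, endo=None,
               cons=np.nan, alt="R"):
    ref = "A" if alt != "A" else "G"
    v = Variant(VariantChange(ref, pos, alt), clinical_class=clin)
    stab = None
    if extra is not None or endo is not None:
        stab = StabilityRecord(v.change, extra, endo)
    return AnnotatedVariant(v, flags or RoleFlags(), stab, cons)


class TestClassCounts:
    def test_empty_input_all_zero(self):
        c = class_counts([])
        assert c.n_total == c.n_union == 0

    def test_overlapping_flags_counted_once_in_union(self):
        flags = RoleFlags(at_conserved=True, alters_disulfide=True,
                          alters_ca_site=True)
        c = class_counts([_annotated(5, flags=flags)])
        assert c.n_union == 1
        assert (c.n_conserved, c.n_disulfide, c.n_ca) == (1, 1, 1)

    def test_union_inequality_and_partition(self):
        rng = np.random.default_rng(9)
        records = []
        for i in range(200):
            flags = RoleFlags(at_conserved=bool(rng.random() < 0.4),
                              alters_disulfide=bool(rng.random() < 0.2),
                              alters_ca_site=bool(rng.random() < 0.15))
            clin = ("pathogenic", "benign", "vus")[rng.integers(3)]
            records.append(_annotated(i + 1, clin=clin, flags=flags,
                                      extra=float(rng.normal()),
                                      endo=float(rng.normal())))
        c = class_counts(records)
        assert c.n_union <= c.n_conserved + c.n_disulfide + c.n_ca
        assert c.n_union <= c.n_total
        assert sum(c.n_by_clinical.values()) == c.n_total
        assert sum(c.n_delta.values()) == c.n_total  # all records complete

    def test_partial_records_excluded_from_delta(self):
        records = [_annotated(1, extra=1.0, endo=None),
                   _annotated(2, extra=5.0, endo=0.5)]
        c = class_counts(records)
        assert sum(c.n_delta.values()) == 1

    def test_domain_filter(self, domain_map):
        inside = _annotated(30)    # LA1 spans 25..64
        outside = _annotated(660)  # EGF3
        c = class_counts([inside, outside], domain_map, "classA")
        assert c.n_total == 1


class TestCoverage:
    def test_full_and_empty(self, domain_map):
        spans = [(e.start, e.end)
                 for e in domain_map.entries_of_class("classA")]
        all_positions = [p for s, e in spans for p in range(s, e + 1)]
        full = [_annotated(p) for p in all_positions]
        assert residue_coverage(full, domain_map) == 1.0
        assert residue_coverage([], domain_map) == 0.0

    def test_matches_position_set_oracle(self, domain_map):
        rng = np.random.default_rng(3)
        records = [_annotated(int(rng.integers(1, 700)), alt="T")
                   for _ in range(150)]
        spans = [(e.start, e.end)
                 for e in domain_map.entries_of_class("classA")]
        hit = {r.variant.change.position for r in records
               if any(s <= r.variant.change.position <= e for s, e in spans)}
        total = sum(e - s + 1 for s, e in spans)
        assert residue_coverage(records, domain_map) == len(hit) / total


class TestDistributionCompare:
    def test_identical_distributions_p_near_one(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=30)
        records = [_annotated(100 * j + i + 1, clin=c, extra=float(v),
                              endo=0.0, alt="T")
                   for j, (c, arr) in enumerate((("pathogenic", vals),
                                                 ("vus", vals)))
                   for i, v in enumerate(arr)]
        out = ddg_distribution_compare(records, group_by_domain=False)
        p = out[0].tests["pathogenic_vs_vus"]["p"]
        assert p > 0.8

    def test_planted_shift_detected_per_class(self):
        rng = np.random.default_rng(0)
        records = []
        for i in range(50):
            records.append(_annotated(i + 1, clin="pathogenic",
                                      extra=float(rng.normal(3.0, 1.0)),
                                      endo=0.0))
        for i in range(50):
            records.append(_annotated(i + 101, clin="benign",
                                      extra=float(rng.normal(0.0, 1.0)),
                                      endo=0.0))
        out = ddg_distribution_compare(records, group_by_domain=False)
        assert out[0].tests["pathogenic_vs_benign"]["p"] < 0.001
        assert out[0].frac_exceeding["pathogenic"] > \
            out[0].frac_exceeding["benign"]

    def test_empty_class_skipped(self):
        records = [_annotated(i + 1, clin="vus", extra=1.0, endo=0.0)
                   for i in range(5)]
        out = ddg_distribution_compare(records, group_by_domain=False)
        assert "skipped" in out[0].tests["pathogenic_vs_vus"]


class TestConservationAssociation:
    def test_monotone_relation_gives_rho_one(self):
        records = [_annotated(i + 1, extra=float(i), endo=0.0,
                              cons=float(i) / 10)
                   for i in range(20)]
        out = conservation_vs_stability(records)
        assert out["overall"]["vs_condition_delta"]["rho"] == \
            pytest.approx(1.0)

    def test_independent_values_give_small_rho(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            records = [_annotated(i + 1, extra=float(rng.normal()),
                                  endo=0.0, cons=float(rng.normal()))
                       for i in range(200)]
            out = conservation_vs_stability(records)
            if abs(out["overall"]["vs_condition_delta"]["rho"]) < 0.2:
                hits += 1
        assert hits >= 19  # |rho| < 0.2 in >= 95% of seeded runs

    def test_domain_split_counts_partition(self, domain_map):
        rng = np.random.default_rng(2)
        records = [_annotated(int(p), extra=float(rng.normal()), endo=0.0,
                              cons=float(rng.normal()), alt="T")
                   for p in rng.integers(1, 840, size=100)]
        out = conservation_vs_stability(records, domain_map)
        # per-class subsets never exceed the overall count
        assert all(out[k]["n"] <= out["overall"]["n"] for k in out)


class TestReport:
    def _records(self):
        rng = np.random.default_rng(4)
        out = []
        for i in range(30):
            flags = RoleFlags(at_conserved=bool(rng.random() < 0.5))
            out.append(_annotated(i + 25, clin="vus", flags=flags,
                                  extra=float(rng.normal()),
                                  endo=float(rng.normal())))
        return out

    def test_two_runs_byte_identical(self, tmp_path, domain_map):
        records = self._records()
        p1 = generate_report(records, tmp_path / "a", domain_map=domain_map)
        p2 = generate_report(records[::-1], tmp_path / "b",
                             domain_map=domain_map)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_empty_variant_set_is_valid(self, tmp_path):
        paths = generate_report([], tmp_path / "empty")
        summary = json.loads(paths["summary"].read_text())
        assert summary["n_total"] == 0

    def test_row_count_equals_unique_variants(self, tmp_path):
        records = self._records()
        paths = generate_report(records, tmp_path / "rows")
        lines = [l for l in paths["variants"].read_text().splitlines()
                 if l and not l.startswith("#")]
        assert len(lines) - 1 == len(records)  # header + one row per variant
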