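"""Statistics against hand computations and brute-force enumeration."""

import itertools

import numpy as np
import pytest
from scipy import stats

from octseg.errors import (
    ComparabilityError,
    DegenerateInputError,
    ValidationError,
)
from octseg.io import GraderAnnotationSet, LayerBoundary
from octseg.metrics import (
    concordance_correlation,
    delta_bl,
    inter_grader_reproducibility,
    method_agreement,
    reproducibility_comparison,
    scatter_report,
    wilcoxon_signed_rank,
)


def flat_boundary(row, width=20, layer="ILM", frame=0):
    return LayerBoundary(layer, frame, np.full(width, float(row)))


def grader_set(offsets_by_layer, grader_id, method="manual", width=20):
    boundaries = [
        flat_boundary(10 + off, width=width, layer=layer)
        for layer, off in offsets_by_layer.items()
    ]
    return GraderAnnotationSet(method, grader_id, boundaries, volume_id="v1")


class TestDeltaBL:
    def test_identical_boundaries_zero(self):
        a = flat_boundary(12)
        assert np.nanmax(delta_bl(a, flat_boundary(12), 3.87)) == 0.0

    def test_offset_scaling(self):
        d = delta_bl(flat_boundary(10), flat_boundary(12), 3.87)
        assert np.allclose(d[np.isfinite(d)], 7.74)

    def test_matches_columnwise_oracle_and_symmetry(self, rng):
        a = LayerBoundary("ILM", 0, rng.uniform(0, 50, 30))
        b = LayerBoundary("ILM", 0, rng.uniform(0, 50, 30))
        d = delta_bl(a, b, 2.5)
        assert np.allclose(d, np.abs(a.positions - b.positions) * 2.5)
        assert np.allclose(d, delta_bl(b, a, 2.5))

    def test_triangle_inequality(self, rng):
        a, b, c = (LayerBoundary("ILM", 0, rng.uniform(0, 50, 30)) for _ in range(3))
        ac = delta_bl(a, c, 1.0)
        ab = delta_bl(a, b, 1.0)
        bc = delta_bl(b, c, 1.0)
        assert np.all(ac <= ab + bc + 1e-12)

    def test_mismatched_layer_rejected(self):
        with pytest.raises(ComparabilityError):
            delta_bl(flat_boundary(1, layer="ILM"), flat_boundary(1, layer="BM"), 1.0)

    def test_no_common_columns_warns(self):
        a = LayerBoundary("ILM", 0, np.array([1.0, np.nan, 1.0, np.nan]))
        b = LayerBoundary("ILM", 0, np.array([np.nan, 1.0, np.nan, 1.0]))
        with pytest.warns(UserWarning):
            d = delta_bl(a, b, 1.0)
        assert np.all(np.isnan(d))


class TestConcordance:
    def test_perfect_concordance(self):
        x = [1.0, 2.0, 3.0, 7.0]
        assert concordance_correlation(x, x) == pytest.approx(1.0)

    def test_perfect_discordance(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])
        assert concordance_correlation(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # x=(1,2,3,4), y=x+0.5: 2*1.25 / (1.25+1.25+0.25) = 10/11
        assert concordance_correlation(
            [1, 2, 3, 4], [1.5, 2.5, 3.5, 4.5]
        ) == pytest.approx(10.0 / 11.0)

    def test_bounded_by_pearson(self, rng):
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.normal(size=12) + 0.5 * x
            ccc = concordance_correlation(x, y)
            assert abs(ccc) <= abs(stats.pearsonr(x, y)[0]) + 1e-12

    def test_equals_pearson_when_moments_match(self, rng):
        x = rng.normal(size=200)
        y = np.roll(x, 1)  # same mean and variance
        assert concordance_correlation(x, y) == pytest.approx(
            stats.pearsonr(x, y)[0] * x.var() / (0.5 * (x.var() + y.var())), rel=1e-9
        )

    def test_degenerate_raises(self):
        with pytest.raises(DegenerateInputError):
            concordance_correlation([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])


def exact_p_enumeration(diffs):
    """Two-sided p by enumerating all sign patterns with midranks."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    n = len(d)
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.array(ws)
    lower = np.mean(ws <= w_plus + 1e-9)
    upper = np.mean(ws >= w_plus - 1e-9)
    return min(1.0, 2.0 * min(lower, upper))


class TestWilcoxon:
    def test_all_positive_closed_form(self):
        stat, p = wilcoxon_signed_rank([1, 2, 3, 4, 5])
        assert stat == 0.0
        assert p == pytest.approx(2.0 / 2**5)

    def test_antisymmetric_p_is_one(self):
        _, p = wilcoxon_signed_rank([-1, 1, -2, 2])
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            d = np.round(rng.normal(size=10) * 4) / 2.0
            if np.all(d == 0):
                continue
            _, p = wilcoxon_signed_rank(d)
            assert p == pytest.approx(exact_p_enumeration(d), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(10):
            d = rng.normal(size=12)
            _, p = wilcoxon_signed_rank(d)
            assert p == pytest.approx(
                stats.wilcoxon(d, method="exact").pvalue, abs=1e-12
            )

    def test_exact_distribution_sums_to_one(self):
        # the DP used for the exact p covers all 2^n patterns
        from octseg.metrics import _signed_ranks

        d = np.array([1.0, 2.0, 2.0, 3.0, 5.0])
        ranks = _signed_ranks(d)
        doubled = np.round(2 * ranks).astype(int)
        total = doubled.sum()
        counts = np.zeros(total + 1)
        counts[0] = 1
        for r in doubled:
            counts[r:] += counts[: total + 1 - r]
        assert counts.sum() == 2 ** len(d)

    def test_large_n_normal_approximation(self, rng):
        d = rng.normal(0.3, 1.0, size=60)
        _, p = wilcoxon_signed_rank(d)
        ref = stats.wilcoxon(d, method="approx", correction=False).pvalue
        assert p == pytest.approx(ref, rel=1e-6)

    def test_all_zero_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            wilcoxon_signed_rank([0.0, 0.0])


class TestReproducibility:
    def test_identical_graders_zero(self):
        sets = {"v1": [grader_set({"ILM": 0}, f"g{i}") for i in range(3)]}
        report = inter_grader_reproducibility(sets, 1.0)
        layer = report.per_layer["ILM"]
        assert layer.mean_um == 0.0
        assert layer.sd_um == 0.0
        assert all(v == 0.0 for v in layer.per_volume_um.values())

    def test_constant_offsets_give_four_thirds(self):
        # graders at 0, +1, +2 px with 1 um spacing: pairwise 1, 2, 1 -> 4/3
        sets = {
            "v1": [grader_set({"ILM": off}, f"g{off}") for off in (0, 1, 2)]
        }
        report = inter_grader_reproducibility(sets, 1.0)
        assert report.per_layer["ILM"].per_volume_um["v1"] == pytest.approx(4.0 / 3.0)

    def test_pairwise_stat_twice_deviation_from_mean_two_graders(self):
        # constant offset: each grader deviates d/2 from the grader mean,
        # while the pairwise statistic is d
        sets = {"v1": [grader_set({"ILM": 0}, "g1"), grader_set({"ILM": 3}, "g2")]}
        report = inter_grader_reproducibility(sets, 1.0)
        assert report.per_layer["ILM"].per_volume_um["v1"] == pytest.approx(2 * 1.5)

    def test_matches_nested_loop_oracle(self, rng):
        width = 15
        graders = []
        for g in range(3):
            positions = rng.uniform(10, 20, size=width)
            graders.append(
                GraderAnnotationSet(
                    "manual", f"g{g}",
                    [LayerBoundary("ILM", 0, positions)], volume_id="v1",
                )
            )
        report = inter_grader_reproducibility({"v1": graders}, 2.0)
        acc = []
        for i in range(3):
            for j in range(i + 1, 3):
                for c in range(width):
                    acc.append(
                        abs(
                            graders[i].boundaries[0].positions[c]
                            - graders[j].boundaries[0].positions[c]
                        )
                        * 2.0
                    )
        assert report.per_layer["ILM"].per_volume_um["v1"] == pytest.approx(np.mean(acc))

    def test_single_grader_rejected(self):
        with pytest.raises(ValidationError):
            inter_grader_reproducibility({"v1": [grader_set({"ILM": 0}, "g1")]}, 1.0)


class TestAgreement:
    def _sets(self, shift):
        manual = {
            "v1": [grader_set({"ILM": 0}, "g1"), grader_set({"ILM": 1}, "g2")],
            "v2": [grader_set({"ILM": 2}, "g1"), grader_set({"ILM": 3}, "g2")],
        }
        edge = {
            vol: [
                GraderAnnotationSet(
                    "edgeselect",
                    s.grader_id,
                    [
                        LayerBoundary(
                            b.layer, b.frame_index, b.positions + shift
                        )
                        for b in s.boundaries
                    ],
                    volume_id=s.volume_id,
                )
                for s in sets
            ]
            for vol, sets in manual.items()
        }
        return manual, edge

    def test_identical_methods_degenerate(self):
        manual, edge = self._sets(0.0)
        report = method_agreement(manual, edge, 1.0)
        layer = report.per_layer["ILM"]
        assert layer.mean_um == 0.0
        assert layer.degenerate and layer.p_value == 1.0

    def test_constant_shift(self):
        manual, edge = self._sets(1.0)
        report = method_agreement(manual, edge, 1.0)
        layer = report.per_layer["ILM"]
        assert layer.mean_um == pytest.approx(1.0)
        assert layer.sd_um == pytest.approx(0.0)

    def test_matches_pixelwise_oracle(self, rng):
        width = 20
        manual, edge = {}, {}
        for vol in ("v1", "v2", "v3"):
            manual[vol] = [
                GraderAnnotationSet(
                    "manual", f"g{g}",
                    [LayerBoundary("ILM", 0, rng.uniform(5, 15, width))],
                    volume_id=vol,
                )
                for g in range(2)
            ]
            edge[vol] = [
                GraderAnnotationSet(
                    "edgeselect", f"g{g}",
                    [LayerBoundary("ILM", 0, rng.uniform(5, 15, width))],
                    volume_id=vol,
                )
                for g in range(2)
            ]
        report = method_agreement(manual, edge, 3.0)
        for vol in manual:
            mean_m = np.mean([s.boundaries[0].positions for s in manual[vol]], axis=0)
            mean_e = np.mean([s.boundaries[0].positions for s in edge[vol]], axis=0)
            expected = np.mean(np.abs(mean_m - mean_e)) * 3.0
            assert report.per_layer["ILM"].per_volume_um[vol] == pytest.approx(expected)

    def test_grader_mismatch_rejected(self):
        manual, edge = self._sets(1.0)
        edge["v1"] = edge["v1"][:1] + [
            GraderAnnotationSet(
                "edgeselect", "g9", edge["v1"][1].boundaries, volume_id="v1"
            )
        ]
        with pytest.raises(ValidationError):
            method_agreement(manual, edge, 1.0)


class TestScatterReport:
    def test_figures_written_and_deterministic(self, tmp_path, rng):
        vols = [f"v{i}" for i in range(4)]
        manual = {
            v: [
                grader_set({"ILM": 0, "ISe": 0, "RPE": 0, "BM": 0}, "g1"),
                grader_set({"ILM": i % 3, "ISe": 1, "RPE": 2, "BM": 1}, "g2"),
            ]
            for i, v in enumerate(vols)
        }
        edge = {
            v: [
                GraderAnnotationSet("edgeselect", "g1", manual[v][0].boundaries, volume_id=v),
                GraderAnnotationSet("edgeselect", "g2", manual[v][0].boundaries, volume_id=v),
            ]
            for v in vols
        }
        rep_m = inter_grader_reproducibility(manual, 1.0)
        rep_e = inter_grader_reproducibility(edge, 1.0)
        agreement = method_agreement(manual, edge, 1.0)
        written = scatter_report(rep_m, rep_e, agreement, tmp_path)
        assert len(written) == 2
        assert all(p.exists() and p.stat().st_size > 0 for p in written)
        comparison = reproducibility_comparison(rep_m, rep_e)
        assert set(comparison["layer"]) == {"ILM", "ISe", "RPE", "BM"}
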