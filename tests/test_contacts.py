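"""log-transform/cutoff selection and the restrained distance graph."""

import numpy as np
import pytest

from metalocus.contacts import (ContactMatrix, auto_cutoff,
                                build_distance_graph, transform_and_select)
from metalocus.regions import LocusRegion
from metalocus.synth import make_locus


def region_of(n, res=10_000):
    return LocusRegion(chrom="chrT", start=0, end=n * res, resolution=res,
                       anchor_index=n // 2)


def matrix_from(values, **kw):
    values = np.asarray(values, dtype=float)
    return ContactMatrix(region=region_of(values.shape[0]), values=values,
                         **kw)


class TestTransformAndSelect:
    def test_boundary_score_retained_below_dropped(self):
        # value 10 -> score exactly 1.0, kept; 9.999 -> score < 1, dropped
        vals = np.full((5, 5), 100.0)
        vals[0, 1] = vals[1, 0] = 10.0
        vals[0, 2] = vals[2, 0] = 9.999
        out = transform_and_select(matrix_from(vals), cutoff=1.0)
        assert out.values[0, 1] == pytest.approx(1.0)
        assert np.isnan(out.values[0, 2])

    def test_zero_treated_as_absent_not_minus_inf(self):
        vals = np.full((5, 5), 100.0)
        vals[1, 3] = vals[3, 1] = 0.0
        out = transform_and_select(matrix_from(vals), cutoff=-10.0)
        assert np.isnan(out.values[1, 3])
        assert np.all(np.isfinite(out.values[np.nonzero(vals)]))

    def test_retained_count_matches_brute_force(self, null_locus):
        cm, _, _ = null_locus
        cutoff = 1.0
        out = transform_and_select(cm, cutoff=cutoff)
        # independent filter: count entries with log10(v) >= cutoff
        expected = int(np.sum(np.log10(cm.values[cm.values > 0]) >= cutoff))
        assert int(np.isfinite(out.values).sum()) == expected

    def test_idempotent(self, null_locus):
        cm, _, _ = null_locus
        once = transform_and_select(cm, cutoff=1.0)
        twice = transform_and_select(once, cutoff=1.0)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_all_dropped_warns_and_keeps_backbone_path(self):
        vals = np.full((6, 6), 2.0)  # scores ~0.3 < 1.0 everywhere
        with pytest.warns(UserWarning, match="backbone"):
            out = transform_and_select(matrix_from(vals), cutoff=1.0)
        dg = build_distance_graph(out)
        assert dg.graph.number_of_edges() == 5  # chain only


class TestAutoCutoff:
    def test_degenerate_all_equal_returns_min_score(self):
        vals = np.full((6, 6), 50.0)
        with pytest.warns(UserWarning, match="degenerate"):
            c = auto_cutoff(matrix_from(vals))
        assert c == pytest.approx(np.log10(50.0))

    def test_bimodal_cutoff_between_modes_and_matches_sweep(self):
        # noise mode at score ~0.5, signal mode at score ~2.5
        rng = np.random.default_rng(0)
        n = 40
        vals = 10 ** (0.5 + 0.05 * rng.standard_normal((n, n)))
        sig_mask = rng.random((n, n)) < 0.1
        vals[sig_mask] = 10 ** (2.5 + 0.05 * rng.standard_normal(sig_mask.sum()))
        vals = np.triu(vals) + np.triu(vals, 1).T
        cm = matrix_from(vals)
        c = auto_cutoff(cm)
        assert 0.5 < c < 2.5
        # exhaustive sweep of the documented rule, coded independently
        scores = np.log10(vals[~np.eye(n, dtype=bool)])
        grid = [k * 0.05 for k in range(-100, 100)]
        feasible = [g for g in grid
                    if np.mean(scores >= g) <= 0.15]
        expected = max(min(feasible), float(np.median(scores)))
        assert c == pytest.approx(expected, abs=1e-12)

    def test_scaling_by_ten_shifts_cutoff_by_one(self, null_locus):
        cm, _, _ = null_locus
        c1 = auto_cutoff(cm)
        c10 = auto_cutoff(ContactMatrix(region=cm.region,
                                        values=cm.values * 10.0,
                                        bad_bins=cm.bad_bins))
        assert c10 == pytest.approx(c1 + 1.0, abs=1e-9)

    def test_deterministic(self, null_locus):
        cm, _, _ = null_locus
        assert auto_cutoff(cm) == auto_cutoff(cm)


class TestDistanceGraph:
    def test_inverse_score_distance(self):
        vals = np.full((10, 10), 5.0)
        vals[3, 7] = vals[7, 3] = 100.0  # score 2.0
        cm = transform_and_select(matrix_from(vals), cutoff=2.0)
        dg = build_distance_graph(cm, persistence_length=10.0)
        assert dg.graph[3][7]["distance"] == pytest.approx(0.5)

    def test_backbone_only_chain_edge_count(self):
        vals = np.full((10, 10), 2.0)  # everything below cutoff
        with pytest.warns(UserWarning):
            cm = transform_and_select(matrix_from(vals), cutoff=1.0)
        dg = build_distance_graph(cm)
        assert dg.graph.number_of_edges() == 9
        assert all(d["kind"] == "backbone"
                   for _, _, d in dg.graph.edges(data=True))

    def test_symmetric_no_self_edges(self, null_locus):
        cm, _, _ = null_locus
        dg = build_distance_graph(transform_and_select(cm, 1.0))
        assert all(a != b for a, b in dg.graph.edges)
        for a, b in dg.graph.edges:
            assert dg.graph.has_edge(b, a)

    def test_bad_bins_excluded_and_gap_rejoined(self):
        cm, _, _ = make_locus(seed=2, n_bins=31, bad_bins={10, 11})
        dg = build_distance_graph(transform_and_select(cm, 1.0))
        assert 10 not in dg.graph and 11 not in dg.graph
        assert dg.graph.has_edge(9, 12)
        assert (9, 12) in dg.gap_joined

    def test_backbone_stiffer_than_any_contact(self, null_locus):
        cm, _, _ = null_locus
        dg = build_distance_graph(transform_and_select(cm, 1.0),
                                  persistence_length=10.0)
        contact = [d["distance"] for _, _, d in dg.graph.edges(data=True)
                   if d["kind"] == "contact"]
        backbone = [d["distance"] for _, _, d in dg.graph.edges(data=True)
                    if d["kind"] == "backbone"]
        assert max(backbone) <= min(contact)

    def test_requires_transformed_matrix(self, null_locus):
        cm, _, _ = null_locus
        with pytest.raises(ValueError, match="transform"):
            build_distance_graph(cm)


def test_persistence_length_controls_straightness():
    """High stiffness straightens the chain; low stiffness lets contacts
    fold it into a zig-zag."""
    from metalocus.layout import compute_layout

    cm, _, _ = make_locus(seed=5, noise_cv=0.0, n_bins=41)
    cmt = transform_and_select(cm, 1.0)
    pls = (0.5, 10.0, 1000.0)
    straightness = {}
    for pl in pls:
        _, P = compute_layout(build_distance_graph(cmt, persistence_length=pl))
        steps = np.linalg.norm(np.diff(P, axis=0), axis=1)
        straightness[pl] = np.linalg.norm(P[-1] - P[0]) / steps.sum()
    assert straightness[1000.0] > 0.95
    assert straightness[0.5] < 0.6
    assert straightness[0.5] <= straightness[10.0] <= straightness[1000.0]


def test_asymmetric_matrix_rejected():
    vals = np.full((5, 5), 2.0)
    vals[0, 1] = 99.0
    with pytest.raises(ValueError, match="symmetric"):
        matrix_from(vals)
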