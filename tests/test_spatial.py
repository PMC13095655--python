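"""Distance-band weights, Local Moran's I vs an independent oracle,
permutation significance, and metalocus calling."""

import numpy as np
import pandas as pd
import pytest

import metalocus as ml
from metalocus.spatial import (build_weights, call_metaloci, global_morans_i,
                               lmi_analysis, local_moran,
                               permutation_significance)

from conftest import chain_layout, random_layout


# --------------------------------------------------------------------------
# independent oracle: plain-python evaluation of the statistic


def lmi_oracle(values, coords, band):
    """Direct evaluation: z from population moments, binary distance-band
    weights, lag = row-normalized weighted sum.  Coded with explicit loops,
    independent of the package's vectorized path."""
    x = list(map(float, values))
    n = len(x)
    mean = sum(x) / n
    sd = (sum((v - mean) ** 2 for v in x) / n) ** 0.5
    z = [(v - mean) / sd for v in x]
    out = []
    for i in range(n):
        num, den = 0.0, 0.0
        for j in range(n):
            if i == j:
                continue
            dist = ((coords[i][0] - coords[j][0]) ** 2
                    + (coords[i][1] - coords[j][1]) ** 2) ** 0.5
            if dist <= band * (1 + 1e-9):
                num += z[j]
                den += 1.0
        out.append(z[i] * num / den if den else float("nan"))
    return out


class TestWeights:
    def test_chain_interior_neighbors_three_each_side(self):
        gl = chain_layout(30, step=2.0)
        w = build_weights(gl, band_multiplier=3.0)
        for i in range(3, 27):
            assert set(w.neighbors[i]) == {i - 3, i - 2, i - 1,
                                           i + 1, i + 2, i + 3}
        # guarantee: at least two up- and downstream neighbors for interiors
        assert all(len(w.neighbors[i]) >= 4 for i in range(2, 28))

    def test_symmetric_binary_zero_diagonal(self, analyzed_hub):
        W = analyzed_hub.weights.dense()
        np.testing.assert_array_equal(W, W.T)
        assert set(np.unique(W)) <= {0.0, 1.0}
        assert np.all(np.diag(W) == 0)

    def test_scale_free_neighbor_sets(self):
        from dataclasses import replace
        gl = random_layout(40, seed=1)
        w1 = build_weights(gl)
        gl2 = replace(gl, coords=gl.coords * 2.0, mean_step=gl.mean_step * 2,
                      buffer_distance=gl.buffer_distance * 2)
        w2 = build_weights(gl2)
        for a, b in zip(w1.neighbors, w2.neighbors):
            assert set(a) == set(b)

    def test_isolated_bin_flagged(self):
        coords = np.column_stack([np.arange(6, dtype=float), np.zeros(6)])
        coords[5] = [100.0, 100.0]
        gl = chain_layout(6)
        from dataclasses import replace
        gl = replace(gl, coords=coords)
        with pytest.warns(UserWarning, match="isolated"):
            w = build_weights(gl)
        assert len(w.neighbors[5]) == 0
        x = np.random.default_rng(0).random(6)
        p = permutation_significance(x, w, n_perm=99, seed=0)
        assert np.isnan(p[5]) and np.isfinite(p[:5]).all()


class TestLocalMoran:
    def test_constant_signal_all_zero(self):
        gl = chain_layout(10)
        w = build_weights(gl)
        with pytest.warns(UserWarning, match="constant"):
            df = local_moran(np.full(10, 3.0), w)
        np.testing.assert_array_equal(df["z"], 0.0)
        np.testing.assert_array_equal(df["lmi"], 0.0)
        assert (df["quadrant"] == "").all()

    def test_five_bin_toy_matches_hand_oracle(self):
        values = np.array([1.0, 1, 1, 10, 10])
        gl = chain_layout(5)
        w = build_weights(gl, band_multiplier=1.0)  # band covers +/-1 only
        df = local_moran(values, w)
        expected = lmi_oracle(values, gl.coords.tolist(), band=1.0)
        np.testing.assert_allclose(df["lmi"], expected, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_instances_match_oracle(self, seed):
        gl = random_layout(50, seed=seed)
        w = build_weights(gl)
        x = np.random.default_rng(100 + seed).standard_normal(50)
        df = local_moran(x, w)
        expected = lmi_oracle(x, gl.coords.tolist(), band=w.band)
        np.testing.assert_allclose(df["lmi"].to_numpy(), expected, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_mean_lmi_equals_global_moran(self, seed):
        gl = random_layout(60, seed=seed)
        w = build_weights(gl)
        x = np.random.default_rng(seed).standard_normal(60)
        lmi = local_moran(x, w)["lmi"].to_numpy()
        assert np.nanmean(lmi) == pytest.approx(global_morans_i(x, w),
                                                abs=1e-10)

    def test_quadrant_sign_consistency(self, analyzed_hub):
        df = analyzed_hub.lmi.table
        for _, r in df[df["quadrant"] != ""].iterrows():
            expected = {(True, True): "HH", (False, True): "LH",
                        (False, False): "LL", (True, False): "HL"}[
                (r["z"] > 0, r["lag"] > 0)]
            assert r["quadrant"] == expected


class TestPermutation:
    def test_deterministic_bit_for_bit(self):
        gl = random_layout(40, seed=2)
        w = build_weights(gl)
        x = np.random.default_rng(5).standard_normal(40)
        p1 = permutation_significance(x, w, n_perm=499, seed=42)
        p2 = permutation_significance(x, w, n_perm=499, seed=42)
        np.testing.assert_array_equal(p1, p2)

    def test_invariant_to_adding_constant(self):
        gl = random_layout(40, seed=3)
        w = build_weights(gl)
        x = np.random.default_rng(6).standard_normal(40)
        p1 = permutation_significance(x, w, n_perm=299, seed=0)
        p2 = permutation_significance(x + 100.0, w, n_perm=299, seed=0)
        np.testing.assert_array_equal(p1, p2)

    def test_per_bin_and_maxcard_modes_agree(self):
        # the denominator is constant per bin, so p-values coincide
        gl = random_layout(40, seed=4)
        w = build_weights(gl)
        x = np.random.default_rng(7).standard_normal(40)
        p1 = permutation_significance(x, w, n_perm=199, seed=0,
                                      mode="maximal_cardinality")
        p2 = permutation_significance(x, w, n_perm=199, seed=0,
                                      mode="per_bin")
        np.testing.assert_array_equal(p1, p2)

    def test_p_range_and_resolution(self):
        gl = chain_layout(20)
        w = build_weights(gl)
        x = np.random.default_rng(8).standard_normal(20)
        p = permutation_significance(x, w, n_perm=199, seed=0)
        assert np.all(p >= 1 / 200) and np.all(p <= 1.0)
        with pytest.warns(UserWarning, match="coarse"):
            permutation_significance(x, w, n_perm=50, seed=0)

    def test_planted_hub_bins_all_significant(self, hub_locus, analyzed_hub):
        _, _, truth = hub_locus
        hub = set(truth["hubs"][0]["member_bins"])
        df = analyzed_hub.lmi.table
        sub = df[df["bin"].isin(hub)]
        assert (sub["quadrant"] == "HH").all()
        assert (sub["p"] < 0.01).all()

    def test_linearity_mode_runs_and_differs(self):
        gl = chain_layout(40)
        w = build_weights(gl)
        x = np.random.default_rng(9).standard_normal(40)
        p_lin = permutation_significance(x, w, n_perm=199, seed=0,
                                         linearity=True)
        assert np.isfinite(p_lin).all()


class TestCallMetaloci:
    def test_no_significant_bins_empty_list(self):
        gl = chain_layout(20)
        w = build_weights(gl)
        x = np.random.default_rng(10).standard_normal(20)
        res = lmi_analysis(x, w, n_perm=199, seed=0, alpha=1e-6)
        assert call_metaloci(res, w) == []

    def test_hub_recovered_as_single_metalocus(self, hub_locus, analyzed_hub):
        _, _, truth = hub_locus
        hub = set(truth["hubs"][0]["member_bins"])
        ms = analyzed_hub.metaloci
        assert len(ms) == 1
        assert hub <= set(ms[0].core_bins)
        assert set(ms[0].halo_bins).isdisjoint(ms[0].core_bins)

    def test_halo_bins_adjacent_to_core(self, analyzed_hub):
        m = analyzed_hub.metaloci[0]
        w = analyzed_hub.weights
        pos = {int(b): k for k, b in enumerate(w.bins)}
        core_pos = {pos[b] for b in m.core_bins}
        for hb in m.halo_bins:
            assert set(w.neighbors[pos[hb]]) & core_pos

    def test_two_separated_clusters_give_two_metaloci(self):
        """Brute-force flood fill agrees with the component count."""
        gl = chain_layout(60)
        w = build_weights(gl)
        # fabricate a significant table: two far-apart HH blocks
        sig_blocks = [set(range(5, 9)), set(range(40, 44))]
        df = pd.DataFrame({
            "bin": np.arange(60), "z": 1.0, "lag": 1.0, "lmi": 1.0,
            "quadrant": "HH",
            "p": [0.001 if any(i in b for b in sig_blocks) else 0.9
                  for i in range(60)],
        })
        df["significant"] = df["p"] < 0.05
        table = ml.LmiTable(table=df, alpha=0.05)
        ms = call_metaloci(table, w)
        # oracle: flood fill over the +/-3 chain adjacency
        sig = sorted(sig_blocks[0] | sig_blocks[1])
        comps, cur = [], [sig[0]]
        for a, b in zip(sig, sig[1:]):
            if b - a <= 3:
                cur.append(b)
            else:
                comps.append(cur)
                cur = [b]
        comps.append(cur)
        assert len(ms) == len(comps) == 2
        assert [m.core_bins for m in ms] == comps

    def test_noncontiguous_sequence_intervals(self, hub_locus):
        """A metalocus spanning sequence-separated bins exports multiple
        genomic intervals."""
        cm, sig, truth = hub_locus
        res = ml.analyze_locus(cm, sig, ml.PipelineConfig(n_perm=999, seed=1))
        m = res.metaloci[0]
        runs = 1
        members = m.member_bins
        for a, b in zip(members, members[1:]):
            if b - a > 1:
                runs += 1
        assert len(m.genomic_intervals) == runs
        for chrom, s, e in m.genomic_intervals:
            assert chrom == cm.region.chrom and s < e


def test_bh_adjustment_never_adds_calls():
    gl = random_layout(60, seed=6)
    w = build_weights(gl)
    x = np.random.default_rng(12).standard_normal(60)
    plain = lmi_analysis(x, w, n_perm=199, seed=0)
    bh = lmi_analysis(x, w, n_perm=199, seed=0, adjust="bh")
    assert set(np.where(bh.table["significant"])[0]) <= \
        set(np.where(plain.table["significant"])[0])
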