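"""MI statistics vs brute-force oracles; APC; network; SDP classification."""

import itertools
import math
from collections import Counter

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from sdpnet import (
    CladeAssignment,
    apc_correct,
    build_network,
    clade_mi,
    classify_sdps,
    identify_cdps,
    mi_zscores,
    pairwise_mi,
)
from sdpnet.errors import CladeError, SdpnetError
from sdpnet.network import MIMatrix

from conftest import make_msa


# --- independent brute-force oracle ---------------------------------------

def oracle_mi(xs, ys):
    """Plug-in MI in bits from two symbol sequences, via joint frequencies."""
    n = len(xs)
    joint = Counter(zip(xs, ys))
    px = Counter(xs)
    py = Counter(ys)
    mi = 0.0
    for (x, y), c in joint.items():
        pxy = c / n
        mi += pxy * math.log2(pxy / ((px[x] / n) * (py[y] / n)))
    return mi


def random_msa(rng, n_rows=8, n_cols=12, alphabet="ACDG-"):
    rows = {
        f"s{i}": "".join(rng.choice(list(alphabet), size=n_cols))
        for i in range(n_rows)
    }
    # ensure no all-gap column (keeps MSA generic, oracle is unaffected)
    return make_msa(rows)


class TestCladeMI:
    def test_distinct_fixed_residues_give_log2_k(self):
        rows, asg = {}, {}
        for k, res in enumerate("DNEK"):
            for j in range(5):
                sid = f"c{k}s{j}"
                rows[sid] = res
                asg[sid] = f"clade{k}"
        msa = make_msa(rows)
        mi = clade_mi(msa, CladeAssignment(asg), 1)
        assert mi == pytest.approx(math.log2(4), abs=1e-12)

    def test_identical_column_gives_zero(self):
        msa = make_msa({f"s{i}": "W" for i in range(6)})
        asg = CladeAssignment({f"s{i}": "I" if i < 3 else "II" for i in range(6)})
        assert clade_mi(msa, asg, 1) == pytest.approx(0.0, abs=1e-12)

    def test_hand_joint_table(self):
        msa = make_msa({"a": "D", "b": "D", "c": "N", "d": "N", "e": "N", "f": "N"})
        asg = CladeAssignment({s: ("I" if s in "abc" else "II") for s in "abcdef"})
        expected = oracle_mi("DDNNNN", ["I"] * 3 + ["II"] * 3)
        assert clade_mi(msa, asg, 1) == pytest.approx(expected, abs=1e-12)

    def test_single_clade_rejected(self):
        msa = make_msa({"a": "D", "b": "N"})
        with pytest.raises(CladeError):
            clade_mi(msa, CladeAssignment({"a": "I", "b": "I"}), 1)

    def test_gap_is_a_symbol(self):
        msa = make_msa({"a": "-", "b": "-", "c": "A", "d": "A"})
        asg = CladeAssignment({"a": "I", "b": "I", "c": "II", "d": "II"})
        assert clade_mi(msa, asg, 1) == pytest.approx(1.0, abs=1e-12)

    def test_matches_oracle_on_random_msas(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            msa = random_msa(rng)
            labels = rng.choice(["I", "II"], size=8)
            while len(set(labels)) < 2 or min(Counter(labels).values()) < 2:
                labels = rng.choice(["I", "II"], size=8)
            asg = CladeAssignment(dict(zip(msa.ids, labels)))
            for col in range(1, 13):
                expected = oracle_mi(msa.column(col), labels)
                assert clade_mi(msa, asg, col) == pytest.approx(expected, abs=1e-9)


class TestPairwiseMI:
    def test_perfect_two_state_covariation_is_one_bit(self):
        msa = make_msa({"a": "AC", "b": "AC", "c": "GT", "d": "GT"})
        mim = pairwise_mi(msa)
        assert mim.mi_raw[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_constant_column_gives_zero(self):
        msa = make_msa({"a": "AC", "b": "AC", "c": "GC", "d": "TC"})
        assert pairwise_mi(msa).mi_raw[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_entropy_decomposition_by_hand(self):
        msa = make_msa({"a": "AA", "b": "AA", "c": "VC", "d": "VC"})
        # pairs (A,A),(A,A),(V,C),(V,C): H(X)=1, H(Y)=1, H(X,Y)=1
        assert pairwise_mi(msa).mi_raw[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_oracle_on_random_msas(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            msa = random_msa(rng)
            mim = pairwise_mi(msa)
            for i, j in itertools.combinations(range(12), 2):
                expected = oracle_mi(msa.column(i + 1), msa.column(j + 1))
                assert mim.mi_raw[i, j] == pytest.approx(expected, abs=1e-9)

    def test_entropy_bound(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            msa = random_msa(rng, n_rows=12, n_cols=6)
            mim = pairwise_mi(msa)
            for i, j in itertools.combinations(range(6), 2):
                hx = oracle_mi(msa.column(i + 1), msa.column(i + 1))
                hy = oracle_mi(msa.column(j + 1), msa.column(j + 1))
                assert mim.mi_raw[i, j] <= min(hx, hy) + 1e-12

    def test_pseudocount_shrinks_toward_independence(self):
        msa = make_msa({"a": "AC", "b": "AC", "c": "GT", "d": "GT"})
        raw = pairwise_mi(msa).mi_raw[0, 1]
        smoothed = pairwise_mi(msa, pseudocount=0.5).mi_raw[0, 1]
        assert 0 < smoothed < raw

    def test_weights_change_the_estimate(self):
        msa = make_msa({"a": "AC", "b": "AC", "c": "GT", "d": "GC"})
        unweighted = pairwise_mi(msa).mi_raw[0, 1]
        weighted = pairwise_mi(msa, weights=np.array([1, 1, 1, 10.0])).mi_raw[0, 1]
        assert weighted != pytest.approx(unweighted, abs=1e-6)


class TestAPC:
    def test_uniform_mi_cancels_exactly(self):
        m = 5
        mi = np.full((m, m), 0.7)
        np.fill_diagonal(mi, 0.0)
        mim = apc_correct(MIMatrix(columns=np.arange(1, m + 1), mi_raw=mi))
        iu = np.triu_indices(m, k=1)
        assert np.allclose(mim.mi_apc[iu], 0.0, atol=1e-12)

    def test_strong_pair_survives_correction(self):
        rng = np.random.default_rng(5)
        n, m = 200, 20
        data = rng.choice(list("ACDEFGHIKL"), size=(n, m))
        data[:, 3] = data[:, 11]  # perfectly covarying pair
        msa = make_msa({f"s{i}": "".join(r) for i, r in enumerate(data)})
        mim = apc_correct(pairwise_mi(msa))
        # most of the raw signal survives, and it dwarfs the corrected
        # background (which APC centers near zero)
        assert mim.mi_apc[3, 11] > 0.7 * mim.mi_raw[3, 11]
        background = [
            mim.mi_apc[i, j]
            for i, j in itertools.combinations(range(m), 2)
            if (i, j) != (3, 11)
        ]
        assert mim.mi_apc[3, 11] > 10 * max(background)

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        msa = random_msa(rng, n_rows=10, n_cols=8)
        mim = apc_correct(pairwise_mi(msa))
        assert np.allclose(mim.mi_apc, mim.mi_apc.T)

    def test_too_few_columns_rejected(self):
        msa = make_msa({"a": "AC", "b": "GT"})
        with pytest.raises(SdpnetError):
            apc_correct(pairwise_mi(msa))


class TestZScores:
    def test_planted_pair_has_extreme_z(self):
        rng = np.random.default_rng(21)
        n, m = 240, 15
        data = rng.choice(list("ACDEFGHIKL"), size=(n, m))
        data[:, 2] = data[:, 9]
        msa = make_msa({f"s{i}": "".join(r) for i, r in enumerate(data)})
        mim = mi_zscores(msa, n_perm=50, seed=0)
        assert mim.z[2, 9] >= 6.5

    def test_constant_columns_flagged_degenerate(self):
        rows = {f"s{i}": "AAC"[0:2] + "ACGT"[i % 4] for i in range(8)}
        msa = make_msa(rows)
        mim = mi_zscores(msa, n_perm=50, seed=0)
        assert mim.z[0, 1] == 0.0
        assert bool(mim.degenerate[0, 1])

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        msa = random_msa(rng, n_rows=30, n_cols=6, alphabet="ACDEFG")
        a = mi_zscores(msa, n_perm=50, seed=42)
        b = mi_zscores(msa, n_perm=50, seed=42)
        assert np.array_equal(a.z, b.z)


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(8)
    n_per, m = 20, 15
    rows, asg = {}, {}
    clade_res = {"I": "D", "II": "K", "III": "W"}
    for lab, res in clade_res.items():
        for j in range(n_per):
            sid = f"{lab}s{j}"
            row = rng.choice(list("ACDEFGHIKL"), size=m)
            row[4] = res  # planted clade-determining column 5
            rows[sid] = "".join(row)
            asg[sid] = lab
    return make_msa(rows), CladeAssignment(asg)


class TestIdentifyCDPs:
    def test_planted_column_called(self, planted):
        msa, asg = planted
        cdps = identify_cdps(msa, asg, n_perm=200, seed=0)
        assert bool(cdps.loc[cdps.column == 5, "is_cdp"].iloc[0])

    def test_conserved_column_not_called(self):
        rows, asg = {}, {}
        rng = np.random.default_rng(1)
        for i in range(40):
            rows[f"s{i}"] = "W" + "".join(rng.choice(list("ACDE"), size=4))
            asg[f"s{i}"] = "I" if i < 20 else "II"
        cdps = identify_cdps(make_msa(rows), CladeAssignment(asg),
                             n_perm=200, seed=0)
        row = cdps.loc[cdps.column == 1].iloc[0]
        assert row.clade_mi == pytest.approx(0.0, abs=1e-12)
        assert not bool(row.is_cdp)

    def test_seed_determinism(self, planted):
        msa, asg = planted
        a = identify_cdps(msa, asg, n_perm=150, seed=5)
        b = identify_cdps(msa, asg, n_perm=150, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_pvalues_never_zero(self, planted):
        msa, asg = planted
        cdps = identify_cdps(msa, asg, n_perm=150, seed=5)
        assert (cdps.p_value > 0).all()
        assert (cdps.p_value <= 1).all()


class TestBuildNetwork:
    def mim_from_edges(self, m, edges):
        z = np.zeros((m, m))
        for i, j, val in edges:
            z[i, j] = z[j, i] = val
        return MIMatrix(columns=np.arange(1, m + 1), mi_raw=np.zeros((m, m)),
                        mi_apc=np.zeros((m, m)), z=z)

    def test_single_pair(self):
        net = build_network(self.mim_from_edges(5, [(0, 3, 7.0)]), z_cut=6.5)
        assert net.nodes == {1, 4}
        assert net.components == [{1, 4}]

    def test_chain_forms_one_component(self):
        net = build_network(
            self.mim_from_edges(6, [(0, 1, 7.0), (1, 2, 8.0)]), z_cut=6.5)
        assert net.components == [{1, 2, 3}]
        assert net.cumulative[2] == pytest.approx(15.0)

    def test_components_match_transitive_closure_oracle(self):
        rng = np.random.default_rng(17)
        m = 15
        edges = [(i, j, 7.0) for i in range(m) for j in range(i + 1, m)
                 if rng.random() < 0.15]
        net = build_network(self.mim_from_edges(m, edges), z_cut=6.5)
        g = nx.Graph([(i + 1, j + 1) for i, j, _ in edges])
        expected = sorted((set(c) for c in nx.connected_components(g)),
                          key=min)
        assert net.components == expected

    def test_subthreshold_edges_excluded(self):
        net = build_network(
            self.mim_from_edges(4, [(0, 1, 6.4), (2, 3, 6.5)]), z_cut=6.5)
        assert net.nodes == {3, 4}


class TestClassifySDPs:
    def cdp_frame(self, m, cdp_cols):
        return pd.DataFrame({
            "column": np.arange(1, m + 1),
            "clade_mi": 1.0,
            "p_value": 0.001,
            "q_value": 0.01,
            "is_cdp": [c in cdp_cols for c in range(1, m + 1)],
        })

    def net_from_edges(self, edges):
        z = {}
        g = nx.Graph()
        for u, v in edges:
            g.add_edge(u, v, z=7.0, mi_raw=1.0, mi_apc=1.0)
        from sdpnet.network import MINetwork
        return MINetwork(graph=g, z_cut=6.5)

    def test_direct_edge_groups_two_sdps(self):
        net = self.net_from_edges([(1, 2)])
        rep = classify_sdps(self.cdp_frame(6, {1, 2}), net)
        assert rep.sdps == [1, 2]
        assert len(rep.sdns) == 1 and rep.sdns[0]["members"] == [1, 2]

    def test_single_nonsdp_linker_joins_sdn(self):
        # pSDPs 1,2 direct; pSDP 4 reaches 2 only through non-SDP node 9
        net = self.net_from_edges([(1, 2), (2, 9), (9, 4)])
        rep = classify_sdps(self.cdp_frame(9, {1, 2, 4}), net)
        (sdn,) = rep.sdns
        assert sdn["members"] == [1, 2, 4]
        assert sdn["linkers"] == [9]

    def test_two_nonsdp_hops_do_not_join_at_default(self):
        net = self.net_from_edges([(1, 8), (8, 9), (9, 2)])
        rep = classify_sdps(self.cdp_frame(9, {1, 2}), net)
        assert rep.sdps == []  # two singleton SDNs, both stay pSDP
        assert len(rep.sdns) == 2
        rep2 = classify_sdps(self.cdp_frame(9, {1, 2}), net, max_link=2)
        assert rep2.sdps == [1, 2]

    def test_different_component_separate_sdn(self):
        net = self.net_from_edges([(1, 2), (5, 6)])
        rep = classify_sdps(self.cdp_frame(8, {1, 2, 5, 6}), net)
        assert len(rep.sdns) == 2

    def test_status_hierarchy(self):
        # 3 is a CDP outside the network; 7 is a network node but no CDP
        net = self.net_from_edges([(1, 2), (7, 8)])
        rep = classify_sdps(self.cdp_frame(9, {1, 2, 3}), net)
        frame = rep.frame.set_index("column")
        assert frame.loc[3, "status"] == "CDP"
        assert frame.loc[7, "status"] == "none"
        assert set(rep.sdps) <= set(rep.psdps) <= set(rep.cdps)
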