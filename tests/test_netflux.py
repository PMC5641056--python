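import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from oncopass.netflux import (
    InteractionNetwork,
    pathway_flux,
    read_edge_list,
    read_gmt,
    stationary_flux,
    transform_cr_values,
)


def cycle_network(n=5):
    return InteractionNetwork.from_edges(
        [(f"N{i}", f"N{(i + 1) % n}") for i in range(n)]
    )


class TestTransform:
    def test_pivot_maps_to_one(self):
        v = transform_cr_values(pd.Series({"A": 0.4}))
        assert v["A"] == pytest.approx(1.0)

    def test_low_correlation_maps_below_one(self):
        # 2^(-0.6 - 0.4) = 0.5
        v = transform_cr_values(pd.Series({"A": -0.6}))
        assert v["A"] == pytest.approx(0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            transform_cr_values(pd.Series({"A": 1.4}))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            transform_cr_values(pd.Series({"A": np.nan}))

    def test_crhigh_above_one_crlow_below(self):
        v = transform_cr_values(pd.Series({"hi": 0.7, "lo": 0.1}))
        assert v["hi"] > 1.0 > v["lo"]


class TestStationaryFlux:
    def test_uniform_cycle_is_uniform(self):
        net = cycle_network(5)
        vals = pd.Series(1.0, index=[f"N{i}" for i in range(5)])
        pi, edge_flux = stationary_flux(net, vals)
        assert np.allclose(pi.to_numpy(), 0.2, atol=1e-9)
        assert pi.sum() == pytest.approx(1.0, abs=1e-9)
        assert all(f >= 0 for f in edge_flux.values())

    def test_three_node_path_matches_linear_solve(self):
        net = InteractionNetwork.from_edges([("A", "B"), ("B", "C")])
        vals = pd.Series(1.0, index=["A", "B", "C"])
        restart = 0.05
        pi, _ = stationary_flux(net, vals, restart=restart)
        # direct solve of (I - (1-restart) P^T) pi = restart * v_bar
        p = np.array([[0, 1, 0], [0.5, 0, 0.5], [0, 1, 0]])
        v_bar = np.ones(3) / 3
        want = np.linalg.solve(np.eye(3) - (1 - restart) * p.T, restart * v_bar)
        got = pi.loc[["A", "B", "C"]].to_numpy()
        assert np.allclose(got, want, atol=1e-8)

    def test_scale_invariance_of_values(self):
        net = cycle_network(6)
        rng = np.random.default_rng(0)
        vals = pd.Series(
            rng.uniform(0.5, 2.0, 6), index=[f"N{i}" for i in range(6)]
        )
        pi1, _ = stationary_flux(net, vals)
        pi2, _ = stationary_flux(net, 2.0 * vals)
        assert np.allclose(pi1.to_numpy(), pi2.to_numpy(), atol=1e-10)

    def test_missing_genes_get_neutral_value(self):
        net = cycle_network(4)
        pi, _ = stationary_flux(net, pd.Series({"N0": 1.0}))
        assert pi.sum() == pytest.approx(1.0, abs=1e-9)

    def test_disconnected_components_mass_weighted(self):
        net = InteractionNetwork.from_edges(
            [("A", "B"), ("B", "C"), ("X", "Y")]
        )
        vals = pd.Series({"A": 1.0, "B": 1.0, "C": 1.0, "X": 3.0, "Y": 3.0})
        pi, _ = stationary_flux(net, vals)
        assert pi.sum() == pytest.approx(1.0, abs=1e-9)
        # the X-Y component holds 6/9 of the value mass
        assert pi[["X", "Y"]].sum() == pytest.approx(6 / 9, abs=1e-8)

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            InteractionNetwork.from_edges([("A", "A")])

    def test_invalid_restart_rejected(self):
        net = cycle_network(3)
        with pytest.raises(ValueError, match="restart"):
            stationary_flux(net, pd.Series(1.0, index=["N0", "N1", "N2"]), restart=0.0)


class TestPathwayFlux:
    def toy_flux(self):
        net = cycle_network(6)
        rng = np.random.default_rng(1)
        vals = pd.Series(
            rng.uniform(0.5, 2.0, 6), index=[f"N{i}" for i in range(6)]
        )
        return stationary_flux(net, vals)

    def test_whole_network_pathway_has_z_zero(self):
        node_flux, edge_flux = self.toy_flux()
        res = pathway_flux(
            node_flux, edge_flux, {"all": list(node_flux.index)},
            n_permutations=50, seed=0,
        )[0]
        total = node_flux.sum() + sum(edge_flux.values())
        assert res.flux_score == pytest.approx(total)
        assert res.z == 0.0

    def test_exhaustive_null_matches_enumeration_oracle(self):
        node_flux, edge_flux = self.toy_flux()
        members = ["N0", "N1", "N2"]
        res = pathway_flux(
            node_flux, edge_flux, {"p": members}, seed=0, exhaustive=True
        )[0]
        # independent oracle: all C(6,3) member sets on the degree-2 cycle
        nodes = list(node_flux.index)

        def score(mset):
            s = sum(node_flux[m] for m in mset)
            s += sum(
                f for (a, b), f in edge_flux.items() if a in mset and b in mset
            )
            return s

        null = [score(set(c)) for c in itertools.combinations(nodes, 3)]
        mean, sd = np.mean(null), np.std(null)
        want_z = (score(set(members)) - mean) / sd
        assert res.z == pytest.approx(want_z, abs=1e-12)
        assert res.null_mean == pytest.approx(mean, abs=1e-12)

    def test_monotone_in_member_values(self):
        net = cycle_network(6)
        idx = [f"N{i}" for i in range(6)]
        members = ["N0", "N1", "N2"]
        scores = []
        for boost in (1.0, 1.5, 2.5):
            vals = pd.Series(1.0, index=idx)
            vals[members] = boost
            node_flux, edge_flux = stationary_flux(net, vals)
            res = pathway_flux(
                node_flux, edge_flux, {"p": members}, n_permutations=10, seed=0
            )[0]
            scores.append(res.flux_score)
        assert scores[0] <= scores[1] <= scores[2]

    def test_small_pathway_skipped(self):
        node_flux, edge_flux = self.toy_flux()
        res = pathway_flux(node_flux, edge_flux, {"tiny": ["N0", "N1"]}, seed=0)
        assert res == []

    def test_deterministic_given_seed(self):
        node_flux, edge_flux = self.toy_flux()
        a = pathway_flux(node_flux, edge_flux, {"p": ["N0", "N2", "N4"]},
                         n_permutations=100, seed=7)[0]
        b = pathway_flux(node_flux, edge_flux, {"p": ["N0", "N2", "N4"]},
                         n_permutations=100, seed=7)[0]
        assert a.z == b.z


class TestFileFormats:
    def test_edge_list_round_trip(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\tB\t2.0\nB\tC\t1.0\n")
        net = read_edge_list(p)
        assert set(net.nodes) == {"A", "B", "C"}
        assert net.graph["A"]["B"]["weight"] == 2.0

    def test_gmt_parse(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("pw1\tdesc\tA\tB\tC\npw2\tdesc\tX\tY\n")
        sets = read_gmt(p)
        assert sets["pw1"] == ["A", "B", "C"]
        assert sets["pw2"] == ["X", "Y"]
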