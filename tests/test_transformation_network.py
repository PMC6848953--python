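"""Transformation dictionaries, network construction, first neighbors."""

import itertools

import networkx as nx
import numpy as np
import pytest

from fticrms.synthetic_data import SyntheticSpec, generate_sample
from fticrms.transformation_network import (
    Transformation,
    annotate_network,
    build_network,
    class_tally,
    default_transformations,
    edge_table,
    first_neighbors,
    load_transformations,
    node_table,
)


def by_name(name):
    return next(t for t in default_transformations() if t.name == name)


class TestTransformations:
    def test_co2_delta_matches_printed_value(self):
        assert by_name("CO2").delta_mass == pytest.approx(43.98983, abs=1e-5)
        assert round(by_name("CO2").delta_mass, 4) == 43.9898

    def test_ch2_delta_is_the_homologous_series_spacing(self):
        assert by_name("CH2").delta_mass == pytest.approx(14.01565, abs=1e-5)

    def test_masses_always_recomputed_from_formulas(self):
        for t in default_transformations():
            if t.formula is not None:
                assert t.delta_mass == pytest.approx(t.formula.mass, abs=1e-9)

    def test_loader_rejects_inconsistent_rows(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("name,formula,delta_mass\nCO2,CO2,44.1\n")
        with pytest.raises(ValueError, match="disagrees"):
            load_transformations(path)

    def test_loader_accepts_mass_only_and_formula_only_rows(self, tmp_path):
        path = tmp_path / "ok.csv"
        path.write_text("name,formula,delta_mass\nX,,100.5\nCH2,CH2,\n")
        ts = load_transformations(path)
        assert ts[0].delta_mass == 100.5 and ts[0].formula is None
        assert ts[1].delta_mass == pytest.approx(14.01565, abs=1e-5)

    def test_empty_dictionary_gives_empty_network(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("name,formula,delta_mass\n")
        assert load_transformations(path) == []
        g = build_network([100.0, 143.98983], [])
        assert g.number_of_edges() == 0

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValueError):
            Transformation("bad", -1.0)


class TestBuildNetwork:
    def test_exact_co2_pair_connected(self):
        g = build_network([100.0, 143.98983], [by_name("CO2")], tol_da=0.001)
        assert g.number_of_edges() == 1
        ((u, v, data),) = g.edges(data=True)
        assert data["transformation"] == "CO2"
        assert abs(data["residual_da"]) <= 0.001

    def test_ch2_ladder_forms_a_path(self):
        mz = [100.0, 114.01565, 128.03130]
        g = build_network(mz, [by_name("CH2")])
        assert g.number_of_edges() == 2
        assert nx.has_path(g, 100.0, 128.03130)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(9)
        mz = np.sort(rng.uniform(150, 500, 200))
        transforms = [by_name(n) for n in ("CH2", "CO2", "H2O", "O", "hexose")]
        g = build_network(mz, transforms, tol_da=0.001)
        fast = {(round(min(u, v), 9), round(max(u, v), 9), k) for u, v, k in g.edges(keys=True)}
        slow = set()
        for a, b in itertools.combinations(mz, 2):
            lo, hi = (a, b) if a < b else (b, a)
            for t in transforms:
                if abs(hi - lo - t.delta_mass) <= 0.001:
                    slow.add((round(lo, 9), round(hi, 9), t.name))
        assert fast == slow

    def test_input_order_is_irrelevant(self):
        mz = [300.0, 150.0, 164.01565, 343.98983]
        t = [by_name("CH2"), by_name("CO2")]
        e1 = edge_table(build_network(mz, t))
        e2 = edge_table(build_network(list(reversed(mz)), t))
        assert e1.equals(e2)

    def test_residuals_never_exceed_tolerance(self):
        rng = np.random.default_rng(3)
        mz = np.sort(rng.uniform(150, 600, 150))
        g = build_network(mz, tol_da=0.001)
        for _, _, data in g.edges(data=True):
            assert abs(data["residual_da"]) <= 0.001

    def test_planted_chain_edges_recovered(self):
        """Chains planted from a two-entry dictionary whose composite sums
        never alias another entry are found with perfect precision/recall."""
        transforms = [by_name("CO2"), by_name("hexose")]
        spec = SyntheticSpec(
            seed=21,
            n_compounds=0,
            contaminant_fraction=0.0,
            jitter_ppm=0.1,
            n_chains=6,
            chain_length=4,
            chain_transformations=("CO2", "hexose"),
        )
        peaks, truth = generate_sample(spec)
        g = build_network(peaks.mz, transforms, tol_da=0.001)
        found = {tuple(sorted(e[:2])) for e in g.edges(keys=True)}
        planted = set()
        for _, grp in truth.groupby("chain_id"):
            mzs = sorted(grp["observed_mz"])
            masses = sorted(grp["neutral_mass"])
            for a_mz, b_mz, a_m, b_m in zip(mzs, mzs[1:], masses, masses[1:]):
                if any(abs(b_m - a_m - t.delta_mass) < 1e-6 for t in transforms):
                    planted.add((a_mz, b_mz))
        assert planted  # the experiment is non-trivial
        tp = len(found & planted)
        precision = tp / len(found)
        recall = tp / len(planted)
        assert precision >= 0.95 and recall >= 0.95


class TestFirstNeighbors:
    def test_isolated_seed_has_no_neighbors(self):
        g = build_network([100.0, 300.0], [by_name("CH2")])
        sub, n = first_neighbors(g, [100.0])
        assert n == 0
        assert set(sub.nodes) == {100.0}

    def test_planted_star_recovered(self):
        center = 400.0
        partners = [
            center + by_name("CH2").delta_mass,
            center - by_name("CH2").delta_mass,
            center + by_name("CO2").delta_mass,
            center - by_name("CO2").delta_mass,
            center + 2 * by_name("CO2").delta_mass,  # second shell: not a neighbor
        ]
        g = build_network([center] + partners, [by_name("CH2"), by_name("CO2")])
        sub, n = first_neighbors(g, [center])
        assert n == 4
        assert sub.nodes[center]["is_seed"]

    def test_shared_neighbor_counted_once(self):
        d = by_name("CO2").delta_mass
        g = build_network([100.0, 100.0 + d, 100.0 + 2 * d], [by_name("CO2")])
        sub, n = first_neighbors(g, [100.0, 100.0 + 2 * d])
        assert n == 1

    def test_missing_seeds_skipped_with_warning(self, caplog):
        g = build_network([100.0, 114.01565], [by_name("CH2")])
        with caplog.at_level("WARNING"):
            _, n = first_neighbors(g, [999.0, 100.0])
        assert n == 1
        assert "skipped" in caplog.text


class TestAnnotateNetwork:
    def test_nodes_carry_formula_and_class_or_unknown(self):
        import pandas as pd

        mz = [281.24860395, 300.0]
        g = build_network(mz, [by_name("CH2")])
        assignments = pd.DataFrame(
            {
                "mz": [281.24860395],
                "formula": ["C18H34O2"],
                "status": ["assigned"],
            }
        )
        annotate_network(g, assignments)
        assert g.nodes[281.24860395]["compound_class"] == "lipid"
        assert g.nodes[300.0]["formula"] == "unknown"
        tally = class_tally(g)
        assert sum(tally.values()) == g.number_of_nodes()

    def test_node_table_sorted_by_mz(self):
        g = build_network([500.0, 100.0, 114.01565], [by_name("CH2")])
        table = node_table(g)
        assert list(table["mz"]) == sorted(table["mz"])


def test_graphml_roundtrip(tmp_path):
    g = build_network([100.0, 114.01565, 143.98983], [by_name("CH2"), by_name("CO2")])
    path = tmp_path / "net.graphml"
    from fticrms.transformation_network import write_graphml

    write_graphml(g, path)
    back = nx.read_graphml(path)
    assert back.number_of_nodes() == g.number_of_nodes()
    assert back.number_of_edges() == g.number_of_edges()
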