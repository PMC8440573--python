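import networkx as nx
import numpy as np
import pandas as pd
import pytest

from soilweb import metaweb
from soilweb.metaweb import (build_metaweb, compile_kb, extract_local_web,
                             filter_by_geography, filter_by_habitat,
                             generalize_within_families)


@pytest.fixture
def taxonomy():
    return pd.DataFrame({
        "taxon_id": ["a", "b", "c", "f1", "f2", "f3", "nem1"],
        "phylum": ["P1"] * 3 + ["Fungi"] * 3 + ["Nematoda"],
        "family": ["FamA", "FamA", "FamB", "FamF", "FamF", "FamF", "FamN"],
        "genus": ["GenA", "GenA", "GenB", "GenF1", "GenF1", "GenF2", "GenN"],
        "species": list("1234567"),
    })


def ann_frame(rows):
    return pd.DataFrame(
        rows, columns=["taxon_id", "guild", "habitat_layers",
                       "geographic_tags", "is_microorganism"])


class TestCompileKB:
    def test_identical_records_deduplicated(self, kb_frame, taxonomy):
        kb, rep = compile_kb(kb_frame(
            [("a", "b", "predation", "species", "x")] * 2), taxonomy)
        assert len(kb) == 1
        assert rep.n_duplicates == 1

    def test_rank_precedence(self, kb_frame, taxonomy):
        kb, _ = compile_kb(kb_frame([
            ("a", "b", "parasitism", "family", "coarse"),
            ("a", "b", "predation", "species", "fine"),
        ]), taxonomy)
        assert len(kb) == 1
        assert kb.iloc[0]["evidence_rank"] == "species"
        assert kb.iloc[0]["type"] == "predation"

    def test_unknown_taxon_rejected_not_fatal(self, kb_frame, taxonomy):
        kb, rep = compile_kb(kb_frame([
            ("a", "b", "predation", "species", ""),
            ("a", "zz", "predation", "species", ""),
        ]), taxonomy)
        assert len(kb) == 1
        assert len(rep.rejects) == 1

    def test_planted_duplicates_set_union_oracle(self, kb_frame, rng):
        taxa = [f"t{i}" for i in range(30)]
        taxonomy = pd.DataFrame({
            "taxon_id": taxa, "phylum": "P", "family": "F",
            "genus": "G", "species": taxa})
        pairs = set()
        while len(pairs) < 40:
            i, j = rng.integers(0, 30, 2)
            if i != j:
                pairs.add((f"t{i}", f"t{j}"))
        rows = [(r, c, "predation", "species", "") for r, c in pairs]
        dup_idx = rng.choice(len(rows), 10, replace=False)
        rows += [rows[i] for i in dup_idx]
        kb, _ = compile_kb(kb_frame(rows), taxonomy)
        assert len(kb) == len(pairs)  # 40 survive from 50

    def test_self_loops_dropped(self, kb_frame, taxonomy):
        kb, rep = compile_kb(
            kb_frame([("a", "a", "predation", "species", "")]), taxonomy)
        assert len(kb) == 0
        assert rep.n_self_loops == 1


class TestGeneralize:
    def test_genus_expansion_enumeration(self, kb_frame, taxonomy):
        # fungivorous nematode genus feeding on a 3-member fungal family
        kb, _ = compile_kb(kb_frame(
            [("FamF", "nem1", "predation", "family", "")]), taxonomy)
        out = generalize_within_families(kb, taxonomy)
        fine = out[~out["is_coarse"]]
        assert set(fine["resource"]) == {"f1", "f2", "f3"}
        assert (fine["consumer"] == "nem1").all()
        assert (fine["evidence_rank"] == "generalized").all()
        coarse = out[out["is_coarse"]]
        assert len(coarse) == 1  # retained for audit

    def test_species_rank_unchanged(self, kb_frame, taxonomy):
        kb, _ = compile_kb(kb_frame(
            [("a", "b", "predation", "species", "")]), taxonomy)
        out = generalize_within_families(kb, taxonomy)
        assert len(out) == 1
        assert out.iloc[0]["evidence_rank"] == "species"

    def test_empty_family_expands_to_nothing(self, kb_frame, taxonomy):
        kb = kb_frame([("FamEmpty", "a", "predation", "family", "")])
        out = generalize_within_families(kb, taxonomy)
        # unresolvable endpoint passes through unexpanded
        assert len(out) == 1
        assert not out.iloc[0]["is_coarse"]


class TestHabitatFilter:
    def test_disjoint_layers_removed(self, kb_frame):
        ann = ann_frame([("a", "predator", "surface", "temperate_europe", False),
                         ("b", "predator", ">10cm", "temperate_europe", False)])
        kb = kb_frame([("a", "b", "predation", "species", "")])
        assert len(filter_by_habitat(kb, ann)) == 0

    def test_shared_layer_kept(self, kb_frame):
        ann = ann_frame([("a", "predator", "surface|0-10cm", "t", False),
                         ("b", "predator", "0-10cm", "t", False)])
        kb = kb_frame([("a", "b", "predation", "species", "")])
        assert len(filter_by_habitat(kb, ann)) == 1

    def test_missing_annotation_kept(self, kb_frame):
        ann = ann_frame([("a", "predator", "surface", "t", False)])
        kb = kb_frame([("a", "b", "predation", "species", "")])
        assert len(filter_by_habitat(kb, ann)) == 1

    def test_random_layers_match_intersection_oracle(self, kb_frame, rng):
        layers = ["surface", "0-10cm", ">10cm"]
        taxa = [f"t{i}" for i in range(20)]
        assigned = {}
        rows = []
        for t in taxa:
            k = rng.integers(1, 4)
            mine = sorted(rng.choice(3, size=k, replace=False))
            assigned[t] = {layers[i] for i in mine}
            rows.append((t, "predator", "|".join(layers[i] for i in mine),
                         "t", False))
        ann = ann_frame(rows)
        edges = []
        for _ in range(100):
            i, j = rng.integers(0, 20, 2)
            if i != j:
                edges.append((taxa[i], taxa[j], "predation", "species", ""))
        kb = kb_frame(edges)
        out = filter_by_habitat(kb, ann)
        oracle = {(r, c) for r, c, *_ in edges
                  if assigned[r] & assigned[c]}
        assert set(zip(out["resource"], out["consumer"])) == oracle


class TestGeographyFilter:
    def test_tropical_macrofauna_dropped(self, kb_frame):
        ann = ann_frame([("a", "predator", "surface", "tropical", False),
                         ("b", "predator", "surface", "temperate_europe", False)])
        kb = kb_frame([("a", "b", "predation", "species", "")])
        assert len(filter_by_geography(kb, ann)) == 0

    def test_microorganism_empty_tags_retained(self, kb_frame):
        ann = ann_frame([("a", "bacteria_decomposer", "surface", "", True),
                         ("b", "predator", "surface", "temperate_europe", False)])
        kb = kb_frame([("a", "b", "predation", "species", "")])
        assert len(filter_by_geography(kb, ann)) == 1

    def test_mixed_table_node_survivors_match_oracle(self, rng):
        rows = []
        expect = set()
        for i in range(50):
            t = f"t{i}"
            micro = bool(rng.random() < 0.3)
            tags = str(rng.choice(["temperate_europe", "tropical", ""]))
            rows.append((t, "predator", "surface", tags, micro))
            if micro or tags == "temperate_europe":
                expect.add(t)
        ann = ann_frame(rows)
        got = metaweb.geography_survivors([f"t{i}" for i in range(50)], ann)
        assert got == expect


class TestBuildMetaweb:
    def test_edges_restricted_to_observed(self, kb_frame):
        kb = kb_frame([("a", "b", "predation", "species", ""),
                       ("b", "c", "predation", "species", ""),
                       ("c", "d", "predation", "species", ""),
                       ("a", "zz", "predation", "species", "")])
        g = build_metaweb(list("abcde"), kb)
        assert g.number_of_nodes() == 5
        assert g.number_of_edges() == 3
        assert "e" in g  # isolate kept

    def test_empty_kb_ok(self, kb_frame):
        g = build_metaweb(["a", "b"], kb_frame([]))
        assert g.number_of_edges() == 0

    def test_empty_taxa_error(self, kb_frame):
        with pytest.raises(ValueError):
            build_metaweb([], kb_frame([]))

    def test_synthetic_edges_equal_planted_intersection(self, small_scenario):
        kb = small_scenario.interactions
        observed = list(small_scenario.taxonomy["taxon_id"])[:40]
        g = build_metaweb(observed, kb)
        oracle = {(r, c) for r, c in zip(kb["resource"], kb["consumer"])
                  if r in set(observed) and c in set(observed)}
        assert set(g.edges) == oracle


class TestLocalWeb:
    def _detections(self, rows):
        return pd.DataFrame(rows, columns=["replicate", "taxon_id", "reads"])

    def test_induced_edges(self, kb_frame):
        kb = kb_frame([("A", "B", "predation", "species", ""),
                       ("B", "D", "predation", "species", "")])
        mw = build_metaweb(list("ABCD"), kb)
        det = self._detections([(1, "A", 5), (1, "B", 2), (1, "C", 9)])
        lw = extract_local_web(mw, det, plot_id="p")
        assert set(lw.graph.edges) == {("A", "B")}
        assert set(lw.graph.nodes) == {"A", "B", "C"}

    def test_edge_weight_detection_fractions(self, kb_frame):
        kb = kb_frame([("A", "B", "predation", "species", "")])
        mw = build_metaweb(["A", "B"], kb)
        rows = [(r, "A", 1) for r in (1, 2, 3, 4)] + [(1, "B", 1), (3, "B", 1)]
        lw = extract_local_web(mw, self._detections(rows), n_replicates=4)
        assert lw.graph.edges["A", "B"]["weight"] == pytest.approx(0.5)

    def test_reads_summed_over_replicates(self, kb_frame):
        mw = build_metaweb(["A"], kb_frame([]))
        lw = extract_local_web(
            mw, self._detections([(1, "A", 5), (2, "A", 7)]))
        assert lw.read_counts["A"] == 12

    def test_intersection_mode(self, kb_frame):
        mw = build_metaweb(["A", "B"], kb_frame([]))
        rows = [(r, "A", 1) for r in (1, 2, 3, 4)] + [(1, "B", 1)]
        lw = extract_local_web(mw, self._detections(rows), n_replicates=4,
                               aggregation="intersection")
        assert set(lw.graph.nodes) == {"A"}

    def test_empty_plot_warns(self, kb_frame, caplog):
        mw = build_metaweb(["A"], kb_frame([]))
        with caplog.at_level("WARNING"):
            lw = extract_local_web(mw, self._detections([]), plot_id="px")
        assert lw.graph.number_of_nodes() == 0
        assert "zero detected taxa" in caplog.text

    def test_random_scenario_induced_subgraph_oracle(self, small_scenario):
        from soilweb.metaweb import extract_all_webs

        kb = small_scenario.interactions
        mw = build_metaweb(list(small_scenario.taxonomy["taxon_id"]), kb)
        webs = extract_all_webs(mw, small_scenario.observations,
                                small_scenario.design)
        obs = small_scenario.observations
        for lw in webs[:8]:
            present = set(obs[obs["plot_id"] == lw.plot_id]["taxon_id"])
            assert set(lw.graph.nodes) == present
            oracle = {(u, v) for u, v in mw.edges
                      if u in present and v in present}
            assert set(lw.graph.edges) == oracle
            # invariant: local edges subset of metaweb edges
            assert set(lw.graph.edges) <= set(mw.edges)


class TestFilterProperties:
    def _random_setup(self, rng, n=30, m=120):
        taxa = [f"t{i}" for i in range(n)]
        layers = ["surface", "0-10cm", ">10cm"]
        rows = []
        for t in taxa:
            k = rng.integers(1, 4)
            mine = sorted(rng.choice(3, size=int(k), replace=False))
            rows.append((t, "predator", "|".join(layers[i] for i in mine),
                         str(rng.choice(["temperate_europe", "tropical"])),
                         bool(rng.random() < 0.2)))
        ann = ann_frame(rows)
        edges = []
        seen = set()
        while len(edges) < m:
            i, j = rng.integers(0, n, 2)
            if i != j and (i, j) not in seen:
                seen.add((i, j))
                edges.append((taxa[i], taxa[j], "predation", "species", ""))
        kb = pd.DataFrame(edges, columns=["resource", "consumer", "type",
                                          "evidence_rank", "source"])
        return kb, ann

    def test_filters_contractive_and_idempotent(self, rng):
        kb, ann = self._random_setup(rng)
        for f in (lambda k: filter_by_habitat(k, ann),
                  lambda k: filter_by_geography(k, ann)):
            once = f(kb)
            assert len(once) <= len(kb)
            twice = f(once)
            pd.testing.assert_frame_equal(
                once.reset_index(drop=True), twice.reset_index(drop=True))

    def test_filter_order_invariance(self, rng):
        kb, ann = self._random_setup(rng)
        hg = filter_by_geography(filter_by_habitat(kb, ann), ann)
        gh = filter_by_habitat(filter_by_geography(kb, ann), ann)
        key = lambda d: set(zip(d["resource"], d["consumer"]))
        assert key(hg) == key(gh)
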