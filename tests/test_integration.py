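"""Pathway-name canonicalization, overlap, reverse mapping, export."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sysmetab.integration import (
    TripartiteNetwork,
    canonicalize_name,
    export_network,
    overlap_pathways,
    read_network_graphml,
    reverse_map,
)
from sysmetab.reference import load_pathway_analysis, load_syspharm_pathways


class TestCanonicalize:
    def test_slash_and_or_variants_unify(self):
        assert canonicalize_name("Glycolysis/gluconeogenesis") == canonicalize_name(
            "glycolysis or gluconeogenesis"
        )

    def test_idempotent_on_identical_strings(self):
        assert canonicalize_name("Pyruvate metabolism") == canonicalize_name(
            "Pyruvate metabolism"
        )

    def test_stereo_prefixes_survive_as_tokens(self):
        a = canonicalize_name("d-Glutamine and d-glutamate metabolism")
        b = canonicalize_name("D-glutamine and D-glutamate metabolism")
        assert a == b and "glutamine" in a

    def test_empty_name_rejected(self):
        with pytest.raises(ValueError):
            canonicalize_name("   ")

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_case_and_spacing_perturbations_invariant(self, seed):
        rng = np.random.default_rng(seed)
        base = "Glycine, serine and threonine metabolism"
        chars = []
        for ch in base:
            ch = ch.upper() if rng.random() < 0.5 else ch.lower()
            chars.append(ch)
            if ch == " " and rng.random() < 0.5:
                chars.append(" ")
        assert canonicalize_name("".join(chars)) == canonicalize_name(base)


class TestOverlap:
    def test_reference_pathway_sets_split_six_four(self):
        ref = load_pathway_analysis()
        significant = ref.loc[ref.raw_p < 0.05, "pathway"].tolist()
        overlapping, non_overlapping = overlap_pathways(
            significant, load_syspharm_pathways()
        )
        assert len(overlapping) == 6 and len(non_overlapping) == 4
        assert "Aminoacyl-tRNA biosynthesis" in overlapping
        assert "Galactose metabolism" in non_overlapping

    def test_disjoint_sets(self):
        ov, non = overlap_pathways(["a b", "c d"], ["e f"])
        assert ov == [] and non == ["a b", "c d"]

    def test_matches_brute_force_after_canonicalization(self, rng):
        names = [f"pathway {i}" for i in range(30)]
        metab = [names[i] for i in rng.choice(30, 12, replace=False)]
        sys = [names[i].upper() for i in rng.choice(30, 15, replace=False)]
        ov, non = overlap_pathways(metab, sys)
        oracle = {canonicalize_name(n) for n in metab} & {canonicalize_name(n) for n in sys}
        assert {canonicalize_name(n) for n in ov} == oracle
        assert set(ov) | set(non) == set(metab)


def chain_maps():
    return (
        ["pathway one"],
        {"prot1": {"pathway one"}},
        {"cmpdA": {"prot1"}},
        {"herbX": {"cmpdA"}},
    )


class TestReverseMap:
    def test_single_chain_yields_path_of_degree_one(self):
        net = reverse_map(*chain_maps())
        assert net.summary() == {
            "herb": 1,
            "compound": 1,
            "protein": 1,
            "pathway": 1,
            "edges": 3,
        }
        assert all(net.degree(n) in (1, 2) for n in net.graph.nodes)
        assert net.degree("herbX") == 1 and net.degree("pathway one") == 1

    def test_unrelated_entities_excluded(self):
        overlapping, p2p, c2p, h2c = chain_maps()
        p2p["prot2"] = {"some other pathway"}
        c2p["cmpdB"] = {"prot2"}
        h2c["herbY"] = {"cmpdB"}
        net = reverse_map(overlapping, p2p, c2p, h2c)
        assert net.nodes_in_tier("herb") == {"herbX"}
        assert net.nodes_in_tier("protein") == {"prot1"}

    def test_monotone_in_overlap_set(self):
        _, p2p, c2p, h2c = chain_maps()
        p2p["prot2"] = {"pathway two"}
        c2p["cmpdB"] = {"prot2"}
        h2c["herbY"] = {"cmpdB"}
        small = reverse_map(["pathway one"], p2p, c2p, h2c)
        large = reverse_map(["pathway one", "pathway two"], p2p, c2p, h2c)
        assert set(small.graph.nodes) <= set(large.graph.nodes)

    def test_every_node_reachable_from_a_pathway(self, rng):
        p2p = {f"p{i}": {f"pw{rng.integers(3)}"} for i in range(6)}
        c2p = {f"c{i}": {f"p{rng.integers(6)}"} for i in range(8)}
        h2c = {f"h{i}": {f"c{rng.integers(8)}"} for i in range(4)}
        net = reverse_map(["pw0", "pw1", "pw2"], p2p, c2p, h2c)
        pathway_nodes = net.nodes_in_tier("pathway")
        for node in net.graph.nodes:
            assert any(nx.has_path(net.graph, node, p) for p in pathway_nodes)

    def test_planted_synthetic_overlap_recovered_exactly(self):
        from sysmetab.synthetic import (
            SyntheticConfig,
            generate_compound_table,
            generate_target_and_pathway_library,
        )
        from sysmetab.targets import TargetHit, filter_targets

        cfg = SyntheticConfig(seed=5)
        table, truth0 = generate_compound_table(cfg)
        hits, lib, truth = generate_target_and_pathway_library(cfg, truth0)
        kept = filter_targets(
            [TargetHit(r.compound_id, r.protein_id, r.fit_rank, r.z_score) for r in hits.itertuples()]
        )
        c2p: dict[str, set[str]] = {}
        for h in kept:
            c2p.setdefault(h.compound_id, set()).add(h.protein_id)
        h2c: dict[str, set[str]] = {}
        for cid in truth.active_compound_ids:
            h2c.setdefault(truth.herb_of_compound[cid], set()).add(cid)
        net = reverse_map(
            truth.overlap_pathway_names, lib.protein_to_pathways(), c2p, h2c
        )
        assert net.nodes_in_tier("compound") == set(truth.active_compound_ids)
        assert net.nodes_in_tier("protein") == set(truth.target_proteins)
        assert net.nodes_in_tier("herb") == set(h2c)

    def test_empty_overlap_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            net = reverse_map([], {}, {}, {})
        assert net.graph.number_of_nodes() == 0


class TestExport:
    def test_sif_has_one_line_per_edge(self, tmp_path):
        net = reverse_map(*chain_maps())
        out = tmp_path / "net.sif"
        export_network(net, out, "sif")
        lines = out.read_text().strip().splitlines()
        assert len(lines) == 3
        assert any("contains" in ln for ln in lines)

    def test_graphml_round_trip(self, tmp_path):
        net = reverse_map(*chain_maps())
        out = tmp_path / "net.graphml"
        export_network(net, out, "graphml")
        back = read_network_graphml(out)
        assert nx.is_isomorphic(net.graph, back.graph)
        for node in net.graph.nodes:
            assert back.graph.nodes[node]["tier"] == net.graph.nodes[node]["tier"]

    def test_node_count_conservation(self, tmp_path):
        net = reverse_map(*chain_maps())
        export_network(net, tmp_path / "n.graphml", "graphml")
        back = read_network_graphml(tmp_path / "n.graphml")
        assert back.graph.number_of_nodes() == sum(
            len(net.nodes_in_tier(t)) for t in TripartiteNetwork.TIERS
        )

    def test_unsupported_format_lists_supported(self, tmp_path):
        net = reverse_map(*chain_maps())
        with pytest.raises(ValueError, match="sif, graphml"):
            export_network(net, tmp_path / "x", "gexf")
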