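"""Panel expansion, edge filtering, enrichment scores and network decoration."""

import numpy as np
import pandas as pd
import pytest
import networkx as nx

from exoprot import (
    build_network,
    decorate_network,
    eligible_cytokines,
    enrichment_scores,
    expand_cytokine_panel,
    filter_edges,
    generate_network,
)
from exoprot.cytokines import DEFAULT_PANEL_SPEC, write_graphml, write_sif

CASE = "case_associated"
CTRL = "control_associated"


def edges_df(rows):
    return pd.DataFrame(rows, columns=["node1", "node2", "combined_score"])


class TestPanelExpansion:
    def test_range_expansion(self):
        names = expand_cytokine_panel(["CXCL1-16"])
        assert len(names) == 16
        assert names[0] == "CXCL1" and names[-1] == "CXCL16"

    def test_plain_name_passthrough(self):
        assert expand_cytokine_panel(["TNF"]) == ["TNF"]

    def test_default_panel_size(self):
        # TGFb + TNF + IFN + IL1..40 + CXCL1..16 + CCL1..27 = 3 + 83
        assert len(expand_cytokine_panel(DEFAULT_PANEL_SPEC)) == 86

    def test_deduplication_preserves_order(self):
        assert expand_cytokine_panel(["IL1-3", "IL2", "TNF"]) == ["IL1", "IL2", "IL3", "TNF"]

    @pytest.mark.parametrize("bad", ["IL5-2", "IL1-", "-3", ""])
    def test_malformed_range_rejected(self, bad):
        with pytest.raises(ValueError):
            expand_cytokine_panel([bad])


class TestBuildAndFilter:
    def test_score_filter_is_strict(self):
        net = build_network(
            edges_df([("IL6", "A", 0.41), ("IL6", "B", 0.40), ("IL6", "C", 0.39)]),
            ["IL6"],
        )
        kept = filter_edges(net, min_score=0.4)
        assert kept.has_edge("IL6", "A")
        assert not kept.has_edge("IL6", "B")  # exactly 0.40 removed
        assert not kept.has_edge("IL6", "C")

    def test_empty_network_stays_empty(self):
        net = build_network(edges_df([]), ["IL6"])
        assert filter_edges(net).number_of_edges() == 0

    def test_case_insensitive_cytokine_matching(self):
        net = build_network(edges_df([("il6", "A", 0.9)]), ["IL6"])
        assert net.nodes["IL6"]["kind"] == "cytokine"
        assert net.nodes["A"]["kind"] == "protein"

    def test_alias_table(self):
        net = build_network(edges_df([("TGFB1", "A", 0.9)]), ["TGFb"], aliases={"TGFB1": "TGFb"})
        assert net.nodes["TGFb"]["kind"] == "cytokine"

    def test_self_edge_rejected(self):
        with pytest.raises(ValueError, match="self-edge"):
            build_network(edges_df([("A", "A", 0.5)]), [])

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError):
            build_network(edges_df([("A", "B", 1.5)]), [])


class TestEligibility:
    def _net(self, k):
        rows = [("IL6", f"P{i}", 0.9) for i in range(k)]
        return build_network(edges_df(rows), ["IL6"])

    def test_five_connections_retained_four_dropped(self):
        sig = {f"P{i}": CASE for i in range(10)}
        assert eligible_cytokines(self._net(5), sig) == ["IL6"]
        assert eligible_cytokines(self._net(4), sig) == []

    def test_connections_to_nonsignificant_do_not_count(self):
        net = self._net(6)
        sig = {"P0": CASE}  # only one of the six neighbors is significant
        assert eligible_cytokines(net, sig) == []

    def test_no_cytokines_empty(self):
        net = build_network(edges_df([("A", "B", 0.9)]), [])
        assert eligible_cytokines(net, {"A": CASE}) == []


class TestEnrichment:
    def test_hand_built_double_ratio(self):
        """3 case proteins, 2 control proteins; cytokine wired 2-case /
        1-control.  Hand enumeration (protein_count weighting):
        e_case = (2/3)/(3/5) = 10/9, e_ctrl = (1/2)/(3/5) = 5/6,
        fold = 4/3."""
        rows = [("IL6", "A", 0.9), ("IL6", "B", 0.9), ("IL6", "X", 0.9)]
        net = build_network(edges_df(rows), ["IL6"])
        sig = {"A": CASE, "B": CASE, "C": CASE, "X": CTRL, "Y": CTRL}
        table = enrichment_scores(net, sig, min_connections=3)
        row = table.loc["IL6"]
        assert row.k_case == 2 and row.k_control == 1 and row.k_total == 3
        assert row.e_case == pytest.approx(10 / 9)
        assert row.e_control == pytest.approx(5 / 6)
        assert row.fold_connection == pytest.approx(4 / 3)

    def test_symmetric_network_fold_one(self):
        rows = [("IL6", p, 0.9) for p in ["A", "B", "X", "Y"]]
        net = build_network(edges_df(rows), ["IL6"])
        sig = {"A": CASE, "B": CASE, "X": CTRL, "Y": CTRL}
        table = enrichment_scores(net, sig, min_connections=1)
        assert table.loc["IL6", "e_case"] == pytest.approx(table.loc["IL6", "e_control"])
        assert table.loc["IL6", "fold_connection"] == pytest.approx(1.0)

    def test_no_control_connections_fold_infinite(self):
        rows = [("IL6", p, 0.9) for p in ["A", "B", "C", "D", "E"]]
        net = build_network(edges_df(rows), ["IL6"])
        sig = {p: CASE for p in "ABCDE"} | {"X": CTRL}
        table = enrichment_scores(net, sig)
        assert np.isinf(table.loc["IL6", "fold_connection"])

    def test_class_swap_inverts_fold(self):
        rows = [("IL6", "A", 0.9), ("IL6", "B", 0.9), ("IL6", "X", 0.9)]
        net = build_network(edges_df(rows), ["IL6"])
        sig = {"A": CASE, "B": CASE, "C": CASE, "X": CTRL, "Y": CTRL}
        flipped = {p: (CTRL if c == CASE else CASE) for p, c in sig.items()}
        f1 = enrichment_scores(net, sig, min_connections=1).loc["IL6", "fold_connection"]
        f2 = enrichment_scores(net, flipped, min_connections=1).loc["IL6", "fold_connection"]
        assert f1 == pytest.approx(1 / f2)

    def test_adding_case_edge_never_decreases_e_case(self):
        sig = {f"A{i}": CASE for i in range(6)} | {f"X{i}": CTRL for i in range(4)}
        rows = [("IL6", "A0", 0.9), ("IL6", "A1", 0.9), ("IL6", "X0", 0.9), ("IL6", "X1", 0.9)]
        net = build_network(edges_df(rows), ["IL6"])
        e_before = enrichment_scores(net, sig, min_connections=1).loc["IL6", "e_case"]
        net_more = build_network(edges_df(rows + [("IL6", "A2", 0.9)]), ["IL6"])
        e_after = enrichment_scores(net_more, sig, min_connections=1).loc["IL6", "e_case"]
        assert e_after >= e_before

    def test_edge_count_weighting_uses_protein_edges(self):
        """With edge_count weighting the totals come from protein-protein
        edges incident to each class (cytokine edges excluded)."""
        rows = [
            ("IL6", "A", 0.9), ("IL6", "B", 0.9), ("IL6", "X", 0.9),
            ("A", "B", 0.9), ("A", "C", 0.9), ("X", "Y", 0.9),  # protein-protein
        ]
        net = build_network(edges_df(rows), ["IL6"])
        sig = {"A": CASE, "B": CASE, "C": CASE, "X": CTRL, "Y": CTRL}
        table = enrichment_scores(net, sig, class_weighting="edge_count", min_connections=1)
        # T_case = 2 (A-B, A-C), T_ctrl = 1 (X-Y), T_total = 3
        row = table.loc["IL6"]
        assert row.e_case == pytest.approx((2 / 2) / (3 / 3))
        assert row.e_control == pytest.approx((1 / 1) / (3 / 3))

    def test_empty_class_reported_absent(self):
        rows = [("IL6", p, 0.9) for p in "ABCDE"]
        net = build_network(edges_df(rows), ["IL6"])
        sig = {p: CASE for p in "ABCDE"}  # no control proteins at all
        table = enrichment_scores(net, sig)
        assert np.isnan(table.loc["IL6", "e_control"])
        assert np.isnan(table.loc["IL6", "fold_connection"])

    def test_planted_cytokines_recovered_and_ranked_first(self):
        """Fixed-seed recovery: with strong planting (p_planted=0.8 vs
        p_base=0.05) every eligible planted cytokine leans to the case side
        (fold > 1) and planted cytokines outrank all non-planted ones."""
        proteins = [f"P{i:02d}" for i in range(60)]
        case = set(proteins[:30])
        sig = {p: (CASE if p in case else CTRL) for p in proteins}
        panel = expand_cytokine_panel(DEFAULT_PANEL_SPEC)
        planted = {"IL6", "TNF", "IL10"}
        edges = generate_network(
            proteins, case, panel, planted, p_base=0.05, p_planted=0.8, seed=1
        )
        net = filter_edges(build_network(edges, panel), min_score=0.4)
        table = enrichment_scores(net, sig)
        eligible_planted = [c for c in table.index if c in planted]
        assert len(eligible_planted) == 3
        assert (table.loc[eligible_planted, "fold_connection"] > 1).all()
        worst_planted = table.loc[eligible_planted, "fold_connection"].min()
        others = table.loc[[c for c in table.index if c not in planted], "fold_connection"]
        assert (others < worst_planted).all()


class TestDecoration:
    def _setup(self):
        rows = [
            ("IL6", "A", 0.9), ("IL6", "B", 0.9),
            ("IL10", "B", 0.9), ("IL10", "C", 0.9),
            ("A", "C", 0.7),
        ]
        net = build_network(edges_df(rows), ["IL6", "IL10"])
        net.add_node("LONER", kind="protein")
        diff = pd.DataFrame(
            {
                "pi_score": [2.0, -1.5, 0.3, 0.1],
                "class_label": [CASE, CTRL, "not_significant", "not_significant"],
            },
            index=["A", "B", "C", "LONER"],
        )
        enr = pd.DataFrame(index=["IL6", "IL10"])
        return net, diff, enr

    def test_size_is_absolute_pi_for_significant(self):
        net, diff, enr = self._setup()
        nodes, edges = decorate_network(net, diff, enr)
        assert nodes.loc["A", "size"] == 2.0
        assert nodes.loc["B", "size"] == 1.5
        assert np.isnan(nodes.loc["C", "size"])  # not significant: no size

    def test_pro_takes_precedence_over_anti(self):
        net, diff, enr = self._setup()
        nodes, _ = decorate_network(net, diff, enr)
        # B touches IL6 (pro) and IL10 (anti) -> pro; C touches only IL10 -> anti
        assert nodes.loc["B", "inflammation_color"] == "pro"
        assert nodes.loc["C", "inflammation_color"] == "anti"

    def test_isolated_protein_colored_none(self):
        net, diff, enr = self._setup()
        nodes, _ = decorate_network(net, diff, enr)
        assert nodes.loc["LONER", "inflammation_color"] == "none"

    def test_protein_missing_from_table_warns(self):
        net, diff, enr = self._setup()
        with pytest.warns(UserWarning, match="absent"):
            nodes, _ = decorate_network(net, diff.drop("A"), enr)
        assert np.isnan(nodes.loc["A", "pi_score"])

    def test_edge_attribute_is_score(self):
        net, diff, enr = self._setup()
        _, edges = decorate_network(net, diff, enr)
        pair = edges.set_index(["node1", "node2"])["combined_score"]
        lookup = {frozenset(k): v for k, v in pair.items()}
        assert lookup[frozenset(("A", "C"))] == 0.7

    def test_graphml_and_sif_roundtrip(self, tmp_path):
        net, diff, enr = self._setup()
        nodes, _ = decorate_network(net, diff, enr)
        gpath = tmp_path / "net.graphml"
        write_graphml(net, nodes, gpath)
        back = nx.read_graphml(gpath)
        assert back.nodes["A"]["pi_score"] == 2.0
        assert back.nodes["IL6"]["kind"] == "cytokine"
        spath = tmp_path / "net.sif"
        write_sif(net, spath)
        lines = spath.read_text().strip().splitlines()
        assert any(line.split("\t") == ["A", "interacts", "C"] for line in lines)
        assert any(line == "LONER" for line in lines)  # isolates listed
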