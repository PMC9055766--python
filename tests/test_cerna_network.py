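import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ricecerna.annotation_io import ExpressionMatrix
from ricecerna.cerna_network import (
    CeRNAPair,
    ScreenThresholds,
    build_network,
    export_network,
    hypergeom_shared_p,
    import_network_tsv,
    intersect_de,
    screen_pairs,
    sign_filter,
)
from ricecerna.target_pred import TargetMap


class TestHypergeom:
    def test_worked_example(self):
        # all 5 of the lncRNA's miRNAs also among the mRNA's 5, universe 20:
        # only one of C(20,5) draws achieves it
        assert hypergeom_shared_p(5, 5, 5, 20) == pytest.approx(
            1.0 / math.comb(20, 5), rel=0, abs=0
        )

    def test_k_zero_is_certain(self):
        assert hypergeom_shared_p(0, 3, 7, 20) == 1.0

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            hypergeom_shared_p(1, 5, 5, 0)
        with pytest.raises(ValueError):
            hypergeom_shared_p(6, 5, 10, 20)  # k > min(K, n)
        with pytest.raises(ValueError):
            hypergeom_shared_p(1, 25, 5, 20)  # K > M

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_scipy_survival(self, seed):
        rng = np.random.default_rng(seed)
        M = int(rng.integers(1, 60))
        K = int(rng.integers(0, M + 1))
        n = int(rng.integers(0, M + 1))
        k = int(rng.integers(0, min(K, n) + 1))
        ours = hypergeom_shared_p(k, K, n, M)
        scipy_p = float(sps.hypergeom.sf(k - 1, M, K, n))
        assert ours == pytest.approx(scipy_p, rel=1e-10, abs=1e-12)

    def test_antimonotone_in_k(self):
        prev = 1.1
        for k in range(0, 6):
            p = hypergeom_shared_p(k, 5, 8, 30)
            assert p <= prev
            prev = p


def _toy_target_map():
    """lncRNA LA shares 3 of its 4 miRNAs with GA; LB shares 1 with GA."""
    tm = TargetMap()
    for m in ("m1", "m2", "m3", "m4"):
        tm.add(m, "LA", "lncRNA")
    for m in ("m1", "m2", "m3", "m5"):
        tm.add(m, "GA", "mRNA")
    tm.add("m5", "LB", "lncRNA")
    for m in ("m6", "m7", "m8"):
        tm.add(m, "GB", "mRNA")
        tm.add(m, "LB", "lncRNA")
    return tm


class TestScreenPairs:
    def test_statistics_and_thresholds(self):
        tm = _toy_target_map()
        allp = screen_pairs(tm, return_all=True)
        by_id = {(p.lnc_id, p.mrna_id): p for p in allp}
        # enumerated pairs share >= 1 miRNA
        assert set(by_id) == {("LA", "GA"), ("LB", "GA"), ("LB", "GB")}
        pa = by_id[("LA", "GA")]
        assert (pa.k, pa.K, pa.n, pa.M) == (3, 4, 4, 8)
        assert pa.shared_mirnas == frozenset({"m1", "m2", "m3"})
        assert pa.p_hyper == pytest.approx(hypergeom_shared_p(3, 4, 4, 8))
        # screened list applies k >= 3, p < 0.05, fdr < 0.1
        kept = screen_pairs(tm)
        assert {(p.lnc_id, p.mrna_id) for p in kept} <= set(by_id)
        for p in kept:
            assert p.k >= 3 and p.p_hyper < 0.05 and p.fdr < 0.1

    def test_min_shared_gate(self):
        tm = _toy_target_map()
        loose = screen_pairs(tm, ScreenThresholds(1, 1.0, 1.0))
        tight = screen_pairs(tm, ScreenThresholds(3, 1.0, 1.0))
        assert {(p.lnc_id, p.mrna_id) for p in tight} <= {
            (p.lnc_id, p.mrna_id) for p in loose
        }
        assert all(p.k >= 3 for p in tight)

    def test_universe_override(self):
        tm = _toy_target_map()
        p_small = screen_pairs(tm, return_all=True)[0]
        p_big = screen_pairs(tm, universe_size=100, return_all=True)
        p_big = [
            q for q in p_big
            if (q.lnc_id, q.mrna_id) == (p_small.lnc_id, p_small.mrna_id)
        ][0]
        # a larger universe makes the same overlap more surprising
        assert p_big.p_hyper < p_small.p_hyper

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            screen_pairs(TargetMap())


class TestIntersectDE:
    def _pair(self):
        return CeRNAPair(
            "LA", "GA", frozenset({"m1", "m2", "m3"}), 3, 4, 4, 8, 0.01, 0.02
        )

    def test_keeps_only_fully_de_pairs(self):
        p = self._pair()
        de_lnc = {"LA": "down"}
        de_mrna = {"GA": "down"}
        kept, edges = intersect_de([p], de_lnc, {"m1": "up"}, de_mrna)
        assert len(kept) == 1
        assert kept[0].de_shared_mirnas == frozenset({"m1"})
        assert ("LA", "mir-target", "m1") in edges
        assert ("m1", "mir-target", "GA") in edges
        # no DE miRNA -> dropped
        assert intersect_de([p], de_lnc, {}, de_mrna)[0] == []
        # lncRNA ns -> dropped
        assert intersect_de([p], {"LA": "ns"}, {"m1": "up"}, de_mrna)[0] == []


def _expr_from(rows: dict[str, list[float]], reps=3) -> ExpressionMatrix:
    samples = [f"CK{i+1}" for i in range(reps)] + [f"D{i+1}" for i in range(reps)]
    cond = {s: ("CK" if s.startswith("CK") else "D") for s in samples}
    df = pd.DataFrame(rows, index=samples).T
    df.columns = samples
    return ExpressionMatrix(df, "normalized", cond)


class TestSignFilter:
    def _pair(self):
        return CeRNAPair(
            "LA", "GA", frozenset({"m1"}), 3, 4, 4, 8, 0.01, 0.02,
            de_shared_mirnas=frozenset({"m1"}),
        )

    def test_correlation_mode_keeps_cerna_pattern(self):
        lnc = _expr_from({"LA": [10, 11, 12, 2, 2.5, 3]})
        mrna = _expr_from({"GA": [20, 22, 24, 4, 5, 6]})
        mir = _expr_from({"m1": [1, 1.5, 2, 30, 32, 34]})
        kept, edges = sign_filter([self._pair()], lnc, mir, mrna)
        assert len(kept) == 1
        assert kept[0].corr_lnc_mrna > 0
        assert edges

    def test_correlation_mode_rejects_wrong_sign(self):
        lnc = _expr_from({"LA": [10, 11, 12, 2, 2.5, 3]})
        mrna = _expr_from({"GA": [4, 5, 6, 20, 22, 24]})  # anti-correlated
        mir = _expr_from({"m1": [1, 1.5, 2, 30, 32, 34]})
        kept, _ = sign_filter([self._pair()], lnc, mir, mrna)
        assert kept == []

    def test_mirna_must_oppose_both(self):
        lnc = _expr_from({"LA": [10, 11, 12, 2, 2.5, 3]})
        mrna = _expr_from({"GA": [20, 22, 24, 4, 5, 6]})
        mir = _expr_from({"m1": [30, 32, 34, 1, 1.5, 2]})  # follows the targets
        kept, _ = sign_filter([self._pair()], lnc, mir, mrna)
        assert kept == []

    def test_two_replicates_falls_back_to_de_directions(self):
        lnc = _expr_from({"LA": [10, 11, 2, 3]}, reps=2)
        mrna = _expr_from({"GA": [20, 22, 4, 5]}, reps=2)
        mir = _expr_from({"m1": [1, 2, 30, 32]}, reps=2)
        de_l, de_m, de_r = {"LA": "down"}, {"m1": "up"}, {"GA": "down"}
        kept, _ = sign_filter([self._pair()], lnc, mir, mrna, de_l, de_m, de_r)
        assert len(kept) == 1 and math.isnan(kept[0].corr_lnc_mrna)
        # opposing-direction rule violated -> dropped
        kept2, _ = sign_filter(
            [self._pair()], lnc, mir, mrna, de_l, {"m1": "down"}, de_r
        )
        assert kept2 == []

    def test_constant_vector_warns_and_falls_back(self):
        lnc = _expr_from({"LA": [5, 5, 5, 5, 5, 5]})
        mrna = _expr_from({"GA": [20, 22, 24, 4, 5, 6]})
        mir = _expr_from({"m1": [1, 1.5, 2, 30, 32, 34]})
        with pytest.warns(UserWarning, match="constant"):
            kept, _ = sign_filter(
                [self._pair()], lnc, mir, mrna,
                {"LA": "down"}, {"m1": "up"}, {"GA": "down"},
            )
        assert len(kept) == 1

    def test_min_abs_corr_gate(self):
        rng = np.random.default_rng(8)
        base = rng.uniform(5, 10, 6)
        lnc = _expr_from({"LA": list(base)})
        mrna = _expr_from({"GA": list(base + rng.normal(0, 4, 6))})
        mir = _expr_from({"m1": list(30 - base + rng.normal(0, 4, 6))})
        weak = sign_filter([self._pair()], lnc, mir, mrna, min_abs_corr=0.0)[0]
        strong = sign_filter([self._pair()], lnc, mir, mrna, min_abs_corr=0.999)[0]
        assert len(strong) <= len(weak)


class TestNetwork:
    def _network(self):
        pair = CeRNAPair(
            "LA", "GA", frozenset({"m1", "m2", "m3"}), 3, 4, 4, 8, 0.01, 0.02,
            corr_lnc_mrna=0.9, de_shared_mirnas=frozenset({"m1", "m2", "m3"}),
        )
        edges = []
        for m in ("m1", "m2", "m3"):
            edges += [("LA", "mir-target", m), (m, "mir-target", "GA")]
        classes = {"LA": "lncRNA", "GA": "mRNA", "m1": "miRNA",
                   "m2": "miRNA", "m3": "miRNA"}
        return build_network([pair], edges, classes, {"LA": "down"})

    def test_composition_and_attributes(self):
        net = self._network()
        assert net.node_counts() == {"lncRNA": 1, "miRNA": 3, "mRNA": 1}
        assert net.n_components() == 1
        d = net.graph.edges["LA", "GA"]
        assert d["edge_type"] == "ceRNA" and d["k"] == 3
        assert net.graph.nodes["LA"]["direction"] == "down"

    def test_export_round_trip_and_determinism(self, tmp_path):
        net = self._network()
        d1, d2 = tmp_path / "a", tmp_path / "b"
        export_network(net, d1)
        export_network(net, d2)
        for name in ("network.sif", "nodes.tsv", "edges.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
        back = import_network_tsv(d1 / "nodes.tsv", d1 / "edges.tsv")
        assert set(back.graph.nodes) == set(net.graph.nodes)
        assert set(map(frozenset, back.graph.edges)) == set(
            map(frozenset, net.graph.edges)
        )
        sif = (d1 / "network.sif").read_text().splitlines()
        assert len(sif) == net.graph.number_of_edges()
        assert all(len(line.split("\t")) == 3 for line in sif)

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_network(self._network(), tmp_path, formats=("XGMML",))
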