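"""CPM + control-anchored TMM normalization and activity scores."""

import numpy as np
import pandas as pd
import pytest

import e2mpra as m
from e2mpra.activity_scoring import bh_adjust, tmm_factor


def _frag_table(rows):
    return pd.DataFrame(rows, columns=["element_id", "replicate", "channel",
                                       "count"]).assign(n_barcodes=pd.NA)


def _with_controls(extra_rows, n_ctrl=10, ctrl_count=100, replicate=1):
    """Fragment table where control elements have enriched == inserted,
    so the TMM factor exactly cancels the depth ratio and activities
    reduce to log2(enriched/inserted) of the raw counts."""
    rows = []
    for i in range(n_ctrl):
        for ch in ("inserted", "enriched_ATAC"):
            rows.append((f"ctrl{i}", replicate, ch, ctrl_count))
    return _frag_table(rows + extra_rows), {f"ctrl{i}" for i in range(n_ctrl)}


class TestCPM:
    def test_direct_arithmetic(self):
        t = _frag_table([("a", 1, "inserted", 1), ("b", 1, "inserted", 3)])
        out = m.cpm_normalize(t)
        assert out["cpm"].tolist() == [2.5e5, 7.5e5]

    def test_scale_invariance(self):
        t = _frag_table([("a", 1, "inserted", 2), ("b", 1, "inserted", 6)])
        t10 = t.assign(count=t["count"] * 10)
        assert np.allclose(m.cpm_normalize(t)["cpm"],
                           m.cpm_normalize(t10)["cpm"])

    def test_zero_total_errors(self):
        t = _frag_table([("a", 1, "inserted", 0)])
        with pytest.raises(ValueError, match="zero channel total"):
            m.cpm_normalize(t)


class TestTMM:
    def test_identity_controls(self):
        x = np.array([10.0, 20, 30, 40, 50])
        assert tmm_factor(x, x) == pytest.approx(1.0)

    def test_constant_ratio_closed_form(self):
        x = np.array([10.0, 20, 30, 40, 50])
        for c in (0.5, 2.0, 3.7):
            assert tmm_factor(c * x, x) == pytest.approx(c)

    def test_idempotence_machine_precision(self):
        rng = np.random.default_rng(0)
        ins = rng.uniform(10, 100, size=50)
        enr = ins * rng.lognormal(0.3, 0.4, size=50)
        f = tmm_factor(enr, ins)
        assert abs(np.log2(tmm_factor(enr / f, ins))) < 1e-12

    def test_too_few_controls(self):
        with pytest.raises(ValueError, match="usable controls"):
            tmm_factor([1.0, 2.0], [1.0, 2.0])

    def test_trimming_rejects_outlier(self):
        # one wild control must not move the factor
        x = np.full(20, 50.0)
        enr = x.copy()
        enr[0] = 5000.0
        assert tmm_factor(enr, x) == pytest.approx(1.0)


class TestEpigeneticActivity:
    def test_balanced_element_is_zero(self):
        table, ctrl = _with_controls([("e", 1, "inserted", 40),
                                      ("e", 1, "enriched_ATAC", 40)])
        act = m.epigenetic_activity(table, ctrl, "enriched_ATAC", pool=False)
        val = act.loc[act.element_id == "e", "log2_activity"].iloc[0]
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_pooling_is_sum_then_ratio(self):
        rows = []
        for rep, (enr, ins) in ((1, (20, 40)), (2, (60, 40))):
            t, ctrl = _with_controls([("e", rep, "inserted", ins),
                                      ("e", rep, "enriched_ATAC", enr)],
                                     replicate=rep)
            rows.append(t)
        table = pd.concat(rows, ignore_index=True)
        act = m.epigenetic_activity(table, ctrl, "enriched_ATAC")
        pooled = act[(act.element_id == "e") & (act.replicate == "pooled")]
        # pooled = log2(80/80) = 0, not the mean of per-replicate scores
        assert pooled["log2_activity"].iloc[0] == pytest.approx(0.0,
                                                                abs=1e-12)

    def test_zero_inserted_element_missing(self):
        table, ctrl = _with_controls([("e", 1, "inserted", 0),
                                      ("e", 1, "enriched_ATAC", 10)])
        act = m.epigenetic_activity(table, ctrl, "enriched_ATAC", pool=False)
        assert "e" not in set(act["element_id"])

    def test_zero_enriched_uses_pseudocount(self):
        table, ctrl = _with_controls([("e", 1, "inserted", 40),
                                      ("e", 1, "enriched_ATAC", 0)])
        act = m.epigenetic_activity(table, ctrl, "enriched_ATAC", pool=False)
        val = act.loc[act.element_id == "e", "log2_activity"].iloc[0]
        assert np.isfinite(val) and val < -5

    def test_scale_equivariance(self):
        table, ctrl = _with_controls([("e", 1, "inserted", 40),
                                      ("e", 1, "enriched_ATAC", 90)])
        act1 = m.epigenetic_activity(table, ctrl, "enriched_ATAC", pool=False)
        t2 = table.copy()
        enr = t2["channel"] == "enriched_ATAC"
        t2.loc[enr, "count"] *= 7  # channel-wide scaling absorbed by CPM+TMM
        act2 = m.epigenetic_activity(t2, ctrl, "enriched_ATAC", pool=False)
        assert np.allclose(act1["log2_activity"], act2["log2_activity"])


class TestMpraActivity:
    def _barcodes(self, rows):
        return pd.DataFrame(rows, columns=["element_id", "replicate",
                                           "barcode", "dna", "rna"])

    def _ctrl_rows(self, n=10, rep=1):
        return [(f"ctrl{i}", rep, f"cb{i}", 50, 50) for i in range(n)]

    def test_balanced_barcodes_zero(self):
        bdf = self._barcodes(self._ctrl_rows()
                             + [("e", 1, "b1", 30, 30), ("e", 1, "b2", 7, 7)])
        act = m.mpra_activity(bdf, {f"ctrl{i}" for i in range(10)},
                              pool=False)
        assert act.loc[act.element_id == "e", "log2_activity"].iloc[0] == \
            pytest.approx(0.0, abs=1e-12)

    def test_log_mean_aggregation(self):
        bdf = self._barcodes(self._ctrl_rows()
                             + [("e", 1, "b1", 10, 20), ("e", 1, "b2", 10, 80)])
        act = m.mpra_activity(bdf, {f"ctrl{i}" for i in range(10)},
                              pool=False)
        # ratios 2 and 8 -> mean log2 = (1 + 3) / 2 = 2
        assert act.loc[act.element_id == "e", "log2_activity"].iloc[0] == \
            pytest.approx(2.0, abs=1e-9)

    def test_ratio_of_sums_mode(self):
        bdf = self._barcodes(self._ctrl_rows()
                             + [("e", 1, "b1", 10, 20), ("e", 1, "b2", 10, 80)])
        act = m.mpra_activity(bdf, {f"ctrl{i}" for i in range(10)},
                              pool=False, aggregation="ratio_of_sums")
        # log2(100/20) = log2 5
        assert act.loc[act.element_id == "e", "log2_activity"].iloc[0] == \
            pytest.approx(np.log2(5), abs=1e-9)

    def test_agrees_with_epigenetic_on_degenerate_input(self):
        # one barcode per element, barcode counts equal fragment counts
        elements = [("e1", 30, 60), ("e2", 40, 20)] + \
            [(f"ctrl{i}", 50, 50) for i in range(10)]
        bdf = self._barcodes([(e, 1, f"b_{e}", d, r)
                              for e, d, r in elements])
        frag = _frag_table(
            [(e, 1, "inserted", d) for e, d, r in elements]
            + [(e, 1, "enriched_ATAC", r) for e, d, r in elements])
        ctrl = {f"ctrl{i}" for i in range(10)}
        a_mpra = m.mpra_activity(bdf, ctrl, pool=False).set_index("element_id")
        a_epi = m.epigenetic_activity(frag, ctrl, "enriched_ATAC",
                                      pool=False).set_index("element_id")
        for e in ("e1", "e2"):
            assert a_mpra.loc[e, "log2_activity"] == pytest.approx(
                a_epi.loc[e, "log2_activity"], abs=1e-9)


class TestCategoryTestsAndQC:
    def _records(self, values_by_cat):
        rows = []
        cats = {}
        for cat, values in values_by_cat.items():
            for i, v in enumerate(values):
                eid = f"{cat}{i}"
                rows.append({"element_id": eid, "assay": "MPRA",
                             "replicate": "pooled", "log2_activity": v,
                             "support": 10})
                cats[eid] = cat
        return pd.DataFrame(rows), cats

    def test_identical_category_not_significant(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 50)
        rec, cats = self._records({"random_genomic": base, "same": base})
        out = m.category_tests(rec, cats)
        assert out["p"].iloc[0] > 0.9

    def test_shifted_category_significant(self):
        rng = np.random.default_rng(1)
        rec, cats = self._records({
            "random_genomic": rng.normal(0, 1, 50),
            "active": rng.normal(5, 1, 50)})
        out = m.category_tests(rec, cats)
        assert out["adjusted_p"].iloc[0] < 1e-4

    def test_bh_hand_computed(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_bh_monotone(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=40)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()

    def test_replicate_qc_extremes(self):
        rows = []
        for i, v in enumerate([1.0, 2.0, 3.0, 4.0]):
            rows.append({"element_id": f"e{i}", "assay": "MPRA",
                         "replicate": 1, "log2_activity": v, "support": 1})
            rows.append({"element_id": f"e{i}", "assay": "MPRA",
                         "replicate": 2, "log2_activity": v, "support": 1})
            rows.append({"element_id": f"e{i}", "assay": "MPRA",
                         "replicate": 3, "log2_activity": -v, "support": 1})
        qc = m.replicate_qc(pd.DataFrame(rows)).set_index(
            ["replicate_a", "replicate_b"])
        assert qc.loc[(1, 2), "spearman_rho"] == pytest.approx(1.0)
        assert qc.loc[(1, 3), "spearman_rho"] == pytest.approx(-1.0)

    def test_high_depth_replicates_correlate(self, small_designs,
                                             control_ids):
        # element-level latent spread so ranks are informative, then high
        # sequencing depth so each replicate estimates its latent tightly
        truth = m.plant_effects(small_designs, seed=3,
                                config=m.SimConfig(mean_inserted=3000,
                                                   mean_enriched=1000,
                                                   noise_sd=1.0))
        counts = m.simulate_counts(truth, replicates=2, channels="fragments")
        act = m.epigenetic_activity(counts.fragments, control_ids,
                                    "enriched_ATAC")
        varied = {e for e, v in truth.latent["ATAC"].items() if v != 0}
        qc = m.replicate_qc(act[act["element_id"].isin(varied)])
        assert (qc["spearman_rho"] > 0.9).all()
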