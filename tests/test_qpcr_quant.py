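"""Relative quantification, plate calibration and dystrophin metrics."""

import numpy as np
import pandas as pd
import pytest

from dystromark import qpcr_quant as qq
from dystromark import synthetic_data as syn


def run_pipeline(sim):
    calib = sim.truth["calibration_samples"]
    rq = qq.rq_table_from_cq(sim.table, calib)
    cal, factors = qq.calibrate_plates(rq, calib)
    return qq.normalize_to_references(cal), factors


class TestCqToRq:
    @pytest.mark.parametrize(
        "cq, eff, anchor, expected",
        [
            (23.0, 1.0, 20.0, 0.125),
            (20.0, 1.0, 20.0, 1.0),
            (20.0, 0.95, 23.0, 1.95 ** 3),
        ],
    )
    def test_closed_forms(self, cq, eff, anchor, expected):
        assert qq.cq_to_rq(cq, eff, anchor) == pytest.approx(expected, rel=1e-12)

    def test_non_detect_propagates_as_missing(self):
        out = qq.cq_to_rq(np.array([20.0, np.nan]), 1.0, 20.0)
        assert out[0] == 1.0 and np.isnan(out[1])

    def test_efficiency_bounds(self):
        with pytest.raises(ValueError):
            qq.cq_to_rq(20.0, efficiency=0.3, anchor_cq=20.0)


class TestReplicates:
    def test_mean_and_flag(self):
        tbl = pd.DataFrame(
            {
                "sample_id": ["s"] * 4,
                "target": ["g"] * 4,
                "plate_id": ["P1", "P1", "P2", "P2"],
                "cq": [20.0, 21.5, 22.0, 22.1],
            }
        )
        agg = qq.aggregate_replicates(tbl)
        assert set(agg["plate_id"]) == {"P1", "P2"}
        noisy = agg.set_index("plate_id")
        assert noisy.loc["P1", "replicate_flag"]  # SD > 0.5 cycles
        assert not noisy.loc["P2", "replicate_flag"]


class TestCalibration:
    def test_global_offset_cancels_exactly(self):
        sim = syn.simulate_cq_table(
            6, {"G": 1.0}, plate_offsets=(0.0, 1.0), cq_noise_sd=0.0,
            sample_loading_sd=0.0, seed=0
        )
        calib = sim.truth["calibration_samples"]
        rq = qq.rq_table_from_cq(sim.table, calib)
        cal, _ = qq.calibrate_plates(rq, calib)
        # calibration samples measured on both plates agree exactly afterwards
        for sid in calib:
            sub = cal[(cal["sample_id"] == sid)]
            for _, grp in sub.groupby("target"):
                assert grp["rq_calibrated"].max() == pytest.approx(
                    grp["rq_calibrated"].min(), rel=1e-12
                )

    def test_single_plate_factor_one(self):
        sim = syn.simulate_cq_table(6, {"G": 2.0}, plate_offsets=(0.7,), seed=1)
        rq = qq.rq_table_from_cq(sim.table, sim.truth["calibration_samples"])
        cal, factors = qq.calibrate_plates(rq, sim.truth["calibration_samples"])
        assert (factors["factor"] == 1.0).all()
        assert np.allclose(cal["rq_calibrated"], cal["rq_raw"])

    def test_three_plate_offsets_recovered_up_to_scale(self):
        offsets = (0.0, -1.0, 1.0)  # Cq offsets: -1 cycle => RQ x2, +1 => x0.5
        sim = syn.simulate_cq_table(
            9, {"G": 1.0}, plate_offsets=offsets, cq_noise_sd=0.0,
            sample_loading_sd=0.0, seed=2
        )
        rq = qq.rq_table_from_cq(sim.table, sim.truth["calibration_samples"])
        _, factors = qq.calibrate_plates(rq, sim.truth["calibration_samples"])
        f = factors[factors["target"] == "G"].set_index("plate_id")["factor"]
        rel = (f / f["P1"]).to_numpy()
        assert rel == pytest.approx([1.0, 0.5, 2.0], rel=1e-9)

    def test_idempotent(self):
        sim = syn.simulate_cq_table(6, {"G": 3.0}, plate_offsets=(0.0, 0.4),
                                    cq_noise_sd=0.2, seed=3)
        calib = sim.truth["calibration_samples"]
        rq = qq.rq_table_from_cq(sim.table, calib)
        cal, _ = qq.calibrate_plates(rq, calib)
        again = cal.drop(columns=["rq_raw"]).rename(columns={"rq_calibrated": "rq_raw"})
        _, factors2 = qq.calibrate_plates(again, calib)
        assert (factors2["factor"] - 1.0).abs().max() < 1e-12

    def test_missing_calibration_sample_named(self):
        sim = syn.simulate_cq_table(6, {"G": 2.0}, plate_offsets=(0.0, 0.5), seed=4)
        calib = sim.truth["calibration_samples"]
        broken = sim.table[
            ~((sim.table["sample_id"] == calib[0]) & (sim.table["plate_id"] == "P2"))
        ]
        rq = qq.rq_table_from_cq(broken, calib)
        with pytest.raises(qq.CalibrationError, match=calib[0]):
            qq.calibrate_plates(rq, calib)

    def test_arbitrary_plate_shift_invariance(self):
        # adding delta to every Cq of one plate must not move normalised ratios
        base = syn.simulate_cq_table(8, {"G": 8.0}, plate_offsets=(0.0, 0.0),
                                     cq_noise_sd=0.0, seed=5)
        shifted = base.table.copy()
        shifted.loc[shifted["plate_id"] == "P2", "cq"] += 1.234
        norm_a, _ = run_pipeline(base)
        sim_b = syn.SimulatedCqTable(table=shifted, truth=base.truth, seed=5)
        norm_b, _ = run_pipeline(sim_b)
        ra = qq.group_fold_change(norm_a)["G"]
        rb = qq.group_fold_change(norm_b)["G"]
        assert rb == pytest.approx(ra, rel=1e-9)


class TestNormalisation:
    def _table(self, goi_rq, refs):
        rows = [{"sample_id": "s1", "target": "GOI", "rq_raw": goi_rq}]
        rows += [
            {"sample_id": "s1", "target": t, "rq_raw": v}
            for t, v in zip(("SDHA", "RPL13a", "HPRT1"), refs)
        ]
        return pd.DataFrame(rows)

    def test_reference_geomean(self):
        norm = qq.normalize_to_references(self._table(8.0, (2.0, 2.0, 2.0)))
        assert norm["rq_normalised"].iloc[0] == pytest.approx(4.0)
        norm = qq.normalize_to_references(self._table(8.0, (1.0, 4.0, 16.0)))
        assert norm["rq_normalised"].iloc[0] == pytest.approx(2.0)  # geomean 4

    def test_reference_scaling_inverse(self):
        a = qq.normalize_to_references(self._table(8.0, (1.0, 2.0, 4.0)))
        b = qq.normalize_to_references(self._table(8.0, (3.0, 6.0, 12.0)))
        assert b["rq_normalised"].iloc[0] == pytest.approx(
            a["rq_normalised"].iloc[0] / 3.0
        )

    def test_reference_permutation_invariance(self):
        a = qq.normalize_to_references(self._table(8.0, (1.0, 4.0, 16.0)))
        b = qq.normalize_to_references(self._table(8.0, (16.0, 1.0, 4.0)))
        assert a["rq_normalised"].iloc[0] == b["rq_normalised"].iloc[0]

    def test_missing_reference_excludes_sample(self):
        tbl = self._table(8.0, (2.0, 2.0, 2.0)).iloc[:-1]  # drop HPRT1
        norm = qq.normalize_to_references(tbl)
        assert norm.empty and norm.attrs["excluded"] == ["s1"]

    def test_noiseless_fold_change_recovery(self):
        sim = syn.simulate_cq_table(
            8, {"G": 8.0}, plate_offsets=(0.0, 1.7, -0.9), cq_noise_sd=0.0, seed=6
        )
        norm, _ = run_pipeline(sim)
        assert qq.group_fold_change(norm)["G"] == pytest.approx(8.0, rel=1e-9)

    def test_noisy_fold_change_envelope(self):
        sim = syn.simulate_cq_table(
            12, {"G": 100.0}, plate_offsets=(0.0, 0.5), cq_noise_sd=0.25, seed=5
        )
        norm, _ = run_pipeline(sim)
        assert 70.0 <= qq.group_fold_change(norm)["G"] <= 140.0


class TestDystrophinPanel:
    def _norm_table(self, rows):
        return pd.DataFrame(
            [
                {"sample_id": sid, "target": t, "rq_normalised": v}
                for sid, t, v in rows
            ]
        )

    def test_fraction_arithmetic(self):
        tbl = self._norm_table(
            [
                ("s1", "DMD_ex1-2", 1.0),
                ("s1", "DMD_ex44-45", 0.4),
                ("s1", "DMD_ex62-64", 0.1),
                ("s1", "DMD_dp71", 0.125),
            ]
        )
        (panel,) = qq.dystrophin_metrics(tbl)
        assert panel.mid_fraction == pytest.approx(0.4)
        assert panel.maturity_fraction == pytest.approx(0.1)
        assert panel.log10_dp71 == pytest.approx(np.log10(0.125))

    def test_boundary_maturity_one(self):
        tbl = self._norm_table(
            [("s1", "DMD_ex1-2", 0.7), ("s1", "DMD_ex62-64", 0.7)]
        )
        (panel,) = qq.dystrophin_metrics(tbl)
        assert panel.maturity_fraction == pytest.approx(1.0)

    def test_decay_ratio_between_genotypes(self):
        # mutant mature pool scaled to 0.2 of WT at equal initiation
        tbl = self._norm_table(
            [
                ("wt", "DMD_ex1-2", 1.0),
                ("wt", "DMD_ex62-64", 0.5),
                ("mut", "DMD_ex1-2", 1.0),
                ("mut", "DMD_ex62-64", 0.1),
            ]
        )
        panels = {p.sample_id: p for p in qq.dystrophin_metrics(tbl)}
        ratio = panels["mut"].maturity_fraction / panels["wt"].maturity_fraction
        assert ratio == pytest.approx(0.2)

    def test_nonpositive_initiation_raises(self):
        tbl = self._norm_table([("s1", "DMD_ex1-2", -1.0)])
        with pytest.raises(ValueError):
            qq.dystrophin_metrics(tbl)


class TestLog10:
    def test_closed_forms(self):
        tbl = pd.DataFrame({"rq": [1.0, 100.0, 0.125]})
        out = qq.log10_transform(tbl, ["rq"])
        assert out["log10_rq"].tolist() == pytest.approx([0.0, 2.0, -0.90309], abs=1e-5)

    def test_nonpositive_names_row(self):
        tbl = pd.DataFrame({"rq": [1.0, 0.0]}, index=["good", "bad"])
        with pytest.raises(ValueError, match="bad"):
            qq.log10_transform(tbl, ["rq"])

    def test_missing_propagates(self):
        out = qq.log10_transform(pd.DataFrame({"rq": [1.0, np.nan]}), ["rq"])
        assert np.isnan(out["log10_rq"].iloc[1])


def test_reference_stability_diagnostic():
    sim = syn.simulate_cq_table(10, {"G": 2.0}, ref_gene_sd=0.1, cq_noise_sd=0.0, seed=7)
    rq = qq.rq_table_from_cq(sim.table, sim.truth["calibration_samples"])
    m = qq.reference_stability_m(rq)
    assert set(m.index) == {"SDHA", "RPL13a", "HPRT1"}
    assert (m > 0).all()
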