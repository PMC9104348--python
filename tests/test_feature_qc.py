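"""Blank / presence / RSD filters and QC drift correction."""

import numpy as np
import pytest

from metatrack.feature_qc import (
    QcError,
    blank_filter,
    qc_drift_correct,
    qc_presence_filter,
    qc_rsd_filter,
)
from metatrack.io_tables import FeatureTable, Group, SampleRecord


def _table(feature_rows: dict[str, list[float]], groups: list[Group]):
    sample_ids = [f"s{i}" for i in range(len(groups))]
    records = []
    for i, g in enumerate(groups):
        records.append(
            SampleRecord(
                sample_ids[i],
                g,
                mouse_id="m" if g in (Group.TKO, Group.CTRL) else None,
                age_weeks=10.0 if g in (Group.TKO, Group.CTRL) else None,
                lifespan_weeks=30.0 if g in (Group.TKO, Group.CTRL) else None,
                injection_order=i + 1,
            )
        )
    table = FeatureTable(
        list(feature_rows), sample_ids, np.array(list(feature_rows.values()), dtype=float)
    )
    by_group = {
        g: [r.sample_id for r in records if r.group is g] for g in Group
    }
    return table, records, by_group


class TestBlankFilter:
    def _fixture(self, study_mean, blank_mean):
        groups = [Group.TKO, Group.CTRL, Group.BLANK]
        rows = {"f": [study_mean, study_mean, blank_mean]}
        return _table(rows, groups)

    def test_below_factor_removed(self):
        table, _, g = self._fixture(99, 20)
        out, rep = blank_filter(table, g[Group.TKO] + g[Group.CTRL], g[Group.BLANK])
        assert out.n_features == 0 and rep.removed == ["f"]

    def test_boundary_kept(self):
        table, _, g = self._fixture(100, 20)
        out, _ = blank_filter(table, g[Group.TKO] + g[Group.CTRL], g[Group.BLANK])
        assert out.feature_ids == ["f"]

    def test_zero_blank_mean_always_kept(self):
        table, _, g = self._fixture(1e-6, 0.0)
        out, _ = blank_filter(table, g[Group.TKO] + g[Group.CTRL], g[Group.BLANK])
        assert out.feature_ids == ["f"]

    def test_no_blanks_rejected(self):
        table, _, g = self._fixture(10, 1)
        with pytest.raises(QcError):
            blank_filter(table, g[Group.TKO], [])


class TestQcPresenceFilter:
    def _fixture(self, qc_values):
        groups = [Group.QC] * len(qc_values) + [Group.TKO]
        rows = {"f": list(qc_values) + [100.0]}
        return _table(rows, groups)

    def test_half_detected_kept(self):
        table, _, g = self._fixture([1, 2, 3, 4, 5, 0, 0, np.nan, np.nan, np.nan])
        out, _ = qc_presence_filter(table, g[Group.QC], 0.5)
        assert out.feature_ids == ["f"]

    def test_below_half_removed(self):
        table, _, g = self._fixture([1, 2, 3, 4, 0, 0, np.nan, np.nan, np.nan, np.nan])
        out, rep = qc_presence_filter(table, g[Group.QC], 0.5)
        assert out.n_features == 0

    def test_all_missing_removed(self):
        table, _, g = self._fixture([np.nan] * 6)
        out, _ = qc_presence_filter(table, g[Group.QC])
        assert out.n_features == 0

    def test_too_few_qcs_rejected(self):
        table, _, g = self._fixture([1.0])
        with pytest.raises(QcError):
            qc_presence_filter(table, g[Group.QC])


class TestQcRsdFilter:
    def _fixture(self, qc_values):
        groups = [Group.QC] * len(qc_values) + [Group.TKO]
        rows = {"f": list(qc_values) + [100.0]}
        return _table(rows, groups)

    def test_ten_percent_rsd_kept(self):
        # sd([100,110,90]) = 10, mean 100 -> RSD 0.10
        table, _, g = self._fixture([100, 110, 90])
        out, rep = qc_rsd_filter(table, g[Group.QC], 0.30)
        assert out.feature_ids == ["f"]
        assert rep.metrics.loc["f", "qc_rsd"] == pytest.approx(0.10)

    def test_equal_values_zero_rsd_kept(self):
        table, _, g = self._fixture([50, 50, 50, 50])
        out, rep = qc_rsd_filter(table, g[Group.QC])
        assert out.feature_ids == ["f"]
        assert rep.metrics.loc["f", "qc_rsd"] == 0.0

    def test_large_rsd_removed(self):
        # sd([10,100,190]) = 90, mean 100 -> RSD 0.9
        table, _, g = self._fixture([10, 100, 190])
        out, rep = qc_rsd_filter(table, g[Group.QC], 0.30)
        assert out.n_features == 0
        assert rep.metrics.loc["f", "qc_rsd"] == pytest.approx(0.9)

    def test_indeterminate_kept_and_flagged(self):
        table, _, g = self._fixture([100, np.nan, np.nan, np.nan])
        out, rep = qc_rsd_filter(table, g[Group.QC])
        assert out.feature_ids == ["f"] and rep.flagged == ["f"]


class TestFilterIndependence:
    def test_order_does_not_change_surviving_set(self, rng):
        n = 30
        groups = (
            [Group.BLANK] * 2
            + [Group.QC] * 6
            + [Group.TKO] * 8
            + [Group.CTRL] * 8
        )
        rows = {
            f"f{i}": list(rng.lognormal(np.log(10 + 90 * rng.random()), 0.7, len(groups)))
            for i in range(n)
        }
        table, records, g = _table(rows, groups)
        study = g[Group.TKO] + g[Group.CTRL]

        def survivors(order):
            t = table
            for rule in order:
                if rule == "blank":
                    t, _ = blank_filter(t, study, g[Group.BLANK])
                elif rule == "presence":
                    t, _ = qc_presence_filter(t, g[Group.QC])
                else:
                    t, _ = qc_rsd_filter(t, g[Group.QC])
            return set(t.feature_ids)

        a = survivors(["blank", "presence", "rsd"])
        b = survivors(["rsd", "blank", "presence"])
        c = survivors(["presence", "rsd", "blank"])
        assert a == b == c


class TestDriftCorrection:
    def _drift_fixture(self, n=40, drift_fn=None, qc_every=5):
        orders = np.arange(1, n + 1)
        drift = np.ones(n) if drift_fn is None else drift_fn(orders)
        groups = [Group.QC if i % qc_every == 0 else Group.TKO for i in range(n)]
        rows = {"f": list(100.0 * drift)}
        table, records, g = _table(rows, [Group(x) for x in groups])
        return table, records, g[Group.QC]

    def test_constant_qcs_identity(self):
        table, records, qc_ids = self._drift_fixture()
        out, _ = qc_drift_correct(table, records, qc_ids)
        np.testing.assert_allclose(out.values, table.values, rtol=1e-9)

    def test_linear_drift_flattens_qcs(self):
        # 2x multiplicative drift from first to last injection, noiseless
        table, records, qc_ids = self._drift_fixture(
            drift_fn=lambda o: 2.0 ** ((o - 1) / (o.max() - 1))
        )
        out, _ = qc_drift_correct(table, records, qc_ids)
        qcv = out.values[0, out.sample_indices(qc_ids)]
        assert np.std(qcv, ddof=1) / np.mean(qcv) < 0.01

    def test_median_qc_level_preserved(self):
        table, records, qc_ids = self._drift_fixture(drift_fn=lambda o: 1 + o / 50.0)
        before = np.median(table.values[0, table.sample_indices(qc_ids)])
        out, _ = qc_drift_correct(table, records, qc_ids)
        after = np.median(out.values[0, out.sample_indices(qc_ids)])
        assert after == pytest.approx(before, rel=1e-9)

    def test_idempotent_on_corrected_data(self):
        # 4 QCs -> least-squares line, an exact projection in log space
        table, records, qc_ids = self._drift_fixture(n=20, drift_fn=lambda o: 1 + o / 30.0)
        qc4 = qc_ids[:4]
        once, _ = qc_drift_correct(table, records, qc4)
        twice, _ = qc_drift_correct(once, records, qc4)
        np.testing.assert_allclose(twice.values, once.values, rtol=1e-9)

    def test_too_few_qcs_rejected(self):
        table, records, qc_ids = self._drift_fixture()
        with pytest.raises(QcError):
            qc_drift_correct(table, records, qc_ids[:2])

    def test_positive_scaling_preserves_zero_and_sign(self):
        table, records, qc_ids = self._drift_fixture(drift_fn=lambda o: 1 + o / 40.0)
        table.values[0, 3] = 0.0
        out, _ = qc_drift_correct(table, records, qc_ids)
        assert out.values[0, 3] == 0.0
        assert np.all(out.values[0, out.values[0] > 0] > 0)
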