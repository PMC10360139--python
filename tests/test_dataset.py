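"""Tests for the paired-experiment data model, I/O, filtering and correlations."""

import math

import numpy as np
import pytest

from rbekit import dataset as ds
from rbekit.dataset import (
    FilterConfig,
    PairedExperiment,
    apply_exclusion_filters,
    correlation_by_let,
    radiosensitivity_metrics,
    read_survival_table,
    write_survival_table,
)
from rbekit.lqm import LQParams


def _exp(cell="X", ax=0.3, bx=0.03, ap=0.4, bp=0.035, let=2.6, **kw):
    return PairedExperiment(
        cell_line=cell,
        photon=LQParams(ax, bx),
        proton=LQParams(ap, bp),
        let_d=let,
        **kw,
    )


class TestCSVIO:
    def test_roundtrip(self, tmp_path, small_dataset):
        records, _ = small_dataset
        path = tmp_path / "table.csv"
        write_survival_table(records, path)
        back = read_survival_table(path)
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert a.cell_line == b.cell_line
            assert a.photon.alpha == pytest.approx(b.photon.alpha)
            assert a.proton.beta == pytest.approx(b.proton.beta)
            assert a.let_d == pytest.approx(b.let_d)
            np.testing.assert_allclose(a.photon.cov, b.photon.cov)

    def test_three_row_fixture(self, tmp_path):
        path = tmp_path / "t.csv"
        write_survival_table([_exp(cell=f"L{i}") for i in range(3)], path)
        assert len(read_survival_table(path)) == 3

    def test_non_numeric_beta_named(self, tmp_path):
        path = tmp_path / "t.csv"
        write_survival_table([_exp()], path)
        text = path.read_text().replace("0.035", "NA")
        path.write_text(text)
        with pytest.raises(ValueError, match="beta_p"):
            read_survival_table(path)

    def test_missing_column(self, tmp_path):
        path = tmp_path / "t.csv"
        write_survival_table([_exp()], path)
        lines = path.read_text().splitlines()
        lines[0] = lines[0].replace("alpha_x", "alpha_xx")
        path.write_text("\n".join(lines))
        with pytest.raises(ValueError, match="alpha_x"):
            read_survival_table(path)

    def test_mixed_dialect_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        write_survival_table([_exp()], path)
        lines = path.read_text().splitlines()
        lines[0] += ",alpha"
        lines[1] += ",0.1"
        path.write_text("\n".join(lines))
        with pytest.raises(ValueError, match="dialect"):
            read_survival_table(path)


class TestExclusionFilters:
    def test_each_rule_and_reconciliation(self):
        records = [
            _exp(cell="clean1"),
            _exp(cell="clean2", ax=0.5, bx=0.05),
            _exp(cell="clean3", ap=0.6, bp=0.06),
            _exp(cell="clean4", let=37.8),  # boundary LET is kept (strict >)
            _exp(cell="neg_beta", bp=-0.01),
            _exp(cell="hypox", oxygenation="hypoxic"),
            _exp(cell="resistant", ax=0.04, bx=0.0004),  # photon D10 ~ 45 Gy
            _exp(cell="viab", assay="viability"),
            _exp(cell="hot", let=45.0),
            _exp(cell="soft+viab", photon_source="180 kVp", assay="viability"),
        ]
        kept, rep = apply_exclusion_filters(records)
        assert [r.cell_line for r in kept] == ["clean1", "clean2", "clean3", "clean4"]
        assert rep.total_in == 10 and rep.total_out == 4
        assert rep.excluded_by_rule == {
            "beta_nonpositive": 1,
            "hypoxic": 1,
            "radioresistant_d10": 1,
            "viability_assay": 2,  # the double-violation counts here too
            "high_let": 1,
            "low_energy_photon": 1,
        }
        assert rep.n_excluded_unique == 6
        assert rep.reconciles()

    def test_let_boundary_strict(self):
        kept, _ = apply_exclusion_filters([_exp(let=37.8)])
        assert len(kept) == 1
        kept, _ = apply_exclusion_filters([_exp(let=37.8000001)])
        assert len(kept) == 0

    def test_idempotent(self, small_dataset):
        records, _ = small_dataset
        once, _ = apply_exclusion_filters(records)
        twice, rep = apply_exclusion_filters(once)
        assert twice == once
        assert rep.total_out == rep.total_in

    def test_photon_source_parsing(self):
        for src in ("6 MV", "Co-60", "Cs-137", "250 kVp", "unknown source"):
            kept, _ = apply_exclusion_filters([_exp(photon_source=src)])
            assert len(kept) == 1, src
        kept, _ = apply_exclusion_filters([_exp(photon_source="180 kVp")])
        assert len(kept) == 0

    def test_named_cell_line_exclusion(self):
        cfg = FilterConfig(excluded_cell_lines=("HTB140",))
        kept, rep = apply_exclusion_filters([_exp(cell="HTB140"), _exp(cell="OK")], cfg)
        assert [r.cell_line for r in kept] == ["OK"]
        assert rep.excluded_by_rule["radioresistant_d10"] == 1


class TestMetrics:
    def test_linear_photon_values(self):
        m = radiosensitivity_metrics(_exp(ax=0.5, bx=0.0))
        photon = {e.sf_level: e.value for e in m["photon"]}
        assert photon[0.10] == pytest.approx(math.log(10) / 0.5, rel=1e-12)
        assert photon["SF_2Gy"] == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_pure_quadratic_d37(self):
        m = radiosensitivity_metrics(_exp(ax=0.0, bx=0.25))
        photon = {e.sf_level: e.value for e in m["photon"]}
        assert photon[0.37] == pytest.approx(
            math.sqrt(-math.log(0.37) / 0.25), rel=1e-12
        )

    def test_dose_metrics_ordered(self):
        m = radiosensitivity_metrics(_exp(ax=0.3, bx=0.03))
        doses = [e.value for e in m["photon"] if e.sf_level != "SF_2Gy"]
        assert doses == sorted(doses, reverse=True)  # D_5% > ... > D_50%

    def test_stderr_present_with_cov(self, small_dataset):
        records, _ = small_dataset
        m = radiosensitivity_metrics(records[0])
        assert all(e.stderr is not None for e in m["photon"])


class TestCorrelation:
    def test_exact_linear_relation(self):
        recs = []
        for i, d10x in enumerate([2.0, 3.0, 4.0, 5.0, 6.0]):
            ax = math.log(10) / d10x
            ap = math.log(10) / (0.9 * d10x)  # proton D10 = 0.9 * photon D10
            recs.append(_exp(cell=f"L{i}", ax=ax, bx=0.0, ap=ap, bp=0.0, let=2.6))
        df = correlation_by_let(recs, sf_level=0.10)
        assert df.shape[0] == 1
        assert df.loc[0, "pearson_r"] == pytest.approx(1.0, abs=1e-12)
        assert df.loc[0, "slope"] == pytest.approx(0.9, abs=1e-12)
        assert df.loc[0, "intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_noisy_recovery_within_2se(self):
        rng = np.random.default_rng(4)
        slope_true, int_true = 0.8, 0.3
        recs = []
        for i in range(200):
            d10x = rng.uniform(2.0, 8.0)
            d10p = slope_true * d10x + int_true + rng.normal(0.0, 0.2)
            recs.append(
                _exp(
                    cell=f"L{i}",
                    ax=math.log(10) / d10x, bx=0.0,
                    ap=math.log(10) / d10p, bp=0.0,
                    let=9.9,
                )
            )
        from scipy import stats

        df = correlation_by_let(recs, sf_level=0.10)
        x = np.array([math.log(10) / r.photon.alpha for r in recs])
        res = stats.linregress(x, [math.log(10) / r.proton.alpha for r in recs])
        assert abs(df.loc[0, "slope"] - slope_true) < 2 * res.stderr
        assert abs(df.loc[0, "intercept"] - int_true) < 2 * res.intercept_stderr

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="records"):
            correlation_by_let([_exp(cell="a"), _exp(cell="b")])

    def test_constant_proton_error(self):
        recs = [
            _exp(cell=f"L{i}", ax=0.2 + 0.1 * i, bx=0.0, ap=0.5, bp=0.0) for i in range(4)
        ]
        with pytest.raises(ValueError, match="variance"):
            correlation_by_let(recs, sf_level=0.10)
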