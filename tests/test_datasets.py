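"""Dataset containers, validation rules, delimited I/O and packaged fixtures."""

import pytest

from bmdtox.datasets import (
    BenchmarkResponse,
    ContinuousDataset,
    FormatError,
    QuantalDataset,
    ValidationError,
    builtin_fixture,
    list_fixtures,
    load_continuous,
    load_quantal,
    save_continuous,
    save_quantal,
)


class TestQuantalValidation:
    def test_valid_dataset_normalizes_order(self):
        d = QuantalDataset("e", ((50.0, 70, 42), (0.0, 70, 24), (1.0, 70, 19), (0.1, 70, 24)))
        assert d.doses == (0.0, 0.1, 1.0, 50.0)
        assert d.n_affected == (24, 24, 19, 42)

    @pytest.mark.parametrize(
        "groups",
        [
            ((0.0, 70, 24), (1.0, 70, 71), (50.0, 70, 42)),        # affected > n
            ((0.0, 70, 24), (1.0, 70, 19)),                        # too few groups
            ((0.1, 70, 24), (1.0, 70, 19), (50.0, 70, 42)),        # no control
            ((0.0, 70, 24), (1.0, 70, 19), (1.0, 70, 20)),         # duplicate dose
            ((0.0, 70, 24), (-1.0, 70, 19), (50.0, 70, 42)),       # negative dose
            ((0.0, 0, 0), (1.0, 70, 19), (50.0, 70, 42)),          # empty group
        ],
    )
    def test_invalid_datasets_rejected(self, groups):
        with pytest.raises(ValidationError):
            QuantalDataset("bad", groups)

    def test_dose_scaling(self, cystic):
        scaled = cystic.scale_doses(2.0)
        assert scaled.doses == tuple(2 * d for d in cystic.doses)
        assert scaled.n_affected == cystic.n_affected


class TestContinuousValidation:
    def test_valid(self):
        d = ContinuousDataset("w", ((0.0, 20, 5.9, 0.4), (10.0, 20, 5.5, 0.5), (100.0, 20, 4.8, 0.5)))
        assert d.means == (5.9, 5.5, 4.8)

    @pytest.mark.parametrize(
        "groups",
        [
            ((0.0, 20, 5.9, 0.0), (10.0, 20, 5.5, 0.5), (100.0, 20, 4.8, 0.5)),  # sd 0
            ((0.0, 1, 5.9, 0.4), (10.0, 20, 5.5, 0.5), (100.0, 20, 4.8, 0.5)),   # n < 2
        ],
    )
    def test_invalid(self, groups):
        with pytest.raises(ValidationError):
            ContinuousDataset("bad", groups)


class TestIO:
    def test_load_quantal_paper_table_row(self, tmp_path):
        p = tmp_path / "cfd.csv"
        p.write_text("dose,n,affected\n0,70,24\n0.1,70,24\n1,70,19\n50,70,42\n")
        d = load_quantal(p)
        assert len(d.groups) == 4
        assert d.proportions[0] == pytest.approx(24 / 70)

    def test_tab_delimited_autodetected(self, tmp_path):
        p = tmp_path / "cfd.tsv"
        p.write_text("dose\tn\taffected\n0\t70\t24\n1\t70\t19\n50\t70\t42\n")
        assert load_quantal(p).doses == (0.0, 1.0, 50.0)

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("dose,n\n0,70\n1,70\n50,70\n")
        with pytest.raises(FormatError):
            load_quantal(p)

    def test_incidence_above_group_size_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("dose,n,affected\n0,70,24\n1,70,71\n50,70,42\n")
        with pytest.raises(ValidationError):
            load_quantal(p)

    def test_duplicate_dose_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("dose,n,affected\n0,70,24\n1,70,19\n1,70,20\n50,70,42\n")
        with pytest.raises(ValidationError):
            load_quantal(p)

    def test_quantal_round_trip_identity(self, tmp_path, cystic):
        p = tmp_path / "rt.csv"
        save_quantal(cystic, p)
        again = load_quantal(p, endpoint_name=cystic.endpoint_name)
        assert again == cystic

    def test_continuous_round_trip_identity(self, tmp_path):
        d = ContinuousDataset(
            "rt", ((0.0, 12, 100.25, 7.5), (5.0, 12, 92.1, 8.25), (50.0, 12, 70.33, 6.875))
        )
        p = tmp_path / "rt.csv"
        save_continuous(d, p)
        assert load_continuous(p, endpoint_name="rt") == d


class TestFixtures:
    @pytest.mark.parametrize(
        "name,incidences",
        [
            ("cystic_focal_degeneration", (24, 24, 19, 42)),
            ("centrilobular_hypertrophy", (0, 0, 0, 7)),
            ("centrilobular_necrosis", (1, 0, 1, 5)),
        ],
    )
    def test_liver_lesion_fixtures_match_bioassay(self, name, incidences):
        d = builtin_fixture(name)
        assert d.doses == (0.0, 0.1, 1.0, 50.0)
        assert d.n_subjects == (70, 70, 70, 70)
        assert d.n_affected == incidences

    def test_every_fixture_is_valid(self):
        for name in list_fixtures():
            d = builtin_fixture(name)  # construction re-validates invariants
            assert d.doses[0] == 0.0 and len(d.groups) >= 3

    def test_unknown_fixture_lists_available(self):
        with pytest.raises(KeyError, match="cystic_focal_degeneration"):
            builtin_fixture("no_such_lesion")


class TestBenchmarkResponse:
    def test_risk_level_bounds(self):
        with pytest.raises(ValidationError):
            BenchmarkResponse("extra_risk", 1.5)
        with pytest.raises(ValidationError):
            BenchmarkResponse("extra_risk", 0.0)

    def test_one_sd_carries_no_level(self):
        assert BenchmarkResponse("one_sd").level is None
        assert BenchmarkResponse("one_sd", 1.0).level is None
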