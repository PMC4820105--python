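import io

import numpy as np
import pytest

from bandpop.matrix import (
    BandMatrix,
    BandMatrixError,
    drop_incomplete_individuals,
    lynch_milligan_filter,
    parse_dms,
    read_band_matrix,
    read_population_table,
    write_band_matrix,
)
from bandpop.simulate import inject_missing_primer_blocks, simulate_island


class TestReadBandMatrix:
    def test_toy_file_shape_and_labels(self, toy_matrix):
        assert toy_matrix.n_individuals == 4
        assert toy_matrix.n_loci == 3
        assert toy_matrix.population_names == ["A", "B"]
        assert toy_matrix.population_sizes() == {"A": 2, "B": 2}

    def test_round_trip_is_bit_identical(self, toy_csv):
        m = read_band_matrix(io.StringIO(toy_csv))
        buf = io.StringIO()
        write_band_matrix(m, buf)
        assert buf.getvalue().replace("\r\n", "\n") == toy_csv

    def test_non_binary_cell_names_location(self):
        bad = "individual,population,L1\na1,A,2\n"
        with pytest.raises(BandMatrixError, match="'2'.*'a1'.*'L1'"):
            read_band_matrix(io.StringIO(bad))

    def test_duplicate_individuals_rejected(self):
        bad = "individual,population,L1\na1,A,1\na1,A,0\n"
        with pytest.raises(BandMatrixError, match="duplicate individual"):
            read_band_matrix(io.StringIO(bad))

    def test_na_codes_become_missing(self):
        m = read_band_matrix(io.StringIO("individual,population,L1\na1,A,NA\na2,A,1\n"))
        assert m.has_missing()


class TestCoordinates:
    @pytest.mark.parametrize(
        "text,hem,expected",
        [
            ("31° 48´ 17´´", "N", 31 + 48 / 60 + 17 / 3600),
            ("112° 51´ 56´´", "W", -(112 + 51 / 60 + 56 / 3600)),
            ("0° 0´ 0´´", None, 0.0),
            ("12.5", "S", -12.5),
            ("45° 30′ 30″ N", None, 45.508333333333333),
        ],
    )
    def test_dms_parsing(self, text, hem, expected):
        assert parse_dms(text, hem) == pytest.approx(expected, abs=1e-12)

    def test_minutes_over_sixty_rejected(self):
        with pytest.raises(BandMatrixError, match="minutes/seconds"):
            parse_dms("10° 61´ 0´´")

    def test_population_table_reader_hemisphere_columns(self):
        csv = (
            "Population,N,Latitude_N,Longitude_W,Elevation\n"
            "Alpha,30,28° 52´ 56´´,112° 01´ 39´´,60\n"
        )
        t = read_population_table(io.StringIO(csv))
        row = t.table.iloc[0]
        assert row["latitude"] == pytest.approx(28.882222, abs=1e-6)
        assert row["longitude"] == pytest.approx(-112.0275, abs=1e-6)
        assert row["n"] == 30


class TestDropIncomplete:
    def test_single_missing_value_drops_individual(self):
        csv = "individual,population,L1,L2\na1,A,1,NA\na2,A,1,0\na3,A,0,1\n"
        m = read_band_matrix(io.StringIO(csv))
        cleaned, log = drop_incomplete_individuals(m)
        assert cleaned.n_individuals == 2
        assert not cleaned.has_missing()
        assert list(log["individual"]) == ["a1"]

    def test_complete_matrix_unchanged(self, toy_matrix):
        cleaned, log = drop_incomplete_individuals(toy_matrix)
        assert np.array_equal(cleaned.data, toy_matrix.data)
        assert log.empty

    def test_locus_count_never_changes(self, toy_matrix):
        cleaned, _ = drop_incomplete_individuals(toy_matrix)
        assert cleaned.loci == toy_matrix.loci

    def test_primer_block_failure_reported(self):
        m, _ = simulate_island(K=2, N=10, L=6, theta_true=0.1, seed=3)
        primer_of = {l: ("p835" if i < 3 else "p846") for i, l in enumerate(m.loci)}
        dirty = inject_missing_primer_blocks(m, primer_of, fraction=0.2, seed=4)
        cleaned, log = drop_incomplete_individuals(dirty, primer_of)
        assert not cleaned.has_missing()
        assert len(log) >= 1
        assert log["reason"].str.contains("failed primer").all()

    def test_emptied_population_is_an_error(self):
        csv = "individual,population,L1\na1,A,NA\nb1,B,1\nb2,B,0\n"
        m = read_band_matrix(io.StringIO(csv))
        with pytest.raises(BandMatrixError, match="empties population"):
            drop_incomplete_individuals(m)


class TestLynchMilliganFilter:
    def _matrix_with_presence(self, n_present: int, N: int = 40) -> BandMatrix:
        data = np.zeros((N, 2), dtype=np.int8)
        data[:n_present, 0] = 1
        data[: N // 2, 1] = 1  # companion locus, safely polymorphic
        return BandMatrix(
            [f"i{k}" for k in range(N)], ["A"] * N, ["hot", "ok"], data
        )

    def test_high_presence_locus_excluded(self):
        # presence 39/40 = 0.975 > 1 - 3/40 = 0.925
        m = self._matrix_with_presence(39)
        filtered, report = lynch_milligan_filter(m, "pooled")
        assert filtered.loci == ["ok"]
        assert list(report.excluded["locus"]) == ["hot"]
        assert report.excluded["presence_freq"].iloc[0] == pytest.approx(0.975)

    def test_moderate_presence_retained(self):
        m = self._matrix_with_presence(30)  # 0.75 <= 0.925
        filtered, report = lynch_milligan_filter(m, "pooled")
        assert filtered.n_loci == 2
        assert report.excluded.empty

    def test_all_absent_locus_retained(self):
        m = self._matrix_with_presence(0)  # x = 1: threshold is on high presence
        filtered, _ = lynch_milligan_filter(m, "pooled")
        assert "hot" in filtered.loci

    def test_idempotent(self):
        m, _ = simulate_island(
            K=3, N=20, L=120, theta_true=0.15, pi_dist={"a": 0.3, "b": 0.3}, seed=9
        )
        once, _ = lynch_milligan_filter(m, "pooled")
        twice, report = lynch_milligan_filter(once, "pooled")
        assert twice.loci == once.loci
        assert report.excluded.empty

    def test_individual_count_never_changes(self):
        m = self._matrix_with_presence(39)
        filtered, _ = lynch_milligan_filter(m, "pooled")
        assert filtered.n_individuals == m.n_individuals

    def test_small_sample_degenerate(self):
        m = self._matrix_with_presence(2, N=3)
        with pytest.raises(BandMatrixError, match="N=3"):
            lynch_milligan_filter(m, "pooled")

    def test_per_population_unit(self):
        m, _ = simulate_island(K=2, N=30, L=50, theta_true=0.2,
                               pi_dist={"a": 0.3, "b": 0.3}, seed=2)
        pop = m.population_names[0]
        filtered, report = lynch_milligan_filter(m, pop)
        assert report.unit == pop
        assert report.N == 30
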