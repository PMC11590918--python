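import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rtlsval import (
    BarnLayout,
    FormatError,
    GridError,
    RowError,
    Session,
    TagStream,
    netluky_layout,
    read_observer_table,
    read_position_table,
    write_position_table,
)

from conftest import EPOCH, make_session


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadPositionTable:
    def test_two_rows_one_tag(self, tmp_path):
        p = write(
            tmp_path,
            "pos.csv",
            "tag_id,timestamp,x,y\n"
            "A,2023-01-19T09:00:00,1.0,2.0\n"
            "A,2023-01-19T09:00:01,1.5,2.5\n",
        )
        streams, report = read_position_table(p)
        assert len(streams) == 1 and len(streams[0]) == 2
        assert report.n_rows == report.n_kept == 2
        np.testing.assert_allclose(streams[0].x, [1.0, 1.5])

    def test_empty_file_with_header(self, tmp_path):
        p = write(tmp_path, "pos.csv", "tag_id,timestamp,x,y\n")
        streams, report = read_position_table(p)
        assert streams == [] and report.n_rows == 0

    def test_bad_coordinate_cites_line(self, tmp_path):
        p = write(
            tmp_path,
            "pos.csv",
            "tag_id,timestamp,x,y\n"
            "A,2023-01-19T09:00:00,1.0,2.0\n"
            "A,2023-01-19T09:00:01,oops,2.5\n",
        )
        with pytest.raises(RowError, match="line 3"):
            read_position_table(p)

    def test_missing_column_named(self, tmp_path):
        p = write(tmp_path, "pos.csv", "tag_id,timestamp,x\nA,2023-01-19T09:00:00,1\n")
        with pytest.raises(FormatError, match="'y'"):
            read_position_table(p)

    def test_duplicates_keep_first_and_conserve(self, tmp_path):
        p = write(
            tmp_path,
            "pos.csv",
            "tag_id,timestamp,x,y\n"
            "A,2023-01-19T09:00:00,1.0,0\n"
            "A,2023-01-19T09:00:00,9.0,9\n"
            "A,2023-01-19T09:00:01,2.0,0\n",
        )
        streams, report = read_position_table(p)
        assert len(streams[0]) == 2
        assert streams[0].x[0] == 1.0  # first occurrence wins
        assert report.n_duplicates_dropped == 1
        assert report.n_kept + report.n_duplicates_dropped == report.n_rows

    def test_deterministic_across_reads(self, tmp_path):
        body = "tag_id,timestamp,x,y\n" + "".join(
            f"A,2023-01-19T09:00:{i:02d},{i}.0,{i}.5\n" for i in range(10)
        )
        p = write(tmp_path, "pos.csv", body)
        s1, _ = read_position_table(p)
        s2, _ = read_position_table(p)
        np.testing.assert_array_equal(s1[0].t, s2[0].t)
        np.testing.assert_array_equal(s1[0].x, s2[0].x)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.integers(0, 5000),  # milliseconds of offset
            st.floats(0, 31, allow_nan=False, width=32),
            st.floats(0, 12, allow_nan=False, width=32),
        ),
        min_size=1,
        max_size=20,
        unique_by=lambda r: r[0],
    )
)
def test_position_roundtrip(tmp_path_factory, rows):
    """Write-then-read reproduces timestamps to ms and coordinates to 1e-6 m."""
    rows = sorted(rows)
    session = make_session(10.0)
    stream = TagStream(
        "T",
        np.array([r[0] / 1000.0 for r in rows]),
        np.array([r[1] for r in rows], dtype=float),
        np.array([r[2] for r in rows], dtype=float),
        session,
    )
    path = tmp_path_factory.mktemp("rt") / "pos.csv"
    write_position_table([stream], path)
    back, _ = read_position_table(path, session=session)
    assert len(back) == 1
    np.testing.assert_allclose(back[0].t, stream.t, atol=5e-4)
    np.testing.assert_allclose(back[0].x, stream.x, atol=1e-6)
    np.testing.assert_allclose(back[0].y, stream.y, atol=1e-6)


class TestObserverTable:
    def test_grid_aligned_rows(self, tmp_path):
        body = "focal_id,timestamp,proximate_tag\n" + "".join(
            f"cow,2023-01-19T09:00:{s:02d},A\n" for s in (0, 15, 30, 45)
        )
        recs = read_observer_table(write(tmp_path, "obs.csv", body))
        assert len(recs) == 4
        assert [r.t for r in recs] == [0.0, 15.0, 30.0, 45.0]

    def test_off_grid_rejected_without_tolerance(self, tmp_path):
        body = "focal_id,timestamp,proximate_tag\ncow,2023-01-19T09:00:17,A\n"
        with pytest.raises(GridError):
            read_observer_table(
                write(tmp_path, "obs.csv", body), session=make_session(600.0)
            )

    def test_tolerance_snaps(self, tmp_path):
        body = "focal_id,timestamp,proximate_tag\ncow,2023-01-19T09:00:16,A\n"
        recs = read_observer_table(
            write(tmp_path, "obs.csv", body), session=make_session(600.0), tolerance=1.0
        )
        assert recs[0].t == 15.0

    @pytest.mark.parametrize("token", ["", "none", "NONE", "NA", "-"])
    def test_none_tokens_normalised(self, tmp_path, token):
        body = f"focal_id,timestamp,proximate_tag\ncow,2023-01-19T09:00:00,{token}\n"
        recs = read_observer_table(write(tmp_path, "obs.csv", body))
        assert recs[0].proximate_tag is None


class TestNetlukyLayout:
    def test_dimensions_and_counts(self, layout):
        assert layout.width == 31.0 and layout.depth == 12.0
        assert len(layout.anchors) == 6
        assert len(layout.stationary_tags) == 10

    def test_tag_heights_by_zone(self, layout):
        feeding = [t for t, (x, y, h) in layout.stationary_tags.items() if y > 9.8]
        others = [t for t, (x, y, h) in layout.stationary_tags.items() if y <= 9.8]
        assert len(feeding) == 3
        assert all(layout.stationary_tags[t][2] == pytest.approx(2.0) for t in feeding)
        assert all(1.0 <= layout.stationary_tags[t][2] <= 1.5 for t in others)

    def test_all_placements_inside_barn(self, layout):
        for x, y, _ in layout.anchors:
            assert bool(layout.contains(x, y))
        for x, y, _ in layout.stationary_tags.values():
            assert bool(layout.contains(x, y))
        for x0, y0, x1, y1 in layout.zones.values():
            assert 0 <= x0 <= x1 <= layout.width and 0 <= y0 <= y1 <= layout.depth

    def test_yaml_roundtrip(self, layout, tmp_path):
        path = tmp_path / "layout.yaml"
        layout.to_yaml(path)
        again = BarnLayout.from_yaml(path)
        assert again == layout


class TestInvariants:
    def test_placement_outside_barn_rejected(self):
        with pytest.raises(ValueError):
            BarnLayout(width=10, depth=5, stationary_tags={"A": (11.0, 1.0, 1.0)})

    def test_session_end_before_start_rejected(self):
        with pytest.raises(ValueError):
            Session(start=EPOCH, end=EPOCH)

    def test_stream_requires_increasing_time(self, session600):
        with pytest.raises(ValueError):
            TagStream("A", [0.0, 0.0], [1.0, 2.0], [1.0, 2.0], session600)
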