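"""Single-file datastore: schema, mask persistence, SQL access, CSV export."""

import numpy as np
import pandas as pd
import pytest

from mycotrack.benchmark import random_mask
from mycotrack.errors import DatastoreError
from mycotrack.masks import PixelMask
from mycotrack.store import ProjectDB


@pytest.fixture()
def db(tmp_path):
    with ProjectDB(tmp_path / "p.db") as handle:
        yield handle


def _tables(db):
    return {r[0] for r in db.conn.execute(
        "SELECT name FROM sqlite_master WHERE type='table'")}


class TestInit:
    def test_fresh_schema(self, db):
        assert {"project", "channel", "frame", "cell", "roi",
                "background_roi", "measurement", "event"} <= _tables(db)
        assert db.conn.execute("SELECT count(*) FROM cell").fetchone()[0] == 0

    def test_reopen_is_noop(self, tmp_path):
        p = tmp_path / "p.db"
        with ProjectDB(p) as db:
            db.save_cell("A", None, 0, None, None)
        with ProjectDB(p) as db:
            assert db.conn.execute(
                "SELECT count(*) FROM cell").fetchone()[0] == 1

    def test_corrupted_file_not_overwritten(self, tmp_path):
        p = tmp_path / "junk.db"
        p.write_bytes(b"this is not a database " * 30)
        before = p.read_bytes()
        with pytest.raises(DatastoreError):
            ProjectDB(p)
        assert p.read_bytes() == before


class TestRoi:
    def test_round_trip_exact(self, db, rng):
        db.save_cell("A", None, 0, None, None)
        for f in range(20):
            mask = random_mask(rng, n_pixels=500)
            db.save_roi("A", PixelMask(mask.pixels, f))
            loaded, prov = db.load_roi("A", f)
            assert loaded.pixels == mask.pixels
            assert prov == "auto"

    def test_overwrite_flips_provenance(self, db):
        db.save_cell("A", None, 0, None, None)
        db.save_roi("A", PixelMask(frozenset({(1, 1)}), 4))
        db.save_roi("A", PixelMask(frozenset({(2, 2)}), 4),
                    provenance="manual")
        mask, prov = db.load_roi("A", 4)
        assert prov == "manual"
        assert mask.pixels == frozenset({(2, 2)})

    def test_missing_row_raises(self, db):
        with pytest.raises(DatastoreError):
            db.load_roi("Z", 0)

    def test_rois_survive_reopen(self, tmp_path, rng):
        # one transaction per mask: everything saved is durable
        p = tmp_path / "p.db"
        masks = []
        with ProjectDB(p) as db:
            db.save_cell("A", None, 0, None, None)
            for f in range(100):
                m = random_mask(rng, n_pixels=60)
                masks.append(m)
                db.save_roi("A", PixelMask(m.pixels, f))
        with ProjectDB(p) as db:
            for f, m in enumerate(masks):
                loaded, _ = db.load_roi("A", f)
                assert loaded.pixels == m.pixels


class TestSQL:
    def _three_division_lineage(self, db):
        db.save_cell("A", None, 0, 9, "divided")
        for gen1 in ("AA", "AB"):
            db.save_cell(gen1, "A", 10, 19, "divided")
            for suffix in ("A", "B"):
                db.save_cell(gen1 + suffix, gen1, 20, None, None)

    def test_cell_count_after_three_divisions(self, db):
        self._three_division_lineage(db)
        df = db.run_sql("SELECT count(*) AS n FROM cell")
        assert df["n"].iloc[0] == 7

    def test_write_statements_rejected(self, db):
        with pytest.raises(DatastoreError):
            db.run_sql("DROP TABLE cell")
        with pytest.raises(DatastoreError):
            db.run_sql("INSERT INTO cell (name, birth_frame) VALUES ('Z', 0)")
        assert "cell" in _tables(db)

    def test_shipped_ratio_query_on_constants(self, db):
        db.save_cell("A", None, 0, None, None)
        db.save_cell("B", None, 0, None, None)
        rows = []
        for cell in ("A", "B"):
            for f in range(5):
                db.save_roi(cell, PixelMask(frozenset({(0, 0)}), f))
                rows.append((cell, f, "ch1", "mean_corrected", 300.0))
                rows.append((cell, f, "ch2", "mean_corrected", 100.0))
        db.save_measurements(rows)
        df = db.run_sql(db.ratio_timecourse_sql("ch1", "ch2"))
        assert len(df) == 5
        assert np.allclose(df["mean_ratio"], 3.0)
        assert np.allclose(df["sd_ratio"], 0.0)
        assert (df["n_cells"] == 2).all()

    def test_ratio_query_skips_nonpositive_denominator(self, db):
        db.save_cell("A", None, 0, None, None)
        db.save_roi("A", PixelMask(frozenset({(0, 0)}), 0))
        db.save_measurements([
            ("A", 0, "ch1", "mean_corrected", 300.0),
            ("A", 0, "ch2", "mean_corrected", 0.0)])
        assert db.run_sql(db.ratio_timecourse_sql()).empty


class TestExport:
    def test_header_plus_rows(self, db, tmp_path):
        db.save_cell("A", None, 0, None, None)
        for f in range(3):
            db.save_roi("A", PixelMask(frozenset({(0, 0)}), f))
        db.save_measurements(
            [("A", f, "", "area_px", float(f)) for f in range(3)])
        out = db.export_csv("measurement", tmp_path / "m.csv")
        lines = out.read_text().strip().splitlines()
        assert len(lines) == 4
        assert lines[0] == "cell,frame,channel,variable,value"

    def test_round_trip_preserves_values(self, db, tmp_path):
        db.save_cell("A", None, 0, None, None)
        db.save_roi("A", PixelMask(frozenset({(0, 0)}), 0))
        db.save_measurements([("A", 0, "", "area_um2", 4.443147)])
        out = db.export_csv("SELECT * FROM measurement", tmp_path / "m.csv")
        df = pd.read_csv(out)
        assert df["value"].iloc[0] == 4.443147

    def test_empty_query_is_header_only(self, db, tmp_path):
        out = db.export_csv("SELECT name FROM cell", tmp_path / "e.csv")
        assert out.read_text().strip() == "name"


class TestIntegrity:
    def test_cascade_delete(self, db):
        db.save_cell("A", None, 0, 5, "divided")
        db.save_cell("AA", "A", 6, None, None)
        db.save_roi("AA", PixelMask(frozenset({(0, 0)}), 6))
        db.save_measurements([("AA", 6, "ch1", "mean", 1.0)])
        db.delete_cell("A")
        for table in ("cell", "roi", "measurement"):
            assert db.conn.execute(
                f"SELECT count(*) FROM {table}").fetchone()[0] == 0

    def test_fuzzed_operations_keep_referential_integrity(self, db, rng):
        names = ["A"]
        db.save_cell("A", None, 0, None, None)
        for step in range(150):
            op = rng.integers(4)
            name = names[int(rng.integers(len(names)))]
            if op == 0 and len(name) < 4:  # divide
                db.save_cell(name, None if len(name) == 1 else name[:-1],
                             0, step, "divided")
                for suffix in ("A", "B"):
                    child = name + suffix
                    if child not in names:
                        db.save_cell(child, name, step + 1, None, None)
                        names.append(child)
            elif op == 1:  # add a mask + measurement
                f = int(rng.integers(50))
                db.save_roi(name, PixelMask(frozenset({(0, 0), (0, 1)}), f))
                db.save_measurements([(name, f, "ch1", "mean",
                                       float(rng.random()))])
            elif op == 2:  # manual correction
                f = int(rng.integers(50))
                db.save_roi(name, PixelMask(frozenset({(1, 1)}), f),
                            provenance="manual")
            elif op == 3 and len(names) > 3:  # delete a subtree
                victim = names[int(rng.integers(1, len(names)))]
                db.delete_cell(victim)
                names = [n for n in names if not n.startswith(victim)]
                if not names:
                    names = ["A"]
                    db.save_cell("A", None, 0, None, None)
            db.check_integrity()
        # orphan measurements are impossible by construction
        orphans = db.conn.execute(
            "SELECT count(*) FROM measurement m LEFT JOIN roi r "
            "ON m.cell = r.cell AND m.frame = r.frame "
            "WHERE r.cell IS NULL").fetchone()[0]
        assert orphans == 0
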