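"""Single-file relational datastore for a tracking project.

Everything a project acquires — frame metadata, registration shifts, cells,
ROIs, division/state events and measurements — lives in one SQLite file, so
a project is exchanged by copying that file (plus the image folders).
Masks are stored as row-wise run-length-encoded text; measurements are
long-format ``(cell, frame, channel, variable, value)`` rows so new
variables need no schema change.

Ad-hoc analysis happens through :meth:`ProjectDB.run_sql`, which executes
queries on a read-only connection (write statements fail at the engine
level), and :meth:`ProjectDB.export_csv`.
"""

from __future__ import annotations

import json
import math
import sqlite3
from pathlib import Path

import pandas as pd

from .errors import DatastoreError
from .masks import PixelMask, mask_to_rle, rle_to_mask

SCHEMA_VERSION = 1

_SCHEMA = """
CREATE TABLE IF NOT EXISTS project (
    key   TEXT PRIMARY KEY,
    value TEXT
);
CREATE TABLE IF NOT EXISTS channel (
    name      TEXT PRIMARY KEY,
    directory TEXT
);
CREATE TABLE IF NOT EXISTS frame (
    frame_index INTEGER PRIMARY KEY,
    time_min    REAL,
    excluded    INTEGER NOT NULL DEFAULT 0,
    note        TEXT NOT NULL DEFAULT '',
    shift_dy    INTEGER NOT NULL DEFAULT 0,
    shift_dx    INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE IF NOT EXISTS cell (
    name        TEXT PRIMARY KEY,
    parent      TEXT REFERENCES cell(name) ON DELETE CASCADE,
    birth_frame INTEGER NOT NULL,
    end_frame   INTEGER,
    fate        TEXT
);
CREATE TABLE IF NOT EXISTS roi (
    cell       TEXT NOT NULL REFERENCES cell(name) ON DELETE CASCADE,
    frame      INTEGER NOT NULL,
    rle_mask   TEXT NOT NULL,
    provenance TEXT NOT NULL CHECK (provenance IN ('auto', 'manual')),
    PRIMARY KEY (cell, frame)
);
CREATE TABLE IF NOT EXISTS background_roi (
    id       INTEGER PRIMARY KEY CHECK (id = 1),
    rle_mask TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS background_mean (
    frame   INTEGER NOT NULL,
    channel TEXT NOT NULL,
    value   REAL NOT NULL,
    PRIMARY KEY (frame, channel)
);
CREATE TABLE IF NOT EXISTS measurement (
    cell     TEXT NOT NULL,
    frame    INTEGER NOT NULL,
    channel  TEXT NOT NULL DEFAULT '',
    variable TEXT NOT NULL,
    value    REAL,
    PRIMARY KEY (cell, frame, channel, variable),
    FOREIGN KEY (cell, frame) REFERENCES roi(cell, frame) ON DELETE CASCADE
);
CREATE TABLE IF NOT EXISTS cell_state (
    cell  TEXT NOT NULL REFERENCES cell(name) ON DELETE CASCADE,
    frame INTEGER NOT NULL,
    state TEXT NOT NULL,
    PRIMARY KEY (cell, frame)
);
CREATE TABLE IF NOT EXISTS event (
    id      INTEGER PRIMARY KEY AUTOINCREMENT,
    type    TEXT NOT NULL,
    frame   INTEGER,
    payload TEXT NOT NULL DEFAULT ''
);
"""

#: Shipped example query: per-frame mean and SD over cells of the
#: background-corrected green-to-red fluorescence ratio (the induction
#: time-course).  Cells with non-positive denominator are excluded.
RATIO_TIMECOURSE_SQL = """
SELECT g.frame AS frame_index,
       AVG(g.value / r.value) AS mean_ratio,
       sqrt(MAX(AVG(g.value * g.value / (r.value * r.value))
                - AVG(g.value / r.value) * AVG(g.value / r.value),
                0.0)) AS sd_ratio,
       COUNT(*) AS n_cells
FROM measurement AS g
JOIN measurement AS r
  ON g.cell = r.cell AND g.frame = r.frame
WHERE g.channel = '{num}' AND g.variable = 'mean_corrected'
  AND r.channel = '{den}' AND r.variable = 'mean_corrected'
  AND r.value > 0
GROUP BY g.frame
ORDER BY g.frame
"""


class ProjectDB:
    """Open (creating if needed) the project database at ``path``."""

    def __init__(self, path):
        self.path = Path(path)
        existed = self.path.exists() and self.path.stat().st_size > 0
        self.conn = sqlite3.connect(self.path)
        self.conn.execute("PRAGMA foreign_keys = ON")
        try:
            if existed:
                row = self.conn.execute(
                    "SELECT value FROM project WHERE key='schema_version'"
                ).fetchone()
                if row is None:
                    raise DatastoreError(
                        f"{self.path} exists but is not a mycotrack project")
                if int(row[0]) != SCHEMA_VERSION:
                    raise DatastoreError(
                        f"schema version {row[0]} != {SCHEMA_VERSION}; "
                        "migrate before opening")
            else:
                self.conn.executescript(_SCHEMA)
                self.conn.execute(
                    "INSERT INTO project (key, value) VALUES (?, ?)",
                    ("schema_version", str(SCHEMA_VERSION)))
                self.conn.commit()
        except sqlite3.DatabaseError as exc:
            self.conn.close()
            raise DatastoreError(
                f"{self.path} is not a valid database: {exc}") from exc

    def close(self):
        self.conn.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # -- project / frame metadata ------------------------------------------

    def set_meta(self, key: str, value) -> None:
        with self.conn:
            self.conn.execute(
                "INSERT INTO project (key, value) VALUES (?, ?) "
                "ON CONFLICT(key) DO UPDATE SET value=excluded.value",
                (key, str(value)))

    def get_meta(self, key: str, default=None):
        row = self.conn.execute(
            "SELECT value FROM project WHERE key=?", (key,)).fetchone()
        return default if row is None else row[0]

    def save_channel(self, name: str, directory: str = "") -> None:
        with self.conn:
            self.conn.execute(
                "INSERT OR REPLACE INTO channel (name, directory) "
                "VALUES (?, ?)", (name, str(directory)))

    def save_frame(self, frame_index: int, time_min: float,
                   excluded: bool = False, note: str = "",
                   shift_dy: int = 0, shift_dx: int = 0) -> None:
        with self.conn:
            self.conn.execute(
                "INSERT OR REPLACE INTO frame "
                "(frame_index, time_min, excluded, note, shift_dy, shift_dx) "
                "VALUES (?, ?, ?, ?, ?, ?)",
                (frame_index, float(time_min), int(excluded), note,
                 int(shift_dy), int(shift_dx)))

    def frame_times(self) -> list[float]:
        rows = self.conn.execute(
            "SELECT time_min FROM frame ORDER BY frame_index").fetchall()
        return [r[0] for r in rows]

    # -- cells and ROIs ----------------------------------------------------

    def save_cell(self, name: str, parent: str | None, birth_frame: int,
                  end_frame: int | None, fate: str | None) -> None:
        with self.conn:
            # upsert, not INSERT OR REPLACE: REPLACE deletes the old row and
            # the self-referencing ON DELETE CASCADE would wipe the subtree
            self.conn.execute(
                "INSERT INTO cell (name, parent, birth_frame, end_frame, "
                "fate) VALUES (?, ?, ?, ?, ?) "
                "ON CONFLICT(name) DO UPDATE SET parent=excluded.parent, "
                "birth_frame=excluded.birth_frame, "
                "end_frame=excluded.end_frame, fate=excluded.fate",
                (name, parent, birth_frame, end_frame, fate))

    def delete_cell(self, name: str) -> None:
        with self.conn:
            self.conn.execute("DELETE FROM cell WHERE name=?", (name,))

    def save_roi(self, cell: str, mask: PixelMask,
                 provenance: str = "auto") -> None:
        """Persist one selection; one transaction per mask (crash-safe)."""
        if provenance not in ("auto", "manual"):
            raise DatastoreError(f"bad provenance {provenance!r}")
        with self.conn:
            self.conn.execute(
                "INSERT INTO roi (cell, frame, rle_mask, provenance) "
                "VALUES (?, ?, ?, ?) "
                "ON CONFLICT(cell, frame) DO UPDATE SET "
                "rle_mask=excluded.rle_mask, provenance=excluded.provenance",
                (cell, mask.frame_index, mask_to_rle(mask), provenance))

    def load_roi(self, cell: str, frame: int) -> tuple[PixelMask, str]:
        row = self.conn.execute(
            "SELECT rle_mask, provenance FROM roi WHERE cell=? AND frame=?",
            (cell, frame)).fetchone()
        if row is None:
            raise DatastoreError(f"no ROI for cell {cell!r} frame {frame}")
        return rle_to_mask(row[0], frame), row[1]

    def has_roi(self, cell: str, frame: int) -> bool:
        return self.conn.execute(
            "SELECT 1 FROM roi WHERE cell=? AND frame=?",
            (cell, frame)).fetchone() is not None

    def save_background_roi(self, mask: PixelMask) -> None:
        with self.conn:
            self.conn.execute(
                "INSERT OR REPLACE INTO background_roi (id, rle_mask) "
                "VALUES (1, ?)", (mask_to_rle(mask),))

    def load_background_roi(self) -> PixelMask | None:
        row = self.conn.execute(
            "SELECT rle_mask FROM background_roi WHERE id=1").fetchone()
        return None if row is None else rle_to_mask(row[0])

    # -- measurements ------------------------------------------------------

    def save_measurements(self, rows) -> None:
        """rows: iterable of (cell, frame, channel, variable, value)."""
        with self.conn:
            self.conn.executemany(
                "INSERT OR REPLACE INTO measurement "
                "(cell, frame, channel, variable, value) "
                "VALUES (?, ?, ?, ?, ?)", list(rows))

    def save_background_mean(self, frame: int, channel: str,
                             value: float) -> None:
        with self.conn:
            self.conn.execute(
                "INSERT OR REPLACE INTO background_mean "
                "(frame, channel, value) VALUES (?, ?, ?)",
                (frame, channel, float(value)))

    def background_means(self) -> dict[tuple[int, str], float]:
        rows = self.conn.execute(
            "SELECT frame, channel, value FROM background_mean").fetchall()
        return {(r[0], r[1]): r[2] for r in rows}

    # -- events ------------------------------------------------------------

    def log_event(self, type_: str, frame: int | None = None,
                  **payload) -> None:
        with self.conn:
            self.conn.execute(
                "INSERT INTO event (type, frame, payload) VALUES (?, ?, ?)",
                (type_, frame, json.dumps(payload, sort_keys=True)))

    # -- querying and export ----------------------------------------------

    def run_sql(self, query: str) -> pd.DataFrame:
        """Execute a read-only query and return the rows as a DataFrame.

        File-backed projects run the query on a separate connection opened
        in read-only mode, so DROP / INSERT / UPDATE statements are
        rejected by the engine itself; in-memory projects (tests, throwaway
        analyses) guard the live connection with an authorizer that denies
        everything but reads.
        """
        self.conn.commit()
        if str(self.path) == ":memory:":
            allowed = (sqlite3.SQLITE_SELECT, sqlite3.SQLITE_READ,
                       sqlite3.SQLITE_FUNCTION, sqlite3.SQLITE_RECURSIVE)

            def authorizer(action, *_):
                return (sqlite3.SQLITE_OK if action in allowed
                        else sqlite3.SQLITE_DENY)

            self.conn.create_function("sqrt", 1, math.sqrt)
            self.conn.set_authorizer(authorizer)
            try:
                return pd.read_sql_query(query, self.conn)
            except (sqlite3.OperationalError, sqlite3.DatabaseError,
                    pd.errors.DatabaseError) as exc:
                raise DatastoreError(f"query rejected: {exc}") from exc
            finally:
                self.conn.set_authorizer(None)
        ro = sqlite3.connect(f"file:{self.path}?mode=ro", uri=True)
        try:
            ro.create_function("sqrt", 1, math.sqrt)
            try:
                return pd.read_sql_query(query, ro)
            except (sqlite3.OperationalError, pd.errors.DatabaseError) as exc:
                raise DatastoreError(f"query rejected: {exc}") from exc
        finally:
            ro.close()

    def ratio_timecourse_sql(self, num_channel: str = "ch1",
                             den_channel: str = "ch2") -> str:
        """The shipped green-to-red ratio query, ready for :meth:`run_sql`."""
        return RATIO_TIMECOURSE_SQL.format(num=num_channel, den=den_channel)

    def export_csv(self, selection: str, path) -> Path:
        """Export a table name or a SELECT query as an RFC-4180 CSV file.

        The file has a header row; floats keep full repr precision.
        """
        q = selection.strip()
        if not q.lower().startswith(("select", "with")):
            q = f"SELECT * FROM {q}"  # a bare table name
        df = self.run_sql(q)
        path = Path(path)
        df.to_csv(path, index=False, lineterminator="\r\n")
        return path

    def check_integrity(self) -> None:
        bad = self.conn.execute("PRAGMA foreign_key_check").fetchall()
        if bad:
            raise DatastoreError(f"foreign key violations: {bad}")
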