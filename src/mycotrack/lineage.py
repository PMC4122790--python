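"""Cell identities, binomial naming, states and division bookkeeping.

Initial cells are named with single letters (A, B, ...) and daughters by
appending A or B to the parent's name, so cell A divides into AA and AB and
AB divides into ABA and ABB.  The generation of a cell is therefore
``len(name) - 1`` and every non-initial cell's parent name is its own name
minus the last character.

Division is user-annotated: the annotated division frame is the first frame
of the daughters' existence and the parent's last frame is the one before.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .errors import LineageError, NotDefinedError
from .masks import PixelMask

FATES = ("divided", "dead", "ignored", "censored")
STATES = ("active", "ignored", "dead")

_INITIAL_RE = re.compile(r"^[A-Z]$")
_NAME_RE = re.compile(r"^[A-Z][AB]*$")


def is_valid_name(name: str) -> bool:
    return bool(_NAME_RE.match(name))


def generation(name: str) -> int:
    return len(name) - 1


def parent_name(name: str) -> str | None:
    return name[:-1] if len(name) > 1 else None


def daughter_names(name: str) -> tuple[str, str]:
    return name + "A", name + "B"


@dataclass
class CellRecord:
    """One tracked cell: identity, lifetime and fate."""

    name: str
    parent: str | None
    birth_frame: int
    end_frame: int | None = None  # None while the cell is still tracked
    fate: str | None = None       # None while active; else one of FATES
    states: dict[int, str] = field(default_factory=dict)  # frame -> state
    properties: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        if not is_valid_name(self.name):
            raise LineageError(
                f"invalid cell name {self.name!r}: initial cells are single "
                "letters A-Z, daughters append A or B")
        if self.parent is not None and self.parent != parent_name(self.name):
            raise LineageError(
                f"parent of {self.name!r} must be {parent_name(self.name)!r}")
        if self.end_frame is not None and self.end_frame < self.birth_frame:
            raise LineageError("birth_frame must be <= end_frame")

    @property
    def generation(self) -> int:
        return generation(self.name)

    def state_at(self, frame: int) -> str:
        """State applying at a frame: the latest state set at or before it."""
        state = "active"
        for f in sorted(self.states):
            if f <= frame:
                state = self.states[f]
        return state

    def alive_at(self, frame: int) -> bool:
        if frame < self.birth_frame:
            return False
        if self.end_frame is not None and frame > self.end_frame:
            return False
        return self.state_at(frame) == "active"


class Lineage:
    """In-memory registry of cell records with naming-scheme enforcement."""

    def __init__(self):
        self.cells: dict[str, CellRecord] = {}

    def __contains__(self, name: str) -> bool:
        return name in self.cells

    def __getitem__(self, name: str) -> CellRecord:
        try:
            return self.cells[name]
        except KeyError:
            raise LineageError(f"unknown cell {name!r}") from None

    def roots(self) -> list[CellRecord]:
        return [c for c in self.cells.values() if c.parent is None]

    def children(self, name: str) -> list[CellRecord]:
        return [self.cells[d] for d in daughter_names(name)
                if d in self.cells]

    def create_initial_cell(self, name: str, mask: PixelMask,
                            frame: int) -> CellRecord:
        """Register a user-delineated initial cell (generation 0)."""
        if not _INITIAL_RE.match(name):
            raise LineageError(
                f"initial cell names are single letters A-Z, got {name!r}")
        if name in self.cells:
            raise LineageError(f"cell name {name!r} already in use")
        if mask.area == 0:
            raise LineageError("initial cell mask must be nonempty")
        rec = CellRecord(name=name, parent=None, birth_frame=frame)
        self.cells[name] = rec
        return rec

    def record_division(self, parent: str, frame: int, mask_a: PixelMask,
                        mask_b: PixelMask
                        ) -> tuple[CellRecord, CellRecord]:
        """Close the parent at ``frame - 1`` and open daughters at ``frame``.

        Daughter A's mask is the first mask supplied; which physical pole it
        corresponds to is up to the annotator and is simply recorded.
        """
        rec = self[parent]
        if rec.fate is not None:
            raise LineageError(
                f"cell {parent!r} already has fate {rec.fate!r}")
        if frame <= rec.birth_frame:
            raise LineageError("division frame must be after birth")
        if mask_a.area == 0 or mask_b.area == 0:
            raise LineageError("daughter masks must be nonempty")
        if mask_a.intersects(mask_b):
            raise LineageError("daughter masks must be disjoint")
        rec.end_frame = frame - 1
        rec.fate = "divided"
        names = daughter_names(parent)
        out = []
        for dname in names:
            child = CellRecord(name=dname, parent=parent, birth_frame=frame)
            self.cells[dname] = child
            out.append(child)
        return out[0], out[1]

    def set_cell_state(self, name: str, frame: int, state: str) -> CellRecord:
        """Mark a cell ignored/dead/active from ``frame`` onward.

        Ignored and dead cells are skipped by segmentation and excluded
        from measurement aggregates; a dead cell keeps its last mask for
        display whereas an ignored one is dropped from processing entirely.
        """
        rec = self[name]
        if state not in STATES:
            raise LineageError(
                f"unknown state {state!r}; use one of {STATES} "
                "(free-form labels go through set_cell_property)")
        if frame < rec.birth_frame:
            raise LineageError("state frame before the cell's birth")
        rec.states[frame] = state
        if state in ("ignored", "dead") and rec.fate is None:
            rec.fate = state
            if rec.end_frame is None:
                rec.end_frame = frame
        return rec

    def set_cell_property(self, name: str, frame: int,
                          label: str) -> CellRecord:
        """Attach a free-form annotation (e.g. "exits-field") to a cell."""
        rec = self[name]
        rec.properties[frame] = label
        return rec

    def active_cells(self, frame: int) -> list[CellRecord]:
        return sorted((c for c in self.cells.values() if c.alive_at(frame)),
                      key=lambda c: c.name)

    def interdivision_time(self, name: str,
                           times_min: list[float]) -> tuple[float, bool]:
        """Minutes between a cell's birth and its division.

        Returns ``(minutes, left_censored)``: an initial cell already
        present at the movie start has an unknown true birth time and is
        flagged left-censored.  Cells that never divided have no defined
        interdivision time.
        """
        rec = self[name]
        if rec.fate != "divided" or rec.end_frame is None:
            raise NotDefinedError(
                f"interdivision time undefined for {name!r} "
                f"(fate={rec.fate!r})")
        t_div = times_min[rec.end_frame + 1]
        t_birth = times_min[rec.birth_frame]
        left_censored = rec.parent is None and rec.birth_frame == 0
        return t_div - t_birth, left_censored

    def check_soundness(self) -> None:
        """Raise if the tree violates the naming/lifetime invariants."""
        for rec in self.cells.values():
            if rec.parent is not None:
                if rec.parent not in self.cells:
                    raise LineageError(f"missing parent of {rec.name!r}")
                par = self.cells[rec.parent]
                if par.end_frame is None or \
                        rec.birth_frame != par.end_frame + 1:
                    raise LineageError(
                        f"birth of {rec.name!r} must follow the division "
                        f"of {rec.parent!r}")
            if rec.fate == "divided":
                kids = self.children(rec.name)
                if len(kids) != 2:
                    raise LineageError(
                        f"divided cell {rec.name!r} must have two daughters")

    def copy(self) -> "Lineage":
        out = Lineage()
        for name, rec in self.cells.items():
            out.cells[name] = replace(rec, states=dict(rec.states),
                                      properties=dict(rec.properties))
        return out
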