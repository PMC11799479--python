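"""Life pattern formats (RLE, plaintext ``.cells``) and CSV state I/O.

Coordinates are 0-based, row-major, origin at the top-left, everywhere in
this package. The builtin pattern library provides the canonical fixtures
(block, blinker, toad, glider, Gosper glider gun, r-pentomino) used to pin
the engine against known Conway dynamics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np

from .engine import WILDTYPE, LatticeState

__all__ = [
    "Pattern",
    "PatternFormatError",
    "builtin_patterns",
    "load_pattern",
    "parse_plaintext",
    "parse_rle",
    "place",
    "read_state_csv",
    "read_trajectory_csv",
    "write_plaintext",
    "write_rle",
    "write_state_csv",
    "write_trajectory_csv",
]


class PatternFormatError(ValueError):
    """Malformed pattern file; the message names the offending line/column."""


@dataclass(frozen=True)
class Pattern:
    """A finite Life pattern: extents plus the set of live (row, col) cells."""

    name: str
    width: int
    height: int
    cells: frozenset

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("pattern extents must be positive")
        for r, c in self.cells:
            if not (0 <= r < self.height and 0 <= c < self.width):
                raise ValueError(
                    f"cell ({r}, {c}) outside declared extents "
                    f"{self.height}x{self.width}"
                )

    def __len__(self) -> int:
        return len(self.cells)


_HEADER_RE = re.compile(
    r"^\s*x\s*=\s*(\d+)\s*,\s*y\s*=\s*(\d+)\s*(?:,\s*rule\s*=\s*([^\s,]+)\s*)?$",
    re.IGNORECASE,
)


def parse_rle(text: str, name: str = "pattern") -> Pattern:
    """Parse run-length-encoded Life text into a :class:`Pattern`.

    Accepts ``#`` comment lines, a ``x = <w>, y = <h>[, rule = B3/S23]``
    header and a body of run counts over ``b`` (dead), ``o`` (alive),
    ``$`` (end of row) terminated by ``!``. Cells beyond a row's encoded
    prefix are dead.
    """
    lines = text.splitlines()
    width = height = None
    body_start = 0
    for i, line in enumerate(lines):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        m = _HEADER_RE.match(stripped)
        if m is None:
            raise PatternFormatError(f"line {i + 1}: expected RLE header, got {stripped!r}")
        width, height = int(m.group(1)), int(m.group(2))
        body_start = i + 1
        break
    if width is None:
        raise PatternFormatError("missing RLE header line 'x = <w>, y = <h>'")

    cells = set()
    row = col = 0
    count = 0
    ended = False
    for i in range(body_start, len(lines)):
        if ended:
            break
        line = lines[i]
        j = 0
        while j < len(line):
            ch = line[j]
            if ch.isspace():
                j += 1
                continue
            if ch.isdigit():
                num = ch
                while j + 1 < len(line) and line[j + 1].isdigit():
                    j += 1
                    num += line[j]
                count = int(num)
            elif ch in "boBO":
                n = count if count else 1
                if ch in "oO":
                    if col + n > width or row >= height:
                        raise PatternFormatError(
                            f"line {i + 1}, col {j + 1}: live run exceeds "
                            f"declared extents {width}x{height}"
                        )
                    for cc in range(col, col + n):
                        cells.add((row, cc))
                col += n
                if col > width:
                    raise PatternFormatError(
                        f"line {i + 1}, col {j + 1}: row {row} longer than "
                        f"declared width {width}"
                    )
                count = 0
            elif ch == "$":
                n = count if count else 1
                row += n
                col = 0
                count = 0
                if row > height:
                    raise PatternFormatError(
                        f"line {i + 1}, col {j + 1}: more rows than declared "
                        f"height {height}"
                    )
            elif ch == "!":
                ended = True
                break
            else:
                raise PatternFormatError(
                    f"line {i + 1}, col {j + 1}: unknown RLE character {ch!r}"
                )
            j += 1
    if not ended:
        raise PatternFormatError("RLE body not terminated by '!'")
    return Pattern(name=name, width=width, height=height, cells=frozenset(cells))


def write_rle(pattern: Pattern) -> str:
    """Encode a pattern as RLE text that :func:`parse_rle` inverts exactly.

    Coordinates are 0-based, row-major, origin top-left.
    """
    out = [f"#N {pattern.name}", f"x = {pattern.width}, y = {pattern.height}, rule = B3/S23"]
    runs = []
    for r in range(pattern.height):
        row_runs = []
        col = 0
        while col < pattern.width:
            alive = (r, col) in pattern.cells
            n = 1
            while col + n < pattern.width and ((r, col + n) in pattern.cells) == alive:
                n += 1
            row_runs.append((n, "o" if alive else "b"))
            col += n
        # trailing dead cells of a row are implicit
        if row_runs and row_runs[-1][1] == "b":
            row_runs.pop()
        runs.append(row_runs)

    body = ""
    for i, row_runs in enumerate(runs):
        for n, ch in row_runs:
            body += (str(n) if n > 1 else "") + ch
        body += "$" if i < len(runs) - 1 else "!"
    # wrap the body at 70 characters, the conventional RLE line width
    wrapped = "\n".join(body[i : i + 70] for i in range(0, len(body), 70))
    out.append(wrapped if body else "!")
    return "\n".join(out) + "\n"


def parse_plaintext(text: str, name: str = "pattern") -> Pattern:
    """Parse ``.cells`` plaintext: ``.`` dead, ``O`` alive, ``!`` comments.

    Rows may be ragged; short rows are padded dead on the right.
    """
    rows = []
    for i, line in enumerate(text.splitlines()):
        if line.startswith("!"):
            continue
        stripped = line.rstrip()
        for j, ch in enumerate(stripped):
            if ch not in ".O":
                raise PatternFormatError(
                    f"line {i + 1}, col {j + 1}: unexpected character {ch!r} "
                    "(body allows only '.', 'O')"
                )
        rows.append(stripped)
    while rows and not rows[-1]:
        rows.pop()
    if not rows:
        raise PatternFormatError("plaintext pattern has no body rows")
    height = len(rows)
    width = max(len(r) for r in rows)
    cells = frozenset(
        (r, c) for r, line in enumerate(rows) for c, ch in enumerate(line) if ch == "O"
    )
    return Pattern(name=name, width=width, height=height, cells=cells)


def write_plaintext(pattern: Pattern) -> str:
    """Encode a pattern as ``.cells`` plaintext."""
    lines = [f"!Name: {pattern.name}"]
    for r in range(pattern.height):
        lines.append(
            "".join("O" if (r, c) in pattern.cells else "." for c in range(pattern.width))
        )
    return "\n".join(lines) + "\n"


def load_pattern(path: Union[str, Path]) -> Pattern:
    """Read a pattern file, dispatching on the ``.rle``/``.cells`` suffix."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".rle":
        return parse_rle(text, name=path.stem)
    if path.suffix.lower() == ".cells":
        return parse_plaintext(text, name=path.stem)
    raise PatternFormatError(f"unrecognized pattern suffix {path.suffix!r}")


def place(pattern: Pattern, state: LatticeState, top_left: tuple) -> LatticeState:
    """Return a copy of ``state`` with the pattern's live cells stamped in.

    Every live cell must land strictly inside the lattice interior (border
    sites cannot act and may not be seeded). Genomes at the stamped sites
    are wildtype; all other sites are unchanged.
    """
    r0, c0 = top_left
    s = state.size
    new = state.copy()
    for r, c in pattern.cells:
        rr, cc = r0 + r, c0 + c
        if not (0 < rr < s - 1 and 0 < cc < s - 1):
            raise ValueError(
                f"pattern cell at ({rr}, {cc}) overlaps the border of the "
                f"{s}x{s} lattice"
            )
        new.occupancy[rr, cc] = 1
        new.lonely[rr, cc] = WILDTYPE.lonely
        new.born[rr, cc] = WILDTYPE.born
        new.crowded[rr, cc] = WILDTYPE.crowded
    return new


_GRID_FILES = ("occupancy.csv", "lonely.csv", "born.csv", "crowded.csv")


def write_state_csv(state: LatticeState, out_dir: Union[str, Path]) -> None:
    """Dump the four grids as CSV (occupancy as integers, thresholds at full
    precision) into ``out_dir``. Rows are lattice rows, origin top-left."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savetxt(out_dir / "occupancy.csv", state.occupancy, fmt="%d", delimiter=",")
    for name in ("lonely", "born", "crowded"):
        np.savetxt(out_dir / f"{name}.csv", getattr(state, name), fmt="%.17g", delimiter=",")


def read_state_csv(in_dir: Union[str, Path], generation: int = 0) -> LatticeState:
    """Rebuild a :class:`LatticeState` from :func:`write_state_csv` output."""
    in_dir = Path(in_dir)
    grids = {}
    for fname in _GRID_FILES:
        arr = np.loadtxt(in_dir / fname, delimiter=",", ndmin=2)
        grids[fname.split(".")[0]] = arr
    shapes = {g.shape for g in grids.values()}
    if len(shapes) != 1:
        raise ValueError(f"grid CSV shape mismatch: {sorted(shapes)}")
    (shape,) = shapes
    if shape[0] != shape[1]:
        raise ValueError(f"grid CSVs are not square: {shape}")
    return LatticeState(
        occupancy=grids["occupancy"].astype(np.uint8),
        lonely=grids["lonely"],
        born=grids["born"],
        crowded=grids["crowded"],
        generation=generation,
    )


def write_trajectory_csv(path: Union[str, Path], trajectory: Iterable[int]) -> None:
    """Write the per-generation population as ``generation,population`` CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("generation,population\n")
        for gen, pop in enumerate(trajectory):
            fh.write(f"{gen},{int(pop)}\n")


def read_trajectory_csv(path: Union[str, Path]) -> np.ndarray:
    """Read a trajectory CSV back into a population array."""
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return data[:, 1].astype(np.int64)


# Builtin fixture patterns, written as plaintext for readability.
_BUILTIN_CELLS = {
    "block": "OO\nOO",
    "blinker": "OOO",
    "toad": ".OOO\nOOO.",
    "glider": ".O.\n..O\nOOO",
    "r_pentomino": ".OO\nOO.\n.O.",
    "gosper_glider_gun": (
        "........................O...........\n"
        "......................O.O...........\n"
        "............OO......OO............OO\n"
        "...........O...O....OO............OO\n"
        "OO........O.....O...OO..............\n"
        "OO........O...O.OO....O.O...........\n"
        "..........O.....O.......O...........\n"
        "...........O...O....................\n"
        "............OO......................"
    ),
}


def builtin_patterns() -> dict:
    """The canonical fixture patterns, keyed by name."""
    return {
        name: parse_plaintext(text, name=name) for name, text in _BUILTIN_CELLS.items()
    }
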