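"""British and Irish national grid references.

Ordnance Survey (GB) references use a two-letter 100 km square prefix
("SU1234"); Irish grid references use a single letter ("J1234").  The letter
alphabets omit I, giving a 5 x 5 layout of 100 km squares within each 500 km
block.  The number of digits encodes precision: 2n digits give a square of
side 10^(5-n) metres, so "SU12" is a 10 km square and "SU123456" a 100 m
square.  Tetrad (DINTY letter, 2 km) and quadrant (NE/NW/SE/SW, 5 km)
suffixes on 10 km squares are recognised so that they can be rejected as too
coarse for a 1 km analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

BRITISH = "British"
IRISH = "Irish"

# Grid letters skip I; tetrad (DINTY) letters skip O.
_GRID_LETTERS = "ABCDEFGHJKLMNOPQRSTUVWXYZ"
_TETRAD_LETTERS = "ABCDEFGHIJKLMNPQRSTUVWXYZ"
_QUADRANTS = {"SW": (0, 0), "SE": (5000, 0), "NW": (0, 5000), "NE": (5000, 5000)}

_REF_RE = re.compile(r"([A-Z]{1,2})(\d*)([A-Z]{1,2})?")


class GridRefError(ValueError):
    """Raised when a grid reference string cannot be interpreted."""


class CoarseGridRefError(ValueError):
    """Raised when a reference is coarser than the 1 km analysis resolution."""


@dataclass(frozen=True)
class ParsedGridRef:
    """A grid reference resolved to the origin of its square.

    ``easting_m``/``northing_m`` locate the south-west corner of the square
    on the relevant national grid; ``precision_m`` is the side length.
    """

    system: str
    easting_m: int
    northing_m: int
    precision_m: int


@dataclass(frozen=True, order=True)
class GridCell1km:
    """A 1 km x 1 km grid cell (a "monad"), the spatial unit of the analysis."""

    system: str
    easting_km: int
    northing_km: int

    @property
    def label(self) -> str:
        return _cell_label(self.system, self.easting_km, self.northing_km)


def _letter_index(ch: str) -> int:
    i = _GRID_LETTERS.find(ch)
    if i < 0:
        raise GridRefError(f"invalid grid letter {ch!r}")
    return i


def _british_100km_origin(l1: str, l2: str) -> tuple[int, int]:
    i1, i2 = _letter_index(l1), _letter_index(l2)
    e100 = ((i1 - 2) % 5) * 5 + (i2 % 5)
    n100 = (19 - (i1 // 5) * 5) - (i2 // 5)
    if n100 < 0:
        raise GridRefError(f"grid square {l1}{l2} lies outside the grid")
    return e100 * 100_000, n100 * 100_000


def _irish_100km_origin(l1: str) -> tuple[int, int]:
    i = _letter_index(l1)
    return (i % 5) * 100_000, (4 - i // 5) * 100_000


def _british_letters(e100: int, n100: int) -> str:
    i1 = (19 - n100) - (19 - n100) % 5 + (e100 + 10) // 5
    i2 = (19 - n100) * 5 % 25 + e100 % 5
    return _GRID_LETTERS[i1] + _GRID_LETTERS[i2]


def _irish_letter(e100: int, n100: int) -> str:
    return _GRID_LETTERS[(4 - n100) * 5 + e100]


def _cell_label(system: str, easting_km: int, northing_km: int) -> str:
    e100, n100 = easting_km // 100, northing_km // 100
    if system == BRITISH:
        letters = _british_letters(e100, n100)
    else:
        letters = _irish_letter(e100, n100)
    return f"{letters}{easting_km % 100:02d}{northing_km % 100:02d}"


def parse_grid_reference(gridref_raw: str) -> ParsedGridRef:
    """Parse a raw grid-reference string, inferring system and precision.

    Raises :class:`GridRefError` for anything that is not a well-formed
    British (two-letter) or Irish (one-letter) reference.
    """
    s = re.sub(r"\s+", "", str(gridref_raw)).upper()
    if not s:
        raise GridRefError("empty grid reference")
    m = _REF_RE.fullmatch(s)
    if m is None:
        raise GridRefError(f"unparseable grid reference {gridref_raw!r}")
    letters, digits, suffix = m.group(1), m.group(2), m.group(3)

    if len(digits) % 2 != 0 or len(digits) > 10:
        raise GridRefError(f"odd or overlong digit group in {gridref_raw!r}")
    n = len(digits) // 2

    if len(letters) == 2:
        system = BRITISH
        e0, n0 = _british_100km_origin(letters[0], letters[1])
    else:
        system = IRISH
        e0, n0 = _irish_100km_origin(letters[0])

    step = 10 ** (5 - n)  # metres per digit unit
    easting = e0 + (int(digits[:n]) * step if n else 0)
    northing = n0 + (int(digits[n:]) * step if n else 0)
    precision = step

    if suffix is not None:
        if len(suffix) == 1:
            # Tetrad: DINTY letter on a 10 km square -> 2 km.
            if n != 1:
                raise GridRefError(f"tetrad letter needs a 10 km square: {gridref_raw!r}")
            ti = _TETRAD_LETTERS.find(suffix)
            if ti < 0:
                raise GridRefError(f"invalid tetrad letter in {gridref_raw!r}")
            easting += (ti // 5) * 2000
            northing += (ti % 5) * 2000
            precision = 2000
        else:
            if n != 1 or suffix not in _QUADRANTS:
                raise GridRefError(f"invalid quadrant suffix in {gridref_raw!r}")
            de, dn = _QUADRANTS[suffix]
            easting += de
            northing += dn
            precision = 5000

    return ParsedGridRef(system, easting, northing, precision)


def truncate_to_1km(parsed: ParsedGridRef) -> GridCell1km:
    """Snap a parsed reference to its enclosing 1 km cell.

    References coarser than 1 km (tetrads, quadrants, 10 km squares, ...)
    cannot be placed in a single monad and raise
    :class:`CoarseGridRefError`.
    """
    if parsed.precision_m > 1000:
        raise CoarseGridRefError(
            f"precision {parsed.precision_m} m is coarser than 1 km"
        )
    return GridCell1km(parsed.system, parsed.easting_m // 1000, parsed.northing_m // 1000)


def cell_from_label(label: str) -> GridCell1km:
    """Parse a canonical 1 km cell label (letters + 2+2 digits)."""
    parsed = parse_grid_reference(label)
    if parsed.precision_m != 1000:
        raise GridRefError(f"{label!r} is not a 1 km cell label")
    return truncate_to_1km(parsed)
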