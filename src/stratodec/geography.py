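"""Discrete areas, range states, state spaces and time strata.

A lineage's geographic range is a nonempty set of discrete areas, encoded
as a bitmask over area indices (bit ``i`` set means area ``i`` occupied).
The *null range* (no areas, ``bits == 0``) exists only as an anagenetic
absorbing state reached by extinction of the last occupied area: it is
never valid tip data and never speciates.

Time strata partition the timescale (Myr before present) into intervals
with possibly different sets of allowed areas, which is how paleogeographic
constraints such as "this landmass did not exist before time T" enter the
model.  Strata are half-open ``[younger, older)``: a node whose age falls
exactly on a boundary belongs to the younger stratum, so a constraint that
an area may not occur "until 15 Myr ago" permits it at ages strictly
below 15.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import yaml

__all__ = [
    "Area",
    "Stratum",
    "Geography",
    "StateSpace",
    "TipRangeMatrix",
    "GeographyError",
    "build_state_space",
    "stratum_state_mask",
    "parse_geography_file",
    "write_geography_file",
    "load_geography_config",
]


class GeographyError(ValueError):
    """Invalid geography input (file, config, or constraint structure)."""


@dataclass(frozen=True)
class Area:
    """A discrete biogeographic region."""

    index: int
    code: str
    name: str = ""


@dataclass(frozen=True)
class Stratum:
    """A time interval ``[younger_bound, older_bound)`` in Myr before present
    with a bitmask of areas allowed to be occupied while in it."""

    older_bound: float
    younger_bound: float
    allowed_areas: int

    def __post_init__(self) -> None:
        if not self.older_bound > self.younger_bound >= 0:
            raise GeographyError(
                f"stratum bounds must satisfy older > younger >= 0, got "
                f"[{self.younger_bound}, {self.older_bound})"
            )

    def contains(self, age: float) -> bool:
        """Whether an age (Myr) falls in this stratum (half-open interval)."""
        return self.younger_bound <= age < self.older_bound


@dataclass
class Geography:
    """Area set, time strata and (optional) pairwise dispersal multipliers.

    Strata must tile ``[0, oldest)`` with no gaps or overlaps and are stored
    youngest first.  The multiplier matrix scales the per-pair dispersal
    rate ``d``; the diagonal is unused (self-dispersal is undefined).
    """

    areas: list[Area]
    strata: list[Stratum] = field(default_factory=list)
    dispersal_multipliers: list[list[float]] | None = None

    def __post_init__(self) -> None:
        codes = [a.code for a in self.areas]
        if len(set(codes)) != len(codes):
            raise GeographyError(f"duplicate area codes: {codes}")
        for i, a in enumerate(self.areas):
            if a.index != i:
                raise GeographyError("area indices must be consecutive from 0")
        full = (1 << len(self.areas)) - 1
        if not self.strata:
            self.strata = [Stratum(math.inf, 0.0, full)]
        self.strata = sorted(self.strata, key=lambda s: s.younger_bound)
        prev_old = 0.0
        for s in self.strata:
            if s.younger_bound != prev_old:
                raise GeographyError("strata must tile the timescale without gaps/overlaps")
            if s.allowed_areas & ~full:
                raise GeographyError("stratum allows undeclared areas")
            prev_old = s.older_bound
        if self.dispersal_multipliers is not None:
            m = self.dispersal_multipliers
            n = len(self.areas)
            if len(m) != n or any(len(row) != n for row in m):
                raise GeographyError("multiplier matrix must be n_areas x n_areas")
            if any(x < 0 for row in m for x in row):
                raise GeographyError("dispersal multipliers must be nonnegative")

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    def stratum_index_at(self, age: float) -> int:
        """Index (youngest first) of the stratum governing ``age``.

        A node exactly at a boundary belongs to the younger stratum, so
        the lookup uses ``age <= older_bound`` on the youngest-first scan.
        """
        if age < 0:
            raise GeographyError(f"negative age {age}")
        for i, s in enumerate(self.strata):
            if age <= s.older_bound:
                return i
        raise GeographyError(f"age {age} not covered by any stratum")

    def stratum_at(self, age: float) -> Stratum:
        return self.strata[self.stratum_index_at(age)]

    def boundaries_between(self, younger: float, older: float) -> list[float]:
        """Stratum boundary ages strictly inside ``(younger, older)``, ascending.

        Boundaries coinciding with either endpoint split nothing: the
        branch's interior then lies entirely on one side.
        """
        out = []
        for s in self.strata[:-1]:
            b = s.older_bound
            if younger < b < older:
                out.append(b)
        return out

    def range_label(self, bits: int) -> str:
        """Human-readable label for a range bitmask, e.g. ``'ACD'``."""
        if bits == 0:
            return "-"
        return "".join(a.code for a in self.areas if bits >> a.index & 1)


@dataclass(frozen=True)
class StateSpace:
    """Deterministic enumeration of permissible ranges over ``n_areas`` areas.

    States are ordered by range size, then by bitmask value; the null range
    is always at index 0.  ``max_range_size`` caps the number of areas a
    single lineage may occupy (``None`` = unlimited).
    """

    n_areas: int
    max_range_size: int | None
    states: tuple[int, ...]
    sizes: tuple[int, ...]
    index_of: dict[int, int]

    def __len__(self) -> int:
        return len(self.states)

    def index(self, bits: int) -> int:
        try:
            return self.index_of[bits]
        except KeyError:
            raise KeyError(f"range bitmask {bits:b} not in state space") from None


def build_state_space(n_areas: int, max_range_size: int | None = None) -> StateSpace:
    """Enumerate the null range plus every nonempty subset of areas with
    size <= ``max_range_size``, ordered by (size, bitmask value)."""
    if n_areas < 1:
        raise GeographyError("n_areas must be >= 1")
    cap = n_areas if max_range_size is None else min(max_range_size, n_areas)
    if cap < 1:
        raise GeographyError("max_range_size must be >= 1")
    states: list[int] = [0]
    for k in range(1, cap + 1):
        states.extend(
            sorted(sum(1 << i for i in combo) for combo in combinations(range(n_areas), k))
        )
    sizes = tuple(s.bit_count() for s in states)
    return StateSpace(
        n_areas=n_areas,
        max_range_size=max_range_size,
        states=tuple(states),
        sizes=sizes,
        index_of={s: i for i, s in enumerate(states)},
    )


def stratum_state_mask(space: StateSpace, stratum: Stratum) -> list[bool]:
    """Boolean vector: state allowed in stratum iff its areas are a subset of
    the stratum's allowed areas.  The null range is always allowed."""
    return [bits & ~stratum.allowed_areas == 0 for bits in space.states]


@dataclass
class TipRangeMatrix:
    """Observed tip ranges: taxon names with their range bitmasks."""

    taxa: list[str]
    ranges: list[int]
    n_areas: int

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.ranges):
            raise GeographyError("taxon/range count mismatch")
        full = (1 << self.n_areas) - 1
        seen = set()
        for t, r in zip(self.taxa, self.ranges):
            if t in seen:
                raise GeographyError(f"duplicate taxon {t!r}")
            seen.add(t)
            if r == 0:
                raise GeographyError(f"taxon {t!r} has a null (all-zero) range")
            if r & ~full:
                raise GeographyError(f"taxon {t!r} uses undeclared areas")

    def __len__(self) -> int:
        return len(self.taxa)

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.taxa, self.ranges))


_HEADER_RE = re.compile(r"^\s*(\d+)\s+(\d+)\s*(?:\(([^)]*)\))?\s*$")


def parse_geography_file(text: str) -> tuple[list[Area], TipRangeMatrix]:
    """Parse a LAGRANGE/PHYLIP-dialect geography file.

    Format: a header line ``N M (c1 c2 ... cM)`` giving taxon count, area
    count and optional single-letter area codes, followed by ``N`` lines of
    ``taxon  binarystring`` where the string has one 0/1 column per area.
    Lines starting with ``#`` are ignored.  Column ``i`` maps to area bit
    ``i``.
    """
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise GeographyError("empty geography file")
    m = _HEADER_RE.match(lines[0])
    if not m:
        raise GeographyError(f"malformed header line: {lines[0]!r}")
    n_taxa, n_areas = int(m.group(1)), int(m.group(2))
    if m.group(3) is not None:
        codes = m.group(3).split()
        if len(codes) != n_areas:
            raise GeographyError(
                f"header declares {n_areas} areas but lists {len(codes)} codes"
            )
    else:
        codes = [chr(ord("A") + i) for i in range(n_areas)]
    areas = [Area(i, c) for i, c in enumerate(codes)]
    rows = lines[1:]
    if len(rows) != n_taxa:
        raise GeographyError(f"header declares {n_taxa} taxa but file has {len(rows)} rows")
    taxa: list[str] = []
    ranges: list[int] = []
    for ln in rows:
        parts = ln.split()
        if len(parts) != 2:
            raise GeographyError(f"malformed taxon row: {ln!r}")
        name, bstr = parts
        if len(bstr) != n_areas:
            raise GeographyError(
                f"taxon {name!r}: expected {n_areas} columns, got {len(bstr)}"
            )
        if set(bstr) - {"0", "1"}:
            raise GeographyError(f"taxon {name!r}: characters outside {{0,1}}")
        bits = sum(1 << i for i, ch in enumerate(bstr) if ch == "1")
        taxa.append(name)
        ranges.append(bits)
    return areas, TipRangeMatrix(taxa=taxa, ranges=ranges, n_areas=n_areas)


def write_geography_file(areas: Sequence[Area], tips: TipRangeMatrix) -> str:
    """Serialize areas + tip ranges to the LAGRANGE/PHYLIP dialect; inverse
    of :func:`parse_geography_file`."""
    codes = " ".join(a.code for a in areas)
    out = [f"{len(tips)} {len(areas)} ({codes})"]
    for t, r in zip(tips.taxa, tips.ranges):
        bstr = "".join("1" if r >> i & 1 else "0" for i in range(len(areas)))
        out.append(f"{t}\t{bstr}")
    return "\n".join(out) + "\n"


def load_geography_config(text: str) -> Geography:
    """Build a :class:`Geography` from a YAML config.

    Keys: ``areas`` (list of ``{code, name}``), ``strata`` (list of
    ``{older, younger, allowed}`` where ``allowed`` is a string of area
    codes or the word ``all``; ``older`` may be ``inf``), optional
    ``multipliers`` (full matrix).  Without ``strata``, a single
    all-allowing stratum covering all ages is used.
    """
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict) or "areas" not in cfg:
        raise GeographyError("config must be a mapping with an 'areas' key")
    areas = [
        Area(i, str(a["code"]), str(a.get("name", "")))
        for i, a in enumerate(cfg["areas"])
    ]
    code_to_bit = {a.code: 1 << a.index for a in areas}
    full = (1 << len(areas)) - 1
    strata = []
    for s in cfg.get("strata", []):
        allowed_spec = s.get("allowed", "all")
        if allowed_spec == "all":
            allowed = full
        else:
            allowed = 0
            for c in str(allowed_spec):
                if c not in code_to_bit:
                    raise GeographyError(f"unknown area code {c!r} in stratum")
                allowed |= code_to_bit[c]
        older = float(s["older"])
        strata.append(Stratum(older, float(s["younger"]), allowed))
    mult = cfg.get("multipliers")
    return Geography(areas=areas, strata=strata, dispersal_multipliers=mult)
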