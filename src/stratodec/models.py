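"""DEC-family model specifications, anagenetic generators and cladogenesis tables.

Anagenesis (along branches) is a continuous-time Markov chain on range
states with two event types: dispersal (range expansion) adds one area at
rate ``d`` per (source area, target area) pair, optionally scaled by a
dispersal multiplier; extinction (range contraction) removes one occupied
area at rate ``e``.  A singleton range contracts to the null range, which
is absorbing.

Cladogenesis (at nodes) draws an ordered (left, right) daughter range pair
conditional on the ancestor range.  The families differ in which event
classes they permit:

========== ==================== =================== ===========================
family     singleton ancestor   widespread ancestor  notes
========== ==================== =================== ===========================
DEC        sympatry (R,R)       subset sympatry +    vicariance restricted to
                                 vicariance           splits with a singleton part
DIVA-like  sympatry (R,R)       vicariance only      widespread vicariance
                                                      (both parts may exceed 1)
BayArea-   sympatry (R,R)       sympatry (R,R)       identical inheritance only
 like
========== ==================== =================== ===========================

The +j variants add founder-event ("jump") speciation: one daughter keeps
the full ancestral range, the other founds a new singleton range outside
it.  Each non-jump event carries weight ``(3 - j)/3`` and each jump event
weight ``j`` with ``j`` in [0, 3], so j = 0 recovers the base family
exactly and j = 3 puts all cladogenetic mass on jumps.  Probabilities are
the weights renormalized per ancestor after removing events whose
daughters are disallowed in the node's stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geography import Geography, GeographyError, StateSpace, Stratum

__all__ = [
    "ModelSpec",
    "CladoTable",
    "FAMILIES",
    "SYMPATRY",
    "SUBSET_SYMPATRY",
    "VICARIANCE",
    "JUMP",
    "parse_model_name",
    "build_generator",
    "build_clado_table",
    "reduce_to_dec",
]

FAMILIES = ("DEC", "DIVALIKE", "BAYAREALIKE")

# cladogenetic event classes
SYMPATRY = 0
SUBSET_SYMPATRY = 1
VICARIANCE = 2
JUMP = 3
EVENT_CLASS_NAMES = ("sympatry", "subset_sympatry", "vicariance", "jump")


@dataclass(frozen=True)
class ModelSpec:
    """A model family with concrete rates.

    d, e are in events per Myr (per source-area pair and per occupied area
    respectively); j is the dimensionless founder-event weight in [0, 3].
    """

    family: str = "DEC"
    plus_j: bool = False
    d: float = 0.0
    e: float = 0.0
    j: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.d < 0 or self.e < 0:
            raise ValueError("d and e must be nonnegative")
        if not 0.0 <= self.j <= 3.0:
            raise ValueError("j must lie in [0, 3]")
        if not self.plus_j and self.j != 0.0:
            raise ValueError("j must be 0 when plus_j is False")

    @property
    def name(self) -> str:
        return self.family + ("+J" if self.plus_j else "")

    @property
    def n_free_parameters(self) -> int:
        return 3 if self.plus_j else 2


def parse_model_name(name: str) -> tuple[str, bool]:
    """Parse strings like ``DEC``, ``DEC+J``, ``divalike+j`` into
    (family, plus_j)."""
    s = name.strip().upper().replace("-", "")
    plus_j = s.endswith("+J")
    fam = s[:-2] if plus_j else s
    if fam not in FAMILIES:
        raise ValueError(f"unknown model name {name!r}")
    return fam, plus_j


def reduce_to_dec(spec: ModelSpec) -> ModelSpec:
    """Drop the +j flag from a model with j = 0; the reduced model has
    event tables and generators identical to the original."""
    if spec.j != 0.0:
        raise ValueError(f"cannot reduce a model with j = {spec.j} != 0")
    return replace(spec, plus_j=False)


def build_generator(
    space: StateSpace,
    geography: Geography,
    stratum: Stratum,
    d: float,
    e: float,
) -> np.ndarray:
    """Dense anagenetic rate matrix Q over the state space for one stratum.

    rate(R -> R+{a}) = sum_{b in R} d * m[b, a] for a outside R, provided
    R+{a} is within the range-size cap and allowed in the stratum;
    rate(R -> R-{a}) = e for each a in R (singletons contract to the null
    range, which is absorbing).  Rows of states disallowed in the stratum
    are zero: such states cannot be occupied while the stratum applies.
    """
    if d < 0 or e < 0:
        raise ValueError("rates must be nonnegative")
    n = len(space)
    mult = geography.dispersal_multipliers
    cap = space.max_range_size or space.n_areas
    allowed = stratum.allowed_areas
    Q = np.zeros((n, n))
    for i, bits in enumerate(space.states):
        if bits == 0 or bits & ~allowed:
            continue  # null range absorbing; masked states have no dynamics
        size = space.sizes[i]
        for a in range(space.n_areas):
            abit = 1 << a
            if bits & abit:
                Q[i, space.index_of[bits & ~abit]] += e
            elif abit & allowed and size < cap:
                target = bits | abit
                if target in space.index_of:
                    if mult is None:
                        rate = d * size
                    else:
                        rate = d * sum(mult[b][a] for b in range(space.n_areas) if bits >> b & 1)
                    Q[i, space.index_of[target]] += rate
        Q[i, i] = -Q[i].sum()
    return Q


@dataclass(frozen=True)
class CladoTable:
    """Cladogenetic events as flat arrays for fast likelihood combination.

    ``anc``, ``left``, ``right`` are state-space indices; ``prob`` sums to
    1 within each ancestor; ``event_class`` holds the SYMPATRY /
    SUBSET_SYMPATRY / VICARIANCE / JUMP codes.  Ancestors that are masked
    in the stratum (or the null range) have no events.
    """

    n_states: int
    anc: np.ndarray
    left: np.ndarray
    right: np.ndarray
    prob: np.ndarray
    event_class: np.ndarray

    def events_for(self, anc_idx: int):
        """(left, right, prob, class) arrays for one ancestor state."""
        sel = self.anc == anc_idx
        if not sel.any():
            raise GeographyError(
                f"ancestor state {anc_idx} has no cladogenetic events "
                "(null range or masked in its stratum)"
            )
        return self.left[sel], self.right[sel], self.prob[sel], self.event_class[sel]

    def combine(self, v_left: np.ndarray, v_right: np.ndarray) -> np.ndarray:
        """Ancestor-indexed vector sum_e P(e|anc) * v_left[l(e)] * v_right[r(e)].

        This is the pruning step at a node: v_left / v_right are the
        daughters' conditional likelihood vectors transported to the node.
        """
        vals = self.prob * v_left[self.left] * v_right[self.right]
        return np.bincount(self.anc, weights=vals, minlength=self.n_states)


def _nonempty_subsets_between(bits: int) -> list[int]:
    """All nonempty proper subsets of the set ``bits``."""
    sub = (bits - 1) & bits
    out = []
    while sub:
        out.append(sub)
        sub = (sub - 1) & bits
    return out


def build_clado_table(
    space: StateSpace,
    family: str,
    plus_j: bool,
    j: float,
    stratum: Stratum,
) -> CladoTable:
    """Enumerate ordered cladogenetic events per ancestor state with
    normalized probabilities, masking daughters disallowed in ``stratum``.

    See the module docstring for the per-family event inventory and the
    (3 - j)/3 vs j weight convention.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if not 0.0 <= j <= 3.0:
        raise ValueError("j must lie in [0, 3]")
    if not plus_j and j != 0.0:
        raise ValueError("j must be 0 when plus_j is False")
    allowed = stratum.allowed_areas
    w_base = (3.0 - j) / 3.0
    anc_l: list[int] = []
    left_l: list[int] = []
    right_l: list[int] = []
    w_l: list[float] = []
    cls_l: list[int] = []

    def emit(anc, l, r, w, cls):
        if w <= 0.0:
            return
        anc_l.append(anc)
        left_l.append(l)
        right_l.append(r)
        w_l.append(w)
        cls_l.append(cls)

    for i, bits in enumerate(space.states):
        if bits == 0 or bits & ~allowed:
            continue  # null range never speciates; masked ancestor has no row
        size = space.sizes[i]
        if size == 1 or family == "BAYAREALIKE":
            emit(i, i, i, w_base, SYMPATRY)
        if size > 1 and family == "DEC":
            for a in range(space.n_areas):
                if bits >> a & 1:
                    s = space.index_of[1 << a]
                    emit(i, i, s, w_base, SUBSET_SYMPATRY)
                    emit(i, s, i, w_base, SUBSET_SYMPATRY)
        if size > 1 and family in ("DEC", "DIVALIKE"):
            for part in _nonempty_subsets_between(bits):
                rest = bits & ~part
                if family == "DEC" and min(part.bit_count(), rest.bit_count()) != 1:
                    continue
                if part not in space.index_of or rest not in space.index_of:
                    continue  # parts beyond the range-size cap
                emit(i, space.index_of[part], space.index_of[rest], w_base, VICARIANCE)
        if plus_j:
            for a in range(space.n_areas):
                abit = 1 << a
                if bits & abit or not abit & allowed:
                    continue
                s = space.index_of[abit]
                emit(i, i, s, j, JUMP)
                emit(i, s, i, j, JUMP)

    anc = np.asarray(anc_l, dtype=np.intp)
    w = np.asarray(w_l, dtype=float)
    totals = np.bincount(anc, weights=w, minlength=len(space)) if len(anc) else np.zeros(len(space))
    for i, bits in enumerate(space.states):
        if bits and not bits & ~allowed and totals[i] <= 0.0:
            raise GeographyError(
                f"ancestor state {i} has an empty cladogenetic event set after masking"
            )
    prob = w / totals[anc] if len(anc) else w
    return CladoTable(
        n_states=len(space),
        anc=anc,
        left=np.asarray(left_l, dtype=np.intp),
        right=np.asarray(right_l, dtype=np.intp),
        prob=prob,
        event_class=np.asarray(cls_l, dtype=np.int8),
    )
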