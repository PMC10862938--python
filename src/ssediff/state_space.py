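"""Range states, state spaces, and validated rate containers.

A GeoSSE model lives on a finite set of regions (labels such as "A", "B",
"C").  A species *range* is any nonempty subset of those regions; the model
state space is the collection of all such subsets.  This module defines the
canonical representation of ranges and state spaces used throughout the
package, together with the rate-parameter containers for the GeoSSE model
(within-region speciation ``w``, local extinction ``e``, dispersal ``d``,
between-region speciation ``b``) and the two-state BiSSE model.

Canonical ordering: states are sorted by range size, then lexicographically
by region labels.  The ordering is fixed so that vectors, matrices and file
columns are reproducible across runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Tuple


@dataclass(frozen=True, order=True)
class RangeState:
    """A species range: a nonempty, canonically ordered set of regions."""

    regions: Tuple[str, ...]

    def __init__(self, regions: Iterable[str]):
        regs = tuple(sorted(regions))
        if not regs:
            raise ValueError("a range state must contain at least one region")
        if len(set(regs)) != len(regs):
            raise ValueError(f"duplicate regions in range state: {regs}")
        object.__setattr__(self, "regions", regs)

    @property
    def label(self) -> str:
        """Concatenated region labels, e.g. ``'AB'`` for {A,B}."""
        return "".join(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __contains__(self, region: str) -> bool:
        return region in self.regions

    def __iter__(self):
        return iter(self.regions)

    def union(self, region: str) -> "RangeState":
        return RangeState(self.regions + (region,))

    def minus(self, region: str) -> "RangeState":
        rest = tuple(r for r in self.regions if r != region)
        return RangeState(rest)

    def issubset(self, other: "RangeState") -> bool:
        return set(self.regions) <= set(other.regions)

    def __repr__(self) -> str:
        return f"RangeState({{{','.join(self.regions)}}})"


def _sort_key(state: RangeState):
    return (len(state.regions), state.regions)


@dataclass(frozen=True)
class StateSpace:
    """All nonempty subsets of a region set, in canonical order."""

    regions: Tuple[str, ...]
    states: Tuple[RangeState, ...]
    _index: Mapping[RangeState, int] = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        object.__setattr__(
            self, "_index", {s: k for k, s in enumerate(self.states)}
        )

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def index(self, state: RangeState) -> int:
        try:
            return self._index[state]
        except KeyError:
            raise KeyError(f"state {state} not in state space over {self.regions}")

    def labels(self) -> Tuple[str, ...]:
        return tuple(s.label for s in self.states)

    def state_by_label(self, label: str) -> RangeState:
        return self.states[self.index(RangeState(label))]

    def splits(self, state: RangeState) -> Tuple[Tuple[RangeState, RangeState], ...]:
        """All unordered splits of a widespread range into two disjoint,
        nonempty daughter ranges that cover the parent."""
        if len(state) < 2:
            return ()
        regs = state.regions
        out = []
        # iterate subsets containing the first region to avoid mirror pairs
        rest = regs[1:]
        for r in range(0, len(rest)):
            for combo in itertools.combinations(rest, r):
                left = RangeState((regs[0],) + combo)
                right_regs = tuple(x for x in regs if x not in left.regions)
                if right_regs:
                    out.append((left, RangeState(right_regs)))
        return tuple(out)


def enumerate_range_states(regions: Iterable[str]) -> StateSpace:
    """Build the GeoSSE state space over ``regions``.

    Returns all 2^n - 1 nonempty subsets, ordered by size then
    lexicographically; the ordering is deterministic and stable.
    """
    regs = tuple(regions)
    if not regs:
        raise ValueError("at least one region is required")
    if len(set(regs)) != len(regs):
        raise ValueError(f"duplicate region labels: {regs}")
    regs = tuple(sorted(regs))
    states = []
    for r in range(1, len(regs) + 1):
        for combo in itertools.combinations(regs, r):
            states.append(RangeState(combo))
    states.sort(key=_sort_key)
    return StateSpace(regions=regs, states=tuple(states))


SplitKey = Tuple[Tuple[str, ...], Tuple[str, ...]]


def split_key(left: Iterable[str], right: Iterable[str]) -> SplitKey:
    """Canonical key for an unordered range split {left}|{right}."""
    a = tuple(sorted(left))
    b = tuple(sorted(right))
    if not a or not b:
        raise ValueError("both sides of a split must be nonempty")
    if set(a) & set(b):
        raise ValueError(f"split sides must be disjoint: {a} | {b}")
    return (a, b) if (len(a), a) <= (len(b), b) else (b, a)


@dataclass
class GeoSSEParams:
    """GeoSSE rate parameters.

    w : region -> within-region speciation rate (per lineage)
    e : region -> local extinction (extirpation) rate
    d : ordered pair (from, to) -> dispersal rate (per lineage)
    b : unordered split key -> between-region speciation rate; symmetric
        under swapping the two sides of the split.
    """

    w: Dict[str, float]
    e: Dict[str, float]
    d: Dict[Tuple[str, str], float]
    b: Dict[SplitKey, float]

    def b_rate(self, left: Iterable[str], right: Iterable[str]) -> float:
        return self.b[split_key(left, right)]

    def copy(self) -> "GeoSSEParams":
        return GeoSSEParams(dict(self.w), dict(self.e), dict(self.d), dict(self.b))


@dataclass
class BiSSEParams:
    """Binary-state SSE rates: state-dependent speciation (lambda), extinction
    (mu) and anagenetic transitions q12 (1->2) and q21 (2->1)."""

    lambda1: float
    lambda2: float
    mu1: float
    mu2: float
    q12: float
    q21: float

    def __post_init__(self):
        for name in ("lambda1", "lambda2", "mu1", "mu2", "q12", "q21"):
            if getattr(self, name) < 0:
                raise ValueError(f"BiSSE rate {name} must be nonnegative")


def required_split_keys(space: StateSpace) -> Tuple[SplitKey, ...]:
    """All split keys a full GeoSSE parameterization must provide: every
    unordered split of every widespread state."""
    keys = []
    seen = set()
    for s in space.states:
        for left, right in space.splits(s):
            k = split_key(left.regions, right.regions)
            if k not in seen:
                seen.add(k)
                keys.append(k)
    return tuple(keys)


def validate_params(
    params: GeoSSEParams, space: StateSpace, strict: bool = False
) -> GeoSSEParams:
    """Check completeness and sign of a GeoSSE rate set.

    Every region needs a ``w`` and ``e`` entry, every ordered region pair a
    ``d`` entry, and every split of every widespread state a ``b`` entry
    (entries keyed by either orientation of a split are closed symmetrically).
    In ``strict`` mode every rate must be strictly positive — required by the
    rate-from-frequency solver, where all events must remain possible; the
    permissive default (rates >= 0) admits configurations with whole event
    classes switched off.  Validation is idempotent and returns a normalized
    copy.
    """
    regs = space.regions
    w = {}
    e = {}
    for r in regs:
        if r not in params.w:
            raise ValueError(f"missing within-region speciation rate w[{r}]")
        if r not in params.e:
            raise ValueError(f"missing local extinction rate e[{r}]")
        w[r] = float(params.w[r])
        e[r] = float(params.e[r])
    extra = set(params.w) - set(regs)
    if extra:
        raise ValueError(f"w rates reference unknown regions: {sorted(extra)}")
    extra = set(params.e) - set(regs)
    if extra:
        raise ValueError(f"e rates reference unknown regions: {sorted(extra)}")

    d = {}
    for k in regs:
        for l in regs:
            if k == l:
                continue
            if (k, l) not in params.d:
                raise ValueError(f"missing dispersal rate d[{k}>{l}]")
            d[(k, l)] = float(params.d[(k, l)])
    for (k, l) in params.d:
        if k not in regs or l not in regs or k == l:
            raise ValueError(f"invalid dispersal key d[{k}>{l}]")

    b = {}
    normalized = {}
    for (left, right), v in params.b.items():
        key = split_key(left, right)
        if key in normalized and normalized[key] != float(v):
            raise ValueError(
                f"conflicting between-region speciation rates for split {key}"
            )
        normalized[key] = float(v)
    for key in required_split_keys(space):
        if key not in normalized:
            raise ValueError(
                f"missing between-region speciation rate b[{key[0]}|{key[1]}]"
            )
        b[key] = normalized[key]
    for key in normalized:
        if key not in b:
            raise ValueError(f"b rate references split outside state space: {key}")

    for name, mapping in (("w", w), ("e", e), ("d", d), ("b", b)):
        for key, v in mapping.items():
            if v < 0:
                raise ValueError(f"negative rate {name}[{key}] = {v}")
            if strict and v <= 0:
                raise ValueError(
                    f"strict mode requires {name}[{key}] > 0 (got {v})"
                )

    return GeoSSEParams(w=w, e=e, d=d, b=b)
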