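"""Independent brute-force oracle for GeoSSE event rates.

Enumerates every elementary event a species can undergo — within-region
speciation per occupied region, dispersal per unoccupied region,
between-region speciation per ordered range split (each at half its split
rate), and local extinction per occupied region — and accumulates, for each
range state, the total rate of events that create or remove a species with
that state.  Written directly from the event semantics, independently of the
package's closed-form summations.
"""

import itertools

import numpy as np

from ssediff import RangeState


def _ordered_splits(state):
    """All ordered pairs (s, t) of disjoint nonempty ranges with union = state."""
    regs = state.regions
    out = []
    for r in range(1, len(regs)):
        for combo in itertools.combinations(regs, r):
            s = RangeState(combo)
            t = RangeState(tuple(x for x in regs if x not in combo))
            out.append((s, t))
    return out


def brute_force_components(counts, params, space):
    """Per-state dict of gain/loss component totals keyed like
    ('W','+'), ('D','-'), etc."""
    comp = {
        st: {(cls, sign): 0.0 for cls in "WDBE" for sign in "+-"}
        for st in space.states
    }
    n = np.asarray(counts, dtype=float)

    for j in space.states:
        nj = n[space.index(j)]
        # within-region speciation: new endemic in region l, parent unchanged
        for l in j.regions:
            comp[RangeState([l])][("W", "+")] += nj * params.w[l]
        # dispersal into each unoccupied region
        for l in space.regions:
            if l in j.regions:
                continue
            rate = nj * sum(params.d[(k, l)] for k in j.regions)
            comp[j][("D", "-")] += rate
            comp[j.union(l)][("D", "+")] += rate
        # between-region speciation: ordered splits at half the split rate
        for s, t in _ordered_splits(j):
            rate = 0.5 * nj * params.b_rate(s.regions, t.regions)
            comp[j][("B", "-")] += rate
            comp[s][("B", "+")] += rate
            comp[t][("B", "+")] += rate
        # local extinction in each occupied region
        for l in j.regions:
            rate = nj * params.e[l]
            comp[j][("E", "-")] += rate
            if len(j) > 1:
                comp[j.minus(l)][("E", "+")] += rate

    return comp
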