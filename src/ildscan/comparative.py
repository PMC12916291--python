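"""Cross-population comparison of sweep locations.

Sweeps detected independently in different host populations can be compared
once their intervals live on a shared reference coordinate system.  Two
sweeps are "the same" when their intervals overlap by at least a minimum
number of bases; the proportion shared between two populations is a Jaccard
index ``J = matched / (|a| + |b| - matched)``.  Excess within-group versus
between-group sharing is assessed with a permutation test that reassigns
sweeps randomly among populations while preserving each population's sweep
count.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import UsageError
from .types import PopulationSweepSet, SweepCall


def _overlap(a: SweepCall, b: SweepCall) -> int:
    if a.contig_id != b.contig_id:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def sweeps_shared(
    a: PopulationSweepSet,
    b: PopulationSweepSet,
    min_overlap: int = 1,
) -> tuple[int, list[tuple[int, int]]]:
    """Count sweeps shared between two populations.

    Builds a maximum one-to-one matching between intervals overlapping by at
    least ``min_overlap`` bp (maximum bipartite matching on the overlap
    graph, so no admissible pairing is left on the table).  Returns the
    matched count and the matched index pairs (index into
    ``a.sweeps``/``b.sweeps``).
    """
    if not a.sweeps or not b.sweeps:
        return 0, []
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import maximum_bipartite_matching

    adj = np.zeros((len(a.sweeps), len(b.sweeps)), dtype=np.int8)
    for i, sa in enumerate(a.sweeps):
        for j, sb in enumerate(b.sweeps):
            if _overlap(sa, sb) >= min_overlap:
                adj[i, j] = 1
    if not adj.any():
        return 0, []
    match = maximum_bipartite_matching(csr_matrix(adj), perm_type="column")
    pairs = [(i, int(j)) for i, j in enumerate(match) if j >= 0]
    return len(pairs), pairs


def jaccard(
    a: PopulationSweepSet, b: PopulationSweepSet, min_overlap: int = 1
) -> float:
    """Proportion of sweeps shared between two populations.

    ``J = m / (|a| + |b| - m)`` with ``m`` the matched sweep count; undefined
    (raises :class:`UsageError`) when both sets are empty.
    """
    if not a.sweeps and not b.sweeps:
        raise UsageError("Jaccard undefined: both sweep sets are empty")
    m, _ = sweeps_shared(a, b, min_overlap)
    return m / (len(a.sweeps) + len(b.sweeps) - m)


def _mean_group_jaccard(
    sets: Sequence[PopulationSweepSet],
    groups: Sequence[str],
    g1: str,
    g2: str,
    min_overlap: int,
) -> float:
    """Average pairwise J over population pairs of the given group pair."""
    vals = []
    for (i, a), (j, b) in combinations(enumerate(sets), 2):
        gi, gj = groups[i], groups[j]
        if {gi, gj} == {g1, g2} or (g1 == g2 and gi == gj == g1):
            if a.sweeps or b.sweeps:
                vals.append(jaccard(a, b, min_overlap))
    if not vals:
        raise UsageError(f"no population pairs for groups ({g1}, {g2})")
    return float(np.mean(vals))


def sharing_permutation_test(
    sets: Sequence[PopulationSweepSet],
    grouping: Optional[Sequence[str]] = None,
    reps: int = 10_000,
    seed: int = 0,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Permutation test for excess sweep sharing within/between groups.

    The observed mean pairwise Jaccard index for each group comparison is
    ranked against a null in which the pooled sweeps are redealt randomly
    among populations, preserving each population's sweep count (sampling
    from the pooled universe without replacement per permutation).  One-sided
    ``p = (1 + #{null >= observed}) / (1 + reps)``.

    Returns a DataFrame with columns ``group_a, group_b, observed_j, p_value``.
    """
    grouping = list(grouping) if grouping is not None else [s.group for s in sets]
    if len(grouping) != len(sets):
        raise UsageError("grouping must label every population")
    uniq = sorted(set(grouping))
    if len(uniq) < 2:
        raise UsageError("need at least two groups")
    for g in uniq:
        if sum(1 for x in grouping if x == g) < 2:
            raise UsageError(f"group {g!r} needs at least two populations")
    if reps < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p-value")

    comparisons = [(g, g) for g in uniq] + list(combinations(uniq, 2))
    observed = {
        c: _mean_group_jaccard(sets, grouping, *c, min_overlap) for c in comparisons
    }

    rng = np.random.default_rng(seed)
    pooled = [s for ps in sets for s in ps.sweeps]
    counts = [len(ps.sweeps) for ps in sets]
    exceed = {c: 0 for c in comparisons}
    deficit = {c: 0 for c in comparisons}
    for _ in range(reps):
        order = rng.permutation(len(pooled))
        null_sets = []
        k = 0
        for ps, c in zip(sets, counts):
            null_sets.append(
                PopulationSweepSet(
                    population_id=ps.population_id,
                    group=ps.group,
                    sweeps=[pooled[t] for t in order[k : k + c]],
                )
            )
            k += c
        for c in comparisons:
            val = _mean_group_jaccard(null_sets, grouping, *c, min_overlap)
            if val >= observed[c]:
                exceed[c] += 1
            if val <= observed[c]:
                deficit[c] += 1
    return pd.DataFrame(
        {
            "group_a": [c[0] for c in comparisons],
            "group_b": [c[1] for c in comparisons],
            "observed_j": [observed[c] for c in comparisons],
            # one-sided: excess sharing (null >= observed)
            "p_value": [(1 + exceed[c]) / (1 + reps) for c in comparisons],
            # one-sided: sharing deficit (null <= observed)
            "p_value_deficit": [(1 + deficit[c]) / (1 + reps) for c in comparisons],
        }
    )


def jaccard_matrix(
    sets: Sequence[PopulationSweepSet], min_overlap: int = 1
) -> pd.DataFrame:
    """Pairwise Jaccard matrix over populations (NaN when both sets empty)."""
    ids = [s.population_id for s in sets]
    out = pd.DataFrame(np.eye(len(sets)), index=ids, columns=ids)
    for (i, a), (j, b) in combinations(enumerate(sets), 2):
        try:
            v = jaccard(a, b, min_overlap)
        except UsageError:
            v = np.nan
        out.iat[i, j] = out.iat[j, i] = v
    return out
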