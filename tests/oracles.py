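"""Independent reference implementations used only by the tests.

Each oracle recomputes a quantity by the most direct route available —
explicit loops, exhaustive enumeration, exact rational arithmetic —
sharing no code path with the package implementation it checks.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def running_sum_es(scores, is_hit, p):
    """Direct loop over the weighted KS walk.

    ``scores`` ordered best-first, ``is_hit`` booleans of the same
    length.  Returns (ES, 1-based rank at the first max deviation, walk).
    """
    n = len(scores)
    n_h = sum(is_hit)
    hit_weight_total = sum(abs(s) ** p for s, h in zip(scores, is_hit) if h)
    walk = []
    run = 0.0
    for s, h in zip(scores, is_hit):
        if h:
            if hit_weight_total == 0:
                run += 1.0 / n_h
            else:
                run += abs(s) ** p / hit_weight_total
        else:
            run -= 1.0 / (n - n_h)
        walk.append(run)
    best = 0
    for i in range(1, n):
        if abs(walk[i]) > abs(walk[best]):
            best = i
    return walk[best], best + 1, walk


def hypergeom_upper_tail(n_univ, big_k, n_draw, k):
    """Exact P[X >= k] by rational-arithmetic summation of the pmf."""
    total = Fraction(0)
    denom = math.comb(n_univ, n_draw)
    for i in range(k, min(big_k, n_draw) + 1):
        if n_draw - i > n_univ - big_k:
            continue
        total += Fraction(
            math.comb(big_k, i) * math.comb(n_univ - big_k, n_draw - i),
            denom,
        )
    return float(min(total, Fraction(1)))


def hypergeom_by_enumeration(n_univ, big_k, n_draw, k):
    """P[X >= k] by enumerating every possible draw of size n_draw."""
    universe = list(range(n_univ))
    special = set(range(big_k))
    hits = 0
    total = 0
    for draw in itertools.combinations(universe, n_draw):
        total += 1
        if len(special.intersection(draw)) >= k:
            hits += 1
    return hits / total


def bh_stepup(pvalues):
    """Textbook Benjamini–Hochberg step-up with cumulative minimum."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = pvalues[i] * m / rank_from_end
        running_min = min(running_min, val)
        q[i] = min(running_min, 1.0)
    return q


# ---------------------------------------------------------------------------
# naive mapping + collapsing
# ---------------------------------------------------------------------------

def naive_resolve(sid, table, id_type):
    """Re-derived resolution logic: official symbols beat synonyms."""
    if id_type == "entrez":
        try:
            gid = int(sid)
        except ValueError:
            return []
        return [r for r in table.genes_by_id.values() if r.gene_id == gid]
    if id_type == "gene_symbol":
        official = [r for r in table.genes_by_id.values()
                    if r.official_symbol.lower() == sid.lower()]
        if official:
            return official
        return sorted(
            (r for r in table.genes_by_id.values()
             if any(s.lower() == sid.lower() for s in r.synonyms)),
            key=lambda r: r.gene_id,
        )
    return list(table.records.get(sid, []))


def naive_collapse_choice(rows, first_contrast, strategy):
    """Pick one row index per the strategy, by explicit comparison."""
    def p_of(i):
        v = first_contrast.values["P"][i]
        return math.inf if math.isnan(v) else v

    def abs_s_of(i):
        s = first_contrast.values.get("S")
        if s is None or math.isnan(s[i]):
            return 0.0
        return abs(s[i])

    def a_of(i):
        v = first_contrast.values["A"][i]
        return -math.inf if math.isnan(v) else v

    best = rows[0]
    for i in rows[1:]:
        if strategy == "best_p":
            if (p_of(i), -abs_s_of(i), i) < (p_of(best), -abs_s_of(best), best):
                best = i
        elif strategy == "max_abs_s":
            s = first_contrast.values["S"]
            cur = 0.0 if math.isnan(s[i]) else abs(s[i])
            ref = 0.0 if math.isnan(s[best]) else abs(s[best])
            if cur > ref:
                best = i
        elif strategy == "max_a":
            if a_of(i) > a_of(best):
                best = i
    return best


def naive_map_collapse(dataset, table, strategy):
    """Group-by-then-argmin/argmax reference for map_and_collapse.

    Returns {gene_id: representative input row index}.
    """
    groups = {}
    for i, sid in enumerate(dataset.source_ids):
        for rec in naive_resolve(sid, table, dataset.header.source_id_type):
            groups.setdefault(rec.gene_id, []).append(i)
    return {
        gid: naive_collapse_choice(rows, dataset.contrasts[0], strategy)
        for gid, rows in groups.items()
    }
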