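"""Functional enrichment analysis: GSEA-preranked and ORA.

Two complementary tests are provided.

**GSEA preranked.**  Given a genome-wide ranked list of N genes with
scores r_1 >= ... >= r_N (e.g. moderated-t statistics) and a gene set
with N_H members in the list, a weighted Kolmogorov–Smirnov-like running
statistic walks down the list: meeting a member ("hit") increments the
running sum by |r_j|^p / sum_hits |r_j|^p, meeting a non-member
decrements it by 1/(N - N_H).  The enrichment score ES is the signed
maximum deviation of the walk from zero; the weight exponent p defaults
to 1 (the standard weighted scheme; p = 0 recovers the classic KS
statistic).  Significance comes from a gene-label permutation null:
scores are randomly reassigned to genes, ES is recomputed per set, and

* NES  = ES / mean(|null ES| of the matching sign),
* nominal p = upper-tail frequency of the matching-sign null
  ((r + 1) / (n + 1) convention, never exactly zero),
* FDR q = for each set, the fraction of pooled same-sign null NES at
  least as extreme divided by the fraction of observed same-sign NES at
  least as extreme, clipped to [0, 1].

The *leading edge* of a set is the members at ranks up to (positive ES)
or from (negative ES) the rank where |ES| is attained — the genes that
drive the enrichment.

**ORA.**  Over-representation of a gene set within a differentially
expressed gene (DEG) list drawn from a universe of N genes is tested
with the hypergeometric upper tail P[X >= k], where K = |set ∩ universe|,
n = |DEG| and k = |set ∩ DEG|.  P-values are Benjamini–Hochberg adjusted
across the collection.  The default universe is all genes of the
originating contrast after collapsing; the union of the collection's
genes is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    EmptyDegListError,
    EmptyIntersectionError,
    EmptyUniverseError,
    MissingColumnError,
    NoSetsPassSizeFilterError,
    SetEqualsUniverseError,
    ValueOutOfRangeError,
)
from .id_mapping import GeneDataset

RANK_METRICS = ("S", "M")
ORA_UNIVERSES = ("contrast", "collection")


# ---------------------------------------------------------------------------
# Ranked / DEG list creation
# ---------------------------------------------------------------------------

@dataclass
class RankedList:
    """Genes ordered by a rank metric, best score first.

    Ties are broken by ascending gene_id so that the order — to which the
    enrichment score is sensitive — is fully deterministic.
    """

    entries: list[tuple[int, float]]
    metric: str
    contrast_ref: str = ""

    @property
    def gene_ids(self) -> list[int]:
        return [g for g, _ in self.entries]

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, s in self.entries])

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class DegList:
    gene_ids: frozenset[int]
    p_threshold: float
    universe: frozenset[int]
    contrast_ref: str = ""

    def __post_init__(self):
        if not self.gene_ids <= self.universe:
            raise ValueError("DEG list must be a subset of its universe")


def create_ranked_list(gene_dataset: GeneDataset, contrast: str,
                       metric: str = "S") -> RankedList:
    """Build the full ranked list of a contrast (threshold-independent)."""
    if metric not in RANK_METRICS:
        raise MissingColumnError(f"rank metric must be one of {RANK_METRICS}")
    col = gene_dataset.contrast(contrast).values.get(metric)
    if col is None:
        raise MissingColumnError(
            f"contrast {contrast!r} has no {metric} column"
        )
    pairs = [
        (gid, float(v))
        for gid, v in zip(gene_dataset.gene_ids, col)
        if not np.isnan(v)
    ]
    pairs.sort(key=lambda t: (-t[1], t[0]))
    return RankedList(
        entries=pairs, metric=metric,
        contrast_ref=f"{gene_dataset.header.dataset_name}/{contrast}",
    )


def create_deg_list(gene_dataset: GeneDataset, contrast: str,
                    p_threshold: float = 0.05) -> DegList:
    """Genes of a contrast with P <= p_threshold; universe = all genes."""
    col = gene_dataset.contrast(contrast).values.get("P")
    if col is None:
        raise MissingColumnError(f"contrast {contrast!r} has no P column")
    universe = frozenset(gene_dataset.gene_ids)
    with np.errstate(invalid="ignore"):
        mask = ~np.isnan(col) & (col <= p_threshold)
    degs = frozenset(np.asarray(gene_dataset.gene_ids)[mask].tolist())
    if not degs:
        raise EmptyDegListError(
            f"no gene has P <= {p_threshold} in contrast {contrast!r}"
        )
    return DegList(
        gene_ids=degs, p_threshold=p_threshold, universe=universe,
        contrast_ref=f"{gene_dataset.header.dataset_name}/{contrast}",
    )


# ---------------------------------------------------------------------------
# Enrichment score
# ---------------------------------------------------------------------------

def enrichment_score(
    ranked: RankedList, gene_set: Iterable[int], p: float = 1.0
) -> tuple[float, int, np.ndarray]:
    """Weighted KS running statistic of one gene set on one ranked list.

    Returns ``(ES, rank_at_max, running_sum)`` where ``rank_at_max`` is
    the 1-based rank at which |ES| is first attained and ``running_sum``
    is the full N-vector of the walk.
    """
    if p < 0:
        raise ValueOutOfRangeError("weight exponent p must be >= 0")
    members = set(gene_set)
    gene_ids = ranked.gene_ids
    n = len(gene_ids)
    hit = np.fromiter((g in members for g in gene_ids), bool, count=n)
    n_h = int(hit.sum())
    if n_h == 0:
        raise EmptyIntersectionError(
            "gene set does not intersect the ranked list"
        )
    if n_h == n:
        raise SetEqualsUniverseError(
            "gene set covers the whole ranked list; ES is undefined"
        )
    scores = ranked.scores
    w = np.abs(scores[hit]) ** p
    total = w.sum()
    if total == 0:  # all hit scores are zero: fall back to equal weights
        w = np.ones(n_h)
        total = float(n_h)
    step = np.full(n, -1.0 / (n - n_h))
    step[hit] = w / total
    run = np.cumsum(step)
    i = int(np.argmax(np.abs(run)))  # first index attaining the max deviation
    return float(run[i]), i + 1, run


def _es_from_positions(pos: np.ndarray, abs_scores_p: np.ndarray,
                       n: int) -> np.ndarray:
    """Vectorized ES for many hit-position vectors of equal set size.

    ``pos`` is (m, k) of 0-based positions (rows need not be sorted);
    ``abs_scores_p`` is |r|^p for the full ranked list.  Exploits that the
    walk only rises at hits, so its extrema lie immediately after a hit
    (maximum candidates) or immediately before one (minimum candidates).
    """
    pos = np.sort(pos, axis=1)
    k = pos.shape[1]
    w = abs_scores_p[pos]
    total = w.sum(axis=1, keepdims=True)
    degenerate = total[:, 0] == 0
    if degenerate.any():
        w = np.where(degenerate[:, None], 1.0, w)
        total = np.where(degenerate[:, None], float(k), total)
    cw = np.cumsum(w / total, axis=1)
    miss = (pos - np.arange(k)) / (n - k)
    after = cw - miss               # value of the walk at each hit
    before = (cw - w / total) - miss  # value just before each hit
    max_after = after.max(axis=1)
    min_before = before.min(axis=1)
    return np.where(max_after >= -min_before, max_after, min_before)


# ---------------------------------------------------------------------------
# GSEA preranked
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GseaParams:
    weight_exponent: float = 1.0
    n_permutations: int = 1000
    seed: int = 0
    fdr_threshold: float = 0.05
    min_size: int = 10
    max_size: int = 500

    def __post_init__(self):
        if self.weight_exponent < 0:
            raise ValueOutOfRangeError("weight_exponent must be >= 0")
        if self.n_permutations < 10:
            raise ValueOutOfRangeError("n_permutations must be >= 10")


@dataclass
class GseaSetResult:
    set_name: str
    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    rank_at_max: int
    leading_edge: list[int]
    size: int  # members present in the ranked list


@dataclass
class GseaResult:
    """One GSEA-preranked run: per-set results plus provenance."""

    name: str
    ranked: RankedList
    params: GseaParams
    results: list[GseaSetResult]

    def by_name(self) -> dict[str, GseaSetResult]:
        return {r.set_name: r for r in self.results}


def _normalize_collection(
    collection: Mapping[str, Iterable[int]] | Iterable
) -> dict[str, list[int]]:
    """Accept {name: ids}, GeneSet objects, or (name, desc, ids) tuples."""
    if isinstance(collection, Mapping):
        return {name: list(ids) for name, ids in collection.items()}
    out: dict[str, list[int]] = {}
    for item in collection:
        if hasattr(item, "gene_ids") and hasattr(item, "name"):
            out[item.name] = list(item.gene_ids)
        else:
            name, _desc, ids = item
            out[name] = list(ids)
    return out


def gsea_preranked(
    ranked: RankedList,
    collection: Mapping[str, Iterable[int]] | Iterable,
    params: GseaParams = GseaParams(),
    name: str = "",
) -> GseaResult:
    """GSEA-preranked over a gene-set collection.

    The null distribution is generated by gene-label permutation: in each
    of ``params.n_permutations`` iterations, one random reassignment of
    genes to ranks is shared by all sets, and ES is recomputed.  Results
    are reproducible for a fixed ``params.seed``.  Sets whose overlap with
    the ranked list falls outside [min_size, max_size] are dropped; if
    none remains, :class:`NoSetsPassSizeFilterError` is raised.

    Sets with no matching-sign null ES get NaN NES/p/q (reported missing,
    never fabricated).
    """
    sets = _normalize_collection(collection)
    n = len(ranked)
    index = {g: i for i, g in enumerate(ranked.gene_ids)}
    filtered: dict[str, np.ndarray] = {}
    for set_name in sorted(sets):
        pos = np.array(sorted(index[g] for g in set(sets[set_name])
                              if g in index), dtype=int)
        if params.min_size <= pos.size <= params.max_size and pos.size < n:
            filtered[set_name] = pos
    if not filtered:
        raise NoSetsPassSizeFilterError(
            f"no gene set has between {params.min_size} and "
            f"{params.max_size} members in the ranked list"
        )

    scores = ranked.scores
    abs_p = np.abs(scores) ** params.weight_exponent

    # observed statistics via the full walk (also yields rank_at_max)
    observed: dict[str, tuple[float, int]] = {}
    for set_name, pos in filtered.items():
        members = [ranked.gene_ids[i] for i in pos]
        es, rank_at_max, _ = enrichment_score(
            ranked, members, params.weight_exponent
        )
        observed[set_name] = (es, rank_at_max)

    # gene-label permutation null, one shared permutation per iteration
    rng = np.random.default_rng(params.seed)
    n_perm = params.n_permutations
    rand = rng.random((n_perm, n))
    ranks_of_gene = rand.argsort(axis=1).argsort(axis=1)  # (perm, gene)->pos
    null_es: dict[str, np.ndarray] = {}
    for set_name, pos in filtered.items():
        null_es[set_name] = _es_from_positions(
            ranks_of_gene[:, pos], abs_p, n
        )

    # NES for observed and null
    obs_nes: dict[str, float] = {}
    null_nes_parts: list[np.ndarray] = []
    nominal_p: dict[str, float] = {}
    for set_name, (es, _) in observed.items():
        nulls = null_es[set_name]
        same = nulls > 0 if es >= 0 else nulls < 0
        n_same = int(same.sum())
        if n_same == 0:
            obs_nes[set_name] = np.nan
            nominal_p[set_name] = np.nan
            continue
        mean_abs = float(np.abs(nulls[same]).mean())
        obs_nes[set_name] = es / mean_abs
        null_nes_parts.append(nulls[same] / mean_abs)
        r = int((np.abs(nulls[same]) >= abs(es)).sum())
        nominal_p[set_name] = (r + 1) / (n_same + 1)

    pooled = (np.concatenate(null_nes_parts)
              if null_nes_parts else np.empty(0))
    pooled_pos = pooled[pooled > 0]
    pooled_neg = pooled[pooled < 0]
    obs_arr = np.array([obs_nes[s] for s in filtered], dtype=float)
    obs_pos = obs_arr[obs_arr > 0]
    obs_neg = obs_arr[obs_arr < 0]

    results: list[GseaSetResult] = []
    for set_name, pos in filtered.items():
        es, rank_at_max = observed[set_name]
        nes = obs_nes[set_name]
        if np.isnan(nes):
            q = np.nan
        else:
            if nes >= 0:
                num = float((pooled_pos >= nes).mean()) if pooled_pos.size else 0.0
                den = float((obs_pos >= nes).mean()) if obs_pos.size else 1.0
            else:
                num = float((pooled_neg <= nes).mean()) if pooled_neg.size else 0.0
                den = float((obs_neg <= nes).mean()) if obs_neg.size else 1.0
            q = min(1.0, num / den) if den > 0 else 0.0
        if es >= 0:
            le = [ranked.gene_ids[i] for i in pos if i < rank_at_max]
        else:
            le = [ranked.gene_ids[i] for i in pos if i >= rank_at_max - 1]
        results.append(GseaSetResult(
            set_name=set_name, es=es, nes=nes,
            nominal_p=nominal_p[set_name], fdr_q=q,
            rank_at_max=rank_at_max, leading_edge=le, size=pos.size,
        ))
    return GseaResult(name=name or ranked.contrast_ref, ranked=ranked,
                      params=params, results=results)


# ---------------------------------------------------------------------------
# ORA
# ---------------------------------------------------------------------------

@dataclass
class OraSetResult:
    set_name: str
    overlap: int
    p_value: float
    fdr: float


@dataclass
class OraResult:
    name: str
    universe_policy: str
    universe_size: int
    n_deg: int
    results: list[OraSetResult]

    def to_tsv(self) -> str:
        lines = [
            f"# universe={self.universe_policy} (N={self.universe_size}), "
            f"DEG n={self.n_deg}",
            "gene_set\toverlap\tp_value\tfdr",
        ]
        for r in self.results:
            lines.append(
                f"{r.set_name}\t{r.overlap}\t{r.p_value!r}\t{r.fdr!r}"
            )
        return "\n".join(lines) + "\n"


def ora_hypergeometric(
    deg: DegList,
    collection: Mapping[str, Iterable[int]] | Iterable,
    universe_policy: str = "contrast",
    name: str = "",
) -> OraResult:
    """Hypergeometric over-representation test of a DEG list.

    ``universe_policy`` is ``"contrast"`` (all genes of the originating
    contrast, the default) or ``"collection"`` (union of the collection's
    genes, intersected with the contrast universe).
    """
    if universe_policy not in ORA_UNIVERSES:
        raise ValueOutOfRangeError(
            f"universe_policy must be one of {ORA_UNIVERSES}"
        )
    sets = _normalize_collection(collection)
    if universe_policy == "contrast":
        universe = set(deg.universe)
    else:
        universe = set().union(*(set(v) for v in sets.values()))
        universe &= set(deg.universe)
    if not universe:
        raise EmptyUniverseError("ORA universe is empty")
    degs = deg.gene_ids & universe
    n_univ = len(universe)
    n_deg = len(degs)

    names = sorted(sets)
    ks = []
    ps = []
    for set_name in names:
        members = set(sets[set_name]) & universe
        k = len(members & degs)
        big_k = len(members)
        p = float(stats.hypergeom.sf(k - 1, n_univ, big_k, n_deg))
        ks.append(k)
        ps.append(min(1.0, p))
    fdrs = bh_adjust(ps) if ps else []
    results = [
        OraSetResult(set_name=nm, overlap=k, p_value=p, fdr=q)
        for nm, k, p, q in zip(names, ks, ps, fdrs)
    ]
    return OraResult(
        name=name or deg.contrast_ref, universe_policy=universe_policy,
        universe_size=n_univ, n_deg=n_deg, results=results,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueOutOfRangeError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
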