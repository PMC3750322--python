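# Methods

## Scope and data model

`contraset` operates on *contrast datasets*: per-gene (or per-probe)
summaries of differential comparisons, each contrast carrying up to four
statistic columns — M (estimated effect, e.g. log2 fold change; always
required), A (average signal), P (p-value or FDR, in [0, 1]) and S (a
test statistic such as a moderated t). One tab-delimited idMAPS file
holds all contrasts of one analysis as repeating column groups
(`ID M A P S M A P S …`); group order is free but must be identical for
every contrast, and columns with other names pass through untouched.

### idMAPS header dialect

The file-level metadata syntax is this package's own design (the format
it implements is described elsewhere only in terms of content, not
literal syntax): `#%key=value` lines precede the column header row,
with required keys `dataset_name`, `contrast_names` (comma-separated),
`source_id_type` (`probe_set` | `gene_symbol` | `entrez`) and
`organism`; optional `#%gene_set.<contrast>.<param>=` per-contrast
extraction overrides and `#%gene_set.skip=true` flags. The dialect is
greppable, survives tab-oriented tooling, and round-trips exactly
(floats are serialized with `repr`, missing values as `NA`; `NA` is
forbidden in M). ID-list files reuse the dialect with required keys
`gene_set_desc`, `id_type`, `organism` over a single ID column.

## ID mapping and collapsing

Source IDs resolve through a versioned mapping table. Resolution rules:

* `entrez` — direct gene-ID lookup;
* `gene_symbol` — case-insensitive; an official symbol always beats the
  same string occurring as another gene's synonym; synonym hits may
  resolve to several genes;
* `probe_set` — all mapped gene records are returned; a probe mapping
  to k genes contributes its row to each gene's group (fan-out) and is
  counted in the mapping report. When a single best gene is needed
  (external ID lists), RefSeq curation status decides
  (Reviewed > Validated > Provisional > Predicted > Model > Inferred >
  Unknown), ties broken by smallest gene ID.

Collapsing picks one representative row per gene: `best_p` (smallest P;
ties by largest |S|, then input order), `max_abs_s`, `max_a`, or `mean`
(per-column mean of M/A/S; group *minimum* for P — a deliberately
optimistic convention, stated here rather than silently applied). The
default is `best_p` when P exists, else `max_abs_s`, else `max_a`, else
`mean`. The representative is chosen **once per dataset from the first
contrast's values** and applied to all contrasts, keeping every contrast
on the same probe; per-contrast selection would mix probes within a gene
and break cross-contrast comparability. Missing values sort worst
(NaN P = +inf, NaN A = −inf, NaN |S| = 0). Output rows keep the genes'
first-appearance order, which makes collapsing idempotent on already
gene-centric data.

## Gene-set extraction

Candidates of a contrast are genes with P ≤ `p_threshold` (default
0.05), |M| ≥ `m_threshold` (default 0) and, if set, A ≥ `a_threshold`.
UP = candidates with M > 0, DN = M < 0, AR = UP ∪ DN; M = 0 genes join
nothing, so |AR| = |UP| + |DN| always holds before truncation. Within a
set, genes rank by ascending P, then descending |S|, then descending
|M|, then gene ID — fully deterministic, since both GMT export and the
enrichment score are order-sensitive. Size contracts: sets smaller than
`min_size` (default 10) are recorded but not emitted; sets larger than
`max_size` (default 500) keep their most significant genes;
`fixed_size`, if set, takes the top-k of UP and DN (and of AR)
*ignoring* `p_threshold` — it is an alternative to thresholding, not a
refinement of it. The size defaults follow common GSEA practice; only
the 0.05 significance default is anchored in prior use. Names follow
`<dataset>_[<contrast>]_<suffix>`.

## Store and reprocessing

A single-file SQLite database (an embedded store is proportionate for a
library; nothing in the contracts needs a server database) keeps raw
idMAPS text, contrasts, gene sets, and mapping/extraction reports, all
stamped with the mapping-table version. Reprocessing re-runs every
dataset from its stored raw source against a new table; the previous
gene-set generation is marked superseded, never deleted, so provenance
is auditable, and reprocessing with an identical table is byte-identical
(GMT export is sorted by set name). Deleting a dataset cascades to its
contrasts and sets. Overlap percentages default to
100·|A∩B|/min(|A|,|B|) — chosen over Jaccard because it makes subset
relations visible as 100% — with the union (Jaccard) denominator
available.

## Enrichment

* **Enrichment score.** Implemented twice on purpose: a full
  running-sum walk (public `enrichment_score`, also yielding the walk
  and the rank at max) and a closed-form over hit positions used inside
  the permutation loop; their agreement is tested to 1e-12. If all hit
  scores are zero, hit increments fall back to equal weights 1/N_H
  rather than dividing by zero. The rank at the maximum deviation is
  the *first* index attaining it; ties between a positive and negative
  extreme of equal magnitude resolve to the positive one.
* **Null distribution.** Gene-label permutation (the only option for
  preranked input), default 1000 permutations, one shared permutation
  per iteration across all sets, seeded via `numpy.random.default_rng`.
  Nominal p uses the (r + 1)/(n + 1) convention — never exactly zero at
  finite permutations. NES divides ES by the mean |null ES| of matching
  sign; sets with an empty matching-sign null get NaN NES/p/q and are
  reported missing, never fabricated. FDR q follows the standard
  positive/negative pooling (pooled null-NES tail over observed-NES
  tail, clipped to [0, 1]) without additional monotonisation.
* **ORA.** `scipy.stats.hypergeom.sf(k−1, N, K, n)` with BH adjustment
  (`statsmodels`) across the collection. The universe defaults to all
  genes of the originating contrast after collapsing — the natural
  "measured background"; a union-of-collection universe is available
  and the choice is recorded in the output header, since results depend
  on it.

## Results post-processing

The results matrix collates several GSEA runs with sets as rows
(alphabetical) and per-run NES/FDR/rank-at-max columns; absent
set/run combinations are explicit `NA`, never 0 (0 is a valid NES).
The leading-edge matrix pivots one run into genes × passing sets with
boolean, rank-metric-score, or 1-based-rank cells (0 marks non-members
in rank mode since real ranks start at 1; `NA` in statistic mode since
0 is a valid score).

## Synthetic data: what it emulates and what it does not

The generators emulate the *statistical shape* of microarray contrast
data: probes fan into genes (1–3 probes per gene by default), per-probe
standard errors follow a scaled chi-square (df = 8, scale 0.3), the
statistic S = M/SE is standard normal under the null and shifted by
`effect_size` SD units (default 3, a moderate planted effect) for
`n_significant` genes (default 30 of 1000) per contrast, and P is the
two-sided normal tail of S after per-contrast BH adjustment — so the P
column is a genuine FDR and downstream threshold semantics are
meaningful. Ranked-list fixtures shift planted set members' scores by
+2 SD (the canonical power condition; 0 gives the null-calibration
condition). The generators do **not** emulate correlated genes,
batch effects, heavy-tailed error distributions, annotation errors, or
realistic pathway topology; passing tests therefore demonstrate
correctness of the algorithms and calibration under independence, not
performance on real arrays. Problem sizes in the acceptance run (1000
genes, 200 null sets at 500 permutations, 20 power replicates at 1000
permutations) were chosen as the smallest conditions at which the
calibration and power statements are statistically meaningful.

## Numerical and degenerate-input choices

* Ranked-list ties break by ascending gene ID (ES is tie-order
  sensitive; documented, deterministic).
* Genes with NaN rank metric are excluded from ranked lists.
* A set equal to the whole ranked list, or disjoint from it, is an
  error (ES undefined), as are empty DEG lists and empty universes.
* All float parsing accepts plain and scientific notation and rejects
  thousands separators; parse errors carry 1-based line numbers.
* Every stochastic path takes an explicit integer seed; identical
  inputs plus identical mapping version give byte-identical outputs.

## Known limitations

* No phenotype-permutation GSEA (needs sample-level data the store
  never holds) and no wrapping of external GSEA implementations.
* No vendor annotation downloading; mapping tables are supplied as
  text files (or generated synthetically).
* Whether multi-mapped probes should fan out or be dropped is a
  genuinely open design point; fan-out was chosen and is flagged in the
  mapping report (`n_multi_mapped`).
* GSEA FDR values at small permutation counts are granular; with the
  default 1000 permutations the smallest resolvable nominal p is about
  2×10⁻³ per sign.
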