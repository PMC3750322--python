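"""Cross-contrast results matrices and leading-edge matrices.

``extract_results_matrix`` collates several GSEA runs (one per contrast)
into a single spreadsheet with the gene sets as rows and, per contrast,
the selected columns among NES, FDR and rank-at-max; a set analyzed in
one contrast but not another gets an explicit missing marker, never a
zero.  ``extract_leading_edge_matrix`` pivots one GSEA run into a genes ×
significant-sets matrix whose cells are boolean membership, the gene's
rank-metric score, or its 1-based rank in the ranked list.

TSV output uses ``NA`` for missing values; ranks are 1-based; row order
is alphabetical for sets and rank order for genes.
"""

from __future__ import annotations

from typing import IO, Sequence

import numpy as np
import pandas as pd

from .errors import (
    NoResultsError,
    NoSetPassesThresholdError,
    UnknownColumnError,
)
from .enrichment import GseaResult

RESULT_COLUMNS = ("NES", "FDR", "rank")
LEADING_EDGE_MODES = ("boolean", "statistic", "rank")


def extract_results_matrix(
    results: Sequence[GseaResult],
    columns: Sequence[str] = RESULT_COLUMNS,
) -> pd.DataFrame:
    """Combine GSEA runs into one matrix (sets × contrast/column pairs).

    Returns a DataFrame with a two-level column index
    ``(analysis name, column)`` and alphabetically sorted set names as
    the row index; missing set/contrast combinations are NaN.
    """
    if not results:
        raise NoResultsError("no GSEA results to combine")
    for col in columns:
        if col not in RESULT_COLUMNS:
            raise UnknownColumnError(
                f"unknown column {col!r}; expected subset of {RESULT_COLUMNS}"
            )
    if not columns:
        raise UnknownColumnError("at least one column must be selected")
    all_sets = sorted({r.set_name for res in results for r in res.results})
    data: dict[tuple[str, str], list[float]] = {}
    getter = {"NES": lambda r: r.nes, "FDR": lambda r: r.fdr_q,
              "rank": lambda r: float(r.rank_at_max)}
    for res in results:
        by_name = res.by_name()
        for col in columns:
            data[(res.name, col)] = [
                getter[col](by_name[s]) if s in by_name else np.nan
                for s in all_sets
            ]
    df = pd.DataFrame(data, index=pd.Index(all_sets, name="gene_set"))
    df.columns = pd.MultiIndex.from_tuples(df.columns,
                                           names=["contrast", "column"])
    return df


def extract_leading_edge_matrix(
    result: GseaResult,
    fdr_threshold: float = 0.05,
    mode: str = "boolean",
) -> pd.DataFrame:
    """Leading-edge genes (rows) × sets passing the FDR filter (columns).

    ``mode``: ``boolean`` membership, ``statistic`` (the gene's rank-metric
    score), or ``rank`` (1-based rank in the ranked list; 0 = not in the
    leading edge).  Sets with missing (NaN) FDR never pass the filter.
    """
    if mode not in LEADING_EDGE_MODES:
        raise UnknownColumnError(
            f"unknown mode {mode!r}; expected one of {LEADING_EDGE_MODES}"
        )
    passing = [r for r in result.results
               if not np.isnan(r.fdr_q) and r.fdr_q <= fdr_threshold]
    if not passing:
        raise NoSetPassesThresholdError(
            f"no gene set has FDR <= {fdr_threshold}"
        )
    passing.sort(key=lambda r: r.set_name)
    genes = sorted({g for r in passing for g in r.leading_edge})
    rank_of = {g: i + 1 for i, g in enumerate(result.ranked.gene_ids)}
    score_of = dict(result.ranked.entries)
    # rows ordered by rank in the ranked list
    genes.sort(key=lambda g: rank_of[g])

    cols = {}
    for r in passing:
        le = set(r.leading_edge)
        if mode == "boolean":
            cols[r.set_name] = [g in le for g in genes]
        elif mode == "statistic":
            cols[r.set_name] = [score_of[g] if g in le else np.nan
                                for g in genes]
        else:
            cols[r.set_name] = [rank_of[g] if g in le else 0 for g in genes]
    df = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    return df


def write_tsv(df: pd.DataFrame, stream: IO[str] | str | None = None) -> str:
    """Serialize a matrix to TSV with ``NA`` as the missing-value token."""
    text = df.to_csv(sep="\t", na_rep="NA")
    if stream is not None:
        if isinstance(stream, str):
            with open(stream, "w") as fh:
                fh.write(text)
        else:
            stream.write(text)
    return text
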