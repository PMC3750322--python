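"""Mapping source IDs to a gene-centric ID space and collapsing probes.

Microarray and other omics platforms report statistics per *source ID*
(Affymetrix probe set, gene symbol, Entrez-style gene ID).  Gene-set
extraction and enrichment need exactly one row per gene, so datasets are
(1) *mapped* — every source ID resolved to gene records through a
versioned mapping table, with official symbols taking precedence over
synonyms and RefSeq curation status used to pick the best gene — and
(2) *collapsed* — the rows of each gene reduced to one representative
under a named strategy.

Collapsing strategies
---------------------
``best_p``     row with the smallest P (ties: largest |S|, then input order)
``max_abs_s``  row with the largest |S|
``max_a``      row with the largest A
``mean``       per-column arithmetic mean of M, A and S; group minimum for P

The representative row of a gene is chosen once per dataset, from the
first contrast's values, and applied to every contrast; this keeps all
contrasts of a dataset on the same probe and hence cross-comparable.
A probe mapping to k genes contributes its row to each gene's group
(fan-out) before collapsing.

Mapping tables are tab-delimited text with a ``#%version=`` header and
columns ``source_id  gene_id  official_symbol  refseq_status  synonyms``
(synonyms ``|``-separated).  Symbol matching is case-insensitive with
case-preserving output.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import IO, Iterable

import numpy as np

from .errors import (
    EmptyAfterMappingError,
    EmptyRecordListError,
    MappingTableError,
    StrategyRequiresColumnError,
    UnknownIdTypeError,
)
from .idmaps_io import ContrastColumns, ContrastDataset, IdMapsHeader

#: RefSeq curation statuses, best first.
REFSEQ_STATUS_ORDER = (
    "Reviewed", "Validated", "Provisional", "Predicted", "Model",
    "Inferred", "Unknown",
)
_STATUS_RANK = {s: i for i, s in enumerate(REFSEQ_STATUS_ORDER)}

ID_TYPES = ("probe_set", "gene_symbol", "entrez")
COLLAPSE_STRATEGIES = ("best_p", "max_abs_s", "max_a", "mean")


@dataclass(frozen=True)
class GeneRecord:
    gene_id: int
    official_symbol: str
    refseq_status: str = "Unknown"
    synonyms: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.refseq_status not in _STATUS_RANK:
            raise MappingTableError(
                f"unknown RefSeq status {self.refseq_status!r} "
                f"(expected one of {REFSEQ_STATUS_ORDER})"
            )
        if self.gene_id <= 0:
            raise MappingTableError(f"gene_id must be positive: {self.gene_id}")

    @property
    def status_rank(self) -> int:
        return _STATUS_RANK[self.refseq_status]


class MappingTable:
    """Versioned source-ID → gene mapping with symbol and synonym indexes."""

    def __init__(self, version_tag: str,
                 records: dict[str, list[GeneRecord]]):
        if not version_tag:
            raise MappingTableError("version_tag must be non-empty")
        self.version_tag = version_tag
        self.records = records
        self.genes_by_id: dict[int, GeneRecord] = {}
        self.symbol_index: dict[str, GeneRecord] = {}
        self.synonym_index: dict[str, list[GeneRecord]] = {}
        for recs in records.values():
            for rec in recs:
                prev = self.genes_by_id.get(rec.gene_id)
                if prev is not None and prev != rec:
                    raise MappingTableError(
                        f"conflicting records for gene_id {rec.gene_id}"
                    )
                self.genes_by_id[rec.gene_id] = rec
        for rec in self.genes_by_id.values():
            key = rec.official_symbol.lower()
            other = self.symbol_index.get(key)
            if other is not None and other.gene_id != rec.gene_id:
                raise MappingTableError(
                    f"official symbol {rec.official_symbol!r} claimed by two genes"
                )
            self.symbol_index[key] = rec
        for rec in sorted(self.genes_by_id.values(), key=lambda r: r.gene_id):
            for syn in rec.synonyms:
                self.synonym_index.setdefault(syn.lower(), []).append(rec)

    def __eq__(self, other) -> bool:
        return (isinstance(other, MappingTable)
                and self.version_tag == other.version_tag
                and self.records == other.records)


def load_mapping_table(source: str | IO[str]) -> MappingTable:
    """Load a mapping table from tab-delimited text (see module docstring)."""
    text = source if isinstance(source, str) else source.read()
    version = ""
    records: dict[str, list[GeneRecord]] = {}
    for line_no, raw in enumerate(text.splitlines(), start=1):
        if raw.startswith("#%"):
            key, _, value = raw[2:].partition("=")
            if key.strip() == "version":
                version = value.strip()
            continue
        if not raw.strip():
            continue
        cells = raw.split("\t")
        if cells[0] == "source_id":  # optional column header row
            continue
        if len(cells) < 4:
            raise MappingTableError(
                f"line {line_no}: expected >= 4 tab-separated fields"
            )
        source_id, gene_id_s, symbol, status = (c.strip() for c in cells[:4])
        synonyms = frozenset(
            s.strip() for s in (cells[4] if len(cells) > 4 else "").split("|")
            if s.strip()
        )
        try:
            gene_id = int(gene_id_s)
        except ValueError:
            raise MappingTableError(
                f"line {line_no}: bad gene_id {gene_id_s!r}"
            ) from None
        rec = GeneRecord(gene_id=gene_id, official_symbol=symbol,
                         refseq_status=status or "Unknown", synonyms=synonyms)
        records.setdefault(source_id, []).append(rec)
    if not version:
        raise MappingTableError("mapping table lacks a #%version= header")
    return MappingTable(version_tag=version, records=records)


def write_mapping_table(table: MappingTable) -> str:
    out = io.StringIO()
    out.write(f"#%version={table.version_tag}\n")
    out.write("source_id\tgene_id\tofficial_symbol\trefseq_status\tsynonyms\n")
    for source_id in table.records:
        for rec in table.records[source_id]:
            out.write(
                f"{source_id}\t{rec.gene_id}\t{rec.official_symbol}\t"
                f"{rec.refseq_status}\t{'|'.join(sorted(rec.synonyms))}\n"
            )
    return out.getvalue()


# ---------------------------------------------------------------------------
# Resolution and best-gene selection
# ---------------------------------------------------------------------------

def _resolve(id_: str, table: MappingTable, id_type: str
             ) -> tuple[list[GeneRecord], bool]:
    """Resolve one source ID; returns (records, resolved_via_synonym)."""
    if id_type == "entrez":
        try:
            gid = int(id_)
        except ValueError:
            return [], False
        rec = table.genes_by_id.get(gid)
        return ([rec] if rec is not None else []), False
    if id_type == "gene_symbol":
        key = id_.lower()
        rec = table.symbol_index.get(key)
        if rec is not None:
            return [rec], False
        syn = table.synonym_index.get(key, [])
        return list(syn), bool(syn)
    if id_type == "probe_set":
        return list(table.records.get(id_, [])), False
    raise UnknownIdTypeError(
        f"unknown id_type {id_type!r}; expected one of {ID_TYPES}"
    )


def resolve_source_id(id_: str, table: MappingTable,
                      id_type: str) -> list[GeneRecord]:
    """Map one source ID to its gene records.

    For ``gene_symbol``, an official symbol always wins over the same
    string used as another gene's synonym.  An empty list means unmapped.
    """
    return _resolve(id_, table, id_type)[0]


def select_best_gene(records: list[GeneRecord]) -> GeneRecord:
    """Pick the best-curated record (RefSeq status, ties by smallest gene_id)."""
    if not records:
        raise EmptyRecordListError("cannot select from an empty record list")
    return min(records, key=lambda r: (r.status_rank, r.gene_id))


# ---------------------------------------------------------------------------
# Collapsing
# ---------------------------------------------------------------------------

@dataclass
class MappingReport:
    n_input_rows: int
    n_unmapped: int
    n_multi_mapped: int
    n_synonym_resolved: int
    n_collapsed_groups: int
    n_output_genes: int
    unmapped_ids: list[str]
    strategy: str
    mapping_version: str

    def __post_init__(self):
        # without multi-mapped fan-out, genes cannot outnumber mapped rows
        if self.n_multi_mapped == 0:
            assert self.n_output_genes + self.n_unmapped <= self.n_input_rows
        assert self.n_unmapped == len(self.unmapped_ids)


@dataclass
class GeneDataset:
    """A mapped, collapsed dataset: exactly one row per gene."""

    header: IdMapsHeader
    gene_ids: list[int]
    symbols: list[str]
    contrasts: list[ContrastColumns]
    mapping_version: str

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def contrast(self, name: str) -> ContrastColumns:
        for c in self.contrasts:
            if c.contrast_name == name:
                return c
        raise KeyError(name)

    def __eq__(self, other) -> bool:
        return (isinstance(other, GeneDataset)
                and self.gene_ids == other.gene_ids
                and self.symbols == other.symbols
                and self.mapping_version == other.mapping_version
                and self.contrasts == other.contrasts)


def default_strategy(dataset: ContrastDataset) -> str:
    """best_p when P exists, else max_abs_s, else max_a, else mean."""
    letters = set(dataset.contrasts[0].column_order)
    if "P" in letters:
        return "best_p"
    if "S" in letters:
        return "max_abs_s"
    if "A" in letters:
        return "max_a"
    return "mean"


def _representative(rows: list[int], first: ContrastColumns,
                    strategy: str) -> int:
    """Index (into the dataset rows) of the representative row of one group."""
    if strategy == "best_p":
        p = first.values["P"]
        s = first.values.get("S")

        def key(i: int):
            pv = p[i]
            sv = abs(s[i]) if s is not None and not math.isnan(s[i]) else 0.0
            return (math.inf if math.isnan(pv) else pv, -sv, i)
        return min(rows, key=key)
    if strategy == "max_abs_s":
        s = first.values["S"]
        return min(rows, key=lambda i: (-(0.0 if math.isnan(s[i]) else abs(s[i])), i))
    if strategy == "max_a":
        a = first.values["A"]
        return min(rows, key=lambda i: (math.inf if math.isnan(a[i]) else -a[i], i))
    raise AssertionError(strategy)


def map_and_collapse(
    dataset: ContrastDataset,
    table: MappingTable,
    strategy: str | None = None,
) -> tuple[GeneDataset, MappingReport]:
    """Map every row to genes and collapse to one row per gene.

    Returns the gene-centric dataset (rows ordered by first appearance of
    each gene in the input, for deterministic, idempotent output) and a
    :class:`MappingReport` summarizing the procedure.
    """
    dataset.validate()
    if strategy is None:
        strategy = default_strategy(dataset)
    if strategy not in COLLAPSE_STRATEGIES:
        raise ValueError(
            f"unknown strategy {strategy!r}; expected one of {COLLAPSE_STRATEGIES}"
        )
    letters = set(dataset.contrasts[0].column_order)
    needs = {"best_p": "P", "max_abs_s": "S", "max_a": "A"}.get(strategy)
    if needs is not None and needs not in letters:
        raise StrategyRequiresColumnError(
            f"strategy {strategy!r} requires column {needs!r}, "
            f"but the dataset has only {sorted(letters)}"
        )

    id_type = dataset.header.source_id_type
    groups: dict[int, list[int]] = {}
    symbols: dict[int, str] = {}
    unmapped: list[str] = []
    n_multi = 0
    n_syn = 0
    for i, sid in enumerate(dataset.source_ids):
        recs, via_syn = _resolve(sid, table, id_type)
        if not recs:
            unmapped.append(sid)
            continue
        if len(recs) > 1:
            n_multi += 1
        if via_syn:
            n_syn += 1
        for rec in recs:
            groups.setdefault(rec.gene_id, []).append(i)
            symbols[rec.gene_id] = rec.official_symbol
    if not groups:
        raise EmptyAfterMappingError(
            f"no source IDs of type {id_type!r} could be mapped "
            f"(mapping version {table.version_tag})"
        )

    # stable gene order: first appearance in the input
    gene_order = sorted(groups, key=lambda g: groups[g][0])
    first = dataset.contrasts[0]

    out_contrasts: list[ContrastColumns] = []
    if strategy == "mean":
        for c in dataset.contrasts:
            values: dict[str, np.ndarray] = {}
            for letter in c.column_order:
                col = c.values[letter]
                vec = np.empty(len(gene_order))
                for gi, gid in enumerate(gene_order):
                    grp = col[groups[gid]]
                    if letter == "P":
                        vec[gi] = np.nanmin(grp) if not np.isnan(grp).all() else np.nan
                    else:
                        with np.errstate(invalid="ignore"):
                            vec[gi] = (np.nanmean(grp)
                                       if not np.isnan(grp).all() else np.nan)
                values[letter] = vec
            extras = {
                name: [c.extras[name][groups[gid][0]] for gid in gene_order]
                for name in c.extras
            }
            out_contrasts.append(ContrastColumns(
                contrast_name=c.contrast_name, values=values,
                column_order=list(c.column_order), extras=extras,
            ))
    else:
        rep = {gid: _representative(groups[gid], first, strategy)
               for gid in gene_order}
        rep_rows = np.array([rep[gid] for gid in gene_order], dtype=int)
        for c in dataset.contrasts:
            values = {letter: c.values[letter][rep_rows]
                      for letter in c.column_order}
            extras = {name: [c.extras[name][r] for r in rep_rows]
                      for name in c.extras}
            out_contrasts.append(ContrastColumns(
                contrast_name=c.contrast_name, values=values,
                column_order=list(c.column_order), extras=extras,
            ))

    report = MappingReport(
        n_input_rows=dataset.n_rows,
        n_unmapped=len(unmapped),
        n_multi_mapped=n_multi,
        n_synonym_resolved=n_syn,
        n_collapsed_groups=sum(1 for g in groups.values() if len(g) > 1),
        n_output_genes=len(gene_order),
        unmapped_ids=unmapped,
        strategy=strategy,
        mapping_version=table.version_tag,
    )
    gene_dataset = GeneDataset(
        header=dataset.header,
        gene_ids=list(gene_order),
        symbols=[symbols[g] for g in gene_order],
        contrasts=out_contrasts,
        mapping_version=table.version_tag,
    )
    return gene_dataset, report
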