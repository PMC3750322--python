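"""Extraction of UP / DN / AR gene sets from collapsed contrast data.

For each contrast, genes passing the configured thresholds (significance
P, effect magnitude |M|, optionally average signal A) are split by the
sign of M into up-regulated (UP) and down-regulated (DN) sets; the
all-regulated (AR) set is their union and represents the global
transcriptional response of the contrast.  Genes with M == 0 belong to
no set.  Within a set, genes are ordered by significance: ascending P,
then descending |S|, then descending |M|, then gene_id — a fully
deterministic ranking.

Sets smaller than ``min_size`` are not emitted (but recorded in the
extraction report); sets larger than ``max_size`` are truncated to their
top ``max_size`` genes.  Alternatively a ``fixed_size`` takes the top-k
genes of UP and DN regardless of the significance threshold.

Set names follow ``<dataset>_[<contrast>]_<suffix>``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import (
    EmptyAfterMappingError,
    NoStatisticColumnError,
    UnknownContrastError,
)
from .id_mapping import GeneDataset, MappingTable, select_best_gene, _resolve
from .idmaps_io import IdList, IdMapsHeader

SUFFIXES = ("UP", "DN", "AR")


@dataclass(frozen=True)
class ExtractionParams:
    """Thresholds and size limits governing gene-set extraction.

    p_threshold   keep genes with P <= p_threshold (default 0.05)
    m_threshold   keep genes with |M| >= m_threshold (default 0 = off)
    a_threshold   keep genes with A >= a_threshold (default None = off)
    min_size      smallest set emitted (default 10)
    max_size      largest set emitted; larger sets truncated (default 500)
    fixed_size    take exactly the top-k of UP and DN, ignoring p_threshold
    skip          extract nothing for this contrast
    """

    p_threshold: float = 0.05
    m_threshold: float = 0.0
    a_threshold: Optional[float] = None
    min_size: int = 10
    max_size: int = 500
    fixed_size: Optional[int] = None
    skip: bool = False

    def __post_init__(self):
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must be in (0, 1]")
        if self.m_threshold < 0:
            raise ValueError("m_threshold must be non-negative")
        if self.min_size < 1 or self.max_size < 1:
            raise ValueError("size limits must be positive")
        if self.min_size > self.max_size:
            raise ValueError("min_size must be <= max_size")
        if self.fixed_size is not None and not (
            self.min_size <= self.fixed_size <= self.max_size
        ):
            raise ValueError("fixed_size must lie within [min_size, max_size]")


def params_for_contrast(header: IdMapsHeader, base: ExtractionParams,
                        contrast: str) -> ExtractionParams:
    """Apply a dataset header's per-contrast overrides and skip flags."""
    overrides = dict(header.extraction_overrides.get(contrast, {}))
    if header.skip_all or contrast in header.skip_gene_sets:
        overrides["skip"] = True
    return replace(base, **overrides) if overrides else base


@dataclass
class GeneSet:
    name: str
    suffix: Optional[str]  # UP / DN / AR; None for external sets
    #: ordered (rank, gene_id, symbol), rank starting at 1
    members: list[tuple[int, int, str]]
    description: str = ""
    contrast_ref: str = ""
    params_used: Optional[ExtractionParams] = None
    annotation_version: str = ""
    organism: str = ""

    @property
    def gene_ids(self) -> list[int]:
        return [gid for _, gid, _ in self.members]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ExtractionReport:
    """Per-contrast summary of what was (not) emitted and why."""

    contrast: str
    skipped: bool = False
    candidate_counts: dict[str, int] = field(default_factory=dict)
    emitted: dict[str, int] = field(default_factory=dict)
    below_min_size: list[str] = field(default_factory=list)
    truncated: list[str] = field(default_factory=list)

    def to_tsv(self) -> str:
        lines = ["suffix\tcandidates\temitted_size\tnote"]
        for sfx in SUFFIXES:
            note = ("skipped" if self.skipped else
                    "below_min_size" if sfx in self.below_min_size else
                    "truncated" if sfx in self.truncated else "")
            lines.append(
                f"{sfx}\t{self.candidate_counts.get(sfx, 0)}\t"
                f"{self.emitted.get(sfx, 0)}\t{note}"
            )
        return "\n".join(lines) + "\n"


def gene_set_name(dataset_name: str, contrast: str, suffix: str) -> str:
    return f"{dataset_name}_[{contrast}]_{suffix}"


def _significance_order(idx: np.ndarray, p, s, m, gene_ids) -> list[int]:
    """Sort candidate indices by (P asc, |S| desc, |M| desc, gene_id asc)."""
    def key(i: int):
        pv = math.inf if p is None or math.isnan(p[i]) else p[i]
        sv = 0.0 if s is None or math.isnan(s[i]) else abs(s[i])
        return (pv, -sv, -abs(m[i]), gene_ids[i])
    return sorted((int(i) for i in idx), key=key)


def extract_gene_sets(
    gene_dataset: GeneDataset,
    contrast_name: str,
    params: ExtractionParams = ExtractionParams(),
) -> tuple[list[GeneSet], ExtractionReport]:
    """Extract the UP, DN and AR gene sets of one contrast.

    Returns the emitted sets (possibly fewer than three) together with an
    :class:`ExtractionReport`.  With ``params.skip`` no sets are emitted.
    """
    try:
        contrast = gene_dataset.contrast(contrast_name)
    except KeyError:
        raise UnknownContrastError(
            f"contrast {contrast_name!r} not in dataset "
            f"{gene_dataset.header.dataset_name!r}"
        ) from None
    report = ExtractionReport(contrast=contrast_name)
    if params.skip:
        report.skipped = True
        return [], report

    m = contrast.values["M"]
    p = contrast.values.get("P")
    s = contrast.values.get("S")
    a = contrast.values.get("A")
    use_p_filter = params.fixed_size is None
    if use_p_filter and p is None:
        raise NoStatisticColumnError(
            f"contrast {contrast_name!r} has no P column; set fixed_size "
            "to extract by rank instead"
        )
    if params.a_threshold is not None and a is None:
        raise NoStatisticColumnError(
            f"contrast {contrast_name!r} has no A column for a_threshold"
        )

    keep = np.abs(m) >= params.m_threshold
    keep &= m != 0
    if use_p_filter:
        with np.errstate(invalid="ignore"):
            keep &= ~np.isnan(p) & (p <= params.p_threshold)
    if params.a_threshold is not None:
        with np.errstate(invalid="ignore"):
            keep &= ~np.isnan(a) & (a >= params.a_threshold)

    gene_ids = gene_dataset.gene_ids
    symbols = gene_dataset.symbols
    up_idx = _significance_order(np.flatnonzero(keep & (m > 0)), p, s, m, gene_ids)
    dn_idx = _significance_order(np.flatnonzero(keep & (m < 0)), p, s, m, gene_ids)
    limit = params.fixed_size if params.fixed_size is not None else params.max_size
    pre_sizes = {"UP": len(up_idx), "DN": len(dn_idx)}
    up_idx = up_idx[:limit]
    dn_idx = dn_idx[:limit]
    ar_idx = _significance_order(np.array(up_idx + dn_idx, dtype=int),
                                 p, s, m, gene_ids)
    pre_sizes["AR"] = len(ar_idx)
    ar_idx = ar_idx[:limit]

    report.candidate_counts = {
        "UP": len(up_idx), "DN": len(dn_idx), "AR": len(ar_idx)
    }

    dataset_name = gene_dataset.header.dataset_name
    sets: list[GeneSet] = []
    for sfx, idx in (("UP", up_idx), ("DN", dn_idx), ("AR", ar_idx)):
        if pre_sizes[sfx] > len(idx):
            report.truncated.append(sfx)
        if len(idx) < params.min_size:
            if idx:
                report.below_min_size.append(sfx)
            continue
        members = [(rank, gene_ids[i], symbols[i])
                   for rank, i in enumerate(idx, start=1)]
        sets.append(GeneSet(
            name=gene_set_name(dataset_name, contrast_name, sfx),
            suffix=sfx,
            members=members,
            description=(f"{sfx} genes of contrast {contrast_name} "
                         f"({dataset_name})"),
            contrast_ref=f"{dataset_name}/{contrast_name}",
            params_used=params,
            annotation_version=gene_dataset.mapping_version,
            organism=gene_dataset.header.organism,
        ))
        report.emitted[sfx] = len(members)
    return sets, report


@dataclass
class IdListMappingReport:
    n_input: int
    n_mapped: int
    unmapped_ids: list[str]


def idlist_to_gene_set(
    idlist: IdList, table: MappingTable, name: str | None = None
) -> tuple[GeneSet, IdListMappingReport]:
    """Map an external ID list into a gene set.

    Each ID is resolved through the mapping table (official symbols before
    synonyms); multi-mapped IDs contribute their best-curated gene.  The
    resulting external set carries no UP/DN/AR suffix.
    """
    seen: set[int] = set()
    members: list[tuple[int, int, str]] = []
    unmapped: list[str] = []
    for id_ in idlist.ids:
        recs, _ = _resolve(id_, table, idlist.id_type)
        if not recs:
            unmapped.append(id_)
            continue
        best = select_best_gene(recs)
        if best.gene_id in seen:
            continue
        seen.add(best.gene_id)
        members.append((len(members) + 1, best.gene_id, best.official_symbol))
    if not members:
        raise EmptyAfterMappingError(
            f"no IDs of the list could be mapped (type {idlist.id_type!r})"
        )
    report = IdListMappingReport(
        n_input=len(idlist.ids), n_mapped=len(members), unmapped_ids=unmapped
    )
    gs = GeneSet(
        name=name or idlist.name or idlist.gene_set_desc.replace(" ", "_"),
        suffix=None,
        members=members,
        description=idlist.gene_set_desc,
        annotation_version=table.version_tag,
        organism=idlist.organism,
    )
    return gs, report
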