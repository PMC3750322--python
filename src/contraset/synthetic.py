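"""Seed-deterministic synthetic data generators.

Every stage of the pipeline is testable without downloading platform
annotation or expression data: these generators emit mapping tables,
idMAPS contrast datasets with planted differential signal, and ranked
lists with planted enriched gene sets.

The contrast generator draws, for every probe, a standard-normal effect
z; planted significant genes receive an additive shift (``effect_size``,
in SD units of the statistic).  A per-probe standard error is simulated
from a scaled chi-square, the reported effect is M = z·SE, the statistic
S = M/SE = z, the significance P is the two-sided normal tail of S
followed by Benjamini–Hochberg adjustment per contrast (so P behaves
like a real FDR column), and A ~ Normal(8, 2) mimics log-scale average
signal.  All outputs pass their module's validators by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .enrichment import RankedList, bh_adjust
from .geneset_extract import GeneSet
from .id_mapping import (
    REFSEQ_STATUS_ORDER,
    GeneRecord,
    MappingTable,
)
from .idmaps_io import (
    ContrastColumns,
    ContrastDataset,
    IdMapsHeader,
    write_idmaps,
)


@dataclass
class FixtureSpec:
    """Conditions for the synthetic generators.

    ``probes_per_gene`` is an inclusive (low, high) range sampled
    uniformly per gene; ``n_significant`` genes per contrast receive an
    M/S shift of ``effect_size`` SD units, with sign per
    ``significant_direction`` (up / down / both).  ``planted_sets`` lists
    (size, shift) pairs for the ranked-list generator.
    """

    seed: int
    n_genes: int = 1000
    probes_per_gene: tuple[int, int] = (1, 3)
    n_contrasts: int = 3
    n_significant: int = 30
    effect_size: float = 3.0
    significant_direction: str = "both"
    planted_sets: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self):
        if self.n_genes <= 0 or self.n_contrasts <= 0:
            raise ValueError("counts must be positive")
        if self.probes_per_gene[0] < 1:
            raise ValueError("probes_per_gene must be >= 1")
        if self.significant_direction not in ("up", "down", "both"):
            raise ValueError("significant_direction must be up/down/both")


def make_mapping_table(
    spec: FixtureSpec,
    synonym_collisions: int = 0,
    unmapped_fraction: float = 0.0,
) -> MappingTable:
    """Generate a probe → gene mapping table.

    ``synonym_collisions`` genes additionally carry another gene's
    official symbol as a synonym (exercising official-over-synonym
    precedence); probes for an ``unmapped_fraction`` of extra source IDs
    are deliberately left out of the table (they stay unmapped).
    """
    rng = np.random.default_rng(spec.seed)
    records: dict[str, list[GeneRecord]] = {}
    statuses = rng.choice(len(REFSEQ_STATUS_ORDER), size=spec.n_genes)
    genes = []
    for i in range(spec.n_genes):
        gid = i + 1
        synonyms = {f"SYN{gid}A", f"SYN{gid}B"}
        genes.append(dict(
            gene_id=gid,
            official_symbol=f"GENE{gid}",
            refseq_status=REFSEQ_STATUS_ORDER[statuses[i]],
            synonyms=synonyms,
        ))
    for c in range(min(synonym_collisions, spec.n_genes - 1)):
        # gene c+2 claims gene c+1's official symbol as a synonym
        genes[c + 1]["synonyms"] = set(genes[c + 1]["synonyms"]) | {
            genes[c]["official_symbol"]
        }
    lo, hi = spec.probes_per_gene
    n_probes = rng.integers(lo, hi + 1, size=spec.n_genes)
    for g, k in zip(genes, n_probes):
        rec = GeneRecord(
            gene_id=g["gene_id"], official_symbol=g["official_symbol"],
            refseq_status=g["refseq_status"],
            synonyms=frozenset(g["synonyms"]),
        )
        for j in range(int(k)):
            records.setdefault(f"P{g['gene_id']}_{j}_at", []).append(rec)
    return MappingTable(
        version_tag=f"synthetic-build-seed{spec.seed}", records=records
    )


def make_contrast_dataset(
    spec: FixtureSpec,
    table: MappingTable,
    dataset_name: str = "SYNTH",
) -> str:
    """Generate a valid idMAPS file (as text) over the table's probes."""
    rng = np.random.default_rng(spec.seed + 1)
    probes = sorted(table.records)
    n = len(probes)
    gene_of = np.array(
        [table.records[pid][0].gene_id for pid in probes]
    )
    contrast_names = [f"C{i + 1}" for i in range(spec.n_contrasts)]
    header = IdMapsHeader(
        dataset_name=dataset_name,
        dataset_description="synthetic contrast dataset with planted signal",
        contrast_names=contrast_names,
        source_id_type="probe_set",
        organism="synthetic",
    )
    all_genes = np.unique(gene_of)
    contrasts = []
    for c, cname in enumerate(contrast_names):
        n_sig = min(spec.n_significant, all_genes.size)
        sig_genes = rng.choice(all_genes, size=n_sig, replace=False)
        if spec.significant_direction == "up":
            signs = np.ones(n_sig)
        elif spec.significant_direction == "down":
            signs = -np.ones(n_sig)
        else:
            signs = rng.choice([-1.0, 1.0], size=n_sig)
        shift_of = dict(zip(sig_genes.tolist(), (signs * spec.effect_size)))
        z = rng.standard_normal(n)
        z += np.array([shift_of.get(int(g), 0.0) for g in gene_of])
        se = 0.3 * np.sqrt(rng.chisquare(8, size=n) / 8)
        m = z * se
        s = z  # = M / SE
        p_raw = 2 * stats.norm.sf(np.abs(s))
        p = np.asarray(bh_adjust(p_raw))
        a = rng.normal(8, 2, size=n)
        contrasts.append(ContrastColumns(
            contrast_name=cname,
            values={"M": m, "A": a, "P": p, "S": s},
            column_order=["M", "A", "P", "S"],
        ))
    dataset = ContrastDataset(
        header=header, source_ids=list(probes), contrasts=contrasts
    )
    return write_idmaps(dataset)


def make_ranked_fixture(
    seed: int,
    n_genes: int = 1000,
    n_null_sets: int = 20,
    set_size: int = 25,
    planted_sets: int = 0,
    shift: float = 2.0,
) -> tuple[RankedList, dict[str, list[int]], list[str]]:
    """Ranked list with optional planted enriched sets.

    Scores are standard normal; each planted set's members get ``shift``
    added to their scores before ranking (+2 SD is the canonical power
    condition, 0 the null-calibration condition).  Returns the ranked
    list, the whole collection {name: member gene_ids}, and the names of
    the planted sets.
    """
    rng = np.random.default_rng(seed)
    gene_ids = np.arange(1, n_genes + 1)
    scores = rng.standard_normal(n_genes)
    collection: dict[str, list[int]] = {}
    planted_names: list[str] = []
    for i in range(planted_sets):
        members = rng.choice(n_genes, size=set_size, replace=False)
        scores[members] += shift
        name = f"PLANTED_{i + 1}"
        collection[name] = gene_ids[members].tolist()
        planted_names.append(name)
    for i in range(n_null_sets):
        members = rng.choice(n_genes, size=set_size, replace=False)
        collection[f"NULL_{i + 1}"] = gene_ids[members].tolist()
    entries = sorted(zip(gene_ids.tolist(), scores.tolist()),
                     key=lambda t: (-t[1], t[0]))
    ranked = RankedList(entries=entries, metric="S",
                        contrast_ref=f"synthetic/seed{seed}")
    return ranked, collection, planted_names
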