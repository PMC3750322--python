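"""Shared fixtures: tiny hand-written inputs and random-object builders."""

from __future__ import annotations

import numpy as np
import pytest

from contraset import (
    ContrastColumns,
    ContrastDataset,
    FixtureSpec,
    GeneRecord,
    IdMapsHeader,
    MappingTable,
    make_contrast_dataset,
    make_mapping_table,
    parse_idmaps,
)

IDMAPS_3C = """\
#%dataset_name=DEMO
#%dataset_description=three contrasts, full MAPS
#%contrast_names=Early,Late,Interaction
#%source_id_type=probe_set
#%organism=human
ID\tM\tA\tP\tS\tM\tA\tP\tS\tM\tA\tP\tS
p1\t1.2\t8.0\t0.01\t3.5\t0.5\t8.1\t0.2\t1.1\t-0.7\t7.9\t0.04\t-2.5
p2\t-0.8\t6.5\t0.03\t-2.9\t-1.5\t6.4\t0.01\t-4.0\t0.2\t6.6\t0.8\t0.4
p3\t0.1\t9.2\t0.9\t0.2\t2.1\t9.0\t0.001\t5.5\t1.0\t9.1\t0.02\t2.8
"""


@pytest.fixture
def demo_dataset() -> ContrastDataset:
    return parse_idmaps(IDMAPS_3C)


@pytest.fixture
def small_table() -> MappingTable:
    """Three probes → two genes, plus a symbol/synonym collision.

    ``TP53`` is official for gene 1 and a synonym of gene 2; probe
    ``p_multi`` maps to genes 1 and 2 with different RefSeq statuses.
    """
    g1 = GeneRecord(gene_id=1, official_symbol="TP53",
                    refseq_status="Reviewed",
                    synonyms=frozenset({"P53", "TRP53"}))
    g2 = GeneRecord(gene_id=2, official_symbol="BRCA1",
                    refseq_status="Provisional",
                    synonyms=frozenset({"TP53", "RNF53"}))
    g3 = GeneRecord(gene_id=3, official_symbol="EGFR",
                    refseq_status="Validated",
                    synonyms=frozenset({"ERBB1"}))
    return MappingTable(
        version_tag="test-build-1",
        records={
            "p1": [g1], "p2": [g2], "p3": [g3],
            "p_multi": [g2, g1],
        },
    )


@pytest.fixture
def synth_gene_dataset():
    """A mapped, collapsed synthetic dataset with planted signal."""
    from contraset import map_and_collapse

    spec = FixtureSpec(seed=11, n_genes=200, n_contrasts=2,
                       n_significant=30, effect_size=6.0,
                       significant_direction="both")
    table = make_mapping_table(spec)
    dataset = parse_idmaps(make_contrast_dataset(spec, table))
    gene_dataset, _ = map_and_collapse(dataset, table)
    return gene_dataset


# ---------------------------------------------------------------------------
# random-object builders (used by round-trip and oracle-equivalence tests)
# ---------------------------------------------------------------------------

LETTER_ORDERS = (
    ["M"], ["M", "P"], ["M", "A", "P", "S"], ["A", "P", "S", "M"],
    ["S", "A", "P", "M"], ["M", "S"], ["P", "M", "A"],
)


def random_dataset(rng: np.random.Generator, *, with_extras=True,
                   source_ids=None, id_type="probe_set") -> ContrastDataset:
    """A random valid ContrastDataset with random column layout."""
    n_contrasts = int(rng.integers(1, 4))
    n_rows = len(source_ids) if source_ids else int(rng.integers(2, 30))
    order = list(LETTER_ORDERS[rng.integers(0, len(LETTER_ORDERS))])
    if source_ids is None:
        source_ids = [f"probe{i}_{rng.integers(0, 1 << 20)}"
                      for i in range(n_rows)]
    contrasts = []
    for c in range(n_contrasts):
        values = {}
        for letter in order:
            if letter == "M":
                vec = np.round(rng.normal(0, 2, n_rows), 6)
            elif letter == "P":
                vec = np.round(rng.uniform(0, 1, n_rows), 6)
                vec[rng.random(n_rows) < 0.1] = np.nan
            elif letter == "A":
                vec = np.round(rng.normal(8, 2, n_rows), 6)
                vec[rng.random(n_rows) < 0.1] = np.nan
            else:
                vec = np.round(rng.normal(0, 3, n_rows), 6)
                vec[rng.random(n_rows) < 0.1] = np.nan
            values[letter] = vec
        extras = {}
        if with_extras and rng.random() < 0.5:
            extras["note"] = [f"x{rng.integers(0, 99)}" for _ in range(n_rows)]
        contrasts.append(ContrastColumns(
            contrast_name=f"c{c + 1}", values=values,
            column_order=list(order), extras=extras,
        ))
    header = IdMapsHeader(
        dataset_name=f"RAND{rng.integers(0, 1 << 20)}",
        contrast_names=[f"c{i + 1}" for i in range(n_contrasts)],
        source_id_type=id_type,
        organism="synthetic",
    )
    return ContrastDataset(header=header, source_ids=list(source_ids),
                           contrasts=contrasts)


def random_table_and_dataset(rng: np.random.Generator):
    """Random mapping table + dataset pair for collapsing-oracle tests.

    Probes repeat across rows, some probes multi-map, some rows are
    unmapped, so every branch of the collapsing algorithm is exercised.
    """
    n_genes = int(rng.integers(2, 10))
    statuses = ("Reviewed", "Validated", "Provisional", "Predicted",
                "Model", "Inferred", "Unknown")
    genes = [
        GeneRecord(
            gene_id=g + 1, official_symbol=f"G{g + 1}",
            refseq_status=statuses[rng.integers(0, len(statuses))],
        )
        for g in range(n_genes)
    ]
    records: dict[str, list[GeneRecord]] = {}
    n_probes = int(rng.integers(2, 15))
    for p in range(n_probes):
        k = 2 if rng.random() < 0.2 and n_genes >= 2 else 1
        chosen = rng.choice(n_genes, size=k, replace=False)
        records[f"pr{p}"] = [genes[int(i)] for i in chosen]
    table = MappingTable(version_tag="rand", records=records)
    pool = list(records) + [f"unmapped{i}" for i in range(3)]
    n_rows = int(rng.integers(2, 50))
    source_ids = [pool[int(i)] for i in rng.integers(0, len(pool), n_rows)]
    dataset = random_dataset(rng, with_extras=False, source_ids=source_ids)
    # collapsing-oracle tests need the full MAPS complement
    if set(dataset.contrasts[0].column_order) != {"M", "A", "P", "S"}:
        dataset = random_dataset(
            rng, with_extras=False, source_ids=source_ids
        )
        for c in dataset.contrasts:
            n = len(source_ids)
            c.values = {
                "M": np.round(rng.normal(0, 2, n), 6),
                "A": np.round(rng.normal(8, 2, n), 6),
                "P": np.round(rng.uniform(0, 1, n), 6),
                "S": np.round(rng.normal(0, 3, n), 6),
            }
            c.column_order = ["M", "A", "P", "S"]
    return table, dataset
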