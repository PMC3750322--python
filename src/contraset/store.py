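"""Embedded, versioned knowledge base of contrast datasets and gene sets.

A single-file SQLite database holds, for every submitted dataset, the
raw idMAPS source text, the derived contrasts and gene sets, and the
mapping/extraction reports — all stamped with the annotation (mapping
table) version used to produce them.  Keeping the raw source makes the
whole store reprocessable: when a new annotation build arrives,
:meth:`Store.reprocess_all` re-runs every dataset from its stored source
with the new table; old gene sets are marked superseded, never deleted,
so provenance chains stay auditable.

Export surfaces: standard GMT (one set per line,
``name<TAB>description<TAB>gene...``), boolean gene × set membership
matrices, and pairwise set-overlap matrices (shared-gene counts, or
percentages with a min-size — subset-detecting — or union/Jaccard
denominator).
"""

from __future__ import annotations

import datetime as _dt
import fnmatch
import json
import sqlite3
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional

import numpy as np
import pandas as pd

from .errors import (
    DuplicateDatasetNameError,
    DuplicateGeneSetNameError,
    EmptySelectionError,
    MissingSourceDataError,
)
from .geneset_extract import (
    ExtractionParams,
    GeneSet,
    extract_gene_sets,
    idlist_to_gene_set,
    params_for_contrast,
)
from .id_mapping import MappingTable, map_and_collapse
from .idmaps_io import IdList, parse_idmaps

_SCHEMA = """
CREATE TABLE IF NOT EXISTS datasets (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE,
    description TEXT,
    organism TEXT,
    source_id_type TEXT,
    raw_idmaps TEXT NOT NULL,
    strategy TEXT,
    params_json TEXT,
    annotation_version TEXT NOT NULL,
    created_at TEXT NOT NULL,
    metadata_json TEXT
);
CREATE TABLE IF NOT EXISTS contrasts (
    id INTEGER PRIMARY KEY,
    dataset_id INTEGER NOT NULL REFERENCES datasets(id) ON DELETE CASCADE,
    name TEXT NOT NULL,
    UNIQUE (dataset_id, name)
);
CREATE TABLE IF NOT EXISTS id_lists (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE,
    description TEXT,
    id_type TEXT,
    organism TEXT,
    raw_text TEXT NOT NULL,
    created_at TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS gene_sets (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL,
    suffix TEXT,
    description TEXT,
    organism TEXT,
    contrast_id INTEGER REFERENCES contrasts(id) ON DELETE CASCADE,
    id_list_id INTEGER REFERENCES id_lists(id) ON DELETE CASCADE,
    members_json TEXT NOT NULL,
    annotation_version TEXT NOT NULL,
    created_at TEXT NOT NULL,
    superseded INTEGER NOT NULL DEFAULT 0,
    metadata_json TEXT,
    CHECK (contrast_id IS NOT NULL OR id_list_id IS NOT NULL)
);
CREATE TABLE IF NOT EXISTS reports (
    id INTEGER PRIMARY KEY,
    dataset_id INTEGER REFERENCES datasets(id) ON DELETE CASCADE,
    kind TEXT NOT NULL,
    payload_json TEXT NOT NULL,
    created_at TEXT NOT NULL
);
"""


@dataclass
class Selection:
    """Filter over stored gene sets; all criteria are conjunctive.

    ``metadata`` matches against the reserved keys organism / tissue /
    stimulus plus any free-text keys stored at submission.
    """

    organism: Optional[str] = None
    name_glob: Optional[str] = None
    metadata: dict[str, str] = field(default_factory=dict)
    include_superseded: bool = False


@dataclass
class SubmissionRecord:
    dataset_name: str
    n_contrasts: int
    gene_set_names: list[str]
    annotation_version: str
    mapping_report: dict
    extraction_reports: dict[str, dict]


class Store:
    """Gene-set knowledge base backed by a single SQLite file."""

    def __init__(self, path: str = ":memory:"):
        self.path = path
        self._db = sqlite3.connect(path)
        self._db.execute("PRAGMA foreign_keys = ON")
        self._db.executescript(_SCHEMA)
        self._db.commit()

    def close(self) -> None:
        self._db.close()

    # -- submission ---------------------------------------------------------

    def submit_dataset(
        self,
        idmaps_text: str,
        table: MappingTable,
        strategy: str | None = None,
        params: ExtractionParams = ExtractionParams(),
        metadata: dict[str, str] | None = None,
    ) -> SubmissionRecord:
        """Parse, map/collapse, extract gene sets, and persist everything."""
        dataset = parse_idmaps(idmaps_text)
        name = dataset.header.dataset_name
        cur = self._db.execute(
            "SELECT 1 FROM datasets WHERE name = ?", (name,)
        )
        if cur.fetchone() is not None:
            raise DuplicateDatasetNameError(
                f"dataset {name!r} already exists in the store"
            )
        gene_dataset, mapping_report = map_and_collapse(
            dataset, table, strategy
        )
        now = _dt.datetime.now(_dt.timezone.utc).isoformat()
        cur = self._db.execute(
            "INSERT INTO datasets (name, description, organism,"
            " source_id_type, raw_idmaps, strategy, params_json,"
            " annotation_version, created_at, metadata_json)"
            " VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?, ?)",
            (
                name, dataset.header.dataset_description,
                dataset.header.organism, dataset.header.source_id_type,
                idmaps_text, mapping_report.strategy,
                json.dumps(vars(params) if params else {}),
                table.version_tag, now, json.dumps(metadata or {}),
            ),
        )
        dataset_id = cur.lastrowid
        self._db.execute(
            "INSERT INTO reports (dataset_id, kind, payload_json, created_at)"
            " VALUES (?, 'mapping', ?, ?)",
            (dataset_id, json.dumps(vars(mapping_report)), now),
        )
        gene_set_names: list[str] = []
        extraction_reports: dict[str, dict] = {}
        for cname in dataset.header.contrast_names:
            cur = self._db.execute(
                "INSERT INTO contrasts (dataset_id, name) VALUES (?, ?)",
                (dataset_id, cname),
            )
            contrast_id = cur.lastrowid
            cparams = params_for_contrast(dataset.header, params, cname)
            sets, report = extract_gene_sets(gene_dataset, cname, cparams)
            extraction_reports[cname] = {
                "skipped": report.skipped,
                "candidate_counts": report.candidate_counts,
                "emitted": report.emitted,
                "below_min_size": report.below_min_size,
                "truncated": report.truncated,
            }
            for gs in sets:
                self._insert_gene_set(gs, contrast_id=contrast_id,
                                      created_at=now, metadata=metadata)
                gene_set_names.append(gs.name)
            self._db.execute(
                "INSERT INTO reports (dataset_id, kind, payload_json,"
                " created_at) VALUES (?, 'extraction', ?, ?)",
                (dataset_id, json.dumps(extraction_reports[cname]), now),
            )
        self._db.commit()
        return SubmissionRecord(
            dataset_name=name,
            n_contrasts=len(dataset.header.contrast_names),
            gene_set_names=gene_set_names,
            annotation_version=table.version_tag,
            mapping_report=vars(mapping_report),
            extraction_reports=extraction_reports,
        )

    def _insert_gene_set(self, gs: GeneSet, *, contrast_id=None,
                         id_list_id=None, created_at: str,
                         metadata=None) -> None:
        cur = self._db.execute(
            "SELECT 1 FROM gene_sets WHERE name = ? AND superseded = 0",
            (gs.name,),
        )
        if cur.fetchone() is not None:
            raise DuplicateGeneSetNameError(
                f"gene set {gs.name!r} already exists"
            )
        self._db.execute(
            "INSERT INTO gene_sets (name, suffix, description, organism,"
            " contrast_id, id_list_id, members_json, annotation_version,"
            " created_at, metadata_json)"
            " VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?, ?)",
            (
                gs.name, gs.suffix, gs.description,
                gs.organism, contrast_id, id_list_id,
                json.dumps(gs.members), gs.annotation_version,
                created_at, json.dumps(metadata or {}),
            ),
        )

    def submit_gene_set(
        self, idlist: IdList, table: MappingTable,
        name: str | None = None, metadata: dict[str, str] | None = None,
    ) -> GeneSet:
        """Map an external ID list and store it as a suffix-free gene set."""
        gs, _report = idlist_to_gene_set(idlist, table, name=name)
        now = _dt.datetime.now(_dt.timezone.utc).isoformat()
        from .idmaps_io import write_idlist
        cur = self._db.execute(
            "INSERT INTO id_lists (name, description, id_type, organism,"
            " raw_text, created_at) VALUES (?, ?, ?, ?, ?, ?)",
            (gs.name, idlist.gene_set_desc, idlist.id_type,
             idlist.organism, write_idlist(idlist), now),
        )
        self._insert_gene_set(gs, id_list_id=cur.lastrowid,
                              created_at=now, metadata=metadata)
        self._db.commit()
        return gs

    # -- selection & export --------------------------------------------------

    def select_gene_sets(self, selection: Selection = Selection()
                         ) -> list[GeneSet]:
        sql = ("SELECT name, suffix, description, organism, members_json,"
               " annotation_version, metadata_json FROM gene_sets")
        clauses, args = [], []
        if not selection.include_superseded:
            clauses.append("superseded = 0")
        if selection.organism is not None:
            clauses.append("organism = ?")
            args.append(selection.organism)
        if clauses:
            sql += " WHERE " + " AND ".join(clauses)
        sql += " ORDER BY name"
        out: list[GeneSet] = []
        for (name, suffix, desc, organism, members_json, version,
             meta_json) in self._db.execute(sql, args):
            if selection.name_glob and not fnmatch.fnmatch(
                    name, selection.name_glob):
                continue
            meta = json.loads(meta_json or "{}")
            if any(meta.get(k) != v for k, v in selection.metadata.items()):
                continue
            out.append(GeneSet(
                name=name, suffix=suffix,
                members=[tuple(m) for m in json.loads(members_json)],
                description=desc or "", organism=organism or "",
                annotation_version=version,
            ))
        return out

    def export_gmt(self, selection: Selection = Selection()) -> str:
        """Export selected gene sets as standard GMT text."""
        sets = self.select_gene_sets(selection)
        if not sets:
            raise EmptySelectionError("selection matches no gene sets")
        lines = []
        for gs in sets:
            genes = "\t".join(str(g) for g in gs.gene_ids)
            lines.append(f"{gs.name}\t{gs.description}\t{genes}")
        return "\n".join(lines) + "\n"

    def membership_matrix(self, selection: Selection = Selection()
                          ) -> pd.DataFrame:
        """Boolean genes × gene-sets membership matrix."""
        sets = self.select_gene_sets(selection)
        if not sets:
            raise EmptySelectionError("selection matches no gene sets")
        genes = sorted({g for gs in sets for g in gs.gene_ids})
        data = {gs.name: [g in set(gs.gene_ids) for g in genes]
                for gs in sets}
        return pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))

    def overlap_matrix(self, selection: Selection = Selection(),
                       mode: str = "count",
                       denominator: str = "min") -> pd.DataFrame:
        """Pairwise shared-gene counts or percentages between gene sets.

        ``percent`` uses 100·|A∩B| / min(|A|,|B|) by default (detects
        subset relations); ``denominator="union"`` gives the Jaccard
        percentage instead.
        """
        if mode not in ("count", "percent"):
            raise ValueError("mode must be 'count' or 'percent'")
        if denominator not in ("min", "union"):
            raise ValueError("denominator must be 'min' or 'union'")
        sets = self.select_gene_sets(selection)
        if not sets:
            raise EmptySelectionError("selection matches no gene sets")
        names = [gs.name for gs in sets]
        members = [set(gs.gene_ids) for gs in sets]
        k = len(sets)
        mat = np.zeros((k, k))
        for i in range(k):
            for j in range(k):
                inter = len(members[i] & members[j])
                if mode == "count":
                    mat[i, j] = inter
                else:
                    den = (min(len(members[i]), len(members[j]))
                           if denominator == "min"
                           else len(members[i] | members[j]))
                    mat[i, j] = 100.0 * inter / den if den else 0.0
        return pd.DataFrame(mat, index=names, columns=names)

    # -- maintenance ---------------------------------------------------------

    def list_datasets(self) -> list[str]:
        return [r[0] for r in self._db.execute(
            "SELECT name FROM datasets ORDER BY name")]

    def delete_dataset(self, name: str) -> None:
        """Remove a dataset and, by cascade, its contrasts and gene sets."""
        cur = self._db.execute("DELETE FROM datasets WHERE name = ?", (name,))
        if cur.rowcount == 0:
            raise MissingSourceDataError(f"no dataset named {name!r}")
        self._db.commit()

    def reprocess_all(
        self,
        new_table: MappingTable,
        strategy: str | None = None,
        params: ExtractionParams | None = None,
    ) -> dict:
        """Re-run every dataset from its stored raw idMAPS source.

        Contrast-derived gene sets are regenerated with ``new_table`` and
        re-tagged with its version; the previous generation is marked
        superseded (kept for provenance).  Stored strategy/params are
        reused unless overridden.  Returns a summary report.
        """
        rows = self._db.execute(
            "SELECT id, name, raw_idmaps, strategy, params_json"
            " FROM datasets ORDER BY name"
        ).fetchall()
        report = {"n_datasets": len(rows), "datasets": {},
                  "annotation_version": new_table.version_tag}
        now = _dt.datetime.now(_dt.timezone.utc).isoformat()
        for dataset_id, name, raw, old_strategy, params_json in rows:
            if not raw:
                raise MissingSourceDataError(
                    f"dataset {name!r} has no stored source"
                )
            use_strategy = strategy or old_strategy
            if params is not None:
                use_params = params
            else:
                stored = json.loads(params_json or "{}")
                stored.pop("skip", None)
                use_params = (ExtractionParams(**stored) if stored
                              else ExtractionParams())
            dataset = parse_idmaps(raw)
            gene_dataset, mapping_report = map_and_collapse(
                dataset, new_table, use_strategy
            )
            # supersede the previous generation of this dataset's sets
            self._db.execute(
                "UPDATE gene_sets SET superseded = 1 WHERE contrast_id IN"
                " (SELECT id FROM contrasts WHERE dataset_id = ?)",
                (dataset_id,),
            )
            self._db.execute(
                "UPDATE datasets SET annotation_version = ? WHERE id = ?",
                (new_table.version_tag, dataset_id),
            )
            new_sets: list[str] = []
            for cname in dataset.header.contrast_names:
                contrast_id = self._db.execute(
                    "SELECT id FROM contrasts WHERE dataset_id = ?"
                    " AND name = ?", (dataset_id, cname),
                ).fetchone()[0]
                cparams = params_for_contrast(dataset.header, use_params,
                                              cname)
                sets, _ = extract_gene_sets(gene_dataset, cname, cparams)
                for gs in sets:
                    self._insert_gene_set(gs, contrast_id=contrast_id,
                                          created_at=now)
                    new_sets.append(gs.name)
            self._db.execute(
                "INSERT INTO reports (dataset_id, kind, payload_json,"
                " created_at) VALUES (?, 'reprocess', ?, ?)",
                (dataset_id, json.dumps(vars(mapping_report)), now),
            )
            report["datasets"][name] = {"gene_sets": new_sets}
        self._db.commit()
        return report


# ---------------------------------------------------------------------------
# GMT text helpers
# ---------------------------------------------------------------------------

def parse_gmt(source: str | IO[str]) -> list[tuple[str, str, list[str]]]:
    """Parse GMT text into (name, description, member) triples."""
    text = source if isinstance(source, str) else source.read()
    out = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip():
            continue
        cells = raw.split("\t")
        if len(cells) < 3:
            raise ValueError(
                f"GMT line {line_no}: expected name, description and at"
                " least one gene"
            )
        out.append((cells[0], cells[1], [c for c in cells[2:] if c]))
    return out


def write_gmt(sets: Iterable[tuple[str, str, Iterable]] | Iterable) -> str:
    """Write gene sets ((name, desc, members) or GeneSet objects) as GMT."""
    lines = []
    for item in sets:
        if isinstance(item, GeneSet):
            name, desc, members = item.name, item.description, item.gene_ids
        else:
            name, desc, members = item
        lines.append(
            f"{name}\t{desc}\t" + "\t".join(str(m) for m in members)
        )
    return "\n".join(lines) + "\n"
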