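"""Reading and writing idMAPS contrast-data files and ID-list files.

idMAPS is a tab-delimited text format for the per-gene (or per-probe)
summary statistics of one or more *contrasts* — differential comparisons
between experimental conditions.  Each contrast contributes a repeating
group of data columns drawn from the letters

    M  estimated effect of interest (e.g. log2 fold change)  — required
    A  average signal                                         — optional
    P  significance level (p-value or FDR), in [0, 1]         — optional
    S  statistic (e.g. moderated t)                           — optional

so a three-contrast file with all four columns has the column header row
``ID  M A P S  M A P S  M A P S``.  Columns within a group may be in any
order (APSM, SAPM, ...) as long as every contrast uses the same order.
Columns whose name is not one of the four letters are pass-through: they
are preserved verbatim and never influence downstream processing.

File-level metadata precedes the column header row as ``#%key=value``
lines:

    #%dataset_name=MyStudy
    #%dataset_description=free text
    #%contrast_names=Early,Late,Interaction
    #%source_id_type=probe_set
    #%organism=human
    #%gene_set.skip=true                      # no gene sets for the dataset
    #%gene_set.Late.skip=true                 # ... or for one contrast
    #%gene_set.Early.p_threshold=0.01         # per-contrast extraction override

ID-list files use the same ``#%`` dialect with the required keys
``gene_set_desc``, ``id_type`` and ``organism`` followed by a single
column of IDs (no column header row).

Missing values in A/P/S are written/read as ``NA`` (or an empty cell);
M must always be present.  Floats are written with ``repr`` so that a
write→parse round trip is exact.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable

import numpy as np

from .errors import (
    BadPValueError,
    BadValueError,
    DuplicateContrastNameError,
    EmptyListError,
    InconsistentGroupOrderError,
    InvalidDatasetError,
    MalformedHeaderError,
    MissingHeaderKeyError,
    MissingMError,
    RowLengthMismatchError,
)

logger = logging.getLogger(__name__)

STAT_LETTERS = ("M", "A", "P", "S")

#: extraction-override keys accepted in ``#%gene_set.<contrast>.<param>=``
_OVERRIDE_FLOAT = {"p_threshold", "m_threshold", "a_threshold"}
_OVERRIDE_INT = {"min_size", "max_size", "fixed_size"}
_OVERRIDE_BOOL = {"skip"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class IdMapsHeader:
    dataset_name: str
    contrast_names: list[str]
    source_id_type: str
    organism: str
    dataset_description: str = ""
    #: contrast name -> {param name -> parsed value}
    extraction_overrides: dict[str, dict] = field(default_factory=dict)
    #: contrasts for which no gene sets should be extracted
    skip_gene_sets: set[str] = field(default_factory=set)
    #: suppress gene-set extraction for the whole dataset
    skip_all: bool = False
    #: name of the ID column in the column header row
    id_column_name: str = "ID"
    #: unrecognised ``#%`` keys, preserved for round-tripping
    extra_metadata: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.dataset_name:
            raise InvalidDatasetError("dataset_name must be non-empty")
        if not self.contrast_names:
            raise InvalidDatasetError("contrast_names must be non-empty")
        if len(set(self.contrast_names)) != len(self.contrast_names):
            raise InvalidDatasetError("contrast_names must be unique")
        for key in self.extraction_overrides:
            if key not in self.contrast_names:
                raise InvalidDatasetError(
                    f"extraction override names undeclared contrast {key!r}"
                )
        for key in self.skip_gene_sets:
            if key not in self.contrast_names:
                raise InvalidDatasetError(
                    f"skip flag names undeclared contrast {key!r}"
                )


@dataclass
class ContrastColumns:
    """The statistic columns of one contrast.

    ``values`` maps each present letter to a float vector (NaN = missing,
    allowed in A/P/S only); ``column_order`` records the on-file order of
    the letters; ``extras`` holds pass-through columns as verbatim strings.
    """

    contrast_name: str
    values: dict[str, np.ndarray]
    column_order: list[str]
    extras: dict[str, list[str]] = field(default_factory=dict)

    @property
    def M(self) -> np.ndarray:
        return self.values["M"]

    def get(self, letter: str) -> np.ndarray | None:
        return self.values.get(letter)

    def __eq__(self, other) -> bool:  # array-aware equality
        if not isinstance(other, ContrastColumns):
            return NotImplemented
        if (self.contrast_name, self.column_order, self.extras) != (
            other.contrast_name, other.column_order, other.extras
        ):
            return False
        if set(self.values) != set(other.values):
            return False
        return all(
            np.array_equal(self.values[k], other.values[k], equal_nan=True)
            for k in self.values
        )


@dataclass
class ContrastDataset:
    header: IdMapsHeader
    source_ids: list[str]
    contrasts: list[ContrastColumns]

    @property
    def n_rows(self) -> int:
        return len(self.source_ids)

    def contrast(self, name: str) -> ContrastColumns:
        for c in self.contrasts:
            if c.contrast_name == name:
                return c
        raise KeyError(name)

    @property
    def duplicate_source_ids(self) -> list[str]:
        seen: set[str] = set()
        dups: list[str] = []
        for sid in self.source_ids:
            if sid in seen and sid not in dups:
                dups.append(sid)
            seen.add(sid)
        return dups

    def validate(self) -> None:
        self.header.validate()
        if not self.source_ids:
            raise InvalidDatasetError("dataset has no data rows")
        if any(not sid for sid in self.source_ids):
            raise InvalidDatasetError("empty source ID")
        if len(self.contrasts) != len(self.header.contrast_names):
            raise InvalidDatasetError(
                "number of contrast column groups does not match header"
            )
        orders = {tuple(c.column_order) for c in self.contrasts}
        if len(orders) > 1:
            raise InvalidDatasetError("contrasts have differing column orders")
        for c in self.contrasts:
            if "M" not in c.values:
                raise InvalidDatasetError(f"contrast {c.contrast_name!r} lacks M")
            for letter, vec in c.values.items():
                if len(vec) != self.n_rows:
                    raise InvalidDatasetError(
                        f"column {letter} of {c.contrast_name!r} has wrong length"
                    )
            if np.isnan(c.values["M"]).any():
                raise InvalidDatasetError(
                    f"contrast {c.contrast_name!r} has missing M values"
                )
            p = c.values.get("P")
            if p is not None:
                with np.errstate(invalid="ignore"):
                    bad = (p < 0) | (p > 1)
                if bad.any():
                    raise InvalidDatasetError(
                        f"contrast {c.contrast_name!r} has P outside [0, 1]"
                    )


@dataclass
class IdList:
    gene_set_desc: str
    id_type: str
    organism: str
    ids: list[str]
    #: number of duplicate entries dropped during parsing
    n_duplicates_dropped: int = 0
    name: str = ""


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _as_lines(source: str | IO[str]) -> list[str]:
    if isinstance(source, str):
        text = source
    else:
        text = source.read()
    return text.splitlines()


def _parse_float(token: str, *, line: int, column: str) -> float:
    token = token.strip()
    if token == "" or token.upper() == "NA":
        return math.nan
    if "," in token:
        raise BadValueError(
            f"thousands separators are not accepted in column {column}: {token!r}",
            line=line,
        )
    try:
        return float(token)
    except ValueError:
        raise BadValueError(
            f"cannot parse value {token!r} in column {column}", line=line
        ) from None


def _parse_header_lines(lines: list[str]) -> tuple[dict[str, str], int]:
    """Collect ``#%key=value`` pairs; return (pairs, index of first data line)."""
    pairs: dict[str, str] = {}
    i = 0
    for i, raw in enumerate(lines):
        if not raw.startswith("#%"):
            return pairs, i
        body = raw[2:]
        if "=" not in body:
            raise MalformedHeaderError(
                f"header line without '=': {raw!r}", line=i + 1
            )
        key, _, value = body.partition("=")
        key = key.strip()
        if not key:
            raise MalformedHeaderError("empty header key", line=i + 1)
        if key in pairs:
            raise MalformedHeaderError(f"duplicate header key {key!r}", line=i + 1)
        pairs[key] = value
    return pairs, len(lines)


def _parse_override_value(param: str, value: str, line_hint: int) -> object:
    if param in _OVERRIDE_BOOL:
        v = value.strip().lower()
        if v in ("true", "1", "yes"):
            return True
        if v in ("false", "0", "no"):
            return False
        raise MalformedHeaderError(f"bad boolean {value!r} for {param}", line=line_hint)
    if param in _OVERRIDE_INT:
        try:
            return int(value)
        except ValueError:
            raise MalformedHeaderError(
                f"bad integer {value!r} for {param}", line=line_hint
            ) from None
    if param in _OVERRIDE_FLOAT:
        try:
            return float(value)
        except ValueError:
            raise MalformedHeaderError(
                f"bad number {value!r} for {param}", line=line_hint
            ) from None
    raise MalformedHeaderError(f"unknown extraction parameter {param!r}", line=line_hint)


def _build_idmaps_header(pairs: dict[str, str]) -> IdMapsHeader:
    required = ("dataset_name", "contrast_names", "source_id_type", "organism")
    for key in required:
        if key not in pairs:
            raise MissingHeaderKeyError(f"missing required header key {key!r}")
    contrast_names = [c.strip() for c in pairs["contrast_names"].split(",") if c.strip()]
    if len(set(contrast_names)) != len(contrast_names):
        raise DuplicateContrastNameError(
            f"duplicate contrast name in header: {pairs['contrast_names']!r}"
        )
    header = IdMapsHeader(
        dataset_name=pairs["dataset_name"].strip(),
        dataset_description=pairs.get("dataset_description", "").strip(),
        contrast_names=contrast_names,
        source_id_type=pairs["source_id_type"].strip(),
        organism=pairs["organism"].strip(),
        id_column_name=pairs.get("id_column", "ID").strip() or "ID",
    )
    consumed = set(required) | {"dataset_description", "id_column"}
    for key, value in pairs.items():
        if key in consumed:
            continue
        if key == "gene_set.skip":
            header.skip_all = _parse_override_value("skip", value, 0)  # type: ignore[assignment]
            continue
        if key.startswith("gene_set."):
            parts = key.split(".")
            if len(parts) != 3:
                raise MalformedHeaderError(f"bad gene_set override key {key!r}")
            _, contrast, param = parts
            if contrast not in contrast_names:
                raise MalformedHeaderError(
                    f"override names undeclared contrast {contrast!r}"
                )
            parsed = _parse_override_value(param, value, 0)
            if param == "skip":
                if parsed:
                    header.skip_gene_sets.add(contrast)
            else:
                header.extraction_overrides.setdefault(contrast, {})[param] = parsed
            continue
        header.extra_metadata[key] = value
    return header


def _split_column_groups(
    columns: list[str], n_contrasts: int, line: int
) -> tuple[list[list[int]], list[str], dict[int, int]]:
    """Assign data columns (0-based within the data part) to contrast groups.

    Returns (stat column indices per group, per-group letter order,
    extra-column index -> group).
    """
    stat_idx = [i for i, c in enumerate(columns) if c in STAT_LETTERS]
    if not stat_idx:
        raise MissingMError("no M/A/P/S data columns found", line=line)
    if len(stat_idx) % n_contrasts != 0:
        raise InconsistentGroupOrderError(
            f"{len(stat_idx)} statistic columns cannot form {n_contrasts} "
            "equal contrast groups",
            line=line,
        )
    glen = len(stat_idx) // n_contrasts
    groups = [stat_idx[g * glen:(g + 1) * glen] for g in range(n_contrasts)]
    orders = [[columns[i] for i in grp] for grp in groups]
    for order in orders:
        if len(set(order)) != len(order):
            raise InconsistentGroupOrderError(
                f"letter repeated within one contrast group: {order}", line=line
            )
    first = orders[0]
    for g, order in enumerate(orders[1:], start=2):
        if order != first:
            raise InconsistentGroupOrderError(
                f"contrast group {g} order {order} differs from first group {first}",
                line=line,
            )
    if "M" not in first:
        raise MissingMError(
            f"contrast groups lack the required M column (order {first})", line=line
        )
    # pass-through columns attach to the group whose span encloses them;
    # anything before the first group belongs to group 0.
    starts = [grp[0] for grp in groups]
    extra_group: dict[int, int] = {}
    for i, c in enumerate(columns):
        if c in STAT_LETTERS:
            continue
        g = 0
        for gi, s in enumerate(starts):
            if i > s:
                g = gi
        extra_group[i] = g
    return groups, first, extra_group


def parse_idmaps(source: str | IO[str]) -> ContrastDataset:
    """Parse an idMAPS file into a validated :class:`ContrastDataset`.

    ``source`` may be the file content as a string or an open text stream.
    """
    lines = _as_lines(source)
    pairs, data_start = _parse_header_lines(lines)
    header = _build_idmaps_header(pairs)
    if data_start >= len(lines):
        raise MalformedHeaderError("file has no column header row")
    col_line_no = data_start + 1
    columns = lines[data_start].split("\t")
    if len(columns) < 2:
        raise MalformedHeaderError("column header row has no data columns",
                                   line=col_line_no)
    header.id_column_name = columns[0]
    data_cols = columns[1:]
    n = len(header.contrast_names)
    groups, order, extra_group = _split_column_groups(data_cols, n, col_line_no)

    n_cols = len(columns)
    source_ids: list[str] = []
    raw_rows: list[list[str]] = []
    row_lines: list[int] = []
    for offset, raw in enumerate(lines[data_start + 1:]):
        line_no = col_line_no + 1 + offset
        if raw == "":
            continue
        cells = raw.split("\t")
        if len(cells) != n_cols:
            raise RowLengthMismatchError(
                f"row has {len(cells)} cells, expected {n_cols}", line=line_no
            )
        sid = cells[0].strip()
        if not sid:
            raise BadValueError("empty source ID", line=line_no)
        source_ids.append(sid)
        raw_rows.append(cells)
        row_lines.append(line_no)
    if not source_ids:
        raise InvalidDatasetError("file contains no data rows")

    contrasts: list[ContrastColumns] = []
    for g, (cname, grp) in enumerate(zip(header.contrast_names, groups)):
        values: dict[str, np.ndarray] = {}
        for col_pos in grp:
            letter = data_cols[col_pos]
            vec = np.empty(len(raw_rows))
            for r, cells in enumerate(raw_rows):
                vec[r] = _parse_float(
                    cells[col_pos + 1], line=row_lines[r], column=letter
                )
            values[letter] = vec
        m = values["M"]
        if np.isnan(m).any():
            r = int(np.flatnonzero(np.isnan(m))[0])
            raise BadValueError(
                f"missing M value for source ID {source_ids[r]!r} "
                f"in contrast {cname!r}",
                line=row_lines[r],
            )
        p = values.get("P")
        if p is not None:
            with np.errstate(invalid="ignore"):
                bad = np.flatnonzero((p < 0) | (p > 1))
            if bad.size:
                r = int(bad[0])
                raise BadPValueError(
                    f"P value {p[r]!r} outside [0, 1] in contrast {cname!r}",
                    line=row_lines[r],
                )
        extras: dict[str, list[str]] = {}
        for col_pos, grp_of in extra_group.items():
            if grp_of != g:
                continue
            name = data_cols[col_pos]
            if name in extras:
                raise MalformedHeaderError(
                    f"duplicate pass-through column {name!r} in one contrast group",
                    line=col_line_no,
                )
            extras[name] = [cells[col_pos + 1] for cells in raw_rows]
        contrasts.append(
            ContrastColumns(
                contrast_name=cname,
                values=values,
                column_order=list(order),
                extras=extras,
            )
        )

    dups = []
    seen: set[str] = set()
    for sid in source_ids:
        if sid in seen:
            dups.append(sid)
        seen.add(sid)
    if dups:
        logger.info(
            "idMAPS file %r: %d duplicate source IDs (resolved at collapsing)",
            header.dataset_name, len(dups),
        )
    dataset = ContrastDataset(header=header, source_ids=source_ids,
                              contrasts=contrasts)
    dataset.validate()
    return dataset


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return "NA" if math.isnan(x) else repr(float(x))


def write_idmaps(dataset: ContrastDataset, stream: IO[str] | None = None) -> str:
    """Serialize a :class:`ContrastDataset` to idMAPS text.

    The output uses a canonical layout (statistic letters in the dataset's
    recorded order, pass-through columns after them within each contrast
    group) and round-trips exactly through :func:`parse_idmaps`.
    """
    dataset.validate()
    h = dataset.header
    out = io.StringIO()
    out.write(f"#%dataset_name={h.dataset_name}\n")
    if h.dataset_description:
        out.write(f"#%dataset_description={h.dataset_description}\n")
    out.write(f"#%contrast_names={','.join(h.contrast_names)}\n")
    out.write(f"#%source_id_type={h.source_id_type}\n")
    out.write(f"#%organism={h.organism}\n")
    if h.skip_all:
        out.write("#%gene_set.skip=true\n")
    for cname in sorted(h.skip_gene_sets):
        out.write(f"#%gene_set.{cname}.skip=true\n")
    for cname in h.contrast_names:
        for param, value in sorted(h.extraction_overrides.get(cname, {}).items()):
            v = str(value).lower() if isinstance(value, bool) else value
            out.write(f"#%gene_set.{cname}.{param}={v}\n")
    for key, value in h.extra_metadata.items():
        out.write(f"#%{key}={value}\n")

    cols = [h.id_column_name]
    for c in dataset.contrasts:
        cols.extend(c.column_order)
        cols.extend(c.extras)
    out.write("\t".join(cols) + "\n")

    for r, sid in enumerate(dataset.source_ids):
        cells = [sid]
        for c in dataset.contrasts:
            cells.extend(_fmt(c.values[letter][r]) for letter in c.column_order)
            cells.extend(c.extras[name][r] for name in c.extras)
        out.write("\t".join(cells) + "\n")

    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# ID lists
# ---------------------------------------------------------------------------

def parse_idlist(source: str | IO[str]) -> IdList:
    """Parse an ID-list file (``#%`` header + one ID per line).

    IDs are whitespace-trimmed and de-duplicated keeping the first
    occurrence; the number of dropped duplicates is recorded on the
    result and logged as a warning.
    """
    lines = _as_lines(source)
    pairs, data_start = _parse_header_lines(lines)
    for key in ("gene_set_desc", "id_type", "organism"):
        if key not in pairs:
            raise MissingHeaderKeyError(f"missing required header key {key!r}")
    ids: list[str] = []
    seen: set[str] = set()
    n_dup = 0
    for raw in lines[data_start:]:
        token = raw.strip()
        if not token:
            continue
        if token in seen:
            n_dup += 1
            continue
        seen.add(token)
        ids.append(token)
    if not ids:
        raise EmptyListError("ID list contains no IDs")
    if n_dup:
        logger.warning("ID list: dropped %d duplicate IDs", n_dup)
    return IdList(
        gene_set_desc=pairs["gene_set_desc"].strip(),
        id_type=pairs["id_type"].strip(),
        organism=pairs["organism"].strip(),
        ids=ids,
        n_duplicates_dropped=n_dup,
        name=pairs.get("name", "").strip(),
    )


def write_idlist(idlist: IdList) -> str:
    out = io.StringIO()
    if idlist.name:
        out.write(f"#%name={idlist.name}\n")
    out.write(f"#%gene_set_desc={idlist.gene_set_desc}\n")
    out.write(f"#%id_type={idlist.id_type}\n")
    out.write(f"#%organism={idlist.organism}\n")
    for token in idlist.ids:
        out.write(token + "\n")
    return out.getvalue()
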