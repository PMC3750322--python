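"""idMAPS and ID-list parsing, validation, and round-trip behaviour."""

import numpy as np
import pytest

from contraset import parse_idlist, parse_idmaps, write_idmaps
from contraset.errors import (
    BadPValueError,
    BadValueError,
    DuplicateContrastNameError,
    EmptyListError,
    IdMapsParseError,
    InconsistentGroupOrderError,
    InvalidDatasetError,
    MissingHeaderKeyError,
    MissingMError,
    RowLengthMismatchError,
)
from conftest import IDMAPS_3C, random_dataset


def _make(header_over=None, columns="ID\tM\tA\tP\tS", rows=None):
    header = {
        "dataset_name": "D",
        "contrast_names": "c1",
        "source_id_type": "probe_set",
        "organism": "human",
    }
    header.update(header_over or {})
    lines = [f"#%{k}={v}" for k, v in header.items()]
    lines.append(columns)
    lines.extend(rows or ["p1\t1.0\t8.0\t0.5\t2.0", "p2\t-1.0\t7.0\t0.1\t-2.0"])
    return "\n".join(lines) + "\n"


class TestParseIdmaps:
    def test_three_contrast_maps_layout(self, demo_dataset):
        assert demo_dataset.header.contrast_names == [
            "Early", "Late", "Interaction"
        ]
        assert len(demo_dataset.contrasts) == 3
        for c in demo_dataset.contrasts:
            assert set(c.values) == {"M", "A", "P", "S"}
            assert c.column_order == ["M", "A", "P", "S"]
        np.testing.assert_allclose(
            demo_dataset.contrast("Late").values["M"], [0.5, -1.5, 2.1]
        )

    def test_minimum_requirement_is_m_alone(self):
        text = _make(columns="ID\tM", rows=["p1\t0.5", "p2\t-0.5"])
        ds = parse_idmaps(text)
        assert ds.contrasts[0].column_order == ["M"]
        assert "P" not in ds.contrasts[0].values

    def test_any_group_order_accepted_when_consistent(self):
        text = _make(
            header_over={"contrast_names": "c1,c2"},
            columns="ID\tA\tP\tS\tM\tA\tP\tS\tM",
            rows=["p1\t8\t0.5\t2\t1\t7\t0.1\t-2\t-1"],
        )
        ds = parse_idmaps(text)
        assert all(c.column_order == ["A", "P", "S", "M"]
                   for c in ds.contrasts)

    def test_inconsistent_group_order_rejected(self):
        text = _make(
            header_over={"contrast_names": "c1,c2"},
            columns="ID\tM\tA\tP\tS\tM\tP\tA\tS",
            rows=["p1\t1\t8\t0.5\t2\t1\t0.1\t7\t-2"],
        )
        with pytest.raises(InconsistentGroupOrderError):
            parse_idmaps(text)

    def test_group_lacking_m_rejected(self):
        text = _make(columns="ID\tA\tP", rows=["p1\t8\t0.5"])
        with pytest.raises(MissingMError):
            parse_idmaps(text)

    @pytest.mark.parametrize(
        "mutation, error",
        [
            ("drop_cell", RowLengthMismatchError),
            ("bad_p", BadPValueError),
            ("na_in_m", BadValueError),
            ("thousands_sep", BadValueError),
        ],
    )
    def test_row_level_errors_name_the_line(self, mutation, error):
        rows = ["p1\t1.0\t8.0\t0.5\t2.0", "p2\t-1.0\t7.0\t0.1\t-2.0"]
        if mutation == "drop_cell":
            rows[1] = "p2\t-1.0\t7.0\t0.1"
        elif mutation == "bad_p":
            rows[1] = "p2\t-1.0\t7.0\t1.5\t-2.0"
        elif mutation == "na_in_m":
            rows[1] = "p2\tNA\t7.0\t0.1\t-2.0"
        else:
            rows[1] = "p2\t1,000\t7.0\t0.1\t-2.0"
        with pytest.raises(error) as exc:
            parse_idmaps(_make(rows=rows))
        assert exc.value.line == 7  # 4 header lines + column row + 2nd data row

    def test_duplicate_contrast_names_rejected(self):
        with pytest.raises(DuplicateContrastNameError):
            parse_idmaps(_make(header_over={"contrast_names": "c1,c1"},
                               columns="ID\tM\tM",
                               rows=["p1\t1\t2"]))

    def test_missing_header_key_rejected(self):
        text = _make()
        text = text.replace("#%organism=human\n", "")
        with pytest.raises(MissingHeaderKeyError):
            parse_idmaps(text)

    def test_na_allowed_in_optional_columns(self):
        ds = parse_idmaps(_make(rows=["p1\t1.0\tNA\t\t2.0",
                                      "p2\t-1.0\t7.0\t0.1\tNA"]))
        c = ds.contrasts[0]
        assert np.isnan(c.values["A"][0]) and np.isnan(c.values["P"][0])
        assert np.isnan(c.values["S"][1])

    def test_duplicate_source_ids_recorded_not_rejected(self):
        ds = parse_idmaps(_make(rows=["p1\t1\t8\t0.5\t2", "p1\t2\t7\t0.1\t3"]))
        assert ds.duplicate_source_ids == ["p1"]

    def test_extraction_overrides_and_skip_flags(self):
        text = _make(header_over={
            "contrast_names": "c1,c2",
            "gene_set.c2.skip": "true",
            "gene_set.c1.p_threshold": "0.01",
            "gene_set.c1.min_size": "5",
        }, columns="ID\tM\tM", rows=["p1\t1\t2", "p2\t-1\t0.5"])
        h = parse_idmaps(text).header
        assert h.skip_gene_sets == {"c2"}
        assert h.extraction_overrides["c1"] == {"p_threshold": 0.01,
                                                "min_size": 5}


class TestRoundTrip:
    def test_write_parse_identity_many_random_datasets(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            ds = random_dataset(rng)
            assert parse_idmaps(write_idmaps(ds)) == ds

    def test_pass_through_column_preserved_verbatim(self):
        text = _make(columns="ID\tM\tA\tP\tS\tB",
                     rows=["p1\t1\t8\t0.5\t2\thello",
                           "p2\t-1\t7\t0.1\t-2\tworld"])
        ds = parse_idmaps(text)
        assert ds.contrasts[0].extras["B"] == ["hello", "world"]
        assert parse_idmaps(write_idmaps(ds)) == ds

    def test_pass_through_does_not_alter_statistics(self):
        with_extra = parse_idmaps(_make(
            columns="ID\tM\tA\tP\tS\tB",
            rows=["p1\t1\t8\t0.5\t2\tx", "p2\t-1\t7\t0.1\t-2\ty"],
        ))
        without = parse_idmaps(_make())
        for letter in "MAPS":
            np.testing.assert_array_equal(
                with_extra.contrasts[0].values[letter],
                without.contrasts[0].values[letter],
            )

    def test_empty_contrast_list_refused_on_write(self, demo_dataset):
        demo_dataset.contrasts = []
        demo_dataset.header.contrast_names = []
        with pytest.raises(InvalidDatasetError):
            write_idmaps(demo_dataset)

    def test_random_mutations_always_rejected(self):
        """Dropping a cell, shuffling group order, or corrupting P must fail."""
        rng = np.random.default_rng(7)
        for _ in range(40):
            ds = random_dataset(rng, with_extras=False)
            text = write_idmaps(ds)
            lines = text.splitlines()
            col_row = next(i for i, l in enumerate(lines)
                           if not l.startswith("#%"))
            kind = rng.integers(0, 3)
            if kind == 0:  # drop a data cell
                r = int(rng.integers(col_row + 1, len(lines)))
                cells = lines[r].split("\t")
                cells.pop(int(rng.integers(1, len(cells))))
                lines[r] = "\t".join(cells)
            elif kind == 1:  # shuffle the second group's column order
                cols = lines[col_row].split("\t")
                n_per = (len(cols) - 1) // len(ds.contrasts)
                if len(ds.contrasts) < 2 or n_per < 2:
                    continue
                start = 1 + n_per
                cols[start], cols[start + 1] = cols[start + 1], cols[start]
                lines[col_row] = "\t".join(cols)
            else:  # out-of-range P
                if "P" not in ds.contrasts[0].column_order:
                    continue
                cols = lines[col_row].split("\t")
                p_col = cols.index("P")
                r = int(rng.integers(col_row + 1, len(lines)))
                cells = lines[r].split("\t")
                cells[p_col] = "1.5"
                lines[r] = "\t".join(cells)
            with pytest.raises(IdMapsParseError):
                parse_idmaps("\n".join(lines))


class TestIdList:
    IDLIST = ("#%gene_set_desc=Inflammatory Response biological process\n"
              "#%id_type=gene_symbol\n#%organism=human\n"
              "TNF\nIL6\n IL1B \nTNF\nCXCL8\n")

    def test_parse_trims_and_deduplicates(self):
        lst = parse_idlist(self.IDLIST)
        assert lst.ids == ["TNF", "IL6", "IL1B", "CXCL8"]
        assert lst.n_duplicates_dropped == 1
        assert lst.gene_set_desc.startswith("Inflammatory")

    def test_missing_id_type_rejected(self):
        with pytest.raises(MissingHeaderKeyError):
            parse_idlist("#%gene_set_desc=x\n#%organism=human\nTNF\n")

    def test_empty_list_rejected(self):
        with pytest.raises(EmptyListError):
            parse_idlist("#%gene_set_desc=x\n#%id_type=gene_symbol\n"
                         "#%organism=human\n\n")
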