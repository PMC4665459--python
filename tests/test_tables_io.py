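"""Container validation, delimited round-trips, and fixture integrity."""

import io

import numpy as np
import pytest

from bayesdta import tables_io
from bayesdta.tables_io import (
    CountTable2x2,
    NoGoldCrossTab,
    OrdinalCounts,
    PairedBinaryCounts,
    ScoreSet,
    TableParseError,
    TableValidationError,
    VerificationCounts,
    load_fixture,
    read_table,
    write_table,
)


def _roundtrip(table):
    buf = io.StringIO()
    write_table(table, buf)
    return read_table(io.StringIO(buf.getvalue()))


@pytest.mark.parametrize(
    "table",
    [
        CountTable2x2(327, 208, 115, 818),
        PairedBinaryCounts(diseased=(22, 191, 30, 752), nondiseased=(148, 167, 49, 71)),
        OrdinalCounts(diseased=(1, 0, 6, 11, 12), nondiseased=(9, 2, 11, 8, 0)),
        VerificationCounts(s=(31, 298), r=(48, 26), u=(117, 150)),
        NoGoldCrossTab(n=((35, 2), (87, 38))),
        ScoreSet(values=np.array([1.0, 2.5, 3.0]), labels=np.array([0, 1, 1])),
    ],
    ids=["2x2", "paired", "ordinal", "verification", "nogold", "scores"],
)
def test_write_read_roundtrip_is_exact(table):
    back = _roundtrip(table)
    assert type(back) is type(table)
    if isinstance(table, ScoreSet):
        np.testing.assert_array_equal(back.values, table.values)
        np.testing.assert_array_equal(back.labels, table.labels)
    else:
        assert back == table


@pytest.mark.parametrize(
    "build",
    [
        lambda: CountTable2x2(0, 0, 0, 0),
        lambda: CountTable2x2(-1, 2, 3, 4),
        lambda: CountTable2x2(1.5, 2, 3, 4),
        lambda: OrdinalCounts(diseased=(1,), nondiseased=(1,)),
        lambda: OrdinalCounts(diseased=(0, 0), nondiseased=(1, 1)),
        lambda: VerificationCounts(s=(1, 2), r=(0, 0), u=(0, 0, 1)),
        lambda: ScoreSet(values=np.array([1.0, np.inf]), labels=np.array([0, 1])),
        lambda: ScoreSet(values=np.array([1.0, 2.0]), labels=np.array([1, 1])),
    ],
    ids=[
        "empty-2x2",
        "negative-count",
        "fractional-count",
        "one-category",
        "empty-group",
        "ragged-verification",
        "nonfinite-score",
        "single-class",
    ],
)
def test_invalid_tables_are_rejected(build):
    with pytest.raises(TableValidationError):
        build()


def test_read_table_parses_2x2_from_text():
    text = "# bayesdta: 2x2\nx,d0,d1\n0,327,208\n1,115,818\n"
    table = read_table(io.StringIO(text))
    assert table == CountTable2x2(327, 208, 115, 818)


def test_read_table_rejects_missing_or_wrong_header():
    with pytest.raises(TableParseError):
        read_table(io.StringIO("x,d0,d1\n0,1,2\n1,3,4\n"))
    with pytest.raises(TableParseError):
        read_table(io.StringIO("# bayesdta: nonsense\nx,d0,d1\n0,1,2\n"))
    with pytest.raises(TableParseError):
        read_table(
            io.StringIO("# bayesdta: 2x2\nx,d0,d1\n0,1,2\n1,3,4\n"), schema="ordinal"
        )


def test_unknown_fixture_lists_alternatives():
    with pytest.raises(KeyError, match="est_cad"):
        load_fixture("no_such_dataset")


@pytest.mark.parametrize(
    "name, expected_total",
    [
        ("est_cad", 1468),
        ("mammography", 60),
        ("lung_ct_mri", 1430),
        ("scintigraphy", 670),
        ("mammography_verification", 1509),
        ("strongyloides", 162),
        ("reference_vs_gold", 200),
        ("stenosis", 294),
    ],
)
def test_fixture_totals_match_their_sources(name, expected_total):
    table, provenance = load_fixture(name)
    if isinstance(table, CountTable2x2):
        total = table.total
    elif isinstance(table, PairedBinaryCounts):
        total = sum(table.diseased) + sum(table.nondiseased)
    elif isinstance(table, OrdinalCounts):
        total = sum(table.diseased) + sum(table.nondiseased)
    elif isinstance(table, (VerificationCounts, NoGoldCrossTab)):
        total = table.total
    assert total == expected_total
    assert provenance


def test_diabetes_fixture_reproduces_reported_group_means(diabetes):
    assert diabetes.values.size == 78
    assert diabetes.diseased.size == 59
    assert diabetes.nondiseased.size == 19
    assert diabetes.nondiseased.mean() == pytest.approx(107.5, abs=0.05)
    assert diabetes.diseased.mean() - diabetes.nondiseased.mean() == pytest.approx(
        16.1, abs=0.05
    )


def test_stenosis_nondiseased_cells_recovered_by_exhaustive_search(stenosis):
    """The healthy-segment cells are uniquely pinned down by the published
    posterior means (to their printed rounding) and the total of 236."""
    total = 236
    published = {"fpfct": 0.2918, "fpfmri": 0.1668, "bnfpf": 0.1627, "bpfpf": 0.2959}
    denom = total + 4
    solutions = []
    # exhaustive over (b, c, d); each published mean is an exact closed-form
    # Dirichlet mean, so matching to the printed rounding prunes hard
    for d in range(total + 1):
        if abs((d + 1) / denom - published["bnfpf"]) >= 5e-4:
            continue
        for c in range(total + 1 - d):
            if abs((c + d + 2) / denom - published["fpfct"]) >= 5e-4:
                continue
            for b in range(total + 1 - d - c):
                a = total - d - c - b
                if (
                    abs((b + d + 2) / denom - published["fpfmri"]) < 5e-4
                    and abs((b + c + d + 3) / denom - published["bpfpf"]) < 5e-4
                ):
                    solutions.append((a, b, c, d))
    assert solutions == [(168, 0, 30, 38)]
    assert stenosis.nondiseased == (168, 0, 30, 38)
    # reconstructed cells also reproduce the reported specificities 71% / 84%
    a, b, c, d = solutions[0]
    assert round(100 * (a + b) / total) == 71
    assert round(100 * (a + c) / total) == 84


def test_fixture_files_roundtrip_through_io():
    for name in tables_io.list_fixtures():
        table, _ = load_fixture(name)
        back = _roundtrip(table)
        if isinstance(table, ScoreSet):
            np.testing.assert_array_equal(back.values, table.values)
            np.testing.assert_array_equal(back.labels, table.labels)
        else:
            assert back == table
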