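"""Typed count-table containers, delimited-text readers/writers, fixtures.

Every dataset the package operates on is one of six small shapes:

``2x2``
    A single binary test cross-classified with true disease status.
    Convention: first index is the test score X (0 = negative), second is
    disease status D (0 = non-diseased), so ``n10`` counts non-diseased
    subjects with a positive test.
``paired``
    Two binary tests applied to the same subjects, one 2x2 table of
    (test1, test2) outcomes per disease class.
``ordinal``
    A k-category ordinal test, per-category counts for the diseased and
    non-diseased groups.
``verification``
    A k-category test where only some subjects had their disease status
    verified: verified-diseased counts s_i, verified-non-diseased r_i, and
    unverified u_i per test category.
``nogold``
    Two binary tests (an imperfect reference R and a new test T) with no
    disease labels at all: just the R-by-T cross-tabulation.  Convention:
    first index R, second index T.
``scores``
    Subject-level continuous or ordinal scores with a 0/1 disease label.

Files are comma-delimited with a first line ``# bayesdta: <schema>`` naming
the shape, so a file is self-describing and round-trips exactly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "CountTable2x2",
    "PairedBinaryCounts",
    "OrdinalCounts",
    "VerificationCounts",
    "NoGoldCrossTab",
    "ScoreSet",
    "TableValidationError",
    "TableParseError",
    "read_table",
    "write_table",
    "load_fixture",
    "list_fixtures",
    "FIXTURES",
]

SCHEMAS = ("2x2", "paired", "ordinal", "verification", "nogold", "scores")

HEADER_PREFIX = "# bayesdta: "


class TableValidationError(ValueError):
    """Raised when counts violate a container invariant."""


class TableParseError(ValueError):
    """Raised when a delimited file cannot be interpreted."""


def _check_counts(values, *, what: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.size and not np.issubdtype(arr.dtype, np.integer):
        flo = np.asarray(values, dtype=float)
        if not np.allclose(flo, np.round(flo)):
            raise TableValidationError(f"{what}: counts must be integers")
        arr = np.round(flo).astype(np.int64)
    arr = arr.astype(np.int64)
    if np.any(arr < 0):
        raise TableValidationError(f"{what}: counts must be non-negative")
    return arr


@dataclass(frozen=True)
class CountTable2x2:
    """Test-by-disease counts; indices (X, D), 0 = negative/non-diseased."""

    n00: int
    n01: int
    n10: int
    n11: int

    def __post_init__(self) -> None:
        counts = _check_counts(
            [self.n00, self.n01, self.n10, self.n11], what="2x2 table"
        )
        if counts.sum() == 0:
            raise TableValidationError("2x2 table: total count must be positive")
        for name, v in zip(("n00", "n01", "n10", "n11"), counts):
            object.__setattr__(self, name, int(v))

    @property
    def counts(self) -> np.ndarray:
        """Cell counts in the canonical order (n00, n01, n10, n11)."""
        return np.array([self.n00, self.n01, self.n10, self.n11])

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class PairedBinaryCounts:
    """Two binary tests on the same subjects, one 2x2 per disease class.

    Each sub-table is indexed (test1, test2) and stored in the order
    (n00, n01, n10, n11).
    """

    diseased: tuple
    nondiseased: tuple

    def __post_init__(self) -> None:
        for name in ("diseased", "nondiseased"):
            counts = _check_counts(getattr(self, name), what=f"paired {name}")
            if counts.size != 4:
                raise TableValidationError(f"paired {name}: need 4 cells")
            if counts.sum() == 0:
                raise TableValidationError(f"paired {name}: total must be positive")
            object.__setattr__(self, name, tuple(int(v) for v in counts))


@dataclass(frozen=True)
class OrdinalCounts:
    """Per-category counts for an ordinal test, by disease class."""

    diseased: tuple
    nondiseased: tuple

    def __post_init__(self) -> None:
        d = _check_counts(self.diseased, what="ordinal diseased")
        nd = _check_counts(self.nondiseased, what="ordinal non-diseased")
        if d.size != nd.size:
            raise TableValidationError("ordinal: groups must have equal k")
        if d.size < 2:
            raise TableValidationError("ordinal: need at least 2 categories")
        if d.sum() == 0 or nd.sum() == 0:
            raise TableValidationError("ordinal: each group total must be positive")
        object.__setattr__(self, "diseased", tuple(int(v) for v in d))
        object.__setattr__(self, "nondiseased", tuple(int(v) for v in nd))

    @property
    def k(self) -> int:
        return len(self.diseased)


@dataclass(frozen=True)
class VerificationCounts:
    """Verified/unverified counts per test category.

    ``s[i]`` verified diseased, ``r[i]`` verified non-diseased, ``u[i]``
    unverified, for categories i = 1..k in increasing score order (for a
    binary test, index 0 is Y=0 and index 1 is Y=1).  ``m[i] = s+r+u``.
    """

    s: tuple
    r: tuple
    u: tuple

    def __post_init__(self) -> None:
        s = _check_counts(self.s, what="verification s")
        r = _check_counts(self.r, what="verification r")
        u = _check_counts(self.u, what="verification u")
        if not (s.size == r.size == u.size):
            raise TableValidationError("verification: s, r, u must share length")
        if s.size < 2:
            raise TableValidationError("verification: need at least 2 categories")
        if (s + r + u).sum() == 0:
            raise TableValidationError("verification: total must be positive")
        object.__setattr__(self, "s", tuple(int(v) for v in s))
        object.__setattr__(self, "r", tuple(int(v) for v in r))
        object.__setattr__(self, "u", tuple(int(v) for v in u))

    @property
    def k(self) -> int:
        return len(self.s)

    @property
    def m(self) -> tuple:
        return tuple(si + ri + ui for si, ri, ui in zip(self.s, self.r, self.u))

    @property
    def total(self) -> int:
        return int(sum(self.m))


@dataclass(frozen=True)
class NoGoldCrossTab:
    """Reference-by-new-test counts with no disease labels.

    ``n[i][j]`` counts subjects with reference result R=i and new-test result
    T=j.  The (R, T) index order matters: the latent-class likelihood pairs
    the new test's sensitivity with the T=1 column (cells n11 and n01).
    """

    n: tuple  # ((n00, n01), (n10, n11)) with first index R, second T

    def __post_init__(self) -> None:
        arr = _check_counts(np.asarray(self.n).ravel(), what="nogold table")
        if arr.size != 4:
            raise TableValidationError("nogold: need a 2x2 table")
        if arr.sum() == 0:
            raise TableValidationError("nogold: total must be positive")
        object.__setattr__(
            self, "n", ((int(arr[0]), int(arr[1])), (int(arr[2]), int(arr[3])))
        )

    @property
    def total(self) -> int:
        return int(np.asarray(self.n).sum())


@dataclass(frozen=True)
class ScoreSet:
    """Subject-level test scores with binary disease labels."""

    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels)
        if values.ndim != 1 or labels.ndim != 1 or values.size != labels.size:
            raise TableValidationError("scores: values and labels must align")
        if not np.all(np.isfinite(values)):
            raise TableValidationError("scores: values must be finite")
        if not np.isin(labels, (0, 1)).all():
            raise TableValidationError("scores: labels must be 0 or 1")
        labels = labels.astype(np.int64)
        for lab in (0, 1):
            if not np.any(labels == lab):
                raise TableValidationError(f"scores: no subjects with label {lab}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)

    @property
    def diseased(self) -> np.ndarray:
        return self.values[self.labels == 1]

    @property
    def nondiseased(self) -> np.ndarray:
        return self.values[self.labels == 0]


Table = Union[
    CountTable2x2,
    PairedBinaryCounts,
    OrdinalCounts,
    VerificationCounts,
    NoGoldCrossTab,
    ScoreSet,
]

_SCHEMA_OF_TYPE = {
    CountTable2x2: "2x2",
    PairedBinaryCounts: "paired",
    OrdinalCounts: "ordinal",
    VerificationCounts: "verification",
    NoGoldCrossTab: "nogold",
    ScoreSet: "scores",
}


# ---------------------------------------------------------------------------
# delimited-text IO
# ---------------------------------------------------------------------------

def _read_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    return Path(source).read_text()


def _frame(body: str, schema: str) -> pd.DataFrame:
    try:
        return pd.read_csv(io.StringIO(body))
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TableParseError(f"cannot parse {schema} table: {exc}") from exc


def _require(frame: pd.DataFrame, columns: tuple, schema: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise TableParseError(f"{schema} table missing columns {missing}")


def read_table(source, schema: str | None = None) -> Table:
    """Read a validated table from a self-describing delimited file.

    ``source`` may be a path or an open text handle.  ``schema`` is optional;
    when given it must agree with the file's header line.
    """
    text = _read_text(source)
    lines = text.splitlines()
    if not lines or not lines[0].startswith(HEADER_PREFIX):
        raise TableParseError(
            f"first line must be '{HEADER_PREFIX}<schema>' "
            f"with schema one of {SCHEMAS}"
        )
    file_schema = lines[0][len(HEADER_PREFIX):].strip()
    if file_schema not in SCHEMAS:
        raise TableParseError(f"unknown schema {file_schema!r}; expected {SCHEMAS}")
    if schema is not None and schema != file_schema:
        raise TableParseError(
            f"schema mismatch: requested {schema!r} but file says {file_schema!r}"
        )
    body = "\n".join(ln for ln in lines[1:] if not ln.startswith("#"))
    frame = _frame(body, file_schema)

    if file_schema == "2x2":
        _require(frame, ("x", "d0", "d1"), file_schema)
        rows = {int(row.x): row for row in frame.itertuples()}
        if set(rows) != {0, 1}:
            raise TableParseError("2x2 table needs exactly rows x=0 and x=1")
        return CountTable2x2(
            n00=rows[0].d0, n01=rows[0].d1, n10=rows[1].d0, n11=rows[1].d1
        )
    if file_schema == "paired":
        _require(frame, ("group", "test1", "test2", "count"), file_schema)
        cells: dict = {"diseased": {}, "nondiseased": {}}
        for row in frame.itertuples():
            if row.group not in cells:
                raise TableParseError(f"paired: unknown group {row.group!r}")
            cells[row.group][(int(row.test1), int(row.test2))] = row.count
        order = [(0, 0), (0, 1), (1, 0), (1, 1)]
        for g, d in cells.items():
            if set(d) != set(order):
                raise TableParseError(f"paired: group {g!r} must have the 4 cells")
        return PairedBinaryCounts(
            diseased=tuple(cells["diseased"][ij] for ij in order),
            nondiseased=tuple(cells["nondiseased"][ij] for ij in order),
        )
    if file_schema == "ordinal":
        _require(frame, ("category", "diseased", "nondiseased"), file_schema)
        frame = frame.sort_values("category")
        return OrdinalCounts(
            diseased=tuple(frame["diseased"]),
            nondiseased=tuple(frame["nondiseased"]),
        )
    if file_schema == "verification":
        _require(
            frame,
            ("category", "verified_diseased", "verified_nondiseased", "unverified"),
            file_schema,
        )
        frame = frame.sort_values("category")
        return VerificationCounts(
            s=tuple(frame["verified_diseased"]),
            r=tuple(frame["verified_nondiseased"]),
            u=tuple(frame["unverified"]),
        )
    if file_schema == "nogold":
        _require(frame, ("reference", "test", "count"), file_schema)
        cells = {}
        for row in frame.itertuples():
            cells[(int(row.reference), int(row.test))] = row.count
        if set(cells) != {(0, 0), (0, 1), (1, 0), (1, 1)}:
            raise TableParseError("nogold: need the 4 (reference, test) cells")
        return NoGoldCrossTab(
            n=((cells[(0, 0)], cells[(0, 1)]), (cells[(1, 0)], cells[(1, 1)]))
        )
    # scores
    _require(frame, ("value", "label"), file_schema)
    return ScoreSet(values=frame["value"].to_numpy(), labels=frame["label"].to_numpy())


def write_table(table: Table, target) -> None:
    """Write a table as self-describing delimited text (see read_table)."""
    schema = _SCHEMA_OF_TYPE[type(table)]
    lines = [HEADER_PREFIX + schema]
    if isinstance(table, CountTable2x2):
        lines += ["x,d0,d1", f"0,{table.n00},{table.n01}", f"1,{table.n10},{table.n11}"]
    elif isinstance(table, PairedBinaryCounts):
        lines.append("group,test1,test2,count")
        order = [(0, 0), (0, 1), (1, 0), (1, 1)]
        for g in ("diseased", "nondiseased"):
            for (i, j), c in zip(order, getattr(table, g)):
                lines.append(f"{g},{i},{j},{c}")
    elif isinstance(table, OrdinalCounts):
        lines.append("category,diseased,nondiseased")
        for i, (d, nd) in enumerate(zip(table.diseased, table.nondiseased), start=1):
            lines.append(f"{i},{d},{nd}")
    elif isinstance(table, VerificationCounts):
        lines.append("category,verified_diseased,verified_nondiseased,unverified")
        for i, (s, r, u) in enumerate(zip(table.s, table.r, table.u), start=1):
            lines.append(f"{i},{s},{r},{u}")
    elif isinstance(table, NoGoldCrossTab):
        lines.append("reference,test,count")
        for i in (0, 1):
            for j in (0, 1):
                lines.append(f"{i},{j},{table.n[i][j]}")
    elif isinstance(table, ScoreSet):
        lines.append("value,label")
        for v, d in zip(table.values, table.labels):
            v = int(v) if float(v).is_integer() else v
            lines.append(f"{v},{d}")
    else:  # pragma: no cover
        raise TypeError(f"unsupported table type {type(table)}")
    text = "\n".join(lines) + "\n"
    if hasattr(target, "write"):
        target.write(text)
    else:
        Path(target).write_text(text)


# ---------------------------------------------------------------------------
# bundled fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fixture:
    """A bundled worked dataset with its provenance."""

    name: str
    filename: str
    schema: str
    provenance: str
    derived: bool = False


FIXTURES: dict[str, Fixture] = {
    f.name: f
    for f in (
        Fixture(
            "est_cad",
            "est_cad.csv",
            "2x2",
            "Exercise stress test vs angiography-confirmed coronary artery "
            "disease; cohort of 1465 subjects.",
        ),
        Fixture(
            "mammography",
            "mammography.csv",
            "ordinal",
            "Five-category mammogram ratings for 30 women with breast cancer "
            "and 30 without.",
        ),
        Fixture(
            "diabetes",
            "diabetes.csv",
            "scores",
            "Blood glucose (mg/dl) for 59 diabetic and 19 non-diabetic "
            "subjects.  The 59/19 split reproduces the non-diseased group "
            "mean of 107.5 that the published regression intercept reports.",
        ),
        Fixture(
            "lung_ct_mri",
            "lung_ct_mri.csv",
            "paired",
            "Paired CT (test1) and MRI (test2) reads for 995 lung-cancer and "
            "435 cancer-free subjects.",
        ),
        Fixture(
            "scintigraphy",
            "scintigraphy.csv",
            "verification",
            "Hepatic scintigraphy for liver disease with partial "
            "verification; 670 subjects, 474 positive, 150 positives and 117 "
            "negatives unverified.",
        ),
        Fixture(
            "mammography_verification",
            "mammography_verification.csv",
            "verification",
            "Five-category mammography study of 1509 subjects with 249 "
            "unverified.",
        ),
        Fixture(
            "strongyloides",
            "strongyloides.csv",
            "nogold",
            "Stool examination (new test T) against a serologic reference R "
            "for Strongyloides infection in 162 Cambodian refugees; no gold "
            "standard.",
        ),
        Fixture(
            "reference_vs_gold",
            "reference_vs_gold.csv",
            "nogold",
            "Hypothetical imperfect-reference example: new test T "
            "cross-classified with an imperfect reference R (200 subjects).",
        ),
        Fixture(
            "stenosis",
            "stenosis.csv",
            "paired",
            "Paired CT (test1) and MRI (test2) calls on 58 stenosed and 236 "
            "healthy coronary segments.  DERIVED: the non-diseased table is "
            "not fully printed in the source study report; its cells "
            "(168, 0, 30, 38) are reconstructed by exhaustive search over "
            "non-negative integer tables summing to 236 that reproduce the "
            "published posterior means and the printed specificities "
            "71% (CT) and 84% (MRI).",
            derived=True,
        ),
    )
}

#: Informative beta prior hyperparameters elicited for the Strongyloides
#: analysis: (alpha, beta) per parameter; prevalence left uniform.
STRONGYLOIDES_PRIORS = {
    "p": (1.0, 1.0),
    "s1": (4.44, 13.31),
    "c1": (71.25, 3.75),
    "s2": (21.96, 5.49),
    "c2": (4.1, 1.76),
}


def list_fixtures() -> list[str]:
    return sorted(FIXTURES)


def load_fixture(name: str) -> tuple[Table, str]:
    """Return a bundled dataset and its provenance string."""
    if name not in FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(list_fixtures())}"
        )
    fx = FIXTURES[name]
    ref = resources.files("bayesdta").joinpath("data", fx.filename)
    with ref.open("r") as fh:
        table = read_table(fh, schema=fx.schema)
    provenance = ("[DERIVED] " if fx.derived else "") + fx.provenance
    return table, provenance
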