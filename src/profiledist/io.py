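"""Reading and writing allelic profile tables and pair/forest outputs.

Profile tables follow the layout used by MLST/cgMLST/wgMLST typing
databases: tab-separated, one row per profile, first column a profile
identifier (e.g. the sequence type, ST) and the remaining ``m`` columns
the allele calls, one per locus.  Allele calls are categorical tokens;
they are re-coded to a dense integer alphabet ``0..sigma-1`` on read,
because Hamming distance only ever tests per-position equality.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProfileSet",
    "ProfileFormatError",
    "ProfileIdentifierError",
    "read_profiles",
    "write_profiles",
    "read_frequencies",
    "write_pairs",
    "write_forest",
]


class ProfileFormatError(ValueError):
    """Malformed profile table (ragged rows, empty input, bad values)."""


class ProfileIdentifierError(ValueError):
    """Duplicate or missing profile identifiers."""


@dataclass
class ProfileSet:
    """A set of ``d`` equal-length allelic profiles over an integer alphabet.

    Attributes
    ----------
    ids : list of str
        Unique profile identifiers, in input (row) order.
    matrix : ndarray of shape (d, m), dtype int32
        Integer-encoded allele calls; every entry lies in ``[0, sigma)``.
    tokens : list of str
        Decode table: ``tokens[c]`` is the raw allele token encoded as ``c``.
        Encoding is by global first occurrence in row-major order, so
        identical raw tokens map to the same integer wherever they appear.
    freq : ndarray of shape (d,), dtype int64
        Per-profile isolate counts (observation frequencies), default 1.
    """

    ids: list[str]
    matrix: np.ndarray
    tokens: list[str] = field(default_factory=list)
    freq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.ascontiguousarray(np.asarray(self.matrix, dtype=np.int32))
        if self.matrix.ndim != 2:
            raise ProfileFormatError("profile matrix must be 2-dimensional")
        d, m = self.matrix.shape
        if d < 1 or m < 1:
            raise ProfileFormatError("profile set must have d >= 1 rows and m >= 1 loci")
        if len(self.ids) != d:
            raise ProfileIdentifierError(
                f"{len(self.ids)} identifiers for {d} profiles"
            )
        if len(set(self.ids)) != d:
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ProfileIdentifierError(f"duplicate profile identifiers: {dupes}")
        if self.matrix.min() < 0:
            raise ProfileFormatError("encoded alleles must be non-negative")
        if not self.tokens:
            self.tokens = [str(c) for c in range(int(self.matrix.max()) + 1)]
        if int(self.matrix.max()) >= len(self.tokens):
            raise ProfileFormatError("encoded allele outside the decode table")
        if self.freq is None:
            self.freq = np.ones(d, dtype=np.int64)
        else:
            self.freq = np.asarray(self.freq, dtype=np.int64)
            if self.freq.shape != (d,):
                raise ProfileFormatError("freq must have one entry per profile")
            if self.freq.min() < 1:
                raise ProfileFormatError("isolate frequencies must be >= 1")

    @property
    def d(self) -> int:
        return self.matrix.shape[0]

    @property
    def m(self) -> int:
        return self.matrix.shape[1]

    @property
    def sigma(self) -> int:
        """Alphabet size: number of distinct encoded symbols."""
        return len(self.tokens)

    @property
    def token_map(self) -> dict[str, int]:
        return {t: c for c, t in enumerate(self.tokens)}

    def encode_row(self, raw: list[str]) -> np.ndarray:
        """Encode one raw profile with this set's alphabet.

        Tokens never seen in the indexed table are mapped to fresh codes at
        and above ``sigma``; such codes can never match an indexed allele,
        which is exactly the semantics wanted for external query profiles.
        """
        if len(raw) != self.m:
            raise ProfileFormatError(
                f"query profile has {len(raw)} loci, expected {self.m}"
            )
        tm = self.token_map
        out = np.empty(self.m, dtype=np.int32)
        fresh: dict[str, int] = {}
        for pos, tok in enumerate(raw):
            code = tm.get(tok)
            if code is None:
                code = fresh.setdefault(tok, self.sigma + len(fresh))
            out[pos] = code
        return out


def read_profiles(path, has_header: bool = True, id_column: int | str = 0) -> ProfileSet:
    """Read a tab-separated profile table into a :class:`ProfileSet`.

    Parameters
    ----------
    path : path-like
        TSV file; one identifier column plus ``m`` locus columns.
    has_header : bool
        Whether the first line holds locus names rather than data.
    id_column : int or str
        The identifier column, by ordinal or (with a header) by name.

    Raises
    ------
    ProfileFormatError
        Ragged rows (message names the offending line) or an empty table.
    ProfileIdentifierError
        Duplicate profile identifiers.
    """
    with open(path, newline="") as fh:
        rows = [(lineno, row) for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), 1)
                if row and any(f.strip() for f in row)]
    header: list[str] | None = None
    if has_header and rows:
        header = [f.strip() for f in rows[0][1]]
        rows = rows[1:]
    if not rows:
        raise ProfileFormatError(f"empty profile table: {path}")

    ncol = len(rows[0][1])
    for lineno, row in rows:
        if len(row) != ncol:
            raise ProfileFormatError(
                f"ragged row at line {lineno}: expected {ncol} fields, found {len(row)}"
            )
    if ncol < 2:
        raise ProfileFormatError("profile table needs an id column plus >= 1 locus column")

    if isinstance(id_column, str):
        if header is None:
            raise ProfileFormatError("id_column by name requires a header row")
        try:
            id_idx = header.index(id_column)
        except ValueError:
            raise ProfileFormatError(f"no column named {id_column!r} in header") from None
    else:
        id_idx = int(id_column)
        if not -ncol <= id_idx < ncol:
            raise ProfileFormatError(f"id column ordinal {id_idx} out of range")
        id_idx %= ncol

    ids: list[str] = []
    codes: dict[str, int] = {}
    tokens: list[str] = []
    matrix = np.empty((len(rows), ncol - 1), dtype=np.int32)
    for r, (lineno, row) in enumerate(rows):
        ids.append(row[id_idx].strip())
        c = 0
        for j, raw in enumerate(row):
            if j == id_idx:
                continue
            tok = raw.strip()
            code = codes.get(tok)
            if code is None:
                code = codes[tok] = len(tokens)
                tokens.append(tok)
            matrix[r, c] = code
            c += 1
    return ProfileSet(ids=ids, matrix=matrix, tokens=tokens)


def write_profiles(profiles: ProfileSet, path, locus_names: list[str] | None = None) -> None:
    """Write a profile table (decoded tokens) that `read_profiles` round-trips."""
    m = profiles.m
    if locus_names is None:
        locus_names = [f"L{j + 1}" for j in range(m)]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", *locus_names])
        for i, pid in enumerate(profiles.ids):
            w.writerow([pid, *(profiles.tokens[c] for c in profiles.matrix[i])])


def read_frequencies(path, profiles: ProfileSet) -> np.ndarray:
    """Read a two-column ``id<TAB>frequency`` table aligned to *profiles*."""
    freq = np.ones(profiles.d, dtype=np.int64)
    index = {pid: i for i, pid in enumerate(profiles.ids)}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not row or not any(f.strip() for f in row):
                continue
            if len(row) != 2:
                raise ProfileFormatError(
                    f"ragged row at line {lineno}: frequency table needs 2 fields"
                )
            pid, count = row[0].strip(), row[1].strip()
            if pid not in index:
                raise ProfileIdentifierError(f"unknown profile id {pid!r} at line {lineno}")
            freq[index[pid]] = int(count)
    if freq.min() < 1:
        raise ProfileFormatError("isolate frequencies must be >= 1")
    return freq


PAIRS_HEADER = ["id_i", "id_j", "distance"]


def write_pairs(pairs, path) -> None:
    """Write a truncated distance matrix as a sorted ``id_i id_j distance`` TSV.

    Within a pair the lower row index is written first; rows are sorted by
    (distance, id_i, id_j).  An empty pair set yields a header-only file.
    """
    ids = pairs.ids
    rows = sorted(
        (h, ids[i], ids[j]) for i, j, h in pairs.pairs
    )
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(PAIRS_HEADER)
        for h, id_i, id_j in rows:
            w.writerow([id_i, id_j, h])


def write_forest(forest, path, components_path=None) -> None:
    """Write forest edges in acceptance order; optionally component labels."""
    ids = forest.ids
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(PAIRS_HEADER)
        for i, j, h in forest.edges:
            w.writerow([ids[i], ids[j], h])
    if components_path is not None:
        with open(components_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["id", "component"])
            for i, pid in enumerate(ids):
                w.writerow([pid, int(forest.labels[i])])
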