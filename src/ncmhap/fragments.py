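"""Domain types and text I/O for SNP fragment matrices and haplotypes.

A *fragment* is one sequencing read restricted to heterozygous SNP sites:
a string over ``{0, 1, -}`` where ``0``/``1`` code the major/minor allele
and ``-`` marks a site the read does not observe confidently (a gap).
Stacking the fragments row-wise gives the m x n SNP matrix that haplotype
assembly operates on.

Two on-disk formats are supported:

* the *plain matrix* format — one fragment per line over ``{0,1,-}``, with
  an optional leading whitespace-separated fragment id;
* *HapCUT-style fragment files* — per line: a block count ``B``, a fragment
  id, then ``B`` pairs of (1-based start offset, contiguous allele string),
  optionally followed by a quality string which is parsed but ignored.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

GAP = "-"
_ALLELE_CHARS = frozenset("01-")


class FragmentFormatError(ValueError):
    """Raised when a fragment or haplotype file violates its format."""


@dataclass
class SNPMatrix:
    """An m x n matrix of fragments over heterozygous biallelic SNP sites.

    Attributes
    ----------
    alleles
        ``uint8`` array of shape (m, n); entries at unobserved positions are
        canonicalized to 0 and must be ignored by every consumer.
    observed
        Boolean mask of shape (m, n); ``False`` exactly where the fragment
        has a gap.
    fragment_ids
        One opaque label per fragment.
    """

    alleles: np.ndarray
    observed: np.ndarray
    fragment_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        self.observed = np.ascontiguousarray(self.observed, dtype=bool)
        if self.alleles.ndim != 2 or self.alleles.shape != self.observed.shape:
            raise ValueError("alleles and observed must be equal-shape 2-D arrays")
        m, n = self.alleles.shape
        if m < 1 or n < 1:
            raise ValueError("SNPMatrix needs at least one fragment and one site")
        if not self.fragment_ids:
            self.fragment_ids = [f"f{i}" for i in range(m)]
        if len(self.fragment_ids) != m:
            raise ValueError("fragment_ids length must equal the number of rows")
        if np.any(~self.observed.any(axis=1)):
            bad = int(np.flatnonzero(~self.observed.any(axis=1))[0])
            raise ValueError(
                f"fragment {self.fragment_ids[bad]!r} observes no site (all gaps)"
            )
        # canonicalize: gaps carry no allele information
        self.alleles = np.where(self.observed, self.alleles, 0).astype(np.uint8)
        if self.alleles.max(initial=0) > 1:
            raise ValueError("allele codes must be 0 or 1")

    @property
    def n_fragments(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def row_string(self, i: int) -> str:
        """Fragment *i* rendered over ``{0,1,-}``."""
        return "".join(
            str(a) if o else GAP
            for a, o in zip(self.alleles[i], self.observed[i])
        )

    @classmethod
    def from_strings(
        cls, rows: list[str], fragment_ids: list[str] | None = None
    ) -> "SNPMatrix":
        """Build a matrix from equal-length strings over ``{0,1,-}``."""
        if not rows:
            raise ValueError("need at least one fragment row")
        n = len(rows[0])
        if any(len(r) != n for r in rows):
            raise ValueError("ragged fragment rows")
        arr = np.frombuffer("".join(rows).encode(), dtype="S1").reshape(len(rows), n)
        observed = arr != b"-"
        alleles = np.where(arr == b"1", 1, 0).astype(np.uint8)
        return cls(alleles, observed, list(fragment_ids or []))


@dataclass(frozen=True)
class HaplotypePair:
    """Two complementary haplotypes over ``{0,1,-}``.

    All sites are heterozygous SNPs, so wherever both haplotypes are defined
    they carry opposite alleles; ``-`` marks a site that no fragment covered
    and that therefore cannot be phased.
    """

    h1: str
    h2: str

    def __post_init__(self) -> None:
        if len(self.h1) != len(self.h2):
            raise ValueError("h1 and h2 must have equal length")
        for h in (self.h1, self.h2):
            if not set(h) <= _ALLELE_CHARS:
                raise ValueError(f"haplotype contains characters outside {{0,1,-}}: {h!r}")

    @property
    def n_sites(self) -> int:
        return len(self.h1)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (alleles, defined) arrays of shape (2, n)."""
        arr = np.frombuffer((self.h1 + self.h2).encode(), dtype="S1").reshape(2, -1)
        defined = arr != b"-"
        alleles = np.where(arr == b"1", 1, 0).astype(np.uint8)
        return alleles, defined


def read_fragment_matrix(path: str | os.PathLike) -> SNPMatrix:
    """Read the plain matrix format: one fragment per non-empty line.

    A line may carry a leading whitespace-separated fragment id; the final
    whitespace-separated token is always the allele string.
    """
    rows: list[str] = []
    ids: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) == 1:
                frag_id, row = f"f{len(rows)}", tokens[0]
            elif len(tokens) == 2:
                frag_id, row = tokens
            else:
                raise FragmentFormatError(
                    f"{path}:{lineno}: expected '[id] alleles', got {len(tokens)} fields"
                )
            if not set(row) <= _ALLELE_CHARS:
                bad = sorted(set(row) - _ALLELE_CHARS)
                raise FragmentFormatError(
                    f"{path}:{lineno}: characters outside {{0,1,-}}: {bad}"
                )
            if rows and len(row) != len(rows[0]):
                raise FragmentFormatError(
                    f"{path}:{lineno}: line length {len(row)} != {len(rows[0])} of line 1"
                )
            if set(row) == {GAP}:
                raise FragmentFormatError(
                    f"{path}:{lineno}: fragment observes no site (all gaps)"
                )
            rows.append(row)
            ids.append(frag_id)
    if not rows:
        raise FragmentFormatError(f"{path}: no fragments found")
    return SNPMatrix.from_strings(rows, ids)


def read_hapcut_fragments(path: str | os.PathLike, n_sites: int) -> SNPMatrix:
    """Read a HapCUT-style fragment file onto a matrix of width ``n_sites``.

    Line layout: ``B id start_1 alleles_1 ... start_B alleles_B [quality]``
    with 1-based start offsets. The optional trailing quality string is
    ignored — conflicts here are binary, not quality-weighted.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rows: list[str] = []
    ids: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            tokens = line.split()
            try:
                n_blocks = int(tokens[0])
            except (ValueError, IndexError):
                raise FragmentFormatError(
                    f"{path}:{lineno}: first field must be the block count"
                ) from None
            if n_blocks < 1 or len(tokens) < 2:
                raise FragmentFormatError(f"{path}:{lineno}: malformed header fields")
            frag_id = tokens[1]
            body = tokens[2:]
            if len(body) == 2 * n_blocks + 1:
                body = body[:-1]  # quality string, ignored
            if len(body) != 2 * n_blocks:
                raise FragmentFormatError(
                    f"{path}:{lineno}: block count {n_blocks} does not match "
                    f"{len(body)} remaining fields"
                )
            row = [GAP] * n_sites
            covered: set[int] = set()
            for b in range(n_blocks):
                try:
                    start = int(body[2 * b])
                except ValueError:
                    raise FragmentFormatError(
                        f"{path}:{lineno}: block {b + 1} start is not an integer"
                    ) from None
                alleles = body[2 * b + 1]
                if not set(alleles) <= {"0", "1"}:
                    raise FragmentFormatError(
                        f"{path}:{lineno}: block {b + 1} alleles must be over {{0,1}}"
                    )
                if start < 1 or start + len(alleles) - 1 > n_sites:
                    raise FragmentFormatError(
                        f"{path}:{lineno}: block {b + 1} [{start}, "
                        f"{start + len(alleles) - 1}] exceeds n_sites={n_sites}"
                    )
                span = range(start - 1, start - 1 + len(alleles))
                if covered & set(span):
                    raise FragmentFormatError(
                        f"{path}:{lineno}: block {b + 1} overlaps an earlier block"
                    )
                covered.update(span)
                for k, a in zip(span, alleles):
                    row[k] = a
            rows.append("".join(row))
            ids.append(frag_id)
    if not rows:
        raise FragmentFormatError(f"{path}: no fragments found")
    return SNPMatrix.from_strings(rows, ids)


def write_haplotypes(h: HaplotypePair, path: str | os.PathLike) -> None:
    """Write a haplotype pair as two lines over ``{0,1,-}``."""
    try:
        with open(path, "w") as fh:
            fh.write(h.h1 + "\n" + h.h2 + "\n")
    except OSError as exc:
        raise OSError(f"writing haplotypes to {path}: {exc}") from exc


def read_haplotypes(path: str | os.PathLike) -> HaplotypePair:
    """Read a two-line haplotype file (inverse of :func:`write_haplotypes`)."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) != 2:
        raise FragmentFormatError(f"{path}: expected exactly two haplotype lines")
    return HaplotypePair(lines[0], lines[1])


def write_fragment_matrix(x: SNPMatrix, path: str | os.PathLike) -> None:
    """Write the plain matrix format with the id column."""
    with open(path, "w") as fh:
        for i in range(x.n_fragments):
            fh.write(f"{x.fragment_ids[i]} {x.row_string(i)}\n")
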