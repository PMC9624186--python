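"""Data model and file I/O for diploid codominant genotype matrices.

The central object is :class:`GenotypeMatrix`: integer allele calls for
``n_individuals x n_loci x 2`` gene copies, plus a population label per
individual.  Missing calls are ``-9`` on disk (STRUCTURE convention) and
:data:`MISSING` (``-1``) in memory.

Supported formats:

* STRUCTURE plain text, both the two-rows-per-individual dialect and the
  one-row / two-columns-per-locus dialect.
* GenePop, 2- and 3-digit allele encodings.

Population labels are strings everywhere in memory; STRUCTURE files store
consecutive integer codes with a sidecar TSV mapping code to label.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

#: in-memory missing-allele sentinel
MISSING = -1
#: on-disk missing-allele sentinel (STRUCTURE convention)
DISK_MISSING = -9


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class GenotypeMatrix:
    """Diploid multi-allelic genotypes with per-individual population labels.

    Parameters
    ----------
    individual_ids:
        Unique identifier per individual.
    pop_labels:
        Population label per individual (same length as ``individual_ids``).
    alleles:
        Integer array of shape ``(n_individuals, n_loci, 2)``.  Non-missing
        codes are non-negative; missing is :data:`MISSING`.
    locus_names:
        One name per locus.
    """

    individual_ids: list[str]
    pop_labels: list[str]
    alleles: np.ndarray
    locus_names: list[str]
    missing_code: int = MISSING

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        n = len(self.individual_ids)
        if len(self.pop_labels) != n:
            raise ValueError("pop_labels length mismatch")
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n_individuals, n_loci, 2)")
        if self.alleles.shape[0] != n:
            raise ValueError("alleles first dimension must match individual count")
        if self.alleles.shape[1] != len(self.locus_names):
            raise ValueError("alleles second dimension must match locus count")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual_ids must be unique")
        bad = (self.alleles < 0) & (self.alleles != self.missing_code)
        if bad.any():
            raise ValueError("negative allele codes other than the missing sentinel")

    # -- basic introspection -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.pop_labels:
            seen.setdefault(p)
        return list(seen)

    def pop_indices(self, pop: str) -> np.ndarray:
        """Row indices of all individuals belonging to ``pop``."""
        idx = np.flatnonzero(np.asarray(self.pop_labels, dtype=object) == pop)
        if idx.size == 0:
            raise KeyError(f"unknown population label: {pop!r}")
        return idx

    def missing_mask(self) -> np.ndarray:
        """Boolean array, True where the allele call is missing."""
        return self.alleles == self.missing_code

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.pop_labels == other.pop_labels
            and self.locus_names == other.locus_names
            and np.array_equal(self.alleles, other.alleles)
        )


@dataclass
class AlleleFrequencyTable:
    """Relative allele frequencies per (population, locus) over observed copies.

    ``freqs[(pop, locus_index)]`` maps allele code to relative frequency;
    ``sample_size[(pop, locus_index)]`` counts the gene copies observed.
    Entries with ``sample_size == 0`` have no frequency mapping.
    """

    populations: list[str]
    locus_names: list[str]
    freqs: dict[tuple[str, int], dict[int, float]] = field(default_factory=dict)
    sample_size: dict[tuple[str, int], int] = field(default_factory=dict)

    def vector(self, pop: str, locus: int, allele_order: list[int]) -> np.ndarray:
        """Frequency vector for ``pop`` at ``locus`` in the given allele order."""
        f = self.freqs.get((pop, locus), {})
        return np.array([f.get(a, 0.0) for a in allele_order])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def subset(
    g: GenotypeMatrix,
    keep: "set[str] | set[int] | list[str] | list[int]",
) -> GenotypeMatrix:
    """Restrict a matrix to a set of populations (labels) or individuals (indices).

    Order of retained individuals is preserved; loci are unchanged.
    """
    keep = list(keep)
    if not keep:
        raise ValueError("keep must be non-empty")
    if all(isinstance(k, (int, np.integer)) for k in keep):
        idx = sorted(int(k) for k in set(keep))
        for i in idx:
            if i < 0 or i >= g.n_individuals:
                raise KeyError(f"individual index out of range: {i}")
        rows = np.array(idx, dtype=int)
    else:
        labels = set(str(k) for k in keep)
        known = set(g.pop_labels)
        unknown = labels - known
        if unknown:
            raise KeyError(f"unknown population labels: {sorted(unknown)}")
        rows = np.flatnonzero([p in labels for p in g.pop_labels])
    return GenotypeMatrix(
        individual_ids=[g.individual_ids[i] for i in rows],
        pop_labels=[g.pop_labels[i] for i in rows],
        alleles=g.alleles[rows].copy(),
        locus_names=list(g.locus_names),
        missing_code=g.missing_code,
    )


def allele_frequencies(g: GenotypeMatrix) -> AlleleFrequencyTable:
    """Per-(population, locus) allele frequencies over non-missing gene copies."""
    if (g.alleles != g.missing_code).sum() == 0:
        raise ValueError("matrix has no non-missing calls")
    table = AlleleFrequencyTable(populations=g.populations, locus_names=list(g.locus_names))
    for pop in table.populations:
        rows = g.pop_indices(pop)
        for l in range(g.n_loci):
            copies = g.alleles[rows, l, :].ravel()
            copies = copies[copies != g.missing_code]
            table.sample_size[(pop, l)] = int(copies.size)
            if copies.size:
                vals, counts = np.unique(copies, return_counts=True)
                table.freqs[(pop, l)] = {
                    int(a): c / copies.size for a, c in zip(vals, counts)
                }
    return table


# ---------------------------------------------------------------------------
# STRUCTURE format
# ---------------------------------------------------------------------------


def _read_rows(path: str) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            toks = line.split()
            if toks:
                rows.append(toks)
    if not rows:
        raise FormatError(f"{path}: empty file")
    return rows


def _sidecar_path(path: str) -> str:
    return path + ".labels.tsv"


def _load_label_map(path: str) -> dict[str, str]:
    side = _sidecar_path(path)
    mapping: dict[str, str] = {}
    if os.path.exists(side):
        with open(side) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 2 and parts[0] != "code":
                    mapping[parts[0]] = parts[1]
    return mapping


def read_structure_file(path: str, one_row_per_individual: bool = False) -> GenotypeMatrix:
    """Parse a STRUCTURE-format genotype file.

    Two dialects are supported: two consecutive rows per individual (one
    allele column per locus) or one row per individual (two adjacent columns
    per locus).  An optional first line carrying only locus names (fewer
    tokens than the data rows) is treated as a header.  ``-9`` is the missing
    sentinel.  If a ``<path>.labels.tsv`` sidecar exists it maps the integer
    population column back to string labels.
    """
    rows = _read_rows(path)
    header: list[str] | None = None
    if len(rows) >= 2 and len(rows[0]) < len(rows[1]):
        header = rows[0]
        rows = rows[1:]
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        for i, r in enumerate(rows):
            if len(r) != len(rows[0]):
                raise FormatError(
                    f"{path}: ragged row {i + 1} has {len(r)} columns, expected {len(rows[0])}"
                )
    width = widths.pop()
    if width < 3:
        raise FormatError(f"{path}: rows must contain id, population and >=1 locus column")

    label_map = _load_label_map(path)

    def pop_label(tok: str) -> str:
        return label_map.get(tok, tok)

    if one_row_per_individual:
        if (width - 2) % 2:
            raise FormatError(f"{path}: odd number of allele columns in one-row dialect")
        n_loci = (width - 2) // 2
        ids = [r[0] for r in rows]
        pops = [pop_label(r[1]) for r in rows]
        alleles = np.empty((len(rows), n_loci, 2), dtype=np.int64)
        for i, r in enumerate(rows):
            vals = [int(t) for t in r[2:]]
            alleles[i] = np.array(vals, dtype=np.int64).reshape(n_loci, 2)
    else:
        if len(rows) % 2:
            raise FormatError(f"{path}: odd row count in two-row dialect")
        n_loci = width - 2
        ids, pops = [], []
        alleles = np.empty((len(rows) // 2, n_loci, 2), dtype=np.int64)
        for i in range(0, len(rows), 2):
            r1, r2 = rows[i], rows[i + 1]
            if r1[0] != r2[0]:
                raise FormatError(
                    f"{path}: rows {i + 1}/{i + 2} carry different ids ({r1[0]!r} vs {r2[0]!r})"
                )
            ids.append(r1[0])
            pops.append(pop_label(r1[1]))
            alleles[i // 2, :, 0] = [int(t) for t in r1[2:]]
            alleles[i // 2, :, 1] = [int(t) for t in r2[2:]]

    alleles[alleles == DISK_MISSING] = MISSING
    if (alleles < 0).any() and not np.isin(alleles[alleles < 0], [MISSING]).all():
        raise FormatError(f"{path}: negative allele codes other than -9")
    locus_names = header if header and len(header) == n_loci else [
        f"L{j + 1}" for j in range(n_loci)
    ]
    return GenotypeMatrix(ids, pops, alleles, locus_names)


def write_structure_file(
    g: GenotypeMatrix,
    path: str,
    one_row_per_individual: bool = False,
    header: bool = True,
) -> None:
    """Write ``g`` in STRUCTURE format with integer population codes.

    Emits a ``<path>.labels.tsv`` sidecar mapping codes to labels; missing
    alleles are written as ``-9``.
    """
    if g.n_loci == 0:
        raise ValueError("refusing to write a matrix with zero loci")
    pops = g.populations
    code = {p: i + 1 for i, p in enumerate(pops)}
    out = g.alleles.copy()
    out[out == g.missing_code] = DISK_MISSING
    with open(path, "w") as fh:
        if header:
            fh.write(" ".join(g.locus_names) + "\n")
        for i, (ind, pop) in enumerate(zip(g.individual_ids, g.pop_labels)):
            if one_row_per_individual:
                vals = " ".join(str(v) for v in out[i].ravel())
                fh.write(f"{ind} {code[pop]} {vals}\n")
            else:
                for c in (0, 1):
                    vals = " ".join(str(v) for v in out[i, :, c])
                    fh.write(f"{ind} {code[pop]} {vals}\n")
    with open(_sidecar_path(path), "w") as fh:
        fh.write("code\tlabel\n")
        for p, c in code.items():
            fh.write(f"{c}\t{p}\n")


# ---------------------------------------------------------------------------
# GenePop format
# ---------------------------------------------------------------------------


def read_genepop(path: str) -> GenotypeMatrix:
    """Parse a GenePop file (2- or 3-digit allele encoding).

    Each ``Pop`` block becomes one population (labelled ``Pop1``, ``Pop2``, ...
    unless sample ids share a common prefix, in which case that is cosmetic
    only — labels stay positional).  Allele code 0 (``00``/``000``) means
    missing.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if len(lines) < 3:
        raise FormatError(f"{path}: truncated GenePop file")
    body = lines[1:]  # first line is a free-text title

    # locus names: either one per line up to the first Pop, or one
    # comma-separated line
    locus_names: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        chunk = body[i]
        locus_names.extend(t.strip() for t in chunk.split(",") if t.strip())
        i += 1
    if i == len(body):
        raise FormatError(f"{path}: no 'Pop' keyword found")
    if not locus_names:
        raise FormatError(f"{path}: no locus names before first 'Pop'")

    n_loci = len(locus_names)
    ids: list[str] = []
    pops: list[str] = []
    geno_rows: list[list[int]] = []
    pop_no = 0
    digit_width: int | None = None
    for ln in body[i:]:
        if ln.strip().lower() == "pop":
            pop_no += 1
            continue
        if "," not in ln:
            raise FormatError(f"{path}: sample line missing comma separator: {ln!r}")
        name, geno = ln.split(",", 1)
        toks = geno.split()
        if len(toks) != n_loci:
            raise FormatError(
                f"{path}: sample {name.strip()!r} has {len(toks)} genotypes, expected {n_loci}"
            )
        row: list[int] = []
        for tok in toks:
            if len(tok) not in (4, 6):
                raise FormatError(f"{path}: genotype {tok!r} is not 2- or 3-digit encoded")
            w = len(tok) // 2
            if digit_width is None:
                digit_width = w
            elif w != digit_width:
                raise FormatError(f"{path}: inconsistent allele digit width")
            a1, a2 = int(tok[:w]), int(tok[w:])
            row.extend([a1 if a1 else MISSING, a2 if a2 else MISSING])
        ids.append(name.strip())
        pops.append(f"Pop{pop_no}")
        geno_rows.append(row)
    if not ids:
        raise FormatError(f"{path}: no samples")
    alleles = np.array(geno_rows, dtype=np.int64).reshape(len(ids), n_loci, 2)
    return GenotypeMatrix(ids, pops, alleles, locus_names)


def write_genepop(g: GenotypeMatrix, path: str, digits: int = 3, title: str = "hierstruct export") -> None:
    """Write ``g`` as a GenePop file. Allele codes must fit the digit width."""
    if g.n_loci == 0:
        raise ValueError("refusing to write a matrix with zero loci")
    hi = 10**digits - 1
    valid = g.alleles[g.alleles != g.missing_code]
    if valid.size and (valid.max() > hi or valid.min() < 1):
        raise ValueError(f"allele codes must lie in 1..{hi} for {digits}-digit GenePop")
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for name in g.locus_names:
            fh.write(name + "\n")
        for pop in g.populations:
            fh.write("Pop\n")
            for i in g.pop_indices(pop):
                parts = []
                for l in range(g.n_loci):
                    a, b = g.alleles[i, l]
                    a = 0 if a == g.missing_code else int(a)
                    b = 0 if b == g.missing_code else int(b)
                    parts.append(f"{a:0{digits}d}{b:0{digits}d}")
                fh.write(f"{g.individual_ids[i]} , " + " ".join(parts) + "\n")
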