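"""PLINK binary genotype I/O and estimate files.

Reads and writes the small family of plain file formats the toolkit
touches: PLINK binary genotype trios (``.bed``/``.bim``/``.fam``),
population-label files (``.ind``, one label per individual, ``-`` marking
individuals of unknown ancestry), and the whitespace-delimited ``.Q`` /
``.P`` matrices of estimated ancestry fractions and allele frequencies.

Genotypes are held as an I×J ``int8`` matrix of counts of the A1 allele
(0, 1, 2) with ``MISSING`` (−1) as the sentinel.  Only the SNP-major
``.bed`` dialect (mode byte ``0x01``) is supported; the long-obsolete
individual-major dialect is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "PopulationLabels",
    "GenotypeFormatError",
    "read_plink_bed",
    "write_plink_bed",
    "read_ind_file",
    "write_ind_file",
    "write_estimates",
    "read_estimates",
]

MISSING: int = -1

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# PLINK 2-bit codes (within a byte, LSB first): 00 -> hom A1 (2 copies),
# 10 -> het (1 copy), 11 -> hom A2 (0 copies), 01 -> missing.
_CODE_TO_COUNT = np.array([2, MISSING, 1, 0], dtype=np.int8)
_COUNT_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11, MISSING: 0b01}


class GenotypeFormatError(ValueError):
    """Raised for malformed or unsupported PLINK files."""


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes: counts of the A1 allele per (individual, marker).

    Attributes
    ----------
    counts : ndarray of int8, shape (I, J)
        Entries in {0, 1, 2} or ``MISSING`` (−1).
    individual_ids, marker_ids : list of str
        Row and column identifiers.
    allele1, allele2 : list of str
        Per-marker allele labels; ``counts`` counts ``allele1``.
    """

    counts: np.ndarray
    individual_ids: list[str]
    marker_ids: list[str]
    allele1: list[str] = field(default_factory=list)
    allele2: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int8)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        I, J = self.counts.shape
        if I < 1 or J < 1:
            raise ValueError("need at least one individual and one marker")
        if len(self.individual_ids) != I:
            raise ValueError("individual_ids length does not match matrix")
        if len(self.marker_ids) != J:
            raise ValueError("marker_ids length does not match matrix")
        valid = np.isin(self.counts, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("genotype entries must be 0, 1, 2 or missing")
        if not self.allele1:
            self.allele1 = ["A"] * J
        if not self.allele2:
            self.allele2 = ["B"] * J

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_markers(self) -> int:
        return self.counts.shape[1]

    def observed_mask(self) -> np.ndarray:
        """Boolean I×J mask, True where the genotype is non-missing."""
        return self.counts != MISSING


@dataclass
class PopulationLabels:
    """Optional per-individual population assignments for supervised mode.

    ``assignments[i]`` is the population name of individual i, or ``None``
    for individuals whose ancestry is to be estimated.  ``population_names``
    lists the distinct labels in order of first appearance.
    """

    assignments: list[str | None]
    population_names: list[str]

    def __post_init__(self) -> None:
        seen = [a for a in self.assignments if a is not None]
        if set(seen) != set(self.population_names):
            raise ValueError("population_names must equal the set of used labels")
        if len(set(self.population_names)) != len(self.population_names):
            raise ValueError("population_names must be distinct")
        if not self.population_names:
            raise ValueError("at least one individual must carry a label")

    @property
    def n_populations(self) -> int:
        return len(self.population_names)

    def labeled_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.assignments) if a is not None]


def read_plink_bed(bed_path, bim_path=None, fam_path=None) -> GenotypeMatrix:
    """Read a PLINK binary trio into a :class:`GenotypeMatrix`.

    ``bim_path``/``fam_path`` default to the ``.bed`` path with the
    extension swapped.  The A1 allele of the ``.bim`` file is the counted
    allele, so a 2-bit code ``00`` decodes to 2 copies.
    """
    bed_path = Path(bed_path)
    bim_path = Path(bim_path) if bim_path else bed_path.with_suffix(".bim")
    fam_path = Path(fam_path) if fam_path else bed_path.with_suffix(".fam")

    fam_rows = _read_table(fam_path)
    bim_rows = _read_table(bim_path)
    if not fam_rows or not bim_rows:
        raise GenotypeFormatError("empty .fam or .bim file")
    individual_ids = [r[1] if len(r) > 1 else r[0] for r in fam_rows]
    marker_ids = [r[1] for r in bim_rows]
    allele1 = [r[4] if len(r) > 4 else "A" for r in bim_rows]
    allele2 = [r[5] if len(r) > 5 else "B" for r in bim_rows]
    I, J = len(fam_rows), len(bim_rows)

    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw.size < 3 or bytes(raw[:2]) != _BED_MAGIC:
        raise GenotypeFormatError(f"{bed_path} lacks the PLINK .bed magic bytes")
    if raw[2] == 0x00:
        raise GenotypeFormatError(
            "individual-major .bed files are not supported; "
            "convert to SNP-major with a modern PLINK"
        )
    if raw[2] != _SNP_MAJOR:
        raise GenotypeFormatError(f"unknown .bed mode byte {raw[2]:#x}")

    bytes_per_snp = (I + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * J:
        raise GenotypeFormatError(
            f"{bed_path}: expected {bytes_per_snp * J} data bytes for "
            f"{I} individuals x {J} markers, found {body.size} (truncated?)"
        )
    # Unpack 2-bit codes, LSB-first within each byte: J x I after trimming pad.
    mat = body.reshape(J, bytes_per_snp)
    codes = np.empty((J, bytes_per_snp * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (mat >> (2 * shift)) & 0b11
    counts = _CODE_TO_COUNT[codes[:, :I]].T.copy()  # I x J

    return GenotypeMatrix(counts, individual_ids, marker_ids, allele1, allele2)


def write_plink_bed(genotypes: GenotypeMatrix, path_prefix) -> tuple[Path, Path, Path]:
    """Write ``<prefix>.bed/.bim/.fam``; exact round-trip with :func:`read_plink_bed`."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    I, J = genotypes.counts.shape
    bytes_per_snp = (I + 3) // 4

    code = np.empty((J, bytes_per_snp * 4), dtype=np.uint8)
    code[:] = 0  # pad bits: 00
    counts_t = genotypes.counts.T  # J x I
    for val, c in _COUNT_TO_CODE.items():
        code[:, :I][counts_t == val] = c
    packed = np.zeros((J, bytes_per_snp), dtype=np.uint8)
    for shift in range(4):
        packed |= code[:, shift::4] << (2 * shift)

    bed = Path(str(prefix) + ".bed")
    with open(bed, "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        packed.tofile(fh)

    bim = Path(str(prefix) + ".bim")
    with open(bim, "w") as fh:
        for j, mid in enumerate(genotypes.marker_ids):
            fh.write(
                f"1\t{mid}\t0\t{j + 1}\t{genotypes.allele1[j]}\t{genotypes.allele2[j]}\n"
            )

    fam = Path(str(prefix) + ".fam")
    with open(fam, "w") as fh:
        for iid in genotypes.individual_ids:
            fh.write(f"{iid}\t{iid}\t0\t0\t0\t-9\n")
    return bed, bim, fam


def read_ind_file(path, individual_ids: list[str]) -> PopulationLabels:
    """Read a ``.ind`` file: one population label per line, ``-`` = unlabeled.

    Lines align with the ``.fam`` / ``individual_ids`` order.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln != ""]
    if len(lines) != len(individual_ids):
        raise ValueError(
            f".ind file has {len(lines)} labels but there are "
            f"{len(individual_ids)} individuals"
        )
    assignments: list[str | None] = [None if tok == "-" else tok.split()[-1] for tok in lines]
    names: list[str] = []
    for a in assignments:
        if a is not None and a not in names:
            names.append(a)
    if not names:
        raise ValueError(".ind file labels no individuals; supervised mode unusable")
    return PopulationLabels(assignments, names)


def write_ind_file(labels: PopulationLabels, path) -> Path:
    path = Path(path)
    path.write_text("".join((a or "-") + "\n" for a in labels.assignments))
    return path


def write_estimates(Q: np.ndarray, F: np.ndarray, path_prefix, K: int) -> tuple[Path, Path]:
    """Write ``<prefix>.<K>.Q`` (I rows) and ``<prefix>.<K>.P`` (J rows, K cols).

    Six decimal places, whitespace-delimited, matching the conventional
    output granularity of ancestry-estimation tools.
    """
    Q = np.asarray(Q, dtype=float)
    F = np.asarray(F, dtype=float)
    if Q.ndim != 2 or F.ndim != 2 or Q.shape[1] != K or F.shape[0] != K:
        raise ValueError("Q must be I x K and F must be K x J")
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    q_path = Path(f"{prefix}.{K}.Q")
    p_path = Path(f"{prefix}.{K}.P")
    np.savetxt(q_path, Q, fmt="%.6f", delimiter=" ")
    np.savetxt(p_path, F.T, fmt="%.6f", delimiter=" ")
    return q_path, p_path


def read_estimates(path_prefix, K: int) -> tuple[np.ndarray, np.ndarray]:
    """Read back ``.Q``/``.P`` files written by :func:`write_estimates`."""
    prefix = Path(path_prefix)
    Q = np.loadtxt(f"{prefix}.{K}.Q", ndmin=2)
    P = np.loadtxt(f"{prefix}.{K}.P", ndmin=2)
    return Q, P.T


def _read_table(path) -> list[list[str]]:
    rows = []
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if ln:
            rows.append(ln.split())
    return rows
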