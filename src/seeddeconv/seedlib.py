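"""Oligonucleotide handling, seed families and the membership matrix.

An arrayed RNAi screen assays one siRNA *pool* per well, typically four
independent 19-mer duplexes targeting the same gene.  Each guide strand
carries a 6-nucleotide *seed* (canonically positions 2-7, 1-based, read
5'->3' on the guide strand) that dominates miRNA-style target recognition.
All pools containing at least one oligo with a given seed form that seed's
*family*; family membership is the binary design matrix of the off-target
deconvolution model.

There are 4**6 = 4096 possible seeds, so the family space is small and
enumerable while typical libraries contribute ~4000 observed families.
"""

from __future__ import annotations

import csv
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .errors import EmptyLibrary, InvalidAlphabet, SequenceTooShort

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")
SEED_LENGTH = 6
#: total number of distinct 6-mer seeds over {A,C,G,U}
SEED_SPACE_SIZE = len(RNA_ALPHABET) ** SEED_LENGTH

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def normalize_sequence(raw: str) -> str:
    """Uppercase and convert DNA (T) to RNA (U); reject anything else.

    Commercial library files mix DNA and RNA conventions, so T is silently
    accepted; any residual non-ACGU character raises :class:`InvalidAlphabet`.
    """
    if not raw:
        raise InvalidAlphabet("empty sequence")
    seq = raw.strip().upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise InvalidAlphabet(f"non-ACGU characters {sorted(bad)} in {raw!r}")
    return seq


def reverse_complement(seq: str) -> str:
    """RNA reverse complement (A<->U, G<->C), 5'->3'."""
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise InvalidAlphabet(f"non-ACGU characters {sorted(bad)} in {seq!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def enumerate_seed_space() -> list[str]:
    """All 4096 possible 6-mer seeds, lexicographic order."""
    return ["".join(p) for p in itertools.product("ACGU", repeat=SEED_LENGTH)]


@dataclass(frozen=True)
class OligoRecord:
    """One siRNA oligonucleotide of a pool.

    ``sequence`` is stored normalized (RNA, uppercase).  ``declared_strand``
    says which strand the library file reported; seeds are always read from
    the guide (antisense) strand, so passenger-strand records are
    reverse-complemented on access.
    """

    pool_id: str
    gene_id: str
    sequence: str
    declared_strand: str = "guide"

    def __post_init__(self) -> None:
        if self.declared_strand not in ("guide", "passenger"):
            raise ValueError(f"unknown strand {self.declared_strand!r}")
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))

    @property
    def guide_sequence(self) -> str:
        if self.declared_strand == "passenger":
            return reverse_complement(self.sequence)
        return self.sequence


def extract_seed(oligo: OligoRecord | str, seed_start: int = 2) -> str:
    """The 6-mer at guide positions ``seed_start..seed_start+5`` (1-based).

    Default window 2-7, the best-supported determinant of miRNA-style target
    specificity.  A plain string argument is treated as a guide-strand
    sequence (already normalized).
    """
    if not 1 <= seed_start <= 14:
        raise ValueError(f"seed_start must be in 1..14, got {seed_start}")
    guide = oligo.guide_sequence if isinstance(oligo, OligoRecord) else oligo
    if len(guide) < seed_start + SEED_LENGTH - 1:
        raise SequenceTooShort(
            f"length {len(guide)} < {seed_start + SEED_LENGTH - 1} needed for "
            f"window starting at {seed_start}"
        )
    return guide[seed_start - 1 : seed_start - 1 + SEED_LENGTH]


@dataclass
class SeedFamilyIndex:
    """Mapping seed -> set of member pool_ids for one seed window.

    A pool belongs to a family if *any* of its oligos carries the seed;
    membership is binary, so duplicated seeds within a pool count once.
    """

    seed_start: int
    families: dict[str, set[str]] = field(default_factory=dict)
    seed_length: int = SEED_LENGTH

    @property
    def family_size(self) -> dict[str, int]:
        return {seed: len(members) for seed, members in self.families.items()}

    @property
    def seeds(self) -> list[str]:
        """Observed seeds in deterministic (lexicographic) order."""
        return sorted(self.families)

    @property
    def pools(self) -> set[str]:
        out: set[str] = set()
        for members in self.families.values():
            out |= members
        return out


def build_family_index(
    oligos, seed_start: int = 2, *, on_short: str = "drop"
) -> SeedFamilyIndex:
    """Group pools into seed families for one window.

    Oligos too short for the window are dropped with a logged count
    (``on_short="drop"``) or raise (``on_short="raise"``).
    """
    families: dict[str, set[str]] = {}
    n_short = 0
    n_valid = 0
    for oligo in oligos:
        try:
            seed = extract_seed(oligo, seed_start)
        except SequenceTooShort:
            if on_short == "raise":
                raise
            n_short += 1
            continue
        n_valid += 1
        families.setdefault(seed, set()).add(oligo.pool_id)
    if n_short:
        logger.warning("dropped %d oligos too short for window %d", n_short, seed_start)
    if n_valid == 0:
        raise EmptyLibrary("no valid oligo records")
    return SeedFamilyIndex(seed_start=seed_start, families=families)


@dataclass
class MembershipMatrix:
    """Binary pool x seed-family design matrix.

    ``matrix[i, j] == 1`` iff pool ``pool_ids[i]`` has at least one oligo in
    family ``seeds[j]``.  Stored sparse (CSC) — a genome-wide library is
    ~20k pools x ~4k families with <=4 nonzeros per row.
    """

    pool_ids: list[str]
    seeds: list[str]
    matrix: sparse.csc_matrix

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def column_members(self, j: int) -> np.ndarray:
        """Row indices of the pools in family ``seeds[j]``."""
        return self.matrix.indices[self.matrix.indptr[j] : self.matrix.indptr[j + 1]]

    def member_index_arrays(self) -> list[np.ndarray]:
        return [self.column_members(j) for j in range(len(self.seeds))]

    def family_sizes(self) -> np.ndarray:
        return np.diff(self.matrix.indptr)

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()


def build_membership_matrix(index: SeedFamilyIndex, pool_order) -> MembershipMatrix:
    """Assemble the design matrix with rows in ``pool_order``.

    Columns are observed seeds in lexicographic order; pools absent from
    every family get an all-zero row.
    """
    pool_order = list(pool_order)
    row_of = {p: i for i, p in enumerate(pool_order)}
    seeds = index.seeds
    rows: list[int] = []
    cols: list[int] = []
    for j, seed in enumerate(seeds):
        for pool in index.families[seed]:
            i = row_of.get(pool)
            if i is not None:
                rows.append(i)
                cols.append(j)
    mat = sparse.csc_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(pool_order), len(seeds)),
    )
    return MembershipMatrix(pool_ids=pool_order, seeds=seeds, matrix=mat)


def read_library_csv(path, *, strand: str = "guide") -> list[OligoRecord]:
    """Read a library annotation file: columns pool_id, gene_id, oligo_seq.

    ``strand`` declares the orientation of every sequence in the file;
    no auto-detection is attempted.
    """
    oligos: list[OligoRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"pool_id", "oligo_seq"} <= set(reader.fieldnames):
            raise InvalidAlphabet(
                f"{path}: expected header with pool_id, gene_id, oligo_seq"
            )
        for row in reader:
            oligos.append(
                OligoRecord(
                    pool_id=row["pool_id"],
                    gene_id=row.get("gene_id", ""),
                    sequence=row["oligo_seq"],
                    declared_strand=strand,
                )
            )
    if not oligos:
        raise EmptyLibrary(f"{path}: no oligo rows")
    return oligos


def write_family_cache(index: SeedFamilyIndex, path) -> None:
    """Serialize a family index as a (seed, pool_id) CSV cache."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["seed", "pool_id"])
        for seed in index.seeds:
            for pool in sorted(index.families[seed]):
                writer.writerow([seed, pool])


def read_family_cache(path, seed_start: int = 2) -> SeedFamilyIndex:
    """Load a (seed, pool_id) CSV cache back into a family index."""
    families: dict[str, set[str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"seed", "pool_id"} <= set(reader.fieldnames):
            raise InvalidAlphabet(f"{path}: expected header with seed, pool_id")
        for row in reader:
            seed = normalize_sequence(row["seed"])
            if len(seed) != SEED_LENGTH:
                raise InvalidAlphabet(f"{path}: seed {seed!r} is not a 6-mer")
            families.setdefault(seed, set()).add(row["pool_id"])
    if not families:
        raise EmptyLibrary(f"{path}: empty cache")
    return SeedFamilyIndex(seed_start=seed_start, families=families)
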