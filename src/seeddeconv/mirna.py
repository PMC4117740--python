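"""Matching detected off-target seeds to annotated miRNAs.

A seed family detected in a screen becomes biologically interpretable when
an annotated miRNA shares the same seed: the siRNAs are then acting as
mimics of that miRNA.  A miRNA's seed is the 6-mer at positions 2-7 of its
mature sequence — the canonical targeting anchor — regardless of which
window the screen analysis used (pass ``seed_start`` to mirror the screen
window instead).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

from Bio import SeqIO

from .errors import InvalidAlphabet, UnreadableFile
from .seedlib import SEED_LENGTH, normalize_sequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MirnaRecord:
    """One mature miRNA with its derived seed."""

    name: str
    mature_sequence: str
    seed: str


def _make_record(name: str, sequence: str, seed_start: int) -> MirnaRecord | None:
    try:
        seq = normalize_sequence(sequence)
    except InvalidAlphabet:
        logger.warning("skipping %s: invalid sequence", name)
        return None
    if len(seq) < seed_start + SEED_LENGTH - 1:
        logger.warning("skipping %s: mature sequence shorter than 7 nt", name)
        return None
    return MirnaRecord(
        name=name,
        mature_sequence=seq,
        seed=seq[seed_start - 1 : seed_start - 1 + SEED_LENGTH],
    )


def load_mirna_table(path, *, seed_start: int = 2) -> list[MirnaRecord]:
    """Load mature miRNAs from a miRBase-style FASTA or a (name, sequence) CSV.

    Entries too short to carry the seed window are rejected with a warning.
    """
    records: list[MirnaRecord] = []
    with open(path, encoding="utf-8") as fh:
        first = fh.read(1)
    if first == ">":
        for rec in SeqIO.parse(path, "fasta"):
            made = _make_record(rec.id, str(rec.seq), seed_start)
            if made:
                records.append(made)
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            rows = [r for r in reader if r and not r[0].startswith("#")]
        if not rows or len(rows[0]) < 2:
            raise UnreadableFile(f"{path}: expected FASTA or 2-column CSV")
        if rows[0][0].strip().lower() in ("name", "mirna", "mirna_name"):
            rows = rows[1:]
        for row in rows:
            made = _make_record(row[0].strip(), row[1].strip(), seed_start)
            if made:
                records.append(made)
    if not records:
        raise UnreadableFile(f"{path}: no usable miRNA records")
    return records


def match_seeds(
    significant_seeds, mirnas: list[MirnaRecord]
) -> dict[str, list[str]]:
    """Map each detected seed to the annotated miRNAs sharing it.

    Matching is exact string equality after normalization; unmatched seeds
    map to an empty list.
    """
    by_seed: dict[str, list[str]] = {}
    for m in mirnas:
        by_seed.setdefault(m.seed, []).append(m.name)
    out: dict[str, list[str]] = {}
    for seed in sorted(significant_seeds):
        norm = normalize_sequence(seed)
        if len(norm) != SEED_LENGTH:
            raise InvalidAlphabet(f"seed {seed!r} is not a 6-mer")
        out[norm] = sorted(by_seed.get(norm, []))
    return out
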