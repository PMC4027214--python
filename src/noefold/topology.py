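"""DNA duplex topology: sequences, Watson-Crick pairing, residue numbering.

The duplex container is the single source of truth for numbering used
throughout the package: sense-strand residues are numbered 1..n in the
5'->3' direction and complement-strand residues n+1..2n, also 5'->3' on
their own strand, so that residue i pairs with residue 2n+1-i (the two
strands are antiparallel).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: The 15-mer estrogen-response-element duplex of the TFF1 promoter
#: (sense strand, 5'->3'); its complement is TGGCCACCGTGACCT.
TFF1_ERE_SENSE = "AGGTCACGGTGGCCA"

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class SequenceError(ValueError):
    """Raised for sequences containing non-ACGT characters or empty input."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A<->T, G<->C, reversed)."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:  # pragma: no cover - message formatting
        raise SequenceError(f"non-ACGT character {exc.args[0]!r} in sequence") from None


@dataclass(frozen=True)
class DuplexTopology:
    """A blunt-ended B-form DNA duplex with the package's numbering scheme.

    Attributes
    ----------
    sense_sequence, complement_sequence:
        Both 5'->3'. ``complement_sequence`` is the reverse complement of
        ``sense_sequence``.
    pairs:
        ``(sense_residue, complement_residue)`` tuples; residue i pairs
        with 2n+1-i.
    """

    sense_sequence: str
    complement_sequence: str
    pairs: tuple[tuple[int, int], ...] = field(repr=False)

    @property
    def n_pairs(self) -> int:
        return len(self.sense_sequence)

    @property
    def residue_numbers(self) -> range:
        return range(1, 2 * self.n_pairs + 1)

    def base(self, residue: int) -> str:
        """One-letter base identity of a residue number (1..2n)."""
        n = self.n_pairs
        if not 1 <= residue <= 2 * n:
            raise KeyError(f"residue {residue} outside 1..{2 * n}")
        if residue <= n:
            return self.sense_sequence[residue - 1]
        return self.complement_sequence[residue - n - 1]

    def partner(self, residue: int) -> int:
        """The Watson-Crick partner of a residue."""
        n = self.n_pairs
        if not 1 <= residue <= 2 * n:
            raise KeyError(f"residue {residue} outside 1..{2 * n}")
        return 2 * n + 1 - residue

    def strand_of(self, residue: int) -> str:
        """'sense' or 'complement'."""
        return "sense" if residue <= self.n_pairs else "complement"

    def pair_kind(self, pair_index: int) -> str:
        """'AT' or 'GC' for pair ``pair_index`` (0-based along the sense strand)."""
        b = self.sense_sequence[pair_index]
        return "AT" if b in "AT" else "GC"

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "sense_sequence": self.sense_sequence,
                "complement_sequence": self.complement_sequence,
                "pairs": list(self.pairs),
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def build_duplex(sense: str) -> DuplexTopology:
    """Build the duplex topology for a sense strand.

    The complement is the reverse complement, numbered n+1..2n in its own
    5'->3' direction, so pairing is (i, 2n+1-i).
    """
    sense = sense.strip().upper()
    if not sense:
        raise SequenceError("empty sequence")
    bad = set(sense) - set("ACGT")
    if bad:
        raise SequenceError(f"non-ACGT character(s) {sorted(bad)} in sequence")
    n = len(sense)
    pairs = tuple((i, 2 * n + 1 - i) for i in range(1, n + 1))
    return DuplexTopology(sense, reverse_complement(sense), pairs)


def read_fasta_duplex(path: str | Path) -> DuplexTopology:
    """Build a duplex from the first record of a FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    return build_duplex(str(records[0].seq))


def count_imino_protons(
    topology: DuplexTopology, exclude_terminal: bool = True
) -> tuple[int, int]:
    """Count observable Watson-Crick imino protons, one per base pair.

    A:T / T:A pairs contribute a thymine H3 imino proton and G:C / C:G
    pairs a guanine H1.  Terminal pairs exchange rapidly with water (end
    fraying) and are excluded when ``exclude_terminal`` is set.

    Returns ``(thymine_H3_count, guanine_H1_count)``.
    """
    n = topology.n_pairs
    t_h3 = g_h1 = 0
    for idx in range(n):
        if exclude_terminal and idx in (0, n - 1):
            continue
        if topology.pair_kind(idx) == "AT":
            t_h3 += 1
        else:
            g_h1 += 1
    return t_h3, g_h1
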