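"""Sequence registry for the bipartite 16S rRNA decoding A-site models.

The prokaryotic model is a two-strand (bipartite) construct spanning the
helix 44 region that carries both the paromomycin/kanamycin and the
hygromycin B aminoglycoside binding pockets.  The eukaryotic (human-like)
model differs from it by six substitutions (A1408G, A1410U, C1411A on
strand A; G1489U, U1490A, G1491A on strand B).  Three 2'-O-methyl decamers
(1489, 1490, 1491 -- named after the 5'-most E. coli position of their
target window) are fully complementary to the prokaryotic strand B and
carry three, two and one mismatches against the eukaryotic strand B.

Residues are labelled with E. coli small-subunit numbering.  The default
numbering is an affine continuation map (strand A position k -> 1396+k,
strand B position k -> 1483+k) anchored on the text-verifiable labels
(G1401/C1407/C1412 pair names, A1493 at strand-B position 10, the
1489..1498 target window); it is overridable per strand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

__all__ = [
    "Chemistry",
    "RnaStrand",
    "RnaConstruct",
    "MismatchReport",
    "build_registry",
    "count_mismatches",
    "ecoli_label",
    "reverse_complement",
]

_ALPHABET = frozenset("ACGU")

#: Watson-Crick complement; G:U wobbles deliberately count as mismatches
#: (the one/two/three mismatch counts of the oligomers only reconcile under
#: strict A:U / G:C matching).
_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}


class Chemistry(str, Enum):
    RNA = "RNA"
    OME2 = "2OMe-RNA"


def reverse_complement(sequence: str) -> str:
    """Strict Watson-Crick reverse complement of an RNA sequence."""
    return str(Seq(sequence).reverse_complement_rna())


@dataclass(frozen=True)
class RnaStrand:
    """A single oligoribonucleotide strand, 5'->3'.

    ``numbering`` maps each 1-based position to an E. coli residue label
    such as ``"A1493"``, or ``"ext"`` for positions the user declares as
    terminal extensions outside the ribosomal numbering.
    """

    id: str
    sequence: str
    chemistry: Chemistry = Chemistry.RNA
    numbering: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"strand {self.id!r}: empty sequence")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(f"strand {self.id!r}: invalid symbols {sorted(bad)}")
        if self.numbering:
            expected = set(range(1, len(self.sequence) + 1))
            if set(self.numbering) != expected:
                raise ValueError(
                    f"strand {self.id!r}: numbering must cover positions "
                    f"1..{len(self.sequence)} exactly once"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def label(self, position: int) -> str:
        return ecoli_label(self, position)

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "sequence": self.sequence,
            "chemistry": self.chemistry.value,
            "numbering": {str(k): v for k, v in self.numbering.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RnaStrand":
        return cls(
            id=d["id"],
            sequence=d["sequence"],
            chemistry=Chemistry(d["chemistry"]),
            numbering={int(k): v for k, v in d.get("numbering", {}).items()},
        )


@dataclass(frozen=True)
class RnaConstruct:
    """A bipartite duplex model: strand A + strand B + declared reference pairs.

    ``reference_pairs`` lists (positionA, positionB) canonical Watson-Crick
    pairs of the reference secondary structure; they are declared, not
    predicted, and every pair must be sequence-complementary.
    """

    label: str
    strandA: RnaStrand
    strandB: RnaStrand
    reference_pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for (i, j) in self.reference_pairs:
            a = self.strandA.sequence[i - 1]
            b = self.strandB.sequence[j - 1]
            if _WC[a] != b:
                raise ValueError(
                    f"construct {self.label!r}: reference pair "
                    f"({i},{j}) = {a}:{b} is not Watson-Crick complementary"
                )

    def pair_labels(self) -> list[tuple[str, str]]:
        return [
            (self.strandA.label(i), self.strandB.label(j))
            for i, j in self.reference_pairs
        ]

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "strandA": self.strandA.to_dict(),
            "strandB": self.strandB.to_dict(),
            "reference_pairs": [list(p) for p in self.reference_pairs],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RnaConstruct":
        return cls(
            label=d["label"],
            strandA=RnaStrand.from_dict(d["strandA"]),
            strandB=RnaStrand.from_dict(d["strandB"]),
            reference_pairs=tuple(tuple(p) for p in d["reference_pairs"]),
        )


@dataclass(frozen=True)
class MismatchReport:
    """Best antiparallel hybridization window of an oligomer on a target."""

    oligomer_id: str
    target_id: str
    window_start: int  # 1-based position on the target
    match_flags: tuple[bool, ...]  # indexed along the oligomer, 5'->3'

    @property
    def mismatch_count(self) -> int:
        return sum(not f for f in self.match_flags)

    @property
    def window_length(self) -> int:
        return len(self.match_flags)


def ecoli_label(strand: RnaStrand, position: int) -> str:
    """E. coli residue label of ``position`` (1-based) on ``strand``."""
    if not 1 <= position <= len(strand):
        raise IndexError(
            f"position {position} out of range 1..{len(strand)} "
            f"for strand {strand.id!r}"
        )
    if strand.numbering:
        return strand.numbering[position]
    return "ext"


def count_mismatches(oligomer: RnaStrand, target: RnaStrand) -> MismatchReport:
    """Best contiguous antiparallel-complement window of ``oligomer`` on ``target``.

    The oligomer (5'->3') is slid over every contiguous target window of its
    own length; within a window the oligomer position k pairs the target
    position ``window_end - k + 1`` (hybridization is antiparallel).  Strict
    A:U / G:C matches count; everything else, including G:U wobbles, is a
    mismatch.  Ties are broken by the smallest window start.
    """
    L, N = len(oligomer), len(target)
    if L > N:
        raise ValueError(
            f"oligomer {oligomer.id!r} (length {L}) longer than "
            f"target {target.id!r} (length {N})"
        )
    best: MismatchReport | None = None
    for start in range(1, N - L + 2):
        flags = tuple(
            _WC[oligomer.sequence[k]] == target.sequence[start + L - 2 - k]
            for k in range(L)
        )
        report = MismatchReport(oligomer.id, target.id, start, flags)
        if best is None or report.mismatch_count < best.mismatch_count:
            best = report
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Default registry
# ---------------------------------------------------------------------------

_PROK_A = "CCGCGCCCGUCACACCACCCG"
_PROK_B = "GGGUGGUGAAGUCGUAACGCGGC"
_EUK_A = "CCGCGCCCGUCGCUACACCCG"
_EUK_B = "GGGUGUAAAAGUCGUAACGCGGC"
_OLIGOS = {"1489": "ACGACUUCAC", "1490": "UACGACUUCA", "1491": "UUACGACUUC"}

#: Reference canonical pairs of the prokaryotic duplex, (posA, posB).
#: Anchored on the named pairs G1401:C1501 (5,18), C1407:G1494 (11,11) and
#: C1412:G1488 (16,5); four additional terminal pairs at each end; the
#: paromomycin/kanamycin bulge (A1408, A1492, A1493) and the hygromycin B
#: pocket residues (C1402, C1403, U1406 / U1495, U1498, A1499, A1500) are
#: unpaired or non-canonical and therefore absent from the reference list.
_PROK_PAIRS: tuple[tuple[int, int], ...] = (
    (1, 22), (2, 21), (3, 20), (4, 19), (5, 18),      # 1397:1505 .. 1401:1501
    (8, 14), (9, 13),                                  # 1404:1497, 1405:1496
    (11, 11),                                          # 1407:1494
    (13, 8), (14, 7), (15, 6), (16, 5), (17, 4),       # 1409:1491 .. 1413:1487
    (18, 3), (19, 2), (20, 1),                         # 1414:1486 .. 1416:1484
)
#: The eukaryotic mutations break C1409:G1491 (-> C:A); the A1410:U1490 and
#: C1411:G1489 pairs become U1410:A1490 and A1411:U1489 and stay canonical.
_EUK_PAIRS: tuple[tuple[int, int], ...] = tuple(
    p for p in _PROK_PAIRS if p != (13, 8)
)


def _numbering(sequence: str, offset: int) -> dict[int, str]:
    return {
        k: f"{sequence[k - 1]}{offset + k}" for k in range(1, len(sequence) + 1)
    }


def _oligo_numbering(sequence: str, start_target: int) -> dict[int, str]:
    # Oligomer position k pairs E. coli residue (start + L - k) on strand B;
    # the prime marks the antisense strand.
    L = len(sequence)
    return {
        k: f"{sequence[k - 1]}{start_target + L - k}'" for k in range(1, L + 1)
    }


def build_registry() -> dict[str, RnaStrand | RnaConstruct]:
    """Default registry: 4 target strands, 3 oligomers, 2 constructs."""
    strands = {
        "prok_A": RnaStrand("prok_A", _PROK_A, Chemistry.RNA, _numbering(_PROK_A, 1396)),
        "prok_B": RnaStrand("prok_B", _PROK_B, Chemistry.RNA, _numbering(_PROK_B, 1483)),
        "euk_A": RnaStrand("euk_A", _EUK_A, Chemistry.RNA, _numbering(_EUK_A, 1396)),
        "euk_B": RnaStrand("euk_B", _EUK_B, Chemistry.RNA, _numbering(_EUK_B, 1483)),
    }
    registry: dict[str, RnaStrand | RnaConstruct] = dict(strands)
    for name, seq in _OLIGOS.items():
        registry[f"oligo_{name}"] = RnaStrand(
            f"oligo_{name}", seq, Chemistry.OME2, _oligo_numbering(seq, int(name))
        )
    registry["prokaryotic"] = RnaConstruct(
        "prokaryotic", strands["prok_A"], strands["prok_B"], _PROK_PAIRS
    )
    registry["eukaryotic"] = RnaConstruct(
        "eukaryotic", strands["euk_A"], strands["euk_B"], _EUK_PAIRS
    )
    return registry


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def registry_to_json(registry: Mapping[str, RnaStrand | RnaConstruct]) -> str:
    payload = {}
    for key, obj in registry.items():
        kind = "construct" if isinstance(obj, RnaConstruct) else "strand"
        payload[key] = {"kind": kind, **obj.to_dict()}
    return json.dumps(payload, indent=2)


def registry_from_json(text: str) -> dict[str, RnaStrand | RnaConstruct]:
    payload = json.loads(text)
    out: dict[str, RnaStrand | RnaConstruct] = {}
    for key, d in payload.items():
        kind = d.pop("kind")
        out[key] = (
            RnaConstruct.from_dict(d) if kind == "construct" else RnaStrand.from_dict(d)
        )
    return out


def write_fasta(
    strands: Sequence[RnaStrand] | Mapping[str, RnaStrand | RnaConstruct],
    path: str | Path,
) -> None:
    """Write strands as FASTA, one record per strand (id = label)."""
    if isinstance(strands, Mapping):
        strands = [s for s in strands.values() if isinstance(s, RnaStrand)]
    records = [
        SeqRecord(Seq(s.sequence), id=s.id, description=s.chemistry.value)
        for s in strands
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
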