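"""FASTA input/output and consensus/exceptions construction.

The design pipeline consumes up to three FASTA inputs: the consensus
sequences to amplify, an optional "exceptions" file holding the same
sequences with collated SNPs written as IUPAC ambiguity codes, and a
genomic background set used for specificity screening.  Variant sets can
be collapsed into consensus + exceptions with
:func:`generate_exceptions` (pre-aligned, ungapped, equal-length
variants; alignment is out of scope here).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: IUPAC code -> frozenset of concrete bases (N included; Biopython's
#: nonstandard "X" is excluded)
IUPAC_SETS: dict[str, frozenset[str]] = {
    code: frozenset(bases)
    for code, bases in ambiguous_dna_values.items()
    if code != "X"
}
#: frozenset of concrete bases -> IUPAC code
IUPAC_CODES: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

_VALID_CHARS = frozenset(IUPAC_SETS)


class FastaParseError(ValueError):
    """Raised for malformed FASTA content; names the offending line."""


@dataclass
class GeneSequence:
    """One target gene: consensus string plus optional exceptions string.

    The exceptions string has the same length as the consensus and holds
    an IUPAC code per column whose base set always contains the
    consensus base (SNPs collated onto the representative sequence).
    """

    gene_id: str
    consensus: str
    exceptions: str | None = None

    def __post_init__(self) -> None:
        self.consensus = self.consensus.upper()
        if self.exceptions is not None:
            self.exceptions = self.exceptions.upper()
        self.validate()

    @property
    def length(self) -> int:
        return len(self.consensus)

    def validate(self) -> None:
        bad = set(self.consensus) - _VALID_CHARS
        if bad:
            raise ValueError(
                f"gene {self.gene_id!r}: non-IUPAC characters in consensus: {sorted(bad)}"
            )
        if self.exceptions is None:
            return
        if len(self.exceptions) != self.length:
            raise ValueError(
                f"gene {self.gene_id!r}: exceptions length {len(self.exceptions)} "
                f"!= consensus length {self.length}"
            )
        for i, (c, e) in enumerate(zip(self.consensus, self.exceptions)):
            sets = IUPAC_SETS.get(e)
            if sets is None:
                raise ValueError(
                    f"gene {self.gene_id!r}: invalid IUPAC code {e!r} at column {i}"
                )
            if c not in sets and c != "N":
                raise ValueError(
                    f"gene {self.gene_id!r}: exception code {e!r} at column {i} "
                    f"does not contain consensus base {c!r}"
                )


def read_fasta(path: str | Path) -> list[GeneSequence]:
    """Read a FASTA file into GeneSequence records (consensus only).

    IDs are the first whitespace-delimited header token; sequences are
    uppercased; an empty file yields an empty list.  Non-IUPAC characters
    raise :class:`FastaParseError` naming the line number.
    """
    path = Path(path)
    _validate_fasta_text(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(GeneSequence(gene_id=rec.id, consensus=str(rec.seq)))
    return records


def _validate_fasta_text(path: Path) -> None:
    seen_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                seen_header = True
                if len(line) == 1:
                    raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
                continue
            if not seen_header:
                raise FastaParseError(
                    f"{path}:{lineno}: sequence data before any FASTA header"
                )
            bad = set(line.upper()) - _VALID_CHARS
            if bad:
                raise FastaParseError(
                    f"{path}:{lineno}: non-IUPAC characters {sorted(bad)}"
                )


def write_fasta(genes: Iterable[GeneSequence], path: str | Path,
                use_exceptions: bool = False) -> None:
    """Write GeneSequence records to FASTA (60-column wrapped)."""
    records = []
    for g in genes:
        seq = g.exceptions if use_exceptions else g.consensus
        if seq is None:
            raise ValueError(f"gene {g.gene_id!r} has no exceptions sequence")
        records.append(SeqRecord(Seq(seq), id=g.gene_id, description=""))
    SeqIO.write(records, str(path), "fasta")


def generate_exceptions(
    variants: dict[str, Sequence[str]],
) -> tuple[list[GeneSequence], list[GeneSequence]]:
    """Collapse per-gene variant sets into consensus and exceptions records.

    The consensus base per column is the majority base, ties broken
    alphabetically (A < C < G < T); the exception code per column is the
    IUPAC code of the set of observed bases.  Variants must be
    pre-aligned, ungapped, and of identical length within a gene.

    Returns (consensus records, exceptions records); the exceptions
    record for a gene carries both strings.
    """
    consensus_out: list[GeneSequence] = []
    exceptions_out: list[GeneSequence] = []
    for gene_id, seqs in variants.items():
        seqs = [s.upper() for s in seqs]
        if not seqs:
            raise ValueError(f"gene {gene_id!r}: no variants given")
        length = len(seqs[0])
        if any(len(s) != length for s in seqs):
            raise ValueError(f"gene {gene_id!r}: variants have unequal lengths")
        for s in seqs:
            bad = set(s) - set("ACGT")
            if bad:
                raise ValueError(
                    f"gene {gene_id!r}: variant contains non-ACGT characters {sorted(bad)}"
                )
        cons = []
        excs = []
        for col in zip(*seqs):
            counts = {b: col.count(b) for b in set(col)}
            best = max(counts.values())
            # alphabetical tie-break
            cons_base = min(b for b, n in counts.items() if n == best)
            cons.append(cons_base)
            excs.append(IUPAC_CODES[frozenset(col)])
        consensus_str = "".join(cons)
        exceptions_str = "".join(excs)
        consensus_out.append(GeneSequence(gene_id, consensus_str))
        exceptions_out.append(GeneSequence(gene_id, consensus_str, exceptions_str))
    return consensus_out, exceptions_out


def attach_exceptions(
    genes: list[GeneSequence], exceptions: list[GeneSequence]
) -> list[GeneSequence]:
    """Attach exceptions sequences (matched by gene id) to consensus records.

    Genes absent from the exceptions set keep ``exceptions=None``; the
    exceptions record's own sequence string is used as the code string.
    """
    by_id = {g.gene_id: g for g in exceptions}
    out = []
    for g in genes:
        exc = by_id.get(g.gene_id)
        if exc is None:
            out.append(g)
            continue
        out.append(GeneSequence(g.gene_id, g.consensus, exc.consensus))
    return out
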