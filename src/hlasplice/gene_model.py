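"""Gene models, alleles and nucleotide alterations for class I-like HLA genes.

Coordinates are 1-based, inclusive, gene-relative on the sense strand
throughout the package.  A gene model is the ordered list of exon intervals;
introns are derived.  Alleles attach a concrete nucleotide sequence to a gene
model, and :func:`apply_variants` produces mutated alleles (single-base
substitutions and length-preserving block replacements, the two alteration
kinds used in ectopic-expression experiments on these genes).

Splice-acceptor bookkeeping uses the field convention that the last intron
base before an exon start is position -1, the first exon base is +1, and
there is no position 0.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGT")

#: SP1 transcription-factor binding consensus (G/T)GGGCGG(G/A)(G/A)(C/T),
#: expressed as per-position allowed-base sets.
SP1_PATTERN: tuple[str, ...] = ("GT", "G", "G", "G", "C", "G", "G", "GA", "GA", "CT")


class GeneModelError(ValueError):
    """Invalid gene model, allele or variant description."""


@dataclasses.dataclass(frozen=True)
class GeneModel:
    """Exon structure of a plus-strand gene.

    Parameters
    ----------
    gene_id:
        Identifier of the gene.
    exons:
        Ordered ``(start, end)`` pairs, 1-based inclusive, strictly ascending
        and non-overlapping.
    """

    gene_id: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise GeneModelError("gene model needs at least one exon")
        prev_end = 0
        for start, end in self.exons:
            if start < 1 or start > end:
                raise GeneModelError(f"bad exon interval ({start}, {end})")
            if start <= prev_end:
                raise GeneModelError(
                    f"exons must be sorted and non-overlapping; ({start}, {end}) "
                    f"follows an exon ending at {prev_end}"
                )
            prev_end = end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Derived intron intervals (one fewer than the exon count)."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return tuple(out)

    def exon(self, number: int) -> tuple[int, int]:
        """1-based exon interval."""
        return self.exons[number - 1]

    def intron(self, number: int) -> tuple[int, int]:
        """1-based intron interval (intron *n* follows exon *n*)."""
        return self.introns[number - 1]

    def exon_length(self, number: int) -> int:
        s, e = self.exon(number)
        return e - s + 1

    def exon_containing(self, pos: int) -> int | None:
        for i, (s, e) in enumerate(self.exons, start=1):
            if s <= pos <= e:
                return i
        return None

    def acceptor_exon(self, pos: int) -> int:
        """Exon that a 3' splice site at ``pos`` attaches to.

        An acceptor inside exon *k* starts an alternate (shortened) exon *k*;
        an acceptor inside intron *k* starts an extended exon *k+1*.
        """
        for i, (s, e) in enumerate(self.exons, start=1):
            if pos <= e:
                return i
        raise GeneModelError(f"position {pos} lies beyond the last exon")


@dataclasses.dataclass(frozen=True)
class Allele:
    """A named nucleotide sequence attached to a gene model."""

    allele_name: str
    sequence: str
    gene_model: GeneModel

    def __post_init__(self) -> None:
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise GeneModelError(f"allele {self.allele_name}: invalid bases {sorted(bad)}")
        last_end = self.gene_model.exons[-1][1]
        if len(self.sequence) < last_end:
            raise GeneModelError(
                f"allele {self.allele_name}: sequence length {len(self.sequence)} "
                f"shorter than last exon end {last_end}"
            )

    def subseq(self, start: int, end: int) -> str:
        """Inclusive 1-based slice of the genomic sequence."""
        if not (1 <= start <= end <= len(self.sequence)):
            raise GeneModelError(f"range ({start}, {end}) outside sequence")
        return self.sequence[start - 1 : end]

    def exon_seq(self, number: int) -> str:
        return self.subseq(*self.gene_model.exon(number))

    def intron_seq(self, number: int) -> str:
        return self.subseq(*self.gene_model.intron(number))


@dataclasses.dataclass(frozen=True)
class Variant:
    """A substitution or a length-preserving block replacement.

    ``position`` is the 1-based start; for substitutions ``ref_bases`` and
    ``alt_bases`` are single bases, for block replacements they are equal-length
    strings covering ``position .. position+len-1``.
    """

    kind: str
    position: int
    ref_bases: str
    alt_bases: str

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "block_replacement"):
            raise GeneModelError(f"unknown variant kind {self.kind!r}")
        if self.kind == "substitution" and not (
            len(self.ref_bases) == len(self.alt_bases) == 1
        ):
            raise GeneModelError("substitution must have single-base ref and alt")
        if self.kind == "block_replacement" and len(self.ref_bases) != len(self.alt_bases):
            raise GeneModelError("block replacement must be length-preserving")
        if self.position < 1:
            raise GeneModelError("variant position must be >= 1")

    @property
    def end(self) -> int:
        return self.position + len(self.ref_bases) - 1


def build_gene_model(
    exon_table: Iterable[tuple[int, int]], gene_id: str = "gene"
) -> GeneModel:
    """Validate an exon coordinate table and derive the intron structure."""
    return GeneModel(gene_id=gene_id, exons=tuple((int(s), int(e)) for s, e in exon_table))


def apply_variants(allele: Allele, variants: Iterable[Variant]) -> Allele:
    """Return a new allele with all variants applied.

    Reference bases are checked against the allele sequence; a mismatch raises
    :class:`GeneModelError` naming the offending position and observed base.
    """
    seq = list(allele.sequence)
    for v in variants:
        observed = "".join(seq[v.position - 1 : v.end])
        if observed != v.ref_bases:
            raise GeneModelError(
                f"variant at {v.position}: expected {v.ref_bases!r}, "
                f"observed {observed!r} in allele {allele.allele_name}"
            )
        seq[v.position - 1 : v.end] = list(v.alt_bases)
    return dataclasses.replace(allele, sequence="".join(seq))


def acceptor_relative_position(gene_pos: int, exon_start: int) -> int:
    """Signed offset of ``gene_pos`` relative to a 3' splice site.

    The last intron base (``exon_start - 1``) maps to -1 and the first exon
    base maps to +1; there is no position 0.  E.g. position 781 relative to an
    acceptor whose exon starts at 783 is -2.
    """
    if gene_pos < 1:
        raise GeneModelError("gene_pos must be >= 1")
    if exon_start < 2:
        raise GeneModelError("exon_start must be >= 2 (an acceptor needs an intron)")
    if gene_pos >= exon_start:
        return gene_pos - exon_start + 1
    return gene_pos - exon_start


def pyrimidine_fraction(allele: Allele | str, rng: tuple[int, int]) -> float:
    """Fraction of C/T bases in an inclusive 1-based range."""
    start, end = rng
    if end < start:
        raise GeneModelError("empty range")
    seq = allele.subseq(start, end) if isinstance(allele, Allele) else allele[start - 1 : end]
    if len(seq) != end - start + 1:
        raise GeneModelError(f"range ({start}, {end}) outside sequence")
    return sum(seq.count(b) for b in "CT") / len(seq)


def match_degenerate_motif(
    sequence: str, pattern: Sequence[str | frozenset[str] | set[str]]
) -> list[int]:
    """All 1-based positions where a per-position degenerate pattern matches.

    Each pattern element is the set of allowed bases at that offset (a string
    is treated as a set of characters).  A pattern longer than the sequence
    yields no matches.
    """
    if not pattern:
        raise GeneModelError("pattern must be non-empty")
    sets = [frozenset(p) for p in pattern]
    k = len(sets)
    hits = []
    for i in range(len(sequence) - k + 1):
        if all(sequence[i + j] in sets[j] for j in range(k)):
            hits.append(i + 1)
    return hits


# ---------------------------------------------------------------------------
# External interfaces: FASTA alleles and a GFF3-like exon table.

def write_gff(model: GeneModel, path: str | Path, source: str = "hlasplice") -> None:
    lines = []
    for i, (s, e) in enumerate(model.exons, start=1):
        lines.append(
            "\t".join(
                [model.gene_id, source, "exon", str(s), str(e), ".", "+", ".",
                 f"ID=exon{i}"]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff(path: str | Path) -> GeneModel:
    """Read a GFF3-like tab file of exon rows back into a gene model."""
    exons = []
    gene_id = "gene"
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 8 or fields[2] != "exon":
            continue
        gene_id = fields[0]
        exons.append((int(fields[3]), int(fields[4])))
    return build_gene_model(exons, gene_id=gene_id)


def write_fasta(alleles: Iterable[Allele], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(a.sequence), id=a.allele_name, description="")
        for a in alleles
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path, gene_model: GeneModel) -> dict[str, Allele]:
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = Allele(rec.id, str(rec.seq).upper(), gene_model)
    return out
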