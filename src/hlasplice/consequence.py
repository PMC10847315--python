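"""Transcript-level consequences of splice chains.

Frame status is computed from the net change in transcript length relative
to the canonical chain (all splice alterations handled here lie downstream
of the start codon and upstream of the canonical stop, so the transcript
delta equals the coding delta).  Premature termination uses the standard
NMD heuristic: a stop codon more than 50 nt upstream of the final exon-exon
junction flags the transcript for degradation.  Protein fate is positional:
PTC-bearing transcripts are truncated/unstable, in-frame loss of the
transmembrane exon 5 yields a soluble protein, everything else stays
membrane-bound.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence

import pandas as pd

from .gene_model import Allele, GeneModel
from .synthetic_data import (
    CDS_START_MRNA,
    IsoformSpec,
    transcribe,
    transcript_junctions,
    transcript_segments,
)

_STOPS = {"TAA", "TAG", "TGA"}

MEMBRANE_BOUND = "membrane_bound"
SOLUBLE = "soluble"
TRUNCATED_UNSTABLE = "truncated_unstable"

#: distance rule of thumb for NMD: stop > this many nt upstream of the final junction
NMD_JUNCTION_DISTANCE = 50

TRANSMEMBRANE_EXON = 5


@dataclasses.dataclass(frozen=True)
class TranscriptConsequence:
    isoform_id: str
    length_delta: int
    frameshift: bool
    stop_position: int | None  # transcript coordinate of the stop codon's first base
    ptc_flag: bool
    nonstop: bool
    protein_fate: str


def frame_effect(isoform: IsoformSpec, gene_model: GeneModel) -> tuple[int, bool]:
    """Net coding-nucleotide delta vs the canonical transcript and the
    resulting frameshift flag (delta not divisible by 3)."""
    canonical = sum(e - s + 1 for s, e in gene_model.exons)
    this = sum(e - s + 1 for s, e in transcript_segments(gene_model, isoform))
    delta = this - canonical
    return delta, delta % 3 != 0


def find_ptc(
    mrna: str,
    start_position: int,
    junctions: Sequence[int],
    nmd_distance: int = NMD_JUNCTION_DISTANCE,
) -> tuple[int | None, bool, bool]:
    """First in-frame stop from the start codon and its NMD status.

    Returns ``(stop_position, ptc_flag, nonstop)``.  ``ptc_flag`` is true
    when the last base of the stop codon lies strictly more than
    ``nmd_distance`` nt upstream of the final exon-exon junction; a stop
    exactly at the boundary is not flagged.  A transcript with no in-frame
    stop is flagged ``nonstop`` rather than raising.
    """
    if mrna[start_position - 1 : start_position + 2] != "ATG":
        raise ValueError(f"no start codon at position {start_position}")
    stop = None
    for i in range(start_position - 1, len(mrna) - 2, 3):
        if mrna[i : i + 3] in _STOPS:
            stop = i + 1
            break
    if stop is None:
        return None, False, True
    if not junctions:
        return stop, False, False
    last_junction = max(junctions)
    ptc = (last_junction - (stop + 2)) > nmd_distance
    return stop, ptc, False


def protein_fate(ptc_flag: bool, frameshift: bool, lost_exon5: bool) -> str:
    if ptc_flag:
        return TRUNCATED_UNSTABLE
    if lost_exon5 and not frameshift:
        return SOLUBLE
    return MEMBRANE_BOUND


def _retains_exon(gene_model: GeneModel, isoform: IsoformSpec, exon: int) -> bool:
    s, e = gene_model.exon(exon)
    return any(a <= s and e <= b for a, b in transcript_segments(gene_model, isoform))


def classify_consequence(
    allele: Allele,
    isoform: IsoformSpec,
    start_position: int = CDS_START_MRNA,
    nmd_distance: int = NMD_JUNCTION_DISTANCE,
) -> TranscriptConsequence:
    """Full consequence call for one splice chain on one allele."""
    model = allele.gene_model
    delta, shift = frame_effect(isoform, model)
    mrna = transcribe(allele, isoform)
    junctions = transcript_junctions(model, isoform)
    stop, ptc, nonstop = find_ptc(mrna, start_position, junctions, nmd_distance)
    lost_e5 = not _retains_exon(model, isoform, TRANSMEMBRANE_EXON)
    return TranscriptConsequence(
        isoform_id=isoform.isoform_id,
        length_delta=delta,
        frameshift=shift,
        stop_position=stop,
        ptc_flag=ptc,
        nonstop=nonstop,
        protein_fate=protein_fate(ptc, shift, lost_e5),
    )


def annotate_isoforms(
    allele: Allele,
    isoforms: Iterable[IsoformSpec],
    nmd_distance: int = NMD_JUNCTION_DISTANCE,
) -> pd.DataFrame:
    """Consequence table (isoform_id, frameshift, stop_pos, ptc_flag,
    protein_fate, ...) for a collection of splice chains."""
    rows = []
    for iso in isoforms:
        c = classify_consequence(allele, iso, nmd_distance=nmd_distance)
        rows.append(dataclasses.asdict(c))
    return pd.DataFrame(rows)
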