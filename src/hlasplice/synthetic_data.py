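"""Synthetic study-condition generator.

Everything the real experiments measured is emulated here so the whole
analysis can run with no external data:

* four class I-like alleles on one 8-exon gene model, sharing identical
  exon-end contexts (so junction tags are allele-shared) but distinguishable
  by planted 10-bp discriminator sites, with the splice features of interest
  at the coordinates used throughout the package: canonical exon-3 acceptor
  at 719 preceded by a G-rich SP1-matching element (705-714), an alternate
  exon-3 acceptor at 783 created by A at position 781 (-2 of the site) on the
  null-analog allele, a pyrimidine-rich tract at 769-778, and a cryptic
  intron-5 acceptor at 2520, 18 nt upstream of the exon-6 start (2538);
* per-exon-end categorical splice programs, isoform enumeration/sampling and
  transcription of splice chains into mature RNA;
* a steady-state expression model that down-weights PTC-bearing isoforms;
* an error-free paired-end read simulator with a truth table;
* a qPCR Cr-value simulator for twofold dilution series.

All generators are fully deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .gene_model import (
    Allele,
    GeneModel,
    SP1_PATTERN,
    build_gene_model,
    match_degenerate_motif,
)

_RC = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# Splice outcomes, programs and isoforms


class Outcome(NamedTuple):
    """Categorical outcome at one exon 3' end."""

    kind: str  # canonical | alternate_acceptor | skip_to_exon | unspliced
    target: int | None = None

    @property
    def label(self) -> str:
        if self.target is None:
            return self.kind
        return f"{self.kind}:{self.target}"


CANONICAL = Outcome("canonical")
UNSPLICED = Outcome("unspliced")


def alternate_acceptor(position: int) -> Outcome:
    return Outcome("alternate_acceptor", position)


def skip_to_exon(exon: int) -> Outcome:
    return Outcome("skip_to_exon", exon)


class SpliceProgramError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class SpliceProgram:
    """Per-exon-end categorical distribution over splice outcomes.

    Exon ends not listed default to fully canonical splicing.
    """

    outcomes: Mapping[int, Mapping[Outcome, float]]

    def __post_init__(self) -> None:
        for end, dist in self.outcomes.items():
            total = 0.0
            for out, p in dist.items():
                if not (0.0 <= p <= 1.0):
                    raise SpliceProgramError(f"exon end {end}: probability {p} outside [0, 1]")
                total += p
            if abs(total - 1.0) > 1e-9:
                raise SpliceProgramError(f"exon end {end}: probabilities sum to {total}, not 1")

    def distribution(self, exon_end: int) -> dict[Outcome, float]:
        return dict(self.outcomes.get(exon_end, {CANONICAL: 1.0}))


@dataclasses.dataclass(frozen=True)
class IsoformSpec:
    """An ordered splice chain: the outcome taken at each visited exon end."""

    chain: tuple[tuple[int, Outcome], ...]

    def __post_init__(self) -> None:
        donors = [d for d, _ in self.chain]
        if donors != sorted(donors) or len(set(donors)) != len(donors):
            raise SpliceProgramError("chain donors must be strictly increasing")

    @property
    def isoform_id(self) -> str:
        if not self.chain:
            return "single_exon"
        return "|".join(f"e{d}:{out.label}" for d, out in self.chain)

    def outcome_at(self, exon_end: int) -> Outcome | None:
        for d, out in self.chain:
            if d == exon_end:
                return out
        return None


def enumerate_isoforms(
    program: SpliceProgram, gene_model: GeneModel
) -> list[tuple[IsoformSpec, float]]:
    """All splice chains reachable under ``program`` with their probabilities.

    Each pre-mRNA resolves the 3' end of every exon it visits independently;
    exons bypassed by skipping or by an acceptor landing further downstream
    never present their own 3' end.
    """
    n = gene_model.n_exons
    results: list[tuple[IsoformSpec, float]] = []

    def walk(exon: int, prob: float, chain: list[tuple[int, Outcome]]) -> None:
        if exon >= n:
            results.append((IsoformSpec(tuple(chain)), prob))
            return
        for out, p in program.distribution(exon).items():
            if p == 0.0:
                continue
            if out.kind in ("canonical", "unspliced"):
                nxt = exon + 1
            elif out.kind == "skip_to_exon":
                if out.target is None or out.target <= exon + 1 or out.target > n:
                    raise SpliceProgramError(f"invalid skip target {out.target} from exon {exon}")
                nxt = out.target
            elif out.kind == "alternate_acceptor":
                if out.target is None or out.target <= gene_model.exon(exon)[1]:
                    raise SpliceProgramError(
                        f"alternate acceptor {out.target} not downstream of exon {exon}"
                    )
                nxt = gene_model.acceptor_exon(out.target)
            else:  # pragma: no cover - Outcome constructors prevent this
                raise SpliceProgramError(f"unknown outcome kind {out.kind}")
            walk(nxt, prob * p, chain + [(exon, out)])

    walk(1, 1.0, [])
    return results


def sample_isoforms(
    program: SpliceProgram, n: int, seed: int, gene_model: GeneModel
) -> dict[IsoformSpec, int]:
    """Draw ``n`` pre-mRNAs from a splice program (multinomial over chains)."""
    if n < 1:
        raise SpliceProgramError("n must be >= 1")
    isoforms = enumerate_isoforms(program, gene_model)
    probs = np.array([p for _, p in isoforms])
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, probs)
    return {iso: int(c) for (iso, _), c in zip(isoforms, counts)}


def transcript_segments(
    gene_model: GeneModel, isoform: IsoformSpec
) -> list[tuple[int, int]]:
    """Gene-coordinate segments retained in the mature transcript."""
    segs: list[list[int]] = [list(gene_model.exon(1))]
    for donor, out in isoform.chain:
        if segs[-1][1] != gene_model.exon(donor)[1]:
            raise SpliceProgramError(
                f"chain entry at exon {donor} does not follow the current segment"
            )
        if out.kind == "canonical":
            segs.append(list(gene_model.exon(donor + 1)))
        elif out.kind == "unspliced":
            segs[-1][1] = gene_model.exon(donor + 1)[1]
        elif out.kind == "skip_to_exon":
            segs.append(list(gene_model.exon(out.target)))
        elif out.kind == "alternate_acceptor":
            j = gene_model.acceptor_exon(out.target)
            segs.append([out.target, gene_model.exon(j)[1]])
    return [(s, e) for s, e in segs]


def transcribe(allele: Allele, isoform: IsoformSpec) -> str:
    """Mature RNA sequence of a splice chain (concatenated retained segments)."""
    return "".join(
        allele.subseq(s, e) for s, e in transcript_segments(allele.gene_model, isoform)
    )


def transcript_junctions(gene_model: GeneModel, isoform: IsoformSpec) -> list[int]:
    """Transcript coordinates (1-based, last base of upstream segment) of each
    splice junction; retained introns contribute no junction."""
    out = []
    pos = 0
    segs = transcript_segments(gene_model, isoform)
    for s, e in segs[:-1]:
        pos += e - s + 1
        out.append(pos)
    return out


def apply_expression_model(
    counts: Mapping[IsoformSpec, int],
    ptc_flags: Mapping[IsoformSpec, bool],
    degradation_factor: float,
) -> dict[IsoformSpec, float]:
    """Steady-state weights: PTC-bearing isoforms decay by ``degradation_factor``."""
    if not (0.0 < degradation_factor <= 1.0):
        raise ValueError(f"degradation_factor {degradation_factor} outside (0, 1]")
    return {
        iso: c * (degradation_factor if ptc_flags[iso] else 1.0)
        for iso, c in counts.items()
    }


# ---------------------------------------------------------------------------
# Fixture alleles

#: Gene-relative anchor coordinates shared with the study design.
CANONICAL_E3_START = 719
ALT_E3_ACCEPTOR = 783
ALT_E3_MINUS2 = 781
G_RICH_RANGE = (705, 714)
PYR_RICH_RANGE = (769, 778)
INTRON5_CRYPTIC = 2520

FIXTURE_EXONS: tuple[tuple[int, int], ...] = (
    (1, 70),
    (520, 639),
    (719, 958),
    (2032, 2271),
    (2353, 2469),
    (2538, 2570),
    (2651, 2698),
    (2781, 2900),
)
FIXTURE_SEQ_LEN = 2950
#: transcript position of the A of the start codon (within the exon-1 tag).
CDS_START_MRNA = 11
#: transcript position of the planted canonical stop codon (in exon 8).
STOP_MRNA = 890

FIXTURE_ALLELE_NAMES = ("C0303", "C0401", "C0323N", "C0801")
NULL_ALLELE = "C0323N"

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SAFE_CODONS = [c for c in _CODONS if c not in _STOPS]

# tag lengths per exon end: 60-bp exon suffixes for exons 1-5, the entire
# 33-bp exon 6 and the entire 48-bp exon 7 (window lengths 20/47/32).
TAG_LENGTHS = {1: 60, 2: 60, 3: 60, 4: 60, 5: 60, 6: 33, 7: 48}
WINDOW_LENGTHS = {1: 20, 2: 20, 3: 20, 4: 20, 5: 20, 6: 47, 7: 32}


@dataclasses.dataclass(frozen=True)
class FixtureBundle:
    gene_model: GeneModel
    alleles: dict[str, Allele]
    discriminators: dict[str, tuple[str, ...]]
    discriminator_sites: tuple[int, ...]


class _FixtureReject(Exception):
    pass


def _mrna_map(model: GeneModel) -> dict[int, int]:
    """gene position -> canonical transcript position for exonic bases."""
    out = {}
    pos = 0
    for s, e in model.exons:
        for g in range(s, e + 1):
            pos += 1
            out[g] = pos
    return out


def _protected_zones(model: GeneModel) -> list[tuple[int, int]]:
    zones: list[tuple[int, int]] = []
    # tags
    for end, tlen in TAG_LENGTHS.items():
        s, e = model.exon(end)
        zones.append((e - tlen + 1, e))
    # windows: for each exon end, the window-length prefix of every downstream
    # exon and of the immediately following intron must be allele-shared.
    for end, wlen in WINDOW_LENGTHS.items():
        isx, iex = model.intron(end)
        zones.append((isx, min(iex, isx + wlen - 1)))
        for j in range(end + 1, model.n_exons + 1):
            s, e = model.exon(j)
            zones.append((s, min(e, s + wlen - 1)))
    # splice signals and planted features
    zones.append((G_RICH_RANGE[0], 718))          # G-rich element + canonical e3 acceptor
    zones.append((PYR_RICH_RANGE[0], 782))        # pyrimidine tract + alternate acceptor AG
    zones.append((ALT_E3_ACCEPTOR, ALT_E3_ACCEPTOR + 19))   # alternate-acceptor window
    zones.append((2506, 2519))                    # cryptic-acceptor tract + AG
    zones.append((INTRON5_CRYPTIC, INTRON5_CRYPTIC + 19))   # cryptic-acceptor window
    for isx, iex in model.introns:
        zones.append((isx, isx + 1))              # GT donor
        zones.append((iex - 1, iex))              # AG acceptor
    return zones


def _free_intervals(model: GeneModel, last: int) -> list[tuple[int, int]]:
    mask = np.zeros(last + 1, dtype=bool)
    for s, e in _protected_zones(model):
        mask[s : e + 1] = True
    free = []
    start = None
    for p in range(1, last + 1):
        if not mask[p]:
            if start is None:
                start = p
        else:
            if start is not None:
                free.append((start, p - 1))
                start = None
    if start is not None:
        free.append((start, last))
    return free


def _disc_sites(model: GeneModel, spacing: int = 40) -> list[int]:
    sites = []
    for s, e in _free_intervals(model, model.exons[-1][1]):
        if e - s + 1 < 10:
            continue
        here = []
        p = s
        while p + 9 <= e:
            here.append(p)
            p += spacing
        if here and e - 9 >= here[-1] + 10:
            here.append(e - 9)
        sites.extend(here)
    return sites


def _draw_disc(
    rng: np.random.Generator,
    site: int,
    seq: list[str],
    mrna: dict[int, int],
    inv: dict[int, int],
    haystacks: Sequence[str],
) -> str:
    """Draw a 10-mer for one discriminator site.

    Candidates are rejected while they (or their reverse complement) occur
    anywhere in the current allele sequences, so every discriminator is unique
    and strand-unambiguous by construction.  For exonic sites the surrounding
    codons of the canonical reading frame are required to stay stop-free so
    planting a discriminator never truncates the canonical ORF.
    """
    exonic = all(g in mrna for g in range(site, site + 10))
    for _ in range(500):
        cand = "".join(rng.choice(list("ACGT"), size=10))
        rc = reverse_complement(cand)
        if any(cand in h or rc in h for h in haystacks):
            continue
        if not exonic:
            return cand
        trial = list(seq)
        trial[site - 1 : site + 9] = list(cand)
        m0, m1 = mrna[site], mrna[site + 9]
        c0 = CDS_START_MRNA + 3 * ((m0 - CDS_START_MRNA) // 3)
        ok = True
        for cstart in range(c0, m1 + 1, 3):
            codon = "".join(trial[inv[cstart + k] - 1] for k in range(3) if cstart + k in inv)
            if len(codon) == 3 and codon in _STOPS and cstart < STOP_MRNA:
                ok = False
                break
        if ok:
            return cand
    raise _FixtureReject("could not draw a safe discriminator")


def _count_all(haystacks: Sequence[str], needle: str) -> int:
    return sum(h.count(needle) for h in haystacks)


def make_fixture_alleles(seed: int = 0) -> FixtureBundle:
    """Build the four-allele fixture with all planted splice features.

    Post-conditions (verified, with deterministic rebuild on failure):
    alleles share identical exon-end tag and junction-window contexts; the
    null analog carries A at position 781 (-2 of the cryptic exon-3 acceptor
    at 783) while the others carry G; 705-714 is G-rich and a perfect SP1
    consensus match; 769-778 is pyrimidine-rich; intron 5 holds a cryptic
    acceptor 18 nt upstream of the exon-6 start; both cryptic acceptors are
    preceded by AG; every tag, junction window and discriminator is unique
    within (and, for discriminators, private to) its allele in both
    orientations; the canonical ORF of every allele ends at the planted stop.
    """
    for attempt in range(64):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        try:
            return _build_fixture(rng)
        except _FixtureReject:
            continue
    raise RuntimeError("fixture construction failed repeatedly")  # pragma: no cover


def _build_fixture(rng: np.random.Generator) -> FixtureBundle:
    model = build_gene_model(FIXTURE_EXONS, gene_id="HLAC_like")
    mrna = _mrna_map(model)
    inv = {m: g for g, m in mrna.items()}
    n_exonic = len(mrna)

    seq = list("".join(rng.choice(list("ACGT"), size=FIXTURE_SEQ_LEN)))
    # stop-free codon stream over the exonic sequence in the canonical frame
    codons = rng.choice(_SAFE_CODONS, size=n_exonic // 3 + 2)
    stream = "".join(codons)
    for m in range(CDS_START_MRNA, n_exonic + 1):
        seq[inv[m] - 1] = stream[m - CDS_START_MRNA]
    # start and canonical stop codons
    for k, b in enumerate("ATG"):
        seq[inv[CDS_START_MRNA + k] - 1] = b
    for k, b in enumerate("TAA"):
        seq[inv[STOP_MRNA + k] - 1] = b
    # splice donor/acceptor dinucleotides
    for isx, iex in model.introns:
        seq[isx - 1 : isx + 1] = list("GT")
        seq[iex - 2 : iex] = list("AG")
    # G-rich SP1 element before the canonical exon-3 acceptor
    seq[G_RICH_RANGE[0] - 1 : G_RICH_RANGE[1]] = list("GGGGCGGGGC")
    # pyrimidine tract before the alternate exon-3 acceptor; extends to 780 so
    # the codon straddling position 781 can never become a stop.
    pyr = rng.choice(list("CT"), size=782 - PYR_RICH_RANGE[0] - 1)
    seq[PYR_RICH_RANGE[0] - 1 : 780] = list(pyr)
    seq[780] = "G"   # position 781: G on reference alleles
    seq[781] = "G"   # position 782: the G of the (A)G acceptor on the null
    # cryptic intron-5 acceptor: tract, AG, and an in-frame retained segment
    tract5 = rng.choice(list("CT"), size=12)
    seq[2505:2517] = list(tract5)
    seq[2517:2519] = list("AG")
    retained = "".join(rng.choice(_SAFE_CODONS, size=5)) + "CAG"
    seq[INTRON5_CRYPTIC - 1 : 2537] = list(retained)

    sites = _disc_sites(model)
    discs: dict[str, list[str]] = {name: [] for name in FIXTURE_ALLELE_NAMES}
    arrays = {name: list(seq) for name in FIXTURE_ALLELE_NAMES}
    arrays[NULL_ALLELE][ALT_E3_MINUS2 - 1] = "A"
    for site in sites:
        for name in FIXTURE_ALLELE_NAMES:
            current = ["".join(arrays[n]) for n in FIXTURE_ALLELE_NAMES]
            d = _draw_disc(rng, site, arrays[name], mrna, inv, current)
            discs[name].append(d)
            arrays[name][site - 1 : site + 9] = list(d)

    alleles = {
        name: Allele(name, "".join(arr), model) for name, arr in arrays.items()
    }

    _verify_fixture(model, alleles, discs, sites)
    return FixtureBundle(
        gene_model=model,
        alleles=alleles,
        discriminators={k: tuple(v) for k, v in discs.items()},
        discriminator_sites=tuple(sites),
    )


def _verify_fixture(
    model: GeneModel,
    alleles: Mapping[str, Allele],
    discs: Mapping[str, list[str]],
    sites: list[int],
) -> None:
    seqs = {n: a.sequence for n, a in alleles.items()}
    both = {n: (s, reverse_complement(s)) for n, s in seqs.items()}

    # tags unique within each allele, absent from the reverse strand
    for end, tlen in TAG_LENGTHS.items():
        s, e = model.exon(end)
        for n, a in alleles.items():
            tag = a.subseq(e - tlen + 1, e)
            if seqs[n].count(tag) != 1 or both[n][1].count(tag) != 0:
                raise _FixtureReject(f"tag {end} not unique in {n}")
    # alternate-acceptor windows unique, preceded by AG where expected
    for g, wlen in ((ALT_E3_ACCEPTOR, 20), (INTRON5_CRYPTIC, 20)):
        for n, a in alleles.items():
            win = a.subseq(g, g + wlen - 1)
            if seqs[n].count(win) != 1 or both[n][1].count(win) != 0:
                raise _FixtureReject(f"window at {g} not unique in {n}")
    for n, a in alleles.items():
        if a.subseq(2518, 2519) != "AG":
            raise _FixtureReject("cryptic intron-5 acceptor lacks AG")
    if alleles[NULL_ALLELE].subseq(ALT_E3_MINUS2, ALT_E3_MINUS2 + 1) != "AG":
        raise _FixtureReject("null alternate acceptor lacks AG")
    # exon-end contexts shared across alleles; SP1 element present
    ref = alleles[FIXTURE_ALLELE_NAMES[0]]
    if not match_degenerate_motif(ref.subseq(*G_RICH_RANGE), SP1_PATTERN):
        raise _FixtureReject("G-rich element does not match the SP1 consensus")
    # discriminators: unique in own allele, absent from all others (both strands)
    for n in alleles:
        others = [v for m, (v, _) in both.items() if m != n] + [rc for _, rc in both.values()]
        for d in discs[n]:
            if seqs[n].count(d) != 1:
                raise _FixtureReject(f"discriminator {d} not unique in {n}")
            if _count_all(others, d) != 0:
                raise _FixtureReject(f"discriminator {d} leaks into another allele")
    # canonical ORF: translate and require the planted stop to be the first one
    for n, a in alleles.items():
        mrna_seq = "".join(a.subseq(s, e) for s, e in model.exons)
        cds = mrna_seq[CDS_START_MRNA - 1 :]
        for i in range(0, len(cds) - 2, 3):
            codon = cds[i : i + 3]
            if codon in _STOPS:
                if CDS_START_MRNA + i != STOP_MRNA:
                    raise _FixtureReject(f"premature stop in canonical ORF of {n}")
                break
        else:
            raise _FixtureReject("canonical ORF has no stop")


# ---------------------------------------------------------------------------
# Read-pair simulation


@dataclasses.dataclass(frozen=True)
class SampleSpec:
    """Template mixture and read-simulation parameters for one sample."""

    abundances: Mapping[str, float]
    programs: Mapping[str, SpliceProgram]
    degradation_factor: float = 1.0
    n_read_pairs: int = 10000
    fragment_mean: float = 250.0
    fragment_sd: float = 30.0
    read_length: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 80:
            raise ValueError("read_length must be >= 80 (tag + window must fit)")
        if any(a <= 0 for a in self.abundances.values()):
            raise ValueError("abundances must be positive")
        if not (0.0 < self.degradation_factor <= 1.0):
            raise ValueError("degradation_factor outside (0, 1]")


@dataclasses.dataclass(frozen=True)
class TranscriptRecord:
    transcript_id: str
    allele: str
    isoform: IsoformSpec
    sequence: str
    weight: float


def steady_state_pool(
    alleles: Mapping[str, Allele],
    spec: SampleSpec,
    ptc_flags: Mapping[tuple[str, IsoformSpec], bool] | None = None,
) -> list[TranscriptRecord]:
    """Expected steady-state transcript pool under the sample's programs.

    Isoform weights are exact expectations (program probability x template
    abundance), degraded by the PTC model when flags are supplied.
    """
    pool = []
    for name, abundance in spec.abundances.items():
        allele = alleles[name]
        for iso, prob in enumerate_isoforms(spec.programs[name], allele.gene_model):
            if prob == 0.0:
                continue
            w = abundance * prob
            if ptc_flags is not None and ptc_flags.get((name, iso), False):
                w *= spec.degradation_factor
            pool.append(
                TranscriptRecord(
                    transcript_id=f"{name}/{iso.isoform_id}",
                    allele=name,
                    isoform=iso,
                    sequence=transcribe(allele, iso),
                    weight=w,
                )
            )
    return pool


def fragment_pool_weights(
    pool: Sequence[TranscriptRecord], spec: SampleSpec
) -> list[TranscriptRecord]:
    """Re-weight a transcript pool so junction-covering read pairs follow the
    molecule weights exactly.

    Fragments are drawn proportional to ``weight x length`` while the number
    of fragment placements that cover a fixed junction block within one read
    is proportional to ``1 / (length - fragment + 1)``; isoforms of different
    lengths therefore contribute junction-covering pairs at slightly
    different rates.  Installed splice-outcome proportions are read-level
    observations, so recovery scenarios divide each weight by that length
    factor, making the expected classifiable-pair proportions equal the
    installed probabilities at every exon end.
    """
    out = []
    fl = int(round(spec.fragment_mean))
    for t in pool:
        length = len(t.sequence)
        factor = length / max(1, length - fl + 1)
        out.append(dataclasses.replace(t, weight=t.weight / factor))
    return out


def simulate_read_pairs(
    pool: Sequence[TranscriptRecord], spec: SampleSpec
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Error-free paired reads from a weighted transcript pool.

    Fragments are drawn proportional to ``weight x transcript length`` with a
    gaussian fragment length (truncated at the read length) and a uniform
    start.  Mate 1 is the fragment 5' prefix; mate 2 is the reverse
    complement of the fragment 3' suffix.  Returns the read pairs and a truth
    table (read_id, allele, isoform_id, transcript_id, start, fragment_len).
    """
    if not pool:
        raise ValueError("empty transcript pool")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_read_pairs
    rl = spec.read_length
    lengths = np.array([len(t.sequence) for t in pool])
    if lengths.min() < rl:
        raise ValueError("all transcripts must be at least one read long")
    w = np.array([t.weight for t in pool], dtype=float) * lengths
    w = w / w.sum()
    idx = rng.choice(len(pool), size=n, p=w)
    raw = rng.normal(spec.fragment_mean, spec.fragment_sd, size=n)
    frag = np.clip(np.rint(raw).astype(int), rl, lengths[idx])
    starts = (rng.random(n) * (lengths[idx] - frag + 1)).astype(int) + 1

    pairs = []
    rows = []
    for i in range(n):
        t = pool[idx[i]]
        s, fl = int(starts[i]), int(frag[i])
        fragment = t.sequence[s - 1 : s - 1 + fl]
        rid = f"rp{i}"
        pairs.append((rid, fragment[:rl], reverse_complement(fragment[-rl:])))
        rows.append((rid, t.allele, t.isoform.isoform_id, t.transcript_id, s, fl))
    truth = pd.DataFrame(
        rows,
        columns=["read_id", "allele", "isoform_id", "transcript_id", "start", "fragment_len"],
    )
    return pairs, truth


def write_paired_fastq(
    pairs: Sequence[tuple[str, str, str]], path1: str | Path, path2: str | Path
) -> None:
    """Write mates to two FASTQ files with fixed Q40 qualities."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for rid, r1, r2 in pairs:
            f1.write(f"@{rid}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{rid}/2\n{r2}\n+\n{'I' * len(r2)}\n")


# ---------------------------------------------------------------------------
# qPCR Cr simulation


@dataclasses.dataclass(frozen=True)
class CrSimSpec:
    """True initial concentrations and amplification model for a Cr table.

    ``templates`` maps (sample, primer_pair) to the true relative initial
    concentration N0.  ``amplification`` maps primer_pair to the factor
    A = 1 + efficiency.  Cr(d) = [ln(threshold) - ln(N0 d)] / ln(A) + noise.
    """

    templates: Mapping[tuple[str, str], float]
    amplification: Mapping[str, float]
    threshold: float = 1.0
    dilutions: tuple[float, ...] = (1 / 5, 1 / 10, 1 / 20, 1 / 40)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for pp, a in self.amplification.items():
            if a <= 1.0:
                raise ValueError(f"amplification factor for {pp} must be > 1")
        if any(d <= 0 for d in self.dilutions):
            raise ValueError("dilution factors must be positive")
        if list(self.dilutions) != sorted(self.dilutions, reverse=True):
            raise ValueError("dilution factors must be decreasing")


def simulate_cr(spec: CrSimSpec) -> pd.DataFrame:
    """Cr table (sample, primer_pair, dilution_factor, cr) for all dilutions."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for (sample, pp), n0 in spec.templates.items():
        a = spec.amplification[pp]
        for d in spec.dilutions:
            cr = (np.log(spec.threshold) - np.log(n0 * d)) / np.log(a)
            if spec.noise_sd > 0:
                cr += rng.normal(0.0, spec.noise_sd)
            rows.append((sample, pp, d, cr))
    return pd.DataFrame(rows, columns=["sample", "primer_pair", "dilution_factor", "cr"])
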