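"""Tag-based splice-junction classification of paired-end reads.

Read pairs are screened for exon-end *tags* (the 60-bp 3' suffix of exons
1-5, the entire 33-bp exon 6, the entire 48-bp exon 7).  The *window* that
immediately follows a tag within the same read (20 bp after exons 1-5, 47 bp
after exon 6, 32 bp after exon 7) is compared with reference continuations:
the start of each downstream exon (canonical splicing and exon skipping) and
the unspliced intron continuation.  Windows matching no reference are rescued
as alternate 3' splice sites when they occur exactly once in the allele's
pre-mRNA downstream of the exon end and are preceded by AG; everything else
is unclassified.  Pairs from two locally identical alleles are disambiguated
by allele-private 10-bp discriminator sequences.
"""

from __future__ import annotations

import dataclasses
import re
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .gene_model import Allele, GeneModel
from .synthetic_data import (
    CANONICAL,
    Outcome,
    TAG_LENGTHS,
    UNSPLICED,
    WINDOW_LENGTHS,
    alternate_acceptor,
    reverse_complement,
    skip_to_exon,
)

UNCLASSIFIED = "unclassified"
AMBIGUOUS = "ambiguous"


class ClassifierError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class TagScheme:
    """Concrete tag sequences per exon end, with the alleles sharing each tag."""

    gene_model: GeneModel
    tags: Mapping[int, Mapping[str, frozenset[str]]]

    def tag_length(self, exon_end: int) -> int:
        return TAG_LENGTHS[exon_end]

    def window_length(self, exon_end: int) -> int:
        return WINDOW_LENGTHS[exon_end]


def build_tags(gene_model: GeneModel, alleles: Mapping[str, Allele]) -> TagScheme:
    """Extract the per-exon-end tag of every allele; shared tags are merged."""
    tags: dict[int, dict[str, frozenset[str]]] = {}
    for end, tlen in TAG_LENGTHS.items():
        s, e = gene_model.exon(end)
        if e - s + 1 < tlen:
            raise ClassifierError(
                f"exon {end} (length {e - s + 1}) shorter than its {tlen}-bp tag"
            )
        by_seq: dict[str, set[str]] = {}
        for name, allele in alleles.items():
            tag = allele.subseq(e - tlen + 1, e)
            by_seq.setdefault(tag, set()).add(name)
        tags[end] = {t: frozenset(names) for t, names in by_seq.items()}
    return TagScheme(gene_model=gene_model, tags=tags)


def build_junction_references(
    gene_model: GeneModel, allele: Allele
) -> dict[int, dict[str, Outcome | None]]:
    """Window-length reference sequences per exon end.

    For each exon end: the spliced continuation starting at each downstream
    exon (canonical next exon and skip categories) and the genomic (intron)
    continuation for unspliced RNA.  A window produced by two categories is a
    collision, stored as ``None``: classification of that window returns
    unclassified.
    """
    refs: dict[int, dict[str, Outcome | None]] = {}
    n = gene_model.n_exons
    for end, wlen in WINDOW_LENGTHS.items():
        table: dict[str, Outcome | None] = {}

        def put(window: str, outcome: Outcome) -> None:
            if len(window) < wlen:
                return
            if window in table and table[window] != outcome:
                table[window] = None
            else:
                table[window] = outcome

        _, epos = gene_model.exon(end)
        # unspliced: genomic continuation straight into the intron
        put(allele.subseq(epos + 1, epos + wlen), UNSPLICED)
        # canonical and skip targets: spliced continuation from exon j onward
        for j in range(end + 1, n + 1):
            cont = ""
            for k in range(j, n + 1):
                cont += allele.exon_seq(k)
                if len(cont) >= wlen:
                    break
            outcome = CANONICAL if j == end + 1 else skip_to_exon(j)
            put(cont[:wlen], outcome)
        refs[end] = table
    return refs


def merge_references(
    per_allele: Mapping[str, Mapping[int, Mapping[str, Outcome | None]]]
) -> dict[int, dict[str, Outcome | None]]:
    """Gene-level reference table: allele disagreements become collisions."""
    merged: dict[int, dict[str, Outcome | None]] = {}
    for refs in per_allele.values():
        for end, table in refs.items():
            tgt = merged.setdefault(end, {})
            for window, outcome in table.items():
                if window in tgt and tgt[window] != outcome:
                    tgt[window] = None
                else:
                    tgt[window] = outcome
    return merged


def scan_read_pair(
    pair: tuple[str, str], tags: TagScheme
) -> list[tuple[int, str]]:
    """Exon-end tag hits in a read pair: (exon_end, following window).

    Both mates are searched in both orientations so the scan is effectively on
    the sense strand; tag matches too close to the read end to provide a full
    window are dropped.  Identical hits found on both mates (overlapping
    fragments) are reported once.
    """
    r1, r2 = pair
    streams = (r1, reverse_complement(r1), r2, reverse_complement(r2))
    hits: list[tuple[int, str]] = []
    seen: set[tuple[int, str]] = set()
    for end, table in tags.tags.items():
        wlen = tags.window_length(end)
        for tag in table:
            tlen = len(tag)
            for stream in streams:
                start = stream.find(tag)
                while start != -1:
                    wstart = start + tlen
                    if wstart + wlen <= len(stream):
                        window = stream[wstart : wstart + wlen]
                        if (end, window) not in seen:
                            seen.add((end, window))
                            hits.append((end, window))
                    start = stream.find(tag, start + 1)
    return sorted(hits)


def classify_window(
    window: str,
    references: Mapping[str, Outcome | None],
    allele: Allele,
    exon_end: int,
) -> Outcome | None:
    """Classify one junction window against one allele.

    Exact reference match wins; otherwise the window is rescued as an
    alternate acceptor if it occurs exactly once in the allele's pre-mRNA
    downstream of the exon end and is preceded by AG.  ``None`` means
    unclassified (including reference collisions and multi-hit windows).
    """
    if window in references:
        return references[window]
    _, epos = allele.gene_model.exon(exon_end)
    seq = allele.sequence
    occurrences = []
    start = seq.find(window, epos)
    while start != -1:
        occurrences.append(start + 1)  # 1-based gene position
        if len(occurrences) > 1:
            break
        start = seq.find(window, start + 1)
    if len(occurrences) == 1:
        pos = occurrences[0]
        if pos >= 3 and seq[pos - 3 : pos - 1] == "AG":
            return alternate_acceptor(pos)
    return None


def classify_window_pooled(
    window: str,
    per_allele_refs: Mapping[str, Mapping[int, Mapping[str, Outcome | None]]],
    alleles: Mapping[str, Allele],
    exon_end: int,
) -> Outcome | None:
    """Gene-level classification: accept an outcome supported consistently by
    at least one allele; conflicting outcomes across alleles are unclassified."""
    outcomes = set()
    for name, refs in per_allele_refs.items():
        out = classify_window(window, refs[exon_end], alleles[name], exon_end)
        if out is not None:
            outcomes.add(out)
    if len(outcomes) == 1:
        return outcomes.pop()
    return None


class DiscriminatorIndex:
    """Compiled allele-private discriminator search over read pairs."""

    def __init__(self, discriminators: Mapping[str, Sequence[str]]):
        seen: dict[str, str] = {}
        for name, discs in discriminators.items():
            for d in discs:
                if d in seen and seen[d] != name:
                    raise ClassifierError(
                        f"discriminator {d} shared by alleles {seen[d]} and {name}"
                    )
                seen[d] = name
        self._patterns = {
            name: re.compile("|".join(re.escape(d) for d in discs))
            for name, discs in discriminators.items()
            if discs
        }

    def assign(self, pair: tuple[str, str]) -> str | None:
        r1, r2 = pair
        haystack = "\n".join((r1, reverse_complement(r1), r2, reverse_complement(r2)))
        found = [n for n, pat in self._patterns.items() if pat.search(haystack)]
        if len(found) == 1:
            return found[0]
        return None


def assign_allele(
    pair: tuple[str, str], discriminators: Mapping[str, Sequence[str]]
) -> str | None:
    """Allele of origin if exactly one allele's discriminators occur in either
    mate (either orientation); otherwise ``None`` (ambiguous)."""
    return DiscriminatorIndex(discriminators).assign(pair)


def classify_pairs(
    pairs: Iterable[tuple[str, str, str]],
    gene_model: GeneModel,
    alleles: Mapping[str, Allele],
    discriminators: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Scan, disambiguate and classify a stream of read pairs.

    Returns one row per (read pair, exon end) hit with columns ``read_id``,
    ``allele`` (allele name, or "ambiguous" when discriminators are given and
    inconclusive, or "pooled" without discriminators), ``exon_end``,
    ``category`` (outcome label or "unclassified") and ``window``.
    """
    tags = build_tags(gene_model, alleles)
    refs = {name: build_junction_references(gene_model, a) for name, a in alleles.items()}
    index = DiscriminatorIndex(discriminators) if discriminators else None

    rows = []
    for rid, r1, r2 in pairs:
        assigned = index.assign((r1, r2)) if index else None
        for end, window in scan_read_pair((r1, r2), tags):
            if assigned is not None:
                out = classify_window(window, refs[assigned][end], alleles[assigned], end)
                group = assigned
            else:
                out = classify_window_pooled(window, refs, alleles, end)
                group = AMBIGUOUS if index else "pooled"
            rows.append((rid, group, end, out.label if out else UNCLASSIFIED, window))
    return pd.DataFrame(rows, columns=["read_id", "allele", "exon_end", "category", "window"])


def tabulate(
    calls: pd.DataFrame, min_report_fraction: float = 0.005
) -> pd.DataFrame:
    """Count and proportion table per (allele group, exon end, category).

    ``proportion`` is over classifiable pairs (the plotting denominator);
    ``proportion_all`` includes unclassified pairs and sums to 1 per exon end.
    Categories below ``min_report_fraction`` are flagged suppressed for
    plotting but retained in the table.  Exon ends with zero classifiable
    pairs keep their rows with proportion marked missing.
    """
    if calls.empty:
        raise ClassifierError("no junction calls to tabulate")
    counts = (
        calls.groupby(["allele", "exon_end", "category"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    out_rows = []
    for (group, end), sub in counts.groupby(["allele", "exon_end"], sort=True):
        total = int(sub["count"].sum())
        classifiable = int(sub.loc[sub["category"] != UNCLASSIFIED, "count"].sum())
        for _, row in sub.iterrows():
            is_uncls = row["category"] == UNCLASSIFIED
            prop = (
                float("nan")
                if (is_uncls or classifiable == 0)
                else row["count"] / classifiable
            )
            out_rows.append(
                {
                    "allele": group,
                    "exon_end": end,
                    "category": row["category"],
                    "count": int(row["count"]),
                    "n_classifiable": classifiable,
                    "n_total": total,
                    "proportion": prop,
                    "proportion_all": row["count"] / total,
                    "suppressed": (not is_uncls) and classifiable > 0
                    and row["count"] / classifiable < min_report_fraction,
                }
            )
    return pd.DataFrame(out_rows)


def read_paired_fastq(
    path1: str | Path, path2: str | Path
) -> list[tuple[str, str, str]]:
    """Load two mate FASTQ files into (read_id, mate1, mate2) triples."""
    out = []
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    for rec1, rec2 in zip(it1, it2):
        rid = rec1.id.rsplit("/", 1)[0]
        out.append((rid, str(rec1.seq).upper(), str(rec2.seq).upper()))
    return out
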