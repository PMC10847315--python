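"""Packaged simulation scenarios.

The splice-outcome probabilities installed here are the study conditions for
the recovery experiments: the per-allele profiles of the null-analog allele
(alternate exon-3 acceptor use at 53.6% of exon-2-end RNA, with canonical
splicing six-fold rarer than the alternate product; a 35% canonical / 8.7%
alternate / 56.3% unspliced split at the exon-5 end) and of the comparator
allele (96% canonical at the exon-5 end), plus the pooled two-allele gene
profile (14% alternate exon-3 use at the exon-2 end, 14% exon-5 skipping and
5% cryptic intron-5 acceptor use at the exon-4 end).  The null allele's share
of the template pool and its exon-4-end rates follow from those constraints;
exon ends 1, 3, 6 and 7 are kept fully canonical so the recovery experiment
stays controlled.
"""

from __future__ import annotations

from collections.abc import Mapping

from .gene_model import Allele
from .synthetic_data import (
    ALT_E3_ACCEPTOR,
    CANONICAL,
    CrSimSpec,
    INTRON5_CRYPTIC,
    NULL_ALLELE,
    SampleSpec,
    SpliceProgram,
    TranscriptRecord,
    UNSPLICED,
    alternate_acceptor,
    fragment_pool_weights,
    skip_to_exon,
    steady_state_pool,
)

COMPARATOR_ALLELE = "C0801"
REFERENCE_ALLELE = "C0303"
HIGH_ALLELE = "C0401"

# per-allele generative truths (proportions of exon-end RNA)
NULL_E2_ALT = 0.536
NULL_E2_CANONICAL = NULL_E2_ALT / 6.0          # alternate product is six-fold higher
NULL_E5_CANONICAL = 0.35
NULL_E5_ALT = 0.087
NULL_E5_UNSPLICED = 1.0 - NULL_E5_CANONICAL - NULL_E5_ALT
COMPARATOR_E5_CANONICAL = 0.96

# pooled (gene-level) truths and the template mixture they imply
POOLED_E2_ALT = 0.14
POOLED_E4_SKIP = 0.14
POOLED_E4_ALT = 0.05
NULL_SHARE = POOLED_E2_ALT / NULL_E2_ALT       # null share of classifiable pairs
COMPARATOR_E4_SKIP = 0.02
NULL_E4_SKIP = (POOLED_E4_SKIP - (1.0 - NULL_SHARE) * COMPARATOR_E4_SKIP) / NULL_SHARE
NULL_E4_ALT = POOLED_E4_ALT / NULL_SHARE
NULL_E4_UNSPLICED = 0.08

# quantified RNA-level truths for the qPCR and expression scenarios
FOLD_C0401_VS_C0303 = 3.4
FOLD_NULL_BELOW_REFERENCE = 27.0
NULL_RELATIVE_PCT = 9.8


def null_program() -> SpliceProgram:
    """Splice program of the null-analog allele (aberrant ends 2, 4, 5)."""
    return SpliceProgram(
        {
            2: {
                alternate_acceptor(ALT_E3_ACCEPTOR): NULL_E2_ALT,
                CANONICAL: NULL_E2_CANONICAL,
                UNSPLICED: 1.0 - NULL_E2_ALT - NULL_E2_CANONICAL,
            },
            4: {
                skip_to_exon(6): NULL_E4_SKIP,
                alternate_acceptor(INTRON5_CRYPTIC): NULL_E4_ALT,
                UNSPLICED: NULL_E4_UNSPLICED,
                CANONICAL: 1.0 - NULL_E4_SKIP - NULL_E4_ALT - NULL_E4_UNSPLICED,
            },
            5: {
                CANONICAL: NULL_E5_CANONICAL,
                alternate_acceptor(INTRON5_CRYPTIC): NULL_E5_ALT,
                UNSPLICED: NULL_E5_UNSPLICED,
            },
        }
    )


def comparator_program() -> SpliceProgram:
    """Splice program of the co-expressed comparator allele."""
    return SpliceProgram(
        {
            2: {CANONICAL: 0.75, UNSPLICED: 0.25},
            4: {
                skip_to_exon(6): COMPARATOR_E4_SKIP,
                CANONICAL: 0.90,
                UNSPLICED: 0.10 - COMPARATOR_E4_SKIP,
            },
            5: {
                CANONICAL: COMPARATOR_E5_CANONICAL,
                UNSPLICED: 1.0 - COMPARATOR_E5_CANONICAL,
            },
        }
    )


def canonical_program() -> SpliceProgram:
    return SpliceProgram({})


def sample2_spec(n_read_pairs: int = 50000, seed: int = 42, **kwargs) -> SampleSpec:
    """Two-allele sample analog for junction-profile recovery.

    The generator emits the steady-state RNA pool directly (the installed
    proportions are RNA-level observations), so no further PTC degradation is
    applied.  A fixed fragment size is used so junction sampling and allele
    assignment are category-independent; dispersed fragment lengths introduce
    small selection effects near transcript ends that are a property of the
    library geometry, not of the classifier under test.
    """
    kwargs.setdefault("fragment_sd", 0.0)
    return SampleSpec(
        abundances={NULL_ALLELE: NULL_SHARE, COMPARATOR_ALLELE: 1.0 - NULL_SHARE},
        programs={NULL_ALLELE: null_program(), COMPARATOR_ALLELE: comparator_program()},
        degradation_factor=1.0,
        n_read_pairs=n_read_pairs,
        seed=seed,
        **kwargs,
    )


def sample1_spec(n_read_pairs: int = 50000, seed: int = 7, **kwargs) -> SampleSpec:
    """Two-allele expression-recovery sample: identical canonical transcripts,
    null steady-state abundance at 9.8% of the comparator."""
    kwargs.setdefault("fragment_sd", 0.0)
    return SampleSpec(
        abundances={NULL_ALLELE: NULL_RELATIVE_PCT, COMPARATOR_ALLELE: 100.0},
        programs={NULL_ALLELE: canonical_program(), COMPARATOR_ALLELE: canonical_program()},
        degradation_factor=1.0,
        n_read_pairs=n_read_pairs,
        seed=seed,
        **kwargs,
    )


def recovery_pool(
    alleles: Mapping[str, Allele], spec: SampleSpec
) -> list[TranscriptRecord]:
    """Steady-state transcript pool with fragment-sampling weights adjusted so
    the classifiable-pair proportions equal the installed read-level truths."""
    return fragment_pool_weights(steady_state_pool(alleles, spec), spec)


def two_construct_cr_spec(
    ratio: float,
    amplification: float = 1.9,
    noise_sd: float = 0.0,
    seed: int = 0,
    target_name: str = "target",
    reference_name: str = "reference",
) -> CrSimSpec:
    """Noiseless-by-default dilution-series spec for two constructs sharing
    one GFP control, with the target's template at ``ratio`` x the reference."""
    base_hla, base_gfp = 1e-4, 2e-4
    return CrSimSpec(
        templates={
            (target_name, "hla"): ratio * base_hla,
            (reference_name, "hla"): base_hla,
            (target_name, "gfp"): base_gfp,
            (reference_name, "gfp"): base_gfp,
        },
        amplification={"hla": amplification, "gfp": amplification},
        noise_sd=noise_sd,
        seed=seed,
    )


def g781a_panel_specs(seed: int = 0) -> dict[str, CrSimSpec]:
    """Position-781 variant panel (G/A/C/T) against the G reference.

    Only the A variant creates the efficient alternate 3' splice site, so its
    RNA-level truth is set far below the others.
    """
    truths = {"G": 1.0, "A": 1.0 / FOLD_NULL_BELOW_REFERENCE, "C": 1.0, "T": 1.0}
    return {
        base: two_construct_cr_spec(
            ratio, seed=seed, target_name=f"781{base}", reference_name="781G_ref"
        )
        for base, ratio in truths.items()
    }
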