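"""Allele-level RNA abundance from read pairs.

Pairs are attributed to alleles with the discriminator scheme, counted,
normalized to pairs per 10^4 on-target pairs, and expressed as a percentage
relative to a reference allele.  Ambiguous pairs are excluded from both the
numerator and the denominator of relative expression.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence

import pandas as pd

from .junction_classifier import DiscriminatorIndex

NORMALIZATION_SCALE = 1e4


class ExpressionError(ValueError):
    pass


def count_allele_pairs(
    pairs: Iterable[tuple[str, str, str]],
    discriminators: Mapping[str, Sequence[str]],
) -> tuple[dict[str, int], int]:
    """Discriminator-assigned pair counts per allele plus the ambiguous count.

    Conservation: assigned counts + ambiguous = number of input pairs.
    """
    index = DiscriminatorIndex(discriminators)
    counts = {name: 0 for name in discriminators}
    ambiguous = 0
    for _, r1, r2 in pairs:
        assigned = index.assign((r1, r2))
        if assigned is None:
            ambiguous += 1
        else:
            counts[assigned] += 1
    return counts, ambiguous


def normalize(count: int, total_on_target: int) -> float:
    """Normalized read number: pairs per 10^4 on-target pairs."""
    if total_on_target <= 0:
        raise ExpressionError("total_on_target must be positive")
    return count / total_on_target * NORMALIZATION_SCALE


def relative_expression(target_normalized: float, reference_normalized: float) -> float:
    """Percentage of the target allele's normalized level vs the reference."""
    if reference_normalized <= 0:
        raise ExpressionError("reference normalized value must be positive")
    return 100.0 * target_normalized / reference_normalized


def allele_expression_table(
    counts: Mapping[str, int],
    total_on_target: int,
    reference: str,
) -> pd.DataFrame:
    """Per-allele count, normalized read number and relative percentage."""
    if reference not in counts:
        raise ExpressionError(f"reference allele {reference!r} not among counts")
    ref_norm = normalize(counts[reference], total_on_target)
    rows = []
    for name in sorted(counts):
        norm = normalize(counts[name], total_on_target)
        rows.append(
            {
                "allele": name,
                "count": int(counts[name]),
                "normalized": norm,
                "relative_pct": relative_expression(norm, ref_norm),
                "reference": reference,
            }
        )
    return pd.DataFrame(rows)
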