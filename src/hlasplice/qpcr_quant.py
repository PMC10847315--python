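"""qPCR standard-curve relative quantification.

Per primer pair, the PCR efficiency is estimated for each sample by ordinary
least squares of Cr against log10 of the dilution factor; the amplification
factor is A = 10^(-1/slope) and the efficiency E = A - 1.  Plate-level
efficiency is the arithmetic mean of the per-sample E values.  Initial
relative concentrations follow N0 = A^(-Cr).  Target (HLA) concentrations are
then fitted against the co-transfected control (GFP) concentrations across
the dilution series; the relative RNA level of a sample is the mean of
f(g)/g evaluated at the minimum and maximum observed control concentration,
and fold differences are ratios of these levels.

The dilution-series fit is a power law f(x) = a x^b (least squares on
log-log axes); because both axes are concentrations proportional to the same
dilution, the true relation is a power law with b = 1.  An exponential
y = a e^(bx) alternative is available for sensitivity checks.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

GFP_PRIMER = "gfp"


class QpcrError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class EfficiencyEstimate:
    """Per-sample standard-curve slope and the derived efficiency."""

    sample: str
    primer_pair: str
    slope: float
    amplification: float  # A = 10^(-1/slope)
    efficiency: float     # E = A - 1

    @classmethod
    def from_series(cls, sample: str, primer_pair: str,
                    dilutions: np.ndarray, cr: np.ndarray) -> "EfficiencyEstimate":
        slope = float(stats.linregress(np.log10(dilutions), cr).slope)
        if slope >= 0:
            raise QpcrError(
                f"{sample}/{primer_pair}: Cr must decrease with input (slope {slope:.3g})"
            )
        a = 10.0 ** (-1.0 / slope)
        return cls(sample, primer_pair, slope, a, a - 1.0)


@dataclasses.dataclass(frozen=True)
class PowerLawFit:
    """f(x) = a * x^b (or a * e^(bx) for the exponential variant)."""

    a: float
    b: float
    model: str = "power"

    def __call__(self, x: float) -> float:
        if self.model == "power":
            return self.a * x**self.b
        return self.a * np.exp(self.b * x)


def fit_efficiency(series: pd.DataFrame) -> EfficiencyEstimate:
    """Efficiency of one (sample, primer pair) dilution series.

    ``series`` must hold columns sample, primer_pair, dilution_factor, cr for
    a single sample and primer pair, with at least three distinct dilutions.
    """
    samples = series["sample"].unique()
    primers = series["primer_pair"].unique()
    if len(samples) != 1 or len(primers) != 1:
        raise QpcrError("fit_efficiency expects a single sample and primer pair")
    d = series["dilution_factor"].to_numpy(dtype=float)
    if len(np.unique(d)) < 3:
        raise QpcrError("need at least 3 distinct dilutions for an efficiency fit")
    return EfficiencyEstimate.from_series(
        str(samples[0]), str(primers[0]), d, series["cr"].to_numpy(dtype=float)
    )


def plate_efficiency(estimates: Sequence[EfficiencyEstimate]) -> tuple[float, float]:
    """Plate-level (mean efficiency, amplification factor) for one primer pair.

    The mean is over the per-sample efficiencies E, not over slopes.
    """
    if not estimates:
        raise QpcrError("no efficiency estimates to average")
    mean_e = float(np.mean([e.efficiency for e in estimates]))
    return mean_e, 1.0 + mean_e


def initial_concentration(cr: float | np.ndarray, amplification: float):
    """Relative initial target concentration N0 = A^(-Cr) (arbitrary scale)."""
    if amplification <= 1.0:
        raise QpcrError("amplification factor must be > 1")
    return amplification ** (-np.asarray(cr, dtype=float))


def fit_hla_vs_gfp(points: Sequence[tuple[float, float]], model: str = "power") -> PowerLawFit:
    """Fit target concentration as a function of control concentration.

    ``points`` are (gfp N0, hla N0) per dilution; at least three points with
    distinct x are required and all concentrations must be positive.
    """
    if model not in ("power", "exponential"):
        raise QpcrError(f"unknown fit model {model!r}")
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise QpcrError("need at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    if np.any(x <= 0) or np.any(y <= 0):
        raise QpcrError("concentrations must be positive")
    xt = np.log(x) if model == "power" else x
    if np.allclose(xt, xt[0]):
        raise QpcrError("degenerate fit: all control concentrations identical")
    res = stats.linregress(xt, np.log(y))
    return PowerLawFit(a=float(np.exp(res.intercept)), b=float(res.slope), model=model)


def relative_level(fit: PowerLawFit, gfp_values: Sequence[float]) -> float:
    """Endpoint-averaged relative level: mean of f(g)/g at min and max control."""
    g = np.asarray(gfp_values, dtype=float)
    if np.any(g <= 0):
        raise QpcrError("control concentrations must be positive")
    gmin, gmax = float(g.min()), float(g.max())
    return 0.5 * (fit(gmax) / gmax + fit(gmin) / gmin)


def fold_difference(level_a: float, level_b: float) -> float:
    if level_b == 0:
        raise QpcrError("reference level must be nonzero")
    return level_a / level_b


def quantify_plate(
    cr_table: pd.DataFrame,
    gfp_primer: str = GFP_PRIMER,
    model: str = "power",
    exclude_samples: Sequence[str] = (),
) -> dict:
    """Full standard-curve pipeline over one plate's Cr table.

    Returns per-primer-pair plate efficiencies, per-sample relative RNA
    levels (target vs control), and the fold-difference matrix between
    samples.  ``exclude_samples`` drops negative controls from efficiency
    estimation and quantification.
    """
    table = cr_table[~cr_table["sample"].isin(exclude_samples)]
    if table.empty:
        raise QpcrError("empty Cr table")

    per_sample: dict[str, list[EfficiencyEstimate]] = {}
    for (_, _), sub in table.groupby(["sample", "primer_pair"], sort=True):
        est = fit_efficiency(sub)
        per_sample.setdefault(est.primer_pair, []).append(est)
    plate: dict[str, tuple[float, float]] = {
        pp: plate_efficiency(ests) for pp, ests in per_sample.items()
    }

    levels: dict[str, float] = {}
    fits: dict[str, PowerLawFit] = {}
    for sample, sub in table.groupby("sample", sort=True):
        primers = set(sub["primer_pair"])
        if gfp_primer not in primers:
            raise QpcrError(f"sample {sample}: no {gfp_primer!r} control series")
        targets = sorted(primers - {gfp_primer})
        if not targets:
            continue
        target = targets[0]
        gfp = sub[sub["primer_pair"] == gfp_primer].sort_values("dilution_factor")
        hla = sub[sub["primer_pair"] == target].sort_values("dilution_factor")
        g_n0 = initial_concentration(gfp["cr"].to_numpy(), plate[gfp_primer][1])
        h_n0 = initial_concentration(hla["cr"].to_numpy(), plate[target][1])
        fit = fit_hla_vs_gfp(list(zip(g_n0, h_n0)), model=model)
        fits[str(sample)] = fit
        levels[str(sample)] = relative_level(fit, g_n0)

    folds = {
        f"{a}/{b}": fold_difference(levels[a], levels[b])
        for a, b in itertools.permutations(sorted(levels), 2)
    }
    return {
        "plate_efficiency": {pp: {"E": e, "A": a} for pp, (e, a) in sorted(plate.items())},
        "relative_level": dict(sorted(levels.items())),
        "fold_difference": folds,
        "fits": {s: {"a": f.a, "b": f.b, "model": f.model} for s, f in sorted(fits.items())},
    }


def read_cr_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample", "primer_pair", "dilution_factor", "cr"}
    missing = required - set(df.columns)
    if missing:
        raise QpcrError(f"Cr table missing columns: {sorted(missing)}")
    return df
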