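"""Allele-specific quantification: calibration curves, ratio estimation and
imbalance testing (haploChIP and allelic-expression-imbalance assays).

Two-color allelic qPCR reports a log2 fluorescence intensity ratio between
the two alleles of a heterozygote.  A standard curve fitted on genomic-DNA
mixing series (8:1 down to 1:8) linearizes intensity against the true
log2 allele ratio; sample measurements are inverted through the curve and
the cDNA ratio is normalized by the matched genomic-DNA ratio so that 1.0
means balanced allelic output.  Imbalance across heterozygous individuals
is tested with a one-sample t-test against 1.0; antibody-specific allelic
enrichment (haploChIP) compares immunoprecipitation groups against the
control group with Welch's unequal-variance t-test.

All logs are base 2 throughout; gDNA normalization is a subtraction on the
log2 scale (equivalent to dividing the linear ratios).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "AllelicMeasurement",
    "HaploChipResult",
    "STANDARD_MIX_RATIOS",
    "fit_calibration",
    "quantify_allelic_ratio",
    "aei_test",
    "haplochip_allele_enrichment",
]

#: the gDNA mixing-series design: 8:1, 4:1, 2:1, 1:1, 1:2, 1:4, 1:8
STANDARD_MIX_RATIOS = (8.0, 4.0, 2.0, 1.0, 0.5, 0.25, 0.125)


@dataclass(frozen=True)
class CalibrationPoint:
    """One mixing-series point: known allele ratio and measured log2 intensity."""

    mix_ratio: float
    log2_intensity_ratio: float

    def __post_init__(self):
        if self.mix_ratio <= 0:
            raise ValueError("mix_ratio must be positive")


@dataclass(frozen=True)
class CalibrationCurve:
    """log2(intensity ratio) = slope * log2(allele ratio) + intercept."""

    slope: float
    intercept: float
    r_squared: float

    def invert(self, log2_intensity_ratio: float) -> float:
        """Map a measured log2 intensity ratio back to a log2 allele ratio."""
        if abs(self.slope) < 1e-12:
            raise ZeroDivisionError("calibration curve has zero slope")
        return (log2_intensity_ratio - self.intercept) / self.slope


@dataclass(frozen=True)
class AllelicMeasurement:
    """Paired cDNA/gDNA log2 intensity ratios for one heterozygous sample.

    The caller asserts heterozygosity at the locus.  ``signal`` optionally
    carries the absolute assay intensity, used to flag degenerate
    (near-zero-signal) control groups such as IgG.
    """

    sample_id: str
    rsid: str
    cdna_log2_ratio: float
    gdna_log2_ratio: float
    replicate: int = 0
    signal: float | None = None


@dataclass(frozen=True)
class HaploChipResult:
    antibody: str
    allelic_ratio: float
    t_statistic: float
    p_value: float
    n: int
    excluded: bool = False


def fit_calibration(points: list[CalibrationPoint]) -> CalibrationCurve:
    """Ordinary least squares of log2 intensity ratio on log2 mix ratio."""
    if len(points) < 3:
        raise ValueError("calibration requires at least 3 mixing points")
    x = np.log2([p.mix_ratio for p in points])
    y = np.array([p.log2_intensity_ratio for p in points])
    if np.ptp(x) == 0:
        raise ValueError("mix ratios have zero variance")
    if not (x.min() < 0 < x.max()):
        logger.warning(
            "mixing series does not span ratios above and below 1:1"
        )
    fit = stats.linregress(x, y)
    return CalibrationCurve(slope=float(fit.slope),
                            intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue**2))


def quantify_allelic_ratio(m: AllelicMeasurement,
                           curve: CalibrationCurve) -> float:
    """Normalized allelic ratio of one sample (1.0 = no imbalance).

    Both the cDNA and the gDNA log2 intensity ratios are inverted through
    the standard curve; the gDNA log2 allele ratio is subtracted from the
    cDNA one before exponentiation, i.e. the result is
    ratio_cdna / ratio_gdna.
    """
    log2_cdna = curve.invert(m.cdna_log2_ratio)
    log2_gdna = curve.invert(m.gdna_log2_ratio)
    return float(2.0 ** (log2_cdna - log2_gdna))


def aei_test(ratios, expected: float = 1.0) -> tuple[float, float]:
    """One-sample two-tailed t-test of allelic ratios against a 1.0 expectation.

    Constant input exactly equal to the expectation returns (0.0, 1.0) by
    contract; constant input elsewhere has no defined t statistic and is an
    error, as is n < 2.
    """
    arr = np.asarray(list(ratios), dtype=float)
    if len(arr) < 2:
        raise ValueError("aei_test requires at least 2 ratios")
    if np.ptp(arr) == 0:
        if math.isclose(arr[0], expected):
            return 0.0, 1.0
        raise ValueError("ratios have zero variance away from the expectation")
    res = stats.ttest_1samp(arr, popmean=expected)
    return float(res.statistic), float(res.pvalue)


def haplochip_allele_enrichment(
    ip_measurements: dict[str, list[AllelicMeasurement]],
    curve: CalibrationCurve,
    control: str | None = None,
    min_signal: float = 0.0,
) -> dict[str, HaploChipResult]:
    """Per-antibody allelic ratios with Welch comparison against the control.

    ``ip_measurements`` groups measurements by antibody; the control group
    ("input" or "IgG", auto-detected case-insensitively if not named) is
    the reference.  Replicate measurements are averaged on the log2 scale
    per sample before normalization.  Groups whose mean assay signal is at
    or below ``min_signal`` (e.g. a blank IgG pulldown) are flagged and
    excluded from ratio estimation.
    """
    if control is None:
        for key in ip_measurements:
            if key.lower() in ("input", "igg", "control"):
                control = key
                break
    if control is None or control not in ip_measurements:
        raise ValueError("haploChIP requires a control (input or IgG) group")

    def group_log2_ratios(ms: list[AllelicMeasurement]) -> np.ndarray:
        # average replicates per sample on the log2 scale, then invert
        by_sample: dict[str, list[AllelicMeasurement]] = {}
        for m in ms:
            by_sample.setdefault(m.sample_id, []).append(m)
        out = []
        for reps in by_sample.values():
            cdna = float(np.mean([m.cdna_log2_ratio for m in reps]))
            gdna = float(np.mean([m.gdna_log2_ratio for m in reps]))
            out.append(curve.invert(cdna) - curve.invert(gdna))
        return np.asarray(out)

    def group_excluded(ms: list[AllelicMeasurement]) -> bool:
        signals = [m.signal for m in ms if m.signal is not None]
        return bool(signals) and float(np.mean(signals)) <= min_signal

    control_ratios = group_log2_ratios(ip_measurements[control])
    results: dict[str, HaploChipResult] = {}
    for antibody, ms in ip_measurements.items():
        log2_ratios = group_log2_ratios(ms)
        if group_excluded(ms):
            results[antibody] = HaploChipResult(
                antibody, float("nan"), float("nan"), float("nan"),
                n=len(log2_ratios), excluded=True)
            continue
        ratio = float(2.0 ** np.mean(log2_ratios))
        if antibody == control:
            t_stat, p = 0.0, 1.0
        else:
            welch = stats.ttest_ind(log2_ratios, control_ratios,
                                    equal_var=False)
            t_stat, p = float(welch.statistic), float(welch.pvalue)
        results[antibody] = HaploChipResult(antibody, ratio, t_stat, p,
                                            n=len(log2_ratios))
    return results
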