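"""Quantification of the Percentage of UnMethylated Alu (PUMA) from qPCR Cq values.

The estimator is a ratio of efficiency-corrected ratios,

    PUMA = [E_AluH^(-Cq_AluH) / E_L1H^(-Cq_L1H)]
         / [E_AluM^(-Cq_AluM) / E_L1M^(-Cq_L1M)] x 100,

where qAlu H / qAlu M quantify Alu templates after HpaII (methylation-
sensitive) and MspI (insensitive) digestion, and the qL1 reactions normalize
the DNA input of each arm against an L1PA amplicon that carries no CCGG.
Uncertainty is propagated by bootstrap resampling over technical replicates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

ASSAYS = ("qAluH", "qAluM", "qL1H", "qL1M")

CQ_MAX = 45.0


@dataclass(frozen=True)
class QpcrMeasurement:
    """Replicate Cq values of one (sample, assay) well group."""

    sample_id: str
    assay: str
    replicate_cqs: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")
        for cq in self.replicate_cqs:
            if not (0.0 < cq <= CQ_MAX):
                raise ValueError(f"Cq {cq} outside (0, {CQ_MAX}]")

    @property
    def detected(self) -> bool:
        return len(self.replicate_cqs) > 0


class EfficiencySet:
    """Per-assay amplification efficiencies (E = 2 means perfect doubling)."""

    def __init__(
        self,
        efficiencies: Mapping[str, float],
        r_squared: Mapping[str, float] | None = None,
    ):
        for assay in ASSAYS:
            if assay not in efficiencies:
                raise ValueError(f"missing efficiency for assay {assay!r}")
            e = efficiencies[assay]
            if not (1.0 < e <= 2.2):
                raise ValueError(f"efficiency {e} for {assay!r} outside (1, 2.2]")
        self._e = {a: float(efficiencies[a]) for a in ASSAYS}
        self.r_squared = dict(r_squared) if r_squared else {}

    def __getitem__(self, assay: str) -> float:
        return self._e[assay]

    @classmethod
    def uniform(cls, e: float = 2.0) -> "EfficiencySet":
        return cls({a: e for a in ASSAYS})


@dataclass
class PumaResult:
    """PUMA point estimate with resampling SD and cutoff classification."""

    puma: float
    sd: float
    n_resamples: int
    hypomethylated: bool | None = None
    cutoff_used: float | None = None
    not_detected: bool = False


def compute_puma(cq: Mapping[str, float], eff: EfficiencySet) -> float:
    """Efficiency-corrected ratio-of-ratios, as a percentage.

    A missing or non-finite Cq yields NaN (undetermined, mirroring
    non-detected reactions).  Values above 105 trigger a warning but are
    returned raw: an inflated ratio is a diagnostic signal, not data to clamp.
    """
    cqs = {a: cq.get(a, math.nan) for a in ASSAYS}
    if any(c is None or not math.isfinite(c) for c in cqs.values()):
        return math.nan
    num = eff["qAluH"] ** -cqs["qAluH"] / eff["qL1H"] ** -cqs["qL1H"]
    den = eff["qAluM"] ** -cqs["qAluM"] / eff["qL1M"] ** -cqs["qL1M"]
    puma = 100.0 * num / den
    if puma > 105.0:
        warnings.warn(f"PUMA {puma:.1f} exceeds 105%: check assay quality", stacklevel=2)
    return puma


class EfficiencyFit(NamedTuple):
    efficiency: float
    r_squared: float
    slope: float
    intercept: float


def estimate_efficiency(
    dilution_series: Sequence[tuple[float, float]]
) -> EfficiencyFit:
    """Fit a standard curve Cq = m*log10(amount) + b and return E = 10^(-1/m).

    Requires >= 3 points; warns when the series spans < 2 log10 units, when
    r^2 < 0.98 or when E leaves the plausible [1.6, 2.1] range.
    """
    pts = [(float(x), float(y)) for x, y in dilution_series]
    if len(pts) < 3:
        raise ValueError("need >= 3 dilution points to fit a standard curve")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if x.max() - x.min() < 2.0:
        warnings.warn("dilution series spans < 2 log10 units", stacklevel=2)
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError("non-negative standard-curve slope: Cq must fall with input")
    e = 10.0 ** (-1.0 / fit.slope)
    r2 = float(fit.rvalue**2)
    if r2 < 0.98:
        warnings.warn(f"standard curve r^2 = {r2:.3f} < 0.98", stacklevel=2)
    if not (1.6 <= e <= 2.1):
        warnings.warn(f"efficiency {e:.3f} outside [1.6, 2.1]", stacklevel=2)
    return EfficiencyFit(float(e), r2, float(fit.slope), float(fit.intercept))


def drop_replicate_outliers(
    replicate_cqs: Mapping[str, Sequence[float]], max_delta: float = 1.0
) -> dict[str, list[float]]:
    """Optionally drop replicates further than ``max_delta`` cycles from the
    per-assay median.  Not applied by default: data are never silently altered."""
    out: dict[str, list[float]] = {}
    for assay, cqs in replicate_cqs.items():
        cqs = list(cqs)
        if len(cqs) < 2:
            out[assay] = cqs
            continue
        med = float(np.median(cqs))
        out[assay] = [c for c in cqs if abs(c - med) <= max_delta]
    return out


def propagate_uncertainty(
    replicate_cqs: Mapping[str, Sequence[float]],
    eff: EfficiencySet,
    n_resamples: int = 1000,
    seed: int | None = None,
    cutoff: float = 12.0,
) -> PumaResult:
    """Bootstrap PUMA over technical replicates.

    Each resample draws one Cq per assay (with replacement across that
    assay's replicates) and recomputes PUMA; the result reports the mean and
    SD of the resampled distribution.  The seed is mandatory: resampling must
    be reproducible.
    """
    if seed is None:
        raise ValueError("an explicit seed is required for resampling")
    reps = {a: np.asarray(replicate_cqs.get(a, ()), dtype=float) for a in ASSAYS}
    if any(r.size == 0 for r in reps.values()):
        return PumaResult(math.nan, math.nan, 0, None, cutoff, not_detected=True)
    if all(r.size == 1 for r in reps.values()):
        warnings.warn("single replicate in every assay: SD is 0", stacklevel=2)
    rng = np.random.default_rng(seed)
    draws = {
        a: reps[a][rng.integers(0, reps[a].size, size=n_resamples)] for a in ASSAYS
    }
    num = eff["qAluH"] ** -draws["qAluH"] / eff["qL1H"] ** -draws["qL1H"]
    den = eff["qAluM"] ** -draws["qAluM"] / eff["qL1M"] ** -draws["qL1M"]
    pumas = 100.0 * num / den
    mean = float(pumas.mean())
    sd = float(pumas.std(ddof=1)) if n_resamples > 1 else 0.0
    result = PumaResult(mean, sd, n_resamples)
    classify_sample(result, cutoff)
    return result


def classify_sample(result: PumaResult, cutoff: float = 12.0) -> bool | None:
    """Hypomethylated iff PUMA strictly exceeds the cutoff; NaN is undetermined."""
    if math.isnan(result.puma):
        flag = None
    else:
        flag = result.puma > cutoff
    result.hypomethylated = flag
    result.cutoff_used = cutoff
    return flag


def percentile_cutoff(normal_pumas: Sequence[float], q: float = 0.99) -> float:
    """Empirical q-quantile of normal-tissue PUMA (linear interpolation,
    type-7), used as the hypomethylation reference cutoff."""
    values = np.asarray(normal_pumas, dtype=float)
    if values.size < 10:
        raise ValueError("need >= 10 normal values for a stable cutoff")
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    return float(np.quantile(values, q))
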