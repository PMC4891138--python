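"""Mini-genome, methylation-state and Cq simulators with known ground truth.

The generator plants Alu-like copies of a bundled consensus at age-graded
divergence (young, low-divergence copies keep the AACCCGG anchor and the
primer site; old copies progressively lose them), CCGG-free LINE copies used
as the normalizer, and CpG-rich islands, all on a random background contig.
Cq values follow the exponential amplification model
Cq = intercept - log_E(template count) + Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import virtual_qpcr
from .puma_quant import ASSAYS, CQ_MAX
from .types import MethylationState, RepeatFeature, RestrictionSite, revcomp
from .virtual_qpcr import ALU_CONSENSUS, L1_CONSENSUS, PrimerScheme

_BACKGROUND_P = (0.30, 0.20, 0.20, 0.30)  # A, C, G, T: ~40% GC background
_CGI_P = (0.17, 0.33, 0.33, 0.17)  # CpG-island composition, ~66% GC
_CGI_LENGTH = 400

# divergence bands used as subfamily labels: young copies mimic AluY,
# intermediate AluS, old AluJ
_BANDS = ((0.05, "AluYsim"), (0.15, "AluSsim"), (math.inf, "AluJsim"))


@dataclass(frozen=True)
class MiniGenomeSpec:
    """Composition of a planted mini-genome."""

    n_alu: int = 200
    n_line: int = 20
    n_cgi: int = 5
    alu_divergence_range: tuple[float, float] = (0.0, 0.2)
    contig_length: int = 100_000
    seed: int = 0
    contig_name: str = "mini1"

    def __post_init__(self) -> None:
        lo, hi = self.alu_divergence_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("alu_divergence_range must satisfy 0 <= lo <= hi <= 1")
        planted = (
            self.n_alu * len(ALU_CONSENSUS)
            + self.n_line * len(L1_CONSENSUS)
            + self.n_cgi * _CGI_LENGTH
        )
        if planted >= self.contig_length:
            raise ValueError(
                f"planted bp ({planted}) must be < contig_length ({self.contig_length})"
            )


def _subfamily(divergence: float) -> str:
    for upper, name in _BANDS:
        if divergence < upper:
            return name
    raise AssertionError("unreachable")


def _mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """i.i.d. substitutions at the given per-base rate (no indels)."""
    if divergence <= 0:
        return seq
    chars = np.frombuffer(seq.encode(), dtype="S1")
    hit = rng.random(len(seq)) < divergence
    out = chars.copy()
    alphabet = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    for i in np.flatnonzero(hit):
        choices = alphabet[alphabet != chars[i]]
        out[i] = rng.choice(choices)
    return out.tobytes().decode()


def _place_elements(
    lengths: Sequence[int], contig_length: int, rng: np.random.Generator
) -> list[int]:
    """Non-overlapping start positions: elements in random order separated by
    random gaps that partition the free space (feasible at any density)."""
    n = len(lengths)
    free = contig_length - sum(lengths)
    if free < 0:
        raise ValueError("infeasible packing: planted bp exceed contig length")
    order = rng.permutation(n)
    gaps = rng.multinomial(free, np.full(n + 1, 1.0 / (n + 1)))
    starts = [0] * n
    cursor = 0
    for slot, idx in enumerate(order):
        cursor += int(gaps[slot])
        starts[idx] = cursor
        cursor += lengths[idx]
    return starts


def make_minigenome(
    spec: MiniGenomeSpec,
) -> tuple[dict[str, str], dict[str, list[RepeatFeature]]]:
    """Generate (genome, annotations) with planted Alu/LINE/CpG-island features.

    Fully reproducible from ``spec.seed``.  Annotations carry subfamily names
    that encode the divergence band of each Alu copy.
    """
    rng = np.random.default_rng(spec.seed)
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, p=_BACKGROUND_P, size=spec.contig_length)

    lo, hi = spec.alu_divergence_range
    alu_divs = rng.uniform(lo, hi, size=spec.n_alu) if hi > lo else np.full(spec.n_alu, lo)
    elements: list[tuple[str, str, str]] = []  # (sequence, kind, name)
    for d in alu_divs:
        elements.append((_mutate(ALU_CONSENSUS, float(d), rng), "alu", _subfamily(float(d))))
    for _ in range(spec.n_line):
        elements.append((L1_CONSENSUS, "line", "L1PAsim"))
    for _ in range(spec.n_cgi):
        cgi = "".join(rng.choice(bases, p=_CGI_P, size=_CGI_LENGTH))
        elements.append((cgi, "cgi", "CpG_island"))

    starts = _place_elements([len(e[0]) for e in elements], spec.contig_length, rng)
    annotations: dict[str, list[RepeatFeature]] = {"alu": [], "line": [], "cgi": []}
    for (elem_seq, kind, name), start in zip(elements, starts):
        strand = "+" if kind == "cgi" or rng.random() < 0.5 else "-"
        planted = elem_seq if strand == "+" else revcomp(elem_seq)
        seq[start : start + len(planted)] = list(planted)
        meta = {
            "alu": ("Alu", "SINE"),
            "line": ("L1", "LINE"),
            "cgi": ("", ""),
        }[kind]
        annotations[kind].append(
            RepeatFeature(
                spec.contig_name, start, start + len(planted), strand,
                rep_name=name, rep_family=meta[0], rep_class=meta[1],
            )
        )
    for key in annotations:
        annotations[key].sort(key=lambda f: f.start)
    return {spec.contig_name: "".join(seq)}, annotations


def simulate_methylation(
    sites: Sequence[RestrictionSite], p_unmethylated: float, seed: int
) -> MethylationState:
    """i.i.d. Bernoulli methylation per CCGG site (beta 0 or 1)."""
    if not 0.0 <= p_unmethylated <= 1.0:
        raise ValueError("p_unmethylated must be in [0, 1]")
    rng = np.random.default_rng(seed)
    meth = MethylationState()
    unmeth = rng.random(len(sites)) < p_unmethylated
    for site, u in zip(sites, unmeth):
        meth.set_beta(site.contig, site.cut_position, 0.0 if u else 1.0)
    return meth


@dataclass(frozen=True)
class CqModel:
    """Exponential amplification model for Cq generation.

    ``intercepts`` give the Cq of a single template copy; Cq falls by one
    log_E per fold increase in template count.  Matched H/M intercepts make
    the noiseless round-trip exact.
    """

    efficiencies: Mapping[str, float] = field(
        default_factory=lambda: {a: 2.0 for a in ASSAYS}
    )
    intercepts: Mapping[str, float] = field(
        default_factory=lambda: {"qAluH": 34.0, "qAluM": 34.0, "qL1H": 31.0, "qL1M": 31.0}
    )
    noise_sd: float = 0.15
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for a in ASSAYS:
            if not (1.0 < self.efficiencies[a] <= 2.2):
                raise ValueError(f"efficiency for {a} outside (1, 2.2]")
        if self.replicates < 1:
            raise ValueError("need >= 1 replicate")


def count_l1_templates(
    genome: Mapping[str, str],
    line_features: Sequence[RepeatFeature],
    scheme: PrimerScheme,
) -> int:
    """LINE elements carrying both L1PA primer sites (either orientation)."""
    fwd, rev = scheme.l1pa_forward, revcomp(scheme.l1pa_reverse)
    n = 0
    for f in line_features:
        elem = genome[f.contig][f.start : f.end]
        if (fwd in elem and rev in elem) or (
            fwd in revcomp(elem) and rev in revcomp(elem)
        ):
            n += 1
    return n


def simulate_cq(
    genome: Mapping[str, str],
    annotations: Mapping[str, Sequence[RepeatFeature]],
    scheme: PrimerScheme,
    meth: MethylationState,
    model: CqModel,
    seed: int,
    sites: Sequence[RestrictionSite] | None = None,
    candidates: Sequence | None = None,
) -> dict[str, list[float]]:
    """Generate replicate Cq values for the four assays of one sample.

    Template counts come from the electronic PCR (HpaII- and MspI-amplifiable
    Alu products under ``meth``; L1PA copies are digestion-independent).  A
    zero template count yields an empty replicate list (not detected).
    ``candidates`` may carry precomputed maximal (MspI, fully digestible)
    amplicons to avoid rescanning primers across many simulated samples.
    """
    if sites is None:
        sites = virtual_qpcr.find_sites(genome)
    if candidates is None:
        candidates = virtual_qpcr.predict_amplicons(
            genome, annotations["alu"], scheme, "MspI", None, sites
        )
    n_m = len(candidates)
    n_h = sum(
        1 for a in candidates if not meth.is_methylated(*a.anchored_site.key)
    )
    n_l1 = count_l1_templates(genome, annotations.get("line", ()), scheme)
    counts = {"qAluH": n_h, "qAluM": n_m, "qL1H": n_l1, "qL1M": n_l1}

    rng = np.random.default_rng(seed)
    out: dict[str, list[float]] = {}
    for assay in ASSAYS:
        n = counts[assay]
        if n == 0:
            out[assay] = []  # not detected
            continue
        e = model.efficiencies[assay]
        base = model.intercepts[assay] - math.log(n) / math.log(e)
        noise = rng.normal(0.0, model.noise_sd, size=model.replicates) if model.noise_sd else np.zeros(model.replicates)
        out[assay] = [float(min(max(base + x, 1e-6), CQ_MAX)) for x in noise]
    return out
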