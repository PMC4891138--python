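"""Electronic qPCR: methylation-aware HpaII/MspI digestion and amplicon prediction.

Models the assay in silico: genomic DNA is cut at CCGG (MspI always; HpaII
only where the internal CpG is unmethylated), a synthetic adaptor is ligated
to every cut end, and a product is amplified wherever a cut falls in the
AACC^CGG Alu consensus context with a matching Alu primer on the side
pointing toward the cut.  The set of Alu elements owning >= 1 such product
under full digestion (MspI, everything unmethylated) is the QUAluome.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .types import (
    MethylationState,
    RepeatFeature,
    RestrictionSite,
    VirtualAmplicon,
    as_genome,
    revcomp,
)

ENZYMES = ("HpaII", "MspI")


def _load_consensus() -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    text = resources.files("qualu.data").joinpath("consensus.fa").read_text()
    for line in text.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = ""
        elif name:
            seqs[name] += line.strip()
    return seqs


_CONSENSUS = _load_consensus()
ALU_CONSENSUS = _CONSENSUS["AluY_like"]
L1_CONSENSUS = _CONSENSUS["L1PA_like"]


@dataclass(frozen=True)
class PrimerScheme:
    """Primer/adaptor configuration of the assay.

    The chimeric primer is the adaptor followed by the AACC left behind on the
    upstream fragment after an AACC^CGG cut; the Alu primer anneals to the
    consensus ~20 nt upstream of the cut, pointing toward it.
    """

    adaptor_sequence: str
    alu_primer: str
    l1pa_forward: str
    l1pa_reverse: str
    max_mismatches: int = 1
    three_prime_clamp: int = 5
    amplicon_min: int = 40
    amplicon_max: int = 200

    def __post_init__(self) -> None:
        for name in ("adaptor_sequence", "alu_primer", "l1pa_forward", "l1pa_reverse"):
            seq = getattr(self, name)
            if not seq or set(seq.upper()) - set("ACGT"):
                raise ValueError(f"{name} must be non-empty over A/C/G/T")
        if self.amplicon_min >= self.amplicon_max:
            raise ValueError("amplicon_min must be < amplicon_max")
        if self.three_prime_clamp > len(self.alu_primer):
            raise ValueError("three_prime_clamp exceeds alu_primer length")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")

    @property
    def chimeric_primer(self) -> str:
        return self.adaptor_sequence + "AACC"


def default_scheme(**overrides) -> PrimerScheme:
    """The bundled scheme: a 20-mer Alu primer ending 1 nt before the AACC
    junction of the consensus anchor, and a CCGG-free L1PA amplicon."""
    m = ALU_CONSENSUS.find("AACCCGG")
    params = dict(
        adaptor_sequence="GACTCAGTACGATTGGAATC",
        alu_primer=ALU_CONSENSUS[m - 21 : m - 1],
        l1pa_forward=L1_CONSENSUS[100:120],
        l1pa_reverse=revcomp(L1_CONSENSUS[200:220]),
        max_mismatches=1,
        three_prime_clamp=5,
        amplicon_min=40,
        amplicon_max=200,
    )
    params.update(overrides)
    scheme = PrimerScheme(**params)
    _check_l1_amplicon(scheme)
    return scheme


def _check_l1_amplicon(scheme: PrimerScheme) -> None:
    """Warn if the L1PA normalization amplicon contains a CCGG: its copy
    number must be digestion-independent for the normalization to cancel."""
    fwd = L1_CONSENSUS.find(scheme.l1pa_forward)
    rev = L1_CONSENSUS.find(revcomp(scheme.l1pa_reverse))
    if fwd != -1 and rev != -1:
        amplicon = L1_CONSENSUS[fwd : rev + len(scheme.l1pa_reverse)]
    else:
        amplicon = scheme.l1pa_forward + revcomp(scheme.l1pa_reverse)
    if "CCGG" in amplicon:
        warnings.warn(
            "L1PA amplicon contains a CCGG site; normalization will be "
            "digestion-dependent",
            stacklevel=2,
        )


def find_sites(genome) -> list[RestrictionSite]:
    """All CCGG occurrences, flagged for AACCCGG context on either strand."""
    sites: list[RestrictionSite] = []
    for contig, seq in as_genome(genome).items():
        pos = seq.find("CCGG")
        while pos != -1:
            fwd = pos >= 3 and seq[pos - 3 : pos + 4] == "AACCCGG"
            rev = seq[pos : pos + 7] == "CCGGGTT"
            sites.append(RestrictionSite(contig, pos, fwd, rev))
            pos = seq.find("CCGG", pos + 1)
    return sites


def _enzyme_cuts(
    sites: Iterable[RestrictionSite], enzyme: str, meth: MethylationState | None
) -> list[RestrictionSite]:
    if enzyme not in ENZYMES:
        raise ValueError(f"unknown enzyme {enzyme!r}; expected one of {ENZYMES}")
    if enzyme == "MspI" or meth is None:
        return list(sites)
    return [s for s in sites if not meth.is_methylated(*s.key)]


def digest(
    genome,
    enzyme: str,
    meth: MethylationState | None = None,
    sites: Sequence[RestrictionSite] | None = None,
) -> dict[str, list[tuple[int, int]]]:
    """Fragment each contig at enzyme cut positions.

    MspI cuts every CCGG; HpaII skips methylated sites.  Fragments tile each
    contig exactly.
    """
    contigs = as_genome(genome)
    if sites is None:
        sites = find_sites(contigs)
    cut = _enzyme_cuts(sites, enzyme, meth)
    by_contig: dict[str, list[int]] = {name: [] for name in contigs}
    for s in cut:
        by_contig[s.contig].append(s.cut_position)
    fragments: dict[str, list[tuple[int, int]]] = {}
    for name, seq in contigs.items():
        bounds = [0] + sorted(set(by_contig[name])) + [len(seq)]
        fragments[name] = [
            (a, b) for a, b in zip(bounds, bounds[1:]) if b > a
        ]
    return fragments


def _mismatches(primer: str, target: str, clamp: int, max_mm: int) -> int | None:
    """Mismatch count of primer vs target, or None if the 3' clamp is broken
    or the budget exceeded.  N in the target never matches."""
    if len(target) != len(primer):
        return None
    mm = 0
    n = len(primer)
    for i in range(n - 1, -1, -1):
        if primer[i] != target[i]:
            if i >= n - clamp:
                return None
            mm += 1
            if mm > max_mm:
                return None
    return mm


def predict_amplicons(
    genome,
    alu_features: Sequence[RepeatFeature],
    scheme: PrimerScheme,
    enzyme: str = "MspI",
    meth: MethylationState | None = None,
    sites: Sequence[RestrictionSite] | None = None,
) -> list[VirtualAmplicon]:
    """Enumerate assay products over the annotated Alu elements.

    A product is emitted for each AACCCGG-context cut site inside an Alu where
    the enzyme cuts under ``meth``, the Alu primer matches the element within
    ``max_mismatches`` (exact 3' clamp) on the orientation pointing toward the
    cut, and the product length (including the adaptor) falls in
    [amplicon_min, amplicon_max].  One product per (site, orientation), at the
    primer placement closest to the cut.
    """
    contigs = as_genome(genome)
    if sites is None:
        sites = find_sites(contigs)
    cut_sites = _enzyme_cuts(sites, enzyme, meth)

    trees: dict[str, IntervalTree] = {}
    for f in alu_features:
        trees.setdefault(f.contig, IntervalTree()).addi(f.start, f.end, f)

    primer = scheme.alu_primer.upper()
    lp = len(primer)
    adaptor_len = len(scheme.adaptor_sequence)
    # genomic span g must satisfy amplicon_min <= g + adaptor_len <= amplicon_max
    g_min = max(scheme.amplicon_min - adaptor_len, lp)
    g_max = scheme.amplicon_max - adaptor_len

    amplicons: list[VirtualAmplicon] = []
    for site in cut_sites:
        if not site.in_aacccgg_context:
            continue
        tree = trees.get(site.contig)
        if tree is None:
            continue
        owners = [
            iv.data
            for iv in tree.overlap(site.site_start, site.site_start + 4)
            if iv.data.start <= site.site_start and site.site_start + 4 <= iv.data.end
        ]
        if not owners:
            continue
        seq = contigs[site.contig]
        for element in owners:
            if site.context_forward:
                cut = site.cut_position  # AACC | CGG on the forward strand
                # primer window [p, p+lp) upstream, entirely inside the element
                for g in range(g_min, g_max + 1):
                    p = cut - g
                    if p < element.start or p + lp > cut:
                        continue
                    mm = _mismatches(
                        primer, seq[p : p + lp], scheme.three_prime_clamp,
                        scheme.max_mismatches,
                    )
                    if mm is not None:
                        amplicons.append(VirtualAmplicon(
                            element, site.contig, p, cut, "+",
                            g + adaptor_len, site, mm,
                        ))
                        break
            if site.context_reverse:
                cut = site.site_start + 3  # bottom-strand C^CGG in forward coords
                for g in range(g_min, g_max + 1):
                    q_end = cut + g
                    if q_end > element.end or q_end - lp < cut:
                        continue
                    mm = _mismatches(
                        primer, revcomp(seq[q_end - lp : q_end]),
                        scheme.three_prime_clamp, scheme.max_mismatches,
                    )
                    if mm is not None:
                        amplicons.append(VirtualAmplicon(
                            element, site.contig, cut, q_end, "-",
                            g + adaptor_len, site, mm,
                        ))
                        break
    return amplicons


@dataclass(frozen=True)
class QuameomeSummary:
    n_elements: int
    fraction_of_aluome: float
    subfamily_counts: Mapping[str, int] = field(default_factory=dict)


def quameome_census(
    amplicons: Sequence[VirtualAmplicon], alu_features: Sequence[RepeatFeature]
) -> QuameomeSummary:
    """Distinct Alu elements owning >= 1 predicted product, with the fraction
    of the Aluome they represent and a per-subfamily histogram."""
    owners = {a.element for a in amplicons}
    counts = Counter(f.rep_name for f in owners)
    fraction = len(owners) / len(alu_features) if alu_features else 0.0
    return QuameomeSummary(len(owners), fraction, dict(counts))


def expected_puma(
    genome,
    alu_features: Sequence[RepeatFeature],
    scheme: PrimerScheme,
    meth: MethylationState | None = None,
    sites: Sequence[RestrictionSite] | None = None,
) -> float:
    """Simulator ground truth: 100 x HpaII-amplifiable / MspI-amplifiable products."""
    contigs = as_genome(genome)
    if sites is None:
        sites = find_sites(contigs)
    n_m = len(predict_amplicons(contigs, alu_features, scheme, "MspI", meth, sites))
    if n_m == 0:
        raise ValueError("no MspI-amplifiable products; expected PUMA undefined")
    n_h = len(predict_amplicons(contigs, alu_features, scheme, "HpaII", meth, sites))
    return 100.0 * n_h / n_m
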