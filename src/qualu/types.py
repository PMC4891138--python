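"""Core domain types shared across the package.

Coordinates are 0-based, half-open throughout (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

VALID_STRANDS = {"+", "-", "."}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> str:
    """Uppercase a DNA sequence and validate its alphabet (A/C/G/T/N only)."""
    s = seq.upper()
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return s


def as_genome(genome) -> dict[str, str]:
    """Coerce a bare string or a contig->sequence mapping into a genome dict."""
    if isinstance(genome, str):
        return {"seq": normalize_sequence(genome)}
    return {name: normalize_sequence(seq) for name, seq in genome.items()}


@dataclass(frozen=True)
class RepeatFeature:
    """One annotated repeat or CpG-island interval (0-based, half-open)."""

    contig: str
    start: int
    end: int
    strand: str = "."
    rep_name: str = ""
    rep_family: str = ""
    rep_class: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.rep_name!r}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence; on strand '-' the genome carries the reverse complement."""

    contig: str
    start: int
    end: int
    strand: str
    motif: str


@dataclass(frozen=True)
class RestrictionSite:
    """A CCGG (HpaII/MspI) recognition site.

    ``cut_position`` is the top-strand cut offset (C^CGG cuts after the first C).
    ``context_forward``/``context_reverse`` flag whether the site sits in the
    AACCCGG Alu consensus context on the forward or reverse strand.
    """

    contig: str
    site_start: int
    context_forward: bool = False
    context_reverse: bool = False

    @property
    def cut_position(self) -> int:
        return self.site_start + 1

    @property
    def in_aacccgg_context(self) -> bool:
        return self.context_forward or self.context_reverse

    @property
    def key(self) -> tuple[str, int]:
        """Canonical methylation-state key: (contig, top-strand cut position)."""
        return (self.contig, self.cut_position)


class MethylationState:
    """Per-CCGG-site methylation assignment.

    Keyed by (contig, top-strand cut position); values are betas in [0, 1]
    interpreted as the methylated fraction.  A site absent from the mapping is
    unmethylated.  For deterministic digestion a site counts as methylated when
    beta >= 0.5.
    """

    def __init__(self, betas: Mapping[tuple[str, int], float] | None = None):
        self._betas: dict[tuple[str, int], float] = {}
        if betas:
            for key, beta in betas.items():
                self.set_beta(key[0], key[1], beta)

    def set_beta(self, contig: str, cut_position: int, beta: float) -> None:
        if not 0.0 <= beta <= 1.0:
            raise ValueError(f"beta {beta} outside [0, 1]")
        self._betas[(contig, int(cut_position))] = float(beta)

    def beta(self, contig: str, cut_position: int) -> float:
        return self._betas.get((contig, cut_position), 0.0)

    def is_methylated(self, contig: str, cut_position: int) -> bool:
        return self.beta(contig, cut_position) >= 0.5

    def items(self) -> Iterator[tuple[tuple[str, int], float]]:
        return iter(sorted(self._betas.items()))

    def __len__(self) -> int:
        return len(self._betas)

    def unmethylated_fraction(self, sites: Iterable[RestrictionSite]) -> float:
        sites = list(sites)
        if not sites:
            raise ValueError("no sites supplied")
        unmeth = sum(not self.is_methylated(*s.key) for s in sites)
        return unmeth / len(sites)


@dataclass(frozen=True)
class VirtualAmplicon:
    """A predicted assay product anchored at an AACC^CGG cut inside an Alu.

    ``start``/``end`` delimit the genomic footprint (primer 5' end to the cut);
    ``length`` is the full product length including the ligated adaptor.
    """

    element: RepeatFeature
    contig: str
    start: int
    end: int
    strand: str
    length: int
    anchored_site: RestrictionSite
    mismatches: int = 0

    @property
    def subfamily(self) -> str:
        return self.element.rep_name
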