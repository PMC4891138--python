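"""Genome-wide accounting of CpGs, CCGG sites and the AACCCGG Alu anchor.

Produces a per-class census (Alu, LINE, CpG island, whole genome) of element
counts, base pairs, and motif occurrences attributed to each class by
>= 1 bp interval overlap.  Classes are not made exclusive: an occurrence
inside both an Alu and a CpG island counts in both rows, mirroring
independent per-class interval intersections.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .types import MotifHit, RepeatFeature, as_genome, normalize_sequence, revcomp

CENSUS_CLASSES = ("Alu", "LINE", "CpG_island", "Genome")


def scan_motif(genome, motif: str, both_strands: bool = True) -> list[MotifHit]:
    """Find every occurrence of ``motif`` in the genome.

    With ``both_strands``, occurrences of the reverse complement are also
    reported, on strand '-'.  A palindromic motif is reported once per
    position (strand '+').  Overlapping occurrences are all reported; windows
    containing N never match.
    """
    motif = motif.upper()
    if not motif or set(motif) - set("ACGT"):
        raise ValueError(f"motif must be non-empty over A/C/G/T, got {motif!r}")
    contigs = as_genome(genome)
    rc = revcomp(motif)
    hits: list[MotifHit] = []
    for contig, seq in contigs.items():
        for m, strand in ((motif, "+"), (rc, "-")):
            if strand == "-" and (not both_strands or rc == motif):
                continue
            pos = seq.find(m)
            while pos != -1:
                hits.append(MotifHit(contig, pos, pos + len(m), strand, motif))
                pos = seq.find(m, pos + 1)
    hits.sort(key=lambda h: (h.contig, h.start, h.strand))
    return hits


def count_cpg(genome) -> int:
    """Number of CG dinucleotides on the forward strand (CpG is strand-symmetric)."""
    return sum(seq.count("CG") for seq in as_genome(genome).values())


def _parse_rm_out_line(line: str, lineno: int) -> RepeatFeature:
    fields = line.split()
    if len(fields) < 11:
        raise ValueError(f"malformed RepeatMasker line {lineno}: {line!r}")
    try:
        contig = fields[4]
        start = int(fields[5]) - 1  # .out is 1-based inclusive
        end = int(fields[6])
        strand = "-" if fields[8] in ("C", "-") else "+"
        rep_name = fields[9]
        class_family = fields[10]
    except (IndexError, ValueError) as exc:
        raise ValueError(f"malformed RepeatMasker line {lineno}: {line!r}") from exc
    if "/" in class_family:
        rep_class, rep_family = class_family.split("/", 1)
    else:
        rep_class, rep_family = class_family, class_family
    return RepeatFeature(contig, start, end, strand, rep_name, rep_family, rep_class)


def _parse_bed6plus_line(line: str, lineno: int) -> RepeatFeature:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise ValueError(f"malformed BED6+ line {lineno}: {line!r}")
    try:
        contig, start, end, name, _score, strand = fields[:6]
        rep_class = fields[6] if len(fields) > 6 else ""
        rep_family = fields[7] if len(fields) > 7 else ""
        return RepeatFeature(
            contig, int(start), int(end), strand, name, rep_family, rep_class
        )
    except ValueError as exc:
        raise ValueError(f"malformed BED6+ line {lineno}: {line!r}") from exc


_RM_HEADER_TOKENS = ("SW", "score", "perc")


def load_repeatmasker(path, dialect: str = "rm_out") -> list[RepeatFeature]:
    """Load repeat annotations from RepeatMasker ``.out`` or BED6+ files.

    Coordinates are normalized to 0-based half-open; each annotation row is
    one element (fragmented elements are not merged).
    """
    if dialect not in ("rm_out", "bed6plus"):
        raise ValueError(f"unknown dialect {dialect!r}")
    parse = _parse_rm_out_line if dialect == "rm_out" else _parse_bed6plus_line
    features: list[RepeatFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            if dialect == "rm_out" and stripped.split()[0] in _RM_HEADER_TOKENS:
                continue
            features.append(parse(line, lineno))
    return features


def filter_alu(features: Iterable[RepeatFeature]) -> list[RepeatFeature]:
    """Keep Alu-family repeats, discarding FLAM/FRAM free monomers."""
    out = []
    for f in features:
        if f.rep_family.lower() != "alu":
            continue
        if f.rep_name.upper().startswith(("FLAM", "FRAM")):
            continue
        out.append(f)
    return out


def _feature_trees(features: Sequence[RepeatFeature]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for f in features:
        trees.setdefault(f.contig, IntervalTree()).addi(f.start, f.end, f)
    return trees


def _count_overlapping(
    trees: Mapping[str, IntervalTree], intervals: Iterable[tuple[str, int, int]]
) -> int:
    n = 0
    for contig, start, end in intervals:
        tree = trees.get(contig)
        if tree is not None and tree.overlaps(start, end):
            n += 1
    return n


def census(
    genome,
    alu_features: Sequence[RepeatFeature] = (),
    line_features: Sequence[RepeatFeature] = (),
    cgi_features: Sequence[RepeatFeature] = (),
    amplicons: Sequence = (),
    motif_both_strands: bool = True,
) -> pd.DataFrame:
    """Per-class accounting of elements, bp, CpGs, CCGG sites and AACCCGG hits.

    Returns a DataFrame indexed by class with raw counts plus percentages of
    the genome totals.  ``amplicons`` (predicted maximal assay products) fill
    the ``n_quamplicons`` column with the count of distinct elements owning
    >= 1 product.
    """
    contigs = as_genome(genome)
    lengths = {name: len(seq) for name, seq in contigs.items()}
    for f in list(alu_features) + list(line_features) + list(cgi_features):
        if f.contig not in lengths:
            raise ValueError(f"feature on unknown contig {f.contig!r}")
        if f.end > lengths[f.contig]:
            raise ValueError(f"feature {f} extends past end of contig {f.contig!r}")

    cpg_intervals = [
        (h.contig, h.start, h.end)
        for h in scan_motif(contigs, "CG", both_strands=False)
    ]
    ccgg_hits = scan_motif(contigs, "CCGG", both_strands=True)  # palindromic: one/pos
    motif_hits = scan_motif(contigs, "AACCCGG", both_strands=motif_both_strands)
    ccgg_intervals = [(h.contig, h.start, h.end) for h in ccgg_hits]
    motif_intervals = [(h.contig, h.start, h.end) for h in motif_hits]

    owners = {a.element for a in amplicons}
    rows = {}
    per_class = {
        "Alu": list(alu_features),
        "LINE": list(line_features),
        "CpG_island": list(cgi_features),
    }
    for cls, feats in per_class.items():
        trees = _feature_trees(feats)
        rows[cls] = {
            "n_elements": len(feats),
            "n_bp": sum(f.length for f in feats),
            "n_cpg": _count_overlapping(trees, cpg_intervals),
            "n_ccgg": _count_overlapping(trees, ccgg_intervals),
            "n_aacccgg": _count_overlapping(trees, motif_intervals),
            "n_quamplicons": sum(1 for f in feats if f in owners),
        }
    rows["Genome"] = {
        "n_elements": sum(len(v) for v in per_class.values()),
        "n_bp": sum(lengths.values()),
        "n_cpg": len(cpg_intervals),
        "n_ccgg": len(ccgg_intervals),
        "n_aacccgg": len(motif_intervals),
        "n_quamplicons": len(owners),
    }
    table = pd.DataFrame.from_dict(rows, orient="index").loc[list(CENSUS_CLASSES)]
    genome_row = table.loc["Genome"]
    for col in ("n_bp", "n_cpg", "n_ccgg", "n_aacccgg"):
        total = genome_row[col]
        table[f"pct_{col[2:]}"] = 100.0 * table[col] / total if total else 0.0
    return table


def element_motif_fraction(features: Sequence[RepeatFeature], motif_hits) -> float:
    """Fraction of elements fully containing >= 1 motif hit."""
    if not features:
        raise ValueError("no elements supplied")
    trees: dict[str, IntervalTree] = {}
    for h in motif_hits:
        trees.setdefault(h.contig, IntervalTree()).addi(h.start, h.end)
    n = 0
    for f in features:
        tree = trees.get(f.contig)
        if tree is None:
            continue
        if any(iv.begin >= f.start and iv.end <= f.end for iv in tree.overlap(f.start, f.end)):
            n += 1
    return n / len(features)
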