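"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (quadratic scans, exhaustive
enumeration) and shares no code with the implementation under test.
"""

from __future__ import annotations

from itertools import product

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def naive_motif_positions(seq: str, motif: str, both_strands: bool) -> list[tuple[int, str]]:
    """Sliding-window motif scan; (-) hits are reverse-complement occurrences."""
    hits = []
    rc = naive_revcomp(motif)
    for i in range(len(seq) - len(motif) + 1):
        window = seq[i : i + len(motif)]
        if window == motif:
            hits.append((i, "+"))
        elif both_strands and rc != motif and window == rc:
            hits.append((i, "-"))
    return hits


def naive_overlap_count(
    intervals: list[tuple[str, int, int]], features
) -> int:
    """Occurrences sharing >= 1 base with >= 1 feature, by double loop."""
    n = 0
    for contig, start, end in intervals:
        for f in features:
            if f.contig == contig and start < f.end and f.start < end:
                n += 1
                break
    return n


def naive_census_row(seq: str, contig: str, features) -> dict[str, int]:
    """One census row computed entirely from naive scans."""
    cpgs = [(contig, i, i + 2) for i, _ in naive_motif_positions(seq, "CG", False)]
    ccggs = [(contig, i, i + 4) for i, _ in naive_motif_positions(seq, "CCGG", True)]
    anchors = [
        (contig, i, i + 7) for i, _ in naive_motif_positions(seq, "AACCCGG", True)
    ]
    return {
        "n_elements": len(features),
        "n_bp": sum(f.end - f.start for f in features),
        "n_cpg": naive_overlap_count(cpgs, features),
        "n_ccgg": naive_overlap_count(ccggs, features),
        "n_aacccgg": naive_overlap_count(anchors, features),
    }


def naive_mismatch_ok(primer: str, target: str, clamp: int, max_mm: int) -> bool:
    if len(primer) != len(target):
        return False
    if primer[len(primer) - clamp :] != target[len(target) - clamp :]:
        return False
    mm = sum(a != b for a, b in zip(primer, target))
    return mm <= max_mm


def naive_amplifiable_anchors(seq: str, contig: str, alu_features, scheme):
    """Every (site_start, orientation, element) triple with >= 1 valid primer
    placement, by exhaustive enumeration over all placements."""
    lp = len(scheme.alu_primer)
    la = len(scheme.adaptor_sequence)
    triples = set()
    for s, _ in naive_motif_positions(seq, "CCGG", False):
        fwd_ctx = s >= 3 and seq[s - 3 : s + 4] == "AACCCGG"
        rev_ctx = seq[s : s + 7] == "CCGGGTT"
        for f in alu_features:
            if f.contig != contig or not (f.start <= s and s + 4 <= f.end):
                continue
            if fwd_ctx:
                cut = s + 1
                for p in range(f.start, cut - lp + 1):
                    length = (cut - p) + la
                    if not scheme.amplicon_min <= length <= scheme.amplicon_max:
                        continue
                    if naive_mismatch_ok(
                        scheme.alu_primer, seq[p : p + lp],
                        scheme.three_prime_clamp, scheme.max_mismatches,
                    ):
                        triples.add((s, "+", f))
                        break
            if rev_ctx:
                cut = s + 3
                for q_end in range(cut + lp, f.end + 1):
                    length = (q_end - cut) + la
                    if not scheme.amplicon_min <= length <= scheme.amplicon_max:
                        continue
                    if naive_mismatch_ok(
                        scheme.alu_primer, naive_revcomp(seq[q_end - lp : q_end]),
                        scheme.three_prime_clamp, scheme.max_mismatches,
                    ):
                        triples.add((s, "-", f))
                        break
    return triples


def exhaustive_bootstrap_moments(replicates: dict, eff) -> tuple[float, float]:
    """Mean and population SD of PUMA over every replicate combination
    (the limit of bootstrap resampling with uniform draws)."""
    assays = ("qAluH", "qAluM", "qL1H", "qL1M")
    pumas = []
    for combo in product(*(replicates[a] for a in assays)):
        cq = dict(zip(assays, combo))
        num = eff["qAluH"] ** -cq["qAluH"] / eff["qL1H"] ** -cq["qL1H"]
        den = eff["qAluM"] ** -cq["qAluM"] / eff["qL1M"] ** -cq["qL1M"]
        pumas.append(100.0 * num / den)
    n = len(pumas)
    mean = sum(pumas) / n
    var = sum((x - mean) ** 2 for x in pumas) / n
    return mean, var**0.5
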