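"""Does the single AACC^CGG site report whole-element Alu methylation?

Given a per-CpG methylation track, compares the beta of the assay's anchor
CpG against the mean beta of all other covered CpGs in the same Alu element.
An element is concordant when the absolute difference is at most ``delta``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .types import RepeatFeature, RestrictionSite

TRACK_COLUMNS = ("contig", "pos", "beta", "coverage")


def make_track(records) -> pd.DataFrame:
    """Build a per-CpG methylation track from (contig, pos, beta[, coverage]) rows."""
    rows = []
    for rec in records:
        contig, pos, beta = rec[0], int(rec[1]), float(rec[2])
        coverage = int(rec[3]) if len(rec) > 3 else 1
        if not 0.0 <= beta <= 1.0:
            raise ValueError(f"beta {beta} outside [0, 1] at {contig}:{pos}")
        rows.append((contig, pos, beta, coverage))
    track = pd.DataFrame(rows, columns=list(TRACK_COLUMNS))
    track.sort_values(["contig", "pos"], inplace=True, ignore_index=True)
    if track.duplicated(["contig", "pos"]).any():
        raise ValueError("duplicate CpG positions in track")
    return track


def site_vs_element_concordance(
    track: pd.DataFrame,
    alu_features: Sequence[RepeatFeature],
    sites: Sequence[RestrictionSite],
    min_coverage: int = 1,
    delta: float = 0.25,
) -> tuple[float, pd.DataFrame]:
    """Fraction of eligible Alu elements whose anchor-site beta agrees with the
    element mean within ``delta``.

    Eligible elements contain an AACCCGG-context site whose CpG is covered and
    >= 3 other covered CpGs.  Returns (fraction, per-element table).
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must be in [0, 1]")
    covered = track[track["coverage"] >= min_coverage]
    by_contig = {c: g.set_index("pos")["beta"] for c, g in covered.groupby("contig")}

    anchor_sites = [s for s in sites if s.in_aacccgg_context]
    rows = []
    for elem in alu_features:
        betas = by_contig.get(elem.contig)
        if betas is None:
            continue
        in_elem = betas[(betas.index >= elem.start) & (betas.index < elem.end)]
        for site in anchor_sites:
            if site.contig != elem.contig:
                continue
            cpg_pos = site.site_start + 1  # the C of the CCGG's internal CpG
            if not (elem.start <= site.site_start and site.site_start + 4 <= elem.end):
                continue
            if cpg_pos not in in_elem.index:
                continue
            others = in_elem.drop(cpg_pos)
            if len(others) < 3:
                continue
            site_beta = float(in_elem[cpg_pos])
            elem_mean = float(others.mean())
            rows.append(
                {
                    "contig": elem.contig,
                    "element_start": elem.start,
                    "element_end": elem.end,
                    "subfamily": elem.rep_name,
                    "site_pos": cpg_pos,
                    "site_beta": site_beta,
                    "element_mean_beta": elem_mean,
                    "n_other_cpgs": len(others),
                    "concordant": abs(site_beta - elem_mean) <= delta,
                }
            )
    if not rows:
        raise ValueError("no eligible elements (covered anchor + >= 3 other CpGs)")
    table = pd.DataFrame(rows)
    return float(table["concordant"].mean()), table
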