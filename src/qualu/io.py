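"""Readers and writers for the standard formats the tool consumes and emits.

FASTA (via pyfaidx), BED intervals, bedGraph methylation tracks/states,
Cq and dilution-series CSV tables (via pandas), and TOML primer schemes.
"""

from __future__ import annotations

import tomllib
from typing import Mapping, Sequence

import pandas as pd
from pyfaidx import Fasta

from .puma_quant import ASSAYS
from .types import MethylationState, RepeatFeature, normalize_sequence
from .virtual_qpcr import PrimerScheme, default_scheme


def read_fasta(path) -> dict[str, str]:
    """Load a (multi-contig) FASTA into a contig -> uppercase-sequence dict."""
    fa = Fasta(str(path), sequence_always_upper=True, rebuild=True)
    return {name: normalize_sequence(str(fa[name])) for name in fa.keys()}


def write_fasta(genome: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path) -> list[RepeatFeature]:
    """BED4/BED6/BED6+2 intervals (name = rep_name; columns 7-8 = class, family)."""
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"malformed BED line {lineno}: {line!r}")
            features.append(
                RepeatFeature(
                    f[0], int(f[1]), int(f[2]),
                    f[5] if len(f) > 5 else ".",
                    rep_name=f[3] if len(f) > 3 else "",
                    rep_class=f[6] if len(f) > 6 else "",
                    rep_family=f[7] if len(f) > 7 else "",
                )
            )
    return features


def write_bed(features: Sequence[RepeatFeature], path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(
                f"{f.contig}\t{f.start}\t{f.end}\t{f.rep_name}\t0\t{f.strand}"
                f"\t{f.rep_class}\t{f.rep_family}\n"
            )


def read_methylation_bedgraph(path) -> MethylationState:
    """Methylation state over CCGG cut positions (chrom, start, end, beta)."""
    meth = MethylationState()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"malformed bedGraph line {lineno}: {line!r}")
            meth.set_beta(f[0], int(f[1]), float(f[3]))
    return meth


def write_methylation_bedgraph(meth: MethylationState, path) -> None:
    with open(path, "w") as fh:
        for (contig, cut), beta in meth.items():
            fh.write(f"{contig}\t{cut}\t{cut + 1}\t{beta:g}\n")


def read_track_bedgraph(path) -> pd.DataFrame:
    """Per-CpG methylation track: chrom, start, end, beta [, coverage]."""
    from .wgbs_concordance import make_track

    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            records.append(
                (f[0], int(f[1]), float(f[3]), int(f[4]) if len(f) > 4 else 1)
            )
    return make_track(records)


def read_cq_csv(path) -> dict[str, dict[str, list[float]]]:
    """Well table (sample_id, assay, replicate, cq) -> nested replicate dict.

    An empty cq field marks a non-detected well and contributes no replicate.
    """
    df = pd.read_csv(path)
    required = {"sample_id", "assay", "cq"}
    if not required.issubset(df.columns):
        raise ValueError(f"Cq CSV must have columns {sorted(required)}")
    bad = set(df["assay"]) - set(ASSAYS)
    if bad:
        raise ValueError(f"unknown assays in Cq CSV: {sorted(bad)}")
    out: dict[str, dict[str, list[float]]] = {}
    for (sample, assay), grp in df.groupby(["sample_id", "assay"], sort=False):
        cqs = [float(c) for c in grp["cq"] if pd.notna(c)]
        out.setdefault(str(sample), {a: [] for a in ASSAYS})[assay] = cqs
    return out


def read_dilution_csv(path) -> dict[str, list[tuple[float, float]]]:
    """Dilution series table (assay, log10_amount, cq) -> per-assay points."""
    df = pd.read_csv(path)
    required = {"assay", "log10_amount", "cq"}
    if not required.issubset(df.columns):
        raise ValueError(f"dilution CSV must have columns {sorted(required)}")
    return {
        str(assay): list(zip(grp["log10_amount"].astype(float), grp["cq"].astype(float)))
        for assay, grp in df.groupby("assay", sort=False)
    }


def read_scheme(path) -> PrimerScheme:
    """Primer scheme from a TOML file; unspecified keys take the bundled defaults."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return default_scheme(**data)
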