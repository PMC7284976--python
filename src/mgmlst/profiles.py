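"""From per-position coverage to allele abundances and ploidy-100 genotypes.

The chain implemented here turns sequencing evidence over the MLST
marker genes into the genotype the admixture model consumes:

1. pile up per-position base counts over each locus (from SAM/BAM
   alignments or a precomputed TSV pileup);
2. call each marker SNP present/absent (presence needs relative
   abundance >= 1% *and* >= 4 supporting reads, both configurable);
3. infer per-locus allele relative abundances — an allele is present
   only if *all* of its markers are present, its abundance is the
   minimum (optionally mean) of its marker frequencies, and the
   per-locus default allele absorbs the residual mass;
4. encode the abundances as exactly 100 discrete allele copies per
   locus, so a community can be handed to the admixture model as a
   single ploidy-100 individual.

Coordinates are 0-based half-open throughout; SAM input (1-based) is
converted at the boundary by pysam.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .scheme import MarkerSNP, MLSTScheme, SchemeError, StrainProfile

__all__ = [
    "MISSING",
    "LocusPileup",
    "SNPCall",
    "AlleleAbundance",
    "PloidyProfile",
    "pileup_from_alignments",
    "read_pileup_table",
    "write_pileup_table",
    "call_marker_snps",
    "infer_allele_abundance",
    "encode_ploidy",
    "learning_profile_to_ploidy",
    "write_abundance_table",
    "write_structure_file",
]

#: Missing-data code in ploidy vectors and STRUCTURE exports.
MISSING = -9

_BASES = ("A", "C", "G", "T")


@dataclass
class LocusPileup:
    """Per-position base counts over one locus.

    ``base_counts`` has shape (length, 4) in A/C/G/T order; ``depth``
    is the total read count per position (>= the four base counts,
    which exclude N and ambiguous calls).
    """

    locus: str
    depth: np.ndarray
    base_counts: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        self.base_counts = np.asarray(self.base_counts, dtype=np.int64)
        if self.base_counts.shape != (self.depth.shape[0], 4):
            raise ValueError(
                f"locus {self.locus!r}: base_counts shape "
                f"{self.base_counts.shape} inconsistent with depth length "
                f"{self.depth.shape[0]}"
            )
        if np.any(self.base_counts.sum(axis=1) > self.depth):
            raise ValueError(
                f"locus {self.locus!r}: base counts exceed depth at some position"
            )

    @property
    def length(self) -> int:
        return int(self.depth.shape[0])


@dataclass(frozen=True)
class SNPCall:
    """One marker SNP scored in one sample's pileup."""

    marker: MarkerSNP
    count: int
    frequency: float
    present: bool


@dataclass
class AlleleAbundance:
    """Per-locus allele relative abundances (a simplex over allele IDs)."""

    locus: str
    abundances: dict[int, float]

    def __post_init__(self) -> None:
        total = sum(self.abundances.values())
        if any(v < 0 for v in self.abundances.values()):
            raise ValueError(f"locus {self.locus!r}: negative abundance")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"locus {self.locus!r}: abundances sum to {total!r}, not 1"
            )


@dataclass
class PloidyProfile:
    """A sample's genotype: exactly `ploidy` allele copies per locus.

    Entries are catalogue allele IDs or :data:`MISSING`.  Learning
    samples additionally carry their population-group label and
    ``popflag=True``.
    """

    sample: str
    copies: dict[str, np.ndarray]
    group: str | None = None
    popflag: bool = False

    def __post_init__(self) -> None:
        self.copies = {l: np.asarray(v, dtype=np.int64) for l, v in self.copies.items()}
        lengths = {v.shape[0] for v in self.copies.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"sample {self.sample!r}: unequal copy-vector lengths {sorted(lengths)}"
            )

    @property
    def ploidy(self) -> int:
        return int(next(iter(self.copies.values())).shape[0])


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------


def pileup_from_alignments(
    alignments: str | Path,
    locus_regions: Mapping[str, tuple[str, int, int]],
    min_mapq: int = 0,
) -> list[LocusPileup]:
    """Pile up per-position base counts over each locus from SAM/BAM.

    ``locus_regions`` maps locus name -> (reference contig, start, end),
    0-based half-open.  Reads below ``min_mapq`` are excluded; deletions
    and clipped bases contribute nothing.  An alignment file with no
    reads yields all-zero pileups with a warning.
    """
    base_idx = {b: i for i, b in enumerate(_BASES)}
    with pysam.AlignmentFile(str(alignments), check_sq=False) as af:
        lengths = dict(zip(af.references, af.lengths))
        acc: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        by_contig: dict[str, list[tuple[str, int, int]]] = {}
        for locus, (contig, start, end) in locus_regions.items():
            if contig not in lengths:
                raise ValueError(f"locus {locus!r}: contig {contig!r} not in header")
            if start < 0 or end > lengths[contig] or start >= end:
                raise ValueError(
                    f"locus {locus!r}: interval [{start}, {end}) outside "
                    f"reference {contig!r} of length {lengths[contig]}"
                )
            n = end - start
            acc[locus] = (np.zeros(n, np.int64), np.zeros((n, 4), np.int64))
            by_contig.setdefault(contig, []).append((locus, start, end))
        n_reads = 0
        # sequential scan: works on plain SAM with no index
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.mapping_quality < min_mapq:
                continue
            n_reads += 1
            regions = by_contig.get(read.reference_name)
            if not regions:
                continue
            seq = read.query_sequence
            if seq is None:
                continue
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                for locus, start, end in regions:
                    if start <= rpos < end:
                        depth, counts = acc[locus]
                        depth[rpos - start] += 1
                        bi = base_idx.get(seq[qpos])
                        if bi is not None:
                            counts[rpos - start, bi] += 1
        if n_reads == 0:
            warnings.warn(f"{alignments}: no aligned reads; pileups are all zero")
    return [
        LocusPileup(locus=locus, depth=acc[locus][0], base_counts=acc[locus][1])
        for locus in locus_regions
    ]


def read_pileup_table(path: str | Path) -> list[LocusPileup]:
    """Read pileups from TSV: ``locus position A C G T depth``."""
    df = pd.read_csv(path, sep="\t")
    required = {"locus", "position", "A", "C", "G", "T", "depth"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: pileup table needs columns {sorted(required)}")
    pileups = []
    for locus, sub in df.groupby("locus", sort=False):
        sub = sub.sort_values("position")
        length = int(sub["position"].max()) + 1
        depth = np.zeros(length, dtype=np.int64)
        base_counts = np.zeros((length, 4), dtype=np.int64)
        pos = sub["position"].to_numpy()
        depth[pos] = sub["depth"].to_numpy()
        for i, b in enumerate(_BASES):
            base_counts[pos, i] = sub[b].to_numpy()
        pileups.append(LocusPileup(str(locus), depth, base_counts))
    return pileups


def write_pileup_table(pileups: Sequence[LocusPileup], path: str | Path) -> None:
    frames = []
    for p in pileups:
        frames.append(
            pd.DataFrame(
                {
                    "locus": p.locus,
                    "position": np.arange(p.length),
                    "A": p.base_counts[:, 0],
                    "C": p.base_counts[:, 1],
                    "G": p.base_counts[:, 2],
                    "T": p.base_counts[:, 3],
                    "depth": p.depth,
                }
            )
        )
    pd.concat(frames).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# marker-SNP calling
# ---------------------------------------------------------------------------


def call_marker_snps(
    pileups: Sequence[LocusPileup],
    markers: Sequence[MarkerSNP],
    min_freq: float = 0.01,
    min_reads: int = 4,
) -> list[SNPCall]:
    """Score each marker SNP in the pileups.

    A marker is *present* when its relative abundance (supporting reads
    over total depth at the position) is at least ``min_freq`` and it is
    supported by at least ``min_reads`` reads.  Zero-depth positions
    yield frequency 0, absent.
    """
    by_locus = {p.locus: p for p in pileups}
    calls = []
    for m in markers:
        if m.locus not in by_locus:
            raise ValueError(f"marker references unknown locus {m.locus!r}")
        p = by_locus[m.locus]
        if not 0 <= m.position < p.length:
            raise ValueError(
                f"marker position {m.position} outside locus {m.locus!r} "
                f"pileup of length {p.length}"
            )
        count = int(p.base_counts[m.position, _BASES.index(m.base)])
        depth = int(p.depth[m.position])
        freq = count / depth if depth > 0 else 0.0
        calls.append(
            SNPCall(
                marker=m,
                count=count,
                frequency=freq,
                present=(freq >= min_freq and count >= min_reads),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# allele abundances
# ---------------------------------------------------------------------------


def infer_allele_abundance(
    calls: Sequence[SNPCall],
    markers: Sequence[MarkerSNP],
    scheme: MLSTScheme,
    combine: Literal["min", "mean"] = "min",
) -> list[AlleleAbundance]:
    """Infer per-locus allele relative abundances from marker-SNP calls.

    An allele is present only when *all* of its markers are present; a
    present allele's abundance is the minimum (``combine="min"``,
    default) or mean of its marker frequencies.  The locus's default
    allele receives the residual mass ``1 - sum(present non-default)``.
    A residual in (-0.10, 0) is clamped to 0 with a warning; below
    -0.10 the marker frequencies are grossly inconsistent and an error
    is raised.  The returned vector is renormalized to sum to 1.
    """
    call_by_marker = {c.marker: c for c in calls}
    marker_loci = sorted({m.locus for m in markers})
    out = []
    for locus in marker_loci:
        default = scheme.default_allele[locus]
        by_allele: dict[int, list[MarkerSNP]] = {}
        for m in markers:
            if m.locus == locus:
                by_allele.setdefault(m.allele, []).append(m)
        abund: dict[int, float] = {}
        for aid, ms in by_allele.items():
            cs = []
            for m in ms:
                if m not in call_by_marker:
                    raise ValueError(
                        f"no call for marker {m.locus}:{m.position}{m.base} "
                        f"(allele {aid})"
                    )
                cs.append(call_by_marker[m])
            if all(c.present for c in cs):
                freqs = [c.frequency for c in cs]
                abund[aid] = min(freqs) if combine == "min" else float(np.mean(freqs))
        residual = 1.0 - sum(abund.values())
        if residual < -0.10:
            raise ValueError(
                f"locus {locus!r}: present-allele abundances sum to "
                f"{1 - residual:.3f} > 1.10; marker frequencies are "
                "grossly inconsistent"
            )
        if residual < 0:
            warnings.warn(
                f"locus {locus!r}: present-allele abundances sum to "
                f"{1 - residual:.3f}; clamping default-allele residual to 0"
            )
            residual = 0.0
        abund[default] = abund.get(default, 0.0) + residual
        total = sum(abund.values())
        abund = {a: v / total for a, v in abund.items()}
        out.append(AlleleAbundance(locus=locus, abundances=abund))
    return out


# ---------------------------------------------------------------------------
# ploidy encoding
# ---------------------------------------------------------------------------


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def encode_ploidy(abundance: AlleleAbundance, ploidy: int = 100) -> np.ndarray:
    """Encode a locus's allele abundances as exactly ``ploidy`` copies.

    Each abundance is rounded (half away from zero) to a copy number.
    Off-by-one totals are repaired the way simulated 100-member
    communities are: a total of ``ploidy - 1`` is filled with one
    missing-data entry, a total of ``ploidy + 1`` drops one copy of the
    most abundant allele (ties broken toward the lowest allele ID).
    Larger discrepancies fall back to largest-remainder apportionment.
    Returns a sorted int vector of allele IDs / :data:`MISSING`.
    """
    alleles = sorted(abundance.abundances)
    fracs = np.array([abundance.abundances[a] for a in alleles])
    if np.any(fracs < 0):
        raise ValueError("negative abundances cannot be encoded")
    raw = fracs * ploidy
    counts = _round_half_away(raw).astype(np.int64)
    total = int(counts.sum())
    if total == ploidy - 1:
        vec = np.repeat(alleles, counts)
        return np.sort(np.append(vec, MISSING))
    if total == ploidy + 1:
        top = np.max(counts)
        idx = int(np.flatnonzero(counts == top)[0])  # alleles sorted -> lowest ID
        counts[idx] -= 1
    elif total != ploidy:
        # largest-remainder apportionment
        counts = np.floor(raw).astype(np.int64)
        remainder = raw - counts
        short = ploidy - int(counts.sum())
        order = np.lexsort((alleles, -remainder))
        counts[order[:short]] += 1
    vec = np.repeat(alleles, counts)
    return np.sort(vec)


def learning_profile_to_ploidy(strain: StrainProfile, scheme: MLSTScheme,
                               ploidy: int = 100) -> PloidyProfile:
    """Expand a reference strain's allelic profile to a ploidy-N genotype.

    Each locus vector is ``ploidy`` identical copies of the strain's
    allele; the profile must cover every scheme locus.
    """
    scheme.validate_profile(strain)
    copies = {
        l: np.full(ploidy, strain.profile[l], dtype=np.int64)
        for l in scheme.locus_names
    }
    return PloidyProfile(
        sample=strain.strain, copies=copies, group=strain.group, popflag=True
    )


def sample_to_ploidy(
    sample: str,
    abundances: Sequence[AlleleAbundance],
    ploidy: int = 100,
) -> PloidyProfile:
    """Assemble a sample's ploidy profile from per-locus abundances."""
    copies = {a.locus: encode_ploidy(a, ploidy) for a in abundances}
    return PloidyProfile(sample=sample, copies=copies)


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------


def write_abundance_table(
    sample: str, abundances: Sequence[AlleleAbundance], path: str | Path
) -> None:
    """Write abundances as TSV: ``sample locus allele abundance``."""
    rows = [
        {"sample": sample, "locus": a.locus, "allele": aid, "abundance": v}
        for a in abundances
        for aid, v in sorted(a.abundances.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_abundance_table(path: str | Path) -> dict[str, list[AlleleAbundance]]:
    """Read an abundance TSV back into per-sample AlleleAbundance lists."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[AlleleAbundance]] = {}
    for (sample, locus), sub in df.groupby(["sample", "locus"], sort=False):
        out.setdefault(str(sample), []).append(
            AlleleAbundance(
                locus=str(locus),
                abundances={int(r.allele): float(r.abundance) for r in sub.itertuples()},
            )
        )
    return out


def write_structure_file(
    profiles: Sequence[PloidyProfile],
    loci: Sequence[str],
    path: str | Path,
) -> None:
    """Write genotypes in STRUCTURE's multi-row-per-individual format.

    One row per allele copy: label, population index, POPFLAG, then one
    allele ID per locus.  Missing data is written as -9.  Populations
    are numbered by first appearance of the group label; unlabeled
    samples get population 0 and POPFLAG 0.
    """
    group_ids: dict[str, int] = {}
    with open(path, "w") as fh:
        fh.write("\t".join(["label", "pop", "popflag", *loci]) + "\n")
        for prof in profiles:
            if prof.group is not None and prof.group not in group_ids:
                group_ids[prof.group] = len(group_ids) + 1
            pop = group_ids.get(prof.group or "", 0)
            flag = 1 if prof.popflag else 0
            for i in range(prof.ploidy):
                row = [prof.sample, str(pop), str(flag)]
                row += [str(int(prof.copies[l][i])) for l in loci]
                fh.write("\t".join(row) + "\n")
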