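"""Simulated communities, synthetic schemes, and synthetic sequencing evidence.

Three community designs mirror the validation regimes used for
strain-level deconvolution of a skin commensal:

* **Set A** — each community holds a single population group (or a
  closely-related pair reported as one group): the easy, one-hot case.
* **Set B** — group relative abundances drawn from a flat Dirichlet:
  arbitrary mixtures.
* **Set C** — clinically-shaped targets (one dominant group at
  0.5–0.9 plus minor groups), emulating compositions seen in real skin
  samples.

Communities always have exactly 100 members so relative abundances map
directly onto ploidy-100 allele copies; rounding that predicts 99 or
101 members is repaired by inserting one missing member or dropping one
member of the most abundant group.

A synthetic-scheme generator stands in for the curated reference
learning set: K groups, L loci, group-distinctive alleles with a
guaranteed number of distinguishing positions, and optional
within-group allele diversity.  Its output passes learning-set curation
and marker derivation with no exclusions by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .profiles import MISSING, PloidyProfile
from .scheme import Locus, MLSTScheme, StrainProfile
from .profiles import LocusPileup

__all__ = [
    "SimulatedCommunity",
    "SyntheticSchemeSpec",
    "DEFAULT_SET_C_TARGETS",
    "generate_synthetic_scheme",
    "simulate_set_a",
    "simulate_set_b",
    "simulate_set_c",
    "community_to_ploidy",
    "community_to_pileup",
    "community_to_sam",
    "write_community_manifest",
    "write_ground_truth",
]

_BASES = np.array(list("ACGT"))

#: Group names and merge map emulating the six major skin population
#: groups (two clades of RT1 merge into one reporting group).
SIX_GROUP_NAMES = ["RT1", "RT1/IB-3", "RT2/6", "RT3", "RT4/5", "RT8"]
SIX_GROUP_MERGE = {
    "RT1": "RT1", "RT1/IB-3": "RT1", "RT2/6": "RT2/6",
    "RT3": "RT3", "RT4/5": "RT4/5", "RT8": "RT8",
}

#: Ten-group variant with the extra unique-profile groups folded into
#: their parent reporting groups.
TEN_GROUP_NAMES = [
    "RT1", "SK-RT1", "HL025PA1-RT1", "RT1/IB-3", "RT2/6",
    "RT3", "SK187-RT3", "RT4/5", "TIC", "RT8",
]
TEN_GROUP_MERGE = {
    "RT1": "RT1", "SK-RT1": "RT1", "HL025PA1-RT1": "RT1", "RT1/IB-3": "RT1",
    "RT2/6": "RT2/6", "RT3": "RT3", "SK187-RT3": "RT3",
    "RT4/5": "RT4/5", "TIC": "RT4/5", "RT8": "RT8",
}

#: Representative clinically-shaped target compositions over the five
#: reporting groups: one dominant group (0.5-0.9) plus minor groups.
DEFAULT_SET_C_TARGETS: list[dict[str, float]] = [
    {"RT1": 0.70, "RT2/6": 0.10, "RT3": 0.10, "RT4/5": 0.05, "RT8": 0.05},
    {"RT1": 0.90, "RT3": 0.10},
    {"RT2/6": 0.80, "RT1": 0.10, "RT3": 0.05, "RT4/5": 0.05},
    {"RT2/6": 0.60, "RT8": 0.20, "RT1": 0.20},
    {"RT1": 0.50, "RT4/5": 0.30, "RT3": 0.10, "RT2/6": 0.05, "RT8": 0.05},
    {"RT1": 0.55, "RT2/6": 0.25, "RT3": 0.20},
]


@dataclass
class SimulatedCommunity:
    """A 100-member community with its expected reporting-group fractions.

    ``members`` holds strain references; a ``None`` entry is a missing
    member inserted by the 99-member repair.  ``expected`` is computed
    from the realized member counts over non-missing members.
    """

    name: str
    members: list[StrainProfile | None]
    expected: dict[str, float]
    seed: int

    def __post_init__(self) -> None:
        total = sum(self.expected.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"expected fractions sum to {total!r}, not 1")


@dataclass
class SyntheticSchemeSpec:
    """Parameters of the synthetic scheme / learning-set generator."""

    K: int = 6
    L: int = 4
    strains_per_group: int = 10
    alleles_per_locus: int = 8
    within_group_allele_diversity: int = 1
    snp_divergence: int = 2
    locus_length: int = 450
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.K, self.L, self.strains_per_group, self.alleles_per_locus,
               self.locus_length) < 1 or self.snp_divergence < 1:
            raise ValueError("all spec parameters must be positive")
        if self.alleles_per_locus < self.K:
            raise ValueError(
                f"need at least K={self.K} alleles per locus for "
                "group-distinctive alleles"
            )
        if (self.alleles_per_locus - 1) * self.snp_divergence > self.locus_length:
            raise ValueError(
                "infeasible spec: dedicated distinguishing positions exceed "
                f"locus length {self.locus_length}"
            )


# ---------------------------------------------------------------------------
# synthetic scheme generation
# ---------------------------------------------------------------------------


def generate_synthetic_scheme(
    spec: SyntheticSchemeSpec,
) -> tuple[MLSTScheme, list[StrainProfile]]:
    """Generate a scheme and learning set with group-distinctive alleles.

    Allele 1 at every locus is the default allele (the reference
    sequence); every other allele deviates from it at ``snp_divergence``
    dedicated positions no other allele touches, so each non-default
    allele is guaranteed resolvable marker SNPs.  Group *g*'s consensus
    profile carries allele *g* at every locus; a minority of strains per
    group carry one within-group variant allele, so curation excludes
    nothing.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.K == 6:
        names, merge = SIX_GROUP_NAMES, SIX_GROUP_MERGE
    elif spec.K == 10:
        names, merge = TEN_GROUP_NAMES, TEN_GROUP_MERGE
    else:
        names = [f"G{k + 1}" for k in range(spec.K)]
        merge = {g: g for g in names}

    loci = []
    locus_names = [f"locus{i + 1}" for i in range(spec.L)]
    for lname in locus_names:
        ref = rng.choice(_BASES, size=spec.locus_length)
        positions = rng.permutation(spec.locus_length)
        alleles = {1: "".join(ref)}
        for aid in range(2, spec.alleles_per_locus + 1):
            block = positions[
                (aid - 2) * spec.snp_divergence : (aid - 1) * spec.snp_divergence
            ]
            seq = ref.copy()
            for pos in block:
                others = [b for b in "ACGT" if b != ref[pos]]
                seq[pos] = others[int(rng.integers(3))]
            alleles[aid] = "".join(seq)
        loci.append(Locus(name=lname, alleles=alleles))

    scheme = MLSTScheme(
        loci=loci,
        default_allele={l: 1 for l in locus_names},
        merge_map=dict(merge),
    )

    profiles = []
    n_variant = min(spec.within_group_allele_diversity, (spec.strains_per_group - 1) // 2)
    extra = spec.alleles_per_locus - spec.K
    for g, group in enumerate(names):
        consensus = {l: g + 1 for l in locus_names}
        for s in range(spec.strains_per_group):
            prof = dict(consensus)
            # strains 1..n_variant carry one rotated within-group variant
            if 1 <= s <= n_variant and extra > 0 and spec.L >= 2:
                v = s - 1
                vlocus = locus_names[(g + v) % spec.L]
                prof[vlocus] = spec.K + 1 + ((g + v) % extra)
            profiles.append(
                StrainProfile(
                    strain=f"SIM-{group}-{s + 1:02d}",
                    group=group,
                    profile=prof,
                    popflag=True,
                )
            )
    return scheme, profiles


# ---------------------------------------------------------------------------
# community construction
# ---------------------------------------------------------------------------


def _apportion(fracs: Mapping[str, float], size: int) -> tuple[dict[str, int], int]:
    """Fractions -> integer member counts with the 99/101 repair.

    Returns (counts per group, number of missing members: 0 or 1).
    Totals of ``size - 1`` gain a missing member; ``size + 1`` drops one
    member of the most abundant group (ties toward the lexicographically
    first group); larger discrepancies fall back to largest-remainder
    apportionment.
    """
    groups = sorted(fracs)
    raw = np.array([fracs[g] * size for g in groups])
    counts = np.sign(raw) * np.floor(np.abs(raw) + 0.5)
    counts = counts.astype(int)
    total = int(counts.sum())
    if total == size - 1:
        return dict(zip(groups, counts)), 1
    if total == size + 1:
        top = max(counts)
        idx = int(np.flatnonzero(counts == top)[0])
        counts[idx] -= 1
    elif total != size:
        floor = np.floor(raw).astype(int)
        remainder = raw - floor
        short = size - int(floor.sum())
        order = np.lexsort((np.arange(len(groups)), -remainder))
        floor[order[:short]] += 1
        counts = floor
    return dict(zip(groups, counts)), 0


def _pools_by_reporting_group(
    learning: Sequence[StrainProfile], scheme: MLSTScheme
) -> dict[str, list[StrainProfile]]:
    pools: dict[str, list[StrainProfile]] = {}
    for sp in learning:
        pools.setdefault(scheme.reporting_group(sp.group), []).append(sp)
    return pools


def _realized_expected(members: Sequence[StrainProfile | None],
                       scheme: MLSTScheme) -> dict[str, float]:
    present = [m for m in members if m is not None]
    counts: dict[str, int] = {}
    for m in present:
        rg = scheme.reporting_group(m.group)
        counts[rg] = counts.get(rg, 0) + 1
    n = len(present)
    return {g: c / n for g, c in sorted(counts.items())}


def simulate_set_a(
    groups: str | Sequence[str],
    learning: Sequence[StrainProfile],
    scheme: MLSTScheme,
    seed: int,
    size: int = 100,
    name: str | None = None,
) -> SimulatedCommunity:
    """Single-group (or closely-related pair) community.

    All 100 members are drawn uniformly with replacement from the
    requested group(s)' learning strains; the expected vector is 1 on
    the corresponding reporting group.
    """
    if isinstance(groups, str):
        groups = [groups]
    rng = np.random.default_rng(seed)
    known = {sp.group for sp in learning}
    pool = []
    for g in groups:
        strains = [sp for sp in learning if sp.group == g]
        if not strains:
            raise ValueError(
                f"unknown group {g!r}; learning set has {sorted(known)}"
            )
        pool.extend(strains)
    members = [pool[int(i)] for i in rng.integers(len(pool), size=size)]
    return SimulatedCommunity(
        name=name or "setA-" + "+".join(groups),
        members=members,
        expected=_realized_expected(members, scheme),
        seed=seed,
    )


def _assemble(
    targets: Mapping[str, float],
    pools: Mapping[str, Sequence[StrainProfile]],
    rng: np.random.Generator,
    size: int,
) -> list[StrainProfile | None]:
    counts, n_missing = _apportion(targets, size)
    members: list[StrainProfile | None] = []
    for g in sorted(counts):
        if counts[g] == 0:
            continue
        if g not in pools:
            raise ValueError(f"no learning strains for reporting group {g!r}")
        pool = pools[g]
        members.extend(pool[int(i)] for i in rng.integers(len(pool), size=counts[g]))
    members.extend([None] * n_missing)
    return members


def simulate_set_b(
    learning: Sequence[StrainProfile],
    scheme: MLSTScheme,
    seed: int,
    size: int = 100,
    name: str | None = None,
) -> SimulatedCommunity:
    """Random-composition community: flat Dirichlet over reporting groups."""
    rng = np.random.default_rng(seed)
    pools = _pools_by_reporting_group(learning, scheme)
    groups = sorted(pools)
    if len(groups) < 2:
        raise ValueError("Set B needs at least two reporting groups")
    fracs = dict(zip(groups, rng.dirichlet(np.ones(len(groups)))))
    members = _assemble(fracs, pools, rng, size)
    return SimulatedCommunity(
        name=name or f"setB-{seed}",
        members=members,
        expected=_realized_expected(members, scheme),
        seed=seed,
    )


def simulate_set_c(
    target_compositions: Sequence[Mapping[str, float]],
    learning: Sequence[StrainProfile],
    scheme: MLSTScheme,
    seed: int,
    size: int = 100,
) -> list[SimulatedCommunity]:
    """Fixed-target communities shaped like clinical skin compositions."""
    pools = _pools_by_reporting_group(learning, scheme)
    out = []
    for i, targets in enumerate(target_compositions):
        total = sum(targets.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"target composition {i} sums to {total!r}, not 1")
        missing = set(targets) - set(pools)
        if missing:
            raise ValueError(
                f"target composition {i} references groups absent from the "
                f"learning set: {sorted(missing)}"
            )
        rng = np.random.default_rng(seed + i)
        members = _assemble(targets, pools, rng, size)
        out.append(
            SimulatedCommunity(
                name=f"setC-{i + 1}",
                members=members,
                expected=_realized_expected(members, scheme),
                seed=seed + i,
            )
        )
    return out


# ---------------------------------------------------------------------------
# community -> genotype / sequencing evidence
# ---------------------------------------------------------------------------


def community_to_ploidy(
    community: SimulatedCommunity, scheme: MLSTScheme
) -> PloidyProfile:
    """Each member contributes one allele copy per locus (missing -> -9)."""
    copies = {}
    for l in scheme.locus_names:
        copies[l] = np.array(
            [MISSING if m is None else m.profile[l] for m in community.members],
            dtype=np.int64,
        )
    return PloidyProfile(sample=community.name, copies=copies)


def _member_base_dists(
    community: SimulatedCommunity, scheme: MLSTScheme
) -> dict[str, np.ndarray]:
    """Per-locus, per-position base distribution implied by the members."""
    base_idx = {b: i for i, b in enumerate("ACGT")}
    present = [m for m in community.members if m is not None]
    dists = {}
    for locus in scheme.loci:
        dist = np.zeros((locus.aligned_length, 4))
        for m in present:
            seq = locus.alleles[m.profile[locus.name]]
            for pos, b in enumerate(seq):
                if b in base_idx:
                    dist[pos, base_idx[b]] += 1
        dists[locus.name] = dist / len(present)
    return dists


def community_to_pileup(
    community: SimulatedCommunity,
    scheme: MLSTScheme,
    depth: float,
    error_rate: float = 0.0,
    seed: int = 0,
    deterministic: bool = False,
) -> list[LocusPileup]:
    """Synthesize per-position pileups for a community.

    Per position the read count is Poisson(``depth``) and each read base
    is drawn from the member-weighted allele base distribution; with
    probability ``error_rate`` a base is replaced by one of the other
    three uniformly.  At error 0 and unbounded depth the observed base
    frequencies equal the member allele fractions.

    ``deterministic=True`` removes sampling noise entirely (the
    infinite-depth limit at finite counts): every position gets exactly
    ``depth`` reads apportioned to bases by largest remainder.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0 <= error_rate < 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")
    rng = np.random.default_rng(seed)
    pileups = []
    for locus_name, dist in _member_base_dists(community, scheme).items():
        # error model: keep with prob 1-e, else uniform over the other 3
        noisy = dist * (1 - error_rate) + (1 - dist) * error_rate / 3
        n = dist.shape[0]
        counts = np.zeros((n, 4), dtype=np.int64)
        if deterministic:
            d = int(round(depth))
            depths = np.full(n, d)
            raw = noisy * d
            counts = np.floor(raw).astype(np.int64)
            for pos in range(n):
                short = d - int(counts[pos].sum())
                order = np.argsort(-(raw[pos] - counts[pos]))
                counts[pos, order[:short]] += 1
        else:
            depths = rng.poisson(depth, size=n)
            for pos in range(n):
                if depths[pos] > 0:
                    counts[pos] = rng.multinomial(depths[pos], noisy[pos])
        pileups.append(
            LocusPileup(locus=locus_name, depth=depths.astype(np.int64),
                        base_counts=counts)
        )
    return pileups


def community_to_sam(
    community: SimulatedCommunity,
    scheme: MLSTScheme,
    depth: float,
    path: str | Path,
    error_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, tuple[str, int, int]]:
    """Write synthetic full-locus reads as plain SAM.

    One contig per locus; each read is a member's full allele sequence
    with per-base errors, so per-position coverage is the Poisson read
    count.  Returns the locus-region map for
    :func:`mgmlst.profiles.pileup_from_alignments`.
    """
    rng = np.random.default_rng(seed)
    present = [m for m in community.members if m is not None]
    regions = {}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for locus in scheme.loci:
            fh.write(f"@SQ\tSN:{locus.name}\tLN:{locus.aligned_length}\n")
            regions[locus.name] = (locus.name, 0, locus.aligned_length)
        read_id = 0
        for locus in scheme.loci:
            n_reads = int(rng.poisson(depth))
            for _ in range(n_reads):
                m = present[int(rng.integers(len(present)))]
                seq = np.array(list(locus.alleles[m.profile[locus.name]]))
                if error_rate > 0:
                    err = rng.uniform(size=seq.shape[0]) < error_rate
                    for pos in np.flatnonzero(err):
                        others = [b for b in "ACGT" if b != seq[pos]]
                        seq[pos] = others[int(rng.integers(3))]
                fh.write(
                    "\t".join(
                        [
                            f"read{read_id}", "0", locus.name, "1", "60",
                            f"{seq.shape[0]}M", "*", "0", "0",
                            "".join(seq), "*",
                        ]
                    )
                    + "\n"
                )
                read_id += 1
    return regions


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_community_manifest(
    communities: Sequence[SimulatedCommunity], path: str | Path
) -> None:
    """TSV: ``community member_index strain group`` (missing members blank)."""
    rows = []
    for com in communities:
        for i, m in enumerate(com.members):
            rows.append(
                {
                    "community": com.name,
                    "member_index": i,
                    "strain": "" if m is None else m.strain,
                    "group": "" if m is None else m.group,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_ground_truth(
    communities: Sequence[SimulatedCommunity], path: str | Path
) -> None:
    """TSV: ``community group expected_fraction``."""
    rows = [
        {"community": com.name, "group": g, "expected_fraction": f}
        for com in communities
        for g, f in sorted(com.expected.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
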