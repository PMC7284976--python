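"""MLST schemes, learning sets, and marker-SNP derivation.

An MLST scheme is a set of housekeeping loci, each with a catalogue of
pre-aligned, equal-length allele sequences identified by integer IDs
(PubMLST convention).  A *learning set* is a collection of reference
strains with known per-locus allele IDs and a population-group label
(for example a ribotype group such as ``RT2/6``).  From the alleles
that the learning set actually uses, this module derives *marker SNPs*:
(position, base) pairs that uniquely identify one allele at a locus.
One allele per locus is designated the *default allele*: it needs no
markers and later absorbs all coverage not explained by marker SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

__all__ = [
    "Locus",
    "StrainProfile",
    "MLSTScheme",
    "MarkerSNP",
    "SchemeError",
    "load_scheme",
    "write_scheme",
    "load_profile_table",
    "write_profile_table",
    "curate_learning_set",
    "derive_marker_snps",
    "write_marker_table",
    "read_marker_table",
]

VALID_BASES = frozenset("ACGTN")


class SchemeError(ValueError):
    """Raised when a scheme, profile table, or marker set is invalid."""


@dataclass
class Locus:
    """One MLST locus: a name plus its catalogue of aligned alleles."""

    name: str
    alleles: dict[int, str]

    def __post_init__(self) -> None:
        if not self.alleles:
            raise SchemeError(f"locus {self.name!r} has no alleles")
        lengths = {len(s) for s in self.alleles.values()}
        if len(lengths) != 1:
            raise SchemeError(
                f"locus {self.name!r}: allele sequences have unequal lengths "
                f"{sorted(lengths)}; alleles must be pre-aligned"
            )
        for aid, seq in self.alleles.items():
            bad = set(seq.upper()) - VALID_BASES
            if bad:
                raise SchemeError(
                    f"locus {self.name!r} allele {aid}: invalid bases {sorted(bad)}"
                )
        self.alleles = {int(a): s.upper() for a, s in self.alleles.items()}

    @property
    def aligned_length(self) -> int:
        return len(next(iter(self.alleles.values())))


@dataclass
class StrainProfile:
    """A labeled reference strain: group + per-locus allele IDs.

    ``popflag`` marks learning samples (strains whose labels train the
    admixture model); it mirrors STRUCTURE's POPFLAG column.
    """

    strain: str
    group: str
    profile: dict[str, int]
    popflag: bool = True

    def __post_init__(self) -> None:
        if self.popflag and not self.group:
            raise SchemeError(
                f"strain {self.strain!r}: learning samples need a group label"
            )


@dataclass
class MLSTScheme:
    """A validated scheme: loci, per-locus default allele, group merge map.

    The default allele at each locus absorbs coverage not attributed to
    any marker SNP.  ``merge_map`` folds population groups into the
    reporting groups used for final abundances (e.g. two clades of one
    ribotype into a single RT group); it must be total over the group
    labels in use.
    """

    loci: list[Locus]
    default_allele: dict[str, int]
    merge_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [loc.name for loc in self.loci]
        if len(set(names)) != len(names):
            raise SchemeError(f"duplicate locus names: {names}")
        for name in names:
            if name not in self.default_allele:
                raise SchemeError(f"no default allele configured for locus {name!r}")
        for name, aid in self.default_allele.items():
            locus = self.locus(name)
            if aid not in locus.alleles:
                raise SchemeError(
                    f"default allele {aid} not in catalogue of locus {name!r}"
                )

    @property
    def locus_names(self) -> list[str]:
        return [loc.name for loc in self.loci]

    def locus(self, name: str) -> Locus:
        for loc in self.loci:
            if loc.name == name:
                return loc
        raise SchemeError(f"unknown locus {name!r}")

    def reporting_group(self, group: str) -> str:
        """Map a population group to its reporting group (identity if unmapped)."""
        return self.merge_map.get(group, group)

    def validate_profile(self, sp: StrainProfile) -> None:
        for name in self.locus_names:
            if name not in sp.profile:
                raise SchemeError(
                    f"strain {sp.strain!r}: no allele for locus {name!r}"
                )
            aid = sp.profile[name]
            if aid not in self.locus(name).alleles:
                raise SchemeError(
                    f"strain {sp.strain!r}: allele {aid} at locus {name!r} "
                    "is not in the scheme catalogue"
                )


@dataclass(frozen=True)
class MarkerSNP:
    """A (position, base) pair unique to one allele at a locus.

    ``position`` is a 0-based index into the aligned allele sequence.
    """

    locus: str
    position: int
    base: str
    allele: int


# ---------------------------------------------------------------------------
# loading / writing
# ---------------------------------------------------------------------------


def _parse_fasta_alleles(path: str | Path) -> tuple[str, dict[int, str]]:
    """Parse one per-locus allele FASTA with ``locusname_alleleID`` headers."""
    locus_name: str | None = None
    alleles: dict[int, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        if "_" not in header:
            raise SchemeError(
                f"{path}: header {header!r} does not follow 'locus_ID' convention"
            )
        name, _, aid_str = header.rpartition("_")
        try:
            aid = int(aid_str)
        except ValueError:
            raise SchemeError(
                f"{path}: header {header!r}: allele ID {aid_str!r} is not an integer"
            ) from None
        if locus_name is None:
            locus_name = name
        elif name != locus_name:
            raise SchemeError(
                f"{path}: mixed locus names {locus_name!r} and {name!r} in one file"
            )
        if aid in alleles:
            raise SchemeError(f"{path}: duplicate allele ID {aid} for locus {name!r}")
        alleles[aid] = str(rec.seq).upper()
    if locus_name is None:
        raise SchemeError(f"{path}: no FASTA records found")
    return locus_name, alleles


def load_profile_table(path: str | Path) -> pd.DataFrame:
    """Read a profile table: ``strain<TAB>group<TAB><locus1>...<locusN>``."""
    df = pd.read_csv(path, sep="\t", dtype={"strain": str, "group": str})
    for col in ("strain", "group"):
        if col not in df.columns:
            raise SchemeError(f"{path}: profile table lacks required column {col!r}")
    return df


def write_profile_table(profiles: Sequence[StrainProfile], path: str | Path) -> None:
    if not profiles:
        raise SchemeError("no profiles to write")
    loci = list(profiles[0].profile)
    rows = [
        {"strain": sp.strain, "group": sp.group, **{l: sp.profile[l] for l in loci}}
        for sp in profiles
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_scheme(
    allele_fasta_paths: Iterable[str | Path],
    profile_table: str | Path,
    defaults: Mapping[str, int] | str | Path,
    merge_map: Mapping[str, str] | None = None,
) -> tuple[MLSTScheme, list[StrainProfile]]:
    """Load a scheme from per-locus allele FASTAs plus a profile table.

    ``defaults`` is either a mapping locus -> default allele ID or the
    path of a YAML config with keys ``default_allele`` and optionally
    ``merge_map``.

    Raises :class:`SchemeError` on unequal allele lengths, duplicate
    allele IDs, or profiles referencing alleles absent from the FASTAs.
    """
    if isinstance(defaults, (str, Path)):
        with open(defaults) as fh:
            cfg = yaml.safe_load(fh) or {}
        default_allele = {k: int(v) for k, v in cfg.get("default_allele", {}).items()}
        if merge_map is None:
            merge_map = cfg.get("merge_map", {}) or {}
    else:
        default_allele = {k: int(v) for k, v in defaults.items()}
    loci = []
    for path in allele_fasta_paths:
        name, alleles = _parse_fasta_alleles(path)
        loci.append(Locus(name=name, alleles=alleles))
    scheme = MLSTScheme(
        loci=loci, default_allele=default_allele, merge_map=dict(merge_map or {})
    )

    df = load_profile_table(profile_table)
    missing = set(scheme.locus_names) - set(df.columns)
    if missing:
        raise SchemeError(f"profile table lacks locus columns {sorted(missing)}")
    popflag_col = df["popflag"].astype(bool) if "popflag" in df.columns else None
    profiles = []
    for i, row in df.iterrows():
        sp = StrainProfile(
            strain=str(row["strain"]),
            group=str(row["group"]),
            profile={l: int(row[l]) for l in scheme.locus_names},
            popflag=bool(popflag_col.iloc[i]) if popflag_col is not None else True,
        )
        scheme.validate_profile(sp)
        profiles.append(sp)
    return scheme, profiles


def write_scheme(
    scheme: MLSTScheme,
    profiles: Sequence[StrainProfile],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write a scheme back to disk (FASTAs, profile table, YAML config).

    The output round-trips bit-identically through :func:`load_scheme`.
    Returns the paths written, keyed by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for loc in scheme.loci:
        fp = outdir / f"{loc.name}.fasta"
        with open(fp, "w") as fh:
            for aid in sorted(loc.alleles):
                fh.write(f">{loc.name}_{aid}\n{loc.alleles[aid]}\n")
        paths[f"fasta:{loc.name}"] = fp
    prof_path = outdir / "profiles.tsv"
    write_profile_table(profiles, prof_path)
    paths["profiles"] = prof_path
    cfg_path = outdir / "scheme.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(
            {
                "loci": scheme.locus_names,
                "default_allele": scheme.default_allele,
                "merge_map": scheme.merge_map,
            },
            fh,
            sort_keys=False,
        )
    paths["config"] = cfg_path
    return paths


# ---------------------------------------------------------------------------
# learning-set curation
# ---------------------------------------------------------------------------


def _consensus_profiles(
    profiles: Sequence[StrainProfile], loci: Sequence[str]
) -> dict[str, dict[str, int]]:
    """Per-group consensus: the per-locus majority allele (ties -> lowest ID)."""
    consensus: dict[str, dict[str, int]] = {}
    by_group: dict[str, list[StrainProfile]] = {}
    for sp in profiles:
        by_group.setdefault(sp.group, []).append(sp)
    for group, members in by_group.items():
        cons = {}
        for locus in loci:
            counts: dict[int, int] = {}
            for sp in members:
                counts[sp.profile[locus]] = counts.get(sp.profile[locus], 0) + 1
            best = max(counts, key=lambda a: (counts[a], -a))
            cons[locus] = best
        consensus[group] = cons
    return consensus


def curate_learning_set(
    profiles: Sequence[StrainProfile], scheme: MLSTScheme
) -> tuple[list[StrainProfile], list[dict]]:
    """Curate a learning set against per-group consensus allelic profiles.

    For every group the per-locus majority allele forms the consensus
    profile.  A strain is excluded when

    * it carries an allele absent from the scheme's catalogue, or
    * its profile matches the consensus of some *other* group at least
      as well (per-locus exact-match count) as its own group's
      consensus — an ambiguous profile resembling multiple groups.

    Exclusion and consensus computation are iterated to a fixed point,
    so curating an already-curated set removes nothing.  Returns the
    curated profiles plus an exclusion report (one dict per removal
    with keys ``strain``, ``group``, ``reason``).

    Raises :class:`SchemeError` if every strain of a group is excluded.
    """
    loci = scheme.locus_names
    report: list[dict] = []
    groups_declared = {sp.group for sp in profiles}

    kept: list[StrainProfile] = []
    for sp in profiles:
        unknown = [
            (l, sp.profile[l])
            for l in loci
            if sp.profile.get(l) not in scheme.locus(l).alleles
        ]
        if unknown:
            report.append(
                {
                    "strain": sp.strain,
                    "group": sp.group,
                    "reason": "allele not in catalogue: "
                    + ", ".join(f"{l}={a}" for l, a in unknown),
                }
            )
        else:
            kept.append(sp)

    while True:
        consensus = _consensus_profiles(kept, loci)
        removed_this_round = []
        surviving = []
        for sp in kept:
            own = sum(sp.profile[l] == consensus[sp.group][l] for l in loci)
            rivals = {
                g: sum(sp.profile[l] == cons[l] for l in loci)
                for g, cons in consensus.items()
                if g != sp.group
            }
            offenders = [g for g, m in rivals.items() if m >= own]
            if offenders:
                removed_this_round.append(
                    {
                        "strain": sp.strain,
                        "group": sp.group,
                        "reason": "ambiguous profile: matches consensus of "
                        + ", ".join(sorted(offenders))
                        + f" at least as well as own group ({own}/{len(loci)})",
                    }
                )
            else:
                surviving.append(sp)
        report.extend(removed_this_round)
        kept = surviving
        if not removed_this_round:
            break

    for group in sorted(groups_declared):
        if not any(sp.group == group for sp in kept):
            raise SchemeError(
                f"curation excluded every strain of group {group!r}; "
                "the learning set cannot represent this population"
            )
    return kept, report


# ---------------------------------------------------------------------------
# marker-SNP derivation
# ---------------------------------------------------------------------------


def derive_marker_snps(
    scheme: MLSTScheme, learning: Sequence[StrainProfile]
) -> list[MarkerSNP]:
    """Derive marker SNPs for every non-default allele used by the learning set.

    Only alleles appearing in the learning set are considered.  A marker
    for allele *a* at a locus is a position where *a*'s base differs from
    the base of every other considered allele at that locus — i.e. a
    (position, base) pair unique to *a*.  The default allele needs no
    markers.  ``N`` bases never form markers.

    Raises :class:`SchemeError` if a considered non-default allele has no
    distinguishing position (the scheme cannot resolve it) or if the
    learning set is empty.
    """
    if not learning:
        raise SchemeError("empty learning set: no alleles to consider")
    markers: list[MarkerSNP] = []
    for locus in scheme.loci:
        used = sorted({sp.profile[locus.name] for sp in learning})
        for aid in used:
            if aid not in locus.alleles:
                raise SchemeError(
                    f"learning set references allele {aid} absent from "
                    f"locus {locus.name!r}"
                )
        default = scheme.default_allele[locus.name]
        others = {aid: locus.alleles[aid] for aid in used}
        for aid in used:
            if aid == default:
                continue
            seq = locus.alleles[aid]
            found = []
            for pos in range(locus.aligned_length):
                base = seq[pos]
                if base == "N":
                    continue
                if all(
                    others[o][pos] != base for o in used if o != aid
                ):
                    found.append(MarkerSNP(locus.name, pos, base, aid))
            if not found:
                raise SchemeError(
                    f"allele {aid} at locus {locus.name!r} has no position "
                    "distinguishing it from the other considered alleles; "
                    "the scheme cannot resolve it"
                )
            markers.extend(found)
    return markers


def write_marker_table(markers: Sequence[MarkerSNP], path: str | Path) -> None:
    """Write markers as TSV: ``locus position base allele``."""
    pd.DataFrame(
        [
            {"locus": m.locus, "position": m.position, "base": m.base, "allele": m.allele}
            for m in markers
        ]
    ).to_csv(path, sep="\t", index=False)


def read_marker_table(path: str | Path) -> list[MarkerSNP]:
    df = pd.read_csv(path, sep="\t")
    return [
        MarkerSNP(str(r.locus), int(r.position), str(r.base), int(r.allele))
        for r in df.itertuples()
    ]
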