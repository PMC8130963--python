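"""Domain objects for paired genomics/metabolomics link scoring.

The central abstraction is the *strain set*: a gene cluster family (GCF) can be
viewed as the set of strains that contribute a biosynthetic gene cluster (BGC)
to it, and a molecular family (MF) as the set of strains in which any of its
member spectra was observed.  All correlation scoring operates on the four
counts derived from these sets within a fixed strain universe N:

    m = #M   strains exhibiting the molecular family
    g = #G   strains contributing to the gene cluster family
    o = #(G ∩ M)   the overlap
    n = #N   the population size

Strains seen only on one side (genomics without metabolomics, or vice versa)
remain in the universe: the scoring scheme's "neither" term counts them, and
dropping them silently would change n.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Strain",
    "BGC",
    "GCF",
    "Spectrum",
    "MolecularFamily",
    "OccurrenceData",
    "LinkCandidate",
    "StrainResolutionError",
    "derive_strain_sets",
    "enumerate_link_candidates",
]


class StrainResolutionError(KeyError):
    """A member or strain reference does not resolve to a known object."""


@dataclass(frozen=True)
class Strain:
    """A microbial strain, identified by a primary id plus optional aliases."""

    id: str
    aliases: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("strain id must be non-empty")
        object.__setattr__(self, "aliases", frozenset(self.aliases) - {self.id})


@dataclass(frozen=True)
class BGC:
    """A biosynthetic gene cluster predicted in exactly one strain.

    ``candidate_structures`` holds structure references (SMILES strings or
    InChIKey first blocks) proposed for the cluster's product, e.g. from
    homology to annotated reference clusters.  It may be empty, in which case
    the BGC cannot be scored by the fingerprint-based method.
    """

    id: str
    strain: str
    product_type: str = ""
    candidate_structures: tuple[str, ...] = ()


@dataclass(frozen=True)
class GCF:
    """A gene cluster family: a non-empty set of member BGC ids.

    A BGC may belong to more than one family when clustering is run per
    product class (hybrid clusters are clustered under each class).
    """

    id: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"GCF {self.id!r} has no members")
        object.__setattr__(self, "members", frozenset(self.members))


@dataclass(frozen=True)
class Spectrum:
    """An MS2 spectrum: an m/z-sorted peak list plus precursor metadata.

    ``strain_set`` lists strains the (consensus) spectrum was observed in; it
    may be empty for library/training spectra that carry no strain context.
    """

    id: str
    peaks: tuple[tuple[float, float], ...]
    precursor_mz: float = 0.0
    strain_set: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        peaks = tuple(sorted((float(mz), float(it)) for mz, it in self.peaks))
        if any(it < 0 for _, it in peaks):
            raise ValueError(f"spectrum {self.id!r} has a negative intensity")
        object.__setattr__(self, "peaks", peaks)
        object.__setattr__(self, "strain_set", frozenset(self.strain_set))

    @property
    def mz(self) -> tuple[float, ...]:
        return tuple(p[0] for p in self.peaks)

    @property
    def intensity(self) -> tuple[float, ...]:
        return tuple(p[1] for p in self.peaks)


@dataclass(frozen=True)
class MolecularFamily:
    """A molecular family: a non-empty set of member spectrum ids."""

    id: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"molecular family {self.id!r} has no members")
        object.__setattr__(self, "members", frozenset(self.members))


@dataclass(frozen=True)
class LinkCandidate:
    """One candidate GCF-MF (or BGC-spectrum) link with its overlap counts."""

    gcf_id: str
    mf_id: str
    m: int
    g: int
    o: int
    n: int

    def __post_init__(self) -> None:
        validate_counts(self.m, self.g, self.o, self.n)


def validate_counts(m: int, g: int, o: int, n: int) -> None:
    """Check 0 <= o <= min(m, g) <= max(m, g) <= n and o >= m + g - n."""
    if n < 1:
        raise ValueError(f"population size n={n} must be >= 1")
    if not (0 <= m <= n and 0 <= g <= n):
        raise ValueError(f"set sizes m={m}, g={g} must lie in [0, n={n}]")
    if not (max(0, m + g - n) <= o <= min(m, g)):
        raise ValueError(
            f"overlap o={o} infeasible for m={m}, g={g}, n={n} "
            f"(must lie in [{max(0, m + g - n)}, {min(m, g)}])"
        )


@dataclass
class OccurrenceData:
    """Strain universe plus per-GCF and per-MF strain occurrence sets.

    ``strains`` is the ordered universe N; ``gcf_occurrence`` and
    ``mf_occurrence`` map family ids to subsets of it.
    """

    strains: tuple[str, ...]
    gcf_occurrence: dict[str, frozenset[str]] = field(default_factory=dict)
    mf_occurrence: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("strain universe contains duplicate ids")
        if len(self.strains) < 1:
            raise ValueError("strain universe is empty")
        universe = set(self.strains)
        for label, occ in (("GCF", self.gcf_occurrence), ("MF", self.mf_occurrence)):
            for fam, sset in occ.items():
                extra = set(sset) - universe
                if extra:
                    raise StrainResolutionError(
                        f"{label} {fam!r} references strains outside the "
                        f"universe: {sorted(extra)}"
                    )

    @property
    def n(self) -> int:
        return len(self.strains)


def _alias_map(strains: Iterable[Strain]) -> dict[str, str]:
    """Map every id and alias to the primary strain id; reject collisions."""
    amap: dict[str, str] = {}
    for strain in strains:
        for key in {strain.id, *strain.aliases}:
            if key in amap and amap[key] != strain.id:
                raise ValueError(
                    f"strain identifier {key!r} claimed by both "
                    f"{amap[key]!r} and {strain.id!r}"
                )
            amap[key] = strain.id
    return amap


def derive_strain_sets(
    bgcs: Iterable[BGC],
    gcfs: Iterable[GCF],
    spectra: Iterable[Spectrum],
    mfs: Iterable[MolecularFamily],
    strains: Iterable[Strain],
) -> OccurrenceData:
    """Derive per-family strain occurrence sets from object membership.

    A GCF's strain set is the union of its member BGCs' strains; an MF's is
    the union of its member spectra's strain sets.  Alias references are
    canonicalised to primary strain ids.  Unresolvable references raise
    :class:`StrainResolutionError` naming the dangling id.
    """
    strains = list(strains)
    amap = _alias_map(strains)
    bgc_by_id = {b.id: b for b in bgcs}
    spec_by_id = {s.id: s for s in spectra}

    def resolve(ref: str, context: str) -> str:
        try:
            return amap[ref]
        except KeyError:
            raise StrainResolutionError(
                f"unknown strain reference {ref!r} in {context}"
            ) from None

    gcf_occ: dict[str, frozenset[str]] = {}
    for gcf in gcfs:
        members = []
        for bid in gcf.members:
            if bid not in bgc_by_id:
                raise StrainResolutionError(
                    f"GCF {gcf.id!r} references unknown BGC {bid!r}"
                )
            members.append(bgc_by_id[bid])
        gcf_occ[gcf.id] = frozenset(
            resolve(b.strain, f"BGC {b.id!r}") for b in members
        )

    mf_occ: dict[str, frozenset[str]] = {}
    for mf in mfs:
        sset: set[str] = set()
        for sid in mf.members:
            if sid not in spec_by_id:
                raise StrainResolutionError(
                    f"MF {mf.id!r} references unknown spectrum {sid!r}"
                )
            spec = spec_by_id[sid]
            sset.update(resolve(ref, f"spectrum {sid!r}") for ref in spec.strain_set)
        mf_occ[mf.id] = frozenset(sset)

    return OccurrenceData(
        strains=tuple(s.id for s in strains),
        gcf_occurrence=gcf_occ,
        mf_occurrence=mf_occ,
    )


def enumerate_link_candidates(occ: OccurrenceData) -> list[LinkCandidate]:
    """All #GCFs x #MFs candidate links with (m, g, o, n) filled in.

    Candidates are ordered by (GCF id, MF id) for reproducibility.
    """
    n = occ.n
    out = []
    for gcf_id, mf_id in itertools.product(
        sorted(occ.gcf_occurrence), sorted(occ.mf_occurrence)
    ):
        G = occ.gcf_occurrence[gcf_id]
        M = occ.mf_occurrence[mf_id]
        out.append(
            LinkCandidate(
                gcf_id=gcf_id,
                mf_id=mf_id,
                m=len(M),
                g=len(G),
                o=len(G & M),
                n=n,
            )
        )
    return out


def deduplicate_gcfs(gcfs: Sequence[GCF]) -> list[GCF]:
    """Drop GCFs whose member sets duplicate an earlier family's.

    Hybrid product classes can cluster the same BGC set under several class
    labels; identical member sets are kept once (first id in sorted order).
    """
    seen: dict[frozenset[str], GCF] = {}
    for gcf in sorted(gcfs, key=lambda g: g.id):
        if gcf.members not in seen:
            seen[gcf.members] = gcf
    return sorted(seen.values(), key=lambda g: g.id)
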