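"""Taxonomic presence/absence of transporter homologues and the
lineage-uniqueness rule.

Reciprocal-best-hit homologues of each transporter across a grouped library
of species are summarized as per-taxonomic-group species counts. A
transporter is "diatom unique" when it is conserved across the focal
lineage (present in more than one species of EVERY diatom group) yet
essentially absent elsewhere (fewer than 4 non-diatom species in total and
never more than 2 in any single non-diatom group).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

LINEAGE_CLASSES = (
    "diatom",
    "other_ochrophyte",
    "aplastidic_stramenopile",
    "other_secondary_red",
)


@dataclass
class TaxonomyMap:
    """species -> taxonomic group, group -> lineage class."""

    species_group: dict[str, str]
    group_lineage: dict[str, str]

    def __post_init__(self) -> None:
        bad = {l for l in self.group_lineage.values() if l not in LINEAGE_CLASSES}
        if bad:
            raise ValueError(f"unknown lineage classes: {sorted(bad)}")
        unmapped = {g for g in self.species_group.values() if g not in self.group_lineage}
        if unmapped:
            raise ValueError(f"groups without a lineage class: {sorted(unmapped)}")

    @property
    def groups(self) -> list[str]:
        return sorted(self.group_lineage)

    def diatom_groups(self) -> list[str]:
        return sorted(g for g, l in self.group_lineage.items() if l == "diatom")

    def non_diatom_groups(self) -> list[str]:
        return sorted(g for g, l in self.group_lineage.items() if l != "diatom")


@dataclass(frozen=True)
class PresenceProfile:
    """Per-group count of species holding >= 1 RBH homologue."""

    transporter_id: str
    group_counts: tuple[tuple[str, int], ...]

    def count(self, group: str) -> int:
        return dict(self.group_counts).get(group, 0)

    def as_dict(self) -> dict[str, int]:
        return dict(self.group_counts)


def group_presence(
    transporter_id: str,
    species_with_hits: Iterable[str],
    taxmap: TaxonomyMap,
) -> PresenceProfile:
    """Count hit-bearing species per taxonomic group.

    ``species_with_hits`` lists species in which the transporter retrieved a
    reciprocal best hit; duplicates count once. Species missing from the
    taxonomy raise a ValueError naming the offenders.
    """
    species = set(species_with_hits)
    unmapped = sorted(s for s in species if s not in taxmap.species_group)
    if unmapped:
        raise ValueError(f"species not in taxonomy: {unmapped}")
    counts = {g: 0 for g in taxmap.groups}
    for s in species:
        counts[taxmap.species_group[s]] += 1
    return PresenceProfile(
        transporter_id=transporter_id,
        group_counts=tuple(sorted(counts.items())),
    )


def is_diatom_unique(profile: PresenceProfile, taxmap: TaxonomyMap) -> bool:
    """Apply the diatom-uniqueness rule to one presence profile.

    True iff count > 1 in every diatom group, total non-diatom species < 4,
    and no single non-diatom group exceeds 2 species.
    """
    counts = profile.as_dict()
    diatom = taxmap.diatom_groups()
    non_diatom = taxmap.non_diatom_groups()
    if not all(counts.get(g, 0) > 1 for g in diatom):
        return False
    non_diatom_counts = [counts.get(g, 0) for g in non_diatom]
    return sum(non_diatom_counts) < 4 and all(c <= 2 for c in non_diatom_counts)


def conservation_matrix(
    profiles: Sequence[PresenceProfile],
    taxmap: TaxonomyMap,
    min_species: int = 2,
) -> tuple[pd.DataFrame, pd.Series]:
    """Transporter x group count table plus per-group conservation tallies.

    The tally for a group counts transporters with >= ``min_species``
    hit-bearing species in that group (bar-chart semantics: conserved over
    at least two species).
    """
    groups = taxmap.groups
    rows = {p.transporter_id: [p.count(g) for g in groups] for p in profiles}
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=groups).sort_index()
    matrix.index.name = "transporter_id"
    tallies = (matrix >= min_species).sum(axis=0)
    tallies.name = f"n_transporters_ge{min_species}_species"
    return matrix, tallies
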