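"""Taxonomy map from reference sequences and families to ESUs.

An ecologically significant unit (ESU) is the lowest taxonomic group to
which prey sequences can be confidently assigned; several families that
cannot be separated at the 18S V9 locus may share one ESU. The taxonomy
also records which ESUs are bilaterian (candidate prey — microbial and
other non-bilaterian hits are treated as parasites or incidental
ingestion) and which ESUs are "self" for each predator species, i.e.
the predator's own tissue whose reads must be removed from its samples
but kept in samples from unrelated predators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["EsuTaxonomy"]


@dataclass
class EsuTaxonomy:
    """ESU-level taxonomy and per-predator self assignments.

    Parameters
    ----------
    esu_table : pandas.DataFrame
        One row per ESU with columns ``esu`` and boolean
        ``is_bilaterian``.
    self_esus : dict of str -> set of str
        For each predator species, the ESUs matching the predator's own
        taxon (e.g. all Perciformes predators share a Perciformes self
        ESU).
    family_to_esu : dict of str -> str, optional
        Family-level merge map, used where families are
        indistinguishable at the locus.
    """

    esu_table: pd.DataFrame
    self_esus: dict[str, set[str]] = field(default_factory=dict)
    family_to_esu: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"esu", "is_bilaterian"}
        missing = required - set(self.esu_table.columns)
        if missing:
            raise ValueError(f"esu_table missing columns: {sorted(missing)}")
        if self.esu_table["esu"].duplicated().any():
            dupes = self.esu_table.loc[self.esu_table["esu"].duplicated(), "esu"]
            raise ValueError(f"duplicate ESU labels: {sorted(set(dupes))}")
        self.self_esus = {sp: set(esus) for sp, esus in self.self_esus.items()}

    @property
    def esus(self) -> list[str]:
        return list(self.esu_table["esu"])

    @property
    def bilaterian_esus(self) -> set[str]:
        tab = self.esu_table
        return set(tab.loc[tab["is_bilaterian"].astype(bool), "esu"])

    def is_prey(self, esu: str, predator_species: str) -> bool:
        """Whether ``esu`` counts as prey in a sample from ``predator_species``."""
        if esu not in self.bilaterian_esus:
            return False
        return esu not in self.self_esus_of(predator_species)

    def self_esus_of(self, predator_species: str) -> set[str]:
        """Self ESUs for a predator; raises for unknown species."""
        try:
            return self.self_esus[predator_species]
        except KeyError:
            raise KeyError(
                f"no self-ESU entry for predator species {predator_species!r}; "
                "every predator must be declared in the taxonomy"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        """Flat TSV-ready table: esu, is_bilaterian, self_of_species."""
        self_of: dict[str, list[str]] = {e: [] for e in self.esus}
        for sp, esus in self.self_esus.items():
            for e in esus:
                self_of.setdefault(e, []).append(sp)
        out = self.esu_table.copy()
        out["self_of_species"] = [
            ",".join(sorted(self_of.get(e, []))) for e in out["esu"]
        ]
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   family_to_esu: dict[str, str] | None = None) -> "EsuTaxonomy":
        """Inverse of :meth:`to_frame`."""
        self_esus: dict[str, set[str]] = {}
        for _, row in frame.iterrows():
            spp = str(row.get("self_of_species", "") or "")
            for sp in filter(None, spp.split(",")):
                self_esus.setdefault(sp, set()).add(row["esu"])
        return cls(
            esu_table=frame[["esu", "is_bilaterian"]].reset_index(drop=True),
            self_esus=self_esus,
            family_to_esu=dict(family_to_esu or {}),
        )
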