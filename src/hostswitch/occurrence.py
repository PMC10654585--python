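"""Occurrence data model: hosts, mite taxa, and presence/absence records.

A *record* is a unique (host individual, taxon) pair — the unit the
occurrence analysis counts ("p/a" records). Specimen counts within a
record are kept separately as *abundance*. Host individuals that carried
no mites live in the host roster so that prevalence denominators include
them (e.g. 144 examined hosts vs 139 with records).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ReferentialError, SchemaError, ValidationError

__all__ = [
    "SampleSource",
    "EcologicalGroup",
    "Category",
    "HostIndividual",
    "MiteTaxonProfile",
    "OccurrenceRecord",
    "OccurrenceDataset",
    "read_occurrence_table",
    "write_occurrence_table",
]


class SampleSource(enum.Enum):
    WILD_CAPTURE = "wild_capture"
    ROADKILL = "roadkill"
    MUSEUM_SKIN = "museum_skin"


class EcologicalGroup(enum.Enum):
    """Where on the host the mite lives.

    Feather-vane mites transmit by direct plumage contact; quill- and
    skin-dwelling mites (QSM) have restricted contact transmission and
    some disperse by phoresy, so the two groups are never pooled.
    """

    VANE = "vane"
    QUILL_SKIN = "quill_skin"


class Category(enum.Enum):
    """Host-specificity category of a mite taxon on the focal host."""

    SPECIFIC = "specific"
    ALIEN = "alien"
    QSM = "qsm"
    UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class HostIndividual:
    id: str
    species: str
    sample_source: SampleSource
    locality: str | None = None
    #: free-form cross-contamination confidence note for museum skins;
    #: no scoring rule is applied here
    confidence: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("host id must be non-empty")
        if not self.species:
            raise ValidationError(f"host {self.id!r}: species must be non-empty")


@dataclass(frozen=True)
class MiteTaxonProfile:
    name: str
    genus: str
    family: str
    ecological_group: EcologicalGroup
    category: Category = Category.UNASSIGNED

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("taxon name must be non-empty")
        if self.ecological_group is EcologicalGroup.QUILL_SKIN and self.category not in (
            Category.QSM,
            Category.UNASSIGNED,
        ):
            raise ValidationError(
                f"taxon {self.name!r}: quill/skin mites can only be 'qsm' "
                f"or 'unassigned', got {self.category.value!r}"
            )


@dataclass(frozen=True)
class OccurrenceRecord:
    host_id: str
    taxon: str
    abundance: int

    def __post_init__(self) -> None:
        if self.abundance < 1:
            raise ValidationError(
                f"record ({self.host_id!r}, {self.taxon!r}): abundance must be "
                f">= 1, got {self.abundance}"
            )


@dataclass
class OccurrenceDataset:
    """Host roster, taxon registry, and the (host, taxon) records."""

    hosts: dict[str, HostIndividual] = field(default_factory=dict)
    taxa: dict[str, MiteTaxonProfile] = field(default_factory=dict)
    records: list[OccurrenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            if rec.host_id not in self.hosts:
                raise ReferentialError(
                    f"record references host {rec.host_id!r} absent from roster"
                )
            if rec.taxon not in self.taxa:
                raise ReferentialError(
                    f"record references unregistered taxon {rec.taxon!r}"
                )
            key = (rec.host_id, rec.taxon)
            if key in seen:
                raise ReferentialError(
                    f"duplicate record for host/taxon pair {key!r}; one record "
                    "per pair (merge abundances upstream if intended)"
                )
            seen.add(key)

    # -- summaries ---------------------------------------------------------

    @property
    def n_hosts(self) -> int:
        return len(self.hosts)

    @property
    def n_hosts_with_records(self) -> int:
        return len({r.host_id for r in self.records})

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def total_abundance(self) -> int:
        return sum(r.abundance for r in self.records)

    def records_by_host(self) -> dict[str, list[OccurrenceRecord]]:
        out: dict[str, list[OccurrenceRecord]] = {h: [] for h in self.hosts}
        for rec in self.records:
            out[rec.host_id].append(rec)
        return out

    def records_for_taxon(self, name: str) -> list[OccurrenceRecord]:
        return [r for r in self.records if r.taxon == name]

    def with_categories(self, categories: Mapping[str, Category]) -> "OccurrenceDataset":
        """Return a copy with taxon categories replaced."""
        taxa = {
            name: replace(profile, category=categories.get(name, profile.category))
            for name, profile in self.taxa.items()
        }
        return OccurrenceDataset(hosts=dict(self.hosts), taxa=taxa, records=list(self.records))


_ROSTER_COLUMNS = ["host_id", "host_species", "source"]
_RECORD_COLUMNS = [
    "host_id",
    "host_species",
    "source",
    "taxon",
    "genus",
    "family",
    "ecological_group",
    "abundance",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_table(path: Path, required: Iterable[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def read_occurrence_table(path: str | Path, host_roster: str | Path) -> OccurrenceDataset:
    """Read a records table plus a host roster into a validated dataset.

    The roster lists *all* examined hosts (so mite-free individuals are
    representable); every record row must reference a roster host with a
    consistent species/source. Duplicate (host, taxon) rows are an error,
    never silently merged.
    """
    path, host_roster = Path(path), Path(host_roster)
    roster_df = _read_table(host_roster, _ROSTER_COLUMNS)
    hosts: dict[str, HostIndividual] = {}
    for row in roster_df.itertuples(index=False):
        if row.host_id in hosts:
            raise ReferentialError(f"{host_roster}: duplicate host id {row.host_id!r}")
        hosts[row.host_id] = HostIndividual(
            id=row.host_id,
            species=row.host_species,
            sample_source=SampleSource(row.source),
            locality=getattr(row, "locality", None) or None,
            confidence=getattr(row, "confidence", None) or None,
        )

    rec_df = _read_table(path, _RECORD_COLUMNS)
    taxa: dict[str, MiteTaxonProfile] = {}
    records: list[OccurrenceRecord] = []
    for row in rec_df.itertuples(index=False):
        if row.host_id not in hosts:
            raise ReferentialError(
                f"{path}: record host {row.host_id!r} absent from roster"
            )
        host = hosts[row.host_id]
        if row.host_species != host.species or row.source != host.sample_source.value:
            raise ReferentialError(
                f"{path}: host {row.host_id!r} metadata disagrees with roster"
            )
        category = Category(getattr(row, "category", "") or "unassigned")
        profile = MiteTaxonProfile(
            name=row.taxon,
            genus=row.genus,
            family=row.family,
            ecological_group=EcologicalGroup(row.ecological_group),
            category=category,
        )
        if row.taxon in taxa:
            if taxa[row.taxon] != profile:
                raise ReferentialError(
                    f"{path}: taxon {row.taxon!r} redefined with conflicting fields"
                )
        else:
            taxa[row.taxon] = profile
        try:
            abundance = int(row.abundance)
        except ValueError as exc:
            raise ValidationError(
                f"{path}: non-integer abundance {row.abundance!r} "
                f"for ({row.host_id!r}, {row.taxon!r})"
            ) from exc
        records.append(OccurrenceRecord(row.host_id, row.taxon, abundance))

    return OccurrenceDataset(hosts=hosts, taxa=taxa, records=records)


def write_occurrence_table(
    dataset: OccurrenceDataset, path: str | Path, host_roster: str | Path
) -> None:
    """Write the records table and host roster with deterministic ordering."""
    path, host_roster = Path(path), Path(host_roster)
    roster_rows = [
        {
            "host_id": h.id,
            "host_species": h.species,
            "source": h.sample_source.value,
            "locality": h.locality or "",
            "confidence": h.confidence or "",
        }
        for h in sorted(dataset.hosts.values(), key=lambda h: h.id)
    ]
    pd.DataFrame(roster_rows, columns=_ROSTER_COLUMNS + ["locality", "confidence"]).to_csv(
        host_roster, sep=_sep_for(host_roster), index=False
    )

    rec_rows = []
    for rec in sorted(dataset.records, key=lambda r: (r.host_id, r.taxon)):
        host = dataset.hosts[rec.host_id]
        taxon = dataset.taxa[rec.taxon]
        rec_rows.append(
            {
                "host_id": rec.host_id,
                "host_species": host.species,
                "source": host.sample_source.value,
                "taxon": taxon.name,
                "genus": taxon.genus,
                "family": taxon.family,
                "ecological_group": taxon.ecological_group.value,
                "abundance": rec.abundance,
                "category": taxon.category.value,
            }
        )
    pd.DataFrame(rec_rows, columns=_RECORD_COLUMNS + ["category"]).to_csv(
        path, sep=_sep_for(path), index=False
    )
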