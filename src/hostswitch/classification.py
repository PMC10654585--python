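"""Host-specificity classification of mite taxa on a focal host.

A taxon is assigned to one of three categories:

``specific``
    found exclusively on the focal host, with molecular evidence (when
    available) placing its sister taxon on a congeneric brood parasite
    rather than close to any foster-parent mite;
``alien``
    found on foster parents (or genetically continuous with their
    mites), present on the focal host through interspecific transfer;
``qsm``
    quill- and skin-dwelling mites, grouped separately because their
    contact transmission is restricted and some disperse by phoresy.

Rules apply in fixed priority: the ecological rule (quill/skin) first,
then occurrence exclusivity, then genetic proximity. Missing molecular
evidence never blocks classification — occurrence exclusivity alone
suffices for ``specific``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import CoverageError, EvidenceError, SchemaError, ValidationError
from .occurrence import Category, EcologicalGroup, OccurrenceDataset

__all__ = [
    "ClassificationEvidence",
    "classify_taxon",
    "assign_categories",
    "read_evidence_table",
    "write_evidence_table",
    "DEFAULT_GENE_FLOW_THRESHOLD",
]

#: K2P proportion at or below which two populations are treated as
#: connected by ongoing gene flow.
DEFAULT_GENE_FLOW_THRESHOLD = 0.05


@dataclass(frozen=True)
class ClassificationEvidence:
    """Everything known about one taxon that bears on its category."""

    taxon: str
    found_on_focal_host: bool
    found_on_foster_hosts: bool
    ecological_group: EcologicalGroup
    #: binomial of the host carrying the taxon's sister lineage, or None
    #: when the taxon has no molecular data
    sister_taxon_host: str | None = None
    #: K2P distance (proportion) to the nearest foster-parent mite, or
    #: None when unknown
    distance_to_nearest_foster_mite: float | None = None

    def __post_init__(self) -> None:
        if not (self.found_on_focal_host or self.found_on_foster_hosts):
            raise EvidenceError(
                f"taxon {self.taxon!r}: found on neither focal nor foster hosts"
            )
        d = self.distance_to_nearest_foster_mite
        if d is not None and d < 0:
            raise ValidationError(f"taxon {self.taxon!r}: negative distance {d}")


def _genus(binomial: str) -> str:
    return binomial.split()[0] if binomial else ""


def classify_taxon(
    evidence: ClassificationEvidence,
    gene_flow_threshold: float = DEFAULT_GENE_FLOW_THRESHOLD,
    focal_species: str = "Molothrus bonariensis",
) -> Category:
    """Deterministically classify one taxon from its evidence.

    Priority: (1) quill/skin dwellers are ``qsm`` regardless of
    occurrence; (2) otherwise ``specific`` requires exclusivity on the
    focal host, a sister taxon hosted by a congeneric of the focal
    species (or no molecular data), and no shallow genetic link
    (<= ``gene_flow_threshold``) to a foster-parent mite; (3) everything
    else is ``alien``.
    """
    if not 0 < gene_flow_threshold < 1:
        raise ValidationError(
            f"gene_flow_threshold must be in (0, 1), got {gene_flow_threshold}"
        )
    if evidence.ecological_group is EcologicalGroup.QUILL_SKIN:
        return Category.QSM
    if evidence.found_on_focal_host and not evidence.found_on_foster_hosts:
        sister = evidence.sister_taxon_host
        sister_ok = sister is None or _genus(sister) == _genus(focal_species)
        d = evidence.distance_to_nearest_foster_mite
        distance_ok = d is None or d > gene_flow_threshold
        if sister_ok and distance_ok:
            return Category.SPECIFIC
    return Category.ALIEN


def assign_categories(
    dataset: OccurrenceDataset,
    evidence: Mapping[str, ClassificationEvidence],
    gene_flow_threshold: float = DEFAULT_GENE_FLOW_THRESHOLD,
    focal_species: str = "Molothrus bonariensis",
) -> OccurrenceDataset:
    """Classify every taxon in the dataset; returns a new dataset."""
    missing = sorted(set(dataset.taxa) - set(evidence))
    if missing:
        raise CoverageError(f"no classification evidence for taxa: {missing}")
    categories = {}
    for name, profile in dataset.taxa.items():
        ev = evidence[name]
        if ev.ecological_group is not profile.ecological_group:
            raise EvidenceError(
                f"taxon {name!r}: evidence ecological group "
                f"{ev.ecological_group.value!r} disagrees with dataset "
                f"{profile.ecological_group.value!r}"
            )
        categories[name] = classify_taxon(ev, gene_flow_threshold, focal_species)
    return dataset.with_categories(categories)


_EVIDENCE_COLUMNS = [
    "taxon",
    "found_on_focal_host",
    "found_on_foster_hosts",
    "ecological_group",
    "sister_taxon_host",
    "distance_to_nearest_foster_mite",
]


def read_evidence_table(path: str | Path) -> dict[str, ClassificationEvidence]:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _EVIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    out: dict[str, ClassificationEvidence] = {}
    for row in df.itertuples(index=False):
        dist = row.distance_to_nearest_foster_mite
        out[row.taxon] = ClassificationEvidence(
            taxon=row.taxon,
            found_on_focal_host=row.found_on_focal_host.lower() == "true",
            found_on_foster_hosts=row.found_on_foster_hosts.lower() == "true",
            ecological_group=EcologicalGroup(row.ecological_group),
            sister_taxon_host=row.sister_taxon_host or None,
            distance_to_nearest_foster_mite=float(dist) if dist else None,
        )
    return out


def write_evidence_table(
    evidence: Mapping[str, ClassificationEvidence], path: str | Path
) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    rows = []
    for name in sorted(evidence):
        ev = evidence[name]
        d = ev.distance_to_nearest_foster_mite
        rows.append(
            {
                "taxon": ev.taxon,
                "found_on_focal_host": str(ev.found_on_focal_host).lower(),
                "found_on_foster_hosts": str(ev.found_on_foster_hosts).lower(),
                "ecological_group": ev.ecological_group.value,
                "sister_taxon_host": ev.sister_taxon_host or "",
                "distance_to_nearest_foster_mite": "" if d is None else repr(d),
            }
        )
    pd.DataFrame(rows, columns=_EVIDENCE_COLUMNS).to_csv(path, sep=sep, index=False)
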