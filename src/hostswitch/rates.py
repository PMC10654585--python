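"""Prevalence, co-occurrence, and transmission-rate estimation.

The focal host is a brood parasite, so vertical conspecific transmission
is structurally absent (q_vc = 0). Each record (unique host x taxon
presence) is read as one successful colonisation event whose route is
identified by the taxon's category:

* ``specific`` records -> horizontal conspecific transmission (q_hc);
* ``alien`` records   -> interspecific transmission from foster parents
  (q_vi, with a minor horizontal component q_hi);
* ``qsm`` records     -> undetermined route.

The conspecific:interspecific rate ratio is the specific:alien record
share ratio, bounded by assigning the undetermined QSM share entirely to
one side or the other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal
from pathlib import Path

import pandas as pd

from ._rounding import pct, round_half_up
from .errors import CoverageError, ValidationError
from .occurrence import Category, OccurrenceDataset

__all__ = [
    "PrevalenceRow",
    "CategorySubtotal",
    "PrevalenceTable",
    "CooccurrenceSummary",
    "TransmissionEstimate",
    "prevalence_table",
    "cooccurrence_table",
    "estimate_transmission",
    "COMBO_KEYS",
]

_ACTIVE = (Category.SPECIFIC, Category.ALIEN, Category.QSM)
_LETTER = {Category.SPECIFIC: "S", Category.ALIEN: "A", Category.QSM: "Q"}

#: exclusive per-host category combinations, in report order
COMBO_KEYS = ("S", "A", "Q", "S+A", "S+Q", "A+Q", "S+A+Q", "none")


@dataclass(frozen=True)
class PrevalenceRow:
    """One taxon's line of the prevalence table.

    ``prevalence_pct`` uses *all* examined hosts as denominator
    (mite-free individuals included); per-taxon percentages are rounded
    half-up to 2 decimals.
    """

    taxon: str
    category: Category
    n_records: int
    n_specimens: int
    prevalence_pct: float
    record_share_pct: float
    abundance_share_pct: float


@dataclass(frozen=True)
class CategorySubtotal:
    """Category roll-up; percentages rounded half-up to 1 decimal."""

    category: Category
    n_taxa: int
    n_records: int
    n_specimens: int
    n_hosts: int
    record_share_pct: float
    abundance_share_pct: float
    prevalence_pct: float


@dataclass(frozen=True)
class PrevalenceTable:
    rows: tuple[PrevalenceRow, ...]
    subtotals: tuple[CategorySubtotal, ...]
    n_hosts: int
    n_records: int
    n_specimens: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "taxon": r.taxon,
                    "category": r.category.value,
                    "prevalence_pct": r.prevalence_pct,
                    "record_share_pct": r.record_share_pct,
                    "n_records": r.n_records,
                    "n_specimens": r.n_specimens,
                    "abundance_share_pct": r.abundance_share_pct,
                }
                for r in self.rows
            ]
        )


def _require_categories(dataset: OccurrenceDataset) -> None:
    unassigned = sorted(
        name
        for name, t in dataset.taxa.items()
        if t.category not in _ACTIVE
    )
    if unassigned:
        raise CoverageError(f"taxa without assigned category: {unassigned}")


def prevalence_table(dataset: OccurrenceDataset) -> PrevalenceTable:
    """Per-taxon prevalence/record/abundance shares with category subtotals."""
    if dataset.n_hosts == 0:
        raise ValidationError("prevalence undefined: dataset has zero hosts")
    _require_categories(dataset)
    n_hosts = dataset.n_hosts
    n_records = dataset.n_records
    n_specimens = dataset.total_abundance

    per_taxon: dict[str, list] = {name: [0, 0] for name in dataset.taxa}
    hosts_by_cat: dict[Category, set[str]] = {c: set() for c in _ACTIVE}
    for rec in dataset.records:
        per_taxon[rec.taxon][0] += 1
        per_taxon[rec.taxon][1] += rec.abundance
        hosts_by_cat[dataset.taxa[rec.taxon].category].add(rec.host_id)

    rows = []
    for name in sorted(dataset.taxa, key=lambda n: (dataset.taxa[n].category.value, n)):
        nr, na = per_taxon[name]
        rows.append(
            PrevalenceRow(
                taxon=name,
                category=dataset.taxa[name].category,
                n_records=nr,
                n_specimens=na,
                prevalence_pct=pct(nr, n_hosts, 2),
                record_share_pct=pct(nr, n_records, 2) if n_records else 0.0,
                abundance_share_pct=pct(na, n_specimens, 2) if n_specimens else 0.0,
            )
        )

    subtotals = []
    for cat in _ACTIVE:
        cat_rows = [r for r in rows if r.category is cat]
        nr = sum(r.n_records for r in cat_rows)
        na = sum(r.n_specimens for r in cat_rows)
        subtotals.append(
            CategorySubtotal(
                category=cat,
                n_taxa=len(cat_rows),
                n_records=nr,
                n_specimens=na,
                n_hosts=len(hosts_by_cat[cat]),
                record_share_pct=pct(nr, n_records, 1) if n_records else 0.0,
                abundance_share_pct=pct(na, n_specimens, 1) if n_specimens else 0.0,
                prevalence_pct=pct(len(hosts_by_cat[cat]), n_hosts, 1),
            )
        )
    return PrevalenceTable(
        rows=tuple(rows),
        subtotals=tuple(subtotals),
        n_hosts=n_hosts,
        n_records=n_records,
        n_specimens=n_specimens,
    )


@dataclass(frozen=True)
class CooccurrenceSummary:
    """Hosts and records partitioned by exclusive category combination.

    ``host_counts`` maps each combination key (``"S"``, ``"S+A"``, ...,
    ``"none"``) to the number of hosts carrying exactly that set of
    categories; ``record_counts`` maps the same keys to per-category
    record counts. Percentage helpers expose both denominators the
    analysis uses: all examined hosts vs mite-bearing hosts only.
    """

    host_counts: dict[str, int]
    record_counts: dict[str, dict[str, int]]
    n_hosts: int
    n_records: int

    def __post_init__(self) -> None:
        if sum(self.host_counts.values()) != self.n_hosts:
            raise ValidationError("host combination counts do not sum to n_hosts")
        total = sum(sum(d.values()) for d in self.record_counts.values())
        if total != self.n_records:
            raise ValidationError("record combination counts do not sum to n_records")

    @property
    def n_hosts_with_mites(self) -> int:
        return self.n_hosts - self.host_counts.get("none", 0)

    def category_record_totals(self) -> dict[str, int]:
        out = {"specific": 0, "alien": 0, "qsm": 0}
        for counts in self.record_counts.values():
            for cat, n in counts.items():
                out[cat] += n
        return out

    def hosts_with_category(self, category: Category) -> int:
        letter = _LETTER[category]
        return sum(
            n for key, n in self.host_counts.items() if letter in key.split("+")
        )

    def host_pct(self, key: str, denominator: str = "all", ndigits: int = 1) -> float:
        """Share of hosts in one combination; denominator is explicit."""
        denom = self.n_hosts if denominator == "all" else self.n_hosts_with_mites
        return pct(self.host_counts.get(key, 0), denom, ndigits)

    def record_pct(self, key: str, category: str, ndigits: int = 1) -> float:
        return pct(self.record_counts.get(key, {}).get(category, 0), self.n_records, ndigits)


def cooccurrence_table(dataset: OccurrenceDataset) -> CooccurrenceSummary:
    """Assign each host to exactly one exclusive category combination."""
    _require_categories(dataset)
    host_cats: dict[str, set[Category]] = {h: set() for h in dataset.hosts}
    host_records: dict[str, dict[str, int]] = {
        h: {"specific": 0, "alien": 0, "qsm": 0} for h in dataset.hosts
    }
    for rec in dataset.records:
        cat = dataset.taxa[rec.taxon].category
        host_cats[rec.host_id].add(cat)
        host_records[rec.host_id][cat.value] += 1

    host_counts = {k: 0 for k in COMBO_KEYS}
    record_counts: dict[str, dict[str, int]] = {
        k: {"specific": 0, "alien": 0, "qsm": 0} for k in COMBO_KEYS
    }
    for host, cats in host_cats.items():
        if not cats:
            key = "none"
        else:
            key = "+".join(l for c, l in _LETTER.items() if c in cats)
        host_counts[key] += 1
        for cat, n in host_records[host].items():
            record_counts[key][cat] += n
    return CooccurrenceSummary(
        host_counts=host_counts,
        record_counts=record_counts,
        n_hosts=dataset.n_hosts,
        n_records=dataset.n_records,
    )


@dataclass(frozen=True)
class TransmissionEstimate:
    """Route shares and the conspecific:interspecific rate ratio.

    Shares are record shares in percent, rounded half-up to 1 decimal.
    ``ratio_point`` (= specific/alien record counts) is stored unrounded;
    ``ratio_lower``/``ratio_upper`` follow the published arithmetic on
    the *rounded* shares — lower merges the undetermined QSM share into
    the interspecific side (specific / (100 - specific)), upper merges
    it into the conspecific side ((specific + qsm) / alien). The exact
    count-based bounds are kept alongside; they provably bracket
    ``ratio_point`` whenever the QSM share is positive.
    """

    n_specific: int
    n_alien: int
    n_qsm: int
    share_specific_pct: float
    share_alien_pct: float
    share_qsm_pct: float
    ratio_point: float
    ratio_lower: float
    ratio_upper: float
    ratio_lower_exact: float
    ratio_upper_exact: float
    ratio_defined: bool = True

    @property
    def n_records(self) -> int:
        return self.n_specific + self.n_alien + self.n_qsm

    @property
    def ratio_point_display(self) -> float:
        return round_half_up(self.ratio_point, 1) if self.ratio_defined else math.inf

    def as_dict(self) -> dict:
        return {
            "counts": {
                "specific": self.n_specific,
                "alien": self.n_alien,
                "qsm": self.n_qsm,
            },
            "shares_pct": {
                "specific": self.share_specific_pct,
                "alien": self.share_alien_pct,
                "qsm": self.share_qsm_pct,
            },
            "ratio": {
                "point": self.ratio_point if self.ratio_defined else None,
                "lower": self.ratio_lower if self.ratio_defined else None,
                "upper": self.ratio_upper if self.ratio_defined else None,
                "defined": self.ratio_defined,
            },
        }


def _decimal_ratio(numer: float, denom: float) -> float:
    """1-decimal half-up quotient of two already-rounded shares."""
    if denom == 0:
        return math.inf
    d = Decimal(repr(numer)) / Decimal(repr(denom))
    return round_half_up(d, 1)


def estimate_transmission(
    summary: CooccurrenceSummary | tuple[int, int, int],
) -> TransmissionEstimate:
    """Estimate route shares and ratio bounds from category record counts.

    Accepts either a :class:`CooccurrenceSummary` or a raw
    ``(n_specific, n_alien, n_qsm)`` triple. A zero interspecific count
    yields infinite, flagged ratios rather than an exception.
    """
    if isinstance(summary, CooccurrenceSummary):
        totals = summary.category_record_totals()
        ns, na, nq = totals["specific"], totals["alien"], totals["qsm"]
    else:
        ns, na, nq = summary
    if min(ns, na, nq) < 0:
        raise ValidationError(f"negative category counts: {(ns, na, nq)}")
    total = ns + na + nq
    if total == 0:
        raise ValidationError("no records: transmission shares undefined")

    share_s = pct(ns, total, 1)
    share_a = pct(na, total, 1)
    share_q = pct(nq, total, 1)

    if na == 0:
        return TransmissionEstimate(
            n_specific=ns, n_alien=na, n_qsm=nq,
            share_specific_pct=share_s, share_alien_pct=share_a, share_qsm_pct=share_q,
            ratio_point=math.inf, ratio_lower=math.inf, ratio_upper=math.inf,
            ratio_lower_exact=ns / (na + nq) if (na + nq) else math.inf,
            ratio_upper_exact=math.inf,
            ratio_defined=False,
        )

    return TransmissionEstimate(
        n_specific=ns, n_alien=na, n_qsm=nq,
        share_specific_pct=share_s, share_alien_pct=share_a, share_qsm_pct=share_q,
        ratio_point=ns / na,
        ratio_lower=_decimal_ratio(share_s, round_half_up(100 - share_s, 1)),
        ratio_upper=_decimal_ratio(round_half_up(share_s + share_q, 1), share_a),
        ratio_lower_exact=ns / (na + nq),
        ratio_upper_exact=(ns + nq) / na,
    )


# -- report rendering ------------------------------------------------------

_CAT_TITLE = {
    Category.SPECIFIC: "Molothrus-specific",
    Category.ALIEN: "Molothrus-alien",
    Category.QSM: "QSM",
}


def write_prevalence_report(table: PrevalenceTable, path: str | Path) -> None:
    """Write the per-taxon prevalence table (with subtotals) as TSV."""
    rows = []
    for sub in table.subtotals:
        for r in table.rows:
            if r.category is sub.category:
                rows.append(
                    {
                        "taxon": r.taxon,
                        "category": r.category.value,
                        "prevalence_pct": f"{r.prevalence_pct:.2f}",
                        "record_share_pct": f"{r.record_share_pct:.2f}",
                        "n_records": r.n_records,
                        "n_specimens": r.n_specimens,
                        "abundance_share_pct": f"{r.abundance_share_pct:.2f}",
                    }
                )
        rows.append(
            {
                "taxon": f"Subtotal ({_CAT_TITLE[sub.category]}, {sub.n_taxa} species)",
                "category": sub.category.value,
                "prevalence_pct": f"{sub.prevalence_pct:.1f}",
                "record_share_pct": f"{sub.record_share_pct:.1f}",
                "n_records": sub.n_records,
                "n_specimens": sub.n_specimens,
                "abundance_share_pct": f"{sub.abundance_share_pct:.1f}",
            }
        )
    rows.append(
        {
            "taxon": "Total",
            "category": "",
            "prevalence_pct": "",
            "record_share_pct": "",
            "n_records": table.n_records,
            "n_specimens": table.n_specimens,
            "abundance_share_pct": "",
        }
    )
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)


def write_cooccurrence_report(summary: CooccurrenceSummary, path: str | Path) -> None:
    """Write the host/record co-occurrence summary as TSV."""
    rows = []
    for key in COMBO_KEYS:
        rec = summary.record_counts[key]
        rows.append(
            {
                "combination": key,
                "n_hosts": summary.host_counts[key],
                "host_pct_of_all": f"{summary.host_pct(key, 'all'):.1f}",
                "records_specific": rec["specific"],
                "records_alien": rec["alien"],
                "records_qsm": rec["qsm"],
            }
        )
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)


def render_markdown(table: PrevalenceTable, summary: CooccurrenceSummary) -> str:
    """Small human-readable markdown digest of both tables."""
    est = estimate_transmission(summary)
    lines = [
        "| category | taxa | records | share % | specimens | abundance % |",
        "|---|---|---|---|---|---|",
    ]
    for sub in table.subtotals:
        lines.append(
            f"| {_CAT_TITLE[sub.category]} | {sub.n_taxa} | {sub.n_records} | "
            f"{sub.record_share_pct:.1f} | {sub.n_specimens} | "
            f"{sub.abundance_share_pct:.1f} |"
        )
    lines += [
        "",
        f"Hosts: {summary.n_hosts} examined, {summary.n_hosts_with_mites} with mites.",
        f"Conspecific:interspecific ratio {est.ratio_point:.4f} "
        f"(interval {est.ratio_lower:.1f}-{est.ratio_upper:.1f}).",
    ]
    return "\n".join(lines) + "\n"
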