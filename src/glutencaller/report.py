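"""Replicate aggregation, predicted-vs-measured comparison and cohort stats."""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .errors import DiscordanceError, ValidationError
from .masses import diff_and_error, round_half_away, rsd_percent
from .reference import ReferenceLibrary


@dataclass
class ReplicateSet:
    """Concordant replicate acquisitions of one sample, aggregated.

    ``subunit_stats`` maps the subunit display key ``"locus/display"`` to
    ``(mean integer Da of the measured mass, RSD %, n replicates)``.
    """

    sample_id: str
    composition_string: str
    n_replicates: int
    subunit_stats: dict[str, tuple[int, float, int]] = field(default_factory=dict)


def aggregate_replicates(calls: Sequence) -> ReplicateSet:
    """Aggregate >= 2 replicate genotype calls of one sample.

    All replicates must agree on the composition string; otherwise a
    :class:`DiscordanceError` is raised listing the differing replicates.
    Mean masses are rounded half-up to integer Da for display; RSDs use the
    sample standard deviation over the mean.
    """
    if len(calls) < 2:
        raise ValidationError("need at least 2 replicates")
    compositions = {c.composition_string for c in calls}
    if len(compositions) != 1:
        details = [(i, c.composition_string) for i, c in enumerate(calls)]
        raise DiscordanceError(
            f"replicates disagree: {sorted(compositions)}", details=details)
    per_subunit: dict[str, list[float]] = defaultdict(list)
    for call in calls:
        for sub in call.subunit_calls:
            per_subunit[f"{sub.locus}/{sub.display}"].append(sub.matched_mass)
    stats = {}
    for key, masses in per_subunit.items():
        mean = int(round_half_away(sum(masses) / len(masses), 0))
        rsd = rsd_percent(masses) if len(masses) >= 2 else 0.0
        stats[key] = (mean, rsd, len(masses))
    return ReplicateSet(
        sample_id=calls[0].sample_id,
        composition_string=calls[0].composition_string,
        n_replicates=len(calls),
        subunit_stats=stats,
    )


@dataclass(frozen=True)
class ComparisonRow:
    """One predicted-vs-measured observation."""

    allele: str
    variant: str | None
    cultivar: str
    predicted_mass: float | None
    corrected_mass: int
    difference: int | None
    error_pct: float | None


def comparison_table(library: ReferenceLibrary,
                     calls: Sequence) -> list[ComparisonRow]:
    """Adduct-corrected measured masses against gene-predicted masses.

    One row per subunit call; rows for subunits without a public gene
    sequence (1By8*, 1Dx4) carry blank difference/error. For 1Bx7 the
    predicted mass of the classified variant record is used.
    """
    rows: list[ComparisonRow] = []
    for call in calls:
        for sub in call.subunit_calls:
            rec = _record_for_call(library, sub)
            predicted = rec.predicted_mature_mass if rec else None
            if predicted is not None:
                difference, error = diff_and_error(sub.corrected_mass, predicted)
            else:
                difference, error = None, None
            rows.append(ComparisonRow(
                allele=sub.allele, variant=sub.variant,
                cultivar=call.sample_id, predicted_mass=predicted,
                corrected_mass=sub.corrected_mass,
                difference=difference, error_pct=error))
    return rows


def _record_for_call(library, sub):
    records = library.records_for(sub.allele)
    if len(records) == 1:
        return records[0]
    wanted = sub.variant if sub.variant in ("group1", "group2", "OE") else "group2"
    for rec in records:
        if rec.variant == wanted:
            return rec
    return records[0]


@dataclass
class CohortSummary:
    n_samples: int
    n_uncallable: int
    allele_counts: Counter = field(default_factory=Counter)
    bx7_group_counts: Counter = field(default_factory=Counter)
    bx7_carriers: int = 0
    bx7_carrier_pct: float = 0.0
    absent_alleles: list[str] = field(default_factory=list)

    @property
    def bx7_mass_class_counts(self) -> dict[str, int]:
        """1Bx7 calls split purely by corrected-mass class (the duplication
        variant is mass-identical to group 2 and counted with it)."""
        g = self.bx7_group_counts
        return {
            "group1": g.get("group1", 0),
            "group2": (g.get("group2", 0) + g.get("OE", 0)
                       + g.get("group2_or_OE", 0)),
        }

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_uncallable": self.n_uncallable,
            "allele_counts": dict(self.allele_counts),
            "bx7_group_counts": dict(self.bx7_group_counts),
            "bx7_mass_class_counts": self.bx7_mass_class_counts,
            "bx7_carriers": self.bx7_carriers,
            "bx7_carrier_pct": self.bx7_carrier_pct,
            "absent_alleles": self.absent_alleles,
        }


def cohort_summary_stats(library: ReferenceLibrary,
                         calls: Sequence) -> CohortSummary:
    """Per-allele counts, 1Bx7 group counts and the absent-allele list.

    Counts are per called subunit slot (a silent Glu-A1 contributes no
    count); the 7OE variant is tallied under the name "1Bx7OE" so that
    carrier counts and the absent list can distinguish it.
    """
    if not calls:
        raise ValidationError("need at least one call")
    allele_counts: Counter = Counter()
    bx7_groups: Counter = Counter()
    carriers = 0
    n_uncallable = 0
    for call in calls:
        if call.status != "ok":
            n_uncallable += 1
            continue
        has_bx7 = False
        for sub in call.subunit_calls:
            name = sub.allele
            if name == "1Bx7":
                has_bx7 = True
                if sub.variant == "OE":
                    name = "1Bx7OE"
            allele_counts[name] += 1
        if has_bx7:
            carriers += 1
            if call.bx7_classification:
                bx7_groups[call.bx7_classification] += 1
    n_called = len(calls) - n_uncallable
    absent = sorted(n for n in library.subunit_names
                    if allele_counts.get(n, 0) == 0)
    pct = round_half_away(100.0 * carriers / n_called, 1) if n_called else 0.0
    return CohortSummary(
        n_samples=len(calls),
        n_uncallable=n_uncallable,
        allele_counts=allele_counts,
        bx7_group_counts=bx7_groups,
        bx7_carriers=carriers,
        bx7_carrier_pct=pct,
        absent_alleles=absent,
    )


# ---------------------------------------------------------------------------
# writers


def write_calls_tsv(calls: Sequence, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tstatus\tglu_a1\tglu_b1\tglu_d1\t"
                 "bx7_classification\tflags\n")
        for c in calls:
            labels = c.haplotype_labels
            fh.write("\t".join([
                c.sample_id, c.status,
                labels.get("Glu-A1", ""), labels.get("Glu-B1", ""),
                labels.get("Glu-D1", ""),
                c.bx7_classification or "", "; ".join(c.flags)]) + "\n")


def write_comparison_tsv(rows: Sequence[ComparisonRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("allele\tvariant\tcultivar\tpredicted_mass\t"
                 "corrected_mass\tdifference\terror_pct\n")
        for r in rows:
            fh.write("\t".join([
                r.allele, r.variant or "", r.cultivar,
                "" if r.predicted_mass is None else f"{r.predicted_mass:.0f}",
                str(r.corrected_mass),
                "" if r.difference is None else str(r.difference),
                "" if r.error_pct is None else f"{r.error_pct:.2f}"]) + "\n")


def write_report_json(calls: Sequence, summary: CohortSummary, path) -> None:
    payload = {
        "summary": summary.to_dict(),
        "calls": [c.to_dict() for c in calls],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
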