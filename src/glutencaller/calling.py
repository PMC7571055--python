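"""Mass-window genotype calling for wheat HMW-GS.

The procedure mirrors how an analyst reads an intact-protein MALDI-TOF
spectrum of wheat glutenin:

1. every measured peak is compared, after removal of the hypothesis-dependent
   4-vp adduct, against per-subunit mass windows built from the standards
   panel (window = [min observed - tol, max observed + tol], default
   tol = 300 Da — subunits whose reference masses differ by less than that
   are not mass-distinguishable);
2. peaks are not interpreted independently but as a locus composition: one
   haplotype per locus (a tightly linked x+y pair, a lone x, or a silent
   Glu-A1), which is what lets near-isobaric subunits such as 1By15/1By18 be
   identified through their linked partners;
3. near-isobaric pairs that the haplotype constraints cannot separate
   (1Ax2*/1Bx6, 1By8/1By8*) are reported as ambiguous unless orthogonal
   RP-HPLC evidence is supplied;
4. a 1Bx7 call is sub-classified by corrected mass into the ~82,400 Da
   (group 1) or ~83,000 Da (group 2) class; the overexpression variant 7OE is
   mass-identical to group 2 and is resolved only by a gene-duplication PCR
   flag.

The search is an exhaustive enumeration of Glu-A1 x Glu-B1 x Glu-D1
haplotype combinations (at most 3 x 9 x 4), scoring each combination by the
summed distances of its matched peaks to the reference means plus penalties
for unmatched required members and for peaks left unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from math import floor
from typing import Mapping, Sequence

from .errors import ValidationError
from .masses import strip_vp, vp_shift
from .reference import ReferenceLibrary, AlleleRecord, LocusHaplotype, LOCI
from .spectra import PeakList

#: Matching tolerance on adduct-corrected masses, Da. Subunits closer than
#: this are treated as not mass-distinguishable.
DEFAULT_TOL = 300.0

#: Corrected-mass boundary separating the two 1Bx7 classes (midpoint of the
#: ~82,400 and ~83,000 Da class centres).
BX7_GROUP_BOUNDARY = 82_700.0

#: Penalty for a required haplotype member with no matching peak. Large
#: enough that any complete low-error assignment beats an incomplete one.
PENALTY_MISSING = 10_000.0

#: Penalty per measured peak left unassigned by a combination.
PENALTY_UNASSIGNED = 1_000.0


@dataclass(frozen=True)
class EvidenceFlags:
    """Optional orthogonal evidence consulted (never required) by the caller.

    ``bx7_duplication_pcr``: result of the gene-duplication PCR that is the
    only way to tell 1Bx7OE from 1Bx7 group 2 (None = not run).
    ``rphplc_calls``: subunit display names confirmed by RP-HPLC retention
    behaviour, e.g. ``{"8*"}`` or ``{"2*"}``.
    """

    bx7_duplication_pcr: bool | None = None
    rphplc_calls: frozenset[str] = frozenset()


@dataclass(frozen=True)
class SubunitCall:
    """One peak -> subunit assignment."""

    allele: str                   # canonical name, e.g. "1Bx7"
    display: str                  # short form used in composition strings
    locus: str
    subunit_type: str
    variant: str | None           # 1Bx7 classification where applicable
    matched_mass: float           # measured (alkylated) mass, Da
    corrected_mass: int           # adduct-stripped integer mass, Da
    delta_to_reference_mean: float
    ambiguity: str = "none"       # none | paired_alternative | group_uncertain
    alternatives: tuple[str, ...] = ()
    evidence_used: tuple[str, ...] = ()


@dataclass
class GenotypeCall:
    sample_id: str
    status: str                          # "ok" | "uncallable"
    haplotype_labels: dict[str, str] = field(default_factory=dict)
    subunit_calls: list[SubunitCall] = field(default_factory=list)
    composition_string: str = ""
    bx7_classification: str | None = None
    unassigned_peaks: list[float] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)
    score: float = float("inf")

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "status": self.status,
            "haplotypes": self.haplotype_labels,
            "composition": self.composition_string,
            "bx7_classification": self.bx7_classification,
            "unassigned_peaks": self.unassigned_peaks,
            "flags": self.flags,
            "score": self.score,
            "subunits": [
                {
                    "allele": c.allele, "display": c.display,
                    "locus": c.locus, "subunit_type": c.subunit_type,
                    "variant": c.variant, "matched_mass": c.matched_mass,
                    "corrected_mass": c.corrected_mass,
                    "delta_to_reference_mean": c.delta_to_reference_mean,
                    "ambiguity": c.ambiguity,
                    "alternatives": list(c.alternatives),
                    "evidence_used": list(c.evidence_used),
                }
                for c in self.subunit_calls
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GenotypeCall":
        call = cls(
            sample_id=d["sample_id"], status=d["status"],
            haplotype_labels=dict(d.get("haplotypes", {})),
            composition_string=d.get("composition", ""),
            bx7_classification=d.get("bx7_classification"),
            unassigned_peaks=list(d.get("unassigned_peaks", [])),
            flags=list(d.get("flags", [])),
            score=d.get("score", float("inf")),
        )
        call.subunit_calls = [
            SubunitCall(
                allele=s["allele"], display=s["display"], locus=s["locus"],
                subunit_type=s["subunit_type"], variant=s.get("variant"),
                matched_mass=s["matched_mass"],
                corrected_mass=s["corrected_mass"],
                delta_to_reference_mean=s["delta_to_reference_mean"],
                ambiguity=s.get("ambiguity", "none"),
                alternatives=tuple(s.get("alternatives", ())),
                evidence_used=tuple(s.get("evidence_used", ())),
            )
            for s in d.get("subunits", [])
        ]
        return call


def candidate_alleles(library: ReferenceLibrary, corrected_mass: float,
                      tol: float = DEFAULT_TOL) -> list[tuple[str, float]]:
    """All subunits whose corrected-mass window contains ``corrected_mass``.

    Returns ``(name, delta_to_reference_mean)`` pairs sorted by |delta|;
    for 1Bx7 the delta is taken to the nearest variant class mean.
    """
    if tol <= 0:
        raise ValidationError("tolerance must be positive")
    best: dict[str, float] = {}
    for rec in library.alleles.values():
        obs = rec.corrected_reference_masses
        if not obs:
            continue
        lo, hi = min(obs) - tol, max(obs) + tol
        if lo <= corrected_mass <= hi:
            delta = corrected_mass - sum(obs) / len(obs)
            if rec.name not in best or abs(delta) < abs(best[rec.name]):
                best[rec.name] = delta
    return sorted(best.items(), key=lambda kv: abs(kv[1]))


def classify_bx7(library: ReferenceLibrary, corrected_mass: float,
                 evidence: EvidenceFlags | None = None,
                 boundary: float = BX7_GROUP_BOUNDARY,
                 tol: float = DEFAULT_TOL) -> str:
    """Classify a corrected 1Bx7 mass into its variant group.

    Below the boundary the call is ``group1``. Above it, mass alone cannot
    separate group 2 from the overexpression variant; the duplication PCR
    flag decides (``OE`` if positive, ``group2`` if negative,
    ``group2_or_OE`` if not run).
    """
    evidence = evidence or EvidenceFlags()
    windows = []
    for rec in library.records_for("1Bx7"):
        obs = rec.corrected_reference_masses
        if obs:
            windows.append((min(obs) - tol, max(obs) + tol))
    if not any(lo <= corrected_mass <= hi for lo, hi in windows):
        raise ValidationError(
            f"corrected mass {corrected_mass:.0f} outside the 1Bx7 windows")
    if corrected_mass < boundary:
        return "group1"
    if evidence.bx7_duplication_pcr is True:
        return "OE"
    if evidence.bx7_duplication_pcr is False:
        return "group2"
    return "group2_or_OE"


# ---------------------------------------------------------------------------
# combination scoring


@dataclass(frozen=True)
class _MemberWindow:
    record: AlleleRecord
    lo: float
    hi: float
    mean: float


def _member_windows(library: ReferenceLibrary, tol: float
                    ) -> dict[str, list[_MemberWindow]]:
    """Corrected-mass windows per member key; "1Bx7" maps to all variants."""
    out: dict[str, list[_MemberWindow]] = {}
    for rec in library.alleles.values():
        obs = rec.corrected_reference_masses
        if not obs:
            continue
        win = _MemberWindow(rec, min(obs) - tol, max(obs) + tol,
                            sum(obs) / len(obs))
        out.setdefault(rec.key, []).append(win)
        if rec.variant is not None:
            out.setdefault(rec.name, []).append(win)
    return out


@dataclass
class _Slot:
    locus: str
    slot: str                     # "x" | "y"
    member_key: str
    peak_index: int | None = None
    record: AlleleRecord | None = None
    corrected: float | None = None
    delta: float | None = None


@dataclass
class _Combo:
    haps: tuple[LocusHaplotype, LocusHaplotype, LocusHaplotype]
    slots: list[_Slot]
    score: float
    n_missing: int
    n_unassigned: int

    @property
    def labels(self) -> dict[str, str]:
        return {h.locus: h.label for h in self.haps}

    @property
    def composition(self) -> str:
        return ", ".join(h.label for h in self.haps)

    def slot_map(self):
        return {(s.locus, s.slot): s for s in self.slots if s.peak_index is not None}


def _match_member(member_key, windows, masses, assigned, alkylated):
    """Nearest unassigned peak whose corrected mass falls in the member's
    window; returns (peak_index, record, corrected, delta) or None."""
    best = None
    for i, mass in enumerate(masses):
        if i in assigned:
            continue
        for win in windows.get(member_key, ()):
            corr = (mass - vp_shift(win.record.cysteine_count)
                    if alkylated else mass)
            if win.lo <= corr <= win.hi:
                delta = corr - win.mean
                if best is None or abs(delta) < abs(best[3]):
                    best = (i, win.record, corr, delta)
    return best


def _score_combo(haps, windows, masses, alkylated) -> _Combo:
    slots: list[_Slot] = []
    for hap in haps:
        for slot_name, key in zip(("x", "y"), hap.members):
            if key is not None:
                slots.append(_Slot(hap.locus, slot_name, key))
    assigned: set[int] = set()
    n_missing = 0
    total = 0.0
    for slot in slots:   # fixed order: A1x, B1x, B1y, D1x, D1y
        match = _match_member(slot.member_key, windows, masses,
                              assigned, alkylated)
        if match is None:
            n_missing += 1
            continue
        i, rec, corr, delta = match
        assigned.add(i)
        slot.peak_index, slot.record = i, rec
        slot.corrected, slot.delta = corr, delta
        total += abs(delta)
    n_unassigned = len(masses) - len(assigned)
    score = total + PENALTY_MISSING * n_missing + PENALTY_UNASSIGNED * n_unassigned
    return _Combo(tuple(haps), slots, score, n_missing, n_unassigned)


def _is_mass_ambiguous_alternative(best: _Combo, other: _Combo,
                                   tol: float) -> list[tuple[_Slot, _Slot]]:
    """Slots where ``other`` differs from ``best`` only in allele identity
    while matching the same peaks, all within mass ambiguity (< tol of both
    reference means). Returns the differing slot pairs, or [] if ``other``
    is not such an alternative."""
    if (other.n_missing, other.n_unassigned) != (best.n_missing,
                                                 best.n_unassigned):
        return []
    a, b = best.slot_map(), other.slot_map()
    if set(p.peak_index for p in a.values()) != set(p.peak_index
                                                    for p in b.values()):
        return []
    differing: list[tuple[_Slot, _Slot]] = []
    for key, sa in a.items():
        sb = b.get(key)
        if sb is None or sb.peak_index != sa.peak_index:
            return []
        if sb.record.name != sa.record.name:
            if abs(sa.delta) < tol and abs(sb.delta) < tol:
                differing.append((sa, sb))
            else:
                return []
    return differing


def call_genotype(library: ReferenceLibrary, peaks: PeakList,
                  tol: float = DEFAULT_TOL,
                  evidence: EvidenceFlags | None = None,
                  alkylated: bool = True,
                  boundary: float = BX7_GROUP_BOUNDARY) -> GenotypeCall:
    """Map a calibrated peak list to a Glu-A1/Glu-B1/Glu-D1 composition.

    Exhaustively enumerates haplotype combinations, scores each (summed
    |delta to reference mean| + penalties for missing members and
    unassigned peaks) and returns the best. Combinations that differ from
    the best only by swapping near-isobaric subunits on the same peak are
    treated as ties: RP-HPLC evidence decides if supplied, otherwise the
    lexicographically smaller composition is returned and the alternative is
    flagged. A "7" call is afterwards sub-classified into group 1 / group 2 /
    OE using the corrected mass and the duplication-PCR flag.
    """
    if tol <= 0:
        raise ValidationError("tolerance must be positive")
    evidence = evidence or EvidenceFlags()
    masses = [p.mass for p in peaks.peaks]
    if not masses:
        return GenotypeCall(sample_id=peaks.sample_id, status="uncallable",
                            flags=["no peaks in the acquisition range"])

    windows = _member_windows(library, tol)
    combos = [
        _score_combo(haps, windows, masses, alkylated)
        for haps in product(*(
            [h for h in library.haplotypes_for(locus) if h.searchable]
            for locus in LOCI))
    ]
    combos.sort(key=lambda c: (c.score, c.n_unassigned,
                               tuple(h.label for h in c.haps)))
    best = combos[0]

    if all(s.peak_index is None for s in best.slots):
        return GenotypeCall(
            sample_id=peaks.sample_id, status="uncallable",
            unassigned_peaks=list(masses),
            flags=[f"no subunit window matches any of {len(masses)} peaks"])

    # ties: mass-ambiguous alternatives to the best combination
    ties: list[tuple[_Combo, list[tuple[_Slot, _Slot]]]] = [(best, [])]
    for other in combos[1:]:
        differing = _is_mass_ambiguous_alternative(best, other, tol)
        if differing:
            ties.append((other, differing))

    def rphplc_matches(combo: _Combo) -> int:
        displays = {s.record.display for s in combo.slots
                    if s.record is not None}
        return len(displays & set(evidence.rphplc_calls))

    # within a mass-ambiguous tie set the score difference is below the
    # resolution the windows claim, so RP-HPLC evidence decides if present,
    # else the lexicographically smaller composition (deterministic default;
    # compared per-locus so that "7+8" sorts before "7+8*")
    chosen = min(ties, key=lambda t: (-rphplc_matches(t[0]),
                                      tuple(h.label for h in t[0].haps)))[0]
    # alternatives relative to whichever combination was chosen
    alternatives: dict[tuple[str, str], set[str]] = {}
    for other, _ in ties:
        if other is chosen:
            continue
        for sa, sb in _is_mass_ambiguous_alternative(chosen, other, tol):
            alternatives.setdefault((sa.locus, sa.slot),
                                    set()).add(sb.record.display)

    flags: list[str] = []
    calls: list[SubunitCall] = []
    bx7_class = None
    labels = chosen.labels
    for slot in chosen.slots:
        if slot.peak_index is None:
            flags.append(f"required member {slot.member_key} of "
                         f"{labels[slot.locus]} not matched")
            continue
        rec = slot.record
        mass = masses[slot.peak_index]
        corrected = (strip_vp(mass, rec.cysteine_count) if alkylated
                     else floor(mass))
        variant = rec.variant
        display = rec.display
        used: list[str] = []
        ambiguity = "none"
        alts = tuple(sorted(alternatives.get((slot.locus, slot.slot), ())))
        if alts:
            if evidence.rphplc_calls & ({display} | set(alts)):
                used.append("rphplc")
                alts = ()
            else:
                ambiguity = "paired_alternative"
                flags.append(f"ambiguous {display}/{'/'.join(alts)}: "
                             "RP-HPLC recommended")
        if rec.name == "1Bx7":
            bx7_class = classify_bx7(library, corrected, evidence,
                                     boundary=boundary, tol=tol)
            variant = bx7_class
            display = "7"   # classification, not nearest variant, decides
            if bx7_class == "OE":
                display = "7OE"
                used.append("bx7_duplication_pcr")
            elif bx7_class == "group2":
                used.append("bx7_duplication_pcr")
            elif bx7_class == "group2_or_OE":
                ambiguity = ambiguity if ambiguity != "none" else "group_uncertain"
                flags.append("1Bx7 group 2 vs 7OE: duplication PCR recommended")
        calls.append(SubunitCall(
            allele=rec.name, display=display, locus=rec.locus,
            subunit_type=rec.subunit_type, variant=variant,
            matched_mass=mass, corrected_mass=corrected,
            delta_to_reference_mean=slot.delta,
            ambiguity=ambiguity, alternatives=alts,
            evidence_used=tuple(used)))

    # a positive duplication PCR makes the Glu-B1 haplotype the 7OE+8* pair
    if bx7_class == "OE":
        for i, c in enumerate(calls):
            if c.locus == "Glu-B1" and c.subunit_type == "y" and c.allele == "1By8":
                calls[i] = SubunitCall(
                    allele="1By8*", display="8*", locus=c.locus,
                    subunit_type="y", variant=None,
                    matched_mass=c.matched_mass,
                    corrected_mass=c.corrected_mass,
                    delta_to_reference_mean=c.delta_to_reference_mean,
                    ambiguity="none", alternatives=(),
                    evidence_used=c.evidence_used + ("bx7_duplication_pcr",))
        flags = [f for f in flags if not f.startswith("ambiguous 8")]

    def locus_label(locus: str) -> str:
        members = [c for c in calls if c.locus == locus]
        if locus == "Glu-A1":
            return members[0].display if members else "N"
        xs = [c.display for c in members if c.subunit_type == "x"]
        ys = [c.display for c in members if c.subunit_type == "y"]
        if xs and ys:
            return f"{xs[0]}+{ys[0]}"
        return xs[0] if xs else (ys[0] if ys else labels[locus])

    final_labels = {locus: locus_label(locus) for locus in LOCI}
    unassigned = [masses[i] for i in range(len(masses))
                  if i not in {s.peak_index for s in chosen.slots
                               if s.peak_index is not None}]
    for m in unassigned:
        flags.append(f"unassigned peak at {m:.0f} Da")
    return GenotypeCall(
        sample_id=peaks.sample_id,
        status="ok",
        haplotype_labels=final_labels,
        subunit_calls=calls,
        composition_string=", ".join(final_labels[locus] for locus in LOCI),
        bx7_classification=bx7_class,
        unassigned_peaks=unassigned,
        flags=flags,
        score=chosen.score,
    )


def call_cohort(library: ReferenceLibrary,
                samples: Sequence[PeakList],
                evidence: Mapping[str, EvidenceFlags] | None = None,
                tol: float = DEFAULT_TOL,
                alkylated: bool = True):
    """Call every sample and aggregate cohort-level statistics.

    ``evidence`` maps sample_id to :class:`EvidenceFlags`. Per-sample
    failures become "uncallable" entries in the result, never exceptions.
    Returns ``(calls, summary)`` where summary is a
    :class:`~glutencaller.report.CohortSummary`.
    """
    from .report import cohort_summary_stats

    if not samples:
        raise ValidationError("cohort must contain at least one sample")
    evidence = evidence or {}
    calls = [
        call_genotype(library, pl, tol=tol,
                      evidence=evidence.get(pl.sample_id), alkylated=alkylated)
        for pl in samples
    ]
    return calls, cohort_summary_stats(library, calls)
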