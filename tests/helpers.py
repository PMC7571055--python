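"""Shared helpers: cultivar-row peak lists, evidence construction, and an
independent brute-force scorer used to cross-check the caller."""

from itertools import product

import glutencaller as gc
from glutencaller.reference import LOCI, parse_haplotype_label

CULTIVAR_COLS = (("Glu-A1", "glu_a1", "a1x_mass", None),
                 ("Glu-B1", "glu_b1", "b1x_mass", "b1y_mass"),
                 ("Glu-D1", "glu_d1", "d1x_mass", "d1y_mass"))


def peaks_from_row(lib, row):
    return gc.PeakList([gc.Peak(m, 1.0) for m in lib.row_peaks(row)],
                       sample_id=row["cultivar"], calibrated=True)


def expected_composition(row):
    return f'{row["glu_a1"]}, {row["glu_b1"]}, {row["glu_d1"]}'


def row_allele_keys(row):
    """(allele key, mass column) pairs of one cultivar-table row."""
    group = row.get("bx7_group")
    group = group if isinstance(group, str) else None
    out = []
    for locus, comp_col, x_col, y_col in CULTIVAR_COLS:
        x_key, y_key = parse_haplotype_label(locus, row[comp_col], group)
        if x_key is not None:
            out.append((x_key, x_col))
        if y_key is not None:
            out.append((y_key, y_col))
    return out


def study_evidence(row):
    """The orthogonal evidence available in the original study: the
    duplication PCR on every 1Bx7 carrier, and RP-HPLC confirmation of the
    near-isobaric members printed in the composition."""
    pcr = row.get("bx7_dup_pcr")
    pcr = {"true": True, "false": False}.get(pcr) if isinstance(pcr, str) else None
    rphplc = set()
    for token in f'{row["glu_a1"]} {row["glu_b1"]}'.replace("+", " ").split():
        if token in ("2*", "6", "8", "8*"):
            rphplc.add(token)
    return gc.EvidenceFlags(bx7_duplication_pcr=pcr,
                            rphplc_calls=frozenset(rphplc))


def truth_recovered(call, truth_string):
    """True when the call matches the truth exactly, or the truth is among
    the flagged alternatives (8/8* swaps, group2-vs-OE uncertainty)."""
    if call.status != "ok":
        return False
    if call.composition_string == truth_string:
        return True
    exp = dict(zip(LOCI, (t.strip() for t in truth_string.split(","))))
    for locus, got in call.haplotype_labels.items():
        if got == exp[locus]:
            continue
        # every display the caller allows for each slot of this locus
        options = []
        for sub in sorted((s for s in call.subunit_calls if s.locus == locus),
                          key=lambda s: s.subunit_type):
            allowed = {sub.display, *sub.alternatives}
            if sub.allele == "1Bx7" and sub.variant == "group2_or_OE":
                allowed.add("7OE")
            options.append(allowed)
        labels = {"+".join(combo) for combo in product(*options)}
        if exp[locus] not in labels:
            return False
    return True


# ---------------------------------------------------------------------------
# independent brute-force scorer (re-derived from the standards table alone)


def _brute_windows(lib, tol):
    """Corrected-mass windows/means per member key, recomputed directly from
    the standards table with pandas (no caller internals)."""
    obs = {}
    for _, row in lib.standards.iterrows():
        for key, col in row_allele_keys(row):
            obs.setdefault(key, []).append(float(row[col]))
    shifts = {k: 105.14 * lib.alleles[k].cysteine_count for k in obs}
    windows = {}
    for key, masses in obs.items():
        corr = [m - shifts[key] for m in masses]
        windows[key] = (min(corr) - tol, max(corr) + tol,
                        sum(corr) / len(corr), shifts[key])
    # the generic "1Bx7" member may match any variant window
    windows["1Bx7"] = [windows[k] for k in
                       ("1Bx7:group1", "1Bx7:group2", "1Bx7:OE")]
    return windows


def brute_force_scores(lib, masses, tol=300.0,
                       p_missing=10_000.0, p_unassigned=1_000.0):
    """Score of every searchable haplotype combination, greedily matched in
    the fixed member order, as (score, labels) tuples."""
    windows = _brute_windows(lib, tol)
    per_locus = [[h for h in lib.haplotypes_for(locus) if h.searchable]
                 for locus in LOCI]
    results = []
    for haps in product(*per_locus):
        members = [m for h in haps for m in h.members if m is not None]
        assigned, total, missing = set(), 0.0, 0
        for key in members:
            wins = windows.get(key)
            if wins is None:
                missing += 1
                continue
            wins = wins if isinstance(wins, list) else [wins]
            best = None
            for i, m in enumerate(masses):
                if i in assigned:
                    continue
                for lo, hi, mean, shift in wins:
                    corr = m - shift
                    if lo <= corr <= hi:
                        d = abs(corr - mean)
                        if best is None or d < best[1]:
                            best = (i, d)
            if best is None:
                missing += 1
            else:
                assigned.add(best[0])
                total += best[1]
        score = (total + p_missing * missing
                 + p_unassigned * (len(masses) - len(assigned)))
        results.append((score, tuple(h.label for h in haps)))
    return results
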