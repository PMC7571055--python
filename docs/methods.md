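# Methods

## The measurement being modelled

Linear-mode MALDI-TOF of intact wheat glutenin gives one broad peak per
expressed HMW-GS, 3–5 peaks per cultivar, in a 60,000–110,000 Da window,
externally calibrated on BSA (66,463 Da). Replicate precision is reported as
a relative standard deviation and sits around 0.01–0.1 % — tens of Da at
these masses. Everything downstream treats masses as **average** molecular
masses of singly charged ions ([M+H]⁺ ≈ M; the proton and the isotopic
envelope are both far below measurement error at 70–100 kDa, so no charge
deconvolution or isotope modelling is done).

Extraction alkylates cysteine thiols with 4-vinylpyridine, shifting each
subunit up by 105.14 Da per cysteine. Cysteine counts are fixed by subunit
class — 4 for x-type, 7 for y-type, with 1Dx5 (5) and 1Bx20 (2) as the
exceptions — so the shift itself carries information: it is removed
per-hypothesis during matching (the correction depends on which subunit a
peak is being tested against, not on the peak). Corrected masses are
reported as **floored** integers; the floor convention is what reproduces
the published corrected values from the published raw ones in every
checkable pair. Percentage errors are rounded half-away-from-zero to two
decimals on the floored difference.

## Reference library

The packaged TSVs hold (a) the 22 named subunits with cysteine counts, gene
accessions and mature-protein masses predicted from gene sequences (Expasy
average-mass convention) where public sequences exist — 1By8* and 1Dx4 have
none; (b) the locus haplotypes: *Glu-A1* ∈ {1, 2*, N}, ten *Glu-B1* pairs,
four *Glu-D1* pairs; (c) a 24-cultivar standards panel and a 38-cultivar
Korean validation panel with replicate-mean masses and RSDs per expressed
subunit; (d) the per-observation predicted-vs-measured comparison table.

1Bx7 is stored as three variant records sharing the legacy display name "7":
group 1 (~82,400 Da corrected), group 2 (~83,000 Da, an 18 bp coding
insertion ≈ 6 extra residues ≈ 600 Da), and 7OE (the overexpression variant:
group-2 sequence plus a gene duplication that only PCR can see). The
predicted mass of the group-2 record is kept at its printed X13927-derived
value so the comparison table reproduces the published +457…+540 Da
anomalies verbatim.

Two cells of the source tables are mutually inconsistent: the Soissons 1By8
raw mass strips to 75,129 where the corrected table prints 75,133, and the
Nanbu-Komugi 1Dy12 raw mass strips to 68,657 where it prints 68,637. Both
tables are transcribed verbatim; the golden tests pin these two rows at
their printed values and assert exactness for the other ~106 pairs. One
error cell (Baekjoong 1By16) was evidently computed from the unfloored
difference and differs from our convention by exactly 0.01 %.

## Genotype calling

Windows. For each subunit, the corrected-mass window is
`[min(obs) − τ, max(obs) + τ]` over the standards panel, with τ = 300 Da by
default: pairs of subunits whose reference masses differ by less than that
were not distinguishable on the instrument, and every panel mass falls
inside its own subunit's window at this τ. (A 500 Da figure describes
between-subunit separation, not a matching radius, and is not used.)

Search. The caller enumerates every *Glu-A1* × *Glu-B1* × *Glu-D1*
haplotype combination (≤ 3 × 9 × 4; the 7OE+8* pair is excluded from the
mass-only search because it is mass-identical to 7+8*). Within a
combination, members are matched greedily in a fixed order (A1x, B1x, B1y,
D1x, D1y) to the nearest unassigned in-window peak. Score =
Σ|corrected − reference mean| + 10,000 per required-but-unmatched member +
1,000 per unassigned peak; the penalties are set so any complete low-error
assignment beats any incomplete one, and both are configurable. "N" at
*Glu-A1* is a zero-member haplotype with score 0, so a silent locus is
preferred exactly when no x-type peak near 86–88 kDa is left over.

Ties and ambiguity. A runner-up combination that differs from the optimum
only by swapping subunit identities on the *same* peaks, with both
identities within τ of the peak (the 2*/6 and 8/8* situations), is a
mass-ambiguous tie: the score difference is below the resolution the
windows claim, so it is not allowed to decide. RP-HPLC evidence picks the
member it confirms; absent evidence the lexicographically smaller
composition is returned deterministically and the alternative is flagged.
This matters in practice: the validation panel's 1By8 masses straddle the
midpoint between the 1By8 and 1By8* means, so nearest-mean scoring alone
would flip about a third of the `7+8` lines to `7+8*`.

1Bx7 grouping. A "7" call is classified by corrected mass against a
boundary of 82,700 Da — the midpoint of the two class centres; observed
corrected masses leave a ~500 Da dead zone around it, so any boundary in
that zone is equivalent on the panel data. Above the boundary the
duplication-PCR flag decides group 2 vs 7OE (unknown → `group2_or_OE`,
flagged); a positive PCR also forces the 8* partner, since 7OE occurs in
the 7OE+8* haplotype.

Uncallable inputs (no peak matches any window, or an empty list) return a
diagnostic result rather than raising, so cohort runs never abort. Peaks
matching no subunit are reported as unassigned with a flag.

## Peak detection and calibration

The published workflow used vendor software for peak picking, so the
detector here is the package's own, deliberately simple scheme: moving
average smoothing (window 60 Da, forced to odd point-width to stay
phase-neutral), baseline = trace median, noise = 1.4826 × MAD of the
baseline-subtracted trace, candidate peaks = local maxima with prominence ≥
min_snr × noise and height ≥ min_snr × noise, a 400 Da minimum-spacing
filter (higher apex wins), and an intensity-weighted centroid over the
half-height region (each flank walk stops at the half height or at a rise
> 3 × noise, which marks a neighbouring peak's flank). Centroid rather than
apex is reported; the source data does not say which convention its
software used. The default min_snr of 6 makes a false positive over a full
10,000-point trace vanishingly rare; at 3 (a common convention for short
traces) occasional noise maxima pass, which the caller absorbs as
unassigned peaks.

Calibration is one-point multiplicative against BSA by default (a single
external standard is all the protocol provides); a two-point linear model
is available. Scales outside [0.95, 1.05] are rejected as implausible.

## Simulator

A simulated sample is a genotype rendered as one Gaussian peak per
expressed subunit. True masses are the gene-predicted mature masses plus
the 4-vp shift when alkylated; a subunit whose prediction is missing
(1By8*, 1Dx4) **or** deviates from the standards' mean corrected measured
mass by more than 300 Da falls back to that measured mean. The deviation
rule covers 1Bx17 (+646 Da), 1Dx2.2 (−497 Da, measured near the top of the
acquisition window where accuracy degrades) and the group-2 1Bx7 record
(whose X13927-derived prediction belongs to the group-1 mass class);
without it, zero-noise simulations of those genotypes would be uncallable
at the default tolerance, which would say nothing about the caller.

Mass error is multiplicative Gaussian — constant *relative* SD, default
0.05 % (inside the reported 0.011–0.096 % RSD range) — matching how
precision is reported for these data. Intensities are log-normal
(μ = 7, σ = 0.3) and deliberately meaningless: the source data carries no
usable intensity information, so intensities never enter any accuracy
check. Profiles add a constant baseline (20), white noise (SD 5) and
Gaussian peak shape with σ = 150 Da, chosen to look like linear-TOF peaks
at 80 kDa; all are config-exposed and none enters the calling arithmetic.
Cohorts draw genotypes from a supplied pool (by default the Korean panel's
empirical frequencies) with per-sample seeds derived from one master seed,
so runs are byte-reproducible.

What the simulator does *not* emulate: matrix/solvent effects, detector
saturation, mass-dependent resolution, peak tailing, chemical background,
or calibration drift. Passing the round-trip tests therefore shows the
caller is correct **given** the stated error model, not that the error
model exhausts real spectra.

## Problem sizes in the test suite

The suite runs the full 24- and 38-cultivar panels everywhere they appear,
the complete haplotype enumeration cross-check on all 62, 200 simulated
samples for the noisy recovery rate, 100 random sequences for the
average-mass oracle, and 25 simulated profiles for detector recovery —
sizes chosen so the whole suite completes in seconds while every claim is
still exercised end to end.

## Known limitations

* The library is closed-world: a peak from an allele outside the 22 curated
  subunits is reported as unassigned, never discovered de novo.
* Quality scoring (Payne *Glu-1* scores), LMW-GS and gliadins are out of
  scope.
* Calibration behaviour near the acquisition-range edge (relevant to
  1Dx2.2 at ~100.8 kDa) is not modelled; the library's own 1Dx2.2 windows
  absorb the observed systematic offset.
* With only mass in hand, `8/8*`, `2*/6` and `group2/7OE` decisions are
  conventions plus flags; they become definitive only with the RP-HPLC or
  PCR evidence inputs.
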