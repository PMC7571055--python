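# glutencaller

Genotype calling of wheat **high-molecular-weight glutenin subunits
(HMW-GS)** from intact-protein MALDI-TOF mass spectra.

HMW-GS are the 67–101 kDa seed storage proteins encoded at the *Glu-A1*,
*Glu-B1* and *Glu-D1* loci of bread wheat; their allelic composition (written
e.g. `2*, 7+8, 5+10`) is the single best predictor of bread-making quality,
so breeding programmes type thousands of lines for it. This package
implements the desk side of a MALDI-TOF workflow for that job: it turns a
measured peak list into a locus-by-locus subunit composition, for breeders
and cereal chemists who have spectra (or just peak masses) and want calls.

## What it computes

* **4-vinylpyridine adduct correction.** Extraction alkylates cysteines with
  4-vp, adding 105.14 Da per residue. x-type subunits carry 4 cysteines,
  y-type 7 (exceptions: 1Dx5 has 5, 1Bx20 has 2), so an observed mass *m*
  of a subunit with *n* cysteines is compared to gene predictions as
  ⌊*m* − 105.14 *n*⌋.
* **Mass-window matching.** Each of the 22 named subunits has a window
  `[min − τ, max + τ]` built from a 24-cultivar standards panel (default
  τ = 300 Da, the resolution limit below which subunits are not
  mass-distinguishable).
* **Haplotype-constrained calling.** Peaks are interpreted jointly: one
  haplotype per locus (a tightly linked x+y pair such as `13+16`, a lone x,
  or a silent *Glu-A1* "N"). The caller enumerates all combinations, scores
  each by Σ|Δ to reference mean| plus penalties for unmatched members and
  unassigned peaks, and returns the optimum. The linkage is what identifies
  near-isobaric subunits (1By15/1By18/1By20) through their partners.
* **Known ambiguities as first-class results.** 1Ax2*/1Bx6 (means 249 Da
  apart) and 1By8/1By8* (92 Da) cannot be separated by mass; calls are
  flagged and optional RP-HPLC evidence resolves them. A 1Bx7 call is
  sub-classified by corrected mass into group 1 (~82,400 Da) or group 2
  (~83,000 Da); the overexpression variant 1Bx7OE is mass-identical to
  group 2 and resolved only by a gene-duplication PCR flag.
* **Cohort reporting and simulation.** Replicate aggregation (mean, RSD %),
  predicted-vs-measured comparison tables, per-allele cohort counts, and a
  synthetic-spectrum generator (Gaussian peaks, multiplicative mass error,
  baseline + noise) so the whole pipeline is testable without instrument
  data.

## Worked example

```python
from glutencaller import (EvidenceFlags, Peak, PeakList, call_genotype,
                          load_library)

lib = load_library()
# replicate-mean masses of an alkylated Chinese Spring extract
peaks = PeakList([Peak(83488, 1.0), Peak(75886, 1.0),
                  Peak(87493, 1.0), Peak(69410, 1.0)],
                 sample_id="Chinese Spring", calibrated=True)
call = call_genotype(lib, peaks)
print(call.composition_string)
print(call.bx7_classification)
for f in call.flags:
    print("-", f)
```

prints

```
N, 7+8, 2+12
group2_or_OE
- 1Bx7 group 2 vs 7OE: duplication PCR recommended
- ambiguous 8/8*: RP-HPLC recommended
```

i.e. a silent *Glu-A1*, `7+8` at *Glu-B1* and `2+12` at *Glu-D1*. The 1Bx7
peak corrects to 83,067 Da — the group-2 mass class — but mass alone cannot
exclude the overexpression variant, and the 1By8 call sits within 92 Da of
1By8*, so both caveats are flagged. Supplying
`EvidenceFlags(bx7_duplication_pcr=False, rphplc_calls={"8"})` silences
them.

The same operations are available from a shell:

```sh
glutencaller masscalc strip-vp 83488 --cys 4      # -> 83067
glutencaller simulate --composition "2*,7g1+8,5+10" --replicates 5 \
    --sd 0.0005 --seed 17 --out sim/
glutencaller peaks --in profile.tsv --out peaks.tsv
glutencaller call --peaks peaks.tsv --out call.json
glutencaller report --calls calls/ --out report/
```

## Layout

| module | contents |
|---|---|
| `glutencaller.reference` | embedded allele/haplotype library + cultivar panels (TSV fixtures) |
| `glutencaller.masses` | 4-vp arithmetic, average masses, differences, RSDs |
| `glutencaller.spectra` | peak-list/profile I/O, peak picking, BSA calibration |
| `glutencaller.calling` | the haplotype-constrained genotype caller |
| `glutencaller.report` | replicate aggregation, comparison tables, cohort stats |
| `glutencaller.simulate` | synthetic peak lists, profiles and cohorts |
| `glutencaller.cli` | `glutencaller` command with the subcommands above |

See `docs/methods.md` for the model, parameter choices and limitations.
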