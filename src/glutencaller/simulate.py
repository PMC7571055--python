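"""Synthetic HMW-GS mass spectra with the statistical structure the caller
assumes.

A simulated sample is a genotype (one haplotype label per locus, with the
1Bx7 variant spelled out, e.g. ``("2*", "7g1+8", "5+10")``) rendered as one
peak per expressed subunit. The true mass of a subunit is its gene-predicted
mature-protein mass plus the 4-vp adduct when the sample is alkylated;
subunits without a usable predicted mass fall back to the mean
adduct-corrected measured mass from the standards panel. Mass error is
multiplicative Gaussian — a constant *relative* SD, matching how replicate
precision is reported for this kind of data (RSD ~0.01-0.1%). Peak
intensities are log-normal and carry no biological meaning; profile spectra
add Gaussian peak shapes, a constant baseline and white noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence
import json

import numpy as np

from .errors import ValidationError
from .masses import vp_shift
from .reference import ReferenceLibrary, ACQUISITION_RANGE, parse_haplotype_label
from .spectra import Peak, PeakList, ProfileSpectrum

#: |predicted - mean measured| above which the gene-predicted mass is not a
#: usable surrogate for what the instrument reports (systematic deviations,
#: e.g. 1Bx17 and 1Dx2.2) and the measured mean is simulated instead.
PREDICTED_MEASURED_AGREEMENT = 300.0


@dataclass(frozen=True)
class SimulationSpec:
    """Genotype plus noise model for one simulated sample."""

    composition: tuple[str, str, str]      # Glu-A1, Glu-B1, Glu-D1 labels
    alkylated: bool = True
    relative_mass_sd: float = 0.0005       # 0.05%, inside the observed RSD range
    peak_width_sigma: float = 150.0        # Da, Gaussian peak shape (profiles)
    intensity_lognorm: tuple[float, float] = (7.0, 0.3)   # (mu, sigma)
    baseline_level: float = 20.0
    noise_sd: float = 5.0
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.relative_mass_sd <= 0.005:
            raise ValidationError("relative_mass_sd must be in [0, 0.005]")


@dataclass(frozen=True)
class GroundTruth:
    """What was injected: losslessly recoverable from the record."""

    composition: tuple[str, str, str]
    subunits: tuple[tuple[str, float], ...]   # (allele key, true mass in Da)
    alkylated: bool
    seed: int

    @property
    def composition_string(self) -> str:
        a1, b1, d1 = self.composition
        b1 = b1.replace("g1", "").replace("g2", "")
        return f"{a1}, {b1}, {d1}"


_BX7_LABELS = {"7g1": "1Bx7:group1", "7g2": "1Bx7:group2",
               "7oe": "1Bx7:OE", "7OE": "1Bx7:OE"}


def _composition_allele_keys(library: ReferenceLibrary,
                             composition: Sequence[str]) -> list[str]:
    if len(composition) != 3:
        raise ValidationError("composition must have one label per locus")
    keys: list[str] = []
    for locus, label in zip(("Glu-A1", "Glu-B1", "Glu-D1"), composition):
        label = label.replace(" ", "")
        if locus == "Glu-B1":
            parts = label.split("+")
            x_part = _BX7_LABELS.get(parts[0],
                                     "1Bx7:group1" if parts[0] == "7"
                                     else f"1Bx{parts[0]}")
            x_key = x_part
            y_key = f"1By{parts[1]}" if len(parts) > 1 else None
        else:
            x_key, y_key = parse_haplotype_label(locus, label)
        for key in (x_key, y_key):
            if key is None:
                continue
            if key not in library.alleles:
                raise ValidationError(
                    f"unknown haplotype member {key!r} in {locus} label "
                    f"{label!r}")
            keys.append(key)
    return keys


def simulation_mass(library: ReferenceLibrary, key: str) -> float:
    """Adduct-free true mass used for a simulated subunit.

    The gene-predicted mature mass when it agrees with the measured
    reference data to within :data:`PREDICTED_MEASURED_AGREEMENT`; the mean
    adduct-corrected measured mass otherwise (covers the subunits without a
    public gene sequence and those with large systematic offsets).
    """
    rec = library.alleles[key]
    obs = rec.corrected_reference_masses
    measured_mean = sum(obs) / len(obs) if obs else None
    predicted = rec.predicted_mature_mass
    if predicted is None:
        if measured_mean is None:
            raise ValidationError(f"no mass available for {key}")
        return measured_mean
    if (measured_mean is not None
            and abs(predicted - measured_mean) > PREDICTED_MEASURED_AGREEMENT):
        return measured_mean
    return predicted


def _ground_truth(library, spec) -> GroundTruth:
    subunits = []
    for key in _composition_allele_keys(library, spec.composition):
        rec = library.alleles[key]
        mass = simulation_mass(library, key)
        if spec.alkylated:
            mass += vp_shift(rec.cysteine_count)
        subunits.append((key, mass))
    return GroundTruth(composition=tuple(spec.composition),
                       subunits=tuple(subunits),
                       alkylated=spec.alkylated, seed=spec.seed)


def simulate_peaklist(library: ReferenceLibrary, spec: SimulationSpec,
                      sample_id: str = "sim",
                      replicate_id: str = "r1") -> tuple[PeakList, GroundTruth]:
    """One peak per expressed subunit, with multiplicative Gaussian mass
    error and log-normal intensities; deterministic under a fixed seed."""
    truth = _ground_truth(library, spec)
    rng = np.random.default_rng(spec.seed)
    mu, sigma = spec.intensity_lognorm
    peaks = []
    for key, true_mass in truth.subunits:
        observed = true_mass * (1.0 + rng.normal(0.0, spec.relative_mass_sd))
        intensity = float(rng.lognormal(mu, sigma))
        snr = (intensity / spec.noise_sd) if spec.noise_sd > 0 else None
        peaks.append(Peak(mass=float(observed), intensity=intensity, snr=snr))
    pl = PeakList(peaks=peaks, sample_id=sample_id,
                  replicate_id=replicate_id, calibrated=True)
    return pl, truth


def simulate_profile(library: ReferenceLibrary, spec: SimulationSpec,
                     grid_step: float = 5.0) -> ProfileSpectrum:
    """Dense profile: Gaussian peaks (area proportional to the drawn
    intensity) on a constant baseline with white noise, sampled uniformly
    over the acquisition range."""
    peaklist, _ = simulate_peaklist(library, spec)
    # continue the same deterministic stream for the trace noise
    rng = np.random.default_rng((spec.seed, 1))
    lo, hi = ACQUISITION_RANGE
    mz = np.arange(lo, hi + grid_step, grid_step, dtype=float)
    inten = np.full_like(mz, float(spec.baseline_level))
    s = spec.peak_width_sigma
    for p in peaklist.peaks:
        inten += p.intensity * np.exp(-0.5 * ((mz - p.mass) / s) ** 2)
    if spec.noise_sd > 0:
        inten = inten + rng.normal(0.0, spec.noise_sd, size=mz.size)
    return ProfileSpectrum(mz=mz, intensity=np.clip(inten, 0.0, None))


@dataclass
class SimulatedSample:
    sample_id: str
    truth: GroundTruth
    replicates: list[PeakList]


def simulate_cohort(library: ReferenceLibrary,
                    genotypes: Sequence[tuple[str, str, str]],
                    n_samples: int,
                    spec_defaults: SimulationSpec | None = None,
                    seed: int = 0,
                    weights: Sequence[float] | None = None
                    ) -> tuple[list[SimulatedSample], dict]:
    """Draw ``n_samples`` genotypes (optionally weighted) and simulate
    ``n_replicates`` acquisitions each; per-sample seeds derive from the
    master seed, so two runs with the same seed are byte-identical."""
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    defaults = spec_defaults or SimulationSpec(composition=genotypes[0])
    rng = np.random.default_rng(seed)
    p = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        p = w / w.sum()
    picks = rng.choice(len(genotypes), size=n_samples, p=p)
    sample_seeds = rng.integers(0, 2**31 - 1, size=(n_samples,
                                                    defaults.n_replicates))
    samples = []
    for i, g in enumerate(picks):
        composition = tuple(genotypes[g])
        sid = f"sim{i:04d}"
        reps = []
        truth = None
        for r in range(defaults.n_replicates):
            spec = replace(defaults, composition=composition,
                           seed=int(sample_seeds[i, r]))
            pl, truth = simulate_peaklist(library, spec, sample_id=sid,
                                          replicate_id=f"r{r + 1}")
            reps.append(pl)
        samples.append(SimulatedSample(sample_id=sid, truth=truth,
                                       replicates=reps))
    manifest = {
        "seed": seed,
        "n_samples": n_samples,
        "n_replicates": defaults.n_replicates,
        "relative_mass_sd": defaults.relative_mass_sd,
        "alkylated": defaults.alkylated,
        "samples": [
            {
                "sample_id": s.sample_id,
                "composition": list(s.truth.composition),
                "composition_string": s.truth.composition_string,
                "seed": s.truth.seed,
                "subunits": [[k, m] for k, m in s.truth.subunits],
                "replicates": [
                    {"replicate_id": pl.replicate_id,
                     "peaks": [[p.mass, p.intensity] for p in pl.peaks]}
                    for pl in s.replicates
                ],
            }
            for s in samples
        ],
    }
    return samples, manifest


def write_cohort(samples: list[SimulatedSample], manifest: dict,
                 outdir) -> None:
    """Write a simulated cohort as TSV peak lists plus a JSON manifest."""
    from .spectra import write_peaklist

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    for s in samples:
        for pl in s.replicates:
            write_peaklist(pl, outdir / f"{s.sample_id}_{pl.replicate_id}.tsv")


def table_compositions(library: ReferenceLibrary,
                       table: str = "korean") -> list[tuple[str, str, str]]:
    """Genotypes (with 1Bx7 variants spelled out) of one cultivar panel,
    one entry per cultivar — suitable as a frequency-weighted genotype pool."""
    df = library.korean if table == "korean" else library.standards
    out = []
    for _, row in df.iterrows():
        b1 = row["glu_b1"]
        group = row.get("bx7_group")
        if isinstance(group, str) and b1.split("+")[0] == "7":
            tag = {"group1": "7g1", "group2": "7g2", "OE": "7OE"}[group]
            b1 = tag + b1[1:]
        out.append((row["glu_a1"], b1, row["glu_d1"]))
    return out
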