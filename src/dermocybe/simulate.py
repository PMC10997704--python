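"""Synthetic-data generators with known ground truth.

Three generators stand in for the study's raw data so that every downstream
stage is testable without laboratory material or sequence downloads:

* spore measurement sets drawn from a bivariate normal parameterised by the
  published per-species moments (mean, sd of length and width);
* multi-channel HPLC-DAD chromatograms built from a species' encoded pigment
  profile, with Gaussian peaks at the library retention times, channel
  weights, baseline drift and detector noise;
* coupled alignment + pigment-profile data sets in which sequences evolve on
  a fixed star-within-clades topology and profiles are clade templates
  perturbed at a tunable noise rate, so the chemo-phylogenetic congruence
  stage has signal (or, at full noise, provably none) to detect.

All randomness flows from one explicit seed per call; there is no global
random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromatograms import Chromatogram
from .congruence import AlignedSequenceSet
from .morphometrics import SporeMeasurementSet
from .pigments import LEVEL_WEIGHTS, PIGMENT_IDS, PigmentLibrary, SpeciesPigmentProfile

#: Published basidiospore moments (µm): mean/sd of length and width per species.
#: The *C. ominosus* entry uses the higher-precision values from its species
#: description (7.47/4.12); the summary table prints them rounded (7.5/4.1).
TABLE1_SPORE_PARAMS: dict[str, dict[str, float]] = {
    "Cortinarius cinnamomeus": dict(mean_length=6.1, sd_length=0.69, mean_width=4.3, sd_width=0.56),
    "Cortinarius cistoadelphus": dict(mean_length=7.5, sd_length=0.82, mean_width=4.7, sd_width=0.52),
    "Cortinarius croceus": dict(mean_length=8.7, sd_length=0.58, mean_width=5.2, sd_width=0.48),
    "Cortinarius fervidus": dict(mean_length=5.5, sd_length=0.53, mean_width=3.9, sd_width=0.35),
    "Cortinarius hadrocroceus": dict(mean_length=7.8, sd_length=0.55, mean_width=4.6, sd_width=0.33),
    "Cortinarius holoxanthus": dict(mean_length=8.0, sd_length=0.46, mean_width=4.5, sd_width=0.27),
    "Cortinarius huronensis": dict(mean_length=8.7, sd_length=0.48, mean_width=5.1, sd_width=0.36),
    "Cortinarius malicorius": dict(mean_length=6.6, sd_length=0.44, mean_width=3.9, sd_width=0.35),
    "Cortinarius ominosus": dict(mean_length=7.47, sd_length=0.34, mean_width=4.12, sd_width=0.25),
    "Cortinarius pellstonianus": dict(mean_length=8.2, sd_length=0.51, mean_width=5.3, sd_width=0.33),
    "Cortinarius purpureus": dict(mean_length=6.6, sd_length=0.42, mean_width=4.2, sd_width=0.39),
    "Cortinarius rubrophyllus": dict(mean_length=6.0, sd_length=0.39, mean_width=3.9, sd_width=0.35),
    "Cortinarius salignus": dict(mean_length=9.6, sd_length=0.62, mean_width=6.0, sd_width=0.45),
    "Cortinarius sanguineus": dict(mean_length=6.3, sd_length=0.33, mean_width=3.7, sd_width=0.26),
    "Cortinarius sphagnogenus": dict(mean_length=10.0, sd_length=0.97, mean_width=5.9, sd_width=0.59),
    "Cortinarius vitiosus": dict(mean_length=5.8, sd_length=0.35, mean_width=3.5, sd_width=0.21),
}

#: Published per-species mean Q (per-spore length/width ratio) for reference.
TABLE1_Q = {
    "Cortinarius cinnamomeus": 1.42,
    "Cortinarius cistoadelphus": 1.52,
    "Cortinarius croceus": 1.66,
    "Cortinarius fervidus": 1.43,
    "Cortinarius hadrocroceus": 1.69,
    "Cortinarius holoxanthus": 1.78,
    "Cortinarius huronensis": 1.72,
    "Cortinarius malicorius": 1.53,
    "Cortinarius ominosus": 1.82,
    "Cortinarius pellstonianus": 1.55,
    "Cortinarius purpureus": 1.56,
    "Cortinarius rubrophyllus": 1.70,
    "Cortinarius salignus": 1.61,
    "Cortinarius sanguineus": 1.68,
    "Cortinarius sphagnogenus": 1.70,
    "Cortinarius vitiosus": 1.68,
}


@dataclass
class SporeSimParams:
    """Bivariate-normal spore generator parameters (µm)."""

    species_label: str
    mean_length: float
    sd_length: float
    mean_width: float
    sd_width: float
    correlation: float = 0.0
    n: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if self.sd_length < 0 or self.sd_width < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.mean_length <= 0 or self.mean_width <= 0:
            raise ValueError("mean dimensions must be positive")
        if abs(self.correlation) > 1:
            raise ValueError("|correlation| must not exceed 1")

    @classmethod
    def from_table(cls, species: str, n: int = 30, seed: int = 0, correlation: float = 0.0):
        """Parameters for a published species, independent normals by default."""
        p = TABLE1_SPORE_PARAMS[species]
        return cls(species_label=species, n=n, seed=seed, correlation=correlation, **p)


def simulate_spores(params: SporeSimParams) -> SporeMeasurementSet:
    """Draw n (length, width) pairs from the parameterised bivariate normal.

    Non-positive draws (possible only in the extreme tails at realistic
    coefficients of variation) are resampled.  Identical parameters and seed
    give identical measurement sets.
    """
    rng = np.random.default_rng(params.seed)
    cov = np.array(
        [
            [params.sd_length**2, params.correlation * params.sd_length * params.sd_width],
            [params.correlation * params.sd_length * params.sd_width, params.sd_width**2],
        ]
    )
    mean = np.array([params.mean_length, params.mean_width])
    out = np.empty((0, 2))
    need = params.n
    while need > 0:
        # svd method: tolerates the degenerate sd = 0 case
        draw = rng.multivariate_normal(mean, cov, size=need, method="svd")
        good = draw[(draw > 0).all(axis=1)]
        out = np.vstack([out, good])
        need = params.n - len(out)
    return SporeMeasurementSet(
        species=params.species_label, lengths=out[:, 0], widths=out[:, 1]
    )


@dataclass
class ChromSimParams:
    """Chromatogram generator parameters.

    Heights are in relative absorbance units where the tallest peak of a
    non-empty profile is 100.  ``noise_sd`` is per channel per sample;
    ``baseline_drift`` adds a linear ramp (units per minute, split evenly
    across the channels).
    """

    profile: SpeciesPigmentProfile
    noise_sd: float = 0.0
    baseline_drift: float = 0.0
    peak_width_sd: float = 0.05
    time_range: tuple[float, float] = (0.0, 21.0)
    sampling_step: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.peak_width_sd <= 0 or self.sampling_step <= 0:
            raise ValueError("peak width and sampling step must be positive")
        if self.time_range[1] <= self.time_range[0]:
            raise ValueError("empty time range")


def _draw_heights(
    profile: SpeciesPigmentProfile, rng: np.random.Generator
) -> dict[int, float]:
    """Relative peak heights honouring the semi-quantitative encoding.

    Main pigments draw uniformly in [15, 100] with the tallest anchored to
    exactly 100; trace pigments draw uniformly in [6, 9].  The margins away
    from the 5% detection threshold and the 10% trace/main boundary make the
    encoding invertible by the peak caller at low noise.
    """
    mains = sorted(pid for pid, lvl in profile.levels.items() if lvl == "main")
    traces = sorted(pid for pid, lvl in profile.levels.items() if lvl == "trace")
    heights: dict[int, float] = {}
    if mains:
        vals = rng.uniform(15.0, 100.0, size=len(mains))
        vals[np.argmax(vals)] = 100.0
        heights.update(zip(mains, vals))
    for pid in traces:
        heights[pid] = float(rng.uniform(6.0, 9.0))
    return heights


def simulate_chromatogram(
    params: ChromSimParams, library: PigmentLibrary
) -> Chromatogram:
    """Render a species profile as a three-channel chromatogram.

    Each non-absent pigment contributes a Gaussian peak at its library
    retention time, split across the detector channels by its channel
    weights; unknown-peak annotations contribute trace-level peaks with even
    channel weights.  Baseline drift and Gaussian noise are added per channel.
    """
    profile = params.profile
    missing = profile.present - set(library.ids)
    if missing:
        raise ValueError(f"profile references unknown pigment ids {sorted(missing)}")
    t0, t1 = params.time_range
    rts = [library[pid].reference_rt for pid in profile.present]
    rts += list(profile.unknown_peaks)
    if rts and not (t0 <= min(rts) and max(rts) <= t1):
        raise ValueError("time range does not cover all peak retention times")
    rng = np.random.default_rng(params.seed)
    time = np.arange(t0, t1 + params.sampling_step / 2, params.sampling_step)
    channels = np.zeros((3, len(time)))
    heights = _draw_heights(profile, rng)
    for pid, h in heights.items():
        comp = library[pid]
        shape = np.exp(-0.5 * ((time - comp.reference_rt) / params.peak_width_sd) ** 2)
        for c, w in enumerate(comp.channel_weights):
            channels[c] += h * w * shape
    for rt in profile.unknown_peaks:
        h = float(rng.uniform(6.0, 9.0))
        shape = np.exp(-0.5 * ((time - rt) / params.peak_width_sd) ** 2)
        channels += h / 3.0 * shape
    if params.baseline_drift:
        channels += params.baseline_drift * (time - t0) / 3.0
    if params.noise_sd:
        channels += rng.normal(0.0, params.noise_sd, size=channels.shape)
    return Chromatogram(
        time=time,
        absorbance_428=channels[0],
        absorbance_478=channels[1],
        absorbance_519=channels[2],
        sample_label=profile.species,
    )


@dataclass
class EvolSimParams:
    """Coupled sequence + pigment-profile generator parameters.

    ``group_structure`` partitions the taxa into clades (list of lists of
    taxon names); sequences evolve root -> clade ancestor -> taxon with
    ``substitutions_per_site`` expected substitutions per branch, and pigment
    profiles are clade templates whose entries are independently resampled
    with probability ``pigment_noise`` (1 = profiles independent of clades).
    """

    group_structure: list[list[str]]
    alignment_length: int = 600
    substitutions_per_site: float = 0.03
    pigment_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be at least 1")
        if self.substitutions_per_site < 0:
            raise ValueError("substitutions_per_site must be non-negative")
        if not 0 <= self.pigment_noise <= 1:
            raise ValueError("pigment_noise must be in [0, 1]")
        taxa = [t for clade in self.group_structure for t in clade]
        if len(taxa) < 2:
            raise ValueError("need at least two taxa")
        if len(set(taxa)) != len(taxa):
            raise ValueError("clades are not disjoint")

    @property
    def taxa(self) -> list[str]:
        return [t for clade in self.group_structure for t in clade]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)


_BASES = np.array(list("ACGT"))

# weight states for simulated profiles: absent / trace / main band midpoints
_WEIGHT_STATES = np.array([LEVEL_WEIGHTS["absent"], LEVEL_WEIGHTS["trace"], LEVEL_WEIGHTS["main"]])
_STATE_PROBS = np.array([0.5, 0.25, 0.25])


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site uniform substitution: each site changes with probability rate."""
    out = seq.copy()
    hit = rng.random(len(seq)) < rate
    if hit.any():
        # draw a uniformly random *different* base at each hit site
        shift = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 4
    return out


def simulate_coupled_dataset(
    params: EvolSimParams,
) -> tuple[AlignedSequenceSet, pd.DataFrame]:
    """Generate an alignment and a pigment-weight matrix sharing clade structure.

    Returns the aligned sequences and a taxa x 15 pigment abundance table
    (weights on the absent/trace/main scale) suitable for
    :func:`dermocybe.congruence.tanglegram_report`.
    """
    rng = np.random.default_rng(params.seed)
    root = rng.integers(0, 4, size=params.alignment_length)
    names: list[str] = []
    seqs: list[str] = []
    templates: list[np.ndarray] = []
    # distinct clade pigment templates, each with at least one main pigment
    for _ in params.group_structure:
        while True:
            tpl = _WEIGHT_STATES[
                rng.choice(3, size=len(PIGMENT_IDS), p=_STATE_PROBS)
            ]
            if tpl.max() == LEVEL_WEIGHTS["main"] and not any(
                np.array_equal(tpl, t) for t in templates
            ):
                templates.append(tpl)
                break
    rows: list[np.ndarray] = []
    for clade, tpl in zip(params.group_structure, templates):
        ancestor = _mutate(root, params.substitutions_per_site, rng)
        for taxon in clade:
            names.append(taxon)
            seqs.append("".join(_BASES[_mutate(ancestor, params.substitutions_per_site, rng)]))
            while True:
                row = tpl.copy()
                resample = rng.random(len(row)) < params.pigment_noise
                if resample.any():
                    row[resample] = _WEIGHT_STATES[
                        rng.choice(3, size=int(resample.sum()), p=_STATE_PROBS)
                    ]
                if row.sum() > 0:
                    rows.append(row)
                    break
    profiles = pd.DataFrame(
        np.vstack(rows), index=names, columns=[f"p{i}" for i in PIGMENT_IDS]
    )
    return AlignedSequenceSet(names=names, sequences=seqs), profiles
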