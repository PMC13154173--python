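"""Synthetic in-cell 1H NMR spectra with controllable ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: class-specific metabolite concentration fingerprints drawn
log-normally per sample; Lorentzian multiplets whose splitting (in Hz) is
field-invariant so that it shrinks on the ppm axis as the field grows; an
inhomogeneity broadening that is constant *on the ppm scale* across fields
(intact-cell spectra are dominated by susceptibility broadening, which
scales linearly with B0); a broad macromolecular baseline that is present in
excitation-sculpting spectra and strongly attenuated by the CPMG T2 filter;
per-sample global dilution factors; and additive Gaussian noise scaled so
that lower fields have lower signal-to-noise.

Nothing quantum-mechanical is attempted: lines are first-order multiplets
with binomial intensities, which is all the classifiers downstream can see
after 0.04-ppm bucketing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SampleMeta, SpectraSet, Spectrum

DEFAULT_CPMG_ATTENUATION = 0.05  # residual macromolecule weight after the T2 filter
DEFAULT_SNR_BY_FIELD = {400.0: 60.0, 700.0: 120.0, 950.0: 200.0}


@dataclass
class MetabolitePeak:
    """One first-order multiplet: center, relative area, J and natural width."""

    center_ppm: float
    amplitude: float
    j_hz: float = 0.0
    multiplicity: int = 1
    natural_width_hz: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        if self.natural_width_hz < 0:
            raise ValueError("natural_width_hz must be non-negative")


@dataclass
class MetaboliteLibrary:
    metabolites: dict[str, list[MetabolitePeak]]
    macromolecule_humps: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, peaks in self.metabolites.items():
            for pk in peaks:
                if not -0.5 <= pk.center_ppm <= 9.5:
                    raise ValueError(f"{name}: peak center {pk.center_ppm} outside [-0.5, 9.5]")

    @property
    def names(self) -> list[str]:
        return list(self.metabolites)


@dataclass
class ClassProfile:
    """Log-normal concentration fingerprint of one cell phenotype."""

    class_name: str
    log_mean_concentrations: dict[str, float]
    log_sd_concentrations: dict[str, float] | float = 0.2
    macro_level: float = 1.0

    def log_sd(self, name: str) -> float:
        if isinstance(self.log_sd_concentrations, dict):
            sd = self.log_sd_concentrations.get(name, 0.0)
        else:
            sd = float(self.log_sd_concentrations)
        if sd < 0:
            raise ValueError("log-sd must be non-negative")
        return sd


@dataclass
class AcquisitionParams:
    field_mhz: float = 950.0
    experiment: str = "cpmg"
    inhom_width_ppm: float = 0.02
    snr: float = 200.0
    n_points: int = 4096
    ppm_range: tuple[float, float] = (-0.5, 9.4)
    cpmg_attenuation: float = DEFAULT_CPMG_ATTENUATION

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.n_points < 256:
            raise ValueError("n_points must be >= 256")

    def grid(self) -> np.ndarray:
        """Descending ppm grid."""
        low, high = self.ppm_range
        return np.linspace(high, low, self.n_points)


@dataclass
class DatasetDesign:
    classes: list[ClassProfile]
    n_per_class: int = 30
    fields_mhz: Sequence[float] = (950.0,)
    experiments: Sequence[str] = ("cpmg",)
    dilution_log_sd: float = 0.3
    mixtures: list[tuple[str, str, tuple[float, float], int]] = field(default_factory=list)
    seed: int = 0
    snr_by_field: dict[float, float] = field(default_factory=lambda: dict(DEFAULT_SNR_BY_FIELD))
    inhom_width_ppm: float = 0.02
    n_points: int = 4096
    ppm_range: tuple[float, float] = (-0.5, 9.4)
    noise_free: bool = False
    library: "MetaboliteLibrary | None" = None

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("design needs at least one class")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        for _, _, (lo, hi), _ in self.mixtures:
            if not (0 < lo <= hi < 1):
                raise ValueError("mixture fractions must lie strictly inside (0, 1)")

    def acquisition(self, field_mhz: float, experiment: str) -> AcquisitionParams:
        snr = math.inf if self.noise_free else self.snr_by_field.get(float(field_mhz), 100.0)
        return AcquisitionParams(field_mhz=field_mhz, experiment=experiment,
                                 inhom_width_ppm=self.inhom_width_ppm, snr=snr,
                                 n_points=self.n_points, ppm_range=self.ppm_range)


def default_library() -> MetaboliteLibrary:
    """A fixed small-metabolite library for intact-cell spectra.

    Chemical shifts and couplings are textbook values for the abundant
    intracellular metabolites; the crowded 3.2-4.0 ppm sugar/amine region is
    populated so that bucketed spectra show realistic overlap.  Fatty-acid
    envelopes carry a large natural width; three-plus broad macromolecular
    humps model the mobile-protein/lipid baseline.
    """
    P = MetabolitePeak
    metabolites = {
        "lactate": [P(1.33, 3.0, j_hz=7.0, multiplicity=2, natural_width_hz=1.5),
                    P(4.11, 1.0, j_hz=7.0, multiplicity=4, natural_width_hz=1.5)],
        "alanine": [P(1.48, 3.0, j_hz=7.2, multiplicity=2, natural_width_hz=1.5)],
        "acetate": [P(1.95, 3.0, natural_width_hz=1.2)],
        "creatine": [P(3.03, 3.0, natural_width_hz=1.5), P(3.93, 2.0, natural_width_hz=1.5)],
        "choline": [P(3.19, 9.0, natural_width_hz=1.5)],
        "phosphocholine": [P(3.21, 9.0, natural_width_hz=1.5)],
        "glutathione": [P(8.30, 1.0, natural_width_hz=3.0),
                        P(2.54, 2.0, j_hz=7.0, multiplicity=3, natural_width_hz=2.0)],
        "glutamate": [P(2.35, 2.0, j_hz=7.0, multiplicity=3, natural_width_hz=2.0),
                      P(3.75, 1.0, natural_width_hz=2.0)],
        "glycine": [P(3.55, 2.0, natural_width_hz=1.5)],
        "taurine": [P(3.26, 2.0, j_hz=6.6, multiplicity=3, natural_width_hz=1.5),
                    P(3.42, 2.0, j_hz=6.6, multiplicity=3, natural_width_hz=1.5)],
        "myo_inositol": [P(3.27, 1.0, natural_width_hz=1.5),
                         P(3.52, 2.0, j_hz=9.9, multiplicity=2, natural_width_hz=1.5),
                         P(3.61, 2.0, j_hz=9.9, multiplicity=2, natural_width_hz=1.5),
                         P(4.06, 1.0, natural_width_hz=1.5)],
        "glucose": [P(3.40, 1.0, natural_width_hz=1.5), P(3.48, 1.0, natural_width_hz=1.5),
                    P(3.72, 1.5, natural_width_hz=1.5), P(3.84, 1.0, natural_width_hz=1.5),
                    P(5.23, 0.4, j_hz=3.7, multiplicity=2, natural_width_hz=1.5)],
        "fatty_acids": [P(0.90, 6.0, natural_width_hz=6.0),
                        P(1.30, 10.0, natural_width_hz=8.0),
                        P(2.02, 3.0, natural_width_hz=6.0)],
        "ump_reference": [P(6.01, 1.0, natural_width_hz=2.0)],
        "atp_adenine": [P(8.52, 0.6, natural_width_hz=2.5), P(8.24, 0.6, natural_width_hz=2.5)],
    }
    humps = [(0.92, 0.25, 1.0), (1.32, 0.30, 1.2), (2.05, 0.35, 0.8),
             (3.25, 0.50, 0.6), (7.80, 0.70, 0.3)]
    return MetaboliteLibrary(metabolites, humps)


def _lorentzian(x: np.ndarray, center: float, hwhm: float) -> np.ndarray:
    """Unit-area Lorentzian; peak height 1/(pi*hwhm)."""
    return (hwhm / math.pi) / ((x - center) ** 2 + hwhm ** 2)


def clean_signal(concentrations: dict[str, float], acq: AcquisitionParams,
                 lib: MetaboliteLibrary, macro_level: float = 0.0) -> np.ndarray:
    """Noise-free, dilution-free intensity trace on the descending grid."""
    x = acq.grid()
    y = np.zeros_like(x)
    for name, conc in concentrations.items():
        if conc == 0.0:
            continue
        for pk in lib.metabolites[name]:
            gamma = acq.inhom_width_ppm + pk.natural_width_hz / acq.field_mhz
            m = pk.multiplicity
            weights = np.array([math.comb(m - 1, k) for k in range(m)], dtype=float)
            weights /= weights.sum()
            j_ppm = pk.j_hz / acq.field_mhz
            offsets = (np.arange(m) - (m - 1) / 2.0) * j_ppm
            for w, off in zip(weights, offsets):
                y += conc * pk.amplitude * w * _lorentzian(x, pk.center_ppm + off, gamma)
    if macro_level > 0:
        macro_weight = macro_level
        if acq.experiment == "cpmg":
            macro_weight *= acq.cpmg_attenuation
        for center, width_ppm, area in lib.macromolecule_humps:
            y += macro_weight * area * _lorentzian(x, center, width_ppm)
    return y


def draw_concentrations(profile: ClassProfile, lib: MetaboliteLibrary,
                        rng: np.random.Generator) -> dict[str, float]:
    conc = {}
    for name in lib.names:
        mu = profile.log_mean_concentrations.get(name)
        if mu is None or mu == -math.inf:
            conc[name] = 0.0
            continue
        sd = profile.log_sd(name)
        conc[name] = math.exp(mu + (sd * rng.standard_normal() if sd > 0 else 0.0))
    return conc


def render_spectrum(profile: ClassProfile, acq: AcquisitionParams,
                    lib: MetaboliteLibrary, rng: np.random.Generator,
                    sample_id: str = "sample",
                    concentrations: dict[str, float] | None = None,
                    dilution: float | None = None,
                    dilution_log_sd: float = 0.3) -> tuple[Spectrum, dict]:
    """Render one spectrum and return it with its latent truth record.

    Concentrations and the global dilution factor are drawn log-normally
    unless supplied (supplying them lets one biological sample be re-rendered
    at several fields or experiments with fresh noise).
    """
    if concentrations is None:
        concentrations = draw_concentrations(profile, lib, rng)
    if dilution is None:
        dilution = math.exp(dilution_log_sd * rng.standard_normal())
    clean = clean_signal(concentrations, acq, lib, macro_level=profile.macro_level)
    peak = float(np.max(np.abs(clean))) if clean.size else 0.0
    noise_sd = 0.0 if (not np.isfinite(acq.snr) or peak == 0.0) else peak / acq.snr
    y = dilution * clean
    if noise_sd > 0:
        y = y + rng.normal(0.0, dilution * noise_sd, size=y.shape)
    truth = {"sample_id": sample_id, "class_label": profile.class_name,
             "field_mhz": acq.field_mhz, "experiment": acq.experiment,
             "dilution": dilution, "noise_sd": dilution * noise_sd,
             "concentrations": dict(concentrations)}
    return Spectrum(acq.grid(), y, sample_id), truth


def mix_spectra(a: Spectrum, b: Spectrum, fraction: float) -> Spectrum:
    """Convex combination fraction*a + (1-fraction)*b on a shared grid."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    if a.ppm.shape != b.ppm.shape or not np.array_equal(a.ppm, b.ppm):
        raise ValueError("spectra are not on the same ppm grid")
    pair = sorted((a.sample_id, b.sample_id))
    return Spectrum(a.ppm.copy(), fraction * a.intensities + (1 - fraction) * b.intensities,
                    f"{pair[0]}+{pair[1]}")


def simulate_dataset(design: DatasetDesign,
                     lib: MetaboliteLibrary | None = None) -> tuple[SpectraSet, pd.DataFrame]:
    """Simulate pure-class samples (and optional two-class mixtures).

    Each biological replicate draws its latent concentrations and dilution
    once and is then rendered at every requested field and experiment with
    independent noise, mirroring one physical sample measured on several
    spectrometers.  Deterministic given ``design.seed``.
    """
    if lib is None:
        lib = design.library if design.library is not None else default_library()
    profiles = {p.class_name: p for p in design.classes}
    root = np.random.SeedSequence(design.seed)
    latent_ss, noise_ss = root.spawn(2)

    spectra: list[Spectrum] = []
    metas: list[SampleMeta] = []
    truth_rows: list[dict] = []

    def noise_rng() -> np.random.Generator:
        # spawn() advances the sequence, so every call yields a fresh stream
        return np.random.Generator(np.random.Philox(noise_ss.spawn(1)[0]))

    latent_children = latent_ss.spawn(len(design.classes))
    for profile, child in zip(design.classes, latent_children):
        lat_rng = np.random.Generator(np.random.Philox(child))
        for r in range(design.n_per_class):
            conc = draw_concentrations(profile, lib, lat_rng)
            dil = math.exp(design.dilution_log_sd * lat_rng.standard_normal())
            for exp in design.experiments:
                for fmhz in design.fields_mhz:
                    acq = design.acquisition(fmhz, exp)
                    sid = f"{profile.class_name}_r{r:02d}_{exp}_{int(fmhz)}MHz"
                    spec, truth = render_spectrum(profile, acq, lib, noise_rng(), sid,
                                                  concentrations=conc, dilution=dil)
                    spectra.append(spec)
                    metas.append(SampleMeta(sid, profile.class_name, fmhz, exp))
                    truth_rows.append(_flatten_truth(truth, lib))

    mix_children = latent_ss.spawn(len(design.mixtures) or 1)
    for (name_a, name_b, frac_range, n_mix), child in zip(design.mixtures, mix_children):
        if name_a not in profiles or name_b not in profiles:
            raise ValueError(f"mixture references unknown class {name_a!r}/{name_b!r}")
        first, second = sorted((name_a, name_b))
        lat_rng = np.random.Generator(np.random.Philox(child))
        for i in range(n_mix):
            frac = float(lat_rng.uniform(*frac_range))  # fraction of the first (sorted) class
            conc_a = draw_concentrations(profiles[first], lib, lat_rng)
            conc_b = draw_concentrations(profiles[second], lib, lat_rng)
            dil = math.exp(design.dilution_log_sd * lat_rng.standard_normal())
            for exp in design.experiments:
                for fmhz in design.fields_mhz:
                    acq = design.acquisition(fmhz, exp)
                    clean = (frac * clean_signal(conc_a, acq, lib, profiles[first].macro_level)
                             + (1 - frac) * clean_signal(conc_b, acq, lib,
                                                         profiles[second].macro_level))
                    peak = float(np.max(np.abs(clean)))
                    noise_sd = 0.0 if not np.isfinite(acq.snr) else peak / acq.snr
                    y = dil * clean
                    if noise_sd > 0:
                        y = y + noise_rng().normal(0.0, dil * noise_sd, size=y.shape)
                    sid = f"{first}+{second}_m{i:02d}_{exp}_{int(fmhz)}MHz"
                    spectra.append(Spectrum(acq.grid(), y, sid))
                    metas.append(SampleMeta(sid, (first, second), fmhz, exp,
                                            mixture_fraction=frac))
                    truth_rows.append({
                        "sample_id": sid, "class_label": f"{first}+{second}",
                        "field_mhz": fmhz, "experiment": exp, "dilution": dil,
                        "noise_sd": dil * noise_sd, "mixture_fraction": frac,
                        **{f"conc_a_{k}": v for k, v in conc_a.items()},
                        **{f"conc_b_{k}": v for k, v in conc_b.items()},
                    })

    truth = pd.DataFrame(truth_rows)
    return SpectraSet(spectra, metas), truth


def _flatten_truth(truth: dict, lib: MetaboliteLibrary) -> dict:
    row = {k: v for k, v in truth.items() if k != "concentrations"}
    row.update({f"conc_{k}": v for k, v in truth["concentrations"].items()})
    return row


# ---------------------------------------------------------------------------
# Benchmark designs: the fixed study conditions used by tests and examples.
# ---------------------------------------------------------------------------

_BASE_LOG_MEANS = {
    "lactate": 0.4, "alanine": -0.3, "acetate": -0.5, "creatine": 0.1,
    "choline": 0.3, "phosphocholine": 0.0, "glutathione": -0.2, "glutamate": 0.2,
    "glycine": -0.1, "taurine": 0.2, "myo_inositol": 0.0, "glucose": 0.1,
    "fatty_acids": 0.5, "ump_reference": -0.7, "atp_adenine": -0.8,
}

# Marker panels: each phenotype up-/down-regulates a distinct metabolite set,
# giving separated but overlapping fingerprints (the reference singlet is
# never a marker).
_MARKER_PANELS = {
    "neuron": {"lactate": 0.9, "creatine": 0.7, "glutamate": 0.8, "fatty_acids": -0.5},
    "astrocyte": {"myo_inositol": 0.9, "glycine": 0.7, "glutathione": 0.6, "lactate": -0.5},
    "npc": {"choline": 0.8, "phosphocholine": 0.8, "taurine": 0.6, "acetate": -0.5},
    "apc": {"fatty_acids": 0.8, "acetate": 0.8, "alanine": 0.6, "choline": -0.5},
    "epithelial": {"glucose": 0.9, "alanine": 0.7, "glutamate": -0.5, "taurine": 0.5},
    "lymphocyte": {"glutathione": 0.8, "taurine": -0.5, "creatine": -0.6, "glycine": 0.6},
}


def default_profiles(class_names: Sequence[str], separation: float = 1.0,
                     log_sd: float | dict[str, float] = 0.2,
                     macro_level: float = 1.0) -> list[ClassProfile]:
    """Deterministic class fingerprints built from fixed marker panels.

    ``separation`` scales the marker log-mean shifts; ``log_sd`` may be a
    scalar shared by all classes or a per-class mapping.
    """
    panels = list(_MARKER_PANELS.items())
    profiles = []
    for k, name in enumerate(class_names):
        panel = _MARKER_PANELS.get(name, panels[k % len(panels)][1])
        log_means = dict(_BASE_LOG_MEANS)
        for met, shift in panel.items():
            log_means[met] = log_means[met] + separation * shift
        sd = log_sd[name] if isinstance(log_sd, dict) else log_sd
        profiles.append(ClassProfile(name, log_means, sd, macro_level=macro_level))
    return profiles


FOUR_CLASSES = ("neuron", "astrocyte", "npc", "apc")
THREE_CLASSES = ("epithelial", "lymphocyte", "neuron")


def four_class_design(seed: int, n_per_class: int = 30,
                      experiments: Sequence[str] = ("cpmg",)) -> DatasetDesign:
    """4 phenotypes x n_per_class at 950 MHz: the main classification benchmark."""
    return DatasetDesign(classes=default_profiles(FOUR_CLASSES),
                         n_per_class=n_per_class, fields_mhz=(950.0,),
                         experiments=experiments, seed=seed)


def mixture_design(seed: int, n_per_class: int = 30, n_per_pair: int = 10,
                   high_var_class: str = "epithelial") -> DatasetDesign:
    """3 pure classes plus all three pairwise mixtures.

    One class carries roughly double intra-class variability: its inflated
    probability region is what defeats top-2 assignment from a latent-space
    SVM while leaving forest vote fractions usable.
    """
    log_sd = {name: (0.45 if name == high_var_class else 0.2) for name in THREE_CLASSES}
    classes = default_profiles(THREE_CLASSES, log_sd=log_sd)
    pairs = [("epithelial", "lymphocyte"), ("epithelial", "neuron"), ("lymphocyte", "neuron")]
    mixtures = [(a, b, (0.2, 0.8), n_per_pair) for a, b in pairs]
    return DatasetDesign(classes=classes, n_per_class=n_per_class,
                         fields_mhz=(950.0,), mixtures=mixtures, seed=seed)


def cross_field_design(seed: int, n_per_class: int = 20,
                       noise_free: bool = False) -> DatasetDesign:
    """3 classes, every replicate rendered at 400/700/950 MHz."""
    library = None
    if noise_free:
        # inhomogeneity-dominated limit: no Hz-scale structure at all
        lib = default_library()
        clean = {name: [replace(p, j_hz=0.0, natural_width_hz=0.0) for p in peaks]
                 for name, peaks in lib.metabolites.items()}
        library = MetaboliteLibrary(clean, lib.macromolecule_humps)
    return DatasetDesign(classes=default_profiles(THREE_CLASSES),
                         n_per_class=n_per_class,
                         fields_mhz=(400.0, 700.0, 950.0), seed=seed,
                         noise_free=noise_free, library=library)
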