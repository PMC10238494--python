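"""Synthetic data generators for every pipeline input.

Emulates (a) a blood-like proteome, (b) MRM chromatograms — Gaussian
elution peaks over Gaussian baseline noise inside a short LC window,
(c) case/control serum cohorts with planted fold changes and technical
replicates, and (d) calibration and precision series with controlled
multiplicative error. Every generator is deterministic for a fixed seed
and carries its ground truth, so downstream estimators can be validated
against planted values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .candidates import ProteinRecord
from .errors import ConfigurationError

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative log-normal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


@dataclass(frozen=True)
class SyntheticProteomeSpec:
    """Stand-in for a curated blood-protein list.

    Defaults give protein lengths typical of secreted proteins and a
    uniform amino-acid composition (none is dictated by the domain).
    """

    n_proteins: int = 100
    length_range: tuple[int, int] = (80, 600)
    aa_frequencies: dict[str, float] | None = None  # None = uniform
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 0:
            raise ConfigurationError("n_proteins must be >= 0")
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise ConfigurationError("length_range must satisfy 1 <= min <= max")
        if self.aa_frequencies is not None:
            freqs = np.array(
                [self.aa_frequencies.get(a, 0.0) for a in AMINO_ACIDS]
            )
            if (freqs < 0).any():
                raise ConfigurationError("aa_frequencies must be nonnegative")
            if abs(freqs.sum() - 1.0) > 1e-9:
                raise ConfigurationError("aa_frequencies must sum to 1")


def generate_proteome(spec: SyntheticProteomeSpec) -> list[ProteinRecord]:
    """Draw random protein sequences from the spec's residue frequencies."""
    rng = np.random.default_rng(spec.seed)
    if spec.aa_frequencies is None:
        probs = np.full(20, 1 / 20)
    else:
        probs = np.array([spec.aa_frequencies.get(a, 0.0) for a in AMINO_ACIDS])
    records = []
    for i in range(spec.n_proteins):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        seq = "".join(rng.choice(AMINO_ACIDS, size=length, p=probs))
        records.append(ProteinRecord(protein_id=f"PROT{i:05d}", sequence=seq))
    return records


@dataclass(frozen=True)
class ChromatogramSimSpec:
    """One peptide's simulated MRM trace set.

    Three product-ion traces, each ratio_i * peak_height * Gaussian(rt,
    sigma) plus N(0, noise_sd) baseline noise, sampled over a
    ``run_minutes`` LC window. Defaults: 10-minute run at 2 Hz with a
    3-second-wide peak, typical for a short-gradient microflow MRM assay.
    """

    run_minutes: float = 10.0
    sampling_hz: float = 2.0
    peak_rt: float = 5.0
    peak_width_sigma: float = 0.05
    peak_height: float = 1000.0
    noise_sd: float = 10.0
    transition_ratios: tuple[float, float, float] = (0.5, 0.3, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_hz <= 0:
            raise ConfigurationError("sampling_hz must be > 0")
        if not (0 <= self.peak_rt <= self.run_minutes):
            raise ConfigurationError("peak_rt must lie within the run window")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        r = np.asarray(self.transition_ratios, dtype=float)
        if r.shape != (3,) or (r < 0).any() or abs(r.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                "transition_ratios must be 3 nonnegative values summing to 1"
            )

    @property
    def true_best_snr(self) -> float:
        """Planted best-transition SNR: height*max(ratio)/noise_sd."""
        if self.noise_sd == 0:
            return float("inf")
        return self.peak_height * max(self.transition_ratios) / self.noise_sd


@dataclass
class Chromatogram:
    """Per-transition time series for one peptide within one LC run."""

    peptide_id: str
    transitions: list[str]
    time_min: np.ndarray
    intensities: np.ndarray  # shape (n_transitions, n_points)
    run_minutes: float = 10.0


def simulate_chromatogram(
    spec: ChromatogramSimSpec, peptide_id: str = "pep"
) -> Chromatogram:
    """Simulate the top-3 product-ion traces for one peptide."""
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / (60.0 * spec.sampling_hz)
    t = np.arange(0.0, spec.run_minutes + dt / 2, dt)
    shape = np.exp(-((t - spec.peak_rt) ** 2) / (2 * spec.peak_width_sigma**2))
    traces = []
    for ratio in spec.transition_ratios:
        noise = rng.normal(0.0, spec.noise_sd, size=t.size) if spec.noise_sd else 0.0
        traces.append(ratio * spec.peak_height * shape + noise)
    return Chromatogram(
        peptide_id=peptide_id,
        transitions=[f"{peptide_id}_y{i}" for i in (1, 2, 3)],
        time_min=t,
        intensities=np.vstack(traces),
        run_minutes=spec.run_minutes,
    )


@dataclass(frozen=True)
class CohortSimSpec:
    """Case/control cohort with planted differential peptides.

    Base abundances are log10-uniform in [3, 8] (the intensity dynamic
    range typical of neat-blood MRM). Differential peptides are
    multiplied by ``planted_fc`` in cases. Each biological sample gets
    ``n_tech_reps`` technical replicates sharing one biological draw and
    differing by ``cv_technical``.
    """

    n_cases: int = 50
    n_controls: int = 50
    n_peptides: int = 200
    n_differential: int = 20
    planted_fc: float = 1.5
    cv_biological: float = 0.2
    cv_technical: float = 0.2
    n_tech_reps: int = 2
    log10_abundance_range: tuple[float, float] = (3.0, 8.0)
    differential_ids: tuple[str, ...] | None = None  # overrides random choice
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_differential > self.n_peptides:
            raise ConfigurationError("n_differential must be <= n_peptides")
        if self.planted_fc <= 0:
            raise ConfigurationError("planted_fc must be > 0")
        if self.cv_biological < 0 or self.cv_technical < 0:
            raise ConfigurationError("CVs must be >= 0")
        if self.n_tech_reps < 1:
            raise ConfigurationError("n_tech_reps must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth accompanying a generated dataset."""

    differential_peptide_ids: frozenset[str]
    true_fc: dict[str, float]
    quantifiable_flags: dict[str, bool] = field(default_factory=dict)
    true_snr: dict[str, float] = field(default_factory=dict)


@dataclass
class QuantMatrix:
    """Samples x peptides abundance table with sample metadata.

    ``values``: DataFrame indexed by sample_id, one column per peptide.
    ``sample_meta``: DataFrame indexed by sample_id with columns
    ``group`` (case/control), ``replicate_of`` (biological parent id)
    and ``batch``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.sample_meta.index):
            raise ConfigurationError("values and sample_meta indices differ")

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)


def generate_cohort(spec: CohortSimSpec) -> tuple[QuantMatrix, GroundTruth]:
    """Generate a cohort quantification matrix plus its ground truth.

    With all CVs zero the empirical case/control mean ratio of every
    differential peptide equals ``planted_fc`` exactly. A planted_fc of
    1 means no true effects: the differential set is empty.
    """
    rng = np.random.default_rng(spec.seed)
    peptide_ids = [f"pep{i:04d}" for i in range(spec.n_peptides)]
    lo, hi = spec.log10_abundance_range
    base = 10.0 ** rng.uniform(lo, hi, size=spec.n_peptides)

    if spec.differential_ids is not None:
        unknown = set(spec.differential_ids) - set(peptide_ids)
        if unknown:
            raise ConfigurationError(
                f"differential_ids not in peptide panel: {sorted(unknown)}"
            )
        diff_idx = np.array(
            [peptide_ids.index(p) for p in spec.differential_ids], dtype=int
        )
    else:
        diff_idx = rng.choice(
            spec.n_peptides, size=spec.n_differential, replace=False
        )
    fc = np.ones(spec.n_peptides)
    fc[diff_idx] = spec.planted_fc
    if spec.planted_fc == 1.0:
        differential = frozenset()
    else:
        differential = frozenset(peptide_ids[i] for i in sorted(diff_idx))

    groups = ["case"] * spec.n_cases + ["control"] * spec.n_controls
    bio_ids = [f"S{i:04d}" for i in range(len(groups))]

    rows, meta = [], []
    for b, (bio, grp) in enumerate(zip(bio_ids, groups)):
        bio_noise = _lognormal_factors(rng, spec.cv_biological, spec.n_peptides)
        bio_value = base * bio_noise * (fc if grp == "case" else 1.0)
        for r in range(spec.n_tech_reps):
            tech = _lognormal_factors(rng, spec.cv_technical, spec.n_peptides)
            rows.append(bio_value * tech)
            meta.append(
                {
                    "sample_id": f"{bio}_r{r + 1}",
                    "group": grp,
                    "replicate_of": bio,
                    "batch": 1,
                }
            )
    meta_df = pd.DataFrame(meta).set_index("sample_id")
    values = pd.DataFrame(rows, index=meta_df.index, columns=peptide_ids)
    truth = GroundTruth(
        differential_peptide_ids=differential,
        true_fc={pid: float(f) for pid, f in zip(peptide_ids, fc)},
    )
    return QuantMatrix(values=values, sample_meta=meta_df), truth


def generate_calibration_series(
    n_points: int = 6,
    slope: float = 1.0,
    intercept: float = 0.0,
    error_cv: float = 0.0,
    seed: int = 0,
    concentrations: np.ndarray | None = None,
) -> pd.DataFrame:
    """Calibration table of (nominal_conc, measured_response).

    Concentrations default to a two-fold dilution series starting at 1.
    Responses are slope*conc + intercept perturbed by mean-1
    multiplicative log-normal error of coefficient of variation
    ``error_cv``.
    """
    if n_points < 2:
        raise ConfigurationError("n_points must be >= 2")
    if concentrations is None:
        conc = 2.0 ** np.arange(n_points)
    else:
        conc = np.asarray(concentrations, dtype=float)
        if conc.size != n_points:
            raise ConfigurationError("concentrations length must equal n_points")
    if (conc <= 0).any():
        raise ConfigurationError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    response = (slope * conc + intercept) * _lognormal_factors(
        rng, error_cv, conc.size
    )
    return pd.DataFrame({"nominal_conc": conc, "measured_response": response})


def generate_precision_series(
    true_value: float = 100.0,
    n_replicates: int = 5,
    n_days: int = 3,
    cv_within_day: float = 0.05,
    cv_between_day: float = 0.05,
    seed: int = 0,
) -> dict[int, np.ndarray]:
    """Replicate measurements per day for intra/inter-day precision.

    Returns {day: array of n_replicates values}; each day's mean drifts
    by ``cv_between_day`` and replicates scatter by ``cv_within_day``.
    """
    if n_replicates < 2 or n_days < 1:
        raise ConfigurationError("need >= 2 replicates and >= 1 day")
    rng = np.random.default_rng(seed)
    out = {}
    for day in range(n_days):
        day_mean = true_value * _lognormal_factors(rng, cv_between_day, 1)[0]
        out[day] = day_mean * _lognormal_factors(rng, cv_within_day, n_replicates)
    return out
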