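"""File formats and pipeline configuration.

FASTA proteomes (Bio.SeqIO), Skyline-style transition-list CSVs,
long-format chromatogram CSVs, TSV quantification matrices with a
companion sample-metadata table, and a strict YAML pipeline config
(unknown keys rejected, resolved config written next to outputs).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .candidates import ProteinRecord, SelectionConfig, TransitionSet
from .classify import EvalConfig
from .discovery import DiscoveryConfig
from .errors import ConfigurationError, InputError
from .qc import QcConfig
from .screening import ScreeningConfig
from .synthetic import QuantMatrix

TRANSITION_COLUMNS = [
    "protein_id", "peptide", "precursor_mz", "precursor_charge",
    "fragment_ion", "product_mz", "label_state", "heavy_shift",
    "collision_energy",
]


def read_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA; sequences uppercased, duplicate ids rejected."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise InputError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            ProteinRecord(protein_id=rec.id, sequence=str(rec.seq).upper())
        )
    if not records and path.stat().st_size > 0:
        raise InputError(f"no FASTA records parsed from {path}")
    return records


def write_fasta(records: list[ProteinRecord], path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description="")
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def write_transition_list(
    transition_sets: list[tuple[str, TransitionSet]], path
) -> None:
    """Write (protein_id, TransitionSet) pairs as a Skyline-style CSV.

    One row per product ion; m/z values fixed to 6 decimal places so the
    write -> read -> write round trip is byte-identical. The collision
    energy column is carried as opaque metadata (empty here).
    """
    rows = []
    for protein_id, ts in transition_sets:
        for ion_type, idx, z, mz in ts.product_ions:
            rows.append(
                {
                    "protein_id": protein_id,
                    "peptide": ts.sequence,
                    "precursor_mz": f"{ts.precursor_mz:.6f}",
                    "precursor_charge": ts.precursor_charge,
                    "fragment_ion": f"{ion_type}{idx}",
                    "product_mz": f"{mz:.6f}",
                    "label_state": ts.label_state,
                    "heavy_shift": f"{ts.heavy_shift:.6f}",
                    "collision_energy": "",
                }
            )
    pd.DataFrame(rows, columns=TRANSITION_COLUMNS).to_csv(path, index=False)


def read_transition_list(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(TRANSITION_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"transition list missing columns {sorted(missing)}")
    return df


def write_chromatograms_csv(chromatograms, path) -> None:
    """Long-format chromatogram CSV: peptide_id, transition_id, time_min, intensity."""
    frames = []
    for chrom in chromatograms:
        for i, tid in enumerate(chrom.transitions):
            frames.append(
                pd.DataFrame(
                    {
                        "peptide_id": chrom.peptide_id,
                        "transition_id": tid,
                        "time_min": chrom.time_min,
                        "intensity": chrom.intensities[i],
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6g")


def write_quant_matrix(matrix: QuantMatrix, values_path, meta_path) -> None:
    """TSV quantification matrix plus companion sample-metadata TSV."""
    out = matrix.values.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(values_path, sep="\t", index=False, float_format="%.6g")
    meta = matrix.sample_meta.copy()
    meta.insert(0, "sample_id", meta.index)
    meta.to_csv(meta_path, sep="\t", index=False)


def read_quant_matrix(values_path, meta_path) -> QuantMatrix:
    values = pd.read_csv(values_path, sep="\t").set_index("sample_id")
    meta = pd.read_csv(meta_path, sep="\t").set_index("sample_id")
    required = {"group", "replicate_of"}
    if not required <= set(meta.columns):
        raise InputError(f"sample metadata needs columns {sorted(required)}")
    return QuantMatrix(values=values, sample_meta=meta.loc[values.index])


@dataclass(frozen=True)
class ScreeningMixture:
    """Composition of the multi-cancer screening sample mixture.

    Default composition: 40 breast, 20 pancreatic, 20 thyroid,
    20 ovarian, 18 lung and 20 colorectal cancer samples (138 cancer
    samples in total) plus 30 healthy donors.
    """

    cancer_counts: dict[str, int] = field(
        default_factory=lambda: {
            "breast": 40, "pancreatic": 20, "thyroid": 20,
            "ovarian": 20, "lung": 18, "colorectal": 20,
        }
    )
    n_healthy: int = 30

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.cancer_counts.values()) or self.n_healthy < 0:
            raise ConfigurationError("sample counts must be nonnegative")

    @property
    def n_cancer(self) -> int:
        return sum(self.cancer_counts.values())

    @property
    def n_total(self) -> int:
        return self.n_cancer + self.n_healthy


@dataclass(frozen=True)
class CohortDesign:
    """Sizes of the two-stage discovery/validation cohorts."""

    discovery_cases: int = 50
    discovery_controls: int = 50
    validation_cases: int = 96
    validation_controls: int = 95

    def __post_init__(self) -> None:
        for v in dataclasses.astuple(self):
            if v < 3:
                raise ConfigurationError("cohort arms need >= 3 samples")


@dataclass
class PipelineConfig:
    """All stage configurations plus simulation sizes and the global seed."""

    seed: int = 0
    n_proteins: int = 120
    n_cohort_peptides: int = 150
    n_differential: int = 15
    planted_fc: float = 1.5
    cv_biological: float = 0.2
    cv_technical: float = 0.1
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)
    qc: QcConfig = field(default_factory=QcConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    cohorts: CohortDesign = field(default_factory=CohortDesign)
    mixture: ScreeningMixture = field(default_factory=ScreeningMixture)


_SECTION_TYPES = {
    "selection": SelectionConfig,
    "screening": ScreeningConfig,
    "discovery": DiscoveryConfig,
    "qc": QcConfig,
    "evaluation": EvalConfig,
    "cohorts": CohortDesign,
    "mixture": ScreeningMixture,
}


def _build_section(cls, data: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigurationError(
            f"{cls.__name__}: unknown config keys {sorted(unknown)}"
        )
    coerced = dict(data)
    for f in dataclasses.fields(cls):
        if f.name in coerced and isinstance(coerced[f.name], list):
            coerced[f.name] = tuple(coerced[f.name])
    return cls(**coerced)


def load_config(path) -> PipelineConfig:
    """Load and validate a pipeline YAML config; unknown keys are errors."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError("config root must be a mapping")
    top_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - top_fields
    if unknown:
        raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ConfigurationError(f"section {key!r} must be a mapping")
            kwargs[key] = _build_section(_SECTION_TYPES[key], value)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def dump_config(cfg: PipelineConfig, path) -> None:
    """Write the fully resolved configuration next to the run outputs."""

    def _clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: _clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (set, frozenset)):
            return sorted(obj)
        if isinstance(obj, tuple):
            return list(obj)
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(_clean(cfg), fh, sort_keys=True)
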