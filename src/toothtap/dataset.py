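"""Seeded generation and loading of the labeled synthetic percussion dataset.

Each sample is an independent synthetic tooth: a fresh perturbation of the
healthy baseline, a class-conditional lesion draw, one transient simulation,
per-sample normalization and noise, and (optionally) a WAV file on disk.
Per-sample random streams are derived from ``(master_seed, sample_index)``
via ``numpy.random.SeedSequence``, so generation is reproducible, order
independent and shares no stream state across samples.

On-disk layout (when an output directory is given):

    out_dir/wav/<sample_id>.wav     float32 mono 44.1 kHz
    out_dir/metadata.csv            one row per sample
    out_dir/features.csv            sample_id, label, mfcc_00..mfcc_12
    out_dir/config.yaml             generation-config snapshot
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import caries
from .caries import CariesCoefficients, sample_lesion, apply_lesion, perturb_baseline
from .features import FeatureConfig, extract_features
from .mechanics import ImpulseSpec, SimConfig, ToothLayerParams, simulate_percussion
from .signal_chain import PercussionSignal, add_measurement_noise, normalize_signal, read_wav, write_wav

MFCC_COLUMNS = [f"mfcc_{i:02d}" for i in range(13)]
METADATA_COLUMNS = [
    "sample_id",
    "label",
    "lesion_type",
    "alpha",
    "sigma",
    "variability_pct",
    "seed",
    "wav_path",
]

LESION_TYPE = {
    caries.HEALTHY: "none",
    caries.ENAMEL_CARIES: "enamel",
    caries.DENTIN_CARIES: "dentin",
}


@dataclass(frozen=True)
class GenerationConfig:
    """One experimental condition for dataset generation.

    Defaults are the baseline condition: 500 samples per class (1500 total),
    measurement-noise SD 0.01 on the normalized signal, and +/-5%
    inter-tooth parameter variability.  ``solver`` selects the transient
    integrator ("exact" matrix-exponential propagation by default; "rk45"
    is equivalent to ~1e-6 relative and much slower).  ``coefficients``
    optionally overrides the per-class degradation coefficients (e.g. all
    zeros for a null-effect control).
    """

    n_per_class: int = 500
    classes: tuple[str, ...] = caries.CLASS_LABELS
    sigma: float = 0.01
    variability_pct: float = 0.05
    master_seed: int = 0
    output_dir: Path | None = None
    solver: str = "exact"
    coefficients: dict[str, CariesCoefficients] | None = None

    def __post_init__(self) -> None:
        if self.n_per_class <= 0:
            raise ValueError("n_per_class must be positive")
        if self.sigma < 0.0:
            raise ValueError(f"noise SD must be >= 0, got {self.sigma}")
        if not (0.0 <= self.variability_pct < 1.0):
            raise ValueError("variability_pct must be in [0, 1)")
        unknown = set(self.classes) - set(caries.CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")
        if self.solver not in ("exact", "rk45"):
            raise ValueError(f"unknown solver {self.solver!r}")

    @property
    def n_total(self) -> int:
        return self.n_per_class * len(self.classes)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["output_dir"] = str(self.output_dir) if self.output_dir else None
        if self.coefficients is not None:
            d["coefficients"] = {
                label: asdict(coef) for label, coef in self.coefficients.items()
            }
        return d


@dataclass
class DatasetBundle:
    """Metadata + features (+ optionally in-memory signals) of one dataset."""

    metadata: pd.DataFrame
    features: pd.DataFrame
    config: GenerationConfig
    signals: list[PercussionSignal] | None = field(default=None, repr=False)

    @property
    def labels(self) -> np.ndarray:
        return self.features["label"].to_numpy()

    @property
    def feature_matrix(self) -> np.ndarray:
        return self.features[MFCC_COLUMNS].to_numpy()


def sample_rng(master_seed: int, index: int) -> np.random.Generator:
    """Independent per-sample random stream keyed by (master_seed, index)."""
    return np.random.default_rng(np.random.SeedSequence([master_seed, index]))


def generate_sample(
    label: str,
    rng: np.random.Generator,
    cfg: GenerationConfig,
    impulse: ImpulseSpec,
    sim_cfg: SimConfig,
) -> tuple[PercussionSignal, caries.LesionSpec]:
    """Draw one synthetic tooth of the given class and simulate its signal."""
    baseline = ToothLayerParams()
    params = perturb_baseline(baseline, cfg.variability_pct, rng)
    coeffs = (cfg.coefficients or {}).get(label)
    lesion = sample_lesion(label, rng, coefficients=coeffs)
    params = apply_lesion(params, lesion)
    traj = simulate_percussion(params, impulse, sim_cfg, method=cfg.solver)
    signal = normalize_signal(traj.x1, sample_rate=int(sim_cfg.sample_rate))
    signal = add_measurement_noise(signal, cfg.sigma, rng)
    return signal, lesion


def generate_dataset(
    cfg: GenerationConfig,
    feature_cfg: FeatureConfig = FeatureConfig(),
    impulse: ImpulseSpec = ImpulseSpec(),
    sim_cfg: SimConfig = SimConfig(),
    keep_signals: bool = False,
) -> DatasetBundle:
    """Generate the full labeled dataset for one experimental condition.

    Samples are generated class-major with ids ``<label>_<j>``.  If
    ``cfg.output_dir`` is set, WAVs and the metadata/feature/config files
    are written there; otherwise everything stays in memory.
    """
    out_dir = Path(cfg.output_dir) if cfg.output_dir is not None else None
    wav_dir = None
    if out_dir is not None:
        wav_dir = out_dir / "wav"
        wav_dir.mkdir(parents=True, exist_ok=True)

    meta_rows: list[dict] = []
    feat_rows: list[dict] = []
    signals: list[PercussionSignal] = []
    index = 0
    for label in cfg.classes:
        for j in range(cfg.n_per_class):
            sample_id = f"{label}_{j:04d}"
            rng = sample_rng(cfg.master_seed, index)
            try:
                signal, lesion = generate_sample(label, rng, cfg, impulse, sim_cfg)
            except Exception as exc:
                raise RuntimeError(f"sample {sample_id} failed: {exc}") from exc
            wav_path = ""
            if wav_dir is not None:
                wav_path = f"wav/{sample_id}.wav"
                write_wav(signal, wav_dir / f"{sample_id}.wav")
            fv = extract_features(signal, feature_cfg, sample_id=sample_id)
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "label": label,
                    "lesion_type": LESION_TYPE[label],
                    "alpha": lesion.alpha,
                    "sigma": cfg.sigma,
                    "variability_pct": cfg.variability_pct,
                    "seed": index,
                    "wav_path": wav_path,
                }
            )
            feat_rows.append(
                {"sample_id": sample_id, "label": label}
                | dict(zip(MFCC_COLUMNS, fv.values))
            )
            if keep_signals:
                signals.append(signal)
            index += 1

    metadata = pd.DataFrame(meta_rows, columns=METADATA_COLUMNS)
    features = pd.DataFrame(feat_rows, columns=["sample_id", "label"] + MFCC_COLUMNS)
    if out_dir is not None:
        metadata.to_csv(out_dir / "metadata.csv", index=False)
        features.to_csv(out_dir / "features.csv", index=False)
        with open(out_dir / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
    return DatasetBundle(
        metadata=metadata,
        features=features,
        config=cfg,
        signals=signals if keep_signals else None,
    )


def load_dataset(path: Path | str, load_audio: bool = False) -> DatasetBundle:
    """Reload a dataset directory produced by :func:`generate_dataset`.

    Validates the metadata against the persisted config snapshot (class
    counts) and every referenced WAV (existence, sample rate, length).
    """
    path = Path(path)
    meta_file = path / "metadata.csv"
    feat_file = path / "features.csv"
    cfg_file = path / "config.yaml"
    for f in (meta_file, feat_file, cfg_file):
        if not f.exists():
            raise FileNotFoundError(f"missing dataset file: {f}")
    metadata = pd.read_csv(meta_file)
    features = pd.read_csv(feat_file)
    with open(cfg_file) as fh:
        raw = yaml.safe_load(fh)
    coeffs = raw.pop("coefficients", None)
    if coeffs is not None:
        coeffs = {k: CariesCoefficients(**v) for k, v in coeffs.items()}
    raw.pop("output_dir", None)
    cfg = GenerationConfig(
        **{k: tuple(v) if k == "classes" else v for k, v in raw.items()},
        output_dir=path,
        coefficients=coeffs,
    )

    counts = metadata["label"].value_counts()
    for label in cfg.classes:
        if counts.get(label, 0) != cfg.n_per_class:
            raise ValueError(
                f"class count mismatch for {label!r}: expected "
                f"{cfg.n_per_class}, found {counts.get(label, 0)}"
            )
    if len(metadata) != cfg.n_total or len(features) != cfg.n_total:
        raise ValueError("metadata/feature row count does not match config")

    expected_len = SimConfig().n_samples
    signals: list[PercussionSignal] = []
    for row in metadata.itertuples():
        wav = path / row.wav_path
        if not row.wav_path or not wav.exists():
            raise FileNotFoundError(f"missing WAV for sample {row.sample_id}")
        s = read_wav(wav)
        if s.sample_rate != 44100:
            raise ValueError(f"sample {row.sample_id}: unexpected rate {s.sample_rate}")
        if len(s) != expected_len:
            raise ValueError(
                f"sample {row.sample_id}: expected {expected_len} samples, got {len(s)}"
            )
        if load_audio:
            signals.append(s)
    return DatasetBundle(
        metadata=metadata,
        features=features,
        config=cfg,
        signals=signals if load_audio else None,
    )
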