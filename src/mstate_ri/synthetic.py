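"""Synthetic EEG with known microstate structure and band-power effects.

The generator realizes a semi-Markov state sequence (geometric run
lengths with the requested per-state means), renders each sample as the
active template scaled by a rectified-sinusoid GFP envelope with a
per-run random sign, and adds white sensor noise plus configured
band-limited oscillations. Everything is seed-deterministic, and each
recording carries its ground-truth run table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DimensionError, InvalidParameterError, ManifestError
from .io_preprocess import Recording, write_recording
from .microstate import LabelSequence, TemplateSet
from .montage import Montage, standard_montage

ENVELOPE_HZ = 5.0  # rectified-sinusoid GFP envelope frequency
ENVELOPE_FLOOR = 0.5  # keeps trough frames template-dominated at SNR ~ 4

CONDITIONS = ("pre", "during", "post")
GROUPS = ("TMNMT", "Placebo")


@dataclass(frozen=True)
class Oscillation:
    band_low_hz: float
    band_high_hz: float
    amplitude_uv: float  # RMS amplitude of the band-limited component
    channel_subset: tuple[int, ...] | None = None  # None = all channels

    def __post_init__(self) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise InvalidParameterError("need 0 < band_low < band_high")
        if self.amplitude_uv < 0:
            raise InvalidParameterError("amplitude must be nonnegative")


@dataclass(frozen=True)
class GenConfig:
    n_states: int = 4
    mean_durations_ms: tuple[float, ...] = (60.0, 80.0, 100.0, 120.0)
    gfp_scale_uv: float = 10.0
    noise_sd_uv: float = 2.5
    oscillations: tuple[Oscillation, ...] = ()
    fs_hz: float = 512.0
    length_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.mean_durations_ms) != self.n_states:
            raise InvalidParameterError("one mean duration per state required")
        if any(d <= 0 for d in self.mean_durations_ms):
            raise InvalidParameterError("mean durations must be positive")
        if self.length_s <= 0:
            raise InvalidParameterError("length_s must be positive")
        if self.noise_sd_uv < 0:
            raise InvalidParameterError("noise_sd_uv must be nonnegative")
        for osc in self.oscillations:
            if self.fs_hz <= 2 * osc.band_high_hz:
                raise InvalidParameterError(
                    f"fs {self.fs_hz} Hz too low for oscillation up to "
                    f"{osc.band_high_hz} Hz")


@dataclass(frozen=True)
class SubjectSpec:
    subject_id: str
    group: str
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ManifestError(f"unknown group {self.group!r}")
        ri = self.scores.get("RI_intensity")
        if ri is not None and not -5 <= ri <= 5:
            raise ManifestError("RI_intensity must lie in [-5, 5]")


@dataclass(frozen=True)
class EffectSpec:
    """Per (group, condition): band dB offsets and state duration multipliers."""

    band_offsets_db: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=dict)
    duration_multipliers: dict[tuple[str, str], dict[int, float]] = field(
        default_factory=dict)


@dataclass(frozen=True)
class StudyManifest:
    subjects: tuple[SubjectSpec, ...]
    conditions: tuple[str, ...] = CONDITIONS
    effect_spec: EffectSpec = field(default_factory=EffectSpec)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ManifestError("duplicate subject_id in manifest")


@dataclass
class SyntheticRecording:
    recording: Recording
    truth_labels: LabelSequence
    truth_runs: pd.DataFrame  # start, end, state, sign


@dataclass
class StudyDataset:
    montage: Montage
    templates: TemplateSet
    recordings: dict[tuple[str, str, str], SyntheticRecording]
    manifest: StudyManifest

    def score_table(self) -> pd.DataFrame:
        rows = [{"subject": s.subject_id, "group": s.group, **s.scores}
                for s in self.manifest.subjects]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------

def generate_templates(montage: Montage, k: int, smoothness: float = 2.0,
                       seed: int = 0) -> TemplateSet:
    """K mutually near-orthogonal zero-mean unit-GFP topographies.

    Random spatially smooth maps (Gaussian weights over electrode
    distance) are orthogonalized (Gram-Schmidt), which forces pairwise
    spatial correlations to ~0, then scaled to unit GFP. Because maps
    are zero-mean across channels, they live in a (C-1)-dimensional
    subspace, so at most ``n_channels - 1`` mutually orthogonal
    templates exist.
    """
    if k < 2:
        raise InvalidParameterError("k must be >= 2")
    if k > montage.n_channels - 1:
        raise InvalidParameterError(
            f"k {k} exceeds the zero-mean subspace dimension "
            f"({montage.n_channels - 1})")
    rng = np.random.default_rng(seed)
    pos = montage.positions
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    kernel = np.exp(-d2 / (2 * (smoothness / 2.0) ** 2))
    maps = []
    ones = np.ones(montage.n_channels) / np.sqrt(montage.n_channels)
    while len(maps) < k:
        m = kernel @ rng.standard_normal(montage.n_channels)
        m = m - (m @ ones) * ones  # zero mean
        for prev in maps:
            m = m - (m @ prev) * prev
        n = np.linalg.norm(m)
        if n < 1e-9:
            continue
        maps.append(m / n)
    # unit GFP: gfp = ||m|| / sqrt(C) = 1  ->  ||m|| = sqrt(C)
    maps_arr = np.vstack(maps) * np.sqrt(montage.n_channels)
    return TemplateSet(maps_arr, tuple("ABCDEFGHIJ"[:k]), "grand", 1.0)


def sample_state_sequence(config: GenConfig, montage_fs: float | None = None,
                          ) -> tuple[LabelSequence, pd.DataFrame]:
    """Semi-Markov labels with geometric run lengths (truncated at 10x mean).

    Successive runs never repeat a state; the next state is uniform over
    the others. Returns the per-sample labels and the ground-truth run
    table (start, end, state, sign) including the per-run polarity used
    later by the renderer.
    """
    fs = montage_fs or config.fs_hz
    n_samples = int(round(config.length_s * fs))
    rng = np.random.default_rng(config.seed)
    mean_samples = np.array(config.mean_durations_ms) * fs / 1000.0
    if np.any(mean_samples < 1):
        raise InvalidParameterError("mean duration shorter than one sample")
    labels = np.empty(n_samples, dtype=int)
    runs = []
    pos = 0
    state = int(rng.integers(config.n_states))
    while pos < n_samples:
        p = 1.0 / mean_samples[state]
        length = int(min(rng.geometric(p), np.ceil(10 * mean_samples[state])))
        end = min(pos + length, n_samples)
        sign = 1 if rng.random() < 0.5 else -1
        labels[pos:end] = state
        runs.append((pos, end, state, sign))
        pos = end
        if config.n_states > 1:
            step = int(rng.integers(1, config.n_states))
            state = (state + step) % config.n_states
    run_table = pd.DataFrame(runs, columns=["start", "end", "state", "sign"])
    seq = LabelSequence(labels, fs, config.n_states, source="ground_truth")
    return seq, run_table


def _band_noise(rng: np.random.Generator, shape: tuple[int, int], fs: float,
                low: float, high: float) -> np.ndarray:
    """Independent unit-RMS band-limited Gaussian noise rows (FFT masking)."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1], 1.0 / fs)
    spec[:, (freqs < low) | (freqs > high)] = 0.0
    x = np.fft.irfft(spec, shape[-1], axis=-1)
    rms = np.sqrt((x ** 2).mean(axis=-1, keepdims=True))
    return np.divide(x, rms, out=x, where=rms > 0)


def render_eeg(labels: LabelSequence, run_table: pd.DataFrame,
               templates: TemplateSet, config: GenConfig) -> SyntheticRecording:
    """Render labels into a multichannel recording.

    sample = active template x gfp envelope x per-run sign
             + white noise + band-limited oscillations, average-referenced.
    """
    if labels.k != templates.k:
        raise InvalidParameterError("label alphabet does not match templates")
    montage = standard_montage(templates.n_channels)
    n = len(labels.labels)
    fs = labels.fs_hz
    t = np.arange(n) / fs
    envelope = config.gfp_scale_uv * (
        ENVELOPE_FLOOR + (1 - ENVELOPE_FLOOR)
        * np.abs(np.sin(2 * np.pi * ENVELOPE_HZ * t)))
    sign = np.empty(n)
    for start, end, _state, s in run_table.itertuples(index=False):
        sign[start:end] = s
    data = templates.maps[labels.labels].T * (envelope * sign)[None, :]
    rng = np.random.default_rng(config.seed + 1)
    if config.noise_sd_uv > 0:
        data = data + rng.standard_normal(data.shape) * config.noise_sd_uv
    for osc in config.oscillations:
        idx = (np.arange(templates.n_channels) if osc.channel_subset is None
               else np.asarray(osc.channel_subset, dtype=int))
        if idx.max(initial=-1) >= templates.n_channels:
            raise DimensionError("oscillation channel index out of range")
        # independent per-channel realizations: average referencing then
        # removes only ~1/n_channels of the in-band power, uniformly
        wave = _band_noise(rng, (len(idx), n), fs,
                           osc.band_low_hz, osc.band_high_hz)
        data[idx] += osc.amplitude_uv * wave
    data = data - data.mean(axis=0, keepdims=True)
    rec = Recording(data, fs, montage, annotations=["synthetic"])
    return SyntheticRecording(rec, labels, run_table)


def simulate_recording(config: GenConfig, templates: TemplateSet,
                       ) -> SyntheticRecording:
    labels, runs = sample_state_sequence(config)
    return render_eeg(labels, runs, templates, config)


# ---------------------------------------------------------------------------
# Scores and whole studies

#: group -> (mean, sd, low clamp, high clamp) per instrument
SCORE_DISTRIBUTIONS = {
    "THI": {"TMNMT": (38.50, 19.15), "Placebo": (38.7, 15.96),
            "range": (0.0, 100.0)},
    "TFI": {"TMNMT": (94.76, 61.60), "Placebo": (94.45, 52.08),
            "range": (0.0, 250.0)},
    "VAS": {"TMNMT": (4.85, 2.10), "Placebo": (4.77, 1.91),
            "range": (0.0, 10.0)},
    "RI_intensity": {"TMNMT": (-3.6, 1.3), "Placebo": (-1.1, 1.6),
                     "range": (-5.0, 5.0)},
    "RI_duration_s": {"TMNMT": (403.0, 215.0), "Placebo": (96.0, 123.0),
                      "range": (0.0, 3600.0)},
}


def generate_scores(group: str, rng: np.random.Generator) -> dict[str, float]:
    """Gaussian draws from the published summary statistics, clamped."""
    scores = {}
    for name, spec in SCORE_DISTRIBUTIONS.items():
        mean, sd = spec[group]
        lo, hi = spec["range"]
        scores[name] = float(np.clip(rng.normal(mean, sd), lo, hi))
    return scores


def default_manifest(n_per_group: int, seed: int = 0,
                     effect_spec: EffectSpec | None = None,
                     conditions: tuple[str, ...] = CONDITIONS) -> StudyManifest:
    rng = np.random.default_rng(seed)
    subjects = []
    for group in GROUPS:
        for i in range(n_per_group):
            subjects.append(SubjectSpec(f"{group.lower()}{i + 1:03d}", group,
                                        generate_scores(group, rng)))
    return StudyManifest(tuple(subjects), conditions,
                         effect_spec or EffectSpec())


def _apply_effects(base: GenConfig, manifest: StudyManifest, group: str,
                   condition: str) -> GenConfig:
    eff = manifest.effect_spec
    durations = list(base.mean_durations_ms)
    for state, mult in eff.duration_multipliers.get((group, condition), {}).items():
        durations[state] = durations[state] * mult
    oscs = list(base.oscillations)
    from .spectral import DEFAULT_BANDS

    for band, offset_db in eff.band_offsets_db.get((group, condition), {}).items():
        lo, hi = DEFAULT_BANDS[band]
        gain = 10.0 ** (offset_db / 20.0)
        for i, osc in enumerate(oscs):
            if osc.band_low_hz < hi and osc.band_high_hz > lo:
                oscs[i] = replace(osc, amplitude_uv=osc.amplitude_uv * gain)
    return replace(base, mean_durations_ms=tuple(durations),
                   oscillations=tuple(oscs))


def generate_study(manifest: StudyManifest, base: GenConfig,
                   montage: Montage | None = None,
                   templates: TemplateSet | None = None) -> StudyDataset:
    """One recording per subject x condition with effects applied.

    Per-recording seeds derive deterministically from the base seed and
    the (subject, condition) position, so the dataset is reproducible
    as a whole and per recording.
    """
    montage = montage or standard_montage(60)
    templates = templates or generate_templates(montage, base.n_states,
                                                seed=base.seed)
    if templates.n_channels != montage.n_channels:
        raise DimensionError("template/montage channel count mismatch")
    recordings: dict[tuple[str, str, str], SyntheticRecording] = {}
    seq = np.random.SeedSequence(base.seed)
    for si, subj in enumerate(manifest.subjects):
        for ci, cond in enumerate(manifest.conditions):
            cfg = _apply_effects(base, manifest, subj.group, cond)
            sub_seed = int(np.random.default_rng(
                seq.spawn(1)[0]).integers(2 ** 31))
            cfg = replace(cfg, seed=sub_seed)
            recordings[(subj.subject_id, subj.group, cond)] = (
                simulate_recording(cfg, templates))
    return StudyDataset(montage, templates, recordings, manifest)


def write_study(study: StudyDataset, out_dir: str | Path) -> Path:
    """Write recordings, ground truth and `manifest.tsv` under ``out_dir``."""
    out = Path(out_dir)
    (out / "recordings").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    rows = []
    score_map = {s.subject_id: s for s in study.manifest.subjects}
    for (subj, group, cond), srec in sorted(study.recordings.items()):
        stem = f"{subj}_{cond}"
        path = out / "recordings" / f"{stem}.tsv"
        write_recording(path, srec.recording)
        srec.truth_runs.to_csv(out / "truth" / f"{stem}.tsv", sep="\t",
                               index=False)
        scores = score_map[subj].scores
        rows.append({"subject_id": subj, "group": group, "condition": cond,
                     "path": str(path.relative_to(out)), **scores})
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    return out / "manifest.tsv"
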