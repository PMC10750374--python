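"""Config-driven orchestration: simulate -> preprocess -> spectral +
microstate -> stats -> report.

Recordings are generated and preprocessed one at a time so memory stays
bounded; only the 2-20 Hz epochs (for microstate analysis), band-power
rows and ground truth are retained per recording. Identical config and
seed give identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import EmptyResultError, InvalidParameterError, MstateError
from .io_preprocess import epoch_and_reject, filter_band, preprocess
from .microstate import (
    backfit,
    microstate_metrics,
    transition_probabilities,
    two_level_templates,
)
from .spectral import BandScheme, WelchConfig, band_power, welch_psd
from .stats import (
    StatResult,
    correlate_batch,
    fdr_adjust,
    mixed_anova,
    ttest_paired,
)
from .synthetic import (
    CONDITIONS,
    EffectSpec,
    GenConfig,
    Oscillation,
    default_manifest,
    simulate_recording,
)
from .montage import standard_montage
from .synthetic import generate_templates

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    n_per_group: int = 6
    n_channels: int = 60
    k: int = 4
    conditions: tuple[str, ...] = CONDITIONS
    # simulation
    sim_fs_hz: float = 1000.0
    length_s: float = 12.0
    mean_durations_ms: tuple[float, ...] = (60.0, 80.0, 100.0, 120.0)
    gfp_scale_uv: float = 10.0
    noise_sd_uv: float = 2.5
    oscillations: tuple[Oscillation, ...] = (
        Oscillation(8.0, 13.0, 3.0),)
    band_offsets_db: dict = field(default_factory=dict)
    duration_multipliers: dict = field(default_factory=dict)
    # preprocessing
    target_fs_hz: float = 512.0
    band: tuple[float, float] = (0.5, 100.0)
    notches: tuple[float, ...] = (50.0, 100.0)
    epoch_length_s: float = 2.0
    threshold_uv: float = 100.0
    microstate_band: tuple[float, float] = (2.0, 20.0)
    # welch
    welch_segment_s: float = 2.0
    welch_overlap: float = 0.5
    # microstate
    template_level: str = "group"  # group | grand | subject
    min_peak_separation_ms: float = 10.0
    max_maps_per_subject: int | None = 400
    # stats
    alpha: float = 0.05

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "oscillations" in d:
            d["oscillations"] = tuple(
                Oscillation(*o) if not isinstance(o, Oscillation) else o
                for o in d["oscillations"])
        for key in ("mean_durations_ms", "band", "notches", "microstate_band",
                    "conditions"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "band_offsets_db" in d:
            d["band_offsets_db"] = _parse_effect_keys(d["band_offsets_db"])
        if "duration_multipliers" in d:
            d["duration_multipliers"] = {
                k: {int(s): v for s, v in sub.items()}
                for k, sub in _parse_effect_keys(
                    d["duration_multipliers"]).items()}
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def effect_spec(self) -> EffectSpec:
        return EffectSpec(self.band_offsets_db, self.duration_multipliers)

    def gen_config(self) -> GenConfig:
        return GenConfig(n_states=self.k,
                         mean_durations_ms=self.mean_durations_ms,
                         gfp_scale_uv=self.gfp_scale_uv,
                         noise_sd_uv=self.noise_sd_uv,
                         oscillations=self.oscillations,
                         fs_hz=self.sim_fs_hz, length_s=self.length_s,
                         seed=self.seed)

    def welch_config(self) -> WelchConfig:
        m = int(round(self.welch_segment_s * self.target_fs_hz))
        return WelchConfig(m, int(round(m * self.welch_overlap)))


def _parse_effect_keys(d: dict) -> dict:
    """YAML keys 'GROUP:condition' -> (group, condition) tuples."""
    out = {}
    for key, val in d.items():
        if isinstance(key, str) and ":" in key:
            grp, cond = key.split(":", 1)
            out[(grp, cond)] = val
        else:
            out[tuple(key) if not isinstance(key, tuple) else key] = val
    return out


def load_config(path: str | Path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PipelineConfig.from_dict(data or {})


@dataclass
class RunReport:
    config: dict
    version: str
    stage_log: list[dict]
    outputs: list[str]
    n_recordings: int
    n_epochs_rejected: int
    explained_variance: dict

    def to_json(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _config_echo(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["band_offsets_db"] = {f"{g}:{c}": v
                            for (g, c), v in cfg.band_offsets_db.items()}
    d["duration_multipliers"] = {f"{g}:{c}": v
                                 for (g, c), v in cfg.duration_multipliers.items()}
    return d


def analyze_study(cfg: PipelineConfig) -> dict:
    """Simulate and analyze a study in memory; returns all result tables."""
    stage_log: list[dict] = []

    def log_stage(name: str, t0: float, **counts) -> None:
        stage_log.append({"stage": name,
                          "wall_s": round(time.perf_counter() - t0, 3),
                          **counts})
        logger.info("stage %s done (%s)", name, counts)

    t0 = time.perf_counter()
    manifest = default_manifest(cfg.n_per_group, seed=cfg.seed,
                                effect_spec=cfg.effect_spec(),
                                conditions=cfg.conditions)
    montage = standard_montage(cfg.n_channels)
    templates = generate_templates(montage, cfg.k, seed=cfg.seed)
    base = cfg.gen_config()
    scheme = BandScheme()
    wcfg = cfg.welch_config()

    ms_epochs = {}
    truth = {}
    band_rows = []
    n_rejected = 0
    seq = np.random.SeedSequence(cfg.seed)
    from dataclasses import replace as _replace

    from .synthetic import _apply_effects

    for subj in manifest.subjects:
        for cond in manifest.conditions:
            gen = _apply_effects(base, manifest, subj.group, cond)
            sub_seed = int(np.random.default_rng(seq.spawn(1)[0]).integers(2 ** 31))
            gen = _replace(gen, seed=sub_seed)
            srec = simulate_recording(gen, templates)
            rec = preprocess(srec.recording, cfg.target_fs_hz, cfg.band,
                             cfg.notches)
            epochs = epoch_and_reject(rec, cfg.epoch_length_s, cfg.threshold_uv)
            n_rejected += int(epochs.rejection_mask.sum())
            key = (subj.subject_id, subj.group, cond)
            if epochs.n_retained == 0:
                logger.warning("subject %s: no retained epochs", key)
                continue
            psd = welch_psd(epochs, wcfg)
            table = band_power(psd, scheme)
            for band in scheme.names:
                band_rows.append((*key, band, float(table.whole_brain_db[band])))
            rec_ms = filter_band(rec, *cfg.microstate_band)
            # epoch the 2-20 Hz data on the same grid, reusing the broadband
            # rejection mask (amplitude rule applies to the 0.5-100 Hz chain)
            eps_ms = epoch_and_reject(rec_ms, cfg.epoch_length_s,
                                      threshold_uv=1e9)
            eps_ms.rejection_mask = epochs.rejection_mask.copy()
            ms_epochs[key] = eps_ms
            truth[key] = srec
    band_table = pd.DataFrame(
        band_rows, columns=["subject", "group", "condition", "band", "db"])
    log_stage("simulate+preprocess+spectral", t0,
              n_recordings=len(ms_epochs), n_epochs_rejected=n_rejected)

    t0 = time.perf_counter()
    tls = two_level_templates(ms_epochs, cfg.k, cfg.min_peak_separation_ms,
                              cfg.max_maps_per_subject)
    metric_rows, trans_rows = [], []
    label_seqs = {}
    for key in sorted(ms_epochs):
        subj, group, cond = key
        if cfg.template_level == "grand":
            ts = tls["grand"]
        elif cfg.template_level == "subject":
            ts = tls["subject"][key]
        else:
            ts = tls["group"][(group, cond)]
        labels = backfit(ms_epochs[key], ts, cfg.min_peak_separation_ms)
        label_seqs[key] = (labels, ts.class_labels)
        metrics = microstate_metrics(labels, ts.class_labels)
        for cls, row in metrics.iterrows():
            metric_rows.append((subj, group, cond, cls, row.duration_ms,
                                row.occurrence_per_s, row.coverage))
        probs = transition_probabilities(labels)
        for i, ci in enumerate(ts.class_labels):
            for j, cj in enumerate(ts.class_labels):
                if i != j:
                    trans_rows.append((subj, group, cond, ci, cj, probs[i, j]))
    metrics_table = pd.DataFrame(
        metric_rows, columns=["subject", "group", "condition", "class",
                              "duration_ms", "occurrence_per_s", "coverage"])
    trans_table = pd.DataFrame(
        trans_rows, columns=["subject", "group", "condition", "from", "to", "p"])
    ev = {"grand": tls["grand"].explained_variance}
    log_stage("microstate", t0, n_metric_rows=len(metrics_table))

    t0 = time.perf_counter()
    stats_table = run_stats(band_table, metrics_table, trans_table,
                            manifest)
    log_stage("stats", t0, n_stat_rows=len(stats_table))

    return {"manifest": manifest, "templates": tls, "band_table": band_table,
            "metrics_table": metrics_table, "trans_table": trans_table,
            "stats_table": stats_table, "stage_log": stage_log,
            "n_rejected": n_rejected, "explained_variance": ev,
            "labels": label_seqs}


def _stat_row(analysis: str, r: StatResult) -> dict:
    return {"analysis": analysis, "comparison": r.comparison, "test": r.test,
            "statistic": r.statistic, "df": "x".join(f"{d:g}" for d in r.df),
            "p_raw": r.p_raw, "p_fdr": r.p_adjusted}


def _condition_family(table: pd.DataFrame, value_col: str, level_col: str,
                      group: str, analysis: str, rows: list[dict],
                      conditions: tuple[str, ...]) -> None:
    """Mixed ANOVA (level within, condition 'between') + FDR'd paired t."""
    sub = table[table.group == group]
    long = sub.rename(columns={value_col: "value", level_col: "lvl"}).copy()
    long["cond_subject"] = long.subject + "_" + long.condition
    try:
        res = mixed_anova(long, dv="value", within="lvl", between="condition",
                          subject="cond_subject")
        for effect, r in res.items():
            r.comparison = effect
            rows.append(_stat_row(f"{analysis}:{group}:anova", r))
    except (InvalidParameterError, MstateError) as exc:
        logger.warning("ANOVA skipped for %s/%s: %s", analysis, group, exc)
    family: list[StatResult] = []
    for lvl in sorted(sub[level_col].unique()):
        lvl_tab = sub[sub[level_col] == lvl].pivot_table(
            index="subject", columns="condition", values=value_col)
        for c1, c2 in combinations(conditions, 2):
            if c1 not in lvl_tab or c2 not in lvl_tab:
                continue
            pair = lvl_tab[[c1, c2]].dropna()
            try:
                r = ttest_paired(pair[c1], pair[c2],
                                 comparison=f"{lvl}:{c1}-{c2}")
                family.append(r)
            except MstateError as exc:
                logger.warning("paired t skipped (%s %s): %s", lvl, c1, exc)
    if family:
        adj = fdr_adjust([r.p_raw for r in family])
        for r, a in zip(family, adj):
            r.p_adjusted = float(a)
            rows.append(_stat_row(f"{analysis}:{group}:paired", r))


def run_stats(band_table: pd.DataFrame, metrics_table: pd.DataFrame,
              trans_table: pd.DataFrame, manifest) -> pd.DataFrame:
    """The statistical layer over the pipeline tables.

    Per group: a mixed ANOVA per measure (bands or microstate classes as
    the within factor, condition subgroup as the between factor) plus
    FDR-corrected paired t-tests across condition pairs, one family per
    (group, measure). Duration-vs-TFI correlations per subgroup form
    their own FDR family.
    """
    rows: list[dict] = []
    conditions = tuple(manifest.conditions)
    groups = sorted(band_table.group.unique())
    for group in groups:
        _condition_family(band_table, "db", "band", group, "psd", rows,
                          conditions)
        for measure in ("duration_ms", "occurrence_per_s", "coverage"):
            _condition_family(metrics_table, measure, "class", group,
                              measure, rows, conditions)
        tt = trans_table.copy()
        tt["pair"] = tt["from"] + ">" + tt["to"]
        _condition_family(tt, "p", "pair", group, "transition", rows,
                          conditions)
    # duration of class B vs TFI score per subgroup
    scores = {s.subject_id: s.scores.get("TFI", np.nan)
              for s in manifest.subjects}
    pairs = {}
    dur_b = metrics_table[metrics_table["class"] == "B"]
    for (group, cond), sub in dur_b.groupby(["group", "condition"]):
        x = sub.duration_ms.to_numpy()
        y = np.array([scores[s] for s in sub.subject])
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() >= 3:
            pairs[f"durationB~TFI:{group}:{cond}"] = (x[ok], y[ok])
    if pairs:
        try:
            for name, r in correlate_batch(pairs).items():
                rows.append(_stat_row("correlation", r))
        except MstateError as exc:
            logger.warning("correlation family skipped: %s", exc)
    return pd.DataFrame(rows, columns=["analysis", "comparison", "test",
                                       "statistic", "df", "p_raw", "p_fdr"])


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> RunReport:
    """Execute every stage and write TSV artifacts plus report.json.

    On stage failure the partial outputs are moved under ``failed/`` and
    the error is re-raised with the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    try:
        results = analyze_study(cfg)
        t0 = time.perf_counter()
        for name, frame in (("psd_bands.tsv", results["band_table"]),
                            ("metrics.tsv", results["metrics_table"]),
                            ("transitions.tsv", results["trans_table"]),
                            ("stats_report.tsv", results["stats_table"])):
            path = out / name
            frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
            outputs.append(str(path))
        grand = results["templates"]["grand"]
        tpath = out / "templates_grand.tsv"
        pd.DataFrame(grand.maps.T, columns=list(grand.class_labels)).to_csv(
            tpath, sep="\t", index=False, float_format="%.10g")
        outputs.append(str(tpath))
        gpath = out / "templates_group.tsv"
        gframes = []
        for (group, cond), ts in sorted(results["templates"]["group"].items()):
            frame = pd.DataFrame(ts.maps.T, columns=list(ts.class_labels))
            frame.insert(0, "group", group)
            frame.insert(1, "condition", cond)
            frame.insert(2, "channel", range(ts.n_channels))
            gframes.append(frame)
        pd.concat(gframes).to_csv(gpath, sep="\t", index=False,
                                  float_format="%.10g")
        outputs.append(str(gpath))
        labels_dir = out / "labels"
        labels_dir.mkdir(exist_ok=True)
        for (subj, _group, cond), (seq, classes) in results["labels"].items():
            lpath = labels_dir / f"{subj}_{cond}.tsv"
            pd.DataFrame({
                "label": [classes[i] if i >= 0 else "UNASSIGNED"
                          for i in seq.labels]}).to_csv(lpath, sep="\t",
                                                        index=False)
            outputs.append(str(lpath))
        results["stage_log"].append(
            {"stage": "write", "wall_s": round(time.perf_counter() - t0, 3)})
        report = RunReport(_config_echo(cfg), __version__,
                           results["stage_log"], outputs,
                           n_recordings=len(results["metrics_table"]
                                            .groupby(["subject", "condition"])),
                           n_epochs_rejected=results["n_rejected"],
                           explained_variance=results["explained_variance"])
        report.to_json(out / "report.json")
        outputs.append(str(out / "report.json"))
        return report
    except Exception as exc:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for f in outputs:
            Path(f).rename(failed / Path(f).name)
        raise MstateError(f"pipeline failed: {exc}") from exc


# ---------------------------------------------------------------------------
# Disk-based stage entry points (for the stage-wise CLI)

def load_study_recordings(study_dir: str | Path,
                          n_channels: int = 60) -> tuple[dict, pd.DataFrame]:
    """Read `manifest.tsv` and its recordings from a simulate output dir."""
    from .io_preprocess import read_recording

    study_dir = Path(study_dir)
    manifest = pd.read_csv(study_dir / "manifest.tsv", sep="\t")
    montage = standard_montage(n_channels)
    recs = {}
    for row in manifest.itertuples(index=False):
        key = (row.subject_id, row.group, row.condition)
        recs[key] = read_recording(study_dir / row.path, montage)
    return recs, manifest


def stage_preprocess(study_dir: str | Path, out_dir: str | Path,
                     cfg: PipelineConfig) -> None:
    """Preprocess every recording of a simulated study; write TSVs."""
    from .io_preprocess import write_recording

    recs, manifest = load_study_recordings(study_dir, cfg.n_channels)
    out = Path(out_dir)
    (out / "preprocessed").mkdir(parents=True, exist_ok=True)
    rej_rows = []
    for (subj, group, cond), rec in sorted(recs.items()):
        pre = preprocess(rec, cfg.target_fs_hz, cfg.band, cfg.notches)
        write_recording(out / "preprocessed" / f"{subj}_{cond}.tsv", pre)
        epochs = epoch_and_reject(pre, cfg.epoch_length_s, cfg.threshold_uv)
        for i, (m, why) in enumerate(zip(epochs.rejection_mask,
                                         epochs.rejection_reasons)):
            if m:
                rej_rows.append((subj, cond, i, why))
    pd.DataFrame(rej_rows, columns=["subject", "condition", "epoch", "reason"]
                 ).to_csv(out / "rejection.tsv", sep="\t", index=False)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)


def _preprocessed_epochs(in_dir: Path, cfg: PipelineConfig) -> tuple[dict, pd.DataFrame]:
    from .io_preprocess import read_recording

    manifest = pd.read_csv(in_dir / "manifest.tsv", sep="\t")
    montage = standard_montage(cfg.n_channels)
    pre_dir = in_dir / "preprocessed"
    epochs = {}
    for row in manifest.itertuples(index=False):
        key = (row.subject_id, row.group, row.condition)
        path = pre_dir / f"{row.subject_id}_{row.condition}.tsv"
        rec = read_recording(path, montage)
        epochs[key] = (rec, epoch_and_reject(rec, cfg.epoch_length_s,
                                             cfg.threshold_uv))
    return epochs, manifest


def stage_spectral(in_dir: str | Path, out_dir: str | Path,
                   cfg: PipelineConfig) -> None:
    """Welch band powers from a `preprocess` output directory."""
    epochs, manifest = _preprocessed_epochs(Path(in_dir), cfg)
    scheme = BandScheme()
    rows = []
    for key, (_rec, eps) in sorted(epochs.items()):
        table = band_power(welch_psd(eps, cfg.welch_config()), scheme)
        for band in scheme.names:
            rows.append((*key, band, float(table.whole_brain_db[band])))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["subject", "group", "condition", "band", "db"]
                 ).to_csv(out / "psd_bands.tsv", sep="\t", index=False,
                          float_format="%.10g")
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)


def stage_microstate(in_dir: str | Path, out_dir: str | Path,
                     cfg: PipelineConfig) -> None:
    """Microstate tables from a `preprocess` output directory."""
    epochs, manifest = _preprocessed_epochs(Path(in_dir), cfg)
    ms = {}
    for key, (rec, eps) in epochs.items():
        rec_ms = filter_band(rec, *cfg.microstate_band)
        e = epoch_and_reject(rec_ms, cfg.epoch_length_s, threshold_uv=1e9)
        e.rejection_mask = eps.rejection_mask.copy()
        ms[key] = e
    tls = two_level_templates(ms, cfg.k, cfg.min_peak_separation_ms,
                              cfg.max_maps_per_subject)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metric_rows, trans_rows = [], []
    for key in sorted(ms):
        subj, group, cond = key
        ts = (tls["grand"] if cfg.template_level == "grand"
              else tls["subject"][key] if cfg.template_level == "subject"
              else tls["group"][(group, cond)])
        labels = backfit(ms[key], ts, cfg.min_peak_separation_ms)
        for cls, row in microstate_metrics(labels, ts.class_labels).iterrows():
            metric_rows.append((subj, group, cond, cls, row.duration_ms,
                                row.occurrence_per_s, row.coverage))
        probs = transition_probabilities(labels)
        for i, ci in enumerate(ts.class_labels):
            for j, cj in enumerate(ts.class_labels):
                if i != j:
                    trans_rows.append((subj, group, cond, ci, cj, probs[i, j]))
    pd.DataFrame(metric_rows,
                 columns=["subject", "group", "condition", "class",
                          "duration_ms", "occurrence_per_s", "coverage"]
                 ).to_csv(out / "metrics.tsv", sep="\t", index=False,
                          float_format="%.10g")
    pd.DataFrame(trans_rows,
                 columns=["subject", "group", "condition", "from", "to", "p"]
                 ).to_csv(out / "transitions.tsv", sep="\t", index=False,
                          float_format="%.10g")
    grand = tls["grand"]
    pd.DataFrame(grand.maps.T, columns=list(grand.class_labels)).to_csv(
        out / "templates_grand.tsv", sep="\t", index=False,
        float_format="%.10g")
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)


def stage_stats(in_dir: str | Path, out_dir: str | Path,
                cfg: PipelineConfig, manifest_dir: str | Path | None = None) -> None:
    """Statistics from psd_bands/metrics/transitions TSVs."""
    in_dir = Path(in_dir)
    band_table = pd.read_csv(in_dir / "psd_bands.tsv", sep="\t")
    metrics_table = pd.read_csv(in_dir / "metrics.tsv", sep="\t")
    trans_table = pd.read_csv(in_dir / "transitions.tsv", sep="\t")
    mpath = Path(manifest_dir or in_dir) / "manifest.tsv"
    mdf = pd.read_csv(mpath, sep="\t")
    from .synthetic import StudyManifest, SubjectSpec

    score_cols = [c for c in mdf.columns
                  if c not in ("subject_id", "group", "condition", "path")]
    subjects = []
    for sid, sub in mdf.groupby("subject_id", sort=True):
        row = sub.iloc[0]
        subjects.append(SubjectSpec(sid, row.group,
                                    {c: float(row[c]) for c in score_cols}))
    manifest = StudyManifest(tuple(subjects),
                             tuple(pd.unique(mdf.condition)))
    table = run_stats(band_table, metrics_table, trans_table, manifest)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "stats_report.tsv", sep="\t", index=False,
                 float_format="%.10g")


def render_tables(out_dir: str | Path) -> str:
    """Human-readable mean (SD) summary of the metric tables."""
    out = Path(out_dir)
    mpath = out / "metrics.tsv"
    if not mpath.exists():
        raise IOError(f"missing pipeline output: {mpath}")
    metrics = pd.read_csv(mpath, sep="\t")
    if metrics.empty:
        raise EmptyResultError("metrics table is empty")
    lines = []
    for measure in ("duration_ms", "occurrence_per_s", "coverage"):
        for group, sub in metrics.groupby("group"):
            lines.append(f"## {measure} — {group}")
            piv_m = sub.pivot_table(index="class", columns="condition",
                                    values=measure, aggfunc="mean")
            piv_s = sub.pivot_table(index="class", columns="condition",
                                    values=measure, aggfunc="std")
            header = "class\t" + "\t".join(piv_m.columns)
            lines.append(header)
            for cls in piv_m.index:
                cells = [f"{piv_m.loc[cls, c]:.4f} ({piv_s.loc[cls, c]:.4f})"
                         for c in piv_m.columns]
                lines.append(cls + "\t" + "\t".join(cells))
            lines.append("")
    return "\n".join(lines)
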