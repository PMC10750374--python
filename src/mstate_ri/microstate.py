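"""Microstate analysis: GFP, polarity-invariant clustering, back-fitting,
temporal metrics and transition syntax.

All clustering and labeling is invariant to global polarity (maps are
compared by absolute spatial correlation) and to positive rescaling of
the recording. Cluster maps are the first principal orientation of
their member maps (sign-free).

Transition probabilities are row-normalized conditional probabilities
(each row with at least one outgoing transition sums to 1). Published
per-class transition tables do not always follow this convention; this
module makes no attempt to emulate any other normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .errors import (
    DimensionError,
    EmptyResultError,
    InvalidParameterError,
    UndefinedStatisticError,
)
from .io_preprocess import Epochs, Recording

logger = logging.getLogger(__name__)

CLASS_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass
class GfpSeries:
    values: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise InvalidParameterError("GFP must be nonnegative")


@dataclass
class TemplateSet:
    """K zero-mean, unit-norm topographies with class labels."""

    maps: np.ndarray  # K x channels
    class_labels: tuple[str, ...]
    level: str = "subject"  # subject | group | grand
    explained_variance: float = float("nan")

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if len(self.class_labels) != self.maps.shape[0]:
            raise DimensionError("one class label per map required")
        if np.isfinite(self.explained_variance) and not (
                -1e-9 <= self.explained_variance <= 1 + 1e-9):
            raise InvalidParameterError("explained_variance must be in [0, 1]")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]

    def relabeled(self, labels: tuple[str, ...], order: np.ndarray) -> "TemplateSet":
        return TemplateSet(self.maps[order], labels, self.level,
                           self.explained_variance)


@dataclass
class LabelSequence:
    """Per-sample state assignment; -1 marks UNASSIGNED samples."""

    labels: np.ndarray
    fs_hz: float
    k: int
    source: str = "backfit"  # backfit | ground_truth
    epoch_starts: np.ndarray | None = None  # offsets of epoch starts

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and self.labels.max() >= self.k:
            raise InvalidParameterError("label index out of range")
        if self.epoch_starts is None:
            self.epoch_starts = np.array([0])
        else:
            self.epoch_starts = np.asarray(self.epoch_starts, dtype=int)

    def epochs(self) -> list[np.ndarray]:
        bounds = list(self.epoch_starts) + [len(self.labels)]
        return [self.labels[a:b] for a, b in zip(bounds[:-1], bounds[1:])]


# ---------------------------------------------------------------------------
# GFP and peak maps

def gfp(rec: Recording) -> GfpSeries:
    """Spatial standard deviation (population, 1/N) per sample."""
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return GfpSeries(np.sqrt((data ** 2).mean(axis=0)), rec.fs_hz)


def find_gfp_peaks(g: GfpSeries, min_separation_ms: float = 10.0) -> np.ndarray:
    """Strictly interior local maxima, thinned to the stated separation."""
    if len(g.values) < 3:
        return np.array([], dtype=int)
    distance = max(int(round(min_separation_ms * g.fs_hz / 1000.0)), 1)
    peaks, _ = _signal.find_peaks(g.values, distance=distance)
    return peaks


def spatial_correlation(a: np.ndarray, b: np.ndarray,
                        ignore_polarity: bool = True) -> float:
    """Pearson correlation of two topographies across channels."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DimensionError("topographies must have equal channel counts")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise UndefinedStatisticError("zero-variance topography")
    r = float(a @ b / (na * nb))
    return abs(r) if ignore_polarity else r


def _normalize_maps(maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Demean across channels and scale to unit norm; returns (unit, gfp)."""
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    maps = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(maps, axis=1)
    keep = norms > 0
    gfps = norms[keep] / np.sqrt(maps.shape[1])
    return maps[keep] / norms[keep, None], gfps


def gfp_peak_maps(data: Recording | Epochs,
                  min_separation_ms: float = 10.0,
                  max_maps: int | None = None,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Average-referenced topographies at GFP peaks and their GFP values.

    For epoched input, peaks are found within each retained epoch. When
    ``max_maps`` is set, the highest-GFP peaks are kept (deterministic).
    """
    if isinstance(data, Recording):
        blocks = [data.data - data.data.mean(axis=0, keepdims=True)]
        fs = data.fs_hz
    else:
        blocks = [b - b.mean(axis=0, keepdims=True) for b in data.retained]
        fs = data.fs_hz
    maps, gfps = [], []
    for block in blocks:
        g = GfpSeries(np.sqrt((block ** 2).mean(axis=0)), fs)
        peaks = find_gfp_peaks(g, min_separation_ms)
        if peaks.size:
            maps.append(block[:, peaks].T)
            gfps.append(g.values[peaks])
    if not maps:
        raise EmptyResultError("no GFP peaks found")
    maps_arr = np.vstack(maps)
    gfps_arr = np.concatenate(gfps)
    if max_maps is not None and len(maps_arr) > max_maps:
        order = np.argsort(-gfps_arr, kind="stable")[:max_maps]
        order = np.sort(order)
        maps_arr, gfps_arr = maps_arr[order], gfps_arr[order]
    return maps_arr, gfps_arr


# ---------------------------------------------------------------------------
# Clustering

def _principal_orientation(unit_maps: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """First eigenvector of the weighted outer-product sum (sign-free)."""
    if len(unit_maps) == 1:
        return unit_maps[0]
    cov = (unit_maps * weights[:, None]).T @ unit_maps
    vals, vecs = np.linalg.eigh(cov)
    v = vecs[:, -1]
    v = v - v.mean()
    n = np.linalg.norm(v)
    return v / n if n > 0 else unit_maps[0]


class _AahcState:
    """Cluster bookkeeping for atomize-agglomerate clustering.

    Maps are unit-normalized; each map carries weight gfp^2 so the
    atomization order follows global explained variance. During the
    descent, cluster orientations are refreshed by warm-started power
    iteration (cheap, deterministic); ``polish`` recomputes the
    surviving clusters exactly before templates are reported.
    """

    def __init__(self, maps: np.ndarray, gfps: np.ndarray | None = None):
        if gfps is None:
            unit, gfps = _normalize_maps(maps)
        else:
            unit, _ = _normalize_maps(maps)
        if len(unit) == 0:
            raise InvalidParameterError("no nonzero maps to cluster")
        self.unit = unit
        self.w = np.asarray(gfps, dtype=float)[: len(unit)] ** 2
        self.members: list[list[int]] = [[i] for i in range(len(unit))]
        self.cmaps: np.ndarray = unit.copy()
        self.quality: np.ndarray = self.w.copy()

    @property
    def n_clusters(self) -> int:
        return len(self.members)

    def _recompute(self, j: int, exact: bool = False) -> None:
        idx = np.asarray(self.members[j])
        m = self.unit[idx]
        wsub = self.w[idx]
        if len(idx) == 1:
            v = m[0]
        elif exact:
            v = _principal_orientation(m, wsub)
        else:
            v = self.cmaps[j]
            for _ in range(3):
                v = m.T @ (wsub * (m @ v))
                n = np.linalg.norm(v)
                v = v / n if n > 0 else m[0]
            v = v - v.mean()
            n = np.linalg.norm(v)
            v = v / n if n > 0 else m[0]
        self.cmaps[j] = v
        self.quality[j] = float(wsub @ (m @ v) ** 2)

    #: below this many clusters the atomization target is chosen by the
    #: exact explained-variance loss of removing a cluster (its members
    #: falling back to their next-best cluster). The cheap total-quality
    #: criterion used above this size cannot tell a redundant duplicate
    #: cluster from a unique one.
    DELTA_PHASE = 24

    def _delta_ev(self) -> np.ndarray:
        """Per-cluster explained-variance loss if that cluster is removed."""
        corr = np.abs(self.unit @ self.cmaps.T)
        own_cluster = np.empty(len(self.unit), dtype=int)
        for j, idx in enumerate(self.members):
            own_cluster[idx] = j
        rows = np.arange(len(self.unit))
        own = corr[rows, own_cluster].copy()
        corr[rows, own_cluster] = -np.inf
        best_other = corr.max(axis=1)
        loss = self.w * (own ** 2 - best_other ** 2)
        return np.array([loss[idx].sum()
                         for idx in map(np.asarray, self.members)])

    def atomize_step(self) -> None:
        if self.n_clusters <= self.DELTA_PHASE:
            worst = int(np.argmin(self._delta_ev()))
        else:
            worst = int(np.argmin(self.quality))
        orphan_idx = np.asarray(self.members.pop(worst))
        self.cmaps = np.delete(self.cmaps, worst, axis=0)
        self.quality = np.delete(self.quality, worst)
        assign = np.argmax(np.abs(self.unit[orphan_idx] @ self.cmaps.T), axis=1)
        touched = set()
        for i, j in zip(orphan_idx, assign):
            self.members[int(j)].append(int(i))
            touched.add(int(j))
        for j in touched:
            self._recompute(j)

    def run_to(self, k: int) -> None:
        while self.n_clusters > k:
            self.atomize_step()

    def polish(self) -> None:
        for j in range(self.n_clusters):
            self._recompute(j, exact=True)

    def explained_variance(self) -> float:
        return float(self.quality.sum() / self.w.sum())

    def dispersion(self) -> float:
        """Polarity-invariant within-cluster weighted sum of squares."""
        return float(self.w.sum() - self.quality.sum())

    def template_set(self, level: str = "subject") -> TemplateSet:
        self.polish()
        order = np.argsort(-self.quality, kind="stable")
        maps = self.cmaps[order]
        labels = tuple(CLASS_LETTERS[i] for i in range(len(order)))
        return TemplateSet(maps, labels, level, self.explained_variance())


def aahc_cluster(peak_maps: np.ndarray, k_target: int,
                 gfps: np.ndarray | None = None,
                 level: str = "subject") -> TemplateSet:
    """Atomize-agglomerate hierarchical clustering down to ``k_target``.

    Deterministic: starts from singleton clusters and repeatedly
    dissolves the cluster contributing least explained variance,
    reassigning its members by maximal polarity-invariant correlation.
    """
    peak_maps = np.atleast_2d(np.asarray(peak_maps, dtype=float))
    if k_target < 1:
        raise InvalidParameterError("k_target must be >= 1")
    if k_target > len(peak_maps):
        raise InvalidParameterError(
            f"k_target {k_target} exceeds map count {len(peak_maps)}")
    state = _AahcState(peak_maps, gfps)
    if k_target > state.n_clusters:
        raise InvalidParameterError("too few nonzero maps for k_target")
    state.run_to(k_target)
    return state.template_set(level)


def modified_kmeans(peak_maps: np.ndarray, k: int, n_restarts: int = 10,
                    seed: int = 0, gfps: np.ndarray | None = None,
                    max_iter: int = 200, level: str = "subject") -> TemplateSet:
    """Polarity-invariant k-means on GFP-peak maps; best restart kept."""
    unit, g = _normalize_maps(peak_maps)
    if gfps is not None:
        g = np.asarray(gfps, dtype=float)[: len(unit)]
    if k > len(unit):
        raise InvalidParameterError(f"k {k} exceeds map count {len(unit)}")
    w = g ** 2
    rng = np.random.default_rng(seed)
    best_ev, best_maps = -np.inf, None
    for _ in range(n_restarts):
        centers = unit[rng.choice(len(unit), size=k, replace=False)]
        prev = None
        for _ in range(max_iter):
            proj = np.abs(unit @ centers.T)
            assign = np.argmax(proj, axis=1)
            if prev is not None and np.array_equal(assign, prev):
                break
            prev = assign
            for j in range(k):
                sel = assign == j
                if not sel.any():  # re-seed an empty cluster
                    sel = np.zeros(len(unit), bool)
                    sel[int(rng.integers(len(unit)))] = True
                centers[j] = _principal_orientation(unit[sel], w[sel])
        ev = float(w @ (np.max(np.abs(unit @ centers.T), axis=1) ** 2) / w.sum())
        if ev > best_ev:
            best_ev, best_maps = ev, centers.copy()
    order = np.argsort(
        -np.array([w[np.argmax(np.abs(unit @ best_maps.T), axis=1) == j].sum()
                   for j in range(k)]), kind="stable")
    labels = tuple(CLASS_LETTERS[i] for i in range(k))
    return TemplateSet(best_maps[order], labels, level, best_ev)


@dataclass
class KSelection:
    k_values: np.ndarray
    kl_scores: np.ndarray
    cv_scores: np.ndarray
    selected_k: int
    low_confidence: bool
    dispersion: np.ndarray = field(default=None)  # type: ignore[assignment]


def choose_k(peak_maps: np.ndarray, k_range: tuple[int, int] = (2, 8),
             gfps: np.ndarray | None = None) -> KSelection:
    """Score candidate cluster counts by the KL and CV criteria.

    One hierarchical pass yields the dispersion curve W(k); the
    Krzanowski-Lai score compares successive penalized drops of W and
    the selected k maximizes it. The cross-validation criterion (the
    residual variance penalized by ((C-1)/(C-1-k))^2) is reported
    alongside. A selection is flagged low-confidence when the winning
    KL score is less than twice the median of the others.
    """
    kmin, kmax = k_range
    peak_maps = np.atleast_2d(np.asarray(peak_maps, dtype=float))
    n, c = peak_maps.shape
    if kmax - kmin < 1:
        raise InvalidParameterError("k_range must span at least 2 values")
    if kmin < 2 or kmax > n - 1:
        raise InvalidParameterError("k_range must lie within [2, map count - 1]")
    if kmax + 1 >= c - 1:
        raise InvalidParameterError("k_range too large for the channel count")
    state = _AahcState(peak_maps, gfps)
    total_w = state.w.sum()
    disp: dict[int, float] = {}
    lo = max(kmin - 1, 1)
    for k in range(state.n_clusters, lo - 1, -1):
        state.run_to(k)
        if lo <= k <= kmax + 1:
            state.polish()
            disp[k] = state.dispersion()
    ks = np.arange(kmin, kmax + 1)

    def _diff(k: int) -> float:
        wk1 = disp.get(k - 1, total_w if k - 1 == 0 else None)
        return ((k - 1) ** (2.0 / c) * wk1 if k > 1 else 0.0) - k ** (2.0 / c) * disp[k]

    kl = np.array([max(_diff(k), 0.0) / max(abs(_diff(k + 1)), 1e-12)
                   for k in ks])
    sigma2 = np.array([disp[k] / (n * (c - 1)) for k in ks])
    cv = sigma2 * ((c - 1) / (c - 1 - ks)) ** 2
    sel = int(ks[int(np.argmax(kl))])
    best = float(np.max(kl))
    others = np.delete(kl, int(np.argmax(kl)))
    low_conf = bool(best < 2.0 * np.median(others)) if others.size else False
    return KSelection(ks, kl, cv, sel, low_conf,
                      np.array([disp[k] for k in ks]))


# ---------------------------------------------------------------------------
# Label alignment and the two-level pipeline

def _greedy_match(maps: np.ndarray, ref_maps: np.ndarray) -> np.ndarray:
    """order[j] = index into ``maps`` matched to reference map j."""
    corr = np.abs(maps @ ref_maps.T)  # rows: maps, cols: reference
    order = np.full(ref_maps.shape[0], -1)
    used_rows: set[int] = set()
    work = corr.copy()
    for _ in range(min(maps.shape[0], ref_maps.shape[0])):
        i, j = np.unravel_index(np.argmax(work), work.shape)
        order[j] = i
        used_rows.add(int(i))
        work[i, :] = -np.inf
        work[:, j] = -np.inf
    return order


def align_to_reference(ts: TemplateSet, ref: TemplateSet) -> TemplateSet:
    """Relabel ``ts`` so each map takes the class of its best reference match."""
    order = _greedy_match(ts.maps, ref.maps)
    return ts.relabeled(tuple(ref.class_labels), order)


def two_level_templates(recordings: dict[tuple[str, str, str], Recording | Epochs],
                        k: int = 4, min_separation_ms: float = 10.0,
                        max_maps_per_subject: int | None = None,
                        ) -> dict[str, object]:
    """Subject -> subgroup -> grand clustering with aligned class labels.

    ``recordings`` maps (subject_id, group, condition) to 2-20 Hz
    filtered data. Subject-level templates are clustered per recording;
    subgroup (group x condition) level clusters the pooled subject maps;
    the grand level clusters all subject maps and anchors the A..D
    labels. Subjects yielding no usable maps are excluded with a warning.
    """
    subject_sets: dict[tuple[str, str, str], TemplateSet] = {}
    for key in sorted(recordings):
        try:
            maps, gfps = gfp_peak_maps(recordings[key], min_separation_ms,
                                       max_maps=max_maps_per_subject)
            subject_sets[key] = aahc_cluster(maps, k, gfps, level="subject")
        except (EmptyResultError, InvalidParameterError) as exc:
            logger.warning("excluding %s from clustering: %s", key, exc)
    if not subject_sets:
        raise EmptyResultError("no subject yielded usable GFP-peak maps")

    all_maps = np.vstack([ts.maps for ts in subject_sets.values()])
    grand = aahc_cluster(all_maps, k, np.ones(len(all_maps)), level="grand")
    grand = TemplateSet(grand.maps, tuple(CLASS_LETTERS[:k]), "grand",
                        grand.explained_variance)

    group_sets: dict[tuple[str, str], TemplateSet] = {}
    for (subj, grp, cond), ts in subject_sets.items():
        group_sets.setdefault((grp, cond), None)
    for grp_cond in sorted(group_sets):
        pooled = np.vstack([ts.maps for key, ts in subject_sets.items()
                            if (key[1], key[2]) == grp_cond])
        gs = aahc_cluster(pooled, k, np.ones(len(pooled)), level="group")
        group_sets[grp_cond] = align_to_reference(gs, grand)

    subject_aligned = {key: align_to_reference(ts, grand)
                       for key, ts in subject_sets.items()}
    return {"grand": grand, "group": group_sets, "subject": subject_aligned}


# ---------------------------------------------------------------------------
# Back-fitting

def _nearest_peak_fill(peak_idx: np.ndarray, peak_labels: np.ndarray,
                       n_samples: int) -> np.ndarray:
    """Nearest-neighbor label interpolation; ties go to the earlier peak."""
    cuts = (peak_idx[:-1] + peak_idx[1:]) / 2.0
    which = np.searchsorted(cuts, np.arange(n_samples), side="left")
    return peak_labels[which]


def backfit(data: Recording | Epochs, templates: TemplateSet,
            min_separation_ms: float = 10.0) -> LabelSequence:
    """Label every sample by its nearest GFP peak's best-matching template.

    Peaks are labeled by argmax polarity-invariant spatial correlation
    (ties resolved to the lowest class index); non-peak samples take the
    label of the nearest peak. Epoched input is back-fitted epoch by
    epoch over the retained epochs.
    """
    tmaps, _ = _normalize_maps(templates.maps)
    if isinstance(data, Recording):
        blocks = [data.data]
        fs = data.fs_hz
    else:
        blocks = list(data.retained)
        fs = data.fs_hz
    if blocks and blocks[0].shape[0] != templates.n_channels:
        raise DimensionError("recording/template channel count mismatch")
    parts, starts, pos = [], [], 0
    for block in blocks:
        block = block - block.mean(axis=0, keepdims=True)
        g = GfpSeries(np.sqrt((block ** 2).mean(axis=0)), fs)
        peaks = find_gfp_peaks(g, min_separation_ms)
        if peaks.size == 0:
            raise EmptyResultError("no GFP peaks to back-fit")
        maps, _ = _normalize_maps(block[:, peaks].T)
        corr = np.abs(maps @ tmaps.T)
        peak_labels = np.argmax(corr, axis=1)
        parts.append(_nearest_peak_fill(peaks, peak_labels, block.shape[1]))
        starts.append(pos)
        pos += block.shape[1]
    return LabelSequence(np.concatenate(parts), fs, templates.k,
                         source="backfit", epoch_starts=np.array(starts))


def peak_label_accuracy(data: Recording, templates: TemplateSet,
                        truth: LabelSequence,
                        min_separation_ms: float = 10.0) -> float:
    """Fraction of GFP peaks whose back-fit label matches the truth."""
    fitted = backfit(data, templates, min_separation_ms)
    g = gfp(data)
    peaks = find_gfp_peaks(g, min_separation_ms)
    return float(np.mean(fitted.labels[peaks] == truth.labels[peaks]))


# ---------------------------------------------------------------------------
# Temporal metrics and syntax

def _runs(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encoding -> (state per run, length per run)."""
    if labels.size == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    change = np.flatnonzero(np.diff(labels) != 0) + 1
    bounds = np.r_[0, change, len(labels)]
    return labels[bounds[:-1]], np.diff(bounds)


def microstate_metrics(labels: LabelSequence,
                       class_labels: tuple[str, ...] | None = None
                       ) -> pd.DataFrame:
    """Duration (ms), occurrence (/s) and coverage per state.

    Computed per epoch and averaged with equal epoch weights; runs
    truncated by epoch boundaries are included. UNASSIGNED samples (-1)
    are excluded from coverage.
    """
    if labels.labels.size == 0:
        raise EmptyResultError("empty label sequence")
    k = labels.k
    dur_sum = np.zeros(k)
    dur_n = np.zeros(k)
    occ = np.zeros(k)
    cov = np.zeros(k)
    n_epochs = 0
    for ep in labels.epochs():
        ep = ep[ep >= 0] if (ep < 0).any() else ep
        if ep.size == 0:
            continue
        n_epochs += 1
        states, lengths = _runs(ep)
        t_total = ep.size / labels.fs_hz
        for s in range(k):
            sel = states == s
            if sel.any():
                dur_sum[s] += lengths[sel].mean() * 1000.0 / labels.fs_hz
                dur_n[s] += 1
            occ[s] += sel.sum() / t_total
            cov[s] += lengths[sel].sum() / ep.size
    if n_epochs == 0:
        raise EmptyResultError("no labeled samples")
    with np.errstate(invalid="ignore"):
        duration = np.where(dur_n > 0, dur_sum / np.maximum(dur_n, 1), np.nan)
    idx = list(class_labels) if class_labels else list(range(k))
    return pd.DataFrame({"duration_ms": duration,
                         "occurrence_per_s": occ / n_epochs,
                         "coverage": cov / n_epochs},
                        index=pd.Index(idx, name="state"))


def transition_probabilities(labels: LabelSequence) -> np.ndarray:
    """K x K row-normalized run-to-run transition probabilities.

    Self-transitions are impossible by construction; transitions across
    epoch boundaries are not counted. Rows with no outgoing transition
    stay all-zero (flagged with a warning).
    """
    k = labels.k
    counts = np.zeros((k, k))
    for ep in labels.epochs():
        ep = ep[ep >= 0] if (ep < 0).any() else ep
        states, _ = _runs(ep)
        for a, b in zip(states[:-1], states[1:]):
            counts[a, b] += 1
    if counts.sum() == 0:
        logger.warning("single run: all-zero transition matrix")
        return counts
    row_sums = counts.sum(axis=1, keepdims=True)
    zero_rows = np.flatnonzero(row_sums[:, 0] == 0)
    if zero_rows.size:
        logger.warning("states with no outgoing transition: %s",
                       zero_rows.tolist())
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(row_sums > 0, counts / row_sums, 0.0)
    return probs
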