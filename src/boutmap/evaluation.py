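"""Ground-truth evaluation of the pipeline on synthetic experiments.

Each routine generates one or more seeded synthetic trials under the
default study conditions, runs the relevant pipeline stages, and scores
the result against the planted ground truth: bout detection
recall/precision, archetype classification rates, cluster recovery,
pixel-map contrast (ROC AUC of in-footprint vs background pixels), and
bleed-through factor recovery.  Used by the test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np

from .classify import classify_rois
from .cluster import cluster_traces
from .events import (
    STIMULUS_WINDOW,
    SWIM_WINDOW,
    select_stimulus_events,
    select_swim_events,
    extract_windows,
)
from .kinematics import BoutDetector
from .maps import compute_cluster_map
from .preprocess import (
    correct_bleedthrough,
    dff,
    estimate_bleedthrough,
    extract_roi_traces,
    spatial_mean_filter,
)
from .stimulus import StimulusSchedule, make_schedule
from .synthetic import (
    BoutParams,
    NoiseParams,
    PlantedBout,
    generate_movie,
    generate_tail_trace,
    ground_truth_dff,
    make_scene,
    simulate_traces,
    DEFAULT_FRAME_RATE_HZ,
)

__all__ = [
    "bout_detection_scores",
    "scene_classification",
    "classification_summary",
    "noise_free_partition_exact",
    "map_contrast_auc",
    "zero_noise_map_min_correlation",
    "bleed_recovery_error",
]

N_PLANTED_ARCHETYPES = 4  # swim_locked, stim_on, mixed, stim_suppressed


def _default_schedule() -> StimulusSchedule:
    return make_schedule(315.0, 10.0, 5.0)


def bout_detection_scores(
    seeds, tolerance_s: float = 0.05, schedule: StimulusSchedule | None = None
) -> dict:
    """Recall/precision of detected vs planted bout starts."""
    schedule = schedule or _default_schedule()
    detector = BoutDetector()
    n_planted = n_detected = n_recalled = n_correct = 0
    for seed in seeds:
        trace, planted = generate_tail_trace(schedule, 250.0, BoutParams(), seed=int(seed))
        detected = [b for b in detector.detect(trace) if not b.is_excluded]
        p = np.array([b.start_s for b in planted])
        d = np.array([b.start_s for b in detected])
        n_planted += p.size
        n_detected += d.size
        if p.size and d.size:
            n_recalled += int(sum(np.abs(d - s).min() <= tolerance_s for s in p))
            n_correct += int(sum(np.abs(p - s).min() <= tolerance_s for s in d))
    return {
        "recall": n_recalled / max(n_planted, 1),
        "precision": n_correct / max(n_detected, 1),
        "n_planted": n_planted,
    }


def scene_classification(
    seed: int,
    n_per_archetype: int = 20,
    min_size: int | None = None,
    dff_noise_sd: float = 0.05,
    schedule: StimulusSchedule | None = None,
) -> dict:
    """Classify and cluster one synthetic scene against its ground truth.

    ROI traces are simulated at trace level (matched SNR to the rendered
    movie); ``min_size`` defaults to half the per-archetype count, the
    scaled analogue of the full-scale minimum of 50.
    """
    schedule = schedule or _default_schedule()
    if min_size is None:
        min_size = max(2, n_per_archetype // 2)
    scene = make_scene(n_per_archetype, seed=seed)
    _, planted = generate_tail_trace(schedule, 250.0, BoutParams(), seed=seed)
    dff_mat, _ = simulate_traces(
        scene, schedule, planted, dff_noise_sd=dff_noise_sd, seed=seed
    )
    swim_ev = select_swim_events(planted, SWIM_WINDOW, schedule.trial_duration)
    stim_ev = select_stimulus_events(schedule, STIMULUS_WINDOW)
    table, swim_sets, stim_sets = classify_rois(
        dff_mat, DEFAULT_FRAME_RATE_HZ, swim_ev, stim_ev
    )
    cat = table.set_index("roi_id")["category"]

    n_clusters = 0
    for category, sets in (("swim_driven", swim_sets), ("stimulus_driven", stim_sets)):
        ids = [i for i in table.loc[table["category"] == category, "roi_id"] if i in sets]
        if not ids:
            continue
        waveforms = np.asarray([sets[i].average for i in ids])
        clusters, _ = cluster_traces(waveforms, threshold=0.75, min_size=min_size)
        n_clusters += len(clusters)

    return {
        "swim_locked_as_swim_driven": float(
            (cat[scene.rois_of("swim_locked")] == "swim_driven").mean()
        ),
        "stim_on_as_stimulus_driven": float(
            (cat[scene.rois_of("stim_on")] == "stimulus_driven").mean()
        ),
        "mixed_unclassified": float(
            (cat[scene.rois_of("mixed")] == "unclassified").mean()
        ),
        "n_clusters": n_clusters,
    }


def classification_summary(seeds, n_per_archetype: int = 20) -> dict:
    """Aggregate scene_classification over seeds."""
    per_seed = [scene_classification(int(s), n_per_archetype) for s in seeds]
    return {
        "swim_locked_as_swim_driven": float(
            np.mean([r["swim_locked_as_swim_driven"] for r in per_seed])
        ),
        "stim_on_as_stimulus_driven": float(
            np.mean([r["stim_on_as_stimulus_driven"] for r in per_seed])
        ),
        "mixed_unclassified": float(
            np.mean([r["mixed_unclassified"] for r in per_seed])
        ),
        "cluster_recovery_rate": float(
            np.mean([r["n_clusters"] == N_PLANTED_ARCHETYPES for r in per_seed])
        ),
        "n_clusters_per_seed": [r["n_clusters"] for r in per_seed],
    }


def noise_free_partition_exact(seed: int = 3, n_per_archetype: int = 20) -> bool:
    """Does clustering recover the planted partition exactly without noise?"""
    schedule = _default_schedule()
    scene = make_scene(n_per_archetype, seed=seed)
    _, planted = generate_tail_trace(schedule, 250.0, BoutParams(), seed=seed)
    clean, _ = ground_truth_dff(scene, schedule, planted)
    swim_ev = select_swim_events(planted, SWIM_WINDOW, schedule.trial_duration)
    stim_ev = select_stimulus_events(schedule, STIMULUS_WINDOW)
    arch = np.asarray(scene.archetypes)
    min_size = max(2, n_per_archetype // 2)

    groups = [
        (("swim_locked",), swim_ev, SWIM_WINDOW),
        (("stim_on", "mixed", "stim_suppressed"), stim_ev, STIMULUS_WINDOW),
    ]
    for members, events, spec in groups:
        idx = np.flatnonzero(np.isin(arch, members))
        waveforms = np.asarray(
            [extract_windows(clean[i], DEFAULT_FRAME_RATE_HZ, events, spec).average
             for i in idx]
        )
        clusters, labels = cluster_traces(
            waveforms, threshold=0.75, min_size=min_size, roi_ids=idx
        )
        if len(clusters) != len(members):
            return False
        for c in clusters:
            if len(set(arch[c.member_ids])) != 1 or c.n_members != n_per_archetype:
                return False
    return True


def _movie_scene(seed, frame_shape=(64, 48), n_per_archetype=3, bleed=0.2):
    counts = {a: n_per_archetype for a in
              ("swim_locked", "stim_on", "mixed", "stim_suppressed")}
    counts["silent"] = max(1, n_per_archetype // 2)
    return make_scene(counts, frame_shape=frame_shape, bleed_factor=bleed, seed=seed)


def map_contrast_auc(seed: int, noise: NoiseParams = NoiseParams()) -> float:
    """ROC AUC separating in-footprint from background pixels by map value.

    One rendered trial; every archetype's final correlation map is scored
    against its own footprints, pooled into a single AUC.
    """
    from scipy import ndimage
    from sklearn.metrics import roc_auc_score

    schedule = _default_schedule()
    scene = _movie_scene(seed, bleed=0.0)
    _, planted = generate_tail_trace(schedule, 250.0, BoutParams(), seed=seed)
    green, _, _, _ = generate_movie(
        scene, schedule, planted, noise=noise, simulate_bleed=False, seed=seed
    )
    filtered = spatial_mean_filter(green, 2)
    raw = extract_roi_traces(green, scene.footprints)
    dff_mat = dff(raw, DEFAULT_FRAME_RATE_HZ)
    swim_ev = select_swim_events(planted, SWIM_WINDOW, schedule.trial_duration)
    stim_ev = select_stimulus_events(schedule, STIMULUS_WINDOW)
    background = ~ndimage.binary_dilation(scene.footprint_mask(), iterations=2)

    ys, xs = [], []
    for arch, events, spec in (
        ("swim_locked", swim_ev, SWIM_WINDOW),
        ("stim_on", stim_ev, STIMULUS_WINDOW),
        ("mixed", stim_ev, STIMULUS_WINDOW),
        ("stim_suppressed", stim_ev, STIMULUS_WINDOW),
    ):
        rois = scene.rois_of(arch)
        centroid = np.mean(
            [extract_windows(dff_mat[i], DEFAULT_FRAME_RATE_HZ, events, spec).average
             for i in rois],
            axis=0,
        )
        cmap = compute_cluster_map(filtered, centroid, events, spec, cluster_id=arch)
        fp = scene.footprints[rois].sum(axis=0) > 0
        ys.append(np.concatenate([np.ones(fp.sum()), np.zeros(background.sum())]))
        xs.append(np.concatenate([cmap.values[fp], cmap.values[background]]))
    y = np.concatenate(ys)
    x = np.concatenate(xs)
    keep = np.isfinite(x)
    return float(roc_auc_score(y[keep], x[keep]))


def zero_noise_map_min_correlation(seed: int = 1) -> float:
    """Minimum in-footprint correlation for matching clusters, zero noise.

    Uses a deterministic periodic bout train (one bout per stimulus cycle,
    1 s after motion onset) so all event windows are identical and the
    number measures the map machinery rather than bout-process
    variability.
    """
    schedule = _default_schedule()
    scene = _movie_scene(seed, bleed=0.0)
    bouts = [PlantedBout(t_on + 1.0, t_on + 1.3, 30.0) for t_on, _ in schedule.intervals]
    green, _, gt_dff, _ = generate_movie(
        scene, schedule, bouts, noise=NoiseParams(0, 0), simulate_bleed=False,
        seed=seed, gain_jitter_sd=0.0,
    )
    filtered = spatial_mean_filter(green, 2)
    swim_ev = select_swim_events(bouts, SWIM_WINDOW, schedule.trial_duration)
    stim_ev = select_stimulus_events(schedule, STIMULUS_WINDOW)
    worst = 1.0
    for arch, events, spec in (
        ("swim_locked", swim_ev, SWIM_WINDOW),
        ("stim_on", stim_ev, STIMULUS_WINDOW),
        ("mixed", stim_ev, STIMULUS_WINDOW),
        ("stim_suppressed", stim_ev, STIMULUS_WINDOW),
    ):
        rois = scene.rois_of(arch)
        centroid = extract_windows(
            gt_dff[rois[0]], DEFAULT_FRAME_RATE_HZ, events, spec
        ).average
        cmap = compute_cluster_map(filtered, centroid, events, spec)
        fp = scene.footprints[rois].sum(axis=0) > 0
        worst = min(worst, float(np.nanmin(cmap.values[fp])))
    return worst


def bleed_recovery_error(seed: int, noise: NoiseParams) -> float:
    """|estimated - planted| bleed-through factor on a rendered trial."""
    schedule = _default_schedule()
    scene = _movie_scene(seed, bleed=0.2)
    _, planted = generate_tail_trace(schedule, 250.0, BoutParams(), seed=seed)
    green, red, _, _ = generate_movie(scene, schedule, planted, noise=noise, seed=seed)
    est = estimate_bleedthrough(green, red)
    return abs(est - scene.bleed_factor)
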