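"""Evaluation of pipeline output against phantom ground truth.

Detections are matched to true bubble positions frame by frame (nearest
neighbor within a tolerance); from the matching, detection recall,
track-link accuracy and per-vessel speed recovery are derived.  These
utilities quantify how much of the simulated scene the pipeline
recovered and are the basis of the package's recovery experiments.
"""

from __future__ import annotations

import numpy as np

from .core import DetectionSet
from .mcmcda import Association
from .phantom import PhantomTruth

__all__ = [
    "match_detections",
    "detection_recall",
    "true_links",
    "link_accuracy",
    "per_vessel_mean_speeds",
]


def match_detections(
    dset: DetectionSet, truth: PhantomTruth, tolerance_um: float = 20.0
) -> dict[int, tuple[int, float]]:
    """Match detections to true bubbles: index → (bubble index, error µm).

    Per frame, each true bubble claims its nearest detection if within
    ``tolerance_um``; a detection is matched to at most one bubble
    (greedy by increasing distance).
    """
    det_by_frame: dict[int, list[int]] = {}
    for i, d in enumerate(dset.detections):
        det_by_frame.setdefault(d.frame, []).append(i)
    out: dict[int, tuple[int, float]] = {}
    for f, det_idx in det_by_frame.items():
        dpos = np.array([dset.detections[i].position for i in det_idx])
        pairs = []
        for bi, tr in enumerate(truth.bubble_tracks):
            hit = np.flatnonzero(tr.frames == f)
            if not hit.size:
                continue
            dists = np.linalg.norm(dpos - tr.positions[hit[0]], axis=1)
            j = int(np.argmin(dists))
            if dists[j] <= tolerance_um:
                pairs.append((float(dists[j]), bi, det_idx[j]))
        used: set[int] = set()
        for dist, bi, di in sorted(pairs):
            if di in used:
                continue
            used.add(di)
            out[di] = (bi, dist)
    return out


def detection_recall(
    dset: DetectionSet,
    truth: PhantomTruth,
    tolerance_um: float = 20.0,
    frames: set[int] | None = None,
) -> float:
    """Fraction of true bubble positions matched by a detection."""
    match = match_detections(dset, truth, tolerance_um)
    matched_bubble_frames = {
        (bi, dset.detections[di].frame) for di, (bi, _) in match.items()
    }
    n_true = n_hit = 0
    for bi, tr in enumerate(truth.bubble_tracks):
        for f in tr.frames:
            if frames is not None and int(f) not in frames:
                continue
            n_true += 1
            if (bi, int(f)) in matched_bubble_frames:
                n_hit += 1
    if n_true == 0:
        raise ValueError("phantom contains no bubble positions")
    return n_hit / n_true


def true_links(
    dset: DetectionSet, truth: PhantomTruth, tolerance_um: float = 20.0
) -> set[tuple[int, int]]:
    """Ground-truth detection pairs: consecutive matched detections of one bubble."""
    match = match_detections(dset, truth, tolerance_um)
    by_bubble: dict[int, list[int]] = {}
    for di, (bi, _) in match.items():
        by_bubble.setdefault(bi, []).append(di)
    links: set[tuple[int, int]] = set()
    for dis in by_bubble.values():
        dis.sort(key=lambda di: dset.detections[di].frame)
        links.update(zip(dis, dis[1:]))
    return links


def link_accuracy(
    assoc: Association, truth: PhantomTruth, tolerance_um: float = 20.0
) -> float:
    """Fraction of ground-truth links reproduced by the association."""
    truth_links = true_links(assoc.detection_set, truth, tolerance_um)
    if not truth_links:
        raise ValueError("no ground-truth links to compare against")
    pred: set[tuple[int, int]] = set()
    for tr in assoc.tracks:
        pred.update(zip(tr, tr[1:]))
    return len(truth_links & pred) / len(truth_links)


def per_vessel_mean_speeds(
    tracks, truth: PhantomTruth, tolerance_um: float = 60.0
) -> dict[int, float]:
    """Mean recovered track speed per vessel, keyed by segment index.

    Tracks are assigned to the vessel whose centreline passes closest to
    the track's mean position.
    """
    out: dict[int, list[float]] = {}
    for t in tracks:
        center = t.positions.mean(axis=0)
        best_si, best_d = None, np.inf
        for si, seg in enumerate(truth.segments):
            a, b = np.asarray(seg.start), np.asarray(seg.end)
            ab = b - a
            u = np.clip(np.dot(center - a, ab) / np.dot(ab, ab), 0.0, 1.0)
            d = float(np.linalg.norm(center - (a + u * ab)))
            if d < best_d:
                best_si, best_d = si, d
        if best_si is not None and best_d <= tolerance_um:
            out.setdefault(best_si, []).append(t.mean_speed)
    return {si: float(np.mean(v)) for si, v in out.items()}
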