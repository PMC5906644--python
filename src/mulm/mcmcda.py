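"""Microbubble tracking by Markov Chain Monte Carlo Data Association.

At clinical frame rates and bubble concentrations the nearest detection
in the next frame is often the wrong continuation of a track, so
detections are grouped into trajectories by sampling over *associations*
— partitions of all detections into tracks and false alarms — with a
Markov chain whose stationary distribution is the Bayesian posterior

    P(omega | Y)  ∝  P(Y | omega) · P(omega)

where the likelihood term scores each track's measured positions under a
constant-velocity (linear) motion model via Kalman-filter innovations,
and the prior scores the association's structure (Poisson track births
and false alarms per frame, geometric track survival, binomial
detection/miss events).  The chain explores association space with
birth/death, extend/reduce, split/merge, tail-switch and update moves,
restricted by a speed gate; the highest-posterior association visited is
returned.

The association space is combinatorially huge; for tiny instances
(≤ 10 detections) ``exhaustive_map`` enumerates every valid partition
and serves as the exact oracle the sampler is tested against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import Detection, DetectionSet

__all__ = [
    "MotionModelParams",
    "Track",
    "Association",
    "association_log_likelihood",
    "association_log_prior",
    "run_mcmcda",
    "exhaustive_map",
    "tracks_to_kinematics",
]


@dataclass(frozen=True)
class MotionModelParams:
    """Parameters of the linear motion model and the association prior.

    Attributes
    ----------
    process_noise_sigma
        Std of the white acceleration driving the constant-velocity
        model, µm per frame² — how much a bubble may deviate from
        straight-line motion between frames.
    measurement_noise_sigma
        Localization noise std in µm.
    max_speed
        Gating speed in mm s⁻¹: candidate links implying a faster
        bubble are never proposed.
    p_detect
        Probability that a live bubble is detected in a frame.
    false_alarm_rate
        Expected false alarms per frame (Poisson).
    birth_rate
        Expected new tracks per frame (Poisson).
    p_terminate
        Per-frame probability that a live track ends.
    max_missed_frames
        Maximum interior frames a track may skip between detections.
    gate_slack_um
        Additive slack on the gate radius, absorbing localization noise.
    """

    process_noise_sigma: float = 2.0
    measurement_noise_sigma: float = 2.0
    max_speed: float = 5.0
    p_detect: float = 0.9
    false_alarm_rate: float = 1.0
    birth_rate: float = 0.5
    p_terminate: float = 0.1
    max_missed_frames: int = 2
    gate_slack_um: float = 10.0

    def __post_init__(self) -> None:
        for p in (self.p_detect, self.p_terminate):
            if not 0.0 < p < 1.0:
                raise ValueError("probabilities must lie in (0, 1)")
        if self.false_alarm_rate < 0 or self.birth_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.process_noise_sigma <= 0 or self.measurement_noise_sigma <= 0:
            raise ValueError("noise sigmas must be positive")

    def max_step_um(self, frame_rate: float, gap: int) -> float:
        """Gate radius for a link spanning ``gap`` frames."""
        return self.max_speed * 1000.0 / frame_rate * gap + self.gate_slack_um


@dataclass
class Track:
    """A finished trajectory with per-step kinematics.

    ``step_velocities`` holds one (axial, lateral) velocity vector in
    mm s⁻¹ per consecutive detection pair, computed gap-aware
    (Δposition / (frame gap / frame_rate)); ``directions`` the matching
    flow angles in radians, measured from the +lateral axis.
    """

    detections: list[Detection]
    step_velocities: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    directions: np.ndarray = field(default_factory=lambda: np.empty(0))
    mean_speed: float = 0.0

    def __post_init__(self) -> None:
        frames = [d.frame for d in self.detections]
        if len(frames) < 2:
            raise ValueError("a track needs at least two detections")
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("track frames must be strictly increasing")

    @property
    def frames(self) -> list[int]:
        return [d.frame for d in self.detections]

    @property
    def positions(self) -> np.ndarray:
        return np.array([d.position for d in self.detections], dtype=float)


@dataclass
class Association:
    """A partition of a DetectionSet into tracks and false alarms.

    ``tracks`` holds tuples of detection indices into
    ``detection_set.detections``; every index not in a track is a false
    alarm.  The partition is exact: each detection appears exactly once.
    """

    detection_set: DetectionSet
    tracks: list[tuple[int, ...]]
    log_likelihood: float
    log_prior: float

    @property
    def log_posterior(self) -> float:
        return self.log_likelihood + self.log_prior

    @property
    def false_alarms(self) -> frozenset[int]:
        used = {i for tr in self.tracks for i in tr}
        return frozenset(range(len(self.detection_set))) - used

    def validate(self) -> None:
        seen: set[int] = set()
        for tr in self.tracks:
            if len(tr) < 2:
                raise AssertionError("track with fewer than two detections")
            frames = [self.detection_set.detections[i].frame for i in tr]
            if any(b <= a for a, b in zip(frames, frames[1:])):
                raise AssertionError("track frames not strictly increasing")
            if seen & set(tr):
                raise AssertionError("detection assigned to two tracks")
            seen |= set(tr)
        if not seen <= set(range(len(self.detection_set))):
            raise AssertionError("track references unknown detection")


# ---------------------------------------------------------------------------
# scoring


def _track_log_likelihood(
    positions: np.ndarray,
    frames: np.ndarray,
    params: MotionModelParams,
    frame_rate: float,
    log_area: float,
) -> float:
    """Kalman innovation log-likelihood of one track's positions.

    The state is (position, velocity) per axis with a diffuse velocity
    prior at birth; the first detection is scored uniform over the ROI
    area (like a false alarm), subsequent detections by the Gaussian
    innovation density.  Both axes share the (isotropic) covariance
    recursion, so it is run once.
    """
    r2 = params.measurement_noise_sigma**2
    q2 = params.process_noise_sigma**2
    v0 = (params.max_speed * 1000.0 / frame_rate) ** 2  # diffuse velocity prior
    # mean per axis, covariance shared
    x = np.zeros((2, 2))  # rows: [pos, vel], cols: axial/lateral
    x[0] = positions[0]
    p = np.array([[r2, 0.0], [0.0, v0]])
    ll = -log_area
    for k in range(1, len(frames)):
        n = float(frames[k] - frames[k - 1])
        f = np.array([[1.0, n], [0.0, 1.0]])
        q = q2 * np.array([[n**4 / 4.0, n**3 / 2.0], [n**3 / 2.0, n**2]])
        x = f @ x
        p = f @ p @ f.T + q
        s = p[0, 0] + r2
        nu = positions[k] - x[0]
        ll += -math.log(2.0 * math.pi * s) - 0.5 * float(nu @ nu) / s
        gain = p[:, 0] / s
        x = x + np.outer(gain, nu)
        p = p - np.outer(gain, p[0, :])
    return ll


def _log_poisson(k: int, lam: float) -> float:
    if lam == 0.0:
        return 0.0 if k == 0 else -math.inf
    return k * math.log(lam) - lam - math.lgamma(k + 1)


def _track_log_prior(
    frames: np.ndarray, n_frames: int, params: MotionModelParams
) -> float:
    """Structural prior of one track: survival, termination, detect/miss."""
    first, last = int(frames[0]), int(frames[-1])
    alive = last - first  # frames survived after birth
    n_det = len(frames)
    n_miss = (last - first + 1) - n_det
    lp = alive * math.log(1.0 - params.p_terminate)
    lp += n_det * math.log(params.p_detect)
    lp += n_miss * math.log(1.0 - params.p_detect)
    if last < n_frames - 1:
        lp += math.log(params.p_terminate)
    return lp


def association_log_likelihood(assoc: Association, params: MotionModelParams) -> float:
    """Log P(Y | omega): Gaussian innovations for tracks, uniform clutter."""
    dset = assoc.detection_set
    log_area = math.log(dset.roi_area_um2)
    ll = -len(assoc.false_alarms) * log_area
    for tr in assoc.tracks:
        positions = np.array([dset.detections[i].position for i in tr])
        frames = np.array([dset.detections[i].frame for i in tr])
        ll += _track_log_likelihood(positions, frames, params, dset.frame_rate, log_area)
    return ll


def association_log_prior(assoc: Association, params: MotionModelParams) -> float:
    """Log P(omega): Poisson births/false alarms, survival, detect/miss."""
    dset = assoc.detection_set
    n_frames = dset.n_frames
    fa_per_frame = np.zeros(n_frames, dtype=int)
    for i in assoc.false_alarms:
        fa_per_frame[dset.detections[i].frame] += 1
    births_per_frame = np.zeros(n_frames, dtype=int)
    lp = 0.0
    for tr in assoc.tracks:
        frames = np.array([dset.detections[i].frame for i in tr])
        births_per_frame[frames[0]] += 1
        lp += _track_log_prior(frames, n_frames, params)
    for t in range(n_frames):
        lp += _log_poisson(int(fa_per_frame[t]), params.false_alarm_rate)
        lp += _log_poisson(int(births_per_frame[t]), params.birth_rate)
    return lp


class _Scorer:
    """Incremental association scoring with per-track caches."""

    def __init__(self, dset: DetectionSet, params: MotionModelParams) -> None:
        self.dset = dset
        self.params = params
        self.log_area = math.log(dset.roi_area_um2)
        self.frames = np.array([d.frame for d in dset.detections], dtype=int)
        self.positions = dset.positions()
        self._track_cache: dict[tuple[int, ...], float] = {}

    def track_score(self, tr: tuple[int, ...]) -> float:
        """Likelihood + structural prior of one track (cached)."""
        cached = self._track_cache.get(tr)
        if cached is not None:
            return cached
        frames = self.frames[list(tr)]
        s = _track_log_likelihood(
            self.positions[list(tr)], frames, self.params, self.dset.frame_rate, self.log_area
        ) + _track_log_prior(frames, self.dset.n_frames, self.params)
        self._track_cache[tr] = s
        return s

    def total(self, tracks: list[tuple[int, ...]]) -> float:
        n = len(self.dset)
        used = {i for tr in tracks for i in tr}
        n_fa = n - len(used)
        score = -n_fa * self.log_area
        fa_per_frame = np.zeros(self.dset.n_frames, dtype=int)
        births = np.zeros(self.dset.n_frames, dtype=int)
        for i in range(n):
            if i not in used:
                fa_per_frame[self.frames[i]] += 1
        for tr in tracks:
            births[self.frames[tr[0]]] += 1
            score += self.track_score(tr)
        for t in range(self.dset.n_frames):
            score += _log_poisson(int(fa_per_frame[t]), self.params.false_alarm_rate)
            score += _log_poisson(int(births[t]), self.params.birth_rate)
        return score


def _gated_links(dset: DetectionSet, params: MotionModelParams) -> list[list[int]]:
    """forward[i] = detections j reachable from i within the speed gate."""
    n = len(dset)
    frames = np.array([d.frame for d in dset.detections])
    pos = dset.positions()
    forward: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        for j in range(n):
            gap = frames[j] - frames[i]
            if gap < 1 or gap > params.max_missed_frames + 1:
                continue
            if np.linalg.norm(pos[j] - pos[i]) <= params.max_step_um(dset.frame_rate, int(gap)):
                forward[i].append(j)
    return forward


def _canonical(tracks: list[tuple[int, ...]]) -> tuple[tuple[int, ...], ...]:
    return tuple(sorted(tracks))


def _make_association(
    dset: DetectionSet, tracks: list[tuple[int, ...]], params: MotionModelParams
) -> Association:
    assoc = Association(
        detection_set=dset,
        tracks=sorted(tracks),
        log_likelihood=0.0,
        log_prior=0.0,
    )
    assoc.log_likelihood = association_log_likelihood(assoc, params)
    assoc.log_prior = association_log_prior(assoc, params)
    return assoc


# ---------------------------------------------------------------------------
# exhaustive oracle


def exhaustive_map(
    dset: DetectionSet,
    params: MotionModelParams,
    max_detections: int = 10,
) -> Association:
    """Enumerate every valid association and return the exact MAP.

    Guarded to tiny instances — the number of partitions explodes
    combinatorially — and used as the ground-truth oracle for the
    sampler.  Ties are broken toward fewer tracks, then lexicographic
    track order.
    """
    n = len(dset)
    if n > max_detections:
        raise ValueError(
            f"exhaustive enumeration refused for {n} > {max_detections} detections"
        )
    if n == 0:
        return _make_association(dset, [], params)
    forward = _gated_links(dset, params)
    frames = [d.frame for d in dset.detections]
    scorer = _Scorer(dset, params)

    best: tuple[float, int, tuple] | None = None
    best_tracks: list[tuple[int, ...]] | None = None

    open_tracks: list[list[int]] = []

    def recurse(k: int) -> None:
        nonlocal best, best_tracks
        if k == n:
            if any(len(tr) == 1 for tr in open_tracks):
                return  # singleton "track" duplicates the false-alarm branch
            tracks = [tuple(tr) for tr in open_tracks]
            score = scorer.total(tracks)
            canon = _canonical(tracks)
            key = (-score, len(tracks), canon)
            if best is None or key < best:
                best = key
                best_tracks = tracks
            return
        # option 1: false alarm
        recurse(k + 1)
        # option 2: extend an open track
        for tr in open_tracks:
            tail = tr[-1]
            if frames[tail] < frames[k] and k in forward[tail]:
                tr.append(k)
                recurse(k + 1)
                tr.pop()
        # option 3: start a new track (canonical: only as the earliest member)
        open_tracks.append([k])
        recurse(k + 1)
        open_tracks.pop()

    recurse(0)
    assert best_tracks is not None
    return _make_association(dset, best_tracks, params)


# ---------------------------------------------------------------------------
# the sampler


def run_mcmcda(
    dset: DetectionSet,
    params: MotionModelParams | None = None,
    n_iterations: int | None = None,
    seed: int = 0,
    debug_validate: bool = False,
) -> Association:
    """Sample associations with Metropolis–Hastings; return the best visited.

    Starts from the all-false-alarm association and explores with
    birth/death, extend/reduce, split/merge, tail-switch and update
    moves; proposals are restricted to speed-gated links.  The chain
    targets the association posterior (birth/death acceptance carries
    the proposal-probability correction; the remaining moves are treated
    as symmetric).  The highest-posterior association visited is
    returned, so the result can only improve on the initial state.
    Deterministic for a fixed seed.
    """
    params = params or MotionModelParams()
    n = len(dset)
    if n == 0:
        return _make_association(dset, [], params)
    if n_iterations is None:
        n_iterations = 2000 * n
    rng = np.random.default_rng(seed)
    forward = _gated_links(dset, params)
    backward: list[list[int]] = [[] for _ in range(n)]
    for i, js in enumerate(forward):
        for j in js:
            backward[j].append(i)
    frames = [d.frame for d in dset.detections]
    by_frame_idx: dict[int, list[int]] = {}
    for i, f in enumerate(frames):
        by_frame_idx.setdefault(f, []).append(i)
    scorer = _Scorer(dset, params)
    log_area = scorer.log_area
    lam_f, lam_b = params.false_alarm_rate, params.birth_rate

    # chain state, scored incrementally: moves touch at most two tracks
    tracks: list[tuple[int, ...]] = []
    assigned: set[int] = set()
    fa_per_frame = np.zeros(dset.n_frames, dtype=int)
    for f in frames:
        fa_per_frame[f] += 1
    births = np.zeros(dset.n_frames, dtype=int)
    current = scorer.total(tracks)
    best_key = (-current, 0, ())
    best_tracks: list[tuple[int, ...]] = []

    def delta_score(
        removed_idx: list[int], added: list[tuple[int, ...]]
    ) -> float:
        d = 0.0
        fa_delta: dict[int, int] = {}
        birth_delta: dict[int, int] = {}
        for idx in removed_idx:
            tr = tracks[idx]
            d -= scorer.track_score(tr)
            d += len(tr) * -log_area  # members revert to false alarms
            birth_delta[frames[tr[0]]] = birth_delta.get(frames[tr[0]], 0) - 1
            for i in tr:
                fa_delta[frames[i]] = fa_delta.get(frames[i], 0) + 1
        for tr in added:
            d += scorer.track_score(tr)
            d -= len(tr) * -log_area
            birth_delta[frames[tr[0]]] = birth_delta.get(frames[tr[0]], 0) + 1
            for i in tr:
                fa_delta[frames[i]] = fa_delta.get(frames[i], 0) - 1
        for t, dv in fa_delta.items():
            if dv:
                k = int(fa_per_frame[t])
                d += _log_poisson(k + dv, lam_f) - _log_poisson(k, lam_f)
        for t, dv in birth_delta.items():
            if dv:
                k = int(births[t])
                d += _log_poisson(k + dv, lam_b) - _log_poisson(k, lam_b)
        return d

    def apply(removed_idx: list[int], added: list[tuple[int, ...]]) -> None:
        for idx in sorted(removed_idx, reverse=True):
            tr = tracks.pop(idx)
            births[frames[tr[0]]] -= 1
            for i in tr:
                assigned.discard(i)
                fa_per_frame[frames[i]] += 1
        for tr in added:
            tracks.append(tr)
            births[frames[tr[0]]] += 1
            for i in tr:
                assigned.add(i)
                fa_per_frame[frames[i]] -= 1

    Proposal = tuple[list[int], list[tuple[int, ...]], float, float]

    def propose_birth() -> Proposal | None:
        """Grow a new track from a random unassigned seed detection."""
        n_free = n - len(assigned)
        if n_free == 0:
            return None
        log_q = -math.log(n_free)
        seed_det = -1
        for _ in range(30):  # rejection-sample a uniform unassigned detection
            cand = int(rng.integers(n))
            if cand not in assigned:
                seed_det = cand
                break
        if seed_det < 0:
            return None
        tr = [seed_det]
        cont = 0.7
        while True:
            cands = [j for j in forward[tr[-1]] if j not in assigned and j not in tr]
            if not cands:
                break
            if len(tr) >= 2:
                if rng.random() >= cont:
                    log_q += math.log(1.0 - cont)
                    break
                log_q += math.log(cont)
            j = int(cands[rng.integers(len(cands))])
            log_q += -math.log(len(cands))
            tr.append(j)
        if len(tr) < 2:
            return None
        # reverse move: a death picking this track among len(tracks)+1
        log_q_rev = -math.log(len(tracks) + 1)
        return [], [tuple(tr)], log_q, log_q_rev

    def propose_death() -> Proposal | None:
        if not tracks:
            return None
        idx = int(rng.integers(len(tracks)))
        log_q = -math.log(len(tracks))
        # reverse: a birth seeded at one of the freed detections; the full
        # construction-path probability is approximated by the seed term
        n_free_after = n - len(assigned) + len(tracks[idx])
        log_q_rev = -math.log(n_free_after)
        return [idx], [], log_q, log_q_rev

    def propose_extend() -> Proposal | None:
        if not tracks:
            return None
        idx = int(rng.integers(len(tracks)))
        tr = list(tracks[idx])
        if rng.random() < 0.5:
            cands = [j for j in forward[tr[-1]] if j not in assigned]
            if not cands:
                return None
            tr.append(int(cands[rng.integers(len(cands))]))
        else:
            cands = [j for j in backward[tr[0]] if j not in assigned]
            if not cands:
                return None
            tr.insert(0, int(cands[rng.integers(len(cands))]))
        return [idx], [tuple(tr)], 0.0, 0.0

    def propose_reduce() -> Proposal | None:
        longs = [i for i, tr in enumerate(tracks) if len(tr) >= 3]
        if not longs:
            return None
        idx = int(longs[rng.integers(len(longs))])
        tr = list(tracks[idx])
        tr = tr[:-1] if rng.random() < 0.5 else tr[1:]
        return [idx], [tuple(tr)], 0.0, 0.0

    def propose_split() -> Proposal | None:
        longs = [i for i, tr in enumerate(tracks) if len(tr) >= 4]
        if not longs:
            return None
        idx = int(longs[rng.integers(len(longs))])
        tr = tracks[idx]
        cut = int(rng.integers(2, len(tr) - 1))
        return [idx], [tr[:cut], tr[cut:]], 0.0, 0.0

    def propose_merge() -> Proposal | None:
        if len(tracks) < 2:
            return None
        a = int(rng.integers(len(tracks)))
        tra = tracks[a]
        cands = [
            b
            for b, trb in enumerate(tracks)
            if b != a and trb[0] in forward[tra[-1]]
        ]
        if not cands:
            return None
        b = int(cands[rng.integers(len(cands))])
        return [a, b], [tracks[a] + tracks[b]], 0.0, 0.0

    def propose_switch() -> Proposal | None:
        if len(tracks) < 2:
            return None
        ab = rng.choice(len(tracks), size=2, replace=False)
        a, b = int(ab[0]), int(ab[1])
        tra, trb = tracks[a], tracks[b]
        options = [
            (i, j)
            for i in range(1, len(tra))
            for j in range(1, len(trb))
            if trb[j] in forward[tra[i - 1]] and tra[i] in forward[trb[j - 1]]
        ]
        if not options:
            return None
        i, j = options[rng.integers(len(options))]
        na, nb = tra[:i] + trb[j:], trb[:j] + tra[i:]
        if len(na) < 2 or len(nb) < 2:
            return None
        return [a, b], [na, nb], 0.0, 0.0

    def propose_update() -> Proposal | None:
        if not tracks:
            return None
        idx = int(rng.integers(len(tracks)))
        tr = list(tracks[idx])
        k = int(rng.integers(len(tr)))
        cands = [
            j
            for j in by_frame_idx.get(frames[tr[k]], ())
            if j not in assigned and j != tr[k]
        ]
        if cands:
            tr[k] = int(cands[rng.integers(len(cands))])
            prev_ok = k == 0 or tr[k] in forward[tr[k - 1]]
            next_ok = k == len(tr) - 1 or tr[k + 1] in forward[tr[k]]
            if not (prev_ok and next_ok):
                return None
        elif len(tr) >= 3:
            tr = tr[:k] + tr[k + 1 :]
            if 0 < k < len(tr) and tr[k] not in forward[tr[k - 1]]:
                return None
        else:
            return None
        return [idx], [tuple(tr)], 0.0, 0.0

    def propose_insert() -> Proposal | None:
        """Fill an interior missed frame of a track with a free detection."""
        if not tracks:
            return None
        idx = int(rng.integers(len(tracks)))
        tr = tracks[idx]
        track_frames = {frames[i] for i in tr}
        cands = [
            j
            for f in range(frames[tr[0]] + 1, frames[tr[-1]])
            if f not in track_frames
            for j in by_frame_idx.get(f, ())
            if j not in assigned
        ]
        if not cands:
            return None
        j = int(cands[rng.integers(len(cands))])
        k = next(i for i, d in enumerate(tr) if frames[d] > frames[j])
        if j not in forward[tr[k - 1]] or tr[k] not in forward[j]:
            return None
        new_tr = tr[:k] + (j,) + tr[k:]
        return [idx], [new_tr], 0.0, 0.0

    movers = [
        propose_birth,
        propose_death,
        propose_extend,
        propose_reduce,
        propose_split,
        propose_merge,
        propose_switch,
        propose_update,
        propose_insert,
    ]

    for _ in range(n_iterations):
        move = movers[int(rng.integers(len(movers)))]
        proposal = move()
        if proposal is None:
            continue
        removed_idx, added, log_q_fwd, log_q_rev = proposal
        d = delta_score(removed_idx, added)
        log_alpha = d + (log_q_rev - log_q_fwd)
        if log_alpha >= 0 or rng.random() < math.exp(log_alpha):
            apply(removed_idx, added)
            current += d
            if debug_validate:
                _make_association(dset, list(tracks), params).validate()
            if -current < best_key[0] - 1e-9:
                best_key = (-current, len(tracks), _canonical(tracks))
                best_tracks = list(tracks)
            elif -current <= best_key[0] + 1e-9:
                key = (-current, len(tracks), _canonical(tracks))
                if key < best_key:
                    best_key = key
                    best_tracks = list(tracks)

    return _make_association(dset, best_tracks, params)


# ---------------------------------------------------------------------------
# kinematics


def tracks_to_kinematics(assoc: Association, frame_rate: float | None = None) -> list[Track]:
    """Fill per-step velocities, directions and mean speed for each track.

    Velocity of a step spanning ``g`` frames is Δposition / (g /
    frame_rate), in mm s⁻¹; the direction is the angle of that vector
    from the +lateral axis.
    """
    fr = frame_rate if frame_rate is not None else assoc.detection_set.frame_rate
    out: list[Track] = []
    for tr in assoc.tracks:
        dets = [assoc.detection_set.detections[i] for i in tr]
        pos = np.array([d.position for d in dets])
        frames = np.array([d.frame for d in dets], dtype=float)
        dt_s = np.diff(frames) / fr
        vel_um_s = np.diff(pos, axis=0) / dt_s[:, None]
        vel_mm_s = vel_um_s / 1000.0
        speeds = np.linalg.norm(vel_mm_s, axis=1)
        directions = np.arctan2(vel_mm_s[:, 0], vel_mm_s[:, 1])
        out.append(
            Track(
                detections=dets,
                step_velocities=vel_mm_s,
                directions=directions,
                mean_speed=float(speeds.mean()),
            )
        )
    return out
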