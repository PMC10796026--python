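"""Origin inference from abundance tracks by simulated annealing with AIC.

The point-origin model predicts the abundance P(x) from the origin count K,
origin positions, rescaled intensities iota_j = I_j*/v and lam_hat =
Lambda/v.  Sequencing only measures abundance up to a multiplicative
factor, so a scale is profiled analytically by weighted least squares.
Model complexity is controlled with the Akaike information criterion under
a Gaussian residual likelihood,

    AIC = 2 p + N ln(SQ / N),   p = 2K + 2,

(positions and intensities, plus lam_hat and the profiled scale), which the
annealer minimises with trans-dimensional moves (add / remove origin) next
to continuous ones (move origin, perturb intensity, perturb lam_hat).
A final derivative-free polish refines the continuous parameters at the
best K found.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, signal

from .core import AbundanceProfile, _boxcar
from .yeast import PointOriginSet, YeastModelParams, _abundance_grid

__all__ = [
    "InferenceConfig",
    "InferredModel",
    "profile_scale",
    "aic_from_sq",
    "aic_score",
    "initialize_candidates",
    "anneal_fit",
]

_DEFAULT_MOVES = {
    "move": 0.4,
    "intensity": 0.3,
    "add": 0.1,
    "remove": 0.1,
    "lam_hat": 0.1,
}


@dataclass(frozen=True)
class InferenceConfig:
    """Simulated-annealing schedule and proposal settings."""

    t_initial: float | None = None  # None: calibrated from trial moves
    cooling: float = 0.95
    steps_per_temp: int | None = None  # None: 200 * K, clamped to [200, 20000]
    t_stop: float | None = None  # None: t_initial * 1e-3
    move_probs: dict = field(default_factory=lambda: dict(_DEFAULT_MOVES))
    min_separation_bp: float = 1000.0
    intensity_bounds: tuple[float, float] = (1e-7, 1e-1)
    lam_hat_bounds: tuple[float, float] = (1e-8, 1e-2)
    seed: int | None = None
    smoothing_bp: float | None = None
    polish: bool = True

    def __post_init__(self) -> None:
        total = sum(self.move_probs.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"move probabilities must sum to 1, got {total}")
        lo, hi = self.intensity_bounds
        if not (0 < lo < hi):
            raise ValueError("intensity bounds must be positive and increasing")


@dataclass
class InferredModel:
    """Best model visited by the annealer, with fit diagnostics."""

    params: YeastModelParams
    scale: float
    sq: float
    aic: float
    n_bins: int
    trace: np.ndarray  # best AIC after each temperature stage

    @property
    def n_origins(self) -> int:
        return len(self.params.origins)


def profile_scale(model_values, observed, weights=None) -> float:
    """Optimal multiplicative scale lambda minimising sum w (a - lambda P)^2.

    Closed form: lambda = sum(w a P) / sum(w P^2).  The observed track is
    only defined up to such a factor, so it is always profiled out.
    """
    p = np.asarray(model_values, dtype=float)
    a = observed.values() if isinstance(observed, AbundanceProfile) else np.asarray(observed, dtype=float)
    w = np.ones_like(p) if weights is None else np.asarray(weights, dtype=float)
    denom = float(np.sum(w * p * p))
    if denom == 0.0:
        raise ValueError("model values are all zero; scale undefined")
    return float(np.sum(w * a * p) / denom)


def aic_from_sq(sq: float, n_bins: int, n_origins: int) -> float:
    """AIC = 2p + N ln(SQ/N) with p = 2K + 2 free parameters."""
    p = 2 * n_origins + 2
    if n_bins <= p:
        raise ValueError(f"need more bins ({n_bins}) than parameters ({p})")
    if sq <= 0.0:
        warnings.warn("zero residual; AIC is -inf", stacklevel=2)
        return -math.inf
    return 2.0 * p + n_bins * math.log(sq / n_bins)


def aic_score(observed: AbundanceProfile, model: InferredModel) -> float:
    """Recompute the AIC of a fitted model against an observed profile."""
    values, obs = _model_and_obs(observed, model.params)
    lam = profile_scale(values, obs)
    sq = float(np.sum((obs - lam * values) ** 2))
    return aic_from_sq(sq, len(obs), model.n_origins)


def _model_and_obs(observed: AbundanceProfile, params: YeastModelParams):
    values, obs = [], []
    for chrom in observed.chromosomes:
        x = observed.midpoints(chrom)
        pos, iota = params.origins.for_chrom(chrom)
        values.append(_abundance_grid(x, pos, iota, params.lam_hat))
        obs.append(observed.values(chrom))
    return np.concatenate(values), np.concatenate(obs)


def initialize_candidates(
    observed: AbundanceProfile,
    smoothing_bp: float | None = None,
    min_separation_bp: float = 1000.0,
    initial_intensity: float = 1e-4,
) -> PointOriginSet:
    """Seed origins at local maxima of the smoothed abundance track.

    Every origin is a local maximum of the model abundance, so peaks of the
    smoothed data are natural starting candidates.  A monotone profile
    yields its boundary argmax; a flat profile yields no candidates (the
    annealer then relies on insertion moves).
    """
    chroms, positions = [], []
    for chrom in observed.chromosomes:
        x = observed.midpoints(chrom)
        a = observed.values(chrom)
        bin_bp = observed.bin_size(chrom)
        window = 10 if smoothing_bp is None else max(1, int(round(smoothing_bp / bin_bp)))
        s = _boxcar(a, window)
        if np.ptp(s) == 0.0:
            continue
        resid_sd = float(np.std(a - s))
        prominence = max(2.0 * resid_sd / math.sqrt(window), 1e-3 * np.ptp(s))
        distance = max(1, int(round(min_separation_bp / bin_bp)))
        peaks, _ = signal.find_peaks(s, distance=distance, prominence=prominence)
        if len(peaks) == 0:
            peaks = np.array([int(np.argmax(s))])
        chroms.extend([chrom] * len(peaks))
        positions.extend(x[peaks])
    if not positions:
        return PointOriginSet([], [], [])
    return PointOriginSet(chroms, positions, [initial_intensity] * len(positions))


class _State:
    """Mutable annealing state: per-chromosome origin arrays plus lam_hat."""

    __slots__ = ("pos", "iota", "lam_hat")

    def __init__(self, pos: dict, iota: dict, lam_hat: float):
        self.pos = pos  # chrom -> list[float]
        self.iota = iota  # chrom -> list[float]
        self.lam_hat = lam_hat

    def copy(self) -> "_State":
        return _State(
            {c: list(v) for c, v in self.pos.items()},
            {c: list(v) for c, v in self.iota.items()},
            self.lam_hat,
        )

    @property
    def k(self) -> int:
        return sum(len(v) for v in self.pos.values())

    def to_origin_set(self) -> PointOriginSet:
        chroms, pos, iota = [], [], []
        for c in self.pos:
            chroms.extend([c] * len(self.pos[c]))
            pos.extend(self.pos[c])
            iota.extend(self.iota[c])
        return PointOriginSet(chroms, pos, iota)


def _cost(state: _State, data: dict) -> tuple[float, float, float]:
    """(AIC, SQ, scale) of a state against cached per-chromosome data."""
    values, obs = [], []
    for c, (x, a, _L) in data.items():
        p = np.asarray(state.pos[c])
        io = np.asarray(state.iota[c])
        values.append(_abundance_grid(x, p, io, state.lam_hat))
        obs.append(a)
    pv = np.concatenate(values)
    av = np.concatenate(obs)
    denom = float(pv @ pv)
    lam = float(av @ pv) / denom if denom > 0 else 0.0
    resid = av - lam * pv
    sq = float(resid @ resid)
    n = len(av)
    k = state.k
    if sq <= 0.0:
        return -math.inf, sq, lam
    return 2.0 * (2 * k + 2) + n * math.log(sq / n), sq, lam


def _respects_separation(positions: list, idx_ignore: int | None, new_pos: float, min_sep: float) -> bool:
    for i, p in enumerate(positions):
        if i == idx_ignore:
            continue
        if abs(p - new_pos) < min_sep:
            return False
    return True


def _polish(state: _State, data: dict, config: InferenceConfig) -> _State:
    """Refine continuous parameters at fixed K by bounded local minimisation.

    Positions are rescaled to chromosome fractions and intensities / lam_hat
    log-transformed so that all coordinates are O(1); Powell handles the
    kinks the model has where the per-position origin ordering changes.
    """
    chroms = list(state.pos)
    sizes = [len(state.pos[c]) for c in chroms]
    if sum(sizes) == 0:
        return state
    x0, bounds = [], []
    for c in chroms:
        L = data[c][2]
        for p in state.pos[c]:
            x0.append(p / L)
            bounds.append((0.0, 1.0))
    lo, hi = config.intensity_bounds
    for c in chroms:
        for io in state.iota[c]:
            x0.append(math.log(io))
            bounds.append((math.log(lo), math.log(hi)))
    llo, lhi = config.lam_hat_bounds
    x0.append(math.log(state.lam_hat))
    bounds.append((math.log(llo), math.log(lhi)))

    def unpack(vec: np.ndarray) -> _State:
        s = state.copy()
        i = 0
        for c, sz in zip(chroms, sizes):
            s.pos[c] = list(vec[i : i + sz] * data[c][2])
            i += sz
        for c, sz in zip(chroms, sizes):
            s.iota[c] = list(np.exp(vec[i : i + sz]))
            i += sz
        s.lam_hat = float(math.exp(vec[i]))
        return s

    def fun(vec: np.ndarray) -> float:
        aic, _, _ = _cost(unpack(vec), data)
        return aic if math.isfinite(aic) else -1e18

    res = optimize.minimize(
        fun,
        np.asarray(x0),
        method="Powell",
        bounds=bounds,
        options={"maxiter": 30, "xtol": 1e-6, "ftol": 1e-8},
    )
    cand = unpack(res.x)
    # keep the polished state only if it actually improved
    if _cost(cand, data)[0] <= _cost(state, data)[0]:
        return cand
    return state


def anneal_fit(
    observed: AbundanceProfile,
    config: InferenceConfig | None = None,
    fixed_k: int | None = None,
) -> InferredModel:
    """Infer origin number, positions, intensities and lam_hat by annealing.

    lam_hat is shared across chromosomes; the multiplicative scale is
    profiled over the whole dataset.  ``fixed_k`` disables the
    trans-dimensional moves and keeps exactly K origins (used for model
    comparison at fixed complexity).  Reproducible given ``config.seed``.
    """
    config = config or InferenceConfig()
    rng = np.random.default_rng(config.seed)

    data = {}
    for chrom in observed.chromosomes:
        sub = observed.chrom_slice(chrom)
        x = observed.midpoints(chrom)
        a = observed.values(chrom)
        data[chrom] = (x, a, float(sub["end"].max()))
    n_bins = sum(len(d[0]) for d in data.values())
    if n_bins <= 4:
        raise ValueError("too few bins to fit even a single origin")

    cands = initialize_candidates(
        observed, config.smoothing_bp, config.min_separation_bp
    )
    state = _State({c: [] for c in data}, {c: [] for c in data}, 1e-6)
    mid_iota = math.sqrt(config.intensity_bounds[0] * config.intensity_bounds[1])
    for c, p, io in zip(cands.chrom, cands.position, cands.intensity):
        if c in state.pos:
            state.pos[c].append(float(p))
            state.iota[c].append(float(io))
    # every chromosome needs at least one origin for the model to be defined
    for c, (x, a, L) in data.items():
        if not state.pos[c]:
            state.pos[c].append(float(x[np.argmax(a)]))
            state.iota[c].append(mid_iota)

    # data-driven starting decay constant: log dynamic range over a typical
    # half-spacing between candidate peaks
    spans = []
    for c, (x, a, L) in data.items():
        p = sorted(state.pos[c])
        gaps = np.diff(p) if len(p) > 1 else np.array([L / 2.0])
        ratio = max(a.max() / max(a.min(), 1e-12), 1.05)
        spans.append(math.log(ratio) / max(float(np.mean(gaps)) / 2.0, 1.0))
    llo, lhi = config.lam_hat_bounds
    state.lam_hat = float(np.clip(np.mean(spans), llo, lhi))

    move_probs = dict(config.move_probs)
    if fixed_k is not None:
        # trim/pad candidates to exactly K, largest-peak chromosomes first
        flat = [(c, p, io) for c in state.pos for p, io in zip(state.pos[c], state.iota[c])]
        while len(flat) > fixed_k:
            flat.pop(rng.integers(len(flat)))
        chroms = list(data)
        while len(flat) < fixed_k:
            c = chroms[rng.integers(len(chroms))]
            flat.append((c, float(rng.uniform(0, data[c][2])), mid_iota))
        state = _State({c: [] for c in data}, {c: [] for c in data}, state.lam_hat)
        for c, p, io in flat:
            state.pos[c].append(p)
            state.iota[c].append(io)
        move_probs["add"] = move_probs["remove"] = 0.0
        total = sum(move_probs.values())
        move_probs = {k: v / total for k, v in move_probs.items()}

    move_names = list(move_probs)
    move_p = np.array([move_probs[m] for m in move_names])
    chrom_list = list(data)
    mean_bin = np.mean([observed.bin_size(c) for c in chrom_list])

    cur_aic, cur_sq, cur_scale = _cost(state, data)
    best = state.copy()
    best_aic, best_sq, best_scale = cur_aic, cur_sq, cur_scale

    # calibrate the starting temperature from the spread of trial moves
    if config.t_initial is None:
        deltas = []
        widths = {"pos": 10.0 * mean_bin, "iota": 0.5, "lam": 0.1}
        for _ in range(60):
            trial, _ = _propose(state, rng, move_names, move_p, widths, config, data, mid_iota)
            if trial is not None:
                deltas.append(abs(_cost(trial, data)[0] - cur_aic))
        t0 = 3.0 * float(np.median(deltas)) if deltas else 1.0
        t0 = max(t0, 1e-6)
    else:
        t0 = config.t_initial
    t_stop = config.t_stop if config.t_stop is not None else t0 * 1e-3

    widths = {"pos": 10.0 * mean_bin, "iota": 0.5, "lam": 0.1}
    trace = []
    temp = t0
    while temp > t_stop:
        steps = config.steps_per_temp
        if steps is None:
            steps = int(np.clip(200 * max(state.k, 1), 200, 20000))
        n_acc = {m: 0 for m in move_names}
        n_try = {m: 0 for m in move_names}
        for _ in range(steps):
            trial, mname = _propose(state, rng, move_names, move_p, widths, config, data, mid_iota)
            if trial is None:
                continue
            n_try[mname] += 1
            aic, sq, scale = _cost(trial, data)
            delta = aic - cur_aic
            if delta <= 0 or rng.random() < math.exp(-delta / temp):
                state = trial
                cur_aic, cur_sq, cur_scale = aic, sq, scale
                n_acc[mname] += 1
                if aic < best_aic:
                    best, best_aic, best_sq, best_scale = state.copy(), aic, sq, scale
        # adapt proposal widths towards a mid-range acceptance rate
        for key, m in (("pos", "move"), ("iota", "intensity"), ("lam", "lam_hat")):
            if n_try.get(m, 0) >= 10:
                rate = n_acc[m] / n_try[m]
                if rate > 0.5:
                    widths[key] = min(widths[key] * 1.3, 100.0 * mean_bin if key == "pos" else 2.0)
                elif rate < 0.2:
                    widths[key] = max(widths[key] * 0.7, 0.05 * mean_bin if key == "pos" else 0.005)
        trace.append(best_aic)
        temp *= config.cooling

    state = best.copy()
    if config.polish:
        state = _polish(state, data, config)
        aic, sq, scale = _cost(state, data)
        if aic < best_aic:
            best, best_aic, best_sq, best_scale = state, aic, sq, scale
            trace.append(best_aic)

    params = YeastModelParams(origins=best.to_origin_set(), lam_hat=best.lam_hat)
    return InferredModel(
        params=params,
        scale=best_scale,
        sq=best_sq,
        aic=best_aic,
        n_bins=n_bins,
        trace=np.asarray(trace),
    )


def _propose(
    state: _State,
    rng: np.random.Generator,
    move_names: Sequence[str],
    move_p: np.ndarray,
    widths: dict,
    config: InferenceConfig,
    data: dict,
    mid_iota: float,
):
    """Draw one proposal; returns (new state or None, move name)."""
    mname = move_names[rng.choice(len(move_names), p=move_p)]
    chroms = [c for c in state.pos if state.pos[c]]
    min_sep = config.min_separation_bp
    lo, hi = config.intensity_bounds
    llo, lhi = config.lam_hat_bounds

    if mname == "lam_hat":
        trial = state.copy()
        trial.lam_hat = state.lam_hat * math.exp(rng.normal(0.0, widths["lam"]))
        if not (llo <= trial.lam_hat <= lhi):
            return None, mname
        return trial, mname

    if mname == "add":
        c = list(data)[rng.integers(len(data))]
        L = data[c][2]
        new_pos = float(rng.uniform(0.0, L))
        if not _respects_separation(state.pos[c], None, new_pos, min_sep):
            return None, mname
        trial = state.copy()
        trial.pos[c].append(new_pos)
        trial.iota[c].append(mid_iota)
        return trial, mname

    if not chroms:
        return None, mname
    c = chroms[rng.integers(len(chroms))]
    idx = int(rng.integers(len(state.pos[c])))

    if mname == "remove":
        if len(state.pos[c]) <= 1:
            return None, mname
        trial = state.copy()
        trial.pos[c].pop(idx)
        trial.iota[c].pop(idx)
        return trial, mname

    if mname == "move":
        L = data[c][2]
        # occasional wide jumps let an origin hop between basins instead of
        # diffusing through a bad local arrangement
        w = widths["pos"] * (10.0 if rng.random() < 0.15 else 1.0)
        new_pos = state.pos[c][idx] + rng.normal(0.0, w)
        if not (0.0 <= new_pos <= L):
            return None, mname
        if not _respects_separation(state.pos[c], idx, new_pos, min_sep):
            return None, mname
        trial = state.copy()
        trial.pos[c][idx] = float(new_pos)
        return trial, mname

    if mname == "intensity":
        new_iota = state.iota[c][idx] * math.exp(rng.normal(0.0, widths["iota"]))
        if not (lo <= new_iota <= hi):
            return None, mname
        trial = state.copy()
        trial.iota[c][idx] = float(new_iota)
        return trial, mname

    raise ValueError(f"unknown move {mname!r}")
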