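"""Synthetic inputs for every pipeline stage.

This module generates the full chain of ground-truth test material: a Simon
Go/Nogo task design with exact cell counts, behavioral responses with
condition-dependent accuracy and a Simon reaction-time shift, band-limited
oscillatory sources coupled by a nonlinear multivariate autoregressive (nMVAR)
system with known linear and nonlinear edges, sensor mixtures through a known
gain matrix, and amplitude artifacts planted at known trials.  Because every
generator returns its own ground truth alongside the data, all downstream
stages (rejection, beamforming, connectivity estimation, statistics) can be
validated against planted answers without any external recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import EpochedSignal

GO, NOGO = "go", "nogo"
CONGRUENT, INCONGRUENT = "congruent", "incongruent"
RESPONSE_WINDOW_MS = 1700.0

# bounded-growth maps of a standardized parent channel usable as nonlinear
# coupling functions; "centered_square" has zero mean and zero linear term at
# the origin for a standardized Gaussian parent, so it must surface in the
# nonlinear (NC) and not the linear (LC) connectivity estimate
NONLINEAR_FUNCS = {
    "centered_square": lambda z: z * z - 1.0,
    "square": lambda z: z * z,
    "tanh": np.tanh,
}


# ---------------------------------------------------------------------------
# task design
# ---------------------------------------------------------------------------

@dataclass
class TrialEvent:
    index: int  # 1-based
    block: int  # 1-based
    trial_type: str  # go | nogo
    congruency: str  # congruent | incongruent
    stimulus_side: str  # left | right
    correct_response: str  # left | right | none
    iti_ms: float


@dataclass
class TaskDesign:
    trials: list[TrialEvent]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def counts(self) -> dict[tuple[str, str], int]:
        out: dict[tuple[str, str], int] = {}
        for t in self.trials:
            key = (t.trial_type, t.congruency)
            out[key] = out.get(key, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": [t.index for t in self.trials],
                "block": [t.block for t in self.trials],
                "trial_type": [t.trial_type for t in self.trials],
                "congruency": [t.congruency for t in self.trials],
                "stimulus_side": [t.stimulus_side for t in self.trials],
                "correct_response": [t.correct_response for t in self.trials],
                "iti_ms": [t.iti_ms for t in self.trials],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TaskDesign":
        df = pd.read_csv(path)
        trials = [
            TrialEvent(
                index=int(r.trial),
                block=int(r.block),
                trial_type=str(r.trial_type),
                congruency=str(r.congruency),
                stimulus_side=str(r.stimulus_side),
                correct_response=str(r.correct_response),
                iti_ms=float(r.iti_ms),
            )
            for r in df.itertuples()
        ]
        return cls(trials=trials)


def generate_task_design(
    n_trials: int = 720,
    go_fraction: float = 0.7,
    congruent_fraction: float = 0.5,
    n_blocks: int = 6,
    iti_range_ms: tuple[float, float] = (1300.0, 1700.0),
    seed: int = 0,
) -> TaskDesign:
    """Build a blocked Go/Nogo x congruency design with exact cell counts.

    Every (trial type x congruency) cell must come out as an integer number of
    trials per block; otherwise the configuration is rejected with the name of
    the offending cell.  Trial order is shuffled within each block.
    """
    if n_trials == 0:
        return TaskDesign(trials=[])
    if n_blocks < 1 or n_trials % n_blocks:
        raise ValueError(f"n_trials={n_trials} not divisible by n_blocks={n_blocks}")
    per_block = n_trials // n_blocks
    cells = {}
    for ttype, tfrac in ((GO, go_fraction), (NOGO, 1.0 - go_fraction)):
        for cong, cfrac in ((CONGRUENT, congruent_fraction), (INCONGRUENT, 1.0 - congruent_fraction)):
            exact = per_block * tfrac * cfrac
            n_cell = round(exact)
            if abs(exact - n_cell) > 1e-9:
                raise ValueError(
                    f"cell ({ttype}, {cong}) has non-integer per-block count {exact:g}"
                )
            cells[(ttype, cong)] = n_cell
    if sum(cells.values()) != per_block:
        raise ValueError("cell counts do not sum to the block size")

    rng = np.random.default_rng(seed)
    trials: list[TrialEvent] = []
    idx = 1
    for block in range(1, n_blocks + 1):
        block_cells: list[tuple[str, str]] = []
        for key, n_cell in cells.items():
            block_cells.extend([key] * n_cell)
        order = rng.permutation(len(block_cells))
        for j in order:
            ttype, cong = block_cells[j]
            side = "left" if rng.random() < 0.5 else "right"
            if ttype == NOGO:
                resp = "none"
            elif cong == CONGRUENT:
                resp = side
            else:
                resp = "left" if side == "right" else "right"
            iti = float(rng.integers(int(iti_range_ms[0]), int(iti_range_ms[1]) + 1))
            trials.append(
                TrialEvent(
                    index=idx,
                    block=block,
                    trial_type=ttype,
                    congruency=cong,
                    stimulus_side=side,
                    correct_response=resp,
                    iti_ms=iti,
                )
            )
            idx += 1
    return TaskDesign(trials=trials)


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

@dataclass
class BehavioralRecord:
    trial_index: int
    response: str  # left | right | none
    rt_ms: float | None
    outcome: str  # hit | error | miss | correct_omission | false_alarm


def condition_key(trial_type: str, congruency: str) -> str:
    return f"{trial_type}_{congruency}"


def simulate_behavior(
    design: TaskDesign,
    p_correct: dict[str, float],
    rt_model: dict[str, float] | None = None,
    seed: int = 0,
) -> list[BehavioralRecord]:
    """Draw responses per trial with condition-dependent accuracy.

    ``p_correct`` maps condition keys (``go_congruent`` ... ``nogo_incongruent``)
    to the probability of a correct outcome: for Go trials the correct key, for
    Nogo trials a withheld response.  Incorrect Go trials are emitted as
    wrong-key presses; incorrect Nogo trials as prepotent same-side presses.
    Incongruent Go reaction times are shifted by ``simon_shift_ms`` (the Simon
    effect).  These are fixture dynamics, not estimates of any real population.
    """
    rt_model = dict(rt_model or {})
    mean_ms = rt_model.get("mean_ms", 450.0)
    sd_ms = rt_model.get("sd_ms", 90.0)
    shift_ms = rt_model.get("simon_shift_ms", 30.0)
    if sd_ms <= 0:
        raise ValueError("rt sd must be > 0")
    valid = {condition_key(t, c) for t in (GO, NOGO) for c in (CONGRUENT, INCONGRUENT)}
    for key, p in p_correct.items():
        if key not in valid:
            raise ValueError(f"unknown condition key {key!r}")
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p_correct[{key!r}]={p} outside [0, 1]")

    from .stats import code_single_response  # late import: stats uses our types

    rng = np.random.default_rng(seed)
    records: list[BehavioralRecord] = []
    for t in design.trials:
        key = condition_key(t.trial_type, t.congruency)
        p = p_correct.get(key, 1.0)
        correct = rng.random() < p
        base = mean_ms + (shift_ms if (t.trial_type == GO and t.congruency == INCONGRUENT) else 0.0)
        rt = float(np.clip(rng.normal(base, sd_ms), 80.0, RESPONSE_WINDOW_MS - 10.0))
        if t.trial_type == GO:
            if correct:
                response, rt_ms = t.correct_response, rt
            else:
                response = "left" if t.correct_response == "right" else "right"
                rt_ms = rt
        else:
            if correct:
                response, rt_ms = "none", None
            else:
                response, rt_ms = t.stimulus_side, rt  # prepotent direct-route press
        outcome = code_single_response(t, response, rt_ms)
        records.append(BehavioralRecord(t.index, response, rt_ms, outcome))
    return records


# ---------------------------------------------------------------------------
# ground-truth nMVAR system
# ---------------------------------------------------------------------------

def ar2_coefficients(peak_freq_hz: float, fs_hz: float, pole_radius: float) -> tuple[float, float]:
    """AR(2) coefficients for a stochastic oscillation peaking at a given frequency.

    Complex pole pair at radius r and angle 2*pi*f/fs gives
    a1 = 2 r cos(2 pi f / fs), a2 = -r^2; r < 1 guarantees stability.
    """
    if not 0.0 < peak_freq_hz < fs_hz / 2.0:
        raise ValueError(f"peak frequency {peak_freq_hz} outside (0, fs/2)")
    if pole_radius >= 1.0 or pole_radius < 0.0:
        raise ValueError(f"pole radius {pole_radius} must be in [0, 1) for stability")
    a1 = 2.0 * pole_radius * np.cos(2.0 * np.pi * peak_freq_hz / fs_hz)
    a2 = -pole_radius**2
    return float(a1), float(a2)


@dataclass
class NonlinearTerm:
    target: int  # 0-based channel index
    source: int
    lag: int  # >= 1
    func: str  # key into NONLINEAR_FUNCS
    gain: float


@dataclass
class GroundTruthSystem:
    """A known nMVAR generator: x_j(n) = linear + nonlinear couplings + noise.

    ``linear_coeffs[k-1, j, i]`` multiplies the parent at lag k driving target
    j.  Diagonal entries (i == j) act on the raw channel (its own AR dynamics);
    off-diagonal entries act on the parent standardized by its own
    post-burn-in moments, so coupling gains directly control the
    signal-to-innovation ratio of the child.  Cross-channel couplings (linear
    and nonlinear) must form a DAG: exogenous channels are generated first and
    standardized before feeding their children.
    """

    n_channels: int
    order: int
    linear_coeffs: np.ndarray  # (order, M, M)
    nonlinear_terms: list[NonlinearTerm] = field(default_factory=list)
    innovation_sd: np.ndarray | None = None
    burn_in: int = 1000

    def __post_init__(self) -> None:
        self.linear_coeffs = np.asarray(self.linear_coeffs, dtype=float)
        if self.linear_coeffs.shape != (self.order, self.n_channels, self.n_channels):
            raise ValueError("linear_coeffs must have shape (order, M, M)")
        if self.innovation_sd is None:
            self.innovation_sd = np.ones(self.n_channels)
        self.innovation_sd = np.asarray(self.innovation_sd, dtype=float)
        for term in self.nonlinear_terms:
            if term.func not in NONLINEAR_FUNCS:
                raise ValueError(f"unknown nonlinear function tag {term.func!r}")
            if not 1 <= term.lag <= self.order:
                raise ValueError("nonlinear term lag outside model order")

    def companion_spectral_radius(self) -> float:
        m, p = self.n_channels, self.order
        comp = np.zeros((m * p, m * p))
        comp[:m, :] = np.concatenate([self.linear_coeffs[k] for k in range(p)], axis=1)
        if p > 1:
            comp[m:, :-m] = np.eye(m * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))

    def is_stable(self) -> bool:
        return self.companion_spectral_radius() < 1.0

    def linear_edges(self) -> set[tuple[int, int]]:
        """(source, target) pairs with a nonzero off-diagonal linear coefficient."""
        edges = set()
        for k in range(self.order):
            jj, ii = np.nonzero(self.linear_coeffs[k])
            for j, i in zip(jj, ii):
                if i != j:
                    edges.add((int(i), int(j)))
        return edges

    def nonlinear_edges(self) -> set[tuple[int, int]]:
        return {(t.source, t.target) for t in self.nonlinear_terms if t.source != t.target}

    def _topological_order(self) -> list[int]:
        m = self.n_channels
        parents: dict[int, set[int]] = {j: set() for j in range(m)}
        for i, j in self.linear_edges() | self.nonlinear_edges():
            parents[j].add(i)
        order, done = [], set()
        while len(order) < m:
            ready = [j for j in range(m) if j not in done and parents[j] <= done]
            if not ready:
                raise ValueError("cross-channel couplings contain a cycle; "
                                 "exogenous-first generation needs a DAG")
            for j in sorted(ready):
                order.append(j)
                done.add(j)
        return order


def benchmark_b1(fs_hz: float = 256.0, peak_hz: float = 10.0) -> GroundTruthSystem:
    """Three-channel benchmark with one linear and one purely nonlinear edge.

    Channel 0 is an AR(2) oscillator (pole radius 0.95 at ``peak_hz``) with
    unit innovation SD.  Channel 1 receives 0.80 * z0(n-1) linearly; channel 2
    receives 0.60 * (z0(n-1)^2 - 1), an even function with no linear part.
    Both children have 0.55 self-feedback at lag 1 and innovation SD 0.12.
    True edges: linear 0->1, purely nonlinear 0->2.
    """
    a1, a2 = ar2_coefficients(peak_hz, fs_hz, 0.95)
    coeffs = np.zeros((2, 3, 3))
    coeffs[0, 0, 0], coeffs[1, 0, 0] = a1, a2
    coeffs[0, 1, 1] = 0.55
    coeffs[0, 2, 2] = 0.55
    coeffs[0, 1, 0] = 0.80  # linear edge 0 -> 1 (on standardized parent)
    return GroundTruthSystem(
        n_channels=3,
        order=2,
        linear_coeffs=coeffs,
        nonlinear_terms=[NonlinearTerm(target=2, source=0, lag=1, func="centered_square", gain=0.60)],
        innovation_sd=np.array([1.0, 0.12, 0.12]),
        burn_in=1000,
    )


def simulate_nmvar(
    system: GroundTruthSystem, n_samples: int, seed: int = 0
) -> tuple[np.ndarray, dict[str, set[tuple[int, int]]]]:
    """Simulate the system and return (M x L sources, true edge sets).

    Channels are generated in topological order of the cross-coupling DAG.
    Each channel is its own AR filter driven by coupling input plus Gaussian
    innovations; parents feed children through values standardized by the
    parent's own post-burn-in mean and SD.  The burn-in is discarded.
    """
    if not system.is_stable():
        raise ValueError(
            f"linear subsystem unstable (spectral radius "
            f"{system.companion_spectral_radius():.3f} >= 1)"
        )
    if n_samples <= system.burn_in // 100 + 10 * system.order:
        raise ValueError("n_samples too short relative to order")
    m, p, burn = system.n_channels, system.order, system.burn_in
    total = burn + n_samples
    rng = np.random.default_rng(seed)
    x = np.zeros((m, total))
    z = np.zeros((m, total))
    nl_by_target: dict[int, list[NonlinearTerm]] = {}
    for term in system.nonlinear_terms:
        nl_by_target.setdefault(term.target, []).append(term)

    for j in system._topological_order():
        drive = rng.normal(0.0, system.innovation_sd[j], size=total)
        for k in range(p):
            for i in range(m):
                a = system.linear_coeffs[k, j, i]
                if i != j and a != 0.0:
                    drive[k + 1:] += a * z[i, : total - k - 1]
        for term in nl_by_target.get(j, []):
            g = NONLINEAR_FUNCS[term.func]
            drive[term.lag:] += term.gain * g(z[term.source, : total - term.lag])
        a_self = system.linear_coeffs[:, j, j]
        x[j] = sps.lfilter([1.0], np.concatenate([[1.0], -a_self]), drive)
        mu, sd = x[j, burn:].mean(), x[j, burn:].std()
        z[j] = (x[j] - mu) / sd if sd > 0 else 0.0

    edges = {"linear": system.linear_edges(), "nonlinear": system.nonlinear_edges()}
    return x[:, burn:], edges


# ---------------------------------------------------------------------------
# forward mixing and artifacts
# ---------------------------------------------------------------------------

def mix_to_sensors(
    sources: np.ndarray,
    mixing: np.ndarray,
    sensor_noise_sd: float = 0.0,
    seed: int = 0,
    fs_hz: float = 256.0,
    t0_ms: float = 0.0,
) -> EpochedSignal:
    """Project sources through a gain matrix and add white sensor noise.

    ``sources`` is either (M, L) — returned as a single epoch — or
    (trials, M, T).  ``mixing`` is sensors x M.  A rank-deficient mixing
    matrix triggers a warning (beamformer recovery is then not guaranteed).
    """
    sources = np.asarray(sources, dtype=float)
    mixing = np.asarray(mixing, dtype=float)
    if np.linalg.matrix_rank(mixing) < mixing.shape[1]:
        warnings.warn("mixing matrix is rank deficient; source recovery not guaranteed")
    if sources.ndim == 2:
        sources = sources[None, :, :]
    if sources.shape[1] != mixing.shape[1]:
        raise ValueError("mixing column count does not match number of sources")
    rng = np.random.default_rng(seed)
    data = np.einsum("cm,tms->tcs", mixing, sources)
    if sensor_noise_sd > 0:
        data = data + rng.normal(0.0, sensor_noise_sd, size=data.shape)
    return EpochedSignal(data=data, fs_hz=fs_hz, t0_ms=t0_ms)


@dataclass
class ArtifactSpec:
    trial: int  # 0-based epoch index
    kind: str  # spike | flatline
    amplitude_uv: float = 300.0
    duration_ms: float = 100.0


def inject_artifacts(
    epochs: EpochedSignal,
    artifacts: list[ArtifactSpec],
    seed: int = 0,
) -> tuple[EpochedSignal, list[int]]:
    """Plant amplitude artifacts and return (modified epochs, bad-trial list).

    ``spike`` adds a triangular pulse of the given height, raising the
    within-window peak-to-peak above ``amplitude_uv``; ``flatline`` replaces a
    window with its mean so the span collapses below the 0.5 uV floor.
    Channel and onset are drawn from ``seed``.
    """
    out = epochs.copy()
    rng = np.random.default_rng(seed)
    planted: set[int] = set()
    for spec in artifacts:
        if not 0 <= spec.trial < out.n_trials:
            raise ValueError(f"artifact targets missing trial {spec.trial}")
        n_dur = int(round(spec.duration_ms * out.fs_hz / 1000.0))
        if n_dur > out.n_samples:
            raise ValueError(
                f"artifact duration {spec.duration_ms} ms exceeds epoch length"
            )
        ch = int(rng.integers(out.n_channels))
        start = int(rng.integers(0, out.n_samples - n_dur + 1))
        seg = slice(start, start + n_dur)
        if spec.kind == "spike":
            pulse = spec.amplitude_uv * sps.windows.triang(n_dur)
            out.data[spec.trial, ch, seg] += pulse
        elif spec.kind == "flatline":
            out.data[spec.trial, ch, seg] = out.data[spec.trial, ch, seg].mean()
        else:
            raise ValueError(f"unknown artifact kind {spec.kind!r}")
        planted.add(spec.trial)
    return out, sorted(planted)


# ---------------------------------------------------------------------------
# synthetic source grid (stand-in for an anatomical template + atlas)
# ---------------------------------------------------------------------------

def synthetic_source_grid(
    shape: tuple[int, int, int] = (10, 10, 10),
    voxel_edge_mm: float = 10.0,
    n_sensors: int = 64,
    n_regions: int = 8,
):
    """Build a labeled regular voxel grid with a smooth distance-falloff gain.

    Sensors sit on a deterministic Fibonacci-spiral hemisphere above the
    grid; voxel gains fall off with squared sensor-voxel distance, so
    neighboring voxels have correlated lead-field columns (the property
    beamformer leakage and spatial clustering rely on).  Region labels
    partition the grid into equal slabs, standing in for an anatomical
    atlas.  Synthetic stand-in: no volume-conduction physics.
    """
    from .sourceloc import SourceGrid

    nx, ny, nz = shape
    gx, gy, gz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    positions = (
        np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1).astype(float)
        * voxel_edge_mm
    )
    center = positions.mean(axis=0)
    extent = positions.max(axis=0) - positions.min(axis=0)
    radius = 0.75 * float(np.max(extent)) + 2.0 * voxel_edge_mm

    i = np.arange(n_sensors) + 0.5
    cos_theta = 0.15 + 0.85 * i / n_sensors  # upper shell only
    theta = np.arccos(cos_theta)
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    sensors = center + radius * np.stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)],
        axis=1,
    )
    d = np.linalg.norm(sensors[:, None, :] - positions[None, :, :], axis=2)
    d0 = 1.5 * voxel_edge_mm
    leadfield = 1.0 / (1.0 + (d / d0) ** 2)

    # equal slabs along the slowest-varying grid axis -> n_regions labels
    slab = np.minimum((gx.ravel() * n_regions) // nx, n_regions - 1)
    labels = np.array([f"region{int(s)}" for s in slab], dtype=object)
    return SourceGrid(
        voxel_positions=positions,
        voxel_edge_mm=voxel_edge_mm,
        leadfield=leadfield,
        region_labels=labels,
        sensor_positions=sensors,
    )
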