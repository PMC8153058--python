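"""Synthetic study generator.

Emulates the study design end to end so the analysis chain can be exercised
without any scanner data: pseudorandomized trial tables (4 numerosities x 2
formats x 2 tasks, 20 trials per cell, ISI counterbalanced), voxel patterns
built from log-Gaussian numerosity tuning with controllable sharing across
formats and tasks, number-comparison behavioral sessions whose accuracies
follow the erfc Weber model, and math-achievement covariates with a
configurable latent correlation to representational sharing.

Generative model for one region
-------------------------------
A configurable fraction of the region's voxels responds to the stimuli
(the rest are pure noise, which gives activation-based voxel selection a
real target).  Each responsive voxel has a preferred log-numerosity drawn
uniformly on [log 2, log 8] and responds to numerosity ``n`` with a
log-Gaussian tuning curve ``exp(-(log n - p)^2 / (2 * tuning_width^2))``.
Independent tuning maps are drawn for the shared component, each format,
each task, and each format x task cell; condition-specific maps are
orthogonalized against the other maps' class-pattern spans so that zero
sharing means exactly zero linear cross-decodability.  The noiseless
pattern for a condition cell is the convex mixture

    alpha_f*alpha_t*S + (1-alpha_f)*alpha_t*F_f
    + alpha_f*(1-alpha_t)*T_t + (1-alpha_f)*(1-alpha_t)*X_{f,t}

centered and rescaled to unit SD across responsive voxels (so ``snr`` is
comparable across sharing levels), and each trial's beta pattern is
``snr * pattern + N(0, 1)`` voxel-wise noise.  With ``alpha_f = 1`` the two
formats share identical noiseless patterns; with ``alpha_f = 0`` their
patterns carry no shared linear structure, and likewise for tasks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .behavior import BehavioralSession, ComparisonTrial, weber_error
from .dataset import FORMATS, NUMEROSITIES, TASKS, PatternDataset

ISI_LEVELS_MS = (3300, 4300, 5300, 6300, 7300)
STIMULUS_MS = 500

#: The seven comparison ratios of the behavioral session.  The endpoints
#: (5 vs 15, ratio 0.33, and 9 vs 10, ratio 0.9) pin the range; the middle
#: pairs are drawn from the same 5..15 dot range.
RATIO_PAIRS = ((5, 15), (5, 12), (6, 12), (7, 12), (8, 12), (9, 12), (9, 10))

DEFAULT_ROIS = (
    "L_parietal", "R_parietal", "L_IFG", "R_IFG", "L_NFA", "R_NFA",
)

_ORDER_RETRY_CAP = 100_000


class DesignError(RuntimeError):
    """The pseudorandom ordering constraint could not be satisfied."""


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters for one synthetic cohort.

    snr is the ratio of noiseless-pattern SD to voxel noise SD (noise SD is
    fixed at 1).  ``alpha_format`` / ``alpha_task`` set the fraction of
    numerosity signal common to both formats / tasks; ``alpha_sd`` is the
    between-participant spread of the format-sharing fraction, and
    ``brain_behavior_r`` the latent correlation between that fraction and
    the math-achievement covariate.
    """

    n_participants: int = 39
    n_voxels_per_roi: int = 1000
    trials_per_cell: int = 20
    snr: float = 0.5
    tuning_width: float = 0.4
    alpha_format: float = 0.5
    alpha_task: float = 0.5
    alpha_sd: float = 0.15
    active_fraction: float = 0.5
    brain_behavior_r: float = 0.0
    w_mean: float = 0.23
    w_sd: float = 0.05
    behavioral_reps: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_participants, self.n_voxels_per_roi,
               self.trials_per_cell, self.behavioral_reps) < 1:
            raise ValueError("counts must be >= 1")
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        if self.tuning_width <= 0:
            raise ValueError("tuning_width must be positive")
        for name in ("alpha_format", "alpha_task"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not -1.0 <= self.brain_behavior_r <= 1.0:
            raise ValueError("brain_behavior_r must lie in [-1, 1]")
        if self.alpha_sd < 0 or self.w_sd < 0:
            raise ValueError("spread parameters must be >= 0")
        if not 0.0 < self.active_fraction <= 1.0:
            raise ValueError("active_fraction must lie in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Cohort:
    """Everything the analysis consumes for one simulated study."""

    config: CohortConfig
    design: pd.DataFrame
    patterns: dict[tuple[str, str], PatternDataset]
    behavior: dict[str, BehavioralSession]
    covariates: pd.DataFrame  # participant, alpha_format, w_true, math_score

    @property
    def participants(self) -> list[str]:
        return list(self.covariates["participant"])

    @property
    def roi_names(self) -> list[str]:
        return sorted({roi for _, roi in self.patterns})


def _order_cells(cells: list[tuple[int, str]], rng: np.random.Generator,
                 max_run: int = 3) -> list[tuple[int, str]]:
    """Shuffle trial cells so no (numerosity, format) pair repeats more than
    ``max_run`` times consecutively; rejection sampling with a retry cap."""
    cells = list(cells)
    for _ in range(_ORDER_RETRY_CAP):
        rng.shuffle(cells)
        run, ok = 1, True
        for prev, cur in itertools.pairwise(cells):
            run = run + 1 if cur == prev else 1
            if run > max_run:
                ok = False
                break
        if ok:
            return cells
    raise DesignError(
        f"could not satisfy the <= {max_run}-consecutive constraint within "
        f"{_ORDER_RETRY_CAP} shuffles (degenerate trial counts?)"
    )


def _task_design(config: CohortConfig, task: str,
                 rng: np.random.Generator) -> pd.DataFrame:
    cells = [
        (n, f)
        for n in NUMEROSITIES for f in FORMATS
        for _ in range(config.trials_per_cell)
    ]
    ordered = _order_cells(cells, rng)

    # exact ISI counterbalancing within every (numerosity, format) cell:
    # each of the 5 levels appears floor(m/5) times, remainders spread by a
    # per-cell random rotation so the task-level mean stays close to 5300.
    isi_pool: dict[tuple[int, str], list[int]] = {}
    for n in NUMEROSITIES:
        for f in FORMATS:
            m = config.trials_per_cell
            base = list(ISI_LEVELS_MS) * (m // len(ISI_LEVELS_MS))
            rem = m % len(ISI_LEVELS_MS)
            if rem:
                start = int(rng.integers(len(ISI_LEVELS_MS)))
                base += [ISI_LEVELS_MS[(start + i) % len(ISI_LEVELS_MS)]
                         for i in range(rem)]
            rng.shuffle(base)
            isi_pool[(n, f)] = base

    rows = []
    onset = 0
    class_seen: dict[tuple[int, str], int] = {}
    for i, (n, f) in enumerate(ordered):
        isi = isi_pool[(n, f)].pop()
        k = class_seen.get((n, f), 0)
        class_seen[(n, f)] = k + 1
        rows.append(dict(task=task, trial=i, numerosity=n, format=f,
                         chunk=k, isi_ms=isi, onset_ms=onset))
        onset += STIMULUS_MS + isi
    return pd.DataFrame(rows)


def generate_design(config: CohortConfig,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-participant trial tables for both tasks.

    Each task contains ``4 x 2 x trials_per_cell`` trials (160 at defaults;
    320 across the two tasks) in a pseudorandom order where no more than 3
    consecutive trials share the same numerosity and format, with ISIs
    counterbalanced within every condition cell.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    frames = []
    for p in range(config.n_participants):
        pid = f"sub-{p:02d}"
        for task in TASKS:
            df = _task_design(config, task, rng)
            df.insert(0, "participant", pid)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _tuning_map(n_voxels: int, tuning_width: float,
                rng: np.random.Generator) -> np.ndarray:
    """4 x n_voxels noiseless responses from log-Gaussian tuning curves."""
    prefs = rng.uniform(np.log(2), np.log(8), size=n_voxels)
    logn = np.log(np.array(NUMEROSITIES, dtype=float))[:, None]
    return np.exp(-((logn - prefs[None, :]) ** 2)
                  / (2.0 * tuning_width**2))


def _orthogonalize_blocks(blocks: list[np.ndarray]) -> list[np.ndarray]:
    """Project each map's class-pattern block off the span of all previous
    blocks.

    Independent tuning maps drawn over finitely many voxels overlap by
    O(1/sqrt(V)), and because the tuning family is low-dimensional a
    high-snr classifier can exploit that overlap, leaving residual
    cross-condition decodability even at zero sharing.  Sequentially
    orthogonalizing the blocks (while leaving each map's internal 4-class
    geometry intact) makes "no shared signal" mean exactly zero linear
    cross-decodability of the noiseless patterns.
    """
    nv = blocks[0].shape[1]
    total_rows = sum(b.shape[0] for b in blocks)
    if nv <= total_rows + 4:  # too few voxels to orthogonalize; leave raw
        return blocks
    out = []
    basis = np.empty((0, nv))
    for block in blocks:
        centered = block - block.mean(axis=1, keepdims=True)
        if basis.shape[0]:
            centered = centered - (centered @ basis.T) @ basis
        out.append(centered)
        q, _ = np.linalg.qr(centered.T, mode="reduced")
        basis = np.vstack([basis, q.T])
    return out


def _cell_patterns(config: CohortConfig, alpha_f: float, alpha_t: float,
                   rng: np.random.Generator,
                   n_voxels: int | None = None) -> dict[tuple[int, str, str],
                                                        np.ndarray]:
    """Unit-SD noiseless pattern per (numerosity, format, task) cell."""
    nv = config.n_voxels_per_roi if n_voxels is None else n_voxels
    width = config.tuning_width
    raw = [_tuning_map(nv, width, rng) for _ in range(9)]
    ortho = _orthogonalize_blocks(raw)
    shared = ortho[0]
    per_format = dict(zip(FORMATS, ortho[1:3]))
    per_task = dict(zip(TASKS, ortho[3:5]))
    per_cell = dict(zip([(f, t) for f in FORMATS for t in TASKS],
                        ortho[5:9]))
    out = {}
    for i, n in enumerate(NUMEROSITIES):
        for f in FORMATS:
            for t in TASKS:
                mix = (alpha_f * alpha_t * shared[i]
                       + (1 - alpha_f) * alpha_t * per_format[f][i]
                       + alpha_f * (1 - alpha_t) * per_task[t][i]
                       + (1 - alpha_f) * (1 - alpha_t) * per_cell[(f, t)][i])
                mix = mix - mix.mean()
                sd = mix.std()
                out[(n, f, t)] = mix / sd if sd > 0 else mix
    return out


def generate_neural(
    config: CohortConfig,
    design: pd.DataFrame,
    participant_id: str,
    roi_name: str,
    rng: np.random.Generator,
    alpha_f: float | None = None,
    alpha_t: float | None = None,
) -> PatternDataset:
    """Trial beta patterns for one participant and region.

    Every trial's pattern is ``snr * cell_pattern + N(0, 1)`` voxel noise.
    The per-voxel activation t-statistics used for feature selection are
    emitted as a signal-energy surrogate for the all-conditions-vs-baseline
    contrast: the RMS of the noiseless cell patterns scaled by snr, plus
    measurement noise shrinking with the trial count (condition-blind, so
    selection carries no class bias).
    """
    alpha_f = config.alpha_format if alpha_f is None else alpha_f
    alpha_t = config.alpha_task if alpha_t is None else alpha_t
    sub = design[design["participant"] == participant_id]
    if sub.empty:
        raise ValueError(f"participant {participant_id!r} not in design")
    nv = config.n_voxels_per_roi
    # only a fraction of the region's voxels respond to the stimuli; the
    # rest are pure noise, so activation-based selection has a real target
    n_active = max(1, round(config.active_fraction * nv))
    active = np.sort(rng.choice(nv, size=n_active, replace=False))
    cells = _cell_patterns(config, alpha_f, alpha_t, rng,
                           n_voxels=n_active)
    labels = sub[["numerosity", "format", "task", "chunk"]].copy()
    signal = np.zeros((len(sub), nv))
    signal[:, active] = np.stack([
        cells[(int(r.numerosity), r.format, r.task)]
        for r in sub.itertuples()
    ])
    betas = config.snr * signal + rng.standard_normal(signal.shape)
    energy = np.zeros(nv)
    energy[active] = np.sqrt(np.mean(
        np.stack(list(cells.values())) ** 2, axis=0))
    tstats = (config.snr * energy
              + rng.standard_normal(nv) / np.sqrt(len(sub)))
    return PatternDataset(
        betas=betas, labels=labels, participant_id=participant_id,
        roi_name=roi_name, voxel_tstats=tstats,
    )


def generate_behavior(
    w_true: float,
    n_reps: int = 10,
    rng: np.random.Generator | int | None = None,
    participant_id: str = "sub-00",
) -> BehavioralSession:
    """Simulate one 7-ratio number-comparison session.

    Correctness is Bernoulli with success probability
    ``1 - weber_error(n1, n2, w_true)``; RT is a shifted lognormal whose
    location grows with ratio (harder comparisons are slower).  The side of
    the larger set is counterbalanced across repetitions.
    """
    if w_true <= 0:
        raise ValueError("w_true must be positive")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    trials = []
    for small, large in RATIO_PAIRS:
        p_err = weber_error(small, large, w_true)
        ratio = small / large
        for rep in range(n_reps):
            correct = bool(rng.random() >= p_err)
            rt = 250.0 + float(rng.lognormal(
                mean=np.log(450.0) + 0.8 * ratio, sigma=0.3))
            larger_left = rep % 2 == 0
            n1, n2 = (large, small) if larger_left else (small, large)
            trials.append(ComparisonTrial(n1=n1, n2=n2, correct=correct,
                                          rt_ms=rt))
    order = rng.permutation(len(trials))
    return BehavioralSession(trials=[trials[i] for i in order],
                             participant_id=participant_id)


def generate_covariates(
    config: CohortConfig,
    alpha_values: np.ndarray,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Math standard scores (mean 100, SD 15) correlated with sharing.

    The score's latent Gaussian component correlates with the standardized
    per-participant format-sharing values at ``config.brain_behavior_r``.
    """
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    alpha_values = np.asarray(alpha_values, dtype=float)
    n = alpha_values.size
    r = config.brain_behavior_r
    sd = alpha_values.std()
    z_alpha = (alpha_values - alpha_values.mean()) / sd if sd > 0 else \
        np.zeros(n)
    z_new = rng.standard_normal(n)
    z_math = r * z_alpha + np.sqrt(1.0 - r**2) * z_new
    return pd.DataFrame({
        "participant": [f"sub-{i:02d}" for i in range(n)],
        "math_score": 100.0 + 15.0 * z_math,
    })


def draw_participant_alphas(config: CohortConfig,
                            rng: np.random.Generator) -> np.ndarray:
    """Per-participant format-sharing fractions, clipped to (0, 1)."""
    z = rng.standard_normal(config.n_participants)
    return np.clip(config.alpha_format + config.alpha_sd * z, 0.02, 0.98)


def simulate_cohort(
    config: CohortConfig,
    roi_names: tuple[str, ...] = ("L_parietal",),
) -> Cohort:
    """Generate the full synthetic study for a set of regions.

    Reproducible: the same config (including seed) yields a bit-identical
    cohort.  Every stochastic piece draws from child generators spawned
    deterministically from ``config.rng_seed``.
    """
    root = np.random.SeedSequence(config.rng_seed)
    ss_design, ss_alpha, ss_neural, ss_behav, ss_cov = root.spawn(5)
    design = generate_design(config, np.random.default_rng(ss_design))

    alpha_rng = np.random.default_rng(ss_alpha)
    alphas = draw_participant_alphas(config, alpha_rng)
    w_true = np.clip(
        config.w_mean + config.w_sd * alpha_rng.standard_normal(
            config.n_participants),
        0.05, 0.60,
    )

    patterns: dict[tuple[str, str], PatternDataset] = {}
    neural_children = ss_neural.spawn(config.n_participants * len(roi_names))
    behav_children = ss_behav.spawn(config.n_participants)
    behavior: dict[str, BehavioralSession] = {}
    k = 0
    for p in range(config.n_participants):
        pid = f"sub-{p:02d}"
        for roi in roi_names:
            patterns[(pid, roi)] = generate_neural(
                config, design, pid, roi,
                np.random.default_rng(neural_children[k]),
                alpha_f=float(alphas[p]),
            )
            k += 1
        behavior[pid] = generate_behavior(
            float(w_true[p]), config.behavioral_reps,
            np.random.default_rng(behav_children[p]), participant_id=pid,
        )
    covariates = generate_covariates(
        config, alphas, np.random.default_rng(ss_cov))
    covariates["alpha_format"] = alphas
    covariates["w_true"] = w_true
    return Cohort(config=config, design=design, patterns=patterns,
                  behavior=behavior, covariates=covariates)
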