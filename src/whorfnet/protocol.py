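"""Training and read-out protocol for the 2 × 2 label × semantic-type design.

A "subject" is one random network initialisation.  Each subject is run in
four conditions — {concrete, abstract} × {label, no-label} — that share the
same initial connectivity and weights, the same grounding/word-form pattern
streams and the same trial schedule; only the training inputs differ:

* every training trial presents one grounding pattern to *V1 and *M1_L for
  16 time steps with Hebbian learning on;
* in the label condition the concept's word-form pattern is co-presented
  to *A1 and *M1_i; in the no-label condition those areas receive
  uncorrelated white noise instead;
* trials are separated by noise-driven interstimulus intervals (ISIs) that
  last until global inhibition in *A1 and *PB has fallen back to baseline.

After training, learning is frozen and each grounding pattern is presented
alone (2 steps of stimulation, then 28 steps of free evolution under
baseline noise); the low-pass firing-rate estimate ω of every excitatory
cell 30 steps after pattern onset is the cell's response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from . import netcore, plasticity
from .netcore import (
    AREA_SIZE,
    AREA_NAMES,
    N_AREAS,
    ModelParams,
    Network,
    NetworkState,
    NoiseSpec,
)
from .stimuli import (
    GROUNDING_AREAS,
    WORDFORM_AREAS,
    GroundingPattern,
    GroundingSet,
    PatternSpec,
    WordformSet,
    make_grounding_set,
    make_wordform_set,
)

__all__ = [
    "TrialSchedule",
    "Condition",
    "ResponseMatrix",
    "TrainedModel",
    "ExperimentResults",
    "make_training_schedule",
    "run_training_trial",
    "run_isi",
    "train_model",
    "test_model",
    "run_experiment",
    "SEMANTIC_TYPES",
    "LABEL_LEVELS",
]

log = logging.getLogger(__name__)

SEMANTIC_TYPES = ("concrete", "abstract")
LABEL_LEVELS = ("label", "no-label")

_STIM_STEPS = 16      # training stimulation length (time steps)
_TEST_STIM_STEPS = 2  # testing stimulation length
_TEST_TOTAL_STEPS = 30  # read-out time t30, counted from pattern onset

# sub-stream tags for the per-subject seed fan-out
_TAG_SCHEDULE = 2
_TAG_NOISE_TRAIN = 3
_TAG_NOISE_TEST = 4


@dataclass(frozen=True)
class TrialSchedule:
    """Pseudo-random presentation order with exact per-instance counts."""

    order: np.ndarray  # instance indices, length n_instances * reps
    reps_per_instance: int

    def __len__(self) -> int:
        return int(self.order.size)


@dataclass(frozen=True)
class Condition:
    semantic_type: str   # "concrete" | "abstract"
    label: str           # "label" | "no-label"
    subject_seed: int

    def __post_init__(self) -> None:
        if self.semantic_type not in SEMANTIC_TYPES:
            raise ValueError(f"unknown semantic_type {self.semantic_type!r}")
        if self.label not in LABEL_LEVELS:
            raise ValueError(f"unknown label level {self.label!r}")

    @property
    def with_label(self) -> bool:
        return self.label == "label"

    @property
    def code(self) -> int:
        return 2 * SEMANTIC_TYPES.index(self.semantic_type) + LABEL_LEVELS.index(self.label)


@dataclass
class ResponseMatrix:
    """ω_E(e, t30) for every excitatory cell, per presented pattern.

    ``omega`` has shape (n_patterns, 12 areas, 625 cells); row order is
    concept-major (concept 0 instances 0..2, then concept 1, ...).
    """

    omega: np.ndarray
    concept_of: np.ndarray  # concept id per row
    semantic_type: str
    label: str
    subject_seed: int

    def area(self, name: str) -> np.ndarray:
        return self.omega[:, AREA_NAMES.index(name), :]

    @property
    def n_patterns(self) -> int:
        return self.omega.shape[0]

    def all_areas(self) -> np.ndarray:
        """Concatenated response vectors (n_patterns, 12·625)."""
        return self.omega.reshape(self.n_patterns, -1)

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path, schema=np.array(1), omega=self.omega, concept_of=self.concept_of,
            semantic_type=np.array(self.semantic_type), label=np.array(self.label),
            subject_seed=np.array(self.subject_seed),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ResponseMatrix":
        with np.load(path, allow_pickle=False) as z:
            if int(z["schema"]) != 1:
                raise ValueError(f"unsupported response-matrix schema in {path}")
            return cls(
                omega=z["omega"], concept_of=z["concept_of"],
                semantic_type=str(z["semantic_type"]), label=str(z["label"]),
                subject_seed=int(z["subject_seed"]),
            )


@dataclass
class TrainedModel:
    network: Network
    grounding: GroundingSet
    wordforms: WordformSet
    condition: Condition
    ltp_per_trial: np.ndarray
    ltd_per_trial: np.ndarray
    isi_steps: np.ndarray
    provenance: dict


@dataclass
class ExperimentResults:
    """Response matrices for every (subject, semantic-type, label) cell."""

    responses: dict[tuple[int, str, str], ResponseMatrix]
    subject_seeds: tuple[int, ...]
    provenance: dict = field(default_factory=dict)

    def get(self, subject: int, semantic_type: str, label: str) -> ResponseMatrix:
        return self.responses[(subject, semantic_type, label)]


# ---------------------------------------------------------------------------
# Schedule
# ---------------------------------------------------------------------------


def make_training_schedule(n_instances: int, reps: int, seed: int) -> TrialSchedule:
    """Balanced pseudo-random order: each instance exactly ``reps`` times."""
    if n_instances <= 0 or reps <= 0:
        raise ValueError("n_instances and reps must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _TAG_SCHEDULE]))
    order = np.repeat(np.arange(n_instances), reps)
    rng.shuffle(order)
    return TrialSchedule(order=order, reps_per_instance=reps)


# ---------------------------------------------------------------------------
# Single trial / ISI
# ---------------------------------------------------------------------------


def run_training_trial(
    network: Network,
    state: NetworkState,
    pattern: GroundingPattern,
    wordform: dict[str, frozenset[int]] | None,
    rng: np.random.Generator,
    learn: bool = True,
    extra_rng: np.random.Generator | None = None,
) -> tuple[int, int]:
    """One 16-step stimulation trial; returns (LTP, LTD) event counts.

    ``wordform`` maps the perisylvian primary areas to the label cells; if
    None (no-label condition) those areas receive extra uncorrelated white
    noise instead of a correlated input pattern (drawn from ``extra_rng``
    when given, keeping the baseline stream aligned across conditions).
    """
    p = network.params
    drive = {a: pattern.cells(a) for a in GROUNDING_AREAS}
    if wordform is not None:
        missing = [a for a in WORDFORM_AREAS if a not in wordform]
        if missing:
            raise ValueError(f"wordform pattern missing areas {missing}")
        drive.update({a: wordform[a] for a in WORDFORM_AREAS})
    ext = netcore.external_drive(network, drive)
    noise = NoiseSpec(
        rng=rng, baseline=True,
        extra_areas=() if wordform is not None else WORDFORM_AREAS,
        extra_rng=extra_rng,
    )
    n_ltp = n_ltd = 0
    for _ in range(_STIM_STEPS):
        netcore.step(network, state, ext, noise, tau_favg=p.tau_favg_train)
        if learn:
            rep = plasticity.apply_hebbian(network, state)
            n_ltp += rep.n_ltp
            n_ltd += rep.n_ltd
    return n_ltp, n_ltd


def run_isi(
    network: Network,
    state: NetworkState,
    rng: np.random.Generator,
    learn: bool | None = None,
) -> int:
    """Noise-only interval until *A1/*PB global inhibition is back at baseline.

    All four primary areas receive extra environmental white noise; runs at
    least one step and at most ``params.isi_max_steps`` (a cap hit is
    logged as a warning, not an error).  Returns the number of steps run.
    """
    p = network.params
    if learn is None:
        learn = p.isi_learning and network.learning_enabled
    noise = NoiseSpec(rng=rng, baseline=True, extra_areas=netcore.PRIMARY_AREAS)
    ia1 = AREA_NAMES.index("*A1")
    ipb = AREA_NAMES.index("*PB")
    theta = p.isi_inhibition_threshold
    steps = 0
    while True:
        netcore.step(network, state, None, noise, tau_favg=p.tau_favg_train)
        if learn:
            plasticity.apply_hebbian(network, state)
        steps += 1
        if state.G[ia1] < theta and state.G[ipb] < theta:
            break
        if steps >= p.isi_max_steps:
            log.debug(
                "ISI cap of %d steps hit (G[*A1]=%.2f, G[*PB]=%.2f, θ=%.2f)",
                steps, state.G[ia1], state.G[ipb], theta,
            )
            break
    return steps


# ---------------------------------------------------------------------------
# Model-level training / testing
# ---------------------------------------------------------------------------


def _patterns_for_condition(
    condition: Condition, n_concepts: int
) -> tuple[GroundingSet, WordformSet]:
    spec = PatternSpec(
        n_concepts=n_concepts, semantic_type=condition.semantic_type,
        seed=condition.subject_seed,
    )
    grounding = make_grounding_set(spec)
    wordforms = make_wordform_set(n_concepts, seed=condition.subject_seed)
    return grounding, wordforms


def train_model(
    condition: Condition,
    config,
    progress: bool = False,
) -> TrainedModel:
    """Build, initialise and train one model instance for one condition.

    ``config`` must expose ``params`` (ModelParams), ``n_concepts`` and
    ``reps_per_instance``.  All randomness fans out from
    ``condition.subject_seed``: connectivity, pattern streams, the trial
    schedule and every noise realization are shared across the four
    conditions of a subject (common random numbers), re-seeded per trial so
    that stream positions stay aligned even when ISI lengths differ.  The
    only differences between a subject's condition models are the
    manipulated training inputs themselves.
    """
    params: ModelParams = config.params
    grounding, wordforms = _patterns_for_condition(condition, config.n_concepts)
    network = netcore.build_network(params, seed=condition.subject_seed)
    network.learning_enabled = True
    state = netcore.reset_state(network)

    n_instances = config.n_concepts * grounding.spec.instances_per_concept
    schedule = make_training_schedule(
        n_instances, config.reps_per_instance, seed=condition.subject_seed
    )
    seed = int(condition.subject_seed)

    k = grounding.spec.instances_per_concept
    ltp_log = np.zeros(len(schedule), dtype=np.int64)
    ltd_log = np.zeros(len(schedule), dtype=np.int64)
    isi_log = np.zeros(len(schedule), dtype=np.int64)
    for t, inst in enumerate(schedule.order):
        pattern = grounding.patterns[int(inst)]
        wordform = None
        if condition.with_label:
            wordform = {
                a: wordforms.for_instance(pattern.concept_id, pattern.instance_id, a)
                for a in WORDFORM_AREAS
            }
        trial_rng = np.random.default_rng(
            np.random.SeedSequence([seed, _TAG_NOISE_TRAIN, 0, t])
        )
        extra_rng = np.random.default_rng(
            np.random.SeedSequence([seed, _TAG_NOISE_TRAIN, 1, t])
        )
        ltp_log[t], ltd_log[t] = run_training_trial(
            network, state, pattern, wordform, trial_rng, extra_rng=extra_rng
        )
        isi_rng = np.random.default_rng(
            np.random.SeedSequence([seed, _TAG_NOISE_TRAIN, 2, t])
        )
        isi_log[t] = run_isi(network, state, isi_rng)
        if progress and (t + 1) % 200 == 0:
            log.info(
                "trial %d/%d (LTP %d, LTD %d, ISI %d steps)",
                t + 1, len(schedule), ltp_log[t], ltd_log[t], isi_log[t],
            )

    n_capped = int((isi_log >= params.isi_max_steps).sum())
    if n_capped:
        log.warning("ISI step cap hit on %d/%d trials", n_capped, len(schedule))
    provenance = {
        "subject_seed": int(condition.subject_seed),
        "semantic_type": condition.semantic_type,
        "label": condition.label,
        "n_concepts": int(config.n_concepts),
        "reps_per_instance": int(config.reps_per_instance),
        "n_trials": int(len(schedule)),
    }
    return TrainedModel(
        network=network, grounding=grounding, wordforms=wordforms,
        condition=condition, ltp_per_trial=ltp_log, ltd_per_trial=ltd_log,
        isi_steps=isi_log, provenance=provenance,
    )


def test_model(
    network: Network,
    grounding: GroundingSet,
    noise_seed: int,
    condition: Condition | None = None,
) -> ResponseMatrix:
    """Read-out phase: record ω_E(e, t30) for each grounding pattern.

    Identical for all conditions.  Learning is frozen (and asserted frozen
    via a weight checksum).  Per pattern: global reset, 2 stimulation steps
    with all noise off, then 28 steps with baseline noise only; the rate
    estimate uses the testing time constant τ_Favg = 5.

    The background-noise realization is *frozen*: it is re-seeded
    identically for every pattern presentation (and depends only on
    ``noise_seed``, not on the condition), so response differences between
    patterns — and, for a given subject, between conditions — isolate the
    effect of learning from read-out noise (common-random-numbers variance
    reduction).
    """
    p = network.params
    network.learning_enabled = False
    checksum = network.weight_checksum()
    n_patterns = len(grounding.patterns)
    omega = np.zeros((n_patterns, N_AREAS, AREA_SIZE))
    quiet = NoiseSpec.off()
    for i, pattern in enumerate(grounding.patterns):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(noise_seed), _TAG_NOISE_TEST])
        )
        state = netcore.reset_state(network)
        ext = netcore.external_drive(
            network, {a: pattern.cells(a) for a in GROUNDING_AREAS}
        )
        for _ in range(_TEST_STIM_STEPS):
            netcore.step(network, state, ext, quiet, tau_favg=p.tau_favg_test)
        noise = NoiseSpec(rng=rng, baseline=True, extra_areas=())
        for _ in range(_TEST_TOTAL_STEPS - _TEST_STIM_STEPS):
            netcore.step(network, state, None, noise, tau_favg=p.tau_favg_test)
        omega[i] = state.omega.reshape(N_AREAS, AREA_SIZE)

    if network.weight_checksum() != checksum:
        raise RuntimeError("weights changed during the testing phase")
    return ResponseMatrix(
        omega=omega,
        concept_of=np.array([pt.concept_id for pt in grounding.patterns]),
        semantic_type=grounding.spec.semantic_type,
        label=condition.label if condition is not None else "n/a",
        subject_seed=int(noise_seed),
    )


# ---------------------------------------------------------------------------
# Full experiment
# ---------------------------------------------------------------------------


def subject_seeds(master_seed: int, n_subjects: int) -> tuple[int, ...]:
    """Deterministic per-subject seeds fanned out from one master seed."""
    ss = np.random.SeedSequence(int(master_seed))
    return tuple(int(s) % (2**31) for s in ss.generate_state(n_subjects))


def run_experiment(
    config,
    conditions: Iterable[tuple[str, str]] | None = None,
    checkpoint_dir: str | Path | None = None,
    progress: bool = False,
) -> ExperimentResults:
    """Train and test every subject × condition cell of the design.

    ``config`` must expose ``params``, ``n_concepts``, ``reps_per_instance``,
    ``n_subjects`` and ``master_seed``.  If ``checkpoint_dir`` is given,
    each model's response matrix is persisted there and reloaded instead of
    retrained on a rerun (per-model resume after partial failure).
    """
    if conditions is None:
        conditions = [(s, l) for s in SEMANTIC_TYPES for l in LABEL_LEVELS]
    seeds = subject_seeds(config.master_seed, config.n_subjects)
    if checkpoint_dir is not None:
        checkpoint_dir = Path(checkpoint_dir)
        checkpoint_dir.mkdir(parents=True, exist_ok=True)

    responses: dict[tuple[int, str, str], ResponseMatrix] = {}
    for subj, seed in enumerate(seeds):
        for semantic_type, label in conditions:
            key = (subj, semantic_type, label)
            ckpt = None
            if checkpoint_dir is not None:
                ckpt = checkpoint_dir / f"responses_s{subj}_{semantic_type}_{label}.npz"
                if ckpt.exists():
                    responses[key] = ResponseMatrix.load(ckpt)
                    log.info("loaded checkpoint %s", ckpt)
                    continue
            cond = Condition(semantic_type=semantic_type, label=label, subject_seed=seed)
            if progress:
                log.info("training subject %d, %s/%s (seed %d)", subj, semantic_type,
                         label, seed)
            model = train_model(cond, config, progress=progress)
            rm = test_model(model.network, model.grounding, noise_seed=seed,
                            condition=cond)
            responses[key] = rm
            if ckpt is not None:
                rm.save(ckpt)
    return ExperimentResults(
        responses=responses, subject_seeds=seeds,
        provenance={
            "master_seed": int(config.master_seed),
            "n_subjects": int(config.n_subjects),
            "n_concepts": int(config.n_concepts),
            "reps_per_instance": int(config.reps_per_instance),
        },
    )
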