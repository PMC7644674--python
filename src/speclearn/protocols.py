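"""Training protocols: scratch, transfer and cumulative learning.

A protocol is a sequence of steps, each pairing a dataset with a
representation mode.  The convolutional representation threads through
the sequence; the decision head is rebuilt for every task:

SCRATCH      train_all(target)
TRANSFER     train_all(source) -> freeze_all_conv(target)
SCENARIO_A   train_all(source) -> fine_tune(intermediate)
             -> freeze_all_conv(target)
SCENARIO_B   train_all(source) -> fine_tune(intermediate_1)
             -> fine_tune(intermediate_2) -> freeze_all_conv_but_last(target)

Every step is evaluated on its own stratified held-out test subset with
accuracy, one-vs-rest sensitivity/specificity and the confusion matrix.
The harness repeats a protocol over independent stratified 60/20/20
resamples and reports mean +/- sd accuracy; protocols are compared with a
Welch t-test over per-iteration accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .binning import SpectraDataset, SplitIndices, stratified_split
from .nn.classifier import TrainConfig, train_network
from .nn.network import (
    ModelState,
    Network,
    init_parameters,
    replace_decision_head,
    set_representation_mode,
)
from .nn.architectures import build_architecture

__all__ = [
    "Metrics",
    "ProtocolStep",
    "StepResult",
    "ResultTable",
    "TrainConfig",
    "PROTOCOL_PRESETS",
    "protocol_steps",
    "evaluate",
    "evaluate_state",
    "run_protocol",
    "retention_evaluation",
    "run_experiment",
    "compare_ttest",
]


@dataclass(frozen=True)
class Metrics:
    """Accuracy, one-vs-rest sensitivity/specificity and confusion counts."""

    accuracy: float
    sensitivity: np.ndarray
    specificity: np.ndarray
    confusion: np.ndarray  # rows = truth, cols = prediction

    @classmethod
    def from_predictions(cls, y_true, y_pred, n_classes: int) -> "Metrics":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        conf = np.zeros((n_classes, n_classes), dtype=int)
        np.add.at(conf, (y_true, y_pred), 1)
        return cls.from_confusion(conf)

    @classmethod
    def from_confusion(cls, conf: np.ndarray) -> "Metrics":
        conf = np.asarray(conf)
        total = conf.sum()
        tp = np.diag(conf).astype(float)
        fn = conf.sum(axis=1) - tp
        fp = conf.sum(axis=0) - tp
        tn = total - tp - fn - fp
        with np.errstate(invalid="ignore", divide="ignore"):
            sens = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
            spec = np.where(tn + fp > 0, tn / (tn + fp), np.nan)
        return cls(float(tp.sum() / total), sens, spec, conf)


@dataclass(frozen=True)
class ProtocolStep:
    """One stage: which dataset, how the representation is handled."""

    dataset: str
    representation_mode: str  # train_all | fine_tune | freeze_all_conv | freeze_all_conv_but_last


@dataclass
class StepResult:
    step: ProtocolStep
    metrics: Metrics
    state: ModelState  # trained checkpoint after this step
    split: SplitIndices
    history: dict


PROTOCOL_PRESETS = {
    "SCRATCH": ("target",),
    "TRANSFER": ("source", "target"),
    "SCENARIO_A": ("source", "intermediate", "target"),
    "SCENARIO_B": ("source", "intermediate_1", "intermediate_2", "target"),
}


def protocol_steps(preset: str, **datasets: str) -> list[ProtocolStep]:
    """Expand a named preset into explicit steps.

    Keyword arguments map the preset's roles onto dataset names, e.g.
    ``protocol_steps("TRANSFER", source="source", target="histology12")``.
    """
    if preset not in PROTOCOL_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {list(PROTOCOL_PRESETS)}")
    roles = PROTOCOL_PRESETS[preset]
    missing = [r for r in roles if r not in datasets]
    if missing:
        raise ValueError(f"preset {preset} needs datasets for roles {missing}")
    steps = [ProtocolStep(datasets[roles[0]], "train_all")]
    if preset == "TRANSFER":
        steps.append(ProtocolStep(datasets["target"], "freeze_all_conv"))
    elif preset == "SCENARIO_A":
        steps.append(ProtocolStep(datasets["intermediate"], "fine_tune"))
        steps.append(ProtocolStep(datasets["target"], "freeze_all_conv"))
    elif preset == "SCENARIO_B":
        steps.append(ProtocolStep(datasets["intermediate_1"], "fine_tune"))
        steps.append(ProtocolStep(datasets["intermediate_2"], "fine_tune"))
        steps.append(ProtocolStep(datasets["target"], "freeze_all_conv_but_last"))
    return steps


def evaluate_state(state: ModelState, ds: SpectraDataset, test_indices) -> Metrics:
    """Evaluate a trained model state on a dataset's test subset."""
    test_indices = np.asarray(test_indices)
    net = Network(state)
    proba = net.predict_proba(ds.matrix[test_indices])
    y_pred = proba.argmax(axis=1)
    return Metrics.from_predictions(ds.labels[test_indices], y_pred, ds.n_classes)


evaluate = evaluate_state


def train_step(
    state: ModelState | None,
    ds: SpectraDataset,
    split: SplitIndices,
    mode: str,
    arch_name: str,
    cfg: TrainConfig,
) -> tuple[ModelState, dict]:
    """Fit one protocol step and return the best checkpoint."""
    if state is None:
        if mode != "train_all":
            raise ValueError("the first step of a protocol must be train_all")
        arch = build_architecture(arch_name, ds.n_features, ds.n_classes)
        state = init_parameters(arch, seed=cfg.seed)
    else:
        state = replace_decision_head(state, ds.n_classes, seed=cfg.seed)
    state = set_representation_mode(state, mode)
    if mode == "fine_tune":
        # fine-tuning nudges an already-good representation: standard
        # practice is a reduced step size to avoid catastrophic drift
        cfg = TrainConfig(cfg.max_epochs, cfg.batch_size, cfg.learning_rate * 0.1,
                          cfg.patience, cfg.seed, cfg.class_weight)
    return train_network(
        state,
        ds.matrix[split.train], ds.labels[split.train],
        ds.matrix[split.validation], ds.labels[split.validation],
        cfg,
    )


def run_protocol(
    steps: list[ProtocolStep],
    datasets: dict[str, SpectraDataset],
    arch_name: str = "variant_lecun",
    cfg: TrainConfig = TrainConfig(),
    split_seed: int = 0,
    initial_state: ModelState | None = None,
) -> list[StepResult]:
    """Execute protocol steps in order, threading the representation.

    Every step draws its own stratified 60/20/20 split (seeded), trains per
    its representation mode and is scored on its held-out test subset.  All
    datasets must share one feature length — a convolutional stack cannot
    be threaded between inputs of different widths.
    """
    dims = {datasets[s.dataset].n_features for s in steps}
    if len(dims) != 1:
        raise ValueError(f"steps mix feature lengths {sorted(dims)}; rebin to one grid")
    state = initial_state
    if state is None and steps[0].representation_mode != "train_all":
        raise ValueError("the first step of a protocol must be train_all")
    results = []
    for k, step in enumerate(steps):
        ds = datasets[step.dataset]
        split = stratified_split(ds.labels, (0.6, 0.2, 0.2), seed=split_seed + 1000 * k)
        if state is None:
            state, history = train_step(None, ds, split, step.representation_mode,
                                        arch_name, cfg)
        else:
            state, history = train_step(state, ds, split, step.representation_mode,
                                        arch_name, cfg)
        metrics = evaluate_state(state, ds, split.test)
        results.append(StepResult(step, metrics, state.copy(), split, history))
    return results


def retention_evaluation(
    results: list[StepResult],
    datasets: dict[str, SpectraDataset],
    refit_head: bool = False,
    cfg: TrainConfig | None = None,
) -> list[dict]:
    """How much earlier-task accuracy the final representation retains.

    For every earlier step, the final representation is combined with that
    step's saved decision head and re-evaluated on that step's own test
    subset.  With ``refit_head=True`` the head is instead retrained (conv
    stack frozen) before evaluation.  Returns per-step dicts with the
    original and retained accuracy and their difference.
    """
    final = results[-1].state
    out = []
    for res in results[:-1]:
        ds = datasets[res.step.dataset]
        if refit_head:
            if cfg is None:
                raise ValueError("refit_head=True needs a TrainConfig")
            state = replace_decision_head(final, ds.n_classes, seed=cfg.seed)
            state = set_representation_mode(state, "freeze_all_conv")
            state, _ = train_network(
                state,
                ds.matrix[res.split.train], ds.labels[res.split.train],
                ds.matrix[res.split.validation], ds.labels[res.split.validation],
                cfg,
            )
        else:
            # graft the step's saved decision head onto the final representation
            state = res.state.copy()
            end = state.architecture.representation_end
            for i in range(end):
                if final.parameters[i] is not None:
                    state.parameters[i] = {k: v.copy()
                                           for k, v in final.parameters[i].items()}
        retained = evaluate_state(state, ds, res.split.test)
        out.append({
            "dataset": res.step.dataset,
            "original_accuracy": res.metrics.accuracy,
            "retained_accuracy": retained.accuracy,
            "loss": res.metrics.accuracy - retained.accuracy,
        })
    return out


@dataclass
class ResultTable:
    """Per (protocol, architecture, dataset) accuracies over iterations."""

    entries: dict = field(default_factory=dict)  # key -> list of per-iteration Metrics

    def add(self, protocol: str, architecture: str, dataset: str, metrics: Metrics):
        self.entries.setdefault((protocol, architecture, dataset), []).append(metrics)

    def accuracies(self, protocol: str, architecture: str, dataset: str) -> np.ndarray:
        return np.array([m.accuracy
                         for m in self.entries[(protocol, architecture, dataset)]])

    def summary(self) -> dict:
        out = {}
        for key, ms in self.entries.items():
            acc = np.array([m.accuracy for m in ms])
            out[key] = {
                "mean": float(acc.mean()),
                "sd": float(acc.std(ddof=1)) if len(acc) > 1 else 0.0,
                "n_iterations": len(acc),
                "formatted": f"{acc.mean():.2f} ± {acc.std(ddof=1) if len(acc) > 1 else 0.0:.2f}",
            }
        return out


def run_experiment(
    protocols: dict[str, list[ProtocolStep]],
    datasets: dict[str, SpectraDataset],
    arch_names=("variant_lecun",),
    n_iterations: int = 10,
    base_seed: int = 0,
    cfg: TrainConfig = TrainConfig(),
    reuse_source: bool = False,
) -> ResultTable:
    """Repeat each protocol over independent stratified resamples.

    Iteration ``i`` uses split seed ``base_seed + i`` for every protocol and
    architecture, so comparisons between protocols are paired on identical
    subsets.  ``reuse_source=True`` trains the first (source) step once per
    (protocol, architecture) and reuses its representation across
    iterations — the later, small-task steps are still re-split and
    retrained every iteration.
    """
    if n_iterations < 2:
        raise ValueError("need at least 2 iterations for mean +/- sd")
    table = ResultTable()
    for arch in arch_names:
        for name, steps in protocols.items():
            source_state = None
            source_result = None
            if reuse_source and len(steps) > 1:
                ds = datasets[steps[0].dataset]
                split = stratified_split(ds.labels, (0.6, 0.2, 0.2), seed=base_seed)
                step_cfg = TrainConfig(cfg.max_epochs, cfg.batch_size, cfg.learning_rate,
                                       cfg.patience, base_seed, cfg.class_weight)
                source_state, history = train_step(None, ds, split, "train_all",
                                                   arch, step_cfg)
                source_result = StepResult(steps[0], evaluate_state(source_state, ds,
                                                                    split.test),
                                           source_state.copy(), split, history)
            for it in range(n_iterations):
                seed = base_seed + it
                it_cfg = TrainConfig(cfg.max_epochs, cfg.batch_size, cfg.learning_rate,
                                     cfg.patience, seed, cfg.class_weight)
                if source_state is not None:
                    results = run_protocol(steps[1:], datasets, arch, it_cfg,
                                           split_seed=seed,
                                           initial_state=source_state.copy())
                    results = [source_result] + results
                else:
                    results = run_protocol(steps, datasets, arch, it_cfg, split_seed=seed)
                table.add(name, arch, results[-1].step.dataset, results[-1].metrics)
    return table


def compare_ttest(runs_a, runs_b) -> float:
    """Two-sided Welch t-test on per-iteration accuracies.

    When both sequences are constant and equal the statistic is undefined;
    the comparison is then reported as p = 1.0 (no evidence of difference).
    """
    a = np.asarray(runs_a, dtype=float)
    b = np.asarray(runs_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two runs per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)
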