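"""End-to-end training protocol, evaluation and batch statistics.

One run trains the architecture on a labeled spike dataset in two phases
over a seed-shuffled pass through the training split:

* **Phase 1 (unsupervised)** — the first ``feedback_onset_fraction`` of
  the samples drive the reservoir -> winner synapses with local STDP
  only; the readout is then fitted on the collected second-reservoir
  features, making it a rough estimator of the data.
* **Phase 2 (feedback)** — for each remaining sample the frozen readout
  predicts a label, the reward system compares it with the truth, and
  the eligibility-trace snapshot carries the global update into the
  plastic weights (per-sample updates, as in stochastic gradient
  descent).  During this phase the local updates feed the eligibility
  trace only; the reward path owns the weights, so the ``none`` mode
  leaves them untouched.

Before the test split is evaluated the readout is refitted on all
training samples, with their features recomputed under the final
(frozen) weights so that the fitted representation matches the one used
at test time.  Across runs the reservoir structure is fixed (it is a
function of the liquid configs alone) while the winner layer's initial
weights and the sample order are re-randomized from each run's seed;
this also means the first reservoir's response to every sample can be
computed once per dataset and shared across runs and modes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import Dataset, SyntheticSpec, downsample_channels, from_spec, load_shd
from .feedback import FeedbackMode, apply_feedback, compute_reward
from .liquid import LiquidConfig, LiquidTopology, attach_inputs, build_liquid, run_liquid
from .neurons import LIFParams
from .readout import ReadoutModel, extract_features, fit_readout, predict
from .stats import evaluate_confusion, mann_whitney_u
from .synapses import SynapseModelParams
from .wta import RSTDPParams, WTAConfig, build_wta, run_wta

__all__ = [
    "ExperimentConfig",
    "RunResult",
    "BatchResult",
    "default_config",
    "run_training",
    "run_batch",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Declarative description of one experiment."""

    liquid1: LiquidConfig = field(default_factory=LiquidConfig)
    liquid2: LiquidConfig = field(default_factory=lambda: LiquidConfig(seed=1))
    wta: WTAConfig = field(default_factory=WTAConfig)
    rstdp: RSTDPParams = field(default_factory=RSTDPParams)
    feedback_mode: str = "forgiving"
    feedback_onset_fraction: float = 0.5
    n_epochs: int = 1
    dt: float = 1.0
    seeds: tuple[int, ...] = (0,)
    synthetic: SyntheticSpec | None = field(default_factory=SyntheticSpec)
    shd_train_path: str | None = None
    shd_test_path: str | None = None
    shd_downsample: int = 10
    readout_seed: int = 0
    local_updates_in_feedback_phase: bool = False
    carry_traces: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.feedback_onset_fraction <= 1.0:
            raise ValueError("feedback_onset_fraction must lie in [0, 1]")
        if self.dt <= 0 or self.n_epochs < 1:
            raise ValueError("dt must be positive and n_epochs >= 1")
        if self.liquid2.n_input_channels != self.wta.n_excitatory:
            raise ValueError(
                "second reservoir must expose one input channel per winner neuron"
            )

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        raw = dataclasses.asdict(self)
        return _plainify(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        def build(klass, section):
            return klass(**section) if section is not None else None

        def liquid(section):
            section = dict(section)
            section["grid_shape"] = tuple(section["grid_shape"])
            section["lif"] = LIFParams(**section["lif"])
            section["synapse"] = SynapseModelParams(**section["synapse"])
            return LiquidConfig(**section)

        wta_raw = dict(raw["wta"])
        wta_raw["lif"] = LIFParams(**wta_raw["lif"])
        return cls(
            liquid1=liquid(raw["liquid1"]),
            liquid2=liquid(raw["liquid2"]),
            wta=WTAConfig(**wta_raw),
            rstdp=RSTDPParams(**raw["rstdp"]),
            feedback_mode=raw["feedback_mode"],
            feedback_onset_fraction=raw["feedback_onset_fraction"],
            n_epochs=raw["n_epochs"],
            dt=raw["dt"],
            seeds=tuple(raw["seeds"]),
            synthetic=build(SyntheticSpec, raw.get("synthetic")),
            shd_train_path=raw.get("shd_train_path"),
            shd_test_path=raw.get("shd_test_path"),
            shd_downsample=raw.get("shd_downsample", 10),
            readout_seed=raw.get("readout_seed", 0),
            local_updates_in_feedback_phase=raw.get(
                "local_updates_in_feedback_phase", False
            ),
            carry_traces=raw.get("carry_traces", False),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _plainify(obj):
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def default_config(
    n_classes: int = 4,
    seeds: tuple[int, ...] = (0,),
    synthetic: SyntheticSpec | None = None,
    feedback_mode: str = "forgiving",
) -> ExperimentConfig:
    """Config with consistent wiring between the winner layer and liquid 2."""
    if synthetic is None:
        synthetic = SyntheticSpec(n_classes=n_classes)
    wta = WTAConfig()
    liquid1 = LiquidConfig(n_input_channels=synthetic.n_channels, seed=0)
    liquid2 = LiquidConfig(
        n_input_channels=wta.n_excitatory,
        input_fanout_prob=wta.wta_to_liquid2_prob,
        input_weight=wta.wta_to_liquid2_weight,
        seed=1,
    )
    return ExperimentConfig(
        liquid1=liquid1,
        liquid2=liquid2,
        wta=wta,
        synthetic=synthetic,
        seeds=tuple(seeds),
        feedback_mode=feedback_mode,
    )


@dataclass
class RunResult:
    """Outcome of one (mode, seed) training run."""

    seed: int
    mode: str
    accuracy: float
    predictions: np.ndarray
    confusion: np.ndarray

    def __post_init__(self) -> None:
        if int(self.confusion.sum()) != self.predictions.size:
            raise ValueError("confusion matrix does not tally the test set")


@dataclass
class BatchResult:
    table: pd.DataFrame
    summary: dict
    confusions: dict  # (mode, seed) -> np.ndarray


def load_experiment_data(config: ExperimentConfig) -> tuple[Dataset, Dataset]:
    """Materialize the train/test splits named by the config."""
    if config.shd_train_path is not None:
        train = load_shd(config.shd_train_path, split="train")
        test = load_shd(config.shd_test_path, split="test")
        if config.shd_downsample > 1:
            train = downsample_channels(train, config.shd_downsample)
            test = downsample_channels(test, config.shd_downsample)
        return train, test
    if config.synthetic is None:
        raise ValueError("config names neither an SHD path nor a synthetic spec")
    return from_spec(config.synthetic, "train"), from_spec(config.synthetic, "test")


def precompute_liquid1(
    config: ExperimentConfig, dataset: Dataset, topology: LiquidTopology | None = None
) -> list[np.ndarray]:
    """First-reservoir spike rasters per sample (deterministic, shareable)."""
    if topology is None:
        topology = build_liquid(config.liquid1)
    out = []
    for sample in dataset.samples:
        sched = attach_inputs(topology, sample, config.dt)
        duration_ms = sample.duration * 1000.0
        out.append(run_liquid(topology, config.liquid1, sched, duration_ms, config.dt))
    return out


def _liquid2_raster(
    config: ExperimentConfig,
    topo2: LiquidTopology,
    exc_raster: np.ndarray,
    duration_ms: float,
) -> np.ndarray:
    sched = exc_raster.astype(np.float64) @ topo2.input_matrix
    return run_liquid(topo2, config.liquid2, sched, duration_ms, config.dt)


def run_training(
    config: ExperimentConfig,
    train: Dataset,
    test: Dataset,
    seed: int,
    mode: str | FeedbackMode | None = None,
    liquid1_train: list[np.ndarray] | None = None,
    liquid1_test: list[np.ndarray] | None = None,
) -> RunResult:
    """Train for one seed and evaluate on the test split.

    ``liquid1_train``/``liquid1_test`` are optional precomputed
    first-reservoir rasters (see :func:`precompute_liquid1`); they are a
    pure cache and do not change any result.
    """
    mode = FeedbackMode(mode if mode is not None else config.feedback_mode)
    topo1 = build_liquid(config.liquid1)
    topo2 = build_liquid(config.liquid2)
    if liquid1_train is None:
        liquid1_train = precompute_liquid1(config, train, topo1)
    if liquid1_test is None:
        liquid1_test = precompute_liquid1(config, test, topo1)

    rng = np.random.default_rng(seed)
    wta = build_wta(config.wta, topo1.n_neurons, rng, config.rstdp)
    order = np.concatenate(
        [rng.permutation(len(train)) for _ in range(config.n_epochs)]
    )
    onset = int(round(config.feedback_onset_fraction * order.size))

    n2 = topo2.n_neurons
    feats = np.zeros((order.size, n2))
    labels = np.zeros(order.size, dtype=np.int64)
    readout: ReadoutModel | None = None

    for pos, idx in enumerate(order):
        idx = int(idx)
        sample = train.samples[idx]
        duration_ms = sample.duration * 1000.0
        in_feedback = pos >= onset
        if in_feedback and readout is None:
            readout = fit_readout(feats[:pos], labels[:pos], seed=config.readout_seed)
        exc_raster, e_trace = run_wta(
            wta,
            liquid1_train[idx],
            config.rstdp,
            config.dt,
            plastic=(not in_feedback) or config.local_updates_in_feedback_phase,
            accumulate_eligibility=True,
            reset_traces=not config.carry_traces,
        )
        raster2 = _liquid2_raster(config, topo2, exc_raster, duration_ms)
        feats[pos] = extract_features(raster2, sample.duration)
        labels[pos] = sample.label
        if in_feedback and mode is not FeedbackMode.NONE:
            pred = predict(readout, feats[pos])
            reward = compute_reward(int(pred), sample.label, mode)
            apply_feedback(wta.state, reward, config.rstdp)

    # Final refit: recompute every training sample's features under the
    # final weights so the readout sees the same representation the test
    # split will, then fit on all of them.
    final_feats = np.zeros((len(train), n2))
    for idx, sample in enumerate(train.samples):
        exc_raster, _ = run_wta(
            wta,
            liquid1_train[idx],
            config.rstdp,
            config.dt,
            plastic=False,
            accumulate_eligibility=False,
        )
        raster2 = _liquid2_raster(config, topo2, exc_raster, sample.duration * 1000.0)
        final_feats[idx] = extract_features(raster2, sample.duration)
    readout = fit_readout(final_feats, train.labels, seed=config.readout_seed)

    predictions = np.zeros(len(test), dtype=np.int64)
    for i, sample in enumerate(test.samples):
        exc_raster, _ = run_wta(
            wta,
            liquid1_test[i],
            config.rstdp,
            config.dt,
            plastic=False,
            accumulate_eligibility=False,
        )
        raster2 = _liquid2_raster(config, topo2, exc_raster, sample.duration * 1000.0)
        predictions[i] = predict(readout, extract_features(raster2, sample.duration))

    cm, accuracy = evaluate_confusion(predictions, test.labels, train.n_classes)
    return RunResult(
        seed=seed, mode=mode.value, accuracy=accuracy, predictions=predictions, confusion=cm
    )


def run_batch(
    config: ExperimentConfig,
    modes: list[str] | None = None,
    out_dir: str | Path | None = None,
) -> BatchResult:
    """Run every (mode, seed) combination and summarize.

    Emits, when ``out_dir`` is given: ``results.tsv`` (one row per run),
    ``summary.json`` (per-mode statistics and pairwise Mann-Whitney
    comparisons of the per-seed accuracies), per-run confusion matrices
    as TSV, and a ``config.yaml`` snapshot.  All outputs are byte-stable
    across re-runs of the same config.  Failed runs are recorded in the
    table with a null accuracy rather than dropped.
    """
    if modes is None:
        modes = [config.feedback_mode]
    modes = [FeedbackMode(m).value for m in modes]
    train, test = load_experiment_data(config)
    topo1 = build_liquid(config.liquid1)
    liquid1_train = precompute_liquid1(config, train, topo1)
    liquid1_test = precompute_liquid1(config, test, topo1)

    rows = []
    confusions: dict[tuple[str, int], np.ndarray] = {}
    for mode in modes:
        for seed in config.seeds:
            try:
                res = run_training(
                    config, train, test, int(seed), mode, liquid1_train, liquid1_test
                )
            except Exception as exc:  # record, don't silently drop
                rows.append(
                    {"mode": mode, "seed": int(seed), "accuracy": np.nan, "error": str(exc)}
                )
                continue
            rows.append(
                {"mode": mode, "seed": int(seed), "accuracy": res.accuracy, "error": ""}
            )
            confusions[(mode, int(seed))] = res.confusion
    table = pd.DataFrame(rows, columns=["mode", "seed", "accuracy", "error"])

    summary: dict = {"modes": {}, "comparisons": {}}
    for mode in modes:
        acc = table.loc[(table["mode"] == mode) & table["error"].eq(""), "accuracy"]
        summary["modes"][mode] = {
            "n_runs": int(acc.size),
            "mean_accuracy": float(acc.mean()) if acc.size else None,
            "median_accuracy": float(acc.median()) if acc.size else None,
        }
    for i, m_a in enumerate(modes):
        for m_b in modes[i + 1 :]:
            acc_a = table.loc[table["mode"] == m_a, "accuracy"].dropna().to_numpy()
            acc_b = table.loc[table["mode"] == m_b, "accuracy"].dropna().to_numpy()
            if acc_a.size and acc_b.size:
                u, p = mann_whitney_u(acc_a, acc_b)
                summary["comparisons"][f"{m_a}_vs_{m_b}"] = {"U": u, "p_two_sided": p}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "results.tsv", sep="\t", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        for (mode, seed), cm in confusions.items():
            np.savetxt(out / f"confusion_{mode}_{seed}.tsv", cm, fmt="%d", delimiter="\t")
        config.to_yaml(out / "config.yaml")
        with open(out / "run.log", "w") as fh:
            fh.write(f"train samples: {len(train)}, test samples: {len(test)}\n")
            for row in rows:
                fh.write(
                    f"mode={row['mode']} seed={row['seed']} "
                    f"accuracy={row['accuracy']} error={row['error'] or '-'}\n"
                )

    return BatchResult(table=table, summary=summary, confusions=confusions)
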