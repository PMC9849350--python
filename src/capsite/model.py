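"""Model/Results interface over the whole pipeline.

:class:`BindingSiteModel` is built from labelled feature bundles (or a
simulated/on-disk dataset) plus a :class:`~capsite.network.ModelConfig`;
``fit()`` trains either a single network under one of the imbalance
strategies {none, cost_sensitive, oversample, undersample} or the
asymmetric-bagging ensemble, and returns a :class:`BindingSiteResults`
carrying the trained members, the training history, prediction and
evaluation methods, a ``summary()`` table, and directory save/load.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import FeatureBundle, WindowConfig, assemble_bundle
from .imbalance import (
    STRATEGIES,
    PartitionPlan,
    combine_predictions,
    resample_indices,
    train_ensemble,
)
from .metrics import MetricsReport, evaluate
from .network import (
    ModelConfig,
    ModelParams,
    load_model,
    model_forward,
    save_model,
    stratified_split,
    train_model,
)
from .synth import SimDataset, read_fixture_bundle

logger = logging.getLogger("capsite")


def bundles_from_dataset(
    dataset: SimDataset, config: ModelConfig
) -> list[FeatureBundle]:
    """Assemble per-protein feature bundles for the channels a config uses."""
    wc = WindowConfig(config.window_size)
    out = []
    for rec in dataset.records:
        out.append(
            assemble_bundle(
                rec,
                pssm=dataset.pssms.get(rec.id) if "mbf" in config.channels else None,
                embedding=(
                    dataset.embeddings.get(rec.id)
                    if "embedding" in config.channels
                    else None
                ),
                cfg=wc,
                channels=config.channels,
            )
        )
    return out


class BindingSiteModel:
    """A per-residue binding-site classifier specification, ready to fit."""

    def __init__(
        self,
        bundles: list[FeatureBundle],
        config: ModelConfig | None = None,
        strategy: str = "ensemble",
        max_members: int | None = None,
    ):
        if strategy not in STRATEGIES:
            raise ValueError(
                f"unknown strategy {strategy!r}; choose from {STRATEGIES}"
            )
        self.bundles = list(bundles)
        self.config = config or ModelConfig()
        self.strategy = strategy
        self.max_members = max_members

    @classmethod
    def from_dataset(
        cls, dataset: SimDataset, config: ModelConfig | None = None, **kwargs
    ) -> "BindingSiteModel":
        config = config or ModelConfig()
        return cls(bundles_from_dataset(dataset, config), config, **kwargs)

    @classmethod
    def from_directory(
        cls, directory, config: ModelConfig | None = None, **kwargs
    ) -> "BindingSiteModel":
        """Build from a fixture-bundle directory (FASTA + labels + PSSMs +
        embedding container + manifest)."""
        return cls.from_dataset(read_fixture_bundle(directory), config, **kwargs)

    def fit(self) -> "BindingSiteResults":
        cfg = self.config
        if self.strategy == "ensemble":
            ensemble, logs = train_ensemble(self.bundles, cfg, self.max_members)
            return BindingSiteResults(
                config=cfg,
                strategy=self.strategy,
                members=ensemble.members,
                plan=ensemble.plan,
                logs=logs,
            )
        labels = np.concatenate([b.labels for b in self.bundles])
        if len(np.unique(labels)) < 2:
            raise ValueError("training data contain a single class")
        train_idx, val_idx = stratified_split(labels, cfg.val_fraction, cfg.seed)
        plan = resample_indices(labels, self.strategy, cfg.seed, candidates=train_idx)
        weights = None
        if self.strategy == "cost_sensitive":
            weights = np.array([plan.class_weights[labels[i]] for i in plan.indices])
        params, history = train_model(
            self.bundles, cfg,
            train_idx=plan.indices, val_idx=val_idx, sample_weights=weights,
        )
        return BindingSiteResults(
            config=cfg,
            strategy=self.strategy,
            members=[params],
            plan=None,
            logs=[history],
        )


@dataclass
class BindingSiteResults:
    """Trained members plus everything needed to predict and evaluate."""

    config: ModelConfig
    strategy: str
    members: list[ModelParams]
    plan: PartitionPlan | None
    logs: list[list[dict]] = field(default_factory=list)

    # -- prediction -----------------------------------------------------------
    def predict_proba(self, bundles: list[FeatureBundle]) -> list[np.ndarray]:
        """Combined per-protein ``(L, 2)`` probability matrices."""
        per_member = [model_forward(bundles, m) for m in self.members]
        return [
            combine_predictions([pm[i] for pm in per_member])
            for i in range(len(bundles))
        ]

    def predict(self, bundles: list[FeatureBundle]) -> list[np.ndarray]:
        """Positive-class score per residue, one vector per protein."""
        return [p[:, 1] for p in self.predict_proba(bundles)]

    def evaluate(
        self,
        bundles: list[FeatureBundle],
        threshold: float | None = None,
        match_prevalence: bool = False,
    ) -> MetricsReport:
        if any(b.labels is None for b in bundles):
            raise ValueError("evaluation bundles must carry labels")
        scores = np.concatenate(self.predict(bundles))
        labels = np.concatenate([b.labels for b in bundles])
        return evaluate(
            scores, labels,
            threshold=self.config.threshold if threshold is None else threshold,
            match_prevalence=match_prevalence,
        )

    # -- reporting ------------------------------------------------------------
    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Binding-site prediction model",
            "=" * 45,
            f"strategy:            {self.strategy}",
            f"channels:            {', '.join(cfg.channels)}",
            f"window size (MBF):   {cfg.window_size}",
            f"recurrent stacks:    {list(cfg.hidden_sizes)} (bidirectional)",
            f"capsules:            {cfg.caps_count} x dim {cfg.caps_dim}, "
            f"{cfg.routing_iters} routing iterations",
            f"members:             {len(self.members)}",
            f"seed:                {cfg.seed}",
        ]
        if self.plan is not None:
            lines.append(
                f"negative partition:  {self.plan.n_models} balanced bags of "
                f"{len(self.plan.positives)}"
            )
        for m, history in enumerate(self.logs):
            best = min(h["val_loss"] for h in history)
            lines.append(
                f"member {m}: {len(history)} epochs, best val loss {best:.4f}"
            )
        return "\n".join(lines)

    # -- persistence ----------------------------------------------------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for m, params in enumerate(self.members):
            save_model(params, directory / f"member_{m:02d}")
        manifest = {
            "strategy": self.strategy,
            "n_members": len(self.members),
            "config": self.config.to_dict(),
            "logs": self.logs,
            "plan": None
            if self.plan is None
            else {
                "positives": self.plan.positives.tolist(),
                "subsets": [s.tolist() for s in self.plan.subsets],
                "n_models": self.plan.n_models,
            },
        }
        (directory / "ensemble.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "BindingSiteResults":
        directory = Path(directory)
        manifest = json.loads((directory / "ensemble.json").read_text())
        members = [
            load_model(directory / f"member_{m:02d}")
            for m in range(manifest["n_members"])
        ]
        plan = None
        if manifest["plan"] is not None:
            plan = PartitionPlan(
                np.array(manifest["plan"]["positives"], dtype=int),
                [np.array(s, dtype=int) for s in manifest["plan"]["subsets"]],
                manifest["plan"]["n_models"],
            )
        return cls(
            config=ModelConfig.from_dict(manifest["config"]),
            strategy=manifest["strategy"],
            members=members,
            plan=plan,
            logs=manifest["logs"],
        )
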