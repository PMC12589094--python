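"""Model/Results front end.

`DiseaseTrajectoryModel` binds a prepared cohort, a vocabulary and an
architecture configuration; `fit` runs the optimization and returns a
`TrajectoryModelResults` carrying the trained network, the loss trace
and the downstream machinery (rate prediction, sampling, longitudinal
evaluation, attribution, embedding export).

    >>> model = DiseaseTrajectoryModel(cohort, vocab)          # doctest: +SKIP
    >>> res = model.fit()                                      # doctest: +SKIP
    >>> print(res.summary())                                   # doctest: +SKIP
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import attribution as _attribution
from . import evaluation as _evaluation
from . import sampling as _sampling
from . import training as _training
from .model import ModelConfig, TrajectoryTransformer, count_parameters
from .trajectory import Trajectory, prepare_cohort, read_trajectories
from .vocab import TokenVocabulary


class DiseaseTrajectoryModel:
    """An unfitted trajectory transformer bound to a cohort.

    Parameters
    ----------
    cohort
        Prepared trajectories (death-truncated, no-event padding
        inserted).  Pass ``prepare=True`` together with a seed to run
        the preparation pipeline here.
    vocab
        The token vocabulary.
    config
        Architecture; defaults to the desk-scale profile sized to the
        vocabulary.
    """

    def __init__(
        self,
        cohort: Sequence[Trajectory],
        vocab: TokenVocabulary,
        config: ModelConfig | None = None,
        prepare: bool = False,
        prepare_seed: int = 0,
    ):
        if prepare:
            cohort = prepare_cohort(cohort, vocab, seed=prepare_seed)
        self.cohort = list(cohort)
        self.vocab = vocab
        self.config = config or ModelConfig.desk_scale(len(vocab))

    @classmethod
    def from_tsv(
        cls,
        data_path,
        vocab_path,
        config: ModelConfig | None = None,
        **kw,
    ) -> "DiseaseTrajectoryModel":
        vocab = TokenVocabulary.read_tsv(vocab_path)
        cohort = read_trajectories(data_path, vocab)
        return cls(cohort, vocab, config=config, **kw)

    def fit(
        self,
        train_config: _training.TrainConfig | None = None,
        checkpoint_dir=None,
        verbose: bool = False,
    ) -> "TrajectoryModelResults":
        cfg = train_config or _training.TrainConfig.desk_scale()
        net = TrajectoryTransformer(self.config, self.vocab, seed=cfg.seed)
        callback = None
        if verbose:
            def callback(it, row):  # noqa: E306
                print(
                    f"iter {it:>7d}  lr {row['lr']:.2e}  "
                    f"token {row['token_loss']:.4f}  time {row['time_loss']:.4f}"
                )
        trace = _training.fit(
            net, self.cohort, cfg, checkpoint_dir=checkpoint_dir, callback=callback
        )
        return TrajectoryModelResults(net, trace, cfg)


class TrajectoryModelResults:
    """A fitted trajectory transformer with its diagnostics."""

    def __init__(
        self,
        network: TrajectoryTransformer,
        loss_trace: pd.DataFrame,
        train_config: _training.TrainConfig | None = None,
    ):
        self.network = network
        self.loss_trace = loss_trace
        self.train_config = train_config
        self.vocab = network.vocab
        self.config = network.config

    # -- prediction ---------------------------------------------------
    def predict_rates(self, traj: Trajectory) -> np.ndarray:
        """Per-token event rates (events/day) at the last position."""
        return self.network.rate_vector(traj)

    def predict_annual_risk(self, traj: Trajectory) -> np.ndarray:
        """Per-token P(event within a year) at the last position."""
        return _evaluation.annual_risk_from_rate(self.predict_rates(traj))

    # -- generation ---------------------------------------------------
    def sample(
        self, prompt: Trajectory, stop_age_years: float = 80.0, seed: int = 0,
        **kw,
    ) -> Trajectory:
        return _sampling.rollout(
            prompt, self.network, stop_age_years, seed=seed, **kw
        )

    def generate_cohort(self, n: int, seed: int = 0, **kw) -> list[Trajectory]:
        return _sampling.generate_cohort(n, self.network, seed=seed, **kw)

    # -- evaluation ---------------------------------------------------
    def evaluate(
        self, cohort: Sequence[Trajectory], cutoff_age_years: float, **kw
    ) -> _evaluation.EvalReport:
        return _evaluation.longitudinal_eval(
            list(cohort), self.network, cutoff_age_years, **kw
        )

    # -- interpretation -----------------------------------------------
    def shapley(self, traj: Trajectory, **kw) -> _attribution.AttributionResult:
        return _attribution.shapley_attribution(traj, self.network, **kw)

    def embeddings(self, top_k: int = 5):
        return _attribution.export_embeddings(self.network, top_k=top_k)

    # -- reporting ----------------------------------------------------
    def summary(self) -> str:
        cfg = self.config
        last = self.loss_trace.iloc[-1] if len(self.loss_trace) else None
        lines = [
            "Disease trajectory transformer — fit summary",
            "=" * 52,
            f"vocabulary size      {cfg.vocab_size}",
            f"embedding dim        {cfg.embed_dim}",
            f"layers / heads       {cfg.n_layers} / {cfg.n_heads}",
            f"trainable params     {count_parameters(cfg):,}",
            f"weight tying         {cfg.tie_weights}",
        ]
        if self.train_config is not None:
            tc = self.train_config
            lines += [
                f"iterations           {tc.total_iters:,} (batch {tc.batch_size})",
                f"learning rate        {tc.lr_max:g} -> {tc.lr_min:g} (cosine)",
            ]
        if last is not None:
            lines += [
                "-" * 52,
                f"final token loss     {last['token_loss']:.4f} nats/event",
                f"final time loss      {last['time_loss']:.4f} nats/event",
                f"final total loss     {last['total']:.4f} nats/event",
            ]
        return "\n".join(lines)

    # -- persistence --------------------------------------------------
    def save(self, directory) -> None:
        directory = Path(directory)
        self.network.save(directory)
        self.loss_trace.to_csv(directory / "loss_trace.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, directory, vocab=None) -> "TrajectoryModelResults":
        directory = Path(directory)
        net = TrajectoryTransformer.load(directory, vocab=vocab)
        trace_path = directory / "loss_trace.tsv"
        trace = (
            pd.read_csv(trace_path, sep="\t") if trace_path.exists() else pd.DataFrame()
        )
        return cls(net, trace)
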