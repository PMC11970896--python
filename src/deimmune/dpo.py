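"""Direct preference optimization (DPO) against immune-visibility feedback.

The alignment loop tunes a design model so that, for a backbone prompt x, it
prefers generating the less MHC-I-visible of two of its own candidate
sequences.  For each training backbone the *current* model samples two
designs; a fast PWM presentation classifier scores their visibility; the less
visible one becomes the preferred response y_w, the other y_l (ties are
dropped — DPO needs a strict preference).  The loss per pair is

    L = -log sigma( beta * [ (log pi_theta(y_w|x) - log pi_ref(y_w|x))
                           - (log pi_theta(y_l|x) - log pi_ref(y_l|x)) ] )

with pi_ref the frozen base model and beta controlling how far the tuned
policy may drift from it.  The preference dataset is regenerated from the
current model every ``epochs_per_refresh`` epochs (default 2) so that the
model keeps moving away from its own current outputs; the reference
likelihoods always come from the base model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, log_softmax
from scipy.stats import loguniform, uniform

from ._optim import Adam, clip_grad_norm
from .alphabet import encode_sequence
from .presentation import PresentationPredictor
from .sequence_model import BatchConfig, InverseFoldingModel
from .structure import BackboneStructure
from .visibility import absolute_visibility

__all__ = [
    "DPOHyperparams",
    "HYPERPARAM_PRESETS",
    "PreferencePair",
    "generate_preference_pair",
    "build_preference_dataset",
    "dpo_loss",
    "DPOAligner",
    "DPOResults",
    "align",
    "default_sweep_distributions",
    "sample_hyperparams",
    "hyperparameter_sweep",
    "mean_sample_visibility",
    "mean_policy_kl",
    "write_preference_jsonl",
    "read_preference_jsonl",
]


@dataclass(frozen=True)
class DPOHyperparams:
    """Tuning knobs of one alignment run.

    ``sampling_temperature`` governs preference-pair generation only; design
    generation for evaluation uses its own fixed low temperature (0.1).
    The defaults are sized for the mini model's readout head; the published
    full-scale configurations are available in :data:`HYPERPARAM_PRESETS`.
    """

    beta: float = 0.05
    sampling_temperature: float = 0.5
    learning_rate: float = 2e-2
    epochs_per_refresh: int = 2

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if not 0 < self.sampling_temperature <= 1:
            raise ValueError("sampling_temperature must be in (0, 1]")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs_per_refresh < 1:
            raise ValueError("epochs_per_refresh must be >= 1")


#: Named full-scale tuning configurations from the published sweep.
HYPERPARAM_PRESETS: dict[str, DPOHyperparams] = {
    "458340e4": DPOHyperparams(
        beta=3.43e-2, sampling_temperature=0.759, learning_rate=2.86e-6
    ),
    "e32b8ed0": DPOHyperparams(
        beta=4.48e-3, sampling_temperature=0.500, learning_rate=4.62e-7
    ),
}


@dataclass
class PreferencePair:
    """One DPO training example: (prompt, preferred, dispreferred).

    ``visibility_w < visibility_l`` strictly; the reference log-likelihoods
    are computed once with the frozen base model and never change.
    """

    structure_ref: str
    y_w: str
    y_l: str
    order_w: np.ndarray
    order_l: np.ndarray
    ref_log_prob_w: float
    ref_log_prob_l: float
    visibility_w: int
    visibility_l: int

    # Cached teacher-forced decoder contexts (frozen trunk => reusable).
    ctx_w: np.ndarray | None = field(default=None, repr=False, compare=False)
    ctx_l: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.visibility_w < self.visibility_l:
            raise ValueError(
                "preference pairs require strictly lower visibility for y_w"
            )

    def to_json_dict(self) -> dict:
        return {
            "structure_ref": self.structure_ref,
            "y_w": self.y_w,
            "y_l": self.y_l,
            "order_w": np.asarray(self.order_w).tolist(),
            "order_l": np.asarray(self.order_l).tolist(),
            "ref_log_prob_w": self.ref_log_prob_w,
            "ref_log_prob_l": self.ref_log_prob_l,
            "visibility_w": self.visibility_w,
            "visibility_l": self.visibility_l,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "PreferencePair":
        return cls(
            structure_ref=d["structure_ref"],
            y_w=d["y_w"],
            y_l=d["y_l"],
            order_w=np.asarray(d["order_w"], dtype=int),
            order_l=np.asarray(d["order_l"], dtype=int),
            ref_log_prob_w=float(d["ref_log_prob_w"]),
            ref_log_prob_l=float(d["ref_log_prob_l"]),
            visibility_w=int(d["visibility_w"]),
            visibility_l=int(d["visibility_l"]),
        )


def write_preference_jsonl(pairs: Sequence[PreferencePair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(json.dumps(p.to_json_dict()) + "\n")


def read_preference_jsonl(path: str | Path) -> list[PreferencePair]:
    return [
        PreferencePair.from_json_dict(json.loads(line))
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]


def generate_preference_pair(
    current_model: InverseFoldingModel,
    base_model: InverseFoldingModel,
    structure: BackboneStructure,
    predictor: PresentationPredictor,
    temperature: float = 0.5,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    structure_ref: str | None = None,
) -> PreferencePair | None:
    """Sample two candidates from the current model and rank by visibility.

    Returns ``None`` when the two candidates tie in visibility (no strict
    preference exists).  Reference log-likelihoods come from *base_model*
    under each candidate's own decoding order.
    """
    if current_model.config != base_model.config:
        raise ValueError("current and base model must share a configuration")
    if rng is None:
        rng = np.random.default_rng(seed)
    enc = current_model.encode_backbone(structure)
    a = current_model.sample_sequence(enc, temperature=temperature, rng=rng)
    b = current_model.sample_sequence(enc, temperature=temperature, rng=rng)
    vis_a = absolute_visibility(a.sequence, predictor).absolute_visibility
    vis_b = absolute_visibility(b.sequence, predictor).absolute_visibility
    if vis_a == vis_b:
        return None
    (win, vw), (lose, vl) = sorted(
        [(a, vis_a), (b, vis_b)], key=lambda t: t[1]
    )
    ctx_w = current_model.decoding_contexts(enc, win.sequence, win.order)
    ctx_l = current_model.decoding_contexts(enc, lose.sequence, lose.order)
    ref_w = base_model.log_prob_from_contexts(ctx_w, encode_sequence(win.sequence))
    ref_l = base_model.log_prob_from_contexts(ctx_l, encode_sequence(lose.sequence))
    return PreferencePair(
        structure_ref=structure_ref or structure.name or "structure",
        y_w=win.sequence,
        y_l=lose.sequence,
        order_w=win.order,
        order_l=lose.order,
        ref_log_prob_w=ref_w,
        ref_log_prob_l=ref_l,
        visibility_w=vw,
        visibility_l=vl,
        ctx_w=ctx_w,
        ctx_l=ctx_l,
    )


def build_preference_dataset(
    current_model: InverseFoldingModel,
    base_model: InverseFoldingModel,
    structures: Sequence[BackboneStructure],
    predictor: PresentationPredictor,
    temperature: float = 0.5,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> list[PreferencePair]:
    """One preference pair per structure (ties dropped)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    pairs = []
    for s in structures:
        pair = generate_preference_pair(
            current_model, base_model, s, predictor, temperature, rng=rng
        )
        if pair is not None:
            pairs.append(pair)
    return pairs


def dpo_loss(
    pair: PreferencePair,
    policy_log_prob_w: float,
    policy_log_prob_l: float,
    beta: float,
) -> float:
    """-log sigma(beta * (Delta_w - Delta_l)) for one preference pair.

    ``Delta = log pi_theta - log pi_ref``.  At the identity policy
    (Delta_w = Delta_l = 0) the loss equals log 2 for any beta, and it is
    strictly decreasing in the preference margin.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    values = [
        policy_log_prob_w,
        policy_log_prob_l,
        pair.ref_log_prob_w,
        pair.ref_log_prob_l,
    ]
    if not np.all(np.isfinite(values)):
        raise ValueError("log-probabilities must be finite")
    margin = beta * (
        (policy_log_prob_w - pair.ref_log_prob_w)
        - (policy_log_prob_l - pair.ref_log_prob_l)
    )
    return float(np.logaddexp(0.0, -margin))


def _pair_tokens(pair: PreferencePair) -> tuple[np.ndarray, np.ndarray]:
    return encode_sequence(pair.y_w), encode_sequence(pair.y_l)


def _batch_loss_and_grad(
    model: InverseFoldingModel, batch: Sequence[PreferencePair], beta: float
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean DPO loss and head gradient over cached-context pairs."""
    total = 0.0
    grads = {k: np.zeros_like(v) for k, v in model.head.items()}
    for pair in batch:
        tok_w, tok_l = _pair_tokens(pair)
        lp_w, g_w = model.log_prob_from_contexts(pair.ctx_w, tok_w, want_grad=True)
        lp_l, g_l = model.log_prob_from_contexts(pair.ctx_l, tok_l, want_grad=True)
        margin = beta * (
            (lp_w - pair.ref_log_prob_w) - (lp_l - pair.ref_log_prob_l)
        )
        total += float(np.logaddexp(0.0, -margin))
        coeff = -float(expit(-margin)) * beta  # dL/d(log pi_w - ...)
        for k in grads:
            grads[k] += coeff * (g_w[k] - g_l[k])
    n = len(batch)
    return total / n, {k: v / n for k, v in grads.items()}


@dataclass
class DPOResults:
    """Outcome of one alignment run."""

    model: InverseFoldingModel
    base_model: InverseFoldingModel
    hyperparams: DPOHyperparams
    checkpoints: dict[int, InverseFoldingModel]
    history: list[dict]
    refresh_stats: list[dict]
    total_epochs: int
    diverged: bool = False
    divergence_message: str = ""

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)

    def summary(self) -> str:
        """Human-readable account of the run."""
        lines = [
            "DPO alignment results",
            "=" * 52,
            f"beta                 {self.hyperparams.beta:.4g}",
            f"sampling temperature {self.hyperparams.sampling_temperature:.4g}",
            f"learning rate        {self.hyperparams.learning_rate:.4g}",
            f"epochs per refresh   {self.hyperparams.epochs_per_refresh}",
            f"epochs run           {len(self.history)} / {self.total_epochs}",
            f"checkpoints          {sorted(self.checkpoints)}",
            f"diverged             {self.diverged}"
            + (f" ({self.divergence_message})" if self.diverged else ""),
            "-" * 52,
            f"{'epoch':>5} {'pairs':>5} {'mean loss':>10} {'mean vis_w':>10} {'mean vis_l':>10}",
        ]
        for row in self.history:
            lines.append(
                f"{row['epoch']:>5} {row['n_pairs']:>5} {row['mean_loss']:>10.4f} "
                f"{row['mean_visibility_w']:>10.2f} {row['mean_visibility_l']:>10.2f}"
            )
        return "\n".join(lines)


class DPOAligner:
    """Alignment model object: backbone prompts + preference feedback.

    statsmodels-style usage::

        aligner = DPOAligner(base_model, structures, predictor, hyperparams)
        results = aligner.fit(total_epochs=20, seed=0)
        print(results.summary())
    """

    def __init__(
        self,
        base_model: InverseFoldingModel,
        structures: Sequence[BackboneStructure],
        predictor: PresentationPredictor,
        hyperparams: DPOHyperparams | None = None,
        batch_config: BatchConfig | None = None,
    ) -> None:
        if not structures:
            raise ValueError("at least one training structure is required")
        self.base_model = base_model
        self.structures = list(structures)
        self.predictor = predictor
        self.hyperparams = hyperparams or DPOHyperparams()
        self.batch_config = batch_config or BatchConfig()

    def fit(
        self,
        total_epochs: int = 20,
        seed: int = 0,
        checkpoint_epochs: Iterable[int] = (2, 10, 20),
        batch_size: int = 8,
        grad_clip: float = 1.0,
    ) -> DPOResults:
        """Run the refresh/train loop and return a results object.

        Every ``epochs_per_refresh`` epochs a fresh preference dataset is
        generated from the *current* model; the reference model stays the
        frozen base.  Training aborts (with the results flagged diverged)
        on a non-finite loss or a sustained run of near-constant samples.
        """
        if total_epochs < 1:
            raise ValueError("total_epochs must be >= 1")
        hp = self.hyperparams
        rng = np.random.default_rng(seed)
        model = self.base_model.copy()
        opt = Adam(hp.learning_rate)
        checkpoint_epochs = set(int(e) for e in checkpoint_epochs)
        checkpoints: dict[int, InverseFoldingModel] = {}
        history: list[dict] = []
        refresh_stats: list[dict] = []
        diverged = False
        message = ""
        pairs: list[PreferencePair] = []
        gibberish_streak = 0

        for epoch in range(1, total_epochs + 1):
            if (epoch - 1) % hp.epochs_per_refresh == 0:
                pairs = []
                for s in self.structures:
                    pair = generate_preference_pair(
                        model,
                        self.base_model,
                        s,
                        self.predictor,
                        hp.sampling_temperature,
                        rng=rng,
                    )
                    if pair is None:
                        continue
                    for seq in (pair.y_w, pair.y_l):
                        top = max(seq.count(c) for c in set(seq)) / len(seq)
                        gibberish_streak = gibberish_streak + 1 if top > 0.9 else 0
                    if gibberish_streak >= 10:
                        diverged = True
                        message = (
                            "sampled sequences collapsed to near-constant chains "
                            "(>90% single amino acid for 10 consecutive samples)"
                        )
                        break
                    pairs.append(pair)
                if diverged:
                    break
                refresh_stats.append(
                    {
                        "epoch": epoch,
                        "n_pairs": len(pairs),
                        "mean_visibility_w": float(
                            np.mean([p.visibility_w for p in pairs]) if pairs else np.nan
                        ),
                        "mean_visibility_l": float(
                            np.mean([p.visibility_l for p in pairs]) if pairs else np.nan
                        ),
                    }
                )
            if not pairs:
                # Preference signal saturated (all candidate pairs tied):
                # nothing to train on this epoch, model stays as-is.
                history.append(
                    {
                        "epoch": epoch,
                        "n_pairs": 0,
                        "n_batches": 0,
                        "mean_loss": np.nan,
                        "mean_visibility_w": np.nan,
                        "mean_visibility_l": np.nan,
                    }
                )
                if epoch in checkpoint_epochs:
                    checkpoints[epoch] = model.copy()
                continue

            perm = rng.permutation(len(pairs))
            epoch_losses = []
            batch: list[PreferencePair] = []
            batch_tokens = 0
            batches: list[list[PreferencePair]] = []
            for i in perm:
                p = pairs[i]
                tokens = len(p.y_w) + len(p.y_l)
                if batch and (
                    len(batch) >= batch_size
                    or batch_tokens + tokens > self.batch_config.max_tokens_per_batch
                ):
                    batches.append(batch)
                    batch, batch_tokens = [], 0
                batch.append(p)
                batch_tokens += tokens
            if batch:
                batches.append(batch)
            for b in batches:
                loss, grads = _batch_loss_and_grad(model, b, hp.beta)
                if not np.isfinite(loss):
                    diverged = True
                    message = f"non-finite DPO loss at epoch {epoch}"
                    break
                grads = clip_grad_norm(grads, grad_clip)
                opt.step(model.head, grads)
                epoch_losses.append(loss)
            if diverged:
                break
            history.append(
                {
                    "epoch": epoch,
                    "n_pairs": len(pairs),
                    "n_batches": len(batches),
                    "mean_loss": float(np.mean(epoch_losses)),
                    "mean_visibility_w": float(np.mean([p.visibility_w for p in pairs])),
                    "mean_visibility_l": float(np.mean([p.visibility_l for p in pairs])),
                }
            )
            if epoch in checkpoint_epochs:
                checkpoints[epoch] = model.copy()

        return DPOResults(
            model=model,
            base_model=self.base_model,
            hyperparams=hp,
            checkpoints=checkpoints,
            history=history,
            refresh_stats=refresh_stats,
            total_epochs=total_epochs,
            diverged=diverged,
            divergence_message=message,
        )


def align(
    base_model: InverseFoldingModel,
    structures: Sequence[BackboneStructure],
    predictor: PresentationPredictor,
    hyperparams: DPOHyperparams | None = None,
    total_epochs: int = 20,
    seed: int = 0,
    checkpoint_epochs: Iterable[int] = (2, 10, 20),
) -> DPOResults:
    """Functional wrapper around :class:`DPOAligner`."""
    return DPOAligner(base_model, structures, predictor, hyperparams).fit(
        total_epochs=total_epochs, seed=seed, checkpoint_epochs=checkpoint_epochs
    )


def mean_sample_visibility(
    model: InverseFoldingModel,
    structures: Sequence[BackboneStructure],
    predictor: PresentationPredictor,
    temperature: float = 0.1,
    n_per_structure: int = 1,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> float:
    """Mean absolute visibility of sampled designs over *structures*."""
    if rng is None:
        rng = np.random.default_rng(seed)
    values = []
    for s in structures:
        enc = model.encode_backbone(s)
        for _ in range(n_per_structure):
            seq = model.sample_sequence(enc, temperature=temperature, rng=rng).sequence
            values.append(absolute_visibility(seq, predictor).absolute_visibility)
    return float(np.mean(values))


def mean_policy_kl(
    model: InverseFoldingModel,
    base_model: InverseFoldingModel,
    structures: Sequence[BackboneStructure],
    n_per_structure: int = 2,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> float:
    """Mean per-token KL(pi_model || pi_base) on base-model samples.

    Measures how far the tuned policy's next-token distributions have moved
    from the frozen reference at matched contexts.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    kls = []
    for s in structures:
        enc_m = model.encode_backbone(s)
        enc_b = base_model.encode_backbone(s)
        for _ in range(n_per_structure):
            sample = base_model.sample_sequence(enc_b, temperature=1.0, rng=rng)
            ctx = model.decoding_contexts(enc_m, sample.sequence, sample.order)
            lp_m = log_softmax(model.logits(ctx), axis=1)
            lp_b = log_softmax(base_model.logits(ctx), axis=1)
            kls.append(float((np.exp(lp_m) * (lp_m - lp_b)).sum(1).mean()))
    return float(np.mean(kls))


def default_sweep_distributions() -> dict:
    """Published sweep distributions: log-uniform beta and learning rate."""
    return {
        "beta": loguniform(0.001, 0.2),
        "sampling_temperature": uniform(loc=0.01, scale=0.99),
        "learning_rate": loguniform(1e-7, 1e-3),
    }


def sample_hyperparams(
    rng: np.random.Generator, distributions: dict | None = None
) -> DPOHyperparams:
    """Draw one hyperparameter set from the sweep distributions."""
    dists = distributions or default_sweep_distributions()
    return DPOHyperparams(
        beta=float(dists["beta"].rvs(random_state=rng)),
        sampling_temperature=float(dists["sampling_temperature"].rvs(random_state=rng)),
        learning_rate=float(dists["learning_rate"].rvs(random_state=rng)),
    )


def hyperparameter_sweep(
    base_model: InverseFoldingModel,
    structures: Sequence[BackboneStructure],
    predictor: PresentationPredictor,
    n_runs: int,
    seed: int = 0,
    distributions: dict | None = None,
    total_epochs: int = 20,
    checkpoint_epochs: Iterable[int] = (2, 10, 20),
    eval_structures: Sequence[BackboneStructure] | None = None,
) -> pd.DataFrame:
    """Random-search sweep: one aligned run per sampled hyperparameter set.

    Per run and checkpoint the mean visibility and mean sequence recovery of
    single-sample designs on *eval_structures* (default: the training
    structures) are recorded.  Diverged runs are kept in the table with
    ``status='diverged'``; they are not fatal.
    """
    from .design_eval import evaluate_checkpoint  # local import: one-way deps

    rng = np.random.default_rng(seed)
    eval_structures = list(eval_structures or structures)
    rows = []
    for run in range(n_runs):
        hp = sample_hyperparams(rng, distributions)
        run_seed = int(rng.integers(0, 2**31 - 1))
        results = DPOAligner(base_model, structures, predictor, hp).fit(
            total_epochs=total_epochs,
            seed=run_seed,
            checkpoint_epochs=checkpoint_epochs,
        )
        status = "diverged" if results.diverged else "completed"
        checkpoint_items = sorted(results.checkpoints.items())
        if not results.diverged and not checkpoint_items:
            checkpoint_items = [(len(results.history), results.model)]
        for epoch, ckpt in checkpoint_items:
            record = evaluate_checkpoint(
                ckpt,
                eval_structures,
                predictor,
                structure_backend=None,
                protocol="single",
                rng=np.random.default_rng(run_seed + epoch),
                checkpoint_id=f"run{run}:epoch_{epoch}",
            )
            rows.append(
                {
                    "run": run,
                    "status": status,
                    "beta": hp.beta,
                    "sampling_temperature": hp.sampling_temperature,
                    "learning_rate": hp.learning_rate,
                    "checkpoint_epoch": epoch,
                    "mean_relative_visibility": record.mean_relative_visibility,
                    "mean_visibility": record.mean_visibility,
                    "mean_sequence_recovery": record.mean_sequence_recovery,
                }
            )
        if results.diverged and not checkpoint_items:
            rows.append(
                {
                    "run": run,
                    "status": status,
                    "beta": hp.beta,
                    "sampling_temperature": hp.sampling_temperature,
                    "learning_rate": hp.learning_rate,
                    "checkpoint_epoch": None,
                    "mean_relative_visibility": np.nan,
                    "mean_visibility": np.nan,
                    "mean_sequence_recovery": np.nan,
                }
            )
    columns = [
        "run",
        "status",
        "beta",
        "sampling_temperature",
        "learning_rate",
        "checkpoint_epoch",
        "mean_relative_visibility",
        "mean_visibility",
        "mean_sequence_recovery",
    ]
    return pd.DataFrame(rows, columns=columns)
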