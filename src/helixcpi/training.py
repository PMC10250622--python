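"""Training loop, model selection and evaluation statistics.

Models are trained with Adam on binary cross-entropy; after every epoch
the validation AUC is computed and the parameters at the best
validation epoch are the selected model. AUC is the tie-aware rank
(Mann-Whitney) statistic; split-wise comparisons between two models use
a one-sided paired t-test across the per-split AUCs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from . import nn
from .corpus import InteractionRecord, ReceptorRecord
from .decoder import CPIModel, predict_batch
from .encoder import EncoderConfig
from .protein_features import segment_corpus, train_word2vec

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation knobs (published values unavailable; defaults documented)."""
    epochs: int = 100
    batch_size: int = 64
    lr: float = 1e-3
    clip_norm: float = 0.0  # 0 disables gradient clipping
    weight_decay: float = 0.0
    #: linear learning-rate ramp; without it the decoder head overfits
    #: ligand identity in the first epochs and the protein pathway starts
    #: from a poor basin
    warmup_epochs: int = 3
    seed: int = 0
    w2v_epochs: int = 2


@dataclass
class TrainLog:
    train_loss: list[float] = field(default_factory=list)
    val_auc: list[float] = field(default_factory=list)

    @property
    def selected_epoch(self) -> int:
        return int(np.argmax(self.val_auc))

    @property
    def best_val_auc(self) -> float:
        return float(np.max(self.val_auc))


@dataclass
class EvalReport:
    roc: list[tuple[float, float]]
    auc: float
    per_subfamily: dict[str, tuple[int, float | None]]
    split_id: int | None = None


def compute_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Tie-aware rank AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def roc_points(scores: Sequence[float], labels: Sequence[int]
               ) -> list[tuple[float, float]]:
    from sklearn.metrics import roc_curve
    fpr, tpr, _ = roc_curve(labels, scores)
    return list(zip(fpr.tolist(), tpr.tolist()))


def mean_auc(per_split_aucs: Sequence[float]) -> float:
    if len(per_split_aucs) == 0:
        raise ValueError("need at least one AUC")
    return float(np.mean(per_split_aucs))


def paired_one_sided_ttest(a: Sequence[float], b: Sequence[float]
                           ) -> tuple[float, float]:
    """One-sided paired t-test of H1: mean(b - a) > 0.

    Returns (t, p) with df = n-1. With zero variance of the differences
    the statistic is degenerate: p = 0 if the mean difference is
    positive, else 1 (with a warning).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors of >= 2 AUCs")
    diff = b - a
    if np.std(diff, ddof=1) == 0:
        warnings.warn("zero variance of paired differences; degenerate t-test")
        mean = diff.mean()
        return (float("inf") if mean > 0 else (0.0 if mean == 0 else float("-inf")),
                0.0 if mean > 0 else 1.0)
    t, p = stats.ttest_rel(b, a, alternative="greater")
    return float(t), float(p)


def subfamily_auc(results, subfamilies: Mapping[str, str]
                  ) -> dict[str, tuple[int, float | None]]:
    """Within-subfamily AUC; single-label subfamilies report None.

    ``results`` is an iterable of objects with .accession, .probability
    and .label (e.g. PredictionResult with known labels).
    """
    groups: dict[str, list] = {}
    for r in results:
        fam = subfamilies.get(r.accession, "unassigned")
        groups.setdefault(fam, []).append(r)
    out: dict[str, tuple[int, float | None]] = {}
    for fam, rs in sorted(groups.items()):
        labels = [1 if r.label == "positive" else 0 for r in rs]
        if len(set(labels)) < 2:
            out[fam] = (len(rs), None)
        else:
            out[fam] = (len(rs), compute_auc([r.probability for r in rs], labels))
    return out


def _auc_of(results) -> float:
    return compute_auc([r.probability for r in results],
                       [1 if r.label == "positive" else 0 for r in results])


def build_model(config: EncoderConfig, train_records: Sequence[InteractionRecord],
                receptors: Mapping[str, ReceptorRecord],
                train_config: TrainConfig) -> CPIModel:
    """Initialise a model, training word2vec on the training split only."""
    train_accs = sorted({r.accession for r in train_records})
    corpus = segment_corpus((receptors[a] for a in train_accs if a in receptors),
                            include_ecls=config.include_ecls,
                            whole_sequence=config.whole_sequence)
    vocab = train_word2vec(corpus, seed=train_config.seed,
                           dim=config.embed_dim, epochs=train_config.w2v_epochs)
    return CPIModel(config, vocab, seed=train_config.seed)


def train(config: EncoderConfig, train_records: Sequence[InteractionRecord],
          val_records: Sequence[InteractionRecord],
          receptors: Mapping[str, ReceptorRecord],
          train_config: TrainConfig | None = None,
          ) -> tuple[CPIModel, TrainLog]:
    """Train and return the model at its best validation-AUC epoch."""
    tc = train_config or TrainConfig()
    if not train_records or not val_records:
        raise ValueError("train and validation splits must be non-empty")
    if len({r.label for r in val_records}) < 2:
        raise ValueError("validation split needs both labels (AUC undefined)")
    if len({r.label for r in train_records}) < 2:
        raise ValueError("training split needs both labels")

    model = build_model(config, train_records, receptors, tc)

    # featurise once; drop records we cannot featurise
    usable: list[InteractionRecord] = []
    for r in train_records:
        if r.accession not in receptors:
            logger.info("train record %s dropped: unknown accession", r.accession)
            continue
        try:
            model.featurize_compound(r.smiles)
            model.featurize_receptor(receptors[r.accession])
        except Exception as exc:
            logger.info("train record (%s, %s) dropped: %s", r.accession, r.smiles, exc)
            continue
        usable.append(r)

    rng = np.random.default_rng(tc.seed)
    optim = nn.Adam(model.parameters(), lr=tc.lr, weight_decay=tc.weight_decay)
    log = TrainLog()
    best_state = None
    best_auc = -1.0
    n = len(usable)
    labels = np.array([r.y for r in usable], dtype=np.float32)

    for epoch in range(tc.epochs):
        if tc.warmup_epochs and epoch < tc.warmup_epochs:
            optim.lr = tc.lr * (epoch + 1) / (tc.warmup_epochs + 1)
        else:
            optim.lr = tc.lr
        order = rng.permutation(n)
        losses = []
        for s0 in range(0, n, tc.batch_size):
            sel = order[s0:s0 + tc.batch_size]
            batch = [usable[i] for i in sel]
            accs = [r.accession for r in batch]
            uniq = sorted(set(accs))
            acc_to_u = {a: j for j, a in enumerate(uniq)}
            stacks = [model.featurize_receptor(receptors[a]) for a in uniq]
            idx = np.array([acc_to_u[a] for a in accs])
            graphs = [model.featurize_compound(r.smiles) for r in batch]
            logits, _, _ = model.forward(stacks, idx, graphs)
            loss = nn.bce_with_logits(logits, labels[sel])
            optim.zero_grad()
            loss.backward()
            if tc.clip_norm:
                optim.clip_grad_norm(tc.clip_norm)
            optim.step()
            losses.append(float(loss.data))
        log.train_loss.append(float(np.mean(losses)))
        val_results, _ = predict_batch(model, val_records, receptors,
                                       batch_size=tc.batch_size)
        auc = _auc_of(val_results)
        log.val_auc.append(auc)
        if auc > best_auc:
            best_auc = auc
            best_state = model.state()
        logger.info("epoch %d: loss %.4f val AUC %.4f", epoch, log.train_loss[-1], auc)

    model.load_state(best_state)
    return model, log


def evaluate(model: CPIModel, test_records: Sequence[InteractionRecord],
             receptors: Mapping[str, ReceptorRecord],
             subfamilies: Mapping[str, str] | None = None,
             split_id: int | None = None, batch_size: int = 64) -> EvalReport:
    results, _ = predict_batch(model, test_records, receptors, batch_size=batch_size)
    scores = [r.probability for r in results]
    labels = [1 if r.label == "positive" else 0 for r in results]
    per_subfamily = subfamily_auc(results, subfamilies) if subfamilies else {}
    return EvalReport(roc=roc_points(scores, labels),
                      auc=compute_auc(scores, labels),
                      per_subfamily=per_subfamily, split_id=split_id)


def write_roc_csv(report: EvalReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("fpr,tpr\n")
        for fpr, tpr in report.roc:
            fh.write(f"{fpr:.6f},{tpr:.6f}\n")


def plot_roc(report: EvalReport, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fpr, tpr = zip(*report.roc)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, label=f"AUC = {report.auc:.3f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
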