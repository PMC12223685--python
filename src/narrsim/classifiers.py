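"""Binary narrative classifiers behind a uniform train/predict contract.

Two backends:

* ``linear_baseline`` — binary (presence/absence) bag-of-words with
  class-weighted logistic regression.  Deterministic, trains in seconds on
  a CPU, and is the workhorse for exercising the simulation harness
  (splits, learning curves, subgroup evaluation) end to end.  Presence
  features rather than raw term counts keep long narratives from drowning
  rare signal tokens in length-correlated noise.
* ``compact_transformer`` — fine-tunes a compact pretrained transformer
  (distilBERT by default) for sequence classification with a class-weighted
  cross-entropy loss.  Requires the optional ``narrsim[transformer]`` extra
  (``transformers`` + ``torch``); model weights are loaded from a local
  cache path so no network access is needed at train time.

Both backends share the contract: class weights are balanced
inverse-frequency w_c = N / (2 N_c), the decision threshold is fixed at
0.5, and predictions are deterministic given the fitted state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

__all__ = [
    "ClassifierConfig",
    "FittedModel",
    "compute_class_weights",
    "train_classifier",
    "predict",
]

BACKENDS = ("linear_baseline", "compact_transformer")


@dataclass
class ClassifierConfig:
    backend: str = "linear_baseline"
    max_tokens: int = 512
    use_class_weights: bool = True
    epochs: int = 4
    learning_rate: float = 5e-5
    batch_size: int = 16
    seed: int = 0
    model_name: str = "distilbert-base-uncased"
    cache_dir: str | None = None

    def __post_init__(self) -> None:
        if self.backend not in BACKENDS:
            raise ValueError(f"unknown backend: {self.backend!r}")
        if self.max_tokens < 1:
            raise ValueError("max_tokens must be positive")
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")


@dataclass
class FittedModel:
    config: ClassifierConfig
    class_weights: tuple[float, float]  # (w_neg, w_pos)
    state: Any = field(repr=False, default=None)


def compute_class_weights(labels: Sequence[int]) -> tuple[float, float]:
    """Balanced inverse-frequency weights w_c = N / (2 N_c).

    The weighted sample mass is conserved: sum_c N_c * w_c = N, and a
    balanced input yields (1, 1).
    """
    y = np.asarray(labels)
    n = len(y)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos + n_neg != n:
        raise ValueError("labels must be binary 0/1")
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute class weights")
    return n / (2.0 * n_neg), n / (2.0 * n_pos)


def _truncate(texts: Sequence[str], max_tokens: int) -> list[str]:
    return [" ".join(t.split()[:max_tokens]) for t in texts]


def train_classifier(
    texts: Sequence[str], labels: Sequence[int], config: ClassifierConfig
) -> FittedModel:
    """Fit the configured backend on (texts, labels).

    Raises ValueError when only one class is present (a tiny stratified
    budget can produce this; callers should skip the cell, not silently fit)
    or when every text is empty.
    """
    if len(texts) != len(labels):
        raise ValueError("texts and labels must have equal length")
    if len(texts) < 2:
        raise ValueError("need at least 2 training examples")
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    weights = compute_class_weights(y) if config.use_class_weights else (1.0, 1.0)
    texts = _truncate(texts, config.max_tokens)
    if config.backend == "linear_baseline":
        state = _train_linear(texts, y, weights, config)
    else:
        state = _train_transformer(texts, y, weights, config)
    return FittedModel(config=config, class_weights=weights, state=state)


def predict(model: FittedModel, texts: Sequence[str]) -> list[int]:
    """One 0/1 label per input text, order preserving; [] maps to []."""
    if len(texts) == 0:
        return []
    texts = _truncate(texts, model.config.max_tokens)
    if model.config.backend == "linear_baseline":
        return _predict_linear(model.state, texts)
    return _predict_transformer(model.state, texts)


# ---------------------------------------------------------------------------
# Linear bag-of-words baseline
# ---------------------------------------------------------------------------
def _train_linear(texts, y, weights, config):
    from sklearn.feature_extraction.text import CountVectorizer
    from sklearn.linear_model import LogisticRegression

    # \b\w+\b keeps single-character jargon tokens ("v", "s") that the
    # default sklearn pattern would drop.
    vectorizer = CountVectorizer(token_pattern=r"(?u)\b\w+\b", lowercase=True,
                                 binary=True)
    try:
        X = vectorizer.fit_transform(texts)
    except ValueError as err:
        raise ValueError("training corpus is entirely empty") from err
    sample_weight = np.where(y == 1, weights[1], weights[0])
    clf = LogisticRegression(max_iter=2000, random_state=config.seed)
    clf.fit(X, y, sample_weight=sample_weight)
    return {"vectorizer": vectorizer, "clf": clf}


def _predict_linear(state, texts):
    X = state["vectorizer"].transform(texts)
    return [int(v) for v in state["clf"].predict(X)]


# ---------------------------------------------------------------------------
# Compact transformer backend (optional extra)
# ---------------------------------------------------------------------------
def _require_transformer_deps():
    try:
        import torch  # noqa: F401
        import transformers  # noqa: F401
    except ImportError as err:
        raise ImportError(
            "the compact_transformer backend requires the optional "
            "'transformer' extra; install with: pip install narrsim[transformer]"
        ) from err


def _train_transformer(texts, y, weights, config):
    _require_transformer_deps()
    import torch
    from torch.utils.data import DataLoader, TensorDataset
    from transformers import AutoModelForSequenceClassification, AutoTokenizer

    torch.manual_seed(config.seed)
    tokenizer = AutoTokenizer.from_pretrained(config.model_name, cache_dir=config.cache_dir)
    model = AutoModelForSequenceClassification.from_pretrained(
        config.model_name, num_labels=2, cache_dir=config.cache_dir
    )
    enc = tokenizer(
        list(texts),
        truncation=True,
        max_length=config.max_tokens,
        padding=True,
        return_tensors="pt",
    )
    dataset = TensorDataset(enc["input_ids"], enc["attention_mask"], torch.tensor(y))
    loader = DataLoader(dataset, batch_size=config.batch_size, shuffle=True,
                        generator=torch.Generator().manual_seed(config.seed))
    weight = torch.tensor([weights[0], weights[1]], dtype=torch.float32)
    loss_fn = torch.nn.CrossEntropyLoss(weight=weight)
    optim = torch.optim.AdamW(model.parameters(), lr=config.learning_rate)
    model.train()
    for _ in range(config.epochs):
        for input_ids, attention_mask, yb in loader:
            optim.zero_grad()
            logits = model(input_ids=input_ids, attention_mask=attention_mask).logits
            loss = loss_fn(logits, yb)
            loss.backward()
            optim.step()
    model.eval()
    return {"tokenizer": tokenizer, "model": model}


def _predict_transformer(state, texts):
    _require_transformer_deps()
    import torch

    tokenizer, model = state["tokenizer"], state["model"]
    preds: list[int] = []
    with torch.no_grad():
        for start in range(0, len(texts), 64):
            batch = list(texts[start : start + 64])
            enc = tokenizer(
                batch,
                truncation=True,
                max_length=model.config.max_position_embeddings,
                padding=True,
                return_tensors="pt",
            )
            logits = model(**enc).logits
            preds.extend(int(i) for i in logits.argmax(dim=1))
    return preds
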